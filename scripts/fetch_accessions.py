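#!/usr/bin/env python
"""Download the deposited Cistanche GenBank records into data/accessions/.

The accession-based checks in tests/test_acceptance.py need these records;
they are too large to ship in the repository, so run this once on a
machine with network access:

    python scripts/fetch_accessions.py
"""

from pathlib import Path
from urllib.request import urlopen

ACCESSIONS = {
    "MN614127": "Cistanche deserticola",
    "MN614128": "Cistanche salsa",
    "MN614129": "Cistanche sinensis",
    "MN614130": "Cistanche tubulosa",
    "NC_025642": "Cistanche phelypaea",
    "NC_034308": "Rehmannia glutinosa (reference)",
}

EFETCH = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
          "?db=nuccore&id={acc}&rettype=gbwithparts&retmode=text")


def main() -> None:
    outdir = Path(__file__).resolve().parent.parent / "data" / "accessions"
    outdir.mkdir(parents=True, exist_ok=True)
    for acc, label in ACCESSIONS.items():
        dest = outdir / f"{acc}.gb"
        if dest.exists():
            print(f"{acc} ({label}): already present")
            continue
        print(f"fetching {acc} ({label}) ...")
        with urlopen(EFETCH.format(acc=acc), timeout=60) as resp:
            data = resp.read()
        if not data.startswith(b"LOCUS"):
            raise RuntimeError(f"unexpected response for {acc}")
        dest.write_bytes(data)
        print(f"  wrote {dest} ({len(data)} bytes)")


if __name__ == "__main__":
    main()
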