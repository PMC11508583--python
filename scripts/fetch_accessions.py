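#!/usr/bin/env python
"""Download the 29 Chironomidae mitogenome GenBank records from NCBI.

Network helper — NOT part of the test suite or the offline analysis.
Saves one GenBank flat file per accession into the given directory;
``scripts/reproduce_full_analysis.py`` then runs the full comparative analysis
on them.

Usage:
    python scripts/fetch_accessions.py --email you@example.org --out-dir data/mitogenomes
"""

from __future__ import annotations

import argparse
import time
from pathlib import Path

from Bio import Entrez

#: The newly sequenced Conchapelopia togamaculosa mitogenome plus the 28
#: comparison genera.
ACCESSIONS = [
    "PP831866",
    "ON099430", "MZ150770", "ON838257", "MZ747091", "MZ261913",
    "MZ981734", "ON838256", "MZ981735", "OL753645", "ON838255",
    "MZ043575", "MZ127839", "MZ231025", "OM302504", "MZ231026",
    "MZ424311", "OP006251", "MZ041033", "MW837768", "MW846254",
    "MW373526", "ON838254", "MZ424312", "KT003702", "MW837770",
    "MW373525", "MW373524", "MZ475054",
]


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--email", required=True, help="NCBI Entrez contact email")
    ap.add_argument("--out-dir", type=Path, required=True)
    args = ap.parse_args()

    Entrez.email = args.email
    args.out_dir.mkdir(parents=True, exist_ok=True)
    for acc in ACCESSIONS:
        dest = args.out_dir / f"{acc}.gb"
        if dest.exists():
            print(f"{acc}: already present")
            continue
        with Entrez.efetch(db="nucleotide", id=acc, rettype="gb",
                           retmode="text") as handle:
            dest.write_text(handle.read())
        print(f"{acc}: saved")
        time.sleep(0.4)  # NCBI rate limit
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
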