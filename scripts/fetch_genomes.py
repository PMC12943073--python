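#!/usr/bin/env python
"""Download the study genomes from NCBI as GenBank flat files.

Optional helper — the test suite never requires network access.  Fetches
each accession of the packaged 20-species table via NCBI E-utilities and
writes ``<accession>.gbff`` files that ``ribotally report --genome-dir``
can consume.

Usage:
    python scripts/fetch_genomes.py --out-dir genomes/ [--email you@site]
"""

from __future__ import annotations

import argparse
import time
import urllib.parse
import urllib.request
from pathlib import Path

from ribotally.config import load_species_table

EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"


def fetch(accession: str, email: str) -> str:
    params = urllib.parse.urlencode(
        {
            "db": "nuccore",
            "id": accession,
            "rettype": "gbwithparts",
            "retmode": "text",
            "email": email,
            "tool": "ribotally",
        }
    )
    with urllib.request.urlopen(f"{EFETCH}?{params}", timeout=300) as resp:
        return resp.read().decode()


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out-dir", type=Path, required=True)
    parser.add_argument("--email", default="anonymous@example.org")
    parser.add_argument("--delay", type=float, default=0.5,
                        help="Seconds between requests (NCBI rate limit).")
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    for sp in load_species_table():
        for acc in sp.accessions:
            dest = args.out_dir / f"{acc}.gbff"
            if dest.exists():
                print(f"{acc}: already present")
                continue
            print(f"{acc}: fetching ({sp.species})")
            dest.write_text(fetch(acc, args.email))
            time.sleep(args.delay)


if __name__ == "__main__":
    main()
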