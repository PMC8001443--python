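#!/usr/bin/env python
"""Optional helper: fetch the two real casein precursor sequences.

The accession-dependent sequence facts (kappa-casein A precursor,
UniProt P02668: Pro composition 11.1 %; alpha-S2-casein A, UniProt
P02663: WIQP at positions 208-211) need the real sequences, which are
not bundled with the package.  Run this once with network access to
write ``data/accessions/caseins.fasta`` in the package's FASTA header
dialect; the corresponding test activates automatically once the file
exists.  Nothing else in the build requires this download.

Usage:
    python scripts/fetch_accessions.py
"""

from __future__ import annotations

import sys
import urllib.request
from pathlib import Path

ACCESSIONS = {
    "P02668": ("kappa", "A", "kappa-casein precursor (Bos taurus)"),
    "P02663": ("alphaS2", "A", "alpha-S2-casein precursor (Bos taurus)"),
}

OUT = Path(__file__).resolve().parents[1] / "data" / "accessions" / "caseins.fasta"


def main() -> None:
    records = []
    for acc, (fraction, variant, name) in ACCESSIONS.items():
        url = f"https://rest.uniprot.org/uniprotkb/{acc}.fasta"
        try:
            with urllib.request.urlopen(url, timeout=30) as resp:
                text = resp.read().decode()
        except OSError as exc:
            sys.exit(f"could not fetch {acc} from UniProt ({exc}); "
                     "network access is required")
        seq = "".join(line.strip() for line in text.splitlines()
                      if not line.startswith(">"))
        records.append(f">{acc}|{fraction}|{variant}|{name}\n{seq}\n")
    OUT.parent.mkdir(parents=True, exist_ok=True)
    OUT.write_text("".join(records))
    print(f"wrote {len(records)} records to {OUT}")


if __name__ == "__main__":
    main()
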