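#!/usr/bin/env python
"""Download the five His_Phos_1 PDB entries used by the worked example.

Fetches 1K6M, 5HTK, 6HVH (reference isotype) and 1YFK, 2A9J (truncation
isotype) from RCSB into data/his_phos_1/.  Needs network access; run once
before executing the His_Phos_1 acceptance test or
isodom.examples.his_phos_1_example().
"""

import sys
import urllib.request
from pathlib import Path

from isodom.examples import HIS_PHOS_1_PDB_IDS

DEST = Path(__file__).resolve().parents[1] / "data" / "his_phos_1"


def main() -> int:
    DEST.mkdir(parents=True, exist_ok=True)
    ids = [i for ids in HIS_PHOS_1_PDB_IDS.values() for i in ids]
    for pdb_id in ids:
        out = DEST / f"{pdb_id}.pdb"
        if out.exists():
            print(f"{pdb_id}: already present")
            continue
        url = f"https://files.rcsb.org/download/{pdb_id}.pdb"
        print(f"{pdb_id}: fetching {url}")
        with urllib.request.urlopen(url, timeout=60) as resp:
            out.write_bytes(resp.read())
    print(f"done; files in {DEST}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
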