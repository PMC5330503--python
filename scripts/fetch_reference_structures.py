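#!/usr/bin/env python
"""Download the worked-example PDB entries into data/reference_pdb.

Network access is required; entries come from https://files.rcsb.org.
Run once, then the worked-example analysis (analysis/05_worked_examples.py)
and the corresponding acceptance test can operate fully offline.
"""

from __future__ import annotations

import sys
import urllib.request
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from confdiv.examples import all_accessions


def main() -> int:
    out = ROOT / "data" / "reference_pdb"
    out.mkdir(parents=True, exist_ok=True)
    failures = []
    for code in all_accessions():
        dest = out / f"{code.lower()}.pdb"
        if dest.exists():
            print(f"have    {code}")
            continue
        url = f"https://files.rcsb.org/download/{code.upper()}.pdb"
        try:
            with urllib.request.urlopen(url, timeout=60) as resp:
                dest.write_bytes(resp.read())
            print(f"fetched {code}")
        except Exception as exc:
            failures.append(code)
            print(f"FAILED  {code}: {exc}", file=sys.stderr)
    if failures:
        print(f"{len(failures)} entries could not be fetched", file=sys.stderr)
        return 1
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
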