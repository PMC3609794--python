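#!/usr/bin/env python
"""Entropy-loss validation on locally downloaded public genome sequences.

Published reference points (not checked automatically here; the sequences
are large public downloads and are not bundled):

  GenBank AC018460 (BAC insert), k=30:   H=4.99782, dH=6.49%
  RefSeq NC_000913 (E. coli K-12), k=36: dH ~= 0.22%
  RefSeq NC_000908 (M. genitalium), k=500: dH = 0.00% at printed precision
  UCSC sacCer3 (S. cerevisiae), k=40:    dH ~= 0.683882%

Usage:
  python scripts/validate_public_genomes.py genome.fa 30 [36 ...]

Prints one TSV row per read length with H, H_max, dH% and repeat%.
For gigabase genomes add a prefix-partition depth as the last argument
prefixed with "m=", e.g. `... hg19.fa 60 m=5`.
"""

from __future__ import annotations

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from readentropy import assess, read_fasta  # noqa: E402


def main(argv: list[str]) -> int:
    if len(argv) < 2:
        print(__doc__, file=sys.stderr)
        return 2
    path = Path(argv[0])
    prefix_length = 0
    ks = []
    for arg in argv[1:]:
        if arg.startswith("m="):
            prefix_length = int(arg[2:])
        else:
            ks.append(int(arg))
    records = read_fasta(path)
    print("target\tk\tH\tH_max\tdelta_H\trepeat")
    for k in ks:
        res = assess(records, k, prefix_length)
        print(
            f"{path.name}\t{k}\t{res.H:.6f}\t{res.H_max:.6f}"
            f"\t{res.delta_H * 100:.6f}%\t{res.repeat_fraction * 100:.6f}%"
        )
    return 0


if __name__ == "__main__":
    raise SystemExit(main(sys.argv[1:]))
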