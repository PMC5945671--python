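#!/usr/bin/env python
"""Regenerate the packaged synthetic 30-signature fixture matrix.

Columns are sparse Dirichlet draws blended with a small flat floor, giving
well-separated, column-stochastic profiles (max pairwise cosine ~0.52) that
make NNLS refitting well conditioned. Deterministic; rerunning reproduces
src/scarsig/data/signatures30.tsv byte-identically.
"""

from pathlib import Path

import numpy as np

BASES = "ACGT"
SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
K = 30


def main() -> None:
    rng = np.random.default_rng(20180510)
    channels = [(f, s, t) for s in SUBS for f in BASES for t in BASES]
    W = rng.dirichlet(np.full(96, 0.2), size=K).T
    W = 0.9 * W + 0.1 / 96
    W /= W.sum(axis=0)
    out = Path(__file__).resolve().parent.parent / "src" / "scarsig" / "data" / "signatures30.tsv"
    with out.open("w") as fh:
        fh.write(
            "Substitution Type\tTrinucleotide\t"
            + "\t".join(f"AC{i + 1}" for i in range(K)) + "\n"
        )
        for i, (five, sub, three) in enumerate(channels):
            tri = five + sub[0] + three
            fh.write(f"{sub}\t{tri}\t" + "\t".join(f"{W[i, j]:.8f}" for j in range(K)) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
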