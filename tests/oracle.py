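"""Naive enumerate-everything reference for the substring-entropy statistics.

Deliberately independent of the package internals: plain dict counting
over explicit window enumeration, python math only.
"""

import math

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(s: str) -> str:
    return "".join(_COMP.get(c, "N") for c in reversed(s))


def count_windows(seqs, k):
    """Both-strand k-window counts, skipping windows with non-ACGT chars."""
    counts = {}
    for s in seqs:
        for strand in (s, revcomp(s)):
            for i in range(len(strand) - k + 1):
                w = strand[i : i + k]
                if all(c in _COMP for c in w):
                    counts[w] = counts.get(w, 0) + 1
    return counts


def entropy_stats(seqs, k):
    """(H, H_max, delta_H, repeat_fraction, N, n_distinct) or None if no windows."""
    counts = count_windows(seqs, k)
    N = sum(counts.values())
    if N == 0:
        return None
    H = -sum((c / N) * math.log10(c / N) for c in counts.values())
    H_max = math.log10(N)
    dH = (H_max - H) / H_max if H_max > 0 else 0.0
    rep = sum(c for c in counts.values() if c >= 2) / N
    return H, H_max, dH, rep, N, len(counts)
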