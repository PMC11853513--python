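"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use the most literal algorithm available -- exhaustive
loops over every alignment/window, per-column Counters -- and share no
code with the production paths they check.
"""

from collections import Counter
from itertools import product

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def naive_interacts(a: str, b: str, min_run: int = 6, min_gc: int = 3) -> bool:
    """Triple-loop duplex scan: every offset, every window start, extended base
    by base; qualifies on >= min_run consecutive complementary pairs holding
    >= min_gc G-C pairs."""
    br = b[::-1]
    la, lb = len(a), len(br)
    for offset in range(-(lb - 1), la):
        lo, hi = max(0, offset), min(la, lb + offset)
        for start in range(lo, hi):
            run = gc = 0
            for i in range(start, hi):
                if _COMP[a[i]] != br[i - offset]:
                    break
                run += 1
                gc += a[i] in "GC"
                if run >= min_run and gc >= min_gc:
                    return True
    return False


def enumerate_matching(pattern_sets) -> list[str]:
    """All sequences matching a list of allowed-nucleotide sets."""
    return ["".join(t) for t in product(*[sorted(s) for s in pattern_sets])]


def column_mode(seqs: list[str]) -> str:
    """Per-position mode with ties called N (no reference preference)."""
    out = []
    for col in zip(*seqs):
        counts = Counter(col)
        top = counts.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            out.append("N")
        else:
            out.append(top[0][0])
    return "".join(out)


def directional_merge_counts(umis_with_sizes: dict[str, int], d: int) -> int:
    """Number of families left after directional merging, computed naively.

    A family is absorbed by the largest family (ties by UMI) within Hamming
    distance <= d that is at least twice its (pre-merge) size; chains follow
    to their final absorber.
    """

    def hamming(x, y):
        return sum(p != q for p, q in zip(x, y))

    merged = {}
    for u, s in sorted(umis_with_sizes.items(), key=lambda kv: (kv[1], kv[0])):
        cands = [
            v
            for v, sv in umis_with_sizes.items()
            if v != u and v not in merged and sv >= 2 * s and hamming(u, v) <= d
        ]
        if cands:
            merged[u] = max(cands, key=lambda v: (umis_with_sizes[v], v))
    return len(umis_with_sizes) - len(merged)
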