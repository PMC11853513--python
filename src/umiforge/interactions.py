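"""UMI-UMI cross-hybridization simulation.

During multiplex library construction, UMI-bearing primers can anneal to
one another and prime non-specific products.  This module re-creates that
risk in silico: sample a population of UMIs from a design and count the
unordered pairs able to form a stable ungapped antiparallel duplex.

Stability rule (configurable): a pair interacts when some complementary
stretch spans at least ``min_run`` consecutive Watson-Crick base pairs of
which at least ``min_gc_pairs`` are G-C.  Because a longer stretch never
has fewer G-C pairs than a window inside it, the rule reduces to: some
maximal complementary stretch has length >= min_run and total G-C pairs
>= min_gc_pairs.  G-T wobble pairing is off by default and can be enabled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .patterns import UMIPattern, sample_umis

__all__ = [
    "InteractionRule",
    "InteractionHit",
    "InteractionResult",
    "reverse_complement",
    "interacts",
    "simulate_interactions",
    "compare_designs",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an A/C/G/T/N string."""
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid nucleotide(s) {sorted(bad)} in {seq!r}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class InteractionRule:
    """Thresholds for calling a UMI-UMI cross-hybridization.

    min_run
        Minimum number of consecutive complementary base pairs (default 6).
    min_gc_pairs
        Minimum G-C pairs required within the qualifying run (default 3).
    allow_wobble
        Count G.T wobble pairs as paired positions (never as G-C pairs).
        Off by default: the rule speaks of Watson-Crick and G-C pairing.
    """

    min_run: int = 6
    min_gc_pairs: int = 3
    allow_wobble: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.min_gc_pairs <= self.min_run):
            raise ValueError("need 1 <= min_gc_pairs <= min_run")


@dataclass(frozen=True)
class InteractionHit:
    """Outcome of one pair evaluation, with the best duplex found.

    ``offset`` is the shift of ``a`` relative to ``reverse_complement(b)``
    at which the best run occurs; ``run_length``/``gc_pairs`` describe that
    run.  ``interacting`` is the rule verdict.
    """

    interacting: bool
    run_length: int = 0
    gc_pairs: int = 0
    offset: int = 0

    def __bool__(self) -> bool:
        return self.interacting


def _pairs_vector(a: str, rb: str, offset: int, allow_wobble: bool):
    """Paired / G-C flags for `a` against revcomp-space `rb` at one offset.

    A position pairs when the characters match (complementarity in original
    space).  With wobble on, (G,A) and (T,C) in (a, rb) space -- i.e. G.T
    and T.G duplex pairs -- also count as paired, never as G-C.
    """
    lo = max(0, offset)
    hi = min(len(a), len(rb) + offset)
    out = []
    for i in range(lo, hi):
        x, y = a[i], rb[i - offset]
        if x == y:
            out.append((True, x in "GC"))
        elif allow_wobble and (x, y) in (("G", "A"), ("T", "C")):
            out.append((True, False))
        else:
            out.append((False, False))
    return out


def interacts(a: str, b: str, rule: InteractionRule = InteractionRule()) -> InteractionHit:
    """Evaluate whether two UMIs can form a stable cross-hybridization.

    Scans every ungapped antiparallel alignment of ``a`` against ``b``
    (equivalently, ``a`` against ``reverse_complement(b)``) for maximal
    complementary stretches; the pair interacts when some stretch reaches
    ``rule.min_run`` pairs with ``rule.min_gc_pairs`` G-C pairs among them.
    Symmetric in its two sequences.

    Sequences shorter than ``min_run`` cannot qualify; they return a
    non-interacting hit with a warning rather than an error.
    """
    a = a.upper()
    b = b.upper()
    if min(len(a), len(b)) < rule.min_run:
        warnings.warn(
            f"sequence shorter than min_run={rule.min_run}; cannot interact",
            stacklevel=2,
        )
        return InteractionHit(False)
    rb = reverse_complement(b)
    best_any = (-1, -1, 0)  # (run, gc, offset) of the longest run seen
    best_hit = (-1, -1, 0)  # same, restricted to qualifying runs
    for offset in range(-(len(rb) - 1), len(a)):
        run = gc = 0
        for paired, is_gc in _pairs_vector(a, rb, offset, rule.allow_wobble) + [(False, False)]:
            if paired:
                run += 1
                gc += is_gc
            else:
                if run:
                    if (run, gc) > best_any[:2]:
                        best_any = (run, gc, offset)
                    if (
                        run >= rule.min_run
                        and gc >= rule.min_gc_pairs
                        and (run, gc) > best_hit[:2]
                    ):
                        best_hit = (run, gc, offset)
                run = gc = 0
    if best_hit[0] > 0:
        return InteractionHit(True, *best_hit)
    if best_any[0] > 0:
        return InteractionHit(False, *best_any)
    return InteractionHit(False)


def _qualifying_substrings(seq: str, rule: InteractionRule) -> frozenset[str]:
    """Substrings of length >= min_run with >= min_gc_pairs G/C bases.

    Two UMIs interact (without wobble) iff a qualifying substring of one
    equals a qualifying substring of the other's reverse complement: the
    shared substring *is* the complementary stretch, and its G/C content is
    the duplex's G-C pair count (invariant under reverse complement).
    """
    out = set()
    n = len(seq)
    is_gc = np.array([c in "GC" for c in seq], dtype=int)
    cum = np.concatenate([[0], np.cumsum(is_gc)])
    for length in range(rule.min_run, n + 1):
        for start in range(0, n - length + 1):
            if cum[start + length] - cum[start] >= rule.min_gc_pairs:
                out.add(seq[start : start + length])
    return frozenset(out)


@dataclass(frozen=True)
class InteractionResult:
    """Population-level outcome of one interaction simulation."""

    design: str
    n_umis: int
    n_pairs_tested: int
    n_interacting_pairs: int
    interaction_rate: float
    mean_interactions_per_umi: float
    seed: int


def simulate_interactions(
    pattern: UMIPattern,
    n_umis: int = 10_000,
    rule: InteractionRule = InteractionRule(),
    seed: int = 0,
) -> InteractionResult:
    """Sample ``n_umis`` UMIs from a design and test all unordered pairs.

    Each sampled UMI is compared against every other (self-comparison
    excluded; duplicate sequences are kept as distinct individuals, as in
    real labeling).  Deterministic for a fixed seed.

    The default population of 10,000 matches the scale at which the designs
    were originally screened; tests and examples use smaller populations.
    """
    if n_umis < 2:
        raise ValueError("need at least two UMIs to form a pair")
    umis = sample_umis(pattern, n_umis, seed)
    if rule.allow_wobble:
        flags = [
            interacts(a, b, rule).interacting for a, b in combinations(umis, 2)
        ]
        n_hit = sum(flags)
    else:
        # fast path: precompute qualifying-substring sets; a pair interacts
        # iff the forward set of one meets the revcomp set of the other.
        fwd_cache: dict[str, frozenset] = {}
        rev_cache: dict[str, frozenset] = {}
        for u in umis:
            if u not in fwd_cache:
                fwd_cache[u] = _qualifying_substrings(u, rule)
                rev_cache[u] = _qualifying_substrings(reverse_complement(u), rule)
        fwd = [fwd_cache[u] for u in umis]
        rev = [rev_cache[u] for u in umis]
        n_hit = 0
        for i in range(n_umis - 1):
            fi = fwd[i]
            for j in range(i + 1, n_umis):
                if not fi.isdisjoint(rev[j]):
                    n_hit += 1
    n_pairs = n_umis * (n_umis - 1) // 2
    return InteractionResult(
        design=pattern.name or pattern.render(),
        n_umis=n_umis,
        n_pairs_tested=n_pairs,
        n_interacting_pairs=n_hit,
        interaction_rate=n_hit / n_pairs,
        mean_interactions_per_umi=2 * n_hit / n_umis,
        seed=seed,
    )


def compare_designs(
    patterns: list[UMIPattern],
    n_umis: int = 10_000,
    rule: InteractionRule = InteractionRule(),
    seeds: list[int] = (0,),
) -> pd.DataFrame:
    """Run the interaction simulation for several designs over several seeds.

    Returns one row per (design, seed) plus a ``mean_rate`` column carrying
    each design's rate averaged over its seeds.
    """
    if not patterns or not seeds:
        raise ValueError("need at least one pattern and one seed")
    rows = []
    for p in patterns:
        for s in seeds:
            r = simulate_interactions(p, n_umis=n_umis, rule=rule, seed=s)
            rows.append(
                {
                    "design": r.design,
                    "pattern": p.render(),
                    "seed": r.seed,
                    "n_umis": r.n_umis,
                    "n_pairs": r.n_pairs_tested,
                    "n_interacting": r.n_interacting_pairs,
                    "rate": r.interaction_rate,
                    "interactions_per_umi": r.mean_interactions_per_umi,
                }
            )
    df = pd.DataFrame(rows)
    df["mean_rate"] = df.groupby("design")["rate"].transform("mean")
    return df
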