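"""Structured UMI designs as degenerate-base patterns.

A unique molecular identifier (UMI) design is written as a string of IUPAC
degenerate-base codes, one code per position: ``N`` admits any nucleotide,
``S`` admits C or G, ``W`` admits A or T, a plain base fixes the position,
and so on through the full IUPAC table.  A *structured* UMI interleaves
fixed or restricted positions among fully randomized ones to suppress
unintended primer-primer hybridization while retaining labeling capacity.

The capacity of a design -- its *diversity* -- is the number of distinct
sequences it can emit: the product of the per-position allowed-nucleotide
counts.  Diversity in turn controls the risk that two template molecules
receive the same label (a *UMI collision*), a plain birthday problem.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IUPAC_CODES",
    "UMIPattern",
    "CollisionReport",
    "parse_pattern",
    "diversity",
    "enumerate_umis",
    "sample_umis",
    "collision_stats",
    "collision_probability_approx",
    "homopolymer_worst_run",
]

#: IUPAC degenerate nucleotide codes mapped to the nucleotide sets they admit.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_SET_TO_CODE = {v: k for k, v in IUPAC_CODES.items()}

#: Guard for exhaustive enumeration (``enumerate_umis``).
DEFAULT_ENUMERATION_LIMIT = 4**10


@dataclass(frozen=True)
class UMIPattern:
    """A structured UMI design: an ordered list of allowed-nucleotide sets.

    Parameters
    ----------
    positions
        One nonempty subset of ``{A, C, G, T}`` per UMI position.
    name
        Free-form design label (e.g. ``"reference"``).
    """

    positions: tuple[frozenset[str], ...]
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.positions) < 1:
            raise ValueError("a UMI pattern needs at least one position")
        for i, s in enumerate(self.positions):
            if not s or not s <= frozenset("ACGT"):
                raise ValueError(
                    f"position {i + 1}: allowed set must be a nonempty subset of ACGT"
                )

    @property
    def length(self) -> int:
        return len(self.positions)

    def __len__(self) -> int:
        return len(self.positions)

    def render(self) -> str:
        """The IUPAC string for this design (inverse of :func:`parse_pattern`)."""
        return "".join(_SET_TO_CODE[s] for s in self.positions)

    def __str__(self) -> str:
        return self.render()

    def matches(self, seq: str) -> bool:
        """Whether ``seq`` is one of the sequences this design can emit."""
        if len(seq) != self.length:
            return False
        return all(b in s for b, s in zip(seq.upper(), self.positions))

    def concat(self, other: "UMIPattern") -> "UMIPattern":
        """Positional concatenation of two designs."""
        return UMIPattern(self.positions + other.positions, name=f"{self.name}+{other.name}")


@dataclass(frozen=True)
class CollisionReport:
    """Birthday-problem summary for labeling ``n_molecules`` with one design."""

    n_molecules: int
    diversity: int
    p_any_collision: float
    expected_collisions: float


def parse_pattern(text: str, name: str = "") -> UMIPattern:
    """Parse an IUPAC degenerate-base string into a :class:`UMIPattern`.

    Parsing is case-insensitive; whitespace is ignored so designs may be
    written in grouped form, e.g. ``"NNNN A NNNN A NNNN"``.

    Raises
    ------
    ValueError
        If the string is empty or contains a non-IUPAC character; the error
        names the offending (1-based) position.
    """
    compact = "".join(text.split()).upper()
    if not compact:
        raise ValueError("empty UMI pattern")
    positions = []
    for i, code in enumerate(compact):
        try:
            positions.append(IUPAC_CODES[code])
        except KeyError:
            raise ValueError(
                f"invalid IUPAC code {code!r} at position {i + 1} of pattern {text!r}"
            ) from None
    return UMIPattern(tuple(positions), name=name)


def diversity(pattern: UMIPattern) -> int:
    """Number of distinct sequences the design can emit.

    Exact arbitrary-precision product of per-position set sizes; a 12xN
    design gives 4**12 = 16,777,216.
    """
    return math.prod(len(s) for s in pattern.positions)


def enumerate_umis(
    pattern: UMIPattern, limit: int = DEFAULT_ENUMERATION_LIMIT
) -> list[str]:
    """All distinct sequences matching the design, in lexicographic order.

    Refuses (``ValueError``) when the diversity exceeds ``limit``; meant for
    oracle-style exhaustive checks, not for production-size designs.
    """
    d = diversity(pattern)
    if d > limit:
        raise ValueError(
            f"refusing to enumerate {d} sequences (limit {limit}); "
            "use sample_umis for large designs"
        )
    alphabets = [sorted(s) for s in pattern.positions]
    return ["".join(t) for t in itertools.product(*alphabets)]


def sample_umis(pattern: UMIPattern, n: int, seed) -> list[str]:
    """Draw ``n`` UMIs, each position uniform over its allowed set.

    Draws are independent, so duplicates can occur -- exactly as in real
    molecule labeling.  Reproducible for a fixed ``seed`` (any value
    accepted by :func:`numpy.random.default_rng`, including a Generator).

    Uniformity is per position, hence uniform over the design's whole
    sequence space.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cols = []
    for s in pattern.positions:
        alphabet = sorted(s)
        if len(alphabet) == 1:
            cols.append(np.full(n, alphabet[0], dtype="U1"))
        else:
            cols.append(np.array(alphabet, dtype="U1")[rng.integers(len(alphabet), size=n)])
    grid = np.stack(cols, axis=1)
    return ["".join(row) for row in grid]


def collision_stats(pattern: UMIPattern, n_molecules: int) -> CollisionReport:
    """Exact birthday-problem collision risk for ``n_molecules`` labels.

    ``p_any_collision`` is the exact product
    ``1 - prod_{i<n} (1 - i/D)`` with ``D`` the design diversity, evaluated
    in log space for stability; ``expected_collisions`` is the expected
    number of colliding pairs, ``C(n, 2) / D``.
    """
    if n_molecules < 0:
        raise ValueError("n_molecules must be >= 0")
    d = diversity(pattern)
    n = n_molecules
    expected = math.comb(n, 2) / d
    if n >= 2 and n > d:
        p = 1.0  # pigeonhole
    elif n < 2:
        p = 0.0
    else:
        log_no_collision = sum(math.log1p(-i / d) for i in range(1, n))
        p = -math.expm1(log_no_collision)
    return CollisionReport(
        n_molecules=n, diversity=d, p_any_collision=p, expected_collisions=expected
    )


def collision_probability_approx(pattern: UMIPattern, n_molecules: int) -> float:
    """Exponential birthday approximation ``1 - exp(-C(n,2)/D)``.

    Exposed separately as a cross-check on :func:`collision_stats`; the
    exact product is always preferred in reports.
    """
    if n_molecules < 0:
        raise ValueError("n_molecules must be >= 0")
    return -math.expm1(-math.comb(n_molecules, 2) / diversity(pattern))


def homopolymer_worst_run(pattern: UMIPattern, base: str) -> int:
    """Longest run of ``base`` achievable by any sequence of the design.

    Adenine-structured designs can emit long poly-A stretches when the
    fixed adenines abut randomized positions that may also draw A; long
    homopolymers degrade library construction and sequencing.  Computed
    greedily: a position contributes to a run iff ``base`` is in its set.
    """
    base = base.upper()
    if base not in "ACGT" or len(base) != 1:
        raise ValueError(f"base must be one of A/C/G/T, got {base!r}")
    best = run = 0
    for s in pattern.positions:
        run = run + 1 if base in s else 0
        best = max(best, run)
    return best
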