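"""Synthetic UMI-tagged amplicon sequencing libraries with ground truth.

Generates single-end FASTQ reads emulating a two-step barcoding/adapter
PCR workflow: every double-stranded template molecule is labeled by one or
more UMI-bearing primers (on average two labels per molecule after
barcoding PCR and dilution), each labeled template founds a *UMI family*
of reads, polymerase errors strike the labeled template once and are
inherited by its whole family, and sequencer errors strike each read
independently.  A configurable fraction of reads is off-target: random
sequence behind a valid UMI + spacer prefix.

Every run also emits a :class:`TruthSet` -- molecule, family and variant
tables consistent with the FASTQ -- so that downstream consensus calling
can be scored against known truth.

Read layout: ``UMI + spacer + insert`` where the insert is the (possibly
variant, possibly erroneous) amplicon sequence, written in forward
orientation.  Quality strings are constant high quality; the collapse
pipeline ignores them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .patterns import UMIPattern, parse_pattern, sample_umis

__all__ = [
    "Amplicon",
    "TruthVariant",
    "SimConfig",
    "TruthSet",
    "SimulatedRead",
    "simulate_library",
    "genome_equivalents",
    "zero_truncated_poisson_rate",
    "demo_amplicons",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Molecules of amplifiable single-locus template per nanogram of human
#: genomic DNA (one diploid genome is ~6.6 pg, and not every fragment is
#: amplifiable at a given locus).
MOLECULES_PER_NG = 310


@dataclass(frozen=True)
class Amplicon:
    """One target region of a digital-sequencing panel.

    ``start`` is the 1-based genomic coordinate of the first base of
    ``sequence``; ``primer_len_fwd``/``primer_len_rev`` mark the
    primer-derived bases at each end, where variants cannot be interrogated.
    Amplicons are kept short (<= ~110 nt) so fragmented cell-free DNA
    remains amplifiable.
    """

    name: str
    chrom: str
    start: int
    sequence: str
    primer_len_fwd: int = 20
    primer_len_rev: int = 20

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if set(seq) - set("ACGT"):
            raise ValueError(f"amplicon {self.name}: sequence must be A/C/G/T")
        if len(seq) < self.primer_len_fwd + self.primer_len_rev + 1:
            raise ValueError(
                f"amplicon {self.name}: sequence shorter than its two primers"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def genomic_pos(self, offset: int) -> int:
        """1-based genomic coordinate of 0-based amplicon offset."""
        return self.start + offset


@dataclass(frozen=True)
class TruthVariant:
    """A spiked-in single-nucleotide variant with its molecule-level fraction."""

    amplicon: str
    offset: int  # 0-based within the amplicon sequence
    ref: str
    alt: str
    fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("variant fraction must be in [0, 1]")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")


@dataclass
class SimConfig:
    """Parameters of one simulated library.

    umis_per_molecule_mean
        Expected number of distinct UMI labels a double-stranded template
        acquires (default 2.0: roughly one per strand after barcoding PCR
        and dilution).  Labels per molecule are drawn zero-truncated
        Poisson with the rate calibrated so the truncated mean equals this.
    family_size_law
        Reads per UMI family: ``("lognormal", mu, sigma)`` (discretised,
        min 1; default mu=3.0, sigma=0.8, median ~20 reads) or
        ``("constant", k)``.
    polymerase_error_rate
        Per-base substitution probability applied once to each labeled
        template; the whole family inherits these errors, so consensus
        cannot remove them.
    seq_error_rate
        Per-base substitution probability applied independently per read
        (insert only); consensus majority voting removes these.
    off_target_fraction
        Expected fraction of all reads that are off-target (random
        sequence with a valid UMI + spacer prefix).
    """

    pattern: UMIPattern = field(default_factory=lambda: parse_pattern("N" * 12, "reference"))
    molecules_per_amplicon: int = 1000
    truth_variants: Sequence[TruthVariant] = ()
    umis_per_molecule_mean: float = 2.0
    family_size_law: tuple = ("lognormal", 3.0, 0.8)
    seq_error_rate: float = 0.0
    polymerase_error_rate: float = 0.0
    off_target_fraction: float = 0.0
    spacer: str = "CTAG"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("seq_error_rate", "polymerase_error_rate", "off_target_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.off_target_fraction >= 1.0 and self.molecules_per_amplicon > 0:
            raise ValueError("off_target_fraction must be < 1 when on-target molecules exist")
        if self.molecules_per_amplicon < 0:
            raise ValueError("molecules_per_amplicon must be >= 0")
        if self.umis_per_molecule_mean < 1.0:
            raise ValueError("umis_per_molecule_mean must be >= 1 (zero-truncated law)")


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str


@dataclass
class TruthSet:
    """Ground truth emitted alongside the FASTQ.

    molecules
        One row per template molecule: amplicon, molecule id, carried
        variants, number of UMI labels drawn.
    families
        One row per labeled template (UMI family): umi, amplicon, parent
        molecule, template (polymerase) error count, family size in reads.
    variants
        One row per spiked variant: requested fraction, realized mutant
        molecule count and fraction.
    """

    molecules: pd.DataFrame
    families: pd.DataFrame
    variants: pd.DataFrame
    n_on_target_reads: int
    n_off_target_reads: int

    @property
    def n_reads(self) -> int:
        return self.n_on_target_reads + self.n_off_target_reads

    def molecule_counts(self) -> pd.Series:
        """Template molecules per amplicon."""
        return self.molecules.groupby("amplicon").size()

    def family_counts(self) -> pd.Series:
        """Realized UMI labels (families) per amplicon."""
        return self.families.groupby("amplicon").size()


def zero_truncated_poisson_rate(mean: float) -> float:
    """Poisson rate whose zero-truncated distribution has the given mean.

    Solves ``lam / (1 - exp(-lam)) == mean``; for a mean of 2 labels per
    molecule the rate is ~1.5936.
    """
    if mean < 1.0:
        raise ValueError("zero-truncated Poisson mean must be >= 1")
    if mean == 1.0:
        return 0.0
    f = lambda lam: lam / -np.expm1(-lam) - mean
    return brentq(f, 1e-9, max(10.0, 5 * mean))


def _sample_ztp(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson draws (resample zeros)."""
    if lam == 0.0:
        return np.ones(size, dtype=int)
    out = rng.poisson(lam, size)
    while True:
        zero = out == 0
        n0 = int(zero.sum())
        if n0 == 0:
            return out
        out[zero] = rng.poisson(lam, n0)


def _sample_family_sizes(rng: np.random.Generator, law: tuple, size: int) -> np.ndarray:
    kind = law[0]
    if kind == "lognormal":
        _, mu, sigma = law
        return np.maximum(1, np.rint(rng.lognormal(mu, sigma, size)).astype(int))
    if kind == "constant":
        return np.full(size, int(law[1]), dtype=int)
    raise ValueError(f"unknown family_size_law {law!r}")


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> tuple[np.ndarray, int]:
    """Substitute each base with probability ``rate``; returns (seq, n_changes)."""
    if rate <= 0.0:
        return seq, 0
    hits = np.nonzero(rng.random(seq.size) < rate)[0]
    if hits.size == 0:
        return seq, 0
    out = seq.copy()
    # draw a substitute uniformly among the three other bases
    for i in hits:
        choices = _BASES[_BASES != out[i]]
        out[i] = choices[rng.integers(3)]
    return out, int(hits.size)


def simulate_library(
    amplicons: Sequence[Amplicon], config: SimConfig
) -> tuple[list[SimulatedRead], TruthSet]:
    """Generate a synthetic library for a panel of amplicons.

    Per molecule: draw carried variants (independent Bernoulli per spiked
    variant), draw the number of UMI labels (zero-truncated Poisson), and
    for each label draw a UMI, a family size, and once-off template
    (polymerase) errors.  Every read of the family then receives
    independent sequencer errors.  Finally, off-target reads are appended
    so their expected fraction of the total equals
    ``config.off_target_fraction``.

    Fully reproducible: a single seeded generator drives every draw.
    """
    by_name = {a.name: a for a in amplicons}
    if len(by_name) != len(amplicons):
        raise ValueError("duplicate amplicon names")
    for v in config.truth_variants:
        amp = by_name.get(v.amplicon)
        if amp is None:
            raise ValueError(f"variant references unknown amplicon {v.amplicon!r}")
        if not (amp.primer_len_fwd <= v.offset < amp.length - amp.primer_len_rev):
            raise ValueError(
                f"variant offset {v.offset} outside the non-primer region of {v.amplicon}"
            )
        if amp.sequence[v.offset] != v.ref.upper():
            raise ValueError(
                f"variant ref {v.ref!r} does not match {v.amplicon} at offset {v.offset}"
            )

    rng = np.random.default_rng(config.seed)
    lam = zero_truncated_poisson_rate(config.umis_per_molecule_mean)
    umi_len = config.pattern.length
    spacer = config.spacer.upper()

    reads: list[SimulatedRead] = []
    mol_rows = []
    fam_rows = []
    mutant_counts = {i: 0 for i in range(len(config.truth_variants))}
    variants_by_amp: dict[str, list[tuple[int, TruthVariant]]] = {}
    for i, v in enumerate(config.truth_variants):
        variants_by_amp.setdefault(v.amplicon, []).append((i, v))

    for amp in amplicons:
        ref = np.frombuffer(amp.sequence.encode(), dtype=np.uint8)
        amp_vars = variants_by_amp.get(amp.name, [])
        n_mol = config.molecules_per_amplicon
        n_labels = _sample_ztp(rng, lam, n_mol) if n_mol else np.zeros(0, dtype=int)
        for m in range(n_mol):
            carried = [
                (vi, v) for vi, v in amp_vars if rng.random() < v.fraction
            ]
            template = ref
            if carried:
                template = ref.copy()
                for vi, v in carried:
                    template[v.offset] = ord(v.alt.upper())
                    mutant_counts[vi] += 1
            mol_rows.append(
                {
                    "amplicon": amp.name,
                    "molecule_id": f"{amp.name}:{m}",
                    "variants": ";".join(
                        f"{v.offset}{v.ref}>{v.alt}" for _, v in carried
                    ),
                    "n_labels": int(n_labels[m]),
                }
            )
            umis = sample_umis(config.pattern, int(n_labels[m]), rng)
            sizes = _sample_family_sizes(rng, config.family_size_law, int(n_labels[m]))
            for li, (umi, fam_size) in enumerate(zip(umis, sizes)):
                fam_template, n_pol = _mutate(
                    rng, template, config.polymerase_error_rate
                )
                fam_rows.append(
                    {
                        "amplicon": amp.name,
                        "molecule_id": f"{amp.name}:{m}",
                        "umi": umi,
                        "template_errors": n_pol,
                        "family_size": int(fam_size),
                    }
                )
                for r in range(fam_size):
                    insert, _ = _mutate(rng, fam_template, config.seq_error_rate)
                    reads.append(
                        SimulatedRead(
                            read_id=f"{amp.name}:{m}:{li}:{r}",
                            sequence=umi + spacer + insert.tobytes().decode(),
                        )
                    )

    n_on = len(reads)
    n_off = 0
    if config.off_target_fraction > 0.0 and n_on > 0:
        f = config.off_target_fraction
        n_off = int(rng.binomial(n_on, f / (1.0 - f)))
        lengths = [a.length for a in amplicons]
        off_umis = sample_umis(config.pattern, max(n_off, 1), rng)[:n_off]
        for i in range(n_off):
            L = lengths[rng.integers(len(lengths))]
            junk = _BASES[rng.integers(4, size=L)].tobytes().decode()
            reads.append(
                SimulatedRead(read_id=f"offtarget:{i}", sequence=off_umis[i] + spacer + junk)
            )

    var_rows = []
    for vi, v in enumerate(config.truth_variants):
        n_mol = config.molecules_per_amplicon
        var_rows.append(
            {
                "amplicon": v.amplicon,
                "offset": v.offset,
                "chrom": by_name[v.amplicon].chrom,
                "pos": by_name[v.amplicon].genomic_pos(v.offset),
                "ref": v.ref.upper(),
                "alt": v.alt.upper(),
                "requested_fraction": v.fraction,
                "mutant_molecules": mutant_counts[vi],
                "realized_fraction": mutant_counts[vi] / n_mol if n_mol else 0.0,
            }
        )

    truth = TruthSet(
        molecules=pd.DataFrame(
            mol_rows, columns=["amplicon", "molecule_id", "variants", "n_labels"]
        ),
        families=pd.DataFrame(
            fam_rows,
            columns=["amplicon", "molecule_id", "umi", "template_errors", "family_size"],
        ),
        variants=pd.DataFrame(
            var_rows,
            columns=[
                "amplicon", "offset", "chrom", "pos", "ref", "alt",
                "requested_fraction", "mutant_molecules", "realized_fraction",
            ],
        ),
        n_on_target_reads=n_on,
        n_off_target_reads=n_off,
    )
    assert truth.n_reads == len(reads)
    return reads, truth


def genome_equivalents(ng_dna: float) -> int:
    """Template molecules available from a given mass of cell-free DNA.

    1 ng of human genomic DNA corresponds to approximately 310 amplifiable
    single-locus template molecules; the conversion is linear and rounded
    to the nearest molecule.
    """
    if ng_dna < 0:
        raise ValueError("DNA mass cannot be negative")
    return round(ng_dna * MOLECULES_PER_NG)


def demo_amplicons(
    n: int = 2, length: int = 100, seed: int = 7, primer_len: int = 20
) -> list[Amplicon]:
    """Random synthetic amplicon panel for tests and examples.

    Sequences are uniform random, long enough to be pairwise
    distinguishable at any practical k-mer size.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        seq = _BASES[rng.integers(4, size=length)].tobytes().decode()
        out.append(
            Amplicon(
                name=f"AMP{i + 1}",
                chrom=f"chr{i + 1}",
                start=1_000_000 * (i + 1),
                sequence=seq,
                primer_len_fwd=primer_len,
                primer_len_rev=primer_len,
            )
        )
    return out
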