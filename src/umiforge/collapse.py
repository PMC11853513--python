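"""UMI-family consensus collapsing and digital-sequencing statistics.

The digital-sequencing pipeline: extract the UMI from the start of each
read, assign the remaining insert to a panel amplicon by shared k-mers,
cluster reads into UMI families keyed by (UMI, target), collapse each
family to a per-position majority consensus read (families below a size
cutoff, default 3 reads, are discarded), and derive the run-level
digital-sequencing statistics:

* molecules: two consensus reads correspond to about one original
  double-stranded template molecule;
* background error rate: non-reference alleles per position divided by
  consensus coverage, with known polymorphic and spiked positions
  excluded;
* variant allele frequency (VAF) per position, and the overall VAF of a
  panel: total mutant molecules across all monitored positions divided by
  total molecules across all assays;
* off-target fraction: reads not attributable to any intended amplicon.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import Amplicon

__all__ = [
    "ReadRecord",
    "UMIFamily",
    "ConsensusRead",
    "VariantCall",
    "SampleStats",
    "AmpliconIndex",
    "UNASSIGNED",
    "extract_umi",
    "assign_target",
    "cluster_families",
    "consensus",
    "count_molecules",
    "pileup_and_call",
    "sample_stats",
    "collapse_pipeline",
    "CollapseResult",
]

UNASSIGNED = "UNASSIGNED"

_CODE = np.full(256, 4, dtype=np.uint8)  # anything unexpected -> N slot
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_ALPHABET = "ACGTN"


@dataclass
class ReadRecord:
    """One accepted read after UMI extraction."""

    read_id: str
    umi: str
    insert: str
    assigned_target: str = UNASSIGNED


@dataclass
class UMIFamily:
    """Reads sharing one UMI and one target; presumed one labeled template."""

    umi: str
    target: str
    members: list[ReadRecord]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ConsensusRead:
    target: str
    umi: str
    sequence: str
    family_size: int


@dataclass(frozen=True)
class VariantCall:
    """One non-reference substitution observed in consensus reads."""

    target: str
    chrom: str
    pos: int  # 1-based genomic
    amplicon_offset: int  # 0-based within the amplicon
    ref: str
    alt: str
    mutant_consensus_count: int
    coverage: int

    @property
    def vaf(self) -> float:
        return self.mutant_consensus_count / self.coverage

    @property
    def mutant_molecules(self) -> float:
        """Two consensus reads ~ one double-stranded template molecule."""
        return self.mutant_consensus_count / 2.0


@dataclass
class SampleStats:
    """Run-level summary of one collapsed library."""

    n_reads: int
    n_rejected: int
    n_assigned: int
    off_target_fraction: float
    consensus_per_target: dict[str, int]
    molecules_per_target: dict[str, float]
    error_rate: float
    overall_vaf: Optional[float] = None
    molecules_per_ml: Optional[float] = None

    @property
    def total_molecules(self) -> float:
        return sum(self.molecules_per_target.values())

    def to_dict(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "n_rejected": self.n_rejected,
            "n_assigned": self.n_assigned,
            "off_target_fraction": self.off_target_fraction,
            "consensus_per_target": self.consensus_per_target,
            "molecules_per_target": self.molecules_per_target,
            "total_molecules": self.total_molecules,
            "error_rate": self.error_rate,
            "overall_vaf": self.overall_vaf,
            "molecules_per_ml": self.molecules_per_ml,
        }


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def extract_umi(
    raw_read: str,
    umi_len: int,
    spacer: str = "",
    max_spacer_mismatch: int = 1,
    read_id: str = "",
) -> Optional[ReadRecord]:
    """Split a raw read into UMI and insert, verifying the spacer.

    The first ``umi_len`` bases are the UMI; the following ``len(spacer)``
    bases must match the expected spacer within ``max_spacer_mismatch``
    substitutions; the remainder is the insert.  Returns ``None`` for a
    rejected read (too short, or spacer beyond tolerance) -- callers count
    rejections, they are not errors.
    """
    raw = raw_read.upper()
    k = len(spacer)
    if len(raw) < umi_len + k + 1:
        return None
    if k and _hamming(raw[umi_len : umi_len + k], spacer.upper()) > max_spacer_mismatch:
        return None
    return ReadRecord(
        read_id=read_id, umi=raw[:umi_len], insert=raw[umi_len + k :]
    )


class AmpliconIndex:
    """k-mer index over a panel, a desk-scale stand-in for genome alignment.

    Each amplicon contributes the set of its k-mers; an insert is assigned
    to the unique amplicon sharing the most of its k-mers, provided at
    least ``min_match_fraction`` of the insert's k-mers are found there.
    Ties and sub-threshold matches are left unassigned.  Panels whose
    amplicons are not distinguishable at the chosen k are refused at load.
    """

    def __init__(
        self,
        amplicons: Sequence[Amplicon],
        k: int = 15,
        min_match_fraction: float = 0.5,
    ) -> None:
        if k < 4:
            raise ValueError("k-mer size must be >= 4")
        self.k = k
        self.min_match_fraction = min_match_fraction
        self.amplicons = {a.name: a for a in amplicons}
        if len(self.amplicons) != len(amplicons):
            raise ValueError("duplicate amplicon names")
        self._kmer_sets: dict[str, set[str]] = {}
        for a in amplicons:
            if a.length < k:
                raise ValueError(f"amplicon {a.name} shorter than k={k}")
            self._kmer_sets[a.name] = {
                a.sequence[i : i + k] for i in range(a.length - k + 1)
            }
        names = list(self._kmer_sets)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                si, sj = self._kmer_sets[names[i]], self._kmer_sets[names[j]]
                shared = len(si & sj)
                if shared / min(len(si), len(sj)) >= min_match_fraction:
                    raise ValueError(
                        f"amplicons {names[i]} and {names[j]} are not "
                        f"distinguishable at k={k} "
                        f"({shared} shared k-mers)"
                    )
        self._lookup: dict[str, str] = {}
        seen_twice: set[str] = set()
        for name, s in self._kmer_sets.items():
            for kmer in s:
                if kmer in self._lookup:
                    seen_twice.add(kmer)
                else:
                    self._lookup[kmer] = name
        for kmer in seen_twice:
            del self._lookup[kmer]

    def assign(self, insert: str) -> str:
        """Target name for an insert, or ``UNASSIGNED``."""
        n_kmers = len(insert) - self.k + 1
        if n_kmers < 1:
            return UNASSIGNED
        votes: dict[str, int] = defaultdict(int)
        for i in range(n_kmers):
            hit = self._lookup.get(insert[i : i + self.k])
            if hit is not None:
                votes[hit] += 1
        if not votes:
            return UNASSIGNED
        ranked = sorted(votes.items(), key=lambda kv: -kv[1])
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            return UNASSIGNED
        best, count = ranked[0]
        if count < self.min_match_fraction * n_kmers:
            return UNASSIGNED
        return best


def assign_target(
    record: ReadRecord, index: AmpliconIndex
) -> str:
    """Assign a read's insert to a panel amplicon by shared k-mers.

    Mutates ``record.assigned_target`` and returns the target name (or
    ``UNASSIGNED``).
    """
    record.assigned_target = index.assign(record.insert)
    return record.assigned_target


def cluster_families(
    records: Iterable[ReadRecord], merge_distance: int = 0
) -> list[UMIFamily]:
    """Group assigned reads into UMI families keyed by (UMI, target).

    Reads are clustered on their UMI sequence *and* their target: the same
    UMI on two different amplicons labels two different molecules.
    Unassigned reads are ignored.

    With ``merge_distance >= 1``, a directional merge then absorbs small
    families into a same-target family at Hamming distance
    <= ``merge_distance`` whose size is at least twice theirs -- the usual
    correction for sequencing errors inside the UMI itself.  Default is
    exact matching (``merge_distance=0``).

    Output order is deterministic: by (target, umi).
    """
    groups: dict[tuple[str, str], list[ReadRecord]] = defaultdict(list)
    for rec in records:
        if rec.assigned_target == UNASSIGNED:
            continue
        groups[(rec.assigned_target, rec.umi)].append(rec)
    families = [
        UMIFamily(umi=umi, target=target, members=members)
        for (target, umi), members in sorted(groups.items())
    ]
    if merge_distance >= 1:
        families = _directional_merge(families, merge_distance)
    return families


def _directional_merge(families: list[UMIFamily], d: int) -> list[UMIFamily]:
    """Absorb each family into a >=2x-larger same-target family within Hamming d.

    Candidates are processed smallest-first; when several absorbers
    qualify, the largest (ties broken by UMI) wins.  Absorbed members keep
    their own UMI strings but join the absorber's family.
    """
    by_target: dict[str, list[UMIFamily]] = defaultdict(list)
    for f in families:
        by_target[f.target].append(f)
    out: list[UMIFamily] = []
    for target in sorted(by_target):
        fams = sorted(by_target[target], key=lambda f: (f.size, f.umi))
        sizes = {f.umi: f.size for f in fams}  # pre-merge sizes decide absorption
        merged_into: dict[str, str] = {}
        for f in fams:
            candidates = [
                g
                for g in fams
                if g.umi != f.umi
                and g.umi not in merged_into
                and sizes[g.umi] >= 2 * sizes[f.umi]
                and _hamming(f.umi, g.umi) <= d
            ]
            if candidates:
                winner = max(candidates, key=lambda g: (sizes[g.umi], g.umi))
                merged_into[f.umi] = winner.umi
        pool: dict[str, UMIFamily] = {f.umi: f for f in fams}
        for src, dst in merged_into.items():
            # an absorber may itself have been absorbed; follow the chain
            while dst in merged_into:
                dst = merged_into[dst]
            pool[dst].members.extend(pool[src].members)
            del pool[src]
        out.extend(pool[u] for u in sorted(pool))
    return out


def _stack_codes(seqs: Sequence[str], length: int) -> np.ndarray:
    """(n, length) array of base codes 0..4; sequences clipped/padded with N."""
    arr = np.full((len(seqs), length), 4, dtype=np.uint8)
    for i, s in enumerate(seqs):
        b = np.frombuffer(s[:length].encode(), dtype=np.uint8)
        arr[i, : b.size] = _CODE[b]
    return arr


def consensus(
    family: UMIFamily,
    min_family_size: int = 3,
    reference: Optional[str] = None,
) -> Optional[ConsensusRead]:
    """Collapse a family to its per-position majority base.

    Families smaller than ``min_family_size`` (default 3 reads) are
    filtered: they carry too little redundancy for error correction, and
    the cutoff also removes spurious families seeded by errors inside the
    UMI.  Returns ``None`` for a filtered family.

    Member inserts are clipped/padded to the reference length when a
    reference is given, else to the shortest member.  Majority ties are
    broken toward the reference base when one is supplied and among the
    tied alleles, otherwise the position is called ``N``.
    """
    if family.size < min_family_size:
        return None
    seqs = [m.insert for m in family.members]
    length = len(reference) if reference is not None else min(len(s) for s in seqs)
    arr = _stack_codes(seqs, length)
    counts = np.stack([(arr == c).sum(axis=0) for c in range(5)])  # (5, L)
    best = counts.max(axis=0)
    call = counts.argmax(axis=0)
    n_ties = (counts == best).sum(axis=0)
    tied = n_ties > 1
    if tied.any():
        if reference is not None:
            ref_codes = _CODE[np.frombuffer(reference.encode(), dtype=np.uint8)]
            ref_is_tied = counts[ref_codes, np.arange(length)] == best
            call = np.where(tied & ref_is_tied, ref_codes, call)
            call = np.where(tied & ~ref_is_tied, 4, call)
        else:
            call = np.where(tied, 4, call)
    seq = "".join(_ALPHABET[c] for c in call)
    return ConsensusRead(
        target=family.target, umi=family.umi, sequence=seq, family_size=family.size
    )


def count_molecules(consensus_counts: dict[str, int]) -> dict[str, dict]:
    """Convert per-target consensus-read counts into molecule estimates.

    Each original double-stranded molecule contributes on average two UMI
    labels, so two consensus reads correspond to about one template
    molecule.  Reports the fractional estimate (one decimal) and its
    integer floor.
    """
    out = {}
    for target, n in consensus_counts.items():
        if n < 0:
            raise ValueError("consensus counts must be >= 0")
        est = n / 2.0
        out[target] = {"molecules": round(est, 1), "molecules_floor": int(est)}
    return out


def pileup_and_call(
    consensus_reads: Sequence[ConsensusRead],
    amplicons: Sequence[Amplicon],
    exclude_positions: Sequence[tuple[str, int]] = (),
    detection_threshold: int = 1,
) -> tuple[pd.DataFrame, list[VariantCall], float]:
    """Pile up consensus reads per amplicon position; call variants; error rate.

    Returns ``(pileup, calls, error_rate)``:

    * ``pileup``: one row per covered amplicon position with per-allele
      consensus counts (A/C/G/T/N), coverage, and genomic projection;
    * ``calls``: every non-reference substitution allele with consensus
      count >= ``detection_threshold``, at excluded positions too (the
      caller decides what a call at a known SNP means);
    * ``error_rate``: total non-reference A/C/G/T alleles divided by total
      coverage over *non-excluded* positions.  ``exclude_positions`` is a
      list of ``(chrom, 1-based genomic pos)`` for known SNPs and for
      spiked/monitored mutation sites; ``N`` consensus calls count toward
      coverage but never as non-reference alleles.

    Positions covered by no consensus read are omitted from the pileup.
    """
    by_name = {a.name: a for a in amplicons}
    excluded = set()
    for entry in exclude_positions:
        try:
            chrom, pos = entry
            excluded.add((str(chrom), int(pos)))
        except (TypeError, ValueError) as e:
            raise ValueError(f"malformed exclusion entry {entry!r}") from e

    per_target: dict[str, list[ConsensusRead]] = defaultdict(list)
    for cr in consensus_reads:
        if cr.target in by_name:
            per_target[cr.target].append(cr)

    pile_rows = []
    calls: list[VariantCall] = []
    err_numer = 0
    err_denom = 0
    for target in sorted(per_target):
        amp = by_name[target]
        reads = per_target[target]
        arr = _stack_codes([cr.sequence for cr in reads], amp.length)
        counts = np.stack([(arr == c).sum(axis=0) for c in range(5)])  # (5, L)
        ref_codes = _CODE[np.frombuffer(amp.sequence.encode(), dtype=np.uint8)]
        coverage = counts.sum(axis=0)
        for off in range(amp.length):
            cov = int(coverage[off])
            if cov == 0:
                continue
            pos = amp.genomic_pos(off)
            ref_c = int(ref_codes[off])
            row = {
                "target": target,
                "chrom": amp.chrom,
                "pos": pos,
                "amplicon_offset": off,
                "ref": _ALPHABET[ref_c],
                "coverage": cov,
                "excluded": (amp.chrom, pos) in excluded,
            }
            for c in range(5):
                row[_ALPHABET[c]] = int(counts[c, off])
            pile_rows.append(row)
            nonref = cov - int(counts[ref_c, off]) - int(counts[4, off])
            if not row["excluded"]:
                err_numer += nonref
                err_denom += cov
            for c in range(4):
                if c == ref_c:
                    continue
                n_alt = int(counts[c, off])
                if n_alt >= detection_threshold:
                    calls.append(
                        VariantCall(
                            target=target,
                            chrom=amp.chrom,
                            pos=pos,
                            amplicon_offset=off,
                            ref=_ALPHABET[ref_c],
                            alt=_ALPHABET[c],
                            mutant_consensus_count=n_alt,
                            coverage=cov,
                        )
                    )
    pileup = pd.DataFrame(
        pile_rows,
        columns=[
            "target", "chrom", "pos", "amplicon_offset", "ref",
            "A", "C", "G", "T", "N", "coverage", "excluded",
        ],
    )
    error_rate = err_numer / err_denom if err_denom else 0.0
    return pileup, calls, error_rate


def sample_stats(
    n_reads: int,
    n_rejected: int,
    n_assigned: int,
    consensus_reads: Sequence[ConsensusRead],
    calls: Sequence[VariantCall],
    error_rate: float,
    monitored_positions: Sequence[tuple[str, int]] = (),
    plasma_ml: Optional[float] = None,
) -> SampleStats:
    """Assemble the run-level statistics of one collapsed library.

    * off-target fraction: (total reads - target-assigned reads) / total
      reads; spacer-rejected reads count as off-target by this definition.
    * molecules per target: consensus reads / 2.
    * overall VAF (when ``monitored_positions`` -- the panel's known
      mutation sites as (chrom, pos) -- are given): total mutant molecules
      detected at those sites divided by total molecules across all
      assays.
    * molecules per mL plasma when a plasma volume is supplied.
    """
    if n_reads <= 0:
        raise ValueError("no reads")
    cons_counts: dict[str, int] = defaultdict(int)
    for cr in consensus_reads:
        cons_counts[cr.target] += 1
    molecules = {t: n / 2.0 for t, n in sorted(cons_counts.items())}
    total_molecules = sum(molecules.values())

    overall_vaf = None
    if monitored_positions:
        monitored = {(str(c), int(p)) for c, p in monitored_positions}
        mutant = sum(
            call.mutant_molecules
            for call in calls
            if (call.chrom, call.pos) in monitored
        )
        overall_vaf = mutant / total_molecules if total_molecules else 0.0

    return SampleStats(
        n_reads=n_reads,
        n_rejected=n_rejected,
        n_assigned=n_assigned,
        off_target_fraction=(n_reads - n_assigned) / n_reads,
        consensus_per_target=dict(sorted(cons_counts.items())),
        molecules_per_target=molecules,
        error_rate=error_rate,
        overall_vaf=overall_vaf,
        molecules_per_ml=(total_molecules / plasma_ml) if plasma_ml else None,
    )


@dataclass
class CollapseResult:
    """Everything one pipeline run produces, for reporting or inspection."""

    records: list[ReadRecord]
    families: list[UMIFamily]
    consensus_reads: list[ConsensusRead]
    pileup: pd.DataFrame
    calls: list[VariantCall]
    stats: SampleStats
    n_small_families: int


def collapse_pipeline(
    raw_reads: Iterable[tuple[str, str]],
    amplicons: Sequence[Amplicon],
    umi_len: int,
    spacer: str = "",
    max_spacer_mismatch: int = 1,
    k: int = 15,
    min_family_size: int = 3,
    merge_distance: int = 0,
    exclude_positions: Sequence[tuple[str, int]] = (),
    monitored_positions: Sequence[tuple[str, int]] = (),
    detection_threshold: int = 1,
    plasma_ml: Optional[float] = None,
) -> CollapseResult:
    """Run the full extract -> assign -> cluster -> collapse -> score pipeline.

    ``raw_reads`` yields ``(read_id, sequence)``.  All outputs are
    deterministic functions of the inputs and invariant under read-order
    permutation (families are keyed, and outputs sorted, by (target, UMI)).
    """
    index = AmpliconIndex(amplicons, k=k)
    records: list[ReadRecord] = []
    n_reads = 0
    n_rejected = 0
    for read_id, seq in raw_reads:
        n_reads += 1
        rec = extract_umi(seq, umi_len, spacer, max_spacer_mismatch, read_id=read_id)
        if rec is None:
            n_rejected += 1
            continue
        assign_target(rec, index)
        records.append(rec)
    if n_reads == 0:
        raise ValueError("no reads")
    n_assigned = sum(r.assigned_target != UNASSIGNED for r in records)

    families = cluster_families(records, merge_distance=merge_distance)
    consensus_reads = []
    n_small = 0
    for fam in families:
        ref = index.amplicons[fam.target].sequence
        cr = consensus(fam, min_family_size=min_family_size, reference=ref)
        if cr is None:
            n_small += 1
        else:
            consensus_reads.append(cr)

    pileup, calls, error_rate = pileup_and_call(
        consensus_reads,
        amplicons,
        exclude_positions=tuple(exclude_positions) + tuple(monitored_positions),
        detection_threshold=detection_threshold,
    )
    stats = sample_stats(
        n_reads=n_reads,
        n_rejected=n_rejected,
        n_assigned=n_assigned,
        consensus_reads=consensus_reads,
        calls=calls,
        error_rate=error_rate,
        monitored_positions=monitored_positions,
        plasma_ml=plasma_ml,
    )
    return CollapseResult(
        records=records,
        families=families,
        consensus_reads=consensus_reads,
        pileup=pileup,
        calls=calls,
        stats=stats,
        n_small_families=n_small,
    )
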