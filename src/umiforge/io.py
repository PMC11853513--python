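"""File formats: FASTQ/FASTA reads, amplicon manifests, design tables, positions.

Everything on disk is plain text: FASTQ/FASTA via Biopython, tabular data
as TSV via pandas, statistics as JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

from .collapse import ConsensusRead, SampleStats, VariantCall
from .patterns import UMIPattern, parse_pattern
from .simulate import Amplicon, SimulatedRead, TruthSet

__all__ = [
    "read_fastq",
    "write_fastq",
    "read_amplicons",
    "write_amplicons",
    "read_designs",
    "builtin_designs",
    "read_positions",
    "write_truth",
    "write_consensus_fasta",
    "write_calls",
    "write_stats",
    "file_digest",
]

_DATA_DIR = Path(__file__).parent / "data"


def read_fastq(path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a FASTQ file."""
    with open(path) as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq


def write_fastq(reads: Iterable[SimulatedRead], path) -> int:
    """Write reads as standard 4-line FASTQ with constant high quality."""
    records = (
        SeqRecord(
            Seq(r.sequence),
            id=r.read_id,
            description="",
            letter_annotations={"phred_quality": [37] * len(r.sequence)},
        )
        for r in reads
    )
    with open(path, "w") as fh:
        return SeqIO.write(records, fh, "fastq")


def read_amplicons(fasta_path, manifest_path) -> list[Amplicon]:
    """Load a panel from a FASTA plus a TSV manifest.

    Manifest columns: name, chrom, start (1-based), primer_len_fwd,
    primer_len_rev.  Sequences come from the FASTA, keyed by record id.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    man = pd.read_csv(manifest_path, sep="\t")
    required = {"name", "chrom", "start", "primer_len_fwd", "primer_len_rev"}
    missing = required - set(man.columns)
    if missing:
        raise ValueError(f"amplicon manifest missing columns: {sorted(missing)}")
    out = []
    for row in man.itertuples(index=False):
        if row.name not in seqs:
            raise ValueError(f"amplicon {row.name!r} not present in FASTA")
        out.append(
            Amplicon(
                name=str(row.name),
                chrom=str(row.chrom),
                start=int(row.start),
                sequence=seqs[row.name],
                primer_len_fwd=int(row.primer_len_fwd),
                primer_len_rev=int(row.primer_len_rev),
            )
        )
    return out


def write_amplicons(amplicons: Sequence[Amplicon], fasta_path, manifest_path) -> None:
    records = [
        SeqRecord(Seq(a.sequence), id=a.name, description=f"{a.chrom}:{a.start}")
        for a in amplicons
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    pd.DataFrame(
        [
            {
                "name": a.name,
                "chrom": a.chrom,
                "start": a.start,
                "primer_len_fwd": a.primer_len_fwd,
                "primer_len_rev": a.primer_len_rev,
            }
            for a in amplicons
        ]
    ).to_csv(manifest_path, sep="\t", index=False)


def read_designs(path) -> list[UMIPattern]:
    """Load a design library TSV with columns design_name, pattern_string."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"design_name", "pattern_string"} <= set(df.columns):
        raise ValueError("design table needs columns design_name, pattern_string")
    return [
        parse_pattern(str(row.pattern_string), name=str(row.design_name))
        for row in df.itertuples(index=False)
    ]


def builtin_designs() -> list[UMIPattern]:
    """The design library shipped with the package (see data/designs.tsv)."""
    return read_designs(_DATA_DIR / "designs.tsv")


def read_positions(path) -> list[tuple[str, int]]:
    """Read genomic positions from a TSV/BED-like file.

    Two columns -> (chrom, 1-based pos) per line; three columns -> BED
    half-open intervals, expanded to every covered position.  Lines
    starting with ``#`` (and a header line naming a ``pos`` column) are
    skipped.
    """
    out: list[tuple[str, int]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if ln == 1 and not parts[-1].lstrip("-").isdigit():
                continue  # header
            try:
                if len(parts) == 2:
                    out.append((parts[0], int(parts[1])))
                elif len(parts) >= 3:
                    start, end = int(parts[1]), int(parts[2])
                    out.extend((parts[0], p) for p in range(start + 1, end + 1))
                else:
                    raise ValueError
            except ValueError:
                raise ValueError(f"malformed position entry on line {ln}: {line!r}")
    return out


def write_truth(truth: TruthSet, out_prefix) -> dict[str, str]:
    """Write molecules/families/variants tables next to the FASTQ."""
    prefix = str(out_prefix)
    paths = {
        "molecules": f"{prefix}.molecules.tsv",
        "families": f"{prefix}.families.tsv",
        "variants": f"{prefix}.variants.tsv",
    }
    truth.molecules.to_csv(paths["molecules"], sep="\t", index=False)
    truth.families.to_csv(paths["families"], sep="\t", index=False)
    truth.variants.to_csv(paths["variants"], sep="\t", index=False)
    return paths


def write_consensus_fasta(consensus_reads: Sequence[ConsensusRead], path) -> None:
    """Consensus reads as FASTA; family size and UMI recorded in headers."""
    records = [
        SeqRecord(
            Seq(cr.sequence),
            id=f"{cr.target}:{cr.umi}",
            description=f"family_size={cr.family_size}",
        )
        for cr in consensus_reads
    ]
    SeqIO.write(records, str(path), "fasta")


def write_calls(calls: Sequence[VariantCall], path) -> None:
    """Variant calls as a VCF-compatible TSV."""
    pd.DataFrame(
        [
            {
                "CHROM": c.chrom,
                "POS": c.pos,
                "REF": c.ref,
                "ALT": c.alt,
                "target": c.target,
                "mutant_consensus": c.mutant_consensus_count,
                "coverage": c.coverage,
                "VAF": c.vaf,
                "mutant_molecules": c.mutant_molecules,
            }
            for c in calls
        ],
        columns=[
            "CHROM", "POS", "REF", "ALT", "target",
            "mutant_consensus", "coverage", "VAF", "mutant_molecules",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_stats(stats: SampleStats, json_path, tsv_path: Optional[str] = None) -> None:
    with open(json_path, "w") as fh:
        json.dump(stats.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    if tsv_path:
        rows = [
            {
                "target": t,
                "consensus_reads": stats.consensus_per_target[t],
                "molecules": stats.molecules_per_target[t],
            }
            for t in stats.consensus_per_target
        ]
        pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


def file_digest(path) -> str:
    """sha256 of a file, recorded in run provenance."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
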