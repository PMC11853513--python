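"""Extraction, assignment, clustering, consensus, and run statistics."""

import math
import random

import numpy as np
import pytest

import umiforge as uf
from umiforge.collapse import UNASSIGNED, AmpliconIndex

from conftest import random_dna
from oracles import column_mode, directional_merge_counts


def _rec(umi, insert, target="T1", rid="r"):
    return uf.ReadRecord(read_id=rid, umi=umi, insert=insert, assigned_target=target)


class TestExtract:
    def test_splits_umi_spacer_insert(self):
        rec = uf.extract_umi("ACGTACGTACGT" + "CTAG" + "TTTTG", 12, "CTAG")
        assert rec.umi == "ACGTACGTACGT" and rec.insert == "TTTTG"

    def test_one_spacer_mismatch_tolerated_two_rejected(self):
        read = "A" * 12 + "CTCG" + "GGG"
        assert uf.extract_umi(read, 12, "CTAG", max_spacer_mismatch=1) is not None
        read2 = "A" * 12 + "CTCC" + "GGG"
        assert uf.extract_umi(read2, 12, "CTAG", max_spacer_mismatch=1) is None

    def test_too_short_read_rejected(self):
        assert uf.extract_umi("ACGT", 12, "CTAG") is None

    def test_accepted_plus_rejected_conserves_reads(self):
        rng = np.random.default_rng(3)
        reads = ["A" * 12 + "CTAG" + random_dna(rng, 20) for _ in range(50)]
        reads += ["A" * 12 + "GGGG" + random_dna(rng, 20) for _ in range(17)]
        outcomes = [uf.extract_umi(r, 12, "CTAG") for r in reads]
        accepted = sum(o is not None for o in outcomes)
        assert accepted + sum(o is None for o in outcomes) == 67
        assert accepted == 50


class TestAssign:
    def test_exact_substring_is_assigned(self, panel):
        index = AmpliconIndex(panel, k=15)
        rec = _rec("A" * 12, panel[1].sequence[10:90], target=UNASSIGNED)
        assert uf.assign_target(rec, index) == panel[1].name

    def test_random_insert_is_unassigned(self, panel):
        index = AmpliconIndex(panel, k=15)
        rng = np.random.default_rng(4)
        for _ in range(20):
            rec = _rec("A" * 12, random_dna(rng, 100), target=UNASSIGNED)
            assert uf.assign_target(rec, index) == UNASSIGNED

    def test_single_substitution_survives_k15(self, panel):
        index = AmpliconIndex(panel, k=15)
        seq = list(panel[0].sequence)
        seq[50] = "A" if seq[50] != "A" else "C"
        rec = _rec("A" * 12, "".join(seq), target=UNASSIGNED)
        assert uf.assign_target(rec, index) == panel[0].name

    def test_indistinguishable_panel_refused_at_load(self, panel):
        twin = uf.Amplicon("twin", "chr9", 5, panel[0].sequence, 20, 20)
        with pytest.raises(ValueError, match="distinguishable"):
            AmpliconIndex([panel[0], twin], k=15)


class TestCluster:
    def test_exact_grouping_by_umi_and_target(self):
        recs = [
            _rec("AAAA", "ACGT"), _rec("AAAA", "ACGT"), _rec("AAAA", "ACGT"),
            _rec("AAAA", "ACGT", target="T2"),
            _rec("CCCC", "ACGT"),
        ]
        fams = uf.cluster_families(recs)
        key = {(f.target, f.umi): f.size for f in fams}
        assert key == {("T1", "AAAA"): 3, ("T2", "AAAA"): 1, ("T1", "CCCC"): 1}

    def test_unassigned_reads_are_ignored(self):
        recs = [_rec("AAAA", "ACGT"), _rec("AAAA", "ACGT", target=UNASSIGNED)]
        fams = uf.cluster_families(recs)
        assert len(fams) == 1 and fams[0].size == 1

    def test_directional_merge_absorbs_small_neighbours(self):
        recs = [_rec("AAAA", "ACGT", rid=f"a{i}") for i in range(10)]
        recs += [_rec("AAAT", "ACGT", rid=f"b{i}") for i in range(2)]  # 1-mismatch, 5x smaller
        recs += [_rec("GGGG", "ACGT", rid=f"c{i}") for i in range(3)]  # too far
        fams = uf.cluster_families(recs, merge_distance=1)
        sizes = sorted((f.umi, f.size) for f in fams)
        assert sizes == [("AAAA", 12), ("GGGG", 3)]

    def test_similar_sized_families_are_not_merged(self):
        recs = [_rec("AAAA", "ACGT", rid=f"a{i}") for i in range(4)]
        recs += [_rec("AAAT", "ACGT", rid=f"b{i}") for i in range(3)]  # < 2x smaller
        assert len(uf.cluster_families(recs, merge_distance=1)) == 2

    def test_merge_matches_brute_force_oracle(self):
        rng = random.Random(12)
        base_umis = ["AACG", "TTGC", "GGAT", "CATC"]
        for trial in range(30):
            recs = []
            sizes = {}
            for b in base_umis:
                for umi in {b, b[:3] + rng.choice("ACGT"), rng.choice("ACGT") + b[1:]}:
                    n = rng.randint(1, 12)
                    sizes[umi] = sizes.get(umi, 0) + n
                    recs += [_rec(umi, "ACGT", rid=f"{trial}:{umi}:{i}") for i in range(n)]
            assert len(recs) <= 500
            fams = uf.cluster_families(recs, merge_distance=1)
            assert len(fams) == directional_merge_counts(sizes, 1)
            assert sum(f.size for f in fams) == len(recs)


class TestConsensus:
    def test_unanimous_and_majority(self):
        fam = uf.UMIFamily("AAAA", "T1", [_rec("AAAA", s) for s in ("ACGT", "ACGT", "ACGT")])
        assert uf.consensus(fam).sequence == "ACGT"
        fam = uf.UMIFamily("AAAA", "T1", [_rec("AAAA", s) for s in ("ACGT", "ACGA", "ACGT")])
        assert uf.consensus(fam).sequence == "ACGT"

    def test_family_below_cutoff_is_filtered(self):
        fam = uf.UMIFamily("AAAA", "T1", [_rec("AAAA", "ACGT"), _rec("AAAA", "ACGT")])
        assert uf.consensus(fam, min_family_size=3) is None
        assert uf.consensus(fam, min_family_size=2) is not None

    def test_tie_goes_to_reference_else_n(self):
        fam = uf.UMIFamily("AAAA", "T1", [_rec("AAAA", "AAAA"), _rec("AAAA", "AAAC"),
                                          _rec("AAAA", "AACA"), _rec("AAAA", "AACC")])
        # position 2: A/A/C/C tie; position 3: A/C/A/C tie
        assert uf.consensus(fam, min_family_size=3).sequence == "AANN"
        # reference resolves the tie at position 2 (C is tied); at position 3
        # the reference base G is not among the tied alleles, so N stands
        assert uf.consensus(fam, min_family_size=3, reference="AACG").sequence == "AACN"

    def test_matches_per_column_mode_oracle_on_random_families(self):
        rng = np.random.default_rng(31)
        for _ in range(1000):
            n, L = int(rng.integers(3, 9)), int(rng.integers(4, 21))
            seqs = [random_dna(rng, L) for _ in range(n)]
            fam = uf.UMIFamily("ACGT", "T1", [_rec("ACGT", s) for s in seqs])
            assert uf.consensus(fam, min_family_size=3).sequence == column_mode(seqs)

    def test_cutoff_removes_exactly_the_small_families(self):
        rng = np.random.default_rng(32)
        fams = []
        for i in range(200):
            n = int(rng.integers(1, 7))
            fams.append(uf.UMIFamily(f"U{i}", "T1",
                                     [_rec(f"U{i}", random_dna(rng, 10)) for _ in range(n)]))
        kept = [f for f in fams if uf.consensus(f, min_family_size=3) is not None]
        assert {f.umi for f in kept} == {f.umi for f in fams if f.size >= 3}


class TestCountMolecules:
    def test_two_consensus_reads_per_molecule(self):
        out = uf.count_molecules({"T1": 10, "T2": 0, "T3": 7})
        assert out["T1"] == {"molecules": 5.0, "molecules_floor": 5}
        assert out["T2"] == {"molecules": 0.0, "molecules_floor": 0}
        assert out["T3"] == {"molecules": 3.5, "molecules_floor": 3}


class TestPileupAndCall:
    def _consensus_set(self, amp, n_ref, mutations=()):
        """n_ref reference consensus reads plus mutated ones at given offsets."""
        out = [uf.ConsensusRead(amp.name, f"U{i}", amp.sequence, 3) for i in range(n_ref)]
        for j, (off, alt) in enumerate(mutations):
            seq = amp.sequence[:off] + alt + amp.sequence[off + 1:]
            out.append(uf.ConsensusRead(amp.name, f"M{j}", seq, 3))
        return out

    def test_clean_consensus_gives_zero_error_rate(self, panel):
        amp = panel[0]
        pileup, calls, err = uf.pileup_and_call(self._consensus_set(amp, 50), [amp])
        assert err == 0.0 and calls == []
        assert (pileup["coverage"] == 50).all()
        assert (pileup[["A", "C", "G", "T", "N"]].sum(axis=1) == pileup["coverage"]).all()

    def test_error_rate_arithmetic(self, panel):
        amp = panel[0]
        alt1 = "A" if amp.sequence[10] != "A" else "C"
        alt2 = "A" if amp.sequence[20] != "A" else "C"
        reads = self._consensus_set(amp, 999, [(10, alt1), (20, alt2)])
        # read with mutation at 10 is reference elsewhere, so both positions
        # have coverage 1001; 1 non-ref at each of two positions
        pileup, calls, err = uf.pileup_and_call(reads, [amp])
        total_cov = pileup["coverage"].sum()
        assert err == pytest.approx(2 / total_cov)
        assert {(c.amplicon_offset, c.alt) for c in calls} == {(10, alt1), (20, alt2)}
        v = [c for c in calls if c.amplicon_offset == 10][0]
        assert v.coverage == 1001 and v.mutant_consensus_count == 1
        assert v.mutant_molecules == 0.5

    def test_excluded_positions_leave_error_rate(self, panel):
        amp = panel[0]
        alt = "A" if amp.sequence[10] != "A" else "C"
        reads = self._consensus_set(amp, 99, [(10, alt)])
        _, calls, err_all = uf.pileup_and_call(reads, [amp])
        pileup, calls_ex, err_ex = uf.pileup_and_call(
            reads, [amp], exclude_positions=[(amp.chrom, amp.genomic_pos(10))]
        )
        assert err_all > 0 and err_ex == 0.0
        # calls at excluded positions are still reported
        assert {(c.amplicon_offset, c.alt) for c in calls_ex} == {(10, alt)}
        assert pileup.loc[pileup["amplicon_offset"] == 10, "excluded"].all()

    def test_malformed_exclusion_entry_raises(self, panel):
        with pytest.raises(ValueError, match="malformed"):
            uf.pileup_and_call([], [panel[0]], exclude_positions=[("chr1", "xx")])

    def test_n_calls_count_in_coverage_not_errors(self, panel):
        amp = panel[0]
        seq_n = "N" + amp.sequence[1:]
        reads = [uf.ConsensusRead(amp.name, "U0", amp.sequence, 3),
                 uf.ConsensusRead(amp.name, "U1", seq_n, 3)]
        pileup, calls, err = uf.pileup_and_call(reads, [amp])
        assert err == 0.0 and calls == []
        assert pileup.loc[0, "coverage"] == 2 and pileup.loc[0, "N"] == 1


class TestSampleStats:
    def test_off_target_and_overall_vaf_arithmetic(self, panel):
        amp = panel[0]
        cons = [uf.ConsensusRead(amp.name, f"U{i}", amp.sequence, 3) for i in range(20)]
        call = uf.VariantCall(amp.name, amp.chrom, amp.genomic_pos(10), 10,
                              amp.sequence[10], "A" if amp.sequence[10] != "A" else "C",
                              mutant_consensus_count=1, coverage=20)
        s = uf.sample_stats(
            n_reads=100, n_rejected=5, n_assigned=80,
            consensus_reads=cons, calls=[call], error_rate=0.0,
            monitored_positions=[(amp.chrom, amp.genomic_pos(10))],
            plasma_ml=2.0,
        )
        assert s.off_target_fraction == pytest.approx(0.2)
        assert s.molecules_per_target[amp.name] == 10.0
        assert s.overall_vaf == pytest.approx(0.5 / 10.0)
        assert s.molecules_per_ml == pytest.approx(5.0)

    def test_zero_reads_is_an_error(self):
        with pytest.raises(ValueError, match="no reads"):
            uf.sample_stats(0, 0, 0, [], [], 0.0)


class TestPipelineProperties:
    def test_read_order_permutation_invariance(self, panel, small_library):
        cfg, reads, _ = small_library
        pairs = [(r.read_id, r.sequence) for r in reads]
        shuffled = pairs.copy()
        random.Random(77).shuffle(shuffled)
        r1 = uf.collapse_pipeline(pairs, panel, umi_len=12, spacer=cfg.spacer)
        r2 = uf.collapse_pipeline(shuffled, panel, umi_len=12, spacer=cfg.spacer)
        assert [(c.target, c.umi, c.sequence, c.family_size) for c in r1.consensus_reads] == \
               [(c.target, c.umi, c.sequence, c.family_size) for c in r2.consensus_reads]
        assert r1.stats.to_dict() == r2.stats.to_dict()
        assert r1.pileup.equals(r2.pileup)

    def test_conservation_of_reads(self, panel, small_library):
        cfg, reads, _ = small_library
        res = uf.collapse_pipeline(
            [(r.read_id, r.sequence) for r in reads], panel, umi_len=12, spacer=cfg.spacer
        )
        n_unassigned = sum(r.assigned_target == UNASSIGNED for r in res.records)
        in_families = sum(f.size for f in res.families)
        assert res.stats.n_rejected + n_unassigned + in_families == res.stats.n_reads

    def test_clean_end_to_end_is_exact(self, panel):
        cfg = uf.SimConfig(molecules_per_amplicon=40, seed=14)
        reads, truth = uf.simulate_library(panel, cfg)
        res = uf.collapse_pipeline(
            [(r.read_id, r.sequence) for r in reads], panel, umi_len=12, spacer=cfg.spacer
        )
        assert res.stats.error_rate == 0.0
        assert res.stats.off_target_fraction == 0.0
        assert res.calls == []
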