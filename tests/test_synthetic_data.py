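import numpy as np
import pytest

from orfkit.orf_compare import build_unique_clusters
from orfkit.orf_model import orf_nt_length, to_transcript_coords
from orfkit.synthetic_data import (
    CallerProfile,
    gen_orf_callsets,
    gen_peptide_evidence,
    gen_psite_table,
    gen_transcriptome,
)

PER_CAT = {"uORF": 6, "uoORF": 3, "intORF": 3, "doORF": 3, "dORF": 4, "lncRNA-ORF": 4}


class TestGenTranscriptome:
    def test_seed_determinism(self):
        assert repr(gen_transcriptome(5, 2, seed=1)) == repr(gen_transcriptome(5, 2, seed=1))

    def test_different_seeds_differ(self):
        assert repr(gen_transcriptome(5, 2, seed=1)) != repr(gen_transcriptome(5, 2, seed=2))

    def test_single_coding_transcript_cds_multiple_of_three(self):
        txs = gen_transcriptome(1, 0, seed=7)
        (tx,) = txs.values()
        assert tx.cds_tx is not None
        assert (tx.cds_tx[1] - tx.cds_tx[0]) % 3 == 0

    def test_noncoding_only(self):
        txs = gen_transcriptome(0, 3, seed=2)
        assert len(txs) == 3
        assert all(tx.cds_tx is None for tx in txs.values())

    def test_nonpositive_sizes_rejected(self):
        with pytest.raises(ValueError):
            gen_transcriptome(0, 0, seed=1)
        with pytest.raises(ValueError):
            gen_transcriptome(-1, 5, seed=1)

    def test_exon_counts_and_utrs(self):
        txs = gen_transcriptome(30, 0, seed=5)
        for tx in txs.values():
            assert 1 <= len(tx.exons) <= 4
            cs, ce = tx.cds_tx
            assert cs >= 120 and tx.length - ce >= 120  # room for uORFs/dORFs


class TestGenOrfCallsets:
    def test_degenerate_profile_reproduces_truth_exactly(self, small_transcriptome):
        profile = CallerProfile(name="perfect")
        callsets, truth = gen_orf_callsets(small_transcriptome, PER_CAT, [profile], 3, seed=5)
        true_intervals = {
            to_transcript_coords(o, small_transcriptome[o.transcript_id])
            for o in truth.true_orfs.values()
        }
        for calls in callsets.values():
            got = {
                to_transcript_coords(o, small_transcriptome[o.transcript_id]) for o in calls
            }
            assert got == true_intervals

    def test_dropout_one_gives_empty_callsets(self, small_transcriptome):
        profile = CallerProfile(name="dead", dropout_prob=1.0)
        callsets, _ = gen_orf_callsets(small_transcriptome, PER_CAT, [profile], 2, seed=5)
        assert all(calls == [] for calls in callsets.values())

    def test_jittered_variants_share_stop(self, small_transcriptome):
        profile = CallerProfile(name="jittery", jitter_prob=0.5)
        callsets, truth = gen_orf_callsets(small_transcriptome, PER_CAT, [profile], 6, seed=5)
        for calls in callsets.values():
            for call in calls:
                parent = truth.true_orfs[truth.orf_to_cluster[call.orf_id]]
                assert call.stop_codon_pos == parent.stop_codon_pos
                assert call.strand == parent.strand

    def test_unknown_category_key_raises(self, small_transcriptome):
        with pytest.raises(ValueError, match="bogus"):
            gen_orf_callsets(small_transcriptome, {"bogus": 1}, [CallerProfile(name="x")], 1, seed=1)

    def test_spurious_calls_labelled_noise(self, small_transcriptome):
        profile = CallerProfile(name="noisy", spurious_rate=10.0)
        callsets, truth = gen_orf_callsets(small_transcriptome, PER_CAT, [profile], 2, seed=6)
        noise = [
            oid for calls in callsets.values() for oid in (c.orf_id for c in calls)
            if truth.orf_to_cluster[oid] == "noise"
        ]
        assert noise

    def test_determinism_across_runs(self, small_transcriptome):
        profile = CallerProfile(name="p", jitter_prob=0.3, dropout_prob=0.2, spurious_rate=2.0)
        a, _ = gen_orf_callsets(small_transcriptome, PER_CAT, [profile], 4, seed=9)
        b, _ = gen_orf_callsets(small_transcriptome, PER_CAT, [profile], 4, seed=9)
        assert repr(a) == repr(b)

    def test_ground_truth_partitions_non_noise_calls(self, small_transcriptome):
        profile = CallerProfile(name="p", dropout_prob=0.2)
        callsets, truth = gen_orf_callsets(small_transcriptome, PER_CAT, [profile], 3, seed=10)
        all_ids = {c.orf_id for calls in callsets.values() for c in calls}
        assert all_ids == set(truth.orf_to_cluster)
        assert set(truth.orf_to_cluster.values()) <= set(truth.true_orfs) | {"noise"}

    def test_zero_jitter_full_overlap_recovers_partition(self, small_transcriptome):
        profile = CallerProfile(name="p")
        callsets, truth = gen_orf_callsets(small_transcriptome, PER_CAT, [profile], 6, seed=11)
        pooled = [c for calls in callsets.values() for c in calls]
        clusters = build_unique_clusters(pooled, 1.0)
        got = {frozenset(c.member_ids) for c in clusters}
        want: dict[str, set[str]] = {}
        for oid, cl in truth.orf_to_cluster.items():
            want.setdefault(cl, set()).add(oid)
        assert got == {frozenset(v) for v in want.values()}


class TestGenPsiteTable:
    def test_periodicity_one_all_frame_zero(self, small_transcriptome):
        table = gen_psite_table(small_transcriptome, 1.0, 2000, seed=1, cds_fraction=1.0)
        assert (table["frame"] == 0).all()

    def test_periodicity_third_uniform(self, small_transcriptome):
        table = gen_psite_table(small_transcriptome, 1 / 3, 10000, seed=2, cds_fraction=1.0)
        frac = table.loc[table["frame"] == 0, "count"].sum() / table["count"].sum()
        se = np.sqrt((1 / 3) * (2 / 3) / 10000)
        assert abs(frac - 1 / 3) < 3 * se

    def test_depth_zero_empty(self, small_transcriptome):
        assert gen_psite_table(small_transcriptome, 0.5, 0, seed=1).empty

    def test_bad_periodicity_rejected(self, small_transcriptome):
        with pytest.raises(ValueError):
            gen_psite_table(small_transcriptome, 1.5, 100, seed=1)

    def test_weights_must_be_positive(self, small_transcriptome):
        with pytest.raises(ValueError):
            gen_psite_table(small_transcriptome, 0.5, 100, read_len_weights={28: 0.0}, seed=1)

    def test_read_lengths_respect_weights(self, small_transcriptome):
        table = gen_psite_table(
            small_transcriptome, 0.8, 5000, read_len_weights={28: 1.0, 30: 0.0}, seed=3
        )
        assert set(table["read_length"]) == {28}

    def test_frame_labels_consistent_with_cds(self, small_transcriptome):
        table = gen_psite_table(small_transcriptome, 0.7, 3000, seed=4, cds_fraction=1.0)
        for row in table.itertuples():
            cs, _ = small_transcriptome[row.transcript_id].cds_tx
            assert (row.tx_position - cs) % 3 == row.frame

    def test_determinism(self, small_transcriptome):
        a = gen_psite_table(small_transcriptome, 0.6, 3000, seed=8)
        b = gen_psite_table(small_transcriptome, 0.6, 3000, seed=8)
        assert a.equals(b)


class TestGenPeptideEvidence:
    def test_specs_satisfied_exactly(self):
        scenario = {"o1": {"riboseq_detected": True, "tryptic": [(0, 9, True), (20, 9, True)]}}
        peptides, records = gen_peptide_evidence({"o1": 40}, scenario, seed=1)
        assert [(p.aa_start, p.aa_len, p.uniquely_mapping) for p in peptides] == [
            (0, 9, True), (20, 9, True),
        ]
        assert records[0].riboseq_detected

    def test_hla_sources_propagated(self):
        scenario = {"o1": {"hla": [(0, 9, "studyA"), (15, 9, "studyB")]}}
        _, records = gen_peptide_evidence({"o1": 30}, scenario, seed=1)
        assert {p.source_id for p in records[0].hla} == {"studyA", "studyB"}

    def test_empty_scenario(self):
        peptides, records = gen_peptide_evidence({}, {}, seed=1)
        assert peptides == [] and records == []

    def test_peptide_beyond_orf_raises(self):
        with pytest.raises(ValueError, match="outside ORF"):
            gen_peptide_evidence({"o1": 10}, {"o1": {"tryptic": [(5, 9, True)]}}, seed=1)

    def test_all_seven_tiers_constructible(self):
        from orfkit.evidence_tiers import tier_table

        scenario = {
            "t1a": {"riboseq_detected": True, "tryptic": [(0, 9, True), (20, 9, True)]},
            "t1b": {"riboseq_detected": True, "hla": [(0, 9, "s1"), (15, 9, "s2")]},
            "t2a": {"riboseq_detected": True, "tryptic": [(0, 9, True)]},
            "t2b": {"riboseq_detected": True, "hla": [(0, 9, "s1")]},
            "t3": {"hla": [(0, 9, "s1")]},
            "t4": {"riboseq_detected": True},
            "t5": {"insilico_predicted": True},
        }
        lengths = {k: 40 for k in scenario}
        _, records = gen_peptide_evidence(lengths, scenario, seed=2)
        per_orf, _ = tier_table(records)
        assert sorted(per_orf["tier"]) == ["1A", "1B", "2A", "2B", "3", "4", "5"]


class TestJitterRecoveryProperty:
    def test_analytic_threshold_recovers_partition(self, small_transcriptome):
        profile = CallerProfile(name="j", jitter_prob=0.8, max_jitter_codons=2)
        callsets, truth = gen_orf_callsets(small_transcriptome, PER_CAT, [profile], 6, seed=21)
        pooled = [c for calls in callsets.values() for c in calls]
        max_jitter_nt = 3 * profile.max_jitter_codons
        threshold = min(
            (orf_nt_length(o) - max_jitter_nt) / orf_nt_length(o)
            for o in truth.true_orfs.values()
        )
        clusters = build_unique_clusters(pooled, threshold)
        got = {frozenset(c.member_ids) for c in clusters}
        want: dict[str, set[str]] = {}
        for oid, cl in truth.orf_to_cluster.items():
            want.setdefault(cl, set()).add(oid)
        assert got == {frozenset(v) for v in want.values()}
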