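"""Poly(A)-site clustering and APA statistics: examples, oracles, recovery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tailshift import (ConfigurationError, GeneModel, TranscriptModel,
                       ValidationError, annotate_final_exon, apa_analysis,
                       apa_d_statistic, classify_apa_shift, cluster_pas,
                       global_mean_red, red_score, select_pas_pair)
from tailshift.apa import PasCluster

from conftest import stage_samples
from test_annotation import mirror_transcript


def endpoints(*positions, sample="s1"):
    return [(p, sample) for p in positions]


class TestClustering:
    def test_gap_larger_than_window_splits(self):
        cl = cluster_pas(endpoints(100, 100, 100, 101, 101, 160, 160, 160, 160),
                         window=24)
        assert [(c.mode_pos, c.total_count) for c in cl] == [(100, 5), (160, 4)]

    def test_single_endpoint(self):
        cl = cluster_pas(endpoints(500), window=24)
        assert len(cl) == 1 and cl[0].span == (500, 500)

    def test_gap_equal_to_window_merges(self):
        cl = cluster_pas(endpoints(100, 124), window=24)
        assert len(cl) == 1

    def test_mode_tie_breaks_toward_stop(self):
        cl = cluster_pas(endpoints(100, 100, 110, 110), window=24,
                         strand="+", stop_codon_pos=90)
        assert cl[0].mode_pos == 100
        cl = cluster_pas(endpoints(100, 100, 110, 110), window=24,
                         strand="-", stop_codon_pos=150)
        assert cl[0].mode_pos == 110

    def test_negative_window_rejected(self):
        with pytest.raises(ConfigurationError):
            cluster_pas(endpoints(1), window=-1)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.integers(0, 2000), min_size=1, max_size=200),
           st.integers(0, 60))
    def test_matches_transitive_closure_oracle(self, positions, window):
        """Single-linkage over sorted gaps equals brute-force transitive
        closure of the 'within window' relation."""
        pts = endpoints(*positions)
        got = [sorted(p for p in range(c.span[0], c.span[1] + 1)
                      if p in positions)
               for c in cluster_pas(pts, window)]
        # oracle: union-find over all pairs
        uniq = sorted(set(positions))
        parent = {p: p for p in uniq}

        def find(p):
            while parent[p] != p:
                p = parent[p]
            return p

        for a in uniq:
            for b in uniq:
                if abs(a - b) <= window:
                    ra, rb = find(a), find(b)
                    parent[ra] = rb
        groups = {}
        for p in uniq:
            groups.setdefault(find(p), []).append(p)
        oracle = sorted(sorted(g) for g in groups.values())
        assert sorted(got) == oracle


def final_exon_cluster(pos, count, stop=1000):
    c = PasCluster(gene_id="g", chrom="chr1", strand="+", mode_pos=pos,
                   span=(pos, pos), counts={"s1": count}, in_final_exon=True)
    return c


class TestPairSelection:
    def tx(self):
        return TranscriptModel(transcript_id="t", chrom="chr1", strand="+",
                               exons=((1, 2000),), cds=(100, 1000))

    def test_top_two_by_count_ordered_by_distance(self):
        cl = [final_exon_cluster(1050, 50), final_exon_cluster(1300, 30),
              final_exon_cluster(1500, 5)]
        ppas, dpas = select_pas_pair(cl, self.tx())
        assert (ppas.mode_pos, dpas.mode_pos) == (1050, 1300)

    def test_fewer_than_two_qualifying_is_none(self):
        cl = [final_exon_cluster(1050, 50), final_exon_cluster(1300, 3)]
        assert select_pas_pair(cl, self.tx(), min_count=5) is None

    def test_count_tie_broken_by_proximity(self):
        cl = [final_exon_cluster(1500, 30), final_exon_cluster(1100, 30),
              final_exon_cluster(1300, 30)]
        ppas, dpas = select_pas_pair(cl, self.tx())
        assert (ppas.mode_pos, dpas.mode_pos) == (1100, 1300)


class TestDStatistic:
    def test_printed_formula_example(self):
        d, sig = apa_d_statistic(2, 8, 8, 2, pseudocount=1e-9)
        assert d == pytest.approx(4.0, abs=1e-6)
        assert sig

    def test_equal_usage_is_zero(self):
        d, sig = apa_d_statistic(5, 5, 5, 5)
        assert d == 0.0 and not sig

    def test_pseudocount_handles_zero_counts(self):
        d, _ = apa_d_statistic(5, 5, 5, 0, pseudocount=1.0)
        assert d == pytest.approx(math.log2(6), abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            apa_d_statistic(-1, 2, 3, 4)

    def test_threshold_interpretations(self):
        # d = 0.35: significant under d > 0.3, not under d > log2(1.3)
        counts = None
        for dpas1 in range(1, 2000):
            d, _ = apa_d_statistic(100, dpas1, 100, 100, pseudocount=1e-9)
            if 0.33 < d < 0.37:
                counts = (100, dpas1, 100, 100)
                break
        assert counts is not None
        _, sig_log2 = apa_d_statistic(*counts, pseudocount=1e-9, mode="log2")
        _, sig_fold = apa_d_statistic(*counts, pseudocount=1e-9, mode="fold")
        assert sig_log2 and not sig_fold

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.tuples(*[st.integers(0, 500)] * 4),
           st.sampled_from(["log2", "fold", "usage"]))
    def test_condition_swap_symmetry(self, counts, mode):
        p1, d1, p2, d2 = counts
        d_a, sig_a = apa_d_statistic(p1, d1, p2, d2, mode=mode)
        d_b, sig_b = apa_d_statistic(p2, d2, p1, d1, mode=mode)
        assert d_a == pytest.approx(d_b, abs=1e-12)
        assert sig_a == sig_b


class TestRedAndClassification:
    def test_red_example(self):
        c = 1e-9
        r1 = red_score(4, 4, c)
        r2 = red_score(2, 8, c)
        assert r1 == pytest.approx(0.0, abs=1e-6)
        assert r2 - r1 == pytest.approx(-2.0, abs=1e-6)

    def test_identical_usage_zero_delta(self):
        assert red_score(6, 3) - red_score(6, 3) == 0.0

    def test_classification_rules(self):
        assert classify_apa_shift(True, -2.0) == "proximal_up"
        assert classify_apa_shift(True, 2.0) == "distal_up"
        assert classify_apa_shift(False, -2.0) == "unchanged"
        assert classify_apa_shift(True, 0.0) == "unchanged"

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.tuples(*[st.integers(0, 500)] * 4))
    def test_delta_red_antisymmetric_under_swap(self, counts):
        p1, d1, p2, d2 = counts
        delta_a = red_score(d2, p2) - red_score(d1, p1)
        delta_b = red_score(d1, p1) - red_score(d2, p2)
        assert delta_a == pytest.approx(-delta_b, abs=1e-12)


def _mirror_reads(reads, about):
    out = reads.copy()
    out["three_prime_pos"] = about - out["three_prime_pos"]
    out["strand"] = out["strand"].map({"+": "-", "-": "+"})
    return out


def _mirror_genes(genes, about):
    flip = {"+": "-", "-": "+"}
    return [GeneModel(gene_id=g.gene_id, chrom=g.chrom, strand=flip[g.strand],
                      transcripts=tuple(mirror_transcript(t, about)
                                        for t in g.transcripts))
            for g in genes]


class TestEquivariance:
    def test_translation_and_mirror_leave_results_unchanged(self, small_fixture):
        cfg, genes, reads, _, _ = small_fixture
        s1 = stage_samples(reads, cfg.stages[0])
        s2 = stage_samples(reads, cfg.stages[-1])
        base = {r.gene_id: (r.d_statistic, r.delta_red, r.shift_class)
                for r in apa_analysis(reads, genes, s1, s2)}
        assert base

        shift = 7777
        genes_t = [GeneModel(
            gene_id=g.gene_id, chrom=g.chrom, strand=g.strand,
            transcripts=tuple(TranscriptModel(
                transcript_id=t.transcript_id, chrom=t.chrom, strand=t.strand,
                exons=tuple((s + shift, e + shift) for s, e in t.exons),
                cds=(t.cds[0] + shift, t.cds[1] + shift),
                as_class=t.as_class) for t in g.transcripts))
            for g in genes]
        reads_t = reads.assign(three_prime_pos=reads["three_prime_pos"] + shift)
        trans = {r.gene_id: (r.d_statistic, r.delta_red, r.shift_class)
                 for r in apa_analysis(reads_t, genes_t, s1, s2)}
        assert trans == base

        about = 50_000_000
        mirr = {r.gene_id: (r.d_statistic, r.delta_red, r.shift_class)
                for r in apa_analysis(_mirror_reads(reads, about),
                                      _mirror_genes(genes, about), s1, s2)}
        assert mirr == base


class TestRecovery:
    def test_planted_shifts_detected_with_low_false_positive_rate(
            self, default_fixture):
        cfg, genes, reads, _, truth = default_fixture
        s1 = stage_samples(reads, cfg.stages[0])
        s2 = stage_samples(reads, cfg.stages[-1])
        res = apa_analysis(reads, genes, s1, s2)
        planted = set(truth.apa_shift_genes)
        tested = {r.gene_id for r in res}
        sig = {r.gene_id for r in res if r.significant}
        assert len(planted & tested) >= 10
        sens = len(sig & planted) / len(planted & tested)
        fpr = len(sig - planted) / len(tested - planted)
        assert sens >= 0.8
        assert fpr <= 0.10
        # planted proximal shifts are classified as such
        prox = {r.gene_id for r in res if r.shift_class == "proximal_up"}
        assert len(prox & planted) / len(planted & tested) >= 0.8

    def test_global_mean_red_negative_under_proximal_shift(
            self, default_fixture):
        cfg, genes, reads, _, _ = default_fixture
        s1 = stage_samples(reads, cfg.stages[0])
        s2 = stage_samples(reads, cfg.stages[-1])
        res = apa_analysis(reads, genes, s1, s2)
        assert len(res) >= 50
        assert global_mean_red(res) < 0

    def test_empty_result_is_explicit(self):
        assert global_mean_red([]) is None
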