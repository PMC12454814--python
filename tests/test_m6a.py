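"""m6A stoichiometry, region assignment, metagene profiles, Fisher tests."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from tailshift import (TranscriptModel, ValidationError,
                       aggregate_site_counts, assign_region, m6a_diff_all,
                       m6a_diff_test, metagene_profile)
from tailshift.m6a import (M6aSiteCounts, fisher_exact_two_sided,
                           stage_m6a_rate_distribution)

from conftest import stage_samples
from test_annotation import mirror_transcript


def site_counts(n_mod, n_unmod, reps=None):
    reps = reps if reps is not None else {"s1": (n_mod, n_unmod)}
    return M6aSiteCounts(site=("chr1", 100, "+"), gene_id="g1",
                         n_mod=n_mod, n_unmod=n_unmod, per_replicate=reps)


def hypergeom_two_sided(a, b, c, d):
    """Enumeration oracle: sum P(table) over all tables with the observed
    margins whose probability <= the observed table's."""
    r1, c1, n = a + b, a + c, a + b + c + d
    rv = scipy.stats.hypergeom(n, c1, r1)
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


class TestSiteCounts:
    def test_ratio_formula(self):
        assert site_counts(7, 3).ratio == pytest.approx(0.7)

    def test_ratio_bounds(self):
        assert site_counts(0, 10).ratio == 0.0
        assert site_counts(10, 0).ratio == 1.0

    def test_zero_coverage_is_untestable_never_zero(self):
        sc = site_counts(0, 0, reps={})
        assert not sc.testable
        with pytest.raises(ValidationError):
            _ = sc.ratio

    def test_aggregation_pools_and_keeps_replicates(self):
        modcalls = pd.DataFrame({
            "read_id": [f"r{i}" for i in range(10)],
            "gene_id": "g1", "site_chrom": "chr1", "site_pos": 100,
            "site_strand": "+",
            "modified": [1] * 7 + [0] * 3})
        reads = pd.DataFrame({"read_id": [f"r{i}" for i in range(10)],
                              "sample_id": ["a"] * 5 + ["b"] * 5})
        out = aggregate_site_counts(modcalls, reads, ["a", "b"])
        sc = out[("chr1", 100, "+")]
        assert (sc.n_mod, sc.n_unmod) == (7, 3)
        assert sc.per_replicate["a"] == (5, 0)
        assert sc.per_replicate["b"] == (2, 3)

    def test_duplicate_call_rejected(self):
        modcalls = pd.DataFrame({
            "read_id": ["r1", "r1"], "gene_id": "g1", "site_chrom": "chr1",
            "site_pos": 100, "site_strand": "+", "modified": [1, 0]})
        reads = pd.DataFrame({"read_id": ["r1"], "sample_id": ["a"]})
        with pytest.raises(ValidationError):
            aggregate_site_counts(modcalls, reads, ["a"])


def make_tx(strand="+"):
    return TranscriptModel(transcript_id="t", chrom="chr1", strand=strand,
                           exons=((1, 100), (201, 300)), cds=(51, 250))


class TestRegionAssignment:
    def test_cds_terminus_inclusive(self):
        assert assign_region(250, make_tx()) == "CDS"

    def test_first_utr3_base(self):
        assert assign_region(251, make_tx()) == "3UTR"

    def test_upstream_of_cds(self):
        assert assign_region(50, make_tx()) == "5UTR"

    def test_minus_strand_mirror(self):
        m = mirror_transcript(make_tx(), about=1000)
        # genomic 250 mirrors to 750; still the CDS terminus
        assert assign_region(750, m) == "CDS"
        assert assign_region(749, m) == "3UTR"

    def test_intronic_site_unassigned(self):
        assert assign_region(150, make_tx()) == "unassigned"


class TestMetagene:
    def test_single_mid_cds_site(self):
        t = make_tx()  # utr5 50, cds 150, utr3 50 (spliced)
        pos = t.transcript_to_genomic(t.utr5_len + t.cds_len // 2)
        prof = metagene_profile([pos], lambda _: t, bins_per_region=10)
        assert prof[15] == 1.0
        assert prof.sum() == pytest.approx(1.0)

    def test_profile_sums_to_one(self):
        t = make_tx()
        positions = [t.transcript_to_genomic(o) for o in range(0, 200, 7)]
        prof = metagene_profile(positions, lambda _: t, bins_per_region=10)
        assert prof.sum() == pytest.approx(1.0)

    def test_empty_input_gives_zero_profile(self):
        prof = metagene_profile([], lambda _: make_tx(), bins_per_region=10)
        assert prof.sum() == 0.0 and len(prof) == 30

    def test_uniform_scaled_positions_are_flat(self):
        """Sites drawn uniformly on the scaled region axis give a profile a
        chi-square test does not reject as non-uniform."""
        t = make_tx()
        rng = np.random.default_rng(5)
        bounds = {"5UTR": (0, t.utr5_len),
                  "CDS": (t.utr5_len, t.utr5_len + t.cds_len),
                  "3UTR": (t.utr5_len + t.cds_len, t.exonic_length)}
        positions = []
        for _ in range(10_000):
            lo, hi = bounds[("5UTR", "CDS", "3UTR")[rng.integers(3)]]
            off = lo + int(rng.random() * (hi - lo))
            positions.append(t.transcript_to_genomic(off))
        prof = metagene_profile(positions, lambda _: t, bins_per_region=10)
        counts = prof * 10_000
        _, p = scipy.stats.chisquare(counts)
        assert p > 0.001

    def test_invariant_under_mirroring(self):
        t = make_tx()
        m = mirror_transcript(t, about=1000)
        offs = list(range(0, t.exonic_length, 13))
        prof_t = metagene_profile([t.transcript_to_genomic(o) for o in offs],
                                  lambda _: t, bins_per_region=10)
        prof_m = metagene_profile([m.transcript_to_genomic(o) for o in offs],
                                  lambda _: m, bins_per_region=10)
        assert np.allclose(prof_t, prof_m)


class TestDifferentialM6a:
    def test_no_association(self):
        r = m6a_diff_test(site_counts(5, 5), site_counts(5, 5))
        assert r.p_value == pytest.approx(1.0)
        assert r.delta == 0.0 and not r.significant

    def test_complete_separation_p(self):
        r = m6a_diff_test(site_counts(10, 0), site_counts(0, 10))
        assert r.p_value == pytest.approx(2 / 184756, rel=1e-9)

    def test_moderate_association(self):
        r = m6a_diff_test(site_counts(8, 2), site_counts(2, 8))
        assert r.p_value == pytest.approx(0.023, abs=5e-4)
        assert abs(r.delta) == pytest.approx(0.6)
        assert r.significant

    def test_untestable_site_rejected(self):
        with pytest.raises(ValidationError):
            m6a_diff_test(site_counts(0, 0, reps={}), site_counts(5, 5))

    def test_fisher_matches_enumeration_sample(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 12, 4)
            assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(
                hypergeom_two_sided(a, b, c, d), abs=1e-9)

    def test_swap_antisymmetry(self):
        r_ab = m6a_diff_test(site_counts(8, 2), site_counts(3, 7))
        r_ba = m6a_diff_test(site_counts(3, 7), site_counts(8, 2))
        assert r_ab.delta == pytest.approx(-r_ba.delta)
        assert r_ab.p_value == pytest.approx(r_ba.p_value, abs=1e-12)

    def test_bh_adjustment_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        from tailshift.m6a import bh_adjust
        rng = np.random.default_rng(8)
        p = rng.random(200) ** 2
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_adjust(p), ref, atol=1e-12)

    def test_fdr_flag_is_more_conservative(self, small_fixture):
        cfg, _, reads, modcalls, _ = small_fixture
        s1 = stage_samples(reads, cfg.stages[0])
        s2 = stage_samples(reads, cfg.stages[-1])
        raw = m6a_diff_all(modcalls, reads, s1, s2)
        adj = m6a_diff_all(modcalls, reads, s1, s2, fdr=True)
        assert (adj["q_value"] >= adj["p_value"] - 1e-12).all()
        assert adj["significant"].sum() <= raw["significant"].sum()

    def test_planted_deltas_recovered(self, default_fixture):
        cfg, _, reads, modcalls, truth = default_fixture
        s1 = stage_samples(reads, cfg.stages[0])
        s2 = stage_samples(reads, cfg.stages[-1])
        res = m6a_diff_all(modcalls, reads, s1, s2)
        key = (res["site_chrom"] + ":" + res["site_pos"].astype(str) + ":"
               + res["site_strand"])
        planted = set(truth.m6a_diff_sites)
        tested = set(key)
        sig = set(key[res["significant"]])
        assert len(planted & tested) >= 20
        assert len(sig & planted) / len(planted & tested) >= 0.8
        assert len(sig - planted) / len(tested - planted) <= 0.05 + 0.02
        # planted sites gain methylation late: delta positive
        sub = res[key.isin(planted) & res["significant"]]
        assert (sub["delta"] > 0).mean() >= 0.9


class TestStageRates:
    def test_gene_rate_is_mean_of_site_ratios(self):
        modcalls = pd.DataFrame({
            "read_id": [f"r{i}" for i in range(10)],
            "gene_id": "g1",
            "site_chrom": "chr1",
            "site_pos": [100] * 5 + [200] * 5,
            "site_strand": "+",
            "modified": [1, 1, 0, 0, 0] + [1, 1, 1, 0, 0]})
        reads = pd.DataFrame({"read_id": [f"r{i}" for i in range(10)],
                              "sample_id": "a", "stage": "A"})
        out = stage_m6a_rate_distribution(modcalls, reads, ["A"])
        assert out.loc[0, "median"] == pytest.approx((0.4 + 0.6) / 2)

    def test_symmetric_beta_rates_center_near_half(self, default_fixture):
        cfg, _, reads, modcalls, _ = default_fixture
        out = stage_m6a_rate_distribution(modcalls, reads, list(cfg.stages))
        assert len(out) == 4
        assert np.allclose(out["median"], 0.5, atol=0.05)

    def test_empty_stage_omitted(self, caplog):
        modcalls = pd.DataFrame(columns=["read_id", "gene_id", "site_chrom",
                                         "site_pos", "site_strand", "modified"])
        reads = pd.DataFrame({"read_id": ["r1"], "sample_id": ["a"],
                              "stage": ["A"]})
        out = stage_m6a_rate_distribution(modcalls, reads, ["A"])
        assert out.empty
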