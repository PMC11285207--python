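import numpy as np
import pandas as pd
import pytest

from flagseq import enrich, synthgen
from flagseq.errors import FitError, ParameterError

from oracles import gp_upper_tail


class TestGPpmf:
    def test_poisson_limit_at_zero(self):
        assert enrich.gp_pmf(0, enrich.GPParams(1.0, 0.0)) == pytest.approx(
            np.exp(-1.0), rel=1e-12)

    def test_direct_evaluation(self):
        # theta=2, lam=0.3, k=1 -> 2 * exp(-2.3)
        assert enrich.gp_pmf(1, enrich.GPParams(2.0, 0.3)) == pytest.approx(
            2.0 * np.exp(-2.3), rel=1e-12)

    @pytest.mark.parametrize("theta", [0.5, 5.0, 50.0])
    @pytest.mark.parametrize("lam", [0.0, 0.2, 0.5, 0.8])
    def test_normalization(self, theta, lam):
        k = np.arange(0, 20000)
        total = np.exp(enrich.gp_logpmf(k, theta, lam)).sum()
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_invalid_params_raise(self):
        with pytest.raises(ParameterError):
            enrich.GPParams(0.0, 0.0)
        with pytest.raises(ParameterError):
            enrich.GPParams(1.0, 1.0)

    def test_rvs_mean_matches(self, rng):
        lam = 0.3
        draws = enrich.gp_rvs(np.full(200_000, 7.0), lam, rng)
        assert draws.mean() == pytest.approx(7.0 / (1 - lam), rel=0.02)


class TestNormalizeReads:
    def test_cap_subsampling(self):
        counts = pd.Series(np.full(100, 20_000))  # 2,000,000 total
        out, excluded = enrich.normalize_reads(counts, seed=0)
        assert not excluded
        assert out.sum() == 1_250_000
        assert (out <= counts).all()

    def test_between_floor_and_cap_unchanged(self):
        counts = pd.Series(np.full(100, 9_000))  # 900,000
        out, excluded = enrich.normalize_reads(counts, seed=0)
        assert not excluded
        assert (out == counts).all()

    def test_below_floor_excluded(self):
        counts = pd.Series(np.full(100, 7_000))  # 700,000
        _, excluded = enrich.normalize_reads(counts, seed=0)
        assert excluded

    def test_deterministic_per_seed(self):
        counts = pd.Series(np.arange(1, 3001))
        a, _ = enrich.normalize_reads(counts, cap=1000, floor=0, seed=7)
        b, _ = enrich.normalize_reads(counts, cap=1000, floor=0, seed=7)
        c, _ = enrich.normalize_reads(counts, cap=1000, floor=0, seed=8)
        assert (a == b).all()
        assert (a != c).any()


class TestFitNullModel:
    def test_parameter_recovery(self, rng):
        y = enrich.gp_rvs(np.full(10_000, 20.0), 0.2, rng)
        params, degenerate = enrich._fit_gp_mle(y)
        assert not degenerate
        assert params.theta == pytest.approx(20.0, rel=0.05)
        assert abs(params.lam - 0.2) <= 0.05

    def test_poisson_recovery(self, rng):
        y = rng.poisson(15.0, size=10_000)
        params, _ = enrich._fit_gp_mle(y)
        assert abs(params.lam) <= 0.03

    def test_degenerate_constant_flagged(self):
        params, degenerate = enrich._fit_gp_mle(np.full(500, 8))
        assert degenerate
        assert params.lam == 0.0

    def test_too_few_observations_raise(self):
        with pytest.raises(FitError):
            enrich.fit_null_model(np.ones(50), np.ones(50), min_bin_obs=200)

    def test_theta_monotone_in_input(self, rng):
        inp = rng.integers(1, 2000, size=5000)
        out = enrich.gp_rvs(inp * 0.8, 0.2, rng)
        model = enrich.fit_null_model(inp, out)
        assert (np.diff(model.thetas) >= 0).all()
        grid = np.array([1, 10, 100, 1000, 5000])
        thetas, _ = model.params_at(grid)
        assert (np.diff(thetas) >= -1e-9).all()


class TestScorePeptides:
    @pytest.fixture()
    def model(self, rng):
        inp = rng.integers(1, 500, size=4000)
        out = enrich.gp_rvs(inp * 0.8, 0.2, rng)
        return inp, out, enrich.fit_null_model(inp, out)

    def test_p_is_one_at_zero_output(self, model):
        inp, out, m = model
        p = enrich.score_peptides(inp, np.zeros_like(out), m)
        assert (p == 1.0).all()

    def test_far_above_null_tiny_p(self, model):
        inp, _, m = model
        p = enrich.score_peptides(np.array([100.0]), np.array([5000]), m)
        assert p[0] < 1e-6

    def test_matches_bruteforce_tail_sum(self, model, rng):
        inp, out, m = model
        idx = rng.choice(len(inp), size=100, replace=False)
        p = enrich.score_peptides(inp[idx], out[idx], m)
        theta, lam = m.params_at(inp[idx])
        for i in range(100):
            expected = gp_upper_tail(int(out[idx][i]), theta[i], lam[i])
            assert p[i] == pytest.approx(max(expected, 1e-300), abs=1e-12)

    def test_monotone_in_output(self, model):
        inp, _, m = model
        ks = np.arange(0, 200)
        p = enrich.score_peptides(np.full_like(ks, 50.0, dtype=float), ks, m)
        assert (np.diff(p) <= 1e-12).all()


class TestCalling:
    def test_bonferroni_flags(self):
        p = np.array([1e-9, 0.04, 0.5])
        p_adj, flags = enrich.call_seropositive(p, m=344_000)
        assert list(flags) == [True, False, False]
        assert p_adj[0] == pytest.approx(3.44e-4)

    def test_all_ones_no_flags(self):
        _, flags = enrich.call_seropositive(np.ones(5), m=10)
        assert not flags.any()

    def test_empty_vector(self):
        p_adj, flags = enrich.call_seropositive(np.array([]), m=0)
        assert len(p_adj) == 0 and len(flags) == 0

    def test_bad_alpha_raises(self):
        with pytest.raises(ParameterError):
            enrich.call_seropositive(np.array([0.5]), m=1, alpha=1.5)

    def test_fold_change_rules(self):
        inp = np.array([50.0, 24.0, 1000.0])
        out = np.array([500.0, 2400.0, 9000.0])
        sero = np.array([True, True, False])
        fc = enrich.compute_fold_change(inp, out, sero)
        assert fc[0] == pytest.approx(10.0)
        assert fc[1] == 0.0  # below 25 input reads
        assert fc[2] == 0.0  # not seropositive

    def test_qc_boundary(self):
        retained = enrich.qc_samples({"a": 199, "b": 200, "c": 5000})
        assert retained == ["b", "c"]
        assert enrich.qc_samples({}) == []


@pytest.fixture(scope="module")
def sim_library():
    template = synthgen.default_template()
    panel = synthgen.generate_reference_panel(template, n_per_class=10,
                                              seed=21)
    tiles, annotations = synthgen.generate_library(panel, n_nonflagellin=80,
                                                   seed=22)
    return tiles, annotations


class TestTypeIAndPower:
    """Null calibration and sensitivity on simulated cohorts (reduced size;
    the full-size check lives in the acceptance suite)."""


    def test_null_familywise_rate(self, sim_library):
        tiles, _ = sim_library
        design = synthgen.CohortDesign(n_cases=30, n_controls=30, seed=23)
        sim = synthgen.simulate_counts(tiles, design,
                                       total_reads_per_sample=100_000)
        calls, _ = enrich.score_matrix(sim.input_counts, sim.output_counts,
                                       floor=0, min_enriched=0)
        fp = calls.groupby("sample_id")["seropositive"].sum()
        assert (fp > 0).mean() <= 0.05
        assert fp.mean() <= 0.05 * 2  # expected false positives per sample

    def test_power_at_factor_20(self, sim_library):
        tiles, annotations = sim_library
        peps = list(annotations.index[annotations["is_flagellin"]][:80])
        design = synthgen.CohortDesign(
            n_cases=15, n_controls=15, seed=24,
            planted_peptide_sets={"s": peps},
            case_binding_prevalence={"s": 0.5},
            control_binding_prevalence={"s": 0.0},
            enrichment_factor_range=(20.0, 50.0))
        sim = synthgen.simulate_counts(tiles, design,
                                       total_reads_per_sample=100_000)
        calls, _ = enrich.score_matrix(sim.input_counts, sim.output_counts,
                                       floor=0, min_enriched=0)
        truth = sim.truth_bound.stack().rename("bound")
        merged = calls.merge(truth, left_on=["peptide_id", "sample_id"],
                             right_index=True)
        bound = merged[merged["bound"] & (merged["input"] >= 25)]
        assert len(bound) > 100
        assert bound["seropositive"].mean() >= 0.9


def test_score_matrix_interface(library):
    tiles, annotations = library
    design = synthgen.CohortDesign(n_cases=4, n_controls=4, seed=30)
    sim = synthgen.simulate_counts(tiles, design,
                                   total_reads_per_sample=60_000)
    calls, qc = enrich.score_matrix(sim.input_counts, sim.output_counts,
                                    floor=0, min_enriched=0, min_bin_obs=100)
    assert set(calls.columns) == {"peptide_id", "sample_id", "input",
                                  "output", "p", "p_adj", "seropositive",
                                  "fold_change"}
    assert len(qc) == 8
    assert qc["retained"].all()
    # invariants from the call contract
    assert (calls["p_adj"] >= calls["p"] - 1e-15).all()
    assert ((calls["fold_change"] > 0) <= (calls["seropositive"]
                                           & (calls["input"] >= 25))).all()
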