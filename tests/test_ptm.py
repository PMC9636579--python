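import numpy as np
import pandas as pd
import pytest

from parpiomics.ptm import (
    AdprDifferential,
    AdprExperiment,
    IronNormalizer,
    PhosphoDifferential,
    iron_normalize,
    ppm_gate,
    regulation_gate,
)
from parpiomics.synth import gen_adpr, gen_phospho_tmt
from parpiomics.tables import SampleDesign


def _matrix(rng, n=400, cols=4, mu=16.0, sd=2.0):
    base = rng.normal(mu, sd, n)
    return pd.DataFrame(
        {f"S{j}": 2.0 ** (base + rng.normal(0, 0.05, n)) for j in range(cols)},
        index=[f"F{i}" for i in range(n)],
    )


class TestIronNormalize:
    def test_identical_columns_are_untouched(self):
        v = 2.0 ** np.linspace(10, 20, 60)
        X = pd.DataFrame({"A": v, "B": v, "C": v})
        out, scales = iron_normalize(X)
        assert np.allclose(out.to_numpy(), X.to_numpy(), rtol=1e-9)
        assert scales.tolist() == pytest.approx([1.0, 1.0, 1.0])

    def test_exact_twofold_column_restored(self):
        v = 2.0 ** np.linspace(10, 20, 80)
        X = pd.DataFrame({"ref": v, "shifted": 2 * v})
        norm = IronNormalizer().fit(X)
        out = norm.transform(X)
        assert norm.reference_ == "ref"
        assert np.allclose(out["shifted"], X["ref"], rtol=1e-6)
        assert norm.scale_factors_["shifted"] == pytest.approx(0.5, abs=1e-6)
        # reference column passes through untouched
        assert np.array_equal(out["ref"].to_numpy(), X["ref"].to_numpy())

    def test_planted_outliers_leave_invariant_set(self):
        rng = np.random.default_rng(0)
        X = _matrix(rng, n=500)
        outliers = rng.choice(500, 50, replace=False)
        X.iloc[outliers, 1] *= 8.0
        norm = IronNormalizer().fit(X)
        excluded = ~norm.invariant_mask_.to_numpy()
        assert excluded[outliers].mean() >= 0.9
        # unperturbed features are brought within 2% of the reference
        out = norm.transform(X)
        clean = np.setdiff1d(np.arange(500), outliers)
        ref = norm.reference_
        for col in X.columns:
            if col == ref:
                continue
            ratio = out.iloc[clean][col] / out.iloc[clean][ref]
            assert np.median(np.abs(np.log2(ratio))) < np.log2(1.02)

    def test_idempotent_on_own_output(self):
        v = 2.0 ** np.linspace(8, 18, 50)
        X = pd.DataFrame({"a": v, "b": 2 * v, "c": 0.5 * v})
        out, _ = iron_normalize(X)
        _, scales2 = iron_normalize(out)
        assert np.allclose(scales2.to_numpy(), 1.0, atol=1e-6)

    def test_median_log_ratio_zero_postcondition(self):
        rng = np.random.default_rng(1)
        X = _matrix(rng)
        norm = IronNormalizer().fit(X)
        out = norm.transform(X)
        inv = norm.invariant_mask_.to_numpy()
        L = np.log2(out.to_numpy())
        ref = list(X.columns).index(norm.reference_)
        for j in range(X.shape[1]):
            if j != ref:
                assert abs(np.median(L[inv, j] - L[inv, ref])) < 1e-6

    def test_too_few_columns_rejected(self):
        with pytest.raises(ValueError):
            iron_normalize(pd.DataFrame({"A": [1.0, 2.0]}))


class TestPpmGate:
    def test_elementwise_vector(self):
        got = ppm_gate([-5.0, -2.0, 0.0, 2.9, 3.2])
        assert got.tolist() == [False, True, True, True, False]

    def test_closed_interval_boundary(self):
        assert ppm_gate([-3.0])[0]
        assert not ppm_gate([-3.01])[0]

    def test_absent_column_is_noop_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = ppm_gate(None)
        assert out.size == 0
        assert "no-op" in caplog.text


class TestPhosphoDifferential:
    def test_planted_recovery_with_expected_threshold(self):
        exp, truth = gen_phospho_tmt(n_sites=2000, n_up=20, n_down=20, seed=0)
        est = PhosphoDifferential().fit(exp)
        assert est.threshold_.threshold == pytest.approx(0.5, rel=0.15)
        hits = set(est.results_.index[est.results_["passes"]])
        planted = set(truth.planted_regulated_sites)
        assert len(hits & planted) / len(planted) >= 0.9
        assert len(hits & planted) / max(len(hits), 1) >= 0.9
        signs = np.sign([truth.planted_regulated_sites[f] for f in sorted(hits & planted)])
        fitted = np.sign(est.results_.loc[sorted(hits & planted), "log2fc"])
        assert np.array_equal(signs, fitted)

    def test_ppm_outliers_excluded_regardless_of_effect(self):
        exp, truth = gen_phospho_tmt(n_sites=1500, seed=1)
        est = PhosphoDifferential().fit(exp)
        out = est.results_.loc[truth.planted_ppm_outliers]
        assert not out["ppm_ok"].any()
        assert not out["passes"].any()

    def test_null_experiment_has_no_passing_sites(self):
        exp, _ = gen_phospho_tmt(n_sites=800, n_up=0, n_down=0, noise_sd=0.0,
                                 channel_bias_sd=0.0, ppm_outlier_rate=0.0, seed=2)
        est = PhosphoDifferential().fit(exp)
        assert not est.results_["passes"].any()

    def test_invariant_to_single_channel_rescaling(self):
        exp, _ = gen_phospho_tmt(n_sites=600, n_up=5, n_down=5, seed=3)
        res1 = PhosphoDifferential().fit(exp).results_
        exp.quant.intensities.iloc[:, 0] *= 7.0  # global inflation of one channel
        res2 = PhosphoDifferential().fit(exp).results_
        assert np.allclose(res1["log2fc"], res2["log2fc"], atol=0.02)
        assert (res1["passes"] == res2["passes"]).mean() > 0.99

    def test_gate_is_strict_at_the_threshold(self):
        assert not regulation_gate([0.5], [0.001], threshold=0.5, p_cutoff=0.05)[0]
        assert regulation_gate([0.5000001], [0.001], threshold=0.5, p_cutoff=0.05)[0]


class TestAdprDifferential:
    def test_planted_hits_recovered_with_direction(self):
        exp, truth = gen_adpr(n_proteins=1000, n_hits=20, seed=0)
        est = AdprDifferential().fit(exp)
        hits = set(est.results_.index[est.results_["passes"]])
        planted = set(truth.planted_adpr_hits)
        assert len(hits & planted) / len(planted) >= 0.9
        assert (est.results_.loc[sorted(planted), "log2fc"] < 0).all()

    def test_null_experiment(self):
        exp, _ = gen_adpr(n_proteins=500, n_hits=0, noise_sd=0.0, missing_rate=0.0, seed=1)
        est = AdprDifferential().fit(exp)
        assert not est.results_["passes"].any()

    def test_direction_flips_when_arms_swapped(self):
        exp, _ = gen_adpr(n_proteins=400, n_hits=10, seed=2)
        res = AdprDifferential().fit(exp).results_
        swapped_design = exp.design.table.copy()
        swapped_design["role"] = swapped_design["role"].map({"treated": "vehicle", "vehicle": "treated"})
        res_sw = AdprDifferential().fit(AdprExperiment(exp.quant, SampleDesign(swapped_design))).results_
        assert np.allclose(res["log2fc"], -res_sw["log2fc"])
        assert (res["passes"] == res_sw["passes"]).all()

    def test_exact_twofold_with_good_p_is_inclusive(self):
        assert regulation_gate([1.0], [0.01], threshold=np.log2(2.0), p_cutoff=0.05,
                               inclusive_fc=True)[0]
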