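"""Firth regression core: closed-form oracles, separation, scan filters."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import ndtr

from stratgwas.firth import (
    EstimabilityError,
    FirthConvergenceWarning,
    firth_fit,
    minor_allele_count,
    scan_stratum,
)


def two_by_two(n11, n10, n01, n00):
    """Design/outcome for a 2x2 table: (cases|x=1, cases|x=0, ctrls|x=1, ctrls|x=0)."""
    x = np.r_[np.ones(n11), np.zeros(n10), np.ones(n01), np.zeros(n00)]
    y = np.r_[np.ones(n11 + n10), np.zeros(n01 + n00)]
    return np.column_stack([np.ones_like(x), x]), y


def penalized_loglik_2x2(beta, alpha, X, y):
    """Direct penalized likelihood for grid verification."""
    eta = alpha + beta * X[:, 1]
    pi = 1 / (1 + np.exp(-eta))
    w = pi * (1 - pi)
    xtwx = (X * w[:, None]).T @ X
    return np.sum(y * eta - np.log1p(np.exp(eta))) + 0.5 * np.linalg.slogdet(xtwx)[1]


class TestFirthFit:
    def test_symmetric_table_gives_zero_effect(self):
        X, y = two_by_two(10, 10, 10, 10)
        fit = firth_fit(X, y)
        assert fit.beta[1] == pytest.approx(0.0, abs=1e-8)
        assert fit.converged

    def test_matches_half_cell_correction(self):
        # for one binary predictor Firth's penalty adds 0.5 to each cell
        X, y = two_by_two(20, 10, 10, 20)
        fit = firth_fit(X, y)
        expected = np.log(20.5 * 20.5 / (10.5 * 10.5))
        assert fit.beta[1] == pytest.approx(expected, abs=1e-6)

    def test_matches_grid_maximized_penalized_likelihood(self):
        # independent oracle: profile the penalized likelihood directly
        X, y = two_by_two(20, 10, 10, 20)
        fit = firth_fit(X, y)

        def neg_profile(b):
            r = minimize_scalar(
                lambda a: -penalized_loglik_2x2(b, a, X, y),
                bounds=(-5, 5), method="bounded",
                options={"xatol": 1e-10},
            )
            return r.fun

        r = minimize_scalar(neg_profile, bounds=(-4, 4), method="bounded",
                            options={"xatol": 1e-8})
        assert fit.beta[1] == pytest.approx(r.x, abs=1e-4)

    def test_separation_yields_finite_estimates(self):
        # ordinary ML diverges on perfectly separated data
        x = np.r_[np.ones(15), np.zeros(15)]
        X = np.column_stack([np.ones_like(x), x])
        fit = firth_fit(X, x.copy())
        assert np.isfinite(fit.beta).all()
        assert np.isfinite(fit.se).all() and (fit.se > 0).all()
        assert fit.converged

    def test_agrees_with_unpenalized_ml_on_large_data(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        n = 10_000
        g = rng.binomial(2, 0.3, n).astype(float)
        eta = -1.0 + np.log(1.5) * g
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        X = np.column_stack([np.ones(n), g])
        fit = firth_fit(X, y)
        ml = sm.Logit(y, X).fit(disp=0)
        assert abs(fit.beta[1] - ml.params[1]) < 0.01

    def test_wald_p_is_two_sided_normal(self):
        X, y = two_by_two(25, 10, 12, 22)
        fit = firth_fit(X, y)
        assert fit.p[1] == pytest.approx(2 * ndtr(-abs(fit.z[1])), rel=1e-12)

    def test_rank_deficient_design_names_columns(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        X = np.column_stack([np.ones(50), x, 2 * x])
        y = (rng.random(50) < 0.5).astype(float)
        with pytest.raises(EstimabilityError, match="collinear"):
            firth_fit(X, y)

    def test_non_binary_outcome_rejected(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="binary"):
            firth_fit(X, np.full(10, 2.0))
        with pytest.raises(ValueError, match="binary"):
            firth_fit(X, np.ones(10))

    def test_non_convergence_is_flagged_not_silent(self):
        X, y = two_by_two(20, 10, 10, 20)
        with pytest.warns(FirthConvergenceWarning):
            fit = firth_fit(X, y, max_iter=1)
        assert not fit.converged


def _scan_inputs(n_var=5, n_samp=400, seed=0, maf=0.3):
    rng = np.random.default_rng(seed)
    dos = rng.binomial(2, maf, size=(n_var, n_samp)).astype(float)
    variants = pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(n_var)],
        "chr": "1", "pos": 1000 * (1 + np.arange(n_var)),
        "ea": "A", "oa": "G",
    })
    samples = pd.DataFrame({
        "status": rng.permutation(np.r_[np.ones(n_samp // 2), np.zeros(n_samp // 2)]),
        "pc1": rng.normal(size=n_samp),
        "pc2": rng.normal(size=n_samp),
        "wga": rng.binomial(1, 0.1, n_samp),
    })
    return dos, variants, samples


class TestScanStratum:
    def test_low_mac_variant_excluded(self):
        dos, variants, samples = _scan_inputs()
        dos[2] = 0.0
        dos[2, :19] = 1.0  # MAC 19 -> filtered
        dos[3] = 0.0
        dos[3, :20] = 1.0  # MAC 20 -> kept
        out = scan_stratum(dos, variants, samples)
        assert "v2" not in out["variant_id"].tolist()
        assert "v3" in out["variant_id"].tolist()

    def test_monomorphic_variant_skipped(self):
        dos, variants, samples = _scan_inputs()
        dos[1] = 2.0
        out = scan_stratum(dos, variants, samples)
        assert "v1" not in out["variant_id"].tolist()
        assert len(out) == 4

    def test_eaf_reported_by_status(self):
        dos, variants, samples = _scan_inputs(seed=5)
        out = scan_stratum(dos, variants, samples)
        case_mask = samples["status"] == 1
        row = out.iloc[0]
        i = variants.index[variants["variant_id"] == row["variant_id"]][0]
        assert row["eaf_cases"] == pytest.approx(dos[i, case_mask].mean() / 2)
        assert row["eaf_controls"] == pytest.approx(dos[i, ~case_mask].mean() / 2)
        assert row["n_cases"] == case_mask.sum()

    def test_covariate_free_scan_equals_collapsed_table_fit(self):
        # a binary dosage with no covariates is exactly a 2x2 problem
        rng = np.random.default_rng(2)
        n = 300
        g = rng.binomial(1, 0.4, n).astype(float)
        status = rng.binomial(1, 0.5, n).astype(float)
        dos = g[None, :].copy()
        variants = pd.DataFrame({
            "variant_id": ["v0"], "chr": "1", "pos": [100], "ea": "A", "oa": "G",
        })
        samples = pd.DataFrame({"status": status})
        out = scan_stratum(dos, variants, samples, covariates=())
        X = np.column_stack([np.ones(n), g])
        direct = firth_fit(X, status)
        assert out["beta"].iloc[0] == pytest.approx(direct.beta[1], abs=1e-9)
        assert out["se"].iloc[0] == pytest.approx(direct.se[1], abs=1e-9)

    def test_stratum_without_both_classes_rejected(self):
        dos, variants, samples = _scan_inputs()
        samples["status"] = 1.0
        with pytest.raises(ValueError, match="lacks cases or controls"):
            scan_stratum(dos, variants, samples)

    def test_all_variants_filtered_warns_and_returns_empty(self):
        dos, variants, samples = _scan_inputs(n_var=2)
        dos[:] = 0.0
        dos[0, 0] = 1.0
        dos[1, 0] = 1.0
        with pytest.warns(UserWarning, match="no variant passed"):
            out = scan_stratum(dos, variants, samples)
        assert out.empty


def test_minor_allele_count_folds_to_minor():
    assert minor_allele_count(np.array([2.0, 2.0, 1.0, 2.0])) == 1
    assert minor_allele_count(np.array([0.0, 1.0, 0.0])) == 1
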