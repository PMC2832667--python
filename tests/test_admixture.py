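"""Admixture regression, pseudopopulation, and panel combination."""

import numpy as np
import pandas as pd
import pytest

from poolancestry.admixture import (
    build_pseudopopulation,
    check_allele_orientation,
    combine_reference_panels,
    fit_admixture,
    ld_thin_snps,
    select_regression_snps,
)
from poolancestry.simulate import SimConfig, simulate_reference_afs


def _panel(snp_ids, af, n=60, call_rate=1.0, chrom=1):
    return pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chrom,
            "pos": np.arange(1, len(snp_ids) + 1) * 1000,
            "allele_a": "A",
            "allele_b": "B",
            "af": af,
            "call_rate": call_rate,
            "n": n,
        }
    )


@pytest.fixture(scope="module")
def two_panels(rng):
    ids = [f"s{i}" for i in range(2000)]
    return {
        "ref1": _panel(ids, rng.uniform(0.05, 0.95, 2000)),
        "ref2": _panel(ids, rng.uniform(0.05, 0.95, 2000)),
    }


class TestSelectRegressionSnps:
    def test_all_pass(self, two_panels):
        qc = pd.DataFrame({"snp_id": two_panels["ref1"]["snp_id"], "qc_pass": True})
        out = select_regression_snps(qc, two_panels)
        assert len(out) == 2000

    def test_call_rate_boundary_excludes(self, two_panels):
        qc = pd.DataFrame({"snp_id": two_panels["ref1"]["snp_id"], "qc_pass": True})
        panels = {k: v.copy() for k, v in two_panels.items()}
        panels["ref2"].loc[0, "call_rate"] = 0.79
        out = select_regression_snps(qc, panels)
        assert panels["ref2"].loc[0, "snp_id"] not in set(out)

    def test_matches_set_intersection_oracle(self, two_panels, rng):
        qc = pd.DataFrame(
            {
                "snp_id": two_panels["ref1"]["snp_id"],
                "qc_pass": rng.random(2000) < 0.7,
            }
        )
        panels = {k: v.copy() for k, v in two_panels.items()}
        for p in panels.values():
            p["call_rate"] = rng.choice([0.7, 0.9, 1.0], size=2000)
        out = set(select_regression_snps(qc, panels))
        oracle = set(qc.loc[qc["qc_pass"], "snp_id"])
        for p in panels.values():
            oracle &= set(p.loc[p["call_rate"] > 0.8, "snp_id"])
        assert out == oracle

    def test_empty_result_rejected(self, two_panels):
        qc = pd.DataFrame({"snp_id": two_panels["ref1"]["snp_id"], "qc_pass": False})
        with pytest.raises(ValueError):
            select_regression_snps(qc, two_panels)


class TestFitAdmixture:
    def test_noiseless_identity(self, two_panels):
        pooled = pd.Series(
            0.8 * two_panels["ref1"]["af"].to_numpy() + 0.2 * two_panels["ref2"]["af"].to_numpy(),
            index=two_panels["ref1"]["snp_id"],
        )
        fit = fit_admixture(pooled, two_panels)
        np.testing.assert_allclose(fit.beta, [0.8, 0.2], atol=1e-10)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)
        assert fit.n_snp == 2000

    def test_intercept_absorption(self, two_panels):
        pooled = pd.Series(
            0.7 * two_panels["ref1"]["af"].to_numpy()
            + 0.2 * two_panels["ref2"]["af"].to_numpy()
            + 0.05,
            index=two_panels["ref1"]["snp_id"],
        )
        fit = fit_admixture(pooled, two_panels)
        np.testing.assert_allclose(fit.beta, [0.7, 0.2], atol=1e-10)
        assert fit.intercept == pytest.approx(0.05, abs=1e-10)
        assert fit.two_c == pytest.approx(0.1, abs=1e-9)

    def test_too_few_snps_rejected(self, two_panels):
        pooled = pd.Series([0.5, 0.4], index=two_panels["ref1"]["snp_id"][:2])
        with pytest.raises(ValueError):
            fit_admixture(pooled, two_panels)

    def test_collinear_panels_warn_but_fit(self, two_panels):
        panels = {
            "ref1": two_panels["ref1"],
            "ref2": two_panels["ref1"].assign(af=two_panels["ref1"]["af"] + 1e-9),
        }
        pooled = pd.Series(
            two_panels["ref1"]["af"].to_numpy(), index=two_panels["ref1"]["snp_id"]
        )
        fit = fit_admixture(pooled, panels)
        assert fit.collinearity_warning

    def test_recovery_with_pooling_noise(self, rng):
        """beta within +-0.01 of (0.82, 0.18) and within 3 SEs at 1e5 SNPs."""
        cfg = SimConfig(n_snps=100_000, seed=17)
        af, truth = simulate_reference_afs(cfg)
        pooled = pd.Series(
            truth["true_admixed_af"].to_numpy() + rng.normal(0, 0.02, len(truth)),
            index=truth["snp_id"],
        )
        panels = {
            "ref1": _panel(truth["snp_id"], af[:, 0]),
            "ref2": _panel(truth["snp_id"], af[:, 1]),
        }
        fit = fit_admixture(pooled, panels)
        for b, true_b, se in zip(fit.beta, (0.82, 0.18), fit.beta_se):
            assert abs(b - true_b) < 0.01
            assert abs(b - true_b) < 3 * se

    def test_robust_to_pooling_error(self, rng):
        """Estimates with and without pooling noise differ by < 0.02."""
        cfg = SimConfig(n_snps=50_000, seed=18)
        af, truth = simulate_reference_afs(cfg)
        panels = {
            "ref1": _panel(truth["snp_id"], af[:, 0]),
            "ref2": _panel(truth["snp_id"], af[:, 1]),
        }
        exact = pd.Series(truth["true_admixed_af"].to_numpy(), index=truth["snp_id"])
        noisy = exact + rng.normal(0, 0.02, len(truth))
        f1, f2 = fit_admixture(exact, panels), fit_admixture(noisy, panels)
        assert np.all(np.abs(f1.beta - f2.beta) < 0.02)


class TestPseudopopulation:
    def test_single_reference_passthrough(self, two_panels):
        pooled = pd.Series(
            two_panels["ref1"]["af"].to_numpy(), index=two_panels["ref1"]["snp_id"]
        )
        fit = fit_admixture(pooled, two_panels)
        pseudo = build_pseudopopulation(fit, two_panels)
        np.testing.assert_allclose(
            pseudo.af.to_numpy(),
            two_panels["ref1"].set_index("snp_id").loc[pseudo.af.index, "af"],
            atol=1e-8,
        )

    def test_effective_sizes(self, two_panels):
        pooled = pd.Series(
            0.5 * two_panels["ref1"]["af"].to_numpy() + 0.5 * two_panels["ref2"]["af"].to_numpy(),
            index=two_panels["ref1"]["snp_id"],
        )
        fit2 = fit_admixture(pooled, two_panels)
        assert build_pseudopopulation(fit2, two_panels).n_effective == 120
        three = dict(two_panels)
        rng3 = np.random.default_rng(3)
        three["ref3"] = _panel(two_panels["ref1"]["snp_id"], rng3.uniform(0.1, 0.9, 2000), n=90)
        fit3 = fit_admixture(pooled, three)
        assert build_pseudopopulation(fit3, three).n_effective == 210

    def test_weighted_combination_arithmetic(self):
        from poolancestry.admixture import AdmixtureFit

        ids = np.array(["a", "b", "c"])
        panels = {"r1": _panel(ids, [0.2, 0.3, 0.4]), "r2": _panel(ids, [0.6, 0.5, 0.4])}
        fit = AdmixtureFit(
            populations=("r1", "r2"), beta=np.array([0.5, 0.5]),
            beta_se=np.zeros(2), intercept=0.0, intercept_se=0.0,
            n_snp=3, snp_ids=ids, condition_number=1.0, collinearity_warning=False,
        )
        pseudo = build_pseudopopulation(fit, panels)
        np.testing.assert_allclose(pseudo.af.to_numpy(), [0.4, 0.4, 0.4], atol=1e-12)
        assert pseudo.pooling_variance == 0.0


class TestCombinePanels:
    def test_equal_sizes(self):
        a = _panel(["x"], [0.2], n=60)
        b = _panel(["x"], [0.4], n=60)
        out = combine_reference_panels(a, b)
        assert out["af"].iloc[0] == pytest.approx(0.3)
        assert out["n"].iloc[0] == 120

    def test_weighted_mean(self):
        a = _panel(["x"], [0.3], n=90)
        b = _panel(["x"], [0.6], n=45)
        assert combine_reference_panels(a, b)["af"].iloc[0] == pytest.approx(0.4)

    def test_disjoint_snp_sets_rejected(self):
        with pytest.raises(ValueError):
            combine_reference_panels(_panel(["x"], [0.3]), _panel(["y"], [0.4]))

    def test_allele_mismatch_excluded(self):
        a = _panel(["x", "y"], [0.3, 0.4])
        b = _panel(["x", "y"], [0.5, 0.6])
        b.loc[1, "allele_a"] = "C"
        out = combine_reference_panels(a, b)
        assert list(out["snp_id"]) == ["x"]


def test_orientation_checker():
    assert check_allele_orientation(np.full(100, 0.5))
    assert not check_allele_orientation(np.full(100, 0.7))


def test_ld_thinning_spacing():
    tbl = pd.DataFrame(
        {"snp_id": [f"s{i}" for i in range(10)], "chrom": 1,
         "pos": np.arange(10) * 50_000 + 1}
    )
    kept = ld_thin_snps(tbl, min_separation=100_000)
    pos = tbl.set_index("snp_id").loc[kept, "pos"].to_numpy()
    assert np.all(np.diff(pos) >= 100_000)
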