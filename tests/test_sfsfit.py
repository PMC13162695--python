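"""Composite-likelihood machinery: expected SFS, likelihoods, fitting, ranking."""

import numpy as np
import pytest
from scipy import stats

from suspop import sfs as sfsmod
from suspop import simgen
from suspop.demomodels import get_template
from suspop.sfs import SfsTensor, _corner_mask
from suspop.sfsfit import (
    FitResult,
    aic_from_lnl,
    bootstrap_ci,
    compare_models,
    composite_loglik,
    expected_sfs,
    fit_model,
    saturated_loglik,
)
from suspop.simgen import DemographicModel, Event


def _one_pop_template(ne=5000.0):
    """Trivial single-population template used for cheap contract tests."""
    from suspop.demomodels import ModelTemplate

    return ModelTemplate(
        model_id="ONE",
        param_names=["N"],
        lower=np.array([1e2]),
        upper=np.array([1e6]),
        log_scale=np.array([True]),
        builder=lambda v: DemographicModel(populations={"A": float(v[0])}, events=[]),
        defaults=np.array([ne]),
    )


class TestExpectedSfs:
    def test_two_haplotypes_point_mass(self):
        p = expected_sfs(_one_pop_template(), [5000.0], {"A": 2}, 500, 3, outgroup=None)
        assert p.shape == (3,)
        assert p[1] == pytest.approx(1.0)
        assert p[0] == p[2] == 0.0

    def test_same_seed_identical(self):
        tpl = get_template("TT5")
        a = expected_sfs(tpl, tpl.default_vector(), {"NAW": 4, "SAW": 4, "TT": 4}, 2000, 9)
        b = expected_sfs(tpl, tpl.default_vector(), {"NAW": 4, "SAW": 4, "TT": 4}, 2000, 9)
        assert np.array_equal(a, b)

    def test_symmetric_split_axis_swap(self):
        """Two equal-size demes from a symmetric split: p invariant under swap."""
        from suspop.demomodels import ModelTemplate

        def build(v):
            return DemographicModel(
                populations={"A": 5000.0, "B": 5000.0},
                events=[Event(time=float(v[0]), kind="split", derived="B", ancestral="A")],
            )

        tpl = ModelTemplate(
            "SYM", ["T"], np.array([10.0]), np.array([1e5]),
            np.array([True]), build, np.array([2000.0]),
        )
        p = expected_sfs(tpl, [2000.0], {"A": 6, "B": 6}, 60_000, 17, outgroup=None)
        assert np.abs(p - p.T).max() < 0.01

    def test_matches_msprime_simulation(self):
        """Dual-route check: kernel expectation vs independent msprime SNPs."""
        tpl = get_template("TT5")
        model = tpl.build(tpl.default_vector())
        mat, _ = simgen.simulate(
            model, {"CEB": 2, "NAW": 3, "SAW": 3, "TT": 3}, 3000, 100_000, 11,
            mode="snp", return_genealogies=False,
        )
        obs = sfsmod.build_sfs(sfsmod.polarize(mat, "CEB"), ["NAW", "SAW", "TT"])
        p = expected_sfs(tpl, tpl.default_vector(), {"NAW": 6, "SAW": 6, "TT": 6},
                         80_000, 5)
        m = obs.counts[~obs.mask]
        pe = p[~obs.mask]
        S = m.sum()
        use = S * pe > 1
        chi2 = float((((m - S * pe) ** 2) / (S * pe))[use].sum())
        pval = 1 - stats.chi2.cdf(chi2, int(use.sum()) - 1)
        assert pval > 0.001

    def test_floor_prevents_zero_probabilities(self):
        tpl = get_template("TT5")
        p = expected_sfs(tpl, tpl.default_vector(), {"NAW": 4, "SAW": 4, "TT": 4}, 50, 3)
        mask = _corner_mask(p.shape)
        assert p[~mask].min() > 0


class TestLikelihoods:
    def test_point_mass_gives_zero_delta(self):
        counts = np.array([0.0, 10.0, 0.0])
        obs = SfsTensor(["A"], counts, False, _corner_mask((3,)))
        p = np.array([0.0, 1.0, 0.0])
        assert composite_loglik(obs, p) == 0.0
        assert saturated_loglik(obs) == 0.0

    def test_hand_arithmetic(self):
        counts = np.array([0.0, 5.0, 5.0, 0.0])
        obs = SfsTensor(["A"], counts, False, _corner_mask((4,)))
        p = np.array([0.0, 0.5, 0.5, 0.0])
        assert composite_loglik(obs, p) == pytest.approx(10 * np.log10(0.5))

    def test_shape_mismatch(self):
        obs = SfsTensor(["A"], np.zeros(3), False, _corner_mask((3,)))
        with pytest.raises(ValueError, match="shape"):
            composite_loglik(obs, np.zeros(4))

    def test_permutation_invariance(self, rng):
        counts = np.zeros(8)
        counts[1:-1] = rng.integers(1, 30, 6)
        mask = _corner_mask((8,))
        p = np.zeros(8)
        p[1:-1] = rng.dirichlet(np.ones(6))
        obs = SfsTensor(["A"], counts, False, mask)
        base = composite_loglik(obs, p)
        perm = rng.permutation(6)
        counts2, p2 = counts.copy(), p.copy()
        counts2[1:-1], p2[1:-1] = counts[1:-1][perm], p[1:-1][perm]
        assert composite_loglik(SfsTensor(["A"], counts2, False, mask), p2) == pytest.approx(base)

    def test_aic_definition(self):
        assert aic_from_lnl(-100.0, 3) == pytest.approx(6 + 200 * np.log(10))


def _small_obs(seed=101, n_loci=4000):
    tpl = get_template("TT5")
    model = tpl.build(tpl.default_vector())
    mat, _ = simgen.simulate(
        model, {"CEB": 2, "NAW": 4, "SAW": 4, "TT": 4}, n_loci, 100_000, seed,
        mode="snp", return_genealogies=False,
    )
    return sfsmod.build_sfs(sfsmod.polarize(mat, "CEB"), ["NAW", "SAW", "TT"])


class TestFitModel:
    def test_reproducible_runs(self):
        obs = _small_obs()
        kwargs = dict(n_cycles_initial=2, n_cycles_total=4, n_sims=400,
                      n_runs=2, seed=5)
        a = fit_model(obs, get_template("TT5"), **kwargs)
        b = fit_model(obs, get_template("TT5"), **kwargs)
        assert [r.lnl_est for r in a] == [r.lnl_est for r in b]
        assert all(np.array_equal(x.params, y.params) for x, y in zip(a, b))

    def test_fit_close_to_truth_oracle(self):
        """Best-run delta within 3x the delta of the true parameters."""
        obs = _small_obs(seed=55, n_loci=8000)
        tpl = get_template("TT5")
        fits = fit_model(obs, tpl, n_cycles_initial=6, n_cycles_total=14,
                         n_sims=1500, n_runs=2, seed=3, initial_sims_frac=0.33)
        best = fits[0]
        sizes = dict(zip(obs.pop_order, obs.sample_sizes))
        s_final = int(np.random.default_rng([3, 2**20 + 7]).integers(1, 2**31 - 1))
        p_truth = expected_sfs(tpl, tpl.default_vector(), sizes, 60_000, s_final)
        delta_truth = saturated_loglik(obs) - composite_loglik(obs, p_truth)
        assert best.converged
        assert best.delta <= 3 * delta_truth

    def test_delta_nonnegative_up_to_noise(self):
        obs = _small_obs(seed=77, n_loci=3000)
        fits = fit_model(obs, get_template("TT1"), n_cycles_initial=2,
                         n_cycles_total=5, n_sims=500, n_runs=2, seed=9)
        assert all(r.delta > -5.0 for r in fits)


class TestCompareModels:
    @staticmethod
    def _fr(mid, k, delta, aic, se=0.0, fp="x"):
        return FitResult(
            model_id=mid, param_names=[f"p{i}" for i in range(k)],
            params=np.zeros(k), lnl_est=-delta, lnl_obs=0.0, delta=delta,
            aic=aic, run_index=0, seed=1, n_sims=100, obs_fingerprint=fp,
            lnl_se=se,
        )

    def test_aic_breaks_equal_likelihood(self):
        a = self._fr("M4", 4, 100.0, aic_from_lnl(-100.0, 4))
        b = self._fr("M2", 2, 100.0, aic_from_lnl(-100.0, 2))
        assert compare_models([a, b])[0].model_id == "M2"

    def test_noise_level_tie_resolved_by_aic(self):
        # delta gap (0.2) below noise resolution and below the AIC parameter
        # penalty (2 / (2 ln10) ~ 0.43 per parameter): parsimony wins
        a = self._fr("M4", 4, 99.8, aic_from_lnl(-99.8, 4), se=2.0)
        b = self._fr("M3", 3, 100.0, aic_from_lnl(-100.0, 3), se=2.0)
        ranked = compare_models([a, b])
        assert ranked[0].model_id == "M3"
        # but with se = 0 the raw delta ordering stands
        a0 = self._fr("M4", 4, 99.8, aic_from_lnl(-99.8, 4))
        b0 = self._fr("M3", 3, 100.0, aic_from_lnl(-100.0, 3))
        assert compare_models([a0, b0])[0].model_id == "M4"

    def test_clear_delta_gap_ranks_first(self):
        a = self._fr("M4", 4, 90.0, aic_from_lnl(-90.0, 4), se=0.5)
        b = self._fr("M3", 3, 100.0, aic_from_lnl(-100.0, 3), se=0.5)
        assert compare_models([a, b])[0].model_id == "M4"

    def test_fingerprint_mismatch(self):
        a = self._fr("A", 2, 1.0, 1.0, fp="x")
        b = self._fr("B", 2, 1.0, 1.0, fp="y")
        with pytest.raises(ValueError, match="different observed spectra"):
            compare_models([a, b])


class TestBootstrap:
    def test_reproducible_and_brackets_estimate(self):
        obs = _small_obs(seed=31, n_loci=5000)
        tpl = get_template("TT5")
        fits = fit_model(obs, tpl, n_cycles_initial=4, n_cycles_total=10,
                         n_sims=1000, n_runs=2, seed=2, initial_sims_frac=0.4)
        sizes = dict(zip(obs.pop_order, obs.sample_sizes))
        kwargs = dict(S=int(obs.n_unmasked), n_boot=4, n_runs_per_boot=1, seed=8,
                      n_sims=800, n_cycles_initial=3, n_cycles_total=8)
        ci1 = bootstrap_ci(fits[0], tpl, sizes, **kwargs)
        ci2 = bootstrap_ci(fits[0], tpl, sizes, **kwargs)
        assert ci1 == ci2
        for name, (lo, hi) in ci1.items():
            assert lo <= hi

    def test_nboot_validation(self):
        obs = _small_obs(seed=31, n_loci=500)
        fits = fit_model(obs, get_template("TT5"), n_cycles_initial=1,
                         n_cycles_total=2, n_sims=200, n_runs=1, seed=2)
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_ci(fits[0], get_template("TT5"), {"NAW": 8, "SAW": 8, "TT": 8},
                         S=100, n_boot=1)
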