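import math

import numpy as np
import pytest

from carrotdom.demography import (
    DomesticationParams,
    bootstrap_params,
    compare_models,
    composite_loglik,
    expected_sfs,
    fit,
    resample_sfs,
)
from carrotdom.sfs import SiteFrequencySpectrum, fold
from carrotdom.simulate import simulate_sfs

from _oracles import hypergeom_weight

PAPER_SCALE = DomesticationParams(
    nu_B=0.02, nu_C=0.10, T_B=0.015, T=1.3, m_WC=0.15, m_CW=6.5,
    variant="asymmetric",
)


class TestParams:
    def test_validation(self):
        with pytest.raises(ValueError, match="positive"):
            DomesticationParams(0.0, 0.1, 0.015, 1.3)
        with pytest.raises(ValueError, match="m_WC = m_CW = 0"):
            DomesticationParams(0.02, 0.1, 0.015, 1.3, m_WC=1.0,
                                variant="no_migration")
        with pytest.raises(ValueError, match="m_WC = m_CW"):
            DomesticationParams(0.02, 0.1, 0.015, 1.3, m_WC=1.0, m_CW=2.0,
                                variant="symmetric")

    def test_unit_conversion(self):
        d = PAPER_SCALE.as_units("2NW")
        assert d["T"] == pytest.approx(1.3 / 2)
        assert d["m_CW"] == pytest.approx(13.0)
        assert d["nu_C"] == 0.10  # sizes are convention-free

    def test_vector_roundtrip(self):
        vec = PAPER_SCALE.to_vector()
        back = DomesticationParams.from_vector("asymmetric", vec)
        assert back == PAPER_SCALE


class TestExpectedSfs:
    def test_shape_mask_and_determinism(self):
        s1 = expected_sfs(PAPER_SCALE, (10, 10), reps=50, seed=5)
        s2 = expected_sfs(PAPER_SCALE, (10, 10), reps=50, seed=5)
        assert s1.counts.shape == (11, 11)
        assert s1.mask[0, 0] and s1.mask[10, 10]
        np.testing.assert_array_equal(s1.counts, s2.counts)
        assert (s1.counts >= 0).all()

    def test_symmetric_equals_asymmetric_at_equal_rates(self):
        sym = DomesticationParams(0.05, 0.5, 0.05, 1.0, m_WC=2.0, m_CW=2.0,
                                  variant="symmetric")
        asym = DomesticationParams(0.05, 0.5, 0.05, 1.0, m_WC=2.0, m_CW=2.0,
                                   variant="asymmetric")
        a = expected_sfs(sym, (6, 6), reps=40, seed=9)
        b = expected_sfs(asym, (6, 6), reps=40, seed=9)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_neutral_limit_marginals_follow_one_over_i(self):
        """With nu_B = nu_C = 1 and no migration each population is just a
        constant-size population, so each marginal spectrum is ~ 1/i."""
        params = DomesticationParams(1.0, 1.0, 0.1, 1.0, variant="no_migration")
        s = expected_sfs(params, (10, 10), reps=4000, seed=17)
        marginal = s.counts.sum(axis=1)[1:-1]
        i = np.arange(1, 10)
        expected = marginal[0] * i[0] / i
        np.testing.assert_allclose(marginal, expected, rtol=0.12)

    def test_instant_split_matches_panmictic_partition(self):
        """As T, T_B -> 0 the two samples come from one panmictic
        population: the joint SFS is the 1/i single-population spectrum of
        20 copies partitioned hypergeometrically between the subsamples."""
        params = DomesticationParams(1.0, 1.0, 1e-5, 1e-5,
                                     variant="no_migration")
        s = expected_sfs(params, (10, 10), reps=4000, seed=23)
        expected = np.zeros((11, 11))
        for i in range(1, 20):
            for a in range(11):
                b = i - a
                if 0 <= b <= 10:
                    expected[a, b] += (2.0 / i) * hypergeom_weight(20, i, 10, a)
        use = ~s.mask
        ratio = s.counts[use].sum() / expected[use].sum()
        resid = s.counts[use] - ratio * expected[use]
        # aggregate agreement: residuals small relative to total mass
        assert np.abs(resid).sum() / s.counts[use].sum() < 0.10
        corr = np.corrcoef(s.counts[use], expected[use])[0, 1]
        assert corr > 0.99


class TestOdeEngineContract:
    """The moment-ODE engine must reproduce the coalescent engine's
    expected spectra (same scale, same parameter conventions)."""

    @pytest.mark.parametrize(
        "params",
        [
            PAPER_SCALE,
            DomesticationParams(0.1, 0.5, 0.05, 0.8, 3.0, 3.0,
                                variant="symmetric"),
            DomesticationParams(1.0, 1.0, 0.1, 1.0, variant="no_migration"),
        ],
        ids=["bottleneck-asym", "symmetric-mig", "neutral"],
    )
    def test_matches_coalescent_engine(self, params):
        ode = fold(expected_sfs(params, (10, 10), engine="ode"))
        acc = None
        for s in (401, 402):
            e = expected_sfs(params, (10, 10), reps=6000, seed=s)
            acc = e.counts if acc is None else acc + e.counts
        mc = fold(SiteFrequencySpectrum(acc / 2))
        use = ~ode.mask & (mc.counts > 0.01 * mc.counts.max())
        rel = np.abs(ode.counts[use] - mc.counts[use]) / mc.counts[use]
        # closure error plus Monte-Carlo noise: a few percent typical
        assert np.median(rel) < 0.06
        assert rel.max() < 0.25
        # absolute scale agrees too (no free normalization)
        assert ode.counts[use].sum() == pytest.approx(
            mc.counts[use].sum(), rel=0.05)


class TestCompositeLoglik:
    def _sfs(self, arr, folded=False):
        return SiteFrequencySpectrum(np.asarray(arr, dtype=float), folded=folded)

    def test_hand_computed_2x2_toy(self):
        obs = self._sfs([[0.0, 2.0], [3.0, 0.0]])
        model = self._sfs([[0.0, 1.0], [3.0, 0.0]])
        expected = 2 * math.log(1 / 4) + 3 * math.log(3 / 4)
        assert composite_loglik(obs, model) == pytest.approx(expected)

    def test_single_unmasked_entry_is_zero(self):
        obs = self._sfs([0.0, 5.0, 0.0])
        model = self._sfs([0.0, 2.5, 0.0])
        assert composite_loglik(obs, model) == pytest.approx(0.0)

    def test_true_model_beats_perturbations(self, rng):
        model = self._sfs(rng.uniform(0.5, 4, size=(6, 6)))
        obs = model.copy()
        obs.counts = 100 * model.counts  # observed = scaled model
        best = composite_loglik(obs, model)
        for _ in range(20):
            pert = model.copy()
            pert.counts = model.counts * rng.uniform(0.6, 1.6, size=(6, 6))
            assert composite_loglik(obs, pert) <= best + 1e-9

    def test_poisson_mode_agrees_on_ranking(self, rng):
        model = self._sfs(rng.uniform(0.5, 4, size=(5, 5)))
        obs = model.copy()
        obs.counts = np.round(50 * model.counts)
        pert = model.copy()
        pert.counts = model.counts * rng.uniform(0.5, 2.0, size=(5, 5))
        assert composite_loglik(obs, model, "poisson") > composite_loglik(
            obs, pert, "poisson"
        )

    def test_shape_and_folding_mismatches_rejected(self, rng):
        a = self._sfs(np.ones((4, 4)))
        b = self._sfs(np.ones((5, 5)))
        with pytest.raises(ValueError, match="shapes"):
            composite_loglik(a, b)
        with pytest.raises(ValueError, match="folding"):
            composite_loglik(fold(a), a)


@pytest.fixture(scope="module")
def observed_600():
    """One folded 10x10 observed spectrum at the study scale (~600 SNPs)."""
    return simulate_sfs(PAPER_SCALE, theta=165.0, sample_sizes=(10, 10),
                        seed=424, folded=True, engine_reps=800)


class TestFit:
    def test_deterministic_given_seed(self, observed_600):
        kw = dict(n_starts=1, seed=3, reps=60, maxfev=40)
        r1 = fit(observed_600, "symmetric", **kw)
        r2 = fit(observed_600, "symmetric", **kw)
        assert r1.params == r2.params and r1.loglik == r2.loglik

    def test_finds_reasonable_scale(self, observed_600):
        res = fit(observed_600, "asymmetric", n_starts=2, seed=1, reps=150,
                  maxfev=200, extra_starts=(PAPER_SCALE,))
        assert np.isfinite(res.loglik)
        assert res.theta_hat > 0
        # the fitted model should beat a grossly wrong one
        wrong = DomesticationParams(1.0, 1.0, 1.0, 0.01, 0.0, 0.0,
                                    variant="asymmetric")
        worse = fit(observed_600, "asymmetric", n_starts=0, seed=1, reps=150,
                    extra_starts=(wrong,))
        assert res.loglik >= worse.loglik

    def test_nesting_inequality_by_construction(self, observed_600):
        comp = compare_models(observed_600, seed=5, n_starts=2, reps=80,
                              maxfev=60)
        ll = {v: f.loglik for v, f in comp["fits"].items()}
        assert ll["no_migration"] <= ll["symmetric"] + 1e-6
        assert ll["symmetric"] <= ll["asymmetric"] + 1e-6
        for key in ("asym_vs_sym", "asym_vs_none", "sym_vs_none"):
            assert 0 <= comp["lrt"][key]["p"] <= 1


class TestBootstrap:
    def test_degenerate_single_entry_handled(self):
        counts = np.zeros((4, 4))
        counts[1, 2] = 30  # one SNP pattern repeated
        obs = SiteFrequencySpectrum(counts)
        rng = np.random.default_rng(0)
        boot = resample_sfs(obs, rng)
        assert boot.counts[1, 2] == 30

    def test_resampling_preserves_total_and_mask(self, observed_600):
        rng = np.random.default_rng(1)
        boot = resample_sfs(observed_600, rng)
        assert boot.total() == pytest.approx(observed_600.total())
        np.testing.assert_array_equal(boot.mask, observed_600.mask)

    def test_seeded_reproducibility(self, observed_600):
        kw = dict(
            n_boot=3, seed=9,
            fit_kwargs=dict(reps=40, maxfev=25, n_starts=1),
        )
        ci1 = bootstrap_params(observed_600, "symmetric", **kw)
        ci2 = bootstrap_params(observed_600, "symmetric", **kw)
        assert ci1 == ci2
        for lo, hi in ci1.values():
            assert lo <= hi
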