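"""Posterior reduction: modes, HPD, pMCMC, h2, diagnostics, predictions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from venomscale import (
    collinearity_check,
    effective_size,
    gelman_rubin,
    heritability_samples,
    hpd_interval,
    pmcmc,
    posterior_mode,
    predict_ld50,
    summarize_model,
)
from venomscale.bpmm import PosteriorSamples
from venomscale.errors import ValidationError
from venomscale.summaries import ConvergenceReport, delta_ld50


def brute_force_hpd(draws, mass=0.95):
    """Oracle: examine every window of ceil(mass*N) sorted draws."""
    x = sorted(draws)
    n = len(x)
    k = math.ceil(mass * n)
    best = None
    for i in range(n - k + 1):
        width = x[i + k - 1] - x[i]
        if best is None or width < best[0]:
            best = (width, x[i], x[i + k - 1])
    return best[1], best[2]


def _chains_from(draws_per_chain, names):
    return [
        PosteriorSamples(
            param_names=names,
            draws=np.asarray(d),
            seed=i,
            n_iter=len(d),
            burn_in=0,
            thin=1,
        )
        for i, d in enumerate(draws_per_chain)
    ]


class TestPosteriorMode:
    def test_constant_draws(self):
        assert posterior_mode([3.3] * 50) == 3.3

    def test_normal_sample_mode_near_mean(self):
        x = np.random.default_rng(1).normal(5.0, 1.0, 10_000)
        assert abs(posterior_mode(x) - 5.0) < 0.1

    def test_right_skew_mode_below_mean(self):
        x = np.exp(np.random.default_rng(2).normal(0.0, 1.0, 10_000))
        assert posterior_mode(x) < x.mean()

    def test_needs_two_draws(self):
        with pytest.raises(ValidationError):
            posterior_mode([1.0])


class TestHpdInterval:
    def test_integer_ladder_spans_950_values(self):
        lo, hi = hpd_interval(np.arange(1, 1001, dtype=float))
        assert hi - lo == 949.0  # 950 consecutive integers

    def test_constant_draws_zero_width(self):
        lo, hi = hpd_interval(np.full(100, 2.5))
        assert lo == hi == 2.5

    def test_normal_limit(self):
        x = np.random.default_rng(3).standard_normal(200_000)
        lo, hi = hpd_interval(x)
        assert lo == pytest.approx(-1.96, abs=0.1)
        assert hi == pytest.approx(1.96, abs=0.1)

    def test_mass_domain(self):
        with pytest.raises(ValidationError):
            hpd_interval(np.arange(100.0), mass=1.5)

    @settings(max_examples=60, derandomize=True)
    @given(
        st.lists(st.floats(-50, 50), min_size=20, max_size=120),
        st.sampled_from([0.5, 0.8, 0.95]),
    )
    def test_matches_brute_force(self, draws, mass):
        assert hpd_interval(draws, mass) == brute_force_hpd(draws, mass)


class TestPmcmc:
    @pytest.mark.parametrize(
        "pos,neg,expected",
        [(900, 100, 0.2), (1000, 0, 0.001), (500, 500, 1.0)],
    )
    def test_sign_counting(self, pos, neg, expected):
        draws = np.concatenate([np.ones(pos), -np.ones(neg)])
        assert pmcmc(draws) == pytest.approx(expected)

    def test_zeros_count_as_neither_sign(self):
        draws = np.array([0.0] * 10 + [1.0] * 9 + [-1.0])
        assert pmcmc(draws) == pytest.approx(2 * 1 / 20)

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(-100, 100).filter(lambda v: v != 0), min_size=5, max_size=60),
        st.floats(0.1, 10.0),
    )
    def test_scale_invariant_and_sign_symmetric(self, draws, c):
        x = np.asarray(draws)
        assert pmcmc(c * x) == pmcmc(x)
        assert pmcmc(-x) == pmcmc(x)


class TestHeritability:
    def test_single_draw_arithmetic(self):
        vs = heritability_samples([0.6] * 30, [0.1] * 30, [0.3] * 30)
        assert vs.h2_draws[0] == pytest.approx(0.6)
        assert vs.h2.mode == pytest.approx(0.6)

    def test_vanishing_animal_variance(self):
        vs = heritability_samples([1e-12] * 30, [0.5] * 30, [0.5] * 30)
        assert vs.h2.mode == pytest.approx(0.0, abs=1e-9)

    def test_proportions_sum_to_one(self, rng):
        va, s, e = rng.gamma(2, 1, 500), rng.gamma(2, 1, 500), rng.gamma(2, 1, 500)
        vs = heritability_samples(va, s, e)
        total = vs.h2_draws + vs.species_draws + vs.residual_draws
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            heritability_samples([0.5] * 30, [0.5] * 29, [0.5] * 30)


class TestGelmanRubin:
    def test_identical_chains_give_exactly_one(self, rng):
        chain = rng.standard_normal(500)
        assert gelman_rubin([chain, chain.copy(), chain.copy()]) == pytest.approx(1.0, abs=1e-9)

    def test_separated_chains_flagged(self, rng):
        a = rng.normal(0.0, 1.0, 500)
        b = rng.normal(10.0, 1.0, 500)
        assert gelman_rubin([a, b]) > 1.1

    def test_well_mixed_chains_near_one(self, rng):
        chains = [rng.standard_normal(20_000) for _ in range(3)]
        assert gelman_rubin(chains) < 1.05

    def test_shrinks_as_chains_grow(self, rng):
        # same-distribution chains: PSRF trends toward 1 over doublings
        values = []
        for n in (200, 800, 3200):
            values.append(gelman_rubin([rng.standard_normal(n) for _ in range(3)]))
        assert values[2] < values[0] + 0.05
        assert values[2] < 1.05

    def test_single_chain_unavailable(self, rng):
        with pytest.raises(ValidationError):
            gelman_rubin([rng.standard_normal(100)])


class TestEffectiveSize:
    def test_iid_limit(self, rng):
        x = rng.standard_normal(10_000)
        assert effective_size(x) == pytest.approx(10_000, rel=0.10)

    def test_constant_degenerate(self):
        assert effective_size(np.full(200, 1.0)) == 0.0

    def test_ar1_analytic(self, rng):
        # AR(1) with coefficient phi has ESS = N (1-phi)/(1+phi) = N/3 at phi=0.5
        n, phi = 50_000, 0.5
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.standard_normal(n)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        assert effective_size(x) == pytest.approx(n / 3, rel=0.15)

    def test_never_exceeds_n(self, rng):
        x = -np.arange(500.0) + rng.standard_normal(500) * 1e-3  # strong trend
        assert effective_size(x) <= 500


class TestSummarizeModel:
    def _summary(self, fixed_draws, rng):
        names = ["intercept", "var_animal", "var_species", "var_residual"]
        chains = []
        for _ in range(2):
            cols = np.column_stack(
                [
                    fixed_draws + rng.standard_normal(len(fixed_draws)) * 1e-9,
                    rng.gamma(2.0, 0.3, len(fixed_draws)),
                    rng.gamma(2.0, 0.01, len(fixed_draws)),
                    rng.gamma(2.0, 0.13, len(fixed_draws)),
                ]
            )
            chains.append(
                PosteriorSamples(
                    param_names=names, draws=cols, seed=0, n_iter=1, burn_in=0, thin=1
                )
            )
        return summarize_model(chains)

    def test_interval_excluding_zero_is_significant(self, rng):
        draws = rng.normal(3.24, 0.5, 2000)  # HPD well inside the positives
        s = self._summary(draws, rng)
        term = s.fixed_term("intercept")
        assert term.significant
        assert term.hpd_lower > 0

    def test_interval_crossing_zero_not_significant(self, rng):
        draws = rng.normal(0.04, 0.09, 2000)
        s = self._summary(draws, rng)
        assert not s.fixed_term("intercept").significant

    def test_all_zero_draws(self, rng):
        s = self._summary(np.zeros(2000), rng)
        term = s.fixed_term("intercept")
        assert term.mode == pytest.approx(0.0, abs=1e-6)
        assert not term.significant

    def test_report_layout(self, rng):
        s = self._summary(rng.normal(1, 1, 2000), rng)
        df = s.to_frame()
        assert list(df["term"][-3:]) == ["phylogeny_h2", "species", "residual"]
        assert s.convergence.psrf is not None


class TestConvergenceReport:
    def test_single_chain_marked_unavailable(self, rng):
        report = ConvergenceReport(psrf=None, ess={"a": 100.0})
        assert report.converged is None

    def test_threshold_drives_flag(self):
        good = ConvergenceReport(psrf={"a": 1.01}, ess={"a": 2000.0})
        bad = ConvergenceReport(psrf={"a": 1.5}, ess={"a": 2000.0})
        assert good.converged and not bad.converged


class TestCollinearity:
    def test_perfect_collinearity_flagged(self, small_dataset):
        import pandas as pd

        from venomscale import AnalysisTable

        df = small_dataset.table.data.copy()
        sp = df.drop_duplicates(subset="species")
        lut = dict(zip(sp["species"], 2.0 * sp["log10_body_length"]))
        df["chela_ratio"] = df["species"].map(lut)
        report = collinearity_check(AnalysisTable(data=df))
        pair = next(p for p in report.pairs if {p.x, p.y} == {"log10_body_length", "chela_ratio"})
        assert pair.r_squared == pytest.approx(1.0)
        assert pair.flagged

    def test_independent_predictors_unflagged(self, default_dataset):
        # generator covariates are drawn independently; this seed shows no
        # spurious correlation among the 36 species
        report = collinearity_check(default_dataset.table)
        assert len(report.pairs) == 3
        assert not report.any_flagged

    def test_too_few_species_refused(self):
        import pandas as pd

        from venomscale import AnalysisTable

        table = AnalysisTable(
            data=pd.DataFrame(
                {
                    "species": ["a", "b"],
                    "log10_ld50": [0.1, 0.2],
                    "log10_body_length": [1.8, 1.9],
                    "chela_ratio": [1.0, 2.0],
                    "telson_ratio": [1.5, 2.5],
                    "route": ["SC", "SC"],
                }
            )
        )
        with pytest.raises(ValidationError):
            collinearity_check(table)

    def test_constant_predictor_skipped_with_note(self, small_dataset):
        import pandas as pd

        from venomscale import AnalysisTable

        df = small_dataset.table.data.copy()
        df["telson_ratio"] = 2.0
        report = collinearity_check(AnalysisTable(data=df))
        assert len(report.pairs) == 1  # only length vs chela survives
        assert len(report.notes) == 2


class TestPrediction:
    def _mode_summary(self, modes, rng):
        """ModelSummary whose fixed-term modes are (approximately) `modes`."""
        names = list(modes) + ["var_animal", "var_species", "var_residual"]
        draws = np.column_stack(
            [np.full(2000, v) + rng.standard_normal(2000) * 1e-9 for v in modes.values()]
            + [rng.gamma(2, 0.2, 2000), rng.gamma(2, 0.01, 2000), rng.gamma(2, 0.1, 2000)]
        )
        chains = [
            PosteriorSamples(param_names=names, draws=draws, seed=0, n_iter=1, burn_in=0, thin=1),
            PosteriorSamples(param_names=names, draws=draws, seed=1, n_iter=1, burn_in=0, thin=1),
        ]
        return summarize_model(chains)

    def test_direct_evaluation(self, rng):
        s = self._mode_summary(
            {
                "intercept": -4.82,
                "log10_body_length": 3.24,
                "chela_ratio": -0.26,
                "telson_ratio": 0.04,
            },
            rng,
        )
        # 10^(-4.82 + 3.24*2 - 0.26*3.7) with the telson term zeroed
        got = predict_ld50(s, body_length_mm=100.0, chela_ratio=3.7, telson_ratio=0.0)
        assert got == pytest.approx(10 ** (-4.82 + 6.48 - 0.962), rel=1e-4)
        assert got == pytest.approx(5.0, rel=0.01)

    def test_power_law_doubling(self, rng):
        s = self._mode_summary(
            {
                "intercept": -4.82,
                "log10_body_length": 3.24,
                "chela_ratio": -0.26,
                "telson_ratio": 0.04,
            },
            rng,
        )
        ratio = predict_ld50(s, 140.0, 3.7, 2.0) / predict_ld50(s, 70.0, 3.7, 2.0)
        assert ratio == pytest.approx(2**3.24, rel=1e-3)

    def test_covariate_free_when_slopes_zero(self, rng):
        s = self._mode_summary(
            {
                "intercept": 1.0,
                "log10_body_length": 0.0,
                "chela_ratio": 0.0,
                "telson_ratio": 0.0,
            },
            rng,
        )
        a = predict_ld50(s, 50.0, 1.0, 1.0)
        b = predict_ld50(s, 190.0, 6.0, 3.5)
        assert a == pytest.approx(b, rel=1e-6)
        assert delta_ld50(
            s,
            {"body_length_mm": 50.0, "chela_ratio": 1.0, "telson_ratio": 1.0},
            {"body_length_mm": 190.0, "chela_ratio": 6.0, "telson_ratio": 3.5},
        ) == pytest.approx(0.0, abs=1e-6)

    def test_nonpositive_length_rejected(self, rng):
        s = self._mode_summary(
            {
                "intercept": 1.0,
                "log10_body_length": 1.0,
                "chela_ratio": 0.0,
                "telson_ratio": 0.0,
            },
            rng,
        )
        with pytest.raises(ValidationError):
            predict_ld50(s, -5.0, 1.0, 1.0)
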