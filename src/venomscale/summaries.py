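"""Posterior reporting: modes, HPD intervals, pMCMC, phylogenetic
heritability, convergence diagnostics, collinearity screening and derived
LD50 predictions.

The reporting dialect follows common practice for phylogenetic mixed
models: point estimates are posterior modes from a kernel density
estimate, intervals are 95% highest-posterior-density intervals, and a
fixed effect is called significant when its HPD interval excludes zero.
pMCMC is the two-sided Monte-Carlo sign probability, floored at 1/N.
Phylogenetic heritability h2 = sigma2_animal / (sigma2_animal +
sigma2_species + sigma2_residual) is computed per draw, then summarized,
so it carries its own credible interval.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .ingest import AnalysisTable

if TYPE_CHECKING:  # pragma: no cover
    from .bpmm import PosteriorSamples

logger = logging.getLogger(__name__)

#: Continuous predictors screened for pairwise collinearity.
_PREDICTORS = ("log10_body_length", "chela_ratio", "telson_ratio")


def posterior_mode(draws: Sequence[float]) -> float:
    """Mode of a posterior sample via Gaussian KDE (Silverman bandwidth).

    The density is evaluated on a 512-point grid spanning the draw range;
    constant samples short-circuit to the shared value (zero-bandwidth
    guard). Mode estimates are bandwidth-sensitive, so the convention is
    fixed rather than configurable.
    """
    x = np.asarray(draws, dtype=float)
    if x.size < 2:
        raise ValidationError("posterior_mode needs at least 2 draws")
    if np.ptp(x) == 0:
        return float(x[0])
    kde = stats.gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def hpd_interval(draws: Sequence[float], mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``ceil(mass * N)`` sorted draws.

    Ties between equal-width windows resolve to the leftmost window.
    """
    if not (0 < mass < 1):
        raise ValidationError(f"mass must be in (0, 1), got {mass}")
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    if n < 20:
        raise ValidationError("hpd_interval needs at least 20 draws")
    k = int(math.ceil(mass * n))
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def pmcmc(draws: Sequence[float]) -> float:
    """Two-sided Monte-Carlo sign probability, floored at 1/N.

    Twice the smaller of the positive and negative draw fractions; exact
    zeros count as neither sign. A finite sample cannot certify
    probability zero, hence the 1/N floor.
    """
    x = np.asarray(draws, dtype=float)
    if x.size < 1:
        raise ValidationError("pmcmc needs at least 1 draw")
    n = x.size
    n_pos = int((x > 0).sum())
    n_neg = int((x < 0).sum())
    return max(1.0 / n, 2.0 * min(n_pos, n_neg) / n)


@dataclass(frozen=True)
class ComponentSummary:
    """Mode and 95% HPD of one variance proportion."""

    mode: float
    hpd_lower: float
    hpd_upper: float


@dataclass
class VarianceSummary:
    """Per-draw variance proportions and their summaries.

    ``h2`` is the phylogenetic heritability (animal share of the total
    variance); the proportions of each draw sum to 1 exactly.
    """

    h2_draws: np.ndarray
    species_draws: np.ndarray
    residual_draws: np.ndarray
    h2: ComponentSummary = field(init=False)
    species: ComponentSummary = field(init=False)
    residual: ComponentSummary = field(init=False)

    def __post_init__(self) -> None:
        for name in ("h2_draws", "species_draws", "residual_draws"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.h2 = _summary_of(self.h2_draws)
        self.species = _summary_of(self.species_draws)
        self.residual = _summary_of(self.residual_draws)


def _summary_of(draws: np.ndarray) -> ComponentSummary:
    lo, hi = hpd_interval(draws)
    return ComponentSummary(mode=posterior_mode(draws), hpd_lower=lo, hpd_upper=hi)


def heritability_samples(
    var_animal: Sequence[float],
    var_species: Sequence[float],
    var_residual: Sequence[float],
) -> VarianceSummary:
    """Per-draw variance proportions: h2, species share, residual share.

    Computing the ratio draw-by-draw (rather than as a ratio of
    summarized variances) lets each proportion carry its own HPD
    interval.
    """
    va = np.asarray(var_animal, dtype=float)
    vs = np.asarray(var_species, dtype=float)
    ve = np.asarray(var_residual, dtype=float)
    if not (va.shape == vs.shape == ve.shape):
        raise ValidationError("variance draw vectors must have equal length")
    if (va < 0).any() or (vs < 0).any() or (ve < 0).any():
        raise ValidationError("variance draws must be non-negative")
    total = va + vs + ve
    if (total <= 0).any():
        raise ValidationError("total variance must be positive in every draw")
    return VarianceSummary(
        h2_draws=va / total, species_draws=vs / total, residual_draws=ve / total
    )


def gelman_rubin(chains: Sequence[Sequence[float]]) -> float:
    """Potential scale reduction factor from between/within chain variance.

    PSRF = sqrt(1 + B_n / W) where W is the mean within-chain variance
    and B_n the variance of the chain means. The finite-sample (n-1)/n
    deflation is omitted so identical chains give exactly 1. No
    rank-normalization.
    """
    arrays = [np.asarray(c, dtype=float) for c in chains]
    if len(arrays) < 2:
        raise ValidationError("gelman_rubin needs at least 2 chains")
    n = arrays[0].size
    if n < 10 or any(a.size != n for a in arrays):
        raise ValidationError("chains must have equal length >= 10")
    within = float(np.mean([a.var(ddof=1) for a in arrays]))
    between_n = float(np.var([a.mean() for a in arrays], ddof=1))
    if within == 0:
        return 1.0 if between_n == 0 else math.inf
    return math.sqrt(1.0 + between_n / within)


def effective_size(draws: Sequence[float]) -> float:
    """Effective sample size N / (1 + 2 sum of autocorrelations).

    The autocorrelation sum is truncated by Geyer's initial positive
    sequence rule: consecutive pairs (rho_2m + rho_2m+1) are accumulated
    until the first non-positive pair sum. Constant chains are degenerate
    and report 0.
    """
    x = np.asarray(draws, dtype=float)
    n = x.size
    if n < 100:
        raise ValidationError("effective_size needs at least 100 draws")
    x = x - x.mean()
    var0 = float(x @ x) / n
    if var0 == 0:
        logger.warning("effective_size: constant chain (degenerate), reporting 0")
        return 0.0
    # autocovariance by FFT
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conjugate(f), m)[:n].real / n
    rho = acov / var0
    tau = -1.0
    for k in range(0, n - 1, 2):
        pair = rho[k] + rho[k + 1] if k + 1 < n else rho[k]
        if pair <= 0:
            break
        tau += 2.0 * pair
    tau = max(tau, 1.0)
    return float(min(n / tau, n))


@dataclass
class ConvergenceReport:
    """Per-parameter PSRF and pooled ESS, plus an overall flag.

    ``psrf`` is None when only one chain was run (diagnostic
    unavailable). ``converged`` requires every PSRF below the threshold;
    with one chain it is None ("unknown"), not True.
    """

    psrf: Optional[dict[str, float]]
    ess: dict[str, float]
    threshold: float = 1.1
    converged: Optional[bool] = field(init=False)

    def __post_init__(self) -> None:
        if self.psrf is None:
            self.converged = None
        else:
            self.converged = all(v < self.threshold for v in self.psrf.values())


@dataclass(frozen=True)
class FixedEffectSummary:
    term: str
    mode: float
    hpd_lower: float
    hpd_upper: float
    pmcmc: float
    significant: bool


@dataclass
class ModelSummary:
    """Fitted-model report: fixed-effect rows, variance proportions,
    convergence diagnostics."""

    fixed: list[FixedEffectSummary]
    variance: VarianceSummary
    convergence: ConvergenceReport
    n_measures: int = 0
    n_species: int = 0

    def fixed_term(self, term: str) -> FixedEffectSummary:
        for f in self.fixed:
            if f.term == term:
                return f
        raise KeyError(term)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "term": f.term,
                "mode": f.mode,
                "hpd_lower": f.hpd_lower,
                "hpd_upper": f.hpd_upper,
                "pMCMC": f.pmcmc,
                "significant": f.significant,
            }
            for f in self.fixed
        ]
        for name, comp in (
            ("phylogeny_h2", self.variance.h2),
            ("species", self.variance.species),
            ("residual", self.variance.residual),
        ):
            rows.append(
                {
                    "term": name,
                    "mode": comp.mode,
                    "hpd_lower": comp.hpd_lower,
                    "hpd_upper": comp.hpd_upper,
                    "pMCMC": float("nan"),
                    "significant": pd.NA,
                }
            )
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            "fixed": [asdict(f) for f in self.fixed],
            "random": {
                "phylogeny_h2": asdict(self.variance.h2),
                "species": asdict(self.variance.species),
                "residual": asdict(self.variance.residual),
            },
            "convergence": {
                "psrf": self.convergence.psrf,
                "ess": self.convergence.ess,
                "threshold": self.convergence.threshold,
                "converged": self.convergence.converged,
            },
            "n_measures": self.n_measures,
            "n_species": self.n_species,
        }

    def write_json(self, path: str | Path, extra: Optional[dict] = None) -> None:
        payload = self.to_json_dict()
        if extra:
            payload.update(extra)
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def convergence_report(chains: Sequence["PosteriorSamples"], threshold: float = 1.1) -> ConvergenceReport:
    """PSRF across chains and pooled (summed per-chain) ESS per parameter."""
    if not chains:
        raise ValidationError("no chains given")
    names = chains[0].param_names
    ess = {}
    for name in names:
        per_chain = []
        for c in chains:
            d = c.param(name)
            per_chain.append(effective_size(d) if d.size >= 100 else float(d.size))
        ess[name] = float(sum(per_chain))
    if len(chains) < 2:
        return ConvergenceReport(psrf=None, ess=ess, threshold=threshold)
    psrf = {name: gelman_rubin([c.param(name) for c in chains]) for name in names}
    return ConvergenceReport(psrf=psrf, ess=ess, threshold=threshold)


def summarize_model(
    chains: Sequence["PosteriorSamples"],
    n_measures: int = 0,
    n_species: int = 0,
) -> ModelSummary:
    """Reduce chains to the standard report layout.

    Draws are pooled across chains for modes, HPDs and pMCMC; a fixed
    term is significant iff zero lies outside its 95% HPD. Non-converged
    fits still produce a summary — the convergence report carries the
    flag.
    """
    report = convergence_report(chains)
    if report.converged is False:
        logger.warning("summarizing a fit whose PSRF exceeds the threshold")
    names = chains[0].param_names
    pooled = {name: np.concatenate([c.param(name) for c in chains]) for name in names}
    fixed = []
    for name in names:
        if name.startswith("var_"):
            continue
        draws = pooled[name]
        lo, hi = hpd_interval(draws)
        fixed.append(
            FixedEffectSummary(
                term=name,
                mode=posterior_mode(draws),
                hpd_lower=lo,
                hpd_upper=hi,
                pmcmc=pmcmc(draws),
                significant=not (lo <= 0.0 <= hi),
            )
        )
    variance = heritability_samples(
        pooled["var_animal"], pooled["var_species"], pooled["var_residual"]
    )
    return ModelSummary(
        fixed=fixed,
        variance=variance,
        convergence=report,
        n_measures=n_measures,
        n_species=n_species,
    )


@dataclass(frozen=True)
class CollinearityPair:
    x: str
    y: str
    slope: float
    r_squared: float
    p_value: float
    flagged: bool


@dataclass
class CollinearityReport:
    pairs: list[CollinearityPair]
    notes: list[str] = field(default_factory=list)

    @property
    def any_flagged(self) -> bool:
        return any(p.flagged for p in self.pairs)


def collinearity_check(table: AnalysisTable, alpha: float = 0.05) -> CollinearityReport:
    """OLS screen for pairwise correlation among the continuous predictors.

    Runs at the species level (one row per species): morphology is
    constant within species, so measure-level replication would fabricate
    sample size. Pairs with a constant predictor are skipped with a note.
    """
    sp = table.data.drop_duplicates(subset="species")
    if len(sp) < 4:
        raise ValidationError("collinearity check needs at least 4 species")
    pairs = []
    notes = []
    for i, xname in enumerate(_PREDICTORS):
        for yname in _PREDICTORS[i + 1 :]:
            x = sp[xname].to_numpy(float)
            y = sp[yname].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                notes.append(f"{xname} vs {yname}: constant predictor, skipped")
                continue
            fit = stats.linregress(x, y)
            pairs.append(
                CollinearityPair(
                    x=xname,
                    y=yname,
                    slope=float(fit.slope),
                    r_squared=float(fit.rvalue**2),
                    p_value=float(fit.pvalue),
                    flagged=bool(fit.pvalue < alpha),
                )
            )
    return CollinearityReport(pairs=pairs, notes=notes)


def predict_ld50(
    summary: ModelSummary,
    body_length_mm: float,
    chela_ratio: float,
    telson_ratio: float = 0.0,
    route: str = "SC",
) -> float:
    """Predicted LD50 (mg/kg) at the posterior modes.

    Evaluates 10^(linear predictor) at the given covariates; SC is the
    dummy baseline, so ``route="SC"`` adds no route term. Passing
    ``telson_ratio=0`` zeroes the telson contribution (useful for
    fitted-line exports adjusted only for the chela ratio).
    """
    if not (body_length_mm > 0):
        raise ValidationError("body length must be positive")
    if summary.convergence.converged is False:
        logger.warning("predicting from a non-converged fit")
    lp = (
        summary.fixed_term("intercept").mode
        + summary.fixed_term("log10_body_length").mode * math.log10(body_length_mm)
        + summary.fixed_term("chela_ratio").mode * chela_ratio
        + summary.fixed_term("telson_ratio").mode * telson_ratio
    )
    if route != "SC":
        lp += summary.fixed_term(f"route_{route}").mode
    return 10.0**lp


def delta_ld50(summary: ModelSummary, setting_a: dict, setting_b: dict) -> float:
    """Difference in predicted LD50 (mg/kg) between two covariate settings.

    Each setting is a dict of ``predict_ld50`` keyword arguments. Used for
    range statements like "the change in LD50 across the span of body
    lengths in the data".
    """
    return predict_ld50(summary, **setting_a) - predict_ld50(summary, **setting_b)
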