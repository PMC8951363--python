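"""Bayesian phylogenetic mixed model fitted by Gibbs sampling.

The model for measure-level log10 LD50 is

    y = X beta + Z u + Z s + e,
    u ~ N(0, sigma2_a * A),   s ~ N(0, sigma2_s * I),   e ~ N(0, sigma2_e * I),

where X holds the fixed effects (intercept, log10 body length — the
exponent of the LD50 ~ length^a power law — chela ratio, telson ratio and
injection-route dummies with SC as baseline), Z maps each LD50 measure to
its species, and A is the phylogenetic relatedness matrix. ``u`` is the
phylogenetically structured "animal" effect, ``s`` the unstructured
species effect absorbing within-species replication.

All full conditionals are conjugate (Gaussian for beta/u/s, inverse-gamma
for the variances), so the sampler is a plain systematic-scan Gibbs
sampler. Priors follow the common weakly informative convention for this
model family: N(0, 1e10) fixed effects and inverse-gamma variances with
V = 1, nu = 0.002.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .errors import ConfigurationError, ValidationError
from .ingest import ROUTES, AnalysisTable
from .phylo import PhyloCovariance

logger = logging.getLogger(__name__)

#: Canonical fixed-effect order; route dummies keep this order with SC baseline.
FIXED_TERMS = ("intercept", "log10_body_length", "chela_ratio", "telson_ratio")
ROUTE_DUMMIES = ("IV", "IP", "IM")
VARIANCE_TERMS = ("var_animal", "var_species", "var_residual")

_VARIANCE_FLOOR = 1e-12


@dataclass
class DesignMatrices:
    """Design matrices and response for one model fit.

    ``species_idx`` is the dense incidence: row i belongs to species
    ``species_idx[i]`` in ``species_order`` (the explicit Z matrix is
    available as a property). ``A`` is the phylogenetic covariance in the
    same species order.
    """

    X: np.ndarray
    y: np.ndarray
    species_idx: np.ndarray
    A: np.ndarray
    fixed_names: list[str]
    species_order: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.species_idx = np.asarray(self.species_idx, dtype=int)
        self.A = np.asarray(self.A, dtype=float)
        n, p = self.X.shape
        q = len(self.species_order)
        if len(self.y) != n or len(self.species_idx) != n:
            raise ValidationError("X, y and species_idx disagree on row count")
        if len(self.fixed_names) != p:
            raise ValidationError("fixed_names does not match X columns")
        if self.A.shape != (q, q):
            raise ValidationError("A does not match the species count")
        counts = np.bincount(self.species_idx, minlength=q)
        if (counts < 1).any():
            raise ValidationError("every species must have at least one measure")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def q(self) -> int:
        return len(self.species_order)

    @property
    def Z(self) -> np.ndarray:
        Z = np.zeros((self.n, self.q))
        Z[np.arange(self.n), self.species_idx] = 1.0
        return Z


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative priors: IG(nu/2, nu*V/2) variances, N(0, fev) betas."""

    V: float = 1.0
    nu: float = 0.002
    fixed_effect_variance: float = 1e10

    def __post_init__(self) -> None:
        if not (self.V > 0 and self.nu > 0):
            raise ConfigurationError("inverse-gamma prior requires V > 0 and nu > 0")
        if self.fixed_effect_variance < 1e8:
            raise ConfigurationError("fixed-effect prior variance must be >= 1e8")


@dataclass(frozen=True)
class MCMCSettings:
    """Chain schedule. Defaults give 1000 stored draws per chain.

    If the post-hoc effective sample size of any reported parameter falls
    below ``min_ess``, the chain is extended (total iterations doubled) up
    to ``max_extensions`` times.
    """

    n_iter: int = 130_000
    burn_in: int = 30_000
    thin: int = 100
    n_chains: int = 3
    min_ess: float = 1000.0
    max_extensions: int = 2

    def __post_init__(self) -> None:
        if self.n_iter <= 0 or self.burn_in < 0 or self.thin <= 0:
            raise ConfigurationError("n_iter, thin must be positive; burn_in >= 0")
        if self.burn_in >= self.n_iter:
            raise ConfigurationError("burn_in must be smaller than n_iter")
        if self.n_chains < 1:
            raise ConfigurationError("need at least one chain")
        if (self.n_iter - self.burn_in) // self.thin < 1:
            raise ConfigurationError("schedule stores no draws")


@dataclass
class PosteriorSamples:
    """Stored draws for one chain (post burn-in, post thinning)."""

    param_names: list[str]
    draws: np.ndarray  # (n_draws, n_params)
    seed: int
    n_iter: int
    burn_in: int
    thin: int
    n_extensions: int = 0
    converged_ess: bool = True

    def param(self, name: str) -> np.ndarray:
        return self.draws[:, self.param_names.index(name)]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.draws, columns=self.param_names)
        df.insert(0, "iteration", self.burn_in + self.thin * (1 + np.arange(len(df))))
        return df

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "PosteriorSamples":
        df = pd.read_csv(path)
        names = [c for c in df.columns if c != "iteration"]
        it = df["iteration"].to_numpy()
        thin = int(it[1] - it[0]) if len(it) > 1 else 1
        burn = int(it[0] - thin)
        return cls(
            param_names=names,
            draws=df[names].to_numpy(),
            seed=-1,
            n_iter=int(it[-1]),
            burn_in=burn,
            thin=thin,
        )


def build_design(table: AnalysisTable, cov: PhyloCovariance) -> DesignMatrices:
    """Construct X, Z (as species indices), A and y from a curated table.

    Fixed-effect columns come in a fixed order: intercept, log10 body
    length, chela ratio, telson ratio, then dummies for the observed
    non-baseline injection routes (IV, IP, IM; SC is the baseline, so an
    SC row has an all-zero dummy block). Dummies for routes never observed
    are dropped (logged) rather than carried as all-zero columns.
    """
    if list(cov.species_order) != list(table.species_names):
        raise ValidationError(
            "covariance species order does not match the analysis table"
        )
    df = table.data
    bad = sorted(set(df["route"]) - set(ROUTES))
    if bad:
        raise ValidationError(f"unknown route levels: {bad}")
    cols = [
        np.ones(len(df)),
        df["log10_body_length"].to_numpy(float),
        df["chela_ratio"].to_numpy(float),
        df["telson_ratio"].to_numpy(float),
    ]
    names = list(FIXED_TERMS)
    observed = set(df["route"])
    for route in ROUTE_DUMMIES:
        if route in observed:
            cols.append((df["route"] == route).to_numpy(float))
            names.append(f"route_{route}")
        else:
            logger.info("route %s not observed; dummy column dropped", route)
    return DesignMatrices(
        X=np.column_stack(cols),
        y=df["log10_ld50"].to_numpy(float),
        species_idx=np.asarray(table.species_index),
        A=cov.matrix,
        fixed_names=names,
        species_order=list(table.species_names),
    )


@dataclass
class GibbsState:
    """Current values of all model blocks."""

    beta: np.ndarray
    u: np.ndarray
    s: np.ndarray
    var_animal: float
    var_species: float
    var_residual: float


class _Precomp:
    """Quantities reused by every sweep: XtX, species counts, A^-1."""

    def __init__(self, design: DesignMatrices):
        self.X = design.X
        self.Xt = design.X.T
        self.XtX = self.Xt @ design.X
        self.y = design.y
        self.idx = design.species_idx
        self.q = design.q
        self.n = design.n
        self.p = design.X.shape[1]
        self.counts = np.bincount(self.idx, minlength=self.q).astype(float)
        A = design.A
        try:
            c = cho_factor(A, lower=True)
        except np.linalg.LinAlgError:
            logger.warning("A not positive definite; adding 1e-10 jitter")
            c = cho_factor(A + 1e-10 * np.eye(self.q), lower=True)
        self.Ainv = cho_solve(c, np.eye(self.q))
        self.Ainv = 0.5 * (self.Ainv + self.Ainv.T)  # enforce symmetry

    def group_sum(self, v: np.ndarray) -> np.ndarray:
        return np.bincount(self.idx, weights=v, minlength=self.q)


def _draw_mvn_from_precision(
    precision: np.ndarray, linear: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw from N(precision^-1 linear, precision^-1)."""
    L = np.linalg.cholesky(precision)
    mean = cho_solve((L, True), linear)
    z = rng.standard_normal(len(linear))
    return mean + solve_triangular(L.T, z, lower=False)


def _draw_inverse_gamma(shape: float, scale: float, rng: np.random.Generator) -> float:
    draw = scale / rng.gamma(shape)
    if draw < _VARIANCE_FLOOR:
        logger.debug("variance draw floored at %g", _VARIANCE_FLOOR)
        return _VARIANCE_FLOOR
    return float(draw)


def gibbs_sweep(
    state: GibbsState,
    design: DesignMatrices,
    prior: PriorSpec,
    rng: np.random.Generator,
    fixed_variances: Optional[tuple[float, float, float]] = None,
    _pre: Optional[_Precomp] = None,
) -> GibbsState:
    """One systematic scan over beta, u, s and the three variances.

    With ``fixed_variances`` the variance components are held at the given
    (animal, species, residual) values — used for sampler validation
    against the closed-form GLS estimator.
    """
    pre = _pre if _pre is not None else _Precomp(design)
    if fixed_variances is not None:
        state.var_animal, state.var_species, state.var_residual = fixed_variances
    ve = max(state.var_residual, _VARIANCE_FLOOR)
    va = max(state.var_animal, _VARIANCE_FLOOR)
    vs = max(state.var_species, _VARIANCE_FLOOR)

    # beta | rest
    resid = pre.y - state.u[pre.idx] - state.s[pre.idx]
    prec = pre.XtX / ve + np.eye(pre.p) / prior.fixed_effect_variance
    state.beta = _draw_mvn_from_precision(prec, pre.Xt @ resid / ve, rng)

    # u (animal) | rest
    resid = pre.y - pre.X @ state.beta - state.s[pre.idx]
    prec_u = pre.Ainv / va + np.diag(pre.counts / ve)
    state.u = _draw_mvn_from_precision(prec_u, pre.group_sum(resid) / ve, rng)

    # s (species) | rest — diagonal precision, elementwise draw
    resid = pre.y - pre.X @ state.beta - state.u[pre.idx]
    prec_s = pre.counts / ve + 1.0 / vs
    mean_s = pre.group_sum(resid) / ve / prec_s
    state.s = mean_s + rng.standard_normal(pre.q) / np.sqrt(prec_s)

    if fixed_variances is None:
        quad_u = float(state.u @ pre.Ainv @ state.u)
        state.var_animal = _draw_inverse_gamma(
            (prior.nu + pre.q) / 2.0, (prior.nu * prior.V + quad_u) / 2.0, rng
        )
        state.var_species = _draw_inverse_gamma(
            (prior.nu + pre.q) / 2.0, (prior.nu * prior.V + state.s @ state.s) / 2.0, rng
        )
        e = pre.y - pre.X @ state.beta - state.u[pre.idx] - state.s[pre.idx]
        state.var_residual = _draw_inverse_gamma(
            (prior.nu + pre.n) / 2.0, (prior.nu * prior.V + e @ e) / 2.0, rng
        )
    return state


def _initial_state(design: DesignMatrices, variances: tuple[float, float, float]) -> GibbsState:
    return GibbsState(
        beta=np.zeros(design.X.shape[1]),
        u=np.zeros(design.q),
        s=np.zeros(design.q),
        var_animal=variances[0],
        var_species=variances[1],
        var_residual=variances[2],
    )


def run_chain(
    design: DesignMatrices,
    prior: PriorSpec,
    settings: MCMCSettings,
    seed: int,
    initial_variances: tuple[float, float, float] = (1.0, 1.0, 1.0),
    fixed_variances: Optional[tuple[float, float, float]] = None,
) -> PosteriorSamples:
    """Run one Gibbs chain; deterministic given ``seed``.

    Stores the fixed effects and the three variance components post
    burn-in, thinned. If any stored parameter's effective sample size is
    below ``settings.min_ess``, the total iteration count is doubled (up
    to ``settings.max_extensions`` doublings, logged); if the target is
    still unmet the result is flagged via ``converged_ess=False``.
    """
    if design.n == 0:
        raise ValidationError("cannot sample from an empty design")
    from .summaries import effective_size  # local import: no module cycle

    pre = _Precomp(design)
    rng = np.random.default_rng(seed)
    state = _initial_state(design, fixed_variances or initial_variances)
    names = list(design.fixed_names) + list(VARIANCE_TERMS)
    draws: list[np.ndarray] = []

    def run_iters(start: int, stop: int) -> None:
        for it in range(start, stop):
            gibbs_sweep(state, design, prior, rng, fixed_variances=fixed_variances, _pre=pre)
            k = it + 1  # 1-based iteration count
            if k > settings.burn_in and (k - settings.burn_in) % settings.thin == 0:
                draws.append(
                    np.concatenate(
                        [state.beta, [state.var_animal, state.var_species, state.var_residual]]
                    )
                )

    total = settings.n_iter
    run_iters(0, total)
    n_ext = 0
    while True:
        arr = np.asarray(draws)
        ess = [effective_size(arr[:, j]) for j in range(arr.shape[1])] if len(arr) >= 100 else None
        if ess is None or min(ess) >= settings.min_ess:
            ok = True
            break
        if n_ext >= settings.max_extensions:
            logger.warning(
                "chain (seed=%d): min ESS %.0f < %.0f after %d extensions; flagged",
                seed,
                min(ess),
                settings.min_ess,
                n_ext,
            )
            ok = False
            break
        n_ext += 1
        logger.info("chain (seed=%d): extending %d -> %d iterations", seed, total, 2 * total)
        run_iters(total, 2 * total)
        total *= 2

    return PosteriorSamples(
        param_names=names,
        draws=np.asarray(draws),
        seed=seed,
        n_iter=total,
        burn_in=settings.burn_in,
        thin=settings.thin,
        n_extensions=n_ext,
        converged_ess=ok,
    )


#: Over-dispersed starting variances, rotated across chains so the
#: Gelman-Rubin diagnostic starts from genuinely separated states.
_INIT_ROTATION = (0.1, 1.0, 10.0)


def chain_seeds(seed: int, n_chains: int) -> list[int]:
    """Derive independent per-chain seeds from one master seed."""
    words = np.random.SeedSequence(seed).generate_state(n_chains, dtype=np.uint32)
    return [int(w) & 0x7FFFFFFF for w in words]


def run_chains(
    design: DesignMatrices,
    prior: PriorSpec,
    settings: MCMCSettings,
    seed: int,
    fixed_variances: Optional[tuple[float, float, float]] = None,
) -> list[PosteriorSamples]:
    """Run ``settings.n_chains`` chains differing only in seed and start values."""
    chains = []
    for i, chain_seed in enumerate(chain_seeds(seed, settings.n_chains)):
        init = (
            _INIT_ROTATION[i % 3],
            _INIT_ROTATION[(i + 1) % 3],
            _INIT_ROTATION[(i + 2) % 3],
        )
        chains.append(
            run_chain(
                design,
                prior,
                settings,
                seed=chain_seed,
                initial_variances=init,
                fixed_variances=fixed_variances,
            )
        )
    if settings.n_chains < 2:
        logger.warning("single chain: convergence diagnostics will be unavailable")
    return chains


def gls_estimate(design: DesignMatrices, variances: tuple[float, float, float]) -> np.ndarray:
    """Closed-form GLS fixed effects at known variance components.

    beta_hat = (X' V^-1 X)^-1 X' V^-1 y with
    V = va * Z A Z' + vs * Z Z' + ve * I. Used as the independent check
    of the Gibbs sampler when variances are held fixed.
    """
    va, vs, ve = variances
    Z = design.Z
    V = va * Z @ design.A @ Z.T + vs * Z @ Z.T + ve * np.eye(design.n)
    Vinv = np.linalg.inv(V)
    XtVi = design.X.T @ Vinv
    return np.linalg.solve(XtVi @ design.X, XtVi @ design.y)
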