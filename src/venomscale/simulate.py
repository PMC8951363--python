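"""Synthetic datasets with the statistical structure the analysis assumes.

The generator emulates the shape of the comparative LD50 dataset: 36
species carrying 62 LD50 measures between them, body lengths spanning
40.5-200 mm, chela ratios 0.7-6.2, subcutaneous injection dominating, and
a response built on a pure-birth phylogeny with a phylogenetically
heritable residual structure. Ground truth (fixed effects, variance
components, every latent draw) is recorded so recovery tests can score
the fitted model against known values.

Covariates are drawn independently of the tree by default: the model's
phylogenetic structure lives in the response, and simulating Brownian
covariates would entangle recovery tests with covariate phylogenetic
signal.
"""

from __future__ import annotations

import json
import logging
import math
import random
from dataclasses import dataclass, field
from pathlib import Path
import dendropy
import numpy as np

from . import ingest
from .bpmm import DesignMatrices, build_design
from .errors import ConfigurationError
from .ingest import AnalysisTable, MorphologyRecord, PotencyRecord, build_analysis_table
from .phylo import Phylogeny, PhyloCovariance, phylo_covariance

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth configuration for one synthetic dataset.

    Defaults mirror the comparative dataset's published shape: dataset
    size (36 species, 62 measures), covariate ranges (body length
    40.5-200 mm drawn log-uniform so log10 length is uniform; chela ratio
    0.7-6.2), a subcutaneous-heavy route mix, the fitted fixed effects
    (intercept -4.82, body-length exponent 3.24, chela -0.26, telson
    0.04, route effects 0) and variance components 0.60 : 0.01 : 0.26
    (animal : species : residual), giving a true phylogenetic
    heritability of 0.60/0.87 ~= 0.69. The telson-ratio range [1, 4] is a
    declared choice — no published range exists for it.
    """

    n_species: int = 36
    total_measures: int = 62
    birth_rate: float = 1.0
    beta_intercept: float = -4.82
    beta_log10_length: float = 3.24
    beta_chela: float = -0.26
    beta_telson: float = 0.04
    route_effects: dict[str, float] = field(
        default_factory=lambda: {"SC": 0.0, "IV": 0.0, "IP": 0.0, "IM": 0.0}
    )
    var_animal: float = 0.60
    var_species: float = 0.01
    var_residual: float = 0.26
    body_length_range_mm: tuple[float, float] = (40.5, 200.0)
    chela_ratio_range: tuple[float, float] = (0.7, 6.2)
    telson_ratio_range: tuple[float, float] = (1.0, 4.0)
    route_probs: dict[str, float] = field(
        default_factory=lambda: {"SC": 0.5, "IV": 0.3, "IP": 0.15, "IM": 0.05}
    )
    subject_mass_kg: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ConfigurationError("need at least 2 species")
        if self.total_measures < self.n_species:
            raise ConfigurationError("total_measures must be >= n_species")
        for v in (self.var_animal, self.var_species, self.var_residual):
            if v < 0:
                raise ConfigurationError("variance components must be non-negative")
        for lo, hi in (
            self.body_length_range_mm,
            self.chela_ratio_range,
            self.telson_ratio_range,
        ):
            if not (0 < lo <= hi):
                raise ConfigurationError("covariate ranges must be positive and ordered")
        if abs(sum(self.route_probs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("route probabilities must sum to 1")

    @property
    def true_h2(self) -> float:
        total = self.var_animal + self.var_species + self.var_residual
        return self.var_animal / total

    def beta_vector(self, fixed_names: list[str]) -> np.ndarray:
        """Truth in a design's column order (route dummies may be dropped)."""
        by_name = {
            "intercept": self.beta_intercept,
            "log10_body_length": self.beta_log10_length,
            "chela_ratio": self.beta_chela,
            "telson_ratio": self.beta_telson,
        }
        for route, eff in self.route_effects.items():
            by_name[f"route_{route}"] = eff
        return np.array([by_name[name] for name in fixed_names])


@dataclass
class SyntheticDataset:
    """One generated dataset plus everything needed to score a fit on it."""

    table: AnalysisTable
    tree: Phylogeny
    covariance: PhyloCovariance
    design: DesignMatrices
    potency: list[PotencyRecord]
    morphology: list[MorphologyRecord]
    truth: dict


def simulate_tree(n_species: int, birth_rate: float = 1.0, seed: int = 0) -> Phylogeny:
    """Pure-birth (Yule) tree, ultrametric, scaled to depth 1.

    The birth-death simulator stops at the n-th speciation, which leaves
    the newest tips with zero-length branches; every tip branch is
    therefore extended by the exponential waiting time to the (unrealized)
    next event, keeping the tree a proper Yule draw and the species
    covariance nonsingular.
    """
    if n_species < 2:
        raise ConfigurationError("a tree needs at least 2 tips")
    from dendropy.model import birthdeath

    rng = random.Random(seed)
    tree = birthdeath.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0, num_extant_tips=n_species, rng=rng
    )
    tree.seed_node.edge.length = None  # drop the simulator's root stem
    extra = rng.expovariate(n_species * birth_rate)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra

    def _depth(node):  # explicit sum: distance_from_root caches stale values
        d = 0.0
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        return d

    depth = max(_depth(leaf) for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None:
            edge.length = (edge.length or 0.0) / depth
    width = len(str(n_species))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{i:0{width}d}"
    return Phylogeny(tree=tree, has_lengths=True)


def simulate_covariates(
    config: GeneratorConfig, tips: list[str], rng: np.random.Generator
) -> tuple[dict[str, dict[str, float]], np.ndarray, list[str]]:
    """Per-species covariates, a measure allocation, and per-measure routes.

    Body length is log-uniform over its range (so log10 length is
    uniform, matching the model's scale); the shape ratios are uniform.
    Every species receives one measure; the remainder is allocated
    multinomially, mimicking the uneven replication of literature data.
    """
    if len(tips) != config.n_species:
        raise ConfigurationError("tip list does not match n_species")
    lo, hi = config.body_length_range_mm
    log_l = rng.uniform(math.log10(lo), math.log10(hi), config.n_species)
    chela = rng.uniform(*config.chela_ratio_range, config.n_species)
    telson = rng.uniform(*config.telson_ratio_range, config.n_species)
    covariates = {
        sp: {
            "total_length_mm": float(10.0 ** log_l[i]),
            "chela_ratio": float(chela[i]),
            "telson_ratio": float(telson[i]),
        }
        for i, sp in enumerate(tips)
    }
    extra = config.total_measures - config.n_species
    counts = np.ones(config.n_species, dtype=int)
    if extra > 0:
        counts += rng.multinomial(extra, np.full(config.n_species, 1.0 / config.n_species))
    species_idx = np.repeat(np.arange(config.n_species), counts)
    route_names = list(config.route_probs)
    probs = np.array([config.route_probs[r] for r in route_names])
    routes = [route_names[j] for j in rng.choice(len(route_names), config.total_measures, p=probs)]
    return covariates, species_idx, routes


def simulate_response(
    design: DesignMatrices,
    beta: np.ndarray,
    var_animal: float,
    var_species: float,
    var_residual: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw y = X beta + Z u + Z s + e; returns (y, u, s, e).

    u is multivariate normal with covariance var_animal * A (Cholesky of
    A, which is positive definite for generator trees); s and e are iid
    normal.
    """
    q, n = design.q, design.n
    try:
        L = np.linalg.cholesky(design.A)
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError("phylogenetic covariance is not positive definite") from exc
    u = math.sqrt(var_animal) * (L @ rng.standard_normal(q))
    s = math.sqrt(var_species) * rng.standard_normal(q)
    e = math.sqrt(var_residual) * rng.standard_normal(n)
    y = design.X @ beta + u[design.species_idx] + s[design.species_idx] + e
    return y, u, s, e


def _back_compute_morphology(
    species: str, cov: dict[str, float], source: str
) -> MorphologyRecord:
    """Morphology record consistent with the drawn covariates.

    Absolute chela/telson sizes are set from plausible proportions of
    total length (widths at 1/10 and 1/20); only the ratios enter the
    analysis, so the widths are bookkeeping, not biology.
    """
    total = cov["total_length_mm"]
    chela_w = total / 10.0
    telson_w = total / 20.0
    return MorphologyRecord(
        species_name=species,
        total_length_mm=total,
        chela_length_mm=cov["chela_ratio"] * chela_w,
        chela_width_mm=chela_w,
        telson_length_mm=cov["telson_ratio"] * telson_w,
        telson_width_mm=telson_w,
        source_id=source,
    )


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Compose tree, covariates and response into a full dataset.

    The returned table is built by the same curation path that file-based
    inputs take (:func:`build_analysis_table` on the generated potency and
    morphology records), so a disk round-trip reproduces it exactly.
    """
    import pandas as pd

    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config.n_species, config.birth_rate, seed=config.seed)
    tips = tree.tip_labels
    covariates, species_idx, routes = simulate_covariates(config, tips, rng)

    rows = [
        {
            "species": tips[sp],
            "log10_ld50": 0.0,  # placeholder; the response is simulated below
            "log10_body_length": math.log10(covariates[tips[sp]]["total_length_mm"]),
            "chela_ratio": covariates[tips[sp]]["chela_ratio"],
            "telson_ratio": covariates[tips[sp]]["telson_ratio"],
            "route": routes[i],
        }
        for i, sp in enumerate(species_idx)
    ]
    skeleton = AnalysisTable(data=pd.DataFrame(rows))
    cov = phylo_covariance(tree, skeleton.species_names)
    design0 = build_design(skeleton, cov)
    beta = config.beta_vector(design0.fixed_names)
    y, u, s, e = simulate_response(
        design0, beta, config.var_animal, config.var_species, config.var_residual, rng
    )

    potency = [
        PotencyRecord(
            species_name=tips[sp],
            ld50_value=float(10.0 ** y[i]),
            ld50_units="mg/kg",
            subject_mass_kg=config.subject_mass_kg,
            route=routes[i],
            venom_state="dried",
            test_model="Mus musculus",
            source_id=f"sim-{i:03d}",
        )
        for i, sp in enumerate(species_idx)
    ]
    morphology = [
        _back_compute_morphology(sp, covariates[sp], source="sim") for sp in tips
    ]
    table = build_analysis_table(potency, morphology)
    design = build_design(table, cov)
    truth = {
        "seed": config.seed,
        "beta": {name: float(b) for name, b in zip(design0.fixed_names, beta)},
        "lp": (design0.X @ beta).tolist(),
        "var_animal": config.var_animal,
        "var_species": config.var_species,
        "var_residual": config.var_residual,
        "h2": config.true_h2,
        "species_order": tips,
        "u": u.tolist(),
        "s": s.tolist(),
        "e": e.tolist(),
        "y": y.tolist(),
    }
    return SyntheticDataset(
        table=table,
        tree=tree,
        covariance=cov,
        design=design,
        potency=potency,
        morphology=morphology,
        truth=truth,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Emit the dataset in the pipeline's on-disk input formats.

    Writes potency.csv and morphology.csv (curation inputs), tree.nwk,
    and truth.json; floats are written at full round-trip precision so
    re-ingestion reproduces the in-memory table bit for bit.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "potency": outdir / "potency.csv",
        "morphology": outdir / "morphology.csv",
        "tree": outdir / "tree.nwk",
        "truth": outdir / "truth.json",
    }
    ingest.write_potency_csv(ds.potency, paths["potency"])
    ingest.write_morphology_csv(ds.morphology, paths["morphology"])
    from .phylo import write_newick

    write_newick(ds.tree, paths["tree"])
    paths["truth"].write_text(json.dumps(ds.truth, indent=2) + "\n", encoding="utf-8")
    return paths
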