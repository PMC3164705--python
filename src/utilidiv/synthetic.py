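"""Synthetic survey generator with planted, recoverable structure.

Emulates the four input tables of a village-transect tree survey — trait
table, plot memberships, plot covariates, stem records — so that every
pipeline stage has a known ground truth:

* plots are assembled from the pool at fixed richness either uniformly
  (``random``: IV centers on 0), by trait-similarity attraction
  (``clustered``: low FD, negative IV) or by greedy max–min trait
  dispersion (``dispersed``: high FD, positive IV);
* covariates are drawn from field-plausible ranges, with distances laid
  out on the 0–3200 m transect bands, seven plots per site;
* a linear covariate effect on redundancy can be planted through
  :func:`planted_iv` (known slopes for the GLM stage);
* stem DBH is lognormal with a planted property/threshold effect (the
  regression-tree stage's truth).

The defaults mirror the survey design the pipeline targets: 8 sites x 7
plots = 56 plots, six utilitarian properties with three preference ranks
plus non-use. Marginal property frequencies are not calibrated to any real
flora — they are synthetic by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from math import log

import numpy as np
import pandas as pd

from .data import (
    BINARY_PROPERTIES,
    COVARIATE_COLUMNS,
    ORDINAL_PROPERTIES,
    CommunityMatrix,
    TraitTable,
)
from .errors import ConfigError, SchemaError
from .regression_tree import DISTANCE_BANDS
from .trait_space import DistanceMatrix, gower_distance

ASSEMBLY_MODES = ("random", "clustered", "dispersed")


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; the master seed fully determines the output."""

    n_species: int = 80
    n_sites: int = 8
    plots_per_site: int = 7
    richness_range: tuple[int, int] = (8, 30)
    assembly: str = "random"                     # mode applied to every plot
    tau: float = 0.08                            # clustered-mode attraction scale (Gower units)
    dispersal_noise: float = 0.05                # P(random pick) per step in dispersed mode
    ordinal_probs: tuple[float, ...] = (0.4, 0.2, 0.2, 0.2)  # levels 0..3
    binary_prob: float = 0.3
    # planted linear covariate effect on redundancy (for planted_iv)
    iv_intercept: float = 0.12
    beta: dict[str, float] = field(default_factory=lambda: {"basal_area": -6e-4})
    iv_noise_sd: float = 0.05
    # planted DBH rule: log-mean shift for stems of species with
    # dbh_property >= dbh_threshold
    dbh_property: str = "firewood"
    dbh_threshold: int = 2
    dbh_log_mu0: float = log(30.0)
    dbh_log_effect: float = log(110.0 / 30.0)
    dbh_log_sd: float = 0.35
    stems_lambda: float = 2.0                    # stems per member species = 1 + Poisson
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ConfigError("n_species must be >= 2")
        lo, hi = self.richness_range
        if not 1 <= lo <= hi <= self.n_species:
            raise ConfigError("richness_range must satisfy 1 <= lo <= hi <= n_species")
        if self.assembly not in ASSEMBLY_MODES:
            raise ConfigError(f"assembly must be one of {ASSEMBLY_MODES}")
        if abs(sum(self.ordinal_probs) - 1.0) > 1e-9 or len(self.ordinal_probs) != 4:
            raise ConfigError("ordinal_probs must be 4 probabilities summing to 1")
        if max(self.ordinal_probs) >= 1.0 and self.binary_prob in (0.0, 1.0):
            raise ConfigError("configuration is degenerate: no property can vary")
        if not 0 < self.binary_prob < 1:
            raise ConfigError("binary_prob must be in (0, 1)")
        if self.tau <= 0:
            raise ConfigError("tau must be positive")


@dataclass(frozen=True)
class SyntheticDataset:
    traits: TraitTable
    communities: list[CommunityMatrix]
    covariates: pd.DataFrame
    stems: pd.DataFrame
    truth: dict


def generate_pool(cfg: SyntheticConfig, rng: np.random.Generator) -> TraitTable:
    """Draw the species pool: multinomial preference ranks, Bernoulli uses.

    Redraws (up to 100 times) in the vanishingly rare case that every
    property comes out constant, so the Gower matrix is never degenerate.
    """
    width = len(str(cfg.n_species))
    ids = [f"sp{i + 1:0{width}d}" for i in range(cfg.n_species)]
    for _ in range(100):
        cols = {}
        for prop in ORDINAL_PROPERTIES:
            cols[prop] = rng.choice(4, size=cfg.n_species, p=cfg.ordinal_probs)
        for prop in BINARY_PROPERTIES:
            cols[prop] = (rng.random(cfg.n_species) < cfg.binary_prob).astype(int)
        frame = pd.DataFrame(cols, index=pd.Index(ids, name="species_id"))
        if any(frame[c].nunique() > 1 for c in frame.columns):
            return TraitTable(frame)
    raise ConfigError("could not draw a non-degenerate trait table")


def _assemble_one(
    mode: str,
    richness: int,
    dist: np.ndarray,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Indices of one plot's members under the given assembly mode."""
    n = dist.shape[0]
    if richness > n:
        raise SchemaError(f"richness {richness} exceeds pool size {n}")
    if mode == "random":
        return rng.choice(n, size=richness, replace=False)

    selected = [int(rng.integers(n))]
    remaining = set(range(n)) - set(selected)
    while len(selected) < richness:
        rest = np.fromiter(remaining, dtype=int)
        if mode == "clustered":
            mean_d = dist[np.ix_(rest, selected)].mean(axis=1)
            w = np.exp(-mean_d / cfg.tau)
            w /= w.sum()
            pick = int(rng.choice(rest, p=w))
        else:  # dispersed: greedy max-min with occasional random pick
            if rng.random() < cfg.dispersal_noise:
                pick = int(rng.choice(rest))
            else:
                min_d = dist[np.ix_(rest, selected)].min(axis=1)
                pick = int(rest[int(np.argmax(min_d))])
        selected.append(pick)
        remaining.discard(pick)
    return np.array(selected)


def assemble_plots(
    traits: TraitTable,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    dist: DistanceMatrix | None = None,
    modes: list[str] | None = None,
) -> tuple[list[CommunityMatrix], dict[str, str]]:
    """Assemble one community per plot; returns communities + true mode labels.

    Plot ids are ``s<site>_d<band>`` following the transect layout (seven
    distance bands per site). ``modes`` overrides the config-wide assembly
    mode per plot.
    """
    if dist is None:
        dist = gower_distance(traits)
    d = dist.values
    species = np.array(traits.species)
    lo, hi = cfg.richness_range
    n_plots = cfg.n_sites * cfg.plots_per_site
    if modes is not None and len(modes) != n_plots:
        raise ConfigError("modes must have one entry per plot")

    communities, labels = [], {}
    k = 0
    for site in range(1, cfg.n_sites + 1):
        for j in range(cfg.plots_per_site):
            band = DISTANCE_BANDS[j % len(DISTANCE_BANDS)]
            plot_id = f"s{site:02d}_d{band}"
            mode = modes[k] if modes is not None else cfg.assembly
            richness = int(rng.integers(lo, hi + 1))
            idx = _assemble_one(mode, richness, d, cfg, rng)
            communities.append(CommunityMatrix(plot_id, frozenset(species[idx])))
            labels[plot_id] = mode
            k += 1
    return communities, labels


def generate_covariates(
    communities: list[CommunityMatrix],
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Field-plausible covariates per plot; distance follows the transect bands.

    Basal area in m2/ha, canopy height in m, elevation in m; felled trees
    and trails are counts that decay with distance from the village (human
    pressure fades into the interior).
    """
    rows = []
    for com in communities:
        band = int(com.plot_id.rsplit("_d", 1)[1])
        pressure = np.exp(-band / 800.0)  # 1 at the edge, ~0 deep inside
        rows.append(
            {
                "plot_id": com.plot_id,
                "basal_area": float(np.round(rng.uniform(10.0, 80.0), 2)),
                "felled_trees": int(rng.poisson(1.0 + 4.0 * pressure)),
                "canopy_height": float(np.round(np.clip(rng.normal(18.0, 4.0), 5.0, None), 1)),
                "distance_village": band,
                "trails": int(rng.poisson(0.5 + 2.0 * pressure)),
                "elevation": float(np.round(rng.uniform(600.0, 1200.0), 0)),
            }
        )
    return pd.DataFrame(rows).set_index("plot_id")[list(COVARIATE_COLUMNS)]


def planted_iv(
    covariates: pd.DataFrame,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> pd.Series:
    """Synthetic IV with a known linear dependence on covariates.

    iv = intercept + sum_j beta_j x_j + N(0, sd); used to hand the GLM stage
    a response whose true slopes are known exactly.
    """
    unknown = set(cfg.beta) - set(covariates.columns)
    if unknown:
        raise ConfigError(f"beta names unknown covariates: {sorted(unknown)}")
    mean = np.full(len(covariates), cfg.iv_intercept)
    for name, slope in cfg.beta.items():
        mean = mean + slope * covariates[name].to_numpy(dtype=float)
    return pd.Series(
        mean + rng.normal(0.0, cfg.iv_noise_sd, size=len(covariates)),
        index=covariates.index,
        name="iv",
    )


def generate_stems(
    communities: list[CommunityMatrix],
    traits: TraitTable,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Stem records with a planted property->DBH rule.

    Per member species, 1 + Poisson(lambda) stems; DBH is lognormal with a
    log-mean shift for species whose planted property meets the threshold,
    truncated at the 10 cm survey floor by resampling. dbh_log_sd = 0 gives
    the noise-free means exp(mu0) and exp(mu0 + effect) exactly.
    """
    if cfg.dbh_property not in traits.properties:
        raise ConfigError(f"dbh_property {cfg.dbh_property!r} not in trait table")
    hit = traits.data[cfg.dbh_property] >= cfg.dbh_threshold
    rows = []
    for com in communities:
        for sp in sorted(com.members):
            count = 1 + int(rng.poisson(cfg.stems_lambda))
            mu = cfg.dbh_log_mu0 + (cfg.dbh_log_effect if hit[sp] else 0.0)
            dbh = np.exp(rng.normal(mu, cfg.dbh_log_sd, size=count))
            # truncate at the survey floor (margin so 2-dp rounding stays > 10)
            while np.any(dbh <= 10.005):
                redo = dbh <= 10.005
                dbh[redo] = np.exp(rng.normal(mu, cfg.dbh_log_sd, size=int(redo.sum())))
            for v in dbh:
                rows.append({"plot_id": com.plot_id, "species_id": sp, "dbh": round(float(v), 2)})
    return pd.DataFrame(rows, columns=["plot_id", "species_id", "dbh"])


def generate_dataset(cfg: SyntheticConfig, modes: list[str] | None = None) -> SyntheticDataset:
    """All four tables plus the planted truth, from the master seed alone."""
    rng = np.random.default_rng(cfg.seed)
    traits = generate_pool(cfg, rng)
    communities, labels = assemble_plots(traits, cfg, rng, modes=modes)
    covariates = generate_covariates(communities, cfg, rng)
    stems = generate_stems(communities, traits, cfg, rng)
    truth = {
        "assembly_labels": labels,
        "beta": dict(cfg.beta),
        "iv_intercept": cfg.iv_intercept,
        "dbh_rule": {
            "property": cfg.dbh_property,
            "threshold": cfg.dbh_threshold,
            "log_effect": cfg.dbh_log_effect,
            "mean_low": float(np.exp(cfg.dbh_log_mu0)),
            "mean_high": float(np.exp(cfg.dbh_log_mu0 + cfg.dbh_log_effect)),
        },
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cfg).items()
        },
    }
    return SyntheticDataset(traits, communities, covariates, stems, truth)
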