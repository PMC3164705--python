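"""Richness-constrained null model, Index of Variance, property importance.

For each plot, null communities are assembled by drawing the plot's species
richness S uniformly without replacement from the full species pool (the
dendrogram's leaves) and recomputing FD; the dendrogram itself stays fixed
across draws. The plot's observed FD is then compared with the null
distribution two-sidedly at a chosen alpha, and redundancy is summarized by
the Index of Variance

    IV = (Obs - Exp) / Exp,

the relative deviation of observed from expected FD: positive IV means the
plot's species are more utilitarianly distinct than random draws of the
same richness (low redundancy), negative IV the opposite. ``iv_form =
"ratio"`` switches to plain Obs/Exp for sensitivity checks.

Property importance removes one property at a time, rebuilds the Gower
matrix and dendrogram from the reduced table, recomputes all plot FDs, and
ranks properties by the drop in mean FD their removal causes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CommunityMatrix, TraitTable
from .diversity import fd, fd_batch, _membership_vector
from .errors import DegenerateDistanceError, DegenerateNullError, SchemaError
from .trait_space import FunctionalDendrogram, cluster, gower_distance

logger = logging.getLogger(__name__)

DEFAULT_N_ITER = 5000
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class NullModelResult:
    plot_id: str
    richness: int
    observed_fd: float
    expected_fd: float
    null_sd: float
    null_q025: float
    null_q975: float
    p_high: float
    p_low: float
    iv: float
    flag: str  # "higher" | "lower" | "ns"
    n_iter: int
    seed: int | None = None


def random_subsets(pool_size: int, richness: int, n_iter: int, rng: np.random.Generator) -> np.ndarray:
    """(n_iter, pool_size) 0/1 matrix of uniform S-subsets without replacement."""
    if not 1 <= richness <= pool_size:
        raise SchemaError(f"richness {richness} outside 1..{pool_size}")
    # rank of iid uniforms = a uniformly random permutation per row
    u = rng.random((n_iter, pool_size))
    keep = np.argpartition(u, richness - 1, axis=1)[:, :richness]
    out = np.zeros((n_iter, pool_size), dtype=np.int64)
    np.put_along_axis(out, keep, 1, axis=1)
    return out


def null_distribution(
    tree: FunctionalDendrogram,
    richness: int,
    n_iter: int = DEFAULT_N_ITER,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Null FD sample: ``n_iter`` uniform S-subsets of the pool, FD of each."""
    if n_iter < 1:
        raise SchemaError("n_iter must be >= 1")
    rng = np.random.default_rng(rng)
    membership = random_subsets(tree.n_leaves, richness, n_iter, rng)
    return fd_batch(tree, membership)


def index_of_variance(obs: float, exp: float, form: str = "relative") -> float:
    """Index of Variance comparing observed with null-expected FD.

    ``relative`` (default) gives (obs-exp)/exp, zero when observed matches
    expectation; ``ratio`` gives obs/exp.
    """
    if exp <= 0:
        raise DegenerateNullError(f"expected FD must be positive, got {exp}")
    if form == "relative":
        return (obs - exp) / exp
    if form == "ratio":
        return obs / exp
    raise SchemaError(f"unknown iv form {form!r}")


def evaluate_plot(
    plot_id: str,
    observed_fd: float,
    richness: int,
    null_sample: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    iv_form: str = "relative",
    seed: int | None = None,
) -> NullModelResult:
    """Two-sided significance assessment of one plot against its null sample.

    A plot is flagged "higher" when its observed FD exceeds the null
    1 - alpha/2 percentile, "lower" below the alpha/2 percentile, else "ns".
    Tail p-values use the add-one permutation convention
    p = (1 + #extreme) / (1 + n_iter).
    """
    null_sample = np.asarray(null_sample, dtype=float)
    if null_sample.size == 0:
        raise SchemaError("empty null sample")
    n_iter = null_sample.size
    exp = float(null_sample.mean())
    q_low, q_high = np.quantile(null_sample, [alpha / 2.0, 1.0 - alpha / 2.0])
    if observed_fd > q_high:
        flag = "higher"
    elif observed_fd < q_low:
        flag = "lower"
    else:
        flag = "ns"
    return NullModelResult(
        plot_id=plot_id,
        richness=richness,
        observed_fd=float(observed_fd),
        expected_fd=exp,
        null_sd=float(null_sample.std(ddof=1)) if n_iter > 1 else 0.0,
        null_q025=float(q_low),
        null_q975=float(q_high),
        p_high=(1.0 + int((null_sample >= observed_fd).sum())) / (1.0 + n_iter),
        p_low=(1.0 + int((null_sample <= observed_fd).sum())) / (1.0 + n_iter),
        iv=index_of_variance(observed_fd, exp, form=iv_form),
        flag=flag,
        n_iter=n_iter,
        seed=seed,
    )


def run_null_model(
    tree: FunctionalDendrogram,
    communities: list[CommunityMatrix],
    n_iter: int = DEFAULT_N_ITER,
    alpha: float = DEFAULT_ALPHA,
    iv_form: str = "relative",
    rng: np.random.Generator | None = None,
) -> list[NullModelResult]:
    """Observed vs expected FD for every plot against richness-matched nulls.

    Every plot gets its own independent null sample (even when two plots
    share a richness), so significance flags are independent across plots.
    """
    rng = np.random.default_rng(rng)
    results = []
    for com in communities:
        null_sample = null_distribution(tree, com.richness, n_iter=n_iter, rng=rng)
        observed = fd(tree, com.members, plot_id=com.plot_id)
        results.append(
            evaluate_plot(
                com.plot_id, observed.fd, com.richness, null_sample,
                alpha=alpha, iv_form=iv_form,
            )
        )
    return results


def null_results_frame(results: list[NullModelResult]) -> pd.DataFrame:
    cols = [
        "plot_id", "richness", "observed_fd", "expected_fd", "null_sd",
        "null_q025", "null_q975", "p_high", "p_low", "iv", "flag",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results], columns=cols)


def observed_fd_per_plot(
    tree: FunctionalDendrogram, communities: list[CommunityMatrix]
) -> np.ndarray:
    membership = np.stack([_membership_vector(tree, c.members) for c in communities])
    return fd_batch(tree, membership)


def property_importance(
    traits: TraitTable,
    communities: list[CommunityMatrix],
    linkage_method: str = "UPGMA",
) -> pd.DataFrame:
    """Rank properties by how much their removal lowers mean observed FD.

    For each property the Gower matrix and dendrogram are rebuilt from the
    reduced trait table (Gower renormalizes over the remaining properties,
    so pruning the full tree would be wrong), plot FDs are recomputed, and
    the drop fd_all - fd_without is averaged across plots. Rank 1 = largest
    drop = most important property. A removal that leaves an all-constant
    table is reported with NaN values.
    """
    if len(traits.properties) < 2:
        raise SchemaError("need at least 2 properties for a removal analysis")
    full_tree = cluster(gower_distance(traits), linkage_method)
    fd_all = float(observed_fd_per_plot(full_tree, communities).mean())

    rows = []
    for prop in traits.properties:
        try:
            reduced = traits.drop_property(prop)
            tree_p = cluster(gower_distance(reduced), linkage_method)
            fd_without = float(observed_fd_per_plot(tree_p, communities).mean())
        except DegenerateDistanceError as exc:
            logger.warning("property %s removal degenerate: %s", prop, exc)
            fd_without = np.nan
        rows.append({"property": prop, "fd_all": fd_all, "fd_without": fd_without})

    table = pd.DataFrame(rows)
    table["drop"] = table["fd_all"] - table["fd_without"]
    table["rank"] = table["drop"].rank(ascending=False, method="first", na_option="bottom").astype(int)
    return table.sort_values("rank").reset_index(drop=True)
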