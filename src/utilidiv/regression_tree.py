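"""CART regression trees linking utilitarian properties to stem size.

Trees predict stem DBH from the six utilitarian properties: binary splits
chosen greedily to maximize the reduction in within-node sum of squares,
one tree per village-distance band pooled across sites. The full tree is
pruned by cost-complexity pruning with the complexity chosen by K-fold
cross-validation (1-SE rule by default; ``se_rule=0`` for plain minimum).
Model fit is summarized by the Pearson correlation of leaf-mean predictions
with observed DBH; a pruned-to-root model predicts a constant, and its
correlation is reported as 0 with a flag.

Splitting, pruning paths and prediction are delegated to
sklearn.tree.DecisionTreeRegressor (squared-error criterion); this module
adds the CV size selection, the domain-facing node representation (ordinal
splits rendered as "property >= level", binary as "property = 1") and the
per-distance-band orchestration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

from .data import ORDINAL_PROPERTIES, PROPERTIES, TraitTable
from .errors import InsufficientDataError, SchemaError

logger = logging.getLogger(__name__)

DEFAULT_MIN_LEAF = 5
DEFAULT_CV_FOLDS = 10

#: Edge-to-interior plot distances of the transect design, in meters.
DISTANCE_BANDS = (0, 100, 200, 400, 800, 1600, 3200)


@dataclass(frozen=True)
class TreeNode:
    """One node of a fitted tree: a split or (if children are None) a leaf."""

    mean_dbh: float
    count: int
    split_property: str | None = None
    split_threshold: float | None = None     # go right when x >= threshold
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def rule(self) -> str | None:
        """Human-readable right-branch criterion, Fig-style."""
        if self.is_leaf:
            return None
        if self.split_property in ORDINAL_PROPERTIES:
            return f"{self.split_property} >= {int(np.ceil(self.split_threshold))}"
        return f"{self.split_property} = 1"


@dataclass(frozen=True)
class RegressionTreeModel:
    root: TreeNode
    feature_names: tuple[str, ...]
    n_leaves: int
    cv_alphas: np.ndarray = field(repr=False)
    cv_errors: np.ndarray = field(repr=False)
    chosen_alpha: float = 0.0
    pearson_r: float = 0.0
    single_leaf: bool = False
    _estimator: DecisionTreeRegressor | None = field(default=None, repr=False, compare=False)

    def predict(self, x: pd.DataFrame) -> np.ndarray:
        return self._estimator.predict(x[list(self.feature_names)].to_numpy(dtype=float))

    def to_dict(self) -> dict:
        def node_dict(node: TreeNode) -> dict:
            d = {"mean_dbh": round(node.mean_dbh, 6), "count": node.count}
            if not node.is_leaf:
                d.update(
                    rule=node.rule,
                    split_property=node.split_property,
                    split_threshold=node.split_threshold,
                    left=node_dict(node.left),
                    right=node_dict(node.right),
                )
            return d

        return {
            "n_leaves": self.n_leaves,
            "pearson_r": round(float(self.pearson_r), 6),
            "single_leaf": self.single_leaf,
            "chosen_alpha": float(self.chosen_alpha),
            "root": node_dict(self.root),
        }

    def render_text(self) -> str:
        lines: list[str] = []

        def walk(node: TreeNode, indent: str) -> None:
            if node.is_leaf:
                lines.append(f"{indent}leaf: mean DBH {node.mean_dbh:.1f} cm (n={node.count})")
            else:
                lines.append(f"{indent}split: {node.rule}")
                walk(node.left, indent + "  ")
                walk(node.right, indent + "  ")

        walk(self.root, "")
        return "\n".join(lines)


def _extract_nodes(est: DecisionTreeRegressor, feature_names: tuple[str, ...]) -> TreeNode:
    t = est.tree_

    def build(i: int) -> TreeNode:
        if t.children_left[i] == -1:
            return TreeNode(mean_dbh=float(t.value[i][0][0]), count=int(t.n_node_samples[i]))
        return TreeNode(
            mean_dbh=float(t.value[i][0][0]),
            count=int(t.n_node_samples[i]),
            split_property=feature_names[t.feature[i]],
            split_threshold=float(t.threshold[i]),
            # sklearn sends x <= threshold left; we keep that orientation,
            # so "right" is the x >= ceil(threshold) / x = 1 branch
            left=build(t.children_left[i]),
            right=build(t.children_right[i]),
        )

    return build(0)


def _join_features(stems: pd.DataFrame, traits: TraitTable) -> tuple[pd.DataFrame, np.ndarray]:
    unknown = sorted(set(stems["species_id"]) - set(traits.species))
    if unknown:
        raise SchemaError(f"stems reference species absent from traits: {unknown}")
    x = traits.data.loc[stems["species_id"]].reset_index(drop=True)
    y = stems["dbh"].to_numpy(dtype=float)
    return x, y


def grow_tree(
    x: pd.DataFrame,
    y: np.ndarray,
    min_leaf: int = DEFAULT_MIN_LEAF,
) -> DecisionTreeRegressor:
    """Grow the full SSE-splitting tree (no pruning).

    A constant response yields a single-leaf tree; growth otherwise stops
    when no split leaves ``min_leaf`` stems per child or reduces SSE.
    """
    if len(y) < 2 * min_leaf:
        raise InsufficientDataError(
            f"{len(y)} stems < 2 * min_leaf ({min_leaf}) — cannot split"
        )
    est = DecisionTreeRegressor(
        criterion="squared_error", min_samples_leaf=min_leaf, random_state=0
    )
    est.fit(x.to_numpy(dtype=float), y)
    return est


def prune_by_cv(
    x: pd.DataFrame,
    y: np.ndarray,
    min_leaf: int = DEFAULT_MIN_LEAF,
    cv_folds: int = DEFAULT_CV_FOLDS,
    rng: np.random.Generator | None = None,
    se_rule: float = 1.0,
) -> RegressionTreeModel:
    """Grow, then select tree size by K-fold cross-validated cost-complexity.

    Candidate complexities come from the full tree's pruning path; for each,
    the mean squared prediction error across K folds is computed. The chosen
    complexity is the largest alpha (smallest tree) whose CV error is within
    ``se_rule`` standard errors of the minimum — the conventional 1-SE rule,
    which controls overfitting on noisy responses; ``se_rule=0`` gives the
    plain minimum-CV-error rule (ties still go to the smaller tree). The
    final model is refit on all data at the chosen complexity.
    """
    if cv_folds < 2:
        raise SchemaError("cv_folds must be >= 2")
    if len(y) < cv_folds:
        raise InsufficientDataError(f"{len(y)} stems < {cv_folds} folds")
    if se_rule < 0:
        raise SchemaError("se_rule must be >= 0")
    rng = np.random.default_rng(rng)
    feature_names = tuple(x.columns)
    xa = x.to_numpy(dtype=float)

    full = grow_tree(x, y, min_leaf=min_leaf)
    path = full.cost_complexity_pruning_path(xa, y)
    alphas = np.unique(path.ccp_alphas)

    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=int(rng.integers(2**31)))
    folds = list(kf.split(xa))
    fold_mse = np.zeros((len(folds), len(alphas)))
    for fi, (train, test) in enumerate(folds):
        if len(test) == 0 or len(train) < 2 * min_leaf:
            raise InsufficientDataError("degenerate CV fold")
        for ai, alpha in enumerate(alphas):
            est = DecisionTreeRegressor(
                criterion="squared_error",
                min_samples_leaf=min_leaf,
                ccp_alpha=alpha,
                random_state=0,
            )
            est.fit(xa[train], y[train])
            pred = est.predict(xa[test])
            fold_mse[fi, ai] = float(((pred - y[test]) ** 2).mean())
    cv_err = fold_mse.mean(axis=0)
    cv_se = fold_mse.std(axis=0, ddof=1) / np.sqrt(len(folds))

    best_i = int(np.argmin(cv_err))
    budget = cv_err[best_i] + se_rule * cv_se[best_i]
    chosen_alpha = float(alphas[np.flatnonzero(cv_err <= budget + 1e-12).max()])

    est = DecisionTreeRegressor(
        criterion="squared_error",
        min_samples_leaf=min_leaf,
        ccp_alpha=chosen_alpha,
        random_state=0,
    )
    est.fit(xa, y)
    pred = est.predict(xa)
    if np.all(pred == pred[0]):
        r, single = 0.0, True
    else:
        r, single = float(stats.pearsonr(pred, y).statistic), False
    return RegressionTreeModel(
        root=_extract_nodes(est, feature_names),
        feature_names=feature_names,
        n_leaves=int(est.get_n_leaves()),
        cv_alphas=alphas,
        cv_errors=cv_err,
        chosen_alpha=chosen_alpha,
        pearson_r=r,
        single_leaf=single,
        _estimator=est,
    )


def evaluate_tree(model: RegressionTreeModel, x: pd.DataFrame, y: np.ndarray) -> tuple[float, bool]:
    """Pearson r between leaf-mean predictions and observed DBH.

    Returns (r, single_leaf_flag); a constant prediction vector has no
    defined correlation and is reported as r = 0 with the flag set.
    """
    pred = model.predict(x)
    if np.all(pred == pred[0]):
        return 0.0, True
    return float(stats.pearsonr(pred, np.asarray(y, dtype=float)).statistic), False


def trees_by_distance(
    stems: pd.DataFrame,
    traits: TraitTable,
    plot_bands: pd.Series,
    min_leaf: int = DEFAULT_MIN_LEAF,
    cv_folds: int = DEFAULT_CV_FOLDS,
    rng: np.random.Generator | None = None,
    per_species_mean: bool = False,
    se_rule: float = 1.0,
) -> dict[int, RegressionTreeModel]:
    """One pruned tree per village-distance band, pooling plots across sites.

    ``plot_bands`` maps plot_id -> band (meters from the forest edge).
    Bands with too few stems to cross-validate are skipped with a warning.
    With ``per_species_mean`` the response is each species' mean DBH within
    the band rather than individual stems.
    """
    rng = np.random.default_rng(rng)
    unknown = sorted(set(stems["plot_id"]) - set(plot_bands.index))
    if unknown:
        raise SchemaError(f"stems reference plots without a distance band: {unknown}")
    band_of_stem = plot_bands.loc[stems["plot_id"]].to_numpy()

    models: dict[int, RegressionTreeModel] = {}
    for band in sorted(pd.unique(band_of_stem)):
        sub = stems[band_of_stem == band]
        if per_species_mean:
            sub = (
                sub.groupby("species_id", as_index=False)["dbh"].mean()
                .assign(plot_id="pooled")
            )
        x, y = _join_features(sub, traits)
        x = x[list(PROPERTIES)] if set(PROPERTIES) <= set(x.columns) else x
        try:
            models[int(band)] = prune_by_cv(
                x, y, min_leaf=min_leaf, cv_folds=cv_folds, rng=rng, se_rule=se_rule
            )
        except InsufficientDataError as exc:
            logger.warning("distance band %s skipped: %s", band, exc)
    return models
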