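"""End-to-end orchestration: data -> trait space -> FD -> null model -> GLM -> CART.

:func:`run_pipeline` executes the whole analysis from either CSV inputs or
a synthetic-data configuration, writes every stage's table to the output
directory, and stamps a metadata JSON with the seed, iteration counts, and
the conventions (edge-length rule, IV form, winning linkage) that the
numbers depend on. A fixed seed yields byte-identical output bundles.

Stage isolation: each stage consumes only the serialized-able products of
the previous one, and ``run_status.json`` records the stage reached, so a
failed run is identifiable and partial outputs are marked incomplete.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import data as dio
from .diversity import fd
from .drivers import all_subsets_selection, ModelSelectionTable
from .null_model import (
    DEFAULT_ALPHA,
    DEFAULT_N_ITER,
    NullModelResult,
    null_results_frame,
    property_importance,
    run_null_model,
)
from .regression_tree import (
    DEFAULT_CV_FOLDS,
    DEFAULT_MIN_LEAF,
    RegressionTreeModel,
    trees_by_distance,
)
from .synthetic import SyntheticConfig, SyntheticDataset, generate_dataset
from .trait_space import (
    DEFAULT_LINKAGE_CANDIDATES,
    EDGE_LENGTH_CONVENTION,
    FunctionalDendrogram,
    gower_distance,
    select_linkage,
    to_newick,
)
from .errors import UtilidivError

logger = logging.getLogger(__name__)


class PipelineStageError(UtilidivError):
    """A stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one run."""

    traits_path: str | None = None
    communities_path: str | None = None
    communities_wide: bool = False
    covariates_path: str | None = None
    stems_path: str | None = None
    synthetic: SyntheticConfig | None = None
    n_iter: int = DEFAULT_N_ITER
    alpha: float = DEFAULT_ALPHA
    linkage_candidates: tuple[str, ...] = DEFAULT_LINKAGE_CANDIDATES
    iv_form: str = "relative"
    cv_folds: int = DEFAULT_CV_FOLDS
    min_leaf: int = DEFAULT_MIN_LEAF
    seed: int = 0
    outdir: str = "results"


@dataclass
class PipelineResult:
    config: RunConfig
    tree: FunctionalDendrogram
    cophenetic_report: pd.DataFrame
    fd_values: pd.DataFrame
    null_results: list[NullModelResult]
    importance: pd.DataFrame
    selection: ModelSelectionTable | None = None
    trees: dict[int, RegressionTreeModel] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _load_inputs(config: RunConfig, outdir: Path):
    if config.synthetic is not None:
        cfg = dataclasses.replace(config.synthetic, seed=config.seed)
        ds: SyntheticDataset = generate_dataset(cfg)
        dio.write_trait_table(ds.traits, outdir / "traits.csv")
        dio.write_community_matrix(ds.communities, outdir / "communities.csv")
        dio.write_covariates(ds.covariates, outdir / "covariates.csv")
        dio.write_stems(ds.stems, outdir / "stems.csv")
        _json_dump(ds.truth, outdir / "truth.json")
        return ds.traits, ds.communities, ds.covariates, ds.stems
    if config.traits_path is None or config.communities_path is None:
        raise PipelineStageError(
            "stage load_inputs: need traits and communities paths (or a synthetic config)"
        )
    traits = dio.read_trait_table(config.traits_path)
    communities = dio.read_community_matrix(
        config.communities_path, traits, wide=config.communities_wide
    )
    covariates = (
        dio.read_covariates(config.covariates_path) if config.covariates_path else None
    )
    stems = dio.read_stems(config.stems_path) if config.stems_path else None
    return traits, communities, covariates, stems


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage and serialize all outputs under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    status = {"status": "incomplete", "stage": "load_inputs"}
    _json_dump(status, outdir / "run_status.json")
    seeds = np.random.SeedSequence(config.seed).spawn(2)

    stage = "load_inputs"
    try:
        traits, communities, covariates, stems = _load_inputs(config, outdir)
        logger.info(
            "loaded %d species, %d plots, %s stems",
            traits.n_species,
            len(communities),
            "no" if stems is None else len(stems),
        )

        stage = "trait_space"
        dist = gower_distance(traits)
        tree, report = select_linkage(dist, config.linkage_candidates)
        report.to_csv(outdir / "cophenetic_report.csv", index=False)
        (outdir / "dendrogram.nwk").write_text(to_newick(tree) + "\n")

        stage = "diversity"
        fd_rows = [fd(tree, c.members, plot_id=c.plot_id) for c in communities]
        fd_values = pd.DataFrame(
            [{"plot_id": v.plot_id, "richness": v.richness, "fd": v.fd} for v in fd_rows]
        )
        fd_values.to_csv(outdir / "fd_values.csv", index=False)

        stage = "null_model"
        rng = np.random.default_rng(seeds[0])
        null_results = run_null_model(
            tree,
            communities,
            n_iter=config.n_iter,
            alpha=config.alpha,
            iv_form=config.iv_form,
            rng=rng,
        )
        null_frame = null_results_frame(null_results)
        null_frame.to_csv(outdir / "null_results.csv", index=False)
        importance = property_importance(
            traits, communities, linkage_method=tree.linkage_method
        )
        importance.to_csv(outdir / "importance.csv", index=False)

        stage = "drivers_glm"
        selection = None
        if covariates is not None:
            iv_series = null_frame.set_index("plot_id")["iv"]
            selection = all_subsets_selection(covariates, iv_series)
            selection.table.to_csv(outdir / "model_selection.csv", index=False)
            full = selection.fits[
                max(range(len(selection.fits)), key=lambda i: len(selection.fits[i].predictors))
            ]
            _json_dump(
                {"coefficients": full.coefficients, "bse": full.bse, "r2": full.r2},
                outdir / "coefficients.json",
            )
        else:
            logger.warning("no covariates: skipping GLM stage")

        stage = "regression_tree"
        trees: dict[int, RegressionTreeModel] = {}
        if stems is not None and covariates is not None:
            bands = covariates["distance_village"].astype(int)
            trees = trees_by_distance(
                stems,
                traits,
                bands,
                min_leaf=config.min_leaf,
                cv_folds=config.cv_folds,
                rng=np.random.default_rng(seeds[1]),
            )
            _json_dump({str(b): m.to_dict() for b, m in trees.items()}, outdir / "trees.json")
            (outdir / "trees.txt").write_text(
                "\n\n".join(
                    f"distance band {b} m\n{m.render_text()}" for b, m in sorted(trees.items())
                )
                + "\n"
            )
        else:
            logger.warning("no stems and/or covariates: skipping regression-tree stage")

        stage = "metadata"
        metadata = {
            "seed": config.seed,
            "n_iter": config.n_iter,
            "alpha": config.alpha,
            "iv_form": config.iv_form,
            "edge_length_convention": EDGE_LENGTH_CONVENTION,
            "mrca_root_edge_counted": False,
            "linkage_winner": tree.linkage_method,
            "cophenetic_r": tree.cophenetic_r,
            "linkage_candidates": list(config.linkage_candidates),
            "n_species": traits.n_species,
            "n_plots": len(communities),
            "n_stems": None if stems is None else int(len(stems)),
            "cv_folds": config.cv_folds,
            "min_leaf": config.min_leaf,
        }
        _json_dump(metadata, outdir / "metadata.json")
        _json_dump({"status": "completed", "stage": "done"}, outdir / "run_status.json")
    except UtilidivError:
        _json_dump({"status": "failed", "stage": stage}, outdir / "run_status.json")
        raise
    except Exception as exc:
        _json_dump({"status": "failed", "stage": stage}, outdir / "run_status.json")
        raise PipelineStageError(f"stage {stage} failed: {exc}") from exc

    return PipelineResult(
        config=config,
        tree=tree,
        cophenetic_report=report,
        fd_values=fd_values,
        null_results=null_results,
        importance=importance,
        selection=selection,
        trees=trees,
        metadata=metadata,
    )


def summarize(result: PipelineResult) -> str:
    """Plain-text digest: significance counts, property ranking, supported models."""
    frame = null_results_frame(result.null_results)
    counts = frame["flag"].value_counts()
    lines = [
        f"plots: {len(frame)}",
        f"flagged higher (low redundancy): {int(counts.get('higher', 0))}",
        f"flagged lower (high redundancy): {int(counts.get('lower', 0))}",
        f"not significant: {int(counts.get('ns', 0))}",
        f"mean IV: {frame['iv'].mean():.4f}",
        "",
        "property importance (rank: drop in mean FD on removal):",
    ]
    for _, row in result.importance.iterrows():
        lines.append(
            f"  {int(row['rank'])}. {row['property']}: "
            f"FD_all={row['fd_all']:.3f} FD_without={row['fd_without']:.3f} "
            f"drop={row['drop']:.3f}"
        )
    if result.selection is not None:
        lines.append("")
        lines.append("supported GLMs (delta AIC < 2):")
        for _, row in result.selection.supported().iterrows():
            lines.append(
                f"  {row['model']}: AIC={row['aic']:.1f} dAIC={row['delta_aic']:.2f} "
                f"weight={row['akaike_weight']:.3f} R2={row['r2']:.3f}"
            )
    if result.trees:
        lines.append("")
        lines.append("regression-tree root splits by distance band:")
        for band, model in sorted(result.trees.items()):
            rule = model.root.rule or "no split (single leaf)"
            lines.append(f"  {band} m: {rule} (r={model.pearson_r:.2f})")
    return "\n".join(lines)
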