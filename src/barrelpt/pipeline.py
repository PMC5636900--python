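"""End-to-end orchestration: simulate -> features -> metrics -> similarity ->
classify -> report.

The central product is a per-cell feature table combining structure (soma
depth, laminar dendritic complexity reduced to a scalar), ongoing function
(spike rate) and — optionally — evoked function (the two PSTH similarity
indices), plus leave-one-out classification of subcortical targets in
configurable feature spaces.
"""

from __future__ import annotations

import dataclasses
import json
import platform
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classifier import DEFAULT_MERGE_MAP, evaluate_cohort, loo_confidences
from .cohort import (
    CohortConfig,
    SyntheticCell,
    default_config,
    generate_cohort,
)
from .ephys import activity_metrics, compute_psth
from .morphology import LayerScheme, default_layers, feature_vector, laminar_profile, pca_features
from .similarity import TARGET_LABELS, build_templates, normalize_evoked, similarity_indices

__all__ = [
    "RunConfig",
    "run",
    "cell_table",
    "dendrite_scalar",
    "classification_surrogate",
    "group_summary",
    "STRUCTURE_FEATURES",
    "STRUCTURE_SI_FEATURES",
]

#: the combined stimulus-independent feature space (3 parameters)
STRUCTURE_FEATURES = ("soma_depth", "ongoing_rate", "dendrite_scalar")
#: the same space augmented with the evoked-response similarity indices
STRUCTURE_SI_FEATURES = STRUCTURE_FEATURES + ("SI1", "SI2")


def dendrite_scalar(complexity: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Reduce the per-layer complexity 5-vector to one scalar per cell.

    The scalar is the first principal component score of the cohort's
    z-scored (length x branch points) profiles over L1..L5B; it captures the
    dominant axis of laminar-complexity variation across the cohort.
    """
    scores, _, _ = pca_features(np.asarray(complexity, dtype=float), n_components=1)
    return scores[:, 0]


def cell_table(
    cells: Sequence[SyntheticCell],
    layers: LayerScheme | None = None,
    with_similarity: bool = True,
    loo_templates: bool = False,
) -> pd.DataFrame:
    """Per-cell feature/metric table for a cohort.

    Columns: identity and labels, measured spiking metrics, per-layer
    dendritic complexity plus its cohort-level scalar reduction, and (with
    spike trains present) the two PSTH similarity indices. ``loo_templates``
    excludes each cell from its own group template (bias check).
    """
    layers = layers or default_layers()
    rows = []
    psths, ongoing, labels = [], [], []
    for cell in cells:
        row: dict[str, object] = {
            "cell_id": cell.cell_id,
            "label": cell.primary_target,
            "second_label": cell.true_targets[1] if cell.is_dual else "",
            "is_dual": cell.is_dual,
            "soma_depth": cell.soma_depth,
        }
        if cell.trains is not None:
            m = activity_metrics(cell.trains)
            row.update(
                ongoing_rate=m.ongoing_rate,
                burst100_pct=m.burst100_pct,
                burst200_pct=m.burst200_pct,
                onset_rate=m.onset_rate,
                onset_prob=m.onset_prob,
                sustained_rate=m.sustained_rate,
            )
            psths.append(compute_psth(cell.trains))
            ongoing.append(m.ongoing_rate)
            labels.append(cell.primary_target)
        if cell.morphology is not None:
            prof = laminar_profile(cell.morphology, layers)
            fv = feature_vector(cell.morphology, layers)
            row["total_length"] = fv["total_length"]
            row["total_branch_points"] = fv["total_branch_points"]
            for i, name in enumerate(("L1", "L2/3", "L4", "L5A", "L5B")):
                j = layers.index_of(name)
                row[f"complexity_{name}"] = prof.complexity[j]
        rows.append(row)
    table = pd.DataFrame(rows)

    comp_cols = [c for c in table.columns if c.startswith("complexity_")]
    if comp_cols and not table[comp_cols].isna().any().any():
        table["dendrite_scalar"] = dendrite_scalar(table[comp_cols].to_numpy())

    if with_similarity and len(psths) == len(cells) and len(cells) > 0:
        sis = []
        for i in range(len(cells)):
            templates = build_templates(
                psths, ongoing, labels, exclude=i if loo_templates else None
            )
            cell_norm = normalize_evoked(psths[i], ongoing[i])
            sis.append(similarity_indices(cell_norm, templates))
        table["SI1"] = [s.SI1 for s in sis]
        table["SI2"] = [s.SI2 for s in sis]
        for lab in TARGET_LABELS:
            table[f"sim_{lab}"] = [getattr(s, f"sim_{lab}") for s in sis]
    return table


def classification_surrogate(
    seed: int,
    n_per_group: tuple[int, int, int, int] = (5, 5, 5, 4),
    with_si: bool = False,
    n_trials: int = 25,
) -> tuple[float, float]:
    """(mean LOO assignment confidence, accuracy) for one synthetic cohort.

    Draws a cohort with the default calibration at the reconstructed-sample
    group sizes (5/5/5/4 for POm/SC/Pons/Sp5C), computes the combined
    3-feature structure-function space (optionally augmented with SI1/SI2
    from simulated evoked responses), and evaluates leave-one-out
    classification against the POm / Sp5C / merged SC+Pons clusters.
    """
    config = default_config()
    groups = []
    for g, n in zip(config.groups, n_per_group):
        groups.append(dataclasses.replace(g, n_cells=n))
    config = dataclasses.replace(
        config, groups=groups, dual_fraction=0.0, n_trials=n_trials
    )
    cells = generate_cohort(config, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = cell_table(cells, with_similarity=with_si)
        features = STRUCTURE_SI_FEATURES if with_si else STRUCTURE_FEATURES
        X = table[list(features)].to_numpy()
        return loo_confidences(X, table["label"].tolist())


def group_summary(table: pd.DataFrame, config: CohortConfig | None = None) -> pd.DataFrame:
    """Per-group mean +/- SD table mirroring the calibration's layout.

    Includes the calibration's labeled-PT abundances (cells per average
    barrel column and % of L5 NeuN) with their across-group sums when a
    config is given.
    """
    metric_cols = [
        c
        for c in (
            "soma_depth", "ongoing_rate", "burst100_pct", "burst200_pct",
            "onset_rate", "onset_prob", "sustained_rate",
            "total_length", "total_branch_points",
        )
        if c in table.columns
    ]
    out_rows = []
    for lab in TARGET_LABELS:
        sub = table[table["label"] == lab]
        row: dict[str, object] = {"group": lab, "n_cells": len(sub)}
        for c in metric_cols:
            row[f"{c}_mean"] = sub[c].mean() if len(sub) else np.nan
            row[f"{c}_sd"] = sub[c].std(ddof=1) if len(sub) > 1 else np.nan
        out_rows.append(row)
    summary = pd.DataFrame(out_rows)
    if config is not None:
        abundance = {g.target_label: (g.column_cells, g.pct_neun) for g in config.groups}
        summary["cells_per_column"] = [abundance[l][0] for l in summary["group"]]
        summary["pct_neun"] = [abundance[l][1] for l in summary["group"]]
        total = {
            "group": "all",
            "n_cells": int(summary["n_cells"].sum()),
            "cells_per_column": float(summary["cells_per_column"].sum()),
            "pct_neun": float(summary["pct_neun"].sum()),
        }
        summary = pd.concat([summary, pd.DataFrame([total])], ignore_index=True)
    return summary


@dataclass
class RunConfig:
    """Configuration of one end-to-end synthetic (or real-data) run."""

    cohort: CohortConfig = field(default_factory=default_config)
    layers: LayerScheme = field(default_factory=default_layers)
    seed: int = 0
    out_dir: str | Path = "barrelpt_out"
    leave_one_out: bool = True
    with_similarity: bool = True


def run(config: RunConfig) -> dict[str, Path]:
    """Execute the full synthetic pipeline and write the report bundle.

    Emits (CSV/JSON, reproducible byte-for-byte for a fixed seed): the cohort
    manifest, the per-cell feature/metric/similarity table, classification
    results for the evaluated feature spaces, a confusion/confidence summary,
    a per-group summary table, and a log with versions and the seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cells = generate_cohort(config.cohort, seed=config.seed, layers=config.layers)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = cell_table(cells, config.layers, with_similarity=config.with_similarity)

    paths: dict[str, Path] = {}

    manifest = table[["cell_id", "label", "second_label", "is_dual", "soma_depth"]]
    paths["manifest"] = out / "cohort_manifest.csv"
    manifest.to_csv(paths["manifest"], index=False)

    paths["cells"] = out / "cell_table.csv"
    table.to_csv(paths["cells"], index=False)

    spaces: dict[str, tuple[str, ...]] = {
        "soma_depth": ("soma_depth",),
        "ongoing_rate": ("ongoing_rate",),
        "dendrites": ("dendrite_scalar",),
        "combined": STRUCTURE_FEATURES,
    }
    if config.with_similarity:
        spaces["combined+SI"] = STRUCTURE_SI_FEATURES

    clf_frames = []
    summary_json: dict[str, dict] = {}
    for name, feats in spaces.items():
        cols = [f for f in feats if f in table.columns]
        if len(cols) != len(feats):
            warnings.warn(f"space {name!r}: missing features, reduced to {cols}")
        if not cols:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = evaluate_cohort(
                table[cols].to_numpy(),
                table["label"].tolist(),
                is_dual=table["is_dual"].tolist(),
                leave_one_out=config.leave_one_out,
            )
        res.insert(0, "space", name)
        res.insert(1, "cell_id", table["cell_id"].to_numpy())
        clf_frames.append(res)
        merged_labels = sorted(res["true_label"].unique())
        confusion = {
            t: {a: int(((res["true_label"] == t) & (res["assigned"] == a)).sum())
                for a in merged_labels}
            for t in merged_labels
        }
        summary_json[name] = {
            "features": cols,
            "accuracy": float(res["correct"].mean()),
            "mean_confidence": float(res["confidence"].mean()),
            "mean_confidence_correct": float(res.loc[res["correct"], "confidence"].mean()),
            "confusion": confusion,
        }

    paths["classification"] = out / "classification.csv"
    pd.concat(clf_frames, ignore_index=True).to_csv(paths["classification"], index=False)

    paths["confidence"] = out / "classification_summary.json"
    with open(paths["confidence"], "w") as fh:
        json.dump(summary_json, fh, indent=1, sort_keys=True)

    paths["summary"] = out / "group_summary.csv"
    group_summary(table, config.cohort).to_csv(paths["summary"], index=False)

    paths["log"] = out / "run_log.json"
    with open(paths["log"], "w") as fh:
        json.dump(
            {
                "barrelpt_version": __version__,
                "python": platform.python_version(),
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "seed": config.seed,
                "n_cells": len(cells),
                "n_trials": config.cohort.n_trials,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    return paths
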