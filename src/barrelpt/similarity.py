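"""PSTH similarity measure and the two similarity indices (SI1, SI2).

Evoked responses are compared on a normalized scale: the ongoing rate is
subtracted from every 5 ms PSTH bin, negative bins are set to zero, and the
result is divided by its maximal bin. The dissimilarity between two such
normalized PSTHs is the sum of bin-wise absolute differences over the whole
recording window ([-200, 1100] ms) — the smaller the value, the more similar
the responses (0 iff identical).

Each cell's four dissimilarities to the group-average templates (POm, SC,
Pons, Sp5C) are combined into two indices in [-1, 1]:

    SI1 = (sim_Pons - sim_SC)   / (sim_SC  + sim_Pons)
    SI2 = (sim_Sp5C - sim_POm)  / (sim_POm + sim_Sp5C)

so SI1 > 0 means "more similar to SC than to Pons" and SI2 > 0 "more similar
to POm than to Sp5C". A 0/0 ratio is defined as 0 (neutral).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .ephys import PSTH

__all__ = [
    "TARGET_LABELS",
    "NormalizedEvokedPSTH",
    "GroupTemplates",
    "SimilarityIndices",
    "normalize_evoked",
    "similarity",
    "similarity_indices",
    "build_templates",
]

TARGET_LABELS = ("POm", "SC", "Pons", "Sp5C")


@dataclass
class NormalizedEvokedPSTH:
    """Baseline-subtracted, peak-normalized PSTH (values in [0, 1])."""

    edges: np.ndarray
    values: np.ndarray
    source_ongoing_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0) or np.any(self.values > 1 + 1e-12):
            raise ValueError("normalized PSTH values must lie in [0, 1]")


@dataclass
class GroupTemplates:
    """One normalized group-average PSTH per subcortical target."""

    templates: Mapping[str, NormalizedEvokedPSTH]

    def __post_init__(self) -> None:
        missing = [lab for lab in TARGET_LABELS if lab not in self.templates]
        if missing:
            raise ValueError(f"missing template(s) for group(s): {missing}")

    def __getitem__(self, label: str) -> NormalizedEvokedPSTH:
        return self.templates[label]


@dataclass
class SimilarityIndices:
    """Per-target dissimilarity sums and the two combined indices."""

    sim_POm: float
    sim_SC: float
    sim_Pons: float
    sim_Sp5C: float
    SI1: float
    SI2: float


def normalize_evoked(psth: PSTH, ongoing_rate: float) -> NormalizedEvokedPSTH:
    """Subtract the ongoing rate bin-wise, clamp at zero, divide by the peak.

    An all-zero result (e.g., a constant PSTH equal to the ongoing rate)
    stays all-zero.
    """
    v = np.clip(psth.rate - ongoing_rate, 0.0, None)
    peak = v.max() if v.size else 0.0
    if peak > 0:
        v = v / peak
    return NormalizedEvokedPSTH(edges=psth.edges, values=v, source_ongoing_rate=ongoing_rate)


def _check_binning(a: NormalizedEvokedPSTH, b: NormalizedEvokedPSTH) -> None:
    if a.values.shape != b.values.shape or not np.allclose(a.edges, b.edges):
        raise ValueError("PSTHs have different binning/windows")


def similarity(a: NormalizedEvokedPSTH, b: NormalizedEvokedPSTH) -> float:
    """Sum of bin-wise absolute differences (symmetric; 0 iff identical)."""
    _check_binning(a, b)
    return float(np.sum(np.abs(a.values - b.values)))


def _ratio(num: float, den: float) -> float:
    return 0.0 if den == 0 else num / den


def similarity_indices(
    cell: NormalizedEvokedPSTH, templates: GroupTemplates
) -> SimilarityIndices:
    """Dissimilarity of a cell to the four group templates, combined to SI1/SI2."""
    sims = {lab: similarity(cell, templates[lab]) for lab in TARGET_LABELS}
    si1 = _ratio(sims["Pons"] - sims["SC"], sims["SC"] + sims["Pons"])
    si2 = _ratio(sims["Sp5C"] - sims["POm"], sims["POm"] + sims["Sp5C"])
    return SimilarityIndices(
        sim_POm=sims["POm"],
        sim_SC=sims["SC"],
        sim_Pons=sims["Pons"],
        sim_Sp5C=sims["Sp5C"],
        SI1=si1,
        SI2=si2,
    )


def build_templates(
    psths: Sequence[PSTH],
    ongoing_rates: Sequence[float],
    labels: Sequence[str],
    exclude: int | None = None,
) -> GroupTemplates:
    """Average raw PSTHs per target group, then baseline-subtract and normalize.

    The group baseline is the mean ongoing rate of the group's cells. The raw
    group-average PSTH is normalized as a whole (rather than averaging
    normalized per-cell PSTHs). ``exclude`` drops one cell index from its
    group's average — the leave-one-out switch for bias checks.

    Raises if any canonical group ends up empty, naming the group.
    """
    if not (len(psths) == len(ongoing_rates) == len(labels)):
        raise ValueError("psths, ongoing_rates and labels must be index-aligned")
    templates: dict[str, NormalizedEvokedPSTH] = {}
    for lab in TARGET_LABELS:
        idx = [
            i for i, l in enumerate(labels) if l == lab and (exclude is None or i != exclude)
        ]
        if not idx:
            raise ValueError(f"no cells available for group {lab!r}")
        ref = psths[idx[0]]
        mean_rate = np.mean([psths[i].rate for i in idx], axis=0)
        mean_ongoing = float(np.mean([ongoing_rates[i] for i in idx]))
        group_psth = PSTH(
            edges=ref.edges, rate=mean_rate, n_trials=ref.n_trials, bin_width=ref.bin_width
        )
        templates[lab] = normalize_evoked(group_psth, mean_ongoing)
    return GroupTemplates(templates)
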