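"""Synthetic cohorts of pyramidal tract (PT) neurons.

Generates labeled cohorts — soma depths, laminar dendrite morphologies,
per-trial spike trains and retrograde-labeling soma fields — with the
statistical structure the downstream analysis assumes. The default
calibration encodes the published group statistics for the four subcortical
target populations of rat vS1 PTs (POm, SC, Pons, Sp5C): Gaussian soma-depth
distributions, ongoing Poisson spiking with burst doublets, a stereotyped
onset transient in the first 100 ms of a 700 ms whisker air-puff, and
group-specific sustained envelopes (flat at baseline for POm, constant for
SC, decaying for Pons, late-ramping for Sp5C).

Rates in the "Function" calibration are group means with standard errors over
N = 5 cells; per-cell standard deviations are SE * sqrt(5). Soma depths are
population mean +/- SD directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from . import morphology as morpho
from .ephys import DEFAULT_WINDOW, SpikeTrainSet
from .morphology import BASAL, APICAL, SOMA, LayerScheme, NeuronMorphology, default_layers
from .similarity import TARGET_LABELS
from .soma_density import DensityProfile1D

__all__ = [
    "GroupParams",
    "CohortConfig",
    "SpikingParams",
    "SyntheticCell",
    "SomaField",
    "SomaFieldConfig",
    "MorphologyGenerationError",
    "default_config",
    "generate_cohort",
    "generate_spike_trains",
    "generate_morphology",
    "generate_soma_field",
    "realize_cell",
    "reference_neun_profile",
    "SUSTAINED_SHAPES",
    "DENDRITE_LAYERS",
]

DENDRITE_LAYERS = morpho.DENDRITE_LAYERS
SUSTAINED_SHAPES = ("flat_at_baseline", "constant_elevated", "decaying", "late_ramp")


class MorphologyGenerationError(ValueError):
    """Laminar targets unreachable (e.g., requested above the pia)."""


@dataclass
class GroupParams:
    """Generative calibration of one target group.

    Rates in Hz, depths and lengths in um; burst fractions are fractions of
    action potentials; per-layer laminar targets are ordered over
    (L1, L2/3, L4, L5A, L5B).
    """

    target_label: str
    n_cells: int
    depth_mean: float
    depth_sd: float
    ongoing_rate_mean: float
    ongoing_rate_sd: float
    burst100_frac: float
    burst200_frac: float
    onset_rate_mean: float
    onset_rate_sd: float
    onset_prob: float
    sustained_rate_mean: float
    sustained_rate_sd: float
    sustained_shape: str
    laminar_length_targets: tuple[float, ...]  # um per layer
    laminar_bp_targets: tuple[int, ...]        # branch points per layer
    length_rel_sd: float = 0.2                 # per-cell relative SD of lengths
    bp_rel_sd: float = 0.2                     # per-cell relative SD of BP counts
    burst_rel_sd: float = 0.5                  # per-cell relative SD of burst fractions
    column_cells: float = 0.0                  # labeled PTs per average barrel column
    pct_neun: float = 0.0                      # labeled PTs as % of L5 NeuN

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for name in ("ongoing_rate_mean", "onset_rate_mean", "sustained_rate_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.onset_prob <= 1:
            raise ValueError("onset_prob must be in [0, 1]")
        if self.burst200_frac > self.burst100_frac:
            raise ValueError("burst200_frac must be <= burst100_frac")
        if self.sustained_shape not in SUSTAINED_SHAPES:
            raise ValueError(f"unknown sustained shape {self.sustained_shape!r}")
        if len(self.laminar_length_targets) != 5 or len(self.laminar_bp_targets) != 5:
            raise ValueError("laminar targets must cover (L1, L2/3, L4, L5A, L5B)")
        if min(self.laminar_length_targets) < 0 or min(self.laminar_bp_targets) < 0:
            raise ValueError("laminar targets must be nonnegative")


@dataclass
class SpikingParams:
    """Realized per-cell rate parameters driving the spike-train generator."""

    ongoing_rate: float
    onset_rate: float
    onset_prob: float
    sustained_rate: float
    sustained_shape: str
    burst100_frac: float
    burst200_frac: float


@dataclass
class CohortConfig:
    groups: list[GroupParams]
    dual_fraction: float = 0.25
    n_trials: int = 25
    window: tuple[float, float] = DEFAULT_WINDOW
    stimulus_onset: float = 0.0
    stimulus_duration: float = 700.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        lo, hi = self.window
        if not (lo <= self.stimulus_onset and self.stimulus_onset + self.stimulus_duration <= hi):
            raise ValueError("recording window must contain the stimulus")
        if not 0 <= self.dual_fraction <= 1:
            raise ValueError("dual_fraction must be in [0, 1]")


@dataclass
class SyntheticCell:
    cell_id: str
    true_targets: tuple[str, ...]
    soma_depth: float
    morphology: NeuronMorphology | None
    trains: SpikeTrainSet | None
    spiking: SpikingParams
    laminar_length: tuple[float, ...]
    laminar_bp: tuple[int, ...]

    @property
    def primary_target(self) -> str:
        return self.true_targets[0]

    @property
    def is_dual(self) -> bool:
        return len(self.true_targets) > 1


# ---------------------------------------------------------------------------
# Default calibration
# ---------------------------------------------------------------------------

_SQRT5 = math.sqrt(5.0)

#: Per-layer dendritic path-length (um) and branch-point targets over
#: (L1, L2/3, L4, L5A, L5B). Totals match the per-group total length and
#: branch-point counts; the laminar split encodes the reported group
#: contrasts: POm projectors are sparsest in L5A, SC projectors richest in
#: L5A and sparsest in L5B, Pons projectors most complex in L1, and Sp5C
#: projectors least complex in L4.
_LAMINAR_LENGTH = {
    "POm": (1800.0, 2400.0, 1300.0, 1200.0, 6000.0),   # total 12.7 mm
    "SC": (1900.0, 2500.0, 1400.0, 3200.0, 4200.0),    # total 13.2 mm
    "Pons": (3400.0, 3400.0, 1700.0, 2400.0, 5900.0),  # total 16.8 mm
    "Sp5C": (2000.0, 2700.0, 900.0, 2200.0, 6000.0),   # total 13.8 mm
}
_LAMINAR_BP = {
    "POm": (14, 6, 3, 4, 39),    # total 66
    "SC": (15, 7, 4, 18, 33),    # total 77
    "Pons": (30, 10, 5, 12, 41),  # total 98
    "Sp5C": (18, 9, 2, 14, 47),  # total 90
}


def default_config() -> CohortConfig:
    """The published calibration of the four target groups.

    Group sizes (10/6/16/11, summing to 43 — the recorded sample size) are
    proportional to the labeled-PT abundances per average barrel column
    (256/174/421/284). ~25% of cells carry a second target label; 20-30
    stimulation trials per cell (default 25).
    """
    groups = [
        GroupParams(
            target_label="POm", n_cells=10,
            depth_mean=1042.0, depth_sd=105.0,
            ongoing_rate_mean=7.2, ongoing_rate_sd=1.6 * _SQRT5,
            burst100_frac=0.052, burst200_frac=0.021,
            onset_rate_mean=5.1, onset_rate_sd=1.7 * _SQRT5, onset_prob=0.66,
            sustained_rate_mean=0.8, sustained_rate_sd=1.4 * _SQRT5,
            sustained_shape="flat_at_baseline",
            laminar_length_targets=_LAMINAR_LENGTH["POm"],
            laminar_bp_targets=_LAMINAR_BP["POm"],
            length_rel_sd=1.2 / 12.7, bp_rel_sd=3.0 / 66.0,
            column_cells=256.0, pct_neun=7.0,
        ),
        GroupParams(
            target_label="SC", n_cells=6,
            depth_mean=1055.0, depth_sd=97.0,
            ongoing_rate_mean=1.3, ongoing_rate_sd=0.6 * _SQRT5,
            burst100_frac=0.135, burst200_frac=0.062,
            onset_rate_mean=1.7, onset_rate_sd=1.2 * _SQRT5, onset_prob=0.23,
            sustained_rate_mean=2.3, sustained_rate_sd=1.1 * _SQRT5,
            sustained_shape="constant_elevated",
            laminar_length_targets=_LAMINAR_LENGTH["SC"],
            laminar_bp_targets=_LAMINAR_BP["SC"],
            length_rel_sd=3.9 / 13.2, bp_rel_sd=18.0 / 77.0,
            column_cells=174.0, pct_neun=5.0,
        ),
        GroupParams(
            target_label="Pons", n_cells=16,
            depth_mean=1131.0, depth_sd=110.0,
            ongoing_rate_mean=1.8, ongoing_rate_sd=1.1 * _SQRT5,
            burst100_frac=0.052, burst200_frac=0.004,
            onset_rate_mean=4.5, onset_rate_sd=2.9 * _SQRT5, onset_prob=0.38,
            sustained_rate_mean=3.3, sustained_rate_sd=2.1 * _SQRT5,
            sustained_shape="decaying",
            laminar_length_targets=_LAMINAR_LENGTH["Pons"],
            laminar_bp_targets=_LAMINAR_BP["Pons"],
            length_rel_sd=4.7 / 16.8, bp_rel_sd=24.0 / 98.0,
            column_cells=421.0, pct_neun=12.0,
        ),
        GroupParams(
            target_label="Sp5C", n_cells=11,
            depth_mean=1154.0, depth_sd=98.0,
            ongoing_rate_mean=4.3, ongoing_rate_sd=1.0 * _SQRT5,
            burst100_frac=0.046, burst200_frac=0.015,
            onset_rate_mean=6.9, onset_rate_sd=3.1 * _SQRT5, onset_prob=0.64,
            sustained_rate_mean=3.3, sustained_rate_sd=1.6 * _SQRT5,
            sustained_shape="late_ramp",
            laminar_length_targets=_LAMINAR_LENGTH["Sp5C"],
            laminar_bp_targets=_LAMINAR_BP["Sp5C"],
            length_rel_sd=3.8 / 13.8, bp_rel_sd=15.0 / 90.0,
            column_cells=284.0, pct_neun=9.0,
        ),
    ]
    return CohortConfig(groups=groups, dual_fraction=0.25, n_trials=25)


# ---------------------------------------------------------------------------
# Spike trains: inhomogeneous Poisson + burst doublets + onset thinning
# ---------------------------------------------------------------------------

def _sustained_elevation(t: np.ndarray, p: SpikingParams) -> np.ndarray:
    """Elevation above ongoing on [100, 700) ms; mean equals sustained_rate."""
    s = p.sustained_rate
    if p.sustained_shape in ("flat_at_baseline", "constant_elevated"):
        return np.full_like(t, s)
    if p.sustained_shape == "decaying":
        return 2.0 * s * (700.0 - t) / 600.0
    if p.sustained_shape == "late_ramp":
        return np.where(t < 500.0, 0.0, 3.0 * s)
    raise ValueError(p.sustained_shape)


def _elevation_at_700(p: SpikingParams) -> float:
    if p.sustained_shape == "decaying":
        return 0.0
    if p.sustained_shape == "late_ramp":
        return 3.0 * p.sustained_rate
    return p.sustained_rate


def _rate_profile(t: np.ndarray, p: SpikingParams, base_ongoing: float) -> np.ndarray:
    """Base-process rate (Hz) at times t (ms); burst doublets excluded."""
    r = np.full_like(t, base_ongoing, dtype=float)
    r[(t >= 0) & (t < 100)] = p.ongoing_rate + p.onset_rate
    sus = (t >= 100) & (t < 700)
    r[sus] = p.ongoing_rate + _sustained_elevation(t[sus], p)
    ret = (t >= 700) & (t < 800)
    r[ret] = p.ongoing_rate + _elevation_at_700(p) * (800.0 - t[ret]) / 100.0
    r[t >= 800] = p.ongoing_rate
    return r


def _burst_params(p: SpikingParams) -> tuple[float, float]:
    """(doublet probability f, conditional 200 Hz share a).

    If a fraction f of base spikes is followed by a doublet, both spikes of a
    doublet are burst members, so the burst fraction is 2f/(1+f); inverting
    gives f = b100 / (2 - b100). A share a = b200/b100 of doublets uses an
    inter-spike interval <= 5 ms, the rest (5, 10] ms.
    """
    b100, b200 = p.burst100_frac, p.burst200_frac
    if b100 <= 0:
        return 0.0, 0.0
    return b100 / (2.0 - b100), b200 / b100


def generate_spike_trains(
    params: SpikingParams,
    n_trials: int,
    window: tuple[float, float] = DEFAULT_WINDOW,
    seed: int | np.random.Generator | None = None,
) -> SpikeTrainSet:
    """Simulate per-trial spike times for one cell.

    The base process is an inhomogeneous Poisson process (thinning from the
    peak rate): ongoing rate before onset, ongoing + onset elevation on
    [0, 100), ongoing + the group's sustained envelope on [100, 700), a
    linear return to baseline on [700, 800). Each base spike in the ongoing
    period is followed, with the tuned doublet probability, by a second spike
    at a short inter-spike interval (<= 5 ms for the 200 Hz class, (5, 10] ms
    for the 100 Hz class); the pre-onset base rate is reduced so the total
    ongoing rate including doublets matches the target.

    Onset reliability: when the Poisson probability of >= 1 onset-window
    spike exceeds the target onset probability, all of a trial's onset
    spikes are deleted with the complementary probability; otherwise the
    onset rate dominates and no thinning occurs.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lo, hi = window
    if not (lo <= 0.0 and 700.0 <= hi):
        raise ValueError("window must contain the stimulus [0, 700] ms")

    f, a = _burst_params(params)
    base_ongoing = params.ongoing_rate / (1.0 + f)
    peak = max(
        base_ongoing,
        params.ongoing_rate + params.onset_rate,
        params.ongoing_rate
        + (2.0 if params.sustained_shape == "decaying" else 3.0 if params.sustained_shape == "late_ramp" else 1.0)
        * params.sustained_rate,
    )

    lam_onset = (params.ongoing_rate + params.onset_rate) * 0.1
    p_expected = 1.0 - math.exp(-lam_onset)
    thin_prob = 0.0
    if p_expected > params.onset_prob > 0:
        thin_prob = 1.0 - params.onset_prob / p_expected
    elif params.onset_prob == 0:
        thin_prob = 1.0 if p_expected > 0 else 0.0

    span_s = (hi - lo) / 1000.0
    trials: list[np.ndarray] = []
    for _ in range(n_trials):
        if peak <= 0:
            trials.append(np.empty(0))
            continue
        n_cand = rng.poisson(peak * span_s)
        t = np.sort(rng.uniform(lo, hi, size=n_cand))
        keep = rng.random(n_cand) < _rate_profile(t, params, base_ongoing) / peak
        t = t[keep]
        # onset-probability thinning (trial-level deletion)
        if thin_prob > 0 and rng.random() < thin_prob:
            t = t[~((t >= 0) & (t < 100))]
        # burst doublets in the ongoing period
        if f > 0:
            ongoing = t[t < 0]
            doubles = []
            for s in ongoing:
                if rng.random() < f:
                    isi = rng.uniform(0.5, 5.0) if rng.random() < a else rng.uniform(5.0, 10.0)
                    d = s + isi
                    if d < 0:
                        doubles.append(d)
            if doubles:
                t = np.sort(np.concatenate([t, np.array(doubles)]))
        trials.append(np.unique(t))
    return SpikeTrainSet(trials=trials, window=window)


# ---------------------------------------------------------------------------
# Morphologies: laminar-target-matched rooted trees
# ---------------------------------------------------------------------------

class _TreeBuilder:
    def __init__(self, soma_xyz: np.ndarray) -> None:
        self.kinds: list[str] = [SOMA]
        self.xyz: list[np.ndarray] = [np.asarray(soma_xyz, dtype=float)]
        self.parent: list[int] = [-1]
        self.radius: list[float] = [8.0]

    def add(self, kind: str, xyz: np.ndarray, parent: int, radius: float = 0.8) -> int:
        self.kinds.append(kind)
        self.xyz.append(np.asarray(xyz, dtype=float))
        self.parent.append(parent)
        self.radius.append(radius)
        return len(self.kinds) - 1

    def chain(
        self, kind: str, start_idx: int, start: np.ndarray, stop: np.ndarray,
        max_seg: float = 60.0, radius: float = 0.8,
    ) -> int:
        """Straight polyline from start to stop, subdivided to <= max_seg."""
        vec = np.asarray(stop, float) - np.asarray(start, float)
        length = float(np.linalg.norm(vec))
        if length == 0:
            return start_idx
        n_seg = max(1, int(math.ceil(length / max_seg)))
        idx = start_idx
        for k in range(1, n_seg + 1):
            idx = self.add(kind, np.asarray(start) + vec * (k / n_seg), idx, radius)
        return idx

    def build(self, depth_axis: int = 1) -> NeuronMorphology:
        n = len(self.kinds)
        return NeuronMorphology(
            node_ids=np.arange(1, n + 1),
            parent_index=np.array(self.parent),
            kinds=np.array(self.kinds, dtype=object),
            xyz=np.vstack(self.xyz),
            radius=np.array(self.radius),
            depth_axis=depth_axis,
        )


def _horizontal_dir(rng: np.random.Generator) -> np.ndarray:
    theta = rng.uniform(0, 2 * math.pi)
    return np.array([math.cos(theta), 0.0, math.sin(theta)])


def _decorated_path(
    tb: _TreeBuilder, kind: str, start_idx: int, start: np.ndarray,
    length: float, n_bps: int, rng: np.random.Generator,
    closed_loop: bool,
) -> int:
    """Horizontal path of given total length (twigs included) at constant
    depth, carrying exactly ``n_bps`` bifurcations (each spawns one twig).

    ``closed_loop`` lays the backbone as a square returning near its start
    (used for trunk excursions so the trunk can continue upward in place);
    otherwise the backbone runs straight in a random direction.
    """
    if length <= 0 and n_bps == 0:
        return start_idx
    twig_len = min(40.0, length / (2 * n_bps)) if n_bps else 0.0
    if n_bps and twig_len < 2.0:
        twig_len = 2.0  # minimal twig; tiny overshoot of the length target
    backbone = max(length - n_bps * twig_len, 0.0)

    if closed_loop:
        side = backbone / 4.0
        d0 = _horizontal_dir(rng)
        d1 = np.array([-d0[2], 0.0, d0[0]])
        legs = [d0 * side, d1 * side, -d0 * side, -d1 * side]
    else:
        d0 = _horizontal_dir(rng)
        legs = [d0 * backbone]

    # waypoints along the backbone
    pts = [np.asarray(start, float)]
    for leg in legs:
        pts.append(pts[-1] + leg)

    # positions of bifurcations: evenly spaced along the backbone
    bp_fracs = [(k + 1) / (n_bps + 1) for k in range(n_bps)]
    idx = start_idx
    pos = pts[0]
    travelled = 0.0
    bp_iter = iter(bp_fracs)
    next_bp = next(bp_iter, None)
    for wp in pts[1:]:
        seg_vec = wp - pos
        seg_len = float(np.linalg.norm(seg_vec))
        while next_bp is not None and backbone > 0 and travelled + seg_len >= next_bp * backbone - 1e-9:
            at = (next_bp * backbone - travelled) / seg_len if seg_len else 0.0
            bp_xyz = pos + seg_vec * min(max(at, 0.0), 1.0)
            idx = tb.chain(kind, idx, pos, bp_xyz)
            # twig: perpendicular horizontal branch
            perp = np.array([-seg_vec[2], 0.0, seg_vec[0]])
            nrm = np.linalg.norm(perp)
            perp = perp / nrm if nrm else _horizontal_dir(rng)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            tb.chain(kind, idx, bp_xyz, bp_xyz + sign * perp * twig_len)
            pos = bp_xyz
            travelled = next_bp * backbone
            seg_vec = wp - pos
            seg_len = float(np.linalg.norm(seg_vec))
            next_bp = next(bp_iter, None)
        idx = tb.chain(kind, idx, pos, wp)
        pos = wp
        travelled += seg_len
    # degenerate: no backbone but bifurcations requested -> stack twig pairs
    if backbone == 0 and n_bps:
        for _ in range(n_bps):
            bp_xyz = tb.xyz[idx]
            nxt = tb.add(kind, bp_xyz + _horizontal_dir(rng) * twig_len, idx)
            tb.chain(kind, idx, bp_xyz, bp_xyz + _horizontal_dir(rng) * twig_len)
            idx = nxt
    return idx


def generate_morphology(
    group: GroupParams,
    soma_depth: float,
    seed: int | np.random.Generator | None = None,
    layers: LayerScheme | None = None,
) -> NeuronMorphology:
    """Construct a rooted tree matching the group's laminar targets.

    The soma sits at the given depth; basal stems spread horizontally in the
    soma's layer; an apical trunk ascends through the layer bands to the
    shallowest layer with a nonzero target, accumulating each layer's length
    target through horizontal excursions and carrying each layer's branch
    points as bifurcation twigs. Per-layer path lengths match the targets to
    within construction tolerance (< 5%) and branch-point counts exactly.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    layers = layers or default_layers()
    if soma_depth <= 0:
        raise MorphologyGenerationError("soma depth must be positive (below the pia)")
    lengths = np.asarray(group.laminar_length_targets, dtype=float)
    bps = np.asarray(group.laminar_bp_targets, dtype=int)
    if np.any(lengths < 0) or np.any(bps < 0):
        raise MorphologyGenerationError("laminar targets must be nonnegative")
    if np.any((bps > 0) & (lengths <= 0)):
        raise MorphologyGenerationError("a layer with branch points needs nonzero length")

    boundaries = np.asarray(layers.boundaries)
    n5 = len(DENDRITE_LAYERS)
    soma_idx = layers.layer_of_depth(soma_depth)

    tb = _TreeBuilder(np.array([0.0, soma_depth, 0.0]))

    above = [i for i in range(min(soma_idx, n5)) if lengths[i] > 0 or bps[i] > 0]
    top_idx = min(above) if above else None

    # --- apical trunk ---
    trunk_crossing_soma_layer = 0.0
    if top_idx is not None:
        if top_idx >= soma_idx:
            raise MorphologyGenerationError("apical targets must lie above the soma layer")
        pos = np.array([0.0, soma_depth, 0.0])
        idx = 0
        if soma_idx < n5:
            trunk_crossing_soma_layer = soma_depth - boundaries[soma_idx]
        # rise through the soma's own layer (and any interposed layers below
        # the deepest targeted layer)
        for i in range(soma_idx - 1, top_idx - 1, -1):
            entry_depth = boundaries[i + 1]
            exit_depth = boundaries[i] if i > top_idx else 0.5 * (boundaries[i] + boundaries[i + 1])
            if np.linalg.norm(pos[1] - entry_depth) > 1e-9:
                idx = tb.chain(APICAL, idx, pos, np.array([pos[0], entry_depth, pos[2]]), radius=2.0)
                pos = np.array([pos[0], entry_depth, pos[2]])
            mid = 0.5 * (boundaries[i] + boundaries[i + 1])
            target_len = lengths[i] if i < n5 else 0.0
            target_bp = int(bps[i]) if i < n5 else 0
            crossing = entry_depth - exit_depth
            extra = max(target_len - crossing, 0.0)
            # down to (well, up to) the excursion depth
            idx = tb.chain(APICAL, idx, pos, np.array([pos[0], mid, pos[2]]), radius=2.0)
            pos = np.array([pos[0], mid, pos[2]])
            if extra > 0 or target_bp > 0:
                idx = _decorated_path(
                    tb, APICAL, idx, pos, extra, target_bp, rng,
                    closed_loop=(i > top_idx),
                )
                pos = np.array(tb.xyz[idx])
            if i > top_idx:
                idx = tb.chain(APICAL, idx, pos, np.array([pos[0], exit_depth, pos[2]]), radius=2.0)
                pos = np.array([pos[0], exit_depth, pos[2]])

    # --- descending dendrites through layers below the soma ---
    below = [i for i in range(soma_idx + 1, n5) if lengths[i] > 0 or bps[i] > 0]
    bot_idx = max(below) if below else None
    descend_crossing_soma_layer = 0.0
    if bot_idx is not None:
        pos = np.array([0.0, soma_depth, 0.0])
        idx = 0
        if soma_idx < n5:
            descend_crossing_soma_layer = boundaries[soma_idx + 1] - soma_depth
        for i in range(soma_idx + 1, bot_idx + 1):
            entry_depth = boundaries[i]
            mid = 0.5 * (boundaries[i] + boundaries[i + 1])
            exit_depth = boundaries[i + 1] if i < bot_idx else mid
            if abs(pos[1] - entry_depth) > 1e-9:
                idx = tb.chain(BASAL, idx, pos, np.array([pos[0], entry_depth, pos[2]]))
                pos = np.array([pos[0], entry_depth, pos[2]])
            crossing = exit_depth - entry_depth
            extra = max(lengths[i] - crossing, 0.0)
            idx = tb.chain(BASAL, idx, pos, np.array([pos[0], mid, pos[2]]))
            pos = np.array([pos[0], mid, pos[2]])
            if extra > 0 or bps[i] > 0:
                idx = _decorated_path(
                    tb, BASAL, idx, pos, extra, int(bps[i]), rng,
                    closed_loop=(i < bot_idx),
                )
                pos = np.array(tb.xyz[idx])
            if i < bot_idx:
                idx = tb.chain(BASAL, idx, pos, np.array([pos[0], exit_depth, pos[2]]))
                pos = np.array([pos[0], exit_depth, pos[2]])

    # --- basal stems in the soma's layer ---
    basal_total = 0.0
    basal_bps = 0
    if soma_idx < n5:
        basal_total = max(
            lengths[soma_idx] - trunk_crossing_soma_layer - descend_crossing_soma_layer, 0.0
        )
        basal_bps = int(bps[soma_idx])
    if basal_total > 0 or basal_bps > 0:
        n_stems = int(np.clip(math.ceil(basal_total / 1000.0), 1, 7))
        stem_len = basal_total / n_stems
        stem_bps = [basal_bps // n_stems + (1 if k < basal_bps % n_stems else 0) for k in range(n_stems)]
        soma_pos = np.array([0.0, soma_depth, 0.0])
        for k in range(n_stems):
            _decorated_path(tb, BASAL, 0, soma_pos, stem_len, stem_bps[k], rng, closed_loop=False)

    return tb.build()


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _shifted_location(mean: float, sd: float, lower: float) -> float:
    """Location mu' such that E[X | X > lower], X ~ N(mu', sd), equals mean.

    Plain resample-until-positive sampling inflates the mean badly when the
    SD is comparable to (or larger than) the mean — e.g. a nominal 0.8 +/-
    3.1 Hz sustained elevation would average ~2.8 Hz. Shifting the location
    before truncation keeps the group means exactly at their calibrated
    values, which is what calibration recovery requires.
    """
    from scipy.optimize import brentq
    from scipy.stats import norm

    def trunc_mean(mu: float) -> float:
        a = (lower - mu) / sd
        # inverse Mills ratio via log-pdf/log-sf for numerical stability
        return mu + sd * math.exp(norm.logpdf(a) - norm.logsf(a))

    if trunc_mean(mean) - mean < 1e-12:
        return mean
    lo = mean - 50.0 * sd
    return float(brentq(lambda mu: trunc_mean(mu) - mean, lo, mean, xtol=1e-10))


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lower: float = 0.0) -> float:
    """Mean-preserving truncated Gaussian draw (resample until above bound)."""
    if sd <= 0:
        return max(mean, lower)
    if mean <= lower:
        raise ValueError("truncated draw needs mean above the lower bound")
    mu = _shifted_location(mean, sd, lower)
    for _ in range(1000):
        x = rng.normal(mu, sd)
        if x > lower:
            return x
    return max(mean, lower)  # pragma: no cover - pathological calibration


_ALLOWED_DUALS = {
    "POm": ("SC", "Pons"),
    "SC": ("POm", "Pons", "Sp5C"),
    "Pons": ("POm", "SC", "Sp5C"),
    "Sp5C": ("SC", "Pons"),  # POm <-> Sp5C overlap is largely absent
}


def realize_cell(
    group: GroupParams, rng: np.random.Generator
) -> tuple[float, SpikingParams, tuple[float, ...], tuple[int, ...]]:
    """Draw one cell's depth, rates and laminar targets from the group stats."""
    depth = _trunc_normal(rng, group.depth_mean, group.depth_sd)
    if group.burst100_frac > 0:
        b100 = min(_trunc_normal(rng, group.burst100_frac, group.burst100_frac * group.burst_rel_sd, 1e-9), 0.9)
        b200 = min(_trunc_normal(rng, group.burst200_frac, group.burst200_frac * group.burst_rel_sd, 0.0), b100)
    else:
        b100 = b200 = 0.0
    spiking = SpikingParams(
        ongoing_rate=_trunc_normal(rng, group.ongoing_rate_mean, group.ongoing_rate_sd),
        onset_rate=_trunc_normal(rng, group.onset_rate_mean, group.onset_rate_sd),
        onset_prob=group.onset_prob,
        sustained_rate=_trunc_normal(rng, group.sustained_rate_mean, group.sustained_rate_sd),
        sustained_shape=group.sustained_shape,
        burst100_frac=b100,
        burst200_frac=b200 if group.burst200_frac > 0 else 0.0,
    )
    len_scale = _trunc_normal(rng, 1.0, group.length_rel_sd, 0.2)
    bp_scale = _trunc_normal(rng, 1.0, group.bp_rel_sd, 0.2)
    lam_len = tuple(
        float(t * len_scale * _trunc_normal(rng, 1.0, 0.08, 0.3))
        for t in group.laminar_length_targets
    )
    lam_bp = tuple(
        int(round(t * bp_scale * _trunc_normal(rng, 1.0, 0.08, 0.3)))
        for t in group.laminar_bp_targets
    )
    # a layer keeps at least one branch point only if it has length to carry it
    lam_bp = tuple(b if l > 0 else 0 for b, l in zip(lam_bp, lam_len))
    return depth, spiking, lam_len, lam_bp


def generate_cohort(
    config: CohortConfig,
    seed: int | None = None,
    include_morphology: bool = True,
    include_trains: bool = True,
    layers: LayerScheme | None = None,
) -> list[SyntheticCell]:
    """Generate a labeled synthetic cohort; reproducible for a fixed seed.

    Dual-target cells inherit all generative parameters from their primary
    group; the second label (never pairing POm with Sp5C) is annotation only.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    layers = layers or default_layers()
    cells: list[SyntheticCell] = []
    for group in config.groups:
        for k in range(group.n_cells):
            depth, spiking, lam_len, lam_bp = realize_cell(group, rng)
            targets: tuple[str, ...] = (group.target_label,)
            if config.dual_fraction > 0 and rng.random() < config.dual_fraction:
                allowed = [
                    t for t in _ALLOWED_DUALS.get(group.target_label, ())
                    if any(g.target_label == t for g in config.groups)
                ]
                if allowed:
                    targets = (group.target_label, allowed[rng.integers(len(allowed))])
            cell_group = replace(
                group, laminar_length_targets=lam_len, laminar_bp_targets=lam_bp
            )
            morph = (
                generate_morphology(cell_group, depth, rng, layers)
                if include_morphology
                else None
            )
            trains = (
                generate_spike_trains(spiking, config.n_trials, config.window, rng)
                if include_trains
                else None
            )
            cells.append(
                SyntheticCell(
                    cell_id=f"{group.target_label}_{k:03d}",
                    true_targets=targets,
                    soma_depth=depth,
                    morphology=morph,
                    trains=trains,
                    spiking=spiking,
                    laminar_length=lam_len,
                    laminar_bp=lam_bp,
                )
            )
    return cells


# ---------------------------------------------------------------------------
# Soma fields (synthetic retrograde-labeling slices)
# ---------------------------------------------------------------------------

@dataclass
class SomaFieldConfig:
    groups: list[GroupParams]
    n_slices: int = 12
    slice_fraction: tuple[float, float] = (0.6, 1.0)  # column-equivalents per slice
    jitter_bins: int = 2          # +/- integer 50 um bins of pia mis-registration
    n_bins: int = 42
    bin_width: float = 50.0


@dataclass
class SomaField:
    """Per-slice soma depth records per channel, with generation ground truth."""

    slices: list[dict[str, np.ndarray]]   # channel -> soma depths (um)
    ground_truth: dict[str, float]        # labeled somata per average column
    reference_neun: DensityProfile1D      # per-column NeuN profile
    bin_width: float
    n_bins: int


def reference_neun_profile(n_bins: int = 42, bin_width: float = 50.0) -> DensityProfile1D:
    """Synthetic per-column NeuN depth profile (neurons per 50 um bin).

    A smooth layered density with the characteristic L4 peak, scaled so that
    layer 5 (900-1400 um) holds 3500 neurons per average barrel column. This
    is a synthetic stand-in for a measured reference profile; real-data users
    supply their own.
    """
    depths = bin_width * (np.arange(n_bins) + 0.5)
    base = np.select(
        [depths < 100, depths < 600, depths < 900, depths < 1050, depths < 1400, depths < 1850],
        [40.0, 400.0, 500.0, 380.0, 330.0, 400.0],
        default=0.0,
    )
    l4_peak = 450.0 * np.exp(-0.5 * ((depths - 750.0) / 80.0) ** 2)
    counts = gaussian_filter1d(base + l4_peak, sigma=0.8, mode="constant")
    l5 = (depths >= 900) & (depths < 1400)
    counts = counts * (3500.0 / counts[l5].sum())
    return DensityProfile1D(counts=counts, bin_width=bin_width)


def _sample_from_profile(
    profile: DensityProfile1D, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample depths from a binned density (uniform within bins)."""
    p = profile.counts / profile.counts.sum()
    bins = rng.choice(len(p), size=n, p=p)
    return (bins + rng.random(n)) * profile.bin_width


def generate_soma_field(
    config: SomaFieldConfig, seed: int | np.random.Generator | None = None
) -> SomaField:
    """Emit per-slice soma depth records with known per-column ground truth.

    Each slice captures a random fraction of a barrel column's worth of
    somata: NeuN somata follow the reference layered density, labeled somata
    per group follow the group soma-depth Gaussians with per-column totals
    from the calibration. The whole slice is shifted by an integer number of
    bins (pia mis-registration) that the alignment stage must undo.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ref = reference_neun_profile(config.n_bins, config.bin_width)
    n_col = ref.total()
    slices: list[dict[str, np.ndarray]] = []
    for _ in range(config.n_slices):
        c = rng.uniform(*config.slice_fraction)
        offset = config.bin_width * (
            config.jitter_bins + rng.integers(-config.jitter_bins, config.jitter_bins + 1)
        )
        record: dict[str, np.ndarray] = {}
        n_neun = rng.poisson(c * n_col)
        record["NeuN"] = _sample_from_profile(ref, n_neun, rng) + offset
        for g in config.groups:
            n_lab = rng.poisson(c * g.column_cells)
            depths = np.array([_trunc_normal(rng, g.depth_mean, g.depth_sd) for _ in range(n_lab)])
            record[g.target_label] = depths + offset
        slices.append(record)
    return SomaField(
        slices=slices,
        ground_truth={g.target_label: g.column_cells for g in config.groups},
        reference_neun=ref,
        bin_width=config.bin_width,
        n_bins=config.n_bins,
    )
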