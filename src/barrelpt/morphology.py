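"""Dendritic morphometry of layer-5 pyramidal neurons.

A reconstruction is a rooted tree of typed 3D points (soma, basal dendrite,
apical dendrite) read from standard SWC files. The vertical cortical axis is
one of the coordinate axes (default: the second), increasing with depth, with
the pial surface at depth 0. Morphometry is laminar: every dendritic segment
is apportioned to the cortical layer band(s) its depth interval crosses, and
per-layer "complexity" is path length multiplied by the number of branch
points in that layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NeuronMorphology",
    "LayerScheme",
    "LaminarProfile",
    "DendriticFeatureVector",
    "SwcParseError",
    "read_swc",
    "write_swc",
    "laminar_profile",
    "feature_vector",
    "pca_features",
    "default_layers",
    "FEATURE_NAMES",
]

SOMA, BASAL, APICAL = "soma", "basal", "apical"
_SWC_CODE_TO_KIND = {1: SOMA, 3: BASAL, 4: APICAL}
_KIND_TO_SWC_CODE = {v: k for k, v in _SWC_CODE_TO_KIND.items()}

DENDRITE_LAYERS = ("L1", "L2/3", "L4", "L5A", "L5B")


class SwcParseError(ValueError):
    """Malformed SWC content (orphan node, multiple roots, unknown code...)."""


@dataclass
class NeuronMorphology:
    """Rooted tree of typed nodes.

    Arrays are index-aligned; ``parent_index[i]`` is the array index of node
    i's parent, or -1 for the root (which must be the soma). ``depth_axis``
    names the coordinate that increases with cortical depth (pia = 0).
    """

    node_ids: np.ndarray          # (n,) int
    parent_index: np.ndarray      # (n,) int, -1 for root
    kinds: np.ndarray             # (n,) object/str in {soma, basal, apical}
    xyz: np.ndarray               # (n, 3) float, micrometres
    radius: np.ndarray            # (n,) float, micrometres
    depth_axis: int = 1

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=int)
        self.parent_index = np.asarray(self.parent_index, dtype=int)
        self.kinds = np.asarray(self.kinds, dtype=object)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self._validate()

    def _validate(self) -> None:
        n = len(self.node_ids)
        if n == 0:
            raise ValueError("empty morphology")
        roots = np.flatnonzero(self.parent_index < 0)
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        if roots[0] != 0 or self.kinds[0] != SOMA:
            raise ValueError("root must be the first node and of soma type")
        if np.any(self.parent_index[1:] >= np.arange(1, n)):
            raise ValueError("parents must precede children")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite coordinates")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def depths(self) -> np.ndarray:
        return self.xyz[:, self.depth_axis]

    @property
    def soma_depth(self) -> float:
        return float(self.depths[0])

    def children_counts(self) -> np.ndarray:
        counts = np.zeros(self.n_nodes, dtype=int)
        np.add.at(counts, self.parent_index[self.parent_index >= 0], 1)
        return counts

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(parent_xyz, child_xyz, child_kind) for every non-root node."""
        child = np.flatnonzero(self.parent_index >= 0)
        parent = self.parent_index[child]
        return self.xyz[parent], self.xyz[child], self.kinds[child]

    def branch_point_mask(self) -> np.ndarray:
        """Non-soma nodes with >= 2 children (trifurcations count once)."""
        return (self.children_counts() >= 2) & (self.kinds != SOMA)


@dataclass(frozen=True)
class LayerScheme:
    """Contiguous depth bands [lo, hi) covering the cortex from the pia down."""

    names: tuple[str, ...]
    boundaries: tuple[float, ...]  # len(names) + 1, starting at 0

    def __post_init__(self) -> None:
        if len(self.boundaries) != len(self.names) + 1:
            raise ValueError("need len(names)+1 boundaries")
        if self.boundaries[0] != 0:
            raise ValueError("layer boundaries must start at the pia (0)")
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("layer boundaries must be strictly increasing")

    @property
    def n_layers(self) -> int:
        return len(self.names)

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    def span(self, name: str) -> tuple[float, float]:
        i = self.index_of(name)
        return self.boundaries[i], self.boundaries[i + 1]

    def layer_of_depth(self, depth: float) -> int:
        """Index of the layer band containing a depth (clipped into range)."""
        d = min(max(depth, 0.0), np.nextafter(self.boundaries[-1], 0))
        return int(np.searchsorted(self.boundaries, d, side="right") - 1)


def default_layers() -> LayerScheme:
    """Default rat vS1 layer bands.

    Only the L5A/L5B border at 1050 um is anatomically anchored in this
    analysis ("above or below 1050 um"); the other boundaries are nominal and
    overridable via configuration.
    """
    return LayerScheme(
        names=("L1", "L2/3", "L4", "L5A", "L5B", "L6"),
        boundaries=(0.0, 100.0, 600.0, 900.0, 1050.0, 1400.0, 1850.0),
    )


@dataclass
class LaminarProfile:
    """Per-layer dendritic path length, branch-point count and complexity."""

    layers: LayerScheme
    path_length: np.ndarray   # um, per layer
    branch_points: np.ndarray  # count, per layer

    @property
    def complexity(self) -> np.ndarray:
        """Path length x branch points, per layer (um * count)."""
        return self.path_length * self.branch_points

    def as_series(self) -> pd.Series:
        data = {}
        for i, name in enumerate(self.layers.names):
            data[f"length_{name}"] = self.path_length[i]
            data[f"bp_{name}"] = self.branch_points[i]
        return pd.Series(data)


def read_swc(path) -> NeuronMorphology:
    """Read a standard 7-column SWC file.

    Structure codes 1/3/4 map to soma/basal/apical; other codes, orphan
    parents and multiple roots raise :class:`SwcParseError` naming the line.
    """
    rows: list[tuple[int, int, int, float, float, float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SwcParseError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                nid, code = int(parts[0]), int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise SwcParseError(f"{path}:{lineno}: {exc}") from None
            if code not in _SWC_CODE_TO_KIND:
                raise SwcParseError(f"{path}:{lineno}: unknown structure code {code}")
            rows.append((lineno, nid, code, x, y, z, r, parent))

    if not rows:
        raise SwcParseError(f"{path}: no nodes")
    id_to_index = {nid: i for i, (_, nid, *_rest) in enumerate(rows)}
    if len(id_to_index) != len(rows):
        raise SwcParseError(f"{path}: duplicate node ids")

    n = len(rows)
    node_ids = np.empty(n, dtype=int)
    parent_index = np.empty(n, dtype=int)
    kinds = np.empty(n, dtype=object)
    xyz = np.empty((n, 3))
    radius = np.empty(n)
    for i, (lineno, nid, code, x, y, z, r, parent) in enumerate(rows):
        node_ids[i] = nid
        kinds[i] = _SWC_CODE_TO_KIND[code]
        xyz[i] = (x, y, z)
        radius[i] = r
        if parent == -1:
            parent_index[i] = -1
        else:
            if parent not in id_to_index:
                raise SwcParseError(f"{path}:{lineno}: parent {parent} not declared")
            parent_index[i] = id_to_index[parent]
            if parent_index[i] >= i:
                raise SwcParseError(f"{path}:{lineno}: parent {parent} declared after child")
    n_roots = int(np.sum(parent_index == -1))
    if n_roots != 1:
        raise SwcParseError(f"{path}: expected exactly one root, found {n_roots}")
    return NeuronMorphology(node_ids, parent_index, kinds, xyz, radius)


def write_swc(morph: NeuronMorphology, path) -> None:
    """Write standard SWC (1-based ids, parent -1 for the root)."""
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for i in range(morph.n_nodes):
            pid = -1 if morph.parent_index[i] < 0 else int(morph.node_ids[morph.parent_index[i]])
            x, y, z = morph.xyz[i]
            fh.write(
                f"{int(morph.node_ids[i])} {_KIND_TO_SWC_CODE[morph.kinds[i]]} "
                f"{x:.6f} {y:.6f} {z:.6f} {morph.radius[i]:.6f} {pid}\n"
            )


def _segment_layer_lengths(
    d0: np.ndarray, d1: np.ndarray, length: np.ndarray, boundaries: np.ndarray
) -> np.ndarray:
    """Apportion segment Euclidean lengths to depth bands.

    Each segment's length is split proportionally to how much of its depth
    interval falls inside each band; a segment at constant depth goes wholly
    to the band containing it.
    """
    n_layers = len(boundaries) - 1
    out = np.zeros(n_layers)
    lo = np.minimum(d0, d1)
    hi = np.maximum(d0, d1)
    span = hi - lo
    flat = span <= 0
    # constant-depth segments: whole length to the containing band
    if np.any(flat):
        dflat = np.clip(lo[flat], 0, np.nextafter(boundaries[-1], 0))
        idx = np.searchsorted(boundaries, dflat, side="right") - 1
        np.add.at(out, np.clip(idx, 0, n_layers - 1), length[flat])
    sl = ~flat
    if np.any(sl):
        lo_s, hi_s, span_s, len_s = lo[sl], hi[sl], span[sl], length[sl]
        for k in range(n_layers):
            overlap = np.clip(
                np.minimum(hi_s, boundaries[k + 1]) - np.maximum(lo_s, boundaries[k]), 0, None
            )
            out[k] += float(np.sum(len_s * overlap / span_s))
    return out


def laminar_profile(morph: NeuronMorphology, layers: LayerScheme | None = None) -> LaminarProfile:
    """Apportion dendritic length and branch points to cortical layers.

    Segment lengths are split at layer-boundary depths (proportional clipping
    of the depth interval); branch points (non-soma nodes with >= 2 children)
    are assigned to the layer containing their depth. The soma node itself
    contributes no length; edges whose child node is of soma type are skipped.
    """
    layers = layers or default_layers()
    boundaries = np.asarray(layers.boundaries)

    p_xyz, c_xyz, c_kind = morph.edge_arrays()
    dendritic = c_kind != SOMA
    p_xyz, c_xyz = p_xyz[dendritic], c_xyz[dendritic]
    lengths = np.linalg.norm(c_xyz - p_xyz, axis=1)
    d0 = p_xyz[:, morph.depth_axis].copy()
    d1 = c_xyz[:, morph.depth_axis].copy()
    if np.any(d0 < 0) or np.any(d1 < 0):
        warnings.warn("node(s) above the pia (negative depth); clipped to 0", stacklevel=2)
        d0 = np.clip(d0, 0, None)
        d1 = np.clip(d1, 0, None)

    path_length = _segment_layer_lengths(d0, d1, lengths, boundaries)

    bp_mask = morph.branch_point_mask()
    branch_points = np.zeros(layers.n_layers, dtype=int)
    for d in morph.depths[bp_mask]:
        branch_points[layers.layer_of_depth(float(d))] += 1
    return LaminarProfile(layers, path_length, branch_points)


# ---------------------------------------------------------------------------
# 21-dimensional dendritic feature vector
# ---------------------------------------------------------------------------

FEATURE_NAMES: tuple[str, ...] = (
    "soma_depth",
    "total_length",
    "basal_length",
    "apical_length",
    "total_branch_points",
    "basal_branch_points",
    "apical_branch_points",
    "length_L1",
    "length_L2/3",
    "length_L4",
    "length_L5A",
    "length_L5B",
    "bp_L1",
    "bp_L2/3",
    "bp_L4",
    "bp_L5A",
    "bp_L5B",
    "tuft_extent",
    "trunk_length_to_main_bifurcation",
    "n_primary_basal_stems",
    "max_branch_order",
)


@dataclass
class DendriticFeatureVector:
    """Fixed-order 21-feature morphometric summary of one neuron.

    Lengths in um, counts dimensionless. The registry (``FEATURE_NAMES``) is
    the package's documented stand-in feature set and can be swapped for a
    different list without touching downstream code, which only consumes the
    named columns it asks for.
    """

    names: tuple[str, ...]
    values: np.ndarray

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


def _subtree_stats(morph: NeuronMorphology, kind: str) -> tuple[float, int]:
    p_xyz, c_xyz, c_kind = morph.edge_arrays()
    sel = c_kind == kind
    length = float(np.sum(np.linalg.norm(c_xyz[sel] - p_xyz[sel], axis=1)))
    bp = int(np.sum(morph.branch_point_mask() & (morph.kinds == kind)))
    return length, bp


def _branch_orders(morph: NeuronMorphology) -> np.ndarray:
    """Branch order per node: 1 + number of branch points on the root path
    strictly above the node (an unbranched cable has order 1 throughout)."""
    bp = morph.branch_point_mask()
    order = np.ones(morph.n_nodes, dtype=int)
    for i in range(1, morph.n_nodes):
        p = morph.parent_index[i]
        order[i] = order[p] + (1 if bp[p] else 0)
    return order


def feature_vector(
    morph: NeuronMorphology, layers: LayerScheme | None = None
) -> DendriticFeatureVector:
    """Compute the 21-feature morphometric vector of one reconstruction."""
    layers = layers or default_layers()
    profile = laminar_profile(morph, layers)

    basal_len, basal_bp = _subtree_stats(morph, BASAL)
    apical_len, apical_bp = _subtree_stats(morph, APICAL)
    if apical_len == 0:
        warnings.warn("no apical subtree; apical features set to 0", stacklevel=2)

    values = {
        "soma_depth": morph.soma_depth,
        "total_length": basal_len + apical_len,
        "basal_length": basal_len,
        "apical_length": apical_len,
        "total_branch_points": basal_bp + apical_bp,
        "basal_branch_points": basal_bp,
        "apical_branch_points": apical_bp,
    }
    for name in DENDRITE_LAYERS:
        i = layers.index_of(name)
        values[f"length_{name}"] = profile.path_length[i]
        values[f"bp_{name}"] = int(profile.branch_points[i])

    # tuft extent: horizontal bounding-box diagonal of apical nodes shallower
    # than 300 um (upper L2/3 and L1, where the tuft ramifies)
    horiz = [a for a in range(3) if a != morph.depth_axis]
    tuft_sel = (morph.kinds == APICAL) & (morph.depths < 300.0)
    if np.any(tuft_sel):
        extents = np.ptp(morph.xyz[tuft_sel][:, horiz], axis=0)
        values["tuft_extent"] = float(np.hypot(*extents))
    else:
        values["tuft_extent"] = 0.0

    values["trunk_length_to_main_bifurcation"] = _trunk_length_to_bifurcation(morph)
    root_children = np.flatnonzero(morph.parent_index == 0)
    values["n_primary_basal_stems"] = int(np.sum(morph.kinds[root_children] == BASAL))

    dend = morph.kinds != SOMA
    values["max_branch_order"] = int(_branch_orders(morph)[dend].max()) if np.any(dend) else 0

    return DendriticFeatureVector(
        FEATURE_NAMES, np.array([values[n] for n in FEATURE_NAMES], dtype=float)
    )


def _trunk_length_to_bifurcation(morph: NeuronMorphology) -> float:
    """Path length from the soma along the apical trunk to its first
    bifurcation (0 if there is no apical subtree or no apical branch point)."""
    bp = morph.branch_point_mask()
    counts = morph.children_counts()
    children: list[list[int]] = [[] for _ in range(morph.n_nodes)]
    for i in range(1, morph.n_nodes):
        children[morph.parent_index[i]].append(i)
    apical_roots = [i for i in children[0] if morph.kinds[i] == APICAL]
    if not apical_roots:
        return 0.0
    node = apical_roots[0]
    total = float(np.linalg.norm(morph.xyz[node] - morph.xyz[0]))
    while not bp[node]:
        nxt = [c for c in children[node] if morph.kinds[c] == APICAL]
        if not nxt:
            return 0.0  # trunk never bifurcates
        total += float(np.linalg.norm(morph.xyz[nxt[0]] - morph.xyz[node]))
        node = nxt[0]
    return total


def pca_features(
    matrix: np.ndarray | pd.DataFrame, n_components: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of a (cells x features) matrix, z-scored column-wise.

    Zero-variance columns are dropped with a warning. Component signs are
    fixed by making the largest-magnitude loading of each component positive.

    Returns ``(scores, loadings, explained_variance_ratio)`` where
    ``loadings`` has shape (n_components, n_kept_features) and
    ``scores @ loadings`` reproduces the z-scored matrix when all components
    are kept.
    """
    from sklearn.decomposition import PCA

    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 cells")
    std = X.std(axis=0, ddof=0)
    keep = std > 0
    if not np.all(keep):
        warnings.warn(f"dropping {int(np.sum(~keep))} constant feature column(s)", stacklevel=2)
    Xz = (X[:, keep] - X[:, keep].mean(axis=0)) / std[keep]

    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(Xz)
    loadings = pca.components_
    # deterministic sign convention
    flip = np.sign(loadings[np.arange(loadings.shape[0]), np.argmax(np.abs(loadings), axis=1)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip[:, None]
    scores = scores * flip[None, :]
    return scores, loadings, pca.explained_variance_ratio_
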