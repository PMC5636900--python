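"""Vertical soma-density profiles from retrograde-labeling experiments.

Somata marked in each image channel (pan-neuronal NeuN plus one retrograde
tracer per injected target) are summed in 50 um depth intervals per brain
slice. Slices are registered vertically to each other on the L4 peak of
their NeuN profiles, averaged, and amplitude-scaled by least squares onto a
reference NeuN profile expressed in neurons-per-barrel-column units; the
tracer profiles are scaled by the same factor, which converts labeled-soma
counts per slice into counts per average barrel column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "DensityProfile1D",
    "SliceProfiles",
    "bin_profile",
    "align_by_L4_peak",
    "average_profiles",
    "fit_scale",
    "per_column_estimate",
    "estimate_per_column",
    "NEUN_CHANNEL",
    "DEFAULT_BIN_UM",
    "DEFAULT_L4_RANGE",
]

NEUN_CHANNEL = "NeuN"
DEFAULT_BIN_UM = 50.0
DEFAULT_L4_RANGE = (600.0, 900.0)


@dataclass
class DensityProfile1D:
    """50 um-binned vertical soma-count profile.

    ``counts[k]`` is the number of somata with depth in [k*bin, (k+1)*bin).
    ``shift`` records the integer-bin translation applied during alignment and
    ``scale`` the amplitude factor applied when matching a reference profile.
    """

    counts: np.ndarray
    bin_width: float = DEFAULT_BIN_UM
    shift: int = 0
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    def total(self) -> float:
        return float(self.counts.sum())

    def shifted(self, shift: int) -> "DensityProfile1D":
        """Translate by an integer number of bins (zero-padded, mass-preserving
        except for counts pushed past the profile ends)."""
        out = np.zeros_like(self.counts)
        if shift >= 0:
            out[shift:] = self.counts[: self.n_bins - shift] if shift else self.counts
        else:
            out[:shift] = self.counts[-shift:]
        return replace(self, counts=out, shift=self.shift + shift)


@dataclass
class SliceProfiles:
    """Per-channel profiles of one slice (same binning, moved together)."""

    channels: dict[str, DensityProfile1D]

    def __getitem__(self, channel: str) -> DensityProfile1D:
        return self.channels[channel]


def bin_profile(
    depths: np.ndarray, bin_width: float = DEFAULT_BIN_UM, n_bins: int | None = None
) -> DensityProfile1D:
    """Sum somata in [k*bin, (k+1)*bin) depth intervals."""
    depths = np.asarray(depths, dtype=float)
    if depths.size and depths.min() < 0:
        raise ValueError("soma depths must be >= 0")
    if n_bins is None:
        n_bins = int(np.floor(depths.max() / bin_width)) + 1 if depths.size else 1
    edges = bin_width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    if depths.size:
        idx = np.floor(depths / bin_width).astype(int)
        idx = idx[idx < n_bins]
        np.add.at(counts, idx, 1.0)
    del edges
    return DensityProfile1D(counts=counts, bin_width=bin_width)


def _l4_peak_bin(profile: DensityProfile1D, l4_range: tuple[float, float]) -> int | None:
    lo = int(np.floor(l4_range[0] / profile.bin_width))
    hi = int(np.ceil(l4_range[1] / profile.bin_width))
    window = profile.counts[lo:hi]
    if window.size == 0 or window.max() <= 0:
        return None
    # global maximum must fall inside L4 for the slice to be alignable;
    # equal-height peaks tie-break to the shallowest bin (argmax convention)
    peak = lo + int(np.argmax(window))
    if profile.counts.max() > window.max():
        return None
    return peak


def align_by_L4_peak(
    slices: Sequence[SliceProfiles],
    l4_range: tuple[float, float] = DEFAULT_L4_RANGE,
) -> tuple[list[SliceProfiles], list[int]]:
    """Shift each slice so its NeuN L4 peak lands on the median peak bin.

    All channels of a slice move together (pure translation). Slices whose
    NeuN maximum does not fall inside the configured L4 depth range are
    excluded with a warning.

    Returns (aligned slices, applied shifts).
    """
    peaks: list[int | None] = []
    for sl in slices:
        if NEUN_CHANNEL not in sl.channels:
            raise ValueError("every slice needs a NeuN profile for alignment")
        peaks.append(_l4_peak_bin(sl[NEUN_CHANNEL], l4_range))

    valid = [p for p in peaks if p is not None]
    if not valid:
        raise ValueError("no slice has a NeuN maximum inside the L4 range")
    target = int(np.median(valid))

    aligned: list[SliceProfiles] = []
    shifts: list[int] = []
    for sl, peak in zip(slices, peaks):
        if peak is None:
            warnings.warn("slice excluded: no NeuN maximum inside L4 range", stacklevel=2)
            continue
        shift = target - peak
        aligned.append(
            SliceProfiles({ch: prof.shifted(shift) for ch, prof in sl.channels.items()})
        )
        shifts.append(shift)
    return aligned, shifts


def average_profiles(slices: Sequence[SliceProfiles]) -> SliceProfiles:
    """Bin-wise mean of each channel across slices (channels present in all)."""
    if not slices:
        raise ValueError("no slices to average")
    channels = set(slices[0].channels)
    for sl in slices[1:]:
        channels &= set(sl.channels)
    out: dict[str, DensityProfile1D] = {}
    for ch in sorted(channels):
        counts = np.mean([sl[ch].counts for sl in slices], axis=0)
        out[ch] = DensityProfile1D(counts=counts, bin_width=slices[0][ch].bin_width)
    return SliceProfiles(out)


def fit_scale(
    profile: DensityProfile1D,
    reference: DensityProfile1D,
    search_shifts: Iterable[int] = range(-3, 4),
) -> tuple[float, int]:
    """Least-squares amplitude scale of ``profile`` onto ``reference``.

    For each candidate integer shift, the closed-form minimizer of
    sum_b (s * p_b - ref_b)^2 is s = sum(p * ref) / sum(p^2); the
    (scale, shift) pair with the smallest residual is returned.
    """
    if profile.total() == 0:
        raise ValueError("cannot scale an all-zero profile")
    if profile.n_bins != reference.n_bins:
        raise ValueError("profile and reference must share binning")
    best: tuple[float, int] | None = None
    best_err = np.inf
    for shift in search_shifts:
        p = profile.shifted(shift).counts
        denom = float(np.sum(p * p))
        if denom == 0:
            continue
        s = float(np.sum(p * reference.counts)) / denom
        err = float(np.sum((s * p - reference.counts) ** 2))
        if err < best_err:
            best_err = err
            best = (s, shift)
    assert best is not None
    return best


def per_column_estimate(labeled: DensityProfile1D, scale: float) -> float:
    """Labeled somata per average barrel column: scale x total labeled count.

    ``scale`` must come from :func:`fit_scale` of the same slice set's NeuN
    profile onto a reference expressed in per-column units.
    """
    return scale * labeled.total()


def estimate_per_column(
    slices: Sequence[SliceProfiles],
    reference_neun: DensityProfile1D,
    l4_range: tuple[float, float] = DEFAULT_L4_RANGE,
) -> dict[str, float]:
    """Full pipeline: align slices, average, fit scale, estimate per column.

    Returns per-channel per-column estimates for every non-NeuN channel,
    plus the fitted ``scale`` and ``shift`` under those keys.
    """
    aligned, _ = align_by_L4_peak(slices, l4_range)
    avg = average_profiles(aligned)
    scale, shift = fit_scale(avg[NEUN_CHANNEL], reference_neun)
    out: dict[str, float] = {"scale": scale, "shift": float(shift)}
    for ch, prof in avg.channels.items():
        if ch == NEUN_CHANNEL:
            continue
        out[ch] = per_column_estimate(prof.shifted(shift), scale)
    return out
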