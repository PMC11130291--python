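"""Peak-reference construction and intensity normalization.

Multi-sample MSI acquisitions yield per-sample m/z axes that drift slightly
against each other.  A common peak reference is built by (1) averaging the
per-sample axes, (2) picking peaks on each sample's mean spectrum at a
required signal-to-noise ratio, (3) mapping every picked peak back onto the
mean axis by binary search, and (4) averaging the peaks that land in the same
bin.  Bins can optionally be required to collect a minimum number of
per-sample peaks, which summarizes inter-sample mass shifts; with a minimum
of 1 the shifts are deliberately retained as near-duplicate channels.

Pixel spectra are normalized by total ion count (TIC) and channels are put on
a common scale across samples with a per-m/z global scaling factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import argrelextrema

log = logging.getLogger(__name__)

#: Instrument channel spacing on the m/z axis (TOF raster used throughout).
MZ_GRID_SPACING = 0.0487


@dataclass
class MzAxis:
    """A strictly increasing m/z axis."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) == 0:
            raise ValueError("m/z axis must be a nonempty 1-D array")
        if not np.all(np.diff(self.values) > 0):
            raise ValueError("m/z axis must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class PeakReference:
    """Common peak reference: bin-mean m/z values and contribution counts."""

    peaks: np.ndarray
    bin_counts: np.ndarray

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=float)
        self.bin_counts = np.asarray(self.bin_counts, dtype=int)
        if len(self.peaks) != len(self.bin_counts):
            raise ValueError("peaks and bin_counts length mismatch")
        if len(self.peaks) and not np.all(np.diff(self.peaks) > 0):
            raise ValueError("reference peaks must be strictly increasing")
        if np.any(self.bin_counts < 1):
            raise ValueError("bin_counts must be >= 1")

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class IntensityCube:
    """One sample's H x W x P grid of peak intensities.

    ``mz`` labels the P channels; ``background_mask`` is True outside tissue.
    Background pixels carry all-zero intensities.
    """

    sample_id: str
    mz: np.ndarray
    intensities: np.ndarray
    background_mask: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.background_mask = np.asarray(self.background_mask, dtype=bool)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be H x W x P")
        h, w, p = self.intensities.shape
        if self.background_mask.shape != (h, w):
            raise ValueError("background_mask shape mismatch")
        if len(self.mz) != p:
            raise ValueError("mz labels must match channel count")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def tissue_mask(self) -> np.ndarray:
        return ~self.background_mask

    def copy(self) -> "IntensityCube":
        return IntensityCube(
            sample_id=self.sample_id,
            mz=self.mz.copy(),
            intensities=self.intensities.copy(),
            background_mask=self.background_mask.copy(),
        )


def mean_mz_axis(axes: list[MzAxis]) -> MzAxis:
    """Element-wise mean of equally long per-sample m/z axes."""
    if not axes:
        raise ValueError("need at least one axis")
    n = len(axes[0])
    if any(len(a) != n for a in axes):
        raise ValueError("all m/z axes must have the same length")
    return MzAxis(np.mean([a.values for a in axes], axis=0))


def estimate_noise(spectrum: np.ndarray) -> float:
    """Robust noise scale: 1.4826 * MAD of the first difference.

    The first difference removes slowly varying baseline/peak structure so the
    median absolute deviation reflects the channel-to-channel noise floor.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    d = np.diff(spectrum)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad)


def pick_peaks(axis: MzAxis, spectrum: np.ndarray, snr: float = 6.0) -> np.ndarray:
    """Local maxima of a mean spectrum with amplitude/noise >= ``snr``.

    Returns the m/z positions of retained peaks; sub-threshold maxima are
    treated as noise and dropped.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.size == 0:
        raise ValueError("empty spectrum")
    if spectrum.shape != (len(axis),):
        raise ValueError("spectrum must match the m/z axis")
    if not np.all(np.isfinite(spectrum)):
        raise ValueError("spectrum must be finite")
    (idx,) = argrelextrema(spectrum, np.greater)
    if idx.size == 0:
        return np.empty(0, dtype=float)
    noise = estimate_noise(spectrum)
    if noise <= 0:
        # noiseless fixture: every strict local maximum qualifies
        return axis.values[idx]
    keep = spectrum[idx] / noise >= snr
    return axis.values[idx[keep]]


def map_peaks_to_bins(peaks: np.ndarray, grid: MzAxis) -> np.ndarray:
    """Assign each peak to the nearest grid value by binary search.

    Equidistant ties go to the lower index for determinism.
    """
    peaks = np.asarray(peaks, dtype=float)
    g = grid.values
    right = np.searchsorted(g, peaks, side="left")
    right = np.clip(right, 0, len(g) - 1)
    left = np.clip(right - 1, 0, len(g) - 1)
    # tie (equal distance) -> lower index, hence strict '<' for the right side
    choose_right = np.abs(g[right] - peaks) < np.abs(peaks - g[left])
    return np.where(choose_right, right, left)


def consolidate_bins(
    assignments: np.ndarray,
    sample_peak_mzs: np.ndarray,
    min_assignments: int = 1,
) -> PeakReference:
    """Average same-bin peaks into reference peaks, filtering sparse bins.

    ``assignments`` and ``sample_peak_mzs`` are parallel arrays pooled over
    all samples (one entry per picked peak).  Bins collecting fewer than
    ``min_assignments`` peaks are dropped.
    """
    if min_assignments < 1:
        raise ValueError("min_assignments must be >= 1")
    assignments = np.asarray(assignments, dtype=int)
    sample_peak_mzs = np.asarray(sample_peak_mzs, dtype=float)
    if assignments.shape != sample_peak_mzs.shape:
        raise ValueError("assignments and peak m/z arrays must align")
    peaks, counts = [], []
    for b in np.unique(assignments):
        members = sample_peak_mzs[assignments == b]
        if len(members) >= min_assignments:
            peaks.append(members.mean())
            counts.append(len(members))
    order = np.argsort(peaks)
    return PeakReference(np.asarray(peaks)[order], np.asarray(counts)[order])


def build_peak_reference(
    axes: list[MzAxis],
    mean_spectra: list[np.ndarray],
    snr: float = 6.0,
    min_assignments: int = 1,
) -> PeakReference:
    """Full reference-building chain over all samples."""
    grid = mean_mz_axis(axes)
    all_assignments, all_peaks = [], []
    for axis, spec in zip(axes, mean_spectra, strict=True):
        peaks = pick_peaks(axis, spec, snr=snr)
        all_peaks.append(peaks)
        all_assignments.append(map_peaks_to_bins(peaks, grid))
    return consolidate_bins(
        np.concatenate(all_assignments),
        np.concatenate(all_peaks),
        min_assignments=min_assignments,
    )


def tic_normalize(cube: IntensityCube) -> IntensityCube:
    """Divide every tissue pixel's spectrum by its total ion count.

    Tissue pixels with zero TIC cannot be normalized; they are reclassified
    as background (and logged), mirroring the background-discard rule.
    """
    out = cube.copy()
    tic = out.intensities.sum(axis=2)
    tissue = out.tissue_mask
    dead = tissue & (tic <= 0)
    if np.any(dead):
        log.warning(
            "sample %s: %d tissue pixel(s) with zero TIC reclassified as background",
            cube.sample_id,
            int(dead.sum()),
        )
        out.background_mask = out.background_mask | dead
        tissue = out.tissue_mask
    safe = np.where(tic > 0, tic, 1.0)
    out.intensities = np.where(tissue[..., None], out.intensities / safe[..., None], 0.0)
    return out


def global_scale(cubes: list[IntensityCube]) -> list[IntensityCube]:
    """Per-m/z global scaling factor equalizing tissue means across samples.

    Each sample's channel is multiplied by (grand tissue mean over all
    samples) / (that sample's tissue mean); channels with a zero sample mean
    are left untouched.
    """
    if not cubes:
        return []
    sample_means = np.stack(
        [c.intensities[c.tissue_mask].mean(axis=0) for c in cubes]
    )  # S x P
    grand = sample_means.mean(axis=0)
    out = []
    for c, means in zip(cubes, sample_means):
        factors = np.where(means > 0, grand / np.where(means > 0, means, 1.0), 1.0)
        cc = c.copy()
        cc.intensities = cc.intensities * factors[None, None, :]
        out.append(cc)
    return out
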