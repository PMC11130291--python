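"""Match hypoxia-associated MSI m/z values to tandem-MS peptide masses.

MALDI ions are predominantly singly charged, so an MSI m/z converts to a
mass by subtracting one proton: mass = m/z - 1.  Because the true mass of a
TOF peak is uncertain, each associated peak gets a tolerance window that
combines two errors:

* a *standard error* from the peak's full width at half maximum (FWHM),
  computed per sample and combined as the envelope (outermost half-maximum
  points over samples);
* a *minimal technical error* of one channel spacing (0.0487 m/z) either
  side of the peak.

The window is the intersection of the two: lower bound = max(envelope lower,
technical lower), upper bound = min(envelope upper, technical upper), both
shifted by -1 onto the mass scale.  A tandem-MS peptide matches a peak when
its monoisotopic mass falls inside the window (inclusive).  Cysteine-
containing sequences are excluded beforehand as a proxy for modified
peptides.  Proteins with at least two *distinct* matched MSI masses — mass-
shift replicates collapsed into one — whose ion images mutually correlate
(Spearman > 0.80) become peptide candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .preproc import MZ_GRID_SPACING, IntensityCube, MzAxis

log = logging.getLogger(__name__)


@dataclass
class MassWindow:
    """Combined FWHM/technical tolerance window for one MSI peak."""

    peak_mz: float
    half_max_points: list[tuple[float, float]]
    technical_points: tuple[float, float]
    mass_min: float
    mass_max: float

    @property
    def msi_mass(self) -> float:
        return self.peak_mz - 1.0

    @property
    def empty(self) -> bool:
        return self.mass_min > self.mass_max


@dataclass
class PeptideCandidate:
    proteins: str
    gene_names: str
    matched_pairs: list[tuple[float, float]]  # (msi_mass, msms_mass)
    pair_correlations: list[float]
    distinct_count: int
    exemplary_pair: tuple[float, float]  # (mass 1, mass 2): one msms mass per group


def msi_mass(mz: float) -> float:
    """Singly charged mass: m/z * 1 - 1 (one proton)."""
    if mz <= 1.0:
        raise ValueError("m/z must exceed 1 for a singly charged ion")
    return float(mz) - 1.0


def technical_points(peak_mz: float, delta: float = MZ_GRID_SPACING) -> tuple[float, float]:
    """Symmetric minimal technical window of one channel spacing."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    return (peak_mz - delta, peak_mz + delta)


def fwhm_points(
    peak_mz: float, axis: MzAxis, spectrum: np.ndarray
) -> tuple[float, float]:
    """Left/right half-maximum crossings of a peak, linearly interpolated.

    The peak must be a local maximum of the spectrum (the nearest axis point
    to ``peak_mz`` is used).  If a flank never crosses half maximum before
    the axis ends, the window is truncated at the axis bound (logged).
    """
    x = axis.values
    y = np.asarray(spectrum, dtype=float)
    if y.shape != x.shape:
        raise ValueError("spectrum must match the m/z axis")
    pi = int(np.argmin(np.abs(x - peak_mz)))
    half = y[pi] / 2.0

    def _walk(direction: int) -> float:
        i = pi
        while 0 <= i + direction < len(y):
            j = i + direction
            if y[j] < half:
                # linear interpolation between the last point >= half and j
                frac = (y[i] - half) / (y[i] - y[j])
                return float(x[i] + frac * (x[j] - x[i]))
            i = j
        log.info("FWHM flank of peak %.4f truncated at the axis bound", peak_mz)
        return float(x[0] if direction < 0 else x[-1])

    return (_walk(-1), _walk(+1))


def combine_window(
    peak_mz: float,
    half_max_points: list[tuple[float, float]],
    delta: float = MZ_GRID_SPACING,
) -> MassWindow:
    """Clamp the per-sample half-maximum envelope by the technical window.

    mass_min = max(min_i lower_i, peak - delta) - 1 and
    mass_max = min(max_i upper_i, peak + delta) - 1; the -1 applies the
    singly-charged transformation (an affine shift commutes with min/max).
    """
    if not half_max_points:
        raise ValueError("need at least one sample's half-maximum points")
    tp = technical_points(peak_mz, delta)
    lo = max(min(p[0] for p in half_max_points), tp[0]) - 1.0
    hi = min(max(p[1] for p in half_max_points), tp[1]) - 1.0
    win = MassWindow(
        peak_mz=float(peak_mz),
        half_max_points=[(float(a), float(b)) for a, b in half_max_points],
        technical_points=tp,
        mass_min=lo,
        mass_max=hi,
    )
    if win.empty:
        log.warning("peak %.4f produced an empty mass window", peak_mz)
    return win


def windows_from_spectra(
    peak_mzs: np.ndarray,
    axes: list[MzAxis],
    spectra: list[np.ndarray],
    delta: float = MZ_GRID_SPACING,
) -> list[MassWindow]:
    """Per-peak combined windows from per-sample mean spectra."""
    windows = []
    for pm in np.asarray(peak_mzs, dtype=float):
        hm = [fwhm_points(pm, ax, sp) for ax, sp in zip(axes, spectra, strict=True)]
        windows.append(combine_window(pm, hm, delta))
    return windows


def filter_modified(peptides: pd.DataFrame) -> pd.DataFrame:
    """Drop cysteine-containing sequences (proxy for modified peptides)."""
    return peptides[~peptides["Sequence"].str.contains("C")].reset_index(drop=True)


def match_masses(windows: list[MassWindow], peptides: pd.DataFrame) -> pd.DataFrame:
    """Inclusive interval matching of peptide masses against mass windows.

    ``peptides`` must already be filtered for modified sequences.  Returns a
    long-format table with one row per (window, peptide) pair.
    """
    masses = peptides["Mass"].to_numpy(dtype=float)
    order = np.argsort(masses)
    sorted_masses = masses[order]
    rows = []
    for w in windows:
        if w.empty:
            continue
        lo = np.searchsorted(sorted_masses, w.mass_min, side="left")
        hi = np.searchsorted(sorted_masses, w.mass_max, side="right")
        for oi in order[lo:hi]:
            rec = peptides.iloc[oi]
            rows.append(
                {
                    "peak_mz": w.peak_mz,
                    "msi_mass": w.msi_mass,
                    "mass_min": w.mass_min,
                    "mass_max": w.mass_max,
                    "Sequence": rec["Sequence"],
                    "Proteins": rec["Proteins"],
                    "Gene names": rec["Gene names"],
                    "Mass": float(rec["Mass"]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "peak_mz", "msi_mass", "mass_min", "mass_max",
            "Sequence", "Proteins", "Gene names", "Mass",
        ],
    )


def ion_image_vectors(
    cubes: list[IntensityCube], mz_values: np.ndarray
) -> dict[float, np.ndarray]:
    """Concatenated tissue-pixel intensities per m/z over all samples."""
    out: dict[float, np.ndarray] = {}
    for mz in np.asarray(mz_values, dtype=float):
        parts = []
        for cube in cubes:
            ci = int(np.argmin(np.abs(cube.mz - mz)))
            parts.append(cube.intensities[cube.tissue_mask][:, ci])
        out[float(mz)] = np.concatenate(parts)
    return out


def _windows_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


#: peaks further apart than this are never mass-shift replicates of each
#: other (drift spans at most a few channel spacings; isotopes at +1.003
#: must stay distinct)
_SHIFT_NEIGHBORHOOD = 3 * MZ_GRID_SPACING


def _mass_shift_groups(
    peaks: list[dict],
    ion_images: dict[float, np.ndarray],
    replicate_r: float,
) -> list[list[dict]]:
    """Union-find grouping of matched peaks into mass-shift groups.

    Two peaks are the same underlying mass when their combined windows
    overlap, or when they sit within a few channel spacings of each other
    and their ion images are near-duplicates (Pearson r > ``replicate_r``).
    The proximity condition keeps distinct peptides with genuinely similar
    spatial distributions (the interesting case for candidate calling) from
    collapsing into one group.
    """
    n = len(peaks)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = peaks[i], peaks[j]
            same = _windows_overlap(
                (a["mass_min"], a["mass_max"]), (b["mass_min"], b["mass_max"])
            )
            if not same and abs(a["peak_mz"] - b["peak_mz"]) <= _SHIFT_NEIGHBORHOOD:
                ia = ion_images.get(a["peak_mz"])
                ib = ion_images.get(b["peak_mz"])
                if ia is not None and ib is not None and np.ptp(ia) > 0 and np.ptp(ib) > 0:
                    same = pearsonr(ia, ib).statistic > replicate_r
            if same:
                parent[find(i)] = find(j)
    groups: dict[int, list[dict]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(peaks[i])
    return list(groups.values())


def call_candidates(
    matches: pd.DataFrame,
    ion_images: dict[float, np.ndarray],
    min_distinct: int = 2,
    corr_cutoff: float = 0.80,
    replicate_r: float = 0.975,
) -> list[PeptideCandidate]:
    """Emit protein-level peptide candidates from the match table.

    Matched MSI peaks of a protein are collapsed into mass-shift groups
    (overlapping windows or ion-image Pearson r > ``replicate_r``); a
    candidate needs >= ``min_distinct`` groups whose exemplary ion images
    pairwise exceed the Spearman ``corr_cutoff``.  One exemplary mass pair
    per candidate is reported.
    """
    candidates: list[PeptideCandidate] = []
    if matches.empty:
        return candidates
    for protein, sub in matches.groupby("Proteins", sort=True):
        peak_records = [
            dict(
                peak_mz=pm,
                mass_min=g["mass_min"].iloc[0],
                mass_max=g["mass_max"].iloc[0],
                msms=g["Mass"].tolist(),
                msi_mass=g["msi_mass"].iloc[0],
            )
            for pm, g in sub.groupby("peak_mz")
        ]
        groups = _mass_shift_groups(peak_records, ion_images, replicate_r)
        groups.sort(key=lambda g: min(p["peak_mz"] for p in g))
        # exemplar per group: the lowest-m/z member with a usable ion image
        exemplars = []
        for g in groups:
            g = sorted(g, key=lambda p: p["peak_mz"])
            img = ion_images.get(g[0]["peak_mz"])
            exemplars.append((g, img))
        # greedily keep groups whose exemplar images mutually correlate
        kept: list[tuple[dict, np.ndarray]] = []
        correlations: list[float] = []
        for g, img in exemplars:
            if img is None or np.ptp(img) == 0:
                continue
            rhos = [spearmanr(img, kimg).statistic for _, kimg in kept]
            if all(r > corr_cutoff for r in rhos):
                kept.append((g[0], img))
                correlations.extend(rhos)
        if len(kept) < min_distinct:
            continue
        pairs = [
            (p["msi_mass"], m) for p, _ in kept for m in p["msms"]
        ]
        candidates.append(
            PeptideCandidate(
                proteins=str(protein),
                gene_names=str(sub["Gene names"].iloc[0]),
                matched_pairs=pairs,
                pair_correlations=correlations,
                distinct_count=len(kept),
                exemplary_pair=(kept[0][0]["msms"][0], kept[1][0]["msms"][0]),
            )
        )
    return candidates


def candidates_to_frame(candidates: list[PeptideCandidate]) -> pd.DataFrame:
    """Candidate table mirroring the published layout."""
    return pd.DataFrame(
        {
            "Protein(s)": [c.proteins for c in candidates],
            "Gene name(s)": [c.gene_names for c in candidates],
            "Mass 1": [c.exemplary_pair[0] for c in candidates],
            "Mass 2": [c.exemplary_pair[1] for c in candidates],
            "Distinct masses": [c.distinct_count for c in candidates],
        }
    )
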