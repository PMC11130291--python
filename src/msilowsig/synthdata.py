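"""Seeded synthetic multi-sample MSI datasets with known ground truth.

The generator emulates the structure of a multi-sample MALDI-TOF peptide
imaging experiment paired with a co-registered hypoxia annotation:

* an elliptical tissue mask per sample, with background pixels outside;
* a sparse, smooth annotation field in [0,1] built from Gaussian blobs,
  mimicking focal pimonidazole-positive regions;
* a small family of *signal* channels whose intensity is linearly coupled to
  the annotation, kept low-abundant relative to the rest (tissue-mean ratio
  ``signal_abundance_ratio``, default 0.2);
* isotope ladders for every signal channel (+~1.003 m/z per isotope with
  decaying intensity) and near-duplicate mass-shift replicate channels
  (+~0.03 m/z, inter-channel Pearson r > 0.975) — the redundancy that makes
  impurity-based feature ranking unstable on real data;
* high-abundance confounder channels driven by smooth per-sample morphology
  fields that are independent of the annotation;
* a handful of channels *negatively* coupled to the annotation (peptides
  depleted in hypoxic regions, e.g. proliferation markers) — discriminative
  for a regression model yet dissimilar to the induced signal group, the
  behavior that separates impurity-based selection from latent-feature
  recovery;
* a tandem-MS style peptide table whose matchable peptides sit inside the
  mass windows of planted channels and whose decoys are kept well away.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .patching import AnnotationImage
from .preproc import MZ_GRID_SPACING, IntensityCube

_AMINO_ACIDS = "ADEFGHIKLMNPQRSTVWY"  # note: no C (reserved for the exclusion rule)
_ISOTOPE_DECAY = 0.6
_N_MORPHOLOGY_FIELDS = 6
_SIGNAL_BASELINE = 0.3


@dataclass
class SynthConfig:
    n_samples: int = 5
    grid_h: int = 40
    grid_w: int = 40
    n_channels: int = 300
    mz_min: float = 600.0
    mz_max: float = 3200.0
    n_signal_channels: int = 4
    signal_effect: float = 1.0
    signal_abundance_ratio: float = 0.2
    n_isotopes_per_signal: int = 1
    isotope_spacing: float = 1.003
    n_replicates_per_signal: int = 1
    replicate_shift: float = 0.03
    noise_sd: float = 0.06
    basal_amplitude: float = 0.25
    n_morphology_channels: int = 60
    n_anti_channels: int = 6
    anti_effect: float = 0.5
    noise_cv: float = 0.5
    annotation_blob_count: int = 5
    annotation_blob_scale: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mz_min >= self.mz_max:
            raise ValueError("mz_min must be below mz_max")
        if not (0 < self.signal_abundance_ratio <= 1):
            raise ValueError("signal_abundance_ratio must lie in (0, 1]")
        for name in (
            "n_samples", "n_channels", "n_signal_channels",
            "n_isotopes_per_signal", "n_replicates_per_signal",
            "n_anti_channels", "annotation_blob_count",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_channels < self.n_planted + self.n_anti_channels:
            raise ValueError(
                f"n_channels={self.n_channels} cannot hold "
                f"{self.n_planted} planted plus "
                f"{self.n_anti_channels} anti-correlated channels"
            )

    @property
    def n_planted(self) -> int:
        return self.n_signal_channels * (
            1 + self.n_isotopes_per_signal + self.n_replicates_per_signal
        )


@dataclass
class GroundTruth:
    """What was planted: used to score recovery and candidate calling."""

    signal_mz: np.ndarray
    base_signal_mz: np.ndarray
    confounder_mz: np.ndarray
    replicate_groups: list[list[float]]
    true_peptides: list[tuple[str, float, bool]] = field(default_factory=list)
    #: negatively annotation-coupled channels (subset of confounder_mz — they
    #: are not a recovery target, but impurity importance will rank them)
    anti_signal_mz: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if set(np.round(self.signal_mz, 9)) & set(np.round(self.confounder_mz, 9)):
            raise ValueError("signal and confounder m/z sets overlap")
        if any(len(g) == 0 for g in self.replicate_groups):
            raise ValueError("empty replicate group")


def _tissue_mask(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    rr, cc = np.mgrid[0:h, 0:w]
    cy, cx = h / 2 + rng.uniform(-1, 1), w / 2 + rng.uniform(-1, 1)
    ry = h * rng.uniform(0.38, 0.44)
    rx = w * rng.uniform(0.40, 0.46)
    return ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0


def _annotation_field(
    mask: np.ndarray, cfg: SynthConfig, rng: np.random.Generator
) -> np.ndarray:
    h, w = mask.shape
    ann = np.zeros((h, w))
    tissue_idx = np.argwhere(mask)
    if len(tissue_idx) == 0 or cfg.annotation_blob_count == 0:
        return ann
    rr, cc = np.mgrid[0:h, 0:w]
    for _ in range(cfg.annotation_blob_count):
        y, x = tissue_idx[rng.integers(len(tissue_idx))]
        amp = rng.uniform(0.5, 1.0)
        sigma = cfg.annotation_blob_scale * rng.uniform(0.7, 1.3)
        ann += amp * np.exp(-((rr - y) ** 2 + (cc - x) ** 2) / (2 * sigma**2))
    ann = np.clip(ann, 0.0, 1.0)
    ann[~mask] = 0.0
    return ann


def _morphology_fields(
    mask: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    h, w = mask.shape
    fields = np.empty((_N_MORPHOLOGY_FIELDS, h, w))
    for i in range(_N_MORPHOLOGY_FIELDS):
        f = gaussian_filter(rng.standard_normal((h, w)), sigma=min(h, w) / 7)
        lo, hi = f[mask].min(), f[mask].max()
        fields[i] = (f - lo) / (hi - lo) if hi > lo else 0.0
    return fields


def _draw_mz_positions(cfg: SynthConfig, rng: np.random.Generator):
    """Channel m/z layout: bases + confounders on the instrument grid,
    isotopes/replicates at their physical offsets from the bases."""
    n_grid = int(np.floor((cfg.mz_max - cfg.mz_min) / MZ_GRID_SPACING)) + 1
    grid = cfg.mz_min + MZ_GRID_SPACING * np.arange(n_grid)
    n_conf = cfg.n_channels - cfg.n_planted - cfg.n_anti_channels
    for _ in range(100):
        picks = rng.choice(
            n_grid,
            size=cfg.n_signal_channels + cfg.n_anti_channels + n_conf,
            replace=False,
        )
        base_mz = np.sort(grid[picks[: cfg.n_signal_channels]])
        anti_mz = np.sort(
            grid[picks[cfg.n_signal_channels : cfg.n_signal_channels + cfg.n_anti_channels]]
        )
        conf_mz = np.sort(grid[picks[cfg.n_signal_channels + cfg.n_anti_channels :]])
        iso_mz = {
            (s, k): base_mz[s] + k * cfg.isotope_spacing
            for s in range(cfg.n_signal_channels)
            for k in range(1, cfg.n_isotopes_per_signal + 1)
        }
        rep_mz = {
            (s, r): base_mz[s] + r * cfg.replicate_shift
            for s in range(cfg.n_signal_channels)
            for r in range(1, cfg.n_replicates_per_signal + 1)
        }
        everything = np.concatenate(
            [base_mz, anti_mz, conf_mz, list(iso_mz.values()), list(rep_mz.values())]
        )
        if np.min(np.diff(np.sort(everything)), initial=np.inf) > 1e-4 and (
            everything.max() <= cfg.mz_max
        ):
            return base_mz, anti_mz, conf_mz, iso_mz, rep_mz
    raise RuntimeError("could not place channels without collisions")


def generate_dataset(
    config: SynthConfig,
) -> tuple[list[IntensityCube], list[AnnotationImage], GroundTruth]:
    """Generate per-sample cubes, annotations, and the planted ground truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    base_mz, anti_mz, conf_mz, iso_mz, rep_mz = _draw_mz_positions(cfg, rng)

    # assemble sorted channel axis with roles
    entries = [("signal", m, ("base", s)) for s, m in enumerate(base_mz)]
    entries += [("anti", m, ("anti", j)) for j, m in enumerate(anti_mz)]
    entries += [("confounder", m, ("conf", j)) for j, m in enumerate(conf_mz)]
    entries += [("signal", m, ("iso", s, k)) for (s, k), m in iso_mz.items()]
    entries += [("signal", m, ("rep", s, r)) for (s, r), m in rep_mz.items()]
    entries.sort(key=lambda e: e[1])
    mz = np.array([e[1] for e in entries])
    roles = [e[2] for e in entries]

    # confounder channels fall into two classes, mirroring real TOF peptide
    # imaging: a minority of high-abundance channels with clear
    # morphology-driven structure, and a majority of speckle channels whose
    # pixel (shot) noise dominates any weak structure
    n_conf = len(conf_mz)
    n_morph = min(cfg.n_morphology_channels, n_conf)
    is_morph = np.zeros(n_conf, dtype=bool)
    is_morph[rng.choice(n_conf, size=n_morph, replace=False)] = True
    # speckle channels keep a weak structural coupling: real peptide channels
    # are never isolated independent variables, they correlate with tissue
    # structure at varying strength while staying shot-noise dominated
    conf_baseline = np.where(
        is_morph, rng.uniform(0.3, 1.0, n_conf), rng.uniform(0.05, 0.5, n_conf)
    )
    conf_coeff = np.where(
        is_morph, rng.uniform(0.4, 1.0, n_conf), rng.uniform(0.0, 0.15, n_conf)
    )
    conf_field = rng.integers(0, _N_MORPHOLOGY_FIELDS, size=n_conf)
    anti_baseline = rng.uniform(0.55, 0.9, size=cfg.n_anti_channels)
    # ionization efficiency is a property of the peptide: one gain per channel
    signal_gains = rng.uniform(0.7, 1.3, size=cfg.n_signal_channels)

    cubes_raw: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    annotations: list[AnnotationImage] = []
    for s in range(cfg.n_samples):
        sample_id = f"sample{s + 1}"
        mask = _tissue_mask(cfg.grid_h, cfg.grid_w, rng)
        ann = _annotation_field(mask, cfg, rng)
        fields = _morphology_fields(mask, rng)
        h, w = mask.shape
        cube = np.zeros((h, w, cfg.n_channels))

        # bases are paired into synthetic proteins (tryptic peptides of one
        # protein share the protein's full abundance image): each pair gets a
        # shared smooth basal field on top of the annotation coupling
        n_proteins = (cfg.n_signal_channels + 1) // 2
        basal = [
            gaussian_filter(rng.standard_normal((h, w)), sigma=min(h, w) / 7)
            for _ in range(n_proteins)
        ]
        basal = [
            (f - f[mask].min()) / max(f[mask].max() - f[mask].min(), 1e-12)
            for f in basal
        ]
        base_clean = {
            b: signal_gains[b]
            * (
                _SIGNAL_BASELINE
                + cfg.basal_amplitude * basal[b // 2]
                + cfg.signal_effect * ann
            )
            for b in range(cfg.n_signal_channels)
        }
        base_measured: dict[int, np.ndarray] = {}
        # base and isotope channels first (replicates copy the measured base)
        for ci, role in enumerate(roles):
            kind = role[0]
            if kind == "base":
                ch = base_clean[role[1]] + rng.normal(0, cfg.noise_sd, (h, w))
                base_measured[role[1]] = ch
            elif kind == "iso":
                _, b, k = role
                ch = _ISOTOPE_DECAY**k * base_clean[b] + rng.normal(
                    0, cfg.noise_sd * _ISOTOPE_DECAY**k, (h, w)
                )
            elif kind == "anti":
                # hypoxia-depleted peptide: high baseline, negative coupling
                base_level = anti_baseline[role[1]]
                ch = (
                    base_level
                    - cfg.anti_effect * ann
                    + rng.normal(0, cfg.noise_sd, (h, w))
                )
            elif kind == "conf":
                j = role[1]
                clean = conf_baseline[j] + conf_coeff[j] * fields[conf_field[j]]
                # counts-like: pixel noise proportional to local intensity
                ch = clean + rng.normal(0, 1, (h, w)) * cfg.noise_cv * clean
            else:
                continue
            cube[:, :, ci] = ch
        for ci, role in enumerate(roles):
            if role[0] == "rep":
                src = base_measured[role[1]]
                sd = 0.1 * src[mask].std()
                cube[:, :, ci] = src + rng.normal(0, sd, (h, w))
        cube = np.clip(cube, 0.0, None)
        cube[~mask] = 0.0
        cubes_raw.append(cube)
        masks.append(mask)
        annotations.append(AnnotationImage(sample_id, ann))

    # enforce the abundance contract: mean planted intensity over tissue is
    # signal_abundance_ratio times the mean confounder intensity
    signal_cols = [i for i, r in enumerate(roles) if r[0] in ("base", "iso", "rep")]
    conf_cols = [i for i, r in enumerate(roles) if r[0] == "conf"]
    sig_vals = np.concatenate(
        [c[m][:, signal_cols].ravel() for c, m in zip(cubes_raw, masks)]
    )
    if conf_cols:
        conf_vals = np.concatenate(
            [c[m][:, conf_cols].ravel() for c, m in zip(cubes_raw, masks)]
        )
        target = cfg.signal_abundance_ratio * conf_vals.mean()
        factor = target / sig_vals.mean() if sig_vals.size and sig_vals.mean() > 0 else 1.0
        for c in cubes_raw:
            c[:, :, signal_cols] *= factor

    cubes = [
        IntensityCube(
            sample_id=f"sample{s + 1}",
            mz=mz,
            intensities=cubes_raw[s],
            background_mask=~masks[s],
        )
        for s in range(cfg.n_samples)
    ]

    replicate_groups = [
        [float(base_mz[s])]
        + [float(rep_mz[(s, r)]) for r in range(1, cfg.n_replicates_per_signal + 1)]
        for s in range(cfg.n_signal_channels)
    ] + [[float(m)] for m in iso_mz.values()]
    non_signal_cols = [i for i, r in enumerate(roles) if r[0] in ("conf", "anti")]
    truth = GroundTruth(
        signal_mz=np.array(sorted(mz[signal_cols])),
        base_signal_mz=base_mz,
        confounder_mz=np.array(sorted(mz[non_signal_cols])),
        replicate_groups=replicate_groups,
        anti_signal_mz=anti_mz,
    )
    return cubes, annotations, truth


def _random_sequence(rng: np.random.Generator, with_c: bool = False) -> str:
    n = int(rng.integers(8, 15))
    seq = "".join(rng.choice(list(_AMINO_ACIDS), size=n))
    if with_c:
        pos = int(rng.integers(0, n))
        seq = seq[:pos] + "C" + seq[pos + 1 :]
    return seq


def generate_peptide_table(
    truth: GroundTruth,
    n_decoys: int = 20,
    seed: int = 0,
    mass_jitter_sd: float = 0.005,
) -> pd.DataFrame:
    """Tandem-MS style peptide table (Sequence, Proteins, Gene names, Mass).

    Matchable peptides take the singly-charged mass of a planted base signal
    channel (m/z - 1) plus a small jitter well inside the technical error.
    Base channels are paired into synthetic proteins the same way the
    generator pairs their abundance images, so every fully paired protein
    has two distinct matchable masses with correlated ion images.  Decoy
    masses are rejected until they are at least 3 technical errors away from
    every planted channel.  One cysteine-containing row exercises the
    modified-peptide exclusion rule.  Also records (sequence, mass,
    is_matchable) rows in ``truth.true_peptides``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth.true_peptides = []
    bases = np.asarray(truth.base_signal_mz, dtype=float)
    for p in range((len(bases) + 1) // 2):
        protein, gene = f"SYNPROT{p + 1}", f"SYNG{p + 1}"
        for base in bases[2 * p : 2 * p + 2]:
            jitter = float(np.clip(rng.normal(0, mass_jitter_sd), -0.01, 0.01))
            mass = base - 1.0 + jitter
            seq = _random_sequence(rng)
            rows.append((seq, protein, gene, mass))
            truth.true_peptides.append((seq, mass, True))

    # decoys stay clear of every channel's possible window, confounders included
    planted = np.concatenate([truth.signal_mz, truth.confounder_mz]) - 1.0
    min_dist = 3 * MZ_GRID_SPACING
    lo = float(min(truth.signal_mz.min(), truth.confounder_mz.min()) - 1.0) \
        if len(truth.confounder_mz) else float(planted.min())
    hi = float(max(truth.signal_mz.max(), truth.confounder_mz.max()) - 1.0) \
        if len(truth.confounder_mz) else float(planted.max()) + 50.0
    for d in range(n_decoys):
        for _ in range(1000):
            mass = float(rng.uniform(lo, hi))
            if planted.size == 0 or np.min(np.abs(planted - mass)) >= min_dist:
                break
        seq = _random_sequence(rng)
        rows.append((seq, f"DECOYPROT{d + 1}", f"DECG{d + 1}", mass))
        truth.true_peptides.append((seq, mass, False))

    # mandatory cysteine-containing row: would match a planted window but must
    # be excluded by the "C" rule
    c_seq = _random_sequence(rng, with_c=True)
    c_mass = float(bases[0] - 1.0) if len(bases) else float(rng.uniform(lo, hi))
    rows.append((c_seq, "CYSPROT1", "CYSG1", c_mass))
    truth.true_peptides.append((c_seq, c_mass, False))

    return pd.DataFrame(rows, columns=["Sequence", "Proteins", "Gene names", "Mass"])
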