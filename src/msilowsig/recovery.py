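"""Perturbation-based recovery of m/z channels behind a latent feature.

Because the autoencoder is shallow and spatially preserving, the encoded
image of a latent feature can be compared directly against original ion
images.  For one probed channel at a time, all *other* channels are set to
the constant 1 (the maximum of the [0,1] normalized scale) in every pixel,
the modified patches are encoded, and the latent feature's per-patch values
are rank-correlated (Spearman) with the per-patch means of the probed
channel's original ion image.  Channels genuinely encoded by the feature
produce near-perfect correlations; unrelated channels do not.  A channel is
recovered when its correlation exceeds a cutoff (default 0.95) in an
aggregate over samples (default: the minimum, the conservative choice).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .autoencoder import AEModel, encode
from .nn import BatchNorm, Conv1x1, ConvValid
from .patching import AnnotationImage, extract_patches
from .preproc import IntensityCube

log = logging.getLogger(__name__)


@dataclass
class RecoveryResult:
    """Per (m/z, sample) Spearman correlations and the associated set."""

    table: pd.DataFrame  # columns: mz, sample_id, rho
    cutoff: float
    recovered_mz: np.ndarray

    def aggregated(self, how: str = "min") -> pd.Series:
        agg = self.table.groupby("mz")["rho"].agg(how)
        return agg


def _cube_patches(cube: IntensityCube, patch_size: int, step: int) -> np.ndarray:
    """Background-filtered patches on the training extraction grid."""
    dummy = AnnotationImage(cube.sample_id, np.zeros(cube.background_mask.shape))
    ps = extract_patches(cube, dummy, patch_size=patch_size, step=step)
    return ps.patches


def encode_modified(
    model: AEModel,
    cube: IntensityCube,
    mz_index: int,
    latent_index: int | None = None,
    step: int = 2,
) -> np.ndarray:
    """Encode the cube with every channel but ``mz_index`` set to 1.

    Returns each patch's latent values averaged over the spatial latent
    pixels: shape (n_patches, z2), or (n_patches,) when ``latent_index`` is
    given.
    """
    p = cube.shape[2]
    if not (0 <= mz_index < p):
        raise ValueError(f"mz_index {mz_index} out of range for {p} channels")
    patches = _cube_patches(cube, model.config.patch_size, step)
    modified = np.ones_like(patches)
    modified[..., mz_index] = patches[..., mz_index]
    latent = encode(model, modified).mean(axis=(1, 2))
    if latent_index is not None:
        return latent[:, latent_index]
    return latent


def _inference_affine(bn: BatchNorm) -> tuple[np.ndarray, np.ndarray]:
    scale = bn.gamma / np.sqrt(bn.running_var + bn.eps)
    return scale, bn.beta - bn.running_mean * scale


def fast_modified_series(
    model: AEModel,
    patches: np.ndarray,
    mz_index: int,
    latent_index: int,
) -> np.ndarray:
    """Exact fast equivalent of ``encode_modified`` for one channel.

    With all other channels constant at 1, the first (pointwise) convolution
    is affine in the probed channel alone, so its output is a precomputed
    base row plus an outer product — avoiding the full channel contraction.
    ``patches``: the sample's original (n, p, p, P) patches on the recovery
    grid.  Returns the latent feature's per-patch mean, shape (n,).  Agrees
    with ``encode_modified`` up to float round-off (tested).
    """
    conv1: Conv1x1 = model.encoder.layers[0]
    bn1: BatchNorm = model.encoder.layers[1]
    conv2: ConvValid = model.encoder.layers[3]
    bn2: BatchNorm = model.encoder.layers[4]

    base = conv1.w.sum(axis=0) + conv1.b  # (z1,): response to all-ones input
    xk = patches[..., mz_index]  # (n, p, p)
    pre = base[None, None, None, :] + (xk - 1.0)[..., None] * conv1.w[mz_index]
    s1, t1 = _inference_affine(bn1)
    a = np.maximum(pre * s1 + t1, 0.0)

    # second convolution (valid, stride 1) + BN + ReLU
    k = conv2.k
    n, p = a.shape[0], a.shape[1]
    o = p - k + 1
    cols = np.empty((n, o, o, k, k, a.shape[-1]), dtype=a.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, :, i, j, :] = a[:, i : i + o, j : j + o, :]
    cols = cols.reshape(n, o, o, -1)
    s2, t2 = _inference_affine(bn2)
    if model.config.mode == "variational":
        # the mean head mixes all z2 channels, so the full code is needed
        code = np.maximum((cols @ conv2.w + conv2.b) * s2 + t2, 0.0)
        mu = model.mu_head.forward(code, training=False)
        feat = mu[..., latent_index]
    else:
        w_col = conv2.w[:, latent_index]
        pre2 = cols @ w_col + conv2.b[latent_index]
        feat = np.maximum(pre2 * s2[latent_index] + t2[latent_index], 0.0)
    return feat.mean(axis=(1, 2))


def recover_contributors(
    model: AEModel,
    cubes: list[IntensityCube],
    latent_index: int,
    cutoff: float = 0.95,
    step: int = 2,
    aggregate: str = "min",
    orientation: int = 1,
) -> tuple[np.ndarray, RecoveryResult]:
    """Spearman-correlate the probed latent feature against every channel.

    For each channel and sample, the per-patch latent series from the
    modified encoding is correlated with the per-patch mean of the original
    ion image over the same patch grid.  A channel is associated when the
    aggregated correlation (minimum over samples by default, mean optional)
    exceeds ``cutoff``.  Constant series make the correlation undefined; such
    (channel, sample) pairs are treated as non-associated.

    ``orientation`` handles latent features that encode the annotation with
    inverted polarity (a known behavior of impurity-ranked latent features,
    which are discriminative but not necessarily positively correlated):
    with ``orientation=-1`` the cutoff is applied to the negated
    correlations, so coherent negative detectors recover their contributors
    instead of returning nothing.  The default (+1) is the plain high-
    positive-correlation rule.
    """
    if not cubes:
        raise ValueError("need at least one cube")
    if aggregate not in ("min", "mean"):
        raise ValueError("aggregate must be 'min' or 'mean'")
    if orientation not in (1, -1):
        raise ValueError("orientation must be +1 or -1")
    n_channels = cubes[0].shape[2]
    records = []
    n_constant = 0
    for cube in cubes:
        patches = _cube_patches(cube, model.config.patch_size, step)
        ion_means = patches.mean(axis=(1, 2))  # (n_patches, P)
        for ci in range(n_channels):
            series = fast_modified_series(model, patches, ci, latent_index)
            if np.ptp(series) == 0 or np.ptp(ion_means[:, ci]) == 0:
                rho = np.nan
                n_constant += 1
            else:
                rho = spearmanr(series, ion_means[:, ci]).statistic
            records.append((float(cube.mz[ci]), cube.sample_id, rho))
    if n_constant:
        log.info(
            "latent feature %d: %d constant (channel, sample) series treated "
            "as non-associated",
            latent_index,
            n_constant,
        )
    table = pd.DataFrame(records, columns=["mz", "sample_id", "rho"])
    # an undefined (constant-series) sample counts as non-association for
    # that sample, so it must veto the channel under min aggregation —
    # replace before grouping because pandas aggregations skip NaN
    oriented = table.assign(rho=(orientation * table["rho"]).fillna(-2.0))
    agg = oriented.groupby("mz")["rho"].agg(aggregate)
    recovered = np.sort(agg.index[agg > cutoff].to_numpy())
    return recovered, RecoveryResult(table=table, cutoff=cutoff, recovered_mz=recovered)


def recovered_for_additional_features(
    model: AEModel,
    cubes: list[IntensityCube],
    latent_indices: list[int],
    cutoff: float = 0.95,
    step: int = 2,
    aggregate: str = "min",
) -> dict[int, np.ndarray]:
    """Recovered m/z sets for several latent features (overlap reporting)."""
    return {
        li: recover_contributors(model, cubes, li, cutoff, step, aggregate)[0]
        for li in latent_indices
    }
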