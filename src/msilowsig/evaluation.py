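"""Quantitative comparison machinery: SSIM, adjusted R2, group statistics.

Recovered/selected channel sets are compared by the structural similarity
(SSIM) of their ion images to a reference channel's image, per sample.
Distributions of scores are compared with two-sided Mann-Whitney U tests,
with Benjamini-Hochberg control of the false discovery rate at 5% across the
family, and annotated with the usual significance stars.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from skimage.metrics import structural_similarity
from statsmodels.stats.multitest import multipletests


@dataclass
class GroupComparison:
    table: pd.DataFrame  # columns: group_a, group_b, p_raw, p_adj, stars


def significance_stars(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def ssim_to_reference(
    ion_image: np.ndarray,
    reference_image: np.ndarray,
    tissue_mask: np.ndarray | None = None,
) -> float:
    """SSIM between two [0,1] ion images (7x7 uniform window, K1/K2 defaults).

    When a tissue mask is given, both images are cropped to the tissue
    bounding box so that the shared empty background does not inflate the
    score.
    """
    a = np.asarray(ion_image, dtype=float)
    b = np.asarray(reference_image, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if tissue_mask is not None:
        rows = np.any(tissue_mask, axis=1)
        cols = np.any(tissue_mask, axis=0)
        if rows.any():
            r0, r1 = np.flatnonzero(rows)[[0, -1]]
            c0, c1 = np.flatnonzero(cols)[[0, -1]]
            a = a[r0 : r1 + 1, c0 : c1 + 1]
            b = b[r0 : r1 + 1, c0 : c1 + 1]
    win = min(7, (min(a.shape) // 2) * 2 + 1)
    return float(
        structural_similarity(
            a, b, win_size=win, gaussian_weights=False, K1=0.01, K2=0.03,
            data_range=1.0,
        )
    )


def adjusted_r2(r2: float, n_obs: int, n_features: int) -> float:
    """R2 penalized for the number of features: 1-(1-R2)(n-1)/(n-p-1)."""
    if n_obs <= n_features + 1:
        raise ValueError("need n_obs > n_features + 1")
    return 1.0 - (1.0 - r2) * (n_obs - 1) / (n_obs - n_features - 1)


def mann_whitney_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact distribution for small tie-free samples (combined n <= 16), the
    tie-corrected normal approximation otherwise.  Two identical constant
    groups are a no-evidence case and return p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 observations")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 16 and not has_ties) else "asymptotic"
    return float(mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (FDR control)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def compare_groups(score_sets: dict[str, np.ndarray]) -> GroupComparison:
    """All pairwise two-sided Mann-Whitney U tests with BH adjustment."""
    labels = list(score_sets)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    pairs = [
        (labels[i], labels[j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    ]
    raw = np.array(
        [mann_whitney_p(score_sets[x], score_sets[y]) for x, y in pairs]
    )
    adj = benjamini_hochberg(raw)
    table = pd.DataFrame(
        {
            "group_a": [x for x, _ in pairs],
            "group_b": [y for _, y in pairs],
            "p_raw": raw,
            "p_adj": adj,
            "stars": [significance_stars(p) for p in adj],
        }
    )
    return GroupComparison(table=table)


def tukey_box_stats(values: np.ndarray) -> dict[str, float]:
    """Tukey five-number summary: median, quartiles, 1.5*IQR whiskers."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_candidates = v[v >= q1 - 1.5 * iqr]
    hi_candidates = v[v <= q3 + 1.5 * iqr]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(lo_candidates.min()),
        "whisker_high": float(hi_candidates.max()),
    }
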