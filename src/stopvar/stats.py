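"""ROI extraction and group-level inferential statistics.

Covers the second-level analyses relating stopping variability to BOLD
variability: ROI/network means of DoR maps, one-way ANOVAs with eta
squared, voxel-wise two-sample t maps with a Bonferroni voxel threshold
and a cluster-extent filter, Pearson and partial correlations, the
Fisher r-to-z comparison of independent correlations, and the
noncentral-t power/sample-size calculation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.power import TTestIndPower

from .exceptions import ConfigurationError, DataError

# MNI centers (mm) of the inhibition-network ROIs and the calcarine
# control for use on real, normalised data; spheres of 6-mm radius.
ROI_CENTERS_MM = {
    "r_ifg": (51.0, 28.0, 8.0),
    "r_caudate": (15.0, 11.0, 8.0),
    "r_putamen": (28.0, 4.0, 1.0),
    "r_thalamus": (13.0, -19.0, 7.0),
    "r_stn": (9.0, -13.0, -7.0),
}
ROI_SPHERE_RADIUS_MM = 6.0


@dataclass(frozen=True)
class GroupTestResult:
    F: float
    df_between: int
    df_within: int
    p: float
    eta_squared: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float
    covariates: tuple[str, ...] = ()


def sphere_masks(
    shape: tuple[int, int, int],
    affine: np.ndarray,
    centers: Mapping[str, tuple[float, float, float]] = ROI_CENTERS_MM,
    radius_mm: float = ROI_SPHERE_RADIUS_MM,
) -> dict[str, np.ndarray]:
    """Flat boolean sphere masks around mm centers on a voxel grid."""
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel(), np.ones(ii.size)])
    mm = vox @ affine.T
    out = {}
    for name, center in centers.items():
        d = np.linalg.norm(mm[:, :3] - np.asarray(center), axis=1)
        mask = d <= radius_mm
        if not mask.any():
            raise DataError(f"ROI {name} is empty on this grid")
        out[name] = mask
    return out


def extract_roi_values(
    values: np.ndarray,
    masks: Mapping[str, np.ndarray],
    network: Sequence[str] = (),
) -> dict[str, float]:
    """Mean map value per ROI, plus a pooled ``network`` mean.

    The network value is the mean over all voxels pooled across the
    network masks (equal to the mean of ROI means when masks have equal
    sizes).
    """
    values = np.asarray(values).ravel()
    out = {}
    for name, mask in masks.items():
        mask = np.asarray(mask).ravel().astype(bool)
        if not mask.any():
            raise DataError(f"ROI {name} has an empty mask")
        out[name] = float(values[mask].mean())
    if network:
        pooled = np.concatenate([values[np.asarray(masks[n]).ravel().astype(bool)]
                                 for n in network])
        out["network"] = float(pooled.mean())
    return out


def one_way_anova(groups: Mapping[str, np.ndarray]) -> GroupTestResult:
    """One-way fixed-effects ANOVA with eta^2 = SS_between / SS_total."""
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2:
        raise DataError("ANOVA needs at least two groups")
    if any(a.size < 1 for a in arrays):
        raise DataError("every group needs at least one observation")
    n_total = sum(a.size for a in arrays)
    k = len(arrays)
    if n_total - k < 1:
        raise DataError("not enough within-group degrees of freedom")
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    ss_total = ss_between + ss_within
    df_b, df_w = k - 1, n_total - k
    F = (ss_between / df_b) / (ss_within / df_w) if ss_within > 0 else np.inf
    p = float(stats.f.sf(F, df_b, df_w))
    eta2 = float(ss_between / ss_total) if ss_total > 0 else 0.0
    return GroupTestResult(F=float(F), df_between=df_b, df_within=df_w, p=p, eta_squared=eta2)


def voxelwise_group_map(
    maps_by_group: Mapping[str, np.ndarray],
    shape: tuple[int, int, int],
    alpha: float = 0.05,
    min_cluster_voxels: int = 10,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Two-sample t per voxel with Bonferroni + cluster-extent filtering.

    The voxel threshold is the two-sided Bonferroni-corrected alpha over
    all voxels; surviving voxels are grouped into 6-connectivity
    clusters and clusters below ``min_cluster_voxels`` are removed.
    Returns the thresholded t map (0 where non-significant) and a
    cluster table.  Voxels with zero pooled variance are flagged NaN.
    """
    if len(maps_by_group) != 2:
        raise DataError("voxel-wise group map expects exactly two groups")
    (g1, a), (g2, b) = [(k, np.asarray(v, dtype=float)) for k, v in maps_by_group.items()]
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise DataError("need at least two subjects per group")
    t, p = stats.ttest_ind(a, b, axis=0)
    n_vox = t.size
    degenerate = ~np.isfinite(t)
    sig = np.zeros(n_vox, dtype=bool)
    ok = ~degenerate
    sig[ok] = p[ok] < alpha / n_vox
    t_thresh = np.where(sig, t, 0.0)
    t_thresh[degenerate] = np.nan

    structure = ndimage.generate_binary_structure(3, 1)  # faces only
    rows = []
    keep = np.zeros(n_vox, dtype=bool)
    for sign, mask in (("+", sig & (t > 0)), ("-", sig & (t < 0))):
        lab, n_lab = ndimage.label(mask.reshape(shape), structure=structure)
        for lid in range(1, n_lab + 1):
            cluster = (lab == lid).ravel()
            size = int(cluster.sum())
            if size < min_cluster_voxels:
                continue
            keep |= cluster
            peak_flat = np.flatnonzero(cluster)[np.argmax(np.abs(t[cluster]))]
            rows.append(
                {
                    "sign": sign,
                    "size": size,
                    "peak_t": float(t[peak_flat]),
                    "peak_ijk": tuple(int(x) for x in np.unravel_index(peak_flat, shape)),
                    "direction": f"{g1}>{g2}" if sign == "+" else f"{g2}>{g1}",
                }
            )
    t_thresh = np.where(keep, t_thresh, np.where(degenerate, np.nan, 0.0))
    table = pd.DataFrame(rows, columns=["sign", "size", "peak_t", "peak_ijk", "direction"])
    return t_thresh, table


def correlations(
    x: np.ndarray,
    y: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    covariate_names: tuple[str, ...] = (),
) -> CorrelationResult:
    """Pearson r (two-sided p); with covariates, the partial correlation
    via residual-on-residual regression with n - 2 - k degrees of
    freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be 1-D and the same length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DataError("correlation inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DataError("zero-variance input to correlation")
    n = x.size
    if covariates is None:
        if n < 3:
            raise DataError("need n >= 3 for a correlation")
        r, p = stats.pearsonr(x, y)
        return CorrelationResult(r=float(r), n=n, p=float(p))
    Z = np.atleast_2d(np.asarray(covariates, dtype=float))
    if Z.shape[0] != n:
        Z = Z.T
    if Z.shape[0] != n:
        raise DataError("covariates must have one row per observation")
    k = Z.shape[1]
    if n < 3 + k:
        raise DataError(f"need n >= {3 + k} with {k} covariates")
    X = np.column_stack([np.ones(n), Z])
    rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
    ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    tval = r * np.sqrt(df / max(1.0 - r * r, 1e-15))
    p = float(2.0 * stats.t.sf(abs(tval), df))
    return CorrelationResult(r=r, n=n, p=p, covariates=covariate_names or tuple(f"c{i}" for i in range(k)))


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Independent-samples comparison of two Pearson correlations.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided
    normal p.  Swapping the groups negates z.
    """
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise DataError("|r| must be < 1 for the Fisher transform")
    if n1 < 4 or n2 < 4:
        raise DataError("need n >= 4 in each group")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(z), p


def power_sample_size(
    effect_size_d: float, alpha: float = 0.05, power: float = 0.80,
    max_n: int = 1_000_000,
) -> tuple[int, int]:
    """Smallest equal per-group n for a two-sided two-sample t test.

    Uses the noncentral-t power function; returns (n per group, total).
    """
    if effect_size_d <= 0:
        raise ConfigurationError("effect size d must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ConfigurationError("alpha and power must lie in (0, 1)")
    solver = TTestIndPower()
    # analytic starting point, then walk to the smallest achieving n
    try:
        n0 = solver.solve_power(effect_size=effect_size_d, alpha=alpha, power=power)
        n = max(2, int(np.floor(n0)) - 2)
    except Exception:
        n = 2
    n = max(n, 2)
    while n <= max_n:
        if solver.power(effect_size=effect_size_d, nobs1=n, ratio=1.0, alpha=alpha) >= power:
            return n, 2 * n
        n += 1
    raise ConfigurationError("requested power unattainable within the search limit")
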