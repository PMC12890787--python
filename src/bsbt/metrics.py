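"""Segmentation and reliability metrics.

Dice overlap, symmetric average Hausdorff distance over boundary voxels,
two-way mixed-effects absolute-agreement ICC — ICC(A,1) in the
McGraw & Wong taxonomy — with F-distribution confidence bounds,
pooled-covariance LDA with leave-one-out cross-validation scored by
Mann-Whitney AUC, and FDR-corrected nonparametric group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """2|A^B| / (|A|+|B|); both empty -> 1 (correctly predicted absence)."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / (na + nb)


def _boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with at least one face-connected background neighbor."""
    eroded = ndimage.binary_erosion(mask)
    return np.argwhere(mask & ~eroded)


def average_hausdorff(
    a: np.ndarray, b: np.ndarray, spacing_mm: float | np.ndarray = 1.0
) -> float:
    """Symmetric average boundary distance in mm.

    0.5 * [mean_{x in dA} d(x, dB) + mean_{y in dB} d(y, dA)] over
    boundary voxels. Undefined (NaN) when either mask is empty.
    """
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if not a.any() or not b.any():
        return float("nan")
    spacing = np.broadcast_to(np.asarray(spacing_mm, float), (3,))
    pa = _boundary_voxels(a) * spacing
    pb = _boundary_voxels(b) * spacing
    from scipy.spatial import cKDTree

    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    return 0.5 * (d_ab.mean() + d_ba.mean())


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


def icc_two_way(measurements: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """Two-way mixed-effects, absolute-agreement, single-measurement ICC.

    ``measurements`` is (n subjects, k sessions), k = 2 here. Computed
    from the two-way ANOVA mean squares,

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n),

    with the 95% CI from the standard F-distribution bounds.
    """
    Y = np.asarray(measurements, dtype=float)
    n, k = Y.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    mean = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)

    ss_rows = k * ((row_means - mean) ** 2).sum()
    ss_cols = n * ((col_means - mean) ** 2).sum()
    ss_total = ((Y - mean) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    if msr <= mse:
        # no between-subject variance beyond noise
        return ICCResult(icc=0.0, ci_low=0.0, ci_high=0.0, degenerate=True)

    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # McGraw & Wong CI for ICC(A,1)
    a = (k * icc) / (n * (1 - icc))
    b_ = 1 + (k * icc * (n - 1)) / (n * (1 - icc))
    v = (a * msc + b_ * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b_ * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_obs = msr / mse
    fl = stats.f.ppf(1 - alpha / 2, n - 1, v)
    fu = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - fl * mse) / (
        fl * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    hi = n * (fu * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * fu * msr
    )
    _ = f_obs
    return ICCResult(icc=float(icc), ci_low=float(lo), ci_high=float(hi))


def _lda_fit(X: np.ndarray, y: np.ndarray, ridge_rel: float = 1e-6):
    """Pooled-covariance LDA direction and threshold-free score function."""
    X0, X1 = X[y == 0], X[y == 1]
    m0, m1 = X0.mean(axis=0), X1.mean(axis=0)
    n0, n1 = len(X0), len(X1)
    k = X.shape[1]
    S = np.zeros((k, k))
    for Xi, mi in ((X0, m0), (X1, m1)):
        d = Xi - mi
        S += d.T @ d
    S /= max(1, n0 + n1 - 2)
    # ridge guard against singular pooled covariance
    tr = np.trace(S)
    reg = ridge_rel * (tr / k if tr > 0 else 1.0)
    try:
        w = np.linalg.solve(S + reg * np.eye(k), m1 - m0)
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn("singular pooled covariance; increasing ridge", stacklevel=2)
        w = np.linalg.solve(S + (tr + 1.0) * 1e-3 * np.eye(k), m1 - m0)
    return w


def mann_whitney_auc(scores: np.ndarray, groups: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U of held-out scores."""
    s1 = scores[groups == 1]
    s0 = scores[groups == 0]
    greater = (s1[:, None] > s0[None, :]).sum()
    ties = (s1[:, None] == s0[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(s1) * len(s0)))


@dataclass
class ROCResult:
    scores: np.ndarray
    groups: np.ndarray
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray


def lda_loocv_auc(features: np.ndarray, groups: np.ndarray) -> ROCResult:
    """Leave-one-out LDA scores and the ROC they induce.

    For each held-out subject a pooled-covariance LDA is fit on the
    remaining subjects and the held-out projection recorded; the AUC is
    the Mann-Whitney statistic of those scores.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(groups).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("groups must be binary 0/1")
    if (y == 0).sum() == 0 or (y == 1).sum() == 0:
        raise ValueError("both groups must be nonempty")
    n = len(y)
    scores = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        w = _lda_fit(X[keep], y[keep])
        scores[i] = X[i] @ w
    auc = mann_whitney_auc(scores, y)
    order = np.argsort(-scores, kind="stable")
    tp = np.concatenate([[0], np.cumsum(y[order] == 1)]) / max(1, (y == 1).sum())
    fp = np.concatenate([[0], np.cumsum(y[order] == 0)]) / max(1, (y == 0).sum())
    return ROCResult(scores=scores, groups=y, auc=auc, fpr=fp, tpr=tp)


def group_compare(
    values: pd.DataFrame | np.ndarray,
    groups: np.ndarray,
    paired: bool = False,
) -> pd.DataFrame:
    """Per-bundle rank tests with Benjamini-Hochberg correction.

    ``values`` is (subjects x bundles); ``groups`` a binary vector.
    Unpaired comparisons use the Wilcoxon rank-sum test, paired ones the
    signed-rank test (subjects matched by position within each group).
    Returns a DataFrame with p and BH-adjusted q per bundle; all-tied
    data yields p = 1.
    """
    V = pd.DataFrame(values)
    y = np.asarray(groups).astype(int)
    ps = []
    for col in V.columns:
        x0 = V.loc[y == 0, col].to_numpy()
        x1 = V.loc[y == 1, col].to_numpy()
        if min(len(x0), len(x1)) < 3:
            raise ValueError("need >= 3 subjects per group")
        if np.ptp(np.concatenate([x0, x1])) == 0:
            ps.append(1.0)
            continue
        if paired:
            d = x1[: len(x0)] - x0[: len(x1)]
            if np.all(d == 0):
                ps.append(1.0)
                continue
            p = stats.wilcoxon(d, zero_method="wilcox").pvalue
        else:
            p = stats.ranksums(x0, x1).pvalue
        ps.append(float(p))
    rej, q, _, _ = multipletests(ps, method="fdr_bh")
    return pd.DataFrame(
        {"bundle": list(V.columns), "p": ps, "q": q, "significant": rej}
    )


def metric_report(
    pred: np.ndarray,
    truth: np.ndarray,
    spacing_mm: float = 1.0,
    n_classes: int = 17,
) -> pd.DataFrame:
    """Per-label Dice / average HD / volume table for one segmentation."""
    voxvol = float(np.prod(np.broadcast_to(np.asarray(spacing_mm, float), (3,))))
    rows = []
    for v in range(1, n_classes):
        p_, t_ = pred == v, truth == v
        rows.append(
            {
                "label": v,
                "dice": dice(p_, t_),
                "avg_hd_mm": average_hausdorff(p_, t_, spacing_mm),
                "pred_volume_mm3": float(p_.sum()) * voxvol,
                "truth_volume_mm3": float(t_.sum()) * voxvol,
            }
        )
    return pd.DataFrame(rows)
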