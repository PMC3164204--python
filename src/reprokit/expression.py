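"""Core expression containers, normalization, detection calls and
differential expression for a duplicate-design reprogramming time course.

The workflow mirrors a standard Illumina BeadChip analysis: log2
transform + quantile normalization, present/absent calls from detection
p-values (p < 0.01 strict), a duplicate-present probe filter, and an
empirical-Bayes moderated t versus the donor fibroblast group with
Benjamini-Hochberg adjustment.  A probe is *regulated* in a contrast when
p_adj < 0.05 and |log2FC| > log2(1.5); the per-probe regulation profile
is the 5-character 0/1 string over (24h, 48h, 72h, iPS, ES).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import brentq
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

#: strict present-call threshold on the detection p-value
DETECTION_THRESHOLD = 0.01
#: adjusted-p threshold for the regulated flag
PADJ_THRESHOLD = 0.05
#: fold-change threshold (linear scale) for the regulated flag
FC_THRESHOLD = 1.5

#: canonical contrast order used by the regulation profile
CONTRAST_ORDER = ("t24", "t48", "t72", "iPS", "ES")
#: donor (reference) group label
DONOR_GROUP = "donor"


@dataclass
class ExpressionMatrix:
    """Probes x samples log2 intensities with parallel detection p-values.

    Parameters
    ----------
    intensities
        DataFrame indexed by probe id, one column per sample, log2 scale.
    detection_p
        DataFrame of detection p-values, same shape/index/columns.
    groups
        Series mapping sample id -> group label (e.g. ``donor``, ``t24``).
    """

    intensities: pd.DataFrame
    detection_p: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not self.intensities.index.equals(self.detection_p.index) or not (
            self.intensities.columns.equals(self.detection_p.columns)
        ):
            raise ValueError("intensity and detection matrices must share dimensions")
        if self.intensities.index.has_duplicates:
            raise ValueError("duplicate probe ids")
        dp = self.detection_p.to_numpy()
        if np.any((dp < 0) | (dp > 1)):
            raise ValueError("detection p-values must lie in [0, 1]")
        self.groups = self.groups.reindex(self.intensities.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValueError(f"samples without group assignment: {missing}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def samples(self) -> pd.Index:
        return self.intensities.columns

    def group_samples(self, group: str) -> list[str]:
        """Sample ids belonging to ``group`` (order preserved)."""
        return list(self.groups.index[self.groups == group])

    def group_labels(self) -> list[str]:
        """Group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)


@dataclass
class DetectionCalls:
    """Present/absent calls plus the duplicate-present analysis set."""

    present: pd.DataFrame
    analysis_set: pd.Index
    groups: pd.Series = field(repr=False, default=None)

    def group_present(self, group: str) -> pd.Series:
        """Group-level presence: present in *all* replicates of ``group``."""
        cols = list(self.groups.index[self.groups == group])
        if not cols:
            raise KeyError(f"unknown group: {group}")
        return self.present[cols].all(axis=1)


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns to the mean empirical distribution.

    Ties share the average of the corresponding reference quantiles;
    fractional ranks are linearly interpolated, which makes the transform
    idempotent and exact on tie-free columns.
    """
    arr = values.to_numpy(dtype=float)
    n = arr.shape[0]
    if arr.shape[1] == 1:
        return values.copy()
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(arr.shape[1]):
        ranks = stats.rankdata(arr[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, ref)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def normalize(raw: pd.DataFrame, groups: pd.Series, detection_p: pd.DataFrame | None = None,
              log_transform: bool = True) -> ExpressionMatrix:
    """Log2-transform raw intensities and quantile-normalize across samples.

    ``log_transform=False`` skips the log step for input already on the
    log2 scale (e.g. the synthetic generator's output); the quantile step
    is idempotent either way.  Raises on non-positive raw intensities,
    naming the offending probe and sample.
    """
    arr = raw.to_numpy(dtype=float)
    if log_transform:
        bad = np.argwhere(arr <= 0)
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"non-positive intensity at probe {raw.index[i]!r}, sample {raw.columns[j]!r}"
            )
        raw = pd.DataFrame(np.log2(arr), index=raw.index, columns=raw.columns)
    normed = quantile_normalize(raw)
    if detection_p is None:
        detection_p = pd.DataFrame(0.0, index=raw.index, columns=raw.columns)
    return ExpressionMatrix(normed, detection_p, groups)


def call_detection(matrix: ExpressionMatrix) -> DetectionCalls:
    """Present/absent calls and the duplicate-present analysis set.

    A probe is *present* in a sample when its detection p-value is
    strictly below 0.01 (p = 0.01 is absent).  The analysis set keeps
    probes present in all replicates of at least one sample group.
    """
    present = matrix.detection_p < DETECTION_THRESHOLD
    keep = pd.Series(False, index=matrix.probe_ids)
    for group in matrix.group_labels():
        cols = matrix.group_samples(group)
        if len(cols) < 2:
            logger.warning(
                "group %r has a single replicate; duplicate-present rule "
                "degenerates to presence in that sample", group,
            )
        keep |= present[cols].all(axis=1)
    return DetectionCalls(present=present, analysis_set=matrix.probe_ids[keep],
                          groups=matrix.groups)


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d array of p-values")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments prior (d0, s0^2) for the variance distribution.

    Works on z = log(s^2): under the scaled-F model,
    var(z) = trigamma(df/2) + trigamma(d0/2) and
    E[z] = log(s0^2) + digamma(df/2) - digamma(d0/2) + log(d0/df).
    Returns ``(inf, exp(mean))`` when the residual variance of z is
    non-positive (variances more concordant than the chi^2 floor).
    """
    s2 = s2[s2 > 0]
    if s2.size < 2:
        return 0.0, float(s2.mean()) if s2.size else 1.0
    z = np.log(s2)
    evar = z.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 1e-10:
        d0 = np.inf
        s0_2 = float(np.exp(z.mean() - special.digamma(df / 2.0) + np.log(df / 2.0)))
        return d0, s0_2

    def f(x):  # solve trigamma(d0/2) = evar
        return special.polygamma(1, x / 2.0) - evar

    d0 = brentq(f, 1e-6, 1e8)
    s0_2 = float(np.exp(z.mean() - special.digamma(df / 2.0) + special.digamma(d0 / 2.0)
                        + np.log(df / d0)))
    return float(d0), s0_2


def differential_expression(matrix: ExpressionMatrix, calls: DetectionCalls,
                            contrast: str, donor: str = DONOR_GROUP,
                            prior_df: float | None = None) -> pd.DataFrame:
    """Moderated-t differential expression of ``contrast`` versus donor.

    Restricted to the duplicate-present analysis set.  Per-probe pooled
    variances are shrunk toward an empirical-Bayes prior estimated by
    method of moments (``prior_df=0`` disables shrinkage and yields the
    ordinary pooled two-sample t; a finite positive value fixes the prior
    df).  P-values use the t distribution with augmented degrees of
    freedom; BH adjustment is across the analysis set.

    Returns a DataFrame indexed by probe id with columns
    ``log2fc, t, p_raw, p_adj, regulated, direction``.
    """
    c_cols = matrix.group_samples(contrast)
    d_cols = matrix.group_samples(donor)
    if len(c_cols) < 2 or len(d_cols) < 2:
        raise ValueError(
            f"need >=2 samples per group (contrast {contrast}: {len(c_cols)}, "
            f"donor {donor}: {len(d_cols)})"
        )
    probes = calls.analysis_set
    x = matrix.intensities.loc[probes, c_cols].to_numpy()
    y = matrix.intensities.loc[probes, d_cols].to_numpy()
    n1, n2 = x.shape[1], y.shape[1]
    df_resid = n1 + n2 - 2
    log2fc = x.mean(axis=1) - y.mean(axis=1)
    ss = ((x - x.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (y - y.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid

    if prior_df is None:
        d0, s0_2 = _estimate_prior(s2, df_resid)
    elif prior_df == 0:
        d0, s0_2 = 0.0, 0.0
    else:
        d0 = float(prior_df)
        _, s0_2 = _estimate_prior(s2, df_resid)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2fc / se
    zero = se == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance probe(s) with no prior; t set to NA")
        t[zero] = np.nan
    if np.isinf(df_total):
        p_raw = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p_raw = 2.0 * stats.t.sf(np.abs(t), df_total)
    p_raw = np.where(np.isnan(t), np.nan, p_raw)
    p_adj = np.full_like(p_raw, np.nan)
    ok = ~np.isnan(p_raw)
    p_adj[ok] = adjust_bh(p_raw[ok])

    regulated = (p_adj < PADJ_THRESHOLD) & (np.abs(log2fc) > np.log2(FC_THRESHOLD))
    direction = np.where(~regulated, "none", np.where(log2fc > 0, "up", "down"))
    return pd.DataFrame(
        {"log2fc": log2fc, "t": t, "p_raw": p_raw, "p_adj": p_adj,
         "regulated": regulated, "direction": direction},
        index=probes,
    )


def regulation_profile(results: dict[str, pd.DataFrame],
                       order: tuple[str, ...] = CONTRAST_ORDER) -> pd.Series:
    """Per-probe 5-character 0/1 regulation string over the contrasts.

    Character *i* is ``1`` iff the probe is regulated in contrast
    ``order[i]``.  Raises when a contrast is missing.
    """
    missing = [c for c in order if c not in results]
    if missing:
        raise KeyError(f"missing contrasts: {missing}")
    idx = results[order[0]].index
    cols = []
    for c in order:
        r = results[c]
        if not r.index.equals(idx):
            r = r.reindex(idx)
        cols.append(r["regulated"].fillna(False).astype(int).astype(str))
    return pd.Series([''.join(t) for t in zip(*cols)], index=idx, name="profile")


def pca_projection(matrix: ExpressionMatrix, n_components: int = 2) -> pd.DataFrame:
    """Project samples onto the leading principal axes of their probe vectors.

    Probe-wise mean-centering; returns a samples x components DataFrame
    (columns ``PC1``, ``PC2``, ...) with explained variances stored in
    ``.attrs["explained_variance"]``, ordered non-increasing.
    """
    if matrix.samples.size < 3:
        raise ValueError("PCA projection needs at least 3 samples")
    X = matrix.intensities.to_numpy().T  # samples x probes
    X = X - X.mean(axis=0, keepdims=True)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    out = pd.DataFrame(coords, index=matrix.samples,
                       columns=[f"PC{i + 1}" for i in range(n_components)])
    out.attrs["explained_variance"] = pca.explained_variance_
    return out
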