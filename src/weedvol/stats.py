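"""Regression and canonical discriminant statistics for quadrat studies.

Volumes estimated from the meshes are related to ground-truth biomass and
density with Pearson correlation and simple least-squares regression, and
quadrats are classified into weed groups (monocots / dicots / mixture)
with a canonical discriminant analysis (CDA) of their weed-height
features: canonical axes maximize between-group relative to within-group
scatter, and samples are assigned to the nearest group centroid in
canonical space (equivalent to a Mahalanobis rule under the pooled
within-group covariance, with equal priors).  Confusion matrices are
row-normalized percentages, rows ordered monocots, dicots, mixture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

__all__ = [
    "RegressionResult",
    "CDAModel",
    "ConfusionMatrix",
    "GroupSizeError",
    "WEED_CLASS_ORDER",
    "pearson",
    "ols_fit",
    "cda_fit",
    "cda_predict",
    "cda_confusion",
    "analyze_dataset",
]

logger = logging.getLogger(__name__)

#: Canonical group order used throughout reports.
WEED_CLASS_ORDER = ("monocots", "dicots", "mixture")

#: Ridge multiplier applied to a singular pooled within-group scatter.
RIDGE_FRACTION = 1e-8


class GroupSizeError(ValueError):
    """A discriminant group has too few samples to estimate scatter."""


@dataclass
class RegressionResult:
    """Simple linear fit y = slope * x + intercept with its correlation."""

    slope: float
    intercept: float
    r: float
    r_squared: float
    p_value: float
    n: int


@dataclass
class CDAModel:
    """Fitted canonical discriminant model."""

    group_labels: tuple
    group_means: np.ndarray
    canonical_coefficients: np.ndarray  # (features, axes)
    pooled_within_scatter: np.ndarray
    center: np.ndarray
    means_canonical: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.means_canonical = self.transform(self.group_means)

    @property
    def n_axes(self) -> int:
        return self.canonical_coefficients.shape[1]

    def transform(self, features: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(features, dtype=np.float64))
        return (x - self.center) @ self.canonical_coefficients

    def classify(self, features: np.ndarray) -> np.ndarray:
        """Nearest group centroid in canonical space."""
        z = self.transform(features)
        d2 = ((z[:, None, :] - self.means_canonical[None, :, :]) ** 2).sum(axis=2)
        idx = np.argmin(d2, axis=1)
        return np.asarray([self.group_labels[i] for i in idx])


@dataclass
class ConfusionMatrix:
    """Row-normalized classification percentages (true x predicted)."""

    labels: tuple
    percentages: np.ndarray
    counts: np.ndarray
    scheme: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.percentages, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------------
# correlation and regression


def _check_xy(x, y, require_y_varies: bool = True):
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    if require_y_varies and np.ptp(y) == 0:
        raise ValueError("zero variance in y")
    return x, y


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation and its two-sided p-value.

    Significance comes from the exact t transform with n - 2 degrees of
    freedom; constant input raises a zero-variance error.
    """
    x, y = _check_xy(x, y)
    res = scipy.stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def ols_fit(x, y) -> RegressionResult:
    """Least-squares line through (x, y) with r and r^2.

    A constant response is a degenerate but well-defined case: slope 0,
    intercept at the mean, r and r^2 reported as 0.
    """
    x, y = _check_xy(x, y, require_y_varies=False)
    if np.ptp(y) == 0:
        return RegressionResult(0.0, float(y.mean()), 0.0, 0.0, 1.0, len(x))
    lr = scipy.stats.linregress(x, y)
    return RegressionResult(
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        r=float(lr.rvalue),
        r_squared=float(lr.rvalue) ** 2,
        p_value=float(lr.pvalue),
        n=len(x),
    )


# ---------------------------------------------------------------------------
# canonical discriminant analysis


def _group_order(labels: np.ndarray) -> tuple:
    uniq = list(dict.fromkeys(labels.tolist()))
    if set(uniq) <= set(WEED_CLASS_ORDER):
        return tuple(g for g in WEED_CLASS_ORDER if g in uniq)
    return tuple(sorted(uniq))


def cda_fit(features, labels) -> CDAModel:
    """Fit canonical discriminant axes to grouped feature vectors.

    Solves the generalized symmetric eigenproblem Sb w = lambda Sw w for
    the pooled within-group scatter Sw and between-group scatter Sb,
    keeping the min(groups - 1, features) leading axes.  Eigenvectors are
    Sw-normalized, so Euclidean distance in canonical space equals
    Mahalanobis distance under the pooled covariance.  A singular Sw is
    ridge-regularized (1e-8 of its trace, logged).
    """
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    labels = np.asarray(labels)
    if X.shape[0] != len(labels):
        raise ValueError("features and labels must have equal length")
    groups = _group_order(labels)
    for g in groups:
        if np.count_nonzero(labels == g) < 2:
            raise GroupSizeError(f"group {g!r} has fewer than 2 samples")
    n, p = X.shape
    g = len(groups)
    if g < 2:
        raise GroupSizeError("need at least two groups")
    center = X.mean(axis=0)
    means = np.vstack([X[labels == lab].mean(axis=0) for lab in groups])
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    for k, lab in enumerate(groups):
        Xg = X[labels == lab] - means[k]
        Sw += Xg.T @ Xg
        nk = np.count_nonzero(labels == lab)
        d = (means[k] - center)[:, None]
        Sb += nk * (d @ d.T)
    Sw /= max(n - g, 1)
    Sb /= max(g - 1, 1)
    tr = np.trace(Sw)
    eigvals = np.linalg.eigvalsh(Sw)
    if eigvals.min() <= 1e-12 * max(tr, 1e-300):
        ridge = RIDGE_FRACTION * max(tr, 1e-30)
        logger.info("singular within-group scatter; adding ridge %.3g", ridge)
        Sw = Sw + ridge * np.eye(p)
    w, v = scipy.linalg.eigh(Sb, Sw)
    order = np.argsort(w)[::-1]
    k = min(g - 1, p)
    coeffs = v[:, order[:k]]
    return CDAModel(
        group_labels=groups,
        group_means=means,
        canonical_coefficients=coeffs,
        pooled_within_scatter=Sw,
        center=center,
    )


def cda_predict(model: CDAModel, features) -> np.ndarray:
    """Classify feature vectors by nearest centroid in canonical space."""
    return model.classify(features)


def cda_confusion(
    model: CDAModel | None,
    features,
    labels,
    scheme: str = "leave_one_out",
) -> ConfusionMatrix:
    """Confusion matrix of the discriminant classifier, rows as percentages.

    ``leave_one_out`` (default, the less optimistic scheme) refits the
    model without each sample before classifying it; ``resubstitution``
    reuses the supplied fit.  Rows are true groups in canonical order and
    each sums to 100.
    """
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    labels = np.asarray(labels)
    if scheme not in ("resubstitution", "leave_one_out"):
        raise ValueError(f"unknown scheme: {scheme!r}")
    groups = model.group_labels if model is not None else _group_order(labels)
    if scheme == "resubstitution":
        if model is None:
            model = cda_fit(X, labels)
        predicted = model.classify(X)
        groups = model.group_labels
    else:
        full = model if model is not None else cda_fit(X, labels)
        preds = []
        for i in range(len(labels)):
            keep = np.arange(len(labels)) != i
            try:
                m = cda_fit(X[keep], labels[keep])
            except GroupSizeError:
                # a 2-sample group cannot be refit without its member;
                # score that sample against the full fit instead
                m = full
            preds.append(m.classify(X[i : i + 1])[0])
        predicted = np.asarray(preds)
    gidx = {g: k for k, g in enumerate(groups)}
    counts = np.zeros((len(groups), len(groups)), dtype=np.int64)
    for t, pr in zip(labels, predicted):
        counts[gidx[t], gidx.get(pr, 0)] += 1
    rowsum = counts.sum(axis=1, keepdims=True).astype(np.float64)
    rowsum[rowsum == 0] = 1.0
    return ConfusionMatrix(tuple(groups), 100.0 * counts / rowsum, counts, scheme)


# ---------------------------------------------------------------------------
# whole-study analysis

#: DataFrame columns consumed by :func:`analyze_dataset`.
DATASET_COLUMNS = (
    "sample_id",
    "maize_volume_m3",
    "weed_volume_m3",
    "total_volume_m3",
    "maize_biomass_g",
    "weed_biomass_g",
    "weed_density",
    "maize_count",
    "weed_class",
    "weed_max_height_m",
    "weed_p90_height_m",
)


def _relationship(x, y, name: str) -> dict:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        reason = "fewer than 3 samples" if len(x) < 3 else "constant variable"
        return {"name": name, "flag": f"non-significant/degenerate ({reason})", "n": int(len(x))}
    fit = ols_fit(x, y)
    return {
        "name": name,
        "slope": fit.slope,
        "intercept": fit.intercept,
        "r": fit.r,
        "r_squared": fit.r_squared,
        "p_value": fit.p_value,
        "n": fit.n,
    }


def analyze_dataset(data: pd.DataFrame, cda_scheme: str = "leave_one_out") -> dict:
    """Relate estimated volumes to ground truth across a quadrat study.

    Computes the six standard relationships — total volume ~ total
    biomass, maize volume ~ maize biomass, weed volume ~ weed biomass,
    total volume ~ weed density, weed volume ~ weed density, and maize
    count ~ maize volume (routinely degenerate: the crop stand is nearly
    constant per quadrat, and the entry is flagged as such) — plus a
    canonical discriminant classification of weed class from the
    (max, p90) weed-height features, reported as a confusion matrix.
    """
    df = data.copy()
    if "total_volume_m3" not in df:
        df["total_volume_m3"] = df["maize_volume_m3"] + df["weed_volume_m3"]
    total_biomass = df["maize_biomass_g"] + df["weed_biomass_g"]
    rel = [
        _relationship(df["total_volume_m3"], total_biomass, "total_volume~total_biomass"),
        _relationship(df["maize_volume_m3"], df["maize_biomass_g"], "maize_volume~maize_biomass"),
        _relationship(df["weed_volume_m3"], df["weed_biomass_g"], "weed_volume~weed_biomass"),
        _relationship(df["total_volume_m3"], df["weed_density"], "total_volume~weed_density"),
        _relationship(df["weed_volume_m3"], df["weed_density"], "weed_volume~weed_density"),
        # crop-stand density is evaluated where the crop is present: a row
        # crop has a near-constant count per quadrat, which this flags
        _relationship(
            df.loc[df["maize_count"] > 0, "maize_count"],
            df.loc[df["maize_count"] > 0, "maize_volume_m3"],
            "maize_count~maize_volume",
        )
        if "maize_count" in df
        else {"name": "maize_count~maize_volume", "flag": "maize_count column absent", "n": 0},
    ]
    report: dict = {"relationships": {r.pop("name"): r for r in rel}}

    cda_entry: dict = {}
    if {"weed_class", "weed_max_height_m", "weed_p90_height_m"} <= set(df.columns):
        sub = df[df["weed_class"].isin(WEED_CLASS_ORDER)].dropna(
            subset=["weed_max_height_m", "weed_p90_height_m"]
        )
        counts = sub["weed_class"].value_counts()
        usable = counts[counts >= 2].index
        sub = sub[sub["weed_class"].isin(usable)]
        if sub["weed_class"].nunique() >= 2:
            X = sub[["weed_max_height_m", "weed_p90_height_m"]].to_numpy()
            y = sub["weed_class"].to_numpy()
            model = cda_fit(X, y)
            cm = cda_confusion(model, X, y, scheme=cda_scheme)
            cda_entry = {
                "scheme": cm.scheme,
                "labels": list(cm.labels),
                "percentages": cm.percentages.tolist(),
                "counts": cm.counts.tolist(),
            }
        else:
            cda_entry = {"flag": "fewer than two weed classes with >= 2 samples"}
    else:
        cda_entry = {"flag": "weed class or height features absent"}
    report["cda"] = cda_entry
    return report
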