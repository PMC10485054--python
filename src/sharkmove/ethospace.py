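"""Ethospace ordination and per-metric linear models.

The *ethospace* is a PCA ordination of the z-scored per-video metric matrix:
each point is one video, and the spread of points is the range of behaviour
observed.  Group structure (videos with vs without a human swimmer) is
assessed with a 95% data ellipse per group in the PC1-PC2 plane: if each
group's mean score falls inside the other group's ellipse, the mean
behaviours are not distinguishable at that level.

Each metric is additionally regressed on the binary human-presence indicator
with ordinary least squares; for a single binary predictor the slope is the
between-group mean difference and F = t^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["zscore", "ethospace", "fit_linear_models", "EthospaceResult", "GroupEllipse"]


def zscore(matrix, ddof: int = 1):
    """Column-wise z-transform (mean 0, sample SD 1).

    Accepts an array or DataFrame of shape (videos x metrics); constant
    columns cannot be scaled and are dropped with a warning.  Raises on a
    single-row input (no variance to scale by).
    """
    df = pd.DataFrame(matrix).copy()
    if len(df) < 2:
        raise ValueError("z-scoring needs at least 2 rows")
    sd = df.std(ddof=ddof)
    dead = sd[sd == 0].index.tolist()
    if dead:
        warnings.warn(f"dropping zero-variance column(s): {dead}", stacklevel=2)
        df = df.drop(columns=dead)
        sd = sd.drop(dead)
    z = (df - df.mean()) / sd
    return z if isinstance(matrix, pd.DataFrame) else z.to_numpy()


@dataclass
class GroupEllipse:
    """95% data ellipse of one group's scores in the PC1-PC2 plane."""

    center: np.ndarray        # (2,) group mean score
    cov: np.ndarray           # (2, 2) group score covariance
    radii: np.ndarray         # semi-axes, sqrt(eigval * chi2 quantile)
    orientation: float        # angle of the major axis, radians
    level: float = 0.95

    def contains(self, point) -> bool:
        """Is ``point`` inside the ellipse (Mahalanobis test at the level)?"""
        d = np.asarray(point, dtype=float) - self.center
        m2 = float(d @ np.linalg.solve(self.cov, d))
        return bool(m2 <= stats.chi2.ppf(self.level, df=2))


@dataclass
class EthospaceResult:
    loadings: pd.DataFrame          # metric x component weights (eigenvectors)
    scores: pd.DataFrame            # video x component coordinates
    variance_fraction: np.ndarray   # per-component fraction of total variance
    contributions: pd.DataFrame     # per-metric % contribution per component
    group_means: dict               # group label -> mean score vector
    ellipses: dict                  # group label -> GroupEllipse or None
    overlap_verdict: dict = field(default_factory=dict)
    # (a, b) -> True if group a's mean lies inside group b's ellipse


def _pca_eig(z: np.ndarray):
    """Eigendecomposition PCA of a z-scored matrix (columns centred, SD 1)."""
    n = z.shape[0]
    cov = (z.T @ z) / (n - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # deterministic sign: largest-magnitude loading of each component positive
    for j in range(eigvec.shape[1]):
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    return eigval, eigvec


def ethospace(matrix, groups, level: float = 0.95) -> EthospaceResult:
    """PCA ethospace with per-group 95% ellipses and mean-overlap verdicts.

    Parameters
    ----------
    matrix : DataFrame or array, videos x metrics, already z-scored.
    groups : sequence of group labels (e.g. 0/1 human presence), one per video.
    level : ellipse coverage probability (chi-squared with 2 df).

    The ellipse of a group is the data ellipse of its PC1-PC2 scores (score
    covariance scaled by the chi2 quantile); the verdict for an ordered pair
    (a, b) is True when group a's mean score lies inside group b's ellipse.
    Groups with fewer than 3 videos get no ellipse and a ``None`` verdict.
    """
    df = pd.DataFrame(matrix)
    groups = np.asarray(groups)
    if len(groups) != len(df):
        raise ValueError("groups must have one label per row")
    z = df.to_numpy(dtype=float)
    eigval, eigvec = _pca_eig(z)
    comp_names = [f"PC{j + 1}" for j in range(len(eigval))]
    loadings = pd.DataFrame(eigvec, index=df.columns, columns=comp_names)
    scores = pd.DataFrame(z @ eigvec, index=df.index, columns=comp_names)
    total = eigval.sum()
    variance_fraction = eigval / total if total > 0 else eigval
    contributions = pd.DataFrame(
        100.0 * eigvec**2 / np.sum(eigvec**2, axis=0),
        index=df.columns,
        columns=comp_names,
    )

    labels = pd.unique(groups)
    group_means: dict = {}
    ellipses: dict = {}
    for g in labels:
        s = scores.to_numpy()[groups == g][:, :2]
        group_means[g] = scores.to_numpy()[groups == g].mean(axis=0)
        if len(s) < 3:
            ellipses[g] = None
            continue
        cov = np.cov(s, rowvar=False)
        ev, evec = np.linalg.eigh(cov)
        q = stats.chi2.ppf(level, df=2)
        ellipses[g] = GroupEllipse(
            center=s.mean(axis=0),
            cov=cov,
            radii=np.sqrt(np.clip(ev[::-1], 0, None) * q),
            orientation=float(np.arctan2(evec[1, -1], evec[0, -1])),
            level=level,
        )

    verdict: dict = {}
    for a in labels:
        for b in labels:
            if a == b:
                continue
            ell = ellipses[b]
            verdict[(a, b)] = None if ell is None else ell.contains(group_means[a][:2])

    return EthospaceResult(
        loadings=loadings,
        scores=scores,
        variance_fraction=variance_fraction,
        contributions=contributions,
        group_means=group_means,
        ellipses=ellipses,
        overlap_verdict=verdict,
    )


def fit_linear_models(metrics, human_present) -> pd.DataFrame:
    """OLS of each metric on the binary human-presence indicator.

    Returns one row per metric with columns ``coefficient, intercept,
    t_value, p_value, std_error, residual_error, r_squared_pct,
    adj_r_squared_pct, df_num, df_den, f_value``.  With a single binary
    predictor the coefficient is (mean | presence) - (mean | absence), the
    intercept the absence mean, the denominator df n - 2, and F = t^2.
    """
    import statsmodels.api as sm

    df = pd.DataFrame(metrics)
    h = np.asarray(human_present, dtype=float)
    if len(h) != len(df):
        raise ValueError("human_present must have one value per video")
    if len(df) < 3:
        raise ValueError("need at least 3 videos")
    if len(np.unique(h)) < 2:
        raise ValueError("both covariate levels must be present")
    X = sm.add_constant(h)
    rows = []
    for name in df.columns:
        y = df[name].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = sm.OLS(y, X).fit()
            # a metric constant across all videos has no variance to explain:
            # report a null relationship rather than statsmodels' 0/0 artifacts
            degenerate = not np.isfinite(fit.rsquared)
        rows.append(
            {
                "parameter": name,
                "coefficient": fit.params[1],
                "intercept": fit.params[0],
                "t_value": 0.0 if degenerate else fit.tvalues[1],
                "p_value": 1.0 if degenerate else fit.pvalues[1],
                "std_error": fit.bse[1],
                "residual_error": np.sqrt(fit.mse_resid),
                "r_squared_pct": 0.0 if degenerate else 100.0 * fit.rsquared,
                "adj_r_squared_pct": 0.0 if degenerate else 100.0 * fit.rsquared_adj,
                "df_num": int(fit.df_model),
                "df_den": int(fit.df_resid),
                "f_value": 0.0 if degenerate else fit.tvalues[1] ** 2,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
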