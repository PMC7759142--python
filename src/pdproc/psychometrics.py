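"""Reliability and correlation machinery.

Internal consistency is estimated three ways, because no single coefficient
fits a difference-score instrument cleanly:

* Cronbach's alpha — the classical variance-ratio coefficient, applied to
  the sum-score formulation of ``U`` (C items plus reverse-coded IC items).
* McDonald's omega — based on standardized loadings of a single-factor
  maximum-likelihood model, relaxing alpha's equal-functioning assumption.
* Split-half permutation reliability — the item pairs are repeatedly split
  at random into two halves, the parameter of interest is computed from
  each half, the Spearman correlation between half-scores is taken across
  participants and stepped up with the Spearman-Brown formula 2r/(1+r).
  This is the only route available for ``D``, whose ratio form defeats
  item-level coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import ResponseMatrix
from .scoring import build_alt_u_items

__all__ = [
    "cronbach_alpha",
    "mcdonald_omega",
    "spearman_brown",
    "splithalf_reliability",
    "reliability_report",
    "parameter_correlations",
    "interitem_spearman",
    "SplitHalfSummary",
    "ReliabilityReport",
    "CorrelationTable",
    "InterItemCorrelations",
]


class DegenerateDataError(ValueError):
    """Raised when an estimator receives data without usable variance."""


def cronbach_alpha(items) -> float:
    """Cronbach's alpha: m/(m-1) * (1 - sum of item variances / variance of sum)."""
    x = np.asarray(items, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("alpha needs an n x m matrix with m >= 2")
    m = x.shape[1]
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise DegenerateDataError("total score has zero variance")
    return m / (m - 1) * (1.0 - x.var(axis=0, ddof=1).sum() / total_var)


def mcdonald_omega(items, max_iter: int = 2000) -> float:
    """McDonald's omega from a single-factor maximum-likelihood model.

    Items are standardized, a one-factor model is fitted to their
    correlation structure, and omega = (sum lambda)^2 / ((sum lambda)^2 +
    sum psi) over standardized loadings lambda and uniquenesses psi.  The
    factor sign is fixed so the loading sum is non-negative.
    """
    from sklearn.decomposition import FactorAnalysis

    x = np.asarray(items, dtype=float)
    if x.ndim != 2 or x.shape[1] < 3:
        raise ValueError("omega needs an n x m matrix with m >= 3")
    sd = x.std(axis=0)
    if (sd == 0).any():
        raise DegenerateDataError("omega undefined with a constant item")
    z = (x - x.mean(axis=0)) / sd
    fa = FactorAnalysis(n_components=1, max_iter=max_iter, random_state=0)
    fa.fit(z)
    if fa.n_iter_ >= max_iter:
        raise RuntimeError(
            f"one-factor fit did not converge in {max_iter} iterations "
            f"(log-likelihood {fa.loglike_[-1]:.3f})"
        )
    lam = fa.components_[0]
    if lam.sum() < 0:
        lam = -lam
    s = lam.sum()
    return float(s**2 / (s**2 + fa.noise_variance_.sum()))


def spearman_brown(r):
    """Step a half-test correlation up to full length: 2r/(1+r).

    Fixed points at 0 and 1; monotone increasing on (-1, 1].  Undefined at
    r = -1.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= -1.0):
        raise ValueError("Spearman-Brown correction undefined for r <= -1")
    out = 2.0 * r / (1.0 + r)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SplitHalfSummary:
    """Distribution of corrected split-half correlations for one parameter."""

    mean: float
    sd: float
    values: np.ndarray
    n_dropped: int

    def to_dict(self, include_values: bool = True) -> dict:
        d = {"mean": self.mean, "sd": self.sd, "n_dropped": self.n_dropped}
        if include_values:
            d["values"] = [float(v) for v in self.values]
        return d


@dataclass(frozen=True)
class ReliabilityReport:
    alpha: float | None
    omega: float | None
    splithalf_u: SplitHalfSummary
    splithalf_d: SplitHalfSummary
    n_iterations: int
    unreliable: bool = False
    #: alpha/omega of the unreversed variant (C and raw IC items), which a
    #: shared condemnation tendency can push far above the reversed one
    alpha_unreversed: float | None = None
    omega_unreversed: float | None = None

    def to_dict(self, include_values: bool = True) -> dict:
        return {
            "alpha": self.alpha,
            "omega": self.omega,
            "alpha_unreversed": self.alpha_unreversed,
            "omega_unreversed": self.omega_unreversed,
            "n_iterations": self.n_iterations,
            "unreliable": self.unreliable,
            "splithalf_u": self.splithalf_u.to_dict(include_values),
            "splithalf_d": self.splithalf_d.to_dict(include_values),
        }


def _half_scores(c: np.ndarray, ic: np.ndarray, idx: np.ndarray):
    p_c = c[:, idx].mean(axis=1)
    ts = ic[:, idx].mean(axis=1)
    u = p_c - ts
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.clip(np.where(u < 1.0, ts / ((1.0 - p_c) + ts), np.nan), 0.0, 1.0)
    return u, d


def _effectively_constant(x: np.ndarray) -> bool:
    return x.std() <= 1e-12 * (1.0 + np.abs(x).max())


def _spearman_or_none(a: np.ndarray, b: np.ndarray) -> float | None:
    valid = ~(np.isnan(a) | np.isnan(b))
    if valid.sum() < 3:
        return None
    a, b = a[valid], b[valid]
    if _effectively_constant(a) or _effectively_constant(b):
        return None
    r = stats.spearmanr(a, b).statistic
    if not np.isfinite(r) or r <= -1.0:
        return None
    return float(r)


def splithalf_reliability(
    responses: ResponseMatrix, n_iter: int = 10_000, seed: int = 0
) -> ReliabilityReport:
    """Split-half permutation reliability for the U and D parameters.

    Each iteration splits the k dilemma pairs at random into halves of
    floor(k/2) and ceil(k/2) items (4 vs 5 at k = 9), computes U and D from
    each half, correlates the half-scores across participants (Spearman)
    and applies the Spearman-Brown correction.  Participants with an
    undefined D in either half are excluded pairwise from that iteration's
    D correlation.  Iterations whose half-scores have zero variance, too
    few defined values, or a correlation of exactly -1 are dropped and
    counted; if more than half the iterations are dropped for either
    parameter the report is flagged unreliable.

    Alpha and omega are not computed here; see :func:`reliability_report`.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    c = responses.c_items.astype(float)
    ic = responses.ic_items.astype(float)
    k = responses.n_pairs
    h = k // 2
    # splits are drawn over the label set in sorted order, so reordering the
    # columns of the input (labels attached) leaves the report unchanged
    by_label = np.argsort(np.asarray(responses.pair_labels))
    out_u, out_d = [], []
    dropped_u = dropped_d = 0
    for _ in range(n_iter):
        perm = by_label[rng.permutation(k)]
        first, rest = perm[:h], perm[h:]
        u_a, d_a = _half_scores(c, ic, first)
        u_b, d_b = _half_scores(c, ic, rest)
        r_u = _spearman_or_none(u_a, u_b)
        if r_u is None:
            dropped_u += 1
        else:
            out_u.append(spearman_brown(r_u))
        r_d = _spearman_or_none(d_a, d_b)
        if r_d is None:
            dropped_d += 1
        else:
            out_d.append(spearman_brown(r_d))

    def summarize(vals: list, dropped: int) -> SplitHalfSummary:
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            return SplitHalfSummary(np.nan, np.nan, arr, dropped)
        return SplitHalfSummary(
            float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            arr, dropped,
        )

    return ReliabilityReport(
        alpha=None,
        omega=None,
        splithalf_u=summarize(out_u, dropped_u),
        splithalf_d=summarize(out_d, dropped_d),
        n_iterations=n_iter,
        unreliable=max(dropped_u, dropped_d) > n_iter / 2,
    )


def reliability_report(
    responses: ResponseMatrix, n_iter: int = 10_000, seed: int = 0
) -> ReliabilityReport:
    """Full reliability report for a response matrix.

    Alpha and omega are computed on the sum-score formulation of U
    (C items + reverse-coded IC items); the unreversed variant (raw IC
    items) is reported alongside, since a general condemnation tendency can
    make it much larger.  Split-half permutation estimates for U and D are
    attached as in :func:`splithalf_reliability`.  Coefficients that cannot
    be computed on degenerate data are reported as None rather than raising.
    """
    alt = build_alt_u_items(responses).to_numpy()
    unrev = np.hstack([responses.c_items, responses.ic_items]).astype(float)

    def _try(fn, x):
        try:
            return float(fn(x))
        except (DegenerateDataError, RuntimeError, ValueError):
            return None

    sh = splithalf_reliability(responses, n_iter=n_iter, seed=seed)
    return ReliabilityReport(
        alpha=_try(cronbach_alpha, alt),
        omega=_try(mcdonald_omega, alt),
        alpha_unreversed=_try(cronbach_alpha, unrev),
        omega_unreversed=_try(mcdonald_omega, unrev),
        splithalf_u=sh.splithalf_u,
        splithalf_d=sh.splithalf_d,
        n_iterations=sh.n_iterations,
        unreliable=sh.unreliable,
    )


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class CorrelationTable:
    """Pairwise correlation table with two-sided p-values and star marks.

    Cells for zero-variance variables (or pairs with fewer than three
    jointly observed values) are NaN — undefined, not zero.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    method: str

    @property
    def stars(self) -> pd.DataFrame:
        return self.p.map(_stars)

    def annotated(self) -> pd.DataFrame:
        out = self.r.round(2).astype(object)
        for i in out.index:
            for j in out.columns:
                v = self.r.loc[i, j]
                out.loc[i, j] = (
                    "undef" if not np.isfinite(v)
                    else f"{v:.2f}{_stars(self.p.loc[i, j]) if i != j else ''}"
                )
        return out


def parameter_correlations(
    scores: pd.DataFrame,
    extra: pd.Series | pd.DataFrame | None = None,
    method: str = "pearson",
    columns: tuple[str, ...] = ("U", "D", "TS"),
) -> CorrelationTable:
    """Correlation table among PDP parameters (and optional extra scores).

    Missing values (undefined D) are deleted pairwise.  ``method`` is
    ``pearson`` (default, as for parameter tables) or ``spearman``.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    df = scores.loc[:, [c for c in columns if c in scores.columns]].copy()
    if extra is not None:
        extra = extra.to_frame() if isinstance(extra, pd.Series) else extra
        df = df.join(extra, how="left")
    cols = list(df.columns)
    nv = len(cols)
    r = np.full((nv, nv), np.nan)
    p = np.full((nv, nv), np.nan)
    n = np.zeros((nv, nv), dtype=int)
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    for i in range(nv):
        for j in range(i, nv):
            a, b = df[cols[i]].to_numpy(float), df[cols[j]].to_numpy(float)
            valid = ~(np.isnan(a) | np.isnan(b))
            n[i, j] = n[j, i] = valid.sum()
            if valid.sum() < 3:
                continue
            a, b = a[valid], b[valid]
            if _effectively_constant(a) or _effectively_constant(b):
                continue  # undefined cell stays NaN
            if i == j:
                r[i, j], p[i, j] = 1.0, 0.0
                continue
            res = corr(a, b)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    idx = pd.Index(cols)
    return CorrelationTable(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
        method=method,
    )


@dataclass(frozen=True)
class InterItemCorrelations:
    """Rank-correlation matrix over all 2k dilemma items with summaries.

    Constant items yield NaN rows/columns (undefined, flagged in
    ``undefined_items``); summaries are over the finite absolute
    off-diagonal entries.
    """

    matrix: pd.DataFrame
    median_abs: float
    mean_abs: float
    undefined_items: tuple[str, ...]


def interitem_spearman(responses: ResponseMatrix) -> InterItemCorrelations:
    """Spearman correlations between all C and IC dilemma items."""
    if responses.n_participants < 3:
        raise ValueError("need at least 3 participants")
    df = responses.item_frame().astype(float)
    constant = tuple(df.columns[df.std(axis=0) == 0])
    mat = df.corr(method="spearman")
    for col in constant:
        mat.loc[col, :] = np.nan
        mat.loc[:, col] = np.nan
    off = mat.to_numpy()[~np.eye(len(mat), dtype=bool)]
    off = np.abs(off[np.isfinite(off)])
    return InterItemCorrelations(
        matrix=mat,
        median_abs=float(np.median(off)) if off.size else np.nan,
        mean_abs=float(off.mean()) if off.size else np.nan,
        undefined_items=constant,
    )
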