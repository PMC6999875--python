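"""Variability-group comparison and trial-to-trial error-correction analysis.

Subjects are split into LOW/HIGH baseline movement-speed-variability groups at
the cohort mean of sigma^2(Mv).  The error-correction signature is probed two
ways: (i) the sequential effect — the slope of the change in movement speed on
the next trial against the temporal error on the current trial, estimated per
subject and aggregated per group by precision weighting; and (ii) prewhitened
lagged cross-correlations between TE and Mv at lags 0-3 with bootstrap CIs,
which are then correlated with the Adaptation Score across subjects.  L1
(LASSO) regressions select which kinematic predictors carry the within-trial
TE and which variability measures carry the Adaptation Score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import lfilter
from sklearn.linear_model import Lasso

from .errors import DegenerateDataError, TooFewTrialsError

__all__ = [
    "GroupSplit",
    "SequentialEffect",
    "PrewhitenResult",
    "CcfProfile",
    "LassoResult",
    "split_groups",
    "variance_ratio_test",
    "sequential_effect",
    "prewhiten_pair",
    "prewhiten_gappy",
    "lagged_ccf",
    "ccf_score_correlation",
    "lasso_fit",
    "te_model_design",
    "score_model_design",
]

#: Penalties used by the canned model recipes.
TE_MODEL_LAMBDA = 0.6
SCORE_MODEL_LAMBDA = 0.37


# ----------------------------------------------------------------------------
# group split and variance tests
# ----------------------------------------------------------------------------

@dataclass
class GroupSplit:
    threshold: float  # cohort mean of sigma2_Mv
    labels: dict[str, str]  # subject -> "LOW" | "HIGH"

    @property
    def low(self) -> list[str]:
        return [s for s, g in self.labels.items() if g == "LOW"]

    @property
    def high(self) -> list[str]:
        return [s for s, g in self.labels.items() if g == "HIGH"]


def split_groups(sigma2_mv: dict[str, float]) -> GroupSplit:
    """Mean-threshold split: HIGH iff sigma^2(Mv) is above the cohort mean."""
    if len(sigma2_mv) < 4:
        raise TooFewTrialsError("need at least 4 subjects to split")
    vals = np.array(list(sigma2_mv.values()), dtype=float)
    if np.ptp(vals) == 0.0:
        raise DegenerateDataError("all variances equal; split undefined")
    thr = float(vals.mean())
    labels = {s: ("HIGH" if v > thr else "LOW") for s, v in sigma2_mv.items()}
    return GroupSplit(threshold=thr, labels=labels)


def variance_ratio_test(a: np.ndarray, b: np.ndarray) -> tuple[float, tuple[int, int], float]:
    """Ratio of sample variances var(a)/var(b) with an F reference
    distribution and a two-sided p-value (the convention of R's var.test)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise TooFewTrialsError("both groups need at least 2 observations")
    vb = float(np.var(b, ddof=1))
    if vb == 0.0:
        raise DegenerateDataError("zero variance in denominator group")
    ratio = float(np.var(a, ddof=1)) / vb
    dof = (a.size - 1, b.size - 1)
    cdf = stats.f.cdf(ratio, *dof)
    p = float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))
    return ratio, dof, p


# ----------------------------------------------------------------------------
# sequential effect (two-stage per-subject-slope estimator)
# ----------------------------------------------------------------------------

@dataclass
class SequentialEffect:
    subject_slopes: dict[str, float]
    subject_se: dict[str, float]
    subject_intercepts: dict[str, float]
    group_slope: dict[str, float]  # "LOW"/"HIGH" -> precision-weighted mean
    group_slope_se: dict[str, float]
    group_intercept: dict[str, float]
    diff_stat: float  # weighted two-sample z for HIGH - LOW slope difference
    diff_p: float
    excluded_subjects: list[str] = field(default_factory=list)


def _subject_slope(te: np.ndarray, dmv: np.ndarray) -> tuple[float, float, float]:
    """OLS of dMv on TE with intercept; returns (slope, se, intercept)."""
    X = np.column_stack([np.ones_like(te), te])
    beta, res, _, _ = np.linalg.lstsq(X, dmv, rcond=None)
    resid = dmv - X @ beta
    dof = te.size - 2
    s2 = float(resid @ resid) / dof if dof > 0 else np.nan
    sxx = float(np.sum((te - te.mean()) ** 2))
    se = float(np.sqrt(s2 / sxx)) if sxx > 0 else np.nan
    return float(beta[1]), se, float(beta[0])


def sequential_effect(
    baseline: dict[str, pd.DataFrame], split: GroupSplit, min_pairs: int = 10
) -> SequentialEffect:
    """Slope of dMv(t+1) on TE(t) over consecutive valid baseline trials.

    Per-subject least squares; group slope as the precision-weighted mean of
    subject slopes; group difference by a weighted two-sample z statistic.
    ``baseline`` maps subject -> frame with columns trial_index, TE, Mv
    (valid baseline trials only).  Subjects with fewer than ``min_pairs``
    consecutive-trial pairs are excluded from group aggregation and reported.
    A negative slope means late errors (negative TE) speed the next trial up.
    """
    slopes: dict[str, float] = {}
    ses: dict[str, float] = {}
    intercepts: dict[str, float] = {}
    excluded: list[str] = []
    for sid, df in baseline.items():
        df = df.sort_values("trial_index")
        idx = df["trial_index"].to_numpy()
        te = df["TE"].to_numpy(dtype=float)
        mv = df["Mv"].to_numpy(dtype=float)
        consec = np.diff(idx) == 1  # pairs spanning an excluded trial are skipped
        te_t = te[:-1][consec]
        dmv = (mv[1:] - mv[:-1])[consec]
        if te_t.size < min_pairs:
            excluded.append(sid)
            continue
        slopes[sid], ses[sid], intercepts[sid] = _subject_slope(te_t, dmv)

    group_slope: dict[str, float] = {}
    group_se: dict[str, float] = {}
    group_int: dict[str, float] = {}
    for g in ("LOW", "HIGH"):
        members = [s for s in slopes if split.labels.get(s) == g]
        if not members:
            group_slope[g] = group_se[g] = group_int[g] = float("nan")
            continue
        w = np.array([1.0 / max(ses[s], 1e-12) ** 2 for s in members])
        bs = np.array([slopes[s] for s in members])
        cs = np.array([intercepts[s] for s in members])
        group_slope[g] = float(np.sum(w * bs) / np.sum(w))
        group_se[g] = float(np.sqrt(1.0 / np.sum(w)))
        group_int[g] = float(np.sum(w * cs) / np.sum(w))

    if np.isfinite(group_se.get("LOW", np.nan)) and np.isfinite(group_se.get("HIGH", np.nan)):
        z = (group_slope["HIGH"] - group_slope["LOW"]) / np.hypot(
            group_se["HIGH"], group_se["LOW"]
        )
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        z, p = float("nan"), float("nan")
    return SequentialEffect(
        subject_slopes=slopes,
        subject_se=ses,
        subject_intercepts=intercepts,
        group_slope=group_slope,
        group_slope_se=group_se,
        group_intercept=group_int,
        diff_stat=float(z),
        diff_p=p,
        excluded_subjects=excluded,
    )


# ----------------------------------------------------------------------------
# prewhitening and lagged cross-correlation
# ----------------------------------------------------------------------------

@dataclass
class PrewhitenResult:
    te: np.ndarray
    mv: np.ndarray
    ar_order: int
    differenced: bool  # True when a near-unit-root fit forced first differencing
    phi: np.ndarray = field(default_factory=lambda: np.empty(0))  # AR lag coefficients


def _select_ar_order(x: np.ndarray, max_order: int) -> tuple[int, np.ndarray]:
    """AR order by AIC (0..max_order) and the fitted lag coefficients."""
    from statsmodels.tsa.ar_model import AutoReg, ar_select_order

    max_order = min(max_order, x.size // 4)
    if max_order < 1:
        return 0, np.empty(0)
    sel = ar_select_order(x, maxlag=max_order, ic="aic", trend="c")
    lags = sel.ar_lags
    if not lags:
        return 0, np.empty(0)
    order = int(max(lags))
    fit = AutoReg(x, lags=order, trend="c").fit()
    phi = np.asarray(fit.params[1:], dtype=float)
    return order, phi


def prewhiten_pair(
    te: np.ndarray, mv: np.ndarray, max_order: int = 10
) -> PrewhitenResult:
    """Remove serial structure before cross-correlating.

    One AR model is fitted to the TE series (order by AIC up to
    ``max_order``); both series are filtered with the same coefficients and
    the first ``order`` samples dropped — the standard prewhitening contract,
    which leaves cross-dependence interpretable at face-value lags.  If the
    fitted AR polynomial is near unit root the filter is ill-conditioned and
    both series are first-differenced instead (flagged).
    """
    te = np.asarray(te, dtype=float)
    mv = np.asarray(mv, dtype=float)
    if te.size != mv.size:
        raise ValueError("series must be the same length")
    if te.size < 40:
        raise TooFewTrialsError("need at least 40 trials to prewhiten")

    order, phi = _select_ar_order(te, max_order)
    if order == 0:
        return PrewhitenResult(te=te.copy(), mv=mv.copy(), ar_order=0, differenced=False)

    # stationarity check: roots of 1 - phi_1 z - ... - phi_p z^p
    roots = np.roots(np.r_[-phi[::-1], 1.0])
    if roots.size and np.min(np.abs(roots)) < 1.05:
        return PrewhitenResult(
            te=np.diff(te), mv=np.diff(mv), ar_order=order, differenced=True, phi=phi
        )
    kernel = np.r_[1.0, -phi]
    te_w = lfilter(kernel, [1.0], te - te.mean())[order:]
    mv_w = lfilter(kernel, [1.0], mv - mv.mean())[order:]
    return PrewhitenResult(te=te_w, mv=mv_w, ar_order=order, differenced=False, phi=phi)


def prewhiten_gappy(
    te: np.ndarray, mv: np.ndarray, max_order: int = 10
) -> PrewhitenResult:
    """Segment-wise prewhitening for series with NaN gaps (excluded trials).

    The AR model is fitted on the longest contiguous finite run; every run
    longer than the order is filtered with those coefficients, with the first
    ``order`` samples of each run (and the gaps themselves) left as NaN so
    that downstream lag pairing never spans a gap.
    """
    te = np.asarray(te, dtype=float)
    mv = np.asarray(mv, dtype=float)
    finite = np.isfinite(te) & np.isfinite(mv)
    if finite.all():
        return prewhiten_pair(te, mv, max_order)
    # contiguous finite runs
    edges = np.flatnonzero(np.diff(np.r_[0, finite.view(np.int8), 0]))
    runs = list(zip(edges[::2], edges[1::2]))
    longest = max(runs, key=lambda r: r[1] - r[0])
    ref = prewhiten_pair(te[longest[0]:longest[1]], mv[longest[0]:longest[1]], max_order)
    order = ref.ar_order
    te_mean = float(np.mean(te[finite]))
    mv_mean = float(np.mean(mv[finite]))
    out_te = np.full_like(te, np.nan)
    out_mv = np.full_like(mv, np.nan)
    for s, e in runs:
        if order == 0 and not ref.differenced:
            out_te[s:e] = te[s:e]
            out_mv[s:e] = mv[s:e]
        elif ref.differenced:
            if e - s >= 2:
                out_te[s + 1:e] = np.diff(te[s:e])
                out_mv[s + 1:e] = np.diff(mv[s:e])
        elif e - s > order + 1:
            kernel = np.r_[1.0, -ref.phi]
            out_te[s + order:e] = lfilter(kernel, [1.0], te[s:e] - te_mean)[order:]
            out_mv[s + order:e] = lfilter(kernel, [1.0], mv[s:e] - mv_mean)[order:]
    return PrewhitenResult(
        te=out_te, mv=out_mv, ar_order=order, differenced=ref.differenced, phi=ref.phi
    )


@dataclass
class CcfProfile:
    subject_id: str
    lags: tuple[int, ...]
    ccf: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    ar_order_te: int
    n_pairs: np.ndarray


def lagged_ccf(
    te_w: np.ndarray,
    mv_w: np.ndarray,
    lags: tuple[int, ...] = (0, 1, 2, 3),
    n_boot: int = 1000,
    seed: int = 0,
    subject_id: str = "",
    ar_order_te: int = 0,
) -> CcfProfile:
    """Pearson correlation of TE(t) with Mv(t+k) for each lag k, with 95%
    percentile bootstrap CIs from resampling whitened pairs with replacement
    (valid because prewhitening removed the serial structure)."""
    te_w = np.asarray(te_w, dtype=float)
    mv_w = np.asarray(mv_w, dtype=float)
    rng = np.random.default_rng(seed)
    ccf = np.empty(len(lags))
    lo = np.empty(len(lags))
    hi = np.empty(len(lags))
    npairs = np.empty(len(lags), dtype=int)
    for j, k in enumerate(lags):
        a = te_w[: te_w.size - k] if k > 0 else te_w
        b = mv_w[k:]
        n = min(a.size, b.size)
        a, b = a[:n], b[:n]
        finite = np.isfinite(a) & np.isfinite(b)  # NaNs mark gaps; pairs spanning one are dropped
        a, b = a[finite], b[finite]
        n = a.size
        if n < 20:
            raise TooFewTrialsError(f"fewer than 20 pairs at lag {k}")
        npairs[j] = n
        ccf[j] = float(stats.pearsonr(a, b).statistic)
        idx = rng.integers(0, n, size=(n_boot, n))
        ab = a[idx]
        bb = b[idx]
        am = ab - ab.mean(axis=1, keepdims=True)
        bm = bb - bb.mean(axis=1, keepdims=True)
        denom = np.sqrt((am**2).sum(axis=1) * (bm**2).sum(axis=1))
        rs = (am * bm).sum(axis=1) / np.where(denom == 0, np.nan, denom)
        lo[j], hi[j] = np.nanpercentile(rs, [2.5, 97.5])
    return CcfProfile(
        subject_id=subject_id, lags=tuple(lags), ccf=ccf, ci_low=lo, ci_high=hi,
        ar_order_te=ar_order_te, n_pairs=npairs,
    )


def ccf_score_correlation(
    profiles: dict[str, CcfProfile], scores: dict[str, float]
) -> pd.DataFrame:
    """Pearson and Spearman correlation, per lag, between subjects' ccf values
    and their Adaptation Scores."""
    sids = [s for s in profiles if s in scores]
    if len(sids) < 5:
        raise TooFewTrialsError("need at least 5 matched subjects")
    lags = profiles[sids[0]].lags
    sc = np.array([scores[s] for s in sids], dtype=float)
    rows = []
    for j, k in enumerate(lags):
        c = np.array([profiles[s].ccf[j] for s in sids], dtype=float)
        if np.ptp(c) == 0.0:
            raise DegenerateDataError(f"ccf constant across subjects at lag {k}")
        pr = stats.pearsonr(c, sc)
        sr = stats.spearmanr(c, sc)
        rows.append(
            {
                "lag": k,
                "pearson_r": float(pr.statistic),
                "pearson_p": float(pr.pvalue),
                "spearman_r": float(sr.statistic),
                "spearman_p": float(sr.pvalue),
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------------
# LASSO predictor selection
# ----------------------------------------------------------------------------

@dataclass
class LassoResult:
    lam: float
    predictors: list[str]
    beta: np.ndarray  # original-scale coefficients (0 = dropped)
    intercept: float
    ci_low: np.ndarray
    ci_high: np.ndarray
    note: str = (
        "L1 penalization biases coefficients; bootstrap CIs describe "
        "variability of the penalized estimate and should be interpreted "
        "with caution regarding significance."
    )

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictor": self.predictors,
                "beta": self.beta,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "included": self.beta != 0.0,
            }
        )


def _lasso_beta(X: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """Penalized coefficients on the original predictor scale.

    Objective (glmnet convention): (1/2n)||y_c - Xs b||^2 + lam * ||b||_1 with
    predictors standardized to unit (population) SD and the response centered;
    lam = 0 reduces to ordinary least squares.
    """
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise DegenerateDataError("predictor with zero variance")
    Xs = (X - mu) / sd
    ym = float(np.mean(y))
    yc = y - ym
    if lam == 0.0:
        bs, *_ = np.linalg.lstsq(Xs, yc, rcond=None)
    else:
        model = Lasso(alpha=lam, fit_intercept=False, max_iter=200000, tol=1e-12)
        model.fit(Xs, yc)
        bs = model.coef_
    beta = bs / sd
    intercept = ym - float(mu @ beta)
    return beta, intercept


def lasso_fit(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    lam: float,
    n_boot: int = 1000,
    seed: int = 0,
) -> LassoResult:
    """L1-penalized least squares with row-resampling bootstrap CIs.

    Predictors are standardized before penalization and coefficients reported
    on the original scale; each bootstrap replicate re-standardizes and refits
    at the same penalty.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(Xa.shape[1])]
    ya = np.asarray(y, dtype=float)
    beta, intercept = _lasso_beta(Xa, ya, lam)

    rng = np.random.default_rng(seed)
    n = Xa.shape[0]
    if n_boot > 0:
        boots = np.empty((n_boot, Xa.shape[1]))
        for i in range(n_boot):
            idx = rng.integers(0, n, size=n)
            try:
                boots[i], _ = _lasso_beta(Xa[idx], ya[idx], lam)
            except DegenerateDataError:
                boots[i] = np.nan
        lo = np.nanpercentile(boots, 2.5, axis=0)
        hi = np.nanpercentile(boots, 97.5, axis=0)
    else:
        lo = np.full(Xa.shape[1], np.nan)
        hi = np.full(Xa.shape[1], np.nan)
    return LassoResult(
        lam=lam, predictors=names, beta=beta, intercept=intercept, ci_low=lo, ci_high=hi
    )


def te_model_design(
    frame: pd.DataFrame, split: GroupSplit, phase: str
) -> tuple[pd.DataFrame, np.ndarray]:
    """Design for the within-trial TE models of one phase.

    Main effects Ma (deg), Mv (cm/s), tv (cm/s), HIGH-group indicator, T (s)
    and all pairwise interactions; response is TE in ms, pooled across
    subjects' valid trials.
    """
    df = frame[(frame["phase"] == phase) & frame["valid"]].copy()
    df["HIGH"] = df["subject_id"].map(split.labels).eq("HIGH").astype(float)
    main = ["Ma", "Mv", "tv", "HIGH", "T"]
    X = df[main].copy()
    for i in range(len(main)):
        for j in range(i + 1, len(main)):
            X[f"{main[i]}:{main[j]}"] = df[main[i]] * df[main[j]]
    y = df["TE"].to_numpy(dtype=float) * 1000.0  # ms
    return X, y


def score_model_design(
    sigma2_mv: dict[str, float], sigma2_ma: dict[str, float], scores: dict[str, float]
) -> tuple[pd.DataFrame, np.ndarray]:
    """Design for the Adaptation Score model: sigma^2(Mv), sigma^2(Ma) and
    their product, one row per subject."""
    sids = sorted(s for s in scores if s in sigma2_mv and s in sigma2_ma)
    X = pd.DataFrame(
        {
            "sigma2_Mv": [sigma2_mv[s] for s in sids],
            "sigma2_Ma": [sigma2_ma[s] for s in sids],
            "sigma2_Mv:sigma2_Ma": [sigma2_mv[s] * sigma2_ma[s] for s in sids],
        },
        index=sids,
    )
    y = np.array([scores[s] for s in sids], dtype=float)
    return X, y
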