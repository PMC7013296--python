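"""Discrimination statistics for the FFR <= 0.8 endpoint.

Covers the battery used to evaluate the MMAR/MLD index: Pearson correlation,
Mann-Whitney U and chi-squared group tests, ROC analysis with DeLong
variance (single AUC confidence interval and correlated-AUC comparison),
Youden-optimal cut-off with the full 2x2 diagnostic metrics, logistic risk
models, and continuous net reclassification improvement (NRI) / integrated
discrimination improvement (IDI) between a base and an extended model.

Conventions, applied throughout: two-sided p-values; predicted-positive when
score >= threshold; quartiles by linear interpolation between order
statistics (type 7); DeLong confidence intervals on the logit scale, then
back-transformed so the bounds stay inside [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps
from scipy.special import expit, logit

Z95 = sps.norm.ppf(0.975)


# ----------------------------------------------------------------- basic tests
def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with its t-distribution p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Mann-Whitney U with midranks for ties.

    Orientation: U counts (a > b) pairs plus half of the ties, so a group
    ``a`` lying entirely below ``b`` gives U = 0.  The p-value is exact
    (network enumeration) when n_a * n_b <= 400 and there are no ties,
    otherwise a tie-corrected normal approximation without continuity
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) * len(b) <= 400 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)


def chi_squared(table) -> tuple[float, float]:
    """Pearson chi-squared test of independence, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    stat, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def summarize_group(values, group) -> dict:
    """Median (Q1-Q3) per group plus the Mann-Whitney p-value.

    ``group`` is boolean; True rows form group 1.  Quartiles use linear
    interpolation between order statistics.
    """
    values = np.asarray(values, dtype=float)
    group = np.asarray(group, dtype=bool)
    g1, g0 = values[group], values[~group]
    if len(g1) == 0 or len(g0) == 0:
        raise ValueError("both groups must be non-empty")
    out = {}
    for name, v in (("all", values), ("group1", g1), ("group0", g0)):
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        out[name] = {"median": float(med), "q1": float(q1), "q3": float(q3), "n": len(v)}
    _, p = mann_whitney_u(g1, g0)
    out["p_value"] = p
    return out


# ------------------------------------------------------------------------- ROC
@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    var: float                 # DeLong variance of the AUC
    thresholds: np.ndarray     # descending candidate cut-offs
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_pos: int
    n_neg: int


def _check_binary(labels) -> np.ndarray:
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    return labels


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components (V10 per positive, V01 per negative).

    psi(x, y) = 1 if x > y, 1/2 if tie, 0 otherwise; midranks evaluate all
    pairwise comparisons in O(n log n).
    """
    pos, neg = scores[labels], scores[~labels]
    m, n = len(pos), len(neg)
    all_r = sps.rankdata(np.concatenate([pos, neg]))
    pos_r, neg_r = sps.rankdata(pos), sps.rankdata(neg)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return v10, v01


def roc_auc(scores, labels) -> RocResult:
    """AUC (tie-adjusted Mann-Whitney scaling) with a DeLong 95% CI.

    The CI is computed on the logit scale and back-transformed; degenerate
    zero-variance cases (e.g. AUC exactly 1) collapse to a point interval
    with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    v10, v01 = _delong_components(scores, labels)
    m, n = int(labels.sum()), int((~labels).sum())
    auc = float(v10.mean())
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    if var <= 0 or auc in (0.0, 1.0):
        if var <= 0:
            warnings.warn("degenerate DeLong variance; point interval", stacklevel=2)
        lo = hi = auc
        var = max(var, 0.0)
    else:
        se_logit = np.sqrt(var) / (auc * (1 - auc))
        lo = float(expit(logit(auc) - Z95 * se_logit))
        hi = float(expit(logit(auc) + Z95 * se_logit))
    thr = np.unique(scores)[::-1]
    pos, neg = scores[labels], scores[~labels]
    sens = (pos[None, :] >= thr[:, None]).mean(axis=1)
    spec = (neg[None, :] < thr[:, None]).mean(axis=1)
    return RocResult(
        auc=auc, ci_low=lo, ci_high=hi, var=float(var),
        thresholds=thr, sensitivity=sens, specificity=spec, n_pos=m, n_neg=n,
    )


def delong_compare(scores_a, scores_b, labels) -> tuple[float, float, float, float]:
    """Compare two correlated AUCs measured on the same cases (DeLong test).

    Returns (auc_a, auc_b, z, p).  The variance of the difference uses the
    full 2x2 covariance of the structural components.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = _check_binary(labels)
    if len(scores_a) != len(scores_b) or len(scores_a) != len(labels):
        raise ValueError("score vectors and labels must align")
    v10a, v01a = _delong_components(scores_a, labels)
    v10b, v01b = _delong_components(scores_b, labels)
    m, n = len(v10a), len(v01a)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        z = 0.0
        p = 1.0 if np.isclose(auc_a, auc_b) else 0.0
    else:
        z = (auc_a - auc_b) / np.sqrt(var_diff)
        p = float(2 * sps.norm.sf(abs(z)))
    return auc_a, auc_b, float(z), p


@dataclass
class CutoffMetrics:
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    youden: float


def youden_cutoff(roc: RocResult, criterion: str = "youden") -> CutoffMetrics:
    """Optimal cut-off from a RocResult's per-threshold metrics.

    ``criterion``: "youden" maximizes sensitivity + specificity - 1 (ties go
    to the lowest cut-off); "closest" minimizes the distance to the (0, 1)
    corner of ROC space.  PPV/NPV come from the 2x2 table at the chosen
    cut-off on the same data (NaN when a margin is empty).
    """
    sens, spec = roc.sensitivity, roc.specificity
    if criterion == "youden":
        obj = sens + spec - 1.0
        best = int(np.flatnonzero(obj == obj.max())[-1])  # thresholds descend
    elif criterion == "closest":
        d2 = (1.0 - sens) ** 2 + (1.0 - spec) ** 2
        best = int(np.flatnonzero(d2 == d2.min())[-1])
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    tp = sens[best] * roc.n_pos
    fn = roc.n_pos - tp
    tn = spec[best] * roc.n_neg
    fp = roc.n_neg - tn
    ppv = tp / (tp + fp) if tp + fp > 0 else float("nan")
    npv = tn / (tn + fn) if tn + fn > 0 else float("nan")
    return CutoffMetrics(
        cutoff=float(roc.thresholds[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        ppv=float(ppv),
        npv=float(npv),
        youden=float(sens[best] + spec[best] - 1.0),
    )


# -------------------------------------------------------------- risk modelling
@dataclass
class LogisticFit:
    coef: np.ndarray           # intercept first
    fitted: np.ndarray         # predicted probabilities
    converged: bool
    separation: bool


def logistic_fit(design, outcome) -> LogisticFit:
    """Maximum-likelihood logistic regression via iteratively reweighted LS.

    ``design`` holds the covariate columns (no intercept column; one is
    prepended).  Perfect or quasi-perfect separation is flagged rather than
    raised; the returned coefficients are then the last IRLS iterate.
    """
    import statsmodels.api as sm

    X = np.column_stack([np.ones(len(outcome)), np.asarray(design, dtype=float)])
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need n > number of parameters")
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(maxiter=100, tol=1e-8)
        for w in caught:
            if "separat" in str(w.message).lower():
                separation = True
    fitted = np.asarray(res.fittedvalues)
    if np.any(fitted < 1e-10) or np.any(fitted > 1 - 1e-10):
        separation = True
    if separation:
        warnings.warn("separation detected in logistic fit", stacklevel=2)
    return LogisticFit(
        coef=np.asarray(res.params),
        fitted=fitted,
        converged=bool(res.converged),
        separation=separation,
    )


# ------------------------------------------------------------- reclassification
@dataclass
class ReclassificationResult:
    nri: float
    nri_ci: tuple[float, float]
    nri_p: float
    idi: float
    idi_ci: tuple[float, float]
    idi_p: float


def reclassification(base_probs, extended_probs, labels) -> ReclassificationResult:
    """Continuous (category-free) NRI and IDI from base to extended model.

    NRI = [P(up|event) - P(down|event)] + [P(down|non-event) - P(up|non-event)]
    with up/down meaning the extended probability is strictly greater/less
    than the base probability; IDI is the increase in discrimination slope
    (mean predicted risk in events minus non-events).  CIs and p-values use
    the asymptotic variance of the component proportions/means.
    """
    p0 = np.asarray(base_probs, dtype=float)
    p1 = np.asarray(extended_probs, dtype=float)
    labels = _check_binary(labels)
    if len(p0) != len(p1) or len(p0) != len(labels):
        raise ValueError("probability vectors and labels must align")
    if ((p0 < 0) | (p0 > 1) | (p1 < 0) | (p1 > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")

    d = p1 - p0
    de, dn = d[labels], d[~labels]
    ne, nn = len(de), len(dn)

    up_e, down_e = float((de > 0).mean()), float((de < 0).mean())
    up_n, down_n = float((dn > 0).mean()), float((dn < 0).mean())
    nri = (up_e - down_e) + (down_n - up_n)
    var_e = (up_e + down_e - (up_e - down_e) ** 2) / ne
    var_n = (up_n + down_n - (down_n - up_n) ** 2) / nn
    se_nri = np.sqrt(var_e + var_n)
    nri_p = float(2 * sps.norm.sf(abs(nri) / se_nri)) if se_nri > 0 else 1.0

    # computed as the slope difference itself so the identity holds exactly
    idi = float(
        (p1[labels].mean() - p1[~labels].mean())
        - (p0[labels].mean() - p0[~labels].mean())
    )
    se_idi = np.sqrt(
        (np.var(de, ddof=1) / ne if ne > 1 else 0.0)
        + (np.var(dn, ddof=1) / nn if nn > 1 else 0.0)
    )
    idi_p = float(2 * sps.norm.sf(abs(idi) / se_idi)) if se_idi > 0 else 1.0

    return ReclassificationResult(
        nri=float(nri),
        nri_ci=(float(nri - Z95 * se_nri), float(nri + Z95 * se_nri)),
        nri_p=nri_p,
        idi=idi,
        idi_ci=(float(idi - Z95 * se_idi), float(idi + Z95 * se_idi)),
        idi_p=idi_p,
    )


def categorical_nri(base_probs, extended_probs, labels, thresholds) -> float:
    """NRI over user-supplied risk categories (movement across bin edges)."""
    edges = np.asarray(sorted(thresholds), dtype=float)
    c0 = np.digitize(np.asarray(base_probs, dtype=float), edges)
    c1 = np.digitize(np.asarray(extended_probs, dtype=float), edges)
    labels = _check_binary(labels)
    move = np.sign(c1 - c0)
    ev, ne = move[labels], move[~labels]
    return float(((ev > 0).mean() - (ev < 0).mean()) + ((ne < 0).mean() - (ne > 0).mean()))
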