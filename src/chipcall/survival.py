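"""Survival and association statistics, implemented from first principles.

Contents:

* Kaplan-Meier product-limit curves with Greenwood variance and log-log
  confidence bands;
* the k-sample log-rank test (overall and pairwise, unadjusted);
* stratified Cox proportional-hazards regression maximising the stratified
  partial likelihood by Newton-Raphson with the Efron tie correction;
* the Aalen-Johansen cumulative-incidence estimator for competing risks
  (here: therapy-related myeloid neoplasm with death as the competing,
  absorbing event) and Gray's k-sample test on subdistribution hazards;
* Fisher's exact test (two-sided, by hypergeometric enumeration), the
  Wilcoxon rank-sum test (exact for small samples, tie-corrected normal
  approximation otherwise) and a Jonckheere-Terpstra ordered-trend test.

Established packages (lifelines, R's survival/cmprsk) implement the same
estimators; they are used as independent cross-checks in the test suite,
never as the implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class TestResult:
    name: str
    statistic: float
    pvalue: float
    df: Optional[int] = None
    extra: dict = field(default_factory=dict)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        df = f", df={self.df}" if self.df is not None else ""
        return (f"TestResult({self.name}: stat={self.statistic:.4g}{df}, "
                f"p={self.pvalue:.4g})")


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit estimate at the distinct event times."""

    times: np.ndarray          # distinct times with >= 1 event
    n_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    variance: np.ndarray       # Greenwood
    ci_lower: np.ndarray       # log-log 95% band
    ci_upper: np.ndarray
    n_subjects: int
    median: float              # nan when the curve never reaches 0.5
    median_defined: bool

    def survival_at(self, t) -> np.ndarray:
        """Step-function lookup S(t) (right-continuous)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if len(self.times) == 0:
            return np.ones_like(t)
        idx = np.searchsorted(self.times, t, side="right") - 1
        return np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times, "n_risk": self.n_risk,
            "n_events": self.n_events, "survival": self.survival,
            "std_err": np.sqrt(self.variance),
            "ci_lower": self.ci_lower, "ci_upper": self.ci_upper,
        })


def _km_single(times: np.ndarray, events: np.ndarray) -> KMCurve:
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    n = len(times)
    distinct, first_idx = np.unique(times, return_index=True)
    n_risk_all = n - first_idx          # at risk just before each distinct time
    d = np.array([events[times == t].sum() for t in distinct], dtype=float)
    keep = d > 0
    t_ev, n_ev, d_ev = distinct[keep], n_risk_all[keep].astype(float), d[keep]
    frac = np.where(n_ev > 0, 1.0 - d_ev / n_ev, 1.0)
    surv = np.cumprod(frac)
    # Greenwood: var(S) = S^2 * cumsum d / (n (n - d))
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = np.where(n_ev > d_ev, d_ev / (n_ev * (n_ev - d_ev)), np.inf)
    gw = np.cumsum(gw_terms)
    with np.errstate(invalid="ignore"):
        var = np.where(surv > 0, surv ** 2 * gw, 0.0)
    lo, hi = _loglog_ci(surv, var)
    below = surv <= 0.5 + 1e-12
    median_defined = bool(below.any())
    median = float(t_ev[below][0]) if median_defined else float("nan")
    return KMCurve(times=t_ev, n_risk=n_ev, n_events=d_ev, survival=surv,
                   variance=var, ci_lower=lo, ci_upper=hi, n_subjects=n,
                   median=median, median_defined=median_defined)


def _loglog_ci(surv, var):
    lo = np.empty_like(surv)
    hi = np.empty_like(surv)
    with np.errstate(divide="ignore", invalid="ignore"):
        for i, (s, v) in enumerate(zip(surv, var)):
            if s <= 0.0:
                lo[i] = hi[i] = 0.0
            elif s >= 1.0:
                lo[i] = hi[i] = 1.0
            else:
                se_ll = np.sqrt(v) / abs(s * np.log(s))
                theta = np.log(-np.log(s))
                lo[i] = np.exp(-np.exp(theta + Z95 * se_ll))
                hi[i] = np.exp(-np.exp(theta - Z95 * se_ll))
    return lo, hi


def km_fit(times, events, group=None):
    """Kaplan-Meier curves; one curve, or a dict of curves per group level.

    All-censored input gives a flat S(t)=1 curve with an undefined median.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) < 1:
        raise ValidationError("need at least one subject")
    if (times < 0).any():
        raise ValidationError("negative event times")
    if group is None:
        return _km_single(times, events)
    group = np.asarray(group)
    return {g: _km_single(times[group == g], events[group == g])
            for g in pd.unique(group)}


def km_long_frame(curves: Mapping[str, KMCurve]) -> pd.DataFrame:
    """Long-format step data for plotting (group, time, survival, CI...)."""
    frames = []
    for g, c in curves.items():
        f = c.to_frame()
        f.insert(0, "group", g)
        frames.append(f)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def _logrank_core(times, events, group, levels) -> tuple[float, int]:
    k = len(levels)
    gidx = {g: i for i, g in enumerate(levels)}
    gi = np.array([gidx[g] for g in group])
    ev_times = np.unique(times[events == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in ev_times:
        at_risk = times >= t
        n = at_risk.sum()
        if n == 0:
            continue
        nj = np.bincount(gi[at_risk], minlength=k).astype(float)
        dead = at_risk & (times == t) & (events == 1)
        d = dead.sum()
        dj = np.bincount(gi[dead], minlength=k).astype(float)
        O += dj
        E += d * nj / n
        if n > 1:
            factor = d * (n - d) / (n - 1)
            V += factor * (np.diag(nj) / n - np.outer(nj, nj) / n ** 2)
    z = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    try:
        stat = float(z @ np.linalg.solve(Vsub, z))
    except np.linalg.LinAlgError:
        stat = float(z @ np.linalg.pinv(Vsub) @ z)
    return max(stat, 0.0), k - 1


def logrank(times, events, group, pairwise: bool = False):
    """k-sample log-rank test; optionally all pairwise tests, unadjusted.

    Returns a :class:`TestResult`, or (overall, {pair: TestResult}) when
    ``pairwise`` is requested. Empty groups are dropped with a warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group)
    levels = [g for g in pd.unique(group) if (group == g).sum() > 0]
    if len(levels) < len(pd.unique(group)):  # pragma: no cover - defensive
        warnings.warn("dropped empty group level(s)")
    if len(levels) < 2:
        raise ValidationError("log-rank needs >= 2 non-empty groups")
    stat, df = _logrank_core(times, events, group, levels)
    overall = TestResult("logrank", stat, float(stats.chi2.sf(stat, df)), df)
    if not pairwise:
        return overall
    pairs = {}
    for a, b in combinations(levels, 2):
        mask = (group == a) | (group == b)
        s, d = _logrank_core(times[mask], events[mask], group[mask], [a, b])
        pairs[(a, b)] = TestResult(f"logrank[{a} vs {b}]", s,
                                   float(stats.chi2.sf(s, d)), d)
    return overall, pairs


# ---------------------------------------------------------------------------
# stratified Cox (Efron ties)
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    grad_norm: float
    n: int
    n_events: int
    n_strata: int
    warnings: list[str] = field(default_factory=list)

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci(self) -> tuple[np.ndarray, np.ndarray]:
        return (np.exp(self.coef - Z95 * self.se),
                np.exp(self.coef + Z95 * self.se))

    def summary(self) -> pd.DataFrame:
        lci, uci = self.ci
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(self.se > 0, self.coef / self.se, 0.0)
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame({
            "term": self.terms, "coef": self.coef, "hr": self.hr,
            "se": self.se, "lci": lci, "uci": uci, "z": z, "p": p,
        })


def _revcumsum(a: np.ndarray) -> np.ndarray:
    return np.cumsum(a[::-1], axis=0)[::-1]


def _stratum_quantities(X, times, events, beta):
    """(loglik, grad, info) contributions of one stratum under Efron ties."""
    order = np.argsort(times, kind="stable")
    X, times, events = X[order], times[order], events[order]
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -200, 200)
    w = np.exp(eta)
    xw = X * w[:, None]
    xxw = X[:, :, None] * X[:, None, :] * w[:, None, None]
    S0 = _revcumsum(w)
    S1 = _revcumsum(xw)
    S2 = _revcumsum(xxw)
    distinct, first_idx = np.unique(times, return_index=True)
    loglik = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    for t, i0 in zip(distinct, first_idx):
        dead = (times == t) & (events == 1)
        d = int(dead.sum())
        if d == 0:
            continue
        s0, s1, s2 = S0[i0], S1[i0], S2[i0]
        s0d = w[dead].sum()
        s1d = xw[dead].sum(axis=0)
        s2d = xxw[dead].sum(axis=0)
        loglik += eta[dead].sum()
        grad += X[dead].sum(axis=0)
        for l in range(d):
            f = l / d
            phi = s0 - f * s0d
            psi1 = s1 - f * s1d
            psi2 = s2 - f * s2d
            loglik -= np.log(phi)
            grad -= psi1 / phi
            info += psi2 / phi - np.outer(psi1, psi1) / phi ** 2
    return loglik, grad, info


def cox_stratified(X, times, events, strata=None, max_iter: int = 50,
                   tol: float = 1e-8) -> CoxFit:
    """Stratified Cox regression via Newton-Raphson on the stratified
    partial likelihood (Efron tie correction).

    ``X`` is a DataFrame (column names become coefficient names) or 2-d
    array. ``strata`` is a per-subject label (e.g. the cross-classification
    of age group x ISS x prior lines); strata without events contribute
    nothing. Wald CIs are exp(b +/- 1.96 se). Monotone likelihood
    (separation) is flagged, not raised; a singular information matrix with
    a non-zero gradient raises an error naming the offending column.
    """
    if isinstance(X, pd.DataFrame):
        terms = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        if Xv.ndim == 1:
            Xv = Xv[:, None]
        terms = [f"x{i}" for i in range(Xv.shape[1])]
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n, p = Xv.shape
    if strata is None:
        strata = np.zeros(n, dtype=int)
    strata = np.asarray(strata)
    if events.sum() < 1:
        raise ValidationError("no events in any stratum")

    groups = []
    for s in pd.unique(strata):
        m = strata == s
        if events[m].sum() > 0:
            groups.append((Xv[m], times[m], events[m]))

    beta = np.zeros(p)
    warns: list[str] = []
    loglik = grad = info = None

    def evaluate(b):
        ll, g, I = 0.0, np.zeros(p), np.zeros((p, p))
        for Xs, ts, es in groups:
            l_, g_, I_ = _stratum_quantities(Xs, ts, es, b)
            ll += l_
            g += g_
            I += I_
        return ll, g, I

    loglik, grad, info = evaluate(beta)
    n_iter = 0
    converged = np.max(np.abs(grad)) < tol
    while not converged and n_iter < max_iter:
        n_iter += 1
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            if np.max(np.abs(grad)) < 1e-6:
                break
            bad = terms[int(np.argmin(np.diag(info)))]
            raise ValidationError(
                f"singular information matrix (column '{bad}')")
        new_beta = beta + step
        new_ll, new_grad, new_info = evaluate(new_beta)
        halvings = 0
        while new_ll < loglik - 1e-12 and halvings < 25:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_info = evaluate(new_beta)
            halvings += 1
        beta, loglik, grad, info = new_beta, new_ll, new_grad, new_info
        converged = np.max(np.abs(grad)) < tol
    if np.max(np.abs(beta)) > 15:
        warns.append("diverging coefficient: possible monotone likelihood "
                     "(separation)")
    if not converged and np.max(np.abs(grad)) < 1e-6:
        converged = True  # flat likelihood (e.g. no within-stratum contrast)

    diag = np.diag(info)
    if np.any(diag <= 1e-12):
        se = np.full(p, np.inf)
        ok = diag > 1e-12
        if ok.any():
            sub = np.linalg.pinv(info[np.ix_(ok, ok)])
            se[ok] = np.sqrt(np.diag(sub))
        warns.append("information matrix is singular; SEs partially undefined")
    else:
        try:
            cov = np.linalg.inv(info)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            bad = terms[int(np.argmin(diag))]
            raise ValidationError(
                f"singular information matrix (column '{bad}')")
    return CoxFit(terms=terms, coef=beta, se=se, loglik=float(loglik),
                  converged=bool(converged), n_iter=n_iter,
                  grad_norm=float(np.max(np.abs(grad))), n=n,
                  n_events=int(events.sum()), n_strata=len(groups),
                  warnings=warns)


# ---------------------------------------------------------------------------
# competing risks: Aalen-Johansen + Gray's test
# ---------------------------------------------------------------------------

@dataclass
class CIFResult:
    """Cumulative incidence per cause, with event-free survival, such that
    EFS(t) + sum_k CIF_k(t) = 1 at every time (Aalen-Johansen identity)."""

    times: np.ndarray
    n_risk: np.ndarray
    efs: np.ndarray
    cif: dict[int, np.ndarray]
    n_subjects: int

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.times, "n_risk": self.n_risk, "efs": self.efs}
        for k, v in self.cif.items():
            data[f"cif_{k}"] = v
        return pd.DataFrame(data)

    def cif_at(self, cause: int, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        vals = self.cif[cause]
        return np.where(idx < 0, 0.0, vals[np.clip(idx, 0, None)])


def _aj_single(times, event_type, causes) -> CIFResult:
    order = np.argsort(times, kind="stable")
    times, event_type = times[order], event_type[order]
    n = len(times)
    distinct = np.unique(times[event_type > 0])
    n_risk = np.empty(len(distinct))
    efs = np.empty(len(distinct))
    cif = {k: np.empty(len(distinct)) for k in causes}
    s_prev = 1.0
    acc = {k: 0.0 for k in causes}
    for i, t in enumerate(distinct):
        at_risk = (times >= t).sum()
        d_all = ((times == t) & (event_type > 0)).sum()
        for k in causes:
            d_k = ((times == t) & (event_type == k)).sum()
            acc[k] += s_prev * d_k / at_risk
            cif[k][i] = acc[k]
        s_prev *= 1.0 - d_all / at_risk
        n_risk[i] = at_risk
        efs[i] = s_prev
    return CIFResult(times=distinct, n_risk=n_risk, efs=efs, cif=cif,
                     n_subjects=n)


def cif_aalen_johansen(times, event_type, group=None):
    """Aalen-Johansen cumulative incidence per cause (0 = censored; positive
    integers are competing causes, e.g. 1 = TMN, 2 = death)."""
    times = np.asarray(times, dtype=float)
    event_type = np.asarray(event_type, dtype=int)
    if (event_type < 0).any():
        raise ValidationError("event_type must be >= 0 (0 = censored)")
    causes = sorted(int(k) for k in np.unique(event_type) if k > 0)
    if group is None:
        return _aj_single(times, event_type, causes)
    group = np.asarray(group)
    return {g: _aj_single(times[group == g], event_type[group == g], causes)
            for g in pd.unique(group)}


def _left_limit(step_times, step_vals, t, init):
    """Value of a right-continuous step function just before t."""
    idx = np.searchsorted(step_times, t, side="left") - 1
    return init if idx < 0 else step_vals[idx]


def gray_test(times, event_type, group, cause: int = 1,
              rho: float = 0.0) -> TestResult:
    """Gray's k-sample test comparing the subdistribution hazard of one
    cause across groups.

    Subjects who fail from a competing cause remain in the cause-specific
    risk set with the weight Y_j(t)(1-F_kj(t-))/S_j(t-) (Gray's modified
    risk set); the chi-square statistic uses log-rank-style
    observed-minus-expected sums on those weighted risk sets, so it reduces
    exactly to the log-rank test when no competing events are present.
    """
    times = np.asarray(times, dtype=float)
    event_type = np.asarray(event_type, dtype=int)
    group = np.asarray(group)
    levels = [g for g in pd.unique(group) if (group == g).sum() > 0]
    if len(levels) < 2:
        raise ValidationError("Gray's test needs >= 2 non-empty groups")
    k = len(levels)
    per_group = {}
    for g in levels:
        m = group == g
        aj = _aj_single(times[m], event_type[m],
                        sorted(int(c) for c in np.unique(event_type) if c > 0))
        # all-cause survival left-limits need S including the last step: efs
        per_group[g] = (times[m], event_type[m], aj)

    ev_times = np.unique(times[event_type == cause])
    z = np.zeros(k)
    V = np.zeros((k, k))
    # pooled weight for rho != 0
    pooled = _aj_single(times, event_type,
                        sorted(int(c) for c in np.unique(event_type) if c > 0))
    for t in ev_times:
        R = np.zeros(k)
        d = np.zeros(k)
        for j, g in enumerate(levels):
            tj, ej, aj = per_group[g]
            Y = float((tj >= t).sum())
            if Y == 0:
                R[j] = 0.0
                continue
            if cause in aj.cif:
                F_left = _left_limit(aj.times, aj.cif[cause], t, 0.0)
            else:
                F_left = 0.0
            S_left = _left_limit(aj.times, aj.efs, t, 1.0)
            R[j] = Y * (1.0 - F_left) / S_left if S_left > 0 else 0.0
            d[j] = float(((tj == t) & (ej == cause)).sum())
        Rtot = R.sum()
        dtot = d.sum()
        if Rtot <= 0 or dtot == 0:
            continue
        if rho != 0.0:
            F_pooled = (_left_limit(pooled.times, pooled.cif[cause], t, 0.0)
                        if cause in pooled.cif else 0.0)
            w = (1.0 - F_pooled) ** rho
        else:
            w = 1.0
        z += w * (d - dtot * R / Rtot)
        factor = dtot * (Rtot - dtot) / (Rtot - 1.0) if Rtot > 1 else 0.0
        V += w ** 2 * factor * (np.diag(R) / Rtot - np.outer(R, R) / Rtot ** 2)
    zz = z[:-1]
    Vsub = V[:-1, :-1]
    try:
        stat = float(zz @ np.linalg.solve(Vsub, zz))
    except np.linalg.LinAlgError:
        stat = float(zz @ np.linalg.pinv(Vsub) @ zz)
    stat = max(stat, 0.0)
    return TestResult("gray", stat, float(stats.chi2.sf(stat, k - 1)), k - 1,
                      extra={"cause": cause, "rho": rho,
                             "groups": list(levels)})


# ---------------------------------------------------------------------------
# association tests
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table of counts: sum of
    hypergeometric point probabilities no larger than the observed one."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("need a 2x2 table of non-negative integers")
    a = t[0, 0]
    r1, r2 = t[0].sum(), t[1].sum()
    c1 = t[:, 0].sum()
    N = t.sum()
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == N:
        return TestResult("fisher_exact", np.nan, 1.0,
                          extra={"degenerate": True})
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, N, r1, c1)
    p_obs = stats.hypergeom.pmf(a, N, r1, c1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0]) \
            if t[0, 1] * t[1, 0] > 0 else np.inf
    return TestResult("fisher_exact", float(odds), min(p, 1.0))


def _exact_ranksum_cdf(n1: int, N: int):
    """Null distribution of the rank-sum of a sample of size n1 among ranks
    1..N (no ties): returns (support_min, probability vector)."""
    wmin = n1 * (n1 + 1) // 2
    wmax = n1 * (2 * N - n1 + 1) // 2
    width = wmax - wmin + 1
    # dp[k, w]: number of k-subsets of ranks seen so far with sum offset w
    dp = np.zeros((n1 + 1, width))
    dp[0, 0] = 1.0
    for r in range(1, N + 1):
        for kk in range(min(r, n1), 0, -1):
            shifted = np.zeros(width)
            lo = r - kk  # offset contribution of rank r at level kk
            # offset: sum - wmin where wmin includes 1..k; adding rank r to a
            # (kk-1)-subset shifts the offset by r - kk
            if lo < width:
                shifted[lo:] = dp[kk - 1, :width - lo]
            dp[kk] += shifted
    probs = dp[n1] / dp[n1].sum()
    return wmin, probs


def wilcoxon_rank_sum(x, y, exact_max: int = 10) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution when min(n, m) <= ``exact_max`` and there are no
    ties; otherwise normal approximation with tie correction and continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    N = n1 + n2
    has_ties = len(np.unique(pooled)) < N
    U = r1 - n1 * (n1 + 1) / 2.0
    if min(n1, n2) <= exact_max and not has_ties and N <= 300:
        if n1 <= n2:
            wmin, probs = _exact_ranksum_cdf(n1, N)
            w = int(round(r1))
        else:
            wmin, probs = _exact_ranksum_cdf(n2, N)
            w = int(round(ranks[n1:].sum()))
        idx = w - wmin
        cdf = probs[:idx + 1].sum()
        sf = probs[idx:].sum()
        p = min(1.0, 2.0 * min(cdf, sf))
        return TestResult("wilcoxon_rank_sum", float(U), float(p),
                          extra={"method": "exact"})
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (N * (N - 1.0))
    var = n1 * n2 / 12.0 * ((N + 1.0) - tie_term)
    if var <= 0:
        return TestResult("wilcoxon_rank_sum", float(U), 1.0,
                          extra={"method": "normal", "degenerate": True})
    diff = U - mu
    cc = 0.5 * np.sign(diff) if diff != 0 else 0.0
    zstat = (diff - cc) / np.sqrt(var)
    p = min(1.0, 2.0 * float(stats.norm.sf(abs(zstat))))
    return TestResult("wilcoxon_rank_sum", float(U), p,
                      extra={"method": "normal", "z": float(zstat)})


def trend_test(values, ordered_groups, alternative: str = "increasing"
               ) -> TestResult:
    """One-sided ordered-alternative (Jonckheere-Terpstra) test.

    ``ordered_groups`` must be sortable labels (or a pandas Categorical)
    whose natural order defines the trend direction. Works for binary or
    continuous ``values``; ties are handled in the variance.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(ordered_groups)
    if isinstance(ordered_groups, pd.Categorical):
        levels = [l for l in ordered_groups.categories
                  if (groups == l).sum() > 0]
    else:
        levels = sorted(pd.unique(groups))
    if len(levels) < 3:
        raise ValidationError("trend test needs >= 3 ordered groups")
    samples = [values[groups == l] for l in levels]
    jt = 0.0
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            a, b = samples[i], samples[j]
            jt += (a[:, None] < b[None, :]).sum() \
                + 0.5 * (a[:, None] == b[None, :]).sum()
    ni = np.array([len(s) for s in samples], dtype=float)
    N = ni.sum()
    mean = (N ** 2 - (ni ** 2).sum()) / 4.0
    _, t = np.unique(values, return_counts=True)
    t = t.astype(float)
    term1 = (N * (N - 1) * (2 * N + 5)
             - (ni * (ni - 1) * (2 * ni + 5)).sum()
             - (t * (t - 1) * (2 * t + 5)).sum()) / 72.0
    term2 = ((ni * (ni - 1) * (ni - 2)).sum()
             * (t * (t - 1) * (t - 2)).sum()
             / (36.0 * N * (N - 1) * (N - 2)))
    term3 = ((ni * (ni - 1)).sum() * (t * (t - 1)).sum()
             / (8.0 * N * (N - 1)))
    var = term1 + term2 + term3
    if var <= 0:
        return TestResult("jonckheere_terpstra", float(jt), 1.0,
                          extra={"degenerate": True})
    zstat = (jt - mean) / np.sqrt(var)
    if alternative == "increasing":
        p = float(stats.norm.sf(zstat))
    elif alternative == "decreasing":
        p = float(stats.norm.cdf(zstat))
    else:
        raise ValidationError(f"unknown alternative {alternative!r}")
    return TestResult("jonckheere_terpstra", float(jt), p,
                      extra={"z": float(zstat), "alternative": alternative})


def median_survival_table(curves: Mapping[str, KMCurve]) -> pd.DataFrame:
    """Median survival per group, flagged 'not reached' when the curve never
    crosses 0.5."""
    rows = []
    for name, c in curves.items():
        rows.append({
            "group": name,
            "n": c.n_subjects,
            "n_events": int(c.n_events.sum()),
            "median": c.median,
            "median_defined": c.median_defined,
            "label": f"{c.median:g}" if c.median_defined else "not reached",
        })
    return pd.DataFrame(rows)
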