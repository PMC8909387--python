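"""Survival statistics: Kaplan-Meier, log-rank, Cox models, maximally
selected rank-statistic cutpoints, and bootstrap lasso-Cox stability
selection.

The log-rank machinery is implemented here (it is reused by the cutpoint
search, which must evaluate thousands of candidate dichotomies and
permutations); univariate Cox fits are delegated to lifelines (Efron ties)
and the penalized Cox path inside stability selection to scikit-survival.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

__all__ = [
    "SurvivalRecord",
    "KMEstimate",
    "MaxStatResult",
    "StabilitySelectionResult",
    "km_estimate",
    "logrank_test",
    "logrank_statistic",
    "cox_univariate",
    "maxstat_cutpoint",
    "prefilter_univariate",
    "lasso_stability_selection",
    "report_tables",
]


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    time: float
    event: bool

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"{self.patient_id}: survival time must be > 0")


def _as_arrays(time, event) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    if t.shape != e.shape:
        raise ValueError("time and event must have equal length")
    if t.size == 0:
        raise ValueError("need at least one record")
    if np.any(t <= 0):
        raise ValueError("survival times must be > 0")
    return t, e


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass(frozen=True)
class KMEstimate:
    times: np.ndarray  # distinct event times
    survival: np.ndarray  # S(t) just after each event time
    n_at_risk: np.ndarray
    n_events: np.ndarray
    median: float | None  # None = not reached

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(time, event) -> KMEstimate:
    """Product-limit estimator. The median is the smallest event time with
    S(t) <= 0.5, or None ('not reached') if the curve never drops that far."""
    t, e = _as_arrays(time, event)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    ev_times = np.unique(t[e])
    surv = []
    at_risk = []
    n_ev = []
    s = 1.0
    for tj in ev_times:
        nj = int(np.sum(t >= tj))
        dj = int(np.sum((t == tj) & e))
        s *= 1.0 - dj / nj
        surv.append(s)
        at_risk.append(nj)
        n_ev.append(dj)
    surv_arr = np.array(surv)
    median = None
    hit = np.nonzero(surv_arr <= 0.5 + 1e-12)[0]
    if hit.size:
        median = float(ev_times[hit[0]])
    return KMEstimate(ev_times, surv_arr, np.array(at_risk), np.array(n_ev), median)


# ---------------------------------------------------------------------------
# log-rank


def _logrank_zs(time: np.ndarray, event: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Standardized log-rank statistics (O-E)/sqrt(V) of the group-1 arm.

    ``groups`` is an (m, n) boolean matrix; one statistic per row. Rows with
    zero variance yield z = 0.
    """
    ev_times = np.unique(time[event])
    if ev_times.size == 0:
        raise ValueError("no events: log-rank statistic undefined")
    at_risk = time[None, :] >= ev_times[:, None]  # (J, n)
    is_event = (time[None, :] == ev_times[:, None]) & event[None, :]
    n_j = at_risk.sum(axis=1).astype(float)  # (J,)
    d_j = is_event.sum(axis=1).astype(float)
    G = groups.astype(float)  # (m, n)
    n1_j = G @ at_risk.T.astype(float)  # (m, J)
    d1_j = G @ is_event.T.astype(float)
    O = d1_j.sum(axis=1)
    E = (d_j[None, :] * n1_j / n_j[None, :]).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        var_j = (
            d_j[None, :]
            * (n1_j / n_j[None, :])
            * (1.0 - n1_j / n_j[None, :])
            * (n_j[None, :] - d_j[None, :])
            / np.maximum(n_j[None, :] - 1.0, 1.0)
        )
    V = np.nansum(var_j, axis=1)
    z = np.zeros(G.shape[0])
    ok = V > 0
    z[ok] = (O[ok] - E[ok]) / np.sqrt(V[ok])
    return z


def logrank_statistic(time, event, group) -> float:
    """Standardized log-rank z of a single binary grouping."""
    t, e = _as_arrays(time, event)
    g = np.asarray(group, dtype=bool)
    return float(_logrank_zs(t, e, g[None, :])[0])


def logrank_test(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """One-degree-of-freedom log-rank test; returns (chi-square, p)."""
    ta, ea = _as_arrays(time_a, event_a)
    tb, eb = _as_arrays(time_b, event_b)
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    g = np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)])
    z = _logrank_zs(t, e, g[None, :])[0]
    chi2 = z * z
    return float(chi2), float(stats.chi2.sf(chi2, 1))


# ---------------------------------------------------------------------------
# Cox


def cox_univariate(time, event, covariate) -> tuple[float, tuple[float, float], float]:
    """Univariate Cox PH fit (Efron ties): (HR, 95% Wald CI, p)."""
    t, e = _as_arrays(time, event)
    x = np.asarray(covariate, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("covariate is constant")
    df = pd.DataFrame({"time": t, "event": e.astype(int), "x": x})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # convergence failure / separation
        raise RuntimeError(f"Cox fit failed: {exc}") from exc
    row = cph.summary.loc["x"]
    hr = float(np.exp(row["coef"]))
    ci = (float(np.exp(row["coef lower 95%"])), float(np.exp(row["coef upper 95%"])))
    return hr, ci, float(row["p"])


# ---------------------------------------------------------------------------
# maximally selected rank statistics


@dataclass(frozen=True)
class MaxStatResult:
    best_cutoff: float
    max_statistic: float
    permutation_p: float
    n_candidates: int
    cutoffs: np.ndarray = field(repr=False, default=None)
    statistics: np.ndarray = field(repr=False, default=None)


def _candidate_cutoffs(values: np.ndarray, q_range: tuple[float, float]) -> np.ndarray:
    distinct = np.unique(values)
    if distinct.size < 2:
        raise ValueError("covariate is constant; no candidate cutoffs")
    lo, hi = np.quantile(values, q_range[0]), np.quantile(values, q_range[1])
    mids = 0.5 * (distinct[:-1] + distinct[1:])
    inside = mids[(mids >= lo) & (mids <= hi)]
    if inside.size == 0:
        inside = mids  # fall back to all splits when the quantile band is empty
    return inside


def maxstat_cutpoint(
    values,
    time,
    event,
    q_range: tuple[float, float] = (0.1, 0.9),
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> MaxStatResult:
    """Optimal dichotomizing cutoff by maximally selected log-rank statistics.

    Candidates are midpoints between consecutive distinct covariate values
    inside the quantile band. For each candidate the standardized log-rank
    statistic of the induced two groups is computed; the maximizing cutoff is
    returned (ties -> smaller cutoff). The p-value is a permutation p: the
    covariate is permuted against the survival records and the maximum
    re-computed ``n_perm`` times.
    """
    t, e = _as_arrays(time, event)
    x = np.asarray(values, dtype=float)
    if x.shape != t.shape:
        raise ValueError("values and records must align")
    rng = rng or np.random.default_rng()
    cuts = _candidate_cutoffs(x, q_range)
    G = x[None, :] > cuts[:, None]  # (n_cand, n)
    zs = np.abs(_logrank_zs(t, e, G))
    best = int(np.argmax(zs))  # argmax returns the first (smallest cutoff) tie
    obs = float(zs[best])
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(x.size)
        zp = np.abs(_logrank_zs(t, e, G[:, perm]))
        if zp.max() >= obs - 1e-12:
            exceed += 1
    p = (1.0 + exceed) / (n_perm + 1.0)
    return MaxStatResult(float(cuts[best]), obs, p, cuts.size, cuts, zs)


# ---------------------------------------------------------------------------
# bootstrap lasso-Cox stability selection


@dataclass(frozen=True)
class StabilitySelectionResult:
    variables: tuple[str, ...]
    selection_frequency: dict[str, float]
    retained: tuple[str, ...]
    hazard_ratios: dict[str, tuple[float, float, float]]  # var -> (HR, lo, hi)
    B: int
    threshold: float


def _breslow_loglik(beta: np.ndarray, X: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow partial log-likelihood at a fixed coefficient vector."""
    lp = X @ beta
    order = np.argsort(-time, kind="stable")
    t_s, e_s, lp_s = time[order], event[order], lp[order]
    exp_lp = np.exp(lp_s - lp_s.max())
    log_shift = lp_s.max()
    ll = 0.0
    i = 0
    cum = 0.0
    n = t_s.size
    while i < n:
        j = i
        while j < n and t_s[j] == t_s[i]:
            j += 1
        cum += exp_lp[i:j].sum()
        log_denom = np.log(cum) + log_shift
        for k in range(i, j):
            if e_s[k]:
                ll += lp_s[k] - log_denom
        i = j
    return float(ll)


def prefilter_univariate(
    time, event, X: pd.DataFrame, p_threshold: float = 0.1
) -> list[str]:
    """Variables whose univariate Cox p-value is below the entry threshold."""
    keep = []
    for col in X.columns:
        try:
            _, _, p = cox_univariate(time, event, X[col].to_numpy())
        except (ValueError, RuntimeError):
            continue
        if p < p_threshold:
            keep.append(col)
    return keep


def lasso_stability_selection(
    time,
    event,
    X: pd.DataFrame,
    B: int = 500,
    threshold: float = 2.0 / 3.0,
    n_folds: int = 5,
    lambda_rule: str = "1se",
    rng: np.random.Generator | None = None,
) -> StabilitySelectionResult:
    """Bootstrap stability selection with an L1-penalized Cox model.

    For each of ``B`` bootstrap resamples an L1 (lasso) Cox path is fitted and
    the penalty chosen by ``n_folds``-fold cross-validated held-out Breslow
    partial likelihood; the variables with nonzero coefficients at the chosen
    penalty are recorded. Variables selected in more than ``threshold`` of the
    resamples are retained; their HR summaries are exponentiated medians (and
    2.5/97.5 percentiles) of the bootstrap coefficients over resamples where
    the variable was selected.

    ``lambda_rule='1se'`` (default) takes the sparsest penalty within one
    standard error of the cross-validation optimum; ``'optimum'`` takes the
    optimum itself, which is markedly more liberal on pure-noise designs.
    """
    if lambda_rule not in ("1se", "optimum"):
        raise ValueError("lambda_rule must be '1se' or 'optimum'")
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    if B < 1:
        raise ValueError("B must be >= 1")
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    t, e = _as_arrays(time, event)
    n = t.size
    if n < 20:
        raise ValueError("need at least 20 records for stability selection")
    rng = rng or np.random.default_rng()
    cols = list(X.columns)
    Xm = X.to_numpy(dtype=float)
    coefs = np.full((B, len(cols)), np.nan)

    b = 0
    attempts = 0
    while b < B:
        attempts += 1
        if attempts > 20 * B:
            raise RuntimeError("too many failed bootstrap fits")
        idx = rng.integers(0, n, size=n)
        tb, eb, Xb = t[idx], e[idx], Xm[idx]
        if eb.sum() < max(3, n_folds) or np.unique(tb[eb]).size < 2:
            continue
        yb = Surv.from_arrays(event=eb, time=tb)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                path = CoxnetSurvivalAnalysis(
                    l1_ratio=1.0, alpha_min_ratio=0.01, n_alphas=30, fit_baseline_model=False
                )
                path.fit(Xb, yb)
                alphas = path.alphas_
                # K-fold CV: held-out Breslow partial likelihood along the path
                perm = rng.permutation(n)
                folds = np.array_split(perm, n_folds)
                fold_ll = np.full((n_folds, len(alphas)), np.nan)
                for fi, fold in enumerate(folds):
                    mask = np.ones(n, bool)
                    mask[fold] = False
                    if eb[mask].sum() < 2 or eb[~mask].sum() < 1:
                        continue
                    m = CoxnetSurvivalAnalysis(
                        l1_ratio=1.0, alphas=alphas, fit_baseline_model=False
                    )
                    m.fit(Xb[mask], Surv.from_arrays(event=eb[mask], time=tb[mask]))
                    fitted = np.asarray(m.alphas_)
                    for ai, a in enumerate(alphas):
                        hits = np.nonzero(np.isclose(fitted, a, rtol=1e-10))[0]
                        if hits.size == 0:
                            continue  # path may stop early on this fold
                        beta = m.coef_[:, hits[0]]
                        fold_ll[fi, ai] = _breslow_loglik(beta, Xb[~mask], tb[~mask], eb[~mask])
                valid = (~np.isnan(fold_ll)).sum(axis=0)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    mean_ll = np.where(valid == valid.max(), np.nanmean(fold_ll, axis=0), -np.inf)
                best = int(np.argmax(mean_ll))
                if lambda_rule == "1se":
                    k = valid[best]
                    se = (
                        np.nanstd(fold_ll[:, best], ddof=1) / np.sqrt(k) if k > 1 else 0.0
                    )
                    # alphas are decreasing: the first index within one SE of
                    # the optimum is the sparsest acceptable penalty
                    ok = np.nonzero(mean_ll >= mean_ll[best] - se)[0]
                    best = int(ok[0])
                coefs[b] = path.coef_[:, best]
        except (ArithmeticError, ValueError):
            continue
        b += 1

    selected = coefs != 0.0
    freq = {c: float(selected[:, i].mean()) for i, c in enumerate(cols)}
    retained = tuple(c for c in cols if freq[c] > threshold)
    hrs = {}
    for c in retained:
        i = cols.index(c)
        vals = coefs[selected[:, i], i]
        hrs[c] = (
            float(np.exp(np.median(vals))),
            float(np.exp(np.percentile(vals, 2.5))),
            float(np.exp(np.percentile(vals, 97.5))),
        )
    return StabilitySelectionResult(tuple(cols), freq, retained, hrs, B, threshold)


# ---------------------------------------------------------------------------
# report assembly


def report_tables(
    patients: pd.DataFrame,
    binary_vars: Sequence[str],
    continuous_vars: Sequence[str] = (),
    endpoints: Mapping[str, tuple[str, str]] | None = None,
    fixed_cutoffs: Mapping[str, float] | None = None,
    entry_p: float = 0.1,
    B: int = 500,
    threshold: float = 2.0 / 3.0,
    maxstat_perm: int = 200,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Univariate + multivariate (stability-selected) survival report.

    ``patients`` has one row per patient with marker columns and time/event
    columns; ``endpoints`` maps an endpoint name to its (time, event) columns,
    defaulting to PFS/OS. Continuous variables are dichotomized per endpoint
    with the maximally-selected-rank cutoff unless a fixed cutoff is given.
    Returns {'univariate': ..., 'multivariate': ..., 'cutoffs': ...}.
    """
    endpoints = endpoints or {
        "pfs": ("pfs_time", "pfs_event"),
        "os": ("os_time", "os_event"),
    }
    fixed_cutoffs = dict(fixed_cutoffs or {})
    rng = np.random.default_rng(seed)
    uni_rows = []
    multi_rows = []
    cut_rows = []
    for ep, (tcol, ecol) in endpoints.items():
        sub = patients.dropna(subset=[tcol, ecol])
        t = sub[tcol].to_numpy(float)
        e = sub[ecol].to_numpy(float).astype(bool)
        design = {}
        labels = {}
        for var in binary_vars:
            design[var] = sub[var].to_numpy(float)
            labels[var] = f"{var} (High vs Low)"
        for var in continuous_vars:
            vals = sub[var].to_numpy(float)
            if var in fixed_cutoffs:
                cut = float(fixed_cutoffs[var])
            else:
                cut = maxstat_cutpoint(vals[~np.isnan(vals)], t[~np.isnan(vals)],
                                       e[~np.isnan(vals)], n_perm=maxstat_perm,
                                       rng=rng).best_cutoff
            design[var] = (vals > cut).astype(float)
            design[var][np.isnan(vals)] = np.nan
            labels[var] = f"{var} (Low vs High)"
            cut_rows.append({"endpoint": ep, "variable": var, "cutoff": cut})
        X = pd.DataFrame(design, index=sub.index)
        for var in X.columns:
            keep = ~X[var].isna()
            try:
                hr, (lo, hi), p = cox_univariate(t[keep], e[keep], X.loc[keep, var])
            except (ValueError, RuntimeError):
                hr = lo = hi = p = np.nan
            uni_rows.append(
                {"endpoint": ep, "variable": labels[var], "HR": hr,
                 "ci_low": lo, "ci_high": hi, "p": p, "n": int(keep.sum())}
            )
        uni_ep = [r for r in uni_rows if r["endpoint"] == ep]
        entered = [
            v for v, lab in labels.items()
            if any(r["variable"] == lab and np.isfinite(r["p"]) and r["p"] < entry_p for r in uni_ep)
        ]
        if entered:
            Xc = X[entered].dropna()
            idx = Xc.index
            pos = sub.index.get_indexer(idx)
            res = lasso_stability_selection(
                t[pos], e[pos], Xc, B=B, threshold=threshold, rng=rng
            )
            for var in res.retained:
                hr, lo, hi = res.hazard_ratios[var]
                multi_rows.append(
                    {"endpoint": ep, "variable": labels[var], "HR": hr,
                     "ci_low": lo, "ci_high": hi,
                     "selection_frequency": res.selection_frequency[var]}
                )
    return {
        "univariate": pd.DataFrame(uni_rows),
        "multivariate": pd.DataFrame(
            multi_rows,
            columns=["endpoint", "variable", "HR", "ci_low", "ci_high", "selection_frequency"],
        ),
        "cutoffs": pd.DataFrame(cut_rows, columns=["endpoint", "variable", "cutoff"]),
    }
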