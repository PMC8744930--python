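"""Survival analysis: Kaplan-Meier, log-rank, Cox regression, gene screens.

The Cox proportional-hazards model is fitted by Newton-Raphson
maximization of the partial likelihood with Efron's tie correction by
default (Breslow available), to a gradient max-norm below 1e-8; standard
errors come from the inverse observed information.  Missing covariates
are handled per fitted model by complete-case analysis with the dropped
count recorded on the fit.

A per-gene prognostic screen fits univariate Cox models at a fixed
horizon (default 60 months, i.e. 5-year survival, applied as
administrative censoring before fitting) and appends Benjamini-Hochberg
q-values.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    ClinicalTable,
    CoxCoefficient,
    ExpressionMatrix,
    KMCurve,
    SurvivalFit,
)
from .signature import benjamini_hochberg

__all__ = [
    "kaplan_meier",
    "logrank_test",
    "cox_fit",
    "cox_fit_arrays",
    "gene_screen",
    "ConvergenceError",
]

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class ConvergenceError(RuntimeError):
    """Partial likelihood has no interior maximum (separation) or NR failed."""


def kaplan_meier(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Product-limit survival estimate.

    Ties at a time are resolved deaths-before-censorings: subjects
    censored at t remain in the risk set for deaths at t.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("kaplan_meier needs at least one subject")
    if t.shape != e.shape:
        raise ValueError("times and events must have the same length")
    if (t < 0).any():
        raise ValueError("times must be >= 0")

    event_times = np.unique(t[e == 1])
    surv = []
    at_risk = []
    n_ev = []
    s = 1.0
    for et in event_times:
        n_risk = int(np.sum(t >= et))
        d = int(np.sum((t == et) & (e == 1)))
        s *= 1.0 - d / n_risk
        at_risk.append(n_risk)
        n_ev.append(d)
        surv.append(s)
    return KMCurve(
        times=event_times,
        survival=np.asarray(surv, dtype=float),
        at_risk=np.asarray(at_risk, dtype=int),
        n_events=np.asarray(n_ev, dtype=int),
        censor_times=np.sort(t[e == 0]),
    )


def logrank_statistic(
    times: Sequence[float], events: Sequence[int], group: Sequence[int]
) -> float:
    """Two-group log-rank chi-square statistic (no p-value).

    Exposed separately so permutation tests can re-evaluate it cheaply.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(group, dtype=int)
    o_minus_e = 0.0
    var = 0.0
    for et in np.unique(t[e == 1]):
        at_risk = t >= et
        nj = int(at_risk.sum())
        n1j = int((at_risk & (g == 1)).sum())
        dead = (t == et) & (e == 1)
        dj = int(dead.sum())
        d1j = int((dead & (g == 1)).sum())
        o_minus_e += d1j - dj * n1j / nj
        if nj > 1:
            var += dj * (n1j / nj) * (1.0 - n1j / nj) * (nj - dj) / (nj - 1)
    if var == 0:
        return 0.0
    return float(o_minus_e**2 / var)


def logrank_test(
    times: Sequence[float], events: Sequence[int], group: Sequence[int]
) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, p from chi2 with 1 df)."""
    g = np.asarray(group, dtype=int)
    if not ((g == 0).any() and (g == 1).any()):
        raise ValueError("both groups must be non-empty")
    chi2 = logrank_statistic(times, events, g)
    p = float(stats.chi2.sf(chi2, 1)) if chi2 > 0 else 1.0
    return chi2, p


def _cox_loglik(
    beta: np.ndarray,
    t: np.ndarray,
    e: np.ndarray,
    X: np.ndarray,
    ties: str,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Log partial likelihood, gradient and Hessian at ``beta``.

    Data must be sorted by ascending time.  Suffix sums give the risk-set
    aggregates; tied event times share a risk set (Breslow) or use Efron's
    within-tie down-weighting.
    """
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.mean()  # partial likelihood is invariant to this shift
    phi = np.exp(eta)
    phix = phi[:, None] * X
    phixx = phi[:, None, None] * (X[:, :, None] * X[:, None, :])
    S0 = np.cumsum(phi[::-1])[::-1]
    S1 = np.cumsum(phix[::-1], axis=0)[::-1]
    S2 = np.cumsum(phixx[::-1], axis=0)[::-1]

    loglik = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        dead = np.arange(i, j)[e[i:j] == 1]
        d = dead.size
        if d:
            s0r, s1r, s2r = S0[i], S1[i], S2[i]
            loglik += eta[dead].sum()
            grad += X[dead].sum(axis=0)
            if ties == "breslow":
                loglik -= d * np.log(s0r)
                grad -= d * (s1r / s0r)
                hess -= d * (s2r / s0r - np.outer(s1r, s1r) / s0r**2)
            else:  # efron
                s0d = phi[dead].sum()
                s1d = phix[dead].sum(axis=0)
                s2d = phixx[dead].sum(axis=0)
                for l in range(d):
                    f = l / d
                    denom = s0r - f * s0d
                    z = s1r - f * s1d
                    m = s2r - f * s2d
                    loglik -= np.log(denom)
                    grad -= z / denom
                    hess -= m / denom - np.outer(z, z) / denom**2
        i = j
    return float(loglik), grad, hess


def cox_fit_arrays(
    times: Sequence[float],
    events: Sequence[int],
    X: np.ndarray,
    names: Sequence[str],
    ties: str = "efron",
    horizon_months: float | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
    n_dropped_missing: int = 0,
) -> SurvivalFit:
    """Fit a Cox model on raw arrays (no clinical-table plumbing).

    Newton-Raphson with step halving from beta = 0, converged when the
    gradient max-norm drops below ``tol``.  Raises
    :class:`ConvergenceError` on monotone likelihood (separation) and
    ``ValueError`` on degenerate inputs (no events, constant covariate).
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    t = np.asarray(times, dtype=float).copy()
    e = np.asarray(events, dtype=int).copy()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != t.size:
        X = X.T
    names = list(names)
    if X.shape[1] != len(names):
        raise ValueError("design matrix width must match number of names")
    if horizon_months is not None:
        over = t > horizon_months
        t[over] = horizon_months
        e[over] = 0
    if e.sum() == 0:
        raise ValueError("no events; Cox model cannot be fitted")
    for k, name in enumerate(names):
        if np.ptp(X[:, k]) == 0:
            raise ValueError(f"covariate {name!r} is constant")

    order = np.argsort(t, kind="mergesort")
    t, e, Xs = t[order], e[order], X[order]
    # center columns: does not change beta, improves conditioning
    Xc = Xs - Xs.mean(axis=0)

    # a per-SD log HR this large only arises under monotone likelihood
    sd_x = Xc.std(axis=0)
    separation_limit = 10.0

    def _check_separation(b: np.ndarray) -> None:
        scaled = np.abs(b) * sd_x
        if np.max(scaled) > separation_limit:
            worst = names[int(np.argmax(scaled))]
            raise ConvergenceError(
                f"monotone partial likelihood: covariate {worst!r} separates the data"
            )

    beta = np.zeros(Xc.shape[1])
    ll, grad, hess = _cox_loglik(beta, t, e, Xc, ties)
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol:
            _check_separation(beta)
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            raise ConvergenceError(
                f"singular information matrix; covariate {names[int(np.argmax(np.abs(beta)))]!r} "
                "may be separating"
            ) from None
        # step halving keeps the likelihood non-decreasing
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            ll_new, grad_new, hess_new = _cox_loglik(cand, t, e, Xc, ties)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            raise ConvergenceError("step halving failed to improve partial likelihood")
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        _check_separation(beta)
    else:
        worst = names[int(np.argmax(np.abs(beta)))]
        raise ConvergenceError(
            f"Newton-Raphson did not converge; covariate {worst!r} suspected"
        )

    info = -hess
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    coefs = []
    for k, name in enumerate(names):
        b, s = float(beta[k]), float(se[k])
        z = b / s
        coefs.append(
            CoxCoefficient(
                name=name,
                coef=b,
                se=s,
                hr=float(np.exp(b)),
                ci_low=float(np.exp(b - Z_95 * s)),
                ci_high=float(np.exp(b + Z_95 * s)),
                p=float(2.0 * stats.norm.sf(abs(z))),
            )
        )

    logrank_p = None
    if len(names) == 1:
        uniq = np.unique(Xs[:, 0])
        if uniq.size == 2:
            _, logrank_p = logrank_test(t, e, (Xs[:, 0] == uniq.max()).astype(int))

    return SurvivalFit(
        coefficients=coefs,
        n=int(t.size),
        n_events=int(e.sum()),
        log_likelihood=ll,
        ties=ties,
        n_dropped_missing=n_dropped_missing,
        logrank_p=logrank_p,
    )


def cox_fit(
    clinical: ClinicalTable,
    covariates: Sequence[str] = (),
    extra: pd.DataFrame | pd.Series | None = None,
    ties: str = "efron",
    horizon_months: float | None = None,
) -> SurvivalFit:
    """Cox model on a clinical table, with Table-1-style covariate coding.

    ``covariates`` name clinical contrasts (``age``, ``sex``, ``smoking``,
    ``stage``, ``histology``); ``extra`` supplies additional numeric
    covariates (e.g. a signature score or a risk-group indicator) indexed
    by sample id.  Samples with any missing design value are dropped
    (complete-case), with the count recorded on the fit.
    """
    design = clinical.design_matrix(covariates) if covariates else pd.DataFrame(
        index=pd.Index(clinical.sample_ids, name="sample_id")
    )
    if extra is not None:
        if isinstance(extra, pd.Series):
            extra = extra.to_frame(extra.name or "extra")
        extra = extra.reindex(design.index)
        design = pd.concat([design, extra.astype(float)], axis=1)
    if design.shape[1] == 0:
        raise ValueError("no covariates specified")
    complete = design.notna().all(axis=1).to_numpy()
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("cox_fit: dropped %d sample(s) with missing covariates", n_dropped)
    t = clinical.os_time[complete]
    e = clinical.event[complete]
    X = design.to_numpy(dtype=float)[complete]
    return cox_fit_arrays(
        t, e, X, list(design.columns), ties=ties,
        horizon_months=horizon_months, n_dropped_missing=n_dropped,
    )


def gene_screen(
    matrix: ExpressionMatrix,
    gene_list: Sequence[str],
    clinical: ClinicalTable,
    horizon_months: float | None = 60.0,
    dichotomize: str = "median",
    ties: str = "efron",
) -> pd.DataFrame:
    """Univariate per-gene Cox screen at a fixed survival horizon.

    Each gene's expression is either dichotomized at the cohort median
    (``"median"``, high = 1) or used continuously (``"continuous"``).
    Genes with constant expression (or constant after dichotomization) and
    genes whose fit fails to converge are skipped with a logged reason.
    Output is sorted by Wald p with a BH ``q_value`` column appended.
    """
    if dichotomize not in ("median", "continuous"):
        raise ValueError("dichotomize must be 'median' or 'continuous'")
    genes = [g for g in gene_list if matrix.has_gene(g)]
    if not genes:
        raise ValueError("no gene from gene_list is present in the matrix")
    expr = matrix.subset_samples(clinical.sample_ids)
    rows = []
    for gene in genes:
        x = expr.gene_row(gene).astype(float)
        if dichotomize == "median":
            x = (x > np.median(x)).astype(float)
        if np.ptp(x) == 0:
            logger.info("gene_screen: %s skipped (constant expression)", gene)
            continue
        try:
            fit = cox_fit_arrays(
                clinical.os_time, clinical.event, x[:, None], [gene],
                ties=ties, horizon_months=horizon_months,
            )
        except (ConvergenceError, ValueError) as err:
            logger.info("gene_screen: %s skipped (%s)", gene, err)
            continue
        c = fit.coefficients[0]
        rows.append(
            {
                "gene": gene,
                "coef": c.coef,
                "se": c.se,
                "hr": c.hr,
                "ci_low": c.ci_low,
                "ci_high": c.ci_high,
                "p_value": c.p,
                "n": fit.n,
                "n_events": fit.n_events,
            }
        )
    if not rows:
        raise ValueError("no gene could be screened")
    out = pd.DataFrame(rows)
    out["q_value"] = benjamini_hochberg(out["p_value"].to_numpy())
    out = out.sort_values(["p_value", "gene"], kind="mergesort").reset_index(drop=True)
    return out
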