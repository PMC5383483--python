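"""Frequentist tests and sex-change occurrence models.

Three tools used on sex-expression censuses:

* :func:`g_test` -- likelihood-ratio (G) test of independence for an R x C
  contingency table, ``G = 2 sum O ln(O/E)`` with ``(R-1)(C-1)`` degrees of
  freedom, no continuity or Williams correction.  Used to compare the sex
  ratio between census years.
* :func:`kruskal_wallis` -- rank-based omnibus test (tie-corrected) for
  differences in size, light environment or growth among groups.
* :func:`fit_mixed_logistic` / :func:`backward_aic` -- a Bernoulli-logit
  model of whether an individual changes sex between consecutive years, with
  standardized fixed effects (DBH, rPPFD in the leafless and leafy seasons,
  yearly absolute DBH growth in mm) and a Gaussian random intercept per plot.
  The random effect is integrated out by adaptive Gauss-Hermite quadrature
  (default 15 nodes: each plot's integrand is recentred at its conditional
  mode and rescaled by its curvature, so a modest node count is accurate even
  for large plots).  Model choice is backward stepwise by AIC.

Responses are built by :func:`prepare_change_data` from the census records:
one row per individual-year pair with both states expressed and covariates
measured, matching a design in which the first census year lacks winter-light
measurements and growth needs the previous year's DBH.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import expit
from scipy.stats import chi2, kruskal

from .census_io import CensusRecord, build_trajectories
from .transitions import consecutive_expressed_pairs

#: Default quadrature order for the random-intercept integral.
DEFAULT_QUAD_NODES = 15

#: Covariate columns of a change-model frame, in declared model order.
MODEL_TERMS: tuple[str, ...] = ("dbh", "rppfd_winter", "rppfd_summer", "growth")

#: Patterns with at most this many events are not modelled.
MIN_PATTERN_EVENTS = 10


# ---------------------------------------------------------------------------
# contingency-table and rank tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GTestResult:
    g: float
    df: int
    p: float


def g_test(
    counts: np.ndarray | Sequence[Sequence[float]],
    row_labels: Sequence[str] | None = None,
    col_labels: Sequence[str] | None = None,
) -> GTestResult:
    """Likelihood-ratio test of independence for a contingency table.

    Cells with observed count zero contribute nothing to G (the O ln O term
    vanishes in the limit); a zero row or column *total* makes the test
    undefined and raises ``ValueError`` naming the margin.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("contingency table needs at least 2 rows and 2 columns")
    if (table < 0).any():
        raise ValueError("negative cell count")
    row_tot = table.sum(axis=1)
    col_tot = table.sum(axis=0)
    for name, labels, totals in (
        ("row", row_labels, row_tot),
        ("column", col_labels, col_tot),
    ):
        if (totals == 0).any():
            idx = int(np.where(totals == 0)[0][0])
            label = labels[idx] if labels is not None else str(idx)
            raise ValueError(f"{name} {label!r} has zero total; G-test undefined")
    expected = np.outer(row_tot, col_tot) / table.sum()
    observed = table[table > 0]
    g = 2.0 * float((observed * np.log(observed / expected[table > 0])).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return GTestResult(g=g, df=df, p=float(chi2.sf(g, df)))


@dataclass(frozen=True)
class KruskalResult:
    h: float
    df: int
    p: float


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KruskalResult:
    """Kruskal-Wallis rank test across >= 2 nonempty groups (tie-corrected).

    All-identical data make the statistic degenerate; H = 0 with p = 1 is
    returned with a warning rather than an error.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    df = len(groups) - 1
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical; Kruskal-Wallis H set to 0")
        return KruskalResult(h=0.0, df=df, p=1.0)
    h, p = kruskal(*groups)
    return KruskalResult(h=float(h), df=df, p=float(p))


# ---------------------------------------------------------------------------
# change-model data
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChangeModelData:
    """Standardized individual-year design for the sex-change models.

    ``frame`` has one row per usable consecutive-year pair with columns
    ``plot_id``, ``individual_id``, ``year``, ``state_from``, ``state_to``,
    ``response`` and the standardized covariates of :data:`MODEL_TERMS`.
    ``means``/``sds`` store the standardization constants on the raw scales
    (DBH cm, rPPFD fractions, growth mm/yr).
    """

    frame: pd.DataFrame
    means: Mapping[str, float]
    sds: Mapping[str, float]
    response_name: str = "response"


def prepare_change_data(
    records: Iterable[CensusRecord],
    pooling: Mapping[str, str] | None = None,
    focal: tuple[str, str] | None = None,
) -> ChangeModelData:
    """Build the individual-year change dataset from census records.

    The response for a pair (t, t+1) is 1 iff the (optionally pooled) state
    changed.  With ``focal=(origin, destination)`` the rows are restricted to
    pairs *at risk* of that focal change (pooled origin matches) and the
    response is 1 iff exactly that change occurred.  Covariates are DBH and
    both rPPFD seasons measured in year t plus the absolute DBH difference to
    year t-1 expressed in mm; pairs missing any covariate are dropped, which
    excludes the first census year by construction.
    """
    records = list(records)
    dbh_by_key = {(r.individual_id, r.year): r.dbh for r in records}
    cov_by_key = {
        (r.individual_id, r.year): (r.dbh, r.rppfd_winter, r.rppfd_summer)
        for r in records
    }
    rows = []
    for trajectory in build_trajectories(records):
        for y0, y1, s0, s1 in consecutive_expressed_pairs(trajectory):
            p0 = pooling[s0] if pooling else s0
            p1 = pooling[s1] if pooling else s1
            if focal is not None:
                if p0 != focal[0]:
                    continue
                response = int(p1 == focal[1] and p0 != p1)
            else:
                response = int(p0 != p1)
            dbh, rw, rs = cov_by_key[(trajectory.individual_id, y0)]
            dbh_prev = dbh_by_key.get((trajectory.individual_id, y0 - 1))
            if None in (dbh, rw, rs) or dbh_prev is None:
                continue
            rows.append(
                {
                    "plot_id": trajectory.plot_id,
                    "individual_id": trajectory.individual_id,
                    "year": y0,
                    "state_from": p0,
                    "state_to": p1,
                    "response": response,
                    "dbh": dbh,
                    "rppfd_winter": rw,
                    "rppfd_summer": rs,
                    "growth": abs(dbh - dbh_prev) * 10.0,  # cm -> mm
                }
            )
    frame = pd.DataFrame(
        rows,
        columns=[
            "plot_id",
            "individual_id",
            "year",
            "state_from",
            "state_to",
            "response",
            *MODEL_TERMS,
        ],
    )
    means = {}
    sds = {}
    for term in MODEL_TERMS:
        mu = float(frame[term].mean()) if len(frame) else 0.0
        sd = float(frame[term].std(ddof=0)) if len(frame) else 1.0
        if not np.isfinite(sd) or sd == 0.0:
            sd = 1.0
        means[term] = mu
        sds[term] = sd
        if len(frame):
            frame[term] = (frame[term] - mu) / sd
    return ChangeModelData(frame=frame, means=means, sds=sds)


# ---------------------------------------------------------------------------
# mixed logistic model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MixedLogisticFit:
    """Maximum-likelihood fit of the random-intercept logit model."""

    terms: tuple[str, ...]
    intercept: float
    coefficients: Mapping[str, float]
    re_sd: float  # SD of the plot random intercept (0 when fixed out)
    loglik: float
    aic: float
    converged: bool
    n_obs: int
    n_groups: int
    n_quad: int
    std_errors: Mapping[str, float] = field(default_factory=dict)
    separation: bool = False

    # whether the random-intercept variance was a free parameter of the fit
    _re_free: bool = True

    @property
    def n_params(self) -> int:
        # intercept + slopes + (re variance when estimated)
        return 1 + len(self.terms) + (1 if self._re_free else 0)


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pointwise log-likelihood, numerically stable at large |eta|."""
    return y * eta - np.logaddexp(0.0, eta)


def _marginal_loglik(
    beta: np.ndarray,
    sigma: float,
    x: np.ndarray,
    y: np.ndarray,
    group_index: np.ndarray,
    n_groups: int,
    nodes: np.ndarray,
    log_weights: np.ndarray,
) -> float:
    """Marginal log-likelihood, random intercept integrated out per group.

    Adaptive Gauss-Hermite: Newton steps locate each group's conditional mode
    u-hat and curvature; the Hermite nodes are shifted and scaled accordingly.
    """
    eta0 = x @ beta
    if sigma == 0.0:
        return float(_bernoulli_loglik(eta0, y).sum())
    u = np.zeros(n_groups)
    for _ in range(25):
        p = expit(eta0 + sigma * u[group_index])
        grad = sigma * np.bincount(group_index, y - p, minlength=n_groups) - u
        hess = -(sigma**2) * np.bincount(
            group_index, p * (1.0 - p), minlength=n_groups
        ) - 1.0
        step = grad / hess
        u -= step
        if np.abs(step).max() < 1e-9:
            break
    p = expit(eta0 + sigma * u[group_index])
    curvature = (sigma**2) * np.bincount(
        group_index, p * (1.0 - p), minlength=n_groups
    ) + 1.0
    tau = 1.0 / np.sqrt(curvature)
    # integration points per group: u_gj = u-hat_g + sqrt(2) tau_g z_j
    points = u[:, None] + np.sqrt(2.0) * tau[:, None] * nodes[None, :]
    logint = np.empty((n_groups, len(nodes)))
    for j in range(len(nodes)):
        eta = eta0 + sigma * points[group_index, j]
        logint[:, j] = np.bincount(
            group_index, _bernoulli_loglik(eta, y), minlength=n_groups
        )
    # integrand includes the standard-normal density of u; the exp(z^2)
    # factor undoes the Hermite weight's Gaussian kernel at the new scale
    logint += (
        -0.5 * points**2
        - 0.5 * np.log(2.0 * np.pi)
        + nodes[None, :] ** 2
        + log_weights[None, :]
    )
    logint += 0.5 * np.log(2.0) + np.log(tau)[:, None]
    m = logint.max(axis=1)
    return float((m + np.log(np.exp(logint - m[:, None]).sum(axis=1))).sum())


def fit_mixed_logistic(
    frame: pd.DataFrame,
    terms: Sequence[str],
    response: str = "response",
    group: str = "plot_id",
    n_quad: int = DEFAULT_QUAD_NODES,
    re_variance: float | None = None,
    compute_se: bool = True,
) -> MixedLogisticFit:
    """Fit the Bernoulli-logit model with a per-group Gaussian intercept.

    ``re_variance=None`` (default) estimates the random-intercept variance by
    maximum likelihood; passing ``0.0`` fixes it out, reducing the model to a
    plain logistic regression (the oracle case).  Non-convergence and complete
    separation are flagged on the result, never raised.
    """
    terms = tuple(terms)
    y = frame[response].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("response is constant; model undefined")
    x = np.column_stack(
        [np.ones(len(frame))] + [frame[t].to_numpy(dtype=float) for t in terms]
    )
    codes, _ = pd.factorize(frame[group], sort=True)
    n_groups = int(codes.max()) + 1
    estimate_re = re_variance is None
    if estimate_re and n_groups < 2:
        raise ValueError("need >= 2 groups to estimate a random intercept")
    z, w = hermgauss(n_quad)
    log_w = np.log(w)

    def negloglik(theta: np.ndarray) -> float:
        beta = theta[: x.shape[1]]
        sigma = np.exp(theta[-1]) if estimate_re else np.sqrt(re_variance)
        return -_marginal_loglik(beta, sigma, x, y, codes, n_groups, z, log_w)

    theta0 = np.zeros(x.shape[1] + (1 if estimate_re else 0))
    theta0[0] = np.log(y.mean() / (1.0 - y.mean()))
    if estimate_re:
        theta0[-1] = np.log(0.3)
    result = optimize.minimize(negloglik, theta0, method="BFGS")
    if not result.success:  # polish from the BFGS point
        result = optimize.minimize(
            negloglik, result.x, method="Nelder-Mead", options={"maxiter": 4000}
        )
    theta = result.x
    beta = theta[: x.shape[1]]
    sigma = float(np.exp(theta[-1])) if estimate_re else float(np.sqrt(re_variance))
    loglik = -float(result.fun)
    n_params = x.shape[1] + (1 if estimate_re else 0)
    separation = bool(np.abs(beta).max() > 15.0)
    std_errors: dict[str, float] = {}
    if compute_se:
        std_errors = _wald_std_errors(negloglik, theta, ("intercept", *terms))
    return MixedLogisticFit(
        terms=terms,
        intercept=float(beta[0]),
        coefficients={t: float(b) for t, b in zip(terms, beta[1:])},
        re_sd=sigma if estimate_re else float(np.sqrt(re_variance)),
        loglik=loglik,
        aic=-2.0 * loglik + 2.0 * n_params,
        converged=bool(result.success) and not separation,
        n_obs=len(y),
        n_groups=n_groups,
        n_quad=n_quad,
        std_errors=std_errors,
        separation=separation,
        _re_free=estimate_re,
    )


def _wald_std_errors(
    negloglik, theta: np.ndarray, names: Sequence[str]
) -> dict[str, float]:
    """Fixed-effect standard errors from the numerical observed information."""
    k = len(theta)
    h = 1e-4 * np.maximum(np.abs(theta), 1.0)
    hess = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = negloglik(theta + ei + ej)
            fpm = negloglik(theta + ei - ej)
            fmp = negloglik(theta - ei + ej)
            fmm = negloglik(theta - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    try:
        cov = np.linalg.inv(hess)
        variances = np.diag(cov)
        if (variances[: len(names)] <= 0).any():
            return {}
        return {
            name: float(np.sqrt(v)) for name, v in zip(names, variances[: len(names)])
        }
    except np.linalg.LinAlgError:
        return {}


# ---------------------------------------------------------------------------
# backward stepwise selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SelectionResult:
    """Backward-AIC selection outcome with the full trace."""

    final: MixedLogisticFit
    trace: pd.DataFrame  # step, dropped, terms, aic


def backward_aic(
    frame: pd.DataFrame,
    full_terms: Sequence[str],
    response: str = "response",
    group: str = "plot_id",
    n_quad: int = DEFAULT_QUAD_NODES,
    re_variance: float | None = None,
) -> SelectionResult:
    """Backward stepwise AIC selection starting from the full model.

    At each step the single term whose removal lowers AIC most is dropped
    (ties broken by dropping the term latest in the declared order); selection
    stops when no removal lowers AIC.  Candidate fits that fail to converge
    are excluded with a warning.  The intercept and the random intercept are
    never dropped.
    """
    if not full_terms:
        raise ValueError("full_terms must be nonempty")
    order = {t: i for i, t in enumerate(full_terms)}

    def fit(terms: Sequence[str]) -> MixedLogisticFit:
        return fit_mixed_logistic(
            frame,
            terms,
            response=response,
            group=group,
            n_quad=n_quad,
            re_variance=re_variance,
            compute_se=False,
        )

    current_terms = tuple(full_terms)
    current = fit(current_terms)
    rows = [
        {
            "step": 0,
            "dropped": "",
            "terms": "+".join(current_terms) or "1",
            "aic": current.aic,
        }
    ]
    step = 0
    while current_terms:
        candidates = []
        for term in current_terms:
            reduced = tuple(t for t in current_terms if t != term)
            candidate = fit(reduced)
            if not candidate.converged:
                warnings.warn(f"dropping {term!r}: candidate fit did not converge")
                continue
            candidates.append((term, candidate))
        if not candidates:
            break
        best_aic = min(c.aic for _, c in candidates)
        # deterministic tie-break: the term latest in the declared order
        term, candidate = max(
            (tc for tc in candidates if tc[1].aic <= best_aic + 1e-9),
            key=lambda tc: order[tc[0]],
        )
        if candidate.aic >= current.aic:
            break
        step += 1
        current_terms = candidate.terms
        current = candidate
        rows.append(
            {
                "step": step,
                "dropped": term,
                "terms": "+".join(current_terms) or "1",
                "aic": current.aic,
            }
        )
    # refit the winner with standard errors
    final = fit_mixed_logistic(
        frame,
        current.terms,
        response=response,
        group=group,
        n_quad=n_quad,
        re_variance=re_variance,
        compute_se=True,
    )
    return SelectionResult(final=final, trace=pd.DataFrame(rows))
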