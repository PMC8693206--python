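"""Count regression with a log-exposure offset: Poisson, NB2, hurdle-NB.

Infection counts per ward exposure period are typically overdispersed
(variance exceeding the mean) and carry more zeros than a Poisson or even a
negative binomial fit predicts — many wards report no infections of a given
type in a year. The modelling ladder is therefore:

1. Poisson regression with log(hospitalizations) offset, plus a
   Cameron–Trivedi auxiliary-regression test for overdispersion and a
   zero-excess diagnostic;
2. NB2 negative binomial regression (variance mu * (1 + alpha * mu));
3. a hurdle negative binomial: a logistic model for whether any infection
   occurs, and a zero-truncated NB2 for how many occur given at least one.

The hurdle log-likelihood factorizes into the binary part and the truncated
positive part, so the two are maximized separately. The zero-truncated NB
likelihood is maximized by quasi-Newton with analytic gradients; the
dispersion parameter is optimized on the log scale to enforce positivity.

Standard single-family fits (Poisson GLM, NB2, logistic) are delegated to
statsmodels; the hurdle likelihood and its estimator are implemented here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats
from statsmodels.tools import numdiff

from .design import DesignMatrix, build_design, observed_column

FAMILIES = ("poisson", "negbin", "hurdle_negbin")

_ALPHA_BOUNDARY = 1e-6  # below this the NB2 fit is reported as Poisson (alpha = 0)


class ModelError(ValueError):
    """Raised for invalid model inputs (rank deficiency, bad parameters...)."""


# ---------------------------------------------------------------------------
# NB2 probability machinery
# ---------------------------------------------------------------------------

def nb2_logpmf(y: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Log pmf of NB2 with mean mu and variance mu * (1 + alpha * mu).

    Falls back to the Poisson log pmf in the alpha -> 0 limit.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if alpha < 1e-12:
        return stats.poisson.logpmf(y, mu)
    a = 1.0 / alpha  # NB "size"
    return (
        special.gammaln(y + a)
        - special.gammaln(a)
        - special.gammaln(y + 1.0)
        + a * (np.log(a) - np.log(a + mu))
        + y * (np.log(mu) - np.log(a + mu))
    )


def nb2_zero_prob(mu: np.ndarray, alpha: float) -> np.ndarray:
    """P(Y = 0) under NB2: (1 + alpha * mu) ** (-1 / alpha)."""
    mu = np.asarray(mu, dtype=float)
    if alpha < 1e-12:
        return np.exp(-mu)
    return np.exp(-np.log1p(alpha * mu) / alpha)


def truncated_nb2_logpmf(y: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Log pmf of the zero-truncated NB2 on y >= 1 (NB pmf renormalized)."""
    p0 = np.clip(nb2_zero_prob(mu, alpha), 0.0, 1.0 - 1e-15)
    return nb2_logpmf(y, mu, alpha) - np.log1p(-p0)


# ---------------------------------------------------------------------------
# Fit containers
# ---------------------------------------------------------------------------

@dataclass
class CountModelFit:
    """A fitted exposure-offset count model.

    ``beta`` is the count-part coefficient vector on the log-rate scale;
    ``gamma`` (hurdle only) models the log-odds of a *positive* count;
    ``alpha`` is the NB2 dispersion (0 for Poisson and for an NB fit that
    collapsed to the Poisson boundary).
    """

    family: str
    beta: np.ndarray
    term_names: list[str]
    loglik: float
    n_params: int
    converged: bool
    alpha: float | None = None
    gamma: np.ndarray | None = None
    gamma_term_names: list[str] | None = None
    se_beta: np.ndarray | None = None
    se_gamma: np.ndarray | None = None
    se_alpha: float | None = None
    alpha_boundary: bool = False
    reference_levels: dict[str, str] = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    def to_dict(self) -> dict:
        d = {
            "family": self.family,
            "term_names": list(self.term_names),
            "beta": [float(b) for b in self.beta],
            "alpha": None if self.alpha is None else float(self.alpha),
            "gamma": None if self.gamma is None else [float(g) for g in self.gamma],
            "gamma_term_names": self.gamma_term_names,
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "n_params": int(self.n_params),
            "converged": bool(self.converged),
            "alpha_boundary": bool(self.alpha_boundary),
            "reference_levels": dict(self.reference_levels),
        }
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "CountModelFit":
        return cls(
            family=d["family"],
            beta=np.asarray(d["beta"], dtype=float),
            term_names=list(d["term_names"]),
            loglik=float(d["loglik"]),
            n_params=int(d["n_params"]),
            converged=bool(d["converged"]),
            alpha=None if d.get("alpha") is None else float(d["alpha"]),
            gamma=None if d.get("gamma") is None else np.asarray(d["gamma"], dtype=float),
            gamma_term_names=d.get("gamma_term_names"),
            alpha_boundary=bool(d.get("alpha_boundary", False)),
            reference_levels=dict(d.get("reference_levels", {})),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CountModelFit":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class DispersionDiagnostic:
    """Raw moments plus the Cameron–Trivedi overdispersion test and a
    Poisson zero-excess check for a fitted Poisson model."""

    mean_response: float
    variance_response: float
    auxiliary_test_statistic: float
    p_value: float
    overdispersed: bool
    zero_observed: int
    zero_expected_under_fit: float
    zero_excess: bool


def _check_full_rank(dm: DesignMatrix) -> None:
    rank = np.linalg.matrix_rank(dm.predictors)
    if rank < dm.k:
        raise ModelError(
            f"singular design: rank {rank} < {dm.k} columns ({dm.term_names})"
        )


# ---------------------------------------------------------------------------
# Poisson and NB2 (delegated to statsmodels)
# ---------------------------------------------------------------------------

def fit_poisson(dm: DesignMatrix) -> CountModelFit:
    """Poisson MLE with log link and log-exposure offset.

    With an intercept in the design, the score equations force the summed
    fitted counts to equal the summed observed counts.
    """
    _check_full_rank(dm)
    model = sm.GLM(dm.response, dm.predictors, family=sm.families.Poisson(), offset=dm.offset)
    res = model.fit()
    return CountModelFit(
        family="poisson",
        beta=np.asarray(res.params, dtype=float),
        term_names=list(dm.term_names),
        loglik=float(res.llf),
        n_params=dm.k,
        converged=bool(res.converged),
        se_beta=np.asarray(res.bse, dtype=float),
        reference_levels=dict(dm.reference_levels),
    )


def fit_negbin(dm: DesignMatrix) -> CountModelFit:
    """NB2 MLE of (beta, alpha) with log link and log-exposure offset.

    When the dispersion estimate collapses to the Poisson boundary
    (alpha -> 0) the fit is reported with alpha = 0, the Poisson
    log-likelihood, and ``alpha_boundary=True``; the dispersion parameter is
    still counted in ``n_params`` so AIC comparisons across families remain
    like for like.
    """
    _check_full_rank(dm)
    pois = fit_poisson(dm)
    start = np.append(pois.beta, 0.1)
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.NegativeBinomial(
                dm.response, dm.predictors, loglike_method="nb2", offset=dm.offset
            )
            res = model.fit(start_params=start, method="bfgs", maxiter=500, disp=0)
        except Exception:
            res = None

    boundary = CountModelFit(
        family="negbin",
        beta=pois.beta,
        term_names=list(dm.term_names),
        loglik=pois.loglik,
        n_params=dm.k + 1,
        converged=pois.converged,
        alpha=0.0,
        se_beta=pois.se_beta,
        alpha_boundary=True,
        reference_levels=dict(dm.reference_levels),
    )
    if res is None:
        return boundary
    alpha = float(res.params[-1])
    llf = float(res.llf)
    # alpha at (or numerically past) the Poisson boundary, or an interior
    # "optimum" no better than the nested Poisson fit -> report the boundary.
    if not np.isfinite(llf) or alpha <= _ALPHA_BOUNDARY or llf < pois.loglik - 1e-8:
        return boundary
    return CountModelFit(
        family="negbin",
        beta=np.asarray(res.params[:-1], dtype=float),
        term_names=list(dm.term_names),
        loglik=llf,
        n_params=dm.k + 1,
        converged=bool(res.mle_retvals.get("converged", True)),
        alpha=alpha,
        se_beta=np.asarray(res.bse[:-1], dtype=float),
        se_alpha=float(res.bse[-1]),
        reference_levels=dict(dm.reference_levels),
    )


def overdispersion_check(dm: DesignMatrix, poisson_fit: CountModelFit) -> DispersionDiagnostic:
    """Cameron–Trivedi auxiliary regression plus a zero-excess diagnostic.

    Regresses ((y - mu)^2 - y) / mu on mu without intercept; a positive slope
    with one-sided p < 0.05 flags overdispersion. Zero excess is flagged when
    observed zeros exceed the Poisson-predicted zero count sum(exp(-mu_i)) by
    more than 20%.
    """
    if not poisson_fit.converged:
        raise ModelError("overdispersion check requires a converged Poisson fit")
    y = dm.response.astype(float)
    mu = np.exp(dm.predictors @ poisson_fit.beta + dm.offset)
    z = ((y - mu) ** 2 - y) / mu
    aux = sm.OLS(z, mu[:, None]).fit()
    coef = float(aux.params[0])
    tstat = float(aux.tvalues[0])
    # one-sided: overdispersion is a positive-slope alternative
    p_one_sided = float(stats.t.sf(tstat, df=aux.df_resid))
    zero_obs = int(np.sum(y == 0))
    zero_exp = float(np.sum(np.exp(-mu)))
    return DispersionDiagnostic(
        mean_response=float(np.mean(y)),
        variance_response=float(np.var(y, ddof=1)) if len(y) > 1 else 0.0,
        auxiliary_test_statistic=tstat,
        p_value=p_one_sided,
        overdispersed=bool(coef > 0 and p_one_sided < 0.05),
        zero_observed=zero_obs,
        zero_expected_under_fit=zero_exp,
        zero_excess=bool(zero_obs > 1.2 * zero_exp),
    )


# ---------------------------------------------------------------------------
# Hurdle negative binomial
# ---------------------------------------------------------------------------

def hurdle_nb_loglik(
    beta: np.ndarray,
    gamma: np.ndarray,
    alpha: float,
    dm: DesignMatrix,
) -> float:
    """Hurdle-NB log-likelihood on a design matrix.

    The zero part is logistic with ``gamma`` modelling the log-odds of a
    positive count, so pi0_i = logistic(-x_i' gamma). The positive part is a
    zero-truncated NB2 with mean exp(x_i' beta + offset_i) and dispersion
    ``alpha``; the offset enters only the positive part.
    """
    beta = np.asarray(beta, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(gamma)) and np.isfinite(alpha)):
        raise ModelError("non-finite parameter in hurdle log-likelihood")
    if alpha < 0:
        raise ModelError("alpha must be >= 0")
    y = dm.response
    xg = dm.predictors @ gamma
    pos = y > 0
    # log pi0 = log sigma(-xg), log(1 - pi0) = log sigma(xg)
    ll = float(np.sum(special.log_expit(-xg[~pos])))
    if np.any(pos):
        ll += float(np.sum(special.log_expit(xg[pos])))
        mu = np.exp(dm.predictors[pos] @ beta + dm.offset[pos])
        ll += float(np.sum(truncated_nb2_logpmf(y[pos], mu, alpha)))
    return ll


def _truncated_nb_nll_grad(params: np.ndarray, y: np.ndarray, X: np.ndarray,
                           offset: np.ndarray) -> tuple[float, np.ndarray]:
    """Negative log-likelihood and gradient of the zero-truncated NB2.

    Parameters are (beta, log alpha); all responses must be >= 1.
    """
    beta = params[:-1]
    theta = params[-1]
    alpha = np.exp(theta)
    a = np.exp(-theta)  # 1 / alpha
    mu = np.exp(X @ beta + offset)
    logp0 = a * (np.log(a) - np.log(a + mu))
    p0 = np.exp(np.clip(logp0, -745.0, -1e-300))
    one_m_p0 = -np.expm1(np.clip(logp0, -745.0, -1e-12))

    ll = (
        special.gammaln(y + a)
        - special.gammaln(a)
        - special.gammaln(y + 1.0)
        + a * (np.log(a) - np.log(a + mu))
        + y * (np.log(mu) - np.log(a + mu))
        - np.log(one_m_p0)
    )
    # d ll / d mu, including the truncation term
    dll_dmu = y / mu - (a + y) / (a + mu) - p0 * a / (one_m_p0 * (a + mu))
    grad_beta = X.T @ (dll_dmu * mu)
    # d ll / d a, then chain through a = exp(-theta)
    log_ratio = np.log(a) - np.log(a + mu)
    dll_da = (
        special.digamma(y + a)
        - special.digamma(a)
        + log_ratio
        + 1.0
        - (a + y) / (a + mu)
        + p0 * (log_ratio + mu / (a + mu)) / one_m_p0
    )
    grad_theta = -a * np.sum(dll_da)
    grad = np.append(grad_beta, grad_theta)
    return -float(np.sum(ll)), -grad


def fit_truncated_negbin(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    beta0: np.ndarray | None = None,
    alpha0: float = 0.5,
) -> tuple[np.ndarray, float, float, np.ndarray, bool]:
    """MLE of the zero-truncated NB2 (positive part of the hurdle model).

    Returns (beta, alpha, loglik, standard errors of (beta, alpha), converged).
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 1):
        raise ModelError("truncated NB requires all responses >= 1")
    if beta0 is None:
        res = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        beta0 = np.asarray(res.params, dtype=float)
        mu0 = res.fittedvalues
        num = float(np.sum((y - mu0) ** 2 - y))
        den = float(np.sum(mu0**2))
        alpha0 = min(10.0, max(1e-3, num / den)) if den > 0 else 0.5
    def _minimize(start_alpha: float):
        x0 = np.append(beta0, np.log(start_alpha))
        r = optimize.minimize(
            _truncated_nb_nll_grad,
            x0,
            args=(y, X, offset),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-8},
        )
        # a line-search breakdown at float precision can mask an optimum that
        # is already converged: judge by the gradient itself
        _, grad = _truncated_nb_nll_grad(r.x, y, X, offset)
        r.converged = bool(r.success or np.max(np.abs(grad)) < 1e-3)
        return r

    res = _minimize(alpha0)
    if not res.converged and abs(alpha0 - 0.5) > 1e-12:
        retry = _minimize(0.5)
        if retry.converged or retry.fun < res.fun:
            res = retry
    beta = res.x[:-1]
    alpha = float(np.exp(res.x[-1]))
    loglik = -float(res.fun)
    # observed-information standard errors; delta method for alpha = exp(theta)
    se = np.full(len(res.x), np.nan)
    try:
        hess = numdiff.approx_hess(res.x, lambda p: _truncated_nb_nll_grad(p, y, X, offset)[0])
        cov = np.linalg.inv(hess)
        d = np.diag(cov)
        if np.all(d > 0):
            se = np.sqrt(d)
    except np.linalg.LinAlgError:
        pass
    se_alpha = alpha * se[-1]
    return beta, alpha, loglik, np.append(se[:-1], se_alpha), bool(res.converged)


def fit_hurdle_negbin(dm: DesignMatrix) -> CountModelFit:
    """Hurdle-NB MLE, exploiting the separability of the likelihood.

    The binary part (any infection vs none) is a logistic regression over all
    records; the positive part is a zero-truncated NB2 over the records with
    at least one infection, with the log-exposure offset. The same design
    terms are used in both parts. ``n_params`` counts both coefficient
    vectors plus the dispersion.
    """
    _check_full_rank(dm)
    y = dm.response
    pos = y > 0
    if not np.any(pos):
        raise ModelError("all responses are zero: no positive part to fit; use poisson/negbin")
    if np.all(pos):
        raise ModelError("no zero responses: hurdle not identified; use poisson/negbin")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(pos.astype(float), dm.predictors)
        try:
            logit = model.fit(disp=0, maxiter=200)
        except np.linalg.LinAlgError:
            # quasi-separation can make the Newton Hessian singular; BFGS
            # carries its own curvature approximation
            logit = model.fit(disp=0, maxiter=500, method="bfgs")
    gamma = np.asarray(logit.params, dtype=float)

    sub = dm.subset(pos)
    beta, alpha, ll_pos, se_pos, ok_pos = fit_truncated_negbin(
        sub.response, sub.predictors, sub.offset
    )
    loglik = float(logit.llf) + ll_pos
    return CountModelFit(
        family="hurdle_negbin",
        beta=beta,
        term_names=list(dm.term_names),
        loglik=loglik,
        n_params=2 * dm.k + 1,
        converged=bool(logit.mle_retvals.get("converged", True)) and ok_pos,
        alpha=alpha,
        gamma=gamma,
        gamma_term_names=list(dm.term_names),
        se_beta=se_pos[:-1],
        se_gamma=np.asarray(logit.bse, dtype=float),
        se_alpha=float(se_pos[-1]),
        reference_levels=dict(dm.reference_levels),
    )


FITTERS = {
    "poisson": fit_poisson,
    "negbin": fit_negbin,
    "hurdle_negbin": fit_hurdle_negbin,
}


def fit_family(dm: DesignMatrix, family: str) -> CountModelFit:
    if family not in FITTERS:
        raise ModelError(f"unknown family {family!r}; expected one of {FAMILIES}")
    return FITTERS[family](dm)


# ---------------------------------------------------------------------------
# Prediction and screening
# ---------------------------------------------------------------------------

def predict_expected(fit: CountModelFit, dm: DesignMatrix) -> np.ndarray:
    """Expected infection counts per record under a fitted model.

    Poisson / NB2: E_i = exp(x_i' beta + offset_i). Hurdle: the hurdle-NB
    mean, E_i = P(positive)_i * mu_i / (1 - NB0(mu_i, alpha)).

    The design must carry exactly the terms and reference levels the model
    was trained with; any mismatch raises instead of silently coercing.
    """
    if list(dm.term_names) != list(fit.term_names):
        raise ModelError(
            f"design terms {dm.term_names} do not match fitted terms {fit.term_names}"
        )
    for var, ref in fit.reference_levels.items():
        if dm.reference_levels.get(var) != ref:
            raise ModelError(f"reference level mismatch for {var!r}")
    mu = np.exp(dm.predictors @ fit.beta + dm.offset)
    if fit.family in ("poisson", "negbin"):
        return mu
    if fit.family == "hurdle_negbin":
        p_pos = special.expit(dm.predictors @ fit.gamma)
        p0 = np.clip(nb2_zero_prob(mu, fit.alpha), 0.0, 1.0 - 1e-15)
        return p_pos * mu / (1.0 - p0)
    raise ModelError(f"unknown family {fit.family!r}")


def loglik_at(fit: CountModelFit, dm: DesignMatrix) -> float:
    """Log-likelihood of a fitted model evaluated on (possibly new) records."""
    if list(dm.term_names) != list(fit.term_names):
        raise ModelError("design terms do not match fitted terms")
    mu = np.exp(dm.predictors @ fit.beta + dm.offset)
    if fit.family == "poisson":
        return float(np.sum(stats.poisson.logpmf(dm.response, mu)))
    if fit.family == "negbin":
        return float(np.sum(nb2_logpmf(dm.response, mu, fit.alpha or 0.0)))
    if fit.family == "hurdle_negbin":
        return hurdle_nb_loglik(fit.beta, fit.gamma, fit.alpha, dm)
    raise ModelError(f"unknown family {fit.family!r}")


def univariable_screen(
    records: pd.DataFrame,
    candidate_names: list[str] | tuple[str, ...],
    infection_type: str,
    p_threshold: float = 0.20,
) -> tuple[list[str], list[str]]:
    """Screen candidates by single-predictor NB regression Wald tests.

    Each candidate is fitted alone (with intercept and offset); it is
    retained when any of its Wald p-values falls below ``p_threshold``
    (for categorical candidates, any level). A candidate whose univariable
    fit fails to converge is retained conservatively, with a warning.

    Returns (retained names, warnings).
    """
    retained: list[str] = []
    notes: list[str] = []
    for name in candidate_names:
        dm = build_design(records, [name], infection_type)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.NegativeBinomial(
                    dm.response, dm.predictors, loglike_method="nb2", offset=dm.offset
                )
                res = model.fit(method="bfgs", maxiter=300, disp=0)
            converged = bool(res.mle_retvals.get("converged", True))
            pvals = np.asarray(res.pvalues)[1:-1]  # drop intercept and alpha
            if not converged or np.any(~np.isfinite(pvals)):
                retained.append(name)
                notes.append(f"{name}: univariable fit did not converge; retained")
            elif np.any(pvals < p_threshold):
                retained.append(name)
        except Exception as exc:  # singular or degenerate candidate
            retained.append(name)
            notes.append(f"{name}: univariable fit failed ({exc}); retained")
    return retained, notes


__all__ = [
    "CountModelFit",
    "DispersionDiagnostic",
    "FAMILIES",
    "ModelError",
    "build_design",
    "fit_family",
    "fit_hurdle_negbin",
    "fit_negbin",
    "fit_poisson",
    "fit_truncated_negbin",
    "hurdle_nb_loglik",
    "nb2_logpmf",
    "nb2_zero_prob",
    "observed_column",
    "overdispersion_check",
    "predict_expected",
    "truncated_nb2_logpmf",
    "univariable_screen",
]
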