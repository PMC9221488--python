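"""AR(1) + GJR-GARCH(1,1) marginal model with Student-t innovations.

Each channel's series is filtered by

    x_t = c0 + c1 x_{t-1} + a_t,        a_t = sigma_t * xi_t,
    sigma_t^2 = omega + alpha a_{t-1}^2 + beta sigma_{t-1}^2
                + gamma a_{t-1}^2 1{a_{t-1} < 0},
    xi_t ~ t_d, standardized to unit variance,

so that sigma_t^2 is the conditional variance and the standardized residuals
xi_t = a_t / sigma_t are i.i.d.  The probability-integral transform (PIT)
maps them to uniform (0,1) margins, which is what the vine copula consumes.

Innovations are symmetric Student-t (the skew parameter of a skewed-t
specification is deliberately not estimated; the PIT contract is the
symmetric t CDF).  The leverage indicator is the canonical GJR term
1{a_{t-1} < 0}.  Covariance stationarity requires alpha + beta + gamma/2 < 1
for symmetric innovations, with unconditional variance
omega / (1 - alpha - beta - gamma/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import integrate, stats
from statsmodels.tools.numdiff import approx_hess3

__all__ = [
    "ArGjrGarch",
    "GarchResults",
    "garch_loglik",
    "fit_garch",
    "simulate_garch",
    "conditional_cdf",
    "pit_transform",
    "PARAM_NAMES",
]

PARAM_NAMES = ("c0", "c1", "omega", "alpha", "beta", "gamma", "dof")

_STATIONARITY_SLACK = 1e-7


@njit(cache=True)
def _recursion(x, c0, c1, omega, alpha, beta, gamma):  # pragma: no cover - jit
    n = x.shape[0]
    a = np.empty(n - 1)
    for t in range(1, n):
        a[t - 1] = x[t] - c0 - c1 * x[t - 1]
    m = 0.0
    for i in range(n - 1):
        m += a[i]
    m /= n - 1
    v = 0.0
    for i in range(n - 1):
        v += (a[i] - m) ** 2
    v /= n - 1
    s2 = np.empty(n - 1)
    s2[0] = v if v > 1e-300 else 1e-300
    for t in range(1, n - 1):
        lev = gamma * a[t - 1] ** 2 if a[t - 1] < 0.0 else 0.0
        s2[t] = omega + alpha * a[t - 1] ** 2 + beta * s2[t - 1] + lev
    return a, s2


def _admissible(params) -> bool:
    c0, c1, omega, alpha, beta, gamma, dof = params
    return (
        omega > 0.0
        and alpha >= 0.0
        and beta >= 0.0
        and gamma >= 0.0
        and alpha + beta + 0.5 * gamma < 1.0 - _STATIONARITY_SLACK
        and dof > 2.0
        and abs(c1) < 1.0
    )


def _unit_t_logpdf(z, dof):
    """log density of a Student-t rescaled to unit variance."""
    s2 = dof - 2.0
    return (
        math.lgamma((dof + 1.0) / 2.0)
        - math.lgamma(dof / 2.0)
        - 0.5 * math.log(math.pi * s2)
        - (dof + 1.0) / 2.0 * np.log1p(z * z / s2)
    )


def _unit_t_cdf(z, dof):
    return stats.t.cdf(np.asarray(z) * math.sqrt(dof / (dof - 2.0)), dof)


def _unit_t_ppf(u, dof):
    return stats.t.ppf(u, dof) * math.sqrt((dof - 2.0) / dof)


def garch_loglik(params, x) -> float:
    """Exact conditional log-likelihood of the AR(1)+GJR-GARCH(1,1)-t model.

    ``params`` is (c0, c1, omega, alpha, beta, gamma, dof).  sigma_1^2 is
    initialized at the sample variance of the mean-equation residuals.
    Inadmissible parameters return -inf (a rejection signal, not an error).
    """
    params = tuple(float(p) for p in params)
    if not _admissible(params):
        return -math.inf
    x = np.ascontiguousarray(x, dtype=float)
    if x.size < 50:
        raise ValueError("need at least 50 observations")
    c0, c1, omega, alpha, beta, gamma, dof = params
    a, s2 = _recursion(x, c0, c1, omega, alpha, beta, gamma)
    if not np.all(np.isfinite(s2)) or np.any(s2 <= 0):
        return -math.inf
    z = a / np.sqrt(s2)
    ll = np.sum(_unit_t_logpdf(z, dof)) - 0.5 * np.sum(np.log(s2))
    return float(ll) if np.isfinite(ll) else -math.inf


def simulate_garch(params, n, rng=None, innovations=None, burn=500):
    """Simulate the model.  Either a seeded generator or a (burn+n,) vector of
    uniform innovations may be supplied (the latter is how the synthetic-data
    module injects cross-channel dependence)."""
    params = tuple(float(p) for p in params)
    if not _admissible(params):
        raise ValueError(f"inadmissible GARCH parameters {params}")
    c0, c1, omega, alpha, beta, gamma, dof = params
    if innovations is None:
        if isinstance(rng, (int, np.integer)) or rng is None:
            rng = np.random.default_rng(rng)
        u = rng.uniform(size=n + burn)
    else:
        u = np.asarray(innovations, dtype=float)
        if u.size < n + burn:
            burn = u.size - n
            if burn < 0:
                raise ValueError("not enough innovations supplied")
    xi = _unit_t_ppf(np.clip(u, 1e-12, 1 - 1e-12), dof)
    uncond = omega / (1.0 - alpha - beta - 0.5 * gamma)
    x = np.empty(n + burn)
    s2 = uncond
    a_prev = 0.0
    x_prev = c0 / (1.0 - c1) if abs(c1) < 1 else 0.0
    for t in range(n + burn):
        if t > 0:
            lev = gamma * a_prev * a_prev if a_prev < 0 else 0.0
            s2 = omega + alpha * a_prev * a_prev + beta * s2 + lev
        a = math.sqrt(s2) * xi[t]
        x[t] = c0 + c1 * x_prev + a
        a_prev = a
        x_prev = x[t]
    return x[burn:]


@dataclass
class GarchResults:
    """Results of :meth:`ArGjrGarch.fit`.

    ``sigma2``, ``resid`` and ``std_resid`` all have length n-1 (the AR(1)
    mean equation consumes one observation).
    """

    params: pd.Series
    bse: pd.Series
    loglik: float
    converged: bool
    sigma2: np.ndarray
    resid: np.ndarray
    std_resid: np.ndarray
    nobs: int
    x_last: float
    model: "ArGjrGarch" = field(repr=False, default=None)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * len(self.params)

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + len(self.params) * math.log(self.nobs)

    @property
    def persistence(self) -> float:
        p = self.params
        return float(p["alpha"] + p["beta"] + 0.5 * p["gamma"])

    def pit(self) -> np.ndarray:
        """Probability-integral transform of the standardized residuals."""
        u = _unit_t_cdf(self.std_resid, float(self.params["dof"]))
        return np.clip(u, 1e-10, 1.0 - 1e-10)

    def conditional_cdf(self, x_next) -> float:
        """One-step-ahead conditional CDF F(x_{t+1} | history)."""
        p = self.params
        a_n = self.resid[-1]
        s2_n = self.sigma2[-1]
        lev = p["gamma"] * a_n * a_n if a_n < 0 else 0.0
        s2_next = p["omega"] + p["alpha"] * a_n * a_n + p["beta"] * s2_n + lev
        z = (np.asarray(x_next, dtype=float) - p["c0"] - p["c1"] * self.x_last) / math.sqrt(
            s2_next
        )
        out = _unit_t_cdf(z, float(p["dof"]))
        return float(out) if np.ndim(out) == 0 else out

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "loglik": self.loglik,
            "converged": self.converged,
            "nobs": self.nobs,
        }

    def summary(self) -> str:
        tab = pd.DataFrame({"coef": self.params, "std err": self.bse})
        lines = [
            "AR(1)-GJR-GARCH(1,1) Student-t results",
            "=" * 42,
            tab.to_string(float_format=lambda v: f"{v: .6f}"),
            "-" * 42,
            f"nobs {self.nobs}   loglik {self.loglik:.3f}   "
            f"AIC {self.aic:.3f}   BIC {self.bic:.3f}",
            f"persistence alpha+beta+gamma/2 = {self.persistence:.4f}   "
            f"converged: {self.converged}",
        ]
        return "\n".join(lines)


class ArGjrGarch:
    """Per-channel marginal model, statsmodels-style: construct from the data,
    then :meth:`fit` by constrained maximum likelihood from three fixed
    deterministic starting points (no randomness, so refitting reproduces the
    same estimates bit for bit)."""

    def __init__(self, x):
        x = np.ascontiguousarray(x, dtype=float)
        if x.ndim != 1:
            raise ValueError("series must be one-dimensional")
        if not np.all(np.isfinite(x)):
            raise ValueError("series contains non-finite values")
        if x.size < 50:
            raise ValueError("need at least 50 observations")
        if np.ptp(x) == 0:
            raise ValueError("constant series has zero variance; cannot fit")
        self.x = x

    def _starts(self):
        x = self.x
        v = float(np.var(x))
        r1 = float(np.corrcoef(x[:-1], x[1:])[0, 1])
        r1 = np.clip(r1, -0.9, 0.9)
        m = float(np.mean(x))
        c0 = m * (1.0 - r1)
        return [
            (c0, r1, 0.05 * v, 0.05, 0.88, 0.02, 8.0),
            (c0, r1, 0.20 * v, 0.10, 0.70, 0.05, 6.0),
            (0.0, 0.0, 0.50 * v, 0.02, 0.45, 0.02, 12.0),
        ]

    def _fit_constant_variance(self, bounds):
        """Nested AR(1)-t submodel with alpha = beta = gamma = 0.

        When the data carry no ARCH effects the GJR recursion is not
        identified (beta rides a flat likelihood ridge once alpha + gamma
        vanish); the submodel resolves the boundary case.
        """
        from scipy.optimize import minimize

        x = self.x

        def nll(th):
            c0, c1, omega, dof = th
            ll = garch_loglik((c0, c1, omega, 0.0, 0.0, 0.0, dof), x)
            return -ll if np.isfinite(ll) else 1e7

        v = float(np.var(x))
        r1 = float(np.clip(np.corrcoef(x[:-1], x[1:])[0, 1], -0.9, 0.9))
        x0 = np.array([np.mean(x) * (1 - r1), r1, v, 8.0])
        sub_bounds = [bounds[0], bounds[1], bounds[2], bounds[6]]
        res = minimize(nll, x0, method="L-BFGS-B", bounds=sub_bounds,
                       options={"maxiter": 500, "ftol": 1e-12})
        c0, c1, omega, dof = (float(t) for t in res.x)
        return (c0, c1, omega, 0.0, 0.0, 0.0, dof), res

    def fit(self, compute_bse: bool = True) -> GarchResults:
        from scipy.optimize import minimize

        x = self.x
        v = float(np.var(x))
        s = float(np.std(x))
        m = float(np.mean(x))
        bounds = [
            (m - 10 * s, m + 10 * s),
            (-0.995, 0.995),
            (1e-12 * max(v, 1e-12), 10.0 * v),
            (0.0, 0.999),
            (0.0, 0.999),
            (0.0, 0.999),
            (2.1, 100.0),
        ]

        def nll(th):
            ll = garch_loglik(th, x)
            if not np.isfinite(ll):
                # smooth-ish penalty pushing back into the admissible region
                pen = max(0.0, th[3] + th[4] + 0.5 * th[5] - 0.999)
                return 1e7 * (1.0 + pen)
            return -ll

        best = None
        for x0 in self._starts():
            res = minimize(
                nll,
                np.asarray(x0),
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": 500, "ftol": 1e-12},
            )
            if best is None or res.fun < best.fun:
                best = res
        params = tuple(float(t) for t in best.x)
        ll = garch_loglik(params, x)
        converged = bool(best.success) and np.isfinite(ll)

        # BIC comparison against the nested constant-variance AR(1)-t model:
        # resolves the beta non-identifiability when ARCH effects are absent.
        n = x.size
        sub_params, sub_res = self._fit_constant_variance(bounds)
        sub_ll = garch_loglik(sub_params, x)
        bic_full = -2.0 * ll + 7 * math.log(n)
        bic_sub = -2.0 * sub_ll + 4 * math.log(n)
        free = np.ones(7, dtype=bool)
        if np.isfinite(sub_ll) and bic_sub <= bic_full:
            params, ll = sub_params, sub_ll
            converged = bool(sub_res.success)
            free[3:6] = False

        bse = np.full(7, np.nan)
        if compute_bse and converged:
            try:
                idx = np.flatnonzero(free)
                p0 = np.asarray(params)

                def obj(sub):
                    full = p0.copy()
                    full[idx] = sub
                    return -garch_loglik(full, x)

                hess = approx_hess3(p0[idx], obj)
                cov = np.linalg.pinv(hess)
                d = np.diag(cov)
                bse[idx] = np.where(d > 0, np.sqrt(np.abs(d)), np.nan)
            except Exception:
                pass

        a, s2 = _recursion(x, *params[:6])
        return GarchResults(
            params=pd.Series(params, index=PARAM_NAMES),
            bse=pd.Series(bse, index=PARAM_NAMES),
            loglik=float(ll),
            converged=converged,
            sigma2=s2,
            resid=a,
            std_resid=a / np.sqrt(s2),
            nobs=x.size,
            x_last=float(x[-1]),
            model=self,
        )


# -- functional wrappers ----------------------------------------------------


def fit_garch(x) -> GarchResults:
    """Fit the AR(1)+GJR-GARCH(1,1)-t model to a univariate series."""
    return ArGjrGarch(x).fit()


def pit_transform(res: GarchResults) -> np.ndarray:
    if not res.converged:
        raise ValueError("PIT requires a converged marginal model")
    return res.pit()


def conditional_cdf(res: GarchResults, x_next) -> float:
    return res.conditional_cdf(x_next)


def conditional_density_quadrature(res: GarchResults, x_next, lo=None) -> float:
    """Quadrature cross-check of :func:`conditional_cdf`: integrates the
    implied one-step conditional density up to ``x_next``."""
    p = res.params
    a_n = res.resid[-1]
    lev = p["gamma"] * a_n * a_n if a_n < 0 else 0.0
    s2_next = p["omega"] + p["alpha"] * a_n * a_n + p["beta"] * res.sigma2[-1] + lev
    mu = p["c0"] + p["c1"] * res.x_last
    sig = math.sqrt(s2_next)
    dof = float(p["dof"])

    def dens(t):
        z = (t - mu) / sig
        return math.exp(_unit_t_logpdf(np.asarray(z), dof)) / sig

    val, _ = integrate.quad(dens, -np.inf, x_next, epsabs=1e-12, epsrel=1e-12)
    return val
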