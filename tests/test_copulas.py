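"""Unit and property tests for the bivariate copula engine."""

import itertools
import math

import numpy as np
import pytest
from scipy import special, stats

from vinecmc import copulas as cp
from vinecmc.copulas import (
    PairCopula,
    copula_cdf,
    copula_pdf,
    empirical_kendall_tau,
    fit_pair_copula,
    h_function,
    h_inverse,
    params_from_tau,
    sample_pair_copula,
    tau_copula_integral,
    tau_from_params,
)

# a moderate-dependence parameterization of every family
CASES = [
    ("independence", ()),
    ("gaussian", (0.5,)),
    ("student_t", (0.5, 5.0)),
    ("clayton", (1.333,)),
    ("gumbel", (1.667,)),
    ("frank", (4.0,)),
    ("clayton90", (1.333,)),
    ("clayton180", (1.333,)),
    ("clayton270", (1.333,)),
    ("gumbel90", (1.667,)),
    ("gumbel180", (1.667,)),
    ("gumbel270", (1.667,)),
]


def _pc(name, th):
    return PairCopula(name, th)


# ---------------------------------------------------------------------------
# Kendall tau
# ---------------------------------------------------------------------------


def brute_force_tau(x, y):
    """All-pairs concordant-minus-discordant count (no ties assumed)."""
    n = len(x)
    s = 0
    for i, j in itertools.combinations(range(n), 2):
        s += np.sign((x[i] - x[j]) * (y[i] - y[j]))
    return s / (n * (n - 1) / 2)


def test_empirical_tau_small_example():
    x = [1, 2, 3, 4]
    y = [1, 3, 2, 4]
    assert empirical_kendall_tau(x, y) == pytest.approx(2 / 3)
    assert brute_force_tau(x, y) == pytest.approx(2 / 3)


def test_empirical_tau_perfect_concordance_discordance(rng):
    x = rng.normal(size=50)
    assert empirical_kendall_tau(x, x) == pytest.approx(1.0)
    assert empirical_kendall_tau(x, -x) == pytest.approx(-1.0)


def test_empirical_tau_matches_brute_force(rng):
    x = rng.normal(size=40)
    y = 0.5 * x + rng.normal(size=40)
    assert empirical_kendall_tau(x, y) == pytest.approx(brute_force_tau(x, y), abs=1e-12)


def test_empirical_tau_errors():
    with pytest.raises(ValueError):
        empirical_kendall_tau([1, 2], [1, 2, 3])
    with pytest.raises(ValueError):
        empirical_kendall_tau([1], [2])


def test_closed_form_taus():
    assert tau_from_params("gaussian", (0.5,)) == pytest.approx(1 / 3, abs=1e-10)
    assert tau_from_params("clayton", (2.0,)) == pytest.approx(0.5, abs=1e-10)
    assert tau_from_params("gumbel", (4.0,)) == pytest.approx(0.75, abs=1e-10)


@pytest.mark.parametrize(
    "family,tau",
    [
        ("gaussian", 0.4),
        ("gaussian", -0.6),
        ("student_t", 0.3),
        ("clayton", 0.35),
        ("gumbel", 0.55),
        ("frank", 0.45),
        ("frank", -0.3),
        ("clayton90", -0.4),
        ("gumbel270", -0.5),
    ],
)
def test_tau_param_roundtrip(family, tau):
    params = params_from_tau(family, tau)
    assert tau_from_params(family, params) == pytest.approx(tau, abs=1e-10)


def test_params_from_tau_out_of_range():
    with pytest.raises(ValueError):
        params_from_tau("clayton", -0.2)
    with pytest.raises(ValueError):
        params_from_tau("gumbel", -0.1)
    with pytest.raises(ValueError):
        params_from_tau("gaussian", 1.5)


@pytest.mark.parametrize(
    "family,th,expected",
    [
        ("independence", (), 0.0),
        ("gaussian", (0.5,), 1 / 3),
        ("clayton", (2.0,), 0.5),
    ],
)
def test_tau_copula_integral(family, th, expected):
    pc = _pc(family, th)
    assert tau_copula_integral(pc) == pytest.approx(expected, abs=1e-3)


# ---------------------------------------------------------------------------
# CDF / PDF
# ---------------------------------------------------------------------------


def test_cdf_independence_and_clayton_values():
    assert copula_cdf(_pc("independence", ()), 0.3, 0.7) == pytest.approx(0.21)
    # Clayton closed form at theta=2, u=v=0.5: (2^2 + 2^2 - 1)^(-1/2)
    val = copula_cdf(_pc("clayton", (2.0,)), 0.5, 0.5)
    assert val == pytest.approx(7 ** -0.5, abs=1e-12)


@pytest.mark.parametrize("family,th", CASES)
def test_cdf_margins(family, th, rng):
    pc = _pc(family, th)
    u = rng.uniform(0.05, 0.95, 25)
    np.testing.assert_allclose(copula_cdf(pc, u, np.ones_like(u)), u, atol=1e-9)
    np.testing.assert_allclose(copula_cdf(pc, np.ones_like(u), u), u, atol=1e-9)
    np.testing.assert_allclose(copula_cdf(pc, u, np.zeros_like(u)), 0.0, atol=1e-12)


@pytest.mark.parametrize("family,th", CASES)
def test_cdf_two_increasing(family, th, rng):
    pc = _pc(family, th)
    u1 = rng.uniform(0.05, 0.6, 30)
    v1 = rng.uniform(0.05, 0.6, 30)
    u2 = u1 + 0.3
    v2 = v1 + 0.3
    vol = (
        copula_cdf(pc, u2, v2)
        - copula_cdf(pc, u1, v2)
        - copula_cdf(pc, u2, v1)
        + copula_cdf(pc, u1, v1)
    )
    assert np.all(vol >= -1e-9)


def test_cdf_domain_error():
    with pytest.raises(ValueError):
        copula_cdf(_pc("gaussian", (0.5,)), 1.2, 0.5)


def test_pdf_independence_and_gaussian_zero():
    assert copula_pdf(_pc("independence", ()), 0.3, 0.9) == pytest.approx(1.0)
    assert copula_pdf(_pc("gaussian", (0.0,)), 0.2, 0.7) == pytest.approx(1.0)


def test_gaussian_pdf_change_of_variables(rng):
    """c(u,v) = bivariate normal density / product of margins at the quantiles."""
    rho = 0.5
    pc = _pc("gaussian", (rho,))
    u = rng.uniform(0.02, 0.98, 20)
    v = rng.uniform(0.02, 0.98, 20)
    x = special.ndtri(u)
    y = special.ndtri(v)
    cov = np.array([[1, rho], [rho, 1]])
    num = stats.multivariate_normal(cov=cov).pdf(np.column_stack([x, y]))
    den = stats.norm.pdf(x) * stats.norm.pdf(y)
    np.testing.assert_allclose(copula_pdf(pc, u, v), num / den, atol=1e-8)


@pytest.mark.parametrize("family,th", CASES)
def test_pdf_integrates_to_one(family, th):
    g = (np.arange(200) + 0.5) / 200
    U, V = np.meshgrid(g, g)
    integral = copula_pdf(_pc(family, th), U, V).mean()
    assert integral == pytest.approx(1.0, abs=1e-3)


# ---------------------------------------------------------------------------
# h-functions
# ---------------------------------------------------------------------------


def test_h_trivials():
    pc = _pc("independence", ())
    assert h_function(pc, 0.3, 0.8) == pytest.approx(0.3)
    # Gaussian symmetry at the median
    assert h_function(_pc("gaussian", (0.7,)), 0.5, 0.5) == pytest.approx(0.5)


@pytest.mark.parametrize("family,th", CASES)
def test_h_matches_finite_difference(family, th, rng):
    pc = _pc(family, th)
    u = rng.uniform(0.02, 0.98, 100)
    v = rng.uniform(0.02, 0.98, 100)
    eps = 1e-5
    fd = (copula_cdf(pc, u, v + eps) - copula_cdf(pc, u, v - eps)) / (2 * eps)
    np.testing.assert_allclose(h_function(pc, u, v), fd, atol=1e-5)


@pytest.mark.parametrize("family,th", CASES)
def test_hinv_roundtrip(family, th, rng):
    pc = _pc(family, th)
    u = rng.uniform(0.01, 0.99, 200)
    v = rng.uniform(0.01, 0.99, 200)
    np.testing.assert_allclose(h_inverse(pc, h_function(pc, u, v), v), u, atol=1e-8)
    # and the first-argument-conditioning direction used inside the vine
    np.testing.assert_allclose(
        cp.hinv(pc, cp.hfunc(pc, u, v, cond_on=1), u, cond_on=1), v, atol=1e-8
    )


@pytest.mark.parametrize("family,th", CASES)
def test_h_monotone_in_first_argument(family, th, rng):
    pc = _pc(family, th)
    v = float(rng.uniform(0.2, 0.8))
    u = np.linspace(0.02, 0.98, 60)
    h = h_function(pc, u, np.full_like(u, v))
    assert np.all(np.diff(h) > 0)


@pytest.mark.parametrize("family,th", [c for c in CASES if c[0] != "independence"])
def test_sampled_tau_matches_model_tau(family, th, rng):
    n = 5000
    pc = _pc(family, th)
    uv = sample_pair_copula(pc, n, rng)
    tau_hat = empirical_kendall_tau(uv[:, 0], uv[:, 1])
    se = math.sqrt(2 * (2 * n + 5) / (9 * n * (n - 1)))
    assert abs(tau_hat - pc.tau) < 3 * se + 0.01


# ---------------------------------------------------------------------------
# fitting / selection
# ---------------------------------------------------------------------------


def test_fit_recovers_clayton():
    hits = 0
    thetas = []
    for rep in range(50):
        uv = sample_pair_copula(_pc("clayton", (2.0,)), 2000, 1000 + rep)
        fit = fit_pair_copula(uv[:, 0], uv[:, 1])
        if fit.family == "clayton":
            hits += 1
            thetas.append(fit.params[0])
    assert hits >= 45  # >= 90%
    assert all(1.6 <= t <= 2.4 for t in thetas)


def test_fit_recovers_gaussian_rho():
    for rep in range(10):
        uv = sample_pair_copula(_pc("gaussian", (0.8,)), 2000, 2000 + rep)
        fit = fit_pair_copula(uv[:, 0], uv[:, 1], candidates=("gaussian",))
        assert abs(fit.params[0] - 0.8) < 0.05


def test_bic_prefers_independence_on_null():
    hits = 0
    for rep in range(25):
        r = np.random.default_rng(3000 + rep)
        u, v = r.uniform(size=2000), r.uniform(size=2000)
        fit = fit_pair_copula(u, v, criterion="bic")
        hits += fit.family == "independence"
    assert hits >= 20  # >= 80%


def test_fit_negative_dependence_uses_rotation(rng):
    uv = sample_pair_copula(_pc("clayton90", (2.0,)), 2000, rng)
    fit = fit_pair_copula(uv[:, 0], uv[:, 1])
    assert fit.tau < -0.3
    assert fit.family in ("clayton90", "clayton270", "gaussian", "student_t", "frank")


def test_fit_statistics_consistent(rng):
    uv = sample_pair_copula(_pc("gaussian", (0.6,)), 500, rng)
    fit = fit_pair_copula(uv[:, 0], uv[:, 1])
    k = len(fit.params)
    assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * k)
    assert fit.bic == pytest.approx(-2 * fit.loglik + k * math.log(fit.n_obs))


def test_pair_copula_rejects_bad_params():
    with pytest.raises(ValueError):
        PairCopula("gaussian", (1.5,))
    with pytest.raises(ValueError):
        PairCopula("clayton", (-1.0,))
    with pytest.raises(ValueError):
        PairCopula("nosuch", ())
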