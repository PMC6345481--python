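"""Minimum-detectable-effect (MDE) power analysis.

Sensitivity analyses answer: given the sample size, alpha = .05 and target
power = .80, what is the smallest effect the test could have detected?

* Paired t: exact power from the noncentral t distribution with
  df = n - 1 and noncentrality d_z * sqrt(n).
* Pearson correlation: exact power by integrating the sampling density of
  the correlation coefficient under bivariate normality (the
  hypergeometric-function form) beyond the two-tailed critical r.  The
  Fisher-z and noncentral-t approximations are provided as cross-checks;
  at n around 30 they can differ from the exact value in the second
  decimal.
* A generic noncentral-F routine covers repeated-measures F tests.

MDEs are found by bisection on the strictly monotone power functions.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, optimize, special
from scipy import stats as sps


def _two_tailed_nct(crit: float, df: float, nc: float) -> float:
    """P(|T| > crit) for noncentral t; guards the far-tail NaNs of scipy."""
    hi = sps.nct.sf(crit, df, nc)
    if not np.isfinite(hi):
        hi = 1.0 if nc > crit else 0.0
    lo = sps.nct.cdf(-crit, df, nc)
    if not np.isfinite(lo):
        lo = 0.0
    return float(hi + lo)


def _check_alpha_power(alpha: float, power: float | None = None) -> None:
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if power is not None and not alpha < power < 1:
        raise ValueError("power must be in (alpha, 1)")


def power_paired_t(n: int, d: float, alpha: float = 0.05, tails: int = 2) -> float:
    """Exact power of the paired t test for standardized difference d_z = d."""
    if n < 2:
        raise ValueError("need n >= 2")
    if d < 0:
        raise ValueError("d must be nonnegative")
    _check_alpha_power(alpha)
    df = n - 1
    nc = d * np.sqrt(n)
    if tails == 2:
        crit = sps.t.ppf(1 - alpha / 2, df)
        return _two_tailed_nct(crit, df, nc)
    if tails == 1:
        crit = sps.t.ppf(1 - alpha, df)
        hi = sps.nct.sf(crit, df, nc)
        return float(hi if np.isfinite(hi) else (1.0 if nc > crit else 0.0))
    raise ValueError("tails must be 1 or 2")


def mde_paired_t(n: int, alpha: float = 0.05, power: float = 0.80,
                 tails: int = 2) -> float:
    """Smallest d_z detectable with the requested power (bisection to 1e-6)."""
    _check_alpha_power(alpha, power)
    f = lambda d: power_paired_t(n, d, alpha, tails) - power
    if f(10.0) < 0:
        raise ValueError("requested power not attainable with d <= 10")
    return float(optimize.brentq(f, 0.0, 10.0, xtol=1e-8))


# ---------------------------------------------------------------------------
# correlation


def correlation_pdf(r: np.ndarray | float, n: int, rho: float) -> np.ndarray | float:
    """Sampling density of the Pearson correlation under bivariate normality."""
    r = np.asarray(r, dtype=float)
    log_f = (
        np.log(n - 2)
        + special.gammaln(n - 1)
        + (n - 1) / 2 * np.log1p(-rho**2)
        + (n - 4) / 2 * np.log1p(-(r**2))
        - 0.5 * np.log(2 * np.pi)
        - special.gammaln(n - 0.5)
        - (n - 1.5) * np.log1p(-rho * r)
    )
    return np.exp(log_f) * special.hyp2f1(0.5, 0.5, n - 0.5, (1 + rho * r) / 2)


def _critical_r(n: int, alpha: float, tails: int = 2) -> float:
    tc = sps.t.ppf(1 - alpha / tails, n - 2)
    return float(tc / np.sqrt(n - 2 + tc**2))


def power_correlation(
    n: int, rho: float, alpha: float = 0.05, tails: int = 2, method: str = "exact"
) -> float:
    """Power of the two-tailed correlation t test for population |rho|.

    ``method='exact'`` integrates the true sampling density of r;
    ``'nct'`` uses the noncentral-t approximation of the test statistic;
    ``'fisher'`` the Fisher-z normal approximation.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    _check_alpha_power(alpha)
    rho = abs(float(rho))
    if rho >= 1:
        raise ValueError("|rho| must be < 1")
    if method == "exact":
        rc = _critical_r(n, alpha, tails)
        upper, _ = integrate.quad(correlation_pdf, rc, 1.0, args=(n, rho), limit=200)
        lower, _ = integrate.quad(correlation_pdf, -1.0, -rc, args=(n, rho), limit=200)
        return float(upper + (lower if tails == 2 else 0.0))
    if method == "nct":
        df = n - 2
        nc = rho * np.sqrt(n - 2) / np.sqrt(1 - rho**2)
        crit = sps.t.ppf(1 - alpha / tails, df)
        return _two_tailed_nct(crit, df, nc)
    if method == "fisher":
        zr = np.arctanh(rho)
        se = 1.0 / np.sqrt(n - 3)
        zc = sps.norm.ppf(1 - alpha / tails)
        return float(
            sps.norm.sf(zc - zr / se) + (sps.norm.cdf(-zc - zr / se) if tails == 2 else 0.0)
        )
    raise ValueError(f"unknown method {method!r}")


def mde_correlation(
    n: int,
    alpha: float = 0.05,
    power: float = 0.80,
    tails: int = 2,
    method: str = "exact",
    sign: int = 1,
) -> float:
    """Minimum detectable population correlation magnitude.

    ``sign=-1`` reports the value with a negative sign, the convention
    when the association of interest is negative.
    """
    _check_alpha_power(alpha, power)
    f = lambda r: power_correlation(n, r, alpha, tails, method) - power
    if f(0.999) < 0:
        raise ValueError("requested power not attainable for |rho| < 1")
    r = float(optimize.brentq(f, 1e-9, 0.999, xtol=1e-8))
    return sign * r


# ---------------------------------------------------------------------------
# generic noncentral F (repeated-measures sensitivity)


def power_f(df_num: int, df_den: int, noncentrality: float, alpha: float = 0.05) -> float:
    """Power of an F test at the given noncentrality parameter."""
    _check_alpha_power(alpha)
    crit = sps.f.ppf(1 - alpha, df_num, df_den)
    if noncentrality <= 0:
        # scipy's ncf is unreliable at the central boundary
        return float(sps.f.sf(crit, df_num, df_den))
    p = sps.ncf.sf(crit, df_num, df_den, noncentrality)
    if not np.isfinite(p) or not 0.0 <= p <= 1.0:
        return 1.0
    return float(p)


def mde_eta_p2(
    df_num: int,
    df_den: int,
    n_obs: int,
    alpha: float = 0.05,
    power: float = 0.80,
) -> float:
    """Smallest partial eta squared detectable by an F test.

    Uses the mapping lambda = f^2 * (df_den + df_num + 1) with
    f^2 = eta_P^2 / (1 - eta_P^2).  Repeated-measures software differs in
    how the effective noncentrality is composed from the design (epsilon
    multipliers, correlation among measures); this routine states its
    convention and makes no claim of matching any particular program.
    """
    _check_alpha_power(alpha, power)
    del n_obs  # noncentrality composed from the dfs under this convention

    def pw(eta: float) -> float:
        f2 = eta / (1 - eta)
        lam = f2 * (df_den + df_num + 1)
        return power_f(df_num, df_den, lam, alpha)

    f = lambda e: pw(e) - power
    if f(0.999) < 0:
        raise ValueError("requested power not attainable")
    return float(optimize.brentq(f, 1e-9, 0.999, xtol=1e-9))
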