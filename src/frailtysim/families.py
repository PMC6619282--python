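"""Laplace-transform calculus for shared-frailty distributions.

Every supported frailty law is represented through its Laplace transform
``L(c) = E[exp(-c Z)]`` and the signed derivatives ``L^(k)(c)``.  These are
the only objects the marginal likelihood, the posterior frailty mean

    E[Z | N events, accumulated hazard c] = -L^(N+1)(c) / L^(N)(c),

the marginal hazard ratio of survivors, and the median concordance need.

Parametrizations (``theta`` is the association parameter):

* ``gamma`` and ``inverse_gaussian``: mean 1 and variance ``1/theta``.
* ``positive_stable``: ``L(c) = exp(-c^b)`` with ``b = 1/(1+theta)``, so
  ``theta = 0`` is the degenerate no-frailty boundary.  The variance is
  infinite; ``theta`` is only an association index.  A different scale
  convention amounts to redefining ``b`` below.
* ``lognormal``: mean 1 and variance ``1/theta``; no closed-form transform,
  evaluated by adaptive quadrature.  Supported for data generation and
  marginal-hazard-ratio curves only, never for fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize
from scipy.special import gammaln, logsumexp

__all__ = [
    "FrailtyFamily",
    "GammaFrailty",
    "InverseGaussianFrailty",
    "PositiveStableFrailty",
    "LogNormalFrailty",
    "get_family",
    "laplace",
    "laplace_derivative",
    "posterior_expectation",
    "marginal_hazard_ratio",
    "median_concordance",
]

_ROOT_BRACKET = (1e-12, 1e6)
_ROOT_TOL = 1e-10


def _eval_poly(coefs: np.ndarray, first_power: int, x: np.ndarray) -> np.ndarray:
    """sum_j coefs[j] x^(first_power + j), Horner on ascending coefficients."""
    acc = np.zeros_like(x)
    for c in coefs[::-1]:
        acc = acc * x + c
    return acc * x**first_power


def _check_c(c):
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("Laplace transform argument c must be nonnegative")
    return c


@dataclass(frozen=True)
class FrailtyFamily:
    """Base class; subclasses implement ``log_signed_derivative``."""

    theta: float
    name = "abstract"

    def __post_init__(self):
        if self.theta <= 0:
            raise ValueError(f"theta must be positive, got {self.theta}")

    # -- core transform ----------------------------------------------------
    def laplace(self, c):
        """E[exp(-c Z)], in (0, 1] for c >= 0."""
        c = _check_c(c)
        return np.exp(self.log_laplace(c))

    def log_laplace(self, c):
        raise NotImplementedError

    def log_signed_derivative(self, k: int, c):
        """log[ (-1)^k L^(k)(c) ]; complete monotonicity makes this real."""
        raise NotImplementedError

    def laplace_derivative(self, k: int, c):
        """k-th derivative L^(k)(c); sign is (-1)^k."""
        if k < 0:
            raise ValueError("derivative order k must be >= 0")
        c = _check_c(c)
        return (-1.0) ** k * np.exp(self.log_signed_derivative(k, c))

    # -- derived quantities ------------------------------------------------
    def posterior_expectation(self, n_events, cumhaz):
        """E[Z | n_events observed, conditional cumulative hazard cumhaz].

        Vectorized over ``n_events`` / ``cumhaz`` of matching shape.
        """
        n = np.asarray(n_events)
        c = _check_c(cumhaz)
        if np.any(n < 0):
            raise ValueError("n_events must be nonnegative")
        n_b, c_b = np.broadcast_arrays(n, c)
        scalar = n_b.ndim == 0
        flatn, flatc = n_b.ravel(), c_b.ravel()
        flato = np.empty(flatn.shape, dtype=float)
        for order in np.unique(flatn):
            sel = flatn == order
            cc = flatc[sel]
            flato[sel] = np.exp(
                self.log_signed_derivative(int(order) + 1, cc)
                - self.log_signed_derivative(int(order), cc)
            )
        return float(flato[0]) if scalar else flato.reshape(n_b.shape)

    def marginal_hazard_ratio(self, beta: float, cumhaz0):
        """Hazard ratio of survivors between x=1 and x=0 groups.

        ``cumhaz0`` is the baseline cumulative hazard at the evaluation time;
        each group's posterior frailty mean conditions on its own accumulated
        hazard ``cumhaz0 * exp(beta * x)``.
        """
        c0 = _check_c(cumhaz0)
        e0 = self.posterior_expectation(np.zeros_like(c0, dtype=int), c0)
        e1 = self.posterior_expectation(
            np.zeros_like(c0, dtype=int), c0 * np.exp(beta)
        )
        return np.exp(beta) * e1 / e0

    def inverse_laplace(self, p: float) -> float:
        """Solve L(c) = p for c, p in (0, 1)."""
        if not 0.0 < p < 1.0:
            raise ValueError("p must be in (0, 1)")
        lo, hi = _ROOT_BRACKET
        f = lambda c: self.laplace(c) - p  # noqa: E731
        if f(lo) < 0:  # already below target at the tiny end
            return 0.0
        return float(optimize.brentq(f, lo, hi, xtol=_ROOT_TOL))

    def median_concordance(self) -> float:
        """kappa = 4 L(2 L^-1(1/2)) - 1 for clusters of size 2."""
        return float(4.0 * self.laplace(2.0 * self.inverse_laplace(0.5)) - 1.0)


@dataclass(frozen=True)
class GammaFrailty(FrailtyFamily):
    """Gamma frailty, mean 1, variance 1/theta; L(c) = (1 + c/theta)^-theta."""

    name = "gamma"

    def log_laplace(self, c):
        return -self.theta * np.log1p(np.asarray(c, float) / self.theta)

    def log_signed_derivative(self, k, c):
        c = np.asarray(c, dtype=float)
        th = self.theta
        return (
            gammaln(th + k)
            - gammaln(th)
            - k * np.log(th)
            - (th + k) * np.log1p(c / th)
        )

    def posterior_expectation(self, n_events, cumhaz):
        n = np.asarray(n_events, dtype=float)
        c = _check_c(cumhaz)
        out = (self.theta + n) / (self.theta + c)
        return out if out.shape else float(out)

    def inverse_laplace(self, p):
        if not 0.0 < p < 1.0:
            raise ValueError("p must be in (0, 1)")
        return float(self.theta * (p ** (-1.0 / self.theta) - 1.0))

    def median_concordance(self):
        # 4 (1 + 2 m / theta)^-theta - 1 with m = theta (2^(1/theta) - 1)
        return float(4.0 * (2.0 ** (1.0 / self.theta) * 2.0 - 1.0) ** -self.theta - 1.0)


@dataclass(frozen=True)
class InverseGaussianFrailty(FrailtyFamily):
    """Inverse Gaussian frailty, mean 1, variance 1/theta.

    ``L(c) = exp(theta (1 - s))`` with ``s = sqrt(1 + 2 c / theta)``.  The
    signed derivatives satisfy ``(-1)^k L^(k)(c) = L(c) R_k(1/s)`` where the
    polynomials ``R_k`` follow ``R_{k+1} = R_k/s - R_k'(s)/(theta s)``, giving
    the positive-coefficient recursion used below.
    """

    name = "inverse_gaussian"

    def _s(self, c):
        return np.sqrt(1.0 + 2.0 * np.asarray(c, float) / self.theta)

    def log_laplace(self, c):
        return self.theta * (1.0 - self._s(c))

    def _log_poly_coefs(self, k: int) -> np.ndarray:
        """log coefficients of R_k in powers u^k .. u^(2k-1), u = 1/s."""
        log_inv_theta = -np.log(self.theta)
        coefs = np.array([0.0])  # R_1 = u (one coefficient, power 1)
        for m in range(1, k):
            # R_{m+1}: a_{j+1} += a_j ;  a_{j+2} += j * a_j / theta
            # nxt index i holds the coefficient of power m + i
            nxt = np.full(m + 2, -np.inf)
            nxt[1 : m + 1] = coefs
            powers = np.arange(m, 2 * m, dtype=float)
            shifted = coefs + np.log(powers) + log_inv_theta
            nxt[2 : m + 2] = np.logaddexp(nxt[2 : m + 2], shifted)
            coefs = nxt[1:]
        return coefs

    def log_signed_derivative(self, k, c):
        c = np.asarray(c, dtype=float)
        if k == 0:
            return self.log_laplace(c)
        s = self._s(c)
        log_u = -np.log(s).ravel()
        coefs = self._log_poly_coefs(k)  # powers k .. 2k-1
        powers = np.arange(k, k + len(coefs))
        terms = coefs[:, None] + powers[:, None] * log_u[None, :]
        val = logsumexp(terms, axis=0).reshape(s.shape)
        return self.log_laplace(c) + val

    def inverse_laplace(self, p):
        if not 0.0 < p < 1.0:
            raise ValueError("p must be in (0, 1)")
        s = 1.0 - np.log(p) / self.theta
        return float(self.theta * (s * s - 1.0) / 2.0)

    def _coef_triangle(self, k_max: int) -> list[np.ndarray]:
        """Linear-scale coefficients of R_1..R_{k_max} (cached)."""
        cache = getattr(self, "_tri_cache", None)
        if cache is not None and len(cache) >= k_max:
            return cache
        tri = [np.array([1.0])]
        for m in range(1, k_max):
            coefs = tri[-1]
            nxt = np.zeros(m + 2)
            nxt[1 : m + 1] += coefs
            nxt[2 : m + 2] += coefs * np.arange(m, 2 * m) / self.theta
            tri.append(nxt[1:])
        object.__setattr__(self, "_tri_cache", tri)
        return tri

    def posterior_expectation(self, n_events, cumhaz):
        """Ratio R_{N+1}(u)/R_N(u), u = 1/s, via cached polynomial tables."""
        n = np.asarray(n_events)
        c = _check_c(cumhaz)
        if np.any(n < 0):
            raise ValueError("n_events must be nonnegative")
        n_b, c_b = np.broadcast_arrays(n, c)
        scalar = n_b.ndim == 0
        flatn, flatc = n_b.ravel(), c_b.ravel()
        u = 1.0 / self._s(flatc)
        k_max = int(flatn.max()) + 1
        tri = self._coef_triangle(k_max)
        flato = np.empty(flatn.shape, dtype=float)
        ok = True
        for order in np.unique(flatn):
            sel = flatn == order
            us = u[sel]
            if order == 0:
                num = _eval_poly(tri[0], 1, us)
                den = np.ones_like(us)
            else:
                num = _eval_poly(tri[int(order)], int(order) + 1, us)
                den = _eval_poly(tri[int(order) - 1], int(order), us)
            ratio = num / den
            if not np.all(np.isfinite(ratio)):
                ok = False
                break
            flato[sel] = ratio
        if not ok:  # fall back to the log-scale path on overflow
            return super().posterior_expectation(n_events, cumhaz)
        return float(flato[0]) if scalar else flato.reshape(n_b.shape)


@dataclass(frozen=True)
class PositiveStableFrailty(FrailtyFamily):
    """Positive stable frailty, L(c) = exp(-c^b), b = 1/(1+theta).

    theta >= 0; theta = 0 (b = 1) is the degenerate frailty Z == 1.  The
    frailty mean and variance are infinite for theta > 0; the family uniquely
    preserves marginal proportional hazards.  Derivatives are computed by the
    exact power-sum recursion ``(-1)^k L^(k)(c) = L(c) Q_k(c)`` with
    ``Q_k = sum_j q_kj c^(j b - k)``; the recursion
    ``q_{k+1, j+1} += b q_kj``, ``q_{k+1, j} += (k - j b) q_kj`` keeps all
    coefficients positive because b <= 1.
    """

    name = "positive_stable"
    max_order = 30

    def __post_init__(self):
        if self.theta < 0:
            raise ValueError(f"theta must be nonnegative, got {self.theta}")

    @property
    def b(self) -> float:
        return 1.0 / (1.0 + self.theta)

    def log_laplace(self, c):
        c = np.asarray(c, dtype=float)
        return -np.power(c, self.b)

    def _coefs(self, k: int) -> np.ndarray:
        """Positive coefficients q_{k, 1..k} of Q_k (cached triangle)."""
        return self._coef_triangle(k)[k - 1]

    def _coef_triangle(self, k_max: int) -> list[np.ndarray]:
        cache = getattr(self, "_tri_cache", None)
        if cache is not None and len(cache) >= k_max:
            return cache
        b = self.b
        tri = [np.array([b])]  # Q_1 = b c^(b-1)
        for m in range(1, k_max):
            q = tri[-1]
            nxt = np.zeros(m + 1)
            j = np.arange(1, m + 1)
            nxt[1:] += b * q  # shift: c^(jb-m) -> c^((j+1)b-(m+1))
            nxt[:-1] += (m - j * b) * q
            tri.append(nxt)
        object.__setattr__(self, "_tri_cache", tri)
        return tri

    def posterior_expectation(self, n_events, cumhaz):
        """Ratio Q_{N+1}/Q_N = P_{N+1}(y)/(c P_N(y)), y = c^b.

        ``P_k(y) = sum_j q_kj y^j`` with positive coefficients; direct
        polynomial evaluation with a log-scale fallback on overflow.
        """
        n = np.asarray(n_events)
        c = _check_c(cumhaz)
        if np.any(n < 0):
            raise ValueError("n_events must be nonnegative")
        n_b, c_b = np.broadcast_arrays(n, c)
        scalar = n_b.ndim == 0
        flatn, flatc = n_b.ravel(), c_b.ravel()
        if np.any(flatc <= 0):
            raise ValueError(
                "positive-stable posterior expectation requires cumhaz > 0"
            )
        y = np.power(flatc, self.b)
        k_max = int(flatn.max()) + 1
        if k_max > self.max_order:
            raise NotImplementedError(
                f"positive-stable Laplace derivatives capped at order "
                f"{self.max_order}; requested {k_max}"
            )
        tri = self._coef_triangle(k_max)
        flato = np.empty(flatn.shape, dtype=float)
        ok = True
        for order in np.unique(flatn):
            sel = flatn == order
            ys = y[sel]
            num = _eval_poly(tri[int(order)], 1, ys)
            den = (
                np.ones_like(ys)
                if order == 0
                else _eval_poly(tri[int(order) - 1], 1, ys)
            )
            ratio = num / (den * flatc[sel])
            if not np.all(np.isfinite(ratio)):
                ok = False
                break
            flato[sel] = ratio
        if not ok:
            return super().posterior_expectation(n_events, cumhaz)
        return float(flato[0]) if scalar else flato.reshape(n_b.shape)

    def log_signed_derivative(self, k, c):
        c = np.asarray(c, dtype=float)
        if k == 0:
            return self.log_laplace(c)
        if k > self.max_order:
            raise NotImplementedError(
                f"positive-stable Laplace derivatives capped at order "
                f"{self.max_order}; requested {k}"
            )
        if np.any(c <= 0):
            raise ValueError(
                "positive-stable derivatives require c > 0 for k >= 1"
            )
        q = self._coefs(k)
        j = np.arange(1, k + 1)
        logc = np.log(c).ravel()
        with np.errstate(divide="ignore"):  # theta=0 zeroes some coefficients
            logq = np.log(q)
        terms = logq[:, None] + (j * self.b - k)[:, None] * logc[None, :]
        val = logsumexp(terms, axis=0).reshape(c.shape)
        return self.log_laplace(c) + val

    def marginal_hazard_ratio(self, beta: float, cumhaz0):
        # E[Z | survival to hazard c] = b c^(b-1), so the ratio is exp(b beta)
        # for every t > 0: the family preserves marginal proportionality.  The
        # same constant is returned at cumhaz0 = 0 as the continuous limit.
        c0 = _check_c(cumhaz0)
        out = np.full(np.shape(c0), np.exp(self.b * beta))
        return out if out.shape else float(out)

    def inverse_laplace(self, p):
        if not 0.0 < p < 1.0:
            raise ValueError("p must be in (0, 1)")
        return float((-np.log(p)) ** (1.0 / self.b))

    def median_concordance(self):
        # 4 exp(-(2 (log 2)^(1/b))^b) - 1 = 4 * 2^(-2^b) - 1
        return float(4.0 * 2.0 ** (-(2.0 ** self.b)) - 1.0)


@dataclass(frozen=True)
class LogNormalFrailty(FrailtyFamily):
    """Lognormal frailty, mean 1, variance 1/theta, via adaptive quadrature.

    log Z ~ N(-s2/2, s2) with s2 = log(1 + 1/theta).  Generation/plot-only:
    there is no closed-form Laplace transform, so fitting is not supported.
    """

    name = "lognormal"
    max_order = 10

    @property
    def _s2(self) -> float:
        return float(np.log1p(1.0 / self.theta))

    def _moment_integral(self, k: int, c: float) -> float:
        s2 = self._s2
        mu = -s2 / 2.0
        sd = np.sqrt(s2)

        def integrand(w):  # w = log z, standard-normal-ish change of variable
            z = np.exp(mu + sd * w)
            return (
                z**k
                * np.exp(-c * z)
                * np.exp(-0.5 * w * w)
                / np.sqrt(2.0 * np.pi)
            )

        val, _ = integrate.quad(integrand, -12.0, 12.0, limit=200)
        return val

    def log_laplace(self, c):
        c = np.asarray(c, dtype=float)
        flat = np.array([np.log(self._moment_integral(0, ci)) for ci in c.ravel()])
        return flat.reshape(c.shape) if c.shape else float(flat[0])

    def log_signed_derivative(self, k, c):
        if k > self.max_order:
            raise NotImplementedError(
                f"lognormal Laplace derivatives capped at order {self.max_order}"
            )
        c = np.asarray(c, dtype=float)
        flat = np.array(
            [np.log(self._moment_integral(k, ci)) for ci in c.ravel()]
        )
        return flat.reshape(c.shape) if c.shape else float(flat[0])

    def median_concordance(self):
        raise NotImplementedError(
            "median concordance is only implemented for the gamma, "
            "inverse Gaussian and positive stable families"
        )


_FAMILIES = {
    "gamma": GammaFrailty,
    "inverse_gaussian": InverseGaussianFrailty,
    "positive_stable": PositiveStableFrailty,
    "lognormal": LogNormalFrailty,
}


def get_family(name: str, theta: float) -> FrailtyFamily:
    """Construct a frailty family by name."""
    try:
        cls = _FAMILIES[name]
    except KeyError:
        raise ValueError(
            f"unknown frailty family {name!r}; choose from {sorted(_FAMILIES)}"
        ) from None
    return cls(theta)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def laplace(family: FrailtyFamily, c):
    return family.laplace(c)


def laplace_derivative(family: FrailtyFamily, k: int, c):
    return family.laplace_derivative(k, c)


def posterior_expectation(family: FrailtyFamily, n_events, cumhaz):
    return family.posterior_expectation(n_events, cumhaz)


def marginal_hazard_ratio(family: FrailtyFamily, beta: float, cumhaz0):
    return family.marginal_hazard_ratio(beta, cumhaz0)


def median_concordance(family: FrailtyFamily) -> float:
    return family.median_concordance()
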