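"""Quadratic-utility-logistic (QUL) preference model for paired comparisons.

Each strength level g (maximum gain reduction, dB) carries a latent utility

    u(g) = a*g + b*g**2

and the probability that a listener chooses the first of two presented
strengths is a logistic function of the utility difference:

    P(first | g1, g2) = 1 / (1 + exp(-(u(g1) - u(g2)))).

Any intercept cancels in the difference, so the model has exactly two free
parameters.  With concave utility (b < 0) the preferred strength is the
vertex -a/(2b); it is clamped to the tested range (0-18 dB in the study) to
avoid extrapolation.  Fitting is maximum likelihood on the Bernoulli choices,
with the coefficient covariance taken from the inverse observed information.

Listeners who (nearly) always prefer one end of the range produce separated
data: the likelihood increases without bound along a coefficient direction.
Such fits are flagged and reported as endpoint optima with an unreliable
covariance, mirroring how near-deterministic extreme preferrers appear in
real cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .trial_design import Design, Trial

__all__ = [
    "QULFit",
    "qul_probability",
    "qul_utility",
    "fit_qul",
    "g_opt_from_coefficients",
    "preference_curve",
    "InsufficientDesignError",
]

#: Coefficient norm beyond which a still-improving likelihood is treated as
#: separation (perfect preference).  At ||(a, b)|| = 50 the smallest utility
#: gap on the study grid already pins choice probabilities to ~0 or ~1.
SEPARATION_NORM = 50.0

_GRAD_TOL = 1e-8
_MAX_ITER = 500


class InsufficientDesignError(ValueError):
    """The trial set cannot identify two utility coefficients."""


def qul_utility(a: float, b: float, g) -> np.ndarray | float:
    """Quadratic utility u(g) = a*g + b*g^2 (no intercept; it cancels)."""
    g = np.asarray(g, dtype=float)
    out = a * g + b * g * g
    return float(out) if out.ndim == 0 else out


def qul_probability(a: float, b: float, g_first: float, g_second: float) -> float:
    """Probability of choosing the first stimulus over the second.

    Strictly inside (0, 1) up to floating-point underflow; equals 0.5 when
    the two utilities coincide (in particular for identical stimuli or a
    flat utility).
    """
    for name, v in (("a", a), ("b", b), ("g_first", g_first), ("g_second", g_second)):
        if not math.isfinite(v):
            raise ValueError(f"non-finite input {name}={v}")
    du = qul_utility(a, b, g_first) - qul_utility(a, b, g_second)
    return float(expit(du))


def g_opt_from_coefficients(
    a: float, b: float, clamp: tuple[float, float] = (0.0, 18.0)
) -> tuple[float, bool]:
    """Preferred strength implied by (a, b), clamped to the tested range.

    Concave utility (b < 0): the vertex -a/(2b), clipped to [g_lo, g_hi].
    Convex or linear utility (b >= 0): utility is maximised at an endpoint;
    equal endpoint utilities (no preference information) return the interval
    midpoint with ``at_boundary=False`` — a documented degenerate tie-break.
    """
    g_lo, g_hi = clamp
    if not (g_lo < g_hi):
        raise ValueError(f"empty clamp interval [{g_lo}, {g_hi}]")
    if not (math.isfinite(a) and math.isfinite(b)):
        raise ValueError("coefficients must be finite")
    if b < 0:
        g = float(np.clip(-a / (2.0 * b), g_lo, g_hi))
        return g, g in (g_lo, g_hi)
    u_lo = qul_utility(a, b, g_lo)
    u_hi = qul_utility(a, b, g_hi)
    if u_lo == u_hi:
        return 0.5 * (g_lo + g_hi), False
    g = g_lo if u_lo > u_hi else g_hi
    return g, True


@dataclass
class QULFit:
    """Fitted QUL coefficients with uncertainty and diagnostic flags."""

    a: float
    b: float
    covariance: np.ndarray
    g_opt: float
    at_boundary: bool
    converged: bool
    separated: bool
    log_likelihood: float
    g_lo: float
    g_hi: float
    n_trials: int
    degenerate: bool = False
    #: presentation-order bias on the logit scale; 0 unless fit with the
    #: order-effect term enabled
    order_bias: float = 0.0

    @property
    def se_a(self) -> float:
        return float(np.sqrt(self.covariance[0, 0]))

    @property
    def se_b(self) -> float:
        return float(np.sqrt(self.covariance[1, 1]))


def _design_matrix(trials: list[Trial]) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial covariate row (dg, dg^2-difference) and +-1 choice sign."""
    g1 = np.array([t.first for t in trials])
    g2 = np.array([t.second for t in trials])
    X = np.column_stack([g1 - g2, g1 * g1 - g2 * g2])
    y = np.array([1.0 if t.choice == "first" else -1.0 for t in trials])
    return X, y


def _nll_grad(theta: np.ndarray, X: np.ndarray, y: np.ndarray):
    eta = y * (X @ theta)
    # -log sigma(eta) = log(1 + exp(-eta)), computed stably
    nll = float(np.sum(np.logaddexp(0.0, -eta)))
    p_miss = expit(-eta)  # 1 - sigma(eta)
    grad = -(y * p_miss) @ X
    return nll, grad


def _hessian(theta: np.ndarray, X: np.ndarray) -> np.ndarray:
    p = expit(X @ theta)
    w = p * (1.0 - p)
    return (X * w[:, None]).T @ X


def fit_qul(
    trials: list[Trial],
    clamp: tuple[float, float] = (0.0, 18.0),
    order_effect: bool = False,
) -> QULFit:
    """Maximum-likelihood QUL fit for one participant's forced choices.

    Uses quasi-Newton (BFGS) minimisation of the negative Bernoulli
    log-likelihood with analytic gradient (tolerance 1e-8 on the gradient
    norm, at most 500 iterations).  Separation is detected when the
    coefficient norm escapes a documented bound while the likelihood still
    improves; the fit is then reported at the favoured endpoint with the
    covariance flagged unreliable rather than raising.

    ``order_effect`` adds a presentation-order bias delta to the linear
    predictor (P = sigma(delta + du)).  It is off by default: the balanced
    AB/BA design cancels order bias in expectation, but the term lets a
    suspicious analyst check that assumption on their own data.
    """
    if not trials:
        raise InsufficientDesignError("no trials")
    g_lo, g_hi = clamp
    pairs = {frozenset((t.first, t.second)) for t in trials}
    if len(pairs) < 2:
        raise InsufficientDesignError(
            "all trials compare a single level pair; two utility coefficients "
            "are not identifiable"
        )
    for t in trials:
        if not (g_lo <= t.first <= g_hi and g_lo <= t.second <= g_hi):
            raise ValueError(
                f"trial levels ({t.first}, {t.second}) outside clamp [{g_lo}, {g_hi}]"
            )

    X, y = _design_matrix(trials)
    if order_effect:
        X = np.column_stack([X, np.ones(len(trials))])
    res = minimize(
        _nll_grad,
        x0=np.zeros(X.shape[1]),
        args=(X, y),
        jac=True,
        method="BFGS",
        options={"gtol": _GRAD_TOL, "maxiter": _MAX_ITER},
    )
    theta = res.x
    nll, grad = _nll_grad(theta, X, y)
    # Separation: either the coefficients escaped the documented norm bound
    # with the likelihood still improving, or the fit predicts every observed
    # choice (near-)perfectly — the likelihood supremum is 1 and the MLE sits
    # at infinity along a ray.
    separated = bool(
        np.linalg.norm(theta) > SEPARATION_NORM or nll < 1e-4 * len(trials)
    )
    converged = bool(res.success) or float(np.linalg.norm(grad)) < 1e-5

    H = _hessian(theta, X)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((X.shape[1], X.shape[1]), np.nan)
        separated = True

    a, b = float(theta[0]), float(theta[1])
    delta = float(theta[2]) if order_effect else 0.0
    degenerate = False
    if separated:
        # Report the endpoint the data favour; coefficients are on a
        # divergent ray, so only their direction is meaningful.
        g_opt, at_boundary = g_opt_from_coefficients(a, b, clamp)
        if not at_boundary and b >= 0:
            degenerate = True
        cov = np.full_like(cov, np.nan)
    else:
        g_opt, at_boundary = g_opt_from_coefficients(a, b, clamp)
        if b >= 0 and not at_boundary:
            degenerate = True

    return QULFit(
        a=a,
        b=b,
        covariance=cov,
        g_opt=g_opt,
        at_boundary=at_boundary,
        converged=converged,
        separated=separated,
        log_likelihood=-nll,
        g_lo=g_lo,
        g_hi=g_hi,
        n_trials=len(trials),
        degenerate=degenerate,
        order_bias=delta,
    )


def expected_win_fractions(a: float, b: float, levels) -> np.ndarray:
    """Model-implied win fraction per level: mean choice probability against
    every other design level (matching how empirical win fractions tally)."""
    levels = np.asarray(levels, dtype=float)
    u = qul_utility(a, b, levels)
    P = expit(u[:, None] - u[None, :])
    np.fill_diagonal(P, 0.0)
    return P.sum(axis=1) / (len(levels) - 1)


def preference_curve(fit: QULFit, design: Design) -> dict:
    """Expected win fraction per design level with pointwise delta-method SEs.

    The SE at level g propagates the coefficient covariance through the
    gradient of the mean choice probability; for separated fits the curve is
    still returned but the SEs are NaN and flagged unreliable.
    """
    levels = np.asarray(design.levels, dtype=float)
    frac = expected_win_fractions(fit.a, fit.b, levels)

    if fit.separated or not np.all(np.isfinite(fit.covariance)):
        se = np.full(len(levels), np.nan)
        return {"levels": levels, "fraction": frac, "se": se, "se_reliable": False}

    u = qul_utility(fit.a, fit.b, levels)
    se = np.empty(len(levels))
    for i, g in enumerate(levels):
        grad = np.zeros(2)
        for j, g2 in enumerate(levels):
            if j == i:
                continue
            p = expit(u[i] - u[j])
            w = p * (1.0 - p)
            grad += w * np.array([g - g2, g * g - g2 * g2])
        grad /= len(levels) - 1
        se[i] = math.sqrt(max(0.0, float(grad @ fit.covariance @ grad)))
    return {"levels": levels, "fraction": frac, "se": se, "se_reliable": True}
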