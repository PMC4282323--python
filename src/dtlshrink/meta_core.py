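"""Meta-analytic numerics shared by the shrinkage estimators.

The meta view of a drop-the-loser trial is a k-study normal-means system
``Xt_i ~ N(mu_i, W_i)`` with known, unequal variances and a hierarchical
model ``mu_i ~ N(mu, tau^2)``.  Everything here is standard random-effects
meta-analysis machinery: the generalised Q statistic, the Paule-Mandel and
DerSimonian-Laird moment estimators of the between-arm heterogeneity tau^2,
inverse-variance weighted grand means, I^2, and the profile log-likelihood
in tau^2 used by the direct plug-in estimator.

All functions are pure and operate on plain numeric vectors, so they are
usable for ordinary meta-analysis independently of the trial context.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "HeterogeneityFit",
    "generalized_q",
    "fixed_effect_mean",
    "random_effect_mean",
    "paule_mandel_tau2",
    "dersimonian_laird_tau2",
    "profile_loglik_tau2",
    "maximize_profile_tau2",
]

# absolute tolerance on Q(tau2) - (k-1) for the Paule-Mandel root
_Q_ATOL = 1e-10
# absolute tolerance on tau2 for the profile-likelihood maximizer
_TAU2_ATOL = 1e-8
_MAX_BRACKET_DOUBLINGS = 60


@dataclass(frozen=True)
class HeterogeneityFit:
    """Result of a between-arm heterogeneity fit.

    Attributes
    ----------
    tau2
        Estimated between-arm variance, truncated at 0.
    mu_hat
        Grand mean at ``tau2``: the inverse-(W_i + tau2)-weighted mean, so
        it coincides with the fixed-effects mean whenever ``tau2 == 0``.
    method
        One of ``paule_mandel``, ``dersimonian_laird``,
        ``profile_likelihood``, ``fixed``.
    converged
        Solver convergence flag (always True for closed-form methods).
    q0
        Cochran's heterogeneity statistic Q(0).
    i2
        The I^2 inconsistency measure, ``max(0, (Q(0)-(k-1))/Q(0))``;
        only populated by the DerSimonian-Laird fit, else ``nan``.
    """

    tau2: float
    mu_hat: float
    method: str
    converged: bool = True
    q0: float = float("nan")
    i2: float = float("nan")


def _check_vectors(xt, w) -> tuple[np.ndarray, np.ndarray]:
    xt = np.asarray(xt, dtype=float)
    w = np.asarray(w, dtype=float)
    if xt.ndim != 1 or xt.shape != w.shape:
        raise ValueError("xt and w must be 1-D vectors of equal length")
    if xt.size == 0:
        raise ValueError("empty input")
    if not (np.all(np.isfinite(xt)) and np.all(np.isfinite(w))):
        raise ValueError("non-finite inputs")
    if np.any(w <= 0):
        raise ValueError("all variances must be positive")
    return xt, w


def _weighted_mean(xt: np.ndarray, v: np.ndarray) -> float:
    inv = 1.0 / v
    return float(np.sum(xt * inv) / np.sum(inv))


def generalized_q(tau2: float, xt, w) -> float:
    """Generalised Q statistic at a trial value of tau^2.

    With ``V_i = W_i + tau2`` and ``mu_V`` the inverse-V weighted mean,
    returns ``sum((Xt_i - mu_V)^2 / V_i)``.  Non-increasing in tau2; at
    tau2 = 0 it is Cochran's heterogeneity Q.
    """
    if tau2 < 0:
        raise ValueError(f"tau2 must be >= 0, got {tau2}")
    xt, w = _check_vectors(xt, w)
    v = w + tau2
    mu_v = _weighted_mean(xt, v)
    return float(np.sum((xt - mu_v) ** 2 / v))


def fixed_effect_mean(xt, w) -> float:
    """Fixed-effects grand mean: inverse-variance weighted with weights 1/W_i."""
    xt, w = _check_vectors(xt, w)
    return _weighted_mean(xt, w)


def random_effect_mean(xt, w, tau2: float) -> float:
    """Random-effects grand mean with weights 1/(W_i + tau2)."""
    if tau2 < 0:
        raise ValueError(f"tau2 must be >= 0, got {tau2}")
    xt, w = _check_vectors(xt, w)
    return _weighted_mean(xt, w + tau2)


def paule_mandel_tau2(xt, w) -> HeterogeneityFit:
    """Paule-Mandel moment estimator: the tau^2 solving Q(tau^2) = k - 1.

    If ``Q(0) <= k - 1`` the estimate is truncated at 0; otherwise the
    root is found by bracketed 1-D root-finding (Q is monotone
    non-increasing in tau^2, so the root is unique).
    """
    xt, w = _check_vectors(xt, w)
    k = xt.size
    if k < 2:
        raise ValueError("Paule-Mandel requires k >= 2")
    q0 = generalized_q(0.0, xt, w)
    target = float(k - 1)
    if q0 <= target + _Q_ATOL:
        return HeterogeneityFit(
            tau2=0.0, mu_hat=fixed_effect_mean(xt, w), method="paule_mandel", q0=q0
        )

    def f(t: float) -> float:
        return generalized_q(t, xt, w) - target

    hi = 10.0 * max(float(np.var(xt)), float(np.max(w)))
    hi = max(hi, 1e-8)
    n_doublings = 0
    while f(hi) > 0:
        hi *= 2.0
        n_doublings += 1
        if n_doublings > _MAX_BRACKET_DOUBLINGS:
            raise RuntimeError(
                f"Paule-Mandel bracket expansion failed: Q({hi:g}) = "
                f"{f(hi) + target:g} still above k-1 = {target:g}"
            )
    tau2 = float(optimize.brentq(f, 0.0, hi, xtol=1e-14, rtol=8.9e-16))
    return HeterogeneityFit(
        tau2=tau2,
        mu_hat=random_effect_mean(xt, w, tau2),
        method="paule_mandel",
        q0=q0,
    )


def dersimonian_laird_tau2(xt, w) -> HeterogeneityFit:
    """DerSimonian-Laird moment estimator of tau^2, with I^2.

    tau2_DL = max(0, (Q(0) - (k-1)) / (sum(1/W) - sum(1/W^2)/sum(1/W))).
    """
    xt, w = _check_vectors(xt, w)
    k = xt.size
    if k < 2:
        raise ValueError("DerSimonian-Laird requires k >= 2")
    q0 = generalized_q(0.0, xt, w)
    inv = 1.0 / w
    denom = float(np.sum(inv) - np.sum(inv**2) / np.sum(inv))
    if denom <= 0:
        raise ValueError("degenerate weight configuration for DerSimonian-Laird")
    excess = q0 - (k - 1)
    tau2 = max(0.0, excess / denom)
    i2 = max(0.0, excess / q0) if q0 > 0 else 0.0
    return HeterogeneityFit(
        tau2=tau2,
        mu_hat=random_effect_mean(xt, w, tau2),
        method="dersimonian_laird",
        q0=q0,
        i2=i2,
    )


def profile_loglik_tau2(tau2: float, xt, w) -> float:
    """Profile log-likelihood of tau^2 under Xt_i ~ N(mu, W_i + tau^2).

    The grand mean is profiled out at its weighted-mean MLE for the given
    tau^2:  l(tau2) = -1/2 sum[ log(W_i + tau2) + (Xt_i - mu(tau2))^2 /
    (W_i + tau2) ]  (additive constants dropped).
    """
    if tau2 < 0:
        raise ValueError(f"tau2 must be >= 0, got {tau2}")
    xt, w = _check_vectors(xt, w)
    v = w + tau2
    mu = _weighted_mean(xt, v)
    return float(-0.5 * np.sum(np.log(v) + (xt - mu) ** 2 / v))


def maximize_profile_tau2(xt, w) -> HeterogeneityFit:
    """Maximum-profile-likelihood estimate of tau^2 (boundary 0 allowed).

    Bounded 1-D maximization over [0, tau_max] with an expanding upper
    bound; the bound is grown until the maximizer is interior.
    """
    xt, w = _check_vectors(xt, w)
    if xt.size < 2:
        raise ValueError("profile likelihood requires k >= 2")
    if float(np.var(xt)) == 0.0:
        return HeterogeneityFit(
            tau2=0.0, mu_hat=float(xt[0]), method="profile_likelihood"
        )

    hi = 10.0 * max(float(np.var(xt)), float(np.max(w)))
    for _ in range(_MAX_BRACKET_DOUBLINGS):
        res = optimize.minimize_scalar(
            lambda t: -profile_loglik_tau2(t, xt, w),
            bounds=(0.0, hi),
            method="bounded",
            options={"xatol": _TAU2_ATOL},
        )
        if res.x < hi - 10 * _TAU2_ATOL:
            break
        hi *= 2.0
    tau2 = float(res.x)
    # the bounded minimizer never lands exactly on 0; snap when 0 is at
    # least as good as the interior candidate
    if profile_loglik_tau2(0.0, xt, w) >= profile_loglik_tau2(tau2, xt, w):
        tau2 = 0.0
    return HeterogeneityFit(
        tau2=tau2,
        mu_hat=random_effect_mean(xt, w, tau2),
        method="profile_likelihood",
        converged=bool(res.success),
    )
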