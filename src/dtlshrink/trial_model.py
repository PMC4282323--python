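"""Two-stage drop-the-loser trial model.

A drop-the-loser trial runs ``k`` experimental arms in stage 1, keeps only
the arm with the largest stage-1 effect estimate, and re-estimates that
arm's effect on an independent stage-2 population.  Stage-1 estimates are
modelled as ``X_i ~ N(mu_i, sigma1^2)`` with a common, known standard error
``sigma1``; the selected arm's stage-2 estimate is ``Y_s ~ N(mu_s, sigma2^2)``
with known ``sigma2``.  Selecting the maximum makes the naive combined
estimate of ``mu_s`` positively biased, which is the problem the estimators
in :mod:`dtlshrink.estimators` address.

This module holds the data model, the selection rule, the simulator, and the
conversion of a trial to its unequal-variance meta-analytic view (one
"study" per arm, with the selected arm carrying the precision-weighted
stage-1 + stage-2 combination).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy.stats import norm

__all__ = [
    "TrialDesign",
    "TrialOutcome",
    "MetaView",
    "select_best",
    "simulate_trial",
    "combined_mle",
    "to_meta_view",
    "expected_max_std_normal",
]


@dataclass(frozen=True)
class TrialDesign:
    """Design constants of a two-stage drop-the-loser trial.

    Parameters
    ----------
    k
        Number of experimental arms (>= 2).
    sigma1
        Known standard error of every stage-1 arm estimate.
    sigma2
        Known standard error of the selected arm's stage-2 estimate.
        ``numpy.inf`` is allowed and degenerates the model to a
        stage-1-only (equal variance) trial.
    small_k_fix
        Enable the crude ``k = 3`` fix for the shrinkage estimators:
        every ``(k - 3)`` in a shrinkage factor is replaced by ``(k - 2)``.
        Shrinkage estimators otherwise require ``k >= 4``.
    """

    k: int
    sigma1: float
    sigma2: float
    small_k_fix: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "k", int(self.k))
        object.__setattr__(self, "sigma1", float(self.sigma1))
        object.__setattr__(self, "sigma2", float(self.sigma2))
        if self.k < 2:
            raise ValueError(f"need at least 2 arms, got k={self.k}")
        if not self.sigma1 > 0:
            raise ValueError(f"sigma1 must be positive, got {self.sigma1}")
        if not self.sigma2 > 0:
            raise ValueError(f"sigma2 must be positive, got {self.sigma2}")

    @property
    def naive_variance(self) -> float:
        """Variance of the precision-weighted combined estimate, sigma-tilde^2."""
        return 1.0 / (1.0 / self.sigma1**2 + 1.0 / self.sigma2**2)

    @property
    def naive_se(self) -> float:
        return float(np.sqrt(self.naive_variance))

    def shrinkage_k_term(self) -> int:
        """The ``k - 3`` degrees-of-freedom term of the shrinkage factors.

        Returns ``k - 2`` instead when the small-k fix is active.  Raises for
        designs where shrinkage estimation is undefined.
        """
        if self.k >= 4:
            return self.k - 3
        if self.k == 3 and self.small_k_fix:
            return self.k - 2
        raise ValueError(
            f"shrinkage estimators require k >= 4 (or k = 3 with "
            f"small_k_fix); got k={self.k}, small_k_fix={self.small_k_fix}"
        )


@dataclass(frozen=True)
class TrialOutcome:
    """Realized data of one two-stage drop-the-loser trial.

    ``x`` holds the k stage-1 estimates, ``s``/``r`` the 0-based indices of
    the selected (top) and runner-up arms, and ``y_s`` the stage-2 estimate
    of the selected arm.  Stage-2 data exist only for the selected arm.
    """

    x: np.ndarray
    s: int
    r: int
    y_s: float

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        object.__setattr__(self, "x", x)
        k = x.shape[0]
        if not (0 <= self.s < k and 0 <= self.r < k) or self.s == self.r:
            raise ValueError(f"invalid arm indices s={self.s}, r={self.r}")


@dataclass(frozen=True)
class MetaView:
    """Meta-analytic view of a trial: one estimate and known variance per arm.

    Non-selected arms contribute their stage-1 estimate with variance
    ``sigma1^2``; the selected arm contributes the precision-weighted
    stage-1 + stage-2 combination with the smaller combined variance.  This
    is the unequal-variance normal-means system on which the shrinkage
    estimators operate.
    """

    xt: np.ndarray
    w: np.ndarray
    s: int

    def __post_init__(self) -> None:
        xt = np.asarray(self.xt, dtype=float)
        w = np.asarray(self.w, dtype=float)
        if xt.shape != w.shape:
            raise ValueError("xt and w must have the same length")
        if np.any(w <= 0):
            raise ValueError("all variances w must be positive")
        object.__setattr__(self, "xt", xt)
        object.__setattr__(self, "w", w)


def select_best(x: np.ndarray) -> tuple[int, int]:
    """Indices of the best and runner-up arms by stage-1 estimate.

    Ties (probability zero under the continuous model) are broken by the
    lowest index, for both positions.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 arms to define a runner-up")
    s = int(np.argmax(x))
    rest = np.delete(x, s)
    r = int(np.argmax(rest))
    if r >= s:
        r += 1
    return s, r


def simulate_trial(
    design: TrialDesign, mu: np.ndarray, rng: np.random.Generator
) -> TrialOutcome:
    """Draw one trial: stage-1 estimates, selection, stage-2 estimate.

    ``mu`` is the vector of true arm means (length ``design.k``).  Stage-2
    is independent of stage 1 given the selected arm.
    """
    mu = np.asarray(mu, dtype=float)
    if mu.shape[0] != design.k:
        raise ValueError(f"mu has length {mu.shape[0]}, expected k={design.k}")
    x = rng.normal(mu, design.sigma1)
    s, r = select_best(x)
    y_s = float(rng.normal(mu[s], design.sigma2))
    return TrialOutcome(x=x, s=s, r=r, y_s=y_s)


def combined_mle(outcome: TrialOutcome, design: TrialDesign) -> tuple[float, float]:
    """Precision-weighted MLE of the selected mean and its naive variance.

    estimate = (X_s/sigma1^2 + Y_s/sigma2^2) / (1/sigma1^2 + 1/sigma2^2);
    the "naive" variance ignores the selection event and is therefore an
    understatement, just as the estimate is positively biased.
    """
    p1 = 1.0 / design.sigma1**2
    p2 = 1.0 / design.sigma2**2
    var = 1.0 / (p1 + p2)
    est = (outcome.x[outcome.s] * p1 + outcome.y_s * p2) * var
    return float(est), float(var)


def to_meta_view(outcome: TrialOutcome, design: TrialDesign) -> MetaView:
    """Convert a trial outcome to its per-arm meta-analytic representation."""
    xt = outcome.x.astype(float).copy()
    w = np.full(design.k, design.sigma1**2, dtype=float)
    est, var = combined_mle(outcome, design)
    xt[outcome.s] = est
    w[outcome.s] = var
    return MetaView(xt=xt, w=w, s=outcome.s)


def expected_max_std_normal(k: int) -> float:
    """E[max of k iid standard normals], by numerical integration.

    m_k = k * Integral z * phi(z) * Phi(z)^(k-1) dz.  Used as the analytic
    oracle for the selection bias of the MLE when all true means are equal.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    val, _ = integrate.quad(
        lambda z: k * z * norm.pdf(z) * norm.cdf(z) ** (k - 1), -np.inf, np.inf
    )
    return float(val)
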