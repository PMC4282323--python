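"""Point estimators of the selected treatment mean.

Seven estimators of ``mu_s`` after drop-the-loser selection:

``mle``
    Precision-weighted combination of the selected arm's two stages
    (positively biased because it ignores selection).
``umvcue``
    Uniformly minimum variance conditionally unbiased estimator: the
    Rao-Blackwellization of the stage-2 estimate given the sufficient
    statistic and the selection event, built from the runner-up X_r.
``cb``
    Carreras-Brannath two-step shrinkage: Lindley-shrink the stage-1
    estimates toward their unweighted mean, then precision-combine the
    selected arm's shrunk stage-1 value with its stage-2 estimate.
``direct``
    Direct empirical-Bayes plug-in: profile-likelihood tau^2 on the meta
    view, then the normal-normal posterior mean for the selected arm.
``cr_standard`` (S_tau2)
    Carter-Rolph standard-prior shrinkage: Paule-Mandel tau^2,
    random-effects grand mean, and an approximate shrinkage factor.
``cr_proportional`` (S_prop)
    Carter-Rolph proportional-prior shrinkage: prior variance of each arm
    mean proportional to its estimate's variance, giving a single
    Cochran-Q-based factor and the fixed-effects grand mean.
``cr_proportional_lt`` (S_propLT)
    The proportional-prior estimate limited-translated to within one naive
    standard error of the MLE.

Every factor-based method applies the plus-rule (negative shrinkage
factors truncated to 0), so each estimate is a convex combination of its
grand mean and the selected arm's combined estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import meta_core
from .trial_model import MetaView, TrialDesign, TrialOutcome, combined_mle, to_meta_view

__all__ = [
    "ShrinkageFit",
    "ALL_METHODS",
    "estimate_mle",
    "estimate_umvcue",
    "lindley_factor",
    "estimate_cb",
    "estimate_direct",
    "estimate_cr_standard",
    "estimate_cr_proportional",
    "estimate_cr_proportional_lt",
    "estimate_all",
    "mills_ratio",
]

ALL_METHODS = (
    "mle",
    "umvcue",
    "cb",
    "direct",
    "cr_standard",
    "cr_proportional",
    "cr_proportional_lt",
)


@dataclass(frozen=True)
class ShrinkageFit:
    """A point estimate of mu_s with its shrinkage diagnostics.

    ``grand_mean``, ``tau2`` and ``shrink_factor`` are ``nan`` for methods
    where they play no role (mle, umvcue).
    """

    estimate: float
    method: str
    grand_mean: float = float("nan")
    tau2: float = float("nan")
    shrink_factor: float = float("nan")


def mills_ratio(v: float | np.ndarray) -> float | np.ndarray:
    """phi(v) / Phi(v), computed in log space so it is stable for v << 0."""
    return np.exp(norm.logpdf(v) - norm.logcdf(v))


def estimate_mle(outcome: TrialOutcome, design: TrialDesign) -> ShrinkageFit:
    """The naive precision-weighted MLE of the selected mean."""
    est, _ = combined_mle(outcome, design)
    return ShrinkageFit(estimate=est, method="mle")


def estimate_umvcue(outcome: TrialOutcome, design: TrialDesign) -> ShrinkageFit:
    """The UMVCUE: unbiased conditional on the selection event.

    With Z the combined MLE, the estimator is

        Z - (sigma2^2 / sqrt(sigma1^2 + sigma2^2)) * phi(v) / Phi(v),
        v = (Z - X_r) / eta,   eta = sigma1^2 / sqrt(sigma1^2 + sigma2^2),

    i.e. E[Y_s | Z, X_s >= X_r]: conditionally on Z the stage-1 maximum is
    N(Z, eta^2) truncated below at the runner-up X_r, and solving the
    precision-weighted identity for Y_s yields the correction.  When the
    selected arm barely beats the runner-up the correction is largest; when
    it wins by many sigma the correction vanishes and the UMVCUE equals the
    MLE.
    """
    z, _ = combined_mle(outcome, design)
    s1sq = design.sigma1**2
    s2sq = design.sigma2**2
    root = float(np.sqrt(s1sq + s2sq))
    eta = s1sq / root
    v = (z - outcome.x[outcome.r]) / eta
    est = z - (s2sq / root) * float(mills_ratio(v))
    return ShrinkageFit(estimate=est, method="umvcue")


def lindley_factor(
    x: np.ndarray, sigma1: float, k_adjust: bool = False
) -> tuple[float, float]:
    """Lindley's equal-variance shrinkage factor and grand mean.

    C = 1 - (k-3) * sigma1^2 / sum((X_j - Xbar)^2), returned after the
    plus-rule as C+ = max(C, 0), together with the unweighted mean Xbar.
    ``k_adjust`` replaces (k-3) by (k-2) to crudely cover k = 3.  Zero
    stage-1 dispersion gives C+ = 0 (shrink fully to the common value).
    """
    x = np.asarray(x, dtype=float)
    k = x.shape[0]
    kterm = TrialDesign(
        k=k, sigma1=sigma1, sigma2=1.0, small_k_fix=k_adjust
    ).shrinkage_k_term()
    xbar = float(np.mean(x))
    ss = float(np.sum((x - xbar) ** 2))
    if ss == 0.0:
        return 0.0, xbar
    c = 1.0 - kterm * sigma1**2 / ss
    return max(c, 0.0), xbar


def estimate_cb(outcome: TrialOutcome, design: TrialDesign) -> ShrinkageFit:
    """Carreras-Brannath shrinkage estimate.

    Stage 1 only: L_s = Xbar + C+ (X_s - Xbar) with Lindley's factor; then
    L_s is combined with Y_s by the same precision weights as the MLE.
    With C+ = 0 the stage-1 component is Xbar; with C+ such that L_s = X_s
    the estimate equals the MLE exactly.  Under an i.i.d. normal prior on
    the true means this estimator dominates the MLE in MSE.
    """
    c_plus, xbar = lindley_factor(
        outcome.x, design.sigma1, k_adjust=design.small_k_fix
    )
    # guard: raises for k too small
    design.shrinkage_k_term()
    l_s = xbar + c_plus * (outcome.x[outcome.s] - xbar)
    p1 = 1.0 / design.sigma1**2
    p2 = 1.0 / design.sigma2**2
    est = (l_s * p1 + outcome.y_s * p2) / (p1 + p2)
    return ShrinkageFit(
        estimate=float(est),
        method="cb",
        grand_mean=xbar,
        shrink_factor=c_plus,
    )


def estimate_direct(view: MetaView) -> ShrinkageFit:
    """Direct empirical-Bayes plug-in on the meta view.

    Fits tau^2 by profile likelihood, takes the weighted-mean MLE of the
    grand mean at that tau^2, and returns the normal-normal posterior mean
    for the selected arm:

        (tau2 * Xt_s + W_s * mu_hat) / (W_s + tau2).

    The posterior weight is intrinsically in [0, 1], so no plus-rule is
    needed.  When tau^2 is estimated as 0 the estimate collapses to the
    fixed-effects grand mean.
    """
    fit = meta_core.maximize_profile_tau2(view.xt, view.w)
    w_s = float(view.w[view.s])
    weight = fit.tau2 / (w_s + fit.tau2) if fit.tau2 > 0 else 0.0
    est = weight * float(view.xt[view.s]) + (1.0 - weight) * fit.mu_hat
    return ShrinkageFit(
        estimate=float(est),
        method="direct",
        grand_mean=fit.mu_hat,
        tau2=fit.tau2,
        shrink_factor=weight,
    )


def _k_term(view: MetaView, small_k_fix: bool) -> int:
    k = view.xt.shape[0]
    return TrialDesign(
        k=k, sigma1=1.0, sigma2=1.0, small_k_fix=small_k_fix
    ).shrinkage_k_term()


def estimate_cr_standard(view: MetaView, small_k_fix: bool = False) -> ShrinkageFit:
    """Carter-Rolph standard-prior shrinkage estimate (S_tau2).

    tau^2 by Paule-Mandel; grand mean the inverse-(W + tau2)-weighted
    (random-effects) mean; approximate shrinkage factor

        C = 1 - ((k-3)/(k-1)) * W_s / (W_s + tau2_PM)

    applied with the plus-rule:  mu_hat + C+ (Xt_s - mu_hat).  With all W_i
    equal (and tau2_PM > 0) the factor reduces exactly to Lindley's; at
    tau2_PM = 0 it stays strictly positive, 1 - (k-3)/(k-1), so the
    estimate does not collapse onto the grand mean.
    """
    kterm = _k_term(view, small_k_fix)
    k = view.xt.shape[0]
    fit = meta_core.paule_mandel_tau2(view.xt, view.w)
    w_s = float(view.w[view.s])
    c = 1.0 - (kterm / (k - 1.0)) * w_s / (w_s + fit.tau2)
    c_plus = max(c, 0.0)
    est = fit.mu_hat + c_plus * (float(view.xt[view.s]) - fit.mu_hat)
    return ShrinkageFit(
        estimate=float(est),
        method="cr_standard",
        grand_mean=fit.mu_hat,
        tau2=fit.tau2,
        shrink_factor=c_plus,
    )


def estimate_cr_proportional(view: MetaView, small_k_fix: bool = False) -> ShrinkageFit:
    """Carter-Rolph proportional-prior shrinkage estimate (S_prop).

    The prior mu_i ~ N(mu, W_i tau^2) makes the posterior shrinkage weight
    free of W_i, so a single factor serves every arm:

        C = 1 - (k-3) / Q(0),

    with Q(0) Cochran's heterogeneity statistic, plus-rule applied, around
    the fixed-effects grand mean.  All stage estimates identical gives
    Q(0) = 0 and C+ = 0 (full shrinkage to the common value).
    """
    kterm = _k_term(view, small_k_fix)
    mu_fe = meta_core.fixed_effect_mean(view.xt, view.w)
    q0 = meta_core.generalized_q(0.0, view.xt, view.w)
    c_plus = max(1.0 - kterm / q0, 0.0) if q0 > 0 else 0.0
    est = mu_fe + c_plus * (float(view.xt[view.s]) - mu_fe)
    return ShrinkageFit(
        estimate=float(est),
        method="cr_proportional",
        grand_mean=mu_fe,
        tau2=float("nan"),
        shrink_factor=c_plus,
    )


def estimate_cr_proportional_lt(
    view: MetaView, small_k_fix: bool = False, lt_width: float = 1.0
) -> ShrinkageFit:
    """Limited-translation proportional-prior estimate (S_propLT).

    The S_prop estimate clipped to within ``lt_width`` naive standard
    errors (default one, the usual practical choice) of the selected arm's
    combined estimate, protecting an outlying mu_s from over-shrinkage.
    """
    if lt_width < 0:
        raise ValueError("lt_width must be >= 0")
    base = estimate_cr_proportional(view, small_k_fix=small_k_fix)
    xt_s = float(view.xt[view.s])
    half = lt_width * float(np.sqrt(view.w[view.s]))
    est = float(np.clip(base.estimate, xt_s - half, xt_s + half))
    return ShrinkageFit(
        estimate=est,
        method="cr_proportional_lt",
        grand_mean=base.grand_mean,
        tau2=base.tau2,
        shrink_factor=base.shrink_factor,
    )


def estimate_all(
    outcome: TrialOutcome,
    design: TrialDesign,
    methods: tuple[str, ...] | list[str] = ALL_METHODS,
    lt_width: float = 1.0,
) -> pd.DataFrame:
    """All requested estimators as a tidy table.

    Returns a DataFrame with columns method, estimate, grand_mean, tau2,
    shrink_factor, one row per method, in the requested order.
    """
    view = to_meta_view(outcome, design)
    dispatch = {
        "mle": lambda: estimate_mle(outcome, design),
        "umvcue": lambda: estimate_umvcue(outcome, design),
        "cb": lambda: estimate_cb(outcome, design),
        "direct": lambda: estimate_direct(view),
        "cr_standard": lambda: estimate_cr_standard(
            view, small_k_fix=design.small_k_fix
        ),
        "cr_proportional": lambda: estimate_cr_proportional(
            view, small_k_fix=design.small_k_fix
        ),
        "cr_proportional_lt": lambda: estimate_cr_proportional_lt(
            view, small_k_fix=design.small_k_fix, lt_width=lt_width
        ),
    }
    rows = []
    for m in methods:
        if m not in dispatch:
            raise ValueError(f"unknown method {m!r}; choose from {ALL_METHODS}")
        fit = dispatch[m]()
        rows.append(
            {
                "method": fit.method,
                "estimate": fit.estimate,
                "grand_mean": fit.grand_mean,
                "tau2": fit.tau2,
                "shrink_factor": fit.shrink_factor,
            }
        )
    return pd.DataFrame(rows)
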