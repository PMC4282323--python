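"""Monte-Carlo evaluation of the selected-mean estimators.

Reproduces the estimator comparison for the two-stage drop-the-loser
design: a four-scenario grid over true-mean configurations crossed with
stage-error levels, and one-dimensional sweeps over the outlying effect
size delta, the between-arm heterogeneity tau^2, and the number of arms k.

Per replicate the trial is simulated, every requested estimator is
evaluated, and errors are accumulated against that replicate's realized
selected-arm mean ``mu_s`` (which is itself a random variable: a mixture
over the selection event).  Bias and root-MSE are reported scaled by the
naive standard error of the combined MLE, so columns are directly
comparable across stage-error levels.

Scenarios for the true means of the k arms:

    I    drawn i.i.d. N(mu0, tau2) afresh every replicate (default N(0,1))
    II   all zero
    III  one arm at delta = 1, the rest zero
    IV   one arm at delta = 1.5, the rest zero

The engine evaluates all estimators in vectorized form across replicates
(bisection for the Paule-Mandel root, bracketed golden-section for the
profile-likelihood tau^2); the batch code paths are tested against the
scalar estimator API replicate-by-replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .estimators import ALL_METHODS
from .trial_model import TrialDesign

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "run_scenario",
    "run_table1",
    "sweep",
    "TABLE1_SIGMA_LEVELS",
]

_SCENARIOS = ("I", "II", "III", "IV")

# (sigma1, sigma2) levels of the 16-cell grid; the first two are the
# canonical levels, the last two are configurable extras
TABLE1_SIGMA_LEVELS: tuple[tuple[float, float], ...] = (
    (1.0, 1.0),
    (2.0, 1.0),
    (0.5, 1.0),
    (1.0, 2.0),
)


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation cell: a true-means scenario plus a design.

    ``delta`` is the outlying mean of scenarios III/IV (defaults 1 and 1.5
    respectively when left as None); ``mu0``/``tau2`` parameterize the
    normal prior of scenario I.
    """

    scenario: str
    design: TrialDesign
    reps: int = 50_000
    seed: int = 0
    mu0: float = 0.0
    tau2: float = 1.0
    delta: float | None = None

    def __post_init__(self) -> None:
        if self.scenario not in _SCENARIOS:
            raise ValueError(f"scenario must be one of {_SCENARIOS}")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")

    @property
    def effective_delta(self) -> float:
        if self.delta is not None:
            return self.delta
        return {"I": 0.0, "II": 0.0, "III": 1.0, "IV": 1.5}[self.scenario]


@dataclass(frozen=True)
class ScenarioResult:
    """Scaled bias / root-MSE summaries of one simulation cell.

    ``table`` has one row per method with columns scaled_bias, scaled_rmse,
    mc_se_bias, mc_se_rmse.  ``e_mu_s`` is the Monte-Carlo mean of the
    realized selected-arm mean; ``naive_se`` the scaling unit.
    """

    table: pd.DataFrame
    e_mu_s: float
    naive_se: float
    reps: int
    seed: int
    n_failed: int = 0


# ---------------------------------------------------------------------------
# vectorized batch estimators (one row per replicate)
# ---------------------------------------------------------------------------


def _q_batch(t: np.ndarray, xt: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Generalised Q statistic per row at per-row tau^2 values ``t``."""
    v = w + t[:, None]
    inv = 1.0 / v
    mu = (xt * inv).sum(axis=1) / inv.sum(axis=1)
    return ((xt - mu[:, None]) ** 2 * inv).sum(axis=1)


def _profile_ll_batch(t: np.ndarray, xt: np.ndarray, w: np.ndarray) -> np.ndarray:
    v = w + t[:, None]
    inv = 1.0 / v
    mu = (xt * inv).sum(axis=1) / inv.sum(axis=1)
    return -0.5 * (np.log(v) + (xt - mu[:, None]) ** 2 * inv).sum(axis=1)


def _re_mean_batch(t: np.ndarray, xt: np.ndarray, w: np.ndarray) -> np.ndarray:
    inv = 1.0 / (w + t[:, None])
    return (xt * inv).sum(axis=1) / inv.sum(axis=1)


def _paule_mandel_batch(xt: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Per-row Paule-Mandel tau^2 by vectorized bisection."""
    n, k = xt.shape
    target = k - 1.0
    tau2 = np.zeros(n)
    active = _q_batch(tau2, xt, w) > target
    if not np.any(active):
        return tau2
    lo = np.zeros(active.sum())
    hi = 10.0 * np.maximum(xt[active].var(axis=1), w[active].max(axis=1))
    hi = np.maximum(hi, 1e-8)
    xa, wa = xt[active], w[active]
    for _ in range(200):
        too_low = _q_batch(hi, xa, wa) > target
        if not np.any(too_low):
            break
        hi[too_low] *= 2.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        above = _q_batch(mid, xa, wa) > target
        lo = np.where(above, mid, lo)
        hi = np.where(above, hi, mid)
    tau2[active] = 0.5 * (lo + hi)
    return tau2


def _profile_tau2_batch(xt: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Per-row profile-likelihood tau^2: bracketing grid + golden section."""
    n, k = xt.shape
    hi = 10.0 * np.maximum(xt.var(axis=1), w.max(axis=1))
    hi = np.maximum(hi, 1e-8)
    n_grid = 48
    frac = (np.arange(n_grid) / (n_grid - 1.0)) ** 2  # denser near 0
    for _ in range(60):
        grid = hi[:, None] * frac[None, :]
        ll = np.stack([_profile_ll_batch(grid[:, j], xt, w) for j in range(n_grid)], 1)
        jstar = ll.argmax(axis=1)
        at_edge = jstar == n_grid - 1
        if not np.any(at_edge):
            break
        hi[at_edge] *= 2.0
    lo = grid[np.arange(n), np.maximum(jstar - 1, 0)]
    up = grid[np.arange(n), np.minimum(jstar + 1, n_grid - 1)]
    # golden-section maximization on the bracketing interval
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, up
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = _profile_ll_batch(c, xt, w)
    fd = _profile_ll_batch(d, xt, w)
    for _ in range(60):
        left = fc > fd  # maximum lies in [a, d]
        b = np.where(left, d, b)
        a = np.where(left, a, c)
        c_new = b - invphi * (b - a)
        d_new = a + invphi * (b - a)
        # one interior point is inherited, the other is fresh
        c, d = np.where(left, c_new, d), np.where(left, c, d_new)
        f_fresh_c = _profile_ll_batch(c, xt, w)
        f_fresh_d = _profile_ll_batch(d, xt, w)
        fc, fd = np.where(left, f_fresh_c, fd), np.where(left, fc, f_fresh_d)
    tau2 = 0.5 * (a + b)
    # boundary snap: 0 wins when at least as likely
    ll0 = _profile_ll_batch(np.zeros(n), xt, w)
    llt = _profile_ll_batch(tau2, xt, w)
    tau2 = np.where(ll0 >= llt, 0.0, tau2)
    return tau2


def _batch_estimates(
    design: TrialDesign,
    x: np.ndarray,
    s: np.ndarray,
    r: np.ndarray,
    ys: np.ndarray,
    methods: tuple[str, ...],
    lt_width: float = 1.0,
) -> dict[str, np.ndarray]:
    """Evaluate estimators for many replicates at once.

    ``x`` is (reps, k); ``s``/``r``/``ys`` are per-replicate selected index,
    runner-up index, and stage-2 estimate.  Returns method -> (reps,) array.
    Mirrors the scalar functions in :mod:`dtlshrink.estimators` exactly.
    """
    n, k = x.shape
    idx = np.arange(n)
    p1 = 1.0 / design.sigma1**2
    p2 = 1.0 / design.sigma2**2
    var = 1.0 / (p1 + p2)
    xs = x[idx, s]
    z = (xs * p1 + ys * p2) * var

    need_view = any(
        m in methods for m in ("direct", "cr_standard", "cr_proportional",
                               "cr_proportional_lt")
    )
    if need_view:
        xt = x.copy()
        xt[idx, s] = z
        w = np.full((n, k), design.sigma1**2, dtype=float)
        w[idx, s] = var
        w_s = w[idx, s]
        xt_s = xt[idx, s]

    out: dict[str, np.ndarray] = {}
    if "mle" in methods:
        out["mle"] = z
    if "umvcue" in methods:
        s1sq, s2sq = design.sigma1**2, design.sigma2**2
        root = np.sqrt(s1sq + s2sq)
        eta = s1sq / root
        v = (z - x[idx, r]) / eta
        out["umvcue"] = z - (s2sq / root) * np.exp(norm.logpdf(v) - norm.logcdf(v))
    if "cb" in methods:
        kterm = design.shrinkage_k_term()
        xbar = x.mean(axis=1)
        ss = ((x - xbar[:, None]) ** 2).sum(axis=1)
        with np.errstate(divide="ignore"):
            c_plus = np.maximum(1.0 - kterm * design.sigma1**2 / ss, 0.0)
        c_plus = np.where(ss == 0.0, 0.0, c_plus)
        l_s = xbar + c_plus * (xs - xbar)
        out["cb"] = (l_s * p1 + ys * p2) * var
    if "direct" in methods:
        tau2 = _profile_tau2_batch(xt, w)
        mu_hat = _re_mean_batch(tau2, xt, w)
        weight = np.where(tau2 > 0, tau2 / (w_s + tau2), 0.0)
        out["direct"] = weight * xt_s + (1.0 - weight) * mu_hat
    if "cr_standard" in methods:
        kterm = design.shrinkage_k_term()
        tau2_pm = _paule_mandel_batch(xt, w)
        mu_hat = _re_mean_batch(tau2_pm, xt, w)
        c_plus = np.maximum(
            1.0 - (kterm / (k - 1.0)) * w_s / (w_s + tau2_pm), 0.0
        )
        out["cr_standard"] = mu_hat + c_plus * (xt_s - mu_hat)
    if "cr_proportional" in methods or "cr_proportional_lt" in methods:
        kterm = design.shrinkage_k_term()
        mu_fe = _re_mean_batch(np.zeros(n), xt, w)
        q0 = _q_batch(np.zeros(n), xt, w)
        with np.errstate(divide="ignore"):
            c_plus = np.maximum(1.0 - kterm / q0, 0.0)
        c_plus = np.where(q0 == 0.0, 0.0, c_plus)
        s_prop = mu_fe + c_plus * (xt_s - mu_fe)
        if "cr_proportional" in methods:
            out["cr_proportional"] = s_prop
        if "cr_proportional_lt" in methods:
            half = lt_width * np.sqrt(w_s)
            out["cr_proportional_lt"] = np.clip(s_prop, xt_s - half, xt_s + half)
    return out


# ---------------------------------------------------------------------------
# scenario runner
# ---------------------------------------------------------------------------


def _draw_true_means(spec: ScenarioSpec, rng: np.random.Generator) -> np.ndarray:
    k, n = spec.design.k, spec.reps
    if spec.scenario == "I":
        return rng.normal(spec.mu0, np.sqrt(spec.tau2), size=(n, k))
    mu = np.zeros((n, k))
    if spec.scenario in ("III", "IV"):
        mu[:, 0] = spec.effective_delta
    return mu


def run_scenario(
    spec: ScenarioSpec,
    methods: tuple[str, ...] | list[str] = ALL_METHODS,
    lt_width: float = 1.0,
) -> ScenarioResult:
    """Simulate one scenario cell and summarize every requested estimator.

    Fixed seed gives identical output.  A replicate where an estimator
    produces a non-finite value is excluded from that estimator's summary
    and counted in ``n_failed`` (expected to be zero).
    """
    methods = tuple(methods)
    design = spec.design
    rng = np.random.default_rng(spec.seed)
    mu = _draw_true_means(spec, rng)
    x = rng.normal(mu, design.sigma1)
    s = x.argmax(axis=1)
    idx = np.arange(spec.reps)
    masked = x.copy()
    masked[idx, s] = -np.inf
    r = masked.argmax(axis=1)
    mu_s = mu[idx, s]
    ys = rng.normal(mu_s, design.sigma2)

    est = _batch_estimates(design, x, s, r, ys, methods, lt_width=lt_width)
    sigma_t = design.naive_se

    rows = []
    n_failed = 0
    for m in methods:
        err = est[m] - mu_s
        ok = np.isfinite(err)
        n_failed += int((~ok).sum())
        err = err[ok]
        n = err.size
        bias = err.mean()
        mse = (err**2).mean()
        rmse = np.sqrt(mse)
        se_bias = err.std(ddof=1) / np.sqrt(n)
        # delta method for sqrt(mean of squared errors)
        se_rmse = (err**2).std(ddof=1) / (2.0 * rmse * np.sqrt(n))
        rows.append(
            {
                "method": m,
                "scaled_bias": bias / sigma_t,
                "scaled_rmse": rmse / sigma_t,
                "mc_se_bias": se_bias / sigma_t,
                "mc_se_rmse": se_rmse / sigma_t,
                "n": n,
            }
        )
    table = pd.DataFrame(rows).set_index("method")
    return ScenarioResult(
        table=table,
        e_mu_s=float(mu_s.mean()),
        naive_se=sigma_t,
        reps=spec.reps,
        seed=spec.seed,
        n_failed=n_failed,
    )


def _cell_seed(master_seed: int, cell_index: int) -> int:
    """Stable per-cell seed derived from (master seed, cell index)."""
    return int(
        np.random.SeedSequence([master_seed, cell_index]).generate_state(1)[0]
        % (2**31)
    )


def run_table1(
    reps: int = 50_000,
    seed: int = 0,
    k: int = 6,
    sigma_levels: tuple[tuple[float, float], ...] = TABLE1_SIGMA_LEVELS,
    methods: tuple[str, ...] | list[str] = ALL_METHODS,
) -> pd.DataFrame:
    """The 16-cell grid: scenarios I-IV crossed with four (sigma1, sigma2) levels.

    Returns a wide DataFrame, one row per cell, with scaled-bias columns for
    every method but the UMVCUE (whose bias is zero up to sampling error)
    and scaled-root-MSE columns for all methods.
    """
    methods = tuple(methods)
    rows = []
    cell = 0
    for scen in _SCENARIOS:
        for s1, s2 in sigma_levels:
            cell += 1
            design = TrialDesign(k=k, sigma1=s1, sigma2=s2)
            spec = ScenarioSpec(
                scenario=scen,
                design=design,
                reps=reps,
                seed=_cell_seed(seed, cell),
            )
            res = run_scenario(spec, methods=methods)
            row = {
                "cell": cell,
                "scenario": scen,
                "sigma1": s1,
                "sigma2": s2,
                "e_mu_s": res.e_mu_s,
            }
            for m in methods:
                if m != "umvcue":
                    row[f"bias_{m}"] = res.table.loc[m, "scaled_bias"]
            for m in methods:
                row[f"rmse_{m}"] = res.table.loc[m, "scaled_rmse"]
            rows.append(row)
    return pd.DataFrame(rows)


def sweep(
    parameter: str,
    grid,
    design: TrialDesign,
    reps: int = 50_000,
    seed: int = 0,
    methods: tuple[str, ...] | list[str] = ALL_METHODS,
) -> pd.DataFrame:
    """One-dimensional sweep over delta, tau2 or k.

    delta: one arm at delta, rest zero (scenario III/IV family).
    tau2:  true means i.i.d. N(0, tau2) each replicate (scenario I family).
    k:     true means i.i.d. N(0, 1), number of arms varied.

    Returns a long-format DataFrame: one row per (grid point, method) with
    scaled bias, scaled root-MSE, their MC standard errors, and E[mu_s].
    """
    grid = list(grid)
    if not grid:
        raise ValueError("grid must be non-empty")
    if parameter not in ("delta", "tau2", "k"):
        raise ValueError("parameter must be 'delta', 'tau2' or 'k'")
    methods = tuple(methods)
    rows = []
    for i, val in enumerate(grid):
        cell_seed = _cell_seed(seed, i)
        if parameter == "delta":
            spec = ScenarioSpec(
                scenario="III", design=design, reps=reps, seed=cell_seed,
                delta=float(val),
            )
        elif parameter == "tau2":
            spec = ScenarioSpec(
                scenario="I", design=design, reps=reps, seed=cell_seed,
                mu0=0.0, tau2=float(val),
            )
        else:
            d = replace(design, k=int(val))
            spec = ScenarioSpec(
                scenario="I", design=d, reps=reps, seed=cell_seed,
                mu0=0.0, tau2=1.0,
            )
        res = run_scenario(spec, methods=methods)
        for m in methods:
            rows.append(
                {
                    parameter: val,
                    "method": m,
                    "scaled_bias": res.table.loc[m, "scaled_bias"],
                    "scaled_rmse": res.table.loc[m, "scaled_rmse"],
                    "mc_se_bias": res.table.loc[m, "mc_se_bias"],
                    "mc_se_rmse": res.table.loc[m, "mc_se_rmse"],
                    "e_mu_s": res.e_mu_s,
                    "reps": reps,
                    "seed": cell_seed,
                }
            )
    return pd.DataFrame(rows)
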