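"""Bayesian calibration of the growth coefficient A.

The inverse problem minimizes the root-mean-square error (in percentage
points) between simulated and observed channel fillings at the measurement
days, over a log-scaled interval of A.  The optimizer is sequential
model-based optimization (SMBO): a Gaussian-process surrogate of the
objective is refit after every evaluation and the next A maximizes expected
improvement.  One coefficient is fitted per material, shared across all
shapes and sizes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm as _norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import (
    ConstantKernel,
    Matern,
    WhiteKernel,
)

from .datasets import ObservationTable
from .geometry import CHANNEL_SHAPES, ChannelSpec, channel_sdf, initial_levelset
from .lsm import GrowthParams, simulate

DEFAULT_BOUNDS = (1e-4, 1.0)  # mm²/day; spans <1-day to >1-year fill times


@dataclass
class SimConfig:
    """Fixed numerical setup shared by every objective evaluation."""

    spacing_frac: int = 50  # grid spacing = d / spacing_frac
    layer: float = 0.010  # initial neotissue film, mm
    eps: float = 1e-4
    max_step_frac: float = 0.5
    redistance_every: int = 5
    pooled_shapes: tuple[str, ...] = CHANNEL_SHAPES

    def params(self, A: float) -> GrowthParams:
        return GrowthParams(
            A=A,
            eps=self.eps,
            max_step_frac=self.max_step_frac,
            redistance_every=self.redistance_every,
        )


def simulate_channel_filling(
    shape: str,
    d: float,
    A: float,
    config: SimConfig,
    days: list[float],
) -> dict[float, float]:
    """Percent filling of one channel at the requested days."""
    spec = ChannelSpec(shape, d)
    psi = channel_sdf(spec, spacing=d / config.spacing_frac)
    state = initial_levelset(psi, config.layer)
    days = sorted(float(t) for t in days)
    series = simulate(state, config.params(A), t_end=days[-1], record_at=days)
    return {t: 100.0 * series.at(t) for t in days}


def rmse_objective(
    A: float, obs: ObservationTable, config: SimConfig | None = None
) -> float:
    """RMSE (percentage points) between simulated and observed fillings.

    Rows with shape ``"pooled"`` are compared against the mean filling of
    the four cross-sections at that size, matching how the observed values
    pool shapes.  Simulations are shared across rows within one call;
    the result is deterministic in (A, config).
    """
    config = config or SimConfig()
    df = obs.df
    if df.empty:
        raise ValueError("empty observation table")

    # which (shape, d) simulations are needed, and at which days
    needed: dict[tuple[str, float], set[float]] = {}
    for _, row in df.iterrows():
        days = {float(row["day"])}
        if row["shape"] == "pooled":
            for s in config.pooled_shapes:
                needed.setdefault((s, float(row["d_mm"])), set()).update(days)
        else:
            needed.setdefault(
                (str(row["shape"]), float(row["d_mm"])), set()
            ).update(days)

    sim: dict[tuple[str, float], dict[float, float]] = {}
    for (shape, d), days in needed.items():
        sim[(shape, d)] = simulate_channel_filling(
            shape, d, A, config, sorted(days)
        )

    errs = []
    for _, row in df.iterrows():
        day = float(row["day"])
        d = float(row["d_mm"])
        if row["shape"] == "pooled":
            pred = float(
                np.mean([sim[(s, d)][day] for s in config.pooled_shapes])
            )
        else:
            pred = sim[(str(row["shape"]), d)][day]
        errs.append(pred - float(row["filling_pct"]))
    return float(np.sqrt(np.mean(np.square(errs))))


@dataclass
class CalibrationResult:
    """Outcome of an SMBO run over A."""

    A_star: float
    objective_star: float
    trace: list[tuple[float, float]]  # (A tried, objective)
    n_evals: int
    seed: int
    meta: dict = field(default_factory=dict)


def _expected_improvement(
    mu: np.ndarray, sigma: np.ndarray, best: float, xi: float = 0.01
) -> np.ndarray:
    sigma = np.maximum(sigma, 1e-12)
    z = (best - mu - xi) / sigma
    return (best - mu - xi) * _norm.cdf(z) + sigma * _norm.pdf(z)


def minimize_smbo(
    func,
    bounds: tuple[float, float],
    n_iter: int = 25,
    seed: int = 0,
    n_init: int = 6,
    log_scale: bool = True,
) -> CalibrationResult:
    """Minimize a scalar objective by GP-surrogate SMBO.

    The search variable is log10(A) when ``log_scale`` (the default, as A
    spans orders of magnitude).  ``n_iter`` counts total objective
    evaluations, the first ``n_init`` of which are a seeded stratified
    design.  Fixed seed ⟹ identical trace on re-run.
    """
    lo, hi = bounds
    if not 0 < lo < hi:
        raise ValueError("need 0 < A_lo < A_hi")
    if n_iter < max(n_init, 2):
        raise ValueError("n_iter too small")

    def to_x(u: np.ndarray) -> np.ndarray:
        if log_scale:
            la, lb = math.log10(lo), math.log10(hi)
            return 10 ** (la + u * (lb - la))
        return lo + u * (hi - lo)

    rng = np.random.default_rng(seed)
    us = list((np.arange(n_init) + rng.uniform(0, 1, n_init)) / n_init)
    ys: list[float] = []
    xs: list[float] = []
    for u in us:
        x = float(to_x(np.asarray(u)))
        y = float(func(x))
        if not np.isfinite(y):
            raise FloatingPointError(f"non-finite objective at A={x:g}")
        xs.append(x)
        ys.append(y)

    cand = np.linspace(0.0, 1.0, 513)
    while len(xs) < n_iter:
        U = np.asarray(us)[:, None]
        y_arr = np.asarray(ys)
        kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
            length_scale=0.2, length_scale_bounds=(1e-2, 1e1), nu=2.5
        ) + WhiteKernel(1e-6, (1e-10, 1e-1))
        gp = GaussianProcessRegressor(
            kernel=kernel,
            normalize_y=True,
            n_restarts_optimizer=2,
            random_state=seed,
        )
        with warnings.catch_warnings():
            # deterministic objectives drive the fitted noise to its floor
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(U, y_arr)
        mu, sig = gp.predict(cand[:, None], return_std=True)
        ei = _expected_improvement(mu, sig, float(np.min(y_arr)))
        # never re-evaluate (numerically) the same point
        taken = np.abs(cand[:, None] - np.asarray(us)[None, :]).min(axis=1)
        ei[taken < 1e-4] = -np.inf
        u_next = float(cand[int(np.argmax(ei))]) if np.isfinite(ei).any() else float(
            rng.uniform()
        )
        x = float(to_x(np.asarray(u_next)))
        y = float(func(x))
        if not np.isfinite(y):
            raise FloatingPointError(f"non-finite objective at A={x:g}")
        us.append(u_next)
        xs.append(x)
        ys.append(y)

    best = int(np.argmin(ys))
    return CalibrationResult(
        A_star=xs[best],
        objective_star=ys[best],
        trace=list(zip(xs, ys)),
        n_evals=len(xs),
        seed=seed,
        meta={
            "surrogate": "gaussian-process (Matern 5/2)",
            "acquisition": "expected-improvement",
            "bounds": bounds,
            "log_scale": log_scale,
        },
    )


def bayes_optimize(
    obs: ObservationTable,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    n_iter: int = 25,
    seed: int = 0,
    config: SimConfig | None = None,
) -> CalibrationResult:
    """Calibrate A against an observation table by SMBO over log10(A)."""
    config = config or SimConfig()
    result = minimize_smbo(
        lambda A: rmse_objective(A, obs, config),
        bounds=bounds,
        n_iter=n_iter,
        seed=seed,
    )
    result.meta["sim_config"] = config
    return result
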