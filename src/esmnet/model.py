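"""The epidemic spreading model (ESM) of misfolded-protein dynamics.

Each gray-matter region i carries a probability P_i(t) of misfolded-protein
(MP) burden.  On a daily grid, the state evolves by an infection-like gain
and a clearance-like loss,

    dP_i = (1 - P_i) * R_i(t) - P_i * delta_i(t),

plus optional additive Gaussian noise.  R_i is the probability of receiving
infectious-like agents, accumulated as a complement of products over
connected senders; each sender j contributes through its extrinsic infection
rate evaluated at the state delayed by the axonal travel time
tau_ji = fiber_length / V_MP.  The total infection rate of a region is a
normalized logistic function of its own deposition, split into extrinsic and
intrinsic parts by the Gini coefficient of the current deposition vector
(high inter-regional inequality pushes soluble MP outward).  Clearance
capacity decays exponentially with local deposition.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from numba import njit

from .connectome import Connectome

__all__ = [
    "ESMParams",
    "RegionalRates",
    "Trajectory",
    "gini_coefficient",
    "infection_rate",
    "clearance_rate",
    "split_rates",
    "reception_probability",
    "regional_rates",
    "simulate",
    "marginal_rates",
]


@dataclasses.dataclass
class ESMParams:
    """Subject-level ESM constants.

    beta0, delta0 : production / clearance amplitude constants (> 0; values
        above 1 are clamped to 1 when converted to rates).
    noise_mean, noise_sd : mu and sigma of the additive Gaussian noise,
        probability/day and probability/day^(1/2).
    velocity : soluble-MP propagation velocity V_MP, mm/day.
    dt : integration step, days.
    horizon_days : simulated span, days (default 50 years).
    p_seed_init : deposition probability assigned to seed regions at t=0.
    sigmoid_slope, sigmoid_mid : shape of the production sigmoid.
    clearance_decay : exponential decay constant of the clearance rate.
    """

    beta0: float = 0.5
    delta0: float = 0.3
    noise_mean: float = 0.0
    noise_sd: float = 0.0
    velocity: float = 1.0
    dt: float = 1.0
    horizon_days: int = 18250
    p_seed_init: float = 0.01
    sigmoid_slope: float = 10.0
    sigmoid_mid: float = 0.5
    clearance_decay: float = 1.0

    def __post_init__(self) -> None:
        if self.beta0 < 0 or self.delta0 < 0:
            raise ValueError("beta0 and delta0 must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.velocity <= 0 or self.dt <= 0:
            raise ValueError("velocity and dt must be positive")
        if self.horizon_days <= 0:
            raise ValueError("horizon_days must be positive")
        if not 0 < self.p_seed_init <= 1:
            raise ValueError("p_seed_init must be in (0, 1]")
        if self.sigmoid_slope <= 0 or not 0 < self.sigmoid_mid < 1:
            raise ValueError("invalid sigmoid shape constants")
        if self.clearance_decay <= 0:
            raise ValueError("clearance_decay must be positive")

    def replace(self, **kw) -> "ESMParams":
        return dataclasses.replace(self, **kw)


@dataclasses.dataclass
class RegionalRates:
    """Regional infection/clearance rates at one instant."""

    beta_total: np.ndarray
    beta_ext: np.ndarray
    beta_int: np.ndarray
    delta: np.ndarray
    gini: float


@dataclasses.dataclass
class Trajectory:
    """Regional deposition probabilities on the simulation grid."""

    time_days: np.ndarray
    p: np.ndarray
    seeds: frozenset
    params: ESMParams

    @property
    def n_regions(self) -> int:
        return self.p.shape[1]


def gini_coefficient(x) -> float:
    """Gini coefficient of a non-negative vector.

    G = sum_ij |x_i - x_j| / (2 n^2 mean(x)); 0 for perfect equality,
    approaching 1 for complete inequality.  Returns 0 for an all-zero vector.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty vector")
    if x.min() < 0:
        raise ValueError("negative entries")
    total = x.sum()
    if total <= 0:
        return 0.0
    xs = np.sort(x)
    n = x.size
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) * xs).sum() / (n * total))


def infection_rate(p_dep, beta0: float, slope: float = 10.0, mid: float = 0.5):
    """Total infection rate: clamped beta0 times a normalized logistic.

    Anchored so the rate is 0 at zero deposition and min(beta0, 1) at full
    deposition, strictly increasing in between.
    """
    p = np.asarray(p_dep, dtype=float)
    s0 = 1.0 / (1.0 + math.exp(slope * mid))
    s1 = 1.0 / (1.0 + math.exp(-slope * (1.0 - mid)))
    s = 1.0 / (1.0 + np.exp(-slope * (p - mid)))
    out = min(beta0, 1.0) * (s - s0) / (s1 - s0)
    return out if out.ndim else float(out)


def clearance_rate(p_dep, delta0: float, decay: float = 1.0):
    """Clearance rate: min(delta0, 1) * exp(-decay * p_dep)."""
    p = np.asarray(p_dep, dtype=float)
    out = min(delta0, 1.0) * np.exp(-decay * p)
    return out if out.ndim else float(out)


def split_rates(beta_total, gini: float):
    """Split total infection rates into extrinsic and intrinsic parts."""
    if not 0 <= gini < 1:
        raise ValueError("gini must be in [0, 1)")
    bt = np.asarray(beta_total, dtype=float)
    return gini * bt, (1.0 - gini) * bt


def reception_probability(
    p_delayed, p_now_i, acp_col_i, beta_ext_delayed, beta_int_i: float
) -> float:
    """Probability of receiving infectious-like agents at region i.

    Probabilistic accumulation of exogenous factors from every connected
    sender j (each arriving with probability ACP_ji * beta_ext_j at the
    delayed state) and the endogenous factor beta_int_i:

        R_i = 1 - (1 - beta_int_i) * prod_j (1 - ACP_ji * beta_ext_j)

    ``p_delayed``/``p_now_i`` document the states the rates were evaluated
    at; the betas already encode them.
    """
    acp = np.asarray(acp_col_i, dtype=float)
    bext = np.asarray(beta_ext_delayed, dtype=float)
    return float(1.0 - (1.0 - beta_int_i) * np.prod(1.0 - acp * bext))


def regional_rates(p: np.ndarray, params: ESMParams) -> RegionalRates:
    """All regional rates implied by one deposition vector."""
    g = gini_coefficient(p)
    bt = infection_rate(p, params.beta0, params.sigmoid_slope, params.sigmoid_mid)
    bext, bint = split_rates(bt, g)
    delta = clearance_rate(p, params.delta0, params.clearance_decay)
    return RegionalRates(beta_total=bt, beta_ext=bext, beta_int=bint, delta=delta, gini=g)


@njit(cache=False)
def _esm_loop(P, BT, acp, tau, beta0, delta0, slope, mid, decay, mu, noise, dt):  # pragma: no cover
    n_steps = P.shape[0] - 1
    n = P.shape[1]
    s0 = 1.0 / (1.0 + math.exp(slope * mid))
    s1 = 1.0 / (1.0 + math.exp(-slope * (1.0 - mid)))
    denom = s1 - s0
    b0 = min(beta0, 1.0)
    d0 = min(delta0, 1.0)
    for j in range(n):
        BT[0, j] = b0 * (1.0 / (1.0 + math.exp(-slope * (P[0, j] - mid))) - s0) / denom
    for t in range(n_steps):
        # Gini of the current deposition vector (sorted-vector identity)
        total = 0.0
        for j in range(n):
            total += P[t, j]
        if total > 0.0:
            xs = np.sort(P[t])
            acc = 0.0
            for j in range(n):
                acc += (2.0 * (j + 1) - n - 1.0) * xs[j]
            g = acc / (n * total)
        else:
            g = 0.0
        for i in range(n):
            pi = P[t, i]
            prod = 1.0 - (1.0 - g) * BT[t, i]
            for j in range(n):
                if j == i:
                    continue
                a = acp[j, i]
                if a > 0.0:
                    td = t - tau[j, i]
                    if td < 0:
                        td = 0
                    prod *= 1.0 - a * g * BT[td, j]
            r = 1.0 - prod
            delta = d0 * math.exp(-decay * pi)
            v = pi + dt * ((1.0 - pi) * r - pi * delta) + mu * dt + noise[t, i]
            if v < 0.0:
                v = 0.0
            elif v > 1.0:
                v = 1.0
            P[t + 1, i] = v
            BT[t + 1, i] = b0 * (1.0 / (1.0 + math.exp(-slope * (v - mid))) - s0) / denom


def simulate(
    conn: Connectome,
    params: ESMParams,
    seeds,
    rng_seed: int | None = None,
) -> Trajectory:
    """Integrate the ESM by Euler-Maruyama on the daily grid.

    Seeds start at ``p_seed_init`` and all other regions at 0; transmission
    from j to i uses the sender's state delayed by
    round(fiber_length[j][i] / velocity / dt) steps, with the initial
    condition standing in for states before t=0.  With ``rng_seed`` None the
    noise term is omitted and the trajectory is deterministic.  The state is
    clipped to [0, 1] after every step.
    """
    seed_idx = conn._check_indices(seeds)
    n = conn.n_regions
    n_steps = int(round(params.horizon_days / params.dt))
    tau = np.rint(conn.fiber_length / (params.velocity * params.dt)).astype(np.int64)
    P = np.zeros((n_steps + 1, n))
    P[0, seed_idx] = params.p_seed_init
    BT = np.zeros_like(P)
    if rng_seed is not None and params.noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        noise = params.noise_sd * math.sqrt(params.dt) * rng.standard_normal((n_steps, n))
    else:
        noise = np.zeros((n_steps, n))
    _esm_loop(
        P, BT, conn.acp, tau,
        params.beta0, params.delta0,
        params.sigmoid_slope, params.sigmoid_mid, params.clearance_decay,
        params.noise_mean, noise, params.dt,
    )
    if not np.all(np.isfinite(P)):
        raise FloatingPointError("non-finite state in ESM integration")
    time = np.arange(n_steps + 1) * params.dt
    return Trajectory(time_days=time, p=P, seeds=frozenset(seed_idx), params=params)


def marginal_rates(params: ESMParams, n_grid: int = 1001) -> tuple[float, float]:
    """Globally marginalized production and clearance rates.

    Averages the infection and clearance rate functions over all possible
    deposition levels P in [0, 1] by composite trapezoidal quadrature on a
    fixed grid, giving the per-subject summary rates beta_eff and delta_eff.
    """
    p = np.linspace(0.0, 1.0, n_grid)
    beta_eff = float(np.trapezoid(
        infection_rate(p, params.beta0, params.sigmoid_slope, params.sigmoid_mid), p
    ))
    delta_eff = float(np.trapezoid(
        clearance_rate(p, params.delta0, params.clearance_decay), p
    ))
    return beta_eff, delta_eff
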