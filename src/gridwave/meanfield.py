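"""Population mean-field model: Ricciardi gain, nullclines, regime planning.

A single module is reduced to three interacting populations (F, B, I) whose
average rates evolve as

    F, B:   d(nu_i)/dt = (phi_i(nu, c) - nu_i) / tau_E
            d(c_i)/dt  = -c_i / tau_c + alpha_c * nu_i
    I:      d(nu_i)/dt = (phi_i(nu) - nu_i) / tau_I

where phi_i is the stationary firing rate of a LIF neuron receiving white
noise with the mean and variance produced by the other populations at their
current rates (diffusion approximation; the Ricciardi first-passage-time
formula).  Spike-frequency adaptation enters as a mean self-inhibitory
current proportional to the fatigue c_i.  The interplay of recurrent
excitation and fatigue produces either a weakly stable low-rate fixed point
with noise-driven Up/Down relaxation oscillations (slow-wave regime, SW) or
a single stable fixed point with stationary fluctuations (asynchronous
wake-like regime, AW).  The module receives its full in-degree at its own
rates: spatial coupling is the spiking simulator's job, not the planner's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq, root
from scipy.special import erfcx

from .network import ConnectivityKernel, EfficacyMatrix, GridSpec, POPULATIONS
from .neuron import NeuronParams

__all__ = [
    "MeanFieldModel",
    "FixedPoint",
    "Trajectory",
    "input_moments",
    "ricciardi_rate",
    "nullclines",
    "find_fixed_points",
    "integrate_meanfield",
    "classify_regime",
    "tune_regime",
]

_SQRT_PI = math.sqrt(math.pi)


@dataclass(frozen=True)
class MeanFieldModel:
    """Effective single-module description matching the network's input.

    ``M[t][s]`` is the in-degree of a population-``t`` neuron from population
    ``s`` (equal to the network's fixed in-degree for every decay constant),
    ``eff`` the efficacy matrix including the external drive, ``params`` the
    per-population neuron constants.  ``tau_E``/``tau_I`` are the
    phenomenological rate-relaxation time constants (ms).
    """

    M: tuple  # 3x3 nested tuple of in-degrees, M[t][s]
    eff: EfficacyMatrix
    params: tuple  # (NeuronParams F, B, I)
    tau_E: float = 10.0
    tau_I: float = 5.0

    def __post_init__(self):
        if self.tau_E <= 0 or self.tau_I <= 0:
            raise ValueError("tau_E and tau_I must be positive")

    @classmethod
    def from_network_config(
        cls,
        spec: GridSpec,
        kernel: ConnectivityKernel,
        eff: EfficacyMatrix,
        params: dict,
        tau_E: float = 10.0,
        tau_I: float = 5.0,
    ) -> "MeanFieldModel":
        M_row = tuple(kernel.in_degree(k) for k in spec.pop_sizes())
        return cls(
            M=(M_row, M_row, M_row),
            eff=eff,
            params=tuple(params[p] for p in POPULATIONS),
            tau_E=tau_E,
            tau_I=tau_I,
        )

    @property
    def M_array(self) -> np.ndarray:
        return np.asarray(self.M, dtype=float)

    def signed_J(self) -> np.ndarray:
        """Efficacy matrix with the inhibitory-source sign applied."""
        J = self.eff.J_array.copy()
        J[:, 2] *= -1.0
        return J

    def with_eff(self, eff: EfficacyMatrix) -> "MeanFieldModel":
        return replace(self, eff=eff)


def input_moments(rates_hz, model: MeanFieldModel, c=(0.0, 0.0)) -> tuple:
    """Mean and SD of the input-driven depolarization per population (mV).

    ``mu_t = tau_m (sum_s M_ts J_ts nu_s + J_ext nu_ext) - tau_m g_c c_t / C_m``
    and ``sigma_t^2 = tau_m (sum_s M_ts <J_ts^2> nu_s + <J_ext^2> nu_ext)``
    with second moments including the Gaussian weight spread.  Rates in Hz,
    internally converted to events/ms.
    """
    nu = np.asarray(rates_hz, dtype=float)
    if np.any(nu < 0):
        raise ValueError("rates must be >= 0")
    nu_ms = nu * 1e-3
    nu_ext_ms = model.eff.nu_ext_per_pop() * 1e-3
    Js = model.signed_J()
    J2 = model.eff.J_array**2 * (1.0 + model.eff.cv**2)
    M = model.M_array
    mu = np.empty(3)
    sig = np.empty(3)
    c_full = (c[0], c[1], 0.0)
    for t in range(3):
        p = model.params[t]
        drive = float(M[t] @ (Js[t] * nu_ms)) + model.eff.J_ext * nu_ext_ms[t]
        var = float(M[t] @ (J2[t] * nu_ms)) + (
            model.eff.J_ext**2 + model.eff.delta_J_ext**2
        ) * nu_ext_ms[t]
        mu[t] = p.tau_m * drive - p.tau_m * p.adapt_coupling * c_full[t]
        sig[t] = math.sqrt(max(p.tau_m * var, 0.0))
    return mu, sig


def _fpt_integral(lo: float, up: float) -> float:
    """Robust evaluation of ``int_lo^up erfcx(-u) du``.

    ``erfcx(-u) = e^{u^2}(1 + erf u)`` without overflow.  The far-left tail
    (u < -30), where the integrand behaves as ``1/(sqrt(pi)|u|)``, is handled
    by its leading-order closed form.
    """
    tail = 0.0
    if lo < -30.0:
        tail = (math.log(-lo) - math.log(30.0)) / _SQRT_PI
        lo = -30.0
    val, _ = quad(lambda u: erfcx(-u), lo, up, epsrel=1e-10, limit=200)
    return val + tail


def ricciardi_rate(mu: float, sigma: float, params: NeuronParams) -> float:
    """Stationary LIF firing rate (Hz) for input mean ``mu`` and SD ``sigma``.

    ``mu`` is the input-driven mean depolarization: the stationary membrane
    potential sits at ``E + mu``.  The rate is the inverse mean first-passage
    time from reset to threshold plus the refractory period.  The
    deterministic (sigma -> 0) limits are evaluated in closed form.
    """
    if not (np.isfinite(mu) and np.isfinite(sigma)) or sigma < 0:
        raise ValueError("mu and sigma must be finite, sigma >= 0")
    v_inf = params.E + mu
    if sigma < 1e-12 * (params.V_theta - params.V_r):
        if v_inf <= params.V_theta:
            return 0.0
        period = params.tau_arp + params.tau_m * math.log(
            (v_inf - params.V_r) / (v_inf - params.V_theta)
        )
        return 1000.0 / period
    up = (params.V_theta - v_inf) / sigma
    lo = (params.V_r - v_inf) / sigma
    if up > 26.0:
        return 0.0  # rate suppressed as exp(-up^2): numerically zero
    integral = _fpt_integral(lo, up)
    period = params.tau_arp + params.tau_m * _SQRT_PI * integral
    return 1000.0 / period


def gain_rates(rates_hz, model: MeanFieldModel, c=(0.0, 0.0)) -> np.ndarray:
    """phi_i for all three populations at the given rates/fatigues (Hz)."""
    mu, sig = input_moments(rates_hz, model, c)
    return np.array(
        [ricciardi_rate(mu[t], sig[t], model.params[t]) for t in range(3)]
    )


# --------------------------------------------------------------------------
# slaving of B and I to the F phase plane

def _slave_BI(model: MeanFieldModel, nu_F: float, nu_start=(3.0, 5.0)) -> tuple:
    """Stationary (nu_B, nu_I) given nu_F, with c_B at its own equilibrium.

    Damped self-consistent iteration from the warm start (which keeps the
    solution on the continuation branch), finished by a Newton-type polish.
    """
    alpha = model.params[1].alpha_c
    tau_c = model.params[1].tau_c

    def phi_BI(nu_B, nu_I):
        c_B = alpha * tau_c * max(nu_B, 0.0) * 1e-3
        phi = gain_rates((nu_F, max(nu_B, 0.0), max(nu_I, 0.0)), model,
                         c=(0.0, c_B))
        return phi[1], phi[2]

    nu_B, nu_I = nu_start
    for _ in range(80):
        pb, pi = phi_BI(nu_B, nu_I)
        nb = 0.5 * nu_B + 0.5 * pb
        ni = 0.5 * nu_I + 0.5 * pi
        if abs(nb - nu_B) + abs(ni - nu_I) < 1e-4:
            nu_B, nu_I = nb, ni
            break
        nu_B, nu_I = nb, ni
    sol = root(lambda x: np.subtract(phi_BI(*x), x), x0=[nu_B, nu_I],
               method="hybr", tol=1e-12)
    if sol.success:
        nu_B, nu_I = sol.x
    return float(max(nu_B, 0.0)), float(max(nu_I, 0.0))


def _phi_F_slaved(model: MeanFieldModel, nu_F: float, c_F: float,
                  nu_start=(3.0, 5.0)) -> tuple:
    nu_B, nu_I = _slave_BI(model, nu_F, nu_start)
    c_B = model.params[1].alpha_c * model.params[1].tau_c * nu_B * 1e-3
    phi = gain_rates((nu_F, nu_B, nu_I), model, c=(c_F, c_B))
    return float(phi[0]), nu_B, nu_I


def nullclines(model: MeanFieldModel, rate_grid_hz) -> dict:
    """Nullclines of the F population in the (nu, c) phase plane.

    The rate nullcline is the set where ``nu = phi_F(nu, c)`` with B and I at
    their quasi-stationary rates; for each grid rate the unique fatigue
    solving the balance is found by bracketed root search (phi is strictly
    decreasing in c).  The fatigue nullcline is the line
    ``c = alpha_c tau_c nu``.  An S-shaped (non-monotonic) rate nullcline is
    the signature of the bistability behind slow waves.
    """
    grid = np.asarray(rate_grid_hz, dtype=float)
    if np.any(~np.isfinite(grid)) or np.any(grid < 0):
        raise ValueError("rate grid must be finite and >= 0")
    pF = model.params[0]
    c_vals = np.full(grid.size, np.nan)
    start = (3.0, 5.0)
    for i, nu in enumerate(grid):
        def h(c_F):
            phi, *_ = _phi_F_slaved(model, nu, c_F, start)
            return phi - nu
        # phi decreases with c: bracket a sign change
        c_hi = 1.0
        h0 = h(0.0)
        if h0 < 0:
            # even with zero fatigue the gain is below nu: nullcline would
            # need negative fatigue; extend the bracket below zero
            c_lo = -1.0
            while h(c_lo) < 0 and c_lo > -1e4:
                c_lo *= 4.0
            if h(c_lo) < 0:
                continue
            c_vals[i] = brentq(h, c_lo, 0.0, xtol=1e-12)
        else:
            while h(c_hi) > 0 and c_hi < 1e6:
                c_hi *= 4.0
            if h(c_hi) > 0:
                continue
            c_vals[i] = brentq(h, 0.0, c_hi, xtol=1e-12)
        _, nu_B, nu_I = _phi_F_slaved(model, nu, c_vals[i], start)
        start = (nu_B, nu_I)
    alpha, tau_c = pF.alpha_c, pF.tau_c
    return {
        "nu_hz": grid,
        "c_rate_nullcline": c_vals,
        "c_fatigue_nullcline": alpha * tau_c * grid * 1e-3,
    }


# --------------------------------------------------------------------------
# fixed points

@dataclass
class FixedPoint:
    rates_hz: np.ndarray  # (nu_F, nu_B, nu_I)
    c: np.ndarray  # (c_F, c_B)
    stable: bool
    eigenvalues: np.ndarray
    residual: float

    @property
    def stability(self) -> str:
        return "stable" if self.stable else "unstable"


def _rhs(y: np.ndarray, model: MeanFieldModel) -> np.ndarray:
    """Right-hand side of the 5-variable rate/fatigue system (per ms)."""
    nu = np.maximum(y[:3], 0.0)
    c = y[3:5]
    phi = gain_rates(nu, model, c=(c[0], c[1]))
    alpha = np.array([model.params[0].alpha_c, model.params[1].alpha_c])
    tau_c = np.array([model.params[0].tau_c, model.params[1].tau_c])
    dnu = np.empty(3)
    dnu[0] = (phi[0] - y[0]) / model.tau_E
    dnu[1] = (phi[1] - y[1]) / model.tau_E
    dnu[2] = (phi[2] - y[2]) / model.tau_I
    dc = -c / tau_c + alpha * nu[:2] * 1e-3
    return np.concatenate([dnu, dc])


def find_fixed_points(model: MeanFieldModel, nu_max_hz: float = 120.0,
                      n_scan: int = 48) -> list:
    """Locate all fixed points by a scan over nu_F with B, I slaved.

    Sign changes of ``phi_F(nu_F) - nu_F`` along the scan are polished by
    bisection, refined as roots of the full 5-variable system, and classified
    by the eigenvalues of the numerical Jacobian.
    """
    grid = np.concatenate([[0.0], np.geomspace(0.05, nu_max_hz, n_scan - 1)])
    alpha_F = model.params[0].alpha_c
    tau_cF = model.params[0].tau_c
    start = (3.0, 5.0)
    res_vals = np.empty(grid.size)
    slaved = []
    for i, nu in enumerate(grid):
        c_F = alpha_F * tau_cF * nu * 1e-3
        phi, nu_B, nu_I = _phi_F_slaved(model, nu, c_F, start)
        res_vals[i] = phi - nu
        slaved.append((nu_B, nu_I))
        start = (nu_B, nu_I)

    candidates = []
    for i in range(grid.size - 1):
        if res_vals[i] == 0.0:
            candidates.append((grid[i], slaved[i]))
        elif res_vals[i] * res_vals[i + 1] < 0:
            f = lambda nu: _phi_F_slaved(
                model, nu, alpha_F * tau_cF * nu * 1e-3, slaved[i]
            )[0] - nu
            try:
                candidates.append(
                    (brentq(f, grid[i], grid[i + 1], xtol=1e-12), slaved[i])
                )
            except ValueError:
                # slaved B/I branch jumped inside the bracket; keep the
                # midpoint, the residual filter below decides
                candidates.append((0.5 * (grid[i] + grid[i + 1]), slaved[i]))
    if res_vals[-1] == 0.0:
        candidates.append((grid[-1], slaved[-1]))

    points = []
    for nu_F, warm in candidates:
        nu_B, nu_I = _slave_BI(model, nu_F, warm)
        y = np.array([
            nu_F, nu_B, nu_I,
            alpha_F * tau_cF * nu_F * 1e-3,
            model.params[1].alpha_c * model.params[1].tau_c * nu_B * 1e-3,
        ])
        resid = float(np.max(np.abs(_rhs(y, model))))
        if resid > 1e-6:
            continue
        # numerical Jacobian
        J = np.empty((5, 5))
        h = 1e-5
        f0 = _rhs(y, model)
        for k in range(5):
            yk = y.copy()
            yk[k] += h
            J[:, k] = (_rhs(yk, model) - f0) / h
        ev = np.linalg.eigvals(J)
        if points and min(abs(p.rates_hz[0] - y[0]) for p in points) < 1e-6:
            continue
        points.append(FixedPoint(
            rates_hz=np.maximum(y[:3], 0.0),
            c=y[3:5],
            stable=bool(np.all(ev.real < 0)),
            eigenvalues=ev,
            residual=resid,
        ))
    points.sort(key=lambda p: p.rates_hz[0])
    return points


# --------------------------------------------------------------------------
# integration and regime classification

@dataclass
class Trajectory:
    t_ms: np.ndarray
    rates_hz: np.ndarray  # (n, 3)
    c: np.ndarray  # (n, 2)


def integrate_meanfield(
    model: MeanFieldModel,
    duration_ms: float,
    dt_ms: float = 0.5,
    init=None,
    noise_hz: float = 0.0,
    seed: int = 0,
) -> Trajectory:
    """Euler(-Maruyama) integration of the 5-variable mean-field system.

    ``noise_hz`` adds independent Gaussian perturbations of that magnitude
    (Hz per sqrt(ms)) to the three rate equations, emulating finite-size
    fluctuations; rates are clipped at zero after each step.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration_ms / dt_ms))
    y = np.array([1.0, 1.0, 1.0, 0.0, 0.0]) if init is None else np.asarray(init, float).copy()
    rng = np.random.default_rng([seed, 0x0F1E])
    t = np.arange(n + 1) * dt_ms
    out = np.empty((n + 1, 5))
    out[0] = y
    sq = math.sqrt(dt_ms)
    for i in range(n):
        dy = _rhs(y, model) * dt_ms
        if noise_hz > 0:
            dy[:3] += noise_hz * sq * rng.standard_normal(3)
        y = y + dy
        y[:3] = np.maximum(y[:3], 0.0)
        out[i + 1] = y
    return Trajectory(t_ms=t, rates_hz=out[:, :3], c=out[:, 3:5])


def oscillation_stats(traj: Trajectory, lo_hz: float = 3.0, hi_hz: float = 25.0,
                      transient_ms: float = 500.0,
                      smooth_ms: float = 25.0) -> dict:
    """Count hysteretic low/high alternations of nu_F and their frequency.

    The rate is smoothed over ``smooth_ms`` first, so fast noise fluctuations
    around a fixed point do not register: only the slow, deep Up/Down
    relaxation cycles (hundreds of ms, spanning both thresholds) count.
    """
    m = traj.t_ms >= transient_ms
    x = traj.rates_hz[m, 0]
    t = traj.t_ms[m]
    if t.size > 2 and smooth_ms > 0:
        dt = t[1] - t[0]
        w = max(1, int(round(smooth_ms / dt)))
        x = np.convolve(x, np.ones(w) / w, mode="same")
    state = x[0] > hi_hz
    n_up = 0
    up_times = []
    for i in range(x.size):
        if not state and x[i] > hi_hz:
            state = True
            n_up += 1
            up_times.append(t[i])
        elif state and x[i] < lo_hz:
            state = False
    dur_s = (t[-1] - t[0]) * 1e-3 if t.size > 1 else np.nan
    freq = n_up / dur_s if dur_s and dur_s > 0 else 0.0
    return {"n_cycles": n_up, "freq_hz": freq, "up_times_ms": np.array(up_times)}


def classify_regime(model: MeanFieldModel, noise_hz: float = 2.0,
                    duration_ms: float = 4000.0, seed: int = 0,
                    lo_hz: float = 3.0, hi_hz: float = 25.0) -> dict:
    """Classify the module as SW (noise-driven Up/Down alternation) or AW.

    Integrates the mean-field system with small rate noise and counts
    hysteretic alternations of nu_F between the low and high thresholds:
    three or more full cycles mark the slow-wave regime, otherwise the module
    is asynchronous (stationary around its fixed point).
    """
    fps = find_fixed_points(model)
    traj = integrate_meanfield(model, duration_ms, dt_ms=0.5,
                               noise_hz=noise_hz, seed=seed)
    osc = oscillation_stats(traj, lo_hz=lo_hz, hi_hz=hi_hz)
    regime = "SW" if osc["n_cycles"] >= 3 else "AW"
    return {
        "regime": regime,
        "oscillation": osc,
        "fixed_points": fps,
        "trajectory": traj,
    }


def tune_regime(model: MeanFieldModel, target: str, g_lo: float = 0.1,
                g_hi: float = 4.0, n_coarse: int = 12, seed: int = 0) -> tuple:
    """Scale the F-to-F efficacy until the module sits in the target regime.

    A lower foreground-to-foreground efficacy linearizes the rate nullcline
    around the fixed point and abolishes the oscillation (AW); raising it
    restores the S-shape and the noise-driven alternation (SW).  Returns
    ``(adjusted EfficacyMatrix, diagnostics)``; raises if no multiplier in
    the bracket reaches the target.
    """
    if target not in ("SW", "AW"):
        raise ValueError("target must be 'SW' or 'AW'")

    def regime_at(g: float) -> str:
        m = model.with_eff(model.eff.scaled({("F", "F"): g}))
        return classify_regime(m, seed=seed)["regime"]

    if regime_at(1.0) == target:
        return model.eff, {"multiplier": 1.0, "regime": target}

    # SW needs a stronger F-to-F coupling, AW a weaker one
    grid = np.geomspace(1.0, g_hi if target == "SW" else g_lo, n_coarse)
    hit = prev = None
    for g in grid[1:]:
        if regime_at(g) == target:
            hit = g
            break
        prev = g
    if hit is None:
        raise RuntimeError(f"no J_FF multiplier in [{g_lo}, {g_hi}] reaches {target}")
    lo = prev if prev is not None else 1.0  # last multiplier outside the target
    hi = hit
    for _ in range(8):
        mid = math.sqrt(lo * hi)
        if regime_at(mid) == target:
            hi = mid
        else:
            lo = mid
    # step 10% past the boundary into the target side for robustness
    g_star = hi * 1.1 if target == "SW" else hi / 1.1
    if regime_at(g_star) != target:
        g_star = hi
    eff = model.eff.scaled({("F", "F"): g_star})
    return eff, {"multiplier": g_star, "regime": target, "boundary": (lo, hi)}
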