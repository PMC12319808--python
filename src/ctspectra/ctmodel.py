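"""Corticothalamic neural-field model of EEG dynamics (global mode).

Four neural masses are modelled: cortical excitatory (e) and inhibitory (i)
populations, and the thalamic relay/specific (s) and reticular (r) nuclei.
Each population j carries a mean soma membrane potential ``V_j`` (mV), a mean
firing rate ``Q_j`` (1/s), and a presynaptic field ``phi_j`` (1/s).

The dynamics are

* synaptodendritic filtering:
  ``(1/(alpha*beta)) d2V_j/dt2 + (1/alpha + 1/beta) dV_j/dt + V_j
  = sum_k nu_jk phi_k(t - tau_jk)``
* sigmoidal rate conversion: ``Q_j = Qmax / (1 + exp(-pi (V_j - theta) /
  (sigma sqrt(3))))``
* damped-wave propagation for the cortical excitatory field only,
  in the spatially uniform (global) mode:
  ``(1/gamma^2) d2phi_e/dt2 + (2/gamma) dphi_e/dt + phi_e = Q_e``;
  the local populations propagate instantaneously, ``phi_j = Q_j``.

Corticothalamic (e->r, e->s) and thalamocortical (s->e, s->i) projections
carry a one-way axonal delay of ``t0/2`` so that the full loop takes the
corticothalamic return time ``t0``; connections within cortex and within
thalamus are delay-free.  The relay population is additionally driven by a
nonspecific input ``nu_sn * phi_n`` where ``phi_n`` is a constant mean plus
Gaussian white noise.

Integration is explicit Euler-Maruyama on the first-order companion form of
the second-order equations, with delays held in ring buffers.  At normative
resting-state parameters the model produces an alpha-band (8-12 Hz)
resonance riding on a 1/f-like aperiodic background.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import optimize

from .spectral import FitSettings, fit_spectral_model, multitaper_psd, select_alpha

__all__ = [
    "CTParams",
    "SimConfig",
    "SimResult",
    "SweepResult",
    "CTModelError",
    "DivergenceError",
    "SteadyStateError",
    "LinearInstabilityError",
    "firing_rate",
    "firing_rate_slope",
    "steady_state",
    "simulate",
    "linearized_spectrum",
    "alpha_mode_pole",
    "parameter_sweep",
    "spectral_features",
    "sweep_config",
    "DEFAULT_SWEEP_RANGES",
    "COUPLING_NAMES",
]

COUPLING_NAMES = ("nu_ee", "nu_ei", "nu_es", "nu_se", "nu_sr", "nu_sn",
                  "nu_re", "nu_rs")


class CTModelError(Exception):
    """Base error for the corticothalamic model."""


class DivergenceError(CTModelError):
    """The integrated trajectory left the guard bound (unstable regime)."""


class SteadyStateError(CTModelError):
    """Fixed-point search failed to converge."""


class LinearInstabilityError(CTModelError):
    """The linearized system is unstable about the fixed point."""


@dataclass(frozen=True)
class CTParams:
    """Parameters of the corticothalamic model.

    Defaults are the normative resting-state values.  Units: potentials in
    mV, rates in 1/s, couplings in mV*s, delays in s.  Couplings are signed:
    inhibitory connections (``nu_ei``, ``nu_sr``) are negative.
    """

    theta: float = 15.0        # mean firing threshold (mV)
    sigma: float = 6.0         # threshold spread (mV)
    q_max: float = 250.0       # maximum firing rate (1/s)
    gamma: float = 100.0       # cortical damping rate, v_e / r_e (1/s)
    alpha: float = 50.0        # inverse decay time of membrane potential (1/s)
    beta: float = 240.0        # inverse rise time of membrane potential (1/s)
    t0: float = 0.080          # corticothalamic return (loop) time (s)
    nu_ee: float = 1.06        # excitatory -> excitatory (mV*s)
    nu_ei: float = -1.8        # inhibitory -> excitatory (mV*s)
    nu_es: float = 2.20        # relay -> cortical excitatory (mV*s)
    nu_se: float = 2.28        # cortical excitatory -> relay (mV*s)
    nu_sr: float = -0.845      # reticular -> relay (mV*s)
    nu_sn: float = 1.20        # nonspecific noise -> relay (mV*s)
    nu_re: float = 0.91        # cortical excitatory -> reticular (mV*s)
    nu_rs: float = 0.41        # relay -> reticular (mV*s)

    def __post_init__(self) -> None:
        if not (self.q_max > 0 and self.sigma > 0 and self.gamma > 0
                and self.t0 > 0):
            raise ValueError("q_max, sigma, gamma and t0 must be positive")
        if not (self.beta > self.alpha > 0):
            raise ValueError("need beta > alpha > 0")

    def replace(self, **kwargs: float) -> "CTParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "CTParams":
        """Load parameters from a flat key-value YAML/JSON file.

        Keys match the field names; ``t0`` is in seconds.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: expected a flat key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown parameter(s) {sorted(unknown)}")
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass(frozen=True)
class SimConfig:
    """Integration settings for :func:`simulate`.

    ``noise_mean`` and ``noise_sd`` parameterize the nonspecific drive
    ``phi_n`` to the relay nucleus: a constant mean plus Gaussian white
    noise.  ``noise_sd`` is the amplitude of the continuous-time white
    noise (units 1/s per sqrt(Hz)); each Euler-Maruyama step draws
    ``noise_sd / sqrt(dt) * N(0, 1)``.
    """

    dt: float = 0.001          # integration step (s)
    duration: float = 60.0     # simulated span kept after the transient (s)
    transient: float = 5.0     # initial span discarded (s)
    noise_mean: float = 0.5    # constant relay drive (1/s)
    noise_sd: float = 0.1      # white-noise amplitude of phi_n
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (self.duration > 0 and self.transient >= 0):
            raise ValueError("need duration > 0 and transient >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def delay_steps(self, t0: float) -> int:
        """Number of integration steps in the one-way delay t0/2."""
        steps = t0 / 2.0 / self.dt
        n = int(round(steps))
        if n < 1 or abs(steps - n) > 1e-9:
            raise ValueError(
                f"one-way delay t0/2 = {t0 / 2} s is not a whole number of "
                f"steps at dt = {self.dt} s")
        return n

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimResult:
    """Output of one simulation run (post-transient samples only)."""

    time: np.ndarray           # sample times (s), starting after the transient
    v_e: np.ndarray            # cortical excitatory membrane potential (mV)
    phi_e: np.ndarray          # cortical excitatory presynaptic field (1/s)
    v_i: np.ndarray
    v_r: np.ndarray
    v_s: np.ndarray
    params_used: CTParams
    config_used: SimConfig

    @property
    def fs(self) -> float:
        return 1.0 / self.config_used.dt

    def trace(self, which: str = "phi_e") -> np.ndarray:
        """Return the trace used as the EEG proxy.

        ``phi_e`` is the cortical excitatory field (1/s), the standard
        scalp-EEG proxy of this model family whose spectrum carries the
        damped-wave high-frequency roll-off; ``v_e`` is the mean membrane
        potential of the excitatory population, returned on the EEG
        microvolt scale (the model's mV x 1000).
        """
        if which == "phi_e":
            return self.phi_e
        if which == "v_e":
            return self.v_e * 1e3  # mV -> uV, the empirical EEG scale
        raise ValueError("which must be 'phi_e' or 'v_e'")

    def to_csv(self, path: str | Path) -> None:
        arr = np.column_stack([self.time, self.v_e, self.phi_e,
                               self.v_i, self.v_r, self.v_s])
        header = "time,v_e,phi_e,v_i,v_r,v_s"
        np.savetxt(path, arr, delimiter=",", header=header, comments="")
        sidecar = Path(path).with_suffix(".json")
        with open(sidecar, "w") as fh:
            json.dump({"params": self.params_used.to_dict(),
                       "config": self.config_used.to_dict()}, fh, indent=2)


def firing_rate(v: np.ndarray | float, params: CTParams) -> np.ndarray | float:
    """Sigmoidal potential-to-rate conversion.

    ``Q(v) = q_max / (1 + exp(-pi (v - theta) / (sigma sqrt(3))))``.
    The pi/sqrt(3) factor matches the logistic slope to a Gaussian spread of
    thresholds with standard deviation ``sigma``.  Strictly increasing and
    bounded in (0, q_max).
    """
    z = -np.pi * (np.asarray(v, dtype=float) - params.theta) / (
        params.sigma * np.sqrt(3.0))
    out = params.q_max / (1.0 + np.exp(np.clip(z, -700, 700)))
    return float(out) if np.isscalar(v) else out


def firing_rate_slope(v: np.ndarray | float, params: CTParams):
    """Derivative dQ/dV of the sigmoid, the linearization gain (1/(s*mV))."""
    q = firing_rate(v, params)
    return np.pi / (params.sigma * np.sqrt(3.0)) * q * (1.0 - q / params.q_max)


def _steady_residual(v: np.ndarray, params: CTParams, drive: float) -> np.ndarray:
    """Residual of the zero-derivative equations at V = (V_e, V_i, V_r, V_s).

    At steady state the dendritic and wave operators have unit gain, so
    phi_j = Q_j for all populations and the delays drop out.
    """
    v_e, v_i, v_r, v_s = v
    q_e = firing_rate(v_e, params)
    q_i = firing_rate(v_i, params)
    q_r = firing_rate(v_r, params)
    q_s = firing_rate(v_s, params)
    p = params
    return np.array([
        p.nu_ee * q_e + p.nu_ei * q_i + p.nu_es * q_s - v_e,
        p.nu_ee * q_e + p.nu_ei * q_i + p.nu_es * q_s - v_i,
        p.nu_re * q_e + p.nu_rs * q_s - v_r,
        p.nu_se * q_e + p.nu_sr * q_r + p.nu_sn * drive - v_s,
    ])


def steady_state(params: CTParams, drive: float = 1.0,
                 tol: float = 1e-10) -> np.ndarray:
    """Fixed point (V_e, V_i, V_r, V_s) of the model under constant drive.

    Seeds the root search from a handful of starting potentials spanning the
    low-firing branch and returns the root with the lowest cortical
    potential (the physiological resting branch when several roots exist).

    Raises
    ------
    SteadyStateError
        If no root with residual norm below ``tol`` is found.
    """
    roots = []
    for v0 in (-20.0, -5.0, 0.0, 5.0, 10.0):
        sol = optimize.root(_steady_residual, np.full(4, v0),
                            args=(params, drive), method="hybr")
        res = np.linalg.norm(_steady_residual(sol.x, params, drive))
        if res < tol:
            roots.append(sol.x)
    if not roots:
        raise SteadyStateError(
            f"no fixed point found for drive={drive} (params={params})")
    roots.sort(key=lambda r: r[0])
    return roots[0]


# ---------------------------------------------------------------------------
# Euler-Maruyama integration core.  Kept as a standalone function of plain
# arrays so numba can compile it; the wrapper handles setup and errors.
# ---------------------------------------------------------------------------

def _integrate_py(n_total, dt, delay, theta, sig3, q_max, gamma, alpha, beta,
                  nu, v0, noise, guard):
    """Pure-python/numpy reference integrator (see _integrate for layout)."""
    return _integrate_impl(n_total, dt, delay, theta, sig3, q_max, gamma,
                           alpha, beta, nu, v0, noise, guard)


def _integrate_impl(n_total, dt, delay, theta, sig3, q_max, gamma, alpha,
                    beta, nu, v0, noise, guard):
    nu_ee, nu_ei, nu_es, nu_se, nu_sr, nu_sn, nu_re, nu_rs = (
        nu[0], nu[1], nu[2], nu[3], nu[4], nu[5], nu[6], nu[7])
    ab = alpha * beta
    invab = 1.0 / alpha + 1.0 / beta
    g2 = gamma * gamma

    out = np.empty((5, n_total))
    v_e, v_i, v_r, v_s = v0[0], v0[1], v0[2], v0[3]
    dv_e = dv_i = dv_r = dv_s = 0.0
    # sigmoid of the initial state
    q_e = q_max / (1.0 + np.exp(-np.pi * (v_e - theta) / sig3))
    phi_e = q_e
    dphi_e = 0.0

    # ring buffers of the delayed fields, pre-filled with steady values
    q_s0 = q_max / (1.0 + np.exp(-np.pi * (v_s - theta) / sig3))
    buf_e = np.full(delay, phi_e)   # phi_e history for e->r, e->s
    buf_s = np.full(delay, q_s0)    # phi_s history for s->e, s->i
    head = 0

    for k in range(n_total):
        q_e = q_max / (1.0 + np.exp(-np.pi * (v_e - theta) / sig3))
        q_i = q_max / (1.0 + np.exp(-np.pi * (v_i - theta) / sig3))
        q_r = q_max / (1.0 + np.exp(-np.pi * (v_r - theta) / sig3))
        q_s = q_max / (1.0 + np.exp(-np.pi * (v_s - theta) / sig3))

        phi_e_d = buf_e[head]
        phi_s_d = buf_s[head]
        buf_e[head] = phi_e
        buf_s[head] = q_s
        head += 1
        if head == delay:
            head = 0

        i_cortex = nu_ee * phi_e + nu_ei * q_i + nu_es * phi_s_d
        i_r = nu_re * phi_e_d + nu_rs * q_s
        i_s = nu_se * phi_e_d + nu_sr * q_r + nu_sn * noise[k]

        a_e = ab * (i_cortex - v_e - invab * dv_e)
        a_i = ab * (i_cortex - v_i - invab * dv_i)
        a_r = ab * (i_r - v_r - invab * dv_r)
        a_s = ab * (i_s - v_s - invab * dv_s)
        a_phi = g2 * (q_e - phi_e - (2.0 / gamma) * dphi_e)

        v_e += dt * dv_e
        dv_e += dt * a_e
        v_i += dt * dv_i
        dv_i += dt * a_i
        v_r += dt * dv_r
        dv_r += dt * a_r
        v_s += dt * dv_s
        dv_s += dt * a_s
        phi_e += dt * dphi_e
        dphi_e += dt * a_phi

        out[0, k] = v_e
        out[1, k] = phi_e
        out[2, k] = v_i
        out[3, k] = v_r
        out[4, k] = v_s

        if (abs(v_e) > guard or abs(v_s) > guard or abs(v_r) > guard
                or abs(phi_e) > 1e8):
            return out, k
    return out, -1


try:  # numba gives a ~100x speedup on the step loop; fall back gracefully
    from numba import njit

    _integrate = njit(cache=True)(_integrate_impl)
except ImportError:  # pragma: no cover
    _integrate = _integrate_impl


def simulate(params: CTParams, config: SimConfig,
             guard: float = 1e4) -> SimResult:
    """Integrate the model and return the post-transient traces.

    The state is initialized at the fixed point for the mean drive, so with
    ``noise_sd = 0`` the output stays at the fixed point.  Identical
    (params, config) including seed give bitwise-identical traces.

    Raises
    ------
    DivergenceError
        If any potential exceeds ``guard`` (mV) during integration.
    """
    delay = config.delay_steps(params.t0)
    n_trans = int(round(config.transient / config.dt))
    n_keep = int(round((config.duration) / config.dt))
    n_total = n_trans + n_keep

    v0 = steady_state(params, drive=config.noise_mean)
    rng = np.random.default_rng(config.seed)
    noise = config.noise_mean + (
        config.noise_sd / np.sqrt(config.dt)) * rng.standard_normal(n_total)

    out, k_bad = _integrate(
        n_total, config.dt, delay, params.theta,
        params.sigma * np.sqrt(3.0), params.q_max, params.gamma,
        params.alpha, params.beta,
        np.array([params.nu_ee, params.nu_ei, params.nu_es, params.nu_se,
                  params.nu_sr, params.nu_sn, params.nu_re, params.nu_rs]),
        v0, noise, guard)
    if k_bad >= 0:
        raise DivergenceError(
            f"trajectory exceeded guard bound at t = {k_bad * config.dt:.3f} s")

    t = (np.arange(n_keep) + n_trans + 1) * config.dt
    return SimResult(
        time=t,
        v_e=out[0, n_trans:], phi_e=out[1, n_trans:], v_i=out[2, n_trans:],
        v_r=out[3, n_trans:], v_s=out[4, n_trans:],
        params_used=params, config_used=config)


def alpha_mode_pole(params: CTParams, drive: float = 0.5,
                    f_guess: float = 9.5) -> complex:
    """Dominant alpha-band pole of the linearized delay system.

    Solves the transcendental characteristic equation ``det A(s) = 0`` of
    the model linearized at the fixed point for the root nearest the alpha
    resonance.  ``Re(s) < 0`` means the fixed point is a damped (stable)
    resonator; ``Re(s) > 0`` means a self-sustained alpha oscillation.
    """
    vstar = steady_state(params, drive)
    rho = firing_rate_slope(vstar, params)

    def chareq(xy):
        d = np.linalg.det(_linear_system(
            params, rho, complex(xy[0], xy[1])))
        return [d.real, d.imag]

    sol = optimize.fsolve(chareq, [0.0, 2.0 * np.pi * f_guess],
                          full_output=True)
    x, _, ier, msg = sol
    if ier != 1:
        raise LinearInstabilityError(f"pole search failed: {msg}")
    return complex(x[0], x[1])


def _linear_system(params: CTParams, rho: np.ndarray, s: complex) -> np.ndarray:
    """Closed-loop matrix A(s) such that A x = b maps relay input to the
    potential perturbations x = (V_e, V_i, V_r, V_s)."""
    p = params
    L = 1.0 / ((1.0 + s / p.alpha) * (1.0 + s / p.beta))
    W = 1.0 / (1.0 + s / p.gamma) ** 2
    D = np.exp(-s * p.t0 / 2.0)
    ge = rho[0] * W
    gi, gr, gs = rho[1], rho[2], rho[3]
    A = np.eye(4, dtype=complex)
    A[0, 0] -= L * p.nu_ee * ge
    A[0, 1] -= L * p.nu_ei * gi
    A[0, 3] -= L * p.nu_es * gs * D
    A[1, 0] -= L * p.nu_ee * ge
    A[1, 1] -= L * p.nu_ei * gi
    A[1, 3] -= L * p.nu_es * gs * D
    A[2, 0] -= L * p.nu_re * ge * D
    A[2, 3] -= L * p.nu_rs * gs
    A[3, 0] -= L * p.nu_se * ge * D
    A[3, 2] -= L * p.nu_sr * gr
    return A


def linearized_spectrum(params: CTParams, freqs: np.ndarray,
                        noise_mean: float = 0.5,
                        noise_sd: float = 0.1) -> np.ndarray:
    """Analytic one-sided PSD of phi_e from the model linearized at its
    fixed point.

    For small perturbations about the fixed point the sigmoid acts as a
    gain ``rho_j = dQ/dV`` and each block becomes a transfer function:
    dendritic low-pass ``L(w) = 1 / ((1 + iw/alpha)(1 + iw/beta))``, the
    damped-wave operator ``phi_e = Q_e / (1 + iw/gamma)^2`` and delay
    factors ``exp(-i w t0/2)`` on the corticothalamic projections.  The
    4x4 linear system is solved per frequency for unit relay input and the
    squared magnitude is scaled by the one-sided white-noise density
    ``2 * noise_sd**2``.

    Raises
    ------
    LinearInstabilityError
        If the closed-loop response is non-finite on the grid.
    """
    freqs = np.asarray(freqs, dtype=float)
    vstar = steady_state(params, drive=noise_mean)
    rho = firing_rate_slope(vstar, params)  # gains at the fixed point
    p = params

    psd = np.empty_like(freqs)
    for n, f in enumerate(freqs):
        s = 2j * np.pi * f
        A = _linear_system(p, rho, s)
        L = 1.0 / ((1.0 + s / p.alpha) * (1.0 + s / p.beta))
        W = 1.0 / (1.0 + s / p.gamma) ** 2
        b = np.array([0, 0, 0, L * p.nu_sn], dtype=complex)  # unit phi_n
        x = np.linalg.solve(A, b)
        psd[n] = abs(rho[0] * W * x[0]) ** 2
    psd *= 2.0 * noise_sd ** 2  # one-sided white-noise input density
    if not np.all(np.isfinite(psd)):
        raise LinearInstabilityError("non-finite linearized response")
    return psd


# Default sweep ranges: from the normative value toward the configurations
# the coupling-sweep analysis emphasises (stronger reticular->relay
# inhibition; weaker cortex->relay excitation; stronger cortex->reticular
# excitation), i.e. increasing net inhibition of the thalamic relay.
DEFAULT_SWEEP_RANGES = {
    "nu_sr": (-0.845, -1.13),
    "nu_es": (2.20, 1.60),
    "nu_re": (0.91, 1.20),
}


def sweep_config(seed: int = 0) -> SimConfig:
    """Integration settings used for coupling sweeps.

    Sweeps quantify how the spectrum's shape responds to a coupling, which
    requires the near-resonance response to be integrated accurately: the
    step is reduced to 0.25 ms (explicit Euler adds an artificial
    antidamping of about (2 pi f)^2 dt / 2 to an oscillatory mode, which at
    1 ms exceeds the alpha mode's own damping) and the noise is kept small
    so the response stays in the near-linear regime.
    """
    return SimConfig(dt=0.00025, noise_mean=0.5, noise_sd=0.02, seed=seed)


@dataclass
class SweepResult:
    """Spectral features of simulations sweeping one synaptic coupling."""

    which: str
    values: np.ndarray
    offset: np.ndarray
    exponent: np.ndarray
    alpha_power: np.ndarray      # log10 height of the alpha peak, NaN if none
    alpha_cf: np.ndarray         # alpha center frequency (Hz), NaN if none
    diverged: np.ndarray         # bool flags; features are NaN where True
    params_base: CTParams = field(repr=False, default=None)
    config: SimConfig = field(repr=False, default=None)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "param_value": self.values, "offset": self.offset,
            "exponent": self.exponent, "alpha_power": self.alpha_power,
            "alpha_cf": self.alpha_cf, "diverged": self.diverged})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)
        sidecar = Path(path).with_suffix(".json")
        payload = {"which": self.which,
                   "params_base": self.params_base.to_dict()
                   if self.params_base else None,
                   "config": self.config.to_dict() if self.config else None}
        with open(sidecar, "w") as fh:
            json.dump(payload, fh, indent=2)


def spectral_features(result: SimResult,
                      settings: FitSettings | None = None,
                      trace: str = "phi_e",
                      half_bandwidth: float = 0.6,
                      n_tapers: int | None = None) -> tuple:
    """Multitaper PSD + spectral parameterization of one simulation.

    ``n_tapers`` defaults to the 60-s convention (45 tapers) when the
    epoch permits it, otherwise to the 2TW-1 bound.  Returns
    ``(fit, alpha_peak)`` where ``alpha_peak`` may be None.
    """
    settings = settings or FitSettings()
    if n_tapers is None:
        tw = result.config_used.duration * half_bandwidth
        n_tapers = min(45, int(np.floor(2 * tw - 1)))
    spec = multitaper_psd(result.trace(trace), fs=result.fs,
                          half_bandwidth=half_bandwidth, n_tapers=n_tapers)
    fit = fit_spectral_model(spec, settings)
    return fit, select_alpha(fit)


def parameter_sweep(params: CTParams, which: str,
                    values: Sequence[float], config: SimConfig,
                    settings: FitSettings | None = None,
                    trace: str = "v_e") -> SweepResult:
    """Sweep one coupling, simulating and extracting spectral features.

    Every run uses the same seed and integration settings so feature changes
    reflect the coupling alone.  Diverged runs are flagged, with features
    recorded as NaN.

    Features default to the membrane-potential trace (``v_e``, in uV):
    sweeps ask how the spectrum responds to a coupling, and all three
    features (exponent, offset, alpha height) move monotonically with the
    net relay inhibition on that trace, whereas the broadband offset of
    the field spectrum barely moves (the wave operator's roll-off
    dominates its shape); see the methods note.
    """
    if which not in COUPLING_NAMES:
        raise ValueError(f"unknown coupling {which!r}; one of {COUPLING_NAMES}")
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("values list is empty")
    settings = settings or FitSettings()

    n = values.size
    offset = np.full(n, np.nan)
    exponent = np.full(n, np.nan)
    a_pow = np.full(n, np.nan)
    a_cf = np.full(n, np.nan)
    diverged = np.zeros(n, dtype=bool)
    for k, val in enumerate(values):
        p = params.replace(**{which: float(val)})
        try:
            res = simulate(p, config)
            fit, alpha = spectral_features(res, settings, trace=trace)
        except (DivergenceError, SteadyStateError):
            diverged[k] = True
            continue
        offset[k] = fit.aperiodic.offset
        exponent[k] = fit.aperiodic.exponent
        if alpha is not None:
            a_pow[k] = alpha.power
            a_cf[k] = alpha.center
    return SweepResult(which=which, values=values, offset=offset,
                       exponent=exponent, alpha_power=a_pow, alpha_cf=a_cf,
                       diverged=diverged, params_base=params, config=config)
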