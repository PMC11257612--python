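"""Domain types and forward models for chemotactic sensing.

The behaviorally-relevant signal for a bacterium climbing a static exponential
gradient is the rate of change of log-concentration along its path,
``s(t) = g * vx(t)``, where ``g = d(log c)/dx`` is the gradient steepness and
``vx`` the up-gradient velocity.  In shallow gradients ``s`` is well
approximated as a Gaussian process with autocovariance
``g^2 * sigma_v^2 * exp(-|dt|/tau_v)``.

Ligand molecules arrive at the receptor array as a Poisson process with rate
``r(t) = k_D * c(t)`` where ``k_D = 4*D*l`` for a circular absorbing sensor of
radius ``l``.  When many molecules arrive per correlation time the Poisson
process is well approximated by a Gaussian rate
``r(t) = k_D*c(t) + sqrt(r0)*xi(t)`` with unit-intensity white noise ``xi``.

CheA kinase activity responds linearly to deviations of the arrival rate from
baseline through an adaptive (zero-integral) response kernel and carries slow
internal Ornstein-Uhlenbeck noise.

Units: seconds, micrometers, micromolar throughout.  Gradient steepness is
stored in um^-1; command-line interfaces accept mm^-1 and convert (x 1e-3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "MOLECULES_PER_UM3_PER_UM",
    "RUN",
    "TUMBLE",
    "SwimmingPhenotype",
    "Environment",
    "KinasePhenotype",
    "TimeSeries",
    "Track",
    "signal_autocovariance",
    "capture_rate_constant",
    "sample_arrivals",
    "response_kernel",
    "kernel_step_response",
    "mwc_gain",
    "simulate_kinase",
]

#: number density of a 1 uM solution, in molecules per cubic micrometer
MOLECULES_PER_UM3_PER_UM = 602.214

#: run/tumble state labels used in Track.state arrays
RUN = 1
TUMBLE = 0


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass
class SwimmingPhenotype:
    """Run-tumble motility parameters of a single cell (or population median).

    sigma_v2 : variance of the up-gradient velocity component, (um/s)^2
    tau_v    : velocity (signal) correlation time, s
    speed    : swimming speed during runs, um/s
    p_run    : fraction of time spent in the run state
    mean_run : mean run duration, s
    mean_tumble : mean tumble duration, s
    persistence : mean cosine of the tumble reorientation angle
    d_rot    : rotational diffusivity during runs, rad^2/s
    """

    sigma_v2: float
    tau_v: float
    speed: float = 20.0
    p_run: float = 0.85
    mean_run: float = 0.86
    mean_tumble: float = 0.15
    persistence: float = 0.33
    d_rot: float = 0.062

    def __post_init__(self) -> None:
        _require(np.isfinite(self.sigma_v2) and self.sigma_v2 > 0, "sigma_v2 must be > 0")
        _require(np.isfinite(self.tau_v) and self.tau_v > 0, "tau_v must be > 0")
        _require(0.0 <= self.p_run <= 1.0, "p_run must lie in [0, 1]")
        _require(self.mean_run > 0, "mean_run must be > 0")
        _require(self.mean_tumble > 0, "mean_tumble must be > 0")
        _require(-1.0 <= self.persistence <= 1.0, "persistence must lie in [-1, 1]")
        _require(self.d_rot >= 0, "d_rot must be >= 0")


@dataclass
class Environment:
    """Chemical environment: background concentration, gradient, capture rate.

    c0   : background ligand concentration, uM
    g    : gradient steepness d(log c)/dx, um^-1 (0 for uniform background)
    k_D  : capture-rate constant, s^-1 uM^-1 (arrival rate per unit concentration)
    D_ligand : ligand diffusivity, um^2/s
    l_sensor : sensor (receptor-array) radius, um
    """

    c0: float
    g: float = 0.0
    k_D: Optional[float] = None
    D_ligand: float = 800.0
    l_sensor: float = 0.06

    def __post_init__(self) -> None:
        _require(self.c0 >= 0, "c0 must be >= 0")
        _require(self.D_ligand > 0, "D_ligand must be > 0")
        _require(self.l_sensor >= 0, "l_sensor must be >= 0")
        if self.k_D is None:
            self.k_D = capture_rate_constant(self.D_ligand, self.l_sensor)
        _require(self.k_D > 0, "k_D must be > 0")

    @property
    def r0(self) -> float:
        """Background molecule arrival rate k_D * c0, in s^-1."""
        return self.k_D * self.c0

    @classmethod
    def from_g_mm(cls, c0: float, g_mm: float, **kwargs) -> "Environment":
        """Construct with gradient steepness given in mm^-1 (converted x1e-3)."""
        return cls(c0=c0, g=g_mm * 1e-3, **kwargs)


@dataclass
class KinasePhenotype:
    """Kinase response and noise parameters of a single cell.

    G_r   : gain of response to arrival-rate deviations, s
    tau_1 : fast response time, s (0 collapses the fast lobe to an impulse)
    tau_2 : slow adaptation time, s
    D_n   : internal-noise diffusivity, s^-1
    tau_n : internal-noise correlation time, s
    a0    : steady-state kinase activity
    G_inf, K_i : optional MWC gain parameters (G(c0) = G_inf*c0/(c0+K_i))
    """

    G_r: float
    tau_2: float
    D_n: float
    tau_n: float
    tau_1: float = 0.0
    a0: float = 0.3
    G_inf: Optional[float] = None
    K_i: Optional[float] = None

    def __post_init__(self) -> None:
        _require(self.tau_1 >= 0, "tau_1 must be >= 0")
        _require(self.tau_2 > self.tau_1, "tau_2 must exceed tau_1")
        _require(self.D_n >= 0, "D_n must be >= 0")
        _require(self.tau_n > 0, "tau_n must be > 0")

    @property
    def noise_variance(self) -> float:
        """Stationary variance of the internal OU noise, D_n * tau_n."""
        return self.D_n * self.tau_n

    def gain_times_kD(self, env: Environment) -> float:
        """G_r expressed in 1/k_D units (the form quoted from experiments)."""
        return self.G_r * env.k_D


@dataclass
class TimeSeries:
    """Uniformly sampled time series (activity, concentration, arrival rate...)."""

    t: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        _require(self.t.ndim == 1 and self.t.size >= 2, "need at least 2 samples")
        _require(self.values.shape == self.t.shape, "t and values must align")
        diffs = np.diff(self.t)
        _require(np.all(diffs > 0), "times must be strictly increasing")
        dt = diffs[0]
        _require(
            bool(np.all(np.abs(diffs - dt) <= 1e-9 * max(1.0, abs(dt)))),
            "sampling must be uniform within 1e-9",
        )

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @classmethod
    def constant(cls, value: float, duration: float, dt: float, **meta) -> "TimeSeries":
        n = int(round(duration / dt)) + 1
        t = np.arange(n) * dt
        return cls(t=t, values=np.full(n, float(value)), meta=meta)


@dataclass
class Track:
    """A 2D swimming trajectory with optional run/tumble labels."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    state: Optional[np.ndarray] = None  # RUN/TUMBLE per sample
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        _require(self.t.size == self.x.size == self.y.size, "t, x, y must align")
        _require(bool(np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))),
                 "positions must be finite")
        if self.state is not None:
            self.state = np.asarray(self.state)
            _require(self.state.size == self.t.size, "state must align with t")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def vx(self) -> np.ndarray:
        """Up-gradient velocity from forward differences (length n-1)."""
        return np.diff(self.x) / np.diff(self.t)


# ---------------------------------------------------------------------------
# forward models
# ---------------------------------------------------------------------------

def signal_autocovariance(swim: SwimmingPhenotype, g: float, lag) -> np.ndarray:
    """Autocovariance of the signal s = g*vx at time lag ``lag`` (s^-2).

    ``g^2 * sigma_v^2 * exp(-|lag|/tau_v)``; even in the lag; the value at
    lag 0 is the signal variance sigma_s^2.
    """
    lag = np.asarray(lag, dtype=float)
    if not np.all(np.isfinite(lag)):
        raise ValueError("lag must be finite")
    if g < 0:
        raise ValueError("g must be >= 0")
    out = g**2 * swim.sigma_v2 * np.exp(-np.abs(lag) / swim.tau_v)
    return out if out.ndim else float(out)


def capture_rate_constant(D_ligand: float, l_sensor: float) -> float:
    """Capture-rate constant k_D = 4*D*l for an absorbing disk, in s^-1 uM^-1.

    The geometric rate 4*D*l (um^3/s) is converted to arrivals per second per
    micromolar with the number density of a 1 uM solution,
    602.214 molecules/um^3.
    """
    if D_ligand <= 0:
        raise ValueError("D_ligand must be > 0")
    if l_sensor < 0:
        raise ValueError("l_sensor must be >= 0")
    return 4.0 * D_ligand * l_sensor * MOLECULES_PER_UM3_PER_UM


def sample_arrivals(
    c_trace: TimeSeries,
    env: Environment,
    mode: str = "gaussian_rate",
    seed: int = 0,
) -> TimeSeries:
    """Sample molecule arrivals along a concentration trace.

    Returns a TimeSeries of *arrival-rate estimates per bin* (counts/dt for
    ``poisson_events``; the Gaussian rate ``k_D*c + sqrt(r0/dt)*z`` for
    ``gaussian_rate``).  Multiply by ``dt`` to recover counts per bin.
    """
    if np.any(c_trace.values < 0):
        raise ValueError("concentrations must be >= 0")
    if mode not in ("poisson_events", "gaussian_rate"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    dt = c_trace.dt
    lam = env.k_D * c_trace.values  # instantaneous rate
    if mode == "poisson_events":
        counts = rng.poisson(lam * dt)
        rates = counts / dt
    else:
        if env.r0 * dt < 10:
            warnings.warn(
                "gaussian_rate mode with r0*dt < 10: Gaussian approximation "
                "of Poisson arrivals may be poor",
                stacklevel=2,
            )
        rates = lam + np.sqrt(env.r0 / dt) * rng.standard_normal(lam.shape)
    meta = dict(c_trace.meta)
    meta.update(mode=mode, seed=seed, r0=env.r0)
    return TimeSeries(t=c_trace.t.copy(), values=rates, meta=meta)


def response_kernel(kin: KinasePhenotype, t) -> np.ndarray:
    """Kinase response kernel to arrival-rate deviations, K_r(t).

    ``K_r(t) = G_r*[(1/tau_1) e^{-t/tau_1} - (1/tau_2) e^{-t/tau_2}] * Theta(t)``.
    Each lobe integrates to G_r so the kernel has zero integral (perfect
    adaptation).  For ``tau_1 = 0`` the fast lobe is a Dirac impulse of weight
    G_r; this function then returns only the smooth part
    ``-(G_r/tau_2) e^{-t/tau_2}`` and the impulse weight is ``kin.G_r``.

    The equivalent kernel acting on the signal s (rather than on arrival-rate
    deviations) is related by ``K_r(t) = (1/r0) dK/dt``.
    """
    if kin.tau_2 <= kin.tau_1:
        raise ValueError("tau_2 must exceed tau_1")
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t >= 0
    slow = (kin.G_r / kin.tau_2) * np.exp(-t[pos] / kin.tau_2)
    if kin.tau_1 > 0:
        fast = (kin.G_r / kin.tau_1) * np.exp(-t[pos] / kin.tau_1)
        out[pos] = fast - slow
    else:
        out[pos] = -slow
    return out if out.ndim else float(out)


def kernel_step_response(kin: KinasePhenotype, t, delta_r: float) -> np.ndarray:
    """Analytic activity deviation following a step ``delta_r`` in arrival rate.

    ``a(t) - a0 = -delta_r * G_r * (e^{-t/tau_2} - e^{-t/tau_1})`` for t >= 0
    (with the tau_1 term absent when tau_1 = 0): a fast drop of magnitude
    ``G_r*delta_r`` followed by adaptation back to baseline.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t >= 0
    resp = np.exp(-t[pos] / kin.tau_2)
    if kin.tau_1 > 0:
        resp = resp - np.exp(-t[pos] / kin.tau_1)
    out[pos] = -delta_r * kin.G_r * resp
    return out if out.ndim else float(out)


def mwc_gain(c0: float, G_inf: float, K_i: float, with_rate_gain: bool = True):
    """MWC receptor-complex gain.

    Returns ``(G, G_r_kD)`` where ``G(c0) = G_inf*c0/(c0+K_i)`` is the
    dimensionless gain and ``G_r_kD = G/c0 = G_inf/(c0+K_i)`` is the
    arrival-rate gain in 1/k_D units (G_r = G/(k_D*c0)).  In the
    linear-sensing regime (c0 << K_i) G_r*k_D -> G_inf/K_i is constant;
    in the log-sensing regime (c0 >> K_i) it falls off as 1/c0.
    """
    if c0 < 0:
        raise ValueError("c0 must be >= 0")
    G = G_inf * c0 / (c0 + K_i)
    if not with_rate_gain:
        return G
    if c0 == 0:
        raise ValueError("G_r undefined at c0 = 0 (division by zero)")
    return G, G_inf / (c0 + K_i)


def _exact_ou_step(dt: float, tau: float, D: float):
    """Decay factor and increment s.d. for an exact OU update over dt."""
    phi = np.exp(-dt / tau)
    sd = np.sqrt(D * tau * (1.0 - phi**2))
    return phi, sd


def simulate_kinase(
    c_trace: TimeSeries,
    kin: KinasePhenotype,
    env: Environment,
    include_arrival_noise: bool = True,
    include_internal_noise: bool = True,
    seed: int = 0,
    arrival_mode: str = "gaussian_rate",
) -> TimeSeries:
    """Simulate kinase activity along a concentration trace.

    ``a(t) = a0 - int K_r(t-t') (r(t')-r0) dt' + eta_n(t)`` with the adaptive
    kernel of :func:`response_kernel` and internal OU noise of stationary
    variance ``D_n*tau_n`` and correlation time ``tau_n``.  The convolution is
    computed through auxiliary low-pass states updated with exact exponential
    steps (dt-robust), and the OU noise uses the exact discrete update.
    Activity is not clipped to [0, 1] (linear small-signal model); the policy
    is recorded in the output metadata.
    """
    if np.any(c_trace.values < 0):
        raise ValueError("concentrations must be >= 0")
    dt = c_trace.dt
    if dt > kin.tau_2 / 20.0:
        raise ValueError("dt must be <= tau_2/20 for adequate discretization")
    if c_trace.duration < 5.0 * kin.tau_2:
        warnings.warn("trace shorter than 5*tau_2: transients may not settle",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    n = c_trace.values.size
    r0 = env.r0

    if include_arrival_noise:
        r = sample_arrivals(
            c_trace, env, mode=arrival_mode,
            seed=int(rng.integers(0, 2**31 - 1)),
        ).values
    else:
        r = env.k_D * c_trace.values
    dr = r - r0

    # adaptive kernel via low-pass states with exact exponential relaxation
    # per bin.  The input is right-continuous and held *forward* from each
    # sample edge, so y[k] = phi*y[k-1] + (1-phi)*sig[k-1]: a step applied at
    # a sample time starts driving the low-pass states in the following bin,
    # and the sampled response to a piecewise-constant input matches the
    # continuous-time kernel convolution exactly at the sample times.
    def _lowpass_held(sig: np.ndarray, phi: float, x0: float) -> np.ndarray:
        from scipy.signal import lfilter

        zi = np.array([x0])  # start adapted: y[0] = x0 (= sig[-1] level)
        out, _ = lfilter([0.0, 1.0 - phi], [1.0, -phi], sig, zi=zi)
        return out

    phi2 = np.exp(-dt / kin.tau_2)
    m = _lowpass_held(dr, phi2, dr[0])  # start adapted to the initial level
    if kin.tau_1 > 0:
        fast = _lowpass_held(dr, np.exp(-dt / kin.tau_1), dr[0])
    else:
        fast = dr
    response = -kin.G_r * (fast - m)

    if include_internal_noise and kin.D_n > 0:
        from scipy.signal import lfilter

        phin, sdn = _exact_ou_step(dt, kin.tau_n, kin.D_n)
        incr = sdn * rng.standard_normal(n)
        incr[0] = np.sqrt(kin.D_n * kin.tau_n) * rng.standard_normal()
        eta, _ = lfilter([1.0], [1.0, -phin], incr, zi=np.array([0.0]))
    else:
        eta = np.zeros(n)

    a = kin.a0 + response + eta
    meta = dict(c_trace.meta)
    meta.update(
        seed=seed,
        clipped=False,
        arrival_noise=include_arrival_noise,
        internal_noise=include_internal_noise,
        arrival_mode=arrival_mode if include_arrival_noise else "deterministic",
    )
    return TimeSeries(t=c_trace.t.copy(), values=a, meta=meta)
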