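"""Causal-filtering information rates for chemotactic sensing.

How accurately can the behaviorally-relevant signal ``s(t) = g*vx(t)`` be
estimated, causally, from the observations available to (i) an ideal sensor
that sees every molecule arrival, and (ii) an *E. coli* cell that only sees
its own kinase activity?  For jointly Gaussian signal and observations the
transfer-entropy rate from signal to observations equals a predictive-
information decay rate and depends only on the steady-state posterior
variance of ``s`` given past observations:

    I(tau) = -1/2 * ln(1 - rho^2 * exp(-2*tau/tau_v)),
    Idot   = -dI/dtau |_{tau=0} = (1/tau_v) * rho^2 / (1 - rho^2)   [nats/s]

where ``rho^2 = 1 - sigma_{s|.}^2 / sigma_s^2`` is the squared correlation
between the signal and its optimal causal estimate.

Both estimation problems are linear-Gaussian with rational spectra, so the
posterior variance is computed two independent ways:

* ``riccati`` (primary): steady-state Kalman-Bucy filter via the algebraic
  Riccati equation, with correlated process/observation noise for the kinase
  channel (molecule-arrival noise both drives the adaptation state and
  appears in the measured activity).
* ``spectral`` (oracle): causal Wiener filtering by Wiener-Hopf spectral
  factorization of the rational observation spectrum, done on polynomial
  coefficients.

Dimensionless signal-to-noise ratios:

    gamma_r = 2 * r0 * g^2 * sigma_v^2 * tau_v^3        (molecule arrivals)
    gamma_a = (G_r^2 / D_n) * r0^2 * g^2 * sigma_v^2 * tau_v   (kinase)

In the small-signal regime the physical limit reduces to
``Idot_r ~ gamma_r / (4 tau_v)``; an ideal noiseless sensor (D_n -> 0,
gamma_a -> infinity) recovers the physical limit, and in the internal-noise-
dominated regime Idot_a ~ gamma_a / (4 tau_v).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.linalg import expm, solve_continuous_are

from .models import Environment, KinasePhenotype, SwimmingPhenotype

__all__ = [
    "BERG_PURCELL_THRESHOLD",
    "SHALLOW_G",
    "FilterSolution",
    "SNRPair",
    "gamma_r",
    "gamma_a",
    "snr_pair",
    "solve_physical_limit_filter",
    "solve_kinase_filter",
    "info_rate_from_rho",
    "efficiency_eta",
    "noise_psd_components",
    "berg_purcell_check",
    "population_eta_percentiles",
]

#: Berg-Purcell single-run threshold condition, gamma_r > 16/3
BERG_PURCELL_THRESHOLD = 16.0 / 3.0

#: default gradient steepness (um^-1) used to evaluate the g -> 0+ limit;
#: equals 1e-3 mm^-1, deep in the regime where both rates scale as g^2
SHALLOW_G = 1e-6


@dataclass
class StateSpace:
    """Linear stochastic system dX = A X dt + B dw, y = C X + D dw.

    ``w`` is a vector of independent unit-intensity white noises shared by
    state and observation (correlated process/observation noise when B and D
    have a common nonzero column).  ``signal_var`` is the prior variance of
    the signal component X[0].
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray
    signal_var: float
    #: physical magnitude of each (scaled) state variable; X_phys = scale * X
    state_scale: Optional[np.ndarray] = None
    #: physical magnitude of the (scaled) observation
    obs_scale: float = 1.0


@dataclass
class FilterSolution:
    """Steady-state solution of an optimal causal estimation problem."""

    posterior_var: float  # var of s given past observations, s^-2
    rho2: float  # squared correlation of s with its optimal causal estimate
    info_rate: float  # nats/s
    method: str
    tau_v: float
    state_space: Optional[StateSpace] = None
    P: Optional[np.ndarray] = None  # posterior state covariance (riccati)
    gain: Optional[np.ndarray] = None  # Kalman-Bucy gain K

    def info_rate_bits(self) -> float:
        return self.info_rate / np.log(2.0)

    def kernel(self, t_grid: np.ndarray) -> np.ndarray:
        """Optimal causal estimator kernel h(t) = e1' exp((A-KC)t) K.

        The causal estimate is ``shat(t) = int_0^inf h(u) y(t-u) du`` with y
        the (mean-removed) observation.
        """
        if self.gain is None or self.state_space is None:
            raise ValueError("kernel available only for riccati solutions")
        A, C = self.state_space.A, self.state_space.C
        Acl = A - np.outer(self.gain, C)
        return np.array([
            (expm(Acl * t) @ self.gain)[0] if t >= 0 else 0.0 for t in t_grid
        ])


@dataclass
class SNRPair:
    gamma_r: float
    gamma_a: float


def _g_from(env: Environment, g: Optional[float]) -> float:
    gg = env.g if g is None else g
    if gg < 0:
        raise ValueError("g must be >= 0")
    return float(gg)


def gamma_r(env: Environment, swim: SwimmingPhenotype, g: Optional[float] = None) -> float:
    """Dimensionless molecule-arrival SNR, 2*r0*g^2*sigma_v^2*tau_v^3."""
    gg = _g_from(env, g)
    return 2.0 * env.r0 * gg**2 * swim.sigma_v2 * swim.tau_v**3


def gamma_a(
    env: Environment,
    swim: SwimmingPhenotype,
    kin: KinasePhenotype,
    g: Optional[float] = None,
) -> float:
    """Dimensionless kinase-activity SNR, (G_r^2/D_n)*r0^2*g^2*sigma_v^2*tau_v."""
    gg = _g_from(env, g)
    if kin.D_n == 0:
        raise ZeroDivisionError(
            "gamma_a is infinite for D_n = 0 (noiseless sensor branch); "
            "the kinase filter then attains the physical limit"
        )
    return (kin.G_r**2 / kin.D_n) * env.r0**2 * gg**2 * swim.sigma_v2 * swim.tau_v


def snr_pair(env, swim, kin, g=None) -> SNRPair:
    return SNRPair(gamma_r=gamma_r(env, swim, g), gamma_a=gamma_a(env, swim, kin, g))


# ---------------------------------------------------------------------------
# state-space models
# ---------------------------------------------------------------------------

def physical_limit_state_space(
    env: Environment,
    swim: SwimmingPhenotype,
    g: Optional[float] = None,
    integrator_leak: float = 0.0,
) -> StateSpace:
    """Estimation of s from Gaussianized molecule arrivals.

    State (s, x): ds = -(s/tau_v) dt + sqrt(2 sigma_s^2/tau_v) dW,
    dx = s dt (x = log c/c0 along the path).  Observation: the normalized
    arrival-rate deviation (r-r0)/r0 = x + white noise of spectral density
    1/r0.  ``integrator_leak`` adds a small -eps*x damping used by the
    spectral-factorization route (which needs strictly stable dynamics).

    States are scaled to unit natural magnitude (s by sigma_s, x by
    sigma_s*tau_v; observation by its white-noise s.d.) for conditioning;
    posterior variances are reported in physical units downstream.
    """
    gg = _g_from(env, g)
    tau_v = swim.tau_v
    sigma_s2 = gg**2 * swim.sigma_v2
    r0 = env.r0
    if r0 <= 0:
        raise ValueError("r0 must be > 0")
    s_sc = np.sqrt(sigma_s2) if sigma_s2 > 0 else 1.0
    x_sc = s_sc * tau_v
    y_sc = np.sqrt(1.0 / r0)  # observation noise s.d. scale

    A = np.array([[-1.0 / tau_v, 0.0], [s_sc / x_sc, -integrator_leak]])
    B = np.array([[np.sqrt(2.0 * sigma_s2 / tau_v) / s_sc, 0.0], [0.0, 0.0]])
    C = np.array([0.0, x_sc / y_sc])
    D = np.array([0.0, 1.0])
    return StateSpace(A=A, B=B, C=C, D=D, signal_var=sigma_s2 / s_sc**2,
                      state_scale=np.array([s_sc, x_sc]), obs_scale=y_sc)


def kinase_state_space(
    env: Environment,
    swim: SwimmingPhenotype,
    kin: KinasePhenotype,
    g: Optional[float] = None,
    integrator_leak: float = 0.0,
    tau1_noise_floor: float = 1e-6,
) -> StateSpace:
    """Estimation of s from kinase activity (linear response + OU noise).

    With tau_1 = 0 the activity deviation is
        a - a0 = -G_r*(r - r0) + G_r*m + n,
    where m low-passes (r - r0) at tau_2 (adaptation) and n is the internal
    OU noise.  Writing mt = m/r0 and (r-r0)/r0 = x + xi/sqrt(r0):

        state (s, x, mt, n); observation y = G_r*r0*(mt - x) + n - G_r*sqrt(r0)*xi.

    The arrival noise xi both drives mt and enters y: correlated process and
    observation noise, handled by the generalized Riccati equation.  For
    tau_1 > 0 the fast lobe becomes a fifth low-pass state and the observation
    loses its white component; a small white floor (relative s.d.
    ``tau1_noise_floor`` of the internal-noise scale) regularizes that branch.
    """
    gg = _g_from(env, g)
    tau_v, tau_2, tau_n = swim.tau_v, kin.tau_2, kin.tau_n
    sigma_s2 = gg**2 * swim.sigma_v2
    r0 = env.r0
    if r0 <= 0:
        raise ValueError("r0 must be > 0")
    Gr = kin.G_r
    sig_n = np.sqrt(kin.D_n * kin.tau_n) if kin.D_n > 0 else 1.0

    s_sc = np.sqrt(sigma_s2) if sigma_s2 > 0 else 1.0
    x_sc = s_sc * tau_v
    m_sc = x_sc
    n_sc = sig_n
    y_sc = max(Gr * np.sqrt(r0), tau1_noise_floor * sig_n)  # obs white scale

    if kin.tau_1 == 0:
        # states: s, x, mt, n ; noises: (W_s, W_n, xi)
        A = np.array([
            [-1.0 / tau_v, 0.0, 0.0, 0.0],
            [s_sc / x_sc, -integrator_leak, 0.0, 0.0],
            [0.0, x_sc / (tau_2 * m_sc), -1.0 / tau_2, 0.0],
            [0.0, 0.0, 0.0, -1.0 / tau_n],
        ])
        B = np.zeros((4, 3))
        B[0, 0] = np.sqrt(2.0 * sigma_s2 / tau_v) / s_sc
        B[2, 2] = 1.0 / (tau_2 * np.sqrt(r0) * m_sc)
        B[3, 1] = np.sqrt(2.0 * kin.D_n) / n_sc
        C = np.array([
            0.0, -Gr * r0 * x_sc / y_sc, Gr * r0 * m_sc / y_sc, n_sc / y_sc,
        ])
        D = np.array([0.0, 0.0, -Gr * np.sqrt(r0) / y_sc])
        return StateSpace(A=A, B=B, C=C, D=D, signal_var=sigma_s2 / s_sc**2,
                          state_scale=np.array([s_sc, x_sc, m_sc, n_sc]),
                          obs_scale=y_sc)

    # tau_1 > 0 branch: extra fast low-pass state ft = f/r0
    tau_1 = kin.tau_1
    A = np.array([
        [-1.0 / tau_v, 0.0, 0.0, 0.0, 0.0],
        [s_sc / x_sc, -integrator_leak, 0.0, 0.0, 0.0],
        [0.0, x_sc / (tau_2 * m_sc), -1.0 / tau_2, 0.0, 0.0],
        [0.0, x_sc / (tau_1 * m_sc), 0.0, -1.0 / tau_1, 0.0],
        [0.0, 0.0, 0.0, 0.0, -1.0 / tau_n],
    ])
    B = np.zeros((5, 4))
    B[0, 0] = np.sqrt(2.0 * sigma_s2 / tau_v) / s_sc
    B[2, 2] = 1.0 / (tau_2 * np.sqrt(r0) * m_sc)
    B[3, 2] = 1.0 / (tau_1 * np.sqrt(r0) * m_sc)
    B[4, 1] = np.sqrt(2.0 * kin.D_n) / n_sc
    C = np.array([
        0.0, 0.0, Gr * r0 * m_sc / y_sc, -Gr * r0 * m_sc / y_sc, n_sc / y_sc,
    ])
    D = np.zeros(4)
    D[3] = tau1_noise_floor * sig_n / y_sc  # regularizing white floor
    return StateSpace(A=A, B=B, C=C, D=D, signal_var=sigma_s2 / s_sc**2,
                      state_scale=np.array([s_sc, x_sc, m_sc, m_sc, n_sc]),
                      obs_scale=y_sc)


# ---------------------------------------------------------------------------
# solvers
# ---------------------------------------------------------------------------

def _solve_riccati(ss: StateSpace):
    """Steady-state filter covariance via the generalized CARE.

    Solves A P + P A' + Q - (P C' + S) R^-1 (C P + S') = 0 with Q = B B',
    R = D D', S = B D' (filtering dual of scipy's control-form CARE).
    """
    A, B, C, D = ss.A, ss.B, np.atleast_2d(ss.C), np.atleast_2d(ss.D)
    Q = B @ B.T
    R = D @ D.T
    S = B @ D.T
    if R[0, 0] <= 0:
        raise ValueError("observation must carry white noise (D D' > 0)")
    try:
        P = solve_continuous_are(A.T, C.T, Q, R, s=S)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - diagnostic path
        conds = np.linalg.cond(A), np.linalg.cond(Q + np.eye(Q.shape[0]))
        raise RuntimeError(
            f"Riccati solver failed (cond(A)={conds[0]:.2e}, "
            f"cond(Q+I)={conds[1]:.2e}): {exc}"
        ) from exc
    K = (P @ C.T + S) @ np.linalg.inv(R)
    return P, K[:, 0]


def _poly_from_samples(f: Callable[[complex], complex], deg: int, radius: float) -> np.ndarray:
    """Exact coefficients of a polynomial of degree <= deg from FFT samples
    on a circle of given radius (ascending-order coefficients, real part)."""
    m = deg + 1
    w = radius * np.exp(2j * np.pi * np.arange(m) / m)
    vals = np.array([f(z) for z in w])
    # c_j * radius^j = (1/m) sum_k f(w_k) exp(-2*pi*i*j*k/m)  (forward DFT)
    coeffs = np.fft.fft(vals) / m / radius ** np.arange(m)
    return coeffs


def _flip_sign(p: np.ndarray) -> np.ndarray:
    """Coefficients of p(-s) from coefficients of p(s) (ascending order)."""
    out = p.copy()
    out[1::2] *= -1
    return out


def _solve_spectral(ss: StateSpace, signal_index: int = 0) -> float:
    """Posterior variance by causal Wiener filtering (Wiener-Hopf).

    Whitens the observation with the stable, minimum-phase spectral factor
    W(s) of the rational observation spectrum S_y(s) = W(s) W(-s) (factored on
    polynomial coefficients), takes the causal part of the signal-innovation
    cross spectrum by partial fractions, and integrates its squared magnitude
    in closed form over residue pairs.  Requires strictly Hurwitz A (use an
    integrator leak upstream).
    """
    A, B, C, D = ss.A, ss.B, ss.C, ss.D
    n = A.shape[0]
    eigs = np.linalg.eigvals(A)
    if np.any(eigs.real >= 0):
        raise ValueError("spectral method needs strictly stable A (add leak)")
    radius = float(np.median(np.abs(eigs)))
    d_coeffs = npoly.polyfromroots(eigs)  # monic char. polynomial, ascending

    eye = np.eye(n)

    def resolventB(z: complex) -> np.ndarray:
        return np.linalg.solve(z * eye - A, B)

    def d_of(z: complex) -> complex:
        return np.prod(z - eigs)

    nch = B.shape[1]
    # N_k(s) = (C (sI-A)^-1 B + D)_k * d(s), degree <= n
    N = [
        _poly_from_samples(
            lambda z, k=k: (C @ resolventB(z)[:, k] + D[k]) * d_of(z), n, radius
        )
        for k in range(nch)
    ]
    # Gnum_k(s) = (e_sig (sI-A)^-1 B)_k * d(s), degree <= n-1
    Gnum = [
        _poly_from_samples(
            lambda z, k=k: resolventB(z)[signal_index, k] * d_of(z), n - 1, radius
        )
        for k in range(nch)
    ]

    # spectral factorization of S_y numerator: P_y(s) = sum_k N_k(s) N_k(-s)
    Py = np.zeros(2 * n + 1, dtype=complex)
    for Nk in N:
        prod = npoly.polymul(Nk, _flip_sign(Nk))
        Py[: prod.size] += prod
    roots = npoly.polyroots(Py)
    lhp = roots[roots.real < 0]
    if lhp.size * 2 != roots.size:
        raise ValueError("observation spectrum has zeros on the imaginary axis")
    pplus = npoly.polyfromroots(lhp)  # monic stable factor

    def pval(p: np.ndarray, z: complex) -> complex:
        return npoly.polyval(z, p)

    z0 = 1j * radius
    kappa = pval(Py, z0) / (pval(pplus, z0) * pval(pplus, -z0))
    sqrt_kappa = np.sqrt(kappa.real)

    # M(s) = sum_k Gnum_k(s) N_k(-s);  G(s) = M / (d(s) sqrt(kappa) pplus(-s))
    M = np.zeros(2 * n, dtype=complex)
    for Gk, Nk in zip(Gnum, N):
        prod = npoly.polymul(Gk, _flip_sign(Nk))
        M[: prod.size] += prod

    # causal part: residues at the (distinct) LHP poles = eigenvalues of A
    def d_prime(lam: complex) -> complex:
        others = eigs[np.abs(eigs - lam) > 1e-12 * max(radius, 1.0)]
        if others.size != eigs.size - 1:
            raise ValueError("repeated filter poles; spectral route needs "
                             "distinct eigenvalues")
        return np.prod(lam - others)

    res = np.array([
        pval(M, lam) / (d_prime(lam) * sqrt_kappa * pval(pplus, -lam))
        for lam in eigs
    ])
    # E[shat^2] = int_0^inf h(t)^2 dt for h(t) = sum_j res_j exp(eig_j t)
    denom = eigs[:, None] + eigs[None, :]
    est_var = float(np.real(-(res[:, None] * res[None, :] / denom).sum()))
    return ss.signal_var - est_var


def info_rate_from_rho(rho2: float, tau_v: float, units: str = "nats") -> float:
    """Information rate from the squared signal-estimate correlation.

    Exact Gaussian result (1/tau_v) * rho2/(1-rho2) in nats/s, the small-rho2
    form of which is the quoted (1/tau_v)*rho2.  ``units='bits'`` divides by
    ln 2.
    """
    if not 0.0 <= rho2 < 1.0:
        if rho2 == 1.0:
            raise ValueError("rho2 = 1 implies an infinite information rate")
        raise ValueError("rho2 must lie in [0, 1)")
    rate = rho2 / (1.0 - rho2) / tau_v
    if units == "bits":
        return rate / np.log(2.0)
    if units != "nats":
        raise ValueError("units must be 'nats' or 'bits'")
    return rate


def _finalize(ss: StateSpace, pvar_scaled: float, sig_scale2: float,
              tau_v: float, method: str, P=None, K=None) -> FilterSolution:
    pvar = pvar_scaled * sig_scale2
    denom = ss.signal_var * sig_scale2
    rho2 = float(np.clip(1.0 - pvar / denom, 0.0, 1.0 - 1e-15)) if denom > 0 else 0.0
    return FilterSolution(
        posterior_var=pvar,
        rho2=rho2,
        info_rate=info_rate_from_rho(rho2, tau_v),
        method=method,
        tau_v=tau_v,
        state_space=ss,
        P=P,
        gain=K,
    )


def _default_leak(tau_v: float, method: str, leak: Optional[float]) -> float:
    """Integrator regularization.

    The position state x = log(c/c0) is a pure integrator of s.  The CARE
    solver needs a marginally-detectable mode nudged into the stable half
    plane (leak 1e-9/tau_v changes the posterior variance by < 1e-14
    relative), and the spectral factorization needs strictly Hurwitz
    dynamics (leak 1e-8/tau_v).
    """
    if leak is not None:
        return leak
    return (1e-9 if method == "riccati" else 1e-8) / tau_v


def solve_physical_limit_filter(
    env: Environment,
    swim: SwimmingPhenotype,
    g: Optional[float] = None,
    method: str = "riccati",
    integrator_leak: Optional[float] = None,
) -> FilterSolution:
    """Optimal causal estimation of s from Gaussianized molecule arrivals."""
    gg = _g_from(env, g)
    sigma_s2 = gg**2 * swim.sigma_v2
    if gg == 0:
        ss = physical_limit_state_space(env, swim, g=0.0)
        return FilterSolution(0.0, 0.0, 0.0, method, swim.tau_v, state_space=ss)
    leak = _default_leak(swim.tau_v, method, integrator_leak)
    ss = physical_limit_state_space(env, swim, gg, leak)
    if method == "riccati":
        P, K = _solve_riccati(ss)
        return _finalize(ss, P[0, 0], sigma_s2 / ss.signal_var, swim.tau_v,
                         method, P=P, K=K)
    if method == "spectral":
        pvar = _solve_spectral(ss)
        return _finalize(ss, pvar, sigma_s2 / ss.signal_var, swim.tau_v, method)
    raise ValueError(f"unknown method {method!r}")


def solve_kinase_filter(
    env: Environment,
    swim: SwimmingPhenotype,
    kin: KinasePhenotype,
    g: Optional[float] = None,
    method: str = "riccati",
    integrator_leak: Optional[float] = None,
) -> FilterSolution:
    """Optimal causal estimation of s from kinase activity.

    Satisfies the data-processing inequality: the resulting information rate
    never exceeds the physical limit at the same (env, swim, g); for D_n = 0
    (noiseless kinase) it attains it.
    """
    gg = _g_from(env, g)
    sigma_s2 = gg**2 * swim.sigma_v2
    if gg == 0:
        ss = kinase_state_space(env, swim, kin, g=0.0)
        return FilterSolution(0.0, 0.0, 0.0, method, swim.tau_v, state_space=ss)
    leak = _default_leak(swim.tau_v, method, integrator_leak)
    ss = kinase_state_space(env, swim, kin, gg, leak)
    if method == "riccati":
        # near-degenerate corners (e.g. D_n -> 0) can defeat the CARE solver
        # at the smallest leak; retry with a progressively larger one (the
        # posterior variance is insensitive to the leak well beyond these
        # values, see _default_leak)
        last_exc = None
        for leak_try in (leak, 1e-6 / swim.tau_v, 1e-4 / swim.tau_v):
            ss = kinase_state_space(env, swim, kin, gg, leak_try)
            try:
                P, K = _solve_riccati(ss)
                break
            except (RuntimeError, np.linalg.LinAlgError) as exc:
                last_exc = exc
        else:
            raise last_exc
        return _finalize(ss, P[0, 0], sigma_s2 / ss.signal_var, swim.tau_v,
                         method, P=P, K=K)
    if method == "spectral":
        pvar = _solve_spectral(ss)
        return _finalize(ss, pvar, sigma_s2 / ss.signal_var, swim.tau_v, method)
    raise ValueError(f"unknown method {method!r}")


def efficiency_eta(
    env: Environment,
    swim: SwimmingPhenotype,
    kin: KinasePhenotype,
    g: Optional[float] = None,
    method: str = "riccati",
) -> float:
    """Sensing efficiency eta = Idot_{s->a} / Idot_{s->r} in [0, 1].

    For g = 0 the ratio of the leading g^2 coefficients is evaluated at the
    small reference gradient :data:`SHALLOW_G`.
    """
    gg = _g_from(env, g)
    if gg == 0:
        gg = SHALLOW_G
    i_r = solve_physical_limit_filter(env, swim, gg, method=method).info_rate
    i_a = solve_kinase_filter(env, swim, kin, gg, method=method).info_rate
    return i_a / i_r


def noise_psd_components(env: Environment, kin: KinasePhenotype, omega) -> dict:
    """Two-sided PSDs of the kinase-activity noise sources on an omega grid.

    Returns internal-noise PSD 2*D_n*tau_n^2/(1+omega^2 tau_n^2), the
    filtered molecule-arrival noise PSD r0*|Kr~(omega)|^2, and their sum.
    The integral of the internal PSD over domega/2pi is its variance D_n*tau_n.
    """
    omega = np.asarray(omega, dtype=float)
    internal = 2.0 * kin.D_n * kin.tau_n**2 / (1.0 + omega**2 * kin.tau_n**2)
    if kin.tau_1 > 0:
        ker_ft = kin.G_r * (1.0 / (1.0 + 1j * omega * kin.tau_1)
                            - 1.0 / (1.0 + 1j * omega * kin.tau_2))
    else:
        ker_ft = kin.G_r * (1.0 - 1.0 / (1.0 + 1j * omega * kin.tau_2))
    filtered = env.r0 * np.abs(ker_ft) ** 2
    return {
        "omega": omega,
        "internal": internal,
        "filtered_arrival": filtered,
        "total": internal + filtered,
    }


def berg_purcell_check(
    env: Environment, swim: SwimmingPhenotype, g: Optional[float] = None
) -> dict:
    """Berg-Purcell single-run threshold check: passes iff gamma_r > 16/3."""
    gr = gamma_r(env, swim, g)
    return {
        "gamma_r": gr,
        "threshold": BERG_PURCELL_THRESHOLD,
        "passes": bool(gr > BERG_PURCELL_THRESHOLD),
    }


def population_eta_percentiles(
    env: Environment,
    swim: SwimmingPhenotype,
    kin: KinasePhenotype,
    cv: dict,
    n_mc: int = 1000,
    seed: int = 0,
    g: Optional[float] = None,
    percentiles=(5, 50, 95),
) -> dict:
    """Monte-Carlo propagation of cell-to-cell phenotype variability to eta.

    Parameters vary independently across cells with lognormal marginals whose
    medians are the supplied phenotype values and whose coefficients of
    variation are given per parameter in ``cv`` (keys among sigma_v2, tau_v,
    G_r, tau_2, D_n, tau_n; missing keys get zero spread).  Lognormal
    sampling guarantees positivity, so no resampling is needed; the returned
    dict records ``n_resampled = 0`` for interface completeness.
    """
    rng = np.random.default_rng(seed)
    names = ["sigma_v2", "tau_v", "G_r", "tau_2", "D_n", "tau_n"]
    medians = {
        "sigma_v2": swim.sigma_v2, "tau_v": swim.tau_v, "G_r": kin.G_r,
        "tau_2": kin.tau_2, "D_n": kin.D_n, "tau_n": kin.tau_n,
    }
    draws = {}
    for name in names:
        c = float(cv.get(name, 0.0))
        if c <= 0:
            draws[name] = np.full(n_mc, medians[name])
        else:
            sig = np.sqrt(np.log1p(c**2))
            draws[name] = medians[name] * np.exp(sig * rng.standard_normal(n_mc))
    etas = np.empty(n_mc)
    for i in range(n_mc):
        sw = SwimmingPhenotype(
            sigma_v2=draws["sigma_v2"][i], tau_v=draws["tau_v"][i],
            speed=swim.speed, p_run=swim.p_run, mean_run=swim.mean_run,
            mean_tumble=swim.mean_tumble, persistence=swim.persistence,
            d_rot=swim.d_rot,
        )
        kn = KinasePhenotype(
            G_r=draws["G_r"][i], tau_2=draws["tau_2"][i], D_n=draws["D_n"][i],
            tau_n=draws["tau_n"][i], tau_1=kin.tau_1, a0=kin.a0,
        )
        etas[i] = efficiency_eta(env, sw, kn, g)
    pct = {f"p{p}": float(np.percentile(etas, p)) for p in percentiles}
    return {"percentiles": pct, "etas": etas, "n_resampled": 0, "seed": seed}
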