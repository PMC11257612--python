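"""Parameter estimation from tracks and FRET-like activity traces.

The pipeline mirrors the experimental analysis chain:

* swimming: tumble detection -> per-cell Prun -> median-Prun binning ->
  duration-weighted velocity autocorrelation -> Bayesian exponential fit of
  (sigma_v^2, tau_v);
* kinase response: per-cell averaging of repeated step responses ->
  MAP + MCMC fit of the adaptive response kernel (G_r, tau_1, tau_2);
* kinase noise: Kalman-filter marginal likelihood of the OU noise observed
  through white measurement noise -> MAP + MCMC fit of (D_n, tau_n);
* MWC gain curve: log-space least squares of G_inf/(c0 + K_i) on the fitted
  gains across backgrounds;
* aggregation: population medians with a variance that combines cell-to-cell
  spread (1/N) and single-cell posterior uncertainty (1/N^2), both through
  the robust scale estimate 1.4826*mad; first-order uncertainty propagation
  to derived quantities.

All fits use Gaussian likelihoods with log-uniform priors (+-3 decades
around a moment-based initial guess), MAP by multi-start optimization, and
uncertainties from an affine-invariant ensemble sampler; everything is
deterministic given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit
from scipy.optimize import least_squares, minimize

from .models import RUN, TUMBLE, Environment, TimeSeries, Track

__all__ = [
    "FitResult",
    "EnsembleSummary",
    "detect_tumbles",
    "prun_and_bin",
    "velocity_acf",
    "fit_exponential_acf",
    "average_step_response",
    "fit_response_kernel",
    "estimate_block_noise_model",
    "ou_kalman_loglik",
    "fit_ou_noise",
    "fit_mwc",
    "population_median_uncertainty",
    "propagate_uncertainty",
    "fret_to_activity",
    "estimate_fret_anchors",
    "recover_swim_params",
    "recover_response_params",
    "recover_noise_params",
]

MAD_TO_SD = 1.4826


def robust_sd(x: np.ndarray) -> float:
    """1.4826 * median absolute deviation: a robust Gaussian-consistent sd."""
    x = np.asarray(x, dtype=float)
    return MAD_TO_SD * float(np.median(np.abs(x - np.median(x))))


@dataclass
class FitResult:
    """MAP estimate, posterior samples and robust per-parameter uncertainty."""

    param_names: List[str]
    map_estimate: Dict[str, float]
    samples: np.ndarray  # (n_samples, n_params)
    uncertainty: Dict[str, float]  # 1.4826*mad of the posterior samples
    diagnostics: Dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_samples(cls, names, map_vec, samples, **diag):
        unc = {n: robust_sd(samples[:, i]) for i, n in enumerate(names)}
        return cls(
            param_names=list(names),
            map_estimate={n: float(v) for n, v in zip(names, map_vec)},
            samples=samples,
            uncertainty=unc,
            diagnostics=dict(diag),
        )


@dataclass
class EnsembleSummary:
    """Population median and its variance for one parameter.

    ``sem2 = (1/N)(1.4826 mad(theta_MAP))^2 + (1/N^2) sum_k sigma_k^2``
    combines cell-to-cell variation (first term) with single-cell posterior
    uncertainty (second term).
    """

    median: float
    sem2: float
    n_cells: int

    @property
    def sem(self) -> float:
        return float(np.sqrt(self.sem2))


# ---------------------------------------------------------------------------
# MCMC machinery (shared by all fits)
# ---------------------------------------------------------------------------

def _run_mcmc(
    log_post: Callable[[np.ndarray], float],
    x_map: np.ndarray,
    seed: int,
    n_walkers: int = 32,
    n_steps: int = 2000,
    ball: float = 1e-3,
) -> Tuple[np.ndarray, float]:
    """Affine-invariant ensemble sampling around a MAP point.

    Half of the chain is discarded as burn-in; returns flattened samples and
    the mean acceptance fraction (healthy range ~[0.1, 0.7])."""
    import emcee

    ndim = x_map.size
    rs = np.random.RandomState(seed)
    p0 = x_map + ball * np.abs(x_map + 1e-12) * rs.randn(n_walkers, ndim)
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_post)
    sampler._random = rs
    sampler.run_mcmc(p0, n_steps, progress=False)
    acc = float(np.mean(sampler.acceptance_fraction))
    samples = sampler.get_chain(discard=n_steps // 2, flat=True)
    return samples, acc


def _map_multistart(neg_log_post, x0_list, bounds=None):
    best = None
    for x0 in x0_list:
        res = minimize(neg_log_post, x0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    return best.x


def _log_uniform_prior(logx: np.ndarray, centers: np.ndarray,
                       decades: float = 3.0) -> float:
    """Uniform-in-log prior +-``decades`` decades around the initial guess."""
    lo = centers - decades * np.log(10.0)
    hi = centers + decades * np.log(10.0)
    if np.any(logx < lo) or np.any(logx > hi):
        return -np.inf
    return 0.0


# ---------------------------------------------------------------------------
# swimming pipeline
# ---------------------------------------------------------------------------

def detect_tumbles(
    track: Track,
    speed_drop_frac: float = 0.5,
    turn_rate_thresh: float = 6.0,
    merge_gap_s: float = 0.1,
) -> Track:
    """Label each sample run/tumble from speed drops and turn-rate spikes.

    A sample is a tumble candidate when its speed falls below
    ``speed_drop_frac`` times the cell's median speed or its turn rate
    exceeds ``turn_rate_thresh`` (rad/s).  Candidate segments separated by
    gaps shorter than ``merge_gap_s`` are merged.  The labeled track's meta
    records the number of tumble segments; downstream selection keeps only
    cells with at least two.
    """
    if track.t.size < 3:
        raise ValueError("track must have at least 3 samples")
    dt = track.dt
    vx = np.diff(track.x) / dt
    vy = np.diff(track.y) / dt
    speed = np.hypot(vx, vy)
    med = np.median(speed)
    heading = np.arctan2(vy, vx)
    dheading = np.angle(np.exp(1j * np.diff(heading)))
    turn_rate = np.abs(dheading) / dt

    cand = np.zeros(track.t.size, dtype=bool)
    cand[:-1] |= speed < speed_drop_frac * med
    cand[1:-1] |= turn_rate > turn_rate_thresh
    cand[-1] = cand[-2]

    # merge candidate segments separated by sub-merge_gap_s run gaps
    gap = max(1, int(round(merge_gap_s / dt)))
    idx = np.flatnonzero(cand)
    if idx.size:
        starts = [idx[0]]
        ends = []
        for a, b in zip(idx[:-1], idx[1:]):
            if b - a > 1:
                if b - a - 1 <= gap:
                    continue
                ends.append(a)
                starts.append(b)
        ends.append(idx[-1])
        for a, b in zip(starts, ends):
            cand[a:b + 1] = True
        n_tumbles = len(starts)
    else:
        n_tumbles = 0

    state = np.where(cand, TUMBLE, RUN).astype(np.int8)
    meta = dict(track.meta)
    meta.update(n_tumbles=n_tumbles)
    return Track(t=track.t, x=track.x, y=track.y, state=state, meta=meta)


def prun_and_bin(
    tracks: Sequence[Track],
    window: float = 0.01,
    min_tumbles: int = 2,
) -> Tuple[List[Track], np.ndarray]:
    """Per-cell run fraction and the median-Prun cell subset.

    Cells with fewer than ``min_tumbles`` detected tumbles are dropped; the
    subset holds cells with Prun within +-``window`` of the population
    median.  If the subset would be empty the window is doubled until it is
    not (with a warning recording the final width).
    """
    kept = [tr for tr in tracks if tr.meta.get("n_tumbles", 0) >= min_tumbles]
    if not kept:
        raise ValueError("no cells with enough tumbles")
    pruns = np.array([float(np.mean(tr.state == RUN)) for tr in kept])
    med = float(np.median(pruns))
    w = window
    while True:
        sel = np.abs(pruns - med) <= w
        if sel.any():
            break
        w *= 2.0
    if w != window:
        warnings.warn(f"median-Prun window widened to +-{w:.3f}", stacklevel=2)
    subset = [tr for tr, s in zip(kept, sel) if s]
    for tr, p in zip(kept, pruns):
        tr.meta["p_run_hat"] = float(p)
    return subset, pruns


def velocity_acf(
    tracks: Sequence[Track],
    max_lag_s: float = 10.0,
    tau_guess: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Duration-weighted pooled velocity autocorrelation with per-lag SE.

    Per cell, ``V_i(lag) = <vx(t) vx(t+lag)>`` (FFT-based, unbiased per-lag
    normalization); the pooled estimate weights cells by track duration.
    The per-lag standard error uses the effective number of independent
    stretches ``n_eff = T_total/(2*tau_hat)`` with ``tau_hat`` from a first-
    pass exponential fit (iterated once):
    ``Var[V(lag)] ~ (V(0)^2 + V(lag)^2)/n_eff``.
    """
    if not tracks:
        raise ValueError("no tracks supplied")
    dt = tracks[0].dt
    shortest = min(tr.t.size - 1 for tr in tracks)
    n_lag = int(round(max_lag_s / dt))
    if n_lag >= shortest:
        warnings.warn("lag grid truncated to the shortest track", stacklevel=2)
        n_lag = shortest - 1
    lags = np.arange(n_lag + 1) * dt

    Vs, weights = [], []
    for tr in tracks:
        vx = tr.vx
        n = vx.size
        fsize = 1 << int(np.ceil(np.log2(2 * n)))
        f = np.fft.rfft(vx, fsize)
        acov = np.fft.irfft(f * np.conj(f))[: n_lag + 1]
        counts = n - np.arange(n_lag + 1)
        Vs.append(acov / counts)
        weights.append(tr.duration)
    Vs = np.array(Vs)
    wts = np.array(weights)
    V = (Vs * wts[:, None]).sum(axis=0) / wts.sum()

    total_T = float(wts.sum())
    tau_hat = tau_guess
    for _ in range(2 if tau_guess is None else 1):
        if tau_hat is None:
            pos = (lags > 0) & (V > 0)
            coef = np.polyfit(lags[pos][: max(5, n_lag // 4)],
                              np.log(V[pos][: max(5, n_lag // 4)]), 1)
            tau_hat = max(-1.0 / coef[0], dt)
        n_eff = max(total_T / (2.0 * tau_hat), 2.0)
        se = np.sqrt((V[0] ** 2 + V**2) / n_eff)
    return lags, V, se


def acf_covariance(lags: np.ndarray, sig2: float, tau: float,
                   T_total: float) -> np.ndarray:
    """Bartlett covariance of an empirical exponential ACF.

    For a Gaussian process with C(u) = sig2*exp(-|u|/tau) estimated from a
    record of total duration T,

      Cov[Chat(s), Chat(t)] = (sig2^2 tau/T) [ e^{-|t-s|/tau}(1+|t-s|/tau)
                                             + e^{-(t+s)/tau}(1+(t+s)/tau) ].

    The strong lag-to-lag correlation this encodes is what makes diagonal
    least squares on an ACF tail so noisy; the GLS likelihood built on this
    matrix whitens it.
    """
    d = np.abs(lags[:, None] - lags[None, :])
    s = lags[:, None] + lags[None, :]
    return (sig2**2 * tau / T_total) * (
        np.exp(-d / tau) * (1.0 + d / tau) + np.exp(-s / tau) * (1.0 + s / tau)
    )


def _acf_first_pass(x, y):
    early = (x <= x[0] + 1.9) & (y > 0)
    coef = np.polyfit(x[early], np.log(y[early]), 1)
    return (float(np.exp(coef[1])),
            float(np.clip(-1.0 / coef[0], 0.2, 5.0)))


def gls_exponential_acf(lags, V, T_total, fit_range=(0.1, 10.0), n_pass=2):
    """Point estimate of (sigma_v^2, tau_v) by GLS with Bartlett covariance.

    The covariance is built from a first-pass estimate and the fit iterated
    once (mirroring 'use the estimated tau to set the uncertainty').
    Returns (sigma_v2, tau_v, cho_factor, x, y) so callers can reuse the
    whitening.
    """
    from scipy.linalg import cho_factor, cho_solve

    sel = (lags >= fit_range[0] - 1e-12) & (lags <= fit_range[1] + 1e-12)
    if sel.sum() < 5:
        raise ValueError("need at least 5 lags in the fit range")
    x, y = lags[sel], V[sel]
    s2, tau = _acf_first_pass(x, y)
    cf = None
    for _ in range(n_pass):
        C = acf_covariance(x, s2, tau, T_total)
        C[np.diag_indices_from(C)] += 1e-8 * s2**2
        cf = cho_factor(C)

        def nll(p):
            A, tt = np.exp(p)
            r = y - A * np.exp(-x / tt)
            return 0.5 * float(r @ cho_solve(cf, r))

        res = minimize(nll, np.log([s2, tau]), method="Nelder-Mead",
                       options={"xatol": 1e-9, "fatol": 1e-12,
                                "maxiter": 3000})
        s2, tau = np.exp(res.x)
    return float(s2), float(tau), cf, x, y


def fit_exponential_acf(
    lags: np.ndarray,
    V: np.ndarray,
    se: np.ndarray,
    fit_range: Tuple[float, float] = (0.1, 10.0),
    seed: int = 0,
    n_steps: int = 2000,
    T_total: Optional[float] = None,
) -> FitResult:
    """Bayesian fit of sigma_v^2 * exp(-lag/tau_v) to a velocity ACF.

    Gaussian likelihood over the fit range (which excludes lag 0 by
    construction) with log-uniform priors.  When ``T_total`` is given the
    likelihood uses the full Bartlett covariance of the ACF estimate
    (:func:`acf_covariance`, built from a first-pass fit and iterated once);
    otherwise it falls back to the supplied independent per-lag SEs.
    """
    from scipy.linalg import cho_solve

    if not (V[0] > 0):
        raise ValueError("V(0) must be positive")
    sel = (lags >= fit_range[0] - 1e-12) & (lags <= fit_range[1] + 1e-12)
    if sel.sum() < 5:
        raise ValueError("need at least 5 lags in the fit range")
    x, y, s = lags[sel], V[sel], se[sel]

    if T_total is not None:
        s2_0, tau_0, cf, x, y = gls_exponential_acf(lags, V, T_total,
                                                    fit_range)

        def chi2(p):
            A, tt = np.exp(p)
            r = y - A * np.exp(-x / tt)
            return float(r @ cho_solve(cf, r))
    else:
        s2_0, tau_0 = _acf_first_pass(x, y)

        def chi2(p):
            A, tt = np.exp(p)
            return float(np.sum(((y - A * np.exp(-x / tt)) / s) ** 2))

    guess = np.array([np.log(s2_0), np.log(tau_0)])

    def log_post(p):
        lp = _log_uniform_prior(p, guess)
        if not np.isfinite(lp):
            return -np.inf
        return lp - 0.5 * chi2(p)

    x_map = _map_multistart(lambda p: -log_post(p),
                            [guess, guess + [0.2, -0.2], guess + [-0.2, 0.2]])
    samples, acc = _run_mcmc(log_post, x_map, seed, n_steps=n_steps)
    return FitResult.from_samples(
        ["sigma_v2", "tau_v"], np.exp(x_map), np.exp(samples),
        acceptance_fraction=acc, n_points=int(sel.sum()),
    )


# ---------------------------------------------------------------------------
# kinase response pipeline
# ---------------------------------------------------------------------------

def average_step_response(blocks: Sequence[TimeSeries]) -> Dict[str, dict]:
    """Per-direction mean +- SEM response curves of one cell.

    Each block is baseline-aligned on its pre-step window; repeats are
    averaged pointwise and the pointwise SEM computed.  Cells with fewer
    than 2 repeats in a direction are flagged (``ok=False``).
    """
    out = {}
    for direction in ("up", "down"):
        reps = [b for b in blocks if b.meta.get("direction") == direction]
        if not reps:
            continue
        onset = reps[0].meta["step_onset_s"]
        t = reps[0].t
        aligned = []
        for b in reps:
            base = b.values[b.t < onset - 1e-9].mean()
            aligned.append(b.values - base)
        arr = np.array(aligned)
        mean = arr.mean(axis=0)
        sem = (arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
               if arr.shape[0] > 1 else np.full(t.size, np.inf))
        out[direction] = {
            "t": t - onset,
            "mean": mean,
            "sem": sem,
            "n": arr.shape[0],
            "delta_c": reps[0].meta["delta_c"],
            "ok": arr.shape[0] >= 2,
        }
    return out


def estimate_block_noise_model(dataset: Sequence[Sequence[TimeSeries]]) -> dict:
    """Slow-noise model (variance, correlation time, white floor) from a
    step-response dataset.

    Within each cell and direction, the mean over repeats is subtracted from
    every block: the deterministic response cancels exactly in expectation
    and the residuals are pure (block-independent) noise on the full imaged
    grid, whose same-block covariance is (1 - 1/n_rep) * C(u).  Pooling the
    rescaled outer products over blocks and cells and least-squares fitting
    ``var_slow * exp(-|u|/tau) + var_white * delta`` gives a noise model on
    a window long enough (the full imaged block) to identify the slow
    correlation time.
    """
    acc = None
    count = 0
    t_grid = None
    for blocks in dataset:
        for direction in ("up", "down"):
            reps = [b for b in blocks if b.meta.get("direction") == direction]
            if len(reps) < 2:
                continue
            arr = np.array([b.values for b in reps])
            resid = arr - arr.mean(axis=0)
            scale = 1.0 - 1.0 / arr.shape[0]
            if t_grid is None:
                t_grid = reps[0].t
            for r in resid:
                op = np.outer(r, r) / scale
                acc = op if acc is None else acc + op
                count += 1
    if acc is None:
        raise ValueError("need >= 2 repeats per direction for a noise model")
    emp = acc / count
    m = t_grid.size
    dtm = np.abs(t_grid[:, None] - t_grid[None, :])

    def model_cov(p):
        vs, tau, vw = np.exp(p)
        return vs * np.exp(-dtm / tau) + vw * np.eye(m)

    v0 = max(np.trace(emp) / m, 1e-8)

    def cost(p):
        return float(np.sum((model_cov(p) - emp) ** 2))

    from scipy.optimize import minimize as _min

    best = None
    for tau0 in (3.0, 9.0, 30.0):
        r = _min(cost, np.log([0.8 * v0, tau0, 0.2 * v0 + 1e-9]),
                 method="Nelder-Mead",
                 options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 3000})
        if best is None or r.fun < best.fun:
            best = r
    vs, tau, vw = np.exp(best.x)
    return {"var_slow": float(vs), "tau_slow": float(tau),
            "var_white": float(vw), "n_windows": count}


def _response_residual_cov(t_resp, t_base, n_rep, noise):
    """Covariance of a baseline-subtracted, repeat-averaged response curve.

    For block noise h with C(u) = var_slow e^{-|u|/tau} + var_white delta,
    the residual at frame i is h_i - mean(h over baseline frames), averaged
    over n_rep independent blocks:
    Cov_ij = [C_ij - cbar_i - cbar_j + bbar] / n_rep.
    """
    vs, tau, vw = noise["var_slow"], noise["tau_slow"], noise["var_white"]

    def C(u):
        return vs * np.exp(-np.abs(u) / tau) + vw * (np.abs(u) < 1e-12)

    Crr = C(t_resp[:, None] - t_resp[None, :])
    cbar = C(t_resp[:, None] - t_base[None, :]).mean(axis=1)
    bbar = C(t_base[:, None] - t_base[None, :]).mean()
    return (Crr - cbar[:, None] - cbar[None, :] + bbar) / n_rep


def fit_response_kernel(
    avg: Dict[str, dict],
    env: Environment,
    seed: int = 0,
    n_steps: int = 2000,
    tau1_floor: float = 5e-3,
    noise_model: Optional[dict] = None,
    t_baseline: Optional[np.ndarray] = None,
) -> FitResult:
    """MAP + MCMC fit of (G_r*k_D, tau_1, tau_2) to averaged step responses.

    The model response to a concentration step delta_c (arrival-rate step
    delta_r = k_D*delta_c) is ``-delta_r*G_r*(e^{-t/tau_2} - e^{-t/tau_1})``
    for t >= 0.  Up and down averages are fitted jointly with shared
    parameters; log-uniform priors; the identifiability tie-break
    tau_2 > tau_1 is enforced through the prior support.  The gain is
    reported in 1/k_D units.

    When a ``noise_model`` (from :func:`estimate_block_noise_model`) is
    given, the Gaussian likelihood uses the full residual covariance of the
    baseline-subtracted repeat average — essential because the slow kinase
    noise has a correlation time comparable to the adaptation time, so a
    pointwise-SEM likelihood badly understates the uncertainty along the
    (gain, tau_2) valley.  Without it the pointwise SEMs are used.
    """
    data = []
    for direction, d in avg.items():
        if not d["ok"]:
            continue
        # the frame at the step onset is ambiguous (valve switch mid-frame);
        # fit strictly-post-onset samples
        post = d["t"] > 1e-9
        data.append((d["t"][post], d["mean"][post], d["sem"][post],
                     d["delta_c"], d["n"]))
    if not data:
        raise ValueError("no direction with >= 2 repeats")
    if sum(t.size for t, *_ in data) < 10:
        raise ValueError("need >= 10 s of post-step response")

    cho_factors = None
    if noise_model is not None:
        from scipy.linalg import cho_factor

        if t_baseline is None:
            raise ValueError("t_baseline required with a noise model")
        cho_factors = []
        for t, _, _, _, n_rep in data:
            S = _response_residual_cov(t, t_baseline, n_rep, noise_model)
            S[np.diag_indices_from(S)] += 1e-10 * max(noise_model["var_slow"],
                                                      1e-8)
            cho_factors.append(cho_factor(S))

    # moment guesses: early response ~ gain_kD*|delta_c|; tail decay ~ tau_2
    amp = max(np.max(np.abs(m)) for _, m, _, _, _ in data)
    dc = max(abs(d[3]) for d in data)
    t0_, m0_, _, dc0_, _ = data[0]
    tail = (t0_ > 2.0) & (m0_ * np.sign(-dc0_) > 0)
    if tail.sum() >= 4:
        coef = np.polyfit(t0_[tail], np.log(np.abs(m0_[tail])), 1)
        tau2_guess = float(np.clip(-1.0 / coef[0], 1.0, 60.0))
    else:
        tau2_guess = 5.0
    guess = np.array([np.log(max(amp / dc, 1e-3)), np.log(0.2),
                      np.log(tau2_guess)])
    # tau_1 (fast CheY-CheZ relaxation) prior: fixed physical window around
    # the known sub-second relaxation; at 0.75-s sampling tau_1 is only
    # weakly identified and an unbounded prior lets a degenerate
    # (large tau_1, inflated gain) branch leak in
    tau1_lo, tau1_hi = max(tau1_floor, 0.05), 2.0

    def model(p, t, delta_c):
        gain_kD, tau1, tau2 = np.exp(p)
        resp = np.exp(-t / tau2) - np.exp(-t / tau1)
        return -gain_kD * delta_c * resp

    def log_post(p):
        from scipy.linalg import cho_solve

        lp = _log_uniform_prior(p[[0, 2]], guess[[0, 2]], decades=2.0)
        if not np.isfinite(lp):
            return -np.inf
        tau1, tau2 = np.exp(p[1]), np.exp(p[2])
        if not (tau1_lo <= tau1 <= tau1_hi) or tau2 <= tau1:
            return -np.inf
        chi2 = 0.0
        for i, (t, m, s, dc_, _) in enumerate(data):
            r = m - model(p, t, dc_)
            if cho_factors is not None:
                chi2 += float(r @ cho_solve(cho_factors[i], r))
            else:
                chi2 += np.sum((r / s) ** 2)
        return lp - 0.5 * chi2

    starts = [guess, guess + [0.3, -2.0, 0.3], guess + [-0.3, 1.5, -0.3],
              np.array([guess[0], np.log(0.5), np.log(3.0)]),
              np.array([guess[0], np.log(0.5), np.log(12.0)])]
    x_map = _map_multistart(lambda p: -log_post(p), starts)
    samples, acc = _run_mcmc(log_post, x_map, seed, n_steps=n_steps)
    res = FitResult.from_samples(
        ["G_r_kD", "tau_1", "tau_2"], np.exp(x_map), np.exp(samples),
        acceptance_fraction=acc,
    )
    # a flat response shows up as a posterior as wide as the prior
    if res.uncertainty["G_r_kD"] > res.map_estimate["G_r_kD"]:
        res.diagnostics["degenerate"] = 1.0
    return res


# ---------------------------------------------------------------------------
# kinase noise pipeline
# ---------------------------------------------------------------------------

@njit(cache=True)
def _ou_kalman_core(y, dt, Dn, tau_n, a0, meas_var):  # pragma: no cover
    phi = np.exp(-dt / tau_n)
    q = Dn * tau_n * (1.0 - phi * phi)
    mu = 0.0
    P = Dn * tau_n
    ll = 0.0
    for k in range(y.size):
        if k > 0:
            mu = phi * mu
            P = phi * phi * P + q
        S = P + meas_var
        v = y[k] - a0 - mu
        ll += -0.5 * (np.log(2.0 * np.pi * S) + v * v / S)
        K = P / S
        mu = mu + K * v
        P = (1.0 - K) * P
    return ll


def ou_kalman_loglik(y: np.ndarray, dt: float, Dn: float, tau_n: float,
                     a0: float, measurement_noise_sd: float) -> float:
    """Exact Gaussian log-likelihood of an OU process observed in white noise,
    computed by scalar Kalman filtering (O(n))."""
    return float(_ou_kalman_core(np.asarray(y, dtype=np.float64), dt,
                                 Dn, tau_n, a0, measurement_noise_sd**2))


def fit_ou_noise(
    trace: TimeSeries,
    measurement_noise_sd: float,
    seed: int = 0,
    n_steps: int = 2000,
) -> FitResult:
    """MAP + MCMC fit of the internal-noise parameters (D_n, tau_n).

    Kalman-filter marginal likelihood of the OU state observed with white
    measurement noise; log-uniform priors on (D_n, tau_n), flat prior on the
    baseline a0.  A generator with D_n = 0 drives the posterior to the lower
    prior edge, which is flagged in the diagnostics.
    """
    y = trace.values
    dt = trace.dt
    if trace.duration < 50 * 5.0:
        warnings.warn("trace shorter than ~50 correlation times; posterior "
                      "may be wide", stacklevel=2)

    var_tot = float(np.var(y))
    var_ou = max(var_tot - measurement_noise_sd**2, 1e-3 * var_tot)
    c0_ = var_tot
    c1 = float(np.mean((y[:-1] - y.mean()) * (y[1:] - y.mean())))
    rho1 = np.clip((c1) / max(var_ou, 1e-12), 1e-3, 0.999)
    tau_guess = max(-dt / np.log(rho1), dt)
    Dn_guess = var_ou / tau_guess
    guess = np.array([np.log(Dn_guess), np.log(tau_guess)])
    a0_guess = float(np.mean(y))

    def log_post(p):
        lp = _log_uniform_prior(p[:2], guess)
        if not np.isfinite(lp):
            return -np.inf
        Dn, tau_n = np.exp(p[:2])
        return lp + ou_kalman_loglik(y, dt, Dn, tau_n, p[2],
                                     measurement_noise_sd)

    x0 = np.array([guess[0], guess[1], a0_guess])
    x_map = _map_multistart(
        lambda p: -log_post(p),
        [x0, x0 + [0.5, 0.5, 0.0], x0 + [-0.5, -0.5, 0.0]],
    )
    samples, acc = _run_mcmc(log_post, x_map, seed, n_steps=n_steps)
    out = np.column_stack([np.exp(samples[:, 0]), np.exp(samples[:, 1]),
                           samples[:, 2]])
    res = FitResult.from_samples(
        ["D_n", "tau_n", "a0"],
        [np.exp(x_map[0]), np.exp(x_map[1]), x_map[2]],
        out, acceptance_fraction=acc,
    )
    lower_edge = guess[0] - 3.0 * np.log(10.0)
    if x_map[0] < lower_edge + 0.1 * np.log(10.0):
        res.diagnostics["at_lower_prior_edge"] = 1.0
    return res


# ---------------------------------------------------------------------------
# MWC gain fit
# ---------------------------------------------------------------------------

def fit_mwc(gain_table: Sequence[Tuple[float, float, float]],
            weighted: bool = True):
    """Fit (G_inf, K_i) to measured gains across backgrounds.

    ``gain_table`` holds (c0, G_r*k_D, sigma) triples.  The objective is the
    sum of squared *log* residuals between the measured dimensionless gains
    G = G_r*k_D*c0 and the MWC form G_inf*c0/(c0+K_i); log-space residuals
    give the order-of-magnitude-smaller high-background gain similar leverage
    to the others.  By default residuals are weighted by the relative
    measurement errors (1/sigma_log with sigma_log = sigma/gain), which is
    what reproduces the reported gain-curve parameters; ``weighted=False``
    gives every background equal weight.  Multi-start least squares.
    """
    table = [(float(c), float(g), float(s)) for c, g, s in gain_table]
    if len(table) < 2:
        raise ValueError("need gains at >= 2 backgrounds")
    if any(g <= 0 for _, g, _ in table):
        raise ValueError("gains must be positive")
    c0s = np.array([c for c, _, _ in table])
    G = np.array([g * c for c, g, _ in table])  # dimensionless MWC gain
    if weighted:
        wts = np.array([g / s for _, g, s in table])  # 1/sigma_log
    else:
        wts = np.ones(len(table))

    def resid(p):
        G_inf, K_i = np.exp(p)
        return wts * (np.log(G) - np.log(G_inf * c0s / (c0s + K_i)))

    best = None
    for k0 in (np.median(c0s), c0s.min(), c0s.max()):
        p0 = np.log([max(G.max(), 1e-6) * 1.5, k0])
        res = least_squares(resid, p0, method="lm")
        if best is None or res.cost < best.cost:
            best = res
    G_inf, K_i = np.exp(best.x)
    return {
        "G_inf": float(G_inf),
        "K_i": float(K_i),
        "residuals_log": resid(best.x).tolist(),
        "cost": float(best.cost),
    }


# ---------------------------------------------------------------------------
# aggregation and error propagation
# ---------------------------------------------------------------------------

def population_median_uncertainty(
    fits: Sequence[FitResult], param: str
) -> EnsembleSummary:
    """Median of per-cell MAP estimates with its combined variance.

    Variance = (1/N)(1.4826 mad(theta_MAP))^2 + (1/N^2) sum_k sigma_k^2,
    where sigma_k = 1.4826 mad of cell k's posterior samples: cell-to-cell
    variation plus single-cell estimation uncertainty.
    """
    maps = np.array([f.map_estimate[param] for f in fits])
    sigmas = np.array([f.uncertainty[param] for f in fits])
    N = maps.size
    if N < 2:
        raise ValueError("need >= 2 cells")
    sem2 = (robust_sd(maps) ** 2) / N + float(np.sum(sigmas**2)) / N**2
    return EnsembleSummary(median=float(np.median(maps)), sem2=float(sem2),
                           n_cells=int(N))


def propagate_uncertainty(
    f: Callable[..., float],
    theta: Dict[str, float],
    sigma: Dict[str, float],
    rel_step: float = 1e-4,
) -> float:
    """First-order uncertainty of f(theta) with independent parameter errors.

    ``sigma_f^2 = sum_i (df/dtheta_i)^2 sigma_i^2`` with central-difference
    gradients; correlations between parameter uncertainties are neglected.
    Works pointwise for array-valued f as well.
    """
    names = list(theta)
    base = {k: float(v) for k, v in theta.items()}
    var = 0.0
    for name in names:
        s = sigma.get(name, 0.0)
        if s == 0:
            continue
        h = rel_step * max(abs(base[name]), 1e-12)
        up = dict(base)
        dn = dict(base)
        up[name] += h
        dn[name] -= h
        try:
            grad = (np.asarray(f(**up)) - np.asarray(f(**dn))) / (2 * h)
        except Exception as exc:
            raise RuntimeError(f"gradient failed for {name!r}: {exc}") from exc
        var = var + grad**2 * s**2
    return np.sqrt(var)


def fret_to_activity(fret_trace: TimeSeries, fret_min: float,
                     fret_max: float) -> TimeSeries:
    """Normalize a FRET trace to kinase activity.

    ``a(t) = (FRET - FRET_min)/(FRET_max - FRET_min)``; values may leave
    [0, 1] through noise and are deliberately not clipped.
    """
    if not fret_max > fret_min:
        raise ValueError("fret_max must exceed fret_min")
    vals = (fret_trace.values - fret_min) / (fret_max - fret_min)
    meta = dict(fret_trace.meta)
    meta.update(fret_min=fret_min, fret_max=fret_max)
    return TimeSeries(t=fret_trace.t.copy(), values=vals, meta=meta)


def estimate_fret_anchors(
    saturating_block: TimeSeries,
    removal_block: TimeSeries,
    removal_window_s: float = 2.5,
) -> Tuple[float, float]:
    """FRET levels at minimum and maximum kinase activity.

    The minimum-activity anchor is the mean FRET during the saturating
    stimulus; the maximum-activity anchor is the mean over the first
    ``removal_window_s`` seconds of the removal response.
    """
    fmin = float(np.mean(saturating_block.values))
    sel = removal_block.t <= removal_block.t[0] + removal_window_s + 1e-9
    fmax = float(np.mean(removal_block.values[sel]))
    return fmin, fmax


# ---------------------------------------------------------------------------
# end-to-end recovery stages (dataset -> population medians)
# ---------------------------------------------------------------------------

def recover_swim_params(
    tracks: Sequence[Track],
    fit_range: Tuple[float, float] = (0.1, 10.0),
    seed: int = 0,
    n_replicates: int = 4,
) -> dict:
    """Track dataset -> (sigma_v^2, tau_v): detection, median-Prun binning,
    duration-weighted pooled ACF, Bayesian exponential fit, with the
    estimator's sampling uncertainty from a cell-level bootstrap."""
    labeled = [detect_tumbles(tr) for tr in tracks]
    subset, pruns = prun_and_bin(labeled)
    lags, V, se = velocity_acf(subset, max_lag_s=fit_range[1])
    T_total = float(sum(tr.duration for tr in subset))
    fit = fit_exponential_acf(lags, V, se, fit_range=fit_range, seed=seed,
                              T_total=T_total)

    # honest sampling uncertainty of the pooled estimator: bootstrap over
    # cells (captures both the correlated ACF noise and the random phenotype
    # composition of the median-Prun bin)
    boot = _bootstrap_acf_fit(subset, fit_range, seed=seed + 1,
                              n_boot=n_replicates * 6)
    summary = {}
    for name in ("sigma_v2", "tau_v"):
        sem = max(float(np.std(boot[name], ddof=1)), fit.uncertainty[name])
        summary[name] = EnsembleSummary(
            median=fit.map_estimate[name], sem2=sem**2, n_cells=len(subset))
    return {
        "fit": fit,
        "sigma_v2": summary["sigma_v2"],
        "tau_v": summary["tau_v"],
        "n_cells_total": len(tracks),
        "n_cells_median_bin": len(subset),
        "prun_median": float(np.median(pruns)),
        "acf": (lags, V, se),
    }


def _bootstrap_acf_fit(subset, fit_range, seed, n_boot=24):
    """Cell-level bootstrap of the pooled weighted-ACF GLS exponential fit."""
    from scipy.linalg import cho_solve

    rng = np.random.default_rng(seed)
    lags, V, _ = velocity_acf(subset, max_lag_s=fit_range[1])
    T_total = float(sum(tr.duration for tr in subset))
    s2_0, tau_0, cf, x, _ = gls_exponential_acf(lags, V, T_total, fit_range)
    # cache per-cell ACFs once; reuse the full-sample whitening for refits
    n_lag = lags.size - 1
    Vs, wts = [], []
    for tr in subset:
        vx = tr.vx
        n = vx.size
        fsize = 1 << int(np.ceil(np.log2(2 * n)))
        f = np.fft.rfft(vx, fsize)
        acov = np.fft.irfft(f * np.conj(f))[: n_lag + 1]
        Vs.append(acov / (n - np.arange(n_lag + 1)))
        wts.append(tr.duration)
    Vs = np.array(Vs)
    wts = np.array(wts)
    sel = (lags >= fit_range[0] - 1e-12) & (lags <= fit_range[1] + 1e-12)
    out = {"sigma_v2": [], "tau_v": []}
    for _ in range(n_boot):
        idx = rng.integers(0, len(subset), len(subset))
        yb = (Vs[idx] * wts[idx, None]).sum(axis=0) / wts[idx].sum()
        yb = yb[sel]

        def nll(p):
            A, tt = np.exp(p)
            r = yb - A * np.exp(-x / tt)
            return 0.5 * float(r @ cho_solve(cf, r))

        res = minimize(nll, np.log([s2_0, tau_0]), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10,
                                "maxiter": 2000})
        s2b, taub = np.exp(res.x)
        out["sigma_v2"].append(s2b)
        out["tau_v"].append(taub)
    return {k: np.array(v) for k, v in out.items()}


def recover_response_params(
    dataset: Sequence[Sequence[TimeSeries]],
    env: Environment,
    seed: int = 0,
    n_steps: int = 2000,
) -> dict:
    """Step-response dataset -> population medians of (G_r*k_D, tau_2).

    The slow-noise covariance used in every cell's GLS likelihood is
    estimated once from the pooled pre-step baseline windows of the dataset
    itself.
    """
    noise_model = estimate_block_noise_model(dataset)
    b0 = dataset[0][0]
    t_baseline = (b0.t - b0.meta["step_onset_s"])[b0.t < b0.meta["step_onset_s"] - 1e-9]
    fits = []
    for i, blocks in enumerate(dataset):
        avg = average_step_response(blocks)
        fits.append(fit_response_kernel(avg, env, seed=seed + 7919 * i,
                                        n_steps=n_steps,
                                        noise_model=noise_model,
                                        t_baseline=t_baseline))
    return {
        "fits": fits,
        "G_r_kD": population_median_uncertainty(fits, "G_r_kD"),
        "tau_2": population_median_uncertainty(fits, "tau_2"),
    }


def recover_noise_params(
    traces: Sequence[TimeSeries],
    measurement_noise_sd: float = 0.02,
    seed: int = 0,
    n_steps: int = 2000,
) -> dict:
    """Noise-trace dataset -> population medians of (D_n, tau_n)."""
    fits = [
        fit_ou_noise(tr, measurement_noise_sd, seed=seed + 104729 * i,
                     n_steps=n_steps)
        for i, tr in enumerate(traces)
    ]
    return {
        "fits": fits,
        "D_n": population_median_uncertainty(fits, "D_n"),
        "tau_n": population_median_uncertainty(fits, "tau_n"),
    }
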