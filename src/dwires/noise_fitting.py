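"""Rician noise synthesis and maximum-likelihood model fitting.

Noisy magnitude signals are simulated by adding independent Gaussian noise to
the real and imaginary channels of the noise-free signal and taking the
magnitude, which makes the data Rician distributed.  SNR is defined on the
b = 0 signal at TE = 100 ms, so the channel noise standard deviation is
``sigma = exp(-100/T2) / SNR`` for unit proton density.

Each diffusion-weighted magnitude is normalized by an independently noisy
G = 0 magnitude acquired at the same TE, mirroring experimental practice.
The normalized measurement is then treated as Rician with location equal to
the normalized model prediction and scale ``sigma / exp(-TE/T2)``; the noise
in the normalizing b0 itself is neglected, an approximation that is good at
the SNR levels considered (the b0 has the highest SNR of any measurement).

Fitting maximizes the summed Rician log-likelihood over the protocol with a
multi-start Nelder-Mead simplex search; bound constraints are enforced by a
logistic transform to an unconstrained space.  Fits landing within 1% of the
constraint range on any free parameter are flagged as extreme and excluded
from ensemble summaries; a condition with more than 50% extreme fits is
marked invalid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, i0e, logit

from ._optim import batched_nelder_mead
from .signal_model import (
    DEFAULT_TORTUOSITY,
    BimodalTissue,
    PhysicsConstants,
    Tissue,
    _b_value_ms_um2,
    mixture_signal,
    tortuous_diffusivity,
    total_signal,
)

__all__ = [
    "NoiseModel",
    "FitBounds",
    "FitResult",
    "FitSummary",
    "add_rician",
    "simulate_ensemble",
    "rician_loglik",
    "fit_tissue",
    "fit_ensemble",
    "summarize",
]

PARAM_NAMES = ("R", "f_i", "D_i", "D_e")

#: Fraction of the constraint range defining an "extreme" estimate.
EXTREME_FRACTION = 0.01

#: Conditions with fewer than this fraction of valid (non-extreme) fits are
#: marked invalid.
MIN_VALID_FRACTION = 0.5


@dataclass(frozen=True)
class NoiseModel:
    """Channel noise level implied by an SNR at b = 0, TE = 100 ms."""

    snr: float
    T2: float = 125.0

    def __post_init__(self) -> None:
        if not self.snr > 0:
            raise ValueError("snr must be positive")

    @property
    def sigma(self) -> float:
        """Gaussian channel noise SD in signal units (proton density 1)."""
        return math.exp(-100.0 / self.T2) / self.snr


@dataclass(frozen=True)
class FitBounds:
    """Box constraints for the model parameters."""

    R: tuple[float, float] = (0.1, 25.0)
    f_i: tuple[float, float] = (0.01, 1.0)
    D_i: tuple[float, float] = (0.1, 3.0)
    D_e: tuple[float, float] = (0.1, 3.0)

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"bounds for {name} must satisfy lo < hi")

    def lo(self) -> np.ndarray:
        return np.array([getattr(self, n)[0] for n in PARAM_NAMES])

    def hi(self) -> np.ndarray:
        return np.array([getattr(self, n)[1] for n in PARAM_NAMES])

    def is_extreme(self, name: str, value: float) -> bool:
        """True when ``value`` lies within 1% of the constraint range of a bound."""
        lo, hi = getattr(self, name)
        margin = EXTREME_FRACTION * (hi - lo)
        return value < lo + margin or value > hi - margin


DEFAULT_BOUNDS = FitBounds()


@dataclass(frozen=True)
class FitResult:
    """Best-of-restarts ML estimate for one noisy signal vector."""

    estimates: dict[str, float]
    objective: float
    extreme: dict[str, bool]
    fixed_diffusivities: bool
    n_converged: int = 0

    @property
    def any_extreme(self) -> bool:
        return any(self.extreme.values())


@dataclass(frozen=True)
class FitSummary:
    """Ensemble accuracy/precision after excluding extreme fits.

    ``accuracy`` is the mean estimate minus truth (same units as the
    parameter); ``precision`` is the standard deviation of the estimates,
    i.e. the parameter's standard error SE_p.
    """

    accuracy: dict[str, float]
    precision: dict[str, float]
    valid_fraction: float
    n_repeats: int
    valid: bool


def add_rician(noise_free, sigma: float, rng: np.random.Generator):
    """Rician-distributed magnitude of a noise-free signal.

    Returns ``sqrt((S + n1)^2 + n2^2)`` with independent zero-mean Gaussian
    channel noise of SD ``sigma``; broadcasts over array input.
    """
    s = np.asarray(noise_free, dtype=float)
    if np.any(s < 0):
        raise ValueError("noise-free signal must be non-negative")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return s.copy()
    n1 = rng.normal(0.0, sigma, size=s.shape)
    n2 = rng.normal(0.0, sigma, size=s.shape)
    return np.hypot(s + n1, n2)


def simulate_ensemble(
    t: Tissue | BimodalTissue,
    protocol,
    noise: NoiseModel,
    n_repeats: int,
    rng: np.random.Generator,
    constants: PhysicsConstants | None = None,
    tortuosity: str = DEFAULT_TORTUOSITY,
) -> np.ndarray:
    """Simulate normalized noisy signals, shape ``(n_repeats, n_meas)``.

    For each repeat and measurement the Rician DW magnitude is divided by an
    independently noisy G = 0 magnitude at the same TE.  Accepts a bimodal
    tissue, in which case the mixture signal is synthesized (the fit model
    stays single-radius).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    constants = constants or PhysicsConstants()
    signal_fn = mixture_signal if isinstance(t, BimodalTissue) else total_signal
    dw = np.array([signal_fn(t, m, constants, tortuosity) for m in protocol])
    b0 = np.array([math.exp(-m.TE / t.T2) for m in protocol])
    sigma = noise.sigma
    noisy_dw = add_rician(np.broadcast_to(dw, (n_repeats, len(dw))), sigma, rng)
    noisy_b0 = add_rician(np.broadcast_to(b0, (n_repeats, len(b0))), sigma, rng)
    return noisy_dw / noisy_b0


def rician_loglik(prediction, sigma_eff, observed):
    """Rician log-density of ``observed`` given location and scale; broadcasts.

    ln p(x | nu, s) = ln(x/s^2) - (x^2 + nu^2)/(2 s^2) + ln I0(x nu / s^2),
    evaluated with the exponentially scaled Bessel function so large
    arguments cannot overflow.
    """
    nu = np.asarray(prediction, dtype=float)
    s = np.asarray(sigma_eff, dtype=float)
    x = np.asarray(observed, dtype=float)
    if np.any(x < 0):
        raise ValueError("observed magnitudes must be non-negative")
    if np.any(s <= 0):
        raise ValueError("sigma_eff must be positive")
    s2 = s * s
    z = x * nu / s2
    # ln I0(z) = ln(i0e(z)) + z, stable for large z
    return np.log(x / s2) - (x * x + nu * nu) / (2.0 * s2) + np.log(i0e(z)) + z


class _ProtocolModel:
    """Precomputed quantities for fast repeated signal evaluation.

    Caches, per protocol, everything in the GPD sphere series that does not
    depend on the tissue parameters, so one model evaluation is a handful of
    small vectorized operations.
    """

    def __init__(
        self,
        protocol,
        constants: PhysicsConstants | None = None,
        tortuosity: str = DEFAULT_TORTUOSITY,
    ):
        constants = constants or PhysicsConstants()
        self.constants = constants
        self.tortuosity = tortuosity
        G = np.array([m.G for m in protocol])
        Delta = np.array([m.Delta for m in protocol])
        delta = np.array([m.delta for m in protocol])
        self.TE = np.array([m.TE for m in protocol])
        self.b_ms_um2 = _b_value_ms_um2(G, Delta, delta)  # internal units
        x = constants.roots
        x2 = x * x
        M = len(x)
        K = len(G)
        denom = x2 * x2 * x2 * (x2 - 2.0)  # (M,)
        # The GPD series per measurement k is
        #   series_k = sum_m [2 s x^2 delta - 2 + 2 e0 + 2 eD - eDm - eDp] / denom_m
        # with s = D_i/R^2 and exponentials over the four times
        # (delta, Delta, Delta-delta, Delta+delta).  Split into a part linear
        # in s, a constant, and exp(-s * t) terms folded into one matrix
        # product so a batch evaluation is one exp() plus one matmul.
        times = np.stack([delta, Delta, Delta - delta, Delta + delta])  # (4, K)
        self._targs = (x2[:, None, None] * times[None, :, :]).reshape(-1)  # (M*4*K,)
        w = np.array([2.0, 2.0, -1.0, -1.0])
        weight = np.zeros((M, 4, K, K))
        for k in range(K):
            weight[:, :, k, k] = w[None, :] / denom[:, None]
        self._weight = weight.reshape(M * 4 * K, K)
        self._lin = 2.0 * (x2[:, None] * delta[None, :] / denom[:, None]).sum(axis=0)
        self._const = -2.0 * np.sum(1.0 / denom)
        gamma = constants.gamma
        self._pref = 2.0 * gamma * gamma * G * G
        self._buf = None  # lazily allocated chunk buffer

    def intra_signal(self, R: float, D_i: float) -> np.ndarray:
        """Sphere attenuation S_i per measurement (GPD series)."""
        return self.intra_signal_batch(np.atleast_1d(R), np.atleast_1d(D_i))[0]

    _CHUNK = 4096

    def intra_signal_batch(self, R: np.ndarray, D_i: np.ndarray) -> np.ndarray:
        """Sphere attenuation for parameter batches, shape (P,) -> (P, K)."""
        s = D_i / (R * R)  # (P,)
        P = len(s)
        K = len(self.TE)
        series = np.empty((P, K))
        if self._buf is None:
            self._buf = np.empty((self._CHUNK, len(self._targs)))
        # chunked exp + matmul with a reused buffer: keeps the working set in
        # cache and avoids repeated large allocations
        for i in range(0, P, self._CHUNK):
            sl = s[i : i + self._CHUNK]
            b = self._buf[: len(sl)]
            np.multiply(sl[:, None], -self._targs[None, :], out=b)
            # clamp: exp of anything below -60 is negligible in the series,
            # and subnormal-range exp falls off the fast hardware path
            np.maximum(b, -60.0, out=b)
            np.exp(b, out=b)
            np.dot(b, self._weight, out=series[i : i + len(sl)])
        series += s[:, None] * self._lin[None, :] + self._const
        series *= (R**6 / (D_i * D_i))[:, None]
        return np.exp(-self._pref[None, :] * series)

    def normalized_signal(self, theta: np.ndarray) -> np.ndarray:
        """Normalized model prediction f_i S_i + (1 - f_i) S_e per measurement."""
        R, f_i, D_i, D_e = theta
        s_i = self.intra_signal(R, D_i)
        d_t = tortuous_diffusivity(D_e, f_i, self.tortuosity)
        s_e = np.exp(-self.b_ms_um2 * d_t)
        return f_i * s_i + (1.0 - f_i) * s_e

    def normalized_signal_batch(self, thetas: np.ndarray) -> np.ndarray:
        """Model predictions for a batch of parameter vectors (P, 4) -> (P, K)."""
        f_i = thetas[:, 1]
        s_int = self.intra_signal_batch(thetas[:, 0], thetas[:, 2])
        d_t = tortuous_diffusivity(thetas[:, 3], f_i, self.tortuosity)
        s_ext = np.exp(-self.b_ms_um2[None, :] * d_t[:, None])
        return f_i[:, None] * s_int + (1.0 - f_i[:, None]) * s_ext


def _sigma_eff(noise: NoiseModel, TE: np.ndarray, T2: float) -> np.ndarray:
    """Effective Rician scale of normalized data per measurement."""
    return noise.sigma / np.exp(-TE / T2)


def _fit_rows(
    y: np.ndarray,
    model: _ProtocolModel,
    noise: NoiseModel,
    bounds: FitBounds,
    fixed_diffusivities: tuple[float, float] | None,
    starts: np.ndarray,
    T2: float,
    maxiter: int,
) -> list[FitResult]:
    """Multistart Rician ML fits of every row of ``y``.

    ``starts`` has shape (n_rows, n_starts, n_free) in natural units.  All
    rows and all restarts are advanced together through the batched simplex
    search; per row the restart with the lowest negative log-likelihood wins.
    """
    n_rows, n_starts, n_free = starts.shape
    sig_eff = _sigma_eff(noise, model.TE, T2)
    s2 = sig_eff * sig_eff
    # terms of -loglik that do not involve the model prediction
    const = np.sum(y * y / (2.0 * s2) - np.log(y / s2), axis=1)

    lo, hi = bounds.lo(), bounds.hi()
    free = (
        np.array([True, True, False, False])
        if fixed_diffusivities is not None
        else np.ones(4, dtype=bool)
    )
    lo_f, hi_f = lo[free], hi[free]
    span = hi_f - lo_f
    rep_of_problem = np.arange(n_rows * n_starts) // n_starts

    def neg_loglik_core(z: np.ndarray, prob_idx: np.ndarray) -> np.ndarray:
        thetas = np.empty((len(z), 4))
        if fixed_diffusivities is not None:
            thetas[:, 2], thetas[:, 3] = fixed_diffusivities
        thetas[:, free] = lo_f + span * expit(z)
        mu = model.normalized_signal_batch(thetas)
        x = y[rep_of_problem[prob_idx]]
        za = x * mu / s2
        return np.sum(mu * mu / (2.0 * s2) - (np.log(i0e(za)) + za), axis=1)

    z0 = logit(np.clip((starts.reshape(-1, n_free) - lo_f) / span, 1e-9, 1 - 1e-9))
    z_best, f_best, conv = batched_nelder_mead(
        neg_loglik_core, z0, xatol=1e-6, fatol=1e-6, maxiter=maxiter
    )
    f_best = f_best.reshape(n_rows, n_starts)
    z_best = z_best.reshape(n_rows, n_starts, n_free)
    conv = conv.reshape(n_rows, n_starts)
    winner = np.argmin(f_best, axis=1)

    results = []
    for r in range(n_rows):
        theta_full = np.empty(4)
        if fixed_diffusivities is not None:
            theta_full[2], theta_full[3] = fixed_diffusivities
        theta_full[free] = lo_f + span * expit(z_best[r, winner[r]])
        theta_full[:] = np.clip(theta_full, lo, hi)
        estimates = dict(zip(PARAM_NAMES, theta_full.tolist()))
        extreme = {
            name: bool(free[i]) and bounds.is_extreme(name, theta_full[i])
            for i, name in enumerate(PARAM_NAMES)
        }
        results.append(
            FitResult(
                estimates=estimates,
                objective=float(f_best[r, winner[r]] + const[r]),
                extreme=extreme,
                fixed_diffusivities=fixed_diffusivities is not None,
                n_converged=int(conv[r].sum()),
            )
        )
    return results


def fit_tissue(
    ensemble_row,
    protocol,
    noise: NoiseModel,
    bounds: FitBounds = DEFAULT_BOUNDS,
    fixed_diffusivities: tuple[float, float] | None = None,
    n_starts: int = 100,
    rng: np.random.Generator | None = None,
    T2: float = 125.0,
    model: _ProtocolModel | None = None,
    starts: np.ndarray | None = None,
    maxiter: int = 1000,
) -> FitResult:
    """Rician ML fit of the two-compartment model to one signal vector.

    Parameters are searched with Nelder-Mead from ``n_starts`` starting
    points drawn uniformly within the bounds (or from explicit ``starts``,
    shape (n_starts, n_free)); the reported estimate is the restart with the
    lowest negative log-likelihood.  Bounds are enforced by a logistic
    transform to unconstrained space.  With ``fixed_diffusivities =
    (D_i, D_e)`` only R and f_i are free (2 parameters); otherwise all 4.
    """
    y = np.atleast_2d(np.asarray(ensemble_row, dtype=float))
    if y.shape[1] != len(protocol):
        raise ValueError("ensemble_row length must match protocol length")
    if model is None:
        model = _ProtocolModel(protocol)
    n_free = 2 if fixed_diffusivities is not None else 4
    if starts is None:
        if rng is None:
            raise ValueError("provide rng or explicit starts")
        free = slice(0, 2) if n_free == 2 else slice(0, 4)
        lo_f, hi_f = bounds.lo()[free], bounds.hi()[free]
        starts = lo_f + (hi_f - lo_f) * rng.random((n_starts, n_free))
    starts = np.asarray(starts, dtype=float).reshape(1, -1, n_free)
    return _fit_rows(
        y, model, noise, bounds, fixed_diffusivities, starts, T2, maxiter
    )[0]


def fit_ensemble(
    ensemble: np.ndarray,
    protocol,
    noise: NoiseModel,
    bounds: FitBounds = DEFAULT_BOUNDS,
    fixed_diffusivities: tuple[float, float] | None = None,
    n_starts: int = 100,
    rng: np.random.Generator | None = None,
    T2: float = 125.0,
    constants: PhysicsConstants | None = None,
    tortuosity: str = DEFAULT_TORTUOSITY,
    maxiter: int = 1000,
) -> list[FitResult]:
    """Fit every row of an ensemble with multistart ML, one result per row.

    Start values for all rows are drawn up front from ``rng`` so results are
    reproducible for a fixed seed regardless of batching.
    """
    y = np.asarray(ensemble, dtype=float)
    model = _ProtocolModel(protocol, constants, tortuosity)
    rng = rng or np.random.default_rng()
    n_free = 2 if fixed_diffusivities is not None else 4
    free = slice(0, 2) if n_free == 2 else slice(0, 4)
    lo_f, hi_f = bounds.lo()[free], bounds.hi()[free]
    starts = lo_f + (hi_f - lo_f) * rng.random((y.shape[0], n_starts, n_free))
    return _fit_rows(
        y, model, noise, bounds, fixed_diffusivities, starts, T2, maxiter
    )


def summarize(fits, truth: Tissue) -> FitSummary:
    """Ensemble accuracy/precision statistics with the extreme-fit exclusion.

    Fits with any free parameter within 1% of the constraint range are
    excluded.  When more than half of the fits are excluded (or fewer than
    two remain) the condition is marked invalid, mirroring conditions where
    parameter estimation has effectively failed.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("need at least one fit")
    valid = [f for f in fits if not f.any_extreme]
    valid_fraction = len(valid) / len(fits)
    free_names = (
        ("R", "f_i") if fits[0].fixed_diffusivities else PARAM_NAMES
    )
    is_valid = valid_fraction >= MIN_VALID_FRACTION and len(valid) >= 2
    if not is_valid:
        nan = {n: math.nan for n in free_names}
        return FitSummary(nan, dict(nan), valid_fraction, len(fits), False)
    truth_vals = dict(zip(PARAM_NAMES, truth.as_array()))
    accuracy = {}
    precision = {}
    for name in free_names:
        vals = np.array([f.estimates[name] for f in valid])
        accuracy[name] = float(vals.mean() - truth_vals[name])
        precision[name] = float(vals.std(ddof=1))
    return FitSummary(accuracy, precision, valid_fraction, len(fits), True)
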