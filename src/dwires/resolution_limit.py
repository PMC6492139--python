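"""Detectability of parameter changes: the resolution-limit analysis.

A change Delta_p = |p2 - p1| in a model parameter p (cell radius R or
intracellular volume fraction f_i) is declared detectable by a two-sample
z-test at alpha = 0.05 when

    sqrt(SE_p1^2 + SE_p2^2)  <=  Delta_p / 1.96,

where SE_p1, SE_p2 are the standard errors of the baseline and changed-state
estimates.  The left-hand side (the "resolution limit") falls with SNR
roughly as 1/SNR; fitting m/SNR + c to the simulated limits and intersecting
with the threshold yields the SNR required to detect the change:
SNR_req = m / (threshold - c).

Conventions: the simulated SNR grid is {20, 50, 80, 110}; the SNR = 20 point
is always excluded from the 1/SNR fit (its SE estimates are unstable when
many fits hit the constraints); the fit is anchored by a pseudo-point
(SNR = 1e6, limit = 0) expressing that SE -> 0 as SNR -> infinity.  R^2 is
computed on the real points only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .change_scenarios import ChangeScenario
from .noise_fitting import (
    FitBounds,
    DEFAULT_BOUNDS,
    NoiseModel,
    fit_ensemble,
    simulate_ensemble,
    summarize,
)
from .signal_model import Tissue

__all__ = [
    "Z_ALPHA",
    "DEFAULT_SNR_LEVELS",
    "ResolutionCurve",
    "resolution_statistic",
    "detection_threshold",
    "fit_inverse_snr",
    "required_snr",
    "resolution_analysis",
    "required_snr_sweep",
]

#: Two-sided z critical value at alpha = 0.05.
Z_ALPHA = 1.96

DEFAULT_SNR_LEVELS = (20, 50, 80, 110)

#: SNR levels excluded from the 1/SNR fit (unstable SE estimates).
DEFAULT_EXCLUDE_SNRS = (20,)

#: Pseudo-point expressing SE -> 0 as SNR -> infinity.
ANCHOR_SNR = 1.0e6
ANCHOR_VALUE = 0.0


def resolution_statistic(se1: float, se2: float) -> float:
    """Combined standard error sqrt(se1^2 + se2^2) of a difference estimate."""
    if se1 < 0 or se2 < 0:
        raise ValueError("standard errors must be non-negative")
    return math.hypot(se1, se2)


def detection_threshold(p1: float, p2: float) -> float:
    """Largest detectable combined SE: |p2 - p1| / 1.96.

    Returns NaN when the parameter does not change (no threshold exists:
    there is nothing to detect).
    """
    delta = abs(p2 - p1)
    if delta == 0:
        return math.nan
    return delta / Z_ALPHA


def fit_inverse_snr(
    snr_levels,
    limit_values,
    exclude_snrs=DEFAULT_EXCLUDE_SNRS,
    anchor_snr: float = ANCHOR_SNR,
    anchor_value: float = ANCHOR_VALUE,
) -> tuple[float, float, float]:
    """Least-squares fit of ``limit = m/SNR + c``.

    The listed ``exclude_snrs`` are dropped; an asymptotic anchor
    pseudo-point (``anchor_snr``, ``anchor_value``) is appended to the
    regression with unit weight.  Returns ``(m, c, r2)`` with the
    coefficient of determination computed on the real (non-pseudo) points.
    """
    snr = np.asarray(snr_levels, dtype=float)
    lim = np.asarray(limit_values, dtype=float)
    if snr.shape != lim.shape or snr.ndim != 1:
        raise ValueError("snr_levels and limit_values must be 1-D of equal length")
    keep = ~np.isin(snr, np.asarray(exclude_snrs, dtype=float))
    snr, lim = snr[keep], lim[keep]
    if len(snr) < 2:
        raise ValueError("need at least two usable points after exclusion")
    if len(np.unique(snr)) < 2:
        raise ValueError("SNR levels are degenerate (all equal)")
    x = np.append(1.0 / snr, 1.0 / anchor_snr)
    y = np.append(lim, anchor_value)
    m, c = np.polyfit(x, y, 1)
    pred = m / snr + c
    ss_res = float(np.sum((lim - pred) ** 2))
    ss_tot = float(np.sum((lim - lim.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan
    return float(m), float(c), r2


def required_snr(m: float, c: float, threshold: float) -> float:
    """SNR at which the fitted curve m/SNR + c crosses the threshold.

    Returns NaN for an undefined threshold (no parameter change) and +inf
    when ``threshold <= c`` (under this extrapolation the change is
    undetectable at any SNR).
    """
    if math.isnan(threshold):
        return math.nan
    if threshold <= c:
        return math.inf
    return m / (threshold - c)


@dataclass(frozen=True)
class ResolutionCurve:
    """Resolution-limit curve for one parameter of one change scenario."""

    parameter: str
    snr_levels: tuple[float, ...]
    limit_values: tuple[float, ...]
    threshold: float
    fit_m: float
    fit_c: float
    fit_r2: float
    required_snr: float
    valid: bool = True


def resolution_analysis(
    scenario: ChangeScenario,
    protocol,
    snr_levels=DEFAULT_SNR_LEVELS,
    n_repeats: int = 300,
    n_starts: int = 20,
    seed: int | np.random.SeedSequence = 0,
    fix_diffusivities: bool = True,
    bounds: FitBounds = DEFAULT_BOUNDS,
    exclude_snrs=DEFAULT_EXCLUDE_SNRS,
) -> dict[str, ResolutionCurve]:
    """Full simulation-based resolution-limit analysis of one scenario.

    Baseline and changed states are simulated and fitted independently at
    each SNR (no equal-precision assumption); the combined SE per parameter
    is regressed against 1/SNR and intersected with the detection threshold.
    Returns one :class:`ResolutionCurve` per parameter ("R", "f_i").

    ``seed`` feeds a deterministic stream tree: one child stream per
    (state, SNR) ensemble, so any subset of conditions reproduces.
    """
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    states = {"baseline": scenario.baseline, "changed": scenario.changed}
    truth_single = {
        "baseline": scenario.baseline,
        # for asynchronous scenarios the single-radius fit is summarized
        # against the shrunken-population radius and total restricted fraction
        "changed": scenario.changed
        if isinstance(scenario.changed, Tissue)
        else Tissue(
            R=scenario.changed.R_shrunk,
            f_i=max(scenario.changed.f_total, 1e-6),
            D_i=scenario.changed.D_i,
            D_e=scenario.changed.D_e,
            T2=scenario.changed.T2,
        ),
    }
    fixed = (
        (scenario.baseline.D_i, scenario.baseline.D_e) if fix_diffusivities else None
    )
    children = ss.spawn(len(states) * len(snr_levels))
    precision: dict[tuple[str, float], dict[str, float]] = {}
    all_valid = True
    i = 0
    for name, tissue in states.items():
        for snr in snr_levels:
            rng = np.random.default_rng(children[i])
            i += 1
            noise = NoiseModel(snr=snr, T2=tissue.T2)
            ens = simulate_ensemble(tissue, protocol, noise, n_repeats, rng)
            fits = fit_ensemble(
                ens,
                protocol,
                noise,
                bounds=bounds,
                fixed_diffusivities=fixed,
                n_starts=n_starts,
                rng=rng,
                T2=tissue.T2,
            )
            summ = summarize(fits, truth_single[name])
            precision[(name, snr)] = summ.precision
            if not summ.valid:
                all_valid = False

    delta = scenario.delta
    curves = {}
    for param in ("R", "f_i"):
        limits = tuple(
            resolution_statistic(
                precision[("baseline", s)][param], precision[("changed", s)][param]
            )
            if all_valid
            else math.nan
            for s in snr_levels
        )
        thr = detection_threshold(0.0, delta[param])
        n_usable = sum(s not in exclude_snrs for s in snr_levels)
        if all_valid and n_usable >= 2:
            m, c, r2 = fit_inverse_snr(snr_levels, limits, exclude_snrs)
            req = required_snr(m, c, thr)
        else:
            # too few SNR levels for the 1/SNR fit (e.g. a bias-only sweep)
            # or an invalid condition: report limits without a curve
            m = c = r2 = req = math.nan
        curves[param] = ResolutionCurve(
            parameter=param,
            snr_levels=tuple(snr_levels),
            limit_values=limits,
            threshold=thr,
            fit_m=m,
            fit_c=c,
            fit_r2=r2,
            required_snr=req,
            valid=all_valid,
        )
    return curves


def required_snr_sweep(
    scenarios: dict[str, ChangeScenario],
    protocols: dict[str, tuple],
    snr_levels=DEFAULT_SNR_LEVELS,
    n_repeats: int = 300,
    n_starts: int = 20,
    seed: int = 0,
    fix_diffusivities: bool = True,
    exclude_snrs=DEFAULT_EXCLUDE_SNRS,
):
    """Required-SNR table over scenarios and protocols.

    Returns a tidy pandas DataFrame with one row per
    (scenario, protocol, parameter); invalid conditions carry NaN values and
    ``valid = False``.  Each (scenario, protocol) cell gets its own child
    seed stream so the table is reproducible cell-wise.
    """
    import pandas as pd

    ss = np.random.SeedSequence(seed)
    cells = [(sn, pn) for sn in scenarios for pn in protocols]
    children = ss.spawn(len(cells))
    rows = []
    for (scen_name, prot_name), child in zip(cells, children):
        scen = scenarios[scen_name]
        curves = resolution_analysis(
            scen,
            protocols[prot_name],
            snr_levels=snr_levels,
            n_repeats=n_repeats,
            n_starts=n_starts,
            seed=child,
            fix_diffusivities=fix_diffusivities,
            exclude_snrs=exclude_snrs,
        )
        for param, curve in curves.items():
            rows.append(
                {
                    "scenario": scen_name,
                    "protocol": prot_name,
                    "parameter": param,
                    "kind": scen.kind,
                    "baseline_R": scen.baseline.R,
                    "baseline_f_i": scen.baseline.f_i,
                    "D_i": scen.baseline.D_i,
                    "D_e": scen.baseline.D_e,
                    "v": scen.v,
                    "p": scen.p,
                    "threshold": curve.threshold,
                    "fit_m": curve.fit_m,
                    "fit_c": curve.fit_c,
                    "fit_r2": curve.fit_r2,
                    "required_snr": curve.required_snr,
                    "valid": curve.valid,
                }
            )
    return pd.DataFrame(rows)
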