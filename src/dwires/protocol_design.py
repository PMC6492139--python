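"""D-optimal PGSE protocol design under clinical hardware constraints.

The information a protocol carries about the tissue parameters
theta = (R, f_i, D_i, D_e) is summarized by the Fisher information matrix of
the signal model under additive Gaussian noise with constant sigma,

    M = (1/sigma^2) sum_k  grad_theta S(theta, m_k) grad_theta S(theta, m_k)^T,

where S includes the exp(-TE/T2) relaxation factor.  A locally D-optimum
design maximizes |M|; because M depends on theta, robust designs minimize
the criterion summed over a prior sample of tissues:

    f = sum_i -log |M_i|        (lower is better).

Feasible measurements satisfy the clinical constraint set: G <= G_max,
b in [150, 5000] s/mm^2, Delta - delta >= T_180 (= 12 ms, refocusing pulse
plus crushers), Delta + delta <= TE - T_c (T_c = 13 ms, readout and
pre-gradient time), TE <= 100 ms, and a predicted-signal floor of
2 sigma for the prior-median tissue.

The search over (G, Delta, delta) tuples uses a real-coded genetic
algorithm: tournament selection, blend crossover, Gaussian mutation,
elitism, and a penalty for constraint violations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .noise_fitting import _ProtocolModel
from .signal_model import (
    Measurement,
    Tissue,
    TE_MAX,
    T_C,
    TIMING_TOL,
    b_value,
    total_signal,
)

__all__ = [
    "HardwareConstraints",
    "TissuePrior",
    "DesignResult",
    "fisher_matrix",
    "robust_objective",
    "feasible",
    "sample_prior",
    "ga_optimize",
]

PARAM_ORDER = ("R", "f_i", "D_i", "D_e")


@dataclass(frozen=True)
class HardwareConstraints:
    """Clinical feasibility limits for a PGSE measurement."""

    G_max: float = 80.0
    b_min: float = 150.0
    b_max: float = 5000.0
    TE_max: float = TE_MAX
    T_180: float = 12.0
    T_c: float = T_C
    snr_floor: float = 2.0
    #: SNR (defined at b = 0, TE = 100 ms) assumed for the signal floor.
    nominal_snr: float = 20.0

    def __post_init__(self) -> None:
        if self.b_min >= self.b_max:
            raise ValueError("b_min must be below b_max")
        if min(self.G_max, self.TE_max, self.T_180, self.T_c) <= 0:
            raise ValueError("all hardware limits must be positive")


@dataclass(frozen=True)
class TissuePrior:
    """Uniform prior over plausible tumour microstructures."""

    R: tuple[float, float] = (5.0, 20.0)
    f_i: tuple[float, float] = (0.1, 0.74)
    D_i: tuple[float, float] = (0.5, 3.0)
    D_e: tuple[float, float] = (0.5, 3.0)
    N: int = 100

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        for name in PARAM_ORDER:
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"prior range for {name} must satisfy lo < hi")


@dataclass(frozen=True)
class DesignResult:
    """Outcome of a GA protocol search."""

    protocol: tuple[Measurement, ...]
    objective: float
    repeat_index: int
    history: tuple[float, ...]
    feasibility: tuple[bool, ...]
    repeat_objectives: tuple[float, ...] = ()


def _signal_gradient(
    t: Tissue, protocol, rel_step: float = 1e-3, abs_floor: float = 1e-4
) -> np.ndarray:
    """Central finite-difference gradient of S w.r.t. (R, f_i, D_i, D_e).

    Returns shape (4, n_meas).  The signal includes the exp(-TE/T2) factor.
    Steps are relative (1e-3 of the parameter, floored at 1e-4).
    """
    theta = t.as_array()
    model = _ProtocolModel(protocol)
    steps = np.maximum(rel_step * np.abs(theta), abs_floor)
    thetas = np.repeat(theta[None, :], 8, axis=0)
    for j in range(4):
        thetas[2 * j, j] += steps[j]
        thetas[2 * j + 1, j] -= steps[j]
    sig = model.normalized_signal_batch(thetas)  # (8, K)
    relax = np.exp(-model.TE / t.T2)[None, :]
    sig = sig * relax
    grad = (sig[0::2] - sig[1::2]) / (2.0 * steps[:, None])
    return grad


def fisher_matrix(t: Tissue, protocol, sigma: float) -> np.ndarray:
    """Gaussian-noise Fisher information matrix, shape (4, 4).

    ``sigma`` is the channel noise SD in signal units; |M| therefore scales
    as sigma^-8.  M is symmetric positive semidefinite by construction
    with rank at most the number of measurements.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if len(protocol) == 0:
        raise ValueError("protocol must contain at least one measurement")
    g = _signal_gradient(t, protocol)  # (4, K)
    return (g @ g.T) / (sigma * sigma)


def robust_objective(protocol, prior_draws, sigma: float) -> float:
    """Robust D-criterion f = sum_i -log|M_i| over the prior draws.

    A singular M_i (the protocol cannot identify all four parameters for
    that tissue) contributes +inf.  All draws are pushed through the signal
    model in one batch; per draw this agrees with
    ``-log|fisher_matrix(t, protocol, sigma)|``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    thetas = np.array([t.as_array() for t in prior_draws])  # (N, 4)
    T2s = np.array([t.T2 for t in prior_draws])
    N = len(thetas)
    model = _ProtocolModel(protocol)
    K = len(model.TE)
    steps = np.maximum(1e-3 * np.abs(thetas), 1e-4)
    big = np.repeat(thetas[:, None, :], 8, axis=1)  # (N, 8, 4)
    for j in range(4):
        big[:, 2 * j, j] += steps[:, j]
        big[:, 2 * j + 1, j] -= steps[:, j]
    sig = model.normalized_signal_batch(big.reshape(-1, 4)).reshape(N, 8, K)
    sig = sig * np.exp(-model.TE[None, :] / T2s[:, None])[:, None, :]
    grads = (sig[:, 0::2] - sig[:, 1::2]) / (2.0 * steps[:, :, None])  # (N, 4, K)
    Ms = grads @ grads.transpose(0, 2, 1) / (sigma * sigma)
    signs, logdets = np.linalg.slogdet(Ms)
    if np.any(signs <= 0):
        return math.inf
    return float(-logdets.sum())


def sample_prior(
    prior: TissuePrior, rng: np.random.Generator
) -> tuple[list[Tissue], Tissue]:
    """Draw N tissues uniformly from the prior; also return the median tissue.

    The "average" microstructure is the per-parameter median of the draws.
    """
    draws_arr = np.column_stack(
        [rng.uniform(*getattr(prior, name), size=prior.N) for name in PARAM_ORDER]
    )
    draws = [Tissue(*row) for row in draws_arr]
    med = np.median(draws_arr, axis=0)
    return draws, Tissue(*med)


def _violations(
    m: Measurement, hw: HardwareConstraints, median_tissue: Tissue, sigma: float
) -> list[str]:
    out = []
    b = b_value(m)
    if m.G > hw.G_max:
        out.append(f"G={m.G:.1f} exceeds G_max={hw.G_max}")
    if b < hw.b_min - TIMING_TOL:
        out.append(f"b={b:.0f} below b_min={hw.b_min}")
    if b > hw.b_max:
        out.append(f"b={b:.0f} exceeds b_max={hw.b_max}")
    if m.Delta - m.delta < hw.T_180 - TIMING_TOL:
        out.append(f"Delta-delta={m.Delta - m.delta:.2f} below T_180={hw.T_180}")
    if m.Delta + m.delta > m.TE - hw.T_c + TIMING_TOL:
        out.append("Delta+delta exceeds TE - T_c")
    if m.TE > hw.TE_max + TIMING_TOL:
        out.append(f"TE={m.TE:.1f} exceeds TE_max={hw.TE_max}")
    if total_signal(median_tissue, m) / sigma < hw.snr_floor:
        out.append(f"median-tissue signal below {hw.snr_floor} sigma")
    return out


def feasible(
    m: Measurement, hw: HardwareConstraints, median_tissue: Tissue
) -> tuple[bool, list[str]]:
    """Clinical feasibility of one measurement; returns (ok, violations).

    Timing comparisons carry a 0.1 ms slack so protocols printed to three
    significant figures validate.  The signal floor uses the channel sigma
    implied by ``hw.nominal_snr`` at b = 0, TE = 100 ms.
    """
    sigma = math.exp(-100.0 / median_tissue.T2) / hw.nominal_snr
    v = _violations(m, hw, median_tissue, sigma)
    return (len(v) == 0, v)


# ---------------------------------------------------------------------------
# Genetic algorithm

#: Penalty offset for infeasible individuals; any feasible objective is lower.
_PENALTY = 1.0e8


def _decode(genes: np.ndarray, hw: HardwareConstraints) -> list[Measurement]:
    """Genome -> measurements; timing constraints hold by construction.

    Per measurement the genes are (G, t_sep, frac): ``t_sep = Delta - delta``
    (bounded below by T_180) and ``frac`` sets delta as a fraction of the
    largest duration compatible with ``Delta + delta <= TE_max - T_c``, so
    every decoded measurement satisfies all timing constraints and only the
    b-value range and the SNR floor remain to be penalized.
    """
    room = hw.TE_max - hw.T_c
    ms = []
    for k in range(len(genes) // 3):
        G, t_sep, frac = genes[3 * k : 3 * k + 3]
        delta = frac * (room - t_sep) / 2.0
        ms.append(Measurement(G=G, Delta=t_sep + delta, delta=delta))
    return ms


def _fitness(
    genes: np.ndarray,
    hw: HardwareConstraints,
    prior_draws,
    median_tissue: Tissue,
    sigma: float,
) -> float:
    protocol = _decode(genes, hw)
    # graded penalty for the remaining (non-structural) constraints so the
    # search is guided back toward the feasible region
    viol = 0.0
    for m in protocol:
        b = b_value(m)
        viol += max(0.0, (hw.b_min - b) / hw.b_min)
        viol += max(0.0, (b - hw.b_max) / hw.b_max)
        snr_pred = total_signal(median_tissue, m) / sigma
        viol += max(0.0, (hw.snr_floor - snr_pred) / hw.snr_floor)
    if viol > 0:
        return _PENALTY * (1.0 + viol)
    f = robust_objective(protocol, prior_draws, sigma)
    return _PENALTY / 2.0 if math.isinf(f) else f


def _gene_ranges(hw: HardwareConstraints) -> tuple[np.ndarray, np.ndarray]:
    """Box for the (G, t_sep, frac) genes of one measurement."""
    room = hw.TE_max - hw.T_c
    lo = np.array([0.0, hw.T_180, 0.02])
    hi = np.array([hw.G_max, room - 2.0, 1.0])
    return lo, hi


def ga_optimize(
    hw: HardwareConstraints,
    prior_draws,
    median_tissue: Tissue,
    n_measurements: int = 4,
    population: int = 200,
    generations: int = 60,
    repeats: int = 3,
    rng: np.random.Generator | None = None,
    mutation_scale: float = 0.05,
    tournament: int = 2,
    crossover_rate: float = 0.8,
    polish: bool = True,
) -> DesignResult:
    """Search for a robust D-optimum protocol with a genetic algorithm.

    Runs ``repeats`` independent searches and keeps the repeat with the
    lowest objective.  Each generation applies tournament selection (size
    2), blend crossover, Gaussian mutation (SD annealed from 5% of each
    gene's range) and single-individual elitism; infeasible individuals are
    penalized above any feasible objective, graded by violation magnitude.
    With ``polish`` the winning individual is refined by a bounded simplex
    search on the genome (the GA locates the basin, the polish descends to
    its floor).  Raises if no feasible individual is ever found, reporting
    the constraint violations of the best candidate.
    """
    if population < 10:
        raise ValueError("population must be >= 10")
    rng = rng or np.random.default_rng()
    sigma = math.exp(-100.0 / median_tissue.T2) / hw.nominal_snr
    lo, hi = _gene_ranges(hw)
    n_genes = 3 * n_measurements
    glo = np.tile(lo, n_measurements)
    ghi = np.tile(hi, n_measurements)
    span = ghi - glo

    best_overall = None
    repeat_objectives = []
    for rep in range(repeats):
        pop = glo + span * rng.random((population, n_genes))
        fit = np.array(
            [_fitness(ind, hw, prior_draws, median_tissue, sigma) for ind in pop]
        )
        history = []
        for gen in range(generations):
            # anneal mutation from the full scale down to 1/10 of it: broad
            # exploration early, local refinement late
            scale = mutation_scale * (0.1 ** (gen / max(generations - 1, 1)))
            elite_i = int(np.argmin(fit))
            history.append(float(fit[elite_i]))
            # tournament selection
            contenders = rng.integers(0, population, size=(population, tournament))
            winners = contenders[
                np.arange(population), np.argmin(fit[contenders], axis=1)
            ]
            parents = pop[winners]
            # blend crossover on consecutive pairs
            children = parents.copy()
            for i in range(0, population - 1, 2):
                if rng.random() < crossover_rate:
                    u = rng.random(n_genes)
                    a, b = parents[i], parents[i + 1]
                    children[i] = u * a + (1 - u) * b
                    children[i + 1] = u * b + (1 - u) * a
            # Gaussian mutation
            children += rng.normal(0.0, scale * span, children.shape)
            np.clip(children, glo, ghi, out=children)
            # elitism: carry the best individual through unchanged
            children[0] = pop[elite_i]
            pop = children
            fit = np.array(
                [_fitness(ind, hw, prior_draws, median_tissue, sigma) for ind in pop]
            )
        elite_i = int(np.argmin(fit))
        history.append(float(fit[elite_i]))
        elite_genes = pop[elite_i].copy()
        elite_obj = float(fit[elite_i])
        if polish and elite_obj < _PENALTY / 2.0:
            from scipy.optimize import minimize

            def clipped_fitness(g):
                return _fitness(
                    np.clip(g, glo, ghi), hw, prior_draws, median_tissue, sigma
                )

            res = minimize(
                clipped_fitness,
                elite_genes,
                method="Nelder-Mead",
                options={
                    "xatol": 1e-4,
                    "fatol": 1e-6,
                    "maxiter": 4000,
                    "maxfev": 4000,
                },
            )
            if res.fun < elite_obj:
                elite_genes = np.clip(res.x, glo, ghi)
                elite_obj = float(res.fun)
                history.append(elite_obj)
        repeat_objectives.append(elite_obj)
        if best_overall is None or elite_obj < best_overall[1]:
            best_overall = (elite_genes, elite_obj, rep, history)

    genes, obj, rep, history = best_overall
    if obj >= _PENALTY / 2.0:
        protocol = _decode(genes, hw)
        diag = [v for m in protocol for v in _violations(m, hw, median_tissue, sigma)]
        raise RuntimeError(
            "GA found no feasible protocol; best candidate violations: "
            + "; ".join(diag or ["parameters not identifiable (singular M)"])
        )
    protocol = tuple(_decode(genes, hw))
    feas = tuple(feasible(m, hw, median_tissue)[0] for m in protocol)
    return DesignResult(
        protocol=protocol,
        objective=obj,
        repeat_index=rep,
        history=tuple(history),
        feasibility=feas,
        repeat_objectives=tuple(repeat_objectives),
    )
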