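"""Batched Nelder-Mead simplex minimization.

Runs many independent Nelder-Mead searches in lock-step so the objective is
evaluated on large batches of points at once.  This is what makes multistart
ML fitting of thousands of noisy signal vectors tractable: the per-point
cost of a vectorized model evaluation is orders of magnitude below that of
a scalar one.

The update rule is the standard simplex algorithm (reflection, expansion,
outside/inside contraction, shrink) with the usual coefficients
rho = 1, chi = 2, psi = 0.5, sigma = 0.5.  All candidate points for one
iteration are evaluated in a single call; converged problems are compacted
out of the active set.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["batched_nelder_mead"]


def _initial_simplex(x0: np.ndarray) -> np.ndarray:
    """Simplex around each start: per-dimension 5% perturbation (0.00025 at 0)."""
    B, n = x0.shape
    sim = np.repeat(x0[:, None, :], n + 1, axis=1)
    for j in range(n):
        col = sim[:, j + 1, j]
        sim[:, j + 1, j] = np.where(col != 0.0, col * 1.05, 0.00025)
    return sim


def batched_nelder_mead(
    func: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    xatol: float = 1e-6,
    fatol: float = 1e-6,
    maxiter: int = 1000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Minimize ``func`` from every row of ``x0`` simultaneously.

    Parameters
    ----------
    func : callable
        ``func(points, problem_idx) -> values``: maps points ``(P, n)``
        with their owning problem indices ``(P,)`` (into the original batch)
        to objective values ``(P,)``.  Must be vectorized over the leading
        axis; the indices let each problem evaluate against its own data.
    x0 : ndarray, shape (B, n)
        One starting point per problem.
    xatol, fatol : float
        Convergence: the simplex is converged when the largest coordinate
        spread and the largest objective spread both fall below these.
    maxiter : int
        Iteration cap per problem.

    Returns
    -------
    x_best : ndarray (B, n), f_best : ndarray (B,), converged : ndarray (B,) bool
    """
    x0 = np.asarray(x0, dtype=float)
    if x0.ndim != 2:
        raise ValueError("x0 must be 2-D (problems x parameters)")
    B, n = x0.shape
    sim = _initial_simplex(x0)
    f = func(sim.reshape(-1, n), np.repeat(idx0 := np.arange(B), n + 1)).reshape(B, n + 1)

    out_x = np.empty((B, n))
    out_f = np.full(B, np.inf)
    out_conv = np.zeros(B, dtype=bool)
    idx = idx0  # original indices of the active problems

    for _ in range(maxiter):
        order = np.argsort(f, axis=1)
        f = np.take_along_axis(f, order, axis=1)
        sim = np.take_along_axis(sim, order[:, :, None], axis=1)

        conv = (f[:, -1] - f[:, 0] <= fatol) & (
            np.max(np.abs(sim[:, 1:] - sim[:, :1]), axis=(1, 2)) <= xatol
        )
        if conv.any():
            done = idx[conv]
            out_x[done] = sim[conv, 0]
            out_f[done] = f[conv, 0]
            out_conv[done] = True
            keep = ~conv
            if not keep.any():
                return out_x, out_f, out_conv
            sim, f, idx = sim[keep], f[keep], idx[keep]

        centroid = sim[:, :-1].mean(axis=1)
        worst = sim[:, -1]
        diff = centroid - worst
        # candidates: reflection, expansion, outside & inside contraction
        cand = np.stack(
            [
                centroid + diff,
                centroid + 2.0 * diff,
                centroid + 0.5 * diff,
                centroid - 0.5 * diff,
            ],
            axis=1,
        )
        m = sim.shape[0]
        fc = func(cand.reshape(-1, n), np.repeat(idx, 4)).reshape(m, 4)
        fr, fe, foc, fic = fc[:, 0], fc[:, 1], fc[:, 2], fc[:, 3]

        expand = fr < f[:, 0]
        use_e = expand & (fe < fr)
        reflect = ~expand & (fr < f[:, -2])
        out_c = ~expand & ~reflect & (fr < f[:, -1])
        oc_ok = out_c & (foc <= fr)
        in_c = ~expand & ~reflect & ~out_c
        ic_ok = in_c & (fic < f[:, -1])
        shrink = (out_c & ~oc_ok) | (in_c & ~ic_ok)

        choice = np.zeros(m, dtype=int)  # default reflection
        choice[use_e] = 1
        choice[oc_ok] = 2
        choice[ic_ok] = 3
        rows = np.arange(m)
        replace = ~shrink
        sim[replace, -1] = cand[rows[replace], choice[replace]]
        f[replace, -1] = fc[rows[replace], choice[replace]]

        if shrink.any():
            sub = np.flatnonzero(shrink)
            shrunk = sim[sub, :1] + 0.5 * (sim[sub, 1:] - sim[sub, :1])
            sim[sub, 1:] = shrunk
            f[sub, 1:] = func(
                shrunk.reshape(-1, n), np.repeat(idx[sub], n)
            ).reshape(len(sub), n)

    # maxiter exhausted for the remainder: report current best, unconverged
    order = np.argsort(f, axis=1)
    f = np.take_along_axis(f, order, axis=1)
    sim = np.take_along_axis(sim, order[:, :, None], axis=1)
    out_x[idx] = sim[:, 0]
    out_f[idx] = f[:, 0]
    return out_x, out_f, out_conv
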