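"""Shuffled Complex Evolution (SCE-UA) global optimizer.

The population is sampled uniformly in the bound box, sorted, and dealt
into complexes; each complex evolves by the competitive complex evolution
(CCE) step — a sub-simplex chosen with triangular selection probability
attempts a reflection of its worst point through the centroid, falling back
to a contraction and finally to a random replacement — after which the
complexes are shuffled together.  Convergence is declared when the best
objective value improves by less than a relative tolerance over a window of
shuffling loops, or the evaluation budget is exhausted.  Fully
deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = ["SceUaSettings", "SceUaResult", "sceua_minimize"]


@dataclass(frozen=True)
class SceUaSettings:
    """Optimizer controls.

    ``n_complexes`` complexes of ``points_per_complex`` points (default
    2·ndim+1).  The run stops when the relative change of the best
    objective over ``kstop`` consecutive shuffling loops drops below
    ``tol``, or after ``max_evaluations`` objective calls.
    """

    n_complexes: int = 4
    points_per_complex: int | None = None   # default 2*ndim + 1
    max_evaluations: int = 10_000
    tol: float = 1e-5
    kstop: int = 10


@dataclass
class SceUaResult:
    x: np.ndarray
    fun: float
    n_evaluations: int
    n_loops: int
    converged: bool
    trace: list


def sceua_minimize(
    objective: Callable[[np.ndarray], float],
    bounds: Sequence[tuple],
    settings: SceUaSettings = SceUaSettings(),
    seed: int | np.random.SeedSequence = 0,
) -> SceUaResult:
    """Minimize ``objective`` over a bound box with SCE-UA.

    Parameters
    ----------
    objective : callable
        Maps a parameter vector to a finite float (non-finite values are
        treated as +inf; if more than half the initial population is
        non-finite the problem is rejected).
    bounds : sequence of (low, high)
        Finite box constraints, one pair per dimension.

    Returns
    -------
    SceUaResult with the best point found, its objective value and run
    statistics (``trace`` holds the best value after each shuffling loop).
    """
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi)) and np.all(hi > lo)):
        raise ValueError("bounds must be finite with high > low")
    ndim = len(bounds)
    ngs = settings.n_complexes
    npg = settings.points_per_complex or (2 * ndim + 1)
    nps = ndim + 1          # sub-simplex size
    nspl = npg              # evolution steps per complex per loop
    pop_size = ngs * npg

    rng = np.random.default_rng(seed)
    n_eval = 0

    def f(x):
        nonlocal n_eval
        n_eval += 1
        v = objective(x)
        return float(v) if np.isfinite(v) else np.inf

    X = lo + rng.random((pop_size, ndim)) * (hi - lo)
    F = np.array([f(x) for x in X])
    if np.sum(~np.isfinite(F)) > pop_size / 2:
        raise ValueError("objective non-finite on more than half of the initial points")

    order = np.argsort(F, kind="stable")
    X, F = X[order], F[order]

    # triangular selection probabilities within a complex
    probs = 2.0 * (npg - np.arange(npg)) / (npg * (npg + 1))
    trace = [F[0]]
    loop = 0
    converged = False

    while n_eval < settings.max_evaluations:
        loop += 1
        for ig in range(ngs):
            cidx = np.arange(ig, pop_size, ngs)   # systematic deal
            cx, cf = X[cidx].copy(), F[cidx].copy()
            for _ in range(nspl):
                sel = rng.choice(npg, size=nps, replace=False, p=probs)
                sel = sel[np.argsort(cf[sel], kind="stable")]
                worst = sel[-1]
                centroid = cx[sel[:-1]].mean(axis=0)
                # reflection
                cand = 2.0 * centroid - cx[worst]
                if np.any(cand < lo) or np.any(cand > hi):
                    cand = lo + rng.random(ndim) * (hi - lo)
                fc = f(cand)
                if fc >= cf[worst]:
                    # contraction
                    cand = 0.5 * (centroid + cx[worst])
                    fc = f(cand)
                    if fc >= cf[worst]:
                        cand = lo + rng.random(ndim) * (hi - lo)
                        fc = f(cand)
                if fc < cf[worst]:
                    cx[worst], cf[worst] = cand, fc
                res = np.argsort(cf, kind="stable")
                cx, cf = cx[res], cf[res]
                if n_eval >= settings.max_evaluations:
                    break
            X[cidx], F[cidx] = cx, cf
            if n_eval >= settings.max_evaluations:
                break
        order = np.argsort(F, kind="stable")
        X, F = X[order], F[order]
        trace.append(F[0])
        if len(trace) > settings.kstop:
            past = trace[-settings.kstop - 1]
            denom = max(abs(past), abs(trace[-1]), 1e-12)
            if (past - trace[-1]) / denom < settings.tol:
                converged = True
                break

    return SceUaResult(
        x=X[0].copy(), fun=float(F[0]), n_evaluations=n_eval,
        n_loops=loop, converged=converged, trace=trace,
    )
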