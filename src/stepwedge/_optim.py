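"""Shared derivative-free least-squares driver.

Both profile models (the 19-parameter schematic step-wedge profile and the
modified-Gaussian transverse peak) are fitted with the same scheme: a
multi-start Nelder-Mead simplex search of the summed squared residual,
followed by repeated simplex polish from the incumbent until the objective
stops improving.  The restart randomisation is seeded, so fits are
reproducible.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize


def multistart_nelder_mead(
    objective: Callable[[np.ndarray], float],
    starts: Sequence[np.ndarray],
    maxfev: int = 20_000,
    xatol: float = 1e-3,
    frtol: float = 1e-10,
    polish_rounds: int = 5,
) -> tuple[np.ndarray, float, int]:
    """Minimise ``objective`` from several start points; polish the best.

    ``frtol`` is a relative function tolerance: the absolute ``fatol``
    handed to the simplex is ``frtol`` times the objective at the first
    start, so convergence behaviour does not depend on the data scale.

    Returns ``(x_best, f_best, n_starts)``.
    """
    starts = [np.asarray(s, dtype=float) for s in starts]
    f0 = float(objective(starts[0]))
    fatol = max(frtol * abs(f0), 1e-300)

    best_x, best_f = None, np.inf
    for s in starts:
        res = minimize(
            objective,
            s,
            method="Nelder-Mead",
            options={
                "maxfev": maxfev,
                "xatol": xatol,
                "fatol": fatol,
                "adaptive": True,
            },
        )
        if res.fun < best_f:
            best_x, best_f = res.x, float(res.fun)

    # Deep polish: fresh simplexes from the incumbent until the objective
    # stops improving beyond numerical noise.
    for _ in range(polish_rounds):
        res = minimize(
            objective,
            best_x,
            method="Nelder-Mead",
            options={
                "maxfev": min(maxfev, 6000),
                "xatol": 1e-8,
                "fatol": max(1e-14 * abs(f0), 1e-300),
                "adaptive": True,
            },
        )
        improved = best_f - res.fun
        if res.fun < best_f:
            best_x, best_f = res.x, float(res.fun)
        if improved <= 1e-12 * max(abs(best_f), 1e-12 * abs(f0)):
            break
    return np.asarray(best_x, dtype=float), best_f, len(starts)


def r_squared(sse: float, y: np.ndarray) -> float:
    """Coefficient of determination about the sample mean, clipped to [0, 1]."""
    y = np.asarray(y, dtype=float)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 0:
        return 0.0
    return float(np.clip(1.0 - sse / ss_tot, 0.0, 1.0))
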