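"""Microdialysis recovery and interval-average sampling semantics.

A push-pull probe returns dialysate whose concentration is a fixed
fraction (the in-vitro relative recovery) of the surrounding medium;
dividing by that recovery maps dialysate measurements back to ISF
concentrations.  Dialysate samples are collected over intervals, so the
model counterpart of a sample is the time-average of the compartment
concentration over the collection window, stamped at the midpoint.
"""

from __future__ import annotations

import numpy as np

__all__ = ["recovery_from_beaker", "apply_recovery", "window_average_sampling"]


def recovery_from_beaker(dialysate, beaker) -> float:
    """In-vitro relative recovery: mean dialysate / mean beaker concentration."""
    dialysate = np.asarray(dialysate, dtype=float)
    beaker = np.asarray(beaker, dtype=float)
    if dialysate.size == 0 or beaker.size == 0:
        raise ValueError("dialysate and beaker series must be non-empty")
    if np.any(dialysate < 0) or np.any(beaker < 0):
        raise ValueError("concentrations must be non-negative")
    b = beaker.mean()
    if b <= 0:
        raise ValueError("beaker mean concentration must be positive")
    return float(dialysate.mean() / b)


def apply_recovery(dialysate_conc, recovery: float):
    """Convert dialysate concentration(s) to ISF scale: conc / recovery."""
    if not 0.0 < recovery <= 1.0:
        raise ValueError(f"recovery must lie in (0, 1], got {recovery!r}")
    arr = np.asarray(dialysate_conc, dtype=float) / recovery
    return float(arr) if arr.ndim == 0 else arr


def window_average_sampling(
    sim,
    compartment: str,
    windows,
    recovery: float = 1.0,
):
    """Emulate interval dialysate collection from a simulation.

    Returns ``(midpoints, dialysate_conc)`` where each dialysate value is
    ``recovery`` times the time-average of the compartment concentration
    over the window.  Windows must be ascending and non-overlapping and
    lie within the simulated span.
    """
    if not 0.0 < recovery <= 1.0:
        raise ValueError(f"recovery must lie in (0, 1], got {recovery!r}")
    windows = [(float(a), float(b)) for a, b in windows]
    t, c = sim.t, sim.conc(compartment)
    prev_end = -np.inf
    mids, vals = [], []
    for a, b in windows:
        if b <= a:
            raise ValueError(f"degenerate window ({a}, {b})")
        if a < prev_end:
            raise ValueError("windows must be ascending and non-overlapping")
        if a < t[0] or b > t[-1]:
            raise ValueError(f"window ({a}, {b}) outside simulated span")
        prev_end = b
        inner = t[(t > a) & (t < b)]
        grid = np.concatenate([[a], inner, [b]])
        conc = np.interp(grid, t, c)
        vals.append(recovery * np.trapezoid(conc, grid) / (b - a))
        mids.append(0.5 * (a + b))
    return np.asarray(mids), np.asarray(vals)
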