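"""Timescale decomposition and non-dimensional peak analysis.

The concentration history of a solute in a vascularized tissue is governed
by three solute-dependent timescales: the modified input timescale
``n * tau * (L/d)``, the diffusion timescale ``L^2 / D_tissue`` and the
wall-sink decay timescale ``1/k`` with ``k = P_d * S``.  Time is
non-dimensionalized by their sum,

    T* = t / (n tau L/d + L^2/D_tissue + 1/k),

and the normalized concentration is rescaled as

    C* = c_norm * (rho / (phi * Mw)) * (L/d) / Co,

with Mw in kg/mol.  The convection scale ``L/Uo`` is computed for logging
but deliberately excluded from the T* denominator.  Across configurations,
solute sizes and flow arrangements the peak tissue concentration occurs at
a narrow band of T* (the study's headline invariant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import sink_density
from .params import GeometryConfig, SoluteSpec, TissueSpec
from .solver import ConcentrationHistory, effective_diffusivity

__all__ = [
    "TimescaleSet",
    "NondimHistory",
    "compute_timescales",
    "nondimensionalize",
    "parabolic_peak",
    "aggregate_t_peak",
]

#: L/d at or above which runs are flagged as outlier candidates: at such
#: separations the second vessel no longer influences the measurement
#: station and the non-dimensionalization overcounts its timescales.
LD_OUTLIER = 125.0


@dataclass(frozen=True)
class TimescaleSet:
    """The three solute-dependent timescales and their sum (all seconds)."""

    tau_input_scaled: float   # n * tau * (L/d)
    tau_diff: float           # L^2 / D_tissue
    tau_decay: float          # 1 / (P_d * S)
    u0_scale: float | None = None   # reference interstitial velocity (m/s), logged only

    def __post_init__(self):
        for v in (self.tau_input_scaled, self.tau_diff, self.tau_decay):
            if not v > 0:
                raise ValueError("all timescales must be > 0")

    @property
    def t_star_denominator(self) -> float:
        return self.tau_input_scaled + self.tau_diff + self.tau_decay


def compute_timescales(
    s: SoluteSpec,
    g: GeometryConfig,
    t: TissueSpec,
    u0_scale: float | None = None,
) -> TimescaleSet:
    """Input, diffusion and decay timescales for one solute in one geometry."""
    d = g.vessels[0].d
    sink = sink_density(g, s)
    return TimescaleSet(
        tau_input_scaled=g.n * s.tau_in * (g.L / d),
        tau_diff=g.L**2 / effective_diffusivity(s, t),
        tau_decay=1.0 / sink.k_decay,
        u0_scale=u0_scale,
    )


def parabolic_peak(t: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Peak location/value by parabolic interpolation through the discrete
    maximum and its neighbors.

    Returns ``(t_peak, y_peak, bracketed)``; ``bracketed`` is False when the
    maximum sits on the first or last sample (the true peak may lie outside
    the record).
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if t.size < 3:
        i = int(np.argmax(y))
        return float(t[i]), float(y[i]), False
    i = int(np.argmax(y))
    if i == 0 or i == t.size - 1:
        return float(t[i]), float(y[i]), False
    t0, t1, t2 = t[i - 1], t[i], t[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (t0 - t1) * (t0 - t2) * (t1 - t2)
    a = (t2 * (y1 - y0) + t1 * (y0 - y2) + t0 * (y2 - y1)) / denom
    b = (t2**2 * (y0 - y1) + t1**2 * (y2 - y0) + t0**2 * (y1 - y2)) / denom
    if a >= 0:   # flat or degenerate: fall back to the discrete maximum
        return float(t1), float(y1), True
    tp = -b / (2 * a)
    tp = min(max(tp, t0), t2)
    c = y1 - a * t1**2 - b * t1
    return float(tp), float(a * tp**2 + b * tp + c), True


@dataclass
class NondimHistory:
    """Non-dimensional concentration history of one run."""

    t_star: np.ndarray
    c_star: np.ndarray
    t_star_peak: float
    c_star_peak: float
    excluded: bool            # L/d outlier-candidate flag (L/d >= 125)
    peak_bracketed: bool
    timescales: TimescaleSet

    def __post_init__(self):
        if np.any(np.diff(self.t_star) <= 0):
            raise ValueError("t_star must be strictly increasing")


def nondimensionalize(
    h: ConcentrationHistory,
    ts: TimescaleSet,
    s: SoluteSpec,
    g: GeometryConfig,
    metric: str = "volume",
) -> NondimHistory:
    """Rescale a concentration history to (T*, C*) and extract its peak."""
    denom = ts.t_star_denominator
    c_norm = h.series(metric)
    d = g.vessels[0].d
    scale = (s.rho / (g_phi(h) * s.mw)) * (g.L / d) / s.c0
    t_star = h.time_s / denom
    c_star = c_norm * scale
    tp, cp, bracketed = parabolic_peak(h.time_s, c_norm)
    ld = g.L / d
    return NondimHistory(
        t_star=t_star,
        c_star=c_star,
        t_star_peak=tp / denom,
        c_star_peak=cp * scale,
        excluded=bool(ld >= LD_OUTLIER * (1.0 - 1e-9)),
        peak_bracketed=bracketed and h.peak_bracketed,
        timescales=ts,
    )


def g_phi(h: ConcentrationHistory) -> float:
    """Tissue porosity recorded with a run (fallback: baseline 0.4)."""
    return float(h.metadata.get("phi", 0.4))


def aggregate_t_peak(
    runs: list[NondimHistory],
    exclude_ld125: bool = False,
) -> tuple[float, float]:
    """Mean and population standard deviation of T*_peak over a run set.

    With ``exclude_ld125`` the L/d >= 125 outlier candidates (flagged on
    each run) are dropped before aggregating.
    """
    if not runs:
        raise ValueError("aggregate_t_peak requires at least one run")
    vals = [r.t_star_peak for r in runs if not (exclude_ld125 and r.excluded)]
    if not vals:
        raise ValueError("no runs left after excluding L/d outliers")
    arr = np.asarray(vals)
    return float(arr.mean()), float(arr.std(ddof=0))
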