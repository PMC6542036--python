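"""Synthetic stand-in for the in vitro validation measurements.

The fabricated vascularized tissue platform (one 715 um channel in a
3000 um collagen tissue) was perfused with fluorescent dextran; the
normalized intensity, spatially averaged at a radial station of 600 um and
observed over 2 h in N=3 replicate samples, corresponds to the normalized
concentration of the transport model.  No raw data exist, so this module
*generates* pseudo-experimental replicate curves from the forward model
itself: a ground-truth parameter set is drawn uniformly within the measured
[min, max] ranges and multiplicative Gaussian noise emulates the
sample-to-sample variability.  Everything is reproducible bit-for-bit from
(seed, parameters).

The platform is modeled as a pressure-equilibrated diffusion system: the
channel carries a constant normalized concentration (continuous perfusion),
wall exchange is scaled by the measured endothelial (vascular) porosity,
and the measured solute diffusivity acts directly as the effective tissue
diffusivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .geometry import make_geometry
from .params import InVitroPlatform, SoluteSpec, TissueSpec, VesselSpec, invitro_platform
from .solver import SolverOptions, run_simulation

__all__ = [
    "InVitroDraw",
    "PseudoObservationSet",
    "draw_invitro_params",
    "simulate_invitro",
    "generate_observations",
    "envelope_validation",
    "fit_transport_params",
]

#: Radial measurement station (m), from the channel axis.
STATION_RADIUS = 600e-6

#: Observation window (s) and sampling cadence (s).
OBS_DURATION = 2.0 * 3600.0
OBS_DT = 60.0


@dataclass(frozen=True)
class InVitroDraw:
    """One ground-truth parameter draw for the platform forward model."""

    mw: float
    phi: float        # tissue porosity
    eps_v: float      # vascular (endothelial) porosity
    d_f: float        # solute diffusivity in the tissue, m^2/s
    p_d: float        # wall solute permeability, m/s


def draw_invitro_params(
    mw: float,
    seed: int,
    platform: InVitroPlatform | None = None,
) -> InVitroDraw:
    """Uniform draw of (phi, eps_v, D_f, P_d) within the measured ranges."""
    platform = platform or invitro_platform()
    sol = platform.solute(mw)
    rng = np.random.default_rng(seed)
    lo_phi, _, hi_phi = platform.tissue_porosity
    lo_e, _, hi_e = platform.vascular_porosity
    return InVitroDraw(
        mw=float(mw),
        phi=float(rng.uniform(lo_phi, hi_phi)),
        eps_v=float(rng.uniform(lo_e, hi_e)),
        d_f=float(rng.uniform(sol.d_f[0], sol.d_f[2])),
        p_d=float(rng.uniform(sol.p_d[0], sol.p_d[2])),
    )


def _forward_options(nr: int = 48, nz: int = 4) -> SolverOptions:
    return SolverOptions(
        nr=nr, nz=nz, dt=OBS_DT / 6.0, output_dt=OBS_DT, duration=OBS_DURATION,
        inlet_mode="constant", no_flow=True, prescribed_lumen=True,
    )


def simulate_invitro(
    draw: InVitroDraw,
    platform: InVitroPlatform | None = None,
    nr: int = 48,
) -> tuple[np.ndarray, np.ndarray]:
    """Clean normalized concentration at the 600 um station vs time.

    Returns ``(time_s, c_norm)`` on the observation grid.
    """
    platform = platform or invitro_platform()
    tissue = TissueSpec(phi=draw.phi, k_hyd=platform.kappa_hyd / 1e-3, p0=0.0)
    vessel = VesselSpec(
        kind="blood", d=platform.d, length=platform.length,
        lp=1e-12, p_arteriole=0.0, dp=0.0, dpi_osm=0.0,
    )
    solute = SoluteSpec(
        mw=draw.mw, d_h=1.0, sigma=0.0, p_d=draw.p_d, d_f=draw.d_f,
        r_f=1.0, c0=1.0, tau_in=1.0,
    )
    geom = make_geometry("SBC", D=platform.D, vessel=vessel, layout="axisym")
    opts = _forward_options(nr=nr)
    # the platform measures D_f in the gel directly: use it as D_tissue
    opts.d_tissue = draw.d_f
    opts.vascular_porosity = draw.eps_v
    opts.station_frac = (STATION_RADIUS - platform.d / 2.0) / geom.L
    h = run_simulation(geom, solute, tissue, options=opts)
    return h.time_s, h.c_norm_surface


@dataclass
class PseudoObservationSet:
    """N replicate pseudo-experimental curves with known ground truth."""

    mw: float
    time_s: np.ndarray
    replicates: np.ndarray        # (n_rep, n_times)
    clean: np.ndarray             # noise-free forward curve
    truth: InVitroDraw
    noise_cv: float
    seed: int

    @property
    def replicate_mean(self) -> np.ndarray:
        return self.replicates.mean(axis=0)


def generate_observations(
    params: InVitroDraw,
    noise_cv: float = 0.10,
    n_rep: int = 3,
    seed: int = 0,
    platform: InVitroPlatform | None = None,
) -> PseudoObservationSet:
    """Forward-simulate the platform and apply multiplicative Gaussian noise.

    Each replicate sample is ``clean * (1 + noise_cv * N(0,1))``, clipped at
    zero (intensities are non-negative).
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    t, clean = simulate_invitro(params, platform)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_rep, t.size))
    reps = np.clip(clean[None, :] * (1.0 + noise_cv * noise), 0.0, None)
    return PseudoObservationSet(
        mw=params.mw, time_s=t, replicates=reps, clean=clean,
        truth=params, noise_cv=noise_cv, seed=seed,
    )


def envelope_validation(
    obs: PseudoObservationSet,
    platform: InVitroPlatform | None = None,
) -> tuple[bool, float]:
    """Check the replicate mean against the min/max parameter envelope.

    Simulates the forward model with the parameter combinations bounding the
    curve from below (lowest permeability/diffusivity/endothelial porosity,
    highest tissue porosity) and above, and reports the fraction of
    replicate-mean samples falling inside the band.  Passes at >= 90%
    coverage.
    """
    platform = platform or invitro_platform()
    sol = platform.solute(obs.mw)
    lo = InVitroDraw(mw=obs.mw, phi=platform.tissue_porosity[2],
                     eps_v=platform.vascular_porosity[0],
                     d_f=sol.d_f[0], p_d=sol.p_d[0])
    hi = InVitroDraw(mw=obs.mw, phi=platform.tissue_porosity[0],
                     eps_v=platform.vascular_porosity[2],
                     d_f=sol.d_f[2], p_d=sol.p_d[2])
    _, c_lo = simulate_invitro(lo, platform)
    _, c_hi = simulate_invitro(hi, platform)
    mean = obs.replicate_mean
    tol = 1e-12
    inside = (mean >= c_lo - tol) & (mean <= c_hi + tol)
    coverage = float(inside.mean())
    return coverage >= 0.90, coverage


def fit_transport_params(
    time_s: np.ndarray,
    c_norm: np.ndarray,
    mw: float,
    start: InVitroDraw | None = None,
    platform: InVitroPlatform | None = None,
) -> InVitroDraw:
    """Least-squares refit of (P_d, D_f) from an observed station curve.

    Porosities are held at the platform means (they are measured
    independently on the platform); permeability and diffusivity are
    identified in log-space from the curve shape.
    """
    platform = platform or invitro_platform()
    sol = platform.solute(mw)
    if start is None:
        start = InVitroDraw(mw=mw, phi=platform.tissue_porosity[1],
                            eps_v=platform.vascular_porosity[1],
                            d_f=sol.d_f[1], p_d=sol.p_d[1])

    def resid(x):
        draw = InVitroDraw(mw=mw, phi=start.phi, eps_v=start.eps_v,
                           d_f=float(np.exp(x[1])), p_d=float(np.exp(x[0])))
        _, c = simulate_invitro(draw, platform)
        return c - c_norm

    x0 = np.log([start.p_d, start.d_f])
    res = least_squares(resid, x0, xtol=1e-10, ftol=1e-10, diff_step=1e-4)
    return InVitroDraw(mw=mw, phi=start.phi, eps_v=start.eps_v,
                       d_f=float(np.exp(res.x[1])), p_d=float(np.exp(res.x[0])))
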