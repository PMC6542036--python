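"""Coupled lumen / wall / interstitium transport solver.

The reduced model commits to the classical trio of intravascular Poiseuille
flow, Starling transmural filtration and interstitial Darcy flow, with
Kedem-Katchalsky coupling for the solute:

* luminal 1-D advection with an exponentially decaying inlet bolus
  ``c_in(t) = Co * exp(-t / tau)``,
* transmural fluid flux ``Jv = Lp (p_v - p_i - sigma * dPi)`` (blood walls;
  lymph walls drain one-way only) and solute flux
  ``Js = P_d (c_v - c_i) + (1 - sigma) Jv c_upwind``,
* steady Darcy interstitial pressure/velocity (quasi-static, solved once),
* interstitial convection-diffusion with the vessel walls as resolved,
  localized sources/sinks (the homogenized first-order sink ``-k c`` of the
  volume-averaged balance is recovered in the well-mixed limit).

Time integration is monolithic implicit Euler on the coupled tissue+lumen
system.  Under the quasi-static fluid assumption the operator is linear and
time-invariant, so the matrix is LU-factored once per run and each step is a
single back-substitution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import ENVELOPE, Grid, build_grid
from .params import GeometryConfig, SoluteSpec, TissueSpec, VesselSpec

__all__ = [
    "TransportCoeffs",
    "FieldState",
    "ConcentrationHistory",
    "SolverOptions",
    "PerfusionModel",
    "effective_diffusivity",
    "solve_lumen_flow",
    "transmural_fluid_flux",
    "transmural_solute_flux",
    "solve_interstitial_pressure",
    "run_simulation",
]


def effective_diffusivity(s: SoluteSpec, t: TissueSpec) -> float:
    """Effective interstitial diffusivity ``D_tissue = phi * R_F * D_f`` (m^2/s)."""
    return t.phi * s.r_f * s.d_f


@dataclass(frozen=True)
class TransportCoeffs:
    """Interstitial transport coefficients for one solute/tissue pair."""

    d_tissue: float   # m^2/s
    k_decay: float    # 1/s (homogenized wall-sink constant)

    def __post_init__(self):
        if self.d_tissue <= 0:
            raise ValueError("d_tissue must be > 0")


def solve_lumen_flow(v: VesselSpec, nz: int = 1) -> tuple[np.ndarray, float]:
    """Luminal pressure profile and mean velocity of a vessel.

    Returns ``(p_lumen, U)`` with ``p_lumen`` evaluated at ``nz`` axial cell
    centers (ordered along +z) and ``U`` the signed mean axial velocity from
    Poiseuille flow, ``|U| = dP d^2 / (32 mu l)``.  Lymph vessels carry a
    constant luminal pressure and no prescribed axial flow.
    """
    zc = (np.arange(nz) + 0.5) / nz  # fractional position along +z
    if v.kind == "lymph":
        return np.full(nz, float(v.p_arteriole)), 0.0
    u = v.dp * v.d**2 / (32.0 * v.mu_eff * v.length)
    s = (zc if v.flow_sign > 0 else 1.0 - zc)  # fraction of drop traversed
    return v.p_arteriole - v.dp * s, v.flow_sign * u


def transmural_fluid_flux(p_v: float, p_i: float, v: VesselSpec, s: SoluteSpec) -> float:
    """Starling transmural fluid flux, m/s, positive out of the lumen.

    Blood walls: ``Jv = Lp (p_v - p_i - sigma * dPi_osm)``.  Lymph walls are
    one-way drains: ``Jv = min(0, Lp (p_v - p_i))``.
    """
    if v.kind == "lymph":
        return min(0.0, v.lp * (p_v - p_i))
    return v.lp * (p_v - p_i - s.sigma * v.dpi_osm)


def transmural_solute_flux(
    jv: float,
    c_v: float,
    c_i: float,
    s: SoluteSpec,
    *,
    lymph: bool = False,
    p_d_lymph: float | None = None,
) -> float:
    """Kedem-Katchalsky transmural solute flux, mol/(m^2 s), positive outward.

    Blood walls: ``Js = P_d (c_v - c_i) + (1 - sigma) Jv c_up`` with the
    upwinded carrier concentration.  Lymph walls drain convectively
    (``Jv <= 0``) with an elevated diffusive escape ``P_d_lymph (0 - c_i)``.
    """
    if lymph:
        pdl = s.p_d * 10.0 if p_d_lymph is None else p_d_lymph
        return min(0.0, jv) * c_i - pdl * c_i
    c_up = c_v if jv > 0 else c_i
    return s.p_d * (c_v - c_i) + (1.0 - s.sigma) * jv * c_up


@dataclass
class FieldState:
    """Discrete state of one run at time ``t``."""

    t: float
    c_tissue: np.ndarray                 # (n_cells,) mol/m^3
    c_lumen: list[np.ndarray]            # per blood vessel, (nz,)
    p_tissue: np.ndarray                 # (n_cells,) Pa
    p_lumen: list[np.ndarray]            # per vessel, (nz,)


@dataclass
class ConcentrationHistory:
    """Normalized concentration time series of one run.

    ``c_norm_volume`` is the volume-averaged extravascular concentration in
    the tissue surrounding the blood capillary(ies); ``c_norm_surface`` is
    the surface-averaged concentration at a radial distance ``0.2 L`` from
    the blood-vessel wall.  Both are normalized by the maximum intravascular
    concentration (the inlet concentration Co).
    """

    time_s: np.ndarray
    c_norm_volume: np.ndarray
    c_norm_surface: np.ndarray
    metadata: dict = field(default_factory=dict)
    peak_bracketed: bool = True
    ledger: dict = field(default_factory=dict)

    def series(self, metric: str) -> np.ndarray:
        if metric == "volume":
            return self.c_norm_volume
        if metric == "surface":
            return self.c_norm_surface
        raise ValueError(f"unknown metric {metric!r}")


@dataclass
class SolverOptions:
    """Numerical profile and model switches."""

    nr: int = 40
    nz: int = 40
    dt: float = 0.5                  # s
    output_dt: float = 6.0           # s
    duration: float = 4.0 * 3600.0   # s
    station_frac: float = 0.2        # surface station at station_frac * L from the wall
    volume_region: str = "all"       # "all": whole extravascular space;
                                     # "blood": Voronoi region of the blood vessel(s)
    lymph_pd_factor: float = 10.0    # lymph wall P_d as multiple of solute P_d
    inlet_mode: str = "exp"          # "exp" | "constant" | "off"
    prescribed_lumen: bool = False   # well-perfused lumen held at c_in(t)
    no_flow: bool = False            # disable all fluid motion (pure diffusion)
    outer_pressure_bc: str = "dirichlet"   # "dirichlet" | "noflux"
    d_tissue: float | None = None    # override effective diffusivity (m^2/s)
    c_tissue0: float = 0.0           # initial interstitial concentration
    vascular_porosity: float = 1.0   # scales wall exchange area (in vitro walls)
    negative_tol: float = 1e-9       # abort threshold on negative concentration


class PerfusionModel:
    """Assembled transport operator for one (geometry, solute, tissue) triple."""

    def __init__(
        self,
        geometry: GeometryConfig,
        solute: SoluteSpec,
        tissue: TissueSpec,
        options: SolverOptions | None = None,
        grid: Grid | None = None,
    ):
        self.geometry = geometry
        self.solute = solute
        self.tissue = tissue
        self.opt = options or SolverOptions()
        self.grid = grid or build_grid(geometry, self.opt.nr, self.opt.nz)
        self.d_tissue = (
            self.opt.d_tissue
            if self.opt.d_tissue is not None
            else effective_diffusivity(solute, tissue)
        )
        self.blood_idx = [i for i, v in enumerate(geometry.vessels) if v.kind == "blood"]
        self._setup_lumen_flow()
        self._solve_pressure()
        self._assemble()
        from .geometry import sink_density
        self.coeffs = TransportCoeffs(
            d_tissue=self.d_tissue,
            k_decay=solute.p_d * sink_density(geometry).s_density,
        )

    def interstitial_velocity_scale(self) -> float:
        """Volume-weighted mean Darcy speed (m/s): the Uo reference of the
        non-dimensional convection scale L/Uo (logged, not part of T*)."""
        g = self.grid
        if g.if_left.size == 0:
            return 0.0
        areas = np.repeat(g.if_area_per_dz, g.nz) * g.dz
        speeds = np.abs(self.q_if) / areas
        return float(speeds.mean())

    # -- fluid ---------------------------------------------------------

    def _setup_lumen_flow(self):
        nz = self.grid.nz
        self.p_lumen = []
        self.u_lumen = []
        for v in self.geometry.vessels:
            p, u = solve_lumen_flow(v, nz)
            self.p_lumen.append(p)
            self.u_lumen.append(0.0 if self.opt.no_flow else u)

    def _solve_pressure(self):
        """Steady Darcy solve with Robin wall conditions; also computes the
        signed volumetric flow through every face (quasi-static)."""
        g, t, opt = self.grid, self.tissue, self.opt
        n = g.n_cells
        nz, dz = g.nz, g.dz
        if opt.no_flow:
            self.p_tissue = np.full(n, t.p0)
            self.q_if = np.zeros(g.if_left.size * nz)
            self.q_ax = np.zeros(g.ncols * (nz - 1))
            self.q_wall = np.zeros(g.bf_col.size * nz)
            self.q_env = np.zeros(g.bf_col.size * nz)
            return

        rows, cols, vals = [], [], []
        rhs = np.zeros(n)

        def add(i, j, v):
            rows.append(i); cols.append(j); vals.append(v)

        # interior transverse faces
        for f in range(g.if_left.size):
            gcond = t.k_hyd * g.if_area_per_dz[f] * dz / g.if_dist[f]
            for j in range(nz):
                i1 = g.if_left[f] * nz + j
                i2 = g.if_right[f] * nz + j
                add(i1, i1, gcond); add(i1, i2, -gcond)
                add(i2, i2, gcond); add(i2, i1, -gcond)
        # axial faces
        for c in range(g.ncols):
            gcond = t.k_hyd * g.vol_per_dz[c] / dz
            for j in range(nz - 1):
                i1 = c * nz + j
                i2 = i1 + 1
                add(i1, i1, gcond); add(i1, i2, -gcond)
                add(i2, i2, gcond); add(i2, i1, -gcond)
        # boundary faces
        has_dirichlet = False
        wall_entries = []  # (face f, j, cell, conductance, far pressure, lymph?)
        for f in range(g.bf_col.size):
            c = g.bf_col[f]
            area = g.bf_area_per_dz[f] * dz
            if g.bf_kind[f] == ENVELOPE:
                if opt.outer_pressure_bc != "dirichlet":
                    continue
                gcond = t.k_hyd * area / g.bf_dist[f]
                for j in range(nz):
                    i = c * nz + j
                    add(i, i, gcond)
                    rhs[i] += gcond * t.p0
                has_dirichlet = True
            else:
                v = self.geometry.vessels[g.bf_vessel[f]]
                lp = v.lp * opt.vascular_porosity
                gw = area / (1.0 / lp + g.bf_dist[f] / t.k_hyd)
                for j in range(nz):
                    i = c * nz + j
                    if v.kind == "lymph":
                        p_far = self.p_lumen[g.bf_vessel[f]][j]
                        wall_entries.append((f, j, i, gw, p_far, True))
                    else:
                        p_far = (
                            self.p_lumen[g.bf_vessel[f]][j]
                            - self.solute.sigma * v.dpi_osm
                        )
                        wall_entries.append((f, j, i, gw, p_far, False))
        if not has_dirichlet and not any(e[5] for e in wall_entries):
            raise ValueError(
                "interstitial pressure system is all-Neumann; impose the outer "
                "envelope condition (outer_pressure_bc='dirichlet')"
            )

        base = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        # lymph one-way valve: drain only where p_i > p_lymph (active set)
        active = np.ones(len(wall_entries), bool)
        for _ in range(8):
            diag = np.zeros(n)
            b = rhs.copy()
            for k, (f, j, i, gw, p_far, is_lymph) in enumerate(wall_entries):
                if is_lymph and not active[k]:
                    continue
                diag[i] += gw
                b[i] += gw * p_far
            A = base + sp.diags(diag)
            p = spla.spsolve(A.tocsc(), b)
            changed = False
            for k, (f, j, i, gw, p_far, is_lymph) in enumerate(wall_entries):
                if not is_lymph:
                    continue
                open_now = p[i] > p_far
                if open_now != active[k]:
                    active[k] = open_now
                    changed = True
            if not changed:
                break
        self.p_tissue = p

        # face volumetric flows (m^3/s)
        q_if = np.zeros(g.if_left.size * nz)
        for f in range(g.if_left.size):
            gcond = t.k_hyd * g.if_area_per_dz[f] * dz / g.if_dist[f]
            for j in range(nz):
                i1 = g.if_left[f] * nz + j
                i2 = g.if_right[f] * nz + j
                q_if[f * nz + j] = gcond * (p[i1] - p[i2])  # oriented left->right
        q_ax = np.zeros(g.ncols * (nz - 1))
        for c in range(g.ncols):
            gcond = t.k_hyd * g.vol_per_dz[c] / dz
            for j in range(nz - 1):
                q_ax[c * (nz - 1) + j] = gcond * (p[c * nz + j] - p[c * nz + j + 1])
        q_wall = np.zeros(g.bf_col.size * nz)   # positive into tissue
        q_env = np.zeros(g.bf_col.size * nz)    # positive out of tissue
        for k, (f, j, i, gw, p_far, is_lymph) in enumerate(wall_entries):
            if is_lymph and not active[k]:
                continue
            q_wall[f * nz + j] = gw * (p_far - p[i])
        for f in range(g.bf_col.size):
            if g.bf_kind[f] == ENVELOPE and opt.outer_pressure_bc == "dirichlet":
                area = g.bf_area_per_dz[f] * dz
                gcond = t.k_hyd * area / g.bf_dist[f]
                for j in range(nz):
                    i = g.bf_col[f] * nz + j
                    q_env[f * nz + j] = gcond * (p[i] - t.p0)
        self.q_if, self.q_ax, self.q_wall, self.q_env = q_if, q_ax, q_wall, q_env

    def interstitial_velocity(self) -> dict:
        """Darcy flux (superficial velocity, m/s) across faces, for inspection."""
        g = self.grid
        nz, dz = g.nz, g.dz
        u_if = self.q_if.reshape(g.if_left.size, nz) / (
            g.if_area_per_dz[:, None] * dz if g.if_left.size else 1.0
        )
        return {"transverse": u_if, "wall": self.q_wall.reshape(g.bf_col.size, nz)
                / (g.bf_area_per_dz[:, None] * dz)}

    # -- solute operator -------------------------------------------------

    def _assemble(self):
        g, s, t, opt = self.grid, self.solute, self.tissue, self.opt
        nz, dz = g.nz, g.dz
        n = g.n_cells
        nb = 0 if opt.prescribed_lumen else len(self.blood_idx)
        m = n + nb * nz
        self.n_tissue = n
        dtis = self.d_tissue
        rf = s.r_f

        rows, cols, vals = [], [], []

        def add(i, j, v):
            rows.append(i); cols.append(j); vals.append(v)

        def conv(i1, i2, q):
            """Upwind convective exchange through an interior face, flow q from i1 to i2."""
            up = i1 if q > 0 else i2
            add(i1, up, rf * q)
            add(i2, up, -rf * q)

        # tissue-tissue diffusion + convection
        for f in range(g.if_left.size):
            gd = t.phi * dtis * g.if_area_per_dz[f] * dz / g.if_dist[f]
            for j in range(nz):
                i1 = g.if_left[f] * nz + j
                i2 = g.if_right[f] * nz + j
                add(i1, i1, gd); add(i1, i2, -gd)
                add(i2, i2, gd); add(i2, i1, -gd)
                q = self.q_if[f * nz + j]
                if q != 0.0:
                    conv(i1, i2, q)
        for c in range(g.ncols):
            gd = t.phi * dtis * g.vol_per_dz[c] / dz
            for j in range(nz - 1):
                i1 = c * nz + j
                i2 = i1 + 1
                add(i1, i1, gd); add(i1, i2, -gd)
                add(i2, i2, gd); add(i2, i1, -gd)
                q = self.q_ax[c * (nz - 1) + j]
                if q != 0.0:
                    conv(i1, i2, q)

        # boundary faces
        lumen_of = {v: n + b * nz for b, v in enumerate(self.blood_idx)}
        env_out_coeff = np.zeros(n)    # envelope convective loss per cell
        drain_coeff = np.zeros(n)      # lymph drainage loss per cell
        inlet_vec = np.zeros(m)        # multiplied by c_in(t)
        venous_coeff = np.zeros(m)     # venous advective loss
        for f in range(g.bf_col.size):
            c = g.bf_col[f]
            area = g.bf_area_per_dz[f] * dz
            if g.bf_kind[f] == ENVELOPE:
                for j in range(nz):
                    i = c * nz + j
                    q = self.q_env[f * nz + j]
                    if q > 0:   # outflow carries local solute; inflow is solute-free
                        add(i, i, rf * q)
                        env_out_coeff[i] += rf * q
                continue
            vidx = g.bf_vessel[f]
            v = self.geometry.vessels[vidx]
            if v.kind == "lymph":
                pdl = s.p_d * opt.lymph_pd_factor * opt.vascular_porosity
                for j in range(nz):
                    i = c * nz + j
                    q = self.q_wall[f * nz + j]  # <= 0 (drain) when valve open
                    loss = pdl * area + max(0.0, -q)
                    add(i, i, loss)
                    drain_coeff[i] += loss
                continue
            # blood wall: diffusive (series with half-cell tissue resistance)
            # + upwinded convective exchange with the lumen cell
            pd = s.p_d * opt.vascular_porosity
            gd_w = 0.0 if pd == 0.0 else area / (1.0 / pd + g.bf_dist[f] / (t.phi * dtis))
            for j in range(nz):
                i = c * nz + j
                q = (1.0 - s.sigma) * self.q_wall[f * nz + j]
                if opt.prescribed_lumen:
                    # lumen held at c_in(t): wall exchange against a reservoir
                    add(i, i, gd_w)
                    inlet_vec[i] += gd_w
                    venous_coeff[i] += gd_w      # return flux leaves with perfusate
                    if q > 0:
                        inlet_vec[i] += q
                    elif q < 0:
                        add(i, i, -q)
                        venous_coeff[i] += -q
                    continue
                lv = lumen_of[vidx] + j
                add(i, i, gd_w); add(i, lv, -gd_w)
                add(lv, lv, gd_w); add(lv, i, -gd_w)
                if q > 0:        # filtration: carries lumen concentration
                    add(i, lv, -q)
                    add(lv, lv, q)
                elif q < 0:      # reabsorption: carries tissue concentration
                    add(i, i, -q)
                    add(lv, i, q)

        # lumen advection
        a_l = {}
        lumen_vessels = [] if opt.prescribed_lumen else self.blood_idx
        for b, vidx in enumerate(lumen_vessels):
            v = self.geometry.vessels[vidx]
            area_l = math.pi * v.d**2 / 4.0
            a_l[vidx] = area_l
            q_l = abs(self.u_lumen[vidx]) * area_l
            base = n + b * nz
            if q_l == 0.0:
                continue
            order = range(nz) if v.flow_sign > 0 else range(nz - 1, -1, -1)
            prev = None
            for j in order:
                i = base + j
                add(i, i, q_l)             # advective outflow toward next cell
                if prev is None:
                    inlet_vec[i] = q_l     # fed by the inlet bolus
                else:
                    add(i, prev, -q_l)
                prev = i
            venous_coeff[prev] = q_l       # last cell discharges at the venous end

        K = sp.coo_matrix((vals, (rows, cols)), shape=(m, m)).tocsr()
        mass = np.empty(m)
        mass[:n] = t.phi * g.cell_volumes()
        for b, vidx in enumerate(lumen_vessels):
            mass[n + b * nz:n + (b + 1) * nz] = a_l[vidx] * dz
        self._lumen_vessels = lumen_vessels
        self.K = K
        self.mass = mass
        self.inlet_vec = inlet_vec
        self.venous_coeff = venous_coeff
        self.env_out_coeff = env_out_coeff
        self.drain_coeff = drain_coeff
        self._lu = None
        self._lu_dt = None

    # -- time stepping ---------------------------------------------------

    def _factorize(self, dt: float):
        if self._lu is None or self._lu_dt != dt:
            A = sp.diags(self.mass / dt) + self.K
            self._lu = spla.splu(A.tocsc())
            self._lu_dt = dt

    def inlet_concentration(self, t: float) -> float:
        if self.opt.inlet_mode == "off":
            return 0.0
        if self.opt.inlet_mode == "constant":
            return self.solute.c0
        return self.solute.c0 * math.exp(-t / self.solute.tau_in)

    def initial_state(self) -> FieldState:
        n = self.n_tissue
        return FieldState(
            t=0.0,
            c_tissue=np.full(n, self.opt.c_tissue0, float),
            c_lumen=[np.zeros(self.grid.nz) for _ in self._lumen_vessels],
            p_tissue=self.p_tissue.copy(),
            p_lumen=[p.copy() for p in self.p_lumen],
        )

    def _pack(self, state: FieldState) -> np.ndarray:
        if not state.c_lumen:
            return state.c_tissue.copy()
        return np.concatenate([state.c_tissue] + [c for c in state.c_lumen])

    def _unpack(self, y: np.ndarray, t: float) -> FieldState:
        n, nz = self.n_tissue, self.grid.nz
        return FieldState(
            t=t,
            c_tissue=y[:n].copy(),
            c_lumen=[y[n + b * nz:n + (b + 1) * nz].copy()
                     for b in range(len(self._lumen_vessels))],
            p_tissue=self.p_tissue.copy(),
            p_lumen=[p.copy() for p in self.p_lumen],
        )

    def advance_solute(self, state: FieldState, dt: float) -> FieldState:
        """One implicit-Euler step of the coupled lumen/tissue solute system."""
        self._factorize(dt)
        y = self._pack(state)
        t_new = state.t + dt
        rhs = self.mass / dt * y
        rhs += self.inlet_vec * self.inlet_concentration(t_new)
        y_new = self._lu.solve(rhs)
        if y_new.min() < -self.opt.negative_tol * max(self.solute.c0, 1e-300):
            raise FloatingPointError(
                f"negative concentration {y_new.min():.3e} at t={t_new:.1f}s "
                "(flux-limiter violation)"
            )
        return self._unpack(y_new, t_new)

    def run(self, duration: float | None = None) -> ConcentrationHistory:
        """March the system and record the normalized concentration histories."""
        opt = self.opt
        duration = opt.duration if duration is None else duration
        dt = opt.dt
        nsteps = max(1, int(round(duration / dt)))
        every = max(1, int(round(opt.output_dt / dt)))
        self._factorize(dt)

        g = self.grid
        w_vol = np.zeros(self.mass.size)
        w_vol[:self.n_tissue] = g.volume_average_weights(opt.volume_region)
        w_surf = np.zeros(self.mass.size)
        w_surf[:self.n_tissue] = g.station_weights(opt.station_frac * self.geometry.L)

        c0 = self.solute.c0
        y = self._pack(self.initial_state())
        times = [0.0]
        vol = [float(w_vol @ y) / c0]
        surf = [float(w_surf @ y) / c0]
        inlet_cum = venous_cum = drain_cum = env_cum = 0.0
        mass0 = float(self.mass @ y)

        mdt = self.mass / dt
        for step in range(1, nsteps + 1):
            t_new = step * dt
            cin = self.inlet_concentration(t_new)
            rhs = mdt * y
            if cin:
                rhs = rhs + self.inlet_vec * cin
            y = self._lu.solve(rhs)
            inlet_cum += cin * self.inlet_vec.sum() * dt
            venous_cum += float(self.venous_coeff @ y) * dt
            drain_cum += float(self.drain_coeff @ y[:self.n_tissue]) * dt
            env_cum += float(self.env_out_coeff @ y[:self.n_tissue]) * dt
            if step % every == 0:
                times.append(t_new)
                vol.append(float(w_vol @ y) / c0)
                surf.append(float(w_surf @ y) / c0)

        vol_arr = np.asarray(vol)
        ipk = int(np.argmax(vol_arr))
        bracketed = ipk < len(vol_arr) - max(2, len(vol_arr) // 20)
        storage = float(self.mass @ y) - mass0
        ledger = {
            "inlet_in": inlet_cum,
            "venous_out": venous_cum,
            "lymph_drain": drain_cum,
            "envelope_out": env_cum,
            "storage": storage,
            "residual": inlet_cum - venous_cum - drain_cum - env_cum - storage,
        }
        geo = self.geometry
        meta = {
            "config": geo.config,
            "layout": geo.layout,
            "flow_mode": geo.flow_mode,
            "mw_kda": self.solute.mw,
            "L_m": geo.L,
            "D_m": geo.D,
            "d_m": geo.vessels[0].d,
            "n_vessels": geo.n,
            "phi": self.tissue.phi,
            "u0_m_per_s": self.interstitial_velocity_scale(),
            "nr": self.opt.nr,
            "nz": self.opt.nz,
            "dt_s": dt,
            "duration_s": duration,
            "station_frac": opt.station_frac,
        }
        return ConcentrationHistory(
            time_s=np.asarray(times),
            c_norm_volume=vol_arr,
            c_norm_surface=np.asarray(surf),
            metadata=meta,
            peak_bracketed=bool(bracketed),
            ledger=ledger,
        )


def solve_interstitial_pressure(
    grid: Grid,
    geometry: GeometryConfig,
    tissue: TissueSpec,
    solute: SoluteSpec,
    options: SolverOptions | None = None,
) -> tuple[np.ndarray, dict]:
    """Steady Darcy pressure and face flows for a geometry (standalone helper).

    Returns ``(p_tissue, flows)`` where ``flows`` carries the signed
    volumetric face flows (``q_if``, ``q_ax``, ``q_wall``, ``q_env``) used by
    the solute operator.
    """
    model = PerfusionModel(geometry, solute, tissue, options, grid=grid)
    return model.p_tissue, {
        "q_if": model.q_if,
        "q_ax": model.q_ax,
        "q_wall": model.q_wall,
        "q_env": model.q_env,
    }


def run_simulation(
    geometry: GeometryConfig,
    solute: SoluteSpec,
    tissue: TissueSpec,
    duration: float | None = None,
    options: SolverOptions | None = None,
) -> ConcentrationHistory:
    """Build the model for one configuration and march it for ``duration`` seconds."""
    model = PerfusionModel(geometry, solute, tissue, options)
    return model.run(duration)
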