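"""Tissue/vessel geometries and their finite-volume discretizations.

Two reduced-dimensional layouts are supported:

* ``axisym`` — the classical Krogh cylinder: one capillary concentric with a
  tissue annulus, discretized in (r, z).
* ``slab`` — a transverse-axial reduction for dual-vessel domains: the
  vessels appear as parallel wall boundaries at separation ``L`` inside an
  envelope of diameter ``D``; the transverse coordinate is resolved between
  and outside the vessels and the circular cross-section is represented by an
  effective depth chosen so the tissue volume, the wall area (``n*pi*d*l``)
  and the envelope area (``pi*D*l``) all match the cylindrical domain
  exactly.

The decay constant of the homogenized wall sink is ``k = P_d * S`` with the
vessel sink density ``S = 4 n d / D**2`` (wall perimeter per cross-section
area), which reproduces the printed single-capillary decay timescales for
all five solutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .params import (
    BASELINE_TISSUE_DIAMETER,
    GeometryConfig,
    SoluteSpec,
    VesselSpec,
    baseline_tumor,
)

__all__ = [
    "SinkGeometry",
    "Grid",
    "make_geometry",
    "sink_density",
    "build_grid",
]

#: Default multiplier on the blood-wall hydraulic permeability for the highly
#: permeable initial-lymphatic wall.
LYMPH_LP_FACTOR = 10.0


@dataclass(frozen=True)
class SinkGeometry:
    """Homogenized wall-sink quantities of a geometry.

    s_density : vessel wall area per tissue volume, ``4 n d / D**2`` (1/m).
    k_decay : first-order decay constant ``P_d * S`` (1/s); ``None`` when no
        solute was supplied.
    """

    s_density: float
    k_decay: float | None = None


def sink_density(g: GeometryConfig, solute: SoluteSpec | None = None) -> SinkGeometry:
    """Wall-sink density ``S = 4 n d / D**2`` and decay constant ``k = P_d S``."""
    d = g.vessels[0].d
    s = 4.0 * g.n * d / g.D**2
    k = None if solute is None else solute.p_d * s
    return SinkGeometry(s_density=s, k_decay=k)


def make_geometry(
    config: str,
    L: float | None = None,
    flow_mode: str | None = None,
    *,
    D: float | None = None,
    vessel: VesselSpec | None = None,
    layout: str | None = None,
    lymph_lp_factor: float = LYMPH_LP_FACTOR,
    lymph_pressure: float = 0.0,
) -> GeometryConfig:
    """Construct one of the three tissue/vessel configurations.

    Parameters
    ----------
    config : "SBC", "2BC" or "BC_LC".
    L : intercapillary separation (m); required for dual configurations.
        For SBC it defaults to D/2 (the convention that makes the
        single-capillary timescales equal the printed ones).
    flow_mode : "CO" or "CN" for dual configurations ("NA" for SBC).
    D : tissue envelope diameter (m).  Defaults to 200 um for SBC and to
        ``2 L`` for dual configurations (the rule that keeps the domain
        volume per microvessel equal to the single-capillary baseline).
    vessel : template blood vessel; baseline tumor vessel by default.
    layout : grid layout override ("axisym"/"slab").  SBC defaults to the
        axisymmetric Krogh annulus, dual configurations to the slab.
    lymph_lp_factor : lymph wall hydraulic permeability as a multiple of the
        blood-wall value.
    lymph_pressure : luminal pressure of the lymph vessel, Pa (gauge).
    """
    if vessel is None:
        _, vessel = baseline_tumor()
    if config == "SBC":
        if flow_mode not in (None, "NA"):
            raise ValueError(f"SBC has a single vessel; flow_mode {flow_mode!r} is undefined")
        D = BASELINE_TISSUE_DIAMETER if D is None else D
        L = D / 2.0 if L is None else L
        return GeometryConfig(
            config="SBC",
            vessels=(vessel,),
            L=L,
            D=D,
            flow_mode="NA",
            layout=layout or "axisym",
        )

    if config not in ("2BC", "BC_LC"):
        raise ValueError(f"unknown configuration {config!r}")
    if L is None:
        raise ValueError(f"{config} requires an intercapillary separation L")
    if flow_mode not in ("CO", "CN"):
        raise ValueError(f"{config} requires flow_mode 'CO' or 'CN', got {flow_mode!r}")
    D = 2.0 * L if D is None else D
    if L >= D:
        raise ValueError(f"intercapillary separation L={L} must be < tissue diameter D={D}")

    second_sign = 1 if flow_mode == "CO" else -1
    if config == "2BC":
        v2 = replace(vessel, flow_sign=second_sign * vessel.flow_sign)
    else:
        v2 = VesselSpec(
            kind="lymph",
            d=vessel.d,
            length=vessel.length,
            lp=lymph_lp_factor * vessel.lp,
            p_arteriole=lymph_pressure,
            dp=0.0,
            dpi_osm=0.0,
            flow_sign=second_sign * vessel.flow_sign,
            mu_eff=vessel.mu_eff,
        )
    return GeometryConfig(
        config=config,
        vessels=(vessel, v2),
        L=L,
        D=D,
        flow_mode=flow_mode,
        layout=layout or "slab",
    )


# --------------------------------------------------------------------------
# Finite-volume grid
# --------------------------------------------------------------------------

# boundary-face kinds
ENVELOPE = 0
WALL = 1


def _graded(lo: float, hi: float, n: int, beta: float = 2.5) -> np.ndarray:
    """n+1 face positions on [lo, hi], clustered toward both ends.

    A fixed tanh mapping is used so that refining n scales every spacing by
    the same factor (doubling n halves the maximum spacing).
    """
    xi = np.linspace(0.0, 1.0, n + 1)
    s = 0.5 * (1.0 + np.tanh(beta * (xi - 0.5)) / math.tanh(beta / 2.0))
    s[0], s[-1] = 0.0, 1.0
    return lo + (hi - lo) * s


@dataclass
class Grid:
    """Finite-volume discretization of the tissue domain.

    Transverse cells (columns) are shared by all ``nz`` axial slices; the
    tissue cell index is ``col * nz + j``.  Face areas are stored per unit
    axial length (``*_per_dz``).
    """

    geometry: GeometryConfig
    nz: int
    dz: float
    z_centers: np.ndarray           # (nz,)
    # columns
    col_center: np.ndarray          # (ncols,) transverse coordinate (m)
    col_width: np.ndarray           # (ncols,)
    vol_per_dz: np.ndarray          # (ncols,) cell volume per unit dz (m^2)
    # interior transverse faces
    if_left: np.ndarray             # (nif,) column index
    if_right: np.ndarray
    if_area_per_dz: np.ndarray
    if_dist: np.ndarray             # center-to-center distance
    # boundary (transverse) faces
    bf_col: np.ndarray              # adjacent column
    bf_kind: np.ndarray             # ENVELOPE or WALL
    bf_vessel: np.ndarray           # vessel index for WALL faces, -1 otherwise
    bf_area_per_dz: np.ndarray
    bf_dist: np.ndarray             # column center to face distance
    bf_pos: np.ndarray              # face transverse coordinate (m)
    bf_side: np.ndarray             # +1 if tissue lies at larger coordinate than the face
    # ownership of columns for the per-vessel volume average (blood Voronoi region)
    blood_region: np.ndarray        # (ncols,) bool

    @property
    def ncols(self) -> int:
        return self.col_center.size

    @property
    def n_cells(self) -> int:
        return self.ncols * self.nz

    def cell_volumes(self) -> np.ndarray:
        """(ncols*nz,) cell volumes in m^3."""
        return np.repeat(self.vol_per_dz * self.dz, self.nz)

    def nodes_table(self):
        """Cell-center coordinates and volumes as a DataFrame (CSV-ready)."""
        import pandas as pd
        cols = np.repeat(np.arange(self.ncols), self.nz)
        return pd.DataFrame({
            "col": cols,
            "j": np.tile(np.arange(self.nz), self.ncols),
            "transverse_m": self.col_center[cols],
            "z_m": np.tile(self.z_centers, self.ncols),
            "volume_m3": self.cell_volumes(),
            "blood_region": self.blood_region[cols],
        })

    def tissue_volume(self) -> float:
        return float(np.sum(self.vol_per_dz) * self.dz * self.nz)

    def wall_area(self, vessel: int | None = None) -> float:
        sel = self.bf_kind == WALL
        if vessel is not None:
            sel &= self.bf_vessel == vessel
        return float(np.sum(self.bf_area_per_dz[sel]) * self.dz * self.nz)

    # -- measurement weight vectors ------------------------------------

    def volume_average_weights(self, region: str = "blood") -> np.ndarray:
        """Weights over tissue cells for the volume-averaged concentration.

        ``region='blood'`` restricts to the Voronoi tissue region of the
        blood vessel(s) (relevant for BC_LC, where the lymph half-domain is
        excluded); ``'all'`` averages over the whole extravascular space.
        """
        mask = self.blood_region if region == "blood" else np.ones(self.ncols, bool)
        w = np.zeros(self.n_cells)
        for c in np.nonzero(mask)[0]:
            w[c * self.nz:(c + 1) * self.nz] = self.vol_per_dz[c] * self.dz
        return w / w.sum()

    def station_weights(self, distance: float, vessel: int = 0) -> np.ndarray:
        """Weights realizing the surface-averaged concentration at a given
        radial distance from the wall of ``vessel`` (averaged over z and over
        the tissue sides adjacent to that vessel)."""
        sides = []
        for f in np.nonzero((self.bf_kind == WALL) & (self.bf_vessel == vessel))[0]:
            x = self.bf_pos[f] + self.bf_side[f] * distance
            sides.append(self._interp_col_weights(x))
        if not sides:
            raise ValueError(f"vessel {vessel} has no wall faces")
        wcol = np.mean(np.vstack(sides), axis=0)
        w = np.repeat(wcol / self.nz, self.nz)
        return w

    def _interp_col_weights(self, x: float) -> np.ndarray:
        """Linear-interpolation weights over columns for transverse position x."""
        w = np.zeros(self.ncols)
        centers = self.col_center
        lo = self.col_center - self.col_width / 2
        hi = self.col_center + self.col_width / 2
        # locate the column containing x (columns are disjoint but may have gaps)
        inside = np.nonzero((x >= lo - 1e-15) & (x <= hi + 1e-15))[0]
        if inside.size == 0:
            # station falls inside a vessel strip or outside the envelope
            # (near-degenerate geometries): use the nearest tissue column
            c = int(np.argmin(np.abs(centers - x)))
            w[c] = 1.0
            return w
        c = int(inside[0])
        # neighbor on the side of x within the same contiguous segment
        if x >= centers[c] and c + 1 < self.ncols and abs(hi[c] - lo[c + 1]) < 1e-12:
            c2, t = c + 1, (x - centers[c]) / (centers[c + 1] - centers[c])
        elif x < centers[c] and c - 1 >= 0 and abs(lo[c] - hi[c - 1]) < 1e-12:
            c2, t = c - 1, (x - centers[c]) / (centers[c - 1] - centers[c])
        else:
            c2, t = c, 0.0
        w[c] = 1.0 - t
        w[c2] += t
        return w


def _segment_cells(lo, hi, n, beta=2.5):
    faces = _graded(lo, hi, n, beta)
    centers = 0.5 * (faces[:-1] + faces[1:])
    widths = np.diff(faces)
    return faces, centers, widths


def build_grid(g: GeometryConfig, nr: int = 40, nz: int = 40) -> Grid:
    """Discretize a geometry into a finite-volume grid.

    ``nr`` is the total number of transverse cells (radial cells for the
    axisymmetric layout), ``nz`` the number of axial cells.  Spacing is
    graded toward the vessel walls.  Deterministic for fixed inputs.
    """
    if nr < 8 or nz < 2:
        raise ValueError("need nr >= 8 and nz >= 2")
    d = g.vessels[0].d
    length = g.vessels[0].length
    if g.layout == "axisym":
        if g.n != 1:
            raise ValueError("axisymmetric layout supports a single vessel only")
        if d >= g.D:
            raise ValueError("lumen fills the tissue domain (d >= D)")
        return _build_axisym(g, nr, nz, d, length)
    return _build_slab(g, nr, nz, d, length)


def _build_axisym(g, nr, nz, d, length) -> Grid:
    a, b = d / 2.0, g.D / 2.0
    faces, centers, widths = _segment_cells(a, b, nr)
    vol_per_dz = math.pi * (faces[1:] ** 2 - faces[:-1] ** 2)
    if_left = np.arange(nr - 1)
    if_right = if_left + 1
    if_area = 2.0 * math.pi * faces[1:-1]
    if_dist = np.diff(centers)
    bf_col = np.array([0, nr - 1])
    bf_kind = np.array([WALL, ENVELOPE])
    bf_vessel = np.array([0, -1])
    bf_area = np.array([2.0 * math.pi * a, 2.0 * math.pi * b])
    bf_dist = np.array([centers[0] - a, b - centers[-1]])
    bf_pos = np.array([a, b])
    bf_side = np.array([1, -1])
    dz = length / nz
    return Grid(
        geometry=g, nz=nz, dz=dz,
        z_centers=(np.arange(nz) + 0.5) * dz,
        col_center=centers, col_width=widths, vol_per_dz=vol_per_dz,
        if_left=if_left, if_right=if_right, if_area_per_dz=if_area, if_dist=if_dist,
        bf_col=bf_col, bf_kind=bf_kind, bf_vessel=bf_vessel,
        bf_area_per_dz=bf_area, bf_dist=bf_dist, bf_pos=bf_pos, bf_side=bf_side,
        blood_region=np.ones(nr, bool),
    )


def _build_slab(g, nr, nz, d, length) -> Grid:
    """Transverse-axial slab with vessel "throat" columns.

    The circular cross-section (area ``pi D^2/4``) is represented by an
    effective depth ``b``; each vessel occupies only diameter ``d`` of that
    depth, so the transverse line stays connected *around* the vessels: a
    vessel appears as a single partially-blocked column (open area
    ``d*b - pi d^2/4``) whose transverse faces are constricted to depth
    ``b - d``.  Wall exchange (area ``pi d`` per unit length) attaches to the
    throat column.  Tissue volume, wall area and envelope area all match the
    cylindrical domain exactly.
    """
    D, L, n = g.D, g.L, g.n
    tissue_area = math.pi * (D**2 - n * d**2) / 4.0
    if tissue_area <= 0:
        raise ValueError("lumen fills the tissue domain")

    if n == 1:
        x_v = [D / 2.0]
    else:
        x_v = [D / 2.0 - L / 2.0, D / 2.0 + L / 2.0]

    # open tissue width outside the vessel strips
    w_outer = (x_v[0] - d / 2.0)            # == (D - L - d)/2 for duals
    w_mid = (L - d) if n == 2 else None
    # effective depth: strip areas (d*b - pi d^2/4 each) plus open areas
    # (width*b) must sum to tissue_area  ->  b = pi D / 4.
    b = math.pi * D / 4.0
    if b <= d:
        raise ValueError("vessel diameter exceeds the effective slab depth")

    tiny = d / 20.0
    # build the ordered transverse element list:
    # ('seg', lo, hi) open tissue segment | ('throat', vessel_index)
    elements: list[tuple] = []
    if w_outer > tiny:
        elements.append(("seg", 0.0, x_v[0] - d / 2))
    elements.append(("throat", 0))
    if n == 2:
        if w_mid > tiny:
            elements.append(("seg", x_v[0] + d / 2, x_v[1] - d / 2))
        elements.append(("throat", 1))
    if w_outer > tiny:
        elements.append(("seg", x_v[-1] + d / 2, D))

    seg_total = sum(e[2] - e[1] for e in elements if e[0] == "seg")
    n_seg_cells = max(0, nr - n)
    seg_counts = {}
    for idx, e in enumerate(elements):
        if e[0] == "seg":
            frac = (e[2] - e[1]) / seg_total if seg_total > 0 else 0.0
            seg_counts[idx] = max(6, int(round(n_seg_cells * frac)))

    col_center, col_width, vol_per_dz = [], [], []
    throat_col = {}
    if_left, if_right, if_area, if_dist = [], [], [], []
    bf = {k: [] for k in ("col", "kind", "vessel", "area", "dist", "pos", "side")}

    offset = 0
    prev_last = None          # (col index, center) of previous element's last cell
    prev_constricted = False  # previous element was a throat
    for idx, e in enumerate(elements):
        if e[0] == "seg":
            lo, hi = e[1], e[2]
            nc = seg_counts[idx]
            faces, centers, cw = _segment_cells(lo, hi, nc)
            col_center.extend(centers)
            col_width.extend(cw)
            vol_per_dz.extend(cw * b)
            for i in range(nc - 1):
                if_left.append(offset + i)
                if_right.append(offset + i + 1)
                if_area.append(b)
                if_dist.append(centers[i + 1] - centers[i])
            first_center, last = centers[0], (offset + nc - 1, centers[-1])
            if prev_last is not None:
                if_left.append(prev_last[0])
                if_right.append(offset)
                if_area.append(b - d if prev_constricted else b)
                if_dist.append(first_center - prev_last[1])
            prev_last, prev_constricted = last, False
            offset += nc
        else:
            v = e[1]
            xc = x_v[v]
            col_center.append(xc)
            col_width.append(d)
            vol_per_dz.append(d * b - math.pi * d**2 / 4.0)
            throat_col[v] = offset
            if prev_last is not None:
                if_left.append(prev_last[0])
                if_right.append(offset)
                if_area.append(b - d)
                if_dist.append(xc - prev_last[1])
            prev_last, prev_constricted = (offset, xc), True
            # wall exchange: full perimeter, split between the two sides for
            # station bookkeeping; both attach to the throat column
            for side, pos in ((+1, xc - d / 2), (-1, xc + d / 2)):
                bf["col"].append(offset)
                bf["kind"].append(WALL)
                bf["vessel"].append(v)
                bf["area"].append(math.pi * d / 2.0)
                bf["dist"].append(d / 4.0)
                bf["pos"].append(pos)
                bf["side"].append(side)
            offset += 1

    # envelope faces at the two ends of the transverse line
    for col, pos, side in ((0, 0.0, +1), (offset - 1, D, -1)):
        bf["col"].append(col)
        bf["kind"].append(ENVELOPE)
        bf["vessel"].append(-1)
        bf["area"].append(math.pi * D / 2.0)
        bf["dist"].append(max(abs(col_center[col] - pos), d / 4.0))
        bf["pos"].append(pos)
        bf["side"].append(side)

    ncols = offset
    # renormalize cell volumes so the tissue volume is exact even when thin
    # outer gaps were absorbed into the envelope faces
    scale = tissue_area / float(np.sum(vol_per_dz))
    vol_per_dz = [v * scale for v in vol_per_dz]
    # Voronoi ownership: for BC_LC only the blood half-domain is averaged
    centers = np.asarray(col_center)
    if g.config == "BC_LC":
        mid = 0.5 * (x_v[0] + x_v[1])
        blood_region = centers < mid
    else:
        blood_region = np.ones(ncols, bool)

    dz = length / nz
    return Grid(
        geometry=g, nz=nz, dz=dz,
        z_centers=(np.arange(nz) + 0.5) * dz,
        col_center=centers,
        col_width=np.asarray(col_width),
        vol_per_dz=np.asarray(vol_per_dz),
        if_left=np.asarray(if_left, int),
        if_right=np.asarray(if_right, int),
        if_area_per_dz=np.asarray(if_area),
        if_dist=np.asarray(if_dist),
        bf_col=np.asarray(bf["col"], int),
        bf_kind=np.asarray(bf["kind"], int),
        bf_vessel=np.asarray(bf["vessel"], int),
        bf_area_per_dz=np.asarray(bf["area"]),
        bf_dist=np.asarray(bf["dist"]),
        bf_pos=np.asarray(bf["pos"]),
        bf_side=np.asarray(bf["side"], int),
        blood_region=blood_region,
    )
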