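"""Typed parameter model for the breast-tumor transport simulations.

All quantities are SI internally (meters, seconds, Pascals, mol/m^3) except
molecular weight, which is carried in kDa as is conventional for dextran
tracers.  The built-in presets cover the baseline breast-tumor parameter set
(``table1_baseline``), the in vitro vascularized platform
(``table3_invitro``), the per-solute input timescales, and the survey of
in vivo intercapillary separations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

__all__ = [
    "SoluteSpec",
    "TissueSpec",
    "VesselSpec",
    "GeometryConfig",
    "InVitroSolute",
    "SOLUTE_MWS",
    "RHO_SOLUTE",
    "load_solute_preset",
    "baseline_tumor",
    "invitro_platform",
    "intercapillary_survey",
    "PRESET_REGISTRY",
]

#: Solute mass density used in the concentration rescaling C*.  The value is a
#: fixed convention (water-like); C* enters only through peak *location*,
#: which is invariant to any constant scale.
RHO_SOLUTE = 1000.0  # kg/m^3

#: Molecular weights (kDa) with built-in presets.
SOLUTE_MWS = (0.1, 3.0, 10.0, 40.0, 70.0)


def _positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class SoluteSpec:
    """Transport properties of one solute species.

    Parameters
    ----------
    mw : float
        Molecular weight in kDa (1 kDa == 1 kg/mol).
    d_h : float
        Hydrodynamic diameter, nm.
    sigma : float
        Osmotic reflection coefficient of the capillary wall, in [0, 1].
    p_d : float
        Diffusive solute permeability of the capillary wall, m/s.
    d_f : float
        Free diffusion coefficient, m^2/s.
    r_f : float
        Retardation factor multiplying interstitial convective transport.
    c0 : float
        Inlet / initial luminal concentration, mol/m^3.
    tau_in : float
        Input timescale: time for the inlet concentration to decay to 1/e of
        its maximum, assuming exponential decay, s.
    rho : float
        Solute mass density, kg/m^3 (only used in the C* rescaling).
    """

    mw: float
    d_h: float
    sigma: float
    p_d: float
    d_f: float
    r_f: float
    c0: float
    tau_in: float
    rho: float = RHO_SOLUTE

    def __post_init__(self) -> None:
        for name in ("mw", "d_h", "p_d", "d_f", "r_f", "c0", "tau_in", "rho"):
            _positive(name, getattr(self, name))
        if not 0.0 <= self.sigma <= 1.0:
            raise ValueError(f"sigma must lie in [0, 1], got {self.sigma!r}")


@dataclass(frozen=True)
class TissueSpec:
    """Interstitial matrix properties.

    phi : porosity (extravascular fluid volume fraction), dimensionless.
    k_hyd : interstitial hydraulic conductivity, m^2/(Pa s).
    p0 : tissue pressure imposed on the outer envelope, Pa.
    """

    phi: float
    k_hyd: float
    p0: float

    def __post_init__(self) -> None:
        if not 0.0 < self.phi < 1.0:
            raise ValueError(f"phi must lie in (0, 1), got {self.phi!r}")
        _positive("k_hyd", self.k_hyd)


@dataclass(frozen=True)
class VesselSpec:
    """One microvessel (blood or initial lymphatic).

    Blood vessels carry a prescribed Poiseuille flow with a linear axial
    pressure drop ``dp`` from the arteriolar inlet pressure ``p_arteriole``
    and exchange fluid/solute through a Starling / Kedem-Katchalsky wall.
    Lymph vessels carry no inlet solute, have a constant (gauge-zero by
    default) luminal pressure and act as strict one-way drains.
    """

    kind: Literal["blood", "lymph"]
    d: float                  # diameter, m
    length: float             # axial length, m
    lp: float                 # wall hydraulic permeability, m/(Pa s)
    p_arteriole: float        # inlet pressure, Pa (lymph: luminal pressure)
    dp: float                 # axial pressure drop, Pa (lymph: 0)
    dpi_osm: float            # transmural osmotic pressure gradient, Pa
    flow_sign: int = 1        # +1: inlet at z=0; -1: inlet at z=l
    mu_eff: float = 3.0e-3    # effective luminal viscosity, Pa s

    def __post_init__(self) -> None:
        if self.kind not in ("blood", "lymph"):
            raise ValueError(f"vessel kind must be 'blood' or 'lymph', got {self.kind!r}")
        _positive("d", self.d)
        _positive("length", self.length)
        _positive("lp", self.lp)
        _positive("mu_eff", self.mu_eff)
        if self.flow_sign not in (-1, 1):
            raise ValueError("flow_sign must be +1 or -1")
        if self.dp < 0:
            raise ValueError("dp must be >= 0")


@dataclass(frozen=True)
class GeometryConfig:
    """Tissue/vessel layout for one simulation.

    config : "SBC" (single blood capillary, axisymmetric Krogh cylinder),
        "2BC" (two parallel blood capillaries) or "BC_LC" (blood capillary
        paired with a parallel lymph capillary).
    vessels : the microvessels, in transverse order.
    L : intercapillary separation (m).  For SBC, L := D/2 by convention so
        the single-capillary timescales are well defined.
    D : tissue envelope diameter (m).
    flow_mode : "CO" (co-current), "CN" (counter-current) or "NA" (single
        vessel).
    layout : "axisym" for the Krogh annulus, "slab" for the reduced
        transverse-axial dual-vessel domain.
    """

    config: Literal["SBC", "2BC", "BC_LC"]
    vessels: tuple[VesselSpec, ...]
    L: float
    D: float
    flow_mode: Literal["CO", "CN", "NA"]
    layout: Literal["axisym", "slab"] = "axisym"

    def __post_init__(self) -> None:
        _positive("L", self.L)
        _positive("D", self.D)
        if self.config not in ("SBC", "2BC", "BC_LC"):
            raise ValueError(f"unknown config {self.config!r}")
        if self.flow_mode not in ("CO", "CN", "NA"):
            raise ValueError(f"unknown flow_mode {self.flow_mode!r}")
        expected_n = 1 if self.config == "SBC" else 2
        if len(self.vessels) != expected_n:
            raise ValueError(
                f"{self.config} requires {expected_n} vessel(s), got {len(self.vessels)}"
            )
        if self.config == "SBC" and self.flow_mode != "NA":
            raise ValueError("SBC admits flow_mode='NA' only")
        if self.config != "SBC" and self.L >= self.D:
            raise ValueError(f"intercapillary separation L={self.L} must be < D={self.D}")
        kinds = tuple(v.kind for v in self.vessels)
        if self.config == "2BC" and kinds != ("blood", "blood"):
            raise ValueError("2BC requires two blood vessels")
        if self.config == "BC_LC" and kinds != ("blood", "lymph"):
            raise ValueError("BC_LC requires (blood, lymph) vessels")
        if self.config == "SBC" and kinds != ("blood",):
            raise ValueError("SBC requires a single blood vessel")

    @property
    def n(self) -> int:
        """Number of microvessels (blood + lymph)."""
        return len(self.vessels)

    @property
    def blood_vessels(self) -> tuple[VesselSpec, ...]:
        return tuple(v for v in self.vessels if v.kind == "blood")


# --------------------------------------------------------------------------
# Baseline breast-tumor presets
# --------------------------------------------------------------------------

# Columns: mw (kDa) -> (d_h nm, sigma, P_d m/s, D_f m^2/s, R_F, Co mol/m^3,
# tau s).  P_d and D_f strictly decrease and d_h increases with mw; the decay
# timescales 1/(P_d*S) at S=1000/m reproduce the printed single-capillary
# values to 4 significant figures.
_SOLUTE_TABLE: dict[float, tuple[float, float, float, float, float, float, float]] = {
    0.1: (0.69, 0.00025, 800e-8, 89.6e-11, 1.10, 6.11, 284.5),
    3.0: (1.60, 0.00025, 174e-8, 17.0e-11, 1.10, 0.20, 440.1),
    10.0: (5.46, 0.02500, 70e-8, 9.6e-11, 1.07, 0.08, 604.8),
    40.0: (13.2, 0.08600, 33e-8, 7.8e-11, 0.94, 0.02, 1302.0),
    70.0: (14.4, 0.14000, 30e-8, 3.6e-11, 0.84, 0.01, 2319.0),
}


def load_solute_preset(mw: float) -> SoluteSpec:
    """Return the full baseline solute parameter set for molecular weight ``mw`` (kDa).

    Raises
    ------
    KeyError
        If ``mw`` is not one of the five tabulated solutes.
    """
    key = float(mw)
    if key not in _SOLUTE_TABLE:
        valid = ", ".join(str(m) for m in SOLUTE_MWS)
        raise KeyError(f"no preset for mw={mw!r} kDa; valid molecular weights: {valid}")
    d_h, sigma, p_d, d_f, r_f, c0, tau = _SOLUTE_TABLE[key]
    return SoluteSpec(mw=key, d_h=d_h, sigma=sigma, p_d=p_d, d_f=d_f,
                      r_f=r_f, c0=c0, tau_in=tau)


def baseline_tumor() -> tuple[TissueSpec, VesselSpec]:
    """Baseline breast-tumor tissue and blood-vessel template.

    Returns the interstitial matrix spec and a template blood vessel
    (d=10 um, l=1 mm, arteriolar pressure 4394 Pa, axial drop 2394 Pa,
    osmotic gradient 2500 Pa).
    """
    tissue = TissueSpec(phi=0.4, k_hyd=400e-15, p0=2700.0)
    vessel = VesselSpec(
        kind="blood",
        d=10e-6,
        length=1e-3,
        lp=10e-10,
        p_arteriole=4394.0,
        dp=2394.0,
        dpi_osm=2500.0,
    )
    return tissue, vessel


#: Baseline tissue envelope diameter (m).
BASELINE_TISSUE_DIAMETER = 200e-6


# --------------------------------------------------------------------------
# In vitro vascularized platform
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class InVitroSolute:
    """Per-solute (min, mean, max) transport parameters measured on the platform."""

    mw: float
    d_f: tuple[float, float, float]   # (min, mean, max), m^2/s
    p_d: tuple[float, float, float]   # (min, mean, max), m/s

    def __post_init__(self) -> None:
        for name in ("d_f", "p_d"):
            lo, mid, hi = getattr(self, name)
            if not (0 < lo <= mid <= hi):
                raise ValueError(f"{name} triple must satisfy 0 < min <= mean <= max")


@dataclass(frozen=True)
class InVitroPlatform:
    """Geometry and measured parameter ranges of the fabricated tissue platform."""

    d: float = 715e-6                 # vessel diameter, m
    D: float = 3000e-6                # tissue diameter, m
    length: float = 3000e-6           # modeled axial extent, m
    kappa_hyd: float = 1e-12          # interstitial hydraulic permeability, m^2
    tissue_porosity: tuple[float, float, float] = (0.49, 0.53, 0.59)
    vascular_porosity: tuple[float, float, float] = (0.37, 0.40, 0.43)
    solutes: tuple[InVitroSolute, ...] = (
        InVitroSolute(mw=3.0, d_f=(20e-11, 25e-11, 30e-11), p_d=(24e-8, 32e-8, 43e-8)),
        InVitroSolute(mw=70.0, d_f=(3.7e-11, 4.3e-11, 4.9e-11), p_d=(7e-8, 9e-8, 11e-8)),
    )

    def solute(self, mw: float) -> InVitroSolute:
        for s in self.solutes:
            if s.mw == float(mw):
                return s
        valid = ", ".join(str(s.mw) for s in self.solutes)
        raise KeyError(f"no in vitro measurements for mw={mw!r}; available: {valid}")


def invitro_platform() -> InVitroPlatform:
    """Parameters of the fabricated 3-D vascularized tissue platform.

    Tissue and vascular (endothelial) porosity and the per-solute diffusivity
    and permeability are (min, mean, max) triples measured on the platform;
    geometry is fixed (vessel 715 um, tissue 3000 um).
    """
    return InVitroPlatform()


# --------------------------------------------------------------------------
# In vivo intercapillary-separation survey (d = 10 um)
# --------------------------------------------------------------------------

#: Tissue type -> intercapillary separation L (m).  L/d in breast tumors lies
#: between 5 and 21.5; larger values are typical of normal tissue.
INTERCAPILLARY_SURVEY: dict[str, float] = {
    "rat mammary tumor": 50e-6,
    "rabbit neoplastic tissue": 101e-6,
    "mammary carcinoma (low)": 80e-6,
    "mammary carcinoma (high)": 135e-6,
    "normal breast tissue": 215e-6,
    "human large intestine": 107e-6,
    "human colorectal tumor periphery": 54e-6,
    "human colorectal tumor center": 177e-6,
}


def intercapillary_survey() -> dict[str, float]:
    """Measured in vivo intercapillary separations (m), keyed by tissue type."""
    return dict(INTERCAPILLARY_SURVEY)


#: Named preset registry addressable from config files.
PRESET_REGISTRY = {
    "table1_baseline": baseline_tumor,
    "table3_invitro": invitro_platform,
    "intercapillary_survey": intercapillary_survey,
}
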