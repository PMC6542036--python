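# Methods

## The model

`tumortrans` simulates passive transport of a solute (0.1–70 kDa, dextran-like)
from one or two microvessels into the surrounding interstitium of a tumor
tissue cylinder, and analyzes when the extravascular concentration peaks.
The model is a deliberately reduced description built from the classical
trio of transport laws, with the solute coupled through a
Kedem–Katchalsky wall:

* **Lumen (1-D, per vessel).** Poiseuille flow with a prescribed linear
  pressure drop `dP` from the arteriolar pressure `Par`; mean velocity
  `U = dP·d²/(32·μ·l)`. Solute enters as an exponentially decaying bolus
  `c_in(t) = Co·exp(−t/τ)` and is advected with upwinding; the venous end is
  a standard outflow boundary (zero diffusive flux, advective discharge).
  The axial flow rate is held constant along the vessel even though
  transmural filtration is a noticeable fraction (~25%) of the flow at
  baseline parameters; this only perturbs the luminal transit time, which
  is three orders of magnitude shorter than every transport timescale.
* **Wall.** Starling fluid flux `Jv = Lp(p_v − p_i − σΔπ)` (outward
  positive) and Kedem–Katchalsky solute flux
  `Js = P_d(c_v − c_i) + (1−σ)·Jv·c_upwind`. Lymphatic walls are strict
  one-way drains: `Jv = min(0, Lp_lymph(p_lymph − p_i))`,
  `Js = Jv·c_i − P_d_lymph·c_i`, with `Lp_lymph = 10×` the blood-wall value,
  `P_d_lymph = 10×` the solute permeability and `p_lymph = 0` Pa gauge
  (all configurable). The lymph lumen is not tracked; drained solute is
  accounted in the mass ledger.
* **Interstitium.** Steady Darcy flow `u = −k_hyd ∇p` solved once
  (quasi-static; the osmotic term is the constant `σΔπ`), with Robin wall
  conditions and the envelope held at the boundary tissue pressure `Po`.
  Solute obeys `φ ∂c/∂t + R_F·u·∇c − ∇·(φ D_tissue ∇c) = wall sources`,
  with `D_tissue = φ·R_F·D_f`. The homogenized first-order sink `−k·c` with
  `k = P_d·S`, `S = 4nd/D²`, is *not* inserted into the solver — the walls
  are resolved as localized fluxes — but the well-mixed limit of the solver
  reproduces the homogenized decay (property-tested at 2%).

All parameters are SI; presets carry the baseline breast-tumor set
(capillary d = 10 µm, l = 1 mm, tissue D = 200 µm, φ = 0.4,
k_hyd = 4·10⁻¹³ m²/Pa·s, Po = 2700 Pa, Par = 4394 Pa, dP = 2394 Pa,
Δπ = 2500 Pa, Lp = 10⁻⁹ m/Pa·s) and the five-solute table (σ, P_d, D_f,
R_F, Co, τ). The effective luminal viscosity (3·10⁻³ Pa·s, whole-blood
value) is a package convention: it only sets `U`. The solute mass density
ρ = 1000 kg/m³ used in the C* rescaling is likewise a convention; C* enters
results only through peak *locations*, which are invariant to constant
scales.

## Geometries and discretization

* **SBC** (single blood capillary): axisymmetric Krogh annulus in (r, z),
  finite volumes with tanh-graded radial spacing (finer at the wall).
* **2BC / BC_LC** (dual vessels at separation L in an envelope D = 2L):
  a transverse–axial slab reduction. The circular cross-section is
  represented by an effective depth `b = πD/4`; each vessel occupies only
  diameter `d` of that depth ("throat" columns), so the transverse line
  remains connected *around* the vessels — essential for the Darcy field
  (otherwise a lymph drain short-circuits to the envelope instead of
  sweeping the inter-vessel tissue). Tissue volume, wall area (`nπdl`) and
  envelope area (`πDl`) match the cylindrical domain exactly; cell-volume
  and wall-area closure are asserted at 0.1%.
* Time integration: monolithic implicit Euler on the coupled tissue+lumen
  system. Under the quasi-static fluid assumption the operator is linear
  and time-invariant, so it is LU-factored once per run; each step is one
  back-substitution. Default profile nr = nz = 40, dt = 0.5 s, outputs
  every 6 s, 4 h simulated; the fast profile (nr = nz = 20, dt = 2 s) is
  used for the full 45-run campaign. Convection is first-order upwind in
  conservative form (identical to the non-conservative form wherever
  ∇·u = 0); the discrete mass ledger (inlet = storage + venous + lymph +
  envelope outflow) then closes to machine precision, which the property
  suite checks at 0.5%.

## Measurements

Two observables are recorded per run, both normalized by the maximum
intravascular concentration (the inlet concentration Co):

* the **volume-averaged** extravascular concentration over the whole
  tissue domain (the tissue "surrounding the blood capillary"; for the
  lymph-paired configuration this is the full cylinder — the Voronoi
  half-domain partition is available as an option), and
* the **surface-averaged** concentration at a radial distance `0.2 L` from
  the blood-vessel wall (averaged over z and over both sides in the slab).

Peak values/times use parabolic interpolation through the discrete maximum
(the 6 s output cadence would otherwise quantize ~2-minute peaks).
Clearance is the linearly interpolated downward crossing of 10% of the
maximum intravascular concentration.

## Non-dimensional analysis

`T* = t / (nτ·L/d + L²/D_tissue + 1/k)` and
`C* = c_norm · (ρ/(φ·Mw)) · (L/d) / Co` (Mw in kg/mol). The printed form of
the concentration rescaling omits the concentration variable; this package
multiplies the factor by the normalized concentration, which is the only
reading that yields a concentration-like quantity — flagged as an
interpretation, and immaterial for peak times. The convection scale is
deliberately excluded from the T* denominator. The aggregate reports the
arithmetic mean and *population* standard deviation of `T*_peak` over the
unique runs of the three campaigns (15 solute-size runs, 10 counter-current
runs, 20 separation-sweep dual runs, the latter measured at the 0.2 L
station where that campaign's metric is defined), both with and without the
L/d = 125 runs, which are flagged as outlier candidates (at that
separation the second vessel cannot influence the station within the
accumulation time, so the denominator overcounts its timescales).

With these choices the decay timescales `1/(P_d·S)` reproduce the published
single-capillary values to four significant figures for all five solutes —
this is what fixes `S = 4nd/D²` (wall perimeter per cross-section area; the
nominal unit "vessels/m" given for S is not dimensionally usable). The
diffusion timescales match within 0.25% for 0.1–3 kDa and deviate 4–6% for
40–70 kDa, whose exact `D_tissue` provenance is unknown; those entries are
therefore not asserted.

## Synthetic in vitro data

The validation stage emulates the fabricated vascularized platform (715 µm
channel in a 3000 µm tissue, measured tissue porosity 0.49–0.59,
endothelial porosity 0.37–0.43, per-solute D_f and P_d ranges for 3 and
70 kDa). The platform forward model is a pressure-equilibrated special
case of the solver: constant luminal concentration (continuous perfusion,
`prescribed_lumen`), no fluid motion, wall exchange scaled by the
endothelial porosity (flux × porosity — the simplest physically consistent
reading of a porous endothelium), and the measured diffusivity used
directly as `D_tissue` (it is measured in the gel, i.e. already effective).
The generator draws ground-truth parameters uniformly within the measured
[min, max] ranges and applies multiplicative Gaussian noise (CV 10%
default — the study reports only replicate variability, no distribution;
multiplicative is the natural choice for normalized intensities) to the
600 µm station curve, N = 3 replicates over 2 h. It is reproducible
bit-for-bit from (seed, parameters).

What passing the synthetic-validation tests shows: the forward model is
identifiable (a noise-free refit recovers P_d and D_f to ≪5%), the
envelope bounding works, and the comparison plumbing is correct. What it
does *not* show: agreement with real fluorescence data, recirculation
trapping of small solutes (an unmodeled effect the study itself notes), or
imaging artifacts — intensity is identified with concentration by
construction.

## Numerical choices and degenerate inputs

* Wall exchange uses series conductances (wall permeability in series with
  the half-cell tissue resistance), which keeps the wall flux consistent
  under grid refinement; the Darcy solve uses the same form, so discrete
  fluid conservation is exact.
* The lymph one-way valve is an active-set iteration on the pressure solve
  (at baseline pressures the valve is simply open everywhere).
* At L = d the dual slab degenerates to the two throat columns (the
  vessels touch); the station measurement falls back to the nearest tissue
  column. Geometries whose vessels exceed the domain raise errors.
* Negative concentrations beyond 10⁻⁹·Co abort the run with a diagnostic;
  implicit upwinding keeps the scheme positivity-preserving in practice.
* An all-Neumann pressure system (envelope flux-free, no lymph) is refused
  with a message naming the required outer boundary condition.

## Design decisions on genuinely open points

* **Dual-domain size.** One uniform rule D = 2L for all dual-vessel runs
  (so the baseline L = 100 µm duals sit in the same 200 µm envelope as the
  single capillary). The alternative "equal tissue volume per capillary"
  reading (D = 200·√2 µm) was evaluated and rejected: the separation sweep
  lists the same dual case under both campaigns, which only one geometry
  can serve.
* **Input timescales τ** are treated as inputs, not derived: their
  inlet-decay provenance is not reproducible from the published material.
* **Counter-current flow** reverses the second vessel's inlet end; the
  bolus is applied at each vessel's own inlet.
* **Test-campaign metrics** follow where each is defined: volume-averaged
  peaks for the solute-size and flow-direction campaigns, 0.2 L surface
  peaks for the separation sweep.

## Known limitations

These are fidelity gaps of the reduced model class, documented rather than
patched; the acceptance suite asserts the corresponding published values at
face value and leaves them red.

* **A second blood capillary raises, not lowers, the volume-averaged peak
  here.** With D = 2L the dual domain has twice the wall area per tissue
  volume; in any linear Poiseuille/Starling/Darcy model doubling supply and
  sink together raises the peak (the well-mixed ODE shows this in closed
  form, and the equal-volume geometry does not change the sign). The
  published suppression (~25–31%) evidently requires the mixture-theory
  coupling of wall/interstitial fluid flux to solute concentration
  gradients, whose mechanism the source does not specify; it is noted, not
  guessed. The lymph-paired suppression, by contrast, is reproduced and
  slightly overshoots.
* **Late-time clearance is faster than published** (70 kDa reaches 10% in
  ~1.4 h vs 3.25 h): our decay is paced by wall re-uptake plus venous
  washout, whereas the study prescribed flux-free microvessel outlets,
  which recirculate reabsorbed solute. A literally sealed outlet on a 1-D
  advective lumen is ill-posed (the inlet keeps feeding), so the outflow
  condition is kept and the discrepancy documented.
* **Co-current and counter-current histories differ during accumulation**
  (up to ~19% of peak for large solutes in the two-capillary case): with
  the tabulated pressures the Starling flux changes sign along the vessel
  (filtration upstream, reabsorption downstream of z/l ≈ 0.6), and
  reversing one vessel makes the patterns complementary. The published
  curves show no accumulation-phase difference, implying a z-uniform wall
  exchange in the reference model.
* No deformable matrix, receptor binding, RBC two-phase rheology, vessel
  tortuosity or branching, and no systemic pharmacokinetics beyond the
  exponential inlet.
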