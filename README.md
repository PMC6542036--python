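# tumortrans

Reduced-order simulation of solute transport in microvascularized tumor
tissue, for researchers studying nanoparticle/drug delivery: how a
0.1–70 kDa solute injected into one or two parallel microvessels
extravasates, accumulates in the interstitium, and is cleared — and *when*
its tissue concentration peaks.

The package couples three classical components with a Kedem–Katchalsky
solute wall:

* **Poiseuille** luminal flow with a decaying inlet bolus
  `c_in(t) = Co·e^(−t/τ)`,
* **Starling** transmural exchange, `Jv = Lp(p_v − p_i − σΔπ)`,
  `Js = P_d(c_v − c_i) + (1−σ)Jv·c_up` (lymphatic walls drain one-way
  only),
* **Darcy** interstitial flow and the convection–diffusion balance
  `φ∂c/∂t + R_F·u·∇c − ∇·(φD_t∇c) = wall sources`, whose well-mixed limit
  is the homogenized sink `−kc` with `k = P_d·S`, `S = 4nd/D²`.

Three vascular configurations are built in — a single blood capillary in a
Krogh cylinder (SBC), two parallel blood capillaries (2BC), and a blood
capillary paired with a lymphatic (BC_LC) — with co-/counter-current flow
and an intercapillary-separation sweep (L/d = 1…125). Concentration
histories are non-dimensionalized by the sum of the input, diffusion and
decay timescales,

    T* = t / (nτ·L/d + L²/D_tissue + 1/k),

which collapses the peak times of all runs onto a narrow band of T*.
A synthetic-data module emulates the in vitro validation platform
(replicate dextran curves with known ground truth) so the
validation-comparison stage is fully testable.

## Worked example

```python
import numpy as np
from tumortrans import (baseline_tumor, load_solute_preset, make_geometry,
                        run_simulation, SolverOptions, compute_timescales)

tissue, _ = baseline_tumor()
solute = load_solute_preset(0.1)          # 0.1 kDa tracer, tau = 284.5 s
geom = make_geometry("SBC")               # d=10 um capillary, D=200 um tissue

h = run_simulation(geom, solute, tissue,
                   options=SolverOptions(nr=20, nz=20, dt=2.0, duration=3600))
i = int(np.argmax(h.c_norm_volume))
ts = compute_timescales(solute, geom, tissue)
print(f"peak {100*h.c_norm_volume[i]:.1f}% at {h.time_s[i]/60:.1f} min, "
      f"T*_peak = {h.time_s[i]/ts.t_star_denominator:.3f}")
```

prints

```
peak 51.1% at 2.7 min, T*_peak = 0.054
```

— the tissue-averaged concentration rises to ~51% of the inlet
concentration 2.7 minutes after injection (the small tracer equilibrates
across the wall much faster than the bolus decays), and that peak sits at
T* ≈ 0.05 of the summed transport timescales (2995 s for this solute).
Averaged over the full campaign of configurations, solutes and separations
the package obtains a mean T*_peak ≈ 0.016, inside the published
0.027 ± 0.018 band: knowing a solute's transport parameters predicts its
window of maximum tissue exposure without running the simulation.

The `examples/` directory holds one short script per capability (single
capillary, vessel configurations, timescale table, separation sweep,
T* collapse, synthetic in vitro validation); each prints the numbers it
computes with a line on what they mean. A thin CLI mirrors the pipeline:
`tumortrans test1|test2|test3|tpeak|all --outdir out [--fast]`, plus
`tumortrans presets` and `tumortrans validate-config cfg.yaml`.

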