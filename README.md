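# notchcrypt

Simulation and analysis of Notch–Delta patterning circuits in the
intestinal stem-cell niche: what does a direct positive feedback of Notch
signaling onto Notch transcription add to classical lateral inhibition?

In the crypt base, Notch-high stem cells (CBCs) and Notch-low,
ligand-presenting Paneth cells form a mosaic maintained by lateral
inhibition (LI): ligand on one cell activates receptor on its neighbor,
whose signaling then represses its own ligand.  This package implements
and analyzes that circuit with and without an additional positive feedback
(PF) in which cleaved NICD up-regulates Notch receptor production ("PFLI"),
and asks where each circuit can pattern, how fast, and how robustly when
cells grow, divide, and leave the niche.

Per cell *i* (dimensionless protein-only form; `σ`/`δ` are activating and
repressing Hill functions, `⟨·⟩` the contact-weighted neighbor mean):

    dN_i/dτ = β_N [(1−S_PF) + S_PF σ(N_i⟨D_j⟩, k_p, p)] − α_n N_i − N_i⟨D_j⟩
    dD_i/dτ = β_D [(1−S_LI) + S_LI δ(N_i⟨D_j⟩, k_d, h)] − α_D D_i − ⟨N_j⟩D_i
    dR_i/dτ = N_i⟨D_j⟩ − α_R R_i

`S_PF ∈ [0,1]` sets the positive-feedback strength (`S_PF = 0` is pure LI).

The package provides, as library modules with a thin CLI on top:

* `circuits` / `integrate` — the three model forms, exact quasi-steady-state
  reduction, analytic Jacobians, stiff ODE driver;
* `dynamics` — single-cell input–output curves with hysteresis detection,
  exhaustive pair-cell fixed-point census with stability;
* `lattice` / `patterning` — periodic hex/square lattices, maximum-Lyapunov-
  exponent (MLE) patterning maps over production rates, seeded patterning
  runs with pattern-time and mosaic metrics;
* `crypt` — a self-contained 2-D cellular-Potts (GGH) crypt-base simulator
  coupling per-cell Notch ODEs to growth, division, adhesion, anoikis and
  turnover;
* `fixtures`, `config_io`, `cli` — named parameter presets, YAML/JSON
  configs, deterministic CSV outputs with run manifests.

## Worked example

```python
import numpy as np
from notchcrypt import li_default, pfli_default, build_lattice, Topology
from notchcrypt.dynamics import single_cell_response, detect_hysteresis
from notchcrypt.patterning import match_notch_levels, simulate_patterning, pattern_time

# 1. One cell exposed to external ligand: LI is monostable, PFLI is a switch
grid = np.linspace(0, 6, 61)
print(detect_hysteresis(single_cell_response(li_default(), grid)).window)
print(detect_hysteresis(single_cell_response(pfli_default(), grid)).window)

# 2. Patterning speed on a 12x12 periodic hex sheet at matched Notch output
li_matched, scale = match_notch_levels(li_default(), pfli_default())
g = build_lattice(12, 12, Topology.HEX_PERIODIC)
t_li = np.median([pattern_time(simulate_patterning(li_matched, g, s, t_end=200.0))
                  for s in range(5)])
t_pf = np.median([pattern_time(simulate_patterning(pfli_default(), g, s, t_end=200.0))
                  for s in range(5)])
print(round(scale, 3), t_li, t_pf)
```

prints

```
None
(1.5, 2.8000000000000003)
0.869 31.25 23.5
```

LI has no bistable window (`None`): its internal ligand declines smoothly
as external ligand rises.  PFLI is bistable for external ligand between
1.5 and 2.8 — a hysteretic switch.  On the lattice, with LI's Notch
production rescaled by 0.869 so both circuits reach the same NICD level in
the patterned state, the median time to a settled mosaic is ~31 time units
for LI versus ~23 for PFLI (5 seeds; the gap is larger with more seeds):
the feedback speeds up divergence of neighboring cells into opposite
fates.

The same comparisons from the shell:

```sh
notchcrypt single-cell --circuit pfli --out-dir out/
notchcrypt pair --circuit li --out-dir out/
notchcrypt mle-sweep --out-dir out/
notchcrypt crypt-sim --circuit pfli --turnover 4 --seed 1 --out-dir out/
```

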