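# mesocell

Quantitative analysis of cells cultured on nanostructured theranostic
substrates — mesoporous silicon chips functionalized with gold
nanoparticles that steer cell organization through surface topography,
release an antitumor drug from their pores, and amplify Raman signatures
of adhesion molecules (SERS).

The package is aimed at groups running such combined culture / delivery /
sensing experiments, and implements four analysis chains plus a
synthetic-data generator with planted ground truth for every input:

| chain | core quantity |
|---|---|
| `nuclei_graph` + `cell_network` | cell positions from DAPI micrographs; Waxman spatial graph; `Cc`, `Cpl`, small-world-ness `SW = (Cc/Cc_rand)/(Cpl/Cpl_rand)` vs an Erdős–Rényi `G(n,m)` null |
| `release_kinetics` | first-order release fit `c(t) = c0 + cs(1 − e^{−t/τ})`; initial velocity `v = cs/τ`; efficiency `cs/c_load`; drug efficacy `E = 1 − N_drug/N_ctrl` |
| `sers_chemometrics` | area normalization, PCA, k-means class maps; integrin loading ratio `r` at 1569 cm⁻¹ |
| `surface_topography` | roughness `Ra`, radially averaged PSD, fractal dimension `Df = (8 − β)/2`, porosity `P`, particle/pore sizing |

The graph construction uses the Waxman rule
`P(u,v) = α·e^{−d/(βL)}` with fixed acceptance constant `R`, applied as the
deterministic criterion `P − R ≥ 0`, i.e. nodes link iff
`d ≤ d* = βL·ln(α/R)` (defaults α = 1, β = 0.025, R = 0.1, L = field
diagonal).

See `docs/methods.md` for models, conventions and limitations.

## Worked example

Run the end-to-end synthetic demo (all five stages, one consolidated
report):

```
$ mesocell demo --seed 1 --outdir demo_run
wrote demo_run/report.json with stages: ['nuclei_network', 'porosity', 'release', 'sers', 'surface']
```

Selected numbers from `demo_run/report.json` (seed 1) and what they mean:

- `nuclei_network`: 700 cells planted, `n = 676` detected (−3.4%);
  `cc = 0.634`, `cpl = 8.31`, null references `cc_rand = 0.0205`,
  `cpl_rand = 2.76`, giving `sw = 10.3` — a homogeneous layout is still
  strongly "small-world" against an ER null because spatial graphs are
  intrinsically clustered; only *relative* SW between layout classes is
  informative (clustered > uniform).
- `release`: data simulated from `cs = 4.94 μM, τ = 46 h` with noise,
  refit to `cs = 4.91, τ = 44.7`; `initial_velocity = 0.110 μM/h`
  (the noiseless pair gives 4.94/46 = 0.107 ≈ 0.11 μM/h);
  asymptotic efficiency `cs/c_load = 0.164` at 30 μM loading.
- `sers`: PC1 explains 84% of spectral variance and its loading ratio at
  1569 cm⁻¹ is `r_int = 22.2` — the planted integrin band dominates.
- `surface`: planted `Df = 2.5` recovered as 2.52 (fit R² = 0.994);
  Ra = 5.0 nm by construction.
- `porosity`: planted void fraction 0.12 measured as 0.115, identically
  from the binary mask and from the Otsu-segmented grayscale rendering.

Library use mirrors the CLI, e.g.:

```python
from mesocell.release_kinetics import ReleaseModelParams, initial_velocity

v = initial_velocity(ReleaseModelParams(cs=4.94, tau=46.0))  # 0.107 uM/h
```

Other subcommands: `simulate-nuclei`, `simulate-release`, `simulate-sers`,
`simulate-surface`, `simulate-porous`, `network-metrics`, `fit-release`,
`efficacy`, `sers-cluster`, `surface-psd`, `porosity`, `feature-size`.

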