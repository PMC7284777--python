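# Methods

`mesocell` implements the quantitative analyses used to characterize
theranostic cell-culture substrates: gold-functionalized mesoporous silicon
chips that simultaneously steer cell organization through nanoscale
topography, release an antitumor drug from their pores, and amplify Raman
signatures of adhesion molecules (SERS).  The package covers four analysis
chains plus a synthetic-data generator that plants known ground truth for
each of them.

## 1. Cell networks from fluorescence images

**Node detection.**  A DAPI micrograph is smoothed (Gaussian, sd 1 px),
contrast-stretched to [0, 1] and clustered into `k` intensity classes by
one-dimensional k-means (histogram-weighted, 1024 bins, quantile
initialization — deterministic by construction).  Classes are ranked dark to
bright; the `t` darkest classes are background.  DAPI nuclei are bright, so
the default is bright-foreground; an `invert` flag handles dark-signal
stains.  The binary mask is reduced by non-overlapping `r x r` block means
("occupancy"), where `r**2` approximates one nucleus footprint in pixels;
trailing partial blocks are averaged over their true pixel count so the
block-weighted occupancy mean conserves the foreground fraction exactly.
Blocks with occupancy above `p_thresh` become nodes at the block center.

Defaults `k = 3, t = 1, r = 6, p_thresh = 0.5` are calibrated for ~12 um
nuclei at 1.72 um/px.  One caution from the calibration: a Gaussian-rendered
nucleus segments to a footprint noticeably larger than its geometric core,
because the dim rim also separates from the background class; `r` must match
that *segmented* footprint, not the nominal nucleus diameter, or counts
drift by tens of percent.

**Graph construction.**  Nodes are wired with the Waxman rule
`P(u,v) = alpha * exp(-d/(beta*L))` with a fixed acceptance constant `R`:
a link exists iff `P - R >= 0`, which is exactly the distance threshold
`d* = beta*L*ln(alpha/R)`.  Defaults `alpha = 1, beta = 0.025, R = 0.1`;
`L` is the diagonal of the imaged field (computed from the field extent,
not the realized nodes, so sparse detections do not shrink the cutoff).
With the default 1174 x 882 um field, `d* ~ 85 um`.

**Metrics.**  Clustering coefficient `Cc` is the Watts–Strogatz local
coefficient averaged over nodes (degree < 2 contributes 0).  Characteristic
path length `Cpl` is the mean shortest hop count over *reachable* ordered
pairs; unreachable pairs are excluded rather than infinite, so fragmented
layouts keep a finite `Cpl`.  Small-world-ness is
`SW = (Cc/Cc_rand) / (Cpl/Cpl_rand)` against an Erdős–Rényi `G(n, m)`
ensemble with the graph's node and edge counts (default 20 seeded
realizations; ensemble means and sds are reported).

**What SW can and cannot show here.**  For spatially embedded graphs the
ER null has very low clustering (`Cc_rand ~ pi*d*^2 / A`, independent of
density), so *any* geometric layout scores SW well above 1.  The contrast
between aggregated and homogeneous cultures therefore depends on cluster
geometry: compact, mutually separated aggregates (within-cluster diameter
below `d*`) score higher SW than homogeneous layouts because their
within-cluster paths are short while the matched-density ER null is
connected; diffuse aggregates do not.  The synthetic comparison conditions
(below) were chosen in that regime.

## 2. Drug-release kinetics

Cumulative released concentration follows the first-order model
`c(t) = c0 + cs*(1 - exp(-t/tau))` with `cs` (uM) the steady-state
increment and `tau` (h) the system time constant (the time to reach
`1 - 1/e ~ 63.2%` of the increment; we use the exact exponential constant
throughout).  `c0` is fixed to 0 by default (release into pure water from
t = 0); fitting it is optional.  Fits are nonlinear least squares
(`scipy.optimize.curve_fit`) with bounds `cs >= 0`, `tau > 0`,
initialization `cs0 = span(c)`, `tau0` = first time the curve passes 63% of
the span.  A constant curve is returned as a flagged non-converged fit
(`cs ~ 0`, `tau` unidentifiable), never as silent defaults.

Derived quantities: initial release velocity `v = cs/tau` (the Taylor
expansion of the model at t = 0, equal to its analytic slope there);
release efficiency `c(t)/c_load` and its asymptote `cs/c_load`; drug
efficacy from adhering-cell counts `E = 1 - N_drug/N_ctrl` (all six
reported count pairs reproduce the reported efficacies under this
definition, whereas the bare ratio `N_drug/N_ctrl` matches none of them);
and the half-life extension factor `duration / drug half-life`.

The synthetic release assay samples t = 0 plus 29 geometrically spaced
times out to 240 h (10 days).  A dense-early/sparse-late schedule is the
standard design for exponential-relaxation assays; with 30 *uniform*
points most observations sit on the plateau and the tau error floor
(Cramér–Rao variance plus nonlinear-LS bias) exceeds 5% at 5% measurement
noise, while the geometric schedule keeps the median tau error near 4%.

## 3. SERS chemometrics

Spectra (700–3250 1/cm) on a 0.5-um grid are area-normalized (each
spectrum divided by its trapezoidal integral — removes pixel-to-pixel
fluorescence level and is idempotent), decomposed by mean-centered PCA
(five components by default; signs fixed so the largest-magnitude loading
element is positive), and clustered with k-means (five classes by default,
best of 10 restarts, seeded).  The integrin statistic is the loading ratio
`r = max |loading| in [1569 +/- 5 cm^-1] / mean |loading| over the axis`
on PC1.  Absolute values are used because PCA loadings are sign-ambiguous;
the max-in-window form is robust to axis discretization.  A flat loading
gives exactly r = 1; r >> 1 means the 1569 1/cm tryptophan band — the
fingerprint frequency of integrin adhesion molecules — dominates the
component.

## 4. Surface topography

`Ra` is the arithmetic mean absolute deviation from the least-squares
plane.  The power spectral density is a plane-detrended, Hann-windowed 2-D
periodogram normalized so its total equals the (window-weighted) variance
(Parseval holds to ~1%), radially averaged into 32 log-spaced `|q|` bins.
The fractal dimension of an isotropic self-affine surface with Hurst
exponent H obeys `P(q) ~ q^-(2(H+1)+2)` and `Df = 3 - H`, hence
`Df = (8 - beta)/2` from the fitted log-log slope `-beta`, clamped to
[2, 3].  The fit band drops the two lowest bins (detrending leakage) and
the top octave (discretization floor), and weights bins by the square root
of their Fourier-mode count: low-frequency bins hold only a handful of
chi-squared-distributed modes and would otherwise dominate the fit with
pure scatter.  Fits with weighted R² < 0.8 are flagged low-confidence.

Porosity is the void-pixel fraction of a binary micrograph (void = 1);
grayscale images are thresholded first (Otsu, dark phase = void by
default).  Particle/pore sizes are equivalent-circle diameters
`2*sqrt(area/pi)` of 8-connected components, excluding border-touching
components to avoid truncation bias; touching features merge by
construction.

## 5. Synthetic data: what it emulates, and what it does not

All generators are pure functions of `(params, seed)` and return planted
ground truth beside the observable.

- **Nuclei images** (default 1174 x 882 um at 1.72 um/px, the confocal
  region of interest): uniform or Thomas-process layouts.  Nuclei are
  Gaussian blobs (sd = `nucleus_radius`, default 3 um, visible diameter
  ~4 sd ~ 12 um) on a low background with additive Gaussian noise.
  Defaults plant 700 cells — the order observed per region of interest in
  the cultures this emulates (~540–880).  The clustered condition uses 25
  parents with 25 um offspring sd: compact aggregates of ~30 cells,
  separated on the scale of the Waxman cutoff, restricted to the window by
  rejection sampling (clipping would pile mass on the border and corrupt
  segmentation).  Not modelled: optics/PSF, photon noise, intensity
  heterogeneity between nuclei, 3-D stacks.  Passing tests show the
  pipeline recovers planted structure under these idealized conditions,
  not that it is robust to microscope artifacts.
- **Release curves**: exact model plus i.i.d. Gaussian noise, floored at 0.
- **SERS maps**: smooth fluorescence baseline + class-specific
  Lorentzian/Gaussian bands + noise.  The adhesion class carries the six
  fingerprint bands (1126, 1175, 1306, 1506, 1569, 1645 1/cm) with 1569
  strongest.  No baseline drift, cosmic rays, or detector effects.
- **Fractal surfaces**: spectral synthesis — white noise shaped by
  `|q|^-(8-2*Df)/2`, inverse-transformed, rescaled so the plane-detrended
  Ra equals the target exactly (Ra is linear in amplitude).
- **Porous micrographs**: random disks stamped as void until the target
  fraction is hit within 0.5% (exact at 0 and 1).

## 6. Numerical and design choices

- 1-D k-means on a fixed 1024-bin histogram: deterministic, O(bins) per
  iteration, independent of image size; class boundaries are midpoints of
  adjacent centers.
- The Waxman rule is applied as the deterministic decision rule (fixed R),
  not as a Bernoulli draw; this makes graph construction reproducible and
  equal to a distance threshold, which the tests exploit as an exact
  oracle.  (The source description of R is internally inconsistent —
  "R = 0.1 so that the probability of being a connection is 0.9" — the
  inequality form with R = 0.1 is taken literally, i.e. links require
  P >= 0.1.)
- `G(n, m)` rather than `G(n, p)` null: conditioning on the exact edge
  count removes one source of variance from the SW denominator.
- Per-stage seeds in pipeline runs derive from the master seed by fixed
  offsets; every random operation receives an explicit seed and identical
  configs reproduce byte-identical outputs.
- Rounding of report-table values is two-decimal half-up.
- Degenerate inputs (blank images, constant curves, zero-area spectra,
  edgeless graphs) return flagged/NaN results with warnings rather than
  raising, so batch runs survive empty fields.

## 7. Known limitations

- Network metrics from the original micrographs are not reproducible (no
  images are deposited); only direction-of-effect comparisons between
  synthetic layout classes are claimed, and the SW contrast holds in the
  compact-aggregate regime described above, not universally.
- The reported loading-ratio values (r ~ 4.5) and the "~90% in five PCs"
  variance figure depend on the original spectra and are likewise not
  reproduction targets; synthetic maps verify the machinery instead.
- The porosity/particle-sizing procedure reconstructs a standard
  Otsu + connected-components analysis; the reference values (P ~ 12%/40%,
  particle size 8 +/- 1 nm) are used as round-trip targets for the
  synthetic generator only.
- Problem sizes in tests (512² surfaces, 10-seed ensembles, 20–50 null
  replicates) were chosen to make sampling error small relative to the
  asserted tolerances while keeping the default suite fast.
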