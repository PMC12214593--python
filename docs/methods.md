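# Methods

`bretpharm` implements a quantitative workflow for asking which domain of
a G protein-coupled receptor — the transmembrane helix-bundle ("core")
or the phosphorylated C-terminus ("tail") — drives β-arrestin
conformational changes and their downstream functional consequences.
The experimental system it models is the wild-type/chimera quartet
b2AR, V2R, b2V2 (b2AR bundle + V2R tail) and V2b2 (V2R bundle + b2AR
tail), read out with intramolecular FlAsH-BRET conformational
biosensors (positions F1–F10 on β-arrestin), a bead-based
phosphosite immunoassay (OD 405 nm), pERK/total-ERK Western-blot
densitometry, and Rab5 co-localization from segmented confocal images.

## BRET signal model and processing

A well's measured quantity is the acceptor/donor emission ratio over
time. The processing chain is:

1. **Labeling correction.** Technical replicates are averaged per
   condition and time point; the mean mock-labeled (no acceptor
   ligand) signal is subtracted from the mean labeled signal. This
   removes the acceptor-independent background.
2. **Baseline normalization.** Each corrected series is divided by its
   mean over the pre-stimulation baseline window (default the 3 min of
   monitoring before ligand addition, a closed interval `[-3, 0]` min
   relative to stimulation). Baselines with absolute mean below 1e-9
   mark unusable wells and raise.
3. **Vehicle normalization.** The baseline fold change is divided by
   the *time-matched* vehicle trace of the same condition, giving the
   dynamic Δ net BRET change. A scalar-mean vehicle divisor would also
   be defensible; time-matched division is the default because it also
   cancels slow shared drifts exactly. The percent convention is
   `(fold − 1)·100`; the raw fold is available for recruitment-style
   analyses.
4. **Window averaging.** The Δ net change is averaged over the closed
   2–4 min post-stimulation window into one scalar per concentration.
5. **Anchoring.** Concentration series (vehicle excluded — its log
   concentration is undefined; it acts only as the divisor in step 3)
   are anchored by subtracting the response at the lowest tested
   concentration, which therefore maps to exactly 0. At least four
   distinct concentrations are required for fitting.

The synthetic plate generator inverts this chain by construction:
stimulated wells carry `background + base·drift(t)·(1 + r(c)·step(t))`
with `r(c)` the 4PL fold-change response, mock wells only the additive
background, and vehicle wells the driftful unstimulated signal. At
zero noise the full chain returns `100·r(c)` (percent convention)
up to the anchor shift, to floating-point accuracy; a multiplicative
vehicle drift (default 0, configurable per min) cancels identically.
The ligand-addition time offset is a configurable constant (default
0): time points at or before it count as baseline.

## Concentration–response model and responder gating

Responses are fitted with the four-parameter logistic model

    y(x) = bottom + (top − bottom) / (1 + 10^((log10 EC50 − x)·h)),

`x = log10(concentration/µM)`, `h` the Hill slope. Fitting is
unbounded multi-start nonlinear least squares (SciPy trf with the
analytic Jacobian; ftol = xtol = gtol = 1e-10, ≤400 evaluations per
start): starts place `log10 EC50` at the minimum, median and maximum
tested log concentration crossed with Hill slopes ±1, asymptotes
initialised from the response extremes. The best residual sum of
squares wins. Because the model is invariant under
`(bottom, top, h) → (top, bottom, −h)`, the fit is reported in the
canonical form `top ≥ bottom`, so the Hill sign encodes curve
direction and negating all responses negates the fitted slope.

"No fit could be defined" maps to either optimizer non-convergence or
a numerically rank-deficient Jacobian at the winning solution
(condition number > 1e8). The latter catches the two degenerate
situations the gate must reject: exactly flat data (the EC50/Hill
columns vanish when top = bottom) and noise-interpolating step fits
whose slope is so steep that every data point sits on a plateau.

A condition is *responding* iff a fit is defined, `|h| > 0.1`
(strict), `log10 EC50 ∈ [−3, 0.3]` (closed; the tested concentration
window, outside which no sigmoid is supportable by the applied
ligand concentrations), and the condition is not on the manual
override list (reserved for concentration-independent drifts that the
automated gates cannot see; supplied as configuration, reason code
`manual`). Non-responders are assigned a gated value of exactly 0;
responders carry the *observed* response at the highest tested
concentration (not the fitted span — the fingerprint should show what
was measured, not what the asymptote extrapolates to). No parameter
bounds are used during fitting: bounds would silently convert
non-responders into boundary responders, whereas the gates reject them
with an auditable reason.

Deliberate limitation: on pure-noise (flat) data the 4PL fit passes
the Hill/EC50 gates for a scale-invariant fraction of datasets
(measured ≈ 4–8% on the validation panel). This is a property of the
gate definition itself, not of the optimizer; no additional automatic
flat-detection is layered on top, because the gate set is part of the
method under test.

## Fingerprints and clustering

A fingerprint maps each sensor position to its gated response for one
receptor × GRK condition × arrestin isoform; non-responders enter as
exact zeros *before* any normalization. Display normalization divides
by the maximum absolute response so the maximally reacting sensor maps
to ±1 (idempotent, scale-invariant; all-zero fingerprints are
returned unchanged and flagged). Fingerprint matrices are clustered
agglomeratively under Manhattan (city-block) distance; linkage
defaults to complete (configurable: complete/average/single — the
source material does not name one, so this is an explicit package
choice, not an inference). Rows are sorted lexicographically by key
before clustering so merge ties break deterministically. Outputs are
plot-ready tables and a bracket-notation merge tree; no chart or
structure rendering is attempted.

## Downstream readouts

* **Phosphorylation (OD 405 nm).** Per plate and antibody cluster:
  the mean background-well OD is subtracted everywhere; each
  phospho well is divided by its matched, background-subtracted
  loading-control well (the "corrected according to its loading
  control" step, implemented as the standard ratio correction); the
  result is rescaled linearly so the unstimulated negative control is
  0% and the maximal-agonist Control positive control is 100%.
  Normalization is per plate, so a global OD gain cancels exactly.
* **ERK1/2 activation.** ratio(t) = pERK(t)/totalERK(t); the summary
  statistic is the trapezoidal AUC over the measured 0–30 min grid.
  Baseline subtraction before the AUC is off by default (exposed as a
  flag-equivalent by pre-transforming the ratio column).
* **Endosomal co-localization.** Segmentation is upstream; inputs are
  quantified signal tables. Signals are averaged per condition,
  divided by the unstimulated ΔQ-GRK + empty-vector reference of the
  same pair and receptor (fold change), and additionally expressed as
  percent of the per-pair dataset maximum for the two-axis scatter
  (receptor–Rab5 vs arrestin–Rab5).

## Transferability coefficient

For a harmonized quartet response r(·):

    tail  = |r(b2AR) − r(b2V2)| + |r(V2R) − r(V2b2)|
    core  = |r(b2AR) − r(V2b2)| + |r(V2R) − r(b2V2)|
    coefficient = tail − core
    wt_difference = |r(b2AR) − r(V2R)|   (bubble-size magnitude)

Exactly the two listed wild-type/chimera pairings enter each sum.
Positive coefficients mean the readout follows the C-terminus,
negative the helix-bundle; exactly 0 is labelled indeterminate rather
than forced into a class, and no significance threshold is imposed —
the raw value and the wild-type difference are reported and
interpretation is left to the user. The statistic is scale-equivariant,
shift-invariant, and antisymmetric under exchanging the two chimeras.

Per-assay harmonization before scoring: conformational fingerprints
are divided by the per-receptor maximum absolute gated response (zeros
assigned first); phospho values are already percent-of-Control-max and
are used as fractions; recruitment/co-localization responses are
divided by the ΔQ-GRK basal reference and the quartet maximum; ERK
AUCs are divided by the value of the time point with the maximal
measured response for that receptor.

## Synthetic data: what it emulates, and what it does not

Every generator is deterministic given (configuration, seed) and
carries its ground truth:

* **BRET plates** — 4PL concentration dependence per (receptor,
  sensor) in fold-change units (`top = 0.2` ⇒ 20% Δ net BRET change at
  saturation), flat non-responders (`top = bottom`), mock-labeling
  background, shared multiplicative vehicle drift, technical
  triplicates, additive Gaussian ratio noise.
* **Receptor quartets** — responses driven by the tail, the core, or a
  `mix_weight` blend, over the b2/V2 domain composition of the four
  variants.
* **ERK time courses** — difference-of-exponentials kinetics
  `exp(−k_slow t) − exp(−k_fast t)` scaled to a configurable peak
  amplitude above baseline. Rates are fixed at (2.0, 0.35)/min for the
  transient class and (0.8, 0.05)/min for the sustained class: the
  published kinetics give peak times (2 min vs 5 min on the
  0/2/5/10/30 min grid, transient signals back near baseline by
  10 min), not a functional form, and these pairs land the noiseless
  argmax on those grid points with the stated decay behavior.
* **Phospho plates** — OD wells with background, matched loading
  controls and per-cluster negative/positive controls constructed so
  the quantification chain inverts the configured
  fraction-of-Control-max exactly at zero noise.
* **Co-localization tables** — fold changes over an auto-included
  ΔQ-GRK + empty-vector basal reference.

Noise is additive Gaussian on the raw instrument scale, truncated at
physical floors (OD and signals at 0). Replicate-to-replicate variance
magnitudes are configurable defaults, not calibrated to any particular
instrument — the source experiments publish none. The generators do
not model optics, luciferase substrate decay, plate-position effects,
image formation, or biological between-day variability; a clean round
trip therefore demonstrates correctness of the analysis algebra, not
robustness to structured artefacts of real plates.

The validation panel for responder gating uses 50 sigmoidal sensors
(tops 5–25%, log10 EC50 in [−2, −0.2], Hill in [0.7, 1.5] — curves an
experimenter would call well-behaved within the tested dilution
series) and 50 flat sensors on a ten-step half-log dilution series
(1e-3 to 10^1.5 µM). Noise is applied per technical-replicate
measurement with the default triplicates averaged before fitting,
matching the processing contract (single wells are never fitted
directly).

The two end-to-end attribution studies fix the domain driver by
construction: arrestin–Rab5 endosomal delivery increases only for
receptors carrying the V2R C-terminus (tail driver), and ERK kinetic
class follows the helix-bundle (transient for b2AR-bundle receptors,
sustained for V2R-bundle ones), which makes the normalized AUC a
core-driven readout. Studies run at a measurement-level effect/noise
ratio of 5 with three technical replicates per condition. Because the
co-localization fold divides by a *noisy* basal reference, the
effective response noise has heavier tails than the nominal ratio
suggests; the sign-recovery rate of the coefficient is reported rather
than assumed.

## Numerical choices

* 4PL exponent clipped at ±50 to keep `10^z` finite during
  optimization (saturates the sigmoid exactly).
* Baseline-division guard: 1e-9 absolute.
* Jacobian condition limit for "fit defined": 1e8.
* Cluster merge ties: lexicographic row order.
* Trapezoidal AUC requires strictly increasing time points
  (duplicates would double-count a segment).
* Problem sizes in the validation suite (20 fit-recovery instances,
  the 100-condition gate panel, 100 seeded repeats per sign-recovery
  study) were chosen so the whole validation completes in well under a
  minute on one core while keeping binomial rates readable at the
  percent level.

## Known limitations

* The gates cannot distinguish a genuine weak responder from
  favourable noise near the gate boundaries; accuracy on the synthetic
  panel at 5%-of-maximum noise is 94–98% across seeds, bounded mostly
  by the pure-noise pass rate discussed above.
* Manual overrides are pure configuration; the package cannot decide
  which conditions deserve them.
* Harmonization assumes each readout provides exactly the four
  canonical receptor variants; partially measured quartets (e.g. an
  unmeasurable receptor–isoform combination) are rejected rather than
  imputed.
* The transferability coefficient is reported without an uncertainty;
  propagating replicate noise through the harmonization chain would
  require bootstrap machinery that is out of scope here.
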