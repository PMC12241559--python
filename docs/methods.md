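# Methods

This note documents the models behind `svlocus`: what the synthetic
generators emulate, how the analysis operations are defined, the numerical
choices, and the limits of what the synthetic setting can show.

## Coordinate model and structural-variant presets

Coordinates are 1-based and inclusive, so the captured region
chr13:54,000,001–57,300,000 has length 3,300,000 bp and exactly 660 bins at
the 5-kb working resolution. Bin `k` covers
`[start + k·B, start + (k+1)·B − 1]`.

The synthetic locus places the promoter `P` 1.5 Mb into the region, with
landmark spacings fixed to the published geometry: *Pen* 400 kb from `P`,
*RA4* at 225 kb, *PDE* at 116 kb, *PelB* promoter-proximal (30 kb), and the
repressed neighbour gene `N` 600 kb on the opposite side. Eight oriented
CTCF sites are laid out so that four fall between `P` and *Pen*; orientation
is carried in the data model but only the count of intervening sites enters
the quantitative models below.

An allele is an ordered list of edits (inversion, deletion, insertion) on
the reference, maintained internally as an ordered list of oriented
reference segments. This gives exact, total allele→reference liftover
(bijective outside deletions; inversions map `x` in `[a,b]` to `a+b−x`) and
an inverse that fails loudly on deleted material. All breakpoints must lie
on bin boundaries: the analysis operates at bin resolution, each allele bin
then maps wholly into one reference bin, and whole-matrix liftover becomes
an exact accumulation that conserves total counts.

Preset alleles: `Inv1`/`Inv2` invert the interval from the *RA4*/*PDE* bin
to the end of the *Pen* fragment, carrying *Pen* to the respective enhancer
position; `Rel1`/`Rel2`/`Rel3` delete the 10-kb *Pen* fragment and reinsert
it at *RA4*, *PDE*, or just upstream of the promoter (centre-to-centre
~10 kb), on the *Pen*-deleted background. The published inversion sizes are
not geometrically compatible with the published landmark spacings on a
single synthetic axis (an inversion that swaps *Pen* with *RA4* must span at
least their 175-kb separation); the presets therefore pin the landmark
spacings, snap breakpoints to the bin grid, and record the published sizes
and distances as preset metadata.

## Contact-map generator

Expected contacts combine three standard ingredients, multiplied entrywise:

- **distance decay** `(|i−j|+1)^(−α)` with α = 1.0 by default, a typical
  decay exponent for sub-megabase separations;
- **insulation** `β^(#CTCF sites strictly between i and j)` with β = 0.7 —
  each boundary crossing attenuates contacts by 30%;
- **cell-state loops** `1 + Σ κ·exp(−((i−a)² + (j−b)²)/(2w²))`, isotropic
  Gaussian bumps of width w = 2 bins. The active state stacks the promoter
  on its enhancers (κ = 3 for *P*–*Pen*, κ = 1.5 for *P*–*PelB*/*PDE*/*RA4*);
  the inactive state forms the repressive *P*–*N* contact (κ = 2.5).
  Amplitudes are free parameters of the simulator — no quantitative loop
  strengths are published — chosen at the few-fold enrichment scale real
  loops show over their local background.

The matrix is normalised to a total of N = 5×10⁶ expected read pairs,
a realistic valid-pair yield for a capture experiment over one locus.
Observed maps are independent Poisson draws on the upper triangle, mirrored;
a negative-binomial option (gamma–Poisson, `var = μ + a·μ²`) is available
for overdispersion and off by default. Bulk maps are mixtures
`p·E_active + (1−p)·E_inactive`; sorted populations use a 0.95 sorting
purity in scenario runs.

The generator produces no coverage biases along the axis (beyond what decay
and insulation induce), no trans or out-of-region contacts, no fragment-level
artefacts, and no compartment structure. Consequently, passing tests show
that the pipeline's algebra and detection logic are correct under the
stated statistical model — not that they are robust to the full artefact
spectrum of experimental Capture-HiC.

## Balancing, distance normalisation, subtraction

**Knight–Ruiz balancing** uses the inner–outer Newton/conjugate-gradient
iteration of the original algorithm, restricted to the captured region.
Zero-coverage bins are masked first (balancing diverges on empty rows; the
row-sum threshold is configurable). Convergence is declared when every
unmasked row sum is within the relative tolerance (default 1e-6) of the
target. The target defaults to the *mean unmasked raw row sum* rather than
1, keeping balanced values on a count-like scale so subtraction magnitudes
remain comparable across samples; a numeric target (e.g. 1.0) is accepted.

**Subdiagonal scaling** removes the distance-decay difference between two
balanced maps before subtraction: for each separation d, each map's d-th
subdiagonal vector is divided by its own sum and multiplied by the average
of the two sums. The same factor is applied to the matching superdiagonal,
preserving symmetry; the main diagonal is included by default (a flag
excludes it). Masks are harmonised to their union first — otherwise the two
sums run over different entry sets and the subtraction map loses its
zero-sum property. A diagonal with signal in only one map keeps the zero
side at zero and scales the other to the average, with a logged warning.
After scaling, both maps carry identical per-separation totals, so every
subdiagonal of the subtraction map `S = A′ − B′` sums to zero and `S` is
exactly antisymmetric in its inputs. Truncation for display clips contact
maps at the 99th percentile of unmasked upper-triangle values, and
subtraction maps symmetrically by magnitude, preserving sign; scenario
heatmaps share one recorded colour bound across alleles.

**Quantification.** Virtual-4C profiles average the anchor's rows; anchor
windows default to the landmark bin ±1 (15 kb), matching the size of a
contact dot at 5-kb resolution. Anchor-pair quantification averages the
anchor×anchor rectangle. Masked bins are excluded and reported as missing,
never as zero. Cross-allele comparisons run in reference coordinates after
matrix liftover, and default to balanced values (the choice is recorded in
the profile metadata).

**Differential-signal localisation.** Raw subtraction values are dominated
by the near-diagonal count scale, and relative differences by far-diagonal
sampling noise, so extrema are located on a per-separation z-score: the
subtraction map divided by the per-diagonal mean of the averaged pair,
smoothed with a Gaussian matched to the loop width (a matched filter), then
standardised per diagonal by a robust (MAD) noise estimate. The search is
restricted to 5–200-bin separations. A variance estimate at the default
read depth puts planted-loop z-scores at ≈10–18 against a ≈4σ noise
ceiling, which the seeded end-to-end tests confirm.

## Proportion of expressing cells

Fluorescence is modelled in log10 units as a two-component Gaussian
mixture: an off component (location 1.0, scale 0.25) shared with the paired
negative-control sample, and an on component (location 3.0, scale 0.15)
whose location is identical across alleles by default — a soft shared
ceiling rather than a hard truncation, matching the observed sharp upper
limit of reporter abundance in expressing cells. The narrow on-scale
encodes that expressing cells pile up against this ceiling; it also keeps
the 0.99-quantile ceiling statistic stable (quantile noise scales with the
component scale over the square root of the positive count).

Two estimators of the positive fraction are implemented independently:

- **Gating**: threshold at the 99.9% empirical quantile ("lower"
  definition, so the gate is an observed control value) of the negative
  control, held fixed across alleles within a run; cells strictly above the
  gate count as positive (ties are negative). The 0.1% control
  false-positive rate bounds the estimator's bias at ≈0.001.
- **Mixture EM**: two-component Gaussian EM with median-split moment
  initialisation plus four seeded random quantile-split restarts, keeping
  the best likelihood; convergence at log-likelihood gain < 1e-8. The
  component with the greater location is always reported as "on"; fits
  whose components are separated by less than half their combined scales
  are flagged single-component.

The two estimators agree within ~0.002 at default separations; the
agreement tests use a 0.03 envelope.

The **proportion response** maps allele geometry to the expected positive
fraction: `p = logistic(θ₀ − θ₁·log10(distance) − θ₂·n_CTCF)`, strictly
decreasing in both arguments. The functional form is a modelling choice —
only the monotone direction is established — and the coefficients are
calibration constants, fit by weighted least squares to the five reported
allele proportions (6.4%, 27%, 2%, 59%, 62% at their reported distances and
CTCF counts). Those anchors are not jointly consistent with any smooth
logistic (the inversion and relocation series disagree at matched
distances), so the fit weights the saturated shortest-distance anchor
(weight 8) — the best-determined regime, where the response has plateaued —
and bounds the distance coefficient below at 0.05 to preserve strict
monotonicity. Frozen coefficients: θ = (0.7392, 0.0500, 1.1712); the
calibration routine that reproduces them ships in `svlocus.config`. The
model then predicts 63% for the promoter-proximal relocation and 1.4% for
the wildtype geometry. Scenario runs evaluate the response at each allele's
*geometric* (allele-derived) distance and CTCF count; the published
distances remain available as preset metadata.

## Expression model

Each expressing cell transcribes the reporter at a fixed level, so a
sample's expected reporter count is `active_level × p_active × depth`:
sorted-positive samples plateau at `active_level` regardless of allele,
and bulk samples scale linearly with the proportion. Housekeeping genes
(1,000 of 2,000 by default) have sample-independent expected expression up
to the depth factor; the remaining genes carry log-normal per-sample
biological noise (CV 0.5). Counts are Poisson.

FPKM is `counts / (length_kb × mapped_millions)`. The housekeeping
correction coefficient is `1 / median over housekeeping genes of
(FPKM / per-gene cross-sample geometric mean)` — a median-of-ratios
restricted to the stable set, adopted as the closest standard construction
for a coefficient-based FPKM adjustment; the exact published procedure is
external and not fully specified. The construction removes per-sample
scalar distortions exactly up to one global gauge factor `(∏c)^(1/S)`
inherent to any geometric-mean-referenced scheme (DESeq size factors share
it): between-sample structure is exactly invariant, and scalars with unit
product cancel entirely. Genes with a zero FPKM in any sample are excluded
from the median; a sample whose housekeeping genes are all zero is an
error naming the sample. Fold changes between groups use median-of-ratios
size factors over all genes with a pseudocount of 1 raw count;
differential-expression testing is out of scope.

## Problem sizes and determinism

Default problem sizes — 660 bins, 5×10⁶ reads per map, 20,000 cells per
fluorescence sample, 2,000 genes — are the package's standard study
conditions; the seeded test suite and the acceptance script run them
directly (the full six-allele scenario takes a few seconds on one core).
Every stochastic step takes an explicit seed; scenario outputs embed the
config hash and seed, and identical configurations reproduce byte-identical
TSV outputs.

## Known limitations

- The segment engine requires each edit's reference interval to be
  contiguous in the current allele; arbitrarily nested SV compositions are
  rejected rather than mis-mapped. Single-chromosome only; no FASTA or
  liftover-chain handling.
- The logistic proportion response compresses a genuinely non-logistic
  anchor set; it is a calibrated interpolation device, not a mechanistic
  model of enhancer scanning.
- CTCF orientation is recorded but unused quantitatively, although the
  divergent inversion/relocation behaviour at matched distances suggests
  orientation matters; modelling it would require data the synthetic
  setting cannot supply.
- The EM mixture assumes exactly two Gaussian components in log space;
  heavy-tailed autofluorescence or partial-expression intermediates would
  bias the weight estimate in ways the gating estimator would not share.
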