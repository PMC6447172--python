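# Methods

## Activity data model

IC50 values are stored in nmol/L exactly as assay tables print them; the
mol/L conversion (×10⁻⁹) happens only inside the pIC50 transform,
pIC50 = −log₁₀(IC50 × 10⁻⁹). Measurements reported as "> limit" are
censored at the table's limit and assigned the limit's own pIC50, so a
500 nmol/L limit yields exactly 6.30103 whether the table prints "=500" or
">500" — the two cases are experimentally indistinguishable at the assay's
dynamic range and are treated identically downstream.

Cross-reactivity is CR = 100 × IC50(reference)/IC50(analyte), formatted the
way assay tables print it (integers at ≥10%, one decimal below). Because
published CR and IC50 columns are rounded independently, a reconstructed CR
can differ from a printed one by up to a few percent; the packaged
20-triazine table contains three entries whose printed CR and IC50 are
mutually inconsistent beyond rounding, and the tests exclude exactly those.

Train/test splits enforce the interpolation constraint standard in QSAR
validation: the test set's pIC50 range must lie inside the training range.
Splits are drawn by rejection sampling with a configurable retry budget
(default 1000) and are deterministic given a seed. Note that any training
set containing one global-maximum and one global-minimum compound satisfies
the constraints, so with ≥ 2 training compounds a valid split always
exists; the retry budget guards pathological seeds, not unsatisfiability.

## 2D MLR engine

Models are ordinary least squares on named descriptor columns. The
statistic suite follows common QSAR practice:

* r² = 1 − SS_res/SS_tot (SS_tot about the observed mean); SDEC/RMSE uses
  an N divisor.
* adjusted r² uses the n − p − 1 correction.
* q²(LOO) literally refits the model once per left-out compound — no
  hat-matrix shortcut — so the reported value is by construction the one a
  fold-loop produces.
* predictive r² applies the r² formula to test-set predictions from the
  train-fitted model, with SS_tot about the test mean.
* Friedman lack-of-fit is not uniquely standardized; this package uses
  LOF = (SS_res/N)/(1 − (p + 1 + d·p)/N)² with smoothing parameter
  d = 0.5 (the common GFA default). It is a documented convention for
  comparing models of different size, not a reproduction of any particular
  implementation.
* RMSE is reported on the training set; maximum error spans train ∪ test.

Descriptor contributions generalize the three-descriptor difference
quotient to arbitrary k by the leave-one-descriptor-out construction
α(xᵢ) = [R²(all) − R²(all∖xᵢ)]/[k·R²(all) − Σⱼ R²(all∖xⱼ)] × 100; at k = 3
this reduces exactly to the printed form. Contributions are signed (a
descriptor whose removal raises R² gets a negative share) and sum to 100%
by the normalizing denominator. By default they are computed on the
training split; a full-set variant is a flag away.

Subset search is exhaustive over k ≤ 4 descriptors, ranked by q²(LOO) with
ties broken by predictive r² then lexicographic names — fully
deterministic.

## Molecular interaction fields

The probe is an sp³ carbon with charge +1 e. Steric energy is
Lennard-Jones 6–12, E = Σᵢ Aᵢ/rᵢ¹² − Bᵢ/rᵢ⁶; electrostatic is Coulomb,
E = k Σᵢ qᵢ/rᵢᵐ with k = 332.0636 kcal·Å·mol⁻¹·e⁻² and m = 1 (unit
dielectric) by default; m = 2 selects the distance-dependent dielectric
common in CoMFA. Per-atom A/B come from an editable per-element table of
Tripos-5.2-style (R, ε) values combined with the probe as
r_min = Rᵢ + R_probe, ε = √(εᵢ·ε_probe) — drop in a different YAML to use
another force field. Partial charges are read from input files and never
recomputed.

The lattice defaults to 26 × 18 × 22 Å at 2 Å spacing
(floor(extent/spacing)+1 nodes per axis → 14 × 10 × 12 = 1680 nodes per
field), centred on the centroid of the aligned set unless an explicit
origin is given (needed for bit-reproducible maps). Linear column order is
x-fastest; the steric block precedes the electrostatic block.

A grid node coinciding with an atom would be singular; it receives a
±10⁶ kcal/mol sentinel so the cutoff filter resolves it exactly like any
steeply repulsive close contact. Preprocessing applies, in order:
(1) |E| < 0.05 kcal/mol → 0; (2) truncation to ±30 kcal/mol (truncation,
not deletion — the standard CoMFA convention); (3) drop columns with
SD < 0.1; (4) drop columns with fewer than 5 nonzero entries. The
operation is idempotent, which the tests assert directly.

## PLS and cross-validation

PLS1 via NIPALS on mean-centred X and y. Each component's weight vector is
seeded from the covariance of the deflated X with the response residual, so
there is no random initialization; for a single response the iteration
converges at its fixed point immediately, and the loop exists to enforce
the orthogonality invariants at tolerance. Regression coefficients are
flattened back to the column space via b = W(PᵀW)⁻¹q.

q² uses the printed formula with y_mean the mean of the full observed
vector; SDEP/SDEC divide by N, not N − 1. LOO refits per left-out molecule.
LMO draws random 75/25 partitions, computes q² on each held-out quarter,
and reports the mean over repetitions (default 50) plus the SDEP pooled
over all held-out predictions; repetitions with degenerate training
responses are skipped with the divisor adjusted. The default component
count is the argmax of q²(LOO) over 1–5 components, overridable. The
F statistic is reported as [r²/p]/[(1 − r²)/(n − p − 1)] with p = the
component count — a convention, since F definitions vary across QSAR
software.

Field contributions are Σ|bⱼ|·SD(xⱼ) per field kind, normalized to 100% —
the same weighting ("stdev·coeff") used for contour export. Contour maps
carry one scalar grid per field with dropped columns at exact zero and a
JSON sidecar giving the positive/negative percentile levels used for
favorable/unfavorable surfaces; raw-coefficient export is available.

## SRD and FFD variable selection

SRD seeds are the columns of largest |weight| from a preliminary PLS fit
(default one seed per 10 columns). Columns join their nearest same-field
seed within the critical radius (default 1 grid spacing); groups whose
seeds are within the collapse radius (default 2 spacings) merge; everything
else stays singleton. Deterministic given inputs.

FFD lays a two-level Hadamard fractional factorial over the groups plus 20%
as many dummy variables, augmented with its fold-over so main effects are
free of two-factor-interaction aliasing (resolution IV). Every design row's
SDEP comes from LMO cross-validation using the *same* partitions (common
random numbers), so between-row SDEP differences reflect variable inclusion
rather than resampling noise. A variable's effect is mean SDEP over rows
including it minus mean SDEP over rows excluding it. A group is retained
only when its effect beats the dummy significance band,
effect < mean(dummy) − 2·SD(dummy): groups whose contribution is
indistinguishable from dummy noise — including actively detrimental ones —
are dropped. This keep-only-demonstrably-helpful convention is the stricter
of the two readings of dummy-band screening; with few samples, pure-noise
variables that correlate with y by chance are otherwise unremovable. If no
group clears the band the screen is deemed uninformative and all groups are
retained.

## Synthetic data: what it emulates and what it does not

The descriptor generator draws standard-normal descriptors (optionally with
a given covariance, since real descriptor pools are collinear) and builds
y = c + Σaⱼxⱼ + N(0, σ). Defaults mirror the study scale: 20 compounds and
a planted three-descriptor model with coefficients shaped like the leading
published model (6.302 intercept; 6.182/0.946/0.062).

The molecule generator perturbs a fixed scaffold — a six-membered C₃N₃ ring
with a chlorine and two amino arms, loosely a chloro-diamino-s-triazine —
with Gaussian coordinate jitter (default SD 0.3 Å) and zero-sum charge
jitter (default SD 0.05 e), producing an aligned congeneric series on one
frame. The standard 3D benchmark uses 20 such molecules on the study-sized
lattice with noiseless activity spread ≈ 6.3–9.6 pIC50 units, matching the
assay's dynamic range.

Planted field activities come in two modes. Arbitrary sparse weight maps
over thousands of collinear grid columns are *not identifiable* from 20
molecules, so the default plants the weight vector inside the span of the
kept matrix's three leading principal directions, rescaled to the target
activity range: that truth is exactly recoverable (the PLS Krylov space
stays inside the planted span, so at zero noise the coefficient correlation
reaches 1 and LOO q² approaches 1). Explicit sparse maps remain available
for localized-signal tests (contour recovery), where the assertion is
spatial — the top-percentile contour cells coincide with the planted
region — not coefficient-wise.

The grouped screening benchmark (for FFD) uses 60 samples: 5 signal groups
that are noisy copies of mutually orthonormal latent factors (orthonormal
so each group carries information no other group duplicates — the
analogue of distinct spatial regions reporting different substituent
effects) and 15 pure-noise groups of higher-variance columns.

What passing these benchmarks shows: the estimators, cross-validation loops
and selection machinery are correct on data with the assumed
linear-in-fields structure. What they do not show: anything about real
triazine geometries, AM1 charges, alignment quality, or the published
models' probe parameters — those inputs are not machine-readable in the
public record, so the published 3D q² values are structural references, not
reproduction targets.

## Numerical choices and limitations

* Problem sizes in tests and the acceptance script (20-molecule benchmark,
  60-sample screening benchmark, 10–20 seed replications) are chosen as the
  smallest sets on which the asserted properties are stable.
* NIPALS stops early if X deflates to numerical zero; component counts
  request an upper bound.
* Zero-variance responses, rank-deficient descriptor blocks, inconsistent
  grids and out-of-range planted columns raise immediately with the
  offending name in the message.
* The MOL2/SDF/XYZ readers assume one conformer per molecule and trust the
  file's charges; there is no sanity check against a charge model.
* The cube writer emits lengths in Bohr with a placeholder atom when no
  molecule is supplied; some renderers require at least one atom record.
* Exact reproduction of any specific CoMFA implementation's field values is
  a non-goal: probe parameters and dielectric treatment differ across
  programs, so agreement is structural (same functional forms, filters and
  statistics), not bit-level.
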