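# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `scmetab`. It is written for users who need to judge
what the package's validated behavior on synthetic data does and does not
imply for their own instrument data.

## Chemistry kernel

Molecular formulas are plain Hill-style strings (no parentheses, hydrates
or isotope labels), parsed into element→count maps. Monoisotopic masses are
elementwise sums over a packaged table of IUPAC monoisotopic atomic masses
(`data/atomic_masses.tsv`, ≥ 8 decimals), cross-checked in the test suite
against pyteomics. Adduct m/z values subtract one electron mass
(0.00054858 Da) from the neutral-plus-adduct sum because the observed
species is a +1 cation; at the 0.01 Da tolerances used throughout, the
half-millidalton electron correction is not negligible. Only singly charged
positive-mode adducts (+H⁺, +NH₄⁺, +Na⁺, +K⁺) are modeled; multiply charged
species and negative mode are out of scope.

## Preprocessing

The stage order is fixed: **filter → TIC-normalize → deisotope → align**.
Normalization precedes alignment so that the aligned matrix directly holds
relative abundances; deisotoping sums an envelope's intensity into its
monoisotopic peak, so total normalized signal is conserved.

*Filtering* keeps peaks with intensity strictly greater than the export
threshold (default 10³ counts) and reports the removed-peak and
retained-intensity fractions per cell.

*Deisotoping* scans each spectrum in ascending m/z. A peak joins an open
envelope when it lies within `isotope_delta` (default 0.05 Da) of the
envelope's next expected replica position (monoisotopic m/z + k × 1.00336 Da
for the next unfilled slot k, with at most `max_isotope_replicas` = 5 peaks
per envelope). When two open envelopes accept the same peak, the smaller
|observed − expected| wins; exact ties go to the lower monoisotopic m/z.
The joining rule is positional only — it does not score intensity
plausibility — so two distinct ions whose monoisotopic peaks sit ~1.003 Da
apart will be merged. This mirrors the behavior of standard peak-alignment
tools at these tolerances and is the reason the recovery tests use an
ambiguity-screened library (below).

*Alignment* pools the deisotoped peaks of all cells inside
[`mz_min`, `mz_max`] = [100, 1500], sorts them, and cuts the pool into
clusters at every gap larger than `align_delta` (default 0.01 Da). This
greedy gap-cut is deterministic and order-independent and implements a
"maximum delta" semantics exactly: two peaks end up in the same feature iff
they are connected by a chain of sub-tolerance gaps. Consensus m/z is the
intensity-weighted cluster mean. A cell contributing several peaks to one
cluster is summed and logged. Missing values are true zeros; no imputation
is performed.

## Annotation and pathway roll-up

Features are matched against the library over the chosen adducts by
|observed − theoretical| ≤ tolerance (default 0.01 Da, consistent with the
alignment delta; a ppm mode is available). Candidates are ranked by
absolute mass error with a deterministic (name, adduct) tie-break.
Equal-mass isomers — e.g. three bilin pigments sharing C₃₃H₃₆N₄O₆ in the
packaged library — are all retained; the "best" flag goes to the
lexicographically smallest name. Because isomers share a formula, elemental
counting downstream is unaffected by isomer ambiguity.

Pathway roll-up counts *distinct metabolite names* (not features) among the
significantly regulated, annotated features and keeps pathways with at
least `min_hits` = 2 hits. Counting names rather than features prevents an
isomer-rich or doubly-detected metabolite from inflating a pathway. The
packaged pathway table is a small offline fixture with the same schema a
user-supplied table would have; most packaged metabolites deliberately have
no pathway membership, matching how little of a dinoflagellate metabolome
maps onto curated databases.

## Statistics

*Differential testing* is Welch's unequal-variance t-test per feature with
Welch–Satterthwaite degrees of freedom, two-sided p, at raw p < 0.05.
Welch is the robust default for heteroscedastic single-cell intensities.
No multiple-testing correction is applied by default (the workflow this
package implements filters on raw p), but a Benjamini–Hochberg column is
always emitted. Zero-variance features get p = 1 (equal means) or p = 0
(unequal means, flagged degenerate). Per-direction significant counts are
reported because "differential under condition A vs. B" is direction-
ambiguous in common reporting.

*PLS-DA* is PLS1 (the single-response NIPALS specialization, which is
exact in one pass per component) on a ±1-coded response with deflation
between components. The feature matrix is **Pareto-scaled** (divided by the
square root of the per-feature standard deviation) and mean-centered before
fitting. Pareto scaling is the standard metabolomics compromise: plain
centering lets the few highest-abundance metabolites dominate the
covariance and makes the low-abundance differential signal invisible to a
two-component model, while full autoscaling inflates near-constant noise
features. Centering-only and autoscaling remain available via
configuration. Model predictions use the regression coefficients
B = W(PᵀW)⁻¹q. The implementation is verified against scikit-learn's PLS
to 10⁻⁸ on identical inputs.

*Permutation test*: the observed statistic is the between-group over
within-group sum of squares of the fitted score rows (components 1–2); the
model is refit under randomly permuted labels (default 1999 permutations)
and p = (1 + #{perm ≥ obs}) / (1 + n). The smallest attainable p is
therefore 1/2000 = 5 × 10⁻⁴ at the default permutation count.

*Q²* is 1 − PRESS/TSS over held-out ±1 responses from stratified k-fold CV
(default 10 folds); each fold's model is trained, scaled and centered on
training cells only, and TSS is taken about the overall response mean.
Q² > 0.5 is the conventional "good predictability" bound; shuffled labels
give Q² ≤ 0 in expectation. Note the small-sample caveat: at 15 cells per
group the null distribution of CV-Q² has noticeable positive mass
(~10–15% of shuffles), an inherent property of cross-validated R²-type
statistics at small n (reproduced identically by scikit-learn's PLS on the
same folds). The packaged null-calibration test therefore uses 25 cells
per group, where the null is well resolved.

*Heat maps*: selected features are z-scored across all cells (constant
features become zero rows and sort last), then rows and columns are
ordered by agglomerative clustering (Euclidean distance, Ward linkage,
scipy's deterministic leaf order).

## Stoichiometry

For each cell, weighted elemental sums are
Σᵢ count(E, formulaᵢ) × abundanceᵢ for E ∈ {C, N, P} over the features in
scope, where abundance is the TIC-normalized matrix value and the formula
comes from the feature's best annotation. C:N and C:P are ratios of these
sums; they are exactly invariant to rescaling a cell's abundance vector.
Zero denominators are flagged undefined and excluded (with a count) from
the between-group Welch comparison — never coerced to infinity. The default
scope is *significant-and-annotated* features (the subset on which a
regulated-metabolome stoichiometry claim rests); *all-annotated* is
selectable. These metabolome-level ratios are not whole-cell Redfield
ratios: proteins and nucleic acids are invisible to this kind of
measurement, which biases C:N and especially C:P upward.

## Synthetic-data generator

The generator is the package's test bed and defines the study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_cells_per_group` | 15 (light/dark), 10 (N-limitation) | group sizes of the emulated designs |
| `library_size` | 200 | metabolites drawn from the packaged library (capped at its size) |
| `fraction_differential` | 0.3 | fraction of metabolites regulated between conditions |
| `log2_effect_mean`, `log2_effect_sd` | 1.0, 0.25 | magnitude distribution of true log₂ fold changes |
| `baseline_log_intensity_mean`, `_sd` | 11.0, 1.2 | ln ion counts across metabolites (~e¹¹ ≈ 6 × 10⁴ median, two orders of magnitude spread) |
| `cell_log_intensity_sd` | 0.5 | within-group biological variability (≈ 50% CV, typical for single cells) |
| `tic_scale_sd` | 0.3 | per-cell log-normal total-signal factor (sampling efficiency) |
| `mz_jitter_sd` | 0.002 Da | centroid mass error |
| `n_background_ions` | 120 | shared chemical-background ions (present in every cell, non-differential) |
| `n_noise_peaks_mean` | 20 | per-cell spurious peaks (Poisson) |
| `noise_intensity_range` | (5 × 10², 5 × 10⁴) | uniform intensity range of noise |
| `intensity_floor` | 100 | instrument detection floor applied at generation |
| `isotope_max_replicas` | 5 | envelope length; I(M+k)/I(M) from a binomial ¹³C model on carbon count |

Each metabolite contributes its preferred adduct ion plus isotope replicas
at k × 1.00336 Da with binomial(nC, 0.0107) intensity ratios — adequate for
testing 0.05 Da-tolerance deisotoping, though it ignores N/O/S isotopes
and fine structure. Abundances are log-normal with a symmetric ±log₂FC/2
condition shift. The `n_limitation` scenario draws differential metabolites
from nitrogen-free compound classes first and regulates them all upward in
the deplete group, so the implied weighted C:N rises; `light_dark`
regulates a random subset in both directions. The instrument detection
floor is set at 100 counts (below the 10³ export threshold) so the
pipeline's filtering stage has real work to do and its excluded-fraction
accounting is exercised.

Noise modeling deserves a remark: most "noise" in aligned replicate data
comes from ubiquitous background ions (solvent clusters, membrane debris),
which appear at the same m/z in every cell — per-cell-unique random peaks
cannot align across replicates and would inflate the feature count far
beyond what replicated experiments show. The generator therefore models a
shared background-ion set plus a small number of per-cell spurious peaks.
Both are kept ≥ 0.05 Da away from true envelopes by default so
recovery tests have unambiguous ground truth.

`min_library_mz_separation` optionally screens the library before
simulation so that no two kept ions can be confused by deisotoping,
alignment, or annotation (pairwise envelope positions ≥ 0.06 Da apart;
preferred m/z ≥ 0.025 Da from every adduct m/z of every other kept
record). Recovery and annotation-accuracy tests use this screened subset
(~100 of 165 records — the low-mass region of any realistic library is
crowded with isomers and near-isobars); the headline cross-validation and
stoichiometry checks run on the full unscreened library.

### What passing tests show — and what they don't

Synthetic validation establishes that the implementation is correct under
its own model: ions are recovered 1:1 (≥ 95%), annotations are exact
(≥ 99% on the screened library), Welch tests are calibrated (null
rejection 5% ± 1%), effect recovery reaches ≥ 80% sensitivity at
|log₂FC| = 1 with n = 15/group, cross-validated Q² exceeds 0.5 under the
emulated designs, and the weighted C:N responds in the right direction
under emulated N limitation. Real spectra additionally contain centroiding
artifacts, correlated (matrix-effect) noise, in-source fragments, multiple
adducts of the same metabolite, isotope-pattern deviations, and
retention-free coelution of true isobars — none of which the generator
emulates. Passing tests therefore validate the algorithms, not any claim
that a particular real dataset will reach the same recovery rates.

## Numerical and design choices

* TIC-normalized fold changes are compositionally compressed when
  regulation is one-sided (all-up shifts raise the TIC itself); the
  generator's ground-truth fold changes refer to raw abundances, and the
  convergence test measures them there.
* The permutation p and Q² are bit-reproducible under a fixed pipeline
  seed: one `SeedSequence` fans out to the permutation and CV fold
  generators.
* Feature ids are the consensus m/z rendered to 4 decimals with a
  `_2`, `_3`… suffix on collision.
* Peak counts are reported both pre-deisotoping (filtered peaks) and
  post-alignment (features), since either may be the quantity a reader
  wants to compare against an instrument-software export.
* The two-hit pathway criterion, the 10³ intensity threshold, the
  100–1500 m/z window, 5 replicas, 0.05 Da and 0.01 Da deltas, and alpha
  0.05 are the package defaults; every one of them is configurable.

## Known limitations

Single charge state only; no retention time (direct infusion); no MS/MS
scoring of annotation candidates; the pathway fixture is a small offline
stand-in with the documented schema, not a curated database; the
permutation test refits the same model family under permuted labels and
therefore shares any model misspecification between observed and null
statistics.
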