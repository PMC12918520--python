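# Methods

## The ring-trial generative model

The simulator produces, for each laboratory, a feature quantification table
and a DDA MS/MS event log for the six-level mixing design: pure algal
extract (A), three algae-into-DOM mixtures whose algal content follows a
45:15:5 gradient (relative fractions 1, 1/3, 1/9), pure marine DOM (M), and
process blanks. Internal standards are spiked into the DOM pool and into
the blanks, so sample A carries no standards; the QC gate therefore sees
standards only in DOM-bearing samples and blanks. Contaminants ride along
in every injection, blanks included, at a comparable level, which is exactly
the situation the 30 % blank rule is designed to remove (a config knob,
`contaminant_sample_scale`, scales their sample-side level to probe the
threshold boundary).

A compound's apex intensity in a sample is

    apex = base_abundance × class_fraction × sensitivity(lab)
           × response(lab, compound) × lognormal(0, intensity_cv)

* `base_abundance` — lognormal per class: algal ln-median ≈ ln 1.2·10⁴
  (σ = 1.5), DOM ≈ ln 8·10³ (σ = 1.5), contaminants ≈ ln 4·10⁴ (σ = 1.0).
  The heavy tail gives the small high-intensity head over a large weak tail
  that non-targeted DOM data shows.
* `response(lab, compound)` — lognormal with per-laboratory σ
  (`response_sigma`, default 0.6). This term is essential: a purely
  multiplicative laboratory gain cancels under TIC normalization, so without
  compound-specific response differences no laboratory effect would survive
  into the multivariate analysis, contradicting the laboratory-dominant
  clustering that interlaboratory MS comparisons consistently report.
  Setting `response_sigma` ≈ 1.5 makes the laboratory factor dominate the
  sample-type factor, which is the elevated-lab-effect condition exercised
  in the acceptance battery.
* Retention: observed RT = warp(ref_rt) + N(0, rt_sigma) with
  warp(t) = slope·t + offset + curve·(t/G)³·G on a G = 10 min gradient.
  Typical labs have |offset| ≤ 0.6 min and slope ∈ [0.96, 1.04]; "outlier"
  labs carry curve ≈ 0.25–0.40, i.e. a smooth late-gradient drift reaching
  2.5–4 min at t = G while early eluters (including most standards) stay
  inside the 1.7 min alignment window — this is what lets such labs pass
  the standards gate yet mis-align late features.
* Mass: observed m/z = ion_mz · (1 + (bias + jitter)·10⁻⁶), bias ~ N(0,
  1.5 ppm) per lab, jitter σ ∈ [0.5, 2] ppm per feature.
* Detection: a feature is reported when its apex clears the laboratory's
  detection limit (lognormal across labs, ln-median ≈ ln 1.5·10⁴, σ = 0.5);
  its FBMN-style abundance is the Gaussian peak area apex·width·√(2π).

Chromatographic peaks are Gaussian in time (σ ∈ [0.03, 0.08] min). The DDA
engine walks the cycle grid (gradient length / cycle_time), selecting per
cycle the top-k eligible precursors above the detection limit, excluding a
selected m/z ± isolation_width/2 for `exclusion_duration` seconds when
dynamic exclusion is on. Event purity is the precursor's share of summed
MS1 intensity inside the isolation window *plus* an unresolved refractory
DOM background (per-lab level, strongest in the m/z 400–600 hump
mid-gradient). The background produces the two empirical regularities the
purity model must show: chimeric-spectrum rates in the tens of percent with
wide lab-to-lab spread, and purity increasing with precursor intensity
(abundant labile compounds "stay on top" of the background). Fragment
spectra are the intensity-weighted union of the fragments of every known
compound in the window — chimerism is linear in co-eluting MS1 intensity,
with no fragmentation-efficiency differences.

Library annotations are assigned with probability proportional to the
compound's abundance percentile (mean = `annotation_fraction`, default
0.10): in real data it is the intense peaks that match spectral libraries,
and the driver analysis depends on this intensity bias — annotated features
must be detectable in most laboratories for an annotation-merged
classification to make sense.

### Calibration of the defaults

The generator's defaults are fixed once, against the qualitative regime
non-targeted DOM ring-trial data exhibits, not against any test outcome:
per-laboratory feature counts of roughly 500–1800 at the ~2 000-compound
scale; chimeric-spectrum rates averaging ~50 % with individual labs from
~5 % to ~95 %; an annotation rate of ~10 % (higher than the few percent of
real DOM data — at 2 000 compounds a realistic 4 % would leave too few
annotated features to carry the driver analysis; this is a deliberate
scale-down artifact); only a minority of features shared by all 15
laboratories, with the shared fraction rising steeply among the most
intense features. The simulation scale used throughout (15 labs, 950 algal
+ 950 DOM + 100 contaminant compounds + 8 standards, 6 sample types × 4
replicates) is the package's standard problem size; a full pipeline run
takes well under a minute on one CPU.

## Analysis pipeline

Order of operations is fixed: blank filter → (presence/overlap statistics)
→ zero imputation → TIC normalization → distance-based statistics, with the
top-N restriction applied after normalization. Presence/absence for the
overlap and ubiquity analyses is evaluated **after** blank filtering and
**before** imputation, since imputation destroys presence information.
Driver trends (the per-sample-type relative abundances of top drivers) are
likewise computed on raw merged areas, not imputed ones: for gradient
compounds near the detection limit the imputation floor would otherwise
flatten or invert the low end of the trend.

Numerical and procedural choices worth knowing:

* **Blank rule** — MEAN over blank columns vs MEAN over sample columns,
  strictly greater than `blank_ratio` (default 0.3) removes the feature;
  a max-based variant is available. Whether the original rule compared
  means or maxima is not documented anywhere we know of; mean is the
  smoother default.
* **Imputation** — deterministic half of the global minimum nonzero value.
  Keeps the statistics path free of RNG.
* **m/z–RT alignment** — greedy centroid clustering over the pooled
  features sorted by descending mean intensity (ties by lab, then feature
  id, making the result independent of input lab order); a feature joins
  the nearest cluster (normalized Euclidean distance in tolerance units)
  within 10 ppm and 1.7 min, never joining a cluster that already holds a
  feature of the same laboratory; centroids are intensity-weighted means.
  The 1.7 min default reflects observed standard RT deviations; 10 ppm is
  our default, chosen for modern high-resolution instruments.
* **Cosine** — greedy best-pairs-first matching within `frag_tol`, each
  peak used once, square-root intensity weighting (plain-intensity mode by
  config). Matches the matchms greedy cosine on square-root-transformed
  spectra to 10⁻⁹.
* **PERMANOVA** — the distance-based one-way partition; two independent
  one-way tests (sample type, laboratory) are reported side by side rather
  than a sequential two-factor partition (the two R² need not sum to 1).
  When the number of distinct relabelings is ≤ `exact_cap` (default
  10 000), the null is enumerated exhaustively and p = #{F* ≥ F}/n_distinct
  as an exact rational (the identity relabeling counts, so p ≥
  1/n_distinct); otherwise p = (1 + #{F* ≥ F})/(1 + n_permutations) over
  seeded random relabelings. Permuted statistics reuse the identical
  arithmetic path, so fully exchangeable designs (all distances equal)
  yield p = 1 exactly.
* **PCoA** — Gower double-centering and `eigh`; negative eigenvalues of
  semimetric (Bray–Curtis) input are reported, excluded from coordinates,
  and excluded from the explained-proportion denominator. No
  Lingoes/Cailliez correction by default.
* **Isolation/exclusion windows** — closed lower edge, open upper edge
  ([mz − w/2, mz + w/2)); an arbitrary but fixed convention, pinned by a
  boundary test.
* **Random forest** — scikit-learn `RandomForestClassifier`, 300 trees,
  stratified k-fold accuracy with k capped at the smallest class count
  (four replicates per type make a 5-fold stratified split impossible, so
  k = 4 at the default design); impurity importances by default,
  permutation importances by config; importances normalized to sum 1 per
  laboratory before averaging so laboratories weigh equally.
* **Standards matching** — best candidate per standard by smallest ppm
  error, no feature double-counted across standards.

## What passing tests do and do not show

The generator reproduces the *structure* of multi-laboratory DDA data —
intensity-biased detection, lab-specific warps and response, chimerism,
blank contamination — not its chemistry. There are no adducts, isotope
patterns, in-source fragments, profile-mode signal or polarity-specific
behaviour; fragment m/z values are identical across laboratories (only
their mixing varies), which makes spectral clustering easier than in real
data; RT drift is smooth, so alignment is never confronted with local
elution-order swaps. Consequently, green end-to-end tests demonstrate that
the pipeline's inferences are correct and directionally faithful under a
controlled data-generating process; they do not certify performance on real
instrument output. Two known divergences from real data, visible in the
acceptance report: the all-laboratory intersection of top-5 % driver sets
is small here because ~160 annotated features are almost uniformly
informative and random forests split importance among them differently per
lab, whereas real data concentrates driver signal in a few annotated
markers; and at this scale the all-lab shared-feature fraction (~10–15 %)
sits above the ~1 % of full-size real datasets, simply because the
simulated metabolome is ~10× smaller while the intense head is similar.

## Limitations

* One-way PERMANOVA only; no interaction or nested designs.
* No RT-drift correction beyond the alignment tolerance; no batch
  correction.
* Spectral alignment computes no modified (precursor-shift-aware) cosine
  and exports no network topology.
* The purity model treats the DOM background as unresolvable and never
  selects it for MS/MS; real instruments do waste events on background
  ions.
* Per-lab injection replicate counts in the statistics default to n = 4
  per sample type, a free parameter of the design.
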