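# ringms

Interlaboratory LC–MS/MS ring-trial simulation and comparability statistics
for non-targeted metabolomics.

## The problem

When many laboratories acquire non-targeted LC–MS/MS data on the *same*
material — here a dissolved-organic-matter (DOM) matrix mixed with an algal
extract along a 45:15:5 dilution gradient, plus process blanks and eight
spiked internal standards — how comparable are the resulting datasets?
Data-dependent acquisition (DDA) samples only an intensity-biased subset of
ions, retention times drift between instruments, detection limits and
per-compound response differ, and co-eluting ions produce chimeric MS/MS
spectra. `ringms` implements the full comparability battery used to answer
this question, together with a synthetic multi-laboratory ring-trial
generator that reproduces the statistical structure of such data, so every
step of the analysis can be validated against a known ground truth.

It is aimed at mass-spectrometry method developers and environmental
metabolomics groups who want to stress-test cross-laboratory alignment and
multivariate workflows before committing real instrument time.

## What it computes

* **Simulator** (`ringms.simulate`): ground-truth metabolomes with lognormal
  abundances, laboratory profiles (affine-plus-cubic RT warp, sensitivity,
  ppm mass error, per-compound response factors, detection limit, duty
  cycle), top-*k* DDA precursor selection with dynamic exclusion, precursor
  purity against an unresolved DOM background, chimeric fragment mixing in a
  1 *m/z* isolation window, and blank contaminants.
* **QC gate** (`ringms.qc`): a laboratory enters the unified analysis when at
  least 6 of the 8 internal standards match within 10 ppm and 1.7 min;
  reports cluster counts, annotation rate, median RT deviation and the
  chimeric-spectrum rate (purity < 0.9).
* **Alignment** (`ringms.align`): FBMN-style greedy-centroid clustering on
  *m/z* (ppm) + RT, and CMN-style single-linkage clustering of MS/MS spectra
  by square-root-weighted greedy cosine, with abundance from maximum
  precursor intensity.
* **Preprocessing** (`ringms.preprocess`): blank removal (feature dropped
  iff mean blank intensity > 30 % of mean sample intensity), half-minimum
  zero imputation, TIC normalization, top-*N* intensity restriction.
* **Statistics** (`ringms.stats`): Bray–Curtis dissimilarity
  d(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ); classical-scaling PCoA with explicit
  negative-eigenvalue reporting; one-way PERMANOVA with
  SS_total = (1/N)·Σ_{i<j} d²ᵢⱼ, pseudo-F = (SS_among/(g−1))/(SS_within/(N−g)),
  R² = SS_among/SS_total, and exact enumeration of all distinct relabelings
  whenever their number is ≤ 10 000 (Monte-Carlo otherwise); UpSet-style
  exclusive intersection counts; the rank-based ubiquity curve.
* **Drivers** (`ringms.drivers`): merging of features with identical library
  annotations (summed peak areas), per-laboratory random-forest sample-type
  classification with stratified cross-validation, importance averaging into
  a cross-laboratory driver ranking, and top-5 % driver overlap.

## Worked example

```python
from ringms.cli import run_pipeline

config = {
    "seed": 7,
    "simulate": {"n_labs": 5, "n_algal": 150, "n_dom": 150,
                 "n_contaminant": 20, "replicates": 4},
    "preprocess": {"top_n": [100]},
    "stats": {"n_permutations": 999},
}
run = run_pipeline(config, "example_run")
print(run["permanova"][["subset", "factor", "pseudo_F", "R2", "p_value"]])
```

This simulates five laboratories measuring the six-level design (A, A45M,
A15M, A5M, M, blank; four replicates each), gates them on the internal
standards, aligns, preprocesses and runs the battery. Output of the run
above:

```
labs passing QC: ['lab_a', 'lab_b', 'lab_c', 'lab_d', 'lab_e']
global features after blank filter: 249
fraction shared by all labs: 0.193

subset      factor  pseudo_F    R2  p_value
   all sample_type    31.261 0.568    0.001
   all  laboratory     8.759 0.269    0.001
top100 sample_type    35.221 0.597    0.001
top100  laboratory     8.181 0.256    0.001
```

Reading: sample type explains 57 % of the Bray–Curtis variance and the
laboratory 27 % (both p = 0.001 with 999 permutations); restricting to the
100 most intense features sharpens the sample-type separation (R² 0.568 →
0.597), because high-intensity features are detected consistently across
laboratories while weak features behave like lab-specific noise. Only 19 %
of all features are shared by every laboratory. The driver ranking for this
run is headed by algal-gradient metabolites
(`lib_alg0052`, `lib_alg0009`, …), whose relative abundances fall
monotonically along A45M → A15M → A5M → M.

The same pipeline is available from the shell:

```bash
ringms run-all --config run.yaml --outdir out/
ringms simulate --config run.yaml --outdir sim/    # tables + MGF only
```

All outputs are delimited text (aligned matrix with provenance sidecar, QC
summary, PERMANOVA table, PCoA coordinates, ubiquity/intersection tables,
driver rankings) plus a JSON manifest carrying the config hash and the
per-laboratory inclusion decisions.

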