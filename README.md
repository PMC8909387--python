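# scnakit

Copy-number instability scoring and tumor-microenvironment association
analysis for shallow CGH-style data, with a synthetic cohort generator so
the whole pipeline is testable end to end without any external data.

Pipeline stages:

1. **genome model & I/O** (`scnakit.genome`) — chromosome/centromere
   coordinate frame, SEG-like TSV and probe TSV readers/writers
   (0-based half-open internally; a dialect flag converts 1-based input).
2. **segmentation** (`scnakit.segmentation`) — median centering, recursive
   binary segmentation with permutation-tested splits (a CBS stand-in; you
   can also feed pre-segmented tables directly), log-ratio threshold status
   calling, and an explicit baseline-recalibration offset.
3. **instability scores** (`scnakit.instability`) —
   * genomic index `GI = A²/C` (A = maximal merged gain/loss runs,
     C = autosomes carrying them);
   * SCNA counts at focal (< 50% of an arm), arm, and chromosome (both arms,
     same direction, ≥ 80% coverage) levels;
   * large genomic alterations (LGA): per-profile one-copy cutoff estimation,
     step-wise smoothing, small-segment integration with interstitial
     filtering, then counting breaks between adjacent large (≥ 10 Mb)
     same-arm segments; HRD is called at ≥ 18 LGAs.
4. **IHC marker statistics** (`scnakit.ihc`) — H-score (0–300), cutoff
   binarization, 2×2 cross-tabulations (chi-square + Fisher), rank-sum
   comparisons (exact enumeration for small groups).
5. **survival statistics** (`scnakit.survival`) — Kaplan–Meier with
   "not reached" medians, log-rank, univariate Cox (Efron ties, via
   lifelines), maximally selected rank-statistic cutpoints with permutation
   p-values, and bootstrap lasso-Cox stability selection (500 bootstraps,
   > 2/3 selection rule, 5-fold CV with a 1-SE penalty rule by default).
6. **synthetic cohorts** (`scnakit.simulate`) — noise-free profiles with
   *exact* LGA counts and focal/arm/chromosome event counts (construction
   bookkeeping is returned as a `ProfileTruth`), Gaussian probe rendering,
   HRD-conditioned markers, and proportional-hazards survival with
   administrative + random censoring.

## CLI

```sh
scnakit simulate --config cohort.yaml --out cohort/           # patients.tsv, segments.tsv
scnakit segment  --probes probes.tsv --genome genome.yaml --out segments.tsv
scnakit score    --segments segments.tsv --out scores.tsv     # gi, SCNA, lga, hrd_call
scnakit analyze  --patients patients.tsv --scores scores.tsv \
                 --binary-vars hla_e_high,cd3_high -B 500 --out report/
```

A genome model is a small YAML/JSON file (`name`, `length_bp`,
`centromere_bp` per chromosome); a built-in 22-autosome model is used when
none is given.

## Notes

* Sex chromosomes are excluded from all scores by default (configurable).
* Status thresholds default to ±0.2 log2 and are configurable; "total level"
  SCNA scores are event counts by default (a magnitude weighting hook
  exists but is off).
* The one-copy cutoff is the modal inter-segment step (histogram bin 0.05
  within [0.15, 0.9]) scaled by a 0.95 safety margin so that steps at the
  mode always qualify; profiles with < 5 usable steps fall back to 0.3.
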