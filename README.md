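# neurotopo

Topographic density mapping of marked neurons: from per-subject marker
coordinates (x, y in micrometres) and a traced region contour to registered
bin matrices, mean / CV / difference heat maps, and statistically detected
micro-regions of interest (MROIs).

The pipeline:

1. **Registration** — every subject's markers and the shared contour are
   translated so the superior-left corner of the contour bounding box sits
   at (0, 0) (image convention, y grows downward).
2. **Alignment QC** — landmark maximum-Feret lengths per Bregma plane are
   screened for outliers (|z| > 3 SD), planes are checked for mutual
   distinctness (paired t-tests) and for the absence of condition effects
   (one-way ANOVA).
3. **Binning** — square bins sized by the twice-expected-frequency rule
   `bin_area = 2 * contour_area / n` (n = mean markers per subject by
   default), counted on half-open intervals into a subject × bin matrix.
4. **Maps** — per-condition mean, SD and coefficient-of-variance maps, plus
   between-condition difference maps and q-value maps, each rendered to
   PNG/SVG with a machine-readable sidecar of the exact per-bin values.
5. **Statistics** — mass-univariate one-way ANOVA per bin,
   Benjamini–Hochberg FDR over the in-contour bin family (q = 0.1 default),
   Bonferroni-corrected planned contrasts inside the MROI set, PCA of the
   subject × bin matrix, and canonical discriminant analysis (MDA) of
   regional density tables.

A synthetic-cohort module (`neurotopo.synth`) generates two-condition
studies with uniform background activation plus condition-specific Gaussian
hotspots and paired Feret tables, with known ground truth — so the entire
pipeline is testable without histology data.

## Tests

```sh
python -m pytest -q
```

`tests/test_acceptance.py` holds the acceptance criteria (worked examples,
oracle equivalences, FDR control, and end-to-end parameter recovery over 50
simulated cohorts).

## Command line

```sh
# write a synthetic study (markers, contour, Feret table, manifest)
neurotopo simulate --scenario effect --seed 1 --out study/

# full analysis: register -> QC -> bin -> maps -> statistics
neurotopo run --manifest study/manifest.tsv --out results/ --q 0.1

# individual stages
neurotopo qc   --feret study/feret.tsv --out results/qc
neurotopo bin  --manifest study/manifest.tsv --out results/ --bin-side 25
neurotopo mroi --manifest study/manifest.tsv --out results/ --q 0.1
neurotopo pca  --manifest study/manifest.tsv --out results/
neurotopo mda  --table densities.tsv --group-col condition --out results/mda
```

Flags override values from an optional `key = value` config file
(`--config`). Every run writes `run_log.json` capturing all parameters, the
seed and the package version, so a run is reproducible from its log alone.

## File formats

All plain text. Marker files: one `x<TAB>y[<TAB>z]` row per neuron
(comma/whitespace tolerated; `#`/`;` comment lines skipped — Neurolucida
ASCII exports load unchanged). Contour files: one vertex per line with
`# label=...` and `# bregma_mm=...` headers. Feret tables and manifests:
TSV with headers. Units are micrometres except Bregma coordinates (mm).

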