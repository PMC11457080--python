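# Methods

This note documents the statistical model, the synthetic study design, the
numerical choices and the known limitations of the package. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Count model and differential expression

Counts are modeled as negative binomial, Var(Y) = μ + αμ². The pipeline
mirrors the standard two-group workflow:

* **Normalization** — median-of-ratios size factors over genes with
  nonzero counts in every sample, rescaled to geometric mean 1. This makes
  log-fold-change estimates invariant (to within the pseudo-count guard)
  under rescaling any single library.
* **Dispersion** — per-gene method of moments,
  α̂ = max(0, (s²_pooled − m)/m²), where s²_pooled is the within-group
  variance of normalized counts pooled over both treatment groups and m
  the gene's normalized mean. Constant genes get α̂ = 0; a floor of 1e-8
  is applied when the estimate enters the Wald variance.
* **Contrast** — log₂FC = log₂((m̄_HL + ½)/(m̄_LL + ½)); the ½
  pseudo-count guards empty groups. The delta-method standard error uses
  the NB variance at the guarded group means.
* **Reference distribution** — the Wald statistic is referred to a
  Student-t with n₁+n₂−2 degrees of freedom rather than a normal. With
  five replicates per group the dispersion is estimated with eight df, and
  a normal reference is markedly anticonservative (the t reference
  calibrates the null rejection rate at the nominal 5% in the acceptance
  suite; the normal reference rejects at roughly 9% under the same
  conditions).
* **Independent filtering** — genes whose base mean falls below the 10th
  percentile of nonzero base means (configurable) receive no adjusted
  P-value and are called `untested`; the BH adjustment runs over the
  remaining genes only. Downstream, the enrichment universe is exactly
  the set of genes with an adjusted P-value.
* No log-fold-change shrinkage is applied; reported log₂FC are the raw
  contrast estimates.

Significance is padj < 0.05 by default (`alpha_sig`), applied to the
BH-adjusted value.

## Homology integration

Membership (core / accessory / unique) is defined relative to the declared
focal species set; groups with no gene from any focal species are dropped
with a count. A group is DE if ≥1 member gene is called up or down in any
species. Ambiguity considers only significant calls: a species with one up
and one down gene makes the group ambiguous, while `ns`/`untested` genes
never do — a deliberately lenient rule matching the observation that the
vast majority of core DE groups in real data are non-ambiguous. Untested
genes do count in the response-score denominator (the score divides by the
total number of gene models present), with a flag to exclude them.

The seven profile categories (up_all, down_all, up_shared, down_shared,
up_unique, down_unique, contrasting) are exhaustive and mutually exclusive
over non-ambiguous core DE groups; the test suite checks this against a
brute-force enumeration of all 3⁴ sign patterns. Hierarchical clustering
of the score matrix (Euclidean distance, average linkage) is provided for
heatmap parity only; row order is not a tested surface.

## Transcriptional baseline

TPM is within-sample: any per-sample global factor cancels, so what the
baseline measures is *composition* — how much of a species' transcript
pool is taken up by everything else. Baseline groups are core, non-DE,
single-copy in every species, and "expressed" (species-mean TPM ≥
`min_tpm`, default 1; the threshold is exposed because zero-versus-positive
cutoffs are a judgment call). Each ordered pair's ratio vector is
summarized by its **median** (robust to the heavy tails of expression
ratios; no other summary is implied by the procedure) and by the
**exceedance fraction**, the empirical proportion of ratios strictly above
a caller-chosen threshold. The threshold must be passed explicitly — an
"area under the curve beyond 1" statistic is ambiguous between a ratio of
1 and a log₂-ratio of 1, and both are obtainable (thresholds 0 and 1).

Per-species offsets are derived from pairwise medians by averaging each
species' offsets against **all** K species (the self-pair contributing 0)
and centering; averaging over only the K−1 partners would stretch centered
offsets by K/(K−1).

Corrected cross-species ratios subtract the pair offset from
log₂((mean_a + p)/(mean_b + p)) with pseudo-value p = 0.01 TPM
(configurable) guarding near-zero means.

## Expression modes

Mode calls operationalize three qualitative patterns with one declared
threshold, `ratio_t` = 1 log₂ (i.e. 2-fold after baseline correction), in
every pairwise comparison and under both treatments:

* `treatment_DE`: ≥1 focal gene called up, and no other species has any
  significant call in the group;
* `cumulative_paralog`: ≥2 focal copies and the *summed* focal abundance
  clears `ratio_t` against every other species in both treatments;
* `constitutive_high`: single focal copy, no significant focal call, and
  the corrected ratio clears `ratio_t` everywhere;
* precedence `treatment_DE` > `cumulative_paralog` > `constitutive_high`.

Pool fractions divide a group's (paralog-summed) treatment-mean TPM by the
summed abundance of a declared gene-set pool; they are computed
per-treatment because pooled-versus-per-treatment is a presentation
choice, not a statistical one.

## Synthetic study design

The generator emulates the target design: 4 species × 2 treatments × 5
replicates; ~3,000 homology groups per study (1,200 core single-copy, 200
core with focal paralog expansions of 2–4 copies, 800 accessory, 800
unique), giving ~2,100–2,500 genes per species — small enough that the
full pipeline runs in seconds, large enough for stable medians and
calibration checks. Key parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| `dispersion` | 0.05 | NB α, typical for replicated bulk RNA-seq |
| `library_size_mean` | 2×10⁶ | expected column sum; log-normal jitter σ=0.12 |
| `base_mean_log2`, `base_sd_log2` | 3, 2 | log₂ TPM-scale expression distribution |
| `divergence_sd` | 0.25 | per-gene cross-species expression divergence (log₂) |
| `de_fraction` | 0.25 | responsive groups, matching ~23–31% DE genes |
| `de_lfc_mean/sd/min` | 1.5/0.4/0.8 | planted effect magnitudes (log₂) |
| `baseline_offsets` | +0.30/+0.05/−0.30/−0.05 | centered per-species offsets |
| `planted_modes` | 30/30/30 | groups per expression mode |
| `gene_length_mean` | 1.5 kb | log-normal gene lengths, σ=0.35 |

Three design points deserve explanation:

* **Offsets are planted as composition, not as multipliers.** A uniform
  per-species expression multiplier is unobservable through TPM. The
  generator therefore rescales each species' *private* (accessory +
  unique) transcriptome mass so that the treatment-pooled composition
  H_s = 2/(1/D_LL + 1/D_HL) satisfies H_s ∝ 2^(−offset_s) exactly — the
  same mechanism by which a bloated annotation dilutes TPM in real data.
  Pooling matters: treatment effects change each species' composition
  under HL, so planting against the LL composition alone would leave a
  systematic drift of up to ~0.1 log₂ in the recovered offsets.
* **Planted margins.** Constitutive groups put the focal gene +2 log₂
  above the others; cumulative groups give the focal species 3–4 copies at
  ~1.1× the others' single-copy expression (summed margin 1.7–2.1 log₂
  against the 1.0 threshold — per-copy expression only slightly above the
  other species, with the dominance arising from the sum); treatment-DE
  groups plant log₂FC = +1.5 in the focal species only. Planted-mode
  groups are drawn at high expression (log₂ TPM ≈ 5) so that recovery
  failures reflect estimator noise, not detection-limit censoring.
* **Mode evaluation population.** Precision and recall are evaluated on
  the planted-mode groups. Background responsive groups whose random DE
  pattern happens to satisfy a mode definition (e.g. focal-only up) are
  legitimate detections, not false positives, and are excluded from the
  error count.

What the generator does *not* emulate: isoform structure, GC/length
biases, correlated gene modules, outlier samples and batch effects,
unbalanced designs, and annotation errors. Passing recovery tests
therefore demonstrate the pipeline's correctness and calibration under
its own model assumptions, not robustness to every artifact of real data.

## Annotation filters

GFF3 filters keep exactly one mRNA per gene (maximal summed CDS length;
ties broken by file order, which is deterministic and reproducible),
remove genes encoding proteins shorter than 30 aa, and remove explicit
kill lists. Protein length is summed CDS/3 by default; whether the stop
codon is included in the annotated CDS varies by annotation pipeline, so a
`stop_included` flag switches to (CDS−3)/3. A CDS length not divisible by
3 warns and retains the gene. Filters are idempotent and are applied in
the order longest-isoform → ORF filter. Coordinates remain GFF3 1-based
inclusive throughout; attribute preservation beyond ID/Parent is not
attempted (lines are echoed verbatim, so in practice attributes survive).

## Design metrics

DLI = irradiance × photoperiod × 3600/10⁶ (mol m⁻² d⁻¹), reported to two
decimals. The rounding mode is caller-selected (`round2`/`trunc2`)
because published values mix conventions: a raw 9.828 printed as 9.82
implies truncation, while other values are rounding-neutral. U2
uniformity is min/max over measured positions and is invariant under
uniform rescaling.

## Enrichment

One-sided hypergeometric upper-tail p per term ("classic" per-term
testing; any ontology-graph propagation belongs to input preparation).
The term-size filter (≥5 genes, configurable) counts annotations within
the universe by default — a flag switches to within-study counting.
BH adjustment runs across the surviving terms. The test suite checks the
p-values exactly against brute-force enumeration of the hypergeometric
tail for all universe sizes ≤ 30.

## Orchestration and reproducibility

A single YAML config drives the seven-stage pipeline (simulate → de →
integrate → baseline → compare → enrich → report); every threshold lives
in the config and is echoed into the JSON run manifest together with
sha256 hashes of every stage output. All randomness flows from one seed
through independent `numpy.random.default_rng` substreams, so a rerun
with the same config is hash-identical. The `report` stage renders the
DEG summary (counts with one-decimal percentages), the membership × DE
cross-tabulation, the profile census, the baseline report, mode-call
counts (with an explicit "none detected" line when empty) and the top
enrichment rows as markdown.

## Known limitations

* The DE stage is a deliberately transparent NB Wald pipeline; it does
  not implement dispersion shrinkage, lfc moderation or outlier
  refitting, and externally produced DE tables in the same TSV schema can
  be substituted wherever a DE table is consumed.
* Baseline estimation assumes enough (≳50, warned otherwise; ≳300 for
  stable offsets) single-copy non-DE core groups.
* The mode classifier's thresholds are declared operationalizations of
  qualitative patterns; calls near the margin are sensitive to
  `ratio_t` and to the baseline pseudo-value.
* Real cross-species comparisons inherit every caveat of the homology
  grouping itself, which this package consumes as given.
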