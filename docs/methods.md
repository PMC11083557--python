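# Methods

## Scope and data model

The package analyses gene-anchored regions of interest (ROIs): one
promoter window and one CDS span per gene, each classified CGI/nonCGI
by ≥ `min_overlap_bp` (default 1) overlap with a CpG-island track.
Coordinates are 0-based half-open throughout (BED native); 1-based
inputs must be shifted before loading. The promoter window defaults to
−2000/+500 bp around the TSS, oriented by strand and clipped at the
chromosome start; both bounds are config-exposed because promoter
definitions vary between annotation pipelines, and no downstream
contract depends on the default. The CDS ROI is the annotated span,
not an exon-resolved union, keeping exactly one record per gene and
region class.

## Absolute methylation scores

Enrichment assays such as MBD-seq recover read density proportional to
methylated-CpG content, confounded by ROI length, library depth and
CpG density. The score used here is a transparent CpG-density-corrected
RPKM:

    ams[g,s] = (count / (library_size/1e6)) / (length/1e3)
               / ((cpg_count + k) / median(cpg_count + k))

with pseudocount k = 1 so CpG-free ROIs stay finite; switching the
correction off yields a plain RPKM-like score. Absolute values are not
comparable to coupling-factor-normalised scores from enrichment-specific
tools, but all downstream differential logic operates on per-sample 0–1
min–max scaled values and is therefore insensitive to monotone
per-sample rescaling. Constant sample columns scale to all zeros with a
warning rather than erroring, so degenerate inputs flow through.
Scaling is applied per ROI-class submatrix (promoter and CDS
separately), mirroring normalising "each ROI matrix" on its own.

## Differential methylation

Per subtype, tumor and normal samples are aligned by pair ID and each
ROI is tested with a two-sided paired t-test on the scaled scores;
Δmean = mean(tumor) − mean(normal). Calls: hyper if Δ > 0.2 and
p < 0.05, hypo if Δ < −0.2 and p < 0.05, else ns. The gate is on raw p
by default, with BH q-values always reported and a strict-FDR mode
(`gate="q"`) available; the default reproduces the published criterion,
the FDR gate is the defensible variant. Degenerate rows (zero-variance
differences) follow a fixed convention: p = 0 if the common difference
is non-zero, else p = 1, avoiding NaN propagation. Gene-level calls
take the union over region classes; genes with conflicting directions
across regions are dropped with a warning.

Supporting operations: top-k most-variable selection uses SD/SD_max
(rank-preserving; ties broken lexicographically by ROI key), and sample
clustering is UPGMA on Euclidean distances with ties broken by the
smallest cluster-id pair — both tie-breaks are fixed so outputs are
deterministic.

## Quadrant integration and candidate screening

Expression differentials reuse the paired-t machinery on log2
intensities (log2FC = paired mean difference). A gene enters a
quadrant only with both a methylation call and |log2FC| ≥ log2(1.2)
(threshold config-exposed). Subtype specificity is exact set algebra:
specific(s) = calls(s) \ ∪ others; shared = ∩ all subtypes.

The candidate screen makes the visual "most subtype-specific pattern"
step computable: per candidate, the methylation margin is
median(target-subtype tumors) − median(other tumors) on scaled scores
(sign must match the call), the expression margin analogously (sign
must match the quadrant), candidates pass when both magnitudes exceed
config margins (defaults 0.05 / 0.5), and ranking is by the product of
magnitudes. The margins are medians, not means, to be robust to the
skewed per-subtype distributions typical of such cohorts.

## Survival analysis

Median splits label subjects high/low per marker value with ties going
low (a fixed convention; the "hypomethylation group" is the
below-median methylation group). A composite risk rule pairs a
methylation direction with an expression direction; exactly the
subjects matching both are high risk. The Kaplan–Meier estimator and
Mantel–Haenszel log-rank test are implemented directly (subjects
censored at an event time count as at risk at that time; variance uses
the hypergeometric form with the (n−d)/(n−1) factor; zero total
variance returns p = 1 with a warning). No Cox modelling: the analysis
reports KM + log-rank only, and hazard ratios exist solely inside the
simulator.

The data-driven cutoff scan searches observed values within the
20th–80th percentile band for the minimum log-rank p. Because minimum-p
selection is anti-conservative, the scan always reports a
permutation-adjusted p: the full scan is re-run on label permutations
(default 200) and the adjusted p is the rank of the observed minimum
among permuted minima (add-one estimator).

## MS-HRM quantification

A melting profile (−dF/dT vs temperature) of a bisulfite-PCR product is
modelled as two peaks: unmethylated template melting at a lower
temperature, methylated at a higher one. Peak areas are trapezoidal
integrals over fixed temperature windows (defaults bracket the
simulator's peak centers at 78 °C and 85 °C, split at 81.5 °C), with a
"zero" or "linear endpoints" baseline, clipped at zero. The default
metric is the methylated-peak AUC divided by total peak AUC;
normalisation and baseline are exposed, and since calibration is a
fitted line, any affine change of the metric is absorbed — the choice
does not alter calibrated percents. Calibration is OLS of known percent
on metric over the 0/50/100 % standards (≥ 2 distinct standards
required; identical metrics are non-identifiable and rejected);
predictions are clipped to [0, 100] with an extrapolation flag.

## Synthetic cohort generator

The generator emulates the structure of a four-subtype paired
tumor/normal MBD-seq + microarray + clinical study, with defaults as
the study conditions: 500 genes, 10 pairs per subtype, 15 hyper + 15
hypo genes planted per subtype plus 5 planted in all subtypes,
effect size 0.3 on the latent 0–1 methylation scale, log2 expression
shift 1.0 for the coupled ("integrated") 60 % of planted genes, and a
200-subject survival validation cohort with hazard ratio 3 and 30 %
censoring.

* **Latent methylation fractions.** Null ROIs draw baselines from a
  bimodal Beta(0.7, 0.7) stretched to [0.05, 0.95]; per-sample
  biological jitter is Gaussian (sd 0.05), clipped to [0.02, 0.98].
  Planted ROIs draw baselines with headroom for the shift (hypo from
  U(effect+0.25, 0.9), hyper mirrored) so the planted state is
  realisable; the planted tumor latent is exactly the matched normal
  latent ± effect. Effects sit on the CDS region by default
  (gene-body methylation), config-exposed.
* **Counts.** Negative binomial with mean ∝ depth × latent fraction ×
  ROI length × relative CpG density — the same normalisers the scoring
  stage divides out, so scaled scores recover the latent fraction up to
  a per-sample monotone transform. The NB size (default 200, variance
  2–3× Poisson at the default depth) models residual technical
  overdispersion; biological variability is already carried by the
  latent jitter, so a much smaller size would double-count noise and
  make the planted 0.3 shift undetectable at the 0.2-delta threshold —
  i.e. it would describe an assay too noisy for the thresholds the
  analysis is built around.
* **Expression.** Gene means ~ N(8, 1.5²) log2 units, noise sd 0.3;
  integrated planted genes shift tumor expression by ∓/± the coupling
  effect through the planted latent shift (hypo→up, hyper→down). The
  designated marker (first integrated TNBC-hypo gene) carries a 1.5×
  stronger expression shift, mirroring a marker selected precisely for
  having the most subtype-restricted pattern of all candidates.
* **Survival.** A separate validation cohort of subjects (distinct
  from the discovery pairs, as prognosis is typically validated in a
  larger external cohort) carries marker methylation (beta-value-like)
  and expression values; subjects below the cohort median in
  methylation and above it in expression have hazard multiplied by the
  hazard ratio. Event times are exponential; censoring times are
  exponential with rate chosen so the expected censored fraction equals
  the configured rate.
* **Melting curves.** Two Gaussian peaks with weights (1−f, f) plus
  additive Gaussian noise (default sd 0.01 against a peak height of
  ~0.4). Real HRM peaks are asymmetric, but the calibration contract is
  ratio-based, so peak shape is immaterial to it.

What the generator does **not** emulate: copy-number and purity
confounding, batch effects, probe-level microarray artefacts,
fragment-level sequencing noise, and non-proportional hazards. Passing
tests therefore demonstrate the correctness and calibration of the
analysis chain under a clean generative model, not robustness to those
real-data pathologies.

## Numerical and design choices

* BH q-values are the exact step-up definition, returned in input
  order; p-values outside [0, 1] are rejected.
* The paired t statistic uses the ddof-1 standard deviation; p from
  the t distribution with n−1 df.
* All simulations and the pipeline derive every random draw from a
  single `numpy` Generator seeded by the config, so identical
  config+seed reproduces outputs bitwise; output TSVs fix float
  formatting (6 significant digits) so file checksums reproduce too.
* Problem sizes in the test-suite and acceptance script (20 null
  cohorts, 50 survival replicates per arm, 200 oracle datasets, 1000
  primitive comparisons) were chosen to keep Monte-Carlo error well
  inside the asserted bounds while completing in seconds.
* The pipeline's survival stage tries candidates in rank order and
  uses the first with usable survival data: per-subject assay columns
  named for the gene (`meth_<gene>`/`expr_<gene>`) in the clinical
  table (validation-cohort mode), or a lookup in the cohort matrices
  when the clinical subjects are the cohort tumors. If no passing
  candidate has data the stage is skipped and says so.

## Known limitations

* The ams is a documented stand-in, not a reimplementation of
  enrichment-specific coupling-factor normalisation; absolute score
  values differ between tools even though scaled-delta logic does not.
* Gene-level collapsing drops direction-conflicted genes rather than
  modelling region heterogeneity.
* The candidate screen formalises a step that was partly visual in
  practice; its margins are package definitions, clearly config-exposed.
* The minimum-p cutoff scan's permutation adjustment assumes
  exchangeability of marker values across subjects under the null.
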