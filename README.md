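# methylquad

Integrative DNA-methylation / gene-expression analysis for nominating
subtype-specific, prognosis-associated genes from MBD-seq-style region
counts — the kind of workflow used to flag gene-body hypomethylated,
overexpressed markers (e.g. *ATP1A1*-like genes) in triple-negative
breast cancer (TNBC).

## Who this is for

Computational epigenomics analysts who have, per cohort:

* an ROI (region of interest) read-count matrix from an enrichment
  assay such as MBD-seq (genes/regions × samples),
* matched tumor/normal pairs across intrinsic subtypes
  (LumA, LumB, HER2, TNBC),
* a log2 expression matrix, a clinical survival table, and optionally
  MS-HRM melting curves for locus-level validation.

A synthetic-cohort generator with planted truth is a first-class part
of the package, so every stage can be validated end to end without any
external download.

## The method

1. **Scoring** — ROI counts become absolute methylation scores (ams):
   reads/kb/million corrected by relative CpG density
   `ams = (c / (N/10⁶)) / (L/10³) / ((CpG+1)/median(CpG+1))`,
   then each sample is min–max scaled to [0, 1] per ROI class.
2. **Differential methylation** — per subtype, paired t-tests on
   tumor−normal scaled scores; a gene/region is *hyper*methylated when
   Δmean > 0.2 with p < 0.05, *hypo*methylated when Δmean < −0.2
   (BH q-values reported; a strict-FDR gate is available). Context
   composition over {CGI, nonCGI} × {promoter, CDS} is summarised per
   direction.
3. **Integration** — genes with both a methylation call and
   |log2FC| ≥ log2(1.2) fall into four quadrants (hypo_up, hypo_down,
   hyper_up, hyper_down); subtype-specific sets are exact set algebra
   (called in exactly one subtype vs shared by all); candidates are
   ranked by the product of their methylation and expression
   median-margins versus the other subtypes, with sign gates.
4. **Survival** — median splits of marker methylation and expression,
   a composite risk rule (e.g. high risk = hypomethylated AND highly
   expressed), from-scratch Kaplan–Meier `S(t) = Π(1 − dᵢ/nᵢ)` and
   Mantel–Haenszel log-rank `χ² = (ΣO−ΣE)²/ΣV`, plus a minimum-p
   cutoff scan that always reports a permutation-adjusted p.
5. **MS-HRM** — percent methylation from melting-peak areas:
   methylated-peak AUC fraction calibrated by OLS against the
   0 / 50 / 100 % standards.

## Worked example

```bash
python examples/02_differential_methylation.py
```

```
TNBC: 15 hypermethylated, 20 hypomethylated genes
planted TNBC-hypo recovered: 15/15
  hyper: 87% non-CGI, 100% CDS (of 15 calls)
  hypo: 75% non-CGI, 100% CDS (of 20 calls)
```

All 15 subtype-specific planted hypomethylated genes (plus the 5
planted in every subtype) are recovered at the Δ > 0.2, p < 0.05
thresholds, and the calls concentrate in non-CGI gene-body (CDS)
context — the generator plants its effects there. Continuing with
`examples/03_quadrant_integration.py` ranks the planted marker first
among the TNBC-specific hypo_up candidates:

```
gene_id quadrant  meth_margin  expr_margin  passes    score
  G0028  hypo_up    -0.271643     1.455476    True 0.395370
```

and `examples/06_full_pipeline.py` runs every stage from one config:
the top candidate's composite-risk stratification of the simulated
200-subject validation cohort gives a log-rank p ≈ 2×10⁻⁹.

Each example script (`examples/01`–`06`) exercises one capability and
prints a line or two explaining the numbers. A thin CLI wraps the
orchestration: `methylquad run`, `methylquad simulate-cohort`,
`methylquad simulate-melt`, `methylquad hrm`.

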