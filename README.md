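# palscreen

Topology-aware pathway activation scoring and pan-cancer biomarker
screening from a signed interactome.

## The problem

Single-gene expression levels are noisy cancer biomarkers.  An alternative
is to score whole molecular pathways: aggregate the expression changes of a
pathway's members, weighted by whether each member activates or represses
the pathway, into one *Pathway Activation Level* (PAL).  Beyond manually
curated ("classical") pathways, pathways can be built **algorithmically**
around every gene of an interactome — the *gene-centric* pathway of gene
*g* is the subnetwork within one interaction of *g*, with the participants
of any adjacent biochemical process included.  `palscreen` implements the
whole chain for researchers who want to test that idea, or use it:

1. a signed, typed, directed interactome model (gene products, metabolites,
   process nodes; activation / inhibition / other edges) with TSV I/O and
   pathway-collection merging;
2. gene-centric pathway construction and activator/repressor role (ARR)
   annotation by sign voting from the central gene;
3. PAL computation from case-to-normal expression ratios (RNA counts with
   median-of-ratios normalization, or label-based proteomic log-ratios);
4. biomarker screens: cancer-type-specific (one-vs-rest), tumor-vs-normal,
   and survival (median split, Kaplan–Meier, log-rank, univariate Cox);
5. a synthetic-study generator with planted, recoverable effects, so every
   stage is testable without any external download.

## The score

For pathway *p* and one tumor sample,

```
PAL_p = Σ_n log(CNR_n) · PG_p,n · ARR_p,n  /  Σ_n |ARR_p,n|
```

where CNR_n is the gene's case-to-normal ratio (tumor expression over the
geometric mean of same-site normals), PG_p,n indicates membership, and
ARR_p,n ∈ {−1, −0.5, 0, +0.5, +1} encodes the member's activator/repressor
role.  Both sums run over assay-covered members.  Positive PAL means the
pathway is up-regulated relative to normal tissue.

An analyte (gene or pathway) is a significant potential biomarker when its
orientation-resolved AUC exceeds 0.7 and its Benjamini–Hochberg adjusted
p-value is below 0.05; survival biomarkers additionally require the Cox
hazard-ratio confidence interval to exclude 1.  See `docs/methods.md` for
the full model description and design rationale.

## Worked example

Simulate a three-cancer-type study (134 tumors + 33 normals per type) with
one planted cancer-type marker (gene `G0007`, ten-fold up in type C1) and
one planted prognostic gene (`G0020`, log hazard ratio 0.9 per SD on
overall survival), then run the full screen:

```sh
palscreen simulate demo --config demo_config.yaml   # writes interactome/expression/clinical TSVs
palscreen run-all demo/interactome.tsv demo/expression.tsv demo/clinical.tsv demo_out
```

The run prints the per-stratum summary (counts of significant analytes and
their percentage share); the first rows:

```
         screen cancer_type             category  n_tested  n_significant  percent
    cancer_type          C1                 gene        60              1 1.666667
    cancer_type          C1 gene_centric_pathway        60              2 3.333333
    cancer_type          C2                 gene        60              1 1.666667
```

`demo_out/screen_cancer_type.tsv` holds the per-analyte detail.  The
planted gene dominates its stratum, and the gene-centric pathway built
around it is carried to significance by the same signal:

```
  analyte             category cancer_type  auc_oriented            q
    G0007                 gene          C1      1.000000 2.613026e-58
gcp_G0007 gene_centric_pathway          C1      0.997912 7.995877e-58
```

(`G0007` also passes in the C2 and C3 strata: one-vs-rest pools the shifted
C1 samples into their "rest" groups, so the plant separates those contrasts
too — expected, not a false positive.)  In
`demo_out/screen_survival_os.tsv` the planted prognostic gene is recovered
with a high-vs-low hazard ratio near its planted effect in every type:

```
  analyte category cancer_type       hr   ci_low  ci_high            q
    G0020     gene          C1 2.467972 1.624098 3.750320 7.759328e-04
    G0020     gene          C2 2.631343 1.723183 4.018124 2.116393e-04
    G0020     gene          C3 3.435699 2.225786 5.303308 2.770336e-07
```

Every exclusion (uninformative pathways, unsplittable analytes,
non-converged fits, skipped strata) is listed with a reason in
`demo_out/run_log.txt`.  The same steps are available as library calls
(`palscreen.run_study`) and as stage-by-stage subcommands
(`build-pathways`, `annotate`, `pal`, `screen-type`, `screen-tumor`,
`screen-survival`).

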