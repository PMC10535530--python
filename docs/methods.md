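# Methods

## The model

`palscreen` scores the activation of molecular pathways from expression
data and screens genes and pathways as cancer biomarkers.  Three layers
make up the model.

**Interactome.**  A directed graph whose nodes are gene products,
metabolites, and assistive *process* nodes (biochemical reactions and
transport events, each with at least two participants), and whose edges
carry one of three labels: `activation`, `inhibition`, or `other` (complex
assembly, compound relations, and other links that cannot be signed).
Parallel edges between one ordered node pair are retained when their labels
differ — curated source pathways can assert both an activating and an
inhibiting influence, and both votes matter downstream — while identical
(source, target, label) triples are merged.  The graph is built either by
parsing an edge table or by merging many per-pathway edge sets
(`merge_pathway_collection`).

**Gene-centric pathways.**  For every gene product *g*, the pathway
centered at *g* is the set of nodes within one interaction of *g*, plus one
expansion pass: if a neighbor is a process node, all participants of that
process join the pathway.  Expansion is deliberately single-pass (a
participant that is itself a process is included but not expanded), and the
radius counts only non-process hops.  The neighborhood direction is
configurable (`out`, `in`, `both`); the default is `both`, since a
regulator one step upstream of *g* is as much part of *g*'s local network
as a target one step downstream, and the choice is recorded in every run
log so either convention is reproducible.

**Activator/repressor roles (ARR).**  Each member *n* of a gene-centric
pathway *p* receives a weight ARR_p,n ∈ {−1, −0.5, 0, +0.5, +1} by sign
voting.  Every edge connecting *n* to the central gene — directly, or
through a process node adjacent to the central gene — casts one vote:
+1 (activation), −1 (inhibition), 0 (`other`).  A process hop relays the
participant's sign unchanged.  Votes aggregate as: unanimous nonzero sign →
±1; strict majority → ±0.5; tie, all-zero, or no connecting edge → 0.  The
central gene is always +1.  This realizes the five-value semantics — full
activator/repressor, probable activator/repressor, unclear — with a
concrete, enumerable rule: it is deterministic, order-independent, and
antisymmetric under global activation↔inhibition relabeling (all three are
property-tested).  Members that cannot be signed simply drop out of the
activation score (weight 0), which is the conservative choice.

## Pathway activation level

For a tumor sample with per-gene case-to-normal ratios CNR_n, the
activation of pathway *p* is

    PAL_p = Σ_n log(CNR_n) · PG_p,n · ARR_p,n  /  Σ_n |ARR_p,n|

with PG_p,n the membership indicator.  Both sums run over genes present in
the assay *and* in the pathway: a member without expression data (including
every metabolite and process node) contributes to neither sum.  The
symmetric treatment of numerator and denominator keeps PAL an unbiased
weighted mean of observed log-ratios; the alternative — normalizing by all
members — would shrink poorly covered pathways toward zero and conflate
coverage with inactivity.  Pathways with no covered nonzero-ARR member have
an undefined PAL and are excluded upstream with a machine-readable reason
(`all-zero ARR` / `no expression coverage`).

The logarithm base defaults to 10 and is recorded in the PAL matrix
provenance.  It rescales PAL by a constant, so AUCs, ranks, median splits,
and survival results are invariant to it; only the raw PAL values change.

**Case-to-normal ratios.**  RNA counts are first normalized with
median-of-ratios size factors (the DESeq2 estimator: per sample, the median
over genes nonzero in every sample of log count minus the gene's
log-geometric-mean, exponentiated).  CNR_n is then (tumor + 1) divided by
the geometric mean of (normal + 1) over the control group — the normal
samples of the same cancer type, never pooled across anatomical sites.  The
pseudocount of 1 (configurable) guarantees finite, strictly positive
ratios on count data.  Normal samples are ratioed against their own control
group so activation levels exist for them too, which the tumor-vs-normal
contrast requires.  Label-based proteomic data arrive as gene-level
log-ratios instead; CNR is the tumor-to-average-normal ratio obtained by
subtracting the mean normal log-ratio and exponentiating in the input's log
base (2 by default).  Genes quantified in fewer than half of the normals
are dropped (threshold configurable); missing tumor values map to CNR 1 —
absence of evidence, not evidence of change.

## Biomarker screens

Analytes are gene expression levels or pathway activation levels; screening
treats them identically.

**Cancer-type and tumor screens.**  Each analyte is scored in a two-group
contrast (one cancer type vs the rest of the pooled tumors; or tumor vs
matched-site normal) with the Mann–Whitney AUC (ties count one half) and a
two-sided rank-sum p-value, exact for small tie-free groups.  p-values are
Benjamini–Hochberg adjusted within each cancer type × category × contrast
stratum, and an analyte is a significant potential biomarker when
max(AUC, 1−AUC) > 0.7 and q < 0.05.  Orienting the AUC lets both over- and
under-expressed markers qualify; the raw directional AUC is reported next
to it.  The rank test is unpaired by default because both contrasts compare
unequal-sized groups; a paired signed-rank mode exists for matched
tumor/normal designs.

**Survival screens.**  Per cancer type and category, each analyte
dichotomizes the cohort at its median (values strictly above the median are
`high`; ties go low, which makes the split deterministic).  Group survival
is compared with the log-rank test, and the univariate Cox model on the
high-vs-low indicator (Efron tie handling, scalar Newton iteration on the
partial likelihood) supplies the hazard ratio with a 95% Wald interval.
BH adjustment runs over the stratum's log-rank p-values (a switch adjusts
the Cox Wald p instead); significance requires q < 0.05 *and* a confidence
interval excluding 1.  Constant analytes are `unsplittable`, monotone
likelihoods (complete separation) are `non_converged`; both carry a status,
are reported, and are excluded from the adjustment rather than silently
dropped.  The scalar Newton solver exists because a screen fits thousands
of one-covariate models; it is cross-validated against lifelines'
`CoxPHFitter` to 1e−6 in the test suite, and lifelines still provides the
Kaplan–Meier estimates.

## Synthetic studies

The generator emulates the structure of a pan-cancer cohort so the full
pipeline is testable without external data.  Defaults define the reference
study: 3 cancer types × (134 tumors + 33 site-matched normals), i.e. ≈400
tumor subjects and a ≈4:1 tumor:normal ratio per type, the scale of a large
public pan-cancer cohort.  Counts are Poisson draws around a log-normal
mean: per-gene baseline (SD 1 on the natural-log scale around a mean of
500 counts), per-sample biological noise (SD 0.35), and a per-sample
library-depth factor (log-SD 0.15) that exercises normalization.  The
interactome generator draws Poisson out-degrees (mean 3) and labels edges
activation/inhibition/other with probabilities 0.5/0.3/0.2, guaranteeing
every process node ≥2 participants.

Planted effects are the recoverable ground truth:

* **Gene plants** shift one gene's tumor log10-mean by a stated effect in a
  stated contrast (default study: five type-markers at 1.0 log10 — a
  ten-fold shift, the scale of a strong marker).
* **Pathway plants** shift every nonzero-ARR member coherently, the sign of
  each member's shift matching its role, so the pathway's activation moves
  maximally while each member moves weakly.  The aggregation demonstration
  uses 0.15 log10 (≈1.4-fold) per member: members land near AUC 0.75 while
  the pathway's PAL exceeds AUC 0.95 — the weak-coherent-signal regime in
  which pathway-level scoring is claimed to pay off.
* **Survival plants** tie an endpoint's hazard to the standardized log
  analyte level: log hazard = log(baseline) + Σ log-HR · z.  Hazards act on
  the log scale because expression influences risk multiplicatively.  Each
  prognostic analyte is planted into one endpoint (OS or PFS): overall and
  progression-free survival are distinct processes, and stacking several
  strong per-SD hazards into one endpoint makes each marker's marginal
  median-split hazard ratio collapse through frailty (non-collapsibility of
  proportional hazards) — a property of the simulation, not of the screen.
  The reference study plants log-HR 0.7 and 0.9 on OS and 1.1 on PFS.
  Censoring is independent uniform: C ~ U(0, c_max) with c_max solved
  numerically so the expected censored fraction equals the configured rate
  (0.3 by default).

What the generator does **not** emulate: tissue-of-origin expression
programs (all cancer types share one baseline, so between-type differences
are pure noise plus plants — real cohorts separate far more easily),
batch and labeling-chemistry structure in proteomic data, gene–gene
correlation beyond planted pathway coherence, and informative censoring.
Passing tests therefore demonstrate correctness and calibration of the
machinery, not clinical performance on real cohorts.

## Numerical choices and degenerate inputs

* Median-of-ratios requires at least one gene nonzero in every sample;
  otherwise a `NormalizationError` is raised rather than guessing.
* AUC and rank tests return AUC 0.5 / p 1 for constant analytes.
* BH adjustment validates p ∈ (0, 1]; log-rank p-values are clipped at
  1e−300 before adjustment to avoid log-domain underflow.
* The Cox Newton iteration stops at |step| < 1e−10, caps |β| at 20
  (beyond which the likelihood is effectively monotone), and reports
  `CoxConvergenceError` instead of returning a divergent estimate.
* Zero total events yields log-rank p 1 with a degenerate flag; strata with
  zero events are reported as not applicable rather than failing the run.
* The pipeline is fully deterministic: identical config and inputs produce
  byte-identical report bundles (sorted serialization everywhere).

## Scale of the shipped studies

Test-suite and acceptance-script studies run at the reference scale above
(≈60–200 graph nodes, ≈400 tumor subjects, 1,000-analyte null panels,
20-seed end-to-end replication, 100-replicate interval-coverage checks).
These sizes give the rank statistics and Cox fits comfortable power while
keeping a full run in minutes on one CPU; they are the package's chosen
study conditions, stated here so results are interpretable at face value.

## Known limitations

* The ARR vote rule is a declared, versioned stand-in for the original
  recursive annotation procedure, which is not published in reproducible
  detail; alternative rules can be swapped in behind the same interface.
* Sign propagation stops at the pathway radius; no multi-hop or
  fixed-point cycle resolution.
* FDR strata follow the per-cancer-type, per-category design; analytes
  correlated across strata (e.g. overlapping pathways) are not jointly
  modeled.
* The survival screen fits univariate models only; no multivariate
  adjustment, time-dependent covariates, or optimal-cutpoint search (the
  median is the only split).
* Proteomic mode trusts the upstream gene-level quantification; no
  peptide-to-gene mapping or batch correction is attempted.
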