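# Methods

## Problem and model

`methmark` implements a methylation-array marker-discovery workflow for
distinguishing pediatric renal tumor entities — clear cell sarcoma of the
kidney (CCSK), rhabdoid tumor of the kidney (RTK), the Ewing's sarcoma
family of tumors (ESFT), with non-neoplastic kidney (NK) as reference, and
Wilms' tumor (WT) / congenital mesoblastic nephroma (CMN) as additional
negatives for the single-locus assay.

The measurement unit is the per-probe **β-value**, the fraction
β = M/(M+U) of methylated over total probe signal, in [0, 1].  The
effect statistic throughout is **Δβ**, the difference of group-mean
β-values between a tumor group and a comparator.  No significance test is
attached to Δβ: the method is a pure effect-size threshold rule, which is
appropriate at the cohort sizes it targets (n = 3–6 per entity) where a
test would be badly underpowered and the 0.3 threshold already demands a
biologically large shift.

### β computation

`compute_beta(m, u)` returns the plain ratio m/(m+u) with no background
offset added to the denominator.  Scanner software often adds a +100
stabilising offset; we deliberately do not, because the ratio definition
is the documented one for this workflow.  Users matching our numbers
against offset-computed matrices should expect small deviations for
low-intensity probes.  m+u = 0 yields a missing value.

### Probe QC

Two filters, both with **strict** inequalities (values exactly at a
threshold are retained):

* detection p-value > 0.05 in **any** sample removes the probe
  (`detection_scope="any_sample"`, the conservative reading; a per-probe
  `all_samples` scope is selectable because the verbal rule is ambiguous);
* within-entity standard deviation of β > 0.2 for **any** entity removes
  the probe (the filter's purpose is to keep probes that behave
  consistently inside each entity).

The SD uses the sample (n−1) denominator by default.  At n = 3 per entity
the n−1 vs n choice materially changes the filter, so it is exposed as
`sd_ddof` and recorded in the QC report.  Entities with fewer than two
non-missing values contribute no SD.  When a probe fails both filters the
detection reason is recorded (detection precedence), so the report's
reason counts partition the input.

### Differential methylation and marker selection

For tumor T vs reference R, per probe: Δβ = mean(β, T) − mean(β, R) over
non-missing samples.  Calls: *hyper* iff Δβ > +0.3, *hypo* iff
Δβ < −0.3, else *none*; both strict.  Counts are tabulated per direction
× CpG-island stratum, with gene counts deduplicated per stratum.

A probe is **group-specific** for T (hyper) iff its Δβ exceeds +0.3
against *every* other tumor group *and* the reference; hypo symmetric.
Genes are lifted from probes by "≥ 1 qualifying probe", and island strata
are combined at gene level.  With strict pairwise thresholds the specific
sets for a fixed direction are provably disjoint across groups (two
groups cannot each exceed the other by 0.3).  A gene can appear in both
directions via different probes; the counts table reports such overlaps
rather than silently deduplicating.

### Numerical boundary handling

Group-mean differences, entity SDs and single-locus differences are
rounded to 10 decimals before the strict comparison.  Rationale: the rule
is stated in decimal arithmetic, and float64 representation error would
otherwise flip decimal-exact boundary cases (e.g. means 0.40 and 0.10
give a float difference 0.30000000000000004 > 0.3).  A true effect within
10⁻¹⁰ of the threshold has no scientific meaning at these sample sizes.

### Clustering and purity

Two-way agglomerative clustering with the Euclidean metric and complete
linkage on raw β-values (no row standardisation by default; a
`standardize_rows` switch exists).  The sample matrix for clustering is
the union over tumors of all called probes, each counted once.  scipy's
`linkage`/`fcluster`/`to_tree` provide the algorithmic core; the tests
verify the merge heights against an independent O(n³) re-implementation.

"Every case clusters with its own entity" is operationalised as **cluster
purity**: cut the dendrogram into k clusters (k = number of distinct
entity labels), score the fraction of samples carrying their cluster's
majority label.  Purity 1.0 reproduces the qualitative claim exactly and
degrades gracefully when it fails.

### Gene panel and single-locus caller

The panel matrix averages, per gene, all QC-passing probes
(default panel ADRA1D, MGMT, VHL, THBS1).  A sample missing every probe
of a requested gene cannot be averaged and is excluded with a report.
The single-locus caller classifies a sample as marker-positive
("CCSK-like") iff its marker-gene average exceeds the reference-group
mean by more than 0.3 — the same Δ rule as calling, chosen because the
laboratory assay this emulates is scored from a gel with no quantitative
cut-off of its own.  A missing marker value returns *indeterminate*,
distinct from a negative call.

### Bisulfite conversion, PCR and COBRA

Conversion is modelled on the top strand at 100% efficiency: every C
outside a CpG reads T; a CpG C reads C iff methylated in that molecule.
Incomplete conversion is not modelled (no failure rate is available to
calibrate one); sequence length is preserved and A/G/T are fixed points.

Primers carry lower-case 5' tags (forward tag; reverse T7-promoter tag)
and upper-case genomic parts written in converted coordinates.  Matching
is exact (no mismatch tolerance — the intended use is assay design
validation, where a non-exact match is a design error); a molecule with
no site pair yields no product, and multiple candidate products raise an
ambiguity error listing loci.

Digestion cuts at every occurrence of the recognition sequence in the
product — including constant sites falling in the tags, as a real enzyme
would in the double-stranded product — with fixed offsets A^CGT
(HpyCH4IV) and T^CGA (TaqI).  Only fragment lengths are modelled, not
overhangs.  Per covered CpG the *cut fraction* is the fraction of
molecules whose product carries the intact site across that CpG; for an
ACGT-context CpG this equals the methylated fraction exactly (site
survives conversion iff methylated), which the tests verify exhaustively
over all 2^k states for k ≤ 6.  The binary per-case call is
hypermethylated iff cut fraction > 0.5, the midpoint between the 0% and
100% methylated controls.

## Synthetic data generator

The generator emulates a small promoter-centric methylation array study:

| parameter | default | meaning |
|---|---|---|
| `n_probes` | 2000 | array size (desk-scale stand-in for a 27k array) |
| `island_fraction` | 0.7 | fraction of probes on CpG islands (promoter arrays are island-heavy) |
| `groups` | CCSK/RTK/ESFT/NK × 6 | entities and samples per entity |
| `n_planted_hyper` / `n_planted_hypo` | 50 / 20 | planted DM probes per tumor group (hyper on islands, hypo on open sea — the direction each baseline makes feasible) |
| `effect_size` | 0.45 | mean Δβ of planted sites, comfortably above the 0.3 call threshold |
| `baseline_island_mean` / `baseline_open_mean` | 0.08 / 0.65 | stratum baselines emulating the bimodal β distribution |
| `noise_concentration` ν | 50 | Beta(μν, (1−μ)ν) noise; within-group SD ≈ 0.04–0.07, below the 0.2 QC exclusion |
| `dropout_rate` | 0.005 | per-cell probability of a failed detection (detection p drawn from U(0.06, 0.5) instead of U(0, 0.04)) |

Each planted probe sits on its own gene, and planted sets are disjoint
across groups, so probe recovery and group-exclusive gene recovery are
both well defined.  On top, four named panel genes (THBS1, MGMT, VHL,
ADRA1D; three probes each) carry a tumor-type-specific pattern — THBS1
hyper only in CCSK, MGMT hyper in all tumors, VHL hypo in CCSK+RTK,
ADRA1D graded — whose offsets are expressed in units of `effect_size`, so
`effect_size=0` produces a pure null matrix with no structure anywhere.
The truth registry lists every planted site and, for marker recovery,
the genes whose *configured* (noise-free) means satisfy the specificity
rule at Δβ > 0.3.

What the generator does **not** model: probe cross-hybridisation,
SNP-under-probe artifacts, batch/chip effects, between-probe baseline
heterogeneity beyond the two strata, and correlated noise between
neighbouring probes.  Passing recovery tests therefore demonstrates that
the statistical machinery is correct under the stated noise model, not
that the thresholds are optimal for any particular real cohort.

A fixed seed fixes every emitted value (matrices, truth, template
molecules); the acceptance script threads one seed through all stages.

## Problem sizes

The packaged study runs 2000 probes × 24 samples; recovery, clustering
and null experiments complete in seconds.  Restriction-assay controls
use 10,000 molecules (binomial 99% interval at the 50% control:
4871–5129 methylated of 10,000) and per-case cohorts 2000 molecules,
at which the 0.9 vs 0.05 site fractions are separated from the 0.5 call
threshold by > 40 binomial standard deviations.

## Known limitations

* Only the top strand is modelled in conversion/PCR; assays designed
  against the bottom strand must be reverse-complemented first.
* Exact primer matching; degenerate or mismatch-tolerant primers are out
  of scope.
* The gene-count convention assumes one gene symbol per probe;
  multi-gene manifests must be collapsed to a single symbol beforehand.
* Raw scanner output (IDAT) and GEO series formats are not parsed; the
  pipeline starts from delimited text matrices exported by upstream
  tools.
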