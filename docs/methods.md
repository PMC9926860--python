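# Methods

## Derived glycan traits

A glycomics panel is a compositional table: within each glycan class
(*N*, *O*, GSL) the relative abundances of all glycans in a sample sum to
100. Panels are renormalised to 100 on load; inputs whose totals deviate
by more than 1% are reported, which absorbs dialect differences between
quantification pipelines. The trait value of sample *s* for trait *t* is
`Σ_g a_gs · c_gt` with `c_gt` the epitope count of trait *t* on glycan
*g*; values are therefore in relative-abundance units and can exceed 100
when an epitope occurs more than once per structure. Integration across
classes is plain summation after case-insensitive trait-name alignment; a
trait absent from a class contributes 0.

Epitope counts come from one of three rule modes:

* **motif_count** — anchored matching of a pattern tree against the parsed
  structure; every residue of the glycan is tried as the anchor and
  anchors count independently. Negative constraints exclude decorated
  matches (a Le^x galactose must not be further sialylated, a T-antigen
  core must be unsubstituted). The ganglioside trait uses a *presence*
  variant (any sialic acid makes a GSL a ganglioside, counted once).
* **numeric_property** — currently antennarity: the number of GlcNAc
  residues attached to an α-mannose of the trimannosyl core, which
  excludes the chitobiose and bisecting GlcNAcs.
* **annotation_column** — a pre-annotated count from the input table, the
  input path for species reported as compositions only, where a structure
  cannot be parsed. This keeps composition-only supplementary rows usable
  without guessing topology.

The combined "(s)Lex/a" trait is the sum of the four Lewis-family motifs
(Le^x, Le^a, sLe^x, sLe^a); the plain forms exclude sialylated galactoses
so the family never double-counts an anchor. Sub-traits are emitted
separately. The sialylation traits accept both Neu5Ac and Neu5Gc at the
stated linkage.

## Grammar and canonical form

Structures are condensed IUPAC read leaf-to-root:
`Name(<anomer><carbon>-<position>)`, side branches bracketed immediately
before their parent, substituents suffixed to the residue name
(`GlcNAc6S`). The monosaccharide vocabulary is closed and configurable;
unknown tokens are rejected at parse time with the offending token, and
bracket errors carry the character offset. Branch order is canonicalised
by (linkage position ascending, full serialized subtree lexicographic),
making serialize∘parse a fixed point and parse∘serialize an isomorphism.
Ambiguous linkages (`?`/`x`) match only wildcard pattern fields, never
concrete ones — an uncertain sialic-acid linkage contributes to neither
the α-2,3 nor the α-2,6 trait rather than being guessed.

## Correlation analysis

Trait–gene and gene–gene associations use Spearman's rank correlation
with midrank ties, p-values from the t-approximation (exact permutation
available behind a flag); at the cohort sizes this package targets
(≈ 19 samples) the t-approximation is standard practice and its null
starring rate is verified by simulation in the acceptance suite. Pairs
are starred on raw p at 0.05/0.01/0.001; Benjamini–Hochberg adjusted
values are emitted alongside but do not drive the stars, matching the
conventional presentation of such heatmaps. Missing values are removed
pairwise; fewer than 4 complete pairs is a refusal, and constant vectors
yield a missing correlation with a warning rather than a number.

## RV2 cohort bridge

Two cohorts with disjoint samples cannot be compared sample-wise, but the
*correlation structure* over a shared gene set can: the pipeline computes
the GST×TF Spearman matrix in each cohort, row-aligns on the sorted shared
GST symbols, and compares the matrices with the modified RV coefficient
(RV2). Columns are mean-centred, configuration matrices `AAᵀ`/`BBᵀ` formed,
their diagonals deleted, and the coefficient is the Frobenius inner
product over the product of Frobenius norms. Deleting the diagonals
removes the self-covariance terms that push the classical RV coefficient
toward 1 in high dimensions; the result lies in [−1, 1], is invariant to
orthogonal column rotations and positive column scaling, and equals 1 for
a matrix with itself. Significance, where wanted, comes from permuting
the row order of one matrix: `p = (1 + #{permuted ≥ observed}) / (n_perm + 1)`
with the seed recorded. Fewer than 3 rows is a refusal (the
diagonal-deleted configuration degenerates).

## Multivariate overview

PCA uses autoscaling (centred, unit variance, sd with n−1) so each trait
enters on the same footing, then an SVD; component signs are fixed by
making the largest-magnitude loading positive, which keeps outputs
deterministic. To prevent the class with the most traits from dominating,
blocks are balanced before PCA: each class keeps its top-variance traits
down to the smallest class's count ("min-block" policy; "all" is
selectable). Constant features are dropped with a warning; requesting
more components than the rank truncates with a warning. Radar (group
profile) data are mean z-scores per FAB class, z-transformed over all
samples with sample sd (n−1 throughout the package).

## FAB group statistics

Per-gene one-way ANOVA across FAB classes followed by Tukey's HSD
(studentized range; Tukey–Kramer for unequal group sizes), with pairwise
tiers at p ≤ 0.05/0.01/0.001/0.0001. Groups below the minimum size
(default 3, configurable) are excluded before testing — very small rare
classes cannot support the post-hoc comparisons — and exclusions are
recorded in the run manifest. No cross-gene multiple-testing adjustment
is applied; results are presented per gene, with the family-wise picture
left to the reader as is conventional for such screens.

Microarray inputs arrive pre-normalised; where multiple probe sets map to
one gene, the probe with the highest mean expression across samples is
retained (ties to the lexicographically smallest probe id), a
deterministic collapse rule that replaces manual curation and is logged
per gene. Gene rows missing in more than 20% of samples are dropped;
remaining missing values are excluded pairwise in correlations.

## Synthetic cohorts and what they show

The generator emulates the statistical structure of the target setting:

* **Structures** are drawn from a built-in library of 8 templates per
  class (biantennary/triantennary *N*-glycans with sialylated, Lewis- and
  LacNAc-bearing antennae; *O*-glycan cores Tn/T/sialyl-T/core 2 with
  sulfation, H and α-2,8 variants; GSL lacto/ganglio/neolacto series with
  Neu5Gc and Lewis variants), each hand-annotated with its epitope counts.
  These annotations are the ground truth the motif engine is tested
  against; a template planting more epitopes than it has residues is
  refused as infeasible.
* **Abundances** per sample are Dirichlet-distributed around group-specific
  target compositions and total exactly 100. Defaults: 19 samples in
  groups M1/M2/M4/M5/M6 (2/3/3/6/5 — the M5/M6-dominated composition the
  analysis targets), 20 glycans per class, concentration 300 (sample-level
  compositional noise of a few percentage points). Group shifts
  multiply target weights: ×3.0 on Lewis-bearing glycans for M5, ×2.5 on
  (non-Lewis) sialylated glycans for M6, ×2.0 on H-bearing glycans for M4,
  mirroring the monocytic/erythroid/myelomonocytic contrasts of interest.
* **Expression**: each coupled GST is `baseline + effect · z(trait) +
  σ·N(0,1)` with σ = 0.5 and |effect| ∈ {0.8, 1.0} (e.g. FUT7→(s)Lex/a +,
  ST6GALNAC6→α-2,6 −); each coupled TF drives a signed combination of its
  GSTs' signal parts (SPI1/CEBPA→FUT7/FUT4 +, GATA1→ST3GAL2 + and FUT7 −,
  RUNX1/CBFA2T3→ST8SIA6 +, TAL1→ST6GALNAC1 +). Uncoupled panel genes are
  pure noise. Gene identities are mnemonic labels for planted roles, not
  biological claims.
* **Seeds**: the cohort *structure* (base compositions) derives from the
  config seed, the sampling noise from a separate stream, so "noise
  replicates" of one cohort (same structure, independent noise — used to
  exercise the RV2 bridge) are well defined. `dirichlet_concentration=None`
  with `expression_noise_sd=0` gives the noise-free limit in which trait
  recovery is exact and planted correlations reach ±1.

What passing tests show: the trait formula, motif engine, correlation,
PCA/radar and group-statistics code paths recover planted truth under
realistic compositional and expression noise. What they do not show: the
generator has no measurement batch effects, no missing glycan
identifications, no compositions-only species by default, no heavy-tailed
expression, and far fewer glycans than a real panel — conclusions about
real-data performance are limited accordingly.

## Problem sizes and numerics

The test suite and `scripts/acceptance.py` use simulation sizes chosen to
estimate each quantity stably on a single CPU in minutes: 50 seeds for
trait recovery and coupling-sign recovery in the suite (25 in the script),
100–200 replicates × 100 pairs for the null starring rate, 300–500
families for the Tukey family-wise error. Trait recovery is compared at
1e-9 absolute tolerance (double-precision accumulation order differs from
the nested-loop ground truth); RV2 self-correlation at 1e-12. CSV outputs
are written with a fixed `%.10g` float format, which together with
seed-derived randomness makes repeated pipeline runs byte-identical.

## Known limitations

* The grammar covers condensed IUPAC with single-character anomers and
  numeric positions; GlycoCT/WURCS and repeat units are out of scope
  (GlyTouCan accessions are carried as metadata only).
* Motif matching is injective on children but does not attempt glycan
  isomorphism beyond the canonical branch order; exotic multi-anchor
  overlapping epitopes count per anchor, which is the intended multiplicity
  semantics but differs from substructure-set counting.
* The externally published per-cell-line trait tables needed to check the
  printed cross-class correlations are not shipped; the corresponding test
  documents the expected location and fails until they are supplied.
* The RV2 permutation test permutes rows under an exchangeability
  assumption that is questionable when rows (genes) are strongly
  correlated; treat its p-value as descriptive.
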