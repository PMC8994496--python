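# Methods

`stressnet` re-implements, as a tested and reusable pipeline, a
transcriptome analysis of pre-slaughter stress in bovine muscle: cows
exposed to combined emotional and physical stress are compared with cows
handled under limited stress, in two muscles with different metabolic
profiles (*M. longissimus thoracis*, LT, oxidative; *M. semitendinosus*,
ST, glycolytic), on a custom oligonucleotide microarray. This note
documents the statistical model of every stage, the synthetic-data
generator that stands in for the raw arrays and the proprietary promoter-
and interaction-databases, the numerical choices, and what the test suite
does and does not demonstrate.

## Normalization

The platform carries 10,064 probes, of which 1,614 are non-biological
control probes, covering 4,210 genes (several probes per gene).
Cell-level quality flags (spot saturation, uniformity, signal above
background) are taken as an input; failing cells become missing values and
probes failing everywhere are dropped.

Normalization is ratio-based in two sequential divisions:

1. every intensity on an array is divided by the median intensity of that
   array's control probes — removing the per-array multiplicative scale;
2. every probe's stage-1 value is divided by the probe's median stage-1
   value across all arrays — removing the probe-specific baseline.

Rows still containing a missing value are then removed and the matrix is
log2-transformed. Two exact contracts follow and are enforced to 1e-9 in
the tests: after stage 1 the control-probe median of every array is 1, and
after stage 2 every retained probe's cross-array median is 1 (both on the
pre-log scale). The stage-2 median is computed on stage-1 values rather
than raw values — the two divisions are sequential, and this is the only
order under which both contracts can hold simultaneously. Control probes
are excluded from the matrix handed to the differential analysis (they
carry no biological signal); both divisors are kept as provenance.
Medians use the standard midpoint convention on even counts, so the whole
stage is deterministic. Background subtraction and spatial artifact
correction belong to the scanner software and are out of scope.

## Differential expression

Each muscle is analysed separately (n = 16 stressed vs 16 limited-stress
arrays per muscle). Every probe receives an ordinary least-squares fit of
its log2 values on stress, diet (a control diet vs one enriched with
vitamin E and plant polyphenols, "EP") and their interaction, in treatment
coding. The contrast of interest is the stress main effect averaged over
diets, c = β_stress + ½·β_stress:diet, which in a balanced design equals
the plain difference of group means. The original model mentions an
additional "period" term that is never defined; the design-matrix builder
accepts arbitrary extra covariates for this purpose but none is included
by default, since only stress effects were ever detected.

Variances are moderated with the standard empirical-Bayes scheme:
per-probe residual variances s²_g with d_g degrees of freedom are assumed
to follow a scaled inverse-chi-square prior (s₀², d₀), estimated by
moment-matching the log sample variances against the theoretical scaled-F
distribution. Writing e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the excess
of Var(e) over the mean of ψ′(d_g/2) estimates ψ′(d₀/2), inverted by a
Newton iteration on the trigamma function; the mean of e then gives s₀².
The posterior variance

    s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g)

yields the moderated t with d₀ + d_g degrees of freedom. Degenerate cases:
zero-variance probes are excluded from prior estimation (they carry no
information about it); when the observed variances are essentially
homogeneous the trigamma equation has no positive root and d₀ is clamped
at 10⁶, which is numerically the normal reference; d₀ = 0 recovers the
ordinary t exactly. The implementation is cross-checked in the test suite
against R/limma's `lmFit`/`eBayes` on the same data and contrast (prior
estimates, t and p agree to at least six digits) — limma serves only as an
independent oracle, never as the implementation.

P-values are Benjamini–Hochberg adjusted across probes within a muscle
(step-up, via statsmodels, verified against a brute-force restatement of
the definition). Gene calls then apply a probe-consistency rule: a gene is
differentially expressed iff at least 80% of its probes are significant at
adjusted p < 0.10 (boundary inclusive: 4 of 5 probes passes) **and** all
of its probe log2 ratios share one strict sign. The gene-level effect is
the median probe log2 ratio — robust and unbiased under the generative
model — reported as a signed linear fold change (−2^|median| for
down-regulation). The probe→gene map must be functional; a probe mapped to
two genes is an input error, not a tie to resolve silently.

## Over-representation tests

**Annotation terms.** One-sided hypergeometric upper-tail tests of a query
gene list against the background of genes represented on the array, with
BH control applied within each namespace (biological process and
molecular function separately, mirroring how the results are reported) and
significance at FDR < 0.08. Query genes absent from the background are
dropped with a warning; the background is gene-level — probes are
collapsed to genes before testing, since enrichment operates on gene
lists. No term-size floor or ceiling is applied and no GO-graph
propagation is performed: the annotation table is taken as already
materialized.

**Promoter cis-modules.** A cis-transcriptional module is a framework of
co-occurring transcription-factor binding sites in a promoter. Module-hit
tables (module, gene, promoter, match-position count) are consumed as an
input; promoter extraction and library scanning are proprietary upstream
steps and out of scope. Each module's 2×2 table counts *genes* — a gene
counts once however many of its promoters match — against the array
universe, tested with the one-sided Fisher exact test (equivalently the
hypergeometric tail on the observed margins, verified against exact
integer-arithmetic enumeration). The reported *occurrence* sums match
positions over the query's promoters, which is why it can exceed the
target-gene count. Modules are selected at strict p < 0.1 and intersected
across muscles by module identifier. Genes with no retrievable promoter
must be removed from both query and universe by the caller; the tabulation
refuses queries that are not a subset of the universe.

## Network extraction

The interaction database is a directed edge list with two relation types —
Regulation edges point regulator → gene, Expression edges point gene →
expression target — each carrying a bibliographic reference count.
Duplicate edges merge by summing references; a node's "known relations"
is its total incident edge count. Around a seed set (the differential
genes targeted by the most-represented promoter modules: at least 5
target genes per module in LT, 4 in ST, and the cross-muscle common
modules for the core network), the extraction admits:

* a **regulator** candidate ∉ seeds with Regulation edges into ≥ 2 seeds,
  at least one such edge with ≥ 3 references, and database degree ≥ 2
  (≥ 5 under the stricter profile used for the core network);
* a **target** candidate ∉ seeds receiving Expression edges from ≥ 2
  seeds, at least one such edge with ≥ 3 references, and degree ≥ 6.

"Common to the seeds" is operationalized as ≥ 2 seed connections
(`min_connected`, exposed as a knob) — the weakest non-trivial reading.
The reference threshold is satisfied by the best qualifying edge
(per-edge maximum, not a sum). Both readings are configurable because the
upstream tool's exact semantics are not public. Raising any threshold can
only shrink the admitted sets (verified as a monotonicity property), and
the extraction agrees with a literal brute-force scan of every database
node on random databases. The major regulators/targets are the
intersections of the role sets across the extracted networks.

## QTL containment

Gene loci and QTL intervals are normalized to 0-based half-open
coordinates at load time (1-based inclusive tables are converted; BED is
read as-is). A gene maps into a QTL only when its span is entirely
contained — same chromosome, QTL start ≤ gene start and gene end ≤ QTL
end, endpoint equality allowed, strand ignored. A gene may hit several
QTLs; hits are then filtered by trait class (by default "meat-quality":
shear force, muscle compression, tenderness score, muscle pH, juiciness,
marbling score) and unique genes are counted. Which database trait names
belong to which class is user-supplied input, as the original grouping is
not enumerated anywhere.

## Synthetic data generator

The generator emulates the study's inputs end to end with planted ground
truth, so every downstream stage is testable without any download.
Defaults are the study's conditions: 10,064 probes (1,614 controls),
4,210 genes with 1–4 probes each, 32 animals in a 2 stress × 2 diet
balanced design, both muscles sampled per animal (64 arrays, 16 per
stress group within a muscle).

Intensities are log-normal — Gaussian on the log2 scale around a per-probe
baseline (uniform on [6, 12]) — with additive noise (σ = 0.2), a per-array
multiplicative scale (log2-normal, σ = 0.1) applied to all probes
including controls, and the planted effect added to every non-control
probe of a differential gene in the stressed samples of its designated
muscle(s). This matches the ratio-based normalization exactly: the paper
never states the intensity distribution, so log-normality is a modeling
choice, not data-derived. 40 genes are planted as differential with
|log2 fold change| uniform on [1, 2] (signs 60% up, echoing the observed
skew), allocated 40% to both muscles, 40% LT-only, 20% ST-only —
proportions chosen once to resemble the published split. Per-cell QC
failures occur at rate 0.001, so after missing-row removal ~94% of probes
survive; real platforms lose probes at broadly similar rates, but no
published figure exists for this one.

The other resources are fabricated around that truth: planted promoter
modules hit all common differential genes plus a couple of
muscle-specific ones (match positions 1 + Poisson(0.5)) over a 1%
background rate applied to every module across all genes; the interaction
database gives planted regulators Regulation edges into up to six common
differential genes (references from a shifted geometric distribution,
minimum 3; filler relations raise their degree past both profile cuts)
and planted targets the mirror-image Expression edges, while decoy nodes
each violate exactly one admission rule; QTL-spanning genes sit fully
inside dedicated meat-quality QTLs at coordinates no other gene can
reach, with boundary-straddling loci exercising the strict-containment
rule; and one planted annotation term covers all differential genes plus
1% background. All randomness flows from one integer seed through
`numpy.random.SeedSequence.spawn`, one child stream per artefact, so
identical (seed, config) pairs produce byte-identical files.

What passing tests therefore show: the pipeline recovers exactly the kind
of signal it models — additive log-scale group effects, module/network
evidence planted precisely at the admission thresholds. What they do not
show: robustness to probe-level artifacts (spatial gradients, saturation,
dye effects), annotation incompleteness, correlated probes within a gene,
or literature-curation biases in real interaction databases. Real-data
performance claims rest on the original study, not on these simulations.

## Problem sizes used by the checks

The statistical suites run at sizes chosen to give stable rates while
keeping the whole test run in minutes on one CPU: null calibration uses
100 data sets of 5,000 probes with 16 arrays per group (one muscle);
planted-signal recovery uses 50 full-scale bundles (10,064 probes, both
muscles); the Fisher/hypergeometric enumeration oracle is exhaustive over
all 2×2 tables with total count ≤ 25 plus 500 random tables with margins
up to 40; BH is compared with the brute-force step-up on 1,000 random
vectors; QTL containment against an all-pairs scan on 10,000 pairs;
network extraction against a whole-database node scan on a 200-node
database. The acceptance script reruns the same machinery at 10 recovery
and 20 null data sets from a user seed. Smaller per-module property
checks (enrichment null rate, module selection null rate, planted
database recovery) use 20–60 seeds at a reduced array size (600 probes,
250 genes) with the same structure.

## Known limitations

* The 80% probe-consistency rule is applied per gene symbol; whether the
  original counted probes per transcript when a gene had several
  transcripts is not stated.
* The Fisher universe is gene-level; a promoter-level universe would give
  slightly different margins for multi-promoter genes.
* "Known relations" counts total incident database edges regardless of
  direction or type; other readings are plausible and the thresholds are
  exposed for that reason.
* The pipeline's TF/TM flags come from an external dictionary input; no
  attempt is made to classify transcription factors computationally.
* The qPCR validation arm of the original study is represented only as an
  optional fold-change comparison column; the assay itself is out of
  scope.
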