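# Methods

## The calling procedure

All calling is rule-based and control-anchored. Coordinates are 0-based,
half-open, on a single linear pseudo-chromosome; the promoter of a gene
is the closed window within 1 kb of its TSS (strand-ignored — the TSS is
a point and the rule set gives no strand asymmetry).

**Array arm.** Probes are first removed on technical grounds: SNP
overlap, bead count below 3 in *any* sample, or detection P above 0.01
in any sample. The "any sample" dialect is a deliberate choice among the
per-sample variants such filters admit; both boundaries are strict.
Age-drift probes are then removed so adult and child controls can pool:
per sex with at least two adult and two child controls, a Welch
two-sample t-test per probe, Benjamini–Hochberg adjustment across probes
within the sex, removal when adjusted P < 0.05 in either sex. Welch + BH
is a transparent stand-in for a limma-style moderated test; with the
default effect size (β shift 0.3 against Beta noise of σ ≈ 0.02–0.035)
the two are operationally indistinguishable, and the test statistic is a
configuration detail, not part of the contract. Probes with zero
variance in both groups yield P = 1 (never removed). The filter is
idempotent: BH-adjusted P values of surviving probes only increase when
significant probes are removed, so a second pass removes nothing.

Gene extraction evaluates per-probe control criteria and requires a run
of at least `min_run` (default 2) *consecutive* qualifying probes within
the surviving, position-sorted promoter probe set. "Consecutive" is
defined on that set: a QC-removed probe does not break a run, because it
no longer exists. Escape candidates: mean β < 0.15 in male and in female
controls, every control β < 0.24, |mean_F − mean_M| < 0.1. Inactivated
candidates: male mean < 0.15, every male < 0.25, every female > 0.25,
female mean < 0.5. Every comparison is strict, and the 0.24 / 0.25
asymmetry between the two rule sets is preserved verbatim. Genes with
fewer than `min_run` surviving promoter probes are reported *ineligible*
rather than negative. Probes with any missing control value cannot
satisfy an "all controls" clause and count as un-flagged.

Patient calls are restricted to previously extracted genes and use the
same run rule: escape_hyper at β > 0.25; inactive_hypo at β < 0.15;
inactive_hyper at β > 0.5 **and** β > (per-probe maximum female-control
β) + 0.05. The margin term anchors hypermethylation to the observed
control ceiling rather than an absolute cutoff. A missing patient β is
un-flagged (and logged), so it breaks runs conservatively.

The "more than two consecutive probes" phrasing of the original rule is
read as a run of **at least two**, because the accompanying illustration
applies the rule to genes carrying exactly two promoter probes;
`min_run` is configurable for the ≥3 reading.

**Concordance** against a reference XCI annotation is
100·concordant/candidates, rounded half-up to one decimal; candidates
missing from the annotation count discordant; an empty candidate list is
reported not-applicable rather than 0%.

**RRBS arm (PAR1).** CpGs with coverage below 10 in one or more samples
are removed (strict "less than"); methylation ratio = methylated/total.
Extraction first excludes CpGs where any control ratio exceeds 0.24,
then flags CpGs with control mean < 0.15 in both sexes and sex
difference (mean_F − mean_M) inside the **closed** band [−0.1, 0.1]. A
gene is selected at ≥ `min_cpg` (default 2) qualifying CpGs — a count,
not a run, as the CpG-level rule has no consecutiveness clause. Patient
calls count criterion CpGs with ratio > 0.25. Input is assumed
destranded; CpG dyad collapsing is out of scope.

**XCI skew.** With digested/undigested peak heights (dᵢ, uᵢ) of a
heterozygous microsatellite, per-allele survival is rᵢ = dᵢ/uᵢ
(normalising by the undigested peak removes allele-specific PCR bias —
the point of running both digests), and the ratio is
100·max(rᵢ)/(r₁+r₂) ∈ [50, 100]. Classification: skewed at ≥ 80
(threshold configurable; the source rules state the boundary both as
"80% or more" and "more than 80%", and the inclusive reading is used),
uninformative for single-peak (homozygous) samples, not-applicable when
both alleles digest completely. The exact two-allele arithmetic is not
printed in the original description; the normalized-share formula is
this package's documented choice. It is scale-invariant and recovers the
simulator's skew parameter exactly in the noise-free limit.

## The generative model

Bulk tissue is a mixture of exactly two cell populations: cells whose
rearranged X is inactive (weight *f*, the skew fraction, ∈ [0.5, 1]) and
cells whose normal X is inactive (weight 1 − *f*). At a gene with copy
number *c* on the rearranged X (0 deletion, 1 neutral, 2 duplication,
3 triplication; outside segments *c* = 1), an allele is methylated iff
it lies on the inactive chromosome and the gene is subject to XCI there.
Escape alleles are never methylated; perturbed genes behave as
inactivated on the rearranged chromosome only. The expected
methylated-allele fraction is

  μ = [ f·c·1(inactive on rearranged) + (1−f)·1(inactive on normal) ] / (1 + c),

always a ratio of small integers: normal female inactivated gene 1/2;
duplication at f = 1 → 2/3; deletion at f = 1 → 0; either at f = 0.5 →
1/2 (the masking effect — random XCI makes a rearranged gene look
normal). Males have a single, active X: μ = 0 for every class.

The array's response maps μ affinely, β_mean = μ_low + (m − μ_low)·μ,
with baseline μ_low = 0.05 (background of an unmethylated promoter) and
methylated-allele level m = 0.9 (bisulfite conversion and probe
chemistry saturate below 1). This puts a normal female inactivated
promoter at β ≈ 0.475 — inside the (0.25, 0.5) extraction band, as real
blood data sit — and a fully skewed duplication at ≈ 0.62. β values are
drawn from a Beta distribution with that mean (clamped to [0.01, 0.99])
and concentration κ = 200 (SD ≈ 0.015 at the baseline, ≈ 0.035
mid-scale), a realistic array noise level at which the control criteria
hold with high probability for cohorts of ~11 per sex. RRBS counts are
Binomial(Poisson(depth), p) with the same per-gene p; PAR1 genes escape
in both sexes, so controls sit at μ_low. Assay peaks are per-allele
heights with multiplicative lognormal noise; the digested height of an
allele is proportional to the fraction of cells in which its chromosome
is inactive.

Other generator features: gene classes are apportioned deterministically
by largest-remainder rounding (default mix 10% escape, 5% mostly-escape,
25% variable, 45% inactive, 15% mostly-inactive; `mostly_*` classes
behave identically to their parent class and differ only as annotation
labels); variable-class genes re-draw a Bernoulli(0.5) escape status per
individual, so they qualify for neither extraction rule in a cohort of
any size — as in real data; a fixed random 5% of probes shift by +0.3 in
adults only (age drift); QC metadata (bead counts, detection P, SNP
flags) are simulated with ~2–3% failing probes. Genes sit 4 kb apart so
±1 kb promoter windows never overlap; each non-PAR gene carries 2–6
probes uniform in its window (several probes per promoter, as on
methylation arrays); PAR1 genes carry sequencing CpGs instead of probes,
mirroring the array's absence of PAR1 coverage.

Determinism: every stochastic operation derives its own substream from
the master seed and a fixed label, per sample where applicable — so
identical seeds give bit-identical outputs, and adding or removing
patients never changes control draws (extraction is provably unaffected
by patient columns).

What the generator does **not** model: probe cross-hybridisation,
normalisation and batch artefacts (inputs are assumed BMIQ-normalised
and batch-corrected; the sample-sheet batch column is provenance only),
cell-type composition, spatially correlated methylation beyond the gene
unit, CpG strand structure, or real hg19 coordinates. Passing tests
therefore demonstrate the correctness and statistical behaviour of the
*calling rules* under the stated noise model, not performance on raw
array or sequencing data.

## Default cohort and study designs

The default control cohort mirrors the study design the rules come from:
4 adult females + 7 girls and 4 adult males + 8 boys for the array arm;
the RRBS arm uses its own 4 + 4 adult controls. The default simulated
genome has 200 X-linked genes plus 10 PAR1 genes. The bundled
"complex-rearrangement" patient design places a deletion over ~20% and a
duplication over ~40% of the gene list and perturbs three escape genes
inside the duplication under complete skew (f = 1). Property suites use
20–50 seeds of this design; the acceptance script reports
duplication-hypermethylation rates over 20 seeds at f = 1.0 and f = 0.5.
These sizes give stable rates (SE of a per-seed fraction over ~30
duplicated genes × 20 seeds is ≈ 1–2 percentage points) while keeping a
full run in seconds.

## Numerical and degenerate-input choices

* Concordance rounding: decimal half-up at one decimal (72.727 → 72.7).
* Run ties: the earliest maximal run is reported; at most one call per
  gene per call type.
* Zero-variance drift tests → P = 1; zero-coverage ratio cells → NaN;
  complete digestion of both alleles → not-applicable.
* Beta means are clamped to [0.01, 0.99] before noise so concentrations
  stay finite; the drift shift is clamped the same way.
* `SegmentSet` validates non-overlap and half-open intervals at
  construction; positions outside segments have copy number 1.
* Thresholds are all plain config keys (`PipelineConfig`), echoed into
  every summary for provenance.

## Known limitations

* The drift filter substitutes Welch t + BH for a moderated linear-model
  test; with very few controls per group (2–4) its power profile differs
  from the moderated version, though both are far beyond saturation at
  the default simulated effect size.
* Variable-escape genes are modelled as a per-individual coin flip;
  real variable escape is partly tissue- and locus-structured.
* The RRBS arm assumes destranded, pre-aggregated counts; alignment,
  trimming and CpG-dyad merging are upstream concerns.
* With ~11 controls per sex, a variable gene occasionally (P ≈ 2⁻¹¹ per
  gene) presents an all-escape control panel and enters the escape
  candidate list; downstream patient calls on such genes are annotated
  by their true class in the reports, and the phenomenon mirrors the
  irreducible ambiguity of variable escape in small cohorts.
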