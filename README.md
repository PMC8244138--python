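# escapex

Calling X-chromosome-inactivation **escape** and **inactivated** genes from
promoter methylation, and detecting abnormal promoter methylation in
patients with X-chromosome rearrangements.

## The problem

X-chromosome inactivation (XCI) silences one of the two female X
chromosomes, methylating the promoters of silenced ("inactivated") genes
on the inactive X (Xi). Roughly 15% of X-linked genes *escape* XCI: their
Xi promoters stay unmethylated. In bulk blood this yields a crisp
sex-stratified signature per promoter probe:

| gene class | male β | female β |
|---|---|---|
| escape | ≈ baseline (~0.05) | ≈ baseline |
| inactivated | ≈ baseline | ≈ 0.45–0.5 (one methylated allele of two) |

`escapex` implements the rule-based procedure that exploits this
signature:

* **Array arm** — after probe QC (bead count < 3 in any sample, SNP
  overlap, detection P > 0.01; then removal of age-drift probes by Welch
  t + Benjamini–Hochberg between adult and child controls), genes are
  extracted whose promoter (±1 kb of TSS) carries ≥ 2 *consecutive*
  probes that are hypomethylated in controls of both sexes (escape
  candidates: mean β < 0.15, all controls < 0.24, |Δβ| < 0.1) or
  male-low / female-intermediate (inactivated candidates: male mean
  < 0.15, all males < 0.25, all females > 0.25, female mean < 0.5).
  Patients are then screened for runs of β > 0.25 in escape genes
  (abnormal hypermethylation), β < 0.15 in inactivated genes
  (hypomethylation, e.g. on deletions) and β > 0.5 ∧ β > max female
  control + 0.05 (hypermethylation, e.g. on duplications under skewed
  XCI).
* **RRBS arm** — pseudoautosomal (PAR1) genes have no array probes; the
  same logic runs on per-CpG methylation ratios (C / (C+T) reads, depth
  ≥ 10 in every sample), counting qualifying CpGs instead of runs.
* **XCI skew assay** — HpaII digestion destroys the active-X allele
  before PCR of a polymorphic repeat; with digested/undigested heights
  (dᵢ, uᵢ), the skew ratio is 100·max(rᵢ)/(r₁+r₂) with rᵢ = dᵢ/uᵢ,
  skewed when ≥ 80%.
* **Synthetic cohorts** — a mechanistic generator (two cell populations:
  rearranged X inactive with probability *f*, normal X inactive with
  1 − *f*; per-allele methylation; Beta/binomial noise) emulates every
  input: control cohorts of both sexes and age groups, copy-number
  segments (deletion / duplication / triplication), variable-escape
  genes, age-drift probes, and assay peaks. The masking effect falls out
  of the arithmetic: an inactivated gene duplicated on the rearranged X
  has expected methylated-allele fraction μ = f·2/3 + (1−f)·1/3, which
  at random XCI (f = 0.5) equals 0.5 — indistinguishable from a normal
  female.

## Worked example

```python
import escapex as ex
from escapex.pipeline import PipelineConfig, make_rearranged_patient, run_pipeline

model = ex.build_genome_model(seed=3)                       # 200 genes + 10 PAR1 genes
patient = make_rearranged_patient(model, "P1", skew=1.0)    # del + dup, 3 perturbed escape genes
summary = run_pipeline(PipelineConfig(seed=3, out_dir="run1", patients=[patient]))
print(summary["escape"], summary["patients"]["P1"]["by_type"])
```

prints (seed 3):

```
{'n_candidates': 26, 'n_concordant': 26, 'concordance_percent': 100.0}
{'escape_hyper': {'cn2': 3, 'total': 3},
 'inactive_hypo': {'cn0': 16, 'total': 16},
 'inactive_hyper': {'cn2': 44, 'total': 44}}
```

i.e. 26 escape candidates extracted from controls (all concordant with
the generator's annotation); in the fully skewed patient exactly the 3
perturbed escape genes are called hypermethylated — all on the
duplicated segment (`cn2`) — every hypomethylation call lies on the
deleted segment (`cn0`), and duplicated inactivated genes show the
expected hypermethylation. The same run reports the XCI assay (ratio
100%, skewed) and zero PAR1 abnormalities in the RRBS arm.

The same stages are available from the shell:

```bash
escapex run --seed 3 --out run1
escapex simulate --out sim --seed 4
escapex qc --beta sim/beta.tsv --probes sim/probes.tsv --samples sim/samples.tsv --qc sim/qc.tsv --out qc
escapex call-array --beta qc/beta_filtered.tsv --probes qc/probes_filtered.tsv \
    --samples qc/samples.tsv --genes sim/genes.bed --out calls
```

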