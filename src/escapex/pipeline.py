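"""End-to-end orchestration: simulate → QC → array calls → RRBS calls → XCI.

The pipeline runs either in simulation mode (a :class:`GenomeModel`,
control cohort, and patient specs are generated from one master seed) or
on files previously written by the simulator or an external pre-processing
step. Every stage writes its intermediate artifacts, and the summary
echoes every threshold used, so a run is reproducible from its output
directory alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from . import array_calls, qc, rrbs, synthetic, xci
from . import io as exio
from .model import (
    BetaMatrix,
    CohortSpec,
    ConfigurationError,
    CpGCountTable,
    GenomeModel,
    InputError,
    PatientSpec,
    PeakPair,
    SegmentSet,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat configuration: one named key per threshold, defaults as printed.

    Thresholds mirror the calling rules (β cutoffs, promoter window,
    minimum run/CpG counts, RRBS depth, drift-test alpha, XCI skew
    threshold); the cohort and patient sections drive simulation mode.
    """

    seed: int = 0
    out_dir: str = "escapex_out"

    # genome / cohort (simulation mode)
    n_genes: int = 200
    n_par1_genes: int = 10
    probes_per_promoter: tuple[int, int] = (2, 6)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    rrbs_cohort: CohortSpec | None = None  # defaults to 4M + 4F adults
    patients: list[PatientSpec] = field(default_factory=list)
    rrbs_mean_depth: float = 50.0
    peak_noise_sd: float = 0.05

    # thresholds
    window: int = 1000
    min_run: int = 2
    min_cpg: int = 2
    min_depth: int = 10
    alpha: float = 0.05
    drift_filter_enabled: bool = True
    skew_threshold: float = 80.0
    escape_mean_max: float = 0.15
    escape_all_max: float = 0.24
    sex_diff_max: float = 0.1
    inactive_male_mean_max: float = 0.15
    inactive_male_all_max: float = 0.25
    inactive_female_all_min: float = 0.25
    inactive_female_mean_max: float = 0.5
    call_hyper_escape_min: float = 0.25
    call_hypo_min: float = 0.15
    call_hyper_inactive_min: float = 0.5
    call_hyper_margin: float = 0.05
    rrbs_control_exclude_above: float = 0.24
    rrbs_hyper_min: float = 0.25

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ConfigurationError("window must be > 0")
        for name in (
            "escape_mean_max", "escape_all_max", "sex_diff_max",
            "inactive_male_mean_max", "inactive_male_all_max",
            "inactive_female_all_min", "inactive_female_mean_max",
            "call_hyper_escape_min", "call_hypo_min",
            "call_hyper_inactive_min", "call_hyper_margin",
            "rrbs_control_exclude_above", "rrbs_hyper_min", "alpha",
        ):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigurationError(f"{name}={v} outside (0, 1)")

    def thresholds(self) -> dict[str, Any]:
        skip = {"cohort", "rrbs_cohort", "patients", "out_dir"}
        return {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(self).items()
            if k not in skip
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        if "cohort" in raw and isinstance(raw["cohort"], dict):
            raw["cohort"] = CohortSpec(**raw["cohort"])
        if "rrbs_cohort" in raw and isinstance(raw["rrbs_cohort"], dict):
            raw["rrbs_cohort"] = CohortSpec(**raw["rrbs_cohort"])
        if "probes_per_promoter" in raw:
            raw["probes_per_promoter"] = tuple(raw["probes_per_promoter"])
        if "patients" in raw:
            raw["patients"] = [
                p if isinstance(p, PatientSpec) else _patient_from_dict(p)
                for p in raw["patients"]
            ]
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _patient_from_dict(d: dict[str, Any]) -> PatientSpec:
    return PatientSpec(
        patient_id=d["patient_id"],
        segments=SegmentSet(tuple(tuple(s) for s in d.get("segments", ()))),
        skew=float(d.get("skew", 1.0)),
        perturbed_genes=frozenset(d.get("perturbed_genes", ())),
    )


def default_rrbs_cohort() -> CohortSpec:
    """The RRBS arm's own control group: four adult males, four adult females."""
    return CohortSpec(n_adult_female=4, n_girl=0, n_adult_male=4, n_boy=0)


# ------------------------------------------------------------ study design


def segment_for_genes(
    model: GenomeModel, gene_ids: Sequence[str], copy_number: int
) -> tuple[int, int, int]:
    """Smallest segment covering the promoter windows of the given genes."""
    sel = model.genes[model.genes["gene_id"].isin(set(gene_ids))]
    if sel.empty:
        raise InputError("no such genes in model")
    start = int(sel["tss"].min()) - synthetic.PROMOTER_HALF_WIDTH
    end = int(sel["tss"].max()) + synthetic.PROMOTER_HALF_WIDTH + 1
    return (max(start, 0), end, copy_number)


def make_rearranged_patient(
    model: GenomeModel,
    patient_id: str = "P1",
    skew: float = 1.0,
    deletion_gene_range: tuple[float, float] = (0.10, 0.30),
    duplication_gene_range: tuple[float, float] = (0.45, 0.85),
    n_perturbed: int = 3,
) -> PatientSpec:
    """A patient with one deletion and one duplication on the rearranged X.

    Segment extents are given as fractions of the non-PAR gene list, so
    the same design scales with the genome model. ``n_perturbed`` escape
    or mostly-escape genes inside the duplication lose their escape
    status on the rearranged chromosome, emulating the rare
    complex-rearrangement phenotype.
    """
    nonpar = model.genes[~model.genes["par1"]].reset_index(drop=True)
    n = len(nonpar)

    def ids(frac: tuple[float, float]) -> list[str]:
        lo, hi = int(frac[0] * n), int(frac[1] * n)
        return nonpar["gene_id"].iloc[lo:hi].tolist()

    del_ids, dup_ids = ids(deletion_gene_range), ids(duplication_gene_range)
    if set(del_ids) & set(dup_ids):
        raise ConfigurationError("deletion and duplication ranges overlap")
    dup_escape = nonpar[
        nonpar["gene_id"].isin(dup_ids)
        & nonpar["category"].isin(["escape", "mostly_escape"])
    ]["gene_id"].tolist()
    if len(dup_escape) < n_perturbed:
        raise ConfigurationError(
            f"duplication contains only {len(dup_escape)} escape genes, "
            f"cannot perturb {n_perturbed}"
        )
    segments = SegmentSet(
        (
            segment_for_genes(model, del_ids, 0),
            segment_for_genes(model, dup_ids, 2),
        )
    )
    return PatientSpec(
        patient_id=patient_id,
        segments=segments,
        skew=skew,
        perturbed_genes=frozenset(dup_escape[:n_perturbed]),
    )


# ------------------------------------------------------------ report


def render_heatmap_table(
    matrix: BetaMatrix,
    gene_ids: Sequence[str],
    promoter_sets: Sequence[array_calls.PromoterProbeSet],
    patient_ids: Sequence[str],
    hyper_min: float = 0.25,
) -> pd.DataFrame:
    """Long-format (gene, probe, patient, β, over-threshold) table.

    One row per gene probe per patient with the β value and a strict
    β > 0.25 dichotomy flag — the gray/pink heatmap convention.
    """
    by_gene = {ps.gene_id: ps for ps in promoter_sets}
    present = set(matrix.values.index)
    rows = []
    for g in gene_ids:
        ps = by_gene.get(g)
        if ps is None:
            continue
        for pid in ps.probe_ids:
            if pid not in present:
                continue
            for patient in patient_ids:
                b = matrix.values.at[pid, patient]
                rows.append(
                    {
                        "gene_id": g,
                        "probe_id": pid,
                        "patient_id": patient,
                        "beta": float(b) if pd.notna(b) else float("nan"),
                        "hypermethylated": bool(pd.notna(b) and b > hyper_min),
                    }
                )
    return pd.DataFrame(
        rows, columns=["gene_id", "probe_id", "patient_id", "beta", "hypermethylated"]
    )


def _stratify_by_copy_number(
    calls: pd.DataFrame, model_genes: pd.DataFrame, patient: PatientSpec
) -> dict[str, dict[str, int]]:
    """Call counts per call type, split by the segment copy number at the gene."""
    tss = model_genes.set_index("gene_id")["tss"]
    out: dict[str, dict[str, int]] = {}
    for r in calls.itertuples(index=False):
        cn = patient.segments.copy_number_at(int(tss.loc[r.gene_id]))
        bucket = out.setdefault(r.call_type, {})
        key = f"cn{cn}"
        bucket[key] = bucket.get(key, 0) + 1
        bucket["total"] = bucket.get("total", 0) + 1
    return out


# ------------------------------------------------------------ pipeline


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the full simulated study and write all artifacts.

    Returns the report summary (also written as ``summary.json``):
    candidate counts and concordance against the generator's own
    annotation, per-patient calls stratified by copy number, PAR1 RRBS
    calls, and XCI classifications.
    """
    out = Path(config.out_dir)
    inputs_dir = out / "inputs"
    results_dir = out / "results"
    inputs_dir.mkdir(parents=True, exist_ok=True)
    results_dir.mkdir(parents=True, exist_ok=True)

    seed = config.seed
    model = synthetic.build_genome_model(
        n_genes=config.n_genes,
        probes_per_promoter_range=config.probes_per_promoter,
        seed=seed,
        n_par1_genes=config.n_par1_genes,
    )
    patients = list(config.patients)
    matrix = synthetic.simulate_beta_matrix(model, config.cohort, patients, seed=seed)
    qca = synthetic.simulate_qc_annotations(
        model, list(matrix.values.columns), seed=seed
    )
    rrbs_cohort = config.rrbs_cohort or default_rrbs_cohort()
    counts = synthetic.simulate_rrbs_counts(
        model, rrbs_cohort, patients, mean_depth=config.rrbs_mean_depth, seed=seed
    )
    peak_rows = []
    peaks_by_patient: dict[str, PeakPair] = {}
    for i, p in enumerate(patients):
        pp = synthetic.simulate_peak_heights(
            p.skew, informative=True, seed=seed + i, noise_sd=config.peak_noise_sd
        )
        peaks_by_patient[p.patient_id] = pp
        for allele in range(pp.n_alleles):
            peak_rows.append(
                {
                    "sample": p.patient_id,
                    "locus": "AR",
                    "allele": allele + 1,
                    "undigested": pp.undigested[allele],
                    "digested": pp.digested[allele],
                }
            )

    # ---- write simulated inputs
    exio.write_model_inputs(model, inputs_dir)
    exio.write_beta_matrix(
        matrix,
        inputs_dir / "beta.tsv",
        inputs_dir / "probes.tsv",
        inputs_dir / "samples.tsv",
    )
    exio.write_qc(qca, inputs_dir / "qc.tsv")
    exio.write_cpg_counts(
        counts, inputs_dir / "cpg_counts.tsv", inputs_dir / "rrbs_samples.tsv"
    )
    exio.write_peaks(peak_rows, inputs_dir / "peaks.tsv")
    for p in patients:
        exio.write_segments(p.segments, inputs_dir / f"segments_{p.patient_id}.bed")

    # ---- QC
    filtered, removal_log = qc.filter_probes(matrix, qca)
    logger.info("technical filter: %d -> %d probes", len(matrix.values), len(filtered.values))
    filtered, drift_removed = qc.drift_filter(
        filtered, alpha=config.alpha, enabled=config.drift_filter_enabled
    )
    logger.info("drift filter removed %d probes", len(drift_removed))
    removal_log.to_csv(results_dir / "probe_removal_log.tsv", sep="\t", index=False)
    pd.Series(drift_removed, name="probe_id").to_csv(
        results_dir / "drift_removed.tsv", sep="\t", index=False
    )
    exio.write_beta_matrix(
        filtered,
        results_dir / "beta_filtered.tsv",
        results_dir / "probes_filtered.tsv",
        results_dir / "samples.tsv",
    )

    # ---- array extraction and concordance
    annotation = model.gene_annotations()
    promoter_sets = array_calls.assign_promoter_probes(
        annotation, filtered.positions, window=config.window
    )
    esc = array_calls.extract_escape_candidates(
        filtered, promoter_sets,
        min_run=config.min_run,
        mean_max=config.escape_mean_max,
        all_controls_max=config.escape_all_max,
        sex_diff_max=config.sex_diff_max,
    )
    ina = array_calls.extract_inactivated_candidates(
        filtered, promoter_sets,
        min_run=config.min_run,
        male_mean_max=config.inactive_male_mean_max,
        male_all_max=config.inactive_male_all_max,
        female_all_min=config.inactive_female_all_min,
        female_mean_max=config.inactive_female_mean_max,
    )
    esc.to_csv(results_dir / "escape_candidates.tsv", sep="\t", index=False)
    ina.to_csv(results_dir / "inactivated_candidates.tsv", sep="\t", index=False)

    categories = {g.gene_id: g.category for g in annotation}
    esc_genes = array_calls.selected_genes(esc)
    ina_genes = array_calls.selected_genes(ina)
    esc_conc = array_calls.concordance(esc_genes, categories, ("escape", "mostly_escape"))
    ina_conc = array_calls.concordance(
        ina_genes, categories, ("inactive", "mostly_inactive")
    )

    # ---- patient calls
    patient_section: dict[str, Any] = {}
    all_calls = []
    for p in patients:
        calls = array_calls.call_patient_abnormalities(
            filtered, p.patient_id, esc_genes, ina_genes, promoter_sets,
            min_run=config.min_run,
            hyper_escape_min=config.call_hyper_escape_min,
            hypo_min=config.call_hypo_min,
            hyper_inactive_min=config.call_hyper_inactive_min,
            hyper_margin=config.call_hyper_margin,
        )
        frame = array_calls.calls_to_frame(calls)
        all_calls.append(frame)
        patient_section[p.patient_id] = {
            "n_calls": int(len(frame)),
            "by_type": _stratify_by_copy_number(frame, model.genes, p),
        }
    calls_frame = (
        pd.concat(all_calls, ignore_index=True)
        if all_calls
        else array_calls.calls_to_frame([])
    )
    calls_frame.to_csv(results_dir / "patient_calls.tsv", sep="\t", index=False)

    heat = render_heatmap_table(
        matrix, esc_genes, promoter_sets, [p.patient_id for p in patients],
        hyper_min=config.call_hyper_escape_min,
    )
    heat.to_csv(results_dir / "heatmap_long.tsv", sep="\t", index=False)

    # ---- RRBS arm
    counts_f, depth_removed = rrbs.depth_filter(counts, min_depth=config.min_depth)
    ratios = rrbs.methylation_ratio(counts_f)
    par1 = rrbs.extract_par1_escape(
        ratios, counts_f.samples, annotation,
        window=config.window,
        min_cpg=config.min_cpg,
        mean_max=config.escape_mean_max,
        control_exclude_above=config.rrbs_control_exclude_above,
    )
    par1.to_csv(results_dir / "par1_genes.tsv", sep="\t", index=False)
    rrbs_section: dict[str, Any] = {
        "n_cpgs_removed_by_depth": len(depth_removed),
        "n_par1_selected": int(par1["selected"].sum()),
        "calls": {},
    }
    rrbs_frames = []
    for p in patients:
        rcalls = rrbs.call_rrbs_abnormalities(
            ratios, p.patient_id, par1,
            min_cpg=config.min_cpg, hyper_min=config.rrbs_hyper_min,
        )
        rrbs_frames.append(rcalls)
        rrbs_section["calls"][p.patient_id] = int(len(rcalls))
    (
        pd.concat(rrbs_frames, ignore_index=True)
        if rrbs_frames
        else pd.DataFrame(columns=["patient_id", "gene_id", "call_type", "n_hyper_cpgs"])
    ).to_csv(results_dir / "rrbs_calls.tsv", sep="\t", index=False)

    # ---- XCI assay
    xci_section = {}
    for p in patients:
        res = xci.xci_ratio(peaks_by_patient[p.patient_id], config.skew_threshold)
        xci_section[p.patient_id] = {
            "ratio": res.ratio,
            "classification": res.classification,
        }

    summary: dict[str, Any] = {
        "thresholds": config.thresholds(),
        "n_probes_input": int(len(matrix.values)),
        "n_probes_after_qc": int(len(filtered.values)),
        "escape": {
            "n_candidates": esc_conc[0],
            "n_concordant": esc_conc[1],
            "concordance_percent": esc_conc[2],
        },
        "inactivated": {
            "n_candidates": ina_conc[0],
            "n_concordant": ina_conc[1],
            "concordance_percent": ina_conc[2],
        },
        "patients": patient_section,
        "rrbs": rrbs_section,
        "xci": xci_section,
    }
    with open(results_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    _summary_tsv(summary).to_csv(results_dir / "summary.tsv", sep="\t", index=False)
    return summary


def _summary_tsv(summary: dict[str, Any]) -> pd.DataFrame:
    rows = [
        {"metric": "n_probes_input", "value": summary["n_probes_input"]},
        {"metric": "n_probes_after_qc", "value": summary["n_probes_after_qc"]},
        {"metric": "escape_candidates", "value": summary["escape"]["n_candidates"]},
        {
            "metric": "escape_concordance_percent",
            "value": summary["escape"]["concordance_percent"],
        },
        {
            "metric": "inactivated_candidates",
            "value": summary["inactivated"]["n_candidates"],
        },
        {
            "metric": "inactivated_concordance_percent",
            "value": summary["inactivated"]["concordance_percent"],
        },
    ]
    for pid, sec in summary["patients"].items():
        rows.append({"metric": f"{pid}_n_calls", "value": sec["n_calls"]})
    for pid, n in summary["rrbs"]["calls"].items():
        rows.append({"metric": f"{pid}_rrbs_calls", "value": n})
    for pid, sec in summary["xci"].items():
        rows.append({"metric": f"{pid}_xci_ratio", "value": sec["ratio"]})
    return pd.DataFrame(rows)
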