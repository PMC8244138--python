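"""Plain-text readers/writers for every pipeline artifact.

All tables are tab-separated. Gene annotation travels as BED6+2 (extra
columns: XCI category and PAR1/nonPAR region tag), copy-number segments
as BED4, bisulfite counts in a methylKit-like wide layout with
coverage/numCs/numTs triplets per sample. Coordinates are 0-based
half-open; the TSS is written as a 1-bp interval.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    CHROM,
    BetaMatrix,
    CpGCountTable,
    GeneAnnotation,
    GenomeModel,
    InputError,
    QcAnnotations,
    SegmentSet,
)

# ---------------------------------------------------------------- genes


def write_gene_bed(genes: pd.DataFrame, path: str | Path) -> None:
    bed = pd.DataFrame(
        {
            "chrom": CHROM,
            "start": genes["tss"],
            "end": genes["tss"] + 1,
            "name": genes["gene_id"],
            "score": 0,
            "strand": genes["strand"],
            "category": genes["category"],
            "region": np.where(genes["par1"], "PAR1", "nonPAR"),
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_gene_bed(path: str | Path) -> list[GeneAnnotation]:
    cols = ["chrom", "start", "end", "name", "score", "strand", "category", "region"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols)
    return [
        GeneAnnotation(
            gene_id=str(r.name_),
            tss=int(r.start),
            strand=str(r.strand),
            category=str(r.category),
            par1=r.region == "PAR1",
        )
        for r in df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


# ---------------------------------------------------------------- array


def write_probe_manifest(probes: pd.DataFrame, path: str | Path) -> None:
    probes[["probe_id", "pos"]].to_csv(path, sep="\t", index=False)


def write_beta_matrix(matrix: BetaMatrix, beta_path: str | Path,
                      manifest_path: str | Path, samples_path: str | Path) -> None:
    matrix.values.to_csv(beta_path, sep="\t", index_label="probe_id")
    pd.DataFrame(
        {"probe_id": matrix.positions.index, "pos": matrix.positions.to_numpy()}
    ).to_csv(manifest_path, sep="\t", index=False)
    matrix.samples.to_csv(samples_path, sep="\t", index_label="sample_id")


def read_beta_matrix(beta_path: str | Path, manifest_path: str | Path,
                     samples_path: str | Path) -> BetaMatrix:
    values = pd.read_csv(beta_path, sep="\t", index_col="probe_id")
    manifest = pd.read_csv(manifest_path, sep="\t")
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
    missing = set(values.index) - set(manifest["probe_id"])
    if missing:
        raise InputError(f"probes missing from manifest: {sorted(missing)[:5]}")
    positions = (
        manifest.set_index("probe_id")["pos"].loc[values.index].astype(int)
    )
    order = positions.sort_values().index
    return BetaMatrix(
        values=values.loc[order], positions=positions.loc[order], samples=samples
    )


def write_qc(qc: QcAnnotations, path: str | Path) -> None:
    wide = pd.DataFrame({"snp_flag": qc.snp_flag.astype(int)})
    for s in qc.bead_counts.columns:
        wide[f"beads.{s}"] = qc.bead_counts[s]
    for s in qc.detection_p.columns:
        wide[f"detp.{s}"] = qc.detection_p[s]
    wide.to_csv(path, sep="\t", index_label="probe_id")


def read_qc(path: str | Path) -> QcAnnotations:
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    bead_cols = [c for c in df.columns if c.startswith("beads.")]
    detp_cols = [c for c in df.columns if c.startswith("detp.")]
    return QcAnnotations(
        bead_counts=df[bead_cols].rename(columns=lambda c: c[len("beads."):]),
        detection_p=df[detp_cols].rename(columns=lambda c: c[len("detp."):]),
        snp_flag=df["snp_flag"].astype(bool),
    )


# ---------------------------------------------------------------- RRBS


def write_cpg_counts(counts: CpGCountTable, counts_path: str | Path,
                     samples_path: str | Path | None = None) -> None:
    wide = pd.DataFrame(
        {"chrom": CHROM, "pos": counts.coverage.index, "strand": "+"}
    ).set_index("pos", drop=False)
    for s in counts.coverage.columns:
        wide[f"coverage.{s}"] = counts.coverage[s]
        wide[f"numCs.{s}"] = counts.methylated[s]
        wide[f"numTs.{s}"] = counts.coverage[s] - counts.methylated[s]
    wide.to_csv(counts_path, sep="\t", index=False)
    if samples_path is not None:
        counts.samples.to_csv(samples_path, sep="\t", index_label="sample_id")


def read_cpg_counts(counts_path: str | Path, samples_path: str | Path) -> CpGCountTable:
    df = pd.read_csv(counts_path, sep="\t")
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
    df = df.set_index("pos")
    sids = [c[len("coverage."):] for c in df.columns if c.startswith("coverage.")]
    coverage = pd.DataFrame({s: df[f"coverage.{s}"] for s in sids})
    methylated = pd.DataFrame({s: df[f"numCs.{s}"] for s in sids})
    return CpGCountTable(coverage=coverage, methylated=methylated, samples=samples)


# ---------------------------------------------------------------- segments / peaks


def write_segments(segments: SegmentSet, path: str | Path) -> None:
    segments.to_frame().to_csv(path, sep="\t", header=False, index=False)


def read_segments(path: str | Path) -> SegmentSet:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "copy_number"]
    )
    return SegmentSet(
        tuple(
            (int(r.start), int(r.end), int(r.copy_number))
            for r in df.itertuples(index=False)
        )
    )


def write_peaks(rows: Sequence[dict], path: str | Path) -> None:
    """Peak table rows: sample, locus, allele, undigested, digested."""
    pd.DataFrame(
        rows, columns=["sample", "locus", "allele", "undigested", "digested"]
    ).to_csv(path, sep="\t", index=False)


def read_peaks(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------- model bundle


def write_model_inputs(model: GenomeModel, out_dir: str | Path) -> dict[str, Path]:
    """Write the gene/probe universe of a genome model to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": out / "genes.bed",
        "probes": out / "probes.tsv",
    }
    write_gene_bed(model.genes, paths["genes"])
    write_probe_manifest(model.probes, paths["probes"])
    return paths
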