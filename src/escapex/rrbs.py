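"""CpG-level calling for pseudoautosomal (PAR1) genes from bisulfite counts.

PAR1 genes escape XCI in both sexes and are missing from the methylation
array, so their promoters are assayed by reduced-representation bisulfite
sequencing instead. The rules mirror the array procedure but operate on
per-CpG methylation ratios (C reads / total reads) and count qualifying
CpGs rather than requiring a consecutive run.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import ConfigurationError, CpGCountTable, GeneAnnotation

logger = logging.getLogger(__name__)

DEFAULT_MIN_DEPTH = 10
DEFAULT_MIN_CPG = 2


def depth_filter(
    counts: CpGCountTable, min_depth: int = DEFAULT_MIN_DEPTH
) -> tuple[CpGCountTable, list[int]]:
    """Drop CpGs with coverage below ``min_depth`` in one or more samples.

    The boundary is "less than": exactly ``min_depth`` reads everywhere is
    retained. Returns the filtered table and the removed positions.
    """
    cov = counts.coverage
    keep = (cov >= min_depth).all(axis=1)
    removed = cov.index[~keep].tolist()
    filtered = CpGCountTable(
        coverage=cov.loc[keep],
        methylated=counts.methylated.loc[keep],
        samples=counts.samples,
    )
    return filtered, removed


def methylation_ratio(counts: CpGCountTable) -> pd.DataFrame:
    """Per-CpG methylation ratio = methylated / total reads.

    Expects the depth filter already applied; any residual zero-coverage
    cell yields NaN rather than an error.
    """
    cov = counts.coverage.to_numpy(dtype=float)
    meth = counts.methylated.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(cov > 0, meth / cov, np.nan)
    return pd.DataFrame(r, index=counts.coverage.index, columns=counts.coverage.columns)


def _control_cols(samples: pd.DataFrame, sex: str) -> list[str]:
    mask = (samples["role"] == "control") & (samples["sex"] == sex)
    return samples.index[mask].tolist()


def extract_par1_escape(
    ratios: pd.DataFrame,
    samples: pd.DataFrame,
    annotation: Sequence[GeneAnnotation],
    window: int = 1000,
    min_cpg: int = DEFAULT_MIN_CPG,
    mean_max: float = 0.15,
    control_exclude_above: float = 0.24,
    sex_diff_band: tuple[float, float] = (-0.1, 0.1),
) -> pd.DataFrame:
    """Extract PAR1 genes with hypomethylated promoters in controls.

    CpGs within [tss − w, tss + w] of a PAR1 gene are first screened:
    any CpG where one or more controls has ratio > 0.24 is excluded.
    Remaining CpGs qualify when the control mean ratio is < 0.15 in both
    sexes and the sex difference (mean_F − mean_M) lies in the closed
    band [−0.1, 0.1]. A gene is selected when at least ``min_cpg`` CpGs
    qualify — a count, not a run. Genes with no surviving CpGs are
    ineligible. The returned table records the qualifying ("criterion")
    CpGs per gene; patient calls are evaluated on exactly those CpGs.
    """
    males = _control_cols(samples, "M")
    females = _control_cols(samples, "F")
    if len(males) < 2 or len(females) < 2:
        raise ConfigurationError("need >=2 controls per sex for PAR1 extraction")
    ctrl = males + females

    pos = ratios.index.to_numpy()
    mean_m = ratios[males].mean(axis=1).to_numpy()
    mean_f = ratios[females].mean(axis=1).to_numpy()
    ctrl_max = ratios[ctrl].max(axis=1).to_numpy()
    lo_band, hi_band = sex_diff_band

    keep_cpg = ctrl_max <= control_exclude_above  # "> 0.24" excluded, strict
    qualifies = (
        keep_cpg
        & (mean_m < mean_max)
        & (mean_f < mean_max)
        & ((mean_f - mean_m) >= lo_band)
        & ((mean_f - mean_m) <= hi_band)
    )

    rows = []
    for gene in annotation:
        if not gene.par1:
            continue
        in_window = (pos >= gene.tss - window) & (pos <= gene.tss + window)
        surviving = in_window & keep_cpg
        flagged = pos[in_window & qualifies]
        rows.append(
            {
                "gene_id": gene.gene_id,
                "n_cpgs": int(surviving.sum()),
                "eligible": bool(surviving.sum() > 0),
                "n_qualifying": int(len(flagged)),
                "selected": bool(len(flagged) >= min_cpg),
                "criterion_cpgs": ";".join(str(p) for p in flagged),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "n_cpgs", "eligible", "n_qualifying", "selected", "criterion_cpgs"],
    )


def call_rrbs_abnormalities(
    ratios: pd.DataFrame,
    patient_id: str,
    par1_genes: pd.DataFrame,
    min_cpg: int = DEFAULT_MIN_CPG,
    hyper_min: float = 0.25,
) -> pd.DataFrame:
    """Call abnormal PAR1 promoter hypermethylation in one patient.

    For each extracted gene, count the patient's criterion CpGs with
    methylation ratio > 0.25; a call is emitted when the count reaches
    ``min_cpg``. CpGs the patient is missing (depth-filtered) are not
    counted and are logged.
    """
    if patient_id not in ratios.columns:
        raise ConfigurationError(f"patient {patient_id!r} not in ratio table")
    rows = []
    for r in par1_genes.itertuples(index=False):
        if not r.selected:
            continue
        cpgs = [int(p) for p in r.criterion_cpgs.split(";") if p]
        n_hyper = 0
        for p in cpgs:
            if p not in ratios.index or pd.isna(ratios.at[p, patient_id]):
                logger.info("patient %s missing CpG %d (%s)", patient_id, p, r.gene_id)
                continue
            if ratios.at[p, patient_id] > hyper_min:
                n_hyper += 1
        if n_hyper >= min_cpg:
            rows.append(
                {
                    "patient_id": patient_id,
                    "gene_id": r.gene_id,
                    "call_type": "escape_hyper",
                    "n_hyper_cpgs": n_hyper,
                }
            )
    return pd.DataFrame(
        rows, columns=["patient_id", "gene_id", "call_type", "n_hyper_cpgs"]
    )
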