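"""Promoter-window calling of escape and inactivated genes from array β values.

The procedure works gene by gene on the QC-surviving probes within 1 kb
of the TSS, ordered by genomic position. Control criteria are evaluated
per probe, and a gene qualifies when at least ``min_run`` *consecutive*
promoter probes satisfy them (consecutive within the surviving promoter
probe set; a QC-removed probe does not break a run because it is absent
from the set). All threshold comparisons are strict, exactly as printed
in the field's rule set — note the deliberate 0.24 (escape, all controls)
vs 0.25 (inactivated, per-sex) asymmetry.

Escape-gene extraction (controls only):
    mean β < 0.15 in males AND in females, every control β < 0.24,
    and |mean_F − mean_M| < 0.1.
Inactivated-gene extraction (controls only):
    male mean β < 0.15, every male β < 0.25,
    every female β > 0.25, female mean β < 0.5.
Patient calls, restricted to previously extracted genes:
    escape_hyper   — patient β > 0.25 on a run;
    inactive_hypo  — patient β < 0.15 on a run;
    inactive_hyper — patient β > 0.5 AND β > max female-control β + 0.05.
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    BetaMatrix,
    ConfigurationError,
    GeneAnnotation,
    InputError,
    MethCall,
    PromoterProbeSet,
)

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 1000
DEFAULT_MIN_RUN = 2


def assign_promoter_probes(
    annotation: Sequence[GeneAnnotation],
    probe_positions: pd.Series,
    window: int = DEFAULT_WINDOW,
) -> list[PromoterProbeSet]:
    """Assign probes to each gene's promoter window [tss − w, tss + w].

    The window is closed on both ends and ignores strand (the TSS is a
    point). A probe may serve several genes when windows overlap; genes
    without probes are returned with empty sets.
    """
    if window <= 0:
        raise ConfigurationError("window must be > 0")
    pos = probe_positions.to_numpy()
    if len(pos) > 1 and not np.all(np.diff(pos) > 0):
        raise InputError("probe positions must be sorted ascending")
    ids = probe_positions.index.to_numpy()

    out = []
    for gene in annotation:
        lo = np.searchsorted(pos, gene.tss - window, side="left")
        hi = np.searchsorted(pos, gene.tss + window, side="right")
        out.append(
            PromoterProbeSet(
                gene_id=gene.gene_id,
                probe_ids=tuple(ids[lo:hi]),
                positions=tuple(int(p) for p in pos[lo:hi]),
            )
        )
    return out


def max_run(flags: Sequence[bool]) -> tuple[int, int | None]:
    """Longest run of consecutive True values and its start index.

    Returns ``(0, None)`` for empty input or no True; ties broken by the
    smallest start index.
    """
    best_len, best_start = 0, None
    cur_len, cur_start = 0, 0
    for i, f in enumerate(flags):
        if f:
            if cur_len == 0:
                cur_start = i
            cur_len += 1
            if cur_len > best_len:
                best_len, best_start = cur_len, cur_start
        else:
            cur_len = 0
    return best_len, best_start


def _control_stats(matrix: BetaMatrix) -> pd.DataFrame:
    """Per-probe control summaries used by both extraction rules."""
    males = matrix.control_columns(sex="M")
    females = matrix.control_columns(sex="F")
    if len(males) < 2 or len(females) < 2:
        raise ConfigurationError("need >=2 controls per sex for extraction")
    m = matrix.values[males]
    f = matrix.values[females]
    return pd.DataFrame(
        {
            "mean_m": m.mean(axis=1),
            "mean_f": f.mean(axis=1),
            "max_m": m.max(axis=1),
            "max_f": f.max(axis=1),
            "min_f": f.min(axis=1),
            "max_all": pd.concat([m, f], axis=1).max(axis=1),
            "n_missing": pd.concat([m, f], axis=1).isna().sum(axis=1),
        }
    )


def _extract(
    matrix: BetaMatrix,
    promoter_sets: Sequence[PromoterProbeSet],
    probe_flags: pd.Series,
    usable: pd.Series,
    min_run: int,
) -> pd.DataFrame:
    """Shared run-based gene selection over per-probe boolean flags.

    Probes with any missing control value are unusable: they cannot
    satisfy an "all controls" condition, so they count as un-flagged (and
    still occupy their slot in the run).
    """
    rows = []
    for ps in promoter_sets:
        pids = [p for p in ps.probe_ids if p in probe_flags.index]
        n = len(pids)
        if n < min_run:
            rows.append(
                {
                    "gene_id": ps.gene_id,
                    "n_probes": n,
                    "eligible": False,
                    "selected": False,
                    "run_length": 0,
                    "run_probes": "",
                }
            )
            continue
        flags = (probe_flags.loc[pids] & usable.loc[pids]).tolist()
        length, start = max_run(flags)
        selected = length >= min_run
        rows.append(
            {
                "gene_id": ps.gene_id,
                "n_probes": n,
                "eligible": True,
                "selected": selected,
                "run_length": length,
                "run_probes": ";".join(pids[start : start + length]) if selected else "",
            }
        )
    return pd.DataFrame(rows)


def extract_escape_candidates(
    matrix: BetaMatrix,
    promoter_sets: Sequence[PromoterProbeSet],
    min_run: int = DEFAULT_MIN_RUN,
    mean_max: float = 0.15,
    all_controls_max: float = 0.24,
    sex_diff_max: float = 0.1,
) -> pd.DataFrame:
    """Extract candidate escape genes from control hypomethylation.

    Per probe the criteria are: mean β < 0.15 in male *and* female
    controls, every control β < 0.24, and |mean_F − mean_M| < 0.1 — all
    strict. A gene is selected when ≥ ``min_run`` consecutive promoter
    probes qualify; genes with fewer surviving probes are ineligible
    (reported, never counted negative). Patient columns are ignored.
    """
    s = _control_stats(matrix)
    flags = (
        (s["mean_m"] < mean_max)
        & (s["mean_f"] < mean_max)
        & (s["max_all"] < all_controls_max)
        & ((s["mean_f"] - s["mean_m"]).abs() < sex_diff_max)
    )
    usable = s["n_missing"] == 0
    return _extract(matrix, promoter_sets, flags, usable, min_run)


def extract_inactivated_candidates(
    matrix: BetaMatrix,
    promoter_sets: Sequence[PromoterProbeSet],
    min_run: int = DEFAULT_MIN_RUN,
    male_mean_max: float = 0.15,
    male_all_max: float = 0.25,
    female_all_min: float = 0.25,
    female_mean_max: float = 0.5,
) -> pd.DataFrame:
    """Extract candidate inactivated (XCI-subject) genes.

    Per probe: hypomethylated in male controls (mean β < 0.15, all male
    β < 0.25) and not hypomethylated in female controls (all female
    β > 0.25, female mean β < 0.5). Run rule as for escape extraction.
    """
    s = _control_stats(matrix)
    flags = (
        (s["mean_m"] < male_mean_max)
        & (s["max_m"] < male_all_max)
        & (s["min_f"] > female_all_min)
        & (s["mean_f"] < female_mean_max)
    )
    usable = s["n_missing"] == 0
    return _extract(matrix, promoter_sets, flags, usable, min_run)


def selected_genes(candidates: pd.DataFrame) -> list[str]:
    """Gene ids marked selected in an extraction table."""
    return candidates.loc[candidates["selected"], "gene_id"].tolist()


def concordance(
    candidates: Iterable[str],
    annotation: Mapping[str, str],
    accepted_categories: Iterable[str],
) -> tuple[int, int, float | None]:
    """Compare a candidate gene list against a reference XCI annotation.

    Returns ``(n_candidates, n_concordant, percent)`` where percent is
    100·concordant/candidates rounded half-up to one decimal. Candidates
    absent from the annotation count as discordant (category "unknown").
    An empty candidate list yields percent ``None`` (not applicable).
    """
    accepted = set(accepted_categories)
    cand = list(candidates)
    n = len(cand)
    if n == 0:
        return 0, 0, None
    hits = sum(1 for g in cand if annotation.get(g, "unknown") in accepted)
    percent = float(
        (Decimal(100 * hits) / Decimal(n)).quantize(Decimal("0.1"), ROUND_HALF_UP)
    )
    return n, hits, percent


def call_patient_abnormalities(
    matrix: BetaMatrix,
    patient_id: str,
    escape_genes: Sequence[str],
    inactivated_genes: Sequence[str],
    promoter_sets: Sequence[PromoterProbeSet],
    min_run: int = DEFAULT_MIN_RUN,
    hyper_escape_min: float = 0.25,
    hypo_min: float = 0.15,
    hyper_inactive_min: float = 0.5,
    hyper_margin: float = 0.05,
) -> list[MethCall]:
    """Call abnormal promoter methylation in one patient.

    For extracted escape genes, probes with patient β > 0.25 are flagged
    (escape_hyper). For extracted inactivated genes, β < 0.15 flags
    hypomethylation and β > 0.5 together with β > (max female-control β
    at the probe + 0.05) flags hypermethylation. A call is emitted when
    ≥ ``min_run`` consecutive flagged probes exist; at most one call per
    gene per call type (the longest run, earliest on ties). Missing
    patient β counts as un-flagged and is logged.
    """
    if patient_id not in matrix.values.columns:
        raise InputError(f"patient {patient_id!r} not in matrix")
    females = matrix.control_columns(sex="F")
    if not females:
        raise ConfigurationError("no female controls for hypermethylation margin")
    max_f = matrix.values[females].max(axis=1)
    beta = matrix.values[patient_id]

    sets_by_gene = {ps.gene_id: ps for ps in promoter_sets}
    present = set(matrix.values.index)
    calls: list[MethCall] = []

    def emit(gene_id: str, call_type: str, flag_fn) -> None:
        ps = sets_by_gene.get(gene_id)
        if ps is None:
            return
        pids = [p for p in ps.probe_ids if p in present]
        flags = []
        for p in pids:
            b = beta.loc[p]
            if pd.isna(b):
                logger.info("patient %s missing beta at %s (%s)", patient_id, p, gene_id)
                flags.append(False)
            else:
                flags.append(bool(flag_fn(p, float(b))))
        length, start = max_run(flags)
        if length >= min_run:
            calls.append(
                MethCall(
                    patient_id=patient_id,
                    gene_id=gene_id,
                    call_type=call_type,
                    supporting_probes=tuple(pids[start : start + length]),
                    run_length=length,
                )
            )

    for g in escape_genes:
        emit(g, "escape_hyper", lambda p, b: b > hyper_escape_min)
    for g in inactivated_genes:
        emit(g, "inactive_hypo", lambda p, b: b < hypo_min)
        emit(
            g,
            "inactive_hyper",
            lambda p, b: b > hyper_inactive_min and b > max_f.loc[p] + hyper_margin,
        )
    return calls


def calls_to_frame(calls: Sequence[MethCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": c.patient_id,
                "gene_id": c.gene_id,
                "call_type": c.call_type,
                "run_length": c.run_length,
                "supporting_probes": ";".join(c.supporting_probes),
            }
            for c in calls
        ],
        columns=["patient_id", "gene_id", "call_type", "run_length", "supporting_probes"],
    )
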