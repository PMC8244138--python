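"""Probe-level quality control of the methylation array.

Two filters applied before any calling:

* technical filter — drop probes overlapping a SNP, with fewer than three
  beads in any sample, or with a detection P value above 0.01 in any
  sample (this inspects only QC metadata, never β values);
* age-drift filter — drop probes whose β differs between adult and child
  controls (Welch t per sex, Benjamini–Hochberg adjusted across probes,
  removed if adjusted P < alpha in either sex). Keeping only age-stable
  probes lets adult and child controls pool into one reference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import BetaMatrix, ConfigurationError, InputError, QcAnnotations

MIN_BEADS = 3
DETECTION_P_MAX = 0.01


def filter_probes(
    matrix: BetaMatrix, qc: QcAnnotations
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Apply the technical probe filter; return (filtered matrix, removal log).

    A probe is dropped if it is SNP-flagged, or if in *any* sample its
    bead count is < 3 or its detection P value is > 0.01 (both boundaries
    strict as stated: exactly 3 beads or P = 0.01 pass). The removal log
    has one row per dropped probe with a semicolon-joined reason string.
    """
    probe_ids = matrix.values.index
    if not qc.covers(probe_ids):
        missing = set(probe_ids) - set(qc.bead_counts.index)
        missing |= set(probe_ids) - set(qc.detection_p.index)
        missing |= set(probe_ids) - set(qc.snp_flag.index)
        raise InputError(f"probes absent from QC annotations: {sorted(missing)[:5]}")

    cols = list(matrix.values.columns)
    beads = qc.bead_counts.loc[probe_ids, cols]
    detp = qc.detection_p.loc[probe_ids, cols]
    snp = qc.snp_flag.loc[probe_ids].astype(bool)

    low_beads = (beads < MIN_BEADS).any(axis=1)
    high_detp = (detp > DETECTION_P_MAX).any(axis=1)
    drop = snp | low_beads | high_detp

    reasons = []
    for pid in probe_ids[drop]:
        r = []
        if snp.loc[pid]:
            r.append("snp")
        if low_beads.loc[pid]:
            r.append("low_beads")
        if high_detp.loc[pid]:
            r.append("high_detection_p")
        reasons.append({"probe_id": pid, "reason": ";".join(r)})
    log = pd.DataFrame(reasons, columns=["probe_id", "reason"])

    keep = probe_ids[~drop]
    filtered = BetaMatrix(
        values=matrix.values.loc[keep],
        positions=matrix.positions.loc[keep],
        samples=matrix.samples,
    )
    return filtered, log


def _welch_p(adult: np.ndarray, child: np.ndarray) -> np.ndarray:
    """Row-wise Welch t P values; degenerate rows (zero variance both
    groups, e.g. identical values) yield P = 1 so they are never removed."""
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(adult, child, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    return np.where(np.isfinite(p), p, 1.0)


def drift_filter(
    matrix: BetaMatrix,
    alpha: float = 0.05,
    enabled: bool = True,
) -> tuple[BetaMatrix, list[str]]:
    """Remove probes with age-related methylation drift among controls.

    For each sex with ≥2 adult and ≥2 child controls, a Welch two-sample
    t-test compares adult vs child β per probe; P values are BH-adjusted
    across probes within the sex, and a probe is removed if adjusted
    P < ``alpha`` in either sex. Patients are never inspected. Raises
    ``ConfigurationError`` if no sex has enough controls, unless the
    filter is explicitly disabled.
    """
    if not enabled:
        return matrix, []
    if not 0 < alpha < 1:
        raise ConfigurationError(f"alpha={alpha} outside (0, 1)")

    removed = np.zeros(len(matrix.values), dtype=bool)
    any_sex_tested = False
    for sex in ("M", "F"):
        adults = matrix.control_columns(sex=sex, age_group="adult")
        children = matrix.control_columns(sex=sex, age_group="child")
        if len(adults) < 2 or len(children) < 2:
            continue
        any_sex_tested = True
        p = _welch_p(
            matrix.values[adults].to_numpy(float),
            matrix.values[children].to_numpy(float),
        )
        reject, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
        removed |= reject
    if not any_sex_tested:
        raise ConfigurationError(
            "drift_filter needs >=2 adult and >=2 child controls in at least "
            "one sex (pass enabled=False to skip explicitly)"
        )

    removed_ids = matrix.values.index[removed].tolist()
    keep = matrix.values.index[~removed]
    filtered = BetaMatrix(
        values=matrix.values.loc[keep],
        positions=matrix.positions.loc[keep],
        samples=matrix.samples,
    )
    return filtered, removed_ids
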