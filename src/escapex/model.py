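"""Core data containers for the escape-gene methylation pipeline.

The pipeline works on a single linear pseudo-chromosome ("chrX") with
0-based, half-open coordinates throughout. Gene categories follow the
field's consensus vocabulary: a gene either *escapes* X-chromosome
inactivation (its promoter on the inactive X stays unmethylated), is
*inactive* (subject to XCI; one methylated allele of two in females), or
is *variable* (escape status differs between individuals). ``mostly_*``
categories denote majority-vote consensus calls in reference annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GENE_CATEGORIES = (
    "escape",
    "mostly_escape",
    "variable",
    "inactive",
    "mostly_inactive",
)

ESCAPE_LIKE = frozenset({"escape", "mostly_escape"})
INACTIVE_LIKE = frozenset({"inactive", "mostly_inactive"})

CHROM = "chrX"


class EscapexError(Exception):
    """Base class for pipeline errors."""


class InputError(EscapexError):
    """Malformed or inconsistent input data (CLI exit code 2)."""


class ConfigurationError(EscapexError):
    """Invalid configuration or parameters (CLI exit code 3)."""


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene: TSS position, strand, XCI-status category, PAR1 flag."""

    gene_id: str
    tss: int
    strand: str
    category: str
    par1: bool = False

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise InputError(f"{self.gene_id}: negative TSS")
        if self.strand not in ("+", "-"):
            raise InputError(f"{self.gene_id}: strand must be + or -")
        if self.category not in GENE_CATEGORIES + ("unknown",):
            raise InputError(f"{self.gene_id}: unknown category {self.category!r}")


@dataclass(frozen=True)
class SegmentSet:
    """Copy-number segments of a rearranged X chromosome.

    Each segment is ``(start, end, copy_number)`` in 0-based half-open
    coordinates; ``copy_number`` counts how many copies of the interval the
    rearranged X carries (0 deletion, 1 neutral, 2 duplication,
    3 triplication). Positions outside all segments have copy number 1.
    """

    segments: tuple[tuple[int, int, int], ...] = ()

    def __post_init__(self) -> None:
        prev_end = None
        for start, end, cn in sorted(self.segments):
            if start >= end:
                raise InputError(f"segment ({start}, {end}): start must be < end")
            if cn not in (0, 1, 2, 3):
                raise InputError(f"segment copy number {cn} outside {{0,1,2,3}}")
            if prev_end is not None and start < prev_end:
                raise InputError("segments overlap")
            prev_end = end
        object.__setattr__(self, "segments", tuple(sorted(self.segments)))

    def copy_number_at(self, pos: int) -> int:
        for start, end, cn in self.segments:
            if start <= pos < end:
                return cn
        return 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.segments), columns=["start", "end", "copy_number"]
        ).assign(chrom=CHROM)[["chrom", "start", "end", "copy_number"]]


@dataclass(frozen=True)
class PatientSpec:
    """A simulated patient with an X rearrangement.

    ``skew`` is the fraction of cells in which the rearranged X is the
    inactive one; random XCI is 0.5, complete skew toward the abnormal X
    is 1.0 (the common case, since structurally abnormal X chromosomes are
    preferentially inactivated). ``perturbed_genes`` lose their escape
    status on the rearranged chromosome only — the mechanism hypothesised
    for the hypermethylated escape genes seen under complex rearrangement.
    """

    patient_id: str
    segments: SegmentSet = field(default_factory=SegmentSet)
    skew: float = 1.0
    perturbed_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not 0.5 <= self.skew <= 1.0:
            raise ConfigurationError(
                f"{self.patient_id}: skew {self.skew} outside [0.5, 1.0]"
            )
        object.__setattr__(self, "perturbed_genes", frozenset(self.perturbed_genes))


@dataclass(frozen=True)
class CohortSpec:
    """Control-cohort structure and noise model for the simulator.

    Defaults mirror a blood methylation study design: 4 adult females +
    7 girls and 4 adult males + 8 boys. ``kappa`` is the Beta-distribution
    concentration (a+b) of per-probe noise; ``mu_low`` the baseline β of an
    unmethylated promoter; ``meth_level`` the β of a fully methylated
    allele (array saturation < 1 from incomplete bisulfite conversion and
    probe chemistry). ``drift_probe_fraction`` of probes shift by
    ``drift_shift`` in adults only, emulating age-related drift.
    """

    n_adult_female: int = 4
    n_girl: int = 7
    n_adult_male: int = 4
    n_boy: int = 8
    kappa: float = 200.0
    mu_low: float = 0.05
    meth_level: float = 0.9
    drift_probe_fraction: float = 0.05
    drift_shift: float = 0.3

    def __post_init__(self) -> None:
        for name in ("n_adult_female", "n_girl", "n_adult_male", "n_boy"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.kappa <= 1:
            raise ConfigurationError("kappa must be > 1")
        if not 0 <= self.drift_probe_fraction <= 1:
            raise ConfigurationError("drift_probe_fraction must be in [0, 1]")
        if not 0 < self.mu_low < self.meth_level <= 1:
            raise ConfigurationError("need 0 < mu_low < meth_level <= 1")

    @property
    def n_female(self) -> int:
        return self.n_adult_female + self.n_girl

    @property
    def n_male(self) -> int:
        return self.n_adult_male + self.n_boy


@dataclass
class GenomeModel:
    """Gene/probe/CpG universe on the pseudo X chromosome.

    ``genes``: DataFrame with columns gene_id, tss, strand, category, par1.
    ``probes``: DataFrame with columns probe_id, pos (array probes; PAR1
    genes carry none, matching the array's lack of PAR1 coverage).
    ``cpgs``: positions of bisulfite-sequencing CpGs, restricted to PAR1
    promoters. ``par1_boundary``: first base beyond PAR1.
    """

    genes: pd.DataFrame
    probes: pd.DataFrame
    cpgs: np.ndarray
    par1_boundary: int
    chrom_length: int

    def __post_init__(self) -> None:
        pos = self.probes["pos"].to_numpy()
        if len(pos) > 1 and not np.all(np.diff(pos) > 0):
            raise InputError("probe positions must be strictly increasing")
        if len(self.cpgs) > 1 and not np.all(np.diff(self.cpgs) > 0):
            raise InputError("CpG positions must be strictly increasing")

    def gene_annotations(self) -> list[GeneAnnotation]:
        return [
            GeneAnnotation(r.gene_id, int(r.tss), r.strand, r.category, bool(r.par1))
            for r in self.genes.itertuples(index=False)
        ]


@dataclass
class BetaMatrix:
    """Array β values (probes × samples) with probe positions and a sample sheet.

    ``values``: DataFrame indexed by probe_id, one column per sample, β in
    [0, 1] or NaN. ``positions``: Series probe_id → bp, sorted ascending.
    ``samples``: DataFrame indexed by sample_id with columns sex (M/F),
    age_group (adult/child), role (control/patient), batch.
    """

    values: pd.DataFrame
    positions: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.positions.index):
            raise InputError("values index and positions index differ")
        if not self.samples.index.is_unique:
            raise InputError("duplicate sample ids")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise InputError(f"samples absent from sample sheet: {sorted(missing)}")
        pos = self.positions.to_numpy()
        if len(pos) > 1 and not np.all(np.diff(pos) > 0):
            raise InputError("probe positions must be sorted ascending")
        vals = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=1.0) > 1:
                raise InputError("beta values outside [0, 1]")

    def control_columns(self, sex: str | None = None, age_group: str | None = None) -> list[str]:
        mask = self.samples["role"] == "control"
        if sex is not None:
            mask &= self.samples["sex"] == sex
        if age_group is not None:
            mask &= self.samples["age_group"] == age_group
        return [s for s in self.values.columns if s in self.samples.index[mask]]

    def subset_probes(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        keep = [p for p in self.values.index if p in set(probe_ids)]
        return BetaMatrix(
            values=self.values.loc[keep],
            positions=self.positions.loc[keep],
            samples=self.samples,
        )


@dataclass
class QcAnnotations:
    """Per-probe QC metadata of the methylation array.

    ``bead_counts`` and ``detection_p``: DataFrames (probe × sample).
    ``snp_flag``: boolean Series per probe (probe overlaps a SNP).
    """

    bead_counts: pd.DataFrame
    detection_p: pd.DataFrame
    snp_flag: pd.Series

    def covers(self, probe_ids: Iterable[str]) -> bool:
        ids = set(probe_ids)
        return (
            ids <= set(self.bead_counts.index)
            and ids <= set(self.detection_p.index)
            and ids <= set(self.snp_flag.index)
        )


@dataclass
class CpGCountTable:
    """Bisulfite-sequencing read counts per CpG per sample.

    ``coverage`` and ``methylated``: DataFrames indexed by CpG position
    (bp), one column per sample; methylated ≤ coverage elementwise.
    """

    coverage: pd.DataFrame
    methylated: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.coverage.index.equals(self.methylated.index):
            raise InputError("coverage and methylated indexes differ")
        if list(self.coverage.columns) != list(self.methylated.columns):
            raise InputError("coverage and methylated columns differ")
        if (self.methylated.to_numpy() > self.coverage.to_numpy()).any():
            raise InputError("methylated count exceeds coverage")


@dataclass(frozen=True)
class PromoterProbeSet:
    """Probes falling in one gene's promoter window, ordered by position."""

    gene_id: str
    probe_ids: tuple[str, ...]
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.positions) > 1 and not all(
            a < b for a, b in zip(self.positions, self.positions[1:])
        ):
            raise InputError(f"{self.gene_id}: promoter probes not position-sorted")

    def __len__(self) -> int:
        return len(self.probe_ids)


CALL_TYPES = ("escape_hyper", "inactive_hypo", "inactive_hyper")


@dataclass(frozen=True)
class MethCall:
    """One gene-level abnormal-methylation call in one patient."""

    patient_id: str
    gene_id: str
    call_type: str
    supporting_probes: tuple[str, ...]
    run_length: int

    def __post_init__(self) -> None:
        if self.call_type not in CALL_TYPES:
            raise InputError(f"unknown call type {self.call_type!r}")
        if self.run_length != len(self.supporting_probes):
            raise InputError("run_length must equal number of supporting probes")


@dataclass(frozen=True)
class PeakPair:
    """Fluorescence peak heights of one microsatellite locus in one sample.

    Heterozygous samples have two alleles, each with a peak height from the
    undigested and the HpaII-digested PCR; homozygous (uninformative)
    samples emit a single peak.
    """

    undigested: tuple[float, ...]
    digested: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.undigested) <= 2 or len(self.undigested) != len(self.digested):
            raise InputError("PeakPair needs 1 or 2 alleles with matching heights")
        if any(u <= 0 for u in self.undigested):
            raise InputError("undigested heights must be > 0")
        if any(d < 0 for d in self.digested):
            raise InputError("digested heights must be >= 0")

    @property
    def n_alleles(self) -> int:
        return len(self.undigested)


@dataclass(frozen=True)
class XciResult:
    """XCI skew ratio (percent, [50, 100]) and its classification."""

    ratio: float | None
    classification: str  # skewed | random | uninformative | not_applicable
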