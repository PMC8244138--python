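"""Mechanistic synthetic cohort: XCI mosaicism × gene class × copy number.

The generative model treats bulk blood as a mixture of exactly two cell
populations: cells in which the rearranged X is inactive (weight ``f``,
the XCI skew fraction) and cells in which the normal X is inactive
(weight ``1 − f``). A promoter allele is methylated iff it lies on the
inactive chromosome of its cell *and* the gene is subject to inactivation
there; escape-gene alleles are never methylated. The expected methylated
allele fraction μ is therefore a ratio of small integers — e.g. an
inactive gene on a duplicated segment (2 copies on the rearranged X) in a
fully skewed patient gives μ = 2/3, while at random XCI (f = 0.5) the
duplication averages out to μ = 0.5·(2/3) + 0.5·(1/3) = 0.5 and is
indistinguishable from a normal female: the masking effect.

Array β values map the allele fraction through the assay response
β_mean = μ_low + (meth_level − μ_low)·μ (unmethylated baseline μ_low,
saturating below 1 because bisulfite conversion and probe chemistry never
read a methylated allele as exactly β = 1), then add Beta-distributed
noise with concentration κ. Bisulfite-sequencing counts are binomial in
the same per-CpG methylation probability at Poisson coverage.
"""

from __future__ import annotations

import zlib
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    CHROM,
    GENE_CATEGORIES,
    BetaMatrix,
    CohortSpec,
    ConfigurationError,
    CpGCountTable,
    GenomeModel,
    PatientSpec,
    PeakPair,
    QcAnnotations,
)

GENE_SPACING = 4_000  # bp between TSSs; keeps ±1 kb promoter windows disjoint
PROMOTER_HALF_WIDTH = 1_000


def derive_rng(seed: int, label: str) -> np.random.Generator:
    """Independent, reproducible substream for one named operation."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])
    )


def _largest_remainder_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Deterministic apportionment of n items to categories (largest remainder)."""
    cats = list(proportions)
    exact = np.array([proportions[c] * n for c in cats])
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    short = n - counts.sum()
    # Ties broken by category order, matching the stable argsort.
    for i in np.argsort(-remainder, kind="stable")[:short]:
        counts[i] += 1
    return dict(zip(cats, counts.tolist()))


def build_genome_model(
    n_genes: int = 200,
    class_proportions: dict[str, float] | None = None,
    probes_per_promoter_range: tuple[int, int] = (2, 6),
    seed: int = 0,
    n_par1_genes: int = 10,
    cpgs_per_promoter_range: tuple[int, int] = (4, 8),
) -> GenomeModel:
    """Lay out genes, array probes, and PAR1 CpGs on a pseudo X chromosome.

    ``n_genes`` non-pseudoautosomal genes get categories apportioned
    deterministically from ``class_proportions`` (largest-remainder
    rounding) and shuffled along the chromosome; each carries a uniform
    number of probes in ``probes_per_promoter_range`` placed uniformly in
    [TSS − 1 kb, TSS + 1 kb]. ``n_par1_genes`` pseudoautosomal genes sit
    before ``par1_boundary``; they all escape XCI, carry no array probes
    (the array has none there) and instead get sequencing CpGs.
    """
    if n_genes < 1:
        raise ConfigurationError("n_genes must be >= 1")
    if class_proportions is None:
        # ~15% escape-like, 20-30% variable, remainder subject to XCI.
        class_proportions = {
            "escape": 0.10,
            "mostly_escape": 0.05,
            "variable": 0.25,
            "inactive": 0.45,
            "mostly_inactive": 0.15,
        }
    unknown = set(class_proportions) - set(GENE_CATEGORIES)
    if unknown:
        raise ConfigurationError(f"unknown gene categories: {sorted(unknown)}")
    if abs(sum(class_proportions.values()) - 1.0) > 1e-9:
        raise ConfigurationError("class proportions must sum to 1")
    lo, hi = probes_per_promoter_range
    if not 0 <= lo <= hi:
        raise ConfigurationError("invalid probes_per_promoter_range")

    rng = derive_rng(seed, "genome")
    par1_boundary = n_par1_genes * GENE_SPACING

    counts = _largest_remainder_counts(n_genes, class_proportions)
    categories = np.array(
        [c for c in class_proportions for _ in range(counts[c])], dtype=object
    )
    rng.shuffle(categories)

    rows = []
    for j in range(n_par1_genes):
        rows.append(
            {
                "gene_id": f"PAR1G{j + 1:03d}",
                "tss": GENE_SPACING // 2 + j * GENE_SPACING,
                "strand": "+" if rng.random() < 0.5 else "-",
                "category": "escape",
                "par1": True,
            }
        )
    for i in range(n_genes):
        rows.append(
            {
                "gene_id": f"XG{i + 1:04d}",
                "tss": par1_boundary + GENE_SPACING // 2 + i * GENE_SPACING,
                "strand": "+" if rng.random() < 0.5 else "-",
                "category": categories[i],
                "par1": False,
            }
        )
    genes = pd.DataFrame(rows)

    probe_pos: list[int] = []
    for r in genes.itertuples(index=False):
        if r.par1:
            continue
        k = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
        offs = rng.choice(2 * PROMOTER_HALF_WIDTH + 1, size=k, replace=False)
        probe_pos.extend(int(r.tss) - PROMOTER_HALF_WIDTH + np.sort(offs))
    probe_pos.sort()
    probes = pd.DataFrame(
        {"probe_id": [f"cg{i:06d}" for i in range(len(probe_pos))], "pos": probe_pos}
    )

    cpg_pos: list[int] = []
    clo, chi = cpgs_per_promoter_range
    for r in genes[genes["par1"]].itertuples(index=False):
        k = int(rng.integers(clo, chi + 1))
        offs = rng.choice(2 * PROMOTER_HALF_WIDTH + 1, size=k, replace=False)
        cpg_pos.extend(int(r.tss) - PROMOTER_HALF_WIDTH + np.sort(offs))
    cpg_pos.sort()

    chrom_length = par1_boundary + (n_genes + 1) * GENE_SPACING
    return GenomeModel(
        genes=genes,
        probes=probes,
        cpgs=np.asarray(cpg_pos, dtype=int),
        par1_boundary=par1_boundary,
        chrom_length=chrom_length,
    )


def expected_methylation(
    category: str,
    sex: str,
    *,
    copy_number: int = 1,
    skew: float = 1.0,
    perturbed: bool = False,
    variable_escapes: bool | None = None,
) -> float:
    """Expected methylated-allele fraction μ for one gene in one sample.

    ``copy_number`` is the gene's copy count on the rearranged X (1 for
    controls and unrearranged regions), ``skew`` the fraction of cells
    with the rearranged X inactive. ``perturbed`` switches an escape gene
    to inactive behaviour on the rearranged chromosome only. For variable
    genes the per-individual escape status must be resolved by the caller
    (``variable_escapes``).

    Returns a ratio of two integers ≤ 4: μ = [f·c·I(inactive on
    rearranged) + (1 − f)·I(inactive on normal)] / (1 + c).
    """
    if sex == "M":
        return 0.0  # single X, always active: no promoter methylation
    if category == "variable":
        if variable_escapes is None:
            raise ConfigurationError("variable gene needs a resolved escape status")
        category = "escape" if variable_escapes else "inactive"
    escape_like = category in ("escape", "mostly_escape")
    inactive_on_normal = not escape_like
    inactive_on_rearranged = (not escape_like) or perturbed
    c = int(copy_number)
    f = float(skew)
    methylated = f * c * inactive_on_rearranged + (1.0 - f) * inactive_on_normal
    return methylated / (1 + c)


def beta_mean(mu: float, cohort: CohortSpec) -> float:
    """Map an allele fraction to the array's expected β (clamped to (0, 1))."""
    m = cohort.mu_low + (cohort.meth_level - cohort.mu_low) * mu
    return float(np.clip(m, 0.01, 0.99))


def _sample_sheet(cohort: CohortSpec, patients: Sequence[PatientSpec]) -> pd.DataFrame:
    rows = []
    groups = [
        ("F", "adult", cohort.n_adult_female, "AF"),
        ("F", "child", cohort.n_girl, "GC"),
        ("M", "adult", cohort.n_adult_male, "AM"),
        ("M", "child", cohort.n_boy, "BC"),
    ]
    batch = 0
    for sex, age, n, tag in groups:
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{tag}{i + 1:02d}",
                    "sex": sex,
                    "age_group": age,
                    "role": "control",
                    "batch": f"b{batch % 2 + 1}",
                }
            )
            batch += 1
    for p in patients:
        rows.append(
            {
                "sample_id": p.patient_id,
                "sex": "F",
                "age_group": "child",
                "role": "patient",
                "batch": "b1",
            }
        )
    sheet = pd.DataFrame(rows).set_index("sample_id")
    if not sheet.index.is_unique:
        raise ConfigurationError("duplicate sample ids (patient id clashes a control)")
    return sheet


def _gene_mu_for_sample(
    model: GenomeModel,
    sample_id: str,
    sex: str,
    patient: PatientSpec | None,
    seed: int,
) -> np.ndarray:
    """Per-gene μ for one sample; variable genes re-drawn per individual."""
    genes = model.genes
    rng_var = derive_rng(seed, f"variable:{sample_id}")
    # One Bernoulli(0.5) escape status per variable gene per individual,
    # drawn in gene order for reproducibility.
    var_draws = rng_var.random(len(genes)) < 0.5
    mu = np.empty(len(genes))
    for i, r in enumerate(genes.itertuples(index=False)):
        if patient is None:
            cn, f, perturbed = 1, 1.0, False
        else:
            cn = patient.segments.copy_number_at(int(r.tss))
            f = patient.skew
            perturbed = r.gene_id in patient.perturbed_genes
        mu[i] = expected_methylation(
            r.category,
            sex,
            copy_number=cn,
            skew=f,
            perturbed=perturbed,
            variable_escapes=bool(var_draws[i]) if r.category == "variable" else None,
        )
    return mu


def simulate_beta_matrix(
    model: GenomeModel,
    cohort: CohortSpec,
    patients: Sequence[PatientSpec] = (),
    seed: int = 0,
) -> BetaMatrix:
    """Draw the probes × samples β matrix with a complete sample sheet.

    Each β ~ Beta(mean·κ, (1 − mean)·κ) where the mean comes from the
    allele-fraction model; a fixed random subset of probes
    (``drift_probe_fraction``) additionally shifts by ``drift_shift`` in
    adults only. Each sample uses its own seed substream, so adding or
    removing patients never changes control draws.
    """
    if cohort.kappa <= 1:
        raise ConfigurationError("kappa must be > 1")
    sheet = _sample_sheet(cohort, patients)
    by_id = {p.patient_id: p for p in patients}

    probes = model.probes
    probe_pos = probes["pos"].to_numpy()
    gene_tss = model.genes["tss"].to_numpy()
    # Probes lie in disjoint promoter windows, so nearest TSS identifies the gene.
    gene_idx = np.abs(probe_pos[:, None] - gene_tss[None, :]).argmin(axis=1)

    rng_drift = derive_rng(seed, "drift-probes")
    n_drift = int(round(cohort.drift_probe_fraction * len(probes)))
    drift_mask = np.zeros(len(probes), dtype=bool)
    if n_drift:
        drift_mask[rng_drift.choice(len(probes), size=n_drift, replace=False)] = True

    columns = {}
    for sample_id, row in sheet.iterrows():
        mu = _gene_mu_for_sample(
            model, sample_id, row["sex"], by_id.get(sample_id), seed
        )
        means = np.array([beta_mean(m, cohort) for m in mu])[gene_idx]
        if row["age_group"] == "adult":
            means = np.where(
                drift_mask, np.clip(means + cohort.drift_shift, 0.01, 0.99), means
            )
        rng = derive_rng(seed, f"beta:{sample_id}")
        a = means * cohort.kappa
        b = (1.0 - means) * cohort.kappa
        columns[sample_id] = rng.beta(a, b)

    values = pd.DataFrame(columns, index=probes["probe_id"])
    positions = pd.Series(
        probe_pos, index=probes["probe_id"], name="pos", dtype=int
    )
    return BetaMatrix(values=values, positions=positions, samples=sheet)


def drift_probe_ids(model: GenomeModel, cohort: CohortSpec, seed: int) -> list[str]:
    """Ground-truth ids of the age-drift probes for a given seed."""
    rng = derive_rng(seed, "drift-probes")
    n_drift = int(round(cohort.drift_probe_fraction * len(model.probes)))
    if not n_drift:
        return []
    idx = rng.choice(len(model.probes), size=n_drift, replace=False)
    return model.probes["probe_id"].iloc[np.sort(idx)].tolist()


def simulate_qc_annotations(
    model: GenomeModel,
    sample_ids: Sequence[str],
    seed: int = 0,
    snp_fraction: float = 0.02,
    bead_mean: float = 15.0,
    fail_detection_fraction: float = 0.01,
) -> QcAnnotations:
    """Emulate array QC metadata: bead counts, detection P values, SNP flags."""
    rng = derive_rng(seed, "qc")
    probe_ids = model.probes["probe_id"]
    n, m = len(probe_ids), len(sample_ids)
    beads = rng.poisson(bead_mean, size=(n, m))
    detp = rng.uniform(0.0, 0.005, size=(n, m))
    bad = rng.random((n, m)) < fail_detection_fraction
    detp = np.where(bad, rng.uniform(0.02, 0.5, size=(n, m)), detp)
    snp = pd.Series(rng.random(n) < snp_fraction, index=probe_ids, name="snp_flag")
    return QcAnnotations(
        bead_counts=pd.DataFrame(beads, index=probe_ids, columns=list(sample_ids)),
        detection_p=pd.DataFrame(detp, index=probe_ids, columns=list(sample_ids)),
        snp_flag=snp,
    )


def simulate_rrbs_counts(
    model: GenomeModel,
    cohort: CohortSpec,
    patients: Sequence[PatientSpec] = (),
    mean_depth: float = 50.0,
    seed: int = 0,
) -> CpGCountTable:
    """Binomial methylated counts at Poisson coverage for PAR1 CpGs.

    PAR1 genes escape XCI in both sexes, so unperturbed CpGs sit at the
    unmethylated baseline μ_low; rearrangements and perturbations act
    through the same allele-fraction model as the array.
    """
    if mean_depth < 1:
        raise ConfigurationError("mean_depth must be >= 1")
    sheet = _sample_sheet(cohort, patients)
    by_id = {p.patient_id: p for p in patients}

    cpg_pos = model.cpgs
    par1_genes = model.genes[model.genes["par1"]].reset_index(drop=True)
    tss = par1_genes["tss"].to_numpy()
    gene_idx = np.abs(cpg_pos[:, None] - tss[None, :]).argmin(axis=1)

    cov_cols, meth_cols = {}, {}
    for sample_id, row in sheet.iterrows():
        patient = by_id.get(sample_id)
        mu = np.empty(len(par1_genes))
        for i, r in enumerate(par1_genes.itertuples(index=False)):
            if patient is None:
                cn, f, perturbed = 1, 1.0, False
            else:
                cn = patient.segments.copy_number_at(int(r.tss))
                f = patient.skew
                perturbed = r.gene_id in patient.perturbed_genes
            mu[i] = expected_methylation(
                r.category, row["sex"], copy_number=cn, skew=f, perturbed=perturbed
            )
        p = np.clip(
            cohort.mu_low + (cohort.meth_level - cohort.mu_low) * mu, 0.01, 0.99
        )[gene_idx]
        rng = derive_rng(seed, f"rrbs:{sample_id}")
        total = rng.poisson(mean_depth, size=len(cpg_pos))
        meth = rng.binomial(total, p)
        cov_cols[sample_id] = total
        meth_cols[sample_id] = meth

    index = pd.Index(cpg_pos, name="pos")
    return CpGCountTable(
        coverage=pd.DataFrame(cov_cols, index=index),
        methylated=pd.DataFrame(meth_cols, index=index),
        samples=sheet,
    )


def simulate_peak_heights(
    f: float,
    informative: bool = True,
    seed: int = 0,
    noise_sd: float = 0.0,
    base_height: float = 1000.0,
) -> PeakPair:
    """Microsatellite peak heights for the HpaII skew assay.

    Allele 1 is the allele on the rearranged X. Undigested PCR amplifies
    both alleles equally; HpaII destroys unmethylated (active-X) copies,
    so the digested height of an allele is proportional to the fraction of
    cells in which that allele's chromosome is inactive (f and 1 − f).
    Multiplicative lognormal noise with σ = ``noise_sd``; 0 is noise-free.
    A homozygous (single-peak) sample is emitted with ``informative=False``.
    """
    if not 0.5 <= f <= 1.0:
        raise ConfigurationError(f"skew f={f} outside [0.5, 1.0]")
    rng = derive_rng(seed, "peaks")

    def noisy(x: float) -> float:
        return float(x * np.exp(rng.normal(0.0, noise_sd))) if noise_sd > 0 else float(x)

    if not informative:
        return PeakPair(
            undigested=(noisy(base_height),),
            # Both alleles co-migrate: digested peak pools all inactive copies.
            digested=(noisy(base_height),),
        )
    return PeakPair(
        undigested=(noisy(base_height), noisy(base_height)),
        digested=(noisy(base_height * f), noisy(base_height * (1.0 - f))),
    )
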