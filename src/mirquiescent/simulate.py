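"""Synthetic cohorts, genomes and target catalogs with known ground truth.

The cohort generator emulates the study design the analysis assumes: a
321-miRNA Q-PCR panel with a U6 reference row, 10 healthy controls (right and
left colon), 8 UC and 8 CD patients with paired quiescent/inflamed biopsies,
detection censoring near CT 35, and patient-to-patient dispersion calibrated
so the population of per-miRNA SDs of 10×log10 relative expression has mean
≈ 6.3 and SD ≈ 1.4.

Model
-----
CT(miRNA i, sample s) = CT_U6(s) + baseline_i + noise(i, s) − effect(i, s)/q,
with q = 10·log10(2) cycles per log-fold unit.  Patient noise is *uniform*
on the cycle scale: the sample SD of n = 8 normal draws is itself so variable
(SD ≈ 0.26·σ) that a normal-noise design cannot reach an SD-of-SDs as low as
1.4 at a mean of 6.3; a bounded noise law (SD of the n = 8 sample SD
≈ 0.19·σ) can.  Per-miRNA dispersions are drawn from a moment-matched gamma.
Controls carry only small technical noise — the dispersion statistic is
defined across disease patients, and controls act as the reference baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .containers import (
    DISEASE_CONDITIONS,
    LOG_FOLD_PER_CYCLE,
    CtMatrix,
    LocusSet,
    MirGeneAnnotation,
    SampleTable,
    TargetCatalog,
)
from .errors import ConfigError

# Sample-SD moment constants E[S]/σ and SD(S)/σ for n=8 uniform draws,
# obtained by moment matching (2e6 replicates).  They calibrate the gamma
# over per-miRNA dispersions so the *measured* pooled SD statistics land on
# the configured targets.
_SD_MEAN_FACTOR = 0.9816
_SD_SD_FACTOR = 0.1910

MAX_CT = 40.0  # beyond this the reaction is recorded as "no amplification"


@dataclass(frozen=True)
class PlantedEffect:
    """A true expression shift for one miRNA in one disease × state condition."""

    mirna_index: int
    condition: str
    log_fold: float  # 10×log10 units; positive = over-expression


@dataclass
class CohortConfig:
    n_mirnas: int = 321
    n_controls: int = 10
    n_uc: int = 8
    n_cd: int = 8
    paired_states: bool = True
    reference_id: str = "U6"
    reference_ct_mean: float = 20.0
    reference_ct_sd: float = 0.25
    baseline_delta_ct_range: tuple[float, float] = (2.0, 12.0)
    #: targets for the pooled per-miRNA SD population, 10×log10 units
    dispersion_mean: float = 6.3
    dispersion_sd: float = 1.4
    control_noise_sd: float = 1.0  # technical noise of control samples, log units
    #: fraction of the panel whose baseline sits beyond the detection limit
    detection_tail_fraction: float = 0.4
    tail_delta_ct_range: tuple[float, float] = (17.5, 21.0)
    #: None → plant the default disease pattern; [] → no effects
    planted_up: list[PlantedEffect] | None = None
    planted_down: list[PlantedEffect] | None = None
    #: quiescent effects carry over to the inflamed state (plus optional shift)
    inflamed_carryover: bool = True
    inflamed_extra_log_fold: float = 0.0
    #: magnitude range the default plant draws from (observed alterations
    #: span roughly 7–20 on the 10×log10 scale)
    default_effect_range: tuple[float, float] = (9.0, 18.0)
    #: miRNA index groups whose patient-level variation is shared (coordinated
    #: regulation); None → the default plant's common set forms one block
    coregulated_blocks: list[tuple[int, ...]] | None = None
    #: fraction of a block member's noise *variance* from the shared component
    coregulation_share: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_mirnas, self.n_controls, self.n_uc, self.n_cd) < 1:
            raise ConfigError("all cohort counts must be >= 1")
        if self.dispersion_mean < 0 or self.dispersion_sd < 0:
            raise ConfigError("dispersion targets must be non-negative")
        if not 0 <= self.detection_tail_fraction < 1:
            raise ConfigError("detection_tail_fraction must be in [0, 1)")
        for eff in (self.planted_up or []) + (self.planted_down or []):
            if not 0 <= eff.mirna_index < self.n_mirnas:
                raise ConfigError(
                    f"planted effect references miRNA index {eff.mirna_index} "
                    f"outside the {self.n_mirnas}-miRNA panel"
                )
            if eff.condition not in DISEASE_CONDITIONS:
                raise ConfigError(f"unknown planted condition {eff.condition!r}")
        for eff in self.planted_up or []:
            if eff.log_fold <= 0:
                raise ConfigError("planted_up effects must have positive log_fold")
        for eff in self.planted_down or []:
            if eff.log_fold >= 0:
                raise ConfigError("planted_down effects must have negative log_fold")
        if not 0.0 <= self.coregulation_share <= 1.0:
            raise ConfigError("coregulation_share must be in [0, 1]")
        for block in self.coregulated_blocks or []:
            for i in block:
                if not 0 <= i < self.n_mirnas:
                    raise ConfigError(
                        f"co-regulated block references miRNA index {i} outside the panel"
                    )

    def mirna_ids(self) -> list[str]:
        width = len(str(self.n_mirnas))
        return [f"mir-{i + 1:0{width}d}" for i in range(self.n_mirnas)]

    def n_tail(self) -> int:
        return int(round(self.detection_tail_fraction * self.n_mirnas))


@dataclass
class Truth:
    """Ground truth accompanying a synthetic cohort."""

    effects: dict[tuple[str, str], float]  # (mirna_id, condition) → log_fold
    sample_class: dict[str, str]  # sample_id → control | UC | CD
    sigma_log_fold: dict[str, float]  # per-miRNA true dispersion, log units
    undetectable: set[str]  # tail miRNAs placed beyond the detection limit
    baseline_delta_ct: dict[str, float]
    coregulated: list[tuple[str, ...]] = dc_field(default_factory=list)

    def direction(self, mirna_id: str, condition: str) -> str:
        eff = self.effects.get((mirna_id, condition), 0.0)
        if eff > 0:
            return "up"
        return "down" if eff < 0 else "unchanged"


def _default_plant(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[list[PlantedEffect], list[PlantedEffect], tuple[int, ...]]:
    """The study-scale default pattern: 8 miRNAs up in both diseases (one
    coordinated block sharing a single magnitude), 6 down in UC only, 15 up
    in CD only (quiescent; carryover covers inflamed)."""
    usable = config.n_mirnas - config.n_tail()
    n_common, n_uc_down, n_cd_only = 8, 6, 15
    need = n_common + n_uc_down + n_cd_only
    if usable < need:  # tiny panels: scale the pattern down proportionally
        n_common = max(1, usable // 4)
        n_uc_down = max(0, usable // 8)
        n_cd_only = max(0, usable // 4)
        need = n_common + n_uc_down + n_cd_only
    lo, hi = config.default_effect_range
    mag = lambda: float(rng.uniform(lo, hi))
    up, down = [], []
    idx = iter(range(need))
    common = []
    m_common = mag()  # coordinated regulation: one shift for the whole block
    for _ in range(n_common):
        i = next(idx)
        common.append(i)
        up.append(PlantedEffect(i, "UC_quiescent", m_common))
        up.append(PlantedEffect(i, "CD_quiescent", m_common))
    for _ in range(n_uc_down):
        i = next(idx)
        down.append(PlantedEffect(i, "UC_quiescent", -mag()))
    for _ in range(n_cd_only):
        i = next(idx)
        up.append(PlantedEffect(i, "CD_quiescent", mag()))
    return up, down, tuple(common)


def _build_samples(config: CohortConfig, rng: np.random.Generator) -> SampleTable:
    rows = []
    for i in range(config.n_controls):
        rows.append(
            {
                "sample_id": f"CTRL_{i + 1:02d}",
                "subject_id": f"CTRL_{i + 1:02d}",
                "group": "control",
                "state": "right_colon" if i % 2 == 0 else "left_colon",
                "grade": int(rng.integers(0, 2)),
            }
        )
    for group, count in (("UC", config.n_uc), ("CD", config.n_cd)):
        for i in range(count):
            subject = f"{group}_{i + 1:02d}"
            rows.append(
                {
                    "sample_id": f"{subject}_Q",
                    "subject_id": subject,
                    "group": group,
                    "state": "quiescent",
                    "grade": int(rng.integers(0, 2)),
                }
            )
            if config.paired_states:
                rows.append(
                    {
                        "sample_id": f"{subject}_I",
                        "subject_id": subject,
                        "group": group,
                        "state": "inflamed",
                        "grade": int(rng.integers(2, 5)),
                    }
                )
    frame = pd.DataFrame(rows).set_index("sample_id")
    return SampleTable(frame)


def _draw_sigmas(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-miRNA dispersions (log units) from a gamma matched so the pooled
    n=8 sample-SD population hits (dispersion_mean, dispersion_sd)."""
    if config.dispersion_mean == 0:
        return np.zeros(config.n_mirnas)
    m_g = config.dispersion_mean / _SD_MEAN_FACTOR
    var_between = (
        config.dispersion_sd**2 - (_SD_SD_FACTOR * m_g) ** 2
    ) / (_SD_MEAN_FACTOR**2 + _SD_SD_FACTOR**2)
    s_g = float(np.sqrt(max(var_between, 1e-12)))
    shape = (m_g / s_g) ** 2
    scale = s_g**2 / m_g
    return rng.gamma(shape, scale, size=config.n_mirnas)


def generate_cohort(
    config: CohortConfig | None = None,
) -> tuple[CtMatrix, SampleTable, Truth]:
    """Generate (CT matrix, sample metadata, ground truth), reproducible by seed."""
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples = _build_samples(config, rng)
    mirna_ids = config.mirna_ids()
    n_tail = config.n_tail()

    planted_up, planted_down = config.planted_up, config.planted_down
    blocks = config.coregulated_blocks
    if planted_up is None and planted_down is None:
        planted_up, planted_down, common = _default_plant(config, rng)
        if blocks is None and len(common) >= 2:
            blocks = [common]
    blocks = blocks or []
    planted = list(planted_up or []) + list(planted_down or [])
    for eff in planted:
        if mirna_ids[eff.mirna_index] == config.reference_id:
            raise ConfigError("cannot plant an effect on the reference RNA")

    # effects per (mirna, condition), with quiescent → inflamed carryover
    effects: dict[tuple[str, str], float] = {}
    for eff in planted:
        key = (mirna_ids[eff.mirna_index], eff.condition)
        effects[key] = effects.get(key, 0.0) + eff.log_fold
    if config.inflamed_carryover:
        for (mid, cond), lf in list(effects.items()):
            if cond.endswith("_quiescent"):
                icond = cond.replace("_quiescent", "_inflamed")
                extra = np.sign(lf) * config.inflamed_extra_log_fold
                effects[(mid, icond)] = effects.get((mid, icond), 0.0) + lf + extra

    sample_ids = samples.sample_ids
    n_samples = len(sample_ids)
    ref_ct = rng.normal(config.reference_ct_mean, config.reference_ct_sd, n_samples)

    baseline = rng.uniform(*config.baseline_delta_ct_range, size=config.n_mirnas)
    if n_tail:
        baseline[config.n_mirnas - n_tail :] = rng.uniform(
            *config.tail_delta_ct_range, size=n_tail
        )
    sigma = _draw_sigmas(config, rng)

    group = samples.frame["group"].to_numpy()
    state = samples.frame["state"].to_numpy()
    is_control = group == "control"
    condition_of = np.array(
        ["" if c else f"{g}_{s}" for c, g, s in zip(is_control, group, state)]
    )

    half_width = np.sqrt(3.0) * sigma  # uniform noise: SD σ ⇒ support ±√3σ
    noise_log = rng.uniform(-1.0, 1.0, size=(config.n_mirnas, n_samples)) * half_width[:, None]
    # co-regulated blocks: members mix a shared unit-SD patient profile into
    # their noise, keeping each member's total SD at σ_i
    share = config.coregulation_share
    for block in blocks:
        shared = rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), size=n_samples)
        for i in block:
            noise_log[i] = sigma[i] * (
                np.sqrt(share) * shared
                + np.sqrt(1.0 - share) * noise_log[i] / np.where(sigma[i] > 0, sigma[i], 1.0)
            )
    noise_log[:, is_control] = rng.normal(
        0.0, config.control_noise_sd, size=(config.n_mirnas, int(is_control.sum()))
    )

    effect_log = np.zeros((config.n_mirnas, n_samples))
    for (mid, cond), lf in effects.items():
        i = mirna_ids.index(mid)
        effect_log[i, condition_of == cond] += lf

    ct = (
        ref_ct[None, :]
        + baseline[:, None]
        + (noise_log - effect_log) / LOG_FOLD_PER_CYCLE
    )
    ct = np.where(ct > MAX_CT, np.nan, ct)

    values = pd.DataFrame(ct, index=mirna_ids, columns=sample_ids)
    values.loc[config.reference_id] = ref_ct
    matrix = CtMatrix(values, reference_id=config.reference_id)

    truth = Truth(
        effects=effects,
        sample_class={s: g for s, g in zip(sample_ids, group)},
        sigma_log_fold=dict(zip(mirna_ids, sigma)),
        undetectable=set(mirna_ids[config.n_mirnas - n_tail :]) if n_tail else set(),
        baseline_delta_ct=dict(zip(mirna_ids, baseline)),
        coregulated=[tuple(mirna_ids[i] for i in b) for b in blocks],
    )
    return matrix, samples, truth


# ---------------------------------------------------------------------------
# Genome annotation and susceptibility loci
# ---------------------------------------------------------------------------

@dataclass
class AnnotationConfig:
    mirna_ids: list[str] | None = None  # default: a fresh 321-miRNA panel
    n_singletons: int = 20
    n_duplexes: int = 2
    n_clusters: int = 1
    cluster_size: int = 3
    n_chromosomes: int = 5
    chromosome_length: int = 50_000_000
    gene_length: int = 100
    gene_spacing: int = 1_000_000
    n_loci: int = 4
    locus_length: int = 2_000_000
    n_genes_in_loci: int = 3  # singleton genes placed inside loci
    seed: int = 0

    def validate(self) -> None:
        if self.n_clusters and self.cluster_size < 3:
            raise ConfigError("clusters need >= 3 genes per band")
        if self.n_genes_in_loci > self.n_singletons:
            raise ConfigError("n_genes_in_loci exceeds the singleton count")


@dataclass
class AnnotationTruth:
    duplex_bands: list[tuple[str, str, list[str]]]  # (chrom, band, gene_ids)
    cluster_bands: list[tuple[str, str, list[str]]]
    genes_in_loci: set[str]
    genome_sizes: dict[str, int]


def generate_annotation(
    config: AnnotationConfig | None = None,
) -> tuple[list[MirGeneAnnotation], LocusSet, AnnotationTruth]:
    """Emit an annotation with planted duplexes/clusters and loci overlapping
    a known subset of genes."""
    config = config or AnnotationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    mirna_ids = config.mirna_ids or CohortConfig().mirna_ids()
    n_genes = (
        config.n_singletons
        + 2 * config.n_duplexes
        + config.cluster_size * config.n_clusters
    )
    if n_genes > len(mirna_ids):
        raise ConfigError(
            f"annotation needs {n_genes} miRNAs, panel has {len(mirna_ids)}"
        )
    genome_sizes = {
        f"chr{i + 1}": config.chromosome_length for i in range(config.n_chromosomes)
    }
    capacity = config.n_chromosomes * (config.chromosome_length // config.gene_spacing)
    if n_genes > capacity:
        raise ConfigError(
            f"{n_genes} genes exceed genome capacity of {capacity} placements"
        )

    chroms = sorted(genome_sizes)
    loci_rows = []
    for j in range(config.n_loci):
        chrom = chroms[j % len(chroms)]
        start = 1 + (j // len(chroms)) * (config.locus_length + config.gene_spacing)
        loci_rows.append(
            {
                "locus_id": f"IBD-{j + 1}",
                "chromosome": chrom,
                "start": start,
                "end": start + config.locus_length - 1,
                "source": "linkage" if j % 2 == 0 else "GWAS",
            }
        )
    loci = LocusSet(
        pd.DataFrame(
            loci_rows, columns=["locus_id", "chromosome", "start", "end", "source"]
        ).set_index("locus_id")
    )

    annotation: list[MirGeneAnnotation] = []
    truth = AnnotationTruth(
        duplex_bands=[], cluster_bands=[], genes_in_loci=set(),
        genome_sizes=genome_sizes,
    )
    mirna_iter = iter(mirna_ids)
    # lay genes on a spacing grid, skipping locus territory unless planted there
    cursor = {
        c: config.n_loci * (config.locus_length + config.gene_spacing) + 1
        for c in chroms
    }

    def place(chrom: str) -> int:
        pos = cursor[chrom]
        cursor[chrom] += config.gene_spacing
        if cursor[chrom] > config.chromosome_length:
            raise ConfigError("genome capacity exhausted during placement")
        return pos

    band_serial = {c: 11 for c in chroms}

    def next_band(chrom: str) -> str:
        band_serial[chrom] += 1
        return f"{chrom.removeprefix('chr')}q{band_serial[chrom]}.{int(rng.integers(1, 4))}"

    def add_gene(chrom: str, start: int, band: str, suffix: str = "") -> MirGeneAnnotation:
        mid = next(mirna_iter)
        rec = MirGeneAnnotation(
            gene_id=mid + suffix,
            mirna_id=mid,
            chromosome=chrom,
            start=start,
            end=start + config.gene_length - 1,
            strand="+" if rng.integers(0, 2) else "-",
            band=band,
        )
        annotation.append(rec)
        return rec

    for d in range(config.n_duplexes):
        chrom = chroms[d % len(chroms)]
        band = next_band(chrom)
        base = place(chrom)
        genes = [add_gene(chrom, base + j * (config.gene_length + 50), band) for j in range(2)]
        truth.duplex_bands.append((chrom, band, [g.gene_id for g in genes]))
    for k in range(config.n_clusters):
        chrom = chroms[(config.n_duplexes + k) % len(chroms)]
        band = next_band(chrom)
        base = place(chrom)
        genes = [
            add_gene(chrom, base + j * (config.gene_length + 50), band)
            for j in range(config.cluster_size)
        ]
        truth.cluster_bands.append((chrom, band, [g.gene_id for g in genes]))
    for s in range(config.n_singletons):
        if s < config.n_genes_in_loci and config.n_loci:
            row = loci.frame.iloc[s % config.n_loci]
            chrom = row["chromosome"]
            start = int(row["start"]) + 500 + (s // config.n_loci) * config.gene_spacing // 10
            rec = add_gene(chrom, start, next_band(chrom))
            truth.genes_in_loci.add(rec.gene_id)
        else:
            chrom = chroms[s % len(chroms)]
            add_gene(chrom, place(chrom), next_band(chrom))
    return annotation, loci, truth


# ---------------------------------------------------------------------------
# Target catalog and gene → process table
# ---------------------------------------------------------------------------

@dataclass
class TargetConfig:
    mirna_ids: list[str] | None = None
    n_genes: int = 200
    interactions_per_gene: int = 3
    processes: tuple[str, ...] = (
        "proliferation",
        "apoptosis",
        "autophagy",
        "ecm_adhesion",
        "immunity",
    )
    #: genes targeted exclusively by the designated up-regulated subset
    n_strict_genes: int = 5
    up_mirnas: list[str] | None = None  # default: first 8 panel miRNAs
    seed: int = 0

    def validate(self) -> None:
        if self.n_strict_genes > self.n_genes:
            raise ConfigError("n_strict_genes exceeds n_genes")
        if self.interactions_per_gene < 1:
            raise ConfigError("interactions_per_gene must be >= 1")


@dataclass
class TargetTruth:
    strict_genes: set[str]
    up_mirnas: list[str]


def generate_target_catalog(
    config: TargetConfig | None = None,
) -> tuple[TargetCatalog, pd.DataFrame, TargetTruth]:
    """Catalog where a known gene subset is targeted only by the up-set."""
    config = config or TargetConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    mirna_ids = config.mirna_ids or CohortConfig().mirna_ids()
    up = config.up_mirnas or mirna_ids[:8]
    others = [m for m in mirna_ids if m not in set(up)]
    if not others:
        raise ConfigError("no non-up miRNAs available for non-strict genes")
    genes = [f"GENE{i + 1:04d}" for i in range(config.n_genes)]
    strict = set(genes[: config.n_strict_genes])
    rows = []
    for g in genes:
        kk = config.interactions_per_gene
        if g in strict:
            partners = list(rng.choice(up, size=min(kk, len(up)), replace=False))
        else:
            # at least one non-up partner vetoes strictness
            partners = [others[int(rng.integers(len(others)))]]
            pool = [m for m in mirna_ids if m != partners[0]]
            extra = min(kk - 1, len(pool))
            if extra > 0:
                partners += list(rng.choice(pool, size=extra, replace=False))
        for m in partners:
            rows.append(
                {"mirna_id": m, "gene_id": g, "score": float(rng.uniform(-25.0, -5.0))}
            )
    catalog = TargetCatalog(pd.DataFrame(rows, columns=["mirna_id", "gene_id", "score"]))
    proc_rows = []
    for g in genes:
        k = int(rng.integers(1, 3))
        for p in rng.choice(config.processes, size=k, replace=False):
            proc_rows.append({"gene_id": g, "process": str(p)})
    process_table = pd.DataFrame(proc_rows, columns=["gene_id", "process"])
    return catalog, process_table, TargetTruth(strict_genes=strict, up_mirnas=list(up))
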