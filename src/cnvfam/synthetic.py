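"""Synthetic family-cohort generator.

Emulates a hypertension-ascertained sibship study genotyped on a SNP array
and called by two CNV callers: ~192 sibships (~444 siblings), a fasting
plasma glucose-like quantitative trait with age/sex/BMI/ethnicity/site
covariate structure and a family random effect, one common focal deletion
region (carrier frequency ~5.2%) with a depressive trait effect transmitted
within families, background common deletion/duplication regions with no
trait effect, abundant rare background CNVs, and two caller call-sets that
agree on detection but disagree on boundaries by a probe or two.

The probe map is a regular grid (default 1 kb spacing) over one probed
window per chromosome; it is a miniature of a genome-wide array, sized so
that rare background CNVs stay individually rare (<5%) while keeping a
full pipeline run cheap. Every latent assignment is recorded in the truth
record, sufficient for confusion tables at any downstream step.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .qc import SampleQcMetrics
from .types import (
    CallSource,
    CnvCall,
    CnvState,
    Family,
    PhenotypeRecord,
    SnpLocus,
    normalize_chrom,
)

_SITE_LABELS = ("siteA", "siteB", "siteC", "siteD", "siteE")


@dataclass
class SyntheticCohortSpec:
    """All parameters of the simulated study.

    Marginal trait/covariate parameters default to the study sample's
    summary characteristics (FPG 91.36 +/- 16.93 mg/dl, age 48.27 +/- 8.46,
    45.59% male, BMI 25.33 +/- 3.42, 96.38% Chinese, five recruiting
    sites); rare-CNV rates default to the observed per-sample means (36.69
    deletions, 14.15 duplications). ``family_random_sd`` defaults to a
    sibling intraclass correlation of ~0.26 (half the reported FPG
    heritability of ~0.52). The focal deletion region defaults to
    chr3:53,003,415-53,013,826 at carrier frequency 5.2% with a -4.3 mg/dl
    effect.
    """

    n_families: int = 192
    sibship_sizes: tuple[int, ...] = (1, 2, 3, 4)
    sibship_size_probs: tuple[float, ...] = (0.19, 0.44, 0.23, 0.14)
    trait_mean: float = 91.36
    trait_sd: float = 16.93
    age_mean: float = 48.27
    age_sd: float = 8.46
    male_prop: float = 0.4559
    bmi_mean: float = 25.33
    bmi_sd: float = 3.42
    ethnicity_prop_chinese: float = 0.9638
    site_probs: tuple[float, ...] = (0.1332, 0.1467, 0.3679, 0.3476, 0.0046)
    hypertension_prop: float = 0.60
    # covariate effects on the trait (mg/dl per unit)
    beta_age: float = 0.2
    beta_sex_male: float = 1.5
    beta_bmi: float = 0.5
    beta_ethnicity_japanese: float = 1.0
    beta_hypertension: float = 2.0
    site_effects: tuple[float, ...] = (0.0, 1.0, -1.0, 0.5, -0.5)
    # focal common deletion
    focal_region: tuple[str, int, int] = ("chr3", 53003415, 53013826)
    focal_carrier_freq: float = 0.052
    focal_effect: float = -4.3
    transmission_prob: float = 0.5
    family_random_sd: float = 8.6
    # background CNVs
    n_background_common: int = 16
    background_freq_range: tuple[float, float] = (0.055, 0.15)
    background_len_probes: int = 20
    rare_del_rate: float = 36.69
    rare_dup_rate: float = 14.15
    rare_len_probes: tuple[int, int] = (13, 35)
    # caller discordance and array geometry
    boundary_jitter_probes: int = 1
    caller_miss_rate: float = 0.0
    region_margin_probes: int = 2
    probe_spacing_bp: int = 1000
    n_chromosomes: int = 22
    window_start_bp: int = 52_000_000
    window_span_bp: int = 10_000_000
    lrr_sd_mean: float = 0.18
    lrr_sd_sd: float = 0.05
    seed: int = 17

    def __post_init__(self) -> None:
        for probs, name in ((self.sibship_size_probs, "sibship_size_probs"),
                            (self.site_probs, "site_probs")):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        for name in ("trait_sd", "age_sd", "bmi_sd", "probe_spacing_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.family_random_sd < 0:
            raise ValueError("family_random_sd must be >= 0")
        if not (0.0 < self.focal_carrier_freq < 1.0):
            raise ValueError("focal_carrier_freq must be in (0, 1)")
        if len(self.site_probs) != len(self.site_effects):
            raise ValueError("site_probs and site_effects must align")
        chrom, start, end = self.focal_region
        chrom = normalize_chrom(chrom)
        if not chrom[3:].isdigit() or int(chrom[3:]) > self.n_chromosomes:
            raise ValueError("focal region chromosome outside the simulated genome")
        if end - start + 1 <= 10_000:
            raise ValueError("focal region must span more than 10 kb to survive QC")
        lo, hi = self._probe_range(start, end)
        if hi - lo + 1 < 10:
            raise ValueError("focal region must contain at least 10 probes to survive QC")
        if self.rare_len_probes[0] < 2 * self.boundary_jitter_probes + 11:
            raise ValueError("rare CNVs too short to survive QC after boundary jitter")

    @property
    def n_probes_per_chrom(self) -> int:
        return self.window_span_bp // self.probe_spacing_bp

    def _probe_range(self, start_bp: int, end_bp: int) -> tuple[int, int]:
        """Indices of the first/last probe inside [start_bp, end_bp]."""
        lo = math.ceil((start_bp - self.window_start_bp) / self.probe_spacing_bp)
        hi = math.floor((end_bp - self.window_start_bp) / self.probe_spacing_bp)
        return lo, hi

    def probe_pos(self, index: int) -> int:
        return self.window_start_bp + index * self.probe_spacing_bp


@dataclass
class RegionTruth:
    chrom: str
    start_bp: int  # true CNV span (region expanded to the probe margin)
    end_bp: int
    state: str
    target_freq: float
    carriers: list[str]


@dataclass
class SyntheticTruth:
    """Latent assignments behind a generated cohort."""

    focal: RegionTruth
    background: list[RegionTruth]
    rare_counts: dict[str, tuple[int, int]]  # sample -> (n_del, n_dup)
    family_effects: dict[str, float]
    sigma_between: float
    sigma_within: float
    focal_effect: float

    @property
    def residual_icc(self) -> float:
        b2, w2 = self.sigma_between**2, self.sigma_within**2
        return b2 / (b2 + w2)


@dataclass
class SyntheticCohort:
    spec: SyntheticCohortSpec
    families: list[Family]
    snp_map: list[SnpLocus]
    calls_caller_a: list[CnvCall]
    calls_caller_b: list[CnvCall]
    qc_metrics: list[SampleQcMetrics]
    phenotypes: list[PhenotypeRecord]
    truth: SyntheticTruth

    @property
    def sample_ids(self) -> list[str]:
        return [sid for fam in self.families for sid in fam.member_ids]

    @property
    def lrr_sd(self) -> dict[str, float]:
        return {m.sample_id: m.lrr_sd for m in self.qc_metrics}


def _make_families(spec: SyntheticCohortSpec, rng: np.random.Generator) -> list[Family]:
    sizes = rng.choice(spec.sibship_sizes, size=spec.n_families, p=spec.sibship_size_probs)
    families = []
    for i, m in enumerate(sizes):
        fid = f"F{i + 1:04d}"
        ids = [f"{fid}-{j + 1}" for j in range(int(m))]
        sex = {sid: (1 if rng.random() < spec.male_prop else 2) for sid in ids}
        families.append(Family(family_id=fid, member_ids=ids, sex=sex))
    return families


def _familial_carriers(
    families: list[Family], f: float, tau: float, rng: np.random.Generator
) -> set[str]:
    """Choose carriers clustered in families: each family is a carrier family
    with probability q (set so the expected carrier fraction is f); within a
    carrier family one random member carries and each sibling carries with
    the transmission probability tau."""
    n = sum(len(fam.member_ids) for fam in families)
    expected_per_family = [1 + (len(fam.member_ids) - 1) * tau for fam in families]
    q = min(1.0, f * n / sum(expected_per_family))
    carriers: set[str] = set()
    for fam in families:
        if rng.random() >= q:
            continue
        members = list(fam.member_ids)
        index = members[rng.integers(len(members))]
        carriers.add(index)
        for sid in members:
            if sid != index and rng.random() < tau:
                carriers.add(sid)
    return carriers


def _make_snp_map(spec: SyntheticCohortSpec) -> list[SnpLocus]:
    loci = []
    for c in range(1, spec.n_chromosomes + 1):
        chrom = f"chr{c}"
        for i in range(spec.n_probes_per_chrom):
            loci.append(SnpLocus(snp_id=f"snp{c}_{i}", chrom=chrom, position_bp=spec.probe_pos(i)))
    return loci


class _Placement:
    """Per-sample occupied probe intervals, to forbid a sample carrying
    overlapping CNVs (buffered so jittered caller boundaries and the merge
    rule cannot fuse distinct CNVs)."""

    def __init__(self, buffer_probes: int):
        self.buffer = buffer_probes
        self.occupied: dict[tuple[str, int], list[tuple[int, int]]] = {}

    def try_place(self, sample: str, chrom_i: int, lo: int, hi: int) -> bool:
        key = (sample, chrom_i)
        ivs = self.occupied.setdefault(key, [])
        blo, bhi = lo - self.buffer, hi + self.buffer
        for s, e in ivs:
            if s <= bhi and e >= blo:
                return False
        ivs.append((lo, hi))
        return True


def _region_calls(
    spec: SyntheticCohortSpec,
    chrom_i: int,
    lo: int,
    hi: int,
    state: CnvState,
    carriers: set[str],
    placement: _Placement,
) -> list[tuple[str, int, int, int, CnvState]]:
    """(sample, chrom_i, lo, hi, state) tuples for one shared region."""
    out = []
    for sid in sorted(carriers):
        if placement.try_place(sid, chrom_i, lo, hi):
            out.append((sid, chrom_i, lo, hi, state))
    return out


def _covariate_trait(
    spec: SyntheticCohortSpec,
    families: list[Family],
    carriers: set[str],
    effect: float,
    rng: np.random.Generator,
) -> tuple[list[PhenotypeRecord], dict[str, float], float]:
    """Generate covariates and the trait; returns (records, family effects,
    within-family residual SD)."""
    p_sex = spec.male_prop
    p_eth = 1.0 - spec.ethnicity_prop_chinese  # P(Japanese)
    p_htn = spec.hypertension_prop
    site_probs = np.asarray(spec.site_probs)
    site_eff = np.asarray(spec.site_effects)
    site_mean = float(site_probs @ site_eff)
    var_site = float(site_probs @ (site_eff - site_mean) ** 2)
    f = spec.focal_carrier_freq
    var_cov = (
        spec.beta_age**2 * spec.age_sd**2
        + spec.beta_sex_male**2 * p_sex * (1 - p_sex)
        + spec.beta_bmi**2 * spec.bmi_sd**2
        + spec.beta_ethnicity_japanese**2 * p_eth * (1 - p_eth)
        + spec.beta_hypertension**2 * p_htn * (1 - p_htn)
        + var_site
        + effect**2 * f * (1 - f)
    )
    sigma_e2 = spec.trait_sd**2 - var_cov - spec.family_random_sd**2
    if sigma_e2 <= 0:
        raise ValueError(
            "trait_sd too small for the requested covariate, CNV and family variance"
        )
    sigma_e = math.sqrt(sigma_e2)

    records: list[PhenotypeRecord] = []
    fam_effects: dict[str, float] = {}
    for fam in families:
        b_f = rng.normal(0.0, spec.family_random_sd)
        fam_effects[fam.family_id] = b_f
        site = _SITE_LABELS[rng.choice(len(site_probs), p=site_probs)]
        ethnicity = "Japanese" if rng.random() < p_eth else "Chinese"
        for sid in fam.member_ids:
            male = fam.sex[sid] == 1
            age = rng.normal(spec.age_mean, spec.age_sd)
            bmi = rng.normal(spec.bmi_mean, spec.bmi_sd)
            htn = int(rng.random() < p_htn)
            y = (
                spec.trait_mean
                + spec.beta_age * (age - spec.age_mean)
                + spec.beta_sex_male * ((1.0 if male else 0.0) - p_sex)
                + spec.beta_bmi * (bmi - spec.bmi_mean)
                + spec.beta_ethnicity_japanese * ((1.0 if ethnicity == "Japanese" else 0.0) - p_eth)
                + spec.beta_hypertension * (htn - p_htn)
                + (site_eff[_SITE_LABELS.index(site)] - site_mean)
                + (effect if sid in carriers else 0.0)
                + b_f
                + rng.normal(0.0, sigma_e)
            )
            records.append(
                PhenotypeRecord(
                    sample_id=sid,
                    trait_value=float(y),
                    age=float(age),
                    sex=1 if male else 2,
                    bmi=float(bmi),
                    ethnicity=ethnicity,
                    site=site,
                    hypertension=htn,
                )
            )
    return records, fam_effects, sigma_e


def generate_cohort(spec: Optional[SyntheticCohortSpec] = None) -> SyntheticCohort:
    """Generate a complete synthetic study: pedigree, probe map, two caller
    call-sets, per-sample QC metrics, phenotypes, and the truth record."""
    spec = spec or SyntheticCohortSpec()
    rng = np.random.default_rng(spec.seed)
    families = _make_families(spec, rng)
    sample_ids = [sid for fam in families for sid in fam.member_ids]
    snp_map = _make_snp_map(spec)

    margin = spec.region_margin_probes
    buffer = 2 * spec.boundary_jitter_probes + 3
    placement = _Placement(buffer_probes=buffer)
    raw: list[tuple[str, int, int, int, CnvState]] = []

    # focal common deletion
    chrom_focal = int(normalize_chrom(spec.focal_region[0])[3:])
    lo_f, hi_f = spec._probe_range(spec.focal_region[1], spec.focal_region[2])
    lo_f, hi_f = lo_f - margin, hi_f + margin
    focal_carriers = _familial_carriers(families, spec.focal_carrier_freq, spec.transmission_prob, rng)
    raw.extend(_region_calls(spec, chrom_focal, lo_f, hi_f, CnvState.DELETION, focal_carriers, placement))
    truth_focal = RegionTruth(
        chrom=f"chr{chrom_focal}",
        start_bp=spec.probe_pos(lo_f),
        end_bp=spec.probe_pos(hi_f),
        state=CnvState.DELETION.value,
        target_freq=spec.focal_carrier_freq,
        carriers=sorted(focal_carriers),
    )

    # background common regions (no trait effect), alternating del/dup,
    # one per chromosome other than the focal one
    other_chroms = [c for c in range(1, spec.n_chromosomes + 1) if c != chrom_focal]
    n_bg = spec.n_background_common
    lo_freq, hi_freq = spec.background_freq_range
    bg_truth: list[RegionTruth] = []
    K = spec.n_probes_per_chrom
    for r in range(n_bg):
        state = CnvState.DELETION if r % 2 == 0 else CnvState.DUPLICATION
        chrom_i = other_chroms[r % len(other_chroms)]
        shift = (r // len(other_chroms)) * (spec.background_len_probes + 10 * buffer)
        lo = K // 2 + shift
        hi = lo + spec.background_len_probes - 1
        if hi + margin >= K:
            raise ValueError("background region outside the probed window")
        freq = lo_freq + (hi_freq - lo_freq) * (r // 2) / max(1, (n_bg + 1) // 2 - 1)
        carriers = _familial_carriers(families, freq, spec.transmission_prob, rng)
        raw.extend(_region_calls(spec, chrom_i, lo - margin, hi + margin, state, carriers, placement))
        bg_truth.append(
            RegionTruth(
                chrom=f"chr{chrom_i}",
                start_bp=spec.probe_pos(lo - margin),
                end_bp=spec.probe_pos(hi + margin),
                state=state.value,
                target_freq=freq,
                carriers=sorted(carriers),
            )
        )

    # rare background CNVs, unique to (mostly) one sample each
    rare_counts: dict[str, tuple[int, int]] = {}
    len_lo, len_hi = spec.rare_len_probes
    for sid in sample_ids:
        n_del = int(rng.poisson(spec.rare_del_rate))
        n_dup = int(rng.poisson(spec.rare_dup_rate))
        rare_counts[sid] = (n_del, n_dup)
        for state, count in ((CnvState.DELETION, n_del), (CnvState.DUPLICATION, n_dup)):
            placed = 0
            attempts = 0
            while placed < count and attempts < 100 * count + 100:
                attempts += 1
                chrom_i = int(rng.integers(1, spec.n_chromosomes + 1))
                L = int(rng.integers(len_lo, len_hi + 1))
                lo = int(rng.integers(0, K - L))
                if placement.try_place(sid, chrom_i, lo, lo + L - 1):
                    raw.append((sid, chrom_i, lo, lo + L - 1, state))
                    placed += 1

    # caller A reports true spans; caller B jitters boundaries and may miss
    calls_a: list[CnvCall] = []
    calls_b: list[CnvCall] = []
    j = spec.boundary_jitter_probes
    for sid, chrom_i, lo, hi, state in raw:
        chrom = f"chr{chrom_i}"
        cn = 1 if state is CnvState.DELETION else 3
        calls_a.append(
            CnvCall(
                sample_id=sid,
                chrom=chrom,
                start_bp=spec.probe_pos(lo),
                end_bp=spec.probe_pos(hi),
                state=state,
                num_snps=hi - lo + 1,
                copy_number=cn,
                source=CallSource.CALLER_A,
            )
        )
        if spec.caller_miss_rate > 0 and rng.random() < spec.caller_miss_rate:
            continue
        if j > 0:
            lo_b = int(np.clip(lo + rng.integers(-j, j + 1), 0, K - 1))
            hi_b = int(np.clip(hi + rng.integers(-j, j + 1), lo_b, K - 1))
        else:
            lo_b, hi_b = lo, hi
        calls_b.append(
            CnvCall(
                sample_id=sid,
                chrom=chrom,
                start_bp=spec.probe_pos(lo_b),
                end_bp=spec.probe_pos(hi_b),
                state=state,
                num_snps=hi_b - lo_b + 1,
                copy_number=cn,
                source=CallSource.CALLER_B,
            )
        )

    counts_a: dict[str, int] = {sid: 0 for sid in sample_ids}
    counts_b: dict[str, int] = {sid: 0 for sid in sample_ids}
    for c in calls_a:
        counts_a[c.sample_id] += 1
    for c in calls_b:
        counts_b[c.sample_id] += 1
    qc_metrics = [
        SampleQcMetrics(
            sample_id=sid,
            lrr_sd=float(max(0.02, rng.normal(spec.lrr_sd_mean, spec.lrr_sd_sd))),
            n_calls_by_source={
                CallSource.CALLER_A: counts_a[sid],
                CallSource.CALLER_B: counts_b[sid],
            },
        )
        for sid in sample_ids
    ]

    phenotypes, fam_effects, sigma_e = _covariate_trait(
        spec, families, focal_carriers, spec.focal_effect, rng
    )

    truth = SyntheticTruth(
        focal=truth_focal,
        background=bg_truth,
        rare_counts=rare_counts,
        family_effects=fam_effects,
        sigma_between=spec.family_random_sd,
        sigma_within=sigma_e,
        focal_effect=spec.focal_effect,
    )
    return SyntheticCohort(
        spec=spec,
        families=families,
        snp_map=snp_map,
        calls_caller_a=calls_a,
        calls_caller_b=calls_b,
        qc_metrics=qc_metrics,
        phenotypes=phenotypes,
        truth=truth,
    )


def generate_null_trait(
    families: list[Family], spec: Optional[SyntheticCohortSpec] = None
) -> list[PhenotypeRecord]:
    """Phenotypes from the identical trait machinery with zero CNV effect
    (for type-I-error studies). Deterministic given (families, spec.seed)."""
    spec = spec or SyntheticCohortSpec()
    rng = np.random.default_rng([spec.seed, 9])
    records, _, _ = _covariate_trait(spec, families, set(), 0.0, rng)
    return records


_PENNCNV_STATE = {0: 1, 1: 2, 3: 5, 4: 6}


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write a cohort in the pipeline's on-disk formats: two rawcnv call
    lists, snps.tsv, ped.fam, pheno.tsv, metrics.tsv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    probe_id = {(l.chrom, l.position_bp): l.snp_id for l in cohort.snp_map}

    for label, calls in (("caller_a", cohort.calls_caller_a), ("caller_b", cohort.calls_caller_b)):
        p = outdir / f"{label}.rawcnv"
        with open(p, "w") as fh:
            for c in calls:
                st = _PENNCNV_STATE.get(c.copy_number if c.copy_number is not None else
                                        (1 if c.state is CnvState.DELETION else 3))
                snp1 = probe_id.get((c.chrom, c.start_bp), "NA")
                snp2 = probe_id.get((c.chrom, c.end_bp), "NA")
                fh.write(
                    f"{c.chrom}:{c.start_bp}-{c.end_bp} numsnp={c.num_snps} "
                    f"length={c.length_bp:,} state{st},cn={c.copy_number} {c.sample_id} "
                    f"startsnp={snp1} endsnp={snp2}\n"
                )
        paths[label] = p

    p = outdir / "snps.tsv"
    with open(p, "w") as fh:
        fh.write("snp_id\tchrom\tposition\n")
        for l in cohort.snp_map:
            fh.write(f"{l.snp_id}\t{l.chrom}\t{l.position_bp}\n")
    paths["snp_map"] = p

    p = outdir / "ped.fam"
    with open(p, "w") as fh:
        for fam in cohort.families:
            for sid in fam.member_ids:
                fh.write(f"{fam.family_id} {sid} 0 0 {fam.sex.get(sid, 0)} -9\n")
    paths["pedigree"] = p

    p = outdir / "pheno.tsv"
    with open(p, "w") as fh:
        fh.write("sample_id\tFPG\tage\tsex\tbmi\tethnicity\tsite\thypertension\n")
        for r in cohort.phenotypes:
            fh.write(
                f"{r.sample_id}\t{r.trait_value:.4f}\t{r.age:.2f}\t{r.sex}\t{r.bmi:.2f}"
                f"\t{r.ethnicity}\t{r.site}\t{r.hypertension}\n"
            )
    paths["phenotypes"] = p

    p = outdir / "metrics.tsv"
    with open(p, "w") as fh:
        fh.write("sample_id\tlrr_sd\tn_calls_callerA\tn_calls_callerB\n")
        for m in cohort.qc_metrics:
            fh.write(
                f"{m.sample_id}\t{m.lrr_sd:.4f}\t{m.n_calls_by_source[CallSource.CALLER_A]}"
                f"\t{m.n_calls_by_source[CallSource.CALLER_B]}\n"
            )
    paths["metrics"] = p

    p = outdir / "truth.json"
    truth = {
        "focal": asdict(cohort.truth.focal),
        "background": [asdict(r) for r in cohort.truth.background],
        "rare_counts": cohort.truth.rare_counts,
        "family_effects": cohort.truth.family_effects,
        "sigma_between": cohort.truth.sigma_between,
        "sigma_within": cohort.truth.sigma_within,
        "focal_effect": cohort.truth.focal_effect,
    }
    with open(p, "w") as fh:
        json.dump(truth, fh, indent=1)
    paths["truth"] = p
    return paths
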