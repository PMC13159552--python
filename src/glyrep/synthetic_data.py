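"""Synthetic multi-cohort, multi-platform glycomics GWAS data with known
ground truth, plus the printed 19-locus replication fixture.

The generative model: genotype dosages are Binomial(2, MAF) under
Hardy-Weinberg equilibrium; each glycan peak's latent log-abundance is a
sum of genetic effects (applied where a feature selector matches the
peak's classified structure), latent-factor loadings, age/sex/batch
terms and Gaussian noise; peaks are then closed compositionally
(exponentiated and normalized per sample), so a positive effect on one
peak induces small negative effects on the rest — as in real
total-area-normalized glycomics data.

Seeding: one master seed; per-cohort streams are derived with stable
per-cohort offsets, so adding a cohort never perturbs existing ones.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from glyrep.glycan_model import (
    GlycanFeatures,
    TraitDefinition,
    TraitTerm,
    _match_selector,
    classify_glycan,
    parse_composition,
)

logger = logging.getLogger(__name__)

UHPLC = "UHPLC-FD"
MALDI = "MALDI-MS"

#: default direct-peak panels. The MALDI panel distinguishes alpha2,6-
#: (E) from alpha2,3-linked (L) sialic acids; the UHPLC panel cannot and
#: codes total sialic acid as E.
DEFAULT_PANELS: dict[str, tuple[str, ...]] = {
    MALDI: (
        # oligomannose
        "H5N2", "H6N2", "H7N2", "H8N2", "H9N2",
        # diantennary
        "H3N4", "H3N4F1", "H4N4", "H4N4F1", "H4N4F1E1", "H5N4",
        "H5N4E1", "H5N4E2", "H5N4F1", "H5N4F1E1", "H5N4F1E2",
        "H5N4E1L1", "H5N4L1", "H5N4L2", "H5N4F1E1L1",
        # bisected
        "H3N5F1", "H4N5F1", "H4N5F1E1", "H5N5E1",
        # triantennary
        "H6N5", "H6N5E1", "H6N5E2", "H6N5E3", "H6N5F1E1L2",
        "H6N5E1L2", "H6N5F1E1L1", "H6N5L3",
        # tetraantennary
        "H7N6", "H7N6E2L1", "H7N6F1E1L3", "H7N6E1L3", "H7N6F1E1L2",
        "H7N6E4",
    ),
    UHPLC: (
        "H5N2", "H6N2", "H7N2", "H8N2", "H9N2",
        "H3N4", "H3N4F1", "H4N4", "H4N4F1", "H4N4F1E1", "H5N4",
        "H5N4E1", "H5N4E2", "H5N4F1", "H5N4F1E1", "H5N4F1E2",
        "H3N5F1", "H4N5F1",
        "H6N5", "H6N5E1", "H6N5E2", "H6N5E3",
        "H7N6", "H7N6E2", "H7N6E4",
    ),
}


@dataclass(frozen=True)
class CohortSpec:
    cohort_id: str
    platform: str
    n_samples: int


@dataclass(frozen=True)
class EffectSpec:
    """One genetic effect: locus index, a trait selector (feature
    expression over the glycan panel) and the effect size in latent
    log-abundance SD units."""

    locus: int
    selector: str
    beta: float


@dataclass
class SimConfig:
    """Full generative specification for synthetic cohorts."""

    cohorts: list[CohortSpec]
    n_loci: int = 2
    mafs: list[float] = field(default_factory=list)
    n_null_snps: int = 0
    n_factors: int = 2
    factor_scale: float = 0.3
    effect_map: list[EffectSpec] = field(default_factory=list)
    age_slope: float = 0.0
    sex_offset: float = 0.0
    noise_sd: float = 1.0
    n_batches: int = 1
    batch_shift_sd: float = 0.0
    case_interaction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.cohorts = [
            c if isinstance(c, CohortSpec) else CohortSpec(**c) for c in self.cohorts
        ]
        self.effect_map = [
            e if isinstance(e, EffectSpec) else EffectSpec(**e) for e in self.effect_map
        ]
        if not self.mafs:
            self.mafs = [0.3] * self.n_loci
        self.validate()

    def validate(self) -> None:
        if len(self.mafs) != self.n_loci:
            raise ValueError("mafs length must equal n_loci")
        for m in self.mafs:
            if not (0.0 < m <= 0.5):
                raise ValueError(f"MAF must be in (0, 0.5]; got {m}")
        for c in self.cohorts:
            if c.n_samples < 50:
                raise ValueError(f"cohort {c.cohort_id}: need n_samples >= 50")
            if c.platform not in DEFAULT_PANELS:
                raise ValueError(f"unknown platform {c.platform!r}")
        platforms = {c.platform for c in self.cohorts}
        for eff in self.effect_map:
            if not (0 <= eff.locus < self.n_loci):
                raise ValueError(f"effect locus {eff.locus} out of range")
            if not any(
                _selector_hits(eff.selector, DEFAULT_PANELS[pf]) for pf in platforms
            ):
                raise ValueError(
                    f"effect selector {eff.selector!r} matches no composition "
                    f"on any configured platform"
                )

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _selector_hits(selector: str, panel: Sequence[str]) -> bool:
    for code in panel:
        comp = parse_composition(code)
        if _match_selector(selector, comp, classify_glycan(comp)):
            return True
    return False


@dataclass
class CohortData:
    """Simulated cohort: dosages, closed direct-peak abundances, covariates."""

    cohort_id: str
    platform: str
    dosages: pd.DataFrame  # samples x (loci + null SNPs), values {0,1,2}
    peaks: pd.DataFrame  # samples x compositions, rows sum to 1
    covariates: pd.DataFrame  # age, sex, batch, case


def _stream(seed: int, *tags: str) -> np.random.Generator:
    """Derive an independent, stable RNG stream from the master seed."""
    offsets = [zlib.crc32(t.encode()) for t in tags]
    return np.random.default_rng([seed, *offsets])


def simulate_cohort(config: SimConfig, cohort_id: str) -> CohortData:
    """Simulate one cohort per the generative model in the module docstring.

    Deterministic given (config, cohort_id): identical calls return
    bit-identical data.
    """
    spec = next((c for c in config.cohorts if c.cohort_id == cohort_id), None)
    if spec is None:
        raise ValueError(f"cohort {cohort_id!r} not in config")
    panel = DEFAULT_PANELS[spec.platform]
    codes = list(panel)
    comps = [parse_composition(c) for c in codes]
    feats = [classify_glycan(c) for c in comps]
    n_peaks = len(codes)
    n = spec.n_samples

    # panel-level structure shared across cohorts on the same platform
    # moderate baseline spread: keeps any single trait family well below
    # half the total signal, so closure-induced anti-correlation cannot
    # dominate a configured genetic effect
    rng_panel = _stream(config.seed, "panel", spec.platform)
    baseline = rng_panel.normal(0.0, 0.5, size=n_peaks)
    loadings = rng_panel.normal(0.0, config.factor_scale, size=(config.n_factors, n_peaks))
    age_sens = rng_panel.normal(0.0, 1.0, size=n_peaks)
    sex_sens = rng_panel.normal(0.0, 1.0, size=n_peaks)
    # null-SNP MAFs shared across cohorts
    rng_null = _stream(config.seed, "null-snps")
    null_mafs = rng_null.uniform(0.05, 0.5, size=config.n_null_snps)

    rng = _stream(config.seed, "cohort", cohort_id)

    all_mafs = np.concatenate([np.asarray(config.mafs, dtype=float), null_mafs])
    dosages = rng.binomial(2, all_mafs, size=(n, all_mafs.size)).astype(float)

    age = rng.normal(60.0, 8.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    batch = rng.integers(0, config.n_batches, size=n)
    case = np.zeros(n)

    latent = np.tile(baseline, (n, 1))
    # genetic effects on matching peaks, centered dosage
    for eff in config.effect_map:
        mask = np.array(
            [_match_selector(eff.selector, c, f) for c, f in zip(comps, feats)]
        )
        if not mask.any():
            continue  # selector valid config-wide but absent on this platform
        g = dosages[:, eff.locus] - 2.0 * config.mafs[eff.locus]
        scale = 1.0 + config.case_interaction * case
        latent[:, mask] += (eff.beta * scale * g)[:, None]
    # latent factors (compositional correlation among peaks)
    factors = rng.normal(0.0, 1.0, size=(n, config.n_factors))
    latent += factors @ loadings
    # covariates
    z_age = (age - 60.0) / 8.0
    latent += config.age_slope * np.outer(z_age, age_sens)
    latent += config.sex_offset * np.outer(sex - 0.5, sex_sens)
    if config.batch_shift_sd > 0:
        rng_batch = _stream(config.seed, "batch", spec.platform)
        shifts = rng_batch.normal(0.0, config.batch_shift_sd, size=(config.n_batches, n_peaks))
        latent += shifts[batch]
    latent += rng.normal(0.0, config.noise_sd, size=(n, n_peaks))

    # compositional closure: exponentiate and normalize per sample
    latent -= latent.max(axis=1, keepdims=True)  # overflow guard
    raw = np.exp(latent)
    peaks = raw / raw.sum(axis=1, keepdims=True)

    sample_ids = [f"{cohort_id}_S{i:05d}" for i in range(n)]
    snp_ids = [f"locus{i}" for i in range(config.n_loci)] + [
        f"null{i}" for i in range(config.n_null_snps)
    ]
    return CohortData(
        cohort_id=cohort_id,
        platform=spec.platform,
        dosages=pd.DataFrame(dosages, index=sample_ids, columns=snp_ids),
        peaks=pd.DataFrame(peaks, index=sample_ids, columns=codes),
        covariates=pd.DataFrame(
            {"age": age, "sex": sex, "batch": batch, "case": case}, index=sample_ids
        ),
    )


# ---------------------------------------------------------------------------
# Default trait definitions for simulated panels
# ---------------------------------------------------------------------------

def default_trait_definitions(platform: str) -> list[TraitDefinition]:
    """Direct traits for every panel peak plus derived traits mirroring
    common glycomics summaries (fucosylation, antennarity fractions,
    sialylation per antenna)."""
    panel = DEFAULT_PANELS[platform]
    defs = [
        TraitDefinition(
            trait_id=code, platform=platform, kind="direct",
            numerator=(TraitTerm(code),),
        )
        for code in panel
    ]
    derived = [
        ("FUC", (TraitTerm("F>=1"),), (TraitTerm("*"),), 1.0),
        ("OM", (TraitTerm("class=oligomannose"),), (TraitTerm("*"),), 1.0),
        ("CA2", (TraitTerm("antennae=2"),), (TraitTerm("class=complex"),), 1.0),
        ("CA3", (TraitTerm("antennae=3"),), (TraitTerm("class=complex"),), 1.0),
        ("CA4", (TraitTerm("antennae=4"),), (TraitTerm("class=complex"),), 1.0),
        ("A2S", (TraitTerm("antennae=2", "S"),), (TraitTerm("antennae=2"),), 2.0),
        ("A3S", (TraitTerm("antennae=3", "S"),), (TraitTerm("antennae=3"),), 3.0),
        ("A4S", (TraitTerm("antennae=4", "S"),), (TraitTerm("antennae=4"),), 4.0),
    ]
    if platform == MALDI:
        derived += [
            ("A2E", (TraitTerm("antennae=2", "E"),), (TraitTerm("antennae=2"),), 2.0),
            ("A3E", (TraitTerm("antennae=3", "E"),), (TraitTerm("antennae=3"),), 3.0),
            ("A4E", (TraitTerm("antennae=4", "E"),), (TraitTerm("antennae=4"),), 4.0),
            ("A2L", (TraitTerm("antennae=2", "L"),), (TraitTerm("antennae=2"),), 2.0),
            ("A3L", (TraitTerm("antennae=3", "L"),), (TraitTerm("antennae=3"),), 3.0),
            ("A4L", (TraitTerm("antennae=4", "L"),), (TraitTerm("antennae=4"),), 4.0),
        ]
    for trait_id, num, den, scale in derived:
        defs.append(
            TraitDefinition(
                trait_id=trait_id, platform=platform, kind="derived",
                numerator=num, denominator=den, scale=scale,
            )
        )
    return defs


# ---------------------------------------------------------------------------
# Printed 19-locus replication fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Table1Row:
    snp: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    gene: str
    p_cauchy_uhplc: float
    p_cauchy_maldi: float
    p_fisher_printed: float


def parse_decimal_comma(cell: str) -> float:
    """Parse a decimal-comma scientific cell like ``"4,25E-02"`` to a
    float, locale-independently."""
    return float(cell.strip().replace(",", "."))


# (snp, chr, pos, EA, RA, gene, P Cauchy UHPLC-FD, P Cauchy MALDI-MS, P Fisher)
_TABLE1_CELLS = [
    ("rs34881159", "1", 161_590_503, "A", "T", "FCGR2B", "4,25E-02", "4,59E-08", "4,11E-08"),
    ("rs10188206", "2", 26_142_632, "A", "T", "NDUFB4P4", "6,79E-03", "1,62E-02", "1,11E-03"),
    ("rs523118", "3", 135_965_888, "G", "T", "PCCB", "1,84E-06", "3,11E-04", "1,27E-08"),
    ("rs7647487", "3", 196_206_175, "C", "T", "RNF168", "1,42E-03", "4,80E-02", "7,21E-04"),
    ("rs76360119", "5", 179_183_793, "A", "G", "MGAT4B", "2,84E-05", "2,34E-05", "1,47E-08"),
    ("rs9352006", "6", 74_238_815, "A", "G", "MBD4", "1,19E-01", "1,77E-01", "1,03E-01"),
    ("rs2881699", "7", 6_544_886, "C", "G", "GRID2IP", "1,67E-05", "2,15E-02", "5,68E-06"),
    ("rs2511737", "8", 103_580_527, "A", "C", "ODF1", "4,76E-02", "1,73E-04", "1,05E-04"),
    ("rs7866188", "9", 94_681_588, "A", "C", "ROR2", "3,89E-01", "1,03E-01", "1,69E-01"),
    ("rs2497318", "10", 94_432_000, "C", "T", "EIF2S2P3", "1,13E-01", "8,07E-03", "7,32E-03"),
    ("rs10896045", "11", 65_555_524, "A", "G", "OVOL1", "1,87E-02", "3,80E-03", "7,48E-04"),
    ("rs667633", "11", 114_366_732, "C", "T", "NXPE2", "4,10E-01", "2,30E-01", "3,17E-01"),
    ("rs1150975", "12", 32_052_422, "A", "C", "RPLP2P4", "1,68E-02", "1,18E-03", "2,34E-04"),
    ("rs7402780", "15", 44_336_044, "A", "G", "FRMD5", "6,15E-01", "1,79E-02", "6,07E-02"),
    ("rs11071549", "15", 60_941_324, "G", "T", "RORA", "9,12E-01", "8,91E-01", "9,81E-01"),
    ("rs2305479", "17", 38_062_217, "C", "T", "GSDMB", "7,22E-03", "8,46E-02", "5,13E-03"),
    ("rs56214516", "17", 43_836_953, "A", "C", "CRHR1", "2,38E-01", "1,09E-02", "1,81E-02"),
    ("rs11085197", "19", 6_713_175, "C", "G", "C3", "5,54E-02", "2,64E-25", "8,85E-25"),
    ("rs7412", "19", 45_412_079, "C", "T", "APOE4", "5,73E-01", "2,10E-03", "9,30E-03"),
]


def table1_fixture() -> list[Table1Row]:
    """The 19-locus replication table: index SNPs, candidate genes, and
    per-platform Cauchy-aggregated p-values (plus the printed Fisher
    p-value for cross-checking)."""
    return [
        Table1Row(
            snp=snp, chromosome=chrom, position=pos,
            effect_allele=ea, other_allele=ra, gene=gene,
            p_cauchy_uhplc=parse_decimal_comma(p_u),
            p_cauchy_maldi=parse_decimal_comma(p_m),
            p_fisher_printed=parse_decimal_comma(p_f),
        )
        for snp, chrom, pos, ea, ra, gene, p_u, p_m, p_f in _TABLE1_CELLS
    ]


# ---------------------------------------------------------------------------
# Null p-value panels for calibration studies
# ---------------------------------------------------------------------------

def simulate_null_pvalue_panels(
    n_traits: int, rho: float, n_reps: int, seed: int
) -> np.ndarray:
    """Replicate panels of two-sided p-values from equicorrelated null
    z-scores; shape (n_reps, n_traits). rho must be in [0, 1)."""
    if not (0.0 <= rho < 1.0):
        raise ValueError(f"rho must be in [0, 1); got {rho}")
    if n_reps < 0:
        raise ValueError("n_reps must be >= 0")
    rng = np.random.default_rng(seed)
    if n_reps == 0:
        return np.empty((0, n_traits))
    shared = rng.standard_normal((n_reps, 1))
    indep = rng.standard_normal((n_reps, n_traits))
    z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indep
    return 2.0 * ndtr(-np.abs(z))


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_cohort(cohort: CohortData, out_dir: str | Path, vcf: bool = False) -> dict[str, Path]:
    """Write a cohort as plain TSVs (genotypes, peaks, covariates) and
    optionally a dosage VCF."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    stem = cohort.cohort_id
    paths["genotypes"] = out / f"{stem}.genotypes.tsv"
    cohort.dosages.rename_axis("sample_id").to_csv(paths["genotypes"], sep="\t")
    paths["peaks"] = out / f"{stem}.peaks.tsv"
    cohort.peaks.rename_axis("sample_id").to_csv(paths["peaks"], sep="\t")
    paths["covariates"] = out / f"{stem}.covariates.tsv"
    cohort.covariates.rename_axis("sample_id").to_csv(paths["covariates"], sep="\t")
    if vcf:
        paths["vcf"] = out / f"{stem}.vcf"
        _write_dosage_vcf(cohort, paths["vcf"])
    return paths


def _write_dosage_vcf(cohort: CohortData, path: Path) -> None:
    samples = list(cohort.dosages.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for i, snp in enumerate(cohort.dosages.columns):
            ds = cohort.dosages[snp].to_numpy()
            row = [
                "1", str(1000 + i), str(snp), "A", "G", ".", "PASS", ".", "DS",
            ] + [f"{d:g}" for d in ds]
            fh.write("\t".join(row) + "\n")
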