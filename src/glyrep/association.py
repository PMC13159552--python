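"""Per-variant, per-trait linear association, summary-statistic
harmonization, fixed-effects inverse-variance-weighted meta-analysis,
a multivariate omnibus test from single-trait summary statistics, and
R-squared of association.

Two-sided p-values use the standard normal reference for beta/se
(GWAS convention at the sample sizes of interest), while the residual
variance estimate keeps the n-2 degrees-of-freedom correction.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class AssocRecord:
    """One variant-trait association in one cohort."""

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    trait_id: str
    cohort_id: str
    beta: float
    se: float
    p: float
    n: int
    eaf: float = float("nan")
    untestable: bool = False

    def validate(self) -> None:
        if not self.untestable:
            if not self.se > 0:
                raise ValueError(f"{self.variant_id}/{self.trait_id}: se must be > 0")
            if not (0.0 < self.p <= 1.0):
                raise ValueError(f"{self.variant_id}/{self.trait_id}: p outside (0, 1]")


@dataclass(frozen=True)
class MetaRecord:
    """Meta-analyzed variant-trait association across cohorts."""

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    trait_id: str
    beta: float
    se: float
    p: float
    n: int
    eaf: float
    k_cohorts: int
    q_het: float


def _two_sided_p(z: float) -> float:
    # survival-function form keeps precision for large |z|
    return float(max(2.0 * ndtr(-abs(z)), 5e-324))


def assoc_linear(
    dosage: np.ndarray,
    y: np.ndarray,
    variant_id: str = "",
    trait_id: str = "",
    cohort_id: str = "",
    chromosome: str = "",
    position: int = 0,
    effect_allele: str = "",
    other_allele: str = "",
) -> AssocRecord:
    """Additive-model OLS of a (residualized, normal-transformed) trait
    on genotype dosage.

    Returns an :class:`AssocRecord`; a monomorphic dosage yields a
    record flagged untestable rather than an exception. Requires
    n >= 10.
    """
    g = np.asarray(dosage, dtype=float)
    y = np.asarray(y, dtype=float)
    if g.shape != y.shape or g.ndim != 1:
        raise ValueError("dosage and trait must be 1-D and equal length")
    n = g.size
    if n < 10:
        raise ValueError(f"need n >= 10, got {n}")
    eaf = float(np.mean(g) / 2.0)

    sxx = float(np.sum((g - g.mean()) ** 2))
    common = dict(
        variant_id=variant_id, chromosome=chromosome, position=position,
        effect_allele=effect_allele, other_allele=other_allele,
        trait_id=trait_id, cohort_id=cohort_id, n=n, eaf=eaf,
    )
    if sxx == 0.0:
        logger.info("variant %s: monomorphic dosage, flagged untestable", variant_id)
        return AssocRecord(
            beta=float("nan"), se=float("nan"), p=float("nan"),
            untestable=True, **common,
        )
    beta = float(np.sum((g - g.mean()) * (y - y.mean())) / sxx)
    resid = (y - y.mean()) - beta * (g - g.mean())
    sigma2 = float(resid @ resid) / (n - 2)
    se = math.sqrt(sigma2 / sxx)
    if se == 0.0:
        # perfect fit: report an effectively-zero p
        return AssocRecord(beta=beta, se=5e-324, p=5e-324, **common)
    return AssocRecord(beta=beta, se=se, p=_two_sided_p(beta / se), **common)


def assoc_scan(
    G: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized OLS of every trait column of ``Y`` on every dosage
    column of ``G``; returns (beta, se, p) arrays of shape
    (n_variants, n_traits). Monomorphic variants get NaN rows.

    Must agree with :func:`assoc_linear` applied cell by cell (tested).
    """
    G = np.asarray(G, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = G.shape[0]
    if Y.shape[0] != n:
        raise ValueError("G and Y must have matching sample counts")
    Gc = G - G.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sxx = np.sum(Gc**2, axis=0)  # (V,)
    mono = sxx == 0.0
    sxx_safe = np.where(mono, np.nan, sxx)
    beta = (Gc.T @ Yc) / sxx_safe[:, None]  # (V, T)
    syy = np.sum(Yc**2, axis=0)  # (T,)
    rss = syy[None, :] - beta**2 * sxx_safe[:, None]
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / sxx_safe[:, None])
    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
    p = 2.0 * ndtr(-np.abs(z))
    p = np.maximum(p, 5e-324)
    p[np.isnan(z)] = np.nan
    return beta, se, p


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

def _is_strand_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def harmonize_records(
    records: Sequence[AssocRecord],
    maf_floor: float = 0.01,
) -> tuple[list[AssocRecord], Counter]:
    """Align records across cohorts to a per-variant reference allele pair.

    The reference (effect, other) pair is fixed from the first record
    seen for each variant-trait key; swapped-allele records get beta
    sign flipped and eaf complemented; irreconcilable or
    strand-ambiguous mismatches are dropped. QC filters: se > 0,
    p in (0, 1], eaf-implied MAF >= ``maf_floor`` (records without eaf
    pass). Exact duplicates are deduplicated.

    Returns (aligned records, drop-reason counter); the counter also
    carries the ``input`` and ``output`` totals so every record is
    accounted for.
    """
    log = Counter()
    log["input"] = len(records)
    reference: dict[tuple[str, str], tuple[str, str]] = {}
    seen: set[tuple] = set()
    out: list[AssocRecord] = []
    for rec in records:
        key = (rec.variant_id or f"{rec.chromosome}:{rec.position}", rec.trait_id)
        dedup_key = (key, rec.cohort_id, rec.beta, rec.se, rec.p, rec.n)
        if dedup_key in seen:
            log["duplicate"] += 1
            continue
        seen.add(dedup_key)
        if rec.untestable:
            log["untestable"] += 1
            continue
        if not rec.se > 0:
            log["bad_se"] += 1
            continue
        if not (0.0 < rec.p <= 1.0):
            log["bad_p"] += 1
            continue
        if not math.isnan(rec.eaf):
            maf = min(rec.eaf, 1.0 - rec.eaf)
            if maf < maf_floor:
                log["maf_below_floor"] += 1
                continue

        ea, oa = rec.effect_allele.upper(), rec.other_allele.upper()
        if key not in reference:
            reference[key] = (ea, oa)
            out.append(rec)
            log["aligned"] += 1
            continue
        ref_ea, ref_oa = reference[key]
        if (ea, oa) == (ref_ea, ref_oa):
            out.append(rec)
            log["aligned"] += 1
        elif (ea, oa) == (ref_oa, ref_ea):
            out.append(
                replace(
                    rec,
                    effect_allele=ref_ea,
                    other_allele=ref_oa,
                    beta=-rec.beta,
                    eaf=1.0 - rec.eaf if not math.isnan(rec.eaf) else rec.eaf,
                )
            )
            log["aligned_swapped"] += 1
        elif _is_strand_ambiguous(ea, oa) or _is_strand_ambiguous(ref_ea, ref_oa):
            log["strand_ambiguous_mismatch"] += 1
            logger.info("dropped strand-ambiguous mismatch at %s", key)
        else:
            log["allele_mismatch"] += 1
            logger.info("dropped irreconcilable alleles at %s: (%s,%s)", key, ea, oa)
    log["output"] = len(out)
    return out, log


def ivw_meta(records: Sequence[AssocRecord]) -> MetaRecord:
    """Fixed-effects inverse-variance-weighted meta-analysis of aligned
    records for one variant-trait pair.

    w_i = 1/se_i^2; beta = sum(w b)/sum(w); se = sum(w)^(-1/2);
    two-sided normal p; Cochran's Q = sum w (b - beta)^2.
    """
    if not records:
        raise ValueError("ivw_meta: empty input")
    keys = {(r.variant_id, r.trait_id) for r in records}
    if len(keys) > 1:
        raise ValueError(f"ivw_meta: mixed variant-trait keys {keys}")
    b = np.array([r.beta for r in records])
    se = np.array([r.se for r in records])
    if not (se > 0).all():
        raise ValueError("ivw_meta: all standard errors must be > 0")
    w = 1.0 / se**2
    beta = float(np.sum(w * b) / np.sum(w))
    se_meta = float(1.0 / math.sqrt(np.sum(w)))
    q = float(np.sum(w * (b - beta) ** 2))
    n = int(sum(r.n for r in records))
    eafs = np.array([r.eaf for r in records], dtype=float)
    ns = np.array([r.n for r in records], dtype=float)
    ok = ~np.isnan(eafs)
    eaf = float(np.sum(eafs[ok] * ns[ok]) / np.sum(ns[ok])) if ok.any() else float("nan")
    first = records[0]
    return MetaRecord(
        variant_id=first.variant_id,
        chromosome=first.chromosome,
        position=first.position,
        effect_allele=first.effect_allele,
        other_allele=first.other_allele,
        trait_id=first.trait_id,
        beta=beta,
        se=se_meta,
        p=_two_sided_p(beta / se_meta),
        n=n,
        eaf=eaf,
        k_cohorts=len(records),
        q_het=q,
    )


# ---------------------------------------------------------------------------
# Multivariate omnibus & R^2
# ---------------------------------------------------------------------------

def estimate_trait_correlation(
    null_z: np.ndarray, shrinkage: float = 0.05
) -> np.ndarray:
    """Estimate the trait correlation matrix from null-SNP z-scores
    (rows: SNPs, columns: traits), shrunk toward identity by
    ``(1 - shrinkage) * R + shrinkage * I``."""
    Z = np.asarray(null_z, dtype=float)
    if Z.ndim != 2 or Z.shape[0] < 2:
        raise ValueError("need a 2-D z-score matrix with >= 2 null SNPs")
    R = np.corrcoef(Z, rowvar=False)
    R = np.atleast_2d(R)
    m = R.shape[0]
    return (1.0 - shrinkage) * R + shrinkage * np.eye(m)


def omnibus_multitrait(
    z: np.ndarray,
    R: np.ndarray | None = None,
    null_z: np.ndarray | None = None,
    max_ridge: float = 0.1,
) -> tuple[float, float]:
    """Chi-square omnibus test of a z-score vector over correlated traits.

    Q = z' R^{-1} z referred to chi-square with m = dim(R) degrees of
    freedom — an asymptotic stand-in for MANOVA-type multi-trait tests
    built from single-trait summary statistics. ``R`` defaults to an
    estimate from ``null_z`` (or identity when neither is given). A
    non-positive-definite ``R`` is ridge-regularized up to ``max_ridge``
    (logged); beyond that it is an error.

    Returns (Q, p).
    """
    z = np.asarray(z, dtype=float).ravel()
    m = z.size
    if m == 0:
        raise ValueError("empty z-score vector")
    if R is None:
        R = estimate_trait_correlation(null_z) if null_z is not None else np.eye(m)
    R = np.asarray(R, dtype=float)
    if R.shape != (m, m):
        raise ValueError(f"R must be {m}x{m}")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("R must be symmetric")

    ridge = 0.0
    while True:
        try:
            c = np.linalg.cholesky(R + ridge * np.eye(m))
            break
        except np.linalg.LinAlgError:
            ridge = 1e-8 if ridge == 0.0 else ridge * 10.0
            if ridge > max_ridge:
                raise ValueError(
                    f"R not positive-definite after ridge cap {max_ridge}"
                ) from None
    if ridge > 0.0:
        logger.info("omnibus_multitrait: applied ridge %g to R", ridge)
    u = np.linalg.solve(c, z)
    q = float(u @ u)
    p = float(stats.chi2.sf(q, df=m))
    if q > 0.0:
        p = max(p, 5e-324)
    return q, p


def assoc_r2(beta: float, se: float, n: int) -> float:
    """Coefficient of determination of a single-variant association:
    R^2 = z^2 / (n - 2 + z^2) with z = beta/se. Lies in [0, 1)."""
    if not se > 0:
        raise ValueError("se must be > 0")
    if n <= 2:
        raise ValueError(f"need n > 2, got {n}")
    z2 = (beta / se) ** 2
    return z2 / (n - 2 + z2)


# ---------------------------------------------------------------------------
# Summary-statistics I/O (GWAS-SSF-like TSV)
# ---------------------------------------------------------------------------

SUMSTATS_COLUMNS = [
    "variant_id", "chromosome", "base_pair_location", "effect_allele",
    "other_allele", "beta", "standard_error", "p_value", "n",
    "effect_allele_frequency", "trait_id", "cohort_id",
]


def records_to_frame(records: Iterable[AssocRecord | MetaRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "variant_id": r.variant_id,
                "chromosome": r.chromosome,
                "base_pair_location": r.position,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "beta": r.beta,
                "standard_error": r.se,
                "p_value": r.p,
                "n": r.n,
                "effect_allele_frequency": r.eaf,
                "trait_id": r.trait_id,
                "cohort_id": getattr(r, "cohort_id", "META"),
            }
        )
    return pd.DataFrame(rows, columns=SUMSTATS_COLUMNS)


def write_sumstats(records: Iterable[AssocRecord | MetaRecord], path: str) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_sumstats(path: str) -> list[AssocRecord]:
    """Read a summary-statistics TSV (gzip-transparent via pandas)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(SUMSTATS_COLUMNS) - {"cohort_id"} - set(df.columns)
    if missing:
        raise ValueError(f"sumstats file {path} missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            AssocRecord(
                variant_id=str(row.variant_id),
                chromosome=str(row.chromosome),
                position=int(row.base_pair_location),
                effect_allele=str(row.effect_allele),
                other_allele=str(row.other_allele),
                trait_id=str(row.trait_id),
                cohort_id=str(getattr(row, "cohort_id", "")),
                beta=float(row.beta),
                se=float(row.standard_error),
                p=float(row.p_value),
                n=int(row.n),
                eaf=float(row.effect_allele_frequency),
            )
        )
    return records
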