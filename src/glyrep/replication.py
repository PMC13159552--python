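"""Replication cascade for multi-trait QTLs measured on two platforms.

Per locus: weighted Cauchy (ACAT) aggregation of per-trait association
p-values within each platform group, then a Fisher product combination
of the two group p-values, then a Bonferroni decision at
alpha / n_loci_tested.

The Fisher statistic X2 = -2(ln p1 + ln p2) is referred to chi-square
with 4 degrees of freedom (2k, k = 2 groups); the survival function is
evaluated in the closed form exp(-X2/2) * (1 + X2/2), carried in log
space so extreme inputs stay finite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: inputs are clamped into this interval before log/tan transforms
P_MIN = 1e-300
P_MAX = 1.0 - 1e-16

#: below this, tan{(0.5-p)pi} is evaluated as its tail expansion 1/(p*pi)
SMALL_P = 1e-15
#: above this Cauchy statistic, the combined p is evaluated as 1/(pi*T)
LARGE_T = 1e15

#: smallest positive subnormal double; floor for underflowing tail p-values
_TINY = 5e-324

FISHER_DF = 4


@dataclass(frozen=True)
class PlatformGroup:
    """A named trait panel over which Cauchy aggregation runs."""

    label: str  # "UHPLC-FD" or "MALDI-MS"
    trait_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.trait_ids:
            raise ValueError("platform group needs at least one trait")

    @property
    def n_traits(self) -> int:
        return len(self.trait_ids)

    @property
    def weight(self) -> float:
        """Equal per-trait aggregation weight 1/n_traits."""
        return 1.0 / self.n_traits


@dataclass(frozen=True)
class CauchyResult:
    """Cauchy-aggregated statistic and p-value for one locus and group."""

    locus: str
    group: str
    T: float
    p: float
    n_traits_used: int


@dataclass(frozen=True)
class FisherResult:
    """Fisher product combination across the two platform groups."""

    locus: str
    X2: float
    p: float
    log10_p: float
    threshold: float
    replicated: bool
    df: int = FISHER_DF


def _clamp_pvalues(p: np.ndarray, where: str) -> np.ndarray:
    lo = p < P_MIN
    hi = p > P_MAX
    n_clamped = int(lo.sum() + hi.sum())
    if n_clamped:
        logger.info("%s: clamped %d p-value(s) into [%g, %g]", where, n_clamped, P_MIN, P_MAX)
    return np.clip(p, P_MIN, P_MAX)


def cauchy_tan(p: np.ndarray) -> np.ndarray:
    """tan{(0.5 - p) * pi} with the tail expansion 1/(p*pi) for p < 1e-15."""
    p = np.asarray(p, dtype=float)
    out = np.empty_like(p)
    small = p < SMALL_P
    out[small] = 1.0 / (p[small] * math.pi)
    out[~small] = np.tan((0.5 - p[~small]) * math.pi)
    return out


def cauchy_combine(
    pvalues: Sequence[float],
    weights: Sequence[float] | None = None,
    locus: str = "",
    group: str = "",
    drop_missing: bool = True,
) -> CauchyResult:
    """Weighted Cauchy (ACAT) combination of p-values.

    T = sum_i w_i * tan{(0.5 - p_i) pi}; combined p = 0.5 - arctan(T)/pi,
    with the tail approximations noted in the module docstring. Valid
    under arbitrary dependence among the input tests.

    Missing p-values (NaN) are dropped when ``drop_missing`` is true
    (weights renormalized over the available traits); otherwise they
    raise. Default weights are equal, 1/n.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("cauchy_combine: empty p-value list")
    if weights is None:
        w = np.full(p.shape, 1.0 / p.size)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != p.shape:
            raise ValueError("weights and p-values have different lengths")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")

    missing = np.isnan(p)
    if missing.any():
        if not drop_missing:
            raise ValueError(
                f"cauchy_combine: {int(missing.sum())} missing p-value(s) in strict mode"
            )
        logger.info(
            "cauchy_combine %s/%s: dropped %d missing trait p-value(s)",
            locus, group, int(missing.sum()),
        )
        p, w = p[~missing], w[~missing]
        if p.size == 0:
            raise ValueError("cauchy_combine: all p-values missing")

    if (p <= 0).any() or (p > 1).any():
        bad = p[(p <= 0) | (p > 1)]
        raise ValueError(f"p-values must lie in (0, 1]; got {bad[:5]}")

    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("weights sum to zero")
    w = w / wsum

    p = _clamp_pvalues(p, f"cauchy_combine {locus}/{group}")
    T = float(np.sum(w * cauchy_tan(p)))
    if T > LARGE_T:
        combined = 1.0 / (math.pi * T)
    else:
        # atan2(1, T)/pi == 0.5 - atan(T)/pi, without the cancellation
        # the subtraction from 0.5 suffers for large positive T
        combined = math.atan2(1.0, T) / math.pi
    combined = min(max(combined, _TINY), P_MAX)
    return CauchyResult(locus=locus, group=group, T=T, p=combined, n_traits_used=int(p.size))


def fisher_combine(
    p_group1: float,
    p_group2: float,
    locus: str = "",
    threshold: float = float("nan"),
) -> FisherResult:
    """One-sided Fisher product combination of two group p-values.

    X2 = -2 (ln p1 + ln p2) referred to chi-square with 4 df; the
    survival function exp(-X2/2)(1 + X2/2) is evaluated via its
    logarithm so that inputs down to ~1e-300 give finite nonzero output.
    """
    for p in (p_group1, p_group2):
        if not (0.0 < p <= 1.0):
            if p == 0.0:
                raise ValueError(
                    "fisher_combine: p = 0 input; clamp upstream (e.g. to 1e-300)"
                )
            raise ValueError(f"fisher_combine: p-value {p} outside (0, 1]")
    x2 = -2.0 * (math.log(p_group1) + math.log(p_group2))
    # chi2(4) survival in closed form: exp(-x/2) * (1 + x/2)
    log_p = -x2 / 2.0 + math.log1p(x2 / 2.0)
    p = math.exp(log_p) if log_p > -745.0 else 0.0
    if p == 0.0:
        p = _TINY  # keep finite and nonzero; exact magnitude in log10_p
    p = min(p, 1.0)
    log10_p = log_p / math.log(10.0)
    replicated = bool(p < threshold) if math.isfinite(threshold) else False
    return FisherResult(
        locus=locus, X2=x2, p=p, log10_p=log10_p,
        threshold=threshold, replicated=replicated,
    )


@dataclass(frozen=True)
class LocusPanels:
    """Per-locus input to the cascade.

    Either per-group trait p-value panels (``panels``) or pre-aggregated
    group p-values (``aggregated``); exactly one must be provided.
    Optional genomic coordinates and a gene label ride along for output.
    """

    locus: str
    panels: Mapping[str, Sequence[float]] | None = None
    aggregated: Mapping[str, float] | None = None
    gene: str = ""
    chromosome: str = ""
    position: int = 0

    def __post_init__(self) -> None:
        if (self.panels is None) == (self.aggregated is None):
            raise ValueError("provide exactly one of panels or aggregated")


@dataclass
class ReplicationRow:
    """One line of the replication output table."""

    locus: str
    gene: str
    chromosome: str
    position: int
    cauchy: dict[str, CauchyResult]
    fisher: FisherResult | None
    skipped_reason: str = ""


@dataclass
class ReplicationTable:
    rows: list[ReplicationRow]
    threshold: float
    alpha: float
    n_loci_tested: int

    @property
    def n_replicated(self) -> int:
        return sum(1 for r in self.rows if r.fisher is not None and r.fisher.replicated)

    def summary(self) -> str:
        return (
            f"replicated {self.n_replicated} of {self.n_loci_tested} loci "
            f"at threshold {self.alpha}/{self.n_loci_tested} = {self.threshold:.3g}"
        )


def replicate_loci(
    loci: Sequence[LocusPanels],
    alpha: float = 0.05,
    groups: Sequence[str] = ("UHPLC-FD", "MALDI-MS"),
    strict_traits: bool = False,
) -> ReplicationTable:
    """Run the full cascade over a set of loci.

    threshold = alpha / n_loci_tested; per locus, each group panel is
    Cauchy-aggregated (pre-aggregated p-values pass through), the two
    group p-values are Fisher-combined, and the locus is flagged
    replicated iff the Fisher p falls below the threshold. A locus
    missing one of the groups fails that locus with a logged reason and
    does not count toward the Bonferroni denominator.
    """
    if not loci:
        raise ValueError("replicate_loci: no loci supplied")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1); got {alpha}")

    testable = []
    skipped: list[ReplicationRow] = []
    for lp in loci:
        available = set((lp.panels or lp.aggregated or {}).keys())
        missing = [g for g in groups if g not in available]
        if missing:
            reason = f"missing group(s): {', '.join(missing)}"
            logger.warning("locus %s skipped: %s", lp.locus, reason)
            skipped.append(
                ReplicationRow(
                    locus=lp.locus, gene=lp.gene, chromosome=lp.chromosome,
                    position=lp.position, cauchy={}, fisher=None,
                    skipped_reason=reason,
                )
            )
        else:
            testable.append(lp)

    n_tested = len(testable)
    if n_tested == 0:
        raise ValueError("replicate_loci: no locus has both group panels")
    threshold = alpha / n_tested

    rows: list[ReplicationRow] = []
    for lp in testable:
        cauchy: dict[str, CauchyResult] = {}
        for g in groups:
            if lp.aggregated is not None:
                p = float(lp.aggregated[g])
                if not (0.0 < p <= 1.0):
                    raise ValueError(
                        f"locus {lp.locus}: pre-aggregated p for {g} outside (0, 1]"
                    )
                cauchy[g] = CauchyResult(
                    locus=lp.locus, group=g,
                    T=float(cauchy_tan(np.array([p]))[0]),
                    p=p, n_traits_used=0,
                )
            else:
                cauchy[g] = cauchy_combine(
                    lp.panels[g], locus=lp.locus, group=g,
                    drop_missing=not strict_traits,
                )
        fisher = fisher_combine(
            cauchy[groups[0]].p, cauchy[groups[1]].p,
            locus=lp.locus, threshold=threshold,
        )
        rows.append(
            ReplicationRow(
                locus=lp.locus, gene=lp.gene, chromosome=lp.chromosome,
                position=lp.position, cauchy=cauchy, fisher=fisher,
            )
        )

    rows.extend(skipped)
    rows.sort(key=lambda r: (_chrom_key(r.chromosome), r.position, r.locus))
    table = ReplicationTable(
        rows=rows, threshold=threshold, alpha=alpha, n_loci_tested=n_tested
    )
    logger.info(table.summary())
    return table


def _chrom_key(chrom: str) -> tuple[int, str]:
    c = str(chrom).removeprefix("chr")
    try:
        return (int(c), "")
    except ValueError:
        return (10**6, c)
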