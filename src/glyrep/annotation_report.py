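"""Locus annotation by associated glycan spectrum and R-squared,
platform comparison, evidence-tally gene prioritization, and report
generation."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from glyrep.glycan_model import GlycanFeatures
from glyrep.replication import ReplicationTable

logger = logging.getLogger(__name__)

EXPRESSION_COLUMNS = ("hepatocytes", "plasma_cells")


@dataclass(frozen=True)
class AnnotationRecord:
    """Association of one locus with one trait, for annotation."""

    locus: str
    trait_id: str
    platform: str
    r2: float
    p: float
    features: GlycanFeatures | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 < 1.0):
            raise ValueError(f"R^2 must be in [0, 1); got {self.r2}")


def top_trait_table(
    annotations: Sequence[AnnotationRecord],
    loci: Sequence[str] | None = None,
    k: int = 3,
) -> pd.DataFrame:
    """Per locus, the k traits with the strongest association.

    Sorted by descending R^2; ties broken by ascending p, then lexical
    trait_id. Unknown loci yield an empty block with a warning.
    """
    by_locus: dict[str, list[AnnotationRecord]] = {}
    for a in annotations:
        by_locus.setdefault(a.locus, []).append(a)
    if loci is None:
        loci = sorted(by_locus)
    rows = []
    for locus in loci:
        anns = by_locus.get(locus)
        if not anns:
            logger.warning("top_trait_table: no annotations for locus %s", locus)
            continue
        ranked = sorted(anns, key=lambda a: (-a.r2, a.p, a.trait_id))[:k]
        for rank, a in enumerate(ranked, start=1):
            row = {
                "locus": locus, "rank": rank, "trait_id": a.trait_id,
                "platform": a.platform, "r2": a.r2, "p": a.p,
            }
            if a.features is not None:
                row.update(a.features.as_dict())
            rows.append(row)
    return pd.DataFrame(rows)


def platform_ratio(
    pairs: Sequence[tuple[float, float]],
) -> dict[str, float]:
    """Compare association strength between two platforms over matched
    (reference, comparison) R^2 pairs.

    Returns all three averaging conventions, labeled — ratio of sums,
    mean of per-pair ratios (zero-denominator pairs excluded and
    logged), geometric mean of ratios (pairs with a zero on either side
    excluded) — asserting no single convention as canonical.
    """
    if not pairs:
        raise ValueError("platform_ratio: no pairs supplied")
    ref = np.array([a for a, _ in pairs], dtype=float)
    cmp_ = np.array([b for _, b in pairs], dtype=float)
    out: dict[str, float] = {}
    if ref.sum() == 0:
        raise ValueError("platform_ratio: reference sum is zero")
    out["ratio_of_sums"] = float(cmp_.sum() / ref.sum())

    nonzero = ref > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("platform_ratio: %d zero-denominator pair(s) excluded", n_dropped)
    if not nonzero.any():
        raise ValueError("platform_ratio: no pairs with nonzero reference")
    out["mean_of_ratios"] = float(np.mean(cmp_[nonzero] / ref[nonzero]))

    both = nonzero & (cmp_ > 0)
    if both.any():
        out["geometric_mean_of_ratios"] = float(
            np.exp(np.mean(np.log(cmp_[both] / ref[both])))
        )
    else:
        out["geometric_mean_of_ratios"] = float("nan")
    out["n_pairs"] = float(len(pairs))
    out["n_pairs_used_mean"] = float(int(nonzero.sum()))
    return out


@dataclass
class EvidenceMatrix:
    """Boolean evidence table for candidate genes.

    ``table`` is indexed by gene; expression columns (hepatocytes,
    plasma_cells) are treated separately from evidence columns, which
    are free-form (e.g. glycosyltransferase, CDG, VEP-deleterious,
    DEPICT, SMR/HEIDI eQTL, pQTL colocalization, nearest gene).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        bad = [
            c for c in self.table.columns
            if not set(pd.unique(self.table[c])) <= {0, 1, True, False}
        ]
        if bad:
            raise ValueError(f"non-boolean evidence columns: {bad}")
        self.table = self.table.astype(bool)

    @property
    def evidence_columns(self) -> list[str]:
        return [c for c in self.table.columns if c not in EXPRESSION_COLUMNS]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EvidenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)


def prioritize_genes(evidence: EvidenceMatrix, min_evidence: int = 2) -> pd.DataFrame:
    """High-confidence candidate genes: expressed in hepatocytes OR
    plasma cells, AND supported by at least ``min_evidence`` evidence
    columns. Sorted by evidence count descending (then gene name)."""
    t = evidence.table
    expr_cols = [c for c in EXPRESSION_COLUMNS if c in t.columns]
    if not expr_cols:
        raise ValueError(f"evidence matrix needs expression columns {EXPRESSION_COLUMNS}")
    expressed = t[expr_cols].any(axis=1)
    counts = t[evidence.evidence_columns].sum(axis=1)
    keep = expressed & (counts >= min_evidence)
    out = pd.DataFrame(
        {"gene": t.index[keep], "n_evidence": counts[keep].astype(int).to_numpy()}
    )
    return out.sort_values(
        ["n_evidence", "gene"], ascending=[False, True], ignore_index=True
    )


# ---------------------------------------------------------------------------
# Report generation
# ---------------------------------------------------------------------------

def replication_table_frame(table: ReplicationTable) -> pd.DataFrame:
    """Flatten a ReplicationTable into the output TSV layout (printed
    table column order: locus, gene, per-group T and p, X2, Fisher p,
    threshold, decision)."""
    rows = []
    for r in table.rows:
        row: dict[str, object] = {
            "locus": r.locus, "gene": r.gene,
            "chromosome": r.chromosome, "position": r.position,
        }
        for g, c in r.cauchy.items():
            tag = g.replace("-", "_").lower()
            row[f"T_{tag}"] = c.T
            row[f"p_cauchy_{tag}"] = c.p
            row[f"n_traits_{tag}"] = c.n_traits_used
        if r.fisher is not None:
            row["X2"] = r.fisher.X2
            row["p_fisher"] = r.fisher.p
            row["log10_p_fisher"] = r.fisher.log10_p
            row["threshold"] = r.fisher.threshold
            row["replicated"] = r.fisher.replicated
        else:
            row["skipped_reason"] = r.skipped_reason
        rows.append(row)
    return pd.DataFrame(rows)


def config_hash(config: Mapping | None) -> str:
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_report(
    out_dir: str | Path,
    replication: ReplicationTable | None = None,
    annotations: Sequence[AnnotationRecord] | None = None,
    prioritized: pd.DataFrame | None = None,
    config: Mapping | None = None,
) -> dict[str, Path]:
    """Emit the TSV bundle plus a deterministic Markdown summary.

    The summary body carries the tool version and a config hash but no
    timestamp, so reruns on identical inputs are byte-identical.
    """
    from glyrep import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    lines = [
        "# Replication report",
        "",
        f"- tool version: {__version__}",
        f"- config hash: {config_hash(config)}",
        "",
    ]
    if replication is not None:
        df = replication_table_frame(replication)
        paths["replication"] = out / "replication.tsv"
        df.to_csv(paths["replication"], sep="\t", index=False)
        lines += [
            "## Replication",
            "",
            f"- {replication.summary()}",
        ]
        for r in replication.rows:
            if r.fisher is None:
                verdict = f"skipped ({r.skipped_reason})"
            else:
                verdict = "REPLICATED" if r.fisher.replicated else "not replicated"
            label = f"{r.locus} ({r.gene})" if r.gene else r.locus
            p_txt = f"p_fisher={r.fisher.p:.3g}" if r.fisher is not None else ""
            lines.append(f"  - {label}: {verdict} {p_txt}".rstrip())
        lines.append("")
    else:
        lines += ["## Replication", "", "- zero loci supplied", ""]

    if annotations:
        top = top_trait_table(annotations)
        paths["annotations"] = out / "top_traits.tsv"
        top.to_csv(paths["annotations"], sep="\t", index=False)
        lines += [
            "## Annotation",
            "",
            f"- {len(annotations)} locus-trait annotations across "
            f"{top['locus'].nunique() if not top.empty else 0} loci",
            "",
        ]
    if prioritized is not None:
        paths["prioritized"] = out / "prioritized_genes.tsv"
        prioritized.to_csv(paths["prioritized"], sep="\t", index=False)
        genes = ", ".join(prioritized["gene"]) if len(prioritized) else "none"
        lines += [
            "## Gene prioritization",
            "",
            f"- {len(prioritized)} high-confidence gene(s): {genes}",
            "",
        ]
    paths["summary"] = out / "summary.md"
    paths["summary"].write_text("\n".join(lines) + "\n")
    return paths
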