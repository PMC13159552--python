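"""Pipeline orchestration: simulate -> derive traits -> per-cohort GWAS
-> per-platform IVW meta-analysis -> Cauchy/Fisher replication cascade
-> report. Every stage persists a plain TSV so any stage can instead be
fed from external real data."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from glyrep import association as assoc
from glyrep import glycan_model as gm
from glyrep import synthetic_data as sd
from glyrep.annotation_report import write_report
from glyrep.config import PipelineConfig
from glyrep.replication import LocusPanels, ReplicationTable, replicate_loci

logger = logging.getLogger(__name__)


def preprocess_phenotypes(
    peaks: pd.DataFrame,
    covariates: pd.DataFrame,
    trait_defs: list[gm.TraitDefinition],
    rint_offset: float = 3.0 / 8.0,
) -> pd.DataFrame:
    """Evaluate traits from direct peaks, adjust for sex and age, and
    quantile-transform the residuals to normal. Constant traits are
    dropped with a warning."""
    traits = {}
    for defn in trait_defs:
        traits[defn.trait_id] = gm.evaluate_derived_trait(defn, peaks)
    values = pd.DataFrame(traits, index=peaks.index)
    X = np.column_stack(
        [
            np.ones(len(values)),
            covariates["age"].to_numpy(float),
            covariates["sex"].to_numpy(float),
        ]
    )
    out = {}
    for col in values.columns:
        y = values[col].to_numpy(float)
        if np.isnan(y).any():
            # missing trait values excluded pairwise: fill with column mean
            # before residualization would bias; drop samples instead is
            # heavier — for simulated data missing should not occur
            logger.warning("trait %s: %d missing values", col, int(np.isnan(y).sum()))
            y = np.where(np.isnan(y), np.nanmean(y), y)
        if np.all(y == y[0]):
            logger.warning("trait %s constant after QC; dropped", col)
            continue
        resid = gm.residualize_covariates(y, X)
        out[col] = gm.rank_inverse_normal(resid, offset=rint_offset)
    return pd.DataFrame(out, index=values.index)


def cohort_gwas(
    cohort: sd.CohortData,
    phenotypes: pd.DataFrame,
) -> list[assoc.AssocRecord]:
    """Vectorized per-variant, per-trait association scan for one cohort."""
    G = cohort.dosages.to_numpy(float)
    Y = phenotypes.to_numpy(float)
    beta, se, p = assoc.assoc_scan(G, Y)
    n = G.shape[0]
    records = []
    for vi, variant in enumerate(cohort.dosages.columns):
        eaf = float(G[:, vi].mean() / 2.0)
        for ti, trait in enumerate(phenotypes.columns):
            untestable = bool(np.isnan(beta[vi, ti]))
            records.append(
                assoc.AssocRecord(
                    variant_id=str(variant), chromosome="1", position=1000 + vi,
                    effect_allele="A", other_allele="G",
                    trait_id=str(trait), cohort_id=cohort.cohort_id,
                    beta=float(beta[vi, ti]), se=float(se[vi, ti]),
                    p=float(p[vi, ti]), n=n, eaf=eaf, untestable=untestable,
                )
            )
    return records


def meta_analyze(
    records: list[assoc.AssocRecord], maf_floor: float = 0.01
) -> list[assoc.MetaRecord]:
    """Harmonize then IVW-meta-analyze per variant-trait pair."""
    aligned, log = assoc.harmonize_records(records, maf_floor=maf_floor)
    logger.info("harmonization: %s", dict(log))
    by_key: dict[tuple[str, str], list[assoc.AssocRecord]] = {}
    for r in aligned:
        by_key.setdefault((r.variant_id, r.trait_id), []).append(r)
    return [assoc.ivw_meta(v) for v in by_key.values()]


def run_pipeline(config: PipelineConfig) -> ReplicationTable:
    """Run every stage and persist intermediate TSVs under
    ``config.out_dir``. Returns the replication table."""
    if config.sim is None:
        raise ValueError("run_pipeline requires a simulation config (sim)")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    platforms = sorted({c.platform for c in config.sim.cohorts})
    if len(platforms) != 2:
        raise ValueError("the replication cascade needs cohorts on exactly 2 platforms")

    meta_by_platform: dict[str, list[assoc.MetaRecord]] = {}
    for platform in platforms:
        cohort_records: list[assoc.AssocRecord] = []
        for spec in config.sim.cohorts:
            if spec.platform != platform:
                continue
            cohort = sd.simulate_cohort(config.sim, spec.cohort_id)
            sd.write_cohort(cohort, out / "cohorts")
            defs = sd.default_trait_definitions(platform)
            pheno = preprocess_phenotypes(
                cohort.peaks, cohort.covariates, defs, rint_offset=config.rint_offset
            )
            pheno.rename_axis("sample_id").to_csv(
                out / "cohorts" / f"{spec.cohort_id}.phenotypes.tsv", sep="\t"
            )
            records = cohort_gwas(cohort, pheno)
            assoc.write_sumstats(
                records, str(out / "cohorts" / f"{spec.cohort_id}.sumstats.tsv")
            )
            cohort_records.extend(records)
        meta = meta_analyze(cohort_records, maf_floor=config.maf_floor)
        meta_by_platform[platform] = meta
        assoc.write_sumstats(
            meta, str(out / f"meta.{platform.replace('-', '_')}.tsv")
        )

    loci_ids = [f"locus{i}" for i in range(config.sim.n_loci)]
    panels_rows = []
    loci = []
    for locus in loci_ids:
        panels = {}
        for platform, meta in meta_by_platform.items():
            ps = [m.p for m in meta if m.variant_id == locus]
            panels[platform] = ps
            for m in meta:
                if m.variant_id == locus:
                    panels_rows.append(
                        {"locus_id": locus, "group": platform,
                         "trait_id": m.trait_id, "p": m.p}
                    )
        loci.append(LocusPanels(locus=locus, panels=panels))
    pd.DataFrame(panels_rows).to_csv(out / "panels.tsv", sep="\t", index=False)

    table = replicate_loci(
        loci, alpha=config.alpha, groups=tuple(platforms),
        strict_traits=config.strict_traits,
    )
    write_report(out / "report", replication=table, config=config.to_dict())
    return table
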