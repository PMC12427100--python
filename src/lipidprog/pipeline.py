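"""End-to-end orchestration of the lipidomics prognosis analysis.

Stage order: preprocess -> (optional) two-group differential expression +
characteristic enrichment -> lipidome subtyping -> subtype-conditioned
differential expression + enrichment -> survival screen + HR-direction
enrichment -> lipid-gene correlation, class gene sets and ether-class
overlap.  Stages whose inputs are absent (no clinical table, no gene
matrix) are skipped with a logged notice; every emitted table carries a
sidecar JSON with the parameters and seed that produced it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as lio
from .containers import AbundanceMatrix, ClinicalTable
from .diffexp import differential_lipids, significant_sets
from .enrichment import enrich_characteristics, enrich_gene_sets, enrich_survival_direction
from .errors import ConfigError
from .nomenclature import ETHER_CLASSES, characteristic_table, parse_many
from .preprocess import preprocess
from .subtype import assign_subtypes
from .survival import km_curve, logrank_test, screen_features
from .transomics import class_gene_sets, correlate_all, overlap_genes, rank_classes

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and stage parameters of one pipeline run."""

    lipid_matrix: str | Path | None = None
    clinical: str | Path | None = None
    gene_matrix: str | Path | None = None
    gmt: str | Path | None = None
    max_missing: float = 0.70
    alpha: float = 0.05
    lfc_threshold: float = 1.0
    perplexity: float = 15.0
    tsne_iterations: int = 3000
    k: int = 2
    rho_threshold: float = 0.4
    chain_bins: list[int] | None = None
    db_bins: list[int] | None = None
    paired: bool = False
    strict_names: bool = False
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0 <= self.max_missing < 1:
            raise ConfigError("max_missing must be in [0, 1)")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.k != 2:
            raise ConfigError("only k=2 subtyping is supported")
        if self.rho_threshold < 0 or self.rho_threshold >= 1:
            raise ConfigError("rho_threshold must be in [0, 1)")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)


def run_pipeline(
    cfg: RunConfig,
    outdir: str | Path,
    lipids: AbundanceMatrix | None = None,
    clinical: ClinicalTable | None = None,
    genes: pd.DataFrame | None = None,
) -> dict[str, object]:
    """Run every applicable stage; write TSV reports under ``outdir``.

    Matrices may be passed in-memory (overriding the config paths).
    Returns a dict of the in-memory stage results.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {**dataclasses.asdict(cfg), "stage": None}
    meta = {k: (str(v) if isinstance(v, Path) else v) for k, v in meta.items()}
    results: dict[str, object] = {}

    if lipids is None:
        if cfg.lipid_matrix is None:
            raise ConfigError("no lipid matrix given")
        lipids = lio.read_matrix(cfg.lipid_matrix)
    groups = None
    if clinical is None and cfg.clinical is not None:
        clinical, groups = lio.read_clinical(cfg.clinical)
    if groups is not None and lipids.sample_groups is None:
        lipids.sample_groups = groups
    if genes is None and cfg.gene_matrix is not None:
        genes = lio.read_expression(cfg.gene_matrix)

    # --- nomenclature + preprocessing -----------------------------------
    species, failed = parse_many(lipids.species_ids, strict=cfg.strict_names)
    if failed:
        lipids = lipids.with_data(lipids.data.drop(index=failed))
    clean = preprocess(lipids, max_missing_rate=cfg.max_missing)
    chars = characteristic_table(
        [sp for sp in species if sp.raw_name in set(clean.species_ids)],
        chain_bins=cfg.chain_bins, db_bins=cfg.db_bins,
    )
    results["matrix"] = clean
    results["characteristics"] = chars
    lio.write_table(chars.reset_index(), outdir / "characteristics.tsv",
                    {**meta, "stage": "nomenclature", "n_unparseable": len(failed)})
    clean.data.to_csv(outdir / "matrix.clean.tsv", sep="\t",
                      float_format="%.6g", index_label="species_id")

    # --- two-group differential expression (given groups) ---------------
    if clean.sample_groups is not None and clean.sample_groups.reindex(clean.sample_ids).nunique() == 2:
        de = differential_lipids(clean, alpha=cfg.alpha,
                                 lfc_threshold=cfg.lfc_threshold, paired=cfg.paired)
        up, down = significant_sets(de)
        enr = enrich_characteristics(chars, up, down, alpha=cfg.alpha)
        results["diffexp"] = de
        results["enrichment"] = enr
        lio.write_table(de.sort_values("adj_p_value"), outdir / "diffexp.tsv",
                        {**meta, "stage": "diffexp"})
        lio.write_table(enr, outdir / "enrichment.tsv", {**meta, "stage": "enrichment"})
    else:
        logger.info("no two-group sample labels: group diffexp stage skipped")

    # --- subtyping + subtype-conditioned DE -----------------------------
    assignments = assign_subtypes(clean, chars, seed=cfg.seed,
                                  perplexity=cfg.perplexity, iterations=cfg.tsne_iterations)
    results["subtypes"] = assignments
    lio.write_table(assignments.reset_index(), outdir / "subtypes.tsv",
                    {**meta, "stage": "subtype"})

    sub_groups = assignments["cluster"]
    de_sub = differential_lipids(clean, groups=sub_groups, alpha=cfg.alpha,
                                 lfc_threshold=cfg.lfc_threshold)
    up_sub, down_sub = significant_sets(de_sub)
    enr_sub = enrich_characteristics(chars, up_sub, down_sub, alpha=cfg.alpha)
    results["diffexp_subtype"] = de_sub
    results["enrichment_subtype"] = enr_sub
    lio.write_table(de_sub.sort_values("adj_p_value"), outdir / "diffexp.subtype.tsv",
                    {**meta, "stage": "diffexp_subtype"})
    lio.write_table(enr_sub, outdir / "enrichment.subtype.tsv",
                    {**meta, "stage": "enrichment_subtype"})

    # --- survival --------------------------------------------------------
    if clinical is not None:
        screen = screen_features(clean, clinical, alpha=cfg.alpha)
        enr_surv = enrich_survival_direction(screen, chars, alpha=cfg.alpha)
        results["survival_screen"] = screen
        results["survival_enrichment"] = enr_surv
        lio.write_table(screen.sort_values("logrank_p"), outdir / "survival.screen.tsv",
                        {**meta, "stage": "survival"})
        lio.write_table(enr_surv, outdir / "survival.enrichment.tsv",
                        {**meta, "stage": "survival_enrichment"})
        # subtype KM comparison
        shared = assignments.index.intersection(clinical.table.index)
        if len(shared) and clinical.event.loc[shared].any():
            stat, p = logrank_test(sub_groups.loc[shared], clinical)
            curves = km_curve(sub_groups.loc[shared], clinical)
            km = pd.concat([c.assign(group=lab) for lab, c in curves.items()])
            results["km_subtype"] = km
            results["km_logrank_p"] = p
            lio.write_table(km, outdir / "km.subtype.tsv",
                            {**meta, "stage": "km_subtype", "logrank_chi2": stat, "logrank_p": p})
    else:
        logger.info("no clinical table: survival stage skipped")

    # --- trans-omics ------------------------------------------------------
    if genes is not None:
        corr = correlate_all(clean, genes, rho_threshold=cfg.rho_threshold,
                             alpha=cfg.alpha, significant_only=True)
        sets = class_gene_sets(corr, chars)
        ranking = rank_classes(sets)
        ether_present = [c for c in ranking["class"] if c in ETHER_CLASSES][:3]
        overlap = overlap_genes(sets, ether_present) if ether_present else set()
        results["correlations"] = corr
        results["class_gene_sets"] = sets
        results["class_ranking"] = ranking
        results["overlap_genes"] = overlap
        lio.write_table(corr, outdir / "correlations.sig.tsv", {**meta, "stage": "transomics"})
        lio.write_table(ranking, outdir / "class_gene_counts.tsv",
                        {**meta, "stage": "transomics"})
        (outdir / "overlap_genes.txt").write_text("\n".join(sorted(overlap)) + "\n")
        if cfg.gmt is not None:
            gene_sets = lio.read_gmt(cfg.gmt)
            enr_genes = enrich_gene_sets(overlap, set(genes.index), gene_sets, alpha=cfg.alpha)
            results["gene_set_enrichment"] = enr_genes
            lio.write_table(enr_genes, outdir / "gene_set_enrichment.tsv",
                            {**meta, "stage": "gene_set_enrichment"})
    else:
        logger.info("no gene matrix: trans-omics stage skipped")

    (outdir / "run_metadata.json").write_text(
        json.dumps({k: v for k, v in meta.items() if k != "stage"}, indent=1, sort_keys=True)
    )
    return results
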