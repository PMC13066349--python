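"""Full analysis pipeline: ages → divergence → sets → enrichment report.

The pipeline mirrors the study design it implements: assign each gene a
phylostratigraphic age from ortholog hits; attach (or estimate, when
codon alignments are supplied) per-gene divergence indices; construct the
study sets (receptor set, its GPCR and non-GPCR partitions, the
development-keyword subset); then test each set against its background
for enrichment at the focal age stage and at the low-DI threshold, plus a
2×2 independence test of the DI partition against development
association.  Every filtering decision (genes without hits, missing
values excluded from denominators, dS = 0 pairs) is logged.

Outputs are deterministic: identical inputs and configuration produce
byte-identical report files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .divergence import PairwiseCodonAlignment, classify_selection, compute_di, estimate_dnds
from .enrichment import (
    EnrichmentResult,
    enrichment_test,
    partition_2x2_test,
    round_half_up,
    threshold_share,
)
from .genesets import GeneSet, development_filter, difference, intersect
from .io import PipelineConfig, _meta_line, universe_records
from .strata import StratumLadder, age_distribution, assign_pai_table, default_ladder

__all__ = ["PipelineResult", "run_pipeline", "write_report"]


@dataclass
class PipelineResult:
    """Everything the pipeline computes, ready for reporting."""

    universe: pd.DataFrame
    sets: dict[str, GeneSet]
    report: pd.DataFrame
    table_2x2: dict | None
    pai_percent: pd.DataFrame
    di_shares: pd.DataFrame
    dnds: list = field(default_factory=list)
    di_records: list = field(default_factory=list)
    log: list[str] = field(default_factory=list)


def run_pipeline(
    universe: pd.DataFrame,
    config: PipelineConfig | None = None,
    hits: pd.DataFrame | None = None,
    species_map: Mapping[str, int] | None = None,
    sets: Mapping[str, GeneSet] | None = None,
    alignments: Sequence[PairwiseCodonAlignment] | None = None,
    ladder: StratumLadder | None = None,
    study_set: str = "Receptors_80",
    gpcr_set: str = "allGPCR_420",
) -> PipelineResult:
    """Run the full analysis over one universe.

    ``universe`` must follow the universe-table schema.  When ``hits`` and
    ``species_map`` are given, ages are (re)assigned from the hit table at
    ``config.identity_threshold``; otherwise the table's ``pai`` column is
    used as-is.  When ``alignments`` are given, per-gene divergence
    indices are estimated from them and override the ``di`` column for
    those genes.  ``sets`` must contain the study set; the GPCR background
    set defaults to the ``is_gpcr`` flag when not supplied.
    """
    config = config or PipelineConfig()
    ladder = ladder or default_ladder()
    log: list[str] = []

    if universe is None or len(universe) == 0:
        raise ValueError("empty input: universe has no genes")
    if universe["gene_id"].duplicated().any():
        dup = universe.loc[universe["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene id {dup!r}")
    universe = universe.copy().reset_index(drop=True)

    # --- stage 1: phylostratigraphic ages ------------------------------------
    if hits is not None:
        if species_map is None:
            raise ValueError("stage pai: species_map required when hits are given")
        pai = assign_pai_table(
            hits, species_map, universe["gene_id"], config.identity_threshold, ladder
        )
        no_hit = int((~universe["gene_id"].isin(hits["gene_id"])).sum())
        if no_hit:
            log.append(
                f"pai: {no_hit} genes without any ortholog hit assigned terminal rank {ladder.max_rank}"
            )
        universe["pai"] = universe["gene_id"].map(pai).astype("Int64")

    # --- stage 2: divergence (optional estimation from alignments) -----------
    dnds_estimates = []
    di_records = []
    if alignments:
        by_gene: dict[str, list] = {}
        for aln in alignments:
            est = estimate_dnds(aln)
            dnds_estimates.append(est)
            by_gene.setdefault(aln.gene_id, []).append(est)
            if est.ratio is None:
                log.append(f"dnds: pair {aln.gene_id}/{aln.species_label} has dS=0; ratio undefined")
            if est.n_discarded:
                log.append(
                    f"dnds: pair {aln.gene_id}/{aln.species_label} discarded "
                    f"{est.n_discarded} gapped/ambiguous codon columns"
                )
        di_map: dict[str, float | None] = {}
        for gene_id in sorted(by_gene):
            rec = compute_di(by_gene[gene_id], neutrality_band=config.neutrality_band)
            di_records.append(rec)
            di_map[gene_id] = rec.di
            if rec.di is None:
                log.append(f"di: gene {gene_id} has no defined pair ratio; DI missing")
        est_di = universe["gene_id"].map(di_map)
        universe.loc[est_di.notna(), "di"] = est_di[est_di.notna()]

    universe["selection_class"] = [
        classify_selection(None if pd.isna(v) else float(v), config.neutrality_band)
        for v in universe["di"]
    ]

    # --- stage 3: set constructions -------------------------------------------
    all_set = GeneSet.from_ids("allCDS", universe["gene_id"])
    sets = dict(sets or {})
    if study_set not in sets:
        raise ValueError(f"stage sets: study set {study_set!r} not provided")
    receptors = sets[study_set]
    if gpcr_set in sets:
        gpcrs = sets[gpcr_set]
    else:
        gpcrs = GeneSet.from_ids(gpcr_set, universe.loc[universe["is_gpcr"], "gene_id"])
        log.append(f"sets: {gpcr_set} derived from is_gpcr flag ({len(gpcrs)} genes)")
    outside = receptors.members - all_set.members
    if outside:
        raise ValueError(f"set {receptors.name} contains genes outside the universe: {sorted(outside)[:3]}")

    app_gpcr = intersect(receptors, gpcrs, name=f"appGPCR_{len(receptors.members & gpcrs.members)}")
    app_not_gpcr = difference(receptors, gpcrs, name=f"app_not_GPCR_{len(receptors.members - gpcrs.members)}")
    rec_records = [r for r in universe_records(universe) if r.gene_id in receptors]
    dev = development_filter(rec_records, name=f"app_Development_{sum(1 for r in rec_records if r.is_development)}")
    derived = {
        "allCDS": all_set,
        receptors.name: receptors,
        gpcrs.name: gpcrs,
        app_gpcr.name: app_gpcr,
        app_not_gpcr.name: app_not_gpcr,
        dev.name: dev,
    }

    # --- stage 4: distributions and enrichment --------------------------------
    idx = universe.set_index("gene_id")
    pai_series = idx["pai"]
    di_series = idx["di"]
    n_missing_pai = int(pai_series.isna().sum())
    n_missing_di = int(di_series.isna().sum())
    if n_missing_pai:
        log.append(f"enrich: {n_missing_pai} genes with missing PAI excluded from age denominators")
    if n_missing_di:
        log.append(f"enrich: {n_missing_di} genes with missing DI excluded from DI denominators")

    def pai_of(gs: GeneSet) -> pd.Series:
        s = pai_series.loc[sorted(gs.members)]
        return s.dropna().astype(int)

    def di_of(gs: GeneSet) -> pd.Series:
        return di_series.loc[sorted(gs.members)].dropna().astype(float)

    pai_rows = {}
    for name in (all_set.name, receptors.name, gpcrs.name, app_gpcr.name, app_not_gpcr.name):
        values = pai_of(derived[name])
        if len(values):
            dist = age_distribution(values, ladder)
            pai_rows[name] = {rank: dist.percent[rank] for rank in ladder.ranks}
    pai_percent = pd.DataFrame(pai_rows).T
    pai_percent.index.name = "set"

    results: list[EnrichmentResult] = []

    def add_pai_test(study: GeneSet, background: GeneSet, ranks: tuple[int, ...]) -> None:
        sp, bp = pai_of(study), pai_of(background)
        if not len(sp) or not len(bp):
            log.append(f"enrich: skipped PAI test {study.name} vs {background.name} (no ages)")
            return
        category = f"PAI={ranks[0]}" if len(ranks) == 1 else "PAI in {" + ",".join(map(str, ranks)) + "}"
        try:
            results.append(
                enrichment_test(
                    study.name, background.name, category,
                    observed=int(sp.isin(ranks).sum()), n=len(sp),
                    background_in=int(bp.isin(ranks).sum()), background_total=len(bp),
                )
            )
        except ValueError as err:
            log.append(f"enrich: skipped {category} test {study.name} vs {background.name} ({err})")

    def add_di_test(study: GeneSet, background: GeneSet) -> None:
        sd, bd = di_of(study), di_of(background)
        if not len(sd) or not len(bd):
            log.append(f"enrich: skipped DI test {study.name} vs {background.name} (no DI values)")
            return
        try:
            results.append(
                enrichment_test(
                    study.name, background.name, f"DI<={config.di_cut:g}",
                    observed=int((sd <= config.di_cut).sum()), n=len(sd),
                    background_in=int((bd <= config.di_cut).sum()), background_total=len(bd),
                )
            )
        except ValueError as err:
            log.append(f"enrich: skipped DI test {study.name} vs {background.name} ({err})")

    focus = (config.pai_focus_rank,)
    add_pai_test(receptors, all_set, focus)
    add_pai_test(gpcrs, all_set, focus)
    add_pai_test(app_gpcr, gpcrs, focus)
    add_pai_test(app_not_gpcr, all_set, tuple(config.pai_focus_ranks_alt))
    add_di_test(receptors, all_set)
    add_di_test(app_gpcr, gpcrs)

    report = pd.DataFrame(
        [
            {
                "set": r.set_name, "background": r.background_name, "category": r.category,
                "observed": r.observed, "expected": round(r.expected, 2), "n": r.n,
                "chi2": round(r.chi2, 4), "df": r.df, "p": r.p_value,
                "tier": r.tier, "direction": r.direction,
            }
            for r in results
        ]
    )

    # --- stage 5: DI shares and the 2x2 development split ----------------------
    share_rows = []
    for name in (all_set.name, receptors.name, gpcrs.name, app_gpcr.name):
        values = di_of(derived[name])
        if len(values):
            count, percent = threshold_share(values, config.di_cut)
            above_1 = int((values > 1.0).sum())
            share_rows.append(
                {
                    "set": name, "n": len(values),
                    "at_or_below_cut": count, "percent_at_or_below": round_half_up(percent, 1),
                    "above_1": above_1, "percent_above_1": round_half_up(100.0 * above_1 / len(values), 2),
                }
            )
    di_shares = pd.DataFrame(share_rows)

    table_2x2 = None
    rec_with_di = [r for r in rec_records if r.di is not None]
    if rec_with_di:
        try:
            obs, exp, chi2, df_, p = partition_2x2_test(
                rec_with_di,
                row_predicate=lambda g: g.di <= config.di_cut,
                col_predicate=lambda g: g.is_development,
            )
            table_2x2 = {
                "rows": [f"DI<={config.di_cut:g}", f"DI>{config.di_cut:g}"],
                "cols": ["development", "other"],
                "observed": obs.astype(int).tolist(),
                "expected": np.round(exp, 2).tolist(),
                "chi2": round(chi2, 4), "df": df_, "p": p,
            }
        except ValueError as err:
            log.append(f"enrich: 2x2 development test skipped ({err})")
    else:
        log.append("enrich: 2x2 development test skipped (all DI missing in study set)")

    return PipelineResult(
        universe=universe, sets=derived, report=report, table_2x2=table_2x2,
        pai_percent=pai_percent, di_shares=di_shares,
        dnds=dnds_estimates, di_records=di_records, log=log,
    )


def write_report(result: PipelineResult, out_dir: str | Path, config: PipelineConfig | None = None) -> None:
    """Write the report bundle: TSV + JSON mirror + per-gene table + log.

    Files carry no timestamps; identical runs are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = _meta_line(config)

    with open(out / "enrichment.tsv", "w", encoding="utf-8") as fh:
        fh.write(meta)
        result.report.to_csv(fh, sep="\t", index=False, float_format="%.6g")

    with open(out / "pai_distribution.tsv", "w", encoding="utf-8") as fh:
        fh.write(meta)
        result.pai_percent.round(4).to_csv(fh, sep="\t")

    with open(out / "di_shares.tsv", "w", encoding="utf-8") as fh:
        fh.write(meta)
        result.di_shares.to_csv(fh, sep="\t", index=False, float_format="%.6g")

    genes = result.universe[["gene_id", "pai", "di", "selection_class"]]
    with open(out / "gene_evolution.tsv", "w", encoding="utf-8") as fh:
        fh.write(meta)
        genes.to_csv(fh, sep="\t", index=False, float_format="%.6g")

    payload = {
        "sets": {name: len(gs) for name, gs in sorted(result.sets.items())},
        "enrichment": result.report.to_dict(orient="records"),
        "development_2x2": result.table_2x2,
        "di_shares": result.di_shares.to_dict(orient="records"),
    }
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")

    with open(out / "pipeline_log.txt", "w", encoding="utf-8") as fh:
        for line in result.log:
            fh.write(line + "\n")
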