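"""End-to-end orchestration over synthetic cohorts.

Chains the pipeline stages (catalog -> pairs -> scores) on a simulated
study and measures recovery of the planted truth.  The catalog built from
transcript calls carries its own enhancer ids, so cohort matrices keyed by
the generator's ids are re-keyed by coordinate matching before pairing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import calling, modulators, pairing, scoring
from .simulate import SimResult


@dataclass
class PipelineRun:
    catalog: calling.EnhancerCatalog
    truth_to_catalog: dict[str, str | None]
    candidates: pd.DataFrame
    pairs: pd.DataFrame


def build_catalog(sim: SimResult) -> tuple[calling.EnhancerCatalog, dict[str, str | None]]:
    """Catalog from the simulated calls, plus truth-id -> catalog-id map."""
    cfg = sim.config
    catalog = calling.call_enhancers(sim.calls, sim.genome.genes, cfg.replicate_map())
    matched = pairing.match_regions(catalog.regions, sim.truth.enhancers)
    truth_to_catalog = {
        sim.truth.enhancers.iloc[pos]["enhancer_id"]: cat_id
        for pos, cat_id in matched.items()
    }
    return catalog, truth_to_catalog


def rekeyed_matrices(sim: SimResult, truth_to_catalog: dict) -> pairing.CohortMatrices:
    """Cohort matrices re-indexed from generator enhancer ids to catalog ids."""
    rename = {t: c for t, c in truth_to_catalog.items() if c is not None}
    mats = sim.cohort.to_matrices()
    return pairing.CohortMatrices(
        expression=mats.expression,
        atac=mats.atac.rename(index=rename),
        methylation=mats.methylation.rename(index=rename),
        erna=mats.erna.rename(index=rename),
        sample_type=mats.sample_type,
    )


def run_pairing(sim: SimResult, window: int = 500_000, alpha: float = 0.05,
                min_abs_r: float = 0.3) -> PipelineRun:
    catalog, truth_to_catalog = build_catalog(sim)
    mats = rekeyed_matrices(sim, truth_to_catalog)
    candidates = pairing.candidate_pairs(catalog.regions, sim.genome.genes, window)
    pairs = pairing.fdr_filter(pairing.correlate_pairs(candidates, mats), alpha, min_abs_r)
    return PipelineRun(catalog, truth_to_catalog, candidates, pairs)


def pair_recovery(sim: SimResult, run: PipelineRun) -> dict:
    """Recovery of planted pair records and realized false-discovery rate.

    A planted record is the (catalog enhancer, gene, planted modality)
    combination in one cancer type; everything else scored by the screen is
    null by construction.
    """
    cancer_types = sim.cohort.sample_map.unique()
    planted_keys = set()
    for row in sim.truth.pairs.itertuples(index=False):
        cat_id = run.truth_to_catalog.get(row.enhancer_id)
        for ct in cancer_types:
            planted_keys.add((cat_id, row.gene_id, row.modality, ct))
    key_cols = ["enhancer_id", "gene_id", "modality", "cancer_type"]
    keys = list(map(tuple, run.pairs[key_cols].itertuples(index=False)))
    is_planted = np.array([k in planted_keys for k in keys])
    functional = run.pairs["functional"].to_numpy()
    n_func = int(functional.sum())
    n_false = int((functional & ~is_planted).sum())
    return {
        "n_planted_records": len(planted_keys),
        "n_planted_recovered": int((functional & is_planted).sum()),
        "recovery_rate": float((functional & is_planted).sum() / max(1, len(planted_keys))),
        "n_null_records": int((~is_planted).sum()),
        "n_false_positives": n_false,
        "realized_fdr": n_false / n_func if n_func else 0.0,
        "n_functional": n_func,
    }


def immune_ees(sim: SimResult, run: PipelineRun, cancer_type: str) -> tuple:
    """EES of the planted immune gene set in one cancer type, and its
    correlation against the infiltration columns."""
    cmax = scoring.cor_max_per_gene(run.pairs, cancer_type)
    sample_map = sim.cohort.sample_map
    ct_samples = list(sample_map.index[sample_map == cancer_type])
    universe = set(sim.cohort.expression.index)
    profile = scoring.compute_ees(
        sim.cohort.expression, cmax, sim.truth.immune_genes, universe,
        gene_set_name="IMMUNE_EVASION", cancer_type=cancer_type, samples=ct_samples,
    )
    report = scoring.correlate_ees_infiltration(profile.ees, sim.infiltration.loc[ct_samples])
    return profile, report


def modulator_scan(sim: SimResult, cancer_type: str | None = None) -> tuple[pd.DataFrame, str]:
    """Diffcor scan for the gated pair on the generator-keyed matrices;
    returns (ranked results, planted modulator gene id)."""
    gated = sim.truth.pairs.set_index("pair_id").loc[sim.truth.modulators.iloc[0]["pair_id"]]
    mod_gene = sim.truth.modulators.iloc[0]["gene_id"]
    activity = {
        "atac": sim.cohort.atac, "methylation": sim.cohort.methylation,
        "erna": sim.cohort.erna,
    }[gated["modality"]].loc[gated["enhancer_id"]]
    sample_map = sim.cohort.sample_map
    samples = None
    if cancer_type is not None:
        samples = list(sample_map.index[sample_map == cancer_type])
    results = modulators.scan_modulators(
        sim.cohort.expression, activity, gated["gene_id"], samples=samples,
    )
    return results, mod_gene
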