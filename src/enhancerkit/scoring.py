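"""Gene-set enrichment of enhancer targets and the Enhancer Effect Score.

For a gene set G and one cancer type, the per-sample score is

    EES_s = (-log2 p_enrich) * sum_i RPKM_i(s) * |Cor_max|_i / sum_i RPKM_i(s)

where p_enrich is the hypergeometric upper-tail probability that the
enhancer target genes overlap G as much as observed, RPKM_i(s) is gene i's
expression in sample s, and |Cor_max|_i is the largest absolute enhancer
correlation among gene i's functional pairs.  The sum runs over gene-set
members that have a functional pair; members without one carry no defined
Cor_max and are dropped from both numerator and denominator (optionally
kept with weight-zero correlation via ``include_unpaired``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

P_FLOOR = 1e-300  # enrichment p floor before -log2, avoids infinite scores


class ScoringError(ValueError):
    pass


@dataclass
class EESProfile:
    gene_set: str
    cancer_type: str | None
    enrichment_p: float
    ees: pd.Series  # sample -> score (NaN where all weights vanish)
    per_gene: pd.DataFrame  # gene_id, cor_max
    degenerate_samples: list[str] = field(default_factory=list)


def hypergeom_enrichment(
    target_genes: set[str] | list[str],
    gene_set: set[str] | list[str],
    universe: set[str] | list[str],
) -> float:
    """Upper-tail hypergeometric p: probability of drawing at least the
    observed overlap when |target_genes| genes are drawn from the universe
    containing |gene_set| successes."""
    universe = set(universe)
    if not universe:
        raise ScoringError("empty universe")
    targets = set(target_genes) & universe
    members = set(gene_set) & universe
    k = len(targets & members)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(members), len(targets)))


def cor_max_per_gene(
    pairs: pd.DataFrame, cancer_type: str | None = None
) -> pd.Series:
    """Per gene, max |r| over its functional pairs (any modality).

    Restricted to one cancer type unless ``cancer_type`` is None
    (pan-cancer maximum).  Genes without a functional pair are absent.
    """
    func = pairs[pairs["functional"]]
    if cancer_type is not None:
        func = func[func["cancer_type"] == cancer_type]
    if func.empty:
        return pd.Series(dtype=float, name="cor_max")
    return func.assign(abs_r=func["r"].abs()).groupby("gene_id")["abs_r"].max().rename("cor_max")


def compute_ees(
    expression: pd.DataFrame,
    cor_max: pd.Series,
    gene_set: list[str],
    universe: set[str] | list[str],
    gene_set_name: str = "",
    cancer_type: str | None = None,
    samples: list[str] | None = None,
    include_unpaired: bool = False,
    p_floor: float = P_FLOOR,
) -> EESProfile:
    """Per-sample EES for one gene set in one cancer type.

    Expression columns may cover more samples than requested; ``samples``
    restricts the profile.  Samples where every weight is zero get NaN and
    are listed in ``degenerate_samples``.
    """
    if samples is not None:
        expression = expression.loc[:, samples]
    p_enrich = hypergeom_enrichment(set(cor_max.index), gene_set, universe)
    members = [g for g in dict.fromkeys(gene_set) if g in expression.index]
    if include_unpaired:
        cvec = cor_max.reindex(members).fillna(0.0)
        active = members
    else:
        active = [g for g in members if g in cor_max.index]
        cvec = cor_max.reindex(active)
    log_term = -np.log2(max(p_enrich, p_floor))
    if not active:
        ees = pd.Series(0.0 if p_enrich >= 1.0 else np.nan, index=expression.columns)
        return EESProfile(gene_set_name, cancer_type, p_enrich, ees,
                          pd.DataFrame({"gene_id": [], "cor_max": []}),
                          degenerate_samples=list(expression.columns) if p_enrich < 1.0 else [])
    w = expression.loc[active].to_numpy(dtype=float)
    c = cvec.to_numpy(dtype=float)
    wsum = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        weighted = (w * c[:, None]).sum(axis=0) / wsum
    ees_vals = log_term * weighted
    ees = pd.Series(ees_vals, index=expression.columns, name="ees")
    degenerate = list(expression.columns[wsum == 0])
    ees[wsum == 0] = np.nan
    if p_enrich >= 1.0:
        ees[:] = 0.0  # -log2(1) = 0 regardless of weights
        degenerate = []
    per_gene = pd.DataFrame({"gene_id": active, "cor_max": c})
    return EESProfile(gene_set_name, cancer_type, p_enrich, ees, per_gene, degenerate)


def correlate_ees_infiltration(
    ees: pd.Series, infiltration: pd.DataFrame, alpha: float = 0.05, min_obs: int = 3
) -> pd.DataFrame:
    """Pearson r and two-sided p of the EES against each infiltration
    column over shared samples; significance at raw p < alpha (no FDR)."""
    shared = ees.index.intersection(infiltration.index)
    rows = []
    for col in infiltration.columns:
        x = ees.loc[shared].to_numpy(dtype=float)
        y = infiltration.loc[shared, col].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        n = int(ok.sum())
        if n < min_obs or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
            rows.append((col, n, np.nan, np.nan, False, "not_evaluable"))
            continue
        r, p = stats.pearsonr(x[ok], y[ok])
        rows.append((col, n, float(r), float(p), bool(p < alpha), ""))
    return pd.DataFrame(rows, columns=["cell_type", "n", "r", "p", "significant", "note"])


def hallmark_enrichment_scan(
    pairs: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    universe: set[str] | list[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hypergeometric enrichment p and target-coverage fraction for each
    (cancer type, gene set).

    Coverage = |targets intersect set| / |set| (fraction of the set's genes
    that are enhancer targets in that cancer type).
    """
    universe = set(universe)
    cancer_types = sorted(pairs["cancer_type"].unique())
    pvals = pd.DataFrame(index=cancer_types, columns=list(gene_sets), dtype=float)
    coverage = pd.DataFrame(index=cancer_types, columns=list(gene_sets), dtype=float)
    for ct in cancer_types:
        targets = set(pairs[(pairs["functional"]) & (pairs["cancer_type"] == ct)]["gene_id"])
        for name, members in gene_sets.items():
            pvals.loc[ct, name] = hypergeom_enrichment(targets, members, universe)
            member_set = set(members)
            coverage.loc[ct, name] = (
                len(targets & member_set) / len(member_set) if member_set else np.nan
            )
    return pvals, coverage
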