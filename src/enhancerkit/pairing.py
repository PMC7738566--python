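"""Enhancer-gene pair construction, correlation, and FDR filtering.

Candidate pairs are all (enhancer, gene) combinations whose edge-to-edge
distance is at most 500 kb on one chromosome, optionally augmented with an
external pair list (union semantics; the external list can add long-range
pairs but never removes window pairs).  Each pair is scored per cancer type
and per activity modality (ATAC signal, methylation beta, eRNA expression)
by Pearson correlation of activity against gene expression, then filtered
with Benjamini-Hochberg FDR within each (cancer type x modality) family and
an absolute-correlation gate: functional means q < 0.05 and |r| >= 0.3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

MODALITIES = ("atac", "methylation", "erna")

PAIR_COLUMNS = [
    "enhancer_id", "gene_id", "cancer_type", "modality", "n_obs", "r", "p", "q",
    "functional", "source", "note",
]


class PairingError(ValueError):
    pass


@dataclass
class CohortMatrices:
    """Cohort inputs: expression is genes x samples; the three activity
    matrices are enhancers x samples; sample_type maps sample -> cancer."""

    expression: pd.DataFrame
    atac: pd.DataFrame | None
    methylation: pd.DataFrame | None
    erna: pd.DataFrame | None
    sample_type: pd.Series

    def modality(self, name: str) -> pd.DataFrame | None:
        if name not in MODALITIES:
            raise PairingError(f"unknown modality {name!r}")
        return getattr(self, name)


# ---------------------------------------------------------------------------
# candidates


def candidate_pairs(
    catalog_regions: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 500_000,
    external_pairs: pd.DataFrame | None = None,
    match_dist: int = 500,
) -> pd.DataFrame:
    """All same-chromosome pairs within ``window`` bp edge distance, plus
    external-list pairs whose region matches a catalog enhancer (overlap or
    nearest within ``match_dist``).  Deduplicated with window provenance
    winning over the external list."""
    rows: list[tuple[str, str, str]] = []
    for chrom, enh in catalog_regions.groupby("chrom", sort=False):
        gsub = genes[genes["chrom"] == chrom]
        if gsub.empty:
            continue
        es = enh["start"].to_numpy()[:, None]
        ee = enh["end"].to_numpy()[:, None]
        gs = gsub["start"].to_numpy()[None, :]
        ge = gsub["end"].to_numpy()[None, :]
        dist = np.maximum(0, np.maximum(gs - ee, es - ge))
        ii, jj = np.nonzero(dist <= window)
        eids = enh["enhancer_id"].to_numpy()
        gids = gsub["gene_id"].to_numpy()
        rows.extend((eids[i], gids[j], "window") for i, j in zip(ii, jj))
    if external_pairs is not None and len(external_pairs):
        matched = match_regions(catalog_regions, external_pairs, max_dist=match_dist)
        for pos, eid in matched.items():
            if eid is not None:
                rows.append((eid, external_pairs.iloc[pos]["gene_id"], "external_list"))
    out = pd.DataFrame(rows, columns=["enhancer_id", "gene_id", "source"])
    # window provenance wins on duplicates
    out["rank"] = (out["source"] != "window").astype(int)
    out = (
        out.sort_values(["enhancer_id", "gene_id", "rank"], kind="stable")
        .drop_duplicates(["enhancer_id", "gene_id"], keep="first")
        .drop(columns="rank")
        .reset_index(drop=True)
    )
    return out


def match_regions(
    catalog_regions: pd.DataFrame, other: pd.DataFrame, max_dist: int = 500
) -> dict[int, str | None]:
    """Map each row of ``other`` to the nearest catalog enhancer within
    ``max_dist`` bp (edge distance, overlap = 0); ties break to the catalog
    entry with the leftmost start.  Unmatched rows map to None."""
    result: dict[int, str | None] = {}
    by_chrom = {c: g for c, g in catalog_regions.groupby("chrom", sort=False)}
    for pos, row in enumerate(other.itertuples(index=False)):
        sub = by_chrom.get(row.chrom)
        if sub is None:
            result[pos] = None
            continue
        es = sub["start"].to_numpy()
        ee = sub["end"].to_numpy()
        dist = np.maximum(0, np.maximum(es - row.end, row.start - ee))
        ok = dist <= max_dist
        if not ok.any():
            result[pos] = None
            continue
        best = np.lexsort((es, dist))  # min distance, ties -> leftmost start
        best = best[ok[best]][0]
        result[pos] = sub["enhancer_id"].iloc[best]
    return result


def map_erna_profile(
    catalog_regions: pd.DataFrame,
    profile_regions: pd.DataFrame,
    max_dist: int = 500,
) -> dict[str, str]:
    """Assign each catalog enhancer the nearest external eRNA-profile entry
    situated within ``max_dist`` bp; ties break to the leftmost profile
    start.  ``profile_regions`` needs (profile_id, chrom, start, end)."""
    mapping: dict[str, str] = {}
    by_chrom = {c: g for c, g in profile_regions.groupby("chrom", sort=False)}
    for row in catalog_regions.itertuples(index=False):
        sub = by_chrom.get(row.chrom)
        if sub is None:
            continue
        ps = sub["start"].to_numpy()
        pe = sub["end"].to_numpy()
        dist = np.maximum(0, np.maximum(ps - row.end, row.start - pe))
        ok = dist <= max_dist
        if not ok.any():
            continue
        order = np.lexsort((ps, dist))
        order = order[ok[order]]
        mapping[row.enhancer_id] = sub["profile_id"].iloc[order[0]]
    return mapping


def enhancer_activity(
    matrices: CohortMatrices, enhancer_id: str, modality: str
) -> pd.Series | None:
    """Per-sample activity of one enhancer; None when the modality matrix is
    absent or lacks the enhancer (explicit missing result, never zeros)."""
    mat = matrices.modality(modality)
    if mat is None or enhancer_id not in mat.index:
        return None
    return mat.loc[enhancer_id]


# ---------------------------------------------------------------------------
# correlation


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    r = float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return r, float(2.0 * stats.t.sf(abs(t), n - 2))


def correlate_pairs(
    candidates: pd.DataFrame,
    matrices: CohortMatrices,
    min_obs: int = 3,
    modalities: tuple[str, ...] = MODALITIES,
) -> pd.DataFrame:
    """Score every candidate per cancer type and modality.

    Pearson r and its two-sided p are computed over pairwise-complete
    samples of one cancer type; records with fewer than ``min_obs``
    observations or a zero-variance vector are flagged not-evaluable.
    Missing modality rows yield a ``missing_modality`` note.
    """
    records = []
    sample_type = matrices.sample_type
    for ct in sample_type.unique():
        ct_samples = sample_type.index[sample_type == ct]
        expr_ct = matrices.expression.loc[:, matrices.expression.columns.intersection(ct_samples)]
        for modality in modalities:
            mat = matrices.modality(modality)
            if mat is None:
                act_vals = None
            else:
                shared = mat.columns.intersection(expr_ct.columns).intersection(ct_samples)
                act_sub = mat.loc[:, shared]
                expr_sub = expr_ct.loc[:, shared]
                act_vals = act_sub.to_numpy(dtype=float)
                expr_vals = expr_sub.to_numpy(dtype=float)
                act_row = {k: i for i, k in enumerate(act_sub.index)}
                expr_row = {k: i for i, k in enumerate(expr_sub.index)}
            for cand in candidates.itertuples(index=False):
                rec = {
                    "enhancer_id": cand.enhancer_id, "gene_id": cand.gene_id,
                    "cancer_type": ct, "modality": modality, "n_obs": 0,
                    "r": np.nan, "p": np.nan, "q": np.nan, "functional": False,
                    "source": cand.source, "note": "",
                }
                if (
                    act_vals is None
                    or cand.enhancer_id not in act_row
                    or cand.gene_id not in expr_row
                ):
                    rec["note"] = "missing_modality"
                    records.append(rec)
                    continue
                x = act_vals[act_row[cand.enhancer_id]]
                y = expr_vals[expr_row[cand.gene_id]]
                ok = np.isfinite(x) & np.isfinite(y)
                x, y = x[ok], y[ok]
                rec["n_obs"] = int(ok.sum())
                if rec["n_obs"] < min_obs:
                    rec["note"] = "too_few_observations"
                elif np.ptp(x) == 0 or np.ptp(y) == 0:
                    rec["note"] = "zero_variance"
                else:
                    rec["r"], rec["p"] = _pearson_with_p(x, y)
                records.append(rec)
    return pd.DataFrame(records, columns=PAIR_COLUMNS)


def fdr_filter(
    pairs: pd.DataFrame, alpha: float = 0.05, min_abs_r: float = 0.3
) -> pd.DataFrame:
    """Benjamini-Hochberg q-values within each (cancer type x modality)
    family; functional <=> q < alpha and |r| >= min_abs_r."""
    pairs = pairs.copy()
    pairs["q"] = np.nan
    for _key, idx in pairs.groupby(["cancer_type", "modality"], sort=False).groups.items():
        sub = pairs.loc[idx]
        ok = sub["p"].notna()
        if ok.sum() == 0:
            continue
        q = multipletests(sub.loc[ok, "p"].to_numpy(), method="fdr_bh")[1]
        pairs.loc[sub.index[ok], "q"] = q
    pairs["functional"] = (pairs["q"] < alpha) & (pairs["r"].abs() >= min_abs_r)
    pairs["functional"] = pairs["functional"].fillna(False)
    return pairs


# ---------------------------------------------------------------------------
# summaries


def summarize_pairs(pairs: pd.DataFrame) -> dict:
    """Counts over the functional records: functional enhancers, targets per
    enhancer, enhancers per gene, modality support overlap (per unique
    enhancer-gene-cancer combination), and cross-cancer recurrence."""
    func = pairs[pairs["functional"]]
    combos = func.groupby(["enhancer_id", "gene_id", "cancer_type"])["modality"].agg(
        lambda m: tuple(sorted(set(m)))
    )
    support_counts: dict[str, int] = {}
    for mods in combos:
        key = "+".join(mods)
        support_counts[key] = support_counts.get(key, 0) + 1
    eg = func[["enhancer_id", "gene_id"]].drop_duplicates()
    recurrence = (
        func[["enhancer_id", "gene_id", "cancer_type"]]
        .drop_duplicates()
        .groupby(["enhancer_id", "gene_id"])["cancer_type"]
        .nunique()
    )
    return {
        "n_functional_records": int(len(func)),
        "n_functional_pairs": int(len(eg)),
        "n_functional_enhancers": int(eg["enhancer_id"].nunique()),
        "n_target_genes": int(eg["gene_id"].nunique()),
        "targets_per_enhancer": eg.groupby("enhancer_id")["gene_id"].nunique().to_dict(),
        "enhancers_per_gene": eg.groupby("gene_id")["enhancer_id"].nunique().to_dict(),
        "modality_support": support_counts,
        "recurrence_histogram": recurrence.value_counts().sort_index().to_dict(),
    }


def gene_skip_counts(
    pairs: pd.DataFrame, catalog_regions: pd.DataFrame, genes: pd.DataFrame
) -> pd.DataFrame:
    """Number of annotated genes whose body lies within the span between an
    enhancer's edge and its target's nearest edge (0 = neighboring gene).

    Trans-chromosomal pairs (possible via external lists) are excluded with
    a note.  Operates on unique functional (enhancer, gene) pairs.
    """
    enh = catalog_regions.set_index("enhancer_id")
    gen = genes.set_index("gene_id")
    func = pairs[pairs["functional"]][["enhancer_id", "gene_id"]].drop_duplicates()
    rows = []
    for row in func.itertuples(index=False):
        if row.gene_id not in gen.index or row.enhancer_id not in enh.index:
            rows.append((row.enhancer_id, row.gene_id, np.nan, "missing_coordinates"))
            continue
        e = enh.loc[row.enhancer_id]
        g = gen.loc[row.gene_id]
        if e["chrom"] != g["chrom"]:
            rows.append((row.enhancer_id, row.gene_id, np.nan, "trans_chromosomal"))
            continue
        if g["start"] >= e["end"]:
            lo, hi = e["end"], g["start"]
        elif g["end"] <= e["start"]:
            lo, hi = g["end"], e["start"]
        else:
            rows.append((row.enhancer_id, row.gene_id, 0, "overlapping"))
            continue
        between = gen[
            (gen["chrom"] == e["chrom"])
            & (gen["start"] >= lo)
            & (gen["end"] <= hi)
            & (gen.index != row.gene_id)
        ]
        rows.append((row.enhancer_id, row.gene_id, len(between), ""))
    return pd.DataFrame(rows, columns=["enhancer_id", "gene_id", "n_skipped", "note"])


# ---------------------------------------------------------------------------
# differential expression


def differential_expression(
    expression: pd.DataFrame,
    group_labels: pd.Series,
    fc_cutoff: float = 1.5,
    alpha: float = 0.05,
    pooled_normal_mean: pd.Series | None = None,
    min_normals: int = 5,
) -> pd.DataFrame:
    """Tumor-vs-normal differential expression: fold change (tumor mean /
    normal mean), Welch t-test p, BH q; DE <=> FC > fc_cutoff and q < alpha.

    With fewer than ``min_normals`` normal samples, a provided pooled-normal
    mean replaces the cohort normals and the result is flagged descriptive
    (fold change only, no test).
    """
    tumor = group_labels.index[group_labels == "tumor"]
    normal = group_labels.index[group_labels == "normal"]
    t_mat = expression.loc[:, expression.columns.intersection(tumor)]
    n_mat = expression.loc[:, expression.columns.intersection(normal)]
    t_mean = t_mat.mean(axis=1)
    out = pd.DataFrame(index=expression.index)
    if n_mat.shape[1] < min_normals:
        if pooled_normal_mean is None:
            raise PairingError(
                f"fewer than {min_normals} normal samples and no pooled normal mean supplied"
            )
        n_mean = pooled_normal_mean.reindex(expression.index)
        out["fold_change"] = t_mean / n_mean.where(n_mean > 0)
        out["p"] = np.nan
        out["q"] = np.nan
        out["de"] = False
        out["note"] = "descriptive_pooled_normal"
        return out.reset_index()
    if t_mat.shape[1] < 2:
        raise PairingError("need at least two tumor samples")
    n_mean = n_mat.mean(axis=1)
    out["fold_change"] = t_mean / n_mean.where(n_mean > 0)
    tstat, p = stats.ttest_ind(t_mat, n_mat, axis=1, equal_var=False)
    out["p"] = p
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = multipletests(out.loc[ok, "p"].to_numpy(), method="fdr_bh")[1]
    out["de"] = (out["fold_change"] > fc_cutoff) & (out["q"] < alpha)
    out["de"] = out["de"].fillna(False)
    out["note"] = np.where(out["fold_change"].isna(), "undefined_fold_change", "")
    return out.reset_index()
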