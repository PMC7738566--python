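"""Conditional-correlation search for modulators of an enhancer-gene pair.

For each candidate modulator gene, samples are sorted by the modulator's
expression; the bottom and top quarters form low/high groups, the pair's
activity-expression Pearson correlation is recomputed within each group,
and Diffcor = |r_high - r_low| ranks the candidates.  Genes with
Diffcor >= 0.5 are flagged as candidate modulators.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

MIN_SPLIT = 4  # smallest N with non-empty quartiles
MIN_SAMPLES = 12  # evaluable correlations need >= 3 samples per quartile

RESULT_COLUMNS = [
    "modulator_gene_id", "n_low", "n_high", "r_low", "r_high",
    "diffcor", "diffcor_signed", "candidate", "degenerate", "note",
]


class ModulatorError(ValueError):
    pass


def quartile_split(modulator_expr: pd.Series) -> tuple[list, list, bool]:
    """Bottom and top floor(N/4) samples by modulator expression.

    Sorting is stable on (expression, sample id) so ties are deterministic;
    a fully tied vector still splits but is flagged degenerate.  Splits with
    fewer than 3 samples per group exist but are not evaluable downstream.
    """
    n = len(modulator_expr)
    if n < MIN_SPLIT:
        raise ModulatorError(f"need >= {MIN_SPLIT} samples, got {n}")
    q = n // 4
    order = modulator_expr.reset_index(drop=True).to_frame("v")
    order["sample"] = modulator_expr.index
    order = order.sort_values(["v", "sample"], kind="stable")
    ordered = order["sample"].tolist()
    degenerate = bool(modulator_expr.nunique() <= 1)
    return ordered[:q], ordered[n - q:], degenerate


def _safe_pearson(x: np.ndarray, y: np.ndarray, min_obs: int = 3):
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < min_obs:
        return None, "too_few_observations"
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, "zero_variance"
    return float(stats.pearsonr(x, y)[0]), ""


def diffcor(
    activity: pd.Series,
    expression: pd.Series,
    low: list,
    high: list,
    min_diffcor: float = 0.5,
) -> dict:
    """Within-group correlations and their difference for one split."""
    r_low, note_l = _safe_pearson(
        activity.loc[low].to_numpy(dtype=float), expression.loc[low].to_numpy(dtype=float)
    )
    r_high, note_h = _safe_pearson(
        activity.loc[high].to_numpy(dtype=float), expression.loc[high].to_numpy(dtype=float)
    )
    note = note_l or note_h
    if r_low is None or r_high is None:
        return {
            "n_low": len(low), "n_high": len(high), "r_low": np.nan, "r_high": np.nan,
            "diffcor": np.nan, "diffcor_signed": np.nan, "candidate": False, "note": note,
        }
    signed = r_high - r_low
    return {
        "n_low": len(low), "n_high": len(high), "r_low": r_low, "r_high": r_high,
        "diffcor": abs(signed), "diffcor_signed": signed,
        "candidate": bool(abs(signed) >= min_diffcor), "note": "",
    }


def scan_modulators(
    expression: pd.DataFrame,
    pair_activity: pd.Series,
    target_gene: str,
    samples: list[str] | None = None,
    exclude: tuple[str, ...] = (),
    min_diffcor: float = 0.5,
) -> pd.DataFrame:
    """Rank every gene by the Diffcor it induces on one enhancer-gene pair.

    The target gene itself (and any ``exclude`` entries) are skipped; rows
    are sorted by Diffcor descending with ties broken by gene id.  Genes
    with degenerate splits carry a flag and NaN correlations sort last.
    """
    if target_gene not in expression.index:
        raise ModulatorError(f"target gene {target_gene!r} absent from expression matrix")
    if samples is None:
        samples = [s for s in expression.columns if s in pair_activity.index]
    expr_sub = expression.loc[:, samples]
    target_expr = expr_sub.loc[target_gene]
    activity = pair_activity.loc[samples]
    skip = {target_gene, *exclude}
    rows = []
    for gene in expr_sub.index:
        if gene in skip:
            continue
        mod_expr = expr_sub.loc[gene]
        try:
            low, high, degenerate = quartile_split(mod_expr)
        except ModulatorError:
            rows.append({
                "modulator_gene_id": gene, "n_low": 0, "n_high": 0, "r_low": np.nan,
                "r_high": np.nan, "diffcor": np.nan, "diffcor_signed": np.nan,
                "candidate": False, "degenerate": True, "note": "not_evaluable",
            })
            continue
        rec = diffcor(activity, target_expr, low, high, min_diffcor)
        rec["modulator_gene_id"] = gene
        rec["degenerate"] = degenerate
        if degenerate:
            rec["candidate"] = False
            rec["note"] = rec["note"] or "degenerate_split"
        rows.append(rec)
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    out = out.sort_values(
        ["diffcor", "modulator_gene_id"], ascending=[False, True], kind="stable",
        na_position="last",
    ).reset_index(drop=True)
    return out


def top_modulators(results: pd.DataFrame, k: int = 20) -> pd.DataFrame:
    """Top-k candidate modulators by Diffcor."""
    return results[results["candidate"]].head(k).reset_index(drop=True)
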