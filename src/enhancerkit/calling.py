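"""Putative-enhancer catalog construction from nascent-transcription calls.

The pipeline mirrors standard eRNA-based enhancer identification: interval
calls from run-on sequencing are filtered by an RPKM cutoff (mean >= 1 for
cell lines with replicates, >= 2 without), stripped of anything within 5 kb
of a gene's 5'/3' termini or overlapping a gene body, merged across cell
lines with a 500 bp gap tolerance, and classified by how many cell lines
contribute activity (specific = 1, common = all, intermediate otherwise).

All coordinates are 0-based half-open.  Filtering and exclusion are per-call
predicates, so their order does not affect the final catalog.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree


class CallingError(ValueError):
    pass


@dataclass
class EnhancerCatalog:
    """Merged putative enhancers with per-cell-line mean eRNA RPKM.

    ``regions`` has columns (enhancer_id, chrom, start, end, n_active,
    enhancer_class); ``activity`` is an enhancer x cell-line matrix of mean
    RPKM with NaN marking inactive lines.
    """

    regions: pd.DataFrame
    activity: pd.DataFrame

    def __len__(self) -> int:
        return len(self.regions)


def filter_by_rpkm(
    calls: pd.DataFrame,
    replicate_map: dict[str, int],
    min_rpkm_replicated: float = 1.0,
    min_rpkm_unreplicated: float = 2.0,
) -> pd.DataFrame:
    """Keep call regions whose replicate-averaged RPKM clears the cutoff.

    Replicate calls of the same cell line over the same region are averaged;
    the output has one row per (cell line, region) carrying the mean RPKM.
    """
    for cl in calls["cell_line"].unique():
        if cl not in replicate_map:
            raise CallingError(f"cell line {cl!r} missing from replicate map")
    if calls.empty:
        return calls.drop(columns=["replicate"], errors="ignore").copy()
    merged = (
        calls.groupby(["cell_line", "chrom", "start", "end", "strand", "name"], sort=False)
        ["rpkm"].mean().reset_index()
    )
    n_reps = merged["cell_line"].map(replicate_map)
    cutoff = np.where(n_reps > 1, min_rpkm_replicated, min_rpkm_unreplicated)
    return merged[merged["rpkm"].to_numpy() >= cutoff].reset_index(drop=True)


def genic_exclusion_zones(genes: pd.DataFrame, distance: int = 5000) -> dict[str, IntervalTree]:
    """Half-open exclusion zones: anchor +- distance around both UTR anchors
    plus the gene body itself, per chromosome."""
    if distance < 0:
        raise CallingError("exclusion distance must be non-negative")
    trees: dict[str, IntervalTree] = {}
    for row in genes.itertuples(index=False):
        tree = trees.setdefault(row.chrom, IntervalTree())
        for anchor in (row.utr5_anchor, row.utr3_anchor):
            tree.addi(max(0, anchor - distance), anchor + distance)
        tree.addi(row.start, row.end)
    return trees


def exclude_genic(
    calls: pd.DataFrame,
    genes: pd.DataFrame,
    distance: int = 5000,
    allow_empty_genes: bool = False,
) -> pd.DataFrame:
    """Drop whole calls that overlap any genic exclusion zone (subtractive
    `intersect -v` semantics: any 1 bp overlap removes the record)."""
    if genes.empty and not allow_empty_genes:
        raise CallingError("gene annotation is empty; pass allow_empty_genes=True to skip")
    trees = genic_exclusion_zones(genes, distance)
    if calls.empty:
        return calls.copy()
    keep = [
        not (row.chrom in trees and trees[row.chrom].overlaps(row.start, row.end))
        for row in calls.itertuples(index=False)
    ]
    return calls[keep].reset_index(drop=True)


def merge_across_celltypes(calls: pd.DataFrame, gap: int = 500) -> EnhancerCatalog:
    """Merge filtered calls from all cell lines into catalog intervals.

    Calls whose distance is <= ``gap`` (overlap counts as 0; the boundary is
    inclusive) belong to the same enhancer, by transitive closure and
    irrespective of strand or input order.  Each catalog interval spans its
    component calls; per-cell-line activity is the mean RPKM of that line's
    component calls, with absent lines recorded as NaN (inactive).
    """
    cell_lines = sorted(calls["cell_line"].unique()) if len(calls) else []
    if calls.empty:
        regions = pd.DataFrame(
            columns=["enhancer_id", "chrom", "start", "end", "n_active", "enhancer_class"]
        )
        return EnhancerCatalog(regions=regions, activity=pd.DataFrame(columns=cell_lines))

    calls = calls.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
    rows, act_rows = [], []
    for chrom, grp in calls.groupby("chrom", sort=True):
        grp = grp.reset_index(drop=True)
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_start, cur_end = int(starts[0]), int(ends[0])
        members = [0]
        clusters = []
        for i in range(1, len(grp)):
            if starts[i] - cur_end <= gap:
                cur_end = max(cur_end, int(ends[i]))
                members.append(i)
            else:
                clusters.append((cur_start, cur_end, members))
                cur_start, cur_end, members = int(starts[i]), int(ends[i]), [i]
        clusters.append((cur_start, cur_end, members))
        for start, end, idx in clusters:
            sub = grp.iloc[idx]
            rows.append((chrom, start, end))
            act_rows.append(sub.groupby("cell_line")["rpkm"].mean())

    regions = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    regions.insert(0, "enhancer_id", [f"ENH{i + 1:05d}" for i in range(len(regions))])
    activity = pd.DataFrame(act_rows).reindex(columns=cell_lines)
    activity.index = pd.Index(regions["enhancer_id"], name="enhancer_id")
    regions["n_active"] = activity.notna().sum(axis=1).to_numpy()
    regions["enhancer_class"] = ""
    return EnhancerCatalog(regions=regions, activity=activity)


def classify_enhancers(catalog: EnhancerCatalog, n_cell_lines: int) -> EnhancerCatalog:
    """Label each enhancer specific (1 active line), common (all lines) or
    intermediate, based on how many cell lines contributed calls."""
    n_active = catalog.regions["n_active"].to_numpy()
    if len(n_active) and n_active.min() < 1:
        raise CallingError("catalog record with zero active cell lines")
    if n_active.max(initial=0) > n_cell_lines:
        raise CallingError("record active in more lines than n_cell_lines")
    labels = np.where(
        n_active == n_cell_lines, "common", np.where(n_active == 1, "specific", "intermediate")
    )
    regions = catalog.regions.copy()
    regions["enhancer_class"] = labels
    return EnhancerCatalog(regions=regions, activity=catalog.activity)


def call_enhancers(
    calls: pd.DataFrame,
    genes: pd.DataFrame,
    replicate_map: dict[str, int],
    n_cell_lines: int | None = None,
    genic_distance: int = 5000,
    merge_gap: int = 500,
    allow_empty_genes: bool = False,
) -> EnhancerCatalog:
    """Full pipeline: RPKM filter -> genic exclusion -> merge -> classify."""
    filtered = filter_by_rpkm(calls, replicate_map)
    intergenic = exclude_genic(filtered, genes, genic_distance, allow_empty_genes)
    catalog = merge_across_celltypes(intergenic, merge_gap)
    if n_cell_lines is None:
        n_cell_lines = len(replicate_map)
    return classify_enhancers(catalog, n_cell_lines)


# ---------------------------------------------------------------------------
# conservation profiling


class _ScoreTrack:
    """Prefix-sum lookup over a sorted, non-overlapping bedGraph track."""

    def __init__(self, track: pd.DataFrame):
        self._chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, grp in track.groupby("chrom", sort=False):
            grp = grp.sort_values("start")
            starts = grp["start"].to_numpy(dtype=np.int64)
            ends = grp["end"].to_numpy(dtype=np.int64)
            vals = grp["score"].to_numpy(dtype=np.float64)
            lens = (ends - starts).astype(np.float64)
            cum_w = np.concatenate([[0.0], np.cumsum(vals * lens)])
            cum_l = np.concatenate([[0.0], np.cumsum(lens)])
            self._chrom[chrom] = (starts, ends, vals, np.stack([cum_w, cum_l]))

    def window_sums(self, chrom: str, qstart: np.ndarray, qend: np.ndarray):
        """Vectorised (weighted sum, covered bases) for many query windows."""
        if chrom not in self._chrom:
            z = np.zeros(len(qstart))
            return z, z.copy()
        starts, ends, vals, cums = self._chrom[chrom]
        cum_w, cum_l = cums

        def prefix(pos: np.ndarray):
            # totals over track bases strictly left of pos
            i = np.searchsorted(starts, pos, side="right")
            w = cum_w[i]
            ln = cum_l[i]
            # subtract the part of segment i-1 at or right of pos
            has = i > 0
            j = np.where(has, i - 1, 0)
            over = np.clip(ends[j] - pos, 0, ends[j] - starts[j]) * has
            return w - vals[j] * over, ln - over

        w_hi, l_hi = prefix(np.asarray(qend))
        w_lo, l_lo = prefix(np.asarray(qstart))
        return w_hi - w_lo, l_hi - l_lo


def _window_curve(
    regions: pd.DataFrame, track: _ScoreTrack, half: int, window: int
) -> pd.DataFrame:
    offsets = np.arange(-half, half, window)
    tot_w = np.zeros(len(offsets))
    tot_l = np.zeros(len(offsets))
    for row in regions.itertuples(index=False):
        center = (int(row.start) + int(row.end)) // 2
        qs = center + offsets
        w, ln = track.window_sums(row.chrom, qs, qs + window)
        tot_w += w
        tot_l += ln
    with np.errstate(invalid="ignore"):
        mean = np.where(tot_l > 0, tot_w / np.maximum(tot_l, 1e-300), np.nan)
    return pd.DataFrame({"offset": offsets, "mean_score": mean, "covered_bases": tot_l})


def sample_background_regions(
    chrom_sizes: pd.Series, n: int, length: int, seed: int = 0
) -> pd.DataFrame:
    """Uniformly sample n regions of fixed length from chromosome space."""
    rng = np.random.default_rng(seed)
    sizes = chrom_sizes.to_numpy(dtype=np.float64)
    probs = sizes / sizes.sum()
    rows = []
    for _ in range(n):
        ci = int(rng.choice(len(chrom_sizes), p=probs))
        chrom = chrom_sizes.index[ci]
        start = int(rng.integers(0, max(1, int(sizes[ci]) - length)))
        rows.append((chrom, start, start + length))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def conservation_profile(
    regions: pd.DataFrame,
    score_track: pd.DataFrame,
    chrom_sizes: pd.Series,
    flank: int = 2500,
    window: int = 50,
    seed: int = 0,
    n_background: int | None = None,
) -> pd.DataFrame:
    """Mean per-window conservation around enhancer centers, against a
    count- and length-matched uniform random background.

    Windows of ``window`` bp tile a span of (mean enhancer length / 2 +
    flank) on each side of the region center; bases absent from the track
    are excluded from the means.  Returns a tidy frame with one row per
    (group, window offset).
    """
    if window <= 0 or flank < 0:
        raise CallingError("window must be positive and flank non-negative")
    if regions.empty:
        raise CallingError("no regions to profile")
    track = _ScoreTrack(score_track)
    mean_len = int(round(float((regions["end"] - regions["start"]).mean())))
    half = window * int(np.ceil((flank + mean_len / 2) / window))
    enh_curve = _window_curve(regions, track, half, window)
    if n_background is None:
        n_background = len(regions)
    bg = sample_background_regions(chrom_sizes, n_background, mean_len, seed)
    bg_curve = _window_curve(bg, track, half, window)
    enh_curve["group"] = "enhancer"
    bg_curve["group"] = "background"
    return pd.concat([enh_curve, bg_curve], ignore_index=True)
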