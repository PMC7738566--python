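"""Readers and writers for the plain-text formats the pipeline exchanges.

Coordinates are BED-style throughout: 0-based, half-open intervals.
Matrices are TSV with the feature id in the first column and sample ids in
the header row.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "utr5_anchor", "utr3_anchor"]
CALL_COLUMNS = ["chrom", "start", "end", "name", "rpkm", "strand", "cell_line", "replicate"]


class ExternalPairParseError(ValueError):
    """Raised when an external enhancer-gene pair list is malformed."""


# ---------------------------------------------------------------------------
# chromosome sizes


def read_chrom_sizes(path: str) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return df.set_index("chrom")["length"]


def write_chrom_sizes(sizes: pd.Series, path: str) -> None:
    sizes.rename("length").to_csv(path, sep="\t", header=False)


# ---------------------------------------------------------------------------
# gene annotation (BED12)


def write_genes_bed12(genes: pd.DataFrame, path: str) -> None:
    """Write gene models as single-block BED12 records."""
    with open(path, "w") as fh:
        for row in genes.itertuples(index=False):
            size = row.end - row.start
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        row.chrom, row.start, row.end, row.gene_id, 0, row.strand,
                        row.start, row.end, "0,0,0", 1, f"{size},", "0,",
                    )
                )
                + "\n"
            )


def read_genes_bed12(path: str) -> pd.DataFrame:
    """Read BED12 gene models; UTR anchors derive from strand.

    The 5' anchor is the transcription start (interval start on '+', end on
    '-'); the 3' anchor is the opposite terminus.  Unstranded records are
    treated as '+'.
    """
    cols = ["chrom", "start", "end", "gene_id", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, usecols=range(6), names=cols)
    if df.empty:
        return pd.DataFrame(columns=GENE_COLUMNS)
    minus = df["strand"] == "-"
    df["utr5_anchor"] = df["start"].where(~minus, df["end"])
    df["utr3_anchor"] = df["end"].where(~minus, df["start"])
    return df[GENE_COLUMNS]


# ---------------------------------------------------------------------------
# transcript calls (BED6 + rpkm), one file per cell line per replicate


def write_transcript_calls(calls: pd.DataFrame, outdir: str) -> list[str]:
    os.makedirs(outdir, exist_ok=True)
    paths = []
    for (cell, rep), grp in calls.groupby(["cell_line", "replicate"], sort=True):
        path = os.path.join(outdir, f"{cell}.{rep}.bed")
        out = grp[["chrom", "start", "end", "name", "rpkm", "strand"]].copy()
        out.insert(5, "score", 0)
        out = out[["chrom", "start", "end", "name", "score", "strand", "rpkm"]]
        out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")
        paths.append(path)
    return paths


def read_transcript_calls(path: str, cell_line: str, replicate: str) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "name", "score", "strand", "rpkm"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols)
    df["cell_line"] = cell_line
    df["replicate"] = replicate
    return df[CALL_COLUMNS]


def read_calls_dir(directory: str) -> pd.DataFrame:
    """Read every ``<cell_line>.<replicate>.bed`` file in a directory."""
    frames = []
    for fname in sorted(os.listdir(directory)):
        if not fname.endswith(".bed"):
            continue
        stem = fname[: -len(".bed")]
        cell, _, rep = stem.rpartition(".")
        if not cell:
            cell, rep = stem, "rep1"
        frames.append(read_transcript_calls(os.path.join(directory, fname), cell, rep))
    if not frames:
        return pd.DataFrame(columns=CALL_COLUMNS)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# matrices and sample maps


def read_matrix(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(matrix: pd.DataFrame, path: str, index_label: str = "feature_id") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label, float_format="%.8g")


def read_sample_map(path: str) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("sample")["cancer_type"]


def write_sample_map(sample_map: pd.Series, path: str) -> None:
    sample_map.rename("cancer_type").rename_axis("sample").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            name, members = fields[0], [g for g in fields[2:] if g]
            sets[name] = members
    return sets


def write_gmt(gene_sets: Mapping[str, Iterable[str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


# ---------------------------------------------------------------------------
# external enhancer-gene pair lists (GeneHancer-like TSV)


def read_external_pairs(path: str) -> pd.DataFrame:
    """Read a TSV of (chrom, start, end, gene_id) external pairs.

    Raises ExternalPairParseError with the offending 1-based line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[:1] == ["chrom"]:
                continue
            if len(fields) < 4:
                raise ExternalPairParseError(
                    f"{path}: line {lineno}: expected >= 4 tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ExternalPairParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if not 0 <= start < end:
                raise ExternalPairParseError(
                    f"{path}: line {lineno}: invalid interval [{start}, {end})"
                )
            rows.append((fields[0], start, end, fields[3]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


# ---------------------------------------------------------------------------
# bedGraph score tracks


def read_bedgraph(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "score"])
    # tolerate a leading "track ..." declaration line
    df = df[~df["chrom"].astype(str).str.startswith("track")].reset_index(drop=True)
    return df.astype({"start": int, "end": int, "score": float})


def write_bedgraph(track: pd.DataFrame, path: str) -> None:
    track[["chrom", "start", "end", "score"]].to_csv(
        path, sep="\t", header=False, index=False, float_format="%.6g"
    )


# ---------------------------------------------------------------------------
# enhancer catalog (BED6+ with id, class, n_active)


def write_catalog(regions: pd.DataFrame, path: str) -> None:
    out = regions[["chrom", "start", "end", "enhancer_id", "n_active", "enhancer_class"]].copy()
    out.insert(5, "strand", ".")
    out.to_csv(path, sep="\t", header=False, index=False)


def read_catalog(path: str) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "enhancer_id", "n_active", "strand", "enhancer_class"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols)
    return df[["enhancer_id", "chrom", "start", "end", "n_active", "enhancer_class"]]


# ---------------------------------------------------------------------------
# generic record tables (truth tables, pair tables, results)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
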