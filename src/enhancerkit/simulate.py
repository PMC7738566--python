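"""Synthetic cohorts with planted enhancer-gene structure.

Every input the pipeline consumes can be generated here with a known truth:
a gene annotation, per-cell-line nascent-transcription interval calls that
contain planted enhancers plus deliberate failure-mode noise, cohort
matrices in which planted enhancer activity linearly drives target-gene
expression at a controlled Pearson correlation, modulator genes whose
expression level gates a pair's correlation, and immune infiltration scores
coupled to an immune gene set.

Correlations are planted through a shared Gaussian latent factor: for a pair
with target correlation rho, activity = a and the gene's latent is
``rho * a + sqrt(1 - rho^2) * eps``.  Emitted values are affine maps of the
latents truncated to their natural range (non-negative RPKM-like expression
and ATAC/eRNA signal; methylation beta in [0, 1] oriented *against*
activity), so the population correlation on the emitted scale equals the
planted value up to a negligible truncation mass.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as ekio

MODALITIES = ("atac", "methylation", "erna")

# emission-scale constants: latents are N(0,1); expression/signal ~ 5 + z
# truncated at 0 (truncation mass ~3e-7), methylation ~ 0.5 - 0.12*a clipped
# to [0,1] (clip mass ~3e-5)
_EMIT_MEAN = 5.0
_METH_CENTER = 0.5
_METH_SCALE = 0.12
_IMMUNE_FACTOR_LOAD = 0.8
_IMMUNE_LOAD_MIN_R = 0.6

_ZONE_PAD = 5_500  # clearance beyond the 5 kb genic exclusion zone
_SPACING = 1_600  # placement spacing; > merge gap so planted loci never fuse


class ConfigError(ValueError):
    pass


class CapacityError(ValueError):
    """The requested gene/enhancer layout does not fit the genome."""


@dataclass
class SimConfig:
    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 10_000_000
    n_genes: int = 200
    n_cell_lines: int = 7
    n_planted_enhancers: int = 10
    n_noise_transcripts: int = 30
    n_cancer_types: int = 7
    samples_per_type: int = 100
    # (enhancer_index, gene_index, target_correlation, modality)
    planted_pairs: list[tuple[int, int, float, str]] = field(default_factory=list)
    # (modulator_gene_index, planted_pair_index, cor_high, cor_low)
    modulator_spec: list[tuple[int, int, float, float]] = field(default_factory=list)
    immune_set_size: int = 20
    infiltration_coupling: float = 0.0
    gene_len_min: int = 5_000
    gene_len_max: int = 15_000
    enhancer_len_min: int = 800
    enhancer_len_max: int = 2_000
    # per planted enhancer, explicit list of active cell-line indices;
    # None assigns a deterministic common/specific/intermediate rotation
    active_lines: list[list[int]] | None = None
    # gene indices forming the immune set; None derives it from planted pairs
    immune_genes: list[int] | None = None

    def __post_init__(self) -> None:
        self.planted_pairs = [tuple(p) for p in self.planted_pairs]
        self.modulator_spec = [tuple(m) for m in self.modulator_spec]

    # -- names ------------------------------------------------------------
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def cell_lines(self) -> list[str]:
        return [f"CL{i + 1}" for i in range(self.n_cell_lines)]

    def replicate_map(self) -> dict[str, int]:
        """Alternate replicated (2) and unreplicated (1) cell lines."""
        return {cl: 2 if i % 2 == 0 else 1 for i, cl in enumerate(self.cell_lines())}

    def cancer_types(self) -> list[str]:
        return [f"CT{i + 1}" for i in range(self.n_cancer_types)]

    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]

    def enhancer_ids(self) -> list[str]:
        return [f"E{i + 1:04d}" for i in range(self.n_planted_enhancers)]

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.n_chroms < 1 or self.chrom_length < 100_000:
            raise ConfigError("need at least one chromosome of >= 100 kb")
        if self.n_genes < 0 or self.n_cell_lines < 1:
            raise ConfigError("n_genes must be >= 0 and n_cell_lines >= 1")
        pair_genes: set[int] = set()
        for pair in self.planted_pairs:
            e, g, r, m = pair
            if not 0 <= e < self.n_planted_enhancers:
                raise ConfigError(f"pair references unknown enhancer index {e}")
            if not 0 <= g < self.n_genes:
                raise ConfigError(f"pair references unknown gene index {g}")
            if abs(r) > 0.999:
                raise ConfigError(f"|target_correlation| > 0.999 requested for pair {pair}")
            if m not in MODALITIES:
                raise ConfigError(f"unknown modality {m!r}")
            if g in pair_genes:
                raise ConfigError(f"gene index {g} appears in more than one planted pair")
            pair_genes.add(g)
        for spec in self.modulator_spec:
            gm, p, ch, cl = spec
            if not 0 <= p < len(self.planted_pairs):
                raise ConfigError(f"modulator gates pair index {p}, which is not planted")
            if not 0 <= gm < self.n_genes:
                raise ConfigError(f"modulator gene index {gm} out of range")
            if gm == self.planted_pairs[p][1]:
                raise ConfigError("modulator gene cannot be the gated pair's own target")
            if max(abs(ch), abs(cl)) > 0.999:
                raise ConfigError("modulator gate correlations must be within +-0.999")
        if self.active_lines is not None:
            if len(self.active_lines) != self.n_planted_enhancers:
                raise ConfigError("active_lines must have one entry per planted enhancer")
            for lines in self.active_lines:
                if not lines or any(not 0 <= i < self.n_cell_lines for i in lines):
                    raise ConfigError("active_lines entries must be non-empty valid indices")
        if not 0.0 <= self.infiltration_coupling <= 1.0:
            raise ConfigError("infiltration_coupling must lie in [0, 1]")

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["planted_pairs"] = [list(p) for p in self.planted_pairs]
        d["modulator_spec"] = [list(m) for m in self.modulator_spec]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class Genome:
    genes: pd.DataFrame  # gene_id, chrom, start, end, strand, utr5/utr3 anchors
    chrom_sizes: pd.Series


@dataclass
class TruthTable:
    """Planted structure, written alongside the synthetic inputs."""

    enhancers: pd.DataFrame  # enhancer_id, chrom, start, end, active_lines, n_active, class
    pairs: pd.DataFrame  # pair_id, enhancer_id, gene_id, planted_r, modality
    modulators: pd.DataFrame  # gene_id, pair_id, cor_high, cor_low
    noise_calls: pd.DataFrame  # noise_id, mode, chrom, start, end, cell_line, expect_in_catalog
    immune_genes: list[str] = field(default_factory=list)
    coupled_infiltration: list[str] = field(default_factory=list)

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        ekio.write_table(self.enhancers, os.path.join(outdir, "truth_enhancers.tsv"))
        ekio.write_table(self.pairs, os.path.join(outdir, "truth_pairs.tsv"))
        ekio.write_table(self.modulators, os.path.join(outdir, "truth_modulators.tsv"))
        ekio.write_table(self.noise_calls, os.path.join(outdir, "truth_noise_calls.tsv"))
        with open(os.path.join(outdir, "truth_meta.json"), "w") as fh:
            json.dump(
                {
                    "immune_genes": self.immune_genes,
                    "coupled_infiltration": self.coupled_infiltration,
                },
                fh,
                indent=1,
            )

    @classmethod
    def read(cls, outdir: str) -> "TruthTable":
        with open(os.path.join(outdir, "truth_meta.json")) as fh:
            meta = json.load(fh)
        return cls(
            enhancers=ekio.read_table(os.path.join(outdir, "truth_enhancers.tsv")),
            pairs=ekio.read_table(os.path.join(outdir, "truth_pairs.tsv")),
            modulators=ekio.read_table(os.path.join(outdir, "truth_modulators.tsv")),
            noise_calls=ekio.read_table(os.path.join(outdir, "truth_noise_calls.tsv")),
            immune_genes=meta["immune_genes"],
            coupled_infiltration=meta["coupled_infiltration"],
        )


@dataclass
class Cohort:
    expression: pd.DataFrame  # genes x samples, RPKM-like
    atac: pd.DataFrame  # enhancers x samples
    methylation: pd.DataFrame  # enhancers x samples, beta in [0, 1]
    erna: pd.DataFrame  # enhancers x samples
    sample_map: pd.Series  # sample -> cancer type
    immune_factor: pd.Series  # latent factor behind the immune gene set
    activity_gauss: dict[str, pd.DataFrame]  # modality -> latent activity

    def to_matrices(self):
        from .pairing import CohortMatrices

        return CohortMatrices(
            expression=self.expression,
            atac=self.atac,
            methylation=self.methylation,
            erna=self.erna,
            sample_type=self.sample_map,
        )


# ---------------------------------------------------------------------------
# genome


def generate_genome(cfg: SimConfig) -> Genome:
    """Lay non-nested gene models on evenly sized slots per chromosome."""
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 11])
    chroms = cfg.chrom_names()
    sizes = pd.Series({c: cfg.chrom_length for c in chroms})
    if cfg.n_genes == 0:
        genes = pd.DataFrame(columns=ekio.GENE_COLUMNS)
        return Genome(genes=genes, chrom_sizes=sizes)

    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[i] += 1
    rows = []
    gid = 0
    for c, n_here in zip(chroms, per_chrom):
        if n_here == 0:
            continue
        slot = cfg.chrom_length // n_here
        if slot < cfg.gene_len_max + 3 * _ZONE_PAD:
            raise CapacityError(
                f"{n_here} genes of up to {cfg.gene_len_max} bp do not fit "
                f"{cfg.chrom_length} bp of {c} with intergenic clearance"
            )
        for j in range(n_here):
            length = int(rng.integers(cfg.gene_len_min, cfg.gene_len_max + 1))
            max_off = slot - length - 3 * _ZONE_PAD
            start = j * slot + int(rng.integers(0, max(1, max_off // 4)))
            end = start + length
            strand = "+" if rng.random() < 0.5 else "-"
            utr5, utr3 = (start, end) if strand == "+" else (end, start)
            rows.append((f"G{gid + 1:04d}", c, start, end, strand, utr5, utr3))
            gid += 1
    genes = pd.DataFrame(rows, columns=ekio.GENE_COLUMNS)
    return Genome(genes=genes, chrom_sizes=sizes)


# ---------------------------------------------------------------------------
# transcript calls


def _zones(genes: pd.DataFrame, chrom_sizes: pd.Series) -> list[dict]:
    """Intergenic placement zone to the right of each gene, clear of all
    5 kb exclusion windows, with a running placement cursor."""
    zones = []
    for chrom, grp in genes.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        ends = grp["end"].tolist()
        starts = grp["start"].tolist()
        for i in range(len(grp)):
            zstart = ends[i] + _ZONE_PAD
            zend = (starts[i + 1] - _ZONE_PAD) if i + 1 < len(grp) else int(
                chrom_sizes[chrom] - 1_000
            )
            zones.append({"chrom": chrom, "start": zstart, "end": zend, "cursor": zstart})
    return zones


def _place(zones: list[dict], zone_idx: int, length: int) -> tuple[str, int]:
    n = len(zones)
    for k in range(n):
        z = zones[(zone_idx + k) % n]
        if z["cursor"] + length <= z["end"]:
            pos = z["cursor"]
            z["cursor"] = pos + length + _SPACING
            return z["chrom"], pos
    raise CapacityError("no intergenic zone can accommodate another planted interval")


def _assign_active_lines(cfg: SimConfig, rng: np.random.Generator) -> list[list[int]]:
    if cfg.active_lines is not None:
        return [sorted(v) for v in cfg.active_lines]
    n = cfg.n_cell_lines
    out = []
    for i in range(cfg.n_planted_enhancers):
        mode = i % 3
        if mode == 0 or (mode == 2 and n < 3):
            out.append(list(range(n)))  # common
        elif mode == 1:
            out.append([(i // 3) % n])  # specific
        else:  # intermediate: 2 .. n-1 lines
            size = int(rng.integers(2, n))
            out.append(sorted(rng.choice(n, size=size, replace=False).tolist()))
    return out


def _class_label(n_active: int, n_lines: int) -> str:
    if n_active == n_lines:
        return "common"
    if n_active == 1:
        return "specific"
    return "intermediate"


def generate_transcript_calls(
    cfg: SimConfig, genome: Genome
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Emit per-cell-line interval calls: planted enhancers in their active
    lines, plus low-RPKM, genic-proximal and singleton-cell-line noise.

    Returns (calls, truth_enhancers, truth_noise).
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 23])
    genes, sizes = genome.genes, genome.chrom_sizes
    if cfg.n_planted_enhancers > 0 and genes.empty:
        raise CapacityError("planted enhancers need at least one gene-defined zone")
    zones = _zones(genes, sizes)
    lines = cfg.cell_lines()
    reps = cfg.replicate_map()
    active = _assign_active_lines(cfg, rng)

    # anchor each planted enhancer near its first paired gene so that window
    # pairing at 500 kb always reaches the target
    anchor_gene = {}
    for e, g, _r, _m in cfg.planted_pairs:
        anchor_gene.setdefault(e, g)

    call_rows, enh_rows = [], []
    for i in range(cfg.n_planted_enhancers):
        length = int(rng.integers(cfg.enhancer_len_min, cfg.enhancer_len_max + 1))
        zone_idx = anchor_gene.get(i, (i * max(1, cfg.n_genes // max(1, cfg.n_planted_enhancers))))
        chrom, start = _place(zones, zone_idx % max(1, len(zones)), length)
        eid = f"E{i + 1:04d}"
        names = [lines[k] for k in active[i]]
        enh_rows.append(
            (eid, chrom, start, start + length, ",".join(names), len(names),
             _class_label(len(names), cfg.n_cell_lines))
        )
        for k in active[i]:
            cl = lines[k]
            base = float(rng.uniform(2.5, 8.0))
            for r in range(reps[cl]):
                rpkm = max(2.1, base + float(rng.uniform(-0.3, 0.3)))
                call_rows.append(
                    (chrom, start, start + length, f"{eid}.{cl}", rpkm, ".", cl, f"r{r + 1}")
                )

    noise_rows = []
    modes = ("low_rpkm", "genic_proximal", "singleton")
    for j in range(cfg.n_noise_transcripts):
        mode = modes[j % 3]
        cl = lines[j % len(lines)]
        nid = f"N{j + 1:04d}"
        length = int(rng.integers(cfg.enhancer_len_min, cfg.enhancer_len_max + 1))
        if mode == "genic_proximal":
            # 2-3 kb past a gene terminus: intergenic, but inside the 5 kb
            # UTR exclusion zone
            g = genes.iloc[j % len(genes)] if len(genes) else None
            if g is None:
                continue
            chrom, start = g["chrom"], int(g["end"]) + 2_000
            length = min(length, 1_000)
            for r in range(reps[cl]):
                call_rows.append(
                    (chrom, start, start + length, nid, 5.0, ".", cl, f"r{r + 1}")
                )
            expect = False
        elif mode == "low_rpkm":
            chrom, start = _place(zones, (j * 7) % max(1, len(zones)), length)
            if reps[cl] > 1:
                for r, v in zip(range(reps[cl]), (0.4, 0.8)):
                    call_rows.append((chrom, start, start + length, nid, v, ".", cl, f"r{r + 1}"))
            else:
                call_rows.append((chrom, start, start + length, nid, 1.5, ".", cl, "r1"))
            expect = False
        else:  # singleton: legitimate intergenic signal in one cell line
            chrom, start = _place(zones, (j * 13) % max(1, len(zones)), length)
            for r in range(reps[cl]):
                call_rows.append((chrom, start, start + length, nid, 5.0, ".", cl, f"r{r + 1}"))
            expect = True
        noise_rows.append((nid, mode, chrom, start, start + length, cl, expect))

    calls = pd.DataFrame(
        call_rows,
        columns=["chrom", "start", "end", "name", "rpkm", "strand", "cell_line", "replicate"],
    )
    truth_enh = pd.DataFrame(
        enh_rows,
        columns=["enhancer_id", "chrom", "start", "end", "active_lines", "n_active",
                 "enhancer_class"],
    )
    truth_noise = pd.DataFrame(
        noise_rows,
        columns=["noise_id", "mode", "chrom", "start", "end", "cell_line", "expect_in_catalog"],
    )
    return calls, truth_enh, truth_noise


# ---------------------------------------------------------------------------
# cohort matrices


def _pairs_table(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for i, (e, g, r, m) in enumerate(cfg.planted_pairs):
        planted_r = -abs(r) if m == "methylation" else float(r)
        rows.append((f"P{i + 1:04d}", f"E{e + 1:04d}", f"G{g + 1:04d}", planted_r, m))
    return pd.DataFrame(rows, columns=["pair_id", "enhancer_id", "gene_id", "planted_r", "modality"])


def _immune_gene_ids(cfg: SimConfig) -> list[str]:
    if cfg.immune_genes is not None:
        return [f"G{g + 1:04d}" for g in cfg.immune_genes]
    picks = [g for _e, g, _r, _m in cfg.planted_pairs[: cfg.immune_set_size]]
    return [f"G{g + 1:04d}" for g in picks]


def generate_cohort(cfg: SimConfig, truth_pairs: pd.DataFrame | None = None) -> Cohort:
    """Draw cohort matrices with the configured pair correlations planted.

    ``truth_pairs`` defaults to the table implied by ``cfg.planted_pairs``.
    """
    cfg.validate()
    if truth_pairs is None:
        truth_pairs = _pairs_table(cfg)
    rng = np.random.default_rng([cfg.seed, 37])
    gene_ids = cfg.gene_ids()
    enh_ids = cfg.enhancer_ids()
    immune = _immune_gene_ids(cfg)
    high_r = {
        row.gene_id
        for row in truth_pairs.itertuples()
        if abs(row.planted_r) >= _IMMUNE_LOAD_MIN_R
    }

    samples, stypes = [], []
    for ct in cfg.cancer_types():
        for s in range(cfg.samples_per_type):
            samples.append(f"{ct}_s{s + 1:04d}")
            stypes.append(ct)
    sample_map = pd.Series(stypes, index=pd.Index(samples, name="sample"), name="cancer_type")

    n_total = len(samples)
    act = {m: rng.standard_normal((len(enh_ids), n_total)) for m in MODALITIES}
    factor = rng.standard_normal(n_total)
    eps = rng.standard_normal((len(gene_ids), n_total))

    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    enh_pos = {e: i for i, e in enumerate(enh_ids)}

    lam = _IMMUNE_FACTOR_LOAD
    for g in immune:
        gi = gene_pos[g]
        if g in high_r:  # high-correlation immune genes load on the factor
            eps[gi] = lam * factor + np.sqrt(1.0 - lam * lam) * eps[gi]

    z = eps.copy()
    for row in truth_pairs.itertuples():
        gi, ei = gene_pos[row.gene_id], enh_pos[row.enhancer_id]
        rho = abs(row.planted_r)
        sgn = 1.0 if (row.planted_r >= 0 or row.modality == "methylation") else -1.0
        a = act[row.modality][ei]
        z[gi] = sgn * rho * a + np.sqrt(1.0 - rho * rho) * eps[gi]

    expression = pd.DataFrame(
        np.maximum(0.0, _EMIT_MEAN + z), index=pd.Index(gene_ids, name="gene_id"),
        columns=samples,
    )
    eidx = pd.Index(enh_ids, name="enhancer_id")
    atac = pd.DataFrame(np.maximum(0.0, _EMIT_MEAN + act["atac"]), index=eidx, columns=samples)
    erna = pd.DataFrame(np.maximum(0.0, _EMIT_MEAN + act["erna"]), index=eidx, columns=samples)
    meth = pd.DataFrame(
        np.clip(_METH_CENTER - _METH_SCALE * act["methylation"], 0.0, 1.0),
        index=eidx, columns=samples,
    )
    return Cohort(
        expression=expression,
        atac=atac,
        methylation=meth,
        erna=erna,
        sample_map=sample_map,
        immune_factor=pd.Series(factor, index=samples, name="immune_factor"),
        activity_gauss={m: pd.DataFrame(act[m], index=eidx, columns=samples) for m in MODALITIES},
    )


def plant_modulators(cfg: SimConfig, cohort: Cohort) -> pd.DataFrame:
    """Rebuild gated genes so the pair correlation differs between the top
    and bottom expression quartile of each modulator gene (in place).

    Within each cancer type the gated gene's latent mixes the pair's
    activity latent with weight ``cor_low`` (bottom quartile of the
    modulator), ``cor_high`` (top quartile) or their mean (middle half).
    """
    cfg.validate()
    pairs = _pairs_table(cfg)
    rng = np.random.default_rng([cfg.seed, 53])
    rows = []
    for gm, p, ch, cl in cfg.modulator_spec:
        pair = pairs.iloc[p]
        gene_id, enh_id, modality = pair.gene_id, pair.enhancer_id, pair.modality
        mod_id = f"G{gm + 1:04d}"
        a_all = cohort.activity_gauss[modality].loc[enh_id]
        mod_expr = cohort.expression.loc[mod_id]
        new = pd.Series(0.0, index=cohort.expression.columns)
        for _ct, ct_samples in cohort.sample_map.groupby(cohort.sample_map, sort=False):
            s = ct_samples.index
            n = len(s)
            q = n // 4
            order = np.argsort(mod_expr.loc[s].to_numpy(), kind="stable")
            rho = np.full(n, (ch + cl) / 2.0)
            rho[order[:q]] = cl
            rho[order[n - q:]] = ch
            # gate magnitudes refer to the activity latent; the measured
            # methylation correlation carries the opposite sign as usual
            sgn = 1.0 if (pair.planted_r >= 0 or modality == "methylation") else -1.0
            a = a_all.loc[s].to_numpy()
            eta = rng.standard_normal(n)
            z = sgn * rho * a + np.sqrt(1.0 - rho * rho) * eta
            new.loc[s] = np.maximum(0.0, _EMIT_MEAN + z)
        cohort.expression.loc[gene_id] = new
        rows.append((mod_id, pair.pair_id, ch, cl))
    return pd.DataFrame(rows, columns=["gene_id", "pair_id", "cor_high", "cor_low"])


_INFILTRATION_CELLS = [
    "Act_CD8", "NK", "Act_CD4", "Tfh", "Treg", "MDSC", "B_cell", "DC",
]
_N_COUPLED = 2


def generate_infiltration(cfg: SimConfig, cohort: Cohort) -> tuple[pd.DataFrame, list[str]]:
    """Per-sample infiltration scores; the first columns couple to the
    immune latent factor with strength ``infiltration_coupling``."""
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 71])
    n = len(cohort.sample_map)
    c = cfg.infiltration_coupling
    f = cohort.immune_factor.to_numpy()
    cols = {}
    coupled = _INFILTRATION_CELLS[:_N_COUPLED] if c > 0 else []
    for name in _INFILTRATION_CELLS:
        noise = rng.standard_normal(n)
        if name in coupled:
            cols[name] = c * f + np.sqrt(1.0 - c * c) * noise
        else:
            cols[name] = noise
    inf = pd.DataFrame(cols, index=cohort.sample_map.index)
    return inf, coupled


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class SimResult:
    config: SimConfig
    genome: Genome
    calls: pd.DataFrame
    truth: TruthTable
    cohort: Cohort
    infiltration: pd.DataFrame
    gene_sets: dict[str, list[str]]


def _gene_sets(cfg: SimConfig, truth_pairs: pd.DataFrame, immune: list[str],
               rng: np.random.Generator) -> dict[str, list[str]]:
    sets = {"IMMUNE_EVASION": list(immune)}
    pool = [g for g in cfg.gene_ids() if g not in set(immune)]
    size = max(3, cfg.immune_set_size)
    for k in range(2):
        if len(pool) >= size:
            picks = sorted(rng.choice(len(pool), size=size, replace=False).tolist())
            sets[f"DECOY_SET_{k + 1}"] = [pool[i] for i in picks]
    return sets


def simulate_all(cfg: SimConfig) -> SimResult:
    """Run every generator stage and assemble the full truth table."""
    cfg.validate()
    genome = generate_genome(cfg)
    calls, truth_enh, truth_noise = generate_transcript_calls(cfg, genome)
    truth_pairs = _pairs_table(cfg)
    cohort = generate_cohort(cfg, truth_pairs)
    truth_mod = plant_modulators(cfg, cohort)
    infiltration, coupled = generate_infiltration(cfg, cohort)
    immune = _immune_gene_ids(cfg)
    rng = np.random.default_rng([cfg.seed, 97])
    gene_sets = _gene_sets(cfg, truth_pairs, immune, rng)
    truth = TruthTable(
        enhancers=truth_enh,
        pairs=truth_pairs,
        modulators=truth_mod,
        noise_calls=truth_noise,
        immune_genes=immune,
        coupled_infiltration=coupled,
    )
    return SimResult(
        config=cfg, genome=genome, calls=calls, truth=truth, cohort=cohort,
        infiltration=infiltration, gene_sets=gene_sets,
    )


def write_outputs(res: SimResult, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    ekio.write_chrom_sizes(res.genome.chrom_sizes, os.path.join(outdir, "chrom.sizes"))
    ekio.write_genes_bed12(res.genome.genes, os.path.join(outdir, "genes.bed"))
    ekio.write_transcript_calls(res.calls, os.path.join(outdir, "calls"))
    ekio.write_matrix(res.cohort.expression, os.path.join(outdir, "expression.tsv"), "gene_id")
    ekio.write_matrix(res.cohort.atac, os.path.join(outdir, "atac.tsv"), "enhancer_id")
    ekio.write_matrix(res.cohort.methylation, os.path.join(outdir, "methylation.tsv"), "enhancer_id")
    ekio.write_matrix(res.cohort.erna, os.path.join(outdir, "erna.tsv"), "enhancer_id")
    ekio.write_sample_map(res.cohort.sample_map, os.path.join(outdir, "samples.tsv"))
    ekio.write_matrix(res.infiltration, os.path.join(outdir, "infiltration.tsv"), "sample")
    ekio.write_gmt(res.gene_sets, os.path.join(outdir, "gene_sets.gmt"))
    res.truth.write(outdir)
    with open(os.path.join(outdir, "config.json"), "w") as fh:
        json.dump(res.config.to_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
# ready-made configurations


def demo_config(
    seed: int = 0,
    *,
    n_cancer_types: int = 5,
    samples_per_type: int = 200,
    n_pairs: int = 30,
    target_r: float = 0.6,
    n_genes: int = 600,
    n_chroms: int = 4,
    chrom_length: int = 10_000_000,
    n_noise: int = 30,
    immune: bool = False,
    immune_set_size: int = 20,
    immune_r_high: float = 0.9,
    immune_r_low: float = 0.35,
    infiltration_coupling: float = 0.0,
    modulator: tuple[float, float] | None = None,
) -> SimConfig:
    """A standard study-sized configuration: one synthetic cell line per
    cancer type, pairs planted across the three modalities in rotation, an
    optional immune gene set with heterogeneous pair strengths, and an
    optional expression gate on the first planted pair."""
    if n_pairs + (immune_set_size if immune else 0) > n_genes // 2:
        raise ConfigError("too many planted pairs for the requested gene count")
    stride = max(2, n_genes // (n_pairs + (immune_set_size if immune else 0) + 2))
    pairs: list[tuple[int, int, float, str]] = []
    used: set[int] = set()
    nxt = 0

    def take() -> int:
        nonlocal nxt
        g = nxt % n_genes
        while g in used:
            nxt += 1
            g = nxt % n_genes
        used.add(g)
        nxt += stride
        return g

    for i in range(n_pairs):
        pairs.append((i, take(), target_r, MODALITIES[i % 3]))
    immune_genes: list[int] | None = None
    n_enh = n_pairs
    if immune:
        immune_genes = []
        for k in range(immune_set_size):
            g = take()
            r = immune_r_high if k % 2 == 0 else immune_r_low
            pairs.append((n_enh, g, r, "atac" if k % 2 == 0 else "erna"))
            immune_genes.append(g)
            n_enh += 1
    spec = []
    if modulator is not None:
        gm = next(i for i in range(n_genes) if i not in used)
        used.add(gm)
        spec.append((gm, 0, modulator[0], modulator[1]))
    return SimConfig(
        seed=seed,
        n_chroms=n_chroms,
        chrom_length=chrom_length,
        n_genes=n_genes,
        n_cell_lines=n_cancer_types,
        n_planted_enhancers=n_enh,
        n_noise_transcripts=n_noise,
        n_cancer_types=n_cancer_types,
        samples_per_type=samples_per_type,
        planted_pairs=pairs,
        modulator_spec=spec,
        immune_set_size=immune_set_size,
        infiltration_coupling=infiltration_coupling,
        immune_genes=immune_genes,
    )
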