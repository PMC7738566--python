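"""Enhancer-gene pairing: candidates, correlation, FDR, and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import enhancerkit as ek
from enhancerkit.pairing import CohortMatrices, PairingError

from conftest import random_genes


def _regions(rows):
    return pd.DataFrame(rows, columns=["enhancer_id", "chrom", "start", "end"])


class TestCandidates:
    GENES = pd.DataFrame(
        [
            ("G1", "chr1", 599_000, 610_000, "+", 599_000, 610_000),
            ("G2", "chr2", 0, 10_000, "+", 0, 10_000),
        ],
        columns=["gene_id", "chrom", "start", "end", "strand", "utr5_anchor", "utr3_anchor"],
    )

    def test_gene_within_window_is_candidate(self):
        cat = _regions([("E1", "chr1", 99_000, 100_000)])
        out = ek.candidate_pairs(cat, self.GENES, window=500_000)
        assert set(zip(out["enhancer_id"], out["gene_id"])) == {("E1", "G1")}

    def test_gene_beyond_window_or_other_chrom_excluded(self):
        cat = _regions([("E1", "chr1", 0, 1_000)])
        out = ek.candidate_pairs(cat, self.GENES, window=500_000)
        assert out.empty  # G1 is 598 kb away, G2 on another chromosome

    def test_matches_quadratic_distance_oracle(self):
        rng = np.random.default_rng(23)
        genes = random_genes(rng, 50)
        starts = rng.integers(0, 1_000_000, size=20)
        cat = pd.DataFrame(
            {
                "enhancer_id": [f"E{i}" for i in range(20)],
                "chrom": rng.choice(["chr1", "chr2"], size=20),
                "start": starts,
                "end": starts + rng.integers(500, 2_000, size=20),
            }
        )
        window = 100_000
        got = set(map(tuple, ek.candidate_pairs(cat, genes, window)[
            ["enhancer_id", "gene_id"]].itertuples(index=False)))
        expected = set()
        for e in cat.itertuples(index=False):
            for g in genes.itertuples(index=False):
                if e.chrom != g.chrom:
                    continue
                d = max(0, max(g.start - e.end, e.start - g.end))
                if d <= window:
                    expected.add((e.enhancer_id, g.gene_id))
        assert got == expected

    def test_external_pairs_union_semantics(self):
        cat = _regions([("E1", "chr1", 99_000, 100_000)])
        ext = pd.DataFrame(
            [("chr1", 99_100, 99_900, "G2"), ("chr1", 99_100, 99_900, "G1")],
            columns=["chrom", "start", "end", "gene_id"],
        )
        out = ek.candidate_pairs(cat, self.GENES, window=500_000, external_pairs=ext)
        pairs = set(zip(out["enhancer_id"], out["gene_id"]))
        assert pairs == {("E1", "G1"), ("E1", "G2")}
        src = out.set_index("gene_id")["source"]
        assert src["G1"] == "window"  # window provenance wins on duplicates
        assert src["G2"] == "external_list"

    def test_unmatched_external_region_dropped(self):
        cat = _regions([("E1", "chr1", 99_000, 100_000)])
        ext = pd.DataFrame([("chr1", 200_000, 201_000, "G2")],
                           columns=["chrom", "start", "end", "gene_id"])
        out = ek.candidate_pairs(cat, self.GENES, window=500_000, external_pairs=ext)
        assert ("E1", "G2") not in set(zip(out["enhancer_id"], out["gene_id"]))


class TestErnaProfileMapping:
    CAT = _regions([("E1", "chr1", 10_000, 11_000)])

    def _profiles(self, rows):
        return pd.DataFrame(rows, columns=["profile_id", "chrom", "start", "end"])

    def test_entry_within_500bp_maps(self):
        prof = self._profiles([("P1", "chr1", 11_300, 11_800)])  # 300 bp away
        assert ek.map_erna_profile(self.CAT, prof) == {"E1": "P1"}

    def test_entry_beyond_500bp_unmapped(self):
        prof = self._profiles([("P1", "chr1", 11_800, 12_300)])  # 800 bp away
        assert ek.map_erna_profile(self.CAT, prof) == {}

    def test_nearest_wins_with_leftmost_tiebreak(self):
        prof = self._profiles([
            ("P_far", "chr1", 11_400, 11_900),   # 400 bp away
            ("P_near", "chr1", 11_100, 11_600),  # 100 bp away
        ])
        assert ek.map_erna_profile(self.CAT, prof)["E1"] == "P_near"
        tie = self._profiles([
            ("P_right", "chr1", 11_100, 11_600),  # 100 bp right
            ("P_left", "chr1", 9_400, 9_900),     # 100 bp left, leftmost start
        ])
        assert ek.map_erna_profile(self.CAT, tie)["E1"] == "P_left"


def _matrices(expr, act, sample_types, modality="atac"):
    kwargs = {"atac": None, "methylation": None, "erna": None}
    kwargs[modality] = act
    return CohortMatrices(expression=expr, sample_type=sample_types, **kwargs)


class TestCorrelation:
    def _setup(self, x, y):
        samples = [f"s{i}" for i in range(len(x))]
        expr = pd.DataFrame([y], index=["G1"], columns=samples)
        act = pd.DataFrame([x], index=["E1"], columns=samples)
        stypes = pd.Series("CT1", index=samples)
        cands = pd.DataFrame([("E1", "G1", "window")],
                             columns=["enhancer_id", "gene_id", "source"])
        return cands, _matrices(expr, act, stypes)

    def test_identical_vectors_give_r_one(self):
        v = [1.0, 3.0, 2.0, 5.0, 4.0]
        cands, mats = self._setup(v, v)
        out = ek.correlate_pairs(cands, mats, modalities=("atac",))
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert out["p"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_exact_linearity(self):
        cands, mats = self._setup([1, 2, 3, 4], [2, 4, 6, 8])
        out = ek.correlate_pairs(cands, mats, modalities=("atac",))
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_missing_modality_flagged_not_zero(self):
        cands, mats = self._setup([1, 2, 3], [1, 2, 3])
        cands2 = pd.DataFrame([("E_absent", "G1", "window")],
                              columns=["enhancer_id", "gene_id", "source"])
        out = ek.correlate_pairs(cands2, mats, modalities=("atac",))
        assert out["note"].iloc[0] == "missing_modality"
        assert np.isnan(out["r"].iloc[0])
        assert ek.enhancer_activity(mats, "E_absent", "atac") is None

    def test_zero_variance_flagged(self):
        cands, mats = self._setup([2, 2, 2, 2], [1, 2, 3, 4])
        out = ek.correlate_pairs(cands, mats, modalities=("atac",))
        assert out["note"].iloc[0] == "zero_variance"
        assert not out["functional"].any()

    def test_too_few_observations_flagged(self):
        cands, mats = self._setup([1, 2], [1, 2])
        out = ek.correlate_pairs(cands, mats, modalities=("atac",))
        assert out["note"].iloc[0] == "too_few_observations"

    def test_matches_textbook_formula_oracle(self):
        rng = np.random.default_rng(31)
        n = 25
        samples = [f"s{i}" for i in range(n)]
        stypes = pd.Series("CT1", index=samples)
        expr = pd.DataFrame(rng.normal(size=(30, n)),
                            index=[f"G{i}" for i in range(30)], columns=samples)
        act = pd.DataFrame(rng.normal(size=(30, n)),
                           index=[f"E{i}" for i in range(30)], columns=samples)
        cands = pd.DataFrame(
            [(f"E{i}", f"G{i}", "window") for i in range(30)],
            columns=["enhancer_id", "gene_id", "source"],
        )
        out = ek.correlate_pairs(cands, _matrices(expr, act, stypes), modalities=("atac",))
        for row in out.itertuples():
            x = act.loc[row.enhancer_id].to_numpy()
            y = expr.loc[row.gene_id].to_numpy()
            # direct textbook formula
            r_exp = (np.sum((x - x.mean()) * (y - y.mean()))
                     / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
            t = r_exp * np.sqrt((n - 2) / (1 - r_exp**2))
            p_exp = 2 * stats.t.sf(abs(t), n - 2)
            assert row.r == pytest.approx(r_exp, abs=1e-12)
            assert row.p == pytest.approx(p_exp, abs=1e-12)

    def test_functional_set_invariant_under_sample_permutation(self, small_sim):
        mats = small_sim.cohort.to_matrices()
        cat = small_sim.truth.enhancers.rename(columns={"enhancer_id": "enhancer_id"})
        cands = ek.candidate_pairs(cat, small_sim.genome.genes, window=500_000)
        base = ek.fdr_filter(ek.correlate_pairs(cands, mats))
        rng = np.random.default_rng(0)
        perm = rng.permutation(mats.expression.columns.to_numpy())
        mats2 = CohortMatrices(
            expression=mats.expression.loc[:, perm],
            atac=mats.atac.loc[:, perm],
            methylation=mats.methylation.loc[:, perm],
            erna=mats.erna.loc[:, perm],
            sample_type=mats.sample_type,
        )
        shuffled = ek.fdr_filter(ek.correlate_pairs(cands, mats2))

        def functional_set(df):
            f = df[df["functional"]]
            return set(zip(f["enhancer_id"], f["gene_id"], f["cancer_type"], f["modality"]))

        assert functional_set(base) == functional_set(shuffled)


def _bh_reference(pvals):
    """Step-up BH: sort, scale by m/rank, enforce monotonicity by cummin."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestFdrFilter:
    def _pairs(self, pvals, rs=None, ct="CT1", modality="atac"):
        rs = rs if rs is not None else [0.9] * len(pvals)
        return pd.DataFrame(
            {
                "enhancer_id": [f"E{i}" for i in range(len(pvals))],
                "gene_id": [f"G{i}" for i in range(len(pvals))],
                "cancer_type": ct, "modality": modality, "n_obs": 100,
                "r": rs, "p": pvals, "q": np.nan, "functional": False,
                "source": "window", "note": "",
            }
        )

    def test_hand_computed_bh(self):
        out = ek.fdr_filter(self._pairs([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(out["q"], 0.04)

    def test_single_test_family(self):
        out = ek.fdr_filter(self._pairs([0.03]))
        assert out["q"].iloc[0] == pytest.approx(0.03)

    def test_magnitude_gate_blocks_weak_correlation(self):
        out = ek.fdr_filter(self._pairs([0.001, 0.5], rs=[0.2, 0.9]))
        assert out["q"].iloc[0] < 0.05 and not out["functional"].iloc[0]

    def test_families_are_per_cancer_and_modality(self):
        a = self._pairs([0.04] * 2, ct="CT1")
        b = self._pairs([0.5] * 50, ct="CT2")
        out = ek.fdr_filter(pd.concat([a, b], ignore_index=True))
        # CT1's family is untouched by CT2's many large p-values
        assert np.allclose(out[out["cancer_type"] == "CT1"]["q"], 0.04)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    def test_bh_matches_step_up_reference(self, pvals):
        out = ek.fdr_filter(self._pairs(pvals))
        assert np.allclose(out["q"].to_numpy(), _bh_reference(pvals), atol=1e-12)

    def test_methylation_pairs_pass_on_magnitude(self, small_sim):
        mats = small_sim.cohort.to_matrices()
        cands = ek.candidate_pairs(small_sim.truth.enhancers, small_sim.genome.genes)
        pairs = ek.fdr_filter(ek.correlate_pairs(cands, mats))
        planted = small_sim.truth.pairs
        meth = planted[planted["modality"] == "methylation"]
        sub = pairs.merge(meth, on=["enhancer_id", "gene_id"])
        sub = sub[sub["modality_x"] == "methylation"]
        assert (sub["r"] < 0).all()
        assert sub["functional"].mean() > 0.8


class TestSummaries:
    def _pairs(self, rows):
        return pd.DataFrame(
            rows,
            columns=["enhancer_id", "gene_id", "cancer_type", "modality", "r", "functional"],
        )

    def test_counts_match_brute_force_tally(self):
        rng = np.random.default_rng(2)
        rows = []
        for e in range(4):
            for g in range(3):
                for ct in ("CT1", "CT2", "CT3"):
                    for m in ("atac", "methylation", "erna"):
                        rows.append((f"E{e}", f"G{g}", ct, m, 0.5, bool(rng.random() < 0.3)))
        pairs = self._pairs(rows)
        s = ek.summarize_pairs(pairs)
        func = pairs[pairs["functional"]]
        assert s["n_functional_records"] == len(func)
        eg = func[["enhancer_id", "gene_id"]].drop_duplicates()
        assert s["n_functional_pairs"] == len(eg)
        assert s["n_functional_enhancers"] == func["enhancer_id"].nunique()
        assert sum(s["recurrence_histogram"].values()) == len(eg)
        assert sum(s["modality_support"].values()) == len(
            func[["enhancer_id", "gene_id", "cancer_type"]].drop_duplicates()
        )

    def test_recurrence_and_triple_support(self):
        rows = [("E1", "G1", ct, m, 0.5, True)
                for ct in ("CT1", "CT2", "CT3") for m in ("atac", "methylation", "erna")]
        s = ek.summarize_pairs(self._pairs(rows))
        assert s["recurrence_histogram"] == {3: 1}
        assert s["modality_support"] == {"atac+erna+methylation": 3}


class TestGeneSkip:
    GENES = pd.DataFrame(
        [
            ("G1", "chr1", 10_000, 12_000, "+", 10_000, 12_000),
            ("G2", "chr1", 20_000, 22_000, "+", 20_000, 22_000),
            ("G3", "chr1", 30_000, 32_000, "+", 30_000, 32_000),
            ("G4", "chr1", 40_000, 42_000, "+", 40_000, 42_000),
        ],
        columns=["gene_id", "chrom", "start", "end", "strand", "utr5_anchor", "utr3_anchor"],
    )
    CAT = _regions([("E1", "chr1", 0, 1_000)])

    def _pairs(self, gene):
        return pd.DataFrame(
            [("E1", gene, "CT1", "atac", 0.5, True)],
            columns=["enhancer_id", "gene_id", "cancer_type", "modality", "r", "functional"],
        )

    def test_adjacent_gene_skips_zero(self):
        out = ek.gene_skip_counts(self._pairs("G1"), self.CAT, self.GENES)
        assert out["n_skipped"].iloc[0] == 0

    def test_two_genes_inside_span(self):
        out = ek.gene_skip_counts(self._pairs("G3"), self.CAT, self.GENES)
        assert out["n_skipped"].iloc[0] == 2

    def test_matches_containment_oracle(self):
        rng = np.random.default_rng(8)
        genes = random_genes(rng, 30, chroms=("chr1",), span=500_000)
        starts = rng.integers(0, 500_000, size=10)
        cat = pd.DataFrame({"enhancer_id": [f"E{i}" for i in range(10)], "chrom": "chr1",
                            "start": starts, "end": starts + 1_000})
        rows = [(f"E{i}", genes["gene_id"].iloc[rng.integers(len(genes))], "CT1", "atac",
                 0.5, True) for i in range(10)]
        pairs = pd.DataFrame(rows, columns=["enhancer_id", "gene_id", "cancer_type",
                                            "modality", "r", "functional"])
        out = ek.gene_skip_counts(pairs, cat, genes).set_index(["enhancer_id", "gene_id"])
        for (eid, gid), row in out.iterrows():
            e = cat.set_index("enhancer_id").loc[eid]
            g = genes.set_index("gene_id").loc[gid]
            if g["start"] >= e["end"]:
                lo, hi = e["end"], g["start"]
            elif g["end"] <= e["start"]:
                lo, hi = g["end"], e["start"]
            else:
                assert row["n_skipped"] == 0
                continue
            n = sum(
                1 for o in genes.itertuples(index=False)
                if o.gene_id != gid and o.start >= lo and o.end <= hi
            )
            assert row["n_skipped"] == n

    def test_trans_chromosomal_excluded_with_note(self):
        genes = pd.concat([self.GENES, pd.DataFrame(
            [("G9", "chr2", 0, 1_000, "+", 0, 1_000)], columns=self.GENES.columns)],
            ignore_index=True)
        out = ek.gene_skip_counts(self._pairs("G9"), self.CAT, genes)
        assert out["note"].iloc[0] == "trans_chromosomal"
        assert np.isnan(out["n_skipped"].iloc[0])


class TestDifferentialExpression:
    def _expr(self, tumor, normal):
        nt, nn = len(tumor[0]), len(normal[0])
        cols = [f"t{i}" for i in range(nt)] + [f"n{i}" for i in range(nn)]
        data = [list(t) + list(n) for t, n in zip(tumor, normal)]
        expr = pd.DataFrame(data, index=[f"G{i}" for i in range(len(tumor))], columns=cols)
        labels = pd.Series(["tumor"] * nt + ["normal"] * nn, index=cols)
        return expr, labels

    def test_identical_groups_not_de(self):
        expr, labels = self._expr([[5, 5, 5, 5, 5]], [[5, 5, 5, 5, 5]])
        out = ek.differential_expression(expr, labels)
        assert out["fold_change"].iloc[0] == pytest.approx(1.0)
        assert not out["de"].iloc[0]

    def test_two_fold_change_with_tiny_variance_is_de(self):
        rng = np.random.default_rng(1)
        t = 10 + rng.normal(0, 0.01, size=10)
        n = 5 + rng.normal(0, 0.01, size=10)
        expr, labels = self._expr([t], [n])
        out = ek.differential_expression(expr, labels)
        # Welch oracle on the same vectors
        p_exp = stats.ttest_ind(t, n, equal_var=False).pvalue
        assert out["p"].iloc[0] == pytest.approx(p_exp)
        assert out["de"].iloc[0]

    def test_fold_change_gate_blocks_significant_but_small_shift(self):
        rng = np.random.default_rng(2)
        t = 7.0 + rng.normal(0, 0.01, size=20)
        n = 5.0 + rng.normal(0, 0.01, size=20)
        expr, labels = self._expr([t], [n])
        out = ek.differential_expression(expr, labels)
        assert out["q"].iloc[0] < 0.05
        assert out["fold_change"].iloc[0] < 1.5
        assert not out["de"].iloc[0]

    def test_pooled_normal_fallback_is_descriptive(self):
        expr, labels = self._expr([[10, 10, 10]], [[5]])
        pooled = pd.Series([5.0], index=["G0"])
        out = ek.differential_expression(expr, labels, pooled_normal_mean=pooled)
        assert out["note"].iloc[0] == "descriptive_pooled_normal"
        assert out["fold_change"].iloc[0] == pytest.approx(2.0)
        assert np.isnan(out["p"].iloc[0])

    def test_zero_normal_mean_flagged(self):
        expr, labels = self._expr([[1, 1, 1, 1, 1]], [[0, 0, 0, 0, 0]])
        out = ek.differential_expression(expr, labels)
        assert np.isnan(out["fold_change"].iloc[0])
        assert out["note"].iloc[0] == "undefined_fold_change"
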