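"""P+T score construction: harmonization, LD, clumping (vs a literal greedy
oracle), the weighted-sum formula (vs hand computation), grid, and
standardization."""

import numpy as np
import pandas as pd
import pytest

from chipscan.scores import (CLUMP_R2_GRID, P_THRESHOLD_GRID, WINDOW_BP_GRID,
                             ClumpResult, MonomorphicVariantError, PtConfig,
                             build_pt_score, clump, enumerate_candidate_grid,
                             harmonize_alleles, ld_r2, standardize_score,
                             build_grid_scores)
from conftest import make_dosage, make_sumstats


# ------------------------------------------------------------------- oracles

def oracle_greedy_clump(sumstats, reference, r2_clump, window_bp):
    """Literal transcription of the greedy clumping definition."""
    recs = sumstats.to_dict("records")
    recs.sort(key=lambda r: (r["pvalue"], str(r["chrom"]), r["pos"]))
    remaining = list(recs)
    indices, removed = [], {}
    while remaining:
        head = remaining.pop(0)
        indices.append(head["variant_id"])
        survivors = []
        for r in remaining:
            near = (str(r["chrom"]) == str(head["chrom"])
                    and abs(r["pos"] - head["pos"]) <= window_bp)
            if near:
                a = reference.dosage(head["variant_id"])
                b = reference.dosage(r["variant_id"])
                if a.std() == 0 or b.std() == 0:
                    r2 = 0.0
                else:
                    r2 = np.corrcoef(a, b)[0, 1] ** 2
                if r2 >= r2_clump:
                    removed[r["variant_id"]] = head["variant_id"]
                    continue
            survivors.append(r)
        remaining = survivors
    return indices, removed


def oracle_pt_score(sumstats, genotypes, index_ids, p_thresh):
    """Literal weighted sum: sum_j beta_j G_ij over clumped j with p_j < p_r."""
    scores = np.zeros(genotypes.n_samples)
    for _, rec in sumstats.iterrows():
        if rec["variant_id"] in index_ids and rec["pvalue"] < p_thresh:
            g = genotypes.dosage(rec["variant_id"]).copy()
            if np.isnan(g).any():
                g[np.isnan(g)] = np.nanmean(g)
            scores = scores + rec["beta"] * g
    return scores


def random_instance(rng, n_ref=40, n_geno=6, max_var=12):
    m = int(rng.integers(1, max_var + 1))
    pos = np.sort(rng.choice(np.arange(1, 4_000_000, 1000), size=m,
                             replace=False))
    base = rng.integers(0, 3, size=(n_ref, m)).astype(float)
    # force correlated pairs and occasional monomorphic columns
    for j in range(1, m):
        u = rng.uniform()
        if u < 0.3:
            base[:, j] = base[:, j - 1]          # perfect proxy
        elif u < 0.4:
            base[:, j] = float(rng.integers(0, 3))  # monomorphic
    ref = make_dosage(base, positions=list(pos))
    geno = make_dosage(rng.integers(0, 3, size=(n_geno, m)).astype(float),
                       positions=list(pos))
    # discrete p values force ties; betas arbitrary
    pvals = rng.choice([1e-8, 1e-5, 1e-3, 0.02, 0.3, 0.3], size=m)
    betas = np.round(rng.normal(0, 0.5, size=m), 3)
    ss = make_sumstats(ref, betas, pvals)
    return ref, geno, ss


# -------------------------------------------------------------- harmonization

class TestHarmonize:
    def _geno(self):
        return make_dosage(np.zeros((2, 5)),
                           positions=[100, 200, 300, 400, 500],
                           counted=["A", "C", "T", "G", "A"],
                           other=["G", "A", "C", "T", "T"])

    def test_rules_on_toy_set(self):
        geno = self._geno()
        ss = pd.DataFrame({
            "gene_id": "G", "chrom": "1",
            "pos": [100, 200, 300, 400, 500],
            "effect_allele": ["A", "A", "T", "C", "A"],
            "other_allele": ["G", "C", "C", "A", "T"],
            "beta": [0.3, 0.3, 0.2, 0.1, 0.5],
            "pvalue": 0.01, "se": 0.1, "eaf": 0.4, "n": 100, "tss": 100,
        })
        out = harmonize_alleles(ss, geno)
        # identity kept; swap flipped; allele mismatch dropped; A/T ambiguous dropped
        assert len(out) == 3
        assert out.loc[out["pos"] == 100, "beta"].iloc[0] == 0.3
        flipped = out.loc[out["pos"] == 200].iloc[0]
        assert flipped["beta"] == -0.3
        assert flipped["effect_allele"] == "C"
        assert flipped["eaf"] == pytest.approx(0.6)
        assert 400 not in out["pos"].values  # C/A vs G/T mismatch
        assert 500 not in out["pos"].values  # A/T strand-ambiguous

    def test_ambiguous_kept_when_requested(self):
        geno = self._geno()
        ss = pd.DataFrame({
            "gene_id": "G", "chrom": "1", "pos": [500],
            "effect_allele": ["A"], "other_allele": ["T"],
            "beta": [0.5], "pvalue": 0.01, "se": 0.1, "eaf": 0.4,
            "n": 100, "tss": 100,
        })
        assert len(harmonize_alleles(ss, geno, drop_ambiguous=False)) == 1

    def test_duplicated_positions_rejected(self):
        geno = self._geno()
        ss = pd.DataFrame({
            "gene_id": "G", "chrom": "1", "pos": [100, 100],
            "effect_allele": ["A", "A"], "other_allele": ["G", "G"],
            "beta": [0.1, 0.2], "pvalue": 0.5, "se": 0.1, "eaf": 0.4,
            "n": 100, "tss": 100,
        })
        with pytest.raises(ValueError, match="duplicated"):
            harmonize_alleles(ss, geno)


# ----------------------------------------------------------------------- LD

class TestLdR2:
    def test_self_and_duplicate_columns(self):
        vals = np.array([[0, 0], [1, 1], [2, 2], [0, 0], [1, 1], [2, 2.0]])
        dm = make_dosage(vals)
        ids = dm.variants["variant_id"]
        assert ld_r2(dm, ids[0], ids[0]) == pytest.approx(1.0)
        assert ld_r2(dm, ids[0], ids[1]) == pytest.approx(1.0)

    def test_independent_variants_near_zero(self):
        rng = np.random.default_rng(0)
        dm = make_dosage(rng.integers(0, 3, size=(10_000, 2)).astype(float))
        ids = dm.variants["variant_id"]
        assert ld_r2(dm, ids[0], ids[1]) < 0.01

    def test_monomorphic_raises(self):
        dm = make_dosage(np.column_stack([np.ones(6), np.arange(6) % 3]).astype(float))
        ids = dm.variants["variant_id"]
        with pytest.raises(MonomorphicVariantError):
            ld_r2(dm, ids[0], ids[1])


# ------------------------------------------------------------------ clumping

class TestClump:
    def test_single_variant_is_sole_index(self):
        dm = make_dosage(np.array([[0.], [1], [2], [1]]))
        ss = make_sumstats(dm, [0.2], [1e-4])
        res = clump(ss, dm, 0.1, 250_000)
        assert res.index_variant_ids == [dm.variants["variant_id"][0]]
        assert res.removed == {}

    def test_five_variant_toy_matches_hand_enumeration(self):
        # top hit at pos 1000; two perfect proxies inside the window; one
        # perfect proxy outside the window; one independent variant inside
        rng = np.random.default_rng(3)
        x = rng.integers(0, 3, size=200).astype(float)
        indep = rng.integers(0, 3, size=200).astype(float)
        vals = np.column_stack([x, x, x, indep, x])
        positions = [1000, 2000, 3000, 4000, 900_000]
        dm = make_dosage(vals, positions=positions)
        ss = make_sumstats(dm, [0.5] * 5, [1e-9, 1e-4, 1e-3, 1e-2, 1e-5])
        res = clump(ss, dm, r2_clump=0.1, window_bp=10_000)
        ids = dm.variants["variant_id"]
        assert sorted(res.index_variant_ids) == sorted([ids[0], ids[3], ids[4]])
        assert res.removed == {ids[1]: ids[0], ids[2]: ids[0]}

    def test_matches_greedy_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            ref, _, ss = random_instance(rng)
            r2c = float(rng.choice(CLUMP_R2_GRID))
            w = int(rng.choice([5_000, 100_000, 1_000_000]))
            got = clump(ss, ref, r2c, w)
            exp_idx, exp_removed = oracle_greedy_clump(ss, ref, r2c, w)
            assert got.index_variant_ids == exp_idx
            assert got.removed == exp_removed

    def test_order_invariance(self):
        rng = np.random.default_rng(9)
        ref, _, ss = random_instance(rng)
        res1 = clump(ss, ref, 0.1, 1_000_000)
        shuffled = ss.sample(frac=1.0, random_state=1).reset_index(drop=True)
        res2 = clump(shuffled, ref, 0.1, 1_000_000)
        assert res1.index_variant_ids == res2.index_variant_ids
        assert res1.removed == res2.removed

    def test_variant_absent_from_reference(self):
        dm = make_dosage(np.array([[0.], [1], [2], [1]]), positions=[1000])
        ss = pd.concat([
            make_sumstats(dm, [0.2], [1e-4]),
            make_sumstats(make_dosage(np.array([[0.], [1], [2], [1]]),
                                      positions=[2000]), [0.1], [1e-2]),
        ], ignore_index=True)
        dropped = clump(ss, dm, 0.1, 250_000)
        assert dropped.index_variant_ids == [dm.variants["variant_id"][0]]
        kept = clump(ss, dm, 0.1, 250_000, missing_reference="keep")
        assert len(kept.index_variant_ids) == 2


# -------------------------------------------------------------------- scoring

class TestBuildPtScore:
    def test_hand_computed_toy(self):
        # beta=(0.5,-0.2,0.1), p=(1e-9,1e-6,0.5), threshold 1e-3, row (2,1,2):
        # 0.5*2 + (-0.2)*1 = 0.8, third variant excluded by the indicator
        dm = make_dosage(np.array([[2.0, 1.0, 2.0], [0.0, 0.0, 1.0]]))
        ss = make_sumstats(dm, [0.5, -0.2, 0.1], [1e-9, 1e-6, 0.5])
        clumped = ClumpResult(index_variant_ids=list(dm.variants["variant_id"]))
        sv = build_pt_score(dm, ss, clumped, p_thresh=1e-3)
        assert sv.values[0] == pytest.approx(0.8)
        assert sv.values[1] == pytest.approx(0.0)
        assert sv.n_variants_used == 2
        assert not sv.degenerate

    def test_threshold_is_strict(self):
        dm = make_dosage(np.array([[2.0], [1.0]]))
        ss = make_sumstats(dm, [1.0], [1e-3])
        clumped = ClumpResult(index_variant_ids=list(dm.variants["variant_id"]))
        sv = build_pt_score(dm, ss, clumped, p_thresh=1e-3)
        assert sv.n_variants_used == 0 and sv.degenerate

    def test_zero_betas_give_zero_score(self):
        dm = make_dosage(np.array([[2.0, 1.0], [0.0, 2.0]]))
        ss = make_sumstats(dm, [0.0, 0.0], [1e-9, 1e-9])
        clumped = ClumpResult(index_variant_ids=list(dm.variants["variant_id"]))
        sv = build_pt_score(dm, ss, clumped, p_thresh=0.1)
        np.testing.assert_allclose(sv.values, 0.0)

    def test_missing_dosage_mean_imputed(self):
        dm = make_dosage(np.array([[2.0], [np.nan], [0.0]]))
        ss = make_sumstats(dm, [1.0], [1e-9])
        clumped = ClumpResult(index_variant_ids=list(dm.variants["variant_id"]))
        sv = build_pt_score(dm, ss, clumped, p_thresh=0.1)
        assert sv.values[1] == pytest.approx(1.0)  # mean of 2 and 0

    def test_matches_literal_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            ref, geno, ss = random_instance(rng)
            r2c = float(rng.choice(CLUMP_R2_GRID))
            w = int(rng.choice([5_000, 1_000_000]))
            p_r = float(rng.choice(P_THRESHOLD_GRID))
            clumped = clump(ss, ref, r2c, w)
            sv = build_pt_score(geno, ss, clumped, p_r)
            exp = oracle_pt_score(ss, geno, set(clumped.index_variant_ids), p_r)
            np.testing.assert_allclose(sv.values, exp, atol=1e-12)

    def test_score_linearity_in_weights(self):
        rng = np.random.default_rng(8)
        ref, geno, ss = random_instance(rng, max_var=8)
        clumped = clump(ss, ref, 0.1, 1_000_000)
        ss2 = ss.copy()
        ss2["beta"] = rng.normal(size=len(ss))
        ss_sum = ss.copy()
        ss_sum["beta"] = ss["beta"] + ss2["beta"]
        a = build_pt_score(geno, ss, clumped, 0.1).values
        b = build_pt_score(geno, ss2, clumped, 0.1).values
        c = build_pt_score(geno, ss_sum, clumped, 0.1).values
        np.testing.assert_allclose(a + b, c, atol=1e-10)

    def test_monotone_inclusion_in_threshold(self):
        rng = np.random.default_rng(10)
        ref, geno, ss = random_instance(rng)
        clumped = clump(ss, ref, 0.01, 1_000_000)
        used = [build_pt_score(geno, ss, clumped, p).n_variants_used
                for p in sorted(P_THRESHOLD_GRID)]
        assert used == sorted(used)


class TestGrid:
    def test_grid_size_order_uniqueness(self):
        grid = enumerate_candidate_grid()
        assert len(grid) == 30
        assert len(set(grid)) == 30
        assert grid[0] == PtConfig(0.1, 5e-8, 250_000)
        assert {c.r2_clump for c in grid} == set(CLUMP_R2_GRID)
        assert {c.p_thresh for c in grid} == set(P_THRESHOLD_GRID)
        assert {c.window_bp for c in grid} == set(WINDOW_BP_GRID)

    def test_off_grid_config_rejected(self):
        with pytest.raises(ValueError):
            PtConfig(0.5, 5e-8, 250_000)


class TestStandardize:
    def _score(self, values, **kw):
        from chipscan.scores import ScoreVector
        return ScoreVector(gene_id="G", config=None,
                           sample_ids=[f"S{i}" for i in range(len(values))],
                           values=np.asarray(values, dtype=float),
                           n_variants_used=1, **kw)

    def test_hand_computed_population_sd(self):
        out = standardize_score(self._score([1, 2, 3]))
        np.testing.assert_allclose(out.values, [-1.2247, 0.0, 1.2247],
                                   atol=1e-4)
        assert out.standardized

    def test_constant_score_degenerate(self):
        out = standardize_score(self._score([2, 2, 2]))
        assert out.degenerate
        np.testing.assert_allclose(out.values, 0.0)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            standardize_score(self._score([1, 2, 3]), population=[])

    def test_subset_population_statistics(self):
        # standardize on a stratum: that stratum gets mean 0, SD 1
        out = standardize_score(self._score([1, 2, 3, 100]),
                                population=["S0", "S1", "S2"])
        np.testing.assert_allclose(out.values[:3].mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.values[:3].std(), 1.0, atol=1e-12)


class TestGridScores:
    def test_grid_build_returns_30_standardized_candidates(self):
        rng = np.random.default_rng(11)
        ref, geno, ss = random_instance(rng, n_ref=60, n_geno=40, max_var=10)
        out = build_grid_scores(geno, ss, ref)
        assert len(out) == 30
        for sv in out:
            assert sv.standardized
            if not sv.degenerate:
                assert abs(np.nanmean(sv.values)) < 1e-8
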