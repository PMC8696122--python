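"""ORA and GSEA: hypergeometric enrichment, signal-to-noise ranking,
enrichment scores and permutation normalization."""
import numpy as np
import pandas as pd
import pytest

from lncnet.enrichment import (
    GeneSetCollection,
    gsea,
    gsea_es,
    leading_edge,
    ora_hypergeom,
    read_gmt,
    signal_to_noise_rank,
    signal_to_noise_scores,
    significant_sets,
    write_gmt,
)
from lncnet.models import ValidationError


class TestOra:
    def test_single_tail_example(self):
        universe = [f"g{i}" for i in range(20)]
        p, k = ora_hypergeom(universe[:5], universe[:5], universe)
        assert k == 5
        assert p == pytest.approx(1 / 15_504, rel=1e-9)

    def test_zero_overlap(self):
        universe = [f"g{i}" for i in range(20)]
        p, k = ora_hypergeom(universe[:5], universe[10:15], universe)
        assert (p, k) == (1.0, 0)

    def test_de_equals_universe(self):
        universe = [f"g{i}" for i in range(20)]
        p, k = ora_hypergeom(universe, universe[:7], universe)
        assert k == 7 and p == pytest.approx(1.0)

    def test_outside_universe_restricted(self):
        universe = [f"g{i}" for i in range(10)]
        p, k = ora_hypergeom(["g0", "g1", "alien"], universe[:2], universe)
        assert k == 2


class TestGmtRoundTrip:
    def test_round_trip(self, tmp_path):
        sets = {"s1": {"a", "b", "c"}, "s2": {"x"}}
        path = str(tmp_path / "sets.gmt")
        write_gmt(sets, path, descriptions={"s1": "BP"})
        coll = read_gmt(path)
        assert coll.sets == sets and coll.categories["s1"] == "BP"

    def test_empty_collection(self, tmp_path):
        path = str(tmp_path / "empty.gmt")
        write_gmt({}, path)
        assert len(read_gmt(path)) == 0


class TestSignalToNoise:
    def test_floor_arithmetic(self):
        # constant groups: both sds floor to 0.2*|mu| (min 0.2)
        expr = pd.DataFrame([[2.0, 2.0, 2.0, 1.0, 1.0, 1.0]], index=["g"],
                            columns=list("abcdef"))
        s = signal_to_noise_scores(expr, list("abc"), list("def"))
        assert s["g"] == pytest.approx(1 / 0.6)

    def test_antisymmetry(self):
        rng = np.random.default_rng(8)
        expr = pd.DataFrame(rng.random((5, 6)), columns=list("abcdef"))
        fwd = signal_to_noise_scores(expr, list("abc"), list("def"))
        rev = signal_to_noise_scores(expr, list("def"), list("abc"))
        assert np.allclose(fwd, -rev)

    def test_zero_scores_stable_order(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 1.0, 2.0], [1.0, 2.0, 1.0, 2.0]],
            index=["g2", "g1"], columns=list("abcd"),
        )
        ranked = signal_to_noise_rank(expr, ["a", "b"], ["c", "d"])
        assert list(ranked.index) == ["g2", "g1"]  # input order preserved on ties

    def test_small_group_error(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], columns=list("abc"))
        with pytest.raises(ValidationError):
            signal_to_noise_scores(expr, ["a"], ["b", "c"])


class TestEnrichmentScore:
    def test_top_gene_hand_walk(self):
        ranked = pd.Series([2.0, 2.0, -2.0, -2.0], index=["g1", "g2", "g3", "g4"])
        es, running = gsea_es(ranked, {"g1"})
        assert es == pytest.approx(1.0)
        assert running[0] == pytest.approx(1.0)

    def test_all_genes_degenerate(self):
        ranked = pd.Series([3.0, 2.0, 1.0], index=["a", "b", "c"])
        es, running = gsea_es(ranked, {"a", "b", "c"})
        assert es == pytest.approx(1.0) and running[-1] == pytest.approx(1.0)

    def test_reversal_negates_loading(self):
        ranked = pd.Series([4.0, 3.0, 2.0, 1.0, 0.5, 0.1],
                           index=[f"g{i}" for i in range(6)])
        es_top, _ = gsea_es(ranked, {"g0", "g1"})
        es_rev, _ = gsea_es(ranked[::-1], {"g0", "g1"})
        assert es_top > 0 > es_rev

    def test_bounds_property(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(40)]
        ranked = pd.Series(rng.normal(size=40), index=genes).sort_values(ascending=False)
        for _ in range(50):
            size = rng.integers(1, 39)
            members = rng.choice(genes, size=size, replace=False)
            es, _ = gsea_es(ranked, set(members))
            assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12

    def test_empty_or_absent_set_error(self):
        ranked = pd.Series([1.0, 0.5], index=["a", "b"])
        with pytest.raises(ValidationError):
            gsea_es(ranked, {"zz"})

    def test_leading_edge_contains_top_hit(self):
        ranked = pd.Series([4.0, 3.0, 2.0, 1.0], index=list("abcd"))
        le = leading_edge(ranked, {"a", "d"})
        assert "a" in le


def _phenotype_frame(seed=0, n_genes=60, planted=10, delta=3.0):
    """Six-vs-six phenotype design with `planted` genes shifted in group A."""
    rng = np.random.default_rng(seed)
    cols_a = [f"A{i}" for i in range(6)]
    cols_b = [f"B{i}" for i in range(6)]
    base = rng.normal(5.0, 1.0, size=(n_genes, 12))
    base[:planted, :6] += delta
    genes = [f"g{i}" for i in range(n_genes)]
    return (
        pd.DataFrame(base, index=genes, columns=cols_a + cols_b),
        cols_a,
        cols_b,
        set(genes[:planted]),
    )


class TestGseaPermutation:
    def test_planted_set_significant(self):
        expr, cols_a, cols_b, planted = _phenotype_frame()
        coll = GeneSetCollection(sets={"planted": planted,
                                       "random": {f"g{i}" for i in range(30, 45)}})
        res = gsea(expr, cols_a, cols_b, coll, n_perm=1000, seed=0).set_index("set")
        assert res.loc["planted", "nes"] > 1.0
        assert res.loc["planted", "p"] < 0.05

    def test_determinism(self):
        expr, cols_a, cols_b, planted = _phenotype_frame()
        coll = GeneSetCollection(sets={"planted": planted})
        r1 = gsea(expr, cols_a, cols_b, coll, n_perm=200, seed=3)
        r2 = gsea(expr, cols_a, cols_b, coll, n_perm=200, seed=3)
        pd.testing.assert_frame_equal(r1, r2)

    def test_degenerate_null_nes_one(self):
        # identical columns: every relabeling gives the same ES
        expr = pd.DataFrame(
            np.tile(np.arange(10, dtype=float)[:, None], (1, 8)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(8)],
        )
        coll = GeneSetCollection(sets={"s": {"g0", "g1"}})
        res = gsea(expr, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)],
                   coll, n_perm=50, seed=0)
        assert res.loc[0, "nes"] == pytest.approx(1.0)
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_random_set_mean_es_near_zero(self):
        # genome-scale ranked list: uniformly random sets have ES centred on 0
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(1000)]
        ranked = pd.Series(
            np.sort(rng.normal(size=1000))[::-1], index=genes
        )
        es_values = [
            gsea_es(ranked, set(rng.choice(genes, size=50, replace=False)))[0]
            for _ in range(1000)
        ]
        assert abs(np.mean(es_values)) < 0.05

    def test_too_few_permutations_error(self):
        expr, cols_a, cols_b, planted = _phenotype_frame()
        coll = GeneSetCollection(sets={"planted": planted})
        with pytest.raises(ValidationError):
            gsea(expr, cols_a, cols_b, coll, n_perm=5)


class TestSignificantSets:
    def frame(self, nes, p=0.01, q=0.1):
        return pd.DataFrame([{"set": "s", "size": 5, "es": np.sign(nes) * 0.5,
                              "nes": nes, "p": p, "q": q}])

    def test_boundary_nes_excluded(self):
        assert len(significant_sets(self.frame(1.0))) == 0

    def test_all_three_required(self):
        assert len(significant_sets(self.frame(2.1, p=0.01, q=0.24))) == 1
        assert len(significant_sets(self.frame(2.1, p=0.05, q=0.24))) == 0
        assert len(significant_sets(self.frame(2.1, p=0.01, q=0.25))) == 0

    def test_absolute_nes(self):
        assert len(significant_sets(self.frame(-1.8, p=0.002, q=0.10))) == 1
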