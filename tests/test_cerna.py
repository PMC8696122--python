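"""ceRNA triplet inference: SCC filter, sponge test, triplet assembly, export."""
import numpy as np
import pandas as pd
import pytest

from lncnet.cerna import (
    build_cerna_graph,
    build_cerna_triplets,
    export_cerna_network,
    negative_coexpression_pairs,
    network_counts,
    sponge_hypergeom_test,
    spearman_cc,
)
from lncnet.models import ValidationError
from lncnet.simulate import SimulationConfig, simulate


def targets(pairs):
    return pd.DataFrame(
        [{"mirna_id": m, "target_id": t, "target_class": ""} for m, t in pairs]
    )


class TestNegativeCoexpression:
    def test_boundary_is_strict(self):
        # Spearman rho exactly -0.7: sum d^2 = 34, n = 5
        feat = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0]], index=["f1"])
        mir = pd.DataFrame([[3.0, 5.0, 4.0, 2.0, 1.0]], index=["m1"])
        assert spearman_cc(feat.loc["f1"], mir.loc["m1"]) == -0.7
        out = negative_coexpression_pairs(feat, mir, targets([("m1", "f1")]))
        assert len(out) == 0

    def test_perfect_anticorrelation_retained(self):
        feat = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["f1"])
        mir = pd.DataFrame([[9.0, 7.0, 5.0, 3.0]], index=["m1"])
        out = negative_coexpression_pairs(feat, mir, targets([("m1", "f1")]))
        assert len(out) == 1 and out.iloc[0]["scc"] == -1.0

    def test_targeting_required(self):
        feat = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["f1"])
        mir = pd.DataFrame([[9.0, 7.0, 5.0, 3.0]], index=["m1"])
        out = negative_coexpression_pairs(feat, mir, targets([("m1", "other")]))
        assert len(out) == 0

    def test_missing_feature_skipped(self):
        feat = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["f1"])
        mir = pd.DataFrame([[9.0, 7.0, 5.0, 3.0]], index=["m1"])
        out = negative_coexpression_pairs(
            feat, mir, targets([("m1", "f1"), ("m1", "ghost")])
        )
        assert list(out["feature_id"]) == ["f1"]


class TestSpongeTest:
    def test_k_zero_is_one(self):
        assert sponge_hypergeom_test(30, 5, 7, 0) == 1.0

    def test_enumerated_examples(self):
        assert sponge_hypergeom_test(10, 4, 5, 2) == pytest.approx(186 / 252, abs=1e-12)
        assert sponge_hypergeom_test(6, 3, 3, 3) == pytest.approx(0.05, abs=1e-12)

    def test_single_shared_small_universe(self):
        assert sponge_hypergeom_test(2, 1, 1, 1) == pytest.approx(0.5)


class TestTripletAssembly:
    def planted_frames(self):
        # one mRNA and one lncRNA sharing miRNA m1, perfectly co-expressed
        samples = list("abcdef")
        prof = np.array([1.0, 4.0, 2.0, 8.0, 6.0, 3.0])
        expr_m = pd.DataFrame([prof], index=["G1"], columns=samples)
        expr_l = pd.DataFrame([prof * 2], index=["L1"], columns=samples)
        pairs_m = pd.DataFrame([{"mirna_id": "m1", "feature_id": "G1", "scc": -1.0}])
        pairs_l = pd.DataFrame([{"mirna_id": "m1", "feature_id": "L1", "scc": -1.0}])
        return pairs_m, pairs_l, expr_m, expr_l

    def test_retained_in_large_universe(self):
        pm, pl, em, el = self.planted_frames()
        trips = build_cerna_triplets(pm, pl, em, el, universe_size=30)
        assert len(trips) == 1
        t = trips[0]
        assert t.mirna_ids == ("m1",) and t.k_shared == 1
        assert t.p_sponge == pytest.approx(1 / 30)

    def test_small_universe_rejected(self):
        # k=1, K=1, n=1, M=2 -> p = 0.5 >= 0.05
        pm, pl, em, el = self.planted_frames()
        assert build_cerna_triplets(pm, pl, em, el, universe_size=2) == []

    def test_pcc_rule_strict(self):
        pm, pl, em, el = self.planted_frames()
        # identical profiles give PCC = 1.0 exactly: strict > 1.0 must reject
        assert build_cerna_triplets(pm, pl, em, el, universe_size=30,
                                    pcc_threshold=1.0) == []

    def test_weak_pcc_rejected(self):
        pm, pl, em, el = self.planted_frames()
        el.loc["L1"] = [2.0, 3.0, 1.0, 8.0, 4.0, 7.0]  # correlated but r < 0.9
        from lncnet.stats import pearson_cc
        assert pearson_cc(em.loc["G1"], el.loc["L1"]) < 0.9
        assert build_cerna_triplets(pm, pl, em, el, universe_size=30) == []

    def test_empty_universe_error(self):
        pm, pl, em, el = self.planted_frames()
        with pytest.raises(ValidationError):
            build_cerna_triplets(pm, pl, em, el, universe_size=0)

    def test_relabeling_invariance(self):
        pm, pl, em, el = self.planted_frames()
        before = build_cerna_triplets(pm, pl, em, el, universe_size=30)
        ren = {"G1": "zzz9", "L1": "aaa1"}
        pm2 = pm.assign(feature_id=pm["feature_id"].map(ren))
        pl2 = pl.assign(feature_id=pl["feature_id"].map(ren))
        after = build_cerna_triplets(
            pm2, pl2, em.rename(index=ren), el.rename(index=ren), universe_size=30
        )
        assert len(before) == len(after) == 1
        assert after[0].p_sponge == before[0].p_sponge


class TestPlantedRecovery:
    def test_noiseless_exact(self, noiseless_dataset):
        ds = noiseless_dataset
        counts_m = ds.mrna_counts.values
        counts_l = ds.lncrna_counts.values
        counts_mi = ds.mirna_counts.values
        pm = negative_coexpression_pairs(counts_m, counts_mi, ds.mirna_targets)
        pl = negative_coexpression_pairs(counts_l, counts_mi, ds.mirna_targets)
        trips = build_cerna_triplets(
            pm, pl, counts_m, counts_l, universe_size=len(counts_mi.index)
        )
        found = {(t.mrna_id, m, t.lncrna_id) for t in trips for m in t.mirna_ids}
        assert found == ds.truth.cerna_triplets

    def test_recovery_degrades_with_noise(self):
        recalls = []
        for strength in (1.0, 0.85, 0.4):
            ds = simulate(SimulationConfig(seed=13, corr_strength=strength,
                                           nb_dispersion=0.0, library_cv=0.0))
            pm = negative_coexpression_pairs(
                ds.mrna_counts.values, ds.mirna_counts.values, ds.mirna_targets
            )
            pl = negative_coexpression_pairs(
                ds.lncrna_counts.values, ds.mirna_counts.values, ds.mirna_targets
            )
            trips = build_cerna_triplets(
                pm, pl, ds.mrna_counts.values, ds.lncrna_counts.values,
                universe_size=ds.config.n_mirna,
            )
            found = {(t.mrna_id, m, t.lncrna_id) for t in trips for m in t.mirna_ids}
            recalls.append(
                len(found & ds.truth.cerna_triplets) / len(ds.truth.cerna_triplets)
            )
        assert recalls[0] == 1.0
        assert recalls[0] >= recalls[1] >= recalls[2]


class TestExport:
    def test_single_triplet_graph(self):
        from lncnet.models import CeRNATriplet

        t = CeRNATriplet("G1", "L1", ("m1",), -1.0, -1.0, 1.0, 1, 0.01)
        g = build_cerna_graph([t])
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 3
        counts = network_counts([t])
        assert counts == {"n_mrna": 1, "n_lncrna": 1, "n_mirna": 1, "n_triplets": 1}

    def test_empty_export(self, tmp_path):
        counts = export_cerna_network(
            [], str(tmp_path / "c.graphml"), str(tmp_path / "c.tsv")
        )
        assert counts["n_triplets"] == 0
        assert (tmp_path / "c.graphml").exists() and (tmp_path / "c.tsv").exists()
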