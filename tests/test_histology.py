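import numpy as np
import pandas as pd
import pytest

from esckit.histology import (
    MetaFeatureSelector,
    patient_split,
    qc_and_sample_tiles,
    select_meta_features,
)
from esckit.io import TileFeatureTable
from esckit.simulate import CohortSimConfig, simulate_tile_features


@pytest.fixture
def tile_cohort():
    cfg = CohortSimConfig(
        n_slides=24, tiles_per_slide_raw=40, n_tile_features=60,
        planted_feature_shift=3.0, seed=21,
    )
    return simulate_tile_features(cfg)


class TestQC:
    def test_boundary_background_retained(self):
        meta = pd.DataFrame(
            {
                "tile_id": ["t1", "t2", "t3"],
                "slide_id": "sl",
                "patient_id": "p",
                "background_fraction": [0.20, 0.21, 0.05],
            }
        )
        feats = pd.DataFrame({"f1": [1.0, 2.0, 3.0]})
        out = qc_and_sample_tiles(
            TileFeatureTable(meta, feats), tiles_per_slide=10, seed=0
        )
        assert set(out.meta["tile_id"]) == {"t1", "t3"}

    def test_exact_sampling_count(self, tile_cohort):
        tiles, _ = tile_cohort
        out = qc_and_sample_tiles(tiles, tiles_per_slide=20, seed=1)
        per_slide = out.meta["slide_id"].value_counts()
        assert (per_slide == 20).all()

    def test_deterministic_under_seed(self, tile_cohort):
        tiles, _ = tile_cohort
        a = qc_and_sample_tiles(tiles, tiles_per_slide=15, seed=3)
        b = qc_and_sample_tiles(tiles, tiles_per_slide=15, seed=3)
        assert list(a.meta["tile_id"]) == list(b.meta["tile_id"])

    def test_short_slide_contributes_all_with_warning(self):
        meta = pd.DataFrame(
            {
                "tile_id": [f"t{i}" for i in range(5)],
                "slide_id": "sl",
                "patient_id": "p",
                "background_fraction": 0.1,
            }
        )
        feats = pd.DataFrame({"f": np.arange(5.0)})
        with pytest.warns(UserWarning, match="fewer"):
            out = qc_and_sample_tiles(
                TileFeatureTable(meta, feats), tiles_per_slide=50, seed=0
            )
        assert len(out) == 5

    def test_slide_with_no_passing_tiles_is_error(self):
        meta = pd.DataFrame(
            {
                "tile_id": ["t1"],
                "slide_id": "bad",
                "patient_id": "p",
                "background_fraction": [0.9],
            }
        )
        feats = pd.DataFrame({"f": [1.0]})
        with pytest.raises(ValueError, match="bad"):
            qc_and_sample_tiles(TileFeatureTable(meta, feats), seed=0)


class TestPatientSplit:
    def test_disjoint_and_complete(self, tile_cohort):
        tiles, _ = tile_cohort
        plan = patient_split(tiles, 0.65, seed=0)
        disc, test = set(plan.discovery_patients), set(plan.test_patients)
        assert not disc & test
        assert disc | test == set(tiles.meta["patient_id"])

    def test_discovery_tile_fraction_near_target(self, tile_cohort):
        tiles, _ = tile_cohort
        plan = patient_split(tiles, 0.65, seed=5)
        frac = tiles.meta["patient_id"].isin(plan.discovery_patients).mean()
        assert 0.5 < frac < 0.8

    @pytest.mark.parametrize("seed", range(25))
    def test_groups_present_in_both_halves_over_many_seeds(self, seed):
        cfg = CohortSimConfig(
            n_slides=10, tiles_per_slide_raw=10, n_tile_features=8,
            n_planted_features_per_group=1, seed=17,
        )
        tiles, _ = simulate_tile_features(cfg)
        plan = patient_split(tiles, 0.65, seed=seed)
        g = tiles.meta.drop_duplicates("patient_id").set_index("patient_id")["group"]
        assert set(g[plan.discovery_patients]) == set(g)
        assert set(g[plan.test_patients]) == set(g)

    def test_single_patient_group_is_error(self):
        meta = pd.DataFrame(
            {
                "tile_id": ["t1", "t2", "t3"],
                "slide_id": ["a", "b", "c"],
                "patient_id": ["pa", "pb", "pc"],
                "group": ["g1", "g1", "g2"],
                "background_fraction": 0.0,
            }
        )
        feats = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="single patient"):
            patient_split(TileFeatureTable(meta, feats), 0.65, seed=0)


class TestMetaFeatureSelection:
    def test_recovers_planted_features(self, tile_cohort):
        tiles, truth = tile_cohort
        model = select_meta_features(tiles, fdr_cutoff=0.01, top_n=5)
        for g, feats in truth["planted_features"].items():
            assert len(set(model.selected_[g]) & set(feats)) >= 4

    def test_constant_feature_never_selected(self, tile_cohort):
        tiles, _ = tile_cohort
        tiles.features["F0001"] = 7.0
        model = select_meta_features(tiles)
        for feats in model.selected_.values():
            assert "F0001" not in feats

    def test_feature_high_in_two_groups_excluded_by_uniqueness(self):
        rng = np.random.default_rng(0)
        n = 400
        groups = np.repeat(["a", "b", "c", "d"], n // 4)
        feats = pd.DataFrame(
            rng.normal(size=(n, 6)), columns=[f"f{i}" for i in range(6)]
        )
        # f0 high in both a and b; f1 unique to a; f2 unique to b
        feats.loc[np.isin(groups, ["a", "b"]), "f0"] += 4.0
        feats.loc[groups == "a", "f1"] += 4.0
        feats.loc[groups == "b", "f2"] += 4.0
        meta = pd.DataFrame(
            {
                "tile_id": [f"t{i}" for i in range(n)],
                "slide_id": np.repeat([f"sl{i}" for i in range(8)], n // 8),
                "patient_id": np.repeat([f"p{i}" for i in range(8)], n // 8),
                "group": groups,
                "background_fraction": 0.0,
            }
        )
        model = select_meta_features(TileFeatureTable(meta, feats), top_n=1)
        assert model.selected_["a"] == ["f1"]
        assert model.selected_["b"] == ["f2"]
        for feats_sel in model.selected_.values():
            assert "f0" not in feats_sel

    def test_joint_bh_differs_from_per_group_decoy(self):
        # BH must run once across ALL group x feature pairs: with three
        # groups whose p-value spectra differ, a per-group adjustment (the
        # decoy) produces different adjusted values.  (Two one-vs-rest
        # groups would be mirror images and could not discriminate.)
        from esckit.enrichment import bh_adjust

        rng = np.random.default_rng(3)
        n = 300
        groups = np.repeat(["a", "b", "c"], n // 3)
        feats = pd.DataFrame(
            rng.normal(size=(n, 40)), columns=[f"f{i}" for i in range(40)]
        )
        feats.loc[groups == "a", ["f0", "f1", "f2"]] += 2.0  # strong in a only
        feats.loc[groups == "b", "f3"] += 0.4  # weak in b
        meta = pd.DataFrame(
            {
                "tile_id": [f"t{i}" for i in range(n)],
                "slide_id": np.repeat([f"s{i}" for i in range(3)], n // 3),
                "patient_id": np.repeat([f"p{i}" for i in range(3)], n // 3),
                "group": groups,
                "background_fraction": 0.0,
            }
        )
        model = MetaFeatureSelector(fdr_cutoff=0.05).fit(
            TileFeatureTable(meta, feats)
        )
        table = model.stats_
        joint = table["adj_p"].to_numpy()
        per_group = np.concatenate(
            [
                bh_adjust(table.loc[table["group"] == g, "p"].to_numpy())
                for g in sorted(set(groups))
            ]
        )
        assert not np.allclose(joint, per_group)

    def test_selection_invariant_to_feature_column_order(self, tile_cohort):
        tiles, _ = tile_cohort
        model_a = select_meta_features(tiles)
        reversed_feats = tiles.features[tiles.features.columns[::-1]]
        shuffled = TileFeatureTable(tiles.meta.copy(), reversed_feats)
        model_b = select_meta_features(shuffled)
        assert {g: set(v) for g, v in model_a.selected_.items()} == {
            g: set(v) for g, v in model_b.selected_.items()
        }

    def test_transform_sums_selected_features(self, tile_cohort):
        tiles, _ = tile_cohort
        model = select_meta_features(tiles)
        meta_vals = model.transform(tiles)
        g = model.groups_[0]
        expected = tiles.features[model.selected_[g]].sum(axis=1).to_numpy()
        np.testing.assert_allclose(meta_vals[g].to_numpy(), expected)

    def test_null_data_selects_at_most_chance(self):
        selected_counts = []
        for seed in range(10):
            cfg = CohortSimConfig(
                n_slides=16, tiles_per_slide_raw=25, n_tile_features=50,
                planted_feature_shift=0.0, seed=300 + seed,
            )
            tiles, _ = simulate_tile_features(cfg)
            model = select_meta_features(tiles, fdr_cutoff=0.01, top_n=5)
            selected_counts.append(
                sum(len(v) for v in model.selected_.values())
            )
        # with no signal, FDR < 0.01 over 200 pairs admits ~0 selections
        assert np.mean(selected_counts) <= 1.0


class TestValidation:
    def test_planted_signal_validates_concordantly(self, tile_cohort):
        tiles, truth = tile_cohort
        plan = patient_split(tiles, 0.65, seed=2)
        disc = tiles.select_rows(tiles.meta["patient_id"].isin(plan.discovery_patients))
        test = tiles.select_rows(tiles.meta["patient_id"].isin(plan.test_patients))
        model = select_meta_features(disc)
        report = model.validate(test)
        assert report["direction_concordant"].all()
        assert (report["p"] < 0.01).all()

    def test_label_permuted_test_half_is_nonconcordant_or_nonsig(self, tile_cohort):
        tiles, _ = tile_cohort
        plan = patient_split(tiles, 0.65, seed=2)
        disc = tiles.select_rows(tiles.meta["patient_id"].isin(plan.discovery_patients))
        test = tiles.select_rows(tiles.meta["patient_id"].isin(plan.test_patients))
        model = select_meta_features(disc)
        rng = np.random.default_rng(0)
        permuted_meta = test.meta.copy()
        permuted_meta["group"] = rng.permutation(permuted_meta["group"].to_numpy())
        report = model.validate(TileFeatureTable(permuted_meta, test.features))
        # permuting labels breaks the planted link for at least some groups
        strong = report["direction_concordant"] & (report["p"] < 0.01)
        assert not strong.all()

    def test_empty_test_table_rejected(self, tile_cohort):
        tiles, _ = tile_cohort
        model = select_meta_features(tiles)
        empty = tiles.select_rows(np.zeros(len(tiles), dtype=bool))
        with pytest.raises(ValueError, match="empty"):
            model.validate(empty)

    def test_group_absent_from_test_skipped(self, tile_cohort):
        tiles, _ = tile_cohort
        model = select_meta_features(tiles)
        g0 = model.groups_[0]
        subset = tiles.select_rows((tiles.meta["group"] != g0).to_numpy())
        report = model.validate(subset)
        assert report.loc[g0, "note"] == "group absent from test"
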