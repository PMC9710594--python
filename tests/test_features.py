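import numpy as np
import pandas as pd
import pytest

from codes.exceptions import CodesError, KeyCollisionError
from codes.features import (
    FeatureTable,
    NormalizationStats,
    buried_surface_area,
    clean_and_impute,
    consrank_score,
    contact_class_counts,
    contact_frequencies,
    internal_registry,
    load_external_features,
    merge_tables,
    nis,
    zscore,
)
from codes.geometry import ContactMap, residue_contacts, transform_model
from codes.structure_io import ComplexModel

from conftest import make_atom, random_rotation


def cmap(pairs, model_id="m"):
    return ContactMap("t", model_id, frozenset(pairs), 5.0)


def pair(i):
    return (("A", i, ""), ("B", i, ""))


class TestContactFrequencies:
    def test_contact_in_all_maps(self):
        ensemble = [cmap({pair(1)}, f"m{i}") for i in range(4)]
        assert contact_frequencies(ensemble)[pair(1)] == 1.0

    def test_contact_in_one_of_m(self):
        ensemble = [cmap({pair(1)}, "m0")] + [cmap({pair(2)}, f"m{i}") for i in range(1, 5)]
        assert contact_frequencies(ensemble)[pair(1)] == pytest.approx(1 / 5)

    def test_empty_ensemble_raises(self):
        with pytest.raises(CodesError):
            contact_frequencies([])

    def test_matches_dictionary_tally_oracle(self):
        rng = np.random.default_rng(17)
        ensemble = []
        for i in range(20):
            pairs = {pair(int(j)) for j in rng.integers(0, 12, size=rng.integers(1, 8))}
            ensemble.append(cmap(pairs, f"m{i}"))
        # oracle: explicit per-contact count
        tally = {}
        for m in ensemble:
            for c in m.contacts:
                tally[c] = tally.get(c, 0) + 1
        expected = {c: n / 20 for c, n in tally.items()}
        assert contact_frequencies(ensemble) == expected


class TestConsrankScore:
    def test_identical_ensemble_scores_one(self):
        ensemble = [cmap({pair(1), pair(2)}, f"m{i}") for i in range(6)]
        freqs = contact_frequencies(ensemble)
        for m in ensemble:
            assert consrank_score(m, freqs) == 1.0

    def test_unique_contacts_score_one_over_m(self):
        ensemble = [cmap({pair(i)}, f"m{i}") for i in range(8)]
        freqs = contact_frequencies(ensemble)
        assert consrank_score(ensemble[0], freqs) == pytest.approx(1 / 8)

    def test_contactless_model_scores_zero(self):
        ensemble = [cmap({pair(1)}, "m0"), cmap(set(), "m1")]
        freqs = contact_frequencies(ensemble)
        assert consrank_score(ensemble[1], freqs) == 0.0

    def test_hand_tally_on_small_mixed_ensemble(self):
        maps = [
            cmap({pair(1), pair(2)}, "a"),
            cmap({pair(1)}, "b"),
            cmap({pair(2), pair(3)}, "c"),
        ]
        freqs = contact_frequencies(maps)
        # freq: pair1=2/3, pair2=2/3, pair3=1/3
        assert consrank_score(maps[0], freqs) == pytest.approx((2 / 3 + 2 / 3) / 2)
        assert consrank_score(maps[2], freqs) == pytest.approx((2 / 3 + 1 / 3) / 2)

    def test_scores_in_unit_interval_and_copy_monotonicity(self, decoy_ensemble):
        decoys, _ = decoy_ensemble
        maps = [residue_contacts(d) for d in decoys[:12]]
        freqs = contact_frequencies(maps)
        scores = [consrank_score(m, freqs) for m in maps]
        assert all(0.0 <= s <= 1.0 for s in scores)
        # duplicating decoy 0 never decreases its score
        dup = maps + [cmap(maps[0].contacts, "copy")]
        dup_freqs = contact_frequencies(dup)
        assert consrank_score(maps[0], dup_freqs) >= scores[0] - 1e-12

    def test_sum_variant(self):
        maps = [cmap({pair(1), pair(2)}, "a"), cmap({pair(1)}, "b")]
        freqs = contact_frequencies(maps)
        assert consrank_score(maps[0], freqs, normalize=False) == pytest.approx(1.5)


def _contact_pair_complex(res_a, res_b, distance=4.0):
    atoms = [
        make_atom(1, [0, 0, 0], res_name=res_a, chain="A", resseq=1),
        make_atom(2, [distance, 0, 0], res_name=res_b, chain="B", resseq=1),
    ]
    return ComplexModel("m", "t", atoms, frozenset("A"), frozenset("B"))


class TestContactClassCounts:
    def test_lys_asp_is_charged_charged(self):
        counts = contact_class_counts(_contact_pair_complex("LYS", "ASP"))
        assert counts["NC_charged_charged"] == 1
        assert counts["NC_total"] == 1
        assert counts["NC_apolar_apolar"] == 0

    def test_phe_phe_overlapping_classes(self):
        counts = contact_class_counts(_contact_pair_complex("PHE", "PHE"))
        assert counts["NC_aromatic_aromatic"] == 1
        assert counts["NC_apolar_apolar"] == 1
        assert counts["NC_apolar_aromatic"] == 1
        assert counts["NC_total"] == 1

    def test_contactless_model_all_zero(self):
        counts = contact_class_counts(_contact_pair_complex("ALA", "GLY", distance=50))
        assert all(v == 0 for v in counts.values())

    def test_registry_has_21_count_features(self):
        counts = contact_class_counts(_contact_pair_complex("ALA", "GLY"))
        assert len(counts) == 21

    def test_invariant_under_rigid_motion(self, native):
        rng = np.random.default_rng(30)
        moved = transform_model(native, random_rotation(rng), np.array([5.0, 1.0, -3.0]))
        assert contact_class_counts(moved) == contact_class_counts(native)


class TestBuriedSurfaceArea:
    def test_separated_bodies_zero(self):
        model = _contact_pair_complex("ALA", "GLY", distance=100.0)
        total, polar, apolar = buried_surface_area(model)
        assert total == pytest.approx(0.0, abs=1e-6)

    def test_total_is_polar_plus_apolar(self, native):
        total, polar, apolar = buried_surface_area(native, point_number=240)
        assert total == pytest.approx(polar + apolar, abs=1e-6)
        assert total > 0

    def test_two_sphere_analytic_oracle(self):
        from biotite.structure.info import vdw_radius_single

        probe = 1.4
        r = vdw_radius_single("C") + probe
        d = 1.5 * r  # overlapping extended spheres
        model = _contact_pair_complex("ALA", "ALA", distance=d)
        total, _, _ = buried_surface_area(model, point_number=960)
        # analytic: each equal sphere buries a cap of height h = r - d/2
        cap_area = 2 * np.pi * r * (r - d / 2)
        assert total == pytest.approx(2 * cap_area, rel=0.05)


class TestNis:
    def _star_complex(self, receptor_names, ligand_names):
        """Single-atom residues spread far apart; ligand 100 Å away."""
        atoms = []
        serial = 0
        for i, name in enumerate(receptor_names):
            serial += 1
            atoms.append(make_atom(serial, [i * 20.0, 0, 0], res_name=name,
                                   chain="A", resseq=i + 1))
        for i, name in enumerate(ligand_names):
            serial += 1
            atoms.append(make_atom(serial, [i * 20.0, 500.0, 0], res_name=name,
                                   chain="B", resseq=i + 1))
        return ComplexModel("m", "t", atoms, frozenset("A"), frozenset("B"))

    def test_planted_six_polar_four_apolar(self):
        model = self._star_complex(
            ["SER", "THR", "ASN", "LYS", "ASP", "GLN", "ALA", "VAL", "LEU"],
            ["ILE"],
        )
        polar_pct, apolar_pct = nis(model)
        assert polar_pct == pytest.approx(60.0)
        assert apolar_pct == pytest.approx(40.0)

    def test_all_polar_exposed(self):
        model = self._star_complex(["SER", "LYS", "ASP"], ["GLN"])
        assert nis(model) == pytest.approx((100.0, 0.0))

    def test_no_exposed_noninterface_residue_is_missing(self):
        model = _contact_pair_complex("ALA", "GLY", distance=4.0)
        polar_pct, apolar_pct = nis(model)
        assert np.isnan(polar_pct) and np.isnan(apolar_pct)


def _table(rows, columns):
    idx = pd.MultiIndex.from_tuples(list(rows), names=["target_id", "model_id"])
    return FeatureTable(pd.DataFrame(list(rows.values()), index=idx, columns=columns))


class TestLoadExternalFeatures:
    def _write(self, path, df):
        df.to_csv(path, sep="\t", index=False)

    def test_disjoint_columns_union(self, tmp_path):
        a = tmp_path / "a.tsv"
        b = tmp_path / "b.tsv"
        self._write(a, pd.DataFrame({"target_id": ["t1"], "model_id": ["m1"], "f1": [1.0]}))
        self._write(b, pd.DataFrame({"target_id": ["t1"], "model_id": ["m1"], "f2": [2.0]}))
        table = load_external_features([a, b])
        assert set(table.registry) == {"f1", "f2"}
        assert table.data.loc[("t1", "m1"), "f1"] == 1.0

    def test_row_in_one_file_only_marks_missing(self, tmp_path):
        a = tmp_path / "a.tsv"
        b = tmp_path / "b.tsv"
        self._write(a, pd.DataFrame({"target_id": ["t1", "t1"], "model_id": ["m1", "m2"], "f1": [1.0, 2.0]}))
        self._write(b, pd.DataFrame({"target_id": ["t1"], "model_id": ["m1"], "f2": [5.0]}))
        table = load_external_features([a, b])
        assert np.isnan(table.data.loc[("t1", "m2"), "f2"])

    def test_conflicting_duplicate_key_raises(self, tmp_path):
        a = tmp_path / "a.tsv"
        b = tmp_path / "b.tsv"
        self._write(a, pd.DataFrame({"target_id": ["t1"], "model_id": ["m1"], "f1": [1.0]}))
        self._write(b, pd.DataFrame({"target_id": ["t1"], "model_id": ["m1"], "f1": [9.0]}))
        with pytest.raises(KeyCollisionError):
            load_external_features([a, b])

    def test_unknown_columns_ignored_with_registry(self, tmp_path):
        a = tmp_path / "a.tsv"
        self._write(a, pd.DataFrame({"target_id": ["t1"], "model_id": ["m1"],
                                     "f1": [1.0], "junk": [0.0]}))
        table = load_external_features([a], registry=["f1"])
        assert table.registry == ["f1"]


class TestCleanAndImpute:
    def test_feature_over_30pct_missing_dropped(self):
        rows = {("t1", f"m{i}"): [float(i), np.nan if i < 4 else 1.0] for i in range(10)}
        table = _table(rows, ["keep", "gappy"])
        cleaned = clean_and_impute(table)
        assert cleaned.registry == ["keep"]

    def test_single_gap_filled_with_target_mean(self):
        rows = {
            ("t1", "m1"): [1.0], ("t1", "m2"): [3.0], ("t1", "m3"): [np.nan],
            ("t2", "m1"): [10.0], ("t2", "m2"): [20.0],
        }
        cleaned = clean_and_impute(_table(rows, ["f"]))
        assert cleaned.data.loc[("t1", "m3"), "f"] == pytest.approx(2.0)

    def test_target_without_observation_uses_global_mean(self):
        rows = {
            ("t1", "m1"): [2.0], ("t1", "m2"): [4.0], ("t1", "m3"): [3.0],
            ("t2", "m1"): [np.nan],
        }
        cleaned = clean_and_impute(_table(rows, ["f"]))
        assert cleaned.data.loc[("t2", "m1"), "f"] == pytest.approx(3.0)

    def test_planted_missingness_matches_hand_computation(self):
        rows = {
            ("t1", "m1"): [1.0, 5.0],
            ("t1", "m2"): [np.nan, 7.0],
            ("t2", "m1"): [4.0, np.nan],
            ("t2", "m2"): [6.0, 9.0],
        }
        cleaned = clean_and_impute(_table(rows, ["f1", "f2"]))
        expected = pd.DataFrame(
            [[1.0, 5.0], [1.0, 7.0], [4.0, 9.0], [6.0, 9.0]],
            index=cleaned.data.index, columns=["f1", "f2"],
        )
        pd.testing.assert_frame_equal(cleaned.data, expected)

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        rows = {("t1", f"m{i}"): list(rng.normal(size=3)) for i in range(6)}
        rows[("t1", "m0")][1] = np.nan
        table = _table(rows, ["a", "b", "c"])
        once = clean_and_impute(table)
        twice = clean_and_impute(once)
        pd.testing.assert_frame_equal(once.data, twice.data)


class TestZscore:
    def test_train_rows_normalize_to_zero_mean_unit_sd(self):
        rng = np.random.default_rng(9)
        rows = {("t1", f"m{i}"): list(rng.normal(3, 2, size=4)) for i in range(50)}
        table = _table(rows, ["a", "b", "c", "d"])
        stats = NormalizationStats.fit(table)
        z = zscore(table, stats)
        np.testing.assert_allclose(z.data.mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(z.data.std(axis=0, ddof=0), 1.0, atol=1e-8)

    def test_value_at_mean_is_zero_and_mean_plus_sd_is_one(self):
        rows = {("t", "m1"): [0.0], ("t", "m2"): [2.0]}
        table = _table(rows, ["f"])
        stats = NormalizationStats.fit(table)  # mu=1, sigma=1
        z = zscore(table, stats)
        assert z.data.loc[("t", "m1"), "f"] == pytest.approx(-1.0)
        assert zscore(_table({("t", "m3"): [stats.mu["f"] + stats.sigma["f"]]}, ["f"]), stats).data.iloc[0, 0] == pytest.approx(1.0)

    def test_constant_feature_dropped(self):
        rows = {("t", "m1"): [1.0, 5.0], ("t", "m2"): [2.0, 5.0]}
        table = _table(rows, ["ok", "const"])
        z = zscore(table, NormalizationStats.fit(table))
        assert z.registry == ["ok"]


class TestMergeTables:
    def test_duplicate_columns_rejected(self):
        a = _table({("t", "m1"): [1.0]}, ["f"])
        b = _table({("t", "m1"): [2.0]}, ["f"])
        with pytest.raises(KeyCollisionError):
            merge_tables(a, b)

    def test_registry_order_preserved(self):
        a = _table({("t", "m1"): [1.0]}, ["f1"])
        b = _table({("t", "m1"): [2.0]}, ["f2"])
        assert merge_tables(a, b).registry == ["f1", "f2"]


def test_internal_registry_names():
    names = internal_registry()
    assert names[0] == "CONSRANK_score"
    assert len(names) == 1 + 15 + 5 + 1 + 3 + 2
    assert len(set(names)) == len(names)
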