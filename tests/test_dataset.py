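"""Curation: encoding, cytotoxicity labelling, splitting, scaling, joining."""

import numpy as np
import pandas as pd
import pytest

from nanoqstr import dataset, synthdata
from nanoqstr.errors import ValidationError


class TestCoatingGroups:
    @pytest.mark.parametrize("coating,group", [
        ("PEG", "polymer-based"),
        ("polyethylene glycol", "polymer-based"),
        ("bovine serum albumin", "protein-based"),
        ("none", "bare"),
        (None, "bare"),
        ("", "bare"),
        ("citrate", "other"),
    ])
    def test_keyword_grouping(self, coating, group):
        assert dataset.coating_group(coating) == group

    def test_ordinal_codes(self):
        assert dataset.COATING_GROUP_ORDINALS == {
            "bare": 0, "polymer-based": 1, "protein-based": 2, "other": 3,
        }


class TestLabel:
    @pytest.mark.parametrize("v,expected", [
        (0.699, "cytotoxic"),   # strictly below the threshold
        (0.70, "non-cytotoxic"),  # boundary is non-cytotoxic
        (1.05, "non-cytotoxic"),
    ])
    def test_threshold_rule(self, v, expected):
        assert dataset.label_cytotoxicity([v])[0] == expected

    def test_negative_viability_rejected(self):
        with pytest.raises(ValidationError):
            dataset.label_cytotoxicity([-0.1])

    def test_matches_brute_force_thresholding(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 1.3, 200)
        got = dataset.label_cytotoxicity(v)
        assert all((g == "cytotoxic") == (x < 0.70) for g, x in zip(got, v))


class TestEncoder:
    def test_fit_transform_roundtrip(self, sim_table):
        table, _ = sim_table
        encoded, enc = dataset.encode_records(table)
        assert encoded["coating_group"].between(0, 3).all()
        assert set(encoded["health_status"].unique()) <= {0, 1}
        assert set(encoded["organism"].unique()) <= {0, 1}
        # persistence round-trip
        again = dataset.Encoder.from_json(enc.to_json())
        assert again.mappings == enc.mappings

    def test_shell_material_ordered_by_frequency(self):
        df = pd.DataFrame({"shell_material": ["carbon"] * 3 + ["silica"] * 1,
                           "coating": ["none"] * 4})
        _, enc = dataset.encode_records(df)
        assert enc.mappings["shell_material"]["carbon"] == 0
        assert enc.mappings["shell_material"]["silica"] == 1

    def test_unseen_category_falls_back_and_flags(self):
        train = pd.DataFrame({"shell_material": ["carbon", "silica"], "coating": ["none"] * 2})
        _, enc = dataset.encode_records(train)
        query = pd.DataFrame({"shell_material": ["MnO2"], "coating": ["none"]})
        out = enc.transform(query)
        assert out["shell_material_unseen"].iloc[0] == 1


class TestSplit:
    def test_contract_on_synthetic_tables(self):
        """Quota, experiment coverage and stratum balance on random tables."""
        rng = np.random.default_rng(1)
        for trial in range(100):
            # study-sized tables: a 5-point stratum tolerance needs a
            # hold-out set that is not dominated by rounding granularity
            n_exp = rng.integers(10, 25)
            rows = []
            for e in range(n_exp):
                for _ in range(rng.integers(6, 14)):
                    rows.append({"experiment_id": f"E{e}",
                                 "viability": rng.uniform(0.3, 1.2)})
            df = pd.DataFrame(rows)
            split = dataset.stratified_split(df, seed=trial)
            assert set(split.train_ids) | set(split.test_ids) == set(df.index)
            assert not set(split.train_ids) & set(split.test_ids)
            assert abs(len(split.test_ids) - round(0.3 * len(df))) <= 1
            # every experiment represented in the hold-out set
            assert set(df.loc[split.test_ids, "experiment_id"]) == set(df["experiment_id"])
            # label proportions within 5 percentage points
            lab = pd.Series(dataset.label_cytotoxicity(df["viability"]), index=df.index)
            full = (lab == "cytotoxic").mean()
            for ids in (split.train_ids, split.test_ids):
                assert abs((lab.loc[ids] == "cytotoxic").mean() - full) <= 0.05 + 1e-9

    def test_deterministic_under_seed(self, sim_table):
        table, _ = sim_table
        s1 = dataset.stratified_split(table, seed=9)
        s2 = dataset.stratified_split(table, seed=9)
        assert np.array_equal(s1.test_ids, s2.test_ids)

    def test_single_row_experiment_stays_in_training(self):
        df = pd.DataFrame({
            "experiment_id": ["A"] * 6 + ["B"],
            "viability": [0.9, 0.8, 0.5, 0.6, 1.0, 0.95, 0.4],
        })
        with pytest.warns(UserWarning, match="single row"):
            split = dataset.stratified_split(df, seed=0)
        assert 6 in split.train_ids

    def test_bad_fraction_rejected(self, sim_table):
        with pytest.raises(ValidationError):
            dataset.stratified_split(sim_table[0], test_frac=1.5)


class TestScaler:
    def test_hand_example_population_sd(self):
        train = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        scaler = dataset.Scaler().fit(train)
        got = scaler.transform(train)["x"].to_numpy()
        assert got == pytest.approx([-1.224744871, 0.0, 1.224744871])

    def test_train_mean_maps_to_zero(self):
        train = pd.DataFrame({"x": [2.0, 4.0, 6.0]})
        scaler = dataset.Scaler().fit(train)
        assert scaler.transform(pd.DataFrame({"x": [4.0]}))["x"].iloc[0] == 0.0

    def test_roundtrip_inverse(self):
        rng = np.random.default_rng(2)
        train = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        scaler = dataset.Scaler().fit(train)
        back = scaler.inverse_transform(scaler.transform(train))
        assert np.abs(back.to_numpy() - train.to_numpy()).max() < 1e-10

    def test_constant_column_passes_through_with_warning(self):
        train = pd.DataFrame({"x": [1.0, 2.0], "c": [5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            scaler = dataset.Scaler().fit(train)
        out = scaler.transform(train)
        assert (out["c"] == 5.0).all()

    def test_training_columns_standardised(self):
        rng = np.random.default_rng(3)
        train = pd.DataFrame(rng.normal(3, 7, size=(50, 3)), columns=list("xyz"))
        out = dataset.Scaler().fit(train).transform(train)
        assert np.abs(out.mean().to_numpy()).max() < 1e-10
        assert np.abs(out.std(ddof=0).to_numpy() - 1).max() < 1e-10


class TestJoinDescriptors:
    def _desc(self):
        rows = []
        for phase, diam in synthdata.DEFAULT_PARTICLES:
            row = {"phase": phase, "diameter_nm": diam}
            row.update({f"D{i}": float(i) for i in range(1, 58)})
            rows.append(row)
        return pd.DataFrame(rows)

    def test_row_count_and_columns_preserved(self, sim_table):
        table, _ = sim_table
        joined = dataset.join_descriptors(table, self._desc())
        assert len(joined) == len(table) == 186
        assert sum(c.startswith("D") for c in joined.columns) >= 57

    def test_empty_descriptor_table_rejected(self, sim_table):
        with pytest.raises(ValidationError):
            dataset.join_descriptors(sim_table[0], self._desc().iloc[:0])

    def test_missing_particle_listed(self, sim_table):
        table, _ = sim_table
        desc = self._desc().iloc[:-1]  # drop the largest particle
        with pytest.raises(ValidationError, match="Fe5C2"):
            dataset.join_descriptors(table, desc)

    def test_duplicate_particle_is_ambiguous(self, sim_table):
        table, _ = sim_table
        desc = pd.concat([self._desc(), self._desc().iloc[[0]]], ignore_index=True)
        with pytest.raises(ValidationError, match="ambiguous|Fe2C"):
            dataset.join_descriptors(table, desc)


def test_percent_scale_viability_converted(tmp_path):
    path = tmp_path / "v.csv"
    pd.DataFrame({"viability": [95.0, 45.0], "zeta_potential": [1, 2]}).to_csv(path, index=False)
    df = dataset.read_viability_csv(path)
    assert df["viability"].tolist() == [0.95, 0.45]
    assert "zeta_potential" not in df.columns
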