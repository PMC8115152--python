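"""Table I/O, deduplication, descriptor pre-filter, Kennard-Stone split."""

import numpy as np
import pandas as pd
import pytest

from conftest import kennard_stone_bruteforce
from skinperm import (
    QsarDataset,
    assign_split,
    deduplicate,
    kennard_stone_split,
    prefilter_descriptors,
    read_table,
)
from skinperm.dataset import DatasetError, standardize


def make_csv(tmp_path, rows, header="id,smiles,logkp"):
    path = tmp_path / "data.csv"
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path


class TestReadTable:
    def test_well_formed(self, tmp_path):
        path = make_csv(tmp_path, ["a,CCO,-2.1", "b,CCC,-1.5", "c,CCN,-3.0"])
        ds = read_table(path)
        assert len(ds) == 3
        assert ds.descriptor_source == "computed"

    def test_missing_logkp_column_named(self, tmp_path):
        path = make_csv(tmp_path, ["a,CCO"], header="id,smiles")
        with pytest.raises(DatasetError, match="logkp"):
            read_table(path)

    def test_non_numeric_logkp_reports_row(self, tmp_path):
        path = make_csv(tmp_path, ["a,CCO,-2.1", "b,CCC,oops"])
        with pytest.raises(DatasetError, match="row"):
            read_table(path)

    def test_duplicate_ids_rejected(self, tmp_path):
        path = make_csv(tmp_path, ["a,CCO,-2.1", "a,CCC,-1.5"])
        with pytest.raises(DatasetError, match="duplicate"):
            read_table(path)

    def test_tabulated_descriptors_detected(self, tmp_path):
        path = make_csv(
            tmp_path,
            ["a,CCO,-2.1,0.5,0.0,0", "b,CCC,-1.0,0.3,0.1,1"],
            header="id,smiles,logkp,cos2_alogp,x3v,neoplastic80",
        )
        ds = read_table(path)
        assert ds.descriptor_source == "tabulated"
        assert ds.has_descriptors

    def test_large_table_round_trip(self, tmp_path):
        # a table shaped like the full 274-compound set
        n = 274
        frame = pd.DataFrame({
            "id": [f"c{i}" for i in range(n)],
            "smiles": ["CCO"] * n,
            "logkp": np.linspace(-6.10, -0.76, n),
        })
        path = tmp_path / "full.csv"
        frame.to_csv(path, index=False)
        assert len(read_table(path)) == 274


class TestDeduplicate:
    def make_ds(self, records):
        frame = pd.DataFrame(records, columns=["id", "smiles", "logkp"])
        return QsarDataset(frame)

    def test_same_structure_different_smiles_collapses(self):
        ds = self.make_ds([("a", "CCO", -2.1), ("b", "OCC", -2.1)])
        out = deduplicate(ds)
        assert len(out) == 1
        assert out.removed_duplicates == [("a", "b")]

    def test_disjoint_structures_unchanged(self):
        ds = self.make_ds([("a", "CCO", -2.1), ("b", "CCC", -1.0)])
        assert len(deduplicate(ds)) == 2

    def test_conflicting_logkp_warns(self):
        ds = self.make_ds([("a", "CCO", -2.1), ("b", "OCC", -3.5)])
        with pytest.warns(UserWarning, match="duplicate structure"):
            out = deduplicate(ds)
        assert len(out) == 1

    def test_idempotent(self):
        ds = self.make_ds([
            ("a", "CCO", -2.1), ("b", "OCC", -2.1), ("c", "CCC", -1.0),
        ])
        once = deduplicate(ds)
        twice = deduplicate(once)
        assert list(once.frame["id"]) == list(twice.frame["id"])

    def test_nine_duplicate_pairs_shrink_283_to_274(self):
        # mirrors the real curation: 283 records containing nine duplicated
        # structures reduce to 274 unique compounds
        base = [(f"u{i}", "C" * (i + 1), -3.0) for i in range(265)]
        pairs = [
            ("Nc1ccc(N)cc1", "NC1=CC=C(N)C=C1"),
            ("Oc1ccc(cc1)[N+](=O)[O-]", "O=[N+]([O-])c1ccc(O)cc1"),
            ("COC(=O)c1ccc(O)cc1", "O=C(OC)c1ccc(O)cc1"),
            ("Nc1ccccc1N", "NC1=CC=CC=C1N"),
            ("Oc1ccc2ccccc2c1", "C1=CC2=CC(O)=CC=C2C=C1"),
            ("Nc1ccc(N)c(c1)[N+](=O)[O-]", "NC1=CC([N+](=O)[O-])=C(N)C=C1"),
            ("CCCCCCCCCO", "OCCCCCCCCC"),
            ("Nc1ccc(Cl)c(N)c1", "NC1=CC(N)=C(Cl)C=C1"),
            ("CCCCCCCO", "OCCCCCCC"),
        ]
        rows = list(base)
        for i, (s1, s2) in enumerate(pairs):
            rows.append((f"d{i}a", s1, -2.0))
            rows.append((f"d{i}b", s2, -2.0))
        ds = QsarDataset(
            pd.DataFrame(rows, columns=["id", "smiles", "logkp"]),
        )
        assert len(ds) == 283
        out = deduplicate(ds)
        assert len(out) == 274


class TestPrefilter:
    def test_constant_column_dropped(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        X[:, 1] = 4.2
        assert prefilter_descriptors(X) == [0, 2]

    def test_identical_column_second_dropped(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        X = np.column_stack([x, x, rng.normal(size=30)])
        assert prefilter_descriptors(X) == [0, 2]

    def test_independent_columns_all_kept(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 5))
        corr = np.corrcoef(X.T)
        assert np.all(np.abs(corr - np.eye(5)) < 0.90)  # oracle precondition
        assert prefilter_descriptors(X) == [0, 1, 2, 3, 4]

    def test_threshold_is_strict(self):
        x = np.arange(10.0)
        X = np.column_stack([x, -x])  # r exactly -1
        assert prefilter_descriptors(X, r_max=0.90) == [0]
        assert prefilter_descriptors(X, r_max=1.0) == [0, 1]


class TestKennardStone:
    def test_one_dimensional_example(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0]])
        result = kennard_stone_split(X, 3)
        assert result.selection_order == (0, 3, 2)
        assert result.train_indices == (0, 2, 3)
        assert result.test_indices == (1,)

    def test_last_left_out_is_maxmin_last(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 2))
        result = kennard_stone_split(X, 11)
        # the lone test point is the one the max-min rule would add last
        full = kennard_stone_bruteforce(X, 12)
        assert result.test_indices == (full[-1],)

    @pytest.mark.parametrize("n,n_train,seed", [(10, 5, 0), (30, 12, 1), (50, 25, 2)])
    def test_matches_bruteforce_maxmin(self, n, n_train, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 3))
        result = kennard_stone_split(X, n_train)
        assert list(result.selection_order) == kennard_stone_bruteforce(X, n_train)

    def test_deterministic_across_runs(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 3))
        assert kennard_stone_split(X, 15) == kennard_stone_split(X.copy(), 15)

    def test_degenerate_identical_rows_tie_break_low_index(self):
        X = np.zeros((6, 2))
        result = kennard_stone_split(X, 3)
        assert result.train_indices == (0, 1, 2)

    def test_coverage_radius_property(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 2))
        result = kennard_stone_split(X, 20)
        train = np.array(result.train_indices)
        # radius at which the last training point was admitted
        last = result.selection_order[-1]
        prior = np.array(result.selection_order[:-1])
        radius = np.min(np.linalg.norm(X[prior] - X[last], axis=1))
        for t in result.test_indices:
            d = np.min(np.linalg.norm(X[train] - X[t], axis=1))
            assert d <= radius + 1e-12

    def test_split_sizes_on_study_scale_table(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(274, 3))
        result = kennard_stone_split(standardize(X), 139)
        assert len(result.train_indices) == 139
        assert len(result.test_indices) == 135

    def test_assign_split_labels(self):
        from skinperm import SynthConfig, generate_dataset

        ds = generate_dataset(SynthConfig(n=30, seed=0))
        labeled, result = assign_split(ds, 20)
        assert (labeled.frame["split"] == "train").sum() == 20
        assert (labeled.frame["split"] == "test").sum() == 10
        assert set(labeled.frame.loc[list(result.train_indices), "split"]) == {"train"}

    def test_invalid_n_train_rejected(self):
        with pytest.raises(ValueError):
            kennard_stone_split(np.zeros((5, 2)), 1)
        with pytest.raises(ValueError):
            kennard_stone_split(np.zeros((5, 2)), 5)
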