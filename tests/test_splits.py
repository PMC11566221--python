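"""Splitter contracts: disjoint covering partitions, group integrity,
PCM-aware balance and determinism."""

import numpy as np
import pandas as pd
import pytest

import qsarkit as qk
from qsarkit.splits import (butina_clusters, murcko_scaffold,
                            random_split_indices)
from qsarkit.synth import FixtureSpec, make_dataset, make_pcm_dataset


def assert_partition(train, test, n):
    assert len(train) > 0 and len(test) > 0
    assert set(train).isdisjoint(test)
    assert sorted(set(train) | set(test)) == list(range(n))


class TestRandomSplit:
    def test_exact_fraction(self):
        train, test = random_split_indices(10, 0.2, seed=0)
        assert len(test) == 2 and len(train) == 8

    def test_deterministic(self):
        a = random_split_indices(100, 0.2, seed=5)
        b = random_split_indices(100, 0.2, seed=5)
        np.testing.assert_array_equal(a[1], b[1])

    def test_different_seeds_differ(self):
        tests = {tuple(random_split_indices(100, 0.2, seed=s)[1])
                 for s in range(10)}
        assert len(tests) >= 9

    def test_empty_subset_errors(self):
        with pytest.raises(ValueError):
            random_split_indices(10, 0.01, seed=0)

    def test_stratified_preserves_class_ratio(self):
        labels = np.array([0] * 80 + [1] * 20)
        train, test = random_split_indices(100, 0.2, seed=1,
                                           stratify=labels)
        assert_partition(train, test, 100)
        assert labels[test].sum() == 4  # 20% of the 20 positives


class TestScaffoldSplit:
    def test_shared_scaffold_stays_together(self, dataset):
        split = qk.ScaffoldSplit(0.2, seed=0)
        train, test = split.split(dataset)
        assert_partition(train, test, len(dataset))
        # brute-force audit: scaffold sets of the subsets do not intersect
        scaffolds = [murcko_scaffold(s) for s in dataset.smiles]
        train_sc = {scaffolds[i] for i in train}
        test_sc = {scaffolds[i] for i in test}
        assert train_sc.isdisjoint(test_sc)

    def test_toolkit_scaffold_oracle(self):
        # toluene and ethylbenzene share the benzene scaffold
        assert murcko_scaffold("Cc1ccccc1") == murcko_scaffold("CCc1ccccc1")

    def test_acyclic_molecules_form_singletons(self):
        df = pd.DataFrame({"smiles": ["CCO", "CCCO", "CCCCO", "CCN", "CCCN",
                                      "CCCCN", "CCC", "CCCC", "CCCCC", "CO"],
                           "y": np.arange(10.0)})
        ds = qk.QSARDataset.from_table(
            df, "smiles",
            [qk.TargetProperty("y", qk.TargetTask.REGRESSION)])
        train, test = qk.ScaffoldSplit(0.2, seed=1).split(ds)
        assert_partition(train, test, 10)
        assert len(test) == 2


class TestClusterSplit:
    def test_no_cluster_straddles_subsets(self, dataset):
        train, test = qk.ClusterSplit(0.2, seed=0).split(dataset)
        assert_partition(train, test, len(dataset))
        labels = butina_clusters(dataset.smiles, cutoff=0.4)
        train_c = {labels[i] for i in train}
        test_c = {labels[i] for i in test}
        assert train_c.isdisjoint(test_c)

    def test_fraction_within_largest_cluster_bound(self, dataset):
        train, test = qk.ClusterSplit(0.2, seed=0).split(dataset)
        labels = butina_clusters(dataset.smiles, cutoff=0.4)
        largest = np.bincount(labels).max()
        achieved = len(test) / len(dataset)
        assert abs(achieved - 0.2) <= largest / len(dataset)

    def test_deterministic(self, dataset):
        a = qk.ClusterSplit(0.2, seed=3).split(dataset)
        b = qk.ClusterSplit(0.2, seed=3).split(dataset)
        np.testing.assert_array_equal(a[1], b[1])

    def test_single_cluster_errors(self):
        df = pd.DataFrame({"smiles": ["CCO", "CCO", "CCO"],
                           "y": [1.0, 2.0, 3.0]})
        ds = qk.QSARDataset.from_table(
            df, "smiles",
            [qk.TargetProperty("y", qk.TargetTask.REGRESSION)])
        with pytest.raises(ValueError, match="single cluster"):
            qk.ClusterSplit(0.2, seed=0).split(ds)


class TestTemporalSplit:
    def make(self, years):
        df = pd.DataFrame({"smiles": ["CCO", "CCC", "CCN"][: len(years)],
                           "year": years, "y": [1.0, 2.0, 3.0][: len(years)]})
        return qk.QSARDataset.from_table(
            df, "smiles", [qk.TargetProperty("y", qk.TargetTask.REGRESSION)])

    def test_cutoff_partition(self):
        train, test = qk.TemporalSplit("year", 2015).split(
            self.make([2009, 2012, 2020]))
        assert train.tolist() == [0, 1] and test.tolist() == [2]

    def test_cutoff_below_min_errors(self):
        with pytest.raises(ValueError):
            qk.TemporalSplit("year", 2000).split(self.make([2009, 2012, 2020]))

    def test_monotone_in_cutoff(self, dataset):
        sizes = []
        for cutoff in (2008, 2012, 2016):
            train, _ = qk.TemporalSplit("year", cutoff).split(dataset)
            sizes.append(len(train))
        assert sizes == sorted(sizes)


class TestManualSplit:
    def test_passthrough(self):
        train, test = qk.ManualSplit(["train", "test", "train"]).split()
        assert train.tolist() == [0, 2] and test.tolist() == [1]

    def test_all_train_errors(self):
        with pytest.raises(ValueError):
            qk.ManualSplit(["train", "train"]).split()

    def test_unknown_label_errors(self):
        with pytest.raises(ValueError, match="unknown"):
            qk.ManualSplit(["train", "validation"])

    def test_config_roundtrip(self):
        split = qk.ManualSplit(["train", "test"])
        cfg = split.to_config()
        rebuilt = qk.ManualSplit(cfg["labels"])
        assert rebuilt.split()[1].tolist() == split.split()[1].tolist()


class TestBootstrapSplit:
    def test_yields_valid_partitions(self, dataset):
        boot = qk.BootstrapSplit(qk.RandomSplit(0.2), n_replicates=5, seed=1)
        partitions = list(boot.splits(dataset))
        assert len(partitions) == 5
        for train, test in partitions:
            assert_partition(train, test, len(dataset))

    def test_sequence_reproducible(self, dataset):
        def run():
            boot = qk.BootstrapSplit(qk.RandomSplit(0.2), 5, seed=1)
            return [tuple(test) for _, test in boot.splits(dataset)]
        assert run() == run()

    def test_replicates_are_distinct(self, dataset):
        boot = qk.BootstrapSplit(qk.RandomSplit(0.2), 5, seed=1)
        tests = {tuple(test) for _, test in boot.splits(dataset)}
        assert len(tests) >= 2


class TestPCMSplit:
    def test_per_protein_fraction_within_tolerance(self, pcm_dataset):
        split = qk.PCMSplit(qk.RandomSplit(0.2, seed=42))
        train, test = split.split(pcm_dataset)
        assert_partition(train, test, len(pcm_dataset))
        prot = pcm_dataset.table["protein_id"].to_numpy()
        for p in np.unique(prot):
            rows = np.flatnonzero(prot == p)
            frac = len(np.intersect1d(rows, test)) / len(rows)
            assert 0.1 <= frac <= 0.3

    def test_molecule_never_straddles(self, pcm_dataset):
        train, test = qk.PCMSplit(qk.RandomSplit(0.2, seed=42)).split(
            pcm_dataset)
        keys = pcm_dataset.molecule_keys()
        train_mols = {keys[i] for i in train}
        test_mols = {keys[i] for i in test}
        assert train_mols.isdisjoint(test_mols)

    def test_deterministic(self, pcm_dataset):
        a = qk.PCMSplit(qk.RandomSplit(0.2, seed=9)).split(pcm_dataset)
        b = qk.PCMSplit(qk.RandomSplit(0.2, seed=9)).split(pcm_dataset)
        np.testing.assert_array_equal(a[1], b[1])


class TestLeaveTargetOut:
    def test_held_out_protein_exclusive(self, pcm_dataset):
        train, test = qk.LeaveTargetOut({"P3"}).split(pcm_dataset)
        prot = pcm_dataset.table["protein_id"].to_numpy()
        assert set(prot[test]) == {"P3"}
        assert "P3" not in set(prot[train])

    def test_hold_all_errors(self, pcm_dataset):
        proteins = set(pcm_dataset.table["protein_id"])
        with pytest.raises(ValueError, match="every protein"):
            qk.LeaveTargetOut(proteins).split(pcm_dataset)

    def test_empty_held_out_errors(self):
        with pytest.raises(ValueError):
            qk.LeaveTargetOut(set())


class TestTemporalPerTarget:
    def make(self):
        rows = [("c1ccccc1C", "P1", 2010), ("c1ccccc1C", "P2", 2018),
                ("c1ccccc1CC", "P1", 2019), ("c1ccccc1N", "P2", 2012),
                ("c1ccccc1O", "P1", 2020), ("c1ccccc1O", "P2", 2009)]
        df = pd.DataFrame(rows, columns=["smiles", "protein_id", "year"])
        df["y"] = np.arange(6.0)
        seqs = {"P1": "ACDEF", "P2": "ACDEG"}
        return qk.PCMDataset.from_table(
            df, "smiles", [qk.TargetProperty("y", qk.TargetTask.REGRESSION)],
            protein_id_column="protein_id", protein_sequences=seqs)

    def test_first_occurrence_rule(self):
        ds = self.make()
        train, test = qk.TemporalPerTarget("year", 2015).split(ds)
        # hand-rolled oracle: min year per molecule decides all its rows
        keys = ds.molecule_keys()
        years = ds.table["year"].to_numpy()
        first = {}
        for k, y in zip(keys, years):
            first[k] = min(first.get(k, 10**9), y)
        expected_train = [i for i, k in enumerate(keys) if first[k] <= 2015]
        assert train.tolist() == expected_train
        # molecule seen 2010 and 2018: both rows train
        assert 0 in train and 1 in train

    def test_single_late_molecule_goes_to_test(self):
        train, test = qk.TemporalPerTarget("year", 2015).split(self.make())
        assert 2 in test

    def test_no_molecule_straddles(self, pcm_dataset):
        train, test = qk.TemporalPerTarget("year", 2012).split(pcm_dataset)
        keys = pcm_dataset.molecule_keys()
        assert {keys[i] for i in train}.isdisjoint({keys[i] for i in test})


@pytest.mark.parametrize("split_factory", [
    lambda: qk.RandomSplit(0.2, seed=0),
    lambda: qk.ScaffoldSplit(0.2, seed=0),
    lambda: qk.ClusterSplit(0.2, seed=0),
    lambda: qk.TemporalSplit("year", 2012),
])
def test_every_splitter_returns_disjoint_covering_partition(split_factory,
                                                            dataset):
    train, test = split_factory().split(dataset)
    assert_partition(train, test, len(dataset))


def test_splits_are_pure_functions_of_seed():
    ds1 = make_dataset(FixtureSpec())
    ds2 = make_dataset(FixtureSpec())
    for factory in (qk.RandomSplit, qk.ScaffoldSplit, qk.ClusterSplit):
        a = factory(0.2, seed=4).split(ds1)
        b = factory(0.2, seed=4).split(ds2)
        np.testing.assert_array_equal(a[1], b[1])
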