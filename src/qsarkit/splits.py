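"""Train/test split strategies, including group- and PCM-aware splits.

Every splitter is a pure function of (inputs, seed) and returns a pair
of disjoint, covering, non-empty positional index arrays. Group
respecting splitters (scaffold, cluster, PCM, temporal-per-molecule)
never place two rows of one group in different subsets.
"""

from __future__ import annotations

import warnings
from abc import ABC, abstractmethod

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold
from rdkit.ML.Cluster import Butina

from .persistence import derive_seed

DEFAULT_TEST_FRACTION = 0.2


def _check_partition(train: np.ndarray, test: np.ndarray, n: int) -> None:
    if len(train) == 0 or len(test) == 0:
        raise ValueError("split produced an empty train or test subset")
    assert len(set(train) & set(test)) == 0
    assert len(train) + len(test) == n


class DataSplit(ABC):
    """Contract: ``split(dataset) -> (train_indices, test_indices)``."""

    name: str
    seed: int | None = None

    @abstractmethod
    def split(self, dataset) -> tuple[np.ndarray, np.ndarray]: ...

    def to_config(self) -> dict:
        return {"type": self.name, "seed": self.seed}


def random_split_indices(n: int, test_fraction: float, seed: int,
                         stratify: np.ndarray | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random partition with |test| = round(n * test_fraction).

    With ``stratify`` labels, test picks are made per class so class
    ratios are preserved within rounding.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    if n < 2:
        raise ValueError("need at least two rows to split")
    n_test = int(round(n * test_fraction))
    if n_test == 0 or n_test == n:
        raise ValueError(
            f"test_fraction {test_fraction} yields an empty subset for n={n}")
    rng = np.random.default_rng(seed)
    if stratify is None:
        perm = rng.permutation(n)
        test = np.sort(perm[:n_test])
    else:
        stratify = np.asarray(stratify)
        picks: list[int] = []
        classes = pd.unique(stratify)
        for cls in classes:
            members = np.flatnonzero(stratify == cls)
            k = int(round(len(members) * test_fraction))
            k = min(max(k, 1 if n_test >= len(classes) else 0), len(members) - 1)
            picks.extend(rng.permutation(members)[:k].tolist())
        test = np.sort(np.array(picks, dtype=int))
    train = np.setdiff1d(np.arange(n), test)
    _check_partition(train, test, n)
    return train, test


class RandomSplit(DataSplit):
    """Seeded uniform random split; stratifies by class labels when the
    dataset declares only classification targets."""

    def __init__(self, test_fraction: float = DEFAULT_TEST_FRACTION,
                 seed: int | None = None, stratify: bool = True):
        self.test_fraction = test_fraction
        self.seed = seed
        self.stratify = stratify
        self.name = "RandomSplit"

    def split(self, dataset):
        seed = self.seed if self.seed is not None else dataset.random_state
        labels = None
        if self.stratify and dataset.target_properties and all(
                tp.task.is_classification for tp in dataset.target_properties):
            labels = dataset.table[
                dataset.target_properties[0].label_column].to_numpy()
        return random_split_indices(len(dataset), self.test_fraction, seed,
                                    stratify=labels)


def murcko_scaffold(smiles: str) -> str:
    """Bemis–Murcko scaffold SMILES with stereochemistry stripped;
    acyclic molecules yield the empty string."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    Chem.RemoveStereochemistry(mol)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    return Chem.MolToSmiles(scaffold)


def group_split_indices(groups: list, test_fraction: float, seed: int
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Greedy whole-group assignment: shuffle groups by seed, fill the
    test set until it reaches round(n * fraction), remainder to train."""
    n = len(groups)
    n_test = int(round(n * test_fraction))
    members: dict = {}
    for i, g in enumerate(groups):
        members.setdefault(g, []).append(i)
    keys = sorted(members, key=repr)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(keys))
    test: list[int] = []
    for k in order:
        if len(test) >= n_test:
            break
        test.extend(members[keys[k]])
    test_arr = np.sort(np.array(test, dtype=int))
    train = np.setdiff1d(np.arange(n), test_arr)
    _check_partition(train, test_arr, n)
    return train, test_arr


class ScaffoldSplit(DataSplit):
    """Group molecules by Bemis–Murcko scaffold and assign whole groups.

    Acyclic molecules (empty scaffold) form singleton groups keyed by
    their own canonical SMILES.
    """

    def __init__(self, test_fraction: float = DEFAULT_TEST_FRACTION,
                 seed: int | None = None):
        self.test_fraction = test_fraction
        self.seed = seed
        self.name = "ScaffoldSplit"

    def groups_for(self, smiles: list[str]) -> list[str]:
        out = []
        for smi in smiles:
            scaf = murcko_scaffold(smi)
            out.append(scaf if scaf else f"acyclic:{Chem.CanonSmiles(smi)}:{len(out)}")
        return out

    def split(self, dataset):
        seed = self.seed if self.seed is not None else dataset.random_state
        groups = self.groups_for(dataset.smiles)
        return group_split_indices(groups, self.test_fraction, seed)


def butina_clusters(smiles: list[str], cutoff: float = 0.4,
                    radius: int = 3, n_bits: int = 2048) -> np.ndarray:
    """Taylor–Butina leader clustering on Tanimoto distance between
    circular fingerprints; returns a cluster label per molecule."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fps = []
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"invalid SMILES: {smi!r}")
        fps.append(gen.GetFingerprint(mol))
    dists = []
    for i in range(1, len(fps)):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[:i])
        dists.extend(1.0 - s for s in sims)
    clusters = Butina.ClusterData(dists, len(fps), cutoff, isDistData=True)
    labels = np.empty(len(fps), dtype=int)
    for ci, members in enumerate(clusters):
        labels[list(members)] = ci
    return labels


class ClusterSplit(DataSplit):
    """Assign whole Taylor–Butina clusters to train or test.

    Clusters are packed greedily, largest first, into the subset that is
    currently furthest below its target size — a deterministic
    approximation of globally balanced cluster assignment.
    """

    def __init__(self, test_fraction: float = DEFAULT_TEST_FRACTION,
                 seed: int | None = None, distance_cutoff: float = 0.4):
        self.test_fraction = test_fraction
        self.seed = seed
        self.distance_cutoff = distance_cutoff
        self.name = "ClusterSplit"

    def split(self, dataset):
        seed = self.seed if self.seed is not None else dataset.random_state
        labels = butina_clusters(dataset.smiles, cutoff=self.distance_cutoff)
        n = len(labels)
        n_clusters = labels.max() + 1
        if n_clusters < 2:
            raise ValueError(
                "all molecules fall in a single cluster; use another split")
        sizes = np.bincount(labels)
        # order largest-first; ties broken by a seeded shuffle for replica variety
        rng = np.random.default_rng(seed)
        order = rng.permutation(n_clusters)
        order = order[np.argsort(-sizes[order], kind="stable")]
        target = {"test": int(round(n * self.test_fraction))}
        target["train"] = n - target["test"]
        current = {"train": 0, "test": 0}
        assignment: dict[int, str] = {}
        for ci in order:
            deficits = {s: target[s] - current[s] for s in ("train", "test")}
            side = max(deficits, key=lambda s: (deficits[s], s == "train"))
            assignment[ci] = side
            current[side] += sizes[ci]
        test = np.flatnonzero([assignment[c] == "test" for c in labels])
        train = np.setdiff1d(np.arange(n), test)
        _check_partition(train, test, n)
        return train, test


class TemporalSplit(DataSplit):
    """Train on rows with timepoint <= cutoff, test on later rows."""

    def __init__(self, time_column: str, cutoff: float):
        self.time_column = time_column
        self.cutoff = cutoff
        self.name = "TemporalSplit"

    def split(self, dataset):
        t = dataset.table[self.time_column].to_numpy(dtype=float)
        train = np.flatnonzero(t <= self.cutoff)
        test = np.flatnonzero(t > self.cutoff)
        _check_partition(train, test, len(t))
        return train, test


class ManualSplit(DataSplit):
    """Apply a predefined per-row train/test labelling."""

    def __init__(self, labels):
        self.labels = list(labels)
        self.name = "ManualSplit"
        bad = set(self.labels) - {"train", "test"}
        if bad:
            raise ValueError(f"unknown subset labels: {sorted(bad)}")

    def split(self, dataset=None):
        arr = np.array(self.labels)
        train = np.flatnonzero(arr == "train")
        test = np.flatnonzero(arr == "test")
        _check_partition(train, test, len(arr))
        return train, test

    def to_config(self):
        return {"type": self.name, "labels": self.labels}


class BootstrapSplit:
    """Repeat a base split with derived seeds, one per replicate."""

    def __init__(self, base: DataSplit, n_replicates: int, seed: int):
        if n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        self.base = base
        self.n_replicates = n_replicates
        self.seed = seed
        self.name = "BootstrapSplit"

    def splits(self, dataset):
        for rep in range(self.n_replicates):
            self.base.seed = derive_seed(self.seed, f"bootstrap_{rep}")
            yield self.base.split(dataset)


class PCMSplit(DataSplit):
    """Molecule-level split for compound–protein pair datasets.

    The base split is applied to unique molecules so all rows of one
    molecule (across proteins) move together. The per-protein test
    fraction is then checked against the global fraction (tolerance
    ±0.1); on violation the split is re-drawn with an incremented seed
    (up to 20 attempts) and the attempt with the smallest maximum
    per-protein deviation is kept.
    """

    def __init__(self, base: DataSplit, tolerance: float = 0.1,
                 max_attempts: int = 20):
        self.base = base
        self.tolerance = tolerance
        self.max_attempts = max_attempts
        self.name = "PCMSplit"
        self.seed = base.seed

    def split(self, dataset):
        mol_keys = dataset.molecule_keys()
        uniq = list(dict.fromkeys(mol_keys))
        proxy = _MoleculeProxy(dataset, uniq)
        base_seed = self.base.seed if self.base.seed is not None else dataset.random_state
        global_frac = getattr(self.base, "test_fraction", DEFAULT_TEST_FRACTION)
        prot = dataset.table[dataset.protein_id_column].to_numpy()
        best = None
        best_dev = np.inf
        for attempt in range(self.max_attempts):
            self.base.seed = base_seed + attempt
            mtrain, mtest = self.base.split(proxy)
            test_keys = {uniq[i] for i in mtest}
            test = np.flatnonzero([k in test_keys for k in mol_keys])
            train = np.setdiff1d(np.arange(len(mol_keys)), test)
            devs = []
            for p in pd.unique(prot):
                rows = prot == p
                frac = np.isin(np.flatnonzero(rows), test).sum() / rows.sum()
                devs.append(abs(frac - global_frac))
            dev = max(devs)
            if dev < best_dev:
                best_dev, best = dev, (train, test)
            if dev <= self.tolerance:
                break
        else:
            warnings.warn(
                f"per-protein balance tolerance {self.tolerance} unmet; "
                f"best max deviation {best_dev:.3f}")
        self.base.seed = base_seed
        _check_partition(*best, len(mol_keys))
        return best


class _MoleculeProxy:
    """Minimal dataset view over unique molecules, for base splitters."""

    def __init__(self, dataset, unique_keys):
        self.random_state = dataset.random_state
        self.target_properties = []
        first = {k: i for i, k in reversed(list(enumerate(dataset.molecule_keys())))}
        rows = [first[k] for k in unique_keys]
        self.table = dataset.table.iloc[rows].reset_index(drop=True)
        self.smiles = [dataset.smiles[i] for i in rows]

    def __len__(self):
        return len(self.smiles)


class LeaveTargetOut(DataSplit):
    """Hold out every row of the named proteins for the test set."""

    def __init__(self, held_out):
        self.held_out = set(held_out)
        if not self.held_out:
            raise ValueError("held_out must be non-empty")
        self.name = "LeaveTargetOut"

    def split(self, dataset):
        prot = dataset.table[dataset.protein_id_column].to_numpy()
        all_proteins = set(prot)
        if self.held_out >= all_proteins:
            raise ValueError("cannot hold out every protein")
        test = np.flatnonzero([p in self.held_out for p in prot])
        train = np.setdiff1d(np.arange(len(prot)), test)
        _check_partition(train, test, len(prot))
        return train, test

    def to_config(self):
        return {"type": self.name, "held_out": sorted(self.held_out)}


class TemporalPerTarget(DataSplit):
    """Temporal split keyed on each molecule's first occurrence.

    A molecule's timepoint is the minimum over all its rows (any
    protein); all rows of molecules first seen at or before the cutoff
    go to train, the rest to test, so no molecule straddles subsets.
    """

    def __init__(self, time_column: str, cutoff: float):
        self.time_column = time_column
        self.cutoff = cutoff
        self.name = "TemporalPerTarget"

    def split(self, dataset):
        keys = dataset.molecule_keys()
        t = dataset.table[self.time_column].to_numpy(dtype=float)
        first = {}
        for k, ti in zip(keys, t):
            first[k] = min(first.get(k, np.inf), ti)
        train = np.flatnonzero([first[k] <= self.cutoff for k in keys])
        test = np.setdiff1d(np.arange(len(keys)), train)
        _check_partition(train, test, len(keys))
        return train, test

    def to_config(self):
        return {"type": self.name, "time_column": self.time_column,
                "cutoff": self.cutoff}


SPLIT_REGISTRY = {
    "random": RandomSplit,
    "scaffold": ScaffoldSplit,
    "cluster": ClusterSplit,
    "temporal": TemporalSplit,
    "manual": ManualSplit,
}
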