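"""Dataset containers and the fixed-order preparation orchestrator.

:class:`MoleculeTable` stores identified molecules with arbitrary
property columns and row-aligned descriptor matrices. :class:`QSARDataset`
adds target properties, train/test assignment and the feature pipeline
state; :class:`PCMDataset` extends it to compound–protein pairs.

Preparation runs in a fixed, auditable order — data filters, descriptor
calculation, train/test split, feature filtering (train-fitted), feature
standardization (train-fitted, applied everywhere) and an optional
applicability domain — and records the full recipe so the identical
featurization can be replayed on new molecules at prediction time.
"""

from __future__ import annotations

import logging
from abc import ABC, abstractmethod
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from . import persistence
from .descriptors import (DescriptorSet, ProteinDescriptorSet,
                          TabularDescriptors, descriptor_from_config)
from .filters import (DataFilter, FeatureFilter, FeatureStandardizer,
                      RepeatsFilter, data_filter_from_config,
                      feature_filter_from_config)
from .tasks import TargetProperty, TargetTask, infer_task

logger = logging.getLogger(__name__)

ID_COL = "mol_id"
SMILES_COL = "smiles"
SUBSET_COL = "subset"


def discretize_column(values: np.ndarray, thresholds: Sequence[float]) -> np.ndarray:
    """Map continuous values to class indices by ascending thresholds.

    Class ``k`` covers the half-open interval ``[t_k, t_{k+1})`` with
    ``(-inf, t_1)`` as class 0 — a value exactly on a threshold belongs
    to the upper class.
    """
    th = list(thresholds)
    if sorted(th) != th or len(set(th)) != len(th):
        raise ValueError(f"thresholds must be strictly ascending, got {th}")
    return np.searchsorted(th, np.asarray(values, dtype=float), side="right")


class MoleculeTable:
    """Identified molecules plus property columns and descriptor matrices."""

    def __init__(self, name: str, table: pd.DataFrame, random_state: int = 42):
        self.name = name
        self.table = table.reset_index(drop=True)
        self.random_state = int(random_state)
        self.descriptors: dict[str, pd.DataFrame] = {}
        self.descriptor_sets: list[DescriptorSet] = []
        self.n_invalid_dropped = 0

    # -- construction ------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, smiles_col: str, name: str,
                       random_state: int = 42) -> "MoleculeTable":
        if smiles_col not in df.columns:
            raise KeyError(f"SMILES column {smiles_col!r} not in table")
        df = df.reset_index(drop=True)
        valid = []
        for i, smi in enumerate(df[smiles_col]):
            if isinstance(smi, str) and Chem.MolFromSmiles(smi) is not None:
                valid.append(i)
        n_dropped = len(df) - len(valid)
        if not valid:
            raise ValueError("no valid SMILES in input; empty dataset")
        if n_dropped:
            logger.warning("dropped %d rows with unparsable SMILES", n_dropped)
        out_df = df.iloc[valid].reset_index(drop=True)
        pad = max(4, len(str(len(out_df))))
        table = pd.DataFrame({
            ID_COL: [f"{name}_{i:0{pad}d}" for i in range(len(out_df))],
            SMILES_COL: out_df[smiles_col],
        })
        for col in out_df.columns:
            if col not in (smiles_col,):
                table[col] = out_df[col].to_numpy()
        obj = cls(name, table, random_state)
        obj.n_invalid_dropped = n_dropped
        return obj

    @classmethod
    def from_csv(cls, path: str | Path, smiles_col: str, name: str | None = None,
                 random_state: int = 42) -> "MoleculeTable":
        path = Path(path)
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        df = pd.read_csv(path, sep=sep)
        return cls.from_dataframe(df, smiles_col, name or path.stem, random_state)

    @classmethod
    def from_sdf(cls, path: str | Path, name: str | None = None,
                 random_state: int = 42) -> "MoleculeTable":
        rows = []
        for mol in Chem.SDMolSupplier(str(path)):
            if mol is None:
                rows.append({"_smiles": "invalid"})
                continue
            rec = {"_smiles": Chem.MolToSmiles(mol)}
            rec.update(mol.GetPropsAsDict())
            rows.append(rec)
        df = pd.DataFrame(rows)
        return cls.from_dataframe(df, "_smiles", name or Path(path).stem,
                                  random_state)

    # -- basic accessors ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.table)

    @property
    def smiles(self) -> list[str]:
        return self.table[SMILES_COL].tolist()

    @property
    def ids(self) -> list[str]:
        return self.table[ID_COL].tolist()

    def molecule_keys(self) -> list[str]:
        """Canonical SMILES per row — the molecule-level grouping key."""
        return [Chem.CanonSmiles(s) for s in self.smiles]

    # -- descriptors -------------------------------------------------------
    def add_descriptors(self, dset: DescriptorSet) -> None:
        if isinstance(dset, TabularDescriptors):
            keys = self.ids if set(self.ids) & set(dset.table.index) else self.smiles
            mat = dset.transform_keys(keys)
        else:
            mat = dset.transform_smiles(self.smiles)
        if len(mat) != len(self):
            raise ValueError(
                f"descriptor set {dset.name} returned {len(mat)} rows "
                f"for {len(self)} molecules")
        mat.index = self.table.index
        self.descriptors[dset.name] = mat
        self.descriptor_sets.append(dset)

    def descriptor_matrix(self) -> pd.DataFrame | None:
        if not self.descriptors:
            return None
        return pd.concat(self.descriptors.values(), axis=1)

    def _subset_rows(self, keep: np.ndarray) -> None:
        self.table = self.table.iloc[keep].reset_index(drop=True)
        for k in self.descriptors:
            self.descriptors[k] = (
                self.descriptors[k].iloc[keep].reset_index(drop=True))


class QSARDataset(MoleculeTable):
    """A molecule table with modelling targets and preparation state."""

    def __init__(self, name: str, table: pd.DataFrame,
                 target_properties: Sequence[TargetProperty],
                 random_state: int = 42):
        super().__init__(name, table, random_state)
        if not target_properties:
            raise ValueError("no target properties defined")
        for tp in target_properties:
            if tp.name not in self.table.columns:
                raise KeyError(f"target column {tp.name!r} not in table")
        self.target_properties = list(target_properties)
        self._drop_all_missing_targets()
        for tp in self.target_properties:
            self.discretize(tp)
        if SUBSET_COL not in self.table.columns:
            self.table[SUBSET_COL] = "unassigned"
        self.feature_names: list[str] | None = None
        self.standardizer: FeatureStandardizer | None = None
        self.imputation: dict[str, float] = {}
        self.recipe: dict = {}
        self.ad_flags: pd.Series | None = None
        self.applicability_domain = None

    @classmethod
    def from_table(cls, df: pd.DataFrame, smiles_col: str,
                   target_properties: Sequence[TargetProperty],
                   name: str = "dataset", random_state: int = 42
                   ) -> "QSARDataset":
        for tp in target_properties:
            if tp.name not in df.columns:
                raise KeyError(f"target column {tp.name!r} not in table")
        mt = MoleculeTable.from_dataframe(df, smiles_col, name, random_state)
        ds = cls(name, mt.table, target_properties, random_state)
        ds.n_invalid_dropped = mt.n_invalid_dropped
        return ds

    @classmethod
    def from_csv(cls, path, smiles_col, target_properties=None, name=None,
                 random_state: int = 42):
        mt = MoleculeTable.from_csv(path, smiles_col, name, random_state)
        ds = cls(mt.name, mt.table, target_properties, random_state)
        ds.n_invalid_dropped = mt.n_invalid_dropped
        return ds

    # -- targets -----------------------------------------------------------
    def _drop_all_missing_targets(self) -> None:
        cols = [tp.name for tp in self.target_properties]
        missing_all = self.table[cols].isna().all(axis=1)
        if missing_all.any():
            logger.warning("dropping %d rows missing every target",
                           int(missing_all.sum()))
            self._subset_rows(np.flatnonzero(~missing_all.to_numpy()))

    def discretize(self, tp: TargetProperty) -> None:
        """Add the class-label column for a thresholded classification target;
        the original continuous column is preserved untouched."""
        if not (tp.task.is_classification and tp.thresholds):
            return
        vals = self.table[tp.name].to_numpy(dtype=float)
        labels = discretize_column(vals, tp.thresholds).astype(float)
        labels[np.isnan(vals)] = np.nan
        self.table[tp.label_column] = labels

    @property
    def task(self):
        return infer_task(self.target_properties)

    @property
    def target_columns(self) -> list[str]:
        return [tp.label_column for tp in self.target_properties]

    # -- subsets -----------------------------------------------------------
    def set_split(self, train_idx: np.ndarray, test_idx: np.ndarray) -> None:
        col = np.array(["unassigned"] * len(self), dtype=object)
        col[np.asarray(train_idx)] = "train"
        col[np.asarray(test_idx)] = "test"
        if (col == "unassigned").any():
            raise ValueError("split does not cover all rows")
        self.table[SUBSET_COL] = col

    def subset_indices(self, subset: str) -> np.ndarray:
        if subset == "all":
            return np.arange(len(self))
        return np.flatnonzero((self.table[SUBSET_COL] == subset).to_numpy())

    # -- preparation -------------------------------------------------------
    def prepare(self,
                data_filters: Sequence[DataFilter] = (),
                descriptor_sets: Sequence[DescriptorSet] = (),
                splitter=None,
                feature_filters: Sequence[FeatureFilter] = (),
                standardize: bool = True,
                applicability_domain=None,
                ad_remove: bool = False) -> "QSARDataset":
        """Run the fixed-order preparation pipeline and record the recipe."""
        recipe: dict = {"seed": self.random_state}
        # (1) row filters
        recipe["data_filters"] = []
        for f in data_filters:
            if isinstance(f, RepeatsFilter):
                if not self.descriptors:
                    for dset in descriptor_sets:
                        self.add_descriptors(dset)
                keep = f.filter(self.table, dataset=self)
            else:
                keep = f.filter(self.table, dataset=self)
            self._subset_rows(keep)
            recipe["data_filters"].append(f.to_config())
        # (2) descriptors
        for dset in descriptor_sets:
            if dset.name not in self.descriptors:
                self.add_descriptors(dset)
        recipe["descriptors"] = [d.to_config() for d in self.descriptor_sets]
        # (3) split
        if splitter is not None:
            train_idx, test_idx = splitter.split(self)
            self.set_split(train_idx, test_idx)
            recipe["split"] = splitter.to_config()
        train = self.subset_indices("train")
        if splitter is not None and (len(train) == 0 or
                                     len(self.subset_indices("test")) == 0):
            raise ValueError("split produced an empty subset")
        # (4) feature filters, train-fitted
        full = self.descriptor_matrix()
        feature_names = list(full.columns) if full is not None else []
        recipe["feature_filters"] = []
        if full is not None and len(train):
            medians = full.iloc[train].median(axis=0)
            work = full.fillna(medians)
            train_work = work.iloc[train]
            for ff in feature_filters:
                ff.fit(train_work[feature_names])
                feature_names = list(ff.selected_)
                recipe["feature_filters"].append(ff.to_config())
            if not feature_names:
                raise ValueError("feature filtering removed every feature")
            # (5) imputation + standardizer, train-fitted
            self.imputation = {c: float(medians[c]) for c in feature_names
                               if not np.isnan(medians[c])}
            if standardize:
                self.standardizer = FeatureStandardizer().fit(
                    work.iloc[train][feature_names])
        self.feature_names = feature_names
        recipe["feature_names"] = feature_names
        recipe["imputation"] = self.imputation
        recipe["standardizer"] = (self.standardizer.to_config()
                                  if self.standardizer else None)
        # (6) applicability domain on train, flags for test
        recipe["applicability_domain"] = None
        if applicability_domain is not None:
            applicability_domain.fit(self.get_features("train").to_numpy())
            flags = applicability_domain.contains(
                self.get_features("all").to_numpy())
            self.ad_flags = pd.Series(flags, index=self.table.index)
            self.applicability_domain = applicability_domain
            recipe["applicability_domain"] = applicability_domain.to_config()
            if ad_remove:
                test = self.subset_indices("test")
                out = test[~flags[test]]
                if len(out):
                    keepmask = np.ones(len(self), dtype=bool)
                    keepmask[out] = False
                    self._subset_rows(np.flatnonzero(keepmask))
                    self.ad_flags = self.ad_flags.iloc[
                        np.flatnonzero(keepmask)].reset_index(drop=True)
        self.recipe = recipe
        return self

    # -- feature access ----------------------------------------------------
    def get_features(self, subset: str = "all", raw: bool = False
                     ) -> pd.DataFrame:
        """Selected (and, unless ``raw``, imputed + standardized) features."""
        full = self.descriptor_matrix()
        if full is None:
            raise RuntimeError("no descriptors computed")
        idx = self.subset_indices(subset)
        cols = self.feature_names if self.feature_names is not None else list(
            full.columns)
        out = full.iloc[idx][cols]
        if raw:
            return out
        if self.imputation:
            out = out.fillna(pd.Series(self.imputation))
        if self.standardizer is not None:
            out = self.standardizer.transform(out)
        return out

    def get_targets(self, subset: str = "all") -> pd.DataFrame:
        idx = self.subset_indices(subset)
        return self.table.iloc[idx][self.target_columns]

    # -- persistence -------------------------------------------------------
    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        files = ["table.tsv"]
        self.table.to_csv(directory / "table.tsv", sep="\t", index=False)
        for dname, mat in self.descriptors.items():
            fname = f"descriptors_{dname}.tsv"
            mat.to_csv(directory / fname, sep="\t", index=False)
            files.append(fname)
        meta = {
            "class": type(self).__name__,
            "name": self.name,
            "random_state": self.random_state,
            "target_properties": [tp.to_config() for tp in
                                  self.target_properties],
            "recipe": self.recipe,
            "feature_names": self.feature_names,
            "imputation": self.imputation,
            "standardizer": (self.standardizer.to_config()
                             if self.standardizer else None),
            "descriptor_names": list(self.descriptors),
            "files": sorted(files),
            "extra": self._extra_meta(),
        }
        return persistence.save_meta(directory, meta)

    def _extra_meta(self) -> dict:
        return {}

    @classmethod
    def load(cls, directory: str | Path) -> "QSARDataset":
        directory = Path(directory)
        meta = persistence.load_meta(directory)
        table = pd.read_csv(directory / "table.tsv", sep="\t")
        tps = [TargetProperty.from_config(c)
               for c in meta["target_properties"]]
        klass = PCMDataset if meta["class"] == "PCMDataset" else QSARDataset
        if klass is PCMDataset:
            ds = PCMDataset(meta["name"], table, tps,
                            protein_id_column=meta["extra"]["protein_id_column"],
                            protein_sequences=meta["extra"]["protein_sequences"],
                            random_state=meta["random_state"])
        else:
            ds = QSARDataset(meta["name"], table, tps,
                             random_state=meta["random_state"])
        ds.recipe = meta["recipe"]
        ds.feature_names = meta["feature_names"]
        ds.imputation = meta["imputation"] or {}
        if meta["standardizer"]:
            ds.standardizer = FeatureStandardizer.from_config(
                meta["standardizer"])
        for dname in meta["descriptor_names"]:
            mat = pd.read_csv(directory / f"descriptors_{dname}.tsv", sep="\t")
            mat.columns = [str(c) for c in mat.columns]
            ds.descriptors[dname] = mat
        for cfg in meta["recipe"].get("descriptors", []):
            try:
                ds.descriptor_sets.append(descriptor_from_config(cfg))
            except ValueError:
                logger.warning("descriptor %s not rebuildable; matrix only",
                               cfg.get("name"))
        return ds


class PCMDataset(QSARDataset):
    """Compound–protein pair dataset for proteochemometric modelling.

    Each row is one (molecule, protein) pair; every protein id occurring
    in the table must have a sequence entry. Molecule-level operations
    (group splits) key on canonical SMILES so a molecule's rows across
    proteins always move together.
    """

    def __init__(self, name: str, table: pd.DataFrame,
                 target_properties: Sequence[TargetProperty],
                 protein_id_column: str,
                 protein_sequences: Mapping[str, str],
                 random_state: int = 42):
        super().__init__(name, table, target_properties, random_state)
        if protein_id_column not in self.table.columns:
            raise KeyError(f"protein column {protein_id_column!r} not in table")
        self.protein_id_column = protein_id_column
        self.protein_sequences = dict(protein_sequences)
        missing = set(self.table[protein_id_column]) - set(
            self.protein_sequences)
        if missing:
            raise ValueError(f"no sequence for protein ids: {sorted(missing)}")
        self.protein_descriptor_sets: list[ProteinDescriptorSet] = []

    @classmethod
    def from_table(cls, df, smiles_col, target_properties,
                   protein_id_column, protein_sequences,
                   name="pcm_dataset", random_state: int = 42):
        mt = MoleculeTable.from_dataframe(df, smiles_col, name, random_state)
        ds = cls(name, mt.table, target_properties,
                 protein_id_column, protein_sequences, random_state)
        ds.n_invalid_dropped = mt.n_invalid_dropped
        return ds

    def add_protein_descriptors(self, pset: ProteinDescriptorSet) -> None:
        per_protein = pset.transform_sequences(self.protein_sequences)
        rows = per_protein.loc[self.table[self.protein_id_column]]
        rows.index = self.table.index
        self.descriptors[pset.name] = rows
        self.protein_descriptor_sets.append(pset)

    def prepare(self, *args, protein_descriptor_sets=(), **kwargs):
        for pset in protein_descriptor_sets:
            if pset.name not in self.descriptors:
                self.add_protein_descriptors(pset)
        return super().prepare(*args, **kwargs)

    def _extra_meta(self) -> dict:
        return {"protein_id_column": self.protein_id_column,
                "protein_sequences": self.protein_sequences}


def pcm_featurize(ds: PCMDataset,
                  mol_sets: Sequence[DescriptorSet],
                  prot_sets: Sequence[ProteinDescriptorSet]) -> pd.DataFrame:
    """Concatenate [molecular | protein] descriptor blocks per pair row.

    Two rows with the same molecule but different proteins differ only
    in the protein block.
    """
    blocks = []
    for dset in mol_sets:
        blocks.append(dset.transform_smiles(ds.smiles).set_index(ds.table.index))
    prot_ids = ds.table[ds.protein_id_column]
    missing = set(prot_ids) - set(ds.protein_sequences)
    if missing:
        raise ValueError(f"no sequence for protein ids: {sorted(missing)}")
    for pset in prot_sets:
        per_protein = pset.transform_sequences(ds.protein_sequences)
        rows = per_protein.loc[prot_ids]
        rows.index = ds.table.index
        blocks.append(rows)
    return pd.concat(blocks, axis=1)


class DataSource(ABC):
    """Contract for programmatic dataset creation.

    Repeated calls with the same parameters must yield identical tables.
    """

    name: str

    @abstractmethod
    def get_dataframe(self) -> pd.DataFrame: ...

    @property
    @abstractmethod
    def smiles_column(self) -> str: ...

    def get_dataset(self, target_properties: Sequence[TargetProperty],
                    random_state: int = 42) -> QSARDataset:
        return QSARDataset.from_table(
            self.get_dataframe(), self.smiles_column, target_properties,
            name=self.name, random_state=random_state)
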