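"""Molecular and protein descriptor sets.

A :class:`DescriptorSet` maps molecules to fixed-width numeric vectors;
a :class:`ProteinDescriptorSet` does the same for amino-acid sequences.
Descriptor matrices are pure functions of (canonical structure,
configuration): recomputing a matrix reproduces the stored values
elementwise. Column names are globally unique through
``"<set_name>_<col>"`` prefixing, so matrices from several sets can be
concatenated without collisions.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator


class DescriptorSet(ABC):
    """A named featurizer producing one numeric vector per molecule."""

    name: str

    @property
    @abstractmethod
    def descriptor_names(self) -> list[str]:
        """Unprefixed output column names."""

    @property
    def columns(self) -> list[str]:
        return [f"{self.name}_{c}" for c in self.descriptor_names]

    @property
    def width(self) -> int:
        return len(self.descriptor_names)

    @abstractmethod
    def transform_smiles(self, smiles: Sequence[str]) -> pd.DataFrame:
        """Featurize SMILES; returns a frame with prefixed columns."""

    @abstractmethod
    def to_config(self) -> dict: ...

    def __call__(self, smiles: Sequence[str]) -> pd.DataFrame:
        return self.transform_smiles(smiles)


class MorganFingerprint(DescriptorSet):
    """Circular (Morgan) fingerprint bits.

    Defaults follow common bioactivity-modelling practice: radius 3,
    2048 bits. Entries are 0/1.
    """

    def __init__(self, radius: int = 3, n_bits: int = 2048, name: str | None = None):
        if radius < 0:
            raise ValueError("radius must be >= 0")
        if n_bits < 16:
            raise ValueError("n_bits must be >= 16")
        self.radius = int(radius)
        self.n_bits = int(n_bits)
        self.name = name or f"MorganFP_r{radius}_{n_bits}"

    @property
    def descriptor_names(self) -> list[str]:
        return [str(i) for i in range(self.n_bits)]

    def transform_smiles(self, smiles: Sequence[str]) -> pd.DataFrame:
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=self.radius, fpSize=self.n_bits
        )
        rows = np.zeros((len(smiles), self.n_bits), dtype=np.int8)
        for i, smi in enumerate(smiles):
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise ValueError(f"invalid SMILES at index {i}: {smi!r}")
            fp = gen.GetFingerprint(mol)
            rows[i, list(fp.GetOnBits())] = 1
        return pd.DataFrame(rows, columns=self.columns)

    def to_config(self) -> dict:
        return {"type": "morgan", "radius": self.radius, "n_bits": self.n_bits,
                "name": self.name}


class TabularDescriptors(DescriptorSet):
    """Serve externally supplied per-molecule values verbatim.

    The table is keyed by molecule identifier or SMILES; rows of the
    dataset without a matching key get NaN values (counted in
    ``self.n_unmatched`` after a transform) which are median-imputed
    during dataset preparation.
    """

    def __init__(self, table: pd.DataFrame, key_column: str, name: str = "Tabular"):
        if table[key_column].duplicated().any():
            dups = table[key_column][table[key_column].duplicated()].tolist()
            raise ValueError(f"duplicate keys in descriptor table: {dups}")
        non_key = [c for c in table.columns if c != key_column]
        bad = [c for c in non_key
               if not pd.api.types.is_numeric_dtype(table[c])]
        if bad:
            raise ValueError(f"non-numeric descriptor columns: {bad}")
        self.table = table.set_index(key_column)[non_key]
        self.key_column = key_column
        self.name = name
        self.n_unmatched = 0

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.table.columns)

    def transform_keys(self, keys: Sequence[str]) -> pd.DataFrame:
        out = self.table.reindex(list(keys))
        self.n_unmatched = int(out.isna().all(axis=1).sum())
        if len(out) and self.n_unmatched == len(out):
            raise ValueError("no descriptor-table key matched any dataset row")
        out.columns = self.columns
        return out.reset_index(drop=True)

    def transform_smiles(self, smiles: Sequence[str]) -> pd.DataFrame:
        return self.transform_keys(smiles)

    def to_config(self) -> dict:
        return {"type": "tabular", "name": self.name,
                "key_column": self.key_column,
                "table": {"index": self.table.index.tolist(),
                          "columns": self.table.columns.tolist(),
                          "data": self.table.to_numpy().tolist()}}


class PredictorDescriptor(DescriptorSet):
    """Use a fitted model's predictions as descriptors (stacked modelling).

    Width equals the number of model outputs: one column per regression
    task, one per class probability for classifiers.
    """

    def __init__(self, model, name: str | None = None):
        if not model.is_fitted:
            raise ValueError(f"model {model.name!r} is not fitted")
        self.model = model
        self.name = name or f"Predictor_{model.name}"

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.model.output_columns)

    def transform_smiles(self, smiles: Sequence[str]) -> pd.DataFrame:
        preds = self.model.predict_from_smiles(smiles)
        out = preds[self.model.output_columns].copy()
        out.columns = self.columns
        return out.reset_index(drop=True)

    def to_config(self) -> dict:
        return {"type": "predictor", "name": self.name}


# ---------------------------------------------------------------------------
# Protein descriptors

#: Five principal-property scales per amino acid (Sandberg et al. 1998).
#: Columns z1..z5 capture lipophilicity, steric bulk/polarizability,
#: polarity, and two electronic-property components.
Z_SCALES: dict[str, tuple[float, float, float, float, float]] = {
    "A": (0.24, -2.32, 0.60, -0.14, 1.30),
    "R": (3.52, 2.50, -3.50, 1.99, -0.17),
    "N": (3.05, 1.62, 1.04, -1.15, 1.61),
    "D": (3.98, 0.93, 1.93, -2.46, 0.75),
    "C": (0.84, -1.67, 3.71, 0.18, -2.65),
    "Q": (1.75, 0.50, -1.44, -1.34, 0.66),
    "E": (3.11, 0.26, -0.11, -3.04, -0.25),
    "G": (2.05, -4.06, 0.36, -0.82, -0.38),
    "H": (2.47, 1.95, 0.26, 3.90, 0.09),
    "I": (-3.89, -1.73, -1.71, -0.84, 0.26),
    "L": (-4.28, -1.30, -1.49, -0.72, 0.84),
    "K": (2.29, 0.89, -2.49, 1.49, 0.31),
    "M": (-2.85, -0.22, 0.47, 1.94, -0.98),
    "F": (-4.22, 1.94, 1.06, 0.54, -0.62),
    "P": (-1.66, 0.27, 1.84, 0.70, 2.00),
    "S": (2.39, -1.07, 1.15, -1.39, 0.67),
    "T": (0.75, -2.18, -1.12, -1.46, -0.40),
    "W": (-4.36, 3.94, 0.59, 3.44, -1.59),
    "Y": (-2.54, 2.44, 0.43, 0.04, -1.47),
    "V": (-2.59, -2.64, -1.54, -0.85, -0.02),
}

GAP = "-"


def pad_alignment(sequences: Mapping[str, str]) -> dict[str, str]:
    """Default alignment hook: pad every sequence to the maximum length
    with trailing gap characters. A real MSA callable with the same
    signature can be injected instead."""
    if not sequences:
        return {}
    length = max(len(s) for s in sequences.values())
    return {k: s + GAP * (length - len(s)) for k, s in sequences.items()}


class ProteinDescriptorSet(DescriptorSet):
    """Base for featurizers mapping protein sequences to vectors."""

    needs_alignment: bool = False
    alignment_hook: Callable[[Mapping[str, str]], Mapping[str, str]] | None = None

    def transform_smiles(self, smiles):  # pragma: no cover - proteins only
        raise TypeError(f"{self.name} featurizes protein sequences, not SMILES")

    @abstractmethod
    def transform_sequences(self, sequences: Mapping[str, str]) -> pd.DataFrame:
        """Featurize sequences; returns a frame indexed by protein id."""


class ZScales(ProteinDescriptorSet):
    """Z-scale physicochemical descriptors of protein sequences.

    Each residue maps to its 3- or 5-dimensional z-scale vector; gaps
    map to the zero vector. ``mode="mean"`` averages over non-gap
    positions (invariant to trailing gaps); ``mode="per_position"``
    concatenates per-residue vectors and requires all sequences to share
    one aligned length (the default hook pads with trailing gaps).
    """

    def __init__(self, n_scales: int = 5, mode: str = "mean",
                 alignment_hook: Callable | None = None, name: str | None = None):
        if n_scales not in (3, 5):
            raise ValueError("n_scales must be 3 or 5")
        if mode not in ("mean", "per_position"):
            raise ValueError("mode must be 'mean' or 'per_position'")
        self.n_scales = n_scales
        self.mode = mode
        self.needs_alignment = mode == "per_position"
        self.alignment_hook = alignment_hook or (
            pad_alignment if self.needs_alignment else None)
        self.name = name or f"ZScales{n_scales}_{mode}"
        self._aligned_length: int | None = None

    @property
    def descriptor_names(self) -> list[str]:
        if self.mode == "mean":
            return [f"z{i + 1}" for i in range(self.n_scales)]
        if self._aligned_length is None:
            raise RuntimeError("per_position width known only after transform")
        return [f"p{p}_z{i + 1}" for p in range(self._aligned_length)
                for i in range(self.n_scales)]

    def _residue_vector(self, seq_id: str, seq: str) -> np.ndarray:
        out = np.zeros((len(seq), self.n_scales))
        for pos, aa in enumerate(seq):
            if aa == GAP:
                continue
            if aa not in Z_SCALES:
                raise ValueError(
                    f"unknown residue {aa!r} at position {pos} of {seq_id!r}")
            out[pos] = Z_SCALES[aa][: self.n_scales]
        return out

    def transform_sequences(self, sequences: Mapping[str, str]) -> pd.DataFrame:
        seqs = dict(sequences)
        if self.mode == "per_position":
            lengths = {len(s) for s in seqs.values()}
            if len(lengths) > 1:
                if self.alignment_hook is None:
                    raise ValueError(
                        "per_position mode requires equal-length sequences "
                        "or an alignment hook")
                seqs = dict(self.alignment_hook(seqs))
            self._aligned_length = len(next(iter(seqs.values()))) if seqs else 0
        rows = {}
        for pid, seq in seqs.items():
            vec = self._residue_vector(pid, seq)
            if self.mode == "mean":
                mask = np.array([aa != GAP for aa in seq])
                rows[pid] = vec[mask].mean(axis=0) if mask.any() else vec.sum(axis=0)
            else:
                rows[pid] = vec.ravel()
        return pd.DataFrame.from_dict(rows, orient="index", columns=self.columns)

    def to_config(self) -> dict:
        return {"type": "zscales", "n_scales": self.n_scales, "mode": self.mode,
                "name": self.name}


def descriptor_from_config(cfg: dict) -> DescriptorSet:
    """Rebuild a descriptor set from its JSON configuration."""
    kind = cfg["type"]
    if kind == "morgan":
        return MorganFingerprint(cfg["radius"], cfg["n_bits"], name=cfg["name"])
    if kind == "zscales":
        return ZScales(cfg["n_scales"], cfg["mode"], name=cfg["name"])
    if kind == "tabular":
        t = cfg["table"]
        frame = pd.DataFrame(t["data"], columns=t["columns"])
        frame.insert(0, cfg["key_column"], t["index"])
        return TabularDescriptors(frame, cfg["key_column"], name=cfg["name"])
    raise ValueError(f"unknown descriptor type {kind!r}")


DESCRIPTOR_REGISTRY: dict[str, Callable[[], DescriptorSet]] = {
    "morgan": MorganFingerprint,
    "zscales": ZScales,
}
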