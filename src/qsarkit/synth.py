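"""Synthetic molecule, property and protein-family generation.

Every module of the package is testable without external downloads: the
generator enumerates valid molecules from a handful of distinct ring
scaffolds decorated combinatorially with acyclic substituents, so each
structural series shares a Bemis–Murcko scaffold and series are
separable by fingerprint similarity. Regression targets are built as a
known linear function of fingerprint bits plus a per-series offset
(and, for compound–protein pairs, a per-protein offset) with Gaussian
noise, and the ground-truth components are returned so recovery can be
tested. Generation is a pure function of the spec: identical specs give
identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .data import PCMDataset, QSARDataset
from .tasks import TargetProperty, TargetTask

#: Ring-system templates with two substitution slots; each defines one
#: structural series (a distinct Bemis–Murcko scaffold).
SCAFFOLD_TEMPLATES = [
    "c1cc({})ccc1-c1ccccc1",            # biphenyl
    "O=C(Nc1ccccc1)c1ccc({})cc1",       # benzanilide
    "c1cc({})ccc1Oc1ccccc1",            # diphenyl ether
    "O=C(c1ccc({})cc1)N1CCCCC1",        # phenyl piperidinyl ketone
    "c1cc({})ccc1-c1ncccn1",            # phenyl-pyrimidine
    "c1cc({})ccc1Cc1ccccc1",            # diphenylmethane
    "O=S(=O)(c1ccccc1)Nc1ccc({})cc1",   # sulfonanilide
    "c1cc({})ccc1-c1cccs1",             # phenyl-thiophene
]

#: Acyclic substituents (never alter the ring scaffold). One substitution
#: point per series keeps the analogs within a series close in
#: fingerprint space, as in a congeneric medicinal-chemistry series.
SUBSTITUENTS = [
    "C", "CC", "CCC", "CCCC", "CCCCC", "O", "OC", "OCC", "N", "NC", "NCC",
    "Cl", "F", "Br", "I", "C(C)C", "CO", "CCO", "CN", "CCN", "C(F)(F)F",
    "CCl", "COC", "CC(C)C",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class FixtureSpec:
    """Conditions of the synthetic study fixtures.

    ``series_effect`` spaces per-series bioactivity offsets (log units),
    making structural clusters informative — the regime in which group
    aware splits are genuinely harder than random splits.
    ``protein_effect`` does the same across protein targets for PCM
    fixtures.
    """

    n_molecules: int = 60
    n_series: int = 3
    n_proteins: int = 4
    noise_sd: float = 0.3
    n_signal_bits: int = 10
    weight_sd: float = 1.0
    series_effect: float = 2.0
    protein_effect: float = 2.0
    seed: int = 42
    year_range: tuple[int, int] = (2005, 2020)
    mutation_rate: float = 0.1
    protein_length: int = 60


def make_molecules(spec: FixtureSpec) -> tuple[list[str], np.ndarray]:
    """Enumerate valid SMILES in ``n_series`` scaffold series.

    Returns the SMILES list and an integer series label per molecule.
    """
    if spec.n_series < 1 or spec.n_series > len(SCAFFOLD_TEMPLATES):
        raise ValueError(
            f"n_series must be in [1, {len(SCAFFOLD_TEMPLATES)}]")
    per_series = [spec.n_molecules // spec.n_series] * spec.n_series
    for i in range(spec.n_molecules % spec.n_series):
        per_series[i] += 1
    capacity = len(SUBSTITUENTS)
    if max(per_series) > capacity:
        raise ValueError(
            f"requested {max(per_series)} molecules per series exceeds "
            f"enumerable space {capacity}")
    rng = np.random.default_rng(spec.seed)
    smiles, labels = [], []
    for si in range(spec.n_series):
        template = SCAFFOLD_TEMPLATES[si]
        for p in rng.permutation(capacity)[: per_series[si]]:
            smi = template.format(SUBSTITUENTS[int(p)])
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise RuntimeError(f"generated invalid SMILES: {smi!r}")
            smiles.append(Chem.MolToSmiles(mol))
            labels.append(si)
    return smiles, np.asarray(labels)


def _fingerprints(smiles: list[str], radius: int = 3,
                  n_bits: int = 2048) -> np.ndarray:
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius,
                                                    fpSize=n_bits)
    out = np.zeros((len(smiles), n_bits), dtype=np.int8)
    for i, smi in enumerate(smiles):
        fp = gen.GetFingerprint(Chem.MolFromSmiles(smi))
        out[i, list(fp.GetOnBits())] = 1
    return out


def make_regression_target(smiles: list[str], series: np.ndarray,
                           spec: FixtureSpec,
                           protein_index: np.ndarray | None = None
                           ) -> tuple[np.ndarray, dict]:
    """Synthesize y = w · (fingerprint bits) + series offset
    (+ protein offset) + N(0, noise_sd).

    The returned components dict reconstructs y exactly at noise_sd=0.
    """
    rng = np.random.default_rng(spec.seed + 1)
    fps = _fingerprints(smiles)
    variances = fps.var(axis=0)
    order = np.lexsort((np.arange(fps.shape[1]), -variances))
    signal_bits = np.sort(order[: spec.n_signal_bits])
    weights = rng.normal(0.0, spec.weight_sd, len(signal_bits))
    linear = fps[:, signal_bits] @ weights
    centers = (np.arange(int(series.max()) + 1)
               - series.max() / 2) * spec.series_effect
    series_part = centers[series]
    protein_part = np.zeros(len(smiles))
    protein_offsets = None
    if protein_index is not None:
        protein_offsets = (np.arange(spec.n_proteins)
                           - (spec.n_proteins - 1) / 2) * spec.protein_effect
        protein_part = protein_offsets[protein_index]
    noise = rng.normal(0.0, spec.noise_sd, len(smiles)) if spec.noise_sd \
        else np.zeros(len(smiles))
    y = 6.5 + linear + series_part + protein_part + noise
    components = {"signal_bits": signal_bits, "weights": weights,
                  "linear": linear, "series_offsets": centers,
                  "series_part": series_part, "protein_part": protein_part,
                  "protein_offsets": protein_offsets, "noise": noise,
                  "intercept": 6.5}
    return y, components


def make_proteins(spec: FixtureSpec) -> dict[str, str]:
    """Equal-length sequences mutated from a common seeded ancestor;
    pairwise identity decreases with the mutation rate."""
    if spec.n_proteins < 2:
        raise ValueError("n_proteins must be >= 2")
    rng = np.random.default_rng(spec.seed + 2)
    aa = np.array(list(AMINO_ACIDS))
    ancestor = rng.integers(0, len(aa), spec.protein_length)
    out = {}
    for p in range(spec.n_proteins):
        seq = ancestor.copy()
        hit = rng.random(spec.protein_length) < spec.mutation_rate
        seq[hit] = rng.integers(0, len(aa), int(hit.sum()))
        out[f"P{p + 1}"] = "".join(aa[seq])
    return out


def make_dataframe(spec: FixtureSpec) -> tuple[pd.DataFrame, dict]:
    """Single-target regression fixture table with year annotations."""
    smiles, series = make_molecules(spec)
    y, components = make_regression_target(smiles, series, spec)
    rng = np.random.default_rng(spec.seed + 3)
    years = rng.integers(spec.year_range[0], spec.year_range[1] + 1,
                         len(smiles))
    df = pd.DataFrame({"smiles": smiles, "pchembl": y, "series": series,
                       "year": years})
    return df, components


def make_dataset(spec: FixtureSpec, name: str = "synthetic") -> QSARDataset:
    df, _ = make_dataframe(spec)
    return QSARDataset.from_table(
        df, "smiles",
        [TargetProperty("pchembl", TargetTask.REGRESSION)],
        name=name, random_state=spec.seed)


def make_pcm_dataframe(spec: FixtureSpec
                       ) -> tuple[pd.DataFrame, dict[str, str], dict]:
    """Full molecule × protein cross of pairs with per-protein offsets."""
    smiles, series = make_molecules(spec)
    sequences = make_proteins(spec)
    protein_ids = list(sequences)
    pair_smiles, pair_series, pair_protein = [], [], []
    for i, smi in enumerate(smiles):
        for p in range(spec.n_proteins):
            pair_smiles.append(smi)
            pair_series.append(series[i])
            pair_protein.append(p)
    pair_series = np.asarray(pair_series)
    pair_protein = np.asarray(pair_protein)
    y, components = make_regression_target(pair_smiles, pair_series, spec,
                                           protein_index=pair_protein)
    rng = np.random.default_rng(spec.seed + 4)
    years = rng.integers(spec.year_range[0], spec.year_range[1] + 1,
                         len(pair_smiles))
    df = pd.DataFrame({"smiles": pair_smiles,
                       "protein_id": [protein_ids[p] for p in pair_protein],
                       "pchembl": y, "series": pair_series, "year": years})
    return df, sequences, components


def make_pcm_dataset(spec: FixtureSpec,
                     name: str = "synthetic_pcm") -> PCMDataset:
    df, sequences, _ = make_pcm_dataframe(spec)
    return PCMDataset.from_table(
        df, "smiles",
        [TargetProperty("pchembl", TargetTask.REGRESSION)],
        protein_id_column="protein_id", protein_sequences=sequences,
        name=name, random_state=spec.seed)


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid, seq in sequences.items():
            fh.write(f">{pid}\n{seq}\n")


def read_fasta(path) -> dict[str, str]:
    out: dict[str, str] = {}
    current = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                current = line[1:].split()[0]
                out[current] = ""
            elif current is not None:
                out[current] += line
    return out
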