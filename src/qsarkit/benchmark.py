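"""Declarative, replicated benchmarking of component combinations.

A :class:`BenchmarkSettings` object defines a Cartesian grid of data
sources × descriptor configurations × preparation variants × models,
each repeated over ``n_replicas`` replicas with seeds derived from the
base seed. Results accumulate in a tidy table — one row per (replica,
source, descriptors, preparation, model, target, metric) — written
incrementally so an interrupted run resumes by regenerating only the
missing rows.
"""

from __future__ import annotations

import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .assessment import METRICS, TestSetAssessor
from .data import DataSource
from .descriptors import descriptor_from_config
from .persistence import canonical_json, derive_seed
from .splits import SPLIT_REGISTRY
from .tasks import TargetProperty

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["replica_id", "seed", "data_source", "descriptors",
                  "prep", "model", "target", "metric", "score", "error"]


def build_splitter(cfg: dict, seed: int):
    """Instantiate a splitter from a JSON-style config, injecting the seed."""
    cfg = dict(cfg)
    kind = cfg.pop("type")
    cfg.pop("name", None)
    klass = SPLIT_REGISTRY[kind]
    try:
        return klass(seed=seed, **cfg)
    except TypeError:
        return klass(**cfg)


@dataclass
class BenchmarkSettings:
    """Declarative grid of benchmark components.

    ``descriptors`` is a list of (label, [descriptor configs]);
    ``prep_variants`` a list of split configs with a ``name`` key;
    ``models`` a list of unfitted model templates cloned per cell.
    """

    name: str
    n_replicas: int
    base_seed: int
    data_sources: Sequence[DataSource]
    descriptors: Sequence[tuple[str, list[dict]]]
    prep_variants: Sequence[dict]
    models: Sequence
    target_properties: Sequence[TargetProperty]
    metrics: Sequence[str] = ("r2",)
    test_fraction: float = 0.2
    prepare_kwargs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")

    def to_config(self) -> dict:
        return {
            "name": self.name, "n_replicas": self.n_replicas,
            "base_seed": self.base_seed,
            "data_sources": [s.name for s in self.data_sources],
            "descriptors": [{"label": lab, "sets": cfgs}
                            for lab, cfgs in self.descriptors],
            "prep_variants": list(self.prep_variants),
            "models": [m.name for m in self.models],
            "targets": [tp.to_config() for tp in self.target_properties],
            "metrics": list(self.metrics),
        }

    def grid(self):
        for source in self.data_sources:
            for desc_label, desc_cfgs in self.descriptors:
                for prep in self.prep_variants:
                    for model in self.models:
                        for replica in range(self.n_replicas):
                            yield (source, desc_label, desc_cfgs, prep,
                                   model, replica)


def _cell_label(source, desc_label, prep, model, replica) -> str:
    return (f"{source.name}|{desc_label}|{prep['name']}|{model.name}"
            f"|replica_{replica}")


def run_benchmark(settings: BenchmarkSettings,
                  out_dir: str | Path) -> pd.DataFrame:
    """Execute every grid cell × replica, appending rows incrementally.

    A crashed or partial run resumes: cells already present in
    ``results.tsv`` are skipped and the final table is identical to a
    fresh run. Component failures are recorded as rows with an error
    string and a missing score; the run continues.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "settings.json").write_text(
        canonical_json(settings.to_config()) + "\n", encoding="utf-8")
    results_path = out_dir / "results.tsv"
    done: set[tuple] = set()
    if results_path.exists():
        prev = pd.read_csv(results_path, sep="\t")
        done = {tuple(r) for r in prev[
            ["replica_id", "data_source", "descriptors", "prep",
             "model"]].itertuples(index=False)}
    header_needed = not results_path.exists()
    for source, desc_label, desc_cfgs, prep, model, replica in settings.grid():
        key = (replica, source.name, desc_label, prep["name"], model.name)
        if key in done:
            continue
        label = _cell_label(source, desc_label, prep, model, replica)
        seed = derive_seed(settings.base_seed, label)
        rows = []
        try:
            rows = _run_cell(settings, source, desc_cfgs, prep, model,
                             replica, seed)
        except Exception as exc:  # record failure, keep running
            logger.error("cell %s failed: %s", label, exc)
            logger.debug(traceback.format_exc())
            rows = [{"replica_id": replica, "seed": seed,
                     "data_source": source.name, "descriptors": desc_label,
                     "prep": prep["name"], "model": model.name,
                     "target": tp.name, "metric": m, "score": np.nan,
                     "error": f"{type(exc).__name__}: {exc}"}
                    for tp in settings.target_properties
                    for m in settings.metrics]
        for row in rows:
            row.setdefault("descriptors", desc_label)
        frame = pd.DataFrame(rows, columns=RESULT_COLUMNS)
        frame.to_csv(results_path, sep="\t", index=False, mode="a",
                     header=header_needed, na_rep="NA")
        header_needed = False
    out = pd.read_csv(results_path, sep="\t")
    return out.sort_values(
        ["data_source", "descriptors", "prep", "model", "replica_id",
         "target", "metric"]).reset_index(drop=True)


def _run_cell(settings, source, desc_cfgs, prep, model, replica, seed):
    # dataset seed depends on (source, replica) only, so replicas are
    # paired across preparation variants and models
    data_seed = derive_seed(settings.base_seed,
                            f"{source.name}|replica_{replica}")
    dataset = source.get_dataset(list(settings.target_properties),
                                 random_state=data_seed)
    dsets = [descriptor_from_config(c) for c in desc_cfgs]
    split_cfg = {"test_fraction": settings.test_fraction, **prep}
    split_cfg.pop("name", None)
    splitter = build_splitter(split_cfg, seed)
    dataset.prepare(descriptor_sets=dsets, splitter=splitter,
                    **settings.prepare_kwargs)
    fitted = model.clone()
    fitted.random_state = seed
    fitted.fit(dataset)
    rows = []
    for metric_name in settings.metrics:
        assessor = TestSetAssessor(metric=METRICS[metric_name])
        result = assessor(fitted, dataset)
        per_task = result.per_task.iloc[0]
        for tp in settings.target_properties:
            rows.append({"replica_id": replica, "seed": seed,
                         "data_source": source.name,
                         "prep": prep["name"], "model": model.name,
                         "target": tp.name, "metric": metric_name,
                         "score": float(per_task[tp.name]), "error": ""})
    return rows


def compare_split_difficulty(results: pd.DataFrame, split_a: str,
                             split_b: str, metric: str = "r2"
                             ) -> dict[str, pd.DataFrame]:
    """Per-model score summaries and paired per-replica deltas for two
    preparation variants (no hypothesis test — descriptive only)."""
    present = set(results["prep"])
    for s in (split_a, split_b):
        if s not in present:
            raise KeyError(f"split {s!r} not present in results")
    sub = results[(results["metric"] == metric) &
                  (results["prep"].isin([split_a, split_b]))]
    summary = (sub.groupby(["model", "target", "prep"])["score"]
               .agg(["mean", "std", "count"]).reset_index())
    a = sub[sub["prep"] == split_a]
    b = sub[sub["prep"] == split_b]
    keys = ["model", "target", "replica_id", "data_source", "descriptors"]
    merged = a.merge(b, on=keys, suffixes=("_a", "_b"))
    merged["delta"] = merged["score_a"] - merged["score_b"]
    deltas = merged[keys + ["score_a", "score_b", "delta"]]
    return {"summary": summary, "deltas": deltas}
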