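"""Target properties and modelling task semantics.

A dataset declares one or more target properties, each tied to a
:class:`TargetTask` (regression, binary or multi-class classification).
The overall :class:`ModelTask` of a model is derived deterministically
from the list of declared targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence


class TargetTask(Enum):
    """Per-property modelling task."""

    REGRESSION = "REGRESSION"
    SINGLECLASS = "SINGLECLASS"
    MULTICLASS = "MULTICLASS"

    @property
    def is_classification(self) -> bool:
        return self is not TargetTask.REGRESSION


class ModelTask(Enum):
    """Overall task of a model, derived from its target properties."""

    REGRESSION = "REGRESSION"
    SINGLECLASS = "SINGLECLASS"
    MULTICLASS = "MULTICLASS"
    MULTITASK_REGRESSION = "MULTITASK_REGRESSION"
    MULTITASK_SINGLECLASS = "MULTITASK_SINGLECLASS"
    MULTITASK_MULTICLASS = "MULTITASK_MULTICLASS"
    MULTITASK_MIXED = "MULTITASK_MIXED"

    @property
    def is_multitask(self) -> bool:
        return self.value.startswith("MULTITASK")

    @property
    def is_regression(self) -> bool:
        return self in (ModelTask.REGRESSION, ModelTask.MULTITASK_REGRESSION)

    @property
    def is_classification(self) -> bool:
        return not self.is_regression and self is not ModelTask.MULTITASK_MIXED


@dataclass
class TargetProperty:
    """A named target column together with its modelling task.

    Parameters
    ----------
    name:
        Column identifier in the owning dataset.
    task:
        The per-property :class:`TargetTask`.
    thresholds:
        Optional ascending cut points used to discretize a continuous
        column for classification. ``SINGLECLASS`` requires exactly one
        threshold (or an already-binary column); ``MULTICLASS`` requires
        at least two thresholds, producing at least three classes.
    """

    name: str
    task: TargetTask
    thresholds: list[float] | None = field(default=None)

    def __post_init__(self) -> None:
        if isinstance(self.task, str):
            self.task = TargetTask[self.task]
        if self.thresholds is not None:
            th = [float(t) for t in self.thresholds]
            if sorted(th) != th or len(set(th)) != len(th):
                raise ValueError(
                    f"thresholds for {self.name!r} must be strictly ascending, got {th}"
                )
            self.thresholds = th
        if self.task is TargetTask.MULTICLASS:
            if self.thresholds is None or len(self.thresholds) < 2:
                raise ValueError(
                    "MULTICLASS requires >= 2 thresholds (>= 3 classes)"
                )
        if self.task is TargetTask.SINGLECLASS and self.thresholds is not None:
            if len(self.thresholds) != 1:
                raise ValueError("SINGLECLASS requires exactly one threshold")

    @property
    def n_classes(self) -> int | None:
        if self.task is TargetTask.REGRESSION:
            return None
        if self.thresholds is None:
            return 2
        return len(self.thresholds) + 1

    @property
    def label_column(self) -> str:
        """Column holding the modelled value (discretized for classification)."""
        if self.task.is_classification and self.thresholds is not None:
            return f"{self.name}_class"
        return self.name

    def to_config(self) -> dict:
        return {
            "name": self.name,
            "task": self.task.value,
            "thresholds": self.thresholds,
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "TargetProperty":
        return cls(cfg["name"], TargetTask[cfg["task"]], cfg.get("thresholds"))


def infer_task(target_properties: Sequence[TargetProperty]) -> ModelTask:
    """Derive the overall :class:`ModelTask` from the declared targets.

    A single property maps to its own task; two or more properties of an
    identical task map to the corresponding ``MULTITASK_*`` variant, and
    mixed per-property tasks map to ``MULTITASK_MIXED``.
    """
    if not target_properties:
        raise ValueError("no target properties defined")
    tasks = {tp.task for tp in target_properties}
    if len(target_properties) == 1:
        return ModelTask[target_properties[0].task.value]
    if len(tasks) == 1:
        return ModelTask[f"MULTITASK_{tasks.pop().value}"]
    return ModelTask.MULTITASK_MIXED
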