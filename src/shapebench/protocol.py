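"""The twelve learning/transfer tasks and the 20-epoch training protocol.

Each experiment trains a fresh binary classifier on one category pair (the
learning pair, split 85/15 into train/validation) and, after every epoch,
evaluates it both on the held-out validation images (learning accuracy)
and on the full set of a disjoint category pair it never trains on (the
transfer pair).  The class mapping follows column correspondence: class 0
of the transfer pair is scored as class 0 of the learning pair.

The twelve tasks fall into six groups: A and B probe local features
(parallelism and angles among quadrilaterals), C and D probe the presence
of a hole (regular and irregular shapes), E probes connectivity, and F
probes the inside/outside relationship.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .dataset import TRAIN_FRACTION, make_splits
from .models import Classifier, evaluate

__all__ = [
    "DEFAULT_EPOCHS",
    "ExperimentDef",
    "RunLog",
    "registry",
    "get_experiment",
    "run_experiment",
    "run_learning_task",
    "write_log",
    "read_log",
]

DEFAULT_EPOCHS = 20


@dataclass(frozen=True)
class ExperimentDef:
    """One learning/transfer task: two category pairs and an epoch budget."""

    id: str
    group: str
    learning_pair: tuple[str, str]  # (class 0, class 1)
    transfer_pair: tuple[str, str]  # (class 0, class 1)
    epochs: int = DEFAULT_EPOCHS

    @property
    def categories(self) -> tuple[str, ...]:
        return (*self.learning_pair, *self.transfer_pair)


_EXPERIMENTS: tuple[ExperimentDef, ...] = (
    ExperimentDef("A.1", "A", ("square", "trapezoid"), ("rectangle", "trapezoid")),
    ExperimentDef("A.2", "A", ("parallelogram", "trapezoid"), ("rectangle", "parallelogram")),
    ExperimentDef("A.3", "A", ("square", "trapezoid"), ("rectangle", "trapezoid")),
    ExperimentDef("B.1", "B", ("square", "parallelogram"), ("trapezoid", "parallelogram")),
    ExperimentDef("B.2", "B", ("square", "parallelogram"), ("rectangle", "parallelogram")),
    ExperimentDef("B.3", "B", ("square", "parallelogram"), ("rectangle", "trapezoid")),
    ExperimentDef("C.1", "C", ("disk", "ring"), ("triangle-solid", "triangle-ring")),
    ExperimentDef("C.2", "C", ("disk", "ring"), ("square-solid", "square-ring")),
    ExperimentDef(
        "D.1", "D",
        ("irregular-disk", "irregular-ring"),
        ("irregular-triangle-solid", "irregular-triangle-ring"),
    ),
    ExperimentDef(
        "D.2", "D",
        ("irregular-disk", "irregular-ring"),
        ("irregular-square", "irregular-square-ring"),
    ),
    ExperimentDef(
        "E", "E",
        ("isosceles-triangle-outline", "disassembled-isosceles-triangle"),
        ("irregular-triangle-outline", "disassembled-irregular-triangle"),
    ),
    ExperimentDef(
        "F", "F",
        ("dot-inside-circle", "dot-outside-circle"),
        ("dot-inside-square", "dot-outside-square"),
    ),
)


def registry() -> tuple[ExperimentDef, ...]:
    """All twelve experiment definitions, in table order."""
    return _EXPERIMENTS


def get_experiment(exp_id: str) -> ExperimentDef:
    for e in _EXPERIMENTS:
        if e.id == exp_id:
            return e
    raise ValueError(f"unknown experiment id: {exp_id!r}")


@dataclass
class RunLog:
    """Per-epoch learning and transfer accuracies for one run."""

    experiment_id: str
    model_name: str
    seed: int
    learning: list[float] = field(default_factory=list)  # percent, epoch 1..K
    transfer: list[float] = field(default_factory=list)
    valid: bool = True

    def __post_init__(self) -> None:
        if len(self.learning) != len(self.transfer):
            raise ValueError("learning and transfer curves must align")

    @property
    def epochs(self) -> int:
        return len(self.learning)


def run_learning_task(
    model: Classifier,
    train_images: np.ndarray,
    train_labels: np.ndarray,
    eval_sets: Mapping[str, tuple[np.ndarray, np.ndarray]],
    epochs: int,
    train_seed: int,
) -> dict[str, list[float]]:
    """Train ``epochs`` passes, evaluating every named set after each epoch.

    Batch order is reshuffled each epoch from ``train_seed``.  Returns
    ``{set name: [accuracy at epoch 1, ..., accuracy at epoch K]}`` —
    accuracies are measured after each full training epoch, never at
    initialization.
    """
    rng = np.random.default_rng(train_seed)
    curves: dict[str, list[float]] = {name: [] for name in eval_sets}
    for _ in range(epochs):
        model.train_one_epoch(train_images, train_labels, rng)
        for name, (x, y) in eval_sets.items():
            curves[name].append(evaluate(model, x, y))
    return curves


def run_experiment(
    exp: ExperimentDef,
    model_factory: Callable[[int], Classifier],
    images: Mapping[str, np.ndarray],
    split_seed: int = 0,
    train_seed: int = 0,
    *,
    model_name: str = "reference",
    epochs: int | None = None,
    train_frac: float = TRAIN_FRACTION,
) -> RunLog:
    """Run one full learning/transfer experiment.

    ``images`` maps each of the experiment's four categories to its stack
    of model-ready images.  The learning pair is split per category into
    train/validation; the transfer pair is evaluated whole (both
    categories, all images) after every epoch and never enters a training
    batch.
    """
    missing = [c for c in exp.categories if c not in images]
    if missing:
        raise ValueError(f"images missing for categories: {missing}")
    epochs = epochs or exp.epochs

    manifest = pd.DataFrame(
        [
            {"path": f"{cat}/{i}", "category": cat, "split": ""}
            for cat in exp.learning_pair
            for i in range(len(images[cat]))
        ]
    )
    tagged = make_splits(manifest, exp.learning_pair, train_frac, split_seed)

    def collect(split: str) -> tuple[np.ndarray, np.ndarray]:
        xs, ys = [], []
        for cls, cat in enumerate(exp.learning_pair):
            sel = tagged[(tagged["category"] == cat) & (tagged["split"] == split)]
            idx = [int(p.rsplit("/", 1)[1]) for p in sel["path"]]
            xs.append(images[cat][idx])
            ys.append(np.full(len(idx), cls, dtype=np.int64))
        return np.concatenate(xs), np.concatenate(ys)

    x_train, y_train = collect("train")
    x_val, y_val = collect("validation")
    x_tr = np.concatenate([images[c] for c in exp.transfer_pair])
    y_tr = np.concatenate(
        [
            np.full(len(images[c]), cls, dtype=np.int64)
            for cls, c in enumerate(exp.transfer_pair)
        ]
    )

    model = model_factory(train_seed)
    try:
        curves = run_learning_task(
            model,
            x_train,
            y_train,
            {"learning": (x_val, y_val), "transfer": (x_tr, y_tr)},
            epochs,
            train_seed,
        )
    except Exception:
        return RunLog(exp.id, model_name, train_seed, [], [], valid=False)
    return RunLog(
        exp.id, model_name, train_seed, curves["learning"], curves["transfer"]
    )


# ---------------------------------------------------------------------------
# log persistence
# ---------------------------------------------------------------------------


def write_log(log: RunLog, path: str | Path) -> None:
    """CSV with commented metadata header and epoch/accuracy columns."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# experiment={log.experiment_id}\n")
        fh.write(f"# model={log.model_name}\n")
        fh.write(f"# seed={log.seed}\n")
        fh.write("epoch,learning_acc,transfer_acc\n")
        for e, (la, ta) in enumerate(zip(log.learning, log.transfer), start=1):
            fh.write(f"{e},{la:.6f},{ta:.6f}\n")


def read_log(path: str | Path) -> RunLog:
    """Parse a run-log CSV, validating the epoch sequence.

    Externally produced CSVs with columns (epoch, learning_acc,
    transfer_acc) and no metadata header are accepted; metadata defaults
    are then blank.
    """
    path = Path(path)
    meta = {"experiment": "", "model": "", "seed": "0"}
    rows: list[tuple[int, float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                meta[key.strip()] = value.strip()
                continue
            if line.lower().startswith("epoch"):
                continue
            parts = line.split(",")
            try:
                rows.append((int(parts[0]), float(parts[1]), float(parts[2])))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}") from exc
    epochs = [r[0] for r in rows]
    if epochs != list(range(1, len(rows) + 1)):
        raise ValueError(f"{path}: epochs must run consecutively from 1, got {epochs}")
    return RunLog(
        experiment_id=meta["experiment"],
        model_name=meta["model"],
        seed=int(meta["seed"] or 0),
        learning=[r[1] for r in rows],
        transfer=[r[2] for r in rows],
    )
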