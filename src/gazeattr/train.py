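"""Training loop with per-epoch checkpointing, splits, and evaluation.

After every epoch the full parameter vector and the learning rate in force
during that epoch are snapshotted; the resulting :class:`CheckpointSet` is the
replay substrate for gradient-based influence computation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import GroupShuffleSplit, train_test_split

from .metrics import MetricsReport, report_from_predictions
from .model import GazeClassifier, GBACConfig, build_model, prepare_records, slice_batch
from .nn import Adam, bce_with_logits, sigmoid
from .types import SampleRecord


@dataclass
class CheckpointSet:
    """Ordered per-epoch parameter snapshots w(i) with their learning rates."""

    checkpoints: list[tuple[np.ndarray, float]] = field(default_factory=list)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for _, eta in self.checkpoints:
            if eta <= 0:
                raise ValueError("learning rates must be positive")

    @property
    def k(self) -> int:
        return len(self.checkpoints)

    def append(self, params: np.ndarray, eta: float) -> None:
        if eta <= 0:
            raise ValueError("learning rates must be positive")
        self.checkpoints.append((np.asarray(params, dtype=np.float64).copy(), float(eta)))

    def subsample(self, every: int) -> "CheckpointSet":
        """Keep every ``every``-th checkpoint, counting from the first."""
        return CheckpointSet(self.checkpoints[::every], seed=self.seed)

    def save(self, directory) -> None:
        """One .npz per epoch plus a JSON manifest with eta_i and the seed."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {"version": 1, "seed": self.seed, "k": self.k, "etas": [], "files": []}
        for i, (w, eta) in enumerate(self.checkpoints):
            fname = f"checkpoint_{i:03d}.npz"
            np.savez_compressed(directory / fname, params=w)
            manifest["etas"].append(eta)
            manifest["files"].append(fname)
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory) -> "CheckpointSet":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        ckpts = [
            (np.load(directory / f)["params"], eta)
            for f, eta in zip(manifest["files"], manifest["etas"])
        ]
        return cls(ckpts, seed=manifest.get("seed"))


def split_dataset(
    records: Sequence[SampleRecord],
    seed: int,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    participant_disjoint: bool = False,
) -> tuple[list[SampleRecord], list[SampleRecord], list[SampleRecord]]:
    """Train/val/test split, stratified by label (default) or participant-disjoint.

    In participant-disjoint mode no (group, participant) appears in more than
    one split, which avoids leakage of a participant's idiosyncratic gaze
    style between train and test.
    """
    records = list(records)
    f_train, f_val, f_test = fractions
    if not np.isclose(f_train + f_val + f_test, 1.0):
        raise ValueError("fractions must sum to 1")
    idx = np.arange(len(records))
    labels = np.array([r.label for r in records])
    if participant_disjoint:
        groups = np.array([f"{r.scanpath.group_label}:{r.participant_index}" for r in records])
        gss = GroupShuffleSplit(n_splits=1, test_size=f_test, random_state=seed)
        trainval_idx, test_idx = next(gss.split(idx, labels, groups))
        gss2 = GroupShuffleSplit(n_splits=1, test_size=f_val / (f_train + f_val), random_state=seed + 1)
        train_idx, val_idx = next(gss2.split(trainval_idx, groups=groups[trainval_idx]))
        train_idx, val_idx = trainval_idx[train_idx], trainval_idx[val_idx]
    else:
        trainval_idx, test_idx = train_test_split(
            idx, test_size=f_test, random_state=seed, stratify=labels
        )
        train_idx, val_idx = train_test_split(
            trainval_idx,
            test_size=f_val / (f_train + f_val),
            random_state=seed + 1,
            stratify=labels[trainval_idx],
        )
    pick = lambda ii: [records[i] for i in ii]
    return pick(train_idx), pick(val_idx), pick(test_idx)


def _epoch_metrics(model: GazeClassifier, prepared: dict, batch_size: int) -> tuple[float, float]:
    logits = forward_in_batches(model, prepared, batch_size)
    loss, _ = bce_with_logits(logits, prepared["labels"])
    acc = float(np.mean((sigmoid(logits) >= 0.5) == (prepared["labels"] >= 0.5)))
    return float(loss.mean()), acc


def forward_in_batches(model: GazeClassifier, prepared: dict, batch_size: int = 64) -> np.ndarray:
    """Eval-mode logits over a prepared dataset, chunked to bound memory."""
    n = len(prepared["labels"])
    out = np.empty(n)
    for start in range(0, n, batch_size):
        idx = np.arange(start, min(start + batch_size, n))
        out[idx] = model.forward(slice_batch(prepared, idx), train=False)
    return out


def train(
    model: GazeClassifier,
    train_records: Sequence[SampleRecord] | dict,
    config: GBACConfig,
    seed: int,
    val_records: Sequence[SampleRecord] | dict | None = None,
) -> tuple[CheckpointSet, pd.DataFrame]:
    """Train with Adam/BCE for ``config.epochs`` epochs, checkpointing each one.

    Fully reproducible given (model initialization, data, seed): batch order
    and dropout masks are drawn from a generator seeded here.  A single-class
    dataset trains with a warning (the loss remains defined); an empty
    dataset raises.

    ``train_records``/``val_records`` may be raw SampleRecords or already
    prepared arrays from :func:`prepare_records`.
    """
    prepared = train_records if isinstance(train_records, dict) else prepare_records(train_records, config)
    n = len(prepared["labels"])
    if n == 0:
        raise ValueError("empty training set")
    if len(np.unique(prepared["labels"])) < 2:
        import warnings

        warnings.warn("training set contains a single class; proceeding", stacklevel=2)
    prepared_val = None
    if val_records is not None:
        prepared_val = val_records if isinstance(val_records, dict) else prepare_records(val_records, config)

    rng = np.random.default_rng(seed)
    optimizer = Adam(model.params(), lr=config.learning_rate)
    checkpoints = CheckpointSet(seed=seed)
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = slice_batch(prepared, idx)
            optimizer.zero_grad()
            logits = model.forward(batch, train=True, rng=rng)
            loss, dlogits = bce_with_logits(logits, batch["labels"])
            model.backward(dlogits / len(idx))
            optimizer.step()
        checkpoints.append(model.get_flat_params(), config.learning_rate)
        train_loss, train_acc = _epoch_metrics(model, prepared, config.batch_size)
        row = {"epoch": epoch + 1, "train_loss": train_loss, "train_accuracy": train_acc}
        if prepared_val is not None:
            row["val_loss"], row["val_accuracy"] = _epoch_metrics(model, prepared_val, config.batch_size)
        history.append(row)
    return checkpoints, pd.DataFrame(history)


def evaluate(
    model: GazeClassifier,
    records: Sequence[SampleRecord] | dict,
    config: GBACConfig | None = None,
    threshold: float = 0.5,
) -> MetricsReport:
    """Hard-label metrics on a dataset at the given probability threshold."""
    config = config or model.config
    prepared = records if isinstance(records, dict) else prepare_records(records, config)
    if len(prepared["labels"]) == 0:
        raise ValueError("empty evaluation set")
    logits = forward_in_batches(model, prepared, config.batch_size)
    return report_from_predictions(prepared["labels"], sigmoid(logits), threshold)
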