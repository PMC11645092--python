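"""Checkpoint-replay training-data attribution (TracIn).

Training is replayed through the per-epoch checkpoints w(i) with learning
rates eta_i.  For a per-sample loss l,

    self_influence(x)   = sum_i eta_i * <grad l(w(i), x), grad l(w(i), x)>
    influence(x, x')    = sum_i eta_i * <grad l(w(i), x), grad l(w(i), x')>

High self-influence flags outliers and mislabeled samples; large positive
(negative) influence on a test sample marks a proponent (opponent).

Gradients default to the final fusion layer ("last_layer"), the standard
scalable practice; "full" differentiates every parameter and is the mode the
brute-force oracle tests exercise.  The production table computations are
vectorized over samples via the closed-form last-layer gradient
(sigmoid(z) - y) * [features, 1]; the per-sample path goes through ordinary
backprop, so the two routes are independent implementations of the same sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import GazeClassifier, prepare_records, slice_batch
from .nn import bce_with_logits
from .train import CheckpointSet
from .types import SampleRecord

GRADIENT_MODES = ("last_layer", "full")


@dataclass
class InfluenceTable:
    """Self-influence scores and/or pairwise train-by-test influence."""

    gradient_mode: str
    self_scores: Optional[pd.Series] = None  # index: sample_id
    pairwise: Optional[pd.DataFrame] = None  # index: train ids, columns: test ids

    def self_to_csv(self, path) -> None:
        self.self_scores.rename("self_influence").rename_axis("sample_id").to_csv(path)

    def pairwise_to_csv(self, path) -> None:
        long = self.pairwise.rename_axis("train_id").reset_index().melt(
            id_vars="train_id", var_name="test_id", value_name="influence"
        )
        long.to_csv(path, index=False)


def _as_batch(model: GazeClassifier, sample) -> dict:
    if isinstance(sample, SampleRecord):
        return prepare_records([sample], model.config)
    return sample


def per_sample_gradient(model: GazeClassifier, sample, mode: str = "last_layer") -> np.ndarray:
    """Gradient of one sample's BCE loss at the model's current parameters.

    The model must already hold the checkpoint parameters of interest.  The
    returned vector is flattened in the order documented by
    :meth:`GazeClassifier.params` (or just final-layer W then b for
    ``last_layer``).
    """
    if mode not in GRADIENT_MODES:
        raise ValueError(f"unknown gradient mode {mode!r}")
    batch = _as_batch(model, sample)
    model.zero_grad()
    logits = model.forward(batch, train=False)
    _, dlogits = bce_with_logits(logits, batch["labels"])
    model.backward(dlogits)
    params = model.last_layer_params() if mode == "last_layer" else None
    return model.flat_grad(params)


def _last_layer_grads_batch(model: GazeClassifier, batch: dict) -> np.ndarray:
    """Closed-form per-sample last-layer gradients, shape (B, 4).

    d l / d W_final = (sigmoid(z) - y) * features, d l / d b = sigmoid(z) - y,
    flattened as [W_0, W_1, W_2, b] to match :func:`per_sample_gradient`.
    """
    logits = model.forward(batch, train=False)
    _, resid = bce_with_logits(logits, batch["labels"])
    feats = model.last_features  # (B, 3)
    return np.concatenate([resid[:, None] * feats, resid[:, None]], axis=1)


def _with_checkpoints(model: GazeClassifier, checkpoints: CheckpointSet):
    if checkpoints.k < 1:
        raise ValueError("empty checkpoint set")
    return model.get_flat_params()


def self_influence(checkpoints: CheckpointSet, model: GazeClassifier, sample, mode: str = "last_layer") -> float:
    """Sum over checkpoints of eta_i * ||grad l||^2 for one sample (>= 0)."""
    saved = _with_checkpoints(model, checkpoints)
    try:
        total = 0.0
        for w, eta in checkpoints.checkpoints:
            model.set_flat_params(w)
            g = per_sample_gradient(model, sample, mode)
            total += eta * float(g @ g)
        return total
    finally:
        model.set_flat_params(saved)


def influence(
    checkpoints: CheckpointSet, model: GazeClassifier, train_sample, test_sample, mode: str = "last_layer"
) -> float:
    """Sum over checkpoints of eta_i * <grad l(train), grad l(test)> (symmetric)."""
    saved = _with_checkpoints(model, checkpoints)
    try:
        total = 0.0
        for w, eta in checkpoints.checkpoints:
            model.set_flat_params(w)
            g_train = per_sample_gradient(model, train_sample, mode)
            g_test = per_sample_gradient(model, test_sample, mode)
            total += eta * float(g_train @ g_test)
        return total
    finally:
        model.set_flat_params(saved)


def _gradient_matrix(model: GazeClassifier, prepared: dict, mode: str, batch_size: int) -> np.ndarray:
    """(n_samples, n_grad_params) gradient matrix at the current parameters."""
    n = len(prepared["labels"])
    if mode == "last_layer":
        rows = []
        for start in range(0, n, batch_size):
            idx = np.arange(start, min(start + batch_size, n))
            rows.append(_last_layer_grads_batch(model, slice_batch(prepared, idx)))
        return np.concatenate(rows, axis=0)
    rows = []
    for i in range(n):
        rows.append(per_sample_gradient(model, slice_batch(prepared, np.array([i])), mode))
    return np.stack(rows)


def self_influence_table(
    checkpoints: CheckpointSet,
    model: GazeClassifier,
    dataset: Sequence[SampleRecord] | dict,
    mode: str = "last_layer",
    batch_size: int = 64,
) -> InfluenceTable:
    """Self-influence for every sample in one pass per checkpoint (production path)."""
    if mode not in GRADIENT_MODES:
        raise ValueError(f"unknown gradient mode {mode!r}")
    prepared = dataset if isinstance(dataset, dict) else prepare_records(dataset, model.config)
    saved = _with_checkpoints(model, checkpoints)
    try:
        scores = np.zeros(len(prepared["labels"]))
        for w, eta in checkpoints.checkpoints:
            model.set_flat_params(w)
            G = _gradient_matrix(model, prepared, mode, batch_size)
            scores += eta * np.einsum("ij,ij->i", G, G)
        return InfluenceTable(mode, self_scores=pd.Series(scores, index=prepared["sample_ids"]))
    finally:
        model.set_flat_params(saved)


def influence_table(
    checkpoints: CheckpointSet,
    model: GazeClassifier,
    train_set: Sequence[SampleRecord] | dict,
    test_set: Sequence[SampleRecord] | dict,
    mode: str = "last_layer",
    batch_size: int = 64,
) -> InfluenceTable:
    """Pairwise train-by-test influence matrix (production path)."""
    if mode not in GRADIENT_MODES:
        raise ValueError(f"unknown gradient mode {mode!r}")
    prep_train = train_set if isinstance(train_set, dict) else prepare_records(train_set, model.config)
    prep_test = test_set if isinstance(test_set, dict) else prepare_records(test_set, model.config)
    saved = _with_checkpoints(model, checkpoints)
    try:
        M = np.zeros((len(prep_train["labels"]), len(prep_test["labels"])))
        for w, eta in checkpoints.checkpoints:
            model.set_flat_params(w)
            G_train = _gradient_matrix(model, prep_train, mode, batch_size)
            G_test = _gradient_matrix(model, prep_test, mode, batch_size)
            M += eta * (G_train @ G_test.T)
        return InfluenceTable(
            mode,
            pairwise=pd.DataFrame(M, index=prep_train["sample_ids"], columns=prep_test["sample_ids"]),
        )
    finally:
        model.set_flat_params(saved)


def rank_self_influence(
    checkpoints: CheckpointSet,
    model: GazeClassifier,
    dataset: Sequence[SampleRecord] | dict,
    mode: str = "last_layer",
) -> list[tuple[str, float]]:
    """Samples ordered by descending self-influence, ties broken by sample_id."""
    table = self_influence_table(checkpoints, model, dataset, mode)
    items = list(table.self_scores.items())
    items.sort(key=lambda kv: (-kv[1], kv[0]))
    return items


def proponents_opponents(
    checkpoints: CheckpointSet,
    model: GazeClassifier,
    train_set: Sequence[SampleRecord] | dict,
    test_sample,
    top_k: int,
    mode: str = "last_layer",
) -> tuple[list[tuple[str, float]], list[tuple[str, float]]]:
    """Top-k most positive (proponents) and most negative (opponents) trainers."""
    test_batch = _as_batch(model, test_sample) if not isinstance(test_sample, dict) else test_sample
    table = influence_table(checkpoints, model, train_set, test_batch, mode)
    scores = table.pairwise.iloc[:, 0]
    if top_k > len(scores):
        raise ValueError("top_k exceeds the training-set size")
    items = list(scores.items())
    proponents = sorted(items, key=lambda kv: (-kv[1], kv[0]))[:top_k]
    opponents = sorted(items, key=lambda kv: (kv[1], kv[0]))[:top_k]
    return proponents, opponents
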