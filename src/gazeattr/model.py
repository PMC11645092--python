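"""The three-branch gaze classifier.

One CNN encodes the stimulus image, a second (identically shaped) CNN encodes
the fixation map, and an LSTM encodes the scanpath coordinate sequence via its
final hidden state.  Each branch output passes through its own linear head
reducing it to a single scalar; the three scalars are concatenated and a final
linear layer plus sigmoid produces the probability of the ASD class.  Training
uses binary cross-entropy with Adam (the single-logit sigmoid head is the
two-class softmax special case).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.transform import resize

from .nn import LSTM, Conv2d, Dropout, GlobalAvgPool, Linear, MaxPool2d, Param, ReLU, sigmoid
from .types import SampleRecord


@dataclass
class GBACConfig:
    """Hyperparameters of the classifier.

    Defaults follow the reference architecture: four conv layers with filter
    counts [32, 64, 128, 256] and 3x3 kernels in both CNN branches, a
    two-layer LSTM with hidden size 1024 and dropout 0.3 fed (x, y) pairs,
    sigmoid + binary cross-entropy, Adam, 16 epochs.  Input image size,
    learning rate and batch size are not fixed by the architecture and
    default to desk-trainable values.
    """

    conv_filters: tuple[int, ...] = (32, 64, 128, 256)
    kernel_size: int = 3
    lstm_layers: int = 2
    lstm_hidden: int = 1024
    lstm_dropout: float = 0.3
    epochs: int = 16
    runs: int = 5
    input_image_size: tuple[int, int] = (128, 128)
    image_channels: int = 1
    learning_rate: float = 1e-4
    batch_size: int = 32
    use_augmented_scanpaths: bool = True
    max_seq_len: int = 2000
    final_pool: str = "gap"  # "gap" | "flatten"

    def __post_init__(self) -> None:
        if len(self.conv_filters) < 1:
            raise ValueError("need at least one conv layer")
        if self.lstm_layers < 1 or self.lstm_hidden < 1:
            raise ValueError("invalid LSTM configuration")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("invalid training configuration")


def desk_config(**overrides) -> GBACConfig:
    """A reduced configuration sized for CPU-scale synthetic experiments."""
    base = dict(
        conv_filters=(8, 16),
        lstm_layers=1,
        lstm_hidden=16,
        lstm_dropout=0.0,
        epochs=8,
        input_image_size=(32, 32),
        learning_rate=1e-2,
        batch_size=16,
        use_augmented_scanpaths=False,
        final_pool="flatten",
    )
    base.update(overrides)
    return GBACConfig(**base)


class _Flatten:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class _ConvBranch:
    """Conv/ReLU/max-pool stack ending in a fixed-size feature vector.

    The final reduction is either global average pooling (translation
    invariant; one feature per channel) or a flatten of the last pooled
    feature maps (keeps coarse spatial layout, which matters when class
    signal lives in *where* fixations land).
    """

    def __init__(
        self,
        in_ch: int,
        filters: Sequence[int],
        kernel: int,
        rng: np.random.Generator,
        name: str,
        input_hw: tuple[int, int],
        final_pool: str = "gap",
    ):
        if final_pool not in ("gap", "flatten"):
            raise ValueError(f"unknown final_pool {final_pool!r}")
        self.layers: list = []
        ch = in_ch
        h, w = input_hw
        for li, f in enumerate(filters):
            self.layers.append(Conv2d(ch, f, rng, kernel, name=f"{name}.conv{li}"))
            self.layers.append(ReLU())
            if final_pool == "flatten" or li < len(filters) - 1:
                self.layers.append(MaxPool2d())
                h, w = h // 2, w // 2
            ch = f
        if final_pool == "gap":
            self.layers.append(GlobalAvgPool())
            self.out_features = ch
        else:
            self.layers.append(_Flatten())
            self.out_features = ch * h * w

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class GazeClassifier:
    """SampleRecord batches -> P(ASD).  Built by :func:`build_model`."""

    def __init__(self, config: GBACConfig, rng: np.random.Generator):
        self.config = config
        self.image_branch = _ConvBranch(
            config.image_channels, config.conv_filters, config.kernel_size, rng, "img",
            config.input_image_size, config.final_pool,
        )
        self.fixmap_branch = _ConvBranch(
            1, config.conv_filters, config.kernel_size, rng, "fix",
            config.input_image_size, config.final_pool,
        )
        self.lstm_layers: list[LSTM] = []
        self.lstm_dropouts: list[Dropout] = []
        in_size = 2
        for li in range(config.lstm_layers):
            self.lstm_layers.append(LSTM(in_size, config.lstm_hidden, rng, name=f"scn.lstm{li}"))
            if li < config.lstm_layers - 1:
                self.lstm_dropouts.append(Dropout(config.lstm_dropout))
            in_size = config.lstm_hidden
        self.head_img = Linear(self.image_branch.out_features, 1, rng, name="head_img")
        self.head_fix = Linear(self.fixmap_branch.out_features, 1, rng, name="head_fix")
        self.head_scn = Linear(config.lstm_hidden, 1, rng, name="head_scn")
        self.final = Linear(3, 1, rng, name="final")
        self.last_features: np.ndarray | None = None  # concat input to the final layer

    # -- parameter plumbing ------------------------------------------------
    def params(self) -> list[Param]:
        """All parameters in a fixed, documented order.

        Order: image branch convs, fixmap branch convs, LSTM layers (Wx, Wh, b
        each), then the per-branch heads (image, fixmap, scanpath) and the
        final fusion layer.  Flattened vectors follow this order.
        """
        out = self.image_branch.params() + self.fixmap_branch.params()
        for l in self.lstm_layers:
            out += l.params()
        out += self.head_img.params() + self.head_fix.params() + self.head_scn.params() + self.final.params()
        return out

    def last_layer_params(self) -> list[Param]:
        return self.final.params()

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def get_flat_params(self) -> np.ndarray:
        return np.concatenate([p.value.ravel() for p in self.params()])

    def set_flat_params(self, flat: np.ndarray) -> None:
        flat = np.asarray(flat, dtype=np.float64)
        if flat.size != self.n_params:
            raise ValueError(f"expected {self.n_params} parameters, got {flat.size}")
        offset = 0
        for p in self.params():
            p.value[...] = flat[offset : offset + p.size].reshape(p.value.shape)
            offset += p.size

    def flat_grad(self, params: Sequence[Param] | None = None) -> np.ndarray:
        params = self.params() if params is None else list(params)
        return np.concatenate([p.grad.ravel() for p in params])

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    # -- forward / backward ------------------------------------------------
    def forward(self, batch: dict, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        """Return logits (B,).  ``batch`` comes from :func:`prepare_records`."""
        self._seq_shape = batch["seqs"].shape
        feat_img = self.image_branch.forward(batch["images"], train)
        feat_fix = self.fixmap_branch.forward(batch["fixmaps"], train)
        h = batch["seqs"]
        for li, lstm in enumerate(self.lstm_layers):
            h = lstm.forward(h, batch["lengths"], train=train)
            if li < len(self.lstm_dropouts):
                h = self.lstm_dropouts[li].forward(h, train=train, rng=rng)
        h_final = h[:, -1]  # masking carries each sequence's true last state here
        o_img = self.head_img.forward(feat_img, train)
        o_fix = self.head_fix.forward(feat_fix, train)
        o_scn = self.head_scn.forward(h_final, train)
        concat = np.concatenate([o_img, o_fix, o_scn], axis=1)
        self.last_features = concat
        logits = self.final.forward(concat, train)[:, 0]
        return logits

    def predict_proba(self, batch: dict) -> np.ndarray:
        return sigmoid(self.forward(batch, train=False))

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients given d(loss)/d(logit), shape (B,)."""
        dconcat = self.final.backward(dlogits[:, None])
        d_img = self.head_img.backward(dconcat[:, 0:1])
        d_fix = self.head_fix.backward(dconcat[:, 1:2])
        d_hfinal = self.head_scn.backward(dconcat[:, 2:3])
        self.image_branch.backward(d_img)
        self.fixmap_branch.backward(d_fix)
        B, T, _ = self._seq_shape
        dh = np.zeros((B, T, self.config.lstm_hidden))
        dh[:, -1] = d_hfinal
        for li in range(len(self.lstm_layers) - 1, -1, -1):
            if li < len(self.lstm_dropouts):
                dh = self.lstm_dropouts[li].backward(dh)
            dh = self.lstm_layers[li].backward(dh)


def build_model(config: GBACConfig, seed: int = 0) -> GazeClassifier:
    """Construct a classifier with reproducible initial weights."""
    return GazeClassifier(config, np.random.default_rng(seed))


# -- input preparation -----------------------------------------------------

def _to_channels(pixels: np.ndarray, channels: int) -> np.ndarray:
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.max() > 1.5:
        arr = arr / 255.0
    if arr.ndim == 3:
        if channels == 1:
            arr = arr.mean(axis=2)
        else:
            arr = np.moveaxis(arr, 2, 0)
    if arr.ndim == 2:
        arr = np.broadcast_to(arr, (channels, *arr.shape)).copy() if channels > 1 else arr[None]
    return arr


def prepare_records(records: Sequence[SampleRecord], config: GBACConfig) -> dict:
    """Convert SampleRecords into the dense arrays the model consumes.

    Images and fixation maps are resized to ``config.input_image_size``;
    scanpath coordinates are normalized to [0, 1] by the *original* stimulus
    width/height (scale invariance across stimulus sizes) and padded to the
    longest sequence.  With ``use_augmented_scanpaths`` the replicated,
    jittered sequence feeds the LSTM when present on the record; otherwise
    the original fixations do.
    """
    if not records:
        raise ValueError("no records to prepare")
    H, W = config.input_image_size
    n = len(records)
    images = np.zeros((n, config.image_channels, H, W))
    fixmaps = np.zeros((n, 1, H, W))
    seq_list = []
    for i, rec in enumerate(records):
        img = _to_channels(rec.image.pixels, config.image_channels)
        if img.shape[1:] != (H, W):
            img = np.stack([resize(c, (H, W), order=1, anti_aliasing=False) for c in img])
        images[i] = img
        fm = rec.fixation_map.astype(np.float64)
        if fm.shape != (H, W):
            fm = resize(fm, (H, W), order=1, anti_aliasing=False)
        fixmaps[i, 0] = fm
        sp = rec.scanpath
        if config.use_augmented_scanpaths and rec.augmented_scanpath is not None:
            sp = rec.augmented_scanpath
        h0, w0 = rec.image.shape
        xy = sp.xy()[: config.max_seq_len]
        xy = xy / np.array([max(w0 - 1, 1), max(h0 - 1, 1)], dtype=float)
        seq_list.append(xy)
    lengths = np.array([len(s) for s in seq_list], dtype=int)
    T = int(lengths.max())
    seqs = np.zeros((n, T, 2))
    for i, s in enumerate(seq_list):
        seqs[i, : len(s)] = s
    return {
        "images": images,
        "fixmaps": fixmaps,
        "seqs": seqs,
        "lengths": lengths,
        "labels": np.array([rec.label for rec in records], dtype=np.float64),
        "sample_ids": [rec.sample_id for rec in records],
    }


def slice_batch(prepared: dict, idx: np.ndarray) -> dict:
    """Index a prepared dataset; re-trims the padding to the slice's max length."""
    lengths = prepared["lengths"][idx]
    T = int(lengths.max())
    return {
        "images": prepared["images"][idx],
        "fixmaps": prepared["fixmaps"][idx],
        "seqs": prepared["seqs"][idx][:, :T],
        "lengths": lengths,
        "labels": prepared["labels"][idx],
        "sample_ids": [prepared["sample_ids"][i] for i in np.atleast_1d(idx)],
    }
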