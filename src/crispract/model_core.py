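"""Dual-branch CNN / CNN-BGRU sequence-to-activity regression model.

Topology
--------
one-hot ``(4 x N)`` input
-> shared convolution (first CNN layer, common to both branches)
-> branch A: stacked convolutions + max-pool + flatten + dense  (multi-layer CNN)
-> branch B: [optional convolution +] bidirectional GRU + dense (hybrid CNN-BGRU)
-> concatenation -> dense head -> single linear output.

Transfer learning fine-tunes a trained base model under a
:class:`FreezePlan`; the default plan trains the shared convolution, the
whole BGRU branch, and the final output layer while freezing the remaining
CNN-branch and post-concatenation dense layers.

The backend (:mod:`crispract.nn`) is pure NumPy, so builds, training, and
dropout are bit-deterministic given a seed, and frozen weights are exactly
unchanged by fine-tuning.
"""

from __future__ import annotations

import copy
import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .nn import Adam, BiGRU, Conv1D, Dense, Dropout, Flatten, Layer, MaxPool1D

FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# Specs and configs
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Declarative description of the network.

    The published architecture's exact layer sizes are not printed; these
    defaults are documented stand-ins and every field is configurable.
    """

    input_len: int = 28
    shared_conv: tuple[int, int] = (128, 5)  # (filters, kernel), ReLU
    cnn_branch: tuple[tuple[int, int], ...] = ((64, 3), (32, 3), (32, 3))
    cnn_pool: int = 2
    cnn_dense: int = 64
    rnn_conv: tuple[int, int] | None = None  # optional conv before the BGRU
    bigru_units: int = 64
    rnn_dense: int = 64
    head_dense: tuple[int, ...] = (128, 64)
    dropout: float = 0.3

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        d["shared_conv"] = tuple(d["shared_conv"])
        d["cnn_branch"] = tuple(tuple(c) for c in d["cnn_branch"])
        if d.get("rnn_conv") is not None:
            d["rnn_conv"] = tuple(d["rnn_conv"])
        d["head_dense"] = tuple(d["head_dense"])
        return cls(**d)

    def spec_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def small(cls, input_len: int = 28) -> "ModelSpec":
        """Reduced spec for fast tests/CI; same topology."""
        return cls(
            input_len=input_len,
            shared_conv=(32, 5),
            cnn_branch=((16, 3), (16, 3)),
            cnn_pool=2,
            cnn_dense=32,
            bigru_units=16,
            rnn_dense=32,
            head_dense=(32, 16),
            dropout=0.2,
        )


@dataclass
class FreezePlan:
    """Partition of layer names into trainable and frozen sets."""

    trainable: set[str]
    frozen: set[str]

    def __post_init__(self) -> None:
        self.trainable = set(self.trainable)
        self.frozen = set(self.frozen)
        overlap = self.trainable & self.frozen
        if overlap:
            raise ValueError(f"layers both trainable and frozen: {sorted(overlap)}")

    def validate(self, model: "ActivityModel") -> None:
        names = {layer.name for layer in model.layers}
        unknown = (self.trainable | self.frozen) - names
        if unknown:
            raise ValueError(f"plan references unknown layers: {sorted(unknown)}")
        missing = names - (self.trainable | self.frozen)
        if missing:
            raise ValueError(f"plan does not cover layers: {sorted(missing)}")

    def to_dict(self) -> dict:
        return {"trainable": sorted(self.trainable), "frozen": sorted(self.frozen)}

    @classmethod
    def from_dict(cls, d: dict) -> "FreezePlan":
        return cls(trainable=set(d["trainable"]), frozen=set(d["frozen"]))

    @classmethod
    def all_trainable(cls, model: "ActivityModel") -> "FreezePlan":
        return cls(trainable={layer.name for layer in model.layers}, frozen=set())

    @classmethod
    def all_frozen(cls, model: "ActivityModel") -> "FreezePlan":
        return cls(trainable=set(), frozen={layer.name for layer in model.layers})


@dataclass
class TrainConfig:
    epochs: int = 25
    batch_size: int = 128
    lr: float = 1e-3
    seed: int = 0
    validation_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in [0, 1)")


#: defaults standing in for the tuned-but-unpublished training values
BASE_TRAIN = TrainConfig(epochs=25, batch_size=128, lr=1e-3)
TRANSFER_TRAIN = TrainConfig(epochs=8, batch_size=16, lr=1e-4)


@dataclass
class LabeledDataset:
    """Uniform-length target-site sequences with standardized activity targets."""

    sequences: list[str]
    targets: np.ndarray
    name: str = ""
    nuclease: str = "SpCas9"

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=np.float64)
        if len(self.sequences) != len(self.targets):
            raise ValueError("sequences and targets must align")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("sequences must have uniform length")
        if len(self.sequences) != len(set(self.sequences)):
            raise ValueError(f"duplicate guide sequences in dataset {self.name!r}")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def input_len(self) -> int:
        return len(self.sequences[0])

    def guides(self) -> list[str]:
        """20-nt protospacers (windows always start with the protospacer)."""
        return [s[:20] for s in self.sequences]

    def encoded(self) -> np.ndarray:
        from .guide_design import encode_batch

        return encode_batch(self.sequences)

    def subset(self, idx: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset(
            sequences=[self.sequences[i] for i in idx],
            targets=self.targets[list(idx)],
            name=self.name,
            nuclease=self.nuclease,
        )


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class ActivityModel:
    """The assembled dual-branch network.  Use :func:`build_model`."""

    def __init__(self, spec: ModelSpec, seed: int):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)

        filters, kernel = spec.shared_conv
        L = spec.input_len
        self.shared = Conv1D("shared_conv", 4, filters, kernel, activation="relu")
        Ls = self.shared.out_len(L)

        # branch A: multi-layer CNN
        self.branch_a: list[Layer] = []
        c_in, La = filters, Ls
        for i, (f, k) in enumerate(spec.cnn_branch, start=1):
            conv = Conv1D(f"cnnA_conv{i}", c_in, f, k, activation="relu")
            La = conv.out_len(La)
            self.branch_a.append(conv)
            c_in = f
        self.branch_a.append(MaxPool1D("cnnA_pool", spec.cnn_pool))
        La //= spec.cnn_pool
        if La < 1:
            raise ValueError("input too short for the CNN branch")
        self.branch_a.append(Flatten("cnnA_flatten"))
        self.branch_a.append(Dense("cnnA_dense", La * c_in, spec.cnn_dense, activation="relu"))
        self.branch_a.append(Dropout("cnnA_dropout", spec.dropout))

        # branch B: hybrid CNN-BGRU
        self.branch_b: list[Layer] = []
        c_in, Lb = filters, Ls
        if spec.rnn_conv is not None:
            f, k = spec.rnn_conv
            conv = Conv1D("rnnB_conv", c_in, f, k, activation="relu")
            Lb = conv.out_len(Lb)
            self.branch_b.append(conv)
            c_in = f
        self.branch_b.append(BiGRU("rnnB_bigru", c_in, spec.bigru_units))
        self.branch_b.append(
            Dense("rnnB_dense", 2 * spec.bigru_units, spec.rnn_dense, activation="relu")
        )
        self.branch_b.append(Dropout("rnnB_dropout", spec.dropout))

        # merge head
        self.head: list[Layer] = []
        d_in = spec.cnn_dense + spec.rnn_dense
        for i, units in enumerate(spec.head_dense, start=1):
            self.head.append(Dense(f"head_dense{i}", d_in, units, activation="relu"))
            self.head.append(Dropout(f"head_dropout{i}", spec.dropout))
            d_in = units
        self.output = Dense("output", d_in, 1, activation="linear")

        self.layers: list[Layer] = (
            [self.shared] + self.branch_a + self.branch_b + self.head + [self.output]
        )
        names = [layer.name for layer in self.layers]
        if len(names) != len(set(names)):
            raise ValueError("layer names must be unique")
        for layer in self.layers:
            layer.init(rng)

    # -- passes -----------------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 3 or x.shape[1] != 4:
            raise ValueError("input must have shape (batch, 4, N)")
        if x.shape[2] != self.spec.input_len:
            raise ValueError(
                f"model expects input length {self.spec.input_len}, got {x.shape[2]}"
            )
        return x.transpose(0, 2, 1)  # -> (batch, N, 4)

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        h = self.shared.forward(self._check_input(x), train, rng)
        a = h
        for layer in self.branch_a:
            a = layer.forward(a, train, rng)
        b = h
        for layer in self.branch_b:
            b = layer.forward(b, train, rng)
        m = np.concatenate([a, b], axis=1)
        for layer in self.head:
            m = layer.forward(m, train, rng)
        return self.output.forward(m, train, rng)[:, 0]

    def backward(self, dout: np.ndarray) -> None:
        dm = self.output.backward(dout[:, None])
        for layer in reversed(self.head):
            dm = layer.backward(dm)
        na = self.spec.cnn_dense
        da, db = dm[:, :na], dm[:, na:]
        for layer in reversed(self.branch_a):
            da = layer.backward(da)
        for layer in reversed(self.branch_b):
            db = layer.backward(db)
        self.shared.backward(da + db)

    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.zero_grads()

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def get_weights(self) -> dict[str, np.ndarray]:
        return {
            f"{layer.name}/{k}": v.copy() for layer in self.layers for k, v in layer.params.items()
        }

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for layer in self.layers:
            for k in layer.params:
                layer.params[k] = weights[f"{layer.name}/{k}"].copy()

    def clone(self) -> "ActivityModel":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def build_model(spec: ModelSpec, seed: int) -> ActivityModel:
    """Deterministically initialize the dual-branch network."""
    return ActivityModel(spec, seed)


def default_freeze_plan(model: ActivityModel) -> FreezePlan:
    """Fine-tuning plan: train the shared initial convolution, the whole
    CNN-BGRU branch, and the final output layer; freeze the multi-layer CNN
    branch and the post-concatenation dense layers."""
    trainable = {"shared_conv", "output"} | {layer.name for layer in model.branch_b}
    frozen = {layer.name for layer in model.layers} - trainable
    plan = FreezePlan(trainable=trainable, frozen=frozen)
    plan.validate(model)
    return plan


FREEZE_PRESETS = {
    "default": default_freeze_plan,
    "none": FreezePlan.all_trainable,
    "all": FreezePlan.all_frozen,
}


def _fit(
    model: ActivityModel,
    x: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    trainable: set[str],
) -> list[float]:
    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(lr=cfg.lr)
    n = len(y)
    history: list[float] = []
    for _ in range(cfg.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start: start + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            model.zero_grads()
            pred = model.forward(xb, train=True, rng=rng)
            err = pred - yb
            loss = float(np.mean(err * err))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at step {optimizer.t}; lower the learning rate"
                )
            model.backward(2.0 * err / len(yb))
            optimizer.step(model.layers, trainable)
            epoch_loss += loss * len(yb)
        history.append(epoch_loss / n)
    if len(history) > 1 and history[-1] > history[0]:
        warnings.warn("training loss did not decrease over training", stacklevel=3)
    return history


def train_base(model: ActivityModel, data: LabeledDataset, cfg: TrainConfig) -> list[float]:
    """Train all layers with Adam/MSE; returns per-epoch training loss."""
    if len(data) < 5000:
        warnings.warn(
            f"base dataset has only {len(data)} examples; base models are "
            "intended for large datasets",
            stacklevel=2,
        )
    x = data.encoded()
    trainable = {layer.name for layer in model.layers}
    return _fit(model, x, data.targets, cfg, trainable)


def transfer_train(
    base: ActivityModel,
    plan: FreezePlan,
    data: LabeledDataset,
    cfg: TrainConfig,
) -> ActivityModel:
    """Fine-tune a copy of ``base``; only ``plan.trainable`` weights change.

    Frozen weights are bit-identical before and after.
    """
    plan.validate(base)
    model = base.clone()
    x = data.encoded()
    _fit(model, x, data.targets, cfg, set(plan.trainable))
    return model


def predict(model: ActivityModel, inputs: np.ndarray | LabeledDataset | Sequence[str]) -> np.ndarray:
    """Deterministic inference: one float per input."""
    if isinstance(inputs, LabeledDataset):
        x = inputs.encoded()
    elif isinstance(inputs, np.ndarray):
        x = inputs
    else:
        from .guide_design import encode_batch

        x = encode_batch(list(inputs))
    return model.forward(x, train=False)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_model(model: ActivityModel, path: str) -> None:
    """Write ``{path}.json`` (spec + provenance) and ``{path}.npz`` (weights)."""
    meta = {
        "format_version": FORMAT_VERSION,
        "spec": model.spec.to_dict(),
        "spec_hash": model.spec.spec_hash(),
        "seed": model.seed,
    }
    with open(f"{path}.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    np.savez(f"{path}.npz", **model.get_weights())


def load_model(path: str) -> ActivityModel:
    try:
        with open(f"{path}.json") as fh:
            meta = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise ValueError(f"cannot read model metadata {path}.json: {exc}") from exc
    if meta.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {meta.get('format_version')}")
    spec = ModelSpec.from_dict(meta["spec"])
    if spec.spec_hash() != meta["spec_hash"]:
        raise ValueError("spec hash mismatch: model file corrupt or edited")
    model = build_model(spec, seed=int(meta["seed"]))
    with np.load(f"{path}.npz") as npz:
        weights = {k: npz[k] for k in npz.files}
    expected = set(model.get_weights())
    if set(weights) != expected:
        raise ValueError("weight file does not match the model spec")
    model.set_weights(weights)
    return model
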