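"""Step 2 — per-pixel flow classification and the vessel-level majority rule.

Every cross-section pixel of a detected vessel/grid-line crossing yields a
16 x 16 x 200 spatio-temporal data block; a small 3D convolutional network
maps each block to a flow probability, a threshold of 0.5 binarizes it,
and the crossing is called flowing when strictly more than 50% of its
pixels are flowing (so a 3-of-4 cross-section is flowing, a 2-of-4 one is
not). A logistic regression on the flattened block is kept as the
baseline the network is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

from . import _network


@dataclass
class CNNConfig:
    """Hyper-parameters of the 3D-CNN and its training procedure.

    The convolution/pooling geometry is fixed (8 filters of 7x7x7, then 8
    of 5x5x5, then 2x2x2 max-pool); on a 16x16x200 input it flattens to
    exactly 6840 features. Training minimizes categorical cross-entropy
    with Adadelta in batches of 30 for up to 100 epochs, stopping early
    once the training loss change stays below tol for `patience`
    consecutive epochs ("until the weights converge").
    """

    input_shape: tuple[int, int, int] = (16, 16, 200)
    mlp_hidden: int = 128
    prob_threshold: float = 0.5
    majority: float = 0.5
    batch_size: int = 30
    max_epochs: int = 100
    tol: float = 1e-4
    patience: int = 3
    seed: int = 0


@dataclass
class TrainingHistory:
    """Per-epoch training loss and error rate."""

    loss: list[float] = field(default_factory=list)
    error_rate: list[float] = field(default_factory=list)
    converged_epoch: int | None = None


@dataclass
class FlowDecision:
    """Per-pixel probabilities/labels and the vessel-level majority call."""

    probabilities: np.ndarray
    pixel_labels: np.ndarray
    flowing_fraction: float
    vessel_flowing: bool


def layer_output_shapes(
    config: CNNConfig | None = None,
    input_shape: tuple[int, int, int] | None = None,
) -> list[tuple]:
    """Shape after each layer, ending with the flattened length.

    Valid (no-padding) stride-1 convolutions and non-overlapping 2x2x2
    pooling with floor division — the only combination under which the
    canonical 16x16x200 block flattens to the architecture's 6840-vector.
    An input too small for the first convolution is an error; an input
    that only supports a prefix of the stack returns that prefix.
    """
    config = config or CNNConfig()
    shape = tuple(input_shape or config.input_shape)
    s1 = _network.conv_out_shape(shape, _network.K1)  # raises if conv1 cannot fit
    shapes = [s1 + (_network.N_FILTERS,)]
    try:
        s2 = _network.conv_out_shape(s1, _network.K2)
    except ValueError:
        return shapes
    sp = _network.pool_out_shape(s2)
    flat = int(np.prod(sp)) * _network.N_FILTERS
    shapes += [s2 + (_network.N_FILTERS,), sp + (_network.N_FILTERS,), (flat,)]
    return shapes


def normalize_block(raw: np.ndarray) -> np.ndarray:
    """Per-block linear rescale to [0, 1]; a constant block maps to zeros."""
    raw = np.asarray(raw, dtype=np.float64)
    if not np.all(np.isfinite(raw)):
        raise ValueError("block contains non-finite values")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.zeros_like(raw, dtype=np.float32)
    return ((raw - lo) / (hi - lo)).astype(np.float32)


def _check_two_classes(labels: np.ndarray) -> None:
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=2)
    if counts[0] < 2 or counts[1] < 2:
        raise ValueError(
            f"training needs >= 2 examples of each class, got {counts[0]} "
            f"non-flowing / {counts[1]} flowing"
        )


class CNNModel:
    """A trained 3D-CNN with the block-normalizing prediction interface."""

    kind = "cnn3d"

    def __init__(self, config: CNNConfig):
        self.config = config
        self.net = _network.ConvNet3D(
            config.input_shape, hidden=config.mlp_hidden, seed=config.seed
        )

    def predict_proba(self, blocks: np.ndarray) -> np.ndarray:
        """Flow-class probability for each (already normalized) block."""
        blocks = np.asarray(blocks)
        if blocks.shape[1:] != tuple(self.config.input_shape):
            raise ValueError(
                f"blocks of shape {blocks.shape[1:]} do not match the model input "
                f"{self.config.input_shape}"
            )
        return self.net.predict_proba(blocks)[:, 1]

    def config_dict(self) -> dict:
        return {
            "kind": self.kind,
            "input_shape": list(self.config.input_shape),
            "mlp_hidden": self.config.mlp_hidden,
            "prob_threshold": self.config.prob_threshold,
            "majority": self.config.majority,
            "seed": self.config.seed,
        }

    def save(self, path) -> None:
        np.savez_compressed(path, **self.net.params)

    @classmethod
    def load(cls, path, cfg: dict) -> "CNNModel":
        config = CNNConfig(
            input_shape=tuple(cfg["input_shape"]),
            mlp_hidden=cfg["mlp_hidden"],
            prob_threshold=cfg.get("prob_threshold", 0.5),
            majority=cfg.get("majority", 0.5),
            seed=cfg.get("seed", 0),
        )
        model = cls(config)
        with np.load(path) as data:
            model.net.params = {k: data[k] for k in data.files}
        return model


def train_cnn(
    blocks: np.ndarray,
    labels: np.ndarray,
    config: CNNConfig | None = None,
) -> tuple[CNNModel, TrainingHistory]:
    """Train the 3D-CNN on normalized blocks with binary flow labels.

    Mini-batch Adadelta on categorical cross-entropy; weight init and
    batch shuffling both derive from config.seed, so a fixed seed gives a
    reproducible model. History records the loss and error rate of each
    epoch; training stops early when the loss change stays below
    config.tol for config.patience consecutive epochs.
    """
    config = config or CNNConfig()
    blocks = np.asarray(blocks, dtype=np.float32)
    labels = np.asarray(labels, dtype=int)
    if blocks.shape[0] != labels.shape[0]:
        raise ValueError("blocks and labels disagree in length")
    _check_two_classes(labels)

    model = CNNModel(config)
    opt = _network.Adadelta(model.net.params)
    rng = np.random.default_rng(config.seed + 1)
    history = TrainingHistory()
    n = blocks.shape[0]
    still = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            loss, grads = model.net.loss_and_grads(blocks[idx], labels[idx])
            opt.step(model.net.params, grads)
            epoch_loss += loss * len(idx)
        epoch_loss /= n
        prob = model.predict_proba(blocks)
        err = float(np.mean((prob >= config.prob_threshold).astype(int) != labels))
        history.loss.append(float(epoch_loss))
        history.error_rate.append(err)
        if epoch > 0 and abs(history.loss[-1] - history.loss[-2]) < config.tol:
            still += 1
            if still >= config.patience:
                history.converged_epoch = epoch
                break
        else:
            still = 0
    return model, history


def predict_pixel(model, block: np.ndarray) -> float:
    """Flow probability of a single normalized block."""
    p = float(model.predict_proba(np.asarray(block)[None, ...])[0])
    if not (0.0 <= p <= 1.0):
        raise ValueError("probability outside [0, 1]")
    return p


def decide_vessel(
    pixel_probabilities,
    prob_threshold: float = 0.5,
    majority: float = 0.5,
) -> FlowDecision:
    """Majority rule over a cross-section.

    A pixel is flowing when its probability is >= prob_threshold; the
    crossing is flowing when the flowing fraction is strictly greater
    than `majority` (so an exactly-half split is non-flowing).
    """
    probs = np.asarray(pixel_probabilities, dtype=float)
    if probs.size == 0:
        raise ValueError("empty probability list")
    binary = (probs >= prob_threshold).astype(int)
    fraction = float(binary.mean())
    return FlowDecision(
        probabilities=probs,
        pixel_labels=binary,
        flowing_fraction=fraction,
        vessel_flowing=fraction > majority,
    )


class LogisticBaseline:
    """Logistic regression on the flattened block: the simple comparator."""

    kind = "logistic"

    def __init__(self, input_shape: tuple[int, int, int], C: float = 1.0, seed: int = 0):
        self.input_shape = tuple(input_shape)
        self.C = C
        self.seed = seed
        self.clf = LogisticRegression(C=C, max_iter=2000, random_state=seed)

    @property
    def coef_length(self) -> int:
        return int(np.prod(self.input_shape))

    def predict_proba(self, blocks: np.ndarray) -> np.ndarray:
        flat = np.asarray(blocks).reshape(len(blocks), -1)
        return self.clf.predict_proba(flat)[:, 1]

    def config_dict(self) -> dict:
        return {"kind": self.kind, "input_shape": list(self.input_shape),
                "C": self.C, "seed": self.seed}

    def save(self, path) -> None:
        np.savez_compressed(path, coef=self.clf.coef_, intercept=self.clf.intercept_,
                            classes=self.clf.classes_)

    @classmethod
    def load(cls, path, cfg: dict) -> "LogisticBaseline":
        model = cls(tuple(cfg["input_shape"]), C=cfg.get("C", 1.0), seed=cfg.get("seed", 0))
        with np.load(path) as data:
            model.clf.coef_ = data["coef"]
            model.clf.intercept_ = data["intercept"]
            model.clf.classes_ = data["classes"]
        return model


def train_logistic_baseline(
    blocks: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    C: float = 1.0,
) -> LogisticBaseline:
    """Fit the L2-regularized logistic baseline on flattened blocks."""
    blocks = np.asarray(blocks, dtype=np.float32)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    model = LogisticBaseline(blocks.shape[1:], C=C, seed=seed)
    model.clf.fit(blocks.reshape(len(blocks), -1), labels)
    return model


def cross_validate_cnn(
    blocks: np.ndarray,
    labels: np.ndarray,
    config: CNNConfig | None = None,
    k: int = 10,
) -> list[float]:
    """Stratified k-fold cross-validated pixel accuracy (architecture check)."""
    from sklearn.model_selection import StratifiedKFold

    config = config or CNNConfig()
    labels = np.asarray(labels, dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    accs = []
    for train_idx, test_idx in skf.split(np.zeros(len(labels)), labels):
        model, _ = train_cnn(blocks[train_idx], labels[train_idx], config)
        prob = model.predict_proba(blocks[test_idx])
        pred = (prob >= config.prob_threshold).astype(int)
        accs.append(float(np.mean(pred == labels[test_idx])))
    return accs
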