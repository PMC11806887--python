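"""CNN risk-SNP prioritizer trained on block feature maps with uncertain labels.

The model is a small convolutional network over the SNP axis of a 31 x F
binary block map: two convolution layers (kernels span all F feature
columns), then a per-row dense head that emits a score in [0, 1] for every
SNP slot. Because training labels exist only at the block level (real
association block = 1, shuffled-feature control = 0), the block score is a
multiple-instance aggregation of the per-SNP scores over the valid rows — by
default a smooth maximum ("the block is positive if it contains at least one
causal-looking SNP"), which, unlike a hard max, supervises every
causal-looking row and keeps per-SNP scores calibrated. Labels are *uncertain*: a positive block contains at
most one truly causal SNP among up to 31, so the binary cross-entropy is
taken against soft targets (default 0.9 for positives, 0.05 for controls)
rather than hard 1/0.

The convolutional stack can be pre-trained as an autoencoder that
reconstructs the valid rows of the maps; its weights then initialize the
classifier. Data are split by chromosome into training / validation / test
partitions so that no chromosome leaks between them; the validation loss
drives both per-epoch model selection and the choice of which ensemble
members to keep.

The network is implemented directly on numpy arrays (manual backprop, Adam
with decoupled weight decay, input dropout, optional monotonicity
projection), which keeps the whole prioritizer dependency-light and
bit-reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .features import BLOCK_ROWS, BlockFeatureMap

__all__ = [
    "ModelConfig",
    "DatasetSplit",
    "SnpScore",
    "EvalReport",
    "TrainedPrioritizer",
    "PretrainResult",
    "split_by_chromosome",
    "pretrain_autoencoder",
    "train",
    "predict_scores",
    "select_candidates",
    "select_block_top",
    "evaluate_auc",
    "soft_cross_entropy",
    "permute_labels",
    "DEFAULT_SCORE_THRESHOLD",
]

#: prediction scores strictly above this mark initial candidates
DEFAULT_SCORE_THRESHOLD = 0.5

_EPS = 1e-7


@dataclass
class ModelConfig:
    """Hyperparameters of the prioritizer.

    ``kernel_rows`` is the height of the convolution kernels along the SNP
    axis. The default of 1 keeps each SNP's score attributable to its own
    annotations (required for meaningful per-SNP candidate selection);
    larger odd values let the model use neighborhood context.
    """

    conv_channels: tuple[int, int] = (16, 16)
    kernel_rows: int = 1
    dense_units: int = 16
    positive_label_confidence: float = 0.9
    control_label_confidence: float = 0.05
    pretrain_epochs: int = 30
    train_epochs: int = 60
    learning_rate: float = 0.01
    weight_decay: float = 1e-4
    input_dropout: float = 0.25
    batch_size: int = 16
    seed: int = 0
    aggregation: str = "softmax"  # softmax | max | mean | noisy-or
    softmax_beta: float = 8.0  # sharpness of the softmax pooling
    model_selection: str = "val"  # val (restore best validation-loss epoch) | final
    monotone: bool = True  # constrain scores to be non-decreasing in every feature
    ensemble_size: int = 7
    ensemble_keep: int = 3  # at most this many members kept for scoring (capped at ensemble_size)
    ensemble_val_margin: float = 0.2  # keep only members within this much of the best validation loss

    def __post_init__(self) -> None:
        if not (0.5 < self.positive_label_confidence <= 1):
            raise ValueError("positive_label_confidence must lie in (0.5, 1]")
        if not (0 <= self.control_label_confidence < 0.5):
            raise ValueError("control_label_confidence must lie in [0, 0.5)")
        if self.positive_label_confidence <= self.control_label_confidence:
            raise ValueError("positive confidence must exceed control confidence")
        if self.kernel_rows < 1 or self.kernel_rows % 2 == 0:
            raise ValueError("kernel_rows must be a positive odd integer")
        if self.aggregation not in ("max", "softmax", "mean", "noisy-or"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        if self.softmax_beta <= 0:
            raise ValueError("softmax_beta must be positive")
        if self.model_selection not in ("val", "final"):
            raise ValueError(f"unknown model_selection {self.model_selection!r}")
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be at least 1")
        if self.ensemble_keep < 1:
            raise ValueError("ensemble_keep must be at least 1")
        if not (0 <= self.input_dropout < 1):
            raise ValueError("input_dropout must lie in [0, 1)")


@dataclass
class DatasetSplit:
    """Chromosome-partitioned block maps; the three chromosome sets are
    pairwise disjoint and each map follows its chromosome."""

    train_chroms: frozenset
    val_chroms: frozenset
    test_chroms: frozenset
    train: list[BlockFeatureMap]
    val: list[BlockFeatureMap]
    test: list[BlockFeatureMap]


@dataclass(frozen=True)
class SnpScore:
    """Per-SNP prediction score with candidate / block-top flags."""

    snp_id: str
    block_id: str
    trait: str
    score: float
    pos: int = 0
    pvalue: float = 1.0
    is_initial_candidate: bool = False
    is_block_top: bool = False


@dataclass
class EvalReport:
    auc: float
    n_test_blocks: int
    partition_counts: dict = field(default_factory=dict)


@dataclass
class PretrainResult:
    """Autoencoder pretraining output: one encoder per ensemble member (the
    first member's losses are reported as the headline numbers)."""

    encoder_params: dict  # member 0, the classifier-initializing stack
    initial_loss: float
    final_loss: float
    loss_history: list[float]
    member_encoders: list = field(default_factory=list)


# ------------------------------------------------------------- primitives


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Same-padded 1D convolution along axis 1. x: (B,L,Cin), W: (K,Cin,Cout)."""
    K = W.shape[0]
    pad = K // 2
    L = x.shape[1]
    xp = np.pad(x, ((0, 0), (pad, pad), (0, 0))) if pad else x
    out = np.zeros((x.shape[0], L, W.shape[2]))
    for k in range(K):
        out += xp[:, k : k + L, :] @ W[k]
    return out + b, xp


def _conv_backward(dout: np.ndarray, xp: np.ndarray, W: np.ndarray):
    K = W.shape[0]
    pad = K // 2
    L = dout.shape[1]
    dW = np.empty_like(W)
    dxp = np.zeros_like(xp)
    for k in range(K):
        dW[k] = np.tensordot(xp[:, k : k + L, :], dout, axes=([0, 1], [0, 1]))
        dxp[:, k : k + L, :] += dout @ W[k].T
    db = dout.sum(axis=(0, 1))
    dx = dxp[:, pad : pad + L, :] if pad else dxp
    return dW, db, dx


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def soft_cross_entropy(p: np.ndarray, q: np.ndarray) -> float:
    """Mean binary cross-entropy of predictions ``p`` against soft targets
    ``q``; with q in {0, 1} this is exactly the hard-label cross-entropy."""
    p = np.clip(np.asarray(p, dtype=float), _EPS, 1 - _EPS)
    q = np.asarray(q, dtype=float)
    return float(np.mean(-(q * np.log(p) + (1 - q) * np.log(1 - p))))


#: weight matrices kept non-negative in monotone mode (the decoder is free:
#: reconstruction needs no monotonicity)
_MONOTONE_KEYS = ("W1", "W2", "Wd", "Wo")


def _init_params(config: ModelConfig, F: int) -> dict:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 0x6D6F64]))
    c1, c2 = config.conv_channels
    K = config.kernel_rows
    D = config.dense_units

    def he(shape, fan_in):
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

    params = {
        "W1": he((K, F, c1), K * F),
        "b1": np.zeros(c1),
        "W2": he((K, c1, c2), K * c1),
        "b2": np.zeros(c2),
        "Wd": he((c2, D), c2),
        "bd": np.zeros(D),
        "Wo": he((D,), D),
        "bo": np.zeros(()),
        "Wdec": he((c2, F), c2),
        "bdec": np.zeros(F),
    }
    if config.monotone:
        for k in _MONOTONE_KEYS:
            params[k] = np.abs(params[k])
    return params


def _project_monotone(params: dict) -> None:
    for k in _MONOTONE_KEYS:
        if k in params:
            np.maximum(params[k], 0.0, out=params[k])


class _Adam:
    """Adam with decoupled weight decay (applied to weight matrices, not biases)."""

    def __init__(self, params: dict, lr: float, weight_decay: float = 0.0, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.wd, self.b1, self.b2, self.eps = lr, weight_decay, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            step = self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.wd and k.startswith("W"):
                step = step + self.lr * self.wd * params[k]
            params[k] = params[k] - step


def _stack(maps: list[BlockFeatureMap]):
    X = np.stack([m.matrix for m in maps]).astype(float)
    mask = np.stack([m.row_mask for m in maps]).astype(bool)
    return X, mask


def _encode(params: dict, X: np.ndarray):
    a1, xp1 = _conv_forward(X, params["W1"], params["b1"])
    h1 = np.maximum(a1, 0.0)
    a2, xp2 = _conv_forward(h1, params["W2"], params["b2"])
    h2 = np.maximum(a2, 0.0)
    return {"a1": a1, "xp1": xp1, "h1": h1, "a2": a2, "xp2": xp2, "h2": h2}


def _row_scores(params: dict, X: np.ndarray):
    cache = _encode(params, X)
    g_pre = cache["h2"] @ params["Wd"] + params["bd"]
    g = np.maximum(g_pre, 0.0)
    z = g @ params["Wo"] + params["bo"]
    p = _sigmoid(z)
    cache.update({"g_pre": g_pre, "g": g, "z": z, "p": p})
    return p, cache


def _softmax_weights(p: np.ndarray, mask: np.ndarray, beta: float) -> np.ndarray:
    shifted = np.where(mask, beta * p, -np.inf)
    shifted = shifted - shifted.max(axis=1, keepdims=True)
    e = np.where(mask, np.exp(shifted), 0.0)
    return e / e.sum(axis=1, keepdims=True)


def _aggregate(p: np.ndarray, mask: np.ndarray, how: str, beta: float = 8.0) -> np.ndarray:
    masked = np.where(mask, p, -np.inf if how == "max" else 0.0)
    if how == "max":
        return masked.max(axis=1)
    if how == "softmax":
        # smooth maximum: every causal-looking row shares the supervision
        return (_softmax_weights(p, mask, beta) * np.where(mask, p, 0.0)).sum(axis=1)
    n = mask.sum(axis=1)
    if how == "mean":
        return masked.sum(axis=1) / n
    # noisy-or: block is positive unless every valid row is negative
    log1m = np.where(mask, np.log1p(-np.clip(p, _EPS, 1 - _EPS)), 0.0)
    return 1.0 - np.exp(log1m.sum(axis=1))


def _classifier_grads(params: dict, X, mask, q, config: ModelConfig):
    """Forward + full backward pass; returns (loss, grads)."""
    p, cache = _row_scores(params, X)
    s = _aggregate(p, mask, config.aggregation, config.softmax_beta)
    s_c = np.clip(s, _EPS, 1 - _EPS)
    B = X.shape[0]
    loss = soft_cross_entropy(s, q)

    dz = np.zeros_like(p)
    if config.aggregation == "max":
        idx = np.where(mask, p, -np.inf).argmax(axis=1)
        dz[np.arange(B), idx] = (s_c - q) / B
    else:
        ds = (s_c - q) / (s_c * (1 - s_c)) / B
        if config.aggregation == "mean":
            dp = (ds / mask.sum(axis=1))[:, None] * mask
            dz = dp * p * (1 - p)
        elif config.aggregation == "softmax":
            w = _softmax_weights(p, mask, config.softmax_beta)
            dp = ds[:, None] * w * (1.0 + config.softmax_beta * (p - s[:, None])) * mask
            dz = dp * p * (1 - p)
        else:  # noisy-or
            dz = (ds * (1 - s_c))[:, None] * p * mask

    grads = {}
    grads["Wo"] = np.tensordot(cache["g"], dz, axes=([0, 1], [0, 1]))
    grads["bo"] = np.asarray(dz.sum())
    dg = dz[..., None] * params["Wo"]
    dg_pre = dg * (cache["g_pre"] > 0)
    grads["Wd"] = np.tensordot(cache["h2"], dg_pre, axes=([0, 1], [0, 1]))
    grads["bd"] = dg_pre.sum(axis=(0, 1))
    dh2 = dg_pre @ params["Wd"].T
    da2 = dh2 * (cache["a2"] > 0)
    grads["W2"], grads["b2"], dh1 = _conv_backward(da2, cache["xp2"], params["W2"])
    da1 = dh1 * (cache["a1"] > 0)
    grads["W1"], grads["b1"], _ = _conv_backward(da1, cache["xp1"], params["W1"])
    return loss, grads


def _ae_loss_grads(params: dict, X, mask, want_grads=True):
    cache = _encode(params, X)
    logits = cache["h2"] @ params["Wdec"] + params["bdec"]
    phat = _sigmoid(logits)
    m = mask[..., None].astype(float)
    denom = max(m.sum() * X.shape[2], 1.0)  # valid cells
    pc = np.clip(phat, _EPS, 1 - _EPS)
    loss = float((-(X * np.log(pc) + (1 - X) * np.log(1 - pc)) * m).sum() / denom)
    if not want_grads:
        return loss, None
    dlogits = (phat - X) * m / denom
    grads = {}
    grads["Wdec"] = np.tensordot(cache["h2"], dlogits, axes=([0, 1], [0, 1]))
    grads["bdec"] = dlogits.sum(axis=(0, 1))
    dh2 = dlogits @ params["Wdec"].T
    da2 = dh2 * (cache["a2"] > 0)
    grads["W2"], grads["b2"], dh1 = _conv_backward(da2, cache["xp2"], params["W2"])
    da1 = dh1 * (cache["a1"] > 0)
    grads["W1"], grads["b1"], _ = _conv_backward(da1, cache["xp1"], params["W1"])
    return loss, grads


# ------------------------------------------------------------- operations


def split_by_chromosome(
    blocks: list[BlockFeatureMap], val_chroms: set, test_chroms: set
) -> DatasetSplit:
    """Partition maps by chromosome; chromosomes not listed for validation or
    test form the training set. Control maps carry their source block's
    chromosome, so a positive and its paired control always land together."""
    val = frozenset(str(c) for c in val_chroms)
    test = frozenset(str(c) for c in test_chroms)
    overlap = val & test
    if overlap:
        raise ValueError(f"chromosomes listed in both val and test: {sorted(overlap)}")
    all_chroms = {str(m.chrom) for m in blocks}
    train = frozenset(all_chroms - val - test)
    if not train:
        raise ValueError("empty training set: every chromosome is held out")
    part = lambda cs: [m for m in blocks if str(m.chrom) in cs]
    return DatasetSplit(
        train_chroms=train,
        val_chroms=val,
        test_chroms=test,
        train=part(train),
        val=part(val),
        test=part(test),
    )


def pretrain_autoencoder(maps: list[BlockFeatureMap], config: ModelConfig) -> PretrainResult:
    """Train a row-reconstruction autoencoder on the conv stack; returns the
    encoder parameters used to initialize the classifier (one encoder per
    ensemble member, each from its own seed, so ensemble diversity survives
    pretraining). With ``pretrain_epochs = 0`` the seeded random
    initialization is returned unchanged."""
    if not maps:
        raise ValueError("need at least one map to pretrain")
    F = maps[0].n_features
    X, mask = _stack(maps)
    n = len(maps)
    encoders: list[dict] = []
    first_history: list[float] = []
    for k_member in range(config.ensemble_size):
        mseed = config.seed + 7919 * k_member
        params = _init_params(replace(config, seed=mseed), F)
        loss0, _ = _ae_loss_grads(params, X, mask, want_grads=False)
        history = [loss0]
        if config.pretrain_epochs > 0:
            rng = np.random.default_rng(np.random.SeedSequence([mseed & 0x7FFFFFFF, 0xAE]))
            opt = _Adam(params, config.learning_rate, config.weight_decay)
            for _ in range(config.pretrain_epochs):
                order = rng.permutation(n)
                for lo in range(0, n, config.batch_size):
                    sel = order[lo : lo + config.batch_size]
                    _, grads = _ae_loss_grads(params, X[sel], mask[sel])
                    opt.step(params, grads)
                loss, _ = _ae_loss_grads(params, X, mask, want_grads=False)
                history.append(loss)
        encoders.append({k: params[k].copy() for k in ("W1", "b1", "W2", "b2")})
        if k_member == 0:
            first_history = history
    return PretrainResult(
        encoder_params=encoders[0],
        initial_loss=first_history[0],
        final_loss=first_history[-1],
        loss_history=first_history,
        member_encoders=encoders,
    )


@dataclass
class TrainedPrioritizer:
    """A trained model: an ensemble of identically structured networks whose
    per-row scores are averaged (ensembling tames the run-to-run variance of
    training on a few dozen blocks)."""

    members: list  # list of parameter dicts
    config: ModelConfig
    n_features: int
    history: list = field(default_factory=list)  # per-member loss histories
    best_epochs: list = field(default_factory=list)

    @property
    def params(self) -> dict:
        return self.members[0]

    def _check(self, maps: list[BlockFeatureMap]) -> None:
        for m in maps:
            if m.n_features != self.n_features:
                raise ValueError(
                    f"feature count mismatch: model has F={self.n_features}, "
                    f"map {m.block_id} has F={m.n_features}"
                )

    def row_score_matrix(self, maps: list[BlockFeatureMap]) -> np.ndarray:
        """Per-row ensemble scores, shape (n_maps, BLOCK_ROWS)."""
        self._check(maps)
        X, _ = _stack(maps)
        return np.mean([_row_scores(p, X)[0] for p in self.members], axis=0)

    def block_scores(self, maps: list[BlockFeatureMap]) -> np.ndarray:
        """Aggregated block scores of the ensemble-averaged row scores."""
        self._check(maps)
        X, mask = _stack(maps)
        p = np.mean([_row_scores(pp, X)[0] for pp in self.members], axis=0)
        return _aggregate(p, mask, self.config.aggregation, self.config.softmax_beta)

    def save(self, path) -> None:
        import json
        from dataclasses import asdict

        flat = {f"m{i}:{k}": v for i, pp in enumerate(self.members) for k, v in pp.items()}
        np.savez(path, **flat)
        with open(str(path) + ".json", "w") as fh:
            json.dump(asdict(self.config) | {"n_features": self.n_features}, fh, indent=1)


def _targets(maps: list[BlockFeatureMap], config: ModelConfig) -> np.ndarray:
    return np.array(
        [
            config.positive_label_confidence
            if m.label == "positive"
            else config.control_label_confidence
            for m in maps
        ]
    )


def train(
    split: DatasetSplit,
    config: ModelConfig,
    encoder_params: dict | list | None = None,
) -> TrainedPrioritizer:
    """Train the prioritizer on the training partition with soft-label BCE of
    the aggregated block score; per member, the epoch with the lowest
    validation loss is kept (training loss stands in when the validation
    partition is empty). ``encoder_params`` may be one encoder dict (shared
    by all members) or a per-member list as produced by
    :func:`pretrain_autoencoder`."""
    labels = {m.label for m in split.train}
    if labels != {"positive", "control"}:
        raise ValueError(f"training partition needs both classes, found {sorted(labels)}")
    F = split.train[0].n_features
    X, mask = _stack(split.train)
    q = _targets(split.train, config)
    if split.val:
        Xv, maskv = _stack(split.val)
        qv = _targets(split.val, config)
    n = len(split.train)

    members: list[dict] = []
    histories: list[dict] = []
    best_epochs: list[int] = []
    for k_member in range(config.ensemble_size):
        mseed = config.seed + 7919 * k_member
        params = _init_params(replace(config, seed=mseed), F)
        if encoder_params is not None:  # pretrained conv stack (per member or shared)
            enc = (
                encoder_params[k_member % len(encoder_params)]
                if isinstance(encoder_params, list)
                else encoder_params
            )
            for k, v in enc.items():
                params[k] = v.copy()
        for k in ("Wdec", "bdec"):  # decoder is pretraining-only
            params.pop(k, None)

        rng = np.random.default_rng(np.random.SeedSequence([mseed & 0x7FFFFFFF, 0x7472]))
        opt = _Adam(params, config.learning_rate, config.weight_decay)
        history = {"train_loss": [], "val_loss": []}
        best = (np.inf, -1, {k: v.copy() for k, v in params.items()})
        for epoch in range(config.train_epochs):
            order = rng.permutation(n)
            for lo in range(0, n, config.batch_size):
                sel = order[lo : lo + config.batch_size]
                Xb = X[sel]
                if config.input_dropout > 0:
                    # inverted feature dropout: no idiosyncratic column combo
                    # is reliable, so the head must pool over many features
                    keep = rng.random(Xb.shape) >= config.input_dropout
                    Xb = Xb * keep / (1.0 - config.input_dropout)
                _, grads = _classifier_grads(params, Xb, mask[sel], q[sel], config)
                opt.step(params, grads)
                if config.monotone:
                    _project_monotone(params)
            p, _ = _row_scores(params, X)
            tr_loss = soft_cross_entropy(_aggregate(p, mask, config.aggregation, config.softmax_beta), q)
            history["train_loss"].append(tr_loss)
            if split.val:
                pv, _ = _row_scores(params, Xv)
                sel_loss = soft_cross_entropy(_aggregate(pv, maskv, config.aggregation, config.softmax_beta), qv)
                history["val_loss"].append(sel_loss)
            else:
                sel_loss = tr_loss
            if sel_loss < best[0]:
                best = (sel_loss, epoch, {k: v.copy() for k, v in params.items()})
        if config.model_selection == "final":
            best = (sel_loss, config.train_epochs - 1, params)
        members.append(best[2])
        histories.append(history)
        best_epochs.append(best[1])

    if split.val and len(members) > 1:
        # keep only members that generalize: rank by held-out loss at their
        # selected epoch and drop any member far behind the best one — a
        # member that memorized the training blocks pollutes the ensemble
        # average. (Without a validation partition all members are kept; the
        # training loss cannot tell a memorizing member from a good one.)
        Xv2, maskv2 = _stack(split.val)
        qv2 = _targets(split.val, config)
        val_losses = [
            soft_cross_entropy(
                _aggregate(_row_scores(p, Xv2)[0], maskv2, config.aggregation, config.softmax_beta),
                qv2,
            )
            for p in members
        ]
        order = sorted(range(len(members)), key=lambda k: (val_losses[k], k))
        cutoff = val_losses[order[0]] + config.ensemble_val_margin
        keep = sorted(k for k in order[: min(config.ensemble_keep, len(members))] if val_losses[k] <= cutoff)
        members = [members[k] for k in keep]
        histories = [histories[k] for k in keep]
        best_epochs = [best_epochs[k] for k in keep]

    return TrainedPrioritizer(
        members=members, config=config, n_features=F, history=histories, best_epochs=best_epochs
    )


def predict_scores(
    model: TrainedPrioritizer, blocks: list[BlockFeatureMap]
) -> list[SnpScore]:
    """One SnpScore per valid SNP row of each map; deterministic given the
    model parameters."""
    p = model.row_score_matrix(blocks)
    out: list[SnpScore] = []
    for i, m in enumerate(blocks):
        for r in range(m.n_valid):
            out.append(
                SnpScore(
                    snp_id=m.snp_ids[r],
                    block_id=m.block_id,
                    trait=m.trait,
                    score=float(p[i, r]),
                    pos=int(m.positions[r]),
                    pvalue=float(m.pvalues[r]),
                )
            )
    return out


def select_candidates(
    scores: list[SnpScore], threshold: float = DEFAULT_SCORE_THRESHOLD
) -> list[SnpScore]:
    """Initial risk-SNP candidates: score strictly greater than the threshold
    (a score exactly at the threshold is not a candidate)."""
    return [replace(s, is_initial_candidate=True) for s in scores if s.score > threshold]


def select_block_top(candidates: list[SnpScore]) -> list[SnpScore]:
    """Within each block holding at least one candidate, flag exactly the
    highest-scoring candidate (ties: lower p-value, then lower position, then
    SNP id)."""
    by_block: dict[str, list[SnpScore]] = {}
    for s in candidates:
        by_block.setdefault(s.block_id, []).append(s)
    tops = []
    for block_id in sorted(by_block):
        best = min(by_block[block_id], key=lambda s: (-s.score, s.pvalue, s.pos, s.snp_id))
        tops.append(replace(best, is_block_top=True))
    return tops


def evaluate_auc(model: TrainedPrioritizer, test_blocks: list[BlockFeatureMap]) -> EvalReport:
    """Block-level ROC AUC (Mann-Whitney; ties count 1/2) of aggregated
    scores against positive/control labels on the test partition."""
    from sklearn.metrics import roc_auc_score

    if not test_blocks:
        raise ValueError("empty test partition")
    y = np.array([1 if m.label == "positive" else 0 for m in test_blocks])
    if len(set(y.tolist())) < 2:
        raise ValueError("test partition holds a single class; AUC undefined")
    s = model.block_scores(test_blocks)
    return EvalReport(auc=float(roc_auc_score(y, s)), n_test_blocks=len(test_blocks))


def permute_labels(maps: list[BlockFeatureMap], rng: np.random.Generator) -> list[BlockFeatureMap]:
    """Randomly reassign the positive/control labels (and their confidences)
    among maps — the permutation null for calibration checks."""
    labels = [(m.label, m.label_confidence) for m in maps]
    perm = rng.permutation(len(maps))
    return [
        replace(m, label=labels[j][0], label_confidence=labels[j][1])
        for m, j in zip(maps, perm)
    ]


def write_scores(scores: list[SnpScore], chrom_of: dict, path) -> None:
    """Tab-delimited score table: snp_id chrom pos trait block_id score
    candidate block_top."""
    with open(path, "w") as fh:
        fh.write("snp_id\tchrom\tpos\ttrait\tblock_id\tscore\tcandidate\tblock_top\n")
        for s in scores:
            fh.write(
                f"{s.snp_id}\t{chrom_of.get(s.block_id, '.')}\t{s.pos}\t{s.trait}\t"
                f"{s.block_id}\t{s.score:.6f}\t{int(s.is_initial_candidate)}\t{int(s.is_block_top)}\n"
            )
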