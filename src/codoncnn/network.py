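"""Per-transcript convolutional encoders with a shared k-class head.

Each transcript's N x 64 codon one-hot matrix is treated as a 1-D signal
with 64 channels and passed through a stack of d identical blocks:

    same-padded 1-D convolution (kernel 3, stride 1)
    -> LeakyReLU
    -> average pooling (kernel 6, stride 6, ceil mode)

The first block maps 64 -> C channels (C = 6 by default), later blocks
C -> C. Ceil-mode pooling shrinks the length by a factor of 6 per block, so
d = ceil(log6 N) blocks (minimum one) reduce any transcript to length
exactly 1; a per-channel affine then yields a C-vector per transcript. The
T per-transcript C-vectors are concatenated and a fully connected layer
maps the (T*C)-vector to k class scores. Encoders have independent
parameters per transcript (lengths and depths differ).

Training minimises softmax cross-entropy with Adam. Everything — parameter
initialisation, mini-batch order, and the optimiser — is driven by one seed,
so a run is exactly reproducible.

Implemented directly on NumPy: convolution is lowered to a matrix product
over sliding windows, and backward passes are hand-derived, which keeps the
model dependency-free and bitwise deterministic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .encoding import EncodedCohort


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture hyper-parameters of the per-transcript encoder."""

    input_channels: int = 64
    conv_kernel: int = 3
    pool_kernel: int = 6
    output_channels: int = 6
    leaky_slope: float = 0.01

    def __post_init__(self) -> None:
        if self.input_channels != 64:
            raise ValueError("input_channels is fixed to the 64-codon alphabet")
        for name in ("conv_kernel", "pool_kernel", "output_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.leaky_slope <= 0:
            raise ValueError("leaky_slope must be positive")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyper-parameters."""

    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 30
    split_ratio: tuple[float, float, float] = (7.0, 1.0, 2.0)
    seed: int = 0


def encoder_depth(codon_count: int, pool_kernel: int = 6) -> int:
    """Number of conv blocks needed to pool a length-N signal down to 1.

    Equals ceil(log_P N) with a floor of one block; computed by iterating
    ceil division so exact powers of P are never misrounded.
    """
    if codon_count < 1:
        raise ValueError("codon_count must be >= 1")
    if pool_kernel < 2:
        raise ValueError("pool_kernel must be >= 2")
    depth = 0
    length = codon_count
    while length > 1:
        length = -(-length // pool_kernel)
        depth += 1
    return max(depth, 1)


def pooled_lengths(codon_count: int, pool_kernel: int, depth: int) -> list[int]:
    """Signal length after each of ``depth`` ceil-mode pooling steps."""
    lengths = []
    length = codon_count
    for _ in range(depth):
        length = -(-length // pool_kernel)
        lengths.append(length)
    return lengths


# ---------------------------------------------------------------------------
# primitive layers (forward + hand-derived backward)
# ---------------------------------------------------------------------------


def _conv1d_forward(X: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Same-padded stride-1 1-D convolution in channel-last layout.

    X: (B, L, Cin); W: (K, Cin, Cout); b: (Cout,) -> Y: (B, L, Cout).
    Evaluated as K shifted GEMMs, which avoids materialising an im2col
    window matrix; the padded input is cached for the backward pass.
    """
    B, L, Cin = X.shape
    K = W.shape[0]
    pl = K // 2
    Xp = np.pad(X, ((0, 0), (pl, K - 1 - pl), (0, 0)))
    Y = np.broadcast_to(b, (B, L, W.shape[2])).copy()
    for k in range(K):
        Y += Xp[:, k : k + L, :] @ W[k]
    return Y, (Xp, L)


def _conv1d_backward(dY: np.ndarray, W: np.ndarray, cache):
    Xp, L = cache
    K = W.shape[0]
    pl = K // 2
    dW = np.empty_like(W)
    for k in range(K):
        dW[k] = np.tensordot(Xp[:, k : k + L, :], dY, axes=([0, 1], [0, 1]))
    db = dY.sum(axis=(0, 1))
    dXp = np.zeros_like(Xp)
    for k in range(K):
        dXp[:, k : k + L, :] += dY @ W[k].T
    dX = dXp[:, pl : pl + L, :]
    return dX, dW, db


def _embed_conv_forward(idx: np.ndarray, W: np.ndarray, b: np.ndarray):
    """First conv layer evaluated directly on codon indices.

    The input is one-hot over 64 codon channels, so the convolution reduces
    to gathering weight rows by codon index and summing over the kernel
    taps: Y[s, l] = b + sum_k W[k, idx[s, l+k-pl]]. Sentinel (pad/N) rows
    contribute zero, matching the all-zero one-hot convention.

    idx: (B, L) int with -1 sentinel; W: (K, 64, Cout) -> Y: (B, L, Cout).
    """
    B, L = idx.shape
    K, _, Cout = W.shape
    pl = K // 2
    idxp = np.full((B, L + K - 1), -1, dtype=idx.dtype)
    idxp[:, pl : pl + L] = idx
    Y = np.broadcast_to(b, (B, L, Cout)).copy()
    zero_row = np.zeros((1, Cout), dtype=W.dtype)
    for k in range(K):
        Wk = np.concatenate([W[k], zero_row])  # index -1 selects the zero row
        Y += Wk[idxp[:, k : k + L]]
    return Y, idxp


def _embed_conv_backward(dY: np.ndarray, W: np.ndarray, idxp: np.ndarray):
    """Weight gradients of the index-gather conv (no input gradient needed)."""
    B, L, Cout = dY.shape
    K = W.shape[0]
    dW = np.zeros_like(W)
    dY2 = dY.reshape(B * L, Cout)
    for k in range(K):
        cols = idxp[:, k : k + L].reshape(-1)
        valid = cols >= 0
        np.add.at(dW[k], cols[valid], dY2[valid])
    db = dY.sum(axis=(0, 1))
    return dW, db


def _leaky_relu_forward(X: np.ndarray, slope: float):
    neg = X < 0
    Y = np.where(neg, slope * X, X)
    return Y, neg


def _leaky_relu_backward(dY: np.ndarray, neg: np.ndarray, slope: float):
    return np.where(neg, slope * dY, dY)


def _avgpool_forward(X: np.ndarray, kernel: int):
    """Ceil-mode average pooling (stride == kernel) in channel-last layout.

    The trailing partial window (if any) averages over the elements actually
    present rather than over zero padding, so a shorter tail is not damped.
    """
    B, L, C = X.shape
    Lout = -(-L // kernel)
    pad = Lout * kernel - L
    Xp = np.pad(X, ((0, 0), (0, pad), (0, 0))) if pad else X
    counts = np.full(Lout, kernel, dtype=X.dtype)
    if pad:
        counts[-1] = L - (Lout - 1) * kernel
    Y = Xp.reshape(B, Lout, kernel, C).sum(axis=2) / counts[:, None]
    return Y, (L, counts)


def _avgpool_backward(dY: np.ndarray, kernel: int, cache):
    L, counts = cache
    dXp = np.repeat(dY / counts[:, None], kernel, axis=1)
    return dXp[:, :L, :]


def _softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and gradient w.r.t. logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    expz = np.exp(z)
    probs = expz / expz.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.mean(np.log(probs[np.arange(n), labels] + 1e-12))
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return float(loss), dlogits


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


@dataclass
class TranscriptEncoderSpec:
    transcript_id: str
    codon_count: int
    depth: int


class ConvNetClassifier:
    """The per-transcript encoder stack plus fully connected class head."""

    def __init__(
        self,
        transcripts: list[tuple[str, int]],
        encoder_config: EncoderConfig = EncoderConfig(),
        class_count: int = 2,
    ) -> None:
        if not transcripts:
            raise ValueError("transcript list must be non-empty")
        if class_count < 2:
            raise ValueError("class_count must be >= 2")
        self.config = encoder_config
        self.class_count = class_count
        self.encoders = [
            TranscriptEncoderSpec(
                transcript_id=tid,
                codon_count=n,
                depth=encoder_depth(n, encoder_config.pool_kernel),
            )
            for tid, n in transcripts
        ]
        self.params: dict[str, np.ndarray] = {}
        self.history: dict[str, list[float]] = {"train_loss": [], "val_accuracy": []}

    # -- structure ---------------------------------------------------------

    @property
    def transcript_ids(self) -> list[str]:
        return [e.transcript_id for e in self.encoders]

    @property
    def head_input_dim(self) -> int:
        return len(self.encoders) * self.config.output_channels

    def _layer_channels(self, depth: int) -> list[tuple[int, int]]:
        C = self.config.output_channels
        return [(self.config.input_channels if i == 0 else C, C) for i in range(depth)]

    def initialize(self, rng: np.random.Generator) -> None:
        """Variance-preserving uniform initialisation.

        Each encoder block shrinks activation variance through the LeakyReLU
        (factor (1 + slope^2)/2) and through average pooling over
        ``pool_kernel`` positions (factor ~1/pool_kernel for weakly
        correlated inputs). The conv weight scale compensates both, so
        activations keep an O(1) scale at any depth instead of collapsing
        geometrically — without it the deeper encoders emit features of
        order 1e-6 and the head cannot train in 30 epochs.
        """
        cfg = self.config
        gain_sq = 2.0 / (1.0 + cfg.leaky_slope**2) * cfg.pool_kernel
        p: dict[str, np.ndarray] = {}
        for e in self.encoders:
            for i, (cin, cout) in enumerate(self._layer_channels(e.depth)):
                s = math.sqrt(3.0 * gain_sq / (cin * cfg.conv_kernel))
                p[f"conv_W/{e.transcript_id}/{i}"] = rng.uniform(
                    -s, s, (cfg.conv_kernel, cin, cout)
                ).astype(np.float32)
                p[f"conv_b/{e.transcript_id}/{i}"] = np.zeros(cout, dtype=np.float32)
            # per-channel affine on the length-1 encoder output
            p[f"affine_w/{e.transcript_id}"] = rng.uniform(
                -1.0, 1.0, cfg.output_channels
            ).astype(np.float32)
            p[f"affine_b/{e.transcript_id}"] = rng.uniform(
                -1.0, 1.0, cfg.output_channels
            ).astype(np.float32)
        # the head starts at zero: encoder features are standardised by
        # calibration, and a zero head gives uniform class probabilities at
        # step 0 instead of random projections of init noise
        p["head_W"] = np.zeros(
            (self.head_input_dim, self.class_count), dtype=np.float32
        )
        p["head_b"] = np.zeros(self.class_count, dtype=np.float32)
        self.params = p

    def calibrate(self, cohort: EncodedCohort, probe_idx: np.ndarray) -> None:
        """Layer-sequential scale calibration on a probe batch.

        The variance each block preserves depends on the correlation
        structure of real codon data, which no static weight scale can
        anticipate across transcripts of very different lengths and depths.
        After random initialisation, each conv layer's pre-activations are
        standardised per channel on the probe batch by folding the centering
        and scaling into the layer's weights and bias. This (a) keeps
        activations O(1) at any depth instead of collapsing geometrically,
        and (b) centres every channel on the LeakyReLU kink, so no channel
        starts stuck in the slow 0.01-slope regime. The per-channel affine
        is then set to standardise the final encoder output, so every
        transcript feeds the head zero-mean, unit-variance features
        regardless of its depth. Deterministic for a fixed probe.
        """
        cfg = self.config
        for e in self.encoders:
            idx = cohort.indices[e.transcript_id][probe_idx]
            h = None
            for i in range(e.depth):
                w_key = f"conv_W/{e.transcript_id}/{i}"
                b_key = f"conv_b/{e.transcript_id}/{i}"
                if i == 0:
                    pre, _ = _embed_conv_forward(idx, self.params[w_key], self.params[b_key])
                else:
                    pre, _ = _conv1d_forward(h, self.params[w_key], self.params[b_key])
                mu = pre.mean(axis=(0, 1))
                sd = np.maximum(pre.std(axis=(0, 1)), 1e-6)
                self.params[w_key] /= sd
                self.params[b_key] = ((self.params[b_key] - mu) / sd).astype(np.float32)
                pre = (pre - mu) / sd
                h, _ = _leaky_relu_forward(pre, cfg.leaky_slope)
                h, _ = _avgpool_forward(h, cfg.pool_kernel)
            vec = h[:, 0, :]
            sd = np.maximum(vec.std(axis=0), 1e-6)
            self.params[f"affine_w/{e.transcript_id}"] = (1.0 / sd).astype(np.float32)
            self.params[f"affine_b/{e.transcript_id}"] = (
                -vec.mean(axis=0) / sd
            ).astype(np.float32)

    # -- forward / backward ------------------------------------------------

    def _encoder_forward(self, e: TranscriptEncoderSpec, idx: np.ndarray, caches):
        cfg = self.config
        layer_caches = []
        h = None
        for i in range(e.depth):
            W = self.params[f"conv_W/{e.transcript_id}/{i}"]
            b = self.params[f"conv_b/{e.transcript_id}/{i}"]
            if i == 0:
                h, conv_cache = _embed_conv_forward(idx, W, b)
            else:
                h, conv_cache = _conv1d_forward(h, W, b)
            h, neg = _leaky_relu_forward(h, cfg.leaky_slope)
            h, pool_cache = _avgpool_forward(h, cfg.pool_kernel)
            layer_caches.append((conv_cache, neg, pool_cache))
        vec = h[:, 0, :]  # length is exactly 1 after the final pool
        out = vec * self.params[f"affine_w/{e.transcript_id}"] + self.params[
            f"affine_b/{e.transcript_id}"
        ]
        if caches is not None:
            caches[e.transcript_id] = (layer_caches, vec)
        return out

    def forward(
        self, cohort: EncodedCohort, sample_idx: np.ndarray, caches: dict | None = None
    ) -> np.ndarray:
        """Class logits (batch, k) for the given cohort rows."""
        parts = []
        for e in self.encoders:
            idx = cohort.indices[e.transcript_id][sample_idx]
            parts.append(self._encoder_forward(e, idx, caches))
        feats = np.concatenate(parts, axis=1)  # (B, T*C)
        if caches is not None:
            caches["head_feats"] = feats
        return feats @ self.params["head_W"] + self.params["head_b"]

    def backward(self, dlogits: np.ndarray, caches: dict) -> dict[str, np.ndarray]:
        cfg = self.config
        C = cfg.output_channels
        feats = caches["head_feats"]
        grads: dict[str, np.ndarray] = {
            "head_W": feats.T @ dlogits,
            "head_b": dlogits.sum(axis=0),
        }
        dfeats = dlogits @ self.params["head_W"].T
        for t_index, e in enumerate(self.encoders):
            dout = dfeats[:, t_index * C : (t_index + 1) * C]
            layer_caches, vec = caches[e.transcript_id]
            grads[f"affine_w/{e.transcript_id}"] = (dout * vec).sum(axis=0)
            grads[f"affine_b/{e.transcript_id}"] = dout.sum(axis=0)
            dh = (dout * self.params[f"affine_w/{e.transcript_id}"])[:, None, :]
            for i in range(e.depth - 1, -1, -1):
                conv_cache, neg, pool_cache = layer_caches[i]
                dh = _avgpool_backward(dh, cfg.pool_kernel, pool_cache)
                dh = _leaky_relu_backward(dh, neg, cfg.leaky_slope)
                W = self.params[f"conv_W/{e.transcript_id}/{i}"]
                if i == 0:
                    dW, db = _embed_conv_backward(dh, W, conv_cache)
                else:
                    dh, dW, db = _conv1d_backward(dh, W, conv_cache)
                grads[f"conv_W/{e.transcript_id}/{i}"] = dW
                grads[f"conv_b/{e.transcript_id}/{i}"] = db
        return grads

    # -- head inspection ---------------------------------------------------

    def head_block(self, transcript_id: str) -> np.ndarray:
        """The (C, k) slice of the head weights fed by one transcript."""
        C = self.config.output_channels
        t_index = self.transcript_ids.index(transcript_id)
        return self.params["head_W"][t_index * C : (t_index + 1) * C, :]

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Checkpoint config + named weight arrays to an .npz archive."""
        meta = {
            "encoder_config": asdict(self.config),
            "class_count": self.class_count,
            "transcripts": [(e.transcript_id, e.codon_count) for e in self.encoders],
            "history": self.history,
        }
        np.savez(path, __meta__=json.dumps(meta), **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "ConvNetClassifier":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            model = cls(
                transcripts=[(t, int(n)) for t, n in meta["transcripts"]],
                encoder_config=EncoderConfig(**meta["encoder_config"]),
                class_count=meta["class_count"],
            )
            model.params = {k: data[k] for k in data.files if k != "__meta__"}
            model.history = meta["history"]
        return model


def build_model(
    transcripts: list[tuple[str, int]],
    encoder_config: EncoderConfig = EncoderConfig(),
    class_count: int = 2,
) -> ConvNetClassifier:
    """Construct the (untrained) per-transcript encoder + head architecture."""
    return ConvNetClassifier(transcripts, encoder_config, class_count)


# ---------------------------------------------------------------------------
# data splitting, training, prediction
# ---------------------------------------------------------------------------


def split_dataset(
    n_samples: int,
    ratio: tuple[float, float, float] = (7.0, 1.0, 2.0),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random disjoint train/validation/test index sets.

    Sizes follow the normalised ratio to within rounding, each part gets at
    least one sample, and the partition is a pure function of the seed.
    """
    if n_samples < 3:
        raise ValueError("need at least 3 samples to split")
    fr = np.asarray(ratio, dtype=float)
    if fr.shape != (3,) or np.any(fr <= 0):
        raise ValueError(f"split ratio must be 3 positive numbers, got {ratio!r}")
    fr = fr / fr.sum()
    sizes = np.floor(n_samples * fr).astype(int)
    # largest-remainder apportionment of the leftover samples
    remainder = n_samples * fr - sizes
    for i in np.argsort(-remainder)[: n_samples - sizes.sum()]:
        sizes[i] += 1
    # guarantee non-empty parts
    while np.any(sizes == 0):
        sizes[int(np.argmin(sizes))] += 1
        sizes[int(np.argmax(sizes))] -= 1
    perm = np.random.default_rng(seed).permutation(n_samples)
    train = perm[: sizes[0]]
    val = perm[sizes[0] : sizes[0] + sizes[1]]
    test = perm[sizes[0] + sizes[1] :]
    return np.sort(train), np.sort(val), np.sort(test)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            g = g.astype(np.float32)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )


def train(
    model: ConvNetClassifier,
    cohort: EncodedCohort,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    config: TrainConfig = TrainConfig(),
) -> ConvNetClassifier:
    """Fit the model with mini-batch Adam on softmax cross-entropy.

    The validation set is used only to record per-epoch accuracy; the
    returned parameters are those of the last epoch. Fully deterministic
    given ``config.seed``.
    """
    if cohort.labels is None:
        raise ValueError("cohort has no labels")
    if cohort.labels.min() < 0 or cohort.labels.max() >= model.class_count:
        raise ValueError(
            f"labels must lie in [0, {model.class_count}), found range "
            f"[{cohort.labels.min()}, {cohort.labels.max()}]"
        )
    missing = [t.transcript_id for t in model.encoders if t.transcript_id not in cohort.indices]
    if missing:
        raise ValueError(f"cohort lacks transcripts required by the model: {missing}")
    for e in model.encoders:
        if cohort.indices[e.transcript_id].shape[1] != e.codon_count:
            raise ValueError(
                f"transcript {e.transcript_id!r}: cohort row count "
                f"{cohort.indices[e.transcript_id].shape[1]} != model codon count "
                f"{e.codon_count}"
            )

    rng = np.random.default_rng(config.seed)
    model.initialize(rng)
    train_idx = np.asarray(train_idx)
    model.calibrate(cohort, train_idx)
    optimizer = _Adam(model.params, config.learning_rate)
    model.history = {"train_loss": [], "val_accuracy": []}

    train_idx = np.asarray(train_idx)
    for _epoch in range(config.epochs):
        order = rng.permutation(len(train_idx))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = train_idx[order[start : start + config.batch_size]]
            caches: dict = {}
            logits = model.forward(cohort, batch, caches)
            loss, dlogits = _softmax_cross_entropy(logits, cohort.labels[batch])
            grads = model.backward(dlogits.astype(np.float32), caches)
            optimizer.step(model.params, grads)
            epoch_loss += loss * len(batch)
        model.history["train_loss"].append(epoch_loss / len(train_idx))
        if len(val_idx):
            _, val_pred = predict(model, cohort, val_idx)
            val_acc = float(np.mean(val_pred == cohort.labels[val_idx]))
        else:
            val_acc = float("nan")
        model.history["val_accuracy"].append(val_acc)
    return model


def predict(
    model: ConvNetClassifier,
    cohort: EncodedCohort,
    sample_idx: np.ndarray | None = None,
    batch_size: int = 256,
) -> tuple[np.ndarray, np.ndarray]:
    """Class scores (n, k) and argmax labels (ties go to the lowest index)."""
    if sample_idx is None:
        sample_idx = np.arange(cohort.n_samples)
    sample_idx = np.asarray(sample_idx)
    scores = np.empty((len(sample_idx), model.class_count), dtype=np.float32)
    for start in range(0, len(sample_idx), batch_size):
        chunk = sample_idx[start : start + batch_size]
        scores[start : start + len(chunk)] = model.forward(cohort, chunk)
    return scores, scores.argmax(axis=1)
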