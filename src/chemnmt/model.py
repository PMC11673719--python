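"""Encoder-decoder transformer for sequence-to-sequence chemical translation.

The architecture follows the classical attention-based encoder-decoder
design: learned token embeddings scaled by sqrt(d_model), sinusoidal
positional encodings, multi-head scaled dot-product attention (causal
self-attention in the decoder, padding masks on both streams), position-wise
feed-forward blocks in pre-norm residual arrangement (x + Sublayer(LN(x)),
final LN per stack), and the inverse-square-root warmup learning-rate
schedule.  Training uses teacher forcing with a sparse categorical
cross-entropy that ignores padding positions.

Two presets ship with the package: the full-scale configuration (4 layers,
8 heads, d_model 512, dff 2048, dropout 0.1) and a desk-scale preset
(2 layers, 4 heads, d_model 128, dff 512) sized so that the whole pipeline —
corpus synthesis, training, decoding, round-trip evaluation — runs on one CPU
in minutes.  Accuracy figures from the desk preset characterise the pipeline,
not the full-scale model.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import DTYPE, Tensor
from .tokens import PAD_ID

NEG_INF = -1e9


@dataclass
class ModelConfig:
    """All transformer and optimisation hyperparameters."""

    num_layers: int = 4
    num_heads: int = 8
    d_model: int = 512
    dff: int = 2048
    dropout_rate: float = 0.1
    input_vocab: int = 0
    target_vocab: int = 0
    max_input_len: int = 600
    max_target_len: int = 702
    warmup_steps: int = 4000
    batch_size: int = 96
    seed: int = 0
    # Adam moments follow the original transformer formulation.
    beta1: float = 0.9
    beta2: float = 0.98
    epsilon: float = 1e-9
    label_smoothing: float = 0.0  # exposed; default off
    grad_clip: float = 0.0  # exposed; 0 disables clipping

    def __post_init__(self) -> None:
        if self.d_model % self.num_heads != 0:
            raise ValueError("d_model must be divisible by num_heads")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.max_input_len <= 0 or self.max_target_len <= 0:
            raise ValueError("sequence lengths must be positive")

    @classmethod
    def full_scale(cls, **kw) -> "ModelConfig":
        return cls(**kw)

    @classmethod
    def desk_scale(cls, **kw) -> "ModelConfig":
        kw.setdefault("num_layers", 2)
        kw.setdefault("num_heads", 4)
        kw.setdefault("d_model", 128)
        kw.setdefault("dff", 512)
        kw.setdefault("batch_size", 64)
        return cls(**kw)


@dataclass
class TrainState:
    step: int
    epoch: int
    train_loss: float
    train_accuracy: float
    checkpoint_path: str | None = None


def learning_rate(step: int, d_model: int, warmup_steps: int) -> float:
    """Inverse-square-root schedule with linear warmup.

    lr = d_model^-0.5 * min(step^-0.5, step * warmup^-1.5)
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    step_f = float(step)
    return d_model ** -0.5 * min(step_f ** -0.5, step_f * warmup_steps ** -1.5)


def masked_loss(labels: np.ndarray, logits: np.ndarray, pad_id: int = PAD_ID) -> float:
    """Mean sparse categorical cross-entropy over non-pad positions.

    Returns 0.0 when every position is padding.
    """
    labels = np.asarray(labels)
    logits = np.asarray(logits, dtype=np.float64)
    if logits.shape[:-1] != labels.shape:
        raise ValueError(f"shape mismatch: labels {labels.shape} vs logits {logits.shape}")
    mask = labels != pad_id
    n = int(mask.sum())
    if n == 0:
        return 0.0
    z = logits - logits.max(axis=-1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    idx = np.indices(labels.shape)
    picked = logp[(*idx, labels)]
    return float(-(picked * mask).sum() / n)


def masked_accuracy(labels: np.ndarray, logits: np.ndarray, pad_id: int = PAD_ID) -> float:
    """Fraction of non-pad positions where argmax(logits) == label."""
    labels = np.asarray(labels)
    logits = np.asarray(logits)
    mask = labels != pad_id
    n = int(mask.sum())
    if n == 0:
        return 0.0
    correct = (logits.argmax(axis=-1) == labels) & mask
    return float(correct.sum() / n)


def sinusoidal_encoding(length: int, d_model: int) -> np.ndarray:
    pos = np.arange(length)[:, None].astype(np.float64)
    i = np.arange(d_model)[None, :].astype(np.float64)
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
    enc = np.empty((length, d_model))
    enc[:, 0::2] = np.sin(angle[:, 0::2])
    enc[:, 1::2] = np.cos(angle[:, 1::2])
    return enc.astype(DTYPE)


class Transformer:
    """A seeded, deterministic encoder-decoder transformer."""

    def __init__(self, config: ModelConfig):
        if config.input_vocab < 5 or config.target_vocab < 5:
            raise ValueError("vocab sizes must include the 4 specials plus tokens")
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, dff = config.d_model, config.dff
        self.params: dict[str, Tensor] = {}

        def glorot(name: str, fan_in: int, fan_out: int) -> None:
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            self.params[name] = ad.parameter(
                rng.uniform(-lim, lim, size=(fan_in, fan_out))
            )

        def zeros(name: str, *shape: int) -> None:
            self.params[name] = ad.parameter(np.zeros(shape))

        def ones(name: str, *shape: int) -> None:
            self.params[name] = ad.parameter(np.ones(shape))

        self.params["emb_in"] = ad.parameter(
            rng.normal(0.0, d ** -0.5, size=(config.input_vocab, d))
        )
        self.params["emb_out"] = ad.parameter(
            rng.normal(0.0, d ** -0.5, size=(config.target_vocab, d))
        )
        for side, layers in (("enc", config.num_layers), ("dec", config.num_layers)):
            for l in range(layers):
                p = f"{side}{l}"
                n_attn = 2 if side == "dec" else 1
                for a in range(n_attn):
                    for w in ("q", "k", "v", "o"):
                        glorot(f"{p}.a{a}.W{w}", d, d)
                        zeros(f"{p}.a{a}.b{w}", d)
                    ones(f"{p}.a{a}.g", d)
                    zeros(f"{p}.a{a}.b", d)
                glorot(f"{p}.ffn.W1", d, dff)
                zeros(f"{p}.ffn.b1", dff)
                glorot(f"{p}.ffn.W2", dff, d)
                zeros(f"{p}.ffn.b2", d)
                ones(f"{p}.ffn.g", d)
                zeros(f"{p}.ffn.b", d)
            ones(f"{side}.final.g", d)
            zeros(f"{side}.final.b", d)
        glorot("out.W", d, config.target_vocab)
        zeros("out.b", config.target_vocab)

        max_len = max(config.max_input_len, config.max_target_len)
        self._pos = sinusoidal_encoding(max_len, d)
        self._causal_cache: dict[int, np.ndarray] = {}

    # -- plumbing -----------------------------------------------------------

    def count_params(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    def _pad_mask(self, ids: np.ndarray) -> np.ndarray:
        # (B, 1, 1, L) additive mask
        return np.where(ids == PAD_ID, NEG_INF, 0.0).astype(DTYPE)[:, None, None, :]

    def _causal_mask(self, length: int) -> np.ndarray:
        if length not in self._causal_cache:
            m = np.triu(np.full((length, length), NEG_INF, dtype=DTYPE), k=1)
            self._causal_cache[length] = m[None, None, :, :]
        return self._causal_cache[length]

    def _mha(self, prefix: str, xq: Tensor, xkv: Tensor, mask: np.ndarray,
             rng) -> Tensor:
        """Pre-norm multi-head attention block: x + Drop(Attn(LN(x)))."""
        cfg = self.config
        d, h = cfg.d_model, cfg.num_heads
        dh = d // h
        B, Lq = xq.shape[0], xq.shape[1]
        Lk = xkv.shape[1]
        P = self.params
        nq = ad.layer_norm(xq, P[f"{prefix}.g"], P[f"{prefix}.b"])
        nkv = nq if xkv is xq else xkv  # cross-attn keys come pre-normalised

        def proj(x: Tensor, w: str, L: int) -> Tensor:
            y = x.reshape(-1, d).matmul(P[f"{prefix}.W{w}"]) + P[f"{prefix}.b{w}"]
            return y.reshape(B, L, h, dh).transpose(0, 2, 1, 3)  # (B,h,L,dh)

        q = proj(nq, "q", Lq)
        k = proj(nkv, "k", Lk)
        v = proj(nkv, "v", Lk)
        scores = q.matmul(k.transpose(0, 1, 3, 2)) * DTYPE(dh ** -0.5)
        scores = scores + Tensor(mask)
        attn = ad.softmax(scores)
        attn = ad.dropout(attn, cfg.dropout_rate, rng)
        ctx = attn.matmul(v).transpose(0, 2, 1, 3).reshape(-1, d)
        out = ctx.matmul(P[f"{prefix}.Wo"]) + P[f"{prefix}.bo"]
        out = out.reshape(B, Lq, d)
        out = ad.dropout(out, cfg.dropout_rate, rng)
        return xq + out

    def _ffn(self, prefix: str, x: Tensor, rng) -> Tensor:
        """Pre-norm feed-forward block: x + Drop(W2 relu(W1 LN(x)))."""
        cfg = self.config
        d = cfg.d_model
        P = self.params
        B, L = x.shape[0], x.shape[1]
        n = ad.layer_norm(x, P[f"{prefix}.g"], P[f"{prefix}.b"])
        h = n.reshape(-1, d).matmul(P[f"{prefix}.W1"]) + P[f"{prefix}.b1"]
        h = h.relu()
        y = h.matmul(P[f"{prefix}.W2"]) + P[f"{prefix}.b2"]
        y = y.reshape(B, L, d)
        y = ad.dropout(y, cfg.dropout_rate, rng)
        return x + y

    def _positional(self, length: int) -> np.ndarray:
        # decoding may run past the training lengths; grow the table lazily
        if length > self._pos.shape[0]:
            self._pos = sinusoidal_encoding(length, self.config.d_model)
        return self._pos[:length]

    def _embed(self, table: Tensor, ids: np.ndarray, rng) -> Tensor:
        d = self.config.d_model
        x = ad.embedding(table, ids) * DTYPE(np.sqrt(d))
        x = x + Tensor(self._positional(ids.shape[1])[None])
        return ad.dropout(x, self.config.dropout_rate, rng)

    # -- forward ------------------------------------------------------------

    def encode(self, inp_ids: np.ndarray, rng=None) -> Tensor:
        pad = self._pad_mask(inp_ids)
        x = self._embed(self.params["emb_in"], inp_ids, rng)
        for l in range(self.config.num_layers):
            x = self._mha(f"enc{l}.a0", x, x, pad, rng)
            x = self._ffn(f"enc{l}.ffn", x, rng)
        return ad.layer_norm(x, self.params["enc.final.g"],
                             self.params["enc.final.b"])

    def decode(self, enc_out: Tensor, inp_ids: np.ndarray, dec_ids: np.ndarray,
               rng=None) -> Tensor:
        cfg = self.config
        self_mask = self._causal_mask(dec_ids.shape[1]) + self._pad_mask(dec_ids)
        cross_mask = self._pad_mask(inp_ids)
        x = self._embed(self.params["emb_out"], dec_ids, rng)
        for l in range(cfg.num_layers):
            x = self._mha(f"dec{l}.a0", x, x, self_mask, rng)
            x = self._mha(f"dec{l}.a1", x, enc_out, cross_mask, rng)
            x = self._ffn(f"dec{l}.ffn", x, rng)
        x = ad.layer_norm(x, self.params["dec.final.g"],
                          self.params["dec.final.b"])
        B, L = dec_ids.shape
        logits = x.reshape(-1, cfg.d_model).matmul(self.params["out.W"])
        logits = logits + self.params["out.b"]
        return logits.reshape(B, L, cfg.target_vocab)

    def forward(self, inp_ids: np.ndarray, dec_ids: np.ndarray, rng=None) -> Tensor:
        return self.decode(self.encode(inp_ids, rng), inp_ids, dec_ids, rng)

    # -- persistence --------------------------------------------------------

    def save(self, directory: str | Path, extra: dict | None = None) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "config.json", "w", encoding="utf-8") as fh:
            json.dump(asdict(self.config), fh, indent=1)
        np.savez(directory / "weights.npz",
                 **{k: v.data for k, v in self.params.items()})
        if extra:
            np.savez(directory / "optimizer.npz", **extra)

    @classmethod
    def load(cls, directory: str | Path) -> "Transformer":
        directory = Path(directory)
        with open(directory / "config.json", encoding="utf-8") as fh:
            config = ModelConfig(**json.load(fh))
        model = cls(config)
        weights = np.load(directory / "weights.npz")
        for k in model.params:
            model.params[k].data = weights[k].astype(DTYPE)
        return model


def build_transformer(config: ModelConfig) -> Transformer:
    """Construct a seeded transformer; identical config+seed => identical weights."""
    return Transformer(config)


class Adam:
    def __init__(self, params: dict[str, Tensor], config: ModelConfig, step: int = 0):
        self.params = params
        self.cfg = config
        self.step = step
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def update(self) -> float:
        cfg = self.cfg
        self.step += 1
        lr = learning_rate(self.step, cfg.d_model, cfg.warmup_steps)
        b1, b2, eps = cfg.beta1, cfg.beta2, cfg.epsilon
        if cfg.grad_clip > 0:
            norm = np.sqrt(sum(float((p.grad ** 2).sum())
                               for p in self.params.values() if p.grad is not None))
            scale = min(1.0, cfg.grad_clip / (norm + 1e-12))
        else:
            scale = 1.0
        f32 = np.float32
        b1f, b2f = f32(b1), f32(b2)
        bc1 = f32(1.0 - b1 ** self.step)
        bc2 = f32(1.0 - b2 ** self.step)
        lrf, epsf = f32(lr), f32(eps)
        scalef = f32(scale)
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad * scalef
            self.m[k] = b1f * self.m[k] + (1 - b1f) * g
            self.v[k] = b2f * self.v[k] + (1 - b2f) * g * g
            p.data -= lrf * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2)
                                                 + epsf)
            p.grad = None
        return lr

    def state(self) -> dict:
        out = {"step": np.asarray(self.step)}
        for k in self.m:
            out[f"m:{k}"] = self.m[k]
            out[f"v:{k}"] = self.v[k]
        return out

    def load_state(self, state) -> None:
        self.step = int(state["step"])
        for k in self.m:
            self.m[k] = state[f"m:{k}"]
            self.v[k] = state[f"v:{k}"]


def evaluate_token_accuracy(model: Transformer,
                            data: tuple[np.ndarray, np.ndarray],
                            batch_size: int = 64) -> float:
    """Teacher-forced token accuracy over a dataset, dropout disabled."""
    inp, tar = np.asarray(data[0]), np.asarray(data[1])
    correct = total = 0
    for start in range(0, inp.shape[0], batch_size):
        binp = inp[start:start + batch_size]
        btar = tar[start:start + batch_size]
        logits = model.forward(binp, btar[:, :-1])
        labels = btar[:, 1:]
        mask = labels != PAD_ID
        correct += int(((logits.data.argmax(axis=-1) == labels) & mask).sum())
        total += int(mask.sum())
    return correct / total if total else 0.0


def train(
    model: Transformer,
    data: tuple[np.ndarray, np.ndarray],
    config: ModelConfig | None = None,
    *,
    epochs: int = 1,
    max_steps: int | None = None,
    checkpoint_dir: str | Path | None = None,
    log_path: str | Path | None = None,
    optimizer: Adam | None = None,
) -> list[TrainState]:
    """Teacher-forced training over encoded ``(input_ids, target_ids)`` arrays.

    Target rows must be ``[start] + ids + [end] + pads``; the decoder is fed
    the row minus its last position and scored against the row shifted left.
    Shuffling and dropout are driven by ``config.seed``; two runs with the
    same seed produce identical loss traces.
    """
    config = config or model.config
    inp, tar = np.asarray(data[0]), np.asarray(data[1])
    if inp.max() >= config.input_vocab or tar.max() >= config.target_vocab:
        raise ValueError("token ids exceed configured vocabulary sizes")
    if inp.shape[0] != tar.shape[0]:
        raise ValueError("input/target row counts differ")
    rng = np.random.default_rng(config.seed + 1)
    opt = optimizer or Adam(model.params, config)
    history: list[TrainState] = []
    log_rows: list[tuple] = []
    done = False
    tar_lens = (tar != PAD_ID).sum(axis=1)
    inp_lens = (inp != PAD_ID).sum(axis=1)
    for epoch in range(1, epochs + 1):
        # seeded shuffle, then stable sort by target length so batches are
        # length-homogeneous (padding work shrinks); batch order reshuffled
        order = rng.permutation(inp.shape[0])
        order = order[np.argsort(tar_lens[order], kind="stable")]
        batches = [order[s : s + config.batch_size]
                   for s in range(0, len(order), config.batch_size)]
        rng.shuffle(batches)
        losses, accs = [], []
        for sel in batches:
            li = max(int(inp_lens[sel].max()), 2)
            lt = max(int(tar_lens[sel].max()), 2)
            binp, btar = inp[sel, :li], tar[sel, :lt]
            dec_in, labels = btar[:, :-1], btar[:, 1:]
            logits = model.forward(binp, dec_in, rng)
            mask = (labels != PAD_ID).astype(DTYPE)
            loss, acc = ad.masked_softmax_cross_entropy(logits, labels, mask)
            loss.backward()
            lr = opt.update()
            losses.append(float(loss.data))
            accs.append(acc)
            log_rows.append((opt.step, float(loss.data), acc, lr))
            if max_steps is not None and opt.step >= max_steps:
                done = True
                break
        state = TrainState(
            step=opt.step,
            epoch=epoch,
            train_loss=float(np.mean(losses)) if losses else 0.0,
            train_accuracy=float(np.mean(accs)) if accs else 0.0,
        )
        if checkpoint_dir is not None:
            ckpt = Path(checkpoint_dir) / f"epoch-{epoch:03d}"
            model.save(ckpt, extra=opt.state())
            state.checkpoint_path = str(ckpt)
        history.append(state)
        if done:
            break
    if log_path is not None:
        new = not Path(log_path).exists()
        with open(log_path, "a", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            if new:
                writer.writerow(["step", "loss", "accuracy", "lr"])
            writer.writerows(log_rows)
    return history
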