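"""Gated multimodal fusion with attention backtracking.

The multimodal adaptation gate (MAG) treats one modality as *primary*
and shifts its representation by a gated, norm-limited *displacement*
computed from the auxiliary modality:

    g = sigmoid(W_g [F_p ; F_a] + b_g)
    H = g * (W_h F_a + b_h)
    E = F_p + alpha * H,   alpha = min(beta * ||F_p||_2 / ||H||_2, 1)

with a trainable scalar beta and alpha defined as 0 when ||H|| = 0.
A static MAG fuses the two static modalities into E_S and a temporal
MAG (parameters shared across windows) fuses each window pair into E_i.

The attention-backtracking module complements each temporal fused
vector with scaled-dot-product attention over *strictly earlier*
windows (residual addition; window 1 has no history and passes through
unchanged).  The static fused vector is treated as day 0 and the
sequence [E_S, Q_1..Q_n] is encoded by a 2-layer LSTM; a linear+sigmoid
head on the final hidden state yields the outcome probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat, l2norm, maximum, minimum, softmax, where
from .config import ModelConfig
from .encoders import (StaticNoteEncoder, TemporalNoteEncoder,
                       TemporalTabularEncoder, encode_static_tabular)
from .layers import LSTM, Linear, Module, NEG_BIAS

LOSS_EPS = 1e-7


@dataclass
class MAGOutput:
    gate: Tensor          # g, entries strictly in (0, 1)
    displacement: Tensor  # H
    alpha: Tensor         # per-row scaling in [0, 1]
    fused: Tensor         # E = F_p + alpha * H


class MAG(Module):
    """One multimodal adaptation gate.

    ``gate_mode='vector'`` gates element-wise (one gate entry per
    displacement dimension); ``'scalar'`` uses a single gate value per
    sample.  ``beta`` is a trainable scalar initialised uniformly on
    (0.5, 1.5).
    """

    def __init__(self, d_primary: int, d_aux: int, rng: np.random.Generator,
                 gate_mode: str = "vector"):
        d_gate = d_primary if gate_mode == "vector" else 1
        self.w_g = Linear(d_primary + d_aux, d_gate, rng)
        self.w_h = Linear(d_aux, d_primary, rng)
        self.beta = Tensor(rng.uniform(0.5, 1.5), requires_grad=True)

    def __call__(self, f_primary: Tensor, f_aux: Tensor) -> MAGOutput:
        if not (np.all(np.isfinite(f_primary.data)) and np.all(np.isfinite(f_aux.data))):
            raise ValueError("non-finite inputs to MAG")
        gate = self.w_g(concat([f_primary, f_aux], axis=-1)).sigmoid()
        disp = gate * self.w_h(f_aux)
        norm_p = l2norm(f_primary)            # (B, 1)
        norm_h = l2norm(disp)
        # floor the denominator to keep the ratio finite; alpha is forced to
        # zero below whenever ||H|| is exactly zero
        denom = maximum(norm_h, Tensor(np.full_like(norm_h.data, 1e-12)))
        ratio = self.beta * norm_p / denom
        alpha = minimum(ratio, Tensor(np.ones_like(ratio.data)))
        alpha = where(norm_h.data == 0.0, Tensor(np.zeros_like(alpha.data)), alpha)
        return MAGOutput(gate=gate, displacement=disp, alpha=alpha,
                         fused=f_primary + alpha * disp)


def mag_fuse(f_primary, f_aux, params: MAG) -> MAGOutput:
    """Functional alias: apply a MAG to a (batch of) representation pair(s)."""
    lift = lambda x: x if isinstance(x, Tensor) else Tensor(np.atleast_2d(x))
    return params(lift(f_primary), lift(f_aux))


class AttentionBacktrack(Module):
    """Causal attention of each window over its strictly-earlier history.

    Q_i = E_i + sum_{j<i} w_ij * (W_v E_j), with w over j < i softmax of
    scaled dot products between projected query E_i and keys E_j.
    Window 1 has no history: Q_1 = E_1.  With ``enabled=False`` the
    module is the identity (the ablation switch).

    The attention weights of the last call are kept on
    ``last_weights`` (B, n, n) for inspection.
    """

    def __init__(self, d_model: int, rng: np.random.Generator, enabled: bool = True):
        self.enabled = enabled
        self.d_model = d_model
        self.w_q = Linear(d_model, d_model, rng, bias=False)
        self.w_k = Linear(d_model, d_model, rng, bias=False)
        self.w_v = Linear(d_model, d_model, rng, bias=False)
        self.last_weights: np.ndarray | None = None

    def __call__(self, e: Tensor) -> Tensor:
        if not self.enabled:
            self.last_weights = None
            return e
        B, n, d = e.shape
        q, k, v = self.w_q(e), self.w_k(e), self.w_v(e)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(d))
        # strict causality: window i may attend only to j < i
        allowed = np.tril(np.ones((n, n), dtype=bool), k=-1)
        bias = np.where(allowed, 0.0, NEG_BIAS)[None, :, :]
        weights = softmax(scores, axis=-1, bias=bias)
        has_history = allowed.any(axis=-1).astype(e.data.dtype)[None, :, None]
        context = (weights @ v) * has_history  # row 1: no history -> zero context
        self.last_weights = np.where(allowed.any(axis=-1)[None, :, None],
                                     weights.data, 0.0)
        return e + context


def attention_backtrack(e: Tensor, params: AttentionBacktrack) -> Tensor:
    return params(e)


class SequenceFusion(Module):
    """Day-0 concatenation and final recurrent fusion.

    Projects the static fused vector to model width, prepends it to the
    backtracked window sequence, runs a 2-layer LSTM and returns the
    final hidden state Z.
    """

    def __init__(self, d_static: int | None, d_model: int, rng: np.random.Generator):
        self.proj = Linear(d_static, d_model, rng) if d_static else None
        self.lstm = LSTM(d_model, d_model, n_layers=2, rng=rng)

    def __call__(self, e_static: Tensor | None, q: Tensor | None) -> Tensor:
        steps = []
        if e_static is not None:
            steps.append(self.proj(e_static).reshape(e_static.shape[0], 1, -1))
        if q is not None:
            steps.append(q)
        seq = steps[0] if len(steps) == 1 else concat(steps, axis=1)
        _, z = self.lstm(seq)
        return z


class PredictionHead(Module):
    """Linear + sigmoid head on the fused representation."""

    def __init__(self, d_model: int, rng: np.random.Generator):
        self.linear = Linear(d_model, 1, rng)

    def __call__(self, z: Tensor) -> Tensor:
        return self.linear(z).sigmoid().reshape(z.shape[0])


def predict(z: Tensor, head: PredictionHead) -> Tensor:
    return head(z)


def bce_loss(y_true: np.ndarray, y_pred: Tensor, eps: float = LOSS_EPS) -> Tensor:
    """Mean binary cross-entropy; predictions are clipped to [eps, 1-eps]."""
    y = np.asarray(y_true, dtype=float)
    if y.size == 0:
        raise ValueError("empty batch in bce_loss")
    p = y_pred.clip(eps, 1.0 - eps)
    ll = Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log()
    return -ll.mean()


@dataclass
class FusedSequence:
    """Intermediates of one forward pass (inspection/testing aid)."""

    e_static: Tensor | None
    e_temporal: Tensor | None
    q: Tensor | None
    z: Tensor
    y_hat: Tensor
    static_mag: MAGOutput | None = None
    temporal_mag: MAGOutput | None = None


class MultimodalFusionModel(Module):
    """The full four-modality fusion network.

    Which modalities exist, which one is primary in each gate, and
    whether backtracking is active all come from :class:`ModelConfig`;
    unused encoders are never constructed, so a two-modality subset
    model physically cannot touch the dropped modalities.
    """

    def __init__(self, cfg: ModelConfig, onehot_dim: int, n_temporal_features: int,
                 window_days: int, vocab_size: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        mods = set(cfg.modalities)
        d = cfg.d_model

        self.static_note_encoder = (
            StaticNoteEncoder(vocab_size, cfg.d_note, rng) if "static_notes" in mods else None)
        self.temporal_tabular_encoder = (
            TemporalTabularEncoder(n_temporal_features, window_days, d, rng)
            if "temporal_tabular" in mods else None)
        self.temporal_note_encoder = (
            TemporalNoteEncoder(vocab_size, cfg, rng) if "temporal_notes" in mods else None)

        static_mods = mods & {"static_tabular", "static_notes"}
        temporal_mods = mods & {"temporal_tabular", "temporal_notes"}
        self.has_static = bool(static_mods)
        self.has_temporal = bool(temporal_mods)

        d_static = None
        if self.has_static:
            if static_mods == {"static_tabular", "static_notes"}:
                d_p = cfg.d_note if cfg.primary_static == "static_notes" else onehot_dim
                d_a = onehot_dim if cfg.primary_static == "static_notes" else cfg.d_note
                self.static_mag = MAG(d_p, d_a, rng, cfg.gate_mode)
                d_static = d_p
            else:
                self.static_mag = None
                d_static = cfg.d_note if "static_notes" in static_mods else onehot_dim
        else:
            self.static_mag = None

        if self.has_temporal:
            if temporal_mods == {"temporal_tabular", "temporal_notes"}:
                self.temporal_mag = MAG(d, d, rng, cfg.gate_mode)
            else:
                self.temporal_mag = None
            self.backtrack = AttentionBacktrack(d, rng, enabled=cfg.backtracking)
        else:
            self.temporal_mag = None
            self.backtrack = None

        self.sequence_fusion = SequenceFusion(d_static, d, rng)
        self.head = PredictionHead(d, rng)

    # -- forward --------------------------------------------------------------

    def __call__(self, batch: dict[str, np.ndarray]) -> FusedSequence:
        mods = set(self.cfg.modalities)

        e_static = static_out = None
        if self.has_static:
            f_st = encode_static_tabular(batch["static_onehot"]) if "static_tabular" in mods else None
            f_sn = (self.static_note_encoder(batch["static_ids"], batch["static_mask"])
                    if "static_notes" in mods else None)
            if self.static_mag is not None:
                f_p, f_a = ((f_sn, f_st) if self.cfg.primary_static == "static_notes"
                            else (f_st, f_sn))
                static_out = self.static_mag(f_p, f_a)
                e_static = static_out.fused
            else:
                e_static = f_sn if f_sn is not None else f_st

        e_temporal = q = temporal_out = None
        if self.has_temporal:
            f_tt = (self.temporal_tabular_encoder(batch["tabular"])
                    if "temporal_tabular" in mods else None)
            f_tn = None
            if "temporal_notes" in mods:
                _, f_tn = self.temporal_note_encoder(batch["note_ids"], batch["note_mask"])
            if self.temporal_mag is not None:
                f_p, f_a = ((f_tn, f_tt) if self.cfg.primary_temporal == "temporal_notes"
                            else (f_tt, f_tn))
                B, n, d = f_p.shape
                temporal_out = self.temporal_mag(f_p.reshape(B * n, d), f_a.reshape(B * n, d))
                e_temporal = temporal_out.fused.reshape(B, n, d)
            else:
                e_temporal = f_tn if f_tn is not None else f_tt
            q = self.backtrack(e_temporal)

        z = self.sequence_fusion(e_static, q)
        y_hat = self.head(z)
        return FusedSequence(e_static=e_static, e_temporal=e_temporal, q=q, z=z,
                             y_hat=y_hat, static_mag=static_out, temporal_mag=temporal_out)
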