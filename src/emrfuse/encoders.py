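"""The four modality encoders.

* static tabular  -> identity on the one-hot vector (projection happens
  in the fusion gates);
* static notes    -> trainable token-embedding table, mean-pooled over
  the document (a paragraph-vector model can be plugged in instead);
* temporal tabular -> per-day affine map + ReLU, then a 2-layer LSTM
  within each window (state reset per window), final hidden state;
* temporal notes  -> segment-recurrent transformer over each window's
  tokens with detached memory carried window to window, mean-pooled to a
  window vector, then a 2-layer LSTM across windows emitting one output
  per window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor
from .config import ModelConfig
from .layers import LSTM, Embedding, Linear, Module, TransformerXLEncoder, masked_mean


@dataclass
class ModalityEmbedding:
    """The four representation outputs for a batch of admissions."""

    f_st: Tensor | None = None   # (B, S) one-hot
    f_sn: Tensor | None = None   # (B, d_note)
    f_tt: Tensor | None = None   # (B, n, d_model)
    f_tn: Tensor | None = None   # (B, n, d_model)


def encode_static_tabular(static_onehot: np.ndarray | Tensor) -> Tensor:
    """Identity encoding: the one-hot vector is the representation."""
    return static_onehot if isinstance(static_onehot, Tensor) else Tensor(static_onehot)


class StaticNoteEncoder(Module):
    """Mean-pooled token embedding of the whole static document.

    Deterministic given parameters; an empty document maps to the zero
    vector (mean over the empty set is defined as zero).
    """

    def __init__(self, vocab_size: int, d_note: int, rng: np.random.Generator):
        self.embedding = Embedding(vocab_size, d_note, rng)
        self.n_calls = 0

    def __call__(self, ids: np.ndarray, mask: np.ndarray) -> Tensor:
        """``ids``: (B, L) int, ``mask``: (B, L) bool -> (B, d_note)."""
        self.n_calls += 1
        return masked_mean(self.embedding(ids), mask, axis=1)


class TemporalTabularEncoder(Module):
    """Window-wise encoder of the dense tabular grid.

    Each window's days are mapped through a shared affine layer with
    ReLU, the day sequence runs through a 2-layer LSTM whose state is
    reset per window, and the final hidden state represents the window.
    """

    def __init__(self, n_features: int, window_days: int, d_model: int,
                 rng: np.random.Generator):
        self.window_days = window_days
        self.proj = Linear(n_features, d_model, rng)
        self.lstm = LSTM(d_model, d_model, n_layers=2, rng=rng)
        self.n_calls = 0

    def __call__(self, x: np.ndarray | Tensor) -> Tensor:
        """``x``: (B, n, W, F) -> (B, n, d_model)."""
        self.n_calls += 1
        t = x if isinstance(x, Tensor) else Tensor(x)
        if not np.all(np.isfinite(t.data)):
            raise ValueError("non-finite values in temporal tabular input")
        B, n, W, F = t.shape
        flat = t.reshape(B * n, W, F)
        hidden = self.proj(flat).relu()          # F'_tt per day
        _, final = self.lstm(hidden)             # state reset per window
        return final.reshape(B, n, -1)


class TemporalNoteEncoder(Module):
    """Segment-recurrent transformer + cross-window LSTM.

    Window i's tokens are contextualised with a detached memory of
    window i-1's hidden states (window 1 starts from empty memory), the
    per-token outputs are mean-pooled into the window vector F', and the
    n-step F' sequence runs through a 2-layer LSTM whose per-step
    outputs are the window representations.
    """

    def __init__(self, vocab_size: int, cfg: ModelConfig, rng: np.random.Generator):
        d = cfg.d_model
        mem_len = cfg.window_token_budget if cfg.memory_len is None else cfg.memory_len
        self.embedding = Embedding(vocab_size, d, rng)
        self.transformer = TransformerXLEncoder(
            dim=d, n_layers=cfg.transformer_layers, n_heads=cfg.transformer_heads,
            d_ff=cfg.d_ff, memory_len=mem_len,
            max_rel=mem_len + cfg.window_token_budget, rng=rng)
        self.lstm = LSTM(d, d, n_layers=2, rng=rng)
        self.n_calls = 0

    def pool_windows(self, ids: np.ndarray, mask: np.ndarray) -> Tensor:
        """Per-window pooled transformer outputs F' -> (B, n, d_model)."""
        from ._autodiff import stack

        B, n, T = ids.shape
        memory = self.transformer.init_memory()
        pooled = []
        for i in range(n):
            h = self.embedding(ids[:, i, :])
            h, memory = self.transformer(h, mask[:, i, :], memory)
            pooled.append(masked_mean(h, mask[:, i, :], axis=1))
        return stack(pooled, axis=1)

    def __call__(self, ids: np.ndarray, mask: np.ndarray) -> tuple[Tensor, Tensor]:
        """``ids``: (B, n, T) int, ``mask``: (B, n, T) bool.

        Returns (F' (B, n, d), F (B, n, d)): pooled transformer vectors
        and the cross-window LSTM outputs.
        """
        self.n_calls += 1
        f_prime = self.pool_windows(ids, mask)
        outputs, _ = self.lstm(f_prime)
        return f_prime, outputs
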