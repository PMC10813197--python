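"""Training protocol, metrics and the experiment grids.

The protocol: stratified 8:1:1 random split, Adam, binary
cross-entropy, up to ``max_epochs`` epochs with the checkpoint of
minimum validation loss retained, AUROC as the primary metric with
AUPRC and F1 (threshold 0.5) alongside, and every reported figure the
mean over several seeded runs (five by default), where each run redraws
the split and the initialisation together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score

from ._autodiff import Tensor, no_grad
from .config import ModelConfig, TrainConfig
from .data_model import DatasetSchema, PatientRecord
from .fusion import MultimodalFusionModel, bce_loss
from .layers import Adam
from .preprocessing import PAD_ID, Preprocessor, Vocab, WindowedRecord

log = logging.getLogger(__name__)


# -- splitting ----------------------------------------------------------------


def split_data(labels: Sequence[int], ratios: tuple[float, float, float],
               seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Label-stratified random partition into train/val/test index arrays.

    Sizes are exactly floor(r_train*N) / floor(r_val*N) / remainder,
    deterministic per seed, disjoint and exhaustive.
    """
    y = np.asarray(labels)
    N = len(y)
    if N < 10:
        raise ValueError(f"need at least 10 records to split, got {N}")
    rng = np.random.default_rng(seed)
    targets = [int(np.floor(ratios[0] * N)), int(np.floor(ratios[1] * N))]
    targets.append(N - sum(targets))
    parts: list[list[int]] = [[], [], []]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        quota = np.array([len(idx) * r for r in ratios])
        base = np.floor(quota).astype(int)
        rem = quota - base
        for _ in range(len(idx) - base.sum()):
            s = int(np.argmax(rem))
            base[s] += 1
            rem[s] = -1
        cuts = np.cumsum(base)[:-1]
        for s, chunk in enumerate(np.split(idx, cuts)):
            parts[s].extend(chunk.tolist())
    # fix up rounding so global sizes match the floor/floor/remainder rule
    for s in range(3):
        while len(parts[s]) > targets[s]:
            d = next(t for t in range(3) if len(parts[t]) < targets[t])
            parts[d].append(parts[s].pop())
    out = []
    for p in parts:
        arr = np.array(sorted(p), dtype=int)
        out.append(arr)
    return out[0], out[1], out[2]


# -- metrics ------------------------------------------------------------------


@dataclass
class Metrics:
    auroc: float | None
    auprc: float | None
    f1: float | None

    def as_dict(self) -> dict:
        return {"auroc": self.auroc, "auprc": self.auprc, "f1": self.f1}


def evaluate_scores(y_true: Sequence[int], scores: Sequence[float],
                    threshold: float = 0.5) -> Metrics:
    """AUROC / AUPRC / F1 of raw scores against binary labels.

    AUROC is the probability that a random positive outscores a random
    negative (ties count one half); AUPRC is step-wise precision-recall
    integration.  With a single class present the ranking metrics are
    undefined and reported as missing (None).
    """
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        return Metrics(None, None, float(f1_score(y, s >= threshold, zero_division=0)))
    return Metrics(
        auroc=float(roc_auc_score(y, s)),
        auprc=float(average_precision_score(y, s)),
        f1=float(f1_score(y, s >= threshold, zero_division=0)),
    )


# -- tensorisation ------------------------------------------------------------


def _pad_ids(token_lists: list[list[int]], budget: int) -> tuple[np.ndarray, np.ndarray]:
    ids = np.full((len(token_lists), budget), PAD_ID, dtype=np.int64)
    mask = np.zeros((len(token_lists), budget), dtype=bool)
    for i, toks in enumerate(token_lists):
        t = toks[:budget]
        ids[i, :len(t)] = t
        mask[i, :len(t)] = True
    return ids, mask


def tensorize(windowed: Sequence[WindowedRecord], vocab: Vocab,
              cfg: ModelConfig) -> dict[str, np.ndarray]:
    """Stack windowed records into dense model-ready arrays."""
    n_rec = len(windowed)
    tab = np.stack([w.subseq_tabular for w in windowed]).astype(np.float32)
    tab_mask = np.stack([w.subseq_tabular_mask for w in windowed]).astype(np.float32)
    static_onehot = np.stack([w.static_onehot for w in windowed]).astype(np.float32)
    static_ids, static_mask = _pad_ids(
        [vocab.encode(w.static_note_tokens) for w in windowed], cfg.static_token_budget)
    n_win = tab.shape[1]
    flat_notes = [vocab.encode(notes) for w in windowed for notes in w.subseq_notes]
    note_ids, note_mask = _pad_ids(flat_notes, cfg.window_token_budget)
    return {
        "tabular": tab,
        "tabular_mask": tab_mask,
        "static_onehot": static_onehot,
        "static_ids": static_ids,
        "static_mask": static_mask,
        "note_ids": note_ids.reshape(n_rec, n_win, -1),
        "note_mask": note_mask.reshape(n_rec, n_win, -1),
        "label_mortality": np.array([w.label_mortality for w in windowed], dtype=np.float32),
        "label_long_stay": np.array([w.label_long_stay for w in windowed], dtype=np.float32),
    }


def _take(tensors: dict[str, np.ndarray], idx: np.ndarray) -> dict[str, np.ndarray]:
    return {k: v[idx] for k, v in tensors.items()}


# -- training -----------------------------------------------------------------


GRAD_CLIP = 1.0


def _clip_gradients(params, max_norm: float) -> None:
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad ** 2).sum())
    total = np.sqrt(total)
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                if p.grad.flags.writeable and not p._grad_shared:
                    p.grad *= scale
                else:
                    p.grad = p.grad * scale


def _batch_scores(model: MultimodalFusionModel, tensors: dict[str, np.ndarray],
                  idx: np.ndarray, batch_size: int = 256) -> np.ndarray:
    scores = np.empty(len(idx))
    with no_grad():
        for lo in range(0, len(idx), batch_size):
            part = idx[lo:lo + batch_size]
            scores[lo:lo + len(part)] = model(_take(tensors, part)).y_hat.data
    return scores


def train(model: MultimodalFusionModel, tensors: dict[str, np.ndarray],
          train_idx: np.ndarray, val_idx: np.ndarray, cfg: TrainConfig,
          seed: int = 0) -> list[dict]:
    """Optimise in place; restore the minimum-validation-loss checkpoint.

    Returns the per-epoch log (train loss, validation loss, selection
    flag).  Aborts on a non-finite loss.
    """
    y_key = f"label_{cfg.task}"
    rng = np.random.default_rng(seed)
    # class-prior initialisation of the head bias: start at the training
    # base rate instead of 0.5 so rare-positive runs skip the collapse phase
    p0 = float(np.clip(tensors[y_key][train_idx].mean(), 1e-3, 1 - 1e-3))
    model.head.linear.bias.data[:] = np.log(p0 / (1.0 - p0))
    opt = Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    best_loss, best_state, best_epoch = np.inf, model.state_dict(), 0
    history: list[dict] = []
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(train_idx)
        losses = []
        for lo in range(0, len(order), cfg.batch_size):
            batch_idx = order[lo:lo + cfg.batch_size]
            batch = _take(tensors, batch_idx)
            out = model(batch)
            loss = bce_loss(batch[y_key], out.y_hat)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(batch starting at {lo}); aborting")
            opt.zero_grad()
            loss.backward()
            _clip_gradients(opt.params, GRAD_CLIP)
            opt.step()
            losses.append(loss.item())
        val_scores = _batch_scores(model, tensors, val_idx)
        val_loss = float(bce_loss(tensors[y_key][val_idx], Tensor(val_scores)).item())
        improved = val_loss < best_loss
        if improved:
            best_loss, best_state, best_epoch = val_loss, model.state_dict(), epoch
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_loss": val_loss, "selected": improved})
        log.info("epoch %d train %.4f val %.4f%s", epoch, np.mean(losses),
                 val_loss, " *" if improved else "")
    model.load_state_dict(best_state)
    log.info("restored checkpoint from epoch %d (val loss %.4f)", best_epoch, best_loss)
    return history


def evaluate(model: MultimodalFusionModel, tensors: dict[str, np.ndarray],
             idx: np.ndarray, task: str) -> tuple[Metrics, np.ndarray]:
    scores = _batch_scores(model, tensors, idx)
    return evaluate_scores(tensors[f"label_{task}"][idx], scores), scores


# -- experiment orchestration -------------------------------------------------


def run_single(records: Sequence[PatientRecord], schema: DatasetSchema,
               model_cfg: ModelConfig, train_cfg: TrainConfig, seed: int
               ) -> tuple[Metrics, list[dict], MultimodalFusionModel]:
    """One seeded run: split, fit preprocessing on train, train, test metrics."""
    labels = [getattr(r, f"label_{train_cfg.task}") for r in records]
    tr, va, te = split_data(labels, train_cfg.ratios, seed)
    pre = Preprocessor(schema).fit([records[i] for i in tr])
    windowed = pre.transform_all(records)
    tensors = tensorize(windowed, pre.vocab, model_cfg)
    model = MultimodalFusionModel(
        model_cfg, onehot_dim=schema.onehot_dim,
        n_temporal_features=len(schema.temporal_features),
        window_days=schema.window_days, vocab_size=len(pre.vocab), seed=seed)
    history = train(model, tensors, tr, va, train_cfg, seed=seed)
    metrics, _ = evaluate(model, tensors, te, train_cfg.task)
    return metrics, history, model


def run_seeds(records: Sequence[PatientRecord], schema: DatasetSchema,
              model_cfg: ModelConfig, train_cfg: TrainConfig) -> pd.DataFrame:
    """Run every seed of the config; one row per seed."""
    rows = []
    for seed in train_cfg.seeds:
        metrics, history, _ = run_single(records, schema, model_cfg, train_cfg, seed)
        rows.append({"seed": seed, **metrics.as_dict(),
                     "best_epoch": next((h["epoch"] for h in reversed(history)
                                         if h["selected"]), None)})
    return pd.DataFrame(rows)


def run_experiment(records: Sequence[PatientRecord], schema: DatasetSchema,
                   grid: Sequence[dict], base_model: ModelConfig,
                   base_train: TrainConfig) -> pd.DataFrame:
    """Run a grid of configuration cells, averaging metrics across seeds.

    Each grid cell is a dict of overrides; keys matching
    :class:`ModelConfig` fields (e.g. ``modality_subset``,
    ``backtracking``, ``primary_static``) are applied to the model
    config and keys matching :class:`TrainConfig` fields (e.g. ``task``)
    to the training config.  Returns one row per cell with per-seed and
    mean metrics.
    """
    model_fields = set(vars(base_model))
    train_fields = set(vars(base_train))
    rows = []
    for cell in grid:
        m_over = {k: v for k, v in cell.items() if k in model_fields}
        t_over = {k: v for k, v in cell.items() if k in train_fields}
        unknown = set(cell) - model_fields - train_fields
        if unknown:
            raise ValueError(f"unknown grid keys: {sorted(unknown)}")
        m_cfg = replace(base_model, **m_over)
        t_cfg = replace(base_train, **t_over)
        per_seed = run_seeds(records, schema, m_cfg, t_cfg)
        row = dict(cell)
        for metric in ("auroc", "auprc", "f1"):
            vals = per_seed[metric].dropna()
            row[f"mean_{metric}"] = float(vals.mean()) if len(vals) else None
            row[f"per_seed_{metric}"] = per_seed[metric].tolist()
        rows.append(row)
    return pd.DataFrame(rows)
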