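"""Training objective and loops.

The model trains on a composite loss: binary cross-entropy on the softmax
head plus a batch supervised contrastive term on the pooled
representations. For a pair of representations Z1, Z2 with cosine distance
D = 1 - cos(Z1, Z2) and pair label y (1 when the two peptides come from
*different* classes):

    L = 1/2 (1-y) D^2  +  1/2 y max(D_max - D, 0)^3

Same-class pairs are pulled together quadratically; different-class pairs
are pushed toward the margin D_max (default 1.5) with a cubic penalty,
which weights hard cross-class pairs heavily and is what lets the minority
toxic class keep a high recall on imbalanced data. The margin shortfall is
clamped at zero so the loss is non-negative even though cosine distance
can reach 2.

The total loss is ``BCE + lambda * mean over unordered in-batch pairs``.
Training is plain Adam with seeded shuffling; identical seeds give
bit-identical runs on one machine.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor
from .model_core import CAPTPModel, ModelConfig, softmax_rows
from .evaluation import MetricReport, evaluate
from .sequence_io import LABEL_TOXIC, EncodedBatch, PeptideRecord, encode_batch

logger = logging.getLogger(__name__)


@dataclass
class ContrastiveConfig:
    d_max: float = 1.5
    pair_strategy: str = "all_pairs"
    lam: float = 1.0  # weight of the contrastive term in the total loss

    def __post_init__(self):
        if not 0.0 < self.d_max <= 2.0:
            raise ValueError("d_max must be in (0, 2]")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.pair_strategy not in ("all_pairs", "sampled"):
            raise ValueError("pair_strategy must be 'all_pairs' or 'sampled'")


@dataclass
class TrainConfig:
    epochs: int = 16
    batch_size: int = 64
    learning_rate: float = 1e-3
    lr_schedule: str = "cosine"  # cosine decay to lr/10, or "constant"
    optimizer: str = "adam"
    patience: int = 10
    seed: int = 0
    folds: int = 5

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 so contrastive pairs exist")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError("lr_schedule must be 'constant' or 'cosine'")


# --------------------------------------------------------------------------
# losses (plain-array reference forms)
# --------------------------------------------------------------------------

def cosine_distance(z1, z2) -> float:
    """1 - cosine similarity; in [0, 2]. Errors on a zero vector."""
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    n1, n2 = np.linalg.norm(z1), np.linalg.norm(z2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("cosine distance undefined for a zero vector")
    return float(1.0 - z1 @ z2 / (n1 * n2))


def contrastive_pair_loss(z1, z2, y: int, d_max: float = 1.5) -> float:
    """Pairwise supervised contrastive loss; y=1 marks a cross-class pair."""
    if y not in (0, 1):
        raise ValueError(f"pair label must be 0 or 1, got {y}")
    d = cosine_distance(z1, z2)
    return 0.5 * (1 - y) * d ** 2 + 0.5 * y * max(d_max - d, 0.0) ** 3


def batch_contrastive_loss(z, labels, d_max: float = 1.5) -> float:
    """Mean pair loss over all unordered pairs in the batch."""
    z = np.asarray(z, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(z) < 2:
        raise ValueError("need at least two representations")
    if len(np.unique(labels)) < 2:
        logger.warning("single-class batch: contrastive loss uses same-class pairs only")
    total, n_pairs = 0.0, 0
    for i in range(len(z)):
        for j in range(i + 1, len(z)):
            total += contrastive_pair_loss(z[i], z[j], int(labels[i] != labels[j]), d_max)
            n_pairs += 1
    return total / n_pairs


def total_loss(probs, labels, z, contrastive: ContrastiveConfig | None = None) -> float:
    """BCE on P(toxic) plus lambda times the batch contrastive term."""
    cc = contrastive or ContrastiveConfig()
    probs = np.clip(np.asarray(probs, dtype=float), 1e-12, 1 - 1e-12)
    labels = np.asarray(labels, dtype=float)
    bce = float(-np.mean(labels * np.log(probs) + (1 - labels) * np.log(1 - probs)))
    if cc.lam == 0.0:
        return bce
    return bce + cc.lam * batch_contrastive_loss(z, labels, cc.d_max)


# --------------------------------------------------------------------------
# differentiable loss (tape form used by the trainer)
# --------------------------------------------------------------------------

def _bce_from_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    m = Tensor(logits.data.max(axis=-1, keepdims=True))
    lse = m + (logits - m).exp().sum(axis=-1, keepdims=True).log()
    logp = logits - lse
    onehot = np.eye(2)[labels]
    return -(logp * Tensor(onehot)).sum() * (1.0 / len(labels))


def _contrastive_from_pooled(z: Tensor, labels: np.ndarray, d_max: float) -> Tensor:
    n = z.shape[0]
    norm = ((z ** 2.0).sum(axis=1, keepdims=True) + 1e-12) ** 0.5
    zn = z / norm
    dist = 1.0 - zn @ zn.swapaxes(0, 1)  # (n, n) pairwise cosine distances
    upper = np.triu(np.ones((n, n)), k=1)
    diff = (labels[:, None] != labels[None, :]).astype(float)
    w_same = Tensor(upper * (1.0 - diff))
    w_diff = Tensor(upper * diff)
    same_term = 0.5 * (dist ** 2.0) * w_same
    diff_term = 0.5 * ((d_max - dist).relu() ** 3.0) * w_diff
    n_pairs = n * (n - 1) / 2
    return (same_term + diff_term).sum() * (1.0 / n_pairs)


def training_loss(
    logits: Tensor, pooled: Tensor, labels: np.ndarray, cc: ContrastiveConfig
) -> tuple[Tensor, float, float]:
    bce = _bce_from_logits(logits, labels)
    if cc.lam == 0.0 or len(labels) < 2:
        return bce, float(bce.data), 0.0
    contrast = _contrastive_from_pooled(pooled, labels, cc.d_max)
    return bce + cc.lam * contrast, float(bce.data), float(contrast.data)


# --------------------------------------------------------------------------
# optimizer
# --------------------------------------------------------------------------

class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# --------------------------------------------------------------------------
# training / cross-validation loops
# --------------------------------------------------------------------------

@dataclass
class TrainResult:
    model: CAPTPModel
    history: list[dict] = field(default_factory=list)


def _slice_batch(batch: EncodedBatch, idx: np.ndarray) -> EncodedBatch:
    return EncodedBatch(
        batch.tokens[idx], batch.mask[idx], batch.labels[idx], batch.lengths[idx]
    )


def train(
    records: list[PeptideRecord],
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    contrastive_config: ContrastiveConfig | None = None,
    val_records: list[PeptideRecord] | None = None,
) -> TrainResult:
    """Fit a fresh model on `records`; early-stops on validation MCC if
    `val_records` is given. Deterministic for a fixed seed pair."""
    mc = model_config or ModelConfig()
    tc = train_config or TrainConfig()
    cc = contrastive_config or ContrastiveConfig()
    present = {r.label for r in records}
    if LABEL_TOXIC not in present or len(present - {LABEL_TOXIC}) == 0:
        raise ValueError("training set must contain both classes")

    model = CAPTPModel(mc)
    opt = Adam(model.parameters(), lr=tc.learning_rate)
    data = encode_batch(records, mc.max_len, mc.add_cls)
    rng = np.random.default_rng(tc.seed)
    history: list[dict] = []
    best_mcc, best_state, patience_left = -np.inf, None, tc.patience

    for epoch in range(tc.epochs):
        if tc.lr_schedule == "cosine" and tc.epochs > 1:
            # decay to lr/10 over the run; calms late-epoch metric jitter
            frac = epoch / (tc.epochs - 1)
            opt.lr = tc.learning_rate * (0.55 + 0.45 * math.cos(math.pi * frac))
        model.training = True
        order = rng.permutation(len(data))
        epoch_bce, epoch_con, n_batches = 0.0, 0.0, 0
        for lo in range(0, len(order), tc.batch_size):
            idx = order[lo : lo + tc.batch_size]
            if len(idx) < 2:
                continue  # a single-sample tail batch has no pairs
            sub = _slice_batch(data, idx)
            logits, pooled = model.forward(sub)
            loss, bce_val, con_val = training_loss(logits, pooled, sub.labels, cc)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}, batch {n_batches}"
                )
            model.zero_grad()
            loss.backward()
            opt.step()
            epoch_bce += bce_val
            epoch_con += con_val
            n_batches += 1
        model.training = False
        entry = {
            "epoch": epoch,
            "bce": epoch_bce / max(n_batches, 1),
            "contrastive": epoch_con / max(n_batches, 1),
        }
        entry["total"] = entry["bce"] + cc.lam * entry["contrastive"]
        if val_records:
            rep = evaluate_model(model, val_records)
            entry.update(val_mcc=rep.mcc, val_bacc=rep.bacc, val_sn=rep.sn, val_sp=rep.sp)
            if rep.mcc > best_mcc:
                best_mcc = rep.mcc
                best_state = [p.data.copy() for p in model.parameters()]
                patience_left = tc.patience
            else:
                patience_left -= 1
        history.append(entry)
        if val_records and patience_left <= 0:
            break
    if best_state is not None:
        for p, saved in zip(model.parameters(), best_state):
            p.data = saved
    return TrainResult(model=model, history=history)


def evaluate_model(model: CAPTPModel, records: list[PeptideRecord]) -> MetricReport:
    """Score a labelled record set: SN/SP/BACC/MCC and AUC at threshold 0.5."""
    y_true = np.array([1 if r.label == LABEL_TOXIC else 0 for r in records])
    scores = model.predict_proba(records)
    return evaluate(y_true, (scores >= 0.5).astype(int), scores)


def stratified_folds(records: list[PeptideRecord], k: int, seed: int) -> list[list[int]]:
    """Seeded stratified fold assignment, stable under input reordering.

    Records are keyed by (id, sequence) before shuffling so the same seed
    yields the same folds however the caller ordered the list.
    """
    by_class: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        by_class.setdefault(r.label, []).append(i)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for lab in sorted(by_class):
        idx = sorted(by_class[lab], key=lambda i: (records[i].id, records[i].sequence))
        if len(idx) < k:
            raise ValueError(f"class {lab!r} has fewer than k={k} records")
        perm = rng.permutation(len(idx))
        for pos, j in enumerate(perm):
            folds[pos % k].append(idx[j])
    return folds


@dataclass
class CrossValResult:
    fold_reports: list[MetricReport]
    mean: dict[str, float]
    pooled: MetricReport


def cross_validate(
    records: list[PeptideRecord],
    k: int = 5,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    contrastive_config: ContrastiveConfig | None = None,
) -> CrossValResult:
    """Stratified k-fold CV; reports per-fold metrics, their mean, and the
    pooled (all held-out predictions scored together) metrics."""
    tc = train_config or TrainConfig()
    folds = stratified_folds(records, k, tc.seed)
    reports: list[MetricReport] = []
    pooled_true: list[int] = []
    pooled_scores: list[float] = []
    for held in range(k):
        test_idx = set(folds[held])
        train_recs = [r for i, r in enumerate(records) if i not in test_idx]
        test_recs = [records[i] for i in folds[held]]
        result = train(train_recs, model_config, tc, contrastive_config)
        rep = evaluate_model(result.model, test_recs)
        reports.append(rep)
        pooled_true.extend(1 if r.label == LABEL_TOXIC else 0 for r in test_recs)
        pooled_scores.extend(result.model.predict_proba(test_recs).tolist())
    mean = {
        key: float(np.mean([getattr(r, key) for r in reports]))
        for key in ("sn", "sp", "bacc", "mcc", "auc")
    }
    scores = np.array(pooled_scores)
    pooled = evaluate(np.array(pooled_true), (scores >= 0.5).astype(int), scores)
    return CrossValResult(fold_reports=reports, mean=mean, pooled=pooled)
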