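"""In-silico mutagenesis (ISM) interpretation of a trained model.

Each residue of a peptide is substituted by the 19 alternative amino acids
and the absolute change in predicted toxicity probability is recorded —
the ISM score. On top of the per-peptide L×20 score matrix the module
derives:

* per-position scores (mean over the 19 substitutions),
* per-amino-acid contribution vectors per class, with the class amino-acid
  composition (AAC) as the natural reference,
* position-ratio profiles: positions are mapped into 10 length-normalised
  bins so peptides of different lengths are comparable, and per-bin score
  means/variances show which regions drive predictions,
* an amino-acid × position-ratio map for the toxic class, and
* clipping scans that truncate sequences from the front, back or both
  ends and re-measure BACC/MCC as a function of the clipping ratio.

Positions are 1-based over the unpadded sequence; the CLS slot, when the
model uses one, is never scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .evaluation import MetricReport
from .model_core import CAPTPModel
from .sequence_io import AMINO_ACIDS, LABEL_TOXIC, PeptideRecord, validate_record
from .training import evaluate_model

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
N_BINS = 10


@dataclass
class ISMMatrix:
    """Absolute probability changes, one row per position, one column per
    substituting amino acid (alphabetical); the self-substitution cell is 0."""

    scores: np.ndarray  # (L, 20), >= 0
    reference: str
    id: str = ""

    def __post_init__(self):
        if self.scores.shape != (len(self.reference), 20):
            raise ValueError("score matrix shape must be (len(sequence), 20)")


def ism_matrix(model: CAPTPModel, sequence: str | PeptideRecord, batch_size: int = 512) -> ISMMatrix:
    """Score every single-residue substitution of `sequence` in one batched sweep."""
    rec = sequence if isinstance(sequence, PeptideRecord) else PeptideRecord("query", sequence)
    if not validate_record(rec, model.config.max_len):
        raise ValueError(f"invalid sequence for record {rec.id!r}")
    seq = rec.sequence
    mutants: list[str] = []
    slots: list[tuple[int, int]] = []
    for p, ref in enumerate(seq):
        for aa in AMINO_ACIDS:
            if aa == ref:
                continue
            mutants.append(seq[:p] + aa + seq[p + 1 :])
            slots.append((p, AA_INDEX[aa]))
    p_wt = model.predict_proba([seq])[0]
    scores = np.zeros((len(seq), 20))
    if mutants:
        p_mut = model.predict_proba(mutants, batch_size=batch_size)
        for (p, a), pm in zip(slots, p_mut):
            scores[p, a] = abs(pm - p_wt)
    return ISMMatrix(scores=scores, reference=seq, id=rec.id)


def position_scores(ism: ISMMatrix) -> np.ndarray:
    """Per-position score: mean of the 19 substitution scores."""
    return ism.scores.sum(axis=1) / 19.0


def aa_contributions(
    results: list[ISMMatrix],
    labels: list[str],
    attribution: str = "reference",
) -> dict[str, dict[str, np.ndarray]]:
    """Per-class amino-acid contribution vectors with the class AAC baseline.

    With ``attribution='reference'`` each position's score is credited to
    the wild-type residue sitting there; ``'target'`` credits the
    substituting residue instead (scores divided by 19 so the two scales
    are comparable). Returns {class: {"contribution": (20,), "aac": (20,)}}.
    """
    if attribution not in ("reference", "target"):
        raise ValueError("attribution must be 'reference' or 'target'")
    per_class: dict[str, list[np.ndarray]] = {}
    aac_counts: dict[str, np.ndarray] = {}
    for ism, lab in zip(results, labels, strict=True):
        vec = np.zeros(20)
        if attribution == "reference":
            pos = position_scores(ism)
            for p, ref in enumerate(ism.reference):
                vec[AA_INDEX[ref]] += pos[p]
        else:
            vec = ism.scores.sum(axis=0) / 19.0
        per_class.setdefault(lab, []).append(vec)
        counts = aac_counts.setdefault(lab, np.zeros(20))
        for ref in ism.reference:
            counts[AA_INDEX[ref]] += 1
    out = {}
    for lab, vecs in per_class.items():
        aac = aac_counts[lab] / aac_counts[lab].sum()
        out[lab] = {"contribution": np.mean(vecs, axis=0), "aac": aac}
    if not out:
        raise ValueError("no records given")
    return out


def position_ratio_bin(position: int, length: int, n_bins: int = N_BINS) -> int:
    """Map a 1-based position into one of `n_bins` length-normalised bins."""
    if not 1 <= position <= length:
        raise ValueError(f"position {position} outside 1..{length}")
    return min((position - 1) * n_bins // length + 1, n_bins)


@dataclass
class PositionRatioProfile:
    """Per-bin mean and variance of pooled position scores; NaN marks an
    empty bin."""

    mean: np.ndarray  # (n_bins,)
    var: np.ndarray  # (n_bins,)
    count: np.ndarray  # (n_bins,) int

    def top_bins(self, n: int = 3) -> list[int]:
        """1-based bins ranked by mean score, descending, NaNs last."""
        order = np.argsort(np.where(np.isnan(self.mean), -np.inf, self.mean))[::-1]
        return [int(b) + 1 for b in order[:n]]


def position_ratio_profile(results: list[ISMMatrix], n_bins: int = N_BINS) -> PositionRatioProfile:
    """Pool every per-position score of a record set into its bin."""
    if not results:
        raise ValueError("no ISM results given")
    pooled: list[list[float]] = [[] for _ in range(n_bins)]
    for ism in results:
        scores = position_scores(ism)
        length = len(ism.reference)
        for p in range(1, length + 1):
            pooled[position_ratio_bin(p, length, n_bins) - 1].append(scores[p - 1])
    mean = np.full(n_bins, np.nan)
    var = np.full(n_bins, np.nan)
    count = np.zeros(n_bins, dtype=int)
    for b, vals in enumerate(pooled):
        count[b] = len(vals)
        if vals:
            mean[b] = float(np.mean(vals))
            var[b] = float(np.var(vals))
    return PositionRatioProfile(mean=mean, var=var, count=count)


def aa_position_map(results: list[ISMMatrix], n_bins: int = N_BINS) -> np.ndarray:
    """20 x n_bins map of mean position scores, min-max normalised to [0, 1].

    Cell (a, b) pools the position scores of every residue `a` falling in
    bin `b` over the record set (intended for the toxic class); empty
    cells are NaN and excluded from the normalisation.
    """
    if not results:
        raise ValueError("no ISM results given")
    total = np.zeros((20, n_bins))
    count = np.zeros((20, n_bins))
    for ism in results:
        scores = position_scores(ism)
        length = len(ism.reference)
        for p, ref in enumerate(ism.reference, start=1):
            b = position_ratio_bin(p, length, n_bins) - 1
            total[AA_INDEX[ref], b] += scores[p - 1]
            count[AA_INDEX[ref], b] += 1
    with np.errstate(invalid="ignore"):
        raw = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    occupied = ~np.isnan(raw)
    lo, hi = np.nanmin(raw), np.nanmax(raw)
    norm = np.full_like(raw, np.nan)
    if hi > lo:
        norm[occupied] = (raw[occupied] - lo) / (hi - lo)
    else:
        norm[occupied] = 1.0
    return norm


# --------------------------------------------------------------------------
# clipping scans
# --------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def truncate_sequence(seq: str, ratio: float, mode: str) -> str:
    """Remove round(ratio*L) residues from the chosen end(s); never empty."""
    if not 0.0 <= ratio < 1.0:
        raise ValueError(f"clipping ratio must be in [0, 1), got {ratio}")
    length = len(seq)
    if mode == "forward":
        n = min(_round_half_up(ratio * length), length - 1)
        return seq[n:]
    if mode == "backward":
        n = min(_round_half_up(ratio * length), length - 1)
        return seq[: length - n]
    if mode == "both":
        n = _round_half_up(ratio * length / 2.0)
        if length - 2 * n < 1:
            mid = (length - 1) // 2
            return seq[mid : mid + 1]
        return seq[n : length - n]
    raise ValueError(f"unknown clip mode {mode!r}")


@dataclass
class ClipScanResult:
    mode: str
    ratios: list[float]
    reports: list[MetricReport] = field(default_factory=list)

    def bacc_curve(self) -> list[float]:
        return [r.bacc for r in self.reports]

    def mcc_curve(self) -> list[float]:
        return [r.mcc for r in self.reports]


def clip_scan(
    model: CAPTPModel,
    records: list[PeptideRecord],
    ratios: list[float],
    mode: str,
) -> ClipScanResult:
    """Re-evaluate the model on progressively truncated copies of `records`."""
    result = ClipScanResult(mode=mode, ratios=list(ratios))
    for r in ratios:
        clipped = [
            PeptideRecord(rec.id, truncate_sequence(rec.sequence, r, mode), rec.label, rec.source)
            for rec in records
        ]
        result.reports.append(evaluate_model(model, clipped))
    return result


def ism_for_records(
    model: CAPTPModel, records: list[PeptideRecord], batch_size: int = 512
) -> list[ISMMatrix]:
    return [ism_matrix(model, r, batch_size=batch_size) for r in records]


def toxic_subset(records: list[PeptideRecord]) -> list[PeptideRecord]:
    return [r for r in records if r.label == LABEL_TOXIC]
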