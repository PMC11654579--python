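"""Seeded generator of imbalanced labelled peptide corpora.

The generator emulates the shape of a curated toxicity corpus — a ~1:2.5
toxic:non-toxic imbalance over peptides of 5-50 residues — while planting
short class-discriminative motifs in the toxic class so that downstream
recovery is checkable: by default one motif in the head region (first
length-decile) and one in the central region (deciles 5-6), mirroring
where real toxicity-relevant patterns concentrate. Negatives are pure
background. Region placement reuses the same position-ratio binning as the
interpretation suite, so "the planted motif sits in bin 1" is true by
construction, not approximately.

Backgrounds are uniform over the 20 residues by default (which maximises
motif contrast); a natural-composition preset is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .interpretation import position_ratio_bin
from .sequence_io import (
    AMINO_ACIDS,
    LABEL_NON_TOXIC,
    LABEL_TOXIC,
    PeptideRecord,
    validate_record,
)

_REGION_BINS = {"head": (1,), "center": (5, 6), "tail": (10,), "uniform": tuple(range(1, 11))}

# Swiss-Prot-like residue frequencies, renormalised over the 20 standard letters.
NATURAL_AAC = {
    "A": 0.0826, "C": 0.0139, "D": 0.0546, "E": 0.0672, "F": 0.0387,
    "G": 0.0708, "H": 0.0228, "I": 0.0593, "K": 0.0580, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0474, "Q": 0.0393, "R": 0.0553,
    "S": 0.0660, "T": 0.0535, "V": 0.0687, "W": 0.0110, "Y": 0.0292,
}


@dataclass
class MotifSpec:
    """A short motif planted in a region of positive sequences."""

    motif: str = "WKKR"
    region: str = "head"
    insertion_prob: float = 1.0
    mutation_rate: float = 0.0

    def __post_init__(self):
        if self.region not in _REGION_BINS:
            raise ValueError(f"region must be one of {sorted(_REGION_BINS)}")
        if not all(c in AMINO_ACIDS for c in self.motif):
            raise ValueError(f"motif {self.motif!r} has non-standard residues")
        if not 0.0 <= self.insertion_prob <= 1.0 or not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("probabilities must be in [0, 1]")


def default_motifs() -> list[MotifSpec]:
    """One head motif and one central motif, occasionally corrupted.

    Insertion probabilities are deliberately below 1 so a substantial
    fraction of toxic peptides carry only one of the two motifs — if nearly
    every positive carried both, either motif alone would be redundant for
    classification and mutagenesis would under-attribute it.
    """
    return [
        MotifSpec("WKKR", "head", insertion_prob=0.6, mutation_rate=0.03),
        MotifSpec("CCHF", "center", insertion_prob=0.6, mutation_rate=0.03),
    ]


@dataclass
class CorpusSpec:
    """Study conditions for one synthetic corpus (defaults: 1:2.5 imbalance,
    lengths 5-50, uniform background, head + center motifs)."""

    n_pos: int = 570
    n_neg: int = 1425
    min_len: int = 5
    max_len: int = 50
    background: dict[str, float] | None = None  # None = uniform
    motifs: list[MotifSpec] = field(default_factory=default_motifs)
    seed: int = 0

    def __post_init__(self):
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("class sizes must be non-negative")
        if not 1 <= self.min_len <= self.max_len:
            raise ValueError("need 1 <= min_len <= max_len")
        for m in self.motifs:
            if len(m.motif) >= self.min_len:
                raise ValueError(
                    f"motif {m.motif!r} is not shorter than the minimum length {self.min_len}"
                )


def _background_probs(spec: CorpusSpec) -> np.ndarray:
    if spec.background is None:
        return np.full(20, 0.05)
    p = np.array([spec.background.get(aa, 0.0) for aa in AMINO_ACIDS], dtype=float)
    if p.sum() <= 0:
        raise ValueError("background distribution sums to zero")
    return p / p.sum()


def _motif_start(rng: np.random.Generator, length: int, m: int, region: str) -> int:
    """0-based start placing the motif inside the region's position-ratio bins.

    Chooses uniformly among the starts that minimise the number of motif
    residues falling outside the region — zero spill whenever the sequence
    is long enough for the region's bins to hold the whole motif, the
    tightest achievable placement otherwise (short sequences have bins
    narrower than the motif).
    """
    bins = _REGION_BINS[region]
    spill = [
        (
            sum(position_ratio_bin(q, length) not in bins for q in range(p, p + m)),
            p - 1,
        )
        for p in range(1, length - m + 2)
    ]
    best = min(s for s, _ in spill)
    candidates = [start for s, start in spill if s == best]
    return int(rng.choice(candidates))


def _plant(rng: np.random.Generator, seq: list[str], motif: MotifSpec, length: int) -> None:
    start = _motif_start(rng, length, len(motif.motif), motif.region)
    for i, aa in enumerate(motif.motif):
        if motif.mutation_rate > 0 and rng.random() < motif.mutation_rate:
            aa = AMINO_ACIDS[rng.integers(20)]
        seq[start + i] = aa


def generate_corpus(spec: CorpusSpec | None = None) -> list[PeptideRecord]:
    """Draw a labelled corpus; deterministic for a fixed spec seed."""
    spec = spec or CorpusSpec()
    rng = np.random.default_rng(spec.seed)
    probs = _background_probs(spec)
    alphabet = np.array(list(AMINO_ACIDS))
    records: list[PeptideRecord] = []
    for label, n, prefix in (
        (LABEL_TOXIC, spec.n_pos, "pos"),
        (LABEL_NON_TOXIC, spec.n_neg, "neg"),
    ):
        for i in range(n):
            length = int(rng.integers(spec.min_len, spec.max_len + 1))
            seq = list(rng.choice(alphabet, size=length, p=probs))
            if label == LABEL_TOXIC and spec.motifs:
                planted = False
                for motif in spec.motifs:
                    if rng.random() < motif.insertion_prob:
                        _plant(rng, seq, motif, length)
                        planted = True
                if not planted:
                    # every toxic peptide carries at least one motif, else it
                    # would be indistinguishable from background
                    _plant(rng, seq, spec.motifs[int(rng.integers(len(spec.motifs)))], length)
            rec = PeptideRecord(f"{prefix}_{i:05d}", "".join(seq), label, "synthetic")
            assert validate_record(rec, spec.max_len)
            records.append(rec)
    return records


def corpus_stats(records: list[PeptideRecord]) -> dict:
    """Class counts, per-class length histograms, and per-class AAC."""
    if not records:
        raise ValueError("empty corpus")
    stats: dict = {"n": len(records), "classes": {}}
    for lab in sorted({r.label for r in records}):
        members = [r for r in records if r.label == lab]
        lengths = np.array([len(r.sequence) for r in members])
        counts = np.zeros(20)
        for r in members:
            for aa in r.sequence:
                counts[AMINO_ACIDS.index(aa)] += 1
        stats["classes"][lab] = {
            "count": len(members),
            "length_min": int(lengths.min()),
            "length_max": int(lengths.max()),
            "length_mean": float(lengths.mean()),
            "length_hist": {int(l): int(c) for l, c in zip(*np.unique(lengths, return_counts=True))},
            "aac": {aa: float(c / counts.sum()) for aa, c in zip(AMINO_ACIDS, counts)},
        }
    return stats
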