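"""Dataset-construction workflow for the toxicity corpus.

The pipeline mirrors how the training corpus is curated from several
labelled source collections: merge sources verbatim, drop every sequence
that carries contradictory labels across sources, deduplicate exact
sequence copies, reduce redundancy at 90% pairwise identity, and draw a
stratified 85/15 train/test split.

The redundancy reducer is a greedy longest-first clusterer with an ungapped
end-anchored identity (matches over the shorter length). It approximates
CD-HIT's behaviour without the compiled dependency; a hook shells out to a
``cd-hit`` binary when one is available, but the internal method is the
tested default.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sequence_io import LABEL_NON_TOXIC, LABEL_TOXIC, PeptideRecord, read_fasta, write_fasta


@dataclass
class CurationReport:
    """Per-stage record counts; serialisable with dataclasses.asdict."""

    n_input: dict[str, int] = field(default_factory=dict)
    n_conflict_removed: int = 0
    n_after_dedup: dict[str, int] = field(default_factory=dict)
    n_after_redundancy: dict[str, int] = field(default_factory=dict)
    n_train: dict[str, int] = field(default_factory=dict)
    n_test: dict[str, int] = field(default_factory=dict)
    seed: int = 0


def merge_sources(sources: list[list[PeptideRecord]]) -> list[PeptideRecord]:
    """Concatenate labelled sources; duplicates are deliberately retained."""
    merged: list[PeptideRecord] = []
    for src in sources:
        merged.extend(src)
    return merged


def remove_conflicts(records: list[PeptideRecord]) -> tuple[list[PeptideRecord], int]:
    """Drop every copy of any sequence that appears with both labels."""
    labels_by_seq: dict[str, set[str]] = {}
    for r in records:
        labels_by_seq.setdefault(r.sequence, set()).add(r.label)
    conflicted = {s for s, labs in labels_by_seq.items() if len(labs) > 1}
    kept = [r for r in records if r.sequence not in conflicted]
    return kept, len(records) - len(kept)


def deduplicate(records: list[PeptideRecord]) -> list[PeptideRecord]:
    """One record per unique sequence; the first occurrence wins."""
    seen: set[str] = set()
    out = []
    for r in records:
        if r.sequence not in seen:
            seen.add(r.sequence)
            out.append(r)
    return out


def pairwise_identity(a: str, b: str) -> float:
    """Ungapped zero-offset identity: matching positions over the shorter length."""
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return sum(x == y for x, y in zip(a[:n], b[:n])) / n


def reduce_redundancy(
    records: list[PeptideRecord], threshold: float = 0.9
) -> tuple[list[PeptideRecord], dict[str, str]]:
    """Greedy longest-first clustering at `threshold` identity.

    Records are visited longest first (ties broken lexicographically by
    sequence); each joins the first representative it matches at >= threshold
    identity, else founds a new cluster. Returns the representatives and a
    map record_id -> representative_id.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"identity threshold must be in (0, 1], got {threshold}")
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.sequence))
    reps: list[PeptideRecord] = []
    assignment: dict[str, str] = {}
    for r in ordered:
        for rep in reps:
            if pairwise_identity(r.sequence, rep.sequence) >= threshold:
                assignment[r.id] = rep.id
                break
        else:
            reps.append(r)
            assignment[r.id] = r.id
    return reps, assignment


def reduce_redundancy_cdhit(
    records: list[PeptideRecord], threshold: float = 0.9, binary: str = "cd-hit"
) -> list[PeptideRecord]:
    """Optional hook: cluster with an external cd-hit binary if installed."""
    if shutil.which(binary) is None:
        raise FileNotFoundError(f"{binary} not found on PATH; use reduce_redundancy instead")
    with tempfile.TemporaryDirectory() as tmp:
        fin, fout = Path(tmp) / "in.fasta", Path(tmp) / "out"
        write_fasta(records, fin)
        subprocess.run(
            [binary, "-i", str(fin), "-o", str(fout), "-c", str(threshold), "-n", "2", "-l", "4"],
            check=True,
            capture_output=True,
        )
        by_id = {r.id: r for r in records}
        return [by_id[r.id] for r in read_fasta(fout) if r.id in by_id]


def stratified_split(
    records: list[PeptideRecord],
    test_fraction: float = 0.15,
    seed: int = 0,
) -> tuple[list[PeptideRecord], list[PeptideRecord], CurationReport]:
    """Seeded per-class split; the test set gets exactly floor(f*N) per class.

    On class totals 2138/5375 at f=0.15 this yields test 320/806 and train
    1818/4569. Record order within each partition follows the input order.
    """
    classes = {LABEL_TOXIC: [], LABEL_NON_TOXIC: []}
    for r in records:
        if r.label not in classes:
            raise ValueError(f"record {r.id!r} is unlabelled; curate labels first")
        classes[r.label].append(r)
    rng = np.random.default_rng(seed)
    test_ids: set[int] = set()
    report = CurationReport(seed=seed)
    for lab, members in classes.items():
        if len(members) < 2:
            raise ValueError(f"class {lab!r} has fewer than 2 records")
        n_test = math.floor(test_fraction * len(members))
        chosen = rng.choice(len(members), size=n_test, replace=False)
        test_ids.update(id(members[i]) for i in chosen)
        report.n_test[lab] = n_test
        report.n_train[lab] = len(members) - n_test
    train = [r for r in records if id(r) not in test_ids]
    test = [r for r in records if id(r) in test_ids]
    return train, test, report


def curate(
    sources: dict[str, list[PeptideRecord]],
    threshold: float = 0.9,
    test_fraction: float = 0.15,
    seed: int = 0,
) -> tuple[list[PeptideRecord], list[PeptideRecord], CurationReport]:
    """Run the full pipeline: merge, de-conflict, dedup, reduce, split."""
    merged = merge_sources(list(sources.values()))
    kept, n_conflict = remove_conflicts(merged)
    deduped = deduplicate(kept)
    reps, _ = reduce_redundancy(deduped, threshold)
    train, test, report = stratified_split(reps, test_fraction, seed)
    report.n_input = {name: len(v) for name, v in sources.items()}
    report.n_conflict_removed = n_conflict
    report.n_after_dedup = _class_counts(deduped)
    report.n_after_redundancy = _class_counts(reps)
    return train, test, report


def _class_counts(records: list[PeptideRecord]) -> dict[str, int]:
    counts = {LABEL_TOXIC: 0, LABEL_NON_TOXIC: 0}
    for r in records:
        counts[r.label] = counts.get(r.label, 0) + 1
    return counts
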