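"""Peptide FASTA I/O, validation, and integer encoding.

Peptides are short amino-acid sequences over the 20 standard letters; the
toxicity model consumes them as right-padded token-index matrices. The
vocabulary is fixed and published so checkpoints are reproducible:
alphabetical ``A..Y -> 1..20``, ``PAD = 0``, and a ``CLS`` marker at index
21 that is prepended only when the model pools the CLS row.

Labels travel either in the FASTA header (``>id|toxic`` / ``>id|non_toxic``)
or in a CSV sidecar with columns ``id,label``.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"  # alphabetical
PAD_INDEX = 0
CLS_INDEX = 21
TOKEN_INDEX = {aa: i + 1 for i, aa in enumerate(AMINO_ACIDS)}
INDEX_TOKEN = {i: aa for aa, i in TOKEN_INDEX.items()}
DEFAULT_MAX_LEN = 50

LABEL_TOXIC = "toxic"
LABEL_NON_TOXIC = "non_toxic"
LABEL_UNLABELLED = "unlabelled"
_LABELS = {LABEL_TOXIC, LABEL_NON_TOXIC, LABEL_UNLABELLED}


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed; carries the offending line."""

    def __init__(self, message: str, line: int):
        super().__init__(f"{message} (line {line})")
        self.line = line


@dataclass
class PeptideRecord:
    """One labelled peptide sequence with provenance."""

    id: str
    sequence: str
    label: str = LABEL_UNLABELLED
    source: str = ""

    def __post_init__(self):
        if self.label not in _LABELS:
            raise ValueError(f"unknown label {self.label!r} for record {self.id!r}")
        self.sequence = self.sequence.upper()


@dataclass
class EncodedBatch:
    """Model-ready padded token matrix with mask, labels and lengths."""

    tokens: np.ndarray  # (batch, max_len) int
    mask: np.ndarray  # (batch, max_len) bool
    labels: np.ndarray  # (batch,) int in {0,1}; -1 for unlabelled
    lengths: np.ndarray  # (batch,) int
    ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return self.tokens.shape[0]


def validate_record(record: PeptideRecord, max_len: int = DEFAULT_MAX_LEN) -> bool:
    """True iff the sequence uses only standard residues and 1 <= length <= max_len."""
    seq = record.sequence
    return 0 < len(seq) <= max_len and all(c in TOKEN_INDEX for c in seq)


def _label_from_header(header: str) -> tuple[str, str]:
    """Split a ``id|label`` header; returns (id, label)."""
    if "|" in header:
        rid, _, tag = header.rpartition("|")
        if tag in (LABEL_TOXIC, LABEL_NON_TOXIC):
            return rid, tag
    return header, LABEL_UNLABELLED


def read_label_sidecar(path: str | Path) -> dict[str, str]:
    """Read a CSV sidecar with columns id,label into a dict."""
    labels: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            lab = row["label"].strip().lower()
            if lab not in (LABEL_TOXIC, LABEL_NON_TOXIC):
                raise ValueError(f"unknown label {lab!r} for id {row['id']!r}")
            labels[row["id"].strip()] = lab
    return labels


def read_fasta(
    path: str | Path,
    label: str | None = None,
    sidecar: dict[str, str] | str | Path | None = None,
    source: str = "",
) -> list[PeptideRecord]:
    """Read peptides from FASTA, in file order.

    Label assignment, in precedence order: the `label` argument applied to
    all records; a sidecar mapping id -> label; a ``|toxic`` / ``|non_toxic``
    header suffix; otherwise unlabelled. Residues are upcased; CRLF and
    wrapped sequences are accepted. Sequence validity is NOT enforced here —
    use :func:`validate_record` so callers can report invalid entries.
    """
    path = Path(path)
    _check_fasta_shape(path)
    if isinstance(sidecar, (str, Path)):
        sidecar = read_label_sidecar(sidecar)
    if not source:
        source = path.stem
    records: list[PeptideRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        header = entry.description.split()[0] if entry.description else entry.id
        rid, header_label = _label_from_header(header)
        if label is not None:
            lab = label
        elif sidecar is not None and rid in sidecar:
            lab = sidecar[rid]
        else:
            lab = header_label
        records.append(PeptideRecord(rid, str(entry.seq).upper(), lab, source))
    if not records:
        warnings.warn(f"no FASTA records in {path}", stacklevel=2)
    return records


def _check_fasta_shape(path: Path) -> None:
    """Reject text that is not FASTA, reporting the offending line number."""
    with open(path) as fh:
        in_record = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            if line.startswith(">"):
                in_record = True
            elif not in_record:
                raise FastaParseError("sequence data before any '>' header", lineno)


def write_fasta(records: list[PeptideRecord], path: str | Path, with_labels: bool = True) -> None:
    """Write records as single-line FASTA; labels go into ``id|label`` headers."""
    out = []
    for r in records:
        header = f"{r.id}|{r.label}" if with_labels and r.label != LABEL_UNLABELLED else r.id
        out.append(SeqRecord(Seq(r.sequence), id=header, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=None)
        writer.write_file(out)


def encode_batch(
    records: list[PeptideRecord],
    max_len: int = DEFAULT_MAX_LEN,
    add_cls: bool = False,
) -> EncodedBatch:
    """Encode validated records into a right-padded token matrix.

    With ``add_cls`` the CLS index is prepended and the padded width grows to
    ``max_len + 1`` so a full-length peptide still fits.
    """
    width = max_len + 1 if add_cls else max_len
    n = len(records)
    tokens = np.zeros((n, width), dtype=np.int64)
    mask = np.zeros((n, width), dtype=bool)
    labels = np.full(n, -1, dtype=np.int64)
    lengths = np.zeros(n, dtype=np.int64)
    ids = []
    for i, r in enumerate(records):
        if len(r.sequence) > max_len:
            raise ValueError(f"record {r.id!r} exceeds max_len={max_len}")
        if not validate_record(r, max_len):
            raise ValueError(f"record {r.id!r} has a non-standard residue")
        idx = [TOKEN_INDEX[c] for c in r.sequence]
        if add_cls:
            idx = [CLS_INDEX] + idx
        tokens[i, : len(idx)] = idx
        mask[i, : len(idx)] = True
        lengths[i] = len(idx)
        if r.label == LABEL_TOXIC:
            labels[i] = 1
        elif r.label == LABEL_NON_TOXIC:
            labels[i] = 0
        ids.append(r.id)
    return EncodedBatch(tokens, mask, labels, lengths, ids)


def decode_tokens(tokens: np.ndarray) -> str:
    """Inverse of encoding for one row: drop PAD and CLS, map indices back."""
    return "".join(INDEX_TOKEN[t] for t in np.asarray(tokens).tolist() if t in INDEX_TOKEN)
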