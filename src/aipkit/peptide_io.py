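"""Reading, validating and padding peptide sequences.

Peptides are short (1-25 residues after truncation) strings over the 20
standard amino acids.  Shorter peptides are padded with ``'-'`` gaps up to a
fixed 25-symbol window so that every downstream encoding has a constant
dimension; for positional enrichment analysis the first 15 N-terminal
positions are used instead, with missing positions coded ``'O'``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

#: The 20 standard amino acids in alphabetical one-letter order.  This order
#: is frozen: every encoder indexes residues by position in this string.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
#: Fill symbol for non-existing positions in the 15-residue analysis window.
ANALYSIS_FILL = "O"
#: Fixed padding window: encodings are defined over 25 positions.
WINDOW = 25
#: N-terminal span used by positional enrichment analysis.
ANALYSIS_SPAN = 15

_AA_SET = frozenset(AMINO_ACIDS)


class PeptideError(ValueError):
    """Invalid peptide sequence or FASTA content."""


@dataclass(frozen=True)
class PeptideRecord:
    """A validated peptide: identifier plus residue string (no padding).

    ``sequence`` holds only residues (gaps never stored); use
    :meth:`padded` for the fixed-window form.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise PeptideError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in _AA_SET:
                raise PeptideError(
                    f"record {self.id!r}: non-standard symbol {ch!r} at "
                    f"position {pos} (alphabet is the 20 standard amino acids)"
                )

    @property
    def raw_length(self) -> int:
        return len(self.sequence)

    def padded(self, window: int = WINDOW) -> str:
        return pad_peptide(self.sequence, window=window)

    def analysis_window(self, span: int = ANALYSIS_SPAN) -> str:
        return fill_O_for_analysis(self.sequence, span=span)


@dataclass
class LabeledDataset:
    """Ordered peptide records with binary class labels (1=positive, 0=negative)."""

    records: list[PeptideRecord]
    labels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) and len(self.labels) != len(self.records):
            raise PeptideError(
                f"{len(self.records)} records but {len(self.labels)} labels"
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def require_both_classes(self) -> None:
        if len(set(self.labels.tolist())) < 2:
            raise PeptideError("training requires both positive and negative labels")


def _clean_sequence(name: str, seq: str, max_length: int) -> str:
    seq = seq.strip()
    if not seq:
        raise PeptideError(f"record {name!r}: empty sequence")
    if seq != seq.upper():
        warnings.warn(f"record {name!r}: lowercase residues upper-cased", stacklevel=3)
        seq = seq.upper()
    seq = seq.replace(GAP, "")  # stored form is gap-free
    if len(seq) > max_length:
        log.warning(
            "record %r: %d residues, truncated to first %d", name, len(seq), max_length
        )
        seq = seq[:max_length]
    return seq


def read_fasta(
    path: str | Path, max_length: int = WINDOW, errors: str = "raise"
) -> list[PeptideRecord]:
    """Read peptides from a FASTA file.

    Sequences longer than ``max_length`` are truncated to their first
    ``max_length`` residues (with a logged warning); lowercase input is
    upper-cased.  Non-standard letters (including B, J, O, U, X, Z) are
    rejected with a diagnostic naming the symbol and its position; with
    ``errors="skip"`` the offending record is dropped instead.
    """
    path = Path(path)
    if errors not in ("raise", "skip"):
        raise ValueError("errors must be 'raise' or 'skip'")
    records: list[PeptideRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        try:
            seq = _clean_sequence(entry.id, str(entry.seq), max_length)
            records.append(PeptideRecord(id=entry.id, sequence=seq))
        except PeptideError:
            if errors == "raise":
                raise
            log.warning("skipping invalid record %r", entry.id)
    if not records:
        raise PeptideError(f"no FASTA records read from {path}")
    return records


def write_fasta(records: Iterable[PeptideRecord], path: str | Path) -> None:
    entries = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(entries, str(path), "fasta")


def read_labeled_fasta(
    positive_path: str | Path, negative_path: str | Path, max_length: int = WINDOW
) -> LabeledDataset:
    """Build a dataset from the field's usual shape: one FASTA per class."""
    pos = read_fasta(positive_path, max_length=max_length)
    neg = read_fasta(negative_path, max_length=max_length)
    labels = np.concatenate([np.ones(len(pos), int), np.zeros(len(neg), int)])
    return LabeledDataset(records=pos + neg, labels=labels)


_LABEL_ALIASES = {
    "1": 1, "pos": 1, "positive": 1, "aip": 1, "true": 1,
    "0": 0, "neg": 0, "negative": 0, "non-aip": 0, "false": 0,
}


def read_label_file(path: str | Path) -> dict[str, int]:
    """Read a two-column delimited label file: ``id<TAB>label``.

    Labels may be 1/0, positive/negative or pos/neg (case-insensitive).
    A header line ``id\\tlabel`` is permitted and skipped.
    """
    labels: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise PeptideError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
        key, raw = parts[0].strip(), parts[1].strip().lower()
        if lineno == 1 and (key.lower(), raw) == ("id", "label"):
            continue
        if raw not in _LABEL_ALIASES:
            raise PeptideError(f"{path}:{lineno}: unrecognised label {parts[1]!r}")
        labels[key] = _LABEL_ALIASES[raw]
    if not labels:
        raise PeptideError(f"no labels read from {path}")
    return labels


def attach_labels(
    records: Sequence[PeptideRecord], labels: dict[str, int]
) -> LabeledDataset:
    missing = [r.id for r in records if r.id not in labels]
    if missing:
        raise PeptideError(f"no label for record(s): {', '.join(missing[:5])}")
    y = np.array([labels[r.id] for r in records], dtype=int)
    return LabeledDataset(records=list(records), labels=y)


def pad_peptide(sequence: str, window: int = WINDOW) -> str:
    """Left-align ``sequence`` in a ``window``-symbol frame, gap-filling the tail.

    Raises if the sequence is empty or longer than the window (callers must
    truncate first).
    """
    if not sequence:
        raise PeptideError("cannot pad an empty sequence")
    if len(sequence) > window:
        raise PeptideError(
            f"sequence of length {len(sequence)} exceeds window {window}; truncate first"
        )
    return sequence + GAP * (window - len(sequence))


def fill_O_for_analysis(sequence: str, span: int = ANALYSIS_SPAN) -> str:
    """First ``span`` N-terminal symbols, with non-existing positions coded 'O'."""
    head = sequence[:span]
    return head + ANALYSIS_FILL * (span - len(head))


def write_predictions(table, path: str | Path) -> None:
    """Write a prediction table as TSV with header (NA for absent values)."""
    table.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
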