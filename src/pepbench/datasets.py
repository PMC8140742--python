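"""Labelled peptide datasets: FASTA I/O, validation and synthetic fixtures.

A dataset is an ordered collection of uniquely named amino-acid sequences,
each carrying a binary class label.  Labels live either in the FASTA header
(``>id|label``) or in a sidecar CSV with columns ``id,label``; the sidecar
wins when both are present.  Sequences are restricted to the 20 natural
amino acids; ambiguity codes (B, J, O, U, X, Z) and gap characters are
rejected in strict mode and dropped with a log message in lenient mode.

The synthetic generator produces two-class datasets whose positive class
carries a controllable residue-composition bias, the simplest signal a
compositional encoding can detect.
"""

from __future__ import annotations

import csv
import logging
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from pepbench.errors import (
    EmptyInputError,
    InvalidParameterError,
    LabelingError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: The 20 natural amino acids, alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class SequenceRecord:
    """One labelled peptide: unique id, sequence, binary class in {0, 1}."""

    id: str
    sequence: str
    label: int

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        if self.label not in (0, 1):
            raise ValidationError(f"record {self.id!r}: label must be 0 or 1, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PeptideDataset:
    """Named, ordered set of labelled peptide sequences."""

    name: str
    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValidationError(f"dataset {self.name!r}: duplicate record id {dup!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def label_map(self) -> dict[str, int]:
        return {r.id: r.label for r in self.records}

    def subset(self, ids: Iterable[str]) -> "PeptideDataset":
        """Records whose id is in ``ids``, original order preserved."""
        wanted = set(ids)
        return PeptideDataset(self.name, [r for r in self.records if r.id in wanted])

    def duplicate_sequences(self) -> list[tuple[str, str]]:
        """Pairs of record ids sharing an identical sequence (flagged, never removed)."""
        by_seq: dict[str, str] = {}
        dups = []
        for r in self.records:
            if r.sequence in by_seq:
                dups.append((by_seq[r.sequence], r.id))
            else:
                by_seq[r.sequence] = r.id
        return dups


def _sanitize(seq: str, record_id: str, strict: bool) -> str | None:
    """Uppercase and validate one raw sequence; None means drop (lenient mode)."""
    seq = seq.upper().strip().strip("*")
    bad = sorted(set(seq) - _AA_SET)
    if bad:
        msg = f"record {record_id!r}: non-standard symbol(s) {''.join(bad)!r}"
        if strict:
            raise ValidationError(msg)
        logger.warning("dropping %s", msg)
        return None
    if not seq:
        msg = f"record {record_id!r}: empty sequence after sanitization"
        if strict:
            raise ValidationError(msg)
        logger.warning("dropping %s", msg)
        return None
    return seq


def _parse_label(raw: str, record_id: str) -> int:
    try:
        value = int(raw)
    except (TypeError, ValueError):
        raise LabelingError(f"record {record_id!r}: label {raw!r} is not 0/1") from None
    if value not in (0, 1):
        raise LabelingError(f"record {record_id!r}: label {value} is not 0/1")
    return value


def read_label_table(path: str | Path) -> dict[str, int]:
    """Read a sidecar CSV with header ``id,label`` into a mapping."""
    table: dict[str, int] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"id", "label"} <= set(reader.fieldnames):
            raise ValidationError(f"{path}: sidecar table must have columns id,label")
        for row in reader:
            table[row["id"]] = _parse_label(row["label"], row["id"])
    return table


def read_fasta_dataset(
    path: str | Path,
    labels: str | Path | None = None,
    *,
    name: str | None = None,
    strict: bool = True,
) -> PeptideDataset:
    """Read a labelled peptide dataset from FASTA.

    Labels come from the header convention ``>id|label``; a sidecar CSV
    (columns ``id,label``) overrides headers.  Record order is preserved.

    Parameters
    ----------
    path:
        FASTA file (single-line or wrapped).
    labels:
        Optional sidecar CSV path.
    strict:
        If True (default), any non-standard residue raises; if False the
        offending records are dropped with a log message.
    """
    path = Path(path)
    sidecar = read_label_table(labels) if labels is not None else {}
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rec_id, sep, header_label = rec.id.partition("|")
        if rec_id in sidecar:
            label = sidecar[rec_id]
        elif sep:
            label = _parse_label(header_label, rec_id)
        else:
            raise LabelingError(
                f"record {rec_id!r}: no '|label' header suffix and no sidecar row"
            )
        seq = _sanitize(str(rec.seq), rec_id, strict)
        if seq is None:
            continue
        records.append(SequenceRecord(rec_id, seq, label))
    if not records:
        raise EmptyInputError(f"{path}: no records parsed")
    ds = PeptideDataset(name or path.stem, records)
    dups = ds.duplicate_sequences()
    if dups:
        logger.warning("%s: %d duplicated sequence pair(s), kept as-is", ds.name, len(dups))
    return ds


def write_fasta_dataset(dataset: PeptideDataset, path: str | Path) -> None:
    """Write a dataset as FASTA with ``>id|label`` headers (round-trips with the reader)."""
    out = [
        SeqRecord(Seq(r.sequence), id=f"{r.id}|{r.label}", description="")
        for r in dataset.records
    ]
    SeqIO.write(out, str(path), "fasta")


def generate_synthetic_dataset(
    n: int,
    imbalance: float = 0.5,
    length_range: tuple[int, int] = (3, 255),
    bias_residues: Sequence[str] = ("K", "R"),
    bias_strength: float = 0.3,
    seed: int = 0,
    *,
    name: str = "synthetic",
) -> PeptideDataset:
    """Generate a two-class dataset with a composition-biased positive class.

    Negative-class sequences draw residues uniformly from the 20 amino
    acids.  Positive-class sequences move probability mass
    ``bias_strength`` from the uniform background onto ``bias_residues``
    (spread uniformly over them), so the positive class is enriched for
    those residues — a signal any compositional encoding can recover.
    Lengths are uniform over ``length_range``; class sizes are exact:
    ``round(imbalance * n)`` positives.

    Fully deterministic under a fixed ``seed``.
    """
    if n < 2:
        raise InvalidParameterError(f"n must be >= 2, got {n}")
    if not 0.0 < imbalance < 1.0:
        raise InvalidParameterError(f"imbalance must lie in (0, 1), got {imbalance}")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise InvalidParameterError(f"bad length_range {length_range}")
    if not 0.0 <= bias_strength < 1.0:
        raise InvalidParameterError(f"bias_strength must lie in [0, 1), got {bias_strength}")
    bias_idx = [AMINO_ACIDS.index(a) for a in bias_residues]
    if not bias_idx:
        raise InvalidParameterError("bias_residues must be non-empty")

    n_pos = round(imbalance * n)
    if n_pos == 0 or n_pos == n:
        raise InvalidParameterError(
            f"imbalance {imbalance} with n={n} leaves a class empty"
        )

    rng = np.random.default_rng(seed)
    p_neg = np.full(20, 1 / 20)
    p_pos = p_neg * (1 - bias_strength)
    p_pos[bias_idx] += bias_strength / len(bias_idx)

    aa = np.array(list(AMINO_ACIDS))
    records = []
    for i in range(n):
        label = 1 if i < n_pos else 0
        length = int(rng.integers(lo, hi + 1))
        probs = p_pos if label else p_neg
        seq = "".join(aa[rng.choice(20, size=length, p=probs)])
        records.append(SequenceRecord(f"seq{i:04d}", seq, label))
    return PeptideDataset(name, records)


def dataset_summary(dataset: PeptideDataset) -> dict:
    """Counts per class, length statistics and the class-imbalance ratio.

    Imbalance is the minority-class share ``min(class counts) / n``; for a
    single-class dataset the present class is the minority by convention.
    """
    if len(dataset) == 0:
        raise EmptyInputError(f"dataset {dataset.name!r} is empty")
    lengths = [len(r) for r in dataset.records]
    labels = dataset.labels
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    present = [c for c in (n_pos, n_neg) if c > 0]
    return {
        "name": dataset.name,
        "n": len(dataset),
        "n_positive": n_pos,
        "n_negative": n_neg,
        "imbalance": min(present) / len(dataset),
        "min_length": min(lengths),
        "mean_length": statistics.fmean(lengths),
        "median_length": statistics.median(lengths),
        "max_length": max(lengths),
        "duplicate_pairs": len(dataset.duplicate_sequences()),
    }
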