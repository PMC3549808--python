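"""Labelled antigen datasets: per-residue epitope masks on protein sequences.

Two lossless on-disk encodings are supported for per-residue binary epitope
labels:

* **case-coded FASTA** — UPPERCASE residues are epitope, lowercase are
  non-epitope.  Sequences are stored upper-cased in memory; the mask carries
  the labels.
* **plain FASTA + BED3 intervals** — a 3-column tab-separated file
  (``id  start  end``, 0-based half-open) marking epitope segments; the mask
  is true on the union of a record's intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical by one-letter code.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Ambiguity codes accepted in sequences (excluded from composition counts).
AMBIGUOUS_AA = "XBZU"
ALPHABET = frozenset(STANDARD_AA + AMBIGUOUS_AA)


class FastaParseError(ValueError):
    """Malformed FASTA input; message carries the offending line number."""


class AlphabetError(ValueError):
    """A sequence character outside the amino-acid alphabet."""


class EmptyDatasetError(ValueError):
    """A dataset with no records where at least one is required."""


class DuplicateIdError(ValueError):
    """Two records share an id within one dataset."""


class IntervalError(ValueError):
    """An epitope interval is out of bounds or names an unknown sequence."""


@dataclass
class AntigenRecord:
    """One antigen protein with a per-residue binary epitope mask.

    Parameters
    ----------
    id : str
        Unique record identifier.
    sequence : str
        Amino-acid sequence over the 20 standard letters plus X/B/Z/U.
        Stored upper-cased.
    epitope_mask : numpy.ndarray of bool
        ``True`` where the residue belongs to an epitope; same length as
        ``sequence``.
    """

    id: str
    sequence: str
    epitope_mask: np.ndarray

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        for pos, ch in enumerate(self.sequence):
            if ch not in ALPHABET:
                raise AlphabetError(
                    f"record {self.id!r}: character {ch!r} at position {pos} "
                    f"is not an amino-acid letter"
                )
        self.epitope_mask = np.asarray(self.epitope_mask, dtype=bool)
        if self.epitope_mask.shape != (len(self.sequence),):
            raise ValueError(
                f"record {self.id!r}: mask length {self.epitope_mask.size} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AntigenRecord):
            return NotImplemented
        return (
            self.id == other.id
            and self.sequence == other.sequence
            and bool(np.array_equal(self.epitope_mask, other.epitope_mask))
        )


@dataclass
class EpitopeDataset:
    """An ordered collection of :class:`AntigenRecord` with unique ids."""

    records: list[AntigenRecord] = field(default_factory=list)
    name: str = "dataset"

    def __post_init__(self) -> None:
        self.records = list(self.records)
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise DuplicateIdError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AntigenRecord]:
        return iter(self.records)

    def __getitem__(self, record_id: str) -> AntigenRecord:
        for rec in self.records:
            if rec.id == record_id:
                return rec
        raise KeyError(record_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EpitopeDataset):
            return NotImplemented
        return self.records == other.records

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    @property
    def total_residues(self) -> int:
        return sum(len(rec) for rec in self.records)

    @property
    def epitope_residues(self) -> int:
        return int(sum(rec.epitope_mask.sum() for rec in self.records))

    @property
    def nonepitope_residues(self) -> int:
        return self.total_residues - self.epitope_residues

    def subset(self, record_ids: Iterable[str], name: str | None = None) -> "EpitopeDataset":
        """Return a dataset containing the named records, in dataset order."""
        wanted = set(record_ids)
        missing = wanted - set(self.ids)
        if missing:
            raise KeyError(f"unknown record ids: {sorted(missing)}")
        return EpitopeDataset(
            [rec for rec in self.records if rec.id in wanted],
            name=name or self.name,
        )


def read_epitope_fasta(path: str | Path, name: str | None = None) -> EpitopeDataset:
    """Read a case-coded FASTA file (uppercase = epitope residue).

    Raises
    ------
    FastaParseError
        On syntactically malformed input, with the offending line number.
    EmptyDatasetError
        If the file contains no records.
    AlphabetError
        If a sequence character is not an amino-acid letter.
    """
    path = Path(path)
    records: list[AntigenRecord] = []
    current_id: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if current_id is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(f"{path}: record {current_id!r} has no sequence")
        mask = np.fromiter((c.isupper() for c in seq), dtype=bool, count=len(seq))
        records.append(AntigenRecord(current_id, seq, mask))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                current_id = line[1:].split()[0] if line[1:].strip() else ""
                if not current_id:
                    raise FastaParseError(f"{path}:{lineno}: empty record header")
                chunks = []
            else:
                if current_id is None:
                    raise FastaParseError(
                        f"{path}:{lineno}: sequence data before first '>' header"
                    )
                for ch in line:
                    if ch.upper() not in ALPHABET:
                        raise AlphabetError(
                            f"{path}:{lineno}: character {ch!r} is not an "
                            f"amino-acid letter"
                        )
                chunks.append(line)
        flush()

    if not records:
        raise EmptyDatasetError(f"{path}: no FASTA records found")
    return EpitopeDataset(records, name=name or path.stem)


def read_interval_labels(
    fasta_path: str | Path,
    bed_path: str | Path,
    name: str | None = None,
) -> EpitopeDataset:
    """Read plain FASTA plus a BED3 interval file of epitope segments.

    Intervals are 0-based half-open; the mask is true on the union of a
    record's intervals.  Sequence letter case in the FASTA is ignored.
    """
    fasta_path, bed_path = Path(fasta_path), Path(bed_path)
    seqs: dict[str, str] = {}
    order: list[str] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise DuplicateIdError(f"{fasta_path}: duplicate record id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
        order.append(rec.id)
    if not seqs:
        raise EmptyDatasetError(f"{fasta_path}: no FASTA records found")

    masks = {rid: np.zeros(len(seq), dtype=bool) for rid, seq in seqs.items()}
    with open(bed_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise IntervalError(
                    f"{bed_path}:{lineno}: expected 3 columns (id, start, end)"
                )
            rid, start_s, end_s = fields[0], fields[1], fields[2]
            if rid not in seqs:
                raise IntervalError(
                    f"{bed_path}:{lineno}: id {rid!r} not present in {fasta_path}"
                )
            start, end = int(start_s), int(end_s)
            if not (0 <= start < end <= len(seqs[rid])):
                raise IntervalError(
                    f"{bed_path}:{lineno}: interval [{start}, {end}) out of "
                    f"bounds for {rid!r} (length {len(seqs[rid])})"
                )
            masks[rid][start:end] = True

    records = [AntigenRecord(rid, seqs[rid], masks[rid]) for rid in order]
    return EpitopeDataset(records, name=name or fasta_path.stem)


def write_epitope_fasta(
    dataset: EpitopeDataset, path: str | Path, width: int = 60
) -> Path:
    """Write a dataset as case-coded FASTA; inverse of :func:`read_epitope_fasta`."""
    if len(dataset) == 0:
        raise EmptyDatasetError("refusing to write a dataset with no records")
    path = Path(path)
    with open(path, "w") as fh:
        for rec in dataset:
            cased = "".join(
                c.upper() if m else c.lower()
                for c, m in zip(rec.sequence, rec.epitope_mask)
            )
            fh.write(f">{rec.id}\n")
            for i in range(0, len(cased), width):
                fh.write(cased[i : i + width] + "\n")
    return path


def composition_summary(
    epitope_residues: int, nonepitope_residues: int, proteins: int | None = None
) -> dict:
    """Composition statistics from raw residue counts.

    ``epitope_density`` is ``100 * epitope / total``, rounded to two decimals
    (a percentage).
    """
    total = epitope_residues + nonepitope_residues
    if total <= 0:
        raise EmptyDatasetError("summary of zero residues")
    out = {
        "epitope_residues": int(epitope_residues),
        "nonepitope_residues": int(nonepitope_residues),
        "total_residues": int(total),
        "epitope_density": round(100.0 * epitope_residues / total, 2),
    }
    if proteins is not None:
        out = {"proteins": int(proteins), **out}
    return out


def dataset_summary(dataset: EpitopeDataset) -> dict:
    """Per-dataset composition summary (counts and epitope density in %)."""
    if len(dataset) == 0:
        raise EmptyDatasetError(f"dataset {dataset.name!r} has no records")
    return composition_summary(
        dataset.epitope_residues, dataset.nonepitope_residues, proteins=len(dataset)
    )


def write_summary_tsv(datasets: Iterable[EpitopeDataset], path: str | Path) -> Path:
    """Emit a Table-1-style composition summary, one dataset per row."""
    import pandas as pd

    rows = []
    for ds in datasets:
        rows.append({"dataset": ds.name, **dataset_summary(ds)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return Path(path)
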