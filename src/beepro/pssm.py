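"""Per-residue evolutionary-information vectors (position-specific scoring matrices).

Three interchangeable sources are supported:

* ``file`` — parse the ASCII matrix that ``psiblast -out_ascii_pssm`` writes
  (the first 20-column block of per-position log-likelihood scores);
* ``psiblast`` — invoke a local PSI-BLAST against a formatted protein
  database (e-value 0.001, 3 iterations by default) and parse its output;
* ``pseudo`` — a deterministic substitution-score profile (BLOSUM62 row per
  residue) requiring no external tool, used for offline testing.  It carries
  residue-identity information only, not alignment-derived conservation.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from .io_datasets import AMBIGUOUS_AA, STANDARD_AA, AntigenRecord

logger = logging.getLogger(__name__)

#: Column order of the PSI-BLAST ASCII matrix score block.
PSSM_COLUMNS = "ARNDCQEGHILKMFPSTWYV"


class PSSMParseError(ValueError):
    """Malformed ASCII PSSM input."""


class PSSMAlignmentError(ValueError):
    """A PSSM whose rows do not match the associated sequence."""


class PsiblastConfigError(RuntimeError):
    """PSI-BLAST executable or database unavailable."""


class PsiblastRunError(RuntimeError):
    """PSI-BLAST exited with an error; carries captured diagnostics."""


@dataclass
class PSSMatrix:
    """Per-residue 20-value log-likelihood vectors aligned to one sequence."""

    sequence_id: str
    rows: np.ndarray
    source: str = "file"

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.ndim != 2 or self.rows.shape[1] != 20:
            raise ValueError(
                f"PSSM for {self.sequence_id!r}: expected shape (L, 20), "
                f"got {self.rows.shape}"
            )
        if not np.all(np.isfinite(self.rows)):
            raise ValueError(f"PSSM for {self.sequence_id!r}: non-finite values")
        if self.source not in ("psiblast", "file", "pseudo"):
            raise ValueError(f"unknown PSSM source {self.source!r}")

    def __len__(self) -> int:
        return self.rows.shape[0]


def parse_ascii_pssm(path: str | Path, expected_sequence: str) -> PSSMatrix:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file aligned to a sequence.

    Only the first score block (20 log-likelihood columns) is read; the
    percentage block and trailing statistics are ignored.  Row residues must
    match ``expected_sequence`` position by position.
    """
    path = Path(path)
    expected_sequence = expected_sequence.upper()
    rows: list[list[float]] = []
    residues: list[str] = []
    header_seen = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        fields = stripped.split()
        if not header_seen:
            # The column-header line lists the 20 residue letters (twice in
            # full psiblast output: scores then percentages).
            if len(fields) >= 20 and all(f in PSSM_COLUMNS for f in fields[:20]):
                header_seen = True
            continue
        if not fields[0].isdigit():
            break  # trailing K/lambda statistics block
        if len(fields) < 22:
            raise PSSMParseError(
                f"{path}:{lineno}: expected position, residue and 20 scores"
            )
        residues.append(fields[1])
        try:
            rows.append([float(v) for v in fields[2:22]])
        except ValueError as exc:
            raise PSSMParseError(f"{path}:{lineno}: bad score field") from exc
    if not header_seen or not rows:
        raise PSSMParseError(f"{path}: no PSSM score block found")
    if len(rows) != len(expected_sequence):
        raise PSSMAlignmentError(
            f"{path}: {len(rows)} PSSM rows vs sequence length "
            f"{len(expected_sequence)}"
        )
    for i, (file_res, seq_res) in enumerate(zip(residues, expected_sequence)):
        if file_res.upper() != seq_res:
            raise PSSMAlignmentError(
                f"{path}: residue mismatch at position {i}: file has "
                f"{file_res!r}, sequence has {seq_res!r}"
            )
    return PSSMatrix(sequence_id="", rows=np.array(rows), source="file")


def write_ascii_pssm(
    path: str | Path, sequence: str, rows: np.ndarray, sequence_id: str = "query"
) -> Path:
    """Write a matrix in the ASCII dialect :func:`parse_ascii_pssm` reads.

    Used to persist matrices and to build round-trip fixtures.
    """
    rows = np.asarray(rows, dtype=float)
    if rows.shape != (len(sequence), 20):
        raise ValueError(f"rows shape {rows.shape} vs sequence length {len(sequence)}")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"\nLast position-specific scoring matrix computed for {sequence_id}\n")
        fh.write("            " + "  ".join(PSSM_COLUMNS) + "\n")
        for i, (res, row) in enumerate(zip(sequence.upper(), rows), start=1):
            scores = " ".join(f"{v:6.2f}" if v != int(v) else f"{int(v):3d}" for v in row)
            fh.write(f"{i:5d} {res}  {scores}\n")
    return path


def pseudo_pssm(record: AntigenRecord) -> PSSMatrix:
    """Deterministic profile: row *i* is the BLOSUM62 row of residue *i*.

    Ambiguous residues (X/B/Z/U) get an all-zero row.  Pure function of the
    sequence; no randomness, no external tools.
    """
    blosum = substitution_matrices.load("BLOSUM62")
    table = {
        aa: np.array([float(blosum[aa, b]) for b in PSSM_COLUMNS])
        for aa in STANDARD_AA
    }
    zero = np.zeros(20)
    rows = np.stack(
        [zero if aa in AMBIGUOUS_AA else table[aa] for aa in record.sequence]
    )
    return PSSMatrix(sequence_id=record.id, rows=rows, source="pseudo")


def run_psiblast(
    record: AntigenRecord,
    db_path: str | Path,
    evalue: float = 0.001,
    iterations: int = 3,
    executable: str = "psiblast",
) -> PSSMatrix:
    """Generate a PSSM with PSI-BLAST against a formatted protein database.

    Fails fast with :class:`PsiblastConfigError` if the executable or the
    database is missing; on success the ASCII matrix is parsed with
    :func:`parse_ascii_pssm` and the invocation is logged.
    """
    exe = shutil.which(executable)
    if exe is None:
        raise PsiblastConfigError(
            f"PSI-BLAST executable {executable!r} not found on PATH"
        )
    db_path = Path(db_path)
    if not any(db_path.parent.glob(db_path.name + "*")):
        raise PsiblastConfigError(f"protein database {db_path} not found")

    with tempfile.TemporaryDirectory(prefix="beepro_psiblast_") as tmp:
        tmp = Path(tmp)
        query = tmp / "query.fasta"
        query.write_text(f">{record.id}\n{record.sequence}\n")
        out_pssm = tmp / "query.pssm"
        cmd = [
            exe,
            "-query", str(query),
            "-db", str(db_path),
            "-evalue", str(evalue),
            "-num_iterations", str(iterations),
            "-out_ascii_pssm", str(out_pssm),
            "-out", str(tmp / "query.out"),
        ]
        try:
            version = subprocess.run(
                [exe, "-version"], capture_output=True, text=True, check=False
            ).stdout.strip()
        except OSError:
            version = "unknown"
        logger.info("running PSI-BLAST (%s): %s", version, " ".join(cmd))
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0 or not out_pssm.exists():
            raise PsiblastRunError(
                f"psiblast failed (exit {proc.returncode}): {proc.stderr.strip()}"
            )
        matrix = parse_ascii_pssm(out_pssm, record.sequence)
    matrix.sequence_id = record.id
    matrix.source = "psiblast"
    return matrix


def pssm_row_sum(matrix: PSSMatrix) -> np.ndarray:
    """Per-residue sum of the 20 log-likelihood values (the hybrid PSSM channel)."""
    return matrix.rows.sum(axis=1)


def load_pssm_dir(
    directory: str | Path, record: AntigenRecord, suffix: str = ".pssm"
) -> PSSMatrix:
    """Load ``<directory>/<record id><suffix>`` for one record."""
    path = Path(directory) / f"{record.id}{suffix}"
    if not path.exists():
        raise FileNotFoundError(f"no PSSM file for record {record.id!r}: {path}")
    matrix = parse_ascii_pssm(path, record.sequence)
    matrix.sequence_id = record.id
    return matrix
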