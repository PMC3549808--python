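"""Per-residue feature construction: sliding windows and distance-weighted averages.

Every residue of every protein yields one feature row (terminal positions are
zero-padded, never dropped) and one label: +1 when the central residue of the
window lies in an epitope, -1 otherwise.

Three representations are built here:

* single-scale windows of width *w* (one propensity value per window position);
* PSSM windows of width 20*w* (the 20-value profile row per position);
* hybrid rows with one distance-weighted window average per feature,

      avg_scale = sum_i (1 - f |c - i|) s_i / w

  where *c* is the central position, *f* the linear weighting factor and
  *s_i* the feature's per-residue value (for the PSSM feature, the row sum of
  the 20 log-likelihood values).  The denominator is *w* unconditionally,
  including near the termini where padded positions contribute s_i = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io_datasets import AMBIGUOUS_AA, AntigenRecord
from .pssm import PSSMatrix, pssm_row_sum
from .scales import FeatureSet, PropensityScale

ALLOWED_WINDOWS = tuple(range(5, 30, 2))
ALLOWED_F = (0.00, 0.02, 0.04, 0.06, 0.08, 0.10)


class WindowConfigError(ValueError):
    """Invalid window size or weighting factor."""


class FeatureConfigError(ValueError):
    """Inconsistent feature inputs (e.g. missing PSSM or AAR scale)."""


@dataclass(frozen=True)
class WindowConfig:
    """Window size *w* (odd, 5..29) and linear weighting factor *f* (0..0.10)."""

    w: int = 19
    f: float = 0.08

    def __post_init__(self) -> None:
        if self.w not in ALLOWED_WINDOWS:
            raise WindowConfigError(
                f"window size {self.w} not in odd range 5..29"
            )
        if not (0.0 <= self.f <= 0.10):
            raise WindowConfigError(f"weighting factor {self.f} outside [0, 0.10]")

    @property
    def half(self) -> int:
        return (self.w - 1) // 2


@dataclass
class FeatureMatrix:
    """Per-residue feature rows with +/-1 labels and provenance metadata."""

    X: np.ndarray
    labels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.labels.shape != (self.X.shape[0],):
            raise ValueError("label count must equal row count")
        if not np.all(np.isin(self.labels, (-1, 1))):
            raise ValueError("labels must be +/-1")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def row_width(self) -> int:
        return self.X.shape[1]


def label_rows(record: AntigenRecord) -> np.ndarray:
    """+1 for epitope residues, -1 otherwise; one entry per residue."""
    return np.where(record.epitope_mask, 1, -1)


def scale_values(record: AntigenRecord, scale: PropensityScale) -> np.ndarray:
    """Per-residue scale values; ambiguous residues contribute 0."""
    return np.array(
        [0.0 if aa in AMBIGUOUS_AA else scale[aa] for aa in record.sequence]
    )


def _padded_windows(values: np.ndarray, w: int) -> np.ndarray:
    """All length-w windows over a 1-D series, zero-padded at both termini.

    Returns shape (len(values), w); row i is centred on position i.
    """
    half = (w - 1) // 2
    padded = np.pad(values, half, mode="constant")
    return sliding_window_view(padded, w)


def single_scale_vectors(
    record: AntigenRecord, scale: PropensityScale, config: WindowConfig
) -> FeatureMatrix:
    """Size-w window of raw scale values centred on each residue."""
    windows = _padded_windows(scale_values(record, scale), config.w)
    return FeatureMatrix(
        windows.copy(),
        label_rows(record),
        provenance={"kind": "single", "scale": scale.name, "w": config.w},
    )


def pssm_vectors(
    record: AntigenRecord, matrix: PSSMatrix, config: WindowConfig
) -> FeatureMatrix:
    """Size-20w window of concatenated PSSM rows; zero rows pad the termini."""
    if len(matrix) != len(record):
        raise FeatureConfigError(
            f"PSSM has {len(matrix)} rows but record {record.id!r} has "
            f"{len(record)} residues"
        )
    half = config.half
    padded = np.pad(matrix.rows, ((half, half), (0, 0)), mode="constant")
    # window i covers padded rows [i, i + w); flatten rows in window order
    windows = sliding_window_view(padded, (config.w, 20)).reshape(
        len(record), config.w * 20
    )
    return FeatureMatrix(
        windows.copy(),
        label_rows(record),
        provenance={"kind": "pssm", "source": matrix.source, "w": config.w},
    )


def window_weights(config: WindowConfig) -> np.ndarray:
    """The w per-position weights 1 - f*|c - i|, centre weight 1."""
    offsets = np.arange(config.w) - config.half
    return 1.0 - config.f * np.abs(offsets)


def hybrid_vectors(
    record: AntigenRecord,
    feature_set: FeatureSet,
    config: WindowConfig,
    aar_scale: PropensityScale | None = None,
    pssm_matrix: PSSMatrix | None = None,
) -> FeatureMatrix:
    """One distance-weighted window average per feature, per residue.

    Feature order follows ``feature_set.names``.  The AAR channel requires a
    (fold-specific) ``aar_scale``; the PSSM channel requires ``pssm_matrix``.
    """
    if feature_set.include_aar and aar_scale is None:
        raise FeatureConfigError("feature set includes AAR but no AAR scale given")
    if feature_set.include_pssm and pssm_matrix is None:
        raise FeatureConfigError("feature set includes PSSM but no PSSM given")

    channels: list[np.ndarray] = []
    if feature_set.include_aar:
        channels.append(scale_values(record, aar_scale))
    if feature_set.include_pssm:
        if len(pssm_matrix) != len(record):
            raise FeatureConfigError(
                f"PSSM has {len(pssm_matrix)} rows but record {record.id!r} "
                f"has {len(record)} residues"
            )
        channels.append(pssm_row_sum(pssm_matrix))
    for scale in feature_set.scales:
        channels.append(scale_values(record, scale))

    weights = window_weights(config)
    cols = [
        _padded_windows(s, config.w) @ weights / config.w for s in channels
    ]
    X = np.column_stack(cols) if cols else np.empty((len(record), 0))
    return FeatureMatrix(
        X,
        label_rows(record),
        provenance={
            "kind": "hybrid",
            "features": list(feature_set.names),
            "w": config.w,
            "f": config.f,
        },
    )


@dataclass(frozen=True)
class FeatureScaler:
    """Column-wise [-1, 1] min-max scaler fitted on training rows only.

    Constant training columns map to 0; test values outside the training
    range are *not* clipped and may fall outside [-1, 1].
    """

    mins: np.ndarray
    maxs: np.ndarray

    def transform(self, m: FeatureMatrix) -> FeatureMatrix:
        if m.row_width != self.mins.size:
            raise ValueError(
                f"matrix width {m.row_width} != scaler width {self.mins.size}"
            )
        span = self.maxs - self.mins
        with np.errstate(divide="ignore", invalid="ignore"):
            scaled = 2.0 * (m.X - self.mins) / span - 1.0
        scaled[:, span == 0] = 0.0
        return FeatureMatrix(scaled, m.labels, {**m.provenance, "scaled": True})


def fit_scaler(train: FeatureMatrix) -> FeatureScaler:
    """Learn per-column min/max from a training matrix."""
    if train.n_rows == 0:
        raise ValueError("cannot fit a scaler on an empty matrix")
    return FeatureScaler(train.X.min(axis=0), train.X.max(axis=0))


def apply_scaler(scaler: FeatureScaler, m: FeatureMatrix) -> FeatureMatrix:
    return scaler.transform(m)


def stack(matrices: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Concatenate per-record feature matrices into one (row order preserved)."""
    if not matrices:
        raise ValueError("nothing to stack")
    widths = {m.row_width for m in matrices}
    if len(widths) != 1:
        raise ValueError(f"inconsistent row widths: {sorted(widths)}")
    return FeatureMatrix(
        np.vstack([m.X for m in matrices]),
        np.concatenate([m.labels for m in matrices]),
        provenance=dict(matrices[0].provenance),
    )


def export_svmlight(m: FeatureMatrix, path) -> None:
    """Dump rows in the sparse ``label index:value`` text format of SVM tools."""
    with open(path, "w") as fh:
        for label, row in zip(m.labels, m.X):
            feats = " ".join(f"{j + 1}:{v:.10g}" for j, v in enumerate(row) if v != 0)
            fh.write(f"{label:+d} {feats}\n")
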