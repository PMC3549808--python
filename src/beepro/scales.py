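"""Propensity scales: the amino-acid-ratio (AAR) scale and physicochemical scales.

The AAR scale is computed from labelled training data: for each standard amino
acid it is the ratio of its normalized occurrence frequency among epitope
residues to that among non-epitope residues,

    p(a) = [ f(a+) / sum_j f(j+) ] / [ f(a-) / sum_j f(j-) ]

with an additive pseudocount applied to every count so the ratio stays finite
when a residue type is absent from one class (which happens after data splits;
no logarithm is taken).  Scales are min-max normalized to [-1, 1] before use:

    rho(a) = 2 (p(a) - min) / (max - min) - 1.

The 18 candidate physicochemical scales are bundled in AAIndex1 flat-file
format and parsed by :func:`parse_aaindex`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_datasets import AMBIGUOUS_AA, STANDARD_AA, EpitopeDataset

logger = logging.getLogger(__name__)

#: Residue order of the two value rows in an AAIndex1 entry.
AAINDEX_ROW_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Bundled physicochemical scale accessions, in the fixed feature order.
BUNDLED_SCALE_ORDER = (
    "WELJ810101",  # antigenicity
    "PARJ860101",  # hydrophilicity (HPLC)
    "HOPT810101",  # hydrophilicity
    "KYTJ820101",  # hydrophobicity
    "JANJ780101",  # accessible surface area
    "KARP850101",  # flexibility
    "VINM940101",  # flexibility (B-values)
    "BASU050101",  # interactivity
    "ZHOH040101",  # buriability
    "GRAR740101",  # composition
    "GRAR740102",  # polarity
    "GRAR740103",  # volume
    "CHAM830107",  # charge transfer capability
    "CHAM830108",  # charge transfer donor capability
    "FAUJ880109",  # hydrogen-bond donor capability
    "LEVM780101",  # alpha helix
    "LEVM780102",  # beta structure
    "LEVM780103",  # coil
)

#: Scales dropped from the candidate set by feature selection: accessible
#: surface area, polarity, interactivity and buriability.
REMOVED_IN_FINAL = ("JANJ780101", "GRAR740102", "BASU050101", "ZHOH040101")


class DegenerateClassError(ValueError):
    """A dataset with no epitope (or no non-epitope) residues."""


class DegenerateScaleError(ValueError):
    """A frequency ratio with a zero denominator after pseudocounting."""


class AAIndexFormatError(ValueError):
    """Malformed AAIndex1 input."""


class UnknownScaleError(KeyError):
    """A scale accession or preset name that is not available."""


@dataclass(frozen=True)
class PropensityScale:
    """A named mapping from the 20 standard amino acids to real values."""

    name: str
    values: Mapping[str, float]
    normalized: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        vals = dict(self.values)
        missing = set(STANDARD_AA) - set(vals)
        extra = set(vals) - set(STANDARD_AA)
        if missing or extra:
            raise ValueError(
                f"scale {self.name!r}: must map exactly the 20 standard amino "
                f"acids (missing={sorted(missing)}, extra={sorted(extra)})"
            )
        arr = np.array([vals[a] for a in STANDARD_AA], dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"scale {self.name!r}: non-finite values")
        if self.normalized and (arr.min() < -1 - 1e-12 or arr.max() > 1 + 1e-12):
            raise ValueError(f"scale {self.name!r}: normalized values outside [-1, 1]")
        object.__setattr__(self, "values", vals)

    def __getitem__(self, aa: str) -> float:
        return self.values[aa]

    def as_array(self) -> np.ndarray:
        """Values in the alphabetical residue order of ``STANDARD_AA``."""
        return np.array([self.values[a] for a in STANDARD_AA], dtype=float)

    def to_tsv(self, path: str | Path) -> Path:
        with open(path, "w") as fh:
            fh.write("residue\tvalue\n")
            for a in STANDARD_AA:
                fh.write(f"{a}\t{self.values[a]:.10g}\n")
        return Path(path)


@dataclass(frozen=True)
class CompositionCounts:
    """Per-amino-acid occurrence counts in epitope and non-epitope residues."""

    epitope_counts: Mapping[str, int]
    nonepitope_counts: Mapping[str, int]
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        for attr in ("epitope_counts", "nonepitope_counts"):
            counts = {a: int(dict(getattr(self, attr)).get(a, 0)) for a in STANDARD_AA}
            if any(v < 0 for v in counts.values()):
                raise ValueError(f"{attr}: negative count")
            object.__setattr__(self, attr, counts)
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")


def count_composition(dataset: EpitopeDataset, pseudocount: float = 1.0) -> CompositionCounts:
    """Tally epitope / non-epitope residue composition over the 20 standard letters.

    Ambiguous residues (X/B/Z/U) are excluded from both classes; their
    exclusion is logged.
    """
    epi = dict.fromkeys(STANDARD_AA, 0)
    non = dict.fromkeys(STANDARD_AA, 0)
    skipped = 0
    for rec in dataset:
        for aa, is_epi in zip(rec.sequence, rec.epitope_mask):
            if aa in AMBIGUOUS_AA:
                skipped += 1
                continue
            (epi if is_epi else non)[aa] += 1
    if skipped:
        logger.info(
            "count_composition(%s): excluded %d ambiguous residue(s) (X/B/Z/U)",
            dataset.name, skipped,
        )
    if sum(epi.values()) == 0 or sum(non.values()) == 0:
        raise DegenerateClassError(
            f"dataset {dataset.name!r}: needs at least one epitope and one "
            f"non-epitope residue among the standard amino acids"
        )
    return CompositionCounts(epi, non, pseudocount=pseudocount)


def compute_aar_scale(counts: CompositionCounts, name: str = "AAR") -> PropensityScale:
    """Raw amino-acid-ratio scale from composition counts (no logarithm)."""
    pc = counts.pseudocount
    epi = np.array([counts.epitope_counts[a] + pc for a in STANDARD_AA])
    non = np.array([counts.nonepitope_counts[a] + pc for a in STANDARD_AA])
    if epi.sum() <= 0 or non.sum() <= 0 or np.any(non == 0):
        raise DegenerateScaleError(
            "zero class total or zero non-epitope frequency after pseudocounting"
        )
    p = (epi / epi.sum()) / (non / non.sum())
    return PropensityScale(name, dict(zip(STANDARD_AA, p)), normalized=False,
                           description="amino-acid ratio propensity (raw)")


def normalize_scale(scale: PropensityScale) -> PropensityScale:
    """Min-max normalize a scale to [-1, 1].

    A degenerate scale (all values equal) maps to all zeros, the midpoint of
    the target range.
    """
    arr = scale.as_array()
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"scale {scale.name!r}: non-finite values")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        rho = np.zeros_like(arr)
    else:
        rho = 2.0 * (arr - lo) / (hi - lo) - 1.0
    return PropensityScale(scale.name, dict(zip(STANDARD_AA, rho)), normalized=True,
                           description=scale.description)


def compute_normalized_aar(dataset: EpitopeDataset, pseudocount: float = 1.0) -> PropensityScale:
    """Convenience: composition counts -> raw AAR -> [-1, 1] normalization."""
    return normalize_scale(compute_aar_scale(count_composition(dataset, pseudocount)))


def parse_aaindex(source: str | Path) -> dict[str, PropensityScale]:
    """Parse an AAIndex1 flat file into scales keyed by accession.

    Each entry contributes its ``H`` accession, ``D`` description and the two
    ten-value rows following the ``I`` line (residue order ARNDCQEGHI /
    LKMFPSTWYV).  ``NA`` values are rejected.
    """
    path = Path(source)
    text = path.read_text()
    scales: dict[str, PropensityScale] = {}
    accession: str | None = None
    description: list[str] = []
    values: list[float] = []
    in_values = False

    def finish() -> None:
        nonlocal accession, description, values, in_values
        if accession is None:
            return
        if len(values) != 20:
            raise AAIndexFormatError(
                f"entry {accession}: expected 20 values, got {len(values)}"
            )
        scales[accession] = PropensityScale(
            accession,
            dict(zip(AAINDEX_ROW_ORDER, values)),
            normalized=False,
            description=" ".join(description),
        )
        accession, description, values, in_values = None, [], [], False

    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("*") or not line.strip():
            continue
        if line.startswith("//"):
            finish()
        elif line.startswith("H "):
            finish()
            accession = line[2:].strip()
            in_values = False
        elif line.startswith("D "):
            description.append(line[2:].strip())
        elif line.startswith("I "):
            in_values = True
        elif in_values and line.startswith(" "):
            for tok in line.split():
                if tok.upper() == "NA":
                    raise AAIndexFormatError(
                        f"{path}:{lineno}: entry {accession}: 'NA' value not allowed"
                    )
                try:
                    values.append(float(tok))
                except ValueError as exc:
                    raise AAIndexFormatError(
                        f"{path}:{lineno}: bad value {tok!r}"
                    ) from exc
    finish()
    if not scales:
        raise AAIndexFormatError(f"{path}: no AAIndex entries found")
    return scales


def load_bundled_scales() -> dict[str, PropensityScale]:
    """The 18 bundled candidate physicochemical scales, keyed by accession."""
    ref = resources.files("beepro.data").joinpath("aaindex18_curated.txt")
    with resources.as_file(ref) as path:
        return parse_aaindex(path)


# ---------------------------------------------------------------------------
# Feature sets


@dataclass(frozen=True)
class FeatureSet:
    """An ordered hybrid feature list: AAR, PSSM, and physicochemical scales.

    The order of ``names`` is the feature/column order everywhere downstream
    and the candidate order of backward feature elimination.
    """

    name: str
    include_aar: bool
    include_pssm: bool
    scales: tuple[PropensityScale, ...] = field(default_factory=tuple)

    @property
    def names(self) -> tuple[str, ...]:
        out: list[str] = []
        if self.include_aar:
            out.append("AAR")
        if self.include_pssm:
            out.append("PSSM")
        out.extend(s.name for s in self.scales)
        return tuple(out)

    @property
    def n_features(self) -> int:
        return len(self.names)

    def drop(self, feature_name: str) -> "FeatureSet":
        """A new set with one feature removed (for backward elimination)."""
        if feature_name == "AAR" and self.include_aar:
            return replace(self, name=f"{self.name}-AAR", include_aar=False)
        if feature_name == "PSSM" and self.include_pssm:
            return replace(self, name=f"{self.name}-PSSM", include_pssm=False)
        kept = tuple(s for s in self.scales if s.name != feature_name)
        if len(kept) == len(self.scales):
            raise UnknownScaleError(feature_name)
        return replace(self, name=f"{self.name}-{feature_name}", scales=kept)


def get_feature_set(selection: str | Sequence[str] = "final16") -> FeatureSet:
    """Build a feature set from a preset name or a custom list of names.

    Presets: ``candidate20`` (AAR + PSSM + all 18 bundled scales) and
    ``final16`` (candidate20 minus accessible surface area, polarity,
    interactivity and buriability).  A custom list may mix ``"AAR"``,
    ``"PSSM"`` and bundled accessions, in the desired order.
    """
    bundled = load_bundled_scales()
    if isinstance(selection, str):
        if selection == "candidate20":
            names: Sequence[str] = ("AAR", "PSSM", *BUNDLED_SCALE_ORDER)
        elif selection == "final16":
            names = ("AAR", "PSSM",
                     *(a for a in BUNDLED_SCALE_ORDER if a not in REMOVED_IN_FINAL))
        else:
            raise UnknownScaleError(f"unknown preset {selection!r}")
        preset_name = selection
    else:
        names = tuple(selection)
        preset_name = "custom"

    include_aar = "AAR" in names
    include_pssm = "PSSM" in names
    scales = []
    for n in names:
        if n in ("AAR", "PSSM"):
            continue
        if n not in bundled:
            raise UnknownScaleError(f"unknown scale {n!r}")
        scales.append(bundled[n])
    return FeatureSet(preset_name, include_aar, include_pssm, tuple(scales))


def custom_feature_set(
    name: str,
    scales: Iterable[PropensityScale],
    include_aar: bool = False,
    include_pssm: bool = False,
) -> FeatureSet:
    """A feature set over caller-supplied scales (e.g. planted synthetic ones)."""
    return FeatureSet(name, include_aar, include_pssm, tuple(scales))
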