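"""Synthetic labelled antigen datasets with controllable epitope signal.

The generator emulates the structure of curated linear-epitope datasets: a
set of protein sequences in which contiguous epitope segments (default 8-20
residues, typical linear epitope lengths) cover a target fraction of
residues.  Epitope-segment residues are drawn from a composition enriched
for a chosen residue set; background residues from a uniform (or natural
frequency) composition.  Everything is reproducible from one seed.

The defaults mirror the composition of a protective linear-epitope
collection: 57 proteins of 300-900 residues at ~5% epitope density with a
mild (2x) enrichment of hydrophilic residues inside epitopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_datasets import STANDARD_AA, AntigenRecord, EpitopeDataset
from .scales import PropensityScale

#: Approximate natural amino-acid frequencies (vertebrate proteomes).
NATURAL_FREQUENCIES = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.053, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}


class SyntheticSpecError(ValueError):
    """Unsatisfiable or invalid generator specification."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_proteins: int = 57
    length_range: tuple[int, int] = (300, 900)
    epitope_density: float = 0.05
    enriched_residues: tuple[str, ...] = ("D", "E", "K", "N", "S", "G")
    enrichment_strength: float = 2.0
    segment_length_range: tuple[int, int] = (8, 20)
    seed: int = 0
    background: str = "uniform"
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise SyntheticSpecError("need at least one protein")
        lo, hi = self.length_range
        if not (29 <= lo <= hi):
            raise SyntheticSpecError(
                "protein lengths must be >= 29 (window capability) and ordered"
            )
        if not (0.0 < self.epitope_density < 1.0):
            raise SyntheticSpecError("epitope density must be in (0, 1)")
        slo, shi = self.segment_length_range
        if not (1 <= slo <= shi):
            raise SyntheticSpecError("segment length range must be ordered and >= 1")
        if shi > hi:
            raise SyntheticSpecError("epitope segments longer than proteins")
        if self.enrichment_strength < 1.0:
            raise SyntheticSpecError("enrichment strength must be >= 1")
        bad = set(self.enriched_residues) - set(STANDARD_AA)
        if bad:
            raise SyntheticSpecError(f"unknown enriched residues {sorted(bad)}")
        if self.background not in ("uniform", "natural"):
            raise SyntheticSpecError(f"unknown background {self.background!r}")
        if self.epitope_density * hi < slo:
            raise SyntheticSpecError(
                "density too low to place even one minimal segment"
            )


def _compositions(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """(background, epitope) sampling probabilities over STANDARD_AA."""
    if spec.background == "uniform":
        base = np.full(20, 1.0 / 20)
    else:
        base = np.array([NATURAL_FREQUENCIES[a] for a in STANDARD_AA])
        base = base / base.sum()
    boost = np.array(
        [spec.enrichment_strength if a in spec.enriched_residues else 1.0
         for a in STANDARD_AA]
    )
    epi = base * boost
    return base, epi / epi.sum()


def generate(spec: SyntheticSpec) -> EpitopeDataset:
    """Draw a labelled dataset from the spec, reproducibly from its seed.

    Per protein, non-overlapping epitope segments are placed by rejection
    sampling until the protein's residue budget (density x length) is
    exhausted; the realized global density therefore approximates the target
    up to segment granularity.
    """
    rng = np.random.default_rng(spec.seed)
    background, epitope_comp = _compositions(spec)
    aa = np.array(list(STANDARD_AA))
    slo, shi = spec.segment_length_range

    records = []
    for p in range(spec.n_proteins):
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        mask = np.zeros(length, dtype=bool)
        budget = int(round(spec.epitope_density * length))
        placed = 0
        attempts = 0
        while budget - placed >= slo and attempts < 200:
            seg = int(rng.integers(slo, min(shi, budget - placed) + 1))
            start = int(rng.integers(0, length - seg + 1))
            if mask[max(0, start - 1): start + seg + 1].any():
                attempts += 1
                continue
            mask[start: start + seg] = True
            placed += seg
        seq = np.where(
            mask,
            rng.choice(aa, size=length, p=epitope_comp),
            rng.choice(aa, size=length, p=background),
        )
        records.append(AntigenRecord(f"syn{p:04d}", "".join(seq), mask))

    ds = EpitopeDataset(records, name=spec.name)
    realized = ds.epitope_residues / ds.total_residues
    ds.name = f"{spec.name}(density={realized:.3f})"
    return ds


def strongly_enriched_spec(seed: int = 11, n_proteins: int = 60) -> SyntheticSpec:
    """The canonical strongly-enriched (near-separable) recovery condition.

    Epitope segments are at least as long as the widest default window
    (24-40 vs w=19), so every epitope-centred window is majority-epitope and
    every background window minority-epitope: window composition separates
    the classes by construction.  A 25x enrichment makes epitope segments
    ~91% enriched-residue content against a 30% background rate, and
    60 proteins of 150-300 residues give >10,000 residues.
    """
    return SyntheticSpec(
        n_proteins=n_proteins,
        length_range=(150, 300),
        epitope_density=0.15,
        enrichment_strength=25.0,
        segment_length_range=(24, 40),
        seed=seed,
        name="strongly-enriched",
    )


def planted_recovery_spec(seed: int = 23) -> SyntheticSpec:
    """A smaller near-separable condition for feature-selection recovery runs.

    The enrichment set is deliberately compact (3 of 20 residues) so that a
    random permutation of the informative scale's values lands its high
    values on residues disjoint from the signal set in most draws — decoys
    built from such permutations are then genuinely uninformative, which is
    the premise of the feature-selection recovery check.
    """
    return SyntheticSpec(
        n_proteins=30,
        length_range=(160, 320),  # every protein's budget fits >= 1 segment
        epitope_density=0.15,
        enriched_residues=("D", "E", "K"),
        enrichment_strength=25.0,
        segment_length_range=(24, 40),
        seed=seed,
        name="planted",
    )


@dataclass
class PlantedFeatures:
    """A dataset plus one informative scale and permuted decoy scales."""

    dataset: EpitopeDataset
    informative: PropensityScale
    decoys: list[PropensityScale] = field(default_factory=list)

    @property
    def all_scales(self) -> list[PropensityScale]:
        """Decoys first, informative last.

        Backward feature elimination considers candidates in feature order;
        listing the decoys first lets redundant noise be stripped before the
        informative scale is ever tested for removal, avoiding the classic
        redundancy-masking artifact where partially-overlapping decoys stand
        in for the signal feature.
        """
        return [*self.decoys, self.informative]


def planted_feature_dataset(
    spec: SyntheticSpec, n_decoy_scales: int = 5
) -> PlantedFeatures:
    """Generate a dataset with one planted informative scale among decoys.

    The informative scale takes +1 exactly on the enriched residues and -1
    elsewhere, so it tracks the composition signal the generator plants.
    Each decoy is a seeded random permutation of the informative values
    across residues (same value multiset, scrambled assignment).
    """
    dataset = generate(spec)
    values = {
        a: (1.0 if a in spec.enriched_residues else -1.0) for a in STANDARD_AA
    }
    informative = PropensityScale(
        "PLANTED_INFORMATIVE", values, normalized=True,
        description="high exactly on the enrichment residue set",
    )
    rng = np.random.default_rng(spec.seed + 1_000_003)
    base = informative.as_array()
    decoys = []
    for d in range(n_decoy_scales):
        perm = rng.permutation(20)
        decoys.append(PropensityScale(
            f"DECOY_{d:02d}",
            dict(zip(STANDARD_AA, base[perm])),
            normalized=True,
            description="seeded permutation of the informative scale",
        ))
    return PlantedFeatures(dataset, informative, decoys)
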