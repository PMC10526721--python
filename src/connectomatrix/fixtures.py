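"""Packaged curation fixtures and a typology-respecting random-matrix generator.

Two curated matrices ship with the package:

* the **pre-tractography fixture** — every printed connectional fact about
  the two exemplar regions (middle frontal gyrus F2, angular gyrus AG) plus
  figure-level rows that flesh out their maps and populate the ten named
  pathway systems, with the homotopic callosal rule applied;
* the **tractography-era fixture** — the conservative matrix whose AG and F2
  long-range rows are proper subsets of the classical rows, lacking exactly
  the era-difference exemplar units; it contains only type-3 association
  entries (plus rule-generated commissural links), since short/medium-range
  and projection connections are not validated in that era's sources.

Every fixture row carries a provenance note; rows not printed in the source
body are tagged ``"figure-level, unverified"``.  The random generator fills
each pair's single allowed slot with a configurable per-type density, so its
output passes the full validator for any seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib.resources import as_file, files
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .evidence import EvidenceDB, IngestReport, ingest_curation_file
from .matrix import ConnectionMatrix, Era
from .registry import Registry, default_registry
from .typology import DistanceType, classify_pair

__all__ = [
    "packaged_curation_path",
    "packaged_sidecar_path",
    "build_pre_dti_fixture",
    "build_dti_fixture",
    "build_fixture_db",
    "in_paper_facts",
    "GeneratorConfig",
    "random_matrix",
]

_ERA_FILES = {Era.PRE_DTI: "curation_pre_dti.csv", Era.DTI: "curation_dti.csv"}

#: Provenance tag on fixture rows that restate facts printed in the source
#: body (worked example, era-difference exemplars); all other rows are
#: tagged "figure-level, unverified".
IN_PAPER_TAG = "in-paper"


def packaged_curation_path(era: Era | str) -> Path:
    """Filesystem path of the packaged curation CSV for *era*."""
    resource = files("connectomatrix.data").joinpath(_ERA_FILES[Era(era)])
    with as_file(resource) as p:
        return Path(p)


def packaged_sidecar_path() -> Path:
    with as_file(files("connectomatrix.data").joinpath("sidecar.json")) as p:
        return Path(p)


def build_fixture_db(
    era: Era | str,
    registry: Registry | None = None,
    supplementary: Iterable[str | Path] = (),
) -> tuple[EvidenceDB, IngestReport]:
    """Ingest the packaged curation fixture for *era* into an evidence DB."""
    registry = registry or default_registry()
    return ingest_curation_file(
        packaged_curation_path(era),
        registry,
        sidecar_path=packaged_sidecar_path(),
        supplementary_paths=supplementary,
    )


def build_pre_dti_fixture(
    registry: Registry | None = None,
    supplementary: Iterable[str | Path] = (),
) -> ConnectionMatrix:
    """The packaged classical (pre-tractography) matrix.

    Optional *supplementary* curation CSVs (e.g. the full published matrix
    tables) are merged row-wise; their rows pass through the same validator
    and quarantine path as the packaged ones.
    """
    db, _ = build_fixture_db(Era.PRE_DTI, registry, supplementary)
    return db.to_matrix(Era.PRE_DTI, apply_commissural_rule=True)


def build_dti_fixture(registry: Registry | None = None) -> ConnectionMatrix:
    """The packaged tractography-era matrix (type-3 association entries
    plus rule-generated homotopic commissural links only)."""
    db, _ = build_fixture_db(Era.DTI, registry)
    return db.to_matrix(Era.DTI, apply_commissural_rule=True)


def in_paper_facts(era: Era | str) -> tuple[tuple[str, str, int, str, str], ...]:
    """The fixture rows whose provenance tag marks them as printed facts:
    ``(region_a, region_b, type, pathway, provenance_note)`` tuples."""
    frame = pd.read_csv(packaged_curation_path(era), dtype=str, keep_default_na=False)
    facts = []
    for row in frame.itertuples(index=False):
        if row.notes.startswith(IN_PAPER_TAG):
            facts.append(
                (row.region_a, row.region_b, int(row.type), row.pathway, row.notes)
            )
    return tuple(facts)


_DEFAULT_DENSITY = {
    # Adjacent gyri are almost always interconnected by U-fibers; long-range
    # fascicles touch a minority of cross-lobe pairs; projection systems
    # reach a moderate share of cortico-subcortical pairs.
    DistanceType.SHORT_RANGE: 0.9,
    DistanceType.MEDIUM_RANGE: 0.5,
    DistanceType.LONG_RANGE: 0.15,
    DistanceType.PROJECTION: 0.3,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the random-matrix generator.

    ``per_type_density[t]`` is the probability that a pair whose single
    allowed slot is type *t* gets that slot occupied.  Same seed and config
    always yield an identical matrix.
    """

    seed: int
    per_type_density: Mapping[DistanceType, float] = field(
        default_factory=lambda: dict(_DEFAULT_DENSITY)
    )
    era: Era = Era.PRE_DTI

    def __post_init__(self) -> None:
        for t, p in self.per_type_density.items():
            DistanceType(t)
            if not 0.0 <= float(p) <= 1.0:
                raise ValueError(
                    f"density for type {int(t)} must be in [0, 1], got {p!r}"
                )

    def density(self, dtype: DistanceType) -> float:
        return float(self.per_type_density.get(dtype, 0.0))


def random_matrix(
    config: GeneratorConfig, registry: Registry | None = None
) -> ConnectionMatrix:
    """Generate a random matrix that respects the typology by construction.

    For every cortical pair the pair's single allowed distance type is
    occupied with the configured density; cortical-subcortical pairs are
    occupied (type 4) with the projection density.  The output passes the
    full validator for any seed.
    """
    registry = registry or default_registry()
    rng = np.random.default_rng(config.seed)
    m = ConnectionMatrix(registry, config.era)
    cortical = registry.cortical_codes
    for i, a in enumerate(cortical):
        for b in cortical[i + 1:]:
            t = classify_pair(registry, a, b)
            if rng.random() < config.density(t):
                m.set_connection(a, b, t)
    for a in cortical:
        for b in registry.subcortical_codes:
            if rng.random() < config.density(DistanceType.PROJECTION):
                m.set_connection(a, b, DistanceType.PROJECTION)
    return m
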