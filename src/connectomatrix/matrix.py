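"""The connection matrix C: era-tagged, evidence-annotated presence vectors.

Each element C(i, j) of the matrix is a 1x4 logical vector over the distance
types — slot *k* records the presence (True) or absence (False) of a type-k
connection between parcellation units *i* and *j*, ordered types 1 through 4
top to bottom.  Occupied slots may carry a pathway name (the association
fascicle or projection system mediating the connection) and evidence
identifiers pointing into the curation layer.

The matrix is undirected (classical sources establish pathway stems, not
directionality) and era-tagged: a matrix holds either pre-tractography
("pre_dti") or tractography-era ("dti") knowledge, never a mixture.
Homotopic callosal connections are generated by rule — one commissural entry
per cortical unit, linking it to its contralateral mirror region — and live
beside, not inside, the four association/projection slots.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import pandas as pd

from .errors import CompatibilityError, TypologyError, UnknownPathwayError
from .registry import Registry
from .typology import (
    ConnectionClass,
    DistanceType,
    classify_pair_scope,
    validate_assertion,
)

__all__ = [
    "Era",
    "ConnectionVector",
    "ConnectionMatrix",
    "empty_matrix",
    "serialize",
    "deserialize",
]

SCHEMA_VERSION = 1


class Era(str, enum.Enum):
    """Provenance era of the connectional knowledge in a matrix."""

    PRE_DTI = "pre_dti"
    DTI = "dti"


@dataclass(frozen=True)
class ConnectionVector:
    """The per-pair 1x4 presence vector with per-slot annotations.

    ``slots[k]`` is the presence flag for distance type ``k+1``.  ``pathways``
    and ``evidence`` map an occupied :class:`DistanceType` to the mediating
    pathway name and the supporting evidence identifiers.
    """

    slots: tuple[bool, bool, bool, bool] = (False, False, False, False)
    pathways: Mapping[DistanceType, str] = field(default_factory=dict)
    evidence: Mapping[DistanceType, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.slots) != 4:
            raise ValueError("a connection vector has exactly 4 slots")

    def present(self, dtype: DistanceType | int) -> bool:
        return self.slots[DistanceType(dtype) - 1]

    @property
    def occupied_types(self) -> tuple[DistanceType, ...]:
        return tuple(t for t in DistanceType if self.slots[t - 1])

    @property
    def is_empty(self) -> bool:
        return not any(self.slots)

    def with_slot(
        self,
        dtype: DistanceType,
        pathway: str | None = None,
        evidence: Iterable[str] = (),
    ) -> "ConnectionVector":
        slots = list(self.slots)
        slots[dtype - 1] = True
        pathways = dict(self.pathways)
        if pathway is not None:
            pathways[dtype] = pathway
        ev = dict(self.evidence)
        merged = tuple(dict.fromkeys((*ev.get(dtype, ()), *evidence)))
        if merged:
            ev[dtype] = merged
        return ConnectionVector(tuple(slots), pathways, ev)

    def render(self, style: str = "binary") -> str:
        """Column-vector rendering: ``"0010"`` (binary style) or ``"0030"``
        (typed style, printing the type number in the occupied slot)."""
        if style == "binary":
            return "".join("1" if s else "0" for s in self.slots)
        if style == "typed":
            return "".join(str(i + 1) if s else "0" for i, s in enumerate(self.slots))
        raise ValueError(f"unknown slot style {style!r} (use 'binary' or 'typed')")

    def __eq__(self, other) -> bool:
        if not isinstance(other, ConnectionVector):
            return NotImplemented
        return (
            self.slots == other.slots
            and dict(self.pathways) == dict(other.pathways)
            and dict(self.evidence) == dict(other.evidence)
        )


_EMPTY_VECTOR = ConnectionVector()


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


class ConnectionMatrix:
    """Era-tagged collection of connection vectors over a registry.

    Symmetric by construction (``C(a, b) is C(b, a)``), with no diagonal:
    querying a unit against itself is an error.  Every stored element passes
    the typology validator; rejected assertions never enter the matrix.
    """

    def __init__(
        self,
        registry: Registry,
        era: Era,
        pathway_catalog: frozenset[str] | None = None,
    ):
        self.registry = registry
        self.era = Era(era)
        self.registry_checksum = registry.checksum()
        #: Known pathway names; when set, unknown pathway labels are rejected.
        self.pathway_catalog = pathway_catalog
        self._elements: dict[tuple[str, str], ConnectionVector] = {}
        self.commissural_rule_applied = False

    # -- element access ---------------------------------------------------
    def get(self, a: str, b: str) -> ConnectionVector:
        """The connection vector for the unordered pair ``{a, b}`` (an
        all-absent vector if nothing has been curated)."""
        self.registry.unit(a), self.registry.unit(b)
        if a == b:
            raise ValueError(f"the matrix diagonal is undefined (pair {a!r}, {a!r})")
        return self._elements.get(_pair_key(a, b), _EMPTY_VECTOR)

    def set_connection(
        self,
        a: str,
        b: str,
        dtype: DistanceType | int,
        pathway: str | None = None,
        evidence: Iterable[str] = (),
    ) -> None:
        """Record a connection of the given distance type between *a* and *b*.

        The assertion is validated against the typology first and rejected
        (``TypologyError`` carrying the validator's report) on any violation;
        symmetry is automatic because storage is keyed on the unordered pair.
        """
        report = validate_assertion(self.registry, a, b, dtype)
        if not report.ok:
            raise TypologyError("; ".join(report.violations))
        if (
            pathway is not None
            and self.pathway_catalog is not None
            and pathway not in self.pathway_catalog
        ):
            raise UnknownPathwayError(pathway)
        key = _pair_key(a, b)
        vec = self._elements.get(key, _EMPTY_VECTOR)
        self._elements[key] = vec.with_slot(DistanceType(dtype), pathway, evidence)

    def apply_homotopic_callosal_rule(self) -> None:
        """Mark every cortical unit as commissurally connected to its
        contralateral homolog.  Heterotopic callosal entries are never
        created; applying the rule twice is a no-op."""
        self.commissural_rule_applied = True

    @property
    def commissural_units(self) -> frozenset[str]:
        """Cortical units with a (rule-generated) homotopic commissural
        connection — all of them once the rule has been applied."""
        if not self.commissural_rule_applied:
            return frozenset()
        return frozenset(self.registry.cortical_codes)

    # -- iteration / queries ----------------------------------------------
    def pairs(self) -> Iterator[tuple[str, str]]:
        yield from sorted(self._elements)

    def entries(self) -> Iterator[tuple[str, str, DistanceType, ConnectionVector]]:
        """Yield ``(a, b, dtype, vector)`` for every occupied slot, in stable
        sorted order."""
        for key in sorted(self._elements):
            vec = self._elements[key]
            for t in vec.occupied_types:
                yield (*key, t, vec)

    def partners(self, region: str, dtype: DistanceType | int) -> frozenset[str]:
        """Units connected to *region* through a type-*dtype* slot."""
        self.registry.unit(region)
        t = DistanceType(dtype)
        out = set()
        for (a, b), vec in self._elements.items():
            if region in (a, b) and vec.present(t):
                out.add(b if a == region else a)
        return frozenset(out)

    def n_entries(self, dtype: DistanceType | int | None = None) -> int:
        if dtype is None:
            return sum(len(v.occupied_types) for v in self._elements.values())
        t = DistanceType(dtype)
        return sum(1 for v in self._elements.values() if v.present(t))

    def validate(self) -> list[str]:
        """Re-run the typology validator over every stored element; a valid
        matrix returns an empty list."""
        problems = []
        for (a, b), vec in self._elements.items():
            for t in vec.occupied_types:
                report = validate_assertion(self.registry, a, b, t)
                problems.extend(report.violations)
        return problems

    def __eq__(self, other) -> bool:
        if not isinstance(other, ConnectionMatrix):
            return NotImplemented
        return (
            self.era is other.era
            and self.registry_checksum == other.registry_checksum
            and self._elements == other._elements
            and self.commissural_rule_applied == other.commissural_rule_applied
        )

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        elements = []
        for (a, b) in sorted(self._elements):
            vec = self._elements[(a, b)]
            elements.append(
                {
                    "a": a,
                    "b": b,
                    "slots": [bool(s) for s in vec.slots],
                    "pathways": {str(int(t)): p for t, p in sorted(vec.pathways.items())},
                    "evidence": {
                        str(int(t)): list(e) for t, e in sorted(vec.evidence.items())
                    },
                }
            )
        return {
            "schema_version": SCHEMA_VERSION,
            "era": self.era.value,
            "registry_checksum": self.registry_checksum,
            "commissural_rule_applied": self.commissural_rule_applied,
            "elements": elements,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n"

    @classmethod
    def from_dict(cls, data: Mapping, registry: Registry) -> "ConnectionMatrix":
        checksum = data.get("registry_checksum")
        if checksum != registry.checksum():
            raise CompatibilityError(
                "matrix was serialized against a different registry "
                f"(checksum {checksum!r} != {registry.checksum()!r})"
            )
        m = cls(registry, Era(data["era"]))
        for el in data.get("elements", []):
            vec = ConnectionVector(
                tuple(bool(s) for s in el["slots"]),
                {DistanceType(int(k)): v for k, v in el.get("pathways", {}).items()},
                {
                    DistanceType(int(k)): tuple(v)
                    for k, v in el.get("evidence", {}).items()
                },
            )
            m._elements[_pair_key(el["a"], el["b"])] = vec
        if data.get("commissural_rule_applied"):
            m.apply_homotopic_callosal_rule()
        problems = m.validate()
        if problems:
            raise TypologyError(
                "deserialized matrix fails validation: " + "; ".join(problems[:5])
            )
        return m

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per occupied pair-slot with columns
        era, unit_a, unit_b, type, scope, pathway, evidence_ids."""
        rows = []
        for a, b, t, vec in self.entries():
            _, scope = classify_pair_scope(self.registry, a, b)
            rows.append(
                {
                    "era": self.era.value,
                    "unit_a": a,
                    "unit_b": b,
                    "type": int(t),
                    "scope": scope.value,
                    "pathway": vec.pathways.get(t, ""),
                    "evidence_ids": ";".join(vec.evidence.get(t, ())),
                }
            )
        if self.commissural_rule_applied:
            for code in self.registry.cortical_codes:
                rows.append(
                    {
                        "era": self.era.value,
                        "unit_a": f"{code}_L",
                        "unit_b": f"{code}_R",
                        "type": 0,
                        "scope": ConnectionClass.COMMISSURAL.value,
                        "pathway": "corpus callosum (homotopic)",
                        "evidence_ids": "",
                    }
                )
        columns = ["era", "unit_a", "unit_b", "type", "scope", "pathway", "evidence_ids"]
        return pd.DataFrame(rows, columns=columns)

    def to_graph(self) -> nx.MultiGraph:
        """GraphML-ready multigraph: every cortical unit is a node; edges
        carry type, scope, pathway and era attributes.  Subcortical units
        appear only when a projection edge reaches them, so a cortex-only
        matrix has exactly the registry's cortical unit count as nodes."""
        g = nx.MultiGraph(era=self.era.value, registry_checksum=self.registry_checksum)
        for code in self.registry.cortical_codes:
            unit = self.registry.unit(code)
            g.add_node(code, name=unit.full_name, tier=unit.tier.value, lobe=unit.lobe.value)
        for a, b, t, vec in self.entries():
            for code in (a, b):
                if code not in g:
                    unit = self.registry.unit(code)
                    g.add_node(
                        code, name=unit.full_name, tier=unit.tier.value, lobe=unit.lobe.value
                    )
            _, scope = classify_pair_scope(self.registry, a, b)
            g.add_edge(
                a,
                b,
                key=f"type{int(t)}",
                type=int(t),
                scope=scope.value,
                pathway=vec.pathways.get(t, ""),
                era=self.era.value,
            )
        return g


def empty_matrix(registry: Registry, era: Era | str) -> ConnectionMatrix:
    """A matrix with every vector all-absent, dimensioned by the registry."""
    return ConnectionMatrix(registry, Era(era))


def serialize(matrix: ConnectionMatrix, path: str | Path, fmt: str | None = None) -> None:
    """Write a matrix to *path* as canonical JSON, long CSV, or GraphML.

    The format is inferred from the suffix when *fmt* is not given.  Only the
    JSON form round-trips with full fidelity (evidence, era, checksum).
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "json":
        path.write_text(matrix.to_json())
    elif fmt == "csv":
        matrix.to_frame().to_csv(path, index=False)
    elif fmt == "graphml":
        nx.write_graphml(matrix.to_graph(), path)
    else:
        raise ValueError(f"unknown matrix format {fmt!r} (use json, csv or graphml)")


def deserialize(path: str | Path, registry: Registry) -> ConnectionMatrix:
    """Load a canonical-JSON matrix, verifying it against *registry*."""
    data = json.loads(Path(path).read_text())
    return ConnectionMatrix.from_dict(data, registry)
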