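"""The four-way distance typology of cerebral connections.

Association connections between cortical parcellation units are classed by a
purely structural rule over the registry's adjacency and lobe maps:

* **type 1** (short-range, intragyral/juxtagyral): the two gyri are adjacent —
  either within one lobe (*intralobar*) or across a lobe border
  (*juxtalobar*, the U-fiber case);
* **type 2** (medium-range, intralobar): non-adjacent units of the same lobe;
* **type 3** (long-range, interlobar): units of different lobes that are not
  adjacent, mediated by the named association fascicles;
* **type 4** (projection): any cortical–subcortical pair.

The rule system is exclusive: type 1/2 connections for a unit pair cannot
coexist with type 3, so every pair admits exactly one distance type.  No
metric (mm) threshold is involved — classification is relational only.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .errors import TypologyError
from .registry import Registry

__all__ = [
    "DistanceType",
    "ConnectionClass",
    "Scope",
    "classify_pair",
    "classify_pair_scope",
    "allowed_slots",
    "validate_assertion",
    "ValidationReport",
]


class DistanceType(enum.IntEnum):
    """Distance type 1–4.  The integer is an index into the connection
    vector, not a magnitude."""

    SHORT_RANGE = 1      # intragyral / juxtagyral (adjacent units)
    MEDIUM_RANGE = 2     # intralobar (non-adjacent, same lobe)
    LONG_RANGE = 3       # interlobar association
    PROJECTION = 4       # cortico-subcortical

    @property
    def label(self) -> str:
        return _LABELS[self]


_LABELS = {
    DistanceType.SHORT_RANGE: "short_range",
    DistanceType.MEDIUM_RANGE: "medium_range",
    DistanceType.LONG_RANGE: "long_range",
    DistanceType.PROJECTION: "projection",
}


class ConnectionClass(str, enum.Enum):
    """Broad fiber-class of a connection.  Commissural entries always link a
    cortical unit with its contralateral homolog (heterotopic callosal
    connections are excluded from this framework)."""

    LOCAL = "local"
    ASSOCIATIONAL = "associational"
    COMMISSURAL = "commissural"
    PROJECTION = "projection"


class Scope(str, enum.Enum):
    """Scope qualifier of a classified pair.  Distinguishes the two type-1
    rows of the typology table (intralobar vs juxtalobar short-range)."""

    INTRALOBAR = "intralobar"
    JUXTALOBAR = "juxtalobar"
    INTERLOBAR = "interlobar"
    CORTICO_SUBCORTICAL = "cortico_subcortical"


def _check_pair(registry: Registry, a: str, b: str) -> tuple[bool, bool]:
    if a == b:
        raise ValueError(f"distance type of a unit with itself is undefined ({a!r})")
    return registry.unit(a).is_cortical, registry.unit(b).is_cortical


def classify_pair(registry: Registry, a: str, b: str) -> DistanceType:
    """Distance type of the pair ``{a, b}`` under *registry*.

    Deterministic and symmetric in its arguments.  Raises
    :class:`~connectomatrix.errors.UnknownUnitError` for codes missing from
    the registry, ``ValueError`` for ``a == b``, and
    :class:`~connectomatrix.errors.TypologyError` for a pair of two
    subcortical units (the typology covers connections involving cortex).
    """
    a_cort, b_cort = _check_pair(registry, a, b)
    if a_cort and b_cort:
        if registry.are_adjacent(a, b):
            return DistanceType.SHORT_RANGE
        if registry.same_lobe(a, b):
            return DistanceType.MEDIUM_RANGE
        return DistanceType.LONG_RANGE
    if a_cort or b_cort:
        return DistanceType.PROJECTION
    raise TypologyError(
        f"({a}, {b}): the distance typology is defined for pairs involving "
        "cerebral cortex; both units are subcortical"
    )


def classify_pair_scope(registry: Registry, a: str, b: str) -> tuple[DistanceType, Scope]:
    """Distance type plus its scope qualifier (intralobar / juxtalobar /
    interlobar / cortico-subcortical)."""
    dtype = classify_pair(registry, a, b)
    if dtype is DistanceType.SHORT_RANGE:
        scope = Scope.INTRALOBAR if registry.same_lobe(a, b) else Scope.JUXTALOBAR
    elif dtype is DistanceType.MEDIUM_RANGE:
        scope = Scope.INTRALOBAR
    elif dtype is DistanceType.LONG_RANGE:
        scope = Scope.INTERLOBAR
    else:
        scope = Scope.CORTICO_SUBCORTICAL
    return dtype, scope


def allowed_slots(registry: Registry, a: str, b: str) -> frozenset[DistanceType]:
    """The set of distance-type slots a curated connection between *a* and
    *b* may legally occupy.

    Because type 1/2 cannot coexist with type 3 and the classification is a
    function of adjacency and lobe membership, the set is always a singleton:
    the pair's classified type (``{4}`` for any cortico-subcortical pair).
    """
    return frozenset({classify_pair(registry, a, b)})


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of checking an asserted connection against the rule system.
    Violations are data, not exceptions."""

    region_a: str
    region_b: str
    claimed_type: DistanceType | None
    violations: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_assertion(
    registry: Registry, a: str, b: str, claimed_type: DistanceType | int
) -> ValidationReport:
    """Check a claimed distance type for a unit pair against the typology.

    Returns a report with zero violations iff
    ``claimed_type in allowed_slots(registry, a, b)``.  Unit codes must exist
    in the registry (that is a lookup error, not a violation); everything
    else — self-pairs, subcortical pairs, a type outside 1–4, a mismatched
    type — is reported as a violation.
    """
    a_unit, b_unit = registry.unit(a), registry.unit(b)
    violations: list[str] = []
    try:
        claimed = DistanceType(claimed_type)
    except ValueError:
        return ValidationReport(a, b, None, (f"invalid distance type {claimed_type!r}",))

    if a == b:
        return ValidationReport(a, b, claimed, ("self-connection is undefined",))
    if not (a_unit.is_cortical or b_unit.is_cortical):
        return ValidationReport(
            a, b, claimed, ("typology requires at least one cortical unit",)
        )

    expected = classify_pair(registry, a, b)
    if claimed is not expected:
        if claimed is DistanceType.PROJECTION:
            violations.append(
                f"projection type requires a subcortical partner; "
                f"{a} and {b} are both cortical"
            )
        elif expected is DistanceType.PROJECTION:
            violations.append(
                f"cortico-subcortical pair ({a}, {b}) must use projection type 4, "
                f"not type {int(claimed)}"
            )
        elif claimed is DistanceType.LONG_RANGE:
            rel = "adjacent" if registry.are_adjacent(a, b) else "non-adjacent"
            violations.append(
                f"type 3 asserted for {rel} intralobar pair ({a}, {b}); "
                f"type 1/2 connections exclude type 3"
            )
        else:
            violations.append(
                f"type {int(claimed)} asserted for ({a}, {b}) but the "
                f"adjacency/lobe maps force type {int(expected)} "
                f"({expected.label})"
            )
    return ValidationReport(a, b, claimed, tuple(violations))
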