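"""Consumer-facing analyses over a connection matrix.

* **Region connectivity maps** — the per-type partner table of a focus
  region, with pathway labels on long-range entries.
* **Era comparison** — set differences between the partner tables of two
  matrices (classical vs tractography-era knowledge) for one region.
* **Lesion disconnection** — the cumulative, per-type set of remote regions
  putatively disconnected by a lesion spanning one or more parcellation
  units; first-order (direct partners) by default, with an explicit opt-in
  multi-hop depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import CompatibilityError
from .matrix import ConnectionMatrix
from .registry import Tier
from .typology import DistanceType

__all__ = [
    "ConnectivityMap",
    "EraDiff",
    "DisconnectionReport",
    "connectivity_map",
    "era_diff",
    "lesion_disconnection",
    "render_map",
    "plot_map",
]


@dataclass(frozen=True)
class ConnectivityMap:
    """Per-type partner sets of one focus region (the tabular form of a
    region's anatomic connectivity map)."""

    focus_region: str
    per_type_partners: Mapping[DistanceType, frozenset[str]]
    pathway_annotations: Mapping[str, str]  # type-3/4 partner -> pathway name
    commissural_partner: str | None = None

    def partners(self, dtype: DistanceType | int) -> frozenset[str]:
        return self.per_type_partners.get(DistanceType(dtype), frozenset())


@dataclass(frozen=True)
class EraDiff:
    """Partner-set differences for one region between two eras."""

    region: str
    only_in_a: Mapping[DistanceType, frozenset[str]]
    only_in_b: Mapping[DistanceType, frozenset[str]]


@dataclass(frozen=True)
class DisconnectionReport:
    """Cumulative disconnection pattern of a (possibly multi-unit) lesion.

    ``per_type_affected[t]`` is the union over lesioned units of their
    type-t partners, minus the lesioned set itself; ``provenance`` records
    which lesioned unit(s) contributed each affected unit.
    """

    lesioned_units: frozenset[str]
    per_type_affected: Mapping[DistanceType, frozenset[str]]
    provenance: Mapping[tuple[int, str], frozenset[str]]
    commissural_affected: frozenset[str] = frozenset()
    depth: int = 1

    def affected(self, dtype: DistanceType | int) -> frozenset[str]:
        return self.per_type_affected.get(DistanceType(dtype), frozenset())


def connectivity_map(matrix: ConnectionMatrix, region: str) -> ConnectivityMap:
    """Exhaustive per-type partner sets of *region*, with pathway labels
    where curated."""
    matrix.registry.unit(region)
    per_type = {t: matrix.partners(region, t) for t in DistanceType}
    annotations: dict[str, str] = {}
    for t in (DistanceType.LONG_RANGE, DistanceType.PROJECTION):
        for partner in per_type[t]:
            vec = matrix.get(region, partner)
            pathway = vec.pathways.get(t)
            if pathway:
                annotations[partner] = pathway
    commissural = None
    if matrix.commissural_rule_applied and matrix.registry.unit(region).is_cortical:
        # the homotopic rule links every cortical unit to its mirror region
        commissural = f"{region} (contralateral)"
    return ConnectivityMap(region, per_type, annotations, commissural)


def era_diff(
    matrix_a: ConnectionMatrix, matrix_b: ConnectionMatrix, region: str
) -> EraDiff:
    """Per-type partner-set differences of *region* between two matrices
    sharing a registry."""
    if matrix_a.registry_checksum != matrix_b.registry_checksum:
        raise CompatibilityError(
            "era comparison requires both matrices to share one registry"
        )
    map_a = connectivity_map(matrix_a, region)
    map_b = connectivity_map(matrix_b, region)
    only_a = {t: map_a.partners(t) - map_b.partners(t) for t in DistanceType}
    only_b = {t: map_b.partners(t) - map_a.partners(t) for t in DistanceType}
    return EraDiff(region, only_a, only_b)


def lesion_disconnection(
    matrix: ConnectionMatrix,
    lesioned: Iterable[str],
    thalamic_only: bool = False,
    depth: int = 1,
) -> DisconnectionReport:
    """Remote regions putatively disconnected by a lesion over *lesioned*.

    Direct (first-order) semantics by default: the type-t affected set is the
    union of the lesioned units' type-t partners, excluding the lesioned
    units themselves.  ``depth > 1`` opts in to multi-hop propagation, where
    each newly affected cortical unit seeds the next wave.  With
    ``thalamic_only`` the projection (type 4) output is restricted to
    thalamic partners.  An empty lesion yields an empty report.
    """
    lesioned = frozenset(lesioned)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    for code in lesioned:
        if not matrix.registry.unit(code).is_cortical:
            raise ValueError(f"lesioned units must be cortical, got {code!r}")

    affected: dict[DistanceType, set[str]] = {t: set() for t in DistanceType}
    provenance: dict[tuple[int, str], set[str]] = {}
    frontier = lesioned
    visited = set(lesioned)
    for _ in range(depth):
        next_frontier: set[str] = set()
        for source in sorted(frontier):
            for t in DistanceType:
                for partner in matrix.partners(source, t):
                    if partner in lesioned:
                        continue
                    affected[t].add(partner)
                    provenance.setdefault((int(t), partner), set()).add(source)
                    if partner not in visited and matrix.registry.unit(partner).is_cortical:
                        next_frontier.add(partner)
        visited |= next_frontier
        frontier = next_frontier
        if not frontier:
            break

    if thalamic_only:
        thalamic = set(matrix.registry.tier_codes(Tier.THALAMIC))
        dropped = affected[DistanceType.PROJECTION] - thalamic
        affected[DistanceType.PROJECTION] &= thalamic
        for unit in dropped:
            provenance.pop((int(DistanceType.PROJECTION), unit), None)

    commissural = frozenset()
    if matrix.commissural_rule_applied:
        commissural = frozenset(f"{u} (contralateral)" for u in sorted(lesioned))

    return DisconnectionReport(
        lesioned_units=lesioned,
        per_type_affected={t: frozenset(s) for t, s in affected.items()},
        provenance={k: frozenset(v) for k, v in provenance.items()},
        commissural_affected=commissural,
        depth=depth,
    )


# ---------------------------------------------------------------------------
# rendering

def _map_rows(obj: ConnectivityMap | DisconnectionReport) -> list[tuple[int, str, str]]:
    rows = []
    if isinstance(obj, ConnectivityMap):
        for t in DistanceType:
            for partner in sorted(obj.partners(t)):
                rows.append((int(t), partner, obj.pathway_annotations.get(partner, "")))
    else:
        for t in DistanceType:
            for unit in sorted(obj.affected(t)):
                # ';' keeps the CSV rendering unambiguous for multi-unit lesions
                via = ";".join(sorted(obj.provenance.get((int(t), unit), ())))
                rows.append((int(t), unit, via))
    return rows


def render_map(
    obj: ConnectivityMap | DisconnectionReport, style: str = "markdown"
) -> str:
    """Deterministic tabular rendering (rows sorted by type, then partner).

    ``style`` is ``"markdown"`` or ``"csv"``.  The third column is the
    pathway label for a connectivity map and the contributing lesioned
    unit(s) for a disconnection report.
    """
    rows = _map_rows(obj)
    if isinstance(obj, ConnectivityMap):
        title = f"Connectivity map: {obj.focus_region}"
        third = "pathway"
    else:
        title = "Lesion disconnection: " + ",".join(sorted(obj.lesioned_units))
        third = "via"
    if style == "csv":
        lines = [f"type,partner,{third}"]
        lines += [f"{t},{p},{v}" for t, p, v in rows]
        return "\n".join(lines) + "\n"
    if style == "markdown":
        lines = [f"### {title}", "", f"| type | partner | {third} |", "| --- | --- | --- |"]
        lines += [f"| {t} | {p} | {v} |" for t, p, v in rows]
        present = sorted({t for t, _, _ in rows})
        legend = {1: "red (short-range)", 2: "green (medium-range)",
                  3: "blue (long-range)", 4: "gray (projection)"}
        if present:
            lines += ["", "Legend: " + "; ".join(f"type {t} = {legend[t]}" for t in present)]
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown render style {style!r} (use 'markdown' or 'csv')")


_TYPE_COLORS = {1: "tab:red", 2: "tab:green", 3: "tab:blue", 4: "0.5"}


def plot_map(
    obj: ConnectivityMap | DisconnectionReport, path: str | Path
) -> None:
    """Schematic per-type drawing (focus/lesion in the center, partners
    arranged on a circle, colored by distance type as in the tabular maps)."""
    import math

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = _map_rows(obj)
    center = (
        obj.focus_region
        if isinstance(obj, ConnectivityMap)
        else ",".join(sorted(obj.lesioned_units))
    )
    fig, ax = plt.subplots(figsize=(7, 7))
    ax.scatter([0], [0], s=600, c="0.3", zorder=3)
    ax.annotate(center, (0, 0), ha="center", va="center", color="white", zorder=4)
    n = max(len(rows), 1)
    for i, (t, partner, _) in enumerate(rows):
        theta = 2 * math.pi * i / n
        x, y = math.cos(theta), math.sin(theta)
        color = _TYPE_COLORS[t]
        ax.plot([0, x], [0, y], color=color, lw=1.2, zorder=1)
        ax.scatter([x], [y], s=300, c=color, zorder=3)
        ax.annotate(partner, (1.12 * x, 1.12 * y), ha="center", va="center", fontsize=8)
    handles = [
        plt.Line2D([], [], color=c, label=f"type {t}")
        for t, c in _TYPE_COLORS.items()
        if any(r[0] == t for r in rows)
    ]
    if handles:
        ax.legend(handles=handles, loc="lower left")
    ax.set_xlim(-1.35, 1.35)
    ax.set_ylim(-1.35, 1.35)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
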