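"""Anatomic frame of reference: parcellation units, lobes, and gyral adjacency.

The registry holds the rows/columns of the connectivity matrix — named gyral
cortical regions and subcortical nuclei (parcellation units, PUs) — together
with the two structural relations the connection typology is defined over:
lobe membership and inter-gyral adjacency.  The packaged default registry
contains the 48 printed cortical units of the gyral parcellation system of
the original Harvard-Oxford Atlas, the seven thalamic units, and aggregate
striatal / pontine / hippocampal / amygdalar units used as projection targets.

Adjacency is never derivable from the unit list alone: it is a declared,
auditable input (an editable part of the config), and every typology decision
is relative to the adjacency the registry was loaded with.
"""

from __future__ import annotations

import csv
import enum
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .errors import ConfigError, UnknownUnitError

__all__ = [
    "Tier",
    "Lobe",
    "ParcellationUnit",
    "Registry",
    "load_registry",
    "write_registry",
    "default_registry",
    "homotopic_counterpart",
    "THALAMIC_UNITS",
]

#: The seven thalamic parcellation units (anterior, medial, lateral anterior,
#: lateral posterior, posterior, lateral geniculate, medial geniculate).
THALAMIC_UNITS = frozenset({"A", "M", "La", "Lp", "P", "LGN", "MGN"})


class Tier(str, enum.Enum):
    """Gross anatomical tier of a parcellation unit."""

    CORTICAL = "cortical"
    THALAMIC = "thalamic"
    STRIATAL = "striatal"
    OTHER_SUBCORTICAL = "other_subcortical"

    @property
    def is_cortical(self) -> bool:
        return self is Tier.CORTICAL


class Lobe(str, enum.Enum):
    """Cerebral lobe; the insula counts as a distinct lobe in this framework,
    and subcortical units carry ``NONE``."""

    FRONTAL = "frontal"
    PARIETAL = "parietal"
    TEMPORAL = "temporal"
    OCCIPITAL = "occipital"
    INSULA = "insula"
    LIMBIC = "limbic"
    NONE = "none"


@dataclass(frozen=True)
class ParcellationUnit:
    """One atlas region — a row/column of the connectivity matrix.

    Parameters
    ----------
    code : str
        Short unique label, e.g. ``"AG"`` or ``"F2"``.
    full_name : str
        Human-readable region name, e.g. ``"Angular gyrus"``.
    tier : Tier
        Cortical, thalamic, striatal or other subcortical.
    lobe : Lobe
        Lobe membership; cortical units must have a lobe, subcortical units
        must carry ``Lobe.NONE``.
    brodmann_areas : tuple of str
        Associated Brodmann area labels (may be empty).
    functional_systems : tuple of str
        Associated functional-system labels (may be empty).
    """

    code: str
    full_name: str
    tier: Tier
    lobe: Lobe = Lobe.NONE
    brodmann_areas: tuple[str, ...] = ()
    functional_systems: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.code:
            raise ConfigError("unit code must be non-empty")
        if self.tier.is_cortical and self.lobe is Lobe.NONE:
            raise ConfigError(f"cortical unit {self.code!r} must be assigned a lobe")
        if not self.tier.is_cortical and self.lobe is not Lobe.NONE:
            raise ConfigError(f"subcortical unit {self.code!r} must have lobe 'none'")

    @property
    def is_cortical(self) -> bool:
        return self.tier.is_cortical

    def to_dict(self) -> dict:
        d = {
            "code": self.code,
            "name": self.full_name,
            "tier": self.tier.value,
            "lobe": self.lobe.value,
        }
        if self.brodmann_areas:
            d["brodmann"] = list(self.brodmann_areas)
        if self.functional_systems:
            d["systems"] = list(self.functional_systems)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParcellationUnit":
        try:
            tier = Tier(d.get("tier", "cortical"))
            lobe = Lobe(d.get("lobe", "none"))
        except ValueError as exc:
            raise ConfigError(f"unit {d.get('code')!r}: {exc}") from exc
        missing = {"code", "name"} - set(d)
        if missing:
            raise ConfigError(f"unit entry missing fields {sorted(missing)}: {d!r}")
        return cls(
            code=str(d["code"]),
            full_name=str(d["name"]),
            tier=tier,
            lobe=lobe,
            brodmann_areas=tuple(str(x) for x in d.get("brodmann", ())),
            functional_systems=tuple(str(x) for x in d.get("systems", ())),
        )


class Registry:
    """Validated set of parcellation units plus the lobe map and adjacency graph.

    The adjacency relation is symmetric and irreflexive, defined over cortical
    unit codes only, and every endpoint must exist in the unit set.
    """

    def __init__(
        self,
        units: Iterable[ParcellationUnit],
        adjacency: Iterable[tuple[str, str]] = (),
        metadata: Mapping | None = None,
    ):
        self._units: dict[str, ParcellationUnit] = {}
        for u in units:
            if u.code in self._units:
                raise ConfigError(f"duplicate unit code {u.code!r}")
            self._units[u.code] = u
        self._adjacency: set[frozenset[str]] = set()
        for a, b in adjacency:
            if a == b:
                raise ConfigError(f"self-adjacency {a!r} is not allowed")
            for c in (a, b):
                if c not in self._units:
                    raise ConfigError(f"adjacency references unknown unit {c!r}")
                if not self._units[c].is_cortical:
                    raise ConfigError(f"adjacency endpoint {c!r} is not cortical")
            self._adjacency.add(frozenset((a, b)))
        self.metadata: dict = dict(metadata or {})

    # -- lookup -----------------------------------------------------------
    def __contains__(self, code: str) -> bool:
        return code in self._units

    def __len__(self) -> int:
        return len(self._units)

    def unit(self, code: str) -> ParcellationUnit:
        try:
            return self._units[code]
        except KeyError:
            raise UnknownUnitError(code) from None

    @property
    def units(self) -> tuple[ParcellationUnit, ...]:
        return tuple(self._units[c] for c in sorted(self._units))

    @property
    def cortical_codes(self) -> tuple[str, ...]:
        return tuple(c for c in sorted(self._units) if self._units[c].is_cortical)

    @property
    def subcortical_codes(self) -> tuple[str, ...]:
        return tuple(c for c in sorted(self._units) if not self._units[c].is_cortical)

    def tier_codes(self, tier: Tier) -> tuple[str, ...]:
        return tuple(c for c in sorted(self._units) if self._units[c].tier is tier)

    @property
    def thalamic_codes(self) -> tuple[str, ...]:
        return self.tier_codes(Tier.THALAMIC)

    @property
    def adjacency_pairs(self) -> tuple[tuple[str, str], ...]:
        return tuple(sorted(tuple(sorted(e)) for e in self._adjacency))

    def lobe(self, code: str) -> Lobe:
        return self.unit(code).lobe

    # -- typology-facing relations ---------------------------------------
    def are_adjacent(self, a: str, b: str) -> bool:
        """True iff cortical units *a* and *b* share a declared gyral border."""
        ua, ub = self.unit(a), self.unit(b)
        if a == b:
            raise ValueError("self-adjacency is undefined")
        if not (ua.is_cortical and ub.is_cortical):
            raise ValueError("adjacency is defined between cortical units only")
        return frozenset((a, b)) in self._adjacency

    def same_lobe(self, a: str, b: str) -> bool:
        """True iff cortical units *a* and *b* lie in the same lobe."""
        ua, ub = self.unit(a), self.unit(b)
        if not (ua.is_cortical and ub.is_cortical):
            raise ValueError("lobe comparison is defined between cortical units only")
        return ua.lobe is ub.lobe

    def neighbors(self, code: str) -> frozenset[str]:
        self.unit(code)
        return frozenset(
            next(iter(e - {code})) for e in self._adjacency if code in e
        )

    # -- identity ---------------------------------------------------------
    def checksum(self) -> str:
        """SHA-256 of the canonical serialized form; identifies the anatomic
        frame a matrix was built against."""
        payload = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(payload.encode()).hexdigest()

    def __eq__(self, other) -> bool:
        if not isinstance(other, Registry):
            return NotImplemented
        return (
            self._units == other._units
            and self._adjacency == other._adjacency
        )

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "units": [u.to_dict() for u in self.units],
            "adjacency": [list(p) for p in self.adjacency_pairs],
            "metadata": dict(sorted(self.metadata.items())),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Registry":
        if "units" not in d:
            raise ConfigError("registry config must contain a 'units' block")
        units = [ParcellationUnit.from_dict(u) for u in d["units"]]
        adjacency = [tuple(p) for p in d.get("adjacency", [])]
        for p in adjacency:
            if len(p) != 2:
                raise ConfigError(f"adjacency entry must be a pair: {p!r}")
        return cls(units, adjacency, d.get("metadata"))


def load_registry(config_path: str | Path) -> Registry:
    """Load and validate a registry from a JSON or YAML config file.

    The config has a ``units`` block (code, name, tier, lobe, brodmann,
    systems), an ``adjacency`` block (list of unordered cortical code pairs)
    and an optional ``metadata`` block.
    """
    path = Path(config_path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, Mapping):
        raise ConfigError(f"registry config root must be a mapping: {path}")
    return Registry.from_dict(data)


def write_registry(registry: Registry, path: str | Path) -> None:
    """Write a registry config (JSON, or YAML for ``.yaml``/``.yml`` paths)."""
    path = Path(path)
    data = registry.to_dict()
    if path.suffix.lower() in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=1, sort_keys=False) + "\n")


def load_units_csv(path: str | Path) -> list[ParcellationUnit]:
    """Import a units table from CSV (columns: code, name, tier, lobe,
    brodmann, systems; the last two are ``;``-separated lists)."""
    units = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            d = {
                "code": row["code"],
                "name": row["name"],
                "tier": row.get("tier", "cortical"),
                "lobe": row.get("lobe", "none"),
            }
            for key in ("brodmann", "systems"):
                if row.get(key):
                    d[key] = [x.strip() for x in row[key].split(";") if x.strip()]
            units.append(ParcellationUnit.from_dict(d))
    return units


def default_registry() -> Registry:
    """The packaged registry: 48 printed cortical units, 7 thalamic units,
    and aggregate subcortical projection targets, with the editable default
    lobe map and gyral adjacency fixture."""
    from importlib.resources import files

    data = json.loads(files("connectomatrix.data").joinpath("registry.json").read_text())
    return Registry.from_dict(data)


_HEMISPHERES = {"L": "R", "R": "L"}


def homotopic_counterpart(tagged_code: str, registry: Registry | None = None) -> str:
    """Contralateral mirror-image unit of a hemisphere-tagged cortical code.

    ``"F2_L"`` maps to ``"F2_R"`` and vice versa; applying the map twice is
    the identity.  Homotopy is defined for cerebral cortex only, so passing a
    subcortical code raises ``ValueError``.  When *registry* is given, the
    bare code must exist in it.
    """
    code, sep, hemi = tagged_code.rpartition("_")
    if not sep or hemi not in _HEMISPHERES:
        raise ValueError(
            f"expected a hemisphere-tagged code like 'AG_L' or 'AG_R', got {tagged_code!r}"
        )
    if registry is not None and not registry.unit(code).is_cortical:
        raise ValueError(
            f"homotopic counterpart is defined for cortical units only, not {code!r}"
        )
    return f"{code}_{_HEMISPHERES[hemi]}"
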