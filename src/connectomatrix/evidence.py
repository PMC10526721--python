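"""Literature-curation layer: publications, evidence records, pathways and
connection assertions.

The unit of curated knowledge is the assertion "Region A is connected to
Region B by Pathway C", backed by one or more evidence records (publication
plus page/table/figure/tracer/species locators).  Assertions are typed with
the distance typology and era-tagged; rows that violate the typology are
quarantined into the ingest report rather than silently dropped or admitted.

The flat-file interchange format is a long CSV (one assertion per row) with
a JSON sidecar declaring publications and pathway entities; an embedded
sqlite store provides a zero-infrastructure single-file save/load.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ConfigError, UnknownPathwayError
from .matrix import ConnectionMatrix, Era
from .registry import Registry
from .typology import ConnectionClass, DistanceType, validate_assertion

__all__ = [
    "Publication",
    "EvidenceRecord",
    "Pathway",
    "ConnectionAssertion",
    "EvidenceDB",
    "IngestReport",
    "ingest_curation_file",
]

CURATION_COLUMNS = (
    "region_a", "region_b", "type", "pathway", "era",
    "publication", "page", "table", "figure", "tracer", "species", "notes",
)

DISTANCE_CATEGORIES = {"intragyral", "juxtagyral", "intralobar", "long_range"}


@dataclass(frozen=True)
class Publication:
    identifier: str
    year: int | None = None
    species: str = "human"
    method: str = ""


@dataclass(frozen=True)
class EvidenceRecord:
    """One locator into a publication supporting an assertion."""

    identifier: str
    publication_ref: str
    page: str = ""
    table: str = ""
    figure: str = ""
    tracer_type: str = ""
    species: str = "human"
    notes: str = ""


@dataclass
class Pathway:
    """A named fiber system (e.g. the superior longitudinal fascicle).

    ``region_set`` is derived at ingest time as the union of endpoints of
    all assertions annotated with this pathway.
    """

    preferred_name: str
    synonyms: tuple[str, ...] = ()
    connection_class: ConnectionClass = ConnectionClass.ASSOCIATIONAL
    distance_category: str = "long_range"
    region_set: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.distance_category not in DISTANCE_CATEGORIES:
            raise ConfigError(
                f"pathway {self.preferred_name!r}: distance_category must be one of "
                f"{sorted(DISTANCE_CATEGORIES)}"
            )


@dataclass(frozen=True)
class ConnectionAssertion:
    """'Region A is connected to Region B by Pathway C', typed and era-tagged."""

    region_a: str
    region_b: str
    claimed_type: DistanceType
    era: Era
    pathway_ref: str | None = None
    evidence: tuple[str, ...] = ()
    notes: str = ""

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.region_a, self.region_b)))


@dataclass
class IngestReport:
    """Per-row diagnostics from a curation ingest; quarantined rows never
    reach the database."""

    n_rows: int = 0
    n_accepted: int = 0
    quarantined: list[tuple[int, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.quarantined

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_accepted": self.n_accepted,
            "quarantined": [{"row": r, "problem": p} for r, p in self.quarantined],
        }


class EvidenceDB:
    """In-memory curation database with referential integrity.

    Publications, pathways (with synonym-aware case-insensitive lookup),
    evidence records and validated connection assertions.
    """

    def __init__(self, registry: Registry):
        self.registry = registry
        self.publications: dict[str, Publication] = {}
        self.pathways: dict[str, Pathway] = {}
        self.evidence_records: dict[str, EvidenceRecord] = {}
        self.assertions: list[ConnectionAssertion] = []
        self._pathway_index: dict[str, str] = {}  # lowercased name/synonym -> preferred

    # -- population -------------------------------------------------------
    def add_publication(self, pub: Publication) -> None:
        if pub.identifier in self.publications:
            raise ConfigError(f"duplicate publication identifier {pub.identifier!r}")
        self.publications[pub.identifier] = pub

    def add_pathway(self, pathway: Pathway) -> None:
        if pathway.preferred_name in self.pathways:
            raise ConfigError(f"duplicate pathway {pathway.preferred_name!r}")
        for code in pathway.region_set:
            self.registry.unit(code)
        self.pathways[pathway.preferred_name] = pathway
        for name in (pathway.preferred_name, *pathway.synonyms):
            self._pathway_index[name.lower()] = pathway.preferred_name

    def add_evidence(self, record: EvidenceRecord) -> None:
        if record.publication_ref not in self.publications:
            raise ConfigError(
                f"evidence {record.identifier!r} references unknown publication "
                f"{record.publication_ref!r}"
            )
        self.evidence_records[record.identifier] = record

    def resolve_pathway(self, name: str) -> Pathway:
        key = name.strip().lower()
        if key not in self._pathway_index:
            raise UnknownPathwayError(name)
        return self.pathways[self._pathway_index[key]]

    # -- queries ----------------------------------------------------------
    def pathway_regions(self, pathway_name: str) -> frozenset[str]:
        """Units interconnected by the named pathway (synonym-aware)."""
        return self.resolve_pathway(pathway_name).region_set

    def query_by_region(
        self, region: str
    ) -> dict[DistanceType, tuple[ConnectionAssertion, ...]]:
        """All assertions touching *region*, grouped by distance type,
        duplicate-free, ordered by (type, partner code)."""
        self.registry.unit(region)
        groups: dict[DistanceType, dict[tuple, ConnectionAssertion]] = {
            t: {} for t in DistanceType
        }
        for a in self.assertions:
            if region in (a.region_a, a.region_b):
                partner = a.region_b if a.region_a == region else a.region_a
                groups[a.claimed_type].setdefault((partner, a.pathway_ref), a)
        return {
            t: tuple(d[k] for k in sorted(d, key=lambda k: (k[0], k[1] or "")))
            for t, d in groups.items()
        }

    def query_by_type(self, dtype: DistanceType | int) -> frozenset[tuple[str, str]]:
        """All unit pairs asserted with the given distance type."""
        t = DistanceType(dtype)
        return frozenset(a.pair for a in self.assertions if a.claimed_type is t)

    # -- matrix construction ----------------------------------------------
    def to_matrix(self, era: Era | str, apply_commissural_rule: bool = True) -> ConnectionMatrix:
        """Build the era's connection matrix from the stored assertions."""
        era = Era(era)
        m = ConnectionMatrix(
            self.registry, era, pathway_catalog=frozenset(self.pathways)
        )
        for a in self.assertions:
            if a.era is era:
                m.set_connection(
                    a.region_a, a.region_b, a.claimed_type,
                    pathway=a.pathway_ref, evidence=a.evidence,
                )
        if apply_commissural_rule:
            m.apply_homotopic_callosal_rule()
        return m

    # -- sqlite single-file store -----------------------------------------
    def to_sqlite(self, path: str | Path) -> None:
        con = sqlite3.connect(path)
        try:
            cur = con.cursor()
            cur.executescript(
                """
                DROP TABLE IF EXISTS publications;
                DROP TABLE IF EXISTS pathways;
                DROP TABLE IF EXISTS evidence;
                DROP TABLE IF EXISTS assertions;
                CREATE TABLE publications (identifier TEXT PRIMARY KEY, year INT,
                    species TEXT, method TEXT);
                CREATE TABLE pathways (preferred_name TEXT PRIMARY KEY, synonyms TEXT,
                    connection_class TEXT, distance_category TEXT);
                CREATE TABLE evidence (identifier TEXT PRIMARY KEY, publication_ref TEXT
                    REFERENCES publications(identifier), page TEXT, tbl TEXT,
                    figure TEXT, tracer_type TEXT, species TEXT, notes TEXT);
                CREATE TABLE assertions (region_a TEXT, region_b TEXT, type INT,
                    era TEXT, pathway TEXT, evidence TEXT, notes TEXT);
                """
            )
            cur.executemany(
                "INSERT INTO publications VALUES (?,?,?,?)",
                [(p.identifier, p.year, p.species, p.method) for p in self.publications.values()],
            )
            cur.executemany(
                "INSERT INTO pathways VALUES (?,?,?,?)",
                [
                    (p.preferred_name, json.dumps(list(p.synonyms)),
                     p.connection_class.value, p.distance_category)
                    for p in self.pathways.values()
                ],
            )
            cur.executemany(
                "INSERT INTO evidence VALUES (?,?,?,?,?,?,?,?)",
                [
                    (e.identifier, e.publication_ref, e.page, e.table, e.figure,
                     e.tracer_type, e.species, e.notes)
                    for e in self.evidence_records.values()
                ],
            )
            cur.executemany(
                "INSERT INTO assertions VALUES (?,?,?,?,?,?,?)",
                [
                    (a.region_a, a.region_b, int(a.claimed_type), a.era.value,
                     a.pathway_ref, json.dumps(list(a.evidence)), a.notes)
                    for a in self.assertions
                ],
            )
            con.commit()
        finally:
            con.close()

    @classmethod
    def from_sqlite(cls, path: str | Path, registry: Registry) -> "EvidenceDB":
        db = cls(registry)
        con = sqlite3.connect(path)
        try:
            cur = con.cursor()
            for row in cur.execute("SELECT * FROM publications ORDER BY identifier"):
                db.add_publication(Publication(*row))
            for name, syn, cls_, cat in cur.execute(
                "SELECT * FROM pathways ORDER BY preferred_name"
            ):
                db.add_pathway(
                    Pathway(name, tuple(json.loads(syn)), ConnectionClass(cls_), cat)
                )
            for row in cur.execute("SELECT * FROM evidence ORDER BY identifier"):
                db.add_evidence(EvidenceRecord(*row))
            for ra, rb, t, era, pw, ev, notes in cur.execute(
                "SELECT * FROM assertions ORDER BY rowid"
            ):
                db.assertions.append(
                    ConnectionAssertion(
                        ra, rb, DistanceType(t), Era(era), pw,
                        tuple(json.loads(ev)), notes,
                    )
                )
        finally:
            con.close()
        db._rebuild_pathway_regions()
        return db

    # -- internals --------------------------------------------------------
    def _rebuild_pathway_regions(self) -> None:
        regions: dict[str, set[str]] = {name: set() for name in self.pathways}
        for a in self.assertions:
            if a.pathway_ref:
                regions[a.pathway_ref].update((a.region_a, a.region_b))
        for name, units in regions.items():
            self.pathways[name].region_set = frozenset(units)


def load_sidecar(path: str | Path, registry: Registry) -> tuple[list[Publication], list[Pathway]]:
    """Parse a publications/pathways sidecar JSON."""
    data = json.loads(Path(path).read_text())
    pubs = [
        Publication(
            identifier=p["identifier"],
            year=p.get("year"),
            species=p.get("species", "human"),
            method=p.get("method", ""),
        )
        for p in data.get("publications", [])
    ]
    pathways = [
        Pathway(
            preferred_name=p["name"],
            synonyms=tuple(p.get("synonyms", ())),
            connection_class=ConnectionClass(p.get("class", "associational")),
            distance_category=p.get("distance_category", "long_range"),
        )
        for p in data.get("pathways", [])
    ]
    return pubs, pathways


def ingest_curation_file(
    path: str | Path,
    registry: Registry,
    sidecar_path: str | Path | None = None,
    supplementary_paths: Iterable[str | Path] = (),
) -> tuple[EvidenceDB, IngestReport]:
    """Ingest a long-format curation CSV (plus optional sidecar JSON).

    Every row is validated: unknown unit codes, unknown pathways or
    publications, bad type values and typology violations are quarantined
    with per-row diagnostics; valid rows become assertions with stable,
    deterministic evidence identifiers (``E0001`` in row order).  Additional
    curation CSVs (e.g. supplementary tables) may be appended via
    *supplementary_paths*; their rows continue the row numbering.
    """
    db = EvidenceDB(registry)
    if sidecar_path is not None:
        pubs, pathways = load_sidecar(sidecar_path, registry)
        for p in pubs:
            db.add_publication(p)
        for p in pathways:
            db.add_pathway(p)

    frames = [pd.read_csv(p, dtype=str, keep_default_na=False)
              for p in (path, *supplementary_paths)]
    frame = pd.concat(frames, ignore_index=True) if len(frames) > 1 else frames[0]
    missing = {"region_a", "region_b", "type", "era"} - set(frame.columns)
    if missing:
        raise ConfigError(f"curation file missing required columns {sorted(missing)}")

    report = IngestReport(n_rows=len(frame))
    for idx, row in enumerate(frame.itertuples(index=False), start=1):
        problem = _ingest_row(db, idx, row._asdict())
        if problem is None:
            report.n_accepted += 1
        else:
            report.quarantined.append((idx, problem))
    db._rebuild_pathway_regions()
    return db, report


def _ingest_row(db: EvidenceDB, idx: int, row: Mapping[str, str]) -> str | None:
    ra, rb = row.get("region_a", "").strip(), row.get("region_b", "").strip()
    for code in (ra, rb):
        if code not in db.registry:
            return f"unknown unit code {code!r}"
    try:
        dtype = DistanceType(int(row["type"]))
    except (KeyError, ValueError):
        return f"invalid distance type {row.get('type')!r}"
    try:
        era = Era(row.get("era", "").strip())
    except ValueError:
        return f"invalid era {row.get('era')!r}"

    report = validate_assertion(db.registry, ra, rb, dtype)
    if not report.ok:
        return "typology violation: " + "; ".join(report.violations)

    pathway_name = row.get("pathway", "").strip() or None
    preferred = None
    if pathway_name:
        try:
            preferred = db.resolve_pathway(pathway_name).preferred_name
        except UnknownPathwayError:
            return f"unknown pathway {pathway_name!r}"

    pub = row.get("publication", "").strip()
    evidence_ids: tuple[str, ...] = ()
    if pub:
        if pub not in db.publications:
            return f"unknown publication {pub!r}"
        eid = f"E{idx:04d}"
        db.add_evidence(
            EvidenceRecord(
                identifier=eid,
                publication_ref=pub,
                page=row.get("page", ""),
                table=row.get("table", ""),
                figure=row.get("figure", ""),
                tracer_type=row.get("tracer", ""),
                species=row.get("species", "") or db.publications[pub].species,
                notes=row.get("notes", ""),
            )
        )
        evidence_ids = (eid,)

    db.assertions.append(
        ConnectionAssertion(
            region_a=ra,
            region_b=rb,
            claimed_type=dtype,
            era=era,
            pathway_ref=preferred,
            evidence=evidence_ids,
            notes=row.get("notes", ""),
        )
    )
    return None
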