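"""KO assignment from tabular hits and presence/absence catalog screening.

Assignment follows a best-hit rule: hits passing the active thresholds are
ranked by (evalue ascending, identity descending, subject id ascending);
the top hit's KO is taken, and when the top subject has no KO mapping the
second-ranked hit is used instead (once — the fallback is not recursive).

Two threshold modes:

* ``strain`` — evalue < 1e-10;
* ``metagenome`` — evalue < 1e-10 and identity > 90%.

Bundled catalogs (versioned TSV fixtures, ``ko_id  symbol  family``):
``phycobilisome`` (allophycocyanin, phycocyanin, phycoerythrin and
phycoerythrobilin families, 26 KOs) and ``recombination`` (recBCD-related
plus DNA-polymerase-III and primosome orthologs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from panmeta.seqio import HitRecord, ProfileMatrix

logger = logging.getLogger(__name__)

STRAIN_MODE_MAX_EVALUE = 1e-10
METAGENOME_MODE_MIN_IDENTITY = 90.0

__all__ = [
    "KOEntry",
    "KOCatalog",
    "KOAssignment",
    "load_catalog",
    "assign_ko",
    "assign_ko_table",
    "presence_matrix",
    "family_summary",
    "FamilySummary",
]


@dataclass(frozen=True)
class KOEntry:
    ko_id: str
    symbol: str
    family: str


@dataclass(frozen=True)
class KOCatalog:
    """An ordered catalog of KO entries grouped into gene families."""

    name: str
    entries: tuple[KOEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.ko_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError(f"catalog {self.name!r}: duplicate KO ids")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def ko_ids(self) -> list[str]:
        return [e.ko_id for e in self.entries]

    @property
    def families(self) -> list[str]:
        seen: list[str] = []
        for e in self.entries:
            if e.family not in seen:
                seen.append(e.family)
        return seen

    def family_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for e in self.entries:
            sizes[e.family] = sizes.get(e.family, 0) + 1
        return sizes

    def entry(self, ko_id: str) -> KOEntry:
        for e in self.entries:
            if e.ko_id == ko_id:
                return e
        raise KeyError(ko_id)


def load_catalog(name_or_path: str) -> KOCatalog:
    """Load a bundled catalog by name or any catalog TSV by path."""
    path = Path(name_or_path)
    if path.suffix == ".tsv" and path.exists():
        text = path.read_text(encoding="utf-8")
        name = path.stem
    else:
        ref = resources.files("panmeta").joinpath(f"data/{name_or_path}.tsv")
        if not ref.is_file():
            raise ValueError(f"unknown catalog {name_or_path!r}")
        text = ref.read_text(encoding="utf-8")
        name = name_or_path
    entries: list[KOEntry] = []
    lines = text.splitlines()
    if not lines or lines[0].split("\t") != ["ko_id", "symbol", "family"]:
        raise ValueError(f"catalog {name!r}: bad header")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValueError(f"catalog {name!r}: line {lineno}: expected 3 columns")
        entries.append(KOEntry(*fields))
    return KOCatalog(name=name, entries=tuple(entries))


@dataclass(frozen=True)
class KOAssignment:
    """Result of assigning one query to a KO (or leaving it unassigned)."""

    query_id: str
    ko_id: str | None
    hit: HitRecord | None
    rank: int | None  # 1 = best hit, 2 = second-hit fallback


def _hit_order(hit: HitRecord) -> tuple:
    return (hit.evalue, -hit.percent_identity, hit.subject_id)


def assign_ko(
    query_id: str,
    hits_for_query: Sequence[HitRecord],
    ko_map: Mapping[str, str],
    max_evalue: float = STRAIN_MODE_MAX_EVALUE,
    min_identity: float | None = None,
) -> KOAssignment:
    """Assign one query to a KO with the best-hit / second-hit rule.

    Hits failing ``evalue < max_evalue`` (and, when ``min_identity`` is
    set, ``identity > min_identity``) are discarded.  Remaining hits are
    ranked by evalue, then identity (descending), then subject id; the
    rank-1 subject's KO is assigned, falling back once to rank 2 when the
    rank-1 subject has no KO mapping.  No passing hit -> unassigned.
    """
    passing = [
        h
        for h in hits_for_query
        if h.query_id == query_id
        and h.evalue < max_evalue
        and (min_identity is None or h.percent_identity > min_identity)
    ]
    ranked = sorted(passing, key=_hit_order)
    for rank, hit in enumerate(ranked[:2], start=1):
        ko = ko_map.get(hit.subject_id)
        if ko is not None:
            return KOAssignment(query_id=query_id, ko_id=ko, hit=hit, rank=rank)
    return KOAssignment(query_id=query_id, ko_id=None, hit=None, rank=None)


def assign_ko_table(
    hits: Sequence[HitRecord],
    ko_map: Mapping[str, str],
    max_evalue: float = STRAIN_MODE_MAX_EVALUE,
    min_identity: float | None = None,
) -> dict[str, KOAssignment]:
    """Assign every query appearing in ``hits``; returns query -> assignment."""
    by_query: dict[str, list[HitRecord]] = {}
    for hit in hits:
        by_query.setdefault(hit.query_id, []).append(hit)
    return {
        q: assign_ko(q, qhits, ko_map, max_evalue, min_identity)
        for q, qhits in by_query.items()
    }


def presence_matrix(
    assignments_by_entity: Mapping[str, Sequence[KOAssignment]],
    catalog: KOCatalog,
    entity_order: Sequence[str] | None = None,
) -> ProfileMatrix:
    """0/1 matrix: catalog KOs (rows, catalog order) x entities (columns).

    A cell is 1 iff at least one query of the entity was assigned to that
    KO.  Assigned KOs absent from the catalog are ignored with a log entry.
    """
    entities = list(entity_order) if entity_order is not None else list(
        assignments_by_entity
    )
    ko_index = {ko: i for i, ko in enumerate(catalog.ko_ids)}
    values = np.zeros((len(catalog), len(entities)))
    for j, entity in enumerate(entities):
        for assignment in assignments_by_entity.get(entity, ()):
            if assignment.ko_id is None:
                continue
            i = ko_index.get(assignment.ko_id)
            if i is None:
                logger.info(
                    "presence_matrix: KO %s assigned to %s is not in catalog "
                    "%s; ignored",
                    assignment.ko_id,
                    entity,
                    catalog.name,
                )
                continue
            values[i, j] = 1.0
    return ProfileMatrix(catalog.ko_ids, entities, values)


@dataclass(frozen=True)
class FamilySummary:
    family: str
    n_present: int
    n_total: int
    missing: tuple[str, ...]  # gene symbols absent from the entity


def family_summary(
    presence: ProfileMatrix, catalog: KOCatalog
) -> dict[str, dict[str, FamilySummary]]:
    """Per entity and catalog family: present counts and missing symbols."""
    if presence.row_labels != catalog.ko_ids:
        raise ValueError("presence matrix rows do not match catalog order")
    out: dict[str, dict[str, FamilySummary]] = {}
    for j, entity in enumerate(presence.col_labels):
        fams: dict[str, FamilySummary] = {}
        for family in catalog.families:
            members = [e for e in catalog.entries if e.family == family]
            present = [
                e
                for e in members
                if presence.values[catalog.ko_ids.index(e.ko_id), j] > 0
            ]
            missing = tuple(
                e.symbol for e in members if e not in present
            )
            fams[family] = FamilySummary(
                family=family,
                n_present=len(present),
                n_total=len(members),
                missing=missing,
            )
        out[entity] = fams
    return out
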