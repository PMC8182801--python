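"""Curate a raw table of structure determinations into structure families.

A refcode family (all determinations of one chemical compound) can mix
polymorphs, redeterminations and alternative space-group settings of the
same lattice.  Partitioning by similarity of Niggli-reduced cells, using the
scalar metric deformation measure with a 0.12 tolerance, separates phases
while tolerating re-settings (e.g. P2_1/c versus P2_1/n descriptions of one
lattice).  The curated families then pass through temperature
deduplication (10 K grouping tolerance, lowest-R representative) and
window filters: entries limited to 90-300 K, a representative at >=273 K
required, and a total span of >=50 K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

from .cells import ReductionError, UnitCell, deformation_measure, niggli_reduce

__all__ = [
    "CsdEntry",
    "StructureFamily",
    "RejectionRecord",
    "ROOM_TEMPERATURE",
    "screen_entries",
    "assign_temperature",
    "partition_refcode_family",
    "deduplicate_by_temperature",
    "filter_family",
    "single_publication_subset",
    "entries_from_dataframe",
    "build_families",
]

log = logging.getLogger(__name__)

#: recorded temperature for entries whose publication gives none
ROOM_TEMPERATURE = 293.0


@dataclass(frozen=True)
class CsdEntry:
    """One structure determination: cell, conditions and provenance flags."""

    refcode: str
    cell: UnitCell
    temperature: Optional[float]  # K, None = unrecorded ("room temperature")
    r_factor: Optional[float]
    pressure_flag: bool = False
    has_coordinates: bool = True
    is_organic: bool = True
    is_polymeric: bool = False
    publication_id: str = ""

    def __post_init__(self) -> None:
        if not self.refcode:
            raise ValueError("refcode must be non-empty")
        if self.temperature is not None and not 0.0 < self.temperature < 1000.0:
            raise ValueError(f"implausible temperature {self.temperature} K")

    @property
    def refcode_root(self) -> str:
        return self.refcode[:6]

    @property
    def suffix(self) -> str:
        return self.refcode[6:]


@dataclass(frozen=True)
class StructureFamily:
    """Determinations of one crystal phase, sorted by assigned temperature."""

    family_id: str
    entries: tuple[CsdEntry, ...]
    reduced_cells: tuple[UnitCell, ...]  # parallel to entries

    @property
    def n_entries(self) -> int:
        return len(self.entries)

    @property
    def temperatures(self) -> tuple[float, ...]:
        return tuple(assign_temperature(e) for e in self.entries)

    @property
    def single_publication(self) -> bool:
        return len({e.publication_id for e in self.entries}) == 1

    @property
    def t_min(self) -> float:
        return min(self.temperatures)

    @property
    def t_max(self) -> float:
        return max(self.temperatures)


@dataclass(frozen=True)
class RejectionRecord:
    """Machine-readable reason an entry or family was dropped."""

    family_id: Optional[str]
    refcode: Optional[str]
    reason: str  # pressure / no_coordinates / not_organic / polymeric /
    #              out_of_window / duplicate_T / no_273K / range_lt_50K /
    #              too_few_entries / unreducible_cell


def screen_entries(
    entries: Sequence[CsdEntry],
) -> tuple[list[CsdEntry], list[RejectionRecord]]:
    """Apply the entry-level constraints, preserving order.

    Discards non-ambient-pressure entries, entries without 3-D coordinates,
    non-organic entries and polymeric structures.
    """
    kept: list[CsdEntry] = []
    rejected: list[RejectionRecord] = []
    for e in entries:
        if e.pressure_flag:
            rejected.append(RejectionRecord(None, e.refcode, "pressure"))
        elif not e.has_coordinates:
            rejected.append(RejectionRecord(None, e.refcode, "no_coordinates"))
        elif not e.is_organic:
            rejected.append(RejectionRecord(None, e.refcode, "not_organic"))
        elif e.is_polymeric:
            rejected.append(RejectionRecord(None, e.refcode, "polymeric"))
        else:
            kept.append(e)
    return kept, rejected


def assign_temperature(entry: CsdEntry) -> float:
    """Recorded temperature, or 293 K when the publication gives none.

    Explicit temperatures are returned unchanged, including values inside
    the nominal room-temperature range 283-303 K: only *unrecorded*
    temperatures are assumed to be room temperature.
    """
    return ROOM_TEMPERATURE if entry.temperature is None else entry.temperature


def _entry_sort_key(entry: CsdEntry) -> tuple[str, float]:
    return (entry.suffix, assign_temperature(entry))


def partition_refcode_family(
    entries: Sequence[CsdEntry],
    tol: float = 0.12,
    niggli_eps: float = 1e-5,
) -> tuple[list[StructureFamily], list[RejectionRecord]]:
    """Split one refcode family into structure families by reduced-cell metric.

    Single-linkage clustering on the deformation measure between
    Niggli-reduced cells: an entry joins a family if its reduced cell is
    within ``tol`` of any current member, and families bridged by a new
    entry are merged, so members are connected by chains of pairwise
    measures <= tol.  Entries whose cells fail to reduce are quarantined
    with a logged warning rather than silently dropped.
    """
    roots = {e.refcode_root for e in entries}
    if len(roots) > 1:
        raise ValueError(f"entries span multiple refcode roots: {sorted(roots)}")
    ordered = sorted(entries, key=_entry_sort_key)

    quarantined: list[RejectionRecord] = []
    clusters: list[tuple[list[CsdEntry], list[UnitCell]]] = []
    for e in ordered:
        try:
            reduced, _ = niggli_reduce(e.cell, eps=niggli_eps)
        except ReductionError as exc:
            log.warning("quarantining %s: cell failed Niggli reduction (%s)", e.refcode, exc)
            quarantined.append(RejectionRecord(None, e.refcode, "unreducible_cell"))
            continue
        hits = [
            i
            for i, (_, cells) in enumerate(clusters)
            if any(
                deformation_measure(reduced, other, check_reduced=False) <= tol
                for other in cells
            )
        ]
        if not hits:
            clusters.append(([e], [reduced]))
        else:
            target = clusters[hits[0]]
            target[0].append(e)
            target[1].append(reduced)
            for i in reversed(hits[1:]):  # chain links two clusters: merge
                more_e, more_c = clusters.pop(i)
                target[0].extend(more_e)
                target[1].extend(more_c)

    root = next(iter(roots)) if roots else "XXXXXX"
    families = []
    for i, (members, cells) in enumerate(clusters, start=1):
        order = sorted(range(len(members)), key=lambda j: assign_temperature(members[j]))
        families.append(
            StructureFamily(
                family_id=f"{root}-{i}",
                entries=tuple(members[j] for j in order),
                reduced_cells=tuple(cells[j] for j in order),
            )
        )
    return families, quarantined


def deduplicate_by_temperature(
    family: StructureFamily, tol_t: float = 10.0
) -> StructureFamily:
    """Keep one representative per unique temperature (10 K grouping).

    Walking the ascending-temperature list, an entry within ``tol_t`` of the
    first member of the current group joins that group; each group is then
    represented by its lowest-R entry (a missing R loses to any reported R;
    remaining ties go to the earliest refcode suffix).
    """
    order = sorted(range(family.n_entries), key=lambda i: assign_temperature(family.entries[i]))
    groups: list[list[int]] = []
    for i in order:
        t = assign_temperature(family.entries[i])
        if groups and t - assign_temperature(family.entries[groups[-1][0]]) <= tol_t:
            groups[-1].append(i)
        else:
            groups.append([i])

    def rank(i: int) -> tuple[float, str]:
        e = family.entries[i]
        r = e.r_factor if e.r_factor is not None else float("inf")
        return (r, e.suffix)

    keep = [min(g, key=rank) for g in groups]
    return replace(
        family,
        entries=tuple(family.entries[i] for i in keep),
        reduced_cells=tuple(family.reduced_cells[i] for i in keep),
    )


def filter_family(
    family: StructureFamily,
    t_window: tuple[float, float] = (90.0, 300.0),
    min_top_t: float = 273.0,
    min_range: float = 50.0,
) -> tuple[Optional[StructureFamily], list[RejectionRecord]]:
    """Apply the temperature-window filters; returns (family or None, log).

    Entries outside the window are removed; the family survives only if a
    representative at or above ``min_top_t`` remains, the total temperature
    span is at least ``min_range``, and at least two entries remain.
    """
    records: list[RejectionRecord] = []
    keep_idx = []
    for i, e in enumerate(family.entries):
        t = assign_temperature(e)
        if t_window[0] <= t <= t_window[1]:
            keep_idx.append(i)
        else:
            records.append(RejectionRecord(family.family_id, e.refcode, "out_of_window"))
    trimmed = replace(
        family,
        entries=tuple(family.entries[i] for i in keep_idx),
        reduced_cells=tuple(family.reduced_cells[i] for i in keep_idx),
    )
    if trimmed.n_entries < 2:
        records.append(RejectionRecord(family.family_id, None, "too_few_entries"))
        return None, records
    if trimmed.t_max < min_top_t:
        records.append(RejectionRecord(family.family_id, None, "no_273K"))
        return None, records
    if trimmed.t_max - trimmed.t_min < min_range:
        records.append(RejectionRecord(family.family_id, None, "range_lt_50K"))
        return None, records
    return trimmed, records


def single_publication_subset(
    families: Iterable[StructureFamily], min_n: int = 4
) -> list[StructureFamily]:
    """Families whose entries all share one publication, with >= min_n entries."""
    return [f for f in families if f.single_publication and f.n_entries >= min_n]


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

_COLUMNS = [
    "refcode", "a", "b", "c", "alpha", "beta", "gamma",
    "temperature_K", "r_factor", "pressure_flag", "has_coords",
    "organic", "polymeric", "publication_id",
]


def entries_from_dataframe(df: pd.DataFrame) -> list[CsdEntry]:
    """Build entries from the flat CSV schema (empty field = missing)."""
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"entry table is missing columns: {missing}")
    entries = []
    for row in df.itertuples(index=False):
        cell = UnitCell(row.a, row.b, row.c, row.alpha, row.beta, row.gamma)
        temp = None if pd.isna(row.temperature_K) else float(row.temperature_K)
        rfac = None if pd.isna(row.r_factor) else float(row.r_factor)
        entries.append(
            CsdEntry(
                refcode=str(row.refcode),
                cell=cell,
                temperature=temp,
                r_factor=rfac,
                pressure_flag=bool(row.pressure_flag),
                has_coordinates=bool(row.has_coords),
                is_organic=bool(row.organic),
                is_polymeric=bool(row.polymeric),
                publication_id=str(row.publication_id),
            )
        )
    return entries


def build_families(
    entries: Sequence[CsdEntry],
    tol: float = 0.12,
    dedup_tol: float = 10.0,
    t_window: tuple[float, float] = (90.0, 300.0),
    min_top_t: float = 273.0,
    min_range: float = 50.0,
    niggli_eps: float = 1e-5,
) -> tuple[list[StructureFamily], list[RejectionRecord]]:
    """Screen, partition, deduplicate and filter a full entry table."""
    screened, rejections = screen_entries(entries)
    by_root: dict[str, list[CsdEntry]] = {}
    for e in screened:
        by_root.setdefault(e.refcode_root, []).append(e)
    accepted: list[StructureFamily] = []
    for root in sorted(by_root):
        fams, quarantined = partition_refcode_family(by_root[root], tol=tol, niggli_eps=niggli_eps)
        rejections.extend(quarantined)
        for fam in fams:
            fam = deduplicate_by_temperature(fam, tol_t=dedup_tol)
            kept, records = filter_family(
                fam, t_window=t_window, min_top_t=min_top_t, min_range=min_range
            )
            rejections.extend(records)
            if kept is not None:
                accepted.append(kept)
    return accepted, rejections
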