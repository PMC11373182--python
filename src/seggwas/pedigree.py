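"""Pedigree container and TSV input/output.

A pedigree is an ordered collection of individuals with sire/dam links.
IDs are opaque strings; unknown parents are represented as ``None``
internally and as a configurable code (``"0"`` or ``"NA"`` by default)
on disk.  Parents that are named in a sire/dam column but never appear
as a row of their own are inserted as *phantom* founders, as is the
unknown mate of an individual with exactly one recorded parent --
phantoms carry no phenotype and simply conduct the Hardy-Weinberg
founder prior through the pedigree.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

MALE = "male"
FEMALE = "female"
UNKNOWN_SEX = "unknown"

DEFAULT_UNKNOWN_CODES = ("0", "NA", "")

_SEX_CODES = {
    "m": MALE, "male": MALE, "1": MALE,
    "f": FEMALE, "female": FEMALE, "2": FEMALE,
    "u": UNKNOWN_SEX, "unknown": UNKNOWN_SEX, "0": UNKNOWN_SEX, "na": UNKNOWN_SEX,
}
_SEX_OUT = {MALE: "M", FEMALE: "F", UNKNOWN_SEX: "U"}


class PedigreeError(ValueError):
    """Invalid pedigree structure or file."""


class CycleError(PedigreeError):
    """A directed cycle exists through the parent links."""


@dataclass(frozen=True)
class Individual:
    """One pedigree record: ``sire``/``dam`` are ids or ``None`` for unknown."""

    id: str
    sire: str | None = None
    dam: str | None = None
    sex: str = UNKNOWN_SEX

    def __post_init__(self) -> None:
        if self.sire == self.id or self.dam == self.id:
            raise CycleError(f"individual {self.id!r} is its own parent")
        if self.sex not in (MALE, FEMALE, UNKNOWN_SEX):
            raise PedigreeError(f"invalid sex {self.sex!r} for {self.id!r}")


class Pedigree:
    """Validated, topologically orderable pedigree.

    Parameters
    ----------
    individuals:
        Records in input order.  Named-but-unlisted parents and unknown
        mates are auto-inserted as phantom founders (appended after the
        real records, in deterministic order).
    sex_recorded:
        Whether the source data carried a sex column; controls whether
        :func:`write_pedigree` emits one.
    """

    def __init__(self, individuals: Iterable[Individual], *, sex_recorded: bool = True):
        records = list(individuals)
        index: dict[str, int] = {}
        for ind in records:
            if ind.id in index:
                raise PedigreeError(f"duplicate id {ind.id!r}")
            index[ind.id] = len(index)

        phantoms: list[Individual] = []
        # parents named but never listed become founders with that id
        seen_phantom: set[str] = set()
        for ind in records:
            for parent, sex in ((ind.sire, MALE), (ind.dam, FEMALE)):
                if parent is not None and parent not in index and parent not in seen_phantom:
                    phantoms.append(Individual(parent, None, None, sex))
                    seen_phantom.add(parent)
                    log.warning("pedigree: parent %r of %r has no record; "
                                "inserted as phantom founder", parent, ind.id)
        for ph in phantoms:
            index[ph.id] = len(index)
        records = records + phantoms

        # exactly one known parent: insert a unique phantom mate so every
        # non-founder has two parents (the phantom stands for an unrelated
        # population animal, i.e. the Hardy-Weinberg prior)
        mates: list[Individual] = []
        fixed: list[Individual] = []
        for ind in records:
            sire, dam = ind.sire, ind.dam
            if (sire is None) != (dam is None):
                if sire is None:
                    sire = f"~sire_of_{ind.id}"
                    mates.append(Individual(sire, None, None, MALE))
                else:
                    dam = f"~dam_of_{ind.id}"
                    mates.append(Individual(dam, None, None, FEMALE))
                log.warning("pedigree: %r has one unknown parent; phantom mate inserted", ind.id)
                fixed.append(Individual(ind.id, sire, dam, ind.sex))
            else:
                fixed.append(ind)
        for ph in mates:
            index[ph.id] = len(index)
        records = fixed + mates

        self._individuals: list[Individual] = records
        self._index: dict[str, int] = {ind.id: i for i, ind in enumerate(records)}
        self.phantom_ids: frozenset[str] = frozenset(
            [p.id for p in phantoms] + [m.id for m in mates])
        self.sex_recorded = bool(sex_recorded)
        self._topo: list[str] | None = None
        self.topological_order()  # validates acyclicity eagerly

    # -- basic container protocol ------------------------------------------
    def __len__(self) -> int:
        return len(self._individuals)

    def __contains__(self, ident: str) -> bool:
        return ident in self._index

    def __getitem__(self, ident: str) -> Individual:
        return self._individuals[self._index[ident]]

    def __iter__(self):
        return iter(self._individuals)

    @property
    def individuals(self) -> Sequence[Individual]:
        return tuple(self._individuals)

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self._individuals]

    def position(self, ident: str) -> int:
        return self._index[ident]

    @property
    def founders(self) -> list[str]:
        """Ids with both parents unknown (includes phantoms)."""
        return [i.id for i in self._individuals if i.sire is None and i.dam is None]

    def sex_of(self, ident: str) -> str:
        return self[ident].sex

    def topological_order(self) -> list[str]:
        """Ids ordered so every parent precedes its offspring.

        Stable: ties are broken by input order, so re-reading the same
        file reproduces the same order.
        """
        if self._topo is not None:
            return self._topo
        n = len(self._individuals)
        children: list[list[int]] = [[] for _ in range(n)]
        indeg = [0] * n
        for i, ind in enumerate(self._individuals):
            for parent in (ind.sire, ind.dam):
                if parent is not None:
                    children[self._index[parent]].append(i)
                    indeg[i] += 1
        ready = [i for i in range(n) if indeg[i] == 0]
        heapq.heapify(ready)
        order: list[int] = []
        while ready:
            i = heapq.heappop(ready)
            order.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    heapq.heappush(ready, c)
        if len(order) != n:
            stuck = min(i for i in range(n) if indeg[i] > 0)
            raise CycleError(
                f"pedigree contains a cycle through {self._individuals[stuck].id!r}")
        self._topo = [self._individuals[i].id for i in order]
        return self._topo


def read_pedigree(path: str | Path, *, columns: dict[str, str] | None = None,
                  unknown_codes: Sequence[str] = DEFAULT_UNKNOWN_CODES,
                  sep: str = "\t") -> Pedigree:
    """Read a pedigree TSV with header columns ``id sire dam [sex]``.

    ``columns`` maps the canonical names to the file's column names,
    e.g. ``{"id": "animal", "sire": "father"}``.
    """
    colmap = {"id": "id", "sire": "sire", "dam": "dam", "sex": "sex"}
    if columns:
        colmap.update(columns)
    unknown = {c.upper() for c in unknown_codes} | set(unknown_codes)

    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)
        pos = {name: i for i, name in enumerate(header)}
        for req in ("id", "sire", "dam"):
            if colmap[req] not in pos:
                raise PedigreeError(f"{path}: missing column {colmap[req]!r}")
        has_sex = colmap["sex"] in pos

        def parent(value: str) -> str | None:
            return None if value in unknown or value.upper() in unknown else value

        records = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split(sep)
            try:
                ident = fields[pos[colmap["id"]]]
                sire = parent(fields[pos[colmap["sire"]]])
                dam = parent(fields[pos[colmap["dam"]]])
                sex = UNKNOWN_SEX
                if has_sex:
                    raw = fields[pos[colmap["sex"]]].strip().lower()
                    if raw not in _SEX_CODES:
                        raise PedigreeError(f"{path}:{lineno}: invalid sex code {raw!r}")
                    sex = _SEX_CODES[raw]
            except IndexError:
                raise PedigreeError(f"{path}:{lineno}: too few fields") from None
            records.append(Individual(ident, sire, dam, sex))
    return Pedigree(records, sex_recorded=has_sex)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    """Write non-phantom rows in the canonical dialect (unknown = ``0``)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        cols = ["id", "sire", "dam"] + (["sex"] if ped.sex_recorded else [])
        fh.write("\t".join(cols) + "\n")
        for ind in ped:
            if ind.id in ped.phantom_ids:
                continue
            row = [ind.id, ind.sire or "0", ind.dam or "0"]
            if ped.sex_recorded:
                row.append(_SEX_OUT[ind.sex])
            fh.write("\t".join(row) + "\n")


def pedigree_summary(ped: Pedigree) -> dict[str, int]:
    """Counts of animals and of distinct sires/dams with offspring."""
    sires = {i.sire for i in ped if i.sire is not None}
    dams = {i.dam for i in ped if i.dam is not None}
    return {"n_animals": len(ped), "n_sires": len(sires), "n_dams": len(dams),
            "n_founders": len(ped.founders), "n_phantoms": len(ped.phantom_ids)}
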