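"""Categorical phenotype tables.

Phenotype classes are small integers ``0..K-1`` (default horn-status
coding: 0 = polled, 1 = scurs/knobs, 2 = horned); a missing record is
``MISSING`` (-1) and is written as ``NA``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

MISSING = -1

DEFAULT_LABELS = ("polled", "scurs/knobs", "horned")


class PhenotypeError(ValueError):
    """Invalid phenotype value or file."""


class PhenotypeTable:
    """Mapping id -> phenotype class, with class labels.

    Ids absent from the table are treated as MISSING when queried, so a
    table can legitimately cover only the phenotyped subset of a pedigree.
    """

    def __init__(self, values: Mapping[str, int],
                 labels: Sequence[str] = DEFAULT_LABELS):
        self.labels = tuple(labels)
        if len(self.labels) < 2:
            raise PhenotypeError("need at least two phenotype classes")
        k = len(self.labels)
        self._values: dict[str, int] = {}
        for ident, val in values.items():
            val = int(val)
            if val != MISSING and not (0 <= val < k):
                raise PhenotypeError(
                    f"phenotype {val} for {ident!r} outside 0..{k - 1}")
            self._values[ident] = val

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    def get(self, ident: str) -> int:
        return self._values.get(ident, MISSING)

    def __len__(self) -> int:
        return len(self._values)

    def items(self):
        return self._values.items()

    def ids(self) -> list[str]:
        return list(self._values)

    def n_missing(self) -> int:
        return sum(1 for v in self._values.values() if v == MISSING)

    def vector(self, ids: Iterable[str]) -> np.ndarray:
        """Class codes aligned to ``ids`` (MISSING for absent records)."""
        return np.array([self.get(i) for i in ids], dtype=np.int64)

    def restrict(self, ids: Iterable[str]) -> "PhenotypeTable":
        """Keep records for ``ids`` only; everything else becomes MISSING."""
        keep = set(ids)
        return PhenotypeTable(
            {i: v for i, v in self._values.items() if i in keep}, self.labels)

    def counts_by_class(self, ids: Iterable[str] | None = None) -> np.ndarray:
        y = self.vector(ids if ids is not None else self.ids())
        return np.bincount(y[y >= 0], minlength=self.n_classes)

    def attach_check(self, ped) -> None:
        """Raise if any phenotyped id is absent from the pedigree."""
        missing = [i for i in self._values if i not in ped]
        if missing:
            raise PhenotypeError(
                f"{len(missing)} phenotyped ids absent from pedigree "
                f"(first: {missing[0]!r})")


def read_phenotypes(path: str | Path, labels: Sequence[str] = DEFAULT_LABELS,
                    sep: str = "\t") -> PhenotypeTable:
    """Read a TSV with header ``id<TAB>phenotype``; MISSING coded ``NA``."""
    path = Path(path)
    values: dict[str, int] = {}
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)
        pos = {name: i for i, name in enumerate(header)}
        if "id" not in pos or "phenotype" not in pos:
            raise PhenotypeError(f"{path}: header must contain 'id' and 'phenotype'")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split(sep)
            ident = fields[pos["id"]]
            raw = fields[pos["phenotype"]]
            if raw.upper() in ("NA", ""):
                values[ident] = MISSING
            else:
                try:
                    values[ident] = int(raw)
                except ValueError:
                    raise PhenotypeError(
                        f"{path}:{lineno}: bad phenotype {raw!r}") from None
            if ident in values and values[ident] != MISSING and \
                    not (0 <= values[ident] < len(labels)):
                raise PhenotypeError(
                    f"{path}:{lineno}: phenotype {raw!r} outside 0..{len(labels) - 1}")
    return PhenotypeTable(values, labels)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("id\tphenotype\n")
        for ident, val in table.items():
            fh.write(f"{ident}\t{'NA' if val == MISSING else val}\n")
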