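"""Penetrance matrices: P(phenotype class | unordered QTL genotype class).

The matrix has K phenotype rows and three genotype columns (0 = aa,
1 = heterozygote, 2 = AA).  Each genotype column is a conditional
distribution over phenotype classes and must sum to one.  Incomplete
penetrance shows up as off-diagonal mass.

Module constants provide the standard horn-status matrices used for
Merino sheep work: a canonical starting matrix for EM, the three
simulation scenarios of decreasing penetrance, and the literature
estimates for rams, ewes and the pooled sexes.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .phenotypes import DEFAULT_LABELS

COLUMN_SUM_TOL = 1e-6


class PenetranceError(ValueError):
    """Invalid penetrance matrix."""


class PenetranceMatrix:
    """K x 3 matrix of P(phenotype k | genotype class g)."""

    def __init__(self, matrix, labels: Sequence[str] | None = None):
        m = np.asarray(matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 3 or m.shape[0] < 2:
            raise PenetranceError(f"matrix must be K x 3 with K >= 2, got {m.shape}")
        if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
            raise PenetranceError("entries must lie in [0, 1]")
        sums = m.sum(axis=0)
        bad = np.flatnonzero(np.abs(sums - 1.0) > COLUMN_SUM_TOL)
        if bad.size:
            raise PenetranceError(
                "genotype column(s) "
                + ", ".join(f"{g} (sum {sums[g]:.6g})" for g in bad)
                + " do not sum to 1")
        self._m = np.clip(m, 0.0, 1.0)
        self._m.setflags(write=False)
        if labels is None:
            labels = DEFAULT_LABELS if m.shape[0] == 3 else tuple(
                f"class{k}" for k in range(m.shape[0]))
        if len(labels) != m.shape[0]:
            raise PenetranceError("label count does not match matrix rows")
        self.labels = tuple(labels)

    @property
    def entries(self) -> np.ndarray:
        return self._m

    @property
    def n_classes(self) -> int:
        return self._m.shape[0]

    def __getitem__(self, kg) -> float:
        return float(self._m[kg])

    def __eq__(self, other) -> bool:
        return (isinstance(other, PenetranceMatrix)
                and self.labels == other.labels
                and np.array_equal(self._m, other._m))

    def __repr__(self) -> str:
        return f"PenetranceMatrix({self._m.tolist()}, labels={self.labels})"

    def max_abs_diff(self, other: "PenetranceMatrix") -> float:
        return float(np.max(np.abs(self._m - other.entries)))

    def flipped(self) -> "PenetranceMatrix":
        """Swap the allele labels (genotype columns 0 and 2)."""
        return PenetranceMatrix(self._m[:, ::-1], self.labels)

    def soften(self, eps: float = 0.01) -> "PenetranceMatrix":
        """Blend each genotype column with a uniform column.

        Useful for EM starting values: exact zeros in a starting matrix
        are absorbing under the M-step and can make otherwise plausible
        data impossible; a small ``eps`` keeps every phenotype-genotype
        combination admissible while preserving the matrix's orientation.
        """
        k = self.n_classes
        return PenetranceMatrix((1 - eps) * self._m + eps / k, self.labels)

    @classmethod
    def identity(cls, k: int = 3, labels: Sequence[str] | None = None
                 ) -> "PenetranceMatrix":
        """Complete penetrance: phenotype class == genotype class (K = 3)."""
        if k != 3:
            raise PenetranceError("identity penetrance requires K = 3")
        return cls(np.eye(3), labels)


def read_penetrance(path: str | Path) -> PenetranceMatrix:
    """Read ``{"phenotype_labels": [...], "matrix": [[...], ...]}`` JSON."""
    with Path(path).open("r", encoding="utf-8") as fh:
        data = json.load(fh)
    try:
        return PenetranceMatrix(data["matrix"], data.get("phenotype_labels"))
    except KeyError as exc:
        raise PenetranceError(f"{path}: missing key {exc}") from None


def write_penetrance(matrix: PenetranceMatrix, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump({"phenotype_labels": list(matrix.labels),
                   "matrix": matrix.entries.tolist()}, fh, indent=1)
        fh.write("\n")


# Canonical EM starting values for a dominant-with-modifiers horn-type
# trait: polled certain for aa, horned certain for AA, heterozygotes
# mostly scurred.
HORN_START = PenetranceMatrix(
    [[1.00, 0.25, 0.00],
     [0.00, 0.75, 0.00],
     [0.00, 0.00, 1.00]])

# Simulation scenarios of decreasing penetrance used to probe how far the
# expected allele count can track a causal genotype.
SCENARIO_PENETRANCE = {
    1: PenetranceMatrix.identity(),
    2: PenetranceMatrix([[1.00, 0.25, 0.00],
                         [0.00, 0.50, 0.00],
                         [0.00, 0.25, 1.00]]),
    3: PenetranceMatrix([[0.50, 0.25, 0.00],
                         [0.50, 0.50, 0.50],
                         [0.00, 0.25, 0.50]]),
}

# Penetrance estimates reported for Merino horn status (males show almost
# complete penetrance, females express horns in only ~22% of AA animals).
MALE_HORN_PENETRANCE = PenetranceMatrix(
    [[1.00, 0.23, 0.00],
     [0.00, 0.76, 0.00],
     [0.00, 0.01, 1.00]])

# The published female heterozygote column (0.07/0.92/0.02) sums to 1.01
# from rounding; it is renormalised here.
_f = np.array([[1.00, 0.07, 0.00],
               [0.00, 0.92, 0.78],
               [0.00, 0.02, 0.22]])
FEMALE_HORN_PENETRANCE = PenetranceMatrix(_f / _f.sum(axis=0, keepdims=True))
del _f

POOLED_HORN_PENETRANCE = PenetranceMatrix(
    [[1.00, 0.48, 0.00],
     [0.00, 0.52, 0.59],
     [0.00, 0.00, 0.41]])
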