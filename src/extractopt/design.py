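"""Rotatable central composite designs (CCD) and factor coding.

A CCD for k factors combines 2**k factorial corners at coded ±1, 2*k axial
(star) points at coded ±alpha on each axis, and replicated center points at
coded 0.  With alpha = (2**k)**0.25 the design is *rotatable*: the variance
of the fitted second-order prediction depends only on the distance from the
center, so the surface is estimated equally well in every direction.

Factor coding is the affine map ``coded = (real - center) / half_range`` that
sends the low/high factorial levels to -1/+1.  All model fitting downstream
happens on the coded scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorDef",
    "DesignPoint",
    "DesignMatrix",
    "InvalidDesignError",
    "rotatable_alpha",
    "generate_rotatable_ccd",
    "to_coded",
    "to_real",
]

BLOCKS = ("factorial", "axial", "center")


class InvalidDesignError(ValueError):
    """Raised when a requested design is not a valid CCD."""


@dataclass(frozen=True)
class FactorDef:
    """One experimental factor and its real-to-coded axis.

    Parameters
    ----------
    name : str
        Factor label, e.g. ``"temperature"``.
    unit : str
        Physical unit of the real scale (``"°C"``, ``"%"``,
        ``"mL solvent per g solid"`` ...).
    center : float
        Real value at coded 0.
    half_range : float
        Real distance from coded 0 to coded ±1; must be positive.
    """

    name: str
    unit: str
    center: float
    half_range: float

    def __post_init__(self) -> None:
        if not self.half_range > 0:
            raise InvalidDesignError(
                f"factor {self.name!r}: half_range must be > 0, "
                f"got {self.half_range}"
            )

    def to_coded(self, real_level: float) -> float:
        """Map a real level onto the coded scale."""
        return (np.asarray(real_level) - self.center) / self.half_range

    def to_real(self, coded_level: float) -> float:
        """Map a coded level back to real units (inverse of :meth:`to_coded`)."""
        return self.center + np.asarray(coded_level) * self.half_range


def to_coded(factor: FactorDef, real_level: float) -> float:
    """Functional alias for :meth:`FactorDef.to_coded`."""
    return factor.to_coded(real_level)


def to_real(factor: FactorDef, coded_level: float) -> float:
    """Functional alias for :meth:`FactorDef.to_real`."""
    return factor.to_real(coded_level)


def rotatable_alpha(k: int) -> float:
    """Axial distance (2**k)**(1/4) that makes a k-factor CCD rotatable."""
    return (2.0**k) ** 0.25


@dataclass(frozen=True)
class DesignPoint:
    """A single run: its coded and real coordinates and design block."""

    run_id: int
    coded: tuple[float, ...]
    real: tuple[float, ...]
    block: str

    def __post_init__(self) -> None:
        if self.block not in BLOCKS:
            raise InvalidDesignError(f"unknown block {self.block!r}")
        if len(self.coded) != len(self.real):
            raise InvalidDesignError("coded/real dimension mismatch")


@dataclass
class DesignMatrix:
    """An experimental design: factors plus an ordered list of runs."""

    factors: list[FactorDef]
    points: list[DesignPoint]
    alpha: float

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def n_runs(self) -> int:
        return len(self.points)

    @property
    def run_ids(self) -> np.ndarray:
        return np.array([p.run_id for p in self.points])

    @property
    def coded(self) -> np.ndarray:
        """(n_runs, k) array of coded factor levels."""
        return np.array([p.coded for p in self.points], dtype=float)

    @property
    def real(self) -> np.ndarray:
        """(n_runs, k) array of real factor levels."""
        return np.array([p.real for p in self.points], dtype=float)

    @property
    def blocks(self) -> list[str]:
        return [p.block for p in self.points]

    def coded_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-factor (low, high) coded range actually spanned by the runs."""
        c = self.coded
        return c.min(axis=0), c.max(axis=0)

    # ------------------------------------------------------------------ I/O
    def to_frame(self) -> pd.DataFrame:
        """Tabular form: run_id, block, then coded and real columns per factor."""
        data: dict[str, object] = {"run_id": self.run_ids, "block": self.blocks}
        coded = self.coded
        real = self.real
        for j, f in enumerate(self.factors):
            data[f"{f.name}_coded"] = coded[:, j]
            data[f"{f.name}_real"] = real[:, j]
        return pd.DataFrame(data)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_real(
        cls,
        factors: Sequence[FactorDef],
        real_levels: np.ndarray,
        blocks: Sequence[str] | None = None,
        run_ids: Sequence[int] | None = None,
        alpha: float | None = None,
    ) -> "DesignMatrix":
        """Build a design from real run levels, coding them via the factors.

        ``blocks`` defaults to a geometric classification of each coded row:
        all-zero rows are centers, rows with exactly one nonzero coordinate
        are axial, everything else factorial.
        """
        factors = list(factors)
        real_levels = np.atleast_2d(np.asarray(real_levels, dtype=float))
        n, k = real_levels.shape
        if k != len(factors):
            raise InvalidDesignError(
                f"{len(factors)} factors but {k} columns of levels"
            )
        coded = np.column_stack(
            [f.to_coded(real_levels[:, j]) for j, f in enumerate(factors)]
        )
        if run_ids is None:
            run_ids = range(1, n + 1)
        if blocks is None:
            blocks = [_classify(row) for row in coded]
        if alpha is None:
            alpha = rotatable_alpha(k) if k >= 2 else 1.0
        points = [
            DesignPoint(int(r), tuple(c), tuple(x), b)
            for r, c, x, b in zip(run_ids, coded, real_levels, blocks)
        ]
        return cls(factors, points, float(alpha))

    @classmethod
    def read_csv(
        cls, path: str | Path, factors: Sequence[FactorDef]
    ) -> "DesignMatrix":
        """Read a design written by :meth:`write_csv` (real columns are
        authoritative; coded levels are re-derived from the factors)."""
        df = pd.read_csv(path)
        real = np.column_stack([df[f"{f.name}_real"].to_numpy() for f in factors])
        blocks = list(df["block"]) if "block" in df else None
        return cls.from_real(
            factors, real, blocks=blocks, run_ids=df["run_id"].tolist()
        )


def _classify(coded_row: np.ndarray, tol: float = 1e-9) -> str:
    nonzero = np.abs(coded_row) > tol
    if not nonzero.any():
        return "center"
    if nonzero.sum() == 1:
        return "axial"
    return "factorial"


def generate_rotatable_ccd(
    factors: Sequence[FactorDef], n_center: int
) -> DesignMatrix:
    """Construct a rotatable CCD for the given factors.

    Runs come in canonical order: the 2**k factorial corners in binary order
    (last factor cycling fastest, -1 before +1), then for each factor its
    low and high axial point, then the ``n_center`` center replicates.

    Parameters
    ----------
    factors : sequence of FactorDef
        Between 2 and 8 factors.
    n_center : int
        Number of center-point replicates (>= 1); >= 2 are needed later for
        a pure-error estimate.

    Returns
    -------
    DesignMatrix
        ``2**k + 2*k + n_center`` runs with axial distance
        ``alpha = (2**k)**0.25``.
    """
    k = len(factors)
    if not 2 <= k <= 8:
        raise InvalidDesignError(f"CCD requires 2 <= k <= 8 factors, got {k}")
    if n_center < 1:
        raise InvalidDesignError("n_center must be >= 1")
    alpha = rotatable_alpha(k)

    coded_rows: list[tuple[float, ...]] = []
    blocks: list[str] = []
    for corner in itertools.product((-1.0, 1.0), repeat=k):
        coded_rows.append(corner)
        blocks.append("factorial")
    for j in range(k):
        for sign in (-1.0, 1.0):
            row = [0.0] * k
            row[j] = sign * alpha
            coded_rows.append(tuple(row))
            blocks.append("axial")
    for _ in range(n_center):
        coded_rows.append((0.0,) * k)
        blocks.append("center")

    points = []
    for i, (row, block) in enumerate(zip(coded_rows, blocks), start=1):
        real = tuple(f.to_real(c) for f, c in zip(factors, row))
        points.append(DesignPoint(i, row, real, block))
    return DesignMatrix(list(factors), points, alpha)
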