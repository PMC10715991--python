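"""Core containers: wavenumber grids, spectra and spectrum sets.

A :class:`WavenumberGrid` is the shared uniform abscissa of one study; every
:class:`Spectrum` carries a reference to its grid plus provenance metadata
(brand, batch, role, container cup, pairing, timeline position).  A
:class:`SpectrumSet` is an ordered collection of spectra on one grid with
unique sample ids — the unit all pipeline stages consume and produce.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, ValidationError

__all__ = [
    "WavenumberGrid",
    "CANONICAL_GRID",
    "Role",
    "Cup",
    "SpectrumMeta",
    "Spectrum",
    "SpectrumSet",
    "align_sets",
]


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform wavenumber axis: value at index i is ``start + i * step`` (cm^-1)."""

    start: float
    step: float
    n_points: int

    def __post_init__(self) -> None:
        if not self.step > 0:
            raise ValidationError(f"grid step must be > 0, got {self.step}")
        if self.n_points < 2:
            raise ValidationError(f"grid needs at least 2 points, got {self.n_points}")

    @property
    def values(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_points)

    @property
    def stop(self) -> float:
        """Last abscissa value (inclusive)."""
        return self.start + self.step * (self.n_points - 1)

    def __len__(self) -> int:
        return self.n_points


#: The instrument grid used throughout: 4000 cm^-1 upward at 8 cm^-1 steps.
#: The nominal 4000-12500 cm^-1 range does not divide evenly by 8, so the
#: canonical grid keeps the inclusive start and an integer point count,
#: ending at 12496 cm^-1.  Any other uniform grid is equally accepted.
CANONICAL_GRID = WavenumberGrid(start=4000.0, step=8.0, n_points=1063)


class Role(str, enum.Enum):
    PRODUCT = "product"
    STANDARD = "standard"
    EMPTY_PAD = "empty_pad"


class Cup(str, enum.Enum):
    """Sample container cup: the classical Bruker cup or the self-made one."""

    CLASSICAL = "classical"
    SELFMADE = "selfmade"


@dataclass(frozen=True)
class SpectrumMeta:
    """Per-spectrum provenance.

    ``pair_id`` links the two measurements of one sample source taken in the
    two cups; ``date_index`` is the batch's integer position on the
    production timeline.
    """

    sample_id: str
    role: Role = Role.PRODUCT
    cup: Cup = Cup.CLASSICAL
    brand: str | None = None
    batch_id: str | None = None
    pair_id: str | None = None
    date_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "role", Role(self.role))
        object.__setattr__(self, "cup", Cup(self.cup))
        if not self.sample_id:
            raise ValidationError("sample_id must be a non-empty string")
        if self.role in (Role.PRODUCT, Role.STANDARD):
            if not self.brand or not self.batch_id:
                raise ValidationError(
                    f"{self.role.value} spectrum {self.sample_id!r} requires brand and batch_id"
                )


@dataclass(frozen=True)
class Spectrum:
    """One absorbance vector (arbitrary units) on a shared grid."""

    meta: SpectrumMeta
    grid: WavenumberGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.shape[0] != self.grid.n_points:
            raise ValidationError(
                f"spectrum {self.meta.sample_id!r}: expected {self.grid.n_points} values, "
                f"got shape {vals.shape}"
            )
        if not np.all(np.isfinite(vals)):
            raise ValidationError(
                f"spectrum {self.meta.sample_id!r} contains non-finite values"
            )

    def with_values(self, values: np.ndarray) -> "Spectrum":
        return Spectrum(meta=self.meta, grid=self.grid, values=values)

    def with_meta(self, **kwargs) -> "Spectrum":
        return Spectrum(meta=replace(self.meta, **kwargs), grid=self.grid, values=self.values)


@dataclass
class SpectrumSet:
    """Non-empty ordered collection of spectra on one identical grid."""

    grid: WavenumberGrid
    spectra: list[Spectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValidationError("SpectrumSet must contain at least one spectrum")
        seen: set[str] = set()
        for s in self.spectra:
            if s.grid != self.grid:
                raise AlignmentError(
                    f"spectrum {s.meta.sample_id!r} on grid {s.grid}, set grid is {self.grid}"
                )
            if s.meta.sample_id in seen:
                raise ValidationError(f"duplicate sample_id {s.meta.sample_id!r}")
            seen.add(s.meta.sample_id)

    @classmethod
    def from_spectra(cls, spectra: Sequence[Spectrum]) -> "SpectrumSet":
        if not spectra:
            raise ValidationError("cannot build a SpectrumSet from zero spectra")
        return cls(grid=spectra[0].grid, spectra=list(spectra))

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, key: int | str) -> Spectrum:
        if isinstance(key, str):
            for s in self.spectra:
                if s.meta.sample_id == key:
                    return s
            raise KeyError(key)
        return self.spectra[key]

    @property
    def sample_ids(self) -> list[str]:
        return [s.meta.sample_id for s in self.spectra]

    @property
    def values(self) -> np.ndarray:
        """(n_spectra, n_points) matrix of absorbances, row order = set order."""
        return np.vstack([s.values for s in self.spectra])

    def mean_spectrum(self, sample_id: str = "mean") -> Spectrum:
        meta = SpectrumMeta(sample_id=sample_id, role=Role.EMPTY_PAD)
        return Spectrum(meta=meta, grid=self.grid, values=self.values.mean(axis=0))

    def select(
        self,
        *,
        role: Role | str | None = None,
        brand: str | None = None,
        cup: Cup | str | None = None,
        predicate: Callable[[Spectrum], bool] | None = None,
    ) -> "SpectrumSet":
        """Subset by metadata; raises if the selection is empty."""
        role = Role(role) if role is not None else None
        cup = Cup(cup) if cup is not None else None
        picked = [
            s
            for s in self.spectra
            if (role is None or s.meta.role == role)
            and (brand is None or s.meta.brand == brand)
            and (cup is None or s.meta.cup == cup)
            and (predicate is None or predicate(s))
        ]
        if not picked:
            raise ValidationError("selection produced an empty SpectrumSet")
        return SpectrumSet(grid=self.grid, spectra=picked)

    def map_values(self, fn: Callable[[Spectrum], np.ndarray]) -> "SpectrumSet":
        """Apply ``fn`` to each spectrum's values; metadata and order pass through."""
        return SpectrumSet(
            grid=self.grid, spectra=[s.with_values(fn(s)) for s in self.spectra]
        )

    def metadata_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": s.meta.sample_id,
                "brand": s.meta.brand,
                "batch_id": s.meta.batch_id,
                "role": s.meta.role.value,
                "cup": s.meta.cup.value,
                "pair_id": s.meta.pair_id,
                "date_index": s.meta.date_index,
            }
            for s in self.spectra
        ]
        return pd.DataFrame(rows)


def align_sets(sets: Iterable[SpectrumSet]) -> SpectrumSet:
    """Merge sets sharing an identical grid into one; duplicate ids rejected."""
    sets = list(sets)
    if not sets:
        raise ValidationError("align_sets needs at least one set")
    grid = sets[0].grid
    for s in sets[1:]:
        if s.grid != grid:
            raise AlignmentError(f"grid mismatch: {grid} vs {s.grid}")
    merged: list[Spectrum] = []
    for s in sets:
        merged.extend(s.spectra)
    return SpectrumSet(grid=grid, spectra=merged)
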