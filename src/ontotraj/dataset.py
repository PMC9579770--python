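"""Core data containers for landmark datasets.

A landmark configuration is an ordered set of k points in R^3 with a role
label per point: ``fixed`` for anatomical landmarks, ``curve:<id>`` for
semilandmarks on a curve, ``surface:<id>`` for semilandmarks on a surface
patch. A dataset stacks configurations sharing one landmarking scheme and
carries specimen metadata (species, age in days, family).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LandmarkConfiguration", "ShapeDataset", "SchemeError"]


class SchemeError(ValueError):
    """Raised when landmark counts or label sequences are inconsistent."""


def _as_coords(coords) -> np.ndarray:
    arr = np.asarray(coords, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise SchemeError(f"coordinates must be (k, 3), got {arr.shape}")
    return arr


@dataclass
class LandmarkConfiguration:
    """One specimen's k x 3 coordinate block with per-point role labels."""

    coords: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.coords = _as_coords(self.coords)
        if not self.labels:
            self.labels = ["fixed"] * self.k
        if len(self.labels) != self.k:
            raise SchemeError(
                f"{len(self.labels)} labels for {self.k} landmarks"
            )

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    def validate(self) -> None:
        """Check the invariants a valid configuration must satisfy."""
        if self.k < 3:
            raise SchemeError("a configuration needs at least 3 landmarks")
        if not np.all(np.isfinite(self.coords)):
            raise SchemeError("non-finite coordinates")
        d = self.coords[:, None, :] - self.coords[None, :, :]
        dist = np.sqrt((d**2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        i, j = np.unravel_index(np.argmin(dist), dist.shape)
        if dist[i, j] == 0.0:
            raise SchemeError(f"landmarks {i} and {j} coincide exactly")

    def same_scheme(self, other: "LandmarkConfiguration") -> bool:
        return self.k == other.k and self.labels == other.labels


@dataclass
class ShapeDataset:
    """Stacked landmark configurations with specimen metadata.

    Parameters
    ----------
    coords : (n, k, 3) array
        One configuration per specimen, consistent landmark order.
    meta : DataFrame
        One row per specimen; must contain ``species`` and ``age`` (days);
        optional ``family``. Row order matches ``coords``.
    labels : list of str
        Per-landmark role tags shared by all specimens.
    """

    coords: np.ndarray
    meta: pd.DataFrame
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise SchemeError(
                f"coords must be (n, k, 3), got {self.coords.shape}"
            )
        if len(self.meta) != self.n:
            raise SchemeError(
                f"{len(self.meta)} metadata rows for {self.n} specimens"
            )
        for col in ("species", "age"):
            if col not in self.meta.columns:
                raise SchemeError(f"metadata misses required column {col!r}")
        if not self.labels:
            self.labels = ["fixed"] * self.k
        if len(self.labels) != self.k:
            raise SchemeError(
                f"{len(self.labels)} labels for {self.k} landmarks"
            )
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    def config(self, i: int) -> LandmarkConfiguration:
        return LandmarkConfiguration(self.coords[i], list(self.labels))

    def cells(self) -> pd.DataFrame:
        """Species x age cell table with specimen counts."""
        return (
            self.meta.groupby(["species", "age"], observed=True)
            .size()
            .rename("n")
            .reset_index()
        )
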