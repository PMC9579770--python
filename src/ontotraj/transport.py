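"""Parallel transport of per-species ontogenetic trajectories.

Developmental trajectories of different species start from different
shapes; to compare the *changes* along them, each species' sequence of
stage means is moved to a common starting shape — the consensus of the
first-stage (e.g. 7-day) means — using the Euclidean linear-shift
approximation of parallel transport:

1. superimpose the first-stage expected marginal means of all species by
   a generalized Procrustes analysis *without scaling*, giving the common
   reference;
2. apply each species' first-stage superimposition (rotation and
   translation) to all of its stage means;
3. translate every stage of that species by the residual offset so its
   trajectory starts exactly at the reference.

Stepwise differences (growth vectors) are invariant to step 3, and the
within-cell residual of every specimen is carried over untouched, so the
residual covariance of the shape model is preserved exactly.

A second mode, ``opa_per_stage``, superimposes each stage mean
independently onto the reference; the two readings of the procedure are
not operationally identical, and the mode used is recorded in the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dataset import SchemeError
from .geometry import gpa, opa_align
from .shapemodel import ShapeModelFit

__all__ = [
    "CommonReference",
    "TransportResult",
    "common_reference",
    "transport_trajectories",
    "transport_individuals",
]

#: Largest tangent-space norm of a stage mean from the reference below
#: which the Euclidean (linear-shift) approximation is considered safe.
VARIATION_WARN_THRESHOLD = 0.3


@dataclass
class CommonReference:
    """Consensus of the first-stage means plus the per-species alignments."""

    consensus: np.ndarray  # (k, 3)
    aligned: dict  # species -> aligned first-stage mean (k, 3)
    transforms: dict  # species -> RigidTransform onto the consensus


@dataclass
class TransportResult:
    """Transported per-species stage means (and, once individuals are
    transported, per-specimen shapes and updated coefficients)."""

    reference: np.ndarray  # (k, 3) common first-stage consensus
    ages: list
    species: list
    transported_means: dict  # species -> (a, 3k) flattened transported means
    mode: str
    transported_individuals: np.ndarray | None = None  # (n, 3k)
    beta_tr: np.ndarray | None = None
    max_deviation: float = 0.0

    def mean(self, species, age) -> np.ndarray:
        return self.transported_means[species][self.ages.index(age)]

    def means_matrix(self, cells) -> np.ndarray:
        """Stack transported means in the given (species, age) cell order."""
        return np.array([self.mean(s, a) for s, a in cells])


def common_reference(first_stage_means: dict) -> CommonReference:
    """GPA (no scaling) of the per-species first-stage means.

    With a single species the reference is that species' mean (warning).
    """
    species = sorted(first_stage_means)
    shapes = np.array([np.asarray(first_stage_means[s], float) for s in species])
    if shapes.ndim != 3 or shapes.shape[2] != 3:
        raise SchemeError("first-stage means must be (k, 3) configurations")
    if len(species) == 1:
        warnings.warn(
            "single species: the common reference is its own first-stage mean",
            RuntimeWarning,
            stacklevel=2,
        )
        m = shapes[0] - shapes[0].mean(axis=0)
        aligned, tf = opa_align(shapes[0], m)
        return CommonReference(
            consensus=m, aligned={species[0]: aligned}, transforms={species[0]: tf}
        )
    res = gpa(shapes, scaling=False)
    aligned = {}
    transforms = {}
    for j, s in enumerate(species):
        al, tf = opa_align(shapes[j], res.consensus)
        aligned[s] = al
        transforms[s] = tf
    return CommonReference(
        consensus=res.consensus, aligned=aligned, transforms=transforms
    )


def transport_trajectories(
    stage_means: dict,
    ages,
    reference: CommonReference | None = None,
    mode: str = "linear_shift",
) -> TransportResult:
    """Transport every species' ordered stage means to the common start.

    Parameters
    ----------
    stage_means : dict species -> (a, k, 3)
        Stage-mean configurations ordered by age within species.
    ages : sequence of int
        Ages (days) shared by all species, ascending.
    reference : CommonReference, optional
        Precomputed common first-stage reference; built if omitted.
    mode : {"linear_shift", "opa_per_stage"}
        ``linear_shift`` (default) applies the first-stage superimposition
        to all stages then shifts trajectories to share the exact start.
        ``opa_per_stage`` superimposes each stage mean independently.
    """
    ages = list(ages)
    if sorted(ages) != ages:
        raise ValueError("ages must be ascending")
    species = sorted(stage_means)
    shapes = {}
    for s in species:
        arr = np.asarray(stage_means[s], dtype=float)
        if arr.shape[0] != len(ages):
            raise ValueError(
                f"species {s!r} has {arr.shape[0]} stage means for "
                f"{len(ages)} ages"
            )
        shapes[s] = arr
    if mode not in ("linear_shift", "opa_per_stage"):
        raise ValueError(f"unknown transport mode {mode!r}")
    if reference is None:
        reference = common_reference({s: shapes[s][0] for s in species})
    zbar = reference.consensus
    zbar_vec = zbar.ravel()
    transported = {}
    for s in species:
        if mode == "linear_shift":
            tf = reference.transforms.get(s)
            if tf is None:
                _, tf = opa_align(shapes[s][0], zbar)
            moved = np.array([tf.apply(m) for m in shapes[s]])
            shift = zbar_vec - moved[0].ravel()
            transported[s] = moved.reshape(len(ages), -1) + shift
        else:
            rows = []
            for m in shapes[s]:
                al, _ = opa_align(m, zbar)
                rows.append(np.asarray(al).ravel())
            transported[s] = np.array(rows)
    max_dev = max(
        float(np.linalg.norm(transported[s][j] - zbar_vec))
        for s in species
        for j in range(len(ages))
    )
    scale = float(np.linalg.norm(zbar_vec)) or 1.0
    if max_dev / scale > VARIATION_WARN_THRESHOLD:
        warnings.warn(
            f"largest stage-mean deviation from the reference is "
            f"{max_dev / scale:.3f} of its norm (> {VARIATION_WARN_THRESHOLD}); "
            "the Euclidean approximation of parallel transport may be poor",
            RuntimeWarning,
            stacklevel=2,
        )
    return TransportResult(
        reference=zbar,
        ages=ages,
        species=species,
        transported_means=transported,
        mode=mode,
        max_deviation=max_dev / scale,
    )


def transport_individuals(
    fit: ShapeModelFit, transport: TransportResult
) -> TransportResult:
    """Carry every specimen into the transported space.

    Each transported specimen is its transported cell mean plus its
    *original* tangent residual from the shape model, so within-cell
    scatter (and hence the residual covariance) is preserved exactly.
    The coefficients are updated as ``beta_tr = L^-1 zhat_tr``, which
    requires the square (cell-means) contrast matrix.

    Returns the same :class:`TransportResult` with
    ``transported_individuals`` and ``beta_tr`` filled in.
    """
    design = fit.design
    if design is None:
        raise ValueError("fit must carry a DesignSpec (use build_design)")
    L = design.L
    if L.shape[0] != L.shape[1]:
        raise ValueError(
            "contrast matrix L is not square; transported coefficients "
            "beta_tr = L^-1 zhat_tr need cell-means coding"
        )
    zhat_tr = transport.means_matrix(design.cells)
    beta_tr = np.linalg.solve(L, zhat_tr)
    Y_tr = zhat_tr[design.cell_index] + fit.residuals
    transport.transported_individuals = Y_tr
    transport.beta_tr = beta_tr
    return transport
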