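"""Synthetic ontogeny generator with exact, exported ground truth.

Generates landmark datasets with the statistical structure the trajectory
analysis assumes — species-specific piecewise-linear mean trajectories in
tangent space with controllable growth-vector magnitudes and pairwise
angles (both between species at the same interval and between consecutive
intervals within a species), a log-centroid-size allometric component,
i.i.d. Gaussian landmark noise, and per-specimen nuisance rotation /
translation / size — so that every pipeline stage is testable without
external data.

Exactness construction
----------------------
Planted effects are displacement fields of the form ``a (x) e``: every
landmark moves along one fixed spatial direction ``e`` by a per-landmark
scalar ``a_l``, with the scalar field orthogonal to the couplings into
translation, rotation and scale at the base shape (``sum a_l = 0`` and
``sum a_l base_l = 0``). Stage means are placed on the unit-centroid-size
sphere. Under this construction the identity rotation is *exactly*
optimal at every Procrustes step, superimposition is a no-op at zero
noise, and the statistics the pipeline reports have a closed form that
the generator computes and stores as ground truth. Requested step
magnitudes are calibrated by a fixed-point iteration so the *realized*
(tangent-projected) magnitudes equal the requested values.

The built-in base shape is a 40-point 3D toy "mandible" with labelled
pseudo-curves and a surface patch, so the sliding module is exercisable
on synthetic data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import null_space

from .dataset import ShapeDataset
from .sliding import SlidingScheme

__all__ = [
    "OntogenySpec",
    "GroundTruth",
    "InfeasibleAnglesError",
    "base_shape",
    "make_growth_vectors",
    "generate_ground_truth",
    "generate_dataset",
]


class InfeasibleAnglesError(ValueError):
    """Requested angle structure admits no vector realization."""


# Study-like defaults: 3 species x 5 stages, ~6 specimens per cell,
# per-interval step magnitudes chosen so per-day rates and path distances
# match the rodent mandible ontogeny they emulate (mouse front-loaded:
# 0.021/day then 0.002/day; gerbil 0.009 then 0.005; hamster 0.011 then
# 0.006; path distances ~0.26, 0.28 Procrustes units).
_DEFAULT_SPECIES = ("gerbil", "hamster", "mouse")
_DEFAULT_AGES = (7, 14, 35, 63, 100)
_DEFAULT_MAGNITUDES = {
    "gerbil": (0.063, 0.105, 0.056, 0.0333),
    "hamster": (0.077, 0.126, 0.0476, 0.0296),
    "mouse": (0.147, 0.042, 0.042, 0.0296),
}
# Between-species angles at the same interval (degrees).
_DEFAULT_WITHIN_INTERVAL_ANGLES = {
    ("gerbil", "mouse", 0): 37.0,
    ("gerbil", "hamster", 0): 82.30,
    ("hamster", "mouse", 0): 76.39,
    ("gerbil", "hamster", 1): 39.28,
    ("hamster", "mouse", 1): 46.20,
    ("gerbil", "mouse", 1): 45.0,
    ("gerbil", "mouse", 2): 55.0,
    ("gerbil", "hamster", 2): 60.0,
    ("hamster", "mouse", 2): 65.0,
    ("gerbil", "mouse", 3): 60.0,
    ("gerbil", "hamster", 3): 70.0,
    ("hamster", "mouse", 3): 70.0,
}
# Within-species angle between the vectors of interval t-1 and t.
_DEFAULT_CONSECUTIVE_ANGLES = {
    ("mouse", 1): 50.0,
    ("mouse", 2): 50.0,
    ("mouse", 3): 60.0,
    ("gerbil", 1): 70.5,
    ("gerbil", 2): 58.4,
    ("gerbil", 3): 60.0,
    ("hamster", 1): 80.5,
    ("hamster", 2): 39.5,
    ("hamster", 3): 60.0,
}
_DEFAULT_OFFSETS = {"gerbil": 0.12, "hamster": 0.06, "mouse": 0.0}


@dataclass
class OntogenySpec:
    """Design of one synthetic ontogeny study.

    Magnitudes are requested in Procrustes (tangent-space) units per
    interval; angles in degrees. ``log_size_schedule`` gives the log
    centroid size per stage; individual sizes jitter around it with sd
    ``logcs_sd``. ``allometric_slope_magnitude`` adds a shape displacement
    of ``slope * (log CS - schedule)`` per specimen along a dedicated
    direction (zero by default: the planted growth vectors already
    represent the *total* stage-to-stage shape change, allometric part
    included).
    """

    n_fixed: int = 10
    curve_sizes: tuple = (6, 6)
    patch_size: int = 18
    species: tuple = _DEFAULT_SPECIES
    ages: tuple = _DEFAULT_AGES
    n_per_cell: int = 6
    magnitudes: dict = dc_field(default_factory=lambda: dict(_DEFAULT_MAGNITUDES))
    within_interval_angles: dict = dc_field(
        default_factory=lambda: dict(_DEFAULT_WITHIN_INTERVAL_ANGLES)
    )
    consecutive_angles: dict = dc_field(
        default_factory=lambda: dict(_DEFAULT_CONSECUTIVE_ANGLES)
    )
    offset_magnitudes: dict = dc_field(default_factory=lambda: dict(_DEFAULT_OFFSETS))
    allometric_slope_magnitude: float = 0.0
    log_size_schedule: tuple = tuple(np.log((1.0, 1.3, 1.7, 2.0, 2.2)))
    logcs_sd: float = 0.05
    noise_sd: float = 0.003
    rotation_nuisance: bool = True
    translation_range: float = 1.0
    seed: int = 0

    @property
    def k(self) -> int:
        return self.n_fixed + sum(self.curve_sizes) + self.patch_size

    @property
    def n_intervals(self) -> int:
        return len(self.ages) - 1

    def validate(self) -> None:
        if len(self.ages) < 2 or list(self.ages) != sorted(self.ages):
            raise ValueError("ages must be >= 2 values, ascending")
        if len(self.log_size_schedule) != len(self.ages):
            raise ValueError("log_size_schedule must have one value per age")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        T = self.n_intervals
        for s in self.species:
            if s not in self.magnitudes or len(self.magnitudes[s]) != T:
                raise ValueError(f"need {T} magnitudes for species {s!r}")
        for key, a in {
            **self.within_interval_angles,
            **self.consecutive_angles,
        }.items():
            if not 0.0 <= a <= 180.0:
                raise ValueError(f"angle {key} = {a} outside [0, 180]")
        needed = 3 + 3 * (T - 1) + len(self.species) + 1
        if self.k - 4 < needed:
            raise ValueError(
                f"k = {self.k} landmarks give only {self.k - 4} usable "
                f"directions; the requested design needs {needed}"
            )

    def angle(self, s1: str, s2: str, interval: int) -> float:
        key = (s1, s2, interval)
        if key in self.within_interval_angles:
            return self.within_interval_angles[key]
        return self.within_interval_angles[(s2, s1, interval)]


def base_shape(spec: OntogenySpec):
    """Deterministic toy 3D mandible-like base shape.

    Returns (coords, labels, scheme): the (k, 3) centred unit-centroid-
    size configuration, per-landmark role labels, and a SlidingScheme for
    the pseudo-curves and the surface patch.
    """
    fixed = np.array(
        [
            [0.0, 0.0, 0.0],
            [2.0, 0.0, 0.0],
            [2.0, 1.0, 0.0],
            [1.6, 1.2, 0.1],
            [1.2, 0.8, -0.1],
            [0.4, 0.2, 0.1],
            [0.8, 0.1, -0.1],
            [1.0, 0.5, 0.15],
            [1.5, 0.3, 0.1],
            [0.2, 0.6, 0.0],
        ]
    )[: spec.n_fixed]
    if spec.n_fixed > 10:
        extra = spec.n_fixed - 10
        t = np.linspace(0.1, 1.9, extra)
        fixed = np.vstack([fixed, np.column_stack([t, 0.6 + 0.2 * np.sin(3 * t), 0.05 * np.cos(5 * t)])])
    blocks = [fixed]
    labels = ["fixed"] * spec.n_fixed
    curves = {}
    idx = spec.n_fixed
    arcs = [
        lambda t: np.column_stack([1.4 + 0.4 * t, 1.0 + 0.5 * np.sin(np.pi * t), np.full_like(t, 0.05)]),
        lambda t: np.column_stack([0.2 + 1.6 * t, 0.05 + 0.1 * np.sin(np.pi * t), np.full_like(t, -0.05)]),
        lambda t: np.column_stack([0.3 + 1.2 * t, 0.9 - 0.3 * t, 0.12 + 0.05 * np.sin(np.pi * t)]),
    ]
    for c, size in enumerate(spec.curve_sizes):
        t = np.linspace(0.0, 1.0, size)
        pts = arcs[c % len(arcs)](t)
        blocks.append(pts)
        cid = f"c{c}"
        curves[cid] = list(range(idx, idx + size))
        labels += [f"curve:{cid}"] * size
        idx += size
    ncol = max(1, spec.patch_size // 3)
    nrow = int(np.ceil(spec.patch_size / ncol))
    u, v = np.meshgrid(
        np.linspace(0.5, 1.8, ncol), np.linspace(0.2, 0.9, nrow)
    )
    patch = np.column_stack(
        [
            u.ravel(),
            v.ravel(),
            0.2
            - 0.1 * ((u.ravel() - 1.15) / 0.65) ** 2
            - 0.05 * ((v.ravel() - 0.55) / 0.35) ** 2,
        ]
    )[: spec.patch_size]
    blocks.append(patch)
    patches = {"p0": list(range(idx, idx + spec.patch_size))}
    labels += ["surface:p0"] * spec.patch_size
    coords = np.vstack(blocks)
    coords = coords - coords.mean(axis=0)
    coords = coords / np.sqrt((coords**2).sum())
    scheme = SlidingScheme(curves=curves, patches=patches, fixed=list(range(spec.n_fixed)))
    return coords, labels, scheme


class _GrowthBasis:
    """Deterministic orthonormal machinery for planting effects.

    Scalar fields live in the (k-4)-dimensional space orthogonal to the
    translation / rotation / scale couplings of the single-direction
    construction; vectors in shape space are ``a (x) e``.
    """

    def __init__(self, base: np.ndarray, e=(0.0, 0.0, 1.0)):
        self.base = base
        self.k = base.shape[0]
        self.e = np.asarray(e, float)
        self.e = self.e / np.linalg.norm(self.e)
        C = np.vstack([np.ones(self.k), base.T])  # 4 x k constraints
        self.A = null_space(C)  # k x (k - 4), orthonormal columns
        self._used = 0

    def fresh(self, m: int) -> np.ndarray:
        """Next m unused orthonormal scalar-field directions (k x m)."""
        if self._used + m > self.A.shape[1]:
            raise ValueError("scalar-field space exhausted; increase k")
        cols = self.A[:, self._used : self._used + m]
        self._used += m
        return cols

    def field(self, a: np.ndarray) -> np.ndarray:
        """Flattened 3k displacement field a (x) e."""
        return np.outer(a, self.e).ravel()


def _factor_gram(G: np.ndarray, context: str) -> np.ndarray:
    w, V = np.linalg.eigh((G + G.T) / 2.0)
    if w.min() < -1e-8:
        raise InfeasibleAnglesError(
            f"{context}: angle set is not realizable (Gram matrix has "
            f"eigenvalue {w.min():.3e})"
        )
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)  # rows are the factor coordinates


def _plant_directions(spec: OntogenySpec, basis: _GrowthBasis) -> dict:
    """Unit scalar fields per (species, interval) realizing the requested
    angle structure exactly, built interval by interval."""
    sp = list(spec.species)
    T = spec.n_intervals
    # interval 0: mutual species angles only
    G0 = np.eye(len(sp))
    for i, s1 in enumerate(sp):
        for j in range(i + 1, len(sp)):
            G0[i, j] = G0[j, i] = np.cos(np.radians(spec.angle(s1, sp[j], 0)))
    F = _factor_gram(G0, "interval 0")
    cols = basis.fresh(len(sp))
    dirs = {}
    for i, s in enumerate(sp):
        a = cols @ F[i]
        dirs[(s, 0)] = a / np.linalg.norm(a)
    for t in range(1, T):
        prev = {s: dirs[(s, t - 1)] for s in sp}
        beta = {}
        for s in sp:
            b = np.radians(spec.consecutive_angles.get((s, t), 90.0))
            if not 0.0 < b < np.pi:
                raise InfeasibleAnglesError(
                    f"consecutive angle for {s!r} at interval {t} must lie "
                    "strictly between 0 and 180 degrees"
                )
            beta[s] = b
        W = np.eye(len(sp))
        for i, s1 in enumerate(sp):
            for j in range(i + 1, len(sp)):
                s2 = sp[j]
                target = np.cos(np.radians(spec.angle(s1, s2, t)))
                pp = float(prev[s1] @ prev[s2])
                num = target - np.cos(beta[s1]) * np.cos(beta[s2]) * pp
                den = np.sin(beta[s1]) * np.sin(beta[s2])
                w = num / den
                if abs(w) > 1.0 + 1e-9:
                    raise InfeasibleAnglesError(
                        f"interval {t}: angles for the triple "
                        f"({s1!r}, {s2!r}, previous interval) are jointly "
                        f"infeasible (required cosine {w:.3f})"
                    )
                W[i, j] = W[j, i] = np.clip(w, -1.0, 1.0)
        Fw = _factor_gram(W, f"interval {t}")
        cols = basis.fresh(len(sp))
        for i, s in enumerate(sp):
            w_dir = cols @ Fw[i]
            nw = np.linalg.norm(w_dir)
            w_dir = w_dir / nw if nw > 0 else cols[:, i]
            a = np.cos(beta[s]) * prev[s] + np.sin(beta[s]) * w_dir
            dirs[(s, t)] = a / np.linalg.norm(a)
    return dirs


def make_growth_vectors(spec: OntogenySpec):
    """Per-species per-interval growth vectors with exact requested angles
    and magnitudes (in the tangent plane at the base shape).

    Returns ``(vectors, basis)`` where ``vectors`` maps
    ``(species, interval)`` to a flattened 3k displacement field.
    """
    spec.validate()
    base, _, _ = base_shape(spec)
    basis = _GrowthBasis(base)
    dirs = _plant_directions(spec, basis)
    vectors = {
        (s, t): spec.magnitudes[s][t] * basis.field(dirs[(s, t)])
        for s in spec.species
        for t in range(spec.n_intervals)
    }
    return vectors, basis


@dataclass
class GroundTruth:
    """Exact expected pipeline output for a synthetic ontogeny.

    All statistics are the closed-form values the superimposition +
    tangent-projection + transport pipeline converges to at zero noise:
    realized magnitudes equal the requested ones (fixed-point calibrated);
    realized angles may deviate from the requested tangent-plane angles by
    the small curvature effect of the projection (fractions of a degree at
    study-like magnitudes).
    """

    species: list
    ages: list
    magnitudes: dict  # species -> list per interval (realized == requested)
    rates: dict  # species -> list per interval
    path_distances: dict  # species -> float
    within_interval_angles: dict  # "s1|s2|t" -> degrees (realized)
    consecutive_angles: dict  # "s|t" -> degrees (realized)
    growth_vectors: dict  # species -> (T, 3k) realized projected vectors
    stage_means: dict  # species -> (a, k, 3) on-sphere stage mean shapes
    consensus_direction: np.ndarray  # (3k,) unit vector
    noise_sd: float
    seed: int

    def to_json(self, path) -> None:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, dict):
                return {str(k): conv(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            if isinstance(x, (np.floating, np.integer)):
                return float(x)
            return x

        Path(path).write_text(json.dumps(conv(asdict(self)), indent=1))

    def angle(self, s1: str, s2: str, interval: int) -> float:
        for key in (f"{s1}|{s2}|{interval}", f"{s2}|{s1}|{interval}"):
            if key in self.within_interval_angles:
                return self.within_interval_angles[key]
        raise KeyError((s1, s2, interval))


def _stage_tangents(spec, basis, dirs, mags, offsets, slope_field):
    """Tangent-plane position of every species x stage cell mean."""
    T = spec.n_intervals
    logcs = np.asarray(spec.log_size_schedule, float)
    out = {}
    for s in spec.species:
        t_vec = offsets[s].copy()
        rows = [t_vec.copy()]
        for t in range(T):
            t_vec = t_vec + mags[(s, t)] * basis.field(dirs[(s, t)])
            rows.append(t_vec + slope_field * (logcs[t + 1] - logcs[0]))
        # first stage also gets its (zero) allometric term for consistency
        out[s] = np.array(rows)
    return out


def generate_ground_truth(spec: OntogenySpec):
    """Closed-form ground truth for the spec (no specimens generated).

    Returns ``(truth, internals)`` where ``internals`` carries the base
    shape, labels, scheme and the calibrated tangent-plane construction
    used by :func:`generate_dataset`.
    """
    spec.validate()
    base, labels, scheme = base_shape(spec)
    basis = _GrowthBasis(base)
    dirs = _plant_directions(spec, basis)
    offset_cols = basis.fresh(len(spec.species))
    offsets = {
        s: spec.offset_magnitudes.get(s, 0.0)
        * basis.field(offset_cols[:, i] / np.linalg.norm(offset_cols[:, i]))
        for i, s in enumerate(spec.species)
    }
    slope_col = basis.fresh(1)[:, 0]
    slope_field = spec.allometric_slope_magnitude * basis.field(
        slope_col / np.linalg.norm(slope_col)
    )
    c = base.ravel()
    T = spec.n_intervals

    mags = {
        (s, t): float(spec.magnitudes[s][t])
        for s in spec.species
        for t in range(T)
    }
    target = dict(mags)

    def sphere(tv):
        x = c + tv
        return x / np.linalg.norm(x)

    for _ in range(60):
        tangents = _stage_tangents(spec, basis, dirs, mags, offsets, slope_field)
        means = {s: np.array([sphere(tv) for tv in tangents[s]]) for s in spec.species}
        grand = np.mean([m for s in spec.species for m in means[s]], axis=0)
        mhat = grand / np.linalg.norm(grand)
        proj = lambda x: x - (mhat @ x) * mhat
        worst = 0.0
        for s in spec.species:
            for t in range(T):
                g = proj(means[s][t + 1] - means[s][t])
                r = np.linalg.norm(g)
                ratio = target[(s, t)] / r if r > 0 else 1.0
                worst = max(worst, abs(ratio - 1.0))
                mags[(s, t)] *= ratio
        if worst < 1e-13:
            break

    tangents = _stage_tangents(spec, basis, dirs, mags, offsets, slope_field)
    means = {s: np.array([sphere(tv) for tv in tangents[s]]) for s in spec.species}
    grand = np.mean([m for s in spec.species for m in means[s]], axis=0)
    mhat = grand / np.linalg.norm(grand)
    proj = lambda x: x - (mhat @ x) * mhat
    gvecs = {
        s: np.array([proj(means[s][t + 1] - means[s][t]) for t in range(T)])
        for s in spec.species
    }
    days = np.diff(np.asarray(spec.ages, float))
    real_mags = {s: [float(np.linalg.norm(g)) for g in gvecs[s]] for s in spec.species}
    rates = {
        s: [m / d for m, d in zip(real_mags[s], days)] for s in spec.species
    }
    paths = {s: float(np.sum(real_mags[s])) for s in spec.species}

    def ang(u, v):
        cth = np.clip(
            u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1.0, 1.0
        )
        return float(np.degrees(np.arccos(cth)))

    within = {}
    sp = list(spec.species)
    for t in range(T):
        for i, s1 in enumerate(sp):
            for s2 in sp[i + 1 :]:
                within[f"{s1}|{s2}|{t}"] = ang(gvecs[s1][t], gvecs[s2][t])
    consec = {}
    for s in sp:
        for t in range(1, T):
            consec[f"{s}|{t}"] = ang(gvecs[s][t - 1], gvecs[s][t])

    truth = GroundTruth(
        species=sp,
        ages=list(spec.ages),
        magnitudes=real_mags,
        rates=rates,
        path_distances=paths,
        within_interval_angles=within,
        consecutive_angles=consec,
        growth_vectors=gvecs,
        stage_means={s: np.array([m.reshape(-1, 3) for m in means[s]]) for s in sp},
        consensus_direction=mhat,
        noise_sd=spec.noise_sd,
        seed=spec.seed,
    )
    internals = {
        "base": base,
        "labels": labels,
        "scheme": scheme,
        "tangents": tangents,
        "slope_field": slope_field,
        "sphere": sphere,
        "c": c,
    }
    return truth, internals


def generate_dataset(spec: OntogenySpec):
    """Generate a synthetic dataset plus its exact ground truth.

    Specimens are their cell's on-sphere mean shape (plus the individual
    allometric displacement when an allometric slope is requested), with
    i.i.d. Gaussian landmark noise in shape space, scaled to the stage's
    centroid size (log-normal individual jitter), randomly rotated and
    translated. Same seed, byte-identical output.
    """
    truth, internals = generate_ground_truth(spec)
    rng = np.random.default_rng(spec.seed)
    c = internals["c"]
    sphere = internals["sphere"]
    slope_field = internals["slope_field"]
    tangents = internals["tangents"]
    logcs = np.asarray(spec.log_size_schedule, float)
    rows = []
    coords = []
    for s in spec.species:
        for j, age in enumerate(spec.ages):
            for i in range(spec.n_per_cell):
                lcs = logcs[j] + rng.normal(0.0, spec.logcs_sd)
                tv = tangents[s][j]
                if spec.allometric_slope_magnitude != 0.0:
                    # individual allometry: same slope field, individual size
                    tv = tv + slope_field * (lcs - logcs[j])
                x = sphere(tv).reshape(-1, 3).copy()
                x += rng.normal(0.0, spec.noise_sd, x.shape)
                x *= np.exp(lcs)
                if spec.rotation_nuisance:
                    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
                    q *= np.sign(np.diag(r))
                    if np.linalg.det(q) < 0:
                        q[:, -1] *= -1
                    x = x @ q
                if spec.translation_range > 0:
                    x = x + rng.uniform(
                        -spec.translation_range, spec.translation_range, 3
                    )
                coords.append(x)
                rows.append(
                    {
                        "id": f"{s}_{age}d_{i + 1}",
                        "species": s,
                        "age": int(age),
                        "family": i + 1,
                    }
                )
    meta = pd.DataFrame(rows)
    dataset = ShapeDataset(
        coords=np.array(coords), meta=meta, labels=internals["labels"]
    )
    return dataset, truth
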