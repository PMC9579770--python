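"""Semilandmark sliding by bending-energy minimization.

Curve and surface semilandmarks carry no exact point-to-point homology;
they are relaxed along their local tangent directions (one direction for
curve points, a tangent plane for surface points) so that the thin-plate
spline from a reference shape onto each specimen has minimal bending
energy, then back-projected onto the specimen geometry.

The tangent step is the closed-form generalized-least-squares minimizer of
the bending-energy quadratic form over the stacked tangent displacements
(Gunz-style relaxation); by construction the energy after the tangent step
never exceeds the energy before it. Back-projection (onto the specimen
mesh for surface points, onto the piecewise-linear curve otherwise) may
raise the energy again; both values are logged per iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataset import SchemeError, ShapeDataset
from .geometry import gpa, tps_bending_energy

__all__ = [
    "SlidingScheme",
    "SlidingResult",
    "estimate_tangents",
    "slide_semilandmarks",
    "project_to_polyline",
]


@dataclass
class SlidingScheme:
    """Which landmarks slide, and along what.

    ``curves`` maps curve id -> ordered landmark indices composing the
    curve (may include fixed anchor points at the ends; fixed points are
    used as neighbours but never slid). ``patches`` maps patch id -> the
    indices of its surface semilandmarks. ``fixed`` lists indices that are
    never slid.
    """

    curves: dict[str, list[int]] = field(default_factory=dict)
    patches: dict[str, list[int]] = field(default_factory=dict)
    fixed: list[int] = field(default_factory=list)

    def __post_init__(self):
        fixed = set(self.fixed)
        seen: dict[int, str] = {}
        for cid, idx in self.curves.items():
            if len(idx) < 3:
                raise SchemeError(
                    f"curve {cid!r} has {len(idx)} points; needs >= 3"
                )
            for i in idx:
                if i in fixed:
                    continue
                if i in seen:
                    raise SchemeError(
                        f"index {i} appears in both {seen[i]!r} and {cid!r}"
                    )
                seen[i] = cid
        for pid, idx in self.patches.items():
            for i in idx:
                if i in fixed:
                    raise SchemeError(
                        f"index {i} is both fixed and in patch {pid!r}"
                    )
                if i in seen:
                    raise SchemeError(
                        f"index {i} appears in both {seen[i]!r} and {pid!r}"
                    )
                seen[i] = pid

    @property
    def sliding_indices(self) -> list[int]:
        fixed = set(self.fixed)
        out = []
        for idx in self.curves.values():
            out.extend(i for i in idx if i not in fixed)
        for idx in self.patches.values():
            out.extend(i for i in idx if i not in fixed)
        return sorted(set(out))

    def to_table(self, path) -> None:
        """Serialize as a plain-text table: index, role, group id, order."""
        lines = ["index\trole\tgroup\torder"]
        for i in sorted(self.fixed):
            lines.append(f"{i}\tfixed\t-\t-")
        for cid, idx in self.curves.items():
            for order, i in enumerate(idx):
                lines.append(f"{i}\tcurve\t{cid}\t{order}")
        for pid, idx in self.patches.items():
            for order, i in enumerate(idx):
                lines.append(f"{i}\tsurface\t{pid}\t{order}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_table(cls, path) -> "SlidingScheme":
        curves: dict[str, list[tuple[int, int]]] = {}
        patches: dict[str, list[tuple[int, int]]] = {}
        fixed: list[int] = []
        lines = Path(path).read_text().splitlines()
        for ln, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise SchemeError(f"{path}:{ln}: expected 4 tab-separated fields")
            idx, role, group, order = parts
            if role == "fixed":
                fixed.append(int(idx))
            elif role == "curve":
                curves.setdefault(group, []).append((int(order), int(idx)))
            elif role == "surface":
                patches.setdefault(group, []).append((int(order), int(idx)))
            else:
                raise SchemeError(f"{path}:{ln}: unknown role {role!r}")
        return cls(
            curves={c: [i for _, i in sorted(v)] for c, v in curves.items()},
            patches={p: [i for _, i in sorted(v)] for p, v in patches.items()},
            fixed=fixed,
        )


@dataclass
class SlidingResult:
    """Slid coordinates plus the per-iteration bending-energy log.

    ``energy_log`` holds one row per outer iteration per specimen:
    (iteration, specimen, energy before, energy after the tangent step,
    energy after back-projection).
    """

    coords: np.ndarray
    energy_log: list
    iterations: int


def _plane_basis(normal: np.ndarray) -> np.ndarray:
    """Two orthonormal directions spanning the plane orthogonal to normal."""
    n = normal / np.linalg.norm(normal)
    a = np.array([1.0, 0.0, 0.0])
    if abs(n @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    t1 = a - (a @ n) * n
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(n, t1)
    return np.column_stack([t1, t2])


def estimate_tangents(
    config, scheme: SlidingScheme, mesh=None
) -> dict[int, np.ndarray]:
    """Per-semilandmark tangent basis.

    Curve points get one direction (normalized central difference of the
    neighbouring curve points, one-sided at the curve ends). Surface points
    get a 2-column tangent-plane basis: the orthogonal complement of the
    mesh normal at the nearest vertex when a mesh is given, otherwise of
    the normal of the best-fit plane through the 6 nearest patch points.
    """
    coords = np.asarray(
        config.coords if hasattr(config, "coords") else config, dtype=float
    )
    fixed = set(scheme.fixed)
    bases: dict[int, np.ndarray] = {}
    for cid, idx in scheme.curves.items():
        pts = coords[idx]
        for pos, i in enumerate(idx):
            if i in fixed:
                continue
            if pos == 0:
                d = pts[1] - pts[0]
            elif pos == len(idx) - 1:
                d = pts[-1] - pts[-2]
            else:
                d = pts[pos + 1] - pts[pos - 1]
            norm = np.linalg.norm(d)
            if norm == 0:
                raise SchemeError(f"zero tangent at curve {cid!r} index {i}")
            bases[i] = (d / norm)[:, None]
    for pid, idx in scheme.patches.items():
        pts = coords[idx]
        if mesh is not None:
            import trimesh  # optional dependency, mesh back-projection only

            assert isinstance(mesh, trimesh.Trimesh)
            closest = mesh.kdtree.query(coords[idx])[1]
            normals = mesh.vertex_normals[closest]
            for j, i in enumerate(idx):
                bases[i] = _plane_basis(normals[j])
        else:
            for j, i in enumerate(idx):
                d = pts - pts[j]
                order = np.argsort((d**2).sum(axis=1))
                nb = pts[order[: min(7, len(idx))]]  # self + 6 nearest
                nb = nb - nb.mean(axis=0)
                _, _, Vt = np.linalg.svd(nb, full_matrices=False)
                bases[i] = Vt[:2].T  # leading directions span the plane
    return bases


def project_to_polyline(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Nearest point on a piecewise-linear curve, per query point."""
    pts = np.atleast_2d(points)
    a, b = polyline[:-1], polyline[1:]  # segment ends
    ab = b - a
    denom = (ab**2).sum(axis=1)
    denom[denom == 0] = 1.0
    out = np.empty_like(pts)
    for j, p in enumerate(pts):
        t = np.clip(((p - a) * ab).sum(axis=1) / denom, 0.0, 1.0)
        proj = a + t[:, None] * ab
        out[j] = proj[np.argmin(((proj - p) ** 2).sum(axis=1))]
    return out if np.asarray(points).ndim == 2 else out[0]


def _tangent_step(
    y: np.ndarray, Be: np.ndarray, bases: dict[int, np.ndarray]
) -> np.ndarray:
    """Closed-form GLS minimization of bending energy over tangent moves."""
    k = y.shape[0]
    idx = sorted(bases)
    m = sum(bases[i].shape[1] for i in idx)
    U = np.zeros((3 * k, m))
    col = 0
    for i in idx:
        T = bases[i]
        U[3 * i : 3 * i + 3, col : col + T.shape[1]] = T
        col += T.shape[1]
    B3 = np.kron(Be, np.eye(3))
    y0 = y.ravel()
    M = U.T @ B3 @ U
    rhs = -U.T @ B3 @ y0
    try:
        t = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError:
        warnings.warn(
            "singular sliding system; falling back to a small ridge",
            RuntimeWarning,
            stacklevel=2,
        )
        lam = 1e-8 * np.trace(M) / max(M.shape[0], 1)
        t = np.linalg.solve(M + lam * np.eye(M.shape[0]), rhs)
    return (y0 + U @ t).reshape(k, 3)


def slide_semilandmarks(
    dataset,
    scheme: SlidingScheme,
    reference=None,
    meshes=None,
    iterations: int = 3,
    gpa_scaling: bool = True,
    back_project: bool = True,
) -> SlidingResult:
    """Relax semilandmarks by bending-energy minimization.

    Per outer iteration and specimen: estimate tangent directions, solve
    the constrained energy minimization in closed form, then back-project
    the slid points onto the specimen geometry (triangle mesh if given in
    ``meshes``, else the piecewise-linear curve for curve points; surface
    points are left unprojected with a warning when no mesh is available).

    ``reference`` fixes the template whose bending-energy form is
    minimized; by default the GPA consensus of the current coordinates is
    recomputed at each outer iteration.

    ``dataset`` may be a ShapeDataset or an (n, k, 3) array.
    """
    coords = (
        dataset.coords if isinstance(dataset, ShapeDataset) else np.asarray(dataset)
    ).astype(float).copy()
    if coords.ndim != 3:
        raise SchemeError("expected (n, k, 3) coordinates")
    n = coords.shape[0]
    if not scheme.sliding_indices:
        return SlidingResult(coords=coords, energy_log=[], iterations=0)
    has_surface = any(
        i not in set(scheme.fixed) for idx in scheme.patches.values() for i in idx
    )
    if has_surface and meshes is None and back_project:
        warnings.warn(
            "no meshes supplied: surface semilandmarks are slid in their "
            "tangent planes but not back-projected",
            RuntimeWarning,
            stacklevel=2,
        )
    log = []
    for outer in range(1, iterations + 1):
        if reference is not None:
            ref = np.asarray(
                reference.coords if hasattr(reference, "coords") else reference,
                dtype=float,
            )
        else:
            ref = gpa(coords, scaling=gpa_scaling).consensus
        try:
            Be = tps_bending_energy(ref)
        except Exception:
            Be = tps_bending_energy(ref, ridge=1e-8)
        for i in range(n):
            before = float(np.einsum("id,ij,jd->", coords[i], Be, coords[i]))
            original = coords[i].copy()
            slid = _tangent_step(coords[i], Be, estimate_tangents(coords[i], scheme))
            after_slide = float(np.einsum("id,ij,jd->", slid, Be, slid))
            if back_project:
                fixedset = set(scheme.fixed)
                for cid, idx in scheme.curves.items():
                    free = [j for j in idx if j not in fixedset]
                    slid[free] = project_to_polyline(slid[free], original[idx])
                if meshes is not None:
                    mesh = meshes[i] if not hasattr(meshes, "kdtree") else meshes
                    surf = [
                        j
                        for idx in scheme.patches.values()
                        for j in idx
                        if j not in fixedset
                    ]
                    if surf:
                        closest, _, _ = mesh.nearest.on_surface(slid[surf])
                        slid[surf] = closest
            after_proj = float(np.einsum("id,ij,jd->", slid, Be, slid))
            coords[i] = slid
            log.append((outer, i, before, after_slide, after_proj))
    return SlidingResult(coords=coords, energy_log=log, iterations=iterations)
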