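"""End-to-end ontogenetic trajectory analysis.

``run_pipeline`` chains the stages in the canonical order — optional
semilandmark sliding, generalized Procrustes analysis, tangent
projection, PCA, the species x age shape model with RRPP inference, the
allometric model with regression scores, parallel transport to the
youngest common stage, and the growth-vector statistics with sampled
standard errors and permutation tests — and returns one result bundle
with tidy tables plus a provenance record (package and library versions,
seeds, configuration hash) sufficient to reproduce every output exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataset import ShapeDataset
from .geometry import gpa, tangent_to_config
from .shapemodel import (
    build_design,
    fit_shape_model,
    marginal_means,
    rrpp_test,
    allometry_regression_score,
    shape_pca,
    group_variance_summary,
)
from .sliding import SlidingScheme, slide_semilandmarks
from .transport import transport_trajectories, transport_individuals
from .trajectory import (
    growth_vectors,
    interval_contrast,
    vector_angle,
    path_distance,
    sample_uncertainty,
    angle_uncertainty,
    weaning_deflection,
    pairwise_trajectory_tests,
    corrected_magnitude,
    corrected_angle,
    random_angle_null,
    compare_to_axis,
    average_direction,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_outputs",
           "run_study_reproduction"]


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run."""

    scaling: bool = True
    slide: bool = False
    slide_iterations: int = 3
    transport_mode: str = "linear_shift"
    reference_age: int | None = None  # default: youngest common stage
    n_perm: int = 1000
    n_draws: int = 1000
    seed: int = 0
    weaning_intervals: tuple = ((7, 14), (14, 35), (35, 63))
    average_direction_mode: str = "net"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        if cfg.weaning_intervals is not None:
            cfg.weaning_intervals = tuple(tuple(iv) for iv in cfg.weaning_intervals)
        return cfg

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Bundle of every stage output of one pipeline run."""

    procrustes: object
    fit: object
    pca: object
    transported_pca: object
    transport: object
    vectors: list
    growth_table: pd.DataFrame
    path_table: pd.DataFrame
    angle_table: pd.DataFrame
    deflection_table: pd.DataFrame
    axis_table: pd.DataFrame
    direction_table: pd.DataFrame
    pairwise_tests: pd.DataFrame
    model_tests: pd.DataFrame
    variance_table: pd.DataFrame
    allometry: object
    sliding: object | None
    provenance: dict


def _derive_seeds(seed: int, n: int) -> list:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31, size=n)]


def run_pipeline(
    dataset: ShapeDataset,
    config: PipelineConfig | None = None,
    scheme: SlidingScheme | None = None,
    meshes=None,
) -> PipelineResult:
    """Run the full trajectory analysis on a landmark dataset."""
    config = config or PipelineConfig()
    seeds = _derive_seeds(config.seed, 8)
    coords = dataset.coords
    sliding_result = None
    if config.slide:
        if scheme is None:
            raise ValueError("sliding requested but no sliding scheme given")
        sliding_result = slide_semilandmarks(
            dataset,
            scheme,
            meshes=meshes,
            iterations=config.slide_iterations,
            gpa_scaling=config.scaling,
        )
        coords = sliding_result.coords

    proc = gpa(coords, scaling=config.scaling)
    Y = proc.tangent
    n, p = Y.shape

    design = build_design(dataset.meta)
    fit = fit_shape_model(Y, design)
    pca = shape_pca(Y)
    variance_table = group_variance_summary(Y, dataset.meta)

    # model inference: cells vs intercept, and the species x age interaction
    sp = dataset.meta["species"].to_numpy()
    ag = dataset.meta["age"].to_numpy()
    X_int = np.ones((n, 1))
    X_add = np.column_stack(
        [(sp == s).astype(float) for s in design.species_levels]
        + [(ag == a).astype(float) for a in design.age_levels[1:]]
    )
    tests = []
    for name, full, reduced, s in (
        ("species_x_age_cells", design.X, X_int, seeds[0]),
        ("interaction", design.X, X_add, seeds[1]),
    ):
        res = rrpp_test(Y, full, reduced, n_perm=config.n_perm, seed=s)
        row = res.as_frame()
        row.insert(0, "effect", name)
        tests.append(row)
    model_tests = pd.concat(tests, ignore_index=True)

    allom = allometry_regression_score(Y, np.log(proc.centroid_sizes), sp)

    # parallel transport of the marginal-mean trajectories
    zhat = marginal_means(fit)
    ref_age = config.reference_age
    if ref_age is None:
        ref_age = design.age_levels[0]
    ages = list(design.age_levels)
    stage_means = {
        s: np.array(
            [
                tangent_to_config(zhat[design.cell_column(s, a)], proc.consensus)
                for a in ages
            ]
        )
        for s in design.species_levels
    }
    if ref_age != ages[0]:
        order = [ref_age] + [a for a in ages if a != ref_age]
        raise ValueError(
            f"reference age {ref_age} must be the youngest stage {ages[0]} "
            f"(got order {order})"
        )
    transport = transport_trajectories(
        stage_means, ages, mode=config.transport_mode
    )
    transport = transport_individuals(fit, transport)
    Y_tr = transport.transported_individuals
    beta_tr = transport.beta_tr
    tpca = shape_pca(Y_tr)

    vectors = growth_vectors(beta_tr, design, ages)
    by_species = {
        s: [v for v in vectors if v.species == s] for s in design.species_levels
    }

    # per-vector magnitudes, rates and sampled SEs (raw and bias-corrected)
    rows = []
    for j, v in enumerate(vectors):
        dL = interval_contrast(design, v.species, v.age_from, v.age_to)
        unc = sample_uncertainty(
            v.v, fit.Se, fit.XtX_inv, dL, n_draws=config.n_draws,
            seed=seeds[2] + j,
        )
        mag_c = corrected_magnitude(v.v, fit.Se, fit.XtX_inv, dL)
        days = v.age_to - v.age_from
        rows.append(
            {
                "species": v.species,
                "age_from": v.age_from,
                "age_to": v.age_to,
                "magnitude": v.magnitude,
                "rate_per_day": v.rate,
                "magnitude_corrected": mag_c,
                "rate_corrected": mag_c / days,
                "se_magnitude": unc.se_magnitude,
                "se_rate": unc.se_magnitude / days,
                "se_angle": unc.se_angle,
            }
        )
    growth_table = pd.DataFrame(rows)

    # path distances with SEs from joint draws over all intervals
    rows = []
    for j, s in enumerate(design.species_levels):
        dL_all = np.array(
            [
                interval_contrast(design, s, a0, a1)
                for a0, a1 in zip(ages[:-1], ages[1:])
            ]
        )
        unc = sample_uncertainty(
            dL_all @ beta_tr, fit.Se, fit.XtX_inv, dL_all,
            n_draws=config.n_draws, seed=seeds[3] + j,
        )
        path_draws = np.linalg.norm(unc.draws, axis=2).sum(axis=1)
        path_c = float(
            sum(
                corrected_magnitude(
                    v.v,
                    fit.Se,
                    fit.XtX_inv,
                    interval_contrast(design, s, v.age_from, v.age_to),
                )
                for v in by_species[s]
            )
        )
        rows.append(
            {
                "species": s,
                "path_distance": path_distance(by_species[s]),
                "path_corrected": path_c,
                "se_path": float(path_draws.std(ddof=1)),
            }
        )
    path_table = pd.DataFrame(rows)

    # between-species angles per interval, with joint-draw SEs
    rows = []
    pair_id = 0
    for a0, a1 in zip(ages[:-1], ages[1:]):
        for i, s1 in enumerate(design.species_levels):
            for s2 in design.species_levels[i + 1 :]:
                dL_pair = np.array(
                    [
                        interval_contrast(design, s1, a0, a1),
                        interval_contrast(design, s2, a0, a1),
                    ]
                )
                res = angle_uncertainty(
                    fit.Se, fit.XtX_inv, beta_tr, dL_pair,
                    n_draws=config.n_draws, seed=seeds[4] + pair_id,
                )
                pair_id += 1
                V = dL_pair @ beta_tr
                rows.append(
                    {
                        "species_1": s1,
                        "species_2": s2,
                        "age_from": a0,
                        "age_to": a1,
                        "angle": res["angle"],
                        "angle_corrected": corrected_angle(
                            V[0], V[1], dL_pair, fit.Se, fit.XtX_inv
                        ),
                        "se_angle": res["se_angle"],
                        "circular_mean": res["circular_mean"],
                    }
                )
    angle_table = pd.DataFrame(rows)

    # weaning deflection when the canonical intervals are available
    try:
        deflection_table = weaning_deflection(
            beta_tr,
            design,
            fit.Se,
            fit.XtX_inv,
            intervals=config.weaning_intervals,
            n_draws=config.n_draws,
            seed=seeds[5],
        )
    except ValueError:
        deflection_table = pd.DataFrame()

    # average trajectory directions, their angles and the random null
    dirs = {
        s: average_direction(by_species[s], mode=config.average_direction_mode)
        for s in design.species_levels
    }
    dim = int(min(n - design.q, p - 7))
    rows = []
    for i, s1 in enumerate(design.species_levels):
        for s2 in design.species_levels[i + 1 :]:
            ang = vector_angle(dirs[s1], dirs[s2])
            rows.append(
                {
                    "species_1": s1,
                    "species_2": s2,
                    "direction_angle": ang,
                    "p_random": random_angle_null(
                        ang, dim, n_sim=10000, seed=seeds[6]
                    ),
                }
            )
    direction_table = pd.DataFrame(rows)
    if len(direction_table):
        mean_ang = float(direction_table["direction_angle"].mean())
        direction_table["mean_direction_angle"] = mean_ang
        direction_table["p_random_mean"] = random_angle_null(
            mean_ang, dim, n_sim=10000, seed=seeds[6] + 1
        )

    axis_table = compare_to_axis(vectors, tpca.components[0])

    pairwise = pairwise_trajectory_tests(
        Y_tr, dataset.meta, n_perm=config.n_perm, seed=seeds[7], ages=ages
    )

    provenance = {
        "package": "ontotraj",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": asdict(config),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "derived_seeds": seeds,
        "n_specimens": int(n),
        "n_landmarks": int(dataset.k),
        "transport_mode": transport.mode,
    }
    return PipelineResult(
        procrustes=proc,
        fit=fit,
        pca=pca,
        transported_pca=tpca,
        transport=transport,
        vectors=vectors,
        growth_table=growth_table,
        path_table=path_table,
        angle_table=angle_table,
        deflection_table=deflection_table,
        axis_table=axis_table,
        direction_table=direction_table,
        pairwise_tests=pairwise,
        model_tests=model_tests,
        variance_table=variance_table,
        allometry=allom,
        sliding=sliding_result,
        provenance=provenance,
    )


def write_outputs(result: PipelineResult, outdir) -> None:
    """Write the tidy tables (CSV), a JSON trajectory report and the
    provenance record."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "growth_vectors.csv": result.growth_table,
        "path_distances.csv": result.path_table,
        "between_species_angles.csv": result.angle_table,
        "weaning_deflection.csv": result.deflection_table,
        "axis_angles.csv": result.axis_table,
        "average_directions.csv": result.direction_table,
        "pairwise_trajectory_tests.csv": result.pairwise_tests,
        "model_tests.csv": result.model_tests,
        "group_variances.csv": result.variance_table,
    }
    for name, tab in tables.items():
        tab.to_csv(out / name, index=False)
    report = {
        "pc_variance_fractions": result.pca.explained_variance_ratio[:5].tolist(),
        "transported_pc_variance_fractions": result.transported_pca.explained_variance_ratio[:5].tolist(),
        "path_distances": result.path_table.set_index("species")["path_distance"].to_dict(),
        "provenance": result.provenance,
    }
    (out / "report.json").write_text(json.dumps(report, indent=1))


def run_study_reproduction(
    data_dir, config: PipelineConfig | None = None
) -> PipelineResult:
    """Reproduce the rodent mandible ontogeny analysis from a local copy
    of the Dryad deposit (doi:10.5061/dryad.ffbg79cx3).

    Expects ``data_dir`` to contain a ``specimens.csv`` specimen table
    (id, species, age, landmark_path, optional family/mesh_path) whose
    landmark paths point at the deposited per-specimen landmark files in
    any supported dialect. The deposit must be downloaded separately; no
    network access is attempted here.
    """
    from .io import load_dataset

    data_dir = Path(data_dir)
    table = data_dir / "specimens.csv"
    if not table.exists():
        raise FileNotFoundError(
            f"no specimen table at {table}; download the Dryad deposit "
            "(doi:10.5061/dryad.ffbg79cx3) and describe it with a "
            "specimens.csv table first"
        )
    dataset = load_dataset(table)
    return run_pipeline(dataset, config or PipelineConfig())
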