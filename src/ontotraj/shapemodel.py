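"""Multivariate linear shape models on tangent coordinates.

Species x age cell-means models, marginal means, residual-randomization
permutation (RRPP) inference on Procrustes sums of squares, the allometric
model and its regression score, principal component analysis and
group-variance summaries.

Cell-means coding is the default: the design matrix ``X`` has one
indicator column per species x age cell, and the contrast matrix ``L``
selecting the expected marginal means is the identity, hence square and
invertible — a property the parallel-transport step relies on to update
the coefficients as ``beta_tr = L^-1 zhat_tr``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DesignSpec",
    "ShapeModelFit",
    "RRPPResult",
    "AllometryResult",
    "PCAResult",
    "build_design",
    "fit_shape_model",
    "marginal_means",
    "rrpp_test",
    "allometry_regression_score",
    "shape_pca",
    "group_variance_summary",
]


@dataclass
class DesignSpec:
    """Design matrix plus the contrast machinery attached to it."""

    X: np.ndarray
    L: np.ndarray
    cells: list  # (species, age) per design column, deterministic order
    coding: str
    species_levels: list
    age_levels: list
    cell_index: np.ndarray  # per-specimen column index into cells

    @property
    def q(self) -> int:
        return self.X.shape[1]

    def cell_column(self, species, age) -> int:
        try:
            return self.cells.index((species, age))
        except ValueError:
            raise KeyError(f"no design cell for {(species, age)!r}") from None


def build_design(metadata: pd.DataFrame, coding: str = "cell_means") -> DesignSpec:
    """Cell-means design for a species x age layout.

    Column order is deterministic: species sorted alphabetically, ages
    ascending within species. Raises if any species x age cell is empty.
    """
    if coding != "cell_means":
        raise ValueError(f"unsupported coding {coding!r}")
    for col in ("species", "age"):
        if col not in metadata.columns:
            raise KeyError(f"metadata misses column {col!r}")
    species_levels = sorted(metadata["species"].unique())
    age_levels = sorted(metadata["age"].unique())
    cells = [(s, a) for s in species_levels for a in age_levels]
    observed = set(zip(metadata["species"], metadata["age"]))
    missing = [c for c in cells if c not in observed]
    if missing:
        raise ValueError(
            "empty species x age cells: "
            + ", ".join(f"{s}:{a}" for s, a in missing)
        )
    n = len(metadata)
    X = np.zeros((n, len(cells)))
    cell_index = np.empty(n, dtype=int)
    lookup = {c: j for j, c in enumerate(cells)}
    for i, (s, a) in enumerate(zip(metadata["species"], metadata["age"])):
        j = lookup[(s, a)]
        X[i, j] = 1.0
        cell_index[i] = j
    return DesignSpec(
        X=X,
        L=np.eye(len(cells)),
        cells=cells,
        coding=coding,
        species_levels=species_levels,
        age_levels=age_levels,
        cell_index=cell_index,
    )


@dataclass
class ShapeModelFit:
    """Ordinary least squares fit of tangent shape coordinates on X."""

    X: np.ndarray
    beta: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    Se: np.ndarray
    XtX_inv: np.ndarray
    df_resid: int
    design: DesignSpec | None = None


def fit_shape_model(Y: np.ndarray, design) -> ShapeModelFit:
    """Column-wise OLS of the (n, p) tangent matrix on the design.

    ``Se = residuals' residuals / (n - q)`` is the residual covariance
    entering the sampling distribution of contrast estimates.
    """
    X = design.X if isinstance(design, DesignSpec) else np.asarray(design, float)
    Y = np.asarray(Y, dtype=float)
    n, q = X.shape
    if n <= q:
        raise ValueError(f"need n > q, got n={n}, q={q}")
    if np.linalg.matrix_rank(X) < q:
        raise ValueError("rank-deficient design matrix")
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ X.T @ Y
    fitted = X @ beta
    residuals = Y - fitted
    df = n - q
    Se = residuals.T @ residuals / df
    return ShapeModelFit(
        X=X,
        beta=beta,
        fitted=fitted,
        residuals=residuals,
        Se=Se,
        XtX_inv=XtX_inv,
        df_resid=df,
        design=design if isinstance(design, DesignSpec) else None,
    )


def marginal_means(fit: ShapeModelFit, L: np.ndarray | None = None) -> np.ndarray:
    """Expected marginal means ``zhat = L beta``."""
    if L is None:
        L = fit.design.L if fit.design is not None else np.eye(fit.beta.shape[0])
    return np.asarray(L, float) @ fit.beta


@dataclass
class RRPPResult:
    ss_effect: float
    df_effect: int
    ss_resid_full: float
    df_resid_full: int
    f_stat: float
    p_value: float
    n_perm: int
    seed: int | None
    perm_f: np.ndarray = field(repr=False, default=None)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "effect_SS": self.ss_effect,
                    "df": self.df_effect,
                    "residual_SS": self.ss_resid_full,
                    "residual_df": self.df_resid_full,
                    "F": self.f_stat,
                    "p": self.p_value,
                    "n_perm": self.n_perm,
                    "seed": self.seed,
                }
            ]
        )


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X)


def rrpp_test(
    Y: np.ndarray,
    full_design,
    reduced_design,
    n_perm: int = 1000,
    seed: int | None = None,
    exhaustive: bool = False,
) -> RRPPResult:
    """Residual randomization permutation test of nested shape models.

    The observed effect is the drop in residual Procrustes sum of squares
    from the reduced to the full model, summed over all coordinates. The
    null distribution permutes the rows of the *reduced*-model residuals
    with a seeded generator, adds them back to the reduced fitted values
    and recomputes the F-like statistic. The p-value uses the +1 ("the
    observed permutation counts") convention and so is never zero.

    With ``exhaustive=True`` every one of the n! residual permutations is
    evaluated (n <= 8 only) and the p-value is the exact fraction of
    permutations, identity included, with a statistic at least as large.
    """
    Xf = full_design.X if isinstance(full_design, DesignSpec) else np.asarray(full_design, float)
    Xr = reduced_design.X if isinstance(reduced_design, DesignSpec) else np.asarray(reduced_design, float)
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    Hf, Hr = _hat(Xf), _hat(Xr)
    # nestedness: reduced column space must lie inside the full one
    if not np.allclose(Hf @ Xr, Xr, atol=1e-8):
        raise ValueError("reduced design is not nested in the full design")
    rank_f = int(round(np.trace(Hf)))
    rank_r = int(round(np.trace(Hr)))
    df_eff = rank_f - rank_r
    if df_eff <= 0:
        raise ValueError("full and reduced designs have the same column space")
    df_res = n - rank_f
    Rf, Rr = np.eye(n) - Hf, np.eye(n) - Hr

    def f_stat(Ymat):
        rss_f = float(np.einsum("ij,ij->", Rf @ Ymat, Rf @ Ymat))
        rss_r = float(np.einsum("ij,ij->", Rr @ Ymat, Rr @ Ymat))
        ss = rss_r - rss_f
        denom = rss_f / df_res if rss_f > 0 else np.inf
        f = np.inf if denom == 0 else (ss / df_eff) / denom
        return ss, rss_f, f

    ss_obs, rss_f_obs, f_obs = f_stat(Y)
    fitted_r = Hr @ Y
    resid_r = Y - fitted_r
    if exhaustive:
        from itertools import permutations
        from math import factorial

        if n > 8:
            raise ValueError("exhaustive enumeration limited to n <= 8")
        idx_all = np.array(list(permutations(range(n))))
        n_perm = factorial(n)
    else:
        rng = np.random.default_rng(seed)
        idx_all = None
    perm_f = np.empty(n_perm)
    batch = max(1, min(n_perm, int(2e7 // (n * Y.shape[1] + 1))))
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        if exhaustive:
            idx = idx_all[done : done + b]
        else:
            idx = np.array([rng.permutation(n) for _ in range(b)])
        Ystar = fitted_r[None, :, :] + resid_r[idx]
        Ef = np.einsum("ij,bjk->bik", Rf, Ystar)
        Er = np.einsum("ij,bjk->bik", Rr, Ystar)
        rssf = np.einsum("bik,bik->b", Ef, Ef)
        rssr = np.einsum("bik,bik->b", Er, Er)
        with np.errstate(divide="ignore", invalid="ignore"):
            perm_f[done : done + b] = ((rssr - rssf) / df_eff) / (rssf / df_res)
        done += b
    if exhaustive:
        p = np.sum(perm_f >= f_obs - 1e-12) / n_perm
    else:
        p = (np.sum(perm_f >= f_obs) + 1) / (n_perm + 1)
    return RRPPResult(
        ss_effect=ss_obs,
        df_effect=df_eff,
        ss_resid_full=rss_f_obs,
        df_resid_full=df_res,
        f_stat=f_obs,
        p_value=float(p),
        n_perm=n_perm,
        seed=seed,
        perm_f=perm_f,
    )


@dataclass
class AllometryResult:
    """Allometric model output.

    ``scores`` projects the centred tangent rows onto the unit-norm common
    (pooled within-species) allometric slope — the shape variable most
    correlated with log centroid size. ``species_slopes`` are the slopes
    of the species-specific allometric regressions.
    """

    scores: np.ndarray
    common_slope: np.ndarray
    species_slopes: dict
    log_csize: np.ndarray
    species: np.ndarray


def allometry_regression_score(
    Y: np.ndarray, log_csize: np.ndarray, species
) -> AllometryResult:
    """Within-species allometric regression and regression score.

    Fits tangent shape on log centroid size with species-specific
    intercepts and slopes; the regression score is the projection of the
    centred shapes onto the common slope of the pooled within-species
    regression (species intercepts, single slope).
    """
    Y = np.asarray(Y, dtype=float)
    logcs = np.asarray(log_csize, dtype=float)
    sp = np.asarray(species)
    levels = sorted(set(sp.tolist()))
    for s in levels:
        if np.ptp(logcs[sp == s]) == 0:
            raise ValueError(
                f"log centroid size is constant within species {s!r}; "
                "the allometric slope is undefined"
            )
    n = len(Y)
    ind = np.column_stack([(sp == s).astype(float) for s in levels])
    # pooled model: species intercepts + single common slope
    Xc = np.column_stack([ind, logcs])
    beta_c = np.linalg.lstsq(Xc, Y, rcond=None)[0]
    common = beta_c[-1]
    norm = np.linalg.norm(common)
    if norm == 0:
        raise ValueError("zero common allometric slope")
    u = common / norm
    scores = (Y - Y.mean(axis=0)) @ u
    # species-specific slopes
    Xs = np.column_stack([ind, ind * logcs[:, None]])
    beta_s = np.linalg.lstsq(Xs, Y, rcond=None)[0]
    slopes = {s: beta_s[len(levels) + j] for j, s in enumerate(levels)}
    return AllometryResult(
        scores=scores,
        common_slope=common,
        species_slopes=slopes,
        log_csize=logcs,
        species=sp,
    )


@dataclass
class PCAResult:
    scores: np.ndarray
    components: np.ndarray  # one component per row
    explained_variance_ratio: np.ndarray
    mean: np.ndarray


def shape_pca(Y: np.ndarray, n_components: int | None = None) -> PCAResult:
    """PCA of tangent coordinates (centred on the grand mean).

    Deterministic sign convention: the largest-magnitude loading of each
    component is positive. Variance fractions sum to one.
    """
    Y = np.asarray(Y, dtype=float)
    mean = Y.mean(axis=0)
    Yc = Y - mean
    U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    var = s**2
    total = var.sum()
    frac = var / total if total > 0 else var
    ncomp = len(s) if n_components is None else min(n_components, len(s))
    comps = Vt[:ncomp]
    scores = U[:, :ncomp] * s[:ncomp]
    for j in range(ncomp):
        i = np.argmax(np.abs(comps[j]))
        if comps[j, i] < 0:
            comps[j] = -comps[j]
            scores[:, j] = -scores[:, j]
    return PCAResult(
        scores=scores,
        components=comps,
        explained_variance_ratio=frac[:ncomp],
        mean=mean,
    )


def group_variance_summary(Y: np.ndarray, metadata: pd.DataFrame) -> pd.DataFrame:
    """Within-cell tangent variance and per-species ontogenetic variance.

    Within-cell variance is the mean squared tangent distance to the cell
    mean; the ontogenetic variance of a species is the variance of its
    cell means around their own average. Cells with a single specimen are
    excluded with a warning.
    """
    Y = np.asarray(Y, dtype=float)
    metadata = metadata.reset_index(drop=True)
    rows = []
    cell_means = {}
    for (s, a), idx in metadata.groupby(["species", "age"], observed=True).groups.items():
        idx = np.asarray(idx)
        mean = Y[idx].mean(axis=0)
        cell_means[(s, a)] = mean
        if len(idx) < 2:
            warnings.warn(
                f"cell {s}:{a} has a single specimen; within-cell variance "
                "omitted",
                RuntimeWarning,
                stacklevel=2,
            )
            within = np.nan
        else:
            within = float(((Y[idx] - mean) ** 2).sum(axis=1).mean())
        rows.append({"species": s, "age": a, "n": len(idx), "within_variance": within})
    out = pd.DataFrame(rows).sort_values(["species", "age"]).reset_index(drop=True)
    onto = {}
    for s in out["species"].unique():
        means = np.array([cell_means[(s, a)] for a in sorted(out.loc[out.species == s, "age"])])
        onto[s] = float(((means - means.mean(axis=0)) ** 2).sum(axis=1).mean())
    out["ontogenetic_variance"] = out["species"].map(onto)
    return out
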