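"""First-level GLM, contrasts, motion screening and VOI eigenvariate extraction.

The route from voxel data to DCM-ready region series mirrors standard
practice: an ordinary-least-squares GLM with HRF-convolved task regressors,
a faces-greater-than-shapes t-contrast to localise responsive voxels, a
subject-specific peak search constrained to 12 mm around the group peak, and
the first eigenvariate (principal temporal component) of all suprathreshold
voxels within a 6-mm sphere as the region summary time series.  Subjects
whose VOI contains no suprathreshold voxel raise an exclusion signal rather
than yielding an empty series.

Head motion is screened with framewise displacement: the sum of absolute
backward differences of the six realignment parameters, rotations converted
to millimetres on a 50-mm sphere; subjects above a mean FD of 0.5 mm are
flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignMatrix
from .simulate import RegionTimeSeries

__all__ = [
    "GlmFit",
    "VoiExtraction",
    "DesignError",
    "VoiExclusionError",
    "fit_glm",
    "t_contrast",
    "contrast_vector",
    "framewise_displacement",
    "FramewiseDisplacement",
    "extract_voi",
    "extract_subject_regions",
]

MEAN_FD_THRESHOLD_MM = 0.5
ROTATION_RADIUS_MM = 50.0


class DesignError(ValueError):
    """Raised for rank-deficient or mismatched design matrices."""


class VoiExclusionError(RuntimeError):
    """Signals that a subject has no active voxels in a VOI."""

    def __init__(self, subject_id: str, region: str, message: str = ""):
        self.subject_id = subject_id
        self.region = region
        super().__init__(
            message
            or f"no suprathreshold voxels in {region} for {subject_id}; subject excluded"
        )


@dataclass(frozen=True)
class GlmFit:
    """OLS fit of one or many series against a common design."""

    betas: np.ndarray             # (n_regressors,) or (n_regressors, n_series)
    residual_variance: np.ndarray # scalar array or (n_series,)
    degrees_of_freedom: int
    design: DesignMatrix
    xtx_inv: np.ndarray           # pseudoinverse of X'X when rank deficient
    rank: int = 0
    total_variance: np.ndarray = None  # type: ignore[assignment]
    row_space_projector: np.ndarray = None  # type: ignore[assignment]


@dataclass(frozen=True)
class VoiExtraction:
    """First-eigenvariate summary of one subject's VOI."""

    center_offset: np.ndarray
    active_voxel_count: int
    eigenvariate: np.ndarray
    explained_variance_fraction: float


def fit_glm(
    y: np.ndarray, X: DesignMatrix | np.ndarray, allow_deficient: bool = False
) -> GlmFit:
    """Ordinary least squares of ``y`` (one column per series) on the design.

    By default a rank-deficient design raises :class:`DesignError` naming the
    collinear columns.  With ``allow_deficient=True`` estimation proceeds via
    the pseudoinverse (the task design with its three sum-to-zero centered
    valence modulators is deficient by construction); contrasts are then
    checked for estimability in :func:`t_contrast`.
    """
    design = X if isinstance(X, DesignMatrix) else DesignMatrix(
        matrix=np.asarray(X, float),
        column_names=tuple(f"col_{i}" for i in range(np.asarray(X).shape[1])),
    )
    mat = design.matrix
    y = np.asarray(y, dtype=float)
    if y.shape[0] != mat.shape[0]:
        raise DesignError(f"series has {y.shape[0]} rows but design has {mat.shape[0]}")
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1] and not allow_deficient:
        # columns whose R diagonal nearly vanishes are the collinear ones
        _, R = np.linalg.qr(mat)
        diag = np.abs(np.diag(R))
        bad = [design.column_names[i] for i in np.flatnonzero(diag < 1e-8 * diag.max())]
        raise DesignError(f"design is rank deficient; collinear columns: {bad}")

    dof = mat.shape[0] - rank
    if dof <= 0:
        raise DesignError("no residual degrees of freedom")
    pinv = np.linalg.pinv(mat)
    betas = pinv @ y
    resid = y - mat @ betas
    rss = np.sum(resid**2, axis=0)
    return GlmFit(
        betas=betas,
        residual_variance=np.asarray(rss / dof),
        degrees_of_freedom=dof,
        design=design,
        xtx_inv=np.linalg.pinv(mat.T @ mat),
        rank=rank,
        total_variance=np.asarray(y.var(axis=0)),
        row_space_projector=pinv @ mat,
    )


def contrast_vector(design: DesignMatrix, weights: dict[str, float]) -> np.ndarray:
    """Build a contrast vector from named column weights."""
    c = np.zeros(len(design.column_names))
    for name, w in weights.items():
        c[design.column_names.index(name)] = w
    return c


def t_contrast(
    fit: GlmFit, c: np.ndarray, two_sided: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """t statistic(s) and p-value(s) for contrast ``c`` on a GLM fit.

    A noise-free fit (residual variance numerically zero relative to the data
    variance) with a nonzero contrast estimate is reported as t = +/-inf with
    p = 0; a zero estimate with zero variance has no defined statistic and
    raises.  On a rank-deficient design the contrast must be estimable (lie
    in the row space of X).
    """
    c = np.asarray(c, dtype=float)
    if c.shape != (fit.betas.shape[0],):
        raise ValueError(f"contrast length {c.shape} does not match design")
    if not np.any(c):
        raise ValueError("contrast weights are all zero")
    if fit.rank < fit.betas.shape[0]:
        residual_c = c - fit.row_space_projector @ c
        if np.linalg.norm(residual_c) > 1e-8 * np.linalg.norm(c):
            raise DesignError(
                "contrast is not estimable under the rank-deficient design"
            )
    estimate = c @ fit.betas
    var_scale = float(c @ fit.xtx_inv @ c)
    variance = fit.residual_variance * var_scale

    estimate = np.atleast_1d(np.asarray(estimate, float))
    variance = np.atleast_1d(np.asarray(variance, float))
    total = np.atleast_1d(np.asarray(fit.total_variance, float))
    t = np.empty_like(estimate)
    zero_var = variance <= 1e-24 * np.maximum(total, 1e-30) * max(var_scale, 1e-30)
    zero_est = np.abs(estimate) <= 1e-12 * np.sqrt(np.maximum(total, 1e-30))
    if np.any(zero_var & zero_est):
        raise FloatingPointError(
            "contrast variance is zero and the estimate is zero: t undefined"
        )
    t[zero_var] = np.sign(estimate[zero_var]) * np.inf
    t[~zero_var] = estimate[~zero_var] / np.sqrt(variance[~zero_var])
    if two_sided:
        p = 2 * stats.t.sf(np.abs(t), fit.degrees_of_freedom)
    else:
        p = stats.t.sf(t, fit.degrees_of_freedom)
    if t.size == 1:
        return float(t[0]), float(p[0])
    return t, p


@dataclass(frozen=True)
class FramewiseDisplacement:
    fd: np.ndarray
    mean_fd: float
    flagged: bool
    threshold: float = MEAN_FD_THRESHOLD_MM


def framewise_displacement(
    motion: np.ndarray,
    rotation_radius_mm: float = ROTATION_RADIUS_MM,
    threshold: float = MEAN_FD_THRESHOLD_MM,
) -> FramewiseDisplacement:
    """Per-volume framewise displacement and the mean-FD motion flag.

    FD_t sums the absolute volume-to-volume differences of the six
    realignment parameters, rotations (radians) scaled to arc length on a
    sphere of ``rotation_radius_mm``.  FD of the first volume is 0.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must be (n_volumes, 6), got {motion.shape}")
    if motion.shape[0] < 2:
        raise ValueError("need at least two volumes to compute FD")
    deltas = np.abs(np.diff(motion, axis=0))
    deltas[:, 3:] *= rotation_radius_mm
    fd = np.concatenate([[0.0], deltas.sum(axis=1)])
    mean_fd = float(fd.mean())
    return FramewiseDisplacement(fd=fd, mean_fd=mean_fd, flagged=mean_fd > threshold)


def extract_voi(
    voxel_ts: pd.DataFrame,
    design: DesignMatrix,
    contrast: np.ndarray,
    group_peak: np.ndarray | None = None,
    search_radius: float = 12.0,
    voi_radius: float = 6.0,
    threshold_p: float = 0.05,
    subject_id: str = "sub-??",
    region: str = "?",
    two_sided: bool = True,
) -> VoiExtraction:
    """First eigenvariate of the suprathreshold voxels around the subject peak.

    ``voxel_ts`` carries voxel offsets (mm, relative to the group peak) in
    columns ``dx_mm, dy_mm, dz_mm`` and one column per volume.  The subject
    peak is the highest |t| contrast voxel within ``search_radius`` of the
    group peak; the VOI collects voxels within ``voi_radius`` of that peak
    with uncorrected p below ``threshold_p``.  The threshold is two-sided by
    default because regions coupled through net-negative pathways express the
    task as a deactivation; ``two_sided=False`` restores a positive-only
    criterion.  The eigenvariate is the first left singular vector of the
    time-centered VOI matrix, scaled by its singular value over
    sqrt(n_voxels) and sign-aligned to correlate positively with the VOI
    mean series.
    """
    offsets = voxel_ts[["dx_mm", "dy_mm", "dz_mm"]].to_numpy(dtype=float)
    Y = voxel_ts.drop(columns=["dx_mm", "dy_mm", "dz_mm"]).to_numpy(dtype=float).T
    if group_peak is not None:
        offsets = offsets - np.asarray(group_peak, dtype=float)

    fit = fit_glm(Y, design, allow_deficient=True)
    t, p = t_contrast(fit, contrast, two_sided=two_sided)
    t, p = np.atleast_1d(t), np.atleast_1d(p)
    peak_stat = np.abs(t) if two_sided else t

    within_search = np.linalg.norm(offsets, axis=1) <= search_radius + 1e-9
    if not np.any(within_search):
        raise VoiExclusionError(subject_id, region, "no voxels inside the search sphere")
    candidates = np.flatnonzero(within_search)
    peak = candidates[np.argmax(peak_stat[candidates])]
    center = offsets[peak]

    in_voi = np.linalg.norm(offsets - center, axis=1) <= voi_radius + 1e-9
    active = in_voi & (p < threshold_p)
    if not np.any(active):
        raise VoiExclusionError(subject_id, region)

    voi = Y[:, active]
    centered = voi - voi.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    eig = U[:, 0] * S[0] / np.sqrt(voi.shape[1])
    mean_series = centered.mean(axis=1)
    if mean_series @ eig < 0:
        eig = -eig
    total = float(np.sum(S**2))
    return VoiExtraction(
        center_offset=center,
        active_voxel_count=int(active.sum()),
        eigenvariate=eig,
        explained_variance_fraction=float(S[0] ** 2 / total) if total > 0 else 1.0,
    )


def extract_subject_regions(
    voxel_tables: dict[str, pd.DataFrame],
    design: DesignMatrix,
    subject_id: str = "sub-??",
    tr: float = 2.0,
    threshold_p: float = 0.05,
) -> tuple[RegionTimeSeries, dict[str, VoiExtraction]]:
    """Run VOI extraction for all four regions and assemble the DCM series."""
    contrast = contrast_vector(design, {"all_faces": 1.0, "shapes": -1.0})
    extractions: dict[str, VoiExtraction] = {}
    columns = []
    for region, table in voxel_tables.items():
        voi = extract_voi(
            table, design, contrast, subject_id=subject_id, region=region,
            threshold_p=threshold_p,
        )
        extractions[region] = voi
        columns.append(voi.eigenvariate)
    y = np.column_stack(columns)
    return (
        RegionTimeSeries(y=y, tr=tr, region_names=tuple(voxel_tables)),
        extractions,
    )
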