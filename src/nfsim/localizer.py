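"""Functional localizer analysis: smoothing, GLM, contrast t-map, MaxPSC.

The localizer run alternates 16 s blocks of mental drawing, finger
tapping and rest (8 / 8 / 17 blocks). A voxelwise GLM with HRF-convolved
condition regressors plus a centred linear trend yields the
drawing-vs-tapping contrast t-map used for target-region selection, and
the drawing-block percent signal changes yield the participant's MaxPSC
as their 75th percentile (third upper quartile) — deliberately not the
maximum, to leave headroom for fatigue.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import hrf
from .engine import BASELINE_WINDOW_S, IMAGERY_WINDOW_S, window_indices
from .volume import VolumeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "Block",
    "BlockDesign",
    "default_localizer_design",
    "smooth_gaussian",
    "DesignMatrix",
    "build_design_matrix",
    "GLMFit",
    "fit_glm",
    "TMap",
    "contrast_tmap",
    "MaxPSC",
    "compute_max_psc",
    "FWHM_TO_SIGMA",
]

#: FWHM = sigma * sqrt(8 ln 2)
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

CONDITIONS = ("drawing", "tapping", "rest")


@dataclass(frozen=True)
class Block:
    condition: str
    onset_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass
class BlockDesign:
    """Contiguous, non-overlapping localizer blocks."""

    blocks: list[Block]

    def __post_init__(self) -> None:
        t = 0.0
        for b in self.blocks:
            if abs(b.onset_s - t) > 1e-9:
                raise ValueError(
                    f"blocks must be contiguous: expected onset {t}, got {b.onset_s}"
                )
            t = b.onset_s + b.duration_s

    @property
    def total_duration_s(self) -> float:
        if not self.blocks:
            return 0.0
        last = self.blocks[-1]
        return last.onset_s + last.duration_s

    def onsets(self, condition: str) -> list[float]:
        return [b.onset_s for b in self.blocks if b.condition == condition]

    def n_volumes(self, tr_s: float) -> int:
        n = self.total_duration_s / tr_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"design duration {self.total_duration_s}s is not an integer "
                f"number of volumes at TR {tr_s}s"
            )
        return int(round(n))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                [
                    {"condition": b.condition, "onset_s": b.onset_s, "duration_s": b.duration_s}
                    for b in self.blocks
                ],
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "BlockDesign":
        return cls([Block(**b) for b in json.loads(Path(path).read_text())])


def default_localizer_design(block_s: float = 16.0) -> BlockDesign:
    """Alternating rest/drawing/rest/tapping design: 8 + 8 + 17 blocks."""
    blocks = []
    t = 0.0
    tasks = ["drawing", "tapping"] * 8
    for task in tasks:
        blocks.append(Block("rest", t, block_s))
        t += block_s
        blocks.append(Block(task, t, block_s))
        t += block_s
    blocks.append(Block("rest", t, block_s))
    return BlockDesign(blocks)


def smooth_gaussian(series: VolumeSeries, fwhm_mm: float) -> VolumeSeries:
    """Spatially smooth every volume with an isotropic Gaussian kernel.

    The kernel FWHM in millimetres is converted to voxel units via the
    voxel size; FWHM 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if series.voxel_size_mm <= 0:
        raise ValueError("voxel size must be positive")
    if fwhm_mm == 0:
        return VolumeSeries(series.data.copy(), series.voxel_size_mm, series.tr_s)
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / series.voxel_size_mm
    out = ndimage.gaussian_filter(
        series.data, sigma=(sigma_vox, sigma_vox, sigma_vox, 0), mode="nearest"
    )
    return VolumeSeries(out, series.voxel_size_mm, series.tr_s)


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # (n_volumes, n_regressors)
    names: list[str]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]


def build_design_matrix(design: BlockDesign, n_volumes: int, tr_s: float) -> DesignMatrix:
    """HRF-convolved boxcars per task condition + centred linear trend + intercept."""
    if design.total_duration_s > n_volumes * tr_s + 1e-9:
        raise ValueError("design does not fit within the run")
    cols, names = [], []
    for condition in ("drawing", "tapping"):
        onsets = design.onsets(condition)
        if not onsets:
            continue
        durations = {b.duration_s for b in design.blocks if b.condition == condition}
        if len(durations) != 1:
            raise ValueError(f"mixed block durations for {condition}")
        cols.append(hrf.block_regressor(onsets, durations.pop(), n_volumes, tr_s))
        names.append(condition)
    trend = np.arange(n_volumes, dtype=float)
    trend -= trend.mean()
    cols.append(trend)
    names.append("trend")
    cols.append(np.ones(n_volumes))
    names.append("intercept")
    return DesignMatrix(np.column_stack(cols), names)


@dataclass
class GLMFit:
    beta: np.ndarray  # (n_regressors, nx, ny, nz)
    sigma2: np.ndarray  # residual variance per voxel
    df: int
    design: DesignMatrix
    xtx_inv: np.ndarray
    rms: np.ndarray  # root-mean-square signal per voxel, for scale-aware guards


def fit_glm(series: VolumeSeries, X: DesignMatrix) -> GLMFit:
    """Voxelwise ordinary least squares fit of the design matrix."""
    M = X.matrix
    n, p = M.shape
    if n != series.n_volumes:
        raise ValueError("design rows do not match volume count")
    if np.linalg.matrix_rank(M) < p:
        raise ValueError("design matrix is rank deficient")
    Y = series.data.reshape(-1, n).T  # (n_volumes, n_voxels)
    xtx_inv = np.linalg.inv(M.T @ M)
    beta = xtx_inv @ M.T @ Y
    resid = Y - M @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    shape = series.grid_dims
    return GLMFit(
        beta=beta.reshape(p, *shape),
        sigma2=sigma2.reshape(shape),
        df=df,
        design=X,
        xtx_inv=xtx_inv,
        rms=np.sqrt((Y**2).mean(axis=0)).reshape(shape),
    )


@dataclass
class TMap:
    data: np.ndarray  # (nx, ny, nz)
    df: int
    contrast: str

    def save(self, path: str | Path, voxel_size_mm: float) -> None:
        import nibabel as nib

        affine = np.diag([voxel_size_mm] * 3 + [1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), affine), str(path))


def contrast_tmap(
    fit: GLMFit, contrast_weights=None, *, name: str = "drawing-tapping"
) -> TMap:
    """t-statistic map of a contrast of GLM betas.

    Default contrast: drawing - tapping (rest is the implicit baseline).
    Voxels with zero residual variance get a +/-inf sentinel (and 0 where
    the contrast estimate is itself 0); selection downstream requires
    finite t inside its pre-mask.
    """
    names = fit.design.names
    if contrast_weights is None:
        contrast_weights = np.zeros(len(names))
        contrast_weights[names.index("drawing")] = 1.0
        contrast_weights[names.index("tapping")] = -1.0
    c = np.asarray(contrast_weights, dtype=float)
    if c.shape != (len(names),):
        raise ValueError("contrast length does not match design")
    est = np.tensordot(c, fit.beta, axes=1)
    var_scale = float(c @ fit.xtx_inv @ c)
    se = np.sqrt(var_scale * fit.sigma2)
    # residual variance at float rounding level counts as zero
    zero_var = fit.sigma2 <= (1e-9 * fit.rms) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(~zero_var, est / np.where(~zero_var, se, 1.0), np.sign(est) * np.inf)
    t = np.where(zero_var & (np.abs(est) <= 1e-9 * fit.rms), 0.0, t)
    n_inf = int(np.isinf(t).sum())
    if n_inf:
        logger.warning("%d voxels with zero residual variance set to inf t", n_inf)
    return TMap(data=t, df=fit.df, contrast=name)


@dataclass(frozen=True)
class MaxPSC:
    """Per participant x session reference amplitude (percent signal change)."""

    value: float
    participant: int = 0
    session: int = 1

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"max_psc": self.value, "participant": self.participant, "session": self.session}
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "MaxPSC":
        d = json.loads(Path(path).read_text())
        return cls(value=d["max_psc"], participant=d["participant"], session=d["session"])


def drawing_block_pscs(
    series: VolumeSeries, design: BlockDesign, roi_mask: np.ndarray
) -> np.ndarray:
    """Per-drawing-block PSC of the ROI-mean signal.

    Windows mirror the neurofeedback convention: baseline is the mean in
    [-4, +2) s, the active value the mean in [+6, +16) s relative to
    block onset.
    """
    tc = series.roi_timecourse(roi_mask)
    pscs = []
    for onset in design.onsets("drawing"):
        b_idx = window_indices(onset, BASELINE_WINDOW_S, series.tr_s)
        a_idx = window_indices(onset, IMAGERY_WINDOW_S, series.tr_s)
        if b_idx[0] < 0 or a_idx[-1] >= len(tc):
            raise ValueError(f"block at {onset}s: scoring window out of bounds")
        rest_mean = float(tc[b_idx].mean())
        if rest_mean <= 0:
            raise ValueError(f"block at {onset}s: non-positive rest mean {rest_mean}")
        pscs.append(100.0 * (float(tc[a_idx].mean()) - rest_mean) / rest_mean)
    return np.asarray(pscs)


def compute_max_psc(
    series: VolumeSeries,
    design: BlockDesign,
    roi_mask: np.ndarray,
    *,
    quantile: float = 75.0,
    participant: int = 0,
    session: int = 1,
) -> MaxPSC:
    """MaxPSC: the 75th percentile of drawing-block PSC values.

    Linear interpolation between order statistics (h = q/100 * (n-1)).
    """
    pscs = drawing_block_pscs(series, design, roi_mask)
    if len(pscs) < 2:
        raise ValueError("need at least two drawing blocks")
    value = float(np.percentile(pscs, quantile))
    return MaxPSC(value=value, participant=participant, session=session)
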