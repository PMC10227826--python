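"""Intensity-based 2D multimodal registration driven by the NVSA optimizer.

The pipeline maximises normalised mutual information (NMI) between a fixed
image and a warped moving image over the parameters of a similarity (rotation,
isotropic scale, translation) or affine (six-coefficient) transform:

    NMI(M, F) = (H(M) + H(F)) / (2 H(M, F))

with H the Shannon entropy of the joint intensity histogram (equal-width bins
over the nominal [0, 256] range).  NMI is 1 for identical images and tends to
0.5 for independent ones.  RMSE over corresponding pixels is the auxiliary
metric.  Optimisation is performed by negating NMI and minimising.

Conventions: coordinates are 0-based pixel centres with x = column and
y = row; rotation/scale act about the image centre ((W-1)/2, (H-1)/2); the
2x3 matrix returned by :func:`to_matrix` is the output->input sample map used
by inverse-mapping bilinear resampling (out-of-frame samples are filled with
zero and *are* included in the histogram).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage

from .optimizers import (ObjectiveSpec, OptimizerConfig, RunTrace,
                         SearchSpace, optimize)

__all__ = [
    "SimilarityParams", "AffineParams", "RegistrationConfig",
    "RegistrationResult", "normalize_intensity", "to_matrix", "matrix_inverse",
    "matrix_compose", "warp", "nmi", "rmse", "registration_objective",
    "register", "register_runs", "register_ist", "default_bounds",
    "downsample_half", "central_crop",
]

INTENSITY_RANGE = 256.0


# ---------------------------------------------------------------------------
# transform parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimilarityParams:
    """Rotation (degrees), isotropic scale, and pixel translations."""

    theta: float
    scale: float = 1.0
    tx: float = 0.0
    ty: float = 0.0

    def to_vector(self) -> np.ndarray:
        return np.array([self.theta, self.scale, self.tx, self.ty])

    @classmethod
    def from_vector(cls, x) -> "SimilarityParams":
        theta, scale, tx, ty = np.asarray(x, dtype=float)
        return cls(theta=theta, scale=scale, tx=tx, ty=ty)


@dataclass(frozen=True)
class AffineParams:
    """Six coefficients of a 2x3 affine map applied about the image centre."""

    a11: float
    a12: float
    a21: float
    a22: float
    tx: float = 0.0
    ty: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.a11 * self.a22 - self.a12 * self.a21) <= 0.0:
            raise ValueError("affine linear part must be non-singular")

    def to_vector(self) -> np.ndarray:
        return np.array([self.a11, self.a12, self.a21, self.a22,
                         self.tx, self.ty])

    @classmethod
    def from_vector(cls, x) -> "AffineParams":
        a11, a12, a21, a22, tx, ty = np.asarray(x, dtype=float)
        return cls(a11=a11, a12=a12, a21=a21, a22=a22, tx=tx, ty=ty)


def _params_from_vector(x, model: str):
    if model == "similarity":
        return SimilarityParams.from_vector(x)
    if model == "affine":
        return AffineParams.from_vector(x)
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# images and metrics
# ---------------------------------------------------------------------------

def normalize_intensity(img) -> np.ndarray:
    """Affinely rescale intensities so min -> 0 and max -> 256."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or min(img.shape) < 2:
        raise ValueError("expected a 2-D image with H, W >= 2")
    if not np.all(np.isfinite(img)):
        raise ValueError("image intensities must be finite")
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        raise ValueError("constant image: intensity rescale is undefined")
    return (img - lo) * (INTENSITY_RANGE / (hi - lo))


def to_matrix(params, center) -> np.ndarray:
    """2x3 matrix of the point map ``y = A (x - c) + c + t`` on (x, y) coords.

    For similarity parameters ``A = scale * R(theta)`` with R the
    counter-clockwise rotation in xy coordinates.
    """
    cx, cy = float(center[0]), float(center[1])
    if isinstance(params, SimilarityParams):
        th = np.deg2rad(params.theta)
        A = params.scale * np.array([[np.cos(th), -np.sin(th)],
                                     [np.sin(th), np.cos(th)]])
        t = np.array([params.tx, params.ty])
    elif isinstance(params, AffineParams):
        A = np.array([[params.a11, params.a12], [params.a21, params.a22]])
        t = np.array([params.tx, params.ty])
    else:
        raise TypeError(f"unsupported parameter type {type(params)!r}")
    c = np.array([cx, cy])
    b = c + t - A @ c
    return np.hstack([A, b[:, None]])


def matrix_inverse(matrix) -> np.ndarray:
    """Invert a 2x3 point map."""
    matrix = np.asarray(matrix, dtype=float)
    A, b = matrix[:, :2], matrix[:, 2]
    if abs(np.linalg.det(A)) < 1e-15:
        raise np.linalg.LinAlgError("singular transform")
    Ainv = np.linalg.inv(A)
    return np.hstack([Ainv, (-Ainv @ b)[:, None]])


def matrix_compose(m1, m2) -> np.ndarray:
    """Point map ``m1 o m2`` (apply m2 first) as a 2x3 matrix."""
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    A = m1[:, :2] @ m2[:, :2]
    b = m1[:, :2] @ m2[:, 2] + m1[:, 2]
    return np.hstack([A, b[:, None]])


def warp(moving, matrix, out_shape=None, return_mask: bool = False):
    """Inverse-mapping bilinear resample of ``moving`` under a 2x3 point map.

    Each output pixel (x, y) is sampled at ``A @ (x, y) + b`` in the moving
    image; samples outside the frame are zero-filled.  With ``return_mask``
    the boolean in-bounds mask is returned as well.
    """
    moving = np.asarray(moving, dtype=float)
    matrix = np.asarray(matrix, dtype=float)
    if abs(np.linalg.det(matrix[:, :2])) < 1e-15:
        raise np.linalg.LinAlgError("singular transform")
    H, W = out_shape if out_shape is not None else moving.shape
    ys, xs = np.mgrid[0:H, 0:W]
    x_in = matrix[0, 0] * xs + matrix[0, 1] * ys + matrix[0, 2]
    y_in = matrix[1, 0] * xs + matrix[1, 1] * ys + matrix[1, 2]
    out = ndimage.map_coordinates(moving, [y_in, x_in], order=1,
                                  mode="constant", cval=0.0)
    if return_mask:
        h, w = moving.shape
        mask = ((x_in >= 0) & (x_in <= w - 1) & (y_in >= 0) & (y_in <= h - 1))
        return out, mask
    return out


def _entropies(a, b, bins: int):
    counts, _, _ = np.histogram2d(
        np.asarray(a, dtype=float).ravel(), np.asarray(b, dtype=float).ravel(),
        bins=bins, range=[[0.0, INTENSITY_RANGE], [0.0, INTENSITY_RANGE]])
    p = counts / counts.sum()
    pj = p[p > 0]
    h_joint = -float((pj * np.log(pj)).sum())
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)
    pa, pb = pa[pa > 0], pb[pb > 0]
    h_a = -float((pa * np.log(pa)).sum())
    h_b = -float((pb * np.log(pb)).sum())
    return h_a, h_b, h_joint


def nmi(a, b, bins: int = 64) -> float:
    """Normalised mutual information ``(H(a)+H(b)) / (2 H(a,b))``.

    Joint histogram on ``bins x bins`` equal-width bins over [0, 256]; the
    logarithm base cancels in the ratio.  Constant images (zero marginal
    entropy) are rejected.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must have identical shapes")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    h_a, h_b, h_joint = _entropies(a, b, bins)
    if h_a == 0.0 or h_b == 0.0:
        raise ValueError("constant image: NMI is undefined")
    return (h_a + h_b) / (2.0 * h_joint)


def rmse(a, b) -> float:
    """Root mean square pixelwise difference."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must have identical shapes")
    return float(np.sqrt(np.mean((a - b) ** 2)))


# ---------------------------------------------------------------------------
# objective and drivers
# ---------------------------------------------------------------------------

def registration_objective(x, fixed, moving, model: str = "similarity",
                           bins: int = 64, space: SearchSpace | None = None,
                           min_overlap: float = 0.25) -> float:
    """Negated NMI of (fixed, warp(moving, T(x))); the optimizer minimises it.

    If ``space`` is given, an out-of-bounds ``x`` is a precondition error.
    When the warp samples fewer than ``min_overlap`` of its pixels inside the
    moving frame the worst value (0.0, since -NMI < 0 otherwise) is returned,
    which bars the trivial everything-out-of-frame optimum.
    """
    x = np.asarray(x, dtype=float)
    if space is not None and not space.contains(x):
        raise ValueError("parameter vector outside the configured bounds")
    fixed = np.asarray(fixed, dtype=float)
    params = _params_from_vector(x, model)
    H, W = fixed.shape
    center = ((W - 1) / 2.0, (H - 1) / 2.0)
    warped, mask = warp(moving, to_matrix(params, center),
                        out_shape=fixed.shape, return_mask=True)
    if mask.mean() < min_overlap:
        return 0.0
    try:
        return -nmi(fixed, warped, bins=bins)
    except ValueError:
        return 0.0   # constant warp (zero entropy): treat as worst score


def default_bounds(model: str) -> dict:
    """Default per-parameter search intervals.

    Similarity follows the protocol bounds (rotation [0, 360] degrees,
    translation [-30, 30] px) with scale in [0.5, 1.5] -- wide enough to cover
    a CT->MR half-size factor.  Direct affine search gets comparably loose
    coefficient boxes; the two-stage IST pipeline narrows them instead.
    """
    if model == "similarity":
        return {"theta": (0.0, 360.0), "scale": (0.5, 1.5),
                "tx": (-30.0, 30.0), "ty": (-30.0, 30.0)}
    if model == "affine":
        return {"a11": (0.5, 1.5), "a12": (-0.5, 0.5),
                "a21": (-0.5, 0.5), "a22": (0.5, 1.5),
                "tx": (-30.0, 30.0), "ty": (-30.0, 30.0)}
    raise ValueError(f"unknown model {model!r}")


_PARAM_ORDER = {"similarity": ("theta", "scale", "tx", "ty"),
                "affine": ("a11", "a12", "a21", "a22", "tx", "ty")}


def _space_from_bounds(bounds: dict, model: str) -> SearchSpace:
    names = _PARAM_ORDER[model]
    low = np.array([bounds[n][0] for n in names], dtype=float)
    up = np.array([bounds[n][1] for n in names], dtype=float)
    return SearchSpace(low, up)


@dataclass
class RegistrationConfig:
    model: str = "similarity"
    optimizer: OptimizerConfig = field(
        default_factory=lambda: OptimizerConfig(N=30, epochs=100))
    bounds: Optional[dict] = None
    histogram_bins: int = 64
    min_overlap: float = 0.25
    runs: int = 1

    def __post_init__(self) -> None:
        if self.model not in _PARAM_ORDER:
            raise ValueError(f"unknown model {self.model!r}")
        if self.histogram_bins < 2:
            raise ValueError("histogram_bins must be >= 2")


@dataclass
class RegistrationResult:
    params: object
    matrix: np.ndarray
    nmi: float
    rmse: float
    trace: RunTrace
    stage1: "RegistrationResult | None" = None


def register(fixed, moving, config: RegistrationConfig | None = None,
             seed: int | None = None,
             x0: np.ndarray | None = None) -> RegistrationResult:
    """Estimate the transform maximising NMI(fixed, warp(moving)).

    The reported NMI is recomputed from the final transform rather than read
    off the negated optimisation trace.
    """
    if config is None:
        config = RegistrationConfig()
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    bounds = config.bounds if config.bounds is not None \
        else default_bounds(config.model)
    space = _space_from_bounds(bounds, config.model)

    def evaluate(x):
        return registration_objective(
            x, fixed, moving, model=config.model, bins=config.histogram_bins,
            min_overlap=config.min_overlap)

    spec = ObjectiveSpec(evaluate=evaluate, space=space,
                         name=f"nmi-{config.model}")
    opt_cfg = config.optimizer
    if seed is not None:
        opt_cfg = replace(opt_cfg, seed=seed)
    pop, trace = optimize(spec, opt_cfg, x0=x0)

    params = _params_from_vector(pop.best_PV, config.model)
    H, W = fixed.shape
    matrix = to_matrix(params, ((W - 1) / 2.0, (H - 1) / 2.0))
    warped = warp(moving, matrix, out_shape=fixed.shape)
    return RegistrationResult(params=params, matrix=matrix,
                              nmi=nmi(fixed, warped, config.histogram_bins),
                              rmse=rmse(fixed, warped), trace=trace)


def register_runs(fixed, moving, config: RegistrationConfig,
                  seeds) -> list[RegistrationResult]:
    """Independent repeats of :func:`register`, one per seed (the protocol's
    "20 independent runs" mode); aggregate with pandas on the results."""
    return [register(fixed, moving, config, seed=s) for s in seeds]


def register_ist(fixed, moving, config: RegistrationConfig | None = None,
                 delta_linear: float = 0.3, delta_t: float = 15.0,
                 seed: int | None = None) -> RegistrationResult:
    """Two-stage registration with an initial spatial transformation (IST).

    Stage 1 runs the similarity model; stage 2 refines an affine model whose
    coefficient bounds are centred on the stage-1 matrix (+- ``delta_linear``
    on the linear part, +- ``delta_t`` px on translation) and whose initial
    population contains the stage-1 solution.  With ``delta = 0`` the bounds
    degenerate and stage 2 returns the stage-1 transform exactly.
    """
    if config is None:
        config = RegistrationConfig()
    stage1_cfg = replace(config, model="similarity",
                         bounds=config.bounds if config.model == "similarity"
                         else None)
    res1 = register(fixed, moving, stage1_cfg, seed=seed)

    p1 = res1.params
    th = np.deg2rad(p1.theta)
    coeffs = np.array([p1.scale * np.cos(th), -p1.scale * np.sin(th),
                       p1.scale * np.sin(th), p1.scale * np.cos(th),
                       p1.tx, p1.ty])
    delta = np.array([delta_linear] * 4 + [delta_t] * 2, dtype=float)
    names = _PARAM_ORDER["affine"]
    bounds = {n: (coeffs[i] - delta[i], coeffs[i] + delta[i])
              for i, n in enumerate(names)}
    stage2_cfg = replace(config, model="affine", bounds=bounds)
    s2_seed = seed + 1 if seed is not None else None
    res2 = register(fixed, moving, stage2_cfg, seed=s2_seed, x0=coeffs)
    res2.stage1 = res1
    return res2


# ---------------------------------------------------------------------------
# preprocessing helpers (half-size downsample + central crop protocol)
# ---------------------------------------------------------------------------

def downsample_half(img) -> np.ndarray:
    """Bicubic downsample to half size."""
    return ndimage.zoom(np.asarray(img, dtype=float), 0.5, order=3)


def central_crop(img, size: int = 208) -> np.ndarray:
    """Central ``size x size`` crop (removes blank warp margins)."""
    img = np.asarray(img)
    H, W = img.shape
    if H < size or W < size:
        raise ValueError("image smaller than requested crop")
    r0 = (H - size) // 2
    c0 = (W - size) // 2
    return img[r0:r0 + size, c0:c0 + size]
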