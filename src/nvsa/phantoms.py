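"""Seeded synthetic multimodal image pairs with known ground-truth transforms.

A phantom pair emulates a CT/MR-style slice pair: one rendered anatomy (soft-
edged ellipses and rectangles with distinct intensities over a gentle
background ramp) observed under two different monotone-nonlinear intensity
mappings (gamma curves, optionally inverted) so the two images disagree in
intensity while agreeing in structure.  The moving image is additionally
displaced by a known similarity or affine transform and degraded with Gaussian
noise.  Because the ground-truth transform is applied to the anatomy *before*
the moving-side intensity remap, registering moving onto fixed recovers
exactly the ground-truth parameters.

Everything is reproducible from ``PhantomSpec.seed``; rendering uses float64
numpy arithmetic so outputs are platform-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .registration import (AffineParams, SimilarityParams, matrix_compose,
                           matrix_inverse, normalize_intensity, to_matrix,
                           warp)

__all__ = ["PhantomSpec", "make_phantom_pair", "make_tier_pair", "sample_gt",
           "recovery_error", "TIERS"]

TIERS = ("easy", "medium", "hard")

# ground-truth sanity box: the registration defaults the gt must live inside
_THETA_RANGE = (0.0, 360.0)
_T_RANGE = (-30.0, 30.0)
_SCALE_RANGE = (0.5, 1.5)


@dataclass
class PhantomSpec:
    size: tuple = (256, 256)
    n_shapes: int = 6
    gt: object = field(default_factory=lambda: SimilarityParams(theta=0.0))
    modality_fixed: dict = field(
        default_factory=lambda: {"gamma": 1.0, "invert": False})
    modality_moving: dict = field(
        default_factory=lambda: {"gamma": 2.2, "invert": True})
    noise_sigma: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        _check_gt(self.gt)


def _check_gt(gt) -> None:
    if isinstance(gt, SimilarityParams):
        th = gt.theta % 360.0
        ok = (_SCALE_RANGE[0] <= gt.scale <= _SCALE_RANGE[1]
              and _T_RANGE[0] <= gt.tx <= _T_RANGE[1]
              and _T_RANGE[0] <= gt.ty <= _T_RANGE[1]
              and 0.0 <= th <= 360.0)
    elif isinstance(gt, AffineParams):
        ok = (_T_RANGE[0] <= gt.tx <= _T_RANGE[1]
              and _T_RANGE[0] <= gt.ty <= _T_RANGE[1]
              and abs(gt.a11 * gt.a22 - gt.a12 * gt.a21) > 1e-6)
    else:
        raise ValueError(f"unsupported ground-truth type {type(gt)!r}")
    if not ok:
        raise ValueError("ground-truth transform outside the registration "
                         "default bounds")


def _render_base(size, n_shapes: int, rng: np.random.Generator) -> np.ndarray:
    """Anatomy raster: background ramp + head ellipse + n_shapes inner shapes.

    Shape edges are anti-aliased over ~1.5 px so warping and histogramming
    behave like real soft-tissue slices rather than binary masks.
    """
    H, W = size
    ys, xs = np.mgrid[0:H, 0:W].astype(float)
    img = 15.0 + 20.0 * xs / W + 12.0 * ys / H

    def blend(alpha, value):
        return img * (1.0 - alpha) + value * alpha

    def ellipse_alpha(cx, cy, rx, ry, ang):
        ca, sa = np.cos(ang), np.sin(ang)
        xr = (xs - cx) * ca + (ys - cy) * sa
        yr = -(xs - cx) * sa + (ys - cy) * ca
        r = np.sqrt((xr / rx) ** 2 + (yr / ry) ** 2)
        d = (r - 1.0) * min(rx, ry)      # approximate signed distance, px
        return np.clip(0.5 - d / 1.5, 0.0, 1.0)

    def rect_alpha(cx, cy, rx, ry, ang):
        ca, sa = np.cos(ang), np.sin(ang)
        xr = (xs - cx) * ca + (ys - cy) * sa
        yr = -(xs - cx) * sa + (ys - cy) * ca
        d = np.maximum(np.abs(xr) - rx, np.abs(yr) - ry)
        return np.clip(0.5 - d / 1.5, 0.0, 1.0)

    # head outline
    img = blend(ellipse_alpha(0.5 * W, 0.5 * H, 0.40 * W, 0.44 * H,
                              rng.uniform(-0.2, 0.2)), 110.0)

    levels = rng.permutation(np.linspace(60.0, 250.0, n_shapes))
    for i in range(n_shapes):
        cx = rng.uniform(0.30 * W, 0.70 * W)
        cy = rng.uniform(0.30 * H, 0.70 * H)
        rx = rng.uniform(0.05, 0.16) * W
        ry = rng.uniform(0.05, 0.16) * H
        ang = rng.uniform(0.0, np.pi)
        if rng.random() < 0.5:
            alpha = ellipse_alpha(cx, cy, rx, ry, ang)
        else:
            alpha = rect_alpha(cx, cy, rx, ry, ang)
        img = blend(alpha, levels[i])
    return ndimage.gaussian_filter(img, 1.0)


def _remap(img: np.ndarray, gamma: float, invert: bool) -> np.ndarray:
    """Monotone nonlinear intensity mapping on the nominal [0, 256] range."""
    x = np.clip(img, 0.0, 256.0) / 256.0
    out = 256.0 * x ** gamma
    return 256.0 - out if invert else out


def make_phantom_pair(spec: PhantomSpec):
    """Render ``(fixed, moving, gt)``; bit-identical for identical specs.

    fixed  = normalise(remap_fixed(base))
    moving = normalise(remap_moving(base displaced by gt) + noise)
    """
    rng = np.random.default_rng(spec.seed)
    base = _render_base(spec.size, spec.n_shapes, rng)
    H, W = spec.size
    center = ((W - 1) / 2.0, (H - 1) / 2.0)

    fixed = normalize_intensity(_remap(base, **spec.modality_fixed))

    gt_matrix = to_matrix(spec.gt, center)
    moved = warp(base, matrix_inverse(gt_matrix), out_shape=spec.size)
    mov = _remap(moved, **spec.modality_moving)
    if spec.noise_sigma > 0:
        mov = mov + rng.normal(0.0, spec.noise_sigma, size=spec.size)
    moving = normalize_intensity(mov)
    return fixed, moving, spec.gt


def sample_gt(tier: str, rng: np.random.Generator):
    """Draw a ground-truth transform from a named difficulty tier.

    easy:   similarity, |t| <= 15 px, |theta| <= 15 deg, scale = 1
    medium: similarity, |t| <= 20 px, |theta| <= 30 deg, scale in [0.9, 1.1]
    hard:   affine with shear up to 0.1, |t| <= 15 px
    """
    if tier == "easy":
        return SimilarityParams(theta=rng.uniform(-15, 15) % 360.0, scale=1.0,
                                tx=rng.uniform(-15, 15),
                                ty=rng.uniform(-15, 15))
    if tier == "medium":
        return SimilarityParams(theta=rng.uniform(-30, 30) % 360.0,
                                scale=rng.uniform(0.9, 1.1),
                                tx=rng.uniform(-20, 20),
                                ty=rng.uniform(-20, 20))
    if tier == "hard":
        th = np.deg2rad(rng.uniform(-10, 10))
        s = rng.uniform(0.95, 1.05)
        shear = rng.uniform(-0.1, 0.1)
        R = s * np.array([[np.cos(th), -np.sin(th)],
                          [np.sin(th), np.cos(th)]])
        Sh = np.array([[1.0, shear], [0.0, 1.0]])
        A = R @ Sh
        return AffineParams(a11=A[0, 0], a12=A[0, 1], a21=A[1, 0],
                            a22=A[1, 1], tx=rng.uniform(-15, 15),
                            ty=rng.uniform(-15, 15))
    raise ValueError(f"unknown tier {tier!r}; expected one of {TIERS}")


def make_tier_pair(tier: str, seed: int, size=(256, 256), **kwargs):
    """Convenience: sample a tier ground truth and render the pair."""
    gt = sample_gt(tier, np.random.default_rng(seed))
    spec = PhantomSpec(size=size, gt=gt, seed=seed, **kwargs)
    return make_phantom_pair(spec)


def recovery_error(recovered, gt, size):
    """Per-parameter deltas and target registration error of a recovery.

    TRE is the mean Euclidean displacement of the four image corners under
    ``recovered o gt^-1``; exact recovery gives zero everywhere.  Angular
    deltas are wrapped to [0, 180] degrees.
    """
    if type(recovered) is not type(gt):
        raise ValueError("recovered and ground-truth transforms must use "
                         "the same model")
    if isinstance(gt, SimilarityParams):
        d = abs(recovered.theta - gt.theta) % 360.0
        deltas = {"theta": min(d, 360.0 - d),
                  "scale": abs(recovered.scale - gt.scale),
                  "tx": abs(recovered.tx - gt.tx),
                  "ty": abs(recovered.ty - gt.ty)}
    else:
        deltas = {k: abs(getattr(recovered, k) - getattr(gt, k))
                  for k in ("a11", "a12", "a21", "a22", "tx", "ty")}
    H, W = size
    center = ((W - 1) / 2.0, (H - 1) / 2.0)
    C = matrix_compose(to_matrix(recovered, center),
                       matrix_inverse(to_matrix(gt, center)))
    corners = np.array([[0, 0], [W - 1, 0], [0, H - 1], [W - 1, H - 1]],
                       dtype=float)
    mapped = corners @ C[:, :2].T + C[:, 2]
    tre = float(np.mean(np.linalg.norm(mapped - corners, axis=1)))
    return deltas, tre
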