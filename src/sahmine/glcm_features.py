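"""Gray-level cooccurrence matrices (GLCM) and six texture features.

A GLCM for displacement ``(d, theta)`` counts how often two gray levels
co-occur at that pixel offset; its normalized form is the joint
probability of level pairs and carries the image's texture signature.

Counting conventions
--------------------
``unordered`` (default) — each *unordered* adjacent pair {a, b} increments
    M(a, b) and M(b, a) by one when a != b, and M(a, a) by one when
    a == b.  Under this convention one contiguous (1, 1) pair gives
    M(1,1) = 1 and two contiguous (1, 2) pairs give M(1,2) = M(2,1) = 2.
``ordered-symmetric`` — the textbook add-the-transpose matrix (each
    ordered pair and its reverse both counted); provided for
    interoperability with e.g. ``skimage.feature.graycomatrix``.

Both produce symmetric matrices; they differ only in the diagonal's
weight relative to the off-diagonal.

Features (on the normalized matrix p)
-------------------------------------
energy            sum p^2                     uniformity of the texture
contrast          sum (i-j)^2 p               local gray-level variation
entropy           sum -p log2 p               randomness (0 log 0 := 0)
mean              sum i * p_i.                row-marginal mean gray level
local_stability   sum p / (1 + (i-j)^2)       inverse difference moment
correlation       sum (i-mu_i)(j-mu_j) p / (s_i s_j)   linear dependence

Angle offsets in (row, col) with row 0 at top:
0° -> (0, d), 45° -> (-d, d), 90° -> (-d, 0), 135° -> (-d, -d).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

ANGLES = (0, 45, 90, 135)
FEATURE_NAMES = (
    "energy",
    "contrast",
    "entropy",
    "mean",
    "local_stability",
    "correlation",
)


def angle_offset(angle: int, d: int) -> tuple:
    """(row, col) displacement for an angle in degrees and distance d."""
    try:
        dr, dc = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}[angle]
    except KeyError:
        raise ValueError(f"angle must be one of {ANGLES}, got {angle}") from None
    return dr * d, dc * d


@dataclass(frozen=True)
class GLCMParams:
    """Quantization target, displacement, angles, counting convention."""

    levels: int = 16
    distance: int = 1
    angles: Sequence[int] = ANGLES
    counting: str = "unordered"
    degenerate_correlation: str = "zero"  # or "error"

    def __post_init__(self):
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if self.counting not in ("unordered", "ordered-symmetric"):
            raise ValueError("counting must be 'unordered' or 'ordered-symmetric'")
        for a in self.angles:
            angle_offset(a, 1)


@dataclass(frozen=True)
class GLCMatrix:
    """Pair-count matrix for one (d, theta), with its normalized form."""

    counts: np.ndarray
    normalized: Optional[np.ndarray] = None

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class TextureFeatures:
    energy: float
    contrast: float
    entropy: float
    mean: float
    local_stability: float
    correlation: float

    def as_tuple(self) -> tuple:
        return tuple(getattr(self, name) for name in FEATURE_NAMES)


def _as_image(img) -> np.ndarray:
    a = np.asarray(img)
    if a.ndim == 1:
        a = a[np.newaxis, :]
    if a.ndim != 2 or a.size == 0:
        raise ValueError("image must be a non-empty 2-D (or 1-row) array")
    if not np.issubdtype(a.dtype, np.integer):
        if not np.allclose(a, np.round(a)):
            raise ValueError("gray levels must be integers")
        a = np.round(a).astype(np.int64)
    if (a < 0).any():
        raise ValueError("gray levels must be non-negative")
    return a.astype(np.int64)


def quantize_image(img, levels: int) -> np.ndarray:
    """Map gray levels onto [0, levels-1] by uniform binning of the
    occupied range; a constant image maps to level 0.

    For a full-range 8-bit image this is ``floor(v * L / 256)``, so
    ``levels = 256`` is the identity.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    a = _as_image(img)
    vmin, vmax = int(a.min()), int(a.max())
    if vmin == vmax:
        return np.zeros_like(a)
    span = vmax - vmin + 1
    return (a - vmin) * levels // span


def valid_pair_count(shape: tuple, angle: int, d: int) -> int:
    """Number of in-bounds pixel pairs at the (angle, d) offset."""
    rows, cols = shape
    dr, dc = angle_offset(angle, d)
    return max(0, rows - abs(dr)) * max(0, cols - abs(dc))


def compute_glcm(img, params: GLCMParams, angle: int) -> GLCMatrix:
    """Pair-count GLCM of a quantized image for one angle.

    The image must already hold levels in [0, params.levels); the offset
    must fit inside the image.
    """
    a = _as_image(img)
    L = params.levels
    if a.max() >= L:
        raise ValueError(f"image has levels >= {L}; quantize first")
    dr, dc = angle_offset(angle, params.distance)
    if abs(dr) >= a.shape[0] or abs(dc) >= a.shape[1]:
        raise ValueError(
            f"offset {(dr, dc)} exceeds image extent {a.shape} for angle {angle}"
        )
    # source and destination windows of the displacement
    r0, r1 = max(0, -dr), a.shape[0] - max(0, dr)
    c0, c1 = max(0, -dc), a.shape[1] - max(0, dc)
    src = a[r0:r1, c0:c1].ravel()
    dst = a[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
    m = np.zeros((L, L), dtype=np.int64)
    np.add.at(m, (src, dst), 1)
    if params.counting == "unordered":
        neq = src != dst
        np.add.at(m, (dst[neq], src[neq]), 1)
    else:
        np.add.at(m, (dst, src), 1)
    return GLCMatrix(counts=m)


def normalize_glcm(m: GLCMatrix) -> GLCMatrix:
    """Divide counts by their total; errors on an all-zero matrix."""
    total = m.total
    if total <= 0:
        raise ValueError("cannot normalize a GLCM with zero pairs")
    return GLCMatrix(counts=m.counts, normalized=m.counts / total)


def compute_features(
    m,
    degenerate_correlation: str = "zero",
) -> TextureFeatures:
    """The six texture features of a *normalized* GLCM.

    ``m`` is a GLCMatrix with ``normalized`` set, or a probability
    matrix summing to 1.  When either marginal is degenerate
    (sigma_i * sigma_j = 0) the correlation is flagged 0 or raised,
    per ``degenerate_correlation``.
    """
    p = m.normalized if isinstance(m, GLCMatrix) else np.asarray(m, dtype=float)
    if p is None:
        raise ValueError("GLCM is not normalized; call normalize_glcm first")
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("normalized GLCM must be square")
    if (p < 0).any() or abs(float(p.sum()) - 1.0) > 1e-9:
        raise ValueError("input is not a normalized GLCM (must sum to 1)")
    L = p.shape[0]
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    diff2 = (i - j) ** 2

    energy = float((p ** 2).sum())
    contrast = float((diff2 * p).sum())
    nz = p > 0
    logs = np.zeros_like(p)
    logs[nz] = np.log2(p[nz])
    entropy = float(-(p * logs).sum())
    p_i = p.sum(axis=1)
    p_j = p.sum(axis=0)
    mu_i = float((np.arange(L) * p_i).sum())
    mu_j = float((np.arange(L) * p_j).sum())
    local_stability = float((p / (1.0 + diff2)).sum())
    var_i = float(((np.arange(L) - mu_i) ** 2 * p_i).sum())
    var_j = float(((np.arange(L) - mu_j) ** 2 * p_j).sum())
    denom = np.sqrt(var_i) * np.sqrt(var_j)
    if denom <= 0:
        if degenerate_correlation == "error":
            raise ValueError("correlation undefined: degenerate marginals")
        correlation = 0.0
    else:
        correlation = float((((i - mu_i) * (j - mu_j) * p).sum()) / denom)
    return TextureFeatures(
        energy=energy,
        contrast=contrast,
        entropy=entropy,
        mean=mu_i,
        local_stability=local_stability,
        correlation=correlation,
    )


def preprocess_image(
    img,
    center_crop: Optional[int] = None,
    median_size: Optional[int] = None,
) -> np.ndarray:
    """Optional square center-crop and median-filter denoising hooks."""
    a = _as_image(img)
    if center_crop is not None:
        side = min(center_crop, *a.shape)
        r0 = (a.shape[0] - side) // 2
        c0 = (a.shape[1] - side) // 2
        a = a[r0:r0 + side, c0:c0 + side]
    if median_size is not None and median_size > 1:
        a = ndimage.median_filter(a, size=median_size)
    return a


def extract_image_features(img, params: GLCMParams) -> TextureFeatures:
    """Quantize, build one GLCM per requested angle, normalize, compute
    features, and average them arithmetically across angles — a
    rotation-robust texture summary of one image."""
    q = quantize_image(img, params.levels)
    per_angle = []
    for angle in params.angles:
        m = normalize_glcm(compute_glcm(q, params, angle))
        per_angle.append(
            compute_features(m, params.degenerate_correlation).as_tuple()
        )
    means = np.mean(np.asarray(per_angle), axis=0)
    return TextureFeatures(*map(float, means))


def load_gray_image(path) -> np.ndarray:
    """Read a grayscale image (PGM/PNG/...) or a whitespace-delimited
    numeric matrix file into an integer gray-level array."""
    path = Path(path)
    if path.suffix.lower() in (".txt", ".dat", ".mat", ".csv"):
        delim = "," if path.suffix.lower() == ".csv" else None
        return _as_image(np.loadtxt(path, delimiter=delim))
    import imageio.v3 as iio

    a = np.asarray(iio.imread(path))
    if a.ndim == 3:  # collapse RGB(A) channels by simple mean
        a = np.round(a[..., :3].mean(axis=2))
    return _as_image(a)
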