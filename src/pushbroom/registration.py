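"""Homography estimation and projective warping for HSI/video overlay.

The laparoscope registers the false-color image computed from hyperspectral
data onto the simultaneously acquired color-video frame with a one-time
homography, estimated from manually annotated point correspondences.  The
warp convention is

    D(x, y) = S( (H11 x + H12 y + H13) / (H31 x + H32 y + H33),
                 (H21 x + H22 y + H23) / (H31 x + H32 y + H33) )

i.e. the destination image at (x, y) samples the source at the projective
image of (x, y); :func:`estimate_homography` returns the matrix mapping
*source points to destination points*, so pass its inverse to
:func:`warp_image` to place the source image into the destination frame.

Estimation is RANSAC over 4-point minimal samples with a final refit on all
inliers by the Hartley-normalized direct linear transform (DLT).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import EstimationError

__all__ = [
    "Homography",
    "CorrespondenceSet",
    "estimate_homography",
    "warp_image",
    "overlay",
    "read_correspondences_csv",
    "write_correspondences_csv",
]

_DET_EPS = 1e-12


@dataclass(frozen=True)
class Homography:
    """3x3 projective transform, normalized so H33 = 1."""

    H: np.ndarray

    def __post_init__(self):
        H = np.asarray(self.H, dtype=float)
        if H.shape != (3, 3):
            raise ValueError("homography must be 3x3")
        if abs(np.linalg.det(H)) <= _DET_EPS:
            raise ValueError("homography is singular")
        if abs(H[2, 2]) > _DET_EPS:
            H = H / H[2, 2]
        object.__setattr__(self, "H", H)

    @property
    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.H))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 2) points (x, y) through the transform."""
        pts = np.asarray(points, dtype=float)
        ones = np.ones((pts.shape[0], 1))
        hom = np.hstack([pts, ones]) @ self.H.T
        return hom[:, :2] / hom[:, 2:3]

    def to_text(self) -> str:
        return "\n".join(" ".join(repr(float(v)) for v in row) for row in self.H) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "Homography":
        rows = [[float(v) for v in line.split()] for line in text.splitlines() if line.strip()]
        return cls(np.array(rows))

    @classmethod
    def identity(cls) -> "Homography":
        return cls(np.eye(3))


@dataclass(frozen=True)
class CorrespondenceSet:
    """Paired (source, destination) pixel coordinates, shape (n, 2) each."""

    source: np.ndarray
    destination: np.ndarray

    def __post_init__(self):
        src = np.atleast_2d(np.asarray(self.source, dtype=float))
        dst = np.atleast_2d(np.asarray(self.destination, dtype=float))
        if src.shape != dst.shape or src.shape[1] != 2:
            raise ValueError("source/destination must both be (n, 2)")
        if not (np.isfinite(src).all() and np.isfinite(dst).all()):
            raise ValueError("correspondences must be finite")
        object.__setattr__(self, "source", src)
        object.__setattr__(self, "destination", dst)

    def __len__(self) -> int:
        return self.source.shape[0]


def _normalize(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hartley normalization: centroid at origin, mean distance sqrt(2)."""
    centroid = points.mean(axis=0)
    dist = np.linalg.norm(points - centroid, axis=1).mean()
    scale = np.sqrt(2.0) / max(dist, 1e-12)
    T = np.array(
        [[scale, 0.0, -scale * centroid[0]],
         [0.0, scale, -scale * centroid[1]],
         [0.0, 0.0, 1.0]]
    )
    ones = np.ones((points.shape[0], 1))
    normed = (np.hstack([points, ones]) @ T.T)[:, :2]
    return normed, T


def _dlt(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Direct linear transform on Hartley-normalized points; returns 3x3."""
    src_n, T_src = _normalize(src)
    dst_n, T_dst = _normalize(dst)
    n = src.shape[0]
    A = np.zeros((2 * n, 9))
    x, y = src_n[:, 0], src_n[:, 1]
    u, v = dst_n[:, 0], dst_n[:, 1]
    A[0::2, 0], A[0::2, 1], A[0::2, 2] = x, y, 1.0
    A[0::2, 6], A[0::2, 7], A[0::2, 8] = -u * x, -u * y, -u
    A[1::2, 3], A[1::2, 4], A[1::2, 5] = x, y, 1.0
    A[1::2, 6], A[1::2, 7], A[1::2, 8] = -v * x, -v * y, -v
    _, _, vt = np.linalg.svd(A)
    Hn = vt[-1].reshape(3, 3)
    return np.linalg.inv(T_dst) @ Hn @ T_src


def _sample_degenerate(points: np.ndarray) -> bool:
    """True if any 3 of the 4 sampled points are (nearly) collinear."""
    from itertools import combinations

    for i, j, k in combinations(range(points.shape[0]), 3):
        a, b, c = points[i], points[j], points[k]
        area2 = abs((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))
        span = max(np.abs(points).max(), 1.0)
        if area2 <= 1e-9 * span * span:
            return True
    return False


def estimate_homography(
    cs: CorrespondenceSet,
    ransac_threshold_px: float = 3.0,
    seed: int | None = None,
    max_iterations: int = 2000,
    confidence: float = 0.995,
) -> tuple[Homography, np.ndarray]:
    """RANSAC homography from point correspondences.

    Minimal 4-point samples are scored by the back-projection error
    ``|H p_src - p_dst|``; points with error below ``ransac_threshold_px``
    are inliers.  The winning consensus set is refit with the normalized
    DLT over all its inliers.  Iterations stop early once the standard
    adaptive bound for the requested ``confidence`` is reached.  Given the
    same correspondences and seed the result is identical across runs.

    Returns ``(homography, inlier_mask)``.
    """
    n = len(cs)
    if n < 4:
        raise EstimationError(f"need at least 4 correspondences, got {n}")
    src, dst = cs.source, cs.destination
    rng = np.random.default_rng(seed)
    best_mask: np.ndarray | None = None
    best_count = 0
    best_rms = np.inf
    needed = max_iterations
    it = 0
    while it < min(needed, max_iterations):
        it += 1
        pick = rng.choice(n, size=4, replace=False)
        if _sample_degenerate(src[pick]) or _sample_degenerate(dst[pick]):
            continue
        try:
            H = Homography(_dlt(src[pick], dst[pick]))
        except (ValueError, np.linalg.LinAlgError):
            continue
        err = np.linalg.norm(H.apply(src) - dst, axis=1)
        mask = err < ransac_threshold_px
        count = int(mask.sum())
        rms = float(np.sqrt(np.mean(err[mask] ** 2))) if count else np.inf
        if count > best_count or (count == best_count and rms < best_rms):
            best_count, best_mask, best_rms = count, mask, rms
            if count == n:
                break
            w = max(count / n, 1e-9)
            needed = int(np.ceil(np.log(1 - confidence) / np.log(1 - w**4 + 1e-300)))
    if best_mask is None or best_count < 4:
        raise EstimationError("RANSAC failed to find a 4-inlier consensus")
    H = Homography(_dlt(src[best_mask], dst[best_mask]))
    return H, best_mask


def warp_image(
    img: np.ndarray,
    H: Homography,
    out_shape: tuple[int, int],
    order: int = 1,
    fill: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Projective warp: output (x, y) samples the source at H(x, y).

    ``order=1`` is bilinear; use ``order=0`` (nearest neighbor) for label or
    index images to avoid mixing values.  Returns ``(warped, valid_mask)``
    where the mask is False for output pixels whose source coordinates fall
    outside the input; those pixels hold ``fill``.

    To render a source image into the destination frame of a homography
    that maps source *points* to destination *points* (as returned by
    :func:`estimate_homography`), pass ``H.inverse``.
    """
    img = np.asarray(img, dtype=float)
    rows, cols = out_shape
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    mapped = H.apply(pts)
    xs = mapped[:, 0].reshape(rows, cols)
    ys = mapped[:, 1].reshape(rows, cols)
    in_rows, in_cols = img.shape[:2]
    valid = (xs >= 0) & (xs <= in_cols - 1) & (ys >= 0) & (ys <= in_rows - 1)

    def sample(channel: np.ndarray) -> np.ndarray:
        out = ndimage.map_coordinates(
            channel, [ys, xs], order=order, mode="constant", cval=fill
        )
        return np.where(valid, out, fill)

    if img.ndim == 2:
        warped = sample(img)
    else:
        warped = np.dstack([sample(img[..., c]) for c in range(img.shape[2])])
    return warped, valid


def overlay(
    base: np.ndarray,
    registered: np.ndarray,
    alpha: float,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Semitransparent overlay: alpha-blend on valid pixels, base elsewhere."""
    base = np.asarray(base, dtype=float)
    registered = np.asarray(registered, dtype=float)
    if base.shape != registered.shape:
        raise ValueError(
            f"shape mismatch: base {base.shape} vs registered {registered.shape}"
        )
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    blended = (1.0 - alpha) * base + alpha * registered
    if mask is None:
        return blended
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != base.shape[: mask.ndim]:
        raise ValueError("mask shape must match image spatial shape")
    if base.ndim == 3 and mask.ndim == 2:
        mask = mask[..., None]
    return np.where(mask, blended, base)


def write_correspondences_csv(cs: CorrespondenceSet, path: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x_src", "y_src", "x_dst", "y_dst"])
        for (xs, ys), (xd, yd) in zip(cs.source, cs.destination):
            writer.writerow([repr(float(v)) for v in (xs, ys, xd, yd)])


def read_correspondences_csv(path: str) -> CorrespondenceSet:
    src, dst = [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if [h.strip() for h in header] != ["x_src", "y_src", "x_dst", "y_dst"]:
            raise ValueError(f"unexpected correspondence CSV header: {header}")
        for row in reader:
            if not row:
                continue
            xs, ys, xd, yd = (float(v) for v in row)
            src.append((xs, ys))
            dst.append((xd, yd))
    return CorrespondenceSet(np.array(src), np.array(dst))
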