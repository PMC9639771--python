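"""Fascicle tracking with Lucas-Kanade affine optical flow.

Tracks a fascicle region through a B-mode-like image sequence frame by frame,
propagates the fascicle endpoints and aponeurosis line through the accumulated
affine transforms, and converts the result into calibrated length / pennation /
shortening traces that can be resampled onto the EMG timeline via the imaging
trigger.

Coordinate convention: image x rightward (proximal to distal), y downward
(skin to deep); points are (x, y) in pixels; angles live in the image plane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import CubicSpline

logger = logging.getLogger(__name__)

#: Field of view of the imaging probe in mm; the default pixel scale is this
#: divided by the image width.
FIELD_OF_VIEW_MM = 60.0


def mm_per_px_from_fov(image_width_px: int, fov_mm: float = FIELD_OF_VIEW_MM) -> float:
    return fov_mm / float(image_width_px)


# ---------------------------------------------------------------------------
# geometry containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AffineParams:
    """2-D affine transform ``p' = A p + t`` in pixel coordinates."""

    linear: np.ndarray  # (2, 2)
    translation: np.ndarray  # (2,)

    def __post_init__(self):
        A = np.asarray(self.linear, dtype=float).reshape(2, 2)
        t = np.asarray(self.translation, dtype=float).reshape(2)
        if abs(np.linalg.det(A)) < 1e-12:
            raise ValueError("linear part must be nonsingular")
        object.__setattr__(self, "linear", A)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "AffineParams":
        return cls(np.eye(2), np.zeros(2))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (n, 2) array of (x, y) points (or a single point)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = p @ self.linear.T + self.translation
        return out[0] if np.asarray(points).ndim == 1 else out

    def compose(self, other: "AffineParams") -> "AffineParams":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return AffineParams(
            self.linear @ other.linear,
            self.linear @ other.translation + self.translation,
        )

    def inverse(self) -> "AffineParams":
        Ainv = np.linalg.inv(self.linear)
        return AffineParams(Ainv, -Ainv @ self.translation)


@dataclass(frozen=True)
class FascicleGeometry:
    """One fascicle and its insertion aponeurosis, in pixels."""

    endpoints: np.ndarray  # (2, 2): [[x0, y0], [x1, y1]]; row 0 = insertion
    apo_point: np.ndarray  # point on the aponeurosis line
    apo_direction: np.ndarray  # direction of the aponeurosis line
    mm_per_px: float

    def __post_init__(self):
        ep = np.asarray(self.endpoints, dtype=float).reshape(2, 2)
        if np.allclose(ep[0], ep[1]):
            raise ValueError("fascicle endpoints must be distinct")
        if self.mm_per_px <= 0:
            raise ValueError("pixel scale must be positive")
        object.__setattr__(self, "endpoints", ep)
        object.__setattr__(self, "apo_point", np.asarray(self.apo_point, dtype=float).reshape(2))
        object.__setattr__(
            self, "apo_direction", np.asarray(self.apo_direction, dtype=float).reshape(2)
        )

    @property
    def length_px(self) -> float:
        return float(np.linalg.norm(self.endpoints[1] - self.endpoints[0]))

    @property
    def length_mm(self) -> float:
        return self.length_px * self.mm_per_px

    def transformed(self, warp: AffineParams) -> "FascicleGeometry":
        d = warp.linear @ self.apo_direction
        return replace(
            self,
            endpoints=warp.apply(self.endpoints),
            apo_point=warp.apply(self.apo_point),
            apo_direction=d / np.linalg.norm(d),
        )


def pennation_angle(geometry: FascicleGeometry) -> float:
    """Unsigned acute angle (degrees) between fascicle and aponeurosis."""
    v = geometry.endpoints[1] - geometry.endpoints[0]
    nv = np.linalg.norm(v)
    nd = np.linalg.norm(geometry.apo_direction)
    if nv == 0.0 or nd == 0.0:
        raise ValueError("zero-length direction")
    c = abs(float(np.dot(v, geometry.apo_direction)) / (nv * nd))
    return float(np.degrees(np.arccos(np.clip(c, 0.0, 1.0))))


@dataclass
class FascicleTrace:
    """Per-frame fascicle kinematics.

    ``delta_mm`` is the shortening convention used throughout: rest length
    minus current length, positive while the muscle contracts.
    """

    length_mm: np.ndarray
    pennation_deg: np.ndarray
    frame_rate: float
    rest_length_mm: float

    @property
    def delta_mm(self) -> np.ndarray:
        return self.rest_length_mm - self.length_mm

    @property
    def n_frames(self) -> int:
        return int(self.length_mm.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "length_mm": self.length_mm,
                "pennation_deg": self.pennation_deg,
                "delta_mm": self.delta_mm,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Lucas-Kanade affine registration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LKOptions:
    pyramid_levels: int = 3
    max_iter: int = 50
    tol: float = 1e-3  # convergence: max corner displacement update, px
    roi_margin_px: int = 20  # dilation of the fascicle bounding box


@dataclass(frozen=True)
class LKResult:
    params: AffineParams
    converged: bool
    failed: bool
    n_iter: int
    rms_residual: float


def _pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    """Coarse-to-fine Gaussian pyramid, finest level first."""
    out = [np.asarray(img, dtype=float)]
    for _ in range(levels - 1):
        prev = out[-1]
        if min(prev.shape) < 16:
            break
        sm = ndimage.gaussian_filter(prev, sigma=1.0, mode="nearest")
        out.append(sm[::2, ::2])
    return out


def _sample(img: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(img, [ys, xs], order=1, mode="nearest")


def lk_affine_step(
    prev: np.ndarray,
    next_: np.ndarray,
    roi: tuple[int, int, int, int],
    opts: LKOptions = LKOptions(),
    init: AffineParams | None = None,
) -> LKResult:
    """Estimate the affine warp carrying ``roi`` of ``prev`` into ``next_``.

    Forward-additive Gauss-Newton minimization of the sum of squared intensity
    differences over the warped ROI, coarse-to-fine over a Gaussian pyramid.
    The warp maps prev-frame pixel coordinates to next-frame coordinates.
    A textureless ROI (singular normal matrix) returns the identity with
    ``failed=True``.
    """
    prev = np.asarray(prev, dtype=float)
    next_ = np.asarray(next_, dtype=float)
    if prev.shape != next_.shape:
        raise ValueError("frames must have the same shape")
    x0, y0, x1, y1 = roi
    h, w = prev.shape
    x0 = max(0, int(x0)); y0 = max(0, int(y0))
    x1 = min(w, int(x1)); y1 = min(h, int(y1))
    if x1 - x0 < 8 or y1 - y0 < 8:
        raise ValueError("roi too small or outside the frames")

    pyr_prev = _pyramid(prev, opts.pyramid_levels)
    pyr_next = _pyramid(next_, opts.pyramid_levels)
    n_levels = min(len(pyr_prev), len(pyr_next))

    # p = [a11-1, a12, tx, a21, a22-1, ty] at full resolution
    p = np.zeros(6)
    if init is not None:
        p[[0, 1, 3, 4]] = (init.linear - np.eye(2)).ravel()[[0, 1, 2, 3]]
        p[[2, 5]] = init.translation

    total_iters = 0
    converged = False
    rms = np.inf
    for level in range(n_levels - 1, -1, -1):
        s = 2.0**level
        P, N = pyr_prev[level], pyr_next[level]
        gy, gx = np.gradient(N)
        lx0, ly0, lx1, ly1 = (int(round(v / s)) for v in (x0, y0, x1, y1))
        lx1 = min(lx1, P.shape[1]); ly1 = min(ly1, P.shape[0])
        if lx1 - lx0 < 8 or ly1 - ly0 < 8:
            continue
        xs, ys = np.meshgrid(np.arange(lx0, lx1, dtype=float), np.arange(ly0, ly1, dtype=float))
        xs = xs.ravel(); ys = ys.ravel()
        T = _sample(P, xs, ys)
        # scale translation into level coordinates
        pl = p.copy()
        pl[2] /= s; pl[5] /= s
        corners = np.array([[lx0, ly0], [lx1, ly0], [lx0, ly1], [lx1, ly1]], dtype=float)
        converged = False
        for it in range(opts.max_iter):
            wx = (1.0 + pl[0]) * xs + pl[1] * ys + pl[2]
            wy = pl[3] * xs + (1.0 + pl[4]) * ys + pl[5]
            Iw = _sample(N, wx, wy)
            r = Iw - T
            gxi = _sample(gx, wx, wy)
            gyi = _sample(gy, wx, wy)
            J = np.stack([gxi * xs, gxi * ys, gxi, gyi * xs, gyi * ys, gyi], axis=1)
            H = J.T @ J
            b = J.T @ r
            try:
                dp = np.linalg.solve(H, -b)
            except np.linalg.LinAlgError:
                logger.warning("LK normal matrix singular (textureless roi); returning identity")
                return LKResult(AffineParams.identity(), False, True, total_iters, float("inf"))
            pl += dp
            total_iters += 1
            dA = np.array([[dp[0], dp[1]], [dp[3], dp[4]]])
            disp = np.abs(corners @ dA.T + dp[[2, 5]]).max()
            if disp < opts.tol:
                converged = True
                rms = float(np.sqrt(np.mean(r**2)))
                break
        if not converged:
            rms = float(np.sqrt(np.mean(r**2)))
        p = pl.copy()
        p[2] *= s; p[5] *= s

    A = np.array([[1.0 + p[0], p[1]], [p[3], 1.0 + p[4]]])
    t = p[[2, 5]]
    return LKResult(AffineParams(A, t), converged, False, total_iters, rms)


# ---------------------------------------------------------------------------
# sequence tracking
# ---------------------------------------------------------------------------

def _roi_from_geometry(geom: FascicleGeometry, shape: tuple[int, int], margin: int):
    xs = geom.endpoints[:, 0]
    ys = geom.endpoints[:, 1]
    x0 = int(np.floor(xs.min())) - margin
    x1 = int(np.ceil(xs.max())) + margin
    y0 = int(np.floor(ys.min())) - margin
    y1 = int(np.ceil(ys.max())) + margin
    h, w = shape
    return max(0, x0), max(0, y0), min(w, x1), min(h, y1)


@dataclass
class TrackResult:
    trace: FascicleTrace
    geometries: list[FascicleGeometry]
    failed_frames: list[int]


def track_fascicle(
    sequence: np.ndarray,
    init: FascicleGeometry,
    frame_rate: float = 80.0,
    opts: LKOptions = LKOptions(),
    rest_length_mm: float | None = None,
) -> TrackResult:
    """Track fascicle geometry through an image sequence.

    Per frame pair the ROI warp is estimated with :func:`lk_affine_step` and
    the fascicle endpoints and aponeurosis line are propagated through the
    resulting affine; transforms are composed frame to frame with no key-frame
    re-anchoring, so drift is possible and should be checked against ground
    truth on synthetic data.  A failed registration carries the previous
    geometry forward and records the frame index.

    Rest length defaults to the frame-0 tracked length; pass
    ``rest_length_mm`` to override with an explicit rest-window average.
    """
    seq = np.asarray(sequence)
    if seq.ndim != 3 or seq.shape[0] == 0:
        raise ValueError("sequence must be a non-empty (frames, h, w) stack")
    n_frames = seq.shape[0]

    geoms = [init]
    failed: list[int] = []
    lengths = [init.length_mm]
    penn = [pennation_angle(init)]
    for k in range(1, n_frames):
        cur = geoms[-1]
        roi = _roi_from_geometry(cur, seq.shape[1:], opts.roi_margin_px)
        res = lk_affine_step(seq[k - 1], seq[k], roi, opts)
        if res.failed:
            failed.append(k)
            geoms.append(cur)
        else:
            geoms.append(cur.transformed(res.params))
        lengths.append(geoms[-1].length_mm)
        penn.append(pennation_angle(geoms[-1]))

    rest = float(lengths[0]) if rest_length_mm is None else float(rest_length_mm)
    trace = FascicleTrace(
        length_mm=np.asarray(lengths),
        pennation_deg=np.asarray(penn),
        frame_rate=frame_rate,
        rest_length_mm=rest,
    )
    if failed:
        logger.warning("tracking failed on %d/%d frames", len(failed), n_frames)
    return TrackResult(trace=trace, geometries=geoms, failed_frames=failed)


def load_tiff_sequence(path) -> np.ndarray:
    """Read a multi-page grayscale TIFF into a (frames, h, w) float array."""
    import tifffile

    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return np.asarray(arr, dtype=float)


# ---------------------------------------------------------------------------
# resampling onto the EMG timeline
# ---------------------------------------------------------------------------

def resample_to_emg(
    values: np.ndarray,
    trigger_edges: np.ndarray,
) -> tuple[np.ndarray, int]:
    """Interpolate per-frame values onto EMG samples via the trigger edges.

    Each frame value is positioned at its trigger-edge sample index and a
    cubic spline is evaluated at every integer sample between the first and
    last edge (endpoints exact).  Returns ``(samples, start_sample)``.
    """
    values = np.asarray(values, dtype=float)
    edges = np.asarray(trigger_edges, dtype=np.int64)
    if edges.size != values.size:
        raise ValueError(
            f"trigger edge count {edges.size} != frame count {values.size}"
        )
    if np.any(np.diff(edges) <= 0):
        raise ValueError("trigger edges must be strictly increasing")
    spline = CubicSpline(edges.astype(float), values)
    grid = np.arange(edges[0], edges[-1] + 1, dtype=float)
    out = spline(grid)
    out[0] = values[0]
    out[-1] = values[-1]
    return out, int(edges[0])
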