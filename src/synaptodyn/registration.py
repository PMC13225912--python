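"""Time-lapse registration: rigid pre-alignment and chained thin-plate-spline unwarping.

Live axons and dendrites drift and deform over an hour of imaging, which
would masquerade as puncta mobility.  The correction is two-stage: an
integer-pixel translation alignment of every frame to the first frame,
followed by a thin-plate-spline (TPS) unwarp driven by landmark pairs picked
between the *last* frame of the movie (where accumulated deformation is
largest) and the first frame.  Because the deformation accrues gradually,
the moving landmarks are linearly interpolated over time and the movie is
unwarped in consecutive fixed-length chunks (default 30 frames), each chunk
warped by the TPS fitted to its interpolated landmarks.

The TPS here is the classic biharmonic interpolant: an affine part plus a
radial term ``sum_i w_i U(|x - p_i|)`` with kernel ``U(r) = r^2 log r``
(``U(0) = 0``), solved exactly so that every source landmark maps onto its
target, subject to the bending-energy side conditions ``sum w_i = 0`` and
``sum w_i p_i = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

#: camera pixel pitch used for µm <-> px conversion when rendering
PIXEL_UM = 0.1266


class SingularLandmarkError(ValueError):
    """Raised for collinear or duplicated landmark configurations."""


@dataclass
class LandmarkSet:
    """Landmark coordinates (x_px, y_px) describing one frame."""

    points: np.ndarray  # (n, 2) float, columns x, y in pixels
    frame: int = 0

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 2:
            raise ValueError("landmark points must be (n, 2)")

    def __len__(self) -> int:
        return len(self.points)


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    # U(r) = r^2 log r = 0.5 * r^2 * log(r^2), with U(0) = 0
    out = np.zeros_like(r2)
    nz = r2 > 0
    out[nz] = 0.5 * r2[nz] * np.log(r2[nz])
    return out


@dataclass
class TPSTransform:
    """A fitted thin-plate-spline map from source to target coordinates.

    ``affine`` has shape (3, 2): rows are the constant, x and y coefficients
    per output coordinate.  ``weights`` has shape (n, 2): radial-basis weight
    per source landmark per output coordinate.
    """

    source: np.ndarray   # (n, 2)
    affine: np.ndarray   # (3, 2)
    weights: np.ndarray  # (n, 2)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d2 = np.square(pts[:, None, :] - self.source[None, :, :]).sum(axis=2)
        u = _tps_kernel(d2)
        out = (
            self.affine[0]
            + pts @ self.affine[1:]
            + u @ self.weights
        )
        return out

    def invert_points(self, points: np.ndarray, tol: float = 1e-8, max_iter: int = 200) -> np.ndarray:
        """Numerically invert the map at the given points (fixed-point iteration).

        Valid for deformations close to the identity, which is the regime of
        drift correction; raises if the iteration fails to contract.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        x = pts.copy()
        for _ in range(max_iter):
            resid = self(x) - pts
            x = x - resid
            if np.max(np.abs(resid)) < tol:
                return x
        raise RuntimeError("TPS inversion did not converge; deformation too large")


def fit_tps(source: LandmarkSet, target: LandmarkSet, regularization: float = 0.0) -> TPSTransform:
    """Fit the exact thin-plate-spline interpolant mapping source to target landmarks.

    With ``regularization = 0`` every source landmark maps onto its target
    exactly; a positive value relaxes interpolation toward a smoother map
    (standard ridge on the kernel matrix).  Collinear or duplicated source
    landmarks make the system singular and raise :class:`SingularLandmarkError`.
    """
    src = LandmarkSet(source.points if isinstance(source, LandmarkSet) else source).points
    tgt = LandmarkSet(target.points if isinstance(target, LandmarkSet) else target).points
    if len(src) != len(tgt):
        raise ValueError(f"landmark counts differ: {len(src)} vs {len(tgt)}")
    n = len(src)
    if n < 3:
        raise SingularLandmarkError("at least 3 landmarks required")
    P = np.column_stack([np.ones(n), src])
    if np.linalg.matrix_rank(P) < 3:
        raise SingularLandmarkError("landmarks are collinear")
    d2 = np.square(src[:, None, :] - src[None, :, :]).sum(axis=2)
    K = _tps_kernel(d2) + regularization * np.eye(n)
    L = np.zeros((n + 3, n + 3))
    L[:n, :n] = K
    L[:n, n:] = P
    L[n:, :n] = P.T
    rhs = np.zeros((n + 3, 2))
    rhs[:n] = tgt
    try:
        sol = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as exc:  # duplicated points etc.
        raise SingularLandmarkError(f"singular TPS system: {exc}") from exc
    weights = sol[:n]
    affine = sol[n:]
    return TPSTransform(source=src, affine=affine, weights=weights)


def interpolate_landmarks(
    final_landmarks: LandmarkSet,
    identity_landmarks: LandmarkSet,
    n_frames: int,
    chunk: int = 30,
) -> List[LandmarkSet]:
    """Linearly interpolate moving landmarks at each chunk-boundary frame.

    The landmark pair set is picked at the *last* frame; at frame ``f`` the
    moving landmark is ``identity + f / (n_frames - 1) * (final - identity)``.
    Returns one :class:`LandmarkSet` per chunk, at that chunk's end frame
    (the last chunk ends at ``n_frames - 1``).
    """
    fin = final_landmarks.points
    ident = identity_landmarks.points
    if fin.shape != ident.shape:
        raise ValueError("landmark counts differ between final and identity sets")
    if n_frames < chunk:
        raise ValueError("n_frames must be >= chunk")
    n_chunks = int(np.ceil(n_frames / chunk))
    out = []
    for c in range(n_chunks):
        f = min((c + 1) * chunk - 1, n_frames - 1)
        frac = f / (n_frames - 1)
        out.append(LandmarkSet(points=ident + frac * (fin - ident), frame=f))
    return out


def landmark_at_frame(
    final_landmarks: LandmarkSet, identity_landmarks: LandmarkSet, frame: int, n_frames: int
) -> LandmarkSet:
    """Moving landmark positions linearly interpolated at an arbitrary frame."""
    frac = frame / (n_frames - 1)
    return LandmarkSet(
        points=identity_landmarks.points
        + frac * (final_landmarks.points - identity_landmarks.points),
        frame=frame,
    )


# ---------------------------------------------------------------------------
# Rigid translation pre-alignment
# ---------------------------------------------------------------------------

def rigid_prealign(stack: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Align every frame to frame 0 by an integer-pixel translation.

    Returns ``(aligned_stack, shifts)`` where ``shifts[t] = (dx, dy)`` is the
    recovered displacement of frame ``t``'s content relative to frame 0 (x
    rightward, y downward); the aligned frame is the input translated by
    ``(-dx, -dy)`` with zero fill.  Shift estimation is whole-image phase
    cross-correlation, a translation-only stand-in for feature-based rigid
    alignment.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("stack must be a non-empty (t, y, x) array")
    ref = stack[0].astype(float)
    aligned = np.empty_like(stack, dtype=float)
    aligned[0] = ref
    shifts = np.zeros((stack.shape[0], 2), dtype=int)
    for t in range(1, stack.shape[0]):
        # returned shift registers the moving frame onto the reference
        shift, _, _ = phase_cross_correlation(ref, stack[t].astype(float), upsample_factor=1)
        dy, dx = -int(round(shift[0])), -int(round(shift[1]))
        shifts[t] = (dx, dy)
        aligned[t] = ndimage.shift(stack[t].astype(float), (-dy, -dx), order=0, cval=0.0)
    return aligned, shifts


# ---------------------------------------------------------------------------
# Chunked TPS unwarping
# ---------------------------------------------------------------------------

def _grid_coords(shape: Tuple[int, int], mapping: TPSTransform) -> np.ndarray:
    """Mapped (row, col) sampling coordinates for every pixel of a frame."""
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    mapped = mapping(pts)
    return np.vstack([mapped[:, 1], mapped[:, 0]])  # (row, col) order


def unwarp_timelapse(
    stack: np.ndarray,
    final_landmarks: LandmarkSet,
    reference_landmarks: LandmarkSet,
    chunk: int = 30,
    regularization: float = 0.0,
) -> Tuple[np.ndarray, List[TPSTransform]]:
    """Unwarp a time-lapse stack in consecutive ``chunk``-frame subvideos.

    For each chunk the moving landmarks are interpolated at the chunk's end
    frame and a TPS is fitted from the reference landmarks to them; sampling
    the moving frames at the mapped coordinates (bilinear interpolation,
    zero fill outside the canvas) pulls each chunk back onto the reference
    canvas, so successive chunks chain without compounding error.  Returns
    the unwarped stack and the per-chunk transforms.
    """
    stack = np.asarray(stack)
    n_frames = stack.shape[0]
    if n_frames < chunk:
        raise ValueError("stack must have at least `chunk` frames")
    per_chunk = interpolate_landmarks(final_landmarks, reference_landmarks, n_frames, chunk)
    out = np.empty_like(stack, dtype=float)
    transforms: List[TPSTransform] = []
    for c, lms in enumerate(per_chunk):
        tf = fit_tps(reference_landmarks, lms, regularization=regularization)
        transforms.append(tf)
        start = c * chunk
        stop = min((c + 1) * chunk, n_frames)
        if np.allclose(lms.points, reference_landmarks.points):
            out[start:stop] = stack[start:stop].astype(float)
            continue
        coords = _grid_coords(stack.shape[1:], tf)  # shared by every frame of the chunk
        for f in range(start, stop):
            out[f] = ndimage.map_coordinates(
                stack[f].astype(float), coords, order=1, cval=0.0
            ).reshape(stack.shape[1:])
    return out, transforms
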