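"""Landmark-based 2-D co-registration between imaging frames.

The AFM brightfield frame, the stained brightfield frame and the
polarized-light frame are related through landmarks read off an
imprinted 50 um grid; because the polarized image is dark-field, the
stained brightfield image serves as an intermediate, and the two
estimated transforms are composed into the full chain.  Co-registration
accuracy is summarised as the mean held-out landmark displacement
normalised by the grid pitch, in percent.

Coordinates are um, origin top-left, y down (same convention as the
imaging module).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import transform as sktransform

from .collagen import RoiBox
from .errors import EstimationError

_FAMILIES = ("rigid", "similarity", "affine")
_SK_TYPES = {"rigid": "euclidean", "similarity": "similarity", "affine": "affine"}
_MIN_PAIRS = {"rigid": 2, "similarity": 2, "affine": 3}


@dataclass(frozen=True)
class Transform2D:
    """Homogeneous 2-D transform acting on (x, y) points in um."""

    matrix: np.ndarray
    family: str = "affine"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("transform matrix must be 3x3")
        if abs(np.linalg.det(m)) < 1e-12:
            raise EstimationError("singular transform")
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family in ("rigid", "similarity"):
            a = m[:2, :2]
            gram = a.T @ a
            s2 = 0.5 * np.trace(gram)
            if not np.allclose(gram, s2 * np.eye(2), atol=1e-9 * max(s2, 1.0)):
                raise EstimationError(f"matrix is not a {self.family} transform")
        object.__setattr__(self, "matrix", m)

    # -- constructors -----------------------------------------------------
    @classmethod
    def identity(cls, family: str = "rigid") -> "Transform2D":
        return cls(np.eye(3), family)

    @classmethod
    def similarity(
        cls,
        rotation_deg: float = 0.0,
        scale: float = 1.0,
        translation_um: tuple[float, float] = (0.0, 0.0),
    ) -> "Transform2D":
        t = sktransform.SimilarityTransform(
            scale=scale, rotation=np.radians(rotation_deg), translation=translation_um
        )
        family = "similarity" if scale != 1.0 else "rigid"
        return cls(t.params, family)

    # -- behaviour --------------------------------------------------------
    def apply(self, points_um: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        homog = np.hstack([pts, np.ones((pts.shape[0], 1))])
        out = homog @ self.matrix.T
        return out[:, :2] / out[:, 2:3]

    def __call__(self, points_um: np.ndarray) -> np.ndarray:
        return self.apply(points_um)

    @property
    def inverse(self) -> "Transform2D":
        return Transform2D(np.linalg.inv(self.matrix), self.family)

    @property
    def scale(self) -> float:
        """Isotropic scale factor (meaningful for rigid/similarity)."""
        return float(np.sqrt(abs(np.linalg.det(self.matrix[:2, :2]))))


@dataclass
class LandmarkSet:
    """Paired landmark coordinates (um) in source and destination frames."""

    src_um: np.ndarray
    dst_um: np.ndarray
    grid_pitch_um: float = 50.0

    def __post_init__(self) -> None:
        self.src_um = np.atleast_2d(np.asarray(self.src_um, dtype=float))
        self.dst_um = np.atleast_2d(np.asarray(self.dst_um, dtype=float))
        if self.src_um.shape != self.dst_um.shape or self.src_um.shape[1] != 2:
            raise EstimationError("landmark lists must be matching (N, 2) arrays")
        if self.grid_pitch_um <= 0:
            raise EstimationError("grid pitch must be positive")

    def __len__(self) -> int:
        return int(self.src_um.shape[0])


@dataclass(frozen=True)
class TransformFit:
    transform: Transform2D
    rms_residual_um: float
    n_landmarks: int


def estimate_transform(landmarks: LandmarkSet, family: str = "similarity") -> TransformFit:
    """Least-squares landmark alignment within the chosen transform family.

    Default family is similarity (translation + rotation + isotropic
    scale): tissue sections behave as rigid objects imaged at possibly
    different magnifications; ``affine`` accommodates sectioning shear.
    """
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    n = len(landmarks)
    if n < _MIN_PAIRS[family]:
        raise EstimationError(f"{family} estimation needs >= {_MIN_PAIRS[family]} landmark pairs")
    src, dst = landmarks.src_um, landmarks.dst_um
    centred = src - src.mean(axis=0)
    rank = np.linalg.matrix_rank(centred, tol=1e-9 * max(1.0, np.abs(centred).max()))
    if family == "affine" and rank < 2:
        raise EstimationError("affine estimation needs >= 3 non-collinear landmarks")
    if rank < 1:
        raise EstimationError("landmarks are coincident")
    est = sktransform.estimate_transform(_SK_TYPES[family], src, dst)
    if not np.all(np.isfinite(est.params)):
        raise EstimationError("degenerate landmark configuration")
    t = Transform2D(est.params, family)
    resid = t.apply(src) - dst
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return TransformFit(transform=t, rms_residual_um=rms, n_landmarks=n)


def compose(t1: Transform2D, t2: Transform2D) -> Transform2D:
    """Chained transform: compose(t1, t2)(x) == t2(t1(x))."""
    if t1.family == t2.family == "rigid":
        family = "rigid"
    elif t1.family in ("rigid", "similarity") and t2.family in ("rigid", "similarity"):
        family = "similarity"
    else:
        family = "affine"
    return Transform2D(t2.matrix @ t1.matrix, family)


@dataclass(frozen=True)
class MappedRoi:
    """ROI box carried into a destination frame (corner polygon)."""

    roi_id: str
    corners_um: np.ndarray  # (4, 2), order TL, TR, BR, BL
    side_um: float  # NaN for a general affine image of a square

    def in_bounds(self, width_um: float, height_um: float) -> bool:
        x, y = self.corners_um[:, 0], self.corners_um[:, 1]
        return bool((x >= 0).all() and (y >= 0).all() and (x <= width_um).all() and (y <= height_um).all())


def map_roi(box: RoiBox, t: Transform2D) -> MappedRoi:
    """Transform the four ROI corners into the destination frame.

    Under rigid/similarity transforms the image of the square is a
    square of side ``box.side_um * t.scale``.
    """
    corners = t.apply(box.corners_um)
    side = box.side_um * t.scale if t.family in ("rigid", "similarity") else float("nan")
    return MappedRoi(roi_id=box.roi_id, corners_um=corners, side_um=side)


@dataclass(frozen=True)
class CoregError:
    """Held-out landmark co-registration error report."""

    percent_of_pitch: float
    mean_displacement_um: float
    per_landmark_percent: np.ndarray = field(repr=False, default=None)


def coregistration_error(
    estimated: Transform2D,
    heldout: LandmarkSet,
    grid_pitch_um: float | None = None,
) -> CoregError:
    """Mean Euclidean displacement between mapped and true held-out
    landmarks, normalised by the grid pitch (percent)."""
    if len(heldout) < 1:
        raise EstimationError("need at least one held-out landmark pair")
    pitch = grid_pitch_um if grid_pitch_um is not None else heldout.grid_pitch_um
    disp = np.linalg.norm(estimated.apply(heldout.src_um) - heldout.dst_um, axis=1)
    return CoregError(
        percent_of_pitch=100.0 * float(disp.mean()) / pitch,
        mean_displacement_um=float(disp.mean()),
        per_landmark_percent=100.0 * disp / pitch,
    )
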