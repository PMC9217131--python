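"""Image/table I/O and bead-calibrated dual-camera channel registration.

Coordinate convention used throughout the package: ``(x, y)`` means
``(column, row)``, 0-based, with pixel centers at integer coordinates.
Registration is applied to *coordinates* wherever possible; image
resampling exists for visualization only, to avoid interpolation
artifacts in subpixel localizations.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: Physical defaults applied when a file carries no calibration metadata:
#: 100x/1.45 objective pixel size (um) and 20 Hz frame interval (s).
DEFAULT_PIXEL_SIZE_UM = 0.134
DEFAULT_FRAME_INTERVAL_S = 0.05


@dataclass
class FrameStack:
    """A 2D image time series (or z-stack) with physical calibration.

    ``data`` has shape ``(frames, rows, cols)`` for single-channel stacks or
    ``(channels, frames, rows, cols)`` for multi-channel ones.
    """

    data: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim not in (3, 4):
            raise ValueError(
                f"FrameStack data must be 2D/3D/4D, got ndim={self.data.ndim}"
            )
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel_size_um and frame_interval_s must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[-3]

    @property
    def shape_px(self) -> tuple[int, int]:
        return self.data.shape[-2], self.data.shape[-1]


def read_stack(
    path: str | Path,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
) -> FrameStack:
    """Read a TIFF as a FrameStack.

    Calibration is taken from the arguments (a sidecar config resolves
    them); missing values fall back to the documented defaults with a
    warning.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - tifffile error paths
        raise IOError(f"unreadable TIFF {path}: {exc}") from exc
    if pixel_size_um is None:
        warnings.warn(
            f"{path.name}: no pixel size supplied, "
            f"assuming {DEFAULT_PIXEL_SIZE_UM} um",
            stacklevel=2,
        )
        pixel_size_um = DEFAULT_PIXEL_SIZE_UM
    if frame_interval_s is None:
        warnings.warn(
            f"{path.name}: no frame interval supplied, "
            f"assuming {DEFAULT_FRAME_INTERVAL_S} s",
            stacklevel=2,
        )
        frame_interval_s = DEFAULT_FRAME_INTERVAL_S
    return FrameStack(data, pixel_size_um, frame_interval_s)


def write_stack(stack: FrameStack | np.ndarray, path: str | Path) -> None:
    data = stack.data if isinstance(stack, FrameStack) else np.asarray(stack)
    tifffile.imwrite(Path(path), data)


@dataclass
class Affine2D:
    """2D affine transform mapping source-channel (x, y) to target (x, y).

    ``linear`` is the 2x2 matrix, ``offset`` the translation in pixels.
    """

    linear: np.ndarray
    offset: np.ndarray
    rms_residual_px: float = 0.0

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=float).reshape(2, 2)
        self.offset = np.asarray(self.offset, dtype=float).reshape(2)
        if abs(np.linalg.det(self.linear)) <= 1e-12:
            raise ValueError("affine linear part is singular")

    @classmethod
    def identity(cls) -> "Affine2D":
        return cls(np.eye(2), np.zeros(2))

    def inverse(self) -> "Affine2D":
        inv = np.linalg.inv(self.linear)
        return Affine2D(inv, -inv @ self.offset, self.rms_residual_px)

    def to_json(self, path: str | Path) -> None:
        a = self.linear
        payload = {
            "a11": a[0, 0], "a12": a[0, 1], "a21": a[1, 0], "a22": a[1, 1],
            "tx": self.offset[0], "ty": self.offset[1],
            "rms_residual_px": self.rms_residual_px,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "Affine2D":
        d = json.loads(Path(path).read_text())
        return cls(
            [[d["a11"], d["a12"]], [d["a21"], d["a22"]]],
            [d["tx"], d["ty"]],
            d.get("rms_residual_px", 0.0),
        )


@dataclass
class BeadMatch:
    """Mutually-nearest paired bead coordinates in two channels."""

    coords_a: np.ndarray
    coords_b: np.ndarray
    rms_residual_px: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.coords_a = np.atleast_2d(np.asarray(self.coords_a, dtype=float))
        self.coords_b = np.atleast_2d(np.asarray(self.coords_b, dtype=float))
        if self.coords_a.shape != self.coords_b.shape:
            raise ValueError("paired coordinate lists must have equal shape")

    @property
    def n_pairs(self) -> int:
        return len(self.coords_a)


def match_beads(
    coords_a: np.ndarray, coords_b: np.ndarray, max_dist_px: float = 10.0
) -> BeadMatch:
    """Pair beads across channels by mutual nearest neighbors.

    Points without a mutual partner within ``max_dist_px`` are dropped.
    Fewer than 3 surviving pairs leave the affine underdetermined and
    raise.
    """
    coords_a = np.atleast_2d(np.asarray(coords_a, dtype=float))
    coords_b = np.atleast_2d(np.asarray(coords_b, dtype=float))
    if len(coords_a) < 3 or len(coords_b) < 3:
        raise ValueError("need at least 3 beads per channel")
    pairs = mutual_nearest_indices(coords_a, coords_b, max_dist_px)
    if len(pairs) < 3:
        raise ValueError(
            f"only {len(pairs)} mutual bead pairs within {max_dist_px} px; "
            "affine underdetermined"
        )
    ia, ib = pairs[:, 0], pairs[:, 1]
    return BeadMatch(coords_a[ia], coords_b[ib])


def mutual_nearest_indices(
    coords_a: np.ndarray, coords_b: np.ndarray, cutoff: float
) -> np.ndarray:
    """Index pairs (i, j) with a_i and b_j mutual nearest neighbors within
    ``cutoff``; exact ties broken toward the lowest index. Returns an
    (n, 2) int array."""
    coords_a = np.atleast_2d(np.asarray(coords_a, dtype=float))
    coords_b = np.atleast_2d(np.asarray(coords_b, dtype=float))
    if len(coords_a) == 0 or len(coords_b) == 0:
        return np.empty((0, 2), dtype=int)
    tree_a = cKDTree(coords_a)
    tree_b = cKDTree(coords_b)
    d_ab, nn_ab = tree_b.query(coords_a)
    d_ba, nn_ba = tree_a.query(coords_b)
    # cKDTree breaks exact ties by lowest index already; make it explicit
    # for traceability when duplicated coordinates occur.
    pairs = []
    for i, j in enumerate(nn_ab):
        if d_ab[i] <= cutoff and nn_ba[j] == i:
            pairs.append((i, int(j)))
    if pairs and (np.any(d_ab[[p[0] for p in pairs]] == 0)):
        logger.debug("mutual-NN matching encountered zero-distance pairs")
    return np.asarray(pairs, dtype=int) if pairs else np.empty((0, 2), dtype=int)


def fit_affine(match: BeadMatch) -> Affine2D:
    """Least-squares 6-parameter affine A p_a + t ~ p_b.

    Raises on collinear bead geometry (rank-deficient design).
    """
    pa, pb = match.coords_a, match.coords_b
    if len(pa) < 3:
        raise ValueError("need at least 3 bead pairs")
    design = np.column_stack([pa, np.ones(len(pa))])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("bead positions are collinear; affine degenerate")
    sol, *_ = np.linalg.lstsq(design, pb, rcond=None)
    linear = sol[:2].T
    offset = sol[2]
    residuals = design @ sol - pb
    rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1)))) if len(pa) else 0.0
    affine = Affine2D(linear, offset, rms)
    match.rms_residual_px = rms
    return affine


def apply_affine(affine: Affine2D, coords: np.ndarray) -> np.ndarray:
    """Map (n, 2) ``(x, y)`` coordinates through the affine exactly."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    return coords @ affine.linear.T + affine.offset


def apply_affine_image(affine: Affine2D, image: np.ndarray) -> np.ndarray:
    """Resample an image under the affine (bilinear, zero fill).

    Provided for visualization; the live pipeline transforms coordinates
    instead. ``scipy.ndimage.affine_transform`` pulls from input
    coordinates, i.e. needs the inverse map, and works in (row, col)
    order, so the (x, y) affine is conjugated by the axis swap.
    """
    inv = affine.inverse()
    swap = np.array([[0, 1], [1, 0]], dtype=float)
    matrix_rc = swap @ inv.linear @ swap
    offset_rc = (swap @ inv.offset)
    return ndimage.affine_transform(
        np.asarray(image, dtype=float),
        matrix_rc,
        offset=offset_rc,
        order=1,
        mode="constant",
        cval=0.0,
    )
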