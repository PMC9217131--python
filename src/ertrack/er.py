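"""ER segmentation, signed distance maps, and track classification.

The core statistic: for each tracked mRNA particle, (i) an
instantaneous diffusion coefficient (IDC) from the lag-1 mean squared
displacement, and (ii) a cumulative ER localization index — the sum of
signed-distance-map values sampled at the particle's positions, where
pixels on the ER carry positive distances to the nearest ER boundary
and pixels off the ER carry negative distances. A particle is called
ER-associated when its IDC falls below 0.06 um^2/s *and* its cumulative
index is positive, the cut-offs delimiting the slow, ER-resident
cluster of a secretory control transcript. Per-cell ER-association
fractions use only tracks of at least 30 frames and only cells with at
least 3 such tracks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .synth import AcquisitionParams
from .tracking import Track

logger = logging.getLogger(__name__)

#: Mobility cut-off (um^2/s) separating ER-associated from free particles.
D_CUTOFF_UM2_S = 0.06
#: Cumulative index cut-off; positive index = net ER residence.
INDEX_CUTOFF = 0.0
#: Minimum track length (frames) entering ER-association statistics.
MIN_TRACK_LEN = 30
#: Minimum eligible tracks for a cell to be summarized.
MIN_TRACKS_PER_CELL = 3


@dataclass
class TrackMetrics:
    track_id: int
    cell_id: int | None
    n_frames_used: int
    idc_um2_s: float
    cum_er_index: float
    er_associated: bool


@dataclass
class CellSummary:
    cell_id: int
    n_tracks_eligible: int
    n_er_associated: int

    @property
    def fraction_er_associated(self) -> float:
        return self.n_er_associated / self.n_tracks_eligible


def segment_er(
    image: np.ndarray,
    smoothing_sigma_px: float = 0.0,
    threshold_mode: str = "otsu",
    fixed_threshold: float | None = None,
    area_min_px: int = 9,
) -> np.ndarray:
    """Segment the ER channel (or threshold an external probability map).

    ``threshold_mode``: ``"otsu"`` (smoothed-image Otsu), ``"fixed"``
    (absolute threshold ``fixed_threshold``), or ``"probability"``
    (input is a probability map, thresholded at 0.5 without smoothing).
    Objects smaller than ``area_min_px`` are removed. An empty result
    warns but is valid downstream (all distances negative).

    The default applies no extra smoothing: the microscope PSF already
    band-limits the ER channel; raise ``smoothing_sigma_px`` for
    low-SNR single frames.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("segment_er expects a 2D image")
    if threshold_mode == "probability":
        mask = image >= 0.5
    else:
        smoothed = (
            ndimage.gaussian_filter(image, smoothing_sigma_px)
            if smoothing_sigma_px > 0 else image
        )
        if threshold_mode == "otsu":
            if np.ptp(smoothed) == 0:
                warnings.warn("constant image: Otsu threshold degenerate, "
                              "returning empty ER mask", stacklevel=2)
                return np.zeros_like(image, dtype=bool)
            thr = threshold_otsu(smoothed)
        elif threshold_mode == "fixed":
            if fixed_threshold is None:
                raise ValueError("fixed threshold_mode needs fixed_threshold")
            thr = fixed_threshold
        else:
            raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
        mask = smoothed > thr
    if area_min_px > 1 and mask.any():
        labels, n = ndimage.label(mask)
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   range(1, n + 1))
        mask = np.isin(labels, np.flatnonzero(sizes >= area_min_px) + 1)
    if not mask.any():
        warnings.warn("ER segmentation produced an empty mask", stacklevel=2)
    return mask


def signed_distance_map(mask: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance to the ER boundary, in pixels.

    Positive on ER pixels (distance to the nearest background pixel),
    negative elsewhere (minus the distance to the nearest ER pixel).
    Degenerate all-background or all-ER masks are capped at +-(image
    diagonal).
    """
    mask = np.asarray(mask, dtype=bool)
    diag = float(np.hypot(*mask.shape))
    if not mask.any():
        return np.full(mask.shape, -diag)
    if mask.all():
        return np.full(mask.shape, diag)
    dist_in = ndimage.distance_transform_edt(mask)
    dist_out = ndimage.distance_transform_edt(~mask)
    return np.where(mask, dist_in, -dist_out)


def cumulative_er_index(
    track: Track | np.ndarray, sdm: np.ndarray, interpolate: bool = False
) -> float:
    """Sum of signed distances at a track's positions.

    Positions are sampled at the nearest integer pixel by default — the
    distance map is consumed as an image — with bilinear interpolation
    as an option. Positive totals indicate net ER residence.
    """
    pos = track.positions if isinstance(track, Track) else np.atleast_2d(track)
    rows, cols = sdm.shape
    total = 0.0
    for i, (x, y) in enumerate(pos):
        if not (-0.5 <= x <= cols - 0.5 and -0.5 <= y <= rows - 0.5):
            raise ValueError(
                f"track position {i} at ({x:.2f}, {y:.2f}) is out of bounds"
            )
        if interpolate:
            total += float(ndimage.map_coordinates(
                sdm, [[np.clip(y, 0, rows - 1)], [np.clip(x, 0, cols - 1)]],
                order=1,
            )[0])
        else:
            r = int(round(np.clip(y, 0, rows - 1)))
            c = int(round(np.clip(x, 0, cols - 1)))
            total += float(sdm[r, c])
    return total


def instantaneous_diffusion(
    track: Track | np.ndarray,
    params: AcquisitionParams,
) -> float:
    """Instantaneous diffusion coefficient (um^2/s) of one track.

    Mean squared displacement over consecutive-frame pairs, converted
    to um and divided by 4*dt (the 2D Brownian relation MSD = 4 D dt).
    Gap-bridged pairs (frame difference > 1) are excluded. Returns NaN,
    with a warning, if the track has no consecutive-frame pair.
    """
    if isinstance(track, Track):
        frames = track.frames
        pos = track.positions
    else:
        arr = np.atleast_2d(np.asarray(track, dtype=float))
        frames, pos = arr[:, 0], arr[:, 1:3]
    if len(pos) < 2:
        raise ValueError("track must have at least 2 positions")
    dframes = np.diff(frames)
    consecutive = dframes == 1
    if not consecutive.any():
        warnings.warn("track has no consecutive-frame pair; IDC undefined",
                      stacklevel=2)
        return float("nan")
    disp = np.diff(pos, axis=0)[consecutive] * params.pixel_size_um
    msd = float(np.mean(np.sum(disp**2, axis=1)))
    return msd / (4.0 * params.frame_interval_s)


def classify_track(
    idc_um2_s: float,
    cum_er_index: float,
    d_cutoff: float = D_CUTOFF_UM2_S,
    index_cutoff: float = INDEX_CUTOFF,
) -> bool:
    """ER-associated iff the IDC is below the mobility cut-off and the
    cumulative index is positive."""
    return bool(idc_um2_s < d_cutoff and cum_er_index > index_cutoff)


def compute_track_metrics(
    tracks: list[Track],
    sdm: np.ndarray,
    params: AcquisitionParams,
    d_cutoff: float = D_CUTOFF_UM2_S,
    index_cutoff: float = INDEX_CUTOFF,
    interpolate_index: bool = False,
) -> list[TrackMetrics]:
    metrics = []
    for t in tracks:
        idc = instantaneous_diffusion(t, params)
        if np.isnan(idc):
            continue
        index = cumulative_er_index(t, sdm, interpolate=interpolate_index)
        metrics.append(TrackMetrics(
            t.track_id, t.cell_id, t.length, idc, index,
            classify_track(idc, index, d_cutoff, index_cutoff),
        ))
    return metrics


def per_cell_fraction(
    tracks: list[Track],
    metrics: list[TrackMetrics],
    min_track_len: int = MIN_TRACK_LEN,
    min_tracks: int = MIN_TRACKS_PER_CELL,
) -> list[CellSummary]:
    """Per-cell ER-associated fraction over eligible tracks.

    Eligible tracks have length >= ``min_track_len`` and a cell
    assignment; cells with fewer than ``min_tracks`` eligible tracks are
    omitted.
    """
    length_by_id = {t.track_id: t.length for t in tracks}
    by_cell: dict[int, list[TrackMetrics]] = {}
    for m in metrics:
        if m.cell_id is None:
            continue
        if length_by_id.get(m.track_id, m.n_frames_used) < min_track_len:
            continue
        by_cell.setdefault(m.cell_id, []).append(m)
    summaries = []
    for cell_id in sorted(by_cell):
        ms = by_cell[cell_id]
        if len(ms) < min_tracks:
            logger.info("cell %d omitted: only %d eligible tracks",
                        cell_id, len(ms))
            continue
        summaries.append(CellSummary(
            cell_id, len(ms), sum(m.er_associated for m in ms)
        ))
    return summaries


def metrics_to_frame(metrics: list[TrackMetrics]) -> pd.DataFrame:
    return pd.DataFrame([
        {"cell_id": m.cell_id, "track_id": m.track_id,
         "n_frames": m.n_frames_used, "idc_um2_s": m.idc_um2_s,
         "cum_er_index_px": m.cum_er_index,
         "er_associated": m.er_associated}
        for m in metrics
    ], columns=["cell_id", "track_id", "n_frames", "idc_um2_s",
                "cum_er_index_px", "er_associated"])


def summaries_to_frame(summaries: list[CellSummary]) -> pd.DataFrame:
    return pd.DataFrame([
        {"cell_id": s.cell_id, "n_eligible": s.n_tracks_eligible,
         "n_associated": s.n_er_associated,
         "fraction_er_associated": s.fraction_er_associated}
        for s in summaries
    ], columns=["cell_id", "n_eligible", "n_associated",
                "fraction_er_associated"])


def plot_diffusion_vs_index(
    metrics: list[TrackMetrics],
    path,
    d_cutoff: float = D_CUTOFF_UM2_S,
    index_cutoff: float = INDEX_CUTOFF,
) -> None:
    """Scatter of IDC (log y) versus cumulative ER index with the
    classification cut-offs as dashed lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    if metrics:
        idx = np.array([m.cum_er_index for m in metrics])
        idc = np.array([max(m.idc_um2_s, 1e-5) for m in metrics])
        assoc = np.array([m.er_associated for m in metrics])
        ax.scatter(idx[~assoc], idc[~assoc], s=10, c="gray", label="free")
        ax.scatter(idx[assoc], idc[assoc], s=10, c="crimson",
                   label="ER-associated")
        ax.legend(frameon=False)
    ax.axhline(d_cutoff, ls="--", c="k", lw=0.8)
    ax.axvline(index_cutoff, ls="--", c="k", lw=0.8)
    ax.set_yscale("log")
    ax.set_xlabel("cumulative ER localization index (px)")
    ax.set_ylabel("IDC (um$^2$/s)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
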