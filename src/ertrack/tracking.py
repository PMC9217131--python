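"""Frame-to-frame track linking and per-track bookkeeping.

Greedy nearest-neighbor linking: within each new frame, candidate links
to open track heads are sorted by ascending distance and assigned one at
a time, each spot used once. A track may bridge up to ``max_gap`` empty
frames; the distance threshold for a gap-bridged link scales with
sqrt(gap + 1), the growth law of Brownian search radii. Global (LAP)
optimization is deliberately not used: at the particle densities this
package targets the greedy solution differs negligibly and remains
oracle-checkable on toy instances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detect import Spot

logger = logging.getLogger(__name__)


@dataclass
class Track:
    """An ordered sequence of detections sharing an identity."""

    track_id: int
    spots: list[Spot]
    cell_id: int | None = None

    @property
    def length(self) -> int:
        return len(self.spots)

    @property
    def frames(self) -> np.ndarray:
        return np.array([s.frame for s in self.spots])

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y)."""
        return np.array([[s.x_px, s.y_px] for s in self.spots])

    @property
    def mean_intensity(self) -> float:
        return float(np.mean([s.intensity for s in self.spots]))


def link_spots(
    spots_by_frame: list[list[Spot]],
    max_disp_px: float = 8.0,
    max_gap: int = 0,
) -> list[Track]:
    """Link detections into tracks; singleton detections are discarded."""
    if max_disp_px <= 0:
        raise ValueError("max_disp_px must be > 0")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")

    open_tracks: list[list[Spot]] = []
    closed: list[list[Spot]] = []

    for frame_idx, spots in enumerate(spots_by_frame):
        # close tracks whose head is too old to bridge
        still_open = []
        for tr in open_tracks:
            if frame_idx - tr[-1].frame - 1 > max_gap:
                closed.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open

        if spots:
            candidates = []
            for ti, tr in enumerate(open_tracks):
                head = tr[-1]
                gap = frame_idx - head.frame - 1
                limit = max_disp_px * np.sqrt(gap + 1.0)
                for si, s in enumerate(spots):
                    d = float(np.hypot(s.x_px - head.x_px, s.y_px - head.y_px))
                    if d <= limit:
                        candidates.append((d, ti, si))
            candidates.sort(key=lambda t: (t[0], t[1], t[2]))
            used_tracks: set[int] = set()
            used_spots: set[int] = set()
            for d, ti, si in candidates:
                if ti in used_tracks or si in used_spots:
                    continue
                open_tracks[ti].append(spots[si])
                used_tracks.add(ti)
                used_spots.add(si)
            for si, s in enumerate(spots):
                if si not in used_spots:
                    open_tracks.append([s])

    closed.extend(open_tracks)
    tracks = [
        Track(tid, tr)
        for tid, tr in enumerate(
            tr for tr in closed if len(tr) >= 2
        )
    ]
    n_singletons = sum(1 for tr in closed if len(tr) < 2)
    logger.info("linked %d tracks (%d singleton detections discarded)",
                len(tracks), n_singletons)
    return tracks


def filter_tracks(tracks: list[Track], min_length: int = 30) -> list[Track]:
    """Keep tracks with at least ``min_length`` detections."""
    if min_length < 2:
        raise ValueError("min_length must be >= 2")
    kept = [t for t in tracks if t.length >= min_length]
    counts = track_length_counts(tracks)
    logger.info(
        "track filter >=%d: kept %d/%d (>=3: %d, >=10: %d, >=30: %d)",
        min_length, len(kept), len(tracks),
        counts[3], counts[10], counts[30],
    )
    return kept


def track_length_counts(
    tracks: list[Track], thresholds: tuple[int, ...] = (3, 10, 30)
) -> dict[int, int]:
    """Counts of tracks at the standard length thresholds (the bookkeeping
    columns of the study's summary table)."""
    return {
        thr: sum(1 for t in tracks if t.length >= thr) for thr in thresholds
    }


def assign_cells(tracks: list[Track], cell_label_mask: np.ndarray) -> list[Track]:
    """Assign each track the ROI label under its median position.

    Tracks whose median position falls on background (label 0) get
    ``cell_id = None`` and are excluded from per-cell statistics.
    """
    mask = np.asarray(cell_label_mask)
    if mask.ndim != 2:
        raise ValueError("cell label mask must be 2D")
    rows, cols = mask.shape
    for t in tracks:
        pos = t.positions
        mx = float(np.median(pos[:, 0]))
        my = float(np.median(pos[:, 1]))
        r = int(round(np.clip(my, 0, rows - 1)))
        c = int(round(np.clip(mx, 0, cols - 1)))
        label = int(mask[r, c])
        t.cell_id = label if label > 0 else None
    return tracks


def default_max_disp_px(
    D_free_um2_s: float, frame_interval_s: float, pixel_size_um: float
) -> float:
    """4 sigma of the fastest expected per-frame displacement, rounded up."""
    return float(np.ceil(
        4.0 * np.sqrt(4.0 * D_free_um2_s * frame_interval_s) / pixel_size_um
    ))


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Long-format tracks table (track_id, cell_id, frame, x_px, y_px,
    intensity)."""
    rows = []
    for t in tracks:
        for s in t.spots:
            rows.append({
                "track_id": t.track_id, "cell_id": t.cell_id,
                "frame": s.frame, "x_px": s.x_px, "y_px": s.y_px,
                "intensity": s.intensity,
            })
    return pd.DataFrame(
        rows,
        columns=["track_id", "cell_id", "frame", "x_px", "y_px", "intensity"],
    )
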