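"""Fixed-cell smFISH-IF colocalization analysis.

Z-stacks are max-projected; mRNA and translation-site (scAB-GFP) spots
are detected separately; spot pairs are mutual nearest neighbors within
a 3-pixel Euclidean cutoff in the projection. Nuclei come from Otsu
thresholding of the DAPI channel; cytoplasm from a manual threshold on
the smFISH background signal; cell instances by expanding nuclear seeds
through the cytoplasm. The per-cell translating fraction is the share
of cytoplasmic mRNA spots carrying a paired translation-site spot.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .detect import Spot
from .registration import mutual_nearest_indices

logger = logging.getLogger(__name__)

PAIR_CUTOFF_PX = 3.0


@dataclass
class SpotPairing:
    """Partial bijection between two spot sets."""

    pairs: np.ndarray  # (n, 2) indices into (a, b)
    distances_px: np.ndarray
    n_a: int
    n_b: int

    @property
    def unmatched_a(self) -> np.ndarray:
        return np.setdiff1d(np.arange(self.n_a), self.pairs[:, 0])

    @property
    def unmatched_b(self) -> np.ndarray:
        return np.setdiff1d(np.arange(self.n_b), self.pairs[:, 1])


@dataclass
class CellCompartments:
    nuclear_mask: np.ndarray
    cytoplasm_mask: np.ndarray
    cell_labels: np.ndarray


def max_project(zstack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum intensity projection over the leading (z) axis."""
    zstack = np.asarray(zstack)
    if zstack.ndim == 2:
        return zstack
    if zstack.shape[0] < 1:
        raise ValueError("z-stack needs at least one slice")
    return zstack.max(axis=0)


def mutual_nearest_pairs(
    spots_a: list[Spot] | np.ndarray,
    spots_b: list[Spot] | np.ndarray,
    cutoff_px: float = PAIR_CUTOFF_PX,
) -> SpotPairing:
    """Pair spots across channels by mutual nearest neighbors.

    A pair (a, b) is kept iff b is a's nearest neighbor in B, a is b's
    nearest in A, and their Euclidean distance is <= ``cutoff_px``.
    Exact ties break toward the lowest index. The result is symmetric
    in the channel order.
    """
    ca = _coords(spots_a)
    cb = _coords(spots_b)
    pairs = mutual_nearest_indices(ca, cb, cutoff_px)
    if len(pairs):
        d = np.linalg.norm(ca[pairs[:, 0]] - cb[pairs[:, 1]], axis=1)
    else:
        d = np.empty(0)
    return SpotPairing(pairs, d, len(ca), len(cb))


def _coords(spots) -> np.ndarray:
    if isinstance(spots, np.ndarray):
        return np.atleast_2d(spots) if spots.size else np.empty((0, 2))
    if len(spots) == 0:
        return np.empty((0, 2))
    return np.array([[s.x_px, s.y_px] for s in spots])


def segment_compartments(
    dapi_projection: np.ndarray,
    background_projection: np.ndarray,
    cyto_threshold: float,
    min_nucleus_area_px: int = 50,
) -> CellCompartments:
    """Segment nuclei (Otsu on DAPI), cytoplasm (manual threshold on the
    smFISH background channel), and cell instances (nuclear seeds
    expanded through the cytoplasm by watershed)."""
    dapi = np.asarray(dapi_projection, dtype=float)
    bg = np.asarray(background_projection, dtype=float)
    if dapi.shape != bg.shape:
        raise ValueError("channel projections must share shape")
    if cyto_threshold <= 0:
        raise ValueError("cyto_threshold must be > 0")
    if np.ptp(dapi) == 0:
        raise ValueError("constant DAPI image: no nuclei found")
    nuclei = dapi > threshold_otsu(dapi)
    nuclei = ndimage.binary_fill_holes(nuclei)
    labels, n = ndimage.label(nuclei)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    keep = np.flatnonzero(sizes >= min_nucleus_area_px) + 1
    nuclei = np.isin(labels, keep)
    if not nuclei.any():
        raise ValueError("no nuclei found in DAPI channel")
    seeds, n_cells = ndimage.label(nuclei)

    cyto = (bg >= cyto_threshold) & ~nuclei
    if not cyto.any():
        warnings.warn("cytoplasm mask is empty at this threshold",
                      stacklevel=2)
    cell_region = cyto | nuclei
    cell_labels = watershed(
        -ndimage.distance_transform_edt(~nuclei),
        markers=seeds, mask=cell_region,
    )
    logger.info("segmented %d nuclei", n_cells)
    return CellCompartments(nuclei, cyto, cell_labels)


def translating_fraction(
    mrna_spots: list[Spot],
    pairing: SpotPairing,
    compartments: CellCompartments,
) -> pd.DataFrame:
    """Per-cell fraction of cytoplasmic mRNA spots with a translation-site
    pair. Nuclear spots are excluded from the denominator; cells with an
    empty denominator are omitted."""
    coords = _coords(mrna_spots)
    paired = set(pairing.pairs[:, 0].tolist()) if len(pairing.pairs) else set()
    labels = compartments.cell_labels
    rows_img, cols_img = labels.shape
    per_cell: dict[int, list[int]] = {}
    for i, (x, y) in enumerate(coords):
        r = int(round(np.clip(y, 0, rows_img - 1)))
        c = int(round(np.clip(x, 0, cols_img - 1)))
        if not compartments.cytoplasm_mask[r, c]:
            continue
        label = int(labels[r, c])
        if label > 0:
            per_cell.setdefault(label, []).append(i)
    records = []
    for label in sorted(per_cell):
        idx = per_cell[label]
        n_paired = sum(1 for i in idx if i in paired)
        records.append({
            "cell_id": label,
            "n_mrna_spots": len(idx),
            "n_translating": n_paired,
            "fraction_translating": n_paired / len(idx),
        })
    return pd.DataFrame(
        records,
        columns=["cell_id", "n_mrna_spots", "n_translating",
                 "fraction_translating"],
    )
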