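"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use naive O(n^2) enumeration so they stay
independent of the implementation paths they check.
"""

import warnings

import numpy as np
import pytest

from ertrack import synth


def brute_force_signed_distance(mask: np.ndarray) -> np.ndarray:
    """All-pairs signed Euclidean distance map (O(n^2) oracle)."""
    mask = np.asarray(mask, dtype=bool)
    diag = float(np.hypot(*mask.shape))
    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    out = np.empty(mask.shape, dtype=float)
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c]:
                if len(bg) == 0:
                    out[r, c] = diag
                else:
                    out[r, c] = np.sqrt(
                        ((bg - (r, c)) ** 2).sum(axis=1).min())
            else:
                if len(fg) == 0:
                    out[r, c] = -diag
                else:
                    out[r, c] = -np.sqrt(
                        ((fg - (r, c)) ** 2).sum(axis=1).min())
    return out


def brute_force_mutual_nn(
    coords_a: np.ndarray, coords_b: np.ndarray, cutoff: float
) -> set[tuple[int, int]]:
    """Mutual-nearest-neighbor pairs by full enumeration, lowest-index
    tie-break."""
    coords_a = np.atleast_2d(coords_a)
    coords_b = np.atleast_2d(coords_b)
    if len(coords_a) == 0 or len(coords_b) == 0:
        return set()
    d = np.linalg.norm(coords_a[:, None, :] - coords_b[None, :, :], axis=2)
    pairs = set()
    for i in range(len(coords_a)):
        j = int(np.argmin(d[i]))  # argmin takes the lowest index on ties
        if d[i, j] <= cutoff and int(np.argmin(d[:, j])) == i:
            pairs.add((i, j))
    return pairs


@pytest.fixture
def default_params():
    return synth.AcquisitionParams()


@pytest.fixture
def small_params():
    return synth.AcquisitionParams(n_frames=40, shape_px=(96, 96))


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        yield
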