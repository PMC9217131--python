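"""Ground-truthed synthetic microscopy scenes.

Emulates the study conditions of the live-cell and fixed-cell
acquisitions: dual-channel 20 Hz / 100-frame movies at 0.134 um/px with
an ER-marker channel and diffraction-limited mRNA spots, TetraSpeck bead
calibration pairs, GFP foci scenes, and smFISH-IF z-stacks. Every
generator is deterministic given ``(params, seed)``.

Two particle populations are simulated: ER-tethered transcripts confined
to the ER mask with low diffusivity, and free cytosolic transcripts
undergoing 2D Brownian motion. Default diffusivities (0.01 and
0.3 um^2/s) straddle the 0.06 um^2/s mobility cut-off used by the
classifier so that the two behavioral clusters are separable, as they
are in real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .registration import Affine2D, FrameStack, apply_affine

#: Simulation defaults; the D values bracket the 0.06 um^2/s classifier
#: cut-off from either side.
DEFAULT_D_TETHERED_UM2_S = 0.01
DEFAULT_D_FREE_UM2_S = 0.3


@dataclass
class AcquisitionParams:
    """Physical acquisition parameters of a movie."""

    pixel_size_um: float = 0.134
    frame_interval_s: float = 0.05
    n_frames: int = 100
    #: 256 px ~ 34 um at the default pixel size: the footprint of one
    #: imaged HeLa cell (acquisitions image one cell per field)
    shape_px: tuple[int, int] = (256, 256)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")


@dataclass
class GroundTruthParticle:
    """One simulated particle with its true trajectory.

    ``positions_px`` is an (n_frames, 3) array of (frame, x, y) with
    subpixel coordinates; consecutive rows differ by one frame.
    """

    particle_id: int
    population: str  # "tethered" | "free"
    true_D_um2_s: float
    positions_px: np.ndarray

    def __post_init__(self) -> None:
        self.positions_px = np.asarray(self.positions_px, dtype=float)
        frames = self.positions_px[:, 0]
        if len(frames) > 1 and not np.all(np.diff(frames) == 1):
            raise ValueError("consecutive truth positions must differ by 1 frame")
        if self.population not in ("tethered", "free"):
            raise ValueError(f"unknown population {self.population!r}")


@dataclass
class SyntheticScene:
    """A rendered two-channel movie plus its generating truth."""

    movie: FrameStack  # (2, T, Y, X): particle channel, ER channel
    er_mask_truth: np.ndarray
    truth: list[GroundTruthParticle]
    params: AcquisitionParams
    seed: int = 0

    @property
    def tethered_fraction(self) -> float:
        if not self.truth:
            return float("nan")
        n_teth = sum(p.population == "tethered" for p in self.truth)
        return n_teth / len(self.truth)


def make_er_geometry(
    shape_px: tuple[int, int] = (128, 128),
    n_tubules: int = 12,
    tubule_width_px: float = 3.0,
    include_sheet: bool = True,
    seed: int = 0,
    blur_sigma_px: float = 1.0,
    er_intensity: float = 600.0,
    background_level: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate a tubular/sheet ER-like binary mask and its rendered image.

    Tubules are random walks from random anchors, dilated to
    ``tubule_width_px``; an optional perinuclear sheet is an ellipse near
    the image center. The rendered channel is the mask scaled to
    ``er_intensity``, blurred, over ``background_level`` (noise is added
    at movie-rendering time).

    Returns ``(mask, image)``.
    """
    rows, cols = shape_px
    if rows < 64 or cols < 64:
        raise ValueError(f"shape must be at least 64x64, got {shape_px}")
    rng = np.random.default_rng(seed)
    mask = np.zeros((rows, cols), dtype=bool)

    if include_sheet:
        cy = rows / 2 + rng.uniform(-rows / 8, rows / 8)
        cx = cols / 2 + rng.uniform(-cols / 8, cols / 8)
        ry = rows * rng.uniform(0.10, 0.16)
        rx = cols * rng.uniform(0.10, 0.16)
        yy, xx = np.mgrid[0:rows, 0:cols]
        mask |= ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0

    # tubules: persistent random walks seeded on the sheet edge or randomly
    for _ in range(n_tubules):
        y = rng.uniform(rows * 0.1, rows * 0.9)
        x = rng.uniform(cols * 0.1, cols * 0.9)
        angle = rng.uniform(0, 2 * np.pi)
        n_steps = int(rng.integers(rows // 2, int(rows * 1.5)))
        for _ in range(n_steps):
            angle += rng.normal(0, 0.35)
            y = float(np.clip(y + np.sin(angle), 0, rows - 1))
            x = float(np.clip(x + np.cos(angle), 0, cols - 1))
            mask[int(round(y)), int(round(x))] = True

    if mask.any() and tubule_width_px > 1:
        mask = ndimage.binary_dilation(
            mask, iterations=max(1, int(round((tubule_width_px - 1) / 2)))
        )

    image = np.full((rows, cols), float(background_level))
    if mask.any():
        image += ndimage.gaussian_filter(
            mask.astype(float) * er_intensity, blur_sigma_px
        )
    return mask, image


def simulate_particles(
    er_mask: np.ndarray,
    n_tethered: int,
    n_free: int,
    D_tethered_um2_s: float = DEFAULT_D_TETHERED_UM2_S,
    D_free_um2_s: float = DEFAULT_D_FREE_UM2_S,
    params: AcquisitionParams | None = None,
    seed: int = 0,
) -> list[GroundTruthParticle]:
    """Simulate trajectories for the two particle populations.

    Free particles take 2D Brownian steps with per-axis variance
    ``2 D dt`` (converted to pixels), reflected at image borders.
    Tethered particles take Brownian steps with ``D_tethered`` but any
    proposed step whose rounded position leaves the ER mask is rejected
    (the position is repeated), confining them to the mask.
    """
    if params is None:
        params = AcquisitionParams()
    if D_tethered_um2_s < 0 or D_free_um2_s < 0:
        raise ValueError("diffusion coefficients must be >= 0")
    er_mask = np.asarray(er_mask, dtype=bool)
    if n_tethered > 0 and not er_mask.any():
        raise ValueError("cannot tether particles to an empty ER mask")
    rng = np.random.default_rng(seed)
    rows, cols = params.shape_px
    frames = np.arange(params.n_frames)

    def step_sd_px(D: float) -> float:
        return np.sqrt(2.0 * D * params.frame_interval_s) / params.pixel_size_um

    particles: list[GroundTruthParticle] = []
    pid = 0

    if n_tethered > 0:
        er_pix = np.argwhere(er_mask)  # (row, col)
        sd = step_sd_px(D_tethered_um2_s)
        for _ in range(n_tethered):
            r0, c0 = er_pix[rng.integers(len(er_pix))]
            x = c0 + rng.uniform(-0.5, 0.5)
            y = r0 + rng.uniform(-0.5, 0.5)
            # keep the subpixel start inside the mask after rounding
            x = float(np.clip(x, 0, cols - 1))
            y = float(np.clip(y, 0, rows - 1))
            xs, ys = [x], [y]
            for _ in range(params.n_frames - 1):
                dx, dy = rng.normal(0.0, sd, size=2) if sd > 0 else (0.0, 0.0)
                nx, ny = x + dx, y + dy
                ri, ci = int(round(ny)), int(round(nx))
                if (
                    0 <= ri < rows
                    and 0 <= ci < cols
                    and er_mask[ri, ci]
                ):
                    x, y = nx, ny
                xs.append(x)
                ys.append(y)
            particles.append(
                GroundTruthParticle(
                    pid, "tethered", D_tethered_um2_s,
                    np.column_stack([frames, xs, ys]),
                )
            )
            pid += 1

    sd_free = step_sd_px(D_free_um2_s)
    for _ in range(n_free):
        x = rng.uniform(0, cols - 1)
        y = rng.uniform(0, rows - 1)
        xs, ys = [x], [y]
        for _ in range(params.n_frames - 1):
            if sd_free > 0:
                dx, dy = rng.normal(0.0, sd_free, size=2)
            else:
                dx, dy = 0.0, 0.0
            x = _reflect(x + dx, cols - 1)
            y = _reflect(y + dy, rows - 1)
            xs.append(x)
            ys.append(y)
        particles.append(
            GroundTruthParticle(
                pid, "free", D_free_um2_s,
                np.column_stack([frames, xs, ys]),
            )
        )
        pid += 1
    return particles


def _reflect(v: float, vmax: float) -> float:
    """Reflect a coordinate into [0, vmax]."""
    if vmax <= 0:
        return 0.0
    period = 2.0 * vmax
    v = v % period
    return float(period - v) if v > vmax else float(v)


def render_movie(
    particles: list[GroundTruthParticle],
    er_image: np.ndarray,
    params: AcquisitionParams | None = None,
    psf_sigma_px: float = 1.3,
    spot_amplitude: float = 200.0,
    background_level: float = 100.0,
    read_noise_sd: float = 2.0,
    shot_noise: bool = True,
    seed: int = 0,
) -> FrameStack:
    """Render a two-channel movie from truth trajectories.

    Per frame, the particle channel is ``background + sum of isotropic
    2D Gaussians`` centered at the true subpixel positions (peak height
    ``spot_amplitude``), with Poisson shot noise and additive Gaussian
    read noise; the ER channel is the static ER image with the same
    noise model. Output is uint16.
    """
    if params is None:
        params = AcquisitionParams()
    if not 0.8 <= psf_sigma_px <= 3.0:
        raise ValueError("psf_sigma_px must lie in [0.8, 3]")
    if spot_amplitude <= 0 or background_level < 0:
        raise ValueError("amplitudes must be positive")
    rng = np.random.default_rng(seed)
    rows, cols = params.shape_px
    n_frames = params.n_frames
    half = int(np.ceil(4 * psf_sigma_px))

    by_frame: dict[int, list[tuple[float, float]]] = {}
    for p in particles:
        for frame, x, y in p.positions_px:
            by_frame.setdefault(int(frame), []).append((x, y))

    movie = np.empty((2, n_frames, rows, cols), dtype=np.uint16)
    er_image = np.asarray(er_image, dtype=float)
    for t in range(n_frames):
        signal = np.full((rows, cols), float(background_level))
        for x, y in by_frame.get(t, []):
            _add_gaussian(signal, x, y, spot_amplitude, psf_sigma_px, half)
        movie[0, t] = _apply_noise(signal, rng, read_noise_sd, shot_noise)
        movie[1, t] = _apply_noise(er_image, rng, read_noise_sd, shot_noise)
    return FrameStack(movie, params.pixel_size_um, params.frame_interval_s)


def _add_gaussian(
    image: np.ndarray, x: float, y: float, amp: float, sigma: float, half: int
) -> None:
    rows, cols = image.shape
    r0 = max(0, int(np.floor(y)) - half)
    r1 = min(rows, int(np.ceil(y)) + half + 1)
    c0 = max(0, int(np.floor(x)) - half)
    c1 = min(cols, int(np.ceil(x)) + half + 1)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    image[r0:r1, c0:c1] += amp * np.exp(
        -((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * sigma**2)
    )


def _apply_noise(
    signal: np.ndarray, rng: np.random.Generator, read_noise_sd: float,
    shot_noise: bool,
) -> np.ndarray:
    out = rng.poisson(signal).astype(float) if shot_noise else signal.copy()
    if read_noise_sd > 0:
        out += rng.normal(0.0, read_noise_sd, size=signal.shape)
    return np.clip(np.round(out), 0, 65535).astype(np.uint16)


def make_scene(
    n_tethered: int = 12,
    n_free: int = 28,
    params: AcquisitionParams | None = None,
    D_tethered_um2_s: float = DEFAULT_D_TETHERED_UM2_S,
    D_free_um2_s: float = DEFAULT_D_FREE_UM2_S,
    seed: int = 0,
    **render_kwargs,
) -> SyntheticScene:
    """Convenience wrapper: ER geometry + particles + rendered movie."""
    if params is None:
        params = AcquisitionParams()
    rng = np.random.default_rng(seed)
    s_geom, s_part, s_rend = rng.integers(0, 2**31 - 1, size=3)
    mask, er_img = make_er_geometry(params.shape_px, seed=int(s_geom))
    truth = simulate_particles(
        mask, n_tethered, n_free, D_tethered_um2_s, D_free_um2_s,
        params, seed=int(s_part),
    )
    movie = render_movie(truth, er_img, params, seed=int(s_rend), **render_kwargs)
    return SyntheticScene(movie, mask, truth, params, seed)


def make_bead_images(
    true_affine: Affine2D,
    n_beads: int = 20,
    shape_px: tuple[int, int] = (256, 256),
    localization_noise_px: float = 0.0,
    seed: int = 0,
    psf_sigma_px: float = 1.3,
    amplitude: float = 2000.0,
    background_level: float = 100.0,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render a TetraSpeck-style calibration image pair.

    Channel A holds beads at random positions; channel B holds the same
    beads mapped through ``true_affine`` (plus optional localization
    noise). Returns ``(image_a, image_b, truth)`` with truth columns
    ``x_a, y_a, x_b, y_b``.
    """
    if n_beads < 3:
        raise ValueError("need at least 3 beads (affine underdetermined)")
    rng = np.random.default_rng(seed)
    rows, cols = shape_px
    margin = 12
    coords_a = np.column_stack([
        rng.uniform(margin, cols - 1 - margin, n_beads),
        rng.uniform(margin, rows - 1 - margin, n_beads),
    ])
    coords_b = apply_affine(true_affine, coords_a)
    if localization_noise_px > 0:
        coords_b = coords_b + rng.normal(0, localization_noise_px, coords_b.shape)
    half = int(np.ceil(4 * psf_sigma_px))
    img_a = np.full((rows, cols), float(background_level))
    img_b = np.full((rows, cols), float(background_level))
    for (xa, ya), (xb, yb) in zip(coords_a, coords_b):
        _add_gaussian(img_a, xa, ya, amplitude, psf_sigma_px, half)
        _add_gaussian(img_b, xb, yb, amplitude, psf_sigma_px, half)
    truth = pd.DataFrame({
        "x_a": coords_a[:, 0], "y_a": coords_a[:, 1],
        "x_b": coords_b[:, 0], "y_b": coords_b[:, 1],
    })
    return img_a, img_b, truth


def make_foci_scene(
    cell_label_mask: np.ndarray,
    background_level: float = 100.0,
    foci_spec: list[tuple[tuple[float, float], float, float]] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a GFP image with disc-shaped foci of known fold enrichment.

    ``foci_spec`` entries are ``((x, y), radius_px, fold_enrichment)``;
    each focus must fall inside a labeled cell and have fold > 1. The
    returned truth table holds per-cell noiseless intensity fractions in
    foci.
    """
    cell_label_mask = np.asarray(cell_label_mask)
    rows, cols = cell_label_mask.shape
    rng = np.random.default_rng(seed)
    image = np.where(cell_label_mask > 0, float(background_level), 0.0)
    foci_mask = np.zeros((rows, cols), dtype=bool)
    yy, xx = np.mgrid[0:rows, 0:cols]
    for (x, y), radius, fold in (foci_spec or []):
        if fold <= 1:
            raise ValueError("fold_enrichment must be > 1")
        ri, ci = int(round(y)), int(round(x))
        if not (0 <= ri < rows and 0 <= ci < cols) or cell_label_mask[ri, ci] == 0:
            raise ValueError(f"focus center ({x}, {y}) lies outside any cell")
        disc = ((xx - x) ** 2 + (yy - y) ** 2 <= radius**2) & (cell_label_mask > 0)
        image[disc] = fold * background_level
        foci_mask |= disc

    records = []
    for label in np.unique(cell_label_mask[cell_label_mask > 0]):
        cell = cell_label_mask == label
        total = float(image[cell].sum())
        in_foci = float(image[cell & foci_mask].sum())
        records.append({
            "cell_id": int(label),
            "true_fraction_in_foci": in_foci / total if total > 0 else 0.0,
        })
    if noise_sd > 0:
        image = image + rng.normal(0, noise_sd, image.shape)
    return image, pd.DataFrame(records)


def make_fish_scene(
    n_cells: int = 4,
    mrna_per_cell: int = 60,
    translating_fraction: float = 0.5,
    z_slices: int = 7,
    seed: int = 0,
    cell_radius_px: float = 52.0,
    nucleus_radius_px: float = 15.0,
    spot_amplitude: float = 400.0,
    psf_sigma_px: float = 1.3,
    psf_sigma_z: float = 0.8,
    cyto_background: float = 40.0,
    outside_background: float = 5.0,
    read_noise_sd: float = 2.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a fixed-cell smFISH-IF z-stack with known translating fraction.

    Returns ``(stack, truth)`` where ``stack`` has shape
    ``(3, z, rows, cols)`` with channels (DAPI, mRNA, GFP). Cells are
    discs on a grid, each with a central nucleus; mRNA spots are placed
    in the cytoplasmic annulus and a truth-labeled subset of size
    ``round(fraction * n)`` per cell receives a GFP translation-site
    spot at the same position with at most 1 px of lateral jitter.
    Spots spread over adjacent z-slices with a Gaussian axial profile.
    """
    if not 0.0 <= translating_fraction <= 1.0:
        raise ValueError("translating_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_side = int(np.ceil(np.sqrt(n_cells)))
    pitch = int(2 * cell_radius_px + 16)
    rows = cols = n_side * pitch
    stack = np.zeros((3, z_slices, rows, cols), dtype=float)
    stack[1] += outside_background
    yy, xx = np.mgrid[0:rows, 0:cols]
    half = int(np.ceil(4 * psf_sigma_px))

    records = []
    spot_id = 0
    for c in range(n_cells):
        gy, gx = divmod(c, n_side)
        cy = gy * pitch + pitch / 2
        cx = gx * pitch + pitch / 2
        cell = (xx - cx) ** 2 + (yy - cy) ** 2 <= cell_radius_px**2
        nucleus = (xx - cx) ** 2 + (yy - cy) ** 2 <= nucleus_radius_px**2
        stack[1, :, cell] = cyto_background  # smFISH background fills the cell
        for z in range(z_slices):
            stack[0, z][nucleus] = 800.0  # DAPI

        n_translating = int(round(translating_fraction * mrna_per_cell))
        translating = np.zeros(mrna_per_cell, dtype=bool)
        translating[:n_translating] = True
        rng.shuffle(translating)
        for k in range(mrna_per_cell):
            # uniform position in the cytoplasmic annulus
            r = np.sqrt(rng.uniform(
                (nucleus_radius_px + 3) ** 2, (cell_radius_px - 3) ** 2
            ))
            theta = rng.uniform(0, 2 * np.pi)
            x = cx + r * np.cos(theta)
            y = cy + r * np.sin(theta)
            z0 = rng.uniform(1.0, z_slices - 2.0)
            _add_spot_3d(stack[1], x, y, z0, spot_amplitude, psf_sigma_px,
                         psf_sigma_z, half)
            if translating[k]:
                jx, jy = rng.uniform(-0.5, 0.5, size=2)
                _add_spot_3d(stack[2], x + jx, y + jy, z0, spot_amplitude,
                             psf_sigma_px, psf_sigma_z, half)
            records.append({
                "spot_id": spot_id, "cell_id": c + 1,
                "x_px": x, "y_px": y, "z": z0,
                "translating": bool(translating[k]),
            })
            spot_id += 1
    if read_noise_sd > 0:
        stack = stack + rng.normal(0, read_noise_sd, stack.shape)
    stack = np.clip(np.round(stack), 0, 65535).astype(np.uint16)
    return stack, pd.DataFrame(records)


def _add_spot_3d(
    channel: np.ndarray, x: float, y: float, z0: float, amp: float,
    sigma_xy: float, sigma_z: float, half: int,
) -> None:
    for z in range(channel.shape[0]):
        az = amp * np.exp(-((z - z0) ** 2) / (2 * sigma_z**2))
        if az > 1e-3:
            _add_gaussian(channel[z], x, y, az, sigma_xy, half)


def truth_to_csv(particles: list[GroundTruthParticle], path: str | Path) -> None:
    """Write a truth table (particle_id, population, frame, x_px, y_px,
    true_D_um2_s) to CSV."""
    rows = []
    for p in particles:
        for frame, x, y in p.positions_px:
            rows.append({
                "particle_id": p.particle_id, "population": p.population,
                "frame": int(frame), "x_px": x, "y_px": y,
                "true_D_um2_s": p.true_D_um2_s,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def truth_from_csv(path: str | Path) -> list[GroundTruthParticle]:
    df = pd.read_csv(path, float_precision="round_trip")
    particles = []
    for pid, g in df.groupby("particle_id", sort=True):
        g = g.sort_values("frame")
        particles.append(GroundTruthParticle(
            int(pid), str(g["population"].iloc[0]),
            float(g["true_D_um2_s"].iloc[0]),
            g[["frame", "x_px", "y_px"]].to_numpy(dtype=float),
        ))
    return particles
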