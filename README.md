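# ertrack

Single-molecule image analysis of mRNA association with the endoplasmic
reticulum (ER).

When a transcript encoding a secretory or membrane protein is translated,
the nascent chain targets the ribosome-mRNA complex to the ER surface.
In dual-channel live-cell movies (one channel imaging single labeled
mRNA particles, the other a fluorescent ER marker), this recruitment is
visible as particles that move slowly and stay on the ER network.
`ertrack` quantifies that behavior for cell biologists doing
single-particle tracking: it detects and tracks diffraction-limited
spots, scores each track against the ER geometry, classifies tracks as
ER-associated or free, and summarizes per cell. Companion modules handle
bead-based dual-camera registration, fixed-cell smFISH-IF colocalization
(fraction of mRNAs with an active translation site), and quantification
of GFP foci such as those formed by overexpressed IRE1α-GFP.

Because raw microscopy datasets are large, the package ships a
ground-truthed synthetic-microscopy generator that emulates the
acquisitions (20 Hz, 100-frame movies, 0.134 µm pixels, an ER-like
tubular network, two diffusive particle populations, Poisson + read
noise), so the entire pipeline is testable end to end against known
truth.

## The statistics

For each track of at least 30 frames:

- **Instantaneous diffusion coefficient (IDC).** With positions
  $\mathbf{r}_t$ sampled at interval $\Delta t$, the lag-1 mean squared
  displacement gives, via the 2D Brownian relation
  $\mathrm{MSD} = 4D\Delta t$,

  $$\hat D = \frac{1}{4\Delta t}\;\overline{\lVert \mathbf{r}_{t+1}-\mathbf{r}_t \rVert^2}\quad[\mu m^2/s].$$

- **Cumulative ER localization index.** The ER channel is segmented to
  a binary mask and converted to a signed Euclidean distance map
  $S(\mathbf{p})$: positive on the ER (distance to the nearest
  background pixel), negative off it (minus the distance to the nearest
  ER pixel). The index is $\sum_t S(\mathbf{r}_t)$; positive values mean
  net ER residence.

- **Classification.** A track is ER-associated iff
  $\hat D < 0.06\ \mu m^2 s^{-1}$ **and** index $> 0$ — cut-offs that
  delimit the slow, ER-resident cluster of a secretory control
  transcript. Per cell, the ER-associated fraction is computed over
  tracks ≥ 30 frames, for cells with ≥ 3 such tracks.

The smFISH-IF analysis max-projects z-stacks, detects mRNA and
translation-site spots with a scale-normalized Laplacian-of-Gaussian
detector (subpixel quadratic refinement), and pairs them as mutual
nearest neighbors within 3 px. Foci analysis counts a cell as
foci-containing when ≥ 1% of its GFP signal lies in connected regions
≥ 5-fold above the cell's median intensity.

## Worked example

Analyze four synthetic cells in which 30% of particles are ER-tethered
(D = 0.01 µm²/s on the ER) and the rest diffuse freely (D = 0.3 µm²/s):

```bash
$ ertrack live --synthetic --seed 11 --n-cells 4 --f-tethered 0.3 --out-dir demo
 cell_id  n_eligible  n_associated  fraction_er_associated
       1          51            15                0.294118
       2          52            15                0.288462
       3          52            14                0.269231
       4          54            15                0.277778
```

Each row is one cell: `n_eligible` tracks lasted ≥ 30 frames,
`n_associated` of them passed both cut-offs, and the fraction recovers
the simulated 0.3 within a few percent. `demo/` also receives the full
tracks table, per-track metrics (IDC, cumulative index, classification),
a diffusion-vs-index scatter plot, and the resolved configuration used.

The same workflow runs on real data: `ertrack register` fits the
dual-camera affine from TetraSpeck bead images, and `ertrack live`
accepts multi-page TIFF movies (particle + ER channels). See also
`ertrack fish` and `ertrack foci`.

Library use mirrors the CLI:

```python
from ertrack import PipelineConfig, run_live

summary = run_live(PipelineConfig(seed=11),
                   synthetic_spec={"n_cells": 4, "f_tethered": 0.3},
                   out_dir="demo")
```

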