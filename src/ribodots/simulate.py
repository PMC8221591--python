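"""Ground-truthed synthetic inputs for every downstream stage.

Three generators mirror the three data streams of the study:

* :func:`simulate_scene` — a multichannel fluorescence field with
  diffraction-limited hybridization dots (isotropic 2D Gaussians, the standard
  smFISH point-spread proxy) over a noisy background, plus filled Pvalb+ cell
  bodies, with full ground truth (dot centres, integrated intensities, cell
  labels, which cells co-express the dot transcript).
* :func:`simulate_ct_table` — a long-format qPCR CT table with designed group
  effects on target genes, a designed countervailing housekeeping pair, shared
  per-sample loading effects, and technical replicates.
* :func:`simulate_sleep_series` — binary sleep/wake interval scores.

The scene generative model at zero noise is exactly the model the dot
quantifier assumes, so exact-recovery tests are possible.  Everything is
deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import SleepRecord
from .io import PixelCalibration, Scene

__all__ = [
    "SceneParams",
    "SceneTruth",
    "simulate_scene",
    "GeneSpec",
    "CtPanel",
    "CtTruth",
    "default_panel",
    "simulate_ct_table",
    "simulate_sleep_series",
]


# ---------------------------------------------------------------------------
# imaging scenes
# ---------------------------------------------------------------------------

@dataclass
class SceneParams:
    """Knobs of the synthetic scene.

    SNR is defined as (peak pixel value) / background, so a dot of SNR *s* adds
    ``(s - 1) * background`` at its peak.  Dots are isotropic Gaussians of
    ``dot_sigma_um``; cells are filled disks rendered into the Pvalb channel.
    A fraction of cells is designated IEG-positive and receives
    ``dots_per_positive_cell`` dots inside the soma; remaining dots fall in the
    surrounding neuropil.
    """

    shape: tuple[int, int] = (1024, 1024)
    microns_per_pixel: float = 0.25
    background: float = 20.0
    noise_sigma: float = 2.0
    noise_model: str = "gaussian"  # or "poisson"
    dot_sigma_um: float = 0.5
    n_dots: int = 200
    dot_snr: float = 4.0
    dot_channel: str = "Arc"
    n_cells: int = 12
    cell_radius_um: float = 5.0
    cell_snr: float = 4.0
    pvalb_channel: str = "Pvalb"
    frac_ieg_positive_cells: float = 0.3
    dots_per_positive_cell: int = 5
    max_overlap_fraction: float = 0.05
    region_name: str = "CTX"

    def __post_init__(self) -> None:
        if self.background < 0:
            raise ValueError("background must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_dots > 0 and self.dot_snr < 1:
            raise ValueError("dot SNR = peak/background must be >= 1")
        if self.n_cells > 0 and self.cell_snr < 1:
            raise ValueError("cell SNR must be >= 1")
        if not (0 <= self.frac_ieg_positive_cells <= 1):
            raise ValueError("frac_ieg_positive_cells must be in [0, 1]")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        sigma_px = self.dot_sigma_um / self.microns_per_pixel
        margin = 4.0 * sigma_px
        h, w = self.shape
        if 2 * margin >= min(h, w):
            raise ValueError("image too small for dot size: dots would fall outside")
        # expected fraction of dots with another centre within 4 sigma,
        # under uniform placement (Poisson approximation)
        area_px = h * w
        if self.n_dots > 1:
            rho = (self.n_dots - 1) / area_px
            frac = 1.0 - math.exp(-rho * math.pi * (4 * sigma_px) ** 2)
            if frac > self.max_overlap_fraction:
                raise ValueError(
                    f"expected dot-overlap fraction {frac:.3f} exceeds limit "
                    f"{self.max_overlap_fraction}; enlarge the image or reduce n_dots"
                )


@dataclass
class SceneTruth:
    """Ground truth of a simulated scene."""

    dot_centers: np.ndarray            # (n, 2) row, col in pixels
    dot_intensities: np.ndarray        # (n,) integrated intensity per dot (a.u.)
    dot_channel: str
    background: float
    noise_sigma: float
    cell_labels: np.ndarray            # int label image, 0 = background
    ieg_positive_cells: np.ndarray     # labels of cells containing dots
    n_dots_in_region: dict[str, int]
    dot_sigma_px: float


def _render_gaussian_dots(
    img: np.ndarray, centers: np.ndarray, amplitudes: np.ndarray, sigma_px: float
) -> None:
    """Add 2D Gaussian dots in place; ``amplitudes`` are integrated intensities."""
    h, w = img.shape
    r = int(math.ceil(4 * sigma_px))
    for (cy, cx), amp in zip(centers, amplitudes):
        y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
        x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        g = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma_px**2)))
        img[y0:y1, x0:x1] += amp * g / (2 * math.pi * sigma_px**2)


def simulate_scene(
    params: SceneParams | None = None, seed: int = 0
) -> tuple[Scene, SceneTruth]:
    """Render a calibrated scene and return it with its ground truth.

    The dot channel is ``background + sum of Gaussian dots + noise``; the
    Pvalb channel is ``background + filled cell disks + noise``.  IEG-positive
    cells receive dots inside their soma so co-expression overlap has a known
    truth.  Deterministic under ``seed``.
    """
    p = params if params is not None else SceneParams()
    rng = np.random.default_rng(seed)
    h, w = p.shape
    mpp = p.microns_per_pixel
    sigma_px = p.dot_sigma_um / mpp
    margin = 4.0 * sigma_px + 1.0

    # --- cells ------------------------------------------------------------
    cell_labels = np.zeros((h, w), dtype=np.int32)
    cell_centers: list[tuple[float, float]] = []
    r_px = p.cell_radius_um / mpp
    if p.n_cells > 0:
        tries = 0
        while len(cell_centers) < p.n_cells and tries < 20000:
            tries += 1
            cy = rng.uniform(r_px + margin, h - r_px - margin)
            cx = rng.uniform(r_px + margin, w - r_px - margin)
            if all((cy - y) ** 2 + (cx - x) ** 2 > (2.5 * r_px) ** 2
                   for y, x in cell_centers):
                cell_centers.append((cy, cx))
        if len(cell_centers) < p.n_cells:
            raise ValueError("could not place cells without overlap; reduce n_cells")
        yy, xx = np.mgrid[0:h, 0:w]
        for i, (cy, cx) in enumerate(cell_centers, start=1):
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
            cell_labels[disk] = i

    n_pos = int(round(p.frac_ieg_positive_cells * len(cell_centers)))
    pos_cells = rng.permutation(len(cell_centers))[:n_pos] + 1 if n_pos else np.empty(0, int)

    # --- dot placement ----------------------------------------------------
    centers = []
    n_in_cells = min(p.n_dots, n_pos * p.dots_per_positive_cell)
    per_cell = np.zeros(n_pos, dtype=int)
    for k in range(n_in_cells):
        per_cell[k % max(n_pos, 1)] += 1
    for lab, k in zip(pos_cells, per_cell):
        cy, cx = cell_centers[lab - 1]
        for _ in range(k):
            ang = rng.uniform(0, 2 * math.pi)
            rad = 0.7 * r_px * math.sqrt(rng.uniform())
            centers.append((cy + rad * math.sin(ang), cx + rad * math.cos(ang)))
    while len(centers) < p.n_dots:
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        if cell_labels[int(cy), int(cx)] == 0:
            centers.append((cy, cx))
    centers_arr = np.asarray(centers, dtype=float).reshape(-1, 2)

    peak_excess = (p.dot_snr - 1.0) * p.background if p.background > 0 else p.dot_snr
    amp = peak_excess * 2 * math.pi * sigma_px**2  # integrated intensity per dot
    amplitudes = np.full(len(centers_arr), float(amp))

    dot_img = np.full((h, w), float(p.background))
    _render_gaussian_dots(dot_img, centers_arr, amplitudes, sigma_px)

    pvalb_img = np.full((h, w), float(p.background))
    if p.n_cells > 0:
        cell_excess = (p.cell_snr - 1.0) * p.background if p.background > 0 else p.cell_snr
        pvalb_img[cell_labels > 0] += cell_excess

    def _noisy(img: np.ndarray) -> np.ndarray:
        if p.noise_model == "poisson":
            return rng.poisson(np.clip(img, 0, None)).astype(float)
        if p.noise_sigma > 0:
            return img + rng.normal(0.0, p.noise_sigma, img.shape)
        return img

    channels = {p.dot_channel: _noisy(dot_img)}
    if p.n_cells > 0:
        channels[p.pvalb_channel] = _noisy(pvalb_img)

    region_labels = np.ones((h, w), dtype=np.int32)
    scene = Scene(
        channels=channels,
        calibration=PixelCalibration(mpp),
        region_labels=region_labels,
        region_names={p.region_name: 1},
        cell_labels=cell_labels,
    )
    truth = SceneTruth(
        dot_centers=centers_arr,
        dot_intensities=amplitudes,
        dot_channel=p.dot_channel,
        background=p.background,
        noise_sigma=p.noise_sigma,
        cell_labels=cell_labels,
        ieg_positive_cells=np.sort(np.asarray(pos_cells, dtype=int)),
        n_dots_in_region={p.region_name: int(len(centers_arr))},
        dot_sigma_px=sigma_px,
    )
    return scene, truth


# ---------------------------------------------------------------------------
# qPCR CT tables
# ---------------------------------------------------------------------------

@dataclass
class GeneSpec:
    """One gene of a simulated panel.

    ``group_effect`` is the cycles added to CT in the sleep-deprived group;
    for a target gene it equals the true ddCT (so true log2 fold change is
    ``-group_effect``).
    """

    name: str
    baseline_ct: float
    group_effect: float = 0.0
    role: str = "target"  # "target" or "reference"
    stability: str = "stable"  # "stable" | "countervailing" | "unstable"


@dataclass
class CtPanel:
    """Gene panel plus noise structure of a simulated qPCR experiment."""

    genes: list[GeneSpec]
    noise_sigma: float = 0.15      # biological gene x sample noise (cycles)
    replicate_sigma: float = 0.05  # technical replicate noise (cycles)
    sample_sigma: float = 0.30     # per-sample loading effect shared by genes
    region: str = "CTX"
    fraction: str = "IP"

    def __post_init__(self) -> None:
        if min(self.noise_sigma, self.replicate_sigma, self.sample_sigma) < 0:
            raise ValueError("noise sigmas must be >= 0")
        if not self.genes:
            raise ValueError("panel needs at least one gene")


@dataclass
class CtTruth:
    """Ground truth of a simulated CT table."""

    ddct_true: dict[str, float]        # per-gene true ddCT (SD - sleep), cycles
    stability_class: dict[str, str]
    designed_pair: tuple[str, str] | None
    noise_sigma: float
    replicate_sigma: float
    sample_sigma: float


def default_panel() -> CtPanel:
    """The reference study conditions: Table-2-style targets, six candidates.

    Target baselines and effects follow the printed 3-h cortex means.  The
    housekeeping candidates comprise one countervailing pair (+-0.15 cycles)
    plus four unstable genes.  Because a group shift common to every gene of a
    sample is absorbed by the loading term, intergroup differences are
    identifiable only relative to the candidate-panel average; the candidate
    effects therefore sum to zero, and the non-pair effects are arranged so no
    other pair of well-ranked candidates cancels.
    """
    genes = [
        GeneSpec("Arc", 5.16, -1.26, "target", "unstable"),
        GeneSpec("Homer1a", 5.11, -1.06, "target", "unstable"),
        GeneSpec("Bdnf", 5.02, -0.48, "target", "unstable"),
        GeneSpec("Clock", 3.95, -0.19, "target", "unstable"),
        GeneSpec("Actg1", 18.0, +0.15, "reference", "countervailing"),
        GeneSpec("Hprt1", 20.0, -0.15, "reference", "countervailing"),
        GeneSpec("Gapdh", 16.0, +0.50, "reference", "unstable"),
        GeneSpec("Tuba4a", 17.0, +0.70, "reference", "unstable"),
        GeneSpec("Pgk1", 19.0, +0.90, "reference", "unstable"),
        GeneSpec("Tbp", 22.0, -2.10, "reference", "unstable"),
    ]
    return CtPanel(genes=genes)


def simulate_ct_table(
    panel: CtPanel | None = None,
    n_per_group: int | tuple[int, int] = 5,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, CtTruth]:
    """Simulate a long-format CT table.

    CT = baseline + group_effect * 1[SD] + sample loading + biological noise
    + replicate noise.  The loading term is shared by every gene of a sample,
    so it cancels under housekeeping normalization.  Returns the table and the
    truth.  ``n_per_group`` may be an int or a (n_sleep, n_sd) pair; both must
    be >= 2.
    """
    p = panel if panel is not None else default_panel()
    if isinstance(n_per_group, int):
        n_sleep = n_sd = n_per_group
    else:
        n_sleep, n_sd = n_per_group
    if min(n_sleep, n_sd) < 2:
        raise ValueError("need at least 2 samples per group")
    if n_replicates < 1:
        raise ValueError("need at least 1 technical replicate")
    rng = np.random.default_rng(seed)

    rows = []
    sample_id = 0
    for group, n in (("sleep", n_sleep), ("SD", n_sd)):
        for _ in range(n):
            sample_id += 1
            sid = f"{group}_{sample_id:02d}"
            loading = rng.normal(0.0, p.sample_sigma)
            for g in p.genes:
                mu = g.baseline_ct + (g.group_effect if group == "SD" else 0.0)
                bio = rng.normal(0.0, p.noise_sigma)
                for rep in range(1, n_replicates + 1):
                    ct = mu + loading + bio + rng.normal(0.0, p.replicate_sigma)
                    rows.append(
                        (g.name, sid, group, p.region, p.fraction, rep, ct)
                    )
    table = pd.DataFrame(
        rows,
        columns=["gene", "sample", "group", "region", "fraction", "replicate", "CT"],
    )
    pair_genes = [g.name for g in p.genes if g.stability == "countervailing"]
    designed_pair = tuple(pair_genes[:2]) if len(pair_genes) >= 2 else None
    truth = CtTruth(
        ddct_true={g.name: g.group_effect for g in p.genes},
        stability_class={g.name: g.stability for g in p.genes},
        designed_pair=designed_pair,
        noise_sigma=p.noise_sigma,
        replicate_sigma=p.replicate_sigma,
        sample_sigma=p.sample_sigma,
    )
    return table, truth


# ---------------------------------------------------------------------------
# sleep scoring
# ---------------------------------------------------------------------------

def simulate_sleep_series(
    duration_min: int,
    bin_min: int = 5,
    p_sleep: float = 0.75,
    seed: int = 0,
    group: str = "sleep",
) -> SleepRecord:
    """Simulate visually scored sleep/wake bins (i.i.d. Bernoulli per bin)."""
    if duration_min <= 0 or bin_min <= 0:
        raise ValueError("duration and bin length must be positive")
    if duration_min % bin_min != 0:
        raise ValueError(
            f"duration {duration_min} min is not a multiple of bin length {bin_min} min"
        )
    if not (0.0 <= p_sleep <= 1.0):
        raise ValueError("p_sleep must be a probability")
    rng = np.random.default_rng(seed)
    n = duration_min // bin_min
    states = np.where(rng.uniform(size=n) < p_sleep, "sleep", "wake")
    starts = np.arange(n) * bin_min
    lengths = np.full(n, bin_min)
    return SleepRecord(starts=starts, lengths=lengths, states=states, group=group)
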