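"""Semi-automated in-situ hybridization quantification.

The protocol: denoise each channel with a non-local means filter; find
expression components with an adaptive threshold (connected areas whose mean
intensity is at least ``threshold_ratio`` — 200% by default — of their local
surroundings, above a minimum area); partition each anatomical region into
Pvalb+ cell ROIs and the non-Pvalb+ remainder; estimate per-ROI background
from ROI pixels outside every labeled expression area; calibrate the
integrated intensity of a single hybridization dot from representative
isolated dots; and estimate the total dot number of an ROI as its
background-corrected total intensity divided by the single-dot intensity.
Because every threshold is a ratio, all estimates are invariant to a global
intensity rescaling.

Dot counts are real-valued by construction (they are intensity ratios, not
object counts), which lets the estimator count transcripts inside dense
clusters where discrete spots merge.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter
from scipy.spatial import cKDTree
from skimage import measure, morphology
from skimage.restoration import denoise_nl_means, estimate_sigma
from sklearn.base import BaseEstimator
from statsmodels.distributions.empirical_distribution import ECDF

from .io import PixelCalibration, Scene

__all__ = [
    "Component",
    "OverlapResult",
    "denoise",
    "detect_components",
    "classify_rois",
    "estimate_background",
    "select_representative_dots",
    "calibrate_single_dot",
    "count_dots",
    "dots_per_area",
    "overlap_metrics",
    "per_cell_intensity",
    "DotQuantifier",
]


@dataclass
class Component:
    """One connected expression area (a dot, a cell body, or an artifact)."""

    rows: np.ndarray
    cols: np.ndarray
    area_um2: float
    total_intensity: float
    mean_intensity: float
    centroid: tuple[float, float]
    channel: str = ""
    label: str = "expression-dot"
    id: int = 0

    @property
    def n_pixels(self) -> int:
        return len(self.rows)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.rows, self.cols] = True
        return m


def denoise(
    plane: np.ndarray,
    patch_size: int = 5,
    patch_distance: int = 6,
    h: float | None = None,
    sigma: float | None = None,
    h_factor: float = 0.8,
) -> np.ndarray:
    """Non-local means denoising; output is same-shape and non-negative.

    The filter strength ``h`` defaults to ``h_factor`` times the estimated
    noise sigma, so a noiseless image passes through essentially unchanged and
    a constant image is a fixed point.
    """
    img = np.asarray(plane, dtype=float)
    if sigma is None:
        sigma = float(estimate_sigma(img))
    if h is None:
        h = h_factor * sigma
    if h <= 0:
        return np.clip(img, 0.0, None)
    out = denoise_nl_means(
        img, h=h, sigma=sigma, patch_size=patch_size,
        patch_distance=patch_distance, fast_mode=True, preserve_range=True,
    )
    return np.clip(out, 0.0, None)


def detect_components(
    plane: np.ndarray,
    calib: PixelCalibration,
    threshold_ratio: float = 2.0,
    min_area_um2: float = 30.0,
    surround_window_um: float = 40.0,
    mode: str = "component",
    channel: str = "",
    label: str = "expression-dot",
) -> list[Component]:
    """Adaptive-threshold detection of connected expression areas.

    Seed pixels exceed ``threshold_ratio`` times the local mean over a square
    ``surround_window_um`` window; connected seed areas larger than
    ``min_area_um2`` survive.  In the default ``"component"`` mode each
    candidate must additionally have mean intensity >= ``threshold_ratio``
    times the mean of its surround (window pixels excluding the component's
    own pixels); ``"pixel"`` mode skips the component-wise check.
    """
    if threshold_ratio <= 1:
        raise ValueError("threshold_ratio must be > 1")
    if mode not in ("component", "pixel"):
        raise ValueError(f"unknown mode {mode!r}")
    img = np.asarray(plane, dtype=float)
    win = int(round(calib.px(surround_window_um)))
    if win < 3:
        raise ValueError(
            f"surround window of {win} px is smaller than 3 px; "
            "increase surround_window_um"
        )
    local = uniform_filter(img, size=win, mode="reflect")
    seed = img > threshold_ratio * local
    labels = measure.label(seed, connectivity=2)
    out: list[Component] = []
    half = win // 2
    h, w = img.shape
    for rp in measure.regionprops(labels, intensity_image=img):
        area = calib.area_um2(rp.area)
        if not area > min_area_um2:
            continue
        rows, cols = rp.coords[:, 0], rp.coords[:, 1]
        mean_in = float(rp.intensity_mean)
        if mode == "component":
            r0, c0, r1, c1 = rp.bbox
            r0, c0 = max(0, r0 - half), max(0, c0 - half)
            r1, c1 = min(h, r1 + half), min(w, c1 + half)
            window = img[r0:r1, c0:c1]
            inside = np.zeros(window.shape, dtype=bool)
            inside[rows - r0, cols - c0] = True
            surround = window[~inside]
            if surround.size:
                mean_surround = float(surround.mean())
                if mean_surround > 0 and not mean_in >= threshold_ratio * mean_surround:
                    continue
        out.append(
            Component(
                rows=rows, cols=cols, area_um2=area,
                total_intensity=float(img[rows, cols].sum()),
                mean_intensity=mean_in,
                centroid=tuple(rp.centroid), channel=channel, label=label,
                id=len(out) + 1,
            )
        )
    return out


def components_from_labels(
    label_image: np.ndarray,
    plane: np.ndarray,
    calib: PixelCalibration,
    channel: str = "",
    label: str = "Pvalb-cell",
) -> list[Component]:
    """Wrap an integer label mask (e.g. ground-truth cells) as components."""
    img = np.asarray(plane, dtype=float)
    out = []
    for rp in measure.regionprops(label_image, intensity_image=img):
        rows, cols = rp.coords[:, 0], rp.coords[:, 1]
        out.append(
            Component(
                rows=rows, cols=cols, area_um2=calib.area_um2(rp.area),
                total_intensity=float(img[rows, cols].sum()),
                mean_intensity=float(rp.intensity_mean),
                centroid=tuple(rp.centroid), channel=channel, label=label,
                id=int(rp.label),
            )
        )
    return out


@dataclass
class RoiPartition:
    """Exact partition of one region into Pvalb+ cells and the remainder."""

    region: str
    pvalb_mask: np.ndarray       # union of cell pixels inside the region
    non_pvalb_mask: np.ndarray   # region pixels minus cell pixels
    cells: list[Component]       # per-cell components clipped to the region
    warnings: list[str] = field(default_factory=list)


def classify_rois(
    pvalb_cells: list[Component],
    scene: Scene,
) -> dict[str, RoiPartition]:
    """Partition each named region into Pvalb+ ROIs and a non-Pvalb+ ROI.

    The non-Pvalb+ ROI is exactly the region pixels minus all cell pixels, so
    Pvalb+ area + non-Pvalb+ area = region area.  An empty region yields a
    warning record with empty masks.
    """
    shape = scene.shape
    cell_union = np.zeros(shape, dtype=bool)
    for c in pvalb_cells:
        cell_union[c.rows, c.cols] = True
    out: dict[str, RoiPartition] = {}
    for name in scene.region_names:
        region = scene.region_mask(name)
        warn: list[str] = []
        if not region.any():
            warn.append(f"region {name!r} is empty")
            out[name] = RoiPartition(
                region=name, pvalb_mask=np.zeros(shape, bool),
                non_pvalb_mask=np.zeros(shape, bool), cells=[], warnings=warn,
            )
            continue
        cells_in = []
        for c in pvalb_cells:
            keep = region[c.rows, c.cols]
            if not keep.any():
                continue
            rows, cols = c.rows[keep], c.cols[keep]
            cells_in.append(
                Component(
                    rows=rows, cols=cols,
                    area_um2=scene.calibration.area_um2(len(rows)),
                    total_intensity=float("nan"),
                    mean_intensity=float("nan"),
                    centroid=(float(rows.mean()), float(cols.mean())),
                    channel=c.channel, label="Pvalb-cell", id=c.id,
                )
            )
        out[name] = RoiPartition(
            region=name,
            pvalb_mask=region & cell_union,
            non_pvalb_mask=region & ~cell_union,
            cells=cells_in,
            warnings=warn,
        )
    return out


def estimate_background(
    plane: np.ndarray,
    roi_mask: np.ndarray,
    labeled_mask: np.ndarray | None = None,
) -> float:
    """Mean per-pixel intensity of the ROI outside labeled expression areas."""
    img = np.asarray(plane, dtype=float)
    support = roi_mask if labeled_mask is None else roi_mask & ~labeled_mask
    n = int(support.sum())
    if n == 0:
        raise ValueError("labeled expression covers the ROI entirely; no background support")
    return float(img[support].mean())


def select_representative_dots(
    components: list[Component],
    calib: PixelCalibration,
    isolation_factor: float = 2.0,
    min_dots: int = 3,
) -> list[Component]:
    """Automatic stand-in for manually picked representative dots.

    Keeps components with no neighbour centroid within ``isolation_factor``
    equivalent diameters and area inside the central 50% of the component-area
    distribution; falls back to the isolated set, then to all components, if
    too few survive.  Explicit manual id lists can be passed straight to
    :func:`calibrate_single_dot` instead.
    """
    if not components:
        return []
    if len(components) == 1:
        return list(components)
    cents = np.array([c.centroid for c in components])
    diam_px = np.array(
        [2.0 * math.sqrt(c.n_pixels / math.pi) for c in components]
    )
    tree = cKDTree(cents)
    dist, idx = tree.query(cents, k=2)
    nn = dist[:, 1]
    pair_diam = np.maximum(diam_px, diam_px[idx[:, 1]])
    isolated = [c for c, d, pd_ in zip(components, nn, pair_diam)
                if d > isolation_factor * pd_]
    pool = isolated if len(isolated) >= min_dots else list(components)
    areas = np.array([c.area_um2 for c in pool])
    lo, hi = np.percentile(areas, [25, 75])
    central = [c for c in pool if lo <= c.area_um2 <= hi]
    return central if len(central) >= min_dots else pool


def calibrate_single_dot(
    plane: np.ndarray,
    selected_dots: list[Component],
    background_mean: float,
    dilation_px: int = 0,
) -> float:
    """Average integrated intensity of a single hybridization dot.

    D = (sum of selected-dot pixel intensities - background * total pixel
    area) / number of dots.  ``dilation_px`` grows each dot mask by a disk so
    point-spread tails outside the thresholded core are integrated too (the
    extra background is removed by the area term).  Raises if D <= 0.
    """
    if not selected_dots:
        raise ValueError("need at least one selected dot")
    img = np.asarray(plane, dtype=float)
    h, w = img.shape
    total, n_px = 0.0, 0
    selem = morphology.disk(dilation_px) if dilation_px > 0 else None
    for c in selected_dots:
        if selem is None:
            total += float(img[c.rows, c.cols].sum())
            n_px += c.n_pixels
        else:
            r0 = max(0, c.rows.min() - dilation_px)
            r1 = min(h, c.rows.max() + dilation_px + 1)
            c0 = max(0, c.cols.min() - dilation_px)
            c1 = min(w, c.cols.max() + dilation_px + 1)
            local = np.zeros((r1 - r0, c1 - c0), dtype=bool)
            local[c.rows - r0, c.cols - c0] = True
            local = morphology.dilation(local, selem)
            total += float(img[r0:r1, c0:c1][local].sum())
            n_px += int(local.sum())
    d = (total - background_mean * n_px) / len(selected_dots)
    if d <= 0:
        raise ValueError(
            "background exceeds dot signal; single-dot calibration invalid"
        )
    return float(d)


def count_dots(
    plane: np.ndarray,
    roi_mask: np.ndarray,
    background_mean: float,
    single_dot_intensity: float,
) -> float:
    """Total dot number of an ROI: background-corrected intensity / dot intensity.

    N = (sum of ROI intensities - background * ROI pixel area) / D, floored at
    0 with a warning for negative numerators; fractional values are retained.
    """
    if not single_dot_intensity > 0:
        raise ValueError("single_dot_intensity must be > 0")
    img = np.asarray(plane, dtype=float)
    numer = float(img[roi_mask].sum()) - background_mean * int(roi_mask.sum())
    if numer < 0:
        warnings.warn("ROI intensity below background; clamping dot count to 0")
        return 0.0
    return numer / single_dot_intensity


def dots_per_area(
    total_dot_number: float, roi_area_um2: float, unit: str = "mm2"
) -> float:
    """Dot density in dots/mm^2 (default) or dots/um^2."""
    if not roi_area_um2 > 0:
        raise ValueError("ROI area must be > 0")
    per_um2 = total_dot_number / roi_area_um2
    if unit in ("um2", "µm2", "um^2"):
        return per_um2
    if unit in ("mm2", "mm^2"):
        return per_um2 * 1e6
    raise ValueError(f"unknown unit {unit!r}")


@dataclass
class OverlapResult:
    """Co-expression of an IEG within Pvalb+ cells, by count and by area."""

    n_pvalb_cells: int
    n_ieg_pos_pvalb_cells: int
    proportion_by_count: float
    overlap_area_um2: float
    proportion_by_area: float
    positive_cell_ids: list[int]


def overlap_metrics(
    pvalb_cells: list[Component],
    ieg_components: list[Component],
    shape: tuple[int, int],
    calib: PixelCalibration,
    min_overlap_fraction: float = 0.0,
) -> OverlapResult:
    """Mark Pvalb+ cells as IEG+ when IEG pixels overlap them.

    A cell is IEG+ iff the fraction of its pixels covered by IEG components
    strictly exceeds ``min_overlap_fraction`` (default: any overlap).
    ``proportion_by_area`` is the summed area of IEG+ cells over the total
    Pvalb+ cell area; with zero cells the proportions are NaN.
    """
    ieg_mask = np.zeros(shape, dtype=bool)
    for c in ieg_components:
        ieg_mask[c.rows, c.cols] = True
    n_cells = len(pvalb_cells)
    if n_cells == 0:
        return OverlapResult(0, 0, float("nan"), 0.0, float("nan"), [])
    pos_ids, pos_area, overlap_px = [], 0.0, 0
    total_area = sum(c.area_um2 for c in pvalb_cells)
    for c in pvalb_cells:
        inter = int(ieg_mask[c.rows, c.cols].sum())
        overlap_px += inter
        if c.n_pixels and inter / c.n_pixels > min_overlap_fraction:
            pos_ids.append(c.id)
            pos_area += c.area_um2
    return OverlapResult(
        n_pvalb_cells=n_cells,
        n_ieg_pos_pvalb_cells=len(pos_ids),
        proportion_by_count=len(pos_ids) / n_cells,
        overlap_area_um2=calib.area_um2(overlap_px),
        proportion_by_area=(pos_area / total_area) if total_area > 0 else float("nan"),
        positive_cell_ids=pos_ids,
    )


def per_cell_intensity(
    plane: np.ndarray,
    pvalb_cells: list[Component],
    background_mean: float,
) -> tuple[pd.DataFrame, ECDF]:
    """Background-corrected mean Pvalb intensity per cell, plus its ECDF.

    Doubling all pixel values (and the background with them) doubles every
    cell mean — the measure is linear in the image.
    """
    if not pvalb_cells:
        raise ValueError("need at least one Pvalb+ cell")
    img = np.asarray(plane, dtype=float)
    rows = [
        {
            "cell_id": c.id,
            "mean_intensity": float(img[c.rows, c.cols].mean()) - background_mean,
            "area_um2": c.area_um2,
        }
        for c in pvalb_cells
    ]
    df = pd.DataFrame(rows)
    return df, ECDF(df["mean_intensity"].to_numpy())


class DotQuantifier(BaseEstimator):
    """End-to-end dot quantification of one scene, estimator-style.

    ``fit`` runs detection and calibration on a :class:`~ribodots.io.Scene`:
    it finds Pvalb+ cells (from the Pvalb channel, or the scene's cell-label
    mask when ``use_cell_labels``), detects hybridization dots per channel,
    estimates per-ROI backgrounds and the per-channel single-dot intensity,
    and stores the per-ROI quantification.  ``transform`` returns the tidy
    per-ROI table (region x roi_class x channel with area, background, dot
    intensity, dot count and density); ``overlap_table`` and
    ``cell_intensity_table`` expose the co-expression and per-cell Pvalb
    intensity read-outs.
    """

    def __init__(
        self,
        pvalb_channel: str = "Pvalb",
        channels: list[str] | None = None,
        threshold_ratio: float = 2.0,
        min_cell_area_um2: float = 30.0,
        min_dot_area_um2: float = 0.2,
        surround_window_um: float = 40.0,
        dot_dilation_um: float = 1.0,
        denoise: bool = True,
        overlap_min_fraction: float = 0.0,
        area_unit: str = "mm2",
        use_cell_labels: bool = False,
    ):
        self.pvalb_channel = pvalb_channel
        self.channels = channels
        self.threshold_ratio = threshold_ratio
        self.min_cell_area_um2 = min_cell_area_um2
        self.min_dot_area_um2 = min_dot_area_um2
        self.surround_window_um = surround_window_um
        self.dot_dilation_um = dot_dilation_um
        self.denoise = denoise
        self.overlap_min_fraction = overlap_min_fraction
        self.area_unit = area_unit
        self.use_cell_labels = use_cell_labels

    # -- helpers -----------------------------------------------------------

    def _plane(self, scene: Scene, channel: str) -> np.ndarray:
        img = np.asarray(scene.channels[channel], dtype=float)
        if self.denoise:
            img = denoise(img)
        return img

    # -- estimator API -----------------------------------------------------

    def fit(self, X: Scene, y=None) -> "DotQuantifier":
        scene = X
        calib = scene.calibration
        dot_channels = self.channels
        if dot_channels is None:
            dot_channels = [c for c in scene.channel_names if c != self.pvalb_channel]
        if not dot_channels:
            raise ValueError("no dot channels to quantify")

        planes = {ch: self._plane(scene, ch) for ch in dot_channels}

        # Pvalb+ cells
        if self.use_cell_labels and scene.cell_labels is not None:
            ref_plane = (
                self._plane(scene, self.pvalb_channel)
                if self.pvalb_channel in scene.channels
                else next(iter(planes.values()))
            )
            cells = components_from_labels(
                scene.cell_labels, ref_plane, calib, channel=self.pvalb_channel
            )
        elif self.pvalb_channel in scene.channels:
            pv_plane = self._plane(scene, self.pvalb_channel)
            cells = detect_components(
                pv_plane, calib, self.threshold_ratio, self.min_cell_area_um2,
                self.surround_window_um, channel=self.pvalb_channel,
                label="Pvalb-cell",
            )
        else:
            cells = []
        self.cells_ = cells
        self.partitions_ = classify_rois(cells, scene)

        dil_px = int(round(calib.px(self.dot_dilation_um)))
        rows, overlaps, cell_rows = [], [], []
        self.components_: dict[str, list[Component]] = {}
        self.background_: dict[tuple[str, str, str], float] = {}
        self.single_dot_intensity_: dict[tuple[str, str], float] = {}
        self.warnings_: list[str] = []

        for ch in dot_channels:
            plane = planes[ch]
            dots = detect_components(
                plane, calib, self.threshold_ratio, self.min_dot_area_um2,
                self.surround_window_um, channel=ch,
            )
            self.components_[ch] = dots
            dot_mask = np.zeros(scene.shape, dtype=bool)
            for c in dots:
                dot_mask[c.rows, c.cols] = True
            if dil_px > 0 and dots:
                dot_mask = morphology.dilation(dot_mask, morphology.disk(dil_px))

            for region, part in self.partitions_.items():
                for roi_class, roi_mask in (
                    ("Pvalb+", part.pvalb_mask),
                    ("non-Pvalb+", part.non_pvalb_mask),
                ):
                    row = {
                        "region": region, "roi_class": roi_class, "channel": ch,
                        "roi_area_um2": calib.area_um2(int(roi_mask.sum())),
                    }
                    if not roi_mask.any():
                        self.warnings_.append(
                            f"empty ROI {region}/{roi_class}; row flagged missing"
                        )
                        row.update(
                            background_mean=np.nan, single_dot_intensity=np.nan,
                            total_dot_number=np.nan, dots_per_area=np.nan,
                        )
                        rows.append(row)
                        continue
                    support = roi_mask & ~dot_mask
                    if not support.any():
                        self.warnings_.append(
                            f"no background support in {region}/{roi_class}/{ch}"
                        )
                        row.update(
                            background_mean=np.nan, single_dot_intensity=np.nan,
                            total_dot_number=np.nan, dots_per_area=np.nan,
                        )
                        rows.append(row)
                        continue
                    bg = estimate_background(plane, roi_mask, dot_mask)
                    self.background_[(region, roi_class, ch)] = bg

                    region_dots = [
                        c for c in dots
                        if roi_mask[int(round(c.centroid[0])), int(round(c.centroid[1]))]
                    ]
                    calib_dots = select_representative_dots(region_dots, calib) \
                        or select_representative_dots(dots, calib)
                    if not calib_dots:
                        self.warnings_.append(
                            f"no dots for calibration in {region}/{roi_class}/{ch}"
                        )
                        row.update(
                            background_mean=bg, single_dot_intensity=np.nan,
                            total_dot_number=0.0, dots_per_area=0.0,
                        )
                        rows.append(row)
                        continue
                    d = calibrate_single_dot(plane, calib_dots, bg, dilation_px=dil_px)
                    self.single_dot_intensity_[(region, ch)] = d
                    n = count_dots(plane, roi_mask, bg, d)
                    row.update(
                        background_mean=bg,
                        single_dot_intensity=d,
                        n_calibration_dots=len(calib_dots),
                        total_dot_number=n,
                        dots_per_area=dots_per_area(
                            n, row["roi_area_um2"], self.area_unit
                        ),
                    )
                    rows.append(row)

            ov = overlap_metrics(
                cells, dots, scene.shape, calib, self.overlap_min_fraction
            )
            overlaps.append(
                {
                    "channel": ch,
                    "n_pvalb_cells": ov.n_pvalb_cells,
                    "n_ieg_pos_pvalb_cells": ov.n_ieg_pos_pvalb_cells,
                    "proportion_by_count": ov.proportion_by_count,
                    "overlap_area_um2": ov.overlap_area_um2,
                    "proportion_by_area": ov.proportion_by_area,
                }
            )

        if cells and self.pvalb_channel in scene.channels:
            pv_plane = self._plane(scene, self.pvalb_channel)
            cell_mask = np.zeros(scene.shape, dtype=bool)
            for c in cells:
                cell_mask[c.rows, c.cols] = True
            region_all = scene.region_labels > 0
            bg_pv = estimate_background(pv_plane, region_all, cell_mask)
            df, ecdf = per_cell_intensity(pv_plane, cells, bg_pv)
            self.cell_intensity_ = df
            self.cell_intensity_ecdf_ = ecdf

        self.roi_table_ = pd.DataFrame(rows)
        self.overlap_table_ = pd.DataFrame(overlaps)
        return self

    def transform(self, X: Scene | None = None) -> pd.DataFrame:
        if not hasattr(self, "roi_table_"):
            raise RuntimeError("fit the quantifier before calling transform")
        return self.roi_table_.copy()

    def fit_transform(self, X: Scene, y=None) -> pd.DataFrame:
        return self.fit(X).transform()

    def overlap_table(self) -> pd.DataFrame:
        return self.overlap_table_.copy()

    def cell_intensity_table(self) -> pd.DataFrame:
        if not hasattr(self, "cell_intensity_"):
            raise RuntimeError("no Pvalb channel was quantified")
        return self.cell_intensity_.copy()
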