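"""Scene, mask and configuration I/O.

A *scene* is one imaged field: a set of same-shape single-channel 2D intensity
planes, a pixel-size calibration, an integer label image of anatomical regions
(hippocampal DG/CA3/CA1 or neocortical layers), and optionally an integer label
image of parvalbumin-positive (Pvalb+) cell bodies.  Images travel as
multichannel TIFF, masks as integer-label TIFF; channel and region names are
embedded as JSON in the TIFF description so round trips are self-describing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = [
    "PixelCalibration",
    "Scene",
    "RunConfig",
    "read_scene",
    "write_scene",
    "load_config",
]


@dataclass(frozen=True)
class PixelCalibration:
    """Isotropic pixel size shared by every channel of a scene."""

    microns_per_pixel: float

    def __post_init__(self) -> None:
        if not (self.microns_per_pixel > 0):
            raise ValueError(
                f"microns_per_pixel must be > 0, got {self.microns_per_pixel}"
            )

    @property
    def um2_per_px(self) -> float:
        return self.microns_per_pixel**2

    def area_um2(self, n_pixels: int | float) -> float:
        """Convert a pixel count to an area in square microns."""
        return float(n_pixels) * self.um2_per_px

    def px(self, microns: float) -> float:
        """Convert a length in microns to pixels."""
        return microns / self.microns_per_pixel


@dataclass
class Scene:
    """One imaged field with named channels and named region masks.

    ``region_labels`` is an integer image (0 = outside every region) and
    ``region_names`` maps region name -> label value.  ``cell_labels`` is an
    optional integer image of Pvalb+ cell bodies (0 = background), used when
    cells come from a ground-truth mask rather than from detection.
    """

    channels: dict[str, np.ndarray]
    calibration: PixelCalibration
    region_labels: np.ndarray
    region_names: dict[str, int]
    cell_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("Scene needs at least one channel")
        shapes = {ch: np.asarray(img).shape for ch, img in self.channels.items()}
        ref = next(iter(shapes.values()))
        if any(len(s) != 2 for s in shapes.values()):
            raise ValueError(f"channels must be 2D, got shapes {shapes}")
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if self.region_labels.shape != ref:
            raise ValueError(
                f"region mask shape {self.region_labels.shape} != image shape {ref}"
            )
        if not np.issubdtype(self.region_labels.dtype, np.integer):
            raise ValueError("region_labels must be an integer label image")
        if self.cell_labels is not None and self.cell_labels.shape != ref:
            raise ValueError(
                f"cell mask shape {self.cell_labels.shape} != image shape {ref}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def region_mask(self, name: str) -> np.ndarray:
        """Boolean mask of one named region."""
        try:
            label = self.region_names[name]
        except KeyError:
            raise KeyError(
                f"unknown region {name!r}; known: {sorted(self.region_names)}"
            ) from None
        return self.region_labels == label


def write_scene(scene: Scene, image_path: str | Path, mask_path: str | Path) -> None:
    """Write a scene as a multichannel TIFF plus a label-mask TIFF.

    Channel order and region names go into the TIFF description as JSON.
    Integer intensities round-trip bit-exactly.
    """
    image_path, mask_path = Path(image_path), Path(mask_path)
    stack = np.stack([scene.channels[ch] for ch in scene.channel_names])
    meta = {
        "channels": scene.channel_names,
        "microns_per_pixel": scene.calibration.microns_per_pixel,
    }
    tifffile.imwrite(image_path, stack, description=json.dumps(meta))
    pages = [scene.region_labels.astype(np.int32)]
    mask_meta = {
        "region_names": scene.region_names,
        "has_cell_labels": scene.cell_labels is not None,
    }
    if scene.cell_labels is not None:
        pages.append(scene.cell_labels.astype(np.int32))
    tifffile.imwrite(mask_path, np.stack(pages), description=json.dumps(mask_meta))


def _read_description(path: Path) -> dict:
    with tifffile.TiffFile(path) as tf:
        desc = tf.pages[0].description
    try:
        return json.loads(desc) if desc else {}
    except json.JSONDecodeError:
        return {}


def read_scene(
    image_path: str | Path,
    mask_path: str | Path,
    calibration: PixelCalibration | None = None,
    channel_names: list[str] | None = None,
    region_names: dict[str, int] | None = None,
) -> Scene:
    """Read a scene written by :func:`write_scene` (or equivalent files).

    ``calibration`` overrides any pixel size embedded in the image metadata;
    one of the two must be available.  Raises on image/mask shape mismatch.
    """
    image_path, mask_path = Path(image_path), Path(mask_path)
    stack = tifffile.imread(image_path)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(f"expected 2D multichannel image, got shape {stack.shape}")

    meta = _read_description(image_path)
    names = channel_names or meta.get("channels")
    if names is None:
        names = [f"c{i}" for i in range(stack.shape[0])]
    if len(names) != stack.shape[0]:
        raise ValueError(
            f"{len(names)} channel names for {stack.shape[0]} channels"
        )
    if calibration is None:
        mpp = meta.get("microns_per_pixel")
        if mpp is None:
            raise ValueError("no calibration given and none embedded in the image")
        calibration = PixelCalibration(mpp)

    masks = tifffile.imread(mask_path)
    if masks.ndim == 2:
        masks = masks[None]
    mask_meta = _read_description(mask_path)
    rnames = region_names or mask_meta.get("region_names")
    region_labels = np.asarray(masks[0])
    if not np.issubdtype(region_labels.dtype, np.integer):
        region_labels = region_labels.astype(np.int32)
    if rnames is None:
        rnames = {f"region{v}": int(v) for v in np.unique(region_labels) if v != 0}
    else:
        rnames = {str(k): int(v) for k, v in rnames.items()}
    cell_labels = None
    if masks.shape[0] > 1 and mask_meta.get("has_cell_labels", True):
        cell_labels = np.asarray(masks[1]).astype(np.int32)

    if region_labels.shape != stack.shape[1:]:
        raise ValueError(
            f"mask shape {region_labels.shape} != image shape {stack.shape[1:]}"
        )
    return Scene(
        channels={n: stack[i] for i, n in enumerate(names)},
        calibration=calibration,
        region_labels=region_labels,
        region_names=rnames,
        cell_labels=cell_labels,
    )


@dataclass
class RunConfig:
    """Tunable parameters of the quantification and screening protocol.

    Defaults encode the protocol's stated thresholds: expression areas must
    exceed 200% of their surroundings (``threshold_ratio``) over more than
    30 um^2 (``min_component_area_um2``), and sleep-group animals awake for
    more than 60% of the final 45 min are excluded.
    """

    threshold_ratio: float = 2.0
    min_component_area_um2: float = 30.0
    min_dot_area_um2: float = 0.2
    surround_window_um: float = 40.0
    dot_sigma_um: float = 0.5
    dot_dilation_um: float = 1.0
    denoise_patch_size: int = 5
    denoise_patch_distance: int = 6
    denoise_h_factor: float = 0.8
    overlap_min_fraction: float = 0.0
    exclusion_wake_threshold: float = 0.60
    exclusion_window_min: float = 45.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.threshold_ratio > 1):
            raise ValueError(
                f"threshold_ratio must be > 1, got {self.threshold_ratio}"
            )
        for name in ("min_component_area_um2", "min_dot_area_um2",
                     "surround_window_um", "dot_sigma_um",
                     "exclusion_window_min"):
            v = getattr(self, name)
            if not (v > 0):
                raise ValueError(f"{name} must be > 0, got {v}")
        if self.dot_dilation_um < 0:
            raise ValueError("dot_dilation_um must be >= 0")
        if not (0.0 <= self.overlap_min_fraction <= 1.0):
            raise ValueError(
                f"overlap_min_fraction must be in [0, 1], got {self.overlap_min_fraction}"
            )
        if not (0.0 < self.exclusion_wake_threshold < 1.0):
            raise ValueError(
                "exclusion_wake_threshold must be in (0, 1), "
                f"got {self.exclusion_wake_threshold}"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; absent keys take protocol defaults.

    An empty file yields all defaults.  Unknown keys and invariant-violating
    values raise with a descriptive message.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
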