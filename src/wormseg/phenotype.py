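"""Post-processing of soft segmentations into per-worm body endpoints.

The soft segmentation is thresholded at 0.50 into a binary mask, cleaned by
keeping the single largest connected component (one worm per channel by chip
design; eggs, debris and small larvae fall below the area floor), and
measured:

* **length** — the longest geodesic path through the skeleton of the mask
  (8-neighbour graph, axial steps weigh 1 px and diagonal steps sqrt(2)),
  scaled by the pixel size;
* **area** — foreground pixel count times the pixel area;
* **volume** — sum over foreground pixels of pixel area times the local
  channel height, a piecewise-constant function of axial position given by
  the device geometry (channels taper toward the exit in discrete layers
  referenced to the fiduciary mark).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from skimage import measure, morphology

__all__ = [
    "BinaryMask", "ChannelGeometry", "WormPhenotype", "binarize",
    "filter_components", "skeleton_length", "body_area", "body_volume",
    "infer_channel", "infer_device", "GEOMETRY_PRESETS",
]

# The two chip variants ship as YAML config files with placeholder layer
# heights/boundaries (true channel profiles are device-calibration data).
GEOMETRY_PRESETS = ("3L", "4L")


@dataclass(frozen=True)
class BinaryMask:
    """H x W boolean grid with its physical pixel size."""

    grid: np.ndarray
    pixel_size_um: float

    def __post_init__(self):
        if self.grid.ndim != 2 or 0 in self.grid.shape:
            raise ValueError("mask must be a non-empty 2-D grid")

    @property
    def area_px(self) -> int:
        return int(self.grid.sum())


@dataclass(frozen=True)
class ChannelGeometry:
    """Piecewise-constant channel-height profile along the axial direction.

    ``boundaries_um`` are the N+1 strictly increasing layer edges (um from
    the channel entrance, i.e. relative to the fiduciary-referenced origin);
    ``heights_um`` are the N layer heights, strictly decreasing toward the
    exit.
    """

    boundaries_um: tuple[float, ...]
    heights_um: tuple[float, ...]

    def __post_init__(self):
        if len(self.boundaries_um) != len(self.heights_um) + 1:
            raise ValueError("need one more boundary than layer heights")
        if np.any(np.diff(self.boundaries_um) <= 0):
            raise ValueError("layer boundaries must be strictly increasing")
        if np.any(np.diff(self.heights_um) >= 0):
            raise ValueError("layer heights must strictly decrease toward "
                             "the channel exit")

    @classmethod
    def preset(cls, name: str) -> "ChannelGeometry":
        if name not in GEOMETRY_PRESETS:
            raise KeyError(f"unknown geometry preset {name!r}; "
                           f"available: {GEOMETRY_PRESETS}")
        text = resources.files("wormseg.data").joinpath(
            f"geometry_{name}.yaml"
        ).read_text()
        cfg = yaml.safe_load(text)
        return cls(tuple(cfg["boundaries_um"]), tuple(cfg["heights_um"]))

    @classmethod
    def from_yaml(cls, path) -> "ChannelGeometry":
        cfg = yaml.safe_load(Path(path).read_text())
        return cls(tuple(cfg["boundaries_um"]), tuple(cfg["heights_um"]))

    def height_at(self, axial_um: np.ndarray) -> np.ndarray:
        axial_um = np.asarray(axial_um, dtype=float)
        idx = np.searchsorted(self.boundaries_um, axial_um, side="right") - 1
        bad = (idx < 0) | (idx >= len(self.heights_um))
        if np.any(bad):
            raise ValueError(
                f"{int(bad.sum())} pixels lie outside the channel geometry "
                f"({self.boundaries_um[0]}-{self.boundaries_um[-1]} um)"
            )
        return np.asarray(self.heights_um, dtype=float)[idx]


@dataclass
class WormPhenotype:
    """Per-worm body endpoints and provenance."""

    length_um: float
    area_um2: float
    volume_um3: float
    class_label: str
    well_id: str = ""
    channel_id: str = ""
    dose_um: float = float("nan")
    af_mean: float = float("nan")
    af_per_length: float = float("nan")
    af_per_area: float = float("nan")
    qc_flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# mask operations
# ---------------------------------------------------------------------------

def binarize(soft_segmentation: np.ndarray, pixel_size_um: float,
             threshold: float = 0.50,
             pad: tuple[int, int] = (0, 0)) -> BinaryMask:
    """Threshold the worm-class probability plane at 0.50 (ties foreground).

    ``soft_segmentation`` is either the (n_classes, H, W) softmax output
    (worm class = channel 1) or a single (H, W) probability plane.  The
    ``pad`` columns added for the network are removed before measurement.
    """
    probs = np.asarray(soft_segmentation, dtype=float)
    if probs.ndim == 3:
        probs = probs[1]
    if probs.min() < 0 or probs.max() > 1 + 1e-6:
        raise ValueError("probabilities must lie in [0, 1]")
    grid = probs >= threshold
    left, right = pad
    if left or right:
        grid = grid[:, left : grid.shape[1] - right]
    return BinaryMask(grid=grid, pixel_size_um=pixel_size_um)


def filter_components(mask: BinaryMask, min_area_px: int = 2000
                      ) -> tuple[BinaryMask, list[str]]:
    """Keep only the largest connected component if it is large enough.

    8-connectivity; everything except the largest component (eggs, debris,
    small larvae) is removed.  If no component reaches ``min_area_px`` the
    mask comes back empty with a ``no_worm_detected`` flag.  The default
    floor of 2,000 px is far below any L4-to-adult worm at the default
    pixel size and above typical debris.
    """
    labels = measure.label(mask.grid, connectivity=2)
    flags: list[str] = []
    if labels.max() == 0:
        return BinaryMask(np.zeros_like(mask.grid), mask.pixel_size_um), \
            ["no_worm_detected"]
    sizes = np.bincount(labels.ravel())[1:]
    biggest = int(np.argmax(sizes)) + 1
    if sizes[biggest - 1] < min_area_px:
        return BinaryMask(np.zeros_like(mask.grid), mask.pixel_size_um), \
            ["no_worm_detected"]
    if labels.max() > 1:
        flags.append("small_objects_removed")
    return BinaryMask(labels == biggest, mask.pixel_size_um), flags


def _skeleton_graph(skel: np.ndarray):
    """Sparse weighted 8-neighbour graph over skeleton pixels."""
    ys, xs = np.nonzero(skel)
    n = len(ys)
    index = -np.ones(skel.shape, dtype=int)
    index[ys, xs] = np.arange(n)
    rows, cols, wts = [], [], []
    for dy, dx, w in ((0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2)),
                      (1, -1, np.sqrt(2))):
        y2, x2 = ys + dy, xs + dx
        ok = (y2 >= 0) & (y2 < skel.shape[0]) & (x2 >= 0) & (x2 < skel.shape[1])
        ok[ok] &= skel[y2[ok], x2[ok]]
        rows.extend(index[ys[ok], xs[ok]])
        cols.extend(index[y2[ok], x2[ok]])
        wts.extend([w] * int(ok.sum()))
    g = csr_matrix((wts, (rows, cols)), shape=(n, n))
    return g + g.T, np.column_stack([ys, xs])


def skeleton_length(mask: BinaryMask) -> float:
    """Body length: longest geodesic path through the mask's skeleton, in um.

    The mask is thinned to a unit-width skeleton; skeleton pixels form an
    8-neighbour graph (axial edges 1 px, diagonal edges sqrt(2) px) and the
    length is the graph diameter — found by two sweeps of shortest paths
    (exact on trees, which is what skeletons of simple worm shapes are).
    """
    if not mask.grid.any():
        raise ValueError("cannot measure the length of an empty mask")
    skel = morphology.skeletonize(mask.grid)
    if skel.sum() <= 1:
        return 0.0
    graph, _ = _skeleton_graph(skel)
    d0 = dijkstra(graph, indices=0)
    d0[~np.isfinite(d0)] = -1
    u = int(np.argmax(d0))
    du = dijkstra(graph, indices=u)
    du[~np.isfinite(du)] = -1
    return float(du.max()) * mask.pixel_size_um


def body_area(mask: BinaryMask) -> float:
    """Foreground pixel count times pixel area (um^2)."""
    return float(mask.area_px) * mask.pixel_size_um**2


def body_volume(mask: BinaryMask, geometry: ChannelGeometry,
                channel_origin_um: float = 0.0) -> float:
    """Sum of pixel area x local channel height over the mask (um^3).

    ``channel_origin_um`` maps mask row 0 to its axial position in the
    geometry's frame (the fiduciary-referenced channel entrance).
    """
    ys = np.nonzero(mask.grid)[0]
    if ys.size == 0:
        return 0.0
    axial = channel_origin_um + (ys + 0.5) * mask.pixel_size_um
    heights = geometry.height_at(axial)
    counts_weighted = heights.sum()
    return float(counts_weighted) * mask.pixel_size_um**2


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def infer_channel(stack, model, geometry: ChannelGeometry,
                  n_planes: int = 1, min_area_px: int = 2000,
                  threshold: float = 0.50, pad_to: int | None = None,
                  channel_origin_um: float = 0.0) -> WormPhenotype:
    """Preprocess -> network -> post-process one channel into a phenotype.

    Channels classified as partial or empty get a class-only record (no
    body measures); full worms are binarized, component-filtered and
    measured.
    """
    from .model import CLASS_INDEX
    from .nn import no_grad
    from .preprocess import assemble_input, default_pad_width

    if pad_to is None:
        pad_to = default_pad_width(stack.volume.shape[-1])
    inp = assemble_input(stack, t=0, n_planes=n_planes, pad_to=pad_to)
    with no_grad():
        out = model.forward(inp)
    class_idx = int(np.argmax(out.class_probs[0]))
    label = {v: k for k, v in CLASS_INDEX.items()}[class_idx]
    record = WormPhenotype(
        length_um=float("nan"), area_um2=float("nan"),
        volume_um3=float("nan"), class_label=label,
        well_id=stack.well_id,
        channel_id=f"{stack.well_id}/f{stack.fov_index}/c{stack.channel_index}",
    )
    if label != "full":
        record.qc_flags.append("no_full_worm")
        return record
    mask = binarize(out.soft_segmentation[0], stack.pixel_size_um,
                    threshold=threshold, pad=(inp.pad_left, inp.pad_right))
    mask, flags = filter_components(mask, min_area_px=min_area_px)
    record.qc_flags.extend(flags)
    if not mask.grid.any():
        return record
    record.length_um = skeleton_length(mask)
    record.area_um2 = body_area(mask)
    record.volume_um3 = body_volume(mask, geometry, channel_origin_um)
    return record


def infer_device(records, model, geometry: ChannelGeometry,
                 **kwargs) -> list[WormPhenotype]:
    """Batch inference over a device's channel records; failures are isolated.

    Each channel is processed independently; an exception in one channel is
    recorded as a ``processing_error`` flag instead of aborting the run.
    """
    out = []
    for rec in records:
        stack = rec.stack if hasattr(rec, "stack") else rec
        try:
            ph = infer_channel(stack, model, geometry, **kwargs)
        except Exception as exc:  # pragma: no cover - defensive
            ph = WormPhenotype(
                length_um=float("nan"), area_um2=float("nan"),
                volume_um3=float("nan"), class_label="error",
                well_id=getattr(stack, "well_id", ""),
                qc_flags=[f"processing_error:{exc}"],
            )
        if hasattr(rec, "dose_um"):
            ph.dose_um = rec.dose_um
        out.append(ph)
    return out
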