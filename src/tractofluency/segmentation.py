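"""Waypoint-ROI bundle segmentation, statistical outlier cleaning, core clipping.

Tracts are isolated from a whole-brain tractogram by logical operations
on regions of interest: a streamline belongs to a tract if it passes
through every *include* ROI and avoids every *exclude* ROI. Segmented
bundles are then cleaned by iterative rejection of streamlines that are
too long or spatially deviant relative to the bundle, and finally clipped
to the core segment enclosed between the two waypoint ROIs, which removes
the highly variable extreme segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .bundles import Bundle
from .profiling import compute_core, resample_streamline

__all__ = [
    "RoiSpec",
    "CleaningConfig",
    "intersect_waypoints",
    "clean_outliers",
    "clip_to_core",
    "load_rois",
    "DEFAULT_TEMPLATE_ROIS",
]


@dataclass
class RoiSpec:
    """An axis-aligned box ROI (mm) with an include/exclude operation.

    The point-in-box test uses closed intervals on every axis. A voxel
    mask (boolean array + affine) may be supplied instead of a box.
    """

    name: str
    min_mm: np.ndarray | None = None
    max_mm: np.ndarray | None = None
    operation: str = "include"
    mask: np.ndarray | None = None
    mask_affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.operation not in ("include", "exclude"):
            raise ValueError(f"operation must be 'include' or 'exclude', got {self.operation!r}")
        if self.mask is not None:
            if self.mask_affine is None:
                raise ValueError(f"ROI {self.name!r}: mask requires mask_affine")
            self.mask = np.asarray(self.mask, dtype=bool)
            self.mask_affine = np.asarray(self.mask_affine, dtype=float)
            return
        if self.min_mm is None or self.max_mm is None:
            raise ValueError(f"ROI {self.name!r}: provide either a box or a mask")
        self.min_mm = np.asarray(self.min_mm, dtype=float)
        self.max_mm = np.asarray(self.max_mm, dtype=float)
        if self.min_mm.shape != (3,) or self.max_mm.shape != (3,):
            raise ValueError(f"ROI {self.name!r}: box bounds must be 3-vectors")
        if not np.all(self.min_mm < self.max_mm):
            raise ValueError(f"ROI {self.name!r}: require min < max on every axis")

    @classmethod
    def from_nifti(cls, path: str | Path, name: str = "", operation: str = "include",
                   threshold: float = 0.5) -> "RoiSpec":
        """Build a mask ROI from a NIfTI volume (voxels > threshold are inside)."""
        import nibabel as nib

        img = nib.load(str(path))
        return cls(
            name=name or Path(path).stem,
            mask=np.asanyarray(img.dataobj) > threshold,
            mask_affine=img.affine,
            operation=operation,
        )

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: which of the (n, 3) points lie inside the ROI."""
        pts = np.asarray(points, dtype=float)
        if self.mask is not None:
            inv = np.linalg.inv(self.mask_affine)
            vox = np.round(pts @ inv[:3, :3].T + inv[:3, 3]).astype(int)
            inside = np.all((vox >= 0) & (vox < np.array(self.mask.shape)), axis=1)
            out = np.zeros(len(pts), dtype=bool)
            if inside.any():
                v = vox[inside]
                out[inside] = self.mask[v[:, 0], v[:, 1], v[:, 2]]
            return out
        return np.all((pts >= self.min_mm) & (pts <= self.max_mm), axis=1)


@dataclass
class CleaningConfig:
    """Thresholds for statistical outlier rejection.

    ``max_length_sd`` is 4 for most tracts; the inferior cerebellar
    peduncle, a short tract, uses 1 (its documented per-tract deviation).
    ``max_distance_sd`` thresholds the mean node-wise Euclidean distance
    of a streamline from the bundle core, measured on streamlines
    resampled to ``n_nodes_for_core`` nodes.
    """

    max_length_sd: float = 4.0
    max_distance_sd: float = 4.0
    n_nodes_for_core: int = 100
    max_iterations: int = 5

    def __post_init__(self) -> None:
        for name in ("max_length_sd", "max_distance_sd", "n_nodes_for_core", "max_iterations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def intersect_waypoints(bundle: Bundle, roi_specs: list[RoiSpec]) -> Bundle:
    """Keep streamlines passing through every include ROI and no exclude ROI.

    At least one include ROI is required. An empty result is returned
    with a warning rather than raised, so batch runs proceed.
    """
    includes = [r for r in roi_specs if r.operation == "include"]
    excludes = [r for r in roi_specs if r.operation == "exclude"]
    if not includes:
        raise ValueError("at least one include ROI is required")

    keep = np.ones(len(bundle), dtype=bool)
    for i, sl in enumerate(bundle):
        if len(sl) < 2:
            keep[i] = False
            continue
        if not all(roi.contains(sl).any() for roi in includes):
            keep[i] = False
            continue
        if any(roi.contains(sl).any() for roi in excludes):
            keep[i] = False
    if not keep.any():
        warnings.warn(
            f"waypoint intersection left no streamlines (bundle {bundle.name!r})",
            stacklevel=2,
        )
    return bundle.subset(keep)


def _core_deviations(bundle: Bundle, n_nodes: int) -> np.ndarray:
    """Mean node-wise Euclidean distance of each streamline from the core."""
    resampled = np.stack([resample_streamline(s, n_nodes) for s in bundle])
    core, _ = compute_core(resampled)
    return np.linalg.norm(resampled - core, axis=2).mean(axis=1)


def clean_outliers(bundle: Bundle, config: CleaningConfig | None = None) -> Bundle:
    """Iteratively remove length and spatial-deviation outliers.

    A streamline is removed when its length exceeds
    ``mean + max_length_sd * SD`` of the current lengths (strict ``>``),
    or its mean node-wise distance from the current core exceeds
    ``mean + max_distance_sd * SD`` of the current deviations. The core
    and both statistics are recomputed each pass (a gross outlier
    distorts the first core estimate) until no removals occur or
    ``max_iterations`` is reached. SDs use the unbiased (n-1) denominator.
    The output is always a subset of the input; bundles with fewer than
    three streamlines are returned unchanged with a warning.
    """
    config = config or CleaningConfig()
    if len(bundle) < 3:
        if len(bundle) > 0:
            warnings.warn(
                f"bundle {bundle.name!r} has {len(bundle)} streamlines; skipping cleaning",
                stacklevel=2,
            )
        return bundle

    current = bundle
    for _ in range(config.max_iterations):
        if len(current) < 3:
            break
        lengths = current.lengths()
        len_thr = lengths.mean() + config.max_length_sd * lengths.std(ddof=1)
        devs = _core_deviations(current, config.n_nodes_for_core)
        dev_thr = devs.mean() + config.max_distance_sd * devs.std(ddof=1)
        keep = ~((lengths > len_thr) | (devs > dev_thr))
        if keep.all():
            break
        current = current.subset(keep)
    return current


def clip_to_core(bundle: Bundle, first_roi: RoiSpec, second_roi: RoiSpec) -> Bundle:
    """Clip each streamline to the segment between the two waypoint ROIs.

    Every streamline is reoriented to run first->second ROI, then
    truncated between its ROI crossing points. The crossing used is the
    first point inside the ROI walking from the far end, so for a
    streamline that crosses an ROI more than once the crossing nearest
    the other ROI is used, keeping the retained segment enclosed between
    the ROIs. Streamlines that never cross one of the ROIs are dropped
    (counted in a warning).
    """
    kept: list[np.ndarray] = []
    kept_idx: list[int] = []
    dropped = 0
    for i, sl in enumerate(bundle):
        in1 = first_roi.contains(sl)
        in2 = second_roi.contains(sl)
        if not in1.any() or not in2.any():
            dropped += 1
            continue
        # orient so the first ROI is encountered earlier
        if np.flatnonzero(in1)[0] > np.flatnonzero(in2)[0]:
            sl = sl[::-1]
            in1 = in1[::-1]
            in2 = in2[::-1]
        idx1 = np.flatnonzero(in1)
        idx2 = np.flatnonzero(in2)
        after = idx2[idx2 > idx1[0]]
        if len(after) == 0:
            dropped += 1
            continue
        i2 = int(after[0])
        i1 = int(idx1[idx1 < i2][-1])
        seg = sl[i1 : i2 + 1]
        if len(seg) < 2:
            dropped += 1
            continue
        kept.append(seg)
        kept_idx.append(i)
    if dropped:
        warnings.warn(
            f"clip_to_core dropped {dropped} streamline(s) without both ROI crossings "
            f"(bundle {bundle.name!r})",
            stacklevel=2,
        )
    scalars = {k: [v[i] for i in kept_idx] for k, v in bundle.scalars.items()}
    return Bundle(streamlines=kept, name=bundle.name, scalars=scalars)


def load_rois(path: str | Path) -> list[RoiSpec]:
    """Load ROI box specs from a YAML/JSON file.

    Expected structure: a list of ``{name, min_mm: [x,y,z],
    max_mm: [x,y,z], operation: include|exclude}`` mappings.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [
        RoiSpec(
            name=entry["name"],
            min_mm=np.asarray(entry["min_mm"], dtype=float),
            max_mm=np.asarray(entry["max_mm"], dtype=float),
            operation=entry.get("operation", "include"),
        )
        for entry in raw
    ]


def _box(name: str, min_mm, max_mm, operation: str = "include") -> RoiSpec:
    return RoiSpec(name=name, min_mm=np.array(min_mm, float), max_mm=np.array(max_mm, float),
                   operation=operation)


#: Approximate (synthetic) template-space waypoint boxes for the cerebellar
#: peduncles, constructed from their documented anatomical landmarks: the
#: superior SCP waypoint sits on the axial slice z = -10 around the red
#: nucleus, the superior MCP waypoint on z = -16 at the cerebral peduncle,
#: and the inferior ICP waypoint below the pons. These are landmark-based
#: approximations intended as a starting point for co-registered data, not
#: measured coordinates; real analyses should supply their own ROI file.
DEFAULT_TEMPLATE_ROIS: dict[str, list[RoiSpec]] = {
    "SCP_L": [
        _box("SCP_superior_prob_L", (-12, -24, -12), (0, -12, -8)),
        _box("SCP_inferior_L", (-16, -48, -34), (-2, -32, -22)),
    ],
    "SCP_R": [
        _box("SCP_superior_prob_R", (0, -24, -12), (12, -12, -8)),
        _box("SCP_inferior_R", (2, -48, -34), (16, -32, -22)),
    ],
    "MCP_L": [
        _box("MCP_superior_prob_L", (-22, -34, -18), (-4, -16, -14)),
        _box("MCP_lateral_L", (-44, -64, -34), (-24, -40, -18)),
    ],
    "MCP_R": [
        _box("MCP_superior_prob_R", (4, -34, -18), (22, -16, -14)),
        _box("MCP_lateral_R", (24, -64, -34), (44, -40, -18)),
    ],
    "ICP_L": [
        _box("ICP_inferior_prob_L", (-16, -46, -52), (-4, -32, -42)),
        _box("ICP_superior_L", (-20, -58, -38), (-6, -42, -26)),
    ],
    "ICP_R": [
        _box("ICP_inferior_prob_R", (4, -46, -52), (16, -32, -42)),
        _box("ICP_superior_R", (6, -58, -38), (20, -42, -26)),
    ],
    "FAT_L": [
        _box("FAT_ifg_L", (-56, 8, 2), (-34, 28, 18)),
        _box("FAT_sma_L", (-20, -8, 48), (-2, 18, 68)),
    ],
    "FAT_R": [
        _box("FAT_ifg_R", (34, 8, 2), (56, 28, 18)),
        _box("FAT_sma_R", (2, -8, 48), (20, 18, 68)),
    ],
}
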