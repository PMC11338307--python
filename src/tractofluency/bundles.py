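"""Streamline bundles and TRK/TCK input/output.

A :class:`Bundle` is a named collection of streamlines, each an ordered
``(n_points, 3)`` float array of coordinates in a single shared physical
space (millimetres, RAS). All geometry in this package operates on these
world-space coordinates; template-to-native warping is out of scope, so
bundles and ROIs must already be co-registered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import nibabel as nib
from nibabel.streamlines import Tractogram

__all__ = ["Bundle", "streamline_length", "read_bundle", "write_bundle"]


def streamline_length(points: np.ndarray) -> float:
    """Arc length of a polyline given as an (n, 3) array, in mm."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError(f"streamline must be (n, 3), got {points.shape}")
    if len(points) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


@dataclass
class Bundle:
    """A collection of streamlines belonging to one anatomical pathway.

    Parameters
    ----------
    streamlines
        List of ``(n_i, 3)`` float arrays in mm world space.
    name
        Tract label (e.g. ``"MCP_R"``); optional.
    scalars
        Optional per-streamline scalar arrays (one value per point or per
        resampled node), keyed by metric name (``"FA"``, ``"MD"``). Each
        entry is a list parallel to ``streamlines``.
    """

    streamlines: list[np.ndarray]
    name: str = ""
    scalars: dict[str, list[np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.streamlines = [np.asarray(s, dtype=float) for s in self.streamlines]
        for s in self.streamlines:
            if s.ndim != 2 or s.shape[1] != 3:
                raise ValueError(f"streamline must be (n, 3), got {s.shape}")
        for key, arrs in self.scalars.items():
            if len(arrs) != len(self.streamlines):
                raise ValueError(
                    f"scalars[{key!r}] has {len(arrs)} entries for "
                    f"{len(self.streamlines)} streamlines"
                )

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def lengths(self) -> np.ndarray:
        """Arc length of every streamline (mm)."""
        return np.array([streamline_length(s) for s in self.streamlines])

    def subset(self, keep: np.ndarray) -> "Bundle":
        """New bundle containing the streamlines selected by a boolean or index array."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return Bundle(
            streamlines=[self.streamlines[i] for i in keep],
            name=self.name,
            scalars={k: [v[i] for i in keep] for k, v in self.scalars.items()},
        )


def read_bundle(path: str | Path, name: str = "") -> Bundle:
    """Read a TRK or TCK file into a :class:`Bundle` in mm world space.

    TRK headers carry a voxel-to-world affine which nibabel applies on
    load; TCK streamlines are stored in scanner mm already. Either way the
    returned coordinates are RAS mm.
    """
    path = Path(path)
    tractogram_file = nib.streamlines.load(str(path))
    sls = [np.asarray(s, dtype=float) for s in tractogram_file.streamlines]
    if not sls:
        warnings.warn(f"{path.name}: empty tractogram", stacklevel=2)
    return Bundle(streamlines=sls, name=name or path.stem)


def write_bundle(bundle: Bundle, path: str | Path, affine: np.ndarray | None = None) -> Path:
    """Write a bundle to TRK or TCK (chosen by file extension).

    Coordinates are written in mm world space; for TRK an identity
    ``affine_to_rasmm`` is used unless one is given.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.eye(4)
    tg = Tractogram(list(bundle.streamlines), affine_to_rasmm=affine)
    suffix = path.suffix.lower()
    if suffix == ".tck":
        nib.streamlines.TckFile(tg).save(str(path))
    elif suffix == ".trk":
        nib.streamlines.TrkFile(tg).save(str(path))
    else:
        raise ValueError(f"unrecognized streamline format: {suffix!r} (use .tck or .trk)")
    return path
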