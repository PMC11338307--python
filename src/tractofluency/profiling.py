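"""Tract profiling: equidistant resampling, bundle core, and per-node FA/MD.

Tractometry summarizes a bundle by sampling a scalar map (FA, MD) at a
fixed number of equidistant nodes along the bundle core — here 30 by
default. Node numbering is 1-based in every report and output table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bundles import Bundle

__all__ = [
    "DEFAULT_N_NODES",
    "TractProfile",
    "resample_streamline",
    "compute_core",
    "tract_profile",
    "fa_md_from_eigenvalues",
    "VolumeSampler",
]

DEFAULT_N_NODES = 30


def resample_streamline(streamline: np.ndarray, n_nodes: int) -> np.ndarray:
    """Resample a polyline to ``n_nodes`` points at equal arc-length spacing.

    The first and last output points coincide with the streamline
    endpoints; intermediate points are linearly interpolated between the
    input vertices.

    Raises
    ------
    ValueError
        If the streamline has fewer than two points, zero arc length, or
        ``n_nodes < 2``.
    """
    pts = np.asarray(streamline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"streamline must be (n, 3), got {pts.shape}")
    if len(pts) < 2:
        raise ValueError("cannot resample a single-point streamline")
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("streamline has zero arc length")
    target = np.linspace(0.0, total, n_nodes)
    out = np.column_stack([np.interp(target, cum, pts[:, d]) for d in range(3)])
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def compute_core(resampled: np.ndarray | list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Per-node mean position (the tract core) and positional covariance.

    Parameters
    ----------
    resampled
        ``(n_streamlines, n_nodes, 3)`` array, or a list of equally sized
        ``(n_nodes, 3)`` arrays.

    Returns
    -------
    core : (n_nodes, 3) array
        Mean position at each node.
    cov : (n_nodes, 3, 3) array
        Positional covariance at each node (ddof=1; zeros for a single
        streamline).
    """
    if isinstance(resampled, list):
        if not resampled:
            raise ValueError("empty bundle")
        shapes = {np.asarray(s).shape for s in resampled}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent node counts across streamlines: {sorted(shapes)}")
        resampled = np.stack([np.asarray(s, dtype=float) for s in resampled])
    arr = np.asarray(resampled, dtype=float)
    if arr.ndim != 3:
        raise ValueError(f"expected (n_streamlines, n_nodes, 3), got {arr.shape}")
    n_sl, n_nodes, _ = arr.shape
    core = arr.mean(axis=0)
    cov = np.zeros((n_nodes, 3, 3))
    if n_sl > 1:
        centered = arr - core  # (S, K, 3)
        cov = np.einsum("ski,skj->kij", centered, centered) / (n_sl - 1)
    return core, cov


@dataclass
class TractProfile:
    """Per-node scalar summary of one tract for one subject and metric."""

    subject_id: str
    tract: str
    metric: str
    node_values: np.ndarray
    tract_mean: float = field(init=False)

    def __post_init__(self) -> None:
        self.node_values = np.asarray(self.node_values, dtype=float)
        if self.node_values.ndim != 1:
            raise ValueError("node_values must be 1-D")
        self.tract_mean = float(self.node_values.mean())

    @property
    def n_nodes(self) -> int:
        return len(self.node_values)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table; ``node`` is 1-based."""
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "tract": self.tract,
                "metric": self.metric,
                "node": np.arange(1, self.n_nodes + 1),
                "value": self.node_values,
            }
        )


def _gaussian_distance_weights(
    resampled: np.ndarray, core: np.ndarray, cov: np.ndarray
) -> np.ndarray:
    """Node-wise streamline weights ``exp(-d²/2)`` on Mahalanobis distance to the core.

    A small isotropic ridge keeps near-singular node covariances
    invertible; with one streamline all weights are 1.
    """
    n_sl, n_nodes, _ = resampled.shape
    weights = np.ones((n_sl, n_nodes))
    if n_sl < 2:
        return weights
    diff = resampled - core  # (S, K, 3)
    scale = np.trace(cov, axis1=1, axis2=2) / 3.0  # (K,)
    ridge = np.maximum(1e-6, 1e-6 * scale)
    for k in range(n_nodes):
        ck = cov[k] + ridge[k] * np.eye(3)
        d2 = np.einsum("si,ij,sj->s", diff[:, k], np.linalg.inv(ck), diff[:, k])
        weights[:, k] = np.exp(-0.5 * d2)
    return weights


def tract_profile(
    bundle: Bundle,
    scalar_sampler,
    n_nodes: int = DEFAULT_N_NODES,
    weighting: str = "gaussian_distance",
    subject_id: str = "",
    metric: str = "",
) -> TractProfile:
    """Profile a cleaned, clipped, consistently oriented bundle.

    Parameters
    ----------
    bundle
        The bundle to profile; must be non-empty.
    scalar_sampler
        Either a callable mapping an ``(m, 3)`` array of points to ``m``
        scalar values (e.g. a :class:`VolumeSampler`), or the name of a
        per-streamline scalar set stored in ``bundle.scalars`` (arrays are
        linearly resampled to ``n_nodes`` alongside the geometry).
    weighting
        ``"uniform"`` averages streamlines equally at every node;
        ``"gaussian_distance"`` (default, the AFQ convention) down-weights
        streamlines far from the core with ``exp(-d²/2)`` on the node-wise
        Mahalanobis distance.
    """
    if len(bundle) == 0:
        raise ValueError("cannot profile an empty bundle")
    if weighting not in ("uniform", "gaussian_distance"):
        raise ValueError(f"unknown weighting: {weighting!r}")

    resampled = np.stack([resample_streamline(s, n_nodes) for s in bundle])
    n_sl = len(bundle)

    if callable(scalar_sampler):
        values = scalar_sampler(resampled.reshape(-1, 3)).reshape(n_sl, n_nodes)
    else:
        arrs = bundle.scalars.get(scalar_sampler)
        if arrs is None:
            raise KeyError(f"bundle carries no scalar set named {scalar_sampler!r}")
        values = np.stack(
            [_resample_values(v, len(s), n_nodes) for v, s in zip(arrs, bundle.streamlines)]
        )
        metric = metric or str(scalar_sampler)

    if not np.all(np.isfinite(values)):
        bad = sorted(set((np.argwhere(~np.isfinite(values))[:, 1] + 1).tolist()))
        raise ValueError(f"scalar sampler returned non-finite values at nodes {bad}")

    core, cov = compute_core(resampled)
    if weighting == "uniform":
        node_values = values.mean(axis=0)
    else:
        w = _gaussian_distance_weights(resampled, core, cov)
        node_values = (w * values).sum(axis=0) / w.sum(axis=0)

    return TractProfile(
        subject_id=subject_id, tract=bundle.name, metric=metric, node_values=node_values
    )


def _resample_values(values: np.ndarray, n_points: int, n_nodes: int) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if len(values) == n_nodes:
        return values
    src = np.linspace(0.0, 1.0, len(values))
    return np.interp(np.linspace(0.0, 1.0, n_nodes), src, values)


def fa_md_from_eigenvalues(l1: float, l2: float, l3: float) -> dict[str, float]:
    """FA and MD from the three diffusion-tensor eigenvalues.

    MD is the mean of the eigenvalues; FA is their normalized standard
    deviation,

        FA = sqrt(3/2) * sqrt(sum((l_i - MD)^2)) / sqrt(sum(l_i^2)),

    which ranges from 0 (isotropic) to 1 (a single non-zero eigenvalue).
    The all-zero tensor has FA defined as 0 by convention (isotropic
    limit of the 0/0 case).
    """
    lam = np.array([l1, l2, l3], dtype=float)
    if not np.all(np.isfinite(lam)):
        raise ValueError("eigenvalues must be finite")
    if np.any(lam < 0):
        raise ValueError("eigenvalues must be non-negative")
    md = lam.mean()
    denom = np.sqrt((lam**2).sum())
    if denom == 0.0:
        return {"FA": 0.0, "MD": 0.0}
    fa = float(np.sqrt(1.5) * np.sqrt(((lam - md) ** 2).sum()) / denom)
    return {"FA": min(fa, 1.0), "MD": float(md)}


class VolumeSampler:
    """Trilinear scalar sampling from a NIfTI-style volume at mm coordinates."""

    def __init__(self, data: np.ndarray, affine: np.ndarray):
        from scipy.ndimage import map_coordinates  # noqa: F401  (import check)

        self.data = np.asarray(data, dtype=float)
        self.affine = np.asarray(affine, dtype=float)
        self._inv = np.linalg.inv(self.affine)

    @classmethod
    def from_nifti(cls, path) -> "VolumeSampler":
        import nibabel as nib

        img = nib.load(str(path))
        return cls(np.asanyarray(img.dataobj), img.affine)

    def __call__(self, points_mm: np.ndarray) -> np.ndarray:
        from scipy.ndimage import map_coordinates

        pts = np.asarray(points_mm, dtype=float)
        vox = (self._inv[:3, :3] @ pts.T + self._inv[:3, 3:4])
        return map_coordinates(self.data, vox, order=1, mode="nearest")
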