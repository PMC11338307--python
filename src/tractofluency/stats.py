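"""Brain-behavior correlation statistics.

Implements the statistical machinery of the tractometry analysis:

* node-wise and mean-tract Spearman rank correlations,
* Benjamini-Hochberg FDR control across a tract family,
* cluster-size permutation control of familywise error along the tract,
* first-order partial Spearman correlation, and
* the dependent-correlation Z comparison for two correlations sharing a
  variable.

The permutation scheme permutes the behavioral vector across subjects
once per permutation and reuses it at every node, preserving the spatial
autocorrelation of profiles — which is what makes the cluster-size null
valid. Within each tract the familywise error is controlled across the
30 nodes; no further correction is applied across tracts, behavioral
measures, or diffusion metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatsConfig",
    "ClusterResult",
    "spearman_rho",
    "mean_tract_correlations",
    "along_tract_correlation",
    "cluster_permutation_fwe",
    "partial_spearman",
    "dependent_corr_z",
]


@dataclass
class StatsConfig:
    """Significance levels and permutation settings.

    node_alpha is the uncorrected per-node level (0.05); fwe_alpha the
    corrected familywise level of the cluster permutation test (0.05);
    fdr_q the Benjamini-Hochberg level for mean-tract families (0.05).
    """

    node_alpha: float = 0.05
    fwe_alpha: float = 0.05
    fdr_q: float = 0.05
    n_permutations: int = 1000
    seed: int = 0
    tail: str = "two_sided"

    def __post_init__(self) -> None:
        for name in ("node_alpha", "fwe_alpha", "fdr_q"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.tail not in ("two_sided", "one_sided"):
            raise ValueError(f"tail must be 'two_sided' or 'one_sided', got {self.tail!r}")


@dataclass
class ClusterResult:
    """Along-tract cluster permutation outcome for one tract/metric/behavior.

    ``clusters`` lists the significant runs as (start_node, end_node,
    mean_rho) with 1-based, inclusive node numbering: maximal runs of
    nodes with uncorrected p < node_alpha whose length exceeds the
    permutation-derived critical cluster size.
    """

    tract: str
    metric: str
    behavior: str
    clusters: list[tuple[int, int, float]]
    critical_cluster_size: int
    node_rho: np.ndarray
    node_p: np.ndarray
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "tract": self.tract,
            "metric": self.metric,
            "behavior": self.behavior,
            "clusters": [
                {"start_node": int(a), "end_node": int(b), "mean_rho": float(r)}
                for a, b, r in self.clusters
            ],
            "critical_cluster_size": int(self.critical_cluster_size),
            "node_rho": np.asarray(self.node_rho).tolist(),
            "node_p": np.asarray(self.node_p).tolist(),
            "seed": int(self.seed),
        }


def _check_pair(x: np.ndarray, y: np.ndarray, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} observations, got {len(x)}")
    for name, v in (("x", x), ("y", y)):
        if np.unique(v).size < 2:
            raise ValueError(f"{name} has zero variance")
    return x, y


def spearman_rho(x, y, tail: str = "two_sided") -> dict:
    """Spearman rank-order correlation with the t-approximation p-value.

    rho is the Pearson correlation of mid-ranks (average ranks for
    ties); p comes from t = rho*sqrt((n-2)/(1-rho^2)) on n-2 df, doubled
    for the two-sided test. ``tail='one_sided'`` tests rho > 0.
    """
    x, y = _check_pair(x, y, min_n=3)
    alternative = "two-sided" if tail == "two_sided" else "greater"
    res = sps.spearmanr(x, y, alternative=alternative)
    return {"rho": float(res.statistic), "p": float(res.pvalue)}


def mean_tract_correlations(
    tract_means: pd.DataFrame,
    behavior_column: pd.Series,
    fdr_q: float = 0.05,
    tail: str = "two_sided",
) -> pd.DataFrame:
    """Spearman correlation of each tract's mean value with one behavior,
    FDR-corrected across the supplied tract family.

    ``tract_means`` is subjects x tracts (index = subject ids, one column
    per tract); ``behavior_column`` is indexed by the same subject ids.
    Benjamini-Hochberg is applied across the columns of ``tract_means``
    only — callers run separate families per behavioral measure and per
    diffusion metric.
    """
    if tract_means.shape[1] < 1:
        raise ValueError("need at least one tract column")
    missing = set(tract_means.index.astype(str)).symmetric_difference(
        set(behavior_column.index.astype(str))
    )
    if missing:
        raise ValueError(f"subject mismatch between tract means and behavior: {sorted(missing)}")
    behavior = behavior_column.reindex(tract_means.index)

    rows = []
    for tract in tract_means.columns:
        res = spearman_rho(tract_means[tract].to_numpy(), behavior.to_numpy(), tail=tail)
        rows.append({"tract": tract, "rho": res["rho"], "p": res["p"]})
    table = pd.DataFrame(rows)
    reject, p_adj, _, _ = multipletests(table["p"].to_numpy(), alpha=fdr_q, method="fdr_bh")
    table["p_fdr"] = p_adj
    table["fdr_reject"] = reject
    return table


def _zrank(a: np.ndarray, axis: int) -> np.ndarray:
    """Mid-ranks standardized to zero mean, unit (ddof=1) SD along ``axis``."""
    r = sps.rankdata(a, axis=axis)
    r = r - r.mean(axis=axis, keepdims=True)
    sd = r.std(axis=axis, ddof=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return r / sd


def _rho_p_from_ranks(zb: np.ndarray, zp: np.ndarray, n: int, tail: str):
    """Vectorized Spearman rho/p for standardized ranks.

    zb: (P, n) behavior ranks (one row per permutation); zp: (n, K) node
    ranks. Returns (P, K) rho and p arrays using the t-approximation.
    """
    rho = zb @ zp / (n - 1)
    rho_c = np.clip(rho, -1 + 1e-12, 1 - 1e-12)
    t = rho_c * np.sqrt((n - 2) / (1 - rho_c**2))
    if tail == "two_sided":
        p = 2 * sps.t.sf(np.abs(t), df=n - 2)
    else:
        p = sps.t.sf(t, df=n - 2)
    return rho, p


def along_tract_correlation(
    profile_matrix, behavior_column, tail: str = "two_sided"
) -> tuple[np.ndarray, np.ndarray]:
    """Node-by-node Spearman correlation between profiles and behavior.

    ``profile_matrix`` is subjects x nodes. A constant node column is
    degenerate: its rho is set to 0 and p to 1 with a warning, rather
    than failing the run.
    """
    prof = np.asarray(profile_matrix, dtype=float)
    beh = np.asarray(behavior_column, dtype=float)
    if prof.ndim != 2:
        raise ValueError("profile_matrix must be subjects x nodes")
    n, n_nodes = prof.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if len(beh) != n:
        raise ValueError("behavior length must match the number of subjects")
    if np.unique(beh).size < 2:
        raise ValueError("behavior has zero variance")
    if not np.all(np.isfinite(prof)):
        raise ValueError("profile matrix contains missing or non-finite nodes")

    constant = np.array([np.unique(prof[:, k]).size < 2 for k in range(n_nodes)])
    if constant.any():
        import warnings

        warnings.warn(
            f"{int(constant.sum())} constant node column(s); p set to 1", stacklevel=2
        )
    zp = _zrank(prof, axis=0)
    zb = _zrank(beh[None, :], axis=1)
    rho, p = _rho_p_from_ranks(zb, zp, n, tail)
    rho, p = rho[0], p[0]
    rho[constant] = 0.0
    p[constant] = 1.0
    return rho, p


def _max_run_length(mask: np.ndarray) -> np.ndarray:
    """Longest run of True per row of a (P, K) boolean array."""
    P, K = mask.shape
    best = np.zeros(P, dtype=np.int64)
    cur = np.zeros(P, dtype=np.int64)
    for k in range(K):
        cur = (cur + 1) * mask[:, k]
        np.maximum(best, cur, out=best)
    return best


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as 0-based inclusive (start, end) index pairs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


def cluster_permutation_fwe(
    profile_matrix,
    behavior_column,
    config: StatsConfig | None = None,
    tract: str = "",
    metric: str = "",
    behavior_name: str = "",
) -> ClusterResult:
    """Along-tract cluster-size permutation test (maxT-style FWE control).

    Observed node-wise Spearman p-values define candidate clusters:
    maximal runs of adjacent nodes with p < node_alpha. The null
    distribution of the maximum run length is built by permuting the
    behavioral vector across subjects ``n_permutations`` times (profile
    rows fixed, so inter-node correlation is preserved) and recording
    each permutation's longest suprathreshold run. The critical cluster
    size is the ceil((1-fwe_alpha)*n_permutations)-th order statistic of
    that null; observed clusters are significant iff strictly longer.
    Deterministic given ``config.seed``.
    """
    config = config or StatsConfig()
    prof = np.asarray(profile_matrix, dtype=float)
    beh = np.asarray(behavior_column, dtype=float)
    node_rho, node_p = along_tract_correlation(prof, beh, tail=config.tail)
    n, n_nodes = prof.shape

    rng = np.random.default_rng(config.seed)
    zp = _zrank(prof, axis=0)
    zb = _zrank(beh[None, :], axis=1)[0]
    perm_idx = np.stack([rng.permutation(n) for _ in range(config.n_permutations)])
    _, p_null = _rho_p_from_ranks(zb[perm_idx], zp, n, config.tail)
    null_max = np.sort(_max_run_length(p_null < config.node_alpha))
    order = int(np.ceil((1 - config.fwe_alpha) * config.n_permutations)) - 1
    critical = int(null_max[order])

    clusters = [
        (a + 1, b + 1, float(node_rho[a : b + 1].mean()))
        for a, b in _runs(node_p < config.node_alpha)
        if (b - a + 1) > critical
    ]
    return ClusterResult(
        tract=tract,
        metric=metric,
        behavior=behavior_name,
        clusters=clusters,
        critical_cluster_size=critical,
        node_rho=node_rho,
        node_p=node_p,
        seed=config.seed,
    )


def partial_spearman(x, y, covariate, tail: str = "two_sided") -> dict:
    """First-order partial Spearman correlation of x and y given a covariate.

    All three vectors are rank-transformed (mid-ranks) and the standard
    first-order partial Pearson formula is applied to the ranks:

        r_xy.z = (r_xy - r_xz*r_yz) / sqrt((1-r_xz^2)(1-r_yz^2)),

    with a t test on n-3 degrees of freedom.
    """
    x, y = _check_pair(x, y, min_n=4)
    z = np.asarray(covariate, dtype=float)
    if z.shape != x.shape:
        raise ValueError("covariate must match x and y in length")
    if np.unique(z).size < 2:
        raise ValueError("covariate has zero variance")

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rz = sps.rankdata(z)
    r_xy = np.corrcoef(rx, ry)[0, 1]
    r_xz = np.corrcoef(rx, rz)[0, 1]
    r_yz = np.corrcoef(ry, rz)[0, 1]
    if abs(r_xz) >= 1 - 1e-12 or abs(r_yz) >= 1 - 1e-12:
        raise ValueError("degenerate conditioning: covariate is rank-collinear with x or y")
    rho = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    n = len(x)
    df = n - 3
    rho_c = np.clip(rho, -1 + 1e-12, 1 - 1e-12)
    t = rho_c * np.sqrt(df / (1 - rho_c**2))
    p = 2 * sps.t.sf(abs(t), df) if tail == "two_sided" else sps.t.sf(t, df)
    return {"rho": float(rho), "p": float(p)}


def dependent_corr_z(
    r_xy: float, r_xz: float, r_yz: float, n: int, tail: str = "one_sided"
) -> dict:
    """Z test for two dependent correlations sharing variable x.

    Tests H0: rho_xy = rho_xz for correlations r_xy and r_xz that share
    x, accounting for the correlation r_yz between y and z, using the
    Meng-Rosenthal-Rubin statistic on Fisher-transformed correlations:

        Z = (z_xy - z_xz) * sqrt((n-3) / (2*(1-r_yz)*h)),

    where rbar2 = (r_xy^2 + r_xz^2)/2, f = min(1, (1-r_yz)/(2*(1-rbar2))),
    and h = (1 - f*rbar2)/(1 - rbar2). The default tail is one-sided
    (H1: rho_xy > rho_xz); ``tail='two_sided'`` doubles the normal tail
    probability of |Z|.
    """
    for name, r in (("r_xy", r_xy), ("r_xz", r_xz), ("r_yz", r_yz)):
        if not -1 < r < 1:
            raise ValueError(f"{name} must lie strictly inside (-1, 1), got {r}")
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    z_xy = np.arctanh(r_xy)
    z_xz = np.arctanh(r_xz)
    rbar2 = (r_xy**2 + r_xz**2) / 2
    f = min(1.0, (1 - r_yz) / (2 * (1 - rbar2)))
    h = (1 - f * rbar2) / (1 - rbar2)
    Z = (z_xy - z_xz) * np.sqrt((n - 3) / (2 * (1 - r_yz) * h))
    if tail == "two_sided":
        p = 2 * sps.norm.sf(abs(Z))
    else:
        p = sps.norm.sf(Z)
    return {"Z": float(Z), "p": float(p)}
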