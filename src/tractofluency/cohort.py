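"""Synthetic cohort generator.

Emulates the data the tractometry analysis consumes, so every downstream
stage is testable without an MRI download: per-subject streamline bundles
around parametric centerlines for the eight tracts of interest (left and
right superior, middle, and inferior cerebellar peduncles and frontal
aslant tracts), arch-shaped FA/MD node profiles with a mid-tract dip for
the decussating tracts, behavioral measures with a prescribed Spearman
correlation structure, node-localized brain-behavior effects, and
utterance-level transcripts with typed disfluencies.

Rank-correlation targeting uses a Gaussian copula with the
Pearson-Spearman correction ``r_pearson = 2*sin(pi*r_s/6)`` (exact for
the bivariate normal). Every generator is a pure function of its seed
and parameters; one master seed expands into per-subject, per-tract
sub-seeds by stable hashing, so individual subjects are reproducible
independently.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter1d

from .bundles import Bundle
from .profiling import DEFAULT_N_NODES, resample_streamline
from .speech import DISFLUENCY_TYPES, UtteranceRecord

__all__ = [
    "MEASURES",
    "DEFAULT_BEHAVIOR_RANK_CORR",
    "DEFAULT_MARGINALS",
    "DEFAULT_TRACTS",
    "DEFAULT_CENTERLINES",
    "ProfileShape",
    "EffectSpec",
    "CohortConfig",
    "SyntheticSubject",
    "Cohort",
    "subseed",
    "generate_bundle",
    "generate_behavior",
    "generate_scalar_profiles",
    "embed_effect",
    "generate_transcript",
    "generate_cohort",
]

MEASURES = ("speaking_rate", "articulation_rate", "phonemic_fluency", "semantic_fluency")

#: Target Spearman structure of the four behavioral measures: the two
#: rate measures correlate highly with each other (0.599), as do the two
#: verbal-fluency scores (0.548), while cross-block associations are
#: near zero.
DEFAULT_BEHAVIOR_RANK_CORR = np.array(
    [
        [1.000, 0.599, 0.050, 0.050],
        [0.599, 1.000, 0.050, 0.050],
        [0.050, 0.050, 1.000, 0.548],
        [0.050, 0.050, 0.548, 1.000],
    ]
)

#: Marginal mean/SD per measure (speaking and articulation rate in
#: syllables/s; fluency scores in words per task).
DEFAULT_MARGINALS = {
    "speaking_rate": (5.04, 0.68),
    "articulation_rate": (6.42, 1.05),
    "phonemic_fluency": (43.78, 9.83),
    "semantic_fluency": (66.96, 12.22),
}

DEFAULT_TRACTS = ("SCP_L", "SCP_R", "MCP_L", "MCP_R", "ICP_L", "ICP_R", "FAT_L", "FAT_R")

#: Parametric centerline control points (mm) in a synthetic template
#: space. The cerebellar curves are anatomically flavored: SCP and MCP
#: cross the midline (x = 0) mid-course, the ICP stays ipsilateral, and
#: the FAT runs from inferior frontal gyrus up to the supplementary
#: motor area.
DEFAULT_CENTERLINES: dict[str, np.ndarray] = {
    "SCP_L": np.array([(-12, -44, -30), (-8, -36, -22), (0, -28, -14), (7, -21, -10)], float),
    "SCP_R": np.array([(12, -44, -30), (8, -36, -22), (0, -28, -14), (-7, -21, -10)], float),
    "MCP_L": np.array([(-34, -52, -26), (-18, -42, -29), (0, -34, -30), (15, -28, -25)], float),
    "MCP_R": np.array([(34, -52, -26), (18, -42, -29), (0, -34, -30), (-15, -28, -25)], float),
    "ICP_L": np.array([(-9, -42, -50), (-12, -49, -41), (-14, -55, -31)], float),
    "ICP_R": np.array([(9, -42, -50), (12, -49, -41), (14, -55, -31)], float),
    "FAT_L": np.array([(-46, 18, 8), (-35, 13, 27), (-22, 6, 44), (-10, 2, 57)], float),
    "FAT_R": np.array([(46, 18, 8), (35, 13, 27), (22, 6, 44), (10, 2, 57)], float),
}

_DECUSSATING = ("SCP", "MCP")


@dataclass
class ProfileShape:
    """Baseline FA/MD node curves for one tract.

    FA follows an arch ``base + arch*sin(pi*t)``; decussating tracts
    additionally carry a Gaussian dip near mid-tract where left and
    right pathways interdigitate, with MD elevated at the same spot.
    Amplitudes are free calibration parameters of the generator, not
    empirical claims. MD is in mm^2/s.
    """

    fa_base: float = 0.40
    fa_arch: float = 0.12
    fa_dip: float = 0.0
    dip_center: float = 0.5
    dip_width: float = 0.08
    md_base: float = 7.3e-4
    md_arch: float = -0.4e-4
    md_dip: float = 0.0
    fa_subject_sd: float = 0.03
    fa_node_sd: float = 0.04
    md_subject_sd: float = 2.5e-5
    md_node_sd: float = 3.0e-5
    smooth_sigma: float = 1.5

    def curve(self, metric: str, n_nodes: int = DEFAULT_N_NODES) -> np.ndarray:
        t = np.linspace(0.0, 1.0, n_nodes)
        bump = np.exp(-((t - self.dip_center) ** 2) / (2 * self.dip_width**2))
        if metric == "FA":
            return self.fa_base + self.fa_arch * np.sin(np.pi * t) - self.fa_dip * bump
        if metric == "MD":
            return self.md_base + self.md_arch * np.sin(np.pi * t) + self.md_dip * bump
        raise ValueError(f"unknown metric {metric!r}")


def default_profile_shape(tract: str) -> ProfileShape:
    """Arch-shaped profile; decussating tracts (SCP, MCP) get the mid-tract dip."""
    if any(tract.startswith(p) for p in _DECUSSATING):
        return ProfileShape(fa_dip=0.12, md_dip=0.6e-4)
    return ProfileShape()


@dataclass
class EffectSpec:
    """A node-localized brain-behavior effect to embed.

    ``node_window`` is a 1-based inclusive (start, end) pair; ``rho`` is
    the target population Spearman between the scalar values at those
    nodes and the behavioral measure.
    """

    tract: str
    metric: str
    node_window: tuple[int, int]
    behavior: str
    rho: float

    def __post_init__(self) -> None:
        lo, hi = self.node_window
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid node window {self.node_window}")
        if not -1 < self.rho < 1:
            raise ValueError(f"effect rho must lie in (-1, 1), got {self.rho}")


@dataclass
class CohortConfig:
    """Full description of a synthetic cohort.

    Defaults are the study conditions the analysis assumes: 45 subjects,
    the eight tracts of interest, 30-node profiles, the behavioral
    rank-correlation structure above, and one embedded effect mirroring
    the observed pattern (MD in the right MCP vs. speaking rate,
    rho = -0.45 at nodes 17-22).
    """

    n_subjects: int = 45
    tract_names: tuple[str, ...] = DEFAULT_TRACTS
    n_streamlines_per_tract: int = 40
    n_nodes: int = DEFAULT_N_NODES
    centerline_params: dict[str, np.ndarray] = field(
        default_factory=lambda: {k: v.copy() for k, v in DEFAULT_CENTERLINES.items()}
    )
    streamline_jitter_sd: float = 1.5
    scalar_profile_shape: dict[str, ProfileShape] = field(default_factory=dict)
    behavior_rank_corr: np.ndarray = field(
        default_factory=lambda: DEFAULT_BEHAVIOR_RANK_CORR.copy()
    )
    marginal_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS)
    )
    effect_spec: list[EffectSpec] = field(
        default_factory=lambda: [EffectSpec("MCP_R", "MD", (17, 22), "speaking_rate", -0.45)]
    )
    n_utterances: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        self.behavior_rank_corr = _validate_rank_corr(np.asarray(self.behavior_rank_corr, float))
        for name in self.tract_names:
            if name not in self.centerline_params:
                raise ValueError(f"tract {name!r} has no centerline parameters")
            self.scalar_profile_shape.setdefault(name, default_profile_shape(name))
        for eff in self.effect_spec:
            if eff.tract not in self.tract_names:
                raise ValueError(f"effect references unknown tract {eff.tract!r}")
            if eff.behavior not in MEASURES:
                raise ValueError(f"effect references unknown behavior {eff.behavior!r}")
            if eff.node_window[1] > self.n_nodes:
                raise ValueError(
                    f"effect window {eff.node_window} exceeds {self.n_nodes} nodes"
                )


@dataclass
class SyntheticSubject:
    """One generated subject: geometry, scalars, behavior row, transcript."""

    subject_id: str
    bundles: dict[str, Bundle] = field(default_factory=dict)
    scalar_profiles: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    behavior: dict[str, float] = field(default_factory=dict)
    transcript: list[UtteranceRecord] = field(default_factory=list)


@dataclass
class Cohort:
    """A generated cohort plus its ground truth, keyed for the pipeline."""

    config: CohortConfig
    behavior: pd.DataFrame
    profiles: dict[tuple[str, str], np.ndarray]
    subjects: list[SyntheticSubject]

    @property
    def subject_ids(self) -> list[str]:
        return list(self.behavior.index)


def subseed(master_seed: int, *keys) -> np.random.SeedSequence:
    """Expand a master seed into an independent, stable sub-stream.

    String/int keys are hashed with CRC-32, so the same (seed, keys)
    always yields the same stream regardless of generation order.
    """
    digest = zlib.crc32("/".join(str(k) for k in keys).encode())
    return np.random.SeedSequence(entropy=int(master_seed) & 0x7FFFFFFF, spawn_key=(digest,))


def _validate_rank_corr(m: np.ndarray) -> np.ndarray:
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("rank-correlation matrix must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("rank-correlation matrix must be symmetric")
    if not np.allclose(np.diag(m), 1.0):
        raise ValueError("rank-correlation matrix must have a unit diagonal")
    if np.any(np.abs(m) > 1):
        raise ValueError("rank-correlation entries must lie in [-1, 1]")
    pearson = 2 * np.sin(np.pi * m / 6)
    np.fill_diagonal(pearson, 1.0)
    eig = np.linalg.eigvalsh(pearson)
    if eig.min() < -1e-10:
        raise ValueError(
            f"rank-correlation matrix is not positive semidefinite "
            f"(latent eigenvalue {eig.min():.6g})"
        )
    return m


# ---------------------------------------------------------------------------
# Streamline geometry


def _centerline_polyline(control_points: np.ndarray, n_points: int) -> np.ndarray:
    """Smooth curve through the control points, resampled to equidistant points."""
    cp = np.asarray(control_points, dtype=float)
    if cp.ndim != 2 or cp.shape[1] != 3 or len(cp) < 2:
        raise ValueError("centerline needs at least 2 control points of shape (m, 3)")
    chord = np.linalg.norm(np.diff(cp, axis=0), axis=1)
    if chord.sum() <= 0:
        raise ValueError("degenerate centerline: zero length")
    u = np.concatenate([[0.0], np.cumsum(chord)]) / chord.sum()
    if len(cp) == 2:
        dense = np.linspace(0, 1, 50)[:, None] * (cp[1] - cp[0]) + cp[0]
    else:
        spline = CubicSpline(u, cp, axis=0)
        dense = spline(np.linspace(0.0, 1.0, 200))
    return resample_streamline(dense, n_points)


def _smooth_offsets(rng: np.random.Generator, n_streamlines: int, n_points: int,
                    jitter_sd: float) -> np.ndarray:
    """Spatially coherent per-streamline offsets, (S, P, 3), mean-square jitter_sd.

    Each streamline's offset along each axis is a random degree-3
    polynomial in normalized arc length, expressed in Legendre
    polynomials normalized to unit mean square, with independent normal
    coefficients — a smooth curve-level displacement rather than
    independent per-point noise.
    """
    degree = 3
    t = np.linspace(-1.0, 1.0, n_points)
    basis = np.stack(
        [np.sqrt(2 * k + 1) * np.polynomial.legendre.Legendre.basis(k)(t)
         for k in range(degree + 1)]
    )  # (4, P)
    coef = rng.normal(0.0, jitter_sd / np.sqrt(degree + 1), size=(n_streamlines, 3, degree + 1))
    return np.einsum("sdk,kp->spd", coef, basis)


def generate_bundle(
    centerline_params: np.ndarray,
    n_streamlines: int,
    jitter_sd: float,
    seed: int | np.random.SeedSequence = 0,
    n_points: int = 60,
    name: str = "",
) -> Bundle:
    """Generate streamlines following a centerline with smooth offsets.

    With ``jitter_sd = 0`` every streamline is an identical copy of the
    resampled centerline. Deterministic given the seed.
    """
    if n_streamlines < 1:
        raise ValueError("n_streamlines must be >= 1")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    center = _centerline_polyline(centerline_params, n_points)
    if jitter_sd == 0:
        return Bundle([center.copy() for _ in range(n_streamlines)], name=name)
    rng = np.random.default_rng(seed)
    offsets = _smooth_offsets(rng, n_streamlines, n_points, jitter_sd)
    return Bundle([center + offsets[i] for i in range(n_streamlines)], name=name)


# ---------------------------------------------------------------------------
# Behavior


def generate_behavior(
    n_subjects: int,
    behavior_rank_corr: np.ndarray | None = None,
    marginal_params: dict[str, tuple[float, float]] | None = None,
    seed: int | np.random.SeedSequence = 0,
    enforce_ar_ge_sr: bool = True,
) -> pd.DataFrame:
    """Sample the four behavioral measures from a Gaussian copula.

    The target Spearman matrix is mapped to latent Pearson correlations
    with ``r = 2*sin(pi*r_s/6)``, the latent normal sample is scaled to
    the requested marginal means/SDs, and (by default) articulation rate
    is floored at speaking rate per subject by reflecting the few
    violating values about the speaking rate — articulation rate is
    higher than speaking rate for every subject, at the cost of a small
    (~0.02 at the default marginals) upward shift of the realized
    speaking-articulation Spearman correlation.
    """
    if n_subjects < 3:
        raise ValueError("n_subjects must be >= 3")
    target = _validate_rank_corr(
        np.asarray(
            DEFAULT_BEHAVIOR_RANK_CORR if behavior_rank_corr is None else behavior_rank_corr,
            float,
        )
    )
    marginals = dict(DEFAULT_MARGINALS if marginal_params is None else marginal_params)
    pearson = 2 * np.sin(np.pi * target / 6)
    np.fill_diagonal(pearson, 1.0)
    # eigenvalue square root tolerates the semidefinite boundary
    w, v = np.linalg.eigh(pearson)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_subjects, len(MEASURES))) @ root.T

    data = {}
    for j, measure in enumerate(MEASURES):
        mean, sd = marginals[measure]
        data[measure] = mean + sd * z[:, j]
    df = pd.DataFrame(data, index=[f"S{i + 1:03d}" for i in range(n_subjects)])
    df.index.name = "subject_id"
    if enforce_ar_ge_sr and {"speaking_rate", "articulation_rate"} <= set(df.columns):
        sr = df["speaking_rate"].to_numpy()
        ar = df["articulation_rate"].to_numpy()
        df["articulation_rate"] = sr + np.abs(ar - sr)
    for measure in MEASURES:
        df[measure] = df[measure].clip(lower=0.0)
    return df


# ---------------------------------------------------------------------------
# Scalar profiles and embedded effects


def generate_scalar_profiles(
    n_subjects: int,
    base_curve: np.ndarray,
    subject_sd: float,
    node_sd: float,
    smooth_sigma: float = 1.5,
    seed: int | np.random.SeedSequence = 0,
    clip: tuple[float, float] | None = None,
) -> np.ndarray:
    """Subjects x nodes scalar matrix around a shared baseline curve.

    Each subject's profile is the baseline plus a subject-level offset
    (SD ``subject_sd``) plus node-wise noise smoothed along the node axis
    with a Gaussian kernel of ``smooth_sigma`` nodes and rescaled to SD
    ``node_sd`` — giving the profiles realistic inter-node
    autocorrelation.
    """
    rng = np.random.default_rng(seed)
    base = np.asarray(base_curve, dtype=float)
    n_nodes = len(base)
    offsets = rng.normal(0.0, subject_sd, size=(n_subjects, 1))
    noise = rng.standard_normal((n_subjects, n_nodes))
    if smooth_sigma > 0:
        noise = gaussian_filter1d(noise, smooth_sigma, axis=1, mode="nearest")
        noise = noise / noise.std() * node_sd
    else:
        noise = noise * node_sd
    out = base + offsets + noise
    if clip is not None:
        out = np.clip(out, *clip)
    return out


def _normal_scores(values: np.ndarray) -> np.ndarray:
    """Standardized normal scores of the mid-ranks (ddof=1 scaling)."""
    ranks = sps.rankdata(values)
    z = sps.norm.ppf(ranks / (len(values) + 1))
    z = z - z.mean()
    sd = z.std(ddof=1)
    return z / sd if sd > 0 else z


def embed_effect(
    profiles_by_subject: np.ndarray,
    behavior: np.ndarray,
    node_window: tuple[int, int],
    effect_rho: float,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Mix a behavioral signal into a contiguous window of profile nodes.

    Within the 1-based inclusive ``node_window``, each node column is
    replaced by ``mean + sd*(sqrt(1-r^2)*z(values) + r*z(behavior))``
    where ``z`` denotes standardized (normal-score) transforms and
    ``r = 2*sin(pi*effect_rho/6)`` is the latent Pearson value, so the
    population Spearman between the node and the behavior approaches
    ``effect_rho``. Nodes outside the window are untouched;
    ``effect_rho = 0`` returns the input bit-for-bit.
    """
    prof = np.array(profiles_by_subject, dtype=float, copy=True)
    beh = np.asarray(behavior, dtype=float)
    if prof.ndim != 2 or len(beh) != prof.shape[0]:
        raise ValueError("profiles must be subjects x nodes aligned with behavior")
    lo, hi = node_window
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid node window {node_window}")
    if hi > prof.shape[1]:
        raise IndexError(f"node window {node_window} exceeds profile length {prof.shape[1]}")
    if np.unique(beh).size < 2:
        raise ValueError("behavior column has zero variance")
    if not -1 < effect_rho < 1:
        raise ValueError(f"effect_rho must lie in (-1, 1), got {effect_rho}")
    if effect_rho == 0:
        return prof

    r = 2 * np.sin(np.pi * effect_rho / 6)
    zb = _normal_scores(beh)
    for k in range(lo - 1, hi):
        col = prof[:, k]
        mean, sd = col.mean(), col.std(ddof=1)
        if sd == 0:
            continue
        zv = (col - mean) / sd
        prof[:, k] = mean + sd * (np.sqrt(1 - r**2) * zv + r * zb)
    return prof


# ---------------------------------------------------------------------------
# Transcripts

#: Per-utterance occurrence probability of each disfluency type:
#: interjections and revisions dominate, with part-word repetitions,
#: stuttered syllables, phrase repetitions, and dysrhythmic phonation
#: occurring at much lower rates.
DEFAULT_DISFLUENCY_RATES = {"I": 0.14, "R": 0.10, "PW": 0.03, "SS": 0.02, "PR": 0.02, "DP": 0.01}


def generate_transcript(
    n_utterances: int = 50,
    syllable_rate_fluent: float = 6.42,
    disfluency_rates_by_type: dict[str, float] | None = None,
    seed: int | np.random.SeedSequence = 0,
    subject_id: str = "S001",
    disfluency_multiplier: float = 1.0,
    pause_s_per_disfluency: float = 0.6,
    mean_syllables: float = 11.0,
    n_disfluent: int | None = None,
) -> list[UtteranceRecord]:
    """Generate one subject's utterance-annotated transcript.

    Fluent durations follow ``n_syllables / rate`` with lognormal rate
    variation around ``syllable_rate_fluent``; each disfluency type
    occurs independently per utterance with its configured rate (scaled
    by ``disfluency_multiplier``) and adds pause time, so disfluent
    utterances have a lower local syllable rate — which is what makes
    speaking rate fall below articulation rate. ``n_disfluent`` forces a
    minimum number of disfluent utterances.
    """
    if n_utterances < 1:
        raise ValueError("n_utterances must be >= 1")
    rates = dict(DEFAULT_DISFLUENCY_RATES if disfluency_rates_by_type is None
                 else disfluency_rates_by_type)
    unknown = set(rates) - set(DISFLUENCY_TYPES)
    if unknown:
        raise ValueError(f"unknown disfluency types: {sorted(unknown)}")
    if any(r < 0 for r in rates.values()):
        raise ValueError("disfluency rates must be >= 0")
    all_zero = all(r == 0 for r in rates.values()) or disfluency_multiplier == 0
    if n_disfluent and all_zero:
        raise ValueError("cannot force disfluent utterances when all rates are zero")

    rng = np.random.default_rng(seed)
    records: list[UtteranceRecord] = []
    for i in range(n_utterances):
        n_syll = 1 + rng.poisson(mean_syllables - 1)
        rate = syllable_rate_fluent * np.exp(rng.normal(0.0, 0.08))
        duration = n_syll / rate
        types = set()
        if not all_zero:
            for t, r in rates.items():
                if rng.random() < min(1.0, disfluency_multiplier * r):
                    types.add(t)
        duration += sum(0.2 + rng.exponential(pause_s_per_disfluency) for _ in types)
        records.append(
            UtteranceRecord(
                subject_id=subject_id,
                utterance_id=i + 1,
                duration_s=float(duration),
                n_syllables=int(n_syll),
                disfluency_types=frozenset(types),
            )
        )

    if n_disfluent:
        fluent_idx = [i for i, u in enumerate(records) if not u.is_disfluent]
        need = n_disfluent - (n_utterances - len(fluent_idx))
        if need > len(fluent_idx):
            raise ValueError("n_disfluent exceeds the number of utterances")
        if need > 0:
            names = [t for t in rates if rates[t] > 0]
            probs = np.array([rates[t] for t in names]) / sum(rates[t] for t in names)
            for i in rng.choice(fluent_idx, size=need, replace=False):
                t = str(rng.choice(names, p=probs))
                u = records[i]
                records[i] = replace(
                    u,
                    disfluency_types=frozenset({t}),
                    duration_s=u.duration_s + 0.2 + rng.exponential(pause_s_per_disfluency),
                )
    return records


# ---------------------------------------------------------------------------
# Full cohort


def generate_cohort(config: CohortConfig | None = None, with_bundles: bool = True) -> Cohort:
    """Generate a full synthetic cohort from one master seed.

    Behavioral measures come from the Gaussian copula; per-tract scalar
    node profiles are drawn around each tract's baseline curve and the
    configured effects are embedded; each subject gets a transcript
    whose articulation rate tracks their behavioral row and whose
    disfluency propensity falls with speaking rate (slower speakers are
    more disfluent); optionally, streamline bundles are generated around
    the tract centerlines with per-streamline FA/MD arrays carrying the
    subject's node profile.
    """
    config = config or CohortConfig()
    behavior = generate_behavior(
        config.n_subjects,
        config.behavior_rank_corr,
        config.marginal_params,
        seed=subseed(config.seed, "behavior"),
    )
    subject_ids = list(behavior.index)

    profiles: dict[tuple[str, str], np.ndarray] = {}
    for tract in config.tract_names:
        shape = config.scalar_profile_shape[tract]
        for metric, subject_sd, node_sd, clip in (
            ("FA", shape.fa_subject_sd, shape.fa_node_sd, (0.0, 1.0)),
            ("MD", shape.md_subject_sd, shape.md_node_sd, (1e-6, None)),
        ):
            clip_hi = clip[1] if clip[1] is not None else np.inf
            profiles[(tract, metric)] = generate_scalar_profiles(
                config.n_subjects,
                shape.curve(metric, config.n_nodes),
                subject_sd,
                node_sd,
                smooth_sigma=shape.smooth_sigma,
                seed=subseed(config.seed, "profiles", tract, metric),
                clip=(clip[0], clip_hi),
            )
    for eff in config.effect_spec:
        key = (eff.tract, eff.metric)
        profiles[key] = embed_effect(
            profiles[key],
            behavior[eff.behavior].to_numpy(),
            eff.node_window,
            eff.rho,
            seed=subseed(config.seed, "effect", eff.tract, eff.metric, eff.behavior),
        )

    sr = behavior["speaking_rate"].to_numpy()
    sr_z = (sr - sr.mean()) / (sr.std(ddof=1) or 1.0)
    subjects: list[SyntheticSubject] = []
    for i, sid in enumerate(subject_ids):
        rng_mult = np.random.default_rng(subseed(config.seed, "disfluency", sid))
        multiplier = float(np.exp(-0.8 * sr_z[i] + rng_mult.normal(0.0, 0.3)))
        transcript = generate_transcript(
            n_utterances=config.n_utterances,
            syllable_rate_fluent=float(behavior.loc[sid, "articulation_rate"]),
            seed=subseed(config.seed, "transcript", sid),
            subject_id=sid,
            disfluency_multiplier=multiplier,
        )
        subject = SyntheticSubject(
            subject_id=sid,
            behavior=behavior.loc[sid].to_dict(),
            transcript=transcript,
            scalar_profiles={key: mat[i] for key, mat in profiles.items()},
        )
        if with_bundles:
            for tract in config.tract_names:
                bundle = generate_bundle(
                    config.centerline_params[tract],
                    config.n_streamlines_per_tract,
                    config.streamline_jitter_sd,
                    seed=subseed(config.seed, "bundle", sid, tract),
                    name=tract,
                )
                rng_sc = np.random.default_rng(subseed(config.seed, "scalars", sid, tract))
                n_pts = len(bundle.streamlines[0])
                for metric, sl_sd in (("FA", 0.01), ("MD", 1e-5)):
                    node_curve = subject.scalar_profiles[(tract, metric)]
                    dense = np.interp(
                        np.linspace(0, 1, n_pts),
                        np.linspace(0, 1, len(node_curve)),
                        node_curve,
                    )
                    bundle.scalars[metric] = [
                        dense + rng_sc.normal(0.0, sl_sd, size=n_pts) for _ in range(len(bundle))
                    ]
                subject.bundles[tract] = bundle
        subjects.append(subject)

    return Cohort(config=config, behavior=behavior, profiles=profiles, subjects=subjects)
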