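"""End-to-end pipeline: synth -> segment -> profile -> correlate -> report.

Each stage writes its intermediate artifacts under the output directory
(plain CSV/TSV/JSON plus TCK bundles), a serialized copy of the resolved
configuration is always written next to the outputs, and every source of
randomness flows through the configured seed, so a run is reproducible
from its config alone. A stage failure leaves partial outputs in place
with a ``FAILED`` marker naming the stage.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bundles import Bundle, read_bundle, write_bundle
from .cohort import Cohort, CohortConfig, EffectSpec, generate_cohort
from .segmentation import CleaningConfig, RoiSpec, clean_outliers, clip_to_core, intersect_waypoints
from .profiling import tract_profile
from .stats import StatsConfig, cluster_permutation_fwe, mean_tract_correlations, partial_spearman

logger = logging.getLogger("tractofluency")

__all__ = ["PipelineConfig", "run_pipeline", "read_streamlines", "write_report"]


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run.

    ``cleaning_overrides`` maps tract names to :class:`CleaningConfig`
    replacements; by default the inferior cerebellar peduncles use the
    1-SD length criterion while every other tract uses 4 SD.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    cleaning_overrides: dict[str, CleaningConfig] = field(
        default_factory=lambda: {
            "ICP_L": CleaningConfig(max_length_sd=1.0),
            "ICP_R": CleaningConfig(max_length_sd=1.0),
        }
    )
    n_nodes: int = 30
    weighting: str = "gaussian_distance"
    stats: StatsConfig = field(default_factory=StatsConfig)
    behaviors: tuple[str, ...] = (
        "speaking_rate",
        "articulation_rate",
        "phonemic_fluency",
        "semantic_fluency",
    )
    metrics: tuple[str, ...] = ("FA", "MD")
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["centerline_params"] = {
            k: np.asarray(v).tolist() for k, v in d["cohort"]["centerline_params"].items()
        }
        d["cohort"]["behavior_rank_corr"] = np.asarray(
            d["cohort"]["behavior_rank_corr"]
        ).tolist()
        d["version"] = __version__
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "cohort" in raw:
            c = dict(raw["cohort"])
            if "centerline_params" in c:
                c["centerline_params"] = {
                    k: np.asarray(v, float) for k, v in c["centerline_params"].items()
                }
            if "behavior_rank_corr" in c:
                c["behavior_rank_corr"] = np.asarray(c["behavior_rank_corr"], float)
            if "effect_spec" in c:
                c["effect_spec"] = [
                    EffectSpec(
                        tract=e["tract"],
                        metric=e["metric"],
                        node_window=tuple(e["node_window"]),
                        behavior=e["behavior"],
                        rho=float(e["rho"]),
                    )
                    for e in c["effect_spec"]
                ]
            if "tract_names" in c:
                c["tract_names"] = tuple(c["tract_names"])
            kwargs["cohort"] = CohortConfig(**c)
        if "cleaning" in raw:
            kwargs["cleaning"] = CleaningConfig(**raw["cleaning"])
        if "cleaning_overrides" in raw:
            kwargs["cleaning_overrides"] = {
                k: CleaningConfig(**v) for k, v in raw["cleaning_overrides"].items()
            }
        if "stats" in raw:
            kwargs["stats"] = StatsConfig(**raw["stats"])
        for key in ("n_nodes", "weighting", "behaviors", "metrics", "log_level"):
            if key in raw:
                kwargs[key] = tuple(raw[key]) if key in ("behaviors", "metrics") else raw[key]
        return cls(**kwargs)


def _waypoint_rois_from_centerline(centerline: np.ndarray, tract: str,
                                   pad: float = 6.0) -> tuple[RoiSpec, RoiSpec]:
    """Boxes straddling the 15% and 85% arc positions of the tract centerline.

    In synthetic mode the generator's own geometry defines the waypoint
    ROIs, mirroring how template ROIs would enclose the core segment of a
    real tract.
    """
    from .cohort import _centerline_polyline

    poly = _centerline_polyline(centerline, 100)
    first, second = poly[15], poly[85]
    mk = lambda name, p: RoiSpec(name=name, min_mm=p - pad, max_mm=p + pad, operation="include")
    return mk(f"{tract}_waypoint1", first), mk(f"{tract}_waypoint2", second)


def read_streamlines(path: str | Path, pattern: str = "*.tck") -> dict[str, Bundle]:
    """Read every TRK/TCK file under a directory into a tract -> Bundle map."""
    path = Path(path)
    if path.is_file():
        return {path.stem: read_bundle(path)}
    bundles = {}
    for f in sorted(list(path.glob(pattern)) + list(path.glob("*.trk"))):
        bundles[f.stem] = read_bundle(f)
    return bundles


def write_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(report, indent=2, default=_default, sort_keys=True))
    return path


def run_pipeline(config: PipelineConfig | None = None, out_dir: str | Path = "tractofluency_run",
                 write_bundles: bool = False) -> dict:
    """Execute the full synthetic pipeline and write all artifacts.

    Stages: cohort generation, waypoint segmentation + cleaning +
    core clipping per subject and tract, 30-node profiling, mean-tract
    FDR statistics and along-tract cluster permutation statistics with
    partial-correlation follow-ups. Returns (and writes) the run report.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))

    stage = "synth"
    try:
        report: dict = {"version": __version__, "seed": config.cohort.seed, "stages": {}}

        cohort = generate_cohort(config.cohort, with_bundles=True)
        cohort.behavior.to_csv(out / "behavior.csv")
        _write_transcripts(cohort, out / "transcripts.tsv")
        report["stages"]["synth"] = {
            "n_subjects": len(cohort.subjects),
            "n_tracts": len(config.cohort.tract_names),
            "n_utterances_per_subject": config.cohort.n_utterances,
        }

        stage = "segment"
        counts = {"input": 0, "after_waypoints": 0, "after_cleaning": 0, "after_clipping": 0}
        segmented: dict[tuple[str, str], Bundle] = {}
        for subject in cohort.subjects:
            for tract, bundle in subject.bundles.items():
                roi1, roi2 = _waypoint_rois_from_centerline(
                    config.cohort.centerline_params[tract], tract
                )
                counts["input"] += len(bundle)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    kept = intersect_waypoints(bundle, [roi1, roi2])
                    counts["after_waypoints"] += len(kept)
                    cleaned = clean_outliers(
                        kept, config.cleaning_overrides.get(tract, config.cleaning)
                    )
                    counts["after_cleaning"] += len(cleaned)
                    clipped = clip_to_core(cleaned, roi1, roi2)
                counts["after_clipping"] += len(clipped)
                segmented[(subject.subject_id, tract)] = clipped
                if write_bundles:
                    write_bundle(clipped, out / "bundles" / subject.subject_id / f"{tract}.tck")
        report["stages"]["segment"] = counts

        stage = "profile"
        rows = []
        profile_matrices: dict[tuple[str, str], np.ndarray] = {}
        for tract in config.cohort.tract_names:
            for metric in config.metrics:
                mat = []
                for subject in cohort.subjects:
                    bundle = segmented[(subject.subject_id, tract)]
                    prof = tract_profile(
                        bundle,
                        metric,
                        n_nodes=config.n_nodes,
                        weighting=config.weighting,
                        subject_id=subject.subject_id,
                    )
                    mat.append(prof.node_values)
                    rows.append(prof.to_frame())
                profile_matrices[(tract, metric)] = np.stack(mat)
        profiles_df = pd.concat(rows, ignore_index=True)
        profiles_df.to_csv(out / "profiles.csv", index=False)
        tract_means = {
            f"{tract}:{metric}": profile_matrices[(tract, metric)].mean(axis=1)
            for tract in config.cohort.tract_names
            for metric in config.metrics
        }
        report["stages"]["profile"] = {"n_profiles": len(rows), "n_nodes": config.n_nodes}

        stage = "correlate"
        correlation_report = _correlate(config, cohort, profile_matrices)
        mean_rows = []
        for metric in config.metrics:
            means = pd.DataFrame(
                {t: tract_means[f"{t}:{metric}"] for t in config.cohort.tract_names},
                index=cohort.subject_ids,
            )
            for behavior in config.behaviors:
                table = mean_tract_correlations(
                    means, cohort.behavior[behavior], fdr_q=config.stats.fdr_q
                )
                table.insert(0, "metric", metric)
                table.insert(0, "behavior", behavior)
                mean_rows.append(table)
        mean_table = pd.concat(mean_rows, ignore_index=True)
        mean_table.to_csv(out / "mean_tract_correlations.csv", index=False)
        correlation_report["mean_tract"] = mean_table.to_dict(orient="records")

        n_sig = sum(len(e["clusters"]) for e in correlation_report["along_tract"])
        report["stages"]["correlate"] = {
            "n_along_tract_tests": len(correlation_report["along_tract"]),
            "n_significant_clusters": n_sig,
            "n_fdr_rejections": int(mean_table["fdr_reject"].sum()),
        }
        report["headline"] = [
            {
                "tract": e["tract"],
                "metric": e["metric"],
                "behavior": e["behavior"],
                "clusters": e["clusters"],
                "partial_given_articulation_rate": e.get("partial_given_articulation_rate"),
            }
            for e in correlation_report["along_tract"]
            if e["clusters"]
        ]
        write_report(correlation_report, out / "correlation_report.json")
        write_report(report, out / "run_report.json")
        return report
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _write_transcripts(cohort: Cohort, path: Path) -> None:
    from .speech import write_transcripts

    utts = [u for s in cohort.subjects for u in s.transcript]
    write_transcripts(utts, path)


def _correlate(config: PipelineConfig, cohort: Cohort, profile_matrices) -> dict:
    """Along-tract cluster statistics with partial-correlation follow-ups."""
    entries = []
    for (tract, metric), mat in profile_matrices.items():
        for behavior in config.behaviors:
            beh = cohort.behavior[behavior].to_numpy()
            stats_cfg = StatsConfig(
                node_alpha=config.stats.node_alpha,
                fwe_alpha=config.stats.fwe_alpha,
                fdr_q=config.stats.fdr_q,
                n_permutations=config.stats.n_permutations,
                seed=int(
                    np.random.SeedSequence(
                        [config.stats.seed, zlib_crc(f"{tract}/{metric}/{behavior}")]
                    ).generate_state(1)[0]
                    % (2**31)
                ),
                tail=config.stats.tail,
            )
            result = cluster_permutation_fwe(
                mat, beh, stats_cfg, tract=tract, metric=metric, behavior_name=behavior
            )
            entry = result.to_dict()
            if result.clusters and behavior != "articulation_rate":
                lo, hi, _ = result.clusters[0]
                cluster_mean = mat[:, lo - 1 : hi].mean(axis=1)
                entry["partial_given_articulation_rate"] = partial_spearman(
                    cluster_mean, beh, cohort.behavior["articulation_rate"].to_numpy()
                )
            entries.append(entry)
    return {"along_tract": entries, "seed": config.stats.seed}


def zlib_crc(text: str) -> int:
    import zlib

    return zlib.crc32(text.encode())
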