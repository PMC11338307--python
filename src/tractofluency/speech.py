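"""Speech-fluency measures from utterance-annotated transcripts.

Four measures are computed per subject:

* **speaking rate** — syllables per second over the whole speech sample,
  disfluent utterances included (a global measure of verbal output);
* **articulation rate** — syllables per second over fluent utterances
  only (a measure of articulatory motor control);
* **phonemic / semantic verbal fluency** — the number of correct unique
  responses produced under letter / category criteria, summed over the
  three criteria of each task.

Disfluency annotations use six types: interjections (I), revisions (R),
part-word repetitions (PW), stuttered syllables (SS), phrase repetitions
(PR), and dysrhythmic phonation (DP). Syllable counts and utterance
durations are taken as given in the transcript — they come from human
transcription, not from audio processing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DISFLUENCY_TYPES",
    "UtteranceRecord",
    "FluencyResponseSet",
    "speaking_rate",
    "articulation_rate",
    "verbal_fluency_score",
    "disfluency_stats",
    "read_transcripts",
    "write_transcripts",
    "read_response_sets",
    "behavior_table_from_transcripts",
]

DISFLUENCY_TYPES = ("I", "R", "PW", "SS", "PR", "DP")

#: Number of utterances entering the rate computations when a longer
#: transcript is supplied (the fixed-sample convention).
DEFAULT_RATE_WINDOW = 50


@dataclass(frozen=True)
class UtteranceRecord:
    """One transcribed utterance.

    An utterance communicates an idea, has a well-defined intonation
    contour, and is grammatically complete; it is disfluent exactly when
    it carries at least one disfluency annotation.
    """

    subject_id: str
    utterance_id: int
    duration_s: float
    n_syllables: int
    disfluency_types: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"utterance {self.utterance_id}: duration must be > 0")
        if self.n_syllables < 0:
            raise ValueError(f"utterance {self.utterance_id}: negative syllable count")
        unknown = set(self.disfluency_types) - set(DISFLUENCY_TYPES)
        if unknown:
            raise ValueError(f"unknown disfluency types: {sorted(unknown)}")
        object.__setattr__(self, "disfluency_types", frozenset(self.disfluency_types))

    @property
    def is_disfluent(self) -> bool:
        return len(self.disfluency_types) > 0


def _rate_window(utterances, first_k: int | None):
    utterances = list(utterances)
    if not utterances:
        raise ValueError("no utterances supplied")
    if first_k is not None:
        utterances = utterances[:first_k]
    return utterances


def speaking_rate(utterances, first_k: int | None = DEFAULT_RATE_WINDOW) -> float:
    """Syllables per second over the entire speech sample, no exclusions.

    When more than ``first_k`` utterances are supplied only the first
    ``first_k`` enter the computation (pass ``first_k=None`` to use all).
    """
    window = _rate_window(utterances, first_k)
    total_dur = sum(u.duration_s for u in window)
    if total_dur <= 0:
        raise ValueError("total duration is zero")
    return sum(u.n_syllables for u in window) / total_dur


def articulation_rate(utterances, first_k: int | None = DEFAULT_RATE_WINDOW) -> float:
    """Syllables per second over fluent utterances only.

    Disfluency exclusion is at utterance granularity: an utterance with
    any disfluency annotation is excluded whole.
    """
    window = _rate_window(utterances, first_k)
    fluent = [u for u in window if not u.is_disfluent]
    if not fluent:
        raise ValueError("articulation rate undefined: no fluent utterances")
    total_dur = sum(u.duration_s for u in fluent)
    if total_dur <= 0:
        raise ValueError("total fluent duration is zero")
    return sum(u.n_syllables for u in fluent) / total_dur


@dataclass
class FluencyResponseSet:
    """Responses produced under one verbal-fluency criterion.

    ``exclusions`` flags individual words (reason ``"erroneous"`` or
    ``"repetition"``); ``subcategory_exemplars`` maps a subcategory word
    (e.g. "birds") to the set of its specific exemplars — the
    subcategory word is not counted when the speaker also produced at
    least one exemplar of it.
    """

    task: str
    criterion: str
    responses: list[str]
    exclusions: dict[str, str] = field(default_factory=dict)
    subcategory_exemplars: dict[str, set] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.task not in ("phonemic", "semantic"):
            raise ValueError(f"task must be 'phonemic' or 'semantic', got {self.task!r}")

    def count_valid(self) -> int:
        """Number of correct unique responses under this criterion."""
        produced = set(self.responses)
        seen: set = set()
        count = 0
        for word in self.responses:
            if word in seen:
                continue  # repetition
            seen.add(word)
            if word in self.exclusions:
                continue
            exemplars = self.subcategory_exemplars.get(word)
            if exemplars and (set(exemplars) & (produced - {word})):
                continue  # subcategory named alongside its exemplars
            count += 1
        return count


def verbal_fluency_score(response_sets: list[FluencyResponseSet]) -> int:
    """Total correct unique responses summed across the three criteria of one task."""
    if len(response_sets) != 3:
        raise ValueError(f"expected exactly 3 criteria, got {len(response_sets)}")
    tasks = {rs.task for rs in response_sets}
    if len(tasks) != 1:
        raise ValueError(f"criteria mix tasks: {sorted(tasks)}")
    return sum(rs.count_valid() for rs in response_sets)


def disfluency_stats(utterances) -> dict:
    """Percent of disfluent utterances and the per-type annotation shares.

    ``type_distribution`` gives each type's percentage of all disfluency
    annotations (summing to 100 when any exist; all zero otherwise).
    """
    utterances = list(utterances)
    if not utterances:
        raise ValueError("no utterances supplied")
    n_disfluent = sum(u.is_disfluent for u in utterances)
    counts = {t: 0 for t in DISFLUENCY_TYPES}
    for u in utterances:
        for t in u.disfluency_types:
            counts[t] += 1
    total = sum(counts.values())
    dist = {t: (100.0 * c / total if total else 0.0) for t, c in counts.items()}
    return {
        "percent_disfluent": 100.0 * n_disfluent / len(utterances),
        "type_distribution": dist,
        "n_utterances": len(utterances),
        "n_disfluent": n_disfluent,
    }


# ---------------------------------------------------------------------------
# I/O

_TSV_COLUMNS = [
    "subject_id",
    "utterance_id",
    "duration_s",
    "n_syllables",
    "disfluency_types",
    "is_disfluent",
]


def write_transcripts(utterances, path: str | Path) -> Path:
    """Write utterance records to TSV (one row per utterance)."""
    rows = [
        {
            "subject_id": u.subject_id,
            "utterance_id": u.utterance_id,
            "duration_s": u.duration_s,
            "n_syllables": u.n_syllables,
            "disfluency_types": ";".join(sorted(u.disfluency_types)),
            "is_disfluent": int(u.is_disfluent),
        }
        for u in utterances
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


def read_transcripts(path: str | Path) -> dict[str, list[UtteranceRecord]]:
    """Read a transcript TSV into per-subject utterance lists.

    The ``is_disfluent`` column, when present, must agree with the
    ``disfluency_types`` column.
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    out: dict[str, list[UtteranceRecord]] = {}
    for _, row in df.iterrows():
        raw = row.get("disfluency_types", "")
        types = frozenset(t for t in str(raw).split(";") if t) if pd.notna(raw) else frozenset()
        rec = UtteranceRecord(
            subject_id=str(row["subject_id"]),
            utterance_id=int(row["utterance_id"]),
            duration_s=float(row["duration_s"]),
            n_syllables=int(row["n_syllables"]),
            disfluency_types=types,
        )
        if "is_disfluent" in df.columns and bool(int(row["is_disfluent"])) != rec.is_disfluent:
            raise ValueError(
                f"subject {rec.subject_id} utterance {rec.utterance_id}: "
                "is_disfluent flag contradicts disfluency_types"
            )
        out.setdefault(rec.subject_id, []).append(rec)
    for recs in out.values():
        recs.sort(key=lambda u: u.utterance_id)
    return out


def read_response_sets(path: str | Path) -> dict[str, dict[str, list[FluencyResponseSet]]]:
    """Read verbal-fluency responses from JSON.

    Expected structure: a list of objects with keys ``subject_id``,
    ``task``, ``criterion``, ``responses`` (list), optional
    ``exclusions`` (word -> reason) and ``subcategory_exemplars``
    (word -> list of exemplars). Returns
    ``{subject_id: {task: [FluencyResponseSet, ...]}}``.
    """
    with open(path) as fh:
        raw = json.load(fh)
    out: dict[str, dict[str, list[FluencyResponseSet]]] = {}
    for entry in raw:
        rs = FluencyResponseSet(
            task=entry["task"],
            criterion=entry["criterion"],
            responses=list(entry["responses"]),
            exclusions=dict(entry.get("exclusions", {})),
            subcategory_exemplars={
                k: set(v) for k, v in entry.get("subcategory_exemplars", {}).items()
            },
        )
        out.setdefault(str(entry["subject_id"]), {}).setdefault(rs.task, []).append(rs)
    return out


def behavior_table_from_transcripts(
    transcripts: dict[str, list[UtteranceRecord]],
    response_sets: dict[str, dict[str, list[FluencyResponseSet]]] | None = None,
    first_k: int | None = DEFAULT_RATE_WINDOW,
) -> pd.DataFrame:
    """Build the per-subject behavior table from transcripts (and responses).

    Columns: subject_id, speaking_rate, articulation_rate and, when
    response sets are supplied, phonemic_fluency and semantic_fluency.
    """
    rows = []
    for sid, utts in sorted(transcripts.items()):
        row = {
            "subject_id": sid,
            "speaking_rate": speaking_rate(utts, first_k=first_k),
            "articulation_rate": articulation_rate(utts, first_k=first_k),
        }
        if response_sets is not None:
            by_task = response_sets.get(sid, {})
            for task, col in (("phonemic", "phonemic_fluency"), ("semantic", "semantic_fluency")):
                if task in by_task:
                    row[col] = verbal_fluency_score(by_task[task])
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")
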