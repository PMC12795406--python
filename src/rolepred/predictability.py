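"""Position-conditioned predictability records.

Each argument contributes one record at its own first occurrence and one at
every later informative event — the occurrence of the other argument and the
occurrence of the verb — read from the trajectory state *after* consuming
that element.  Two binary flags record what precedes the read-off point:
``after_argument`` (the other argument has been consumed; always False for
single-argument utterances) and ``after_verb``.  Adjunct tokens never
trigger records.

``baseline_accuracy`` is the expected accuracy, restricted to one role, of a
naive classifier predicting labels according to their dataset proportions:
for items of a given role it simply equals that role's proportion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .corpus import AnnotatedUtterance, Role
from .model import RoleTrajectory

__all__ = [
    "PredictabilityRecord",
    "extract_records",
    "baseline_accuracy",
    "stimulus_final_probability",
    "records_to_frame",
    "write_records",
    "read_records",
]

RECORD_COLUMNS = [
    "sentence_id",
    "language",
    "role",
    "after_argument",
    "after_verb",
    "nominality",
    "verb_class",
    "p_correct",
]


@dataclass(frozen=True)
class PredictabilityRecord:
    sentence_id: str
    language: str
    role: str
    after_argument: bool | None
    after_verb: bool | None
    nominality: str
    verb_class: str
    p_correct: float
    condition_labels: Mapping[str, str] | None = None

    def __post_init__(self):
        if not (0.0 <= self.p_correct <= 1.0):
            raise ValueError(f"p_correct {self.p_correct} outside [0, 1]")


def _check_match(traj: RoleTrajectory, utt: AnnotatedUtterance) -> None:
    if traj.utterance_id != utt.id:
        raise ValueError(f"trajectory for {traj.utterance_id!r} does not match utterance {utt.id!r}")
    roles = {a.role.value for a in utt.arguments}
    if set(traj.arg_elements) != roles:
        raise ValueError("trajectory arguments do not match utterance arguments")


def extract_records(traj: RoleTrajectory, utt: AnnotatedUtterance) -> list[PredictabilityRecord]:
    """One record per argument per informative event.

    For word order AVP the A argument yields three records — at its own
    occurrence, at the verb, and at P — with flags (F,F), (F,T), (T,T); the
    P argument yields a single (T,T) record.
    """
    _check_match(traj, utt)
    nominality = {a.role.value: a.nominality.value for a in utt.arguments}
    records = []
    for role, t_own in sorted(traj.arg_elements.items(), key=lambda kv: kv[1]):
        other = next((r for r in traj.arg_elements if r != role), None)
        t_other = traj.arg_elements[other] if other is not None else None
        events = [t_own]
        events += [t for t in (t_other, traj.verb_element) if t is not None and t > t_own]
        for t in sorted(events):
            records.append(
                PredictabilityRecord(
                    sentence_id=utt.id,
                    language=utt.language,
                    role=role,
                    after_argument=t_other is not None and t_other <= t,
                    after_verb=traj.verb_element <= t,
                    nominality=nominality[role],
                    verb_class=utt.verb_class,
                    p_correct=traj.p_correct(role, t),
                )
            )
    return records


def baseline_accuracy(role_proportions: Mapping, role) -> float:
    """Expected accuracy on items of ``role`` under proportional prediction."""
    props = {Role(k).value: float(v) for k, v in role_proportions.items()}
    if any(v < 0 for v in props.values()) or abs(sum(props.values()) - 1.0) > 1e-8:
        raise ValueError(f"invalid role proportions {props}")
    return props[Role(role).value]


def stimulus_final_probability(traj: RoleTrajectory, utt: AnnotatedUtterance) -> list[PredictabilityRecord]:
    """Final-time-point record per argument, condition labels carried through."""
    _check_match(traj, utt)
    if not utt.conditions:
        raise ValueError(f"stimulus utterance {utt.id} has no condition labels")
    nominality = {a.role.value: a.nominality.value for a in utt.arguments}
    t_final = traj.n_points - 1
    return [
        PredictabilityRecord(
            sentence_id=utt.id,
            language=utt.language,
            role=role,
            after_argument=None,
            after_verb=None,
            nominality=nominality[role],
            verb_class=utt.verb_class,
            p_correct=traj.p_correct(role, t_final),
            condition_labels=dict(utt.conditions),
        )
        for role in sorted(traj.arg_elements)
    ]


# ---------------------------------------------------------------------------
# tabular I/O (the regression module's input format)
# ---------------------------------------------------------------------------

def records_to_frame(records: Iterable[PredictabilityRecord]) -> pd.DataFrame:
    rows = []
    cond_keys: list[str] = []
    records = list(records)
    for r in records:
        if r.condition_labels:
            for k in r.condition_labels:
                if k not in cond_keys:
                    cond_keys.append(k)
    for r in records:
        row = {c: getattr(r, c) for c in RECORD_COLUMNS}
        for k in cond_keys:
            row[f"cond_{k}"] = (r.condition_labels or {}).get(k)
        rows.append(row)
    return pd.DataFrame(rows, columns=RECORD_COLUMNS + [f"cond_{k}" for k in cond_keys])


def write_records(records: Iterable[PredictabilityRecord] | pd.DataFrame, path: str | Path) -> None:
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records table missing columns {sorted(missing)}")
    return df
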