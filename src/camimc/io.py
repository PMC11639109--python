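"""CSV input/output and record-level scoring.

Two tidy CSV dialects are consumed and produced:

* assessment CSV — one row per patient-day-rater with the raw CAM-IMC
  item responses (fluctuation yes/no, RASS, inattention error count,
  five ``disorient_*`` columns coded correct/error) plus the same-day
  reference diagnosis; missing responses are empty fields;
* baseline CSV — one row per patient with age, sex, Mini-Cog,
  preoperative orientation and RASS.

:func:`score_records` turns assessment rows into scored records
(point components, total, positivity, item flags, subgroup flags) and
keeps an exclusion ledger so that eligible = analyzed + excluded with
per-reason counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .instrument import (
    DISORIENTATION_DIMENSIONS,
    DEFAULT_CUTOFF,
    BaselineAssessment,
    FeatureResponses,
    MissingPolicy,
    cam_imc,
    item_flags,
    subgroup_flags,
)

__all__ = [
    "ASSESSMENT_COLUMNS",
    "BASELINE_COLUMNS",
    "MalformedInputError",
    "ScoredRecords",
    "read_assessments",
    "read_baseline",
    "write_csv",
    "responses_from_row",
    "score_records",
]

logger = logging.getLogger("camimc")

_DIM_COLUMNS = tuple(f"disorient_{d}" for d in DISORIENTATION_DIMENSIONS)

ASSESSMENT_COLUMNS = (
    "patient_id", "day", "rater_id", "rater_role",
    "fluctuation", "rass", "inattention_errors",
    *_DIM_COLUMNS,
    "reference_delirium",
)

BASELINE_COLUMNS = ("patient_id", "age", "sex", "minicog")


class MalformedInputError(ValueError):
    """Raised for structurally invalid input (missing required columns)."""


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MalformedInputError(f"{what} is missing required columns: {missing}")


def read_assessments(path: Union[str, Path]) -> pd.DataFrame:
    """Read an assessment CSV (empty fields are missing responses)."""
    df = pd.read_csv(
        path,
        dtype={"patient_id": str, "rater_id": str, "rater_role": str,
               "fluctuation": str, **{c: str for c in _DIM_COLUMNS}},
        keep_default_na=False,
        na_values=[""],
    )
    _require_columns(df, ASSESSMENT_COLUMNS, f"assessment file {path}")
    df["day"] = pd.to_numeric(df["day"], errors="raise").astype(int)
    for col in ("rass", "inattention_errors"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype("Int64")
    df["reference_delirium"] = pd.to_numeric(
        df["reference_delirium"], errors="coerce"
    ).astype("Int64")
    return df


def read_baseline(path: Union[str, Path]) -> pd.DataFrame:
    """Read a baseline CSV (one row per patient)."""
    df = pd.read_csv(path, dtype={"patient_id": str, "sex": str},
                     keep_default_na=False, na_values=[""])
    _require_columns(df, BASELINE_COLUMNS, f"baseline file {path}")
    df["age"] = pd.to_numeric(df["age"], errors="raise").astype(int)
    for col in ("minicog", "baseline_orientation", "baseline_rass"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    return df


def write_csv(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a table in the package's CSV dialect (empty = missing)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, na_rep="")


def _tristate(value) -> Optional[bool]:
    """'yes'/'no' or 'error'/'correct' (case-insensitive) to bool, NA to None."""
    if pd.isna(value) or value == "":
        return None
    v = str(value).strip().lower()
    if v in ("yes", "error", "1", "true"):
        return True
    if v in ("no", "correct", "0", "false"):
        return False
    raise ValueError(f"unrecognised response {value!r}")


def responses_from_row(row) -> FeatureResponses:
    """Build :class:`FeatureResponses` from one assessment-CSV row."""
    return FeatureResponses(
        fluctuation_present=_tristate(row["fluctuation"]),
        rass=None if pd.isna(row["rass"]) else int(row["rass"]),
        inattention_errors=(
            None if pd.isna(row["inattention_errors"])
            else int(row["inattention_errors"])
        ),
        disorientation={
            dim: _tristate(row[f"disorient_{dim}"])
            for dim in DISORIENTATION_DIMENSIONS
        },
    )


@dataclass
class ScoredRecords:
    """Scored index observations plus the exclusion ledger.

    ``ledger`` satisfies eligible = analyzed + excluded, with excluded
    broken down by reason (mirroring a participant flow chart).
    """

    data: pd.DataFrame
    excluded: pd.DataFrame
    ledger: dict = field(default_factory=dict)


def score_records(
    assessments: pd.DataFrame,
    baseline: Optional[pd.DataFrame] = None,
    cutoff: int = DEFAULT_CUTOFF,
    policy: MissingPolicy = "strict",
) -> ScoredRecords:
    """Score every index assessment row and attach analysis flags.

    Adds the point components, total, positivity at ``cutoff``, the
    item-level dichotomisations (``flag_*``) and — when a baseline table
    is given — the subgroup flags (``subgroup_elderly``,
    ``subgroup_cognitive_impairment``).  Rows that cannot be scored
    under the missing-data policy (or are malformed) land in
    ``excluded`` with a line-numbered reason; reference-rater rows are
    not scored.
    """
    _require_columns(assessments, ASSESSMENT_COLUMNS, "assessment table")
    idx_rows = assessments[assessments["rater_role"] == "index"]

    records, exclusions = [], []
    for line, (_, row) in enumerate(idx_rows.iterrows(), start=2):
        try:
            responses = responses_from_row(row)
            score = cam_imc(responses, cutoff=cutoff, policy=policy)
        except ValueError as exc:  # malformed values
            exclusions.append({
                "patient_id": row["patient_id"], "day": row["day"],
                "rater_id": row["rater_id"], "line": line,
                "reason": f"malformed: {exc}",
            })
            continue
        if not score.assessable:
            exclusions.append({
                "patient_id": row["patient_id"], "day": row["day"],
                "rater_id": row["rater_id"], "line": line,
                "reason": "unassessable: " + "; ".join(score.reasons),
            })
            continue
        if pd.isna(row["reference_delirium"]):
            exclusions.append({
                "patient_id": row["patient_id"], "day": row["day"],
                "rater_id": row["rater_id"], "line": line,
                "reason": "no reference diagnosis",
            })
            continue
        flags = item_flags(responses)
        records.append({
            "patient_id": row["patient_id"],
            "day": int(row["day"]),
            "rater_id": row["rater_id"],
            "pts_fluctuation": score.pts_fluctuation,
            "pts_consciousness": score.pts_consciousness,
            "pts_inattention": score.pts_inattention,
            "pts_disorientation": score.pts_disorientation,
            "camimc_total": score.total,
            "camimc_positive": score.positive,
            "flag_fluctuation": flags.fluctuation,
            "flag_consciousness": flags.consciousness,
            "flag_inattention": flags.inattention,
            "flag_disorientation": flags.disorientation,
            "reference_delirium": bool(row["reference_delirium"]),
        })

    data = pd.DataFrame(records)
    excluded = pd.DataFrame(
        exclusions, columns=["patient_id", "day", "rater_id", "line", "reason"]
    )

    if baseline is not None and not data.empty:
        _require_columns(baseline, BASELINE_COLUMNS, "baseline table")
        flags = []
        for _, b in baseline.iterrows():
            sf = subgroup_flags(BaselineAssessment(
                patient_id=str(b["patient_id"]),
                age=int(b["age"]),
                sex=str(b["sex"]),
                minicog=None if pd.isna(b.get("minicog")) else int(b["minicog"]),
            ))
            flags.append({
                "patient_id": str(b["patient_id"]),
                "subgroup_elderly": sf.elderly,
                "subgroup_cognitive_impairment": sf.cognitive_impairment,
            })
        data = data.merge(pd.DataFrame(flags), on="patient_id", how="left")

    n_eligible = len(idx_rows)
    reason_counts = (
        excluded["reason"].str.split(":").str[0].value_counts().to_dict()
        if not excluded.empty else {}
    )
    ledger = {
        "eligible": n_eligible,
        "analyzed": len(data),
        "excluded": len(excluded),
        "excluded_by_reason": reason_counts,
    }
    if len(excluded):
        logger.info("excluded %d of %d index assessments: %s",
                    len(excluded), n_eligible, reason_counts)
    return ScoredRecords(data=data, excluded=excluded, ledger=ledger)
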