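"""Data-cleaning rules and exclusion accounting.

Two rules, applied in order:

1. Respondents who gave every state the same value are taken not to have
   understood the task and are dropped entirely (exact equality on the
   quarter-grid value representation).
2. Individual tasks completed within 1 second are unreliable and dropped.

The resulting record count obeys the identity

    retained = (participants - all-same) * states_per_respondent - fast
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import pandas as pd

from .core import DomainError

FAST_TASK_THRESHOLD_S = 1.0


@dataclass
class ExclusionReport:
    n_participants_in: int
    n_allsame_excluded: int
    n_fast_tasks_excluded: int
    n_participants_retained: int
    n_records_retained: int
    states_per_respondent: int = 5

    @classmethod
    def from_counts(
        cls,
        n_participants: int,
        n_allsame: int,
        n_fast_tasks: int,
        states_per_respondent: int = 5,
    ) -> "ExclusionReport":
        """Build the report from the published exclusion arithmetic alone."""
        retained = n_participants - n_allsame
        return cls(
            n_participants_in=n_participants,
            n_allsame_excluded=n_allsame,
            n_fast_tasks_excluded=n_fast_tasks,
            n_participants_retained=retained,
            n_records_retained=retained * states_per_respondent - n_fast_tasks,
            states_per_respondent=states_per_respondent,
        )

    def identity_holds(self) -> bool:
        return self.n_records_retained == (
            (self.n_participants_in - self.n_allsame_excluded)
            * self.states_per_respondent
            - self.n_fast_tasks_excluded
        )

    def __str__(self) -> str:
        return (
            "Exclusion report\n"
            f"  participants in:            {self.n_participants_in}\n"
            f"  all-same-value excluded:    {self.n_allsame_excluded}\n"
            f"  fast tasks (<=1 s) excluded: {self.n_fast_tasks_excluded}\n"
            f"  participants retained:      {self.n_participants_retained}\n"
            f"  records retained:           {self.n_records_retained}\n"
        )


def _check_nonempty(records: pd.DataFrame) -> None:
    if len(records) == 0:
        raise DomainError("no records supplied")
    counts = records.groupby("respondent_id").size()
    if (counts < 1).any():
        raise DomainError("respondent with zero records")


def filter_allsame(records: pd.DataFrame) -> Tuple[pd.DataFrame, List[str]]:
    """Drop respondents whose recorded values are all equal.

    Returns the retained records and the excluded respondent ids.
    """
    _check_nonempty(records)
    nuniq = records.groupby("respondent_id")["U"].nunique()
    excluded = sorted(nuniq.index[nuniq == 1])
    retained = records[~records["respondent_id"].isin(excluded)]
    return retained, excluded


def filter_fast_tasks(records: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Drop individual tasks completed within 1 second (inclusive bound).

    Returns the retained and the excluded records.
    """
    if records["duration_s"].isna().any():
        raise DomainError("missing task duration")
    if (records["duration_s"] < 0).any():
        raise DomainError("negative task duration")
    fast = records["duration_s"] <= FAST_TASK_THRESHOLD_S
    return records[~fast], records[fast]


def apply_qc(records: pd.DataFrame) -> Tuple[pd.DataFrame, ExclusionReport]:
    """Both filters in the published order: all-same first, then fast tasks."""
    n_in = records["respondent_id"].nunique()
    kept, allsame_ids = filter_allsame(records)
    kept, fast = filter_fast_tasks(kept)
    states_per = (
        int(records.groupby("respondent_id").size().mode().iloc[0])
        if len(records)
        else 0
    )
    report = ExclusionReport(
        n_participants_in=n_in,
        n_allsame_excluded=len(allsame_ids),
        n_fast_tasks_excluded=int(len(fast)),
        n_participants_retained=n_in - len(allsame_ids),
        n_records_retained=int(len(kept)),
        states_per_respondent=states_per,
    )
    return kept, report
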