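"""Change-rate statistics and responder phenotyping.

Two change rates drive the analysis:

* **functional reactivity** of an edge,
  ``(z_ON - z_OFF) / |z_OFF|`` — positive when the connectivity strengthened
  after levodopa, negative when it weakened;
* **tremor responsiveness** of a subject,
  ``(tremor_OFF - tremor_ON) / tremor_OFF`` computed on the UPDRS III tremor
  sub-score (items 20 + 21) — 1 means complete resolution, 0 no response.

Patients are split into dopamine-responsive (responsiveness at or above the
cohort median) and dopamine-resistant (below) groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .connectivity import ConnectivitySet, Edge

__all__ = [
    "DENOM_FLOOR",
    "edge_reactivity",
    "tremor_responsiveness",
    "compose_subscores",
    "median_split",
    "GroupAssignment",
    "ReactivityTable",
    "build_reactivity_table",
]

#: |z_OFF| is floored at this value so the reactivity of (near) zero-baseline
#: edges stays finite; floored entries are flagged in the table.
DENOM_FLOOR = 1e-6

TREMOR_ITEMS = (20, 21)
RIGIDITY_ITEMS = (22,)
BRADYKINESIA_ITEMS = (23, 24, 25, 26, 27, 31)


def edge_reactivity(z_on: float, z_off: float) -> float:
    """FC change rate of one edge: ``(z_on - z_off) / max(|z_off|, 1e-6)``."""
    if not (np.isfinite(z_on) and np.isfinite(z_off)):
        raise ValueError("non-finite connectivity value")
    return (z_on - z_off) / max(abs(z_off), DENOM_FLOOR)


def tremor_responsiveness(off_score: float, on_score: float) -> float:
    """Tremor change rate ``(off - on) / off``; requires baseline tremor."""
    if off_score <= 0:
        raise ValueError("no baseline tremor — subject must be excluded")
    return (off_score - on_score) / off_score


class SubScores(NamedTuple):
    tremor: int
    rigidity: int
    bradykinesia: int


def compose_subscores(item_scores: Mapping[int, int]) -> SubScores:
    """Compose UPDRS III sub-scores from per-item ratings.

    Tremor = items 20 + 21; rigidity = item 22; bradykinesia = items
    23 + 24 + 25 + 26 + 27 + 31.
    """
    needed = TREMOR_ITEMS + RIGIDITY_ITEMS + BRADYKINESIA_ITEMS
    missing = [i for i in needed if i not in item_scores]
    if missing:
        raise ValueError(f"missing UPDRS III item(s): {missing}")
    return SubScores(
        tremor=sum(item_scores[i] for i in TREMOR_ITEMS),
        rigidity=sum(item_scores[i] for i in RIGIDITY_ITEMS),
        bradykinesia=sum(item_scores[i] for i in BRADYKINESIA_ITEMS),
    )


@dataclass
class GroupAssignment:
    """Median-split responder phenotype: subject -> resistant/responsive."""

    assignments: dict[str, str]
    cohort_median: float

    @property
    def responsive(self) -> list[str]:
        return [s for s, g in self.assignments.items() if g == "responsive"]

    @property
    def resistant(self) -> list[str]:
        return [s for s, g in self.assignments.items() if g == "resistant"]


def median_split(responsiveness: Mapping[str, float]) -> GroupAssignment:
    """Split subjects at the cohort median of tremor responsiveness.

    Subjects at or above the median are responsive, below it resistant (ties
    go to the responsive group).  The median is the standard midpoint-of-two
    for even n.  An empty or single-member group triggers a warning; the
    downstream stratified resampling will reject it outright.
    """
    if len(responsiveness) < 4:
        raise ValueError("median split needs at least 4 subjects")
    vals = np.asarray(list(responsiveness.values()), dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite responsiveness value")
    med = float(np.median(vals))
    assign = {s: ("responsive" if v >= med else "resistant")
              for s, v in responsiveness.items()}
    ga = GroupAssignment(assign, med)
    for name, members in (("responsive", ga.responsive), ("resistant", ga.resistant)):
        if len(members) < 2:
            warnings.warn(
                f"median split leaves {name} group with {len(members)} subject(s); "
                "stratified resampling requires >= 2 per class", stacklevel=2)
    return ga


@dataclass
class ReactivityTable:
    """Subjects x edges matrix of FC change rates.

    ``floored`` flags entries where the |z_OFF| denominator hit the
    ``DENOM_FLOOR`` guard.
    """

    values: np.ndarray            # n_subjects x n_edges
    subject_ids: list[str]
    edge_index: list[Edge]
    floored: np.ndarray           # bool, same shape

    def validate(self) -> None:
        if self.values.shape != (len(self.subject_ids), len(self.edge_index)):
            raise ValueError("reactivity dimensions inconsistent with index")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite reactivity values")

    def subset(self, system: str | None = None,
               edge_mask: Sequence[bool] | None = None) -> "ReactivityTable":
        """Restrict to one system ('da'/'ach') or an explicit edge mask."""
        if edge_mask is None:
            if system is None:
                raise ValueError("give either system or edge_mask")
            edge_mask = [e.system == system.lower() for e in self.edge_index]
        mask = np.asarray(edge_mask, dtype=bool)
        return ReactivityTable(
            values=self.values[:, mask],
            subject_ids=list(self.subject_ids),
            edge_index=[e for e, m in zip(self.edge_index, mask) if m],
            floored=self.floored[:, mask],
        )

    def edge_column(self, edge: Edge) -> np.ndarray:
        return self.values[:, self.edge_index.index(edge)]

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, sid in enumerate(self.subject_ids):
            for j, e in enumerate(self.edge_index):
                rows.append((sid, e.system, e.subcortical, e.cortical,
                             self.values[i, j], bool(self.floored[i, j])))
        return pd.DataFrame(rows, columns=[
            "subject_id", "system", "subcortical", "cortical",
            "change_rate", "denominator_floored"])


def build_reactivity_table(off: Sequence[ConnectivitySet],
                           on: Sequence[ConnectivitySet]) -> ReactivityTable:
    """Pair OFF/ON connectivity sets by subject and compute all edge reactivities."""
    on_by_subject = {cs.subject_id: cs for cs in on}
    subject_ids, rows, flags = [], [], []
    edge_index = None
    for cs_off in off:
        cs_on = on_by_subject.get(cs_off.subject_id)
        if cs_on is None:
            raise ValueError(f"missing ON session for {cs_off.subject_id}")
        if edge_index is None:
            edge_index = cs_off.edge_index
        elif cs_off.edge_index != edge_index or cs_on.edge_index != edge_index:
            raise ValueError("edge index differs across subjects")
        z_off = cs_off.flatten()
        z_on = cs_on.flatten()
        denom = np.maximum(np.abs(z_off), DENOM_FLOOR)
        rows.append((z_on - z_off) / denom)
        flags.append(np.abs(z_off) < DENOM_FLOOR)
        subject_ids.append(cs_off.subject_id)
    table = ReactivityTable(np.asarray(rows), subject_ids, list(edge_index),
                            np.asarray(flags))
    table.validate()
    return table
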