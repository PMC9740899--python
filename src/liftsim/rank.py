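"""Points-based ranking of alternatives over stress criteria.

Per criterion, alternatives receive points 1..n by ascending value
(lowest value one point, highest n points); points are summed per
alternative into an overall score.  For motion sequences the highest
score marks the most strenuous sequence; for exoskeleton concepts the
lowest score marks the concept with the highest relief potential.

Ties between equal (rounded) values are resolved by a configurable
policy; the applied resolution is recorded in an audit list so the
choice is always reversible.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (IncompleteTableError, InvalidArgumentError,
                     MissingDispersionError)

TIE_POLICIES = ("by_dispersion_more_points_to_larger_sd",
                "by_dispersion_more_points_to_smaller_sd",
                "average_points", "stable_order")


@dataclass
class RankingTable:
    """Criteria x alternatives values with points and overall scores."""

    values: pd.DataFrame                      # index = criteria
    sds: pd.DataFrame | None = None
    direction: str = "max_is_selected"        # or "min_is_selected"
    tie_policy: str = "by_dispersion_more_points_to_larger_sd"
    weights: dict[str, float] | None = None
    points: pd.DataFrame | None = None
    scores: pd.Series | None = None
    selected: str | None = None
    tie_audit: list = field(default_factory=list)

    def __post_init__(self):
        if self.direction not in ("max_is_selected", "min_is_selected"):
            raise InvalidArgumentError(f"bad direction {self.direction!r}")
        if self.tie_policy not in TIE_POLICIES:
            raise InvalidArgumentError(f"bad tie policy {self.tie_policy!r}")

    def rank(self) -> "RankingTable":
        points = {}
        audit = []
        if len(self.values.columns) == 1:
            # degenerate table: the lone alternative takes 1 point per row
            self.points = pd.DataFrame(1.0, index=self.values.index,
                                       columns=self.values.columns)
            self.scores = self.points.sum(axis=0)
            self.selected = self.values.columns[0]
            self.tie_audit = []
            return self
        for criterion in self.values.index:
            sds = None
            if self.sds is not None and criterion in self.sds.index:
                row = self.sds.loc[criterion]
                if not row.isna().any():
                    sds = row
            pts = assign_points(self.values.loc[criterion], sds,
                                self.tie_policy, audit_label=criterion,
                                audit=audit)
            points[criterion] = pts
        self.points = pd.DataFrame(points).T[self.values.columns]
        weights = self.weights or {}
        weighted = self.points.mul(
            pd.Series({c: weights.get(c, 1.0) for c in self.points.index}),
            axis=0)
        self.scores = weighted.sum(axis=0)
        if self.direction == "max_is_selected":
            self.selected = self.scores.idxmax()
        else:
            self.selected = self.scores.idxmin()
        self.tie_audit = audit
        return self


def assign_points(values, dispersions=None,
                  tiebreak: str = "by_dispersion_more_points_to_larger_sd",
                  audit_label: str = "", audit: list | None = None
                  ) -> pd.Series:
    """Points 1..n ascending by value with configurable tie resolution."""
    if tiebreak not in TIE_POLICIES:
        raise InvalidArgumentError(f"unknown tie policy {tiebreak!r}")
    values = pd.Series(values, dtype=float)
    if len(values) < 2:
        raise InvalidArgumentError("need at least 2 alternatives")
    if not np.all(np.isfinite(values.to_numpy())):
        raise InvalidArgumentError("criterion values must be finite")
    n = len(values)
    points = pd.Series(np.zeros(n), index=values.index)
    order = np.argsort(values.to_numpy(), kind="stable")
    ranked = values.iloc[order]
    # walk groups of tied values
    pos = 0
    arr = ranked.to_numpy()
    while pos < n:
        end = pos
        while end + 1 < n and arr[end + 1] == arr[pos]:
            end += 1
        group = list(ranked.index[pos:end + 1])
        ranks = list(range(pos + 1, end + 2))      # points for this group
        if len(group) > 1:
            if tiebreak == "average_points":
                avg = sum(ranks) / len(ranks)
                for alt in group:
                    points[alt] = avg
            elif tiebreak == "stable_order":
                for alt, r in zip(group, ranks):
                    points[alt] = r
            else:
                if dispersions is None:
                    raise MissingDispersionError(
                        f"tie at value {arr[pos]} ({audit_label or 'row'}) "
                        f"needs dispersions for policy {tiebreak}")
                disp = pd.Series(dispersions, dtype=float)[group]
                asc = tiebreak == "by_dispersion_more_points_to_larger_sd"
                ordered = disp.sort_values(ascending=asc,
                                           kind="stable").index
                for alt, r in zip(ordered, ranks):
                    points[alt] = r
            if audit is not None:
                audit.append({
                    "criterion": audit_label, "value": float(arr[pos]),
                    "alternatives": group, "policy": tiebreak,
                    "points": {a: float(points[a]) for a in group}})
        else:
            points[group[0]] = ranks[0]
        pos = end + 1
    return points


def overall_score(table: RankingTable) -> tuple[pd.Series, str]:
    """Column sums of the points matrix and the selected alternative."""
    if table.points is None:
        table.rank()
    if table.points.isna().any().any():
        missing = [(c, a) for c in table.points.index
                   for a in table.points.columns
                   if pd.isna(table.points.loc[c, a])]
        raise IncompleteTableError("points matrix incomplete",
                                   missing=missing)
    return table.scores, table.selected
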