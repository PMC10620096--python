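"""Receptor prioritization: priority values, scaled ranks, composite rank.

Two orthogonal lines of evidence are combined.  *Turnover* priority rewards
proteins depleted on starvation in WT cells whose depletion is rescued in
autophagy-null cells; *proximity* priority rewards proteins enriched near
ATG8 on starvation in a LIR-docking-site-dependent manner.  Within each
experiment priorities are ranked descending and scaled by the number of
quantified proteins; across experiments of one class the minimum scaled
rank is kept; the two class ranks are summed and sorted ascending to give
the final composite rank.  A protein must appear in at least one experiment
of each class to be ranked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator


def turnover_priority(wt_fc, ko_minus_wt):
    """Starvation/autophagy turnover priority.

    priority = min(|wt_fc|, ko_minus_wt) when the protein is depleted in WT
    (wt_fc <= 0) and stabilized by the KO (ko_minus_wt >= 0); otherwise 0.
    Accepts scalars or aligned array-likes.
    """
    wt = np.asarray(wt_fc, dtype=float)
    delta = np.asarray(ko_minus_wt, dtype=float)
    out = np.where((wt <= 0) & (delta >= 0), np.minimum(np.abs(wt), delta), 0.0)
    if np.isscalar(wt_fc) or np.ndim(wt_fc) == 0:
        return float(out)
    if isinstance(wt_fc, pd.Series):
        return pd.Series(out, index=wt_fc.index, name="priority")
    return out


def proximity_priority(wt_fc, mutant_minus_wt):
    """ATG8-proximity priority.

    priority = min(wt_fc, |mutant_minus_wt|) when the protein is enriched in
    WT-ATG8 on starvation (wt_fc >= 0) and the enrichment is lost in the LDS
    mutant (mutant_minus_wt <= 0); otherwise 0.
    """
    wt = np.asarray(wt_fc, dtype=float)
    delta = np.asarray(mutant_minus_wt, dtype=float)
    out = np.where((wt >= 0) & (delta <= 0), np.minimum(wt, np.abs(delta)), 0.0)
    if np.isscalar(wt_fc) or np.ndim(wt_fc) == 0:
        return float(out)
    if isinstance(wt_fc, pd.Series):
        return pd.Series(out, index=wt_fc.index, name="priority")
    return out


def scaled_ranks(
    priorities: pd.Series,
    n_total: int | None = None,
    zero_priority: str = "tail",
) -> pd.Series:
    """Descending dense rank scaled by the experiment's protein count.

    Rank 1 is the highest priority; ties break by protein-ID lexicographic
    order; scaled rank = rank / N with N the number of proteins quantified
    in the experiment (``n_total`` overrides ``len(priorities)``).

    ``zero_priority="tail"`` ranks zero-priority proteins at the tail (the
    default); ``"drop"`` removes them before ranking, with N then counting
    only the positive-priority proteins.
    """
    if zero_priority not in ("tail", "drop"):
        raise ValueError(f"unknown zero_priority mode {zero_priority!r}")
    pr = priorities.astype(float)
    if (pr < 0).any():
        raise ValueError("priorities must be non-negative")
    if zero_priority == "drop":
        pr = pr[pr > 0]
        n = len(pr)
    else:
        n = len(pr) if n_total is None else n_total
    if n == 0:
        return pd.Series(dtype=float, name="scaled_rank")
    order = pr.to_frame("p").assign(_pid=pr.index.astype(str)) \
        .sort_values(["p", "_pid"], ascending=[False, True], kind="mergesort")
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order.index, dtype=float)
    out = (ranks / n).reindex(priorities.index if zero_priority == "tail" else pr.index)
    out.name = "scaled_rank"
    return out


def combine_min(per_experiment: list[pd.Series]) -> pd.Series:
    """Minimum scaled rank over the experiments where a protein was quantified."""
    if not per_experiment:
        raise ValueError("need at least one experiment")
    combined = pd.concat(per_experiment, axis=1)
    out = combined.min(axis=1, skipna=True)
    out.name = "min_scaled_rank"
    return out


def composite_rank(
    turnover_rank: pd.Series,
    proximity_rank: pd.Series,
) -> pd.DataFrame:
    """Sum the two class ranks and sort ascending into the final ranking.

    Only proteins present in at least one turnover experiment *and* one
    proximity experiment are eligible; ties in the summed rank break by
    protein-ID order.
    """
    eligible = turnover_rank.dropna().index.intersection(proximity_rank.dropna().index)
    summed = turnover_rank.loc[eligible] + proximity_rank.loc[eligible]
    order = summed.to_frame("summed_rank").assign(_pid=summed.index.astype(str)) \
        .sort_values(["summed_rank", "_pid"], kind="mergesort")
    out = pd.DataFrame(
        {
            "scaled_rank_turnover": turnover_rank.loc[order.index],
            "scaled_rank_proximity": proximity_rank.loc[order.index],
            "summed_rank": order["summed_rank"],
            "final_rank": np.arange(1, len(order) + 1),
        }
    )
    out.index.name = "protein_id"
    return out


@dataclass
class DependenceClassification:
    """Per-protein genotype-dependent stabilization call."""

    table: pd.DataFrame   # delta, stabilized, golgi_class
    counts: pd.DataFrame  # per golgi_class: n_stabilized / n_total
    threshold: float


def classify_dependence(
    fc_wt: pd.Series,
    fc_ko: pd.Series,
    ann: pd.DataFrame,
    threshold: float = 0.2,
    reference: pd.Index | list | None = None,
) -> DependenceClassification:
    """Classify proteins as stabilized by a KO (delta > threshold, strict).

    delta = KO log2FC - WT log2FC for the same starved/untreated contrast.
    Counts of stabilized vs total per Golgi class are reported over
    ``reference`` when given (e.g. the FIP200-stabilized CAP set), else over
    all classified proteins.
    """
    common = fc_wt.index.intersection(fc_ko.index)
    delta = (fc_ko.loc[common] - fc_wt.loc[common]).astype(float)
    table = pd.DataFrame(
        {
            "stabilization_delta": delta,
            "stabilized": delta > threshold,
            "golgi_class": ann["golgi_class"].reindex(common),
        }
    )
    table.index.name = "protein_id"
    scope = table if reference is None else table.loc[table.index.intersection(pd.Index(reference))]
    counts = scope.groupby("golgi_class")["stabilized"].agg(
        n_stabilized="sum", n_total="count"
    )
    return DependenceClassification(table=table, counts=counts, threshold=threshold)


class ReceptorRanker(BaseEstimator):
    """Composite receptor prioritization in estimator form.

    ``fit`` takes two lists of per-experiment evidence tables, each a
    DataFrame indexed by protein with columns ``wt_fc`` and ``delta``
    (KO-WT for turnover experiments, mutant-WT for proximity experiments),
    computes per-experiment priorities and scaled ranks, combines by
    minimum within each class, and builds the composite ranking.

    Attributes
    ----------
    turnover_rank_ , proximity_rank_ : per-class minimum scaled ranks
    ranking_ : the composite PriorityRankTable (DataFrame)
    """

    def __init__(self, zero_priority: str = "tail"):
        self.zero_priority = zero_priority

    def _class_rank(self, tables, priority_fn) -> pd.Series:
        ranks = []
        for tab in tables:
            pr = priority_fn(tab["wt_fc"], tab["delta"])
            ranks.append(scaled_ranks(pr, zero_priority=self.zero_priority))
        return combine_min(ranks)

    def fit(self, turnover_tables, proximity_tables) -> "ReceptorRanker":
        self.turnover_rank_ = self._class_rank(turnover_tables, turnover_priority)
        self.proximity_rank_ = self._class_rank(proximity_tables, proximity_priority)
        self.ranking_ = composite_rank(self.turnover_rank_, self.proximity_rank_)
        return self

    def fit_predict(self, turnover_tables, proximity_tables) -> pd.DataFrame:
        return self.fit(turnover_tables, proximity_tables).ranking_
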