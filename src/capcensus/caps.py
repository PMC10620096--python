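"""Consensus-profile CAP calling.

Candidate autophagy proteins (CAPs) are proteins whose standardized
abundance profile across genotype x treatment conditions tracks the
consensus profile of known autophagy fluxers — depleted on starvation in
autophagy-proficient cells, rescued in autophagy-null cells.  Agreement is
scored as the root-mean-square error (RMSE) between a protein's per-channel
z-scores and the channel-expanded consensus:

    RMSE = sqrt( sum_i (predicted_i - observed_i)^2 / n_channels )

and the lowest-RMSE decile of scored proteins is called as CAPs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import ZScoreMatrix
from .normalize import benjamini_hochberg, condition_medians


@dataclass
class ConsensusProfile:
    """Per-condition predicted z (median over known fluxers of their
    condition-median z) plus the fluxer panel it was built from."""

    values: pd.Series  # index: MultiIndex (genotype, treatment)
    fluxers: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.fluxers) == 0:
            raise ValueError("consensus profile requires at least one known fluxer")

    def expand_to_channels(self, design: pd.DataFrame) -> pd.Series:
        """Each channel inherits its condition's consensus value."""
        vals = {
            row.channel_id: self.values[(row.genotype, row.treatment)]
            for row in design.itertuples(index=False)
        }
        return pd.Series(vals)


@dataclass
class CapSet:
    """The called CAP membership for one experiment."""

    experiment_id: str
    members: list
    fraction: float
    rmse_threshold: float
    n_scored: int

    def __contains__(self, protein_id) -> bool:
        return protein_id in set(self.members)

    def as_series(self, index: pd.Index) -> pd.Series:
        return pd.Series(index.isin(self.members), index=index, name="is_cap")


def build_consensus(z: ZScoreMatrix, known_fluxers) -> ConsensusProfile:
    """Median across known fluxers of each fluxer's condition-median z."""
    fluxers = [p for p in known_fluxers if p in z.values.index]
    if not fluxers:
        raise ValueError("no known fluxer is quantified in this experiment")
    cm = condition_medians(
        ZScoreMatrix(z.values.loc[fluxers], z.design, z.source_experiment_id)
    )
    consensus = cm.median(axis=0, skipna=True)
    return ConsensusProfile(values=consensus, fluxers=fluxers)


def rmse_scores(
    z: ZScoreMatrix,
    consensus: ConsensusProfile,
    missing_policy: str = "complete",
) -> pd.DataFrame:
    """Per-protein RMSE against the channel-expanded consensus.

    ``missing_policy="complete"`` (default) scores only proteins quantified
    in every channel — the formula divides by the full channel count — and
    marks the rest ``complete=False`` with a missing RMSE.
    ``missing_policy="observed"`` instead averages the squared error over
    the observed channels.
    """
    if missing_policy not in ("complete", "observed"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    predicted = consensus.expand_to_channels(z.design).reindex(z.values.columns)
    if predicted.isna().any():
        raise ValueError("consensus does not cover every design condition")
    diff2 = (z.values - predicted) ** 2
    n_obs = z.values.notna().sum(axis=1)
    n_channels = z.values.shape[1]
    complete = n_obs == n_channels
    if missing_policy == "complete":
        rmse = np.sqrt(diff2.sum(axis=1, skipna=False) / n_channels)
    else:
        rmse = np.sqrt(diff2.sum(axis=1, skipna=True) / n_obs.where(n_obs > 0))
    out = pd.DataFrame(
        {"rmse": rmse, "n_channels": n_obs.astype(int), "complete": complete}
    )
    out.index.name = "protein_id"
    return out


def call_caps(
    rmse_table: pd.DataFrame,
    fraction: float = 0.10,
    experiment_id: str = "",
) -> CapSet:
    """Call the lowest-RMSE decile as CAPs.

    Membership size is ``floor(fraction x N_scored)`` over proteins with a
    defined RMSE; boundary ties are broken by protein-ID lexicographic order
    so the call is deterministic and order-independent.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    scored = rmse_table.loc[rmse_table["rmse"].notna()]
    n_scored = len(scored)
    if n_scored == 0:
        raise ValueError("no scored proteins to call CAPs from")
    # exact decimal floor; binary-float fraction*N can land a hair under an
    # integer boundary
    k = int(Fraction(str(fraction)) * n_scored)
    ordered = scored.assign(_pid=scored.index).sort_values(
        ["rmse", "_pid"], kind="mergesort"
    )
    members = ordered.index[:k].tolist()
    threshold = float(ordered["rmse"].iloc[k - 1]) if k > 0 else math.nan
    return CapSet(
        experiment_id=experiment_id,
        members=members,
        fraction=fraction,
        rmse_threshold=threshold,
        n_scored=n_scored,
    )


@dataclass
class OverlapReport:
    intersection: list
    n_a: int
    n_b: int
    n_common: int
    jaccard: float


def cap_overlap(a: CapSet, b: CapSet) -> OverlapReport:
    """Exact intersection of two CAP sets (e.g. two starvation regimes)."""
    sa, sb = set(a.members), set(b.members)
    common = sorted(sa & sb)
    union = len(sa | sb)
    return OverlapReport(
        intersection=common,
        n_a=len(sa),
        n_b=len(sb),
        n_common=len(common),
        jaccard=len(common) / union if union else math.nan,
    )


def enrichment(
    caps: CapSet,
    background,
    ann: pd.DataFrame,
    grouping: str = "compartment",
) -> pd.DataFrame:
    """Per-term two-sided Fisher's exact test of CAPs vs background, BH-adjusted.

    ``grouping`` names an annotation column ("compartment", "golgi_class",
    or any custom flat-label column).  Terms absent from the background are
    skipped.
    """
    background = pd.Index(background).unique()
    if len(background) == 0:
        raise ValueError("empty background")
    cap_ids = set(caps.members)
    if not cap_ids <= set(background):
        raise ValueError("CAP set must be a subset of the background")
    terms = ann.loc[ann.index.intersection(background), grouping]
    rows = []
    n_cap = len(cap_ids)
    n_bg = len(background)
    for term in sorted(terms.dropna().unique()):
        in_term = set(terms.index[terms == term])
        a = len(cap_ids & in_term)
        b = n_cap - a
        c = len(in_term) - a
        d = (n_bg - n_cap) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(dict(term=term, n_cap=a, n_background=len(in_term),
                         odds_ratio=odds, p_value=p))
    out = pd.DataFrame(rows).set_index("term")
    out["q_value"] = benjamini_hochberg(out["p_value"])
    return out


class CapCaller(BaseEstimator):
    """Consensus-RMSE CAP classifier in estimator form.

    ``fit(Z, y)`` takes a protein x channel z-score DataFrame and a boolean
    known-fluxer indicator aligned to its rows (plus the channel design via
    the ``design`` fit parameter), builds the fluxer consensus profile and
    scores every protein.  ``predict`` returns boolean CAP membership for
    the fitted proteins; ``score_samples`` returns negative RMSE (higher =
    more CAP-like), following the outlier-detector convention.

    Attributes
    ----------
    consensus_ : ConsensusProfile
    rmse_ : pandas.DataFrame with columns (rmse, n_channels, complete)
    cap_set_ : CapSet
    labels_ : pandas.Series of bool, CAP membership
    """

    def __init__(self, fraction: float = 0.10, missing_policy: str = "complete"):
        self.fraction = fraction
        self.missing_policy = missing_policy

    def fit(self, Z: pd.DataFrame, y, design: pd.DataFrame) -> "CapCaller":
        y = pd.Series(np.asarray(y, dtype=bool), index=Z.index)
        zmat = ZScoreMatrix(values=Z, design=design,
                            source_experiment_id=str(design["experiment_id"].iloc[0]))
        self.consensus_ = build_consensus(zmat, Z.index[y])
        self.rmse_ = rmse_scores(zmat, self.consensus_, self.missing_policy)
        self.cap_set_ = call_caps(self.rmse_, self.fraction,
                                  experiment_id=zmat.source_experiment_id)
        self.labels_ = self.cap_set_.as_series(Z.index)
        return self

    def fit_predict(self, Z, y, design) -> pd.Series:
        return self.fit(Z, y, design).labels_

    def predict(self, Z: pd.DataFrame) -> pd.Series:
        return pd.Series(Z.index.isin(self.cap_set_.members), index=Z.index,
                         name="is_cap")

    def score_samples(self, Z: pd.DataFrame) -> pd.Series:
        return -self.rmse_["rmse"].reindex(Z.index)
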