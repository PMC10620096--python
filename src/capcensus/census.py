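"""Absolute copy numbers and the compartment copy-loss census.

Per-cell copy numbers come from a TMT-adapted proteomic ruler: relative TMT
reporter signal apportions each peptide's MS1 precursor area to the
untreated wild-type channels, the apportioned signal is summed per protein,
and the histone-anchored ruler converts signal to copies per cell using the
fixed histone:DNA mass ratio.  Copies lost on starvation follow from each
protein's relative fold change, and the census aggregates losses per
subcellular compartment, split into CAP-attributable and other loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.constants import Avogadro
from sklearn.base import BaseEstimator

from .caps import CapSet

logger = logging.getLogger("capcensus")


def apportion_ms1(
    peptides: pd.DataFrame,
    channels: list[str],
    reference_channels: list[str],
) -> pd.Series:
    """Apportion MS1 precursor area to the reference channels, per protein.

    For each peptide the reference share is (sum of reference reporter
    intensities) / (sum over all reporter intensities); share x MS1 area is
    summed to the protein level.  Peptides with zero total reporter signal
    carry no quantitative information and are excluded (logged).
    """
    reference_channels = list(reference_channels)
    if not reference_channels:
        raise ValueError("reference_channels must be non-empty")
    missing = set(channels) - set(peptides.columns)
    if missing:
        raise ValueError(f"peptide table lacks reporter channels: {sorted(missing)}")
    if not set(reference_channels) <= set(channels):
        raise ValueError("reference channels must be a subset of design channels")
    total = peptides[channels].sum(axis=1)
    zero = total == 0
    if zero.any():
        logger.warning("apportion_ms1: excluding %d peptide(s) with zero reporter signal",
                       int(zero.sum()))
    pep = peptides.loc[~zero]
    share = pep[reference_channels].sum(axis=1) / pep[channels].sum(axis=1)
    signal = (share * pep["ms1_area"]).groupby(pep["protein_id"]).sum()
    signal.name = "apportioned_signal"
    signal.index.name = "protein_id"
    return signal


def ruler_copies(
    signal: pd.Series,
    ann: pd.DataFrame,
    dna_mass_pg: float = 6.5,
) -> pd.Series:
    """Histone-anchored proteomic ruler: signal -> copies per cell.

    copies_i = signal_i x (m_DNA x N_A / M_i) / sum_histones(signal_h),
    with m_DNA the DNA mass per cell (pg) and M_i the molar mass (g/mol).
    The default 6.5 pg corresponds to a diploid human genome; adjust for
    aneuploid lines.
    """
    molar_mass = ann["molar_mass"].reindex(signal.index)
    histones = ann.index[ann["histone"]].intersection(signal.index)
    hist_signal = signal.reindex(histones).sum()
    if len(histones) == 0 or not hist_signal > 0:
        raise ValueError("ruler requires at least one histone with signal")
    copies = signal * (dna_mass_pg * 1e-12 * Avogadro / molar_mass) / hist_signal
    copies.name = "copies_per_cell"
    return copies


def copy_loss(
    copies: pd.Series,
    log2fc: pd.Series,
    signed: bool = False,
) -> pd.DataFrame:
    """Copies lost per protein from copies and the starved/untreated log2 FC.

    copies_lost = copies x max(0, 1 - 2**log2fc); proteins that increase
    lose nothing (``signed=True`` keeps negative losses for gainers
    instead of clamping).
    """
    common = copies.index.intersection(log2fc.index)
    loss = copies.loc[common] * (1.0 - 2.0 ** log2fc.loc[common])
    if not signed:
        loss = loss.clip(lower=0.0)
    out = pd.DataFrame({"copies_per_cell": copies.loc[common], "copies_lost": loss})
    out.index.name = "protein_id"
    return out


@dataclass
class CensusSummary:
    """Per-compartment copy-loss census plus the grand totals."""

    table: pd.DataFrame          # per compartment: cap/total loss and fractions
    total_cap_loss: float        # summed copies lost from CAPs
    total_loss: float            # summed copies lost from all proteins


def compartment_census(
    copies: pd.DataFrame,
    caps: CapSet,
    ann: pd.DataFrame,
    split_golgi: bool = False,
) -> CensusSummary:
    """Aggregate copy loss per compartment, CAP-attributable vs other.

    Per compartment: summed CAP loss, summed total loss, the compartment's
    percentage of all CAP loss (sums to 100), and the fraction of that
    compartment's total loss attributable to CAPs (missing where the
    compartment lost nothing).  ``split_golgi`` separates Golgi membrane
    from Golgi-associated proteins.
    """
    df = copies.copy()
    comp = ann["compartment"].reindex(df.index)
    if split_golgi:
        gc = ann["golgi_class"].reindex(df.index)
        comp = comp.where(comp != "Golgi",
                          gc.map({"membrane": "Golgi membrane",
                                  "associated": "Golgi associated"}))
    df["compartment"] = comp
    df["is_cap"] = df.index.isin(caps.members)

    grouped = df.groupby("compartment", dropna=False)
    cap_loss = grouped.apply(
        lambda g: g.loc[g["is_cap"], "copies_lost"].sum(), include_groups=False
    )
    total_loss = grouped["copies_lost"].sum()
    all_cap = df.loc[df["is_cap"], "copies_lost"].sum()
    all_loss = df["copies_lost"].sum()
    table = pd.DataFrame(
        {
            "cap_copies_lost": cap_loss,
            "total_copies_lost": total_loss,
            "pct_of_all_cap_loss": 100.0 * cap_loss / all_cap if all_cap > 0 else np.nan,
            "cap_attributable_fraction": (cap_loss / total_loss).where(total_loss > 0),
        }
    )
    table.index.name = "compartment"
    return CensusSummary(table=table, total_cap_loss=float(all_cap),
                         total_loss=float(all_loss))


class ProteomeRuler(BaseEstimator):
    """TMT-adapted proteomic ruler in estimator form.

    ``fit`` apportions peptide MS1 areas to the reference (untreated WT)
    channels and anchors on histones; ``transform``/``predict`` return
    copies per cell for the fitted proteins.

    Attributes
    ----------
    signal_ : per-protein apportioned MS1 signal
    copies_ : per-protein copies per cell
    """

    def __init__(self, dna_mass_pg: float = 6.5):
        self.dna_mass_pg = dna_mass_pg

    def fit(self, peptides: pd.DataFrame, y=None, *, channels, reference_channels,
            annotations) -> "ProteomeRuler":
        self.signal_ = apportion_ms1(peptides, channels, reference_channels)
        self.copies_ = ruler_copies(self.signal_, annotations, self.dna_mass_pg)
        return self

    def transform(self, X=None) -> pd.Series:
        return self.copies_

    def fit_transform(self, peptides, y=None, **fit_params) -> pd.Series:
        return self.fit(peptides, y, **fit_params).transform()
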