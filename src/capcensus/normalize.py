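"""Channel normalization, log2 transform, z-scoring, and differential tests.

The processing chain mirrors standard isobaric-labelling practice: scale the
reporter channels to a common total (or median), log2-transform, standardize
each protein's profile across the plex, then summarize and test per
condition.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .io import QuantExperiment, ZScoreMatrix

logger = logging.getLogger("capcensus")


class ChannelNormalizer(TransformerMixin, BaseEstimator):
    """Scale each channel so its column sum (or median) equals the grand mean.

    Parameters
    ----------
    method : {"sum", "median"}
        Column statistic to equalize.  Total-proteome experiments are
        conventionally sum-normalized, proximity-labelling experiments
        median-normalized.
    """

    def __init__(self, method: str = "sum"):
        self.method = method

    def fit(self, X: pd.DataFrame, y=None) -> "ChannelNormalizer":
        if self.method not in ("sum", "median"):
            raise ValueError(f"unknown normalization method {self.method!r}")
        stat = X.sum(axis=0, skipna=True) if self.method == "sum" \
            else X.median(axis=0, skipna=True)
        if (stat == 0).any() or stat.isna().any():
            bad = stat.index[(stat == 0) | stat.isna()].tolist()
            raise ValueError(f"channel(s) with zero/absent {self.method}: {bad}")
        self.column_stat_ = stat
        self.target_ = float(stat.mean())
        self.scale_ = self.target_ / stat
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X * self.scale_.reindex(X.columns)


def channel_normalize(exp: QuantExperiment, method: str = "sum") -> QuantExperiment:
    """Normalize reporter channels; requires a raw (non-normalized) matrix."""
    if exp.normalized:
        raise ValueError("experiment is already normalized")
    if exp.log2:
        raise ValueError("normalize before log2 transform")
    scaled = ChannelNormalizer(method=method).fit_transform(exp.intensity)
    return exp.with_intensity(scaled, normalized=True)


def log2_transform(exp: QuantExperiment) -> QuantExperiment:
    """log2-transform; zeros become missing (a zero reporter ion is treated
    as non-quantification, not as vanishing abundance)."""
    if not exp.normalized:
        raise ValueError("normalize channels before log2 transform")
    if exp.log2:
        raise ValueError("experiment is already log2-transformed")
    vals = exp.intensity.to_numpy(dtype=float)
    if np.nanmin(vals, initial=np.inf) < 0:
        raise ValueError("negative intensity encountered before log2")
    n_zero = int((vals == 0).sum())
    if n_zero:
        logger.warning("log2: %d zero intensities set to missing", n_zero)
    with np.errstate(divide="ignore"):
        out = np.where(vals > 0, np.log2(np.where(vals > 0, vals, 1.0)), np.nan)
    return exp.with_intensity(
        pd.DataFrame(out, index=exp.proteins, columns=exp.channels), log2=True
    )


def zscore(exp: QuantExperiment) -> ZScoreMatrix:
    """Standardize each protein's profile across this experiment's channels.

    Uses the sample (n-1) SD.  Constant rows cannot be standardized and
    become all-missing with a warning.
    """
    if not exp.log2:
        raise ValueError("z-scoring requires log2 data")
    X = exp.intensity
    mean = X.mean(axis=1, skipna=True)
    sd = X.std(axis=1, ddof=1, skipna=True)
    constant = (sd == 0).fillna(False)
    if constant.any():
        logger.warning("z-score: %d constant row(s) set to missing", int(constant.sum()))
    z = X.sub(mean, axis=0).div(sd.where(~constant), axis=0)
    return ZScoreMatrix(values=z, design=exp.design,
                        source_experiment_id=exp.experiment_id)


def condition_medians(z: ZScoreMatrix) -> pd.DataFrame:
    """Median across replicate channels of each (genotype, treatment)."""
    cols = {}
    for cond in z.conditions():
        chans = z.channels_for(*cond)
        cols[cond] = z.values[chans].median(axis=1, skipna=True)
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["genotype", "treatment"])
    return out


def benjamini_hochberg(p: pd.Series) -> pd.Series:
    """BH-adjusted q-values; missing p stay missing."""
    q = pd.Series(np.nan, index=p.index, dtype=float)
    ok = p.notna()
    if ok.any():
        q[ok] = multipletests(p[ok].to_numpy(), method="fdr_bh")[1]
    return q


def fold_changes(
    exp: QuantExperiment,
    contrast: tuple[str, str, str],
    min_replicates: int = 2,
) -> pd.DataFrame:
    """Per-protein log2 fold change and Student's t-test for one contrast.

    ``contrast = (genotype, treatment_a, treatment_b)`` yields
    ``log2FC = mean(a) - mean(b)`` on log2 data, an equal-variance two-sided
    Student's t-test, and BH q-values across all tested proteins.  With fewer
    than two replicates per side the fold change is still returned but p/q
    are missing.
    """
    if not exp.log2:
        raise ValueError("fold changes require log2 data")
    genotype, treat_a, treat_b = contrast
    chans_a = exp.channels_for(genotype, treat_a)
    chans_b = exp.channels_for(genotype, treat_b)
    if not chans_a or not chans_b:
        raise ValueError(f"contrast {contrast} has no channels on one side")
    A = exp.intensity[chans_a]
    B = exp.intensity[chans_b]
    log2fc = A.mean(axis=1, skipna=True) - B.mean(axis=1, skipna=True)

    p = pd.Series(np.nan, index=exp.proteins, dtype=float)
    n_a = A.notna().sum(axis=1)
    n_b = B.notna().sum(axis=1)
    testable = (n_a >= min_replicates) & (n_b >= min_replicates) & (n_a >= 2) & (n_b >= 2)
    if testable.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(
                A[testable], B[testable], axis=1, equal_var=True,
                nan_policy="omit",
            )
        p[testable] = res.pvalue
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": p,
            "q_value": benjamini_hochberg(p),
        }
    )
    out.index.name = "protein_id"
    out.attrs["contrast"] = f"{genotype}:{treat_a}/{treat_b}"
    return out
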