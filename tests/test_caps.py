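import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

import capcensus as cc
from capcensus.io import ZScoreMatrix

from conftest import make_annotations, make_design


def zmatrix(vals, design):
    df = pd.DataFrame(np.asarray(vals, dtype=float),
                      index=[f"P{i:03d}" for i in range(len(vals))],
                      columns=design["channel_id"].tolist())
    return ZScoreMatrix(values=df, design=design, source_experiment_id="toy")


class TestConsensus:
    def test_single_fluxer_equals_its_condition_medians(self, rng):
        design = make_design(n_replicates=3)
        z = zmatrix(rng.normal(size=(4, len(design))), design)
        consensus = cc.build_consensus(z, ["P001"])
        cm = cc.condition_medians(z).loc["P001"]
        pd.testing.assert_series_equal(consensus.values, cm, check_names=False)

    def test_median_of_three_fluxers(self):
        design = make_design(genotypes=("WT",), treatments=("UT",), n_replicates=1)
        z = zmatrix([[-1.0], [-0.5], [-2.0]], design)
        consensus = cc.build_consensus(z, ["P000", "P001", "P002"])
        assert consensus.values[("WT", "UT")] == pytest.approx(-1.0)

    def test_matches_median_of_medians_oracle(self, rng):
        design = make_design(n_replicates=3)
        z = zmatrix(rng.normal(size=(8, len(design))), design)
        fluxers = ["P000", "P003", "P005"]
        consensus = cc.build_consensus(z, fluxers)
        for (g, t) in z.conditions():
            chans = z.channels_for(g, t)
            per_fluxer = [np.median(z.values.loc[f, chans]) for f in fluxers]
            assert consensus.values[(g, t)] == pytest.approx(np.median(per_fluxer))

    def test_no_fluxers_quantified_is_error(self, rng):
        design = make_design()
        z = zmatrix(rng.normal(size=(3, len(design))), design)
        with pytest.raises(ValueError, match="fluxer"):
            cc.build_consensus(z, ["ABSENT"])


def expand(consensus, design):
    return consensus.expand_to_channels(design)


class TestRmse:
    def test_profile_identical_to_consensus_scores_zero(self, rng):
        design = make_design(n_replicates=2)
        z = zmatrix(rng.normal(size=(3, len(design))), design)
        consensus = cc.build_consensus(z, ["P000"])
        z.values.loc["P002"] = expand(consensus, design)[z.values.columns].to_numpy()
        rmse = cc.rmse_scores(z, consensus)
        assert rmse.loc["P002", "rmse"] == pytest.approx(0.0, abs=1e-12)

    def test_two_channel_hand_example(self):
        design = make_design(genotypes=("WT",), n_replicates=1)
        z = zmatrix([[0.0, 0.0], [0.0, -1.0]], design)
        consensus = cc.build_consensus(z, ["P001"])  # predicted (0, -1)
        rmse = cc.rmse_scores(z, consensus)
        assert rmse.loc["P000", "rmse"] == pytest.approx(math.sqrt(0.5))

    def test_matches_brute_force_channel_loop(self, rng):
        design = make_design(n_replicates=3)
        z = zmatrix(rng.normal(size=(20, len(design))), design)
        consensus = cc.build_consensus(z, ["P000", "P001"])
        rmse = cc.rmse_scores(z, consensus)
        pred = expand(consensus, design)
        for pid in z.values.index:
            acc = 0.0
            for ch in z.values.columns:
                acc += (pred[ch] - z.values.loc[pid, ch]) ** 2
            assert rmse.loc[pid, "rmse"] == pytest.approx(
                math.sqrt(acc / len(z.values.columns)), abs=1e-12)

    def test_channel_permutation_invariance(self, rng):
        design = make_design(n_replicates=3)
        z = zmatrix(rng.normal(size=(10, len(design))), design)
        consensus = cc.build_consensus(z, ["P000"])
        base = cc.rmse_scores(z, consensus)["rmse"]
        perm = rng.permutation(len(design))
        z2 = ZScoreMatrix(values=z.values.iloc[:, perm],
                          design=design.iloc[perm].reset_index(drop=True))
        again = cc.rmse_scores(z2, cc.build_consensus(z2, ["P000"]))["rmse"]
        np.testing.assert_allclose(base, again, atol=1e-12)

    def test_missing_policy(self, rng):
        design = make_design(n_replicates=2)
        z = zmatrix(rng.normal(size=(5, len(design))), design)
        z.values.iloc[2, 3] = np.nan
        consensus = cc.build_consensus(z, ["P000"])
        strict = cc.rmse_scores(z, consensus, missing_policy="complete")
        assert not strict.loc["P002", "complete"]
        assert np.isnan(strict.loc["P002", "rmse"])
        loose = cc.rmse_scores(z, consensus, missing_policy="observed")
        assert np.isfinite(loose.loc["P002", "rmse"])


class TestCallCaps:
    def _table(self, rmse_values):
        return pd.DataFrame(
            {"rmse": rmse_values,
             "n_channels": 4, "complete": True},
            index=[f"P{i:04d}" for i in range(len(rmse_values))])

    def test_exact_decile_size(self, rng):
        caps = cc.call_caps(self._table(rng.uniform(size=1000)), fraction=0.10)
        assert len(caps.members) == 100
        assert caps.n_scored == 1000

    def test_members_are_lowest_rmse(self, rng):
        tab = self._table(rng.uniform(size=200))
        caps = cc.call_caps(tab, 0.10)
        cutoff = tab["rmse"].sort_values().iloc[19]
        assert max(tab.loc[caps.members, "rmse"]) <= cutoff
        assert caps.rmse_threshold == pytest.approx(max(tab.loc[caps.members, "rmse"]))

    def test_all_equal_ties_break_by_id(self):
        caps = cc.call_caps(self._table([0.5] * 30), 0.10)
        assert caps.members == ["P0000", "P0001", "P0002"]

    def test_fraction_near_one_approaches_full_set(self, rng):
        tab = self._table(rng.uniform(size=50))
        caps = cc.call_caps(tab, fraction=1.0 - 1e-9)
        assert len(caps.members) == 49  # floor((1-eps) * 50)

    def test_incomplete_proteins_excluded_from_denominator(self, rng):
        tab = self._table(rng.uniform(size=100))
        tab.iloc[:37, tab.columns.get_loc("rmse")] = np.nan
        caps = cc.call_caps(tab, 0.10)
        assert caps.n_scored == 63
        assert len(caps.members) == 6  # floor(0.1 * 63)

    def test_empty_table_is_error(self):
        with pytest.raises(ValueError, match="no scored"):
            cc.call_caps(self._table([np.nan, np.nan]), 0.10)


class TestOverlap:
    def test_identity_disjoint_and_partial(self):
        mk = lambda ids: cc.CapSet("e", list(ids), 0.1, 0.5, 100)
        a = mk(["A", "B", "C"])
        assert cc.cap_overlap(a, a).n_common == 3
        assert cc.cap_overlap(a, mk(["D"])).n_common == 0
        rep = cc.cap_overlap(a, mk(["B", "C", "D"]))
        assert rep.intersection == ["B", "C"]
        assert rep.jaccard == pytest.approx(2 / 4)


class TestEnrichment:
    def test_matches_hypergeometric_enumeration(self):
        """Two-sided Fisher p equals summed hypergeometric point masses."""
        ids = [f"P{i:03d}" for i in range(100)]
        ann = make_annotations(ids)
        ann.loc[ids[:10], "compartment"] = "Golgi"
        ann.loc[ids[:10], "golgi_class"] = "membrane"
        ann.loc[ids[:10], "tm_count"] = 1
        ann = cc.validate_annotations(ann)
        caps = cc.CapSet("e", ids[:5] + ids[20:25], 0.1, 0.5, 100)  # 5 of 10 Golgi
        enr = cc.enrichment(caps, ids, ann, grouping="compartment")
        K, n, N = 10, 10, 100  # Golgi in background, caps drawn, background
        pmf = hypergeom(N, K, n).pmf(np.arange(0, min(K, n) + 1))
        p_expected = pmf[pmf <= pmf[5] * (1 + 1e-7)].sum()
        assert enr.loc["Golgi", "p_value"] == pytest.approx(p_expected, rel=1e-6)
        a, b, c, d = 5, 5, 5, 85
        assert enr.loc["Golgi", "odds_ratio"] == pytest.approx((a * d) / (b * c))

    def test_caps_equal_background_gives_null_result(self):
        ids = [f"P{i}" for i in range(20)]
        ann = make_annotations(ids)
        caps = cc.CapSet("e", ids, 1.0, 1.0, 20)
        enr = cc.enrichment(caps, ids, ann)
        assert (enr["p_value"] == 1.0).all()

    def test_term_absent_from_background_skipped(self):
        ids = ["P1", "P2"]
        ann = make_annotations(ids + ["P3"])
        ann.loc["P3", "compartment"] = "lysosome"
        caps = cc.CapSet("e", ["P1"], 0.5, 0.5, 2)
        enr = cc.enrichment(caps, ids, ann)
        assert "lysosome" not in enr.index

    def test_caps_outside_background_rejected(self):
        ann = make_annotations(["P1"])
        caps = cc.CapSet("e", ["P2"], 0.5, 0.5, 1)
        with pytest.raises(ValueError, match="subset"):
            cc.enrichment(caps, ["P1"], ann)


class TestRecoveryMonotonicity:
    def test_recall_non_decreasing_in_rescue_fraction(self):
        """Stronger genotype dependence never hurts planted-client recall."""
        recalls = []
        for rescue in (0.0, 0.5, 1.0):
            cfg = cc.SimulationConfig(n_proteins=1200, rescue_fraction=rescue,
                                      seed=99)
            exp, ann, truth = cc.simulate_quant(cfg)
            z = cc.zscore(cc.log2_transform(cc.channel_normalize(exp)))
            caller = cc.CapCaller(0.10).fit(z.values, ann["known_fluxer"],
                                            exp.design)
            planted = set(truth.labels.index[
                truth.labels.isin(["autophagy_client", "known_fluxer"])])
            rec = len(set(caller.cap_set_.members) & planted) / len(planted)
            recalls.append(rec)
        assert recalls == sorted(recalls)
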