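"""Window quantification, fold-change classification, metagene and contrasts."""

import numpy as np
import pandas as pd
import pytest

from driploop import breaks
from driploop.breaks import (
    classify_sites,
    group_compare,
    hybrid_correlation,
    metagene,
    site_fold_changes,
    window_signal,
)
from driploop.coverage import CoverageTrack, depth, normalize
from helpers import make_library, random_fragments


def constant_track(value, length=10_000, contig="c"):
    return CoverageTrack({contig: (np.array([0, length]), np.array([float(value)]))},
                         scale="per_million")


def site_frame(positions, contig="c"):
    return pd.DataFrame({
        "contig": [contig] * len(positions),
        "cut_pos": positions,
        "site_id": [f"S{i}" for i in range(len(positions))],
    })


def quants_frame(**columns):
    n = len(next(iter(columns.values())))
    base = {"site_id": [f"S{i}" for i in range(n)]}
    base.update(columns)
    return pd.DataFrame(base)


class TestWindowSignal:
    def test_constant_track_returns_value(self):
        sites = site_frame([3_000, 7_000])
        out = window_signal(constant_track(2.5), sites, 1_000)
        assert np.allclose(out, 2.5)

    def test_clipped_at_contig_start(self):
        track = constant_track(4.0, length=10_000)
        sites = site_frame([200])
        # window [-800, 1200) clips to [0, 1200): mean over the in-bounds range
        out = window_signal(track, sites, 1_000, contig_lengths={"c": 10_000})
        assert out[0] == pytest.approx(4.0)

    def test_matches_slice_average_oracle(self, rng):
        rows = random_fragments(rng, 200)
        track = normalize(depth(make_library(rows)), 55_555)
        dense = np.pad(track.to_dense("chr1"), (0, 12_000))
        sites = site_frame(list(rng.integers(500, 9_500, size=12)), contig="chr1")
        w = 400
        out = window_signal(track, sites, w, contig_lengths={"chr1": 10_000})
        for val, pos in zip(out, sites["cut_pos"]):
            assert val == pytest.approx(dense[pos - w: pos + w].mean())

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            window_signal(constant_track(1.0), site_frame([100]), 0)


def grid_signals(n, values):
    """signals dict for the 2x2 grid x 1 replicate from per-condition arrays."""
    return {
        ("ctrl", "on", 0): np.asarray(values["ctrl_on"], float),
        ("ctrl", "off", 0): np.asarray(values["ctrl_off"], float),
        ("kd", "on", 0): np.asarray(values["kd_on"], float),
        ("kd", "off", 0): np.asarray(values["kd_off"], float),
    }


class TestSiteFoldChanges:
    def test_closed_form_log2(self):
        sites = site_frame([1_000])
        sig = grid_signals(1, dict(ctrl_on=[8.0], ctrl_off=[2.0],
                                   kd_on=[4.0], kd_off=[2.0]))
        q = site_fold_changes(sites, sig, eps=0.0)
        assert q["log2fc_ctrl"].iloc[0] == pytest.approx(2.0)
        assert q["log2fc_kd"].iloc[0] == pytest.approx(1.0)
        assert q["delta"].iloc[0] == pytest.approx(-1.0)
        assert q["preexisting"].iloc[0] == pytest.approx(2.0)

    def test_all_equal_signals_zero_fc(self):
        sites = site_frame([1_000, 2_000])
        sig = grid_signals(2, dict(ctrl_on=[5, 5], ctrl_off=[5, 5],
                                   kd_on=[5, 5], kd_off=[5, 5]))
        q = site_fold_changes(sites, sig, eps=0.1)
        assert np.allclose(q[["log2fc_ctrl", "log2fc_kd", "delta"]], 0.0)

    def test_zero_denominator_without_eps_names_site(self):
        sites = site_frame([1_000])
        sig = grid_signals(1, dict(ctrl_on=[4.0], ctrl_off=[0.0],
                                   kd_on=[4.0], kd_off=[1.0]))
        with pytest.raises(ZeroDivisionError, match="S0"):
            site_fold_changes(sites, sig, eps=0.0)

    def test_replicates_averaged_as_mean_of_log2(self):
        sites = site_frame([1_000])
        sig = {
            ("ctrl", "on", 0): np.array([8.0]), ("ctrl", "off", 0): np.array([2.0]),
            ("ctrl", "on", 1): np.array([2.0]), ("ctrl", "off", 1): np.array([2.0]),
            ("kd", "on", 0): np.array([2.0]), ("kd", "off", 0): np.array([2.0]),
            ("kd", "on", 1): np.array([2.0]), ("kd", "off", 1): np.array([2.0]),
        }
        q = site_fold_changes(sites, sig, eps=0.0)
        # mean of per-replicate log2 FCs: (2 + 0) / 2
        assert q["log2fc_ctrl"].iloc[0] == pytest.approx(1.0)

    def test_missing_condition_rejected(self):
        sites = site_frame([1_000])
        sig = grid_signals(1, dict(ctrl_on=[1], ctrl_off=[1], kd_on=[1], kd_off=[1]))
        del sig[("kd", "off", 0)]
        with pytest.raises(KeyError):
            site_fold_changes(sites, sig, eps=0.1)


class TestClassify:
    @pytest.mark.parametrize("delta,expected", [
        (-1.2, "dependent"),
        (0.0, "independent"),
        (0.7, "increased"),
        (-0.5, "independent"),   # tie at -tau stays independent
        (0.5, "independent"),
        (-0.501, "dependent"),
        (0.501, "increased"),
    ])
    def test_threshold_rule(self, delta, expected):
        q = quants_frame(delta=[delta])
        out, counts = classify_sites(q, tau=0.5)
        assert out["class"].iloc[0] == expected
        assert counts[expected] == 1

    def test_partition_property(self, rng):
        q = quants_frame(delta=rng.normal(0, 1, size=200))
        out, counts = classify_sites(q)
        assert sum(counts.values()) == 200
        assert set(out["class"]) <= {"dependent", "independent", "increased"}

    def test_scale_invariance_of_classification(self, rng):
        """Multiplying all four condition signals (and eps) by k>0 leaves
        delta and the class unchanged."""
        sites = site_frame(list(rng.integers(0, 10_000, size=30)))
        vals = {k: rng.gamma(5, 2, size=30) for k in
                ("ctrl_on", "ctrl_off", "kd_on", "kd_off")}
        eps = 0.1
        q1, _ = classify_sites(site_fold_changes(sites, grid_signals(30, vals), eps))
        k = 37.5
        scaled = {key: v * k for key, v in vals.items()}
        q2, _ = classify_sites(site_fold_changes(sites, grid_signals(30, scaled), eps * k))
        assert np.allclose(q1["delta"], q2["delta"])
        assert (q1["class"] == q2["class"]).all()

    def test_nonfinite_delta_rejected(self):
        with pytest.raises(ValueError):
            classify_sites(quants_frame(delta=[np.nan]))


class TestMetagene:
    def tracks_for(self, on_track, off_track):
        return {
            ("ctrl", "on", 0): on_track, ("ctrl", "off", 0): off_track,
            ("kd", "on", 0): on_track, ("kd", "off", 0): off_track,
        }

    def test_identical_tracks_flat_zero(self):
        t = constant_track(3.0, length=40_000)
        profiles = metagene(self.tracks_for(t, t), site_frame([20_000]),
                            span=5_000, bin_width=100)
        for prof in profiles:
            assert np.allclose(prof.mean_log2fc, 0.0)

    def test_signal_in_single_bin(self):
        off = constant_track(1.0, length=40_000)
        bounds = np.array([0, 20_000, 20_100, 40_000])
        on = CoverageTrack({"c": (bounds, np.array([1.0, 9.0, 1.0]))},
                           scale="per_million")
        profiles = metagene(self.tracks_for(on, off), site_frame([20_000]),
                            span=1_000, bin_width=100, eps=1.0)
        ctrl = next(p for p in profiles if p.arm == "ctrl")
        nonzero = np.flatnonzero(np.abs(ctrl.mean_log2fc) > 1e-12)
        assert list(nonzero) == [10]  # only the bin [cut, cut+100)
        assert ctrl.mean_log2fc[10] == pytest.approx(np.log2(10.0 / 2.0))

    def test_off_contig_sites_excluded_from_bins(self):
        t = constant_track(1.0, length=40_000)
        profiles = metagene(self.tracks_for(t, t), site_frame([3_000]),
                            span=5_000, bin_width=1_000,
                            contig_lengths={"c": 40_000})
        prof = profiles[0]
        assert prof.n_sites[0] == 0   # bin [-5000,-4000) is off-contig
        assert prof.n_sites[-1] == 1

    def test_span_must_tile(self):
        t = constant_track(1.0)
        with pytest.raises(ValueError):
            metagene(self.tracks_for(t, t), site_frame([5_000]),
                     span=1_050, bin_width=100)


class TestGroupCompare:
    def test_identical_groups_no_shift(self, rng):
        vals = rng.normal(size=10)
        q = quants_frame(
            preexisting=np.concatenate([vals, vals]),
            **{"class": ["dependent"] * 10 + ["independent"] * 10},
        )
        res = group_compare(q, "class", "preexisting", "less")
        assert res.test.p >= 0.5

    def test_exact_enumeration_small_groups(self):
        q = quants_frame(
            preexisting=[1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            **{"class": ["dependent"] * 3 + ["independent"] * 3},
        )
        res = group_compare(q, "class", "preexisting", "less")
        assert res.test.p == pytest.approx(0.05)
        assert res.test.method == "exact"

    def test_transcription_split_at_median(self, rng):
        q = quants_frame(
            transcription_level=np.arange(10.0),
            delta=rng.normal(size=10),
        )
        res = group_compare(q, "transcription", "delta", "less")
        assert res.n_a == 5 and res.n_b == 5

    def test_repair_grouping(self, rng):
        q = quants_frame(
            repair_class=["HR"] * 5 + ["NHEJ"] * 5 + ["unassigned"] * 2,
            delta=rng.normal(size=12),
        )
        res = group_compare(q, "repair", "delta", "less")
        assert res.n_a == 5 and res.n_b == 5  # unassigned excluded

    def test_empty_group_rejected(self):
        q = quants_frame(preexisting=[1.0, 2.0], **{"class": ["dependent"] * 2})
        with pytest.raises(ValueError, match="empty group"):
            group_compare(q, "class", "preexisting", "less")


class TestHybridCorrelation:
    def test_perfect_linear_relation(self):
        pre = np.linspace(1, 10, 20)
        q = quants_frame(preexisting=pre, log2fc_kd=0.3 * pre + 1)
        res = hybrid_correlation(q, "kd")
        assert res.statistic == pytest.approx(1.0)

    def test_constant_fold_change_degenerate(self):
        q = quants_frame(preexisting=[1.0, 2.0, 3.0], log2fc_ctrl=[2.0, 2.0, 2.0])
        with pytest.raises(ValueError, match="zero variance"):
            hybrid_correlation(q, "ctrl")

    def test_unknown_arm_rejected(self):
        q = quants_frame(preexisting=[1.0, 2.0, 3.0], log2fc_ctrl=[1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            hybrid_correlation(q, "rnf168")
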