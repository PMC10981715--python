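"""Track aggregation, window summaries, evaluation and rank-sum DMRs."""

import numpy as np
import pandas as pd
import pytest

from fragmeth.errors import UsageError
from fragmeth.features import CpGObservation, Fragment
from fragmeth.hmm import DecodedFragment
from fragmeth.methylome import (
    CpGTrack, WindowSet, aggregate_track, anchor_profile, correlate_tracks,
    evaluate_binary, wilcoxon_dmr, window_summarize,
)

from .oracles import exact_ranksum_p


def decoded(chrom, positions, path, posterior=None, truth=None, start=None, end=None):
    start = positions[0] - 10 if start is None else start
    end = positions[-1] + 10 if end is None else end
    frag = Fragment(chrom, start, end)
    prev = None
    for p in positions:
        frag.observations.append(
            CpGObservation(p, p - start, None if prev is None else p - prev,
                           float(end - start), 0.0, 0.0, z=np.zeros(3))
        )
        prev = p
    frag.truth_states = list(truth) if truth else None
    path_arr = np.array([1 if c == "M" else 0 for c in path])
    post = np.asarray(posterior) if posterior is not None else path_arr.astype(float)
    return DecodedFragment(frag, path_arr, post, 0.0)


class TestAggregate:
    def test_counts_by_example(self):
        track = aggregate_track([
            decoded("chr1", [100], "M"),
            decoded("chr1", [100], "M"),
            decoded("chr1", [100], "U"),
        ])
        assert track.counts[("chr1", 100)] == [2, 3]
        assert track.level("chr1", 100) == pytest.approx(2 / 3)
        assert track.level("chr1", 999) is None

    def test_empty_input_empty_track(self):
        assert len(aggregate_track([])) == 0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        sites = [100 + 20 * i for i in range(10)]
        expect = {}
        decs = []
        for _ in range(100):
            chosen = sorted(rng.choice(10, size=3, replace=False))
            pos = [sites[i] for i in chosen]
            calls = rng.random(3) < 0.5
            for p, c in zip(pos, calls):
                m, t = expect.get(p, (0, 0))
                expect[p] = (m + int(c), t + 1)
            decs.append(decoded("chr1", pos, "".join("M" if c else "U" for c in calls)))
        track = aggregate_track(decs)
        assert {p: tuple(v) for (_, p), v in track.counts.items()} == expect

    def test_tsv_round_trip(self, tmp_path):
        track = aggregate_track([decoded("chr1", [10, 30], "MU")])
        track.to_tsv(str(tmp_path / "t.tsv"))
        back = CpGTrack.from_tsv(str(tmp_path / "t.tsv"))
        assert back.counts == track.counts


class TestWindows:
    def test_density_pools_counts(self):
        track = CpGTrack({("chr1", 10): [2, 3], ("chr1", 20): [1, 1]})
        windows = WindowSet(pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 100}]))
        out = window_summarize(track, windows)
        assert out.loc[0, "density"] == pytest.approx(3 / 4)
        assert out.loc[0, "n_total"] == 4

    def test_empty_window_is_missing(self):
        track = CpGTrack({("chr1", 10): [1, 2]})
        windows = WindowSet(pd.DataFrame([{"chrom": "chr1", "start": 500, "end": 600}]))
        assert np.isnan(window_summarize(track, windows).loc[0, "density"])

    def test_tiling_conserves_counts(self):
        rng = np.random.default_rng(1)
        track = CpGTrack(
            {("chr1", int(p)): [int(rng.integers(0, 3)), 3]
             for p in rng.choice(5000, 200, replace=False)}
        )
        tiles = WindowSet.tiling({"chr1": 5000}, 1000)
        out = window_summarize(track, tiles)
        assert out["n_total"].sum() == sum(v[1] for v in track.counts.values())
        assert out["n_methylated"].sum() == sum(v[0] for v in track.counts.values())

    def test_shores_flank_minus_island(self):
        cgi = WindowSet(pd.DataFrame([{"chrom": "chr1", "start": 5000, "end": 6000,
                                       "name": "i0"}]))
        shores = cgi.shores(2000, {"chr1": 7000})
        rows = shores.df.to_dict("records")
        assert (rows[0]["start"], rows[0]["end"]) == (3000, 5000)
        assert (rows[1]["start"], rows[1]["end"]) == (6000, 7000)  # clipped

    def test_restrict_to_keeps_overlapping(self):
        tiles = WindowSet.tiling({"chr1": 4000}, 1000)
        cgi = WindowSet(pd.DataFrame([{"chrom": "chr1", "start": 1500, "end": 1600}]))
        kept = tiles.restrict_to(cgi)
        assert kept.df["start"].tolist() == [1000]


class TestEvaluateBinary:
    def test_perfect_posteriors_score_one(self):
        decs = [decoded("chr1", [10, 30, 50, 70, 90], "MMMUU", [1, 1, 1, 0, 0], "MMMUU")
                for _ in range(10)]
        rep = evaluate_binary(decs, min_cpgs_per_fragment=5, seed=0)
        assert rep.auroc == 1.0

    def test_uninformative_posteriors_score_half(self):
        rng = np.random.default_rng(2)
        decs = []
        for _ in range(400):
            truth = "".join(rng.choice(["U", "M"], size=5))
            decs.append(decoded("chr1", [10, 30, 50, 70, 90], "UUUUU",
                                rng.random(5), truth))
        rep = evaluate_binary(decs, min_cpgs_per_fragment=5, seed=0)
        assert rep.auroc == pytest.approx(0.5, abs=0.03)

    def test_min_cpg_restriction_and_class_requirement(self):
        short = decoded("chr1", [10], "M", [1.0], "M")
        with pytest.raises(UsageError):
            evaluate_binary([short], min_cpgs_per_fragment=1, seed=0)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        decs, decs_t = [], []
        for _ in range(100):
            truth = "".join(rng.choice(["U", "M"], size=5))
            p = rng.random(5)
            signal = np.clip(p + 0.4 * (np.array(list(truth)) == "M"), 0, 1)
            decs.append(decoded("chr1", [10, 30, 50, 70, 90], "UUUUU", signal, truth))
            decs_t.append(decoded("chr1", [10, 30, 50, 70, 90], "UUUUU",
                                  signal**3, truth))
        r1 = evaluate_binary(decs, 5, seed=1)
        r2 = evaluate_binary(decs_t, 5, seed=1)
        assert r1.auroc == pytest.approx(r2.auroc, abs=1e-12)


class TestCorrelateTracks:
    def test_identical_tracks_correlate_perfectly(self):
        rng = np.random.default_rng(4)
        levels = {("chr1", int(p)): [int(k), 10]
                  for p, k in zip(rng.choice(9999, 50, replace=False),
                                  rng.integers(0, 11, 50))}
        t = CpGTrack({k: list(v) for k, v in levels.items()})
        rep = correlate_tracks(t, t, min_coverage=(1,))
        assert rep.pearson["cpg_cov>=1"] == pytest.approx(1.0)
        assert rep.spearman["cpg_cov>=1"] == pytest.approx(1.0)

    def test_inverted_track_anticorrelates(self):
        t1 = CpGTrack({("chr1", p): [p % 11, 10] for p in range(0, 500, 10)})
        t2 = CpGTrack({("chr1", p): [10 - p % 11, 10] for p in range(0, 500, 10)})
        rep = correlate_tracks(t1, t2, min_coverage=(1,))
        assert rep.pearson["cpg_cov>=1"] == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        a = {("chr1", int(p)): [int(m), 20] for p, m in
             zip(range(0, 1000, 20), rng.integers(0, 21, 50))}
        b = {k: [int(rng.integers(0, 21)), 20] for k in a}
        rep = correlate_tracks(CpGTrack(a), CpGTrack(b), min_coverage=(1,))
        x = np.array([v[0] / v[1] for v in a.values()])
        y = np.array([b[k][0] / b[k][1] for k in a])
        direct = ((x - x.mean()) * (y - y.mean())).sum() / (
            np.sqrt(((x - x.mean()) ** 2).sum()) * np.sqrt(((y - y.mean()) ** 2).sum())
        )
        assert rep.pearson["cpg_cov>=1"] == pytest.approx(direct, abs=1e-12)

    def test_too_few_sites_reported_missing(self):
        t1 = CpGTrack({("chr1", 10): [1, 2], ("chr1", 20): [1, 2]})
        rep = correlate_tracks(t1, t1, min_coverage=(1,))
        assert rep.pearson["cpg_cov>=1"] is None

    def test_coverage_strata_filter_both_tracks(self):
        pred = CpGTrack({("chr1", p): [1, 2] for p in range(0, 100, 10)})
        truth = CpGTrack({("chr1", p): [5, 20] for p in range(0, 100, 10)})
        rep = correlate_tracks(pred, truth, min_coverage=(5,))
        # predicted coverage (2) is below the stratum everywhere
        assert rep.pearson["cpg_cov>=5"] is None


class TestWilcoxonDMR:
    def test_identical_groups_flag_nothing(self):
        df = pd.DataFrame(np.tile(np.arange(6.0), (20, 1)),
                          index=[f"w{i}" for i in range(20)])
        out = wilcoxon_dmr(df, df.copy())
        assert not out["flagged"].any()

    def test_worked_example_matches_exact_enumeration(self):
        case = np.array([0.9, 0.95, 0.92, 0.88])
        control = np.array([0.1, 0.12, 0.08, 0.15])
        expected = exact_ranksum_p(case, control)
        assert expected == pytest.approx(2 / 70, rel=1e-12)  # 0.0286
        out = wilcoxon_dmr(
            pd.DataFrame([case], index=["w0"]),
            pd.DataFrame([control], index=["w0"]),
            p_cutoff=0.05,
        )
        assert out.loc[0, "p"] == pytest.approx(expected, rel=1e-9)
        assert bool(out.loc[0, "flagged"])
        assert out.loc[0, "direction"] == 1

    def test_all_tied_values_give_p_one(self):
        case = pd.DataFrame([[0.5, 0.5, 0.5]], index=["w0"])
        out = wilcoxon_dmr(case, case.copy())
        assert out.loc[0, "p"] == 1.0

    def test_underpowered_windows_skipped(self):
        case = pd.DataFrame([[0.5, np.nan, np.nan]], index=["w0"])
        ctrl = pd.DataFrame([[0.1, 0.2, 0.3]], index=["w0"])
        assert wilcoxon_dmr(case, ctrl).empty

    def test_null_calibration_quick(self):
        rng = np.random.default_rng(6)
        n_windows = 800
        case = pd.DataFrame(rng.normal(size=(n_windows, 8)))
        ctrl = pd.DataFrame(rng.normal(size=(n_windows, 8)))
        out = wilcoxon_dmr(case, ctrl, p_cutoff=0.05)
        rate = out["flagged"].mean()
        # binomial 99% band around the nominal level
        assert abs(rate - 0.05) < 2.6 * np.sqrt(0.05 * 0.95 / n_windows)

    def test_q_values_present_and_bh_ordered(self):
        rng = np.random.default_rng(7)
        case = pd.DataFrame(rng.normal(2, 1, size=(30, 6)))
        ctrl = pd.DataFrame(rng.normal(0, 1, size=(30, 6)))
        out = wilcoxon_dmr(case, ctrl)
        assert (out["q"] >= out["p"] - 1e-12).all()


class TestAnchorProfile:
    def test_constant_track_gives_flat_profile(self):
        track = CpGTrack({("chr1", p): [3, 4] for p in range(0, 4000, 25)})
        anchors = pd.DataFrame([{"chrom": "chr1", "position": 2000, "strand": "+"}])
        prof = anchor_profile(track, anchors, flank=1000, bin_size=100)
        filled = prof["mean_level"].dropna()
        assert np.allclose(filled, 0.75)

    def test_hand_built_profile(self):
        track = CpGTrack({("chr1", 990): [1, 1], ("chr1", 1010): [0, 1],
                          ("chr1", 1110): [1, 2]})
        anchors = pd.DataFrame([{"chrom": "chr1", "position": 1000, "strand": "+"}])
        prof = anchor_profile(track, anchors, flank=200, bin_size=100)
        by_off = dict(zip(prof["offset_start"], prof["mean_level"]))
        assert by_off[-100] == pytest.approx(1.0)
        assert by_off[0] == pytest.approx(0.0)
        assert by_off[100] == pytest.approx(0.5)

    def test_minus_strand_mirrors_plus(self):
        track = CpGTrack({("chr1", 905): [1, 1], ("chr1", 1095): [0, 2]})
        plus = pd.DataFrame([{"chrom": "chr1", "position": 1000, "strand": "+"}])
        minus = pd.DataFrame([{"chrom": "chr1", "position": 1000, "strand": "-"}])
        p1 = anchor_profile(track, plus, flank=200, bin_size=100)["mean_level"]
        p2 = anchor_profile(track, minus, flank=200, bin_size=100)["mean_level"]
        assert np.allclose(p1.to_numpy(), p2.to_numpy()[::-1], equal_nan=True)

    def test_invalid_parameters(self):
        with pytest.raises(UsageError):
            anchor_profile(CpGTrack(), pd.DataFrame(), flank=0, bin_size=10)
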