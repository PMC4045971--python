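"""Read filtering, ratio profiles, pileups, efficiency, bias and duplication."""

import warnings

import numpy as np
import pandas as pd
import pytest

from pddkit.depletion_analysis import (
    AlignedRead,
    AnalysisConfig,
    clip_and_filter,
    depletion_efficiency,
    duplication_analysis,
    expected_duplicates,
    gc_content,
    interprobe_ratio,
    moving_average,
    orf_counts_with_offtarget_tm,
    probe_pileup,
    ratio_profile,
    reads_from_inserts,
)
from pddkit.depletion_model import (
    InsertSizeRange,
    ProbeFootprint,
    footprints_from_hits,
)
from pddkit.libsim import LibraryConfig, simulate_paired_libraries, synthetic_pool
from pddkit.probescan import MatchHit, TranscriptCategory, TranscriptRecord, scan

from conftest import make_probe
from oracles import birthday_expected_duplicates


class TestClipAndFilter:
    ADAPTER = "AGATCGGAAGAGC"

    def test_eleven_nt_is_the_retention_boundary(self):
        reads = ["C" * 10 + self.ADAPTER, "C" * 11 + self.ADAPTER]
        kept = clip_and_filter(reads, self.ADAPTER)
        assert kept == ["C" * 11]

    def test_empty_input_empty_output(self):
        assert clip_and_filter([], self.ADAPTER) == []

    def test_pure_polya_read_is_discarded(self):
        assert clip_and_filter(["A" * 40], self.ADAPTER) == []

    def test_polya_then_adapter_trimming(self):
        read = "CGCGCGCGCGCG" + "A" * 8 + self.ADAPTER + "TTTT"
        assert clip_and_filter([read], self.ADAPTER) == ["CGCGCGCGCGCG"]

    def test_short_polya_run_is_kept(self):
        read = "CGCGCGCGCGCG" + "AAAA"  # run of 4 < 5: not a tail
        assert clip_and_filter([read], self.ADAPTER) == [read]


class TestMovingAverage:
    @pytest.mark.parametrize("window", [7, 9])
    def test_impulse_response_has_window_nonzero_positions(self, window):
        x = np.zeros(101)
        x[50] = 1.0
        sm = moving_average(x, window)
        assert int(np.sum(sm > 0)) == window

    def test_mass_conserved_away_from_edges(self):
        rng = np.random.default_rng(1)
        x = rng.poisson(5, size=200).astype(float)
        sm = moving_average(x, 9)
        # Interior mass is conserved; edge windows are truncated means.
        assert np.sum(sm[4:-4]) == pytest.approx(np.sum(x[4:-4]), rel=0.05)
        assert np.isfinite(sm).all()


def _identical_libraries(transcript_len=300, n=2000, seed=8):
    rng = np.random.default_rng(seed)
    reads = [
        AlignedRead("L", "t", int(s), int(l))
        for s, l in zip(
            rng.integers(0, transcript_len - 100, n), rng.integers(25, 101, n)
        )
    ] + [
        AlignedRead("L", "m", int(s), int(l))
        for s, l in zip(rng.integers(0, 200, n // 4), rng.integers(25, 101, n // 4))
    ]
    return reads


CATS = {"t": TranscriptCategory.rRNA_target, "m": TranscriptCategory.mRNA}
T = TranscriptRecord(id="t", sequence="ACGT" * 75, category="rRNA_target")
GROUP = InsertSizeRange(25, 100)


class TestRatioProfile:
    def test_identical_libraries_give_100_percent_everywhere_unmasked(self):
        reads = _identical_libraries()
        prof = ratio_profile(reads, reads, T, GROUP, CATS)
        vals = prof.values[np.isfinite(prof.values)]
        assert len(vals) > 150
        assert vals == pytest.approx(np.full(len(vals), 100.0))

    def test_zone_without_treated_reads_reports_zero(self):
        un = _identical_libraries()
        tr = [r for r in un if not (100 <= r.five_prime < 140 and r.transcript_id == "t")]
        prof = ratio_profile(tr, un, T, GROUP, CATS)
        # deep inside the emptied zone the smoothing window is fully empty
        core = prof.values[110:130]
        assert np.nanmin(core) == pytest.approx(0.0)

    def test_zero_mrna_reads_in_group_is_an_error_naming_the_group(self):
        reads = [AlignedRead("L", "t", 0, 30)]
        with pytest.raises(ValueError, match=r"\[25, 100\]"):
            ratio_profile(reads, reads, T, GROUP, CATS)


def _simulated_pair(p_cut, seed=42, n=200_000, gap=5, probe_len=25):
    pool = synthetic_pool(seed=seed)
    target = pool[0]
    starts = list(range(gap, len(target) - probe_len - gap, probe_len + gap))
    probes = [
        make_probe(f"p{i:02d}", target.sequence[s : s + probe_len], {target.id})
        for i, s in enumerate(starts)
    ]
    hits = scan(probes, pool)
    fps = footprints_from_hits(hits, probes)
    config = LibraryConfig(n_inserts=n, seed=seed, p_cut=p_cut)
    treated, untreated = simulate_paired_libraries(pool, fps, config)
    return (
        pool,
        fps,
        hits,
        reads_from_inserts(treated, "treated"),
        reads_from_inserts(untreated, "untreated"),
    )


class TestSimulatedDepletion:
    def test_complete_cutting_empties_predicted_zones_only(self):
        pool, fps, _, tr, un = _simulated_pair(p_cut=1.0, gap=80, n=100_000)
        target = pool[0]
        cats = {t.id: t.category for t in pool}
        group = InsertSizeRange(50, 200)
        prof = ratio_profile(tr, un, target, group, cats)
        # Fully-depleted 5' positions for the minimum insert length:
        # start - min_insert + min_duplex .. end - min_duplex.
        zone = np.zeros(len(target), dtype=bool)
        near = np.zeros(len(target), dtype=bool)
        for f in fps:
            zone[max(0, f.start - 50 + 10) : f.end - 10 + 1] = True
            near[max(0, f.start - 200 - 9) : min(len(target), f.end + 9)] = True
        # smoothing bleeds 4 nt, so judge the zone core only
        core = np.flatnonzero(zone).copy()
        core = core[(core - 4 >= 0)]
        core_mask = np.zeros(len(target), dtype=bool)
        for i in np.flatnonzero(zone):
            if zone[max(0, i - 4) : i + 5].all():
                core_mask[i] = True
        vals = prof.values
        assert np.nanmax(vals[core_mask]) <= 5.0
        outside = np.isfinite(vals) & ~near
        assert np.nanmean(vals[outside]) == pytest.approx(100.0, abs=10.0)

    @pytest.mark.parametrize("p_cut,expected", [(0.9, 90.0), (1.0, 100.0)])
    def test_efficiency_recovers_cut_probability(self, p_cut, expected):
        pool, fps, _, tr, un = _simulated_pair(p_cut=p_cut)
        cats = {t.id: t.category for t in pool}
        group = InsertSizeRange(25, 200)
        prof = ratio_profile(tr, un, pool[0], group, cats)
        eff = depletion_efficiency([prof], fps, min_insert=25)
        assert eff == pytest.approx(expected, abs=2.0)
        if p_cut == 1.0:
            assert eff >= 98.0


class TestProbePileup:
    def test_single_probe_mean_equals_its_own_curve(self):
        reads = _identical_libraries()
        prof = ratio_profile(reads, reads, T, GROUP, CATS)
        fp = ProbeFootprint("p1", "t", 100, 125)
        x, mat, mean = probe_pileup([prof], [fp], x_range=(-60, 20))
        np.testing.assert_array_equal(mat["p1"].to_numpy(), mean)

    def test_pileup_smoother_impulse_has_seven_nonzero_positions(self):
        # Push a unit impulse through the pileup smoothing path.
        from pddkit.depletion_analysis import RatioProfile

        values = np.zeros(300)
        values[150] = 1.0
        impulse = RatioProfile("t", GROUP, values, values, values)
        fp = ProbeFootprint("p1", "t", 125, 150)
        config = AnalysisConfig()
        x, mat, mean = probe_pileup([impulse], [fp], config, x_range=(-50, 50))
        assert int(np.sum(mean > 0)) == 7

    def test_recovery_point_on_right_flank(self):
        # Unsmoothed profiles of a single isolated probe expose the model
        # edge: the last depleted 5' position sits min_duplex nt upstream
        # of the probe 3' end; the next position recovers fully.
        pool = synthetic_pool(seed=23)
        target = pool[0]
        probes = [make_probe("p0", target.sequence[400:425], {target.id})]
        fps = footprints_from_hits(scan(probes, pool), probes)
        config = LibraryConfig(n_inserts=150_000, seed=23, p_cut=1.0,
                               size_selection=InsertSizeRange(50, 200))
        treated, untreated = simulate_paired_libraries(pool, fps, config)
        tr = reads_from_inserts(treated, "T")
        un = reads_from_inserts(untreated, "U")
        cats = {t.id: t.category for t in pool}
        group = InsertSizeRange(50, 200)
        cfg = AnalysisConfig(density_window=1, pileup_window=1)
        prof = ratio_profile(tr, un, pool[0], group, cats, cfg)
        x, mat, mean = probe_pileup([prof], fps, cfg, x_range=(-30, 5))
        assert mean[x == -10][0] == pytest.approx(0.0, abs=1e-9)
        assert mean[x == -9][0] > 50.0


class TestInterprobeRatio:
    def test_identical_libraries_give_100_for_every_gap(self):
        reads = _identical_libraries()
        fps = [ProbeFootprint("a", "t", 40, 65), ProbeFootprint("b", "t", 100, 125),
               ProbeFootprint("c", "t", 180, 205)]
        gaps = interprobe_ratio(reads, reads, fps, CATS, GROUP)
        assert [g.distance for g in gaps] == [35, 55]
        for g in gaps:
            assert g.percentage == pytest.approx(100.0)

    def test_counts_match_brute_force_interval_membership(self):
        reads = _identical_libraries()
        fps = [ProbeFootprint("a", "t", 40, 65), ProbeFootprint("b", "t", 100, 125)]
        [gap] = interprobe_ratio(reads, reads, fps, CATS, GROUP)
        lo, hi = 65 - 10, 100 + 10
        manual = sum(
            1 for r in reads
            if r.transcript_id == "t" and lo <= r.five_prime < hi
            and 25 <= r.insert_len <= 100
        )
        assert gap.treated_count == gap.untreated_count == manual

    def test_close_gaps_deplete_fully_wide_gaps_leak(self):
        # One spacing-valid gap (5 nt) and one far beyond the rule (150 nt),
        # complete cutting: the tight gap goes to ~0, the wide one leaks.
        pool = synthetic_pool(seed=19)
        target = pool[0]
        coords = [(100, 125), (130, 155), (305, 330)]
        probes = [make_probe(f"p{i}", target.sequence[b:e], {target.id})
                  for i, (b, e) in enumerate(coords)]
        fps = footprints_from_hits(scan(probes, pool), probes)
        config = LibraryConfig(n_inserts=150_000, seed=19, p_cut=1.0,
                               size_selection=InsertSizeRange(50, 200))
        treated, untreated = simulate_paired_libraries(pool, fps, config)
        tr = reads_from_inserts(treated, "T")
        un = reads_from_inserts(untreated, "U")
        cats = {t.id: t.category for t in pool}
        gaps = interprobe_ratio(tr, un, fps, cats, InsertSizeRange(50, 200))
        tight, wide = gaps
        assert tight.distance == 5 and wide.distance == 150
        assert tight.percentage < 5.0
        assert wide.percentage > tight.percentage + 10

    def test_swapping_libraries_inverts_the_ratio(self):
        pool, fps, _, tr, un = _simulated_pair(p_cut=0.5, n=100_000, gap=40)
        cats = {t.id: t.category for t in pool}
        fwd = interprobe_ratio(tr, un, fps, cats, GROUP)
        rev = interprobe_ratio(un, tr, fps, cats, GROUP)
        for f, r in zip(fwd, rev):
            if f.percentage and r.percentage:
                assert f.percentage * r.percentage == pytest.approx(100.0**2, rel=1e-9)


class TestOrfCounts:
    def test_counts_conserve_totals_and_none_sentinel(self):
        tr = [AlignedRead("T", "m1", 5, 30), AlignedRead("T", "m2", 9, 30)]
        un = [AlignedRead("U", "m1", 5, 30)] * 3
        hits = [MatchHit("p1", "m1", 0, 12, 13, 38.5, False)]
        df = orf_counts_with_offtarget_tm(tr, un, ["m1", "m2"], hits)
        assert df["count_treated"].sum() == len(tr)
        assert df["count_untreated"].sum() == len(un)
        row_m2 = df.set_index("orf_id").loc["m2"]
        assert row_m2["best_offtarget_tm"] is None
        assert df.set_index("orf_id").loc["m1", "best_offtarget_tm"] == pytest.approx(38.5)


class TestGcContent:
    def test_pure_gc_and_pure_at(self):
        assert gc_content(["GGCC", "GCGC"]) == 100.0
        assert gc_content(["AATT"]) == 0.0

    def test_matches_direct_recount(self):
        rng = np.random.default_rng(3)
        reads = ["".join(rng.choice(list("ACGT"), 50)) for _ in range(200)]
        manual = sum(r.count("G") + r.count("C") for r in reads)
        total = sum(len(r) for r in reads)
        assert gc_content(reads) == pytest.approx(100 * manual / total)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            gc_content([])


class TestDuplication:
    def test_single_read_orf_skipped_and_coverage_arithmetic(self):
        df = duplication_analysis(
            {"solo": [5], "ten": list(range(10))},
            {"solo": 500, "ten": 160},
            median_read_len=60,
            seed=1,
        )
        assert list(df["orf_id"]) == ["ten"]
        row = df.iloc[0]
        assert row["available_positions"] == 100
        assert row["coverage"] == pytest.approx(0.1)
        assert row["n_sims"] == 500

    def test_orf_shorter_than_median_read_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="available positions"):
            df = duplication_analysis({"short": [1, 2, 3]}, {"short": 50},
                                      median_read_len=60, seed=1)
        assert df.empty

    @pytest.mark.parametrize("n,P", [(5, 40), (20, 100), (50, 90)])
    def test_reshuffled_mean_matches_birthday_expectation(self, n, P):
        df = duplication_analysis(
            {"orf": list(range(n))}, {"orf": P + 60}, median_read_len=60,
            seed=7, min_sims_large=10_000, min_sims_small=10_000,
        )
        sim_mean = df.iloc[0]["expected_duplicates"]
        analytic = birthday_expected_duplicates(n, P)
        assert expected_duplicates(n, P) == pytest.approx(analytic)
        # 3-sigma band from an independent reshuffle simulation
        rng = np.random.default_rng(123)
        draws = rng.integers(0, P, size=(10_000, n))
        dups = n - np.array([len(np.unique(d)) for d in draws])
        sigma_mean = dups.std(ddof=1) / np.sqrt(len(dups))
        assert abs(sim_mean - analytic) < 3 * max(sigma_mean, 1e-3)

    def test_sim_depth_rule(self):
        df = duplication_analysis(
            {"small": [1, 2, 3], "large": list(range(40))},
            {"small": 200, "large": 400},
            median_read_len=60,
            seed=2,
        )
        depth = df.set_index("orf_id")["n_sims"]
        assert depth["small"] == 500 and depth["large"] == 100
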