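"""Window tiling, SNP counting, top-fraction selection and summaries."""

import random

import pytest

from sexscan import ChromTable, Window, count_patterned, make_windows, per_chromosome_summary, top_percent
from sexscan.poolstats import PatternCall
from sexscan.windowscan import windows_table


def _call(chrom, pos, pattern):
    return PatternCall(chrom, pos, pattern, None, 0.0, 0.5, 20, 20)


class TestMakeWindows:
    def test_tiling_with_truncated_last_window(self):
        table = ChromTable.from_pairs([("LG1", 250_000)])
        spans = [(w.start, w.end) for w in make_windows(table, 100_000)]
        assert spans == [(0, 100_000), (100_000, 200_000), (200_000, 250_000)]

    @pytest.mark.parametrize("length,expected", [(100_000, 1), (99_999, 1)])
    def test_single_window_chromosomes(self, length, expected):
        table = ChromTable.from_pairs([("LG1", length)])
        windows = make_windows(table, 100_000)
        assert len(windows) == expected
        assert windows[-1].end == length

    def test_invalid_size_rejected(self, chroms):
        with pytest.raises(ValueError):
            make_windows(chroms, 0)


class TestCountPatterned:
    def test_one_based_boundary_convention(self, chroms):
        windows = make_windows(chroms, 100_000)
        counted, skipped = count_patterned(
            windows, [_call("LG1", 100_000, "XY"), _call("LG1", 100_001, "XY")]
        )
        assert skipped == 0
        assert counted[0].xy_count == 1  # pos 100000 → 0-based 99999 → [0, 100000)
        assert counted[1].xy_count == 1  # pos 100001 → [100000, 200000)

    def test_patterns_tallied_separately_and_none_ignored(self, chroms):
        windows = make_windows(chroms, 100_000)
        calls = [_call("LG1", 10, "ZW")] * 3 + [_call("LG1", 10, "none")]
        counted, _ = count_patterned(windows, calls)
        assert counted[0].zw_count == 3 and counted[0].xy_count == 0

    def test_unknown_chromosome_skipped_with_count(self, chroms):
        windows = make_windows(chroms, 100_000)
        counted, skipped = count_patterned(windows, [_call("LGX", 5, "XY")])
        assert skipped == 1
        assert sum(w.xy_count for w in counted) == 0

    def test_conservation_and_order_invariance(self, chroms):
        windows = make_windows(chroms, 100_000)
        rng = random.Random(11)
        calls = [
            _call(
                rng.choice(chroms.names),
                rng.randint(1, 100_000),
                rng.choice(["XY", "ZW", "none"]),
            )
            for _ in range(200)
        ]
        counted, skipped = count_patterned(windows, calls)
        n_patterned = sum(1 for c in calls if c.pattern != "none")
        assert sum(w.xy_count + w.zw_count for w in counted) + skipped == n_patterned
        shuffled = calls[:]
        rng.shuffle(shuffled)
        counted2, _ = count_patterned(windows, shuffled)
        assert counted == counted2

    def test_matches_bruteforce_scan_on_random_instances(self):
        rng = random.Random(99)
        for _ in range(100):
            n_chrom = rng.randint(1, 3)
            table = ChromTable.from_pairs(
                (f"c{i}", rng.randint(50_000, 400_000)) for i in range(n_chrom)
            )
            size = rng.choice([50_000, 100_000])
            windows = make_windows(table, size)
            calls = [
                _call(
                    rng.choice(table.names + ("off",)),
                    rng.randint(1, 500_000),
                    rng.choice(["XY", "ZW"]),
                )
                for _ in range(rng.randint(0, 60))
            ]
            counted, skipped = count_patterned(windows, calls)
            expect_xy = [0] * len(windows)
            expect_zw = [0] * len(windows)
            expect_skipped = 0
            for call in calls:  # oracle: linear scan of every window
                coord = call.pos - 1
                for i, w in enumerate(windows):
                    if w.chrom == call.chrom and w.start <= coord < w.end:
                        if call.pattern == "XY":
                            expect_xy[i] += 1
                        else:
                            expect_zw[i] += 1
                        break
                else:
                    expect_skipped += 1
            assert [w.xy_count for w in counted] == expect_xy
            assert [w.zw_count for w in counted] == expect_zw
            assert skipped == expect_skipped


class TestTopPercent:
    def _windows(self, counts):
        return [
            Window("c1", i * 100_000, (i + 1) * 100_000, zw_count=c)
            for i, c in enumerate(counts)
        ]

    def test_top_one_percent_of_300_windows_is_3(self):
        windows = self._windows([0] * 300)
        assert len(top_percent(windows, 0.01, "ZW")) == 3

    def test_top_one_percent_of_7400_windows_is_74(self):
        windows = self._windows([0] * 7400)
        assert len(top_percent(windows, 0.01, "ZW")) == 74

    def test_ties_broken_by_genome_position(self):
        windows = self._windows([2, 5, 0, 5, 1])
        top = top_percent(windows, 0.4, "ZW")
        assert [w.start for w in top] == [100_000, 300_000]

    def test_nonzero_only_restriction(self):
        windows = self._windows([0] * 99 + [3])
        assert len(top_percent(windows, 0.01, "ZW", nonzero_only=True)) == 1
        top = top_percent(windows, 0.01, "ZW", nonzero_only=True)
        assert top[0].zw_count == 3

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            top_percent([], 0.01, "ZW")
        with pytest.raises(ValueError):
            top_percent(self._windows([1]), 0.0, "ZW")
        with pytest.raises(ValueError):
            top_percent(self._windows([1]), 1.5, "ZW")


class TestPerChromosomeSummary:
    def test_fold_enrichment_arithmetic(self):
        """13 of 74 top windows on a chromosome holding 1/20.5 of all
        windows is a 3.6-fold enrichment."""
        all_windows = [
            Window("A", i * 100_000, (i + 1) * 100_000) for i in range(74)
        ] + [Window("B", i * 100_000, (i + 1) * 100_000) for i in range(1517 - 74)]
        top = [
            Window("A", i * 100_000, (i + 1) * 100_000, zw_count=33) for i in range(13)
        ] + [Window("B", i * 100_000, (i + 1) * 100_000, zw_count=90) for i in range(61)]
        summary = per_chromosome_summary(top, all_windows, "ZW").set_index("chrom")
        assert summary.loc["A", "fold_enrichment"] == pytest.approx(3.6, abs=0.05)
        assert summary.loc["A", "n_top_windows"] == 13
        assert summary.loc["A", "total_patterned_snps"] == 13 * 33
        assert summary["n_top_windows"].sum() == len(top)

    def test_single_chromosome_fold_is_one(self):
        all_windows = [Window("A", i, i + 1) for i in range(10)]
        top = all_windows[:2]
        summary = per_chromosome_summary(top, all_windows, "ZW")
        assert summary["fold_enrichment"].tolist() == [1.0]

    def test_absent_chromosome_reported_with_zeros(self):
        all_windows = [Window("A", 0, 10), Window("B", 0, 10)]
        summary = per_chromosome_summary([Window("A", 0, 10)], all_windows, "XY")
        row = summary.set_index("chrom").loc["B"]
        assert row["n_top_windows"] == 0 and row["fold_enrichment"] == 0.0

    def test_top_window_on_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError):
            per_chromosome_summary([Window("Z", 0, 10)], [Window("A", 0, 10)], "XY")


def test_windows_table_flags_top_membership(chroms):
    windows = make_windows(chroms, 100_000)
    counted, _ = count_patterned(windows, [_call("LG1", 5, "XY")])
    df = windows_table(counted, top_xy=[counted[0]], top_zw=[])
    assert df.loc[0, "in_top_xy"] and not df.loc[0, "in_top_zw"]
    assert list(df.columns) == [
        "chrom", "start", "end", "xy_count", "zw_count", "in_top_xy", "in_top_zw",
    ]
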