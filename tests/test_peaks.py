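"""Peak calling, interval algebra vs brute-force oracles, differential
regions, gene annotation."""

import numpy as np
import pandas as pd
import pytest

from chromacal import peaks, signal, simulate
from chromacal.io import GENOME_TARGET
from conftest import frag_frame, interval_frame


def random_peakset(rng, n, n_chroms=2, max_pos=50_000, score=True):
    rows = []
    for _ in range(n):
        chrom = f"c{rng.integers(1, n_chroms + 1)}"
        s = int(rng.integers(0, max_pos))
        rows.append((chrom, s, s + int(rng.integers(10, 800)))
                    + ((float(rng.random() * 100),) if score else ()))
    df = interval_frame(rows, score=score)
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_merge(df, max_gap):
    items = df.sort_values(["chrom", "start"]).to_dict("records")
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                a, b = items[i], items[j]
                if a["chrom"] != b["chrom"]:
                    continue
                gap = max(b["start"] - a["end"], a["start"] - b["end"])
                if gap < max_gap:
                    a["start"] = min(a["start"], b["start"])
                    a["end"] = max(a["end"], b["end"])
                    a["score"] = a.get("score", 0) + b.get("score", 0)
                    items.pop(j)
                    changed = True
                    break
            if changed:
                break
    return (
        pd.DataFrame(items)
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )


def brute_overlaps(a, b):
    out = []
    for r in a.itertuples(index=False):
        for s in b.itertuples(index=False):
            if r.chrom == s.chrom and r.start < s.end and s.start < r.end:
                out.append(True)
                break
        else:
            out.append(False)
    return np.array(out)


def brute_union(dfs):
    events = pd.concat(dfs, ignore_index=True)
    covered = {}
    for r in events.itertuples(index=False):
        covered.setdefault(r.chrom, set()).update(range(r.start, r.end))
    rows = []
    for chrom in sorted(covered):
        pos = sorted(covered[chrom])
        start = prev = pos[0]
        for p in pos[1:]:
            if p != prev + 1:
                rows.append((chrom, start, prev + 1))
                start = p
            prev = p
        rows.append((chrom, start, prev + 1))
    return interval_frame(rows)


# ---------------------------------------------------------------------------


class TestCallPeaksSparse:
    def test_single_block_retained(self):
        track = pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [100],
                              "value": [2.0]})
        ps = peaks.call_peaks_sparse(track)
        assert ps.values.tolist() == [["c1", 0, 100, 200.0]]

    def test_top_percent_quantile_retention(self):
        """100 separated equal-width blocks scoring 1..100: retaining the top
        1% keeps exactly the quantile-threshold survivors."""
        rows = [("c1", i * 1000, i * 1000 + 100, float(i + 1)) for i in range(100)]
        track = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
        ps = peaks.call_peaks_sparse(track, retain_fraction=0.01)
        scores = np.array([100.0 * (i + 1) for i in range(100)])
        expected = (scores >= np.quantile(scores, 0.99)).sum()
        assert len(ps) == expected
        assert ps["score"].max() == 100 * 100.0

    def test_ties_at_threshold_all_kept(self):
        rows = [("c1", i * 1000, i * 1000 + 100, v)
                for i, v in enumerate([1.0] * 5 + [9.0, 9.0])]
        track = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
        ps = peaks.call_peaks_sparse(track, retain_fraction=1 / 7)
        assert (ps["score"] == 900.0).all()
        assert len(ps) == 2

    def test_adjacent_intervals_form_one_block(self):
        track = pd.DataFrame(
            {"chrom": ["c1"] * 3, "start": [0, 50, 100], "end": [50, 100, 300],
             "value": [1.0, 3.0, 1.0]}
        )
        ps = peaks.call_peaks_sparse(track, retain_fraction=1.0)
        assert len(ps) == 1
        assert ps.iloc[0]["score"] == 50 + 150 + 200

    def test_all_zero_track_rejected(self):
        track = pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [10],
                              "value": [0.0]})
        with pytest.raises(ValueError, match="no positive coverage"):
            peaks.call_peaks_sparse(track)

    def test_planted_peak_recovery(self):
        """20 planted fold-5 regions in a 10-Mb genome at 2e5 fragments:
        the caller recovers >= 90% of them at Jaccard >= 0.5."""
        regions = [
            simulate.PlantedRegion("chrT", 400_000 * (i + 1),
                                   400_000 * (i + 1) + 10_000, "common", 5.0)
            for i in range(20)
        ]
        p = simulate.CutrunSimParams(
            target_genome={"chrT": 10_000_000},
            spikein_genome={"chrS": 500_000},
            n_cells=200_000,
            global_level={"cond1": 1.0, "cond2": 1.0},
            planted_regions=regions,
            spikein_rate=0.05,
            n_replicates=1,
            seed=21,
        )
        sim = simulate.simulate_cutrun(p)
        frags = sim.samples["cond1_r1"]
        target = frags[frags["genome"] == GENOME_TARGET]
        assert len(target) > 150_000
        track = signal.coverage_track(target)
        n_blocks_frac = 25 / 10_000  # aim for ~25 retained blocks
        ps = peaks.merge_peaks(peaks.call_peaks_sparse(track, n_blocks_frac), 300)
        recovered = 0
        for r in regions:
            best = 0.0
            for q in ps.itertuples(index=False):
                inter = min(r.end, q.end) - max(r.start, q.start)
                if inter <= 0:
                    continue
                union = max(r.end, q.end) - min(r.start, q.start)
                best = max(best, inter / union)
            recovered += best >= 0.5
        assert recovered >= 18  # >= 90% of 20


class TestMergePeaks:
    def test_gap_below_300_merges(self):
        ps = interval_frame([("c1", 0, 100, 1.0), ("c1", 250, 350, 2.0)], score=True)
        out = peaks.merge_peaks(ps, 300)
        assert out.values.tolist() == [["c1", 0, 350, 3.0]]

    def test_gap_exactly_300_not_merged(self):
        ps = interval_frame([("c1", 0, 100, 1.0), ("c1", 400, 500, 2.0)], score=True)
        out = peaks.merge_peaks(ps, 300)
        assert len(out) == 2

    def test_matches_brute_force_transitive_closure(self, rng):
        for _ in range(25):
            ps = random_peakset(rng, int(rng.integers(2, 120)))
            got = peaks.merge_peaks(ps, 300)
            expected = brute_merge(ps, 300)
            pd.testing.assert_frame_equal(
                got[["chrom", "start", "end"]],
                expected[["chrom", "start", "end"]].astype(got["start"].dtype,
                                                           errors="ignore"),
                check_dtype=False,
            )
            assert np.allclose(got["score"], expected["score"])

    def test_idempotent_and_score_conserving(self, rng):
        ps = random_peakset(rng, 200)
        once = peaks.merge_peaks(ps, 300)
        twice = peaks.merge_peaks(once, 300)
        pd.testing.assert_frame_equal(once, twice)
        assert once["score"].sum() == pytest.approx(ps["score"].sum())


class TestIntersectReplicates:
    def test_identical_sets_pass_through(self, rng):
        ps = peaks.merge_peaks(random_peakset(rng, 50), 1)
        out = peaks.intersect_replicates(ps, ps)
        pd.testing.assert_frame_equal(out, ps.reset_index(drop=True))

    def test_disjoint_sets_empty(self):
        a = interval_frame([("c1", 0, 100)])
        b = interval_frame([("c1", 500, 600)])
        assert len(peaks.intersect_replicates(a, b)) == 0

    def test_first_set_coordinates_retained(self):
        a = interval_frame([("c1", 0, 100)])
        b = interval_frame([("c1", 50, 600)])
        out = peaks.intersect_replicates(a, b)
        assert out.values.tolist() == [["c1", 0, 100]]

    def test_matches_brute_force_overlap_filter(self, rng):
        for _ in range(25):
            a = random_peakset(rng, int(rng.integers(1, 100)), score=False)
            b = random_peakset(rng, int(rng.integers(1, 100)), score=False)
            got = peaks.intersect_replicates(a, b)
            expected = a[brute_overlaps(a, b)].reset_index(drop=True)
            pd.testing.assert_frame_equal(got, expected)


class TestCombinePeakLists:
    def test_duplicate_list_collapses(self):
        a = interval_frame([("c1", 0, 100), ("c1", 500, 700)])
        out = peaks.combine_peak_lists([a, a.copy()])
        pd.testing.assert_frame_equal(out, a)

    def test_disjoint_lists_concatenate_sorted(self):
        a = interval_frame([("c1", 500, 700)])
        b = interval_frame([("c1", 0, 100)])
        out = peaks.combine_peak_lists([a, b])
        assert out["start"].tolist() == [0, 500]

    def test_matches_brute_force_union(self, rng):
        for _ in range(20):
            sets = [random_peakset(rng, int(rng.integers(1, 60)), score=False)
                    for _ in range(3)]
            got = peaks.combine_peak_lists(sets)
            expected = brute_union(sets)
            pd.testing.assert_frame_equal(got, expected)

    def test_commutative(self, rng):
        a = random_peakset(rng, 40, score=False)
        b = random_peakset(rng, 40, score=False)
        pd.testing.assert_frame_equal(
            peaks.combine_peak_lists([a, b]), peaks.combine_peak_lists([b, a])
        )


class TestFilterExclusion:
    def test_exclusion_covering_genome_empties(self, rng):
        ps = random_peakset(rng, 20, score=False)
        excl = interval_frame([("c1", 0, 10**6), ("c2", 0, 10**6)])
        assert len(peaks.filter_exclusion(ps, excl)) == 0

    def test_empty_exclusion_is_identity(self, rng):
        ps = random_peakset(rng, 20, score=False)
        out = peaks.filter_exclusion(ps, interval_frame([]))
        pd.testing.assert_frame_equal(out, ps.reset_index(drop=True))

    def test_matches_brute_force(self, rng):
        for _ in range(25):
            ps = random_peakset(rng, int(rng.integers(1, 100)), score=False)
            excl = random_peakset(rng, int(rng.integers(1, 30)), score=False)
            got = peaks.filter_exclusion(ps, excl)
            expected = ps[~brute_overlaps(ps, excl)].reset_index(drop=True)
            pd.testing.assert_frame_equal(got, expected)


# ---------------------------------------------------------------------------
# differential regions


def _simulate_differential(seed=3, fold=4.0, n_regions=30, level=1.0):
    classes = ["cond1_enriched", "cond2_enriched", "common"]
    regions = [
        simulate.PlantedRegion("chrT", 200_000 * (i + 1),
                               200_000 * (i + 1) + 10_000, classes[i % 3], fold)
        for i in range(n_regions)
    ]
    p = simulate.CutrunSimParams(
        target_genome={"chrT": 200_000 * (n_regions + 1) + 100_000},
        spikein_genome={"chrS": 500_000},
        n_cells=60_000,
        global_level={"cond1": level, "cond2": level},
        planted_regions=regions,
        spikein_rate=0.2,
        n_replicates=2,
        seed=seed,
    )
    sim = simulate.simulate_cutrun(p)
    samples = {
        name: frags[frags["genome"] == GENOME_TARGET].reset_index(drop=True)
        for name, frags in sim.samples.items()
    }
    design = {name: p.condition_of(name) for name in samples}
    region_df = interval_frame(
        [(r.chrom, r.start, r.end) for r in regions]
    )
    return region_df, samples, design, regions


class TestDifferentialRegions:
    def test_identical_counts_class_common(self):
        regions = interval_frame([("c1", 0, 1000), ("c1", 2000, 3000)])
        frags = frag_frame([("c1", 100, 200), ("c1", 2100, 2200)] * 25)
        samples = {f"s{i}": frags.copy() for i in range(4)}
        design = {"s0": "x", "s1": "x", "s2": "y", "s3": "y"}
        out = peaks.differential_regions(regions, samples, design)
        assert (out["log2fc"] == 0).all()
        assert (out["region_class"] == "common").all()

    def test_planted_classes_recovered(self):
        """Fold-4 planted regions with 2 replicates/condition and deep
        coverage: >= 90% of regions get their true class."""
        region_df, samples, design, regions = _simulate_differential()
        # expected background counts/region: well above 50
        out = peaks.differential_regions(region_df, samples, design, alpha=0.05)
        out = out.sort_values("start").reset_index(drop=True)
        truth = [r.region_class for r in sorted(regions, key=lambda r: r.start)]
        correct = (out["region_class"] == truth).sum()
        assert correct / len(truth) >= 0.9

    def test_null_type_i_error_controlled(self):
        """Permuting condition labels on null data keeps the q<0.05 fraction
        within binomial noise of the nominal rate."""
        region_df, samples, design, _ = _simulate_differential(
            seed=17, fold=1.0, n_regions=40
        )
        # swap one replicate across conditions: labels now uninformative
        names = list(samples)
        perm = {names[0]: "cond1", names[2]: "cond1",
                names[1]: "cond2", names[3]: "cond2"}
        out = peaks.differential_regions(region_df, samples, perm, alpha=0.05)
        frac = (out["q"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(out))
        assert frac <= 0.05 + 2 * se

    def test_condition_with_one_sample_rejected(self):
        regions = interval_frame([("c1", 0, 1000)])
        frags = frag_frame([("c1", 100, 200)])
        with pytest.raises(ValueError, match="fewer than 2"):
            peaks.differential_regions(
                regions, {"a": frags, "b": frags, "c": frags},
                {"a": "x", "b": "x", "c": "y"},
            )

    def test_empty_region_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            peaks.differential_regions(
                interval_frame([]), {}, {}
            )


class TestAnnotateRegions:
    GENES = pd.DataFrame(
        {
            "gene_id": ["g1", "g2"],
            "chrom": ["c1", "c1"],
            "start": [10_000, 50_000],
            "end": [20_000, 60_000],
            "strand": ["+", "-"],
            "tss": [10_000, 59_999],
        }
    )

    def test_region_on_tss_promoter_distance_zero(self):
        regions = interval_frame([("c1", 9_500, 10_500)])
        out = peaks.annotate_regions(regions, self.GENES)
        row = out.iloc[0]
        assert row["promoter"] and row["tss_distance"] == 0
        assert row["marked_gene"] == "g1"

    def test_marked_gene_boundary_at_10kb(self):
        # g1's TSS sits at 10,000; a region starting 10,001 bp past it is
        # just outside the marked-gene window, 10,000 bp is just inside
        out_in = peaks.annotate_regions(interval_frame([("c1", 20_001, 20_002)]),
                                        self.GENES)
        assert out_in.iloc[0]["tss_distance"] == 10_001
        assert out_in.iloc[0]["marked_gene"] is None
        out_ok = peaks.annotate_regions(interval_frame([("c1", 20_000, 20_001)]),
                                        self.GENES)
        assert out_ok.iloc[0]["tss_distance"] == 10_000
        assert out_ok.iloc[0]["marked_gene"] == "g1"

    def test_promoter_window_is_halfopen_3kb(self):
        # [tss-3000, tss+3000) around g1's tss=10,000 -> [7000, 13000)
        assert peaks.annotate_regions(
            interval_frame([("c1", 6_000, 7_001)]), self.GENES
        ).iloc[0]["promoter"]
        assert not peaks.annotate_regions(
            interval_frame([("c1", 6_000, 7_000)]), self.GENES
        ).iloc[0]["promoter"]

    def test_nearest_gene_matches_brute_force(self, rng):
        genes = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(30)],
                "chrom": rng.choice(["c1", "c2"], 30),
                "start": rng.integers(0, 100_000, 30),
                "strand": "+",
            }
        )
        genes["end"] = genes["start"] + 1000
        genes["tss"] = genes["start"]
        regions = []
        for _ in range(50):
            s = int(rng.integers(0, 100_000))
            regions.append((str(rng.choice(["c1", "c2"])), s, s + 500))
        out = peaks.annotate_regions(interval_frame(regions), genes)
        for _, row in out.iterrows():
            sub = genes[genes["chrom"] == row["chrom"]]
            dists = [
                max(row["start"] - t, t - (row["end"] - 1), 0)
                for t in sub["tss"]
            ]
            assert row["tss_distance"] == min(dists)

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError, match="empty gene list"):
            peaks.annotate_regions(
                interval_frame([("c1", 0, 10)]), self.GENES.iloc[0:0]
            )
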