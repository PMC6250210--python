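"""Windowed statistics against independent brute-force oracles."""

import numpy as np
import pytest

from introscan import (
    DemographicModel,
    GenomicWindow,
    allele_counts,
    dxy_window,
    dxy_windows,
    fst_wc_window,
    fst_wc_windows,
    make_windows,
    pi_window,
    pi_windows,
    rescale_density,
    simulate,
    sliding_dxy,
    tajimas_d_window,
    tajimas_d_windows,
)
from introscan.haplotypes import SiteAlleleCounts
from introscan.windows import tajima_constants


def counts_from_arrays(**pops):
    """Build SiteAlleleCounts from per-pop (S, 4) arrays."""
    arrays = {k: np.asarray(v, dtype=np.int32) for k, v in pops.items()}
    n = next(iter(arrays.values())).shape[0]
    return SiteAlleleCounts("scaf1", np.arange(1, n + 1), arrays)


def biallelic_counts(pairs_by_pop):
    """pairs_by_pop: pop -> list of (ref_count, total) per site."""
    out = {}
    for pop, pairs in pairs_by_pop.items():
        arr = np.zeros((len(pairs), 4), dtype=np.int32)
        for i, (c, n) in enumerate(pairs):
            arr[i, 0] = c
            arr[i, 1] = n - c
        out[pop] = arr
    return counts_from_arrays(**out)


class TestMakeWindows:
    @pytest.mark.parametrize(
        "length,expected", [(25_000_000, 500), (49_999, 1), (125_000, 3)]
    )
    def test_window_counts(self, length, expected):
        wins = make_windows({"s": length}, 50_000)
        assert len(wins) == expected
        assert wins[0].start == 0
        assert wins[-1].end == length

    def test_one_based_reporting(self):
        w = make_windows({"s": 450_000}, 50_000)[8]
        assert (w.start_1based, w.end_1based) == (400_001, 450_000)


class TestPi:
    def test_single_polymorphic_site_arithmetic(self):
        # one site with 2 ref of 4 called, nine monomorphic callable sites
        pairs = [(2, 4)] + [(4, 4)] * 9
        counts = biallelic_counts({"P": pairs})
        rec = pi_window(counts, GenomicWindow("scaf1", 0, 10), "P", 0.0)
        assert rec.value == pytest.approx((2 * 2 * 2 / (4 * 3)) / 10)
        assert rec.n_sites_used == 10

    def test_all_monomorphic_is_zero(self):
        counts = biallelic_counts({"P": [(6, 6)] * 20})
        rec = pi_window(counts, GenomicWindow("scaf1", 0, 20), "P", 0.0)
        assert rec.value == 0.0

    def test_no_callable_sites_gives_na(self):
        counts = biallelic_counts({"P": [(0, 0)] * 5})
        rec = pi_window(counts, GenomicWindow("scaf1", 0, 5), "P", 0.0)
        assert rec.is_na

    def test_matches_all_pairs_hamming_oracle(self, sim_small, counts_small, windows_small):
        # on complete haploid data pi equals the mean pairwise mismatch
        # fraction over all within-population sequence pairs, exactly
        calls = sim_small.haplotypes.calls
        rows = range(0, 8)  # population I1
        w = windows_small[1]
        seqs = calls[:, w.start : w.end]
        mismatches = [
            (seqs[i] != seqs[j]).mean()
            for i in rows
            for j in rows
            if i < j
        ]
        oracle = np.mean(mismatches)
        rec = pi_window(counts_small, w, "I1")
        assert rec.value == pytest.approx(oracle, abs=1e-12)


class TestDxy:
    def test_fixed_difference_is_one(self):
        counts = biallelic_counts({"A": [(4, 4)] * 5, "B": [(0, 4)] * 5})
        rec = dxy_window(counts, GenomicWindow("scaf1", 0, 5), "A", "B", 0.0)
        assert rec.value == 1.0

    def test_equal_intermediate_frequencies(self):
        counts = biallelic_counts({"A": [(2, 4)] * 5, "B": [(2, 4)] * 5})
        rec = dxy_window(counts, GenomicWindow("scaf1", 0, 5), "A", "B", 0.0)
        assert rec.value == pytest.approx(0.5)

    def test_symmetry_exact(self, counts_small, windows_small):
        for w in windows_small:
            ab = dxy_window(counts_small, w, "I1", "O").value
            ba = dxy_window(counts_small, w, "O", "I1").value
            assert ab == ba

    def test_matches_all_pairs_mismatch_oracle(self, sim_small, counts_small, windows_small):
        # complete-data identity: dxy equals the mean mismatch fraction over
        # all inter-population sequence pairs, exactly
        calls = sim_small.haplotypes.calls
        w = windows_small[0]
        seqs = calls[:, w.start : w.end]
        oracle = np.mean(
            [(seqs[i] != seqs[j]).mean() for i in range(8, 16) for j in range(16, 24)]
        )
        rec = dxy_window(counts_small, w, "I2", "O")
        assert rec.value == pytest.approx(oracle, abs=1e-12)

    def test_span_denominator_mode(self):
        # 5 callable sites of a 10-bp window: the span mode divides the same
        # divergence sum by the full window length
        pairs = [(4, 4)] * 3 + [(0, 4)] * 2 + [(0, 0)] * 5
        counts = biallelic_counts({"A": pairs, "B": [(4, 4)] * 5 + [(0, 0)] * 5})
        w = GenomicWindow("scaf1", 0, 10)
        per_callable = dxy_window(counts, w, "A", "B", 0.0)
        per_span = dxy_window(counts, w, "A", "B", 0.0, denominator="span")
        assert per_callable.value == pytest.approx(2 / 5)
        assert per_span.value == pytest.approx(2 / 10)

    def test_species_tree_ordering(self, counts_small, windows_small):
        d_in = np.mean([dxy_window(counts_small, w, "I1", "I2").value for w in windows_small])
        d_out = np.mean([dxy_window(counts_small, w, "I2", "O").value for w in windows_small])
        assert d_in < d_out

    def test_bounds(self, counts_small, windows_small):
        for w in windows_small:
            v = dxy_window(counts_small, w, "I1", "O").value
            assert 0.0 <= v <= 1.0


def wc_fst_site_oracle(n1, c1, n2, c2):
    """Independent single-site Weir & Cockerham (1984) algebra (r=2, h=0)."""
    p1, p2 = c1 / n1, c2 / n2
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2)
    return a, b


class TestFstWc:
    def test_no_differentiation_near_zero(self):
        # both populations sampled from one panmictic pool: estimator is
        # unbiased, so the windowed value sits near zero
        rng = np.random.default_rng(1)
        n = 16
        truth = rng.uniform(0.2, 0.8, size=300)
        pairs_a = [(int(rng.binomial(n, p)), n) for p in truth]
        pairs_b = [(int(rng.binomial(n, p)), n) for p in truth]
        counts = biallelic_counts({"A": pairs_a, "B": pairs_b})
        rec = fst_wc_window(counts, GenomicWindow("scaf1", 0, 300), "A", "B", 0.0)
        assert abs(rec.value) < 0.05

    def test_fixed_difference_approaches_one(self):
        n = 40
        counts = biallelic_counts({"A": [(n, n)] * 50, "B": [(0, n)] * 50})
        rec = fst_wc_window(counts, GenomicWindow("scaf1", 0, 50), "A", "B", 0.0)
        assert rec.value > 1 - 2 / n

    def test_matches_single_site_oracle(self):
        # 5+5 diploids (10 alleles each) at 3 polymorphic sites
        sites = [((10, 7), (10, 2)), ((10, 5), (10, 5)), ((10, 9), (10, 1))]
        counts = biallelic_counts(
            {"A": [s[0][::-1] for s in sites], "B": [s[1][::-1] for s in sites]}
        )
        # oracle: ratio of summed components
        asum = bsum = 0.0
        for (n1, c1), (n2, c2) in sites:
            a, b = wc_fst_site_oracle(n1, c1, n2, c2)
            asum += a
            bsum += a + b
        rec = fst_wc_window(counts, GenomicWindow("scaf1", 0, 3), "A", "B", 0.0)
        assert rec.value == pytest.approx(asum / bsum, abs=1e-12)

    def test_monomorphic_window_is_na(self):
        counts = biallelic_counts({"A": [(4, 4)] * 5, "B": [(4, 4)] * 5})
        rec = fst_wc_window(counts, GenomicWindow("scaf1", 0, 5), "A", "B", 0.0)
        assert rec.is_na

    def test_symmetry(self, counts_small, windows_small):
        w = windows_small[0]
        assert (
            fst_wc_window(counts_small, w, "I1", "I2").value
            == fst_wc_window(counts_small, w, "I2", "I1").value
        )


def tajimas_d_oracle(n, site_counts):
    """Textbook Tajima (1989) D for constant sample size n; site_counts are
    derived-allele counts at segregating sites."""
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    s = len(site_counts)
    pi = sum(2 * c * (n - c) / (n * (n - 1)) for c in site_counts)
    return (pi - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1))


class TestTajimasD:
    def test_no_segregating_sites_is_na(self):
        counts = biallelic_counts({"P": [(4, 4)] * 10})
        rec = tajimas_d_window(counts, GenomicWindow("scaf1", 0, 10), "P", 0.0)
        assert rec.is_na

    def test_small_example_matches_textbook_oracle(self):
        site_counts = [1, 1, 2]
        pairs = [(4 - c, 4) for c in site_counts] + [(4, 4)] * 7
        counts = biallelic_counts({"P": pairs})
        rec = tajimas_d_window(counts, GenomicWindow("scaf1", 0, 10), "P", 0.0)
        assert rec.value == pytest.approx(tajimas_d_oracle(4, site_counts), abs=1e-12)

    def test_constants_cached_consistently(self):
        assert tajima_constants(10) == tajima_constants(10)
        a1 = tajima_constants(4)[0]
        assert a1 == pytest.approx(1 + 1 / 2 + 1 / 3)

    def test_neutral_simulation_centres_near_zero(self, counts_small, windows_small):
        recs = tajimas_d_windows(counts_small, windows_small, "I1")
        vals = [r.value for r in recs if not r.is_na]
        assert len(vals) >= 3
        assert abs(np.mean(vals)) < 0.5  # tight check is in the larger acceptance run


class TestSlidingDxy:
    def test_window_count_formula(self, counts_small):
        recs = sliding_dxy(counts_small, 50_000, 10_000, 2_000, "I1", "O")
        assert len(recs) == (50_000 - 10_000) // 2_000 + 1 == 21

    def test_step_equals_window_matches_tiling(self, counts_small, small_model):
        tiled = dxy_windows(
            counts_small,
            make_windows({"sim1": small_model.chromosome_length}, 10_000),
            "I1",
            "O",
        )
        slid = sliding_dxy(
            counts_small, small_model.chromosome_length, 10_000, 10_000, "I1", "O"
        )
        assert [r.value for r in slid] == [r.value for r in tiled]

    def test_short_scaffold_gives_single_clipped_window(self, counts_small):
        recs = sliding_dxy(counts_small, 5_000, 10_000, 2_000, "I1", "O")
        assert len(recs) == 1
        assert recs[0].window.span == 5_000

    def test_implanted_low_divergence_tract_detected(self, small_model):
        # copy I2's haplotypes into O across a tract: d_XY collapses there
        sim = simulate(small_model)
        calls = sim.haplotypes.calls.copy()
        tract = slice(80_000, 120_000)
        calls[16:24, tract] = calls[8:16, tract]
        from introscan import HaplotypeMatrix

        matrix = HaplotypeMatrix(
            "sim1", sim.haplotypes.positions, sim.haplotypes.samples, calls
        )
        groups = {"I2": matrix.samples[8:16], "O": matrix.samples[16:24]}
        counts = allele_counts(matrix, groups)
        recs = sliding_dxy(counts, 200_000, 10_000, 2_000, "I2", "O")
        vals = np.array([r.value for r in recs])
        starts = np.array([r.window.start for r in recs])
        inside = (starts >= 80_000) & (starts + 10_000 <= 120_000)
        assert vals[inside].max() < vals[~inside].min()


class TestRescaleDensity:
    def test_maximum_bin_is_one(self):
        rng = np.random.default_rng(0)
        edges, heights = rescale_density(rng.normal(size=500), bins=20)
        assert heights.max() == 1.0
        assert len(edges) == 21

    def test_single_bin(self):
        edges, heights = rescale_density([0.5] * 10, bins=5)
        assert (heights == 1.0).sum() == 1
        assert set(heights) <= {0.0, 1.0}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rescale_density([])


class TestMissingnessRules:
    def test_window_below_callable_minimum_is_na(self):
        # 10 callable sites in a 100-bp window: 10% <= 20% minimum
        pairs = [(2, 4)] * 10
        counts = biallelic_counts({"P": pairs})
        rec = pi_window(counts, GenomicWindow("scaf1", 0, 100), "P")
        assert rec.is_na
        assert rec.n_sites_used == 10

    def test_na_record_propagates_as_nan(self):
        from introscan.windows import records_to_frame

        pairs = [(2, 4)] * 10
        counts = biallelic_counts({"P": pairs})
        recs = [
            pi_window(counts, GenomicWindow("scaf1", 0, 100), "P"),  # 10% callable
            pi_window(counts, GenomicWindow("scaf1", 0, 10), "P", 0.0),
        ]
        df = records_to_frame(recs)
        assert np.isnan(df["value"].iloc[0])
        assert np.isfinite(df["value"].iloc[1])
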