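"""AMR caller: window scanning, the two-model likelihoods, merging, levels."""

import numpy as np
import pandas as pd
import pytest

from beeallele import amr, synthio
from beeallele.io import cpg_positions_from_report

from conftest import make_window


def epiread_frame(chrom_reads):
    rows = [(chrom, start, states)
            for chrom, reads in chrom_reads.items()
            for start, states in reads]
    return pd.DataFrame(rows, columns=["chrom", "start", "states"])


class TestScanWindows:
    def test_window_count_is_cpgs_minus_w_plus_one(self):
        reads = [(0, "CCCCC")] * 10
        epi = epiread_frame({"chr1": reads})
        wins, skipped = amr.scan_windows(epi, {"chr1": [10, 20, 30, 40, 50]},
                                         amr.AmrConfig())
        assert len(wins) == 3 and skipped == 0
        assert [tuple(w.cpg_indices) for w in wins] == [(0, 1, 2), (1, 2, 3),
                                                        (2, 3, 4)]

    def test_low_coverage_cpg_skips_its_windows(self):
        # middle CpG covered by only 9 reads -> all 3 windows touching it skipped
        reads = [(0, "CCCCC")] * 9 + [(0, "C"), (3, "CC")]
        epi = epiread_frame({"chr1": reads})
        wins, skipped = amr.scan_windows(epi, {"chr1": [10, 20, 30, 40, 50]},
                                         amr.AmrConfig())
        assert len(wins) == 0 and skipped == 3

    def test_windows_tested_matches_counting_oracle(self):
        cfg = synthio.MethSimConfig(n_regions=5, cpgs_per_region=9,
                                    reads_per_cpg=10, is_amr=0, seed=2)
        epi, cyt, _ = synthio.simulate_epireads(cfg)
        wins, skipped = amr.scan_windows(epi, cpg_positions_from_report(cyt),
                                         amr.AmrConfig())
        assert len(wins) == 5 * (9 - 3 + 1) and skipped == 0

    def test_allow_list_restricts_chromosomes(self):
        epi = epiread_frame({"chr1": [(0, "CCC")] * 10,
                             "scaffold1": [(0, "CCC")] * 10})
        pos = {"chr1": [1, 2, 3], "scaffold1": [1, 2, 3]}
        wins, _ = amr.scan_windows(epi, pos, amr.AmrConfig(), chroms=["chr1"])
        assert {w.chrom for w in wins} == {"chr1"}

    def test_short_chromosome_warns(self):
        epi = epiread_frame({"chr1": [(0, "CC")] * 10})
        with pytest.warns(UserWarning, match="fewer than"):
            wins, _ = amr.scan_windows(epi, {"chr1": [1, 2]}, amr.AmrConfig())
        assert wins == []


class TestSingleProfile:
    def test_fully_methylated_window(self):
        ll, prof = amr.fit_single_profile(make_window(["CCC"] * 10))
        assert np.allclose(prof, 1.0, atol=1e-5)
        assert ll == pytest.approx(0.0, abs=1e-3)

    def test_half_half_closed_form(self, cc_tt_window):
        ll, prof = amr.fit_single_profile(cc_tt_window)
        assert np.allclose(prof, 0.5)
        assert ll == pytest.approx(60 * np.log(0.5), abs=1e-6)

    def test_profile_is_column_mean_for_complete_reads(self):
        win = make_window(["CCT", "CTT", "CCC", "TTT"])
        _, prof = amr.fit_single_profile(win)
        assert np.allclose(prof, win.reads.mean(axis=0))


class TestTwoProfile:
    def test_separated_epialleles_reach_known_optimum(self, cc_tt_window):
        fit = amr.fit_two_profile(cc_tt_window, amr.AmrConfig(),
                                  np.random.default_rng(0))
        assert fit.ll_two == pytest.approx(20 * np.log(0.5), abs=1e-3)
        assert fit.lr_stat == pytest.approx(
            2 * (20 * np.log(0.5) - 60 * np.log(0.5)), abs=0.01)
        profs = fit.profiles[np.argsort(fit.profiles[:, 0])]
        assert np.allclose(profs[0], 0.0, atol=1e-4)
        assert np.allclose(profs[1], 1.0, atol=1e-4)

    def test_identical_reads_give_zero_likelihood_ratio(self):
        fit = amr.fit_two_profile(make_window(["CCC"] * 12), amr.AmrConfig(),
                                  np.random.default_rng(1))
        assert fit.lr_stat == pytest.approx(0.0, abs=1e-6)
        assert fit.p_value == pytest.approx(1.0, abs=1e-6)

    def test_label_symmetry_of_mixture_likelihood(self, cc_tt_window):
        """Swapping the two fitted profiles leaves the mixture LL unchanged."""
        fit = amr.fit_two_profile(cc_tt_window)
        R = cc_tt_window.reads
        obs = ~np.isnan(R)
        X = np.nan_to_num(R)

        def mix_ll(pa, pb):
            la = np.where(obs, X * np.log(pa) + (1 - X) * np.log1p(-pa), 0).sum(1)
            lb = np.where(obs, X * np.log(pb) + (1 - X) * np.log1p(-pb), 0).sum(1)
            return np.logaddexp(np.log(0.5) + la, np.log(0.5) + lb).sum()

        pa, pb = fit.profiles
        assert mix_ll(pa, pb) == pytest.approx(mix_ll(pb, pa), abs=1e-9)

    def test_nesting_holds_on_noisy_windows(self):
        cfg = synthio.MethSimConfig(n_regions=6, cpgs_per_region=5,
                                    reads_per_cpg=12, is_amr=3,
                                    profile_a=0.7, profile_b=0.2, seed=3)
        epi, cyt, _ = synthio.simulate_epireads(cfg)
        wins, _ = amr.scan_windows(epi, cpg_positions_from_report(cyt),
                                   amr.AmrConfig())
        fits = amr.fit_windows(wins, amr.AmrConfig(), seed=4)
        assert (fits.ll_two >= fits.ll_single - 1e-6).all()

    def test_best_ll_nondecreasing_in_restarts(self):
        rng = np.random.default_rng(6)
        win = make_window(["CCT", "CTT", "TCC", "CCC", "TTT", "TTC",
                           "CTC", "TCT", "CCC", "TTT"])
        lls = []
        for k in range(1, 7):
            fit = amr.fit_two_profile(win, amr.AmrConfig(n_restarts=k),
                                      np.random.default_rng(42))
            lls.append(fit.ll_two)
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_null_windows_give_conservative_pvalues(self):
        """Windows simulated from one shared profile: empirical type-I at
        0.05 does not exceed the nominal level (chi-square reference on the
        mixture LR is conservative)."""
        cfg = synthio.MethSimConfig(n_regions=70, cpgs_per_region=3,
                                    reads_per_cpg=15, is_amr=0,
                                    profile_a=0.5, profile_b=0.5, seed=10)
        epi, cyt, _ = synthio.simulate_epireads(cfg)
        wins, _ = amr.scan_windows(epi, cpg_positions_from_report(cyt),
                                   amr.AmrConfig())
        fits = amr.fit_windows(wins, amr.AmrConfig(), seed=11)
        rate = (fits.p_value < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(fits))
        assert rate <= 0.05 + 3 * se


class TestCallAndAnnotate:
    @staticmethod
    def fits_frame(entries):
        rows = []
        for chrom, s, e, p in entries:
            rows.append(dict(chrom=chrom, start_idx=s, end_idx=e,
                             start_pos=1000 + 50 * s, end_pos=1000 + 50 * e,
                             ll_single=0.0, ll_two=0.0, lr_stat=0.0,
                             p_value=p, converged=True))
        return pd.DataFrame(rows)

    def test_overlapping_significant_windows_merge(self):
        fits = self.fits_frame([("c", 0, 2, 1e-9), ("c", 1, 3, 1e-9),
                                ("c", 2, 4, 0.9), ("c", 3, 5, 0.9)])
        regions = amr.call_amrs(fits, amr.AmrConfig())
        assert len(regions) == 1
        row = regions.iloc[0]
        # spans CpG 0 (pos 1000) to CpG 3 (pos 1150), BED half-open
        assert (row.start, row.end) == (999, 1150)
        assert row.n_windows == 2

    def test_separated_windows_stay_distinct_regions(self):
        entries = [("c", i, i + 2, 0.9) for i in range(12)]
        entries[0] = ("c", 0, 2, 1e-9)
        entries[8] = ("c", 8, 10, 1e-9)
        regions = amr.call_amrs(self.fits_frame(entries), amr.AmrConfig())
        assert len(regions) == 2

    def test_region_carries_min_member_p_and_q(self):
        fits = self.fits_frame([("c", 0, 2, 1e-9), ("c", 1, 3, 1e-6)])
        regions = amr.call_amrs(fits, amr.AmrConfig())
        assert regions.p_value.iloc[0] == 1e-9

    def test_no_significant_windows_gives_empty_table(self):
        regions = amr.call_amrs(self.fits_frame([("c", 0, 2, 0.8)]),
                                amr.AmrConfig())
        assert regions.empty

    @pytest.fixture
    def annotation(self):
        genes = pd.DataFrame({"gene_id": ["g1", "g2"], "chrom": ["c", "c"],
                              "start": [100, 900], "end": [500, 1200]})
        exons = pd.DataFrame({"gene_id": ["g1", "g1"], "chrom": ["c", "c"],
                              "start": [100, 400], "end": [200, 500]})
        return genes, exons

    def region(self, start, end):
        return pd.DataFrame([dict(region_id="r", chrom="c", start=start,
                                  end=end, p_value=1e-9, q_value=1e-6,
                                  n_windows=1)])

    def test_region_in_exon(self, annotation):
        genes, exons = annotation
        out = amr.annotate_amrs(self.region(120, 180), genes, exons)
        assert out.feature.iloc[0] == "exon" and out.gene_ids.iloc[0] == "g1"

    def test_region_in_gene_body_outside_exons_is_intron(self, annotation):
        genes, exons = annotation
        out = amr.annotate_amrs(self.region(250, 350), genes, exons)
        assert out.feature.iloc[0] == "intron"

    def test_region_outside_genes_has_no_annotation(self, annotation):
        genes, exons = annotation
        out = amr.annotate_amrs(self.region(600, 700), genes, exons)
        assert out.feature.iloc[0] == "no_annotation"
        assert out.gene_ids.iloc[0] == ""

    def test_region_spanning_two_genes_lists_both(self, annotation):
        genes, exons = annotation
        out = amr.annotate_amrs(self.region(450, 950), genes, exons)
        assert out.gene_ids.iloc[0] == "g1;g2"


class TestWeightedMethylation:
    @staticmethod
    def report(meth, unmeth, pos=None):
        pos = pos or list(range(100, 100 + 10 * len(meth), 10))
        return pd.DataFrame({"chrom": "c", "pos": pos, "strand": "+",
                             "count_methylated": meth,
                             "count_unmethylated": unmeth})

    @staticmethod
    def gene(start=50, end=500):
        return pd.DataFrame([{"gene_id": "g1", "chrom": "c",
                              "start": start, "end": end}])

    def test_weighted_level_is_pooled_ratio(self):
        out = amr.weighted_methylation(self.report([2, 3], [8, 7]), self.gene())
        assert out.weighted_level.iloc[0] == pytest.approx(0.25)  # 5/20

    def test_unmethylated_gene(self):
        out = amr.weighted_methylation(self.report([0, 0], [10, 10]), self.gene())
        assert out.weighted_level.iloc[0] == 0.0
        assert not out.is_methylated.iloc[0]

    def test_level_exactly_at_error_rate_is_not_methylated(self):
        out = amr.weighted_methylation(self.report([1], [19]), self.gene())
        assert out.weighted_level.iloc[0] == pytest.approx(0.05)
        assert not bool(out.is_methylated.iloc[0])  # strictly greater than

    def test_cpgs_outside_gene_excluded(self):
        out = amr.weighted_methylation(
            self.report([10, 0], [0, 10], pos=[100, 900]), self.gene(50, 500))
        assert out.weighted_level.iloc[0] == pytest.approx(1.0)
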