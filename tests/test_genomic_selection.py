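"""Coverage normalization, amplification/SNP selection proxies, parallelism."""

import math

import numpy as np
import pandas as pd
import pytest

from ampliscope.genomic_selection import (
    AmplificationFit,
    CoverageTrack,
    Feature,
    RelativeCopies,
    SnpTrajectory,
    filter_snp_trajectories,
    fit_amplification,
    fit_snp_selection,
    gene_dose_hotspot,
    parallelism,
    relative_copies,
)


def uniform_track(depth, n_windows=100, window=1000, sample_id="s", dose=0.0, time=0.0):
    starts = np.arange(n_windows) * window
    df = pd.DataFrame(
        {"chrom": "chr1", "start": starts, "end": starts + window, "depth": depth}
    )
    return CoverageTrack(sample_id, dose, time, df)


class TestFeature:
    def test_interval_lengths_in_kb(self):
        # the two amplified regions tracked throughout the analysis
        acrab_region = Feature("acrAB-region", "chr1", 274_000, 576_000)
        rrlb_region = Feature("rrlB-region", "chr1", 4_164_000, 4_189_000)
        assert acrab_region.length_kb == pytest.approx(302.0)
        assert rrlb_region.length_kb == pytest.approx(25.0)

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            Feature("bad", "chr1", 100, 100)


class TestRelativeCopies:
    def amplified_track(self, feature_depth=600.0, background=200.0, **kw):
        depth = np.full(100, background)
        depth[:10] = feature_depth  # 10-window feature at the chromosome start
        return uniform_track(depth, **kw)

    FEATURE = Feature("amp", "chr1", 0, 10_000)

    def test_uniform_depth_gives_unity(self):
        anc = uniform_track(np.full(100, 200.0))
        tr = uniform_track(np.full(100, 200.0), dose=10.0, time=2.0)
        rc = relative_copies([tr], self.FEATURE, anc)
        assert rc.rel_copies[0] == pytest.approx(1.0)

    def test_whole_genome_mean_bias_documented_by_arithmetic(self):
        # feature depth 600 against background 200 over 10% of the genome:
        # the genome mean includes the amplification (240), so mean
        # normalization reports 600/240 = 2.5 while median reports 3.0
        anc = uniform_track(np.full(100, 200.0))
        tr = self.amplified_track(dose=10.0, time=2.0)
        assert relative_copies([tr], self.FEATURE, anc).rel_copies[0] == pytest.approx(2.5)
        assert relative_copies([tr], self.FEATURE, anc, stat="median").rel_copies[
            0
        ] == pytest.approx(3.0)

    def test_invariant_under_global_depth_rescaling(self):
        anc = uniform_track(np.full(100, 200.0))
        tr1 = self.amplified_track(dose=10.0, time=2.0)
        tr2 = self.amplified_track(1800.0, 600.0, dose=10.0, time=2.0)
        r1 = relative_copies([tr1], self.FEATURE, anc).rel_copies[0]
        r2 = relative_copies([tr2], self.FEATURE, anc).rel_copies[0]
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_feature_outside_coverage_rejected(self):
        anc = uniform_track(np.full(100, 200.0))
        outside = Feature("x", "chr2", 0, 1000)
        with pytest.raises(ValueError):
            relative_copies([anc], outside, anc)


class TestAmplificationFit:
    TIMES = np.array([0.0, 2.0, 4.0])

    def rc(self, values, times=None):
        return RelativeCopies(
            Feature("f", "chr1", 0, 1000), 10.0, times if times is not None else self.TIMES, np.asarray(values)
        )

    def test_known_parameter_derivative(self):
        fit = AmplificationFit(p1=2.0, p2=1.0, s_proxy=0.0, fit_rss=0.0)
        assert float(fit.derivative(0.0)) == pytest.approx(0.5)

    def test_flat_track_has_negligible_selection(self):
        fit = fit_amplification(self.rc(np.ones(3)))
        assert fit.s_proxy < 0.01

    def test_noiseless_parameters_recovered(self):
        y = 1.8 * (1 + self.TIMES) / (1 + 0.6 * (1 + self.TIMES))
        fit = fit_amplification(self.rc(y))
        assert fit.p1 == pytest.approx(1.8, rel=5e-3)
        assert fit.p2 == pytest.approx(0.6, rel=5e-3)
        assert fit.s_proxy == pytest.approx(1.8 / (1 + 0.6) ** 2, rel=5e-3)

    def test_derivative_matches_finite_differences(self):
        fit = AmplificationFit(p1=1.8, p2=0.6, s_proxy=0.0, fit_rss=0.0)
        t = np.linspace(0.0, 4.0, 9)
        h = 1e-6
        fd = (fit.predict(t + h) - fit.predict(t - h)) / (2 * h)
        assert np.allclose(fit.derivative(t), fd, rtol=1e-6)

    def test_selection_proxy_max_sits_at_earliest_time(self):
        y = 1.8 * (1 + self.TIMES) / (1 + 0.6 * (1 + self.TIMES))
        fit = fit_amplification(self.rc(y))
        assert fit.s_proxy == pytest.approx(float(fit.derivative(self.TIMES[0])), rel=1e-9)


class TestGeneDoseHotspot:
    def test_symmetric_peak(self):
        est = gene_dose_hotspot({10.0: 1.0, 20.0: 2.0, 30.0: 1.0, 40.0: -2.0})
        assert est.shape == "peaked"

    def test_symmetric_three_point_parabola(self):
        est = gene_dose_hotspot({10.0: 1.0, 20.0: 2.0, 30.0: 1.0, 0.0: -2.0})
        assert est.e_max == pytest.approx(20.0, abs=0.5)

    def test_declining_selection_peaks_at_zero_dose(self):
        # the media-adaptation pattern: selection strictly declines with dose
        est = gene_dose_hotspot({0.0: 2.0, 10.0: 1.4, 20.0: 0.9, 30.0: 0.5, 40.0: 0.2})
        assert est.e_max == 0.0
        assert est.shape == "boundary"

    def test_flat_selection_classified(self):
        est = gene_dose_hotspot({0.0: 1.0, 10.0: 1.0, 20.0: 1.0, 30.0: 1.0})
        assert est.shape == "flat"

    def test_recovery_of_true_peak_under_noise(self):
        rng = np.random.default_rng(5)
        doses = np.arange(0.0, 45.0, 5.0)
        s_true = 1.0 - ((doses - 22.0) / 30.0) ** 2
        hits = 0
        n_runs = 200
        for _ in range(n_runs):
            s_obs = s_true * (1.0 + rng.normal(0.0, 0.10, len(doses)))
            est = gene_dose_hotspot(dict(zip(doses, s_obs)))
            hits += abs(est.e_max - 22.0) <= 5.0
        assert hits / n_runs >= 0.90


class TestSnpSelectionFit:
    def traj(self, times, freq, depth=200):
        return SnpTrajectory(100, "geneX", 10.0, np.asarray(times), np.asarray(freq), np.full(len(freq), depth))

    def test_printed_trajectory_recovers_p19_s1(self):
        # frequencies rounded to 4 decimals, hence the ~2% slack on p
        fit = fit_snp_selection(self.traj([0.0, 3.0, 6.0], [0.05, 0.5139, 0.9531]))
        assert fit.p == pytest.approx(19.0, rel=0.05)
        assert fit.s == pytest.approx(1.0, rel=0.02)

    def test_constant_frequency_is_neutral(self):
        fit = fit_snp_selection(self.traj([0.0, 2.0, 4.0], [0.3, 0.3, 0.3]))
        assert fit.s == pytest.approx(0.0, abs=1e-6)

    def test_declining_frequency_gives_negative_s(self):
        f = 1.0 / (1.0 + 0.5 * np.exp(0.8 * np.array([0.0, 2.0, 4.0])))
        fit = fit_snp_selection(self.traj([0.0, 2.0, 4.0], f))
        assert fit.s == pytest.approx(-0.8, rel=0.01)

    def test_all_zero_frequencies_flagged(self):
        fit = fit_snp_selection(self.traj([0.0, 2.0, 4.0], [0.0, 0.0, 0.0]))
        assert not fit.converged
        assert math.isnan(fit.s)

    def test_binomial_noise_recovery(self):
        # depth-200 binomial sampling of a true s = 0.8 trajectory
        rng = np.random.default_rng(9)
        t = np.array([0.0, 2.0, 4.0, 6.0])
        f_true = 1.0 / (1.0 + 19.0 * np.exp(-0.8 * t))
        s_hat = []
        for _ in range(300):
            f_obs = rng.binomial(200, f_true) / 200.0
            s_hat.append(fit_snp_selection(self.traj(t, f_obs)).s)
        assert np.median(s_hat) == pytest.approx(0.8, rel=0.10)

    def test_frequency_filter(self):
        keep = self.traj([0.0, 2.0], [0.01, 0.06])
        drop = self.traj([0.0, 2.0], [0.01, 0.049])
        out = filter_snp_trajectories([keep, drop])
        assert out == [keep]


class TestParallelism:
    def test_uniform_vector_has_zero_distance(self):
        res = parallelism({"g1": [0.5] * 7, "g2": [0.9, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1]})
        by_gene = {r.gene: r for r in res}
        assert by_gene["g1"].lambda_star == pytest.approx(0.5)
        assert by_gene["g1"].P == pytest.approx(0.0, abs=1e-12)

    def test_single_dose_spike_closed_form(self):
        res = parallelism({"g": [1.0, 0, 0, 0, 0, 0, 0]}, cross_check=True)
        assert res[0].lambda_star == pytest.approx(1.0 / 7.0)
        assert res[0].P == pytest.approx(math.sqrt(6.0 / 7.0), rel=1e-9)

    def test_maximal_gene_has_unit_coefficient(self):
        res = parallelism(
            {"a": [1.0, 0, 0, 0, 0, 0, 0], "b": [0.3, 0.3, 0.3, 0.25, 0.3, 0.3, 0.3]}
        )
        by_gene = {r.gene: r for r in res}
        assert by_gene["a"].p_coeff == pytest.approx(1.0)
        assert by_gene["a"].parallel_flag
        assert by_gene["b"].p_coeff < 0.5

    def test_closed_form_matches_numeric_minimizer(self):
        rng = np.random.default_rng(21)
        vecs = {f"g{i}": rng.uniform(0.0, 1.0, 7) for i in range(20)}
        parallelism(vecs, cross_check=True)  # raises if the check fails

    def test_low_frequency_genes_excluded(self):
        res = parallelism({"rare": [0.01] * 7, "common": [0.5] * 7})
        assert {r.gene for r in res} == {"common"}
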