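import numpy as np
import pytest
from scipy.stats import chi2

from mpspec import (
    ClassLabel,
    FingerprintFeatures,
    SampleRecord,
    add_noise,
    calibrate,
    classify,
    compute_lod,
    correct_quantification,
    extract_features,
    extract_harmonics,
    fit_region,
    generate_blanks,
    generate_reference_signals,
    get_preset,
    mix_signals,
    simulate_contaminant,
    synthesize_template,
)
from mpspec.signal_model import DEFAULT_NOISE_SD
from mpspec._rng import substream


def spectrum_for(cfg, preset, a3):
    return extract_harmonics(synthesize_template(cfg, preset, a3))


def reference_region(cfg, vsop, lod, n=60, seed=0, quantile=0.99):
    refs = generate_reference_signals(cfg, vsop, n=n, seed=seed)
    feats = [extract_features(extract_harmonics(s), lod5=lod.lod) for s in refs]
    return fit_region(feats, quantile=quantile)


class TestExtractFeatures:
    def test_vsop_and_mcp_coordinates(self, cfg, vsop, mcp):
        f = extract_features(spectrum_for(cfg, vsop, 1e-10))
        assert f.r53 == pytest.approx(0.10, rel=1e-9)
        assert f.phi3 == pytest.approx(-2.0, abs=1e-9)
        g = extract_features(spectrum_for(cfg, mcp, 1e-10))
        assert g.r53 == pytest.approx(0.30, rel=1e-9)
        assert g.phi3 == pytest.approx(-30.0, abs=1e-9)

    def test_censoring_when_a5_below_floor(self, cfg, vsop):
        sp = spectrum_for(cfg, vsop, 1e-10)  # A5 = 1e-11
        f = extract_features(sp, lod5=2e-12)
        assert not f.r53_censored
        g = extract_features(sp, lod5=2e-11)  # floor above A5
        assert g.r53_censored
        assert g.r53 == pytest.approx(2e-11 / 1e-10, rel=1e-9)

    def test_scale_invariance(self, cfg, endorem):
        f1 = extract_features(spectrum_for(cfg, endorem, 1e-10))
        f2 = extract_features(spectrum_for(cfg, endorem, 7e-9))
        assert f1.r53 == pytest.approx(f2.r53, rel=1e-9)
        assert f1.phi3 == pytest.approx(f2.phi3, abs=1e-6)

    def test_scaled_spectrum_has_identical_features(self, cfg, vsop):
        sp = spectrum_for(cfg, vsop, 1e-10)
        f1 = extract_features(sp)
        f2 = extract_features(sp.scaled(13.7))
        assert f1.r53 == pytest.approx(f2.r53, rel=1e-12)
        assert f1.phi3 == f2.phi3


class TestFitRegion:
    def test_chi2_threshold_at_99_percent(self):
        pts = [
            FingerprintFeatures(0.10 + dx, -2.0 + dp)
            for dx, dp in [(0.01, 0), (-0.01, 0), (0, 1.0), (0, -1.0),
                           (0.005, 0.5), (-0.005, -0.5)]
        ]
        region = fit_region(pts, quantile=0.99)
        assert region.md2_threshold == pytest.approx(9.210, abs=1e-3)
        assert region.md2_threshold == pytest.approx(chi2.ppf(0.99, 2), rel=1e-12)

    def test_centroid_of_symmetric_cloud(self):
        pts = [
            FingerprintFeatures(0.10 + dx, -2.0 + dp)
            for dx, dp in [(0.02, 1.0), (-0.02, -1.0), (0.02, -1.0), (-0.02, 1.0)]
        ]
        region = fit_region(pts)
        assert region.centroid[0] == pytest.approx(0.10, rel=1e-9)
        assert region.centroid[1] == pytest.approx(-2.0, rel=1e-9)

    def test_degenerate_reference_rejected(self):
        two = [FingerprintFeatures(0.1, -2.0), FingerprintFeatures(0.2, -3.0)]
        with pytest.raises(ValueError):
            fit_region(two)
        collinear = [FingerprintFeatures(0.1 * k, -2.0 * k) for k in (1, 2, 3, 4)]
        with pytest.raises(ValueError, match="singular|collinear"):
            fit_region(collinear)

    def test_censored_points_excluded_with_warning(self):
        pts = [
            FingerprintFeatures(0.10 + dx, -2.0 + dp)
            for dx, dp in [(0.01, 0.3), (-0.01, 0.2), (0.0, 1.0), (0.003, -1.0)]
        ] + [FingerprintFeatures(0.4, -2.0, r53_censored=True)]
        with pytest.warns(UserWarning, match="censored"):
            region = fit_region(pts)
        assert region.n_reference == 4


class TestClassify:
    def test_centroid_is_target_and_lod_gate_first(self, cfg, vsop, lod):
        region = reference_region(cfg, vsop, lod)
        sp = spectrum_for(cfg, vsop, 1e-9)
        assert classify(sp, region, lod) is ClassLabel.target_MNP
        low = spectrum_for(cfg, vsop, 0.5 * lod.lod)
        assert classify(low, region, lod) is ClassLabel.below_LOD

    def test_mcp_signature_rejected_by_vsop_region(self, cfg, vsop, mcp, lod):
        region = reference_region(cfg, vsop, lod)
        sp = spectrum_for(cfg, mcp, 1e-9)  # (0.30, -30 deg)
        assert classify(sp, region, lod) is ClassLabel.contaminated

    def test_coverage_matches_nominal_quantile(self, cfg, vsop, lod):
        # with a large reference set the chi-square(2) ellipse at q = 0.99
        # must accept a fraction of fresh same-law replicates within
        # binomial 99% bounds of q
        region = reference_region(cfg, vsop, lod, n=500, seed=3)
        fresh = generate_reference_signals(cfg, vsop, n=1000, seed=1234)
        labels = [classify(extract_harmonics(s), region, lod) for s in fresh]
        frac = np.mean([l is ClassLabel.target_MNP for l in labels])
        q, n = 0.99, 1000
        bound = 2.576 * np.sqrt(q * (1 - q) / n)
        assert abs(frac - q) <= bound

    def test_contaminant_prior_mostly_rejected(self, cfg, vsop, lod, contaminant):
        region = reference_region(cfg, vsop, lod)
        n_above, n_rejected = 0, 0
        for i in range(200):
            sig = simulate_contaminant(cfg, contaminant, seed=i)
            sig = add_noise(sig, DEFAULT_NOISE_SD, substream(900, "c", i))
            sp = extract_harmonics(sig)
            if sp.amplitude(3) >= lod.lod:
                n_above += 1
                if classify(sp, region, lod) is ClassLabel.contaminated:
                    n_rejected += 1
        assert n_above > 150
        assert n_rejected / n_above >= 0.95

    def test_mixture_distance_monotone_in_contaminant_fraction(
        self, cfg, vsop, lod, contaminant
    ):
        region = reference_region(cfg, vsop, lod)
        tracer = synthesize_template(cfg, vsop, 1e-9)
        cont = simulate_contaminant(cfg, contaminant, seed=4)
        cont_unit = cont.with_samples(
            cont.samples / extract_harmonics(cont).amplitude(3) * 1e-9
        )
        md2s = []
        for frac in (0.0, 0.05, 0.1, 0.2, 0.4, 0.8):
            mixed = tracer.with_samples(
                (1 - frac) * tracer.samples + frac * cont_unit.samples
            )
            feats = extract_features(extract_harmonics(mixed), lod5=lod.lod)
            md2s.append(region.md2(feats))
        assert np.all(np.diff(md2s) > 0)
        assert md2s[0] <= region.md2_threshold  # pure tracer accepted


class TestCorrectQuantification:
    def _cal(self, cfg, vsop):
        return calibrate(spectrum_for(cfg, vsop, 20.0 * 1e-9), 1e-9)

    def test_constructed_exclusion_count_five_of_ten(
        self, cfg, vsop, lod, contaminant
    ):
        region = reference_region(cfg, vsop, lod)
        cal = self._cal(cfg, vsop)
        records = []
        for i in range(10):
            if i < 5:
                sig = simulate_contaminant(cfg, contaminant, seed=100 + i)
            else:
                sig = synthesize_template(cfg, vsop, 1e-9)
            rec = SampleRecord(
                sample_id=f"COL-{i}", treatment="PBS", model="healthy_WT",
                organ="COL", spectrum=extract_harmonics(sig),
            )
            records.append(rec)
        _, exclusions = correct_quantification(records, region, cal, lod)
        row = exclusions.iloc[0]
        assert (row.n_excluded, row.n_total) == (5, 10)

    def test_below_lod_records_not_quantified_not_contaminated(
        self, cfg, vsop, lod
    ):
        region = reference_region(cfg, vsop, lod)
        cal = self._cal(cfg, vsop)
        records = [
            SampleRecord(
                sample_id=f"b{i}", organ="KID",
                spectrum=spectrum_for(cfg, vsop, 0.3 * lod.lod),
            )
            for i in range(4)
        ]
        recs, exclusions = correct_quantification(records, region, cal, lod)
        assert all(r.label is ClassLabel.below_LOD for r in recs)
        assert all(np.isnan(r.fe_mass_kg) for r in recs)
        assert exclusions.n_excluded.sum() == 0

    def test_strong_pure_tracer_records_all_quantified(self, cfg, vsop, lod):
        region = reference_region(cfg, vsop, lod)
        cal = self._cal(cfg, vsop)
        records = []
        for i in range(20):
            rng = substream(55, "t", i)
            pert = vsop.perturbed(rng.normal(0, 1.5), np.exp(rng.normal(0, 0.08)))
            # amplitude within the reference law's range, so feature noise
            # is small against the environmental scatter the region models
            sig = add_noise(
                synthesize_template(cfg, pert, 100 * lod.lod), DEFAULT_NOISE_SD, rng
            )
            records.append(
                SampleRecord(sample_id=f"t{i}", organ="LIV",
                             spectrum=extract_harmonics(sig))
            )
        recs, _ = correct_quantification(records, region, cal, lod)
        quantified = sum(r.label is ClassLabel.target_MNP for r in recs)
        assert quantified >= 19
        for r in recs:
            if r.label is ClassLabel.target_MNP:
                assert np.isfinite(r.fe_mass_kg)

    def test_missing_spectrum_rejected(self, cfg, vsop, lod):
        region = reference_region(cfg, vsop, lod)
        cal = self._cal(cfg, vsop)
        with pytest.raises(ValueError, match="no analyzed spectrum"):
            correct_quantification([SampleRecord(sample_id="x")], region, cal, lod)
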