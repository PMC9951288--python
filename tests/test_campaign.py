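"""Campaign orchestration: libraries, calibration curves, assignment."""

import numpy as np
import pytest

from dadkit.campaign import (Campaign, CompoundEntry, QuantCurve,
                             fit_quant_curve, quantify_peak)
from dadkit.io import RunMeta
from dadkit.purity import pearson_similarity
from dadkit.simulate import (SimCompound, default_time_grid,
                             default_wavelength_grid, make_spectrum, simulate)

T = default_time_grid()
WL = default_wavelength_grid()

MAIN_BANDS = [(230.0, 18.0, 1.0), (272.0, 14.0, 0.55)]
ISTD_BANDS = [(250.0, 12.0, 1.0), (340.0, 20.0, 0.8)]
OTHER_BANDS = [(305.0, 22.0, 1.0)]


def sim_run(run_id, compounds, run_type="sample", compound=None,
            concentration=None, istd=False, istd_concentration=None,
            seed=0, noise_sd=0.05, drift=1.0):
    meta = RunMeta(run_id=run_id, run_type=run_type, compound=compound,
                   concentration=concentration, istd=istd,
                   istd_concentration=istd_concentration)
    chrom, truth = simulate(compounds, T, WL, noise_sd=noise_sd, drift=drift,
                            seed=seed, meta=meta)
    return chrom, truth


def main_compound(conc, rt=0.45, rf=20.0):
    return SimCompound("main", MAIN_BANDS, rt, 0.015, 0.004, rf * conc)


def istd_compound(rt=0.25, area=15.0):
    return SimCompound("istd", ISTD_BANDS, rt, 0.015, 0.0, area)


class TestRegister:
    def test_sample_with_minimal_meta_accepted(self):
        camp = Campaign()
        chrom, _ = sim_run("s1", [main_compound(1.0)])
        camp.register_run(chrom)
        assert len(camp.runs) == 1

    def test_calibration_without_concentration_rejected(self):
        camp = Campaign()
        chrom, _ = sim_run("c1", [main_compound(1.0)], run_type="calibration",
                           compound="main", concentration=None)
        with pytest.raises(ValueError):
            camp.register_run(chrom)

    def test_duplicate_run_id_rejected(self):
        camp = Campaign()
        chrom, _ = sim_run("dup", [main_compound(1.0)])
        camp.register_run(chrom)
        with pytest.raises(ValueError):
            camp.register_run(chrom.copy_with())


class TestBuildLibrary:
    def test_single_run_library_spectrum_matches_truth(self):
        camp = Campaign()
        chrom, truth = sim_run("c1", [main_compound(1.0)],
                               run_type="calibration", compound="main",
                               concentration=1.0, seed=1)
        camp.register_run(chrom)
        camp.build_library()
        entry = camp.library.entries["main"]
        r = pearson_similarity(entry.spectrum, truth.compounds[0]["spectrum"])
        assert r > 0.999
        assert abs(entry.ref_time - 0.45) < 0.01

    def test_linear_detector_gives_proportional_areas(self):
        camp = Campaign()
        for i, conc in enumerate((1.0, 2.0)):
            chrom, _ = sim_run(f"c{i}", [main_compound(conc)],
                               run_type="calibration", compound="main",
                               concentration=conc, seed=10 + i)
            camp.register_run(chrom)
        camp.build_library()
        points = camp.library.entries["main"].calibration_points
        areas = {conc: area for area, conc, _, _ in points}
        assert areas[2.0] / areas[1.0] == pytest.approx(2.0, rel=0.01)

    def test_saturated_only_peak_rejected(self):
        camp = Campaign()
        # area large enough that single-wavelength cells exceed 2000 mAU
        big = SimCompound("main", MAIN_BANDS, 0.45, 0.015, 0.0, 5000.0)
        chrom, _ = sim_run("c1", [big], run_type="calibration",
                           compound="main", concentration=1.0, seed=2)
        camp.register_run(chrom)
        with pytest.raises(ValueError):
            camp.build_library()


def istd_campaign(sample_drift_min=0.0, seed=50):
    """Campaign with an internal standard plus a main compound."""
    camp = Campaign()
    chrom, _ = sim_run("cal_istd", [istd_compound()], run_type="calibration",
                       compound="istd", concentration=1.0, istd=True, seed=seed)
    camp.register_run(chrom)
    for i, conc in enumerate((0.5, 1.0, 2.0)):
        chrom, _ = sim_run(
            f"cal_main_{i}", [main_compound(conc), istd_compound()],
            run_type="calibration", compound="main", concentration=conc,
            istd_concentration=1.0, seed=seed + 1 + i)
        camp.register_run(chrom)
    sample, _ = sim_run(
        "sample", [main_compound(1.3, rt=0.45 + sample_drift_min),
                   istd_compound(rt=0.25 + sample_drift_min)],
        istd_concentration=1.0, seed=seed + 10)
    camp.register_run(sample)
    return camp, sample


class TestRetentionCorrection:
    def test_no_drift_zero_shift(self):
        camp, sample = istd_campaign(sample_drift_min=0.0)
        camp.build_library()
        record = camp.process_run(sample)
        assert abs(record.rt_shift) <= 0.002  # within one time step

    def test_drift_recovered(self):
        camp, sample = istd_campaign(sample_drift_min=0.05)
        camp.build_library()
        record = camp.process_run(sample)
        assert record.rt_shift == pytest.approx(-0.05, abs=0.001)
        # the drifted main peak is still assigned thanks to the correction
        assert any(p.assignment == "main" for p in record.peaks)

    def test_missing_istd_flagged(self):
        camp, _ = istd_campaign()
        camp.build_library()
        lone, _ = sim_run("lonely", [main_compound(1.0)], seed=99)
        record = camp.process_run(lone)
        assert "istd_missing" in record.flags


class TestQuantCurve:
    def entry_with_points(self, points):
        spec = make_spectrum(MAIN_BANDS, WL)
        return CompoundEntry(compound_id="x", spectrum=spec, ref_time=0.45,
                             calibration_points=points)

    def test_exact_line_through_origin(self):
        pts = [(5.0 * c, c, None, None) for c in (1.0, 2.0, 3.0)]
        curve = fit_quant_curve(self.entry_with_points(pts))
        assert curve.slope == pytest.approx(5.0)
        assert curve.r_squared == pytest.approx(1.0)

    def test_single_point(self):
        curve = fit_quant_curve(self.entry_with_points([(10.0, 2.0, None, None)]))
        assert curve.slope == pytest.approx(5.0)

    def test_noisy_slope_recovery(self):
        # distributional check of the estimator: with 2% multiplicative
        # area noise on 5 levels the slope error is typically ~1.6% (the
        # top level dominates the x^2 weighting)
        concs = np.array([0.2, 0.5, 1.0, 2.0, 4.0])
        errors = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            areas = 20.0 * concs * (1 + rng.normal(0, 0.02, concs.size))
            pts = [(a, c, None, None) for a, c in zip(areas, concs)]
            curve = fit_quant_curve(self.entry_with_points(pts))
            errors.append(abs(curve.slope - 20.0) / 20.0)
        assert np.median(errors) < 0.03
        assert np.mean(np.asarray(errors) < 0.03) >= 0.8

    def test_relative_mode(self):
        pts = [(8.0, 2.0, 10.0, 1.0), (4.0, 1.0, 10.0, 1.0)]
        curve = fit_quant_curve(self.entry_with_points(pts), mode="relative")
        assert curve.mode == "relative"
        assert curve.slope == pytest.approx(0.4)

    def test_nonpositive_areas_dropped(self):
        pts = [(0.0, 1.0, None, None), (10.0, 2.0, None, None)]
        with pytest.warns(UserWarning):
            curve = fit_quant_curve(self.entry_with_points(pts))
        assert curve.n_points == 1

    def test_quantify_absolute(self):
        curve = QuantCurve(compound_id="x", mode="absolute", slope=5.0,
                           r_squared=1.0, n_points=3)
        assert quantify_peak(10.0, curve) == pytest.approx(2.0)

    def test_quantify_relative(self):
        curve = QuantCurve(compound_id="x", mode="relative", slope=0.4,
                           r_squared=1.0, n_points=3)
        conc = quantify_peak(8.0, curve, istd_area=10.0, istd_concentration=1.0)
        assert conc == pytest.approx(2.0)


class TestAssignment:
    def build_campaign(self):
        camp = Campaign()
        for i, conc in enumerate((1.0, 2.0)):
            chrom, _ = sim_run(f"cal{i}", [main_compound(conc)],
                               run_type="calibration", compound="main",
                               concentration=conc, seed=30 + i)
            camp.register_run(chrom)
        camp.build_library()
        return camp

    def test_matching_peak_assigned_and_quantified(self):
        camp = self.build_campaign()
        chrom, _ = sim_run("s", [main_compound(1.5)], seed=40)
        record = camp.process_run(chrom)
        main = [p for p in record.peaks if p.assignment == "main"]
        assert len(main) == 1
        assert main[0].concentration == pytest.approx(1.5, rel=0.03)

    def test_retention_window_rule(self):
        camp = self.build_campaign()
        # same spectrum, 0.3 min away from the library retention time
        chrom, _ = sim_run("s", [main_compound(1.0, rt=0.75)], seed=41)
        record = camp.process_run(chrom)
        assert all(p.assignment != "main" for p in record.peaks)
        assert any((p.assignment or "").startswith("unknown_")
                   for p in record.peaks)

    def test_unknown_id_stable_across_runs(self):
        camp = self.build_campaign()
        other = SimCompound("other", OTHER_BANDS, 0.7, 0.015, 0.0, 12.0)
        ids = []
        for i in range(3):
            chrom, _ = sim_run(f"s{i}", [main_compound(1.0), other],
                               seed=60 + i)
            record = camp.process_run(chrom)
            unknowns = {p.assignment for p in record.peaks
                        if (p.assignment or "").startswith("unknown_")}
            assert len(unknowns) == 1
            ids.append(unknowns.pop())
        assert len(set(ids)) == 1

    def test_unknown_grouping_order_independent(self):
        other = SimCompound("other", OTHER_BANDS, 0.7, 0.015, 0.0, 12.0)
        runs = []
        for i in range(3):
            chrom, _ = sim_run(f"s{i}", [main_compound(1.0), other], seed=70 + i)
            runs.append(chrom)
        groupings = []
        for order in ([0, 1, 2], [2, 1, 0]):
            camp = self.build_campaign()
            assignment = {}
            for idx in order:
                record = camp.process_run(runs[idx])
                for p in record.peaks:
                    if (p.assignment or "").startswith("unknown_"):
                        assignment.setdefault(p.assignment, set()).add(record.run_id)
            groupings.append(sorted(frozenset(v) for v in assignment.values()))
        assert groupings[0] == groupings[1]


class TestProcessRun:
    def test_blank_run_empty_record(self):
        camp = Campaign()
        meta = RunMeta(run_id="blank", run_type="blank")
        chrom, _ = simulate([], T, WL, noise_sd=0.05, drift=1.0, seed=5,
                            meta=meta)
        record = camp.process_run(chrom)
        assert record.peaks == []

    def test_overlapped_run_yields_deconvolved_main(self):
        camp = Campaign()
        for i, conc in enumerate((1.0, 2.0)):
            chrom, _ = sim_run(f"cal{i}", [main_compound(conc)],
                               run_type="calibration", compound="main",
                               concentration=conc, seed=80 + i)
            camp.register_run(chrom)
        camp.build_library()
        overlap = SimCompound("other", OTHER_BANDS, 0.48, 0.015, 0.0, 20.0)
        chrom, _ = sim_run("s", [main_compound(1.0), overlap], seed=90)
        record = camp.process_run(chrom)
        comps = [c for p in record.peaks for c in p.components]
        main = [c for c in comps if c.assignment == "main"]
        assert len(main) == 1
        assert main[0].concentration == pytest.approx(1.0, rel=0.10)


class TestProcessCampaign:
    def test_empty_campaign(self):
        result = Campaign().process_campaign()
        assert result.records == []
        assert result.table.empty

    def test_two_calibrations_one_sample(self):
        camp = Campaign()
        for i, conc in enumerate((1.0, 2.0)):
            chrom, _ = sim_run(f"cal{i}", [main_compound(conc)],
                               run_type="calibration", compound="main",
                               concentration=conc, seed=100 + i)
            camp.register_run(chrom)
        sample, _ = sim_run("s", [main_compound(0.8)], seed=110)
        camp.register_run(sample)
        result = camp.process_campaign()
        rows = result.table
        got = rows[(rows["run"] == "s") & (rows["compound"] == "main")]
        assert len(got) == 1
        assert got["concentration"].iloc[0] == pytest.approx(0.8, rel=0.03)
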