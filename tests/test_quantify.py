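"""XIC extraction, peak detection and gating, normalization, fold changes."""

import numpy as np
import pytest

import phuscreen as ps
from phuscreen.quantify import (
    STATUS_ABSENT,
    STATUS_BLQ,
    STATUS_QUANTIFIED,
    FoldChange,
    NormalizationError,
    PeakQuant,
    XIC,
    detect_peak,
    extract_xic,
    fold_change,
    match_across_runs,
    normalization_factor,
)
from phuscreen.synthetic_data import (
    Group,
    PeptideSpec,
    RunSpec,
    apex_for_scan_count,
    gaussian_peak_area,
)
from phuscreen.triage import LibraryEntry


def _entry(mz=500.0, rt=10.0, acc="X", is_standard=False):
    return LibraryEntry(acc, "AAAK", 2, mz, rt, "PRIMARY", is_standard=is_standard)


def _scan(t, mzs, intens):
    return {"time": t, "mz": np.asarray(mzs, float), "intensity": np.asarray(intens, float)}


def _xic(times, intens, entry=None):
    return XIC("r", entry or _entry(), np.asarray(times, float), np.asarray(intens, float))


def _quant(acc, status, rt=10.0, norm_area=None, is_standard=False):
    return PeakQuant("r", acc, status, rt_apex=rt, normalized_area=norm_area,
                     rt_expected=10.0, is_standard=is_standard)


class TestExtractXic:
    def test_ppm_boundary_inclusive_at_5(self):
        target = 500.0
        half = target * 5.0 * 1e-6
        scans = [_scan(0.0, [target + half], [123.0])]
        xic = extract_xic(scans, _entry(mz=target), ppm_tol=5.0)
        assert xic.intensities[0] == 123.0

    def test_six_ppm_offset_excluded(self):
        scans = [_scan(0.0, [500.0 * (1 + 6e-6)], [123.0])]
        xic = extract_xic(scans, _entry(), ppm_tol=5.0)
        assert xic.intensities[0] == 0.0

    def test_empty_scan_list_gives_empty_xic(self):
        xic = extract_xic([], _entry())
        assert xic.times.size == 0 and xic.intensities.size == 0

    def test_centroids_within_window_are_summed(self):
        scans = [_scan(0.0, [499.999, 500.0, 500.001], [10.0, 20.0, 30.0])]
        xic = extract_xic(scans, _entry(), ppm_tol=5.0)
        assert xic.intensities[0] == 60.0


class TestDetectPeak:
    def test_flat_zero_xic_is_absent(self):
        q = detect_peak(_xic(np.arange(20) * 0.1, np.zeros(20)), rt_expected=1.0)
        assert q.status == STATUS_ABSENT and q.scans_across_peak == 0

    @pytest.mark.parametrize("k,status", [(7, STATUS_BLQ), (8, STATUS_QUANTIFIED)])
    def test_scans_across_peak_reliability_boundary(self, k, status):
        times = np.arange(40) * 0.05
        rt = 1.0 + 0.3 * 0.05
        apex = apex_for_scan_count(k, 0.2, rt, 0.05, times[-1], 1e3)
        sigma = 0.2 / 2.3548200450309493
        intens = apex * np.exp(-((times - rt) ** 2) / (2 * sigma**2))
        intens[intens < 1e3] = 0.0
        q = detect_peak(_xic(times, intens), rt_expected=rt, noise_floor=1e3)
        assert q.scans_across_peak == k
        assert q.status == status

    def test_area_matches_analytic_gaussian_within_5pct(self):
        times = np.arange(0, 20, 0.02)
        sigma = 0.2 / 2.3548200450309493
        intens = 1e6 * np.exp(-((times - 10.0) ** 2) / (2 * sigma**2))
        q = detect_peak(_xic(times, intens), rt_expected=10.0, noise_floor=10.0)
        assert q.status == STATUS_QUANTIFIED
        assert q.area == pytest.approx(gaussian_peak_area(1e6, 0.2), rel=0.05)

    def test_peak_outside_rt_tolerance_is_absent(self):
        times = np.arange(0, 20, 0.05)
        sigma = 0.2 / 2.3548200450309493
        intens = 1e6 * np.exp(-((times - 12.0) ** 2) / (2 * sigma**2))
        q = detect_peak(_xic(times, intens), rt_expected=10.0, rt_tol=0.5, noise_floor=1e3)
        assert q.status == STATUS_ABSENT

    def test_nearest_peak_to_expected_rt_wins(self):
        # two peaks inside the window; the apex closer to rt_expected is kept
        times = np.arange(0, 20, 0.05)
        sigma = 0.1 / 2.3548200450309493
        intens = 5e5 * np.exp(-((times - 9.8) ** 2) / (2 * sigma**2))
        intens += 5e5 * np.exp(-((times - 10.45) ** 2) / (2 * sigma**2))
        q = detect_peak(_xic(times, intens), rt_expected=9.9, rt_tol=0.6, noise_floor=1e3)
        assert abs(q.rt_apex - 9.8) < 0.1

    def test_raising_min_scans_never_promotes_blq(self):
        times = np.arange(40) * 0.05
        rt = 1.0 + 0.3 * 0.05
        sigma = 0.2 / 2.3548200450309493
        apex = apex_for_scan_count(9, 0.2, rt, 0.05, times[-1], 1e3)
        intens = apex * np.exp(-((times - rt) ** 2) / (2 * sigma**2))
        intens[intens < 1e3] = 0.0
        statuses = [
            detect_peak(_xic(times, intens), rt_expected=rt, noise_floor=1e3,
                        min_scans=m).status
            for m in range(1, 15)
        ]
        # QUANTIFIED while min_scans <= 9, BLQ after; never flips back
        assert statuses == [STATUS_QUANTIFIED] * 9 + [STATUS_BLQ] * 5


class TestNormalization:
    def _is_quant(self, area):
        return PeakQuant("r", "IS_X", STATUS_QUANTIFIED, rt_apex=1.0, area=area,
                         scans_across_peak=10, is_standard=True)

    def test_factor_is_median_of_is_areas(self):
        quants = [self._is_quant(a) for a in (9.0, 10.0, 11.0)]
        assert normalization_factor(quants) == 10.0

    def test_single_is_peptide_defines_factor(self):
        assert normalization_factor([self._is_quant(42.0)]) == 42.0

    def test_no_quantified_is_raises(self):
        blq = PeakQuant("r", "IS_X", STATUS_BLQ, is_standard=True)
        with pytest.raises(NormalizationError):
            normalization_factor([blq])

    @pytest.mark.parametrize("c", [0.1, 3.7])
    def test_scale_invariance_of_normalized_ratios(self, study, c):
        """Multiplying every centroid intensity of one run by c>0 leaves all
        normalized areas unchanged (IS normalization property)."""
        scans = ps.read_ms1(study.mzml_high)
        scaled = [
            {"time": s["time"], "mz": s["mz"], "intensity": s["intensity"] * c}
            for s in scans
        ]
        quants = ps.quantify_run(scaled, study.bundle.library, run_id="high-scaled")
        base = study.bundle.quant_high
        for acc, q in quants.items():
            assert q.status == base[acc].status
            if q.normalized_area is not None:
                assert q.normalized_area == pytest.approx(base[acc].normalized_area, rel=1e-9)


class TestMatchingAndFoldChange:
    def test_apexes_within_one_minute_match(self):
        pairs = match_across_runs(
            {"X": _quant("X", STATUS_QUANTIFIED, rt=10.0, norm_area=5.0)},
            {"X": _quant("X", STATUS_QUANTIFIED, rt=10.8, norm_area=5.0)},
        )
        qn, qh = pairs["X"]
        assert qn.status == qh.status == STATUS_QUANTIFIED

    def test_apexes_beyond_tolerance_demote_farther_peak(self):
        pairs = match_across_runs(
            {"X": _quant("X", STATUS_QUANTIFIED, rt=10.0, norm_area=5.0)},
            {"X": _quant("X", STATUS_QUANTIFIED, rt=11.3, norm_area=5.0)},
        )
        qn, qh = pairs["X"]
        assert qn.status == STATUS_QUANTIFIED
        assert qh.status == STATUS_ABSENT  # 11.3 is farther from expected 10.0

    def test_identical_runs_match_with_zero_rt_difference(self, study):
        pairs = match_across_runs(study.bundle.quant_normal, study.bundle.quant_normal)
        for qn, qh in pairs.values():
            assert qn.status == qh.status

    def test_quantified_ratio_and_direction(self):
        fc = fold_change((
            _quant("X", STATUS_QUANTIFIED, norm_area=20.0),
            _quant("X", STATUS_QUANTIFIED, norm_area=50.0),
        ))
        assert fc.ratio == pytest.approx(2.5)
        assert fc.direction is Group.HIGH and not fc.pseudo

    def test_blq_on_one_side_grants_pseudo_100(self):
        qn = PeakQuant("r", "X", STATUS_BLQ, rt_apex=10.0, scans_across_peak=2)
        qh = _quant("X", STATUS_QUANTIFIED, norm_area=50.0)
        fc = fold_change((qn, qh))
        assert fc.ratio == 100.0 and fc.pseudo and fc.direction is Group.HIGH

    def test_equal_areas_tie_to_normal(self):
        fc = fold_change((
            _quant("X", STATUS_QUANTIFIED, norm_area=5.0),
            _quant("X", STATUS_QUANTIFIED, norm_area=5.0),
        ))
        assert fc.ratio == 1.0 and fc.direction is Group.NORMAL

    def test_both_unquantifiable_emits_nothing(self):
        qn = PeakQuant("r", "X", STATUS_BLQ, rt_apex=10.0, scans_across_peak=2)
        qh = PeakQuant("r", "X", STATUS_ABSENT)
        assert fold_change((qn, qh)) is None


class TestPipelineLevelProperties:
    def test_group_label_swap_inverts_directions(self, study):
        fcs = ps.compute_fold_changes(study.bundle.quant_normal, study.bundle.quant_high)
        swapped = ps.compute_fold_changes(study.bundle.quant_high, study.bundle.quant_normal)
        fwd = {fc.accession: fc for fc in fcs}
        rev = {fc.accession: fc for fc in swapped}
        assert set(fwd) == set(rev)
        for acc in fwd:
            assert rev[acc].ratio == pytest.approx(fwd[acc].ratio)
            if fwd[acc].ratio > 1.0:
                assert rev[acc].direction is fwd[acc].direction.other()

    @pytest.mark.parametrize("seed", [1, 5, 9])
    def test_fold_change_recovery_within_15pct(self, seed, tmp_path_factory):
        from conftest import build_and_run

        fx = build_and_run(seed, tmp_path_factory.mktemp("recovery"))
        truth = {p.accession: (p.true_fold_change, p.direction)
                 for p in fx.manifest.proteins}
        checked = 0
        for fc in fx.bundle.fold_changes:
            if fc.pseudo:
                continue
            true_fc, true_dir = truth[fc.accession]
            assert fc.ratio == pytest.approx(true_fc, rel=0.15), fc.accession
            if true_fc > 1.2:
                assert fc.direction is true_dir, fc.accession
            checked += 1
        assert checked == 30  # 36 candidates minus 2 absent minus 4 BLQ-pseudo
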