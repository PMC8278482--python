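"""Generator correctness: Gaussian peaks, mzML round trip, fixture structure."""

import numpy as np
import pytest

import phuscreen as ps
from phuscreen.synthetic_data import (
    Group,
    PeptideSpec,
    RunSpec,
    ValidationError,
    expected_scan_count,
    apex_for_scan_count,
    gaussian_peak_area,
)


def _run_spec(peptides, seed=0, noise_sigma=0.0, **kw):
    defaults = dict(
        run_id="r", group=Group.NORMAL, duration=20.0, scan_interval=0.05,
        noise_floor=1e3, seed=seed, noise_sigma=noise_sigma,
        is_peptides=[
            PeptideSpec(f"ISPEP{i}K", 2, 1100.0 + 10 * i, 15.0, 0.3, 5e5)
            for i in range(3)
        ],
    )
    defaults.update(kw)
    return RunSpec(peptides=peptides, **defaults)


class TestGenerateRun:
    def test_zero_apex_contributes_no_centroids(self):
        pep = PeptideSpec("AAAK", 2, 500.0, 10.0, 0.2, 0.0)
        spectra = ps.generate_run(_run_spec([pep]))
        assert not any(np.any(np.isclose(sp["mz"], 500.0)) for sp in spectra)

    def test_scan_count_matches_gaussian_closed_form(self):
        # apex 1e6, fwhm 0.2 min, floor 1e3: the profile crosses the floor at
        # |t-10| = sigma*sqrt(2 ln 1000) = 0.3157 min, so on the 0.05-min grid
        # the scans 9.70..10.30 qualify: 13 of them.
        pep = PeptideSpec("AAAK", 2, 500.0, 10.0, 0.2, 1e6)
        assert expected_scan_count(1e6, 0.2, 10.0, 0.05, 20.0, 1e3) == 13
        spectra = ps.generate_run(_run_spec([pep]))
        n = sum(1 for sp in spectra if np.any(np.isclose(sp["mz"], 500.0)))
        assert n == 13

    def test_identical_seed_gives_byte_identical_mzml(self, tmp_path):
        pep = PeptideSpec("AAAK", 2, 500.0, 10.0, 0.2, 1e6)
        paths = []
        for name in ("a.mzML", "b.mzML"):
            spec = _run_spec([pep], seed=42, noise_sigma=0.05)
            paths.append(ps.write_mzml(ps.generate_run(spec), tmp_path / name))
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_invalid_spec_names_field(self):
        pep = PeptideSpec("AAAK", 2, 500.0, 10.0, -1.0, 1e6)
        with pytest.raises(ValidationError, match="peak_fwhm"):
            ps.generate_run(_run_spec([pep]))
        with pytest.raises(ValidationError, match="scan_interval"):
            ps.generate_run(_run_spec([], scan_interval=-0.1))
        with pytest.raises(ValidationError, match="is_peptides"):
            ps.generate_run(_run_spec([], is_peptides=[]))

    @pytest.mark.parametrize("fwhm,interval", [(0.4, 0.05), (0.2, 0.025), (0.8, 0.1)])
    def test_noiseless_xic_area_matches_analytic_integral(self, fwhm, interval):
        # trapezoid of the generated trace vs A*sigma*sqrt(2 pi), interval <= fwhm/8
        pep = PeptideSpec("AAAK", 2, 500.0, 10.0, fwhm, 1e6)
        spec = _run_spec([pep], scan_interval=interval, noise_floor=1.0)
        times, intens = [], []
        for sp in ps.generate_run(spec):
            hits = np.isclose(sp["mz"], 500.0)
            times.append(sp["time"])
            intens.append(sp["intensity"][hits].sum() if hits.any() else 0.0)
        area = np.trapezoid(intens, times)
        assert area == pytest.approx(gaussian_peak_area(1e6, fwhm), rel=0.05)


class TestMzmlRoundTrip:
    def test_written_file_reads_back_ms1_intact(self, tmp_path):
        pep = PeptideSpec("AAAK", 2, 500.0, 10.0, 0.2, 1e6, ppm_offset=3.0)
        spec = _run_spec([pep], seed=7, noise_sigma=0.05)
        spectra = ps.generate_run(spec)
        scans = ps.read_ms1(ps.write_mzml(spectra, tmp_path / "r.mzML"))
        assert len(scans) == len(spectra)
        for orig, back in zip(spectra, scans):
            assert back["time"] == pytest.approx(orig["time"], abs=1e-6)
            np.testing.assert_allclose(back["mz"], orig["mz"])
            np.testing.assert_allclose(back["intensity"], orig["intensity"])

    def test_ms2_interleaved_file_equals_ms1_only_file_after_demux(self, tmp_path):
        pep = PeptideSpec("AAAK", 2, 500.0, 10.0, 0.2, 1e6)
        mixed = ps.generate_run(_run_spec([pep], seed=3, noise_sigma=0.05), include_ms2=True)
        plain = ps.generate_run(_run_spec([pep], seed=3, noise_sigma=0.05), include_ms2=False)
        assert any(sp["ms_level"] == 2 for sp in mixed)
        got = ps.read_ms1(ps.write_mzml(mixed, tmp_path / "mixed.mzML"))
        want = ps.read_ms1(ps.write_mzml(plain, tmp_path / "plain.mzML"))
        assert len(got) == len(want)
        for a, b in zip(got, want):
            np.testing.assert_allclose(a["intensity"], b["intensity"])


class TestIdentTables:
    def test_group_exclusive_protein_appears_only_in_its_table(self, study):
        tables = ps.generate_ident_tables(study.manifest)
        high_only = [p.accession for p in study.manifest.proteins if p.presence == "high-only"]
        assert set(high_only) <= set(tables[Group.HIGH]["accession"])
        assert not set(high_only) & set(tables[Group.NORMAL]["accession"])

    def test_table_counts_follow_manifest_set_arithmetic(self, study):
        tables = ps.generate_ident_tables(study.manifest)
        for g, key in ((Group.NORMAL, "normal-only"), (Group.HIGH, "high-only")):
            expect = sum(1 for p in study.manifest.proteins if p.presence in (key, "both"))
            assert tables[g]["accession"].nunique() == expect

    def test_empty_manifest_yields_header_only_tables(self):
        tables = ps.generate_ident_tables(ps.FixtureManifest(proteins=[], seed=0))
        for df in tables.values():
            assert len(df) == 0
            assert list(df.columns) == ps.synthetic_data.IDENT_COLUMNS

    def test_duplicate_accession_rejected(self, study):
        bad = ps.FixtureManifest(
            proteins=[study.manifest.proteins[0], study.manifest.proteins[0]], seed=0)
        with pytest.raises(ValidationError, match="duplicate"):
            ps.generate_ident_tables(bad)


class TestStudyFixture:
    def test_tier_union_is_36_candidates(self, study):
        counts = study.manifest.expected_counts()
        assert counts == {
            "primary": 30, "primary_high": 24, "primary_normal": 6,
            "secondary": 6, "candidates": 36, "certified": 26,
        }

    @pytest.mark.parametrize("seed", [2, 3, 11])
    def test_seed_moves_jitter_but_not_structure(self, seed, study):
        m2, rn2, _ = ps.build_study_fixture(seed)
        assert m2.expected_counts() == study.manifest.expected_counts()
        # jitter differs...
        rt1 = {p.accession: p.rt_by_group for p in study.manifest.proteins}
        assert any(rt1[p.accession] != p.rt_by_group for p in m2.proteins)
        # ...but tier/direction/pattern are fixed
        for p1, p2 in zip(study.manifest.proteins, m2.proteins):
            assert (p1.accession, p1.tier, p1.direction, p1.quant_pattern) == (
                p2.accession, p2.tier, p2.direction, p2.quant_pattern)

    def test_each_candidate_has_unique_proteotypic_peptide(self, study):
        for p in study.manifest.proteins:
            if p.tier is None:
                continue
            extra_scores = [row[4] for row in p.extra_peptides]
            assert all(s < p.ion_score for s in extra_scores)

    def test_blq_candidates_have_1_to_3_scan_support(self, study):
        weak = {"blq_normal": study.run_normal, "blq_high": study.run_high}
        n_blq = 0
        for p in study.manifest.proteins:
            if p.quant_pattern not in weak:
                continue
            run = weak[p.quant_pattern]
            pep = next(q for q in run.peptides if q.sequence == p.sequence)
            assert 1 <= pep.n_scans_above_noise <= 3
            n_blq += 1
        assert n_blq >= 2


class TestApexSolver:
    @pytest.mark.parametrize("k", [1, 2, 5, 8, 14])
    def test_solved_apex_gives_exact_scan_count(self, k):
        rt = 10.0 + 0.3 * 0.05  # off the grid symmetry point
        apex = apex_for_scan_count(k, 0.2, rt, 0.05, 20.0, 1e3)
        assert expected_scan_count(apex, 0.2, rt, 0.05, 20.0, 1e3) == k

    def test_symmetric_apex_position_is_rejected(self):
        with pytest.raises(ValidationError, match="equidistant"):
            apex_for_scan_count(2, 0.2, 10.0, 0.05, 20.0, 1e3)  # on-grid: ties
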