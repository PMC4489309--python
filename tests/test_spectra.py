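"""MGF round-trips, CSV output and observed-spectrum annotation."""

import csv

import numpy as np
import pytest

from ionforest import (
    ION_SERIES,
    ObservedSpectrum,
    Peptide,
    annotate,
    parse_peptide,
    read_mgf,
    theoretical_spectrum,
    write_csv,
    write_mgf,
)
from ionforest.ions import FragmentIon, iter_fragments
from ionforest.spectra import MGFError, observed_to_mgf


def _predicted(p, registry, charge=2):
    ions = [
        FragmentIon(i.series, i.ion_charge, i.index, i.mz, float(k + 1))
        for k, i in enumerate(iter_fragments(p, registry))
    ]
    return (p, charge, ions)


class TestMGF:
    def test_write_read_roundtrip(self, registry, tmp_path):
        p = parse_peptide("H-SAoxMPLE-OH", registry)
        q = parse_peptide("ace-PEPTIDEK-OH", registry)
        path = tmp_path / "pred.mgf"
        write_mgf([_predicted(p, registry, 2), _predicted(q, registry, 3)], registry, path)
        spectra = read_mgf(path)
        assert [s.title for s in spectra] == ["H-SAoxMPLE-OH", "ace-PEPTIDEK-OH"]
        assert [s.precursor_charge for s in spectra] == [2, 3]
        for s, peptide in zip(spectra, (p, q)):
            expected = sorted(ion.mz for ion in theoretical_spectrum(peptide, registry))
            np.testing.assert_allclose(s.mz, expected, atol=1e-6)
        # second round-trip is the identity
        out2 = tmp_path / "again.mgf"
        observed_to_mgf(spectra, out2)
        again = read_mgf(out2)
        for a, b in zip(spectra, again):
            assert a.title == b.title and a.precursor_charge == b.precursor_charge
            np.testing.assert_allclose(a.mz, b.mz)
            np.testing.assert_allclose(a.intensity, b.intensity)

    def test_title_and_charge_rendering(self, registry, tmp_path):
        p = parse_peptide("H-SAMPLE-OH", registry)
        path = tmp_path / "one.mgf"
        write_mgf([_predicted(p, registry, 2)], registry, path)
        text = path.read_text()
        assert "TITLE=H-SAMPLE-OH" in text
        assert "CHARGE=2+" in text

    def test_zero_pruning(self, registry, tmp_path):
        p = Peptide("SAMPLE")
        ions = [
            FragmentIon(i.series, i.ion_charge, i.index, i.mz, 0.0 if k % 2 else 1.0)
            for k, i in enumerate(iter_fragments(p, registry))
        ]
        keep, prune = tmp_path / "keep.mgf", tmp_path / "prune.mgf"
        write_mgf([(p, 2, ions)], registry, keep, keep_zeros=True)
        write_mgf([(p, 2, ions)], registry, prune, keep_zeros=False)
        assert len(read_mgf(keep)[0]) == 20
        assert len(read_mgf(prune)[0]) == 10

    def test_unsupported_charge_skipped_with_warning(self, registry, tmp_path):
        path = tmp_path / "mixed.mgf"
        path.write_text(
            "BEGIN IONS\nTITLE=a\nPEPMASS=400.0\nCHARGE=2+\n100.0 1.0\nEND IONS\n"
            "BEGIN IONS\nTITLE=b\nPEPMASS=400.0\nCHARGE=5+\n100.0 1.0\nEND IONS\n"
        )
        with pytest.warns(UserWarning, match="skipped 1"):
            spectra = read_mgf(path)
        assert [s.title for s in spectra] == ["a"]

    def test_empty_peak_list_block(self, registry, tmp_path):
        path = tmp_path / "empty.mgf"
        path.write_text(
            "BEGIN IONS\nTITLE=e\nPEPMASS=400.0\nCHARGE=2+\nEND IONS\n"
        )
        (s,) = read_mgf(path)
        assert len(s) == 0

    def test_malformed_block_names_line(self, registry, tmp_path):
        path = tmp_path / "bad.mgf"
        path.write_text(
            "BEGIN IONS\nTITLE=ok\nPEPMASS=400.0\nCHARGE=2+\n100.0 1.0\nEND IONS\n"
            "BEGIN IONS\nTITLE=bad\nPEPMASS=nonsense\nCHARGE=2+\n100.0 1.0\nEND IONS\n"
        )
        with pytest.raises(MGFError, match="line 7"):
            read_mgf(path)


class TestAnnotate:
    def test_exact_theoretical_peaks_equal_intensities(self, registry):
        p = Peptide("SAMPLE")
        ions = theoretical_spectrum(p, registry)
        s = ObservedSpectrum(
            "t", 2, 500.0, np.array([i.mz for i in ions]), np.full(len(ions), 7.0)
        )
        tv = annotate(p, s, registry)
        assert tv.pooled_matched().all()
        assert np.allclose(tv.pooled(), tv.pooled()[0])

    def test_no_peaks_in_tolerance(self, registry):
        p = Peptide("SAMPLE")
        s = ObservedSpectrum("t", 2, 500.0, np.array([5000.0, 6000.0]), np.array([1.0, 2.0]))
        tv = annotate(p, s, registry, tol=0.02)
        assert tv.n_matched() == 0
        assert np.allclose(tv.pooled(), tv.baseline)

    def test_most_intense_peak_wins(self, registry):
        """Against an exhaustive search oracle on a 5-peak toy spectrum."""
        p = Peptide("GG")
        target_mz = 58.02874018745  # b1
        toy_mz = np.array([57.9, 58.020, 58.033, 58.2, 76.04])
        toy_int = np.array([9.0, 3.0, 5.0, 8.0, 2.0])
        tol = 0.02
        # oracle: enumerate peaks within tol, take the most intense
        in_tol = [(m, i) for m, i in zip(toy_mz, toy_int) if abs(m - target_mz) <= tol]
        expected_raw = max(i for _, i in in_tol)
        assert expected_raw == 5.0  # two candidates, the more intense one
        s = ObservedSpectrum("t", 2, 100.0, toy_mz, toy_int)
        tv = annotate(p, s, registry, tol=tol)
        norm = expected_raw / toy_int.sum()
        assert tv.targets[("b", 1)][0] == pytest.approx(
            np.log2(norm + tv.epsilon), abs=1e-12
        )

    def test_matches_naive_recomputation_and_preserves_ranks(self, registry):
        """Full target vector agrees with a naive per-ion exhaustive search,
        and the strictly monotone transform preserves intensity ranks."""
        p = Peptide("SAMPLE")
        ions = theoretical_spectrum(p, registry)
        rng = np.random.default_rng(3)
        raw = rng.uniform(1.0, 100.0, len(ions))
        order = np.argsort([i.mz for i in ions])
        s = ObservedSpectrum(
            "t", 2, 500.0, np.array([i.mz for i in ions])[order], raw[order]
        )
        tol = 0.02
        tv = annotate(p, s, registry, tol=tol)
        tic = raw.sum()
        naive = []
        for series, z in ION_SERIES:
            for idx in range(1, len(p)):
                mz = next(
                    i.mz
                    for i in ions
                    if (i.series, i.ion_charge, i.index) == (series, z, idx)
                )
                cands = [x / tic for m, x in zip(s.mz, s.intensity) if abs(m - mz) <= tol]
                naive.append(np.log2(max(cands) + tv.epsilon) if cands else tv.baseline)
        np.testing.assert_allclose(tv.pooled(), naive, atol=1e-12)
        matched = tv.pooled()[tv.pooled_matched()]
        naive_matched = np.array(naive)[tv.pooled_matched()]
        assert np.array_equal(np.argsort(matched), np.argsort(naive_matched))

    def test_deterministic(self, registry):
        p = Peptide("SAMPLE")
        ions = theoretical_spectrum(p, registry)
        rng = np.random.default_rng(5)
        s = ObservedSpectrum(
            "t", 2, 500.0, np.array([i.mz for i in ions]), rng.uniform(1, 10, len(ions))
        )
        a, b = annotate(p, s, registry), annotate(p, s, registry)
        np.testing.assert_array_equal(a.pooled(), b.pooled())

    def test_bad_tolerance(self, registry):
        p = Peptide("GG")
        s = ObservedSpectrum("t", 2, 100.0, np.array([58.0]), np.array([1.0]))
        with pytest.raises(ValueError, match="tolerance"):
            annotate(p, s, registry, tol=0.0)


class TestCSV:
    def test_row_count_and_consistency(self, registry, tmp_path):
        p = parse_peptide("H-SAMPLE-OH", registry)
        path = tmp_path / "pred.csv"
        n = write_csv([_predicted(p, registry, 2)], path)
        assert n == 20
        with open(path) as fh:
            rows = list(csv.DictReader(fh))
        assert len(rows) == 20
        assert {r["peptide"] for r in rows} == {"H-SAMPLE-OH"}
        # full float precision round-trips
        mz_back = sorted(float(r["mz"]) for r in rows)
        expected = sorted(i.mz for i in theoretical_spectrum(p, registry))
        assert mz_back == expected
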