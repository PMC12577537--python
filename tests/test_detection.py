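"""Adduct m/z arithmetic, peak matching and detection calls."""

import numpy as np
import pytest

from ugiqc.detection import (
    DEFAULT_ADDUCTS,
    DetectionConfig,
    DetectionRecord,
    PeakList,
    adduct_mz,
    call_detection,
    compound_detected,
    in_window,
    match_peak,
    read_peaklists_csv,
    write_peaklists_csv,
)

ADDUCT = {a.name: a for a in DEFAULT_ADDUCTS}


def make_peaks(mz, intensity, mode="positive", platform="AEMS", well="A1"):
    return PeakList(platform=platform, mode=mode, well=well,
                    mz=np.asarray(mz, float), intensity=np.asarray(intensity, float))


class TestAdductMz:
    def test_protonated(self):
        assert adduct_mz(260.1525, ADDUCT["[M+H]+"]) == pytest.approx(261.1598, abs=1e-4)

    def test_deprotonated(self):
        assert adduct_mz(260.1525, ADDUCT["[M-H]-"]) == pytest.approx(259.1452, abs=1e-4)

    def test_shift_ordering(self):
        for M in (100.0, 260.1525, 600.0):
            assert (
                adduct_mz(M, ADDUCT["[M+Na]+"])
                > adduct_mz(M, ADDUCT["[M+H]+"])
                > adduct_mz(M, ADDUCT["[M-H]-"])
            )


@pytest.mark.parametrize("M, expected", [(300.0, True), (645.0, False), (45.0, False)])
def test_in_window(M, expected):
    assert in_window(M) is expected


class TestMatchPeak:
    def test_exact_match_zero_error(self):
        peaks = make_peaks([100.0, 200.0, 300.0], [10, 20, 30])
        idx = match_peak(peaks, 200.0, tol_ppm=10)
        assert idx == 1
        assert peaks.mz[idx] == 200.0

    def test_out_of_tolerance(self):
        target = 500.0
        peaks = make_peaks([target * (1 + 12e-6)], [100])
        assert match_peak(peaks, target, tol_ppm=10) is None

    def test_tie_broken_by_intensity(self):
        # symmetric +-1/1024 Da about 512 Da: exactly equal |ppm| errors
        target = 512.0
        off = 1.0 / 1024.0
        peaks = make_peaks([target - off, target + off], [100, 900])
        idx = match_peak(peaks, target, tol_ppm=10)
        assert peaks.intensity[idx] == 900

    def test_empty_peaklist(self):
        assert match_peak(make_peaks([], []), 100.0) is None

    def test_agrees_with_linear_scan_oracle(self):
        """Brute-force scan with the same tie-break on 1000 random lists."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = rng.integers(1, 40)
            mz = rng.uniform(50, 650, n)
            inten = rng.lognormal(3, 1, n)
            peaks = make_peaks(mz, inten)
            target = float(rng.uniform(50, 650))
            tol_ppm = float(rng.uniform(1, 50))
            tol = target * tol_ppm * 1e-6
            best = None
            for i in range(len(peaks)):
                err = abs(peaks.mz[i] - target)
                if err > tol:
                    continue
                key = (err, -peaks.intensity[i], peaks.mz[i])
                if best is None or key < best[0]:
                    best = (key, i)
            expected = None if best is None else best[1]
            assert match_peak(peaks, target, tol_ppm) == expected


class TestCallDetection:
    M = 260.1525

    def test_lone_peak_detected_with_unit_noise_floor(self):
        target = adduct_mz(self.M, ADDUCT["[M+H]+"])
        peaks = make_peaks([target], [1000.0])
        records = {r.adduct: r for r in call_detection("c", self.M, peaks)}
        assert records["[M+H]+"].detected
        assert records["[M+H]+"].auc == 1000.0
        assert records["[M+H]+"].mass_error_ppm == pytest.approx(0.0, abs=1e-9)
        assert not records["[M+Na]+"].detected

    def test_weak_peak_fails_snr(self):
        target = adduct_mz(self.M, ADDUCT["[M+H]+"])
        noise_mz = np.linspace(50, 250, 100)
        peaks = make_peaks(
            np.append(noise_mz, target), np.append(np.ones(100), 2.0)
        )
        records = {r.adduct: r for r in call_detection("c", self.M, peaks)}
        assert not records["[M+H]+"].detected  # 2 < 3 x median(1)

    def test_no_match_gives_empty_record(self):
        peaks = make_peaks([100.0], [50.0])
        records = call_detection("c", self.M, peaks)
        assert all(not r.detected and r.auc == 0.0 for r in records)

    def test_own_adducts_excluded_from_noise(self):
        """A strong [M+Na]+ peak must not mask a modest [M+H]+ signal."""
        mh = adduct_mz(self.M, ADDUCT["[M+H]+"])
        mna = adduct_mz(self.M, ADDUCT["[M+Na]+"])
        peaks = make_peaks([mh, mna], [10.0, 10000.0])
        records = {r.adduct: r for r in call_detection("c", self.M, peaks)}
        assert records["[M+H]+"].detected
        assert records["[M+Na]+"].detected

    def test_monotone_in_snr_and_tolerance(self):
        """Raising snr_min or tightening tolerance never adds detections."""
        rng = np.random.default_rng(9)
        masses = rng.uniform(100, 600, 50)
        for M in masses:
            n = rng.integers(2, 30)
            mz = rng.uniform(50, 650, n)
            inten = rng.lognormal(2, 1.5, n)
            # half the time, plant a near-target peak
            if rng.random() < 0.5:
                mz = np.append(mz, adduct_mz(M, ADDUCT["[M+H]+"]) * (1 + rng.normal(0, 5e-6)))
                inten = np.append(inten, rng.lognormal(4, 1))
            peaks = make_peaks(mz, inten)
            loose = {r.adduct: r.detected for r in call_detection(
                "c", M, peaks, DetectionConfig(tol_ppm=20, snr_min=1))}
            strict_snr = {r.adduct: r.detected for r in call_detection(
                "c", M, peaks, DetectionConfig(tol_ppm=20, snr_min=5))}
            strict_tol = {r.adduct: r.detected for r in call_detection(
                "c", M, peaks, DetectionConfig(tol_ppm=2, snr_min=1))}
            for adduct in loose:
                assert not (strict_snr[adduct] and not loose[adduct])
                assert not (strict_tol[adduct] and not loose[adduct])


class TestCompoundRules:
    def rec(self, adduct, detected):
        return DetectionRecord("c", "AEMS", "negative", adduct, detected)

    def test_any_vs_all(self):
        records = [
            self.rec("[M+H]+", False),
            self.rec("[M+Na]+", False),
            self.rec("[M-H]-", True),
        ]
        assert compound_detected(records, "any_adduct")
        assert not compound_detected(records, "all_adducts")

    def test_all_detected(self):
        records = [self.rec(a.name, True) for a in DEFAULT_ADDUCTS]
        assert compound_detected(records, "any_adduct")
        assert compound_detected(records, "all_adducts")

    def test_none_detected(self):
        records = [self.rec(a.name, False) for a in DEFAULT_ADDUCTS]
        assert not compound_detected(records, "any_adduct")
        assert not compound_detected(records, "all_adducts")

    def test_empty_records_error(self):
        with pytest.raises(ValueError):
            compound_detected([])


def test_peaklist_sorted_and_tic():
    peaks = make_peaks([300.0, 100.0, 200.0], [3, 1, 2])
    assert list(peaks.mz) == [100.0, 200.0, 300.0]
    assert peaks.tic == 6.0


def test_record_invariant_enforced():
    with pytest.raises(ValueError):
        DetectionRecord("c", "AEMS", "positive", "[M+H]+", detected=False, auc=5.0)


def test_peaklists_csv_roundtrip(tmp_path):
    rng = np.random.default_rng(1)
    lists = [
        make_peaks(np.sort(rng.uniform(50, 650, 5)), rng.lognormal(3, 1, 5),
                   mode=mode, well=f"P384-01:A{i+1}")
        for i, mode in enumerate(["positive", "negative"])
    ]
    path = tmp_path / "peaks.csv"
    write_peaklists_csv(lists, path)
    back = read_peaklists_csv(path)
    assert len(back) == 2
    for orig, rec in zip(sorted(lists, key=lambda p: p.mode),
                         sorted(back, key=lambda p: p.mode)):
        np.testing.assert_allclose(rec.mz, orig.mz, atol=1e-6)
        np.testing.assert_allclose(rec.intensity, orig.intensity, atol=1e-4)
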