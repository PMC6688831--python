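import numpy as np
import pytest

from neohrv.errors import ParseError, QualityError, ValidationError
from neohrv.rr import (
    WINDOW_SPECS,
    RRSeries,
    extract_windows,
    pma_class,
    read_rr_series,
    screen_rr,
    write_rr_series,
)

from conftest import make_window, random_window


class TestIO:
    def test_single_column_onsets_by_cumulative_sum(self, tmp_path):
        p = tmp_path / "rr.csv"
        p.write_text("rr_ms\n400\n410\n405\n")
        s = read_rr_series(p)
        assert np.allclose(s.onset_s, [0.0, 0.410, 0.815])
        assert np.allclose(s.rr_ms, [400, 410, 405])

    def test_round_trip_identity(self, tmp_path, rng):
        s = random_window(rng, 500)
        write_rr_series(s, tmp_path / "w.csv")
        back = read_rr_series(tmp_path / "w.csv", "S", 28.0, 30.0)
        assert np.allclose(back.onset_s, s.onset_s, atol=1e-9)
        assert np.allclose(back.rr_ms, s.rr_ms, atol=1e-9)

    def test_row_count_preserved(self, tmp_path, rng):
        s = random_window(rng, 2250)
        write_rr_series(s, tmp_path / "w.csv")
        assert len((tmp_path / "w.csv").read_text().splitlines()) == 2251

    def test_empty_series_writes_header_only(self, tmp_path):
        s = RRSeries("S", 28.0, 30.0, np.array([]), np.array([]))
        write_rr_series(s, tmp_path / "e.csv")
        assert (tmp_path / "e.csv").read_text().strip() == "onset_s,rr_ms"

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("rr_ms\n400\nnot_a_number\n410\n")
        with pytest.raises(ParseError, match="line 3"):
            read_rr_series(p)

    def test_inconsistent_onsets_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("onset_s,rr_ms\n0.0,400\n0.5,400\n")
        with pytest.raises(ValidationError):
            read_rr_series(p)


class TestInvariants:
    def test_non_positive_rr_rejected(self):
        with pytest.raises(ValidationError, match="index 1"):
            make_window([400, -5, 400])

    def test_pma_before_ga_rejected(self):
        with pytest.raises(ValidationError):
            make_window([400, 410], ga=30.0, pma=28.0)

    @pytest.mark.parametrize(
        "pma,expected",
        [(26, "<28"), (28, "28-32"), (31.9, "28-32"), (32, "32-36"), (36, ">=36"), (41, ">=36")],
    )
    def test_pma_class_boundaries(self, pma, expected):
        assert pma_class(pma) == expected


class TestScreening:
    def test_clean_series_unchanged(self):
        s = make_window([400.0] * 100)
        cleaned, report = screen_rr(s)
        assert report.n_flagged == 0
        assert cleaned is s

    def test_single_artifact_interpolated(self):
        rr = [400.0] * 50
        rr[20] = 2000.0
        cleaned, report = screen_rr(make_window(rr))
        assert 20 in report.flagged_indices
        assert cleaned.rr_ms[20] == pytest.approx(400.0)
        assert np.all(np.diff(cleaned.onset_s) > 0)

    def test_too_many_artifacts_rejected(self):
        rr = np.full(100, 400.0)
        rr[::3] = 2000.0  # ~33 % out of range
        with pytest.raises(QualityError):
            screen_rr(make_window(rr))

    def test_idempotent(self, rng):
        rr = 400.0 + 20.0 * rng.standard_normal(400)
        rr[[10, 50, 200]] = [1500.0, 100.0, 1200.0]
        cleaned, _ = screen_rr(make_window(np.clip(rr, 50, 2500)))
        _, second = screen_rr(cleaned)
        assert second.n_flagged == 0


class TestWindowing:
    @pytest.mark.parametrize(
        "lc,expected_starts",
        [
            ("L", [0.0]),
            ("S10", [0.0, 300.0]),
            ("S5", [0.0] + [150.0 * k for k in range(1, 5)]),
            ("US", [60.0 * k for k in range(14)]),
        ],
    )
    def test_window_starts_900s(self, lc, expected_starts):
        s = make_window([400.0] * 2250)  # exactly 900 s
        wins = extract_windows(s, WINDOW_SPECS[lc])
        assert len(wins) == len(expected_starts)
        assert [w.window_index for w in wins] == list(range(len(wins)))

    @pytest.mark.parametrize("duration", [600, 750, 899, 1200, 2000])
    @pytest.mark.parametrize("lc", ["US", "S5", "S10"])
    def test_window_count_formula(self, duration, lc):
        n = int(duration / 0.4)
        s = make_window([400.0] * n)
        spec = WINDOW_SPECS[lc]
        wins = extract_windows(s, spec)
        d, t = s.duration_s, spec.length_s
        expected = int(np.floor((d - t) / (t / 2))) + 1 if d >= t else 0
        assert len(wins) == expected

    def test_windows_are_sub_series_of_parent(self, rng):
        s = random_window(rng, 2250)
        for w in extract_windows(s, WINDOW_SPECS["US"]):
            # every beat of the window occurs in the parent
            idx = np.searchsorted(np.round(s.rr_ms, 9), 0)  # noqa: F841
            assert np.isin(np.round(w.rr_ms, 9), np.round(s.rr_ms, 9)).all()
            # within-window onset differences re-derivable from rr
            assert np.allclose(np.diff(w.onset_s), w.rr_ms[1:] / 1000.0, atol=1e-9)
            assert w.duration_s <= 120.0 + 1.0  # length plus final interval

    def test_short_recording_warns_and_returns_empty(self):
        s = make_window([400.0] * 250)  # 100 s
        with pytest.warns(UserWarning, match="shorter"):
            assert extract_windows(s, WINDOW_SPECS["US"]) == []

    def test_full_length_window_is_identity(self):
        s = make_window([400.0] * 2250)
        (w,) = extract_windows(s, WINDOW_SPECS["L"])
        assert w.n_beats == s.n_beats
        assert np.allclose(w.rr_ms, s.rr_ms)
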