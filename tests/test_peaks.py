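"""POM/POI cascade: per-stage examples, invariants and oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import naive_median, naive_methylation_status, naive_windows
from sgrecover.drach import scan_drach
from sgrecover.formats_io import CoverageTrack, Transcript
from sgrecover.peaks import (
    PeakParams,
    Window,
    call_methylation,
    compute_poi,
    remove_shared,
    retain_windows,
    sliding_windows,
    transcript_median,
)


def track(values, tx_id="tx"):
    return CoverageTrack(tx_id, np.asarray(values, dtype=float))


class TestMedian:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([10, 10, 10, 10], 10),
            ([0, 0, 10, 30], 5),  # even length: midpoint of 0 and 10
            ([0, 0, 0], 0),
        ],
    )
    def test_examples(self, values, expected):
        assert transcript_median(track(values)) == expected

    @given(st.lists(st.floats(0, 1000, allow_nan=False), min_size=1, max_size=200))
    def test_matches_sort_based_oracle(self, values):
        assert transcript_median(track(values)) == pytest.approx(naive_median(values))


class TestSlidingWindows:
    def test_starts_for_length_100(self):
        ws = sliding_windows(track([1.0] * 100))
        assert [(w.start, w.end) for w in ws] == [(0, 50), (25, 75), (50, 100)]

    def test_uniform_coverage_pom_one(self):
        for c in (0.5, 1.0, 7.0):
            ws = sliding_windows(track([c] * 125))
            assert all(w.pom == pytest.approx(1.0) for w in ws)

    def test_too_short_yields_nothing(self):
        assert sliding_windows(track([5.0] * 49)) == []

    def test_zero_median_yields_nothing(self):
        values = np.zeros(200)
        values[:40] = 100.0  # zero median despite strong local coverage
        assert sliding_windows(track(values)) == []

    @given(st.lists(st.floats(0.5, 100, allow_nan=False), min_size=50, max_size=300))
    @settings(max_examples=200)
    def test_matches_naive_oracle(self, values):
        got = sliding_windows(track(values))
        expected = naive_windows(values)
        assert [(w.start, w.end) for w in got] == [(s, e) for s, e, _, _ in expected]
        for w, (_, _, mean, pom) in zip(got, expected):
            assert w.mean_cov == pytest.approx(mean)
            assert w.pom == pytest.approx(pom)

    @given(
        st.lists(st.floats(0.5, 100, allow_nan=False), min_size=50, max_size=300),
        st.floats(0.001, 1000),
    )
    @settings(max_examples=200)
    def test_pom_scale_invariance(self, values, c):
        base = sliding_windows(track(values))
        scaled = sliding_windows(track(np.asarray(values) * c))
        assert len(base) == len(scaled)
        for w, ws in zip(base, scaled):
            assert ws.pom == pytest.approx(w.pom, rel=1e-9)

    def test_raising_coverage_inside_window_raises_its_mean(self, rng):
        values = rng.uniform(1, 20, size=150)
        before = sliding_windows(track(values))[0]
        values2 = values.copy()
        values2[10:40] += 5.0
        after = sliding_windows(track(values2))[0]
        assert after.mean_cov > before.mean_cov


class TestRetain:
    def test_pom_threshold_is_strict(self):
        w = Window("tx", 0, 50, 50.0, 3.0)
        assert retain_windows([w]) == []

    def test_coverage_floor_is_inclusive(self):
        w = Window("tx", 0, 50, 10.0, 6.0)
        assert retain_windows([w]) == [w]

    def test_empty(self):
        assert retain_windows([]) == []


class TestRemoveShared:
    def test_one_nt_overlap_removes(self):
        ip = [Window("tx", 0, 50, 20.0, 4.0)]
        inp = [Window("tx", 25, 75, 20.0, 4.0)]
        assert remove_shared(ip, inp) == []

    def test_no_input_windows_keeps_all(self):
        ip = [Window("tx", 0, 50, 20.0, 4.0)]
        assert remove_shared(ip, []) == ip

    def test_adjacent_half_open_kept(self):
        ip = [Window("tx", 0, 50, 20.0, 4.0)]
        inp = [Window("tx", 50, 100, 20.0, 4.0)]
        assert remove_shared(ip, inp) == ip

    def test_other_transcript_ignored(self):
        ip = [Window("tx1", 0, 50, 20.0, 4.0)]
        inp = [Window("tx2", 0, 50, 20.0, 4.0)]
        assert remove_shared(ip, inp) == ip

    def test_exact_mode_requires_identical_coordinates(self):
        ip = [Window("tx", 0, 50, 20.0, 4.0)]
        inp = [Window("tx", 25, 75, 20.0, 4.0)]
        assert remove_shared(ip, inp, mode="exact") == ip
        assert remove_shared(ip, [Window("tx", 0, 50, 9.0, 5.0)], mode="exact") == []


class TestPoi:
    def test_ratio(self):
        w = Window("tx", 0, 4, 30.0, 6.0)
        poi, pom_input, flagged = compute_poi(w, track([5.0, 5.0, 5.0, 5.0]))
        assert pom_input == pytest.approx(1.0)
        assert poi == pytest.approx(6.0)
        assert not flagged

    def test_zero_input_median_floored_and_flagged(self):
        w = Window("tx", 0, 2, 30.0, 4.0)
        poi, pom_input, flagged = compute_poi(w, track([0.0, 0.0, 0.0]))
        assert poi == pytest.approx(40.0)
        assert pom_input == 0.0
        assert flagged

    def test_equal_pom_gives_one(self):
        w = Window("tx", 0, 4, 7.0, 1.0)
        poi, _, _ = compute_poi(w, track([7.0] * 4))
        assert poi == pytest.approx(1.0)


def _spiked_transcript(rng, length=300, peak_at=150, fold=5.0, mean=30.0):
    seq = "".join(rng.choice(list("CGT"), size=length))  # no stray DRACH
    seq = seq[: peak_at - 2] + "GGACT" + seq[peak_at + 3 :]
    flat = np.full(length, mean)
    bump = 1 + (fold - 1) * np.exp(-((np.arange(length) - peak_at) ** 2) / (2 * 12.5**2))
    return Transcript("tx", "g", seq), flat * bump, flat


class TestCallMethylation:
    def test_spiked_peak_with_drach_is_methylated(self, rng):
        tx, ip, flat = _spiked_transcript(rng)
        calls = call_methylation(
            {"tx": track(ip)}, {"tx": track(flat)}, {"tx": scan_drach(tx)}
        )
        assert calls["tx"].status == "methylated"
        (peak,) = calls["tx"].peaks[:1]
        assert any(s.a_position == 150 for s in peak.drach_sites)
        assert peak.poi > 1.0

    def test_identical_ip_and_input_non_methylated(self, rng):
        tx, ip, _ = _spiked_transcript(rng)
        calls = call_methylation(
            {"tx": track(ip)}, {"tx": track(ip)}, {"tx": scan_drach(tx)}
        )
        assert calls["tx"].status == "non_methylated"
        assert calls["tx"].peaks == []

    def test_peak_without_drach_non_methylated(self, rng):
        tx, ip, flat = _spiked_transcript(rng)
        calls = call_methylation({"tx": track(ip)}, {"tx": track(flat)}, {"tx": []})
        assert calls["tx"].status == "non_methylated"

    def test_missing_input_track_treated_as_zero(self, rng, caplog):
        tx, ip, _ = _spiked_transcript(rng)
        with caplog.at_level("INFO"):
            calls = call_methylation({"tx": track(ip)}, {}, {"tx": scan_drach(tx)})
        assert "no input coverage" in caplog.text
        # flat-ish IP against zero input: still needs POM > 3 within IP itself
        assert "tx" in calls

    def test_stats_cascade_monotone(self, rng):
        tx, ip, flat = _spiked_transcript(rng)
        stats: dict = {}
        call_methylation({"tx": track(ip)}, {"tx": track(flat)}, {"tx": scan_drach(tx)}, stats=stats)
        assert (
            stats["windows_scored"]
            >= stats["windows_retained"]
            >= stats["windows_after_shared"]
            >= stats["windows_drach"]
        )


class TestOracleEquivalence:
    def _random_transcriptome(self, rng, n_tx):
        txs, ips, inps = {}, {}, {}
        for i in range(n_tx):
            length = int(rng.integers(30, 500))
            seq = "".join(rng.choice(list("ACGT"), size=length))
            tx_id = f"t{i}"
            txs[tx_id] = Transcript(tx_id, f"g{i}", seq)
            base = rng.choice([0.0, 2.0, 20.0], p=[0.2, 0.3, 0.5])
            ip = rng.poisson(base, size=length).astype(float)
            inp = rng.poisson(base, size=length).astype(float)
            # spike some IP tracks to create real peaks
            if rng.random() < 0.5 and length >= 60:
                c = int(rng.integers(25, length - 25))
                ip[max(0, c - 25) : c + 25] += rng.integers(20, 120)
            ips[tx_id] = CoverageTrack(tx_id, ip)
            inps[tx_id] = CoverageTrack(tx_id, inp)
        return txs, ips, inps

    def test_cascade_matches_naive_reimplementation(self, rng):
        """Full-cascade agreement with an explicit-loop oracle, 100 transcriptomes."""
        for rep in range(100):
            txs, ips, inps = self._random_transcriptome(rng, n_tx=int(rng.integers(1, 20)))
            calls = call_methylation(
                ips, inps, {t: scan_drach(tx) for t, tx in txs.items()}
            )
            for tx_id, tx in txs.items():
                status, surviving = naive_methylation_status(
                    ips[tx_id].values.tolist(), inps[tx_id].values.tolist(), tx.sequence
                )
                call = calls[tx_id]
                assert call.status == status, tx_id
                got = [(p.window.start, p.window.end) for p in call.peaks]
                assert got == [(s, e) for s, e, *_ in surviving]
                for peak, (_, _, mean, pom, anchors) in zip(call.peaks, surviving):
                    assert peak.window.mean_cov == pytest.approx(mean)
                    assert peak.window.pom == pytest.approx(pom)
                    assert [s.a_position for s in peak.drach_sites] == anchors
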