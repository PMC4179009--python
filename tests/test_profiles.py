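"""Gap-probability inversion to PAI/PAVD, against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vegnet import (
    CanopyModel,
    InstrumentGeometry,
    SimulationConfig,
    compute_profile,
    default_height_grid,
    extinction_coefficient,
    gap_profile,
    pai_profile,
    pavd_profile,
    pooled_profile,
    simulate_scan,
    top_of_canopy_pai,
)

COS_Z = np.cos(np.radians(57.5))


def brute_force_pgap(scan, grid):
    """Independent per-shot recount of Pgap(h) = 1 - (#valid z_i < h)/N."""
    out = []
    for h in grid:
        below = sum(1 for r in scan.range_m if r > 0 and COS_Z * r < h)
        out.append(1.0 - below / scan.n_shots)
    return np.array(out)


class TestGapProfile:
    def test_all_gaps_give_unit_pgap(self, scan_factory):
        scan = scan_factory([0.0] * 100)
        assert np.all(gap_profile(scan) == 1.0)

    def test_half_returns_below_5m(self, scan_factory):
        # 50 valid returns all below 5 m height, 50 gaps
        ranges = [2.0 / COS_Z] * 50 + [0.0] * 50
        pgap = gap_profile(scan_factory(ranges), height_grid=np.arange(0.0, 11.0))
        assert pgap[5] == pytest.approx(0.5)

    def test_three_hits_and_97_gaps(self, scan_factory):
        heights = [2.0, 2.0, 8.0]
        ranges = [h / COS_Z for h in heights] + [0.0] * 97
        grid = np.arange(0.0, 16.0)
        pgap = gap_profile(scan_factory(ranges), height_grid=grid)
        assert pgap[5] == pytest.approx(0.98)
        assert pgap[10] == pytest.approx(0.97)

    def test_oracle_equivalence_on_random_small_scans(self, scan_factory, rng):
        grid = default_height_grid(35.0, 0.5)
        for _ in range(200):
            n = int(rng.integers(1, 51))
            ranges = np.where(
                rng.uniform(size=n) < 0.4, 0.0, rng.uniform(0.05, 60.0, size=n)
            )
            scan = scan_factory(ranges)
            np.testing.assert_array_equal(gap_profile(scan, height_grid=grid),
                                          brute_force_pgap(scan, grid))

    def test_strict_below_count_at_exact_height(self, scan_factory):
        scan = scan_factory([5.0 / COS_Z])
        grid = np.array([0.0, 5.0, 10.0])
        pgap = gap_profile(scan, height_grid=grid)
        assert pgap[1] == 1.0  # z_i == h not counted (strict <)
        assert pgap[2] == 0.0

    def test_literal_counting_mode_counts_gaps_as_low_returns(self, scan_factory):
        scan = scan_factory([0.0] * 99 + [10.0])
        grid = np.array([0.0, 1.0, 2.0])
        literal = gap_profile(scan, height_grid=grid, literal_gap_counting=True)
        assert literal[1] == pytest.approx(0.99)  # gaps at z=0 count below 1 m
        physical = gap_profile(scan, height_grid=grid)
        assert physical[1] == 1.0

    def test_non_uniform_grid_rejected(self, scan_factory):
        with pytest.raises(ValueError):
            gap_profile(scan_factory([1.0]), height_grid=np.array([0.0, 1.0, 3.0]))


class TestPaiProfile:
    @pytest.mark.parametrize(
        "pgap, expected",
        [(1.0, 0.0), (0.5, 1.1 * np.log(2)), (np.exp(-1.0), 1.1)],
    )
    def test_closed_form_inversion(self, pgap, expected):
        pai, saturated = pai_profile(np.array([pgap]), n_shots=100)
        assert pai[0] == pytest.approx(expected, abs=1e-12)
        assert not saturated

    def test_saturation_clips_and_flags(self):
        pai, saturated = pai_profile(np.array([1.0, 0.0]), n_shots=100)
        assert saturated
        assert pai[1] == pytest.approx(-1.1 * np.log(1.0 / 200.0))
        assert np.isfinite(pai).all()

    def test_invalid_pgap_rejected(self):
        with pytest.raises(ValueError):
            pai_profile(np.array([1.2]), n_shots=10)


class TestPavdProfile:
    def test_linear_ramp_gives_constant_density(self):
        pai = np.linspace(0.0, 1.5, 31)  # 0 -> 1.5 over 15 m at 0.5 m bins
        pavd = pavd_profile(pai, bin_width=0.5)
        assert np.allclose(pavd, 0.1)

    def test_flat_segment_gives_zero_density(self):
        pai = np.concatenate([np.linspace(0, 1, 11), np.full(10, 1.0)])
        pavd = pavd_profile(pai, bin_width=0.5)
        assert np.allclose(pavd[10:], 0.0)

    def test_smoothing_window_validation(self):
        with pytest.raises(ValueError):
            pavd_profile(np.linspace(0, 1, 11), 0.5, smooth_window=4)

    def test_two_layer_canopy_peaks_recovered_within_one_bin(self, rng):
        canopy = CanopyModel((6.0, 8.0, 12.0, 14.0, 20.0), (0.0, 0.4, 0.0, 0.4, 0.0))
        scans = [
            simulate_scan(canopy, SimulationConfig(n_shots=5000), rng=rng)
            for _ in range(2)
        ]
        prof = pooled_profile(scans, height_grid=default_height_grid(25.0, 1.0))
        pavd = prof.pavd
        centers = prof.height[:-1]
        top2 = centers[np.argsort(pavd)[-4:]]
        # recovered density concentrates in the true 6-8 m and 12-14 m layers
        assert any(5.0 <= c <= 9.0 for c in top2)
        assert any(11.0 <= c <= 15.0 for c in top2)


class TestProfileChain:
    def test_conservation_and_monotonicity(self, rng):
        canopy = CanopyModel.uniform(1.8, 15.0)
        scan = simulate_scan(canopy, SimulationConfig(n_shots=2000), rng=rng)
        prof = compute_profile(scan)
        assert prof.bin_width * prof.pavd.sum() == pytest.approx(prof.pai_top, abs=1e-9)
        assert np.all(np.diff(prof.pgap) <= 1e-12)
        assert np.all(np.diff(prof.pai) >= -1e-12)
        assert prof.pai[0] == 0.0 and prof.pgap[0] == 1.0

    def test_all_gap_scan_has_zero_pai(self, scan_factory):
        prof = compute_profile(scan_factory([0.0] * 50))
        assert top_of_canopy_pai(prof) == 0.0

    def test_top_pai_is_profile_maximum(self, rng):
        scan = simulate_scan(
            CanopyModel.uniform(1.0, 15.0), SimulationConfig(n_shots=1000), rng=rng
        )
        prof = compute_profile(scan)
        assert prof.pai_top >= prof.pai.max() - 1e-12

    @pytest.mark.parametrize("l_top", [0.5, 1.0, 1.5, 2.0])
    def test_parameter_recovery_spherical_lad(self, l_top):
        # N = 10,000 by pooling two 5,000-shot scans of the same canopy
        rng = np.random.default_rng(4242)
        canopy = CanopyModel.uniform(l_top, 15.0)
        scans = [
            simulate_scan(canopy, SimulationConfig(n_shots=5000), rng=rng)
            for _ in range(2)
        ]
        prof = pooled_profile(scans)
        k = extinction_coefficient(57.5)
        expected = 1.1 * k * l_top
        p = np.exp(-k * l_top)
        se = 1.1 * np.sqrt((1 - p) / (p * 10_000))
        assert abs(prof.pai_top - expected) <= 3 * se
        assert abs(prof.pai_top - l_top) / l_top < 0.10

    def test_recovery_monotone_in_true_pai(self):
        rng = np.random.default_rng(7)
        tops = []
        for l_top in (0.5, 1.0, 1.5, 2.0):
            scan = simulate_scan(
                CanopyModel.uniform(l_top, 15.0), SimulationConfig(n_shots=7000), rng=rng
            )
            tops.append(compute_profile(scan).pai_top)
        assert tops == sorted(tops)


class TestProfileCsvRoundTrip:
    def test_round_trip(self, tmp_path, rng, scan_factory):
        from vegnet.profiles import read_profile_csv, write_profile_csv

        scan = scan_factory(rng.uniform(0, 40, 200))
        prof = compute_profile(scan)
        path = write_profile_csv(prof, tmp_path / "p.profile.csv")
        back = read_profile_csv(path)
        np.testing.assert_allclose(back.pai, prof.pai, rtol=1e-8)
        np.testing.assert_allclose(back.pavd, prof.pavd, rtol=1e-6, atol=1e-12)
        assert back.instrument_id == prof.instrument_id
        assert back.timestamp == prof.timestamp
        assert back.n_shots == prof.n_shots
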