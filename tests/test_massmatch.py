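"""Mass windows, interval matching, and candidate calling."""

import numpy as np
import pandas as pd
import pytest

from msilowsig.massmatch import (
    call_candidates,
    combine_window,
    filter_modified,
    fwhm_points,
    match_masses,
    msi_mass,
    technical_points,
)
from msilowsig.preproc import MZ_GRID_SPACING, MzAxis


class TestMsiMass:
    def test_reference_peak(self):
        assert msi_mass(998.472) == pytest.approx(997.472)

    def test_simple_value(self):
        assert msi_mass(600.0) == pytest.approx(599.0)

    def test_mz_at_or_below_one_rejected(self):
        with pytest.raises(ValueError):
            msi_mass(1.0)


class TestTechnicalPoints:
    def test_channel_spacing_window(self):
        lo, hi = technical_points(998.472, 0.0487)
        assert lo == pytest.approx(998.4233)
        assert hi == pytest.approx(998.5207)

    def test_zero_delta_rejected(self):
        with pytest.raises(ValueError):
            technical_points(998.472, 0.0)

    def test_width_is_twice_delta(self):
        lo, hi = technical_points(700.0, 0.1)
        assert hi - lo == pytest.approx(0.2)


class TestFwhmPoints:
    def test_symmetric_triangular_peak(self):
        # triangle of half-width w=0.4: half-max crossings at apex -/+ 0.2
        x = np.arange(599.0, 601.01, 0.01)
        y = np.clip(1.0 - np.abs(x - 600.0) / 0.4, 0, 0.999999)
        lo, hi = fwhm_points(600.0, MzAxis(x), y)
        assert lo == pytest.approx(599.8, abs=0.011)
        assert hi == pytest.approx(600.2, abs=0.011)

    def test_gaussian_peak_width_closed_form(self):
        sigma = 0.1
        x = np.arange(997.0, 999.0, MZ_GRID_SPACING)
        y = np.exp(-((x - 998.0) ** 2) / (2 * sigma**2))
        apex = x[np.argmax(y)]
        lo, hi = fwhm_points(apex, MzAxis(x), y)
        expected = 2 * np.sqrt(2 * np.log(2)) * sigma
        assert hi - lo == pytest.approx(expected, abs=MZ_GRID_SPACING)

    def test_plateau_peak_crossings_at_flank_half_height(self):
        x = np.arange(0.0, 11.0)
        y = np.array([0, 0, 0.5, 1, 1, 1, 1, 1, 0.5, 0, 0], dtype=float)
        lo, hi = fwhm_points(5.0, MzAxis(x), y)
        assert lo == pytest.approx(2.0)
        assert hi == pytest.approx(8.0)

    def test_no_crossing_truncates_at_axis_bound(self):
        x = np.arange(600.0, 601.0, 0.1)
        y = np.linspace(0.9, 1.0, x.size)  # never drops below half right of peak
        lo, hi = fwhm_points(x[-1], MzAxis(x), y)
        assert lo == x[0] and hi == x[-1]


class TestCombineWindow:
    def test_wide_envelope_clamped_to_technical(self):
        w = combine_window(998.472, [(998.0, 999.0)], delta=0.0487)
        assert w.mass_min == pytest.approx(998.4233 - 1.0)
        assert w.mass_max == pytest.approx(998.5207 - 1.0)

    def test_narrow_envelope_used_directly(self):
        w = combine_window(998.472, [(998.46, 998.49)], delta=0.0487)
        assert w.mass_min == pytest.approx(997.46)
        assert w.mass_max == pytest.approx(997.49)

    def test_mixed_envelope(self):
        w = combine_window(998.472, [(998.40, 998.55)], delta=0.0487)
        assert w.mass_min == pytest.approx(997.4233)
        assert w.mass_max == pytest.approx(997.5207)

    def test_multi_sample_envelope_is_outermost(self):
        w = combine_window(700.0, [(699.99, 700.01), (699.98, 700.02)], delta=0.1)
        assert w.mass_min == pytest.approx(698.98)
        assert w.mass_max == pytest.approx(699.02)

    def test_window_nesting_invariants(self):
        rng = np.random.default_rng(0)
        for _ in range(10_000):
            peak = rng.uniform(600, 3200)
            delta = rng.uniform(0.001, 0.2)
            pts = [
                tuple(np.sort(peak + rng.normal(0, 0.1, 2)))
                for _ in range(rng.integers(1, 5))
            ]
            w = combine_window(peak, pts, delta)
            # combined window always inside the shifted technical window
            assert w.mass_min >= peak - delta - 1.0 - 1e-12
            assert w.mass_max <= peak + delta - 1.0 + 1e-12
            env_lo = min(p[0] for p in pts) - 1.0
            env_hi = max(p[1] for p in pts) - 1.0
            if env_lo >= peak - delta - 1.0 and env_hi <= peak + delta - 1.0:
                assert w.mass_min == pytest.approx(env_lo)
                assert w.mass_max == pytest.approx(env_hi)


def _peptides(rows):
    return pd.DataFrame(rows, columns=["Sequence", "Proteins", "Gene names", "Mass"])


class TestMatchMasses:
    def test_inclusive_lower_bound(self):
        w = combine_window(700.0, [(699.0, 701.0)], delta=0.05)
        table = _peptides([("PEPTIDEK", "P1", "G1", w.mass_min)])
        assert len(match_masses([w], table)) == 1

    def test_containment(self):
        w = combine_window(998.472, [(998.40, 998.55)], delta=0.0487)
        table = _peptides([("PEPTIDEK", "P1", "G1", 997.45)])
        assert len(match_masses([w], table)) == 1

    def test_agrees_with_brute_force_on_random_instances(self):
        rng = np.random.default_rng(1)
        windows = []
        for _ in range(1000):
            peak = rng.uniform(600, 3200)
            pts = [tuple(np.sort(peak + rng.normal(0, 0.05, 2)))]
            windows.append(combine_window(peak, pts, rng.uniform(0.01, 0.1)))
        masses = rng.uniform(599, 3199, 1000)
        table = _peptides(
            [(f"PEP{i}", f"P{i}", f"G{i}", m) for i, m in enumerate(masses)]
        )
        fast = match_masses(windows, table)
        brute = {
            (w.peak_mz, float(m))
            for w in windows
            if not w.empty
            for m in masses
            if w.mass_min <= m <= w.mass_max
        }
        assert {(r.peak_mz, r.Mass) for r in fast.itertuples()} == brute

    def test_widening_windows_never_removes_matches(self):
        rng = np.random.default_rng(2)
        masses = rng.uniform(699, 701, 200)
        table = _peptides(
            [(f"PEP{i}", f"P{i}", f"G{i}", m) for i, m in enumerate(masses)]
        )
        narrow = [combine_window(700.5, [(700.45, 700.55)], 0.05)]
        wide = [combine_window(700.5, [(700.3, 700.7)], 0.5)]
        n_set = {r.Mass for r in match_masses(narrow, table).itertuples()}
        w_set = {r.Mass for r in match_masses(wide, table).itertuples()}
        assert n_set <= w_set


class TestFilterModified:
    def test_cysteine_sequences_dropped(self):
        table = _peptides(
            [("ACDEFK", "P1", "G1", 700.0), ("ADEFK", "P2", "G2", 701.0)]
        )
        out = filter_modified(table)
        assert list(out["Sequence"]) == ["ADEFK"]


class TestCallCandidates:
    def _matches(self, rows):
        return pd.DataFrame(
            rows,
            columns=[
                "peak_mz", "msi_mass", "mass_min", "mass_max",
                "Sequence", "Proteins", "Gene names", "Mass",
            ],
        )

    def test_single_mass_is_not_a_candidate(self):
        m = self._matches(
            [(700.0, 699.0, 698.95, 699.05, "PEP", "P1", "G1", 699.0)]
        )
        imgs = {700.0: np.random.default_rng(0).uniform(0, 1, 50)}
        assert call_candidates(m, imgs) == []

    def test_identical_ion_images_give_candidate(self):
        img = np.random.default_rng(1).uniform(0, 1, 50)
        m = self._matches(
            [
                (700.0, 699.0, 698.95, 699.05, "PEPA", "P1", "G1", 699.0),
                (900.0, 899.0, 898.95, 899.05, "PEPB", "P1", "G1", 899.0),
            ]
        )
        cands = call_candidates(m, {700.0: img, 900.0: img.copy()})
        assert len(cands) == 1
        assert cands[0].distinct_count == 2
        assert cands[0].exemplary_pair == (699.0, 899.0)

    def test_uncorrelated_images_rejected(self):
        rng = np.random.default_rng(2)
        m = self._matches(
            [
                (700.0, 699.0, 698.95, 699.05, "PEPA", "P1", "G1", 699.0),
                (900.0, 899.0, 898.95, 899.05, "PEPB", "P1", "G1", 899.0),
            ]
        )
        imgs = {700.0: rng.uniform(0, 1, 200), 900.0: rng.uniform(0, 1, 200)}
        assert call_candidates(m, imgs) == []

    def test_mass_shift_replicates_collapse_to_one_group(self):
        img = np.random.default_rng(3).uniform(0, 1, 50)
        # two peaks with overlapping windows = one mass-shift group
        m = self._matches(
            [
                (700.00, 699.00, 698.95, 699.05, "PEP", "P1", "G1", 699.0),
                (700.03, 699.03, 698.98, 699.08, "PEP", "P1", "G1", 699.0),
            ]
        )
        assert call_candidates(m, {700.00: img, 700.03: img.copy()}) == []
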