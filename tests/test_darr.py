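"""DARR simulation, peak picking, classification, and peak matching."""
import numpy as np
import pytest

from fibrilstack.darr import (
    classify_residue,
    compare_peaklists,
    pick_peaks,
    predict_shifts,
    simulate_darr,
)
from fibrilstack.errors import DomainError
from fibrilstack.refshifts import class_means
from fibrilstack.types import (
    AnalysisConfig,
    Peak2D,
    PeakList2D,
    ShiftEntry,
    ShiftTable,
)


def well_separated_table():
    """Three carbons with shifts far apart: one bonded pair plus a loner."""
    return ShiftTable([
        ShiftEntry("Ala", 1, "CA", 51.2),
        ShiftEntry("Ala", 1, "CB", 22.9),
        ShiftEntry("Gly", 2, "CA", 120.0),  # deliberately isolated frequency
    ])


class TestPredictShifts:
    def test_sheet_alanine_uses_reference_means(self):
        table = predict_shifts(["A"], ["sheet"])
        assert table.get(1, "C'").shift == pytest.approx(175.7)
        assert table.get(1, "CA").shift == pytest.approx(51.4)
        assert table.get(1, "CB").shift == pytest.approx(21.6)

    def test_all_coil_assignment_matches_coil_table(self):
        means = class_means()
        table = predict_shifts("NFGS", ["coil"] * 4)
        for e in table:
            if e.atom in means[e.residue]["coil"]:
                assert e.shift == means[e.residue]["coil"][e.atom]

    def test_sidechain_beyond_cbeta_takes_coil_values(self):
        sheet = predict_shifts(["K"], ["sheet"])
        coil = predict_shifts(["K"], ["coil"])
        for atom in ("CG", "CD", "CE"):
            assert sheet.get(1, atom).shift == coil.get(1, atom).shift

    def test_unknown_residue_names_position(self):
        with pytest.raises(DomainError, match="position 2"):
            predict_shifts(["A", "X", "G"], ["coil"] * 3)

    def test_class_ordering_invariant(self):
        means = class_means()
        for aa, per_class in means.items():
            assert per_class["helix"]["CA"] > per_class["coil"]["CA"] > \
                per_class["sheet"]["CA"]


class TestSimulateDarr:
    def test_table2_cross_peak_position(self, medin_table):
        spectrum = simulate_darr(medin_table)
        peaks = pick_peaks(spectrum, 0.05)
        spacing = spectrum.grid_spacing
        match = [p for p in peaks
                 if abs(p.ppm_indirect - 22.9) <= spacing
                 and abs(p.ppm_direct - 51.2) <= spacing]
        assert len(match) == 1

    def test_single_atom_gives_diagonal_only(self):
        table = ShiftTable([ShiftEntry("Ala", 1, "CA", 51.2)])
        peaks = pick_peaks(simulate_darr(table), 0.05)
        assert len(peaks) == 1
        p = peaks.peaks[0]
        assert p.ppm_direct == pytest.approx(p.ppm_indirect)

    def test_two_bonded_atoms_give_four_peaks(self):
        table = ShiftTable([ShiftEntry("Ala", 1, "CA", 51.2),
                            ShiftEntry("Ala", 1, "CB", 22.9)])
        peaks = pick_peaks(simulate_darr(table), 0.05)
        assert len(peaks) == 4
        kinds = sorted(p.assignment.split()[0] for p in peaks)
        assert kinds == ["cross", "cross", "diagonal", "diagonal"]

    def test_peak_count_for_well_separated_shifts(self):
        peaks = pick_peaks(simulate_darr(well_separated_table()), 0.05)
        # 3 diagonal + 2 cross (one bonded pair, symmetric partners)
        assert len(peaks) == 5

    def test_extra_pair_adds_symmetric_cross_peaks(self):
        table = well_separated_table()
        base = pick_peaks(simulate_darr(table), 0.05)
        extra = pick_peaks(simulate_darr(
            table, extra_pairs=[((1, "CB"), (2, "CA"))]), 0.05)
        assert len(extra) == len(base) + 2

    def test_spectrum_symmetry(self, medin_table):
        peaks = pick_peaks(simulate_darr(medin_table), 0.05)
        spacing = simulate_darr(medin_table).grid_spacing
        cross = [p for p in peaks if p.assignment.startswith("cross")]
        for p in cross:
            partner = [q for q in cross
                       if abs(q.ppm_direct - p.ppm_indirect) <= spacing
                       and abs(q.ppm_indirect - p.ppm_direct) <= spacing]
            assert partner, f"no symmetric partner for {p}"
            assert partner[0].intensity == pytest.approx(p.intensity, rel=0.01)

    def test_shift_outside_window_names_atom(self, medin_table):
        cfg = AnalysisConfig(spectral_window=(0.0, 100.0))
        with pytest.raises(DomainError, match="C'"):
            simulate_darr(medin_table, cfg)

    def test_zero_filling_stabilises_positions(self):
        table = ShiftTable([ShiftEntry("Ala", 1, "CA", 51.37),
                            ShiftEntry("Ala", 1, "CB", 23.11)])
        p512 = pick_peaks(simulate_darr(table, AnalysisConfig(grid_points=512)), 0.05)
        p1024 = pick_peaks(simulate_darr(table, AnalysisConfig(grid_points=1024)), 0.05)
        spacing512 = 200.0 / 512
        for p in p512:
            q = min(p1024, key=lambda q: abs(q.ppm_direct - p.ppm_direct)
                    + abs(q.ppm_indirect - p.ppm_indirect))
            assert abs(q.ppm_direct - p.ppm_direct) < 0.5 * spacing512
            assert abs(q.ppm_indirect - p.ppm_indirect) < 0.5 * spacing512


class TestPickPeaks:
    def test_off_grid_center_recovered_precisely(self):
        table = ShiftTable([ShiftEntry("Ala", 1, "CA", 51.37)])
        spectrum = simulate_darr(table)
        peak = pick_peaks(spectrum, 0.5).peaks[0]
        assert abs(peak.ppm_direct - 51.37) <= 0.1 * spectrum.grid_spacing

    def test_high_threshold_keeps_only_global_max(self, medin_table):
        spectrum = simulate_darr(medin_table)
        peaks = pick_peaks(spectrum, 0.99)
        assert len(peaks) >= 1
        assert all(p.intensity >= 0.99 * spectrum.intensity.max() for p in peaks)

    def test_invalid_threshold_rejected(self, medin_table):
        with pytest.raises(DomainError):
            pick_peaks(simulate_darr(medin_table), 1.5)


class TestClassifyResidue:
    def test_fibril_alanine_is_sheet(self):
        assert classify_residue({"C'": 175.7, "CA": 51.2, "CB": 22.9}, "Ala") == "sheet"

    def test_fibril_aspartate_and_lysine_are_sheet(self):
        assert classify_residue({"C'": 173.8, "CA": 53.4, "CB": 41.3}, "Asp") == "sheet"
        assert classify_residue({"C'": 175.1, "CA": 55.7, "CB": 36.8}, "Lys") == "sheet"

    def test_exact_helix_means_classify_as_helix(self):
        means = class_means()
        obs = dict(means["A"]["helix"])
        assert classify_residue(obs, "A") == "helix"

    def test_far_from_every_class_is_unassignable(self):
        means = class_means()
        obs = {a: v + 10.0 for a, v in means["S"]["coil"].items()}
        assert classify_residue(obs, "Ser") is None

    def test_referencing_offset_does_not_flip_confident_calls(self):
        obs = {"C'": 175.7, "CA": 51.2, "CB": 22.9}
        for delta in (-0.3, 0.3):
            shifted = {a: v + delta for a, v in obs.items()}
            assert classify_residue(shifted, "Ala") == "sheet"

    def test_missing_cbeta_rejected(self):
        with pytest.raises(DomainError):
            classify_residue({"CA": 51.2}, "Ala")


class TestComparePeaklists:
    def test_list_vs_itself_all_matched(self):
        peaks = PeakList2D([Peak2D(51.2, 22.9, 1.0), Peak2D(22.9, 51.2, 1.0)])
        report = compare_peaklists(peaks, peaks, tol=0.5)
        assert report.n_matched == 2
        assert report.rms_error == 0.0
        assert not report.unmatched_a and not report.unmatched_b

    def test_disjoint_lists_no_matches(self):
        a = PeakList2D([Peak2D(51.2, 22.9, 1.0)])
        b = PeakList2D([Peak2D(60.0, 30.0, 1.0)])
        report = compare_peaklists(a, b, tol=0.5)
        assert report.n_matched == 0
        assert report.unmatched_a == [0] and report.unmatched_b == [0]

    def test_simulated_vs_ideal_peaklist_self_consistency(self, medin_table):
        spectrum = simulate_darr(medin_table)
        picked = pick_peaks(spectrum, 0.05)
        cross = PeakList2D([p for p in picked if p.assignment.startswith("cross")])
        from fibrilstack.refshifts import CARBON_TOPOLOGY, one_letter
        shifts = {(e.number, e.atom): e.shift for e in medin_table}
        ideal = []
        for (num, atom), shift in shifts.items():
            res = next(e.residue for e in medin_table if e.number == num)
            for a, b in CARBON_TOPOLOGY[one_letter(res)]:
                if (num, a) in shifts and (num, b) in shifts:
                    ideal.append(Peak2D(shifts[(num, a)], shifts[(num, b)], 1.0))
                    ideal.append(Peak2D(shifts[(num, b)], shifts[(num, a)], 1.0))
        # dedupe (each pair appended once per atom traversal)
        seen = set()
        unique = [p for p in ideal
                  if (p.ppm_direct, p.ppm_indirect) not in seen
                  and not seen.add((p.ppm_direct, p.ppm_indirect))]
        report = compare_peaklists(PeakList2D(unique), cross,
                                   tol=2.0 * spectrum.grid_spacing)
        assert not report.unmatched_a  # every ideal cross-peak was picked
        assert report.rms_error <= spectrum.grid_spacing
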