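"""Presence detection, exclusion matching, isomer resolution, batch updates."""

import pytest

from identmix import (
    IdStatus,
    LibraryEntry,
    PairCode,
    Peak,
    PeakList,
    PresencePattern,
    Tolerances,
    detect_presence,
    identify_batch,
    match_pattern,
)
from identmix.synth import SimulationConfig, generate_peaklists, generate_truth


def ri_peak(ri, intensity=1000.0):
    # peaks carrying a precomputed RI need no ladder
    return Peak(rt=ri, intensity=intensity, ri=ri)


def make_runs(**peaks_by_label):
    return {label: PeakList(label, peaks) for label, peaks in peaks_by_label.items()}


class TestDetectPresence:
    def test_galacturonic_pattern_from_b_and_d_peaks(self):
        entry = LibraryEntry("Galacturonic acid", "(MeOX)(5TMS)", expected_ri=1935.0,
                             ident_code=frozenset({"B", "D"}))
        runs = make_runs(
            A=[], B=[ri_peak(1934)], C=[], D=[ri_peak(1934)],
        )
        pattern = detect_presence(entry, runs)
        assert pattern.present == {"B", "D"}
        assert pattern.support["B"].ri == 1934

    def test_empty_peak_lists_give_all_absent(self):
        entry = LibraryEntry("X", "(TMS)", expected_ri=1500.0)
        pattern = detect_presence(entry, make_runs(A=[], B=[], C=[], D=[]))
        assert pattern.present == frozenset()

    def test_most_intense_qualifying_peak_recorded(self):
        entry = LibraryEntry("X", "(TMS)", expected_ri=1500.0)
        runs = make_runs(A=[ri_peak(1499, 10.0), ri_peak(1501, 100.0)])
        pattern = detect_presence(entry, runs, tolerances=Tolerances(intensity_min_frac=0))
        assert pattern.support["A"].intensity == 100.0

    def test_peaks_outside_window_do_not_count(self):
        entry = LibraryEntry("X", "(TMS)", expected_ri=1500.0)
        runs = make_runs(A=[ri_peak(1489)], B=[ri_peak(1510)])
        pattern = detect_presence(entry, runs)
        assert pattern.present == {"B"}  # 1510 is on the window edge, 1489 outside

    def test_intensity_floor_excludes_weak_peaks(self):
        entry = LibraryEntry("X", "(TMS)", expected_ri=1500.0)
        runs = make_runs(A=[ri_peak(1500, 2.0), ri_peak(2000, 1000.0)])
        pattern = detect_presence(entry, runs)  # floor = 5% of 1000
        assert pattern.present == frozenset()

    def test_gap_filled_peaks_excluded_by_default(self):
        entry = LibraryEntry("X", "(TMS)", expected_ri=1500.0)
        gap_peak = Peak(rt=1500, intensity=100.0, ri=1500.0, gap_filled=True)
        runs = make_runs(A=[gap_peak])
        assert detect_presence(entry, runs).present == frozenset()
        tol = Tolerances(include_gap_filled=True)
        assert detect_presence(entry, runs, tolerances=tol).present == {"A"}


class TestMatchPattern:
    @staticmethod
    def pattern(present, labels=("A", "B", "C", "D")):
        return PresencePattern(labels=tuple(labels), present=frozenset(present))

    def test_exact_match_confirms(self):
        assert match_pattern(self.pattern({"A", "C"}), PairCode.of("A", "C")) is IdStatus.CONFIRMED

    def test_all_absent_is_not_found(self):
        assert match_pattern(self.pattern(set()), PairCode.of("B", "D")) is IdStatus.NOT_FOUND

    @pytest.mark.parametrize("present", [{"A", "B", "C"}, {"A"}, {"B", "D"}, {"A", "B"}])
    def test_everything_else_is_conflict(self, present):
        assert match_pattern(self.pattern(present), PairCode.of("A", "C")) is IdStatus.CONFLICT


class TestIdentifyBatch:
    def test_zero_noise_table2_all_confirmed_with_exact_ris(self, table2_batch):
        lib, design, runs, ladders = table2_batch
        idents, updated = identify_batch(lib, design, runs, ladders)
        assert all(i.status is IdStatus.CONFIRMED for i in idents)
        for ident in idents:
            assert ident.updated_ri == pytest.approx(ident.entry.expected_ri, abs=1e-6)
        # updated library keeps the codes and refreshes names from the new RIs
        assert len(updated) == len(lib)
        assert {e.compound_name for e in updated} == {e.compound_name for e in lib}

    def test_deleting_one_compound_gives_not_found_only_for_it(self, table2_batch):
        lib, design, runs, ladders = table2_batch
        target = "Ribose"
        code = next(e.ident_code for e in lib if e.compound_name == target)
        expected_ri = next(e.expected_ri for e in lib if e.compound_name == target)
        pruned = {
            label: PeakList(
                label,
                [p for p in run.peaks
                 if not (label in code and abs(p.rt - _rt_of(expected_ri, ladders[label])) < 1e-6)],
            )
            for label, run in runs.items()
        }
        idents, _ = identify_batch(lib, design, pruned, ladders)
        by_name = {i.entry.compound_name: i for i in idents}
        assert by_name[target].status is IdStatus.NOT_FOUND
        others = [i for name, i in by_name.items() if name != target]
        assert all(i.status is IdStatus.CONFIRMED for i in others)

    def test_coeluting_pair_with_disjoint_codes_both_confirmed(self):
        # identical expected RI, codes {A,C} vs {B,D}: never co-injected,
        # each confirmed through its own mixtures
        e1 = LibraryEntry("Iso1", "(TMS)", expected_ri=1500.0, ident_code=frozenset({"A", "C"}))
        e2 = LibraryEntry("Iso2", "(TMS)", expected_ri=1500.0, ident_code=frozenset({"B", "D"}))
        from identmix import CompoundLibrary, MixDesign

        lib = CompoundLibrary(entries=[e1, e2])
        design = MixDesign(
            labels=list("ABCD"),
            assignment={e1.name: PairCode.of("A", "C"), e2.name: PairCode.of("B", "D")},
        )
        runs = make_runs(
            A=[ri_peak(1500.0)], B=[ri_peak(1500.0)],
            C=[ri_peak(1500.0)], D=[ri_peak(1500.0)],
        )
        idents, _ = identify_batch(lib, design, runs)
        assert [i.status for i in idents] == [IdStatus.CONFIRMED, IdStatus.CONFIRMED]

    def test_missing_run_for_label_rejected(self, table2_batch):
        lib, design, runs, ladders = table2_batch
        partial = {k: v for k, v in runs.items() if k != "D"}
        with pytest.raises(ValueError, match="D"):
            identify_batch(lib, design, partial, ladders)

    def test_updated_ri_is_intensity_weighted_mean(self):
        entry = LibraryEntry("X", "(TMS)", expected_ri=1500.0, ident_code=frozenset({"A", "B"}))
        from identmix import CompoundLibrary, MixDesign

        lib = CompoundLibrary(entries=[entry])
        design = MixDesign(labels=list("ABCD"),
                           assignment={entry.name: PairCode.of("A", "B")})
        runs = make_runs(
            A=[ri_peak(1499.8, intensity=300.0)],
            B=[ri_peak(1500.4, intensity=100.0)],
            C=[], D=[],
        )
        idents, updated = identify_batch(lib, design, runs)
        expected = (1499.8 * 300 + 1500.4 * 100) / 400
        assert idents[0].updated_ri == pytest.approx(expected)
        assert updated.entries[0].expected_ri == pytest.approx(expected)

    def test_entry_without_code_flagged_unvalidated(self):
        entry = LibraryEntry("X", "(TMS)", expected_ri=1500.0)
        from identmix import CompoundLibrary, MixDesign

        lib = CompoundLibrary(entries=[entry])
        design = MixDesign(labels=list("ABCD"), assignment={})
        runs = make_runs(A=[ri_peak(1500.0)], B=[], C=[], D=[])
        idents, _ = identify_batch(lib, design, runs)
        assert idents[0].status is IdStatus.UNVALIDATED


class TestResolveIsomers:
    def test_mannose_glucose_swap(self):
        """A peak cluster present in A and D goes to the {A,D} candidate."""
        mannose = LibraryEntry("Mannose", "(MeOX)(5TMS)", expected_ri=1876.0,
                               ident_code=frozenset({"A", "D"}))
        glucose = LibraryEntry("Glucose", "(MeOX)(5TMS)", expected_ri=1886.0,
                               ident_code=frozenset({"B", "D"}))
        from identmix import CompoundLibrary, MixDesign

        lib = CompoundLibrary(entries=[mannose, glucose])
        design = MixDesign(
            labels=list("ABCD"),
            assignment={mannose.name: PairCode.of("A", "D"),
                        glucose.name: PairCode.of("B", "D")},
        )
        # only the mannose cluster is present: peaks at 1876 in A and D;
        # the D peak also falls inside glucose's window (|1876-1886| = 10)
        runs = make_runs(A=[ri_peak(1876.0)], B=[], C=[], D=[ri_peak(1876.0)])
        idents, _ = identify_batch(lib, design, runs)
        by_name = {i.entry.compound_name: i for i in idents}
        assert by_name["Mannose"].status is IdStatus.CONFIRMED
        assert by_name["Glucose"].status is IdStatus.NOT_FOUND

    def test_identical_codes_on_same_peak_are_ambiguous(self):
        e1 = LibraryEntry("Twin1", "(TMS)", expected_ri=1500.0, ident_code=frozenset({"A", "B"}))
        e2 = LibraryEntry("Twin2", "(TMS)", expected_ri=1503.0, ident_code=frozenset({"A", "B"}))
        from identmix import CompoundLibrary, MixDesign

        lib = CompoundLibrary(entries=[e1, e2])
        design = MixDesign(
            labels=list("ABCD"),
            assignment={e1.name: PairCode.of("A", "B"), e2.name: PairCode.of("A", "B")},
        )
        runs = make_runs(A=[ri_peak(1501.0)], B=[ri_peak(1501.0)], C=[], D=[])
        idents, _ = identify_batch(lib, design, runs)
        assert all(i.status is IdStatus.AMBIGUOUS for i in idents)


class TestReplicateConsistency:
    def test_inconsistent_code_mix_peaks_demoted_to_conflict(self):
        """Peaks in the two code mixes that disagree in retention beyond the
        within-batch tolerance are not replicates of one analyte: borrowing
        one neighbour's peak per mix must never assemble a confirmation."""
        entry = LibraryEntry("X", "(TMS)", expected_ri=1500.0, ident_code=frozenset({"A", "C"}))
        from identmix import CompoundLibrary, MixDesign

        lib = CompoundLibrary(entries=[entry])
        design = MixDesign(labels=list("ABCD"),
                           assignment={entry.name: PairCode.of("A", "C")})
        # both peaks inside X's +-10 window, but 6.5 RI units apart
        runs = make_runs(A=[ri_peak(1495.0)], B=[], C=[ri_peak(1501.5)], D=[])
        idents, _ = identify_batch(lib, design, runs)
        assert idents[0].status is IdStatus.CONFLICT
        assert "retention" in idents[0].notes

    def test_consistent_pair_preferred_over_most_intense(self):
        """When a mix holds both a neighbour's intense peak and the entry's
        own weaker one, the cross-mix consistent pair wins."""
        entry = LibraryEntry("X", "(TMS)", expected_ri=1500.0, ident_code=frozenset({"A", "C"}))
        from identmix import CompoundLibrary, MixDesign

        lib = CompoundLibrary(entries=[entry])
        design = MixDesign(labels=list("ABCD"),
                           assignment={entry.name: PairCode.of("A", "C")})
        runs = make_runs(
            A=[ri_peak(1500.1, 200.0)],
            B=[],
            C=[ri_peak(1505.0, 900.0), ri_peak(1499.9, 150.0)],
            D=[],
        )
        idents, _ = identify_batch(lib, design, runs)
        assert idents[0].status is IdStatus.CONFIRMED
        assert idents[0].matched_peaks["C"].ri == 1499.9


class TestRobustness:
    def test_decoys_outside_windows_change_nothing(self, table2_batch):
        lib, design, runs, ladders = table2_batch
        baseline, _ = identify_batch(lib, design, runs, ladders)
        spiked = {
            label: PeakList(label, run.peaks + [Peak(rt=_rt_of(2500.0 + i), intensity=5e4)
                                                for i in range(3)])
            for i, (label, run) in enumerate(runs.items())
        }
        idents, _ = identify_batch(lib, design, spiked, ladders)
        assert [i.status for i in idents] == [i.status for i in baseline]

    def test_deleting_one_mix_peak_never_confirms_wrongly(self):
        """Exclusion safety: a missing code-mix peak yields conflict or
        not_found, never a confirmed identity with the wrong pattern."""
        cfg = SimulationConfig(n_compounds=30, k=4, n_clusters=3, noise_sd=0.0, seed=11)
        lib, design, runs, ladders = _simulated_batch(cfg)
        victim = lib.entries[0]
        label = sorted(victim.ident_code)[0]
        pruned = dict(runs)
        keep = [p for p in runs[label].peaks if abs(p.rt - _rt_of(victim.expected_ri)) > 1e-9]
        pruned[label] = PeakList(label, keep)
        idents, _ = identify_batch(lib, design, pruned, ladders)
        by_name = {i.entry.name: i for i in idents}
        assert by_name[victim.name].status in (IdStatus.CONFLICT, IdStatus.NOT_FOUND)
        for ident in idents:
            if ident.status is IdStatus.CONFIRMED:
                assert ident.observed_pattern.present == ident.entry.ident_code

    def test_status_frequencies_reproducible_given_seed(self):
        cfg = SimulationConfig(n_compounds=40, k=4, dropout_rate=0.15, decoy_rate=0.1, seed=5)
        first = _status_counts(cfg)
        second = _status_counts(cfg)
        assert first == second


def _rt_of(ri, ladder=None):
    from identmix.retention import rt_for_ri
    from identmix.synth import default_ladder

    return rt_for_ri(ri, ladder or default_ladder())


def _simulated_batch(cfg):
    lib, design = generate_truth(cfg)
    runs, ladders = generate_peaklists(lib, design, cfg)
    return lib, design, runs, ladders


def _status_counts(cfg):
    lib, design, runs, ladders = _simulated_batch(cfg)
    idents, _ = identify_batch(lib, design, runs, ladders)
    statuses = sorted(i.status.value for i in idents)
    return statuses
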