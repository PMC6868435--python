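"""Cycle segmentation, rupture detection, classification and switching."""

import numpy as np
import pytest

import fretforce as ff
from fretforce.pulling_analysis import HalfCycle, mean_E_vs_force


def make_half(e, f_lo=1.0, f_hi=28.0, phase="stretch", mol="m1", cyc=0):
    e = np.asarray(e, dtype=float)
    n = len(e)
    force = np.linspace(f_lo, f_hi, n) if phase == "stretch" else np.linspace(f_hi, f_lo, n)
    return HalfCycle(
        molecule_id=mol,
        cycle_index=cyc,
        phase=phase,
        time=np.arange(n) * 0.02,
        stage=np.linspace(14000, 16960, n),
        force=force,
        efficiency=e,
    )


def step_half(f_step, e_hi=0.80, e_lo=0.08, n=400, f_lo=1.0, f_hi=28.0):
    force = np.linspace(f_lo, f_hi, n)
    e = np.where(force < f_step, e_hi, e_lo)
    half = make_half(e, f_lo, f_hi)
    half = HalfCycle(**{**half.__dict__, "force": force, "efficiency": e})
    return half


class TestSegmentation:
    def test_four_cycles_yield_four_pairs(self):
        cycles, _ = ff.gen_pulling_ensemble(
            ff.PullingEnsembleSpec(species={"type_I": 4}, cycles_per_molecule=4), seed=2
        )
        halves = ff.segment_cycles(cycles)
        assert len(halves) == 4
        for stretch, relax in halves:
            assert stretch.phase == "stretch" and relax.phase == "relax"
            assert np.all(np.diff(stretch.stage) > 0)
            assert np.all(np.diff(relax.stage) < 0)

    def test_boundary_matches_generator_within_one_sample(self):
        cycles, _ = ff.gen_pulling_ensemble(
            ff.PullingEnsembleSpec(species={"type_II": 2}, cycles_per_molecule=2), seed=3
        )
        for cyc, (stretch, _) in zip(cycles, ff.segment_cycles(cycles)):
            truth_boundary = np.sum(cyc.direction == "stretch") - 1
            assert abs((len(stretch.time) - 1) - truth_boundary) <= 1

    def test_truncated_relax_flagged_partial(self):
        cycles, _ = ff.gen_pulling_ensemble(
            ff.PullingEnsembleSpec(species={"type_I": 1}, cycles_per_molecule=1), seed=4
        )
        cyc = cycles[0]
        n = cyc.n_samples
        cut = int(0.75 * n)  # drop the tail of the relax half
        trimmed = ff.PullingCycle(
            molecule_id=cyc.molecule_id,
            cycle_index=cyc.cycle_index,
            time=cyc.time[:cut],
            stage_position=cyc.stage_position[:cut],
            force=cyc.force[:cut],
            donor=cyc.donor[:cut],
            acceptor=cyc.acceptor[:cut],
            direction=cyc.direction[:cut],
        )
        (_, relax), = ff.segment_cycles([trimmed])
        assert relax.partial

    def test_bad_direction_flags_rejected(self):
        cycles, _ = ff.gen_pulling_ensemble(
            ff.PullingEnsembleSpec(species={"type_I": 1}, cycles_per_molecule=1), seed=5
        )
        cyc = cycles[0]
        flags = np.array(cyc.direction, copy=True)
        flags[:] = "stretch"
        flags[1] = "relax"
        flags[2:] = "stretch"
        with pytest.raises(ff.TraceValidationError):
            bad = ff.PullingCycle(
                molecule_id="m",
                cycle_index=0,
                time=cyc.time[:10],
                stage_position=cyc.stage_position[:10],
                force=cyc.force[:10],
                donor=cyc.donor[:10],
                acceptor=cyc.acceptor[:10],
                direction=flags[:10],
            )
            ff.segment_cycles([bad])


class TestDetectRupture:
    def test_constructed_drop_at_seven_piconewton(self):
        half = step_half(7.0)
        (event,) = ff.detect_rupture(half)
        assert event.kind == "unfold"
        assert event.force == pytest.approx(7.0, abs=0.2)
        assert event.e_before == pytest.approx(0.80, abs=0.02)
        assert event.e_after == pytest.approx(0.08, abs=0.02)

    def test_gradual_decline_produces_no_event(self):
        e = np.linspace(0.75, 0.25, 400)  # Type I strand slippage
        assert ff.detect_rupture(make_half(e)) == []

    def test_two_drops_returned_in_force_order(self):
        n = 600
        force = np.linspace(1.0, 28.0, n)
        e = np.full(n, 0.85)
        e[force >= 8.0] = 0.40  # delta 0.45: the dominant transition
        e[force >= 18.0] = 0.08  # delta 0.32
        half = make_half(e)
        half.force = force
        events = ff.detect_rupture(half)
        assert len(events) == 2
        assert events[0].force < events[1].force
        biggest = max(events, key=lambda ev: ev.delta_e)
        assert biggest.force == pytest.approx(8.0, abs=0.3)

    def test_refold_kind_on_relax_half(self):
        n = 400
        force = np.linspace(28.0, 1.0, n)
        e = np.where(force > 4.0, 0.08, 0.78)
        half = make_half(e, phase="relax")
        half.force = force
        (event,) = ff.detect_rupture(half)
        assert event.kind == "refold"
        assert event.force == pytest.approx(4.0, abs=0.3)

    def test_short_half_rejected(self):
        with pytest.raises(ValueError):
            ff.detect_rupture(make_half(np.full(5, 0.8)))


class TestClassifyCycle:
    def test_noiseless_archetypes_classify_exactly(self):
        spec = ff.PullingEnsembleSpec(
            species={"complete": 5, "type_I": 5, "type_II": 5}, e_noise=0.0
        )
        cycles, truth = ff.gen_pulling_ensemble(spec, seed=1)
        labels, _ = ff.classify_ensemble(cycles)
        truth_map = {
            (r.molecule_id, r.cycle): r.archetype for r in truth.itertuples()
        }
        for lab in labels:
            assert lab.label == truth_map[(lab.molecule_id, lab.cycle_index)]

    def test_type_II_range_is_respected(self):
        e = np.concatenate([np.full(50, 0.68), np.linspace(0.68, 0.37, 350)])
        lab = ff.classify_cycle(make_half(e))
        assert lab.label == "type_II"
        assert 0.30 <= lab.lowest_e < 0.45

    def test_ultrastable_cycle_is_no_unfolding(self):
        lab = ff.classify_cycle(make_half(np.full(400, 0.8)))
        assert lab.label == "no_unfolding"

    def test_cycle_not_reaching_max_force_excluded(self):
        half = make_half(np.full(400, 0.8), f_hi=20.0)
        with pytest.warns(UserWarning):
            assert ff.classify_cycle(half, f_max=28.0) is None

    def test_archetype_fractions_recovered_at_noise(self):
        spec = ff.PullingEnsembleSpec()  # exact counts 58/150/55, sigma 0.03
        cycles, _ = ff.gen_pulling_ensemble(spec, seed=4)
        labels, _ = ff.classify_ensemble(cycles)
        frac = {
            lab: sum(1 for l in labels if l.label == lab) / len(labels)
            for lab in ("complete", "type_I", "type_II")
        }
        assert frac["complete"] == pytest.approx(58 / 263, abs=0.02)
        assert frac["type_I"] == pytest.approx(150 / 263, abs=0.02)
        assert frac["type_II"] == pytest.approx(55 / 263, abs=0.02)


class TestSwitchingStats:
    def test_pair_counting(self):
        mat = ff.switching_stats({"m1": ["complete", "type_I", "type_I", "complete"]})
        i = mat.labels.index("complete")
        j = mat.labels.index("type_I")
        assert mat.counts[i, j] == 1
        assert mat.counts[j, j] == 1
        assert mat.counts[j, i] == 1
        assert mat.counts.sum() == 3

    def test_identical_labels_have_zero_off_diagonal(self):
        mat = ff.switching_stats({"m1": ["type_I"] * 5, "m2": ["type_I"] * 3})
        off = mat.counts.sum() - np.trace(mat.counts)
        assert off == 0
        assert mat.conditional_switch_fraction()["type_I"] == 0.0

    def test_no_pairs_raises(self):
        with pytest.raises(ff.InsufficientDataError):
            ff.switching_stats({"m1": ["complete"]})

    def test_markov_generator_switch_fractions_recovered(self):
        switching = {
            "complete": {"complete": 0.67, "type_I": 0.33},
            "type_I": {"complete": 0.16, "type_I": 0.84},
        }
        spec = ff.PullingEnsembleSpec(
            species={"complete": 120, "type_I": 120},
            exact_counts=False,
            switching=switching,
            cycles_per_molecule=4,
        )
        cycles, truth = ff.gen_pulling_ensemble(spec, seed=8)
        labels, _ = ff.classify_ensemble(cycles)
        by_mol = {}
        for lab in labels:
            by_mol.setdefault(lab.molecule_id, []).append(lab)
        mat = ff.switching_stats(by_mol)
        frac = mat.conditional_switch_fraction()
        i = mat.labels.index("complete")
        n_c = mat.counts[i].sum()
        se_c = np.sqrt(0.33 * 0.67 / max(n_c, 1))
        assert abs(frac["complete"] - 0.33) < 2 * se_c + 0.02
        j = mat.labels.index("type_I")
        n_t = mat.counts[j].sum()
        se_t = np.sqrt(0.16 * 0.84 / max(n_t, 1))
        assert abs(frac["type_I"] - 0.16) < 2 * se_t + 0.02


class TestMeanEVsForce:
    def test_noiseless_type_I_curve_matches_archetype(self):
        spec = ff.PullingEnsembleSpec(species={"type_I": 6}, e_noise=0.0)
        cycles, _ = ff.gen_pulling_ensemble(spec, seed=6)
        _, halves = ff.classify_ensemble(cycles)
        table = mean_E_vs_force({"type_I": [h for h, _ in halves]})
        arch = ff.ARCHETYPES["type_I"]
        for row in table.itertuples():
            expected = float(arch.e_of_force(row.force_bin_pN))
            assert abs(row.mean_E - expected) < 0.02  # within half-bin curvature

    def test_se_shrinks_with_ensemble_size(self):
        small = ff.PullingEnsembleSpec(species={"type_I": 8})
        large = ff.PullingEnsembleSpec(species={"type_I": 32})
        tables = []
        for spec in (small, large):
            cycles, _ = ff.gen_pulling_ensemble(spec, seed=9)
            _, halves = ff.classify_ensemble(cycles)
            tables.append(mean_E_vs_force({"type_I": [h for h, _ in halves]}))
        merged = tables[0].merge(
            tables[1], on="force_bin_pN", suffixes=("_small", "_large")
        )
        ratio = np.nanmedian(merged.se_E_small / merged.se_E_large)
        assert 1.3 < ratio < 3.2  # ~2 expected for 4x the cycles

    def test_single_cycle_has_undefined_se(self):
        spec = ff.PullingEnsembleSpec(species={"type_I": 1}, cycles_per_molecule=1)
        cycles, _ = ff.gen_pulling_ensemble(spec, seed=10)
        _, halves = ff.classify_ensemble(cycles)
        table = mean_E_vs_force({"type_I": [halves[0][0]]})
        assert table.se_E.isna().all()
        assert (table.n_cycles == 1).all()


class TestRuptureForceTable:
    def test_events_counted_and_censoring_recorded(self):
        spec = ff.PullingEnsembleSpec(
            species={"complete": 20, "ultrastable": 3}, cycles_per_molecule=4
        )
        cycles, _ = ff.gen_pulling_ensemble(spec, seed=12)
        labels, _ = ff.classify_ensemble(cycles)
        table, samples = ff.rupture_force_table(labels, "complete")
        assert len(samples.forces) == 20
        assert samples.n_censored == 3
        assert (table[table.is_primary].kind == "unfold").all()

    def test_end_to_end_kinetic_recovery(self, schedule):
        """Generator -> detection -> truncated MLE recovers the pathway."""
        spec = ff.PullingEnsembleSpec(species={"complete": 300})
        cycles, _ = ff.gen_pulling_ensemble(spec, seed=11)
        labels, _ = ff.classify_ensemble(cycles)
        _, samples = ff.rupture_force_table(labels, "complete")
        fit = ff.fit_ds(samples, 1, schedule, n_starts=6, seed=0, truncated=True)
        c = fit.mixture.components[0]
        truth = ff.ARCHETYPES["complete"].rupture_model
        assert abs(c.dx_dagger - truth.dx_dagger) / truth.dx_dagger < 0.15
        assert abs(np.log(c.tau0 / truth.tau0)) < 0.3
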