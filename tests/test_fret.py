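"""FRET measurement, ordered restriction criteria, bleach and quench controls."""

import numpy as np
import pytest

from synaptraffick.fret import (
    FretSynapseRecord,
    acceptor_bleach_timecourse,
    apply_restriction_criteria,
    fret_participation,
    measure_synapse_fret,
    normalize_to_control,
    ph_quench_control,
)
from synaptraffick.puncta import ChannelImage, detect_clusters
from synaptraffick.scenes import (
    KineticTruth,
    make_dendrite_scene,
    simulate_bleach_series,
    simulate_fret_pair,
)
from tests.conftest import well_separated_truth


def rec(i, donor_sum=10000.0, donor_mean=1000.0, fret_sum=50.0,
        total=100.0):
    return FretSynapseRecord(synapse_id=i, donor_sum=donor_sum,
                             donor_mean=donor_mean, fret_sum=fret_sum,
                             total_acceptor_sum=total)


def fret_scene(efficiency, coupling=0.5, donor_peak=2000.0,
               acceptor_peak=1500.0, bleed_through=0.0):
    """Three-channel scene obeying the donor-quenching emission model."""
    truth = well_separated_truth(n_synaptic=10, n_extrasynaptic=0,
                                 peak=donor_peak)
    base, truth = make_dendrite_scene(truth, channels=("shape",),
                                      marker_channel="_none")
    shape_px = base["shape"].pixels - truth.background_level  # unit profile
    profile = shape_px / donor_peak
    px = truth.pixel_size_um
    donor = ChannelImage(profile * donor_peak * (1 - efficiency) + 10.0,
                         px, "donor")
    fret = ChannelImage(profile * acceptor_peak * efficiency * coupling
                        + bleed_through, px, "fret")
    total = ChannelImage(profile * acceptor_peak + 10.0, px, "total")
    return donor, fret, total, truth


class TestMeasureSynapseFret:
    def _clusters(self, donor, truth):
        mask = donor.pixels >= 0.5 * donor.pixels.max()
        return detect_clusters(mask, donor, (0.0, 3.0))

    def test_cluster_without_acceptor_signal_dropped(self):
        donor, fret, total, truth = fret_scene(efficiency=0.2)
        flat_total = ChannelImage(np.full(total.shape, 1.0), 0.1, "total")
        clusters = self._clusters(donor, truth)
        records, dropped = measure_synapse_fret(
            donor, fret, flat_total, clusters, acceptor_threshold=100.0)
        assert records == [] and dropped == len(clusters)

    def test_zero_efficiency_gives_zero_fret_sums(self):
        donor, fret, total, truth = fret_scene(efficiency=0.0)
        records, _ = measure_synapse_fret(donor, fret, total,
                                          self._clusters(donor, truth))
        assert records and all(r.fret_sum == pytest.approx(0.0, abs=1e-9)
                               for r in records)

    def test_ratio_follows_simulator_algebra(self):
        # E=0.2, coupling 0.5 -> fret/total ~ 0.1 per cluster
        donor, fret, total, truth = fret_scene(efficiency=0.2, coupling=0.5)
        records, _ = measure_synapse_fret(donor, fret, total,
                                          self._clusters(donor, truth))
        assert records
        for r in records:
            assert r.fret_total_ratio == pytest.approx(0.1, rel=0.1)

    def test_shape_mismatch_rejected(self):
        donor, fret, total, truth = fret_scene(efficiency=0.1)
        bad = ChannelImage(np.ones((4, 4)), 0.1, "fret")
        with pytest.raises(ValueError, match="shape"):
            measure_synapse_fret(donor, bad, total,
                                 self._clusters(donor, truth))


class TestRestrictionCriteria:
    def test_small_cell_rejected_wholesale(self):
        records = [rec(i) for i in range(14)]
        res = apply_restriction_criteria(records, cell_id="c")
        assert res.rejected and "15" in res.rejection_reason
        assert res.records == []

    def test_ratio_at_least_one_dropped(self):
        records = [rec(i) for i in range(15)]
        records[0].fret_sum = 120.0  # ratio 1.2
        res = apply_restriction_criteria(records)
        assert res.drop_counts["criterion_2_ratio"] == 1
        assert all(r.fret_total_ratio < 1 for r in res.records)

    def test_donor_mean_boundary_inclusive(self):
        records = [rec(i) for i in range(16)]
        records[0].donor_mean = 499.0
        records[1].donor_mean = 500.0
        res = apply_restriction_criteria(records)
        assert res.drop_counts["criterion_3_donor_floor"] == 1
        ids = {r.synapse_id for r in res.records}
        assert 0 not in ids and 1 in ids

    def test_sum_cap_uses_survivors_of_prior_criteria(self):
        # 15 synapses at donor_sum 10000 plus one bright outlier at 40000:
        # survivor mean (after 2-3, all survive) = 11875, cap = 35625
        records = [rec(i) for i in range(15)] + [rec(15, donor_sum=40000.0)]
        res = apply_restriction_criteria(records)
        assert res.drop_counts["criterion_4_sum_cap"] == 1
        assert all(r.donor_sum <= 3 * 11875.0 for r in res.records)

    def test_each_criterion_removes_designed_violators(self):
        records = [rec(i) for i in range(17)]
        records[3].fret_sum = 200.0         # violates criterion 2
        records[5].donor_mean = 100.0       # violates criterion 3
        records[7].donor_sum = 10_000_000.0  # violates criterion 4
        res = apply_restriction_criteria(records)
        assert res.drop_counts == {
            "criterion_1_min_synapses": 0, "criterion_2_ratio": 1,
            "criterion_3_donor_floor": 1, "criterion_4_sum_cap": 1}
        assert {r.synapse_id for r in res.records} == \
            set(range(17)) - {3, 5, 7}

    def test_idempotent_on_own_output(self):
        records = [rec(i, donor_sum=10000 + 100 * i) for i in range(20)]
        records[0].fret_sum = 150.0
        records[1].donor_mean = 50.0
        first = apply_restriction_criteria(records, min_synapses=15)
        again = apply_restriction_criteria(first.records, min_synapses=15)
        assert [r.synapse_id for r in again.records] == \
            [r.synapse_id for r in first.records]

    def test_raising_donor_floor_never_grows_survivors(self):
        rng = np.random.default_rng(2)
        records = [rec(i, donor_mean=float(rng.uniform(200, 2000)))
                   for i in range(30)]
        prev = None
        for floor in (100, 400, 800, 1600):
            res = apply_restriction_criteria(list(records),
                                             donor_mean_floor=floor)
            ids = {r.synapse_id for r in res.records}
            if prev is not None:
                assert ids <= prev
            prev = ids

    def test_no_valid_synapses_flagged(self):
        records = [rec(i, donor_mean=10.0) for i in range(15)]
        res = apply_restriction_criteria(records)
        assert res.rejected and res.rejection_reason == "no valid synapses"


class TestParticipation:
    def test_simple_ratio(self):
        res = apply_restriction_criteria([rec(i, fret_sum=50.0, total=100.0)
                                          for i in range(15)])
        assert fret_participation(res) == pytest.approx(0.5)

    def test_zero_efficiency_scene_ratio_near_zero(self):
        res = apply_restriction_criteria([rec(i, fret_sum=0.0)
                                          for i in range(15)])
        assert fret_participation(res) == 0.0

    def test_always_below_one_after_criteria(self):
        rng = np.random.default_rng(9)
        records = [rec(i, fret_sum=float(rng.uniform(0, 200)), total=100.0)
                   for i in range(40)]
        res = apply_restriction_criteria(records)
        assert fret_participation(res) < 1.0


class TestAcceptorBleach:
    def test_simulated_dequench_and_efficiency(self):
        kin = KineticTruth(fret_efficiency=0.2)
        donor, fret, bi = simulate_bleach_series(kin, donor_true=100.0,
                                                 acceptor_true=100.0)
        rep = acceptor_bleach_timecourse(donor, fret, bi)
        assert rep.donor_dequench_pct == pytest.approx(25.0, abs=1e-6)
        assert rep.efficiency_estimate == pytest.approx(0.2, abs=1e-9)
        assert not rep.incomplete_bleach

    def test_zero_efficiency_null_result(self):
        kin = KineticTruth(fret_efficiency=0.0)
        donor, fret, bi = simulate_bleach_series(kin)
        rep = acceptor_bleach_timecourse(donor, fret, bi)
        assert rep.donor_dequench_pct == pytest.approx(0.0, abs=1e-9)
        assert rep.efficiency_estimate == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("e", [0.05, 0.1, 0.3])
    def test_efficiency_recovered_under_noise(self, e):
        kin = KineticTruth(fret_efficiency=e)
        donor, fret, bi = simulate_bleach_series(
            kin, donor_true=100.0, acceptor_true=100.0, noise_sd=2.0,
            seed=int(e * 100))
        rep = acceptor_bleach_timecourse(donor, fret, bi)
        assert rep.efficiency_estimate == pytest.approx(e, abs=0.02)

    @pytest.mark.parametrize("gain", [0.5, 10.0])
    def test_estimate_invariant_to_global_rescale(self, gain):
        kin = KineticTruth(fret_efficiency=0.15)
        donor, fret, bi = simulate_bleach_series(kin)
        a = acceptor_bleach_timecourse(donor, fret, bi)
        b = acceptor_bleach_timecourse(donor * gain, fret * gain, bi)
        assert a.efficiency_estimate == pytest.approx(b.efficiency_estimate)

    def test_incomplete_bleach_warned(self):
        donor = [80, 80, 80, 85, 85]
        fret = [100, 100, 100, 80, 80]  # only 20% reduction
        with pytest.warns(UserWarning, match="incomplete"):
            rep = acceptor_bleach_timecourse(donor, fret, bleach_index=3)
        assert rep.incomplete_bleach

    def test_requires_two_prebleach_frames(self):
        with pytest.raises(ValueError, match="pre-bleach"):
            acceptor_bleach_timecourse([80, 100], [100, 0], bleach_index=1)


class TestPhQuench:
    def test_simple_ratio(self):
        assert ph_quench_control([100.0], [5.0]) == pytest.approx(0.05)

    def test_full_quench_limit(self):
        kin = KineticTruth(fret_efficiency=0.2)
        _, f_hbs, _ = simulate_fret_pair(kin, donor_true=100, acceptor_true=100)
        _, f_mes, _ = simulate_fret_pair(kin, donor_true=0.0,
                                         acceptor_true=100)
        # donor quenched: FRET channel collapses (no donor to transfer from)
        assert ph_quench_control([f_hbs], [f_mes * 0.0 + f_mes]) \
            == pytest.approx(f_mes / f_hbs)
        assert f_mes / f_hbs == pytest.approx(0.0, abs=1e-9) or f_mes == 0

    def test_bleed_through_only_signal_unchanged(self):
        kin = KineticTruth(fret_efficiency=0.0)
        _, f_hbs, _ = simulate_fret_pair(kin, donor_true=100,
                                         acceptor_true=100, bleed_through=7.0)
        _, f_mes, _ = simulate_fret_pair(kin, donor_true=0.0,
                                         acceptor_true=100, bleed_through=7.0)
        assert ph_quench_control([f_hbs], [f_mes]) == pytest.approx(1.0)

    def test_zero_hbs_rejected(self):
        with pytest.raises(ValueError, match="HBS"):
            ph_quench_control([0.0], [1.0])


def test_normalize_to_control_scale():
    out = normalize_to_control([50.0, 100.0, 150.0], control_mean=100.0)
    np.testing.assert_allclose(out, [50.0, 100.0, 150.0])
    with pytest.raises(ValueError):
        normalize_to_control([1.0], 0.0)
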