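"""Morphodynamic event detectors: examples, oracles, recovery."""

import numpy as np
import pytest

from ctlkit.couples import (CoupleTrack, coupling_fraction,
                            detect_detachment, detect_tight_coupling,
                            detect_translocation,
                            first_off_interface_lamella,
                            interface_diameter_ratio, score_events)
from ctlkit.presets import get_preset
from ctlkit.sim import gen_couple_tracks

DT = 20.0


def make_track(ratios, angles=None, arc=None, couple_id="t"):
    n = len(ratios)
    ratios = np.asarray(ratios, float)
    return CoupleTrack(
        couple_id=couple_id, frame_interval_s=DT,
        times_s=np.arange(n) * DT,
        interface_width_um=ratios * 10.0,
        ctl_width_um=np.full(n, 10.0),
        arc_pos_um=np.zeros(n) if arc is None else np.asarray(arc, float),
        lamella_angles_deg=[[] for _ in range(n)] if angles is None
        else [list(a) for a in angles],
        contact_flag=np.ones(n, dtype=bool))


# ---------------------------------------------------------------------------
# Brute-force frame-scan oracles (independent of the implementation)
# ---------------------------------------------------------------------------

def oracle_coupling(track, rmin, persist):
    r = track.interface_width_um / track.ctl_width_um
    for i in range(len(r) - persist + 1):
        if all(r[i + j] >= rmin for j in range(persist)):
            return track.times_s[i]
    return None


def oracle_detach(track, t_c, amin, persist):
    frames = [k for k in range(len(track)) if track.times_s[k] >= t_c]
    for s in range(len(frames) - persist + 1):
        if all(any(a >= amin for a in track.lamella_angles_deg[frames[s + j]])
               for j in range(persist)):
            return True, track.times_s[frames[s]] - t_c
    return False, None


class TestTightCoupling:
    def test_ratio_one_from_frame_three(self):
        r = [0.1, 0.2, 0.1] + [1.0] * 5
        assert detect_tight_coupling(make_track(r)) == 60.0

    def test_never_couples(self):
        assert detect_tight_coupling(make_track([0.2] * 10)) is None

    def test_persistence_requirement(self):
        r = [0.1, 1.0, 0.1, 1.0, 1.0, 0.1]
        assert detect_tight_coupling(make_track(r)) == 60.0

    def test_matches_frame_scan_oracle(self, rng):
        for _ in range(50):
            r = rng.uniform(0.4, 1.1, 20)
            tr = make_track(r)
            assert detect_tight_coupling(tr) == oracle_coupling(tr, 0.8, 2)


class TestOffInterfaceLamella:
    def test_first_off_lamella_two_frames_after_coupling(self):
        angles = [[], [], [120.0], [120.0]]
        tr = make_track([1.0] * 4, angles=angles)
        assert first_off_interface_lamella(tr, 0.0) == 40.0

    def test_proximal_lamellae_do_not_count(self):
        tr = make_track([1.0] * 6, angles=[[30.0]] * 6)
        assert first_off_interface_lamella(tr, 0.0) is None

    def test_matches_frame_scan_oracle(self, rng):
        for _ in range(50):
            angles = [[rng.uniform(0, 180)] if rng.random() < 0.4 else []
                      for _ in range(15)]
            tr = make_track([1.0] * 15, angles=angles)
            want = next((t - 40.0 for t, fa in zip(tr.times_s, angles)
                         if t >= 40.0 and any(a >= 90 for a in fa)), None)
            assert first_off_interface_lamella(tr, 40.0) == want


class TestTranslocation:
    def test_constant_arc_is_negative(self):
        assert detect_translocation(make_track([1.0] * 10), 0.0) is False

    def test_monotone_drift_is_positive(self):
        arc = np.linspace(0, 10, 10)
        assert detect_translocation(make_track([1.0] * 10, arc=arc), 0.0)

    def test_net_not_cumulative_displacement(self):
        # oscillation travels far cumulatively but never 5 um from start
        arc = 2.0 * np.sin(np.linspace(0, 10 * np.pi, 40))
        assert detect_translocation(make_track([1.0] * 40, arc=arc),
                                    0.0) is False

    def test_sensitivity_and_specificity_on_ground_truth(self):
        """Noise-free synthetic cohort: detector >= 0.95 on both."""
        tracks, truths = gen_couple_tracks("MEL5mC_A375_noAg", 600, 21)
        tp = fp = fn = tn = 0
        for tr, g in zip(tracks, truths):
            if not g.coupled:
                continue
            got = detect_translocation(tr, 0.0)
            tp += got and g.translocated
            fp += got and not g.translocated
            fn += (not got) and g.translocated
            tn += (not got) and not g.translocated
        assert tp / (tp + fn) >= 0.95
        assert tn / (tn + fp) >= 0.95


class TestDetachment:
    def test_persistent_opposite_lamella(self):
        angles = [[] for _ in range(10)]
        for k in (4, 5, 6):
            angles[k] = [170.0]
        tr = make_track([1.0] * 10, angles=angles)
        detached, t = detect_detachment(tr, 0.0)
        assert detached and t == 4 * DT

    def test_isolated_frames_do_not_detach(self):
        angles = [[170.0] if k % 2 == 0 else [] for k in range(10)]
        tr = make_track([1.0] * 10, angles=angles)
        assert detect_detachment(tr, 0.0) == (False, None)

    def test_matches_frame_scan_oracle(self, rng):
        for _ in range(50):
            angles = [[rng.uniform(100, 180)] if rng.random() < 0.5 else []
                      for _ in range(15)]
            tr = make_track([1.0] * 15, angles=angles)
            assert detect_detachment(tr, 20.0) == oracle_detach(
                tr, 20.0, 150.0, 3)


class TestInterfaceDiameterRatio:
    def test_sampling_at_requested_times(self):
        r = [0.0, 0.5, 1.0, 1.0]
        out = interface_diameter_ratio(make_track(r), 0.0, [0, 20, 40])
        assert out == pytest.approx([0.0, 0.5, 1.0])


class TestCohorts:
    def test_coupling_fraction_bounds(self):
        all_c = score_events([make_track([1.0] * 5) for _ in range(4)])
        assert coupling_fraction(all_c) == 1.0
        none_c = score_events([make_track([0.1] * 5) for _ in range(4)])
        assert coupling_fraction(none_c) == 0.0

    def test_threshold_monotonicity(self):
        """Raising thresholds never increases event fractions."""
        tracks, _ = gen_couple_tracks("MEL5mC_A375_noAg", 300, 23)
        fracs = []
        for rmin in (0.6, 0.8, 0.95, 1.05):
            ev = score_events(tracks, width_ratio_min=rmin)
            fracs.append(coupling_fraction(ev))
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

        tfracs = []
        ev_tables = [score_events(tracks, displacement_min_um=d)
                     for d in (2.0, 5.0, 9.0)]
        for ev in ev_tables:
            cou = ev[ev["coupled"]]
            tfracs.append(cou["translocated"].mean())
        assert all(a >= b for a, b in zip(tfracs, tfracs[1:]))

    def test_detector_recovery_of_preset_statistics(self):
        """End-to-end: detectors on synthetic cohorts recover the preset
        fractions and event times within 3 standard errors."""
        p = get_preset("1G4_Mel624_kd")
        tracks, _ = gen_couple_tracks("1G4_Mel624_kd", 400, 31)
        ev = score_events(tracks)
        frac = coupling_fraction(ev)
        assert abs(frac - p.coupling_prob) < 3 * np.sqrt(
            p.coupling_prob * (1 - p.coupling_prob) / len(ev))

        cou = ev[ev["coupled"]]
        dfrac = cou["detached"].mean()
        assert abs(dfrac - p.detach_prob) < 3 * np.sqrt(
            p.detach_prob * (1 - p.detach_prob) / len(cou))

        dt_min = cou["t_detach_s"].dropna() / 60.0
        se = dt_min.std(ddof=1) / np.sqrt(len(dt_min))
        assert abs(dt_min.mean() - p.detach_time_mean_min) < 3 * se

    def test_event_times_relative_to_coupling(self):
        tracks, _ = gen_couple_tracks("1G4_SIL_Mel624_pep", 200, 33)
        ev = score_events(tracks)
        cou = ev[ev["coupled"]]
        lam = cou["t_first_off_lamella_s"].dropna()
        assert (lam >= 0).all()
        assert (lam <= cou.loc[lam.index, "horizon_s"]).all()
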