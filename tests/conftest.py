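import dataclasses

import numpy as np
import pytest


def slice_track(track, n_frames):
    """First ``n_frames`` frames of a couple track (for fast rendering)."""
    return dataclasses.replace(
        track,
        times_s=track.times_s[:n_frames],
        interface_width_um=track.interface_width_um[:n_frames],
        ctl_width_um=track.ctl_width_um[:n_frames],
        arc_pos_um=track.arc_pos_um[:n_frames],
        lamella_angles_deg=track.lamella_angles_deg[:n_frames],
        contact_flag=track.contact_flag[:n_frames],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
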