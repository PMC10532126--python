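import numpy as np
import pytest

from thermoresp.losses import LossSpec
from thermoresp.net import NetConfig, build_model
from thermoresp.simulate import BreathingProfile, simulate_sequence
from thermoresp.train import TrainConfig
from thermoresp.windows import WindowSpec, sequence_to_clips


@pytest.fixture
def clean_profile():
    """Noiseless, drift-free 12 bpm sinusoidal breathing."""
    return BreathingProfile(rr_bpm=12.0, amplitude=600.0, noise_sd=0.0,
                            drift_per_s=0.0, seed=7)


@pytest.fixture
def clean_sequence(clean_profile):
    return simulate_sequence(clean_profile, duration_s=15.0, fps=8.7)


@pytest.fixture(scope="session")
def tiny_net_config():
    """Desk-scale architecture used by the fast network tests."""
    return NetConfig(
        window_len=16, alpha=2, beta=8, width_multiplier=0.0625,
        in_channels=1, fusion_kernel_t=5, stem_spatial_k=5,
        residual_spatial_k=3, dropout=0.0,
    )


@pytest.fixture(scope="session")
def tiny_window_spec():
    return WindowSpec(window_len_frames=16, stride_frames=16, target_fps=8.0,
                      out_height=16, out_width=16, channels=1)


@pytest.fixture(scope="session")
def tiny_model(tiny_net_config):
    return build_model(tiny_net_config, seed=3)


@pytest.fixture(scope="session")
def tiny_clips(tiny_window_spec):
    """A handful of clip pairs from two subjects at 16x16 resolution."""
    clips = []
    for i, rr in enumerate((9.0, 14.0, 21.0, 27.0)):
        prof = BreathingProfile(rr_bpm=rr, amplitude=600.0, noise_sd=0.0, seed=i)
        seq = simulate_sequence(prof, duration_s=4.0, fps=8.0,
                                resolution=(16, 16), subject_id=f"S{i % 2}")
        clips.extend(sequence_to_clips(seq, tiny_window_spec, 2, 8))
    return clips


@pytest.fixture
def tiny_train_config(tiny_net_config, tiny_window_spec):
    return TrainConfig(
        loss=LossSpec("mse", "mean"), warmup_epochs=1, warmup_lr=1e-3,
        post_warmup_lr=1e-3, epochs=2, batch_size=4, optimizer="adam",
        seed=5, net=tiny_net_config, window=tiny_window_spec,
    )
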