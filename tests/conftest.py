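import numpy as np
import pytest

from phasetrack import Settings, SyntheticSpec, generate_video


@pytest.fixture
def unit_settings():
    """Settings matched to the synthetic fixtures (1 µm pixels)."""
    # manual z-score limit (the classic -1.5 rule); size gates bracket the
    # apparent (thresholded) blob diameter, slightly above nominal
    return Settings(pixel_size=1.0, time_between_images=10.0,
                    gaussian_radius=3.0, smallest_cell_diameter=5.0,
                    largest_cell_diameter=40.0, cutting_cell_diameter=18.0,
                    highest_cell_velocity=2.0, shortest_cell_track=4,
                    segmentation_limit=-1.5)


@pytest.fixture
def small_video():
    """A small rendered video with ground truth (well-separated cells)."""
    spec = SyntheticSpec(frame_shape=(220, 220), pixel_size=1.0, n_frames=10,
                         n_cells=8, cell_diameter=14.0, cell_diameter_sd=1.0,
                         sigma_step=1.0, noise_sd=2.0,
                         min_separation_factor=2.5, seed=11)
    return generate_video(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
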