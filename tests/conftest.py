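import numpy as np
import pytest

from wormchip import imgen
from wormchip.geometry import TrapGeometry

TRAP_PATCH = 128


@pytest.fixture(scope="session")
def geometry() -> TrapGeometry:
    return TrapGeometry()


def trap_scene_spec(seed: int, n_frames: int = 80, noise_sd: float = 300.0) -> imgen.SceneSpec:
    return imgen.SceneSpec(
        rng_seed=seed,
        pixel_size=0.8,
        frame_interval=10.0,
        n_frames=n_frames,
        noise_sd=noise_sd,
    )


@pytest.fixture(scope="session")
def alive_trap_series():
    """One alive embryo (twitch 300 min, hatch 720 min) with both channels."""
    spec = trap_scene_spec(11, n_frames=80)
    embryo_spec = imgen.EmbryoSpec(
        alive=True,
        t_twitch=300.0,
        t_hatch=720.0,
        intensity_ramp=imgen.IntensityRamp(baseline=1.0, slope=0.001, plateau=1.6),
    )
    return imgen.render_trap_series(spec, embryo_spec, patch_size=TRAP_PATCH)


@pytest.fixture(scope="session")
def dead_trap_series():
    spec = trap_scene_spec(12, n_frames=40, noise_sd=0.0)
    embryo_spec = imgen.EmbryoSpec(alive=False, twitch_amplitude=0.0)
    return imgen.render_trap_series(spec, embryo_spec, patch_size=TRAP_PATCH)


@pytest.fixture(scope="session")
def logistic_chamber():
    """Three worms growing along a known logistic curve, no eggs."""
    spec = imgen.SceneSpec.for_chamber(rng_seed=3, n_frames=49, noise_sd=300.0)
    growth = imgen.LogisticGrowth(lower=1500, upper=6000, rate=0.006, midpoint=700)
    worms = [imgen.WormSpec(growth=growth) for _ in range(3)]
    series, truth = imgen.render_chamber_series(spec, worms)
    return spec, growth, series, truth


@pytest.fixture(scope="session")
def curved_larva():
    spec = imgen.SceneSpec(rng_seed=5, noise_sd=300.0, n_frames=2)
    return imgen.render_larva(spec, length_um=250.0, diameter_um=12.0, gfp_level=2.0)


def make_rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
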