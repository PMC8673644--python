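import numpy as np
import pytest

from clickchain import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def click_spec(**kw) -> simulate.ClickClassSpec:
    """A valid click class with overridable fields (jitter off by default)."""
    defaults = dict(
        name="a",
        center_freq=40_000.0,
        bandwidth=10_000.0,
        duration=300e-6,
        modal_idi=0.1,
        idi_jitter=0.0,
        source_level=150.0,
        freq_jitter=0.0,
        duration_jitter=0.0,
    )
    defaults.update(kw)
    return simulate.ClickClassSpec(**defaults)


def small_scene(tmp_path, duration=10.0, fs=48_000.0, noise_floor=50.0, seed=7, **kw):
    """One-class scene: 15-kHz clicks at 0.1-s spacing, fixed received level."""
    spec = click_spec(
        name="a", center_freq=15_000.0, bandwidth=3_000.0, duration=250e-6,
        modal_idi=0.1, source_level=kw.pop("source_level", 150.0),
    )
    cfg = simulate.SceneConfig(
        fs=fs,
        total_duration=duration,
        noise_floor=noise_floor,
        classes=[spec],
        encounters=[simulate.Encounter("a", 0.0, duration)],
        min_rl=kw.pop("min_rl", 125.0),
        seed=seed,
        **kw,
    )
    wav, truth = simulate.synth_scene(cfg, tmp_path)
    return cfg, wav, truth


def gaussian_spectra(n, center_bin, n_bins=35, width=3.0, noise=0.5, rng=None, baseline=50.0):
    """Synthetic dB spectra: a Gaussian bump on a noisy baseline."""
    rng = rng or np.random.default_rng(0)
    bins = np.arange(n_bins)
    bump = 40.0 * np.exp(-((bins - center_bin) ** 2) / (2 * width**2))
    return baseline + bump + rng.normal(0, noise, (n, n_bins))
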