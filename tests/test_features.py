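"""Feature chain: STFT, Mel projection, dB compression, rendering, augmentation."""

import io

import numpy as np
import pytest
from PIL import Image
from scipy.signal.windows import hann

from dusafnet.features import (
    DB_FLOOR,
    IMG_SIZE,
    N_FRAMES,
    N_MELS,
    AugmentConfig,
    image_augment,
    log_compress,
    mel_filterbank,
    mel_project,
    render_image,
    segment_logmel,
    spec_augment,
    stft_power,
)


class TestStftPower:
    def test_zero_input_zero_power(self):
        p = stft_power(np.zeros(48_000))
        assert p.shape == (257, N_FRAMES)
        assert np.all(p == 0.0)

    def test_frame_count_is_298(self):
        assert N_FRAMES == 1 + (48_000 - 400) // 160 == 298

    def test_tone_maps_to_expected_bin(self):
        t = np.arange(48_000) / 16_000
        p = stft_power(np.sin(2 * np.pi * 1000 * t))
        assert np.all(p.argmax(axis=0) == round(1000 * 512 / 16_000))  # bin 32

    def test_parseval_against_direct_dft(self):
        """One frame's power spectrum must match an explicit DFT."""
        rng = np.random.default_rng(0)
        x = np.zeros(48_000)
        x[:400] = rng.standard_normal(400)
        p = stft_power(x)
        frame = x[:400] * hann(400, sym=False)
        direct = np.abs(np.fft.rfft(frame, n=512)) ** 2
        assert np.allclose(p[:, 0], direct)
        # Parseval on the zero-padded frame
        full = np.fft.fft(frame, n=512)
        assert np.isclose(np.sum(np.abs(full) ** 2) / 512, np.sum(frame**2))

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            stft_power(np.zeros(1000))


class TestMelProjection:
    def test_acts_as_weighted_column_sum(self):
        p = np.random.default_rng(1).uniform(size=(257, 5))
        fb = mel_filterbank()
        assert np.allclose(mel_project(p), fb @ p)
        ones = np.ones((1, 257))
        assert np.allclose(ones @ p, p.sum(axis=0))

    def test_nonnegative_on_nonnegative_power(self):
        p = np.random.default_rng(2).uniform(size=(257, 10))
        assert np.all(mel_project(p) >= 0.0)

    def test_tone_at_center_frequency_maximizes_its_filter(self):
        # restricted to filters whose triangle spans several FFT bins;
        # below ~index 48 the Mel spacing is finer than one linear bin
        fb = mel_filterbank()
        for m in (64, 80, 100, 120):
            center_bin = np.argmax(fb[m])
            p = np.zeros((257, 1))
            p[center_bin] = 1.0
            response = mel_project(p)[:, 0]
            assert response.argmax() == m or np.isclose(response[m], response.max())

    def test_filterbank_shape_and_coverage(self):
        fb = mel_filterbank()
        assert fb.shape == (N_MELS, 257)
        assert np.all(fb >= 0.0)
        # filters wider than one FFT bin all have support; the narrowest
        # low-frequency triangles may fall between bins at this resolution
        assert np.all(fb[48:].sum(axis=1) > 0)
        # the bank jointly covers the whole spectrum up to Nyquist
        assert (fb.sum(axis=0)[1:] > 0).mean() > 0.95


class TestLogCompress:
    @pytest.mark.parametrize("value,expected", [(0.0, -100.0), (1.0, 10 * np.log10(1 + 1e-10)), (10.0, 10.0)])
    def test_reference_points(self, value, expected):
        assert np.isclose(log_compress(np.array([value]))[0], expected, atol=1e-6)

    def test_floor_is_db_floor(self):
        assert np.isclose(DB_FLOOR, -100.0)


class TestRenderImage:
    def test_shape_and_dtype(self):
        lm = segment_logmel(np.random.default_rng(3).standard_normal(48_000) * 0.1)
        img = render_image(lm)
        assert img.shape == (IMG_SIZE, IMG_SIZE)
        assert img.dtype == np.uint8

    def test_constant_input_renders_mid_gray(self):
        img = render_image(np.full((N_MELS, N_FRAMES), -37.0))
        assert np.all(img == 128)

    def test_png_round_trip_lossless(self):
        lm = segment_logmel(np.random.default_rng(4).standard_normal(48_000) * 0.1)
        img = render_image(lm)
        buf = io.BytesIO()
        Image.fromarray(img).save(buf, format="PNG")
        buf.seek(0)
        assert np.array_equal(np.asarray(Image.open(buf)), img)

    def test_low_frequencies_render_at_bottom(self):
        """Energy in low Mel bands must appear in the bottom image rows."""
        lm = np.full((N_MELS, N_FRAMES), -100.0)
        lm[:10, :] = 0.0  # lowest bands hot
        img = render_image(lm)
        assert img[-5:, :].mean() > img[:5, :].mean()

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            render_image(np.full((4, 4), np.nan))


class TestSpecAugment:
    def test_zero_bounds_is_identity(self):
        x = np.random.default_rng(5).uniform(-80, 0, size=(N_MELS, N_FRAMES))
        out = spec_augment(x, AugmentConfig(f_max=0, tau_max=0), np.random.default_rng(0))
        assert np.array_equal(out, x)

    def test_masked_cell_count_inclusion_exclusion(self):
        rng = np.random.default_rng(6)
        x = np.random.default_rng(7).uniform(-80, -1, size=(64, 100))
        for seed in range(20):
            r = np.random.default_rng(seed)
            f = int(r.integers(0, 17))
            m0 = int(r.integers(0, 64 - f + 1))
            tau = int(r.integers(0, 21))
            t0 = int(r.integers(0, 100 - tau + 1))
            out = spec_augment(x, AugmentConfig(f_max=16, tau_max=20), np.random.default_rng(seed))
            n_floor = int((out == DB_FLOOR).sum())
            assert n_floor == f * 100 + tau * 64 - f * tau

    def test_unmasked_cells_untouched(self):
        x = np.random.default_rng(8).uniform(-80, -1, size=(64, 100))
        out = spec_augment(x, AugmentConfig(f_max=8, tau_max=8), np.random.default_rng(1))
        changed = out != x
        assert np.all(out[changed] == DB_FLOOR)

    def test_uint8_image_masks_to_zero(self):
        x = np.full((64, 100), 200, dtype=np.uint8)
        out = spec_augment(x, AugmentConfig(f_max=8, tau_max=8), np.random.default_rng(12))
        assert set(np.unique(out)) <= {0, 200}

    def test_shape_preserved(self):
        x = np.zeros((64, 100))
        out = spec_augment(x, AugmentConfig(f_max=16, tau_max=20), np.random.default_rng(2))
        assert out.shape == x.shape


class TestImageAugment:
    def test_eval_normalization_of_mid_gray(self):
        img = np.full((224, 224), 128, dtype=np.uint8)
        out = image_augment(img, AugmentConfig(), train=False)
        assert out.shape == (3, 224, 224)
        assert np.allclose(out, 128 / 255 * 2 - 1, atol=1e-6)

    def test_train_output_bounded(self):
        img = np.random.default_rng(9).integers(0, 256, size=(224, 224), dtype=np.uint8)
        out = image_augment(img, AugmentConfig(), np.random.default_rng(3), train=True)
        assert out.min() >= -1.0 and out.max() <= 1.0

    def test_train_deterministic_under_seed(self):
        img = np.random.default_rng(10).integers(0, 256, size=(224, 224), dtype=np.uint8)
        a = image_augment(img, AugmentConfig(), np.random.default_rng(4), train=True)
        b = image_augment(img, AugmentConfig(), np.random.default_rng(4), train=True)
        assert np.array_equal(a, b)

    def test_channels_replicated(self):
        img = np.random.default_rng(11).integers(0, 256, size=(224, 224), dtype=np.uint8)
        out = image_augment(img, AugmentConfig(), train=False)
        assert np.array_equal(out[0], out[1]) and np.array_equal(out[1], out[2])


def test_disjoint_f0_species_have_distinct_band_argmax():
    """Feature separability: the dominant Mel row differs across species."""
    from dusafnet import SyntheticCallSpec, synth_call

    rows = []
    for f0 in (800.0, 2600.0):
        spec = SyntheticCallSpec(species_id=0, f0=f0, n_harmonics=1, syllable_dur=3.0,
                                 gap_dur=0.0, snr_db=40.0, total_dur=3.0)
        lm = segment_logmel(synth_call(spec, seed=0)[:48_000])
        rows.append(int(lm.mean(axis=1).argmax()))
    assert rows[0] != rows[1]
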