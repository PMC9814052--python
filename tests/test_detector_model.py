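"""Detector simulator: raw-word codec, frame generation, packetization."""

import numpy as np
import pytest

from jfreduce import detector_model as dm
from jfreduce.conversion import convert_frame_reference


class TestCalibrationTruth:
    def test_deterministic_for_seed(self, small_geometry):
        a = dm.make_calibration_truth(small_geometry, seed=1)
        b = dm.make_calibration_truth(small_geometry, seed=1)
        np.testing.assert_array_equal(a.pedestal_true, b.pedestal_true)
        np.testing.assert_array_equal(a.gain_true, b.gain_true)

    def test_gain_magnitudes_strictly_decrease_everywhere(self, truth):
        g = truth.gain_true
        assert np.all(g[0] > g[1]) and np.all(g[1] > g[2])
        assert np.all(g > 0)

    def test_pedestals_within_adc_range(self, truth):
        assert truth.pedestal_true.min() >= 0
        assert truth.pedestal_true.max() <= dm.ADC_MAX


class TestRawWordCodec:
    def test_roundtrip_all_stages(self):
        stage = np.repeat(np.arange(3), 100)
        adc = np.tile(np.linspace(0, dm.ADC_MAX, 100, dtype=np.int64), 3)
        words = dm.encode_raw_words(stage, adc)
        s2, a2 = dm.decode_raw_words(words)
        np.testing.assert_array_equal(s2, stage)
        np.testing.assert_array_equal(a2, adc)

    def test_invalid_gain_code_decodes_to_minus_one(self):
        word = np.array([2 << dm.GAIN_SHIFT | 123], dtype=np.uint16)
        stage, adc = dm.decode_raw_words(word)
        assert stage[0] == -1 and adc[0] == 123

    def test_zero_photons_zero_noise_gives_pedestal(self):
        word = dm.encode_raw_pixel(photons=0.0, energy_kev=12.4,
                                   pedestal=1000.0, gain=40.0, stage=0)
        stage, adc = dm.decode_raw_words(np.array([word], dtype=np.uint16))
        assert stage[0] == 0 and adc[0] == 1000

    def test_encode_decode_photon_roundtrip_bound(self):
        """Noise-free encode/decode recovers photons within the
        1 ADC-unit / (E * gain) quantization bound, over a grid of
        intensities and energies."""
        for energy in (4.0, 8.0, 12.4, 20.0):
            for gain, stage in ((40.0, 0), (1.4, 1), (0.4, 2)):
                # stay below 14-bit ADC saturation (clamping is separate,
                # defined behaviour)
                p_max = (dm.ADC_MAX - 1001.0) / (energy * gain)
                photons = np.linspace(0.0, p_max, 257)
                words = np.array([
                    dm.encode_raw_pixel(p, energy, 1000.0, gain, stage)
                    for p in photons], dtype=np.uint16)
                _, adc = dm.decode_raw_words(words)
                recovered = (adc - 1000.0) / (gain * energy)
                assert np.max(np.abs(recovered - photons)) <= \
                    1.0 / (energy * gain)

    def test_simulated_frames_never_contain_code_two(self, small_truth,
                                                     small_geometry):
        frames = dm.simulate_dark_frames(small_truth, 1, 5, seed=4)
        frame, _ = dm.simulate_diffraction_frame(
            small_truth, small_geometry, [], background_mean=2.0, seed=5)
        for f in frames + [frame]:
            stage, _ = dm.decode_raw_words(f.pixels)
            assert np.all(stage >= 0)


class TestDarkFrames:
    def test_noise_free_darks_are_identical_pedestal_constants(
            self, small_geometry):
        truth = dm.make_calibration_truth(small_geometry, seed=7,
                                          noise_sigma=(0.0, 0.0, 0.0))
        frames = dm.simulate_dark_frames(truth, 0, 10, seed=8)
        _, adc0 = dm.decode_raw_words(frames[0].pixels)
        np.testing.assert_array_equal(adc0, np.rint(truth.pedestal_true[0, 0]))
        for f in frames[1:]:
            np.testing.assert_array_equal(f.pixels, frames[0].pixels)

    def test_frame_numbers_strictly_increasing(self, small_truth):
        frames = dm.simulate_dark_frames(small_truth, 2, 20, seed=9)
        numbers = [f.frame_number for f in frames]
        assert numbers == list(range(1, 21))

    def test_sample_sd_matches_noise_sigma_at_n_1000(self, small_geometry):
        """Per-pixel sample SD of 1000 sigma=10 darks lies in [9, 11] for
        at least 99% of pixels (chi-square bounds put ~4.5 SEs inside)."""
        truth = dm.make_calibration_truth(small_geometry, seed=10,
                                          noise_sigma=(10.0, 10.0, 10.0))
        frames = dm.simulate_dark_frames(truth, 0, 1000, seed=11)
        adcs = np.stack([dm.decode_raw_words(f.pixels)[1] for f in frames])
        sd = adcs.std(axis=0)
        assert np.mean((sd >= 9.0) & (sd <= 11.0)) >= 0.99

    def test_invalid_stage_rejected(self, small_truth):
        with pytest.raises(ValueError):
            dm.simulate_dark_frames(small_truth, 3, 2, seed=1)


class TestDiffractionFrames:
    def test_no_signal_no_noise_decodes_to_zero_photons(self, small_geometry):
        truth = dm.make_calibration_truth(small_geometry, seed=12,
                                          noise_sigma=(0.0, 0.0, 0.0))
        frame, table = dm.simulate_diffraction_frame(
            truth, small_geometry, [], background_mean=0.0, seed=13,
            readout_noise=False)
        assert table == []
        photons = convert_frame_reference(
            frame, truth.pedestal_true[:, 0], truth.gain_true[:, 0], 12.4)
        # pedestal rounding to integer ADC is the only residual
        assert np.nanmax(np.abs(photons)) <= 0.5 / (truth.gain_true[2].min() * 12.4)

    def test_spot_outside_module_rejected(self, small_truth, small_geometry):
        bad = dm.SpotSpec(x=1000.0, y=5.0, intensity=100.0)
        with pytest.raises(ValueError, match="outside"):
            dm.simulate_diffraction_frame(small_truth, small_geometry,
                                          [bad], 1.0, seed=1)

    def test_photon_conservation_within_poisson(self, truth, module_geometry,
                                                diffraction_frame):
        """Total decoded photons match injected intensity + background to
        within 5 sigma of the Poisson total."""
        frame, table = diffraction_frame
        photons = convert_frame_reference(
            frame, truth.pedestal_true[:, 0], truth.gain_true[:, 0], 12.4)
        total = np.nansum(photons)
        expected = sum(s.intensity for s in table) + \
            module_geometry.module_pixels * 1.0
        assert abs(total - expected) < 5.0 * np.sqrt(expected)

    def test_ground_truth_table_returned_verbatim(self, small_truth,
                                                  small_geometry):
        spots = [dm.SpotSpec(10.0, 12.0, 200.0, 1.1)]
        _, table = dm.simulate_diffraction_frame(small_truth, small_geometry,
                                                 spots, 0.5, seed=14)
        assert table == spots


class TestPacketization:
    def test_one_module_frame_yields_128_packets_of_8192_bytes(
            self, truth):
        frame = dm.simulate_dark_frames(truth, 0, 1, seed=15)[0]
        packets = dm.packetize_module_frame(frame)
        assert len(packets) == 128
        assert all(len(p.payload) == 8192 for p in packets)

    def test_reassembly_is_bit_exact(self, truth):
        frame = dm.simulate_dark_frames(truth, 0, 1, seed=16)[0]
        packets = dm.packetize_module_frame(frame)
        rebuilt = dm.reassemble_frame(packets[::-1], frame.pixels.shape)
        np.testing.assert_array_equal(rebuilt.pixels, frame.pixels)


@pytest.fixture(scope="module")
def preload(truth):
    return dm.simulate_dark_frames(truth, 0, 1, seed=17)[0]


class TestInternalPacketGenerator:
    def test_five_frames_give_640_packets_numbered_1_to_5(self, preload):
        packets = list(dm.internal_packet_generator(preload, 5, 1))
        assert len(packets) == 5 * 128
        assert sorted({p.frame_number for p in packets}) == [1, 2, 3, 4, 5]

    def test_preload_is_exactly_one_mebibyte(self, preload):
        assert preload.nbytes == 2 ** 20
        with pytest.raises(dm.ConfigurationError):
            list(dm.internal_packet_generator(b"\x00" * 1000, 1, 1))

    def test_zero_drop_probability_equals_in_order_stream(self, preload):
        a = list(dm.internal_packet_generator(preload, 2, 2,
                                              dm.RandomDrop(0.0), seed=1))
        b = list(dm.internal_packet_generator(preload, 2, 2,
                                              dm.InOrder(), seed=99))
        assert a == b

    def test_bounded_reorder_respects_displacement_bound(self, preload):
        k = 32
        packets = list(dm.internal_packet_generator(
            preload, 3, 1, dm.BoundedReorder(k), seed=5))
        reference = list(dm.internal_packet_generator(preload, 3, 1))
        pos = {(p.frame_number, p.packet_index): i
               for i, p in enumerate(reference)}
        for i, p in enumerate(packets):
            assert abs(pos[(p.frame_number, p.packet_index)] - i) <= k

    def test_drops_are_seeded_and_logged(self, preload):
        log = dm.GeneratorLog()
        packets = list(dm.internal_packet_generator(
            preload, 4, 1, dm.RandomDrop(0.05), seed=21, log=log))
        assert log.packets_dropped == 4 * 128 - len(packets)
        assert len(log.dropped) == log.packets_dropped
        again = list(dm.internal_packet_generator(
            preload, 4, 1, dm.RandomDrop(0.05), seed=21))
        assert packets == again


class TestCaptureFiles:
    def test_capture_roundtrip(self, truth, tmp_path):
        frame = dm.simulate_dark_frames(truth, 1, 1, seed=18)[0]
        packets = dm.packetize_module_frame(frame)
        path = tmp_path / "capture.bin"
        assert dm.save_capture(path, packets) == 128
        loaded = dm.load_capture(path)
        assert loaded == packets
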