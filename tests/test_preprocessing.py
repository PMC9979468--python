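import numpy as np
import pytest
from PIL import Image

from fundus_scattering.preprocessing import (
    ChannelImage,
    ConfigurationError,
    RawImage,
    extract_channel,
    load_image,
    preprocess_dataset,
    resize_image,
)


def _write_png(path, pixels):
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.round(np.asarray(pixels) * 255.0).astype(np.uint8)).save(path)


class TestLoadImage:
    def test_all_black_png_loads_as_zeros(self, tmp_path):
        _write_png(tmp_path / "x.png", np.zeros((3, 3, 3)))
        raw = load_image(tmp_path / "x.png")
        assert raw.pixels.shape == (3, 3, 3)
        assert np.all(raw.pixels == 0.0)
        assert raw.label == "unlabelled"

    def test_label_inferred_from_directory(self, tmp_path):
        _write_png(tmp_path / "glaucoma" / "a.png", np.zeros((2, 2, 3)))
        _write_png(tmp_path / "healthy" / "b.png", np.ones((2, 2, 3)))
        assert load_image(tmp_path / "glaucoma" / "a.png").label == "glaucoma"
        assert load_image(tmp_path / "healthy" / "b.png").label == "healthy"

    def test_roundtrip_within_8bit_quantization(self, tmp_path):
        rng = np.random.default_rng(0)
        pixels = rng.random((16, 20, 3))
        _write_png(tmp_path / "p.png", pixels)
        raw = load_image(tmp_path / "p.png")
        assert np.abs(raw.pixels - pixels).max() <= 1.0 / 255.0 + 1e-12

    def test_single_plane_replicated_with_warning(self, tmp_path, caplog):
        Image.fromarray((np.ones((4, 4)) * 128).astype(np.uint8), mode="L").save(
            tmp_path / "gray.png"
        )
        with caplog.at_level("WARNING"):
            raw = load_image(tmp_path / "gray.png")
        assert raw.pixels.shape == (4, 4, 3)
        assert np.allclose(raw.pixels[..., 0], raw.pixels[..., 2])
        assert any("single-plane" in r.message for r in caplog.records)

    def test_unreadable_file_raises_with_path(self, tmp_path):
        bad = tmp_path / "corrupt.png"
        bad.write_bytes(b"not a png at all")
        with pytest.raises(IOError, match="corrupt.png"):
            load_image(bad)


class TestExtractChannel:
    def test_white_image_grayscale_sums_weights(self):
        img = RawImage(np.ones((4, 4, 3)))
        gs = extract_channel(img, "GS")
        assert np.allclose(gs.pixels, 0.2989 + 0.5870 + 0.1140)

    @pytest.mark.parametrize("channel,plane", [("RC", 0), ("GC", 1), ("BC", 2)])
    def test_plane_passthrough(self, channel, plane):
        pixels = np.zeros((3, 5, 3))
        pixels[..., plane] = 1.0
        out = extract_channel(RawImage(pixels), channel)
        assert np.all(out.pixels == 1.0)

    def test_red_only_grayscale_weight(self):
        pixels = np.zeros((3, 3, 3))
        pixels[..., 0] = 1.0
        out = extract_channel(RawImage(pixels), "GS")
        assert np.allclose(out.pixels, 0.2989)

    def test_unknown_channel_token(self):
        with pytest.raises(ConfigurationError):
            extract_channel(RawImage(np.zeros((2, 2, 3))), "XX")


class TestResize:
    def test_identity_resize(self):
        rng = np.random.default_rng(1)
        ch = ChannelImage(rng.random((300, 300)), "GS")
        out = resize_image(ch, (300, 300))
        assert np.array_equal(out.pixels, ch.pixels)

    def test_constant_image_is_fixed_point(self):
        ch = ChannelImage(np.full((600, 450), 0.37), "GC")
        out = resize_image(ch, (300, 300))
        assert out.size == (300, 300)
        assert np.allclose(out.pixels, 0.37, atol=1e-9)

    def test_centred_disc_stays_centred(self):
        # centroid measured by the brute-force moment formula
        n = 600
        rr, cc = np.mgrid[0:n, 0:n]
        disc = (np.hypot(rr - n / 2 + 0.5, cc - n / 2 + 0.5) < 80).astype(float)
        out = resize_image(ChannelImage(disc, "GS"), (300, 300)).pixels
        total = out.sum()
        r0 = (np.arange(300)[:, None] * out).sum() / total
        c0 = (np.arange(300)[None, :] * out).sum() / total
        assert abs(r0 - 149.5) < 1.0 and abs(c0 - 149.5) < 1.0

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ConfigurationError):
            resize_image(ChannelImage(np.zeros((4, 4)), "GS"), (0, 10))

    def test_values_clipped_to_unit_range(self):
        rng = np.random.default_rng(2)
        ch = ChannelImage((rng.random((500, 500)) > 0.5).astype(float), "GS")
        out = resize_image(ch, (300, 300))
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0


class TestChannelResizeCommutation:
    @pytest.mark.parametrize("channel", ["RC", "GC", "BC"])
    def test_plane_channels_commute_exactly(self, channel):
        rng = np.random.default_rng(3)
        raw = RawImage(rng.random((120, 90, 3)))
        a = resize_image(extract_channel(raw, channel), (60, 60)).pixels
        resized_raw = np.stack(
            [resize_image(ChannelImage(raw.pixels[..., k], "RC"), (60, 60)).pixels
             for k in range(3)],
            axis=-1,
        )
        b = extract_channel(RawImage(resized_raw), channel).pixels
        assert np.array_equal(a, b)

    def test_grayscale_commutes_on_constant_images(self):
        raw = RawImage(np.full((120, 90, 3), 0.6))
        a = resize_image(extract_channel(raw, "GS"), (60, 60)).pixels
        resized_raw = np.stack(
            [resize_image(ChannelImage(raw.pixels[..., k], "RC"), (60, 60)).pixels
             for k in range(3)],
            axis=-1,
        )
        b = extract_channel(RawImage(resized_raw), "GS").pixels
        assert np.allclose(a, b, atol=1e-6)


class TestPreprocessDataset:
    @pytest.fixture()
    def root(self, tmp_path):
        rng = np.random.default_rng(4)
        _write_png(tmp_path / "healthy" / "im1.png", rng.random((40, 40, 3)))
        _write_png(tmp_path / "healthy" / "im2.png", rng.random((50, 30, 3)))
        _write_png(tmp_path / "glaucoma" / "im1.png", rng.random((32, 48, 3)))
        return tmp_path

    def test_sorted_traversal_and_labels(self, root):
        out = preprocess_dataset(root, "GS", (30, 30))
        assert [im.label for im in out] == ["glaucoma", "healthy", "healthy"]
        assert all(im.size == (30, 30) for im in out)

    def test_deterministic_across_runs(self, root):
        a = preprocess_dataset(root, "GC", (30, 30))
        b = preprocess_dataset(root, "GC", (30, 30))
        assert all(np.array_equal(x.pixels, y.pixels) for x, y in zip(a, b))

    def test_non_image_file_skipped(self, root, caplog):
        (root / "healthy" / "notes.txt").write_text("not an image")
        (root / "healthy" / "broken.png").write_bytes(b"junk")
        with caplog.at_level("WARNING"):
            out = preprocess_dataset(root, "GS", (30, 30))
        assert len(out) == 3

    def test_empty_root_raises(self, tmp_path):
        (tmp_path / "empty").mkdir()
        with pytest.raises(IOError, match="no images"):
            preprocess_dataset(tmp_path / "empty", "GS", (30, 30))
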