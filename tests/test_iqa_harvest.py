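"""NR-IQA indicators, frame extraction and two-stage threshold filtering."""

import numpy as np
import pytest
from scipy import ndimage

from podkit.arch_builder import InvalidConfigError, PodkitError
from podkit.iqa_harvest import (
    FrameRecord, FrameSequence, ThresholdProfile, clarity, edge_sharpness,
    extract_frames, glcm_energy, image_entropy, score_frame, to_grayscale,
    two_stage_filter,
)
from podkit.synth_fixtures import SceneConfig, generate_clip, generate_scene


def _blur(img, sigma):
    out = ndimage.gaussian_filter(img.astype(float), sigma if img.ndim == 2
                                  else (sigma, sigma, 0))
    return np.clip(out, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# indicator values on constructed images
# ---------------------------------------------------------------------------

def test_constant_image_indicator_values():
    img = np.full((32, 32), 77, dtype=np.uint8)
    assert clarity(img) == 0.0
    assert edge_sharpness(img) == 0.0
    assert image_entropy(img) == 0.0
    assert glcm_energy(img) == 1.0


def test_checkerboard_entropy_is_one_bit():
    cb = (np.indices((16, 16)).sum(axis=0) % 2 * 255).astype(np.uint8)
    assert image_entropy(cb) == pytest.approx(1.0)


def test_checkerboard_glcm_energy_is_half():
    # strict two-level checkerboard: all co-occurring pairs are a<->b, so the
    # symmetric GLCM holds two cells of mass 1/2 -> energy 0.5
    cb = (np.indices((16, 16)).sum(axis=0) % 2 * 255).astype(np.uint8)
    assert glcm_energy(cb) == pytest.approx(0.5)


def test_all_256_levels_equally_frequent_gives_8_bits():
    img = np.arange(256, dtype=np.uint8).reshape(16, 16)
    assert image_entropy(img) == pytest.approx(8.0)


def test_noise_has_lower_glcm_energy_than_constant():
    rng = np.random.default_rng(0)
    noise = rng.integers(0, 256, size=(64, 64), dtype=np.uint8)
    assert glcm_energy(noise) < glcm_energy(np.full((64, 64), 100, np.uint8))


def test_clarity_on_single_bright_pixel_matches_hand_convolution():
    img = np.zeros((8, 8), dtype=np.uint8)
    img[3, 4] = 200
    kernel = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=float)
    resp = ndimage.convolve(img.astype(float), kernel, mode="reflect")
    assert clarity(img) == pytest.approx(resp.var())
    assert clarity(img) > 0


def test_tenengrad_on_tiny_image_matches_manual_gradient():
    img = np.array([[0, 0, 255, 255]] * 4, dtype=np.uint8)
    gx = ndimage.sobel(img.astype(float), axis=1, mode="reflect")
    gy = ndimage.sobel(img.astype(float), axis=0, mode="reflect")
    assert edge_sharpness(img) == pytest.approx(np.mean(gx ** 2 + gy ** 2))


def test_step_edge_sharper_than_blurred_step():
    step = np.zeros((32, 32), dtype=np.uint8)
    step[:, 16:] = 255
    assert edge_sharpness(step) > edge_sharpness(_blur(step, 2.0))


def test_empty_image_raises():
    with pytest.raises(InvalidConfigError):
        clarity(np.zeros((0, 0)))


def test_indicators_invariant_under_flips(dense_scene):
    img = dense_scene.image
    base = score_frame(img)
    for flipped in (img[:, ::-1], img[::-1]):
        f = score_frame(flipped)
        assert f.clarity == pytest.approx(base.clarity)
        assert f.edge_sharpness == pytest.approx(base.edge_sharpness)
        assert f.entropy_bits == pytest.approx(base.entropy_bits)
        assert f.glcm_energy == pytest.approx(base.glcm_energy)


def test_blur_monotonicity_on_fixed_scene(dense_scene):
    img = dense_scene.image
    cl = [clarity(_blur(img, s)) if s else clarity(img) for s in (0, 1, 2, 4)]
    sh = [edge_sharpness(_blur(img, s)) if s else edge_sharpness(img)
          for s in (0, 1, 2, 4)]
    assert all(a > b for a, b in zip(cl, cl[1:]))
    assert all(a > b for a, b in zip(sh, sh[1:]))


def test_grayscale_uses_luma_weights():
    img = np.zeros((2, 2, 3), dtype=np.uint8)
    img[..., 1] = 100  # pure green
    assert to_grayscale(img)[0, 0] == round(0.587 * 100)


# ---------------------------------------------------------------------------
# frame extraction
# ---------------------------------------------------------------------------

def test_extraction_boundary_rule_two_second_clip():
    frames = [np.zeros((4, 4, 3), np.uint8)] * 120  # 2.0 s at 60 fps
    recs = extract_frames(FrameSequence(frames, 60.0, "c"), 1.0)
    assert [r.timestamp for r in recs] == [0.0, 1.0]


def test_extraction_includes_final_frame_when_present():
    frames = [np.zeros((4, 4, 3), np.uint8)] * 121
    recs = extract_frames(FrameSequence(frames, 60.0, "c"), 1.0)
    assert [r.timestamp for r in recs] == [0.0, 1.0, 2.0]


def test_extraction_of_empty_video_returns_empty_list():
    assert extract_frames(FrameSequence([], 30.0, "c"), 1.0) == []


def test_extraction_index_oracle_five_second_clip():
    n, fps = 150, 30.0
    frames = [np.full((2, 2, 3), i % 256, np.uint8) for i in range(n)]
    recs = extract_frames(FrameSequence(frames, fps, "c"), 1.0)
    expected = [i for i in range(10) if round(i * fps) < n]
    assert len(recs) == len(expected) == 5
    for r, i in zip(recs, expected):
        assert np.array_equal(r.image, frames[round(i * fps)])


def test_unreadable_video_error_names_clip(tmp_path):
    bad = tmp_path / "broken.mp4"
    bad.write_bytes(b"not a video")
    with pytest.raises(PodkitError, match="broken"):
        extract_frames(bad)


# ---------------------------------------------------------------------------
# two-stage filtering
# ---------------------------------------------------------------------------

def _frame(img, clip="a", t=0.0):
    fr = FrameRecord(clip_id=clip, timestamp=t, image=img)
    fr.indicators = score_frame(img)
    return fr


def test_all_above_bounds_all_retained(dense_scene):
    frames = [_frame(dense_scene.image, t=float(i)) for i in range(3)]
    kept, audit = two_stage_filter(frames, ThresholdProfile(stage1={"clarity": (0.0, None)}))
    assert len(kept) == 3 and all(a["kept"] for a in audit)


def test_stage1_rejection_records_failing_indicator(dense_scene):
    sharp = _frame(dense_scene.image)
    blurred = _frame(_blur(dense_scene.image, 4.0), t=1.0)
    bound = (sharp.indicators.clarity + blurred.indicators.clarity) / 2
    kept, audit = two_stage_filter([sharp, blurred],
                                   ThresholdProfile(stage1={"clarity": (bound, None)}))
    assert kept == [sharp]
    assert audit[1]["stage"] == 1 and audit[1]["reasons"] == ("clarity",)


def test_two_mode_separation_keeps_exactly_the_sharp_frames(dense_scene):
    rng = np.random.default_rng(0)
    sharp = [_frame(np.clip(dense_scene.image.astype(int)
                            + rng.integers(-4, 5, dense_scene.image.shape), 0, 255)
                    .astype(np.uint8), t=float(i)) for i in range(10)]
    blurred = [_frame(_blur(dense_scene.image, 3.0 + 0.1 * i), t=10.0 + i)
               for i in range(10)]
    lo = max(f.indicators.clarity for f in blurred)
    hi = min(f.indicators.clarity for f in sharp)
    assert lo < hi, "modes must be separable"
    profile = ThresholdProfile(stage1={"clarity": ((lo + hi) / 2, None)})
    mixed = blurred[:5] + sharp + blurred[5:]
    kept, _ = two_stage_filter(mixed, profile)
    assert set(id(f) for f in kept) == set(id(f) for f in sharp)


def test_filtering_is_order_independent(dense_scene):
    frames = [_frame(_blur(dense_scene.image, s), t=float(i))
              for i, s in enumerate((0, 1, 2, 3))]
    profile = ThresholdProfile(stage1={"clarity": (frames[2].indicators.clarity, None)})
    kept_fwd, _ = two_stage_filter(list(frames), profile)
    kept_rev, _ = two_stage_filter(list(reversed(frames)), profile)
    assert set(id(f) for f in kept_fwd) == set(id(f) for f in kept_rev)


def test_unknown_stage2_subset_raises(dense_scene):
    fr = _frame(dense_scene.image, clip="clipX")
    profile = ThresholdProfile(stage1={}, stage2={"clipY": {"clarity": (0.0, None)}})
    with pytest.raises(PodkitError, match="clipX"):
        two_stage_filter([fr], profile)


def test_stage2_must_not_be_looser_than_stage1():
    with pytest.raises(InvalidConfigError):
        ThresholdProfile(stage1={"clarity": (10.0, None)},
                         stage2={"s": {"clarity": (5.0, None)}})


def test_percentile_profile_and_clip_blur_schedule():
    cfg = SceneConfig(image_size=(64, 96), n_pods=6, seed=5)
    clip = generate_clip(cfg, 2.0, 5.0, jitter=0.0,
                         blur_schedule=lambda t: 0.0 if t < 1.0 else 4.0)
    recs = [FrameRecord(clip_id=clip.clip_id, timestamp=i / 5.0, image=f)
            for i, f in enumerate(clip.frames)]
    for r in recs:
        r.indicators = score_frame(r.image)
    early = [r.indicators.clarity for r in recs[:5]]
    late = [r.indicators.clarity for r in recs[5:]]
    assert min(early) > max(late)
    profile = ThresholdProfile.from_percentiles(recs, q=50.0,
                                                indicators=("clarity",))
    kept, _ = two_stage_filter(recs, profile)
    assert all(r.indicators.clarity >= profile.stage1["clarity"][0] for r in kept)
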