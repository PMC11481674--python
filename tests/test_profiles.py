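import numpy as np
import pytest

from cortiquant import (
    Micrograph,
    SimulationConfig,
    circular_permutation_null,
    detect_cortical_puncta,
    extract_membrane_profile,
    normalize_profile,
    profile_correlation,
    puncta_overlap,
    simulate_field,
)
from cortiquant.geometry import circular_distance
from cortiquant.profiles import MembraneProfile
from cortiquant.segment import mask_to_rois


def _profile(values_by_channel, perimeter=10.0):
    n = len(next(iter(values_by_channel.values())))
    return MembraneProfile(
        cell_label=1, n_samples=n, perimeter=perimeter,
        arc_positions=np.arange(n) * perimeter / n,
        intensity={k: np.asarray(v, float)
                   for k, v in values_by_channel.items()})


def test_normalize_affine_map():
    prof = normalize_profile(_profile({"GFP": [2, 4, 6]}))
    np.testing.assert_allclose(prof.normalized["GFP"], [0, 0.5, 1])
    assert not prof.constant_flags["GFP"]


def test_normalize_constant_flag():
    prof = normalize_profile(_profile({"GFP": [5, 5, 5]}))
    np.testing.assert_allclose(prof.normalized["GFP"], [0.5, 0.5, 0.5])
    assert prof.constant_flags["GFP"]


def test_normalize_idempotent():
    prof = normalize_profile(_profile({"GFP": [0.0, 0.25, 1.0]}))
    np.testing.assert_allclose(prof.normalized["GFP"], [0.0, 0.25, 1.0])


def test_correlation_affine_invariance():
    x = np.sin(np.linspace(0, 4 * np.pi, 72))
    prof = _profile({"a": x, "b": 3 * x + 7, "c": -x})
    assert profile_correlation(prof, "a", "b") == pytest.approx(1.0)
    assert profile_correlation(prof, "a", "c") == pytest.approx(-1.0)


def test_correlation_constant_channel_undefined():
    prof = _profile({"a": [1, 2, 3, 4], "b": [2, 2, 2, 2]})
    assert np.isnan(profile_correlation(prof, "a", "b"))


def test_uniform_image_gives_constant_profile(disc_mask):
    micro = Micrograph(np.full((1, 64, 64), 7.0), ["GFP"], 0.08)
    roi, = mask_to_rois(disc_mask)
    prof = normalize_profile(extract_membrane_profile(micro, roi,
                                                      n_samples=90))
    assert prof.constant_flags["GFP"]
    assert detect_cortical_puncta(prof, "GFP").size == 0


def test_single_bump_detected_at_center():
    n = 120
    arc = np.arange(n) * 12.0 / n
    vals = 0.05 + np.exp(-circular_distance(arc, 5.0, 12.0) ** 2 / 0.1)
    prof = normalize_profile(_profile({"GFP": vals}, perimeter=12.0))
    peaks = detect_cortical_puncta(prof, "GFP")
    assert len(peaks) == 1
    assert abs(peaks[0] - 5.0) <= 12.0 / n + 1e-9


def test_simulated_puncta_match_truth():
    """Noise-free cell with 6 cortical punctae: detected arc positions match
    the simulator's ground truth 1:1 within 2 sample spacings."""
    cfg = SimulationConfig(seed=14, n_cells=3, puncta_per_cell=6,
                           puncta_sigma=0.15, puncta_enrichment=0.9,
                           membrane_fraction=0.7, noise=False)
    micro, mask, truth = simulate_field(cfg)
    for roi in mask_to_rois(mask):
        cell = next(c for c in truth.cells if c.label == roi.label)
        prof = normalize_profile(
            extract_membrane_profile(micro, roi, n_samples=150))
        peaks = detect_cortical_puncta(prof, "GFP",
                                       min_separation_um=0.15)
        assert len(peaks) == 6
        spacing = prof.perimeter / prof.n_samples
        d = circular_distance(np.sort(peaks),
                              np.sort(cell.puncta_arcs_um), prof.perimeter)
        assert np.all(d <= 2 * spacing)


def test_rotation_equivariance():
    """Rotating the field by 90 deg leaves the profile unchanged up to a
    circular shift (start-vertex ambiguity of the ellipse major axis)."""
    cfg = SimulationConfig(seed=13, n_cells=1, noise=False,
                           field_shape=(256, 256), puncta_per_cell=5,
                           membrane_fraction=0.7, puncta_enrichment=0.9)
    micro, mask, _ = simulate_field(cfg)
    roi, = mask_to_rois(mask)
    p0 = extract_membrane_profile(micro, roi, n_samples=120).intensity["GFP"]

    rot_img = np.rot90(micro.pixels[0]).copy()
    rot_mask = np.rot90(mask.labels).copy()
    from cortiquant import LabelMask
    roi_r, = mask_to_rois(LabelMask(rot_mask))
    p1 = extract_membrane_profile(
        Micrograph(rot_img[None], ["GFP"], micro.pixel_size), roi_r,
        n_samples=120).intensity["GFP"]

    # best circular alignment in either direction
    def best_rms(a, b):
        cands = [np.roll(b, s) for s in range(len(b))]
        cands += [np.roll(b[::-1], s) for s in range(len(b))]
        return min(np.sqrt(np.mean((a - c) ** 2)) for c in cands)

    assert best_rms(p0, p1) < 0.05 * (p0.max() - p0.min())


def test_overlap_trivial_cases():
    frac, pairs = puncta_overlap([1.0, 5.0], [1.0, 5.0], 12.0)
    assert frac == 1.0 and len(pairs) == 2
    frac, _ = puncta_overlap([1.0, 5.0], [3.0, 9.0], 24.0, tolerance_um=0.3)
    assert frac == 0.0
    frac, _ = puncta_overlap([], [1.0], 12.0)
    assert np.isnan(frac)
    frac, _ = puncta_overlap([0.1], [11.9], 12.0, tolerance_um=0.3)
    assert frac == 1.0      # wraps around the contour


def test_correlation_invariant_under_common_circular_shift():
    rng = np.random.default_rng(1)
    x, y = rng.normal(size=(2, 90))
    p1 = _profile({"a": x, "b": y})
    p2 = _profile({"a": np.roll(x, 17), "b": np.roll(y, 17)})
    assert profile_correlation(p1, "a", "b") == pytest.approx(
        profile_correlation(p2, "a", "b"))
    f1, _ = puncta_overlap([1.0, 4.0], [1.1, 8.0], 10.0)
    f2, _ = puncta_overlap([3.0, 6.0], [3.1, 10.0 % 10.0], 10.0)
    assert f1 == f2


def test_permutation_null_separates_modes(twochannel_field):
    cfg, micro, mask, truth = twochannel_field
    rois = mask_to_rois(mask)
    rs = []
    for roi in rois[:4]:
        prof = extract_membrane_profile(micro, roi, n_samples=150)
        r, null, p = circular_permutation_null(prof, "GFP", "mRFP",
                                               n_permutations=300, seed=1)
        rs.append(r)
        assert p < 0.05                       # colocalized: significant
        assert -1.0 <= r <= 1.0
        assert np.all(null <= 1.0)
    assert np.mean(rs) > 0.8
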