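import numpy as np
import pytest

from otloc.auto_features import (
    COMPACT_LENGTH,
    FULL_LENGTH,
    MEASUREMENT_NAMES,
    PAD,
    FeatureMatrix,
    build_feature_matrix,
    expand_ratio_features,
    expansion_length,
    expansion_names,
    find_extrema,
    matrix_row_keys,
    measure_extremum,
    select_eight,
)
from otloc.beats import BeatWindow

# ---------------------------------------------------------------------------
# Brute-force contour-line oracle
# ---------------------------------------------------------------------------

def oracle_peak(y, i):
    """Prominence/bases/width of the peak at i by direct two-sided scan."""
    n = len(y)
    lmin, lpos = y[i], i
    j = i - 1
    while j >= 0 and y[j] <= y[i]:
        if y[j] < lmin:
            lmin, lpos = y[j], j
        j -= 1
    rmin, rpos = y[i], i
    k = i + 1
    while k < n and y[k] <= y[i]:
        if y[k] < rmin:
            rmin, rpos = y[k], k
        k += 1
    prom = y[i] - max(lmin, rmin)
    level = y[i] - prom / 2.0
    j = i
    while j > lpos and y[j] > level:
        j -= 1
    # an exact hit on the level needs no interpolation (avoids 0/0 on
    # plateaus whose half-prominence underflows onto the sample value)
    li = j if y[j] >= level else j + (level - y[j]) / (y[j + 1] - y[j])
    k = i
    while k < rpos and y[k] > level:
        k += 1
    ri = k if y[k] >= level else k - (level - y[k]) / (y[k - 1] - y[k])
    return prom, lpos, rpos, ri - li


def check_against_oracle(y):
    for e in find_extrema(y):
        sig = y if e.kind == "peak" else -y
        i = int(e.location)
        prom, lpos, rpos, width = oracle_peak(sig, i)
        assert e.prominence == pytest.approx(prom)
        assert e.dist_left == pytest.approx(i - lpos)
        assert e.dist_right == pytest.approx(rpos - i)
        assert e.width_half_prom == pytest.approx(width)
        assert e.span == pytest.approx(e.dist_left + e.dist_right)
        assert e.amplitude == pytest.approx(sig[i])
        assert e.contour_height == pytest.approx(prom - sig[i])


class TestFindExtrema:
    def test_triangle(self):
        y = np.array([0, 0.25, 0.5, 0.75, 1.0, 0.75, 0.5, 0.25, 0])
        (e,) = find_extrema(y)
        assert e.kind == "peak"
        assert e.prominence == 1.0
        assert e.amplitude == 1.0
        assert e.contour_height == 0.0
        assert e.width_half_prom == pytest.approx(4.0)  # half the base width
        assert e.span == 8.0

    def test_valley_mirror_of_triangle(self):
        y = -np.array([0, 0.25, 0.5, 0.75, 1.0, 0.75, 0.5, 0.25, 0])
        (e,) = find_extrema(y)
        assert e.kind == "valley"
        assert e.prominence == 1.0
        assert e.amplitude == 1.0
        assert e.width_half_prom == pytest.approx(4.0)

    def test_two_peaks_and_valley(self):
        y = np.array([0.0, 2.0, 1.0, 3.0, 0.0])
        ext = find_extrema(y)
        kinds = [(e.kind, e.location) for e in ext]
        assert kinds == [("peak", 1), ("valley", 2), ("peak", 3)]
        assert ext[0].prominence == 1.0  # bounded by the higher neighbour
        assert ext[2].prominence == 3.0
        assert ext[1].prominence == 1.0
        check_against_oracle(y)

    def test_small_peak_bounded_by_higher(self):
        y = np.array([0.0, 1.0, 0.5, 2.0, 0.0])
        check_against_oracle(y)
        e = find_extrema(y)[0]
        assert e.dist_right == 1.0  # right base at the inter-peak valley

    def test_monotone_ramp_empty(self):
        assert find_extrema(np.arange(10.0)) == []

    def test_plateau_reports_first_sample(self):
        y = np.array([0.0, 1.0, 1.0, 1.0, 0.0])
        (e,) = find_extrema(y)
        assert e.location == 1

    def test_oracle_equivalence_random_batch(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            y = rng.normal(size=rng.integers(10, 60))
            check_against_oracle(y)

    def test_measure_extremum_single(self):
        y = np.array([0.0, 2.0, 1.0, 3.0, 0.0])
        e = measure_extremum(y, 1, "peak")
        assert e.prominence == 1.0
        with pytest.raises(ValueError):
            measure_extremum(y, 2, "peak")  # it's a valley


class TestSelectEight:
    def _extrema(self, locations):
        y = np.zeros(700)
        for loc in locations:
            y[loc] = 1.0
        return find_extrema(y)

    def test_full_neighbourhood(self):
        locs = list(range(100, 600, 50))  # 10 peaks
        ext = [e for e in self._extrema(locs) if e.kind == "peak"]
        chosen = select_eight(ext, ref_offset=255)  # closest is ordinal 4
        assert [e.location for e in chosen] == [100, 150, 200, 250, 300, 350,
                                                400, 450]

    def test_single_extremum_padding(self):
        ext = [e for e in self._extrema([335]) if e.kind == "peak"]
        chosen = select_eight(ext, ref_offset=335)
        assert [e.kind for e in chosen] == ["pad"] * 3 + ["peak"] + ["pad"] * 4

    def test_empty_gives_eight_pads(self):
        assert select_eight([], 335) == [PAD] * 8

    def test_tie_prefers_earlier(self):
        ext = [e for e in self._extrema([300, 340]) if e.kind == "peak"]
        chosen = select_eight(ext, ref_offset=320)
        assert chosen[3].location == 300


def _window(beat_class, fill=None, seed=0):
    n = 430 if beat_class == "SR" else 670
    if fill is None:
        rng = np.random.default_rng(seed)
        seg = rng.normal(0, 0.2, (12, n))
    else:
        seg = np.full((12, n), float(fill))
    return BeatWindow(beat_class, seg, n // 2)


class TestFeatureMatrix:
    def test_shape_and_keys(self):
        m = build_feature_matrix(_window("SR"), _window("PVC"))
        assert m.values.shape == (192, 8)
        assert len(matrix_row_keys()) == 192
        assert matrix_row_keys()[0] == "SR.I.1"
        assert matrix_row_keys()[96] == "PVC.I.1"

    def test_zero_windows_zero_matrix(self):
        m = build_feature_matrix(_window("SR", fill=0.0), _window("PVC", fill=0.0))
        assert np.abs(m.values).max() == 0.0

    def test_deterministic(self):
        a = build_feature_matrix(_window("SR"), _window("PVC"))
        b = build_feature_matrix(_window("SR"), _window("PVC"))
        assert np.array_equal(a.values, b.values)

    def test_csv_round_trip(self, tmp_path):
        m = build_feature_matrix(_window("SR"), _window("PVC"))
        m.to_csv(tmp_path / "m.csv")
        back = FeatureMatrix.from_csv(tmp_path / "m.csv")
        assert np.allclose(back.values, m.values)

    def test_location_equivariance(self):
        # same contents shifted (with constant low padding) leave every
        # measurement except location unchanged
        rng = np.random.default_rng(9)
        core = rng.normal(0, 0.5, 100)
        low = core.min() - 1.0

        def embed(offset, n=430):
            y = np.full(n, low)
            y[offset:offset + core.size] = core
            return y

        a = find_extrema(embed(50))
        b = find_extrema(embed(90))
        core_a = [e for e in a if 50 <= e.location < 150]
        core_b = [e for e in b if 90 <= e.location < 190]
        assert len(core_a) == len(core_b) > 0
        for ea, eb in zip(core_a, core_b):
            assert eb.location - ea.location == 40
            for name in MEASUREMENT_NAMES[1:]:
                assert getattr(ea, name) == pytest.approx(getattr(eb, name))


@pytest.fixture(scope="module")
def matrix():
    rng = np.random.default_rng(1)
    return FeatureMatrix(rng.normal(1.0, 0.5, (192, 8)))


class TestExpansion:

    def test_lengths(self, matrix):
        assert expansion_length("compact") == COMPACT_LENGTH == 41_472
        assert expansion_length("full") == FULL_LENGTH == 611_328
        assert expand_ratio_features(matrix).values.size == COMPACT_LENGTH
        fv = expand_ratio_features(matrix, recipe="full", with_names=False)
        assert fv.values.size == FULL_LENGTH

    def test_named_cells_match_formulas(self, matrix):
        fv = expand_ratio_features(matrix)
        s = fv.to_series()
        keys = matrix_row_keys()
        M = matrix.values
        r = {k: i for i, k in enumerate(keys)}
        assert s["raw(SR.V1.1.location)"] == M[r["SR.V1.1"], 0]
        assert s["ratio(SR.V1.1.prominence, SR.V1.1.location)"] == pytest.approx(
            M[r["SR.V1.1"], 1] / M[r["SR.V1.1"], 0])
        assert s["ratio(SR.V1.5.location, PVC.V1.5.dist_right)"] == pytest.approx(
            M[r["SR.V1.5"], 0] / M[r["PVC.V1.5"], 3])
        assert s["diff(PVC.V1.5.dist_left, SR.V1.5.dist_left)"] == pytest.approx(
            M[r["PVC.V1.5"], 2] - M[r["SR.V1.5"], 2])

    def test_reported_top_feature_names_present(self, matrix):
        names = set(expand_ratio_features(matrix).names)
        assert "ratio(SR.V1.5.location, PVC.V1.5.dist_right)" in names
        assert "ratio(PVC.V1.5.prominence, PVC.V3.5.prominence)" in names
        assert "diff(PVC.V1.5.dist_left, SR.V1.5.dist_left)" in names

    def test_full_recipe_column_blocks(self, matrix):
        fv = expand_ratio_features(matrix, recipe="full")
        s = fv.to_series()
        M = matrix.values
        keys = matrix_row_keys()
        r = {k: i for i, k in enumerate(keys)}
        assert s["ratio(SR.I.1.location, SR.I.2.location)"] == pytest.approx(
            M[r["SR.I.1"], 0] / M[r["SR.I.2"], 0])
        assert s["diff(PVC.V6.8.contour_height, SR.I.1.contour_height)"] == \
            pytest.approx(M[r["PVC.V6.8"], 7] - M[r["SR.I.1"], 7])

    def test_zero_denominator_gives_zero(self):
        vals = np.ones((192, 8))
        vals[0, 0] = 0.0
        fv = expand_ratio_features(FeatureMatrix(vals))
        s = fv.to_series()
        assert s["ratio(SR.I.1.prominence, SR.I.1.location)"] == 0.0
        assert np.all(np.isfinite(fv.values))

    def test_length_constant_across_inputs(self):
        rng = np.random.default_rng(2)
        sizes = {expand_ratio_features(
            FeatureMatrix(rng.normal(size=(192, 8)))).values.size
            for _ in range(3)}
        assert sizes == {COMPACT_LENGTH}

    def test_names_match_length(self):
        assert len(expansion_names("compact")) == COMPACT_LENGTH
        assert len(expansion_names("full")) == FULL_LENGTH
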