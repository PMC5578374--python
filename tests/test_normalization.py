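import numpy as np
import pytest
from scipy.stats import ortho_group

from phyloprofiler import (
    BitScoreProfile,
    SpeciesCatalog,
    npp_score,
    npp_transform,
    simulate_bitscores,
    simulate_profiles,
    svd_score,
    svd_transform,
)


def bits_profile(values, prefix="q"):
    values = np.asarray(values, dtype=float)
    proteins = tuple(f"{prefix}{i}" for i in range(values.shape[0]))
    catalog = SpeciesCatalog(tuple(f"s{j}" for j in range(values.shape[1])))
    return BitScoreProfile(proteins, catalog, values)


@pytest.fixture
def simulated_bits():
    profile, _ = simulate_profiles(seed=21, flip_noise=0.05)
    return simulate_bitscores(profile, seed=22)


class TestNpp:
    def test_worked_two_by_two_pipeline(self):
        # floor: [[100, 1], [80, 160]]; log2 row ratios:
        # [[0, -log2(100)], [-1, 0]]; two-row columns z-score to +-1/sqrt(2)
        norm = npp_transform(bits_profile([[100, 50], [80, 160]]),
                             score_floor=70, min_homologs=1)
        r = 1 / np.sqrt(2)
        assert np.allclose(norm.values, [[r, -r], [-r, r]], atol=1e-12)

    def test_identical_scores_above_floor_give_zero_log_ratios(self):
        # both rows flat above the floor -> all log-ratios 0 -> every column
        # has zero spread and is zeroed with a warning
        raw = [[120, 120, 120], [90, 90, 90]]
        with pytest.warns(UserWarning, match="zero spread"):
            norm = npp_transform(bits_profile(raw), score_floor=70,
                                 min_homologs=1)
        assert np.allclose(norm.values, 0.0)
        assert norm.params["zero_sd_columns"] == ["s0", "s1", "s2"]

    def test_poorly_conserved_protein_dropped_with_reason(self):
        raw = [[60, 50, 40], [80, 160, 90], [75, 71, 200]]
        norm = npp_transform(bits_profile(raw), score_floor=70, min_homologs=1)
        assert norm.dropped_proteins == [("q0", "poor conservation")]
        assert "q0" not in norm.proteins

    def test_all_dropped_is_an_error_naming_parameters(self):
        with pytest.raises(ValueError, match="min_homologs=12"):
            npp_transform(bits_profile([[60, 50], [30, 20]]),
                          score_floor=70, min_homologs=12)

    def test_column_zscore_invariant(self, simulated_bits):
        norm = npp_transform(simulated_bits, min_homologs=5)
        zero_sd = norm.params["zero_sd_columns"]
        keep = [i for i, s in enumerate(norm.dimensions) if s not in zero_sd]
        vals = norm.values[:, keep]
        assert np.abs(vals.mean(axis=0)).max() < 1e-9
        assert np.abs(vals.std(axis=0, ddof=1) - 1).max() < 1e-9

    def test_min_homolog_filter_is_monotone(self, simulated_bits):
        kept = [
            set(npp_transform(simulated_bits, min_homologs=k).proteins)
            for k in (1, 5, 10, 20)
        ]
        for tighter, looser in zip(kept[1:], kept):
            assert tighter <= looser


class TestSvd:
    def test_rows_have_unit_norm(self, simulated_bits):
        norm = svd_transform(simulated_bits, trim_fraction=0.3, min_homologs=5)
        assert np.abs(np.linalg.norm(norm.values, axis=1) - 1).max() < 1e-9

    def test_trim_fraction_selects_ceiling_of_columns(self):
        rng = np.random.default_rng(7)
        raw = rng.uniform(60, 200, size=(12, 10))
        norm = svd_transform(bits_profile(raw), trim_fraction=0.3,
                             min_homologs=1)
        assert len(norm.dimensions) == 3  # ceil(0.3 * 10)

    def test_reconstruction_before_trimming(self):
        rng = np.random.default_rng(8)
        raw = rng.uniform(0, 200, size=(6, 5))
        floored = np.where(raw < 60, 0.0, raw)
        keep = floored.any(axis=1)
        scaled = floored[keep] / floored[keep].max(axis=1, keepdims=True)
        u, s, vt = np.linalg.svd(scaled, full_matrices=False)
        assert np.abs(u @ np.diag(s) @ vt - scaled).max() < 1e-9

    def test_rank_one_matrix_rows_collapse_up_to_sign(self):
        # a rank-1 bit-score matrix has identical rows after row-max scaling,
        # so the single informative singular dimension carries everything and
        # the retained rows collapse to +-1 when only it is kept
        col = np.array([[1.0], [0.5], [0.8]])
        row = np.array([[100.0, 150.0, 90.0]])
        norm = svd_transform(bits_profile(col @ row), score_floor=60,
                             trim_fraction=1 / 3, min_homologs=1)
        assert norm.values.shape == (3, 1)
        assert np.allclose(np.abs(norm.values), 1.0, atol=1e-9)
        assert np.allclose(norm.values, norm.values[0], atol=1e-9)
        # cross-check against a reference factorization of the same instance
        scaled = (col @ row) / (col @ row).max(axis=1, keepdims=True)
        reference = np.linalg.svd(scaled)[0]
        assert np.allclose(np.abs(reference[:, 0]) * np.sqrt(3), 1.0,
                           atol=1e-9)

    def test_invalid_trim_fraction_and_degenerate_matrix(self):
        prof = bits_profile([[100, 80], [90, 70]])
        for bad in (0.0, 1.5, -0.2):
            with pytest.raises(ValueError, match="trim_fraction"):
                svd_transform(prof, trim_fraction=bad, min_homologs=1)
        with pytest.raises(ValueError, match="all zero"):
            svd_transform(bits_profile([[10, 20], [30, 40]]),
                          score_floor=60, trim_fraction=1.0, min_homologs=1)

    def test_distances_invariant_to_rotation_of_row_space(self):
        # with every singular dimension retained and nothing filtered, the
        # factor basis cancels out of pairwise Euclidean distances
        rng = np.random.default_rng(9)
        raw = rng.uniform(60, 200, size=(8, 6))
        prof = bits_profile(raw)
        base = svd_score(svd_transform(prof, trim_fraction=1.0, min_homologs=1))
        rot = ortho_group.rvs(6, random_state=rng)
        scaled = raw / raw.max(axis=1, keepdims=True)
        rotated = scaled @ rot
        u, s, vt = np.linalg.svd(rotated, full_matrices=False)
        unit = u / np.linalg.norm(u, axis=1, keepdims=True)
        from scipy.spatial.distance import pdist, squareform
        rotated_dm = squareform(pdist(unit))
        assert np.allclose(base.values, rotated_dm, atol=1e-8)


class TestScorers:
    def test_identical_rows_score_as_identical(self):
        raw = [[100, 80, 120], [100, 80, 120], [200, 90, 60]]
        npp = npp_transform(bits_profile(raw), min_homologs=1)
        assert npp_score(npp).values[0, 1] == pytest.approx(1.0)
        svd = svd_transform(bits_profile(raw), trim_fraction=1.0, min_homologs=1)
        assert svd_score(svd).values[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_unit_sphere_law_of_cosines(self, simulated_bits):
        norm = svd_transform(simulated_bits, trim_fraction=0.3, min_homologs=5)
        dm = svd_score(norm).values
        gram = norm.values @ norm.values.T
        assert np.allclose(dm ** 2, np.clip(2 - 2 * gram, 0, None), atol=1e-9)
        assert dm.max() <= 2 + 1e-9

    def test_method_mismatch_rejected(self, simulated_bits):
        npp = npp_transform(simulated_bits, min_homologs=5)
        svd = svd_transform(simulated_bits, min_homologs=5)
        with pytest.raises(ValueError):
            npp_score(svd)
        with pytest.raises(ValueError):
            svd_score(npp)
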