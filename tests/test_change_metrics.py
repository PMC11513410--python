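"""Occupancy surfaces, AOO change, richness, beta diversity, Růžička."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from isdm_change import (
    OccupancySurface,
    area_of_occupancy,
    classify_change,
    occupancy_probability,
    ruzicka,
    spatial_distance_decay,
    stack_richness,
    temporal_dissimilarity_map,
    whittaker_beta,
)
from isdm_change.grid import regular_grid


def _surface(p, cell_area=10_000.0):
    p = np.asarray(p, float)
    return OccupancySurface(p_draws=p, cell_areas=np.full(p.shape[1], cell_area))


# -- occupancy --------------------------------------------------------------

def test_occupancy_closed_forms():
    lam = np.zeros((1, 3, 2))
    lam[0, 1, :] = np.log(2.0)
    lam[0, 2, :] = 1e4
    surf = occupancy_probability(lam, np.ones(3))
    np.testing.assert_allclose(surf.p_draws[0, 0], 0.0)
    np.testing.assert_allclose(surf.p_draws[0, 1], 0.5)
    assert np.all(surf.p_draws <= 1.0) and surf.p_draws[0, 2, 0] == pytest.approx(1.0)


def test_occupancy_rejects_negative_or_mismatched():
    with pytest.raises(ValueError):
        occupancy_probability(-np.ones((1, 2, 2)), np.ones(2))
    with pytest.raises(ValueError):
        occupancy_probability(np.ones((1, 2, 2)), np.ones(3))


# -- area of occupancy ------------------------------------------------------

def test_aoo_hand_sum_in_cells_and_km2():
    p = np.zeros((1, 3, 2))
    p[0, :, 0] = [0.2, 0.5, 0.9]
    p[0, :, 1] = [0.2, 0.5, 0.9]
    s = area_of_occupancy(_surface(p))
    assert s.median_a_cells[0] == pytest.approx(1.6)
    assert s.a_draws[0, 0] * s.cell_area_km2 == pytest.approx(16_000.0)


def test_aoo_all_occupied_equals_cell_count():
    p = np.ones((5, 7, 2))
    s = area_of_occupancy(_surface(p))
    np.testing.assert_allclose(s.median_a_cells, 7.0)


def test_cells_to_km2_conversion_at_100km_grain():
    """A change of 14.6 cells on a 100-km grid is 146,000 km²."""
    p = np.zeros((200, 20, 2))
    rng = np.random.default_rng(0)
    p[:, :, 0] = rng.uniform(0, 0.2, (200, 20))
    p[:, :, 1] = p[:, :, 0] + 14.6 / 20  # uniform gain of 14.6 cells total
    s = area_of_occupancy(_surface(p))
    assert s.median_delta_cells == pytest.approx(14.6)
    assert s.median_delta_km2 == pytest.approx(146_000.0)
    np.testing.assert_allclose(np.array(s.ci_delta_km2), np.array(s.ci_delta_cells) * 10_000)


def test_aoo_linear_in_probability_scaling():
    rng = np.random.default_rng(1)
    p = rng.uniform(0, 1, (50, 12, 2))
    s1 = area_of_occupancy(_surface(p))
    s2 = area_of_occupancy(_surface(0.4 * p))
    np.testing.assert_allclose(s2.a_draws, 0.4 * s1.a_draws, atol=1e-12)


def test_delta_uses_paired_draws_not_marginal_intervals():
    """Anti-correlated periods: the paired ΔA interval is tight even though
    both marginal intervals are wide."""
    rng = np.random.default_rng(2)
    base = rng.uniform(0.2, 0.8, (500, 1))
    p = np.zeros((500, 1, 2))
    p[:, :, 0] = base
    p[:, :, 1] = base + 0.05
    s = area_of_occupancy(_surface(p))
    np.testing.assert_allclose(s.delta_draws, 0.05, atol=1e-12)
    lo, hi = s.ci_delta_cells
    assert hi - lo < 1e-9  # a naive difference of marginal intervals would span ~1.2


def test_change_classes():
    draws = np.column_stack(
        [
            np.full(200, 0.3),                      # certain gain
            np.linspace(-0.05, 0.25, 200),          # uncertain gain
            np.zeros(200),                          # no change
            np.full(200, -0.3),                     # certain loss
            np.linspace(-0.25, 0.05, 200),          # uncertain loss
        ]
    )
    out = classify_change(draws)
    assert list(out) == ["certain gain", "uncertain gain", "no change", "certain loss", "uncertain loss"]


# -- richness ---------------------------------------------------------------

def test_stacked_richness_sums_species_medians():
    s_all = {f"sp{i}": _surface(np.ones((1200, 4, 2))) for i in range(5)}
    stack, sr, dsr = stack_richness(s_all, n_samples=1000, seed=0)
    np.testing.assert_allclose(sr, 5.0)
    np.testing.assert_allclose(dsr, 0.0)
    assert stack.shape == (5, 4, 2)


def test_richness_additivity_of_single_species_change():
    p_flat = np.full((1000, 3, 2), 0.4)
    p_up = p_flat.copy()
    p_up[:, 1, 1] = 0.6  # one species gains 0.2 in one cell
    s_all = {"a": _surface(p_flat), "b": _surface(p_up)}
    _, sr, dsr = stack_richness(s_all, seed=0)
    assert dsr[1] == pytest.approx(0.2)
    assert dsr[0] == pytest.approx(0.0)


def test_richness_with_few_draws_uses_all(caplog):
    s_all = {"a": _surface(np.full((100, 2, 2), 0.5))}
    _, sr, _ = stack_richness(s_all, n_samples=1000, seed=0)
    np.testing.assert_allclose(sr, 0.5)


# -- Whittaker beta ---------------------------------------------------------

def test_beta_one_when_all_species_everywhere():
    gamma, abar, beta = whittaker_beta(np.ones((4, 6)))
    assert gamma == pytest.approx(4.0)
    assert abar == pytest.approx(4.0)
    assert beta == pytest.approx(1.0)


def test_beta_two_for_perfect_turnover():
    p = np.array([[1.0, 0.0], [0.0, 1.0]])
    gamma, abar, beta = whittaker_beta(p)
    assert (gamma, abar, beta) == (pytest.approx(2.0), pytest.approx(1.0), pytest.approx(2.0))


def test_beta_invariant_under_cell_replication(rng):
    p = rng.uniform(0, 1, (5, 8))
    _, _, b1 = whittaker_beta(p)
    _, _, b2 = whittaker_beta(np.tile(p, (1, 2)))
    # alpha-bar is replication-invariant; gamma saturates identically when
    # every cell appears the same number of times
    g1, a1, _ = whittaker_beta(p)
    g2, a2, _ = whittaker_beta(np.tile(p, (1, 2)))
    assert a2 == pytest.approx(a1)
    assert g2 >= g1  # pooled richness can only grow with more cells


def test_beta_at_least_one_for_random_stacks(rng):
    for _ in range(50):
        p = rng.uniform(0, 1, (rng.integers(2, 6), rng.integers(2, 10)))
        gamma, abar, beta = whittaker_beta(p)
        assert beta >= 1.0 - 1e-9


def test_beta_undefined_when_no_species():
    gamma, abar, beta = whittaker_beta(np.zeros((3, 4)))
    assert np.isnan(beta) and abar == 0.0


# -- Růžička ----------------------------------------------------------------

def test_ruzicka_worked_examples():
    assert ruzicka(np.array([0.2, 0.5, 0.0]), np.array([0.4, 0.1, 0.0])) == pytest.approx(1 - 0.3 / 0.9)
    assert ruzicka(np.ones(4), np.ones(4)) == 0.0
    assert ruzicka(np.array([1.0, 0.0]), np.array([0.0, 2.0])) == 1.0
    assert np.isnan(ruzicka(np.zeros(3), np.zeros(3)))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(0, 10, allow_nan=False), min_size=1, max_size=8),
    st.data(),
)
def test_ruzicka_metric_properties(x, data):
    y = data.draw(st.lists(st.floats(0, 10, allow_nan=False), min_size=len(x), max_size=len(x)))
    x, y = np.array(x), np.array(y)
    if x.max() == 0 and y.max() == 0:
        return
    r = ruzicka(x, y)
    assert 0.0 <= r <= 1.0
    assert r == pytest.approx(ruzicka(y, x))
    assert ruzicka(x, x) == 0.0 or x.max() == 0


def test_ruzicka_input_validation():
    with pytest.raises(ValueError):
        ruzicka(np.array([1.0]), np.array([1.0, 2.0]))
    with pytest.raises(ValueError):
        ruzicka(np.array([-1.0]), np.array([1.0]))


# -- temporal dissimilarity -------------------------------------------------

def test_temporal_map_identical_stacks_zero():
    p = np.random.default_rng(3).uniform(0.1, 1, (4, 6))
    np.testing.assert_allclose(temporal_dissimilarity_map(p, p), 0.0)


def test_temporal_map_full_turnover_is_one():
    s1 = np.array([[1.0], [0.0], [0.0]])
    s2 = np.array([[0.0], [1.0], [0.0]])
    assert temporal_dissimilarity_map(s1, s2)[0] == 1.0


def test_temporal_map_scale_invariant(rng):
    s1 = rng.uniform(0, 1, (5, 7))
    s2 = rng.uniform(0, 1, (5, 7))
    r = temporal_dissimilarity_map(s1, s2)
    r_scaled = temporal_dissimilarity_map(3.7 * s1, 3.7 * s2)
    np.testing.assert_allclose(r, r_scaled, atol=1e-12)


def test_temporal_map_propagates_empty_cells():
    s = np.zeros((2, 3))
    s[0, 0] = 1.0
    out = temporal_dissimilarity_map(s, s)
    assert out[0] == 0.0 and np.isnan(out[1]) and np.isnan(out[2])


# -- distance decay ---------------------------------------------------------

def test_decay_constant_composition_is_zero_everywhere():
    grid = regular_grid(6, 6, 100)
    stack = np.tile(np.array([[0.5], [0.3]]), (1, 36))
    out = spatial_distance_decay({1: stack, 2: stack}, grid.centroids, n_pairs=2000, bins=5, seed=0)
    filled = out.dropna(subset=["median_dissimilarity"])
    np.testing.assert_allclose(filled["median_dissimilarity"], 0.0, atol=1e-12)


def test_decay_increases_along_composition_gradient():
    grid = regular_grid(15, 15, 100)
    x = grid.centroids[:, 0]
    t = (x - x.min()) / (x.max() - x.min())
    stack = np.vstack([1 - t, t])  # species A fades west→east, B the reverse
    out = spatial_distance_decay({1: stack}, grid.centroids, n_pairs=20_000, bins=8, seed=1)
    filled = out.dropna(subset=["median_dissimilarity"])
    rho = stats.spearmanr(filled["bin_mid_km"], filled["median_dissimilarity"]).statistic
    assert rho > 0


def test_decay_deterministic_given_seed():
    grid = regular_grid(8, 8, 100)
    stack = np.random.default_rng(5).uniform(0, 1, (3, 64))
    a = spatial_distance_decay({1: stack}, grid.centroids, n_pairs=5000, bins=6, seed=9)
    b = spatial_distance_decay({1: stack}, grid.centroids, n_pairs=5000, bins=6, seed=9)
    assert a.equals(b)


def test_decay_needs_two_cells():
    with pytest.raises(ValueError):
        spatial_distance_decay({1: np.ones((1, 1))}, np.zeros((1, 2)))
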