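"""Integrity statistics: per-state Phi maps, surfaces, Fano factors."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from _oracle import BruteForceIIT
from swarmphi.integrity_analysis import (
    fano,
    local_global_difference,
    mean_phi,
    normalized_surface,
    phi_fano_correlation,
    phi_per_state,
    phi_surface,
    top_k_mean,
    variance_phi,
    weighted_mean_position,
)
from swarmphi.state_encoding import Trajectory


# ----------------------------------------------------------------------
# per-state Phi and scalar statistics
# ----------------------------------------------------------------------
def test_phi_per_state_independent_nodes_all_zero(noisy_tpm):
    results = phi_per_state(noisy_tpm, scope="full_system")
    assert set(results) == {0, 1, 2, 3}
    assert all(r.big_phi == 0.0 for r in results.values())


def test_phi_per_state_copy_matches_exhaustive_oracle(copy_tpm):
    results = phi_per_state(copy_tpm, scope="full_system", cut_scheme="cut_one")
    assert len(results) == 4
    oracle_phi, _, _ = BruteForceIIT(copy_tpm).big_phi((1, 1), "exhaustive")
    assert results[3].big_phi == pytest.approx(oracle_phi, abs=1e-8)


def test_phi_per_state_deterministic(majority3_tpm):
    a = phi_per_state(majority3_tpm, scope="full_system")
    b = phi_per_state(majority3_tpm, scope="full_system")
    assert [a[s].big_phi for s in sorted(a)] == [b[s].big_phi for s in sorted(b)]


def test_scalar_statistics_examples():
    per_state = {0: 0.0, 1: 0.0, 2: 0.0, 3: 2.0}
    assert mean_phi(per_state) == pytest.approx(0.5)
    assert variance_phi(per_state) == pytest.approx(0.75)  # population variance
    assert fano(0.5, 0.75) == pytest.approx(1.5)
    assert fano(0.0, 0.0) is None
    constant = {s: 0.7 for s in range(4)}
    assert fano(mean_phi(constant), variance_phi(constant)) == pytest.approx(0.0)


# ----------------------------------------------------------------------
# surfaces
# ----------------------------------------------------------------------
@pytest.fixture(scope="module")
def tiny_surface(school2):
    grid = {"xi_D": (100.0, 400.0), "xi_VF": (np.pi, 2 * np.pi), "xi_TR": (0.0,)}
    return phi_surface(school2, grid, dt_frames=20, setting="local", scope="full_system")


def test_surface_shape_contract(tiny_surface):
    assert len(tiny_surface.table) == 4
    assert all(len(v) == 4 for v in tiny_surface.per_state.values())
    assert (tiny_surface.table["mean_phi"] >= 0).all()
    assert (tiny_surface.table["var_phi"] >= 0).all()


def test_surface_permutation_invariant(school2):
    grid = {"xi_D": (200.0,), "xi_VF": (2 * np.pi,), "xi_TR": (0.0,)}
    a = phi_surface(school2, grid, 20, scope="full_system")
    swapped = Trajectory(positions=school2.positions[:, ::-1, :], fps=school2.fps)
    b = phi_surface(swapped, grid, 20, scope="full_system")
    assert a.table["mean_phi"].iloc[0] == pytest.approx(
        b.table["mean_phi"].iloc[0], abs=1e-9
    )


def test_surface_degenerate_extremes_near_zero_phi(school2):
    # huge xi_D, complete field, zero turning: states pinned all-ON for a
    # cohesive school -> near-degenerate TPM -> Phi ~ 0
    grid = {"xi_D": (100000.0,), "xi_VF": (2 * np.pi,), "xi_TR": (0.0,)}
    surf = phi_surface(school2, grid, 20, scope="full_system")
    # residual integration comes only from the maximum-entropy fill of the
    # three never-visited rows; the observed dynamics are degenerate
    assert surf.table["mean_phi"].iloc[0] < 0.1
    on_rate = surf.per_state[0]  # all-ON state dominates the chain
    assert len(on_rate) == 4


def test_global_setting_surface(school3):
    grid = {"Xi_CM": (300.0,), "Xi_AD": (np.pi / 2,)}
    surf = phi_surface(school3, grid, 20, setting="global", scope="full_system")
    assert len(surf.table) == 1
    assert surf.table["mean_phi"].iloc[0] >= 0


def _surface_from_values(values, axis_vals=None):
    """Build a synthetic 1-axis surface for arithmetic tests."""
    import pandas as pd

    from swarmphi.integrity_analysis import PhiSurface

    values = np.asarray(values, float)
    axis_vals = tuple(axis_vals if axis_vals is not None else np.arange(len(values), dtype=float))
    table = pd.DataFrame({"xi_D": axis_vals, "mean_phi": values, "var_phi": 0.0, "fano": 0.0})
    return PhiSurface(
        table=table,
        axes={"xi_D": axis_vals},
        dt_frames=1,
        n_individuals=2,
        scope="full_system",
        setting="local",
        per_state={i: np.array([v] * 4) for i, v in enumerate(values)},
    )


def test_normalized_surface_max_maps_to_one():
    surf = _surface_from_values([0.1, 0.4, 0.2])
    norm = normalized_surface(surf)
    assert norm.table["mean_phi"].max() == pytest.approx(1.0)
    np.testing.assert_allclose(norm.table["mean_phi"], [0.25, 1.0, 0.5])


def test_normalized_surface_all_zero_error():
    with pytest.raises(ValueError):
        normalized_surface(_surface_from_values([0.0, 0.0]))


def test_normalized_surface_region_split():
    surf = _surface_from_values([0.1, 0.4, 0.2, 0.8], axis_vals=(1.0, 2.0, 3.0, 4.0))
    region = surf.table["xi_D"].to_numpy() <= 2.0  # normalize within a sub-region
    norm = normalized_surface(surf, region=region)
    np.testing.assert_allclose(norm.table["mean_phi"], [0.25, 1.0, 0.5, 2.0])


def test_weighted_mean_position_examples():
    surf = _surface_from_values([0.0, 1.0, 0.0])
    assert weighted_mean_position(surf)["xi_D"] == pytest.approx(1.0)
    surf2 = _surface_from_values([0.8, 0.0, 0.8])
    assert weighted_mean_position(surf2)["xi_D"] == pytest.approx(1.0)  # midpoint
    surf3 = _surface_from_values([0.6, 1.0, 0.9, 0.1])
    # cells above 0.5 * max: values 0.6, 1.0, 0.9 at coords 0, 1, 2
    expect = (0.6 * 0 + 1.0 * 1 + 0.9 * 2) / 2.5
    assert weighted_mean_position(surf3)["xi_D"] == pytest.approx(expect)


def test_top_k_mean_examples():
    rng = np.random.default_rng(0)
    vals = rng.uniform(size=17)
    surf = _surface_from_values(vals)
    assert top_k_mean(surf, 1) == pytest.approx(vals.max())
    assert top_k_mean(surf, 100) == pytest.approx(vals.mean())
    k = 5
    assert top_k_mean(surf, k) == pytest.approx(np.sort(vals)[::-1][:k].mean())


def test_local_global_difference():
    a = _surface_from_values([0.1, 0.2, 0.3])
    assert local_global_difference(a, a, k=2) == pytest.approx(0.0)
    b = _surface_from_values([0.1 + 0.05, 0.2 + 0.05, 0.3 + 0.05])
    assert local_global_difference(b, a, k=2) == pytest.approx(0.05)


def test_phi_fano_correlation():
    means = np.linspace(0.1, 1.0, 10)
    r, excluded = phi_fano_correlation(list(zip(means, 2 * means + 0.1)))
    assert r == pytest.approx(1.0)
    assert excluded == 0
    r, _ = phi_fano_correlation([(m, 0.5) for m in means])
    assert np.isnan(r)  # constant fano -> undefined, documented as NaN
    rng = np.random.default_rng(1)
    pts = list(zip(rng.uniform(size=30), rng.uniform(size=30)))
    r, _ = phi_fano_correlation(pts)
    ref = pearsonr([p[0] for p in pts], [p[1] for p in pts]).statistic
    assert r == pytest.approx(ref, abs=1e-12)
    r, excluded = phi_fano_correlation([(0.1, None), (0.2, 0.3), (0.3, np.nan), (0.4, 0.5)])
    assert excluded == 2


def test_surface_csv_roundtrip(tiny_surface, tmp_path):
    tiny_surface.to_csv(tmp_path / "surface.csv")
    import pandas as pd

    df = pd.read_csv(tmp_path / "surface.csv")
    assert len(df) == 4
    assert {"xi_D", "xi_VF", "xi_TR", "mean_phi", "var_phi", "dt_frames", "n"} <= set(df.columns)
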