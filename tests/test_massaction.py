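import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from smtkin.massaction import (
    MassActionState,
    estimate_nuclear_volume,
    invert_for_sites,
    invert_stage_table,
    predict_bound_fraction,
    relative_concentration,
)

SPHERE_VOLUME_R5 = 523.5987756  # (4/3) pi 5^3, closed form


def make_state(lam1, lam2, V=200.0, k1=3.0, k2=0.15):
    return MassActionState("s", V_n=V, k1=k1, k2=k2, lambda1=lam1, lambda2=lam2)


def test_predict_single_class_limit_and_symmetry():
    # lambda2 = 0: B = 0 and D follows the single-class occupancy
    D, B = predict_bound_fraction(make_state(1.5, 0.0))
    r1 = 1.5 / 3.0
    assert B == 0.0
    assert D == pytest.approx(r1 / (1 + r1))
    # equal occupancy ratios: D = 2/3, B = 1/2
    D, B = predict_bound_fraction(make_state(3.0, 0.15))
    assert D == pytest.approx(2 / 3)
    assert B == pytest.approx(1 / 2)


def test_halving_volume_doubles_association_and_raises_D():
    """Fixed apparent sites in a shrinking nucleus concentrate DNA and
    strictly increase the bound fraction."""
    lam1, lam2, V = 0.8, 0.1, 300.0
    D_big, _ = predict_bound_fraction(make_state(lam1, lam2, V=V))
    # same N_app (= lambda * V), half the volume -> doubled lambdas
    D_small, _ = predict_bound_fraction(make_state(2 * lam1, 2 * lam2, V=V / 2))
    assert D_small > D_big


@settings(deadline=None, max_examples=100)
@given(
    lam1=st.floats(1e-3, 50.0), lam2=st.floats(1e-3, 50.0),
    k1=st.floats(0.5, 50.0), k2=st.floats(1e-3, 0.49), V=st.floats(1.0, 1e3),
)
def test_invert_is_exact_inverse_of_predict(lam1, lam2, k1, k2, V):
    state = MassActionState("s", V_n=V, k1=k1, k2=k2, lambda1=lam1, lambda2=lam2)
    D, B = predict_bound_fraction(state)
    n1, n2 = invert_for_sites(D, B, k1, k2, V)
    # algebraically exact; conditioning through 1/(1-D) costs digits
    # when occupancy approaches saturation
    assert n1 == pytest.approx(lam1 * V, rel=1e-6)
    assert n2 == pytest.approx(lam2 * V, rel=1e-6)


def test_invert_rejects_saturation():
    with pytest.raises(ValueError):
        invert_for_sites(1.0, 0.5, 3.0, 0.15, 200.0)
    with pytest.raises(ValueError):
        invert_for_sites(0.5, 1.5, 3.0, 0.15, 200.0)


def test_monotonicity_of_bound_fraction():
    """D increases in each apparent site number and in 1/V_n (checked at
    random parameter points)."""
    rng = np.random.default_rng(40)
    for _ in range(100):
        lam1, lam2 = rng.uniform(0.01, 5, 2)
        k1, k2 = 3.0, 0.15
        V = rng.uniform(50, 500)
        D0, _ = predict_bound_fraction(make_state(lam1, lam2, V=V))
        # shrink the nucleus at fixed N_app
        f = rng.uniform(0.5, 0.95)
        D1, _ = predict_bound_fraction(make_state(lam1 / f, lam2 / f, V=V * f))
        assert D1 > D0
        # more sites of either class at fixed volume
        D2, _ = predict_bound_fraction(make_state(lam1 * 1.3, lam2, V=V))
        D3, _ = predict_bound_fraction(make_state(lam1, lam2 * 1.3, V=V))
        assert D2 > D0 and D3 > D0


def test_stage_table_volume_driven_rise_keeps_sites_flat():
    """When shrinking volume alone explains the rising bound fraction,
    the apparent site numbers stay constant across stages."""
    k1, k2 = 1 / 0.3, 1 / 2.0
    lamV1, lamV2 = 160.0, 24.0          # lambda_i * V_n, fixed
    rows = []
    for stage, V in [("64-cell", 400.0), ("1k-cell", 250.0), ("oblong", 130.0)]:
        st_ = MassActionState(stage, V_n=V, k1=k1, k2=k2,
                              lambda1=lamV1 / V, lambda2=lamV2 / V)
        D, B = predict_bound_fraction(st_)
        rows.append((stage, D, B, V))
    df = pd.DataFrame(rows, columns=["stage", "D", "B", "V_n"])
    out = invert_stage_table(df, k1, k2)
    assert np.allclose(out["N_app_total"], 1.0, rtol=1e-9)
    assert np.allclose(out["D_pred"], df["D"], rtol=1e-9)
    assert out["D"].is_monotonic_increasing     # volume-driven rise


def test_error_propagation_taylor_matches_bootstrap():
    df = pd.DataFrame({
        "stage": ["a", "b"], "D": [0.05, 0.2], "B": [0.2, 0.2],
        "V_n": [400.0, 150.0], "D_sem": [0.005, 0.01],
        "B_sem": [0.02, 0.02], "V_n_sem": [20.0, 8.0],
    })
    k1, k2 = 1 / 0.3, 1 / 6.8
    boot = invert_stage_table(df, k1, k2, n_boot=10000, seed=41)
    tay = invert_stage_table(df, k1, k2, error_method="taylor")
    # agreement of the non-reference stage s.e. within ~10 %
    assert boot["N_app_total_sem"].iloc[1] == pytest.approx(
        tay["N_app_total_sem"].iloc[1], rel=0.12)


def test_sphere_volume_closed_form():
    geo = estimate_nuclear_volume([5.0, 5.0, 5.0])
    assert geo.volume_um3 == pytest.approx(SPHERE_VOLUME_R5, rel=1e-9)
    geo = estimate_nuclear_volume([5.0, 5.0])
    assert geo.volume_um3 == pytest.approx(SPHERE_VOLUME_R5, rel=1e-9)


def test_contour_ellipse_volume_within_5_percent():
    a, b = 6.0, 4.0
    theta = np.linspace(0, 2 * np.pi, 400, endpoint=False)
    contour = np.column_stack([a * np.cos(theta) + 3.0, b * np.sin(theta) - 1.0])
    geo = estimate_nuclear_volume(contour, mode="intermediate")
    expected = 4 / 3 * np.pi * a * b * np.sqrt(a * b)
    assert geo.volume_um3 == pytest.approx(expected, rel=0.05)
    assert geo.axes_um[0] == pytest.approx(a, rel=0.03)
    assert geo.axes_um[1] == pytest.approx(b, rel=0.03)
    with pytest.raises(ValueError):
        estimate_nuclear_volume(np.zeros((10, 2)))


def test_relative_concentration_scales_with_counts():
    geo = estimate_nuclear_volume([2.879411911, 2.879411911, 2.879411911])
    assert geo.volume_um3 == pytest.approx(100.0, rel=1e-6)
    assert relative_concentration([10], geo) == pytest.approx(0.1, rel=1e-6)
    assert relative_concentration([10, 20, 30], geo) == pytest.approx(0.2, rel=1e-6)
    assert relative_concentration([20, 40, 60], geo) == pytest.approx(
        2 * relative_concentration([10, 20, 30], geo))
    with pytest.raises(ValueError):
        relative_concentration([], geo)
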