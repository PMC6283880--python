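import numpy as np
import pandas as pd
import pytest

from smtkin.itm import (
    ClassProbabilities,
    ITMCounts,
    bootstrap_estimates,
    class_probability_matrix,
    correct_counts,
    fold_change_ci,
    linearity_check,
    observation_probabilities,
)
from smtkin.schedules import interlaced
from smtkin.synthetic import (
    SOX19B_LIKE,
    TBP_LIKE,
    EmbryoScenario,
    KineticGroundTruth,
    generate_stage_series,
    simulate_itm_events,
)


@pytest.fixture(scope="module")
def itm():
    return interlaced()


def test_probabilities_trivial_limits(itm):
    p = observation_probabilities(0.0, 0.0, itm)
    assert p.as_tuple() == pytest.approx((1.0, 1.0, 1.0))
    # overwhelming bleaching: nothing survives into a second frame
    p = observation_probabilities(0.0, 500.0, itm)
    assert p.p_all < 1e-6 and p.p_long < 1e-6
    # ordering always holds
    p = observation_probabilities(0.5, 3.0, itm)
    assert p.p_long <= p.p_all <= p.p_detect <= 1.0


@pytest.mark.parametrize("k_off, kb", [
    (1 / 6.8, 7.3),     # stable class, strong bleaching
    (1 / 0.3, 7.3),     # transient class, strong bleaching
    (1 / 2.0, 5.8),     # stable class, moderate bleaching
    (1 / 2.0, 0.0),     # no bleaching
])
def test_probabilities_match_monte_carlo(k_off, kb, itm):
    """Closed-form phase-averaged probabilities agree with the event
    simulator within 3 Monte-Carlo standard errors."""
    n = 400_000
    truth = KineticGroundTruth(k1=max(k_off, 10.0), k2=k_off, frac_stable=1.0, kb=kb)
    ev = simulate_itm_events(truth, itm, n, seed=30)
    mc = np.array([ev["detected"].mean(), ev["all_bound"].mean(),
                   ev["long_bound"].mean()])
    se = np.sqrt(mc * (1 - mc) / n)
    cf = np.array(observation_probabilities(k_off, kb, itm).as_tuple())
    assert np.all(np.abs(cf - mc) <= 3 * np.maximum(se, 1e-9))


def test_identity_probabilities_return_raw_ratios(itm):
    ident = ClassProbabilities(1.0, 1.0, 1.0)
    # p_long = p_all makes the 2x2 system singular; perturb off-diagonal
    probs = (ClassProbabilities(1.0, 1.0, 0.0), ClassProbabilities(1.0, 1.0, 1.0))
    counts = ITMCounts("e", "s", n_detected=100, n_all_bound=40, n_long=10)
    est = correct_counts(counts, probs)
    assert est.F_raw == pytest.approx(0.4)
    assert est.R_raw == pytest.approx(0.25)
    # with identity-like detection, D = F_raw and B = R_raw
    assert est.D == pytest.approx(est.F_raw)
    assert est.B == pytest.approx(est.R_raw)


def test_correction_inverts_expected_counts_exactly(itm):
    """Linear-algebra identity: expectation counts from (n1, n2, probs)
    correct back to (n1, n2) and the true bound fraction."""
    probs = class_probability_matrix(TBP_LIKE.k1, TBP_LIKE.k2, TBP_LIKE.kb, itm)
    p1, p2 = probs
    n1, n2, n_free = 400.0, 100.0, 1500.0
    counts = ITMCounts(
        "e", "s",
        n_detected=n_free + n1 * p1.p_detect + n2 * p2.p_detect,
        n_all_bound=n1 * p1.p_all + n2 * p2.p_all,
        n_long=n1 * p1.p_long + n2 * p2.p_long,
    )
    est = correct_counts(counts, probs)
    assert est.B == pytest.approx(n2 / (n1 + n2), rel=1e-12)
    assert est.D == pytest.approx((n1 + n2) / (n1 + n2 + n_free), rel=1e-12)
    assert est.R_raw != pytest.approx(est.B, rel=0.01)   # raw ratio is biased


def test_corrected_estimates_recover_simulation_truth(itm):
    """Round trip through the event simulator at scale: corrected D and
    B match the generator's ground truth; the raw ratios do not."""
    truth = TBP_LIKE
    probs = class_probability_matrix(truth.k1, truth.k2, truth.kb, itm)
    ev = simulate_itm_events(truth, itm, 1_000_000, seed=31, p_bound=0.24)
    counts = ITMCounts(
        "e", "s", n_detected=int(ev["detected"].sum()),
        n_all_bound=int(ev["all_bound"].sum()), n_long=int(ev["long_bound"].sum()),
    )
    est = correct_counts(counts, probs)
    # the 2x2 solve amplifies count noise; ~2-4% relative scatter at this n
    assert est.D == pytest.approx(0.24, rel=0.06)
    assert est.B == pytest.approx(truth.frac_stable, rel=0.10)
    assert abs(est.R_raw - truth.frac_stable) > 0.02
    assert abs(est.F_raw - 0.24) > 0.2          # raw F wildly off at these rates


def test_counts_validation_and_exclusion():
    with pytest.raises(ValueError):
        ITMCounts("e", "s", n_detected=10, n_all_bound=20, n_long=1)
    assert ITMCounts("e", "s", 100, 1, 0).excluded
    assert not ITMCounts("e", "s", 100, 2, 0).excluded


def test_bootstrap_identical_embryos_have_zero_spread(itm):
    probs = class_probability_matrix(TBP_LIKE.k1, TBP_LIKE.k2, TBP_LIKE.kb, itm)
    df = pd.DataFrame({
        "stage": ["s"] * 5, "embryo": range(5),
        "n_detected": [1000] * 5, "n_all_bound": [50] * 5, "n_long": [10] * 5,
    })
    est = bootstrap_estimates(df, probs, n_subsets=200, seed=32)
    assert est.D_sem == pytest.approx(0.0, abs=1e-12)
    assert est.B_sem == pytest.approx(0.0, abs=1e-12)
    assert est.n_embryos == 5


def test_bootstrap_spread_shrinks_with_cohort_size(itm):
    probs = class_probability_matrix(TBP_LIKE.k1, TBP_LIKE.k2, TBP_LIKE.kb, itm)
    rng = np.random.default_rng(33)

    def cohort(n_embryos):
        det = rng.poisson(2000, n_embryos)
        nall = rng.binomial(det, 0.05)
        nlong = rng.binomial(nall, 0.2)
        return pd.DataFrame({
            "stage": ["s"] * n_embryos, "embryo": range(n_embryos),
            "n_detected": det, "n_all_bound": nall, "n_long": nlong,
        })

    sems = [np.mean([
        bootstrap_estimates(cohort(n), probs, n_subsets=300, seed=rng).D_sem
        for _ in range(10)
    ]) for n in (5, 20)]
    assert sems[1] < sems[0] / 1.4      # roughly 1/sqrt(n) shrinkage


def test_bootstrap_excludes_sparse_embryos_and_single_embryo_passthrough(itm):
    probs = class_probability_matrix(TBP_LIKE.k1, TBP_LIKE.k2, TBP_LIKE.kb, itm)
    df = pd.DataFrame({
        "stage": ["s"] * 2, "embryo": [0, 1],
        "n_detected": [1000, 800], "n_all_bound": [50, 1], "n_long": [10, 0],
    })
    est = bootstrap_estimates(df, probs, seed=34)
    assert est.n_excluded == 1
    assert est.n_embryos == 1
    assert np.isnan(est.D_sem)          # undefined error, flagged


def test_stage_series_fold_change_recovered_within_ci(itm):
    """Ground-truth bound fraction doubled between stages: the corrected
    estimates' ratio covers 2 within the bootstrap CI."""
    truth = SOX19B_LIKE
    scens = [
        EmbryoScenario("early", 400, 25000, 0.10, 0.3),
        EmbryoScenario("late", 200, 25000, 0.20, 0.3),
    ]
    df = generate_stage_series(scens, truth, seed=35, n_embryos=5)
    probs = class_probability_matrix(truth.k1, truth.k2, truth.kb, itm)
    e0 = bootstrap_estimates(df[df.stage == "early"], probs, seed=36)
    e1 = bootstrap_estimates(df[df.stage == "late"], probs, seed=37)
    fold, lo, hi = fold_change_ci(e0, e1)
    assert lo <= 2.0 <= hi
    # stable proportion is stage-constant when rates and mix are constant
    assert abs(e1.B - e0.B) < 3 * np.hypot(e0.B_sem, e1.B_sem) + 0.05


def test_linearity_preferred_for_mass_action_cohorts(itm):
    rng = np.random.default_rng(38)
    x = rng.uniform(2000, 12000, 8)
    lin = pd.DataFrame({
        "stage": "s", "embryo": range(8),
        "n_detected": x.astype(int),
        "n_all_bound": rng.poisson(0.04 * x),
    })
    assert linearity_check(lin)["preferred"] == "linear"
    sat = lin.copy()
    sat["n_all_bound"] = rng.poisson(600 * x / (4000 + x))
    assert linearity_check(sat)["preferred"] == "concave"
    zero = lin.copy()
    zero["n_all_bound"] = 0
    res = linearity_check(zero)
    assert res["slope"] == pytest.approx(0.0)
    with pytest.raises(ValueError):
        linearity_check(lin.iloc[:2])
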