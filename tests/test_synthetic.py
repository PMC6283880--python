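import numpy as np
import pytest
from scipy import stats

from smtkin.kinetics import build_histogram, global_fit
from smtkin.schedules import continuous, interlaced, timelapse
from smtkin.synthetic import (
    SOX19B_LIKE,
    TBP_LIKE,
    EmbryoScenario,
    KineticGroundTruth,
    generate_stage_series,
    render_movie,
    sample_binding_durations,
    simulate_itm_events,
)

# closed-form mean visible duration for a single class under the
# half-frame rule: tau * exp(-k*tau_on/2) / (1 - exp(-k*tau)), computed
# independently at k=0.147/s, tau_on=tau_tl=0.25 s
MEAN_DURATION_CLOSED_FORM = 6.8023


def test_single_class_mean_duration_matches_long_residence_time():
    """With only the stable class and no bleaching, the mean on-time
    approaches the 6.8 s residence time (1/k2)."""
    truth = KineticGroundTruth(k1=10.0, k2=0.147, frac_stable=1.0, kb=0.0)
    m = sample_binding_durations(truth, continuous(0.25), 20000, seed=1)
    mean_s = m.mean() * 0.25
    assert mean_s == pytest.approx(MEAN_DURATION_CLOSED_FORM, abs=0.15)
    assert mean_s == pytest.approx(6.8, abs=0.2)


def test_instant_bleaching_gives_single_frame_durations():
    """kb >> 1/tau_on: every detected molecule bleaches within its first
    frame (the kb -> infinity limit of the sampler)."""
    truth = KineticGroundTruth(k1=3.33, k2=0.147, frac_stable=0.2, kb=60.0)
    m = sample_binding_durations(truth, timelapse(0.25, 1.0), 1_000_000, seed=2)
    assert len(m) > 100          # a few survive the first half frame
    assert m.max() == 1


def test_single_exponential_rate_recovered_within_3_se():
    """One class, no bleaching: the fitted rate equals the input rate."""
    k_true = 0.8
    truth = KineticGroundTruth(k1=k_true, k2=0.0, frac_stable=0.0, kb=0.0)
    m = sample_binding_durations(truth, timelapse(0.25, 1.0), 10000, seed=3)
    fit = global_fit([build_histogram(m, 0.25, 1.0)], model="single")
    se = fit.stderr.get("k1", np.nan)
    assert np.isfinite(se)
    assert abs(fit.k1 - k_true) < 3 * max(se, 1e-3)


def test_bleaching_depends_only_on_illuminated_time():
    """Doubling the dark time leaves the frames-to-bleach distribution
    unchanged (bleaching is gated by illumination)."""
    truth = KineticGroundTruth(k1=1.0, k2=0.0, frac_stable=1.0, kb=4.0)
    m_short = sample_binding_durations(truth, timelapse(0.25, 0.5), 20000, seed=4)
    m_long = sample_binding_durations(truth, timelapse(0.25, 1.0), 20000, seed=5)
    # same expected number of frames although wall-clock dark time doubled
    sem = m_short.std() / np.sqrt(len(m_short))
    assert m_short.mean() == pytest.approx(m_long.mean(), abs=4 * sem)


def test_duration_histogram_matches_binned_mixture_model():
    """Sampled durations follow the discrete two-class decay with the
    effective rates kb*tau_on/tau_tl + k_i (goodness of fit)."""
    tau_on, tau_tl = 0.25, 1.0
    truth = KineticGroundTruth(k1=3.33, k2=0.147, frac_stable=0.2, kb=7.3)
    m = sample_binding_durations(truth, timelapse(tau_on, tau_tl), 100000, seed=6)
    # independent oracle: per-class detection and per-frame survival
    half = tau_on / 2
    p_det = np.exp(-(np.array([truth.k1, truth.k2]) + truth.kb) * half)
    w = np.array([1 - truth.frac_stable, truth.frac_stable]) * p_det
    w /= w.sum()
    lam = (truth.kb * tau_on / tau_tl + np.array([truth.k1, truth.k2])) * tau_tl
    rho = np.exp(-lam)
    kmax = m.max()
    grid = np.arange(1, kmax + 1)
    pm = w[0] * (1 - rho[0]) * rho[0] ** (grid - 1) + w[1] * (1 - rho[1]) * rho[1] ** (grid - 1)
    pm[-1] += 1 - pm.sum()          # tail mass into the last bin
    obs = np.bincount(m, minlength=kmax + 1)[1:]
    keep = len(m) * pm > 5
    chi2 = np.sum((obs[keep] - len(m) * pm[keep]) ** 2 / (len(m) * pm[keep]))
    p = stats.chi2.sf(chi2, keep.sum() - 1)
    assert p > 1e-3


def test_generators_reproduce_bit_identically_under_fixed_seed():
    truth = TBP_LIKE
    a = sample_binding_durations(truth, timelapse(0.25, 1.0), 1000, seed=9)
    b = sample_binding_durations(truth, timelapse(0.25, 1.0), 1000, seed=9)
    assert np.array_equal(a, b)
    ea = simulate_itm_events(truth, interlaced(), 1000, seed=9, p_bound=0.5)
    eb = simulate_itm_events(truth, interlaced(), 1000, seed=9, p_bound=0.5)
    assert ea.equals(eb)
    scen = EmbryoScenario("oblong", 150, 200, 0.3, 0.2)
    ma = render_movie(scen, truth, continuous(0.25), seed=9, n_frames=5, shape=(32, 32))
    mb = render_movie(scen, truth, continuous(0.25), seed=9, n_frames=5, shape=(32, 32))
    assert np.array_equal(ma.frames, mb.frames)
    assert ma.truth.equals(mb.truth)


def test_itm_event_classes_are_nested_and_immortals_survive():
    ev = simulate_itm_events(TBP_LIKE, interlaced(), 20000, seed=10, p_bound=0.7)
    bound = ev[ev["class"] != "free"]
    assert (bound["long_bound"] <= bound["all_bound"]).all()
    assert (bound["all_bound"] <= bound["detected"]).all()
    free = ev[ev["class"] == "free"]
    assert (free["n_frames"] == 1).all()
    assert not free["all_bound"].any() and not free["long_bound"].any()

    immortal = KineticGroundTruth(k1=1.0, k2=0.0, frac_stable=1.0, kb=0.0)
    ev = simulate_itm_events(immortal, interlaced(), 500, seed=11)
    assert ev["long_bound"].all()


def test_rendered_photons_match_truth_within_poisson_error():
    scen = EmbryoScenario("oblong", 150, 150, 1.0, 0.2)
    snr, background, read_noise = 5.0, 100.0, 2.0
    psf_sigma, pixel = 0.15, 0.166
    movie = render_movie(
        scen, TBP_LIKE, continuous(0.25), psf_sigma=psf_sigma, snr=snr,
        seed=12, n_frames=30, shape=(64, 64), background=background,
        read_noise=read_noise,
    )
    amp = snr * np.sqrt(background + read_noise**2)
    expected_spot_photons = len(movie.truth) * amp * 2 * np.pi * (psf_sigma / pixel) ** 2
    n_pix = movie.frames.size
    measured = movie.frames.sum() - background * n_pix
    noise_sd = np.sqrt(background * n_pix + n_pix * read_noise**2 + expected_spot_photons)
    # 4 sigma plus a small allowance for Gaussian tails clipped at edges
    assert abs(measured - expected_spot_photons) < 4 * noise_sd + 0.02 * expected_spot_photons


def test_empty_movie_is_pure_noise():
    scen = EmbryoScenario("oblong", 150, 0, 0.5, 0.2)
    movie = render_movie(scen, TBP_LIKE, continuous(0.25), seed=13, n_frames=5,
                         shape=(32, 32))
    assert len(movie.truth) == 0
    assert movie.frames.mean() == pytest.approx(100.0, rel=0.05)


def test_stage_series_doubled_bound_fraction_doubles_raw_ratio():
    scens = [
        EmbryoScenario("a", 300, 20000, 0.08, 0.2),
        EmbryoScenario("b", 150, 20000, 0.16, 0.2),
    ]
    df = generate_stage_series(scens, TBP_LIKE, seed=14, n_embryos=4)
    f = df.groupby("stage").sum(numeric_only=True)
    ratio = (f.loc["b", "n_all_bound"] / f.loc["b", "n_detected"]) / (
        f.loc["a", "n_all_bound"] / f.loc["a", "n_detected"])
    assert ratio == pytest.approx(2.0, rel=0.25)


def test_ground_truth_validation():
    with pytest.raises(ValueError):
        KineticGroundTruth(k1=0.1, k2=0.5, frac_stable=0.5, kb=1.0)  # k1 < k2
    with pytest.raises(ValueError):
        KineticGroundTruth(k1=1.0, k2=0.1, frac_stable=1.5, kb=1.0)
    with pytest.raises(ValueError):
        EmbryoScenario("s", -5.0, 10, 0.1, 0.1)
    with pytest.raises(ValueError):
        sample_binding_durations(TBP_LIKE, interlaced(), 10, seed=0)
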