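"""Seeded generators of ground-truth single-molecule data.

The generators realize the physical model underlying the analysis — two
exponential chromatin-dissociation classes, photobleaching active only
while the laser is on, Brownian motion of unbound molecules — rather than
the closed-form approximations fitted downstream.  This lets the test
suite quantify the approximation error of the fitted models themselves.

Conventions
-----------
* A molecule photoactivates ("appears") at wall time ``t0`` and is lost at
  the earlier of unbinding (exponential in wall time, rate ``k_i``) and
  photobleaching (exponential in *illuminated* time, rate ``kb``).
* A molecule is visible in a frame if it is present for at least half of
  that frame's illumination (symmetric half-frame rule).
* A molecule visible in ``m`` consecutive frames of a time-lapse condition
  reports a fluorescent "on" time of ``m * tau_tl`` seconds.

All randomness flows through :func:`numpy.random.default_rng`; passing the
same seed reproduces outputs bit-identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile

from .schedules import IlluminationSchedule, interlaced

__all__ = [
    "KineticGroundTruth",
    "EmbryoScenario",
    "SimulatedMovie",
    "TBP_LIKE",
    "SOX19B_LIKE",
    "sample_binding_durations",
    "sample_detected_durations",
    "simulate_timelapse_experiment",
    "simulate_itm_events",
    "render_movie",
    "generate_stage_series",
]

TRUTH_COLUMNS = [
    "molecule_id", "frame", "x_um", "y_um", "class", "bound_start_s", "bound_end_s",
]


@dataclass(frozen=True)
class KineticGroundTruth:
    """True kinetic parameters of a simulated molecule population.

    Parameters
    ----------
    k1, k2 : float
        Dissociation rate constants of the transient (fast) and stable
        (slow) binding class (1/s); ``k1 > k2`` when both classes are
        populated.
    frac_stable : float
        Probability that a binding event belongs to the stable class.
    kb : float
        Photobleaching rate constant while illuminated (1/s).
    lambda1, lambda2 : float
        Pseudo-first-order association rates into transient and stable
        sites (1/s); used by the mass-action layer, not by the duration
        sampler.
    D_free : float
        Diffusion coefficient of unbound molecules (µm²/s).
    """

    k1: float
    k2: float
    frac_stable: float
    kb: float
    lambda1: float = 0.0
    lambda2: float = 0.0
    D_free: float = 2.0

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "kb", "lambda1", "lambda2", "D_free"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.frac_stable <= 1.0:
            raise ValueError("frac_stable must be in [0, 1]")
        if 0.0 < self.frac_stable < 1.0 and not self.k1 > self.k2:
            raise ValueError("k1 must exceed k2 when both classes are present")


#: Parameter set resembling a general transcription factor with a long
#: stable residence time (transient 0.3 s, stable 6.8 s, bleaching 7.3/s).
TBP_LIKE = KineticGroundTruth(k1=1 / 0.3, k2=1 / 6.8, frac_stable=0.2, kb=7.3)

#: Parameter set resembling a sequence-specific factor with a shorter
#: stable residence time (transient 0.3 s, stable 2.0 s, bleaching 5.8/s).
SOX19B_LIKE = KineticGroundTruth(k1=1 / 0.3, k2=1 / 2.0, frac_stable=0.2, kb=5.8)


@dataclass(frozen=True)
class EmbryoScenario:
    """Stage-level description of one embryo population."""

    stage: str
    nuclear_volume: float          # µm³
    n_molecules: int               # expression level (activated molecules)
    bound_fraction_true: float
    stable_proportion_true: float

    def __post_init__(self) -> None:
        if self.nuclear_volume <= 0:
            raise ValueError("nuclear_volume must be positive")
        for name in ("bound_fraction_true", "stable_proportion_true"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SimulatedMovie:
    """A rendered image stack plus its ground truth."""

    frames: np.ndarray             # (n_frames, h, w) counts
    pixel_size: float              # µm
    schedule: IlluminationSchedule
    truth: pd.DataFrame            # TRUTH_COLUMNS
    seed: int

    def save(self, path, truth_path=None) -> None:
        tifffile.imwrite(path, self.frames.astype(np.float32))
        if truth_path is not None:
            self.truth.to_csv(truth_path, sep="\t", index=False)


def _rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ----------------------------------------------------------------------
# lifetime machinery
# ----------------------------------------------------------------------

def _exponential(rng, rate, n):
    """Exponential draws that tolerate rate == 0 (infinite lifetime)."""
    if rate == 0:
        return np.full(n, np.inf)
    return rng.exponential(1.0 / rate, size=n)


def _draw_class_rates(truth: KineticGroundTruth, rng, n):
    stable = rng.random(n) < truth.frac_stable
    k_off = np.where(stable, truth.k2, truth.k1)
    return stable, k_off


def _bind_times(rng, k_off):
    """Exponential unbinding times for per-molecule rates (0 -> inf)."""
    u = rng.random(k_off.shape)
    with np.errstate(divide="ignore"):
        return np.where(k_off > 0, -np.log1p(-u) / np.where(k_off > 0, k_off, 1.0), np.inf)


# ----------------------------------------------------------------------
# time-lapse visible-duration sampler
# ----------------------------------------------------------------------

def sample_binding_durations(truth, schedule, n, seed):
    """Sample visible-fluorescence durations (in frames) under time-lapse.

    Each of ``n`` bound molecules appears at the start of frame 0, unbinds
    after an exponential wall time (rate ``k1`` or ``k2``, class chosen
    with ``frac_stable``) and bleaches after an exponential *illuminated*
    time (rate ``kb``).  A molecule present for at least half of a frame's
    illumination is visible in that frame; the reported duration is the
    number of consecutive visible frames starting at frame 0.  Molecules
    never visible (lost within the first half frame) are dropped.

    Returns
    -------
    numpy.ndarray of int
        Visible durations in frames (``>= 1``); multiply by
        ``schedule.tau_tl`` for seconds.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if schedule.mode not in ("continuous", "timelapse"):
        raise ValueError("duration sampling requires a continuous or timelapse schedule")
    if truth.frac_stable < 1 and truth.k1 == 0 and truth.kb == 0:
        raise ValueError("transient class with zero dissociation and zero bleaching never ends")
    rng = _rng(seed)
    _, k_off = _draw_class_rates(truth, rng, n)
    t_bind = _bind_times(rng, k_off)
    l_bleach = _exponential(rng, truth.kb, n)

    half = schedule.tau_on / 2.0
    # visible in frame j  <=>  t_bind > j*tau_tl + half  and
    #                          l_bleach > j*tau_on + half
    with np.errstate(invalid="ignore"):
        m_bind = np.ceil((t_bind - half) / schedule.tau_tl)
        m_bleach = np.ceil((l_bleach - half) / schedule.tau_on)
    m = np.minimum(m_bind, m_bleach)
    m = m[np.isfinite(m) & (m >= 1)].astype(np.int64)
    return m


def sample_detected_durations(truth, schedule, n_detected, seed):
    """Like :func:`sample_binding_durations`, but yields exactly
    ``n_detected`` visible durations (the experiment records detected
    molecules; molecules lost before their first frame are not counted)."""
    rng = _rng(seed)
    out = []
    got = 0
    for _ in range(1000):
        batch = sample_binding_durations(truth, schedule, 4 * n_detected, rng)
        out.append(batch)
        got += len(batch)
        if got >= n_detected:
            return np.concatenate(out)[:n_detected]
    raise RuntimeError("detection probability too low to collect the requested molecules")


def simulate_timelapse_experiment(truth, tau_on, tau_tls, n_detected_total, seed):
    """Simulate a full multi-condition time-lapse experiment.

    Detected molecules are split equally across the time-lapse conditions.
    Returns ``{tau_tl: durations_in_frames}``.
    """
    from .schedules import timelapse as _tl

    rng = _rng(seed)
    nper = n_detected_total // len(tau_tls)
    return {
        tl: sample_detected_durations(truth, _tl(tau_on, tl), nper, rng)
        for tl in tau_tls
    }


# ----------------------------------------------------------------------
# interlaced time-lapse (ITM) event simulator
# ----------------------------------------------------------------------

def simulate_itm_events(truth, schedule, n, seed, p_bound=1.0, max_cycles=1000):
    """Simulate detection and classification outcomes under an ITM schedule.

    Molecules appear at a uniformly random phase of the ITM cycle.  Bound
    molecules persist until unbinding (wall time) or bleaching
    (illuminated time) and are visible in every frame for at least half of
    whose illumination they are present.  Unbound molecules diffuse with
    ``D_free`` and are recorded as detected in exactly one frame: between
    165 ms frames a molecule with µm²/s-scale mobility virtually never
    stays within the 166 nm linking gate, and out-of-plane motion removes
    it from the light sheet.

    Parameters
    ----------
    p_bound : float
        Probability that a molecule is chromatin-bound at activation
        (remainder are free).  Default 1 (pure bound population, as used
        for observation-probability oracles).
    max_cycles : int
        Acquisition horizon in ITM cycles; molecules surviving beyond it
        (possible only for vanishing rates) are truncated there.

    Returns
    -------
    pandas.DataFrame
        Columns ``molecule_id, class, n_frames, detected, all_bound,
        long_bound`` — one row per molecule.  ``all_bound`` means visible
        in at least two successive acquisitions; ``long_bound`` means the
        visible span crosses at least one long dark time.
    """
    if schedule.mode != "interlaced":
        raise ValueError("simulate_itm_events requires an interlaced schedule")
    rng = _rng(seed)
    F = schedule.frames_per_burst
    a = schedule.tau_on
    T = schedule.cycle_time
    half = a / 2.0

    bound = rng.random(n) < p_bound
    stable, k_off = _draw_class_rates(truth, rng, n)
    t0 = rng.uniform(0.0, T, size=n)
    t_bind = _bind_times(rng, k_off)
    l_bleach = _exponential(rng, truth.kb, n)

    # wall time of death: unbinding, or bleaching converted from
    # illuminated to wall time given the appearance phase
    g0 = schedule.cumulative_illumination(t0)
    finite_bleach = np.isfinite(l_bleach)
    t_bleach_wall = np.full(n, np.inf)
    if finite_bleach.any():
        t_bleach_wall[finite_bleach] = schedule.wall_time_at_illumination(
            g0[finite_bleach] + l_bleach[finite_bleach]
        )
    death = np.minimum(t0 + t_bind, t_bleach_wall)
    death = np.minimum(death, max_cycles * T)

    # first acquisition eligible for visibility (appearance before the
    # midpoint of its illumination)
    f0 = np.ceil((t0 - half) / a)
    in_burst0 = f0 <= F - 1
    j0 = np.where(in_burst0, np.maximum(f0, 0), F).astype(np.int64)
    s_j0 = np.where(in_burst0, j0 * a, T)
    detected_bound = death >= np.maximum(s_j0, t0) + half

    # last acquisition with death past the illumination midpoint
    q = death - half
    b1 = np.floor(q / T)
    rem = q - b1 * T
    f1 = np.minimum(F - 1, np.floor(rem / a))
    j1 = (b1 * F + f1).astype(np.int64)

    n_frames = np.where(detected_bound, j1 - j0 + 1, 0)
    all_bound = detected_bound & (n_frames >= 2)
    long_bound = detected_bound & ((j1 // F) > (j0 // F))

    cls = np.where(bound, np.where(stable, "stable", "transient"), "free")
    detected = np.where(bound, detected_bound, True)
    out = pd.DataFrame(
        {
            "molecule_id": np.arange(n),
            "class": cls,
            "n_frames": np.where(bound, n_frames, 1).astype(np.int64),
            "detected": detected,
            "all_bound": np.where(bound, all_bound, False),
            "long_bound": np.where(bound, long_bound, False),
        }
    )
    return out


# ----------------------------------------------------------------------
# movie rendering
# ----------------------------------------------------------------------

def render_movie(
    scenario,
    truth,
    schedule,
    psf_sigma=0.15,
    snr=4.0,
    seed=0,
    n_frames=50,
    shape=(64, 64),
    pixel_size=0.166,
    background=100.0,
    read_noise=2.0,
):
    """Render a 2D movie of diffraction-limited spots with ground truth.

    Spots are isotropic 2D Gaussians of width ``psf_sigma`` (µm) whose
    peak amplitude is ``snr`` times the background noise standard
    deviation ``sqrt(background + read_noise**2)``; frames carry Poisson
    photon noise plus Gaussian read noise (gain 1).  ``snr`` may be a
    scalar or a ``(low, high)`` range sampled per molecule.

    Bound molecules are stationary from activation until unbinding or
    bleaching; free molecules perform Brownian motion with ``D_free`` and
    stay visible until they bleach.  Photoactivation is staggered: each
    molecule turns on in a frame drawn uniformly over the movie, keeping
    the per-frame spot density sparse as in photoactivated acquisitions.
    """
    if np.min(snr) <= 0:
        raise ValueError("snr must be positive")
    if psf_sigma < pixel_size / 2:
        warnings.warn("psf_sigma below half a pixel: spots are undersampled")
    rng = _rng(seed)
    h, w = shape
    n = scenario.n_molecules
    noise_sd = np.sqrt(background + read_noise**2)

    bound = rng.random(n) < scenario.bound_fraction_true
    stable, k_off = _draw_class_rates(
        replace(truth, frac_stable=scenario.stable_proportion_true), rng, n
    )
    t_bind = np.where(bound, _bind_times(rng, k_off), 0.0)
    l_bleach = _exponential(rng, truth.kb, n)
    half = schedule.tau_on / 2.0
    with np.errstate(invalid="ignore"):
        m_bleach = np.ceil((l_bleach - half) / schedule.tau_on)
        m_bind = np.where(
            bound, np.ceil((t_bind - half) / schedule.tau_tl), np.inf
        )
    m_vis = np.clip(np.minimum(m_bind, m_bleach), 0, n_frames)

    margin = 3.0 * psf_sigma / pixel_size
    x0 = rng.uniform(margin, w - 1 - margin, size=n) * pixel_size
    y0 = rng.uniform(margin, h - 1 - margin, size=n) * pixel_size
    if np.ndim(snr) > 0:
        snr_i = rng.uniform(snr[0], snr[1], size=n)
    else:
        snr_i = np.full(n, float(snr))
    amp = snr_i * noise_sd

    yy, xx = np.mgrid[0:h, 0:w]
    expected = np.full((n_frames, h, w), float(background))
    rows = []
    step = np.sqrt(2.0 * truth.D_free * schedule.tau_tl)
    first_frame = rng.integers(0, n_frames, size=n)
    for i in range(n):
        x, y = x0[i], y0[i]
        cls = "stable" if (bound[i] and stable[i]) else (
            "transient" if bound[i] else "free")
        for dj in range(int(min(m_vis[i], n_frames - first_frame[i]))):
            j = int(first_frame[i]) + dj
            if not bound[i] and dj > 0:
                x += rng.normal(0.0, step)
                y += rng.normal(0.0, step)
                if not (0 <= x <= (w - 1) * pixel_size and 0 <= y <= (h - 1) * pixel_size):
                    break
            px, py = x / pixel_size, y / pixel_size
            expected[j] += amp[i] * np.exp(
                -((xx - px) ** 2 + (yy - py) ** 2) / (2 * (psf_sigma / pixel_size) ** 2)
            )
            rows.append((i, j, x, y, cls, 0.0, t_bind[i] if bound[i] else 0.0))
    frames = rng.poisson(expected).astype(float) + rng.normal(
        0.0, read_noise, size=expected.shape
    )
    truth_df = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    seed_val = seed if isinstance(seed, (int, np.integer)) else -1
    return SimulatedMovie(frames, pixel_size, schedule, truth_df, int(seed_val))


# ----------------------------------------------------------------------
# stage-series generator
# ----------------------------------------------------------------------

def generate_stage_series(
    scenarios,
    truth,
    seed,
    n_embryos=5,
    expression_cv=0.3,
    schedule=None,
):
    """Generate per-embryo ITM count tables for a series of stages.

    Expression levels are jittered log-normally between embryos with
    coefficient of variation ``expression_cv`` (the small between-embryo
    variation in mRNA-injected expression).  Each molecule is bound with
    the stage's true bound fraction (law of mass action, no saturation),
    stable with the stage's true stable proportion, and observed through
    the ITM event simulator.

    Parameters
    ----------
    scenarios : list of EmbryoScenario
    truth : KineticGroundTruth or mapping stage -> KineticGroundTruth
    n_embryos : int or mapping stage -> int

    Returns
    -------
    pandas.DataFrame
        Columns ``stage, embryo, n_detected, n_all_bound, n_long``.
    """
    if len(scenarios) < 2:
        raise ValueError("need at least two stages")
    rng = _rng(seed)
    if schedule is None:
        schedule = interlaced()
    sigma = np.sqrt(np.log1p(expression_cv**2))
    rows = []
    for sc in scenarios:
        tr = truth[sc.stage] if isinstance(truth, dict) else truth
        tr = replace(tr, frac_stable=sc.stable_proportion_true)
        ne = n_embryos[sc.stage] if isinstance(n_embryos, dict) else n_embryos
        for e in range(ne):
            n_mol = max(1, int(round(
                sc.n_molecules * rng.lognormal(-sigma**2 / 2, sigma))))
            ev = simulate_itm_events(
                tr, schedule, n_mol, rng, p_bound=sc.bound_fraction_true
            )
            rows.append(
                (
                    sc.stage,
                    e,
                    int(ev["detected"].sum()),
                    int(ev["all_bound"].sum()),
                    int(ev["long_bound"].sum()),
                )
            )
    return pd.DataFrame(rows, columns=["stage", "embryo", "n_detected", "n_all_bound", "n_long"])
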