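"""Configuration, orchestration and reporting for end-to-end runs.

A run is described by a plain-text INI-style config (key = value under
``[section]`` headers; no code execution).  Every stochastic step draws
from the single mandatory seed, so a rerun with the same config and seed
reproduces all tables bit-identically; a manifest records the package
version, seed and all parameters of the run.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .itm import bootstrap_estimates, class_probability_matrix, linearity_check
from .kinetics import build_histogram, compare_models, global_fit
from .massaction import invert_stage_table
from .schedules import IlluminationSchedule, interlaced, timelapse
from .synthetic import (
    TBP_LIKE,
    SOX19B_LIKE,
    EmbryoScenario,
    KineticGroundTruth,
    generate_stage_series,
    simulate_timelapse_experiment,
)

__all__ = ["RunConfig", "load_config", "run_pipeline", "make_report", "setup_logging"]

log = logging.getLogger("smtkin")

TRUTH_PRESETS = {"tbp": TBP_LIKE, "sox19b": SOX19B_LIKE}


def setup_logging(level=logging.INFO, stream=None):
    """Structured per-stage logging with counts at every filter."""
    handler = logging.StreamHandler(stream or sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("smtkin")
    root.handlers[:] = [handler]
    root.setLevel(level)
    return root


@dataclass
class RunConfig:
    """Parsed and validated run configuration."""

    mode: str                       # "timelapse", "itm" or "both"
    seed: int
    outdir: Path
    schedules: dict = field(default_factory=dict)
    kinetics: dict = field(default_factory=dict)
    itm: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True).encode()
        ).hexdigest()[:16]


def _parse_schedule(section) -> IlluminationSchedule:
    mode = section.get("mode", "timelapse")
    tau_on = section.getfloat("tau_on")
    if mode == "interlaced":
        return interlaced(
            tau_on=tau_on,
            frames_per_burst=section.getint("frames_per_burst", 2),
            dark_long=section.getfloat("dark_long"),
        )
    return timelapse(tau_on, section.getfloat("tau_tl", tau_on))


def _parse_truth(spec: str) -> KineticGroundTruth:
    spec = spec.strip()
    if spec.lower() in TRUTH_PRESETS:
        return TRUTH_PRESETS[spec.lower()]
    vals = dict(item.split("=") for item in spec.split())
    return KineticGroundTruth(
        k1=float(vals["k1"]), k2=float(vals["k2"]),
        frac_stable=float(vals.get("frac_stable", 0.2)),
        kb=float(vals["kb"]),
    )


def _parse_stages(spec: str):
    out = []
    for item in spec.split(","):
        stage, vol, nmol, d, b = item.strip().split(":")
        out.append(EmbryoScenario(stage, float(vol), int(nmol), float(d), float(b)))
    return out


def load_config(path) -> RunConfig:
    """Parse and validate a run config file."""
    cp = configparser.ConfigParser()
    read = cp.read(path)
    if not read:
        raise FileNotFoundError(path)
    if "run" not in cp:
        raise ValueError("config needs a [run] section")
    run = cp["run"]
    if "seed" not in run:
        raise ValueError("a seed is mandatory for every stochastic step")
    mode = run.get("mode", "both")
    if mode not in ("timelapse", "itm", "both"):
        raise ValueError(f"unknown run mode {mode!r}")
    schedules = {
        name.split(":", 1)[1]: _parse_schedule(cp[name])
        for name in cp.sections() if name.startswith("schedule:")
    }
    cfg = RunConfig(
        mode=mode,
        seed=run.getint("seed"),
        outdir=Path(run.get("outdir", "smtkin_out")),
        schedules=schedules,
        kinetics=dict(cp["kinetics"]) if "kinetics" in cp else {},
        itm=dict(cp["itm"]) if "itm" in cp else {},
        raw={s: dict(cp[s]) for s in cp.sections()},
    )
    if mode in ("itm", "both"):
        ref = cfg.itm.get("schedule", "itm")
        if ref not in schedules:
            raise ValueError(f"ITM section references undefined schedule {ref!r}")
    return cfg


def _run_timelapse(cfg, rng, outdir):
    kin = cfg.kinetics
    truth = _parse_truth(kin.get("truth", "tbp"))
    tau_on = float(kin.get("tau_on", 0.25))
    tls = [float(x) for x in kin.get("tau_tls", "0.25 0.5 1 2 4").split()]
    n_total = int(kin.get("n_detected", 4780))
    log.info("timelapse: simulating %d detected molecules over %d conditions",
             n_total, len(tls))
    data = simulate_timelapse_experiment(truth, tau_on, tls, n_total, rng)
    hists = [build_histogram(m, tau_on, tl) for tl, m in data.items()]
    rows = []
    for h in hists:
        for t, c, e in zip(h.times, h.counts, h.errors):
            rows.append((h.tau_on, h.tau_tl, t, c, e))
    hist_df = pd.DataFrame(rows, columns=["tau_on", "tau_tl", "t_s", "count", "error"])
    hist_df.to_csv(outdir / "histograms.tsv", sep="\t", index=False)

    fit_d = global_fit(hists, model="double")
    fit_s = global_fit(hists, model="single")
    preferred, chi_s, chi_d = compare_models(fit_s, fit_d)
    log.info("fit: 1/k1=%.3f s 1/k2=%.3f s kb=%.3f /s; %s model preferred",
             1 / fit_d.k1, 1 / fit_d.k2, fit_d.kb, preferred)
    with open(outdir / "fit_report.txt", "w") as fh:
        fh.write("global residence-time fit\n")
        fh.write(f"conditions: tau_on={tau_on}s tau_tl={tls}\n")
        fh.write(f"molecules (detected): {n_total}\n")
        for name, f in (("double", fit_d), ("single", fit_s)):
            fh.write(f"\n[{name}]\n")
            fh.write(f"kb = {f.kb:.4f} +- {f.stderr.get('kb', float('nan')):.4f} 1/s\n")
            fh.write(f"k1 = {f.k1:.4f} 1/s  (residence {1 / f.k1:.3f} s)\n")
            if name == "double":
                fh.write(f"k2 = {f.k2:.4f} 1/s  (residence {1 / f.k2:.3f} s)\n")
                fh.write(f"B  = {f.B:.3f}\n")
            fh.write(f"reduced chi2 = {f.redchi:.4g}\n")
        fh.write(f"\npreferred model: {preferred} "
                 f"(reduced chi2 {chi_d:.4g} double vs {chi_s:.4g} single)\n")
    return {"fit_double": fit_d, "fit_single": fit_s, "preferred": preferred,
            "histograms": hist_df}


def _run_itm(cfg, rng, outdir, fit=None):
    itm_cfg = cfg.itm
    schedule = cfg.schedules[itm_cfg.get("schedule", "itm")]
    truth = _parse_truth(itm_cfg.get("truth", "tbp"))
    scenarios = _parse_stages(itm_cfg.get(
        "stages", "64-cell:500:8000:0.04:0.2, oblong:150:8000:0.24:0.2"))
    n_embryos = int(itm_cfg.get("n_embryos", 5))
    counts = generate_stage_series(
        scenarios, truth, seed=rng, n_embryos=n_embryos, schedule=schedule)
    counts.to_csv(outdir / "itm_counts.tsv", sep="\t", index=False)
    log.info("itm: %d embryos x %d stages, %d detected molecules total",
             n_embryos, len(scenarios), counts["n_detected"].sum())

    rates_from = itm_cfg.get("rates", "truth")
    if rates_from == "fit" and fit is not None:
        k1, k2, kb = fit.k1, fit.k2, fit.kb
    else:
        k1, k2, kb = truth.k1, truth.k2, truth.kb
    probs = class_probability_matrix(k1, k2, kb, schedule)
    subsets = int(itm_cfg.get("subsets", 900))
    frac = float(itm_cfg.get("frac", 0.8))
    rows = []
    lin = {}
    for sc in scenarios:
        sub = counts[counts["stage"] == sc.stage]
        est = bootstrap_estimates(sub, probs, n_subsets=subsets, frac=frac,
                                  seed=rng)
        if len(sub) >= 3:
            lin[sc.stage] = linearity_check(sub)
        rows.append((sc.stage, sc.nuclear_volume, est.F_raw, est.R_raw,
                     est.D, est.D_sem, est.B, est.B_sem,
                     est.n_embryos, est.n_excluded))
    est_df = pd.DataFrame(rows, columns=[
        "stage", "V_n", "F_raw", "R_raw", "D", "D_sem", "B", "B_sem",
        "n_embryos", "n_excluded"])
    est_df.to_csv(outdir / "stage_estimates.tsv", sep="\t", index=False)

    ma_in = est_df[["stage", "D", "B", "V_n", "D_sem", "B_sem"]].copy()
    ma_in["V_n_sem"] = 0.05 * ma_in["V_n"]
    valid = (ma_in["D"] > 0) & (ma_in["D"] < 1)
    bundle = {"counts": counts, "estimates": est_df, "linearity": lin}
    if valid.iloc[0] and valid.sum() >= 2:
        ma = invert_stage_table(ma_in[valid], k1, k2, seed=int(rng.integers(2**31)))
        ma.to_csv(outdir / "massaction.tsv", sep="\t", index=False)
        bundle["massaction"] = ma
    else:
        log.warning("mass-action inversion skipped: bound fractions outside (0, 1)")
    return bundle


def run_pipeline(config) -> dict:
    """Execute a configured run; returns the result bundle.

    Stages execute in order (simulate/ingest, fit or estimate, model
    inversion); any stage failure aborts with a stage-tagged error.  All
    tables are written under ``config.outdir`` together with a manifest.
    """
    cfg = config if isinstance(config, RunConfig) else load_config(config)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    bundle = {"config": cfg}
    try:
        if cfg.mode in ("timelapse", "both"):
            bundle.update(_run_timelapse(cfg, rng, outdir))
    except Exception as exc:
        raise RuntimeError(f"[timelapse] stage failed: {exc}") from exc
    try:
        if cfg.mode in ("itm", "both"):
            bundle.update(_run_itm(cfg, rng, outdir, fit=bundle.get("fit_double")))
    except Exception as exc:
        raise RuntimeError(f"[itm] stage failed: {exc}") from exc
    with open(outdir / "manifest.txt", "w") as fh:
        fh.write(f"smtkin {__version__}\nseed {cfg.seed}\nmode {cfg.mode}\n")
        fh.write(f"config-digest {cfg.digest()}\n")
        for sec, vals in cfg.raw.items():
            for k, v in vals.items():
                fh.write(f"{sec}.{k} = {v}\n")
    return bundle


def make_report(bundle, path=None, plots=False) -> str:
    """Human-readable summary of a result bundle.

    A partial bundle (e.g. time-lapse only) yields a partial report with
    a warning line for each missing section.
    """
    lines = ["smtkin run report", "=" * 40]
    if "fit_double" in bundle:
        f, s = bundle["fit_double"], bundle["fit_single"]
        lines += [
            "",
            "residence-time kinetics (global fit)",
            f"  transient residence time: {1 / f.k1:.3f} s",
            f"  stable residence time:    {1 / f.k2:.3f} s",
            f"  photobleaching rate:      {f.kb:.3f} 1/s",
            f"  stable amplitude 1-B:     {1 - f.B:.3f}",
            f"  reduced chi2: double {f.redchi:.4g}, single {s.redchi:.4g}"
            f" -> {bundle['preferred']} preferred",
        ]
    else:
        lines += ["", "WARNING: no time-lapse section in this run"]
    if "estimates" in bundle:
        est = bundle["estimates"]
        lines += ["", "ITM stage estimates (bound fraction D, stable proportion B)"]
        for _, r in est.iterrows():
            lines.append(
                f"  {r['stage']:>10}: D = {r['D']:.4f} +- {r['D_sem']:.4f}"
                f"   B = {r['B']:.3f} +- {r['B_sem']:.3f}"
                f"   ({int(r['n_embryos'])} embryos, {int(r['n_excluded'])} excluded)")
        d = est["D"].to_numpy()
        if len(d) >= 2 and d[0] > 0:
            lines.append(f"  bound-fraction fold change "
                         f"{est['stage'].iloc[0]} -> {est['stage'].iloc[-1]}: "
                         f"{d[-1] / d[0]:.2f}")
        for stage, res in bundle.get("linearity", {}).items():
            lines.append(f"  {stage}: bound vs detected fits "
                         f"{res['preferred']} (slope {res['slope']:.4f})")
    else:
        lines += ["", "WARNING: no ITM section in this run"]
    if "massaction" in bundle:
        ma = bundle["massaction"]
        lines += ["", "mass-action inversion (apparent binding sites, reference = 1)"]
        for _, r in ma.iterrows():
            sem = f" +- {r['N_app_total_sem']:.2f}" if "N_app_total_sem" in ma else ""
            lines.append(f"  {r['stage']:>10}: N_app = {r['N_app_total']:.2f}{sem}"
                         f"   (V_n = {r['V_n']:.0f} um3, D_pred = {r['D_pred']:.4f})")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    if plots and "estimates" in bundle:
        _plot_estimates(bundle, Path(path).parent if path else Path("."))
    return text


def _plot_estimates(bundle, outdir):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    est = bundle["estimates"]
    fig, axes = plt.subplots(1, 3 if "massaction" in bundle else 2,
                             figsize=(10, 3), constrained_layout=True)
    axes[0].errorbar(range(len(est)), est["D"], yerr=est["D_sem"], fmt="o-")
    axes[0].set_ylabel("bound fraction D")
    axes[1].errorbar(range(len(est)), est["B"], yerr=est["B_sem"], fmt="o-")
    axes[1].set_ylabel("stable proportion B")
    for ax in axes:
        ax.set_xticks(range(len(est)))
        ax.set_xticklabels(est["stage"], rotation=45)
    if "massaction" in bundle:
        ma = bundle["massaction"]
        axes[2].plot(range(len(ma)), ma["N_app_total"], "s-")
        axes[2].set_ylabel("apparent sites (rel.)")
    fig.savefig(outdir / "report.png", dpi=120)
    plt.close(fig)
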