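"""Equilibrium mass-action model of TF-chromatin occupancy.

Free TFs associate with pseudo-first-order rates ``lambda_i = k_on,i *
[sites_i]`` into a transient (i=1) and a stable (i=2) binding class and
dissociate with rate constants ``k_i``.  At equilibrium the occupancy
ratios are ``f_i / f_free = lambda_i / k_i``, giving a chromatin-bound
fraction

    D = (r1 + r2) / (1 + r1 + r2),      r_i = lambda_i / k_i,

and a stable proportion ``B = r2 / (r1 + r2)`` — both independent of TF
copy number as long as binding sites are not saturated.  Because the
association rate constant is not experimentally accessible, site numbers
are reported as the dimensionless *apparent number of chromatin binding
sites* ``N_app,i ∝ lambda_i * V_n``, normalized to a reference stage:
shrinking the nuclear volume at fixed sites raises every ``lambda_i``
and with it the bound fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MassActionState",
    "NucleusGeometry",
    "predict_bound_fraction",
    "invert_for_sites",
    "invert_stage_table",
    "estimate_nuclear_volume",
    "relative_concentration",
]


@dataclass
class MassActionState:
    """Per-stage equilibrium description."""

    stage: str
    V_n: float                     # nuclear volume, µm³
    k1: float                      # transient dissociation rate, 1/s
    k2: float                      # stable dissociation rate, 1/s
    lambda1: float = np.nan        # pseudo-association rates, 1/s
    lambda2: float = np.nan
    N_app_1: float = np.nan        # apparent site numbers (relative units)
    N_app_2: float = np.nan
    N_app_total: float = np.nan
    D_pred: float = np.nan
    B_pred: float = np.nan

    def __post_init__(self) -> None:
        if self.V_n <= 0:
            raise ValueError("V_n must be positive")


@dataclass(frozen=True)
class NucleusGeometry:
    """Nuclear volume derived from envelope measurements."""

    stage: str
    axes_um: tuple
    volume_um3: float
    method: str

    def __post_init__(self) -> None:
        if self.volume_um3 <= 0:
            raise ValueError("volume must be positive")


def predict_bound_fraction(state):
    """Equilibrium bound fraction and stable proportion from the rates.

    Updates and returns ``(D_pred, B_pred)``; contains no TF-abundance
    term by construction (occupancy fractions are copy-number free in the
    absence of saturation).
    """
    if state.k1 <= 0 or state.k2 <= 0:
        raise ValueError("dissociation rates must be positive")
    if state.lambda1 < 0 or state.lambda2 < 0:
        raise ValueError("association rates must be non-negative")
    r1 = state.lambda1 / state.k1
    r2 = state.lambda2 / state.k2
    D = (r1 + r2) / (1.0 + r1 + r2)
    B = r2 / (r1 + r2) if (r1 + r2) > 0 else 0.0
    state.D_pred, state.B_pred = D, B
    return D, B


def invert_for_sites(D, B, k1, k2, V_n, V_ref=None):
    """Apparent binding-site numbers from measured (D, B) and volume.

    Inverts the equilibrium relations: ``r2 = B*D/(1-D)``, ``r1 =
    (1-B)*D/(1-D)``, ``lambda_i = r_i * k_i`` and ``N_app,i ∝ lambda_i *
    V_n`` (known only up to the global association constant; pass
    ``V_ref`` — typically the reference stage's ``lambda_i * V_n`` tuple
    — via :func:`invert_stage_table` for normalized output).

    Returns ``(N_app_1, N_app_2)`` in units of ``lambda_i * V_n``
    (µm³/s).  ``D >= 1`` (saturation) is rejected.
    """
    if not 0.0 < D < 1.0:
        raise ValueError("D must lie strictly between 0 and 1 (no saturation)")
    if not 0.0 <= B <= 1.0:
        raise ValueError("B must lie in [0, 1]")
    odds = D / (1.0 - D)
    lam1 = (1.0 - B) * odds * k1
    lam2 = B * odds * k2
    return lam1 * V_n, lam2 * V_n


def invert_stage_table(
    stages,
    k1,
    k2,
    reference=None,
    n_boot=10000,
    seed=0,
    error_method="bootstrap",
):
    """Apparent site numbers across stages, normalized to a reference.

    Parameters
    ----------
    stages : DataFrame with columns ``stage, D, B, V_n`` and optional
        ``D_sem, B_sem, V_n_sem``.
    reference : stage label whose ``N_app`` is set to 1 (default: first
        row).
    error_method : {"bootstrap", "taylor"}
        Parametric bootstrap (Gaussian draws of D, B, V_n truncated to
        their domains) or first-order Taylor propagation.

    Returns
    -------
    DataFrame with ``N_app_1, N_app_2, N_app_total`` and their errors
    (``*_sem``), ``lambda1, lambda2``, ``D_pred`` round-trip check.
    """
    df = stages.reset_index(drop=True).copy()
    bad = df.loc[~((df["D"] > 0) & (df["D"] < 1)), "stage"].tolist()
    if bad:
        raise ValueError(f"D must lie strictly in (0, 1); offending stages: {bad}")
    if reference is None:
        reference = df["stage"].iloc[0]

    def napp(D, B, V):
        odds = D / (1.0 - D)
        return (1.0 - B) * odds * k1 * V, B * odds * k2 * V

    n1, n2 = napp(df["D"].to_numpy(), df["B"].to_numpy(), df["V_n"].to_numpy())
    ref = df.index[df["stage"] == reference][0]
    scale1, scale2 = n1[ref], n2[ref]
    scale_tot = (n1 + n2)[ref]
    out = df.copy()
    out["lambda1"] = n1 / df["V_n"]
    out["lambda2"] = n2 / df["V_n"]
    out["N_app_1"] = n1 / scale1
    out["N_app_2"] = n2 / scale2
    out["N_app_total"] = (n1 + n2) / scale_tot

    has_err = all(c in df for c in ("D_sem", "B_sem", "V_n_sem"))
    if has_err:
        if error_method == "bootstrap":
            rng = np.random.default_rng(seed)
            draws = []
            with np.errstate(divide="ignore", invalid="ignore"):
                for _ in range(n_boot):
                    D = np.clip(rng.normal(df["D"], df["D_sem"]), 1e-6, 1 - 1e-6)
                    B = np.clip(rng.normal(df["B"], df["B_sem"]), 0.0, 1.0)
                    V = np.clip(rng.normal(df["V_n"], df["V_n_sem"]), 1e-9, None)
                    a, b = napp(D, B, V)
                    draws.append((a / a[ref], b / b[ref], (a + b) / (a + b)[ref]))
            arr = np.array(draws)
            arr[~np.isfinite(arr)] = np.nan   # reference-stage draws at B = 0
            out["N_app_1_sem"] = np.nanstd(arr[:, 0, :], axis=0)
            out["N_app_2_sem"] = np.nanstd(arr[:, 1, :], axis=0)
            out["N_app_total_sem"] = np.nanstd(arr[:, 2, :], axis=0)
        elif error_method == "taylor":
            for col, f in (
                ("N_app_1", lambda D, B, V: (1 - B) * D / (1 - D) * k1 * V),
                ("N_app_2", lambda D, B, V: B * D / (1 - D) * k2 * V),
                ("N_app_total",
                 lambda D, B, V: ((1 - B) * k1 + B * k2) * D / (1 - D) * V),
            ):
                grads = _numeric_grad(f, df)
                var = sum(
                    (grads[p] * df[f"{p}_sem"]) ** 2 for p in ("D", "B", "V_n")
                )
                vals = f(df["D"], df["B"], df["V_n"])
                rel = np.sqrt(var) / vals
                # the reported quantity is a ratio to the reference stage,
                # whose own uncertainty enters every other stage's error
                rel_ratio = np.sqrt(rel**2 + rel.iloc[ref] ** 2)
                rel_ratio.iloc[ref] = 0.0
                out[f"{col}_sem"] = out[col] * rel_ratio
        else:
            raise ValueError("error_method must be 'bootstrap' or 'taylor'")

    # forward-prediction round trip
    r1 = out["lambda1"] / k1
    r2 = out["lambda2"] / k2
    out["D_pred"] = (r1 + r2) / (1 + r1 + r2)
    return out


def _numeric_grad(f, df, rel=1e-6):
    grads = {}
    base = f(df["D"], df["B"], df["V_n"])
    for p in ("D", "B", "V_n"):
        kw = {q: df[q].astype(float).copy() for q in ("D", "B", "V_n")}
        h = np.maximum(np.abs(kw[p]) * rel, 1e-12)
        kw[p] = kw[p] + h
        grads[p] = (f(kw["D"], kw["B"], kw["V_n"]) - base) / h
    return grads


def estimate_nuclear_volume(measurement, stage="", mode="intermediate"):
    """Nuclear volume from envelope measurements via an ellipsoid model.

    ``measurement`` is either a pair/triple of semi-axes (µm) or an
    ``(n, 2)`` array of envelope contour points (µm), whose in-plane
    semi-axes are taken from the second moments of the contour (for
    points uniform in the ellipse parameter, the semi-axis equals
    ``sqrt(2)`` times the principal standard deviation).

    With only in-plane semi-axes ``a >= b``, the out-of-plane semi-axis
    is ``b`` (``mode="prolate"``), ``a`` (``"oblate"``), or
    ``sqrt(a*b)`` (``"intermediate"``, default); volume is
    ``(4/3)*pi*a*b*c``.
    """
    arr = np.asarray(measurement, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 2:
        if len(arr) < 5 or np.ptp(arr, axis=0).min() <= 0:
            raise ValueError("degenerate contour")
        centered = arr - arr.mean(axis=0)
        evals = np.linalg.eigvalsh(np.cov(centered.T))[::-1]
        axes = tuple(np.sqrt(2.0 * evals))
        method = f"contour-{mode}"
    elif arr.ndim == 1 and arr.size in (2, 3):
        if np.any(arr <= 0):
            raise ValueError("axes must be positive")
        axes = tuple(sorted(arr, reverse=True))
        method = f"axes-{mode}" if arr.size == 2 else "axes-3d"
    else:
        raise ValueError("measurement must be semi-axes or an (n, 2) contour")

    if len(axes) == 3:
        a, b, c = axes
    else:
        a, b = axes
        c = {"prolate": b, "oblate": a, "intermediate": np.sqrt(a * b)}[mode]
    volume = 4.0 / 3.0 * np.pi * a * b * c
    return NucleusGeometry(stage=stage, axes_um=(a, b, c), volume_um3=float(volume),
                           method=method)


def relative_concentration(first_frame_counts, geometry):
    """Relative molecule concentration (molecules/µm³) per nucleus.

    ``first_frame_counts`` are molecule counts from the first frame after
    each photoactivation pulse (later frames under-count because of
    bleaching); the mean count over activations is divided by the nuclear
    volume.  The value is relative — it reports on activated fusion
    proteins, not on endogenous TF concentration.
    """
    counts = np.asarray(first_frame_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("no designated first frames")
    return float(counts.mean() / geometry.volume_um3)
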