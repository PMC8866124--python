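"""Lipari--Szabo model-free analysis of backbone 15N relaxation.

Forward model: the spectral density

    J(w) = (2/5) [ S^2 tc / (1 + (w tc)^2) + (1 - S^2) t' / (1 + (w t')^2) ],
    1/t' = 1/tc + 1/te,

with overall correlation time tc (isotropic tumbling), order parameter
S^2 and internal time te, feeds the standard dipolar + CSA expressions
for R1, R2 and the heteronuclear NOE evaluated at {0, wN, wH-wN, wH,
wH+wN}.  Constants (N-H bond length 1.02 A, 15N CSA -172 ppm,
literature gyromagnetic ratios) are community defaults.

The fit shares a single tc across residues and selects per residue
between the {S^2} and {S^2, te} models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar

from .constants import GAMMA, MU_0, PLANCK_HBAR
from .errors import DataError, FitError

__all__ = [
    "MotionParams",
    "spectral_density",
    "predict_rates",
    "fit_modelfree",
]

N_H_BOND = 1.02e-10  # m
CSA_15N = -172e-6  # dimensionless (ppm)


@dataclass
class MotionParams:
    """Lipari--Szabo parameters: S^2 (0-1), tc in ns, te in ps."""

    s2: float
    tau_c_ns: float
    tau_e_ps: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.s2 <= 1.0:
            raise ValueError(f"S^2 must lie in [0, 1], got {self.s2}")
        if not self.tau_c_ns > 0:
            raise ValueError("tau_c must be positive")
        if self.tau_e_ps < 0:
            raise ValueError("tau_e must be non-negative")


def spectral_density(m: MotionParams, omega) -> np.ndarray:
    """J(omega) in s/rad for angular frequencies omega (rad/s)."""
    omega = np.asarray(omega, dtype=float)
    tc = m.tau_c_ns * 1e-9
    te = m.tau_e_ps * 1e-12
    if te > 0:
        tp = 1.0 / (1.0 / tc + 1.0 / te)
    else:
        tp = 0.0
    j = m.s2 * tc / (1.0 + (omega * tc) ** 2)
    if tp > 0:
        j = j + (1.0 - m.s2) * tp / (1.0 + (omega * tp) ** 2)
    return 0.4 * j


def _frequencies(field_mhz: float) -> dict[str, float]:
    w_h = 2.0 * np.pi * field_mhz * 1e6
    w_n = w_h * GAMMA["15N"] / GAMMA["1H"]  # negative gamma: sign irrelevant in J
    return dict(w_h=w_h, w_n=w_n)


def dipolar_coupling() -> float:
    """N-H dipolar coupling constant d = mu0 hbar gH gN / (4 pi r^3), rad/s."""
    return (
        MU_0 * PLANCK_HBAR * GAMMA["1H"] * abs(GAMMA["15N"])
        / (4.0 * np.pi * N_H_BOND**3)
    )


def predict_rates(m: MotionParams, field_mhz: float,
                  d: float | None = None, csa: float = CSA_15N) -> tuple[float, float, float]:
    """(R1, R2, NOE) for one residue at one static field.

    Standard dipolar + CSA expressions over J at the five canonical
    frequencies; exchange-free (R_ex belongs to the dispersion model).
    """
    w = _frequencies(field_mhz)
    w_h, w_n = w["w_h"], abs(w["w_n"])
    d = dipolar_coupling() if d is None else d
    d2 = d * d / 4.0
    c = abs(w_n) * csa / np.sqrt(3.0)
    c2 = c * c

    j = {key: float(spectral_density(m, val)) for key, val in dict(
        zero=0.0, wn=w_n, wh=w_h, diff=w_h - w_n, summ=w_h + w_n
    ).items()}

    r1 = d2 * (j["diff"] + 3.0 * j["wn"] + 6.0 * j["summ"]) + c2 * j["wn"]
    r2 = 0.5 * d2 * (
        4.0 * j["zero"] + j["diff"] + 3.0 * j["wn"]
        + 6.0 * j["wh"] + 6.0 * j["summ"]
    ) + (c2 / 6.0) * (4.0 * j["zero"] + 3.0 * j["wn"])
    gamma_ratio = GAMMA["1H"] / GAMMA["15N"]  # signed: 15N NOE can dip below 1
    noe = 1.0 + d2 * gamma_ratio * (6.0 * j["summ"] - j["diff"]) / r1
    return float(r1), float(r2), float(noe)


def _residue_sse(tc_ns: float, group: pd.DataFrame, model: str) -> tuple[float, float, float]:
    """Best (sse, s2, te) of one residue (all its fields) for a fixed tc."""

    def residuals(s2: float, te_ps: float) -> np.ndarray:
        m = MotionParams(s2, tc_ns, te_ps)
        out = []
        for _, row in group.iterrows():
            r1, r2, noe = predict_rates(m, row["field_mhz"])
            for pred, key in ((r1, "r1"), (r2, "r2"), (noe, "noe")):
                # sigma = 0 (noiseless input): fall back to a tiny relative
                # floor so exact models are still preferred by the selection
                sig = row[f"{key}_err"]
                if not sig > 0:
                    sig = max(1e-3 * abs(row[key]), 1e-6)
                out.append((row[key] - pred) / sig)
        return np.asarray(out)

    def sse(s2: float, te_ps: float) -> float:
        return float(np.sum(residuals(s2, te_ps) ** 2))

    if model == "s2":
        res = minimize_scalar(lambda s: sse(s, 0.0), bounds=(0.0, 1.0),
                              method="bounded", options=dict(xatol=1e-5))
        return float(res.fun), float(res.x), 0.0
    # {S^2, te}: grid over te, then a joint 2-parameter refinement
    te_grid = np.concatenate([[0.0], np.geomspace(1.0, 3000.0, 12)])
    best = (np.inf, 0.5, 0.0)
    for te in te_grid:
        res = minimize_scalar(lambda s: sse(s, te), bounds=(0.0, 1.0),
                              method="bounded", options=dict(xatol=1e-4))
        if res.fun < best[0]:
            best = (float(res.fun), float(res.x), float(te))
    out = least_squares(
        lambda p: residuals(float(np.clip(p[0], 0, 1)), float(max(p[1], 0.0))),
        x0=[best[1], max(best[2], 1e-3)],
        bounds=([0.0, 0.0], [1.0, 5000.0]),
        diff_step=1e-4,
    )
    s2 = float(np.clip(out.x[0], 0.0, 1.0))
    te = float(max(out.x[1], 0.0))
    return float(2.0 * out.cost), s2, te


def fit_modelfree(
    data: pd.DataFrame,
    tc_bounds_ns: tuple[float, float] = (1.0, 20.0),
    models: tuple[str, ...] = ("s2", "s2te"),
) -> pd.DataFrame:
    """Model-free fit with a global tc shared across residues.

    ``data`` columns: residue, field_mhz, r1, r1_err, r2, r2_err, noe,
    noe_err (one row per residue per field; single-field default).
    Per residue the simplest adequate model is chosen by AIC between
    {S^2} and {S^2, te}.  Returns a frame with fitted s2, tau_e_ps,
    tau_c_ns, model and a converged flag per residue.
    """
    required = {"residue", "field_mhz", "r1", "r1_err", "r2", "r2_err",
                "noe", "noe_err"}
    if not required <= set(data.columns):
        raise DataError(f"relaxation table needs columns {sorted(required)}")
    if data.empty:
        raise DataError("empty relaxation table")
    groups = [(res, g) for res, g in data.groupby("residue", sort=False)]

    # the tc scan uses the fuller {S^2, te} model (it nests {S^2} through
    # te = 0); scanning with the restricted model alone biases tc when
    # internal motion is present
    scan_model = "s2te" if "s2te" in models else models[0]

    def total_sse(tc: float) -> float:
        return sum(_residue_sse(tc, g, scan_model)[0] for _, g in groups)

    # coarse grid then local refine for the shared tumbling time
    grid = np.linspace(tc_bounds_ns[0], tc_bounds_ns[1], 16)
    sses = [total_sse(t) for t in grid]
    i = int(np.argmin(sses))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(total_sse, bounds=(lo, hi), method="bounded",
                          options=dict(xatol=1e-3))
    if not np.isfinite(res.fun):
        raise FitError("tumbling-time optimisation failed")
    tc = float(res.x)

    out = []
    for residue, g in groups:
        fits = {}
        for model in models:
            try:
                sse, s2, te = _residue_sse(tc, g, model)
                k = 1 if model == "s2" else 2
                fits[model] = (sse + 2 * k, sse, s2, te)  # AIC-like score
            except Exception:
                continue
        if not fits:
            out.append(dict(residue=residue, s2=np.nan, tau_e_ps=np.nan,
                            tau_c_ns=tc, model="none", converged=False))
            continue
        model = min(fits, key=lambda m: fits[m][0])
        _, sse, s2, te = fits[model]
        out.append(dict(residue=residue, s2=s2, tau_e_ps=te,
                        tau_c_ns=tc, model=model, converged=True, sse=sse))
    return pd.DataFrame(out)
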