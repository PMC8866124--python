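"""Global two-site fitting of CPMG relaxation dispersion data.

The workflow mirrors the standard dispersion analysis: peak intensities
are converted to effective relaxation rates ``R2eff = -(1/T) ln(I/I0)``,
intensity uncertainties come from the pooled standard deviation of
technical replicates and are propagated to R2eff by Monte Carlo, and a
single two-site exchange model is fitted simultaneously across spins,
static fields and nuclei: the exchange rate ``k_ex`` and minor
population ``p_minor`` are shared globally, the shift difference
``|ddelta|`` is per spin per nucleus, and the intrinsic rate ``R2,0`` is
per spin per nucleus per field.

The fit exploits the model structure: for a trial (k_ex, p_minor) the
exchange contribution is additive in R2,0, so each R2,0 has a
weighted-mean closed form and each |ddelta| reduces to a 1-D
minimisation, evaluated on vectorised grids of the exact closed-form
profile.  The outer 2-D problem is solved by Nelder--Mead from a
multi-start grid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

from .errors import DataError, FitError
from .exchange import (
    ExchangeParameters,
    canonical_nucleus,
    exchange_contribution,
    ppm_to_angular,
    refocusing_counts,
    CpmgSchedule,
)

__all__ = [
    "DispersionDataset",
    "FitConfig",
    "FitResult",
    "r2eff_from_intensities",
    "pooled_sd",
    "propagate_r2eff_errors",
    "global_fit",
    "mc_parameter_uncertainty",
    "detect_exchange",
]

#: Exact column order of the on-disk dispersion table (intensity mode).
INTENSITY_COLUMNS = [
    "dataset_id", "spin", "nucleus", "field_mhz", "relax_time_s",
    "nu_cpmg_hz", "intensity", "intensity_ref", "replicate_index",
]
#: Exact column order of the on-disk dispersion table (R2eff mode).
R2EFF_COLUMNS = [
    "dataset_id", "spin", "nucleus", "field_mhz", "relax_time_s",
    "nu_cpmg_hz", "r2eff", "r2eff_err", "replicate_index",
]


def r2eff_from_intensities(intensity, intensity_ref, relax_time: float):
    """Constant-time conversion ``R2eff = -(1/T) ln(I / I0)``."""
    intensity = np.asarray(intensity, dtype=float)
    intensity_ref = np.asarray(intensity_ref, dtype=float)
    if not relax_time > 0:
        raise DataError("relax_time must be positive")
    if np.any(intensity <= 0) or np.any(intensity_ref <= 0):
        raise DataError(
            "non-positive intensity encountered; peak picking upstream failed"
        )
    return -np.log(intensity / intensity_ref) / relax_time


def pooled_sd(replicate_pools: Iterable[Sequence[float]]) -> float:
    """Pooled standard deviation over per-(spin, nu_cpmg) replicate pools.

    ``sigma^2 = sum_pools sum_i (x_i - mean_pool)^2 / sum_pools (n_pool - 1)``,
    using only pools with at least two members.
    """
    num = 0.0
    dof = 0
    for pool in replicate_pools:
        x = np.asarray(list(pool), dtype=float)
        if x.size < 2:
            continue
        num += float(np.sum((x - x.mean()) ** 2))
        dof += x.size - 1
    if dof == 0:
        raise DataError(
            "no replicate pool with >= 2 members; cannot estimate uncertainty"
        )
    return float(np.sqrt(num / dof))


def propagate_r2eff_errors(
    intensity: float,
    intensity_ref: float,
    sigma_i: float,
    relax_time: float,
    n_draws: int = 1000,
    seed: int = 0,
    sigma_i_ref: float | None = None,
) -> float:
    """Monte Carlo propagation of intensity noise to sigma(R2eff).

    Both the peak intensity and the reference intensity are perturbed by
    Gaussian noise.  Draws producing non-positive intensities are
    rejected and resampled; if more than half of the attempted draws are
    rejected the noise model is deemed invalid.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    if sigma_i < 0:
        raise DataError("sigma_i must be non-negative")
    if sigma_i == 0.0:
        return 0.0
    if sigma_i_ref is None:
        sigma_i_ref = sigma_i
    rng = np.random.default_rng(seed)
    kept_i = np.empty(0)
    kept_i0 = np.empty(0)
    attempts = 0
    while kept_i.size < n_draws:
        todo = n_draws - kept_i.size
        draw_i = intensity + sigma_i * rng.standard_normal(todo)
        draw_i0 = intensity_ref + sigma_i_ref * rng.standard_normal(todo)
        attempts += todo
        ok = (draw_i > 0) & (draw_i0 > 0)
        kept_i = np.concatenate([kept_i, draw_i[ok]])
        kept_i0 = np.concatenate([kept_i0, draw_i0[ok]])
        if attempts >= 2 * n_draws and kept_i.size < attempts / 2:
            raise DataError(
                "more than 50% of Monte Carlo draws gave non-positive "
                "intensities; noise model invalid"
            )
    r2 = r2eff_from_intensities(kept_i[:n_draws], kept_i0[:n_draws], relax_time)
    return float(np.std(r2, ddof=1))


@dataclass
class DispersionDataset:
    """Per-spin, per-field, per-nucleus dispersion profiles.

    Backed by a tidy :class:`pandas.DataFrame` with either the
    intensity-mode or the R2eff-mode column set (never mixed).
    ``replicate_index`` distinguishes technical replicates of the same
    (spin, nu_cpmg) point.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        cols = list(self.df.columns)
        if all(c in cols for c in INTENSITY_COLUMNS) and "r2eff" not in cols:
            self.mode = "intensity"
        elif all(c in cols for c in R2EFF_COLUMNS) and "intensity" not in cols:
            self.mode = "r2eff"
        else:
            raise DataError(
                f"dispersion table columns {cols} match neither the intensity "
                "nor the r2eff schema (and must not mix them)"
            )
        df = self.df.copy()
        df["spin"] = df["spin"].astype(str)
        df["nucleus"] = df["nucleus"].map(canonical_nucleus)
        for col in df.columns:
            if col not in ("dataset_id", "spin", "nucleus"):
                df[col] = pd.to_numeric(df[col])
        if self.mode == "intensity" and np.any(df["intensity_ref"] <= 0):
            raise DataError("reference intensities must be positive")
        if self.mode == "r2eff" and np.any(df["r2eff_err"] < 0):
            raise DataError("r2eff_err must be non-negative")
        self.df = df

    def replicate_pools(self) -> list[np.ndarray]:
        """Replicate intensity pools keyed by (spin, nucleus, field, nu)."""
        if self.mode != "intensity":
            raise DataError("replicate pools are defined for intensity mode")
        groups = self.df.groupby(["spin", "nucleus", "field_mhz", "nu_cpmg_hz"])
        return [g["intensity"].to_numpy() for _, g in groups]

    def to_r2eff(self, n_draws: int = 500, seed: int = 0) -> "DispersionDataset":
        """Convert an intensity-mode dataset to R2eff with uncertainties.

        Replicates of a (spin, nu) point are averaged; the pooled
        intensity s.d. of the whole dataset, scaled by 1/sqrt(n_rep),
        is propagated to sigma(R2eff) by Monte Carlo.
        """
        if self.mode == "r2eff":
            return self
        sigma_i = pooled_sd(self.replicate_pools())
        rows = []
        keys = ["dataset_id", "spin", "nucleus", "field_mhz", "relax_time_s",
                "nu_cpmg_hz"]
        # sorted grouping keeps the conversion (and its per-point MC seeds)
        # invariant to the ordering of the input records
        for i, (key, g) in enumerate(self.df.groupby(keys, sort=True)):
            rec = dict(zip(keys, key))
            mean_i = g["intensity"].mean()
            i0 = g["intensity_ref"].iloc[0]
            n_rep = len(g)
            rec["r2eff"] = float(
                r2eff_from_intensities(mean_i, i0, rec["relax_time_s"])
            )
            rec["r2eff_err"] = propagate_r2eff_errors(
                mean_i, i0, sigma_i / np.sqrt(n_rep), rec["relax_time_s"],
                n_draws=max(n_draws, 100), seed=seed + i,
            )
            rec["replicate_index"] = 0
            rows.append(rec)
        return DispersionDataset(pd.DataFrame(rows, columns=R2EFF_COLUMNS))

    def units(self) -> list[tuple[str, str]]:
        """(spin, nucleus) fitting units, in first-appearance order."""
        seen: dict[tuple[str, str], None] = {}
        for spin, nuc in zip(self.df["spin"], self.df["nucleus"]):
            seen.setdefault((spin, nuc), None)
        return list(seen)


@dataclass
class FitConfig:
    """Configuration of the global two-site fit."""

    kex_starts: Sequence[float] = (250.0, 1000.0, 2500.0, 7000.0, 20000.0)
    pminor_starts: Sequence[float] = (0.01, 0.05, 0.15)
    kex_bounds: tuple[float, float] = (1.0, 1e5)
    pminor_bounds: tuple[float, float] = (1e-6, 0.499)
    #: per-nucleus upper bound of the |ddelta| search, ppm.  The grid must
    #: resolve the SSE basin, whose width in ppm scales inversely with the
    #: gyromagnetic ratio, hence the much tighter 1H bound.
    ddelta_max: Mapping[str, float] | float = field(
        default_factory=lambda: {"15N": 8.0, "1HN": 2.0, "13C": 4.0}
    )
    n_refine_starts: int = 3  # Nelder-Mead polish of the best grid starts
    nm_maxiter: int = 400
    nm_xatol: float = 1e-4
    nm_fatol: float = 1e-8
    dd_stages: int = 4  # refinement stages of the |ddelta| grid scan
    seed: int = 0


@dataclass
class FitResult:
    """Point estimate, uncertainties and diagnostics of a global fit."""

    params: ExchangeParameters
    r2_base: dict  # (spin, nucleus, field_mhz) -> fitted R2,0
    kex_err: float | None
    pminor_err: float | None
    redchi: float
    chisq: float
    n_points: int
    n_params: int
    seed: int
    spin_flags: dict = field(default_factory=dict)  # (spin, nucleus) -> bool
    converged: bool = True


class _Unit:
    """Precomputed arrays for one (spin, nucleus) fitting unit.

    All of the unit's profiles (one per static field) are concatenated
    into flat per-point arrays so that a trial (k_ex, p_minor, ddelta)
    costs a single vectorised closed-form evaluation; ``offsets`` marks
    the per-profile segments for the per-profile R2,0 profiling.
    """

    __slots__ = ("spin", "nucleus", "fields", "nu", "counts", "conv",
                 "relax", "obs", "sigma", "w", "offsets")

    def __init__(self, spin: str, nucleus: str, df: pd.DataFrame) -> None:
        self.spin = spin
        self.nucleus = nucleus
        self.fields = []
        nu_l, cnt_l, conv_l, relax_l, obs_l, sig_l, offsets = \
            [], [], [], [], [], [], [0]
        for (field_mhz, relax_time), g in df.groupby(["field_mhz", "relax_time_s"]):
            nu = g["nu_cpmg_hz"].to_numpy()
            counts = refocusing_counts(CpmgSchedule(relax_time, nu, field_mhz))
            conv = float(ppm_to_angular(1.0, nucleus, field_mhz))
            self.fields.append(float(field_mhz))
            nu_l.append(nu)
            cnt_l.append(counts)
            conv_l.append(np.full(nu.size, conv))
            relax_l.append(np.full(nu.size, float(relax_time)))
            obs_l.append(g["r2eff"].to_numpy())
            sig_l.append(g["r2eff_err"].to_numpy())
            offsets.append(offsets[-1] + nu.size)
        self.nu = np.concatenate(nu_l)
        self.counts = np.concatenate(cnt_l)
        self.conv = np.concatenate(conv_l)
        self.relax = np.concatenate(relax_l)
        self.obs = np.concatenate(obs_l)
        self.sigma = np.concatenate(sig_l)
        self.w = np.ones_like(self.obs)
        self.offsets = np.asarray(offsets[:-1])


def _prepare_units(data: DispersionDataset) -> list[_Unit]:
    df = data.df
    units = [
        _Unit(spin, nuc, df[(df["spin"] == spin) & (df["nucleus"] == nuc)])
        for spin, nuc in data.units()
    ]
    # sigma = 0 guard: replace by the dataset median of the positive sigmas
    all_sig = np.concatenate([u.sigma for u in units])
    med = np.median(all_sig[all_sig > 0]) if np.any(all_sig > 0) else 1.0
    for u in units:
        sig = np.where(u.sigma > 0, u.sigma, med)
        u.w = 1.0 / sig**2
    return units


def _dd_max_for(config_value, nucleus: str) -> float:
    if isinstance(config_value, (int, float)):
        return float(config_value)
    return float(config_value.get(nucleus, 8.0))


def _unit_sse(kex: float, pb: float, unit: _Unit, dd_max,
              stages: int = 4) -> tuple[float, float, list[float]]:
    """Best SSE of one unit for fixed (k_ex, p_minor).

    |ddelta| is found by nested vectorised grid scans (a coarse scan
    over [0, dd_max(nucleus)] followed by three 4-fold refinements
    around the running optimum; the SSE can be multi-modal in |ddelta|,
    so the coarse step must resolve the global basin); each R2,0 is the
    weighted mean of (observed - Rex).  Returns (sse, ddelta, r20s).
    """
    dd_hi = _dd_max_for(dd_max, unit.nucleus)

    w = unit.w[None, :]
    obs = unit.obs[None, :]
    seg = unit.offsets
    w_seg_sum = np.add.reduceat(unit.w, seg)

    def sse_grid(dd_grid: np.ndarray) -> np.ndarray:
        dw = unit.conv[None, :] * dd_grid[:, None]
        rex = exchange_contribution(
            kex, pb, dw, unit.nu[None, :], unit.relax[None, :],
            counts=unit.counts[None, :],
        )
        resid = obs - rex
        # profiled R2,0: weighted mean of resid per per-field segment
        r20 = np.add.reduceat(w * resid, seg, axis=1) / w_seg_sum
        resid = resid - np.repeat(r20, np.diff(np.append(seg, unit.nu.size)),
                                  axis=1)
        return np.sum(w * resid**2, axis=1)

    grid = np.linspace(0.0, dd_hi, 33)
    for _ in range(max(stages, 1)):
        sse = sse_grid(grid)
        i = int(np.argmin(sse))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, grid.size - 1)]
        dd, best = float(grid[i]), float(sse[i])
        grid = np.linspace(lo, hi, 9)
    # recover the profiled R2,0 values at the optimum
    rex = exchange_contribution(kex, pb, unit.conv * dd, unit.nu, unit.relax,
                                counts=unit.counts)
    resid = unit.obs - rex
    r20s = list(np.add.reduceat(unit.w * resid, seg) / w_seg_sum)
    return best, dd, r20s


def _total_sse(kex: float, pb: float, units: list[_Unit], dd_max,
               stages: int = 4) -> float:
    return sum(_unit_sse(kex, pb, u, dd_max, stages)[0] for u in units)


def global_fit(data: DispersionDataset, config: FitConfig | None = None) -> FitResult:
    """Global two-site fit across all spins, fields and nuclei.

    Minimises ``sum ((R2eff_obs - R2eff_model) / sigma)^2`` with k_ex
    and p_minor shared, |ddelta| per (spin, nucleus) and R2,0 per
    (spin, nucleus, field).  Multi-start: the weighted SSE is evaluated
    on the start grid and the best ``n_refine_starts`` points are
    polished by Nelder--Mead in (log k_ex, logit p_minor).
    """
    config = config or FitConfig()
    data = data.to_r2eff(seed=config.seed)
    units = _prepare_units(data)
    if not units:
        raise DataError("empty dataset")
    dd_max = config.ddelta_max

    def trans(kex, pb):
        return np.array([np.log(kex), np.log(pb / (1.0 - pb))])

    def untrans(x):
        kex = float(np.exp(np.clip(x[0], np.log(config.kex_bounds[0]),
                                   np.log(config.kex_bounds[1]))))
        pb = 1.0 / (1.0 + np.exp(-x[1]))
        pb = float(np.clip(pb, *config.pminor_bounds))
        return kex, pb

    def objective(x):
        kex, pb = untrans(x)
        return _total_sse(kex, pb, units, dd_max, config.dd_stages)

    starts = [(k, p) for k in config.kex_starts for p in config.pminor_starts]
    grid_sse = [_total_sse(k, p, units, dd_max, config.dd_stages)
                for k, p in starts]
    order = np.argsort(grid_sse)
    best = None
    any_success = False
    for idx in order[: max(config.n_refine_starts, 1)]:
        res = minimize(
            objective, trans(*starts[idx]), method="Nelder-Mead",
            options=dict(xatol=config.nm_xatol, fatol=config.nm_fatol,
                         maxiter=config.nm_maxiter),
        )
        any_success = any_success or res.success
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError("global fit failed from every start")
    kex, pb = untrans(best.x)

    ddeltas: dict = {}
    r2_base: dict = {}
    chisq = 0.0
    n_points = 0
    for u in units:
        sse, dd, r20s = _unit_sse(kex, pb, u, dd_max)
        chisq += sse
        ddeltas[(u.spin, u.nucleus)] = dd
        for field_mhz, r20 in zip(u.fields, r20s):
            r2_base[(u.spin, u.nucleus, field_mhz)] = r20
        n_points += u.nu.size
    n_params = 2 + len(units) + len(r2_base)
    dof = max(n_points - n_params, 1)
    params = ExchangeParameters(kex, pb, ddeltas)
    flags = {(u.spin, u.nucleus): True for u in units}
    return FitResult(
        params=params, r2_base=r2_base, kex_err=None, pminor_err=None,
        redchi=chisq / dof, chisq=chisq, n_points=n_points,
        n_params=n_params, seed=config.seed, spin_flags=flags,
        converged=any_success,
    )


def _perturbed(data: DispersionDataset, rng: np.random.Generator) -> DispersionDataset:
    """Dataset with R2eff values perturbed by their own uncertainties."""
    data = data.to_r2eff()
    df = data.df.copy()
    df["r2eff"] = df["r2eff"] + df["r2eff_err"] * rng.standard_normal(len(df))
    return DispersionDataset(df)


def mc_parameter_uncertainty(
    fit: FitResult,
    data: DispersionDataset,
    n_draws: int = 50,
    seed: int = 0,
    config: FitConfig | None = None,
) -> FitResult:
    """Monte Carlo 1-sigma uncertainties on the global parameters.

    Refits ``n_draws`` datasets whose R2eff values are perturbed by
    their per-point uncertainties; warm-started at the point estimate.
    Raises :class:`FitError` when fewer than 80% of refits converge.
    Returns a copy of ``fit`` with ``kex_err``/``pminor_err`` filled in.
    """
    if not fit.converged:
        raise FitError("point estimate did not converge")
    base = config or FitConfig()
    warm = dataclasses.replace(
        base,
        kex_starts=(fit.params.k_ex,),
        pminor_starts=(max(fit.params.p_minor, base.pminor_bounds[0]),),
        n_refine_starts=1,
        nm_xatol=1e-3, nm_fatol=1e-4, nm_maxiter=60, dd_stages=2,
    )
    rng = np.random.default_rng(seed)
    data = data.to_r2eff(seed=base.seed)
    kexs, pbs = [], []
    failures = 0
    for _ in range(n_draws):
        try:
            r = global_fit(_perturbed(data, rng), warm)
            if not r.converged:
                raise FitError("refit did not converge")
            kexs.append(r.params.k_ex)
            pbs.append(r.params.p_minor)
        except (FitError, DataError):
            failures += 1
    if len(kexs) < 0.8 * n_draws:
        raise FitError(
            f"only {len(kexs)}/{n_draws} Monte Carlo refits converged"
        )
    out = dataclasses.replace(fit)
    out.kex_err = float(np.std(kexs, ddof=1))
    out.pminor_err = float(np.std(pbs, ddof=1))
    return out


def _lm_shape(nu: np.ndarray, kex: float) -> np.ndarray:
    """Luz--Meiboom dispersion shape ``1 - (4 nu/kex) tanh(kex/4 nu)``."""
    return 1.0 - (4.0 * nu / kex) * np.tanh(kex / (4.0 * nu))


def detect_exchange(
    nu_cpmg,
    r2eff,
    r2eff_err,
    alpha: float = 0.05,
) -> dict:
    """Flat-vs-dispersion decision for a single spin's profile.

    Compares a flat model (R2,0 only) against a two-parameter exchange
    shape (Luz--Meiboom amplitude x shape(k_ex), the amplitude profiled
    linearly and k_ex scanned) with an F-test at level ``alpha``; AIC
    values for both models are reported alongside.

    Returns a dict with keys ``exchange`` (bool), ``f_stat``,
    ``p_value``, ``aic_flat``, ``aic_exchange``, ``kex``, ``amplitude``.
    """
    nu = np.asarray(nu_cpmg, dtype=float)
    obs = np.asarray(r2eff, dtype=float)
    sig = np.asarray(r2eff_err, dtype=float)
    n = nu.size
    if n < 6:
        raise DataError("need at least 6 nu_cpmg points")
    p_alt = 3
    if n <= p_alt:
        raise DataError("fewer points than model parameters")
    sig = np.where(sig > 0, sig, np.median(sig[sig > 0]) if np.any(sig > 0) else 1.0)
    w = 1.0 / sig**2

    r20_flat = np.sum(w * obs) / np.sum(w)
    sse0 = float(np.sum(w * (obs - r20_flat) ** 2))

    def sse_for(kex: float):
        g = _lm_shape(nu, kex)
        # weighted linear LS in (r20, amplitude)
        X = np.stack([np.ones_like(nu), g], axis=1)
        Xw = X * w[:, None]
        beta, *_ = np.linalg.lstsq(X.T @ Xw, Xw.T @ obs, rcond=None)
        resid = obs - X @ beta
        return float(np.sum(w * resid**2)), beta

    kex_grid = np.geomspace(200.0, 1e5, 25)
    sses = [sse_for(k)[0] for k in kex_grid]
    i = int(np.argmin(sses))
    lo, hi = kex_grid[max(i - 1, 0)], kex_grid[min(i + 1, kex_grid.size - 1)]
    fine = np.geomspace(lo, hi, 15)
    sses_f = [sse_for(k)[0] for k in fine]
    j = int(np.argmin(sses_f))
    kex_best = float(fine[j])
    sse1, beta = sse_for(kex_best)

    df1 = p_alt - 1
    df2 = n - p_alt
    f_stat = ((sse0 - sse1) / df1) / (sse1 / df2) if sse1 > 0 else np.inf
    p_value = float(stats.f.sf(f_stat, df1, df2))
    aic_flat = n * np.log(max(sse0, 1e-300) / n) + 2 * 1
    aic_alt = n * np.log(max(sse1, 1e-300) / n) + 2 * p_alt
    return dict(
        exchange=bool(p_value < alpha),
        f_stat=float(f_stat),
        p_value=p_value,
        aic_flat=float(aic_flat),
        aic_exchange=float(aic_alt),
        kex=kex_best,
        amplitude=float(beta[1]),
        r2_base=float(beta[0]),
    )
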