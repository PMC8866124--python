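"""Chemical-shift logic: peak collinearity, fractional position, Ddelta comparison.

Wild-type and variant amide peaks that report on the same two-state
equilibrium in fast exchange fall on a straight line in the 1H-15N
plane; the fractional position of an observed peak along the
major->minor axis estimates the minor-state population.  Distances are
computed in composite shift space with the community-standard 0.14
weighting of 15N relative to 1H.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "N15_WEIGHT",
    "PeakList",
    "collinearity_deviation",
    "fractional_position",
    "compare_delta_sets",
]

#: Composite-shift weighting of 15N relative to 1H.
N15_WEIGHT = 0.14


@dataclass
class PeakList:
    """Per-residue 1H/15N peak positions in ppm."""

    peaks: pd.DataFrame  # index: residue, columns: h_ppm, n_ppm

    def __post_init__(self) -> None:
        required = {"h_ppm", "n_ppm"}
        if not required <= set(self.peaks.columns):
            raise DataError("peak list needs h_ppm and n_ppm columns")
        if self.peaks.index.has_duplicates:
            raise DataError("residues must be keyed uniquely")
        if not np.all(np.isfinite(self.peaks[["h_ppm", "n_ppm"]].to_numpy())):
            raise DataError("peak positions must be finite")

    def composite(self) -> pd.DataFrame:
        out = self.peaks.copy()
        out["n_ppm"] = out["n_ppm"] * N15_WEIGHT
        return out


def _composite(point) -> np.ndarray:
    p = np.asarray(point, dtype=float)
    if p.shape != (2,) or not np.all(np.isfinite(p)):
        raise DataError("a peak is an (1H ppm, 15N ppm) pair of finite values")
    return np.array([p[0], N15_WEIGHT * p[1]])


def collinearity_deviation(p_wt, p_m1, p_m2) -> float:
    """Perpendicular distance of the wild-type peak from the variant line.

    All three peaks are mapped to composite space; the middle-classified
    point (wild type) is measured against the line through the two
    variants.  Zero iff the three peaks are collinear.
    """
    a = _composite(p_m1)
    b = _composite(p_m2)
    x = _composite(p_wt)
    d = b - a
    norm = np.linalg.norm(d)
    if norm == 0:
        raise DataError("the two endpoint peaks coincide")
    # 2-D point-to-line distance via the cross product magnitude
    return float(abs(d[0] * (x[1] - a[1]) - d[1] * (x[0] - a[0])) / norm)


def fractional_position(p_obs, p_major, p_minor) -> tuple[float, bool]:
    """Fractional position of an observed peak along major -> minor.

    Under fast-exchange averaging ``delta_obs = (1 - f) delta_major +
    f delta_minor``, so the scalar projection of (obs - major) onto
    (minor - major) in composite space estimates the minor-state
    fraction f.  Returns (fraction, in_range) without clipping.
    """
    a = _composite(p_major)
    b = _composite(p_minor)
    x = _composite(p_obs)
    d = b - a
    denom = float(d @ d)
    if denom == 0:
        raise DataError("major and minor endpoint peaks coincide")
    f = float((x - a) @ d / denom)
    return f, bool(0.0 <= f <= 1.0)


def compare_delta_sets(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Per-nucleus slope/correlation/RMSD between two |Ddelta| sets.

    Inputs are frames with columns (residue, nucleus, ddelta_ppm); the
    comparison runs over residues shared by both sets, per nucleus:
    least-squares slope through the origin, Pearson correlation and
    RMSD.  Requires >= 3 shared residues per nucleus.
    """
    for df, nm in ((a, "a"), (b, "b")):
        if not {"residue", "nucleus", "ddelta_ppm"} <= set(df.columns):
            raise DataError(f"delta set {nm} needs residue/nucleus/ddelta_ppm")
    merged = a.merge(b, on=["residue", "nucleus"], suffixes=("_a", "_b"))
    rows = []
    for nucleus, g in merged.groupby("nucleus"):
        if len(g) < 3:
            raise DataError(
                f"fewer than 3 shared residues for nucleus {nucleus}"
            )
        x = g["ddelta_ppm_a"].to_numpy(dtype=float)
        y = g["ddelta_ppm_b"].to_numpy(dtype=float)
        slope = float(np.sum(x * y) / np.sum(x * x))
        sx, sy = x.std(), y.std()
        corr = float(np.corrcoef(x, y)[0, 1]) if sx > 0 and sy > 0 else np.nan
        rmsd = float(np.sqrt(np.mean((x - y) ** 2)))
        rows.append(dict(nucleus=nucleus, slope=slope, correlation=corr,
                         rmsd=rmsd, n=len(g)))
    return pd.DataFrame(rows)
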