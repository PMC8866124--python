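"""Forward models for two-site chemical exchange.

A major conformation A interconverts with a minor conformation B
(A <=> B, total rate constant ``k_ex = k_AB + k_BA``, minor population
``p_minor``).  The module provides

* numerical Bloch--McConnell propagation of the two-state transverse
  magnetisation through an ideal-pulse constant-time CPMG element,
* the Carver--Richards closed form (fast vectorised cross-check and
  fitting accelerator),
* the Luz--Meiboom fast-exchange limit, and
* on-resonance rotating-frame relaxation (R1rho) via the dominant decay
  eigenvalue of the full 6x6 two-state evolution matrix, with the
  Trott--Palmer closed form as an analytic cross-check.

Conventions: ``nu_cpmg = N / (2 T)`` with ``N`` refocusing pulses in a
constant relaxation time ``T``; 180-degree pulses are ideal and
instantaneous; both states share the same intrinsic transverse rate
``R2,0`` per spin per field (the model stays identifiable without a
state-specific offset).  Shift differences are magnitude-only by
default; signed values are accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import expm

from .constants import GAMMA_RATIO
from .errors import ScheduleError, UnknownNucleusError

__all__ = [
    "ExchangeParameters",
    "SpinProbe",
    "CpmgSchedule",
    "SpinLockSchedule",
    "ppm_to_angular",
    "refocusing_counts",
    "simulate_cpmg_profile",
    "carver_richards_profile",
    "carver_richards_r2eff",
    "exchange_contribution",
    "bloch_mcconnell_r2eff",
    "luz_meiboom_rex",
    "r1rho_on_resonance",
    "r1rho_closed_form",
]


_CANONICAL_NUCLEI = {"15N": "15N", "1H": "1HN", "1HN": "1HN", "13C": "13C"}


def canonical_nucleus(nucleus: str) -> str:
    """Normalise a nucleus label, raising for unsupported ones."""
    try:
        return _CANONICAL_NUCLEI[str(nucleus).strip()]
    except KeyError:
        raise UnknownNucleusError(
            f"unknown nucleus {nucleus!r}; supported: 15N, 1HN, 13C"
        ) from None


@dataclass
class ExchangeParameters:
    """Global two-site exchange kinetics plus per-spin shift differences.

    Parameters
    ----------
    k_ex : float
        Total exchange rate constant ``k_AB + k_BA`` in s^-1.
    p_minor : float
        Fractional population of the minor state, ``0 <= p_minor <= 0.5``
        (the symmetric boundary 0.5 describes a degenerate two-site
        process such as an aromatic ring flip).
    ddelta_ppm : mapping
        Shift differences between the states in ppm, keyed by
        ``(spin_id, nucleus)``.
    """

    k_ex: float
    p_minor: float
    ddelta_ppm: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.k_ex > 0:
            raise ValueError(f"k_ex must be positive, got {self.k_ex}")
        if not 0.0 <= self.p_minor <= 0.5:
            raise ValueError(f"p_minor must lie in [0, 0.5], got {self.p_minor}")
        self.ddelta_ppm = {
            (str(s), canonical_nucleus(n)): float(v)
            for (s, n), v in dict(self.ddelta_ppm).items()
        }

    @property
    def p_major(self) -> float:
        return 1.0 - self.p_minor

    @property
    def k_forward(self) -> float:
        """Rate major -> minor (detailed balance)."""
        return self.p_minor * self.k_ex

    @property
    def k_reverse(self) -> float:
        """Rate minor -> major."""
        return self.p_major * self.k_ex

    def ddelta(self, spin_id: str, nucleus: str) -> float:
        return self.ddelta_ppm[(str(spin_id), canonical_nucleus(nucleus))]


@dataclass
class SpinProbe:
    """One observed spin: residue+atom, nucleus and base relaxation rates.

    ``r2_base`` maps the static field (1H MHz) to the intrinsic
    transverse rate R2,0 in s^-1; ``r1`` is the longitudinal rate needed
    for rotating-frame calculations.
    """

    spin_id: str
    nucleus: str
    r2_base: Mapping[float, float]
    r1: float = 0.0

    def __post_init__(self) -> None:
        self.nucleus = canonical_nucleus(self.nucleus)
        self.r2_base = {float(k): float(v) for k, v in dict(self.r2_base).items()}
        if any(v < 0 for v in self.r2_base.values()):
            raise ValueError("R2,0 must be non-negative")
        if self.r1 < 0:
            raise ValueError("R1 must be non-negative")

    def r2_at(self, field_mhz: float) -> float:
        try:
            return self.r2_base[float(field_mhz)]
        except KeyError:
            raise KeyError(
                f"no R2,0 for spin {self.spin_id} at {field_mhz} MHz"
            ) from None


@dataclass
class CpmgSchedule:
    """Constant-time CPMG schedule at one static field."""

    relax_time: float  # constant relaxation delay T, s
    nu_cpmg: Sequence[float]  # CPMG frequencies, Hz
    field_mhz: float  # static field as 1H Larmor frequency, MHz

    def __post_init__(self) -> None:
        if not self.relax_time > 0:
            raise ScheduleError("relax_time must be positive")
        if not self.field_mhz > 0:
            raise ScheduleError("field_mhz must be positive")
        self.nu_cpmg = np.asarray(self.nu_cpmg, dtype=float)
        if np.any(self.nu_cpmg <= 0):
            raise ScheduleError("all nu_cpmg must be positive")


@dataclass
class SpinLockSchedule:
    """On-resonance spin-lock schedule (R1rho)."""

    omega1_hz: Sequence[float]  # spin-lock field strengths omega1/2pi, Hz
    relax_delay: float = 0.020  # s
    offset_hz: float = 0.0  # carrier offset; 0 = on resonance

    def __post_init__(self) -> None:
        self.omega1_hz = np.asarray(self.omega1_hz, dtype=float)
        if np.any(self.omega1_hz <= 0):
            raise ScheduleError("all spin-lock field strengths must be positive")
        if not self.relax_delay > 0:
            raise ScheduleError("relax_delay must be positive")


def ppm_to_angular(delta_ppm: float, nucleus: str, field_mhz: float):
    """Convert a shift difference in ppm to rad s^-1 at a given field.

    ``field_mhz`` is the 1H Larmor frequency; the nucleus' Larmor
    frequency is obtained through the gyromagnetic-ratio magnitude.
    """
    if not field_mhz > 0:
        raise ValueError("field_mhz must be positive")
    nuc = canonical_nucleus(nucleus)
    larmor_hz = field_mhz * 1e6 * GAMMA_RATIO[nuc]
    return 2.0 * np.pi * np.asarray(delta_ppm, dtype=float) * 1e-6 * larmor_hz


def refocusing_counts(schedule: CpmgSchedule, tol: float = 1e-6) -> np.ndarray:
    """Even refocusing-pulse counts ``N = 2 T nu`` for a schedule.

    Raises :class:`ScheduleError` naming the offending frequency when a
    nu_cpmg does not correspond to an even integer pulse count within
    the rounding tolerance ``tol`` (absolute, in pulses).
    """
    raw = 2.0 * schedule.relax_time * schedule.nu_cpmg
    counts = np.rint(raw / 2.0) * 2.0
    bad = np.abs(raw - counts) > tol
    if np.any(bad):
        nu_bad = schedule.nu_cpmg[bad][0]
        raise ScheduleError(
            f"nu_cpmg = {nu_bad} Hz gives a non-even pulse count "
            f"{raw[np.argmax(bad)]:.6f} for T = {schedule.relax_time} s"
        )
    return counts.astype(int)


def bloch_mcconnell_r2eff(
    k_ex: float,
    p_minor: float,
    domega: float,
    r2_base: float,
    relax_time: float,
    nu_cpmg,
    tol: float = 1e-6,
) -> np.ndarray:
    """R2eff by numerical propagation of the two-state evolution matrix.

    The complex transverse magnetisation of the two states evolves under

    ``A = [[-R2,0 - k_f + i*W_A, k_r], [k_f, -R2,0 - k_r + i*W_B]]``

    with W_A = 0, W_B = domega (a common offset refocuses under ideal
    pulses).  One CPMG element (tau - 180 - 2tau - 180 - tau) with ideal
    180-degree pulses modelled as complex conjugation collapses to the
    linear map ``U = E(tau) conj(E(2tau)) E(tau)`` because conjugations
    occur in pairs; the element is applied N/2 times with
    ``tau = T / (2N)``.  Magnetisation starts in the equilibrium state
    vector (p_major, p_minor) and ``R2eff = -(1/T) ln(|M_A(T)| / p_A)``.
    """
    nu_cpmg = np.atleast_1d(np.asarray(nu_cpmg, dtype=float))
    schedule = CpmgSchedule(relax_time, nu_cpmg, field_mhz=1.0)
    counts = refocusing_counts(schedule, tol=tol)
    p_a = 1.0 - p_minor
    p_b = p_minor
    k_f = p_b * k_ex
    k_r = p_a * k_ex
    if p_b == 0.0 or domega == 0.0:
        return np.full(nu_cpmg.shape, float(r2_base))
    A = np.array(
        [
            [-r2_base - k_f + 0.0j, k_r],
            [k_f, -r2_base - k_r + 1j * domega],
        ],
        dtype=complex,
    )
    m0 = np.array([p_a, p_b], dtype=complex)
    out = np.empty(nu_cpmg.shape, dtype=float)
    cache: dict[int, float] = {}
    for i, n_pulse in enumerate(counts):
        if n_pulse in cache:
            out[i] = cache[n_pulse]
            continue
        tau = relax_time / (2.0 * n_pulse)
        e1 = expm(A * tau)
        e2 = e1 @ e1
        u = e1 @ np.conj(e2) @ e1
        m = np.linalg.matrix_power(u, n_pulse // 2) @ m0
        mag = abs(m[0]) / p_a
        out[i] = -np.log(mag) / relax_time
        cache[int(n_pulse)] = out[i]
    return out


def simulate_cpmg_profile(
    params: ExchangeParameters,
    spin: SpinProbe,
    schedule: CpmgSchedule,
) -> np.ndarray:
    """R2eff per scheduled nu_cpmg from Bloch--McConnell propagation."""
    ddelta = params.ddelta(spin.spin_id, spin.nucleus)
    domega = float(ppm_to_angular(ddelta, spin.nucleus, schedule.field_mhz))
    return bloch_mcconnell_r2eff(
        params.k_ex,
        params.p_minor,
        domega,
        spin.r2_at(schedule.field_mhz),
        schedule.relax_time,
        schedule.nu_cpmg,
    )


def _expm2(a11, a12, a21, a22, t):
    """exp(t*A) for broadcast arrays of 2x2 complex matrices (Sylvester).

    Returns the four entries of the exponential.  Degenerate eigenvalue
    pairs are handled by the confluent limit exp(l t) (I + t (A - l I)).
    """
    tr = a11 + a22
    disc = np.sqrt((a11 - a22) ** 2 + 4.0 * a12 * a21 + 0j)
    lp = 0.5 * (tr + disc)
    lm = 0.5 * (tr - disc)
    diff = lp - lm
    degen = np.abs(diff) < 1e-12 * np.maximum(np.abs(lp), 1.0)
    safe = np.where(degen, 1.0, diff)
    ep = np.exp(lp * t)
    em = np.exp(lm * t)
    c1 = (ep - em) / safe  # coefficient of A
    c0 = (lp * em - lm * ep) / safe  # coefficient of I
    # confluent limit
    c1 = np.where(degen, t * np.exp(lp * t), c1)
    c0 = np.where(degen, (1.0 - lp * t) * np.exp(lp * t), c0)
    return c0 + c1 * a11, c1 * a12, c1 * a21, c0 + c1 * a22


def _matpow2(u11, u12, u21, u22, n):
    """U**n for broadcast arrays of 2x2 complex matrices, integer n per element."""
    tr = u11 + u22
    disc = np.sqrt((u11 - u22) ** 2 + 4.0 * u12 * u21 + 0j)
    lp = 0.5 * (tr + disc)
    lm = 0.5 * (tr - disc)
    diff = lp - lm
    degen = np.abs(diff) < 1e-12 * np.maximum(np.abs(lp), 1.0)
    safe = np.where(degen, 1.0, diff)
    pp = lp**n
    pm = lm**n
    c1 = (pp - pm) / safe
    c0 = (lp * pm - lm * pp) / safe
    c1 = np.where(degen, n * lp ** (n - 1), c1)
    c0 = np.where(degen, (1.0 - n) * lp**n, c0)
    return c0 + c1 * u11, c1 * u12, c1 * u21, c0 + c1 * u22


def exchange_contribution(
    k_ex, p_minor, domega, nu_cpmg, relax_time: float, counts=None
) -> np.ndarray:
    """Exchange part of R2eff (closed form), i.e. R2eff - R2,0.

    The intrinsic rate enters the evolution matrix as ``-R2,0 * I``,
    which commutes with everything else, so R2eff is exactly
    ``R2,0 + Rex`` and Rex can be computed once with R2,0 = 0.
    ``counts`` allows reuse of precomputed refocusing-pulse counts in
    tight fitting loops.
    """
    nu = np.asarray(nu_cpmg, dtype=float)
    domega = np.asarray(domega, dtype=float)
    shape = np.broadcast(domega, nu).shape
    p_b = float(p_minor)
    p_a = 1.0 - p_b
    if p_b == 0.0:
        return np.zeros(shape)
    if counts is None:
        counts = refocusing_counts(CpmgSchedule(relax_time, np.atleast_1d(nu), 1.0))
        counts = counts.reshape(np.atleast_1d(nu).shape)
    counts = np.broadcast_to(counts, shape)
    domega = np.broadcast_to(domega, shape)
    relax_time = np.broadcast_to(np.asarray(relax_time, dtype=float), shape)
    k_f = p_b * k_ex
    k_r = p_a * k_ex
    tau = relax_time / (2.0 * counts)
    a11 = np.full(shape, -k_f, dtype=complex)
    a12 = np.full(shape, k_r, dtype=complex)
    a21 = np.full(shape, k_f, dtype=complex)
    a22 = -k_r + 1j * domega + np.zeros(shape, dtype=complex)
    e1 = _expm2(a11, a12, a21, a22, tau)
    # E(2 tau) = E(tau)^2 (cheaper than a second exponential)
    e2 = (
        np.conj(e1[0] * e1[0] + e1[1] * e1[2]),
        np.conj(e1[1] * (e1[0] + e1[3])),
        np.conj(e1[2] * (e1[0] + e1[3])),
        np.conj(e1[3] * e1[3] + e1[1] * e1[2]),
    )
    # U = E(tau) conj(E(2 tau)) E(tau)
    f11 = e1[0] * e2[0] + e1[1] * e2[2]
    f12 = e1[0] * e2[1] + e1[1] * e2[3]
    f21 = e1[2] * e2[0] + e1[3] * e2[2]
    f22 = e1[2] * e2[1] + e1[3] * e2[3]
    u11 = f11 * e1[0] + f12 * e1[2]
    u12 = f11 * e1[1] + f12 * e1[3]
    u21 = f21 * e1[0] + f22 * e1[2]
    u22 = f21 * e1[1] + f22 * e1[3]
    w11, w12, _, _ = _matpow2(u11, u12, u21, u22, counts // 2)
    m_a = w11 * p_a + w12 * p_b
    with np.errstate(divide="ignore", invalid="ignore"):
        out = -np.log(np.abs(m_a) / p_a) / relax_time
    return np.asarray(out, dtype=float)


def carver_richards_r2eff(
    k_ex, p_minor, domega, r2_base, nu_cpmg, relax_time: float = 0.032
) -> np.ndarray:
    """Closed-form R2eff for equal-R2,0 ideal-pulse two-site CPMG.

    Analytic (Sylvester/eigenvalue) evaluation of the Carver--Richards
    problem: the two-state transverse evolution over one CPMG element
    and its N/2-fold repetition are written in scalar complex algebra,
    so the result is exact for the model -- the historical approximate
    Carver--Richards expression deviates by several s^-1 at small pulse
    counts in slow-exchange corners, which this route avoids.
    Vectorised over ``nu_cpmg`` and broadcastable against ``domega``.
    """
    rex = exchange_contribution(k_ex, p_minor, domega, nu_cpmg, relax_time)
    return np.asarray(r2_base + rex, dtype=float)


def carver_richards_profile(
    params: ExchangeParameters,
    spin: SpinProbe,
    schedule: CpmgSchedule,
) -> np.ndarray:
    """Closed-form R2eff profile; falls back to propagation when unstable."""
    ddelta = params.ddelta(spin.spin_id, spin.nucleus)
    domega = float(ppm_to_angular(ddelta, spin.nucleus, schedule.field_mhz))
    r20 = spin.r2_at(schedule.field_mhz)
    out = carver_richards_r2eff(
        params.k_ex, params.p_minor, domega, r20, schedule.nu_cpmg,
        relax_time=schedule.relax_time,
    )
    bad = ~np.isfinite(out)
    if np.any(bad):
        fallback = bloch_mcconnell_r2eff(
            params.k_ex, params.p_minor, domega, r20,
            schedule.relax_time, np.asarray(schedule.nu_cpmg)[bad],
        )
        out = np.array(out, dtype=float)
        out[bad] = fallback
    return out


def luz_meiboom_rex(params: ExchangeParameters, domega, nu_cpmg) -> np.ndarray:
    """Fast-exchange (Luz--Meiboom) exchange contribution to R2eff.

    ``R_ex = (p_A p_B dw^2 / k_ex) (1 - (4 nu / k_ex) tanh(k_ex / 4 nu))``.
    Valid for ``k_ex >> |domega|``; the caller is responsible for the
    regime.
    """
    nu = np.asarray(nu_cpmg, dtype=float)
    domega = np.asarray(domega, dtype=float)
    p_a, p_b = params.p_major, params.p_minor
    k = params.k_ex
    return (p_a * p_b * domega**2 / k) * (1.0 - (4.0 * nu / k) * np.tanh(k / (4.0 * nu)))


def _r1rho_evolution_matrix(
    k_ex: float, p_minor: float, domega: float,
    r1: float, r2: float, omega1: float,
) -> np.ndarray:
    """6x6 two-state rotating-frame evolution matrix (x, y, z per state).

    Spin lock of amplitude ``omega1`` along x; state offsets are placed
    symmetrically around the population-average shift (the on-resonance
    carrier position): W_A = -p_B domega, W_B = p_A domega.
    """
    p_a = 1.0 - p_minor
    k_f = p_minor * k_ex
    k_r = p_a * k_ex
    off = {"A": -p_minor * domega, "B": p_a * domega}

    def block(omega_z: float) -> np.ndarray:
        return np.array(
            [
                [-r2, -omega_z, 0.0],
                [omega_z, -r2, -omega1],
                [0.0, omega1, -r1],
            ]
        )

    L = np.zeros((6, 6))
    L[:3, :3] = block(off["A"]) - k_f * np.eye(3)
    L[3:, 3:] = block(off["B"]) - k_r * np.eye(3)
    L[:3, 3:] = k_r * np.eye(3)
    L[3:, :3] = k_f * np.eye(3)
    return L


def r1rho_on_resonance(
    params: ExchangeParameters,
    spin: SpinProbe,
    schedule: SpinLockSchedule,
    field_mhz: float,
) -> np.ndarray:
    """On-resonance R1rho per spin-lock field strength.

    For each omega1 the dominant decay rate is the negated real part of
    the eigenvalue of the full 6x6 two-state evolution matrix whose mode
    carries the largest share of the initially spin-locked
    magnetisation (p_A, 0, 0, p_B, 0, 0).
    """
    ddelta = params.ddelta(spin.spin_id, spin.nucleus)
    domega = float(ppm_to_angular(ddelta, spin.nucleus, field_mhz))
    r2 = spin.r2_at(field_mhz)
    m0 = np.array([params.p_major, 0.0, 0.0, params.p_minor, 0.0, 0.0])
    obs = np.array([1.0, 0.0, 0.0, 1.0, 0.0, 0.0])
    out = np.empty(len(schedule.omega1_hz))
    for i, w1_hz in enumerate(schedule.omega1_hz):
        L = _r1rho_evolution_matrix(
            params.k_ex, params.p_minor, domega, spin.r1, r2, 2.0 * np.pi * w1_hz
        )
        w, v = np.linalg.eig(L)
        coeff = np.linalg.solve(v, m0.astype(complex))
        weight = np.abs(coeff * (obs @ v))
        out[i] = -w[np.argmax(weight)].real
    return out


def r1rho_closed_form(
    params: ExchangeParameters,
    spin: SpinProbe,
    schedule: SpinLockSchedule,
    field_mhz: float,
) -> np.ndarray:
    """Trott--Palmer style closed form for on-resonance two-site R1rho.

    ``R1rho = R1 cos^2(t) + sin^2(t) (R2 + p_A p_B dw^2 k_ex /
    (wA^2 wB^2 / we^2 + k_ex^2))`` with tilt t = 90 degrees on
    resonance.  Used as an independent cross-check of the eigenvalue
    route.
    """
    ddelta = params.ddelta(spin.spin_id, spin.nucleus)
    domega = float(ppm_to_angular(ddelta, spin.nucleus, field_mhz))
    r2 = spin.r2_at(field_mhz)
    p_a, p_b = params.p_major, params.p_minor
    w1 = 2.0 * np.pi * schedule.omega1_hz
    wa2 = (p_b * domega) ** 2 + w1**2
    wb2 = (p_a * domega) ** 2 + w1**2
    we2 = w1**2
    rex = p_a * p_b * domega**2 * params.k_ex / (wa2 * wb2 / we2 + params.k_ex**2)
    return r2 + rex
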