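"""Ground-truth-known synthetic inputs for every pipeline stage.

Every generator is a pure function of (parameters, seed) and returns
its artefact together with a :class:`GroundTruthRecord` that is
sufficient to regenerate it bit-identically and to score any downstream
analysis against the truth.

The dispersion fixtures mirror the published experimental design: the
wild-type two-site parameters (p_minor = 2.8%, k_ex = 2,600 s^-1) and
the two minor-state-stabilising variants H493A (k_ex = 2,830 s^-1,
slightly raised minor population) and V517A (k_ex = 6,800 s^-1,
near-inverted populations); 15N CPMG with T = 32 ms and nu_CPMG
31.25-1,000 Hz, amide-1H CPMG with T = 20 ms and 50-2,000 Hz, aromatic
13C CPMG with T = 20 ms and 100-1,000 Hz.  Shift differences are drawn
uniformly within the observed spans (up to 4.7 ppm 15N, 1.1 ppm 1HN)
with one spin pinned at each span maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dispersion import DispersionDataset, INTENSITY_COLUMNS
from .errors import DataError
from .exchange import (
    CpmgSchedule,
    ExchangeParameters,
    bloch_mcconnell_r2eff,
    ppm_to_angular,
)
from .modelfree import MotionParams, predict_rates
from .seqpca import AlignedFamily, REFERENCE_POSITIONS
from .structure import Structure

__all__ = [
    "FIXTURES",
    "GroundTruthRecord",
    "nitrogen_schedule",
    "proton_schedule",
    "carbon_schedule",
    "make_dispersion_dataset",
    "make_sequence_family",
    "make_breathing_cage",
    "make_relaxation_set",
]

#: Named two-site parameter fixtures traceable to the published fits.
FIXTURES: dict[str, dict[str, float]] = {
    "wildtype": dict(k_ex=2600.0, p_minor=0.028),
    "H493A": dict(k_ex=2830.0, p_minor=0.05),
    "V517A": dict(k_ex=6800.0, p_minor=0.45),
}

#: Observed shift-difference spans (ppm) bounding the fixture draws.
DDELTA_SPAN = {"15N": 4.7, "1HN": 1.1, "13C": 2.0}


def nitrogen_schedule(field_mhz: float) -> CpmgSchedule:
    """15N CPMG: T = 32 ms, nu = 31.25-1,000 Hz."""
    nu = np.array([31.25, 62.5, 125.0, 187.5, 250.0, 312.5, 375.0,
                   500.0, 625.0, 750.0, 875.0, 1000.0])
    return CpmgSchedule(0.032, nu, field_mhz)


def proton_schedule(field_mhz: float) -> CpmgSchedule:
    """Amide-1H CPMG: T = 20 ms, nu = 50-2,000 Hz."""
    nu = np.array([50.0, 100.0, 200.0, 300.0, 400.0, 600.0, 800.0,
                   1000.0, 1200.0, 1400.0, 1600.0, 1800.0, 2000.0])
    return CpmgSchedule(0.020, nu, field_mhz)


def carbon_schedule(field_mhz: float) -> CpmgSchedule:
    """Aromatic 13C CPMG: T = 20 ms, nu = 100-1,000 Hz."""
    return CpmgSchedule(0.020, np.arange(100.0, 1001.0, 100.0), field_mhz)


DEFAULT_SCHEDULES = (
    ("15N", 600.0, nitrogen_schedule),
    ("15N", 850.0, nitrogen_schedule),
    ("1HN", 600.0, proton_schedule),
    ("1HN", 950.0, proton_schedule),
)


@dataclass
class GroundTruthRecord:
    """Exact generating parameters of a synthetic artefact."""

    kind: str
    seed: int
    noise: float
    params: ExchangeParameters | None = None
    r2_base: dict = field(default_factory=dict)
    labels: list | None = None
    cavity_volume: float | None = None
    motions: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = dict(kind=self.kind, seed=self.seed, noise=self.noise)
        if self.params is not None:
            out["k_ex"] = self.params.k_ex
            out["p_minor"] = self.params.p_minor
            out["ddelta_ppm"] = {
                f"{s}/{n}": v for (s, n), v in self.params.ddelta_ppm.items()
            }
        if self.r2_base:
            out["r2_base"] = {f"{s}/{n}/{f}": v for (s, n, f), v in self.r2_base.items()}
        if self.labels is not None:
            out["labels"] = list(self.labels)
        if self.cavity_volume is not None:
            out["cavity_volume"] = self.cavity_volume
        if self.motions:
            out["motions"] = self.motions
        out.update(self.extra)
        return out


def make_dispersion_dataset(
    fixture: str = "wildtype",
    n_spins: int = 15,
    schedules=DEFAULT_SCHEDULES,
    noise: float = 0.02,
    seed: int = 0,
    i0: float = 100.0,
    n_replicate_points: int = 2,
) -> tuple[DispersionDataset, GroundTruthRecord]:
    """Synthetic multi-field, multi-nucleus CPMG intensity dataset.

    Intensities are ``I0 exp(-R2eff T)`` from Bloch--McConnell
    propagation of the fixture's two-site parameters, perturbed by
    Gaussian noise of s.d. ``noise * I0``; per spin and schedule,
    ``n_replicate_points`` randomly chosen nu_CPMG points carry a
    technical replicate.

    A real dataset contains only residues whose peaks survive exchange
    broadening, so each spin's shift difference is drawn (uniformly
    within the observed span, by rejection) such that its true
    intensities stay above the detection limit at every scheduled point
    under the fixture's exchange parameters.  One spin is pinned at the
    span maximum when that is measurable (always true for the wild-type
    kinetics), making span recovery testable.
    """
    if fixture not in FIXTURES:
        raise DataError(
            f"unknown fixture {fixture!r}; available: {sorted(FIXTURES)}"
        )
    if noise < 0:
        raise DataError("noise must be non-negative")
    if n_spins < 1:
        raise DataError("n_spins must be >= 1")
    rng = np.random.default_rng(seed)
    fx = FIXTURES[fixture]

    spins = [f"R{i + 1}" for i in range(n_spins)]
    base_r2 = {"15N": 8.0, "1HN": 14.0, "13C": 12.0}
    r2_base: dict[tuple[str, str, float], float] = {}
    by_nucleus: dict[str, list] = {}
    for nuc, field_mhz, make_schedule in schedules:
        by_nucleus.setdefault(nuc, []).append(
            (float(field_mhz), make_schedule(field_mhz))
        )
        for spin in spins:
            r20 = base_r2.get(nuc, 10.0) * (field_mhz / 600.0) ** 0.5 \
                + rng.uniform(-1.0, 1.0)
            r2_base[(spin, nuc, float(field_mhz))] = r20

    detection_limit = 3.0 * noise * i0

    def measurable(spin: str, nuc: str, dd: float) -> bool:
        """True intensities above the detection limit at every point."""
        if noise == 0:
            return True
        for field_mhz, schedule in by_nucleus[nuc]:
            dw = float(ppm_to_angular(dd, nuc, field_mhz))
            r2eff = bloch_mcconnell_r2eff(
                fx["k_ex"], fx["p_minor"], dw,
                r2_base[(spin, nuc, field_mhz)],
                schedule.relax_time, schedule.nu_cpmg,
            )
            if (i0 * np.exp(-r2eff * schedule.relax_time)).min() < detection_limit:
                return False
        return True

    ddelta: dict[tuple[str, str], float] = {}
    for nuc in sorted(by_nucleus):
        span = DDELTA_SPAN.get(nuc, 2.0)
        for k, spin in enumerate(spins):
            dd = span if k == 0 else float(rng.uniform(0.15 * span, span))
            for _ in range(200):
                if measurable(spin, nuc, dd):
                    break
                dd = float(rng.uniform(0.15 * span, span))
            else:
                raise DataError(
                    f"no measurable shift difference found for {spin}/{nuc}"
                )
            ddelta[(spin, nuc)] = dd
    params = ExchangeParameters(fx["k_ex"], fx["p_minor"], ddelta)

    n_dropped = 0
    rows = []
    for nuc, field_mhz, make_schedule in schedules:
        schedule = make_schedule(field_mhz)
        for spin in spins:
            r20 = r2_base[(spin, nuc, float(field_mhz))]
            dw = float(ppm_to_angular(ddelta[(spin, nuc)], nuc, field_mhz))
            r2eff = bloch_mcconnell_r2eff(
                params.k_ex, params.p_minor, dw, r20,
                schedule.relax_time, schedule.nu_cpmg,
            )
            clean = i0 * np.exp(-r2eff * schedule.relax_time)
            rep_at = set(rng.choice(len(clean), size=min(n_replicate_points,
                                                         len(clean)),
                                    replace=False))
            i0_obs = i0 + noise * i0 * rng.standard_normal()
            for j, (nu, mu) in enumerate(zip(schedule.nu_cpmg, clean)):
                n_rep = 2 if j in rep_at else 1
                for rep in range(n_rep):
                    obs = mu + noise * i0 * rng.standard_normal()
                    if obs <= 0:  # cannot enter the log conversion
                        n_dropped += 1
                        continue
                    rows.append(dict(
                        dataset_id=fixture, spin=spin, nucleus=nuc,
                        field_mhz=field_mhz,
                        relax_time_s=schedule.relax_time,
                        nu_cpmg_hz=float(nu),
                        intensity=float(obs),
                        intensity_ref=float(i0_obs),
                        replicate_index=rep,
                    ))
    data = DispersionDataset(pd.DataFrame(rows, columns=INTENSITY_COLUMNS))
    truth = GroundTruthRecord(
        kind="dispersion", seed=seed, noise=noise, params=params,
        r2_base=r2_base, extra=dict(fixture=fixture, i0=i0, n_dropped=n_dropped),
    )
    return data, truth


# residue pools implementing the observed group signatures at the three
# scored positions (493 / 517 / 541)
_GROUP1_POOLS = {"493": "HFYE", "517": "VAT", "541": "AGS"}
_GROUP2_POOLS = {"493": "ASGT", "517": "IL", "541": "YFWL"}


def make_sequence_family(
    n_group1: int = 20,
    n_group2: int = 20,
    seed: int = 0,
    include_reference: bool = True,
    width: int = 60,
) -> tuple[AlignedFamily, GroundTruthRecord]:
    """Aligned family with two planted size-score groups.

    Group 1 carries the eclipsed-ring signature (larger 493, small 517
    and 541); group 2 the staggered signature (small 493, Ile/Leu 517,
    large 541).  The anchor column is all Tyr/Phe.  The JIP1 reference
    row (H493 / V517 / A541 / Y526) is prepended when requested and
    belongs to group 1.
    """
    if n_group1 < 1 or n_group2 < 1:
        raise DataError("need at least one sequence per group")
    rng = np.random.default_rng(seed)
    colmap = {493: 3, 517: 27, 520: 30, 526: 36, 541: 51}
    assert set(colmap) == set(REFERENCE_POSITIONS)
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    background = [alphabet[i] for i in rng.integers(0, len(alphabet), width)]

    def build(pools: dict[str, str], anchor: str) -> str:
        s = list(background)
        s[colmap[493]] = pools["493"][rng.integers(len(pools["493"]))]
        s[colmap[517]] = pools["517"][rng.integers(len(pools["517"]))]
        s[colmap[541]] = pools["541"][rng.integers(len(pools["541"]))]
        s[colmap[520]] = "QRK"[rng.integers(3)]
        s[colmap[526]] = anchor
        return "".join(s)

    names, seqs, labels = [], [], []
    if include_reference:
        s = list(background)
        s[colmap[493]], s[colmap[517]], s[colmap[541]] = "H", "V", "A"
        s[colmap[520]], s[colmap[526]] = "Q", "Y"
        names.append("JIP1")
        seqs.append("".join(s))
        labels.append(1)
    for i in range(n_group1):
        names.append(f"G1_{i + 1}")
        seqs.append(build(_GROUP1_POOLS, "YF"[rng.integers(2)]))
        labels.append(1)
    for i in range(n_group2):
        names.append(f"G2_{i + 1}")
        seqs.append(build(_GROUP2_POOLS, "YF"[rng.integers(2)]))
        labels.append(2)
    family = AlignedFamily(names, seqs, colmap)
    truth = GroundTruthRecord(kind="sequence_family", seed=seed, noise=0.0,
                              labels=labels)
    return family, truth


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately equidistributed unit vectors."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.stack([
        np.sin(phi) * np.cos(theta),
        np.sin(phi) * np.sin(theta),
        np.cos(phi),
    ], axis=1)


def make_breathing_cage(
    gate_displacement: float = 0.0,
    seed: int = 0,
    shell_radius: float = 6.0,
    n_atoms: int = 600,
    cutoff: float = 1.09,
    gate_cap_deg: float = 30.0,
) -> tuple[Structure, Structure, GroundTruthRecord]:
    """Two-conformation carbon cage with an analytically known cavity.

    Pseudo-atoms tile a sphere of ``shell_radius``; the cavity of the
    closed cage is a ball of radius ``shell_radius - (r_vdw(C) +
    cutoff)``.  The open conformation displaces the polar cap of atoms
    (within ``gate_cap_deg`` of the +z pole) radially outward by
    ``gate_displacement``, mimicking a gate of surrounding residues
    swinging open; the vacated funnel enlarges the pocket monotonically
    with the displacement.
    """
    if gate_displacement < 0:
        raise DataError("gate displacement must be non-negative")
    dirs = _fibonacci_sphere(n_atoms)
    coords = shell_radius * dirs
    atoms = [
        ("A", i + 1, "CAG", "C1", "C", coords[i]) for i in range(n_atoms)
    ]
    closed = Structure.from_atoms(atoms)
    cap = dirs[:, 2] > np.cos(np.radians(gate_cap_deg))
    open_coords = coords.copy()
    open_coords[cap] = (shell_radius + gate_displacement) * dirs[cap]
    open_atoms = [
        ("A", i + 1, "CAG", "C1", "C", open_coords[i]) for i in range(n_atoms)
    ]
    opened = Structure.from_atoms(open_atoms)
    from .constants import VDW_RADII

    cavity_radius = shell_radius - (VDW_RADII["C"] + cutoff)
    volume = 4.0 / 3.0 * np.pi * cavity_radius**3
    truth = GroundTruthRecord(
        kind="breathing_cage", seed=seed, noise=0.0, cavity_volume=float(volume),
        extra=dict(gate_displacement=gate_displacement,
                   shell_radius=shell_radius, cutoff=cutoff),
    )
    return closed, opened, truth


def make_relaxation_set(
    motions: dict[str, MotionParams],
    fields_mhz=(600.0,),
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruthRecord]:
    """Forward-generated 15N R1/R2/NOE table with Gaussian noise.

    ``noise`` is the fractional s.d. applied to R1 and R2 (absolute for
    the NOE, scaled by 0.02 per 1% to keep it in its natural units).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for residue, m in motions.items():
        for f in fields_mhz:
            r1, r2, noe = predict_rates(m, f)
            sig1 = noise * r1
            sig2 = noise * r2
            sign = noise * 2.0  # NOE: absolute sigma, 0.06 at 3% noise
            rows.append(dict(
                residue=residue, field_mhz=float(f),
                r1=r1 + sig1 * rng.standard_normal(), r1_err=sig1,
                r2=r2 + sig2 * rng.standard_normal(), r2_err=sig2,
                noe=noe + sign * rng.standard_normal(), noe_err=sign,
            ))
    truth = GroundTruthRecord(
        kind="relaxation", seed=seed, noise=noise,
        motions={
            r: dict(s2=m.s2, tau_c_ns=m.tau_c_ns, tau_e_ps=m.tau_e_ps)
            for r, m in motions.items()
        },
    )
    return pd.DataFrame(rows), truth
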