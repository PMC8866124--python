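"""File formats: dispersion tables (CSV), PDB structures, aligned FASTA,
structured JSON fit reports.

CSV is UTF-8 with dot decimal separator and a mandatory exact header;
JSON reports use stable key ordering so that regenerating from the same
inputs and seeds is bit-identical except for the timestamp field.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .dispersion import (
    DispersionDataset,
    FitResult,
    INTENSITY_COLUMNS,
    R2EFF_COLUMNS,
)
from .errors import DataError, StructureError
from .seqpca import AlignedFamily
from .structure import MorphTrajectory, Structure

logger = logging.getLogger(__name__)

__all__ = [
    "read_dispersion_table",
    "write_dispersion_table",
    "read_pdb",
    "write_pdb",
    "read_fasta",
    "write_fasta",
    "fit_report",
    "write_fit_report",
]


def read_dispersion_table(path) -> DispersionDataset:
    """Read and validate a dispersion CSV (intensity or R2eff mode)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str)
    cols = list(df.columns)
    if cols == INTENSITY_COLUMNS:
        numeric = [c for c in INTENSITY_COLUMNS
                   if c not in ("dataset_id", "spin", "nucleus")]
    elif cols == R2EFF_COLUMNS:
        numeric = [c for c in R2EFF_COLUMNS
                   if c not in ("dataset_id", "spin", "nucleus")]
    else:
        raise DataError(
            f"{path}: header {cols} matches neither the intensity-mode nor "
            f"the r2eff-mode schema"
        )
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise DataError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r} at data row {row + 1}"
            )
        df[col] = converted
    return DispersionDataset(df)


def write_dispersion_table(data: DispersionDataset, path) -> None:
    cols = INTENSITY_COLUMNS if data.mode == "intensity" else R2EFF_COLUMNS
    data.df.to_csv(path, index=False, columns=cols)


def _element_of(atom: gemmi.Atom, name: str) -> str:
    el = atom.element.name.strip()
    if el and el != "X":
        return el
    stripped = name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "C"


def read_pdb(path) -> Structure:
    """First model of a PDB file; altloc 'A' or blank; heavy + H atoms.

    Coordinates are parsed to 0.001 Angstrom (PDB precision).
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise StructureError(f"{path}: no models / ATOM records")
    if len(st) > 1:
        logger.info("%s: %d models; using model 1 only", path, len(st))
    model = st[0]
    atoms = []
    for chain in model:
        for residue in chain:
            for atom in residue:
                if atom.altloc not in ("", "\0", "A"):
                    continue
                atoms.append((
                    chain.name, residue.seqid.num, residue.name.strip(),
                    atom.name.strip(), _element_of(atom, atom.name),
                    [atom.pos.x, atom.pos.y, atom.pos.z],
                ))
    if not atoms:
        raise StructureError(f"{path}: no ATOM/HETATM records")
    return Structure.from_atoms(atoms)


def _to_gemmi_model(s: Structure, num: int = 1) -> gemmi.Model:
    # gemmi's add_residue/add_chain copy their argument, so residues and
    # chains must be fully populated before they are added
    model = gemmi.Model(num)
    residues: dict[tuple, gemmi.Residue] = {}
    chain_order: list[str] = []
    for i in range(len(s)):
        cid = str(s.chains[i])
        rkey = (cid, int(s.res_nums[i]))
        if rkey not in residues:
            res = gemmi.Residue()
            res.name = str(s.res_names[i])
            res.seqid = gemmi.SeqId(int(s.res_nums[i]), " ")
            residues[rkey] = res
        if cid not in chain_order:
            chain_order.append(cid)
        atom = gemmi.Atom()
        atom.name = str(s.atom_names[i])
        atom.element = gemmi.Element(str(s.elements[i]))
        atom.occ = 1.0
        atom.pos = gemmi.Position(*s.coords[i])
        residues[rkey].add_atom(atom)
    for cid in chain_order:
        chain = gemmi.Chain(cid)
        for (c, _), res in residues.items():
            if c == cid:
                chain.add_residue(res)
        model.add_chain(chain)
    return model


def write_pdb(s: Structure | MorphTrajectory, path) -> None:
    """Write a structure (or a trajectory as a multi-model PDB)."""
    path = Path(path)
    st = gemmi.Structure()
    st.name = "ringflip"
    if isinstance(s, MorphTrajectory):
        for i, frame in enumerate(s.frames):
            st.add_model(_to_gemmi_model(frame, num=i + 1))
    else:
        st.add_model(_to_gemmi_model(s))
    st.setup_entities()
    st.write_pdb(str(path))


def read_fasta(path) -> AlignedFamily:
    """Aligned FASTA (gap character '-'), order preserved."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    names, seqs = [], []
    for record in SeqIO.parse(str(path), "fasta"):
        names.append(record.id)
        seqs.append(str(record.seq).upper())
    if not names:
        raise DataError(f"{path}: no sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        off = [n for n, s in zip(names, seqs) if len(s) != len(seqs[0])][0]
        raise DataError(
            f"{path}: ragged alignment (sequence {off!r} differs in length)"
        )
    return AlignedFamily(names, seqs, {})


def write_fasta(family: AlignedFamily, path) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(family.names, family.sequences):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def fit_report(fit: FitResult, input_digest: str = "",
               timestamp: str | None = None) -> dict:
    """Structured fit report with stable key ordering."""
    ddelta = {
        f"{spin}/{nucleus}": round(v, 6)
        for (spin, nucleus), v in sorted(fit.params.ddelta_ppm.items())
    }
    r2 = {
        f"{spin}/{nucleus}/{field:g}": round(v, 6)
        for (spin, nucleus, field), v in sorted(fit.r2_base.items())
    }
    return dict(
        package_version=__version__,
        input_digest=input_digest,
        timestamp=timestamp or "",
        seed=fit.seed,
        k_ex=fit.params.k_ex,
        k_ex_err=fit.kex_err,
        p_minor=fit.params.p_minor,
        p_minor_err=fit.pminor_err,
        ddelta_ppm=ddelta,
        r2_base=r2,
        chisq=fit.chisq,
        redchi=fit.redchi,
        n_points=fit.n_points,
        n_params=fit.n_params,
        converged=fit.converged,
    )


def write_fit_report(fit: FitResult, path, input_digest: str = "",
                     timestamp: str | None = None) -> None:
    with open(path, "w") as fh:
        json.dump(fit_report(fit, input_digest, timestamp), fh, indent=2,
                  sort_keys=False)
        fh.write("\n")
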