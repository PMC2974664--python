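"""Ground-truth labeling from antigen-antibody complex structures.

An antigen residue is antibody-interacting iff at least one of its heavy
atoms lies within 4 Å (inclusive) of any heavy atom of an antibody chain —
the benchmark interface definition.  Hydrogens are excluded (rarely resolved
in the crystal structures these labels come from), HETATM records (glycans,
ligands, waters) are excluded from both sides, and for alternate locations
Biopython's highest-occupancy conformer is used.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from Bio.SeqUtils import seq1
from scipy.spatial.distance import cdist

from .io import AntigenRecord

logger = logging.getLogger(__name__)


@dataclass
class ComplexSpec:
    """Which chains of a PDB file form the antigen and the antibody."""

    structure_path: str | Path
    antigen_chains: list[str]
    antibody_chains: list[str]
    cutoff: float = 4.0

    def __post_init__(self) -> None:
        if not self.antigen_chains or not self.antibody_chains:
            raise ValueError("antigen and antibody chain lists must be non-empty")
        overlap = set(self.antigen_chains) & set(self.antibody_chains)
        if overlap:
            raise ValueError(f"chains cannot be on both sides: {sorted(overlap)}")
        if self.cutoff <= 0:
            raise ValueError(f"cutoff must be positive, got {self.cutoff}")


def _heavy_atom_coords(residue) -> np.ndarray:
    """Coordinates of a residue's heavy atoms (hydrogens/deuteriums excluded)."""
    coords = [
        atom.coord
        for atom in residue.get_atoms()  # yields highest-occupancy altloc
        if (atom.element or "").upper() not in ("H", "D")
    ]
    return np.array(coords, dtype=float).reshape(-1, 3)


def _standard_residues(chain):
    """ATOM-record residues of a chain, in chain order (HETATM excluded)."""
    return [res for res in chain if res.id[0] == " "]


def label_from_complex(spec: ComplexSpec) -> list[AntigenRecord]:
    """Derive per-residue interaction labels for each antigen chain.

    A residue is labeled 1 iff the minimum distance between any of its heavy
    atoms and any antibody heavy atom is <= ``spec.cutoff`` (inclusive at
    exactly 4.0 Å by default).  The returned sequence is read from the
    resolved ATOM residues in chain order; residues without coordinates are
    skipped with a warning.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = PDBParser(QUIET=True).get_structure("complex", str(spec.structure_path))
    model = next(structure.get_models())
    available = [c.id for c in model]
    for cid in list(spec.antigen_chains) + list(spec.antibody_chains):
        if cid not in available:
            raise ValueError(
                f"chain {cid!r} not found in {spec.structure_path}; "
                f"available chains: {available}"
            )

    antibody_coords = []
    for cid in spec.antibody_chains:
        for res in _standard_residues(model[cid]):
            antibody_coords.append(_heavy_atom_coords(res))
    antibody_xyz = (
        np.vstack([c for c in antibody_coords if len(c)])
        if antibody_coords
        else np.empty((0, 3))
    )
    if len(antibody_xyz) == 0:
        raise ValueError("antibody chains contain no heavy atoms")

    records = []
    for cid in spec.antigen_chains:
        seq_letters: list[str] = []
        labels: list[int] = []
        for res in _standard_residues(model[cid]):
            xyz = _heavy_atom_coords(res)
            if len(xyz) == 0:
                logger.warning(
                    "chain %s residue %s has no heavy atoms; skipped", cid, res.id
                )
                continue
            letter = seq1(res.get_resname(), undef_code="X")
            min_dist = cdist(xyz, antibody_xyz).min()
            seq_letters.append(letter)
            labels.append(1 if min_dist <= spec.cutoff else 0)
        if not seq_letters:
            raise ValueError(f"antigen chain {cid!r} has no residues with coordinates")
        records.append(AntigenRecord(id=cid, sequence="".join(seq_letters), labels=labels))
    return records


_AA3 = [
    "ALA", "CYS", "ASP", "GLU", "PHE", "GLY", "HIS", "ILE", "LYS", "LEU",
    "MET", "ASN", "PRO", "GLN", "ARG", "SER", "THR", "VAL", "TRP", "TYR",
]


def _atom_line(serial, name, resname, chain, resseq, xyz, element) -> str:
    # strict PDB columns: name 13-16, altloc 17, resname 18-20, chain 22,
    # resseq 23-26, icode 27, x from 31
    return (
        f"ATOM  {serial:>5d} {name:<4s} {resname:>3s} {chain}{resseq:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element:>2s}"
    )


def generate_complex_fixture(
    n_antigen_residues: int,
    n_epitope_residues: int,
    seed: int,
    contact_distance: float = 3.5,
    spacing: float = 10.0,
    return_labels: bool = False,
) -> str | tuple[str, list[int]]:
    """Build a synthetic two-chain PDB complex with a known interface.

    Chain A ("antigen") residues sit along a line ``spacing`` Å apart, each
    with a CA and a jittered CB atom.  Chain B ("antibody") places one atom
    ``contact_distance`` Å from the CA of each chosen epitope residue, plus a
    distant anchor atom, so labeling chain A at a cutoff above
    ``contact_distance`` recovers exactly the chosen residues.  Deterministic
    under ``seed``; the geometry guarantees non-epitope residues stay far
    from every antibody atom provided ``spacing`` comfortably exceeds the
    contact distance.
    """
    if n_epitope_residues > n_antigen_residues:
        raise ValueError("cannot request more epitope residues than residues")
    if n_antigen_residues < 1:
        raise ValueError("need at least one antigen residue")
    if contact_distance >= spacing / 2:
        raise ValueError(
            f"contact distance {contact_distance} too large for spacing {spacing}: "
            "non-epitope residues would fall inside the cutoff"
        )
    rng = np.random.default_rng(seed)
    epitope = set(
        rng.choice(n_antigen_residues, size=n_epitope_residues, replace=False).tolist()
    )

    lines = []
    serial = 1
    ca_positions: dict[int, np.ndarray] = {}
    for i in range(n_antigen_residues):
        resname = _AA3[rng.integers(len(_AA3))]
        # jitter on a 0.25 A grid: exactly representable in the 3-decimal
        # PDB fixed-point columns AND in binary floats, so a planted contact
        # at exactly the cutoff stays exactly at the cutoff after parsing
        ca = np.array([spacing * i, 0.0, 0.0]) + rng.integers(-1, 2, 3) * 0.25
        cb = ca + np.array([0.0, 1.5, 0.0]) + rng.integers(-1, 2, 3) * 0.25
        ca_positions[i] = ca
        lines.append(_atom_line(serial, " CA", resname, "A", i + 1, ca, "C")); serial += 1
        lines.append(_atom_line(serial, " CB", resname, "A", i + 1, cb, "C")); serial += 1
    lines.append(f"TER   {serial:>5d}      {_AA3[0]:>3s} A{n_antigen_residues:>4d}")
    serial += 1

    resseq = 1
    for i in sorted(epitope):
        # contact atom exactly contact_distance below residue i's actual CA,
        # on the opposite side from its CB
        atom = ca_positions[i] + np.array([0.0, -contact_distance, 0.0])
        lines.append(_atom_line(serial, " CA", "ALA", "B", resseq, atom, "C"))
        serial += 1
        resseq += 1
    # distant anchor keeps chain B non-empty even with an empty epitope
    anchor = np.array([-10 * spacing, -10 * spacing, -10 * spacing])
    lines.append(_atom_line(serial, " CA", "GLY", "B", resseq, anchor, "C"))
    serial += 1
    lines.append(f"TER   {serial:>5d}      GLY B{resseq:>4d}")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if return_labels:
        planted = [1 if i in epitope else 0 for i in range(n_antigen_residues)]
        return text, planted
    return text
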