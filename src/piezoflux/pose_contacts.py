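"""Residue-contact frequencies across a docking-pose ensemble.

Given a fixed receptor structure and an ensemble of ligand poses (e.g. from
AutoDock Vina), the contact profile reports for each receptor residue the
fraction of poses in which any of its atoms lies within a distance cutoff
(default 3.5 A) of any ligand atom.  This is the statistic behind "residue X
is within 3.5 A of the ligand in 78% of all possible binding poses".

Structures are standard PDB; the ligand is recognized as HETATM records whose
residue name matches a configurable set (default ``{"LIG"}``).  Hydrogens,
if present in the file, participate in the distance checks; a heavy-atom-only
mode is available behind a flag.  The distance comparison is inclusive
(``<= cutoff``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBIO, PDBParser, StructureBuilder
from scipy.spatial import cKDTree

ATOM_COLUMNS = (
    "chain", "resseq", "resname", "atom_name", "element",
    "x", "y", "z", "hetero", "is_ligand",
)

DEFAULT_LIGAND_RESNAMES = frozenset({"LIG"})

ResidueKey = tuple[str, int, str]  # (chain, resseq, resname)


@dataclass
class PoseEnsemble:
    """Fixed receptor atoms plus one atom table per ligand pose."""

    receptor: pd.DataFrame
    poses: list[pd.DataFrame]

    def __post_init__(self) -> None:
        if len(self.poses) < 1:
            raise ValueError("a pose ensemble needs at least one pose")

    @property
    def n_poses(self) -> int:
        return len(self.poses)


@dataclass
class ContactProfile:
    """Per-residue fraction of poses with at least one ligand contact."""

    fractions: dict[ResidueKey, float]
    cutoff: float
    n_poses: int

    def to_frame(self) -> pd.DataFrame:
        """Bar-chart-ready table sorted by descending contact fraction."""
        rows = [
            {
                "chain": chain,
                "resseq": resseq,
                "residue": f"{resname}{resseq}",
                "fraction": frac,
                "percent": 100.0 * frac,
                "n_poses": self.n_poses,
            }
            for (chain, resseq, resname), frac in self.fractions.items()
        ]
        df = pd.DataFrame(
            rows, columns=["chain", "resseq", "residue", "fraction", "percent", "n_poses"]
        )
        return df.sort_values(
            ["fraction", "chain", "resseq"], ascending=[False, True, True]
        ).reset_index(drop=True)


def _structure_to_frame(structure, ligand_resnames: frozenset[str]) -> list[pd.DataFrame]:
    frames = []
    for model in structure:
        rows = []
        for chain in model:
            for res in chain:
                hetfield = res.id[0]
                hetero = hetfield.strip() != ""
                is_ligand = hetero and res.resname.strip() in ligand_resnames
                for atom in res:
                    x, y, z = atom.coord
                    rows.append(
                        {
                            "chain": chain.id,
                            "resseq": int(res.id[1]),
                            "resname": res.resname.strip(),
                            "atom_name": atom.get_name(),
                            "element": (atom.element or "").strip(),
                            "x": float(x), "y": float(y), "z": float(z),
                            "hetero": hetero,
                            "is_ligand": is_ligand,
                        }
                    )
        frames.append(pd.DataFrame(rows, columns=list(ATOM_COLUMNS)))
    return frames


def read_structure(
    path: str | Path,
    ligand_resnames: frozenset[str] | set[str] = DEFAULT_LIGAND_RESNAMES,
    warn_no_ligand: bool = True,
) -> pd.DataFrame:
    """Read a PDB file into an atom table (first model).

    The ``is_ligand`` flag is set for HETATM records whose residue name is in
    ``ligand_resnames``.  A file containing no HETATM records parses fine but
    triggers a warning (zero ligand atoms), unless ``warn_no_ligand=False``.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    frames = _structure_to_frame(structure, frozenset(ligand_resnames))
    if not frames or len(frames[0]) == 0:
        raise ValueError(f"no atoms parsed from {path}")
    atoms = frames[0]
    if warn_no_ligand and not atoms["hetero"].any():
        warnings.warn(
            f"{path}: no HETATM records; zero ligand atoms", stacklevel=2
        )
    return atoms


def read_pose_ensemble(
    receptor_path: str | Path,
    poses_path: str | Path | list[str | Path],
    ligand_resnames: frozenset[str] | set[str] = DEFAULT_LIGAND_RESNAMES,
) -> PoseEnsemble:
    """Load a receptor PDB and ligand poses (multi-model PDB or one file each)."""
    receptor_atoms = read_structure(receptor_path, ligand_resnames, warn_no_ligand=False)
    receptor = receptor_atoms[~receptor_atoms["is_ligand"]].reset_index(drop=True)
    paths = poses_path if isinstance(poses_path, list) else [poses_path]
    parser = PDBParser(QUIET=True)
    poses = []
    for p in paths:
        structure = parser.get_structure("poses", str(p))
        for frame in _structure_to_frame(structure, frozenset(ligand_resnames)):
            lig = frame[frame["is_ligand"]].reset_index(drop=True)
            if len(lig) == 0:
                raise ValueError(f"{p}: model without ligand atoms ({ligand_resnames})")
            poses.append(lig)
    return PoseEnsemble(receptor=receptor, poses=poses)


def residues_within(
    receptor: pd.DataFrame,
    ligand: pd.DataFrame,
    cutoff: float = 3.5,
    heavy_only: bool = False,
) -> set[ResidueKey]:
    """Receptor residues with ANY atom within ``cutoff`` A of ANY ligand atom.

    The comparison is inclusive (``<= cutoff``).  With ``heavy_only=True``,
    hydrogen atoms on both sides are ignored.
    """
    if len(receptor) == 0 or len(ligand) == 0:
        raise ValueError("receptor and ligand atom sets must be nonempty")
    rec = receptor[receptor["element"] != "H"] if heavy_only else receptor
    lig = ligand[ligand["element"] != "H"] if heavy_only else ligand
    if len(rec) == 0 or len(lig) == 0:
        return set()
    tree = cKDTree(lig[["x", "y", "z"]].to_numpy(float))
    dmin, _ = tree.query(rec[["x", "y", "z"]].to_numpy(float), k=1)
    hit = rec.loc[dmin <= cutoff, ["chain", "resseq", "resname"]]
    return {
        (str(c), int(s), str(n))
        for c, s, n in hit.itertuples(index=False, name=None)
    }


def contact_frequency(
    ensemble: PoseEnsemble, cutoff: float = 3.5, heavy_only: bool = False
) -> ContactProfile:
    """Fraction of poses contacting each residue (zero-contact residues omitted).

    Fractions are exact multiples of ``1 / n_poses``.
    """
    counts: dict[ResidueKey, int] = {}
    for pose in ensemble.poses:
        for key in residues_within(ensemble.receptor, pose, cutoff, heavy_only):
            counts[key] = counts.get(key, 0) + 1
    n = ensemble.n_poses
    fractions = {key: c / n for key, c in counts.items()}
    return ContactProfile(fractions=fractions, cutoff=cutoff, n_poses=n)


# ---------------------------------------------------------------------------
# PDB writing (used by the synthetic pose fixtures)


def _build_structure(models: list[pd.DataFrame]):
    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("s")
    for i, atoms in enumerate(models):
        builder.init_model(i)
        builder.init_seg("    ")
        serial = 1
        current_chain = None
        current_res = None
        for row in atoms.itertuples(index=False):
            if row.chain != current_chain:
                builder.init_chain(row.chain)
                current_chain = row.chain
                current_res = None
            hetfield = f"H_{row.resname}" if row.hetero else " "
            res_key = (hetfield, int(row.resseq), row.resname)
            if res_key != current_res:
                builder.init_residue(row.resname, hetfield, int(row.resseq), " ")
                current_res = res_key
            builder.init_atom(
                row.atom_name,
                np.array([row.x, row.y, row.z], float),
                0.0, 1.0, " ",
                row.atom_name.center(4)[:4],
                serial,
                element=row.element or None,
            )
            serial += 1
    return builder.get_structure()


def write_pdb(atoms: pd.DataFrame, path: str | Path) -> None:
    """Write one atom table as a single-model PDB (ATOM/HETATM records)."""
    io = PDBIO()
    io.set_structure(_build_structure([atoms]))
    io.save(str(path))


def write_pose_ensemble(
    ensemble: PoseEnsemble, receptor_path: str | Path, poses_path: str | Path
) -> None:
    """Write the receptor and a MODEL/ENDMDL multi-model ligand-pose PDB."""
    write_pdb(ensemble.receptor, receptor_path)
    io = PDBIO()
    io.set_structure(_build_structure(ensemble.poses))
    io.save(str(poses_path))
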