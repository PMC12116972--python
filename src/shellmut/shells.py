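"""Coordination-shell classification of residues around catalytic metal ions.

Each amino-acid residue is assigned the minimum Euclidean distance from any
of its non-hydrogen atoms to any catalytic metal site, then binned into
half-open distance shells: first [0, b1), second [b1, b2), third [b2, b3),
outside [b3, inf).  Defaults b1, b2, b3 = 5, 8, 12 angstrom reflect the
substrate-contact, hydrogen-bond-network, and long-range-interaction scales
around multicopper oxidase Cu centres.

Structures are read with gemmi (PDB or mmCIF); the first model is used and
alternate conformations are resolved to the highest-occupancy atom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SHELL_LABELS = ("first", "second", "third", "outside")
DEFAULT_BOUNDS = (5.0, 8.0, 12.0)
DEFAULT_METALS = ("CU",)


class NoMetalSitesError(ValueError):
    """The structure contains no hetero atom of the requested elements."""


@dataclass(frozen=True)
class MetalSite:
    element: str
    label: str
    xyz: tuple[float, float, float]


@dataclass(frozen=True)
class ShellAssignment:
    chain: str
    resnum: int  # author residue number, 1-based
    resname: str
    min_distance: float  # angstrom, over heavy atoms x metal sites
    shell: str
    nearest_metal: str


def read_structure(path: str | Path) -> gemmi.Structure:
    """Read a PDB or mmCIF file into a gemmi Structure."""
    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    return structure


def _is_amino_acid(residue: gemmi.Residue) -> bool:
    info = gemmi.find_tabulated_residue(residue.name)
    return info is not None and info.is_amino_acid()


def _dedupe_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Resolve alternate conformations to the highest-occupancy atom per name."""
    best: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    return list(best.values())


def find_metal_sites(
    structure: gemmi.Structure, elements=DEFAULT_METALS
) -> list[MetalSite]:
    """Collect hetero atoms of the given elements as metal sites, in file order."""
    wanted = {e.upper() for e in elements}
    sites: list[MetalSite] = []
    model = structure[0]
    counter: dict[str, int] = {}
    for chain in model:
        for residue in chain:
            if _is_amino_acid(residue):
                continue
            for atom in residue:
                elem = atom.element.name.upper()
                if elem in wanted:
                    counter[elem] = counter.get(elem, 0) + 1
                    sites.append(
                        MetalSite(
                            element=elem,
                            label=f"{elem}{counter[elem]}",
                            xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                        )
                    )
    if not sites:
        raise NoMetalSitesError(
            f"no metal sites found for elements {sorted(wanted)}"
        )
    return sites


def assign_shells(
    structure: gemmi.Structure,
    metals: list[MetalSite],
    bounds: tuple[float, float, float] = DEFAULT_BOUNDS,
    ca_only: bool = False,
) -> list[ShellAssignment]:
    """Assign every amino-acid residue a shell by minimum heavy-atom distance.

    ``ca_only`` measures from the C-alpha atom alone, a coarser convention
    useful for sensitivity checks.
    """
    b1, b2, b3 = bounds
    if not 0 < b1 < b2 < b3:
        raise ValueError(f"shell bounds must satisfy 0 < b1 < b2 < b3, got {bounds}")
    if not metals:
        raise ValueError("metal site list is empty")

    metal_xyz = np.array([m.xyz for m in metals])  # (M, 3)
    out: list[ShellAssignment] = []
    model = structure[0]
    for chain in model:
        for residue in chain:
            if not _is_amino_acid(residue):
                continue
            atoms = _dedupe_altlocs(residue)
            if ca_only:
                atoms = [a for a in atoms if a.name == "CA"]
            coords = np.array(
                [
                    (a.pos.x, a.pos.y, a.pos.z)
                    for a in atoms
                    if not a.element.is_hydrogen
                ]
            )
            if coords.size == 0:
                logger.warning(
                    "skipping residue %s %s%d: no heavy atoms",
                    residue.name, chain.name, residue.seqid.num,
                )
                continue
            # (A, M) pairwise distances
            d = np.linalg.norm(coords[:, None, :] - metal_xyz[None, :, :], axis=2)
            flat = int(d.argmin())
            min_d = float(d.flat[flat])
            nearest = metals[flat % len(metals)].label
            if min_d < b1:
                shell = "first"
            elif min_d < b2:
                shell = "second"
            elif min_d < b3:
                shell = "third"
            else:
                shell = "outside"
            out.append(
                ShellAssignment(
                    chain=chain.name,
                    resnum=residue.seqid.num,
                    resname=residue.name,
                    min_distance=min_d,
                    shell=shell,
                    nearest_metal=nearest,
                )
            )
    return out


def shell_summary(
    assignments: list[ShellAssignment], subset: list[int] | None = None
) -> dict[str, int]:
    """Count residues per shell, optionally restricted to a subset of positions."""
    if subset is not None:
        known = {a.resnum for a in assignments}
        missing = sorted(set(subset) - known)
        if missing:
            raise KeyError(f"positions absent from structure: {missing}")
        pool = [a for a in assignments if a.resnum in set(subset)]
    else:
        pool = assignments
    counts = {label: 0 for label in SHELL_LABELS}
    for a in pool:
        counts[a.shell] += 1
    return counts


def assignments_to_frame(assignments: list[ShellAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chain": a.chain,
                "position": a.resnum,
                "resname": a.resname,
                "min_distance_A": a.min_distance,
                "nearest_metal": a.nearest_metal,
                "shell": a.shell,
            }
            for a in assignments
        ],
        columns=["chain", "position", "resname", "min_distance_A", "nearest_metal", "shell"],
    )
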