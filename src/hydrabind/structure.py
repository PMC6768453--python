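"""PDB structure loading and atom selection, backed by MDAnalysis.

Provides the bridge between coordinate files and the package's occluder
representation: every atom becomes a :class:`~hydrabind.spheres.SoluteAtom`
with a Bondi van der Waals radius, and MDAnalysis selection expressions
identify ligand atoms or the atoms defining an analysis-region center.
"""

from __future__ import annotations

import warnings

import numpy as np

from .constants import vdw_radius
from .spheres import SoluteAtom

__all__ = ["load_structure", "select_atoms", "region_center"]


def _universe(path):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # PDBs without elements/masses are fine here
        return mda.Universe(str(path))


def _guess_element(atom) -> str:
    el = getattr(atom, "element", "") or ""
    if el.strip():
        return el.strip()
    name = atom.name.strip()
    # strip leading digits (e.g. 1HB2), then take the leading alpha run
    core = name.lstrip("0123456789")
    return core[:1].upper() if core else "C"


def _to_solute_atoms(group, radius_overrides=None) -> list[SoluteAtom]:
    atoms = []
    for a in group.atoms:
        el = _guess_element(a)
        atoms.append(
            SoluteAtom(
                serial=int(a.id),
                element=el,
                position=tuple(float(x) for x in a.position),
                radius=vdw_radius(el, radius_overrides),
            )
        )
    return atoms


def load_structure(path, selection: str = "all", radius_overrides=None) -> list[SoluteAtom]:
    """Read a PDB file into SoluteAtom records (1-based serials, Å)."""
    u = _universe(path)
    return _to_solute_atoms(u.select_atoms(selection), radius_overrides)


def select_atoms(path, selection: str, radius_overrides=None) -> list[SoluteAtom]:
    """Atoms matching an MDAnalysis selection expression (e.g. ``resname LIG``)."""
    return load_structure(path, selection, radius_overrides)


def region_center(path, selection: str) -> np.ndarray:
    """Geometric center (Å) of a PDB atom selection.

    Used to define the center of the spherical hydration-analysis region
    when no reference ligand is available.
    """
    u = _universe(path)
    group = u.select_atoms(selection)
    if len(group) == 0:
        raise ValueError(f"selection {selection!r} matched no atoms")
    return group.positions.mean(axis=0).astype(float)
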