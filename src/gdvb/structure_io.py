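"""Read and write macromolecular structure files.

Atoms are exposed as an ordered list of :class:`AtomRecord`; the order is
stable and defines the row index of every downstream matrix (contact graph,
orbit matrix, feature matrix).  Parsing of PDB and mmCIF is delegated to
:mod:`gemmi`; writing emits fixed-column PDB ``ATOM``/``HETATM`` records with
the B column (columns 61-66, ``%6.2f``) replaced.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi

__all__ = [
    "AtomRecord",
    "StructureModel",
    "Selection",
    "read_structure",
    "mark_environment",
    "write_structure_with_b",
    "write_pdb",
]

#: element symbols treated as hydrogen for the heavy-atom selection
_HYDROGENS = {"H", "D", "T"}
_WATERS = {"HOH", "WAT", "DOD", "H2O"}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structural model.

    Coordinates are in Å, ``b_value`` in Å².  ``is_environment`` marks
    symmetry-related copies that complete a surface atom's contact shell:
    they participate in the contact graph and in feature smoothing but are
    excluded from the regression response and from evaluation.
    """

    serial: int
    atom_name: str
    element: str
    altloc: str
    res_name: str
    chain_id: str
    res_seq: int
    icode: str
    x: float
    y: float
    z: float
    occupancy: float
    b_value: float
    is_hetero: bool = False
    is_environment: bool = False

    def __post_init__(self) -> None:
        for c in (self.x, self.y, self.z):
            if not math.isfinite(c):
                raise ValueError(
                    f"non-finite coordinate for atom {self.chain_id}/"
                    f"{self.res_seq}{self.icode}/{self.atom_name}"
                )


@dataclass
class StructureModel:
    """An ordered atom list plus entry-level metadata."""

    entry_id: str
    atoms: list[AtomRecord]
    resolution: float | None = None
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not any(not a.is_environment for a in self.atoms):
            raise ValueError("structure must contain at least one non-environment atom")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self):
        import numpy as np

        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    @property
    def b_values(self):
        import numpy as np

        return np.array([a.b_value for a in self.atoms], dtype=float)

    @property
    def core_mask(self):
        """Boolean mask selecting non-environment atoms (regression rows)."""
        import numpy as np

        return np.array([not a.is_environment for a in self.atoms], dtype=bool)


@dataclass(frozen=True)
class Selection:
    """Atom-selection specification applied at read time.

    The default (``heavy-protein``) keeps non-hydrogen polymer atoms and
    drops waters and hetero compounds.  ``chains``/``res_names`` restrict to
    the given identifiers when not None.
    """

    include_hydrogens: bool = False
    include_hetero: bool = False
    include_waters: bool = False
    chains: frozenset[str] | None = None
    res_names: frozenset[str] | None = None

    @classmethod
    def from_spec(cls, spec: "str | Selection") -> "Selection":
        if isinstance(spec, Selection):
            return spec
        if spec == "heavy-protein":
            return cls()
        if spec == "all-atoms":
            return cls(include_hydrogens=True, include_hetero=True, include_waters=True)
        raise ValueError(f"unknown selection spec: {spec!r}")

    def admits(self, atom: AtomRecord) -> bool:
        if not self.include_hydrogens and atom.element.upper() in _HYDROGENS:
            return False
        is_water = atom.res_name.upper() in _WATERS
        if is_water and not self.include_waters:
            return False
        if atom.is_hetero and not is_water and not self.include_hetero:
            return False
        if self.chains is not None and atom.chain_id not in self.chains:
            return False
        if self.res_names is not None and atom.res_name not in self.res_names:
            return False
        return True


def _atoms_from_gemmi(st: gemmi.Structure) -> Iterable[AtomRecord]:
    if len(st) > 1:
        warnings.warn(
            f"{st.name or 'structure'}: {len(st)} models present; using model 1 only",
            stacklevel=3,
        )
    model = st[0]
    for chain in model:
        for residue in chain:
            het = residue.het_flag == "H"
            for atom in residue:
                yield AtomRecord(
                    serial=atom.serial,
                    atom_name=atom.name,
                    element=atom.element.name,
                    altloc=atom.altloc.strip("\x00") if atom.altloc else "",
                    res_name=residue.name,
                    chain_id=chain.name,
                    res_seq=residue.seqid.num,
                    icode=residue.seqid.icode.strip() if residue.seqid.icode else "",
                    x=atom.pos.x,
                    y=atom.pos.y,
                    z=atom.pos.z,
                    occupancy=atom.occ,
                    b_value=atom.b_iso,
                    is_hetero=het,
                )


def _resolve_altlocs(atoms: Sequence[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom site: highest occupancy, ties to the
    lexicographically smallest altloc (blank sorts first)."""
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for a in atoms:
        key = (a.chain_id, a.res_seq, a.icode, a.res_name, a.atom_name)
        if key not in best:
            best[key] = a
            order.append(key)
        else:
            b = best[key]
            if a.occupancy > b.occupancy or (
                a.occupancy == b.occupancy and a.altloc < b.altloc
            ):
                best[key] = a
    return [best[k] for k in order]


def read_structure(
    path: str | Path, selection: "str | Selection" = "heavy-protein"
) -> StructureModel:
    """Read a PDB or mmCIF file and return the selected atoms in file order.

    Parameters
    ----------
    path
        Structure file; the format is detected from the contents/extension.
    selection
        ``"heavy-protein"`` (default), ``"all-atoms"`` or a :class:`Selection`.

    Raises
    ------
    ValueError
        If the file cannot be parsed or the selection leaves zero atoms.
    """
    path = Path(path)
    sel = Selection.from_spec(selection)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"no models found in {path}")
    atoms = [a for a in _atoms_from_gemmi(st) if sel.admits(a)]
    atoms = _resolve_altlocs(atoms)
    if not atoms:
        raise ValueError(f"selection left zero atoms in {path}")
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    return StructureModel(
        entry_id=st.name or path.stem,
        atoms=atoms,
        resolution=resolution,
    )


def mark_environment(model: StructureModel, flags: Sequence[bool]) -> StructureModel:
    """Return a copy of *model* with per-atom environment flags set.

    Environment atoms are symmetry-related copies added by an external
    expansion step; they stay in the atom list (and the contact graph) but
    downstream fitting and evaluation must skip them.
    """
    if len(flags) != len(model.atoms):
        raise ValueError(
            f"flags length {len(flags)} != atom count {len(model.atoms)}"
        )
    atoms = [replace(a, is_environment=bool(f)) for a, f in zip(model.atoms, flags)]
    return StructureModel(
        entry_id=model.entry_id,
        atoms=atoms,
        resolution=model.resolution,
        metadata=dict(model.metadata),
    )


def _pdb_line(a: AtomRecord, serial: int, b: float) -> str:
    record = "HETATM" if a.is_hetero else "ATOM  "
    name = a.atom_name
    # conventional name justification: pad 1-char/2-char element names
    if len(name) < 4 and len(a.element) == 1:
        name = f" {name}"
    return (
        f"{record}{serial:5d} {name:<4s}{a.altloc or ' ':1s}{a.res_name:<3s} "
        f"{a.chain_id[:1]:1s}{a.res_seq:4d}{a.icode or ' ':1s}   "
        f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}{b:6.2f}"
        f"          {a.element:>2s}"
    )


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model as minimal fixed-column PDB ATOM/HETATM records."""
    lines = [
        _pdb_line(a, i + 1, a.b_value) for i, a in enumerate(model.atoms)
    ]
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_structure_with_b(
    model: StructureModel, values: Sequence[float], path: str | Path
) -> None:
    """Write a PDB whose B column holds *values* (one per non-environment atom).

    Environment atoms are omitted from the output.  Negative values are
    permitted: the writer is routinely used for normalized (z-scored) scores.
    """
    core = [a for a in model.atoms if not a.is_environment]
    if len(values) != len(core):
        raise ValueError(
            f"values length {len(values)} != non-environment atom count {len(core)}"
        )
    lines = [_pdb_line(a, i + 1, float(v)) for i, (a, v) in enumerate(zip(core, values), 0)]
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
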