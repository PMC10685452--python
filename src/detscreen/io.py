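"""Readers and writers for annotated structures and trajectories.

Supported formats:

* **PDB** (read/write) — fixed-width records via biotite; multi-model files
  use MODEL/ENDMDL, CRYST1 supplies the box.  PDB coordinates are in Å and
  are converted to nm at this boundary.
* **GRO** (read only) — standard fixed-width file; the first three floats of
  the box line are taken as orthorhombic extents.
* **xyzext** (read/write, byte-stable) — an extended-XYZ dialect: line 1 is
  the atom count, line 2 is ``time=<ps> box=<Lx>,<Ly>,<Lz> units=nm`` and
  every following line is ``name x y z`` with nm coordinates printed to four
  decimals.  Writer output is deterministic, so write→read→write is
  byte-identical.

Chemical identity (which species is a lipid, which detergent atoms are head
vs. tail) is not encoded in coordinate files; it comes from an *annotation
mapping* (:class:`Annotations`), either built programmatically or loaded from
a flat TOML file::

    [classes]
    DOPC = "lipid"
    MEG9 = "detergent"

    [roles.MEG9]
    O1 = "head"
    C8 = "tail"

In xyzext files written by this package the atom-name field is a compound
``species:class:molecule_id:residue_index:atom_name[:role]`` token, which
makes the dialect fully self-describing; plain names (e.g. from third-party
xyz files) are accepted too and treated as single-atom molecules of a species
equal to the name, classified through the annotation mapping.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import AtomRecord, Box, Frame, Topology, Trajectory, is_heavy

__all__ = [
    "Annotations",
    "ParseError",
    "parse_structure",
    "read_trajectory",
    "write_trajectory",
]


class ParseError(ValueError):
    """Malformed structure/trajectory file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


@dataclass
class Annotations:
    """Mapping of species → molecule class and (species, atom name) → role."""

    species_class: dict[str, str] = field(default_factory=dict)
    roles: dict[tuple[str, str], str] = field(default_factory=dict)

    @classmethod
    def from_toml(cls, path: str | Path) -> "Annotations":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        species_class = {str(k): str(v) for k, v in data.get("classes", {}).items()}
        roles = {}
        for species, mapping in data.get("roles", {}).items():
            for atom_name, role in mapping.items():
                roles[(str(species), str(atom_name))] = str(role)
        return cls(species_class, roles)

    def class_of(self, species: str) -> str:
        try:
            return self.species_class[species]
        except KeyError:
            raise ParseError(
                f"unknown species {species!r}: no molecule class annotation; "
                f"annotated species are {sorted(self.species_class)}"
            ) from None

    def role_of(self, species: str, atom_name: str) -> str:
        return self.roles.get((species, atom_name), "none")


# ---------------------------------------------------------------------------
# biotite-backed PDB / GRO reading
# ---------------------------------------------------------------------------


def _records_from_atom_array(arr, annotations: Annotations) -> list[AtomRecord]:
    """Build AtomRecords from a biotite AtomArray (one model)."""
    records: list[AtomRecord] = []
    molecule_id = 0
    prev_key: tuple | None = None
    prev_class: str | None = None
    for i in range(arr.array_length()):
        species = str(arr.res_name[i]).strip()
        mol_class = annotations.class_of(species)
        key = (str(arr.chain_id[i]), int(arr.res_id[i]), species)
        if mol_class == "protein":
            # contiguous protein residues in one chain form one molecule
            if prev_class != "protein" or (prev_key and prev_key[0] != key[0]):
                molecule_id += 1
        elif key != prev_key:
            molecule_id += 1
        prev_key, prev_class = key, mol_class
        name = str(arr.atom_name[i]).strip()
        element = str(arr.element[i]).strip() if "element" in arr.get_annotation_categories() else ""
        records.append(
            AtomRecord(
                atom_id=i + 1,
                name=name,
                element=element,
                is_heavy=is_heavy(element, name),
                molecule_id=molecule_id,
                molecule_class=mol_class,
                species=species,
                residue_index=int(arr.res_id[i]) if mol_class == "protein" else 0,
                role=annotations.role_of(species, name) if mol_class == "detergent" else "none",
            )
        )
    return records


def _read_biotite(path: Path, fmt: str, annotations: Annotations) -> Trajectory:
    import biotite.structure as struc

    if fmt == "pdb":
        from biotite.structure.io.pdb import PDBFile

        stack = PDBFile.read(str(path)).get_structure(model=None)
    else:
        from biotite.structure.io.gro import GROFile

        stack = GROFile.read(str(path)).get_structure(model=None)
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    first = stack[0]
    topology = Topology(_records_from_atom_array(first, annotations))
    if stack.box is None:
        raise ParseError(f"{path} declares no box (CRYST1 / box line missing)")
    frames = []
    for m in range(stack.stack_depth()):
        box = Box.from_matrix(np.asarray(stack.box[m]) / 10.0)  # Å → nm
        coords = np.asarray(stack.coord[m], dtype=float) / 10.0
        frames.append(Frame(time=float(m), box=box, coords=coords))
    return Trajectory(topology, frames)


# ---------------------------------------------------------------------------
# xyzext dialect
# ---------------------------------------------------------------------------


def _xyz_name(rec: AtomRecord) -> str:
    token = (
        f"{rec.species}:{rec.molecule_class}:{rec.molecule_id}:"
        f"{rec.residue_index}:{rec.name}"
    )
    if rec.role != "none":
        token += f":{rec.role}"
    return token


def _record_from_xyz_name(token: str, atom_id: int, annotations: Annotations | None) -> AtomRecord:
    parts = token.split(":")
    if len(parts) >= 5:
        species, mol_class = parts[0], parts[1]
        mol_id, resi, name = int(parts[2]), int(parts[3]), parts[4]
        role = parts[5] if len(parts) > 5 else "none"
        if mol_class == "detergent" and role == "none" and annotations is not None:
            role = annotations.role_of(species, name)
    else:
        # plain xyz name: single-atom molecule, species == name
        species = name = token
        mol_id, resi, role = atom_id, 0, "none"
        if annotations is None:
            raise ParseError(
                f"plain atom name {token!r} requires a class annotation for species {token!r}"
            )
        mol_class = annotations.class_of(species)
        role = annotations.role_of(species, name)
    return AtomRecord(
        atom_id=atom_id,
        name=name,
        element="",
        is_heavy=is_heavy("", name),
        molecule_id=mol_id,
        molecule_class=mol_class,
        species=species,
        residue_index=resi if mol_class == "protein" else 0,
        role=role if mol_class == "detergent" else "none",
    )


def _read_xyzext(path: Path, annotations: Annotations | None) -> Trajectory:
    text = Path(path).read_text().splitlines()
    frames: list[Frame] = []
    topology: Topology | None = None
    i = 0
    while i < len(text):
        if not text[i].strip():
            i += 1
            continue
        try:
            n = int(text[i].strip())
        except ValueError:
            raise ParseError(f"expected atom count, got {text[i]!r}", line=i + 1)
        header = text[i + 1] if i + 1 < len(text) else ""
        fields = dict(
            kv.split("=", 1) for kv in header.split() if "=" in kv
        )
        try:
            time = float(fields["time"])
            box = Box(tuple(float(x) for x in fields["box"].split(",")))
        except (KeyError, ValueError):
            raise ParseError(
                f"malformed header {header!r} (need time=<ps> box=<Lx>,<Ly>,<Lz>)",
                line=i + 2,
            )
        if fields.get("units", "nm") != "nm":
            raise ParseError(f"unsupported units {fields.get('units')!r}", line=i + 2)
        records: list[AtomRecord] = []
        coords = np.empty((n, 3), dtype=float)
        for k in range(n):
            lineno = i + 2 + k
            if lineno >= len(text):
                raise ParseError(
                    f"frame declares {n} atoms but file ends after {k}", line=lineno
                )
            parts = text[lineno].split()
            if len(parts) != 4:
                raise ParseError(f"expected 'name x y z', got {text[lineno]!r}", line=lineno + 1)
            try:
                coords[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise ParseError(f"non-numeric coordinate in {text[lineno]!r}", line=lineno + 1)
            if topology is None:
                records.append(_record_from_xyz_name(parts[0], k + 1, annotations))
        if topology is None:
            topology = Topology(records)
        elif n != len(topology):
            raise ParseError(
                f"frame atom count {n} differs from first frame ({len(topology)})",
                line=i + 1,
            )
        frames.append(Frame(time=time, box=box, coords=coords))
        i += 2 + n
    if topology is None:
        raise ParseError(f"{path} contains no frames")
    return Trajectory(topology, frames)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def read_trajectory(
    path: str | Path,
    format: str,
    annotations: Annotations | None = None,
) -> Trajectory:
    """Read a full trajectory.  PDB frame times are model indices in ps."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format in ("pdb", "gro"):
        if annotations is None:
            raise ValueError(f"{format} input requires species annotations")
        return _read_biotite(path, format, annotations)
    if format == "xyzext":
        return _read_xyzext(path, annotations)
    raise ValueError(f"unknown format {format!r}; expected pdb, gro or xyzext")


def parse_structure(
    path: str | Path,
    format: str,
    annotations: Annotations | None = None,
) -> tuple[Topology, Frame]:
    """Parse a structure file and return its topology and first frame."""
    traj = read_trajectory(path, format, annotations)
    return traj.topology, traj.frames[0]


def write_trajectory(traj: Trajectory, path: str | Path, format: str = "xyzext") -> None:
    """Write a trajectory; output is byte-stable for identical input."""
    if len(traj.frames) == 0:
        raise ValueError("trajectory has no frames to write")
    path = Path(path)
    if format == "xyzext":
        lines: list[str] = []
        names = [_xyz_name(rec) for rec in traj.topology]
        for frame in traj.frames:
            bx, by, bz = frame.box.lengths
            lines.append(str(len(traj.topology)))
            lines.append(
                f"time={frame.time:.4f} box={bx:.4f},{by:.4f},{bz:.4f} units=nm"
            )
            for name, xyz in zip(names, frame.coords):
                lines.append(f"{name} {xyz[0]:.4f} {xyz[1]:.4f} {xyz[2]:.4f}")
        path.write_text("\n".join(lines) + "\n")
        return
    if format == "pdb":
        _write_pdb(traj, path)
        return
    raise ValueError(f"unknown output format {format!r}; expected pdb or xyzext")


def _write_pdb(traj: Trajectory, path: Path) -> None:
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = len(traj.topology)
    arr = struc.AtomArray(n)
    for i, rec in enumerate(traj.topology):
        arr.chain_id[i] = "A"
        arr.res_id[i] = rec.residue_index if rec.residue_index else rec.molecule_id
        arr.res_name[i] = rec.species[:5]
        arr.atom_name[i] = rec.name[:6]
        arr.element[i] = rec.element or rec.name[:1].upper()
        arr.hetero[i] = rec.molecule_class != "protein"
    stack = struc.stack([arr] * len(traj.frames))
    stack.coord = np.stack([f.coords for f in traj.frames]) * 10.0  # nm → Å
    stack.box = np.stack([np.diag(f.box.array) * 10.0 for f in traj.frames])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
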