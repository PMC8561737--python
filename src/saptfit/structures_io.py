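"""Core geometric data model and standard-format I/O.

Density maps are stored as 3D numpy arrays indexed ``data[ix, iy, iz]``
(x fastest in memory-order terms of the convention below): voxel index
``i`` corresponds to model-space position ``origin + i * voxel_size``
(0-based). MRC files whose ``mapc/mapr/maps`` axis-order fields differ
from (1, 2, 3) are transposed on read so that downstream code sees a
single convention.

Atomic models are a lightweight chain/residue/atom hierarchy; PDB reading
and writing is delegated to :mod:`gemmi`, with alternate locations
resolved to the highest-occupancy conformer on read.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "AtomicModel",
    "DensityMap",
    "Sequence",
    "MapFormatError",
    "read_map",
    "write_map",
    "read_model",
    "write_model",
    "model_sequence",
    "read_fasta",
    "write_fasta",
    "THREE_TO_ONE",
    "ELEMENT_Z",
]


class MapFormatError(ValueError):
    """Raised when an MRC header field is malformed."""


# 3-letter -> 1-letter for the 20 standard amino acids; MSE (selenomethionine)
# is treated as methionine, everything else maps to X.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k != "MSE"}

ELEMENT_Z = {
    "H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16, "SE": 34, "FE": 26,
    "MG": 12, "ZN": 30, "CA": 20, "MN": 25, "X": 6,
}

VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclasses.dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray  # (3,) Å
    b_factor: float = 20.0
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")


@dataclasses.dataclass
class Residue:
    seq_num: int
    name: str  # 3-letter code
    atoms: list[Atom] = dataclasses.field(default_factory=list)

    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name.upper(), "X")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclasses.dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = dataclasses.field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)


@dataclasses.dataclass
class AtomicModel:
    chains: list[Chain] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate chain ids: {ids}")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in model")

    def iter_atoms(self) -> Iterator[tuple[Chain, Residue, Atom]]:
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    yield c, r, a

    def coordinates(self) -> np.ndarray:
        """All atom positions as an (n_atoms, 3) array in file order."""
        pts = [a.position for _, _, a in self.iter_atoms()]
        if not pts:
            return np.zeros((0, 3))
        return np.array(pts)

    def atomic_numbers(self) -> np.ndarray:
        return np.array(
            [ELEMENT_Z.get(a.element.upper(), 6) for _, _, a in self.iter_atoms()],
            dtype=float,
        )

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    def center_of_mass(self) -> np.ndarray:
        """Atomic-number-weighted centre of mass (Å)."""
        xyz = self.coordinates()
        w = self.atomic_numbers()
        return (xyz * w[:, None]).sum(axis=0) / w.sum()

    def bounding_radius(self, center: np.ndarray | None = None) -> float:
        """Maximum atom distance from ``center`` (default: centre of mass)."""
        if center is None:
            center = self.center_of_mass()
        d = np.linalg.norm(self.coordinates() - center, axis=1)
        return float(d.max())

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AtomicModel":
        """Return a copy with positions mapped to ``rotation @ x + translation``."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        out = []
        for c in self.chains:
            new_res = [
                Residue(
                    r.seq_num,
                    r.name,
                    [
                        Atom(a.name, a.element, rotation @ a.position + translation,
                             a.b_factor, a.occupancy)
                        for a in r.atoms
                    ],
                )
                for r in c.residues
            ]
            out.append(Chain(c.chain_id, new_res))
        return AtomicModel(out)

    def copy(self) -> "AtomicModel":
        return self.transformed(np.eye(3), np.zeros(3))


@dataclasses.dataclass
class DensityMap:
    """A 3D density grid.

    ``data[i, j, k]`` sits at model-space position
    ``origin + (i, j, k) * voxel_size`` (Å, elementwise).
    """

    data: np.ndarray
    voxel_size: np.ndarray  # (3,) Å
    origin: np.ndarray = None  # (3,) Å
    nominal_resolution: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or min(self.data.shape) < 2:
            raise ValueError("map grid must be 3D with >= 2 voxels per axis")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("map contains non-finite values")
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)
        ).copy()
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be positive on all axes")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_extent(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) corners of the grid in model space (Å)."""
        upper = self.origin + (np.array(self.shape) - 1) * self.voxel_size
        return self.origin.copy(), upper

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of model-space points (Å)."""
        return (np.asarray(xyz, dtype=float) - self.origin) / self.voxel_size

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.voxel_size

    def interpolate(self, xyz: np.ndarray, cval: float = 0.0) -> np.ndarray:
        """Trilinear interpolation at model-space points (n, 3) Å."""
        from scipy.ndimage import map_coordinates

        idx = self.world_to_index(np.atleast_2d(xyz))
        return map_coordinates(
            self.data.astype(float), idx.T, order=1, mode="constant", cval=cval
        )

    def copy(self) -> "DensityMap":
        return DensityMap(
            self.data.copy(), self.voxel_size.copy(), self.origin.copy(),
            self.nominal_resolution,
        )


@dataclasses.dataclass
class Sequence:
    id: str
    residues: str

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        bad = set(self.residues) - VALID_AA
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


# ---------------------------------------------------------------------------
# MRC maps

def read_map(path: str | Path, nominal_resolution: float | None = None) -> DensityMap:
    """Read an MRC2014 map, normalizing axis order to (x, y, z).

    The origin is taken from the ORIGIN header record plus any NxSTART
    offsets; files whose mapc/mapr/maps permute the axes are transposed so
    that voxel values land at the same model-space coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"cannot parse MRC header of {path}: {exc}") from exc

    mapc = m.header_i32(17)
    mapr = m.header_i32(18)
    maps_ = m.header_i32(19)
    if sorted((mapc, mapr, maps_)) != [1, 2, 3]:
        raise MapFormatError(
            f"malformed axis-order fields mapc/mapr/maps = {(mapc, mapr, maps_)}"
        )
    nstart = [m.header_i32(5), m.header_i32(6), m.header_i32(7)]
    # reorder axes (and nstart) to X, Y, Z
    m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    arr = np.array(m.grid, copy=True)
    cell = m.grid.unit_cell
    shape = arr.shape
    if any(s < 2 for s in shape):
        raise MapFormatError(f"grid dimensions {shape} too small (need >= 2 per axis)")
    voxel = np.array([cell.a / shape[0], cell.b / shape[1], cell.c / shape[2]])
    if np.any(voxel <= 0) or not np.all(np.isfinite(voxel)):
        raise MapFormatError(f"malformed cell dimensions {cell.parameters[:3]}")
    # ORIGIN record (MRC2014 words 50-52); nstart offsets add on top
    origin_rec = np.array(
        [m.header_float(50), m.header_float(51), m.header_float(52)]
    )
    if not np.all(np.isfinite(origin_rec)):
        raise MapFormatError("malformed ORIGIN header record")
    perm = [mapc - 1, mapr - 1, maps_ - 1]
    nstart_xyz = np.zeros(3)
    for file_axis, xyz_axis in enumerate(perm):
        nstart_xyz[xyz_axis] = nstart[file_axis]
    origin = origin_rec + nstart_xyz * voxel
    if not np.all(np.isfinite(arr)):
        raise MapFormatError("map contains non-finite voxel values")
    return DensityMap(arr, voxel, origin, nominal_resolution)


def write_map(density_map: DensityMap, path: str | Path) -> None:
    """Write a map as MRC2014 (mode 2, axis order x, y, z)."""
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(density_map.data, dtype=np.float32))
    shape = density_map.shape
    vx = density_map.voxel_size
    m.grid.unit_cell = gemmi.UnitCell(
        shape[0] * vx[0], shape[1] * vx[1], shape[2] * vx[2], 90.0, 90.0, 90.0
    )
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    for word, val in zip((50, 51, 52), density_map.origin):
        m.set_header_float(word, float(val))
    try:
        m.write_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot write map to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# PDB models

def read_model(path: str | Path) -> AtomicModel:
    """Read a PDB file; altlocs resolve to highest occupancy (ties: first)."""
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise ValueError(f"{path}: no models in file")
    chains = []
    for ch in st[0]:
        residues = []
        for res in ch:
            atoms: dict[str, Atom] = {}
            occ: dict[str, float] = {}
            for at in res:
                a = Atom(
                    at.name,
                    at.element.name.upper() or "C",
                    np.array([at.pos.x, at.pos.y, at.pos.z]),
                    at.b_iso,
                    at.occ,
                )
                if at.name not in atoms or at.occ > occ[at.name]:
                    atoms[at.name] = a
                    occ[at.name] = at.occ
            if atoms:
                residues.append(
                    Residue(res.seqid.num, res.name, list(atoms.values()))
                )
        if residues:
            chains.append(Chain(ch.name, residues))
    if not chains:
        raise ValueError(f"{path}: no ATOM records")
    return AtomicModel(chains)


def write_model(model: AtomicModel, path: str | Path) -> None:
    st = gemmi.Structure()
    st.name = Path(path).stem
    gm = gemmi.Model("1")
    for c in model.chains:
        gc = gemmi.Chain(c.chain_id)
        for r in c.residues:
            gr = gemmi.Residue()
            gr.name = r.name
            gr.seqid = gemmi.SeqId(r.seq_num, " ")
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element.capitalize())
                ga.pos = gemmi.Position(*a.position)
                ga.b_iso = a.b_factor
                ga.occ = a.occupancy
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def model_sequence(model: AtomicModel, chain_id: str) -> Sequence:
    """One-letter sequence of a chain, nonstandard residues as X."""
    chain = model.chain(chain_id)  # raises KeyError for unknown chain
    return Sequence(chain_id, "".join(r.one_letter() for r in chain.residues))


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[Sequence]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = "".join(ch for ch in str(rec.seq).upper() if ch != "*")
        seq = "".join(ch if ch in VALID_AA else "X" for ch in seq)
        out.append(Sequence(rec.id, seq))
    return out


def write_fasta(seqs: Iterable[Sequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), 60):
                fh.write(s.residues[i : i + 60] + "\n")
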