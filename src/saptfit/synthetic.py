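"""Synthetic fixtures: toy proteins, symmetric assemblies, homologues, maps.

The generators emulate the study system for this pipeline: double-ring
multimeric assemblies with cyclic symmetry (a GroEL-like 7-fold, two-ring
geometry), simulated density at 3-18 Å with optional voxel noise, and
homologue libraries at controlled sequence identity and coordinate
perturbation. Every generator is a pure function of its arguments and a
mandatory integer seed.

Toy subunits are pseudo-proteins: a self-avoiding Cα random walk with
3.8 Å steps, with N, C, O and Cβ atoms added by ideal local geometry and a
random standard-residue sequence. Side chains beyond Cβ are not built;
fitting here operates at ≥3 Å where they contribute no visible detail.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .density import simulate_density
from .structures_io import (
    Atom,
    AtomicModel,
    Chain,
    DensityMap,
    ONE_TO_THREE,
    Residue,
    Sequence,
    write_fasta,
    write_map,
    write_model,
)

__all__ = [
    "AssemblySpec",
    "make_toy_subunit",
    "make_assembly",
    "make_homologue",
    "make_noisy_map",
    "ring_transforms",
    "emit_test_case",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
CA_STEP = 3.8  # Å, ideal consecutive Cα distance
MIN_NONBONDED = 4.0  # Å, self-avoidance radius of the Cα walk


@dataclasses.dataclass
class AssemblySpec:
    n_fold: int
    n_rings: int
    ring_radius: float  # Å
    ring_offset: float  # Å axial separation between rings
    subunit: AtomicModel
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fold < 1 or self.n_rings not in (1, 2):
            raise ValueError("n_fold >= 1 and n_rings in {1, 2} required")
        if self.ring_radius <= self.subunit.bounding_radius():
            raise ValueError(
                "ring_radius must exceed the subunit bounding radius "
                f"({self.subunit.bounding_radius():.1f} Å)"
            )


def make_toy_subunit(n_res: int, seed: int) -> AtomicModel:
    """Deterministic pseudo-protein with main chain + Cβ atoms.

    Cα positions form a self-avoiding random walk (3.8 Å steps, non-bonded
    Cα-Cα distance kept >= 3 Å by rejection); the remaining atoms are set
    by idealized local frames.
    """
    if n_res < 5:
        raise ValueError("n_res must be >= 5")
    rng = np.random.default_rng(seed)
    ca = _self_avoiding_walk(n_res, rng)
    seq = "".join(rng.choice(list(AA20)) for _ in range(n_res))
    return _build_model_from_trace(ca, seq, chain_id="A")


def _self_avoiding_walk(n: int, rng: np.random.Generator) -> np.ndarray:
    # confinement radius sized for a compact globule at ~4 Å Cα spacing
    r_conf = 3.4 * n ** (1.0 / 3.0)
    pts = [np.zeros(3)]
    direction = _random_unit(rng)
    while len(pts) < n:
        center = np.mean(pts, axis=0)
        for attempt in range(300):
            step = direction + 1.4 * _random_unit(rng)
            step /= np.linalg.norm(step)
            cand = pts[-1] + CA_STEP * step
            if np.linalg.norm(cand - center) > r_conf:
                continue
            prev = np.array(pts[:-1]) if len(pts) > 1 else np.zeros((0, 3))
            if prev.size == 0 or np.linalg.norm(prev - cand, axis=1).min() >= MIN_NONBONDED:
                pts.append(cand)
                direction = step
                break
        else:  # backtrack on dead ends
            pts.pop()
            if not pts:
                pts = [np.zeros(3)]
            direction = _random_unit(rng)
    pts = np.array(pts)
    return pts - pts.mean(axis=0)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _build_model_from_trace(ca: np.ndarray, seq: str, chain_id: str) -> AtomicModel:
    n = len(ca)
    residues = []
    for i in range(n):
        prev_ca = ca[i - 1] if i > 0 else ca[i] - np.array([CA_STEP, 0, 0])
        next_ca = ca[i + 1] if i < n - 1 else ca[i] + np.array([CA_STEP, 0, 0])
        u = _safe_unit(ca[i] - prev_ca)
        v = _safe_unit(next_ca - ca[i])
        # local frame: backbone direction and a perpendicular
        w = _safe_unit(np.cross(u, v), fallback=np.array([0.0, 0.0, 1.0]))
        bis = _safe_unit(u - v, fallback=np.array([0.0, 1.0, 0.0]))
        aa = seq[i]
        atoms = [
            Atom("N", "N", ca[i] - 1.46 * u + 0.3 * w),
            Atom("CA", "C", ca[i]),
            Atom("C", "C", ca[i] + 1.52 * v + 0.3 * w),
            Atom("O", "O", ca[i] + 1.52 * v + 0.3 * w + 1.23 * bis),
        ]
        if aa != "G":
            atoms.append(Atom("CB", "C", ca[i] + 1.53 * _safe_unit(bis + 0.8 * w)))
        residues.append(Residue(i + 1, ONE_TO_THREE[aa], atoms))
    return AtomicModel([Chain(chain_id, residues)])


def _safe_unit(v: np.ndarray, fallback: np.ndarray | None = None) -> np.ndarray:
    nrm = np.linalg.norm(v)
    if nrm < 1e-9:
        return fallback if fallback is not None else np.array([1.0, 0.0, 0.0])
    return v / nrm


def ring_transforms(spec: AssemblySpec) -> list[tuple[np.ndarray, np.ndarray]]:
    """Generating (rotation, translation) for each subunit copy.

    Copies sit on ``n_rings`` circles of radius ``ring_radius`` about the z
    axis, rings separated axially by ``ring_offset``; copy i of a ring is
    the subunit rotated by i * 360/n_fold about z (about its own centre of
    mass) and moved to its ring position. The second ring is additionally
    flipped 180° about x, mimicking the back-to-back double-ring packing.
    """
    com = spec.subunit.center_of_mass()
    out = []
    for ring in range(spec.n_rings):
        z = (ring - (spec.n_rings - 1) / 2.0) * spec.ring_offset
        flip = _rot_x(np.pi) if ring == 1 else np.eye(3)
        for i in range(spec.n_fold):
            ang = 2.0 * np.pi * i / spec.n_fold
            rot = _rot_z(ang) @ flip
            center = np.array(
                [spec.ring_radius * np.cos(ang), spec.ring_radius * np.sin(ang), z]
            )
            # x -> rot @ (x - com) + center, expressed as rot @ x + t
            out.append((rot, center - rot @ com))
    return out


def _rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])


def _rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0, 0], [0, c, -s], [0, s, c]])


def make_assembly(
    spec: AssemblySpec,
) -> tuple[AtomicModel, list[tuple[np.ndarray, np.ndarray]]]:
    """Build the symmetric assembly and return it with the true transforms.

    Each copy's transform maps subunit coordinates x to
    ``rot @ (x - com) + com + t`` where com is the subunit centre of mass;
    the returned translation is chosen so the transform composes as
    ``rot @ x + t``.
    """
    transforms = []
    chains = []
    ids = _chain_ids(spec.n_fold * spec.n_rings)
    for k, (rot, t) in enumerate(ring_transforms(spec)):
        copy = spec.subunit.transformed(rot, t)
        chains.append(Chain(ids[k], copy.chains[0].residues))
        transforms.append((rot, t))
    assembly = AtomicModel(chains)
    _check_overlap(assembly, spec)
    return assembly, transforms


def _chain_ids(n: int) -> list[str]:
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"
    return [alphabet[i % len(alphabet)] * (i // len(alphabet) + 1) for i in range(n)]


def _check_overlap(assembly: AtomicModel, spec: AssemblySpec) -> None:
    from scipy.spatial import cKDTree

    coords = [
        np.array([a.position for r in c.residues for a in r.atoms])
        for c in assembly.chains
    ]
    for i in range(len(coords)):
        tree = cKDTree(coords[i])
        for j in range(i + 1, len(coords)):
            d, _ = tree.query(coords[j], k=1)
            if d.min() < 1.5:
                raise ValueError(
                    f"assembly spec produces overlapping chains {i} and {j} "
                    f"(min distance {d.min():.2f} Å)"
                )


def make_homologue(
    subunit: AtomicModel,
    target_identity: float,
    coord_noise: float,
    seed: int,
    delete_terminal: int = 0,
) -> tuple[AtomicModel, Sequence]:
    """Derive a homologue at a controlled identity and coordinate error.

    Exactly ``round((100 - target_identity)/100 * n_res)`` residues are
    mutated to random different amino acids; all atom positions receive
    isotropic Gaussian noise of sd ``coord_noise`` Å. ``delete_terminal``
    trims that many C-terminal residues to emulate domain-only homologues.
    """
    if not 0.0 < target_identity <= 100.0:
        raise ValueError("target_identity must be in (0, 100]")
    rng = np.random.default_rng(seed)
    chain = subunit.chains[0]
    n_res = len(chain.residues)
    n_keep = n_res - int(delete_terminal)
    n_mut = int(round((100.0 - target_identity) / 100.0 * n_keep))
    mutate = set(rng.choice(n_keep, size=n_mut, replace=False).tolist())
    residues = []
    seq_chars = []
    for i, res in enumerate(chain.residues[:n_keep]):
        aa = res.one_letter()
        if i in mutate:
            choices = [c for c in AA20 if c != aa]
            aa = str(rng.choice(choices))
        seq_chars.append(aa)
        atoms = []
        for a in res.atoms:
            if aa == "G" and a.name == "CB":
                continue
            noise = rng.normal(scale=coord_noise, size=3) if coord_noise > 0 else 0.0
            atoms.append(Atom(a.name, a.element, a.position + noise, a.b_factor, a.occupancy))
        if i in mutate and aa != "G" and res.atom("CB") is None and res.atom("CA") is not None:
            pass  # mutated from GLY: no Cβ to build without full geometry
        residues.append(Residue(res.seq_num, ONE_TO_THREE[aa], atoms))
    hom = AtomicModel([Chain(chain.chain_id, residues)])
    return hom, Sequence("homologue", "".join(seq_chars))


def make_noisy_map(
    model: AtomicModel,
    resolution: float,
    noise_sd_fraction: float,
    seed: int,
    grid: DensityMap | None = None,
    voxel_size: float | None = None,
) -> DensityMap:
    """Simulated density plus additive Gaussian voxel noise.

    Noise sd is ``noise_sd_fraction`` times the sd of the noise-free map;
    the result is deterministic under ``seed``.
    """
    if noise_sd_fraction < 0:
        raise ValueError("noise_sd_fraction must be >= 0")
    clean = simulate_density(model, resolution, grid=grid, voxel_size=voxel_size)
    if noise_sd_fraction == 0:
        return clean
    rng = np.random.default_rng(seed)
    sd = float(clean.data.std())
    noisy = clean.data + rng.normal(scale=noise_sd_fraction * sd, size=clean.shape)
    return DensityMap(noisy, clean.voxel_size, clean.origin, resolution)


def emit_test_case(
    out_dir: str | Path,
    n_res: int = 50,
    n_fold: int = 7,
    n_rings: int = 2,
    ring_radius: float = 28.0,
    ring_offset: float = 30.0,
    resolution: float = 8.0,
    noise_sd_fraction: float = 0.0,
    identities: tuple[float, ...] = (100.0, 70.0, 40.0),
    seed: int = 0,
) -> dict:
    """Write a complete test case: map, target FASTA, library, truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subunit = make_toy_subunit(n_res, seed)
    spec = AssemblySpec(n_fold, n_rings, ring_radius, ring_offset, subunit, seed)
    assembly, transforms = make_assembly(spec)
    density = make_noisy_map(assembly, resolution, noise_sd_fraction, seed + 1)
    write_map(density, out_dir / "map.mrc")
    write_model(subunit, out_dir / "subunit.pdb")
    from .structures_io import model_sequence

    target = model_sequence(subunit, "A")
    target = Sequence("target", target.residues)
    write_fasta([target], out_dir / "target.fasta")
    lib_dir = out_dir / "library"
    lib_dir.mkdir(exist_ok=True)
    lib_seqs = []
    for k, ident in enumerate(identities):
        noise = 0.0 if ident == 100.0 else 0.5
        hom, seq = make_homologue(subunit, ident, noise, seed + 10 + k)
        name = f"hom{int(ident)}_A"
        write_model(hom, lib_dir / f"{name}.pdb")
        lib_seqs.append(Sequence(name, seq.residues))
    write_fasta(lib_seqs, lib_dir / "library.fasta")
    truth = {
        "resolution": resolution,
        "n_copies": n_fold * n_rings,
        "transforms": [
            {"rotation": r.tolist(), "translation": t.tolist()}
            for r, t in transforms
        ],
        "subunit_centers": [
            (r @ subunit.center_of_mass() + t).tolist() for r, t in transforms
        ],
        "seed": seed,
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth
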