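"""Shared fixtures: toy subunits, placed single-copy maps, ring assemblies.

Everything is generated programmatically with fixed seeds; session scope
keeps the expensive density simulations to one evaluation each.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from saptfit.density import simulate_density
from saptfit.synthetic import AssemblySpec, make_assembly, make_toy_subunit


@pytest.fixture(scope="session")
def subunit():
    """50-residue compact pseudo-protein, seed 1."""
    return make_toy_subunit(50, seed=1)


@pytest.fixture(scope="session")
def single_copy_case(subunit):
    """Subunit placed at a known rotation/translation with its 8 Å map."""
    com = subunit.center_of_mass()
    rotation = Rotation.from_euler("zyx", [30.0, 10.0, -20.0], degrees=True).as_matrix()
    center = com + np.array([5.0, -3.0, 2.0])
    placed = subunit.transformed(rotation, center - rotation @ com)
    density = simulate_density(placed, 8.0, voxel_size=2.0, pad=12.0)
    return {
        "model": subunit,
        "placed": placed,
        "rotation": rotation,
        "center": center,
        "map": density,
        "resolution": 8.0,
    }


@pytest.fixture(scope="session")
def ring7_case(subunit):
    """7-fold single-ring assembly with its 8 Å map and true transforms."""
    spec = AssemblySpec(
        n_fold=7, n_rings=1, ring_radius=28.0, ring_offset=30.0,
        subunit=subunit, rng_seed=1,
    )
    assembly, transforms = make_assembly(spec)
    density = simulate_density(assembly, 8.0, voxel_size=2.0, pad=8.0)
    return {
        "subunit": subunit,
        "assembly": assembly,
        "transforms": transforms,
        "map": density,
        "resolution": 8.0,
    }


@pytest.fixture(scope="session")
def double_ring_case():
    """14-subunit double-ring assembly (7-fold, two rings) at 8 Å."""
    subunit = make_toy_subunit(50, seed=1)
    spec = AssemblySpec(
        n_fold=7, n_rings=2, ring_radius=28.0, ring_offset=30.0,
        subunit=subunit, rng_seed=1,
    )
    assembly, transforms = make_assembly(spec)
    density = simulate_density(assembly, 8.0, voxel_size=2.0, pad=10.0)
    return {
        "subunit": subunit,
        "assembly": assembly,
        "transforms": transforms,
        "map": density,
        "resolution": 8.0,
    }
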