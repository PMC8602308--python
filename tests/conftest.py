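"""Shared fixtures: every test system is generated, never loaded."""

import numpy as np
import pytest

from tsforge import conformers, q2mm
from tsforge.synthfix import (
    ToySpec,
    make_catalysis_fixture,
    make_three_well_system,
    make_toy_ts_system,
    make_validation_fixture,
    mock_qm_reference,
)


@pytest.fixture(scope="session")
def toy_system():
    """Small minimized toy TS chain with its ground-truth force field."""
    return make_toy_ts_system(ToySpec(n_rotatable=3, seed=7))


@pytest.fixture(scope="session")
def toy_reference(toy_system):
    s, ff = toy_system
    return mock_qm_reference(s, ff, seed=7)


@pytest.fixture(scope="session")
def three_well():
    return make_three_well_system()


@pytest.fixture(scope="session")
def catalysis():
    return make_catalysis_fixture(seed=13)


@pytest.fixture(scope="session")
def validation_records():
    return make_validation_fixture(
        n=77,
        mismatch_ids=list(range(1, 12)),
        exclusion_ids=list(range(73, 78)),
        seed=0,
    )


def finite_difference_gradient(system, coords, step=1e-6):
    """Central-difference gradient of a CompiledSystem, for oracles."""
    g = np.zeros_like(coords)
    c = coords.copy()
    for a in range(coords.shape[0]):
        for m in range(3):
            c[a, m] += step
            ep = system.energy_and_gradient(c)[0]
            c[a, m] -= 2 * step
            em = system.energy_and_gradient(c)[0]
            c[a, m] += step
            g[a, m] = (ep - em) / (2 * step)
    return g


def true_minima_from_scan(s, ff, step_deg=1):
    """1°-resolution torsion-scan oracle returning deduplicated true minima.

    Every grid start is minimized; stationary points that are not minima
    (a symmetric start can relax onto a saddle and stall there with zero
    gradient) are rejected by checking that no Hessian eigenvalue is
    significantly negative beyond the six rigid-body modes.
    """
    from tsforge.mmcore import CompiledSystem, minimize_compiled

    cs = CompiledSystem(s, ff)
    quads = conformers.rotatable_torsions(s)
    assert len(quads) == 1, "scan oracle assumes a single rotatable bond"
    (_, i, j, _) = quads[0]
    moved = conformers._rotation_partition(s)[(i, j)]
    pool = []
    for deg in range(0, 360, step_deg):
        c = s.coords.copy()
        conformers._rotate_about_bond(c, i, j, moved, float(deg))
        cmin, e, _, converged, _ = minimize_compiled(cs, c)
        if converged:
            pool.append((e, cmin))
    ens = conformers.dedupe(pool, label="scan")
    minima = []
    for e, c in ens.conformers:
        w = np.linalg.eigvalsh(cs.hessian(c))
        if w[0] > -1e-3:
            minima.append((e, c))
    return minima
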