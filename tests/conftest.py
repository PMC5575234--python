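"""Shared fixtures and independent oracles.

The dense design-matrix builder below constructs P = FQ row by row from
first principles (explicit DFT matrix, probe diagonal, crop selectors);
it never calls the package's FFT-based operator and serves as the
independent reference for operator, likelihood and gradient tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.linalg import dft

from cryoptycho.forward import ForwardOperator, ObjectField
from cryoptycho.geometry import ComplexField2D, ScanPlan
from cryoptycho.probes import ProbeField


def dense_design_matrix(
    probe_values: np.ndarray,
    positions: np.ndarray,
    object_shape: tuple[int, int],
) -> np.ndarray:
    """Explicit (K*M, N) design matrix: unitary 2D DFT x diag(psi) x crop."""
    m1, m2 = probe_values.shape
    n1, n2 = object_shape
    big_n = n1 * n2
    big_m = m1 * m2
    f2d = np.kron(dft(m1), dft(m2)) / np.sqrt(big_m)  # unitary, row-major
    blocks = []
    for r, c in positions:
        crop = np.zeros((big_m, big_n))
        for a in range(m1):
            for b in range(m2):
                crop[a * m2 + b, (r + a) * n2 + (c + b)] = 1.0
        blocks.append(f2d @ (np.diag(probe_values.ravel()) @ crop))
    return np.vstack(blocks)


def make_probe(values: np.ndarray, pixel_size: float = 1.0) -> ProbeField:
    """Wrap raw complex values as a ProbeField (normalization from data)."""
    power = float(np.sum(np.abs(values) ** 2))
    return ProbeField(
        field=ComplexField2D(values, pixel_size),
        total_electrons=power,
        aperture_half_angle=1e9,  # free-form test probes: no aperture claim
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_operator(rng):
    """4x4 probe on an 8x8 object, 4 scan positions."""
    psi = rng.standard_normal((4, 4)) + 1j * rng.standard_normal((4, 4))
    probe = make_probe(psi)
    scan = ScanPlan(
        positions=np.array([[0, 0], [2, 1], [4, 4], [1, 3]]), step=2
    )
    return ForwardOperator(probe=probe, scanplan=scan, object_shape=(8, 8))


@pytest.fixture
def tiny_object(rng) -> np.ndarray:
    t = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
    return 0.5 * t


@pytest.fixture
def tiny_counts(tiny_operator, tiny_object, rng) -> np.ndarray:
    return rng.poisson(50.0 * tiny_operator.intensities(tiny_object)).astype(
        float
    )
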