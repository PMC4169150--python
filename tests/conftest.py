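"""Shared fixtures: small maps/designs and a scaled-down simulated study."""

import numpy as np
import pandas as pd
import pytest

import dynqtl as dq


@pytest.fixture(scope="session")
def preset():
    """Default study preset (map, crossing design, calibrated architecture)."""
    return dq.default_study_preset()


@pytest.fixture(scope="session")
def small_map():
    return dq.GeneticMap.uniform({f"C{i}": 10 for i in range(1, 6)}, 100.0)


@pytest.fixture(scope="session")
def small_design():
    return dq.CrossingDesign(
        ["P1", "P2", "P3", "P4"],
        [("F1", "P1", "P2", 50), ("F2", "P3", "P4", 50)])


@pytest.fixture(scope="session")
def tiny_study():
    """Scaled-down preset study (110 lines, 176 markers) for smoke tests."""
    gmap, design, arch = dq.default_study_preset(markers_per_chromosome=8)
    design = dq.CrossingDesign(
        design.parents,
        [(f, a, b, n) for (f, a, b, _), n in
         zip(design.families, (25, 25, 30, 30))])
    return dq.simulate_study(seed=11, gmap=gmap, design=design, arch=arch)


def make_genotypes(calls, families, markers=None):
    """Build a GenotypeMatrix from a raw array and a family label list."""
    calls = np.asarray(calls, dtype=float)
    n, m = calls.shape
    lines = pd.Index([f"L{i:03d}" for i in range(n)])
    markers = pd.Index(markers if markers is not None
                       else [f"M{j:02d}" for j in range(m)])
    fam = pd.Series(list(families), index=lines)
    return dq.GenotypeMatrix(calls, lines, markers, fam)


@pytest.fixture
def make_geno():
    return make_genotypes
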