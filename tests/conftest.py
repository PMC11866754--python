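"""Shared fixtures: converged mean-field contexts and small trained models.

Everything is generated at test time; quantum fixtures use the water
monomer/dimer geometries in minimal or small double-zeta bases so the full
pipeline runs in seconds.
"""

import numpy as np
import pytest

from osvnet.geometry import Geometry
from osvnet.models import PairMLPRegressor
from osvnet.mp2 import lmo_pair_energies
from osvnet.scf import localize_occupied, run_mean_field
from osvnet.synthetic import WATER_DIMER, WATER_MONOMER


@pytest.fixture(scope="session")
def water_sto3g():
    scf = run_mean_field(WATER_MONOMER, "sto-3g")
    lmos = localize_occupied(scf)
    return scf, lmos


@pytest.fixture(scope="session")
def water_631g():
    scf = run_mean_field(WATER_MONOMER, "6-31g")
    lmos = localize_occupied(scf)
    return scf, lmos


@pytest.fixture(scope="session")
def dimer_sto3g():
    scf = run_mean_field(WATER_DIMER, "sto-3g")
    lmos = localize_occupied(scf)
    return scf, lmos


@pytest.fixture(scope="session")
def water_labels(water_sto3g):
    return lmo_pair_energies(*water_sto3g)


@pytest.fixture(scope="session")
def h2_sto3g():
    geom = Geometry(("H", "H"), np.array([[0.0, 0.0, 0.0],
                                          [0.0, 0.0, 0.7408481486]]))
    return run_mean_field(geom, "sto-3g", frozen_core=False)


@pytest.fixture(scope="session")
def tiny_base():
    """A small trained base regressor for fine-tuning/analysis tests."""
    rng = np.random.default_rng(42)
    X = rng.normal(size=(400, 24))
    y = 0.01 * np.tanh(X.sum(axis=1) / 4.0) - 0.02
    est = PairMLPRegressor(n_hidden_layers=3, hidden_width=20,
                           schedule=((60, 1e-3), (20, 1e-4)),
                           batch_size=32, seed=3)
    est.fit(X, y)
    return est, X, y


@pytest.fixture(scope="session")
def reference_base_256():
    """A 10x50 net on 256 inputs (the reference architecture), minimally
    trained — used for parameter accounting and identity contracts."""
    rng = np.random.default_rng(0)
    X = rng.normal(size=(8, 256))
    y = rng.normal(size=8) * 0.01
    est = PairMLPRegressor(schedule=((1, 1e-3),), batch_size=8,
                           validation_fraction=0.0, seed=1)
    est.fit(X, y)
    return est
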