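"""Shared fixtures: synthetic structures with known disorder and their fits.

Fits are session-scoped because they are the expensive part of the suite;
several test modules (recovery, invariants, output writers) share them.
"""

from __future__ import annotations

import numpy as np
import pytest

import echt
from echt.optimize import OptimizerConfig, fit_echt, fit_isotropic_mode

# no Gly/Ala/Pro, one gamma atom each: 6 heavy atoms per residue
SEQ = ["SER", "VAL", "THR", "LEU", "ASP", "PHE"]

THREE_LEVELS = {"levels": ["chain", "ss", "residue", "atomic"]}
FOUR_LEVELS = {"levels": ["chain", "ss", "residue", "backbone_sidechain", "atomic"]}


def make_fixture(spec, n_residues=8, scheme_cfg=None, noise_b=0.0, seed=0,
                 isotropic_output=False):
    atoms = echt.make_peptide(n_residues, sequence=SEQ, conformation="helix")
    scheme = echt.parse_custom_levels(scheme_cfg, atoms)
    atoms, truth = echt.make_ground_truth(
        atoms, scheme, spec, noise_b=noise_b, seed=seed,
        isotropic_output=isotropic_output,
    )
    return atoms, truth


@pytest.fixture(scope="session")
def helix_atoms():
    return echt.make_peptide(8, sequence=SEQ, conformation="helix")


@pytest.fixture(scope="session")
def chain_fixture():
    """Single chain-level component, mean B = 10 A^2, noise-free."""
    return make_fixture([{"level": "chain", "group": "all", "b": 10.0}],
                        scheme_cfg=THREE_LEVELS)


@pytest.fixture(scope="session")
def chain_fit(chain_fixture):
    atoms, truth = chain_fixture
    scheme = echt.parse_custom_levels(THREE_LEVELS, atoms)
    model, trace = fit_echt(atoms, scheme, OptimizerConfig())
    return atoms, truth, model, trace


@pytest.fixture(scope="session")
def hotspot_fixture():
    """Chain level 8 A^2 plus one hot residue (+20 A^2 on residue index 3)."""
    return make_fixture(
        [{"level": "chain", "group": "all", "b": 8.0},
         {"level": "residue", "group": 3, "b": 20.0}],
    )


@pytest.fixture(scope="session")
def hotspot_fit(hotspot_fixture):
    atoms, truth = hotspot_fixture
    scheme = echt.build_default_scheme(atoms)
    model, trace = fit_echt(atoms, scheme, OptimizerConfig())
    return atoms, truth, model, trace


@pytest.fixture(scope="session")
def overparam_fit(chain_fixture):
    """The chain-only fixture fitted with an extra backbone/sidechain level."""
    atoms, truth = chain_fixture
    scheme = echt.parse_custom_levels(FOUR_LEVELS, atoms)
    model, trace = fit_echt(atoms, scheme, OptimizerConfig())
    return atoms, truth, model, trace


@pytest.fixture(scope="session")
def iso_fit():
    """Chain-only fixture reduced to i-ADPs, fitted in isotropic mode."""
    atoms, truth = make_fixture([{"level": "chain", "group": "all", "b": 10.0}],
                                scheme_cfg=THREE_LEVELS, isotropic_output=True)
    scheme = echt.parse_custom_levels(THREE_LEVELS, atoms)
    model, trace = fit_isotropic_mode(atoms, scheme, OptimizerConfig())
    return atoms, truth, model, trace


@pytest.fixture(scope="session")
def split_fit():
    """Two-level fixture with an exact 75/25 chain/residue split of total B."""
    cfg = {"levels": ["chain", "residue", "atomic"]}
    atoms, truth = make_fixture(
        [{"level": "chain", "group": "all", "b": 7.5},
         {"level": "residue", "group": 3, "b": 15.0}],
        n_residues=6,
        scheme_cfg=cfg,
    )
    scheme = echt.parse_custom_levels(cfg, atoms)
    model, trace = fit_echt(atoms, scheme, OptimizerConfig())
    return atoms, truth, model, trace


@pytest.fixture(scope="session")
def all_fits(chain_fit, hotspot_fit, overparam_fit, iso_fit):
    return {
        "chain": chain_fit,
        "hotspot": hotspot_fit,
        "overparam": overparam_fit,
        "iso": iso_fit,
    }


def random_valid_tls(seed: int, n_atoms: int = 5):
    """A random physically-valid small-libration TLS set plus atom positions."""
    from echt import adp
    from echt.tls import TLSMatrices

    rng = np.random.default_rng(seed)
    a = rng.normal(size=(6, 10)) * 0.05
    cov = a @ a.T
    d = np.diag([0.08] * 3 + [1.0] * 3)  # keep |L| << 0.01 rad^2
    cov = d @ cov @ d
    l6 = adp.from_matrix(cov[:3, :3])
    t6 = adp.from_matrix(cov[3:, 3:])
    s = cov[:3, 3:]
    s = s - np.eye(3) * np.trace(s) / 3.0
    m = TLSMatrices(T=t6, L=l6, S=s.reshape(-1)[:8], origin=rng.normal(size=3))
    pos = m.origin + rng.normal(scale=4.0, size=(n_atoms, 3))
    return m, pos
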