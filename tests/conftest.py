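"""Shared fixtures: cluster geometries, kernels and noiseless study runs.

Heavy objects (S-value kernels, full-scale dose maps, the optimization
report) are session-scoped so the whole suite builds them once.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from spheradose.geometry import SpheroidConfig, build_cluster
from spheradose.pipeline import (ScenarioConfig, reference_decay_profiles,
                                 run_optimize, scenario_drugs)
from spheradose.survival import (KernelCache, RadiobiologicalParams,
                                 compute_doses, expected_sf)
from spheradose.synthetic_data import ProfileGeneratorParams


@pytest.fixture(scope="session")
def study_geo() -> SpheroidConfig:
    """The study geometry: 6/3-um cells, 12-um lattice, 200-um spheroid in a
    350-um cluster."""
    return SpheroidConfig()


@pytest.fixture(scope="session")
def lattice(study_geo):
    return build_cluster(study_geo)


@pytest.fixture(scope="session")
def kernels(study_geo):
    return KernelCache(study_geo)


@pytest.fixture(scope="session")
def small_geo() -> SpheroidConfig:
    """A desk-scale cluster for direct pairwise oracles and grid searches."""
    return SpheroidConfig(spheroid_radius=60.0, cluster_radius=110.0)


@pytest.fixture(scope="session")
def small_lattice(small_geo):
    return build_cluster(small_geo)


@pytest.fixture(scope="session")
def small_kernels(small_geo):
    return KernelCache(small_geo)


@pytest.fixture(scope="session")
def noiseless_config() -> ScenarioConfig:
    return ScenarioConfig(generator=ProfileGeneratorParams(noise_cv=0.0))


@pytest.fixture(scope="session")
def reference_profiles(noiseless_config):
    """Noiseless full-amount cumulated-decay profiles (antibody, liposome
    with and without preirradiation) at 13.75 kBq/mL."""
    return reference_decay_profiles(noiseless_config, seed=7)


@pytest.fixture(scope="session")
def lq_params() -> RadiobiologicalParams:
    return RadiobiologicalParams()


@pytest.fixture(scope="session")
def monotherapy_sfs(noiseless_config, reference_profiles, lattice, kernels,
                    lq_params):
    """Expected SFs of the two monotherapies with and without daughters
    retained in the spheroid."""
    out = {}
    for label, f_lip in (("antibody", 0.0), ("liposome", 1.0)):
        for daughters in (True, False):
            drugs = scenario_drugs(noiseless_config, reference_profiles, f_lip,
                                   antibody_daughters_in_spheroid=daughters,
                                   liposome_daughters_in_spheroid=daughters)
            dm = compute_doses(lattice, drugs, kernels)
            out[(label, daughters)] = expected_sf(dm, lq_params).expected_sf
    return out


@pytest.fixture(scope="session")
def optimization_report(noiseless_config, tmp_path_factory):
    """Full-scale optimization of the three therapies (noiseless profiles)."""
    outdir = tmp_path_factory.mktemp("optimize")
    return run_optimize(noiseless_config, seed=7, outdir=outdir)


@pytest.fixture(scope="session")
def cocktail_dosemap(noiseless_config, reference_profiles, lattice, kernels):
    """Dose map of the 50/50 cocktail under the default daughter assumptions."""
    drugs = scenario_drugs(noiseless_config, reference_profiles, 0.5)
    return compute_doses(lattice, drugs, kernels)
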