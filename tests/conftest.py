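import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from siqchip import (Reaction, SampleManifest, ReactionVolumes, Scenario,
                     Species, ToyGenome, synthetic)


@pytest.fixture(scope="session")
def example_manifest_path() -> str:
    return str(Path(__file__).resolve().parent.parent
               / "examples" / "manifest_h3k27me3.yaml")


@pytest.fixture
def paper_ip_manifest() -> SampleManifest:
    """The published H3K27me3 IP bench numbers (rho unmeasured, left at 1)."""
    return SampleManifest(mapped_reads=37_298_373, library_sequenced=20,
                          library_total=856, pcr_cycles=11,
                          ip_mass_total=24.2, mass_into_library=10,
                          bead_capture_yield=1.0, name="ip")


@pytest.fixture
def unit_manifest() -> SampleManifest:
    """A manifest in which every scaling factor is exactly 1."""
    return SampleManifest(mapped_reads=1000, library_sequenced=5,
                          library_total=5, pcr_cycles=0, ip_mass_total=7,
                          mass_into_library=7, bead_capture_yield=1.0)


@pytest.fixture
def volumes() -> ReactionVolumes:
    return ReactionVolumes(total_volume=110, input_aliquot=10)


@pytest.fixture
def figure_reaction() -> Reaction:
    """Four-component depletion system: target, two off-targets, inert pool.

    Antibody 6 uM; K_B = 11, 0.1, 0.5 1/uM; off-target totals 0.3 uM.
    """
    return Reaction(6.0, [
        Species("target", 10.7, 11.0),
        Species("offtarget2", 0.3, 0.1),
        Species("offtarget3", 0.3, 0.5),
        Species("inert", 0.0, 0.0),
    ])


@pytest.fixture(scope="session")
def toy_genome() -> ToyGenome:
    return ToyGenome(sizes={"chr1": 1_000_000, "chr2": 1_000_000},
                     interval_width=10_000)


def _random_distribution(rng: np.random.Generator, genome: ToyGenome) -> dict:
    parts = {c: rng.random(genome.n_bins(c)) + 0.1 for c in genome.chroms}
    total = sum(p.sum() for p in parts.values())
    return {c: p / total for c, p in parts.items()}


@pytest.fixture(scope="session")
def recovery_scenario(toy_genome) -> Scenario:
    """Three binding species with smooth random genomic distributions."""
    rng = np.random.default_rng(2024)
    reaction = Reaction(6.0, [Species("target", 10.7, 11.0),
                              Species("offtarget2", 0.3, 0.1),
                              Species("offtarget3", 0.3, 0.5)])
    dists = {name: _random_distribution(rng, toy_genome)
             for name in ("target", "offtarget2", "offtarget3")}
    return Scenario(reaction=reaction, genome=toy_genome, distributions=dists)


@pytest.fixture(scope="session")
def generated_pair(recovery_scenario):
    """The same scenario sampled at two depths (shared by several tests)."""
    return {depth: synthetic.generate(recovery_scenario, depth=depth, seed=42)
            for depth in (10_000, 100_000)}
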