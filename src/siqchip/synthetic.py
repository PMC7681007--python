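"""Ground-truth fixture generator: chromatin, equilibrium IP, fragment files.

A scenario specifies a toy genome (chromosome sizes and an interval
width), a competitive binding reaction (antibody load, species totals and
binding constants) and, per chromatin species, a genomic distribution
``o_i(x)`` -- the fraction of that species' fragments starting in
interval x. The generator

1. solves the binding isotherm for the per-species bound concentrations,
2. samples input fragments with species/interval probabilities
   proportional to ``S_i_t * o_i(x)`` and IP fragments proportional to
   ``S_i_b * o_i(x)`` (a multinomial over species-by-interval cells),
3. draws fragment lengths from a truncated discrete Gaussian
   (default mean 150 bp, sd 20, support [50, 500] -- a typical sonicated
   mononucleosome-scale library),
4. records every expectation in a ledger, including the exact predicted
   efficiency track, and fabricates an experiment manifest whose alpha
   equals the ledger's true value.

Because sampling weights are normalized within each sample, the true
alpha is fixed by the sampled depths and the bound-to-total concentration
ratio:

    alpha_true = (depth_input / depth_ip) * (sum_i S_i_b / sum_i S_i_t)

The fabricated manifest realizes this alpha purely through the reaction
volume factor (all other factor ratios are set to 1), so running the
alpha module on it reproduces the ledger value. Counts and concentrations
are linked by an arbitrary fixed (V - v_in) * N_A scale: only fractions
drive the sampling, never absolute molar amounts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .alpha import ReactionVolumes, SampleManifest, dump_manifest
from .isotherm import Reaction, predict_efficiency, solve_binding
from .tracks import FragmentSet

__all__ = [
    "ToyGenome",
    "LengthModel",
    "Scenario",
    "GeneratorLedger",
    "GeneratedExperiment",
    "generate",
    "uniform_distribution",
    "block_distribution",
    "expected_fragments",
]


def expected_fragments(n_bound: float, fraction: float) -> float:
    """Expected bound fragments of one species falling on one interval.

    With ``n_bound`` fragments of a species captured in total and a
    fraction ``o_i(x)`` of that species residing at x, the expected count
    at x is simply their product (the antibody is assumed unbiased with
    respect to genomic position).
    """
    if n_bound < 0 or not (0 <= fraction <= 1):
        raise ValueError("need n_bound >= 0 and 0 <= fraction <= 1")
    return n_bound * fraction


@dataclass(frozen=True)
class ToyGenome:
    """Chromosome sizes (bp) and the interval width tracks are built on."""

    sizes: Mapping[str, int]
    interval_width: int = 10_000

    def n_bins(self, chrom: str) -> int:
        return -(-self.sizes[chrom] // self.interval_width)

    @property
    def chroms(self) -> list:
        return sorted(self.sizes)

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.chroms)


def uniform_distribution(genome: ToyGenome) -> dict:
    """o(x) uniform over every interval of the genome."""
    n = genome.total_bins
    return {c: np.full(genome.n_bins(c), 1.0 / n) for c in genome.chroms}


def block_distribution(genome: ToyGenome, blocks) -> dict:
    """o(x) uniform over listed bin ranges: [(chrom, first_bin, last_bin+1), ...]."""
    dist = {c: np.zeros(genome.n_bins(c)) for c in genome.chroms}
    for chrom, lo, hi in blocks:
        if not (0 <= lo < hi <= genome.n_bins(chrom)):
            raise ValueError(f"block {chrom}:{lo}-{hi} outside genome")
        dist[chrom][lo:hi] = 1.0
    total = sum(a.sum() for a in dist.values())
    if total == 0:
        raise ValueError("block distribution covers no bins")
    return {c: a / total for c, a in dist.items()}


@dataclass(frozen=True)
class LengthModel:
    """Truncated discrete Gaussian fragment-length distribution."""

    mean: float = 150.0
    sd: float = 20.0
    minimum: int = 50
    maximum: int = 500

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        out = np.empty(n, dtype=np.int64)
        filled = 0
        while filled < n:
            draw = np.rint(rng.normal(self.mean, self.sd, n - filled)).astype(
                np.int64)
            keep = draw[(draw >= self.minimum) & (draw <= self.maximum)]
            out[filled: filled + len(keep)] = keep
            filled += len(keep)
        return out


@dataclass
class Scenario:
    """Everything the generator needs: reaction, genome, distributions, depths."""

    reaction: Reaction
    genome: ToyGenome
    distributions: Mapping[str, Mapping[str, np.ndarray]]
    length_model: LengthModel = field(default_factory=LengthModel)

    def __post_init__(self) -> None:
        names = {s.name for s in self.reaction.species}
        for name, dist in self.distributions.items():
            if name not in names:
                raise ValueError(f"distribution for unknown species {name!r}")
            total = sum(np.asarray(dist[c]).sum() for c in dist)
            if not np.isclose(total, 1.0, atol=1e-8):
                raise ValueError(f"o(x) for {name!r} must sum to 1, got {total}")
        if not self.distributions:
            raise ValueError("scenario needs at least one genomic species")

    def genomic_species(self) -> list:
        return [s for s in self.reaction.species if s.name in self.distributions]


@dataclass
class GeneratorLedger:
    """Ground truth recorded at generation time.

    Fully determines the expected efficiency track, so the recovery of
    Eq.-level predictions from the sampled fragment files can be tested
    without any external data.
    """

    seed: int
    alpha_true: float
    depth_ip: int
    depth_input: int
    bound_concentration: dict
    total_concentration: dict
    bound_fragments: dict      # sampled per-species IP fragment counts
    total_fragments: dict      # sampled per-species input fragment counts
    expected_ip: dict          # per chrom, expected IP counts per bin
    expected_input: dict
    expected_efficiency: dict  # per chrom, the isotherm-predicted e(x)
    free_antibody: float
    length_model: dict

    def to_json(self, path) -> None:
        def _ser(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            raise TypeError(f"not serializable: {type(obj)}")
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, default=_ser, indent=1, sort_keys=True)


@dataclass
class GeneratedExperiment:
    ip: FragmentSet
    input: FragmentSet
    ledger: GeneratorLedger
    manifest_ip: SampleManifest
    manifest_input: SampleManifest
    volumes: ReactionVolumes


def _sample_fragments(rng: np.random.Generator, genome: ToyGenome,
                      cell_probs: np.ndarray, cells: list, depth: int,
                      length_model: LengthModel) -> tuple:
    """Draw ``depth`` fragments from the (species, chrom, bin) cell grid."""
    counts = rng.multinomial(depth, cell_probs)
    chroms, starts = [], []
    species_counts: dict = {}
    w = genome.interval_width
    for (name, chrom, b), c in zip(cells, counts):
        if c == 0:
            continue
        species_counts[name] = species_counts.get(name, 0) + int(c)
        hi = min(w, genome.sizes[chrom] - b * w)
        starts.append(b * w + rng.integers(0, hi, size=c))
        chroms.extend([chrom] * int(c))
    starts = (np.concatenate(starts) if starts
              else np.empty(0, dtype=np.int64))
    lengths = length_model.sample(rng, len(starts))
    chroms = np.array(chroms, dtype=object)
    order = np.lexsort((lengths, starts, chroms))
    return (FragmentSet(chroms[order], starts[order], lengths[order]),
            species_counts)


def _fabricated_manifests(alpha_true: float, depth_ip: int, depth_input: int):
    """A manifest whose computed alpha equals ``alpha_true`` exactly.

    All factor ratios are 1 (identical IP and input bookkeeping); the
    whole of alpha is carried by the volume factor v_in/(V - v_in).
    """
    V = 100.0
    v_in = V * alpha_true / (1.0 + alpha_true)
    volumes = ReactionVolumes(total_volume=V, input_aliquot=v_in)

    def manifest(reads, name):
        return SampleManifest(mapped_reads=float(reads), library_sequenced=1.0,
                              library_total=1.0, pcr_cycles=0,
                              ip_mass_total=1.0, mass_into_library=1.0,
                              bead_capture_yield=1.0, name=name)
    return manifest(depth_ip, "ip"), manifest(depth_input, "input"), volumes


def generate(scenario: Scenario, depth: int, seed: int,
             depth_input: Optional[int] = None,
             out_prefix: Optional[str] = None) -> GeneratedExperiment:
    """Sample an IP/input fragment-file pair with fully known ground truth.

    ``depth`` is the number of IP fragments; the input is sampled at the
    same depth unless ``depth_input`` is given. With a fixed seed the
    outputs are byte-identical across runs. When ``out_prefix`` is given,
    writes ``<prefix>.ip.bed``, ``<prefix>.input.bed``,
    ``<prefix>.ledger.json`` and ``<prefix>.manifest.yaml``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    depth_input = depth if depth_input is None else depth_input
    root = np.random.SeedSequence(seed)
    rng_input, rng_ip = (np.random.default_rng(s) for s in root.spawn(2))

    solution = solve_binding(scenario.reaction)
    genomic = scenario.genomic_species()
    totals = np.array([s.total for s in genomic])
    bounds = np.array([solution.bound_of(s.name) for s in genomic])
    sum_t, sum_b = float(totals.sum()), float(bounds.sum())
    if sum_b <= 0:
        raise ValueError("infeasible scenario: no genomic species binds")

    genome = scenario.genome
    cells, p_in, p_ip = [], [], []
    for s, st, sb in zip(genomic, totals, bounds):
        dist = scenario.distributions[s.name]
        for chrom in genome.chroms:
            probs = np.asarray(dist.get(chrom, np.zeros(genome.n_bins(chrom))))
            for b in range(len(probs)):
                if probs[b] == 0:
                    continue
                cells.append((s.name, chrom, b))
                p_in.append(st / sum_t * probs[b])
                p_ip.append(sb / sum_b * probs[b])
    p_in = np.asarray(p_in) / np.sum(p_in)
    p_ip = np.asarray(p_ip) / np.sum(p_ip)

    input_set, n_t = _sample_fragments(rng_input, genome, p_in, cells,
                                       depth_input, scenario.length_model)
    ip_set, n_b = _sample_fragments(rng_ip, genome, p_ip, cells, depth,
                                    scenario.length_model)

    alpha_true = (depth_input / depth) * (sum_b / sum_t)
    man_ip, man_in, volumes = _fabricated_manifests(alpha_true, depth, depth_input)

    expected_ip, expected_input, expected_eff = {}, {}, {}
    for chrom in genome.chroms:
        nb = genome.n_bins(chrom)
        e_ip = np.zeros(nb)
        e_in = np.zeros(nb)
        dists = {}
        for s, st, sb in zip(genomic, totals, bounds):
            o = np.asarray(scenario.distributions[s.name].get(chrom,
                                                              np.zeros(nb)))
            e_ip += depth * (sb / sum_b) * o
            e_in += depth_input * (st / sum_t) * o
        expected_ip[chrom] = e_ip
        expected_input[chrom] = e_in
    # predicted efficiency uses the full multi-chromosome distributions
    flat = {}
    for s in genomic:
        flat[s.name] = np.concatenate(
            [np.asarray(scenario.distributions[s.name].get(
                c, np.zeros(genome.n_bins(c)))) for c in genome.chroms])
    eff_flat, _ = predict_efficiency(solution, flat)
    offset = 0
    for chrom in genome.chroms:
        nb = genome.n_bins(chrom)
        expected_eff[chrom] = eff_flat[offset: offset + nb]
        offset += nb

    ledger = GeneratorLedger(
        seed=seed,
        alpha_true=alpha_true,
        depth_ip=depth,
        depth_input=depth_input,
        bound_concentration={s.name: float(b) for s, b in zip(genomic, bounds)},
        total_concentration={s.name: float(t) for s, t in zip(genomic, totals)},
        bound_fragments=n_b,
        total_fragments=n_t,
        expected_ip=expected_ip,
        expected_input=expected_input,
        expected_efficiency=expected_eff,
        free_antibody=solution.free_antibody,
        length_model=scenario.length_model.__dict__.copy(),
    )

    result = GeneratedExperiment(ip=ip_set, input=input_set, ledger=ledger,
                                 manifest_ip=man_ip, manifest_input=man_in,
                                 volumes=volumes)
    if out_prefix is not None:
        _write_bed(ip_set, f"{out_prefix}.ip.bed")
        _write_bed(input_set, f"{out_prefix}.input.bed")
        ledger.to_json(f"{out_prefix}.ledger.json")
        dump_manifest(man_ip, man_in, volumes, f"{out_prefix}.manifest.yaml")
    return result


def _write_bed(frags: FragmentSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, length in zip(frags.chroms, frags.starts,
                                        frags.lengths):
            fh.write(f"{chrom}\t{start}\t{start + length}\n")
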