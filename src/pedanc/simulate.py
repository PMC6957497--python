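"""Ancestry-level simulation of admixed pedigrees, plus evaluation metrics.

The generator reproduces the study design the correction method is built
for, at the level the method operates on (ancestry tracks, not genotypes):

* founder haploid tracks are two-state Markov chains along the genetic map
  — the first locus is Bernoulli(lamb), and over each inter-marker gap of
  d Morgans a recombination occurs with probability 1 - exp(-d*tau), upon
  which the ancestry is resampled Bernoulli(lamb) (tau = 8 founder
  generations by default, lamb = 0.8 population-A proportion);
* descendants are gene-dropped: each meiosis transmits a mosaic of the
  parent's two haplotypes, switching source with probability 1 - exp(-d)
  per gap (a single-generation crossover process, tau = 1);
* observation errors flip each ancestry allele independently at rate
  epsilon, and the observed dosage is the sum of the observed alleles.

Defaults mirror a chromosome-22-like map: L markers uniformly spaced so
the chromosome spans roughly 60 cM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ancestry_io import AncestryMatrix, GeneticMap
from .detect_correct import count_mendelian_inconsistent, double_crossover_runs
from .pedigree import Pedigree

__all__ = [
    "SimConfig",
    "SimData",
    "Metrics",
    "uniform_map",
    "simulate_founder_track",
    "gene_drop",
    "inject_errors",
    "simulate_pedigree",
    "evaluate",
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation conditions.

    lamb: population-A admixture proportion (0.8 ~ African-American
    African proportion); tau_founder: generations since admixture driving
    founder ancestry-switch density (8); tau_meiosis: single-generation
    crossover rate, fixed at 1; epsilon: allelic flip rate injected into
    the observed matrix; default_quality: constant quality attached to
    observed calls.
    """

    lamb: float = 0.8
    tau_founder: float = 8.0
    tau_meiosis: float = 1.0
    epsilon: float = 0.01
    default_quality: float = 0.99

    def __post_init__(self) -> None:
        if not 0 < self.lamb <= 1:
            raise ValueError(f"lamb must be in (0, 1], got {self.lamb}")
        if not 0 <= self.epsilon < 0.5:
            raise ValueError(f"epsilon must be in [0, 0.5), got {self.epsilon}")
        if self.tau_founder <= 0 or self.tau_meiosis <= 0:
            raise ValueError("tau values must be positive")


def uniform_map(L: int, spacing_cm: float = 0.03, chrom: str = "22") -> GeneticMap:
    """L markers uniformly spaced ``spacing_cm`` apart on one chromosome.

    The default spacing (0.03 cM) makes a 2000-marker map span 60 cM,
    roughly the genetic length of chromosome 22.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    ids = [f"m{t}" for t in range(L)]
    pos = np.arange(L, dtype=float) * spacing_cm
    return GeneticMap(chroms={chrom: (ids, pos)})


def _founder_tracks(
    d_M: np.ndarray, n_tracks: int, lamb: float, tau: float, rng: np.random.Generator
) -> np.ndarray:
    """(n_tracks, L) haploid founder chains, vectorized across tracks.

    Implemented by resample-on-recombination: each track's value at locus t
    is the Bernoulli(lamb) draw made at the most recent recombination at or
    before t. This allows invisible self-switches but has exactly the
    conditional-transition marginal law.
    """
    L = len(d_M) + 1
    draws = (rng.random((n_tracks, L)) < lamb).astype(np.int8)
    rec = np.ones((n_tracks, L), dtype=bool)
    if L > 1:
        p_rec = 1 - np.exp(-np.asarray(d_M) * tau)
        rec[:, 1:] = rng.random((n_tracks, L - 1)) < p_rec[None, :]
    idx = np.where(rec, np.arange(L)[None, :], 0)
    idx = np.maximum.accumulate(idx, axis=1)
    return np.take_along_axis(draws, idx, axis=1)


def simulate_founder_track(
    gmap: GeneticMap, lamb: float, tau: float, rng: np.random.Generator, chrom: str | None = None
) -> np.ndarray:
    """One haploid founder ancestry track along the map (values in {0,1})."""
    if chrom is None:
        (chrom,) = gmap.chroms.keys() if len(gmap.chroms) == 1 else (None,)
        if chrom is None:
            raise ValueError("specify chrom for a multi-chromosome map")
    return _founder_tracks(gmap.distances_morgans(chrom), 1, lamb, tau, rng)[0]


def _meiosis(
    hap1: np.ndarray, hap2: np.ndarray, d_M: np.ndarray, tau: float, rng: np.random.Generator
) -> np.ndarray:
    """Transmitted haplotype: mosaic of the two parental haplotypes,
    starting from a uniformly chosen one and switching source with
    probability 1 - exp(-d*tau) per gap."""
    L = len(hap1)
    switches = np.zeros(L, dtype=np.int64)
    if L > 1:
        p = 1 - np.exp(-np.asarray(d_M) * tau)
        switches[1:] = rng.random(L - 1) < p
    source = (rng.integers(0, 2) + np.cumsum(switches)) % 2
    return np.where(source == 0, hap1, hap2).astype(np.int8)


@dataclass
class SimData:
    """Simulated truth and observation for one pedigree and map."""

    ped: Pedigree
    gmap: GeneticMap
    tracks: dict[str, tuple[np.ndarray, np.ndarray]]
    truth: AncestryMatrix
    observed: AncestryMatrix | None = None
    config: SimConfig = field(default_factory=SimConfig)


def gene_drop(
    ped: Pedigree, gmap: GeneticMap, config: SimConfig, rng: np.random.Generator
) -> SimData:
    """Simulate allele tracks for a whole pedigree.

    Founders get independent admixture chains; each non-founder (visited in
    topological order) receives one recombined haplotype per present
    parent. A child with a single recorded parent draws the other haplotype
    from the population admixture chain, like a founder haplotype.
    """
    chroms = list(gmap.chroms)
    tracks: dict[str, list[np.ndarray]] = {iid: [[], []] for iid in ped.ids}
    for chrom in chroms:
        d_M = gmap.distances_morgans(chrom)
        for ind in ped.topological_order():
            hap_pair = []
            for parent_id in (ind.father_id, ind.mother_id):
                if parent_id is None:
                    hap_pair.append(
                        _founder_tracks(d_M, 1, config.lamb, config.tau_founder, rng)[0]
                    )
                else:
                    p1, p2 = (
                        tracks[parent_id][0][-1],
                        tracks[parent_id][1][-1],
                    )
                    hap_pair.append(_meiosis(p1, p2, d_M, config.tau_meiosis, rng))
            tracks[ind.id][0].append(hap_pair[0])
            tracks[ind.id][1].append(hap_pair[1])
    joined = {
        iid: (np.concatenate(h1), np.concatenate(h2))
        for iid, (h1, h2) in tracks.items()
    }
    dosages = np.stack(
        [joined[iid][0] + joined[iid][1] for iid in ped.ids], axis=1
    ).astype(np.int8)
    truth = AncestryMatrix(
        marker_ids=gmap.marker_ids, individual_ids=list(ped.ids), dosages=dosages
    )
    return SimData(ped=ped, gmap=gmap, tracks=joined, truth=truth, config=config)


def inject_errors(
    sim: SimData, epsilon: float, rng: np.random.Generator
) -> AncestryMatrix:
    """Flip each ancestry allele independently at rate epsilon and emit the
    observed dosage matrix with a constant quality layer."""
    if not 0 <= epsilon < 0.5:
        raise ValueError(f"epsilon must be in [0, 0.5), got {epsilon}")
    cols = []
    for iid in sim.ped.ids:
        h1, h2 = sim.tracks[iid]
        f1 = rng.random(h1.shape) < epsilon
        f2 = rng.random(h2.shape) < epsilon
        cols.append((h1 ^ f1) + (h2 ^ f2))
    dosages = np.stack(cols, axis=1).astype(np.int8)
    quality = np.full(dosages.shape, sim.config.default_quality)
    observed = AncestryMatrix(
        marker_ids=list(sim.truth.marker_ids),
        individual_ids=list(sim.truth.individual_ids),
        dosages=dosages,
        quality=quality,
    )
    sim.observed = observed
    return observed


def simulate_pedigree(
    ped: Pedigree,
    gmap: GeneticMap,
    config: SimConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> SimData:
    """Convenience wrapper: gene-drop the pedigree and inject observation
    errors at ``config.epsilon``."""
    config = config or SimConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sim = gene_drop(ped, gmap, config, rng)
    inject_errors(sim, config.epsilon, rng)
    return sim


@dataclass
class Metrics:
    """Accuracy metrics of an inferred matrix against the truth."""

    dosage_error_rate: float
    loci_with_errors: int
    mendelian_error_loci: int
    double_crossover_runs: int
    per_individual_loci_with_errors: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "dosage_error_rate": self.dosage_error_rate,
            "loci_with_errors": self.loci_with_errors,
            "mendelian_error_loci": self.mendelian_error_loci,
            "double_crossover_runs": self.double_crossover_runs,
            "per_individual_loci_with_errors": self.per_individual_loci_with_errors,
        }


def _metrics_against_truth(
    truth: AncestryMatrix,
    inferred: AncestryMatrix,
    ped: Pedigree,
    gmap: GeneticMap,
    window_cm: float,
) -> Metrics:
    if truth.shape != inferred.shape:
        raise ValueError(
            f"shape mismatch: truth {truth.shape} vs inferred {inferred.shape}"
        )
    X = truth.dosages.astype(np.int64)
    Y = inferred.dosages.astype(np.int64)
    obs = (X >= 0) & (Y >= 0)
    n_cells = truth.shape[0] * truth.shape[1]
    err = float(np.abs((Y - X))[obs].sum() / n_cells)
    wrong = (Y != X) & obs
    dc = 0
    start = 0
    for chrom, (ids, pos) in gmap.chroms.items():
        stop = start + len(ids)
        for j in range(inferred.n_individuals):
            dc += len(
                double_crossover_runs(inferred.dosages[start:stop, j], pos, window_cm)
            )
        start = stop
    return Metrics(
        dosage_error_rate=err,
        loci_with_errors=int(wrong.any(axis=1).sum()),
        mendelian_error_loci=count_mendelian_inconsistent(inferred, ped),
        double_crossover_runs=dc,
        per_individual_loci_with_errors={
            iid: int(wrong[:, j].sum())
            for j, iid in enumerate(inferred.individual_ids)
        },
    )


def evaluate(
    truth: AncestryMatrix,
    observed: AncestryMatrix,
    corrected: AncestryMatrix,
    ped: Pedigree,
    gmap: GeneticMap,
    window_cm: float = 2.0,
) -> tuple[Metrics, Metrics]:
    """Before/after metrics: observed-vs-truth and corrected-vs-truth.

    The dosage error rate is sum |Y - X| / (n * L); loci-with-errors counts
    loci where at least one individual's dosage is wrong.
    """
    before = _metrics_against_truth(truth, observed, ped, gmap, window_cm)
    after = _metrics_against_truth(truth, corrected, ped, gmap, window_cm)
    return before, after
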