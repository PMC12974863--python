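"""Forward-time simulation of recombining haploid bacterial populations.

Individuals are haploid genomes tracked as sparse mutation maps relative to an
empty ancestral chromosome. Reproduction, horizontal gene transfer (HGT) and
population regulation are explicit per-generation events (a non-Wright-Fisher
model). Six scenarios are supported:

``neutral``
    single panmictic population, neutral mutations, uniform HGT.
``stepping_stone``
    linear chain of demes exchanging a fixed number of migrants per
    generation; HGT acts within demes.
``hotspot``
    recombination-rate heterogeneity: a fraction of HGT tracts is forced to
    initiate at predefined hotspot coordinates.
``mutation_het``
    mutation-rate heterogeneity: half the lineages (label p1) never mutate
    de novo, and HGT donors are drawn 50/50 from the two label groups.
``selective_uniform``
    diversifying selection on an additive trait where every site has effect
    magnitude 1 (trait = #m1 - #m2); selection starts mid-run.
``selective_gamma``
    as above but with per-site effect magnitudes drawn once from a Gamma
    distribution with mean one (shape x scale = 1).

Two neutral mutation types, ``m1`` and ``m2``, arise with equal probability.
Under selection the trait value of a genome is the sum of effect coefficients
over its m1 mutations minus the sum over its m2 mutations, and fitness is a
normalized power function of the absolute deviation from the population mean
trait, favouring both tails (diversifying selection).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "M1",
    "M2",
    "SCENARIOS",
    "Mutation",
    "Genome",
    "EffectTable",
    "ScenarioSpec",
    "SimOutput",
    "ParameterError",
    "ConfigurationError",
    "ExtinctionError",
    "mutate_population",
    "hgt_event",
    "sample_hgt_start",
    "sample_hgt_donor",
    "trait_score",
    "fitness_vector",
    "reproduce_and_regulate",
    "migrate_stepping_stone",
    "draw_effect_table",
    "run_scenario",
    "desk_spec",
    "paper_spec",
]

#: internal allele codes; 0 is the (implicit) ancestral state
M1 = 1
M2 = 2

SCENARIOS = (
    "neutral",
    "stepping_stone",
    "hotspot",
    "mutation_het",
    "selective_uniform",
    "selective_gamma",
)

SELECTIVE_SCENARIOS = ("selective_uniform", "selective_gamma")


class ParameterError(ValueError):
    """A numeric parameter is out of its valid range."""


class ConfigurationError(ValueError):
    """A scenario configuration is internally inconsistent."""


class ExtinctionError(RuntimeError):
    """The whole population (or a deme) produced zero offspring."""


@dataclass(frozen=True)
class Mutation:
    """A single derived mutation: 0-based site index and type (m1 or m2)."""

    position: int
    mtype: int

    def __post_init__(self):
        if self.mtype not in (M1, M2):
            raise ParameterError(f"mtype must be {M1} (m1) or {M2} (m2)")


class Genome:
    """Sparse haploid genome: sorted mutation positions and their types.

    ``positions``/``types`` are treated as immutable; every operation that
    changes a genome returns a new ``Genome`` (arrays may be shared between
    clonal copies).
    """

    __slots__ = ("positions", "types", "deme", "lineage_id")

    def __init__(self, positions=None, types=None, deme: int = 0, lineage_id: int = 0):
        self.positions = (
            np.asarray(positions, dtype=np.int64)
            if positions is not None
            else np.empty(0, dtype=np.int64)
        )
        self.types = (
            np.asarray(types, dtype=np.int8)
            if types is not None
            else np.empty(0, dtype=np.int8)
        )
        if self.positions.shape != self.types.shape:
            raise ParameterError("positions and types must have equal length")
        self.deme = deme
        self.lineage_id = lineage_id

    @classmethod
    def _fast(cls, positions, types, deme, lineage_id) -> "Genome":
        # internal constructor skipping validation (arrays already typed)
        g = object.__new__(cls)
        g.positions = positions
        g.types = types
        g.deme = deme
        g.lineage_id = lineage_id
        return g

    @classmethod
    def from_mutations(cls, mutations: dict[int, int], deme: int = 0, lineage_id: int = 0) -> "Genome":
        pos = np.fromiter(sorted(mutations), dtype=np.int64, count=len(mutations))
        typ = np.array([mutations[p] for p in pos], dtype=np.int8)
        return cls(pos, typ, deme=deme, lineage_id=lineage_id)

    @property
    def mutations(self) -> dict[int, int]:
        """Mutations as a {position: mtype} dict (convenience view)."""
        return dict(zip(self.positions.tolist(), self.types.tolist()))

    @property
    def n_mutations(self) -> int:
        return int(self.positions.size)

    def replace(self, positions, types) -> "Genome":
        """New genome with the same deme/lineage labels but new mutation arrays."""
        return Genome._fast(
            np.asarray(positions, dtype=np.int64),
            np.asarray(types, dtype=np.int8),
            self.deme,
            self.lineage_id,
        )

    def clone(self) -> "Genome":
        """Clonal copy sharing the (immutable) mutation arrays."""
        return Genome._fast(self.positions, self.types, self.deme, self.lineage_id)

    def __eq__(self, other):
        if not isinstance(other, Genome):
            return NotImplemented
        return (
            np.array_equal(self.positions, other.positions)
            and np.array_equal(self.types, other.types)
        )

    def __repr__(self):
        return f"Genome(n_mutations={self.n_mutations}, deme={self.deme}, lineage_id={self.lineage_id})"


@dataclass
class EffectTable:
    """Per-site nonnegative effect magnitudes for the quantitative trait."""

    genome_length: int
    coefficients: np.ndarray

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        if self.coefficients.shape != (self.genome_length,):
            raise ParameterError("coefficients must have one entry per site")
        if np.any(self.coefficients < 0):
            raise ParameterError("effect coefficients must be nonnegative")

    @classmethod
    def uniform(cls, genome_length: int) -> "EffectTable":
        """All-ones table: the trait reduces to (#m1 - #m2)."""
        return cls(genome_length, np.ones(genome_length))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"position": np.arange(self.genome_length), "coefficient": self.coefficients}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class ScenarioSpec:
    """Complete configuration of one simulation run."""

    scenario: str
    genome_length: int = 1_000_000
    pop_size: int = 10_000
    n_demes: int = 1
    migrants_per_gen: int = 0
    mutation_rate: float = 1e-6
    hgt_events_per_gen: int = 1
    hgt_tract_length: int = 10_000
    hotspot_positions: tuple[int, ...] = ()
    hotspot_fraction: float = 0.0
    generations: int = 10_000
    selection_start: int = 5_001
    fitness_amplitude: float = 1.0
    fitness_exponent: int = 5
    fitness_epsilon: float = 1e-6
    gamma_shape: float = 1.0
    gamma_scale: float = 1.0
    base_lambda: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        if self.mutation_rate < 0:
            raise ParameterError("mutation_rate must be nonnegative")
        if not (0.0 <= self.hotspot_fraction <= 1.0):
            raise ParameterError("hotspot_fraction must lie in [0, 1]")
        if self.hotspot_fraction > 0 and not self.hotspot_positions:
            raise ConfigurationError("hotspot_fraction > 0 requires hotspot_positions")
        if self.pop_size <= 0 or self.genome_length <= 0:
            raise ParameterError("pop_size and genome_length must be positive")
        if self.n_demes < 1:
            raise ParameterError("n_demes must be >= 1")
        if self.scenario == "stepping_stone" and self.pop_size % self.n_demes:
            raise ConfigurationError("pop_size must be divisible by n_demes")
        if self.scenario in SELECTIVE_SCENARIOS and self.selection_start > self.generations:
            raise ConfigurationError(
                "selection_start must not exceed generations in selective scenarios"
            )
        if self.scenario == "selective_gamma" and (
            self.gamma_shape <= 0 or self.gamma_scale <= 0
        ):
            raise ParameterError("gamma parameters must be positive")

    def asdict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hotspot_positions"] = list(self.hotspot_positions)
        return d


@dataclass
class SimOutput:
    """Result of one scenario run."""

    final_population: list
    trait_values: np.ndarray
    generation_log: pd.DataFrame
    spec: ScenarioSpec
    effects: EffectTable


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def _merge_mutations(genome: Genome, new_pos: np.ndarray, new_typ: np.ndarray) -> Genome:
    """Insert new mutations; a new mutation at an occupied site replaces the
    resident record (finite-sites convention); among same-generation draws at
    one site, the last draw wins."""
    if new_pos.size == 0:
        return genome
    # stable sort; keep the last occurrence of each duplicated new position
    order = np.argsort(new_pos, kind="stable")
    new_pos = new_pos[order]
    new_typ = new_typ[order]
    keep = np.ones(new_pos.size, dtype=bool)
    keep[:-1] = new_pos[1:] != new_pos[:-1]
    new_pos = new_pos[keep]
    new_typ = new_typ[keep]

    pos, typ = genome.positions, genome.types
    loc = pos.searchsorted(new_pos)
    if pos.size:
        inb = loc < pos.size
        present = np.zeros(new_pos.size, dtype=bool)
        present[inb] = pos[loc[inb]] == new_pos[inb]
    else:
        present = np.zeros(new_pos.size, dtype=bool)
    typ_out = typ.copy()
    if present.any():
        typ_out[loc[present]] = new_typ[present]
    ins = ~present
    if ins.any():
        ins_pos = new_pos[ins].astype(np.int64)
        ins_typ = new_typ[ins]
        tgt = loc[ins] + np.arange(ins_pos.size)  # final indices of inserts
        out_pos = np.empty(pos.size + ins_pos.size, dtype=np.int64)
        out_typ = np.empty(out_pos.size, dtype=np.int8)
        mask = np.ones(out_pos.size, dtype=bool)
        mask[tgt] = False
        out_pos[mask] = pos
        out_pos[tgt] = ins_pos
        out_typ[mask] = typ_out
        out_typ[tgt] = ins_typ
        return Genome._fast(out_pos, out_typ, genome.deme, genome.lineage_id)
    return Genome._fast(pos, typ_out, genome.deme, genome.lineage_id)


def mutate_population(
    pop: list[Genome],
    rate: float,
    length: int,
    rng: np.random.Generator,
    mask=None,
) -> list[Genome]:
    """One generation of de novo mutation.

    Each genome gains Poisson(rate x length) mutations at uniform positions;
    each is m1 or m2 with probability 1/2. ``mask`` (boolean per genome, True
    = mutable) supports the mutation-heterogeneity scenario.
    """
    if rate < 0:
        raise ParameterError("mutation rate must be nonnegative")
    if rate == 0 or not pop:
        return list(pop)
    counts = rng.poisson(rate * length, size=len(pop))
    if mask is not None:
        counts = np.where(np.asarray(mask, dtype=bool), counts, 0)
    out = []
    for g, k in zip(pop, counts):
        if k == 0:
            out.append(g)
            continue
        new_pos = rng.integers(0, length, size=k)
        new_typ = rng.integers(M1, M2 + 1, size=k).astype(np.int8)
        out.append(_merge_mutations(g, new_pos, new_typ))
    return out


def hgt_event(
    recipient: Genome,
    donor: Genome,
    start: int,
    tract: int,
    genome_length: int | None = None,
) -> Genome:
    """Copy the donor's mutations in [start, start + tract) into the
    recipient, replacing the recipient's mutations in that interval.

    The tract is half-open. Without ``genome_length`` it is truncated
    implicitly at the chromosome end (no positions exist beyond it); with
    ``genome_length`` the chromosome is treated as circular and a tract
    running past the end wraps around to [0, start + tract - L). The
    simulator passes ``genome_length``, so tract coverage is uniform along
    the (circular) chromosome. Returns the recipient unchanged (same
    object) when the event is a no-op.
    """
    if start < 0:
        raise ParameterError("tract start must be nonnegative")
    if tract <= 0 or recipient is donor:
        return recipient
    end = start + tract
    if genome_length is not None and end > genome_length:
        g = _splice(recipient, donor, start, genome_length)
        return _splice(g, donor, 0, end - genome_length)
    return _splice(recipient, donor, start, end)


def _splice(recipient: Genome, donor: Genome, start: int, end: int) -> Genome:
    """Replace the recipient's mutations in [start, end) by the donor's."""
    rp = recipient.positions
    dp = donor.positions
    r_lo = rp.searchsorted(start)
    r_hi = rp.searchsorted(end)
    d_lo = dp.searchsorted(start)
    d_hi = dp.searchsorted(end)
    if r_lo == r_hi and d_lo == d_hi:
        return recipient
    out_pos = np.concatenate((rp[:r_lo], dp[d_lo:d_hi], rp[r_hi:]))
    out_typ = np.concatenate(
        (recipient.types[:r_lo], donor.types[d_lo:d_hi], recipient.types[r_hi:])
    )
    return Genome._fast(out_pos, out_typ, recipient.deme, recipient.lineage_id)


def sample_hgt_start(spec: ScenarioSpec, rng: np.random.Generator) -> int:
    """Draw a tract start: with probability ``hotspot_fraction`` a uniformly
    chosen hotspot coordinate, otherwise uniform on [0, genome_length)."""
    if spec.hotspot_fraction > 0:
        if not spec.hotspot_positions:
            raise ConfigurationError("hotspot_fraction > 0 requires hotspot_positions")
        if rng.random() < spec.hotspot_fraction:
            return int(spec.hotspot_positions[rng.integers(len(spec.hotspot_positions))])
    return int(rng.integers(0, spec.genome_length))


def sample_hgt_donor(
    n: int,
    recipient: int,
    rng: np.random.Generator,
    label_groups: tuple[np.ndarray, np.ndarray] | None = None,
) -> int:
    """Pick an HGT donor index, uniform among the other individuals.

    For the mutation-heterogeneity scenario, ``label_groups`` holds the index
    arrays of the p1 and p2 label groups; the donor's group is chosen with
    probability 1/2 each, then the donor uniformly within it (excluding the
    recipient; a group containing only the recipient defers to the other).
    """
    if n < 2:
        raise ConfigurationError("need at least two individuals for HGT")
    if label_groups is None:
        j = int(rng.integers(n - 1))
        return j if j < recipient else j + 1
    group = label_groups[int(rng.integers(2))]
    if group.size == 0 or (group.size == 1 and group[0] == recipient):
        group = label_groups[0] if group is label_groups[1] else label_groups[1]
    while True:
        j = int(group[rng.integers(group.size)])
        if j != recipient:
            return j


def trait_score(g: Genome, effects: EffectTable) -> float:
    """Quantitative trait value: sum of effect coefficients over m1 mutations
    minus the sum over m2 mutations. With an all-ones table this is simply
    the m1 count minus the m2 count."""
    if g.positions.size and g.positions[-1] >= effects.genome_length:
        raise ParameterError("genome has mutations beyond the effect table length")
    c = effects.coefficients[g.positions]
    sign = np.where(g.types == M1, 1.0, -1.0)
    return float(np.dot(c, sign))


def fitness_vector(
    scores,
    amplitude: float = 1.0,
    exponent: int = 5,
    epsilon: float = 1e-6,
) -> np.ndarray:
    """Diversifying-selection fitness.

    fitness_i = 2.0 + amplitude * |s_i - mu|^exponent /
                (max_j |s_j - mu|^exponent + epsilon)

    with mu the current population mean score. Individuals at the tails of
    the trait distribution approach 2.0 + amplitude; all-equal scores give
    exactly 2.0 (a flat, neutral generation).
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size == 0:
        raise ParameterError("fitness_vector requires a non-empty score vector")
    d = np.abs(scores - scores.mean()) ** exponent
    return 2.0 + amplitude * d / (d.max() + epsilon)


def reproduce_and_regulate(
    pop: list[Genome],
    lambdas,
    capacity: int,
    rng: np.random.Generator,
    return_counts: bool = False,
):
    """Poisson reproduction followed by hard carrying-capacity regulation.

    Each parent i produces Poisson(lambda_i) clonal offspring; if the total
    exceeds ``capacity`` a uniform random subset of exactly ``capacity``
    offspring survives. Zero total offspring raises :class:`ExtinctionError`.
    """
    lambdas = np.asarray(lambdas, dtype=np.float64)
    if len(pop) != lambdas.size:
        raise ParameterError("one lambda per parent required")
    if capacity <= 0:
        raise ParameterError("capacity must be positive")
    counts = rng.poisson(lambdas)
    total = int(counts.sum())
    if total == 0:
        raise ExtinctionError(
            f"population extinct: {len(pop)} parents produced zero offspring"
        )
    parent_idx = np.repeat(np.arange(len(pop)), counts)
    if total > capacity:
        parent_idx = rng.choice(parent_idx, size=capacity, replace=False)
    offspring = [pop[i].clone() for i in parent_idx]
    if return_counts:
        return offspring, counts
    return offspring


def migrate_stepping_stone(
    demes: list[list[Genome]],
    migrants: int,
    rng: np.random.Generator,
) -> list[list[Genome]]:
    """Exchange migrants between adjacent demes on a line.

    Each deme sends ``migrants`` uniformly chosen individuals to each
    neighbouring deme (1 neighbour for end demes, 2 for interior demes); all
    emigrants of a deme are distinct. The total individual count is
    conserved.
    """
    if migrants < 0:
        raise ParameterError("migrants must be nonnegative")
    nd = len(demes)
    if migrants == 0 or nd < 2:
        return [list(d) for d in demes]
    moves = []  # (source, dest, indices)
    for d, deme in enumerate(demes):
        neighbours = [x for x in (d - 1, d + 1) if 0 <= x < nd]
        need = migrants * len(neighbours)
        if need > len(deme):
            raise ConfigurationError(
                f"deme {d} has {len(deme)} individuals but must send {need} migrants"
            )
        chosen = rng.choice(len(deme), size=need, replace=False)
        for k, nb in enumerate(neighbours):
            moves.append((d, nb, chosen[k * migrants : (k + 1) * migrants]))
    leaving = [set() for _ in range(nd)]
    incoming: list[list[Genome]] = [[] for _ in range(nd)]
    for src, dst, idx in moves:
        for i in idx.tolist():
            leaving[src].add(i)
            incoming[dst].append(demes[src][i])
    out = []
    for d, deme in enumerate(demes):
        stay = [g for i, g in enumerate(deme) if i not in leaving[d]]
        for g in incoming[d]:
            g.deme = d
        out.append(stay + incoming[d])
    return out


def draw_effect_table(
    length: int, shape: float, scale: float, rng: np.random.Generator
) -> EffectTable:
    """Draw one Gamma(shape, scale) effect magnitude per site.

    The sampling law has mean shape x scale; the study configurations keep
    this product at 1 so that overall selection intensity matches the
    uniform-effect model while concentrating effects on few sites when the
    scale is large.
    """
    if shape <= 0 or scale <= 0:
        raise ParameterError("Gamma shape and scale must be positive")
    return EffectTable(length, rng.gamma(shape, scale, size=length))


# ---------------------------------------------------------------------------
# scenario orchestration
# ---------------------------------------------------------------------------


def _hgt_generation(
    deme: list[Genome],
    spec: ScenarioSpec,
    rng: np.random.Generator,
    label_groups=None,
) -> int:
    """Apply the per-generation HGT schedule in place; return the number of
    recipients. Every individual is scheduled as a recipient of
    ``hgt_events_per_gen`` events (event rate 1.0); events are applied
    sequentially, so donors reflect earlier same-generation transfers."""
    n = len(deme)
    if n < 2 or spec.hgt_events_per_gen <= 0 or spec.hgt_tract_length <= 0:
        return 0
    e = spec.hgt_events_per_gen
    if label_groups is None:
        # batched draws, distributionally identical to sample_hgt_donor /
        # sample_hgt_start applied per event
        recipients = np.repeat(np.arange(n), e)
        donors = rng.integers(0, n - 1, size=n * e)
        donors += donors >= recipients
        starts = rng.integers(0, spec.genome_length, size=n * e)
        if spec.hotspot_fraction > 0:
            hot = rng.random(n * e) < spec.hotspot_fraction
            hotspots = np.asarray(spec.hotspot_positions, dtype=np.int64)
            picks = rng.integers(0, hotspots.size, size=n * e)
            starts = np.where(hot, hotspots[picks], starts)
        donors = donors.tolist()
        starts = starts.tolist()
        tract = spec.hgt_tract_length
        ev = 0
        for i in range(n):
            for _ in range(e):
                deme[i] = hgt_event(
                    deme[i], deme[donors[ev]], starts[ev], tract, spec.genome_length
                )
                ev += 1
        return n
    for i in range(n):
        for _ in range(e):
            j = sample_hgt_donor(n, i, rng, label_groups)
            start = sample_hgt_start(spec, rng)
            deme[i] = hgt_event(
                deme[i], deme[j], start, spec.hgt_tract_length, spec.genome_length
            )
    return n


def _population_scores(pop: list[Genome], effects: EffectTable, uniform: bool) -> np.ndarray:
    """Trait scores for a whole population; with all-ones effects the score
    reduces to m1-count minus m2-count, computed without the coefficient
    gather (types are coded 1/2, so the score is 3n - 2*sum(types))."""
    if uniform:
        return np.fromiter(
            (3 * g.types.size - 2 * int(g.types.sum()) for g in pop),
            dtype=np.float64,
            count=len(pop),
        )
    return np.fromiter(
        (trait_score(g, effects) for g in pop), dtype=np.float64, count=len(pop)
    )


def _label_groups(deme: list[Genome]) -> tuple[np.ndarray, np.ndarray]:
    labels = np.fromiter((g.lineage_id % 2 for g in deme), dtype=np.int64, count=len(deme))
    return np.flatnonzero(labels == 0), np.flatnonzero(labels == 1)


def run_scenario(spec: ScenarioSpec) -> SimOutput:
    """Run one scenario from generation 1 to ``spec.generations``.

    Per-generation event order: mutation (skipped for p1-labelled lineages
    in ``mutation_het``), HGT, migration (``stepping_stone`` only), fitness
    evaluation (base lambda during the neutral phase, diversifying-selection
    fitness from ``selection_start`` onwards in selective scenarios), then
    Poisson reproduction with per-deme capacity regulation. Identical specs
    (including seed) give identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    nd = spec.n_demes if spec.scenario == "stepping_stone" else 1
    per_deme = spec.pop_size // nd
    demes: list[list[Genome]] = []
    lid = 0
    for d in range(nd):
        demes.append([Genome(deme=d, lineage_id=lid + i) for i in range(per_deme)])
        lid += per_deme

    if spec.scenario == "selective_gamma":
        effects = draw_effect_table(spec.genome_length, spec.gamma_shape, spec.gamma_scale, rng)
    else:
        effects = EffectTable.uniform(spec.genome_length)

    log_rows = []
    for gen in range(1, spec.generations + 1):
        selection_on = (
            spec.scenario in SELECTIVE_SCENARIOS and gen >= spec.selection_start
        )
        # mutation
        for d in range(nd):
            mask = None
            if spec.scenario == "mutation_het":
                # de novo mutation disabled in the p1 label group
                mask = [g.lineage_id % 2 == 1 for g in demes[d]]
            demes[d] = mutate_population(
                demes[d], spec.mutation_rate, spec.genome_length, rng, mask=mask
            )
        # HGT
        n_recip = 0
        for d in range(nd):
            groups = _label_groups(demes[d]) if spec.scenario == "mutation_het" else None
            n_recip += _hgt_generation(demes[d], spec, rng, groups)
        # migration
        if spec.scenario == "stepping_stone" and spec.migrants_per_gen > 0:
            demes = migrate_stepping_stone(demes, spec.migrants_per_gen, rng)
        # fitness + reproduction (per deme, hard capacity)
        mean_score = np.nan
        new_demes = []
        for d in range(nd):
            if selection_on:
                scores = _population_scores(
                    demes[d], effects, spec.scenario != "selective_gamma"
                )
                lams = fitness_vector(
                    scores,
                    spec.fitness_amplitude,
                    spec.fitness_exponent,
                    spec.fitness_epsilon,
                )
                mean_score = float(scores.mean())
            else:
                lams = np.full(len(demes[d]), spec.base_lambda)
            new_demes.append(reproduce_and_regulate(demes[d], lams, per_deme, rng))
        demes = new_demes
        log_rows.append(
            (gen, sum(len(d) for d in demes), mean_score, n_recip)
        )

    final = [g for deme in demes for g in deme]
    traits = _population_scores(final, effects, spec.scenario != "selective_gamma")
    log = pd.DataFrame(
        log_rows, columns=["generation", "pop_size", "mean_score", "hgt_recipients"]
    )
    return SimOutput(final, traits, log, spec, effects)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

#: Desk-scale tract lengths (bp), scaling the full-scale 1/20/100 kb tracts by
#: the genome-length ratio (1 Mb -> 100 kb) so tract/genome ratios are kept.
DESK_TRACTS = {"low": 100, "intermediate": 2_000, "high": 10_000}


def desk_spec(scenario: str, tract: str | int = "intermediate", seed: int = 0, **overrides) -> ScenarioSpec:
    """Desk-scale preset: N=500, L=100 kb, 2,000 generations, selection from
    generation 1,001. Per-genome rates (one mutation and one HGT event per
    genome per generation) and tract/genome ratios match the full-scale
    configurations."""
    tract_bp = DESK_TRACTS[tract] if isinstance(tract, str) else int(tract)
    kw = dict(
        scenario=scenario,
        genome_length=100_000,
        pop_size=500,
        mutation_rate=1e-5,
        hgt_events_per_gen=1,
        hgt_tract_length=tract_bp,
        generations=2_000,
        selection_start=1_001,
        seed=seed,
    )
    if scenario == "stepping_stone":
        kw.update(n_demes=10, migrants_per_gen=1, pop_size=500)
    elif scenario == "hotspot":
        kw.update(hotspot_positions=(25_000, 50_000, 75_000), hotspot_fraction=0.8)
    elif scenario == "selective_uniform":
        kw.update(fitness_amplitude=1.0, fitness_exponent=5)
    elif scenario == "selective_gamma":
        # mean-1 Gamma mirroring the 1 Mb / scale-1e5 configuration scaled by
        # the genome-length ratio: shape x L ~ 10 sites carry almost all of
        # the trait, so several distinct loading peaks can arise
        kw.update(
            fitness_amplitude=1.0,
            fitness_exponent=5,
            gamma_shape=1e-4,
            gamma_scale=1e4,
        )
    kw.update(overrides)
    return ScenarioSpec(**kw)


def paper_spec(scenario: str, seed: int = 0, **overrides) -> ScenarioSpec:
    """Full-scale preset: 1 Mb genome (5 Mb for the refined Gamma model),
    N=10,000, 10,000 generations, selection from generation 5,001."""
    kw = dict(
        scenario=scenario,
        genome_length=1_000_000,
        pop_size=10_000,
        mutation_rate=1e-6,
        hgt_events_per_gen=1,
        hgt_tract_length=10_000,
        generations=10_000,
        selection_start=5_001,
        seed=seed,
    )
    if scenario == "stepping_stone":
        kw.update(n_demes=10, migrants_per_gen=10, pop_size=10_000)
    elif scenario == "hotspot":
        kw.update(
            hotspot_positions=(250_000, 500_000, 750_000),
            hotspot_fraction=0.8,
            hgt_tract_length=20_000,
        )
    elif scenario == "mutation_het":
        kw.update(hgt_tract_length=20_000)
    elif scenario == "selective_uniform":
        kw.update(hgt_tract_length=20_000, fitness_amplitude=1.0, fitness_exponent=5)
    elif scenario == "selective_gamma":
        # refined model: 5 Mb genome, 5 x 20 kb tracts per generation,
        # mean-1 Gamma with scale 5e6, gentler fitness (2.0-2.5, exponent 10)
        kw.update(
            genome_length=5_000_000,
            hgt_events_per_gen=5,
            hgt_tract_length=20_000,
            fitness_amplitude=0.5,
            fitness_exponent=10,
            gamma_shape=2e-7,
            gamma_scale=5e6,
        )
    kw.update(overrides)
    return ScenarioSpec(**kw)


def write_outputs(out: SimOutput, directory) -> None:
    """Write trait table, effect table and generation log as TSV files."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "id": [f"strain_{i}" for i in range(len(out.final_population))],
            "deme": [g.deme for g in out.final_population],
            "score": out.trait_values,
        }
    ).to_csv(directory / "traits.tsv", sep="\t", index=False)
    out.effects.to_tsv(directory / "effects.tsv")
    out.generation_log.to_csv(directory / "generation_log.tsv", sep="\t", index=False)
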