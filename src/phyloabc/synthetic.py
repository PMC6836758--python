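"""Coalescent simulation of multi-population divergence scenarios.

The simulator realizes the standard neutral n-coalescent inside a rooted
population tree with no migration.  Backward in time, lineages within a
branch of (census diploid-equivalent) size ``N`` coalesce at rate
``1 / (inheritance_scalar * 2N)`` per lineage pair; at each merge event the
remaining lineages of the source branch transfer into the destination
branch, which keeps its own size.  Mutations fall on the genealogy as a
Poisson process at rate ``mu_site_gen * length_bp`` per lineage per
generation and are placed under the infinite-sites model: each mutation
gets a fresh site.  Output alignments are encoded over {A, G} (ancestral /
derived) so downstream statistics treat them as ordinary sequences.

The built-in scenarios describe four competing biogeographic histories for
seven populations of the Sitka periwinkle *Littorina sitkana* sampled on
both sides of the North Pacific: ERI, KHO, STA, PET in the northwestern
Pacific (NWP) and KOD, COR, JUN in the northeastern Pacific (NEP).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .data_model import LocusSpec, SeqRecordEntry, SequencePanel

__all__ = [
    "PriorSpec",
    "MergeEvent",
    "ScenarioSpec",
    "ParameterDraw",
    "SamplingDesign",
    "PriorSpecificationError",
    "builtin_scenarios",
    "default_loci",
    "default_design",
    "draw_parameters",
    "simulate_locus",
    "simulate_locus_matrix",
    "simulate_dataset",
    "child_rng",
    "REGION_OF_POP",
    "MULTILOCUS_SAMPLE_SIZES",
    "SCENARIO1_REFERENCE_PARAMS",
]


class PriorSpecificationError(ValueError):
    """Priors + ordering constraints cannot be jointly satisfied."""


@dataclass(frozen=True)
class PriorSpec:
    """Uniform prior over a demographic parameter.

    Units are individuals for population sizes and generations for event
    times.
    """

    lower: float
    upper: float
    kind: str = "uniform"

    def __post_init__(self) -> None:
        if self.kind != "uniform":
            raise ValueError(f"unsupported prior kind {self.kind!r}")
        if not (0 <= self.lower < self.upper):
            raise ValueError(f"require 0 <= lower < upper, got [{self.lower}, {self.upper}]")


@dataclass(frozen=True)
class MergeEvent:
    """Backward-in-time merge: at ``time_param`` the remaining lineages of
    ``source`` transfer into ``dest`` (which keeps its own size)."""

    time_param: str
    source: str
    dest: str


@dataclass(frozen=True)
class ScenarioSpec:
    """A labeled population-divergence history.

    ``events`` must define a rooted tree over ``populations``: every
    population branch is the source of exactly one merge except the root
    branch, which never merges.  ``size_param`` maps each branch to the name
    of its size parameter; a branch keeps one size for its whole duration
    (there are no separate ancestral-size parameters).
    """

    id: str
    populations: tuple[str, ...]
    events: tuple[MergeEvent, ...]
    size_param: Mapping[str, str]
    priors: Mapping[str, PriorSpec]
    ordering_constraints: tuple[tuple[str, str], ...] = ()
    description: str = ""

    def __post_init__(self) -> None:
        sources = [e.source for e in self.events]
        if len(set(sources)) != len(sources):
            raise ValueError(f"{self.id}: a branch merges more than once")
        roots = set(self.populations) - set(sources)
        if len(roots) != 1:
            raise ValueError(f"{self.id}: events must leave exactly one root branch, got {roots}")
        if len(self.events) != len(self.populations) - 1:
            raise ValueError(f"{self.id}: {len(self.populations)} populations need "
                             f"{len(self.populations) - 1} merges")
        for pop in self.populations:
            if pop not in self.size_param:
                raise ValueError(f"{self.id}: no size parameter for branch {pop!r}")

    @property
    def root(self) -> str:
        return next(iter(set(self.populations) - {e.source for e in self.events}))

    @property
    def parameters(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for p in self.size_param.values():
            seen.setdefault(p, None)
        for e in self.events:
            seen.setdefault(e.time_param, None)
        return tuple(seen)

    def all_constraints(self) -> tuple[tuple[str, str], ...]:
        """Declared ordering constraints plus the structural ones.

        Structurally, if branch B absorbs a merge at time t_f and B itself
        merges away at time t_e, then t_f < t_e (B must still exist when it
        receives lineages).
        """
        merge_time = {e.source: e.time_param for e in self.events}
        structural = []
        for e in self.events:
            if e.dest in merge_time:
                structural.append((e.time_param, merge_time[e.dest]))
        out: dict[tuple[str, str], None] = {}
        for c in list(self.ordering_constraints) + structural:
            out.setdefault(c, None)
        return tuple(out)


@dataclass(frozen=True)
class ParameterDraw:
    scenario_id: str
    values: Mapping[str, float]
    seed: int


@dataclass(frozen=True)
class SamplingDesign:
    """Individuals sampled per population; gene copies follow the locus
    ploidy (1 copy per individual for mtDNA, 2 for nuclear)."""

    individuals: Mapping[str, int]

    def __post_init__(self) -> None:
        for pop, n in self.individuals.items():
            if n < 1:
                raise ValueError(f"population {pop!r}: need >= 1 individual, got {n}")

    def gene_copies(self, population: str, locus: LocusSpec) -> int:
        return self.individuals[population] * locus.copies_per_individual


# ---------------------------------------------------------------------------
# built-in study design

REGION_OF_POP: dict[str, str] = {
    "ERI": "NWP", "KHO": "NWP", "STA": "NWP", "PET": "NWP",
    "KOD": "NEP", "COR": "NEP", "JUN": "NEP",
}

#: individuals per population in the multi-locus sampling design
MULTILOCUS_SAMPLE_SIZES: dict[str, int] = {
    "ERI": 11, "KHO": 16, "STA": 8, "PET": 16,
    "KOD": 9, "COR": 12, "JUN": 8,
}

_POPS = ("ERI", "KHO", "STA", "PET", "KOD", "COR", "JUN")

#: posterior modal parameter estimates for the single-colonization history of
#: L. sitkana (sizes in individuals, times in generations); used as the
#: canonical "true" parameter point for pseudo-observed-data experiments.
SCENARIO1_REFERENCE_PARAMS: dict[str, float] = {
    "N_COR": 144_000, "N_KOD": 19_900, "N_JUN": 21_200, "N_PET": 99_800,
    "N_ERI": 321_000, "N_KHO": 88_800, "N_STA": 315_000,
    "t_a": 2_810, "t_b": 22_400, "t_c": 54_400,
    "t_d": 205_000, "t_e": 244_000, "t_f": 483_000,
}

DEFAULT_SIZE_PRIOR = PriorSpec(100.0, 1e6)
DEFAULT_TIME_PRIOR = PriorSpec(10.0, 6e5)


def default_loci(generation_time_years: float = 1.0) -> list[LocusSpec]:
    """The four-locus design: one mtDNA locus and three nuclear introns.

    The mtDNA mutation rate derives from a sequence divergence rate of 1%
    per million years (0.5% per lineage), i.e. 5e-9 per site per year,
    scaled by the generation time; the nuclear default is 1e-9 per site per
    year (no published rate exists for these introns).
    """
    g = generation_time_years
    mt = 5e-9 * g
    nuc = 1e-9 * g
    return [
        LocusSpec("CYTB", 433, inheritance_scalar=0.25, mu_site_gen=mt, copies_per_individual=1),
        LocusSpec("ATPSa", 881, inheritance_scalar=1.0, mu_site_gen=nuc, copies_per_individual=2),
        LocusSpec("ATPSb", 612, inheritance_scalar=1.0, mu_site_gen=nuc, copies_per_individual=2),
        LocusSpec("APN54", 597, inheritance_scalar=1.0, mu_site_gen=nuc, copies_per_individual=2),
    ]


def default_design() -> SamplingDesign:
    return SamplingDesign(dict(MULTILOCUS_SAMPLE_SIZES))


def _scenario(
    sid: str,
    events: Sequence[MergeEvent],
    extra_constraints: Sequence[tuple[str, str]] = (),
    description: str = "",
    size_prior: PriorSpec = DEFAULT_SIZE_PRIOR,
    time_prior: PriorSpec = DEFAULT_TIME_PRIOR,
) -> ScenarioSpec:
    size_param = {p: f"N_{p}" for p in _POPS}
    priors: dict[str, PriorSpec] = {f"N_{p}": size_prior for p in _POPS}
    for e in events:
        priors[e.time_param] = time_prior
    return ScenarioSpec(
        id=sid,
        populations=_POPS,
        events=tuple(events),
        size_param=size_param,
        priors=priors,
        ordering_constraints=tuple(extra_constraints),
        description=description,
    )


def builtin_scenarios(
    size_prior: PriorSpec = DEFAULT_SIZE_PRIOR,
    time_prior: PriorSpec = DEFAULT_TIME_PRIOR,
) -> list[ScenarioSpec]:
    """The four competing biogeographic histories.

    1. Single colonization of the NEP from Kamchatka (PET): the NEP clade
       {KOD, COR, JUN} merges into the PET lineage once.
    2. Two colonizations: {KOD} and {COR, JUN} merge into PET independently.
    3. Reverse direction: PET derives from the NEP ancestral lineage.
    4. Null: the NEP clade is sister to all NWP populations (joins at the
       root), with no special tie to PET.
    """
    kw = dict(size_prior=size_prior, time_prior=time_prior)
    s1 = _scenario(
        "scenario1",
        [
            MergeEvent("t_a", "KOD", "COR"),
            MergeEvent("t_b", "JUN", "COR"),
            MergeEvent("t_c", "COR", "PET"),
            MergeEvent("t_d", "STA", "ERI"),
            MergeEvent("t_e", "PET", "ERI"),
            MergeEvent("t_f", "KHO", "ERI"),
        ],
        extra_constraints=[("t_a", "t_b"), ("t_d", "t_f"), ("t_e", "t_f")],
        description="single NWP(PET) -> NEP colonization",
        **kw,
    )
    s2 = _scenario(
        "scenario2",
        [
            MergeEvent("t_a", "JUN", "COR"),
            MergeEvent("t_b", "COR", "PET"),
            MergeEvent("t_c", "KOD", "PET"),
            MergeEvent("t_d", "STA", "ERI"),
            MergeEvent("t_e", "PET", "ERI"),
            MergeEvent("t_f", "KHO", "ERI"),
        ],
        extra_constraints=[("t_d", "t_f"), ("t_e", "t_f")],
        description="two independent NWP(PET) -> NEP colonizations",
        **kw,
    )
    s3 = _scenario(
        "scenario3",
        [
            MergeEvent("t_a", "KOD", "COR"),
            MergeEvent("t_b", "JUN", "COR"),
            MergeEvent("t_c", "PET", "COR"),
            MergeEvent("t_d", "STA", "ERI"),
            MergeEvent("t_e", "COR", "ERI"),
            MergeEvent("t_f", "KHO", "ERI"),
        ],
        extra_constraints=[("t_a", "t_b"), ("t_d", "t_f"), ("t_e", "t_f")],
        description="PET colonized from the NEP ancestor",
        **kw,
    )
    s4 = _scenario(
        "scenario4",
        [
            MergeEvent("t_a", "KOD", "COR"),
            MergeEvent("t_b", "JUN", "COR"),
            MergeEvent("t_d", "STA", "ERI"),
            MergeEvent("t_e", "PET", "ERI"),
            MergeEvent("t_f", "KHO", "ERI"),
            MergeEvent("t_g", "COR", "ERI"),
        ],
        extra_constraints=[
            ("t_a", "t_b"), ("t_d", "t_g"), ("t_e", "t_g"), ("t_f", "t_g"),
        ],
        description="null: NEP clade sister to all NWP populations",
        **kw,
    )
    return [s1, s2, s3, s4]


# ---------------------------------------------------------------------------
# parameter draws


def draw_parameters(
    scenario: ScenarioSpec,
    rng_seed: int | np.random.Generator,
    max_rejections: int = 100_000,
) -> ParameterDraw:
    """Independent uniform draws; draws violating the scenario's ordering
    constraints are rejected and redrawn."""
    if isinstance(rng_seed, np.random.Generator):
        rng, seed = rng_seed, -1
    else:
        rng, seed = np.random.default_rng(rng_seed), int(rng_seed)
    params = scenario.parameters
    constraints = scenario.all_constraints()
    for p in params:
        if p not in scenario.priors:
            raise PriorSpecificationError(f"{scenario.id}: no prior for {p!r}")
    idx = {p: i for i, p in enumerate(params)}
    lows = np.array([scenario.priors[p].lower for p in params])
    spans = np.array([scenario.priors[p].upper - scenario.priors[p].lower for p in params])
    cpairs = [(idx[a], idx[b]) for a, b in constraints]
    for _ in range(max_rejections):
        v = lows + rng.random(len(params)) * spans
        if all(v[a] < v[b] for a, b in cpairs):
            return ParameterDraw(scenario.id, dict(zip(params, v.tolist())), seed)
    raise PriorSpecificationError(
        f"{scenario.id}: no draw satisfied {constraints} in {max_rejections} tries"
    )


# ---------------------------------------------------------------------------
# the coalescent


def child_rng(master_seed: int, counter: int) -> np.random.Generator:
    """Documented counter scheme: child generator i of a master seed is
    seeded from ``SeedSequence((master_seed, counter))``."""
    return np.random.default_rng(np.random.SeedSequence((master_seed, counter)))


def _coalesce_branch(
    lineages: list[tuple[int, "np.ndarray | None"]],
    rate_pair: float,
    t_start: float,
    t_end: float,
    nodes_time: list[float],
    parent_of: dict[int, int],
    next_id: list[int],
    rng: np.random.Generator,
) -> float:
    """Coalesce a branch's lineages over [t_start, t_end); returns final time."""
    t = t_start
    while len(lineages) > 1:
        k = len(lineages)
        total_rate = rate_pair * k * (k - 1) / 2.0
        t_next = t - math.log(rng.random()) / total_rate
        if t_next >= t_end:
            return t_end
        t = t_next
        i = int(rng.random() * k)
        j = int(rng.random() * (k - 1))
        if j >= i:
            j += 1
        a = lineages[max(i, j)]
        b = lineages[min(i, j)]
        del lineages[max(i, j)]
        del lineages[min(i, j)]
        new = next_id[0]
        next_id[0] += 1
        nodes_time.append(t)
        parent_of[a[0]] = new
        parent_of[b[0]] = new
        lineages.append((new, None))
    return t_end


def _simulate_genealogy(
    scenario: ScenarioSpec,
    draw: ParameterDraw,
    locus: LocusSpec,
    copies: Mapping[str, int],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Simulate one gene genealogy.

    Returns (parent array, node time array, leaf population labels).
    Leaves are numbered 0..n-1 in population order.
    """
    vals = draw.values
    pop_order = [p for p in scenario.populations if copies.get(p, 0) > 0]
    n = sum(copies[p] for p in pop_order)
    leaf_pop: list[str] = []
    branch_lineages: dict[str, list[tuple[int, None]]] = {p: [] for p in scenario.populations}
    nid = 0
    for p in pop_order:
        for _ in range(copies[p]):
            branch_lineages[p].append((nid, None))
            leaf_pop.append(p)
            nid += 1
    nodes_time: list[float] = [0.0] * n
    parent_of: dict[int, int] = {}
    next_id = [n]

    def pair_rate(branch: str) -> float:
        N = vals[scenario.size_param[branch]]
        return 1.0 / (locus.inheritance_scalar * 2.0 * N)

    events = sorted(scenario.events, key=lambda e: vals[e.time_param])
    t_cur = 0.0
    for ev in events:
        t_ev = vals[ev.time_param]
        for br, lin in branch_lineages.items():
            if len(lin) > 1:
                _coalesce_branch(
                    lin, pair_rate(br), t_cur, t_ev, nodes_time, parent_of, next_id, rng
                )
        branch_lineages[ev.dest].extend(branch_lineages[ev.source])
        branch_lineages[ev.source] = []
        t_cur = t_ev
    root = scenario.root
    _coalesce_branch(
        branch_lineages[root],
        pair_rate(root),
        t_cur,
        math.inf,
        nodes_time,
        parent_of,
        next_id,
        rng,
    )
    n_nodes = next_id[0]
    parent = np.full(n_nodes, -1, dtype=np.int64)
    for c, p in parent_of.items():
        parent[c] = p
    return parent, np.asarray(nodes_time), leaf_pop


def _drop_mutations(
    parent: np.ndarray,
    times: np.ndarray,
    n_leaves: int,
    locus: LocusSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Poisson mutations on the genealogy under infinite sites.

    Returns (genotype matrix n_leaves x n_mut of 0/1, 1-based site
    positions, finite_sites_fallback flag).  When the number of mutations
    exceeds the locus length, sites are re-used (finite-sites fallback) and
    repeated hits at a site toggle the state.
    """
    n_nodes = len(parent)
    has_parent = parent >= 0
    lengths = np.zeros(n_nodes)
    lengths[has_parent] = times[parent[has_parent]] - times[np.nonzero(has_parent)[0]]
    total_len = lengths.sum()
    u = locus.mu_locus_gen
    n_mut = int(rng.poisson(u * total_len))
    if n_mut == 0:
        return np.zeros((n_leaves, 0), dtype=np.uint8), np.zeros(0, dtype=int), False
    edge_nodes = np.nonzero(has_parent)[0]
    cum = np.cumsum(lengths[edge_nodes])
    hit_nodes = edge_nodes[np.searchsorted(cum, rng.random(n_mut) * total_len)]
    fallback = n_mut > locus.length_bp
    if fallback:
        sites = rng.integers(0, locus.length_bp, size=n_mut)
    else:
        # rejection sampling of distinct sites; n_mut << length_bp in practice
        sites = np.unique(rng.integers(0, locus.length_bp, size=n_mut))
        while len(sites) < n_mut:
            extra = rng.integers(0, locus.length_bp, size=n_mut - len(sites))
            sites = np.unique(np.concatenate([sites, extra]))
        rng.shuffle(sites)  # decouple site order from node assignment order
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    for c in edge_nodes:
        children[parent[c]].append(int(c))
    # collapse mutations at the same site (only possible in fallback mode)
    uniq_sites, inverse = np.unique(sites, return_inverse=True)
    mat = np.zeros((n_leaves, len(uniq_sites)), dtype=np.uint8)
    for m in range(n_mut):
        col = inverse[m]
        stack = [int(hit_nodes[m])]
        while stack:
            v = stack.pop()
            if v < n_leaves:
                mat[v, col] ^= 1
            else:
                stack.extend(children[v])
    order = np.argsort(uniq_sites)
    return mat[:, order], uniq_sites[order] + 1, fallback


def simulate_locus_matrix(
    scenario: ScenarioSpec,
    draw: ParameterDraw,
    locus: LocusSpec,
    design: SamplingDesign,
    rng_seed: int | np.random.Generator,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Fast path: simulate one locus and return the variant matrix.

    Returns (0/1 genotype matrix, per-copy population labels, 1-based
    positions of the variant sites).  This is what the ABC reference-table
    builder consumes; :func:`simulate_locus` wraps it into full sequences.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    for p in scenario.populations:
        if p not in design.individuals:
            raise ValueError(f"design missing population {p!r}")
    copies = {p: design.gene_copies(p, locus) for p in scenario.populations}
    parent, times, leaf_pop = _simulate_genealogy(scenario, draw, locus, copies, rng)
    mat, positions, _ = _drop_mutations(parent, times, len(leaf_pop), locus, rng)
    return mat, leaf_pop, positions


def _matrix_to_records(
    mat: np.ndarray,
    positions: np.ndarray,
    leaf_pop: list[str],
    locus: LocusSpec,
    region_of: Mapping[str, str],
) -> list[SeqRecordEntry]:
    n = len(leaf_pop)
    base = np.full((n, locus.length_bp), ord("A"), dtype=np.uint8)
    if len(positions):
        cols = positions - 1
        derived = mat.astype(bool)
        for j, c in enumerate(cols):
            base[derived[:, j], c] = ord("G")
    records: list[SeqRecordEntry] = []
    counters: dict[str, int] = {}
    for i in range(n):
        pop = leaf_pop[i]
        c = counters.get(pop, 0)
        counters[pop] = c + 1
        ind_idx, allele = divmod(c, locus.copies_per_individual)
        records.append(
            SeqRecordEntry(
                individual=f"{pop}_{ind_idx + 1:03d}",
                population=pop,
                region=region_of.get(pop, "NWP"),
                sequence=base[i].tobytes().decode(),
                allele_index=allele,
            )
        )
    return records


def simulate_locus(
    scenario: ScenarioSpec,
    draw: ParameterDraw,
    locus: LocusSpec,
    design: SamplingDesign,
    rng_seed: int | np.random.Generator,
    region_of: Mapping[str, str] | None = None,
) -> list[SeqRecordEntry]:
    """Simulate one locus as full {A, G}-encoded panel records."""
    mat, leaf_pop, positions = simulate_locus_matrix(scenario, draw, locus, design, rng_seed)
    return _matrix_to_records(mat, positions, leaf_pop, locus, region_of or REGION_OF_POP)


def simulate_dataset(
    scenario: ScenarioSpec,
    draw: ParameterDraw,
    loci: Sequence[LocusSpec],
    design: SamplingDesign,
    rng_seed: int,
    region_of: Mapping[str, str] | None = None,
) -> SequencePanel:
    """Independent coalescent realizations per locus, bundled into a panel."""
    records = {}
    for i, locus in enumerate(loci):
        rng = child_rng(rng_seed, i)
        records[locus.name] = simulate_locus(
            scenario, draw, locus, design, rng, region_of=region_of
        )
    return SequencePanel(loci=list(loci), records=records)
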