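"""Finite-n stochastic simulator for two successive epidemics.

Each replicate builds a fresh configuration-model graph (i.i.d. degrees,
uniform half-edge pairing, self-loops dropped and parallel edges merged),
runs the first epidemic as bond percolation from a uniform seed, then the
second epidemic as a discrete-generation (Reed-Frost) process whose
directed per-pair contact probabilities depend on both endpoints'
first-epidemic history through the immunity model.  An epidemic is
"large" when its size (seed included) exceeds a cutoff; the defaults
follow the convention 100 / 200 / 300 for n = 500 / 1000 / >= 5000.

Estimators: p_maj_hat is the fraction of replicates with a large first
epidemic whose second epidemic is also large (binomial standard error);
z_maj_hat is the mean infected fraction over those large second
epidemics (sample standard error).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .degrees import DegreeDistribution
from .immunity import ImmunityModel

__all__ = [
    "SimConfig",
    "SimResult",
    "Graph",
    "default_cutoff",
    "build_configuration_graph",
    "simulate_first_epidemic",
    "simulate_second_epidemic",
    "run_study",
]


def default_cutoff(n: int) -> int:
    """Large-outbreak size cutoff by population size: 100 (n<=500),
    200 (n<=1000), 300 otherwise."""
    if n <= 500:
        return 100
    if n <= 1000:
        return 200
    return 300


@dataclass(frozen=True)
class Graph:
    """Simple undirected graph in CSR adjacency form plus an edge list."""

    n: int
    edges: np.ndarray  # (m, 2) int array, u < v, unique
    indptr: np.ndarray
    indices: np.ndarray
    n_removed: int = 0  # self-loops dropped + parallel edges merged

    @property
    def m(self) -> int:
        return len(self.edges)

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.m / self.n

    def neighbours(self, u: int) -> np.ndarray:
        return self.indices[self.indptr[u] : self.indptr[u + 1]]


def build_configuration_graph(
    n: int, dist: DegreeDistribution, rng: np.random.Generator
) -> Graph:
    """Configuration model: i.i.d. degrees, uniform random pairing of
    half-edges (one leftover half-edge dropped if the total is odd),
    self-loops removed and parallel edges merged."""
    if n < 2:
        raise ValueError("n must be >= 2")
    degrees = dist.sample(n, rng)
    stubs = np.repeat(np.arange(n, dtype=np.int64), degrees)
    rng.shuffle(stubs)
    if len(stubs) % 2 == 1:
        stubs = stubs[:-1]
    pairs = stubs.reshape(-1, 2)
    n_raw = len(pairs)
    pairs = pairs[pairs[:, 0] != pairs[:, 1]]  # self-loops
    lo = np.minimum(pairs[:, 0], pairs[:, 1])
    hi = np.maximum(pairs[:, 0], pairs[:, 1])
    key = lo * n + hi
    _, keep = np.unique(key, return_index=True)  # merge parallel edges
    edges = np.column_stack([lo[keep], hi[keep]])
    n_removed = n_raw - len(edges)
    # CSR adjacency from both edge directions
    src = np.concatenate([edges[:, 0], edges[:, 1]])
    dst = np.concatenate([edges[:, 1], edges[:, 0]])
    order = np.argsort(src, kind="stable")
    indices = dst[order]
    counts = np.bincount(src, minlength=n)
    indptr = np.concatenate([[0], np.cumsum(counts)])
    return Graph(
        n=n, edges=edges, indptr=indptr, indices=indices, n_removed=n_removed
    )


def simulate_first_epidemic(
    graph: Graph, p1: float, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Bond percolation: retain each edge with probability p1; the infected
    set is the retained-graph component of a uniform seed.  Returns the
    boolean infected mask and the seed vertex."""
    if not 0.0 <= p1 <= 1.0:
        raise ValueError("p1 must lie in [0, 1]")
    seed = int(rng.integers(graph.n))
    if graph.m == 0 or p1 == 0.0:
        infected = np.zeros(graph.n, dtype=bool)
        infected[seed] = True
        return infected, seed
    keep = rng.random(graph.m) < p1
    e = graph.edges[keep]
    data = np.ones(len(e), dtype=np.int8)
    adj = csr_matrix(
        (data, (e[:, 0], e[:, 1])), shape=(graph.n, graph.n)
    )
    _, labels = connected_components(adj, directed=False)
    return labels == labels[seed], seed


def _choose_second_seed(
    first_infected: np.ndarray,
    susceptible: np.ndarray,
    im: ImmunityModel,
    rng: np.random.Generator,
) -> int | None:
    """Second-epidemic seeding.

    Polarized: uniform among remaining susceptibles.  Leaky: uniform from
    the whole population with an alpha_S rejection loop for prior cases.
    General: uniform from the whole population.
    """
    n = len(first_infected)
    if im.kind == "polarized":
        cand = np.flatnonzero(susceptible)
        if len(cand) == 0:
            return None
        return int(cand[rng.integers(len(cand))])
    if im.kind in ("leaky_multiplicative", "leaky_rates"):
        while True:
            i = int(rng.integers(n))
            if not first_infected[i] or rng.random() < im.alpha_S:
                return i
    return int(rng.integers(n))


def simulate_second_epidemic(
    graph: Graph,
    first_infected: np.ndarray,
    im: ImmunityModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int | None, bool]:
    """Discrete-generation second epidemic on the percolated history.

    Polarized: each prior case is immune once-for-all with probability
    1 - alpha; every directed infectious->susceptible attempt succeeds
    with probability p'.  Leaky/general: each ordered pair (u, v) with u
    infectious and v susceptible is resolved once with probability
    pi[a(u), a(v)], a(.) the first-epidemic indicator.  The chosen seed
    is infected unconditionally.

    Returns (infected mask, seed or None if everyone is immune,
    seed-was-prior-case flag).
    """
    n = graph.n
    a = first_infected.astype(np.int8)
    if im.kind == "polarized":
        immune = first_infected & (rng.random(n) >= im.alpha)
        pimat = np.full((2, 2), im.p_prime)
    else:
        immune = np.zeros(n, dtype=bool)
        pimat = im.pi_matrix
    susceptible = ~immune
    seed = _choose_second_seed(first_infected, susceptible, im, rng)
    infected = np.zeros(n, dtype=bool)
    if seed is None:
        return infected, None, False
    infected[seed] = True
    susceptible[seed] = False
    frontier = np.array([seed], dtype=np.int64)
    indptr, indices = graph.indptr, graph.indices
    while len(frontier):
        starts = indptr[frontier]
        counts = indptr[frontier + 1] - starts
        total = int(counts.sum())
        if total == 0:
            break
        shift = np.repeat(
            starts - np.concatenate([[0], np.cumsum(counts)[:-1]]), counts
        )
        targets = indices[shift + np.arange(total)]
        src_a = np.repeat(a[frontier], counts)
        open_mask = susceptible[targets]
        targets = targets[open_mask]
        src_a = src_a[open_mask]
        if len(targets) == 0:
            break
        probs = pimat[src_a, a[targets]]
        hits = targets[rng.random(len(targets)) < probs]
        new = np.unique(hits)
        if len(new) == 0:
            break
        infected[new] = True
        susceptible[new] = False
        frontier = new
    return infected, seed, bool(first_infected[seed])


@dataclass(frozen=True)
class SimConfig:
    """Two-epidemic simulation study settings."""

    n: int
    dist: DegreeDistribution
    p1: float
    immunity: ImmunityModel
    replicates: int = 1000
    cutoff_first: int | None = None
    cutoff_second: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for c in (self.cutoff_first, self.cutoff_second):
            if c is not None and c < 1:
                raise ValueError("cutoffs must be >= 1")


@dataclass(frozen=True)
class SimResult:
    """Estimates with standard errors and the per-replicate record.

    ``records`` columns: replicate, size1, large1, seed2_prior_case,
    size2, large2.
    """

    p_maj_hat: float
    p_maj_se: float
    z_maj_hat: float
    z_maj_se: float
    n_large_first: int
    n_large_second: int
    n_replicates: int
    estimates_defined: bool
    records: np.ndarray = field(repr=False)


def run_study(cfg: SimConfig) -> SimResult:
    """Run the replicate loop: fresh graph, first epidemic, second epidemic.

    Per-replicate RNG streams are spawned deterministically from the
    master seed, so results are reproducible and order-independent.
    """
    c1 = cfg.cutoff_first if cfg.cutoff_first is not None else default_cutoff(cfg.n)
    c2 = cfg.cutoff_second if cfg.cutoff_second is not None else default_cutoff(cfg.n)
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.replicates)
    rec = np.zeros(
        cfg.replicates,
        dtype=[
            ("replicate", np.int64),
            ("size1", np.int64),
            ("large1", bool),
            ("seed2_prior_case", bool),
            ("size2", np.int64),
            ("large2", bool),
        ],
    )
    for r in range(cfg.replicates):
        rng = np.random.default_rng(streams[r])
        graph = build_configuration_graph(cfg.n, cfg.dist, rng)
        inf1, _ = simulate_first_epidemic(graph, cfg.p1, rng)
        size1 = int(inf1.sum())
        inf2, seed2, seed_prior = simulate_second_epidemic(
            graph, inf1, cfg.immunity, rng
        )
        size2 = int(inf2.sum())
        rec[r] = (r, size1, size1 > c1, seed_prior, size2, size2 > c2)

    large1 = rec["large1"]
    m1 = int(large1.sum())
    both = rec["large1"] & rec["large2"]
    m2 = int(both.sum())
    if m1 == 0:
        return SimResult(
            p_maj_hat=np.nan, p_maj_se=np.nan, z_maj_hat=np.nan, z_maj_se=np.nan,
            n_large_first=0, n_large_second=0, n_replicates=cfg.replicates,
            estimates_defined=False, records=rec,
        )
    p_hat = m2 / m1
    p_se = float(np.sqrt(p_hat * (1.0 - p_hat) / m1))
    if m2 > 0:
        fracs = rec["size2"][both] / cfg.n
        z_hat = float(fracs.mean())
        z_se = float(fracs.std(ddof=1) / np.sqrt(m2)) if m2 > 1 else np.nan
    else:
        z_hat, z_se = np.nan, np.nan
    return SimResult(
        p_maj_hat=float(p_hat),
        p_maj_se=p_se,
        z_maj_hat=z_hat,
        z_maj_se=z_se,
        n_large_first=m1,
        n_large_second=m2,
        n_replicates=cfg.replicates,
        estimates_defined=True,
        records=rec,
    )
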