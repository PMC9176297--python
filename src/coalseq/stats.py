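"""Summary statistics and the statistical validation harness.

Site statistics are computed by genotype propagation; branch statistics by
tree traversal.  The validation harness runs registered suites of
replicate simulations and compares their Monte-Carlo means against
analytic population-genetic expectations, with 3-standard-error
tolerances and fixed seeds, writing a machine-readable report.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import ancestry, mutations
from . import tables as tbl

__all__ = [
    "segregating_sites",
    "pairwise_diversity",
    "sfs",
    "tmrca",
    "num_trees",
    "total_branch_length",
    "total_edge_area",
    "ValidationReport",
    "run_validation",
]


def segregating_sites(t: tbl.TableCollection) -> int:
    """Number of sites at which the samples carry more than one allele."""
    if not t.samples:
        raise ValueError("tables have no samples")
    count = 0
    for sid in range(len(t.sites)):
        if len(set(tbl.site_genotypes(t, sid))) > 1:
            count += 1
    return count


def pairwise_diversity(t: tbl.TableCollection) -> float:
    """Mean number of pairwise differences between sample genomes."""
    samples = t.samples
    n = len(samples)
    if n < 2:
        raise ValueError("need at least two samples")
    tot = 0.0
    for sid in range(len(t.sites)):
        g = tbl.site_genotypes(t, sid)
        from collections import Counter
        counts = Counter(g)
        same = sum(c * (c - 1) / 2 for c in counts.values())
        tot += n * (n - 1) / 2 - same
    return tot / (n * (n - 1) / 2)


def sfs(t: tbl.TableCollection) -> np.ndarray:
    """Unfolded site frequency spectrum: xi[i-1] = #sites with i derived
    copies (i = 1..n-1); multi-allelic sites count all non-ancestral
    alleles."""
    n = len(t.samples)
    out = np.zeros(n - 1, dtype=int)
    for sid, site in enumerate(t.sites):
        g = tbl.site_genotypes(t, sid)
        k = sum(1 for a in g if a != site.ancestral_state)
        if 0 < k < n:
            out[k - 1] += 1
    return out


def tmrca(t: tbl.TableCollection, position: float) -> float:
    return tbl.tree_at(t, position).tmrca()


def num_trees(t: tbl.TableCollection) -> int:
    return sum(1 for _ in tbl.iterate_trees(t))


def total_branch_length(t: tbl.TableCollection, position: float) -> float:
    return tbl.tree_at(t, position).total_branch_length()


def total_edge_area(t: tbl.TableCollection) -> float:
    """Sum over edges of span times duration (the mutational target)."""
    return sum(
        (e.right - e.left) * (t.nodes[e.parent].time - t.nodes[e.child].time)
        for e in t.edges
    )


# ---------------------------------------------------------------------------
# validation harness
# ---------------------------------------------------------------------------

@dataclass
class Check:
    name: str
    statistic: float
    expectation: float
    tolerance: float
    passed: bool
    replicates: int
    seed: int


@dataclass
class ValidationReport:
    suite: str
    seed: int
    checks: list

    @property
    def all_passed(self):
        return all(c.passed for c in self.checks)

    def to_json(self) -> str:
        return json.dumps(
            {
                "suite": self.suite,
                "seed": self.seed,
                "all_passed": self.all_passed,
                "checks": [asdict(c) for c in self.checks],
            },
            indent=2,
        )


def _mc_check(name, values, expectation, seed):
    values = np.asarray(values, dtype=float)
    mean = float(values.mean())
    se = float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else np.inf
    tol = 3 * se
    return Check(name, mean, float(expectation), tol,
                 abs(mean - expectation) <= tol, len(values), seed)


def _suite_kingman_basic(reps, seed):
    """Mean T_MRCA and Watterson's S against Kingman expectations."""
    n, N, ploidy, theta = 10, 1.0e4, 2, 10.0
    an = sum(1.0 / i for i in range(1, n))
    rng = np.random.default_rng(seed)
    tm, pair_tm, segsites = [], [], []
    mu = theta / (2 * ploidy * N)  # per-site rate giving scaled theta
    for _ in range(reps):
        s1, s2 = int(rng.integers(2**31)), int(rng.integers(2**31))
        t = ancestry.sim_ancestry(
            samples=[(0, n // ploidy)], ploidy=ploidy, population_size=N,
            sequence_length=1, discrete_genome=False, seed=s1,
        )
        tm.append(tmrca(t, 0))
        pair = ancestry.sim_ancestry(
            samples=[(0, 1)], ploidy=2, population_size=N,
            sequence_length=1, seed=s2,
        )
        pair_tm.append(tmrca(pair, 0))
        mt = mutations.sim_mutations(
            t, mutations.MutationParams(rate=mu, seed=s1, discrete=False)
        )
        segsites.append(segregating_sites(mt))
    checks = [
        _mc_check("mean_tmrca", tm, 2 * ploidy * N * (1 - 1 / n), seed),
        _mc_check("mean_pair_tmrca", pair_tm, ploidy * N, seed),
        _mc_check("watterson_segsites", segsites, theta * an, seed),
    ]
    return checks


def _suite_bottleneck(reps, seed):
    """Pair coalescence probability inside an instantaneous bottleneck."""
    from .demography import Demography, DemographicEvent, Population

    B, N, T = 0.7, 1000.0, 5.0
    d = Demography(
        [Population("pop0", N)],
        events=[DemographicEvent(time=T, kind="BOTTLENECK",
                                 population="pop0", strength=B)],
    )
    rng = np.random.default_rng(seed)
    hits = []  # among pairs still uncoalesced when the bottleneck fires
    for _ in range(reps):
        t = ancestry.sim_ancestry(
            samples=[(0, 1)], ploidy=2, demography=d, sequence_length=1,
            seed=int(rng.integers(2**31)),
        )
        root_t = tmrca(t, 0)
        if root_t >= T:
            hits.append(1.0 if root_t == T else 0.0)
    return [_mc_check("bottleneck_pair_coal", hits, 1 - np.exp(-B), seed)]


SUITES = {
    "kingman_basic": _suite_kingman_basic,
    "bottleneck": _suite_bottleneck,
}


def run_validation(suite_name: str, reps: int = 500, seed: int = 1) -> ValidationReport:
    """Execute a registered validation suite; reproducible given the seed."""
    if suite_name not in SUITES:
        raise ValueError(f"unknown suite {suite_name!r}; have {sorted(SUITES)}")
    if reps == 0:
        return ValidationReport(suite_name, seed, [])
    checks = SUITES[suite_name](reps, seed)
    return ValidationReport(suite_name, seed, checks)
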