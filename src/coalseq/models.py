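"""Alternative ancestry models.

The ancestry engine runs Hudson's coalescent by default; the models here
plug into it: the SMC/SMC' approximations (naive rejection sampling of
common-ancestor events), the discrete-time Wright-Fisher model (DTWF),
instantaneous bottlenecks, and the Beta- and Dirac- multiple-merger
(Lambda) coalescents.  Models can be switched mid-run, e.g. some tens of
generations of DTWF followed by the standard coalescent.

Lambda-coalescent rates follow lambda_{b,k} = int_0^1 x^{k-2} (1-x)^{b-k}
Lambda(dx), normalised so that lambda_{2,2} = 1:

* BETA(alpha): Lambda is the Beta(2-alpha, alpha) distribution,
  1 < alpha < 2, giving lambda_{b,k} = B(k-alpha, b-k+alpha)/B(2-alpha, alpha).
* DIRAC(psi, c): a unit Kingman atom at 0 plus mass c at psi, giving
  lambda_{b,k} = 1[k=2] + c psi^{k-2} (1-psi)^{b-k}.

Rates are on the coalescent timescale; the engine converts to generations
by dividing by ploidy * N.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, comb

__all__ = [
    "Model",
    "HUDSON",
    "SMC",
    "SMC_PRIME",
    "DTWF",
    "BottleneckEvent",
    "smc_accept",
    "lambda_merger_rate",
    "sample_lambda_event",
    "apply_bottleneck",
    "dtwf_generation",
    "switch_model",
]


@dataclass(frozen=True)
class Model:
    kind: str                  # HUDSON | SMC | SMC_PRIME | DTWF | BETA | DIRAC
    alpha: float = None        # BETA
    psi: float = None          # DIRAC
    c: float = None            # DIRAC

    def __post_init__(self):
        if self.kind == "BETA" and not (1 < self.alpha < 2):
            raise ValueError("BETA requires 1 < alpha < 2")
        if self.kind == "DIRAC":
            if not (0 < self.psi <= 1):
                raise ValueError("DIRAC requires 0 < psi <= 1")
            if self.c is None or self.c < 0:
                raise ValueError("DIRAC requires c >= 0")
        if self.kind not in ("HUDSON", "SMC", "SMC_PRIME", "DTWF", "BETA", "DIRAC"):
            raise ValueError(f"unknown model kind {self.kind!r}")

    @property
    def is_multiple_merger(self):
        return self.kind in ("BETA", "DIRAC")


HUDSON = Model("HUDSON")
SMC = Model("SMC")
SMC_PRIME = Model("SMC_PRIME")
DTWF = Model("DTWF")


@dataclass
class BottleneckEvent:
    time: float
    population: int
    strength: float  # B, the imaginary coalescence duration


# ---------------------------------------------------------------------------
# SMC / SMC'
# ---------------------------------------------------------------------------

def smc_accept(a, b, variant: str) -> bool:
    """Whether a candidate common-ancestor pair is accepted.

    Under SMC only pairs with overlapping ancestral material coalesce;
    SMC' additionally accepts pairs that are adjacent (share a breakpoint).
    Rejected candidates advance time without merging.
    """
    ends_a = [(s.left, s.right) for s in a.segments]
    ends_b = [(s.left, s.right) for s in b.segments]
    overlap = any(l1 < r2 and l2 < r1 for l1, r1 in ends_a for l2, r2 in ends_b)
    if overlap:
        return True
    if variant == "SMC_PRIME":
        return any(
            r1 == l2 or r2 == l1 for l1, r1 in ends_a for l2, r2 in ends_b
        )
    if variant != "SMC":
        raise ValueError(f"unknown SMC variant {variant!r}")
    return False


# ---------------------------------------------------------------------------
# Lambda coalescents
# ---------------------------------------------------------------------------

def lambda_merger_rate(b: int, k: int, model: Model) -> float:
    """Rate lambda_{b,k} at which a fixed set of k out of b lineages merges."""
    if not (2 <= k <= b):
        raise ValueError("need 2 <= k <= b")
    if model.kind == "BETA":
        a = model.alpha
        return float(np.exp(betaln(k - a, b - k + a) - betaln(2 - a, a)))
    if model.kind == "DIRAC":
        psi, c = model.psi, model.c
        atom = c * psi ** (k - 2) * (1 - psi) ** (b - k)
        return float((1.0 if k == 2 else 0.0) + atom)
    if model.kind in ("HUDSON", "SMC", "SMC_PRIME"):
        return 1.0 if k == 2 else 0.0
    raise ValueError(f"{model.kind} has no Lambda measure")


def lambda_total_rate(b: int, model: Model) -> float:
    """Total merger rate sum_k C(b,k) lambda_{b,k} (coalescent timescale)."""
    return float(sum(
        comb(b, k, exact=True) * lambda_merger_rate(b, k, model)
        for k in range(2, b + 1)
    ))


def lambda_event_pmf(b: int, model: Model) -> np.ndarray:
    """P(merger size = k), k = 2..b, for the next event among b lineages."""
    w = np.array([
        comb(b, k, exact=True) * lambda_merger_rate(b, k, model)
        for k in range(2, b + 1)
    ])
    return w / w.sum()


def sample_lambda_event(b: int, model: Model, rng: np.random.Generator) -> int:
    """Draw the number of lineages k merging in the next Lambda event."""
    if b < 2:
        raise ValueError("need at least two lineages")
    if b == 2:
        return 2
    pmf = lambda_event_pmf(b, model)
    return 2 + int(rng.choice(len(pmf), p=pmf))


# ---------------------------------------------------------------------------
# instantaneous bottlenecks
# ---------------------------------------------------------------------------

def apply_bottleneck(state, ev) -> None:
    """Burst of coalescence: a single-locus Kingman run for imaginary time B.

    All merge nodes get the bottleneck's (real) time, so a strong bottleneck
    produces multiple-merger nodes.  Pair coalescence probability is
    1 - exp(-B).
    """
    B = float(ev.strength)
    pid = state.population_id(ev.population)
    lineages = state.lineages_in(pid, label=0)
    if B <= 0 or len(lineages) < 2:
        return
    blocks = [[lin] for lin in lineages]
    tau = 0.0
    while len(blocks) > 1:
        k = len(blocks)
        tau += state.rng.exponential(1.0 / (k * (k - 1) / 2))
        if tau > B:
            break
        i, j = sorted(state.rng.choice(k, size=2, replace=False))
        blocks[i].extend(blocks.pop(j))
    for block in blocks:
        if len(block) >= 2:
            for lin in block:
                state.remove_lineage(lin)
            merged = state.merge_lineages(block, state.time)
            if merged is not None:
                merged.population = pid
                state.insert_lineage(merged)


# ---------------------------------------------------------------------------
# discrete-time Wright-Fisher
# ---------------------------------------------------------------------------

def dtwf_generation(state) -> None:
    """One backwards generation: every genome picks a unique diploid parent.

    Per population of size N(t) diploid individuals, each lineage picks a
    uniform parent; its material is split between the parent's two haploid
    genomes by Poisson-distributed crossovers (mean = recombination map
    mass, positions map-weighted), so multiple recombinations in one
    generation are crossovers between the same two parental haploids.
    Lineages landing on the same parental haploid merge with a node at the
    next generation.
    """
    if state.ploidy != 2:
        raise ValueError("the DTWF model is defined for ploidy 2")
    t = state.time
    rng = state.rng
    rmap = state.recombination_map
    mean_crossovers = rmap.total_mass
    # migration: per-generation move probabilities
    landing = {}
    for pid in range(state.num_populations):
        lineages = list(state.lineages_in(pid, label=0))
        if not lineages:
            continue
        mig_row = state.migration_matrix[pid]
        for lin in lineages:
            dest = pid
            if mig_row.sum() > 0:
                u = rng.random()
                acc = 0.0
                for j, mj in enumerate(mig_row):
                    acc += mj
                    if u < acc:
                        dest = j
                        if state.record_migrations:
                            state.record_migration(lin, pid, j, t)
                        break
            N = int(round(state.current_size(dest)))
            if N < 1:
                raise ValueError(f"population size < 1 at generation {t}")
            parent = int(rng.integers(N))
            if mean_crossovers == 0:
                hap = int(rng.integers(2))
                lin.population = dest
                landing.setdefault((dest, parent, hap), []).append(lin)
            else:
                nx = rng.poisson(mean_crossovers)
                cuts = sorted(
                    _crossover_position(rmap, rng, state.discrete_genome)
                    for _ in range(nx)
                )
                first_hap = int(rng.integers(2))
                for hap, piece in _split_at(lin, cuts, first_hap, state):
                    piece.population = dest
                    landing.setdefault((dest, parent, hap), []).append(piece)
            state.remove_lineage(lin)
    for (dest, _, _), group in sorted(landing.items()):
        if len(group) == 1:
            state.insert_lineage(group[0])
        else:
            merged = state.merge_lineages(group, t + 1)
            if merged is not None:
                merged.population = dest
                state.insert_lineage(merged)
    state.time = t + 1


def _crossover_position(rmap, rng, discrete):
    x = rmap.position_of_mass(0.0, rng.random() * rmap.total_mass)
    if discrete:
        x = float(int(x) + 1)
        x = min(x, rmap.sequence_length)
    return x


def _split_at(lin, cuts, first_hap, state):
    """Split a lineage at crossover positions, alternating haploid copies.

    Yields ``(hap, lineage_piece)`` for the at most two non-empty pieces.
    """
    from .ancestry import Lineage, Segment

    pieces = {0: [], 1: []}
    for seg in lin.segments:
        bounds = [seg.left] + [c for c in cuts if seg.left < c < seg.right] + [seg.right]
        for l, r in zip(bounds, bounds[1:]):
            n_before = sum(1 for c in cuts if c <= l)
            hap = (first_hap + n_before) % 2
            pieces[hap].append(Segment(l, r, seg.node))
    for hap in (0, 1):
        if pieces[hap]:
            yield hap, Lineage(pieces[hap], lin.population, lin.label)


# ---------------------------------------------------------------------------

def switch_model(state, new_model: Model, at_time: float):
    """Switch the running ancestry model at ``at_time``.

    No events of the old model occur after ``at_time``; a DTWF phase leaves
    the simulation clock at an integer generation which becomes the start
    time of the new model.  Switching to the current model is a no-op.
    """
    if at_time < state.time:
        raise ValueError("cannot switch models in the past")
    if new_model == state.model:
        return state
    state.time = max(state.time, float(at_time))
    state.model = new_model
    state.event_log.append((state.time, "MODEL_SWITCH", new_model.kind))
    return state
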