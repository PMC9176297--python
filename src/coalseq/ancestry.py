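"""Backwards-in-time ancestry simulation (Hudson's algorithm and friends).

The engine tracks a set of extant *lineages*, each an ordered list of
disjoint ancestral segments (intervals of the genome inherited by at least
one sample).  Events:

* recombination splits a lineage at a breakpoint drawn from the
  recombination map over the lineage's span (including "trapped"
  non-ancestral gaps, where recombination still occurs);
* gene conversion extracts a geometrically/exponentially distributed tract
  of ancestry into an independent lineage, leaving the flanks joined;
* common-ancestor events merge two (or, under multiple-merger models,
  more) lineages, recording a node and edges wherever their ancestral
  material overlaps; intervals inherited by the whole sample reach their
  MRCA and are retired;
* migration moves lineages between populations at the demography's
  backwards rates; demographic events fire at their scheduled times.

Rates are per generation; the pairwise coalescence rate in a population of
size N is ``1/(ploidy * N)``, so "coalescent units" are ``ploidy * N``
generations.  With ``record_full_arg`` every recombination stores two
flagged nodes and every common-ancestor event a node, with unary edges, so
the complete ARG is recoverable; simplification restores the default
output.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import models as models_mod
from . import sweeps as sweeps_mod
from . import tables as tbl
from .demography import Demography, apply_demographic_event, validate_demography
from .ratemap import RateMap

__all__ = [
    "Segment",
    "Lineage",
    "AncestryParams",
    "Simulator",
    "sim_ancestry",
    "count_links",
    "recombination_event",
    "gene_conversion_event",
    "recombination_bound",
    "initialize_from_tables",
    "draw_tract_length",
]


@dataclass
class Segment:
    left: float
    right: float
    node: int


@dataclass(eq=False)
class Lineage:
    """An extant ancestor: ordered disjoint ancestral segments."""

    segments: list
    population: int = 0
    label: int = 0

    @property
    def left(self):
        return self.segments[0].left

    @property
    def right(self):
        return self.segments[-1].right

    def copy(self):
        return Lineage(
            [Segment(s.left, s.right, s.node) for s in self.segments],
            self.population,
            self.label,
        )


def count_links(lineage: Lineage, rate_map: RateMap, discrete: bool = True) -> float:
    """Recombination mass of a lineage's span, open on the left.

    The full span (including trapped gaps) contributes, but no breakpoint
    may fall at or before the first ancestral position; on discrete genomes
    the rightmost unit carries no internal breakpoint either.
    """
    if not lineage.segments:
        return 0.0
    left, right = lineage.left, lineage.right
    if discrete:
        return rate_map.mass(left, right - 1)
    return rate_map.mass(left, right)


def recombination_event(lineage: Lineage, breakpoint: float):
    """Split a lineage at a breakpoint strictly inside its span."""
    if not (lineage.left < breakpoint < lineage.right):
        raise ValueError("breakpoint must lie strictly inside the span")
    a, b = [], []
    for s in lineage.segments:
        if s.right <= breakpoint:
            a.append(s)
        elif s.left >= breakpoint:
            b.append(s)
        else:
            a.append(Segment(s.left, breakpoint, s.node))
            b.append(Segment(breakpoint, s.right, s.node))
    return (
        Lineage(a, lineage.population, lineage.label),
        Lineage(b, lineage.population, lineage.label),
    )


def gene_conversion_event(lineage: Lineage, start: float, tract_length: float):
    """Extract the ancestry inside tract ``[start, start + tract_length)``.

    Returns ``(outside, inside)``; ``inside`` is ``None`` (a no-op) when the
    tract misses the ancestral material entirely or swallows all of it.
    """
    if tract_length <= 0:
        raise ValueError("tract_length must be positive")
    end = start + tract_length
    inside, outside = [], []
    for s in lineage.segments:
        l, r = max(s.left, start), min(s.right, end)
        if l < r:
            inside.append(Segment(l, r, s.node))
        if s.left < min(s.right, start):
            outside.append(Segment(s.left, min(s.right, start), s.node))
        if max(s.left, end) < s.right:
            outside.append(Segment(max(s.left, end), s.right, s.node))
    if not inside or not outside:
        return lineage, None
    return (
        Lineage(outside, lineage.population, lineage.label),
        Lineage(inside, lineage.population, lineage.label),
    )


def draw_tract_length(rng, mean: float, discrete: bool) -> float:
    """Gene-conversion tract length: Geometric(1/mean) (discrete, support
    >= 1) or Exponential(mean) (continuous)."""
    if discrete:
        return float(rng.geometric(1.0 / mean))
    return float(rng.exponential(mean))


def recombination_bound(n: int, rho: float) -> float:
    """Upper bound on the expected number of recombination events within
    trapped ancestral material: ``rho (rho + 1) (sum_{i<n} 1/i)^2``."""
    if n < 2:
        raise ValueError("need n >= 2")
    if rho < 0:
        raise ValueError("need rho >= 0")
    h = sum(1.0 / i for i in range(1, n))
    return rho * (rho + 1.0) * h * h


# ---------------------------------------------------------------------------
# overlap counts: piecewise-constant map of pending-segment counts
# ---------------------------------------------------------------------------

class OverlapCounts:
    """How many extant segments cover each genome position.

    When the count over an interval drops to one, that interval has
    reached its MRCA and is retired from all further ancestry.
    """

    def __init__(self, L, initial):
        self.pos = [0.0, float(L)]
        self.val = [int(initial)]

    def pieces(self, left, right):
        import bisect
        out = []
        i = bisect.bisect_right(self.pos, left) - 1
        while i < len(self.val) and self.pos[i] < right:
            l = max(self.pos[i], left)
            r = min(self.pos[i + 1], right)
            if l < r:
                out.append((l, r, self.val[i]))
            i += 1
        return out

    def _split_at(self, x):
        import bisect
        i = bisect.bisect_left(self.pos, x)
        if i < len(self.pos) and self.pos[i] == x:
            return
        self.pos.insert(i, x)
        self.val.insert(i, self.val[i - 1])

    def add(self, left, right, delta):
        import bisect
        self._split_at(left)
        self._split_at(right)
        i = bisect.bisect_left(self.pos, left)
        while i < len(self.val) and self.pos[i] < right:
            self.val[i] += delta
            i += 1

    def set_zero(self, left, right):
        import bisect
        self._split_at(left)
        self._split_at(right)
        i = bisect.bisect_left(self.pos, left)
        while i < len(self.val) and self.pos[i] < right:
            self.val[i] = 0
            i += 1


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class AncestryParams:
    """Everything a replicate needs; ``seed`` makes it reproducible."""

    samples: list                       # [(population, num_individuals), ...]
    sequence_length: float = 1.0
    ploidy: int = 2
    discrete_genome: bool = True
    recombination: object = 0.0         # RateMap or uniform per-unit rate
    gene_conversion: object = 0.0       # RateMap or uniform initiation rate
    gene_conversion_tract_mean: float = None
    demography: Demography = None
    population_size: float = 1.0        # used when demography is None
    models: list = None                 # [(Model, end_time or None), ...]
    sweep: sweeps_mod.SweepParams = None
    record_full_arg: bool = False
    record_migrations: bool = False
    end_time: float = None
    seed: int = 1

    def __post_init__(self):
        if self.demography is None:
            self.demography = Demography.isolated(self.population_size)
        if self.models is None:
            self.models = [(models_mod.HUDSON, None)]
        ends = [e for _, e in self.models[:-1]]
        if any(e is None for e in ends) or ends != sorted(ends):
            raise ValueError("model schedule end times must be increasing; "
                             "only the last model may be open-ended")
        if not isinstance(self.recombination, RateMap):
            self.recombination = RateMap.uniform(
                self.sequence_length, float(self.recombination)
            )
        if not isinstance(self.gene_conversion, RateMap):
            self.gene_conversion = RateMap.uniform(
                self.sequence_length, float(self.gene_conversion)
            )
        if self.gene_conversion.total_mass > 0 and not self.gene_conversion_tract_mean:
            raise ValueError("gene conversion requires a mean tract length")


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

class Simulator:
    """Algorithm state: current time, extant lineages, tables under
    construction, and the seeded random generator."""

    def __init__(self, params: AncestryParams, tables=None, lineages=None,
                 start_time=0.0):
        self.params = params
        p = params
        bad = validate_demography(p.demography, [s[0] for s in p.samples] or None)
        if bad:
            raise ValueError(f"invalid demography: {bad}")
        self.demography = p.demography
        self.ploidy = p.ploidy
        if any(m.kind == "DTWF" for m, _ in p.models) and p.ploidy != 2:
            raise ValueError("the DTWF model is defined for ploidy 2")
        self.discrete_genome = p.discrete_genome
        self.recombination_map = p.recombination
        self.gc_map = p.gene_conversion
        self.record_full_arg = p.record_full_arg
        self.record_migrations = p.record_migrations
        self.rng = np.random.default_rng(p.seed)
        self.L = float(p.sequence_length)
        self.time = float(start_time)
        self.model = p.models[0][0]
        self.event_log = []
        self.num_re_events = 0
        self.num_trapped_re_events = 0
        self.num_ca_events = 0
        self.num_gc_events = 0
        self.gc_tract_lengths = []
        self.sweep_position = None if p.sweep is None else p.sweep.position
        self.migration_matrix = self.demography.migration_matrix.copy().astype(float)
        self.pop_state = [
            (0.0, float(pop.initial_size), float(pop.growth_rate))
            for pop in self.demography.populations
        ]
        self.lineages = {}
        if tables is None:
            self.tables = tbl.TableCollection(self.L, p.discrete_genome)
            n_genomes = 0
            for pop, count in p.samples:
                pid = self.demography.population_id(pop)
                for _ in range(int(count)):
                    nodes = []
                    for _ in range(p.ploidy):
                        u = self.tables.add_node(
                            tbl.NODE_IS_SAMPLE, 0.0, pid,
                            len(self.tables.individuals),
                        )
                        nodes.append(u)
                        self.insert_lineage(
                            Lineage([Segment(0.0, self.L, u)], pid, 0)
                        )
                        n_genomes += 1
                    self.tables.add_individual(nodes)
            if n_genomes == 0:
                raise ValueError("at least one sample is required")
            self.S = OverlapCounts(self.L, n_genomes)
            if n_genomes == 1:
                # a single genome is its own MRCA everywhere
                self.S.set_zero(0.0, self.L)
                self.lineages = {}
        else:
            self.tables = tables
            self.S = OverlapCounts(self.L, 0)
            for lin in lineages:
                self.insert_lineage(lin)
                for s in lin.segments:
                    self.S.add(s.left, s.right, 1)

    # -- lineage bookkeeping --------------------------------------------
    @property
    def num_populations(self):
        return self.demography.num_populations

    def population_id(self, x):
        return self.demography.population_id(x)

    def insert_lineage(self, lin):
        self.lineages.setdefault((lin.population, lin.label), []).append(lin)

    def remove_lineage(self, lin):
        key = (lin.population, lin.label)
        lst = self.lineages[key]
        for i, x in enumerate(lst):
            if x is lin:
                del lst[i]
                break
        else:
            raise ValueError("lineage not found")
        if not lst:
            del self.lineages[key]

    def relabel(self, lin, label):
        self.remove_lineage(lin)
        lin.label = label
        self.insert_lineage(lin)

    def lineages_in(self, population, label=0):
        return list(self.lineages.get((population, label), ()))

    def num_lineages_in(self, population, label=0):
        return len(self.lineages.get((population, label), ()))

    def all_lineages(self):
        for key in sorted(self.lineages):
            yield from self.lineages[key]

    @property
    def num_lineages(self):
        return sum(len(v) for v in self.lineages.values())

    def current_size(self, pid, at=None):
        t = self.time if at is None else at
        t0, size, growth = self.pop_state[pid]
        return size * np.exp(-growth * (t - t0))

    # -- demographic-event hooks ----------------------------------------
    def move_all_lineages(self, src, dest):
        for label in sorted({lb for (p, lb) in self.lineages if p == src}):
            for lin in self.lineages_in(src, label):
                self.remove_lineage(lin)
                if self.record_migrations:
                    self.record_migration(lin, src, dest, self.time)
                lin.population = dest
                self.insert_lineage(lin)

    def split_lineages(self, src, dests, proportions):
        cum = np.cumsum(proportions)
        for lin in self.lineages_in(src, 0):
            u = self.rng.random()
            dest = dests[int(np.searchsorted(cum, u))] if u < cum[-1] else dests[-1]
            self.remove_lineage(lin)
            if self.record_migrations:
                self.record_migration(lin, src, dest, self.time)
            lin.population = dest
            self.insert_lineage(lin)

    def pulse_lineages(self, src, dest, proportion):
        for lin in self.lineages_in(src, 0):
            if self.rng.random() < proportion:
                self.remove_lineage(lin)
                if self.record_migrations:
                    self.record_migration(lin, src, dest, self.time)
                lin.population = dest
                self.insert_lineage(lin)

    def record_migration(self, lin, src, dest, time):
        for s in lin.segments:
            self.tables.migrations.append(
                tbl.MigrationRecord(s.left, s.right, s.node, src, dest, time)
            )

    def census(self):
        for lin in list(self.all_lineages()):
            u = self.tables.add_node(
                tbl.NODE_CENSUS, self.time, lin.population
            )
            for s in lin.segments:
                self.tables.add_edge(s.left, s.right, u, s.node)
                s.node = u

    # -- merging ---------------------------------------------------------
    def merge_lineages(self, lins, time, force_node=False):
        """Merge already-removed lineages; record node/edges at overlaps.

        Returns the merged lineage carrying the remaining (non-MRCA)
        material, or ``None`` if everything coalesced fully.  With
        ``record_full_arg`` (or ``force_node``) a node is stored even if no
        material overlaps, flagged as a pass-through common ancestor.
        """
        full_arg = self.record_full_arg or force_node
        segs = [s for lin in lins for s in lin.segments]
        points = sorted({x for s in segs for x in (s.left, s.right)})
        node = None
        coalesced_anywhere = False
        if full_arg:
            node = self.tables.add_node(0, time, lins[0].population)
        carried = []
        for l, r in zip(points, points[1:]):
            cover = [s for s in segs if s.left <= l and r <= s.right]
            if not cover:
                continue
            m = len(cover)
            if m >= 2:
                coalesced_anywhere = True
                if node is None:
                    node = self.tables.add_node(0, time, lins[0].population)
                for s in sorted(cover, key=lambda s: s.node):
                    self.tables.add_edge(l, r, node, s.node)
                for (sl, sr, cnt) in self.S.pieces(l, r):
                    if cnt == m:
                        self.S.set_zero(sl, sr)  # reached the MRCA
                    else:
                        self.S.add(sl, sr, -(m - 1))
                        carried.append(Segment(sl, sr, node))
            else:
                s = cover[0]
                if full_arg:
                    self.tables.add_edge(l, r, node, s.node)
                    carried.append(Segment(l, r, node))
                else:
                    carried.append(Segment(l, r, s.node))
        if full_arg and not coalesced_anywhere:
            self.tables.nodes[node].flags |= tbl.NODE_CA_PASSTHROUGH
        self.num_ca_events += 1
        if not carried:
            return None
        merged = []
        for s in carried:
            if merged and merged[-1].node == s.node and merged[-1].right == s.left:
                merged[-1].right = s.right
            else:
                merged.append(s)
        return Lineage(merged, lins[0].population, lins[0].label)

    # -- recombination / gene conversion ---------------------------------
    def lineage_links(self, lin):
        return count_links(lin, self.recombination_map, self.discrete_genome)

    def total_recombination_mass(self):
        return sum(self.lineage_links(lin) for lin in self.all_lineages())

    def lineage_gc_mass(self, lin):
        return count_links(lin, self.gc_map, self.discrete_genome)

    def total_gc_mass(self):
        return sum(self.lineage_gc_mass(lin) for lin in self.all_lineages())

    def _pick_lineage(self, mass_fn, total):
        u = self.rng.random() * total
        for lin in self.all_lineages():
            w = mass_fn(lin)
            if u < w:
                return lin
            u -= w
        return lin  # numerical slack: last positive-mass lineage

    def _draw_breakpoint(self, lin, rate_map):
        left, right = lin.left, lin.right
        if self.discrete_genome:
            total = rate_map.mass(left, right - 1)
            x = rate_map.position_of_mass(left, self.rng.random() * total)
            bp = float(int(x) + 1)
            return min(bp, right - 1)
        total = rate_map.mass(left, right)
        return rate_map.position_of_mass(left, self.rng.random() * total)

    def recombination_event(self):
        """Execute one recombination event; returns the two lineages."""
        total = self.total_recombination_mass()
        lin = self._pick_lineage(self.lineage_links, total)
        bp = self._draw_breakpoint(lin, self.recombination_map)
        trapped = not any(s.left < bp < s.right for s in lin.segments)
        self.num_re_events += 1
        if trapped:
            self.num_trapped_re_events += 1
        self.remove_lineage(lin)
        a, b = recombination_event(lin, bp)
        if self.record_full_arg:
            for piece in (a, b):
                w = self.tables.add_node(
                    tbl.NODE_RECOMB_EVENT, self.time, piece.population
                )
                for s in piece.segments:
                    self.tables.add_edge(s.left, s.right, w, s.node)
                    s.node = w
        self.insert_lineage(a)
        self.insert_lineage(b)
        self.event_log.append((self.time, "RE", bp))
        return a, b

    def gc_event(self):
        total = self.total_gc_mass()
        lin = self._pick_lineage(self.lineage_gc_mass, total)
        start = self._draw_breakpoint(lin, self.gc_map)
        length = draw_tract_length(
            self.rng, self.params.gene_conversion_tract_mean, self.discrete_genome
        )
        self.gc_tract_lengths.append(length)
        self.num_gc_events += 1
        outside, inside = gene_conversion_event(lin, start, length)
        self.event_log.append((self.time, "GC", (start, length)))
        if inside is None:
            return
        self.remove_lineage(lin)
        self.insert_lineage(outside)
        self.insert_lineage(inside)

    def migration_event(self):
        rows = self.migration_matrix.sum(axis=1)
        weights = []
        for (pid, label), lst in sorted(self.lineages.items()):
            weights.append(((pid, label), len(lst) * rows[pid]))
        total = sum(w for _, w in weights)
        u = self.rng.random() * total
        for (pid, label), w in weights:
            if u < w:
                break
            u -= w
        lst = self.lineages[(pid, label)]
        lin = lst[int(self.rng.integers(len(lst)))]
        row = self.migration_matrix[pid]
        dest = int(self.rng.choice(len(row), p=row / row.sum()))
        self.remove_lineage(lin)
        if self.record_migrations:
            self.record_migration(lin, pid, dest, self.time)
        lin.population = dest
        self.insert_lineage(lin)
        self.event_log.append((self.time, "MIG", (pid, dest)))

    # -- common ancestor events ------------------------------------------
    def _coalescence_waiting_time(self, pid, label):
        """Closed-form inversion of the integrated hazard, growth-aware."""
        k = self.num_lineages_in(pid, label)
        if k < 2:
            return np.inf
        t0, size, growth = self.pop_state[pid]
        p = self.ploidy
        if self.model.is_multiple_merger:
            rate = models_mod.lambda_total_rate(k, self.model) / (
                p * self.current_size(pid)
            )
            return self.rng.exponential(1.0 / rate)
        pairs = k * (k - 1) / 2
        E = self.rng.exponential()
        if growth == 0:
            return E * p * size / pairs
        arg = 1.0 + E * growth * p * size * np.exp(-growth * (self.time - t0)) / pairs
        if arg <= 0:
            return np.inf
        return np.log(arg) / growth

    def common_ancestor_event(self, pid, label):
        lst = self.lineages[(pid, label)]
        i, j = self.rng.choice(len(lst), size=2, replace=False)
        a, b = lst[int(i)], lst[int(j)]
        if self.model.kind in ("SMC", "SMC_PRIME"):
            if not models_mod.smc_accept(a, b, self.model.kind):
                self.event_log.append((self.time, "CA_REJECT", label))
                return
        self.remove_lineage(a)
        self.remove_lineage(b)
        merged = self.merge_lineages([a, b], self.time)
        if merged is not None:
            self.insert_lineage(merged)
        self.event_log.append((self.time, "CA", label))

    def lambda_event(self, pid, label):
        lst = self.lineages[(pid, label)]
        k = models_mod.sample_lambda_event(len(lst), self.model, self.rng)
        idx = sorted(self.rng.choice(len(lst), size=k, replace=False))
        chosen = [lst[int(i)] for i in idx]
        for lin in chosen:
            self.remove_lineage(lin)
        merged = self.merge_lineages(chosen, self.time)
        if merged is not None:
            self.insert_lineage(merged)
        self.event_log.append((self.time, "CA", (label, k)))

    # -- main loops -------------------------------------------------------
    def _schedule(self):
        sched = [
            (ev.time, 0, "DEMOGRAPHIC", ev) for ev in self.demography.events
        ]
        t_acc = 0.0
        for model, end in self.params.models[:-1]:
            sched.append((float(end), 1, "MODEL_SWITCH", None))
        if self.params.end_time is not None:
            sched.append((float(self.params.end_time), 2, "END", None))
        sched.sort(key=lambda x: (x[0], x[1]))
        return sched

    def run(self):
        p = self.params
        if p.sweep is not None:
            traj = sweeps_mod.sample_trajectory(p.sweep, self.rng)
            sweeps_mod.sweep_phase(self, traj, p.sweep)
        schedule = self._schedule()
        model_iter = iter(p.models[1:])
        si = 0
        while si < len(schedule) and schedule[si][0] < self.time:
            # scheduled items overtaken by the sweep phase are skipped
            if schedule[si][2] == "MODEL_SWITCH":
                self.model = next(model_iter)[0]
            si += 1
        while self.num_lineages > 0:
            next_sched = schedule[si][0] if si < len(schedule) else np.inf
            if self.model.kind == "DTWF":
                while self.num_lineages > 0 and self.time + 1 <= next_sched:
                    if not self._dtwf_fast_path(next_sched):
                        models_mod.dtwf_generation(self)
                if self.num_lineages == 0:
                    break
                progressed = False
            else:
                progressed = self._continuous_step(next_sched)
            if progressed:
                continue
            if si >= len(schedule):
                raise RuntimeError("simulation stalled: all rates zero")
            t, _, kind, payload = schedule[si]
            si += 1
            self.time = max(self.time, t)
            if kind == "DEMOGRAPHIC":
                apply_demographic_event(self, payload)
            elif kind == "MODEL_SWITCH":
                models_mod.switch_model(self, next(model_iter)[0], t)
            elif kind == "END":
                break
        return self.finalise()

    def _continuous_step(self, next_sched):
        """One competing-risks event; returns False when the next scheduled
        discontinuity pre-empts the stochastic draw."""
        R = self.total_recombination_mass()
        G = self.total_gc_mass()
        rows = self.migration_matrix.sum(axis=1)
        M = sum(
            len(lst) * rows[pid] for (pid, label), lst in self.lineages.items()
        )
        other = R + G + M
        w_other = self.rng.exponential(1.0 / other) if other > 0 else np.inf
        w_coal = np.inf
        coal_key = None
        for (pid, label) in sorted(self.lineages):
            w = self._coalescence_waiting_time(pid, label)
            if w < w_coal:
                w_coal, coal_key = w, (pid, label)
        wait = min(w_other, w_coal)
        if self.time + wait >= next_sched:
            return False
        if not np.isfinite(wait):
            if self.num_lineages > 1:
                raise RuntimeError("simulation stalled: all rates zero")
            return False
        self.time += wait
        if w_coal <= w_other:
            pid, label = coal_key
            if self.model.is_multiple_merger:
                self.lambda_event(pid, label)
            else:
                self.common_ancestor_event(pid, label)
        else:
            u = self.rng.random() * other
            if u < R:
                self.recombination_event()
            elif u < R + G:
                self.gc_event()
            else:
                self.migration_event()
        return True

    def _dtwf_fast_path(self, stop) -> bool:
        """Exact vectorised DTWF stepping for the homogeneous case.

        With no recombination, migration or growth and a single population,
        each generation assigns every lineage a uniform haploid genome among
        2N independently, so generations are i.i.d.; whole blocks of
        collision-free generations can be drawn at once and skipped to the
        first generation in which two lineages hit the same genome.  The
        resulting process is distributionally identical to stepping one
        generation at a time.
        """
        if self.recombination_map.total_mass > 0:
            return False
        if self.migration_matrix.sum() > 0:
            return False
        keys = list(self.lineages)
        if len(keys) != 1 or keys[0][1] != 0:
            return False
        pid = keys[0][0]
        _, size, growth = self.pop_state[pid]
        if growth != 0:
            return False
        k = self.num_lineages_in(pid, 0)
        if k < 2:
            return False
        N = int(round(self.current_size(pid)))
        if N < 1:
            raise ValueError("population size < 1 in DTWF")
        G = 2 * N
        horizon = None if not np.isfinite(stop) else int(np.floor(stop - self.time))
        if horizon is not None and horizon < 1:
            return False
        block = 2048
        done = 0
        while True:
            nb = block if horizon is None else min(block, horizon - done)
            if nb <= 0:
                self.time += done
                return True
            mat = self.rng.integers(G, size=(nb, k))
            srt = np.sort(mat, axis=1)
            dup = (np.diff(srt, axis=1) == 0).any(axis=1)
            if not dup.any():
                done += nb
                continue
            idx = int(np.argmax(dup))
            self.time += done + idx
            t_next = self.time + 1
            groups = {}
            for lin, g in zip(self.lineages_in(pid, 0), mat[idx]):
                groups.setdefault(int(g), []).append(lin)
            for g in sorted(groups):
                lst = groups[g]
                if len(lst) >= 2:
                    for lin in lst:
                        self.remove_lineage(lin)
                    merged = self.merge_lineages(lst, t_next)
                    if merged is not None:
                        merged.population = pid
                        self.insert_lineage(merged)
            self.time = t_next
            return True

    def finalise(self):
        t = tbl.sort_tables(self.tables.squash_edges())
        self.tables = t
        return t


# ---------------------------------------------------------------------------

def sim_ancestry(params=None, **kwargs) -> tbl.TableCollection:
    """Simulate genetic ancestry; returns valid, sorted tables.

    Either pass an :class:`AncestryParams`, or its fields as keyword
    arguments.  Identical parameters and seed give byte-identical output
    (via :func:`coalseq.tables.export_text`).
    """
    if params is None:
        params = AncestryParams(**kwargs)
    return Simulator(params).run()


def initialize_from_tables(t: tbl.TableCollection, params: AncestryParams) -> Simulator:
    """Continue ("recapitate") an existing partial ancestry.

    One lineage is created per root node per maximal genomic interval over
    which it is a root; intervals already below a single root everywhere
    are complete and take no further part.  Subsequent simulation appends
    nodes and edges only at times above the input's maximum node time.
    """
    bad = tbl.validate_tables(t)
    if bad:
        raise ValueError(f"invalid input tables: {bad}")
    t = tbl.sort_tables(t)
    start_time = max((n.time for n in t.nodes), default=0.0)
    # collect per-root maximal intervals
    spans = {}  # root -> list of [left, right]
    for tree in tbl.iterate_trees(t):
        left, right = tree.interval
        for root in tree.roots:
            lst = spans.setdefault(root, [])
            if lst and lst[-1][1] == left:
                lst[-1][1] = right
            else:
                lst.append([left, right])
    # intervals covered by a single root are complete
    cover = OverlapCounts(t.sequence_length, 0)
    for root, intervals in spans.items():
        for l, r in intervals:
            cover.add(l, r, 1)
    lineages = []
    for root in sorted(spans):
        pop = t.nodes[root].population
        pop = 0 if pop == tbl.NULL else pop
        for l, r in spans[root]:
            segs = [
                Segment(sl, sr, root)
                for (sl, sr, c) in cover.pieces(l, r)
                if c >= 2
            ]
            merged = []
            for s in segs:
                if merged and merged[-1].right == s.left:
                    merged[-1].right = s.right
                else:
                    merged.append(s)
            if merged:
                lineages.append(Lineage(merged, pop, 0))
    sim = Simulator(params, tables=t.copy(), lineages=lineages,
                    start_time=start_time)
    return sim
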