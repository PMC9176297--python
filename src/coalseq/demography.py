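"""Multi-population demography.

Populations have an initial size and exponential growth rate (backwards in
time: ``N(t) = N0 * exp(-g t)`` at ``t`` generations before present).
Migration rates are *backwards in time*: ``migration_matrix[i][j]`` is the
rate per generation at which a lineage currently in population ``i`` moves
to population ``j`` (equivalently, the fraction of population ``i`` made up
of migrants from ``j`` each generation, forwards in time).  This is the
classical ``ms`` convention; mixing it up is the single most common source
of demography errors, hence :func:`validate_demography`.

Also provides numerics for the pair coalescence rate ``c(t)`` under a
demography, and its inverse, the inverse instantaneous coalescence rate
(IICR), interpretable as a time-varying effective population size.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

__all__ = [
    "Population",
    "DemographicEvent",
    "Demography",
    "validate_demography",
    "population_size_at",
    "apply_demographic_event",
    "pair_coalescence_rate",
    "iicr",
]


@dataclass
class Population:
    name: str
    initial_size: float
    growth_rate: float = 0.0


@dataclass
class DemographicEvent:
    """A scheduled change to the demography or to the extant lineages.

    ``kind`` is one of SIZE_CHANGE, GROWTH_CHANGE, MIGRATION_CHANGE, SPLIT,
    ADMIXTURE, PULSE, CENSUS, BOTTLENECK; the remaining fields are
    kind-specific and unused otherwise.
    """

    time: float
    kind: str
    population: object = None        # name, or list of names for SPLIT derived
    dest: object = None              # ancestral name(s); PULSE dest
    proportion: object = None        # PULSE proportion or ADMIXTURE proportions
    initial_size: float = None
    growth_rate: float = None
    rate: float = None               # MIGRATION_CHANGE
    source: str = None               # MIGRATION_CHANGE source (None = all)
    strength: float = None           # BOTTLENECK B


KINDS = {
    "SIZE_CHANGE", "GROWTH_CHANGE", "MIGRATION_CHANGE", "SPLIT",
    "ADMIXTURE", "PULSE", "CENSUS", "BOTTLENECK",
}


@dataclass
class Demography:
    populations: list = field(default_factory=list)
    migration_matrix: object = None
    events: list = field(default_factory=list)

    def __post_init__(self):
        n = len(self.populations)
        if self.migration_matrix is None:
            self.migration_matrix = np.zeros((n, n))
        else:
            self.migration_matrix = np.asarray(self.migration_matrix, dtype=float)
        self.events = sorted(self.events, key=lambda e: e.time)

    @classmethod
    def isolated(cls, initial_size, growth_rate=0.0, name="pop0"):
        return cls([Population(name, initial_size, growth_rate)])

    @property
    def num_populations(self):
        return len(self.populations)

    def population_id(self, name):
        if isinstance(name, (int, np.integer)):
            return int(name)
        for i, p in enumerate(self.populations):
            if p.name == name:
                return i
        raise KeyError(f"unknown population {name!r}")

    # -- activity windows (backwards time) ------------------------------
    def activity(self):
        """For each population, the backwards-time interval [start, stop)
        during which it is active.  Derived populations of a SPLIT/ADMIXTURE
        are inactive after (older than) the event; ancestral populations
        that only come into being at a split are inactive before it.
        """
        n = self.num_populations
        start = np.zeros(n)
        stop = np.full(n, np.inf)
        ancestral_only = set()
        for ev in self.events:
            if ev.kind in ("SPLIT", "ADMIXTURE"):
                derived = ev.population if isinstance(ev.population, (list, tuple)) \
                    else [ev.population]
                for d in derived:
                    stop[self.population_id(d)] = min(
                        stop[self.population_id(d)], ev.time
                    )
                anc = ev.dest if isinstance(ev.dest, (list, tuple)) else [ev.dest]
                for a in anc:
                    ancestral_only.add(self.population_id(a))
        for i in ancestral_only:
            starts = [
                ev.time for ev in self.events
                if ev.kind in ("SPLIT", "ADMIXTURE")
                and i in [
                    self.population_id(a) for a in (
                        ev.dest if isinstance(ev.dest, (list, tuple)) else [ev.dest]
                    )
                ]
            ]
            if stop[i] == np.inf and starts:
                start[i] = min(starts)
        return start, stop

    @classmethod
    def from_dict(cls, d):
        pops = [
            Population(p["name"], float(p["initial_size"]), float(p.get("growth_rate", 0.0)))
            for p in d["populations"]
        ]
        events = [
            DemographicEvent(
                time=float(e["time"]),
                kind=e["kind"],
                population=e.get("population"),
                dest=e.get("dest"),
                proportion=e.get("proportion"),
                initial_size=e.get("initial_size"),
                growth_rate=e.get("growth_rate"),
                rate=e.get("rate"),
                source=e.get("source"),
                strength=e.get("strength"),
            )
            for e in d.get("events", [])
        ]
        return cls(pops, d.get("migration_matrix"), events)


# ---------------------------------------------------------------------------

def validate_demography(d: Demography, sample_populations=None):
    """Check a demography for the classic interface errors.

    Returns a list of ``(kind, detail)`` violation records (empty = valid).
    """
    v = []
    names = [p.name for p in d.populations]
    if len(set(names)) != len(names):
        v.append(("duplicate_name", names))
    for i, p in enumerate(d.populations):
        if not (p.initial_size > 0) or not np.isfinite(p.initial_size):
            v.append(("nonpositive_size", i))
        if not np.isfinite(p.growth_rate):
            v.append(("bad_growth", i))
    m = d.migration_matrix
    n = d.num_populations
    if m.shape != (n, n):
        v.append(("matrix_shape", m.shape))
        return v
    if np.any(m < 0):
        v.append(("negative_migration", None))
    if np.any(np.diag(m) != 0):
        v.append(("matrix_diagonal", None))
    times = [e.time for e in d.events]
    if any(t < 0 for t in times):
        v.append(("negative_event_time", None))
    if times != sorted(times):
        v.append(("events_unsorted", None))

    def check_pop(x, ev_i):
        try:
            d.population_id(x)
        except KeyError:
            v.append(("unknown_population", ev_i))

    for i, ev in enumerate(d.events):
        if ev.kind not in KINDS:
            v.append(("unknown_event_kind", i))
            continue
        for ref in (ev.population, ev.dest):
            if ref is None:
                continue
            for x in (ref if isinstance(ref, (list, tuple)) else [ref]):
                check_pop(x, i)
        if ev.kind in ("PULSE", "ADMIXTURE"):
            props = ev.proportion if isinstance(ev.proportion, (list, tuple)) \
                else [ev.proportion]
            if any(p is None or not (0 <= p <= 1) for p in props):
                v.append(("bad_proportion", i))
        if ev.kind == "BOTTLENECK" and (ev.strength is None or ev.strength < 0):
            v.append(("bad_bottleneck_strength", i))
        if ev.kind in ("SIZE_CHANGE",) and ev.initial_size is not None \
                and ev.initial_size <= 0:
            v.append(("nonpositive_size_change", i))
        if ev.kind == "MIGRATION_CHANGE" and (ev.rate is None or ev.rate < 0):
            v.append(("bad_migration_rate", i))
    if sample_populations is not None and not v:
        start, stop = d.activity()
        for p in sample_populations:
            i = d.population_id(p)
            if start[i] > 0 or stop[i] <= 0:
                v.append(("sample_from_inactive_population", p))
    # lineages stranded: a population with no outgoing migration ever and
    # never a derived population of any lineage-moving event cannot merge
    # with the rest (only flagged when there are >= 2 populations).
    if n > 1 and not v:
        movable = set()
        mig = m.copy()
        for ev in d.events:
            if ev.kind in ("SPLIT", "ADMIXTURE", "PULSE"):
                derived = ev.population if isinstance(ev.population, (list, tuple)) \
                    else [ev.population]
                for x in derived:
                    movable.add(d.population_id(x))
            if ev.kind == "MIGRATION_CHANGE" and ev.rate and ev.rate > 0:
                if ev.source is None:
                    movable.update(range(n))
                else:
                    movable.add(d.population_id(ev.source))
        stuck = [i for i in range(n) if mig[i].sum() == 0 and i not in movable]
        # a single terminal (ancestral) population is fine; two or more
        # mutually isolated populations can never fully coalesce
        if len(stuck) >= 2:
            for i in stuck:
                v.append(("unreachable_population", d.populations[i].name))
    return v


# ---------------------------------------------------------------------------

def _epochs(d: Demography, pop_id: int):
    """Piecewise (start_time, size_at_start, growth_rate) for one population."""
    p = d.populations[pop_id]
    epochs = [(0.0, float(p.initial_size), float(p.growth_rate))]
    for ev in d.events:
        if ev.kind not in ("SIZE_CHANGE", "GROWTH_CHANGE"):
            continue
        if ev.population is not None and d.population_id(ev.population) != pop_id:
            continue
        t0, s0, g0 = epochs[-1]
        size_now = s0 * np.exp(-g0 * (ev.time - t0))
        size = float(ev.initial_size) if ev.initial_size is not None else size_now
        growth = float(ev.growth_rate) if ev.growth_rate is not None else \
            (g0 if ev.kind == "SIZE_CHANGE" else g0)
        if ev.kind == "GROWTH_CHANGE" and ev.growth_rate is None:
            growth = 0.0
        epochs.append((float(ev.time), size, growth))
    return epochs


def population_size_at(d: Demography, population, t: float) -> float:
    """N(t) for a population, respecting size/growth change events."""
    pid = d.population_id(population)
    start, stop = d.activity()
    if not (start[pid] <= t < stop[pid] or (t == 0 and start[pid] == 0)):
        raise ValueError(
            f"population {d.populations[pid].name!r} inactive at time {t}"
        )
    epochs = _epochs(d, pid)
    t0, s0, g0 = epochs[0]
    for te, se, ge in epochs:
        if te <= t:
            t0, s0, g0 = te, se, ge
    return float(s0 * np.exp(-g0 * (t - t0)))


def apply_demographic_event(state, ev: DemographicEvent):
    """Apply one event to a running simulation state at ``state.time``.

    ``state`` is the ancestry engine's simulator; lineage moves, census node
    insertion and bottleneck coalescence are delegated to it.  Events at
    identical times execute in list order.
    """
    d = state.demography
    if ev.kind == "SIZE_CHANGE" or ev.kind == "GROWTH_CHANGE":
        targets = range(d.num_populations) if ev.population is None \
            else [d.population_id(ev.population)]
        for pid in targets:
            size = ev.initial_size if ev.initial_size is not None \
                else state.current_size(pid)
            growth = ev.growth_rate
            if growth is None:
                growth = state.pop_state[pid][2] if ev.kind == "SIZE_CHANGE" else 0.0
            state.pop_state[pid] = (state.time, float(size), float(growth))
    elif ev.kind == "MIGRATION_CHANGE":
        if ev.source is None and ev.dest is None:
            state.migration_matrix[:] = ev.rate
            np.fill_diagonal(state.migration_matrix, 0.0)
        else:
            state.migration_matrix[
                d.population_id(ev.source), d.population_id(ev.dest)
            ] = ev.rate
    elif ev.kind == "SPLIT":
        derived = ev.population if isinstance(ev.population, (list, tuple)) \
            else [ev.population]
        anc = d.population_id(ev.dest)
        for x in derived:
            pid = d.population_id(x)
            state.move_all_lineages(pid, anc)
            state.migration_matrix[pid, :] = 0.0
            state.migration_matrix[:, pid] = 0.0
    elif ev.kind == "ADMIXTURE":
        pid = d.population_id(ev.population)
        ancs = [d.population_id(a) for a in ev.dest]
        props = list(ev.proportion)
        state.split_lineages(pid, ancs, props)
        state.migration_matrix[pid, :] = 0.0
        state.migration_matrix[:, pid] = 0.0
    elif ev.kind == "PULSE":
        state.pulse_lineages(
            d.population_id(ev.population), d.population_id(ev.dest), ev.proportion
        )
    elif ev.kind == "CENSUS":
        state.census()
    elif ev.kind == "BOTTLENECK":
        from . import models
        models.apply_bottleneck(state, ev)
    else:
        raise ValueError(f"unknown event kind {ev.kind!r}")
    return state


# ---------------------------------------------------------------------------
# pair coalescence rate numerics
# ---------------------------------------------------------------------------

def _pair_states(n):
    states = [(i, i) for i in range(n)] + [
        (i, j) for i in range(n) for j in range(i + 1, n)
    ]
    index = {s: k for k, s in enumerate(states)}
    return states, index


def _generator(d, states, index, migration, sizes, ploidy):
    """Dense generator over pair states plus the absorbing 'coalesced' state."""
    m = len(states)
    Q = np.zeros((m + 1, m + 1))
    for k, (a, b) in enumerate(states):
        for (x, other) in ((a, b), (b, a)):
            for j in range(len(sizes)):
                rate = migration[x, j]
                if rate <= 0 or j == x:
                    continue
                dest = tuple(sorted((j, other)))
                Q[k, index[dest]] += rate
        if a == b:
            Q[k, m] += 1.0 / (ploidy * sizes[a])
        Q[k, k] = -Q[k].sum()
    return Q


def _solve_pair_chain(d: Demography, sample_config, times, ploidy):
    """State-probability vectors of the pair-location chain at grid times.

    Returns ``(probs, fluxes)``: for each grid time, the probability vector
    over pair states + coalesced, and the instantaneous flux into the
    coalesced state.  Piecewise-constant epochs use the matrix exponential;
    growth epochs an adaptive Runge-Kutta integration (rtol 1e-8).
    """
    bad = validate_demography(d)
    if bad:
        raise ValueError(f"invalid demography: {bad}")
    if len(sample_config) != 2:
        raise ValueError("sample_config must place exactly two lineages")
    times = np.asarray(times, dtype=float)
    n = d.num_populations
    states, index = _pair_states(n)
    m = len(states)
    a, b = sorted(d.population_id(x) for x in sample_config)
    p = np.zeros(m + 1)
    p[index[(a, b)]] = 1.0

    def migration_at(t):
        mm = d.migration_matrix.copy()
        for ev in d.events:
            if ev.kind == "MIGRATION_CHANGE" and ev.time <= t:
                if ev.source is None and ev.dest is None:
                    mm[:] = ev.rate
                    np.fill_diagonal(mm, 0.0)
                else:
                    mm[d.population_id(ev.source), d.population_id(ev.dest)] = ev.rate
        return mm

    def growth_at(t):
        out = []
        for i in range(n):
            g = d.populations[i].growth_rate
            for ev in d.events:
                if ev.kind in ("SIZE_CHANGE", "GROWTH_CHANGE") and ev.time <= t \
                        and (ev.population is None or d.population_id(ev.population) == i):
                    if ev.growth_rate is not None:
                        g = ev.growth_rate
                    elif ev.kind == "GROWTH_CHANGE":
                        g = 0.0
            out.append(g)
        return out

    def safe_size(i, t):
        # inactive populations hold no probability mass (no migration into
        # them); their nominal size only keeps the generator finite
        try:
            return population_size_at(d, i, t)
        except ValueError:
            return d.populations[i].initial_size

    event_times = sorted({ev.time for ev in d.events if ev.kind in (
        "SIZE_CHANGE", "GROWTH_CHANGE", "MIGRATION_CHANGE")})
    boundaries = sorted(set([0.0] + event_times + list(times)))
    probs, fluxes = {}, {}
    for seg, t0 in enumerate(boundaries):
        sizes0 = np.array([safe_size(i, t0) for i in range(n)])
        mm = migration_at(t0)
        Q0 = _generator(d, states, index, mm, sizes0, ploidy)
        if t0 in times:
            probs[float(t0)] = p.copy()
            fluxes[float(t0)] = float(p[:m] @ Q0[:m, m])
        if seg + 1 >= len(boundaries):
            break
        t1 = boundaries[seg + 1]
        if all(g == 0 for g in growth_at(t0)):
            p = expm(Q0.T * (t1 - t0)) @ p
        else:
            def rhs(t, y):
                sz = np.array([
                    safe_size(i, min(t, t1 - 1e-12)) for i in range(n)
                ])
                Qt = _generator(d, states, index, mm, sz, ploidy)
                return Qt.T @ y
            sol = solve_ivp(rhs, (t0, t1), p, rtol=1e-8, atol=1e-12)
            p = sol.y[:, -1]
    return (
        np.array([probs[float(t)] for t in times]),
        np.array([fluxes[float(t)] for t in times]),
    )


def pair_coalescence_rate(d: Demography, sample_config, times, ploidy=2):
    """Instantaneous pair coalescence rate c(t) on a time grid.

    ``sample_config`` names the two populations holding one lineage each
    (the same name twice for co-located lineages).  ``c(t)`` is the hazard:
    probability flux into the coalesced state divided by survival.
    """
    times = np.asarray(times, dtype=float)
    probs, fluxes = _solve_pair_chain(d, sample_config, times, ploidy)
    surv = 1.0 - probs[:, -1]
    c = np.full(len(times), np.inf)
    ok = surv > 1e-300
    c[ok] = fluxes[ok] / surv[ok]
    return c


def pair_coalescence_survival(d: Demography, sample_config, times, ploidy=2):
    """P(pair has not coalesced by t), on a grid (same numerics as c(t))."""
    probs, _ = _solve_pair_chain(d, sample_config, times, ploidy)
    return 1.0 - probs[:, -1]


def iicr(rates, ploidy=2):
    """Inverse instantaneous coalescence rate, as an effective size.

    ``IICR(t) = 1 / (ploidy * c(t))``; zero rates map to ``inf``.
    """
    rates = np.asarray(rates, dtype=float)
    out = np.full(rates.shape, np.inf)
    nz = rates > 0
    out[nz] = 1.0 / (ploidy * rates[nz])
    return out
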