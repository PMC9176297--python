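"""Selective sweeps via a structured coalescent conditioned on a trajectory.

A hard sweep is simulated in two steps.  First, the frequency of the
beneficial allele is generated *backwards* from fixation by an Euler jump
process approximating the fixation-conditioned Wright-Fisher diffusion:
starting at ``x = 1 - 1/(ploidy N)``, steps

    x <- x - dt * D(x, alpha) + Normal(0, dt * x (1 - x)),

clipped to (0, 1), until ``x <= 1/(ploidy N)`` (the allele's origin),
where ``alpha = ploidy * N * s`` and the conditioned drift is

    D(x, alpha) = alpha x (1 - x) / (1 - exp(-alpha x)).

Time here is diffusion time, in units of ``ploidy * N`` generations.

Second, the coalescent runs through the trajectory with every lineage
assigned a structured-coalescent "label": the beneficial background (pair
coalescence rate ``1/(ploidy N x)``) or the wild-type background (rate
``1/(ploidy N (1-x))``).  Common-ancestor events only merge lineages
within a label; recombination transfers lineages between backgrounds.
The links that matter during the phase run from the swept site to the far
end of a lineage's material: a breakpoint falling between the site and
the material switches the whole lineage's background (beneficial with
probability ``x``), while a breakpoint inside the material splits it, the
site-side piece keeping its background and the detached piece drawing a
fresh one.  When the trajectory reaches the allele's origin the surviving
beneficial-background lineages merge into the single originating genome,
labels are dropped, and the scheduled base model resumes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SweepParams",
    "Trajectory",
    "conditioned_drift",
    "sample_trajectory",
    "sweep_phase",
]

LABEL_NEUTRAL = 0
LABEL_BENEFICIAL = 1
LABEL_WILD = 2


@dataclass
class SweepParams:
    position: float
    s: float                   # selection coefficient, > 0
    N: float                   # population size (diploid individuals)
    dt: float = 1.0 / 400.0    # Euler step, in units of ploidy*N generations
    ploidy: int = 2
    max_steps: int = 10_000_000

    @property
    def alpha(self) -> float:
        return self.ploidy * self.N * self.s


@dataclass
class Trajectory:
    """Backwards allele-frequency path: times ascend from 0 (sweep end)."""

    times: np.ndarray          # generations before the sweep's end
    freqs: np.ndarray
    dt: float                  # step in generations

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if len(self.times) != len(self.freqs):
            raise ValueError("times and freqs must have equal length")

    @property
    def duration(self) -> float:
        return float(self.times[-1] + self.dt)


def conditioned_drift(x: float, alpha: float) -> float:
    """Drift of the fixation-conditioned Wright-Fisher diffusion.

    Limits: ``x -> 0`` gives 1 for any alpha; ``alpha -> 0`` gives ``1 - x``
    (the neutral conditioned drift).
    """
    if not 0 < x < 1:
        raise ValueError("frequency must lie in (0, 1)")
    ax = alpha * x
    if abs(ax) < 1e-8:
        # series of alpha x (1-x) / (1 - e^{-alpha x}) about ax = 0
        return (1 - x) * (1 + ax / 2 + ax * ax / 12)
    return alpha * x * (1 - x) / (1 - np.exp(-ax))


def sample_trajectory(p: SweepParams, rng: np.random.Generator) -> Trajectory:
    """Euler jump-process draw of the backwards frequency path.

    The fixation-conditioned diffusion is simulated *forward* from the
    allele's origin at ``1/(ploidy N)`` until it reaches
    ``1 - 1/(ploidy N)``, and the sampled path is read in reverse: the path
    law is that of the conditioned diffusion, so traversing it from the
    fixation end gives the backwards-in-time frequency sequence without
    having to derive the time-reversed generator.  (A naive backward Euler
    step with the negated conditioned drift mishandles the entrance
    behaviour at fixation and distorts the coalescence times it induces.)
    """
    if p.s <= 0:
        raise ValueError("selection coefficient must be positive")
    lo = 1.0 / (p.ploidy * p.N)
    alpha = p.alpha
    dt = p.dt
    sd = np.sqrt(dt)
    x = lo
    freqs = [x]
    for step in range(p.max_steps):
        x = x + dt * conditioned_drift(x, alpha) \
            + sd * np.sqrt(max(x * (1 - x), 0.0)) * rng.standard_normal()
        x = min(max(x, lo / 2), 1.0 - lo / 2)
        if x >= 1.0 - lo:
            break
        freqs.append(x)
    else:
        raise RuntimeError("trajectory failed to fix within max_steps")
    freqs = np.array(freqs[::-1])
    freqs[0] = 1.0 - lo
    dt_gen = dt * p.ploidy * p.N
    times = np.arange(len(freqs)) * dt_gen
    return Trajectory(times=times, freqs=freqs, dt=dt_gen)


# ---------------------------------------------------------------------------

def _carries(lineage, position) -> bool:
    return any(s.left <= position < s.right for s in lineage.segments)


def _phase_links(state, lin, pos):
    """Recombination mass relevant to a lineage during the sweep phase.

    The links extend from the swept site to the far end of the lineage's
    material: a breakpoint between the site and the material moves the
    whole lineage between backgrounds, a breakpoint inside the material
    additionally splits it.
    """
    unit = 1.0 if state.discrete_genome else 0.0
    left = min(lin.left, pos)
    right = max(lin.right, pos + unit)
    if state.discrete_genome:
        return state.recombination_map.mass(left, right - 1)
    return state.recombination_map.mass(left, right)


def _draw_phase_breakpoint(state, lin, pos):
    rmap = state.recombination_map
    unit = 1.0 if state.discrete_genome else 0.0
    left = min(lin.left, pos)
    right = max(lin.right, pos + unit)
    if state.discrete_genome:
        total = rmap.mass(left, right - 1)
        x = rmap.position_of_mass(left, state.rng.random() * total)
        return min(float(int(x) + 1), right - 1)
    total = rmap.mass(left, right)
    return rmap.position_of_mass(left, state.rng.random() * total)


def sweep_phase(state, traj: Trajectory, params: SweepParams):
    """Run the structured sweep phase on the ancestry engine ``state``.

    Entered at the engine's current time (the sweep's end); consumes the
    trajectory step by step, treating rates as constant within each step.
    Every lineage is on the beneficial or the wild background; at the end
    of the trajectory the surviving beneficial-background lineages merge
    into the allele's single originating genome and labels are dropped.
    """
    if state.record_full_arg:
        raise NotImplementedError(
            "full-ARG recording is not supported through a sweep phase"
        )
    rng = state.rng
    pos = params.position
    pN = state.ploidy * params.N
    t0 = state.time
    x0 = float(traj.freqs[0])
    for lin in list(state.all_lineages()):
        state.relabel(
            lin, LABEL_BENEFICIAL if rng.random() < x0 else LABEL_WILD
        )
    for step in range(len(traj.freqs)):
        x = float(traj.freqs[step])
        step_end = t0 + (traj.times[step] + traj.dt)
        while state.time < step_end and state.num_lineages > 0:
            rates = _phase_rates(state, x, pN, pos)
            total = sum(r for r, _ in rates)
            if total <= 0:
                state.time = step_end
                break
            wait = rng.exponential(1.0 / total)
            if state.time + wait >= step_end:
                state.time = step_end
                break
            state.time += wait
            u = rng.random() * total
            for r, action in rates:
                if u < r:
                    action(x)
                    break
                u -= r
        if state.num_lineages == 0:
            break
    # allele origin: the beneficial class contracts to one founder genome
    end_time = max(state.time, t0 + traj.duration)
    state.time = end_time
    carriers = [
        lin for lin in list(state.all_lineages()) if lin.label == LABEL_BENEFICIAL
    ]
    if len(carriers) >= 2:
        for lin in carriers:
            state.remove_lineage(lin)
        merged = state.merge_lineages(carriers, end_time)
        if merged is not None:
            state.insert_lineage(merged)
    for lin in list(state.all_lineages()):
        if lin.label != LABEL_NEUTRAL:
            state.relabel(lin, LABEL_NEUTRAL)
    state.event_log.append((state.time, "SWEEP_END", None))
    return state


def _phase_rates(state, x, pN, pos):
    """Competing-risk (rate, action) pairs for the current sweep step."""
    rates = []
    for label, denom in (
        (LABEL_BENEFICIAL, x),
        (LABEL_WILD, 1.0 - x),
    ):
        k = state.num_lineages_in(0, label)
        if k >= 2 and denom > 0:
            rate = k * (k - 1) / 2 / (pN * denom)
            rates.append((rate, _make_ca(state, label)))
    r_rate = sum(
        _phase_links(state, lin, pos) for lin in state.all_lineages()
    )
    if r_rate > 0:
        rates.append((r_rate, _make_re(state, pos, r_rate)))
    return rates


def _make_ca(state, label):
    def action(x):
        lins = state.lineages_in(0, label)
        i, j = state.rng.choice(len(lins), size=2, replace=False)
        a, b = lins[int(i)], lins[int(j)]
        state.remove_lineage(a)
        state.remove_lineage(b)
        merged = state.merge_lineages([a, b], state.time)
        if merged is not None:
            state.insert_lineage(merged)
        state.event_log.append((state.time, "CA", label))
    return action


def _make_re(state, pos, total):
    def action(x):
        u = state.rng.random() * total
        lin = None
        for cand in state.all_lineages():
            w = _phase_links(state, cand, pos)
            if u < w:
                lin = cand
                break
            u -= w
        if lin is None:
            return
        bp = _draw_phase_breakpoint(state, lin, pos)
        new_label = LABEL_BENEFICIAL if state.rng.random() < x else LABEL_WILD
        if lin.left < bp < lin.right:
            from .ancestry import recombination_event

            state.remove_lineage(lin)
            left, right = recombination_event(lin, bp)
            site_side, far_side = (left, right) if pos < bp else (right, left)
            far_side.label = new_label
            state.insert_lineage(site_side)
            state.insert_lineage(far_side)
            state.num_re_events += 1
            state.event_log.append((state.time, "RE", bp))
        else:
            # breakpoint between the site and the material: the whole
            # lineage switches background
            if new_label != lin.label:
                state.relabel(lin, new_label)
            state.event_log.append((state.time, "RE_SWITCH", bp))
    return action
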