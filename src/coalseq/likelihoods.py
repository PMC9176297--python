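"""Likelihoods of ARG realizations and mutation patterns.

With the complete ancestral recombination graph recorded (flagged
recombination and common-ancestor nodes with unary edges), the sampling
density of the realization under the coalescent with recombination in a
single constant-size population can be evaluated.  Working in coalescent
units (time divided by ``ploidy * Ne``), with ``rho`` the population-scaled
recombination rate per unit of genome:

* an inter-event interval with ``k`` lineages of total span ``ell``
  (summed across lineages, trapped gaps included) contributes
  ``-(k(k-1)/2 + rho * ell / 2) * dt``;
* a common-ancestor event contributes rate 1 for its pair (log factor 0);
* a recombination event contributes ``log(rho / 2)`` — the breakpoint is
  uniform over the links — so an ARG containing recombination nodes has
  zero likelihood when ``rho = 0``.

The mutation likelihood is the infinite-sites Poisson-process density over
the tree "area" A (edge span times duration, coalescent units): with S
mutations at recorded positions and times, ``log L = S log(theta/2) -
(theta/2) A``.
"""
from __future__ import annotations

import numpy as np

from . import tables as tbl

__all__ = ["arg_log_likelihood", "mutation_log_likelihood"]


def _reconstruct_events(t: tbl.TableCollection):
    """Replay a full-ARG table collection as an ordered event list.

    Returns ``[(time, kind, k_before, links_before), ...]`` where ``k`` and
    ``links`` (total lineage span, genome units) describe the state in the
    interval *ending* at the event.
    """
    material = {}
    for e in t.edges:
        lo, hi = material.get(e.child, (np.inf, -np.inf))
        material[e.child] = (min(lo, e.left), max(hi, e.right))
    children_of = {}
    for e in t.edges:
        children_of.setdefault(e.parent, set()).add(e.child)

    samples = t.samples
    re_nodes = [
        i for i, n in enumerate(t.nodes) if n.flags & tbl.NODE_RECOMB_EVENT
    ]
    internal = sorted(
        (i for i, n in enumerate(t.nodes) if not n.is_sample),
        key=lambda i: (t.nodes[i].time, i),
    )
    has_recomb = len(
        ({e.left for e in t.edges} | {e.right for e in t.edges})
        - {0.0, t.sequence_length}
    ) > 0
    if has_recomb and not re_nodes:
        raise ValueError(
            "tables do not carry full-ARG recombination records"
        )
    active = set(samples)

    def span(u):
        lo, hi = material.get(u, (0.0, 0.0))
        return max(hi - lo, 0.0)

    events = []
    i = 0
    while i < len(internal):
        u = internal[i]
        nd = t.nodes[u]
        k = len(active)
        links = sum(span(v) for v in active)
        if nd.flags & tbl.NODE_RECOMB_EVENT:
            if i + 1 >= len(internal):
                raise ValueError("unpaired recombination node")
            v = internal[i + 1]
            if t.nodes[v].time != nd.time or not (
                t.nodes[v].flags & tbl.NODE_RECOMB_EVENT
            ):
                raise ValueError("unpaired recombination node")
            (child,) = children_of[u] | children_of[v]
            active.discard(child)
            active.update((u, v))
            events.append((nd.time, "RE", k, links))
            i += 2
        else:
            kids = children_of.get(u, set())
            if len(kids) not in (1, 2):
                raise ValueError(
                    "common-ancestor node must have one or two children"
                )
            for c in kids:
                active.discard(c)
            active.add(u)
            events.append((nd.time, "CA", k, links))
            i += 1
    times = [e[0] for e in events]
    if len(set(times)) != len(times):
        raise ValueError("coincident event times are not supported")
    return events


def arg_log_likelihood(t: tbl.TableCollection, rho: float, Ne: float,
                       ploidy: int = 2) -> float:
    """Log density of a fully recorded ARG at scaled recombination rate rho.

    ``rho`` is per unit of genome length on the coalescent timescale;
    node times in ``t`` are in generations and are divided by
    ``ploidy * Ne``.
    """
    if rho < 0:
        raise ValueError("rho must be non-negative")
    events = _reconstruct_events(t)
    scale = ploidy * Ne
    logl = 0.0
    prev = 0.0
    for time, kind, k, links in events:
        tau = time / scale
        total = k * (k - 1) / 2 + rho * links / 2
        logl -= total * (tau - prev)
        prev = tau
        if kind == "RE":
            if rho == 0:
                return -np.inf
            logl += np.log(rho / 2)
    return logl


def mutation_log_likelihood(t: tbl.TableCollection, theta: float) -> float:
    """Infinite-sites log likelihood of the recorded mutations.

    Node times are taken in coalescent units.  ``theta`` is the scaled
    mutation rate per unit of genome.  Every site must carry exactly one
    mutation; violations raise.
    """
    if theta < 0:
        raise ValueError("theta must be non-negative")
    per_site = {}
    for m in t.mutations:
        per_site[m.site] = per_site.get(m.site, 0) + 1
    if any(c != 1 for c in per_site.values()):
        raise ValueError("infinite-sites violation: a site has >1 mutation")
    area = sum(
        (e.right - e.left) * (t.nodes[e.parent].time - t.nodes[e.child].time)
        for e in t.edges
    )
    S = len(t.mutations)
    if theta == 0:
        return -np.inf if S > 0 else 0.0
    return S * np.log(theta / 2) - (theta / 2) * area
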