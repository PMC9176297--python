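"""Succinct tree-sequence tables.

Genetic ancestry and sequence variation are stored in a set of tables:
nodes (ancestral genomes with creation times), edges (parent/child
inheritance over genome intervals), sites and mutations (sequence
variation), migrations and individuals.  A set of tables encodes the
sequence of correlated "marginal" genealogical trees along the genome:
each edge may span many trees, which is what makes the encoding succinct.

Coordinates are 0-based half-open ``[left, right)``.  Discrete genomes
restrict breakpoints and site positions to integers.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NODE_IS_SAMPLE",
    "NODE_RECOMB_EVENT",
    "NODE_CA_PASSTHROUGH",
    "NODE_CENSUS",
    "NULL",
    "Node",
    "Edge",
    "Site",
    "Mutation",
    "MigrationRecord",
    "Individual",
    "TableCollection",
    "MarginalTree",
    "validate_tables",
    "sort_tables",
    "iterate_trees",
    "simplify",
    "export_text",
    "import_text",
    "export_newick",
    "export_vcf",
]

NODE_IS_SAMPLE = 1
NODE_RECOMB_EVENT = 2
NODE_CA_PASSTHROUGH = 4
NODE_CENSUS = 8

#: Sentinel for "no reference" (null population, individual, parent...).
NULL = -1


@dataclass
class Node:
    flags: int = 0
    time: float = 0.0
    population: int = NULL
    individual: int = NULL

    @property
    def is_sample(self) -> bool:
        return bool(self.flags & NODE_IS_SAMPLE)


@dataclass
class Edge:
    left: float
    right: float
    parent: int
    child: int


@dataclass
class Site:
    position: float
    ancestral_state: str


@dataclass
class Mutation:
    site: int
    node: int
    derived_state: str
    time: float
    parent: int = NULL


@dataclass
class MigrationRecord:
    left: float
    right: float
    node: int
    source: int
    dest: int
    time: float


@dataclass
class Individual:
    nodes: tuple = ()


@dataclass
class TableCollection:
    """The single interchange object between all modules."""

    sequence_length: float
    discrete_genome: bool = True
    nodes: list = field(default_factory=list)
    edges: list = field(default_factory=list)
    sites: list = field(default_factory=list)
    mutations: list = field(default_factory=list)
    migrations: list = field(default_factory=list)
    individuals: list = field(default_factory=list)

    # -- construction helpers -------------------------------------------
    def add_node(self, flags=0, time=0.0, population=NULL, individual=NULL):
        self.nodes.append(Node(flags, float(time), population, individual))
        return len(self.nodes) - 1

    def add_edge(self, left, right, parent, child):
        self.edges.append(Edge(float(left), float(right), parent, child))
        return len(self.edges) - 1

    def add_site(self, position, ancestral_state):
        self.sites.append(Site(float(position), ancestral_state))
        return len(self.sites) - 1

    def add_mutation(self, site, node, derived_state, time, parent=NULL):
        self.mutations.append(Mutation(site, node, derived_state, float(time), parent))
        return len(self.mutations) - 1

    def add_individual(self, nodes=()):
        self.individuals.append(Individual(tuple(nodes)))
        return len(self.individuals) - 1

    @property
    def samples(self):
        return [i for i, n in enumerate(self.nodes) if n.is_sample]

    def copy(self):
        t = TableCollection(self.sequence_length, self.discrete_genome)
        t.nodes = [replace(n) for n in self.nodes]
        t.edges = [replace(e) for e in self.edges]
        t.sites = [replace(s) for s in self.sites]
        t.mutations = [replace(m) for m in self.mutations]
        t.migrations = [replace(m) for m in self.migrations]
        t.individuals = [replace(i) for i in self.individuals]
        return t

    def __eq__(self, other):
        if not isinstance(other, TableCollection):
            return NotImplemented
        return (
            self.sequence_length == other.sequence_length
            and self.discrete_genome == other.discrete_genome
            and self.nodes == other.nodes
            and self.edges == other.edges
            and self.sites == other.sites
            and self.mutations == other.mutations
            and self.migrations == other.migrations
            and self.individuals == other.individuals
        )

    # convenience wrappers
    def validate(self):
        return validate_tables(self)

    def sort(self):
        return sort_tables(self)

    def trees(self):
        return iterate_trees(self)

    def squash_edges(self):
        """Merge abutting edges with identical parent/child in place."""
        edges = sorted(self.edges, key=lambda e: (e.parent, e.child, e.left))
        out = []
        for e in edges:
            if out and out[-1].parent == e.parent and out[-1].child == e.child \
                    and out[-1].right == e.left:
                out[-1].right = e.right
            else:
                out.append(Edge(e.left, e.right, e.parent, e.child))
        self.edges = out
        return self


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_tables(t: TableCollection):
    """Run the data-model consistency checks.

    Returns a list of machine-readable violation records, each a tuple
    ``(kind, row_index)``; the list is empty iff the tables are valid.
    """
    v = []
    n_nodes = len(t.nodes)
    L = t.sequence_length
    if not (L > 0 and np.isfinite(L)):
        v.append(("sequence_length", -1))
        return v
    for i, node in enumerate(t.nodes):
        if not np.isfinite(node.time) or node.time < 0:
            v.append(("node_time", i))
        if node.individual != NULL and not (0 <= node.individual < len(t.individuals)):
            v.append(("individual_ref", i))
    for i, e in enumerate(t.edges):
        if e.left >= e.right:
            v.append(("empty_interval", i))
        if e.left < 0 or e.right > L:
            v.append(("interval_bounds", i))
        if not (0 <= e.parent < n_nodes) or not (0 <= e.child < n_nodes):
            v.append(("node_ref", i))
            continue
        if t.nodes[e.parent].time <= t.nodes[e.child].time:
            v.append(("time_order", i))
        if t.discrete_genome and not (
            float(e.left).is_integer() and float(e.right).is_integer()
        ):
            v.append(("non_integer_coordinate", i))
    # no two edges for the same child may overlap in genome span
    by_child = {}
    for i, e in enumerate(t.edges):
        if 0 <= e.child < n_nodes and e.left < e.right:
            by_child.setdefault(e.child, []).append((e.left, e.right, i))
    for spans in by_child.values():
        spans.sort()
        for (l0, r0, _), (l1, r1, i1) in zip(spans, spans[1:]):
            if l1 < r0:
                v.append(("child_overlap", i1))
    seen_pos = set()
    for i, s in enumerate(t.sites):
        if not (0 <= s.position < L):
            v.append(("position_bounds", i))
        if s.position in seen_pos:
            v.append(("site_duplicate", i))
        seen_pos.add(s.position)
        if t.discrete_genome and not float(s.position).is_integer():
            v.append(("non_integer_position", i))
    for i, m in enumerate(t.mutations):
        if not (0 <= m.site < len(t.sites)) or not (0 <= m.node < n_nodes):
            v.append(("mutation_ref", i))
            continue
        if not np.isfinite(m.time) or m.time < t.nodes[m.node].time:
            v.append(("mutation_time", i))
        else:
            # must lie in the half-open time span of an edge above node at the
            # site's position, unless the node is a root there.
            pos = t.sites[m.site].position
            parent_edges = [
                e for e in t.edges
                if e.child == m.node and e.left <= pos < e.right
            ]
            if parent_edges:
                top = t.nodes[parent_edges[0].parent].time
                if m.time >= top:
                    v.append(("mutation_time", i))
        if m.parent != NULL:
            if not (0 <= m.parent < len(t.mutations)):
                v.append(("mutation_parent_ref", i))
            else:
                p = t.mutations[m.parent]
                if p.site != m.site or p.time < m.time:
                    v.append(("mutation_parent", i))
    for i, m in enumerate(t.migrations):
        if m.left >= m.right:
            v.append(("migration_interval", i))
        if m.source == m.dest:
            v.append(("migration_pops", i))
        if not (0 <= m.node < n_nodes):
            v.append(("migration_node_ref", i))
    seen = set()
    for i, ind in enumerate(t.individuals):
        for u in ind.nodes:
            if not (0 <= u < n_nodes):
                v.append(("individual_node_ref", i))
            elif u in seen:
                v.append(("individual_node_shared", i))
            seen.add(u)
    return v


# ---------------------------------------------------------------------------
# sorting
# ---------------------------------------------------------------------------

def sort_tables(t: TableCollection) -> TableCollection:
    """Return a copy in canonical order.

    Edges are sorted by ``(time(parent), parent, child, left)``; sites by
    position (with mutation site references remapped); mutations by
    ``(site, descending time)`` with parent pointers remapped.  Idempotent.
    """
    if validate_tables(t):
        raise ValueError("cannot sort invalid tables")
    out = t.copy()
    out.edges.sort(key=lambda e: (t.nodes[e.parent].time, e.parent, e.child, e.left))
    site_order = sorted(range(len(t.sites)), key=lambda j: t.sites[j].position)
    site_map = {old: new for new, old in enumerate(site_order)}
    out.sites = [replace(t.sites[j]) for j in site_order]
    mut_order = sorted(
        range(len(t.mutations)),
        key=lambda j: (site_map[t.mutations[j].site], -t.mutations[j].time, j),
    )
    mut_map = {old: new for new, old in enumerate(mut_order)}
    out.mutations = []
    for j in mut_order:
        m = t.mutations[j]
        out.mutations.append(
            Mutation(
                site_map[m.site],
                m.node,
                m.derived_state,
                m.time,
                NULL if m.parent == NULL else mut_map[m.parent],
            )
        )
    out.migrations.sort(key=lambda m: (m.time, m.node, m.left))
    return out


def _is_sorted(t: TableCollection) -> bool:
    keys = [(t.nodes[e.parent].time, e.parent, e.child, e.left) for e in t.edges]
    return all(a <= b for a, b in zip(keys, keys[1:]))


# ---------------------------------------------------------------------------
# marginal trees
# ---------------------------------------------------------------------------

class MarginalTree:
    """The genealogical tree over one genome interval.

    ``parent`` maps node id -> parent node id (or :data:`NULL`); node ids
    are stable across the trees of one table collection.
    """

    def __init__(self, tables, interval, parent):
        self.tables = tables
        self.interval = interval
        self.parent = parent
        self._children = None

    @property
    def children_map(self):
        if self._children is None:
            c = {}
            for u, p in enumerate(self.parent):
                if p != NULL:
                    c.setdefault(p, []).append(u)
            for lst in c.values():
                lst.sort()
            self._children = c
        return self._children

    def children(self, u):
        return self.children_map.get(u, [])

    @property
    def roots(self):
        """Roots reachable from the sample nodes, in ascending id order."""
        roots = set()
        for s in self.tables.samples:
            while self.parent[s] != NULL:
                s = self.parent[s]
            roots.add(s)
        return sorted(roots)

    def path_to_root(self, u):
        path = [u]
        while self.parent[u] != NULL:
            u = self.parent[u]
            path.append(u)
        return path

    def time(self, u):
        return self.tables.nodes[u].time

    def total_branch_length(self):
        tot = 0.0
        for u, p in enumerate(self.parent):
            if p != NULL:
                tot += self.time(p) - self.time(u)
        return tot

    def tmrca(self):
        roots = self.roots
        if len(roots) != 1:
            raise ValueError("tree has multiple roots")
        return self.time(roots[0])


def iterate_trees(t: TableCollection):
    """Yield the marginal trees left to right across ``[0, sequence_length)``.

    Requires sorted, valid tables.  Consecutive trees differ only by the
    edges starting or ending at their shared boundary.
    """
    if not _is_sorted(t):
        raise ValueError("tables must be sorted (see sort_tables)")
    n = len(t.nodes)
    edges = t.edges
    # insertion index: by (left, parent time, parent id) so parents appear
    # after their children's edges are in place; removal by (right, -time).
    ins = sorted(
        range(len(edges)),
        key=lambda j: (edges[j].left, t.nodes[edges[j].parent].time, edges[j].parent, j),
    )
    rem = sorted(
        range(len(edges)),
        key=lambda j: (edges[j].right, -t.nodes[edges[j].parent].time, -edges[j].parent, j),
    )
    breaks = sorted(
        {0.0, t.sequence_length}
        | {e.left for e in edges}
        | {e.right for e in edges}
    )
    breaks = [b for b in breaks if 0.0 <= b <= t.sequence_length]
    parent = [NULL] * n
    i = j = 0
    for left, right in zip(breaks, breaks[1:]):
        while j < len(rem) and edges[rem[j]].right <= left:
            parent[edges[rem[j]].child] = NULL
            j += 1
        while i < len(ins) and edges[ins[i]].left <= left:
            parent[edges[ins[i]].child] = edges[ins[i]].parent
            i += 1
        yield MarginalTree(t, (left, right), list(parent))


def tree_at(t: TableCollection, position: float) -> MarginalTree:
    """The marginal tree covering ``position`` (brute-force construction)."""
    parent = [NULL] * len(t.nodes)
    for e in t.edges:
        if e.left <= position < e.right:
            parent[e.child] = e.parent
    lo = max([0.0] + [e.left for e in t.edges if e.left <= position])
    hi = min([t.sequence_length] + [e.right for e in t.edges if e.right > position])
    return MarginalTree(t, (lo, hi), parent)


# ---------------------------------------------------------------------------
# simplify
# ---------------------------------------------------------------------------

def simplify(t: TableCollection, samples, keep_unary: bool = False):
    """Reduce the tables to the minimal representation for ``samples``.

    Only nodes ancestral to the samples are kept; with ``keep_unary=False``
    ancestors that are unary everywhere are removed and their edges merged.
    The marginal trees restricted to ``samples`` are topologically
    unchanged.  Returns ``(new_tables, node_map)`` where ``node_map[old]``
    is the new id or :data:`NULL`.

    New node ids are assigned in ``(time, old id)`` order.
    """
    if len(samples) == 0:
        raise ValueError("samples must be nonempty")
    for s in samples:
        if not (0 <= s < len(t.nodes)):
            raise ValueError(f"unknown sample id {s}")
    t = sort_tables(t)
    L = t.sequence_length
    sample_set = set(samples)

    out = TableCollection(L, t.discrete_genome)
    node_of = {}  # input node -> provisional output node

    def get_out_node(u, forced_flags=0):
        if u not in node_of:
            nd = t.nodes[u]
            flags = nd.flags
            if u in sample_set:
                flags |= NODE_IS_SAMPLE
            elif not keep_unary:
                # ARG bookkeeping flags belong to removed event nodes; a
                # retained coalescent node keeps only sample/census flags.
                flags &= ~(NODE_RECOMB_EVENT | NODE_CA_PASSTHROUGH)
            node_of[u] = out.add_node(flags | forced_flags, nd.time, nd.population, nd.individual)
        return node_of[u]

    # ancestry map: input node -> list of (left, right, output node)
    A = {s: [(0.0, L, get_out_node(s))] for s in samples}
    raw_edges = []

    edges_by_parent = {}
    for e in t.edges:
        edges_by_parent.setdefault(e.parent, []).append(e)
    parents = sorted(edges_by_parent, key=lambda u: (t.nodes[u].time, u))

    for u in parents:
        # collect mapped ancestry segments inherited through u's edges
        segs = []
        for e in edges_by_parent[u]:
            for (l, r, v) in A.get(e.child, ()):
                ll, rr = max(l, e.left), min(r, e.right)
                if ll < rr:
                    segs.append((ll, rr, v))
        if not segs:
            continue
        is_sample = u in sample_set
        points = sorted({x for l, r, _ in segs for x in (l, r)})
        mapped = []
        for l, r in zip(points, points[1:]):
            cover = [v for (sl, sr, v) in segs if sl <= l and r <= sr]
            if not cover:
                continue
            if len(cover) >= 2 or is_sample or keep_unary:
                w = get_out_node(u)
                for v in sorted(cover):
                    raw_edges.append(Edge(l, r, w, v))
                mapped.append((l, r, w))
            else:
                mapped.append((l, r, cover[0]))
        if is_sample:
            # a sample node represents itself everywhere; keep its initial map
            continue
        # merge abutting pieces mapping to the same output node
        merged = []
        for l, r, v in mapped:
            if merged and merged[-1][2] == v and merged[-1][1] == l:
                merged[-1] = (merged[-1][0], r, v)
            else:
                merged.append((l, r, v))
        A[u] = merged

    # final node ids in (time, old id) order
    order = sorted(node_of, key=lambda u: (t.nodes[u].time, u))
    final = {node_of[u]: k for k, u in enumerate(order)}
    out.nodes = [out.nodes[node_of[u]] for u in order]
    node_map = np.full(len(t.nodes), NULL, dtype=int)
    for u, prov in node_of.items():
        node_map[u] = final[prov]
    for e in raw_edges:
        e.parent = final[e.parent]
        e.child = final[e.child]
    out.edges = raw_edges
    out.squash_edges()

    # individuals referenced by retained nodes
    ind_map = {}
    for nd in out.nodes:
        if nd.individual != NULL:
            if nd.individual not in ind_map:
                ind_map[nd.individual] = out.add_individual(())
            nd.individual = ind_map[nd.individual]
    for old, new in ind_map.items():
        out.individuals[new] = Individual(
            tuple(
                int(node_map[v]) for v in t.individuals[old].nodes if node_map[v] != NULL
            )
        )

    # sites and mutations: remap each mutation onto the output node that
    # carries its input node's material at the site position.
    site_map = {}
    def lookup(u, pos):
        for (l, r, v) in A.get(u, ()):
            if l <= pos < r:
                return v
        return None
    for j, s in enumerate(t.sites):
        new_muts = []
        for m in t.mutations:
            if m.site != j:
                continue
            v = lookup(m.node, s.position)
            if v is not None:
                new_muts.append((m, final[v]))
        if new_muts:
            sid = out.add_site(s.position, s.ancestral_state)
            site_map[j] = sid
            for m, v in new_muts:
                out.add_mutation(sid, v, m.derived_state, m.time)
    _rethread_mutation_parents(out)
    return sort_tables(out), node_map


def _rethread_mutation_parents(t: TableCollection):
    """Recompute mutation ``parent`` pointers by walking node-to-root paths."""
    by_site = {}
    for i, m in enumerate(t.mutations):
        by_site.setdefault(m.site, []).append(i)
    if not by_site:
        return
    t.squash_edges()
    for sid, idxs in by_site.items():
        pos = t.sites[sid].position
        parent = [NULL] * len(t.nodes)
        for e in t.edges:
            if e.left <= pos < e.right:
                parent[e.child] = e.parent
        muts_on_node = {}
        for i in idxs:
            muts_on_node.setdefault(t.mutations[i].node, []).append(i)
        for lst in muts_on_node.values():
            lst.sort(key=lambda i: t.mutations[i].time)
        for i in idxs:
            m = t.mutations[i]
            # youngest strictly-older mutation on the same node, else the
            # youngest mutation on the nearest mutated ancestor node.
            cands = [
                j for j in muts_on_node[m.node]
                if t.mutations[j].time > m.time or (t.mutations[j].time == m.time and j < i)
            ]
            if cands:
                m.parent = min(cands, key=lambda j: t.mutations[j].time)
                continue
            u = parent[m.node]
            m.parent = NULL
            while u != NULL:
                if u in muts_on_node:
                    m.parent = muts_on_node[u][0]
                    break
                u = parent[u]


# ---------------------------------------------------------------------------
# text dump round trip
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return repr(float(x))


def export_text(t: TableCollection) -> str:
    """Serialize tables to the plain-text dump format."""
    buf = io.StringIO()
    w = buf.write
    w(f"#sequence_length {_fmt(t.sequence_length)}\n")
    w(f"#discrete_genome {1 if t.discrete_genome else 0}\n")
    w("#nodes\nid\tflags\ttime\tpopulation\tindividual\n")
    for i, n in enumerate(t.nodes):
        w(f"{i}\t{n.flags}\t{_fmt(n.time)}\t{n.population}\t{n.individual}\n")
    w("#edges\nleft\tright\tparent\tchild\n")
    for e in t.edges:
        w(f"{_fmt(e.left)}\t{_fmt(e.right)}\t{e.parent}\t{e.child}\n")
    w("#sites\nposition\tancestral_state\n")
    for s in t.sites:
        w(f"{_fmt(s.position)}\t{s.ancestral_state}\n")
    w("#mutations\nsite\tnode\tderived_state\ttime\tparent\n")
    for m in t.mutations:
        w(f"{m.site}\t{m.node}\t{m.derived_state}\t{_fmt(m.time)}\t{m.parent}\n")
    w("#migrations\nleft\tright\tnode\tsource\tdest\ttime\n")
    for m in t.migrations:
        w(f"{_fmt(m.left)}\t{_fmt(m.right)}\t{m.node}\t{m.source}\t{m.dest}\t{_fmt(m.time)}\n")
    w("#individuals\nid\tnodes\n")
    for i, ind in enumerate(t.individuals):
        w(f"{i}\t{','.join(str(u) for u in ind.nodes)}\n")
    return buf.getvalue()


class ParseError(ValueError):
    def __init__(self, message, line):
        super().__init__(f"line {line}: {message}")
        self.line = line


def import_text(text: str) -> TableCollection:
    """Parse a text dump produced by :func:`export_text`."""
    lines = text.splitlines()
    t = TableCollection(sequence_length=1.0)
    seen_length = False
    section = None
    for ln, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if line.startswith("#sequence_length"):
            t.sequence_length = float(line.split()[1])
            seen_length = True
            continue
        if line.startswith("#discrete_genome"):
            t.discrete_genome = bool(int(line.split()[1]))
            continue
        if line.startswith("#"):
            section = line[1:].strip()
            continue
        parts = line.split("\t")
        try:
            if section == "nodes":
                if parts[0] == "id":
                    continue
                t.nodes.append(
                    Node(int(parts[1]), float(parts[2]), int(parts[3]), int(parts[4]))
                )
            elif section == "edges":
                if parts[0] == "left":
                    continue
                t.edges.append(
                    Edge(float(parts[0]), float(parts[1]), int(parts[2]), int(parts[3]))
                )
            elif section == "sites":
                if parts[0] == "position":
                    continue
                t.sites.append(Site(float(parts[0]), parts[1]))
            elif section == "mutations":
                if parts[0] == "site":
                    continue
                t.mutations.append(
                    Mutation(int(parts[0]), int(parts[1]), parts[2], float(parts[3]), int(parts[4]))
                )
            elif section == "migrations":
                if parts[0] == "left":
                    continue
                t.migrations.append(
                    MigrationRecord(
                        float(parts[0]), float(parts[1]), int(parts[2]),
                        int(parts[3]), int(parts[4]), float(parts[5]),
                    )
                )
            elif section == "individuals":
                if parts[0] == "id":
                    continue
                nodes = tuple(int(x) for x in parts[1].split(",") if x != "")
                t.individuals.append(Individual(nodes))
            else:
                raise ParseError("content outside any section", ln)
        except (ValueError, IndexError) as err:
            if isinstance(err, ParseError):
                raise
            raise ParseError(f"malformed row: {err}", ln) from err
    if not seen_length:
        raise ParseError("missing #sequence_length preamble", len(lines))
    for i, e in enumerate(t.edges):
        if not (0 <= e.parent < len(t.nodes)) or not (0 <= e.child < len(t.nodes)):
            raise ParseError(f"edge row {i} references unknown node", 0)
    return t


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def export_newick(tree: MarginalTree, precision: int = 14) -> str:
    """Newick with branch lengths time(parent) - time(child); leaves "n<id>"."""
    roots = tree.roots
    if len(roots) != 1:
        raise ValueError("Newick export requires a single-root tree")

    def fmt_len(u, p):
        return f"{tree.time(p) - tree.time(u):.{precision}g}"

    def rec(u, p):
        ch = tree.children(u)
        label = "" if ch else f"n{u}"
        inner = f"({','.join(rec(c, u) for c in ch)})" if ch else ""
        blen = "" if p is None else f":{fmt_len(u, p)}"
        return f"{inner}{label}{blen}"

    return rec(roots[0], None) + ";"


def site_genotypes(t: TableCollection, site_id: int, samples=None):
    """Allele of each sample at a site, by mutation propagation.

    The most recent (smallest-time) mutation on the path above each sample
    wins; samples with no mutation above carry the ancestral state.
    """
    if not (0 <= site_id < len(t.sites)):
        raise ValueError(f"unknown site {site_id}")
    if samples is None:
        samples = t.samples
    site = t.sites[site_id]
    pos = site.position
    parent = [NULL] * len(t.nodes)
    for e in t.edges:
        if e.left <= pos < e.right:
            parent[e.child] = e.parent
    muts = {}
    for m in t.mutations:
        if m.site == site_id:
            # youngest mutation on each node is the one visible below it
            if m.node not in muts or m.time < muts[m.node].time:
                muts[m.node] = m
    out = []
    for s in samples:
        u = s
        allele = site.ancestral_state
        while u != NULL:
            if u in muts:
                allele = muts[u].derived_state
                break
            u = parent[u]
        out.append(allele)
    return out


def export_vcf(t: TableCollection) -> str:
    """VCF 4.2 text: one record per site, CHROM "1", POS = position + 1.

    Genotypes come from mutation propagation down the marginal tree at each
    site.  Sample nodes are grouped into individuals where an individuals
    table is present; otherwise each sample node is a haploid column.
    """
    if not t.discrete_genome:
        raise ValueError("VCF requires discrete (integer) coordinates")
    samples = t.samples
    if t.individuals:
        groups = [
            [u for u in ind.nodes if t.nodes[u].is_sample] for ind in t.individuals
        ]
        groups = [g for g in groups if g]
        names = [f"ind{i}" for i in range(len(groups))]
    else:
        groups = [[u] for u in samples]
        names = [f"n{u}" for u in samples]
    buf = io.StringIO()
    w = buf.write
    w("##fileformat=VCFv4.2\n")
    w(f"##contig=<ID=1,length={int(t.sequence_length)}>\n")
    w('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    w("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(names) + "\n")
    for sid, site in enumerate(t.sites):
        ref = site.ancestral_state
        alts = []
        for m in t.mutations:
            if m.site == sid and m.derived_state != ref and m.derived_state not in alts:
                alts.append(m.derived_state)
        allele_index = {ref: 0}
        for k, a in enumerate(alts, start=1):
            allele_index[a] = k
        geno = dict(zip(samples, site_genotypes(t, sid)))
        cols = []
        for g in groups:
            cols.append("|".join(str(allele_index[geno[u]]) for u in g))
        alt_field = ",".join(alts) if alts else "."
        w(f"1\t{int(site.position) + 1}\t.\t{ref}\t{alt_field}\t.\tPASS\t.\tGT\t"
          + "\t".join(cols) + "\n")
    return buf.getvalue()
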