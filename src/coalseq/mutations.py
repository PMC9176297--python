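"""Finite-sites mutation generation on tree-sequence tables.

Mutations are laid down on an edge-by-edge basis, independently of how the
ancestry was produced: any valid table collection can be mutated.  For each
edge and each rate-map interval overlapping it, the number of mutations is
Poisson with mean ``rate * overlapping_span * edge_duration`` (duration
optionally clipped to a time window); positions are drawn weighted by the
rate map (integers on discrete genomes, where recurrent hits share a site)
and times uniformly on the edge's clipped duration.  Mutations stacked at
one site are threaded oldest to youngest: each mutation's input allele is
its parent mutation's derived allele (or the site's ancestral allele, drawn
from the model's root distribution), and its derived allele is drawn from
the model's transition-matrix row — so recurrent and back mutations arise
naturally.

Transition matrices here have zero diagonal: every recorded mutation
changes state, which keeps genotype and VCF semantics unambiguous.  The
expected number of recorded mutations therefore equals the rate-map mass
times the total edge area, independent of the model.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from . import tables as tbl
from .ratemap import RateMap

__all__ = [
    "MutationModel",
    "MutationParams",
    "builtin_model",
    "sim_mutations",
    "overlay",
    "genotypes_at",
]

_NUC = ["A", "C", "G", "T"]


@dataclass
class MutationModel:
    """Allele alphabet, root distribution and per-mutation transition matrix.

    ``transition_matrix[i, j]`` is the probability that a mutation carried
    by allele ``alleles[i]`` produces ``alleles[j]``.  Rows sum to one and
    the diagonal is zero.  ``kind`` marks special models (infinite alleles)
    that do not use a fixed matrix.
    """

    alleles: list
    root_distribution: np.ndarray = None
    transition_matrix: np.ndarray = None
    kind: str = "matrix"

    def __post_init__(self):
        if self.kind == "infinite_alleles":
            return
        self.root_distribution = np.asarray(self.root_distribution, dtype=float)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        k = len(self.alleles)
        if self.root_distribution.shape != (k,):
            raise ValueError("root distribution has wrong length")
        if abs(self.root_distribution.sum() - 1) > 1e-12:
            raise ValueError("root distribution must sum to 1")
        if self.transition_matrix.shape != (k, k):
            raise ValueError("transition matrix has wrong shape")
        if np.any(np.abs(self.transition_matrix.sum(axis=1) - 1) > 1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(np.diag(self.transition_matrix) != 0):
            raise ValueError("transition matrix diagonal must be zero")

    def index(self, allele):
        try:
            return self.alleles.index(allele)
        except ValueError:
            raise ValueError(f"allele {allele!r} not in model alphabet") from None

    def equilibrium(self) -> np.ndarray:
        """Stationary distribution of the mutation jump chain."""
        P = self.transition_matrix
        w, v = np.linalg.eig(P.T)
        i = int(np.argmin(np.abs(w - 1)))
        pi = np.real(v[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


def _from_rates(alleles, Q, freqs):
    """Jump chain of a rate matrix: zero diagonal, rows renormalised."""
    Q = np.asarray(Q, dtype=float)
    np.fill_diagonal(Q, 0.0)
    P = Q / Q.sum(axis=1, keepdims=True)
    return MutationModel(list(alleles), np.asarray(freqs, dtype=float), P)


def _gtr(exchangeabilities, freqs):
    # order of exchangeabilities: AC, AG, AT, CG, CT, GT
    s = np.zeros((4, 4))
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    for (i, j), x in zip(pairs, exchangeabilities):
        s[i, j] = s[j, i] = x
    Q = s * np.asarray(freqs)[None, :]
    return _from_rates(_NUC, Q, freqs)


def _load_protein_model(name):
    text = resources.files("coalseq.data").joinpath(f"{name}.tsv").read_text()
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    alleles = lines[0].split("\t")
    root = np.array([float(x) for x in lines[1].split("\t")])
    P = np.array([[float(x) for x in ln.split("\t")] for ln in lines[2:]])
    return MutationModel(alleles, root, P)


def builtin_model(name: str, **kw) -> MutationModel:
    """Construct one of the named mutation models.

    Nucleotide models (JC69, K2P, K3P, HKY, F84, GTR) are built from
    exchangeabilities times equilibrium frequencies, then converted to the
    mutation jump chain (zero diagonal, rows renormalised).  PAM and
    BLOSUM62 are 20-allele empirical amino-acid matrices shipped as data
    files.  BINARY is a two-allele flip model and INFINITE_ALLELES labels
    every mutation with a fresh integer allele.
    """
    name = name.upper()
    uniform = np.full(4, 0.25)
    if name == "JC69":
        return _gtr(np.ones(6), uniform)
    if name == "K2P":
        kappa = kw.get("kappa", 2.0)
        return _gtr([1, kappa, 1, 1, kappa, 1], uniform)
    if name == "K3P":
        kappa1 = kw.get("kappa1", 2.0)  # transitions
        kappa2 = kw.get("kappa2", 0.5)  # A<->T / C<->G transversions
        return _gtr([1, kappa1, kappa2, kappa2, kappa1, 1], uniform)
    if name == "HKY":
        kappa = kw.get("kappa", 2.0)
        freqs = np.asarray(kw.get("freqs", uniform), dtype=float)
        if abs(freqs.sum() - 1) > 1e-9:
            raise ValueError("freqs must sum to 1")
        return _gtr([1, kappa, 1, 1, kappa, 1], freqs)
    if name == "F84":
        kappa = kw.get("kappa", 1.0)
        freqs = np.asarray(kw.get("freqs", uniform), dtype=float)
        if abs(freqs.sum() - 1) > 1e-9:
            raise ValueError("freqs must sum to 1")
        pur = freqs[0] + freqs[2]   # A + G
        pyr = freqs[1] + freqs[3]   # C + T
        # transition exchangeability 1 + kappa / (purine or pyrimidine mass)
        return _gtr([1, 1 + kappa / pur, 1, 1, 1 + kappa / pyr, 1], freqs)
    if name == "GTR":
        rates = kw["rates"]
        freqs = np.asarray(kw.get("freqs", uniform), dtype=float)
        if len(rates) != 6:
            raise ValueError("GTR needs 6 exchangeabilities (AC AG AT CG CT GT)")
        if abs(freqs.sum() - 1) > 1e-9:
            raise ValueError("freqs must sum to 1")
        return _gtr(rates, freqs)
    if name in ("PAM", "BLOSUM62"):
        return _load_protein_model(name)
    if name == "BINARY":
        return MutationModel(["0", "1"], np.array([1.0, 0.0]),
                             np.array([[0.0, 1.0], [1.0, 0.0]]))
    if name == "INFINITE_ALLELES":
        return MutationModel(["0"], kind="infinite_alleles")
    raise ValueError(f"unknown mutation model {name!r}")


# ---------------------------------------------------------------------------

@dataclass
class MutationParams:
    rate: object = 0.0                  # RateMap or uniform per-site rate
    model: object = "JC69"              # MutationModel or builtin name
    discrete: bool = None               # default: follow the tables
    start_time: float = None
    end_time: float = None
    keep_existing: bool = False
    seed: int = 1

    def resolved(self, t: tbl.TableCollection):
        rate_map = self.rate if isinstance(self.rate, RateMap) else \
            RateMap.uniform(t.sequence_length, float(self.rate))
        model = self.model if isinstance(self.model, MutationModel) else \
            builtin_model(self.model)
        discrete = t.discrete_genome if self.discrete is None else self.discrete
        lo = -np.inf if self.start_time is None else float(self.start_time)
        hi = np.inf if self.end_time is None else float(self.end_time)
        if lo >= hi:
            raise ValueError("start_time must be below end_time")
        return rate_map, model, discrete, lo, hi


def sim_mutations(t: tbl.TableCollection, p: MutationParams) -> tbl.TableCollection:
    """Overlay mutations on a copy of ``t``; the input is not modified."""
    if tbl.validate_tables(t):
        raise ValueError("input tables are invalid")
    rate_map, model, discrete, lo, hi = p.resolved(t)
    rng = np.random.default_rng(p.seed)
    out = tbl.sort_tables(t)
    # continuous mutation positions on an integer-coordinate ancestry make
    # the result a continuous-genome table collection
    out.discrete_genome = out.discrete_genome and discrete
    if not p.keep_existing:
        out.sites = []
        out.mutations = []

    # 1. throw raw mutations (position, node, time) edge by edge
    raw = []
    for e in out.edges:
        child_t = out.nodes[e.child].time
        parent_t = out.nodes[e.parent].time
        t0, t1 = max(child_t, lo), min(parent_t, hi)
        if t1 <= t0:
            continue
        mass = rate_map.mass(e.left, e.right)
        if mass <= 0:
            continue
        count = rng.poisson(mass * (t1 - t0))
        for _ in range(count):
            x = rate_map.position_of_mass(e.left, rng.random() * mass)
            pos = float(int(x)) if discrete else x
            if not (e.left <= pos < e.right):
                continue  # discrete rounding at the right edge boundary
            raw.append((pos, e.child, rng.uniform(t0, t1)))

    # 2. build/reuse sites and insert mutations
    site_by_pos = {s.position: i for i, s in enumerate(out.sites)}
    counter = sum(
        1 for _ in out.mutations
    ) + len(out.sites)  # infinite-alleles label counter
    for pos, node, time in sorted(raw):
        if pos in site_by_pos:
            sid = site_by_pos[pos]
        else:
            if model.kind == "infinite_alleles":
                anc = "0"
            else:
                anc = model.alleles[
                    rng.choice(len(model.alleles), p=model.root_distribution)
                ]
            sid = out.add_site(pos, anc)
            site_by_pos[pos] = sid
        out.add_mutation(sid, node, "", time)

    # 3. thread parent pointers, then assign derived states oldest-first
    out = tbl.sort_tables(out)
    tbl._rethread_mutation_parents(out)
    out = tbl.sort_tables(out)
    for m in out.mutations:  # sorted by (site, descending time)
        if m.derived_state:
            continue  # kept pre-existing mutation
        if m.parent == tbl.NULL:
            input_state = out.sites[m.site].ancestral_state
        else:
            input_state = out.mutations[m.parent].derived_state
        if model.kind == "infinite_alleles":
            counter += 1
            m.derived_state = str(counter)
        else:
            row = model.transition_matrix[model.index(input_state)]
            m.derived_state = model.alleles[rng.choice(len(row), p=row)]
    bad = tbl.validate_tables(out)
    assert not bad, f"mutation generation produced invalid tables: {bad}"
    return out


def overlay(t: tbl.TableCollection, layers) -> tbl.TableCollection:
    """Apply several mutation layers in sequence, keeping earlier ones.

    Layers with different alphabets must not meet at a shared site; if they
    do, an error names the site.
    """
    if not layers:
        raise ValueError("layers must be nonempty")
    out = t
    for layer in layers:
        layer = MutationParams(**{**layer.__dict__, "keep_existing": True}) \
            if not layer.keep_existing else layer
        _, model, _, _, _ = layer.resolved(out)
        if model.kind != "infinite_alleles":
            for s in out.sites:
                pos_rate = layer.rate.mass(s.position, s.position + 1) \
                    if isinstance(layer.rate, RateMap) else float(layer.rate)
                if pos_rate > 0 and s.ancestral_state not in model.alleles:
                    raise ValueError(
                        f"allele alphabet clash at site position {s.position}"
                    )
        out = sim_mutations(out, layer)
    return out


def genotypes_at(t: tbl.TableCollection, site) -> list:
    """Allele of each sample at a site (most recent mutation above wins)."""
    return tbl.site_genotypes(t, site)
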