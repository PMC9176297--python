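# coalseq

Backwards-in-time population-genetic simulation on succinct
tree-sequence tables: coalescent ancestry with recombination and gene
conversion, multi-population demography, alternative genealogy models
(SMC/SMC′, discrete-time Wright–Fisher, instantaneous bottlenecks, Beta-
and Dirac- multiple-merger coalescents, selective sweeps), an independent
finite-sites mutation generator, and likelihood functions for fully
recorded ancestral recombination graphs (ARGs).

It is written for population geneticists who need ground-truth genealogies
and sequence variation under explicit models — to validate inference
methods, explore analytic approximations, or generate training data — and
for method developers who want a transparent, pure-Python engine whose
every event is inspectable.

## The model

The coalescent traces the ancestry of `n` sampled genomes backwards in
time. Each extant lineage carries an ordered set of *ancestral segments*
(genome intervals inherited by at least one sample). In a population of
size `N(t)` with ploidy `p`, any two lineages in the same population merge
at rate `1/(pN(t))` per generation; recombination splits a lineage at rate
`ρ(x)` per unit per generation over its span (including "trapped"
non-ancestral gaps); gene conversion excises a tract with geometric
(discrete) or exponential (continuous) length. Where merging lineages
overlap, a node and edges are recorded; an interval inherited by the whole
sample has found its MRCA and is retired. The recorded tables — nodes,
edges, sites, mutations, migrations, individuals — encode the sequence of
correlated *marginal trees* along the genome.

Mutations are generated independently of the ancestry, edge by edge: the
count on an edge is Poisson with mean `μ · span · duration`, positions are
drawn from the mutation rate map, and stacked mutations at one site are
threaded parent-to-child so recurrent and back mutations arise naturally
under any row-stochastic transition matrix (JC69, HKY, F84, GTR, K2P,
K3P, PAM, BLOSUM62, binary, infinite-alleles).

With `record_full_arg`, recombination and common-ancestor events store
flagged nodes with unary edges so the complete ARG is preserved;
`arg_log_likelihood` then evaluates the sampling density of the
realization under the coalescent with recombination, and
`mutation_log_likelihood` the infinite-sites Poisson density. Demographic
models (sizes, growth, migration matrices, splits, admixture, pulses,
census, bottlenecks) feed both the simulator and numerical methods for
the pair coalescence rate `c(t)` and its inverse, the IICR.

## A worked example

```python
import coalseq as cq
from coalseq import mutations as mut, stats as st, tables as tbl

ts = cq.sim_ancestry(
    samples=[(0, 3)],            # 3 diploid individuals -> 6 sample genomes
    ploidy=2,
    population_size=1_000,       # N_e diploids
    sequence_length=10_000,      # 10 kb, discrete coordinates
    recombination=1e-8,          # per base per generation
    seed=42,
)
ts = mut.sim_mutations(ts, mut.MutationParams(rate=1e-7, seed=42))

print("marginal trees:   ", st.num_trees(ts))
print("segregating sites:", st.segregating_sites(ts))
print("pairwise diversity:", round(st.pairwise_diversity(ts), 3))
print("TMRCA at 5 kb:    ", round(st.tmrca(ts, 5_000), 1), "generations")
tree = next(tbl.iterate_trees(ts))
print(tbl.export_newick(tree, precision=4))
```

prints

```
marginal trees:    2
segregating sites: 10
pairwise diversity: 3.333
TMRCA at 5 kb:     2819.4 generations
(n3:2819,(n0:676.2,(n4:571.2,(n1:493.8,(n2:311.5,n5:311.5):182.3):77.38):105.1):2143);
```

One recombination event fell inside the 10 kb, so the sample's history is
two marginal trees. Ten of the mutations are polymorphic among the six
genomes; the average pairwise difference of 3.33 sites is an estimate of
θ = 4N_e μ L = 4 per 10 kb (here slightly below its expectation, as single
replicates are). The tree at 5 kb finds the whole sample's common ancestor
2819 generations ago (the expectation is `4N(1 - 1/n) ≈ 3333`); the Newick
string carries branch lengths in generations, with leaves labelled by node
id.

Tables round-trip losslessly through a plain-text dump
(`tables.export_text` / `import_text`), and export to Newick and VCF 4.2.
The same functionality is exposed on the command line:

```sh
coalseq ancestry -n 3 -L 10000 -r 1e-8 -N 1000 --seed 42 -o a.tsdump
coalseq mutations -i a.tsdump -o m.tsdump --rate 1e-7 --model JC69 --seed 42
coalseq likelihood --arg-dump arg.tsdump --rho 1.0 --ne 1000
coalseq validate --suite kingman_basic --reps 300 --seed 1
```

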