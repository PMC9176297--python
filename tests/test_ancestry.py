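"""Tests for the backwards-in-time ancestry engine."""
import numpy as np
import pytest
from scipy import stats as sps

import coalseq as cq
from coalseq import ancestry as anc
from coalseq import tables as tbl
from coalseq.ratemap import RateMap


def lineage(*intervals, node=0):
    return anc.Lineage([anc.Segment(l, r, node) for l, r in intervals])


class TestCountLinks:
    def test_single_unit_discrete(self):
        m = RateMap.uniform(1, 0.5)
        assert anc.count_links(lineage((0, 1)), m, discrete=True) == 0

    def test_trapped_gap_included_continuous(self):
        m = RateMap.uniform(30, 0.1)
        links = anc.count_links(lineage((0, 10), (20, 30)), m, discrete=False)
        assert links == pytest.approx(0.1 * 30)

    def test_discrete_excludes_terminal_unit(self):
        m = RateMap.uniform(100, 1.0)
        assert anc.count_links(lineage((0, 10)), m, discrete=True) == pytest.approx(9)

    def test_zero_rate_map(self):
        m = RateMap.uniform(100, 0.0)
        assert anc.count_links(lineage((0, 50)), m, discrete=False) == 0

    def test_variable_map(self):
        m = RateMap([0, 10, 20], [0.0, 1.0])
        assert anc.count_links(lineage((0, 20)), m, discrete=False) == pytest.approx(10)


class TestRecombinationEvent:
    def test_simple_split(self):
        a, b = anc.recombination_event(lineage((0, 10)), 3)
        assert [(s.left, s.right) for s in a.segments] == [(0, 3)]
        assert [(s.left, s.right) for s in b.segments] == [(3, 10)]

    def test_split_in_trapped_gap(self):
        a, b = anc.recombination_event(lineage((0, 5), (8, 12)), 6)
        assert [(s.left, s.right) for s in a.segments] == [(0, 5)]
        assert [(s.left, s.right) for s in b.segments] == [(8, 12)]

    def test_breakpoint_outside_span_rejected(self):
        with pytest.raises(ValueError):
            anc.recombination_event(lineage((2, 10)), 2)

    @pytest.mark.parametrize("bp", [1.5, 4.0, 9.9])
    def test_interval_algebra(self, bp):
        lin = lineage((0, 3), (5, 10))
        a, b = anc.recombination_event(lin, bp)
        # brute-force set check on a fine grid
        for x in np.arange(0.25, 10, 0.5):
            in_orig = any(s.left <= x < s.right for s in lin.segments)
            in_a = any(s.left <= x < s.right for s in a.segments)
            in_b = any(s.left <= x < s.right for s in b.segments)
            assert in_a == (in_orig and x < bp)
            assert in_b == (in_orig and x >= bp)


class TestGeneConversion:
    def test_tract_inside_segment(self):
        out, ins = anc.gene_conversion_event(lineage((0, 100)), 40, 10)
        assert [(s.left, s.right) for s in out.segments] == [(0, 40), (50, 100)]
        assert [(s.left, s.right) for s in ins.segments] == [(40, 50)]

    def test_tract_covering_whole_span_noop(self):
        lin = lineage((10, 20))
        out, ins = anc.gene_conversion_event(lin, 0, 100)
        assert ins is None and out is lin

    def test_tract_missing_material_noop(self):
        lin = lineage((0, 10))
        out, ins = anc.gene_conversion_event(lin, 50, 5)
        assert ins is None

    @pytest.mark.parametrize("start,length", [(2, 4), (0.5, 6), (4, 10)])
    def test_straddling_boundary_algebra(self, start, length):
        lin = lineage((0, 3), (5, 12))
        out, ins = anc.gene_conversion_event(lin, start, length)
        for x in np.arange(0.25, 12, 0.5):
            in_orig = any(s.left <= x < s.right for s in lin.segments)
            in_tract = start <= x < start + length
            got_in = ins is not None and any(
                s.left <= x < s.right for s in ins.segments
            )
            got_out = any(s.left <= x < s.right for s in out.segments)
            if ins is not None:
                assert got_in == (in_orig and in_tract)
                assert got_out == (in_orig and not in_tract)

    def test_tract_length_mean(self):
        rng = np.random.default_rng(5)
        disc = [anc.draw_tract_length(rng, 10.0, True) for _ in range(4000)]
        cont = [anc.draw_tract_length(rng, 10.0, False) for _ in range(4000)]
        for vals in (disc, cont):
            se = np.std(vals) / np.sqrt(len(vals))
            assert abs(np.mean(vals) - 10.0) <= 3 * se


class TestSimAncestry:
    def test_single_haploid_sample(self):
        t = cq.sim_ancestry(samples=[(0, 1)], ploidy=1, sequence_length=10,
                            population_size=10, seed=1)
        assert len(t.nodes) == 1 and len(t.edges) == 0

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError, match="sample"):
            cq.sim_ancestry(samples=[], sequence_length=10, seed=1)

    def test_structural_validity_with_recombination(self):
        t = cq.sim_ancestry(samples=[(0, 5)], ploidy=2, population_size=100,
                            sequence_length=1000, recombination=1e-4, seed=2)
        assert tbl.validate_tables(t) == []
        for tree in tbl.iterate_trees(t):
            assert len(tree.roots) == 1

    def test_determinism(self):
        kw = dict(samples=[(0, 4)], ploidy=2, population_size=100,
                  sequence_length=500, recombination=2e-4,
                  gene_conversion=1e-4, gene_conversion_tract_mean=20)
        a = cq.sim_ancestry(seed=42, **kw)
        b = cq.sim_ancestry(seed=42, **kw)
        assert tbl.export_text(a) == tbl.export_text(b)

    def test_pair_coalescence_exponential(self):
        # n=2, r=0: T ~ Exp(mean ploidy*N); KS at alpha=0.01
        N = 500.0
        vals = np.array([
            tbl.tree_at(cq.sim_ancestry(
                samples=[(0, 1)], ploidy=2, population_size=N,
                sequence_length=1, seed=s), 0).tmrca()
            for s in range(1, 2001)
        ])
        ks = sps.kstest(vals / (2 * N), "expon")
        assert ks.pvalue > 0.01

    def test_mean_pair_tmrca(self):
        N = 100.0
        vals = [
            tbl.tree_at(cq.sim_ancestry(
                samples=[(0, 1)], ploidy=2, population_size=N,
                sequence_length=1, seed=s), 0).tmrca()
            for s in range(1, 3001)
        ]
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 2 * N) <= 3 * se

    def test_num_trees_increases_with_rho(self):
        from coalseq import stats as st
        rates = [0.0, 5e-5, 2e-4, 8e-4]
        means = []
        for r in rates:
            counts = [st.num_trees(cq.sim_ancestry(
                samples=[(0, 3)], ploidy=2, population_size=50,
                sequence_length=200, recombination=r, seed=s))
                for s in range(1, 41)]
            means.append(np.mean(counts))
        rho_corr = sps.spearmanr(rates, means).statistic
        assert means[0] == 1.0
        assert rho_corr > 0

    def test_end_time_truncates(self):
        t = cq.sim_ancestry(samples=[(0, 5)], ploidy=2, population_size=1000,
                            sequence_length=1, seed=3, end_time=10.0)
        assert all(n.time <= 10.0 for n in t.nodes)
        tree = next(tbl.iterate_trees(t))
        assert len(tree.roots) > 1

    def test_mrca_material_never_reappears(self):
        # once an interval coalesces fully it is retired from every lineage
        sim = anc.Simulator(anc.AncestryParams(
            samples=[(0, 4)], ploidy=2, population_size=50,
            sequence_length=200, recombination=1e-3, seed=9))
        sim.run()
        # overlap counts are 0 where MRCA was found: total of 0 everywhere
        assert all(v == 0 for v in sim.S.val)
        assert sim.num_lineages == 0


class TestRecombinationBound:
    def test_zero_rho(self):
        assert anc.recombination_bound(5, 0.0) == 0.0

    def test_printed_formula(self):
        assert anc.recombination_bound(2, 1.0) == pytest.approx(2.0)
        h = sum(1 / i for i in range(1, 8))
        assert anc.recombination_bound(8, 2.5) == pytest.approx(2.5 * 3.5 * h * h)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            anc.recombination_bound(1, 1.0)

    @pytest.mark.parametrize("n,rho", [(4, 0.5), (8, 2.0)])
    def test_trapped_events_below_bound(self, n, rho):
        N, L = 100.0, 100.0
        r = rho / (2 * 1 * N * L)  # ploidy-1 scaling
        counts = []
        for s in range(1, 101):
            sim = anc.Simulator(anc.AncestryParams(
                samples=[(0, n)], ploidy=1, population_size=N,
                sequence_length=L, recombination=r, seed=s,
                discrete_genome=False))
            sim.run()
            counts.append(sim.num_trapped_re_events)
        assert np.mean(counts) <= anc.recombination_bound(n, rho)


class TestFullArg:
    def test_no_recomb_no_flags(self):
        t = cq.sim_ancestry(samples=[(0, 3)], ploidy=2, population_size=50,
                            sequence_length=100, seed=1, record_full_arg=True)
        assert not any(n.flags & tbl.NODE_RECOMB_EVENT for n in t.nodes)

    def test_recomb_nodes_flagged_in_pairs(self):
        sim = anc.Simulator(anc.AncestryParams(
            samples=[(0, 3)], ploidy=2, population_size=50,
            sequence_length=200, recombination=1e-3, seed=7,
            record_full_arg=True))
        t = sim.run()
        re_nodes = [n for n in t.nodes if n.flags & tbl.NODE_RECOMB_EVENT]
        assert len(re_nodes) == 2 * sim.num_re_events
        times = [n.time for n in re_nodes]
        assert sorted(set(times)) == sorted(times)[::2]

    def test_passthrough_nodes_unary(self):
        t = cq.sim_ancestry(samples=[(0, 3)], ploidy=2, population_size=50,
                            sequence_length=150, recombination=1e-3, seed=3,
                            record_full_arg=True)
        pass_nodes = {
            i for i, n in enumerate(t.nodes)
            if n.flags & tbl.NODE_CA_PASSTHROUGH
        }
        assert pass_nodes
        for tree in tbl.iterate_trees(t):
            for u in pass_nodes:
                assert len(tree.children(u)) <= 1


class TestRecapitation:
    def test_continue_uncoalesced_forest(self):
        part = cq.sim_ancestry(samples=[(0, 3)], ploidy=2, population_size=100,
                               sequence_length=100, recombination=1e-4,
                               seed=2, end_time=30)
        sim = anc.initialize_from_tables(part, anc.AncestryParams(
            samples=[], ploidy=2, population_size=100, sequence_length=100,
            recombination=1e-4, seed=77))
        full = sim.run()
        assert tbl.validate_tables(full) == []
        assert all(len(tr.roots) == 1 for tr in tbl.iterate_trees(full))
        input_edges = {(e.left, e.right, e.parent, e.child) for e in part.edges}
        out_edges = {(e.left, e.right, e.parent, e.child) for e in full.edges}
        assert input_edges <= out_edges
        start = max(n.time for n in part.nodes)
        new_nodes = full.nodes[len(part.nodes):]
        assert all(n.time > start for n in new_nodes)

    def test_fully_coalesced_input_ends_immediately(self):
        done = cq.sim_ancestry(samples=[(0, 3)], ploidy=2, population_size=50,
                               sequence_length=50, seed=5)
        sim = anc.initialize_from_tables(done, anc.AncestryParams(
            samples=[], ploidy=2, population_size=50, sequence_length=50,
            seed=1))
        out = sim.run()
        assert tbl.export_text(out) == tbl.export_text(done)

    def test_empty_input_equivalent_to_fresh(self):
        empty = tbl.TableCollection(50.0)
        for _ in range(4):
            empty.add_node(tbl.NODE_IS_SAMPLE, 0.0, 0)
        sim = anc.initialize_from_tables(empty, anc.AncestryParams(
            samples=[], ploidy=2, population_size=50, sequence_length=50,
            seed=11))
        out = sim.run()
        assert tbl.validate_tables(out) == []
        assert all(len(tr.roots) == 1 for tr in tbl.iterate_trees(out))


class TestGeneConversionSim:
    def test_tract_mean_from_engine(self):
        sim_lengths = []
        for s in range(1, 120):
            sim = anc.Simulator(anc.AncestryParams(
                samples=[(0, 3)], ploidy=2, population_size=100,
                sequence_length=1000, gene_conversion=2e-5,
                gene_conversion_tract_mean=30.0, seed=s))
            sim.run()
            sim_lengths.extend(sim.gc_tract_lengths)
        se = np.std(sim_lengths) / np.sqrt(len(sim_lengths))
        assert abs(np.mean(sim_lengths) - 30.0) <= 3 * se
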