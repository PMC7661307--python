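"""Intron counts, tandem clusters, order signatures, retrocopy calls."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from klfsp.examples import (
    cephalopod_gene_models,
    cephalopod_gene_tree,
    cephalopod_species_tree,
)
from klfsp.reconcile import lca_reconcile
from klfsp.simulate import SimulationConfig, emit_annotations, simulate_family
from klfsp.synteny import (
    GeneModel,
    LocusCluster,
    assign_retro_events,
    classify_retrocopies,
    detect_clusters,
    intron_count,
    order_signature,
    read_gff3,
    signatures_equal,
    write_gff3,
)
from klfsp.reconcile import species_tree_from_string


def gene(gid, start, scaffold="s1", strand="+", n_exons=1, species="X", family=""):
    width = 100
    exons = tuple(
        (start + i * 2 * width, start + i * 2 * width + width) for i in range(n_exons)
    )
    return GeneModel(gid, species, scaffold, start, exons[-1][1], strand, exons, family)


class TestGeneModel:
    def test_intron_count_is_exons_minus_one(self):
        assert intron_count(gene("g", 0, n_exons=1)) == 0
        assert intron_count(gene("g", 0, n_exons=5)) == 4

    def test_cephalopod_models_follow_the_intronless_pattern(self):
        by_family = {}
        for m in cephalopod_gene_models():
            by_family.setdefault(m.family, []).append(m)
        assert all(intron_count(m) == 0 for m in by_family["b"] + by_family["c"])
        assert all(intron_count(m) > 0 for m in by_family["a"])

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(start=10, end=5),
            dict(strand="?"),
            dict(exons=()),
            dict(exons=((0, 50), (40, 80))),
        ],
    )
    def test_invalid_models_rejected(self, kwargs):
        base = dict(
            gene_id="g", species="X", scaffold="s", start=0, end=100,
            strand="+", exons=((0, 100),),
        )
        with pytest.raises(ValueError):
            GeneModel(**{**base, **kwargs})


class TestDetectClusters:
    def test_different_scaffolds_never_co_cluster(self):
        genes = [gene("a", 0, scaffold="s1"), gene("b", 0, scaffold="s2")]
        clusters = detect_clusters(genes)
        assert len(clusters) == 2

    def test_three_genes_within_window_form_one_cluster(self):
        genes = [gene("a", 0), gene("b", 500_000), gene("c", 1_400_000)]
        (c,) = detect_clusters(genes, window=1_500_000)
        assert [g.gene_id for g in c.members] == ["a", "b", "c"]
        assert c.diameter == 1_400_000

    def test_greedy_leftmost_split(self):
        genes = [gene("a", 0), gene("b", 1_000_000), gene("c", 2_000_000)]
        clusters = detect_clusters(genes, window=1_500_000)
        assert [[g.gene_id for g in c.members] for c in clusters] == [["a", "b"], ["c"]]

    def test_same_strand_requirement_splits_mixed_clusters(self):
        genes = [gene("a", 0, strand="+"), gene("b", 1000, strand="-")]
        assert len(detect_clusters(genes)) == 1
        assert len(detect_clusters(genes, require_same_strand=True)) == 2

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            detect_clusters([], window=-1)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        starts=st.lists(st.integers(0, 10_000_000), min_size=1, max_size=12),
        window=st.integers(0, 3_000_000),
    )
    def test_partition_invariants(self, starts, window):
        genes = [gene(f"g{i}", s) for i, s in enumerate(starts)]
        clusters = detect_clusters(genes, window=window)
        # clusters partition the input and respect the diameter bound
        flat = [g.gene_id for c in clusters for g in c.members]
        assert sorted(flat) == sorted(g.gene_id for g in genes)
        assert len(flat) == len(set(flat))
        for c in clusters:
            assert c.diameter <= window


class TestOrderSignature:
    def test_single_gene_cluster(self):
        c = LocusCluster((gene("a", 0, family="a"),), "s1")
        assert len(order_signature(c)) == 1

    def test_conserved_order_across_species(self):
        models = cephalopod_gene_models()
        per_species = {}
        for m in models:
            per_species.setdefault(m.species, []).append(m)
        sigs = [
            order_signature(detect_clusters(v)[0]) for v in per_species.values()
        ]
        assert signatures_equal(sigs[0], sigs[1]) and signatures_equal(sigs[1], sigs[2])

    def test_scaffold_flip_invariance(self):
        fwd = LocusCluster(
            (
                gene("x1", 0, family="b", strand="+"),
                gene("x2", 1000, family="c", strand="+"),
                gene("x3", 2000, family="a", strand="+"),
            ),
            "s1",
        )
        flipped = LocusCluster(
            (
                gene("y1", 0, family="a", strand="-"),
                gene("y2", 1000, family="c", strand="-"),
                gene("y3", 2000, family="b", strand="-"),
            ),
            "s1",
        )
        assert signatures_equal(order_signature(fwd), order_signature(flipped))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        labels=st.lists(st.sampled_from("abc"), min_size=1, max_size=6),
        strands=st.lists(st.sampled_from("+-"), min_size=6, max_size=6),
    )
    def test_equality_is_flip_invariant_equivalence(self, labels, strands):
        members = tuple(
            gene(f"g{i}", i * 1000, family=lab, strand=strands[i])
            for i, lab in enumerate(labels)
        )
        flipped = tuple(
            gene(f"f{i}", i * 1000, family=m.family,
                 strand="-" if m.strand == "+" else "+")
            for i, m in enumerate(reversed(members))
        )
        s1 = order_signature(LocusCluster(members, "s1"))
        s2 = order_signature(LocusCluster(flipped, "s1"))
        assert signatures_equal(s1, s1)
        assert signatures_equal(s1, s2) and signatures_equal(s2, s1)

    def test_unlabelled_member_rejected(self):
        c = LocusCluster((gene("a", 0),), "s1")
        with pytest.raises(ValueError):
            order_signature(c)


class TestClassifyRetrocopies:
    def test_intronless_with_parental_sibling(self):
        calls = {
            c.gene_id: c.call
            for c in classify_retrocopies(
                [gene("a", 0, n_exons=3), gene("b", 10_000, n_exons=1)]
            )
        }
        assert calls == {"a": "parental-like", "b": "retrocopy-candidate"}

    def test_all_intronless_family_is_ambiguous(self):
        calls = classify_retrocopies([gene("a", 0), gene("b", 10_000)])
        assert {c.call for c in calls} == {"ambiguous"}

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            classify_retrocopies([])

    def test_simulated_retro_flags_recovered_exactly(self):
        sp = species_tree_from_string("((A:1.0,B:1.0):1.0,C:2.0);")
        fam = simulate_family(
            sp,
            SimulationConfig(duplication_rate=0.5, retro_fraction=0.5, seed=11),
        )
        truth = {g.gene_id: g.retro for g in fam.all_genes}
        assert any(truth.values()) and not all(truth.values())
        models = emit_annotations(fam)
        by_species = {}
        for m in models:
            by_species.setdefault(m.species, []).append(m)
        for species_models in by_species.values():
            for call in classify_retrocopies(species_models):
                if all(truth[m.gene_id] for m in species_models):
                    assert call.call == "ambiguous"
                else:
                    expect = "retrocopy-candidate" if truth[call.gene_id] else "parental-like"
                    assert call.call == expect


class TestAssignRetroEvents:
    def _cephalopod_calls(self):
        by_species = {}
        for m in cephalopod_gene_models():
            by_species.setdefault(m.species, []).append(m)
        calls = []
        for sp in sorted(by_species):
            calls.extend(classify_retrocopies(by_species[sp]))
        return calls

    def test_no_candidates_no_events(self):
        gt = cephalopod_gene_tree()
        rec = lca_reconcile(gt, cephalopod_species_tree())
        from klfsp.synteny import RetrocopyCall

        calls = [
            RetrocopyCall(c.gene_id, False, "parental-like")
            for c in self._cephalopod_calls()
        ]
        assert assign_retro_events(gt, rec, calls) == []

    def test_cephalopod_fixture_two_stem_events(self):
        gt = cephalopod_gene_tree()
        rec = lca_reconcile(gt, cephalopod_species_tree())
        events = assign_retro_events(gt, rec, self._cephalopod_calls())
        assert len(events) == 2
        assert {e.node_branch for e in events} == {"Cephalopoda"}
        clades = {frozenset(e.clade_leaves) for e in events}
        assert clades == {
            frozenset({"Obi|Obi_b", "Esc|Esc_b", "Dpe|Dpe_b"}),
            frozenset({"Obi|Obi_c", "Esc|Esc_c", "Dpe|Dpe_c"}),
        }

    def test_event_count_bounded_by_duplications(self):
        gt = cephalopod_gene_tree()
        rec = lca_reconcile(gt, cephalopod_species_tree())
        events = assign_retro_events(gt, rec, self._cephalopod_calls())
        assert len(events) <= rec.duplication_count

    def test_simulated_single_retro_event_recovered(self):
        sp = species_tree_from_string("((A:1.0,B:1.0):1.0,C:2.0);")
        # search a seed giving exactly one retroduplication and no loss
        for seed in range(200):
            fam = simulate_family(
                sp,
                SimulationConfig(duplication_rate=0.25, retro_fraction=1.0, seed=seed),
            )
            retro_log = [e for e in fam.event_log if e.type == "retroduplication"]
            if len(retro_log) == 1 and len(fam.event_log) == 1:
                break
        else:
            pytest.fail("no suitable simulation found")
        rec = lca_reconcile(fam.gene_tree, fam.species)
        models = emit_annotations(fam)
        by_species = {}
        for m in models:
            by_species.setdefault(m.species, []).append(m)
        calls = []
        for s in sorted(by_species):
            calls.extend(classify_retrocopies(by_species[s]))
        events = assign_retro_events(fam.gene_tree, rec, calls)
        assert len(events) == 1
        assert events[0].node_branch == retro_log[0].branch


class TestGff3Roundtrip:
    def test_write_then_read_preserves_models(self, tmp_path):
        models = cephalopod_gene_models()
        path = tmp_path / "ceph.gff3"
        write_gff3(models, str(path))
        back = read_gff3(str(path))
        assert len(back) == len(models)
        by_id = {m.gene_id: m for m in back}
        for m in models:
            got = by_id[m.gene_id]
            assert (got.scaffold, got.start, got.end, got.strand) == (
                m.scaffold, m.start, m.end, m.strand,
            )
            assert got.exons == m.exons
            assert got.family == m.family
            assert got.species == m.species
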