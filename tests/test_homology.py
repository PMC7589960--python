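"""Homology-network inference: parsing, BBH, cutoff scan, networks, inventory."""

import numpy as np
import pytest

from m6arhythm.homology import (
    SimilarityFormatError,
    SimilarityHit,
    annotate_networks,
    bbh_orthologs,
    best_hit_map,
    build_networks,
    collapse_redundant,
    count_paralog_networks,
    default_grid,
    inventory_table,
    paralog_edges,
    read_similarity,
    select_cutoff,
    species_of,
)
from m6arhythm.simulate import generate_proteomes, simulate_similarity


def row(q, s, e, bits=200.0):
    return f"{q}\t{s}\t90.0\t100\t10\t0\t1\t100\t1\t100\t{e}\t{bits}"


class TestReadSimilarity:
    def test_parses_twelve_column_rows(self, tmp_path):
        p = tmp_path / "sim.tsv"
        p.write_text(row("A_1", "B_1", "1e-50") + "\n")
        table = read_similarity(p)
        hit = table.hits[0]
        assert hit == SimilarityHit("A_1", "B_1", 1e-50, 200.0)

    def test_self_hits_dropped_and_counted(self, tmp_path):
        p = tmp_path / "sim.tsv"
        p.write_text("\n".join([row("A_1", "A_1", "0.0"), row("A_1", "B_1", "1e-9")]) + "\n")
        table = read_similarity(p)
        assert len(table) == 1
        assert table.n_self_dropped == 1

    def test_comment_and_hand_count(self, tmp_path):
        p = tmp_path / "sim.tsv"
        lines = ["# comment", row("A_1", "B_1", "1e-50"), row("A_2", "A_2", "1e-99"),
                 row("B_1", "A_1", "1e-48")]
        p.write_text("\n".join(lines) + "\n")
        assert len(read_similarity(p)) == 2

    def test_short_row_raises_with_line_number(self, tmp_path):
        p = tmp_path / "sim.tsv"
        p.write_text("A_1\tB_1\t90.0\n")
        with pytest.raises(SimilarityFormatError, match="line 1"):
            read_similarity(p)

    def test_unparseable_numeric_raises_with_line_number(self, tmp_path):
        p = tmp_path / "sim.tsv"
        p.write_text(row("A_1", "B_1", "1e-50") + "\n" + row("A_2", "B_2", "oops") + "\n")
        with pytest.raises(SimilarityFormatError, match="line 2"):
            read_similarity(p)


class TestBestHitsAndBbh:
    def test_smaller_evalue_wins(self):
        hits = [SimilarityHit("A_1", "B_1", 1e-50, 180.0),
                SimilarityHit("A_1", "B_2", 1e-10, 300.0)]
        best = best_hit_map(hits)
        assert best[("A_1", "B")].subject_id == "B_1"

    def test_tie_breaks_by_bitscore_then_lexicographic(self):
        hits = [SimilarityHit("A_1", "B_1", 1e-50, 180.0),
                SimilarityHit("A_1", "B_2", 1e-50, 200.0)]
        assert best_hit_map(hits)[("A_1", "B")].subject_id == "B_2"
        hits = [SimilarityHit("A_1", "B_2", 1e-50, 200.0),
                SimilarityHit("A_1", "B_1", 1e-50, 200.0)]
        assert best_hit_map(hits)[("A_1", "B")].subject_id == "B_1"

    def test_reciprocal_pair_gives_one_edge(self):
        hits = [SimilarityHit("A_1", "B_1", 1e-50, 200.0),
                SimilarityHit("B_1", "A_1", 1e-48, 200.0)]
        edges = bbh_orthologs(best_hit_map(hits))
        assert [(a, b) for a, b, _ in edges] == [("A_1", "B_1")]

    def test_asymmetric_best_hits_give_no_edge(self):
        hits = [SimilarityHit("A_1", "B_1", 1e-50, 200.0),
                SimilarityHit("B_1", "A_2", 1e-60, 200.0),
                SimilarityHit("B_1", "A_1", 1e-40, 200.0)]
        assert bbh_orthologs(best_hit_map(hits)) == []

    def test_bbh_matches_brute_force_on_synthetic_table(self, rng):
        """O(n^2) oracle: check the reciprocal condition for every pair."""
        specs_seeds = range(20)
        for seed in specs_seeds:
            hits = _random_hits(np.random.default_rng(seed))
            edges = {(a, b) for a, b, _ in bbh_orthologs(best_hit_map(hits))}
            oracle = _bbh_oracle(hits)
            assert edges == oracle


def _random_hits(rng, n_species=3, n_per_species=2):
    """Random cross-species directed hit table (all ordered pairs reported)."""
    ids = [f"S{i}_P{j}" for i in range(n_species) for j in range(n_per_species)]
    hits = []
    for q in ids:
        for s in ids:
            if q == s or q.split("_")[0] == s.split("_")[0]:
                continue
            hits.append(SimilarityHit(q, s, 10.0 ** rng.uniform(-80, -5),
                                      float(rng.integers(50, 400))))
    return hits


def _bbh_oracle(hits):
    def best_of(query, target_sp):
        cands = [h for h in hits if h.query_id == query
                 and h.subject_id.split("_")[0] == target_sp]
        return min(cands, key=lambda h: (h.evalue, -h.bitscore, h.subject_id)).subject_id

    edges = set()
    ids = {h.query_id for h in hits}
    for a in ids:
        for b in ids:
            if a >= b or a.split("_")[0] == b.split("_")[0]:
                continue
            if best_of(a, b.split("_")[0]) == b and best_of(b, a.split("_")[0]) == a:
                edges.add((a, b))
    return edges


class TestParalogEdgesAndCutoff:
    def paralog_hits(self):
        """Toy within-species table: 1e-5 -> 1 component of 4; 1e-20 -> 2 of 2; 1e-50 -> 0."""
        pairs = [("S_A", "S_B", 1e-30), ("S_C", "S_D", 1e-25), ("S_B", "S_C", 1e-8)]
        hits = []
        for a, b, e in pairs:
            hits.append(SimilarityHit(a, b, e, 100.0))
            hits.append(SimilarityHit(b, a, e * 2, 100.0))
        return hits

    def test_reciprocal_pair_below_cutoff_is_edge(self):
        hits = [SimilarityHit("S_a", "S_b", 1e-30, 10.0),
                SimilarityHit("S_b", "S_a", 1e-28, 10.0)]
        assert paralog_edges(hits, "S", 1e-20) == [("S_a", "S_b", 1e-30)]

    def test_one_direction_only_gives_no_edge(self):
        hits = [SimilarityHit("S_a", "S_b", 1e-30, 10.0)]
        assert paralog_edges(hits, "S", 1e-20) == []

    def test_cutoff_sweep_matches_brute_force_filter(self, rng):
        ids = [f"S_p{i}" for i in range(5)]
        hits = []
        for a in ids:
            for b in ids:
                if a != b:
                    hits.append(SimilarityHit(a, b, 10.0 ** rng.uniform(-60, -2), 1.0))
        directed = {(h.query_id, h.subject_id): h.evalue for h in hits}
        for cutoff in (1e-5, 1e-10, 1e-20, 1e-40):
            got = {(a, b) for a, b, _ in paralog_edges(hits, "S", cutoff)}
            oracle = {
                (a, b) for a in ids for b in ids if a < b
                and (a, b) in directed and (b, a) in directed
                and min(directed[(a, b)], directed[(b, a)]) <= cutoff
            }
            assert got == oracle

    def test_scan_selects_network_maximising_cutoff(self):
        sel = select_cutoff(self.paralog_hits(), "S", [1e-5, 1e-20, 1e-50])
        assert sel.counts == {1e-5: 1, 1e-20: 2, 1e-50: 0}
        assert sel.selected == 1e-20

    def test_tie_selects_loosest_threshold(self):
        hits = [SimilarityHit("S_a", "S_b", 1e-90, 1.0),
                SimilarityHit("S_b", "S_a", 1e-90, 1.0)]
        sel = select_cutoff(hits, "S", [1e-5, 1e-20, 1e-80])
        assert set(sel.counts.values()) == {1}
        assert sel.selected == 1e-5

    def test_no_hits_flagged(self):
        sel = select_cutoff([], "S", [1e-5, 1e-20])
        assert sel.no_hits and sel.selected == 1e-5
        assert set(sel.counts.values()) == {0}

    def test_tightening_cutoff_never_adds_edges(self, rng):
        ids = [f"S_p{i}" for i in range(6)]
        hits = [SimilarityHit(a, b, 10.0 ** rng.uniform(-60, -2), 1.0)
                for a in ids for b in ids if a != b]
        grid = default_grid(1e-5, 1e-60, 5)
        prev = None
        for c in grid:  # loose -> strict
            edges = {(a, b) for a, b, _ in paralog_edges(hits, "S", c)}
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_scan_removes_twilight_zone_noise_in_hard_mode(self):
        """With between-family noise hits present, a loose cutoff merges the
        two planted families while the selected cutoff separates them."""
        from m6arhythm.simulate import SimilarityModel, generate_proteomes, simulate_similarity
        from m6arhythm.simulate import FamilySpec

        specs = [
            FamilySpec(family_name=n, copies_per_species={"SpA": 3}, ancestral_length=60)
            for n in ("FAM1", "FAM2")
        ]
        proteomes, truth = generate_proteomes(specs, ["SpA"], seed=13)
        table = simulate_similarity(
            proteomes, truth, SimilarityModel(between_hit_prob=1.0), seed=14
        )
        hits = [SimilarityHit(q, s, e, b) for q, s, e, b in
                zip(table.qseqid, table.sseqid, table.evalue, table.bitscore)]
        sel = select_cutoff(hits, "SpA", default_grid())
        assert sel.counts[1e-3] == 1  # noise merges everything
        assert sel.counts[sel.selected] == 2  # families separated
        edges = paralog_edges(hits, "SpA", sel.selected)
        fam = truth.partition()
        assert all(fam[a] == fam[b] for a, b, _ in edges)

    def test_input_order_does_not_change_outputs(self, rng):
        hits = self.paralog_hits()
        shuffled = list(hits)
        rng.shuffle(shuffled)
        assert paralog_edges(hits, "S", 1e-5) == paralog_edges(shuffled, "S", 1e-5)
        assert select_cutoff(hits, "S", [1e-5, 1e-20]).selected == \
            select_cutoff(shuffled, "S", [1e-5, 1e-20]).selected


class TestNetworksAndInventory:
    def test_path_component_forms_single_network(self):
        nets = build_networks([("A_1", "B_1", 1e-50), ("B_1", "C_1", 1e-40)], [])
        assert len(nets) == 1
        assert nets[0].members == {"A_1", "B_1", "C_1"}
        assert nets[0].network_id == "NET_1"

    def test_empty_edges_give_no_networks(self):
        assert build_networks([], []) == []

    def test_bridge_joins_two_subfamilies_into_one_network(self):
        """Two dense within-species subfamilies linked only through one
        species' proteins end up in a single component (the eraser-network
        topology), verified against a union-find oracle."""
        para = [("A_x1", "A_x2", 1e-60), ("A_y1", "A_y2", 1e-60)]
        orth = [("A_x1", "B_z1", 1e-50), ("A_y1", "B_z1", 1e-50)]
        nets = build_networks(orth, para)
        assert len(nets) == 1
        assert nets[0].members == {"A_x1", "A_x2", "A_y1", "A_y2", "B_z1"}
        # independent union-find oracle
        parent = {}

        def find(u):
            parent.setdefault(u, u)
            while parent[u] != u:
                parent[u] = parent[parent[u]]
                u = parent[u]
            return u

        for a, b, _ in para + orth:
            parent[find(a)] = find(b)
        roots = {find(u) for u in parent}
        assert len(roots) == 1

    def test_network_ids_deterministic_by_size_then_member(self):
        nets = build_networks(
            [("B_1", "C_1", 1e-9)], [("A_1", "A_2", 1e-50), ("A_2", "A_3", 1e-50)]
        )
        assert [n.network_id for n in nets] == ["NET_1", "NET_2"]
        assert nets[0].members == {"A_1", "A_2", "A_3"}

    def test_annotation_retention_and_type(self):
        nets = build_networks([("A_1", "B_1", 1e-50)], [])
        annotate_networks(nets, {"A_1": "MTA", "B_1": "other"})
        assert nets[0].is_writer_related and not nets[0].is_eraser_related
        inv = inventory_table(nets)
        assert list(inv.gene_name) == ["MTA"]

    def test_only_other_labels_excluded_from_inventory(self):
        nets = build_networks([("A_1", "B_1", 1e-50)], [])
        annotate_networks(nets, {"A_1": "other", "B_1": "other"})
        assert inventory_table(nets).empty

    def test_unlabelled_member_gets_unknown(self):
        nets = build_networks([("A_1", "B_1", 1e-50)], [])
        annotate_networks(nets, {"A_1": "MTA"})
        assert nets[0].function_labels["B_1"] == "unknown"

    def test_mixed_mta_mtb_network_retained_once_with_both_genes(self):
        nets = build_networks(
            [("A_1", "B_1", 1e-50), ("A_2", "B_2", 1e-50)],
            [("A_1", "A_2", 1e-40), ("B_1", "B_2", 1e-40)],
        )
        annotate_networks(nets, {"A_1": "MTA", "B_1": "MTA", "A_2": "MTB", "B_2": "MTB"})
        inv = inventory_table(nets)
        assert set(inv.gene_name) == {"MTA", "MTB"}
        assert set(inv.network_id) == {"NET_1"}

    def test_inventory_matches_truth_cross_tabulation(self, three_family_specs):
        """Ground-truth pivot oracle on a full synthetic fixture."""
        specs = [
            s.__class__(
                family_name={"FAM1": "MTA", "FAM2": "FIP37", "FAM3": "ALKBH9B"}[s.family_name],
                copies_per_species=s.copies_per_species,
                ancestral_length=s.ancestral_length,
            )
            for s in three_family_specs
        ]
        proteomes, truth = generate_proteomes(specs, ["SpA", "SpB"], seed=21)
        table = simulate_similarity(proteomes, truth, seed=22)
        hits = [
            SimilarityHit(q, s, e, b)
            for q, s, e, b in zip(table.qseqid, table.sseqid, table.evalue, table.bitscore)
        ]
        orth = bbh_orthologs(best_hit_map(hits))
        para = []
        for sp in ("SpA", "SpB"):
            sel = select_cutoff(hits, sp, default_grid())
            para.extend(paralog_edges(hits, sp, sel.selected))
        nets = annotate_networks(build_networks(orth, para), truth.partition())
        inv = inventory_table(nets)
        got = {(r.gene_name, r.species): r.n_members for r in inv.itertuples()}
        expected = {
            (r.family_name, r.species): r.n_members
            for r in truth.cross_tab().itertuples()
        }
        assert got == expected


class TestCollapseRedundant:
    def test_identical_pair_collapses(self):
        reps, cmap = collapse_redundant({"a": "MKV" * 20, "b": "MKV" * 20}, 0.98, 0.5)
        assert len(reps) == 1 and len(cmap) == 1

    def test_near_identical_pair_collapses_at_98(self, rng):
        from Bio import Align

        base = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 50))
        mutant = base[:25] + ("A" if base[25] != "A" else "C") + base[26:]
        # oracle: identity from an exhaustive global alignment
        aligner = Align.PairwiseAligner(mode="global", match_score=1,
                                        mismatch_score=0, gap_score=-1)
        ident = aligner.score(base, mutant) / 50
        assert ident == pytest.approx(0.98)
        reps, cmap = collapse_redundant({"a": base, "b": mutant}, 0.98, 0.5)
        assert len(reps) == 1 and len(cmap) == 1

    def test_diverged_pair_kept_at_98(self, rng):
        base = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 50))
        arr = list(base)
        for i in range(0, 10):  # 10/50 = 20% divergence
            arr[i * 5] = "A" if arr[i * 5] != "A" else "C"
        reps, cmap = collapse_redundant({"a": base, "b": "".join(arr)}, 0.98, 0.5)
        assert len(reps) == 2 and not cmap

    def test_longest_member_is_representative(self):
        long_seq = "MKVAPL" * 20
        short_seq = long_seq[:100]
        reps, cmap = collapse_redundant({"short": short_seq, "long": long_seq}, 0.95, 0.5)
        assert set(reps) == {"long"}
        assert cmap == {"short": "long"}

    def test_empty_input(self):
        assert collapse_redundant({}, 0.98, 0.5) == ({}, {})

    def test_species_tag_parsing(self):
        assert species_of("Zmarina_FIP37_3") == "Zmarina"
        assert species_of("x", {"x": "Sp"}) == "Sp"
        with pytest.raises(ValueError):
            species_of("nounderscore")
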