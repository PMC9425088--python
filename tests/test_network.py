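import json

import numpy as np
import pytest

from dualreg.network import (
    ModelAssignment,
    PPIEdge,
    RegulatorProfile,
    disease_annotation,
    export_network,
    model_I,
    model_II,
    model_III,
    ppi_filter,
    read_gene_disease_table,
    read_ppi_table,
    summarize,
)


def profile(reg, tx=(), sp=()):
    return RegulatorProfile(reg, {g: "up" for g in tx}, set(sp))


def random_system(rng, n_regulators=5, n_genes=100):
    genes = [f"g{i}" for i in range(n_genes)]
    profiles = {}
    for r in range(n_regulators):
        reg = f"R{r}"
        tx = rng.choice(genes + [f"R{k}" for k in range(n_regulators)],
                        size=rng.integers(0, 30), replace=False)
        sp = rng.choice(genes + [f"R{k}" for k in range(n_regulators)],
                        size=rng.integers(0, 30), replace=False)
        profiles[reg] = profile(reg, tx, sp)
    sf = {g for g in genes if rng.random() < 0.2} | {f"R{k}" for k in range(n_regulators)}
    tf = {g for g in genes if rng.random() < 0.2} | {f"R{k}" for k in range(n_regulators)}
    return profiles, sf, tf


def brute_force_model_II(profiles, sf_set):
    out = set()
    for f, pf in profiles.items():
        for s in profiles:
            if s == f or s not in pf.tx_set or s not in sf_set:
                continue
            for g in pf.sp_targets:
                if g in profiles[s].sp_targets:
                    out.add((f, s, g))
    return out


def brute_force_model_III(profiles, tf_set):
    out = set()
    for f, pf in profiles.items():
        for t in profiles:
            if t == f or t not in pf.sp_targets or t not in tf_set:
                continue
            for g in pf.tx_set:
                if g in profiles[t].tx_set:
                    out.add((f, t, g))
    return out


class TestModelI:
    def test_intersection(self):
        p = profile("R", tx=("a", "b", "c"), sp=("b", "c", "d"))
        assert model_I(p) == {"b", "c"}

    def test_disjoint_layers(self):
        assert model_I(profile("R", tx=("a",), sp=("b",))) == set()

    def test_subset_of_both_layers(self, rng):
        for _ in range(20):
            p = profile("R", tx=rng.choice(50, rng.integers(0, 20), replace=False),
                        sp=rng.choice(50, rng.integers(0, 20), replace=False))
            m1 = model_I(p)
            assert m1 <= p.tx_set and m1 <= p.sp_targets


class TestModelII:
    def test_worked_example(self):
        f = profile("F", tx=("S", "x"), sp=("g1", "g2", "g3"))
        s = profile("S", sp=("g2", "g3", "g4"))
        out = model_II(f, {"F": f, "S": s}, sf_set={"S"})
        assert [(a.partner, a.gene) for a in out] == [("S", "g2"), ("S", "g3")]

    def test_no_sf_among_tx_targets(self):
        f = profile("F", tx=("x", "y"), sp=("g1",))
        assert model_II(f, {"F": f}, sf_set={"S"}) == []

    def test_partner_without_profile_skipped(self):
        f = profile("F", tx=("S",), sp=("g1",))
        assert model_II(f, {"F": f}, sf_set={"S"}) == []

    def test_self_partnership_excluded(self):
        f = profile("F", tx=("F",), sp=("g1",))
        assert model_II(f, {"F": f}, sf_set={"F"}) == []

    def test_matches_brute_force_on_random_systems(self, rng):
        for _ in range(30):
            profiles, sf, tf = random_system(rng)
            got = {
                (a.regulator, a.partner, a.gene)
                for p in profiles.values()
                for a in model_II(p, profiles, sf)
            }
            assert got == brute_force_model_II(profiles, sf)


class TestModelIII:
    def test_worked_example(self):
        f = profile("F", tx=("g1", "g2"), sp=("T",))
        t = profile("T", tx=("g2", "g5"))
        out = model_III(f, {"F": f, "T": t}, tf_set={"T"})
        assert [(a.partner, a.gene) for a in out] == [("T", "g2")]

    def test_mirror_duality_with_model_II(self, rng):
        """model_III equals model_II run on layer-swapped profiles."""
        for _ in range(30):
            profiles, sf, tf = random_system(rng)
            swapped = {
                r: RegulatorProfile(r, {g: "up" for g in p.sp_targets}, p.tx_set)
                for r, p in profiles.items()
            }
            got3 = {
                (a.regulator, a.partner, a.gene)
                for p in profiles.values()
                for a in model_III(p, profiles, tf)
            }
            via2 = {
                (a.regulator, a.partner, a.gene)
                for p in swapped.values()
                for a in model_II(p, swapped, tf)
            }
            assert got3 == via2
            assert got3 == brute_force_model_III(profiles, tf)


class TestPpiFilter:
    def assignments(self):
        return [
            ModelAssignment("I", "F", None, "g1"),
            ModelAssignment("II", "F", "S", "g2"),
            ModelAssignment("III", "F", "T", "g3"),
        ]

    def test_confident_edge_kept(self):
        out = ppi_filter(self.assignments(), [PPIEdge("F", "S", 0.8)], 0.7)
        assert {(a.model, a.gene) for a in out} == {("I", "g1"), ("II", "g2")}

    def test_weak_edge_dropped(self):
        out = ppi_filter(self.assignments(), [PPIEdge("F", "S", 0.5)], 0.7)
        assert {a.model for a in out} == {"I"}

    def test_partnerless_always_pass(self):
        out = ppi_filter(self.assignments(), [], 0.9)
        assert [a.model for a in out] == ["I"]

    def test_undirected_edge_lookup(self):
        out = ppi_filter(self.assignments(), [PPIEdge("S", "F", 0.9)], 0.7)
        assert any(a.model == "II" for a in out)

    def test_idempotent_and_monotone(self):
        edges = [PPIEdge("F", "S", 0.6), PPIEdge("F", "T", 0.9)]
        once = ppi_filter(self.assignments(), edges, 0.5)
        assert ppi_filter(once, edges, 0.5) == once
        stricter = ppi_filter(self.assignments(), edges, 0.8)
        assert set(stricter) <= set(once)

    def test_model_constraints(self):
        with pytest.raises(ValueError):
            ModelAssignment("I", "F", "S", "g")
        with pytest.raises(ValueError):
            ModelAssignment("II", "F", None, "g")


class TestDiseaseAnnotation:
    table = [("g1", "neoplastic process"), ("g2", "neoplastic process"),
             ("g1", "leukemia"), ("g1", "neoplastic process")]  # duplicate row

    def test_fractions(self):
        out = disease_annotation({"g1", "g2", "g3", "g4", "g5"}, self.table)
        assert out["neoplastic process"] == pytest.approx(0.4)
        assert out["leukemia"] == pytest.approx(0.2)

    def test_no_annotated_genes(self):
        assert disease_annotation({"x"}, self.table)["leukemia"] == 0.0

    def test_empty_gene_set_undefined(self):
        out = disease_annotation(set(), self.table)
        assert out["neoplastic process"] is None


class TestSummarize:
    def test_counts(self):
        p = RegulatorProfile("R", {"a": "up", "b": "down", "c": "up"}, {"b", "c"}, 4)
        df = summarize({"R": p})
        row = df.iloc[0]
        assert (row.n_tx_targets, row.n_sp_targets, row.n_events, row.n_dual_targets) \
            == (3, 2, 4, 2)

    def test_empty_profile(self):
        df = summarize({"R": RegulatorProfile("R")})
        assert df.iloc[0].tolist() == ["R", 0, 0, 0, 0]

    def test_permutation_invariant(self, rng):
        profiles = {
            f"R{i}": profile(f"R{i}", tx=rng.choice(30, 5, replace=False),
                             sp=rng.choice(30, 5, replace=False))
            for i in range(4)
        }
        a = summarize(profiles)
        b = summarize(dict(reversed(list(profiles.items()))))
        assert a.equals(b)


class TestExportNetwork:
    def make(self):
        profiles = {
            "R1": RegulatorProfile("R1", {"g1": "up", "g2": "down"}, {"g2", "g3"}, 3),
            "R2": RegulatorProfile("R2", {"g3": "up"}, {"g1"}, 1),
        }
        assignments = [ModelAssignment("I", "R1", None, "g2"),
                       ModelAssignment("II", "R1", "R2", "g3")]
        edges = [PPIEdge("R1", "R2", 0.8)]
        return profiles, assignments, edges

    def test_edge_count_and_round_trip(self, tmp_path):
        profiles, assignments, edges = self.make()
        paths = export_network(profiles, assignments, tmp_path, edges)
        lines = paths["edges"].read_text().strip().splitlines()[1:]
        n_layer = sum(len(p.tx_targets) + len(p.sp_targets) for p in profiles.values())
        assert len(lines) == n_layer + len(edges)
        assign_lines = paths["assignments"].read_text().strip().splitlines()[1:]
        got = [tuple(l.split("\t")) for l in assign_lines]
        assert got == [("I", "R1", ".", "g2"), ("II", "R1", "R2", "g3")]
        bundle = json.loads(paths["bundle"].read_text())
        assert bundle["n_edges"] == n_layer + 1

    def test_re_export_byte_identical(self, tmp_path):
        profiles, assignments, edges = self.make()
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = export_network(profiles, assignments, d1, edges, config={"x": 1})
        p2 = export_network(profiles, assignments, d2, edges, config={"x": 1})
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()


class TestTableIO:
    def test_ppi_and_disease_readers(self, tmp_path):
        ppi = tmp_path / "ppi.tsv"
        ppi.write_text("protein_a\tprotein_b\tconfidence\nA\tB\t0.8\n")
        (edge,) = read_ppi_table(ppi)
        assert edge.key == frozenset({"A", "B"}) and edge.confidence == 0.8
        gd = tmp_path / "gd.tsv"
        gd.write_text("gene_id\tdisease_class\ng1\tleukemia\n")
        assert read_gene_disease_table(gd) == [("g1", "leukemia")]
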