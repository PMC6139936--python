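"""Diagnostic-substitution sorting, consensus building and consensus forensics."""

import numpy as np
import pytest

from svakit.records import DELETED, Deletion, ElementRecord, Substitution, encode_states
from svakit.seqio_align import align_to_reference
from svakit.subfamily_sort import (
    SortingParams,
    Subfamily,
    SubfamilyTree,
    assign_element,
    build_consensus,
    cosegregation_scan,
    diagnostic_distance,
    find_candidate_variants,
    sequentiality_check,
    sort_subfamilies,
)
from svakit.synthetic_data import hallmark_consensus_set


def _dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def _mutate(seq, muts):
    s = list(seq)
    for pos, alt in muts:
        s[pos - 1] = alt
    return "".join(s)


def _alt(ref, pos):
    return "ACGT"[("ACGT".index(ref[pos - 1]) + 1) % 4]


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(3)
    ref = _dna(rng, 300)
    fam_x = _mutate(ref, [(100, _alt(ref, 100)), (200, _alt(ref, 200))])
    fam_y = _mutate(ref, [(150, _alt(ref, 150)), (250, _alt(ref, 250))])
    elements = (
        [ElementRecord(f"gg_x{i}", "gg", fam_x) for i in range(50)]
        + [ElementRecord(f"pt_y{i}", "pt", fam_y) for i in range(50)]
        + [ElementRecord(f"hs_r{i}", "hs", ref) for i in range(15)]
    )
    profiles = [align_to_reference(e, ref) for e in elements]
    return ref, profiles, fam_x, fam_y


class TestCandidateVariants:
    def test_support_counting(self, planted):
        ref, profiles, *_ = planted
        cands = find_candidate_variants(profiles, ref, min_support=2)
        supports = {str(v): s for v, s in cands.items()}
        assert supports[f"100:{ref[99]}>{_alt(ref, 100)}"] == 50
        assert supports[f"150:{ref[149]}>{_alt(ref, 150)}"] == 50

    def test_min_support_excludes_singletons(self, planted):
        ref, profiles, *_ = planted
        lone = align_to_reference(_mutate(ref, [(10, _alt(ref, 10))]), ref)
        lone.element_id = "lone"
        cands = find_candidate_variants(list(profiles) + [lone], ref, min_support=10)
        assert not any(v.position == 10 for v in cands)

    def test_counts_match_column_scan(self, rng):
        ref = _dna(rng, 60)
        profiles = []
        for i in range(20):
            k = int(rng.integers(0, 5))
            pos = rng.choice(60, size=k, replace=False) + 1
            seq = _mutate(ref, [(p, _alt(ref, p)) for p in pos])
            prof = align_to_reference(seq, ref)
            prof.element_id = f"e{i}"
            profiles.append(prof)
        cands = find_candidate_variants(profiles, ref, min_support=1)
        # brute-force per-column tally
        for v, s in cands.items():
            count = sum(
                1
                for p in profiles
                if p.calls[v.position - 1] == "ACGT".index(v.alt)
            )
            assert count == s


class TestSorting:
    def test_recovers_planted_subfamilies(self, planted):
        ref, profiles, *_ = planted
        tree = sort_subfamilies(profiles, ref, SortingParams())
        assert len(tree.subfamilies) == 2
        sizes = sorted(s.support for s in tree.subfamilies.values())
        assert sizes == [50, 50]
        at_root = [i for i, n in tree.assignment.items() if n == tree.root_name]
        assert len(at_root) == 15

    def test_min_members_blocks_small_groups(self, rng):
        ref = _dna(rng, 200)
        fam = _mutate(ref, [(50, _alt(ref, 50)), (90, _alt(ref, 90))])
        profiles = [align_to_reference(fam, ref) for _ in range(9)]
        for i, p in enumerate(profiles):
            p.element_id = f"e{i}"
        tree = sort_subfamilies(profiles, ref, SortingParams(min_members=10))
        assert tree.subfamilies == {}
        assert all(v == tree.root_name for v in tree.assignment.values())

    def test_single_shared_variant_insufficient_at_root(self, rng):
        ref = _dna(rng, 200)
        fam = _mutate(ref, [(50, _alt(ref, 50))])
        profiles = [align_to_reference(fam, ref) for _ in range(30)]
        for i, p in enumerate(profiles):
            p.element_id = f"e{i}"
        tree = sort_subfamilies(profiles, ref, SortingParams())
        assert tree.subfamilies == {}

    def test_deterministic(self, planted):
        ref, profiles, *_ = planted
        t1 = sort_subfamilies(profiles, ref, SortingParams())
        t2 = sort_subfamilies(profiles, ref, SortingParams())
        assert {n: s.signature for n, s in t1.subfamilies.items()} == {
            n: s.signature for n, s in t2.subfamilies.items()
        }
        assert t1.assignment == t2.assignment

    def test_degenerate_all_identical(self, rng):
        ref = _dna(rng, 100)
        profiles = [align_to_reference(ref, ref) for _ in range(20)]
        for i, p in enumerate(profiles):
            p.element_id = f"e{i}"
        tree = sort_subfamilies(profiles, ref)
        assert tree.subfamilies == {}

    def test_insertions_excluded_from_diagnostics_by_default(self, rng):
        ref = _dna(rng, 200)
        fam = ref[:100] + "GGGGGGGG" + ref[100:]
        fam = _mutate(fam, [(50, _alt(ref, 50))])
        profiles = [align_to_reference(fam, ref) for _ in range(15)]
        profiles += [align_to_reference(ref, ref) for _ in range(15)]
        for i, p in enumerate(profiles):
            p.element_id = f"e{i}"
        # one substitution + one insertion: only one countable variant by default
        t_default = sort_subfamilies(profiles, ref, SortingParams())
        assert t_default.subfamilies == {}
        t_ins = sort_subfamilies(profiles, ref, SortingParams(include_insertions=True))
        assert len(t_ins.subfamilies) == 1
        sig = next(iter(t_ins.subfamilies.values())).signature
        assert "ins" in sig and "50:" in sig

    def test_consensus_differs_from_parent_exactly_at_diagnostics(self, planted):
        ref, profiles, *_ = planted
        tree = sort_subfamilies(profiles, ref, SortingParams())
        ref_vec = encode_states(ref)
        for sub in tree.subfamilies.values():
            diff = np.flatnonzero(sub.consensus_calls != ref_vec)
            diag_pos = set()
            for d in sub.diagnostics:
                if isinstance(d, Substitution):
                    diag_pos.add(d.position - 1)
                elif isinstance(d, Deletion):
                    diag_pos.update(range(d.start - 1, d.start - 1 + d.length))
            assert set(diff) == diag_pos

    def test_nested_membership_implies_ancestor_match(self, planted):
        ref, profiles, *_ = planted
        tree = sort_subfamilies(profiles, ref, SortingParams())
        by_id = {p.element_id: p for p in profiles}
        for sub in tree.subfamilies.values():
            parent = sub.parent
            while parent != tree.root_name:
                psub = tree.subfamilies[parent]
                assert set(sub.members) <= set(psub.members)
                parent = psub.parent


class TestAssign:
    def test_full_diagnostics_reach_leaf(self, planted):
        ref, profiles, fam_x, _ = planted
        tree = sort_subfamilies(profiles, ref, SortingParams())
        p = align_to_reference(fam_x, ref)
        name = assign_element(p, tree)
        assert name in tree.subfamilies
        assert 100 in [d.position for d in tree.subfamilies[name].diagnostics]

    def test_partial_coverage_stays_at_parent(self, planted):
        ref, profiles, fam_x, _ = planted
        tree = sort_subfamilies(profiles, ref, SortingParams())
        truncated = align_to_reference(fam_x[150:], ref)  # covers only pos 200
        assert assign_element(truncated, tree) == tree.root_name

    def test_unalignable_is_unassigned(self, planted):
        ref, profiles, *_ = planted
        p = align_to_reference("CG" * 60, ref)
        p.unalignable = True
        tree = sort_subfamilies(profiles, ref, SortingParams())
        assert assign_element(p, tree) == "unassigned"


class TestConsensus:
    def test_majority(self, rng):
        ref = "ACGT" * 10
        seqs = [ref, ref, _mutate(ref, [(3, "T")])]
        profiles = [align_to_reference(s, ref) for s in seqs]
        cons = build_consensus(profiles, ref)
        assert cons[2] == "ACGT".index("G")

    def test_tie_resolves_to_parent(self, rng):
        ref = _dna(rng, 40)
        alt = _alt(ref, 7)
        profiles = [align_to_reference(_mutate(ref, [(7, alt)]), ref) for _ in range(5)]
        profiles += [align_to_reference(ref, ref) for _ in range(5)]
        cons = build_consensus(profiles, ref)
        assert cons[6] == encode_states(ref)[6]

    def test_deletion_is_a_state(self, rng):
        ref = _dna(rng, 120)
        el = ref[:40] + ref[60:]
        profiles = [align_to_reference(el, ref) for _ in range(4)]
        cons = build_consensus(profiles, ref)
        deleted = np.flatnonzero(cons == DELETED)
        assert len(deleted) == 20  # the 20-base deletion is carried ...
        assert deleted[-1] - deleted[0] == 19  # ... as one contiguous run
        decoded = "".join("ACGT"[s] for s in cons if s != DELETED)
        assert decoded == el  # placement may differ, the sequence may not

    def test_all_missing_falls_back_to_parent(self, rng):
        ref = _dna(rng, 60)
        profiles = [align_to_reference(ref[30:], ref) for _ in range(3)]
        cons = build_consensus(profiles, ref)
        assert (cons[:30] == encode_states(ref)[:30]).all()


class TestConsensusForensics:
    def test_distance_zero_for_identical(self):
        h = hallmark_consensus_set()
        assert diagnostic_distance(h["D1"], h["D1"], h["D1"]) == 0

    def test_dr_three_substitutions_from_d1(self):
        h = hallmark_consensus_set()
        assert diagnostic_distance(h["DR"], h["D1"], h["D1"]) == 3

    def test_d2_single_20bp_deletion_event(self):
        h = hallmark_consensus_set()
        assert diagnostic_distance(h["D2"], h["D1"], h["D1"]) == 1
        from svakit.seqio_align import call_variants

        p = align_to_reference(h["D2"], h["D1"])
        events = call_variants(p, h["D1"])
        assert events == [Deletion(start=h["deletion"].start, length=20)]

    def test_distance_matches_column_scan(self, rng):
        ref = _dna(rng, 150)
        for _ in range(10):
            k1, k2 = rng.integers(1, 8, size=2)
            p1 = rng.choice(150, size=k1, replace=False) + 1
            p2 = rng.choice(150, size=k2, replace=False) + 1
            a = _mutate(ref, [(p, _alt(ref, p)) for p in p1])
            b = _mutate(ref, [(p, _alt(ref, p)) for p in p2])
            expected = sum(1 for x, y in zip(a, b) if x != y)
            assert diagnostic_distance(a, b, ref) == expected

    def test_cosegregation_recovers_hallmark_pair(self):
        h = hallmark_consensus_set()
        groups = cosegregation_scan(h["ag_subfamilies"], h["DR"])
        pair = [g for g in groups if set(g["positions"]) == {228, 242}]
        assert len(pair) == 1
        assert pair[0]["carriers"] == ["gg_AG1", "gg_AG2", "pt_AG1", "pt_AG2"]

    def test_single_consensus_no_groups(self):
        h = hallmark_consensus_set()
        assert cosegregation_scan({"only": h["DR"]}, h["D1"]) == []

    def test_planted_cosegregating_triple(self, rng):
        ref = _dna(rng, 200)
        triple = [(30, _alt(ref, 30)), (90, _alt(ref, 90)), (160, _alt(ref, 160))]
        cons = {f"fam{i}": _mutate(ref, triple + [(10 + i, _alt(ref, 10 + i))]) for i in range(4)}
        cons["other"] = _mutate(ref, [(180, _alt(ref, 180))])
        groups = cosegregation_scan(cons, ref)
        assert any(set(g["positions"]) == {30, 90, 160} for g in groups)


class TestSequentiality:
    def test_constructed_tree_clean(self, planted):
        ref, profiles, *_ = planted
        tree = sort_subfamilies(profiles, ref, SortingParams())
        assert sequentiality_check(tree) == []

    def test_reversion_detected(self, rng):
        ref = _dna(rng, 120)
        ref_vec = encode_states(ref)
        alt100 = _alt(ref, 100)
        parent_vec = encode_states(_mutate(ref, [(100, alt100), (50, _alt(ref, 50))]))
        child_vec = encode_states(_mutate(ref, [(50, _alt(ref, 50))]))  # reverts pos 100
        tree = SubfamilyTree(root_name="root", reference=ref)
        tree.subfamilies["P"] = Subfamily(
            "P", "root", [Substitution(100, ref[99], alt100)], ["a"], parent_vec
        )
        tree.subfamilies["C"] = Subfamily("C", "P", [], ["a"], child_vec)
        violations = sequentiality_check(tree)
        assert len(violations) == 1
        assert violations[0]["position"] == 100
        assert violations[0]["edge"] == ("P", "C")

    def test_simulated_lineages_sequential(self, noise_free_sim):
        # planted sources themselves must never revert along lineages
        sim = noise_free_sim
        for plan in sim.config.lineages:
            if plan.parent is None:
                continue
            parent_vec = sim.sources[plan.parent]
            child_vec = sim.sources[plan.name]
            ref_vec = encode_states(sim.reference)
            derived = parent_vec != ref_vec
            assert not np.any(derived & (child_vec == ref_vec) & (child_vec != parent_vec))
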