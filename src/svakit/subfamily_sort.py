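"""Diagnostic-substitution subfamily sorting.

Retrotransposon subfamilies descend from source elements: mutations
present in a source are inherited by every copy it spawns, so a
subfamily is recognizable as a set of elements jointly carrying the same
shared ("diagnostic") variants relative to the ancestral consensus,
with younger subfamilies extending - never reverting - the diagnostic
set of their ancestors.

This module automates the classical manual sorting procedure: find the
variant set (of at least ``min_shared_root`` variants at the top level,
``min_shared_nested`` below) whose joint carrier set is largest, form a
subfamily when the carrier set is large enough, derive its consensus,
and recurse both inside the new subfamily and among the leftovers.
Deterministic by construction: ties are broken on (carrier count,
variant count, lowest positions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .records import (
    BASES,
    DELETED,
    MISSING,
    AlignedProfile,
    Deletion,
    Insertion,
    Substitution,
    VariantEvent,
    decode_states,
    encode_states,
)
from .seqio_align import _event_sort_key, variants_from_calls


@dataclass
class SortingParams:
    min_shared_root: int = 2
    min_members: int = 10
    min_shared_nested: int = 1
    coverage_min: float = 0.5
    include_deletions: bool = True  # hallmark indels (20 bp / 11 bp) count as diagnostics
    include_insertions: bool = False
    whitelist: frozenset[str] = frozenset()  # diagnostic signatures exempt from min_members

    def __post_init__(self):
        if self.min_shared_root < 1 or self.min_shared_nested < 1 or self.min_members < 1:
            raise ValueError("thresholds must be >= 1")
        if not 0 < self.coverage_min <= 1:
            raise ValueError("coverage_min must be in (0, 1]")


@dataclass
class Subfamily:
    name: str
    parent: str  # parent subfamily name, or the root reference name
    diagnostics: list[VariantEvent]
    members: list[str]
    consensus_calls: np.ndarray  # state vector in root-reference coordinates
    support: int = 0

    def __post_init__(self):
        self.support = len(self.members)

    @property
    def signature(self) -> str:
        return "+".join(str(d) for d in sorted(self.diagnostics, key=_event_sort_key))

    def consensus_sequence(self) -> str:
        """Consensus as a plain sequence (deleted positions dropped)."""
        return "".join(
            BASES[int(s)] for s in self.consensus_calls if s < DELETED
        )


@dataclass
class SubfamilyTree:
    root_name: str
    reference: str
    subfamilies: dict[str, Subfamily] = field(default_factory=dict)
    assignment: dict[str, str] = field(default_factory=dict)  # element id -> deepest node

    def children(self, name: str) -> list[Subfamily]:
        return sorted(
            (s for s in self.subfamilies.values() if s.parent == name),
            key=lambda s: s.name,
        )

    def depth(self, name: str) -> int:
        d = 0
        while name != self.root_name:
            name = self.subfamilies[name].parent
            d += 1
        return d


# ---------------------------------------------------------------------------
# candidate variants

def _carrier_matrix(
    calls: np.ndarray,
    parent: np.ndarray,
    params: SortingParams,
    pos_offset: int = 0,
):
    """All variants vs ``parent`` and their per-element carrier masks.

    Returns (variants, carrier bool matrix [n_var x n_el], covered bool
    matrix). Missing calls are neither carriers nor non-carriers.
    ``pos_offset`` shifts reported positions when ``calls`` is a slice of
    the full reference frame.
    """
    n_el, L = calls.shape
    variants: list[VariantEvent] = []
    carriers: list[np.ndarray] = []
    covered: list[np.ndarray] = []
    parent_base = parent < DELETED
    for pos in range(L):
        pstate = parent[pos]
        col = calls[:, pos]
        col_cov = col != MISSING
        if pstate == MISSING:
            continue
        for b in range(4):
            if b == pstate:
                continue
            mask = col == b
            if not mask.any():
                continue
            if pstate == DELETED:
                continue  # base where parent deleted: handled as insertion-like, skipped
            variants.append(
                Substitution(position=pos + 1 + pos_offset, ref=BASES[int(pstate)], alt=BASES[b])
            )
            carriers.append(mask)
            covered.append(col_cov)
    if params.include_deletions:
        # maximal runs of element-deleted over parent-base positions, per element
        del_state = (calls == DELETED) & parent_base[None, :]
        runs: dict[tuple[int, int], np.ndarray] = {}
        for e in range(n_el):
            row = del_state[e]
            idx = np.flatnonzero(row)
            if idx.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(idx) > 1)
            starts = np.concatenate(([0], breaks + 1))
            ends = np.concatenate((breaks, [idx.size - 1]))
            for s, t in zip(starts, ends):
                key = (int(idx[s]) + 1 + pos_offset, int(idx[t] - idx[s]) + 1)
                runs.setdefault(key, np.zeros(n_el, dtype=bool))[e] = True
        for (start, length), mask in sorted(runs.items()):
            variants.append(Deletion(start=start, length=length))
            span = slice(start - 1 - pos_offset, start - 1 - pos_offset + length)
            cov = np.all(calls[:, span] != MISSING, axis=1)
            carriers.append(mask)
            covered.append(cov)
    order = sorted(range(len(variants)), key=lambda i: _event_sort_key(variants[i]))
    variants = [variants[i] for i in order]
    carr = (
        np.array([carriers[i] for i in order], dtype=bool)
        if variants
        else np.zeros((0, n_el), dtype=bool)
    )
    cov = (
        np.array([covered[i] for i in order], dtype=bool)
        if variants
        else np.zeros((0, n_el), dtype=bool)
    )
    return variants, carr, cov


def find_candidate_variants(
    profiles: Sequence[AlignedProfile],
    reference: str,
    min_support: int = 2,
    params: Optional[SortingParams] = None,
) -> dict[VariantEvent, int]:
    """Map of every variant carried by >= min_support elements."""
    params = params or SortingParams()
    if not profiles:
        return {}
    calls = np.stack([p.calls for p in profiles])
    variants, carr, _ = _carrier_matrix(calls, encode_states(reference), params)
    support = carr.sum(axis=1)
    return {v: int(s) for v, s in zip(variants, support) if s >= min_support}


# ---------------------------------------------------------------------------
# greedy recursive sorting

def _best_seed(variants, carr, cov, min_shared: int):
    """Largest-joint-carrier variant seed of size >= min_shared.

    The optimum joint carrier set over variant sets of size >= 2 is
    always achieved by a pair (adding variants only shrinks carriers),
    so pair search is exact for min_shared == 2.
    """
    n_var = carr.shape[0]
    if n_var == 0:
        return None
    supports = carr.sum(axis=1)
    if min_shared == 1:
        best_support = int(supports.max())
        if best_support == 0:
            return None
        cand = [i for i in range(n_var) if supports[i] == best_support]
        i = min(cand, key=lambda k: _event_sort_key(variants[k]))
        return [i], carr[i].copy()
    # pair search via boolean matrix product
    inter = carr.astype(np.int32) @ carr.astype(np.int32).T
    np.fill_diagonal(inter, -1)
    best_count = inter.max()
    if best_count <= 0:
        return None
    pairs = np.argwhere(inter == best_count)
    pairs = [(i, j) for i, j in pairs if i < j]
    pairs.sort(key=lambda ij: (_event_sort_key(variants[ij[0]]), _event_sort_key(variants[ij[1]])))
    i, j = pairs[0]
    return [int(i), int(j)], carr[i] & carr[j]


def _extend_seed(seed_idx, seed_carriers, variants, carr):
    """Add every variant strictly carried by the whole seed carrier set
    (more-variants tie-break: the maximal set with the same carriers)."""
    chosen = list(seed_idx)
    nc = seed_carriers.sum()
    for k in range(carr.shape[0]):
        if k in chosen:
            continue
        if (carr[k] & seed_carriers).sum() == nc:
            chosen.append(k)
    chosen.sort(key=lambda k: _event_sort_key(variants[k]))
    return chosen


def _membership(diag_idx, carr, cov) -> np.ndarray:
    """Elements matching all covered diagnostics, covering >= min(2, n_diag)."""
    need = min(2, len(diag_idx))
    n_el = carr.shape[1]
    ok = np.ones(n_el, dtype=bool)
    n_cov = np.zeros(n_el, dtype=int)
    for k in diag_idx:
        ok &= carr[k] | ~cov[k]
        n_cov += cov[k].astype(int)
    return ok & (n_cov >= need)


def _apply_diagnostics(parent: np.ndarray, diagnostics: Iterable[VariantEvent]) -> np.ndarray:
    vec = parent.copy()
    for d in diagnostics:
        if isinstance(d, Substitution):
            vec[d.position - 1] = BASES.index(d.alt)
        elif isinstance(d, Deletion):
            vec[d.start - 1 : d.start - 1 + d.length] = DELETED
    return vec


def sort_subfamilies(
    profiles: Sequence[AlignedProfile],
    reference: str,
    params: Optional[SortingParams] = None,
    root_name: str = "root",
    species_of: Optional[dict[str, str]] = None,
    region: Optional[tuple[int, int]] = None,
) -> SubfamilyTree:
    """Greedy-recursive diagnostic-substitution sorting.

    ``species_of`` (element id -> species tag) only affects subfamily
    naming: groups whose members all come from one species get that
    species prefix, mixed groups are named "shared".

    ``region`` (1-based inclusive) restricts diagnostic discovery to a
    reference window - typically the SINE-R domain, the region
    classically used for subfamily sorting, which shields the
    diagnostics from 5' structural variation (truncation, captured
    exons, VNTR length turnover).
    """
    params = params or SortingParams()
    tree = SubfamilyTree(root_name=root_name, reference=reference)
    if not profiles:
        return tree
    ids = [p.element_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate element ids among profiles")
    calls = np.stack([p.calls for p in profiles])
    ref_vec = encode_states(reference)
    for i in ids:
        tree.assignment[i] = root_name

    counter: dict[str, int] = {}

    def group_name(parent: str, member_ids: list[str]) -> str:
        if species_of:
            sp = {species_of.get(i, "na") for i in member_ids}
            prefix = sp.pop() if len(sp) == 1 else "shared"
        else:
            prefix = "grp"
        counter[parent] = counter.get(parent, 0) + 1
        return f"{prefix}_{parent}.{counter[parent]}"

    if region is not None:
        lo, hi = region
        if not 1 <= lo <= hi <= len(reference):
            raise ValueError("region outside the reference")
        window = slice(lo - 1, hi)
        offset = lo - 1
    else:
        window = slice(0, len(reference))
        offset = 0

    # insertion events are not positional in the reference frame; when
    # enabled they enter as exact (anchor, sequence) characters
    ins_variants: list[Insertion] = []
    ins_carr = ins_cov = None
    if params.include_insertions:
        ins_map: dict[Insertion, np.ndarray] = {}
        for e, p in enumerate(profiles):
            for ins in p.insertions:
                lo_r, hi_r = (region or (1, len(reference)))
                if not lo_r <= max(ins.anchor, 1) <= hi_r:
                    continue
                ins_map.setdefault(ins, np.zeros(len(profiles), dtype=bool))[e] = True
        ins_variants = sorted(ins_map, key=_event_sort_key)
        if ins_variants:
            ins_carr = np.array([ins_map[v] for v in ins_variants], dtype=bool)
            ins_cov = np.array(
                [calls[:, max(v.anchor - 1, 0)] != MISSING for v in ins_variants],
                dtype=bool,
            )

    def sort_group(
        idx: np.ndarray,
        parent_vec: np.ndarray,
        parent_name: str,
        min_shared: int,
        used_ins: frozenset = frozenset(),
    ):
        pool = idx.copy()
        while pool.size:
            sub_calls = calls[pool][:, window]
            variants, carr, cov = _carrier_matrix(
                sub_calls, parent_vec[window], params, pos_offset=offset
            )
            live_ins = [k for k, v in enumerate(ins_variants) if v not in used_ins]
            if live_ins:
                variants = variants + [ins_variants[k] for k in live_ins]
                extra_carr = ins_carr[live_ins][:, pool]
                extra_cov = ins_cov[live_ins][:, pool]
                carr = np.vstack([carr, extra_carr]) if len(carr) else extra_carr
                cov = np.vstack([cov, extra_cov]) if len(cov) else extra_cov
            if not variants:
                return
            # prune variants that cannot reach min_members to keep pair search small
            supports = carr.sum(axis=1)
            thresh = 2 if params.whitelist else params.min_members
            keep = np.flatnonzero(supports >= thresh)
            if keep.size == 0:
                return
            variants = [variants[k] for k in keep]
            carr = carr[keep]
            cov = cov[keep]
            seed = _best_seed(variants, carr, cov, min_shared)
            if seed is None:
                return
            seed_idx, seed_carriers = seed
            diag_idx = _extend_seed(seed_idx, seed_carriers, variants, carr)
            members_mask = _membership(diag_idx, carr, cov)
            member_local = np.flatnonzero(members_mask)
            diagnostics = [variants[k] for k in diag_idx]
            signature = "+".join(str(d) for d in sorted(diagnostics, key=_event_sort_key))
            if member_local.size < params.min_members and signature not in params.whitelist:
                # try remaining variants: mask out this seed and look again
                drop = np.ones(len(variants), dtype=bool)
                for k in seed_idx:
                    drop[k] = False
                variants2 = [v for k, v in enumerate(variants) if drop[k]]
                if not variants2:
                    return
                carr2 = carr[drop]
                cov2 = cov[drop]
                found = False
                while variants2:
                    seed2 = _best_seed(variants2, carr2, cov2, min_shared)
                    if seed2 is None:
                        break
                    s_idx, s_car = seed2
                    d_idx = _extend_seed(s_idx, s_car, variants2, carr2)
                    mm = _membership(d_idx, carr2, cov2)
                    sig2 = "+".join(
                        str(variants2[k]) for k in sorted(d_idx, key=lambda k: _event_sort_key(variants2[k]))
                    )
                    if mm.sum() >= params.min_members or sig2 in params.whitelist:
                        variants, carr, cov = variants2, carr2, cov2
                        diag_idx, member_local = d_idx, np.flatnonzero(mm)
                        diagnostics = [variants2[k] for k in d_idx]
                        found = True
                        break
                    keep2 = np.ones(len(variants2), dtype=bool)
                    for k in s_idx:
                        keep2[k] = False
                    variants2 = [v for k, v in enumerate(variants2) if keep2[k]]
                    carr2 = carr2[keep2]
                    cov2 = cov2[keep2]
                if not found:
                    return
            member_global = pool[member_local]
            member_ids = [ids[g] for g in member_global]
            child_vec = _apply_diagnostics(parent_vec, diagnostics)
            name = group_name(parent_name, member_ids)
            sub = Subfamily(
                name=name,
                parent=parent_name,
                diagnostics=diagnostics,
                members=member_ids,
                consensus_calls=child_vec,
            )
            tree.subfamilies[name] = sub
            for i in member_ids:
                tree.assignment[i] = name
            child_used = used_ins | {d for d in diagnostics if isinstance(d, Insertion)}
            sort_group(member_global, child_vec, name, params.min_shared_nested, child_used)
            pool = np.array([g for g in pool if g not in set(member_global)], dtype=int)

    sort_group(np.arange(len(ids)), ref_vec, root_name, params.min_shared_root)
    # deepest assignment: descend while a child contains the element
    for name, sub in tree.subfamilies.items():
        for i in sub.members:
            cur = tree.assignment[i]
            if tree.depth(name) > tree.depth(cur):
                tree.assignment[i] = name
    return tree


# ---------------------------------------------------------------------------
# downstream operations

def assign_element(profile: AlignedProfile, tree: SubfamilyTree) -> str:
    """Deepest subfamily whose diagnostics the element satisfies.

    Descends only into children where all covered diagnostics match and
    at least min(2, n_diagnostics) of them are covered; unalignable
    profiles are 'unassigned'.
    """
    if profile.unalignable:
        return "unassigned"
    calls = profile.calls
    node = tree.root_name
    while True:
        best_child = None
        best_key = None
        for child in tree.children(node):
            n_cov = 0
            match = True
            for d in child.diagnostics:
                st = _variant_state(calls, d)
                if st == "missing":
                    continue
                n_cov += 1
                if st != "carrier":
                    match = False
                    break
            if match and n_cov >= min(2, len(child.diagnostics)):
                key = (-n_cov, child.name)
                if best_key is None or key < best_key:
                    best_key, best_child = key, child
        if best_child is None:
            return node
        node = best_child.name


def _variant_state(calls: np.ndarray, d: VariantEvent) -> str:
    if isinstance(d, Substitution):
        c = calls[d.position - 1]
        if c == MISSING:
            return "missing"
        return "carrier" if c == BASES.index(d.alt) else "non-carrier"
    if isinstance(d, Deletion):
        span = calls[d.start - 1 : d.start - 1 + d.length]
        if (span == MISSING).any():
            return "missing"
        return "carrier" if (span == DELETED).all() else "non-carrier"
    return "missing"  # insertions are not positional; never used to descend


def build_consensus(
    member_profiles: Sequence[AlignedProfile],
    parent_consensus: np.ndarray | str,
) -> np.ndarray:
    """Majority-rule consensus: per position the most frequent non-missing
    state (deletion is a state); ties and all-missing fall back to the
    parent consensus state."""
    if not member_profiles:
        raise ValueError("need at least one member")
    parent = encode_states(parent_consensus) if isinstance(parent_consensus, str) else parent_consensus
    calls = np.stack([p.calls for p in member_profiles])
    n_el, L = calls.shape
    out = parent.copy()
    counts = np.zeros((5, L), dtype=np.int32)
    for s in range(5):
        counts[s] = (calls == s).sum(axis=0)
    totals = counts.sum(axis=0)
    best = counts.max(axis=0)
    n_best = (counts == best[None, :]).sum(axis=0)
    decided = (totals > 0) & (n_best == 1)
    out[decided] = counts[:, decided].argmax(axis=0)
    return out


def diagnostic_distance(
    consensus_a: str | np.ndarray,
    consensus_b: str | np.ndarray,
    reference: Optional[str] = None,
) -> int:
    """Number of differing events between two consensuses, counting each
    contiguous deletion run once.

    Inputs are call vectors in a common reference frame, or plain
    sequences (then ``reference`` is required and both are aligned to it
    first).
    """
    vec_a = _as_vector(consensus_a, reference)
    vec_b = _as_vector(consensus_b, reference)
    if len(vec_a) != len(vec_b):
        raise ValueError("consensus vectors must share the reference frame")
    events = variants_from_calls(vec_a, vec_b)
    return len(events)


def _as_vector(cons, reference: Optional[str]) -> np.ndarray:
    if isinstance(cons, np.ndarray):
        return cons
    if reference is None:
        if len(cons) > 0:
            return encode_states(cons)
        raise ValueError("empty consensus")
    from .seqio_align import align_to_reference  # local import to avoid cycle

    prof = align_to_reference(cons, reference)
    if prof.unalignable:
        raise ValueError("consensus could not be aligned to the reference")
    return prof.calls


def sequentiality_check(tree: SubfamilyTree) -> list[dict]:
    """Report parent->child edges whose diagnostics revert an ancestral state.

    Diagnostic variants are inherited from source elements and accrue
    sequentially; a child whose consensus restores the root-reference
    state at a position where its parent was already derived implies a
    back-mutation and disqualifies the claimed ancestry.
    """
    violations = []
    root_vec = encode_states(tree.reference)
    for sub in tree.subfamilies.values():
        parent_vec = (
            tree.subfamilies[sub.parent].consensus_calls
            if sub.parent in tree.subfamilies
            else root_vec
        )
        derived = (parent_vec != root_vec) & (parent_vec != MISSING) & (root_vec != MISSING)
        child = sub.consensus_calls
        reverted = derived & (child == root_vec) & (child != parent_vec)
        for pos in np.flatnonzero(reverted):
            violations.append(
                {
                    "edge": (sub.parent, sub.name),
                    "position": int(pos) + 1,
                    "reverted_to": decode_states(root_vec[pos : pos + 1]),
                }
            )
    return violations


def cosegregation_scan(
    consensuses: dict[str, str | np.ndarray],
    reference: str,
) -> list[dict]:
    """Partition shared variants into co-occurring groups.

    A group is a maximal set of variants (relative to ``reference``)
    carried by exactly the same consensuses; only variants shared by at
    least two consensuses are considered. Returns groups sorted by first
    position, each with its variants and carrier names.
    """
    if len(consensuses) < 2:
        return []
    carrier_map: dict[VariantEvent, frozenset[str]] = {}
    ref_vec = encode_states(reference)
    for name, cons in sorted(consensuses.items()):
        vec = _as_vector(cons, reference)
        for ev in variants_from_calls(vec, ref_vec):
            if isinstance(ev, Insertion):
                continue
            carrier_map.setdefault(ev, frozenset())
            carrier_map[ev] = carrier_map[ev] | {name}
    groups: dict[frozenset[str], list[VariantEvent]] = {}
    for ev, carriers in carrier_map.items():
        if len(carriers) >= 2:
            groups.setdefault(carriers, []).append(ev)
    out = []
    for carriers, events in groups.items():
        events.sort(key=_event_sort_key)
        out.append(
            {
                "positions": [e.position if isinstance(e, Substitution) else e.start for e in events],
                "variants": events,
                "carriers": sorted(carriers),
            }
        )
    out.sort(key=lambda g: g["positions"][0])
    return out


def subfamily_table(tree: SubfamilyTree):
    import pandas as pd

    rows = [
        {
            "name": s.name,
            "parent": s.parent,
            "support": s.support,
            "diagnostics": s.signature,
        }
        for s in sorted(tree.subfamilies.values(), key=lambda s: s.name)
    ]
    return pd.DataFrame(rows, columns=["name", "parent", "support", "diagnostics"])
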