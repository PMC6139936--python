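"""Flank-based orthology of insertion loci across species.

Whether two species carry "the same" insertion is decided from the
genomic sequence flanking each element: two loci in different species
are orthologous candidates when both their 5' and 3' flanks are highly
similar and each is the other's unique reciprocal best hit. The signed
offset between the inferred insertion points then separates true
orthologs (offset 0) from near-miss independent integrations — a
distinction that can hinge on a single nucleotide.

Presence/absence histories are read off the fixed hominine species tree
((human, chimpanzee), gorilla) under a Dollo-style rule: an insertion is
gained once, so presence spanning the root implies an ancestral
insertion and any absence below it implies loss or incomplete lineage
sorting in that lineage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align

SPECIES_TREE = (("hs", "pt"), "gg")  # fixed rooted hominine tree


@dataclass
class OrthologyParams:
    seed_k: int = 16
    min_identity: float = 0.9
    flank_len: int = 50
    offset_tolerance: int = 0  # same-site call requires exact insertion point by default


@dataclass(frozen=True)
class InsertionLocus:
    element_id: str
    species: str
    flank5: str
    flank3: str

    def __post_init__(self):
        if not self.flank5 or not self.flank3:
            raise ValueError(f"locus {self.element_id}: flanks must be non-empty")


@dataclass
class LocusMatch:
    locus_a: InsertionLocus
    locus_b: InsertionLocus
    identity5: float
    identity3: float
    offset: int  # signed insertion-point displacement (nt); 0 = same site


def loci_from_table(df: pd.DataFrame) -> list[InsertionLocus]:
    return [
        InsertionLocus(
            element_id=row["id"],
            species=row["species"],
            flank5=str(row["flank5"]).upper(),
            flank3=str(row["flank3"]).upper(),
        )
        for _, row in df.iterrows()
    ]


def _kmer_index(loci: Sequence[InsertionLocus], k: int, side: str):
    index: dict[str, set[int]] = {}
    for i, loc in enumerate(loci):
        flank = loc.flank5 if side == "5" else loc.flank3
        for j in range(len(flank) - k + 1):
            index.setdefault(flank[j : j + k], set()).add(i)
    return index


_id_aligner = Align.PairwiseAligner()
_id_aligner.mode = "global"
_id_aligner.match_score = 1
_id_aligner.mismatch_score = -1
_id_aligner.open_gap_score = -2
_id_aligner.extend_gap_score = -1
_id_aligner.end_deletion_score = 0
_id_aligner.end_insertion_score = 0


def _flank_identity(a: str, b: str) -> tuple[float, int]:
    """Identity over aligned columns and the signed frame shift of a vs b.

    The frame shift is the offset of b's coordinate frame relative to
    a's at the aligned junction-proximal end.
    """
    if a == b:
        return 1.0, 0
    aln = _id_aligner.align(a, b)[0]
    ta, qa = aln.aligned
    matches = sum(
        1
        for (ts, te), (qs, qe) in zip(ta, qa)
        for t, q in zip(range(ts, te), range(qs, qe))
        if a[t] == b[q]
    )
    cols = sum(te - ts for (ts, te) in ta)
    if cols == 0:
        return 0.0, 0
    # offset measured at the last aligned block (junction side for 5' flanks)
    (ts, te), (qs, qe) = ta[-1], qa[-1]
    shift_end = (len(a) - te) - (len(b) - qe)
    return matches / cols, shift_end


def match_loci(
    loci: Sequence[InsertionLocus],
    params: Optional[OrthologyParams] = None,
) -> tuple[list[LocusMatch], list[InsertionLocus]]:
    """Symmetric cross-species matching by reciprocal best flank hits.

    Returns (matches, unresolvable) where unresolvable loci had
    ambiguous multi-way best hits on a flank. The insertion-point
    offset is the difference of the 5' and 3' flank frame shifts: for a
    1-nt displaced integration into an identical target context the 5'
    junction moves while the 3' junction follows, producing offset 1.
    """
    params = params or OrthologyParams()
    k = params.seed_k
    idx5 = _kmer_index(loci, k, "5")
    idx3 = _kmer_index(loci, k, "3")

    def candidates(i: int) -> set[int]:
        loc = loci[i]
        cands: set[int] = set()
        for flank, index in ((loc.flank5, idx5), (loc.flank3, idx3)):
            for j in range(len(flank) - k + 1):
                cands |= index.get(flank[j : j + k], set())
        return {c for c in cands if loci[c].species != loc.species}

    n = len(loci)
    best_hit: list[dict[str, tuple[Optional[int], float]]] = []
    scores: dict[tuple[int, int], tuple[float, float, int]] = {}
    ambiguous: set[int] = set()
    for i in range(n):
        per_species: dict[str, list[tuple[int, float, float, int]]] = {}
        for c in sorted(candidates(i)):
            key = (min(i, c), max(i, c))
            if key not in scores:
                id5, off5 = _flank_identity(loci[key[0]].flank5, loci[key[1]].flank5)
                id3, off3 = _flank_identity(loci[key[0]].flank3, loci[key[1]].flank3)
                # 3' flank aligned from its junction-proximal (left) end
                scores[key] = (id5, id3, off5)
            id5, id3, off = scores[key]
            per_species.setdefault(loci[c].species, []).append((c, id5, id3, off))
        hits: dict[str, tuple[Optional[int], float]] = {}
        for sp, cand_list in per_species.items():
            cand_list.sort(key=lambda t: (-(t[1] + t[2]), loci[t[0]].element_id))
            top = cand_list[0]
            if top[1] < params.min_identity or top[2] < params.min_identity:
                continue
            if len(cand_list) > 1 and abs(
                (cand_list[1][1] + cand_list[1][2]) - (top[1] + top[2])
            ) < 1e-9:
                ambiguous.add(i)
                continue
            hits[sp] = (top[0], top[1] + top[2])
        best_hit.append(hits)

    matches: list[LocusMatch] = []
    for i in range(n):
        if i in ambiguous:
            continue
        for sp, (j, _) in best_hit[i].items():
            if j is None or j <= i or j in ambiguous:
                continue
            back = best_hit[j].get(loci[i].species)
            if back is None or back[0] != i:
                continue
            key = (i, j)
            id5, id3, off = scores[key]
            matches.append(
                LocusMatch(
                    locus_a=loci[i],
                    locus_b=loci[j],
                    identity5=id5,
                    identity3=id3,
                    offset=int(off),
                )
            )
    return matches, [loci[i] for i in sorted(ambiguous)]


@dataclass
class PresencePattern:
    cluster_id: str
    loci: list[InsertionLocus]
    presence: dict[str, bool]
    history: str = ""
    flagged: bool = False

    def species_present(self) -> frozenset[str]:
        return frozenset(sp for sp, p in self.presence.items() if p)


def classify_presence(
    matches: Sequence[LocusMatch],
    loci: Sequence[InsertionLocus],
    species: Sequence[str] = ("gg", "pt", "hs"),
    offset_tolerance: int = 0,
) -> list[PresencePattern]:
    """Cluster loci by transitive same-site matching and emit presence flags.

    Matches with |offset| > tolerance join loci *near* each other but
    are reported as distinct integration sites: they never merge
    clusters. A cluster containing two loci of the same species is
    flagged inconsistent.
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(loci)))
    pos = {id(l): i for i, l in enumerate(loci)}
    for m in matches:
        if abs(m.offset) <= offset_tolerance:
            g.add_edge(pos[id(m.locus_a)], pos[id(m.locus_b)])
    patterns = []
    for ci, comp in enumerate(sorted(nx.connected_components(g), key=lambda c: min(c))):
        members = [loci[i] for i in sorted(comp)]
        present = {sp: any(l.species == sp for l in members) for sp in species}
        seen = [l.species for l in members]
        pat = PresencePattern(
            cluster_id=f"cluster_{ci}",
            loci=members,
            presence=present,
            flagged=len(seen) != len(set(seen)),
        )
        pat.history = parsimony_history(pat)
        patterns.append(pat)
    return patterns


def parsimony_history(pattern: PresencePattern, tree=SPECIES_TREE) -> str:
    """Dollo-style history call on ((hs, pt), gg).

    Presence spanning the root (gorilla plus either human or chimp)
    implies an ancestral hominine insertion; an absence below such a
    gain is loss or incomplete lineage sorting in that lineage. Presence
    confined to human+chimp maps to their common ancestor; a single
    species is a lineage-specific insertion.
    """
    p = pattern.presence
    gg, pt, hs = p.get("gg", False), p.get("pt", False), p.get("hs", False)
    n = sum((gg, pt, hs))
    if n == 0:
        return "absent"
    if n == 1:
        sp = "gg" if gg else ("pt" if pt else "hs")
        return f"{sp}-specific"
    if gg and pt and hs:
        return "ancestral-hominine"
    if hs and pt:
        return "hp-ancestral"
    # gorilla plus exactly one of hs/pt: gain precedes the root, loss below it
    lost = "pt" if hs else "hs"
    return f"ancestral-hominine;loss-or-ILS:{lost}"


def presence_table(patterns: Sequence[PresencePattern]) -> pd.DataFrame:
    rows = [
        {
            "cluster_id": p.cluster_id,
            "members": ";".join(l.element_id for l in p.loci),
            **{f"present_{sp}": v for sp, v in p.presence.items()},
            "history": p.history,
            "flagged": p.flagged,
        }
        for p in patterns
    ]
    return pd.DataFrame(rows)
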