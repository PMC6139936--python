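"""Forward simulation of SVA-like subfamily expansion on the hominine tree.

Source elements sit on branches of the fixed species tree
((human, chimpanzee), gorilla) and acquire diagnostic variants
sequentially along lineages - a child source inherits every variant of
its parent and adds its own, never reverting. Each source spawns copies
that carry the full diagnostic set plus Poisson-distributed random
post-insertion substitutions proportional to copy age; copies may be 5'
truncated, carry an untemplated 5' G, and insert into A-rich target
contexts with exact target-site duplications. Copies of pre-split
sources are emitted in every descendant species (minus stochastic
lineage-specific losses, an incomplete-lineage-sorting proxy) at the
same locus. Every emitted element has one ground-truth row, making the
simulator the oracle for the sorting, orthology, TSD and capture
stages.

Ages are relative units, not years: a copy of age ``a`` carries about
``a * mutation_rate`` substitutions per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import (
    BASES,
    DELETED,
    MISSING,
    Deletion,
    ElementRecord,
    Substitution,
    VariantEvent,
    decode_states,
    encode_states,
)

SPECIES = ("gg", "pt", "hs")
# branch -> species the branch's insertions are visible in
_BRANCH_SPECIES = {
    "hominine": ("gg", "pt", "hs"),
    "hp": ("pt", "hs"),
    "gg": ("gg",),
    "pt": ("pt",),
    "hs": ("hs",),
}
_BRANCH_DESCENDANTS = {
    "hominine": {"hominine", "hp", "gg", "pt", "hs"},
    "hp": {"hp", "pt", "hs"},
    "gg": {"gg"},
    "pt": {"pt"},
    "hs": {"hs"},
}


@dataclass
class CapturePlan:
    donor: str  # exon id in the generated library
    junction_offset: int = 150  # nt into the Alu-like domain where SVA sequence resumes
    min_acquired: int = 80
    max_acquired: int = 250


@dataclass
class LineagePlan:
    name: str
    parent: Optional[str]  # None = root reference
    branch: str  # hominine | hp | gg | pt | hs
    n_copies: int
    n_diagnostics: int = 2
    deletion: Optional[tuple[int, int]] = None  # (start, length) hallmark deletion
    age: float = 1.0
    capture: Optional[CapturePlan] = None


@dataclass
class SimulationConfig:
    seed: int
    reference: Optional[str] = None  # explicit root sequence; default: structured SVA-like
    mutation_rate: float = 0.005  # substitutions/site per age unit, post-insertion
    truncation_prob: float = 0.2
    truncation_keep: tuple[float, float] = (0.55, 0.95)  # kept 3' fraction
    tsd_len_range: tuple[int, int] = (8, 16)
    flank_len: int = 50
    untemplated_g_prob: float = 0.3
    loss_prob: float = 0.1  # per descendant lineage, for pre-split insertions
    n_decoy_pairs: int = 5  # planted 1-nt-offset near-miss locus pairs
    lineages: Optional[list[LineagePlan]] = None

    def __post_init__(self):
        for r in (self.mutation_rate, self.truncation_prob, self.untemplated_g_prob, self.loss_prob):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.lineages is None:
            self.lineages = default_lineage_plan()


def default_lineage_plan() -> list[LineagePlan]:
    """Fifteen nested source lineages across the three hominine branches.

    Copy counts span 30-200; ages span 1-4 units so that, at the default
    mutation rate, post-insertion divergence spans 0.5-2%. Two lineages
    carry hallmark deletions (20 bp in the SINE-R, 11 bp in the
    Alu-like domain) and two are exon-capture founders.
    """
    return [
        LineagePlan("D1", None, "hominine", 100, n_diagnostics=2, age=4.0),
        LineagePlan("D2", "D1", "hominine", 60, n_diagnostics=1, deletion=(560, 20), age=3.5),
        LineagePlan("D3", "D1", "gg", 80, n_diagnostics=2, age=3.0),
        LineagePlan("D3a", "D3", "gg", 40, n_diagnostics=1, age=2.0),
        LineagePlan("D3b", "D3", "gg", 35, n_diagnostics=2, age=1.5),
        LineagePlan("DR", "D1", "hp", 70, n_diagnostics=3, age=3.0),
        LineagePlan("DRa", "DR", "pt", 90, n_diagnostics=2, age=2.0),
        LineagePlan("DRb", "DR", "pt", 200, n_diagnostics=2, age=1.5),
        LineagePlan("F", "DR", "hs", 120, n_diagnostics=2, deletion=(150, 11), age=1.5),
        LineagePlan("Fa", "F", "hs", 30, n_diagnostics=1, age=1.0),
        LineagePlan("E", "DR", "hs", 60, n_diagnostics=3, age=1.2),
        LineagePlan("D4", None, "hominine", 50, n_diagnostics=2, age=2.5),
        LineagePlan("D5", "D4", "pt", 40, n_diagnostics=2, age=1.0),
        LineagePlan("D6cap", "D4", "pt", 45, n_diagnostics=2, age=1.0, capture=CapturePlan("STK40_like")),
        LineagePlan("F1cap", "F", "hs", 40, n_diagnostics=1, age=0.8, capture=CapturePlan("MAST2_like")),
    ]


@dataclass
class StructuredReference:
    sequence: str
    domains: dict[str, tuple[int, int]]  # 1-based inclusive spans
    domain_refs: dict[str, str]  # alu_like / sine_r consensus strings


def build_structured_reference(rng: np.random.Generator) -> StructuredReference:
    """SVA-like composite: hexamers + Alu-like + VNTR + SINE-R + polyA."""
    hexamer = "TCTCCC" * 4
    alu_like = _random_seq(rng, 250)
    unit = _random_seq(rng, 37)
    vntr = unit * 5
    sine_r = _random_seq(rng, 400)
    polya = "A" * 15
    seq = hexamer + alu_like + vntr + sine_r + polya
    h0 = 1
    a0 = h0 + len(hexamer)
    v0 = a0 + len(alu_like)
    s0 = v0 + len(vntr)
    p0 = s0 + len(sine_r)
    return StructuredReference(
        sequence=seq,
        domains={
            "hexamer": (h0, a0 - 1),
            "alu_like": (a0, v0 - 1),
            "vntr": (v0, s0 - 1),
            "sine_r": (s0, p0 - 1),
            "polya": (p0, len(seq)),
        },
        domain_refs={"alu_like": alu_like, "sine_r": sine_r, "vntr": vntr},
    )


def _random_seq(rng: np.random.Generator, n: int, p=None) -> str:
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _random_exon(rng: np.random.Generator, n: int) -> str:
    # GC-rich, as first exons of the co-opted kinase genes are
    return "".join(rng.choice(list("ACGT"), size=n, p=[0.15, 0.35, 0.35, 0.15]))


@dataclass
class SimulationResult:
    elements: list[ElementRecord]
    truth: pd.DataFrame
    reference: str
    domains: dict[str, tuple[int, int]]
    domain_refs: dict[str, str]
    exon_library: dict[str, str]
    sources: dict[str, np.ndarray]  # lineage -> source call vector (reference frame)
    source_diagnostics: dict[str, list[VariantEvent]]  # relative to parent source
    config: SimulationConfig

    def source_sequence(self, lineage: str) -> str:
        return "".join(BASES[int(s)] for s in self.sources[lineage] if s < DELETED)


def simulate_expansion(config: SimulationConfig) -> SimulationResult:
    """Run the forward simulation; deterministic given ``config.seed``."""
    master = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ("sequence", "diagnostics", "mutation", "placement", "truncation", "loss"),
            master.spawn(6),
        )
    }
    rng_seq = streams["sequence"]
    ref = build_structured_reference(rng_seq)
    reference = config.reference or ref.sequence
    if config.reference is not None:
        ref = StructuredReference(
            sequence=reference,
            domains={"sine_r": (1, len(reference))},
            domain_refs={"alu_like": reference[: max(1, len(reference) // 3)], "sine_r": reference},
        )
    L = len(reference)
    ref_vec = encode_states(reference)

    exon_library = {
        "STK40_like": _random_exon(rng_seq, 300),
        "MAST2_like": _random_exon(rng_seq, 280),
        "decoy_exon_1": _random_exon(rng_seq, 220),
        "decoy_exon_2": _random_exon(rng_seq, 260),
    }

    plans = {p.name: p for p in config.lineages}
    _validate_plan(config.lineages, plans)

    # --- sequential diagnostic acquisition along lineages -----------------
    rng_diag = streams["diagnostics"]
    sine_lo, sine_hi = ref.domains.get("sine_r", (1, L))
    sources: dict[str, np.ndarray] = {}
    diags: dict[str, list[VariantEvent]] = {}
    used: set[int] = set()  # one diagnostic position per event, simulation-wide
    for plan in config.lineages:  # plan order respects parent-before-child
        parent_vec = sources[plan.parent] if plan.parent else ref_vec
        vec = parent_vec.copy()
        events: list[VariantEvent] = []
        for _ in range(plan.n_diagnostics):
            while True:
                pos = int(rng_diag.integers(sine_lo, sine_hi + 1))
                if pos not in used and vec[pos - 1] < DELETED:
                    break
            cur = BASES[int(vec[pos - 1])]
            alt = rng_diag.choice([b for b in BASES if b != cur])
            events.append(Substitution(position=pos, ref=cur, alt=str(alt)))
            vec[pos - 1] = BASES.index(alt)
            used.add(pos)
        if plan.deletion is not None:
            start, length = plan.deletion
            vec[start - 1 : start - 1 + length] = DELETED
            events.append(Deletion(start=start, length=length))
            used.update(range(start, start + length))
        sources[plan.name] = vec
        diags[plan.name] = events

    # --- copy generation --------------------------------------------------
    rng_mut = streams["mutation"]
    rng_place = streams["placement"]
    rng_trunc = streams["truncation"]
    rng_loss = streams["loss"]

    elements: list[ElementRecord] = []
    rows: list[dict] = []

    def mutate(seq: str, n_sub: int, rng: np.random.Generator) -> str:
        if n_sub == 0 or not seq:
            return seq
        s = list(seq)
        pos = rng.integers(0, len(s), size=n_sub)
        for p in pos:
            s[p] = rng.choice([b for b in BASES if b != s[p]])
        return "".join(s)

    def make_locus(age: float):
        """(left context, TSD source, right context, tract distance)."""
        tract = "A" * int(rng_place.integers(6, 13))
        spacer = _random_seq(rng_place, int(rng_place.integers(0, 3)))
        left = _random_seq(rng_place, config.flank_len) + tract + spacer
        tsd_len = int(rng_place.integers(config.tsd_len_range[0], config.tsd_len_range[1] + 1))
        tsd = "".join(rng_place.choice(list("ACGT"), size=tsd_len, p=[0.55, 0.15, 0.15, 0.15]))
        right = _random_seq(rng_place, config.flank_len)
        return left, tsd, right, len(spacer)

    def flanks_for(left, tsd, right, age):
        n5 = rng_mut.poisson(age * config.mutation_rate * len(tsd))
        n3 = rng_mut.poisson(age * config.mutation_rate * len(tsd))
        tsd5 = mutate(tsd, int(n5), rng_mut)
        tsd3 = mutate(tsd, int(n3), rng_mut)
        flank5 = (left + tsd5)[-config.flank_len :]
        flank3 = (tsd3 + right)[: config.flank_len]
        return flank5, flank3, tsd5, tsd3

    for plan in config.lineages:
        src_vec = sources[plan.name]
        base_seq = "".join(BASES[int(s)] for s in src_vec if s < DELETED)
        if plan.capture is not None:
            exon = exon_library[plan.capture.donor]
            alu_lo = ref.domains.get("alu_like", (1, L))[0]
            junction_ref = alu_lo + plan.capture.junction_offset
            n_removed = int(np.sum(src_vec[: junction_ref - 1] < DELETED))
            canonical_tail = base_seq[n_removed:]
        species_list = _BRANCH_SPECIES[plan.branch]
        for i in range(plan.n_copies):
            left, tsd, right, tract_gap = make_locus(plan.age)
            locus_id = f"locus_{plan.name}_{i}"
            shared = len(species_list) > 1
            if shared:
                lost = [sp for sp in species_list if rng_loss.random() < config.loss_prob]
                if len(lost) == len(species_list):
                    lost = lost[:-1]  # keep the insertion observable
            else:
                lost = []
            capture_len = None
            if plan.capture is not None:
                capture_len = int(
                    rng_trunc.integers(plan.capture.min_acquired, plan.capture.max_acquired + 1)
                )
            for sp in species_list:
                if sp in lost:
                    continue
                if plan.capture is not None:
                    seq = exon[-capture_len:] + canonical_tail
                else:
                    seq = base_seq
                n_sub = int(rng_mut.poisson(plan.age * config.mutation_rate * len(seq)))
                seq = mutate(seq, n_sub, rng_mut)
                truncated = 0
                if plan.capture is None and rng_trunc.random() < config.truncation_prob:
                    keep = rng_trunc.uniform(*config.truncation_keep)
                    truncated = len(seq) - int(np.ceil(keep * len(seq)))
                    seq = seq[truncated:]
                has_g = rng_place.random() < config.untemplated_g_prob and truncated == 0
                if has_g:
                    seq = "G" + seq
                # a cap-derived G immediately 5' of a captured exon suffix is
                # indistinguishable from one more exonic base when that base is G
                capture_len_alt = None
                if (
                    plan.capture is not None
                    and has_g
                    and capture_len < len(exon)
                    and exon[-(capture_len + 1)] == "G"
                ):
                    capture_len_alt = capture_len + 1
                flank5, flank3, tsd5, tsd3 = flanks_for(left, tsd, right, plan.age)
                eid = f"{sp}_{plan.name}_{i}"
                elements.append(
                    ElementRecord(
                        id=eid,
                        species=sp,
                        sequence=seq,
                        flank5=flank5,
                        flank3=flank3,
                        locus_label=locus_id,
                    )
                )
                rows.append(
                    {
                        "element_id": eid,
                        "species": sp,
                        "lineage": plan.name,
                        "locus_id": locus_id,
                        "shared": shared,
                        "age": plan.age,
                        "tsd": tsd,
                        "tsd5": tsd5,
                        "tsd3": tsd3,
                        "truncated_nt": truncated,
                        "untemplated_g": has_g,
                        "capture_donor": plan.capture.donor if plan.capture else None,
                        "capture_len": capture_len if plan.capture else None,
                        "capture_len_alt": capture_len_alt,
                        "is_decoy": False,
                        "decoy_pair": None,
                        "a_tract_gap": tract_gap,
                    }
                )

    # --- 1-nt-offset decoy locus pairs ------------------------------------
    decoy_src = config.lineages[0]
    for d in range(config.n_decoy_pairs):
        left, tsd, right, tract_gap = make_locus(decoy_src.age)
        # species A inserts at the planned point, species B one nt downstream
        sp_a, sp_b = "gg", "hs"
        ancestral = left + tsd + right  # pre-integration frame
        point_a = len(left)
        point_b = point_a + 1
        for sp, point, tag in ((sp_a, point_a, "a"), (sp_b, point_b, "b")):
            tsd_here = ancestral[point : point + len(tsd)]
            flank5 = (ancestral[:point] + tsd_here)[-config.flank_len :]
            flank3 = (tsd_here + ancestral[point + len(tsd) :])[: config.flank_len]
            eid = f"{sp}_decoy{d}_{tag}"
            seq = "".join(BASES[int(s)] for s in sources[decoy_src.name] if s < DELETED)
            n_sub = int(rng_mut.poisson(decoy_src.age * config.mutation_rate * len(seq)))
            seq = mutate(seq, n_sub, rng_mut)
            elements.append(
                ElementRecord(
                    id=eid,
                    species=sp,
                    sequence=seq,
                    flank5=flank5,
                    flank3=flank3,
                    locus_label=f"locus_decoy{d}_{tag}",
                )
            )
            rows.append(
                {
                    "element_id": eid,
                    "species": sp,
                    "lineage": decoy_src.name,
                    "locus_id": f"locus_decoy{d}_{tag}",
                    "shared": False,
                    "age": decoy_src.age,
                    "tsd": tsd_here,
                    "tsd5": tsd_here,
                    "tsd3": tsd_here,
                    "truncated_nt": 0,
                    "untemplated_g": False,
                    "capture_donor": None,
                    "capture_len": None,
                    "capture_len_alt": None,
                    "is_decoy": True,
                    "decoy_pair": d,
                    "a_tract_gap": tract_gap,
                }
            )

    truth = pd.DataFrame(rows)
    return SimulationResult(
        elements=elements,
        truth=truth,
        reference=reference,
        domains=ref.domains,
        domain_refs=ref.domain_refs,
        exon_library=exon_library,
        sources=sources,
        source_diagnostics=diags,
        config=config,
    )


def _validate_plan(lineages: Sequence[LineagePlan], plans: dict[str, LineagePlan]) -> None:
    seen: set[str] = set()
    for plan in lineages:
        if plan.branch not in _BRANCH_SPECIES:
            raise ValueError(f"unknown branch {plan.branch!r}")
        if plan.n_copies < 0:
            raise ValueError("copy counts must be >= 0")
        if plan.parent is not None:
            if plan.parent not in seen:
                raise ValueError(
                    f"lineage {plan.name!r} listed before its parent {plan.parent!r}"
                )
            if plan.branch not in _BRANCH_DESCENDANTS[plans[plan.parent].branch]:
                raise ValueError(
                    f"lineage {plan.name!r} on branch {plan.branch!r} cannot descend "
                    f"from {plan.parent!r} on branch {plans[plan.parent].branch!r}"
                )
        seen.add(plan.name)


# ---------------------------------------------------------------------------
# scoring

def score_partition(inferred: dict[str, str], truth: pd.DataFrame):
    """Adjusted Rand index + per-subfamily precision/recall.

    ``inferred`` maps element id -> label over exactly the same element
    universe as ``truth`` (restrict the truth table first if the
    pipeline filtered elements).
    """
    from sklearn.metrics import adjusted_rand_score

    truth_labels = dict(zip(truth["element_id"], truth["lineage"]))
    if set(inferred) != set(truth_labels):
        raise ValueError("element universes differ between inference and truth")
    ids = sorted(inferred)
    y_true = [truth_labels[i] for i in ids]
    y_pred = [inferred[i] for i in ids]
    ari = float(adjusted_rand_score(y_true, y_pred))
    per = []
    for lin in sorted(set(y_true)):
        members = {i for i in ids if truth_labels[i] == lin}
        # best-overlap inferred cluster
        counts: dict[str, int] = {}
        for i in members:
            counts[inferred[i]] = counts.get(inferred[i], 0) + 1
        best = max(counts.items(), key=lambda kv: kv[1])[0]
        cluster = {i for i in ids if inferred[i] == best}
        tp = len(members & cluster)
        per.append(
            {
                "lineage": lin,
                "n": len(members),
                "matched_cluster": best,
                "precision": tp / len(cluster) if cluster else 0.0,
                "recall": tp / len(members),
            }
        )
    return ari, pd.DataFrame(per)


def score_presence(patterns, truth: pd.DataFrame):
    """Accuracy of shared vs lineage-specific presence calls.

    A planted locus is called correctly when all and only its species
    instances land in one inferred cluster. Returns (per-class accuracy
    dict, confusion DataFrame).
    """
    cluster_of: dict[str, str] = {}
    members_of: dict[str, set[str]] = {}
    for pat in patterns:
        ids = {l.element_id for l in pat.loci}
        members_of[pat.cluster_id] = ids
        for i in ids:
            cluster_of[i] = pat.cluster_id
    truth_ids = set(truth["element_id"])
    if truth_ids != set(cluster_of):
        raise ValueError("locus universes differ between inference and truth")
    records = []
    for locus_id, grp in truth.groupby("locus_id"):
        ids = set(grp["element_id"])
        clusters = {cluster_of[i] for i in ids}
        correct = len(clusters) == 1 and members_of[next(iter(clusters))] == ids
        records.append(
            {
                "locus_id": locus_id,
                "class": "shared" if bool(grp["shared"].iloc[0]) else "lineage-specific",
                "correct": correct,
            }
        )
    df = pd.DataFrame(records)
    acc = {
        cls: float(sub["correct"].mean())
        for cls, sub in df.groupby("class")
    }
    acc["overall"] = float(df["correct"].mean())
    confusion = df.groupby(["class", "correct"]).size().rename("count").reset_index()
    return acc, confusion


def score_capture(calls: dict, truth: pd.DataFrame) -> float:
    """Fraction of planted capture elements with correct donor and length.

    ``calls`` maps element id -> CaptureCall (or None). A call is
    correct when the donor exon matches and the acquired length equals
    the planted length or its recorded indistinguishable alternative
    (untemplated-G ambiguity).
    """
    cap = truth[truth.capture_donor.notna()]
    if cap.empty:
        raise ValueError("truth contains no capture elements")
    ok = 0
    for _, row in cap.iterrows():
        call = calls.get(row.element_id)
        if call is None or call.exon_id != row.capture_donor:
            continue
        accepted = {int(row.capture_len)}
        if pd.notna(row.capture_len_alt):
            accepted.add(int(row.capture_len_alt))
        if call.acquired_length in accepted:
            ok += 1
    return ok / len(cap)


# ---------------------------------------------------------------------------
# synthetic hallmark consensus set

def hallmark_consensus_set(seed: int = 7) -> dict:
    """Synthetic stand-in consensus set carrying the hallmark subfamily
    relationships of the hominine SVA_D literature.

    The published consensus alignments themselves are not redistributable
    here, so this constructs sequences with the documented structure: DR
    differs from D1 by exactly 3 substitutions; D2 carries the trademark
    20 bp SINE-R deletion relative to D1; a set of "A-G" subfamilies
    share co-segregating substitutions at positions 228 (->A) and 242
    (->G) relative to the DR consensus, each with private diagnostics;
    two further subfamilies carry neither.
    """
    rng = np.random.default_rng(seed)
    d1 = list(_random_seq(rng, 400))
    d1[227] = "G"  # ancestral states at the hallmark positions
    d1[241] = "A"
    d1 = "".join(d1)

    def sub(seq: str, pos: int, alt: str) -> str:
        assert seq[pos - 1] != alt
        return seq[: pos - 1] + alt + seq[pos:]

    dr = d1
    for pos in (57, 133, 310):
        cur = dr[pos - 1]
        dr = sub(dr, pos, "ACGT"[("ACGT".index(cur) + 1) % 4])
    d2 = d1[:299] + d1[319:]  # 20 bp deletion at positions 300-319

    ag_core = sub(sub(dr, 228, "A"), 242, "G")
    consensuses = {}
    private_positions = iter((20, 75, 180, 260, 350, 390, 110, 210))
    for name in ("gg_AG1", "gg_AG2", "pt_AG1", "pt_AG2"):
        pos = next(private_positions)
        cur = ag_core[pos - 1]
        consensuses[name] = sub(ag_core, pos, "ACGT"[("ACGT".index(cur) + 1) % 4])
    for name in ("hs_plain1", "hs_plain2"):
        pos = next(private_positions)
        cur = dr[pos - 1]
        consensuses[name] = sub(dr, pos, "ACGT"[("ACGT".index(cur) + 1) % 4])
    return {
        "D1": d1,
        "DR": dr,
        "D2": d2,
        "ag_subfamilies": consensuses,
        "deletion": Deletion(start=300, length=20),
        "coseg_positions": (228, 242),
    }
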