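"""Canonical SVA domain annotation and 5' exon-capture detection.

A canonical SVA reads, 5' to 3': TCTCCC hexameric repeats, an Alu-like
domain, a VNTR (tandem repeat) region, the retrovirus-derived SINE-R,
and a polyA tail. Non-canonical variants arise when splicing joins the
first exon of a host gene to an acceptor inside the Alu-like domain,
replacing the hexamers and most of the Alu-like sequence with captured
exonic sequence - the pattern seen independently in the human (MAST2)
and chimpanzee (STK40) lineages. Capture is detected as a 5' block that
fails to align to the canonical 5' domains, and attributed to a donor
exon only when the block's 3' end coincides with the exon's 3' end
(the splice criterion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio import Align

HEXAMER_UNIT = "TCTCCC"


@dataclass
class DomainParams:
    min_domain_identity: float = 0.6
    min_sine_r_coverage: float = 0.4  # fraction of the SINE-R reference that must align
    min_alu_coverage: float = 0.25
    min_hexamer_units: int = 2
    hexamer_unit_max_mismatch: int = 1
    min_vntr_len: int = 20
    min_polya_len: int = 5
    min_foreign_len: int = 30
    splice_end_tolerance: int = 2  # nt slack for the 3'-end coincidence test


@dataclass
class DomainAnnotation:
    """1-based inclusive spans per domain; None = absent."""

    hexamer: Optional[tuple[int, int]] = None
    alu_like: Optional[tuple[int, int]] = None
    vntr: Optional[tuple[int, int]] = None
    sine_r: Optional[tuple[int, int]] = None
    polya: Optional[tuple[int, int]] = None
    is_sva: bool = True
    identities: dict = field(default_factory=dict)

    def spans(self) -> dict[str, tuple[int, int]]:
        return {
            k: v
            for k, v in {
                "hexamer": self.hexamer,
                "alu_like": self.alu_like,
                "vntr": self.vntr,
                "sine_r": self.sine_r,
                "polya": self.polya,
            }.items()
            if v is not None
        }


@dataclass
class CaptureCall:
    segment_span: tuple[int, int]  # foreign 5' block, 1-based in the element
    exon_id: str
    acquired_length: int  # matched suffix length of the donor exon
    segment_match_length: int  # matched length measured on the element segment
    junction: int  # 1-based element position where canonical SVA sequence resumes
    acceptor_ag: bool  # dinucleotide immediately 5' of the junction is AG
    transduction_span: Optional[tuple[int, int]] = None  # extra 5' sequence beyond the exon match
    ambiguous: bool = False
    catg_remnant: bool = False  # observation only, never a criterion


_local = Align.PairwiseAligner()
_local.mode = "local"
_local.match_score = 1
_local.mismatch_score = -1
_local.open_gap_score = -3
_local.extend_gap_score = -1


def _best_local(query: str, target: str):
    """(identity, target_span, query_span, score) of the best local hit of
    query in target, spans 0-based half-open; None if no alignment."""
    if not query or not target:
        return None
    aln = _local.align(target, query)
    if len(aln) == 0:
        return None
    best = aln[0]
    tb, qb = best.aligned
    if len(tb) == 0:
        return None
    matches = sum(
        1
        for (ts, te), (qs, qe) in zip(tb, qb)
        for t, q in zip(range(ts, te), range(qs, qe))
        if target[t] == query[q]
    )
    cols = sum(te - ts for ts, te in tb)
    return (
        matches / cols if cols else 0.0,
        (int(tb[0][0]), int(tb[-1][1])),
        (int(qb[0][0]), int(qb[-1][1])),
        best.score,
    )


def _find_hexamer_array(seq: str, params: DomainParams) -> Optional[tuple[int, int]]:
    """First tandem array of >= min units of TCTCCC-like hexamers."""
    n, u = len(seq), len(HEXAMER_UNIT)
    i = 0
    while i + u * params.min_hexamer_units <= n:
        j = i
        units = 0
        while j + u <= n:
            mism = sum(1 for a, b in zip(seq[j : j + u], HEXAMER_UNIT) if a != b)
            if mism <= params.hexamer_unit_max_mismatch:
                units += 1
                j += u
            else:
                break
        if units >= params.min_hexamer_units:
            return (i + 1, j)
        i += 1
    return None


def annotate_domains(
    element: str,
    domain_refs: dict[str, str],
    params: Optional[DomainParams] = None,
) -> DomainAnnotation:
    """Locate the canonical SVA domains in an element.

    ``domain_refs`` must provide 'alu_like' and 'sine_r' consensuses;
    the hexamer unit is fixed. An element without a SINE-R hit at the
    identity floor is not an SVA.
    """
    params = params or DomainParams()
    seq = element.upper()
    ann = DomainAnnotation()

    hit = _best_local(domain_refs["sine_r"], seq)
    if (
        hit is None
        or hit[0] < params.min_domain_identity
        or (hit[2][1] - hit[2][0]) < params.min_sine_r_coverage * len(domain_refs["sine_r"])
    ):
        ann.is_sva = False
        return ann
    ident, (ts, te), _, _ = hit
    ann.sine_r = (ts + 1, te)
    ann.identities["sine_r"] = ident

    head = seq[:ts]
    alu_hit = _best_local(domain_refs["alu_like"], head)
    if (
        alu_hit is not None
        and alu_hit[0] >= params.min_domain_identity
        and (alu_hit[2][1] - alu_hit[2][0]) >= params.min_alu_coverage * len(domain_refs["alu_like"])
    ):
        ident, (as_, ae), (qs, qe), _ = alu_hit
        ann.alu_like = (as_ + 1, ae)
        ann.identities["alu_like"] = ident
        ann.identities["alu_like_ref_span"] = (qs + 1, qe)

    hex_region = head[: ann.alu_like[0] - 1] if ann.alu_like else head
    hx = _find_hexamer_array(hex_region, params)
    if hx is not None:
        ann.hexamer = hx

    if ann.alu_like and ann.sine_r:
        gap_start, gap_end = ann.alu_like[1] + 1, ann.sine_r[0] - 1
        if gap_end - gap_start + 1 >= params.min_vntr_len:
            ann.vntr = (gap_start, gap_end)

    # polyA: first A-run of sufficient length 3' of the SINE-R
    tail = seq[te:]
    i = 0
    while i < len(tail):
        if tail[i] == "A":
            j = i
            while j < len(tail) and tail[j] == "A":
                j += 1
            if j - i >= params.min_polya_len:
                ann.polya = (te + i + 1, te + j)
                break
            i = j
        else:
            i += 1
    return ann


def detect_noncanonical_5p(
    element: str,
    annotation: DomainAnnotation,
    domain_refs: dict[str, str],
    params: Optional[DomainParams] = None,
) -> Optional[dict]:
    """Foreign 5' block upstream of the first canonical domain anchor.

    Returns {'span': (start, end), 'junction': pos, 'acceptor_ag': bool}
    (1-based, inclusive) or None for canonical elements. The block must
    fail to align to the hexamer/Alu-like references (identity below the
    domain floor over most of its length).
    """
    params = params or DomainParams()
    if not annotation.is_sva:
        return None
    seq = element.upper()
    if annotation.hexamer is not None and annotation.hexamer[0] <= params.min_foreign_len:
        return None  # canonical 5' start
    anchors = [s[0] for s in (annotation.hexamer, annotation.alu_like, annotation.sine_r) if s]
    anchor = min(anchors)
    if anchor - 1 < params.min_foreign_len:
        return None
    segment = seq[: anchor - 1]
    # does the putative foreign block actually look like canonical 5' sequence?
    # (include the VNTR if provided: a truncated element can present a bare
    # tandem-repeat residue 5' of its SINE-R, which is canonical, not foreign)
    canonical_5p = HEXAMER_UNIT * 6 + domain_refs["alu_like"] + domain_refs.get("vntr", "")
    hit = _best_local(segment, canonical_5p)
    if hit is not None:
        ident, _, (qs, qe), _ = hit
        covered = (qe - qs) / len(segment)
        if ident >= params.min_domain_identity and covered >= 0.6:
            return None
    return {
        "span": (1, anchor - 1),
        "junction": anchor,
        "acceptor_ag": seq[anchor - 3 : anchor - 1] == "AG",
    }


def assign_exon_source(
    segment: str,
    exon_library: dict[str, str],
    params: Optional[DomainParams] = None,
) -> Optional[CaptureCall]:
    """Attribute a foreign 5' segment to a donor exon.

    The call requires the segment's 3' end to coincide with the exon's
    3' end within the splice tolerance; the matched suffix length of the
    exon is the acquired length, and any segment sequence 5' of the exon
    match is reported as an additional upstream transduction. Multiple
    equally scoring donors yield an ambiguous call.
    """
    params = params or DomainParams()
    segment = segment.upper()
    hits = []
    for exon_id in sorted(exon_library):
        exon = exon_library[exon_id].upper()
        hit = _best_local(segment, exon)
        if hit is None:
            continue
        ident, (es, ee), (ss, se), score = hit
        if ident < 0.8:
            continue
        if len(exon) - ee > params.splice_end_tolerance:
            continue  # segment does not reach the exon 3' end: splice criterion fails
        hits.append((score, exon_id, es, ee, ss, se))
    if not hits:
        return None
    hits.sort(key=lambda h: (-h[0], h[1]))
    ambiguous = len(hits) > 1 and abs(hits[0][0] - hits[1][0]) < 1e-9
    score, exon_id, es, ee, ss, se = hits[0]
    exon = exon_library[exon_id].upper()
    call = CaptureCall(
        segment_span=(1, se),
        exon_id=exon_id,
        acquired_length=len(exon) - es,
        segment_match_length=se - ss,
        junction=se + 1,  # canonical sequence resumes where the exon match ends
        acceptor_ag=segment[max(0, se - 2) : se] == "AG",
        transduction_span=(1, ss) if ss > 0 else None,
        ambiguous=ambiguous,
        catg_remnant="CATG" in segment[:12],
    )
    return call


def detect_capture(
    element: str,
    domain_refs: dict[str, str],
    exon_library: dict[str, str],
    params: Optional[DomainParams] = None,
    junction_pad: int = 25,
) -> Optional[CaptureCall]:
    """Full capture scan: annotate domains, flag a foreign 5' block,
    attribute it to a donor exon.

    The foreign block handed to donor attribution is padded by
    ``junction_pad`` nt past the detected domain anchor because local
    domain hits place the junction only approximately; the exon-3'-end
    splice criterion then pins down the true boundary.
    """
    params = params or DomainParams()
    ann = annotate_domains(element, domain_refs, params)
    foreign = detect_noncanonical_5p(element, ann, domain_refs, params)
    if foreign is None:
        return None
    end = min(len(element), foreign["span"][1] + junction_pad)
    segment = element[:end].upper()
    call = assign_exon_source(segment, exon_library, params)
    return call


def capture_length_distribution(calls: Sequence[CaptureCall]) -> list[int]:
    """Distinct acquired lengths, each counted once, sorted ascending."""
    return sorted({c.acquired_length for c in calls})
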