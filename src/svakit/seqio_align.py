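"""Sequence I/O and reference-anchored alignment.

Elements are aligned one by one to a reference consensus with a
semi-global affine-gap alignment (end gaps free), replacing joint
multiple alignment: every element is expressed as a call vector over
reference positions plus a list of variant events. Copies within a
retrotransposon family are typically >90% identical to their consensus,
so a reference-anchored projection loses essentially nothing while
keeping coordinates stable across thousands of elements.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    A,
    BASES,
    DELETED,
    MISSING,
    AlignedProfile,
    Deletion,
    ElementRecord,
    Insertion,
    Substitution,
    VariantEvent,
    encode_states,
)

_VALID_BASE = set("ACGT")


@dataclass
class ScoringParams:
    """Affine alignment scoring. A gap of length L costs open + (L-1)*extend."""

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -6.0
    gap_extend: float = -1.0
    identity_floor: float = 0.6  # below this the element is flagged unalignable


def _default_species_parser(header: str, species_map: Optional[Mapping[str, str]]) -> str:
    """Species tag from a FASTA id: explicit map lookup, else prefix before '_'."""
    if species_map:
        for key, tag in species_map.items():
            if header == key or header.startswith(key):
                return tag
    return header.split("_", 1)[0]


def read_elements(
    fasta_path,
    species_map: Optional[Mapping[str, str]] = None,
) -> list[ElementRecord]:
    """Read one ElementRecord per FASTA entry.

    Species tags are parsed from headers: if ``species_map`` is given its
    keys are matched as id prefixes, otherwise the portion of the id
    before the first underscore is used (gg_12 -> gg).
    """
    records: list[ElementRecord] = []
    seen: set[str] = set()
    try:
        entries = list(SeqIO.parse(str(fasta_path), "fasta"))
    except Exception as exc:  # pragma: no cover - biopython raises rarely here
        raise ValueError(f"malformed FASTA {fasta_path}: {exc}") from exc
    for rec in entries:
        if not rec.id:
            raise ValueError(f"malformed FASTA {fasta_path}: record with empty id")
        if len(rec.seq) == 0:
            raise ValueError(f"malformed FASTA record {rec.id!r}: empty sequence")
        if rec.id in seen:
            raise ValueError(f"duplicate element id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            ElementRecord(
                id=rec.id,
                species=_default_species_parser(rec.id, species_map),
                sequence=str(rec.seq).upper(),
            )
        )
    if not records:
        warnings.warn(f"no records found in {fasta_path}")
    return records


def write_fasta(records: Iterable[ElementRecord], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


def read_reference_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


LOCUS_COLUMNS = ["id", "species", "flank5", "flank3", "locus_label"]


def read_locus_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in LOCUS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"locus table {path} lacks columns {missing}")
    return df


def write_locus_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _make_aligner(scoring: ScoringParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    # semi-global: unaligned overhangs on either sequence cost nothing
    aligner.end_deletion_score = 0.0
    aligner.end_insertion_score = 0.0
    return aligner


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _project(reference: str, element: str, alignment) -> tuple[np.ndarray, list[Insertion], float]:
    """Turn a Biopython alignment into a call vector + insertion list."""
    L = len(reference)
    calls = np.full(L, MISSING, dtype=np.uint8)
    insertions: list[Insertion] = []
    tblocks, qblocks = alignment.aligned
    matches = 0
    aligned_cols = 0
    prev_tend: Optional[int] = None
    prev_qend: Optional[int] = None
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        if prev_tend is not None:
            if ts > prev_tend and qs == prev_qend:
                # internal gap in the element: reference positions deleted
                calls[prev_tend:ts] = DELETED
            if qs > prev_qend:
                insertions.append(Insertion(anchor=int(prev_tend), sequence=element[prev_qend:qs]))
                if ts > prev_tend:
                    calls[prev_tend:ts] = DELETED
        for t, q in zip(range(ts, te), range(qs, qe)):
            base = element[q]
            if base in _VALID_BASE:
                calls[t] = BASES.index(base)
                if base == reference[t]:
                    matches += 1
            else:
                calls[t] = MISSING  # N / IUPAC ambiguity: never a substitution
            aligned_cols += 1
        prev_tend, prev_qend = te, qe
    identity = matches / aligned_cols if aligned_cols else 0.0
    return calls, insertions, identity, aligned_cols


def align_to_reference(
    element: ElementRecord | str,
    reference: str,
    scoring: Optional[ScoringParams] = None,
) -> AlignedProfile:
    """Semi-global alignment of one element onto a reference consensus.

    End gaps in the element are free and become *missing* reference
    positions; internal gaps become deletion calls. If alignment
    identity falls below the floor the reverse complement is tried; if
    both orientations fail the profile is flagged ``unalignable``.
    """
    scoring = scoring or ScoringParams()
    if isinstance(element, str):
        element = ElementRecord(id="anonymous", species="na", sequence=element)
    seq = element.sequence.upper()
    if not seq or not reference:
        raise ValueError("element and reference must be non-empty")
    aligner = _make_aligner(scoring)

    clean = re.sub("[^ACGT]", "N", seq)
    aln = aligner.align(reference, clean)[0]
    score = float(aln.score)
    calls, insertions, identity, cols = _project(reference, seq, aln)

    def _poor(ident: float, ncols: int) -> bool:
        # a high-identity sliver is not a proper alignment: demand that a
        # reasonable share of the element is actually aligned
        return ident < scoring.identity_floor or ncols < 0.3 * len(seq)

    revcomp = False
    if _poor(identity, cols):
        rc = _revcomp(seq)
        rc_clean = re.sub("[^ACGT]", "N", rc)
        aln_rc = aligner.align(reference, rc_clean)[0]
        calls_rc, ins_rc, id_rc, cols_rc = _project(reference, rc, aln_rc)
        if float(aln_rc.score) > score:
            calls, insertions, identity, cols, revcomp = (
                calls_rc,
                ins_rc,
                id_rc,
                cols_rc,
                True,
            )
            score = float(aln_rc.score)
    return AlignedProfile(
        element_id=element.id,
        calls=calls,
        insertions=insertions,
        identity=identity,
        score=score,
        unalignable=_poor(identity, cols),
        reverse_complemented=revcomp,
    )


def variants_from_calls(calls: np.ndarray, parent: np.ndarray) -> list[VariantEvent]:
    """Variant events of a call vector relative to a parent state vector.

    Missing positions on either side are skipped. Deletions are emitted
    as maximal contiguous runs (one event per run).
    """
    events: list[VariantEvent] = []
    n = len(calls)
    covered = (calls != MISSING) & (parent != MISSING)
    # substitutions: both are bases and differ
    sub_mask = covered & (calls < DELETED) & (parent < DELETED) & (calls != parent)
    for pos in np.flatnonzero(sub_mask):
        events.append(
            Substitution(position=int(pos) + 1, ref=BASES[int(parent[pos])], alt=BASES[int(calls[pos])])
        )
    # deletions relative to parent: element deleted where parent has a base
    del_mask = covered & (calls == DELETED) & (parent != DELETED)
    i = 0
    while i < n:
        if del_mask[i]:
            j = i
            while j + 1 < n and del_mask[j + 1]:
                j += 1
            events.append(Deletion(start=i + 1, length=j - i + 1))
            i = j + 1
        else:
            i += 1
    # parent deleted where element has a base: an insertion relative to parent
    ins_mask = covered & (parent == DELETED) & (calls < DELETED)
    i = 0
    while i < n:
        if ins_mask[i]:
            j = i
            while j + 1 < n and ins_mask[j + 1]:
                j += 1
            seq = "".join(BASES[int(calls[k])] for k in range(i, j + 1))
            events.append(Insertion(anchor=i, sequence=seq))
            i = j + 1
        else:
            i += 1
    events.sort(key=_event_sort_key)
    return events


def _event_sort_key(ev: VariantEvent):
    if isinstance(ev, Substitution):
        return (ev.position, 0, ev.alt)
    if isinstance(ev, Deletion):
        return (ev.start, 1, ev.length)
    return (ev.anchor, 2, ev.sequence)


def call_variants(profile: AlignedProfile, reference: str) -> list[VariantEvent]:
    """All variant events of a profile relative to its reference."""
    ref_vec = encode_states(reference)
    events = variants_from_calls(profile.calls, ref_vec)
    events.extend(profile.insertions)
    events.sort(key=_event_sort_key)
    return events


def coverage_ok(profile: AlignedProfile, min_fraction: float = 0.5) -> bool:
    """Keep elements covering at least ``min_fraction`` of the reference.

    The boundary is inclusive: an element covering exactly half is kept
    (only elements lacking *more* than the allowed share are excluded).
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    return profile.covered_fraction >= min_fraction


def profiles_table(profiles: Sequence[AlignedProfile]) -> pd.DataFrame:
    """Tabular export of call strings (one row per element)."""
    return pd.DataFrame(
        {
            "id": [p.element_id for p in profiles],
            "calls": [p.call_string() for p in profiles],
            "identity": [p.identity for p in profiles],
            "covered_fraction": [p.covered_fraction for p in profiles],
            "unalignable": [p.unalignable for p in profiles],
        }
    )
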