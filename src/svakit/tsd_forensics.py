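"""Target-site duplication (TSD) forensics.

Staggered-nick integration of an L1-mobilized element duplicates a short
stretch of the target site, leaving identical direct repeats 5' and 3'
of a fresh insertion. The two copies then mutate independently, so the
mismatch pattern between them, and between each of them and the
inferred pre-integration site (PIS), records the age and independence
of integration events. An extra 5' guanosine not present in the target
site is the footprint of reverse transcription of the RNA cap.

All positions are reported 1-based from the TSD 5' end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

SLIPPAGE_MAX_EXTRA = 1  # a single extra base inside a homopolymer reads as slippage


@dataclass
class TsdPair:
    tsd5: str
    tsd3: str
    mismatch_positions: list[int]  # 1-based, within the compared overlap

    @property
    def length(self) -> int:
        return len(self.tsd5)

    @property
    def identical(self) -> bool:
        return self.tsd5 == self.tsd3


@dataclass
class TargetSiteComparison:
    observed: str
    ancestral: str
    substitutions: list[tuple[int, str, str]]  # (1-based position, ancestral, observed)
    length_difference: int  # terminal nt difference (observed - ancestral)
    slippage: bool = False  # single extra base inside a homopolymer

    @property
    def substitution_count(self) -> int:
        return len(self.substitutions)


def extract_tsd(
    flank5: str,
    flank3: str,
    min_len: int = 5,
    max_len: int = 30,
    max_mismatch: int = 1,
) -> Optional[TsdPair]:
    """Longest suffix of the 5' flank matching a prefix of the 3' flank.

    Ties (several lengths within the mismatch budget) resolve to the
    longer duplication, then to fewer mismatches.
    """
    flank5, flank3 = flank5.upper(), flank3.upper()
    best: Optional[TsdPair] = None
    upper = min(max_len, len(flank5), len(flank3))
    for L in range(min_len, upper + 1):
        suf = flank5[-L:]
        pre = flank3[:L]
        mism = [i + 1 for i in range(L) if suf[i] != pre[i]]
        if len(mism) <= max_mismatch:
            if (
                best is None
                or L > best.length
                or (L == best.length and len(mism) < len(best.mismatch_positions))
            ):
                best = TsdPair(tsd5=suf, tsd3=pre, mismatch_positions=mism)
    return best


def _compare_fixed(observed: str, ancestral: str) -> list[tuple[int, str, str]]:
    return [
        (i + 1, a, o)
        for i, (o, a) in enumerate(zip(observed, ancestral))
        if o != a
    ]


def _is_homopolymer_slip(longer: str, shorter: str) -> bool:
    """True if removing one base of a homopolymer run from ``longer`` yields ``shorter``."""
    if len(longer) != len(shorter) + 1:
        return False
    for i in range(len(longer)):
        if longer[:i] + longer[i + 1 :] == shorter:
            run_char = longer[i]
            neighbors = longer[max(0, i - 1) : i + 2].replace(run_char, "")
            if (i > 0 and longer[i - 1] == run_char) or (
                i + 1 < len(longer) and longer[i + 1] == run_char
            ):
                return True
    return False


def compare_tsd(observed: str, ancestral: str) -> TargetSiteComparison:
    """End-gap-tolerant comparison of a TSD to an inferred ancestral site.

    A terminal length difference of a few nt is reported separately and
    never counted as substitution; among the possible terminal gap
    placements the one minimizing substitutions is chosen. A single
    extra base inside a homopolymer run is flagged as replication
    slippage rather than aligned as substitutions.
    """
    observed, ancestral = observed.upper(), ancestral.upper()
    if not observed or not ancestral:
        raise ValueError("both sequences must be non-empty")
    diff = len(observed) - len(ancestral)
    if diff == 0:
        return TargetSiteComparison(
            observed, ancestral, _compare_fixed(observed, ancestral), 0
        )
    longer, shorter = (observed, ancestral) if diff > 0 else (ancestral, observed)
    slip = abs(diff) <= SLIPPAGE_MAX_EXTRA and _is_homopolymer_slip(longer, shorter)
    # terminal gaps only: trim |diff| bases split between the two ends of the
    # longer sequence, choosing the split minimizing substitutions
    best_subs: Optional[list[tuple[int, str, str]]] = None
    for left in range(abs(diff) + 1):
        right = abs(diff) - left
        trimmed = longer[left : len(longer) - right] if right else longer[left:]
        if diff > 0:
            subs = _compare_fixed(trimmed, ancestral)
        else:
            subs = _compare_fixed(observed, trimmed)
        if best_subs is None or len(subs) < len(best_subs):
            best_subs = subs
    return TargetSiteComparison(observed, ancestral, best_subs or [], diff, slippage=slip)


def detect_untemplated_g(element_5p: str, target_site: Optional[str]):
    """Untemplated leading guanosine check (RNA-cap signature).

    Returns (flag, count): the number of leading G on the element not
    matched by trailing G of the resolved target-site copy at the 5'
    junction. With an unresolved target site the call is undetermined
    (None, 0).
    """
    if target_site is None or target_site == "":
        return None, 0
    element_5p = element_5p.upper()
    target_site = target_site.upper()
    g_el = len(element_5p) - len(element_5p.lstrip("G"))
    g_ts = len(target_site) - len(target_site.rstrip("G"))
    count = max(0, g_el - g_ts)
    return count > 0, count


def a_tract_distance(
    target_context: str,
    insertion_point: int,
    min_tract_len: int = 6,
    window: int = 50,
) -> Optional[int]:
    """Distance from the 3' end of the nearest upstream A-tract to the
    insertion point (0 = directly adjacent), or None if no tract of
    ``min_tract_len`` lies within ``window`` nt upstream.

    ``insertion_point`` is the 0-based index in ``target_context`` before
    which the element inserted.
    """
    import re as _re

    if not 0 <= insertion_point <= len(target_context):
        raise ValueError("insertion point outside the target context")
    upstream = target_context[:insertion_point].upper()
    best: Optional[int] = None
    for m in _re.finditer("A{%d,}" % min_tract_len, upstream):
        dist = len(upstream) - m.end()
        if dist <= window and (best is None or dist < best):
            best = dist
    return best
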