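"""End-to-end convenience wrappers over the analysis stages.

These are thin orchestration helpers; all substance lives in the stage
modules. The subfamily pipeline aligns every element to the root
reference, applies the coverage filter, sorts on the SINE-R window
(the domain classically used for subfamily definition) and scores the
outcome against simulation truth when available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import DELETED, BASES, ElementRecord
from .seqio_align import AlignedProfile, ScoringParams, align_to_reference, coverage_ok
from .subfamily_sort import SortingParams, SubfamilyTree, sort_subfamilies
from .synthetic_data import SimulationResult, score_partition


@dataclass
class SubfamilyRun:
    tree: SubfamilyTree
    profiles: list[AlignedProfile]
    kept_ids: list[str]
    excluded_ids: list[str]
    assignment: dict[str, str]


def run_subfamily_pipeline(
    elements: Sequence[ElementRecord],
    reference: str,
    region: Optional[tuple[int, int]] = None,
    sorting: Optional[SortingParams] = None,
    scoring: Optional[ScoringParams] = None,
    root_name: str = "root",
) -> SubfamilyRun:
    sorting = sorting or SortingParams()
    profiles = [align_to_reference(e, reference, scoring) for e in elements]
    kept = [p for p in profiles if not p.unalignable and coverage_ok(p, sorting.coverage_min)]
    excluded = [p.element_id for p in profiles if p.element_id not in {k.element_id for k in kept}]
    species = {e.id: e.species for e in elements}
    tree = sort_subfamilies(
        kept, reference, sorting, root_name=root_name, species_of=species, region=region
    )
    return SubfamilyRun(
        tree=tree,
        profiles=profiles,
        kept_ids=[p.element_id for p in kept],
        excluded_ids=excluded,
        assignment={p.element_id: tree.assignment[p.element_id] for p in kept},
    )


def _region_sequence(vec: np.ndarray, region: tuple[int, int]) -> str:
    lo, hi = region
    return "".join(BASES[int(s)] for s in vec[lo - 1 : hi] if s < DELETED)


def score_against_truth(run: SubfamilyRun, sim: SimulationResult, region: tuple[int, int]):
    """(ARI, per-lineage table, fraction of source consensuses recovered exactly).

    Consensus recovery compares decoded sequences over the sorting
    region, because the placement of a deletion within an alignment is
    ambiguous while the resulting sequence is not.
    """
    truth = sim.truth[sim.truth.element_id.isin(run.assignment)]
    ari, per = score_partition(run.assignment, truth)
    recovered = {
        _region_sequence(s.consensus_calls, region) for s in run.tree.subfamilies.values()
    }
    n_hit = sum(
        1 for vec in sim.sources.values() if _region_sequence(vec, region) in recovered
    )
    return ari, per, n_hit / len(sim.sources)
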