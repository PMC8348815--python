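"""Scoring of pipeline output against a simulation truth set.

Used by the validation suite: planted-junction recovery (within a base
tolerance), exactness of array unit counts/orientations, filler-origin
correctness, and event-type agreement are all computed from the
:class:`~tdnarray.simulate.TruthSet` without re-simulation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .pipeline import PipelineResult
from .simulate import Scenario

JUNCTION_TOL_BP = 10


def expected_event_types(truth_event) -> set[str]:
    """Event types the pipeline should call for one planted event."""
    kind = truth_event.kind
    if kind == "TDNA_ARRAY":
        return {"CANONICAL_INSERTION"} if len(truth_event.chain) == 1 else {"COMPLEX_ARRAY"}
    if kind == "TRANSLOCATION_PAIR":
        return {"TRANSLOCATION_FUSION", "TDNA_FREE_FUSION"}
    if kind == "INVERTED_DUPLICATION":
        return {"INVERTED_DUPLICATION"}
    if kind == "CPDNA_FILLER_JUNCTION":
        return {"CPDNA_INSERTION"}
    if kind == "TDNA_FREE_FUSION":
        return {"TDNA_FREE_FUSION"}
    raise ValueError(f"unknown truth kind {kind}")


def planted_junction_points(truth) -> list[tuple[str, int]]:
    """(chrom, position) of every genomic junction side in the truth."""
    points = []
    for ev in truth.events:
        for jt in ev.junctions:
            for side in (jt.left, jt.right):
                kind, subject, coord, _orient = side
                if kind == "GENOMIC":
                    points.append((subject, coord))
    # deduplicate
    return sorted(set(points))


def recovered_anchor_points(result: PipelineResult) -> list[tuple[str, int]]:
    points = []
    for st in list(result.structures) + list(result.fusion_structures):
        for fl in (st.left_flank, st.right_flank):
            if fl is not None:
                points.append((fl.chrom, fl.position))
    return points


def junction_recovery(truth, result: PipelineResult, tol: int = JUNCTION_TOL_BP):
    """(n_recovered, n_planted) junction points within ``tol`` bases."""
    planted = planted_junction_points(truth)
    recovered = recovered_anchor_points(result)
    hit = 0
    for chrom, pos in planted:
        if any(c == chrom and abs(p - pos) <= tol for c, p in recovered):
            hit += 1
    return hit, len(planted)


def _chain_signature(units) -> tuple:
    return tuple((u.kind, u.orientation) for u in units)


def _truth_signature(chain) -> tuple:
    return tuple((u.kind, u.orient) for u in chain)


def _flip_signature(sig: tuple) -> tuple:
    return tuple((k, "-" if o == "+" else "+") for k, o in reversed(sig))


def array_units_exact(truth_event, result: PipelineResult) -> bool:
    """True when some resolved structure reproduces the planted unit chain
    (counts and orientations; the chain read in either direction)."""
    want = _truth_signature(truth_event.chain)
    for st in list(result.structures) + list(result.fusion_structures):
        non_gen = [u for u in st.chain if u.kind not in ("GENOMIC",)]
        got = _chain_signature(non_gen)
        if got == want or got == _flip_signature(want):
            return True
    return False


def filler_origin_correct(truth, result: PipelineResult, min_len: int = 20):
    """(n_correct, n_planted) for planted fillers of at least ``min_len``."""
    planted = []
    for ev in truth.events:
        for jt in ev.junctions:
            if len(jt.filler_seq) >= min_len:
                planted.append(jt)
    correct = 0
    all_reports = [r for reports in result.junctions.values() for r in reports]
    for jt in planted:
        for rep in all_reports:
            if not rep.filler_seq:
                continue
            if abs(len(rep.filler_seq) - len(jt.filler_seq)) > 60:
                continue
            hits = rep.filler_origin_hits
            if hits and hits[0].subject_id == jt.filler_origin:
                correct += 1
                break
    return correct, len(planted)


def event_types_match(truth, result: PipelineResult) -> bool:
    called = {e.event_type for e in result.events}
    for ev in truth.events:
        if not expected_event_types(ev) <= called:
            return False
    return True


@dataclass
class ScenarioScore:
    name: str
    junctions_recovered: int
    junctions_planted: int
    arrays_exact: bool
    fillers_correct: int
    fillers_planted: int
    events_exact: bool


def score_scenario(scenario: Scenario, result: PipelineResult) -> ScenarioScore:
    truth = scenario.truth
    rec, planted = junction_recovery(truth, result)
    arrays = all(
        array_units_exact(ev, result) for ev in truth.events if ev.chain
    )
    fc, fp = filler_origin_correct(truth, result)
    return ScenarioScore(
        name=scenario.name,
        junctions_recovered=rec,
        junctions_planted=planted,
        arrays_exact=arrays,
        fillers_correct=fc,
        fillers_planted=fp,
        events_exact=event_types_match(truth, result),
    )
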