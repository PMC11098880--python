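"""Transparent rule-based surgical phase recognition.

Maps role-augmented scene-graph sequences to the eight workflow phases by
querying for characteristic triplets (e.g. head surgeon hammering patient),
threading a latched surgery-started / surgery-finished state through the
take.  No learned parameters, no phase annotations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .core import ClinicalRole, SceneGraph, SceneSequence, SurgicalPhase

__all__ = ["PhaseState", "phase_of_frame", "recognize_phases"]


@dataclass(frozen=True)
class PhaseState:
    """Latched workflow milestones; monotone within a take."""

    surgery_started: bool = False
    surgery_finished: bool = False
    cementing_seen: bool = False  # precondition for surgery_finished

    def __post_init__(self) -> None:
        if self.surgery_finished and not self.surgery_started:
            raise ValueError("finished implies started")


def _role_of(graph: SceneGraph, node_id: str) -> Optional[ClinicalRole]:
    return graph.nodes[node_id].role


def _has_role_triplet(
    graph: SceneGraph, subject_role: ClinicalRole, relation: str, object_role: ClinicalRole
) -> bool:
    for subj, rel, obj in graph.edges:
        if (
            rel == relation
            and _role_of(graph, subj) == subject_role
            and _role_of(graph, obj) == object_role
        ):
            return True
    return False


def _patient_present(graph: SceneGraph) -> bool:
    return any(n.role == ClinicalRole.PATIENT for n in graph.nodes.values())


def phase_of_frame(
    graph: SceneGraph, state: PhaseState, previous: Optional[SurgicalPhase] = None
) -> tuple[SurgicalPhase, PhaseState]:
    """Classify one frame and update the latched state.

    Rules in priority order (specific action triplets first):
      1. head surgeon Cementing patient            -> Surgery 3: Conclusion
      2. head surgeon Hammering patient            -> Surgery 2: Implant Placement
      3. head surgeon Cutting patient              -> Surgery 1: Implant Placement Prep.
      4. both surgeons Preparing patient           -> Patient Preparation
      5. patient present and surgery not started   -> Patient Roll-In
      6. patient present and surgery finished      -> Patient Roll-Out
      7. no patient and surgery not started        -> OR Preparation
      8. no patient and surgery finished           -> OR Cleanup
      fallback: the previous frame's phase.

    ``surgery_started`` latches when any of rules 1-4 first fires;
    ``surgery_finished`` latches on the first frame after Cementing was
    observed in which no action rule (1-4) fires.
    """
    if any(n.role is None for n in graph.human_nodes()):
        raise ValueError(
            "human nodes lack roles; assign roles (tracking) before phase recognition"
        )
    hs, patient = ClinicalRole.HEAD_SURGEON, ClinicalRole.PATIENT
    assistant = ClinicalRole.ASSISTANT_SURGEON

    cementing = _has_role_triplet(graph, hs, "Cementing", patient)
    hammering = _has_role_triplet(graph, hs, "Hammering", patient)
    cutting = _has_role_triplet(graph, hs, "Cutting", patient)
    preparing = _has_role_triplet(graph, hs, "Preparing", patient) and _has_role_triplet(
        graph, assistant, "Preparing", patient
    )
    action_fired = cementing or hammering or cutting or preparing

    if action_fired:
        state = replace(state, surgery_started=True)
    if cementing:
        state = replace(state, cementing_seen=True)
    if state.cementing_seen and not action_fired and not state.surgery_finished:
        state = replace(state, surgery_finished=True)

    if cementing:
        phase = SurgicalPhase.SURGERY_3
    elif hammering:
        phase = SurgicalPhase.SURGERY_2
    elif cutting:
        phase = SurgicalPhase.SURGERY_1
    elif preparing:
        phase = SurgicalPhase.PATIENT_PREPARATION
    elif _patient_present(graph):
        if not state.surgery_started:
            phase = SurgicalPhase.PATIENT_ROLL_IN
        elif state.surgery_finished:
            phase = SurgicalPhase.PATIENT_ROLL_OUT
        else:
            phase = previous if previous is not None else SurgicalPhase.PATIENT_ROLL_IN
    else:
        if not state.surgery_started:
            phase = SurgicalPhase.OR_PREPARATION
        elif state.surgery_finished:
            phase = SurgicalPhase.OR_CLEANUP
        else:
            phase = previous if previous is not None else SurgicalPhase.OR_PREPARATION
    return phase, state


def _majority_smooth(labels: list[SurgicalPhase], window: int) -> list[SurgicalPhase]:
    if window <= 1:
        return list(labels)
    half = window // 2
    out = []
    for i in range(len(labels)):
        lo, hi = max(0, i - half), min(len(labels), i + half + 1)
        counts = Counter(labels[lo:hi])
        best = max(counts.values())
        # among tied majority labels keep the one at the center if possible
        if counts[labels[i]] == best:
            out.append(labels[i])
        else:
            out.append(next(l for l in labels[lo:hi] if counts[l] == best))
    return out


def recognize_phases(
    sequence: SceneSequence, smoothing_window: int = 1
) -> list[SurgicalPhase]:
    """Left-to-right fold of :func:`phase_of_frame` over a role-augmented
    sequence, with optional odd-window sliding majority smoothing."""
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be a positive odd integer")
    state = PhaseState()
    labels: list[SurgicalPhase] = []
    previous: Optional[SurgicalPhase] = None
    for graph in sequence:
        phase, state = phase_of_frame(graph, state, previous)
        labels.append(phase)
        previous = phase
    return _majority_smooth(labels, smoothing_window)
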