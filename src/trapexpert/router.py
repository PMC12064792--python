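"""Two-stage decision logic: global model routes images to expert models.

Stage one, a global detector trained over all species, makes a first call on
each image.  If it names a species, the image is forwarded only to the expert
model responsible for that species' appearance group, and the expert's answer
is final (direct route).  If it says background — the case where single-stage
models err most, missing small or hidden animals — the image is broadcast to
all experts, and the highest-confidence non-background expert vote wins; only
if every expert also answers background does the image stay background.  An
expert that belongs to the wrong group typically answers with low confidence
(empirically below ~60%), which is why the confidence vote recovers the right
group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Hashable, Iterable, Mapping, Sequence

from .dataset_io import AnnotationRecord, BoundingBox

logger = logging.getLogger(__name__)

__all__ = [
    "Prediction",
    "DetectorHandle",
    "RoutingPolicy",
    "RoutedDecision",
    "RoutingError",
    "image_label_from_detections",
    "route",
    "run_pipeline",
    "decisions_to_dataframe",
]


@dataclass(frozen=True)
class Prediction:
    """A single detector output: class label, confidence, and (for animals)
    a bounding box.  Background predictions carry no box."""

    label: str
    confidence: float
    box: BoundingBox | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass(frozen=True)
class DetectorHandle:
    """A pluggable detector: a name, the label set it may emit (its group's
    species plus background), and a predict callable mapping an image
    reference to a list of predictions."""

    name: str
    classes: frozenset[str]
    predict: Callable[[Hashable], list[Prediction]]

    def __call__(self, image_ref: Hashable) -> list[Prediction]:
        preds = self.predict(image_ref)
        stray = {p.label for p in preds} - self.classes
        if stray:
            raise ValueError(f"detector {self.name!r} emitted foreign labels {sorted(stray)}")
        return preds


@dataclass(frozen=True)
class RoutingPolicy:
    """Configuration of the two-stage router.

    ``expert_of`` maps every species the global model can emit to the id of
    the expert group handling it.  ``min_detection_conf`` is the image-level
    floor below which box predictions are ignored.  When an expert answers
    background on a direct route, ``escalate_on_expert_background`` re-routes
    the image through the broadcast path.  ``out_of_group_conf_note`` is a
    diagnostic threshold (not a filter): out-of-group expert votes are
    expected to fall below it on average.
    """

    expert_of: Mapping[str, int]
    background_label: str = "background"
    min_detection_conf: float = 0.25
    escalate_on_expert_background: bool = True
    out_of_group_conf_note: float = 0.60

    def __post_init__(self) -> None:
        object.__setattr__(self, "expert_of", dict(self.expert_of))

    @property
    def group_ids(self) -> frozenset[int]:
        return frozenset(self.expert_of.values())


@dataclass(frozen=True)
class RoutedDecision:
    """Final two-stage label for one image, with provenance.

    ``path`` is ``direct`` (global named a species, one expert consulted),
    ``broadcast`` (all experts consulted, a non-background vote won) or
    ``background`` (all experts agreed the image is empty).
    """

    final: Prediction
    path: str
    global_vote: Prediction
    expert_votes: dict[int, Prediction] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.path not in ("direct", "broadcast", "background"):
            raise ValueError(f"unknown path {self.path!r}")
        if self.path == "direct" and len(self.expert_votes) != 1:
            raise ValueError("direct route must consult exactly one expert")


@dataclass(frozen=True)
class RoutingError:
    """Recorded in place of a decision when a detector fails on an image."""

    image_id: str
    message: str


def image_label_from_detections(
    preds: Sequence[Prediction], policy: RoutingPolicy
) -> Prediction:
    """Collapse box-level detector output to one image-level prediction.

    The highest-confidence species prediction at or above the detection floor
    wins (ties broken by lexicographic label).  With no qualifying species
    prediction the image is background: at the confidence of an explicit
    background prediction if the detector emitted one, else at
    1 - max(confidence) of the sub-floor detections (1.0 if there were none).
    """
    bg = policy.background_label
    species = [
        p for p in preds
        if p.label != bg and p.confidence >= policy.min_detection_conf
    ]
    if species:
        # argmax confidence, ties to the lexicographically smallest label
        return min(species, key=lambda p: (-p.confidence, p.label))
    explicit_bg = [p for p in preds if p.label == bg]
    if explicit_bg:
        return Prediction(bg, max(p.confidence for p in explicit_bg))
    if preds:
        return Prediction(bg, 1.0 - max(p.confidence for p in preds))
    return Prediction(bg, 1.0)


def _broadcast(
    image_ref, experts: Mapping[int, DetectorHandle], policy: RoutingPolicy
) -> tuple[Prediction, str, dict[int, Prediction]]:
    votes = {
        gid: image_label_from_detections(experts[gid](image_ref), policy)
        for gid in sorted(experts)
    }
    animal = [p for p in votes.values() if p.label != policy.background_label]
    if animal:
        final = min(animal, key=lambda p: (-p.confidence, p.label))
        return final, "broadcast", votes
    final = max(votes.values(), key=lambda p: p.confidence)
    return final, "background", votes


def route(
    image_ref,
    global_model: DetectorHandle,
    experts: Mapping[int, DetectorHandle],
    policy: RoutingPolicy,
) -> RoutedDecision:
    """Make the two-stage decision for one image.

    Species call from the global model -> consult that species' expert only;
    background call -> broadcast to every expert and take the most confident
    non-background vote (background only if the experts are unanimous).
    """
    missing = policy.group_ids - experts.keys()
    if missing:
        raise KeyError(f"no expert model for group(s) {sorted(missing)}")
    global_vote = image_label_from_detections(global_model(image_ref), policy)

    if global_vote.label != policy.background_label:
        try:
            gid = policy.expert_of[global_vote.label]
        except KeyError:
            raise KeyError(
                f"species {global_vote.label!r} has no expert group in the policy"
            ) from None
        expert_vote = image_label_from_detections(experts[gid](image_ref), policy)
        if (
            expert_vote.label == policy.background_label
            and policy.escalate_on_expert_background
        ):
            final, path, votes = _broadcast(image_ref, experts, policy)
            return RoutedDecision(final, path, global_vote, votes)
        return RoutedDecision(expert_vote, "direct", global_vote, {gid: expert_vote})

    final, path, votes = _broadcast(image_ref, experts, policy)
    return RoutedDecision(final, path, global_vote, votes)


def run_pipeline(
    records: Iterable[AnnotationRecord | str],
    global_model: DetectorHandle,
    experts: Mapping[int, DetectorHandle],
    policy: RoutingPolicy,
) -> list[tuple[str, RoutedDecision | RoutingError]]:
    """Route every record through the two-stage pipeline, preserving order.

    A detector failure on one image is recorded as a :class:`RoutingError`
    entry and processing continues.
    """
    out: list[tuple[str, RoutedDecision | RoutingError]] = []
    for rec in records:
        image_id = rec.image_id if isinstance(rec, AnnotationRecord) else str(rec)
        try:
            out.append((image_id, route(image_id, global_model, experts, policy)))
        except (KeyError, ValueError) as exc:
            logger.warning("routing failed on %s: %s", image_id, exc)
            out.append((image_id, RoutingError(image_id, str(exc))))
    return out


def decisions_to_dataframe(results: Sequence[tuple[str, RoutedDecision | RoutingError]]):
    """Tabulate routed decisions (image_id, final label/conf, path, global
    label/conf) for CSV export; failed images appear with path ``error``."""
    import pandas as pd

    rows = []
    for image_id, dec in results:
        if isinstance(dec, RoutingError):
            rows.append(
                dict(image_id=image_id, final_label="", final_conf=float("nan"),
                     path="error", global_label="", global_conf=float("nan"))
            )
        else:
            rows.append(
                dict(
                    image_id=image_id,
                    final_label=dec.final.label,
                    final_conf=dec.final.confidence,
                    path=dec.path,
                    global_label=dec.global_vote.label,
                    global_conf=dec.global_vote.confidence,
                )
            )
    return pd.DataFrame(rows)
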