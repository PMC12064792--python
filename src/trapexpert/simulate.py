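"""Synthetic ground truth and simulated detectors for desk-scale experiments.

Camera-trap pipelines are usually validated on huge image corpora and trained
network weights, neither of which is needed to study the *decision logic* of
a two-stage expert system.  This module replaces the image side with a
generative model of detector behaviour:

* ground truth — an imbalanced species mix (by default the relative
  abundances of a published 24-species benchmark), a configurable fraction of
  empty images (camera triggers with no animal), one animal per image with a
  uniformly placed box, and a camera-site id for held-out splitting;
* detectors — each species has a confusion row (probabilities of being
  predicted as every label, including background = a missed animal) and Beta
  confidence distributions: high confidence when the prediction is correct
  (Beta(8, 2), mean 0.8), low when it is wrong (Beta(2, 3), mean 0.4,
  typically below the 60% range where out-of-group guesses live);
* planted structure — confusion concentrated within appearance groups
  (red deer vs fallow deer, rabbit vs hare), the regime in which grouping
  and expert routing pay off.  Expert detectors see only their group's
  species; confusion mass toward foreign species folds into background.

Every operation is a pure function of (inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .dataset_io import AnnotationRecord, BoundingBox
from .grouping import ConfusionMatrix, GroupAssignment
from .router import (
    DetectorHandle,
    Prediction,
    RoutingPolicy,
    image_label_from_detections,
    run_pipeline,
)
from .evaluation import EvaluationReport, classification_report, published_benchmark

__all__ = [
    "SpeciesProfile",
    "SimConfig",
    "DEFAULT_CORRECT_CONF",
    "DEFAULT_WRONG_CONF",
    "simulate_ground_truth",
    "make_simulated_detector",
    "planted_group_confusion",
    "empirical_confusion",
    "simulate_two_stage_experiment",
    "benchmark_species",
    "background_false_negatives",
]

DEFAULT_CORRECT_CONF = (8.0, 2.0)
DEFAULT_WRONG_CONF = (2.0, 3.0)
BACKGROUND = "background"


@dataclass(frozen=True)
class SpeciesProfile:
    """Generative description of one species as a detector sees it.

    ``confusion_row`` maps every label the detector might emit (including the
    background label, i.e. a missed animal) to a probability; it must sum
    to 1.  ``frequency_weight`` is the species' relative abundance.
    Confidence draws use Beta(*correct_conf*) when the emitted label matches
    the true species and Beta(*wrong_conf*) otherwise.
    """

    label: str
    frequency_weight: float
    confusion_row: Mapping[str, float]
    correct_conf: tuple[float, float] = DEFAULT_CORRECT_CONF
    wrong_conf: tuple[float, float] = DEFAULT_WRONG_CONF

    def __post_init__(self) -> None:
        if self.frequency_weight <= 0:
            raise ValueError(f"{self.label}: frequency_weight must be positive")
        row = dict(self.confusion_row)
        if any(p < 0 for p in row.values()):
            raise ValueError(f"{self.label}: negative confusion probability")
        total = sum(row.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.label}: confusion row sums to {total}, not 1")
        for params in (self.correct_conf, self.wrong_conf):
            if params[0] <= 0 or params[1] <= 0:
                raise ValueError(f"{self.label}: Beta shape parameters must be positive")
        object.__setattr__(self, "confusion_row", row)


@dataclass(frozen=True)
class SimConfig:
    """Conditions of a simulated survey: the species mix, the number of
    images and camera sites, the empty-image fraction, box jitter applied by
    detectors, and the master seed."""

    species: tuple[SpeciesProfile, ...]
    n_images: int
    seed: int
    empty_fraction: float = 0.3
    n_sites: int = 10
    box_jitter_sd: float = 0.02
    background_label: str = BACKGROUND

    def __post_init__(self) -> None:
        if not 0 <= self.empty_fraction < 1:
            raise ValueError("empty_fraction must lie in [0, 1)")
        if self.n_sites < 2:
            raise ValueError("need at least 2 camera sites")
        if self.n_images < 1:
            raise ValueError("n_images must be positive")
        object.__setattr__(self, "species", tuple(self.species))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(p.label for p in self.species)


def _random_box(rng: np.random.Generator) -> BoundingBox:
    w = float(rng.uniform(0.05, 0.4))
    h = float(rng.uniform(0.05, 0.4))
    cx = float(rng.uniform(w / 2, 1 - w / 2))
    cy = float(rng.uniform(h / 2, 1 - h / 2))
    return BoundingBox(cx, cy, w, h)


def simulate_ground_truth(cfg: SimConfig) -> list[AnnotationRecord]:
    """Draw a fully reproducible synthetic survey.

    Each image is empty with probability ``empty_fraction``; otherwise one
    species is drawn proportionally to its frequency weight and given a
    uniformly placed box.  Sites are assigned uniformly.
    """
    rng = np.random.default_rng(cfg.seed)
    weights = np.array([p.frequency_weight for p in cfg.species], dtype=float)
    probs = weights / weights.sum()
    empty = rng.random(cfg.n_images) < cfg.empty_fraction
    species_idx = rng.choice(len(cfg.species), size=cfg.n_images, p=probs)
    sites = rng.integers(0, cfg.n_sites, size=cfg.n_images)
    w = rng.uniform(0.05, 0.4, size=cfg.n_images)
    h = rng.uniform(0.05, 0.4, size=cfg.n_images)
    cx = rng.uniform(w / 2, 1 - w / 2)
    cy = rng.uniform(h / 2, 1 - h / 2)
    records = []
    for i in range(cfg.n_images):
        image_id = f"img{i:06d}"
        site_id = f"site{int(sites[i]):03d}"
        if empty[i]:
            records.append(AnnotationRecord(image_id, site_id, ()))
        else:
            lab = cfg.species[int(species_idx[i])].label
            box = BoundingBox(cx[i], cy[i], w[i], h[i])
            records.append(AnnotationRecord(image_id, site_id, ((lab, box),)))
    return records


def _restrict_row(
    row: Mapping[str, float],
    classes: Sequence[str],
    background_label: str,
    fold_to_background: bool,
) -> np.ndarray:
    """Restrict a confusion row to the labels a detector may emit.

    Mass on foreign labels either folds into background (the detector simply
    does not see those species as candidates, so the animal reads as "no
    known class") or is renormalised over the detector's own labels.
    """
    out = np.array([row.get(lab, 0.0) for lab in classes], dtype=float)
    missing = sum(p for lab, p in row.items() if lab not in classes)
    if missing > 0:
        if fold_to_background:
            out[list(classes).index(background_label)] += missing
        else:
            if out.sum() == 0:
                raise ValueError("confusion row has no mass on the detector's classes")
            out /= out.sum()
    return out


def make_simulated_detector(
    truth: Sequence[AnnotationRecord],
    profiles: Mapping[str, SpeciesProfile] | Sequence[SpeciesProfile],
    classes: Sequence[str],
    seed: int | Sequence[int],
    name: str = "sim",
    background_label: str = BACKGROUND,
    fold_to_background: bool = True,
    box_jitter_sd: float = 0.02,
) -> DetectorHandle:
    """Build a deterministic simulated detector over a known truth index.

    All predictions are drawn up front (vectorised per species), so the
    detector answers identically every time it is consulted on an image —
    like a frozen network — and two pipelines sharing the handle see the
    same votes.  On an image of species ``s`` it emits one prediction drawn
    from ``s``'s confusion row restricted to ``classes`` (confidence from the
    correct-Beta if the label matches, wrong-Beta otherwise; background
    predictions carry no box, others the true box plus Gaussian jitter).  On
    empty images it emits background unless a profile for the background
    label assigns false-alarm mass to species.
    """
    if not isinstance(profiles, Mapping):
        profiles = {p.label: p for p in profiles}
    classes = list(classes)
    if background_label not in classes:
        classes = classes + [background_label]
    class_set = frozenset(classes)
    rng = np.random.default_rng(seed)

    # group images by their true species (None = empty)
    by_species: dict[str | None, list[AnnotationRecord]] = {}
    for rec in truth:
        if rec.is_empty:
            by_species.setdefault(None, []).append(rec)
        else:
            for lab, _ in rec.detections:
                by_species.setdefault(lab, []).append(rec)

    missing = {s for s in by_species if s is not None and s not in profiles}
    if missing:
        raise KeyError(f"no species profile for {sorted(missing)}")

    bg_profile = profiles.get(background_label)
    predictions: dict[str, list[Prediction]] = {}
    for species in sorted(by_species, key=lambda s: (s is None, s or "")):
        recs = by_species[species]
        n = len(recs)
        if species is None:
            if bg_profile is None:
                for rec in recs:
                    predictions[rec.image_id] = [Prediction(background_label, 1.0)]
                continue
            profile, true_label = bg_profile, background_label
        else:
            profile, true_label = profiles[species], species
        row = _restrict_row(profile.confusion_row, classes, background_label,
                            fold_to_background)
        cum = np.cumsum(row)
        draws = np.searchsorted(cum, rng.random(n) * cum[-1], side="right")
        draws = np.minimum(draws, len(classes) - 1)
        conf_ok = rng.beta(*profile.correct_conf, size=n)
        conf_bad = rng.beta(*profile.wrong_conf, size=n)
        jitter = rng.normal(0.0, box_jitter_sd, size=(n, 2))
        for i, rec in enumerate(recs):
            emitted = classes[int(draws[i])]
            conf = float(conf_ok[i] if emitted == true_label else conf_bad[i])
            if emitted == background_label:
                predictions[rec.image_id] = [Prediction(background_label, conf)]
            else:
                if rec.is_empty:
                    box = _random_box(rng)
                else:
                    tb = rec.detections[0][1]
                    cx = min(max(tb.cx + jitter[i, 0], tb.w / 2), 1 - tb.w / 2)
                    cy = min(max(tb.cy + jitter[i, 1], tb.h / 2), 1 - tb.h / 2)
                    box = BoundingBox(cx, cy, tb.w, tb.h)
                predictions[rec.image_id] = [Prediction(emitted, conf, box)]

    def predict(image_ref) -> list[Prediction]:
        try:
            return predictions[image_ref]
        except KeyError:
            raise KeyError(f"detector {name!r} has no image {image_ref!r}") from None

    return DetectorHandle(name, class_set, predict)


def planted_group_confusion(
    groups: Sequence[Sequence[str]],
    within_rate: float,
    across_rate: float,
    miss_rate: float,
    frequency_weights: Mapping[str, float] | None = None,
    correct_conf: tuple[float, float] = DEFAULT_CORRECT_CONF,
    wrong_conf: tuple[float, float] = DEFAULT_WRONG_CONF,
    background_label: str = BACKGROUND,
) -> list[SpeciesProfile]:
    """Confusion profiles with block structure aligned to appearance groups.

    Each rate is a total probability mass budget: ``within_rate`` is spread
    uniformly over the species' same-group peers, ``across_rate`` over all
    out-of-group species, and ``miss_rate`` goes to background; the remainder
    stays on the species itself.  A singleton group has no peers, so its
    within mass stays on the diagonal.
    """
    if not 0 <= across_rate <= within_rate:
        raise ValueError(
            f"need 0 <= across_rate <= within_rate, got {across_rate} > {within_rate}"
        )
    budget = within_rate + across_rate + miss_rate
    if miss_rate < 0 or budget > 1 + 1e-12:
        raise ValueError(f"rates sum to {budget:.4f} > 1; reduce them")
    all_species = [lab for grp in groups for lab in grp]
    if len(set(all_species)) != len(all_species):
        raise ValueError("species appear in more than one group")
    n = len(all_species)
    profiles = []
    for grp in groups:
        g = len(grp)
        for lab in grp:
            row = dict.fromkeys(all_species, 0.0)
            self_mass = 1.0 - miss_rate
            if g > 1:
                for peer in grp:
                    if peer != lab:
                        row[peer] = within_rate / (g - 1)
                self_mass -= within_rate
            if n > g:
                for other in all_species:
                    if other not in grp:
                        row[other] = across_rate / (n - g)
                self_mass -= across_rate
            row[lab] = self_mass
            row[background_label] = miss_rate
            weight = frequency_weights.get(lab, 1.0) if frequency_weights else 1.0
            profiles.append(
                SpeciesProfile(lab, weight, row, correct_conf, wrong_conf)
            )
    return profiles


def empirical_confusion(
    profiles: Sequence[SpeciesProfile] | Mapping[str, SpeciesProfile],
    n_per_species: int,
    seed: int | Sequence[int],
    background_label: str = BACKGROUND,
) -> ConfusionMatrix:
    """Estimate a detector's confusion matrix from simulated predictions.

    A balanced synthetic truth (``n_per_species`` images per species) is run
    through a simulated global detector and the (true, predicted) pairs are
    counted.  The background row counts empty-image predictions when a
    background profile is present, and stays zero otherwise.
    """
    if isinstance(profiles, Mapping):
        profiles = list(profiles.values())
    species = [p.label for p in profiles if p.label != background_label]
    labels = species + [background_label]
    truth = []
    box = BoundingBox(0.5, 0.5, 0.2, 0.2)
    for lab in species:
        for i in range(n_per_species):
            truth.append(AnnotationRecord(f"{lab}_{i}", "site000", ((lab, box),)))
    detector = make_simulated_detector(truth, profiles, labels, seed,
                                       background_label=background_label)
    policy = RoutingPolicy(expert_of={s: 0 for s in species},
                           background_label=background_label,
                           min_detection_conf=0.0)
    truth_labels = [rec.detections[0][0] for rec in truth]
    predicted = [
        image_label_from_detections(detector(rec.image_id), policy).label
        for rec in truth
    ]
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    index = {lab: i for i, lab in enumerate(labels)}
    for t, p in zip(truth_labels, predicted):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(tuple(labels), counts)


def benchmark_species(
    background_label: str = BACKGROUND,
) -> tuple[list[str], list[list[str]], dict[str, float]]:
    """Species codes, four appearance groups, and relative abundances of the
    published 24-species benchmark (supports of its test set)."""
    df = published_benchmark()
    animals = df[df["code"] != "background"]
    species = animals["code"].tolist()
    groups = [
        animals.loc[animals["group"] == g, "code"].tolist()
        for g in ("large", "medium", "small", "micro")
    ]
    weights = dict(zip(animals["code"], animals["support"].astype(float)))
    return species, groups, weights


def background_false_negatives(report: EvaluationReport,
                               background_label: str = BACKGROUND) -> int:
    """Number of animal images called background (missed animals)."""
    cm = report.confusion
    j = cm.labels.index(background_label)
    return int(cm.counts[:, j].sum() - cm.counts[j, j])


def simulate_two_stage_experiment(
    cfg: SimConfig,
    global_profiles: Sequence[SpeciesProfile] | Mapping[str, SpeciesProfile],
    expert_profiles: Sequence[SpeciesProfile] | Mapping[str, SpeciesProfile],
    assignment: GroupAssignment,
    policy: RoutingPolicy | None = None,
) -> tuple[EvaluationReport, EvaluationReport]:
    """Run the single-stage and two-stage pipelines on one simulated survey.

    The same ground truth and the same global detector feed both pipelines:
    single-stage takes the global detector's image-level label as final;
    two-stage routes it through the expert models of ``assignment``.  Expert
    detectors are built from ``expert_profiles`` restricted to their group's
    species (plus background).  Returns the paired evaluation reports over
    species + background.
    """
    if not isinstance(global_profiles, Mapping):
        global_profiles = {p.label: p for p in global_profiles}
    if not isinstance(expert_profiles, Mapping):
        expert_profiles = {p.label: p for p in expert_profiles}
    bg = cfg.background_label
    if policy is None:
        policy = RoutingPolicy(
            expert_of={lab: assignment.group_of(lab) for lab in assignment.labels},
            background_label=bg,
        )
    truth = simulate_ground_truth(cfg)
    all_classes = list(cfg.labels) + [bg]
    global_det = make_simulated_detector(
        truth, global_profiles, all_classes, seed=[cfg.seed, 1],
        name="global", background_label=bg, box_jitter_sd=cfg.box_jitter_sd,
    )
    experts = {}
    for gid in range(assignment.k):
        members = list(assignment.members(gid))
        # the full profile map: an expert is consulted on foreign species too
        # (broadcast); restriction to its classes folds that mass sensibly
        experts[gid] = make_simulated_detector(
            truth,
            expert_profiles,
            members + [bg],
            seed=[cfg.seed, 2 + gid],
            name=f"expert{gid}",
            background_label=bg,
            box_jitter_sd=cfg.box_jitter_sd,
        )

    truth_labels = [
        rec.detections[0][0] if not rec.is_empty else bg for rec in truth
    ]
    single_pred = [
        image_label_from_detections(global_det(rec.image_id), policy).label
        for rec in truth
    ]
    results = run_pipeline(truth, global_det, experts, policy)
    two_pred = [dec.final.label for _, dec in results]

    single = classification_report(truth_labels, single_pred, all_classes)
    two = classification_report(truth_labels, two_pred, all_classes)
    return single, two
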