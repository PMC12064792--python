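# Methods

## The two-stage decision model

A single detector trained over all species of a camera-trap survey makes
two characteristic kinds of error: it confuses morphologically similar
species (the bulk of its off-diagonal confusion mass lies within groups of
look-alikes), and it misses small or partially hidden animals, labelling
their images empty. The two-stage design treats the global detector as a
coarse router: its species call selects one *expert* detector trained only
on that species' appearance group (plus background), and the expert's
answer replaces the global one. A background call instead triggers a
broadcast: every expert votes, and the most confident non-background vote
wins. The final confidence reported is the deciding expert's, not a product
with the global confidence — the expert is the authority on its own group.

This works because of an asymmetry in confidence: an expert looking at an
animal from its own group answers confidently, while an expert shown a
foreign animal either answers background or guesses one of its own classes
at low confidence. The router records a 60% diagnostic threshold for
out-of-group votes; it is an expectation checked in simulation, not a hard
filter, because confidence distributions of real detectors vary.

### Grouping from confusion

Groups are derived from data, not taxonomy. Given the confusion matrix
C (counts, rows = true species), the similarity matrix is the row-normalised
S_ij = C_ij / Σ_k C_ik. S is asymmetric; clustering needs a symmetric
dissimilarity, and we use the mutual-confusion distance
D = 1 − (S + Sᵀ)/2 with a forced zero diagonal. Species are agglomerated
bottom-up with **average linkage** (UPGMA): robust to unequal group sizes
and monotone, so cutting the dendrogram at K clusters is well defined.
Complete and single linkage are available behind a flag for sensitivity
checks. K defaults to 4 but is a user decision; the `group` command prints
the merge heights so the largest height gap can guide the cut.

Numerical determinism matters here: linkage distances are recomputed from
the raw leaf matrix with `math.fsum` (the exactly rounded true sum), so
exact ties are well defined regardless of merge history, and ties are
broken by the smallest (i, j) node-index pair. The merge sequence is
therefore bit-for-bit reproducible and is verified in the tests against an
independent brute-force reference, including tie cases.

Background is removed before clustering — groups contain species only.
A species with an all-zero confusion row (never observed) cannot be placed
by the clustering; it is excluded from the agglomeration and attached
afterwards to the group at minimum mean distance, with a warning.

### Routing edge cases

* Image-level label from box-level output: the highest-confidence species
  prediction at or above `min_detection_conf` (default 0.25); ties broken
  by lexicographic label; otherwise background, at the confidence of an
  explicit background prediction if present, else 1 − max(confidence).
* An expert answering background on a direct route escalates to a full
  broadcast by default (`escalate_on_expert_background`), consistent with
  the broadcast path's purpose of never silently dropping an animal; a flag
  disables it.
* Unanimous expert background keeps the image background at the maximum
  expert background confidence.

### Evaluation

Per-class precision, recall, F1 and support are computed from the
image-level confusion matrix; undefined ratios are 0 (zero-division
convention, flagged by support-0 rows). Micro F1 equals accuracy for
single-label data; macro and support-weighted F1 are reported alongside it
because aggregate F1 figures in the literature rarely state their weighting
— we print all three. mAP@0.5 uses per-class greedy matching by descending
confidence (one truth matches at most one detection, highest IoU first) and
all-point interpolated average precision, which is parameter-free; a
101-point grid option exists for parity with common YOLO tooling. Classes
with no ground truth are excluded from the mean and reported as NaN.

## The simulator

The simulator replaces images with a generative model of detector
behaviour, which is all the decision layer sees:

* **Ground truth** — each image is empty with probability
  `empty_fraction` (default 0.3), else carries one animal drawn
  proportionally to per-species frequency weights with a uniformly placed
  box, plus a uniformly drawn camera-site id. The default species mix is
  the 24-species benchmark table shipped with the package, whose support
  column provides a realistic abundance imbalance (from 61 to 23,417
  instances across classes). One animal per image is the default because
  the evaluation is per-image single-label; multi-animal frames are out of
  the generator's default scope.
* **Detectors** — a species' behaviour is a confusion row (probabilities
  over all labels plus background = a miss) and two Beta confidence laws:
  Beta(8, 2) (mean 0.8) when the emitted label is correct, Beta(2, 3)
  (mean 0.4) when it is wrong. These defaults reproduce the qualitative
  separation that makes confidence voting work — wrong and out-of-group
  answers rarely exceed 60% — and are configurable per species.
* **Planted structure** — `planted_group_confusion` builds confusion rows
  with total mass budgets: `within_rate` spread uniformly over same-group
  peers, `across_rate` over all other species, `miss_rate` on background,
  remainder on the diagonal. The rates are totals (not per-peer), so a
  regime like within 0.3 is feasible for any group size. The default study
  regime is global within 0.3 / across 0.01 / miss 0.05 with experts at one
  tenth of each — experts are better on their own group but not perfect.
* **Expert restriction** — an expert's emission is its species' confusion
  row restricted to the group's labels; mass on foreign labels folds into
  background by default (the expert has no concept of foreign species), or
  is renormalised over its own labels behind a flag.
* A detector draws all its predictions vectorised at construction over the
  supplied truth index, so it is deterministic per image — consulting it
  twice gives the same answer, as a frozen network would — and the global
  model's vote is identical across the single- and two-stage pipelines.
* Sites only partition records for splitting; no site-level covariate
  shift is simulated, isolating the routing mechanism from domain shift.

### What the simulation does and does not show

Passing tests demonstrate that the *decision logic* behaves as designed:
grouping recovers planted appearance structure from empirical confusion,
broadcast voting recovers animals the global model misses, and the
two-stage pipeline dominates single-stage macro F1 when experts are
genuinely better within their groups. The simulator does not model pixel
phenomena (illumination, occlusion, background correlation with species),
confidence miscalibration, sequence/burst correlation, or multi-animal
frames; absolute F1 values obtained in simulation therefore say nothing
about absolute performance on real imagery, only about the relative
behaviour of the two pipelines under stated error structure.

## Problem sizes

The package's own experiments use surveys of 20,000 images (30% empty)
per replicate for pipeline comparisons, 2,000 simulated predictions per
species for empirical confusion matrices, and 20–100 replicate seeds for
stochastic checks — sizes at which every quantity of interest is stable to
well within the margins being asserted while the full suite remains quick
to run.

## Dataset plumbing

* MegaDetector-style batch JSON is ingested as draft labels: corner-based
  normalised boxes are converted to the centre-based YOLO convention at the
  boundary (all internal coordinates are fractions, so image dimensions are
  never required); detections below a configurable confidence floor
  (default 0.25) are dropped, and images with nothing left are marked
  empty.
* Per-group training sets remap species to contiguous group-local indices.
  Empty images are replicated into **every** group's dataset so each expert
  learns to answer background. Images mixing species from different groups
  fit no single expert; they are excluded and reported rather than
  silently assigned.
* Class weights w_i = T/(K·n_i) (T total instances, K classes) counter
  abundance imbalance; they conserve Σ n_i·w_i = T and equal 1 under
  balance. A zero count is an error with advice to merge or drop the class.
* The held-out split partitions whole camera sites, so test images come
  from contexts never seen in training; a per-image split exists behind a
  flag for comparison.

## Known limitations

* Choosing K is deliberately manual (merge heights are printed to assist);
  no automatic gap statistic is applied.
* Detector confidences are taken at face value; no calibration layer.
* The broadcast consults experts only — the global model's second-best
  class is not used as a hint.
* Newick export assumes an ultrametric tree (guaranteed by monotone
  linkages); exporting a non-monotone custom tree is unsupported.
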