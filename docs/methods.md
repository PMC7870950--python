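# Methods

## The diagnostic problem

Hirschsprung's disease (HSCR) is diagnosed by *absence*: a biopsy is
positive for HSCR only when no ganglion cell can be found anywhere in the
submucosal (Meissner) or myenteric (Auerbach) plexus. A single convincing
ganglion cell anywhere in the submucosa or muscularis propria rules the
disease out at that level. The search is therefore a rare-event detection
problem — a handful of target cells in centimetres of tissue — and the
asymmetry of the costs matters: a missed ganglion cell leads to
over-resection of healthy bowel, a hallucinated one to insufficient
surgery.

This package implements a hierarchical-contextual analysis (HCA) of H&E
colon histology for that problem, plus the assisted-diagnosis layer built
on it: candidate detection, anatomical filtering, neighbourhood re-scoring,
triage of candidates into ranked image sets for a pathologist, and the
expert/non-expert classification and consultation rules. Everything is
exercised end to end on synthetic slides with exact ground truth.

## Pipeline

### Stain model

Images are modelled with a two-stain Beer–Lambert law. With unit optical-
density vectors **h** (hematoxylin) and **e** (eosin) in RGB space, a pixel
with concentrations (c_h, c_e) transmits

    I = 255 · exp(−(c_h·h + c_e·e)).

`separate_stains` inverts this by least squares and reports the residual
projection (the component orthogonal to both stains). The synthetic
renderer composes images through exactly this model, so unmixing is exact
up to 8-bit quantisation and injected noise; the reconstruction RMSE on a
noise-free slide is asserted below 0.05 OD in the tests.

### Hierarchical analysis (layer veto)

`segment_layers` classifies smoothed (σ = 2 px) stain concentrations
against per-layer palette centroids, then applies a laminar prior: one
layer per tissue row (row-wise majority vote, 9-row median smoothing).
Pixels with both concentrations below 0.08 OD are background. The
permissible set is exactly {submucosa, muscularis propria}; candidates are
vetoed by the layer under their *centroid* (a single deterministic rule for
boundary-straddling patches, matching the encircling-annotation
convention). Lamina propria and mucosa are merged into one non-permissible
label since the rule only distinguishes permissible from not.

The segmentation contract is behavioural, not operator-specific: pixel
agreement with the generator's ground truth ≥ 0.99 on noise-free slides
and ≥ 0.9 at the default noise level. A blank image yields an
all-background map and a warning rather than an error.

### Candidate detection and base score

Seeds are local maxima of the hematoxylin channel smoothed at σ = 3 px
(minimum separation 15 px, threshold 0.45 OD) — this responds to the
prominent nucleolus of a mature ganglion cell, the compact dark nucleus of
an immature one, and assorted basophilic distractors, which is the point:
the veto and the score, not the seeder, carry the specificity. Four
features are measured in a 100×100 px patch (a mature soma is ~100 px at
the reference magnification of 0.25 µm/px):

| feature | meaning | range |
|---|---|---|
| `nucleus_area` | pale vesicular-nucleus fraction near the centre | 0–1 |
| `nucleolus_prominence` | centre-vs-surround hematoxylin contrast at 6 px and 12 px scales | 0–1 |
| `cytoplasm_abundance` | strongly eosinophilic cytoplasm fraction in the 12–45 px annulus | 0–1 |
| `stain_ratio` | stained (non-lumen) fraction of the patch | 0–1 |

The base score is a logistic over a positively weighted sum
(weights 3.0, 2.5, 2.5, 1.5, bias −4.2), hence monotone nondecreasing in
every feature; an all-zero feature vector scores ≈ 0.015. Candidates below
0.2 are not emitted. Non-maximum suppression keeps the better-scoring of
any two candidates within 50 px (one candidate per soma); ties break by
(score desc, y asc, x asc). The layer veto is applied to seeds before
feature extraction — the result is identical to filtering afterwards, it
merely skips measuring the many vetoed mucosal nuclei.

### Contextual analysis (feedback loop)

Ganglion cells cluster, sit near vessels and are accompanied by Schwann
cells. For each candidate the stage measures

* `cluster_size` — size of its single-linkage cluster (radius 300 px, a
  few soma diameters); a candidate is always in its own cluster;
* `companion_density` — hematoxylin-dense, non-eosinophilic (Schwann-like)
  texture fraction in a 60–160 px annulus, saturating at 0.005;
* `vessel_proximity` — exp(−d/150 px) to the nearest vessel-lumen-like
  component (nearly unstained, 120–5000 px², in permissible tissue);

and re-scores

    contextual = clip(base · (1 + 0.5·cluster + 0.3·companion + 0.2·vessel), 0, 1)

with cluster bonus min((size−1)/3, 1). Candidates below a floor of 0.05
are pruned and the loop repeats (pruning changes cluster structure) until
a fixed point, at most 10 iterations. Pruning is monotone, so termination
is guaranteed; scores of survivors depend only on the surviving set, so
re-running on the output is the identity, and adding a neighbour can never
lower anyone's score. The companion/vessel heuristics are calibrated to
the synthetic renderer's morphology and are not biologically validated
detectors.

### Triage

All slides of a case pool into one ranking. The top 36 candidates by
contextual score are cropped with a 25 px context margin and grouped, in
rank order, into up to 12 sets of 3. A set's score is the best of its
members (a set is reviewed for *any* ganglion cell); a trailing partial
set is kept, because dropping a candidate could hide the only ganglion
cell of the case. The case-level AI score is the mean of the three highest
set scores, the mean of whatever exists when there are fewer than three
sets, and 0 for a case with no sets.

### Decision rules

Applied with the 0.6 boundary inclusive on the
Doubt side:

* **Expert** — any set scored 5 ("ganglion cells seen, certain") ⇒
  Positive (non-HSCR); otherwise Negative. Never Doubt. An empty case is
  Negative (nothing to see), recorded in the basis for audit.
* **Non-expert** — two or more sets scored 5 ⇒ Positive; otherwise
  Negative if the case AI average < 0.6, Doubt if ≥ 0.6. Doubt routes to
  expert consultation; the expert's label replaces it. A Doubt case
  without an expert label is an error, so a high-AI case can never be
  silently finalised Negative by a non-expert.

The rule's known failure mode — two wrongly certain scores of 5 yield an
unreferred false Positive — is reproduced faithfully, not patched.

### Cell-level metrics

A truth cell counts as detected iff ≥ 1 detection centroid lies inside its
polygon (multiple detections count once). Specificity needs a negative
unit the cell-by-cell convention leaves implicit; here it is decoy
locations sampled uniformly in permissible tissue at least 100 px from any
annotated object (10 per truth cell by default, minimum 50), a decoy being
correctly rejected when no detection centroid falls inside its 100×100 px
box. With zero truth cells, sensitivity is reported as undefined (not 0).
Consultation statistics report per-observer counts/rates and the exact-k
cross-observer distribution, always with explicit denominators.

## The synthetic generator

The generator is the study bed, so its defaults define the test
conditions rather than being tuning knobs:

* **Geometry** — horizontal bands (epithelium 6%, mucosa 22%, submucosa
  28%, muscularis 30%, serosa 8% of height, remainder background), which
  makes layer ground truth exact. Default slide 1664×1280 px at
  0.25 µm/px; the whole-slide-scale checks use 8192×6144.
* **Mature ganglion cells** — somata of radius 44–52 px: abundant
  cytoplasm (c_h 0.5, c_e 0.9), pale nucleus at 0.42 of the soma radius
  (0.3, 0.15), one 5 px nucleolus (1.5, 0.2); default 8 per slide in
  clusters of mean size 3, with 2–4 Schwann-like spindles and a companion
  vessel near each cluster.
* **Immature ganglion cells** — radius 17–23 px, small dark nucleus
  (1.0, 0.1) filling 0.75 of the soma, scant intensely stained cytoplasm
  (0.8, 0.5), no visible nucleolus; default 3 per slide. This is the
  neonatal variant that mimics plasma cells and drives real-world
  consultations.
* **Mimics** — plasma-cell-like dark blobs (radius 7–11 px), placed *only*
  in epithelium, mucosa or serosa: exactly the false alarms the
  hierarchical veto exists to remove.
* **Noise** — Gaussian concentration noise (σ = 0.05 OD by default) plus
  0.3·σ along the residual stain direction; crypt-nuclei speckle in the
  mucosa and subtle fibre striping in the muscularis.
* **Cohorts** — one slide per case. HSCR cases have zero ganglion cells;
  non-HSCR cases draw Poisson counts around the defaults (minimum one
  mature cell); inadequate cases emulate too-superficial rectal biopsies:
  epithelium and mucosa only, hence no permissible layer and no ganglia.

A single `numpy` generator seeded from the spec is threaded through every
stochastic call; identical spec and seed reproduce the bundle bit for bit.

What the generator does **not** emulate: curved biopsy geometry, scanner
artefacts and multi-resolution pyramids, stain variability between
laboratories, transition-zone histology, overlapping cell textures, and
the full morphological diversity of real immature ganglion cells. Passing
the synthetic benchmark therefore demonstrates that the pipeline's logic
and rules behave as specified under known conditions — it is *not*
evidence of clinical-grade detection on real slides, for which the
classical detector here stands in for learned detectors whose trained
weights this package does not ship.

## Problem sizes and numerical choices

* The detection benchmark uses 20 default-difficulty cases
  (30% HSCR, 10% inadequate, seed 7) and asserts pooled cell-level
  sensitivity ≥ 90% and specificity ≥ 95%, plus one presented true
  ganglion cell in every ganglion-bearing case — thresholds chosen for
  the synthetic bed, deliberately not the figures a clinical validation
  would quote.
* The presented-area check runs one whole-slide-scale case (8192×6144)
  and asserts that triage shows the pathologist < 1% of the tissue area.
* Stain math runs in float32 (an 8-bit LUT for OD conversion); geometry
  and scores in float64. Score ties break by (score, y, x); cluster
  membership uses ≤ comparisons; the Doubt boundary is ≥ 0.6 exactly.
* Degenerate inputs have defined behaviour throughout: empty candidate
  lists, blank images, all-black images (error: undefined log), zero-set
  cases, bands too thin to host a soma (explicit error, no silent
  truncation).

## Known limitations

* The detector's features and the contextual heuristics are calibrated to
  the renderer; on real slides they would need re-derivation against
  annotated data.
* Serial-section persistence — a real clue for immature ganglion cells —
  is out of scope: context is measured within a single image, and slides
  interact only through case-level triage pooling.
* Specificity depends on an artifact convention for the negative unit
  (decoy sampling); alternative conventions would shift the number.
* Biopsy adequacy is not assessed; inadequate cases are simply expected
  to classify Negative, which the rules produce because no permissible
  layer exists.
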