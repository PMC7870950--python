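# ganglionhca

Hierarchical contextual analysis (HCA) for ganglion-cell detection in H&E
colon histology, with the diagnostic triage layer used in assisted
Hirschsprung-disease (HSCR) work-ups.

HSCR is diagnosed by absence: a case is positive for the disease only when
*no* ganglion cell exists in the submucosal or myenteric plexus, so the
pathologist must rule out a rare event across dozens of slides. This
package implements that search as a deterministic, fully inspectable
pipeline and exercises it end to end on synthetic colon-wall slides with
exact ground truth:

* **synthetic histology** — a seeded generator of layered colon-wall
  images (surface epithelium, mucosa, submucosa, muscularis propria,
  serosa) with mature and immature ganglion cells, plasma-cell-like
  mimics, vessels and Schwann-cell context, plus ASAP-style XML polygon
  annotations and exact per-pixel layer maps;
* **hierarchical analysis** — anatomical layer segmentation and the veto
  rule: ganglion cells occur only in the submucosa and muscularis
  propria, so any candidate anywhere else is negative by anatomy;
* **candidate detection** — a classical blob + hand-crafted-feature
  detector over optical-density stain channels, scoring each candidate in
  [0, 1] with a fixed monotone logistic map;
* **contextual analysis** — iterative re-scoring from neighbourhood
  evidence (clustering, Schwann-like companion texture, vessel
  proximity), with rescore-and-prune feedback to a fixed point;
* **triage** — the top 36 candidates of a case, grouped into up to 12
  ranked sets of 3 images for pathologist review; the case AI score is
  the mean of the three highest set scores;
* **decision rules** — the triage classification criteria: for an
  expert, one set scored 5 ("ganglion cells seen, certain") makes the
  case Positive; for a non-expert, two sets scored 5 make it Positive,
  otherwise a case AI average < 0.6 is Negative and ≥ 0.6 is Doubt, which
  routes the case to expert consultation — plus cell-level
  sensitivity/specificity and cohort consultation statistics.

The scientific model and every default are documented in
[docs/methods.md](docs/methods.md).

## Worked example

```python
import ganglionhca as g
from ganglionhca.config import RunConfig
from ganglionhca.pipeline import analyze_bundle
from ganglionhca.decision_metrics import classify_nonexpert, classify_expert

bundle = g.generate_slide(g.SlideSpec(seed=42))     # 8 mature + 3 immature
analysis = analyze_bundle(bundle, RunConfig(), case_id="demo")
rec = analysis.record
print(f"candidates after contextual analysis: {len(analysis.candidates)}")
print(f"image sets: {len(rec.sets)}")
for s in rec.sets[:3]:
    print(f"  set {s.rank}: {len(s.patches)} patches, set_score={s.set_score:.3f}")
print(f"case AI score (mean of top 3 sets): {rec.avg_top3_ai:.3f}")
print("non-expert, sets scored [4,4,4,...]:",
      classify_nonexpert([4]*len(rec.sets), rec.avg_top3_ai).label)
print("expert, one set scored 5:",
      classify_expert([5] + [1]*(len(rec.sets)-1)).label)
```

prints

```
candidates after contextual analysis: 13
image sets: 5
  set 1: 3 patches, set_score=1.000
  set 2: 3 patches, set_score=1.000
  set 3: 3 patches, set_score=1.000
case AI score (mean of top 3 sets): 1.000
non-expert, sets scored [4,4,4,...]: Doubt
expert, one set scored 5: Positive
```

Read: on this ganglion-bearing slide the pipeline kept 13 candidates (the
11 planted ganglion cells plus near-soma context), triaged them into 5
ranked sets, and gave the case the maximal AI score. A non-expert who was
never certain (all 4s) ends in Doubt — the case goes to an expert rather
than being finalised Negative — while an expert who is certain about a
single set classifies the case Positive (non-HSCR) immediately.

The same flow is available from the shell:

```sh
ganglion-hca simulate --seed 7 --out run/
ganglion-hca triage   --out run/
ganglion-hca evaluate --out run/ --observer-scores scores.csv \
                      --expert-observer expert
```

`scores.csv` is long-format `observer,case_id,set_rank,score` with scores
on the 1–5 certainty scale.

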