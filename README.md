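# broncholoc

Bronchoscope localization in a virtual 3-D bronchial tree from monocular
endoscopic video.

During a bronchoscopy the surgeon steers a flexible camera-tipped scope
through the branching airways using only its 2-D video feed; taking a
wrong branch is easy and costly. `broncholoc` estimates where the scope
is inside a 3-D airway model so its position can be co-displayed next to
the live image. It is aimed at researchers in endoscopic navigation who
need a fully synthetic, ground-truthed testbed for two-phase
track-then-verify localization.

## Method

Localization is split into two phases:

1. **Tracking** — for each consecutive frame pair B(t−1), B(t), two
   displacement estimators run side by side: SIFT feature matching
   (fast, but derailed by sudden scope motion) and block-matching optical
   flow maximizing the normalized cross-correlation
   CC(G,H) = Σ(g−ḡ)(h−h̄)/(MN σ_G σ_H) (slower, robust). A neuro-fuzzy
   arbiter keyed on the *suddenness* of the motion and the match
   confidence picks one; the 2-D motion is lifted to a camera increment
   ΔQ (lateral from the principal-point shift, axial from the scale
   change, roll from the fit angle, with depth hints cast in the virtual
   model) and integrated into the running pose Q.
2. **Verification** — the virtual airway is rendered at Q and compared
   with the real frame: 40-px subblocks are pooled, glare blocks
   (saturation ≈ 0, value ≈ 1) are masked by a fuzzy detector, blocks with
   low non-uniformity I = Σ(x_i² − 2x_i u + u²) = N·SD² are dropped, and
   the surviving block layout is summarized as a 16-region polar
   histogram. Two layouts are compared with
   C_ij = ½ Σ_k (h_i(k)−h_j(k))²/(h_i(k)+h_j(k)), reported as the
   normalized similarity s = 1 − C_ij/(n_i+n_j). If a fuzzy acceptance
   model rejects s, ΔQ is re-scaled over a fixed factor set (line
   search), each candidate re-rendered, and the best-scoring pose kept.

A discrete hidden Markov model μ = (S, O, A, B, π) trained on fork-coded
routes (every airway bifurcation is a numbered choice, so a route is an
integer sequence like 0-0-0) supplies path planning: forward likelihood
for scoring, Viterbi for state inference, Baum–Welch (stopping at a 0.01
mean log-likelihood change) for training.

All study inputs are procedurally generated with ground truth — airway
trees, interior renders with the characteristic dark tunnel and bright
near walls, specular glare blobs, sensor noise, fisheye warp, sudden-jump
trajectories. See `docs/methods.md` for models, parameters and
limitations.

## Worked example

Localize a short synthetic sequence through a straight airway segment:

```python
import numpy as np
from broncholoc import SequenceSpec, synthesize
from broncholoc.pipeline import localize_sequence, feature_report

seq = synthesize(SequenceSpec(name="demo", straight_tube=True, n_steps=6,
                              step_mm=0.5, sway_mm=0.1, image_size=128, seed=5))
verified, tracked, records = localize_sequence(
    seq.frames, seq.airway, seq.poses[0], seq.render_cfg)
truth = np.array([p.position for p in seq.poses])
for k, v in enumerate(verified):
    ev = np.linalg.norm(v.position - truth[k])
    rec = records[k - 1] if k else None
    extra = f"  source={rec['source']}  s={rec['s']:.3f}" if rec else ""
    print(f"frame {k}: verified err {ev:.3f} mm{extra}")
```

prints

```
frame 0: verified err 0.000 mm
frame 1: verified err 0.016 mm  source=features  s=0.997
frame 2: verified err 0.028 mm  source=features  s=0.997
frame 3: verified err 0.033 mm  source=features  s=1.000
frame 4: verified err 0.034 mm  source=features  s=1.000
frame 5: verified err 0.048 mm  source=features  s=1.000
```

— per frame: the position error of the verified pose against the known
camera trajectory (tens of micrometres over a 2.5 mm advance), which
estimator the arbiter trusted, and the normalized shape-context
similarity s of the accepted render (1.0 = the rendered view's salient
block layout matches the frame's exactly). The detector comparison on the
first frame pair,
`print(feature_report(seq.frames[0], seq.frames[1]).to_string(index=False))`:

```
method  total_matches  inliers  outliers
  sift            125      121         4
   orb            130      126         4
 brief             12       11         1
```

where inliers are matches consistent with the dominant 2-D similarity
transform.

The same machinery is scriptable from the shell: `broncholoc fixtures -o
fixtures/` writes the named ground-truthed sequences, `broncholoc
localize -c run.yaml` runs tracking + verification over a frame
directory, `broncholoc features a.png b.png` prints the table above, and
`broncholoc plan --airway tree.obj --hmm model.json --from J0 --to J7`
returns a fork-coded route.

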