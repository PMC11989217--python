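# teawither

Withering is the first step of black-tea manufacture: fresh leaves lose
water under controlled temperature and humidity until their moisture content
(wet basis) falls into the industry's *moderate withering* band of **58–66%**.
Judging that moment by eye is subjective; measuring it destructively is slow.
`teawither` estimates leaf moisture — and the withering verdict — from an
ordinary RGB image.

## How it works

Leaves photographed hourly along a withering run form an ordered series of
time-point *classes*, each with a measured moisture label
`Y_0 > Y_1 > … > Y_n`. A CNN classifier assigns an image a softmax
confidence vector `(N_0, …, N_n)` over those classes, and the continuous
moisture estimate is the expectation of the labels under that distribution:

```
Y = Σᵢ Yᵢ · Nᵢ
```

Because `Y` is a convex combination of the trained labels, the model can
predict moisture for withering stages it never saw: an intermediate
time point draws confidence from its two temporal neighbours and lands
between their labels. The verdict is then read off the band:
`Y > 0.66` → insufficient, `0.58 ≤ Y ≤ 0.66` → moderate, `Y < 0.58` →
excessive.

The classifier backbone is a cross-stage-partial design with two
modifications aimed at the subtle colour/texture differences between
consecutive time points:

* **RFAConv** (receptive-field attention convolution) — each k×k receptive
  field receives its own softmax weighting (k² non-negative weights summing
  to 1 per location), computed from an average-pooled summary through a
  grouped 1×1 convolution, so fields are no longer forced to share one
  kernel's response.
* **C2f_CA** — the C2f fusion block (split → n bottlenecks → concatenate →
  fuse) gated by coordinate attention: per-height and per-width sigmoid
  gates derived from directional pooling.

Model quality is reported with the chemometric suite: RMSEP (root mean
square error of prediction), SD (sample standard deviation of the reference
labels), RPD = SD/RMSEP (values above 2 mark a usable quantitative model),
and the correlation-type statistic Rp (1 for perfect prediction).

All network code runs on a small numpy reverse-mode autodiff engine included
in the package (`teawither.autodiff`), so training and inference are pure
CPU with no deep-learning framework dependency. Estimators follow
scikit-learn conventions (`fit`/`predict`/`get_params`, clone-compatible).

Because real withering-series images are not generally available, the
package ships a deterministic synthetic generator
(`teawither.synthetic`) that renders leaf-like images whose colour darkens,
outline shrinks and texture coarsens monotonically as moisture falls from
~0.78 to ~0.49 across 13 hourly classes — enough structure to exercise and
test every stage of the pipeline end to end.

## Worked example

The ten trained time points carry the moisture labels
`0.7843, 0.7714, 0.763, 0.7501, 0.699, 0.6654, 0.6372, 0.5671, 0.5177,
0.4863`. An image of an *untrained* intermediate stage classified with
confidences `0.91888142` (class 0), `0.08109235` (class 1),
`0.00002619` (class 2), `0.00000001` (class 3) gets:

```python
>>> from teawither import MoistureLabelTable, predict_moisture, assess_withering
>>> table = MoistureLabelTable.reference()
>>> conf = [0.91888142, 0.08109235, 0.00002619, 0.00000001, 0, 0, 0, 0, 0, 0]
>>> predict_moisture(conf, table)
0.78325333
>>> assess_withering(0.78325333)
<WitheringDegree.INSUFFICIENT: 'insufficient'>
```

The estimate `0.78325333` sits between the two wettest labels — the true
moisture of that stage was 0.7799, an error of 0.0034 — and 78.3% moisture
is above the 66% band edge, so the leaves are not yet sufficiently
withered. Note the confidences are used exactly as given (their sum,
0.99999997, deviates from 1 by eight-decimal rounding; no renormalization).

A full synthetic run from the shell:

```sh
teawither synth --out data --seed 1 --classes 13 --per-class 40
teawither train --data data --out run --profile mini --epochs 30 --seed 1
teawither predict --checkpoint run/checkpoint.npz --data data \
    --labels run/labels.csv --out pred.jsonl
teawither evaluate --predictions pred.jsonl --labels data/labels.csv --out metrics.csv
```

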