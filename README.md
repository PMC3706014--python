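# presee

Parameter-free segmentation of time-series streams into piecewise-linear
*character points*, driven by minimum description length (MDL/MML) model
selection — plus the bottom-up benchmark segmenter, a bounded-random-walk
stream generator, and the error/compression statistics used to evaluate
them.

## Who this is for

Stream-mining pipelines over sensor, ecological, medical or financial series
(eddy-covariance flux networks, ICU monitors, traffic loops, stock ticks)
usually cannot afford to mine raw streams; they first reduce a stream
`S = <s_1 ... s_n>` to a short sequence of retained points
`C = <c_1 ... c_m>` whose consecutive pairs define linear segments
approximating the original polyline.  Classic segmenters (top-down,
bottom-up, plain sliding windows) need an error threshold that is hard to
set and data-type dependent.  Here the segment/no-segment decision is made
by code length instead: a run of original lines is replaced by one segment
exactly when doing so shortens the two-part code

    MDL_seg(i, j)   = log2 len(s_i s_j)
                      + sum_k [ log2(w_p d_p(s_i s_j, s_k s_k+1))
                              + log2(w_a d_a(s_i s_j, s_k s_k+1)) ]
    MDL_noseg(i, j) = sum_k log2 len(s_k s_k+1)

    segment  iff  MDL_seg < MDL_noseg

where `d_p` is a Hausdorff-style perpendicular distance
`(l_1^2 + l_2^2)/(l_1 + l_2)` and `d_a = len(L_o) sin(theta)` the angle
distance between an original line and the candidate segment, mixed with
weights `w_p = w_a = 1/2`.  No threshold is required; a greedy single-pass
scan inside a slide window grows each candidate until the inequality first
fails, and a streaming driver emits finished character points while the rest
of the stream is still arriving (one read per point, memory bounded by the
window).  Window size and batch size exist but only trade speed — they do
not change what is retained in any material way.

See `docs/methods.md` for the full model description, numerical choices and
limitations.

## Worked example

```sh
presee generate --size 10000 --lb 0 --ub 3000 --sharpness 0.001 --seed 7 \
       --out walk.csv
presee segment walk.csv walk.seg.csv
presee evaluate walk.csv walk.seg.csv
```

which prints

```
read 10000 points, wrote 5744 character points (compress rate 0.57440)
error_rate 0.091792
n_segments 5743
compress_rate 0.574400
```

The generator produced a bounded random walk of 10,000 records in
`index,value` rows; the parameter-free segmenter kept 5,744 of them, i.e.
the stream shrank to 57% of its size, and the retained polyline sits at a
mean segmenting distance of 0.09 value units from the original lines (mean
over segments of the mean line-to-segment distance).  `walk.seg.csv` holds
the character points in the same two-column format, so any downstream miner
can consume it in place of the raw stream.

The same operations are available as a library:

```python
from presee import (GeneratorConfig, SegmenterConfig, generate_arrays,
                    segment_series, error_rate_arrays, DistanceWeights)
import numpy as np

x, y = generate_arrays(GeneratorConfig(size=10_000, seed=7))
chars = segment_series((x, y), SegmenterConfig())
report = error_rate_arrays(x, y, np.asarray(chars.projections),
                           DistanceWeights())
print(report.error_rate, report.compress_rate)
```

`presee bench-bu` runs the slide-window bottom-up benchmark (the classic
threshold-driven merger) on the same file formats, and `presee sweep` maps
how sensitively its segment count depends on that threshold — the
sensitivity the MDL criterion is designed to avoid.

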