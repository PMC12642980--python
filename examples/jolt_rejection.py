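"""Reject plate-wide mechanical jolts from multi-well trace sets.

A jolt (bumping the bench) shakes every well at once, producing spikes as
large as real contractions.  Because the spike is synchronized across
wells, while beats are not, a quorum test on robust per-well z-scores
separates the two: the injected frame-120 jolt is flagged, the single-well
biological-looking spike at frame 80 is not.
"""

import numpy as np

import contractile as ct

rng = np.random.default_rng(0)
traces = {}
for w in range(9):
    v = np.abs(rng.normal(100, 1.0, size=300))
    v[120] += 80.0          # jolt: appears in every well
    if w == 4:
        v[80] += 80.0       # single-well event: well 4 only
    traces[f"w{w}"] = ct.ContractionTrace(
        values=v, frame_times_s=np.arange(300) / 3.7,
        metric_name="pv_speed", frame_delay_N=2,
    )

report = ct.detect_jolts(traces, z_thresh=5.0)
print(f"flagged jolt frames: {report.flagged_frames} (quorum {report.quorum}/9 wells)")
for f in report.flagged_frames:
    print(f"  frame {f}: wells {sorted(report.wells_affected[f])}")
mask = report.mask(300)
print(f"samples masked from downstream beat detection: {int(mask.sum())}")
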