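"""Nine-well interleaved acquisition: simulate, demultiplex, pick focus.

Nine wells are imaged in an R, G, B colour sequence, one camera frame per
(well, colour) slot, at 100 fps camera rate — so each well/colour pair is
sampled at 100/27 = 3.7 fps.  The phantom monolayer sits at the red focal
depth, so the focus report should select red in every well.
"""

import contractile as ct

cfg = ct.PhantomConfig(image_px=(48, 48), beat_rate_hz=0.25,
                       rise_tau_s=0.3, fall_tau_s=1.0, seed=11)
layout = ct.AcquisitionLayout(
    wells=tuple(f"w{i}" for i in range(9)), colours=("R", "G", "B"), camera_fps=100.0
)
print(f"effective per-well per-colour rate: {ct.effective_rate(layout):.2f} fps")

seq, truth = ct.generate_acquisition(cfg, layout, 15.0)
print(f"camera frames in 15 s: {seq.n_frames}")

stacks = ct.demux(seq, layout)
lengths = sorted({s.n_frames for s in stacks.values()})
print(f"demuxed stacks: {len(stacks)} (frames per stack: {lengths})")

report = ct.focus_report(stacks)
selected = report[report["selected"]]
print("selected colour per well:", dict(zip(selected["well"], selected["colour"])))

plan = ct.plan_two_stage(9, 5.0)
print(f"stage-2 plan: {plan['total_duration_s']:.0f} s to revisit all "
      f"{plan['n_wells']} wells at full rate in the selected colour")
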