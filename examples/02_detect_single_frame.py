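"""Detect the imaging modality, the channels and the bacteria in one frame.

Detection is purely per-frame: skewness of the intensity histogram picks
the modality, ridge filtering + Li thresholding + interior extraction
find the channels, and background subtraction + scale-space blob
filtering + watershed find the cells inside each channel.
"""

from mmscope import (
    FixtureSpec,
    compute_skewness,
    detect_bacteria,
    detect_channels,
    generate_series,
)

frames, truth = generate_series(FixtureSpec(seed=1, n_frames=1))
frame = frames[0]

report = compute_skewness(frame.primary)
print(f"skewness G1 = {report.g1:+.3f} -> {report.modality.value}")
# negative skew = mostly-bright image with sparse dark structures,
# i.e. brightfield; phase contrast would skew positive.

channels = detect_channels(frame.primary, report.modality)
print(f"{len(channels)} channels, pitch {channels.spacing_px:.1f} px "
      f"(truth: {truth.channel_labels[0].max()} channels, 40.0 px)")

bacteria = detect_bacteria(frame, channels)
print(f"{len(bacteria)} bacteria detected (truth: {len(truth.cells[0])})")
for b in bacteria.bacteria[:3]:
    print(f"  channel {b.channel_id}: cell of {b.area} px^2 at row {b.centroid[0]:.0f}")
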