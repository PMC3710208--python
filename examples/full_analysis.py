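"""Full pixel-by-pixel correlation analysis of a simulated time course.

Simulates the five-point time-course preset, writes it out as PNGs + CSV
manifest, then runs the complete pipeline: load, align to the reference,
median-normalize, correlate every pixel against hours post-irradiation
(Spearman), attach exhaustive-permutation p-values, and compose the CSD
(correlation x significance x variance) biosignature map.  Finally a
rectangular ROI over the responsive spot chain is summarized.
"""

from pathlib import Path

from gelcorr import (
    ROI,
    RunConfig,
    TestConfig,
    analyze,
    generate_stack,
    p53_timecourse,
    summarize_roi,
    write_fixture,
)

work = Path("scratch/example_analysis")
spec = p53_timecourse(seed=7)
stack, truth = generate_stack(spec)
fixture = work / "fixture"
write_fixture(stack, spec, fixture)

roi = ROI(12, 32, 80, 14)  # band covering the spot chain and streaks
config = RunConfig(
    manifest=fixture / "manifest.csv",
    variable="hours",
    alignment=fixture / "alignment.json",
    normalization="median",
    test=TestConfig(test="permutation", seed=7),
    rois=[roi],
    out_dir=work / "out",
)
maps = analyze(config)

s = summarize_roi(maps, roi).stats
print(f"output artifacts in {config.out_dir} (maps as .txt + .png, run_log.json)")
print(f"ROI x0={roi.x0} y0={roi.y0} {roi.width}x{roi.height}: "
      f"{s['rho']['count_valid']} valid pixels")
print(f"  mean rho  = {s['rho']['mean']:.3f}   (rank correlation with hours)")
print(f"  max rho   = {s['rho']['max']:.3f}")
print(f"  min p     = {s['p']['min']:.4f}  (exhaustive permutation, 5! = 120 orderings)")
print(f"  max CSD   = {s['CSD']['max']:.3f}  (correlation x significance x variance)")
# A mean rho near +1 over the ROI says intensity there rises consistently with
# time; p = 2/120 is the smallest two-sided level attainable with 5 samples.
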