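"""Generate a synthetic immunoblot time-course stack and write it to disk.

Builds the "p53_timecourse" preset — five 96x96 gel images at 0, 2, 4, 6 and
8 hours with a covariate-responsive spot chain, growing streaks, exposure
jitter, noise and known misalignments — and saves it as 16-bit PNGs plus a
CSV manifest, an alignment JSON (the correcting transforms) and a
ground-truth JSON.
"""

from pathlib import Path

from gelcorr import generate_stack, p53_timecourse, write_fixture

out_dir = Path("scratch/example_fixture")
spec = p53_timecourse(seed=7)
stack, truth = generate_stack(spec)
manifest = write_fixture(stack, spec, out_dir)

print(f"wrote fixture to {out_dir}")
print(f"manifest: {manifest}")
print(f"stack: n={stack.n} images of {stack.H}x{stack.W}, "
      f"intensities {stack.data.min():.0f}..{stack.data.max():.0f} counts")
print(f"covariate (hours): {spec.covariate_values}")
print(f"responsive pixels (>= half-max modulation): {truth.responsive_mask.sum()}")
# The responsive mask is the ground truth a correlation analysis should find;
# alignment.json holds the transforms that undo the simulated misalignments.
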