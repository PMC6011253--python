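"""Check threshold stability across magnifications.

Renders one sampled scene at 1x, 2x and 4x linear scale (emulating 10x/20x/
40x objectives) and runs the pipeline on each.  Because the threshold is
chosen from the histogram's PWM curve — a quantity independent of object
size — it should barely move while areas change 16-fold.
"""

from mana import SyntheticSpec, evaluate, run_pipeline
from mana.synthetic import render, sample_placement

spec = SyntheticSpec(image_size=(512, 512), n_nuclei=100, touching_fraction=0.0, seed=7)
placement = sample_placement(spec)

for scale in (1, 2, 4):
    rgb, annotation, _ = render(spec, placement, scale)
    result = run_pipeline(rgb)
    scores = evaluate(annotation, result.mask)
    print(
        f"scale {scale}x: image {rgb.shape[0]}x{rgb.shape[1]}, "
        f"threshold {result.initial_threshold}, "
        f"{result.n_objects} objects, F1 {scores.f1:.4f}"
    )
# Thresholds within a few gray levels and F1 within a few hundredths of
# each other demonstrate the scale-independence of the histogram-based rule.
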