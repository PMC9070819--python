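"""Train height-pair classifiers end to end and explain them with LRP.

Runs the whole pipeline at desk scale: simulate a cohort, preprocess, run
inverse dynamics, assemble the labeled adjacent-height pairs (lower height =
positive class), train a scaled-down fully connected tanh network per pair,
and back-propagate relevance with the z-rule.  The per-joint summed
contributions should track the planted effect: wrist-led for the lowest pair,
shoulder-led for the highest.
"""

from felanding import GeneratorConfig
from felanding.dnn import TrainConfig, scaled_down_config
from felanding.pipeline import PipelineConfig, run_pipeline
from felanding.synthetic import planted_truth

config = PipelineConfig(
    generator=GeneratorConfig(n_cats=12, trials_per_cat_per_height=4),
    network=scaled_down_config(),          # 600-64-64-2 tanh
    training=TrainConfig(epochs=300),
    seed=4,
)
result = run_pipeline(config)

truth = planted_truth(config.generator)
print("pair   heights    held-out acc   per-joint relevance %          planted lead")
for pid, pr in result.pairs.items():
    jp = pr.relevance.joint_pct
    lead = max(jp, key=jp.get)
    planted = max(truth[pr.heights], key=truth[pr.heights].get)
    mark = "ok" if lead == planted else "MISS"
    print(f"{pid}   {pr.heights}   {pr.test_metrics['accuracy']:.3f}        "
          f"w {jp['wrist']:.1f} / e {jp['elbow']:.1f} / s {jp['shoulder']:.1f}   "
          f"{planted} ({mark})")
print("\n(a correct run recovers the distal-to-proximal shift: the joint the")
print(" generator planted as discriminative leads the relevance table)")
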