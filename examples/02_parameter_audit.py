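"""Audit the trainable parameters of the three detector variants.

The context-augmented detector adds exactly three 544,384-parameter
modules (about +4.4%) over the plain one-stage baseline; the five-module
ablation arm adds two more.
"""

from weednet.model import ModelConfig, build_model, count_parameters

audits = {}
for variant in ("none", "p3-p5", "p3-p7"):
    model = build_model(ModelConfig(context_levels=variant))
    audits[variant] = count_parameters(model)
    print(f"context_levels={variant}")
    print(audits[variant])
    print()

single = (audits["p3-p5"].total - audits["none"].total) // 3
base_m = audits["none"].total_millions()
full_m = audits["p3-p5"].total_millions()
increase = 100 * (full_m - base_m) / base_m  # from the rounded M values, as printed
print(f"per-module overhead : {single:,} parameters")
print(f"relative increase   : {increase:.1f}% (three modules on P3-P5)")
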