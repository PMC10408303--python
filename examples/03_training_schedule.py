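"""The untuned exponential warmup x cosine annealing learning-rate curve.

The warmup factor omega(t) = 1 - exp(-(1-beta2) t) is tied to the Adam
second-momentum coefficient, so no warmup length needs tuning; the
half-cosine factor spans the whole run and anneals the rate to zero.
"""

from weednet.schedule import ScheduleConfig, lr_at, warmup_factor, warmup_period

beta2 = 0.999
cfg = ScheduleConfig(lr_init=1e-4, beta2=beta2, total_steps=8660)

print(f"beta2 = {beta2} -> warmup period = {warmup_period(beta2):.0f} steps")
print(f"omega(0)    = {warmup_factor(0, beta2):.6f}")
print(f"omega(2000) = {warmup_factor(2000, beta2):.6f}  (= 1 - e^-2)")
print()
print(f"{'step':>6} {'lr':>12}")
for t in (0, 200, 1000, 2000, 4330, 8000, 8660):
    print(f"{t:>6} {lr_at(t, cfg):>12.3e}")
# The curve rises from zero while warmup dominates, peaks, then decays to
# zero at the final step under the cosine factor.
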