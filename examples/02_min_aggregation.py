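"""Maximum-confidence aggregation of complementary scorers.

Two profile scorers are built so each is blind to one of two conserved
domains. Their elementwise-minimum aggregate takes, per variant, the most
pathogenic (most confident in the wild type) prediction, so it detects both
domains and separates pathogenic from benign variants better than either
scorer alone.
"""

from minvep import aggregate_min, model_contributions
from minvep.pipeline import blindspot_benchmark

bench = blindspot_benchmark(seed=0)
aucs = bench["aucs"]
print("variant classification AUC (benign-high orientation):")
for name in ("scorer0", "scorer1", "mean_agg", "min_agg"):
    print(f"  {name:10s} {aucs[name]:.3f}")
print("each base scorer misses one domain (AUC ~0.55-0.61); the min aggregate")
print("recovers both (AUC ~0.93) while plain averaging dilutes the signal.")

from minvep.aggregate import ScoreStack

p = bench["proteins"][0]
stack = ScoreStack(
    p.id, ["scorer0", "scorer1"],
    [bench["matrices"]["scorer0"][p.id], bench["matrices"]["scorer1"][p.id]],
)
frac = model_contributions(aggregate_min(stack))
print(f"contribution of each scorer to the minimum on {p.id}: "
      f"{frac[0]:.2f} / {frac[1]:.2f}")
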