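"""Model-summary trace: how R^2 grows as descriptors enter one by one.

Walks the published entry order (LUMO first, then 1/Vs,min, <Vs+>, <Vs>,
1/Vs,max), fitting each prefix model, and prints the classic model-summary
table; then runs an unconstrained forward stepwise selection for contrast.
"""

import espqsar as eq

table = eq.load_table1()

trace = eq.nested_model_trace(table, eq.PUBLISHED_ORDER)
print(f"{'model':<55} {'R':>6} {'R^2':>6} {'adj':>6} {'SE':>6}")
for row in trace.summary_frame().itertuples(index=False):
    print(f"{row.model:<55} {row.r:6.3f} {row.r2:6.3f} {row.r2_adj:6.3f} {row.se:6.3f}")

print()
print("Each added descriptor can only raise R^2; the adjusted R^2 and SE")
print("tell you whether the addition earned its degree of freedom.")
print()

stepwise = eq.stepwise_forward(table, eq.PUBLISHED_ORDER, p_enter=0.05, p_remove=0.10)
if stepwise.steps:
    print("forward stepwise (enter p<0.05, remove p>0.10) selected:")
    for s in stepwise.steps:
        print(f"  {s.action} {s.predictor}: R^2 = {s.model.r2:.3f}")
else:
    print("forward stepwise at p_enter=0.05 admits no descriptor on n=15 —")
    print("no single candidate reaches significance alone; the published")
    print("five-descriptor model emerges only when entry is forced.")
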