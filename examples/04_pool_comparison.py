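"""Mechanistic model versus the depletable-pool comparator.

Both models predict blunted cytokine release for closely spaced doses and
full recovery at 28 days; they differ in mechanism (T-cell state shift
versus a finite cytokine reservoir).  Prints the second/first IL6 peak
ratio of each model per dosing interval and their absolute difference.
"""

import tcesim as ts

table = ts.compare_models(ts.ParameterSet(), ts.PoolParameterSet())
print(table.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
print("\nmax |difference| across intervals:", f"{table.abs_diff.max():.3f}")
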