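"""Screen raw GPS fixes for quality.

Removes the capture night (handling effects) and imprecise fixes
(HDOP > 5 or fewer than 4 satellites), and prints the removal bookkeeping.
Both thresholds are strict: HDOP = 5.0 with 4 satellites survives.
"""

from foraykit import ForayParams, SimulationConfig, quality_filter
from foraykit.simulate import simulate_population

config = SimulationConfig(seed=11, n_territories=3, n_nights=8,
                          hdop_bad_rate=0.10, foray=ForayParams(p_per_night=0.0))
bundle = simulate_population(config, statuses=[("B01", "dominant")])

dep = bundle.deployments[0]
retained, report = quality_filter(bundle.fixes, dep)

print(f"input fixes:               {report.n_input}")
print(f"removed (capture night):   {report.removed_capture_night}")
print(f"removed (HDOP/satellites): {report.removed_quality}")
print(f"retained:                  {report.n_retained} "
      f"({report.pct_removed}% removed)")
# A fix violating both rules is counted once, under the quality rule, so
# the three counts always sum to the input size.
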