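"""Build the biased-SOA schedules and check their printed count structure.

Each design fixes the multiset of stimulus onset asynchronies (SOAs) per
block; randomness only shuffles the order.  The blocked design centres its
Gaussian-shaped count table on -80 ms (sound first) or +80 ms (light first);
the mixed designs balance the two so the block mean is exactly zero.
"""

import numpy as np

from avtoj import exp2_block, exp4_block, schedule_counts

sf = schedule_counts(1, "sound_first")
print("blocked sound-first counts:", dict(sf.counts))
print(f"  total {sf.total} trials, mean {sf.mean:+.0f} ms, SD {sf.sd:.1f} ms")

lf = schedule_counts(1, "light_first")
print(f"blocked light-first mean {lf.mean:+.0f} ms (same profile, +160 ms shift)")

block = exp2_block({"low": "sound_first", "high": "light_first"}, seed=0)
soas = [t.soa for t in block.trials]
print(f"mixed block: {len(soas)} trials, mean SOA {np.mean(soas):+.0f} ms "
      "(biases cancel exactly)")

b4 = exp4_block({"high": -235, "low": 235}, seed=0)
n_adapt = sum(t.phase == "adaptation" for t in b4.trials)
print(f"adaptation/test block: {len(b4.test_trials)} test pairs, "
      f"{n_adapt} adaptation stimuli at -235/+235 ms")
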