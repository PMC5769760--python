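"""Compare the four LWBS-prevention policies against the baseline.

Each policy is a pure transform of the scenario config (extra triage
nurse, fast track for acuity 4-5, waiting room 30->40 seats, 10% faster
staffed activities).  Scenarios share replication seeds (common random
numbers), so differences reflect the policies rather than sampling
noise.  Positive improvement percentages mean fewer walkouts / shorter
stays than baseline.  Uses 8 replications here for speed; the full
protocol uses 30.
"""

from edcasim import POLICIES, apply_policy, default_hrtn_config
from edcasim.metrics import policy_report, replicate

config = default_hrtn_config()
baseline = replicate(config, n=8, seed=1)
per_policy = {pol: replicate(apply_policy(config, pol), n=8, seed=1)
              for pol in POLICIES[1:]}

table = policy_report(baseline, per_policy)
print(table.round(2).to_string(index=False))
print("\nThe fast track dominates the LWBS reduction: the least urgent "
      "patients,\nwho otherwise wait longest, are treated right after triage.")
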