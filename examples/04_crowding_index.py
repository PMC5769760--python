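"""Watch the crowding index over one simulated day.

The engine recomputes a linear overcrowding score (0 = not busy,
200 = dangerously overcrowded) every minute from the census/bed ratio,
the waiting-room fill, and the last bed wait.  Patients' tolerance times
stretch or shrink with it.  Prints an hourly summary with the verbal
category.
"""

import numpy as np

from edcasim import crowding_category, default_hrtn_config
from edcasim.engine import Engine

config = default_hrtn_config().replace(run_length=1440, warm_up=0)
engine = Engine(config, seed=5)
engine.run()

series = np.array(engine.nedocs_series)
print("hour  mean index  category")
for hour in range(24):
    chunk = series[hour * 60:(hour + 1) * 60]
    mean = float(chunk.mean())
    print(f"{hour:4d}  {mean:10.1f}  {crowding_category(mean, config.nedocs_coeffs)}")
print(f"\nday range: {series.min():.0f}-{series.max():.0f}; "
      "evening peaks push the index up and patient patience down.")
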