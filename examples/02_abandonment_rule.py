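"""The cellular-automaton abandonment rule, piece by piece.

Shows the three ingredients of the walk-out decision: the three-bin
tolerance mixture (51% accept up to 2 h, 17% up to 8 h, 32% wait
indefinitely), the crowding adjustment (+30% patience in an idle
department, shrinking as the crowding index rises), and the
neighbour-memory rule (a patient past their tolerance leaves unless the
neighbours they remember were mostly served normally, which buys one
grace period of a tenth of the tolerance).
"""

import numpy as np

from edcasim import (effective_tolerance, extension_time, lwbs_decision,
                     neighbors, sample_tolerance)
from edcasim.ca import SeatGrid
from edcasim.config import CAParams

ca = CAParams()
rng = np.random.default_rng(0)

draws = np.array([sample_tolerance(rng, ca) for _ in range(50_000)])
print(f"tolerance mixture at n=50k: "
      f"<=120 min {np.mean(draws <= 120):.3f}, "
      f"120-480 {np.mean((draws > 120) & np.isfinite(draws)):.3f}, "
      f"infinite {np.mean(np.isinf(draws)):.3f}")

for idx in (0, 100, 200):
    print(f"crowding index {idx:>3}: a 100-min tolerance becomes "
          f"{effective_tolerance(100, idx, ca):.0f} min")

grid = SeatGrid(6, 5)
print(f"\nseat (2,2) von Neumann r=1 neighbours: {neighbors(grid, (2, 2))}")
print(f"corner (0,0) has only {len(neighbors(grid, (0, 0)))} neighbours")

print("\ndecision at the tolerance boundary (wait = adjusted tolerance = 120):")
print("  never had a neighbour          ->", lwbs_decision(120, 120, 0, 0, False, None, 120))
print("  2 delayed vs 1 normal          ->", lwbs_decision(120, 120, 2, 1, True, None, 120))
print("  1 delayed vs 1 normal (tie)    ->", lwbs_decision(120, 120, 1, 1, True, None, 120))
print("  0 delayed vs 2 normal          ->", lwbs_decision(120, 120, 0, 2, True, None, 120),
      f"(deadline would be +{extension_time(120, ca):.0f} min)")
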