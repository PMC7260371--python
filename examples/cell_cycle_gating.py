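"""Cell-cycle gating from integrated nuclear intensity.

Integrated Hoechst intensity is proportional to DNA content, so 2N and 4N
cells form log2-intensity modes one unit apart. This script samples a
population with known phase fractions (as after a G2/M-arresting drug),
fits the constrained mixture, and compares recovered vs true fractions.
"""

import numpy as np

from mitoflux import NucleusRecord, classify_cell_cycle
from mitoflux.simulate import sample_nucleus_population

true_fractions = {"G1": 0.40, "S": 0.15, "G2M": 0.36, "gt4N": 0.09}
rng = np.random.default_rng(4)
phases, intensities = sample_nucleus_population(true_fractions, 2000,
                                                i0=5e5, cv=0.07, rng=rng)
records = [NucleusRecord(i + 1, (0.0, 0.0), 80.0, v)
           for i, v in enumerate(intensities)]

res = classify_cell_cycle(records)
print(f"fitted 2N mode at log2 intensity {res.mu1:.3f} "
      f"(sigmas {res.sigma1:.3f}/{res.sigma2:.3f})")
print(f"{'phase':>6} {'true':>6} {'recovered':>10}")
for ph in ("G1", "S", "G2M", "gt4N"):
    print(f"{ph:>6} {true_fractions[ph]:6.3f} {res.phase_fractions[ph]:10.3f}")
print("-> each phase fraction is recovered to a few percent; the G2M+>4N")
print("   excess is the arrest signature a dose series would track.")
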