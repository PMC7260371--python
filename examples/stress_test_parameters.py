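"""Mito Stress Test parameter derivation.

Builds the canonical four-phase OCR profile (basal 100, post-oligomycin 40,
post-FCCP 150, post-rotenone/antimycin 10) and derives the bioenergetic
partition. The identity basal = ATP-linked + proton leak holds exactly.
"""

from mitoflux import annotate_injections, stress_test_parameters
from mitoflux.xf_io import Measurement, RateSeries

values = [100.0] * 3 + [40.0] * 3 + [150.0] * 3 + [10.0] * 3
series = RateSeries("C3", [
    Measurement(i + 1, (i + 1) * 6.5, v, 20.0) for i, v in enumerate(values)
])
series = annotate_injections(series, "mito_stress_test")
p = stress_test_parameters(series)

print(f"non-mitochondrial OCR : {p.nonmito:6.1f} pmol O2/min")
print(f"basal respiration     : {p.basal_resp:6.1f}")
print(f"  ATP-linked          : {p.atp_linked:6.1f}")
print(f"  proton leak         : {p.proton_leak:6.1f}")
print(f"maximal respiration   : {p.maximal:6.1f}")
print(f"spare capacity        : {p.spare_capacity:6.1f}")
print("-> oligomycin isolates ATP synthesis, FCCP reveals the ceiling, and")
print("   rotenone/antimycin A measures the non-mitochondrial floor.")
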