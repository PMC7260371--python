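"""Mito-stress-test bioenergetic parameters.

The sequential-poison protocol partitions respiration: oligomycin blocks
ATP synthase (remaining OCR = proton leak + non-mitochondrial), FCCP
uncouples the membrane (maximal respiration), and rotenone/antimycin A
shut down the electron transport chain (non-mitochondrial OCR).  The
standard vendor conventions are used by default — the *last* basal
measurement, the *minimum* of the post-oligomycin and post-rotenone/AA
phases, the *maximum* of the post-FCCP phase — with a phase-mean
alternative available.

Derived parameters (all in the units of the input series, so they are
equivariant under normalization):

======================  =================================================
non-mitochondrial       min of the post-rotenone/antimycin phase
basal respiration       last basal measurement − non-mitochondrial
ATP-linked              last basal − min post-oligomycin
proton leak             min post-oligomycin − non-mitochondrial
maximal respiration     max post-FCCP − non-mitochondrial
spare capacity          maximal − basal respiration
======================  =================================================

``basal = atp_linked + proton_leak`` holds exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ProtocolError
from .xf_io import Agent, RateSeries


@dataclass(frozen=True)
class StressTestParams:
    nonmito: float
    basal_resp: float
    atp_linked: float
    proton_leak: float
    maximal: float
    spare_capacity: float
    flags: frozenset[str] = frozenset()


def _phase_indices(series: RateSeries) -> tuple[slice, slice, slice, slice]:
    order = [Agent.OLIGOMYCIN, Agent.FCCP, Agent.ROTENONE_ANTIMYCIN]
    cuts = []
    for agent in order:
        inj = series.injection_after(agent)
        if inj is None:
            raise ProtocolError(f"well {series.well_id}: missing {agent.value} injection")
        cuts.append(inj.after_index)
    if cuts != sorted(cuts):
        raise ProtocolError(f"well {series.well_id}: poison injections out of order")
    n = len(series.measurements)
    o, f, r = cuts
    phases = (slice(0, o), slice(o, f), slice(f, r), slice(r, n))
    names = ("basal", "post-oligomycin", "post-FCCP", "post-rotenone/antimycin")
    for sl, name in zip(phases, names):
        if sl.stop - sl.start < 1:
            raise ProtocolError(f"well {series.well_id}: empty {name} phase")
    return phases


def stress_test_parameters(
    series: RateSeries, convention: str = "extremum"
) -> StressTestParams:
    """Derive the stress-test parameters from an annotated series.

    Negative derived values (e.g. spare capacity after an FCCP overdose
    collapses respiration) are returned but flagged
    ``negative_parameter`` as a possible injection failure.
    """
    if convention not in ("extremum", "phase_mean"):
        raise ValueError(f"unknown convention {convention!r}")
    basal_sl, oligo_sl, fccp_sl, rot_sl = _phase_indices(series)
    ocr = np.asarray(series.ocr, dtype=float)
    if convention == "extremum":
        basal_ref = float(ocr[basal_sl][-1])    # last pre-oligomycin measurement
        oligo_val = float(ocr[oligo_sl].min())
        fccp_val = float(ocr[fccp_sl].max())
        nonmito = float(ocr[rot_sl].min())
    else:
        basal_ref = float(ocr[basal_sl].mean())
        oligo_val = float(ocr[oligo_sl].mean())
        fccp_val = float(ocr[fccp_sl].mean())
        nonmito = float(ocr[rot_sl].mean())

    atp_linked = basal_ref - oligo_val
    proton_leak = oligo_val - nonmito
    basal_resp = atp_linked + proton_leak   # identity holds exactly
    maximal = fccp_val - nonmito
    spare = maximal - basal_resp
    values = (nonmito, basal_resp, atp_linked, proton_leak, maximal, spare)
    flags = frozenset({"negative_parameter"} if any(v < 0 for v in values) else set())
    return StressTestParams(
        nonmito=nonmito,
        basal_resp=basal_resp,
        atp_linked=atp_linked,
        proton_leak=proton_leak,
        maximal=maximal,
        spare_capacity=spare,
        flags=flags,
    )
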