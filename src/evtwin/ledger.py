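"""Process-level bookkeeping: recovery chains, EV purity, DNA per dose.

Works on :class:`~evtwin.streams.StreamState` intermediates or plain step
tables.  Cumulative removals are computed from stream *masses*
(concentration × volume) rather than by multiplying per-step removal
fractions, because volume changes between steps make the naive product
convention disagree with the mass balance; both conventions are reported,
labelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from evtwin.streams import StreamState

#: regulatory limits for cell & gene therapy products (strict "<")
DNA_LIMIT_NG_PER_DOSE = 10.0
PROTEIN_LIMIT_UG_PER_ML = 100.0


@dataclass
class DoseSpec:
    """Dose definition: number of EV particles per administered dose."""

    particles_per_dose: float = 1e10

    def __post_init__(self) -> None:
        if self.particles_per_dose <= 0:
            raise ValueError("dose must be positive")


@dataclass
class LedgerStep:
    """One process step with its input/output streams."""

    name: str
    stream_in: StreamState
    stream_out: StreamState

    @property
    def recovery(self) -> float:
        m = self.stream_in.particle_mass
        return self.stream_out.particle_mass / m if m > 0 else 1.0

    @property
    def protein_removal(self) -> float:
        m = self.stream_in.protein_mass_ug
        return 1.0 - self.stream_out.protein_mass_ug / m if m > 0 else 0.0

    @property
    def dna_removal(self) -> float:
        m = self.stream_in.dna_mass_ng
        return 1.0 - self.stream_out.dna_mass_ng / m if m > 0 else 0.0


def chain_recovery(recoveries: Iterable[float]) -> float:
    """Overall recovery of a step chain: the product of step recoveries."""
    out = 1.0
    for r in recoveries:
        if not (0.0 <= r <= 1.0):
            raise ValueError(f"recovery {r} outside [0, 1]")
        out *= r
    return out


def ev_purity(particles_per_ml: float, protein_ug_ml: float) -> float:
    """EV purity in particles per mg total protein."""
    if protein_ug_ml <= 0:
        raise ValueError("protein concentration must be positive")
    if particles_per_ml < 0:
        raise ValueError("particle concentration must be non-negative")
    return particles_per_ml / (protein_ug_ml * 1e-3)


def dna_per_dose(dna_ng_ml: float, particles_per_ml: float,
                 dose: DoseSpec = DoseSpec()) -> float:
    """dsDNA co-administered with one dose, in ng/dose."""
    if particles_per_ml <= 0:
        raise ValueError("particle concentration must be positive")
    if dna_ng_ml < 0:
        raise ValueError("DNA concentration must be non-negative")
    return dna_ng_ml * dose.particles_per_dose / particles_per_ml


def threshold_check(state: StreamState, dose: DoseSpec = DoseSpec()) -> dict:
    """Check the pool against the regulatory limits (strict '<')."""
    dna = dna_per_dose(state.dna_ng_ml, state.particles_per_ml, dose)
    return {
        "dna_ng_per_dose": dna,
        "dna_pass": dna < DNA_LIMIT_NG_PER_DOSE,
        "protein_ug_per_ml": state.protein_ug_ml,
        "protein_pass": state.protein_ug_ml < PROTEIN_LIMIT_UG_PER_ML,
    }


def run_ledger(steps: Sequence[LedgerStep],
               dose: DoseSpec = DoseSpec()) -> dict:
    """Summarise a step chain: cumulative recovery and impurity removal.

    Cumulative recovery is the product of step recoveries; cumulative
    removals come from the mass balance 1 − mass_final/mass_initial (and the
    naive fraction product is reported alongside for comparison).
    """
    if not steps:
        raise ValueError("need at least one step")
    for a, b in zip(steps, steps[1:]):
        if not np.isclose(a.stream_out.volume_ml, b.stream_in.volume_ml,
                          rtol=1e-6):
            raise ValueError(
                f"volume mismatch between steps {a.name!r} and {b.name!r}")

    rows = []
    cum_rec = 1.0
    for s in steps:
        cum_rec *= s.recovery
        rows.append({
            "step": s.name,
            "recovery": s.recovery,
            "protein_removal": s.protein_removal,
            "dna_removal": s.dna_removal,
            "cumulative_recovery": cum_rec,
        })
    first_in, last_out = steps[0].stream_in, steps[-1].stream_out
    mass_prot0 = first_in.protein_mass_ug
    mass_dna0 = first_in.dna_mass_ng
    summary = {
        "steps": pd.DataFrame(rows),
        "overall_recovery": cum_rec,
        "protein_removal_mass": 1.0 - last_out.protein_mass_ug / mass_prot0
        if mass_prot0 > 0 else 0.0,
        "dna_removal_mass": 1.0 - last_out.dna_mass_ng / mass_dna0
        if mass_dna0 > 0 else 0.0,
        "protein_removal_fraction_product":
            1.0 - float(np.prod([1.0 - s.protein_removal for s in steps])),
        "dna_removal_fraction_product":
            1.0 - float(np.prod([1.0 - s.dna_removal for s in steps])),
        "final_purity_particles_per_mg":
            ev_purity(last_out.particles_per_ml, last_out.protein_ug_ml)
            if last_out.protein_ug_ml > 0 else float("inf"),
        "final_dna_ng_per_dose":
            dna_per_dose(last_out.dna_ng_ml, last_out.particles_per_ml, dose)
            if last_out.particles_per_ml > 0 else 0.0,
        "thresholds": threshold_check(last_out, dose)
        if last_out.particles_per_ml > 0 else None,
    }
    return summary
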