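"""Operating-parameter grid scans over the calibrated chromatography model.

Each grid cell runs one full method simulation with a fixed, CV-based
pooling rule (the collection window scales with flow, mirroring
fraction-based pooling), then reports productivity and pool impurity
responses.  Productivity is pooled product per mL packed bed per hour of
total cycle time (including wash/CIP/re-equilibration); this common
convention is configurable through the response function.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from evtwin.chromatography import (ColumnSystem, MethodProgram, MethodStep,
                                   simulate_chromatography)
from evtwin.ledger import DoseSpec, dna_per_dose


@dataclass
class OperatingPoint:
    """One candidate operating point of a chromatography step."""

    flow_ml_min: float
    feed_volume_cv: float
    gradient_length_cv: float = 20.0
    wash_modifier_mM: float = 0.0

    def __post_init__(self) -> None:
        if min(self.flow_ml_min, self.feed_volume_cv,
               self.gradient_length_cv) <= 0:
            raise ValueError("operating parameters must be positive")
        if self.wash_modifier_mM < 0:
            raise ValueError("wash modifier must be non-negative")

    def replace(self, **kw) -> "OperatingPoint":
        from dataclasses import replace as _r
        return _r(self, **kw)


AXES = ("flow_ml_min", "feed_volume_cv", "gradient_length_cv",
        "wash_modifier_mM")


@dataclass
class ResponseSurface:
    """Productivity/impurity responses over a 2-D operating grid."""

    axis_names: tuple[str, str]
    axis_values: tuple[np.ndarray, np.ndarray]
    productivity: np.ndarray            # particles/(mL·h)
    pool_protein: np.ndarray            # µg/mL in pool
    pool_dna: np.ndarray                # ng/mL in pool
    pool_recovery: np.ndarray           # fraction of injected product
    pool_particles: np.ndarray          # particles/mL in pool
    metadata: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)

    def to_long(self) -> pd.DataFrame:
        a, b = self.axis_values
        rows = []
        for i, va in enumerate(a):
            for j, vb in enumerate(b):
                rows.append({
                    self.axis_names[0]: va, self.axis_names[1]: vb,
                    "productivity": self.productivity[i, j],
                    "pool_protein_ug_ml": self.pool_protein[i, j],
                    "pool_dna_ng_ml": self.pool_dna[i, j],
                    "pool_recovery": self.pool_recovery[i, j],
                    "pool_particles_per_ml": self.pool_particles[i, j],
                })
        return pd.DataFrame(rows)


def productivity(pool_particles: float, column_volume_ml: float,
                 cycle_time_h: float) -> float:
    """Pooled product per mL packed bed per hour of total cycle."""
    if column_volume_ml <= 0 or cycle_time_h <= 0:
        raise ValueError("column volume and cycle time must be positive")
    return pool_particles / (column_volume_ml * cycle_time_h)


@dataclass
class ScanModel:
    """Bundle of calibrated column + method template used by the scans.

    ``program_builder(point) -> MethodProgram`` constructs the method for an
    operating point; ``pool_window_cv`` is the collection window, in CV from
    the start of the elution (or flow-through) section named
    ``pool_from_step``.
    """

    system: ColumnSystem
    program_builder: Callable[[OperatingPoint], MethodProgram]
    pool_window_cv: tuple[float, float]
    pool_from_step: str                  # step kind marking the window origin
    product: str
    protein: str | None = None
    dna: str | None = None
    n_cells: int = 60

    def run_point(self, point: OperatingPoint) -> dict:
        program = self.program_builder(point)
        res = simulate_chromatography(self.system, program,
                                      n_cells=self.n_cells)
        chrom = res.chromatogram
        V = self.system.geometry.volume_ml
        # locate the pooling window: CV offsets from the start of the
        # reference step, converted to time at this flow rate
        t0 = 0.0
        found = False
        for s in program.steps:
            if s.kind == self.pool_from_step and not found:
                found = True
                break
            t0 += s.duration_cv * V / s.flow_ml_min
        if not found:
            raise ValueError(f"no {self.pool_from_step!r} step in program")
        w0, w1 = self.pool_window_cv
        ta = t0 + w0 * V / point.flow_ml_min
        tb = t0 + w1 * V / point.flow_ml_min
        t = chrom["time_min"].to_numpy()
        flow = chrom["flow_ml_min"].to_numpy()
        mask = (t >= ta) & (t <= tb)
        if mask.sum() < 2:
            raise ValueError("pool window contains no simulated samples")
        tw = t[mask]
        pool_vol = float(np.trapezoid(flow[mask], tw))

        def pooled(nm):
            return float(np.trapezoid(chrom[nm].to_numpy()[mask] * flow[mask], tw))

        prod_amt = pooled(self.product)
        injected = res.injected[self.product]
        cycle_h = (program.total_cv() * V / point.flow_ml_min) / 60.0
        return {
            "productivity": productivity(prod_amt, V, cycle_h),
            "pool_particles_per_ml": prod_amt / pool_vol,
            "pool_protein_ug_ml": pooled(self.protein) / pool_vol if self.protein else 0.0,
            "pool_dna_ng_ml": pooled(self.dna) / pool_vol if self.dna else 0.0,
            "pool_recovery": prod_amt / injected if injected > 0 else 0.0,
            "pool_volume_ml": pool_vol,
            "cycle_time_h": cycle_h,
        }


def scan_surface(model: ScanModel,
                 axes: Mapping[str, Sequence[float]],
                 fixed: OperatingPoint) -> ResponseSurface:
    """Run the model over a 2-D operating grid.

    ``axes`` maps exactly two of ``flow_ml_min, feed_volume_cv,
    gradient_length_cv, wash_modifier_mM`` to their grid values; the other
    parameters come from ``fixed``.  A failing cell is recorded with its
    coordinates and the scan continues.
    """
    if len(axes) != 2:
        raise ValueError("exactly two scan axes required")
    for name in axes:
        if name not in AXES:
            raise ValueError(f"unknown axis {name!r}")
    (na, va), (nb, vb) = axes.items()
    va = np.asarray(va, dtype=float)
    vb = np.asarray(vb, dtype=float)
    shape = (va.size, vb.size)
    grids = {k: np.full(shape, np.nan) for k in
             ("productivity", "pool_protein", "pool_dna", "pool_recovery",
              "pool_particles")}
    failures = []
    for (i, x), (j, y) in itertools.product(enumerate(va), enumerate(vb)):
        point = fixed.replace(**{na: float(x), nb: float(y)})
        try:
            out = model.run_point(point)
        except (RuntimeError, ValueError) as exc:
            failures.append({"cell": (i, j), na: x, nb: y, "error": str(exc)})
            continue
        grids["productivity"][i, j] = out["productivity"]
        grids["pool_protein"][i, j] = out["pool_protein_ug_ml"]
        grids["pool_dna"][i, j] = out["pool_dna_ng_ml"]
        grids["pool_recovery"][i, j] = out["pool_recovery"]
        grids["pool_particles"][i, j] = out["pool_particles_per_ml"]
    return ResponseSurface(
        axis_names=(na, nb), axis_values=(va, vb),
        productivity=grids["productivity"],
        pool_protein=grids["pool_protein"],
        pool_dna=grids["pool_dna"],
        pool_recovery=grids["pool_recovery"],
        pool_particles=grids["pool_particles"],
        metadata={"pool_window_cv": model.pool_window_cv,
                  "pool_from_step": model.pool_from_step,
                  "fixed": fixed},
        failures=failures,
    )


def constrained_optimum(surface: ResponseSurface,
                        max_pool_protein_ug_ml: float = 100.0,
                        max_dna_ng_per_dose: float = 10.0,
                        dose: DoseSpec = DoseSpec()) -> dict:
    """Pick the highest-productivity feasible cell of a response surface.

    Feasibility: pool protein below the concentration limit and pool DNA
    per dose below the dose limit (strict '<').  Ties break toward lower
    feed volume, then lower flow rate; an empty feasible set yields an
    infeasibility report rather than an exception.
    """
    a, b = surface.axis_values
    feasible = []
    for i, j in itertools.product(range(a.size), range(b.size)):
        p = surface.productivity[i, j]
        if not np.isfinite(p):
            continue
        prot_ok = surface.pool_protein[i, j] < max_pool_protein_ug_ml
        part = surface.pool_particles[i, j]
        if part > 0:
            dna_dose = dna_per_dose(surface.pool_dna[i, j], part, dose)
        else:
            dna_dose = 0.0
        dna_ok = dna_dose < max_dna_ng_per_dose
        if prot_ok and dna_ok:
            feasible.append((i, j, p, dna_dose))
    if not feasible:
        return {"feasible": False, "reason": "no grid cell satisfies the "
                "purity constraints", "n_cells": int(a.size * b.size)}

    def tiebreak(entry):
        i, j, p, _ = entry
        coords = dict(zip(surface.axis_names, (a[i], b[j])))
        feed = coords.get("feed_volume_cv", 0.0)
        flow = coords.get("flow_ml_min", 0.0)
        return (-p, feed, flow)

    i, j, p, dna_dose = min(feasible, key=tiebreak)
    point = {surface.axis_names[0]: float(a[i]),
             surface.axis_names[1]: float(b[j])}
    return {"feasible": True, "point": point, "indices": (i, j),
            "productivity": float(p),
            "pool_protein_ug_ml": float(surface.pool_protein[i, j]),
            "pool_dna_ng_per_dose": float(dna_dose),
            "pool_recovery": float(surface.pool_recovery[i, j])}
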