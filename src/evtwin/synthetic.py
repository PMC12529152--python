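"""Synthetic dataset generators with known ground truth.

Every generator wraps the corresponding forward simulator and applies a
measurement-noise model typical of the offline assays (NTA/MALS particle
counts, BCA total protein, PicoGreen dsDNA, trypan-blue VCD): multiplicative
lognormal by default, since concentration assays are strictly positive.
Zero-CV generation is bit-identical to the deterministic simulator, and the
same seed always reproduces the same dataset.

Default CVs (stand-ins; assay-level error models are configurable):
particles 0.10, protein 0.05, DNA 0.05, VCD 0.10, glucose/lactate 0.03,
flux 0.02.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from evtwin import chromatography as chrom_mod
from evtwin import cultivation as cult
from evtwin import ufdf as ufdf_mod

DEFAULT_CV = {
    "particles": 0.10, "protein": 0.05, "dna": 0.05,
    "vcd": 0.10, "glucose": 0.03, "lactate": 0.03, "flux": 0.02,
}


@dataclass
class NoiseSpec:
    """Measurement-noise model of one assay."""

    assay: str = "generic"
    cv: float = 0.0
    replicates: int = 1
    distribution: str = "lognormal"   # "lognormal" | "gaussian"

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("CV must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")
        if self.distribution not in ("lognormal", "gaussian"):
            raise ValueError("distribution must be 'lognormal' or 'gaussian'")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Noisy replicates, shape ``(replicates, *values.shape)``.

        Lognormal noise is mean-preserving: factor = exp(N(-s²/2, s²)) with
        s² = ln(1 + CV²) so that E[factor] = 1 and SD[factor] = CV.
        """
        values = np.asarray(values, dtype=float)
        shape = (self.replicates, *values.shape)
        if self.distribution == "lognormal":
            s2 = np.log1p(self.cv ** 2)
            factors = np.exp(rng.normal(-s2 / 2.0, np.sqrt(s2), size=shape))
            return values[None, ...] * factors
        noise = rng.normal(0.0, self.cv, size=shape)
        return values[None, ...] * (1.0 + noise)


@dataclass
class GroundTruthBundle:
    """The generating truth carried alongside each synthetic dataset."""

    kinetic_params: dict | None = None
    schedule: cult.PhaseSchedule | None = None
    initial_state: cult.CultureState | None = None
    fouling_fit: ufdf_mod.FoulingFit | None = None
    j0: float | None = None
    column_system: chrom_mod.ColumnSystem | None = None
    program: chrom_mod.MethodProgram | None = None
    noise: dict = field(default_factory=dict)
    seed: int | None = None


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed))


def gen_cultivation_dataset(params: Mapping[str, cult.KineticParams],
                            schedule: cult.PhaseSchedule,
                            init: cult.CultureState,
                            noise: Mapping[str, NoiseSpec] | None = None,
                            seed: int = 0,
                            t_out: Sequence[float] | None = None
                            ) -> tuple[pd.DataFrame, GroundTruthBundle]:
    """Noisy cultivation trajectory (daily sampling by default).

    ``noise`` maps trajectory variables (``vcd_e6_per_ml``, ``glc_mM``,
    ``lac_mM``, ``product_mM``) to :class:`NoiseSpec`; missing variables
    use the default assay CVs.  With all CVs zero the output equals
    :func:`evtwin.cultivation.simulate_cultivation` exactly (replicate 1).
    """
    clean = cult.simulate_cultivation(init, schedule, params, t_out=t_out)
    if noise is None:
        noise = {
            "vcd_e6_per_ml": NoiseSpec("vcd", DEFAULT_CV["vcd"]),
            "glc_mM": NoiseSpec("glucose", DEFAULT_CV["glucose"]),
            "lac_mM": NoiseSpec("lactate", DEFAULT_CV["lactate"]),
            "product_mM": NoiseSpec("nta", DEFAULT_CV["particles"]),
        }
    rng = _rng(seed)
    frames = []
    max_rep = max((n.replicates for n in noise.values()), default=1)
    for rep in range(max_rep):
        df = clean.copy()
        df["replicate"] = rep + 1
        frames.append(df)
    noisy = pd.concat(frames, ignore_index=True)
    for col in ("vcd_e6_per_ml", "glc_mM", "lac_mM", "product_mM"):
        spec = noise.get(col)
        if spec is None:
            continue
        vals = spec.apply(clean[col].to_numpy(), rng)   # (reps, nt)
        for rep in range(max_rep):
            sel = noisy["replicate"] == rep + 1
            noisy.loc[sel, col] = vals[min(rep, spec.replicates - 1)]
    noisy["particles_per_ml"] = cult.particles_from_product(
        noisy["product_mM"].to_numpy())
    truth = GroundTruthBundle(kinetic_params=dict(params), schedule=schedule,
                              initial_state=init,
                              noise={k: v for k, v in noise.items()},
                              seed=seed)
    return noisy, truth


def default_flux_grid(v_end: float, n_points: int = 400,
                      v_min: float = 1e-4) -> np.ndarray:
    """Sampling grid refined near v = 0, where blocking decay is steepest.

    ``v_min`` is the first non-zero sample (absolute, L/m²): the initial
    decay scale 1/(K_n J0^(2-n)) does not grow with the span, so the
    refinement must not either.
    """
    return np.concatenate([[0.0], np.geomspace(v_min, v_end, n_points - 1)])


def gen_flux_dataset(segments: Sequence[ufdf_mod.FoulingSegment],
                     j0: float,
                     noise: NoiseSpec | None = None,
                     seed: int = 0,
                     v_grid: np.ndarray | None = None
                     ) -> tuple[pd.DataFrame, GroundTruthBundle]:
    """Noisy flux-decline series from stitched blocking-law segments.

    Spans must be contiguous and increasing; in the noiseless case the
    series is strictly decreasing (for K_n > 0) and continuous at the
    changepoints.
    """
    segments = list(segments)
    if j0 <= segments[0].J_R:
        raise ValueError("no flux decline possible: J0 <= first segment J_R")
    fit = ufdf_mod.FoulingFit(segments)
    if v_grid is None:
        v_end = segments[-1].v_end
        if not np.isfinite(v_end):
            v_end = max(segments[-1].v_start * 2.0, 20.0)
        v_grid = default_flux_grid(v_end)
    series = ufdf_mod.simulate_flux(j0, fit, np.asarray(v_grid, dtype=float))
    if noise is None:
        noise = NoiseSpec("flux", 0.0)
    rng = _rng(seed)
    vals = noise.apply(series["flux_LMH"].to_numpy(), rng)
    frames = []
    for rep in range(noise.replicates):
        df = series.copy()
        df["flux_LMH"] = vals[rep]
        df["replicate"] = rep + 1
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    truth = GroundTruthBundle(fouling_fit=fit, j0=j0,
                              noise={"flux": noise}, seed=seed)
    return out, truth


def gen_chromatography_dataset(system: chrom_mod.ColumnSystem,
                               program: chrom_mod.MethodProgram,
                               noise: Mapping[str, NoiseSpec] | None = None,
                               seed: int = 0,
                               fraction_volume_ml: float = 1.5,
                               n_cells: int = 60
                               ) -> tuple[chrom_mod.ChromatographyResult,
                                          pd.DataFrame, GroundTruthBundle]:
    """Simulated chromatogram plus a noisy fraction-assay table.

    Fraction assay values are the noiseless fraction integrals times
    multiplicative noise; with zero CV the table equals the quadrature of
    the simulated outlet profile exactly.
    """
    res = chrom_mod.simulate_chromatography(system, program, n_cells=n_cells)
    fractions = chrom_mod.fractionate(res.chromatogram, fraction_volume_ml)
    if noise is None:
        noise = {nm: NoiseSpec(nm, 0.0) for nm in system.transport.names}
    rng = _rng(seed)
    noisy = fractions.copy()
    for nm in system.transport.names:
        spec = noise.get(nm)
        if spec is None or f"{nm}_conc" not in noisy.columns:
            continue
        vals = spec.apply(fractions[f"{nm}_conc"].to_numpy(), rng)
        noisy[f"{nm}_conc"] = vals.mean(axis=0)  # replicate mean, as assayed
        noisy[f"{nm}_amount"] = noisy[f"{nm}_conc"] * noisy["volume_ml"]
    truth = GroundTruthBundle(column_system=system, program=program,
                              noise=dict(noise), seed=seed)
    return res, noisy, truth
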