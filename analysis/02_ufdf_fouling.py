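#!/usr/bin/env python
"""Identify the fouling mechanism from a two-regime flux series and run UFDF.

Generates the flux-decline curve from the identified constants (intermediate
pore blocking to ~11 L/m², then cake filtration), runs the integral-method
identifier on it to confirm the changepoint and both parameter sets, then
simulates the 2.2×-concentrate / 5-DV-diafilter / 2.2×-concentrate train
with sieving coefficients calibrated to the measured protein (70.8%) and
DNA (77.1%) removals.

Writes: results/ufdf_flux.csv, results/ufdf_fouling_fit.json,
        results/ufdf_step_report.json
"""

import json
import math
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from evtwin import io as evio
from evtwin import ufdf
from evtwin.streams import StreamState
from evtwin.synthetic import default_flux_grid

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    truth = ufdf.FoulingFit([
        ufdf.FoulingSegment(n=1.0, K_n=0.18175, J_R=15.995,
                            v_start=0.0, v_end=11.0),
        ufdf.FoulingSegment(n=0.0, K_n=0.00195, J_R=20.0513,
                            v_start=11.0, v_end=math.inf)])
    grid = default_flux_grid(50.0, n_points=500)
    series = ufdf.simulate_flux(89.9, truth, grid)
    evio.write_flux_series(series, OUT / "ufdf_flux.csv")

    fit = ufdf.identify_fouling(series)
    fit_report = {
        "changepoint_Lm2": fit.changepoint_v,
        "segments": [{"n": s.n, "K_n": s.K_n, "J_R": s.J_R,
                      "r_squared": s.r_squared} for s in fit.segments],
    }
    print(f"identified changepoint at {fit.changepoint_v:.2f} L/m2")
    for s in fit.segments:
        mech = {0.0: "cake", 1.0: "intermediate", 1.5: "standard",
                2.0: "complete"}[s.n]
        print(f"  n={s.n} ({mech}): K_n={s.K_n:.5f}, J_R={s.J_R:.3f}, "
              f"R2={s.r_squared:.4f}")
    with open(OUT / "ufdf_fouling_fit.json", "w") as fh:
        json.dump(fit_report, fh, indent=2)

    # UFDF train on the depth-filtered harvest; sieving calibrated so the
    # full train reproduces the measured removals
    s_protein = ufdf.solve_sieving_for_removal(0.708, 2.2, 5.0, 2.2)
    s_dna = ufdf.solve_sieving_for_removal(0.771, 2.2, 5.0, 2.2)
    cfg = ufdf.UFDFConfig(membrane_area_cm2=115.0, vcf1=2.2, dv=5.0,
                          vcf2=2.2, tmp_bar=0.34,
                          sieving={"particles": 0.0, "protein": s_protein,
                                   "dna": s_dna})
    feed = StreamState(volume_ml=582.0, particles_per_ml=0.6e10,
                       protein_ug_ml=97.8, dna_ng_ml=233.0)
    out = ufdf.simulate_ufdf(feed, cfg, fit=fit, j0=89.9)
    rep = out["report"]
    rep["sieving_protein"] = s_protein
    rep["sieving_dna"] = s_dna
    print(f"sieving: protein {s_protein:.4f}, dna {s_dna:.4f}")
    print(f"UFDF: recovery {rep['recovery']:.1%}, protein removal "
          f"{rep['protein_removal']:.1%}, DNA removal {rep['dna_removal']:.1%}")
    print(f"average flux {rep['average_flux_LMH']:.1f} LMH over "
          f"{rep['process_time_h']:.2f} h")
    evio.write_report(rep, OUT / "ufdf_step_report.json")


if __name__ == "__main__":
    main()
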