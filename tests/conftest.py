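"""Shared fixtures: reference kinetic sets, column systems, method programs."""

import numpy as np
import pytest
from hypothesis import settings

from evtwin import cultivation as cult
from evtwin.chromatography import (ColumnGeometry, ColumnSystem,
                                   ComponentTransport, IsothermParams,
                                   MethodProgram, MethodStep)

settings.register_profile("ci", deadline=None, max_examples=25,
                          derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def growth_schedule():
    return cult.PhaseSchedule(growth_span_h=120.0, collect_span_h=0.0,
                              feed_time_h=None)


@pytest.fixture(scope="session")
def collect_schedule():
    return cult.PhaseSchedule(growth_span_h=0.0, collect_span_h=120.0,
                              feed_time_h=None)


@pytest.fixture(scope="session")
def growth_init():
    return cult.CultureState(vcd=0.02, glc=25.0, lac=0.0, p=0.0)


@pytest.fixture(scope="session")
def collect_init():
    return cult.CultureState(vcd=0.35, glc=25.0, lac=0.0, p=0.0)


@pytest.fixture(scope="session")
def one_ml_column():
    # ~1 mL bed, dimensions of a typical prepacked screening column
    return ColumnGeometry(length_cm=2.5, diameter_cm=0.714,
                          bead_diameter_um=50.0)


@pytest.fixture(scope="session")
def tracer_system(one_ml_column):
    """Single non-binding, non-porous tracer for moment analysis."""
    tr = ComponentTransport(names=["tracer"], eps_tot=[0.75], eps_s=[0.0],
                            D_ax=[0.1], k_eff=[0.0])
    iso = IsothermParams(q_max=[0.0], K0=[0.0], beta=[0.0], k_kin=[0.0])
    return ColumnSystem(one_ml_column, tr, iso)


@pytest.fixture(scope="session")
def aex_system(one_ml_column):
    """Three-component AEX world: EVs elute mid-gradient, protein mostly
    flows through, DNA binds strongly and elutes late."""
    tr = ComponentTransport(
        names=["ev", "protein", "dna"],
        eps_tot=[0.45, 0.70, 0.65],
        eps_s=[0.30, 0.50, 0.60],
        D_ax=[0.08, 0.05, 0.06],
        k_eff=[0.01, 0.005, 0.004],
    )
    # Henry coefficients at the 50 mM load salt: ev 60, protein 2, dna 100
    iso = IsothermParams(
        q_max=np.array([1.2e12, 1.3e3, 2.0e4]),
        K0=np.array([5e-11 * 50.0 ** 3, 1.5e-3 * 50.0 ** 2,
                     5e-3 * 50.0 ** 2.5]),
        beta=np.array([3.0, 2.0, 2.5]),
        k_kin=np.array([2.0, 2.0, 1.0]),
    )
    return ColumnSystem(one_ml_column, tr, iso)


def aex_program(flow=1.0, feed_cv=5.0, gradient_cv=20.0, wash_mod=50.0,
                load={"ev": 1e10, "protein": 100.0, "dna": 150.0},
                grad_end=1000.0):
    return MethodProgram([
        MethodStep("equilibrate", 2.0, flow, mod_start_mM=50.0),
        MethodStep("load", feed_cv, flow, inlet=dict(load), mod_start_mM=50.0),
        MethodStep("wash", 4.0, flow, mod_start_mM=wash_mod),
        MethodStep("gradient", gradient_cv, flow, mod_start_mM=wash_mod,
                   mod_end_mM=grad_end),
        MethodStep("cip", 4.0, flow, mod_start_mM=grad_end),
    ])


@pytest.fixture(scope="session")
def mmsec_system(one_ml_column):
    """Multimodal SEC: large EVs are excluded and flow through; protein and
    DNA enter the pores, protein binds the core ligand (isocratic)."""
    tr = ComponentTransport(
        names=["ev", "protein", "dna"],
        eps_tot=[0.42, 0.80, 0.70],
        eps_s=[0.0, 0.60, 0.50],
        D_ax=[0.10, 0.05, 0.06],
        k_eff=[0.0, 0.006, 0.004],
    )
    iso = IsothermParams(
        q_max=np.array([0.0, 5.0e3, 1.0e3]),
        K0=np.array([0.0, 0.05, 0.002]),
        beta=np.array([0.0, 0.0, 0.0]),
        k_kin=np.array([0.0, 2.0, 2.0]),
    )
    return ColumnSystem(one_ml_column, tr, iso)


@pytest.fixture(scope="session")
def mmsec_scan_model(mmsec_system):
    """Flow-through product scan: pool = flow-through + wash window."""
    from evtwin.optimization import OperatingPoint, ScanModel

    def build(point: OperatingPoint) -> MethodProgram:
        return MethodProgram([
            MethodStep("equilibrate", 1.0, point.flow_ml_min,
                       mod_start_mM=150.0),
            MethodStep("load", point.feed_volume_cv, point.flow_ml_min,
                       inlet={"ev": 2e10, "protein": 120.0, "dna": 160.0},
                       mod_start_mM=150.0),
            MethodStep("wash", 3.0, point.flow_ml_min, mod_start_mM=150.0),
            MethodStep("cip", 3.0, point.flow_ml_min, mod_start_mM=1000.0),
        ])

    return ScanModel(system=mmsec_system, program_builder=build,
                     pool_window_cv=(0.0, 4.0), pool_from_step="load",
                     product="ev", protein="protein", dna="dna", n_cells=25)


@pytest.fixture(scope="session")
def aex_scan_model(aex_system):
    from evtwin.optimization import OperatingPoint, ScanModel

    def build(point: OperatingPoint) -> MethodProgram:
        return MethodProgram([
            MethodStep("load", point.feed_volume_cv, point.flow_ml_min,
                       inlet={"ev": 1e10, "protein": 100.0, "dna": 150.0},
                       mod_start_mM=50.0),
            MethodStep("wash", 3.0, point.flow_ml_min,
                       mod_start_mM=point.wash_modifier_mM),
            MethodStep("gradient", point.gradient_length_cv,
                       point.flow_ml_min,
                       mod_start_mM=point.wash_modifier_mM,
                       mod_end_mM=1000.0),
            MethodStep("cip", 3.0, point.flow_ml_min, mod_start_mM=1000.0),
        ])

    return ScanModel(system=aex_system, program_builder=build,
                     pool_window_cv=(0.0, 8.0), pool_from_step="gradient",
                     product="ev", protein="protein", dna="dna", n_cells=25)


def mmsec_program(flow=0.5, feed_cv=1.0,
                  load={"ev": 2e10, "protein": 120.0, "dna": 160.0}):
    return MethodProgram([
        MethodStep("equilibrate", 1.0, flow, mod_start_mM=150.0),
        MethodStep("load", feed_cv, flow, inlet=dict(load), mod_start_mM=150.0),
        MethodStep("wash", 3.0, flow, mod_start_mM=150.0),
        MethodStep("cip", 4.0, flow, mod_start_mM=1000.0),
    ])
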