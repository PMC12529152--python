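"""Two-phase kinetic model of hMSC cultivation and EV formation.

The cultivation is split into a *growth* phase and a *collect* phase (product
forms only in the latter), each with its own parameter set.  The model is a
macroscopic Monod-type description of viable cell density (VCD), glucose,
lactate and product:

.. math::

    \\mu   &= \\mu_{max} \\frac{Glc}{K_{Glc}+Glc}\\frac{K_{I,Lac}}{K_{I,Lac}+Lac} \\\\
    \\mu_d &= k_D \\frac{Lac}{K_{D,Lac}+Lac}
              + k_{lag,max} \\frac{K_{M,lag}}{K_{M,lag}+t} \\\\
    \\frac{dVCD}{dt} &= (\\mu-\\mu_d)\\,VCD \\\\
    \\frac{dGlc}{dt} &= -\\Big(\\frac{\\mu-\\mu_d}{Y_{X/Glc}} + m_{Glc}
              + \\frac{q_{product}}{Y_{P/Glc}}\\Big)\\,VCD \\\\
    \\frac{dLac}{dt} &= Y_{Lac/Glc}\\,\\Big(-\\frac{dGlc}{dt}\\Big) \\\\
    \\frac{dP}{dt}   &= 10^3\\, q_{product}\\,VCD

The lag term in the death rate models the transient cell stress right after
the media exchange; its clock ``t`` restarts at the exchange event.  The lag
and product terms exist only in the collect phase.

Units: VCD in 1e6 cells/mL, Glc and Lac in mmol/L, P in mmol/L, time in h.
The product rate carries an explicit factor 1000 (mL -> L) because
``q_product`` is specified per 1e6 cells and VCD per mL; the glucose-side
terms use the VCD value directly, following the apparent-yield convention of
the parameter set (the printed yields absorb the volume basis).  The lactate
yield is apparent: it lumps growth-coupled glucose conversion with other
substrates metabolised to lactate, so values above the stoichiometric limit
of 2 are meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

#: particles per mmol of product (Avogadro / 1000)
PARTICLES_PER_MMOL = 6.02214076e20

STATE_COLUMNS = ["vcd_e6_per_ml", "glc_mM", "lac_mM", "product_mM"]


@dataclass
class KineticParams:
    """Kinetic parameter set for one cultivation phase.

    ``q_product``, ``Y_product_glc``, ``k_lag_max`` and ``K_M_lag`` are
    collect-phase-only and must be ``None`` for the growth phase.
    """

    mu_max: float            # 1/h
    k_d: float               # 1/h
    K_glc: float             # mmol/L
    K_i_lac: float           # mmol/L, lactate growth inhibition
    K_d_lac: float           # mmol/L, lactate death half-saturation
    m_glc: float             # mmol_Glc/(1e6 cells h), maintenance
    Y_x_glc: float           # 1e6 cells/mmol_Glc
    Y_lac_glc: float         # mmol_Lac/mmol_Glc (apparent)
    phase: str = "growth"    # "growth" | "collect"
    q_product: float | None = None       # mmol_product/(1e6 cells h)
    Y_product_glc: float | None = None   # mmol_product/mmol_Glc
    k_lag_max: float | None = None       # 1/h
    K_M_lag: float | None = None         # h (lag-decay half time)

    def __post_init__(self) -> None:
        if self.phase not in ("growth", "collect"):
            raise ValueError(f"unknown phase {self.phase!r}")
        for name in ("mu_max", "k_d", "m_glc", "Y_x_glc", "Y_lac_glc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("K_glc", "K_i_lac", "K_d_lac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        collect_only = ("q_product", "Y_product_glc", "k_lag_max", "K_M_lag")
        if self.phase == "growth":
            if any(getattr(self, n) is not None for n in collect_only):
                raise ValueError("product/lag parameters are collect-phase only")
        else:
            missing = [n for n in collect_only if getattr(self, n) is None]
            if missing:
                raise ValueError(f"collect phase requires {missing}")
            if self.K_M_lag <= 0:
                raise ValueError("K_M_lag must be positive")

    def replace(self, **kwargs) -> "KineticParams":
        return replace(self, **kwargs)


# Calibrated parameter sets for the hMSC fed-batch process (growth /
# collect columns of the published calibration).
GROWTH_PARAMS = KineticParams(
    mu_max=0.039, k_d=0.004, K_glc=1.0, K_i_lac=43.0, K_d_lac=45.8,
    m_glc=0.07, Y_x_glc=0.038, Y_lac_glc=1.68, phase="growth",
)
COLLECT_PARAMS = KineticParams(
    mu_max=0.036, k_d=0.004, K_glc=1.0, K_i_lac=43.0, K_d_lac=45.8,
    m_glc=0.07, Y_x_glc=0.031, Y_lac_glc=2.11, phase="collect",
    q_product=5.3e-13, Y_product_glc=1.0e-12, k_lag_max=0.04, K_M_lag=160.0,
)


@dataclass
class CultureState:
    """State of the culture: time within phase and the four balanced species."""

    t: float = 0.0            # h since current phase start (lag clock)
    vcd: float = 0.0          # 1e6 cells/mL
    glc: float = 0.0          # mmol/L
    lac: float = 0.0          # mmol/L
    p: float = 0.0            # mmol product/L

    def __post_init__(self) -> None:
        if min(self.t, self.vcd, self.glc, self.lac, self.p) < 0:
            raise ValueError("culture state components must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.vcd, self.glc, self.lac, self.p])


@dataclass
class PhaseSchedule:
    """Timing of the two phases and the feed / media-exchange events.

    The growth phase runs on ``[0, growth_span_h]``; the media exchange at
    its end switches to the collect parameter set, sets glucose to the
    fresh-medium value, resets lactate and product, and restarts the lag
    clock.  An optional glucose feed bolus (with optional dilution of all
    concentrations) is applied during the growth phase.
    """

    growth_span_h: float = 120.0
    collect_span_h: float = 120.0
    feed_time_h: float | None = 72.0
    feed_glc_bolus_mM: float = 10.0
    feed_dilution: float = 0.0        # fraction of volume added, dilutes all species
    exchange_glc_mM: float = 25.0     # fresh-medium glucose after exchange

    def __post_init__(self) -> None:
        if self.growth_span_h < 0 or self.collect_span_h < 0:
            raise ValueError("phase spans must be non-negative")
        if self.feed_time_h is not None:
            if not (0 <= self.feed_time_h <= self.growth_span_h):
                raise ValueError("feed event outside growth span")
        if not (0 <= self.feed_dilution < 1):
            raise ValueError("feed_dilution must be in [0, 1)")

    @property
    def total_span_h(self) -> float:
        return self.growth_span_h + self.collect_span_h


def specific_growth_rate(glc: float, lac: float, p: KineticParams) -> float:
    """Specific growth rate µ(Glc, Lac): Monod in glucose, inhibited by lactate."""
    if glc < 0 or lac < 0:
        raise ValueError("concentrations must be non-negative")
    return p.mu_max * glc / (p.K_glc + glc) * p.K_i_lac / (p.K_i_lac + lac)


def specific_death_rate(lac: float, t: float, p: KineticParams) -> float:
    """Specific death rate µ_d(Lac, t).

    Lactate-driven term saturating at ``k_d`` plus, in the collect phase, a
    stress/lag term that starts at ``k_lag_max`` and decays with the time
    since the media exchange.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    if lac < 0:
        raise ValueError("lactate must be non-negative")
    mu_d = p.k_d * lac / (p.K_d_lac + lac)
    if p.phase == "collect":
        mu_d += p.k_lag_max * p.K_M_lag / (p.K_M_lag + t)
    return mu_d


def glucose_rate(state: CultureState, mu: float, mu_d: float,
                 p: KineticParams) -> float:
    """dGlc/dt in mmol/(L·h): growth-, maintenance- and product-coupled uptake."""
    if p.Y_x_glc <= 0:
        raise ValueError("Y_x_glc must be positive")
    rate = (mu - mu_d) / p.Y_x_glc + p.m_glc
    if p.phase == "collect":
        if p.Y_product_glc <= 0:
            raise ValueError("Y_product_glc must be positive")
        rate += p.q_product / p.Y_product_glc
    return -rate * state.vcd


def particles_from_product(p_mmol_per_l) -> np.ndarray | float:
    """Convert product concentration (mmol/L) to particles/mL.

    particles/mL = P [mmol/L] × 1e-3 mol/mmol × N_A / 1e3 mL/L
                 = P × 6.02214076e20 / 1e3.
    """
    p_arr = np.asarray(p_mmol_per_l, dtype=float)
    if np.any(p_arr < 0):
        raise ValueError("product concentration must be non-negative")
    out = p_arr * PARTICLES_PER_MMOL / 1e3
    return float(out) if out.ndim == 0 else out


def product_from_particles(particles_per_ml) -> np.ndarray | float:
    """Inverse of :func:`particles_from_product` (particles/mL -> mmol/L)."""
    arr = np.asarray(particles_per_ml, dtype=float)
    out = arr * 1e3 / PARTICLES_PER_MMOL
    return float(out) if out.ndim == 0 else out


def _rhs(t: float, y: np.ndarray, p: KineticParams) -> np.ndarray:
    vcd, glc, lac, prod = np.maximum(y, 0.0)
    mu = specific_growth_rate(glc, lac, p)
    mu_d = specific_death_rate(lac, t, p)
    dvcd = (mu - mu_d) * vcd
    uptake = (mu - mu_d) / p.Y_x_glc + p.m_glc
    dp = 0.0
    if p.phase == "collect":
        uptake += p.q_product / p.Y_product_glc
        dp = 1e3 * p.q_product * vcd
    dglc = -uptake * vcd
    if glc <= 0.0 and dglc < 0.0:
        dglc = 0.0    # substrate exhausted: no further consumption
    dlac = p.Y_lac_glc * max(-dglc, 0.0)
    return np.array([dvcd, dglc, dlac, dp])


def _integrate_phase(y0: np.ndarray, span: float, p: KineticParams,
                     t_eval: np.ndarray, rtol: float, atol: float) -> np.ndarray:
    """Integrate one phase; returns states at t_eval (phase-local times)."""
    if span == 0 or t_eval.size == 0:
        return np.empty((0, 4))
    sol = solve_ivp(_rhs, (0.0, span), y0, args=(p,), method="LSODA",
                    t_eval=t_eval, rtol=rtol, atol=atol, dense_output=False)
    if not sol.success:
        raise RuntimeError(
            f"cultivation solver failed in {p.phase} phase at t={sol.t[-1] if sol.t.size else 0}: "
            f"{sol.message}")
    return sol.y.T


def simulate_cultivation(init: CultureState,
                         schedule: PhaseSchedule,
                         params: Mapping[str, KineticParams],
                         t_out: Sequence[float] | None = None,
                         rtol: float = 1e-8,
                         atol: float = 1e-10) -> pd.DataFrame:
    """Simulate the full two-phase cultivation.

    Parameters
    ----------
    init : CultureState
        State at t = 0 (start of the growth phase, or of the collect phase if
        ``schedule.growth_span_h == 0``).
    schedule : PhaseSchedule
        Phase spans and events.  Events are applied atomically between
        integration segments.
    params : mapping
        ``{"growth": KineticParams, "collect": KineticParams}``; only the
        phases with non-zero span need to be present.
    t_out : sequence of float, optional
        Absolute output times in h (default: every 24 h, matching daily
        sampling).  Event times are not required to be included.

    Returns
    -------
    pandas.DataFrame
        Columns ``time_h, phase, vcd_e6_per_ml, glc_mM, lac_mM, product_mM,
        particles_per_ml``; negative solver excursions are clipped at 0.
    """
    if t_out is None:
        t_out = np.arange(0.0, schedule.total_span_h + 1e-9, 24.0)
    t_out = np.asarray(t_out, dtype=float)
    if np.any(np.diff(t_out) <= 0):
        raise ValueError("output times must be strictly increasing")
    if t_out.size and (t_out[0] < 0 or t_out[-1] > schedule.total_span_h + 1e-9):
        raise ValueError("output times outside the scheduled span")

    rows_t: list[np.ndarray] = []
    rows_y: list[np.ndarray] = []
    rows_phase: list[str] = []

    y = init.as_array().copy()

    # --- growth phase, split at the feed event ---------------------------
    g_span = schedule.growth_span_h
    if g_span > 0:
        pg = params["growth"]
        t_growth = t_out[t_out <= g_span + 1e-12]
        feed_t = schedule.feed_time_h
        segments = [(0.0, g_span)] if feed_t is None or feed_t in (0.0, g_span) \
            else [(0.0, feed_t), (feed_t, g_span)]
        for k, (a, b) in enumerate(segments):
            mask = (t_growth >= a - 1e-12) & (t_growth <= b + 1e-12)
            te = t_growth[mask]
            # integrate in phase-local time (growth clock starts at 0)
            te_local = np.unique(np.clip(te, a, b)) - a
            sol = _integrate_phase_segment(y, a, b, pg, te_local, rtol, atol)
            if te_local.size:
                rows_t.append(te)
                rows_y.append(sol["at_eval"])
                rows_phase.extend(["growth"] * te.size)
            y = sol["final"]
            # de-duplicate the boundary sample between segments
            if k == 0 and len(segments) == 2 and te.size and abs(te[-1] - b) < 1e-9:
                rows_t[-1] = te[:-1]
                rows_y[-1] = rows_y[-1][:-1]
                del rows_phase[-1]
            if k == 0 and len(segments) == 2:
                y = _apply_feed(y, schedule)
        # media exchange: fresh glucose, lactate & product reset, lag restart
        y = np.array([y[0], schedule.exchange_glc_mM, 0.0, 0.0])

    # --- collect phase ----------------------------------------------------
    c_span = schedule.collect_span_h
    if c_span > 0:
        pc = params["collect"]
        t_collect = t_out[t_out > g_span + 1e-12] if g_span > 0 else t_out
        te_local = t_collect - g_span
        sol = _integrate_phase_segment(y, 0.0, c_span, pc, te_local, rtol, atol)
        if te_local.size:
            rows_t.append(t_collect)
            rows_y.append(sol["at_eval"])
            rows_phase.extend(["collect"] * t_collect.size)

    # the t=growth_span sample (if requested) belongs to the growth phase,
    # sampled just before the exchange — keep as produced above.
    t_all = np.concatenate(rows_t) if rows_t else np.empty(0)
    y_all = np.vstack(rows_y) if rows_y else np.empty((0, 4))
    y_all = np.maximum(y_all, 0.0)
    df = pd.DataFrame({
        "time_h": t_all,
        "phase": rows_phase,
        "vcd_e6_per_ml": y_all[:, 0],
        "glc_mM": y_all[:, 1],
        "lac_mM": y_all[:, 2],
        "product_mM": y_all[:, 3],
    })
    df["particles_per_ml"] = particles_from_product(df["product_mM"].to_numpy())
    return df.reset_index(drop=True)


def _integrate_phase_segment(y0: np.ndarray, a: float, b: float,
                             p: KineticParams, te_local: np.ndarray,
                             rtol: float, atol: float) -> dict:
    """Integrate [a, b] of a phase whose clock started at the phase origin.

    ``te_local`` are output times relative to ``a``.  The phase-local clock
    (which the lag term uses) is ``a + tau``.
    """
    span = b - a
    if span <= 0:
        return {"at_eval": np.tile(y0, (te_local.size, 1)), "final": y0.copy()}

    def rhs(tau, y):
        return _rhs(a + tau, y, p)

    # ensure final state is available even if b is not an output time
    te = np.unique(np.concatenate([te_local, [span]]))
    te = te[(te >= 0) & (te <= span + 1e-12)]
    sol = solve_ivp(rhs, (0.0, span), y0, method="LSODA", t_eval=te,
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"cultivation solver failed in {p.phase} phase: {sol.message}")
    ys = sol.y.T
    # map back to the requested subset
    idx = np.searchsorted(sol.t, te_local)
    return {"at_eval": ys[idx], "final": ys[-1]}


def _apply_feed(y: np.ndarray, schedule: PhaseSchedule) -> np.ndarray:
    """Instantaneous glucose bolus with optional dilution of all species."""
    d = schedule.feed_dilution
    y = y * (1.0 - d)
    y[1] += schedule.feed_glc_bolus_mM
    return y


# --------------------------------------------------------------------------
# Parameter estimation
# --------------------------------------------------------------------------

_FITTABLE = {"mu_max", "k_d", "K_glc", "K_i_lac", "K_d_lac", "m_glc",
             "Y_x_glc", "Y_lac_glc", "q_product", "Y_product_glc",
             "k_lag_max", "K_M_lag"}


@dataclass
class FitResult:
    params: dict[str, KineticParams]
    estimates: dict[str, float]       # "phase.name" -> value
    cost: float                       # 0.5 * sum of squared weighted residuals
    success: bool
    message: str
    per_variable_sse: dict[str, float] = field(default_factory=dict)
    nfev: int = 0


def fit_kinetic_params(data: pd.DataFrame,
                       free: Sequence[str],
                       init_params: Mapping[str, KineticParams],
                       schedule: PhaseSchedule,
                       init_state: CultureState,
                       bounds: Mapping[str, tuple[float, float]] | None = None,
                       variables: Iterable[str] = STATE_COLUMNS,
                       x0: Mapping[str, float] | None = None) -> FitResult:
    """Weighted least-squares estimation of kinetic parameters.

    Parameters
    ----------
    data : DataFrame
        Observed trajectory (columns as produced by
        :func:`simulate_cultivation`); may be noisy.
    free : sequence of str
        Parameters to estimate, written ``"phase.name"``
        (e.g. ``"growth.mu_max"``, ``"collect.q_product"``).
    init_params, schedule, init_state
        The model structure; ``init_params`` supplies both the fixed values
        and the default starting guesses for the free parameters.
    bounds : mapping, optional
        ``"phase.name" -> (lo, hi)``; defaults to (0, 10× start).
    variables : iterable of str
        Trajectory columns entering the objective.  Residuals are weighted
        per variable by the reciprocal of its observed range so that VCD,
        metabolites and product (incommensurate units) contribute comparably.
    x0 : mapping, optional
        Override starting guesses per free parameter.

    Returns
    -------
    FitResult
        The objective at the estimate never exceeds the objective at the
        start (trust-region descent property).
    """
    free = list(free)
    for name in free:
        phase, _, pname = name.partition(".")
        if phase not in init_params or pname not in _FITTABLE:
            raise ValueError(f"cannot fit {name!r}")
        if f"{phase}" == "growth" and pname in ("q_product", "Y_product_glc",
                                                "k_lag_max", "K_M_lag"):
            raise ValueError(f"{pname} is collect-phase only")
    variables = [v for v in variables if v in data.columns]
    if not variables:
        raise ValueError("no fit variables present in data")

    # informativeness guard: free collect parameters need collect-phase data
    phases_in_data = set(data["phase"]) if "phase" in data.columns else {"growth", "collect"}
    for name in free:
        phase = name.split(".", 1)[0]
        if phase not in phases_in_data:
            raise ValueError(f"no {phase}-phase data to inform {name!r}")

    t_obs = data["time_h"].to_numpy(dtype=float)
    obs = data[variables].to_numpy(dtype=float)
    ranges = obs.max(axis=0) - obs.min(axis=0)
    ranges[ranges <= 0] = np.maximum(np.abs(obs).max(axis=0), 1.0)[ranges <= 0]
    weights = 1.0 / ranges

    def build(theta: np.ndarray) -> dict[str, KineticParams]:
        p = {k: v for k, v in init_params.items()}
        for val, name in zip(theta, free):
            phase, _, pname = name.partition(".")
            p[phase] = p[phase].replace(**{pname: float(val)})
        return p

    def resid(theta: np.ndarray) -> np.ndarray:
        try:
            sim = simulate_cultivation(init_state, schedule, build(theta),
                                       t_out=t_obs, rtol=1e-8, atol=1e-10)
        except (RuntimeError, ValueError):
            return np.full(obs.size, 1e6)
        r = (sim[variables].to_numpy() - obs) * weights
        return r.ravel()

    theta0 = []
    lo, hi = [], []
    for name in free:
        phase, _, pname = name.partition(".")
        start = getattr(init_params[phase], pname)
        if x0 is not None and name in x0:
            start = x0[name]
        if start is None:
            raise ValueError(f"no starting value for {name}")
        theta0.append(start)
        b = bounds.get(name) if bounds else None
        if b is None:
            b = (0.0, 10.0 * max(start, 1e-300))
        if not (b[0] <= start <= b[1]):
            raise ValueError(f"start for {name} outside bounds {b}")
        lo.append(b[0])
        hi.append(b[1])

    res = least_squares(resid, theta0, bounds=(lo, hi), method="trf",
                        x_scale=np.maximum(np.abs(theta0), 1e-300),
                        xtol=1e-12, ftol=1e-12, gtol=1e-12)

    fitted = build(res.x)
    sim = simulate_cultivation(init_state, schedule, fitted, t_out=t_obs)
    sse = {}
    for j, v in enumerate(variables):
        r = (sim[v].to_numpy() - obs[:, j]) * weights[j]
        sse[v] = float(np.sum(r ** 2))
    return FitResult(
        params=fitted,
        estimates={n: float(v) for n, v in zip(free, res.x)},
        cost=float(res.cost),
        success=bool(res.success),
        message=str(res.message),
        per_variable_sse=sse,
        nfev=int(res.nfev),
    )
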