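"""Synthetic accelerated-oxidation studies with retained ground truth.

The generator emulates the three data surfaces the analysis consumes:

1. **Conductivity traces** — logistic (sigmoid) rises over a drifting
   linear baseline plus i.i.d. Gaussian noise, with the logistic centre
   placed so that the *analytic* baseline/tangent intersection equals the
   requested induction time.  For a logistic of steepness ``k`` the
   maximal slope sits at the centre ``t_c`` and the tangent there meets
   the baseline at ``t_c - 2/k``, independent of baseline drift, so
   ``t_c = osi + 2/k`` exactly.
2. **OSI tables** — per-cell induction times following the log-linear
   temperature law ``osi(T) = 10**(a T + b)`` times an airflow multiplier
   times lognormal replicate noise whose theoretical CV matches
   ``replicate_cv`` (lognormal keeps OSI strictly positive).
3. **Quality-marker panels** — markers evolving with storage and
   correlated with kernel OSI through a single-factor linear mixing
   construction whose mixing weight is solved in closed form so the
   population correlation equals the per-marker target (storage-trend
   leakage into the correlation is compensated exactly).

Everything is driven by one integer seed through ``numpy``'s
``SeedSequence`` spawning, so identical seed + config gives a
byte-identical dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidConfig
from .induction import ConductivityTrace

__all__ = [
    "TraceParams",
    "MarkerSpec",
    "SimulationConfig",
    "StudyDataset",
    "simulate_trace",
    "simulate_osi_study",
    "simulate_storage_osi",
    "simulate_quality_panel",
    "simulate_study",
    "DEFAULT_MARKERS",
]


@dataclass(frozen=True)
class TraceParams:
    """Shape parameters of a synthetic conductivity trace.

    Units: uS/cm for levels and amplitude, uS/cm/h for drift, 1/h for
    steepness, hours for the sampling interval.  The default 0.05 h
    sampling gives sub-1% induction-time resolution for OSI >= 2 h.
    """

    baseline_level: float = 2.0
    baseline_drift: float = 0.02
    rise_amplitude: float = 100.0
    rise_steepness: float = 2.0
    noise_sd: float = 0.1
    sampling_interval: float = 0.05

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise InvalidConfig("sampling_interval must be > 0")
        if self.rise_amplitude <= 0 or self.rise_steepness <= 0:
            raise InvalidConfig("rise amplitude and steepness must be > 0")
        if self.noise_sd < 0 or self.baseline_level < 0:
            raise InvalidConfig("noise_sd and baseline_level must be >= 0")


@dataclass(frozen=True)
class MarkerSpec:
    """Generative law for one quality marker.

    ``base`` is the value at harvest (storage 0), ``slope_per_month`` the
    deterministic storage trend, ``residual_sd`` the Gaussian residual
    scale, ``target_r`` the desired population correlation with kernel
    OSI, and ``(lo, hi)`` the clipping range enforcing the marker's
    physical domain.
    """

    base: float
    slope_per_month: float
    residual_sd: float
    target_r: float
    lo: float = 0.0
    hi: float = math.inf

    def __post_init__(self) -> None:
        if not -1.0 <= self.target_r <= 1.0:
            raise InvalidConfig(f"target_r {self.target_r} outside [-1, 1]")
        if self.residual_sd < 0:
            raise InvalidConfig("residual_sd must be >= 0")
        if abs(self.target_r) == 1.0 and self.residual_sd > 0:
            raise InvalidConfig("|target_r| = 1 requires residual_sd = 0")


#: Default marker panel: harvest levels, storage trends and OSI
#: correlations typical of walnut kernels oxidizing over six months at
#: room temperature.  Oil OSI tracks kernel OSI positively; primary
#: (PV, K232), secondary (K268, hexanal) oxidation markers and sensory
#: rancidity correlate negatively at magnitudes ~0.5-0.9; moisture is
#: uncorrelated with oxidative stability.
DEFAULT_MARKERS: dict[str, MarkerSpec] = {
    "moisture_pct": MarkerSpec(4.0, 0.0, 0.4, 0.0, 0.0, 100.0),
    "fat_pct": MarkerSpec(65.0, 0.0, 1.5, -0.5, 0.0, 100.0),
    "pv": MarkerSpec(0.5, 0.8, 0.8, -0.8),
    "k232": MarkerSpec(1.5, 0.15, 0.2, -0.6),
    "k268": MarkerSpec(0.15, 0.02, 0.03, -0.7),
    "hexanal_mg_kg": MarkerSpec(0.5, 1.0, 0.8, -0.8),
    "oil_osi_h": MarkerSpec(10.0, -0.8, 1.0, 0.8),
    "rancidity": MarkerSpec(0.5, 0.9, 1.0, -0.8, 0.0, 10.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a synthetic accelerated-oxidation study.

    Defaults mirror the standard design: 110/120/130 C by 15/20/25 L/h
    with eight replicates per cell (one per instrument position), the
    log-linear law ``osi(T) = 10**(-0.037 T + 5.181)`` and a 7% replicate
    CV (observed CVs span roughly 4-11%).  Storage sampling is at 0, 4
    and 6 months with eight lots per time point, kernel OSI decaying by
    a factor ``osi_storage_decay`` per month.
    """

    seed: int = 0
    temperatures: tuple[float, ...] = (110.0, 120.0, 130.0)
    airflows: tuple[float, ...] = (15.0, 20.0, 25.0)
    replicates_per_cell: int = 8
    kinetic_a: float = -0.037
    kinetic_b: float = 5.181
    replicate_cv: float = 7.0
    airflow_effects: dict[float, float] = field(default_factory=dict)
    trace_params: TraceParams = field(default_factory=TraceParams)
    storage_months: tuple[float, ...] = (0.0, 4.0, 6.0)
    lots_per_storage: int = 8
    osi_storage_decay: float = 0.85
    markers: dict[str, MarkerSpec] = field(default_factory=lambda: dict(DEFAULT_MARKERS))

    def __post_init__(self) -> None:
        if self.replicate_cv < 0:
            raise InvalidConfig("replicate_cv must be >= 0")
        if self.replicates_per_cell < 1 or self.lots_per_storage < 1:
            raise InvalidConfig("replicate and lot counts must be >= 1")
        if not 0 < self.osi_storage_decay <= 1:
            raise InvalidConfig("osi_storage_decay must lie in (0, 1]")
        if not self.temperatures or not self.airflows:
            raise InvalidConfig("need at least one temperature and one airflow")


@dataclass(frozen=True)
class StudyDataset:
    """A generated study with its ground truth.

    ``osi_truth`` holds the generative per-replicate induction times of
    the temperature x airflow grid; ``traces`` the rendered conductivity
    curves (one per replicate, possibly empty); ``storage_osi`` the
    kernel OSI of each lot at each storage time; ``panels`` the marker
    panel aligned with ``storage_osi`` on (sample_id, storage_months).
    """

    traces: tuple[ConductivityTrace, ...]
    osi_truth: pd.DataFrame
    storage_osi: pd.DataFrame
    panels: pd.DataFrame
    config: SimulationConfig


def _lognormal_factors(rng: np.random.Generator, cv_pct: float, size: int) -> np.ndarray:
    """Unit-mean lognormal multipliers with theoretical CV = cv_pct."""
    if cv_pct == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p((cv_pct / 100.0) ** 2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def simulate_trace(
    induction_time: float,
    trace_params: TraceParams = TraceParams(),
    seed: int | np.random.Generator = 0,
    *,
    sample_id: str = "synthetic",
    temperature: float = 110.0,
    airflow: float = 25.0,
    replicate: int = 1,
) -> ConductivityTrace:
    """Render a conductivity trace whose tangent-method OSI is exact.

    The curve is ``c(t) = L + d t + A / (1 + exp(-k (t - t_c))) + noise``
    with the logistic centre ``t_c = induction_time + 2/k`` so that the
    analytic intersection of the baseline line ``L + d t`` with the
    tangent at the steepest point equals ``induction_time`` (the drift
    term cancels from the intersection).  The trace extends to at least
    1.5x the induction time and past the completed rise.
    """
    if induction_time <= 0:
        raise InvalidConfig("induction_time must be > 0")
    p = trace_params
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_c = induction_time + 2.0 / p.rise_steepness
    duration = max(1.5 * induction_time, t_c + 6.0 / p.rise_steepness)
    t = np.arange(0.0, duration + p.sampling_interval, p.sampling_interval)
    c = (
        p.baseline_level
        + p.baseline_drift * t
        + p.rise_amplitude / (1.0 + np.exp(-p.rise_steepness * (t - t_c)))
    )
    if p.noise_sd > 0:
        c = c + rng.normal(0.0, p.noise_sd, size=t.size)
    return ConductivityTrace(
        sample_id=sample_id,
        temperature=temperature,
        airflow=airflow,
        replicate=replicate,
        time=t,
        conductivity=np.clip(c, 0.0, None),
    )


def simulate_osi_study(
    config: SimulationConfig, render_traces: bool = True
) -> StudyDataset:
    """Generate the temperature x airflow OSI grid (and optionally traces).

    Each replicate's generative OSI is
    ``10**(a T + b) * airflow_effect * lognormal`` with the lognormal
    factor calibrated to ``replicate_cv``.  When ``render_traces`` is
    true a conductivity trace is rendered per replicate with that OSI as
    its exact tangent-method induction time.
    """
    ss = np.random.SeedSequence(config.seed)
    grid_rng = np.random.default_rng(ss.spawn(1)[0])
    trace_ss = ss.spawn(1)[0]

    records = []
    traces: list[ConductivityTrace] = []
    for T in config.temperatures:
        for af in config.airflows:
            base = 10.0 ** (config.kinetic_a * T + config.kinetic_b)
            base *= config.airflow_effects.get(af, 1.0)
            factors = _lognormal_factors(grid_rng, config.replicate_cv, config.replicates_per_cell)
            for rep, f in enumerate(factors, start=1):
                osi = base * f
                records.append(
                    {"temperature_C": T, "airflow_L_h": af, "replicate": rep, "osi_h": osi}
                )
                if render_traces:
                    child = np.random.default_rng(trace_ss.spawn(1)[0])
                    traces.append(
                        simulate_trace(
                            osi,
                            config.trace_params,
                            child,
                            sample_id=f"T{T:g}_F{af:g}",
                            temperature=T,
                            airflow=af,
                            replicate=rep,
                        )
                    )
    osi_truth = pd.DataFrame.from_records(records)
    return StudyDataset(
        traces=tuple(traces),
        osi_truth=osi_truth,
        storage_osi=pd.DataFrame(columns=["sample_id", "storage_months", "osi_h"]),
        panels=pd.DataFrame(),
        config=config,
    )


def simulate_storage_osi(config: SimulationConfig) -> pd.DataFrame:
    """Kernel OSI of each lot at each storage time.

    OSI at storage month m is the harvest-level OSI (the log-linear law
    at the first configured temperature/airflow) times
    ``osi_storage_decay**m`` times lognormal replicate scatter.
    """
    ss = np.random.SeedSequence((config.seed, 1))
    rng = np.random.default_rng(ss)
    T0, af0 = config.temperatures[0], config.airflows[0]
    osi_ref = 10.0 ** (config.kinetic_a * T0 + config.kinetic_b)
    osi_ref *= config.airflow_effects.get(af0, 1.0)
    rows = []
    for m in config.storage_months:
        factors = _lognormal_factors(rng, config.replicate_cv, config.lots_per_storage)
        for lot, f in enumerate(factors, start=1):
            rows.append(
                {
                    "sample_id": f"lot{lot:02d}",
                    "storage_months": float(m),
                    "osi_h": osi_ref * config.osi_storage_decay**m * f,
                }
            )
    return pd.DataFrame(rows)


def _solve_mixing_weight(
    rho: float, trend: np.ndarray, z: np.ndarray, sigma: float
) -> float:
    """Mixing weight lambda so that corr(trend + lambda z + sigma eps, z) = rho.

    ``trend`` is the deterministic storage component, ``z`` the
    standardized OSI (unit variance); the closed form compensates the
    covariance the trend already shares with z:

        lambda = -u + rho * sqrt((var(trend) + sigma^2 - u^2) / (1 - rho^2))

    with u = cov(trend, z).
    """
    u = float(np.cov(trend, z, ddof=1)[0, 1]) if trend.size > 1 else 0.0
    v = float(np.var(trend, ddof=1)) if trend.size > 1 else 0.0
    inner = max(v + sigma**2 - u**2, 0.0)
    return -u + rho * math.sqrt(inner / (1.0 - rho**2))


def simulate_quality_panel(
    config: SimulationConfig, osi_truth: pd.DataFrame
) -> pd.DataFrame:
    """Generate the marker panel correlated with the given kernel OSI.

    ``osi_truth`` must carry columns ``sample_id, storage_months, osi_h``
    (as from :func:`simulate_storage_osi`).  Each marker is

        base + slope * months + lambda * z + residual_sd * eps

    with ``z`` the standardized OSI across the collection and ``lambda``
    solved in closed form (see :func:`_solve_mixing_weight`) so the
    population correlation with OSI equals the marker's ``target_r`` —
    including the correlation the storage trend itself induces through
    the OSI storage decay.  ``|target_r| = 1`` requires a zero residual
    and drops the trend term (perfect linearity is otherwise infeasible).
    Values are clipped to each marker's physical range.
    """
    for col in ("sample_id", "storage_months", "osi_h"):
        if col not in osi_truth.columns:
            raise InvalidConfig(f"osi_truth missing column {col!r}")
    ss = np.random.SeedSequence((config.seed, 2))
    rng = np.random.default_rng(ss)

    months = osi_truth["storage_months"].to_numpy(dtype=float)
    osi = osi_truth["osi_h"].to_numpy(dtype=float)
    sd = float(np.std(osi, ddof=1))
    if sd == 0:
        raise InvalidConfig("OSI series is constant; correlations undefined")
    z = (osi - osi.mean()) / sd

    panel = osi_truth[["sample_id", "storage_months"]].copy()
    for name, spec in config.markers.items():
        rho = spec.target_r
        if abs(rho) == 1.0:
            values = spec.base + math.copysign(1.0, rho) * z
        else:
            trend = spec.base + spec.slope_per_month * months
            lam = _solve_mixing_weight(rho, trend, z, spec.residual_sd)
            eps = rng.normal(0.0, 1.0, size=z.size)
            values = trend + lam * z + spec.residual_sd * eps
        panel[name] = np.clip(values, spec.lo, spec.hi)
    return panel


def simulate_study(config: SimulationConfig, render_traces: bool = True) -> StudyDataset:
    """Generate the full study: OSI grid, traces, storage OSI and panels."""
    grid = simulate_osi_study(config, render_traces=render_traces)
    storage_osi = simulate_storage_osi(config)
    panels = simulate_quality_panel(config, storage_osi)
    return replace(grid, storage_osi=storage_osi, panels=panels)
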