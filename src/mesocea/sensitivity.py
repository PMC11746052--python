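"""One-way and probabilistic sensitivity analysis.

OWSA reruns the full deterministic model at each parameter's range limits
and ranks parameters by the induced ICER swing (tornado).  PSA samples all
non-fixed parameters jointly and independently -- beta for utility-scale
quantities, gamma for costs, moment-matched to the baseline and range --
and summarizes the draws as a cost-effectiveness acceptability curve.

Survival-model parameters are held fixed throughout (no published ranges
or distributions exist for them); because of this the cohort occupancy is
identical across draws, and the PSA evaluates cost/utility accruals as
exact linear functionals of the per-draw discount vector -- the same
arithmetic as the cohort engine, vectorized over draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ParamSpec, StudyConfig, param_specs
from .engine import build_trace, run_arm
from .outcomes import icer

__all__ = [
    "TornadoRow",
    "PSAResult",
    "owsa",
    "sample_param",
    "psa",
    "LAMBDA_GRID_STEP",
    "LAMBDA_GRID_MAX",
]

LAMBDA_GRID_STEP = 1000.0
LAMBDA_GRID_MAX = 120000.0


@dataclass
class TornadoRow:
    name: str
    icer_at_low: float
    icer_at_high: float

    @property
    def width(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def _deterministic_icer(cfg: StudyConfig, overrides: dict) -> float:
    arm1, arm0 = cfg.arms(overrides)
    settings = cfg.settings(overrides)
    utilities = cfg.utilities(overrides)
    r1 = run_arm(arm1, utilities, settings)
    r0 = run_arm(arm0, utilities, settings)
    value, flag = icer(r1.cost, r0.cost, r1.qalys, r0.qalys)
    return value if flag == "tradeoff" else np.nan


def owsa(cfg: StudyConfig, specs: list[ParamSpec] | None = None) -> list[TornadoRow]:
    """One-way sensitivity: ICER at each parameter's low and high limit,
    all other parameters at baseline, sorted by descending swing."""
    if specs is None:
        specs = param_specs(cfg)
    rows = []
    for spec in specs:
        lo = _deterministic_icer(cfg, {spec.name: spec.low})
        hi = _deterministic_icer(cfg, {spec.name: spec.high})
        rows.append(TornadoRow(spec.name, lo, hi))
    rows.sort(key=lambda r: -(r.width if np.isfinite(r.width) else -np.inf))
    return rows


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


def _spec_sd(spec: ParamSpec, sd_rule: str = "range95") -> float:
    if sd_rule == "range95":
        return (spec.high - spec.low) / (2.0 * 1.96)
    if sd_rule == "range4":
        return (spec.high - spec.low) / 4.0
    raise ValueError(f"unknown sd_rule {sd_rule!r}")


def sample_param(
    spec: ParamSpec, rng: np.random.Generator, n: int = 1, sd_rule: str = "range95"
) -> np.ndarray:
    """Moment-matched draws: mean = baseline, sd from the range.

    Gamma uses shape = (m/sd)^2, rate = m/sd^2; beta uses method-of-moments
    on (m, sd), with the variance shrunk when it exceeds the feasible
    m(1-m) bound so the beta remains proper.  Zero spread (or a ``fixed``
    family) returns the baseline.
    """
    m = spec.baseline
    sd = _spec_sd(spec, sd_rule)
    if spec.psa_family == "fixed" or sd <= 0 or m == 0:
        return np.full(n, m)
    if spec.psa_family == "gamma":
        shape = (m / sd) ** 2
        scale = sd**2 / m
        return rng.gamma(shape, scale, size=n)
    # beta
    v = min(sd**2, 0.95 * m * (1.0 - m))
    common = m * (1.0 - m) / v - 1.0
    a = max(m * common, 1e-6)
    b = max((1.0 - m) * common, 1e-6)
    return rng.beta(a, b, size=n)


@dataclass
class PSAResult:
    """Joint parameter draws with per-arm outcomes and the CEAC."""

    draws: pd.DataFrame  # cost1, qalys1, cost0, qalys0, delta_cost, delta_qalys
    ceac: pd.DataFrame  # columns: lam, probability
    wtp: float
    seed: int

    @property
    def n(self) -> int:
        return len(self.draws)

    def ceac_at(self, lam: float) -> float:
        """Fraction of draws with positive incremental net benefit at lam."""
        inmb = self.draws["delta_qalys"].to_numpy() * lam - self.draws["delta_cost"].to_numpy()
        return float(np.mean(inmb > 0))


class _ArmExposures:
    """Static occupancy functionals for one arm (survival held fixed).

    Each accrual category reduces to ``dot(discount_vector, weights)`` with
    draw-independent weights, mirroring the cohort engine cycle by cycle.
    """

    def __init__(self, cfg: StudyConfig, name: str, settings):
        arm = cfg.arm(name)
        self.arm_raw = cfg.raw["arms"][name]
        trace = build_trace(arm, settings)
        K = trace.n_cycles
        self.t_years = np.arange(K + 1) * settings.cycle_years
        self.cycle_years = settings.cycle_years
        half = settings.half_cycle

        def start_of_cycle(x):
            v = np.zeros(K + 1)
            v[:-1] = x[:-1]
            return v

        def boundary(x):
            if not half:
                return start_of_cycle(x)
            w = np.ones(K + 1)
            w[0] = w[-1] = 0.5
            return x * w

        def shifted(x):  # increments attributed to the end boundary
            v = np.zeros(K + 1)
            v[1:] = x
            return v

        pfs, pd_, alive = trace.pfs, trace.pd, trace.alive
        self.w_pfs_state = boundary(pfs)
        self.w_pd_state = boundary(pd_)
        self.w_drug = {}
        for d in arm.drugs:
            v = np.zeros(K + 1)
            w = min(d.paid_cycles, K)
            v[:w] = pfs[:w]
            self.w_drug[d.name] = v
        v = np.zeros(K + 1)
        w = min(arm.chemo_cycles, K)
        v[:w] = pfs[:w]
        self.w_chemo = v
        v = np.zeros(K + 1)
        w_ab = min(arm.chemo_cycles + arm.antibody_cycles, K)
        if w_ab > w:
            v[w:w_ab] = pfs[w:w_ab]
        self.w_antibody = v
        self.w_lab = start_of_cycle(alive)
        ct = arm.monitoring.ct_cycles(K)
        v = np.zeros(K + 1)
        v[ct] = alive[ct]
        self.w_ct = v
        self.w_deaths = shifted(trace.incident_deaths)
        entrants = np.maximum(np.diff(pd_), 0.0)
        self.w_entrants = shifted(entrants)
        self.w_pd_occ = start_of_cycle(pd_)
        self.sub_mode = arm.subsequent.mode
        self.sub_n_cycles = arm.subsequent.n_cycles
        self.sub_components = list(self.arm_raw["subsequent"]["components"])


def psa(
    cfg: StudyConfig,
    specs: list[ParamSpec] | None = None,
    n: int = 10000,
    seed: int = 0,
    sd_rule: str | None = None,
) -> PSAResult:
    """Probabilistic sensitivity analysis with ``n`` joint parameter draws.

    Reproducible for a fixed seed; the CEAC is evaluated on a lambda grid of
    0 to 120,000 in steps of 1,000 plus the study threshold itself.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if specs is None:
        specs = param_specs(cfg)
    if sd_rule is None:
        sd_rule = cfg.raw.get("psa", {}).get("sd_rule", "range95")
    rng = np.random.default_rng(seed)
    values = {s.name: sample_param(s, rng, n, sd_rule) for s in specs}

    def v(name: str, default: float) -> np.ndarray:
        return values.get(name, np.full(n, default))

    settings = cfg.settings()
    r = v("discount_rate", settings.discount_rate)
    a1_name, a0_name = cfg.arm_names

    u_pfs = v("utility_pfs", cfg.raw["utilities"]["pfs"])
    u_pd = v("utility_pd", cfg.raw["utilities"]["pd"])

    out = {}
    for arm_name in (a1_name, a0_name):
        exp_ = _ArmExposures(cfg, arm_name, settings)
        DF = (1.0 + r[:, None]) ** (-exp_.t_years[None, :])  # (n, K+1)

        cost = np.zeros(n)
        for d in exp_.arm_raw["drugs"]:
            cost += v(f"cost_{d['name']}", cfg.raw["costs"][d["name"]]) * (DF @ exp_.w_drug[d["name"]])
        admin_chemo = v("cost_premedication", cfg.raw["costs"]["premedication"]) + v(
            "cost_infusion", cfg.raw["costs"]["infusion"]
        )
        cost += admin_chemo * (DF @ exp_.w_chemo)
        cost += v(
            "cost_secondary_premedication", cfg.raw["costs"]["secondary_premedication"]
        ) * (DF @ exp_.w_antibody)
        cost += v("cost_laboratory", cfg.raw["costs"]["laboratory"]) * (DF @ exp_.w_lab)
        cost += v("cost_ct", cfg.raw["costs"]["ct"]) * (DF @ exp_.w_ct)
        cost += v("cost_end_of_life", cfg.raw["costs"]["end_of_life"]) * (DF @ exp_.w_deaths)
        sub_cost = sum(
            v(f"cost_{c}", cfg.raw["costs"][c]) for c in exp_.sub_components
        )
        if exp_.sub_mode == "one_time":
            cost += sub_cost * exp_.sub_n_cycles * (DF @ exp_.w_entrants)
        else:
            cost += sub_cost * (DF @ exp_.w_pd_occ)

        ae_cost = np.zeros(n)
        ae_dis = np.zeros(n)
        for ae_name, ae in cfg.raw["adverse_events"].items():
            inc = v(f"incidence_{arm_name}_{ae_name}", ae["incidence"][arm_name])
            ae_cost += inc * v(f"cost_ae_{ae_name}", ae["cost"])
            ae_dis += inc * v(f"disutility_ae_{ae_name}", ae["disutility"])
        cost += ae_cost

        qalys = (
            u_pfs * (DF @ exp_.w_pfs_state) + u_pd * (DF @ exp_.w_pd_state)
        ) * exp_.cycle_years - ae_dis * exp_.cycle_years
        out[arm_name] = (cost, qalys)

    c1, q1 = out[a1_name]
    c0, q0 = out[a0_name]
    draws = pd.DataFrame(
        {
            "cost1": c1,
            "qalys1": q1,
            "cost0": c0,
            "qalys0": q0,
            "delta_cost": c1 - c0,
            "delta_qalys": q1 - q0,
        }
    )
    lams = np.unique(
        np.append(np.arange(0.0, LAMBDA_GRID_MAX + LAMBDA_GRID_STEP, LAMBDA_GRID_STEP), cfg.wtp)
    )
    d_c, d_e = draws["delta_cost"].to_numpy(), draws["delta_qalys"].to_numpy()
    prob = [(d_e * lam - d_c > 0).mean() for lam in lams]
    ceac = pd.DataFrame({"lam": lams, "probability": prob})
    return PSAResult(draws=draws, ceac=ceac, wtp=cfg.wtp, seed=seed)
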