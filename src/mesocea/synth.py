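"""Synthetic two-endpoint trial data and emulated curve digitization.

The generator produces coupled progression-free and overall survival times
from known parametric models, applies independent censoring, and can turn
the resulting records into digitized-looking KM step coordinates with an
at-risk table.  It stands in for trial report figures so that curve
reconstruction and model fitting can be exercised end to end against a
known truth.

Coupling: overall survival is drawn from its marginal distribution and a
latent progression time is drawn independently from the progression model;
PFS is the minimum of the two, so PFS <= OS holds surely for every subject.
The marginal PFS distribution therefore deviates slightly from the supplied
progression model (documented in the methods note) -- an acceptable price
for preserving the ordering the cohort engine itself enforces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter

from .distributions import ParametricModel, sample
from .km import DigitizedKM, PseudoIPD

__all__ = ["SyntheticScenario", "ArmIPD", "generate_trial", "digitize"]


@dataclass
class SyntheticScenario:
    """Study conditions for one synthetic two-arm trial."""

    os_models: dict[str, ParametricModel]  # arm name -> OS model
    pfs_models: dict[str, ParametricModel]  # arm name -> progression model
    n_per_arm: int = 200
    admin_cutoff_months: float = 36.0
    dropout_rate: float = 0.1  # fraction with a uniform early-dropout time
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 10:
            raise ValueError("n_per_arm must be >= 10")
        if set(self.os_models) != set(self.pfs_models):
            raise ValueError("os_models and pfs_models must cover the same arms")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass
class ArmIPD:
    os: PseudoIPD
    pfs: PseudoIPD


def generate_trial(scn: SyntheticScenario) -> dict[str, ArmIPD]:
    """Simulate coupled (PFS, OS) records per arm with independent censoring."""
    rng = np.random.default_rng(scn.seed)
    out: dict[str, ArmIPD] = {}
    for arm in scn.os_models:
        n = scn.n_per_arm
        t_os = sample(scn.os_models[arm], n, rng)
        t_prog = sample(scn.pfs_models[arm], n, rng)
        t_pfs = np.minimum(t_prog, t_os)

        cutoff = np.full(n, scn.admin_cutoff_months)
        if scn.dropout_rate > 0:
            drops = rng.uniform(size=n) < scn.dropout_rate
            t_drop = rng.uniform(0, scn.admin_cutoff_months, size=n)
            cutoff = np.where(drops, np.minimum(cutoff, t_drop), cutoff)

        os_ipd = PseudoIPD(np.minimum(t_os, cutoff), (t_os <= cutoff).astype(int))
        pfs_ipd = PseudoIPD(np.minimum(t_pfs, cutoff), (t_pfs <= cutoff).astype(int))
        out[arm] = ArmIPD(os=os_ipd, pfs=pfs_ipd)
    return out


def digitize(
    ipd: PseudoIPD,
    anchor_spacing: float = 3.0,
    round_decimals: int | None = 3,
) -> DigitizedKM:
    """Turn records into KM step coordinates plus an at-risk table.

    Mimics figure digitization: the product-limit curve is evaluated at its
    step times (optionally rounded to 3 decimals, the typical extraction
    precision), and the number at risk is tabulated at regular anchors.
    """
    if ipd.n == 0:
        raise ValueError("cannot digitize an empty dataset")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.times, ipd.events)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    if round_decimals is not None:
        surv = np.minimum.accumulate(np.round(surv, round_decimals))

    t_max = float(ipd.times.max())
    anchors = np.arange(0.0, t_max + anchor_spacing, anchor_spacing)
    # number still at risk = subjects with follow-up time >= anchor
    n_risk = np.array([(ipd.times >= a).sum() for a in anchors], dtype=int)
    keep = n_risk > 0
    keep[0] = True
    return DigitizedKM(
        times=times,
        surv=surv,
        risk_times=anchors[keep],
        n_risk=n_risk[keep],
        total_events=ipd.n_events,
    )
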