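"""Incremental cost-effectiveness statistics.

ICER = (C1 - C0) / (E1 - E0); at willingness-to-pay λ, the incremental net
health benefit is INHB = ΔE - ΔC/λ (QALYs) and the incremental net
monetary benefit is INMB = ΔE·λ - ΔC (currency units), so INMB = INHB·λ
identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["WTP_DEFAULT", "CEAResult", "icer", "net_benefit", "compare", "results_table"]

#: three times China's 2023 per-capita GDP, USD per QALY
WTP_DEFAULT = 38042.49

_TIE_EPS = 1e-9


@dataclass
class CEAResult:
    """Pairwise comparison of a new strategy (1) against a comparator (0)."""

    label: str
    cost1: float
    qalys1: float
    cost0: float
    qalys0: float
    wtp: float = WTP_DEFAULT

    @property
    def delta_cost(self) -> float:
        return self.cost1 - self.cost0

    @property
    def delta_qalys(self) -> float:
        return self.qalys1 - self.qalys0

    @property
    def icer(self) -> float | None:
        value, flag = icer(self.cost1, self.cost0, self.qalys1, self.qalys0)
        return value if flag == "tradeoff" else None

    @property
    def dominance(self) -> str:
        return icer(self.cost1, self.cost0, self.qalys1, self.qalys0)[1]

    @property
    def inhb(self) -> float:
        return net_benefit(self.delta_cost, self.delta_qalys, self.wtp)[0]

    @property
    def inmb(self) -> float:
        return net_benefit(self.delta_cost, self.delta_qalys, self.wtp)[1]


def icer(c1: float, c0: float, e1: float, e0: float) -> tuple[float | None, str]:
    """Incremental cost-effectiveness ratio with dominance classification.

    Returns ``(value, flag)``; the value is None when the ratio is not
    meaningful.  Flags: ``tradeoff`` (ordinary ratio), ``dominant`` (cheaper
    and more effective), ``dominated`` (costlier and less effective),
    ``undefined`` (effect difference numerically zero).
    """
    d_c, d_e = c1 - c0, e1 - e0
    if abs(d_e) < _TIE_EPS:
        return None, "undefined"
    if d_e > 0 and d_c < 0:
        return None, "dominant"
    if d_e < 0 and d_c > 0:
        return None, "dominated"
    return d_c / d_e, "tradeoff"


def net_benefit(delta_cost: float, delta_qalys: float, wtp: float) -> tuple[float, float]:
    """(INHB, INMB) at willingness-to-pay ``wtp`` from unrounded increments."""
    if wtp <= 0:
        raise ValueError("willingness-to-pay must be positive")
    inhb = delta_qalys - delta_cost / wtp
    inmb = delta_qalys * wtp - delta_cost
    return inhb, inmb


def compare(result1, result0, wtp: float = WTP_DEFAULT, label: str = "") -> CEAResult:
    """Build a :class:`CEAResult` from two engine arm results."""
    return CEAResult(
        label=label or f"{result1.name} vs {result0.name}",
        cost1=result1.cost,
        qalys1=result1.qalys,
        cost0=result0.cost,
        qalys0=result0.qalys,
        wtp=wtp,
    )


def results_table(results: list[tuple[str, "CEAResult"]]) -> pd.DataFrame:
    """Base-case results in the standard two-row-per-comparison layout:
    cost, QALY, incremental cost, incremental QALY, INHB, INMB, ICER."""
    rows = []
    for name1_label, r in results:
        rows.append(
            {
                "treatment": name1_label,
                "cost": r.cost1,
                "qaly": r.qalys1,
                "incremental_cost": r.delta_cost,
                "incremental_qaly": r.delta_qalys,
                "inhb": r.inhb,
                "inmb": r.inmb,
                "icer": r.icer if r.icer is not None else r.dominance,
            }
        )
        rows.append(
            {
                "treatment": f"{name1_label} comparator",
                "cost": r.cost0,
                "qaly": r.qalys0,
                "incremental_cost": None,
                "incremental_qaly": None,
                "inhb": None,
                "inmb": None,
                "icer": None,
            }
        )
    return pd.DataFrame(rows)
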