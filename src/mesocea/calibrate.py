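"""Calibration of the subsequent-treatment duration.

The trial reports which post-progression regimens were assumed but not how
long patients received them.  The duration (in cycles) of the one-time
post-progression bundle is therefore the single free quantity per arm; it
is calibrated so the arm's total discounted cost reproduces the published
base-case total for the whole population.  The calibrated values ship in
the package configs and are held fixed -- including for the histology
subgroups, whose follow-up treatment is assumed identical to the whole
population.
"""

from __future__ import annotations

from scipy import optimize

from .config import StudyConfig
from .engine import run_arm

__all__ = ["calibrate_subsequent_cycles"]


def calibrate_subsequent_cycles(
    cfg: StudyConfig, target_costs: dict[str, float] | None = None, max_cycles: float = 40.0
) -> dict[str, float]:
    """Solve, per arm, for the subsequent-treatment duration (cycles) that
    reproduces the target total discounted cost.

    Targets default to each arm's ``calibration.target_total_cost`` entry.
    Returns ``{arm_name: n_cycles}`` without mutating the config.
    """
    settings = cfg.settings()
    utilities = cfg.utilities()
    out: dict[str, float] = {}
    for name in cfg.arm_names:
        if target_costs is not None:
            target = target_costs[name]
        else:
            cal = cfg.raw["arms"][name].get("calibration", {})
            if "target_total_cost" not in cal:
                raise ValueError(f"arm {name!r} has no calibration target")
            target = float(cal["target_total_cost"])

        def gap(n_cycles: float) -> float:
            trial = cfg.copy()
            trial.raw["arms"][name]["subsequent"]["n_cycles"] = float(n_cycles)
            res = run_arm(trial.arm(name), utilities, settings)
            return res.cost - target

        lo, hi = 0.0, max_cycles
        if gap(lo) > 0:
            raise ValueError(
                f"arm {name!r}: fixed costs alone exceed the target total "
                f"({gap(lo):+.2f} USD at zero subsequent treatment)"
            )
        if gap(hi) < 0:
            raise ValueError(f"arm {name!r}: target not reachable within {max_cycles} cycles")
        out[name] = float(optimize.brentq(gap, lo, hi, xtol=1e-6))
    return out
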