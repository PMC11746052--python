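"""Pseudo individual-patient data from digitized Kaplan-Meier curves.

Published trial reports provide only the KM survival steps and the
number-at-risk table printed beneath the figure.  The reconstruction
implemented here redistributes events and (assumed-uniform) censorings
within each at-risk interval until the implied at-risk counts match the
printed table and the product-limit curve matches the digitized steps --
the standard iterative algorithm used throughout health-technology
assessment.  The reconstructed records can then be fitted by maximum
likelihood under each candidate parametric family and ranked by AIC/BIC.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize

from .distributions import (
    FAMILIES,
    PARAM_NAMES,
    ParametricModel,
    density,
    survival,
)

__all__ = [
    "DigitizedKM",
    "PseudoIPD",
    "FamilyFit",
    "FitReport",
    "reconstruct_ipd",
    "fit_mle",
    "fit_all",
    "information_criteria",
    "select_best",
    "read_km_csv",
    "write_ipd_csv",
]

#: tolerance for digitization noise on survival monotonicity; larger
#: violations are rejected, smaller ones are clamped.
MONOTONICITY_TOL = 1e-3


@dataclass
class DigitizedKM:
    """Digitized KM step coordinates plus the number-at-risk table."""

    times: np.ndarray  # step times, months
    surv: np.ndarray  # survival at each step, starting at 1
    risk_times: np.ndarray  # anchor times of the at-risk table
    n_risk: np.ndarray  # patients at risk at each anchor
    total_events: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.surv = np.asarray(self.surv, dtype=float)
        self.risk_times = np.asarray(self.risk_times, dtype=float)
        self.n_risk = np.asarray(self.n_risk, dtype=int)
        if self.times.shape != self.surv.shape:
            raise ValueError("times and surv must have equal length")
        if len(self.risk_times) < 2:
            raise ValueError("at least two at-risk anchors are required")
        if np.any(np.diff(self.times) < 0) or np.any(np.diff(self.risk_times) < 0):
            raise ValueError("times must be non-decreasing")
        if np.any(np.diff(self.n_risk) > 0):
            raise ValueError("at-risk counts must be non-increasing")
        if np.any(self.n_risk < 0) or self.n_risk[0] < 1:
            raise ValueError("at-risk counts must be positive at baseline")
        if np.any((self.surv < -MONOTONICITY_TOL) | (self.surv > 1 + MONOTONICITY_TOL)):
            raise ValueError("survival probabilities must lie in [0, 1]")
        rises = np.diff(self.surv)
        if np.any(rises > MONOTONICITY_TOL):
            raise ValueError(
                "survival increases beyond digitization tolerance "
                f"({MONOTONICITY_TOL}); check the digitized coordinates"
            )
        # clamp sub-tolerance digitization noise
        self.surv = np.minimum.accumulate(np.clip(self.surv, 0.0, 1.0))
        if self.times[0] != 0.0:
            self.times = np.insert(self.times, 0, 0.0)
            self.surv = np.insert(self.surv, 0, 1.0)


@dataclass
class PseudoIPD:
    """Reconstructed individual records: time in months and event flag."""

    times: np.ndarray
    events: np.ndarray  # 1 = event, 0 = censored

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if np.any(self.times < 0):
            raise ValueError("times must be non-negative")
        if self.times.shape != self.events.shape:
            raise ValueError("times and events must have equal length")

    @property
    def n(self) -> int:
        return len(self.times)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())


def reconstruct_ipd(km: DigitizedKM) -> PseudoIPD:
    """Reconstruct pseudo-IPD from digitized steps and the at-risk table.

    Within each interval between at-risk anchors, censoring times are
    assumed uniformly distributed.  The censor count per interval is
    adjusted iteratively until the implied number at risk at the next
    anchor matches the printed table; events at each digitized step are
    chosen so the product-limit estimate tracks the digitized survival.
    Deterministic given the input.
    """
    t = km.times
    S = km.surv
    rt, nr = km.risk_times, km.n_risk
    n_coord = len(t)

    # first coordinate index of each at-risk interval (may equal n_coord when
    # the curve is not digitized beyond the final anchors)
    lower = np.searchsorted(t, rt, side="left")
    # last coordinate at or before each anchor, for survival-ratio guesses
    at_anchor = np.clip(np.searchsorted(t, rt, side="right") - 1, 0, n_coord - 1)

    n_int = len(rt) - 1
    times_out: list[float] = []
    events_out: list[int] = []

    n_hat = np.zeros(n_coord + 1)
    km_hat = np.ones(n_coord)
    d = np.zeros(n_coord, dtype=int)
    cen = np.zeros(n_coord, dtype=int)
    n_hat[0] = nr[0]
    last_event_idx = 0

    for i in range(n_int + 1):
        lo = lower[i]
        lei = last_event_idx
        if i < n_int:
            hi = lower[i + 1] - 1
            if hi < lo:
                continue
        else:
            hi = n_coord - 1
            if hi < lo:
                break
        interval_len = (rt[i + 1] - rt[i]) if i < n_int else (t[hi] - rt[i])

        if i < n_int:
            # initial censor guess: expected at-risk decline not explained by events
            if S[at_anchor[i]] > 0:
                n_cen = int(round(n_hat[lo] * S[at_anchor[i + 1]] / S[at_anchor[i]])) - nr[i + 1]
            else:
                n_cen = 0
        elif km.total_events is not None:
            n_cen = 0  # refined after the pass via the total-event constraint
        else:
            n_cen = 0
        n_cen = max(n_cen, 0)

        for _ in range(60):
            # distribute censor times uniformly over the interval
            if n_cen > 0 and interval_len > 0:
                cen_times = rt[i] + (np.arange(1, n_cen + 1) - 0.5) / n_cen * interval_len
            else:
                cen_times = np.empty(0)
            # censors falling after each coordinate step
            edges = np.append(t[lo : hi + 1], rt[i + 1] if i < n_int else np.inf)
            counts = np.histogram(cen_times, bins=edges)[0] if n_cen > 0 else np.zeros(hi - lo + 1, int)

            n_cur = n_hat[lo]
            lei = last_event_idx
            for j, k in enumerate(range(lo, hi + 1)):
                if k == 0:
                    d[k] = 0
                else:
                    if km_hat[lei] > 0 and n_cur > 0:
                        d[k] = int(round(n_cur * (1.0 - S[k] / km_hat[lei])))
                        d[k] = min(max(d[k], 0), int(n_cur))
                    else:
                        d[k] = 0
                if n_cur > 0 and d[k] > 0:
                    km_hat[k] = km_hat[lei] * (1.0 - d[k] / n_cur)
                    lei = k
                else:
                    km_hat[k] = km_hat[lei]
                cen[k] = counts[j]
                n_next = n_cur - d[k] - cen[k]
                n_cur = max(n_next, 0)
                n_hat[k + 1] = n_cur
            if i >= n_int:
                break
            gap = int(n_cur - nr[i + 1])
            if gap == 0:
                break
            n_cen = max(n_cen + gap, 0)
        last_event_idx = lei

    if km.total_events is not None:
        # reconcile the overall event count by converting tail events/censors
        excess = int(d.sum()) - int(km.total_events)
        if excess > 0:
            for k in range(n_coord - 1, -1, -1):
                take = min(excess, d[k])
                d[k] -= take
                cen[k] += take
                excess -= take
                if excess == 0:
                    break

    for k in range(n_coord):
        times_out.extend([t[k]] * int(d[k]))
        events_out.extend([1] * int(d[k]))
        if cen[k] > 0:
            # censors occurred between this coordinate and the next
            nxt = t[k + 1] if k + 1 < n_coord else t[k]
            spread = np.linspace(t[k], nxt, int(cen[k]) + 2)[1:-1] if nxt > t[k] else [t[k]] * int(cen[k])
            times_out.extend(np.atleast_1d(spread).tolist())
            events_out.extend([0] * int(cen[k]))
    # patients still at risk past the last coordinate are censored there
    remaining = int(n_hat[n_coord])
    if remaining > 0:
        times_out.extend([t[-1]] * remaining)
        events_out.extend([0] * remaining)
    return PseudoIPD(np.array(times_out), np.array(events_out))


# ---------------------------------------------------------------------------
# maximum-likelihood fitting


def _neg_loglik(theta, family, t_event, t_cens):
    model = _model_from_vector(family, theta)
    if model is None:
        return 1e10
    with np.errstate(all="ignore"):
        ll = 0.0
        if len(t_event):
            f = density(model, t_event)
            if np.any(f <= 0) or np.any(~np.isfinite(f)):
                return 1e10
            ll += np.log(f).sum()
        if len(t_cens):
            s = survival(model, t_cens)
            if np.any(s <= 0) or np.any(~np.isfinite(s)):
                return 1e10
            ll += np.log(s).sum()
    if not np.isfinite(ll):
        return 1e10
    return -ll


def _model_from_vector(family, theta):
    """Map an unconstrained optimizer vector to a valid model (log scale for
    positive parameters), or None when outside the admissible region."""
    names = PARAM_NAMES[family]
    params = {}
    for name, x in zip(names, theta):
        if name in ("mu", "meanlog", "Q"):
            params[name] = float(x)
        else:
            if x > 50 or x < -50:
                return None
            params[name] = float(np.exp(x))
    try:
        return ParametricModel(family, params)
    except ValueError:
        return None


def _vector_from_params(family, params):
    return np.array(
        [
            params[n] if n in ("mu", "meanlog", "Q") else np.log(params[n])
            for n in PARAM_NAMES[family]
        ]
    )


def _starting_points(family, times, events):
    """Moment-based, median-based and perturbed initial values."""
    pos = times[times > 0]
    if len(pos) == 0:
        pos = np.array([1.0])
    logs = np.log(pos)
    m, s = float(np.mean(logs)), float(np.std(logs) + 1e-3)
    med = float(np.median(pos))
    mean = float(np.mean(pos))
    rate = max(events.sum(), 1) / times.sum() if times.sum() > 0 else 1.0

    if family == "exponential":
        starts = [{"rate": rate}, {"rate": np.log(2.0) / med}]
    elif family in ("weibull_aft", "loglogistic"):
        shape = min(max((np.pi / np.sqrt(3.0)) / s, 0.2), 20.0)
        starts = [{"shape": shape, "scale": np.exp(m)}, {"shape": 1.0, "scale": mean}]
    elif family == "weibull_ph":
        shape = min(max((np.pi / np.sqrt(3.0)) / s, 0.2), 20.0)
        starts = [
            {"shape": shape, "rate": np.exp(m) ** -shape},
            {"shape": 1.0, "rate": rate},
        ]
    elif family == "gamma":
        v = float(np.var(pos)) + 1e-6
        starts = [
            {"shape": mean**2 / v, "rate": mean / v},
            {"shape": 1.0, "rate": rate},
        ]
    elif family == "gompertz":
        starts = [
            {"shape": 0.05, "rate": rate},
            {"shape": 0.01, "rate": np.log(2.0) / med},
        ]
    elif family == "lognormal":
        starts = [{"meanlog": m, "sdlog": s}, {"meanlog": np.log(med), "sdlog": 1.0}]
    else:  # gengamma_prentice
        starts = [
            {"mu": m, "sigma": s, "Q": 1.0},
            {"mu": np.log(med), "sigma": s, "Q": -0.5},
        ]
    out = [_vector_from_params(family, p) for p in starts]
    rng = np.random.default_rng(0)
    out.append(out[0] + rng.normal(scale=0.3, size=out[0].shape))
    return out


def fit_mle(ipd: PseudoIPD, family: str) -> tuple[ParametricModel, float]:
    """Maximum-likelihood fit of one family to (possibly censored) records.

    The likelihood is the usual right-censored one, ``sum(log f)`` over
    events plus ``sum(log S)`` over censored records, maximized by
    multi-start quasi-Newton optimization on log-transformed positive
    parameters.  Returns the best local optimum and its log-likelihood.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if ipd.n < 10:
        raise ValueError("at least 10 records are required")
    if ipd.n_events < 1:
        raise ValueError("at least one event is required")
    t_event = ipd.times[ipd.events == 1]
    t_cens = ipd.times[ipd.events == 0]
    # zero times contribute no likelihood information under continuous models
    t_event = np.maximum(t_event, 1e-6)

    if family == "exponential" and len(t_cens) == 0:
        rate = len(t_event) / t_event.sum()  # closed-form MLE
        model = ParametricModel("exponential", {"rate": rate})
        return model, -_neg_loglik(np.array([np.log(rate)]), family, t_event, t_cens)

    best = None
    for x0 in _starting_points(family, ipd.times, ipd.events):
        res = optimize.minimize(
            _neg_loglik,
            x0,
            args=(family, t_event, t_cens),
            method="L-BFGS-B",
            options={"maxiter": 500, "gtol": 1e-8, "ftol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    model = _model_from_vector(family, best.x)
    if model is None or best.fun >= 1e9:
        raise RuntimeError(f"MLE for family {family!r} did not converge")
    return model, -float(best.fun)


def information_criteria(loglik: float, k: int, n: int) -> tuple[float, float]:
    """AIC = 2k - 2 lnL and BIC = k ln(n) - 2 lnL."""
    if n < 1 or k < 1:
        raise ValueError("k and n must be >= 1")
    return 2.0 * k - 2.0 * loglik, k * np.log(n) - 2.0 * loglik


@dataclass
class FamilyFit:
    family: str
    model: ParametricModel | None
    loglik: float
    k: int
    aic: float
    bic: float
    converged: bool


@dataclass
class FitReport:
    """Per-family fits with information criteria and the selected families."""

    fits: dict[str, FamilyFit] = field(default_factory=dict)
    n: int = 0

    @property
    def converged(self) -> list[FamilyFit]:
        return [f for f in self.fits.values() if f.converged]

    @property
    def best_aic(self) -> str:
        return select_best(self)

    @property
    def best_bic(self) -> str:
        fits = self.converged
        if not fits:
            raise ValueError("no converged fits in report")
        return min(fits, key=lambda f: (f.bic, f.aic, f.k)).family

    def to_rows(self) -> list[dict]:
        return [
            {
                "family": f.family,
                "loglik": f.loglik,
                "k": f.k,
                "aic": f.aic,
                "bic": f.bic,
                "converged": f.converged,
                **({f"param_{k}": v for k, v in f.model.params.items()} if f.model else {}),
            }
            for f in self.fits.values()
        ]


def select_best(report: FitReport) -> str:
    """Lowest AIC; ties broken by lower BIC, then fewer parameters."""
    fits = report.converged
    if not fits:
        raise ValueError("no converged fits in report")
    return min(fits, key=lambda f: (f.aic, f.bic, f.k)).family


def fit_all(ipd: PseudoIPD, families=FAMILIES) -> FitReport:
    """Fit every candidate family and tabulate AIC/BIC."""
    report = FitReport(n=ipd.n)
    for family in families:
        k = len(PARAM_NAMES[family])
        try:
            model, ll = fit_mle(ipd, family)
            aic, bic = information_criteria(ll, k, ipd.n)
            report.fits[family] = FamilyFit(family, model, ll, k, aic, bic, True)
        except (RuntimeError, ValueError):
            report.fits[family] = FamilyFit(family, None, -np.inf, k, np.inf, np.inf, False)
    return report


# ---------------------------------------------------------------------------
# CSV interfaces


def read_km_csv(points_path, risk_path, total_events: int | None = None) -> DigitizedKM:
    """Read digitized coordinates (time,survival) and a risk table (time,n_at_risk)."""
    pts = np.loadtxt(points_path, delimiter=",", skiprows=1, ndmin=2)
    risk = np.loadtxt(risk_path, delimiter=",", skiprows=1, ndmin=2)
    return DigitizedKM(
        times=pts[:, 0],
        surv=pts[:, 1],
        risk_times=risk[:, 0],
        n_risk=risk[:, 1].astype(int),
        total_events=total_events,
    )


def write_ipd_csv(ipd: PseudoIPD, path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time", "event"])
        for t, e in zip(ipd.times, ipd.events):
            w.writerow([f"{t:.6g}", int(e)])
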