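"""Pseudo individual-patient data: simulation, Kaplan-Meier artifacts,
curve-coordinate inversion, and parametric refitting.

This stage emulates the upstream provenance of the survival inputs: published
trial curves are digitized into step coordinates plus numbers at risk, turned
back into hypothetical individual patient data (a Guyot-style inversion), and
refitted with six candidate parametric families, the best by information
criterion driving the cohort model. Here the "digitized" artifacts are
generated from known log-logistic truth with administrative censoring, so the
whole loop can be validated against the parameters it started from.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import optimize

from .params import SurvivalParams
from .survival import FAMILIES, ParametricCurve

__all__ = [
    "PseudoIPD",
    "KMArtifact",
    "FamilyFit",
    "FitReport",
    "simulate_ipd",
    "km_estimate",
    "reconstruct_ipd",
    "fit_family",
    "select_distribution",
    "fit_all_families",
    "pipeline",
]


@dataclass
class PseudoIPD:
    """Right-censored event times for one arm/endpoint."""

    time: np.ndarray          # months, > 0
    event: np.ndarray         # 1 = event, 0 = censored
    arm: str = ""
    endpoint: str = ""        # "OS" or "PFS"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape:
            raise ValueError("time and event must have the same length")
        if np.any(self.time <= 0):
            raise ValueError("all times must be > 0")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.time, "event": self.event,
             "arm": self.arm, "endpoint": self.endpoint}
        )


@dataclass
class KMArtifact:
    """What figure digitization yields: step coordinates + risk table."""

    times: np.ndarray         # step (event) times, increasing
    survival: np.ndarray      # product-limit value just after each step
    checkpoints: np.ndarray   # risk-table times, increasing, starting at 0
    n_risk: np.ndarray        # subjects at risk at each checkpoint
    n_total: int
    max_time: float           # end of follow-up (last observed time)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        self.checkpoints = np.asarray(self.checkpoints, dtype=float)
        self.n_risk = np.asarray(self.n_risk, dtype=int)
        if np.any((self.survival < 0) | (self.survival > 1)):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival probabilities must be non-increasing")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("step times must be strictly increasing")
        if np.any(np.diff(self.n_risk) > 0):
            raise ValueError("numbers at risk must be non-increasing over time")

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of the curve."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def simulate_ipd(
    truth: SurvivalParams,
    n: int,
    censor_time: float,
    seed: int,
    arm: str = "",
    endpoint: str = "",
) -> PseudoIPD:
    """Draw right-censored log-logistic event times.

    Inverse transform of S(t) = 1/(1 + lam t^gamma): t = ((1-u)/(lam u))^(1/gamma)
    with u ~ Uniform(0,1), then administrative censoring at ``censor_time``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if censor_time <= 0:
        raise ValueError("censor_time must be > 0")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    t = ((1.0 - u) / (truth.lam * u)) ** (1.0 / truth.gamma)
    event = (t <= censor_time).astype(int)
    time = np.minimum(t, censor_time)
    return PseudoIPD(time=time, event=event, arm=arm, endpoint=endpoint)


def km_estimate(
    ipd: PseudoIPD, checkpoints: Optional[Sequence[float]] = None
) -> KMArtifact:
    """Product-limit estimate with numbers at risk at requested checkpoints.

    Default checkpoints are monthly from 0 through the last observed time
    (the spacing a published risk table typically uses).
    """
    if ipd.n == 0:
        raise ValueError("empty dataset")
    max_time = float(ipd.time.max())
    if checkpoints is None:
        checkpoints = np.arange(0.0, math.floor(max_time) + 1.0)
    checkpoints = np.asarray(checkpoints, dtype=float)

    if ipd.n_events == 0:
        import warnings

        warnings.warn("all observations censored; curve is flat at 1.0")
        times = np.empty(0)
        surv = np.empty(0)
    else:
        kmf = KaplanMeierFitter()
        kmf.fit(ipd.time, ipd.event)
        table = kmf.event_table
        sf = kmf.survival_function_.iloc[:, 0]
        mask = table["observed"] > 0
        times = table.index.to_numpy(dtype=float)[mask.to_numpy()]
        surv = sf.loc[mask].to_numpy(dtype=float)

    n_risk = np.array([int(np.sum(ipd.time >= t)) for t in checkpoints])
    return KMArtifact(
        times=times, survival=surv, checkpoints=checkpoints,
        n_risk=n_risk, n_total=ipd.n, max_time=max_time,
    )


def reconstruct_ipd(
    km: KMArtifact, n_total: Optional[int] = None, arm: str = "", endpoint: str = ""
) -> PseudoIPD:
    """Invert step coordinates + risk table back to individual patient data.

    Within each inter-checkpoint interval the number of censored subjects is
    found iteratively so that the running at-risk count matches the risk
    table at the next checkpoint; censoring times are spread uniformly over
    the interval, and event counts at each step are chosen so the re-estimated
    product-limit curve tracks the input steps. After the last checkpoint no
    risk information remains: steps are processed without interior censoring
    and the residual cohort is administratively censored at end of follow-up.
    """
    if n_total is None:
        n_total = km.n_total
    ck = km.checkpoints
    if len(ck) == 0 or ck[0] != 0.0:
        raise ValueError("checkpoints must start at time 0")
    if km.n_risk[0] != n_total:
        raise ValueError(
            f"at-risk count at time 0 ({km.n_risk[0]}) must equal arm size ({n_total})"
        )

    event_times: list[float] = []
    censor_times: list[float] = []

    def process(n_at_risk: float, s_running: float, steps, censors):
        """Walk one interval's steps/censors in time order."""
        merged = sorted(
            [(t, "e", s) for t, s in steps] + [(t, "c", None) for t in censors]
        )
        n = n_at_risk
        s_hat = s_running
        for t, kind, s_target in merged:
            if kind == "c":
                if n > 0:
                    censor_times.append(t)
                    n -= 1
            else:
                if n <= 0 or s_hat <= 0:
                    continue
                d = int(round(n * (1.0 - s_target / s_hat)))
                d = max(0, min(d, int(n)))
                if d > 0:
                    event_times.extend([t] * d)
                    s_hat *= 1.0 - d / n
                    n -= d
        return n, s_hat

    n_cur: float = float(n_total)
    s_run = 1.0
    for i in range(len(ck) - 1):
        lo, hi = ck[i], ck[i + 1]
        in_iv = (km.times >= lo) & (km.times < hi)
        steps = list(zip(km.times[in_iv], km.survival[in_iv]))
        target = float(km.n_risk[i + 1])

        best: Optional[tuple[float, int]] = None
        c_guess = 0
        for _ in range(40):
            saved = (list(event_times), list(censor_times))
            censors = [lo + (j + 0.5) * (hi - lo) / c_guess for j in range(c_guess)]
            n_end, s_end = process(n_cur, s_run, steps, censors)
            diff = n_end - target
            if best is None or abs(diff) < best[0]:
                best = (abs(diff), c_guess)
            if diff == 0:
                best = (0.0, c_guess)
                event_times, censor_times = saved
                break
            event_times, censor_times = saved
            c_new = c_guess + int(diff)
            if c_new == c_guess or c_new < 0:
                break
            c_guess = c_new
        # commit with the best censoring count found
        c_best = best[1] if best else 0
        censors = [lo + (j + 0.5) * (hi - lo) / c_best for j in range(c_best)]
        n_cur, s_run = process(n_cur, s_run, steps, censors)

    # tail beyond the last checkpoint: events only, then administrative censoring
    tail = km.times >= ck[-1]
    steps = list(zip(km.times[tail], km.survival[tail]))
    n_cur, s_run = process(n_cur, s_run, steps, [])
    if n_cur > 0:
        censor_times.extend([max(km.max_time, float(ck[-1]))] * int(round(n_cur)))

    time = np.concatenate([np.asarray(event_times), np.asarray(censor_times)])
    event = np.concatenate(
        [np.ones(len(event_times), dtype=int), np.zeros(len(censor_times), dtype=int)]
    )
    order = np.argsort(time, kind="stable")
    return PseudoIPD(time=time[order], event=event[order], arm=arm, endpoint=endpoint)


# ---------------------------------------------------------------------------
# Parametric fitting and model selection
# ---------------------------------------------------------------------------

@dataclass
class FamilyFit:
    family: str
    params: tuple[float, ...]
    loglik: float
    n_params: int
    converged: bool
    aic: float = field(init=False)
    bic: float = field(init=False)
    n_obs: int = 0

    def __post_init__(self) -> None:
        self.aic = 2 * self.n_params - 2 * self.loglik
        self.bic = (
            self.n_params * math.log(self.n_obs) - 2 * self.loglik
            if self.n_obs > 0
            else math.nan
        )

    def curve(self) -> ParametricCurve:
        return ParametricCurve(self.family, self.params)


@dataclass
class FitReport:
    fits: dict[str, FamilyFit]
    criterion: str
    selected: str

    def table(self) -> pd.DataFrame:
        rows = [
            {"family": f.family, "loglik": f.loglik, "aic": f.aic, "bic": f.bic,
             "converged": f.converged, "params": list(f.params)}
            for f in self.fits.values()
        ]
        return pd.DataFrame(rows).sort_values(self.criterion).reset_index(drop=True)


def _censored_negloglik(curve: ParametricCurve, t_event, t_censor) -> float:
    ll = float(np.sum(curve.log_density(t_event)))
    if len(t_censor):
        ll += float(np.sum(curve.log_survival(t_censor)))
    return -ll


def _initial_params(family: str, t_event: np.ndarray) -> tuple[float, ...]:
    logs = np.log(t_event)
    m = float(np.median(t_event))
    if family == "loglogistic":
        q25, q75 = np.quantile(t_event, [0.25, 0.75])
        gamma0 = math.log(9.0) / math.log(q75 / q25) if q75 > q25 else 1.5
        gamma0 = min(max(gamma0, 0.2), 10.0)
        return (gamma0, m ** (-gamma0))
    if family == "weibull":
        shape0 = min(max(math.pi / (math.sqrt(6.0) * max(logs.std(), 1e-3)), 0.2), 10.0)
        rate0 = math.exp(-(shape0 * logs.mean() + 0.5772))
        return (shape0, rate0)
    if family == "lognormal":
        return (float(logs.mean()), max(float(logs.std()), 1e-3))
    if family == "gamma":
        mean, var = float(t_event.mean()), float(t_event.var())
        shape0 = mean**2 / var if var > 0 else 1.0
        return (max(shape0, 0.05), max(shape0, 0.05) / mean)
    if family == "gompertz":
        return (0.05, 1.0 / float(t_event.mean()))
    return (1.0 / float(t_event.mean()),)


def fit_family(ipd: PseudoIPD, family: str) -> FamilyFit:
    """Maximize the right-censored log-likelihood for one family.

    sum_events log f(t) + sum_censored log S(t); positive parameters are
    optimized on the log scale (the Gompertz shape is unconstrained). The
    exponential rate has the closed form events / total follow-up time.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family '{family}'")
    if ipd.n_events < 1:
        raise ValueError("at least one event is required for fitting")
    t_event = ipd.time[ipd.event == 1]
    t_censor = ipd.time[ipd.event == 0]

    if family == "exponential":
        rate = len(t_event) / float(ipd.time.sum())
        ll = -_censored_negloglik(ParametricCurve("exponential", (rate,)), t_event, t_censor)
        return FamilyFit("exponential", (rate,), ll, 1, True, n_obs=ipd.n)

    x0 = _initial_params(family, t_event)
    if family == "gompertz":
        to_internal = lambda p: np.array([p[0], math.log(p[1])])
        from_internal = lambda x: (float(x[0]), float(math.exp(x[1])))
    else:
        to_internal = lambda p: np.log(np.asarray(p, dtype=float))
        from_internal = lambda x: tuple(float(v) for v in np.exp(x))

    def objective(x: np.ndarray) -> float:
        try:
            curve = ParametricCurve(family, from_internal(x))
        except (ValueError, OverflowError):
            return 1e12
        with np.errstate(all="ignore"):
            nll = _censored_negloglik(curve, t_event, t_censor)
        return nll if np.isfinite(nll) else 1e12

    res = optimize.minimize(
        objective, to_internal(x0), method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
    )
    params = from_internal(res.x)
    ll = -objective(res.x)
    converged = bool(res.success and np.isfinite(ll))
    return FamilyFit(family, params, ll, len(params), converged, n_obs=ipd.n)


def fit_all_families(
    ipd: PseudoIPD, families: Sequence[str] = FAMILIES
) -> dict[str, FamilyFit]:
    fits = {}
    for family in families:
        try:
            fits[family] = fit_family(ipd, family)
        except (ValueError, FloatingPointError):
            continue
    return fits


def select_distribution(
    fits: dict[str, FamilyFit], criterion: str = "aic"
) -> FitReport:
    """Pick the family minimizing AIC (default) or BIC.

    Non-converged fits are excluded; exact ties are broken by the documented
    family ordering (log-logistic first, exponential last).
    """
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    converged = {k: f for k, f in fits.items() if f.converged}
    if not converged:
        raise ValueError("no converged fits to select from")
    order = {fam: i for i, fam in enumerate(FAMILIES)}
    selected = min(converged.values(), key=lambda f: (getattr(f, criterion), order[f.family]))
    return FitReport(fits=fits, criterion=criterion, selected=selected.family)


def pipeline(
    truth: SurvivalParams,
    n: int,
    censor_time: float,
    seed: int,
    criterion: str = "aic",
    arm: str = "",
    endpoint: str = "",
) -> dict:
    """simulate -> KM + risk table -> reconstruct -> fit -> select.

    Returns the intermediate artifacts and the selection report, so the
    round trip back to the generating parameters can be inspected.
    """
    ipd = simulate_ipd(truth, n, censor_time, seed, arm=arm, endpoint=endpoint)
    km = km_estimate(ipd)
    recon = reconstruct_ipd(km, arm=arm, endpoint=endpoint)
    fits = fit_all_families(recon)
    report = select_distribution(fits, criterion)
    return {"ipd": ipd, "km": km, "reconstructed": recon,
            "fits": fits, "report": report}
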