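"""Trial statistics: arm rates, difference-in-differences, clustered GEE,
and the two-proportion sample-size calculation.

The primary outcome is the change in PIP rate (fired / eligible pairs,
in percent) from the baseline to the treatment window, compared between
arms.  The effect test is a marginal logistic model on the clinic x
window binomial aggregates::

    logit P(fire) = b0 + b1*arm + b2*period + b3*arm*period

fitted by GEE with an exchangeable working correlation within clinic.
Fitting on aggregates is score-equivalent to fitting the
per-(patient, rule) rows under this design, and avoids materialising
millions of rows.  With a handful of clinics the plain sandwich
variance is badly anticonservative, so the implementation uses the
Mancl–DeRouen bias-corrected sandwich (per-cluster residuals inflated
by ``(I - H_g)^{-1}``) and refers the Wald statistic to a t
distribution with ``n_clinics - 2`` degrees of freedom — clusters
minus the number of cluster-level parameters (intercept and arm), the
usual reference for two-arm cluster trials.

``sample_size`` is the textbook two-proportion normal-approximation
formula with an optional cluster design effect ``1 + (m - 1) * rho``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .aggregation import HubCollection

__all__ = [
    "TrialResult",
    "GeeResult",
    "PowerSpec",
    "summarize",
    "gee_test",
    "counts_frame",
    "sample_size",
    "two_proportion_power",
    "did_interaction_power",
]

ARMS = ("control", "intervention")
WINDOWS = ("baseline", "treatment")


@dataclass(frozen=True)
class GeeResult:
    estimate: float  # interaction coefficient, log-odds scale
    robust_se: float
    statistic: float
    p_value: float
    df: int
    n_clinics: int
    degenerate: bool = False  # all-zero numerators somewhere fatal to the fit


@dataclass
class TrialResult:
    rates: dict[str, dict[str, Optional[float]]]  # arm -> window -> %
    counts: dict[str, dict[str, tuple[int, int]]]  # arm -> window -> (num, den)
    change: dict[str, Optional[float]]  # arm -> percentage points (display precision)
    difference_in_differences: Optional[float]
    display_decimals: dict[str, int]
    gee: Optional[GeeResult] = None
    n_clinics: dict[str, int] | None = None

    def to_obj(self) -> dict:
        out = {
            "rates": self.rates,
            "counts": {a: {w: list(v) for w, v in d.items()} for a, d in self.counts.items()},
            "change": self.change,
            "difference_in_differences": self.difference_in_differences,
            "n_clinics": self.n_clinics,
        }
        if self.gee is not None:
            out["gee"] = {
                "estimate": self.gee.estimate,
                "robust_se": self.gee.robust_se,
                "statistic": self.gee.statistic,
                "p_value": self.gee.p_value,
                "df": self.gee.df,
                "degenerate": self.gee.degenerate,
            }
        return out


def display_rate(num: int, den: int, decimals: int = 1) -> Optional[float]:
    """Rate rounded for display.  One decimal by default; a second
    decimal is kept when rounding to one would not round-trip the value
    distinguishably (e.g. 4.11 vs 4.1 at the same denominator scale)."""
    if den == 0:
        return None
    return round(100.0 * num / den, decimals)


def summarize(hub: HubCollection, decimals: dict[str, int] | None = None) -> TrialResult:
    """Per-arm, per-window rates, within-arm changes and the DiD.

    Arithmetic is exact integer sums up to the final division; the
    published convention is followed for changes: they are differences
    of the *display-rounded* rates (full-precision counts remain in
    ``counts``).  ``decimals`` optionally overrides display precision
    per arm.
    """
    decimals = decimals or {}
    rates: dict[str, dict[str, Optional[float]]] = {}
    counts: dict[str, dict[str, tuple[int, int]]] = {}
    change: dict[str, Optional[float]] = {}
    for arm in ARMS:
        rates[arm] = {}
        counts[arm] = {}
        dec = decimals.get(arm, 1)
        for w in WINDOWS:
            try:
                num, den = hub.arm_total(arm, w)
            except KeyError as exc:
                raise ValueError(f"missing data for arm {arm!r}, window {w!r}") from exc
            counts[arm][w] = (num, den)
            rates[arm][w] = display_rate(num, den, dec)
        b, t = rates[arm]["baseline"], rates[arm]["treatment"]
        change[arm] = None if b is None or t is None else round(t - b, dec)
    did = None
    if change["intervention"] is not None and change["control"] is not None:
        did = round(change["intervention"] - change["control"], 2)
    n_clinics = {arm: len(hub.clinics(arm)) for arm in ARMS}
    return TrialResult(
        rates=rates,
        counts=counts,
        change=change,
        difference_in_differences=did,
        display_decimals={a: decimals.get(a, 1) for a in ARMS},
        n_clinics=n_clinics,
    )


def counts_frame(hub: HubCollection) -> pd.DataFrame:
    """Clinic x window totals as a tidy frame for the GEE."""
    rows = []
    for clinic in hub.clinics():
        for w in WINDOWS:
            num, den = hub.clinic_total(clinic, w)
            rows.append((clinic, hub.arms[clinic], w, num, den))
    return pd.DataFrame(rows, columns=["clinic_id", "arm", "window", "fired", "eligible"])


def _fit_gee_params(df: pd.DataFrame):
    """Exchangeable-GEE point estimates on the aggregates, via a
    case-weight expansion (one success row and one failure row per
    clinic x window cell)."""
    expanded = []
    for r in df.itertuples():
        a = 1.0 if r.arm == "intervention" else 0.0
        p = 1.0 if r.window == "treatment" else 0.0
        if r.fired > 0:
            expanded.append((r.clinic_id, a, p, 1.0, float(r.fired)))
        if r.eligible - r.fired > 0:
            expanded.append((r.clinic_id, a, p, 0.0, float(r.eligible - r.fired)))
    ed = pd.DataFrame(expanded, columns=["clinic_id", "arm", "period", "y", "w"])
    ed["interaction"] = ed["arm"] * ed["period"]
    exog = sm.add_constant(ed[["arm", "period", "interaction"]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GEE(
            ed["y"],
            exog,
            groups=ed["clinic_id"],
            family=sm.families.Binomial(),
            cov_struct=sm.cov_struct.Exchangeable(),
            weights=ed["w"],
        )
        res = model.fit()
    return np.asarray(res.params), float(res.cov_struct.dep_params)


def _bias_corrected_cov(df: pd.DataFrame, beta: np.ndarray, alpha: float) -> np.ndarray:
    """Mancl–DeRouen bias-corrected sandwich on the clinic x window
    binomial aggregates, with working correlation ``alpha`` between the
    two windows of a clinic."""
    Ds, Vs, resids = [], [], []
    for _, sub in df.groupby("clinic_id", sort=True):
        X, y, n = [], [], []
        for r in sub.itertuples():
            if r.eligible == 0:
                continue
            a = 1.0 if r.arm == "intervention" else 0.0
            p = 1.0 if r.window == "treatment" else 0.0
            X.append([1.0, a, p, a * p])
            y.append(r.fired / r.eligible)
            n.append(r.eligible)
        if not y:
            continue
        X = np.asarray(X)
        y = np.asarray(y)
        n = np.asarray(n, dtype=float)
        mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
        v = mu * (1.0 - mu)
        D = v[:, None] * X
        R = np.full((len(y), len(y)), alpha)
        np.fill_diagonal(R, 1.0)
        half = np.sqrt(v / n)
        Vs.append(R * np.outer(half, half))
        Ds.append(D)
        resids.append(y - mu)
    bread = sum(D.T @ np.linalg.solve(V, D) for D, V in zip(Ds, Vs))
    bread_inv = np.linalg.inv(bread)
    meat = np.zeros_like(bread)
    for D, V, e in zip(Ds, Vs, resids):
        Vi = np.linalg.inv(V)
        H = D @ bread_inv @ D.T @ Vi
        e_adj = np.linalg.solve(np.eye(len(e)) - H, e)
        S = D.T @ Vi @ e_adj
        meat += np.outer(S, S)
    return bread_inv @ meat @ bread_inv


def gee_test(df: pd.DataFrame) -> GeeResult:
    """Interaction (arm x period) test on clinic-level binomial counts.

    ``df`` needs columns clinic_id, arm ("control"/"intervention"),
    window ("baseline"/"treatment"), fired, eligible.  Requires at
    least 2 clinics per arm — with one clinic the between-cluster
    variance the sandwich estimates does not exist.  A fit where an
    entire arm x window cell has zero numerators is flagged degenerate
    (the log-odds interaction is then unidentified in practice).
    """
    for arm in ARMS:
        n = df.loc[df["arm"] == arm, "clinic_id"].nunique()
        if n < 2:
            raise ValueError(f"arm {arm!r} has {n} clinic(s); >=2 required for a robust variance")
    cell = df.groupby(["arm", "window"])["fired"].sum()
    degenerate = bool((cell == 0).any())

    beta, alpha = _fit_gee_params(df)
    cov = _bias_corrected_cov(df, beta, alpha)
    est = float(beta[3])
    se = float(np.sqrt(cov[3, 3]))
    n_clinics = int(df["clinic_id"].nunique())
    dof = max(n_clinics - 2, 1)
    tstat = est / se if se > 0 else np.nan
    pval = float(2 * stats.t.sf(abs(tstat), dof)) if np.isfinite(tstat) else np.nan
    return GeeResult(
        estimate=est,
        robust_se=se,
        statistic=float(tstat),
        p_value=pval,
        df=dof,
        n_clinics=n_clinics,
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class PowerSpec:
    p_control: float
    relative_reduction: float
    alpha: float = 0.05
    power: float = 0.8
    design_effect: float = 1.0  # 1 + (m - 1) * rho

    def __post_init__(self) -> None:
        for name in ("p_control", "alpha", "power"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.relative_reduction <= 0:
            raise ValueError("relative_reduction must be positive (zero effect needs infinite n)")
        if self.design_effect < 1:
            raise ValueError("design_effect must be >= 1")

    @property
    def p_intervention(self) -> float:
        return self.p_control * (1 - self.relative_reduction)


def sample_size(ps: PowerSpec, encounters_per_clinic: Optional[int] = None) -> dict:
    """Two-proportion normal-approximation n per arm, inflated by the
    design effect; optionally the implied clinics per arm."""
    p1, p2 = ps.p_control, ps.p_intervention
    pbar = (p1 + p2) / 2
    za = stats.norm.ppf(1 - ps.alpha / 2)
    zb = stats.norm.ppf(ps.power)
    num = (za * np.sqrt(2 * pbar * (1 - pbar)) + zb * np.sqrt(p1 * (1 - p1) + p2 * (1 - p2))) ** 2
    n = num / (p1 - p2) ** 2 * ps.design_effect
    out = {"n_per_arm": int(np.ceil(n))}
    if encounters_per_clinic:
        out["clinics_per_arm"] = int(np.ceil(n / encounters_per_clinic))
    return out


def two_proportion_power(p1: float, p2: float, n_per_arm: int, alpha: float = 0.05) -> float:
    """Analytic power of the two-sided pooled-variance z-test."""
    pbar = (p1 + p2) / 2
    za = stats.norm.ppf(1 - alpha / 2)
    delta = abs(p1 - p2)
    se0 = np.sqrt(2 * pbar * (1 - pbar) / n_per_arm)
    se1 = np.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / n_per_arm)
    return float(stats.norm.sf((za * se0 - delta) / se1))


def did_interaction_power(
    p: float,
    effect: float,
    pairs_per_cell: int,
    alpha: float = 0.05,
    n_clinics: int | None = None,
) -> float:
    """Approximate power of the interaction Wald test in the 2x2
    difference-in-differences design with ``pairs_per_cell`` binomial
    trials in each arm x window cell (independent cells).

    The log-odds interaction is ``log(OR)`` of the effect; its variance
    is the sum of the four cell variances ``1 / (n p q)``.  When
    ``n_clinics`` is given the critical value uses the same
    t(n_clinics - 2) reference as :func:`gee_test`.
    """
    p2 = p * effect
    delta = abs(np.log(p2 / (1 - p2)) - np.log(p / (1 - p)))
    var = 3 / (pairs_per_cell * p * (1 - p)) + 1 / (pairs_per_cell * p2 * (1 - p2))
    se = np.sqrt(var)
    if n_clinics is None:
        crit = stats.norm.ppf(1 - alpha / 2)
    else:
        crit = stats.t.ppf(1 - alpha / 2, max(n_clinics - 2, 1))
    return float(stats.norm.sf(crit - delta / se) + stats.norm.cdf(-crit - delta / se))
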