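"""Mixed-effects panel regression with a lagged dependent variable.

Builds participant-hour panels from interpolated (not smoothed) hourly
series over the week before and after vaccination, and fits

    y_it = b0 + b1*post + b2*y_lag + b3*age + b4*no_condition + b5*male
           + u_i + e_it,    u_i ~ N(0, s_u^2),  e_it ~ N(0, s_e^2)

by maximum likelihood with participant random intercepts.  The post
indicator marks hours in [0, 72) by default; the sensitivity refit swaps in
[24, 72).  Note the lagged dependent variable together with random effects
induces Nickell-type bias of order 1/T; with T up to 335 hours per
participant it is negligible and intentionally left uncorrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

from .exceptions import ConvergenceError
from .preprocessing import STATUS_MISSING, HourlySeries
from .synthetic import Participant

PANEL_START = -168
PANEL_STOP = 168

COEF_NAMES = ("intercept", "post", "y_lag", "age", "no_condition", "male")


@dataclass(frozen=True)
class PanelSpec:
    """Estimation settings: indicator window and optimizer controls."""

    window: tuple[int, int] = (0, 72)
    tol: float = 1e-8
    maxiter: int = 200

    def __post_init__(self):
        lo, hi = self.window
        if not (PANEL_START <= lo < hi <= PANEL_STOP):
            raise ValueError(f"indicator window {self.window} outside the panel range")


@dataclass(frozen=True)
class RegressionFit:
    """Full statistics schema of a fitted mixed panel regression."""

    coefficients: dict[str, float]
    std_errors: dict[str, float]
    p_values: dict[str, float]  # two-sided
    p_one_sided_post: float
    sigma_u2: float
    sigma_e2: float
    pct_variance_random: float
    r2_between: Optional[float]
    r2_within: Optional[float]
    r2_overall: float
    f_statistic: float
    f_pvalue: float
    n_participants: int
    n_observations: int
    window: tuple[int, int] = (0, 72)
    converged: bool = True
    extra: dict = field(default_factory=dict)

    def format_table(self) -> str:
        """Human-readable report mirroring the published table layout."""
        lines = ["Fixed and Random Effects    Coefficient, Std Err, p-value"]
        labels = {
            "post": f"Between {self.window[0]} and {self.window[1]} h after vaccination",
            "y_lag": "Value in previous hour",
            "age": "Age",
            "no_condition": "No underlying medical condition",
            "male": "Male gender",
            "intercept": "Intercept",
        }
        for name in ("post", "y_lag", "age", "no_condition", "male", "intercept"):
            p = self.p_values[name]
            p_str = "<0.001" if p < 0.001 else f"{p:.4g}"
            lines.append(
                f"{labels[name]}: {self.coefficients[name]:.4f}, "
                f"{self.std_errors[name]:.4f}, {p_str}"
            )
        lines.append(f"F-statistic = {self.f_statistic:.4g} (p-value "
                     f"{'<0.0001' if self.f_pvalue < 1e-4 else f'= {self.f_pvalue:.4g}'})")
        if self.r2_between is not None:
            lines.append(f"R2 Between = {self.r2_between:.4f}")
        if self.r2_within is not None:
            lines.append(f"R2 Within = {self.r2_within:.4f}")
        lines.append(f"R2 Overall = {self.r2_overall:.4f}")
        lines.append(f"% of Variance due to Random Effects: {self.pct_variance_random:.2f}%")
        lines.append(f"n participants = {self.n_participants}, "
                     f"n observations = {self.n_observations}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients,
            "std_errors": self.std_errors,
            "p_values": self.p_values,
            "p_one_sided_post": self.p_one_sided_post,
            "sigma_u2": self.sigma_u2,
            "sigma_e2": self.sigma_e2,
            "pct_variance_random": self.pct_variance_random,
            "r2_between": self.r2_between,
            "r2_within": self.r2_within,
            "r2_overall": self.r2_overall,
            "f_statistic": self.f_statistic,
            "f_pvalue": self.f_pvalue,
            "n_participants": self.n_participants,
            "n_observations": self.n_observations,
            "window": list(self.window),
        }


def bonferroni_threshold(alpha: float, m: int, decimals: Optional[int] = None) -> float:
    """Per-comparison threshold alpha/m; ``decimals`` rounds for reporting."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    threshold = alpha / m
    return round(threshold, decimals) if decimals is not None else threshold


def build_panel(
    series_by_participant: Mapping[str, HourlySeries],
    participants: Mapping[str, Participant],
    tiers: Mapping[str, str],
    asymptomatic_only: bool = False,
    window: tuple[int, int] = (0, 72),
) -> pd.DataFrame:
    """Assemble participant-hour rows from interpolated hourly series.

    A row exists where both the hour and its predecessor are non-missing
    (the lag is taken within participant, within a contiguous run).  With a
    fully observed participant this yields 335 rows over [-168, 168).
    ``asymptomatic_only`` keeps only participants tiered 'none'.
    """
    frames = []
    for pid in sorted(series_by_participant):
        if pid not in participants or pid not in tiers:
            continue
        if asymptomatic_only and tiers[pid] != "none":
            continue
        part = participants[pid]
        series = series_by_participant[pid].slice(PANEL_START, PANEL_STOP)
        ok = series.status != STATUS_MISSING
        usable = ok[1:] & ok[:-1]
        if not usable.any():
            continue
        idx = np.flatnonzero(usable) + 1
        hours = series.start + idx
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "t": hours,
                    "y": series.values[idx],
                    "y_lag": series.values[idx - 1],
                    "post": ((hours >= window[0]) & (hours < window[1])).astype(float),
                    "age": float(part.age),
                    "no_condition": 0.0 if part.underlying_condition else 1.0,
                    "male": 1.0 if part.sex == "male" else 0.0,
                }
            )
        )
    if not frames:
        raise ValueError("panel is empty (no usable participants)")
    return pd.concat(frames, ignore_index=True)


def r_squared_decomposition(
    fitted: np.ndarray, y: np.ndarray, groups: np.ndarray
) -> tuple[Optional[float], Optional[float], float]:
    """(between, within, overall) R-squared from fixed-effect fitted values.

    Between: squared correlation of participant means of fitted values with
    participant means of outcomes; within: same on participant-demeaned
    values; overall: on the raw values.  Between/within are None when
    undefined (single participant or zero variance).
    """

    def _sqcorr(a: np.ndarray, b: np.ndarray) -> Optional[float]:
        if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
            return None
        return float(np.corrcoef(a, b)[0, 1] ** 2)

    df = pd.DataFrame({"g": groups, "fitted": fitted, "y": y})
    means = df.groupby("g")[["fitted", "y"]].mean()
    r2_between = _sqcorr(means["fitted"].to_numpy(), means["y"].to_numpy())
    demeaned = df[["fitted", "y"]].to_numpy() - means.loc[df["g"]].to_numpy()
    r2_within = _sqcorr(demeaned[:, 0], demeaned[:, 1])
    r2_overall = _sqcorr(fitted, y)
    return r2_between, r2_within, float(r2_overall if r2_overall is not None else np.nan)


def fit_mixed_panel(panel: pd.DataFrame, spec: PanelSpec = PanelSpec()) -> RegressionFit:
    """Fit the random-intercept panel model by maximum likelihood.

    The post indicator is recomputed from the hour index ``t`` using
    ``spec.window``, so the same panel serves the main fit and the
    sensitivity refit.
    """
    if panel.empty:
        raise ValueError("panel is empty")
    groups = panel["participant_id"].to_numpy()
    n_participants = len(np.unique(groups))
    if n_participants < 2:
        raise ValueError("need at least two participants for random effects")

    t = panel["t"].to_numpy()
    post = ((t >= spec.window[0]) & (t < spec.window[1])).astype(float)
    X = np.column_stack(
        [
            np.ones(len(panel)),
            post,
            panel["y_lag"].to_numpy(dtype=float),
            panel["age"].to_numpy(dtype=float),
            panel["no_condition"].to_numpy(dtype=float),
            panel["male"].to_numpy(dtype=float),
        ]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix (collinear covariates)")
    y = panel["y"].to_numpy(dtype=float)

    model = MixedLM(y, X, groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=False, method=["bfgs", "powell"], maxiter=spec.maxiter)
    if not result.converged:
        raise ConvergenceError(
            "mixed-model estimation did not converge",
            diagnostics={"maxiter": spec.maxiter, "method": "ml"},
        )

    k = X.shape[1]
    coefs = dict(zip(COEF_NAMES, (float(v) for v in result.fe_params)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ses = dict(zip(COEF_NAMES, (float(v) for v in result.bse_fe)))
    dof = len(y) - k
    pvals = {
        name: 2.0 * float(stats.t.sf(abs(coefs[name] / ses[name]), dof)) for name in COEF_NAMES
    }
    t_post = coefs["post"] / ses["post"]
    p_one_sided = float(stats.t.sf(t_post, dof))

    sigma_u2 = float(np.asarray(result.cov_re)[0, 0])
    sigma_e2 = float(result.scale)
    pct_random = 100.0 * sigma_u2 / (sigma_u2 + sigma_e2)

    # Wald F-test of all slope coefficients jointly zero
    b = result.fe_params[1:]
    cov = result.cov_params()[1:k, 1:k]
    q = k - 1
    f_stat = float(b @ np.linalg.solve(cov, b) / q)
    f_pvalue = float(stats.f.sf(f_stat, q, dof))

    fitted = X @ result.fe_params
    r2_between, r2_within, r2_overall = r_squared_decomposition(fitted, y, groups)

    return RegressionFit(
        coefficients=coefs,
        std_errors=ses,
        p_values=pvals,
        p_one_sided_post=p_one_sided,
        sigma_u2=sigma_u2,
        sigma_e2=sigma_e2,
        pct_variance_random=pct_random,
        r2_between=r2_between,
        r2_within=r2_within,
        r2_overall=r2_overall,
        f_statistic=f_stat,
        f_pvalue=f_pvalue,
        n_participants=n_participants,
        n_observations=len(y),
        window=spec.window,
    )


def sensitivity_refit(panel: pd.DataFrame, window: tuple[int, int] = (24, 72)) -> RegressionFit:
    """Refit with the alternative post-vaccination indicator window."""
    return fit_mixed_panel(panel, PanelSpec(window=window))


def format_pvalue(p: float) -> str:
    """Report p-values below 0.001 as '<0.001', matching the published convention."""
    return "<0.001" if p < 0.001 else f"{p:.4g}"
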