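"""System GMM (Arellano–Bover/Blundell–Bond) estimation of the dynamic
risk-factor equations on unbalanced panels.

The model is

    y_it = alpha * y_{i,t-1} + beta' x_it + mu_i + nu_it,

with a patient-specific effect mu_i and i.i.d. shocks nu_it. OLS on the
levels is biased because y_{i,t-1} is correlated with mu_i ("dynamic panel
bias"). The system estimator stacks two sets of moment conditions:

* first-differenced equations, which remove mu_i, instrumented by lagged
  *levels* — lags >= 2 of the dependent variable, lags >= 1 of predetermined
  regressors, lags >= 2 of endogenous regressors — plus the first differences
  of strictly exogenous regressors;
* levels equations, instrumented by lagged first *differences* — delta
  y_{i,t-1} for the dependent variable, delta x_it for predetermined and
  delta x_{i,t-1} for endogenous regressors — plus the levels of strictly
  exogenous regressors and the constant.

Estimation is one- or two-step GMM; two-step standard errors carry a
Windmeijer-type finite-sample correction. Post-estimation diagnostics are
the Hansen J test of the overidentifying restrictions and the
Arellano–Bond AR(1)/AR(2) tests on the first-differenced residuals.
Moment conditions are formed from whatever valid (t, lag) pairs each patient
contributes, so gaps and unbalanced follow-up are handled naturally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DiagnosticUnavailableError,
    EstimationError,
    InstrumentSingularityError,
    PanelError,
)
from .panel import Panel, as_frame

__all__ = [
    "ModelSpec",
    "GmmFit",
    "InstrumentSet",
    "default_model_spec",
    "first_difference",
    "build_instruments",
    "estimate",
    "pooled_ols",
    "hansen_test",
    "ar_test",
]

_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one equation for estimation.

    Regressor classification controls admissible instrument lags: strictly
    exogenous regressors may be correlated with neither past nor future
    shocks, predetermined ones only with past shocks, endogenous ones also
    with the current shock. The lagged dependent variable is always treated
    as predetermined. ``max_lag`` caps the deepest instrument lag;
    ``collapse`` folds the per-period instrument columns into one column per
    lag distance, curbing instrument proliferation.
    """

    dependent: str
    exogenous: tuple = ()
    predetermined: tuple = ()
    endogenous: tuple = ()
    constant: bool = True
    max_lag: int | None = None
    collapse: bool = False
    two_step: bool = True

    @property
    def regressors(self) -> tuple:
        return tuple(self.exogenous) + tuple(self.predetermined) + tuple(self.endogenous)

    @property
    def param_names(self) -> tuple:
        names = (f"lag_{self.dependent}",) + self.regressors
        if self.constant:
            names = names + ("constant",)
        return names


def default_model_spec(risk_factor: str, collapse: bool = False, two_step: bool = True,
                       max_lag: int | None = None) -> ModelSpec:
    """The default specification of each risk factor's equation.

    Mirrors the shipped coefficient set: ln(duration), age at diagnosis and
    sex are strictly exogenous everywhere; the first-year indicator enters
    the HbA1c equation only; current BMI (and its square, in the LDL
    equation) is predetermined; smoking is endogenous in the HbA1c equation
    and strictly exogenous elsewhere.
    """
    common = ("ln_duration", "age_at_diagnosis", "female")
    if risk_factor == "hba1c":
        return ModelSpec("hba1c", exogenous=common + ("year1",),
                         predetermined=("bmi",), endogenous=("smoking",),
                         collapse=collapse, two_step=two_step, max_lag=max_lag)
    if risk_factor == "sbp":
        return ModelSpec("sbp", exogenous=common + ("smoking",),
                         predetermined=("bmi",),
                         collapse=collapse, two_step=two_step, max_lag=max_lag)
    if risk_factor == "tchdl":
        return ModelSpec("tchdl", exogenous=common + ("smoking",),
                         predetermined=("bmi",),
                         collapse=collapse, two_step=two_step, max_lag=max_lag)
    if risk_factor == "ldl":
        return ModelSpec("ldl", exogenous=common + ("smoking",),
                         predetermined=("bmi", "bmi_squared"),
                         collapse=collapse, two_step=two_step, max_lag=max_lag)
    if risk_factor == "bmi":
        return ModelSpec("bmi", exogenous=common + ("smoking",),
                         collapse=collapse, two_step=two_step, max_lag=max_lag)
    raise KeyError(f"unknown risk factor {risk_factor!r}")


# ---------------------------------------------------------------------------
# panel -> arrays


def _variable_matrix(df: pd.DataFrame, ids, tmax: int, column: str) -> np.ndarray:
    wide = df.pivot(index="patient_id", columns="duration", values=column)
    wide = wide.reindex(index=ids, columns=range(tmax + 1))
    return wide.to_numpy(dtype=float)


def _covariate_matrices(df: pd.DataFrame, ids, tmax: int, names) -> dict:
    n = len(ids)
    grid_t = np.arange(tmax + 1, dtype=float)
    out = {}
    for name in names:
        if name == "ln_duration":
            with np.errstate(divide="ignore"):
                row = np.where(grid_t >= 1, np.log(np.maximum(grid_t, 1e-300)), np.nan)
            out[name] = np.tile(row, (n, 1))
        elif name == "year1":
            out[name] = np.tile((grid_t == 1).astype(float), (n, 1))
        elif name in ("age_at_diagnosis", "female"):
            per_patient = df.groupby("patient_id")[name].first().reindex(ids).to_numpy(float)
            out[name] = np.tile(per_patient[:, None], (1, tmax + 1))
        elif name == "bmi_squared":
            out[name] = _variable_matrix(df, ids, tmax, "bmi") ** 2
        else:
            if name not in df.columns:
                raise PanelError(f"panel lacks covariate column {name!r}")
            out[name] = _variable_matrix(df, ids, tmax, name)
    return out


@dataclass
class _System:
    """Stacked moment-condition arrays for one equation."""

    X: np.ndarray            # (n, R, K) regressors, invalid rows zeroed
    y: np.ndarray            # (n, R)
    Z: np.ndarray            # (n, R, L)
    H: np.ndarray            # (R, R) one-step weighting kernel
    valid_diff: np.ndarray   # (n, R_d) validity of differenced rows
    diff_times: np.ndarray   # times t of the differenced rows
    n_diff_rows: int
    labels: list
    param_names: tuple
    n_patients: int
    person_years: int


def _build_system(panel, spec: ModelSpec) -> _System:
    df = as_frame(panel).copy()
    df["duration"] = df["duration"].astype(int)
    ids = np.sort(df["patient_id"].unique())
    tmax = int(df["duration"].max())
    if tmax < 2:
        raise EstimationError(
            f"panel has maximum duration {tmax}; at least 3 waves (t >= 2) are "
            "required to form differenced moment conditions"
        )

    Y = _variable_matrix(df, ids, tmax, spec.dependent)
    if spec.dependent == "sbp":
        Y = Y / 10.0  # the SBP equation lives on the /10 scale
    covs = _covariate_matrices(df, ids, tmax, spec.regressors)

    obs_y = np.isfinite(Y)
    # ln_duration is NaN at t=0 by construction; no row ever uses covariates at t=0
    obs_x = np.ones_like(obs_y, dtype=bool)
    for name in spec.regressors:
        obs_x &= np.isfinite(covs[name])

    diff_times = np.arange(2, tmax + 1)
    lvl_times = np.arange(1, tmax + 1)
    n = len(ids)
    R_d, R_l = len(diff_times), len(lvl_times)
    R = R_d + R_l
    K = len(spec.param_names)

    valid_d = np.zeros((n, R_d), dtype=bool)
    for j, t in enumerate(diff_times):
        valid_d[:, j] = (obs_y[:, t] & obs_y[:, t - 1] & obs_y[:, t - 2]
                         & obs_x[:, t] & obs_x[:, t - 1])
    valid_l = np.zeros((n, R_l), dtype=bool)
    for j, t in enumerate(lvl_times):
        valid_l[:, j] = obs_y[:, t] & obs_y[:, t - 1] & obs_x[:, t]

    X = np.zeros((n, R, K))
    y = np.zeros((n, R))
    Yz = np.nan_to_num(Y)
    covz = {k: np.nan_to_num(v) for k, v in covs.items()}
    for j, t in enumerate(diff_times):
        X[:, j, 0] = Yz[:, t - 1] - Yz[:, t - 2]
        for k, name in enumerate(spec.regressors, start=1):
            X[:, j, k] = covz[name][:, t] - covz[name][:, t - 1]
        y[:, j] = Yz[:, t] - Yz[:, t - 1]
    for j, t in enumerate(lvl_times):
        r = R_d + j
        X[:, r, 0] = Yz[:, t - 1]
        for k, name in enumerate(spec.regressors, start=1):
            X[:, r, k] = covz[name][:, t]
        if spec.constant:
            X[:, r, K - 1] = 1.0
        y[:, r] = Yz[:, t]

    row_valid = np.concatenate([valid_d, valid_l], axis=1)
    X[~row_valid] = 0.0
    y[~row_valid] = 0.0

    # instruments are built NaN-aware: a lagged level or difference that is
    # not observed must become a zero instrument, never a partial difference
    Z, labels = _build_instrument_matrix(
        spec, Y, covs, diff_times, lvl_times, row_valid, tmax
    )

    # one-step weighting: MA(1) kernel on the differenced block, identity on levels
    H = np.zeros((R, R))
    for j, t in enumerate(diff_times):
        H[j, j] = 2.0
        for j2, t2 in enumerate(diff_times):
            if abs(t - t2) == 1:
                H[j, j2] = -1.0
    for j in range(R_d, R):
        H[j, j] = 1.0

    in_sample = row_valid.any(axis=1)
    person_years = int((obs_y & np.tile(in_sample[:, None], (1, tmax + 1))).sum())

    return _System(
        X=X, y=y, Z=Z, H=H, valid_diff=valid_d, diff_times=diff_times,
        n_diff_rows=R_d, labels=labels, param_names=spec.param_names,
        n_patients=int(in_sample.sum()), person_years=person_years,
    )


def _time_invariant(mat: np.ndarray) -> bool:
    finite = np.isfinite(mat)
    if not finite.any():
        return True
    diffs = np.diff(mat, axis=1)
    return bool(np.nanmax(np.abs(np.where(np.isfinite(diffs), diffs, 0.0))) < _ZERO_TOL)


def _build_instrument_matrix(spec, Yz, covz, diff_times, lvl_times, row_valid, tmax):
    n = Yz.shape[0]
    R_d, R_l = len(diff_times), len(lvl_times)
    R = R_d + R_l
    columns = []
    labels = []

    def gmm_style(values: np.ndarray, var: str, lag_min: int):
        """Lagged levels instrumenting the differenced equation."""
        lag_cap = tmax if spec.max_lag is None else min(tmax, spec.max_lag)
        if spec.collapse:
            for lag in range(lag_min, lag_cap + 1):
                col = np.zeros((n, R))
                hit = False
                for j, t in enumerate(diff_times):
                    if t - lag >= 0:
                        col[:, j] = np.nan_to_num(values[:, t - lag])
                        hit = True
                if hit:
                    columns.append(col)
                    labels.append(f"D.{var}:L{lag}(collapsed)")
        else:
            for j, t in enumerate(diff_times):
                for lag in range(lag_min, min(t, lag_cap) + 1):
                    col = np.zeros((n, R))
                    col[:, j] = np.nan_to_num(values[:, t - lag])
                    columns.append(col)
                    labels.append(f"D.{var}:t={t},L{lag}")

    def level_style(deltas: np.ndarray, var: str, tag: str):
        """Lagged differences instrumenting the levels equation.

        ``deltas[:, j]`` is the instrument value for levels row j (NaN when
        the required difference does not exist).
        """
        vals = np.nan_to_num(deltas)
        if spec.collapse:
            col = np.zeros((n, R))
            col[:, R_d:] = vals
            if np.abs(col).max() > _ZERO_TOL:
                columns.append(col)
                labels.append(f"L.{var}:{tag}(collapsed)")
        else:
            for j, t in enumerate(lvl_times):
                col = np.zeros((n, R))
                col[:, R_d + j] = vals[:, j]
                if np.abs(col).max() > _ZERO_TOL:
                    columns.append(col)
                    labels.append(f"L.{var}:{tag},t={t}")

    def delta_at(values: np.ndarray, t: int) -> np.ndarray:
        if t - 1 < 0:
            return np.full(values.shape[0], np.nan)
        return values[:, t] - values[:, t - 1]

    # dependent variable: predetermined by construction
    gmm_style(Yz, spec.dependent, lag_min=2)
    lvl_dep = np.column_stack([delta_at(Yz, t - 1) for t in lvl_times])
    level_style(lvl_dep, spec.dependent, "D1lag")

    for var in spec.predetermined:
        gmm_style(covz[var], var, lag_min=1)
        lvl = np.column_stack([delta_at(covz[var], t) for t in lvl_times])
        level_style(lvl, var, "D0")

    for var in spec.endogenous:
        gmm_style(covz[var], var, lag_min=2)
        lvl = np.column_stack([delta_at(covz[var], t) for t in lvl_times])
        level_style(lvl, var, "D1lag")

    # strictly exogenous regressors: their own differences in the differenced
    # block, their own levels (plus the constant) in the levels block
    for var in spec.exogenous:
        mat = covz[var]
        if not _time_invariant(mat):
            col = np.zeros((n, R))
            for j, t in enumerate(diff_times):
                col[:, j] = np.nan_to_num(mat[:, t] - mat[:, t - 1])
            columns.append(col)
            labels.append(f"D.{var}:iv")
        col = np.zeros((n, R))
        for j, t in enumerate(lvl_times):
            col[:, R_d + j] = np.nan_to_num(mat[:, t])
        columns.append(col)
        labels.append(f"L.{var}:iv")
    if spec.constant:
        col = np.zeros((n, R))
        col[:, R_d:] = 1.0
        columns.append(col)
        labels.append("L.constant")

    Z = np.stack(columns, axis=2) if columns else np.zeros((n, R, 0))
    Z[~row_valid] = 0.0

    keep = np.abs(Z).max(axis=(0, 1)) > _ZERO_TOL
    Z = Z[:, :, keep]
    labels = [lab for lab, k in zip(labels, keep) if k]
    return Z, labels


# ---------------------------------------------------------------------------
# public operations


def first_difference(panel, variable: str) -> Panel:
    """First differences of ``variable`` along consecutive durations.

    Returns a panel with an added ``d_<variable>`` column; rows without an
    observation in the immediately preceding year (including rows on the far
    side of a gap) are dropped.
    """
    df = as_frame(panel).sort_values(["patient_id", "duration"]).copy()
    prev = df.groupby("patient_id")[variable].shift(1)
    prev_t = df.groupby("patient_id")["duration"].shift(1)
    consecutive = (df["duration"] - prev_t) == 1
    df[f"d_{variable}"] = np.where(consecutive, df[variable] - prev, np.nan)
    out = df[consecutive & df[f"d_{variable}"].notna()].reset_index(drop=True)
    return Panel(out)


@dataclass
class InstrumentSet:
    """Description of the instrument matrix a specification generates."""

    labels: list
    collapse: bool
    n_diff_columns: int
    n_level_columns: int

    @property
    def count(self) -> int:
        return len(self.labels)


def build_instruments(panel, spec: ModelSpec) -> InstrumentSet:
    """Enumerate the instrument columns for ``spec`` on this panel."""
    system = _build_system(panel, spec)
    n_diff = sum(1 for lab in system.labels if lab.startswith("D."))
    return InstrumentSet(
        labels=system.labels,
        collapse=spec.collapse,
        n_diff_columns=n_diff,
        n_level_columns=len(system.labels) - n_diff,
    )


@dataclass
class GmmFit:
    """Result of a system GMM estimation."""

    params: pd.Series
    se: pd.Series
    pvalues: pd.Series
    stars: pd.Series
    vcov: np.ndarray
    spec: ModelSpec
    n_patients: int
    person_years: int
    n_instruments: int
    instrument_labels: list = field(repr=False)
    hansen_stat: float | None
    hansen_df: int
    hansen_p: float | None
    ar_results: dict = field(repr=False)
    two_step: bool = True
    notes: list = field(default_factory=list)

    @property
    def alpha(self) -> float:
        """Estimated coefficient of the lagged dependent variable."""
        return float(self.params.iloc[0])

    def summary(self) -> str:
        lines = [
            f"System GMM fit: {self.spec.dependent}"
            + ("  (two-step, Windmeijer-corrected SEs)" if self.two_step else "  (one-step)"),
            f"patients: {self.n_patients}   person-years: {self.person_years}   "
            f"instruments: {self.n_instruments}",
            "",
            f"{'parameter':<22}{'coef':>10}{'se':>10}{'p':>8}  sig",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<22}{self.params[name]:>10.4f}{self.se[name]:>10.4f}"
                f"{self.pvalues[name]:>8.3f}  {self.stars[name]}"
            )
        if self.hansen_p is not None:
            lines.append(
                f"\nHansen J = {self.hansen_stat:.3f} (df={self.hansen_df}, p={self.hansen_p:.3f})"
            )
        else:
            lines.append("\nHansen J: undefined (just-identified model)")
        for order in (1, 2):
            res = self.ar_results.get(order)
            if isinstance(res, tuple):
                lines.append(f"AR({order}) z = {res[0]:.3f} (p={res[1]:.3f})")
            else:
                lines.append(f"AR({order}): unavailable ({res})")
        if self.notes:
            lines.append("notes: " + "; ".join(self.notes))
        return "\n".join(lines)


def _stars(p: float) -> str:
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.10:
        return "*"
    return ""


def estimate(panel, spec: ModelSpec) -> GmmFit:
    """One- or two-step system GMM estimation of one equation."""
    system = _build_system(panel, spec)
    X, y, Z, H = system.X, system.y, system.Z, system.H
    K = X.shape[2]
    L = Z.shape[2]
    notes = []

    if L < K:
        raise EstimationError(
            f"under-identified: {L} instruments for {K} parameters"
        )

    SZX = np.einsum("nrl,nrk->lk", Z, X)
    SZy = np.einsum("nrl,nr->l", Z, y)
    A_H = np.einsum("nrl,rs,nsm->lm", Z, H, Z, optimize=True)
    W1 = _robust_inverse(A_H, system.labels, context="one-step weighting matrix",
                         require_rank=K, notes=notes)

    theta1, A1 = _gmm_solve(SZX, SZy, W1)
    u1 = y - np.einsum("nrk,k->nr", X, theta1)
    g1 = np.einsum("nrl,nr->nl", Z, u1)
    S = g1.T @ g1

    if spec.two_step:
        W2 = _robust_inverse(S, system.labels, context="two-step weighting matrix",
                             require_rank=K, notes=notes)
        theta, A = _gmm_solve(SZX, SZy, W2)
        u = y - np.einsum("nrk,k->nr", X, theta)
        vcov = _windmeijer_vcov(A, A1, SZX, W1, W2, S, X, Z, u1, u, g1)
        W_used = W2
    else:
        theta, A = theta1, A1
        u = u1
        # robust sandwich for the one-step estimator
        B = A1 @ (SZX.T @ W1)
        vcov = B @ S @ B.T
        W_used = W1

    se = np.sqrt(np.maximum(np.diag(vcov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(se > 0, theta / se, np.inf)
    pvals = 2.0 * stats.norm.sf(np.abs(zstat))

    # Hansen J uses the optimal weighting built from one-step residuals,
    # evaluated at the final residuals.
    hansen_df = L - K
    hansen_stat, hansen_p = None, None
    if hansen_df > 0:
        try:
            g_final = np.einsum("nrl,nr->l", Z, u)
            W_h = W2 if spec.two_step else _robust_inverse(
                S, system.labels, context="Hansen weighting matrix", require_rank=K, notes=notes
            )
            hansen_stat = float(g_final @ W_h @ g_final)
            hansen_p = float(stats.chi2.sf(hansen_stat, hansen_df))
        except InstrumentSingularityError:
            notes.append("Hansen test unavailable: residual moment covariance is singular")

    ar_results = {}
    for order in (1, 2):
        try:
            ar_results[order] = _arellano_bond(
                system, X, Z, u, A, SZX, W_used, vcov, order
            )
        except DiagnosticUnavailableError as exc:
            ar_results[order] = str(exc)

    names = list(system.param_names)
    params = pd.Series(theta, index=names)
    return GmmFit(
        params=params,
        se=pd.Series(se, index=names),
        pvalues=pd.Series(pvals, index=names),
        stars=pd.Series([_stars(p) for p in pvals], index=names),
        vcov=vcov,
        spec=spec,
        n_patients=system.n_patients,
        person_years=system.person_years,
        n_instruments=L,
        instrument_labels=system.labels,
        hansen_stat=hansen_stat,
        hansen_df=hansen_df,
        hansen_p=hansen_p,
        ar_results=ar_results,
        two_step=spec.two_step,
        notes=notes,
    )


def _robust_inverse(mat, labels, context: str, require_rank: int, notes: list):
    """Invert a weighting matrix, detecting instrument collinearity."""
    w, V = np.linalg.eigh((mat + mat.T) / 2.0)
    tol = max(w.max(), 0.0) * 1e-12
    rank = int((w > tol).sum())
    if rank < require_rank:
        # name instruments loading heaviest on the null space
        null = V[:, w <= tol]
        loading = np.abs(null).sum(axis=1) if null.size else np.zeros(len(labels))
        worst = [labels[i] for i in np.argsort(loading)[::-1][:5]]
        raise InstrumentSingularityError(
            f"{context} has rank {rank} < {require_rank}; instruments appear "
            f"collinear (heaviest null-space loadings: {worst})",
            columns=worst,
        )
    if rank < len(w):
        notes.append(f"{context} rank-deficient ({rank}/{len(w)}); pseudo-inverse used")
    inv_w = np.where(w > tol, 1.0 / np.where(w > tol, w, 1.0), 0.0)
    return (V * inv_w) @ V.T


def _gmm_solve(SZX, SZy, W):
    M = SZX.T @ W @ SZX
    try:
        A = np.linalg.inv(M)
    except np.linalg.LinAlgError:
        raise EstimationError("X'ZWZ'X is singular; regressors not identified") from None
    theta = A @ (SZX.T @ W @ SZy)
    return theta, A


def _windmeijer_vcov(A2, A1, SZX, W1, W2, S, X, Z, u1, u2, g1):
    """Two-step variance with the Windmeijer finite-sample correction."""
    K = SZX.shape[1]
    # per-patient pieces
    M = np.einsum("nrl,nrk->nlk", Z, X)           # Z_i' X_i
    g2_total = np.einsum("nrl,nr->l", Z, u2)
    # C[j] = sum_i (Z_i' x_ij)(Z_i' u1_i)'
    C = np.einsum("nlj,nm->jlm", M, g1, optimize=True)
    P = A2 @ (SZX.T @ W2)                          # (K, L)
    q = W2 @ g2_total                              # (L,)
    D = np.empty((K, K))
    for j in range(K):
        dS = C[j] + C[j].T
        D[:, j] = P @ (dS @ q)
    B1 = A1 @ (SZX.T @ W1)
    V1 = B1 @ S @ B1.T                             # robust one-step variance
    V2 = A2
    return V2 + D @ V2 + V2 @ D.T + D @ V1 @ D.T


def _arellano_bond(system, X, Z, u, A, SZX, W, vcov, order: int):
    """Arellano–Bond test for order-``m`` serial correlation in the
    first-differenced residuals."""
    R_d = system.n_diff_rows
    times = system.diff_times
    valid = system.valid_diff
    n, R = u.shape

    w = np.zeros_like(u)
    t_index = {t: j for j, t in enumerate(times)}
    any_pair = False
    for j, t in enumerate(times):
        t_lag = t - order
        if t_lag in t_index:
            jl = t_index[t_lag]
            mask = valid[:, j] & valid[:, jl]
            if mask.any():
                any_pair = True
            w[mask, j] = u[mask, jl]
    if not any_pair:
        raise DiagnosticUnavailableError(
            f"no residual pairs {order} periods apart; panel too short for AR({order})"
        )

    num = float(np.einsum("nr,nr->", w, u))
    c = np.einsum("nr,nr->n", w, u)
    term1 = float(np.sum(c * c))
    if term1 <= _ZERO_TOL:
        raise DiagnosticUnavailableError(
            f"differenced residuals have zero variance; AR({order}) undefined"
        )
    wX = np.einsum("nr,nrk->k", w, X)
    g = np.einsum("nrl,nr->nl", Z, u)
    gw = np.einsum("nl,n->l", g, c)
    term2 = -2.0 * float(wX @ A @ (SZX.T @ W @ gw))
    term3 = float(wX @ vcov @ wX)
    den2 = term1 + term2 + term3
    if den2 <= 0:
        den2 = term1  # conservative fallback when the correction overshoots
    zstat = num / np.sqrt(den2)
    return float(zstat), float(2.0 * stats.norm.sf(abs(zstat)))


def hansen_test(fit: GmmFit):
    """Hansen J test of the overidentifying restrictions."""
    if fit.hansen_p is None:
        raise DiagnosticUnavailableError(
            "Hansen test undefined: model is just-identified or the residual "
            "moment covariance is degenerate"
        )
    return fit.hansen_stat, fit.hansen_p


def ar_test(fit: GmmFit, order: int):
    """Arellano–Bond serial-correlation test on first-differenced residuals."""
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    res = fit.ar_results.get(order)
    if not isinstance(res, tuple):
        raise DiagnosticUnavailableError(str(res))
    return res


def pooled_ols(panel, spec: ModelSpec):
    """Pooled OLS on the levels equation (the biased comparator).

    With a patient-specific effect present, the lagged dependent variable is
    positively correlated with the composite error, so this estimator
    overstates alpha; it exists to demonstrate the dynamic panel bias.
    """
    system = _build_system(panel, spec)
    R_d = system.n_diff_rows
    Xl = system.X[:, R_d:, :].reshape(-1, system.X.shape[2])
    yl = system.y[:, R_d:].reshape(-1)
    rows = np.abs(Xl).sum(axis=1) > 0
    Xl, yl = Xl[rows], yl[rows]
    if Xl.shape[0] <= Xl.shape[1]:
        raise EstimationError("too few level observations for pooled OLS")
    theta, *_ = np.linalg.lstsq(Xl, yl, rcond=None)
    return pd.Series(theta, index=list(system.param_names))
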