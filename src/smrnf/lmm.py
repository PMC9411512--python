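"""Mixed-model endpoint for per-run band power at the feedback electrode.

Model: for subject i in group g (3D/2D) and condition c (real/sham), the
power of one band at Cz in feedback run r (1..6) is

    y_ir = beta0 + beta_g*g + beta_c*c + beta_r*r~ + (interactions)
           + b0_i + b1_i*r~ + e_ir

with g, c effect-coded (+1/-1), r~ the run index centred at 3.5, and
independent random effects b0_i ~ N(0, s0^2) (subject intercept),
b1_i ~ N(0, s1^2) (subject run slope), e ~ N(0, s^2).  Estimation is REML,
profiled over the two variance ratios.  Fixed effects are tested by a
sequential (Type I) ANOVA whose denominator degrees of freedom come from
the Satterthwaite approximation (gradient of each contrast variance with
respect to the variance components against the REML information).

The API follows the Model/Results idiom: build a `PowerTrendModel` from a
power table, `fit()` it, then ask the `PowerTrendResults` for `anova()`,
`summary()` or the variance components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PowerTrendModel",
    "PowerTrendResults",
    "fit_lmm",
    "anova_type1",
    "partial_eta_squared",
    "post_test_per_group",
    "simulate_power_table",
]

GROUP_CODE = {"3D": 1.0, "2D": -1.0}
CONDITION_CODE = {"real": 1.0, "sham": -1.0}

FULL_TERM_ORDER = ("group", "condition", "runs", "group:condition",
                   "group:runs", "condition:runs", "group:condition:runs")


def partial_eta_squared(F: float, df_num: float, df_den: float) -> float:
    """Standard conversion of an F statistic to partial eta squared."""
    if F < 0 or df_num <= 0 or df_den <= 0:
        raise ValueError("F must be >= 0 and both dfs positive")
    return F * df_num / (F * df_num + df_den)


def _effect_columns(df: pd.DataFrame, center_run: float, terms) -> np.ndarray:
    g = df["group"].map(GROUP_CODE).to_numpy(float)
    c = df["condition"].map(CONDITION_CODE).to_numpy(float)
    r = df["run"].to_numpy(float) - center_run
    pool = {"group": g, "condition": c, "runs": r,
            "group:condition": g * c, "group:runs": g * r,
            "condition:runs": c * r, "group:condition:runs": g * c * r}
    cols = [np.ones(len(df))] + [pool[t] for t in terms]
    return np.column_stack(cols)


class PowerTrendModel:
    """Linear mixed model for band-power trends across feedback runs.

    Parameters
    ----------
    y, X : response vector and fixed-effects design (first column intercept).
    subject_ids : per-observation subject labels (grouping factor).
    run_covariate : per-observation centred run value (random-slope design).
    term_names : fixed terms in sequential-test order, excluding the
        intercept; term j occupies column j+1 of ``X``.
    include_random_intercept, include_random_slope : structure switches;
        with both off the model is ordinary least squares.
    """

    def __init__(self, y, X, subject_ids, run_covariate, term_names,
                 include_random_intercept: bool = True,
                 include_random_slope: bool = True):
        self.y = np.asarray(y, float)
        self.X = np.asarray(X, float)
        self.subject_ids = np.asarray(subject_ids)
        self.run_covariate = np.asarray(run_covariate, float)
        self.term_names = tuple(term_names)
        if self.X.shape[1] != len(self.term_names) + 1:
            raise ValueError("X must have one column per term plus intercept")
        self.include_random_intercept = include_random_intercept
        self.include_random_slope = include_random_slope
        self.n_obs, self.n_fixed = self.X.shape
        if np.linalg.matrix_rank(self.X) < self.n_fixed:
            raise ValueError("fixed-effects design is rank deficient")
        # per-subject blocks
        self._blocks = []
        for sid in pd.unique(self.subject_ids):
            idx = np.flatnonzero(self.subject_ids == sid)
            self._blocks.append((self.y[idx], self.X[idx], self.run_covariate[idx]))
        counts = pd.Series(self.subject_ids).value_counts()
        if counts.min() < 2 and include_random_slope:
            raise ValueError("each subject needs >= 2 runs for a random slope")
        # balanced fast path: every subject observed at the same run values
        # shares one V0 block, so each REML evaluation needs one Cholesky
        z0 = self._blocks[0][2]
        self._balanced = all(b[2].shape == z0.shape and np.array_equal(b[2], z0)
                             for b in self._blocks)
        if self._balanced:
            self._Ys = np.stack([b[0] for b in self._blocks])  # (m, n_i)
            self._Xs = np.stack([b[1] for b in self._blocks])  # (m, n_i, p)
            self._z0 = z0

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_power_table(cls, table: pd.DataFrame, band: str = "SMR",
                         channel: str = "Cz", response: str = "mean_power",
                         runs=tuple(range(1, 7)), center_run: float = 3.5,
                         log_power: bool = False,
                         term_order=FULL_TERM_ORDER,
                         include_random_intercept: bool = True,
                         include_random_slope: bool = True) -> "PowerTrendModel":
        """Build the full group x condition x runs model from a long table.

        Keeps one band at one channel, feedback runs only, drops rows whose
        power is missing (all segments rejected).  ``log_power`` applies a
        natural log to the response (off by default: raw uV^2).
        """
        df = table[(table["band"] == band) & (table["channel"] == channel)
                   & table["run"].isin(runs)].dropna(subset=[response]).copy()
        if df.empty:
            raise ValueError(f"no rows for band={band} channel={channel}")
        cells = df.groupby(["group", "condition"])["subject_id"].nunique()
        if (cells < 2).any():
            raise ValueError("need >= 2 subjects per group x condition cell")
        y = df[response].to_numpy(float)
        if log_power:
            y = np.log(y)
        X = _effect_columns(df, center_run, term_order)
        return cls(y, X, df["subject_id"].to_numpy(),
                   df["run"].to_numpy(float) - center_run, term_order,
                   include_random_intercept, include_random_slope)

    @classmethod
    def from_group_subset(cls, table: pd.DataFrame, group: str,
                          band: str = "SMR", channel: str = "Cz",
                          response: str = "mean_power",
                          runs=tuple(range(1, 7)), center_run: float = 3.5,
                          log_power: bool = False,
                          include_random_intercept: bool = True,
                          include_random_slope: bool = True) -> "PowerTrendModel":
        """Per-group post-test model: condition + runs + condition:runs."""
        df = table[(table["band"] == band) & (table["channel"] == channel)
                   & (table["group"] == group) & table["run"].isin(runs)
                   ].dropna(subset=[response]).copy()
        if df.empty:
            raise ValueError(f"no rows for group {group}")
        terms = ("condition", "runs", "condition:runs")
        if df["condition"].nunique() < 2:
            terms = ("runs",)
        y = df[response].to_numpy(float)
        if log_power:
            y = np.log(y)
        X = _effect_columns(df, center_run, terms)
        return cls(y, X, df["subject_id"].to_numpy(),
                   df["run"].to_numpy(float) - center_run, terms,
                   include_random_intercept, include_random_slope)

    # -- REML machinery -----------------------------------------------------

    def _accumulate(self, s0: float, s1: float, se: float):
        """GLS pieces under V_i = se*I + s0*11' + s1*z_i z_i'.

        Returns (XtVX, XtVy, ytVy, logdet) with V in whatever units the
        inputs are given (se=1 yields the profiled V0 parametrization).
        """

        def block_v(n_i, z_i):
            V = se * np.eye(n_i)
            if self.include_random_intercept:
                V += s0
            if self.include_random_slope:
                V += s1 * np.outer(z_i, z_i)
            return V

        if self._balanced:
            n_i = self._z0.size
            L = np.linalg.cholesky(block_v(n_i, self._z0))
            Linv = np.linalg.inv(L)
            m = len(self._blocks)
            logdet = m * 2.0 * np.log(np.diag(L)).sum()
            Xw = np.einsum("ab,mbp->map", Linv, self._Xs)
            yw = np.einsum("ab,mb->ma", Linv, self._Ys)
            XtVX = np.einsum("map,maq->pq", Xw, Xw)
            XtVy = np.einsum("map,ma->p", Xw, yw)
            ytVy = float(np.einsum("ma,ma->", yw, yw))
            return XtVX, XtVy, ytVy, logdet

        p = self.n_fixed
        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        ytVy = 0.0
        logdet = 0.0
        for y_i, X_i, z_i in self._blocks:
            L = np.linalg.cholesky(block_v(y_i.size, z_i))
            logdet += 2.0 * np.log(np.diag(L)).sum()
            Xw = np.linalg.solve(L, X_i)
            yw = np.linalg.solve(L, y_i)
            XtVX += Xw.T @ Xw
            XtVy += Xw.T @ yw
            ytVy += yw @ yw
        return XtVX, XtVy, ytVy, logdet

    def _gls_pieces(self, gamma0: float, gamma1: float):
        """GLS quantities under the profiled V0_i = I + g0*11' + g1*zz'."""
        return self._accumulate(gamma0, gamma1, 1.0)

    def _profiled_neg2reml(self, gamma0: float, gamma1: float):
        XtVX, XtVy, ytVy, logdet = self._gls_pieces(gamma0, gamma1)
        beta = np.linalg.solve(XtVX, XtVy)
        rss = ytVy - beta @ XtVy
        dof = self.n_obs - self.n_fixed
        sign, logdet_xtvx = np.linalg.slogdet(XtVX)
        crit = dof * np.log(max(rss, 1e-300)) + logdet + logdet_xtvx
        return crit, beta, rss / dof, XtVX

    def _neg2reml_theta(self, theta: np.ndarray, active: np.ndarray) -> float:
        """-2 REML log-likelihood in absolute variance units.

        ``theta`` holds the active components of (s0^2, s1^2, s^2) as
        selected by ``active``; inactive variances are pinned at zero.
        """
        full = np.zeros(3)
        full[active] = theta
        XtVX, XtVy, ytVy, logdet = self._accumulate(*full)
        beta = np.linalg.solve(XtVX, XtVy)
        rss = ytVy - beta @ XtVy
        _, logdet_xtvx = np.linalg.slogdet(XtVX)
        return logdet + logdet_xtvx + rss

    def _cov_beta(self, theta3: np.ndarray) -> np.ndarray:
        """(X' V(theta)^-1 X)^-1 in absolute units."""
        XtVX, _, _, _ = self._accumulate(*theta3)
        return np.linalg.inv(XtVX)

    def fit(self, force_zero_variances: bool = False,
            starts=((1.0, 0.1), (0.1, 1.0), (1e-3, 1e-3))) -> "PowerTrendResults":
        """REML fit; multi-start bounded optimisation over variance ratios.

        With ``force_zero_variances`` (or no random structure) the fit
        collapses to ordinary least squares, which downstream tests use as a
        closed-form oracle.  A ratio driven to the zero boundary is reported
        as a singular fit, not an error.
        """
        has_random = ((self.include_random_intercept or self.include_random_slope)
                      and not force_zero_variances)
        if not has_random:
            gamma = np.zeros(2)
            converged = True
        else:
            def obj(lg):
                return self._profiled_neg2reml(lg[0], lg[1])[0]

            best = None
            for x0 in starts:
                res = optimize.minimize(obj, np.asarray(x0, float), method="L-BFGS-B",
                                        bounds=[(0.0, 1e8), (0.0, 1e8)],
                                        options={"ftol": 1e-13, "gtol": 1e-9,
                                                 "maxiter": 500})
                if best is None or res.fun < best.fun - 1e-10:
                    best = res
            gamma = np.asarray(best.x, float)
            converged = bool(best.success)
        if not self.include_random_intercept:
            gamma[0] = 0.0
        if not self.include_random_slope:
            gamma[1] = 0.0

        crit, beta, sigma2, XtVX = self._profiled_neg2reml(gamma[0], gamma[1])
        theta3 = np.array([gamma[0] * sigma2, gamma[1] * sigma2, sigma2])
        # X'V^-1X in absolute units is XtVX / sigma2; invert in V0 units so
        # a perfect (zero-residual) fit still yields a finite zero covariance
        cov_beta = sigma2 * np.linalg.inv(XtVX)
        singular = has_random and bool(
            (self.include_random_intercept and theta3[0] <= 1e-10 * sigma2) or
            (self.include_random_slope and theta3[1] <= 1e-10 * sigma2))
        return PowerTrendResults(model=self, params=beta, cov_params=cov_beta,
                                 vc=theta3, neg2reml=crit, converged=converged,
                                 singular=singular)


def _active_components(model: PowerTrendModel, theta3: np.ndarray) -> np.ndarray:
    """Indices of variance components not pinned at the zero boundary."""
    se2 = theta3[2]
    active = [2]
    if model.include_random_intercept and theta3[0] > 1e-10 * se2:
        active.append(0)
    if model.include_random_slope and theta3[1] > 1e-10 * se2:
        active.append(1)
    return np.array(sorted(active))


def _vc_covariance(model: PowerTrendModel, theta3: np.ndarray,
                   active: np.ndarray) -> np.ndarray | None:
    """Asymptotic covariance of the active variance components.

    A = 2 * H^-1 with H the finite-difference Hessian of the -2 REML
    log-likelihood at the estimate (components at the zero boundary are
    treated as known and excluded).  Returns None when H is not invertible.
    """
    mask = np.zeros(3, dtype=bool)
    mask[active] = True
    th = theta3[active]
    se2 = theta3[2]
    k = th.size
    h = 1e-4 * np.maximum(np.abs(th), 1e-3 * se2)

    def f(t):
        return model._neg2reml_theta(t, mask)

    H = np.empty((k, k))
    f0 = f(th)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                tp, tm = th.copy(), th.copy()
                tp[i] += h[i]
                tm[i] = max(th[i] - h[i], 1e-12 * se2)
                H[i, i] = (f(tp) - 2 * f0 + f(tm)) / ((0.5 * (tp[i] - tm[i])) ** 2)
            else:
                tpp, tpm, tmp, tmm = th.copy(), th.copy(), th.copy(), th.copy()
                tpp[[i, j]] += h[[i, j]]
                tpm[i] += h[i]
                tpm[j] = max(th[j] - h[j], 1e-12 * se2)
                tmp[j] += h[j]
                tmp[i] = max(th[i] - h[i], 1e-12 * se2)
                tmm[i] = max(th[i] - h[i], 1e-12 * se2)
                tmm[j] = max(th[j] - h[j], 1e-12 * se2)
                H[i, j] = H[j, i] = ((f(tpp) - f(tpm) - f(tmp) + f(tmm))
                                     / ((tpp[i] - tmm[i]) * (tpp[j] - tmm[j])))
    try:
        return 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None


def _satterthwaite_df(model: PowerTrendModel, theta3: np.ndarray,
                      contrast: np.ndarray, active: np.ndarray,
                      A: np.ndarray | None) -> float:
    """Satterthwaite denominator df for a single 1-df contrast.

    nu = 2 * var(l'beta)^2 / (g' A g) with g the finite-difference gradient
    of the contrast variance w.r.t. the active variance components and A the
    inverse REML information.
    """
    resid_df = float(model.n_obs - model.n_fixed)
    if A is None:
        return resid_df
    se2 = theta3[2]
    th = theta3[active]
    k = th.size

    def var_l(t):
        full = np.zeros(3)
        full[active] = t
        cov = model._cov_beta(full)
        return float(contrast @ cov @ contrast)

    h = 1e-4 * np.maximum(np.abs(th), 1e-3 * se2)
    grad = np.empty(k)
    for j in range(k):
        tp, tm = th.copy(), th.copy()
        tp[j] += h[j]
        tm[j] = max(tm[j] - h[j], 1e-12 * se2)
        grad[j] = (var_l(tp) - var_l(tm)) / (tp[j] - tm[j])

    v = float(contrast @ model._cov_beta(theta3) @ contrast)
    denom = float(grad @ A @ grad)
    if denom <= 0:
        return resid_df
    nu = 2.0 * v**2 / denom
    # guard against numerically absurd values
    return float(np.clip(nu, 1.0, resid_df))


@dataclass
class PowerTrendResults:
    """REML estimates plus the sequential Satterthwaite ANOVA."""

    model: PowerTrendModel
    params: np.ndarray
    cov_params: np.ndarray
    vc: np.ndarray  # (sigma0^2, sigma1^2, sigma_res^2)
    neg2reml: float
    converged: bool
    singular: bool
    _anova_cache: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def fixed_effects(self) -> pd.Series:
        names = ("Intercept",) + self.model.term_names
        return pd.Series(self.params, index=names)

    @property
    def variance_components(self) -> pd.Series:
        return pd.Series(self.vc, index=["subject_intercept", "subject_run_slope",
                                         "residual"])

    def anova(self, ddf_method: str = "satterthwaite") -> pd.DataFrame:
        """Sequential (Type I) ANOVA of the fixed terms.

        Hypothesis matrices are the rows of the triangular factor from the
        QR decomposition of the fixed design, so with zero random-effect
        variances the F values reduce exactly to ordinary sequential ANOVA.
        ``ddf_method`` is 'satterthwaite' (default) or 'residual' (n - p).
        """
        if ddf_method == "satterthwaite" and self._anova_cache is not None:
            return self._anova_cache
        m = self.model
        R = np.linalg.qr(m.X, mode="r")
        resid_df = float(m.n_obs - m.n_fixed)
        if ddf_method == "satterthwaite" and self.vc[2] > 0:
            active = _active_components(m, self.vc)
            A = _vc_covariance(m, self.vc, active)
        elif ddf_method == "satterthwaite":
            ddf_method = "residual"  # perfect fit: no stochastic part to expand
        rows = []
        for j, name in enumerate(m.term_names):
            L = R[j + 1: j + 2, :]  # every term here is 1 df
            q = L.shape[0]
            LCL = L @ self.cov_params @ L.T
            Lb = L @ self.params
            F = float(Lb @ np.linalg.solve(LCL, Lb) / q)
            if ddf_method == "satterthwaite":
                ddf = _satterthwaite_df(m, self.vc, L[0], active, A)
            elif ddf_method == "residual":
                ddf = resid_df
            else:
                raise ValueError(f"unknown ddf_method {ddf_method!r}")
            p = float(stats.f.sf(F, q, ddf))
            rows.append({"term": name, "F": F, "df_num": q, "df_den": ddf,
                         "p": p, "partial_eta_sq": partial_eta_squared(F, q, ddf)})
        out = pd.DataFrame(rows).set_index("term")
        if ddf_method == "satterthwaite":
            self._anova_cache = out
        return out

    def summary(self) -> str:
        lines = ["Linear mixed model of band power across feedback runs (REML)",
                 f"observations: {self.model.n_obs}   "
                 f"subjects: {len(self.model._blocks)}   "
                 f"converged: {self.converged}   singular: {self.singular}",
                 "", "Fixed effects:"]
        fe = self.fixed_effects
        for name, est, se in zip(fe.index, fe.values, self.bse):
            lines.append(f"  {name:<24s} {est:>10.4f}  (SE {se:.4f})")
        lines.append("")
        lines.append("Variance components:")
        for name, v in self.variance_components.items():
            lines.append(f"  {name:<24s} {v:>10.4f}")
        lines.append("")
        lines.append("Type I ANOVA (Satterthwaite denominator df):")
        an = self.anova()
        for term, row in an.iterrows():
            lines.append(f"  {term:<24s} F({int(row.df_num)},{row.df_den:6.1f}) = "
                         f"{row.F:8.3f}   p = {row.p:.4f}   "
                         f"eta_p^2 = {row.partial_eta_sq:.4f}")
        return "\n".join(lines)


# -- convenience wrappers ---------------------------------------

def fit_lmm(table: pd.DataFrame, band: str = "SMR", channel: str = "Cz",
            **kwargs) -> PowerTrendResults:
    """Fit the full group x condition x runs model on one band's power."""
    return PowerTrendModel.from_power_table(table, band=band, channel=channel,
                                            **kwargs).fit()


def anova_type1(results: PowerTrendResults,
                ddf_method: str = "satterthwaite") -> pd.DataFrame:
    return results.anova(ddf_method=ddf_method)


def post_test_per_group(table: pd.DataFrame, group: str, band: str = "SMR",
                        channel: str = "Cz", **kwargs) -> PowerTrendResults:
    """Per-group follow-up model (condition + runs + condition:runs)."""
    return PowerTrendModel.from_group_subset(table, group, band=band,
                                             channel=channel, **kwargs).fit()


# -- generative power-table model ------------------------------------------

def simulate_power_table(
    n_per_cell: int = 15,
    group_slopes: dict | None = None,
    *,
    mu: float = 4.5,
    group_effect: float = 0.0,
    condition_effect: float = 0.0,
    sigma_intercept: float = 2.0,
    sigma_slope: float = 0.1,
    sigma_res: float = 0.5,
    runs=tuple(range(1, 7)),
    band: str = "SMR",
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a power table directly from the model's own generative process.

    Per-run feedback-site power in uV^2: subject intercepts N(mu + effects,
    sigma_intercept^2), subject run slopes N(group slope, sigma_slope^2) in
    uV^2 per run, residual noise N(0, sigma_res^2).  Used for endpoint
    calibration and power studies without simulating raw EEG.  The default
    scale matches the EEG generator: a 3 uV SMR source gives mu = A^2/2 =
    4.5 uV^2, and its log-normal amplitude heterogeneity and slope spread
    translate to roughly the default sigma values.
    """
    group_slopes = group_slopes if group_slopes is not None else {"3D": 0.0, "2D": 0.0}
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for group in ("3D", "2D"):
        for condition in ("real", "sham"):
            for _ in range(n_per_cell):
                sid += 1
                g = GROUP_CODE[group]
                c = CONDITION_CODE[condition]
                b0 = rng.normal(mu + group_effect * g + condition_effect * c,
                                sigma_intercept)
                b1 = rng.normal(group_slopes[group], sigma_slope)
                for r in runs:
                    y = b0 + b1 * r + rng.normal(0.0, sigma_res)
                    rows.append({"subject_id": f"S{sid:03d}", "group": group,
                                 "condition": condition, "run": r,
                                 "channel": "Cz", "band": band,
                                 "mean_power": y,
                                 "n_segments_used": len(runs),
                                 "n_segments_rejected": 0})
    return pd.DataFrame(rows)
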