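"""Mixed-model ANCOVA of taxon biomass on the detailed grid.

Per taxon group (or total prey), the model for ln(biomass + 1) of each
replicate grab is

    y = zone + period + zone:period + beta1 z + beta2 z^2 + b_station + eps

with sum-to-zero factor contrasts, depth standardized over the analyzed
rows, a station random intercept shared by all visits to a station, and
replicate-level residual error.  Estimation is REML (statsmodels MixedLM);
marginal (Type-III-style) F statistics are computed for the five effects
with denominator degrees of freedom from the Satterthwaite approximation,
implemented here on a closed-form random-intercept REML likelihood (the
same eigen-decomposition construction lmerTest uses).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import effects as me
from .simulate import PREY_GROUPS, TAXA

__all__ = [
    "transform_biomass",
    "standardize_depth",
    "MixedAncova",
    "MixedAncovaResults",
    "fit_mixed_ancova",
    "ancova_report",
    "total_prey_table",
]

#: effect rows of the ANCOVA table, in reporting order
EFFECTS: tuple[str, ...] = ("zone", "period", "zone:period", "depth", "depth2")

_FORMULA = "lnb ~ C(zone, Sum) + C(period, Sum) + C(zone, Sum):C(period, Sum) + z + z2"

_TERM_TO_EFFECT = {
    "C(zone, Sum)": "zone",
    "C(period, Sum)": "period",
    "C(zone, Sum):C(period, Sum)": "zone:period",
    "z": "depth",
    "z2": "depth2",
}


def transform_biomass(y):
    """ln(X + 1) transform of wet biomass; domain error below zero."""
    arr = np.asarray(y, dtype=float)
    if np.any(arr < 0):
        raise ValueError("biomass must be >= 0")
    out = np.log1p(arr)
    return float(out) if np.isscalar(y) else out


def standardize_depth(depths) -> tuple[np.ndarray, np.ndarray]:
    """Center/scale depths to mean 0, SD 1 (n-1 convention); returns (z, z^2)."""
    arr = np.asarray(depths, dtype=float)
    if arr.size < 2 or np.isclose(arr.std(ddof=1), 0.0):
        raise ValueError("need >= 2 distinct depths to standardize")
    z = (arr - arr.mean()) / arr.std(ddof=1)
    return z, z * z


class ConvergenceError(RuntimeError):
    """Mixed-model estimation failed to converge after restarts."""


# ---------------------------------------------------------------------------
# closed-form REML pieces for the random-intercept model (used for the
# Satterthwaite derivatives and as a cross-check of the MixedLM fit)
# ---------------------------------------------------------------------------


@dataclass
class _GroupSums:
    """Sufficient statistics per station for GLS under V = s2e I + s2s J."""

    n_i: np.ndarray  # grabs per station
    SX: np.ndarray  # per-station column sums of X
    Sy: np.ndarray  # per-station sums of y
    XtX: np.ndarray
    Xty: np.ndarray
    yty: float
    n: int
    p: int


def _group_sums(X: np.ndarray, y: np.ndarray, groups: np.ndarray) -> _GroupSums:
    order = np.argsort(groups, kind="stable")
    Xs, ys, gs = X[order], y[order], groups[order]
    _, start = np.unique(gs, return_index=True)
    n_i = np.diff(np.append(start, len(gs)))
    SX = np.add.reduceat(Xs, start, axis=0)
    Sy = np.add.reduceat(ys, start)
    return _GroupSums(
        n_i=n_i.astype(float),
        SX=SX,
        Sy=Sy,
        XtX=X.T @ X,
        Xty=X.T @ y,
        yty=float(y @ y),
        n=len(y),
        p=X.shape[1],
    )


def _gls(theta: np.ndarray, gs: _GroupSums):
    """GLS beta, covariance C = (X'V^-1 X)^-1 and REML log-likelihood."""
    v_s, v_e = float(theta[0]), float(theta[1])
    if v_e <= 0 or v_s < 0:
        return None, None, -np.inf
    c = v_s / (v_e + gs.n_i * v_s)
    XtVX = (gs.XtX - (gs.SX * c[:, None]).T @ gs.SX) / v_e
    XtVy = (gs.Xty - gs.SX.T @ (c * gs.Sy)) / v_e
    ytVy = (gs.yty - float(c @ (gs.Sy**2))) / v_e
    try:
        C = np.linalg.inv(XtVX)
    except np.linalg.LinAlgError:
        return None, None, -np.inf
    beta = C @ XtVy
    logdetV = float(np.sum((gs.n_i - 1) * np.log(v_e) + np.log(v_e + gs.n_i * v_s)))
    sign, logdetXtVX = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return None, None, -np.inf
    resid_quad = ytVy - float(XtVy @ beta)
    ll = -0.5 * (logdetV + logdetXtVX + resid_quad)
    return beta, C, ll


def _theta_cov(theta: np.ndarray, gs: _GroupSums) -> np.ndarray:
    """Asymptotic covariance of the REML variance estimates (inverse
    numeric Hessian of the negative REML log-likelihood)."""
    h = np.maximum(1e-5 * np.abs(theta), 1e-7)
    # keep the stencil inside the feasible region (variances >= 0)
    base = np.array([max(theta[0], h[0]), max(theta[1], 2 * h[1])])

    def ll(t):
        return _gls(t, gs)[2]

    H = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            ei = np.zeros(2)
            ej = np.zeros(2)
            ei[i] = h[i]
            ej[j] = h[j]
            H[i, j] = (
                ll(base + ei + ej) - ll(base + ei - ej)
                - ll(base - ei + ej) + ll(base - ei - ej)
            ) / (4 * h[i] * h[j])
    H = -(H + H.T) / 2.0
    if not np.all(np.isfinite(H)):
        return np.zeros((2, 2))  # forces the residual-df fallback downstream
    try:
        W = np.linalg.inv(H)
        if not np.all(np.isfinite(W)) or W[0, 0] < 0 or W[1, 1] < 0:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        W = np.linalg.pinv(H)
        if not np.all(np.isfinite(W)):
            W = np.zeros((2, 2))
    return W


def _satterthwaite_F(
    L: np.ndarray,
    beta: np.ndarray,
    theta: np.ndarray,
    gs: _GroupSums,
    W: np.ndarray,
) -> tuple[float, float, float]:
    """Type-III F statistic for contrast L with Satterthwaite df2.

    Eigen-decomposes L C L' and pools per-direction candidate df the way
    lmerTest does for multi-df contrasts.
    """
    _, C, _ = _gls(theta, gs)
    M = L @ C @ L.T
    q = L.shape[0]
    Minv = np.linalg.inv(M)
    Lb = L @ beta
    F = float(Lb @ Minv @ Lb) / q

    d, U = np.linalg.eigh(M)
    h = np.maximum(1e-5 * np.abs(theta), 1e-7)
    nus = []
    for i in range(q):
        b_i = U[:, i]
        ell = b_i @ L

        def phi(t):
            _, Ct, _ = _gls(t, gs)
            return float(ell @ Ct @ ell)

        g = np.empty(2)
        for j in range(2):
            ej = np.zeros(2)
            ej[j] = h[j]
            g[j] = (phi(theta + ej) - phi(np.maximum(theta - ej, 0.0))) / (
                (theta[j] + h[j]) - max(theta[j] - h[j], 0.0)
            )
        denom = float(g @ W @ g)
        if denom <= 0 or not np.isfinite(denom):
            nu = float(gs.n - gs.p)  # fall back to the residual df
        else:
            nu = 2.0 * d[i] ** 2 / denom
        nus.append(nu)

    # pool the per-direction df
    terms = [nu / (nu - 2.0) for nu in nus if nu > 2.0]
    if not terms:
        df2 = float(gs.n - gs.p)
    else:
        E = float(np.sum(terms))
        df2 = 2.0 * E / (E - q) if E > q else float(gs.n - gs.p)
    df2 = min(df2, float(gs.n - gs.p))
    return F, float(q), df2


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


def total_prey_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-grab total prey biomass (the six diet groups summed).

    Returns a survey-style table with taxon_group = "total_prey".  Raises
    if any grab lacks an explicit row for one of the six prey groups.
    """
    prey = table[table["taxon_group"].isin(PREY_GROUPS)]
    keys = ["station_id", "zone", "period", "design", "line", "depth_m",
            "sediment", "replicate_index"]
    counts = prey.groupby(keys, observed=True)["taxon_group"].nunique()
    if (counts != len(PREY_GROUPS)).any():
        bad = counts[counts != len(PREY_GROUPS)].index[0]
        raise ValueError(
            f"grab {bad} is missing one of the prey groups {PREY_GROUPS}; "
            "absent groups must be recorded as explicit zeros"
        )
    out = prey.groupby(keys, observed=True, as_index=False)[
        "biomass_wet_g_per_m2"
    ].sum()
    out["taxon_group"] = "total_prey"
    return out


@dataclass
class MixedAncovaResults:
    """REML fit of the per-taxon mixed ANCOVA."""

    response: str
    params: pd.Series
    cov_params: pd.DataFrame
    sigma2_station: float
    sigma2_resid: float
    effect_table: pd.DataFrame  # effect, F, df1, df2, p
    depth_center: float
    depth_scale: float
    transform: str
    n_obs: int
    n_stations: int
    converged: bool
    method: str

    def me_classification(
        self,
        specs: tuple[me.EffectSizeSpec, ...] | None = None,
        alpha: float = 0.05,
    ) -> pd.DataFrame:
        """Effect table augmented with minimum-effects classifications."""
        specs = specs or me.default_effect_sizes()
        rows = []
        for _, r in self.effect_table.iterrows():
            label = me.classify_effect(r["F"], r["df1"], r["df2"], specs, alpha)
            rows.append(label)
        out = self.effect_table.copy()
        out["me_class"] = rows
        return out

    def summary(self) -> str:
        lines = [
            f"Mixed ANCOVA for {self.response} (response {self.transform})",
            f"  n = {self.n_obs} grabs at {self.n_stations} stations; "
            f"REML via {self.method}",
            f"  variance components: station {self.sigma2_station:.4f}, "
            f"residual {self.sigma2_resid:.4f}",
            f"  depth standardized with center {self.depth_center:.3f} m, "
            f"scale {self.depth_scale:.3f} m",
            "",
            self.effect_table.to_string(
                index=False,
                formatters={
                    "F": "{:.3f}".format,
                    "df2": "{:.1f}".format,
                    "p": "{:.4g}".format,
                },
            ),
        ]
        return "\n".join(lines)


class MixedAncova:
    """Mixed-model ANCOVA builder for one taxon group of a survey table."""

    def __init__(self, data: pd.DataFrame, response: str):
        self.response = response
        self.data = data

    @classmethod
    def from_survey_table(cls, table: pd.DataFrame, taxon_group: str) -> "MixedAncova":
        """Build from a long survey table; grid rows only.

        ``taxon_group`` may be any group in the table or ``"total_prey"``.
        """
        grid = table[table["design"] == "grid"]
        if taxon_group == "total_prey":
            sub = total_prey_table(grid)
        else:
            if taxon_group not in set(grid["taxon_group"]):
                raise ValueError(f"taxon group {taxon_group!r} not in table")
            sub = grid[grid["taxon_group"] == taxon_group].copy()
        data = sub[
            ["station_id", "zone", "period", "depth_m", "replicate_index",
             "biomass_wet_g_per_m2"]
        ].copy()
        # canonical row order so estimates are invariant to input ordering
        data = data.sort_values(
            ["station_id", "period", "replicate_index"], kind="stable"
        ).reset_index(drop=True)

        cell = data.groupby(["zone", "period"], observed=True)["station_id"].nunique()
        zones = sorted(data["zone"].unique())
        periods = sorted(data["period"].unique())
        if len(zones) < 2 or len(periods) < 2:
            raise ValueError(
                "the ANCOVA needs >= 2 zones and >= 2 periods; got "
                f"{len(zones)} zone(s), {len(periods)} period(s)"
            )
        for z in zones:
            for p in periods:
                n = cell.get((z, p), 0)
                if n == 0:
                    raise ValueError(
                        f"design is singular: no stations in zone {z}, period {p}"
                    )
                if n < 2:
                    raise ValueError(
                        f"zone {z}, period {p} has {n} station; need >= 2"
                    )
        return cls(data, taxon_group)

    def fit(self, reml: bool = True, max_restarts: int = 5) -> MixedAncovaResults:
        import statsmodels.formula.api as smf

        df = self.data.copy()
        df["lnb"] = transform_biomass(df["biomass_wet_g_per_m2"].to_numpy())
        depths = df["depth_m"].to_numpy()
        center, scale = float(np.mean(depths)), float(np.std(depths, ddof=1))
        z, z2 = standardize_depth(depths)
        df["z"], df["z2"] = z, z2

        model = smf.mixedlm(_FORMULA, df, groups=df["station_id"])
        methods = ["lbfgs", "bfgs", "cg", "powell", "nm"][:max_restarts]
        fit = None
        used = ""
        for method_name in methods:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    cand = model.fit(reml=reml, method=method_name, maxiter=500)
                except (np.linalg.LinAlgError, ValueError):
                    continue
            if cand.converged and np.isfinite(cand.params).all():
                fit = cand
                used = method_name
                break
        if fit is None:
            raise ConvergenceError(
                f"mixed ANCOVA for {self.response} failed to converge "
                f"after {len(methods)} restarts"
            )

        X = np.asarray(model.exog)
        y = df["lnb"].to_numpy()
        groups = df["station_id"].to_numpy()
        gs = _group_sums(X, y, groups)
        theta = np.array([float(fit.cov_re.iloc[0, 0]), float(fit.scale)])
        beta, C, _ = _gls(theta, gs)
        W = _theta_cov(theta, gs)

        design_info = model.data.design_info
        names = design_info.column_names
        rows = []
        for term, effect in _TERM_TO_EFFECT.items():
            sl = design_info.term_name_slices[term]
            idx = np.arange(len(names))[sl]
            L = np.zeros((len(idx), len(names)))
            L[np.arange(len(idx)), idx] = 1.0
            F, df1, df2 = _satterthwaite_F(L, beta, theta, gs, W)
            p = float(stats.f.sf(F, df1, df2))
            rows.append({"effect": effect, "F": F, "df1": df1, "df2": df2, "p": p})

        return MixedAncovaResults(
            response=self.response,
            params=pd.Series(beta, index=names),
            cov_params=pd.DataFrame(C, index=names, columns=names),
            sigma2_station=float(theta[0]),
            sigma2_resid=float(theta[1]),
            effect_table=pd.DataFrame(rows),
            depth_center=center,
            depth_scale=scale,
            transform="ln(x+1)",
            n_obs=len(df),
            n_stations=df["station_id"].nunique(),
            converged=True,
            method=used,
        )


def fit_mixed_ancova(table: pd.DataFrame, taxon_group: str, **fit_kw) -> MixedAncovaResults:
    """Convenience wrapper: build and fit the per-taxon mixed ANCOVA."""
    return MixedAncova.from_survey_table(table, taxon_group).fit(**fit_kw)


_ME_MARKS = {
    "negligible-to-small": "",
    "exceeds-small": "*",
    "exceeds-medium": "**",
    "exceeds-large": "***",
}


def ancova_report(
    fits: list[MixedAncovaResults],
    specs: tuple[me.EffectSizeSpec, ...] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """ANCOVA summary table: one row per response, one column set per effect.

    Cells carry the p-value, a significance flag at the test level, and the
    minimum-effects classification mark ('*' exceeds small, '**' medium,
    '***' large).
    """
    if not fits:
        raise ValueError("no fits supplied")
    specs = specs or me.default_effect_sizes()
    rows = []
    for fit in fits:
        cls = fit.me_classification(specs, alpha)
        row: dict[str, object] = {"response": fit.response}
        for _, r in cls.iterrows():
            e = r["effect"]
            row[f"{e}_p"] = r["p"]
            row[f"{e}_sig"] = bool(r["p"] <= alpha)
            row[f"{e}_me"] = _ME_MARKS[r["me_class"]]
        rows.append(row)
    return pd.DataFrame(rows)
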