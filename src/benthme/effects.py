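"""Minimum-effects (ME) interval hypothesis tests on F statistics.

A classical ANOVA F test asks whether an effect is exactly zero.  For field
surveys of benthic communities that null is rarely interesting: biomass is
patchy and 20-30% swings are ordinary, so tiny effects reach significance at
large n.  The minimum-effects framework instead tests whether the observed
effect exceeds a chosen *boundary* effect size.  The null hypothesis is the
interval "the true effect is no larger than f_ES"; the reference distribution
is a noncentral F whose noncentrality λ encodes the boundary, approximated
for large samples as

    λ = DF_err · PV / (1 − PV) = DF_err · f²

where f is Cohen's effect size and PV = f²/(1+f²) the proportion of variance
it explains.  Rejection means the effect is demonstrably larger than the
boundary, not merely nonzero.

Default boundaries follow the benthic-monitoring convention: small f = 0.2
(natural variability), medium f = 0.5 (a community approaching or crossing an
ecological boundary), large f = 0.8 (disturbance-scale change).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = [
    "EffectSizeSpec",
    "METestResult",
    "default_effect_sizes",
    "pv_from_f",
    "f_from_pv",
    "noncentrality",
    "me_critical_value",
    "me_test",
    "classify_effect",
    "post_hoc_power",
]


def pv_from_f(f: float) -> float:
    """Proportion of variance PV = f²/(1+f²) implied by Cohen's f.

    f = 0.2 gives PV ≈ 0.0385 (≈4%), f = 0.5 gives 0.20, f = 0.8 gives 0.3902.
    """
    if f < 0:
        raise ValueError(f"effect size f must be >= 0, got {f}")
    return f * f / (1.0 + f * f)


def f_from_pv(pv: float) -> float:
    """Inverse conversion: Cohen's f = sqrt(PV/(1−PV))."""
    if not 0.0 <= pv < 1.0:
        raise ValueError(f"pv must lie in [0, 1), got {pv}")
    return math.sqrt(pv / (1.0 - pv))


@dataclass(frozen=True)
class EffectSizeSpec:
    """A named minimum-effect boundary (label, Cohen's f)."""

    label: str
    f: float

    def __post_init__(self) -> None:
        if self.f < 0:
            raise ValueError(f"effect size f must be >= 0, got {self.f}")

    @property
    def pv(self) -> float:
        """Proportion of variance at this boundary."""
        return pv_from_f(self.f)


def default_effect_sizes() -> tuple[EffectSizeSpec, ...]:
    """Benthic-survey boundary triplet: small 0.2, medium 0.5, large 0.8."""
    return (
        EffectSizeSpec("small", 0.2),
        EffectSizeSpec("medium", 0.5),
        EffectSizeSpec("large", 0.8),
    )


def noncentrality(df2: float, f: float, *, form: str = "corrected") -> float:
    """Large-sample noncentrality λ of the boundary distribution.

    form="corrected" (default) is the standard approximation
    λ = df2·PV/(1−PV) = df2·f².  form="printed" evaluates the
    dimensionally odd variant λ = df2·PV/(1/PV) = df2·PV², retained only
    so the two can be compared; it is not used by any default code path.
    """
    if df2 <= 0:
        raise ValueError(f"error df must be > 0, got {df2}")
    if f < 0:
        raise ValueError(f"effect size f must be >= 0, got {f}")
    pv = pv_from_f(f)
    if form == "corrected":
        return df2 * f * f
    if form == "printed":
        return df2 * pv * pv
    raise ValueError(f"unknown form {form!r}; use 'corrected' or 'printed'")


def _check_test_args(df1: float, df2: float, lam: float, alpha: float) -> None:
    if df1 <= 0 or df2 <= 0:
        raise ValueError(f"degrees of freedom must be > 0, got ({df1}, {df2})")
    if lam < 0:
        raise ValueError(f"noncentrality must be >= 0, got {lam}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")


def me_critical_value(df1: float, df2: float, lam: float, alpha: float = 0.05) -> float:
    """Upper (1−alpha) quantile of the noncentral F(df1, df2, λ) distribution.

    At λ = 0 this is the usual central-F critical value; it increases
    strictly with λ.
    """
    _check_test_args(df1, df2, lam, alpha)
    if lam == 0.0:
        return float(stats.f.ppf(1.0 - alpha, df1, df2))
    return float(stats.ncf.ppf(1.0 - alpha, df1, df2, lam))


def _me_sf(F_obs: float, df1: float, df2: float, lam: float) -> float:
    if lam == 0.0:
        return float(stats.f.sf(F_obs, df1, df2))
    return float(stats.ncf.sf(F_obs, df1, df2, lam))


@dataclass(frozen=True)
class METestResult:
    """Outcome of one minimum-effects test at one boundary."""

    effect_label: str
    F_obs: float
    df1: float
    df2: float
    lam: float
    F_crit: float
    p_me: float
    alpha: float
    rejected: bool


def me_test(
    F_obs: float,
    df1: float,
    df2: float,
    spec: EffectSizeSpec,
    alpha: float = 0.05,
    *,
    form: str = "corrected",
) -> METestResult:
    """Test H_ME: true effect ≤ spec.f against Ha: effect > spec.f.

    p_me is the upper-tail probability of F_obs under the boundary
    noncentral F; rejection requires F_obs strictly above the critical
    value (a tie keeps the interval null).
    """
    if F_obs < 0:
        raise ValueError(f"F_obs must be >= 0, got {F_obs}")
    lam = noncentrality(df2, spec.f, form=form)
    _check_test_args(df1, df2, lam, alpha)
    f_crit = me_critical_value(df1, df2, lam, alpha)
    p_me = _me_sf(F_obs, df1, df2, lam)
    return METestResult(
        effect_label=spec.label,
        F_obs=float(F_obs),
        df1=float(df1),
        df2=float(df2),
        lam=float(lam),
        F_crit=f_crit,
        p_me=p_me,
        alpha=float(alpha),
        rejected=bool(F_obs > f_crit),
    )


#: classification label when no boundary is exceeded
NEGLIGIBLE = "negligible-to-small"


def classify_effect(
    F_obs: float,
    df1: float,
    df2: float,
    specs: tuple[EffectSizeSpec, ...] | None = None,
    alpha: float = 0.05,
) -> str:
    """Largest boundary whose ME hypothesis is rejected by F_obs.

    Returns "negligible-to-small" when not even the smallest boundary is
    rejected, otherwise "exceeds-<label>" for the largest rejected
    boundary.  Monotone non-decreasing in F_obs.
    """
    if specs is None:
        specs = default_effect_sizes()
    fs = [s.f for s in specs]
    if any(b <= a for a, b in zip(fs, fs[1:])):
        raise ValueError("effect-size specs must be strictly increasing in f")
    label = NEGLIGIBLE
    for spec in specs:
        if me_test(F_obs, df1, df2, spec, alpha).rejected:
            label = f"exceeds-{spec.label}"
        else:
            break
    return label


def post_hoc_power(df1: float, df2: float, lam: float, alpha: float = 0.05) -> float:
    """Power of the classical F test when the true noncentrality is λ.

    P[F' (df1, df2, λ) > F_crit(central, 1−alpha)]; equals alpha at λ = 0
    and increases to 1 as λ grows.
    """
    _check_test_args(df1, df2, lam, alpha)
    crit = float(stats.f.ppf(1.0 - alpha, df1, df2))
    return _me_sf(crit, df1, df2, lam)
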