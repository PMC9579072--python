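"""Station-averaged community structure analysis.

Pipeline: station x taxon matrix of mean ln(X+1) biomass (grid stations,
rare groups excluded) -> Bray-Curtis dissimilarity -> nonmetric
multidimensional scaling (NMDS) with period-zone centroids and 95% CIs ->
permutational MANOVA (sequential sums of squares of the Gower-centred
distance matrix, pseudo-F, free-permutation p-values) -> pairwise
permutation tests with Holm step-down adjustment.

The distance partitioning follows the McArdle-Anderson construction: with
A = -D^2/2 and G = CAC the double-centred inner-product matrix, the
sequential SS of a term is tr((H_j - H_{j-1}) G) for the hat matrices of
the growing design, and pseudo-F = (SS_term/df_term)/(SS_res/df_res).
Significance comes from free (unrestricted) permutation of rows.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "CommunityMatrix",
    "DissimilarityMatrix",
    "OrdinationResult",
    "NpmanovaResults",
    "build_community_matrix",
    "bray_curtis",
    "nmds",
    "centroids_ci",
    "Npmanova",
    "npmanova",
    "pairwise_permutation",
    "holm_adjust",
]

DEFAULT_TERMS: tuple[str, ...] = ("period", "zone", "sediment", "depth", "period:zone")


@dataclass
class CommunityMatrix:
    """Station-level community matrix plus row metadata.

    ``values``: rows = station visits (station x period), columns = taxon
    groups, entries = station-mean ln(X+1) biomass.  ``meta`` carries the
    design covariates per row (zone, period, sediment, line, depth).
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    dropped_groups: tuple[str, ...]
    average: str

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("community matrix values must be >= 0")
        if not self.values.index.is_unique:
            raise ValueError("community matrix row labels must be unique")


def build_community_matrix(
    table: pd.DataFrame,
    min_prevalence: float = 0.05,
    average: str = "transform-then-average",
    include_hotspots: bool = False,
) -> CommunityMatrix:
    """Average replicate biomass per station visit on the ln(X+1) scale.

    ``average`` picks the order of transform and mean: the default
    transforms each replicate then averages; "average-then-transform"
    averages raw biomass first.  Groups present (biomass > 0) at fewer than
    ``min_prevalence`` of the station visits are dropped.
    """
    if not 0.0 <= min_prevalence < 1.0:
        raise ValueError("min_prevalence must lie in [0, 1)")
    if average not in ("transform-then-average", "average-then-transform"):
        raise ValueError(f"unknown averaging order {average!r}")
    sub = table if include_hotspots else table[table["design"] == "grid"]
    if sub.empty:
        raise ValueError("no rows to build a community matrix from")
    sub = sub.copy()
    sub["row_id"] = sub["station_id"].astype(str) + "|" + sub["period"].astype(str)

    if average == "transform-then-average":
        sub["val"] = np.log1p(sub["biomass_wet_g_per_m2"])
        wide = sub.pivot_table(
            index="row_id", columns="taxon_group", values="val", aggfunc="mean"
        )
    else:
        wide = sub.pivot_table(
            index="row_id",
            columns="taxon_group",
            values="biomass_wet_g_per_m2",
            aggfunc="mean",
        )
        wide = np.log1p(wide)
    wide = wide.fillna(0.0)

    prevalence = (wide > 0).mean(axis=0)
    dropped = tuple(sorted(prevalence.index[prevalence < min_prevalence]))
    wide = wide.drop(columns=list(dropped))
    if wide.shape[1] == 0:
        raise ValueError("all taxon groups dropped by the prevalence filter")

    meta = (
        sub.groupby("row_id", observed=True)
        .agg(
            station_id=("station_id", "first"),
            zone=("zone", "first"),
            period=("period", "first"),
            design=("design", "first"),
            line=("line", "first"),
            sediment=("sediment", "first"),
            depth_m=("depth_m", "mean"),
        )
        .loc[wide.index]
    )
    return CommunityMatrix(values=wide, meta=meta, dropped_groups=dropped, average=average)


@dataclass
class DissimilarityMatrix:
    """Square symmetric Bray-Curtis dissimilarity matrix in [0, 1]."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if arr.shape[0] != arr.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(arr, arr.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(arr), 0.0, atol=1e-12):
            raise ValueError("dissimilarity diagonal must be zero")
        if arr.min() < -1e-12 or arr.max() > 1 + 1e-12:
            raise ValueError("Bray-Curtis entries must lie in [0, 1]")

    @property
    def labels(self) -> pd.Index:
        return self.values.index

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy()


def bray_curtis(M: CommunityMatrix | pd.DataFrame) -> DissimilarityMatrix:
    """Bray-Curtis dissimilarity d(i,j) = sum|x_i - x_j| / sum(x_i + x_j).

    Pairs of all-zero rows are 0/0; they are set to 0 (identical empty
    communities) with a warning.
    """
    vals = M.values if isinstance(M, CommunityMatrix) else M
    arr = np.asarray(vals, dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    if (arr < 0).any():
        raise ValueError("Bray-Curtis requires non-negative values")
    zero_rows = ~arr.any(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        D = squareform(pdist(arr, metric="braycurtis"))
    if zero_rows.sum() >= 2:
        warnings.warn(
            "all-zero row pairs present; their Bray-Curtis dissimilarity "
            "(0/0) is set to 0",
            stacklevel=2,
        )
    D = np.nan_to_num(D, nan=0.0)
    index = vals.index if isinstance(vals, pd.DataFrame) else pd.RangeIndex(len(arr))
    return DissimilarityMatrix(pd.DataFrame(D, index=index, columns=index))


@dataclass
class OrdinationResult:
    """NMDS configuration with Kruskal stress-1 fit statistic."""

    coords: pd.DataFrame
    stress: float
    n_starts: int
    converged: bool
    seed: int | None


def nmds(
    D: DissimilarityMatrix,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 500,
    seed: int | None = None,
) -> OrdinationResult:
    """Nonmetric MDS of a dissimilarity matrix (SMACOF with isotonic
    regression, best of ``n_starts`` random starts).

    Coordinates are centred at the origin and rotated to principal axes
    (axis 1 = dominant gradient); the reported stress is Kruskal stress-1
    so values are comparable across problem sizes.
    """
    from sklearn.manifold import MDS

    if k < 1 or n_starts < 1:
        raise ValueError("k and n_starts must be >= 1")
    mds = MDS(
        n_components=k,
        metric=False,
        n_init=n_starts,
        max_iter=max_iter,
        dissimilarity="precomputed",
        random_state=None if seed is None else int(seed),
        normalized_stress=True,
        eps=1e-7,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        X = mds.fit_transform(D.to_numpy())
    X = X - X.mean(axis=0)
    # rotate to principal axes so axis 1 carries the dominant gradient
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    X = X @ Vt.T
    # sign convention: largest-magnitude loading positive per axis
    for j in range(X.shape[1]):
        if X[np.abs(X[:, j]).argmax(), j] < 0:
            X[:, j] = -X[:, j]
    converged = bool(mds.n_iter_ < max_iter)
    if not converged:
        warnings.warn("NMDS hit the iteration cap in every start; "
                      "returning the best configuration found", stacklevel=2)
    coords = pd.DataFrame(
        X, index=D.labels, columns=[f"axis{i + 1}" for i in range(k)]
    )
    return OrdinationResult(
        coords=coords,
        stress=float(mds.stress_),
        n_starts=n_starts,
        converged=converged,
        seed=seed,
    )


def centroids_ci(
    ordination: OrdinationResult,
    grouping: pd.Series,
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-group centroid and t-based CI half-widths on each NMDS axis.

    Singleton groups get a NaN half-width and ``ci_defined=False``.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    coords = ordination.coords
    grouping = pd.Series(grouping, index=coords.index)
    rows = []
    for g, sub in coords.groupby(grouping, observed=True):
        n = len(sub)
        row: dict[str, object] = {"group": g, "n": n, "ci_defined": n >= 2}
        for ax in coords.columns:
            row[f"{ax}_centroid"] = float(sub[ax].mean())
            if n >= 2:
                se = sub[ax].std(ddof=1) / math.sqrt(n)
                tcrit = stats.t.ppf(0.5 + level / 2.0, n - 1)
                row[f"{ax}_halfwidth"] = float(tcrit * se)
            else:
                row[f"{ax}_halfwidth"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# NPMANOVA
# ---------------------------------------------------------------------------


def _gower_center(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    A = -0.5 * D * D
    C = np.eye(n) - np.full((n, n), 1.0 / n)
    return C @ A @ C


def _term_design(meta: pd.DataFrame, term: str) -> np.ndarray:
    """Model-matrix columns (no intercept) for one NPMANOVA term."""
    def onehot(col: str) -> np.ndarray:
        return pd.get_dummies(meta[col].astype(str)).to_numpy(dtype=float)

    if ":" in term:
        a, b = term.split(":", 1)
        joint = meta[a].astype(str) + ":" + meta[b].astype(str)
        return pd.get_dummies(joint).to_numpy(dtype=float)
    if term == "depth":
        # two-level isobath factor
        return onehot("line")
    return onehot(term)


def _hat(X: np.ndarray) -> tuple[np.ndarray, int]:
    # rank-revealing via SVD for robustness with dummy collinearity
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    tol = s.max() * max(X.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    Ur = U[:, :rank]
    return Ur @ Ur.T, rank


@dataclass
class NpmanovaResults:
    """Sequential-SS NPMANOVA table with permutation p-values."""

    table: pd.DataFrame  # term, df, SS, pseudo_F, R2, p
    total_ss: float
    n_permutations: int | str
    seed: int | None
    term_order: tuple[str, ...]

    def summary(self) -> str:
        head = (
            f"NPMANOVA (sequential SS, {self.n_permutations} permutations, "
            f"seed {self.seed})"
        )
        return head + "\n" + self.table.to_string(index=False)


class Npmanova:
    """Permutational MANOVA of a Bray-Curtis matrix by design factors."""

    def __init__(
        self,
        M: CommunityMatrix,
        term_order: tuple[str, ...] = DEFAULT_TERMS,
    ):
        self.M = M
        self.term_order = tuple(term_order)
        self.D = bray_curtis(M)

    def fit(
        self,
        n_perm: int | str = 9999,
        seed: int | None = None,
    ) -> NpmanovaResults:
        """Partition the distance matrix and permute for p-values.

        ``n_perm="exhaustive"`` enumerates all row permutations (only
        sensible for tiny inputs); otherwise free random permutations with
        p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
        """
        meta = self.M.meta
        D = self.D.to_numpy()
        n = D.shape[0]
        G = _gower_center(D)
        total_ss = float(np.trace(G))

        ones = np.ones((n, 1))
        hats = []
        X = ones
        rank_prev = 1
        dfs = []
        for term in self.term_order:
            X = np.hstack([X, _term_design(meta, term)])
            H, rank = _hat(X)
            df = rank - rank_prev
            if df == 0:
                raise ValueError(
                    f"term {term!r} is confounded with earlier terms "
                    "(adds no model df)"
                )
            hats.append(H)
            dfs.append(df)
            rank_prev = rank
        df_res = n - rank_prev
        if df_res <= 0:
            raise ValueError("zero residual df: model saturates the rows")
        H0, _ = _hat(ones)

        def term_stats(Gm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            traces = np.array([float(np.sum(H * Gm)) for H in hats])
            base = float(np.sum(H0 * Gm))
            ss = np.diff(np.concatenate([[base], traces]))
            ss_res = float(np.trace(Gm)) - float(np.sum(ss)) - base
            F = (ss / np.array(dfs)) / (ss_res / df_res)
            return ss, F

        ss_obs, F_obs = term_stats(G)

        if n_perm == "exhaustive":
            perms = list(itertools.permutations(range(n)))
            count = np.zeros(len(self.term_order))
            for pi in perms:
                idx = np.array(pi)
                _, Fp = term_stats(G[np.ix_(idx, idx)])
                count += Fp >= F_obs - 1e-12
            pvals = count / len(perms)
            n_used: int | str = "exhaustive"
        else:
            n_perm = int(n_perm)
            if n_perm < 99:
                raise ValueError("n_perm must be >= 99")
            rng = np.random.default_rng(seed)
            count = np.zeros(len(self.term_order))
            for _ in range(n_perm):
                idx = rng.permutation(n)
                _, Fp = term_stats(G[np.ix_(idx, idx)])
                count += Fp >= F_obs - 1e-12
            pvals = (1.0 + count) / (1.0 + n_perm)
            n_used = n_perm

        r2 = ss_obs / total_ss
        rows = [
            {
                "term": t,
                "df": dfs[i],
                "SS": ss_obs[i],
                "pseudo_F": F_obs[i],
                "R2": r2[i],
                "p": pvals[i],
            }
            for i, t in enumerate(self.term_order)
        ]
        ss_res = total_ss - float(np.sum(ss_obs))
        rows.append(
            {
                "term": "residual",
                "df": df_res,
                "SS": ss_res,
                "pseudo_F": np.nan,
                "R2": ss_res / total_ss,
                "p": np.nan,
            }
        )
        table = pd.DataFrame(rows)
        assert abs(table["SS"].sum() - total_ss) < 1e-8 * max(total_ss, 1.0)
        return NpmanovaResults(
            table=table,
            total_ss=total_ss,
            n_permutations=n_used,
            seed=seed,
            term_order=self.term_order,
        )


def npmanova(
    M: CommunityMatrix,
    term_order: tuple[str, ...] = DEFAULT_TERMS,
    n_perm: int | str = 9999,
    seed: int | None = None,
) -> NpmanovaResults:
    """Functional wrapper around :class:`Npmanova`."""
    return Npmanova(M, term_order).fit(n_perm=n_perm, seed=seed)


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="holm")[1]


def _two_group_pseudo_F(Dsub: np.ndarray, labels: np.ndarray) -> float:
    G = _gower_center(Dsub)
    X = np.hstack([np.ones((len(labels), 1)), pd.get_dummies(labels).to_numpy(float)])
    H, rank = _hat(X)
    H0, _ = _hat(np.ones((len(labels), 1)))
    ss_model = float(np.sum(H * G)) - float(np.sum(H0 * G))
    ss_res = float(np.trace(G)) - ss_model
    df1 = rank - 1
    df2 = len(labels) - rank
    return (ss_model / df1) / (ss_res / df2)


def pairwise_permutation(
    M: CommunityMatrix,
    grouping: pd.Series | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise two-group permutation tests with Holm adjustment.

    Defaults to the period x zone combinations.  Each pair gets a
    two-group pseudo-F permutation test on its sub-matrix of the full
    Bray-Curtis matrix; Holm step-down controls the family-wise error.
    """
    D = bray_curtis(M).to_numpy()
    if grouping is None:
        grouping = (
            "P" + M.meta["period"].astype(str) + "-" + M.meta["zone"].astype(str)
        )
    grouping = pd.Series(np.asarray(grouping, dtype=object))
    counts = grouping.value_counts()
    groups = [g for g in counts.index if counts[g] >= 2]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with >= 2 members each")
    rng = np.random.default_rng(seed)
    rows = []
    for g1, g2 in itertools.combinations(sorted(groups), 2):
        mask = grouping.isin([g1, g2]).to_numpy()
        Dsub = D[np.ix_(mask, mask)]
        labels = grouping.to_numpy()[mask]
        F_obs = _two_group_pseudo_F(Dsub, labels)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            if _two_group_pseudo_F(Dsub, perm) >= F_obs - 1e-12:
                count += 1
        p = (1.0 + count) / (1.0 + n_perm)
        rows.append({"group1": g1, "group2": g2, "pseudo_F": F_obs, "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_raw"].to_numpy())
    out["significant"] = out["p_holm"] <= alpha
    return out
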