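"""Distance-matrix inference in Aitchison geometry.

Implements the multivariate test battery used throughout the pipeline:

* ``permanova`` — permutational multivariate ANOVA with sequential
  (order-of-entry) sums of squares over an ordered term list, so a model
  like ``smoking + gender + age + log population`` partitions the total
  sum of squares of the distance matrix term by term.  P-values come
  from free permutation of sample labels, with the observed statistic
  included in the null set.
* ``permanova_one_vs_rest`` — each age bin contrasted against all
  others, retaining the remaining covariates.
* ``homogeneity_test`` — multivariate dispersion: principal-coordinate
  embedding, per-group spatial (geometric) medians, each sample's
  distance to its own group's median (with the standard negative-
  eigenvalue correction), and a one-way ANOVA across groups.
* ``anosim`` / ``anosim_units`` — rank-based analysis of similarities
  over family or classroom units.
* ``twins_vs_siblings`` — two-sided Mann-Whitney test of within-twin
  versus within-sibling distances.
"""

from __future__ import annotations

import itertools

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

__all__ = [
    "PermanovaResult",
    "HomogeneityResult",
    "AnosimResult",
    "permanova",
    "permanova_one_vs_rest",
    "homogeneity_test",
    "geometric_median",
    "anosim",
    "anosim_units",
    "twins_vs_siblings",
]

_EXACT_CAP = 8  # max n for exhaustive label permutation


# ---------------------------------------------------------------------------
# design-matrix helpers


def _encode_term(values: pd.Series) -> np.ndarray:
    """Columns for one model term: numeric as-is, categorical dummy-coded."""
    if pd.api.types.is_numeric_dtype(values):
        return np.asarray(values, dtype=float)[:, None]
    dummies = pd.get_dummies(values.astype(str), drop_first=True)
    return dummies.to_numpy(dtype=float)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = len(a)
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection matrix onto the column space of x and its rank."""
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return q @ q.T, int(keep.sum())


@dataclass
class PermanovaResult:
    """Per-term pseudo-F table of a sequential PERMANOVA."""

    table: pd.DataFrame  # index: term; columns: SS, df, R2, F, p
    n_permutations: int
    dropped: list = field(default_factory=list)

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]

    @property
    def terms(self) -> list:
        return [t for t in self.table.index if t not in ("residual", "total")]


def permanova(
    dm: DistanceMatrix,
    design: pd.DataFrame,
    terms: list[str],
    n_perm: int | str = 999,
    seed: int = 0,
    ss_type: str = "sequential",
) -> PermanovaResult:
    """PERMANOVA of a distance matrix on an ordered term list.

    ``design`` rows must align with ``dm.ids``.  ``n_perm="exact"``
    enumerates all label permutations (only for very small n).  Terms
    that add no rank to the design (confounded or constant) are dropped
    with a warning and listed in ``result.dropped``.

    ``ss_type="sequential"`` (the default) partitions the total sum of
    squares in order of entry, so term R2 values plus the residual sum
    to 1.  ``ss_type="marginal"`` tests each term against the model
    holding all others; with correlated terms the marginal sums of
    squares do not partition the total, so the R2 column then need not
    sum to 1.
    """
    if ss_type not in ("sequential", "marginal"):
        raise ValueError("ss_type must be 'sequential' or 'marginal'")
    ids = list(dm.ids)
    design = design.loc[ids]
    d = dm.data
    n = len(ids)
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix is not symmetric")
    g = _gower_center(d)
    ss_total = float(np.trace(g))

    x = np.ones((n, 1))
    hat_prev, rank_prev = _hat(x)
    blocks, hdiffs, dfs, kept, dropped = {}, [], [], [], []
    for term in terms:
        cols = _encode_term(design[term])
        x = np.hstack([x, cols])
        hat_cur, rank_cur = _hat(x)
        df = rank_cur - rank_prev
        if df == 0:
            warnings.warn(f"term {term!r} is confounded or constant; dropped")
            dropped.append(term)
            x = x[:, : x.shape[1] - cols.shape[1]]
            continue
        blocks[term] = cols
        hdiffs.append(hat_cur - hat_prev)
        dfs.append(df)
        kept.append(term)
        hat_prev, rank_prev = hat_cur, rank_cur
    if not kept:
        raise ValueError("no estimable terms in the design")
    h_res = np.eye(n) - hat_prev
    df_res = n - rank_prev
    if ss_type == "marginal":
        hat_full, rank_full = hat_prev, rank_prev
        hdiffs, dfs = [], []
        for term in kept:
            others = [blocks[t] for t in kept if t != term]
            x_red = np.hstack([np.ones((n, 1))] + others)
            hat_red, rank_red = _hat(x_red)
            hdiffs.append(hat_full - hat_red)
            dfs.append(rank_full - rank_red)
    if df_res <= 0:
        raise ValueError("saturated design: no residual degrees of freedom")

    def term_stats(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        ss = np.array([float(np.sum(h * gmat)) for h in hdiffs])
        ss_res = float(np.sum(h_res * gmat))
        return ss, ss_res

    ss_obs, ss_res_obs = term_stats(g)
    f_obs = (ss_obs / np.array(dfs)) / (ss_res_obs / df_res)

    if n_perm == "exact":
        if n > _EXACT_CAP:
            raise ValueError(f"exact permutation only supported for n <= {_EXACT_CAP}")
        perms = np.array(list(itertools.permutations(range(n))))
        n_used = len(perms)
        include_obs = 0  # identity permutation is in the enumeration
    else:
        if n_perm < 99:
            raise ValueError("n_perm must be at least 99 (or 'exact')")
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(int(n_perm))])
        n_used = int(n_perm) + 1  # observed included in the null set
        include_obs = 1

    geq = np.zeros(len(kept))
    eps = 1e-12
    for start in range(0, len(perms), 64):
        chunk = perms[start : start + 64]
        gp = g[chunk[:, :, None], chunk[:, None, :]]
        ss_p = np.einsum("kij,pij->kp", np.array(hdiffs), gp)
        ss_res_p = np.einsum("ij,pij->p", h_res, gp)
        f_p = (ss_p / np.array(dfs)[:, None]) / (ss_res_p[None, :] / df_res)
        geq += (f_p >= f_obs[:, None] - eps).sum(axis=1)
    pvals = (geq + include_obs) / n_used

    rows = {
        t: (ss_obs[i], dfs[i], ss_obs[i] / ss_total, f_obs[i], pvals[i])
        for i, t in enumerate(kept)
    }
    rows["residual"] = (ss_res_obs, df_res, ss_res_obs / ss_total, np.nan, np.nan)
    rows["total"] = (ss_total, n - 1, 1.0, np.nan, np.nan)
    table = pd.DataFrame(rows, index=["SS", "df", "R2", "F", "p"]).T
    return PermanovaResult(table, n_used - 1, dropped)


def permanova_one_vs_rest(
    dm: DistanceMatrix,
    bins: pd.Series,
    design: pd.DataFrame,
    covariates: list[str],
    n_perm: int = 999,
    seed: int = 0,
) -> dict[str, PermanovaResult]:
    """One PERMANOVA per bin, contrasting that bin against all others.

    The bin indicator enters the model first, followed by the remaining
    covariates (age itself is excluded by construction).
    """
    bins = bins.loc[list(dm.ids)]
    levels = [b for b in pd.unique(bins) if b != ""]
    if len(levels) < 2:
        raise ValueError("need at least 2 bins")
    out = {}
    for k, level in enumerate(levels):
        if (bins == level).sum() < 3:
            raise ValueError(f"bin {level!r} has fewer than 3 samples")
        dsg = design.loc[list(dm.ids)].copy()
        dsg["_is_bin"] = (bins == level).astype(float)
        out[level] = permanova(
            dm, dsg, ["_is_bin"] + list(covariates), n_perm=n_perm, seed=seed + k
        )
    return out


# ---------------------------------------------------------------------------
# homogeneity of multivariate dispersion


def geometric_median(points: np.ndarray, tol: float = 1e-8, max_iter: int = 1000):
    """Weiszfeld iteration for the point minimizing summed Euclidean distance."""
    x = points.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(points - x, axis=1)
        if (d < tol).any():
            # at a data point: optimal unless the pull of the others exceeds 1
            at = points[d < tol][0]
            rest = points[d >= tol]
            if len(rest) == 0:
                return at
            r = ((rest - at) / np.linalg.norm(rest - at, axis=1)[:, None]).sum(axis=0)
            if np.linalg.norm(r) <= 1 + tol:
                return at
            d = np.maximum(d, tol)
        w = 1.0 / d
        x_new = (points * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(x_new - x) < tol:
            return x_new
        x = x_new
    return x


@dataclass
class HomogeneityResult:
    """Distances to group spatial medians and the ANOVA comparing them."""

    distances: pd.Series  # per sample, to own group's spatial median
    groups: pd.Series
    medians: dict  # group -> coordinates in the (real) PCoA space
    anova_f: float
    anova_p: float
    used_negative_correction: bool

    def group_means(self) -> pd.Series:
        return self.distances.groupby(self.groups).mean()


def homogeneity_test(dm: DistanceMatrix, groups: pd.Series) -> HomogeneityResult:
    """Betadisper-style homogeneity of multivariate dispersion.

    Embeds the distance matrix by principal coordinates (keeping
    negative-eigenvalue axes separately), finds each group's spatial
    median by Weiszfeld iteration on the real and imaginary axes, and
    compares samples' distances to their own group median across groups
    with a one-way ANOVA.  Squared distances are corrected as
    (real part)^2 - (imaginary part)^2, floored at zero.
    """
    ids = list(dm.ids)
    groups = groups.loc[ids]
    counts = groups.value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index[0]
        raise ValueError(f"group {bad!r} has fewer than 2 samples")
    g = _gower_center(dm.data)
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2)
    tol = 1e-8 * max(1.0, np.abs(eigval).max())
    pos, neg = eigval > tol, eigval < -tol
    real = eigvec[:, pos] * np.sqrt(eigval[pos])
    imag = eigvec[:, neg] * np.sqrt(-eigval[neg])
    used_neg = bool(neg.any())

    dist = np.empty(len(ids))
    medians = {}
    for grp in counts.index:
        sel = (groups == grp).to_numpy()
        med_r = geometric_median(real[sel])
        d2 = ((real[sel] - med_r) ** 2).sum(axis=1)
        if used_neg:
            med_i = geometric_median(imag[sel])
            d2 = np.maximum(d2 - ((imag[sel] - med_i) ** 2).sum(axis=1), 0.0)
        dist[sel] = np.sqrt(d2)
        medians[grp] = med_r
    series = pd.Series(dist, index=ids)
    f, p = stats.f_oneway(*(series[groups == grp] for grp in counts.index))
    return HomogeneityResult(series, groups, medians, float(f), float(p), used_neg)


# ---------------------------------------------------------------------------
# anosim and the twins comparison


@dataclass
class AnosimResult:
    r: float
    p: float
    within: np.ndarray  # within-unit distances (for box plots)
    between: np.ndarray
    n_permutations: int


def _anosim_r(ranks: np.ndarray, within_mask: np.ndarray) -> float:
    m = len(ranks)
    rw = ranks[within_mask].mean()
    rb = ranks[~within_mask].mean()
    return float((rb - rw) / (m / 2.0))


def anosim(
    dm: DistanceMatrix, grouping: pd.Series, n_perm: int = 999, seed: int = 0
) -> AnosimResult:
    """Rank-based analysis of similarities; R in [-1, 1].

    R compares mean between-group and within-group ranks of all pairwise
    distances (average ranks on ties); the p-value permutes group labels
    with the observed statistic included in the null set.
    """
    ids = list(dm.ids)
    labels = grouping.loc[ids].to_numpy()
    if len(np.unique(labels)) < 2:
        raise ValueError("all samples in one group")
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    condensed = dm.data[iu]
    ranks = stats.rankdata(condensed)
    within = labels[iu[0]] == labels[iu[1]]
    if not within.any():
        raise ValueError("no within-group pairs; every group is a singleton")
    r_obs = _anosim_r(ranks, within)
    rng = np.random.default_rng(seed)
    geq = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        w = perm[iu[0]] == perm[iu[1]]
        if _anosim_r(ranks, w) >= r_obs - 1e-12:
            geq += 1
    p = (geq + 1) / (n_perm + 1)
    return AnosimResult(
        r_obs, float(p), condensed[within], condensed[~within], n_perm
    )


def anosim_units(
    dm: DistanceMatrix,
    units: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> AnosimResult:
    """Anosim over family or classroom units.

    Only samples belonging to a unit with at least two members enter the
    test (a unit needs a within-unit pair to be informative), mirroring
    the inclusion rule that a sample must have at least one relationship
    of the tested type.
    """
    units = units.reindex(list(dm.ids))
    units = units[units.notna() & (units.astype(str) != "")]
    sizes = units.value_counts()
    keep_units = sizes[sizes >= 2].index
    members = units[units.isin(keep_units)]
    if len(keep_units) < 2:
        raise ValueError("need at least 2 units of size >= 2")
    sub = dm.filter(list(members.index))
    return anosim(sub, members, n_perm=n_perm, seed=seed)


def twins_vs_siblings(
    dm: DistanceMatrix,
    twin_pairs: list[tuple[str, str]],
    sibling_pairs: list[tuple[str, str]],
) -> dict:
    """Two-sided Mann-Whitney test: within-twin vs within-sibling distances."""
    if not twin_pairs or not sibling_pairs:
        raise ValueError("both twin and sibling pair lists must be non-empty")
    tw = np.array([dm[a, b] for a, b in twin_pairs])
    sb = np.array([dm[a, b] for a, b in sibling_pairs])
    method = "exact" if max(len(tw), len(sb)) <= 20 else "auto"
    res = stats.mannwhitneyu(tw, sb, alternative="two-sided", method=method)
    return {
        "U": float(res.statistic),
        "p": float(res.pvalue),
        "twin_distances": tw,
        "sibling_distances": sb,
    }
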