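"""Per-taxon and per-measure trend models with ensemble consensus.

Responses (CLR abundances, alpha-diversity measures, oral pH, BMI) are
modelled by ordinary linear regression on a focal variable plus the
standard covariate set (gender, age, log town population).  Age can
enter through a degree-2 orthogonal polynomial basis to capture
parabolic trends.  Per-term p-values come from type-II tests: each term
is tested by the F statistic of dropping it from the model containing
all other terms, which makes the p-values invariant to term order.

Across a subsample ensemble, each repetition is fitted separately and
Benjamini-Hochberg adjusted across the responses of that repetition;
the consensus reports the mean adjusted p, the count of significant
repetitions, and a trend direction label (increase, decrease,
parabolic, or late-rise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .subsampling import SubsampleEnsemble

__all__ = ["fit_trend", "consensus", "ph_correlations", "ConsensusResult",
           "classify_direction", "ortho_poly"]

ALPHA = 0.05


def ortho_poly(x: np.ndarray, degree: int = 2) -> np.ndarray:
    """Orthonormal polynomial basis (no constant column), as R's poly()."""
    x = np.asarray(x, dtype=float)
    raw = np.vander(x, degree + 1, increasing=True)
    q, _ = np.linalg.qr(raw)
    return q[:, 1:]


def _encode(values) -> np.ndarray:
    s = pd.Series(values)
    if pd.api.types.is_numeric_dtype(s):
        return s.to_numpy(dtype=float)[:, None]
    return pd.get_dummies(s.astype(str), drop_first=True).to_numpy(dtype=float)


def _term_blocks(frame, focal, covariates, quadratic_age, age_col="age"):
    """Ordered dict term -> design columns; age optionally quadratic."""
    blocks: dict[str, np.ndarray] = {}
    names = [focal] + [c for c in covariates if c != focal]
    for name in names:
        if name == age_col and quadratic_age:
            blocks[name] = ortho_poly(frame[age_col].to_numpy(), 2)
        elif name == "town_population":
            blocks[name] = np.log10(frame[name].to_numpy(dtype=float))[:, None]
        else:
            blocks[name] = _encode(frame[name])
    return blocks


def _rss(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid), rank


def fit_trend(
    y: np.ndarray,
    frame: pd.DataFrame,
    focal: str,
    covariates: tuple = ("gender", "age", "town_population"),
    quadratic_age: bool = False,
) -> dict:
    """Linear model of one response with type-II per-term F tests.

    Returns ``{"p": {term: p}, "sign": sign of the focal coefficient,
    "coef": focal coefficients, "df_resid": ...}``.  For a quadratic
    focal age term the p-value is the joint 2-df test of the age basis
    and ``sign`` is the sign of the quadratic coefficient.
    """
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("non-finite response values")
    blocks = _term_blocks(frame, focal, covariates, quadratic_age)
    n = len(y)
    intercept = np.ones((n, 1))
    x_full = np.hstack([intercept] + list(blocks.values()))
    rss_full, rank_full = _rss(x_full, y)
    df_resid = n - rank_full
    if df_resid < 2:
        raise ValueError("too few samples for the number of model parameters")

    pvals, fvals = {}, {}
    for term in blocks:
        others = [b for t, b in blocks.items() if t != term]
        x_red = np.hstack([intercept] + others) if others else intercept
        rss_red, rank_red = _rss(x_red, y)
        df_t = rank_full - rank_red
        if df_t == 0:
            warnings.warn(f"term {term!r} adds no rank; p set to NaN")
            pvals[term] = np.nan
            fvals[term] = np.nan
            continue
        f = ((rss_red - rss_full) / df_t) / (rss_full / df_resid)
        pvals[term] = float(stats.f.sf(f, df_t, df_resid))
        fvals[term] = float(f)

    beta, _, _, _ = np.linalg.lstsq(x_full, y, rcond=None)
    k = blocks[focal].shape[1]
    focal_coef = beta[1 : 1 + k]
    sign = float(np.sign(focal_coef[-1])) if k else 0.0
    return {"p": pvals, "F": fvals, "sign": sign, "coef": focal_coef,
            "df_resid": df_resid}


def classify_direction(ages: np.ndarray, y: np.ndarray,
                       sig_quadratic: bool | None = None) -> str:
    """Trend label across age: increase, decrease, parabolic, or late-rise.

    Parabolic requires a significant quadratic term with the vertex in
    the interior of the observed age range; late-rise is a flat trend
    below age 50 combined with an overall positive slope.
    """
    ages = np.asarray(ages, dtype=float)
    y = np.asarray(y, dtype=float)
    lin = stats.linregress(ages, y)
    young = ages < 50
    quad = np.polyfit(ages, y, 2)
    if sig_quadratic is None:
        res = fit_trend(y, pd.DataFrame({"age": ages}), "age", (), True)
        # joint test is conservative here; use the curvature's own t-test
        sig_quadratic = res["p"]["age"] < ALPHA
    if sig_quadratic and abs(quad[0]) > 0:
        vertex = -quad[1] / (2 * quad[0])
        span = ages.max() - ages.min()
        interior = ages.min() + 0.1 * span < vertex < ages.max() - 0.1 * span
        if interior:
            if young.sum() >= 10:
                lin_young = stats.linregress(ages[young], y[young])
                flat_young = lin_young.pvalue > ALPHA
            else:
                flat_young = False
            if flat_young and lin.slope > 0:
                return "late-rise"
            return "parabolic"
    return "increase" if lin.slope > 0 else "decrease"


@dataclass
class ConsensusResult:
    """Ensemble consensus for a batch of responses against one focal term."""

    focal: str
    summary: pd.DataFrame  # per response: direction, mean_adjusted_p, n_significant
    n_reps: int
    n_failed: int = 0
    records: list = field(default_factory=list)  # per-rep raw (p, sign) frames

    def __getitem__(self, response: str) -> pd.Series:
        return self.summary.loc[response]


def consensus(
    ensemble: SubsampleEnsemble | None,
    responses: pd.DataFrame,
    meta: pd.DataFrame,
    focal: str,
    covariates: tuple = ("gender", "age", "town_population"),
    quadratic_age: bool = False,
    alpha: float = ALPHA,
) -> ConsensusResult:
    """Fit every response in every subsample; aggregate FDR-adjusted results.

    Within each repetition, focal-term p-values are Benjamini-Hochberg
    adjusted across the batch of responses.  ``ensemble=None`` degrades
    to a single fit on all samples shared by ``responses`` and ``meta``.
    The consensus direction is the majority focal-coefficient sign,
    refined to parabolic / late-rise labels when age is the focal term
    with a quadratic basis.
    """
    if ensemble is None:
        ids = [i for i in responses.index if i in meta.index]
        rep_ids = [ids]
    else:
        rep_ids = [ensemble.all_ids(r) for r in range(ensemble.n_reps)]

    cols = list(responses.columns)
    adj_rows, sign_rows = [], []
    n_failed = 0
    records = []
    for ids in rep_ids:
        frame = meta.loc[ids]
        pvec, svec = [], []
        try:
            for col in cols:
                fit = fit_trend(
                    responses.loc[ids, col].to_numpy(), frame, focal,
                    covariates, quadratic_age,
                )
                pvec.append(fit["p"][focal])
                svec.append(fit["sign"])
        except (ValueError, np.linalg.LinAlgError) as err:
            n_failed += 1
            records.append({"error": str(err)})
            continue
        pvec = np.asarray(pvec)
        adj = np.full_like(pvec, np.nan)
        ok = np.isfinite(pvec)
        if ok.any():
            adj[ok] = multipletests(pvec[ok], method="fdr_bh")[1]
        adj_rows.append(adj)
        sign_rows.append(svec)
        records.append(pd.DataFrame({"p": pvec, "adjusted_p": adj, "sign": svec},
                                    index=cols))
    if not adj_rows:
        raise ValueError("every subsample fit failed")
    adj_mat = np.vstack(adj_rows)
    sign_mat = np.vstack(sign_rows)
    mean_adj = np.nanmean(adj_mat, axis=0)
    n_sig = (adj_mat < alpha).sum(axis=0)
    majority = np.sign(np.nanmean(np.sign(sign_mat), axis=0))

    directions = []
    for j, col in enumerate(cols):
        if focal == "age" and quadratic_age:
            ids0 = rep_ids[0]
            directions.append(
                classify_direction(
                    meta.loc[ids0, "age"].to_numpy(),
                    responses.loc[ids0, col].to_numpy(),
                    sig_quadratic=bool(mean_adj[j] < alpha),
                )
            )
        else:
            directions.append("increase" if majority[j] >= 0 else "decrease")
    summary = pd.DataFrame(
        {"direction": directions, "mean_adjusted_p": mean_adj,
         "n_significant": n_sig},
        index=cols,
    )
    return ConsensusResult(focal, summary, len(adj_rows), n_failed, records)


def ph_correlations(
    meta: pd.DataFrame,
    alpha_div: pd.DataFrame,
    clr: pd.DataFrame | None = None,
    ensemble: SubsampleEnsemble | None = None,
    covariates: tuple = ("gender", "age", "town_population"),
) -> ConsensusResult:
    """Associations of oral pH with alpha diversity and genus CLR values.

    Runs the same linear-model machinery with pH as the focal covariate.
    Requires pH for at least 30 samples; an all-constant pH is an error.
    """
    ph = pd.to_numeric(meta.get("pH"), errors="coerce")
    valid = ph.notna()
    if valid.sum() < 30:
        raise ValueError("pH present for fewer than 30 samples")
    if ph[valid].nunique() == 1:
        raise ValueError("pH is constant; association models are undefined")
    responses = alpha_div.copy()
    if clr is not None:
        responses = responses.join(clr, how="inner")
    keep = [i for i in responses.index if valid.get(i, False)]
    responses = responses.loc[keep].dropna()
    meta_ok = meta.loc[responses.index].copy()
    meta_ok["pH"] = ph.loc[responses.index]
    if ensemble is not None:
        filtered = SubsampleEnsemble(variable=ensemble.variable, seed=ensemble.seed)
        for rep in range(ensemble.n_reps):
            filtered.sets.append({
                g: [i for i in ids if i in responses.index]
                for g, ids in ensemble.sets[rep].items()
            })
        ensemble = filtered
    return consensus(ensemble, responses, meta_ok, focal="pH",
                     covariates=("pH",) + covariates)
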