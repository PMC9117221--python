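"""Repeated matched-control subsampling.

Every statistical comparison in the pipeline runs on an ensemble of
(by default) 100 balanced subsamples rather than on the raw cohort.  For
a binary variable, each subsample holds equal-size yes/no groups with the
controls drawn to match the yes-group's age, gender, and region
distributions.  For age, each subsample draws from six age bins balanced
on gender x region, and the same ensemble doubles for age-as-continuous
models.  Group sizes are identical across all repetitions of an
ensemble.

Eligibility: control pools exclude samples with any reported chronic
disorder (unless the tested variable is that disorder), samples missing
age or gender, and samples from regions not represented in the yes
group.

Matching is stratified sampling on gender x region x age-bin with
proportional allocation to the yes group, falling back to nearest-age
donors within gender x region (then gender, then anyone) when a stratum
is exhausted; a per-repetition matching report records realized
distributions plus Kolmogorov-Smirnov (age) and chi-square
(gender/region) checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import CHRONIC_FLAGS

__all__ = ["AgeBinning", "SubsampleEnsemble", "eligible_controls",
           "subsample_binary", "subsample_age_bins"]


@dataclass(frozen=True)
class AgeBinning:
    """Six age bins: [13,20), [20,30), [30,40), [40,50), [50,60), [60,inf)."""

    edges: tuple = (13.0, 20.0, 30.0, 40.0, 50.0, 60.0, np.inf)
    labels: tuple = ("13-20", "20-30", "30-40", "40-50", "50-60", ">60")

    def assign(self, ages) -> pd.Series:
        index = ages.index if isinstance(ages, pd.Series) else None
        ages = pd.Series(np.asarray(ages, dtype=float), index=index)
        idx = np.searchsorted(self.edges[1:], ages.to_numpy(), side="right")
        out = np.array([""] * len(ages), dtype=object)
        ok = ages.notna().to_numpy() & (ages.to_numpy() >= self.edges[0])
        out[ok] = np.asarray(self.labels, dtype=object)[idx[ok].clip(0, 5)]
        return pd.Series(out, index=ages.index)


@dataclass
class SubsampleEnsemble:
    """A stack of balanced index sets with matching provenance.

    ``sets`` maps each repetition to ``{group_label: list of sample ids}``;
    group sizes are identical across repetitions.
    """

    variable: str
    sets: list = field(default_factory=list)
    matching_report: list = field(default_factory=list)
    seed: int = 0
    rep_seeds: list = field(default_factory=list)

    @property
    def n_reps(self) -> int:
        return len(self.sets)

    def group_sizes(self) -> dict:
        return {g: len(ids) for g, ids in self.sets[0].items()}

    def all_ids(self, rep: int) -> list:
        out = []
        for ids in self.sets[rep].values():
            out.extend(ids)
        return out

    def labels(self, rep: int) -> pd.Series:
        pairs = [(i, g) for g, ids in self.sets[rep].items() for i in ids]
        return pd.Series(dict(pairs))

    def validate(self) -> None:
        sizes = self.group_sizes()
        for rep, s in enumerate(self.sets):
            if {g: len(v) for g, v in s.items()} != sizes:
                raise ValueError(f"group sizes differ at repetition {rep}")
            flat = self.all_ids(rep)
            if len(flat) != len(set(flat)):
                raise ValueError(f"duplicate sample within repetition {rep}")


def _flag_yes(meta: pd.DataFrame, variable: str) -> pd.Series:
    if variable not in meta.columns:
        raise KeyError(f"variable {variable!r} not in metadata")
    return meta[variable].astype(str).str.lower().eq("yes")


def eligible_controls(meta: pd.DataFrame, variable: str) -> set:
    """Sample ids eligible as controls when testing ``variable``.

    Excludes the yes group itself, any sample with a reported chronic
    disorder (unless ``variable`` is that disorder, in which case only the
    *other* chronic disorders disqualify), samples missing age or gender,
    and samples from regions absent from the yes group.
    """
    yes = _flag_yes(meta, variable)
    chronic_cols = [c for c in CHRONIC_FLAGS if c in meta.columns and c != variable]
    chronic = pd.Series(False, index=meta.index)
    for c in chronic_cols:
        chronic |= meta[c].astype(str).str.lower().eq("yes")
    if variable not in CHRONIC_FLAGS and "chronic_disorder_any" in meta.columns:
        chronic |= meta["chronic_disorder_any"].astype(bool)
    missing = meta["age"].isna() | meta["gender"].isna()
    yes_regions = set(meta.loc[yes & ~missing, "region"].dropna())
    in_region = meta["region"].isin(yes_regions)
    ok = ~yes & ~chronic & ~missing & in_region
    if not ok.any():
        raise ValueError(f"empty eligible control pool for {variable!r}")
    return set(meta.index[ok])


def _eligible_yes(meta: pd.DataFrame, variable: str) -> list:
    """Yes-group members usable in tests (age and gender known; no *other*
    chronic disorder)."""
    yes = _flag_yes(meta, variable)
    missing = meta["age"].isna() | meta["gender"].isna()
    other_chronic = pd.Series(False, index=meta.index)
    for c in CHRONIC_FLAGS:
        if c in meta.columns and c != variable:
            other_chronic |= meta[c].astype(str).str.lower().eq("yes")
    return list(meta.index[yes & ~missing & ~other_chronic])


def _match_controls(meta, yes_ids, pool_ids, rng, binning):
    """Draw |yes_ids| controls matching the yes group's joint
    gender x region x age-bin distribution, nearest-age fallback."""
    bins = binning.assign(meta["age"])
    key = meta["gender"].astype(str) + "|" + meta["region"].astype(str)
    strata_yes = {}
    for i in yes_ids:
        strata_yes.setdefault((key[i], bins[i]), []).append(i)
    pool_by_stratum: dict = {}
    for i in pool_ids:
        pool_by_stratum.setdefault((key[i], bins[i]), []).append(i)
    chosen: list = []
    unmet: list = []  # (yes-stratum, deficit)
    taken = set()
    for stratum, members in strata_yes.items():
        avail = [i for i in pool_by_stratum.get(stratum, []) if i not in taken]
        k = min(len(members), len(avail))
        if k:
            pick = rng.choice(len(avail), size=k, replace=False)
            sel = [avail[j] for j in pick]
            chosen.extend(sel)
            taken.update(sel)
        if k < len(members):
            unmet.append((stratum, len(members) - k))
    # relaxation: nearest-age within gender x region, then gender, then anyone
    pool_ages = meta["age"]
    for (skey, sbin), deficit in unmet:
        target_age = np.mean([meta.at[i, "age"] for i in strata_yes[(skey, sbin)]])
        for scope in (
            [i for i in pool_ids if key[i] == skey and i not in taken],
            [i for i in pool_ids
             if key[i].split("|")[0] == skey.split("|")[0] and i not in taken],
            [i for i in pool_ids if i not in taken],
        ):
            if not scope:
                continue
            scope = sorted(scope, key=lambda i: abs(pool_ages[i] - target_age))
            grab = scope[:deficit]
            chosen.extend(grab)
            taken.update(grab)
            deficit -= len(grab)
            if deficit == 0:
                break
        if deficit > 0:
            raise ValueError("control pool exhausted during matching")
    return chosen


def _report(meta, groups: dict) -> dict:
    """Realized distributions plus balance checks for one repetition."""
    rep: dict = {}
    for g, ids in groups.items():
        sub = meta.loc[ids]
        rep[g] = {
            "n": len(ids),
            "age_mean": float(sub["age"].mean()),
            "gender": sub["gender"].value_counts().to_dict(),
            "region": sub["region"].value_counts().to_dict(),
        }
    if len(groups) == 2:
        (ga, ia), (gb, ib) = groups.items()
        ks = stats.ks_2samp(meta.loc[ia, "age"], meta.loc[ib, "age"])
        rep["age_ks_p"] = float(ks.pvalue)
    return rep


def subsample_binary(
    meta: pd.DataFrame,
    variable: str,
    n_reps: int = 100,
    cap: int = 100,
    min_group: int = 10,
    seed: int = 0,
    binning: AgeBinning | None = None,
) -> SubsampleEnsemble:
    """Matched yes/no ensemble for a binary flag.

    Group size is ``min(cap, size of the smaller eligible group)``; when
    both groups exceed ``cap`` (default 100), ``cap`` of each are drawn
    per repetition.
    """
    binning = binning or AgeBinning()
    yes_ids = _eligible_yes(meta, variable)
    pool = sorted(eligible_controls(meta, variable))
    n = min(cap, len(yes_ids), len(pool))
    if n < min_group:
        raise ValueError(
            f"smaller group for {variable!r} has {n} samples (< {min_group})"
        )
    ens = SubsampleEnsemble(variable=variable, seed=seed)
    master = np.random.default_rng(seed)
    for rep in range(n_reps):
        rep_seed = int(master.integers(2**31 - 1))
        rng = np.random.default_rng(rep_seed)
        if len(yes_ids) > n:
            pick = rng.choice(len(yes_ids), size=n, replace=False)
            yes_sel = [yes_ids[j] for j in pick]
        else:
            yes_sel = list(yes_ids)
        controls = _match_controls(meta, yes_sel, pool, rng, binning)
        groups = {"yes": yes_sel, "no": controls}
        ens.sets.append(groups)
        ens.matching_report.append(_report(meta, groups))
        ens.rep_seeds.append(rep_seed)
    ens.validate()
    return ens


def _bin_quotas(meta, eligible, binning, cap):
    """Per-bin stratum quotas balancing gender x region across bins.

    The target joint gender x region distribution is the pooled one over
    all eligible samples; each bin's size is the largest n for which the
    proportional stratum quotas fit the bin's availability (capped).
    """
    sub = meta.loc[sorted(eligible)]
    bins = binning.assign(sub["age"])
    key = sub["gender"].astype(str) + "|" + sub["region"].astype(str)
    target = key.value_counts(normalize=True)
    # a stratum absent from any bin cannot be balanced across bins: drop it
    for lab in binning.labels:
        present = set(key[bins == lab])
        target = target[target.index.isin(present)]
    if target.empty:
        raise ValueError("no gender x region stratum is present in every age bin")
    target = target / target.sum()
    quotas = {}
    for lab in binning.labels:
        in_bin = bins == lab
        if not in_bin.any():
            raise ValueError(f"age bin {lab!r} is empty")
        avail = key[in_bin].value_counts()
        n_max = np.inf
        for stratum, prop in target.items():
            n_max = min(n_max, avail.get(stratum, 0) / prop)
        n_b = int(min(np.floor(n_max), cap))
        if n_b < 2:
            raise ValueError(f"age bin {lab!r} empty after gender/region balancing")
        # largest-remainder apportionment of n_b across strata
        raw = target * n_b
        base = np.floor(raw).astype(int)
        rem = n_b - int(base.sum())
        order = (raw - base).sort_values(ascending=False).index
        for stratum in order[:rem]:
            base[stratum] += 1
        quotas[lab] = {s: int(q) for s, q in base.items() if q > 0}
    return quotas, bins, key


def subsample_age_bins(
    meta: pd.DataFrame,
    binning: AgeBinning | None = None,
    n_reps: int = 100,
    cap: int = 100,
    seed: int = 0,
) -> SubsampleEnsemble:
    """Ensemble of draws from six age bins balanced on gender x region.

    Per-bin sizes are constant across repetitions; the ensemble also
    serves models that treat age as continuous, guaranteeing an even
    spread of ages with balanced gender and region.
    """
    binning = binning or AgeBinning()
    chronic = meta.get("chronic_disorder_any", pd.Series(False, index=meta.index))
    missing = meta["age"].isna() | meta["gender"].isna()
    eligible = set(meta.index[~chronic.astype(bool) & ~missing
                              & (meta["age"] >= binning.edges[0])])
    if not eligible:
        raise ValueError("no eligible samples for age-bin subsampling")
    quotas, bins, key = _bin_quotas(meta, eligible, binning, cap)
    members: dict = {}
    for i in sorted(eligible):
        members.setdefault((bins[i], key[i]), []).append(i)
    ens = SubsampleEnsemble(variable="age_bin", seed=seed)
    master = np.random.default_rng(seed)
    for rep in range(n_reps):
        rep_seed = int(master.integers(2**31 - 1))
        rng = np.random.default_rng(rep_seed)
        groups = {}
        for lab in binning.labels:
            sel = []
            for stratum, q in quotas[lab].items():
                avail = members[(lab, stratum)]
                pick = rng.choice(len(avail), size=q, replace=False)
                sel.extend(avail[j] for j in pick)
            groups[lab] = sel
        ens.sets.append(groups)
        ens.matching_report.append(_report(meta, groups))
        ens.rep_seeds.append(rep_seed)
    ens.validate()
    return ens
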