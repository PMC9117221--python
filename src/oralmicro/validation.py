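"""Planted-effect validation experiments.

Each function generates synthetic cohorts with a known planted
structure, runs the full analysis stack on them, and reports how well
the stack recovers the truth: type-I error under null cohorts, the
parabolic age structure (distinct extreme bins, most-homogeneous middle
bin, quadratic alpha-diversity trends), directional consensus recovery
of trending genera, dispersion differences for a flagged group, and the
co-occurrence network uniqueness ranking.  All are deterministic given
their seed and sized to run on a single CPU in minutes.
"""

from __future__ import annotations

import warnings

import numpy as np

from statsmodels.stats.multitest import multipletests

from .cohort import CohortSpec, ConditionSpec, generate_cohort
from .diversity import aitchison_distance, alpha_diversity, clr_transform
from .io import CountTable, aggregate_to_rank
from .mvtests import (
    anosim_units,
    homogeneity_test,
    permanova,
    permanova_one_vs_rest,
)
from .networks import (
    NetworkEnsemble,
    NetworkSettings,
    filter_rare_taxa,
    infer_network,
    uniqueness_scores,
)
from .subsampling import AgeBinning, subsample_age_bins, subsample_binary
from .trends import consensus, fit_trend

__all__ = [
    "type_one_error_rates",
    "parabolic_age_recovery",
    "trend_direction_recovery",
    "dispersion_flag_recovery",
    "uniqueness_ranking",
]


def type_one_error_rates(n_replicates: int = 600, seed: int = 0,
                         n_perm: int = 199) -> dict:
    """Rejection rates at alpha=0.05 of the whole stack on null cohorts.

    Each replicate draws a 40-sample cohort with no planted effects and
    runs: PERMANOVA on a random binary flag (with gender and age as
    covariates), the dispersion-homogeneity ANOVA on the flag groups,
    anosim over (composition-unrelated) family units, and the per-term
    linear-model test of the flag on one taxon's CLR abundance.
    """
    reject = {"permanova": 0, "homogeneity": 0, "anosim": 0, "trend": 0}
    denom = {k: 0 for k in reject}
    for rep in range(n_replicates):
        spec = CohortSpec(
            n_samples=40, n_taxa=25, reads_per_sample=2000,
            seed=seed * 1_000_000 + rep,
            age_bin_weights=(2, 1, 1, 1, 1, 1),
            condition_specs=[ConditionSpec("smoking", 0.5)],
            family_fraction=0.5, missing_fraction=0.0,
        )
        c = generate_cohort(spec)
        clr = clr_transform(c.counts)
        dm = aitchison_distance(clr)
        meta = c.metadata
        res = permanova(dm, meta[["smoking", "gender", "age"]],
                        ["smoking", "gender", "age"], n_perm=n_perm, seed=rep)
        reject["permanova"] += res["smoking"]["p"] < 0.05
        denom["permanova"] += 1
        reject["homogeneity"] += homogeneity_test(dm, meta["smoking"]).anova_p < 0.05
        denom["homogeneity"] += 1
        units = meta["family_unit"].replace("", np.nan)
        try:
            a = anosim_units(dm, units, n_perm=n_perm, seed=rep)
            reject["anosim"] += a.p < 0.05
            denom["anosim"] += 1
        except ValueError:
            pass
        ft = fit_trend(clr["t0000"].to_numpy(), meta, "smoking", ("gender", "age"))
        reject["trend"] += ft["p"]["smoking"] < 0.05
        denom["trend"] += 1
    return {k: reject[k] / denom[k] for k in reject}


def _parabolic_spec(seed: int) -> CohortSpec:
    # noise s.d. quadratic in age, minimum 0.30 at age 45, ~1.1 at the extremes
    a = 1e-3
    curve = (a, -2 * a * 45, a * 45**2 + 0.30)
    return CohortSpec(
        n_samples=300, n_taxa=60, reads_per_sample=5000, seed=seed,
        age_bin_weights=(1, 1, 1, 1, 1, 1), dispersion_curve=curve,
        extreme_age_effects=(1.0, 1.0, 8), missing_fraction=0.0,
    )


def parabolic_age_recovery(n_seeds: int = 10, seed: int = 0,
                           n_reps: int = 100, n_perm: int = 99) -> dict:
    """Recovery of the parabolic age structure from planted cohorts.

    Cohorts have composition effects concentrated in the extreme age
    bins and latent dispersion minimal near age 45.  Per seed, the
    age-bin subsample ensemble is tested with one-vs-rest PERMANOVA
    (BH-adjusted across bins within each repetition), the dispersion
    homogeneity test, and quadratic-vs-linear Shannon models.
    """
    binning = AgeBinning()
    per_seed = []
    for s in range(n_seeds):
        c = generate_cohort(_parabolic_spec(seed * 1000 + s))
        clr = clr_transform(c.counts)
        dm = aitchison_distance(clr)
        alpha = alpha_diversity(c.counts)
        ens = subsample_age_bins(c.metadata, n_reps=n_reps, seed=seed * 77 + s)
        bins_all = binning.assign(c.metadata["age"])
        adj = {lab: [] for lab in binning.labels}
        disp = {lab: [] for lab in binning.labels}
        p_quad, p_lin = [], []
        for rep in range(ens.n_reps):
            ids = ens.all_ids(rep)
            sub = dm.filter(ids)
            dsg = c.metadata.loc[ids, ["gender", "town_population"]]
            res = permanova_one_vs_rest(sub, bins_all.loc[ids], dsg,
                                        ["gender", "town_population"],
                                        n_perm=n_perm, seed=rep)
            labs = list(res)
            padj = multipletests([res[l]["_is_bin"]["p"] for l in labs],
                                 method="fdr_bh")[1]
            for l, p in zip(labs, padj):
                adj[l].append(p)
            gm = homogeneity_test(sub, bins_all.loc[ids]).group_means()
            for l in gm.index:
                disp[l].append(gm[l])
            fr = c.metadata.loc[ids]
            y = alpha.loc[ids, "shannon"].to_numpy()
            p_quad.append(fit_trend(y, fr, "age", ("gender", "town_population"),
                                    quadratic_age=True)["p"]["age"])
            p_lin.append(fit_trend(y, fr, "age", ("gender", "town_population"),
                                   quadratic_age=False)["p"]["age"])
        mean_adj = {l: float(np.mean(v)) for l, v in adj.items()}
        mean_disp = {l: float(np.mean(v)) for l, v in disp.items()}
        extremes = ("13-20", ">60")
        middles = ("20-30", "30-40", "40-50", "50-60")
        per_seed.append({
            "mean_adjusted_p": mean_adj,
            "mean_dist_to_median": mean_disp,
            "extremes_only_significant": bool(
                all(mean_adj[l] < 0.05 for l in extremes)
                and all(mean_adj[l] >= 0.05 for l in middles)
            ),
            "most_homogeneous_bin": min(mean_disp, key=mean_disp.get),
            "shannon_p_quadratic": float(np.mean(p_quad)),
            "shannon_p_linear": float(np.mean(p_lin)),
        })
    return {
        "per_seed": per_seed,
        "n_seeds": n_seeds,
        "extremes_only": sum(r["extremes_only_significant"] for r in per_seed),
        "min_dispersion_at_40_50": sum(
            r["most_homogeneous_bin"] == "40-50" for r in per_seed),
        "quadratic_beats_linear": sum(
            r["shannon_p_quadratic"] < r["shannon_p_linear"] for r in per_seed),
    }


def trend_direction_recovery(seed: int = 0, n_reps: int = 100,
                             n_taxa: int = 40) -> dict:
    """Consensus recovery of 12 planted age-trending genera.

    Six genera increase with age from a low baseline abundance and six
    decrease from a high baseline (slope magnitude 0.025 CLR/yr); the
    rest are null.  Reports per-genus consensus and false-call counts.
    The low baseline stays above the count-truncation regime so the
    pseudocount cannot leak a spurious trend into the CLR centering.
    """
    rng = np.random.default_rng(seed + 12345)
    baseline = np.zeros(n_taxa)
    baseline[:6] = -1.5
    baseline[6:12] = 2.0
    baseline[12:] = rng.normal(0.0, 1.5, n_taxa - 12)
    slopes = np.zeros(n_taxa)
    slopes[:6] = 0.025
    slopes[6:12] = -0.025
    spec = CohortSpec(
        n_samples=900, n_taxa=n_taxa, reads_per_sample=10000, seed=seed,
        age_bin_weights=(2, 1, 1, 1, 1, 1), age_slopes=slopes,
        baseline_clr=baseline, missing_fraction=0.0,
    )
    c = generate_cohort(spec)
    genus = aggregate_to_rank(c.counts, "genus")
    clr = clr_transform(genus)
    tax = c.counts.taxonomy
    up = [tax.loc[f"t{i:04d}", "genus"] for i in range(6)]
    down = [tax.loc[f"t{i:04d}", "genus"] for i in range(6, 12)]
    ens = subsample_age_bins(c.metadata, n_reps=n_reps, seed=seed + 7)
    res = consensus(ens, clr, c.metadata, focal="age")
    s = res.summary
    planted = s.loc[up + down]
    nulls = s.drop(up + down)
    call = (s["mean_adjusted_p"] < 0.05) & (s["n_significant"] >= 0.8 * n_reps)
    correct = (
        int((call.loc[up] & (s.loc[up, "direction"] == "increase")).sum())
        + int((call.loc[down] & (s.loc[down, "direction"] == "decrease")).sum())
    )
    return {
        "summary": s,
        "n_planted": 12,
        "n_recovered_correct_direction": correct,
        "min_n_significant_planted": int(planted["n_significant"].min()),
        "n_null_called": int(call.loc[nulls.index].sum()),
        "null_min_mean_adjusted_p": float(nulls["mean_adjusted_p"].min()),
    }


def dispersion_flag_recovery(n_seeds: int = 10, seed: int = 0,
                             n_reps: int = 20) -> dict:
    """Recovery of a planted dispersion difference for a binary flag.

    The flagged ("smoking-like") group has its latent noise scaled by
    0.55, so it should sit tighter around its spatial median than the
    matched controls.
    """
    successes = 0
    per_seed = []
    for s in range(n_seeds):
        spec = CohortSpec(
            n_samples=200, n_taxa=40, reads_per_sample=5000,
            seed=seed * 100 + s, age_bin_weights=(2, 1, 1, 1, 1, 1),
            dispersion_curve=(0, 0, 0.8),
            condition_specs=[ConditionSpec("smoking", 0.3, 0.0, 0.55)],
            missing_fraction=0.0,
        )
        c = generate_cohort(spec)
        dm = aitchison_distance(clr_transform(c.counts))
        ens = subsample_binary(c.metadata, "smoking", n_reps=n_reps,
                               seed=seed * 100 + s)
        ps, d_yes, d_no = [], [], []
        for rep in range(ens.n_reps):
            hom = homogeneity_test(dm.filter(ens.all_ids(rep)), ens.labels(rep))
            gm = hom.group_means()
            ps.append(hom.anova_p)
            d_yes.append(gm["yes"])
            d_no.append(gm["no"])
        ok = np.mean(ps) < 0.05 and np.mean(d_yes) < np.mean(d_no)
        successes += ok
        per_seed.append({"mean_anova_p": float(np.mean(ps)),
                         "mean_dist_yes": float(np.mean(d_yes)),
                         "mean_dist_no": float(np.mean(d_no)),
                         "recovered": bool(ok)})
    return {"per_seed": per_seed, "n_seeds": n_seeds, "successes": successes}


def uniqueness_ranking(n_seeds: int = 5, seed: int = 0,
                       n_reps: int = 5) -> dict:
    """Network-uniqueness ranking with one variable carrying planted edges.

    Four binary variables are simulated; only "smoking" carries two
    group-exclusive co-occurrence dependencies (rho=0.7).  The planted
    variable should score strictly highest aggregate uniqueness.
    """
    wins = 0
    per_seed = []
    names = ["smoking", "yeast", "antibiotics", "hypertension"]
    for s in range(n_seeds):
        conds = [ConditionSpec("smoking", 0.15)] + [
            ConditionSpec(n, 0.25) for n in names[1:]
        ]
        spec = CohortSpec(
            n_samples=900, n_taxa=30, reads_per_sample=10000,
            seed=seed * 100 + s, age_bin_weights=(2, 1, 1, 1, 1, 1),
            condition_specs=conds,
            network_effects={"smoking": [(5, 9, 0.7), (12, 20, 0.7)]},
            missing_fraction=0.0,
        )
        c = generate_cohort(spec)
        table = filter_rare_taxa(c.counts)
        settings = NetworkSettings(backend="parcor", parcor_lambda=0.4,
                                   seed=seed * 100 + s)
        ensembles = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for v, name in enumerate(names):
                ens = subsample_binary(c.metadata, name, n_reps=n_reps,
                                       seed=seed * 1000 + s * 10 + v)
                nets = [
                    infer_network(
                        CountTable(table.counts[ens.sets[r]["yes"]],
                                   table.taxonomy),
                        settings,
                    )
                    for r in range(n_reps)
                ]
                ensembles.append(NetworkEnsemble(name, nets, settings=settings))
        agg = uniqueness_scores(ensembles).aggregate["sum"]
        strict = bool(agg["smoking"] > agg.drop("smoking").max())
        wins += strict
        per_seed.append({"aggregate": agg.to_dict(), "planted_wins": strict})
    return {"per_seed": per_seed, "n_seeds": n_seeds, "planted_wins": wins}
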