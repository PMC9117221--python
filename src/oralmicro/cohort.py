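"""Synthetic oral-microbiome cohort generator.

Emulates a citizen-science oral-rinse cohort: a teen-heavy age
distribution over six age bins (13-20, 20-30, 30-40, 40-50, 50-60, >60),
binary lifestyle/health flags at configurable prevalences, family and
classroom units, oral pH and BMI covariates, and an ASV count table with
planted compositional structure.

Counts come from a logistic-normal-multinomial model: each sample has a
latent log-composition

    z = baseline + age_slope * (age - 40) + sum(condition effects)
        + family effect + classroom effect + noise,

with the noise standard deviation given by a quadratic function of age
(optionally rescaled per condition group), then softmax(z) feeds a
multinomial draw at fixed sequencing depth.  Effects are therefore
additive on the CLR scale, the scale on which the downstream models
operate, which makes parameter recovery well-posed.  A ground-truth
ledger records every planted effect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import (
    CHRONIC_FLAGS,
    CountTable,
    validate_metadata,
    write_counts,
    write_metadata,
    write_tree,
)

__all__ = ["CohortSpec", "ConditionSpec", "SyntheticCohort", "generate_cohort",
           "generate_tree", "AGE_BIN_EDGES", "AGE_BIN_LABELS"]

AGE_BIN_EDGES = (13.0, 20.0, 30.0, 40.0, 50.0, 60.0, 85.0)
AGE_BIN_LABELS = ("13-20", "20-30", "30-40", "40-50", "50-60", ">60")

#: age-bin sample counts of the real cohort, usable as generator weights
COHORT_BIN_COUNTS = (964, 41, 28, 85, 46, 42)

REGIONS = ("Catalonia", "Madrid", "Andalusia", "Valencia", "Galicia", "Basque Country")
REGION_WEIGHTS = (0.35, 0.20, 0.15, 0.12, 0.10, 0.08)


@dataclass
class ConditionSpec:
    """A binary questionnaire flag and its planted compositional effect.

    ``effect_size_clr`` is the CLR-scale shift applied to an internally
    chosen subset of taxa in flagged samples (alternating sign across the
    subset so the composition stays roughly balanced).
    ``dispersion_ratio`` rescales the latent noise s.d. for flagged
    samples; values below 1 make the flagged group more homogeneous.
    """

    name: str
    prevalence: float
    effect_size_clr: float = 0.0
    dispersion_ratio: float = 1.0


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort generator."""

    n_samples: int = 400
    n_taxa: int = 80
    reads_per_sample: int = 5000
    age_bin_weights: tuple = COHORT_BIN_COUNTS
    condition_specs: list = field(default_factory=list)
    age_slopes: np.ndarray | None = None  # per-taxon CLR units per year
    dispersion_curve: tuple = (0.0, 0.0, 0.5)  # a*age^2 + b*age + c
    family_effect_sd: float = 0.0
    classroom_effect_sd: float = 0.0
    twin_effect_sd: float = 0.0
    #: (young_shift, old_shift, n_taxa_each): CLR shifts applied to two
    #: disjoint taxon subsets for samples aged <20 and >60 respectively,
    #: planting composition effects concentrated in the extreme age bins.
    extreme_age_effects: tuple | None = None
    #: condition name -> list of (taxon_i, taxon_j, rho): group-exclusive
    #: co-occurrence planted as a shared latent factor in flagged samples.
    network_effects: dict = field(default_factory=dict)
    baseline_sd: float = 1.5
    #: explicit per-taxon baseline log-abundances (overrides baseline_sd draw)
    baseline_clr: np.ndarray | None = None
    family_fraction: float = 0.3
    missing_fraction: float = 0.02
    quantize_ph: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be at least 2")
        if self.n_samples < 1 or self.reads_per_sample < 1:
            raise ValueError("n_samples and reads_per_sample must be positive")
        w = np.asarray(self.age_bin_weights, dtype=float)
        if len(w) != 6 or (w < 0).any() or w.sum() <= 0:
            raise ValueError("age_bin_weights must be 6 nonnegative values")
        for c in self.condition_specs:
            if not 0.0 <= c.prevalence <= 1.0:
                raise ValueError(f"prevalence of {c.name!r} outside [0,1]")
            if not np.isfinite(c.effect_size_clr):
                raise ValueError(f"non-finite effect size for {c.name!r}")
            if c.dispersion_ratio <= 0:
                raise ValueError(f"dispersion_ratio of {c.name!r} must be positive")
        if self.age_slopes is not None:
            s = np.asarray(self.age_slopes, dtype=float)
            if len(s) != self.n_taxa:
                raise ValueError("age_slopes length must equal n_taxa")
            if not np.isfinite(s).all():
                raise ValueError("non-finite age slopes")
        a, b, c = self.dispersion_curve
        ages = np.linspace(7.0, 85.0, 200)
        if ((a * ages**2 + b * ages + c) <= 0).any():
            raise ValueError("dispersion_curve must be positive on ages [7, 85]")


@dataclass
class SyntheticCohort:
    counts: CountTable
    metadata: pd.DataFrame
    tree: TreeNode
    truth: dict

    def __post_init__(self) -> None:
        samples = set(self.counts.sample_ids)
        if not set(self.metadata.index) <= samples:
            raise ValueError("metadata sample ids missing from counts")
        tips = {t.name for t in self.tree.tips()}
        if tips != set(self.counts.taxon_ids):
            raise ValueError("tree tip set differs from taxon set")
        taxa = set(self.counts.taxon_ids)
        for t in self.truth.get("age_trends", {}):
            if t not in taxa:
                raise ValueError(f"truth lists unknown taxon {t!r}")

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_counts(self.counts, outdir / "counts.tsv")
        write_metadata(self.metadata, outdir / "metadata.tsv")
        write_tree(self.tree, outdir / "tree.nwk")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, default=_jsonable)


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    return str(x)


def generate_tree(n_taxa: int, seed: int = 0) -> TreeNode:
    """Random bifurcating rooted tree with exponential branch lengths.

    Tips are labelled ``t0000`` ... matching generated taxon ids.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be at least 2")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=f"t{i:04d}", length=float(rng.exponential(1.0)))
             for i in range(n_taxa)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(length=float(rng.exponential(1.0)), children=[left, right])
        nodes.append(parent)
    root = nodes[0]
    root.length = None  # a root branch has no meaning for PD or UniFrac
    return root


def _draw_ages(rng, n, weights):
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    bins = rng.choice(6, size=n, p=w)
    lo = np.asarray(AGE_BIN_EDGES[:-1])[bins]
    hi = np.asarray(AGE_BIN_EDGES[1:])[bins]
    return rng.uniform(lo, hi)


def _assign_families(rng, ages, fraction):
    """Partition a fraction of samples into family units of size 2-4."""
    n = len(ages)
    family_unit = np.array([""] * n, dtype=object)
    relationship = np.array([""] * n, dtype=object)
    pool = list(rng.permutation(n))
    n_in_units = int(fraction * n)
    uid = 0
    placed = 0
    rels = ["sibling", "twin", "partner", "parent-child", "grandparent-grandchild"]
    while placed + 2 <= n_in_units and len(pool) >= 2:
        rel = rels[rng.integers(len(rels))]
        size = int(rng.integers(2, 5)) if rel == "sibling" else 2
        size = min(size, len(pool))
        members = [pool.pop() for _ in range(size)]
        name = f"fam{uid:04d}"
        for m in members:
            family_unit[m] = name
            relationship[m] = rel
        if rel == "twin":
            ages[members[1]] = ages[members[0]]
        uid += 1
        placed += size
    return family_unit, relationship, ages


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a cohort (counts, metadata, tree, truth ledger) from ``spec``.

    Deterministic given ``spec.seed``; column sums of the count table
    equal ``reads_per_sample`` exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_taxa
    taxa = [f"t{i:04d}" for i in range(p)]
    samples = [f"s{i:05d}" for i in range(n)]

    ages = _draw_ages(rng, n, spec.age_bin_weights)
    gender = np.where(rng.random(n) < 0.5, "female", "male")
    region = rng.choice(REGIONS, size=n, p=REGION_WEIGHTS)
    town_population = np.round(rng.lognormal(10.0, 1.2, size=n)).astype(int) + 500

    family_unit, relationship, ages = _assign_families(
        rng, ages, spec.family_fraction
    )

    # classrooms: school-age samples grouped per region, ~30 per school
    school = np.array([""] * n, dtype=object)
    for reg in REGIONS:
        idx = np.flatnonzero((region == reg) & (ages < 20))
        idx = rng.permutation(idx)
        for k, i in enumerate(idx):
            school[i] = f"{reg[:3].lower()}_school{k // 30:02d}"

    # condition flags: chronic flags mutually exclusive, lifestyle independent
    flags = {}
    chronic_taken = np.zeros(n, dtype=bool)
    for c in spec.condition_specs:
        if c.name in CHRONIC_FLAGS:
            draw = (rng.random(n) < c.prevalence) & ~chronic_taken
            chronic_taken |= draw
        else:
            draw = rng.random(n) < c.prevalence
        flags[c.name] = draw

    # latent log-composition
    if spec.baseline_clr is not None:
        baseline = np.asarray(spec.baseline_clr, dtype=float)
        if len(baseline) != p:
            raise ValueError("baseline_clr length must equal n_taxa")
    else:
        baseline = rng.normal(0.0, spec.baseline_sd, size=p)
    z = np.tile(baseline, (n, 1))
    truth: dict = {"age_trends": {}, "condition_effects": {},
                   "dispersion_curve": list(spec.dispersion_curve),
                   "unit_effects": {"family_sd": spec.family_effect_sd,
                                    "classroom_sd": spec.classroom_effect_sd,
                                    "twin_sd": spec.twin_effect_sd},
                   "network_effects": {}}
    if spec.age_slopes is not None:
        slopes = np.asarray(spec.age_slopes, dtype=float)
        z += np.outer(ages - 40.0, slopes)
        truth["age_trends"] = {
            taxa[i]: float(slopes[i]) for i in np.flatnonzero(slopes != 0)
        }

    free = list(range(p))
    if spec.extreme_age_effects is not None:
        young_shift, old_shift, k = spec.extreme_age_effects
        chosen = rng.choice(free, size=2 * int(k), replace=False)
        young_taxa, old_taxa = chosen[: int(k)], chosen[int(k):]
        free = [i for i in free if i not in set(chosen)]
        z[np.ix_(ages < 20, young_taxa)] += young_shift
        z[np.ix_(ages > 60, old_taxa)] += old_shift
        truth["extreme_age_effects"] = {
            "young": {taxa[i]: float(young_shift) for i in young_taxa},
            "old": {taxa[i]: float(old_shift) for i in old_taxa},
        }

    for c in spec.condition_specs:
        if c.effect_size_clr == 0.0:
            truth["condition_effects"][c.name] = {}
            continue
        k = max(3, p // 10)
        chosen = rng.choice(free, size=min(k, len(free)), replace=False)
        free = [i for i in free if i not in set(chosen)]
        signs = np.where(np.arange(len(chosen)) % 2 == 0, 1.0, -1.0)
        effect = signs * c.effect_size_clr
        z[np.ix_(flags[c.name], chosen)] += effect
        truth["condition_effects"][c.name] = {
            taxa[i]: float(e) for i, e in zip(chosen, effect)
        }

    # unit random effects: one shared composition shift per unit
    for ids, sd in ((family_unit, spec.family_effect_sd),
                    (school, spec.classroom_effect_sd)):
        if sd > 0:
            for u in np.unique(ids):
                if u:
                    z[ids == u] += rng.normal(0.0, sd, size=p)
    if spec.twin_effect_sd > 0:
        for u in np.unique(family_unit[np.asarray(relationship) == "twin"]):
            if u:
                z[family_unit == u] += rng.normal(0.0, spec.twin_effect_sd, size=p)

    # heteroscedastic noise: quadratic-in-age scale, per-condition rescaling
    a, b, cc = spec.dispersion_curve
    scale = a * ages**2 + b * ages + cc
    for c in spec.condition_specs:
        if c.dispersion_ratio != 1.0:
            scale = np.where(flags[c.name], scale * c.dispersion_ratio, scale)
    z += rng.normal(0.0, 1.0, size=(n, p)) * scale[:, None]

    # planted group-exclusive co-occurrence: shared factor in flagged samples
    for cname, pairs in spec.network_effects.items():
        recorded = []
        for (i, j, rho) in pairs:
            if not 0 < abs(rho) < 1:
                raise ValueError("network effect rho must be in (-1, 1), nonzero")
            sel = flags[cname]
            lam = scale[sel] * np.sqrt(abs(rho) / (1 - abs(rho)))
            u = rng.normal(0.0, 1.0, size=sel.sum())
            z[sel, i] += lam * u
            z[sel, j] += np.sign(rho) * lam * u
            recorded.append([taxa[i], taxa[j], float(rho)])
        truth["network_effects"][cname] = recorded

    # softmax then multinomial at fixed depth
    z -= z.max(axis=1, keepdims=True)
    probs = np.exp(z)
    probs /= probs.sum(axis=1, keepdims=True)
    counts = np.empty((p, n), dtype=np.int64)
    for s in range(n):
        counts[:, s] = rng.multinomial(spec.reads_per_sample, probs[s])

    ph = 7.8 - 0.012 * ages + rng.normal(0.0, 0.3, size=n)
    ph = np.clip(ph, 5.0, 10.0)
    if spec.quantize_ph:
        ph = np.round(ph * 2.0) / 2.0
    bmi = np.clip(16.0 + 0.13 * ages + rng.normal(0.0, 2.5, size=n), 12.0, 45.0)

    meta = pd.DataFrame(
        {
            "age": np.round(ages, 1),
            "gender": gender,
            "region": region,
            "town_population": town_population,
            "family_unit": family_unit,
            "relationship": relationship,
            "school": school,
            "pH": np.round(ph, 2),
            "BMI": np.round(bmi, 1),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    for name, f in flags.items():
        meta[name] = np.where(f, "yes", "no")
    # sprinkle missingness in age and gender (truth ages still drove counts)
    if spec.missing_fraction > 0:
        miss = rng.random(n) < spec.missing_fraction
        meta.loc[miss, "age"] = np.nan
        miss_g = rng.random(n) < spec.missing_fraction
        meta.loc[miss_g, "gender"] = np.nan
    meta = validate_metadata(meta)

    phyla = [f"Phylum_{chr(65 + i % 5)}" for i in range(p)]
    genera = [f"Genus_{i:04d}" for i in range(p)]
    taxonomy = pd.DataFrame({"genus": genera, "phylum": phyla}, index=taxa)
    table = CountTable(pd.DataFrame(counts, index=taxa, columns=samples), taxonomy)
    tree = generate_tree(p, seed=spec.seed + 1)
    truth["baseline_clr"] = {taxa[i]: float(baseline[i]) for i in range(p)}
    return SyntheticCohort(table, meta, tree, truth)
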