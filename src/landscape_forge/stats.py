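"""Fitness-landscape statistics.

Single-mutant effect tables, pairwise-additive epistasis with capped
expectations, fraction-functional curves versus mutational distance, logistic
mutational-LD50 fits, peak profiles, and cross-ortholog comparisons of
mutational effects and epistatic site pairs.

Epistasis of a genotype *m* is the deviation of its observed fluorescence from
the additive expectation built from single-mutant measurements::

    epistasis = F_m - F_wt - sum_i (F_i - F_wt) * x_i

with the expectation capped to the observed range of the dataset, and
genotypes containing a mutation never measured in isolation flagged as
non-computable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .genotypes import parse_mutation_set, hamming

#: |epistasis| cutoffs for weak (≈two-fold) and strong (≈ten-fold) interactions
EPISTASIS_WEAK = 0.3
EPISTASIS_STRONG = 1.0

#: minimum genotypes per mutational-distance bin for profile/LD50 points
MIN_PER_DISTANCE = 15


@dataclass
class SingleEffectTable:
    """Per-mutation fluorescence effects measured in isolation."""

    effects: dict[tuple[int, str], float]
    n_obs: dict[tuple[int, str], int]
    f_wt_mean: float
    f_wt_sd: float
    se: dict[tuple[int, str], float] = field(default_factory=dict)
    f_wt_se: float = 0.0


def _mutation_sets(dataset: pd.DataFrame) -> pd.Series:
    return dataset["mutations"].map(parse_mutation_set)


def single_effects(
    dataset: pd.DataFrame,
    wildtype_population: np.ndarray | None = None,
) -> SingleEffectTable:
    """Effect table from genotypes carrying exactly one substitution.

    The wildtype reference is the synonymous-only population when supplied
    (nucleotide-level measurements of the wildtype protein); otherwise the
    collapsed wildtype record's fluorescence with zero spread.
    """
    muts = _mutation_sets(dataset)
    if wildtype_population is not None and len(wildtype_population) > 0:
        f_wt = float(np.mean(wildtype_population))
        sd_wt = float(np.std(wildtype_population, ddof=1)) if len(wildtype_population) > 1 else 0.0
    else:
        wt_rows = dataset[muts.map(len) == 0]
        if wt_rows.empty:
            raise ValueError("no wildtype genotypes in dataset")
        f_wt = float(wt_rows["fluorescence"].mean())
        sd_wt = 0.0

    if wildtype_population is not None and len(wildtype_population) > 1:
        f_wt_se = sd_wt / np.sqrt(len(wildtype_population))
    else:
        f_wt_se = 0.0

    effects: dict[tuple[int, str], float] = {}
    n_obs: dict[tuple[int, str], int] = {}
    se: dict[tuple[int, str], float] = {}
    singles = dataset[muts.map(len) == 1]
    for ms, row in zip(muts[muts.map(len) == 1], singles.itertuples()):
        (mut,) = ms
        effects[mut] = float(row.fluorescence) - f_wt
        n_obs[mut] = int(getattr(row, "n_replicates", 1))
        se[mut] = float(getattr(row, "se", 0.0))
    return SingleEffectTable(effects, n_obs, f_wt, sd_wt, se, float(f_wt_se))


def epistasis(dataset: pd.DataFrame, singles: SingleEffectTable) -> pd.DataFrame:
    """Observed-vs-expected epistasis per genotype (capped expectation).

    Returns one row per genotype with columns: mutations, n_mutations,
    observed, expected, epistasis, computable, null_sd.  ``null_sd`` is the
    propagated measurement noise of the epistasis estimate under additivity:
    the observed value, the d single-mutant measurements and the (1−d)-weighted
    wildtype reference each contribute their standard errors.  Replicate
    noise is treated as homoskedastic: per-genotype standard errors use the
    replicate variance pooled across the dataset (``se`` and ``n_replicates``
    columns), avoiding the heavy small-sample tails of individual variance
    estimates.  Without replicate information the wildtype population sd
    stands in for every measurement.
    """
    observed = dataset["fluorescence"].to_numpy(dtype=float)
    f_min, f_max = float(observed.min()), float(observed.max())
    muts = _mutation_sets(dataset)

    if "se" in dataset.columns and "n_replicates" in dataset.columns:
        se = dataset["se"].to_numpy(dtype=float)
        n_rep = dataset["n_replicates"].to_numpy(dtype=float)
        weight = np.maximum(n_rep - 1, 0)
        good = (se > 0) & (weight > 0)
        if good.any():
            # se_i = replicate_sd_i / sqrt(n_i)  →  pooled replicate variance
            pooled_sd = float(
                np.sqrt(
                    np.sum(weight[good] * se[good] ** 2 * n_rep[good]) / weight[good].sum()
                )
            )
        else:
            pooled_sd = singles.f_wt_sd
        se_obs_all = pooled_sd / np.sqrt(np.maximum(n_rep, 1.0))
        single_se = {
            m: pooled_sd / np.sqrt(max(singles.n_obs.get(m, 1), 1))
            for m in singles.effects
        }
    else:
        se_obs_all = np.full(len(dataset), singles.f_wt_sd)
        single_se = {m: singles.f_wt_sd for m in singles.effects}

    rows = []
    for ms, f_obs, se_obs in zip(muts, observed, se_obs_all):
        d = len(ms)
        computable = all(m in singles.effects for m in ms)
        if computable:
            raw = singles.f_wt_mean + sum(singles.effects[m] for m in ms)
            expected = min(max(raw, f_min), f_max)
            eps = f_obs - expected
            null_var = (
                se_obs**2
                + sum(single_se[m] ** 2 for m in ms)
                + ((1 - d) * singles.f_wt_se) ** 2
            )
        else:
            expected, eps = np.nan, np.nan
            null_var = np.nan
        rows.append((d, f_obs, expected, eps, computable, float(np.sqrt(null_var))))

    out = pd.DataFrame(
        rows,
        columns=["n_mutations", "observed", "expected", "epistasis", "computable", "null_sd"],
    )
    out.insert(0, "mutations", dataset["mutations"].to_numpy())
    return out


def additive_fraction_curve(
    epistasis_records: pd.DataFrame,
    functional_threshold: float,
) -> pd.DataFrame:
    """Observed / additively-expected functional genotype counts per distance.

    For each mutation count d, the ratio of genotypes observed functional to
    genotypes whose capped additive expectation is functional, over computable
    genotypes.  Without epistasis the ratio is 1 at every distance; distances
    whose expected-functional count is zero are omitted.
    """
    rec = epistasis_records[epistasis_records["computable"]]
    rows = []
    for d, grp in rec.groupby("n_mutations", sort=True):
        n_exp = int((grp["expected"] >= functional_threshold).sum())
        if n_exp == 0:
            continue
        n_obs = int((grp["observed"] >= functional_threshold).sum())
        rows.append((int(d), n_obs, n_exp, n_obs / n_exp))
    return pd.DataFrame(rows, columns=["n_mutations", "n_observed", "n_expected", "fraction"])


@dataclass
class LogisticFit:
    """f(x) = L / (1 + exp(-k (x - x0))), with LD50 the solution of f(x) = 0.5."""

    L: float
    k: float
    x0: float
    ld50: float | None
    distances: np.ndarray = field(default_factory=lambda: np.array([]))
    fractions: np.ndarray = field(default_factory=lambda: np.array([]))

    def __call__(self, x):
        return self.L / (1.0 + np.exp(-self.k * (np.asarray(x, dtype=float) - self.x0)))


def fit_logistic(distances: np.ndarray, fractions: np.ndarray, max_x: float) -> LogisticFit:
    def f(x, L, k, x0):
        return L / (1.0 + np.exp(-k * (x - x0)))

    p0 = [1.0, 1.0, float(np.median(distances))]
    popt, _ = optimize.curve_fit(
        f,
        distances,
        fractions,
        p0=p0,
        bounds=([1e-6, 1e-6, 0.0], [1.05, 10.0, max_x]),
        maxfev=20000,
    )
    L, k, x0 = (float(v) for v in popt)
    ld50 = x0 - np.log(2.0 * L - 1.0) / k if L > 0.5 else None
    return LogisticFit(L, k, x0, ld50, np.asarray(distances), np.asarray(fractions))


def fit_ld50(
    dataset: pd.DataFrame,
    mode: str,
    functional_threshold: float | None = None,
    wt_mean: float | None = None,
    wt_sd: float | None = None,
    min_per_bin: int = MIN_PER_DISTANCE,
    min_bins: int = 4,
) -> LogisticFit:
    """Mutational LD50 from per-distance loss fractions.

    ``mode='loss_of_function'``: fraction of genotypes below the functional
    threshold (the upper bound of the darkest gate) at each mutation count.
    ``mode='loss_of_wt_level'``: fraction of genotypes whose fluorescence has
    left the ±2 sd band around the wildtype level.  The fractions are fitted
    with a logistic curve and the LD50 is where the fit crosses 0.5.
    """
    muts = _mutation_sets(dataset)
    d = muts.map(len).to_numpy()
    f = dataset["fluorescence"].to_numpy(dtype=float)

    if mode == "loss_of_function":
        if functional_threshold is None:
            raise ValueError("loss_of_function mode needs functional_threshold")
        lost = f < functional_threshold
    elif mode == "loss_of_wt_level":
        if wt_mean is None or wt_sd is None:
            raise ValueError("loss_of_wt_level mode needs wt_mean and wt_sd")
        lost = np.abs(f - wt_mean) > 2.0 * wt_sd
    else:
        raise ValueError(f"unknown mode: {mode}")

    ds, fracs = [], []
    for dist in sorted(set(d)):
        mask = d == dist
        if mask.sum() < min_per_bin:
            continue
        ds.append(dist)
        fracs.append(float(lost[mask].mean()))
    if len(ds) < min_bins:
        raise ValueError(f"need ≥{min_bins} distance bins with ≥{min_per_bin} genotypes")
    return fit_logistic(np.array(ds, dtype=float), np.array(fracs), max_x=float(max(ds)))


def peak_profile(
    dataset: pd.DataFrame,
    origin: str = "",
    min_per_bin: int = MIN_PER_DISTANCE,
) -> pd.DataFrame:
    """Median fluorescence versus substitution distance from an origin genotype."""
    muts = _mutation_sets(dataset)
    origin_set = parse_mutation_set(origin)
    if not (muts == origin_set).any():
        raise ValueError(f"origin genotype {origin!r} not present in dataset")
    dist = muts.map(lambda ms: hamming(ms, origin_set)).to_numpy()
    f = dataset["fluorescence"].to_numpy(dtype=float)
    rows = []
    for d in sorted(set(dist)):
        mask = dist == d
        if mask.sum() < min_per_bin and d > 0:
            continue
        rows.append((int(d), float(np.median(f[mask])), int(mask.sum())))
    return pd.DataFrame(rows, columns=["distance", "median_fluorescence", "n_genotypes"])


def cross_ortholog_transfer(
    singles_a: SingleEffectTable,
    singles_b: SingleEffectTable,
    site_map: dict[int, int],
) -> tuple[float | None, int, int]:
    """Fraction of mutations neutral in ortholog A but deleterious in B.

    Neutral: effect within ±2 wildtype sd of zero.  Deleterious: effect below
    −5 wildtype sd.  Only identical target states at aligned sites measured in
    both datasets are compared.  Returns (fraction, n_transfer, n_shared).
    """
    shared = 0
    transfer = 0
    for (site_a, alt), eff_a in singles_a.effects.items():
        site_b = site_map.get(site_a)
        if site_b is None or (site_b, alt) not in singles_b.effects:
            continue
        shared += 1
        eff_b = singles_b.effects[(site_b, alt)]
        neutral_a = abs(eff_a) <= 2.0 * singles_a.f_wt_sd
        deleterious_b = eff_b < -5.0 * singles_b.f_wt_sd
        if neutral_a and deleterious_b:
            transfer += 1
    if shared == 0:
        return None, 0, 0
    return transfer / shared, transfer, shared


def pair_epistasis_table(epistasis_records: pd.DataFrame) -> dict[tuple[int, int], float]:
    """Max |epistasis| per site pair, from double mutants only."""
    doubles = epistasis_records[
        (epistasis_records["n_mutations"] == 2) & (epistasis_records["computable"])
    ]
    table: dict[tuple[int, int], float] = {}
    for row in doubles.itertuples():
        sites = tuple(sorted(s for s, _ in parse_mutation_set(row.mutations)))
        if len(sites) != 2:
            continue
        val = abs(float(row.epistasis))
        table[sites] = max(table.get(sites, 0.0), val)
    return table


def shared_epistatic_pairs(
    pairs_a: dict[tuple[int, int], float],
    pairs_b: dict[tuple[int, int], float],
    site_map: dict[int, int],
    cutoff: float = EPISTASIS_WEAK,
) -> tuple[float | None, int, int]:
    """Fraction of epistatic site pairs that are epistatic in both orthologs.

    Among site pairs with measured pair epistasis in both datasets, counts
    those exceeding the cutoff in either, and returns the fraction exceeding
    it in both.  Returns (fraction, n_both, n_either).
    """
    either = 0
    both = 0
    for (s1, s2), val_a in pairs_a.items():
        m1, m2 = site_map.get(s1), site_map.get(s2)
        if m1 is None or m2 is None:
            continue
        key_b = tuple(sorted((m1, m2)))
        if key_b not in pairs_b:
            continue
        val_b = pairs_b[key_b]
        if val_a > cutoff or val_b > cutoff:
            either += 1
            if val_a > cutoff and val_b > cutoff:
                both += 1
    if either == 0:
        return None, 0, 0
    return both / either, both, either


def annotate_effects(
    singles: SingleEffectTable,
    annotations: pd.DataFrame,
) -> dict:
    """Group single-mutant effects by external per-residue annotations.

    ``annotations`` columns: site, and either ``category`` (e.g. buried /
    exposed → rank-sum comparison of effect distributions) or ``score``
    (numeric per-mutation or per-residue value → Spearman rank correlation),
    or both.  Unmatched sites are counted, not fatal.
    """
    eff = pd.DataFrame(
        [(site, alt, v) for (site, alt), v in singles.effects.items()],
        columns=["site", "alt", "effect"],
    )
    merged = eff.merge(annotations, on="site", how="left")
    out: dict = {"n_unmatched": int(merged.iloc[:, -1].isna().sum())}

    if "category" in merged.columns:
        groups = {
            str(cat): grp["effect"].to_numpy()
            for cat, grp in merged.dropna(subset=["category"]).groupby("category")
        }
        out["category_medians"] = {c: float(np.median(v)) for c, v in groups.items()}
        if len(groups) == 2:
            (c1, v1), (c2, v2) = sorted(groups.items())
            stat, p = sps.mannwhitneyu(v1, v2, alternative="two-sided")
            out["rank_sum"] = {"groups": (c1, c2), "statistic": float(stat), "p_value": float(p)}
    if "score" in merged.columns:
        sub = merged.dropna(subset=["score"])
        if len(sub) >= 3:
            rho, p = sps.spearmanr(sub["score"], sub["effect"])
            out["spearman"] = {"rho": float(rho), "p_value": float(p), "n": int(len(sub))}
    return out


def epistatic_pair_proximity(
    pair_table: dict[tuple[int, int], float],
    distance_table: pd.DataFrame,
    cutoff: float = EPISTASIS_WEAK,
) -> dict:
    """Compare spatial distances of epistatic vs non-epistatic site pairs.

    ``distance_table`` columns: site1, site2, distance (externally supplied,
    e.g. Cβ–Cβ distances from a crystal structure).  Pairs without a distance
    are dropped and counted.
    """
    dist = {
        tuple(sorted((int(r.site1), int(r.site2)))): float(r.distance)
        for r in distance_table.itertuples()
    }
    epi, non_epi = [], []
    missing = 0
    for pair, val in pair_table.items():
        if pair not in dist:
            missing += 1
            continue
        (epi if val > cutoff else non_epi).append(dist[pair])
    out = {
        "n_epistatic": len(epi),
        "n_non_epistatic": len(non_epi),
        "n_missing_distance": missing,
        "median_epistatic": float(np.median(epi)) if epi else None,
        "median_non_epistatic": float(np.median(non_epi)) if non_epi else None,
    }
    if epi and non_epi:
        stat, p = sps.mannwhitneyu(epi, non_epi, alternative="two-sided")
        out["rank_sum"] = {"statistic": float(stat), "p_value": float(p)}
    return out
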