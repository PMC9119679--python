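"""Genetic-algorithm design of distant functional genotypes.

The mutation pool admits only substitutions the fitness model has seen often
enough to trust (≥10 distinct training genotypes), whose measured impact over
matched genotype backgrounds is mild (median ≥ −0.1 log10 units over ≥5
background pairs), plus wildtype-state reversions; sampling favors states not
found in natural homologs (ratio 0.6).  A population of wildtype sequences
undergoes shuffling, crossover, pool mutations and over-target trimming, with
fluorescence scored as the median of 20 MC-dropout passes, until the
population-median prediction plateaus.  Candidates at the target distance are
filtered by both the optimized and the a-posteriori networks and reduced to a
diverse set of representatives by greedy identity clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import format_mutation_set, parse_mutation_set
from .model import Network, predict_mc


@dataclass
class GenotypePredictor:
    """A trained network bound to its one-hot encoding."""

    net: Network
    columns: list[tuple[int, str]]
    wildtype: str
    mc_samples: int = 20

    def __post_init__(self):
        self._col_index = {c: i for i, c in enumerate(self.columns)}
        self._wt_cols = np.array(
            [self._col_index[(s + 1, self.wildtype[s])] for s in range(len(self.wildtype))]
        )

    def encode_sets(self, mutation_sets: list[frozenset]) -> np.ndarray:
        X = np.zeros((len(mutation_sets), len(self.columns)), dtype=float)
        X[:, self._wt_cols] = 1.0
        for i, ms in enumerate(mutation_sets):
            for site, alt in ms:
                X[i, self._col_index[(site, self.wildtype[site - 1])]] = 0.0
                X[i, self._col_index[(site, alt)]] = 1.0
        return X

    def mc(self, mutation_sets: list[frozenset], seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
        X = self.encode_sets(mutation_sets)
        return predict_mc(self.net, X, n_samples=self.mc_samples, seed=seed)

    def deterministic(self, mutation_sets: list[frozenset]) -> np.ndarray:
        return self.net.predict(self.encode_sets(mutation_sets))


@dataclass
class MutationPool:
    """Admissible GA moves with provenance and class-weighted sampling."""

    moves: list[tuple[int, str]]
    natural: set[tuple[int, str]]
    provenance: pd.DataFrame
    nonnatural_ratio: float = 0.6

    def __post_init__(self):
        if not self.moves:
            raise ValueError("mutation pool is empty")
        self._nat = [m for m in self.moves if m in self.natural]
        self._non = [m for m in self.moves if m not in self.natural]

    def sample(self, rng: np.random.Generator) -> tuple[int, str]:
        """Draw one move honoring the natural/non-natural ratio."""
        if self._non and (not self._nat or rng.random() < self.nonnatural_ratio):
            return self._non[rng.integers(len(self._non))]
        return self._nat[rng.integers(len(self._nat))]


def make_synthetic_natural_panel(
    landscape, fraction: float = 0.4, seed: int = 0
) -> set[tuple[int, str]]:
    """Stand-in for an alignment of natural homolog states (synthetic).

    Marks the wildtype state at every site as natural plus a random fraction
    of the landscape's panel moves, mimicking states that occur in natural
    sequences of the family.
    """
    rng = np.random.default_rng(seed)
    panel = list(landscape.move_panel)
    n = int(round(fraction * len(panel)))
    idx = rng.choice(len(panel), size=n, replace=False)
    natural = {panel[i] for i in idx}
    natural |= {(s + 1, a) for s, a in enumerate(landscape.wildtype_protein)}
    return natural


def natural_panel_from_alignment(alignment: dict[str, str], wildtype: str) -> set[tuple[int, str]]:
    """States observed at each aligned position of natural homolog sequences."""
    panel: set[tuple[int, str]] = set()
    for seq in alignment.values():
        if len(seq) != len(wildtype):
            raise ValueError("aligned sequences must match the wildtype length")
        for i, a in enumerate(seq):
            if a not in ("-", "."):
                panel.add((i + 1, a))
    return panel


def build_pool(
    dataset: pd.DataFrame,
    training_sets: list[frozenset],
    wildtype: str,
    natural_panel: set[tuple[int, str]],
    min_genotypes: int = 10,
    min_pairs: int = 5,
    min_median_impact: float = -0.1,
    nonnatural_ratio: float = 0.6,
) -> MutationPool:
    """Construct the admissible mutation pool from measured data.

    A substitution qualifies if it occurs in ≥ ``min_genotypes`` distinct
    training genotypes and its median impact over ≥ ``min_pairs`` background
    pairs — genotype pairs identical except for the focal substitution — is
    ≥ ``min_median_impact``.  Wildtype-state reversions at all pool sites are
    always included.
    """
    counts: dict[tuple[int, str], int] = {}
    for ms in training_sets:
        for m in ms:
            counts[m] = counts.get(m, 0) + 1

    mut_sets = [parse_mutation_set(m) for m in dataset["mutations"]]
    f_lookup = dict(zip(mut_sets, dataset["fluorescence"].to_numpy(dtype=float)))
    containing: dict[tuple[int, str], list[frozenset]] = {}
    for ms in mut_sets:
        for m in ms:
            containing.setdefault(m, []).append(ms)

    rows = []
    moves: list[tuple[int, str]] = []
    for m, c in sorted(counts.items()):
        if c < min_genotypes:
            continue
        impacts = []
        for g in containing.get(m, []):
            background = g - {m}
            if background in f_lookup:
                impacts.append(f_lookup[g] - f_lookup[background])
        if len(impacts) < min_pairs:
            continue
        med = float(np.median(impacts))
        if med < min_median_impact:
            continue
        moves.append(m)
        rows.append((m[0], m[1], c, len(impacts), med, m in natural_panel))

    sites = {s for s, _ in moves}
    for s in sorted(sites):
        rev = (s, wildtype[s - 1])
        if rev not in moves:
            moves.append(rev)
            rows.append((s, wildtype[s - 1], counts.get(rev, 0), 0, 0.0, True))

    provenance = pd.DataFrame(
        rows, columns=["site", "alt", "n_genotypes", "n_pairs", "median_impact", "natural"]
    )
    natural = set(natural_panel) | {(s, wildtype[s - 1]) for s in sites}
    return MutationPool(moves, natural, provenance, nonnatural_ratio)


@dataclass
class GaParams:
    population_size: int = 50
    crossover_prob: float = 0.7
    max_crossovers: int = 5
    per_aa_mutation_rate: float = 0.012
    target_mutations: int = 6
    untouched_fraction: float = 0.5
    mc_samples: int = 20
    plateau_eps: float = 0.005
    plateau_window: int = 5
    plateau_extra: int = 3
    max_generations: int = 100
    min_replicates: int = 10
    max_replicates: int = 25

    def __post_init__(self):
        if self.population_size % 2:
            raise ValueError("population size must be even")
        for name in ("crossover_prob", "per_aa_mutation_rate", "untouched_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class EvolveResult:
    population: list[frozenset]
    predictions: np.ndarray
    median_history: list[float]
    sampled_moves: set[tuple[int, str]]
    n_generations: int
    #: on-target genotypes that survived selection in any generation
    at_target_pool: set[frozenset] = field(default_factory=set)


def _crossover(a: dict[int, str], b: dict[int, str], points: np.ndarray, length: int):
    """Reciprocal exchange of mutations between breakpoints (no gene conversion)."""
    bounds = [0, *sorted(points), length]
    new_a, new_b = {}, {}
    for seg, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
        src_a, src_b = (a, b) if seg % 2 == 0 else (b, a)
        for site, alt in src_a.items():
            if lo < site <= hi:
                new_a[site] = alt
        for site, alt in src_b.items():
            if lo < site <= hi:
                new_b[site] = alt
    return new_a, new_b


def evolve(
    predictor: GenotypePredictor,
    pool: MutationPool,
    params: GaParams,
    wildtype: str,
    seed: int = 0,
) -> EvolveResult:
    """One GA run from an all-wildtype population.

    Per generation: shuffle; set an untouched half aside; pair the rest and
    cross over with probability ``crossover_prob`` at 0–``max_crossovers``
    uniformly placed breakpoints; mutate each offspring at a per-residue rate
    with moves sampled from the pool (wildtype states revert); trim genotypes
    over the target by removing one random mutation; score new genotypes as
    the median of MC-dropout passes; merge, sort by predicted fluorescence and
    truncate to the population size.  Stops a few generations after the
    population-median prediction plateaus.
    """
    rng = np.random.default_rng(seed)
    length = len(wildtype)
    pop: list[dict[int, str]] = [dict() for _ in range(params.population_size)]
    (wt_pred,), _ = predictor.mc([frozenset()], seed=seed)
    preds = np.full(params.population_size, wt_pred)
    median_history: list[float] = [float(np.median(preds))]
    sampled: set[tuple[int, str]] = set()
    at_target_pool: set[frozenset] = set()
    plateau_hit = None

    for gen in range(1, params.max_generations + 1):
        order = rng.permutation(len(pop))
        n_untouched = int(round(params.untouched_fraction * len(pop)))
        untouched_idx = order[:n_untouched]
        touched_idx = order[n_untouched:]

        offspring: list[dict[int, str]] = []
        touched = [dict(pop[i]) for i in touched_idx]
        for i in range(0, len(touched) - 1, 2):
            a, b = touched[i], touched[i + 1]
            if rng.random() < params.crossover_prob:
                k = int(rng.integers(0, params.max_crossovers + 1))
                if k > 0:
                    pts = rng.choice(np.arange(1, length), size=min(k, length - 1), replace=False)
                    a, b = _crossover(a, b, pts, length)
            offspring.extend((a, b))
        if len(touched) % 2:
            offspring.append(touched[-1])

        for g in offspring:
            n_events = rng.binomial(length, params.per_aa_mutation_rate)
            for _ in range(n_events):
                site, alt = pool.sample(rng)
                sampled.add((site, alt))
                if alt == wildtype[site - 1]:
                    g.pop(site, None)
                else:
                    g[site] = alt
            while len(g) > params.target_mutations:
                # bounce back: drop a previously added mutation per excess event
                victim = list(g)[rng.integers(len(g))]
                del g[victim]

        # the whole candidate pool is (re-)scored each generation: with
        # stochastic MC-dropout fitness, cached scores would let genotypes
        # with lucky past evaluations survive indefinitely
        all_pop = [pop[i] for i in order] + offspring
        all_sets = [frozenset(g.items()) for g in all_pop]
        all_preds, _ = predictor.mc(all_sets, seed=int(rng.integers(2**31)))
        keep = np.argsort(-all_preds, kind="stable")[: params.population_size]
        pop = [all_pop[i] for i in keep]
        preds = all_preds[keep]
        median_history.append(float(np.median(preds)))
        at_target_pool.update(
            frozenset(g.items()) for g in pop if len(g) == params.target_mutations
        )

        # plateau only counts once the population has reached the target
        # distance: the median is trivially flat while mutations accumulate
        at_target = (
            np.mean([len(g) == params.target_mutations for g in pop]) >= 0.9
        )
        if plateau_hit is None and at_target and gen >= params.plateau_window:
            window = median_history[-(params.plateau_window + 1) :]
            if max(window) - min(window) < params.plateau_eps:
                plateau_hit = gen
        if plateau_hit is not None and gen >= plateau_hit + params.plateau_extra:
            break

    return EvolveResult(
        population=[frozenset(g.items()) for g in pop],
        predictions=preds,
        median_history=median_history,
        sampled_moves=sampled,
        n_generations=len(median_history) - 1,
        at_target_pool=at_target_pool,
    )


def run_replicates(
    predictor: GenotypePredictor,
    pool: MutationPool,
    params: GaParams,
    wildtype: str,
    seed: int = 0,
) -> list[EvolveResult]:
    """Repeat the GA until every pool move has been sampled (≥min_replicates runs)."""
    results: list[EvolveResult] = []
    sampled: set[tuple[int, str]] = set()
    all_moves = set(pool.moves)
    rep = 0
    while rep < params.max_replicates:
        res = evolve(predictor, pool, params, wildtype, seed=seed + 1000 * rep)
        results.append(res)
        sampled |= res.sampled_moves
        rep += 1
        if rep >= params.min_replicates and all_moves <= sampled:
            break
    return results


def filter_candidates(
    populations: list[EvolveResult],
    optimized: GenotypePredictor,
    posterior: GenotypePredictor,
    wildtype: str,
    target: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Unique on-target genotypes that both networks call brighter than wildtype.

    A candidate passes if its MC-median minus sd under the optimized model,
    and its a-posteriori prediction, both exceed the corresponding wildtype
    prediction.
    """
    unique: list[frozenset] = []
    seen = set()
    for res in populations:
        extra = sorted(res.at_target_pool, key=lambda g: tuple(sorted(g)))
        for g in list(res.population) + extra:
            if len(g) == target and g not in seen:
                seen.add(g)
                unique.append(g)
    if not unique:
        return pd.DataFrame(
            columns=["mutations", "n_mutations", "predicted", "predicted_sd", "posterior", "passed"]
        )
    med, sd = optimized.mc(unique, seed=seed)
    (wt_med,), (wt_sd,) = optimized.mc([frozenset()], seed=seed)
    post = posterior.deterministic(unique)
    (wt_post,) = posterior.deterministic([frozenset()])
    passed = ((med - sd) > wt_med) & (post > wt_post)
    return pd.DataFrame(
        {
            "mutations": [format_mutation_set(wildtype, g) for g in unique],
            "n_mutations": [len(g) for g in unique],
            "predicted": med,
            "predicted_sd": sd,
            "posterior": post,
            "passed": passed,
        }
    )


def select_diverse(
    candidates: pd.DataFrame,
    n_representatives: int,
    wildtype: str,
    thresholds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Greedy identity clustering at decreasing thresholds; one pick per cluster.

    Candidates are seeded in order of predicted fluorescence; a candidate joins
    the first cluster whose seed shares ≥ threshold sequence identity,
    otherwise founds a new cluster.  The threshold is lowered stepwise until
    the desired number of clusters is reached; each cluster is represented by
    its brightest member.
    """
    if candidates.empty:
        raise ValueError("no candidates to cluster")
    if thresholds is None:
        thresholds = np.arange(0.999, 0.799, -0.002)
    length = len(wildtype)
    sets = [parse_mutation_set(m) for m in candidates["mutations"]]
    order = np.argsort(-candidates["predicted"].to_numpy(), kind="stable")

    def cluster(threshold: float) -> list[list[int]]:
        clusters: list[list[int]] = []
        for i in order:
            for cl in clusters:
                sites_seed, sites_i = dict(sets[cl[0]]), dict(sets[i])
                shared = set(sites_seed) | set(sites_i)
                diff = sum(1 for s in shared if sites_seed.get(s) != sites_i.get(s))
                ident = (length - diff) / length
                if ident >= threshold:
                    cl.append(i)
                    break
            else:
                clusters.append([i])
        return clusters

    clusters = cluster(1.0)
    for thr in thresholds:
        clusters = cluster(thr)
        if len(clusters) <= n_representatives:
            break
    reps = [cl[0] for cl in clusters[:n_representatives]]
    out = candidates.iloc[reps].copy()
    out["cluster"] = range(len(reps))
    return out.reset_index(drop=True)
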