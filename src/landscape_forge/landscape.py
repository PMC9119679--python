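"""Ground-truth genotype→fluorescence landscapes for simulated sort-seq assays.

The generative model mirrors what deep mutational scans of fluorescent proteins
measure: per-substitution additive effects on a latent *fitness potential*
(log10-fluorescence units), optional pairwise epistatic terms, and an abrupt
sigmoid threshold that maps the potential onto a bimodal fluorescence scale —
a dark mode at ``f_dark`` and a functional mode near the wildtype level
``f_wt``.  Substitutions at the three chromophore sites, and premature stop
codons, abolish fluorescence outright.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
from Bio.Seq import Seq
from scipy.special import expit

from .genotypes import AMINO_ACIDS, STOP, mutations_between, validate_protein

# one unambiguous codon per amino acid (E. coli-leaning choices; any fixed table works)
CODON_FOR = {
    "A": "GCT", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTC", "G": "GGT",
    "H": "CAT", "I": "ATC", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAC",
    "P": "CCG", "Q": "CAG", "R": "CGT", "S": "TCT", "T": "ACC", "V": "GTT",
    "W": "TGG", "Y": "TAC",
}
_BASES = "ACGT"


@dataclass(frozen=True)
class SigmoidTransform:
    """Threshold map from fitness potential to log10 fluorescence.

    ``F = f_dark + (f_wt - f_dark) * sigmoid(steepness * (potential - midpoint))``
    """

    f_dark: float = 1.8
    f_wt: float = 4.2
    steepness: float = 8.0
    midpoint: float = -1.5

    def __post_init__(self):
        if not self.f_dark < self.f_wt:
            raise ValueError("transform requires f_dark < f_wt")
        if self.steepness <= 0:
            raise ValueError("transform must be monotone non-decreasing: steepness > 0")

    def __call__(self, potential):
        return self.f_dark + (self.f_wt - self.f_dark) * expit(
            self.steepness * (np.asarray(potential, dtype=float) - self.midpoint)
        )


@dataclass(frozen=True)
class LinearThresholdTransform:
    """Fluorescence-additive map with a dark floor: ``F = max(f_dark, f_wt + potential)``.

    The additive-null transform: above the floor, fluorescence is exactly the
    wildtype level plus the summed effects, so a landscape without epistatic
    terms is additive on the measured scale (the floor is absorbed by the
    capped-expectation rule of the epistasis statistic).
    """

    f_dark: float = 1.8
    f_wt: float = 4.2

    def __post_init__(self):
        if not self.f_dark < self.f_wt:
            raise ValueError("transform requires f_dark < f_wt")

    def __call__(self, potential):
        return np.maximum(self.f_dark, self.f_wt + np.asarray(potential, dtype=float))


@dataclass
class LandscapeConfig:
    """Distribution parameters of a synthetic landscape.

    Additive effects are drawn from a neutral-or-deleterious mixture:
    with probability ``neutral_fraction`` a ``Normal(0, neutral_sd)`` draw,
    otherwise ``-Exponential(deleterious_scale)``.  Pairwise epistatic terms
    are placed on a panel of candidate substitutions ("moves"); their expected
    number is ``epistatic_density`` per panel move, negative with probability
    ``epistatic_negative_bias`` and exponentially distributed in magnitude.
    """

    neutral_fraction: float = 0.35
    neutral_sd: float = 0.02
    deleterious_scale: float = 0.8
    epistatic_density: float = 0.0
    epistatic_scale: float = 0.5
    epistatic_negative_bias: float = 0.9
    panel_size: int | None = None  # None → all single-nucleotide-reachable moves
    transform: SigmoidTransform = field(default_factory=SigmoidTransform)
    # per-cell log10-F spread; about half a gate width so sorted populations
    # span 2–3 gates and the binned CDF fit is well identified
    cell_noise_sd: float = 0.2
    chromophore_start: int | None = None  # 1-based; None → length // 3


# presets mirroring the two observed peak shapes: near-additive/robust vs
# epistasis-dense/fragile
FLAT_CONFIG = dict(neutral_fraction=0.55, deleterious_scale=0.45, epistatic_density=0.0)
# strict additive null: no epistatic terms AND fluorescence-additive transform
ADDITIVE_CONFIG = dict(
    neutral_fraction=0.55,
    deleterious_scale=0.45,
    epistatic_density=0.0,
    transform=LinearThresholdTransform(),
)
SHARP_CONFIG = dict(
    neutral_fraction=0.30,
    deleterious_scale=0.90,
    epistatic_density=3.0,
    epistatic_scale=0.6,
    epistatic_negative_bias=0.9,
)


@dataclass
class GroundTruthLandscape:
    wildtype_protein: str
    wildtype_cds: str
    chromophore_sites: frozenset[int]
    additive_effects: dict[tuple[int, str], float]
    epistatic_terms: dict[tuple[tuple[int, str], tuple[int, str]], float]
    transform: SigmoidTransform | LinearThresholdTransform
    cell_noise_sd: float
    move_panel: tuple[tuple[int, str], ...]

    def __post_init__(self):
        if 3 * len(self.wildtype_protein) + 3 != len(self.wildtype_cds):
            raise ValueError("coding sequence must be 3×protein length plus stop")

    # -- evaluation ---------------------------------------------------------

    def potential(self, mutations: Iterable[tuple[int, str]]) -> float:
        """Fitness potential: sum of additive effects plus epistatic terms."""
        muts = sorted(mutations)
        p = sum(self.additive_effects.get(m, 0.0) for m in muts)
        if self.epistatic_terms:
            for i in range(len(muts)):
                for j in range(i + 1, len(muts)):
                    p += self.epistatic_terms.get((muts[i], muts[j]), 0.0)
        return p

    def fluorescence_of_mutations(self, mutations: Iterable[tuple[int, str]]) -> float:
        muts = list(mutations)
        for site, alt in muts:
            if alt == STOP or site in self.chromophore_sites:
                return self.transform.f_dark
        return float(self.transform(self.potential(muts)))

    def true_fluorescence(self, protein: str) -> float:
        """log10 fluorescence of a full-length protein genotype."""
        validate_protein(protein)
        return self.fluorescence_of_mutations(
            mutations_between(self.wildtype_protein, protein)
        )

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        d = {
            "wildtype_protein": self.wildtype_protein,
            "wildtype_cds": self.wildtype_cds,
            "chromophore_sites": sorted(self.chromophore_sites),
            "additive_effects": {f"{s}{a}": v for (s, a), v in self.additive_effects.items()},
            "epistatic_terms": {
                f"{s1}{a1}|{s2}{a2}": v
                for ((s1, a1), (s2, a2)), v in self.epistatic_terms.items()
            },
            "transform": {
                "kind": "sigmoid" if isinstance(self.transform, SigmoidTransform) else "linear_threshold",
                **asdict(self.transform),
            },
            "cell_noise_sd": self.cell_noise_sd,
            "move_panel": [f"{s}{a}" for s, a in self.move_panel],
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthLandscape":
        d = json.loads(text)

        def _move(tok):
            return int(tok[:-1]), tok[-1]

        return cls(
            wildtype_protein=d["wildtype_protein"],
            wildtype_cds=d["wildtype_cds"],
            chromophore_sites=frozenset(d["chromophore_sites"]),
            additive_effects={_move(k): v for k, v in d["additive_effects"].items()},
            epistatic_terms={
                tuple(sorted((_move(a), _move(b)))): v
                for k, v in d["epistatic_terms"].items()
                for a, b in [k.split("|")]
            },
            transform=(
                SigmoidTransform(**{k: v for k, v in d["transform"].items() if k != "kind"})
                if d["transform"].get("kind", "sigmoid") == "sigmoid"
                else LinearThresholdTransform(
                    **{k: v for k, v in d["transform"].items() if k != "kind"}
                )
            ),
            cell_noise_sd=d["cell_noise_sd"],
            move_panel=tuple(_move(t) for t in d["move_panel"]),
        )


def reachable_moves(cds: str) -> list[tuple[int, str]]:
    """Amino-acid substitutions reachable by a single nucleotide change."""
    moves = set()
    n_codons = len(cds) // 3 - 1  # exclude stop
    for c in range(n_codons):
        codon = cds[3 * c : 3 * c + 3]
        wt_aa = str(Seq(codon).translate())
        for pos in range(3):
            for b in _BASES:
                if b == codon[pos]:
                    continue
                alt = str(Seq(codon[:pos] + b + codon[pos + 1 :]).translate())
                if alt != wt_aa and alt != STOP:
                    moves.add((c + 1, alt))
    return sorted(moves)


def make_landscape(
    length: int,
    config: LandscapeConfig | None = None,
    seed: int = 0,
) -> GroundTruthLandscape:
    """Draw a random ground-truth landscape of the given protein length.

    The wildtype protein is random; its coding sequence uses one fixed codon
    per amino acid.  Additive effects are drawn for every possible substitution
    at every non-chromophore site; epistatic terms only between moves of the
    panel (single-nucleotide-reachable substitutions, optionally subsampled to
    ``config.panel_size`` to emulate mutational hotspots).
    """
    if length < 30:
        raise ValueError("length must be ≥ 30")
    cfg = config or LandscapeConfig()
    rng = np.random.default_rng(seed)

    protein = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    cds = "".join(CODON_FOR[a] for a in protein) + "TAA"

    chromo_start = cfg.chromophore_start or max(2, length // 3)
    chromophore = frozenset(range(chromo_start, chromo_start + 3))

    effects: dict[tuple[int, str], float] = {}
    for site in range(1, length + 1):
        if site in chromophore:
            continue
        wt_aa = protein[site - 1]
        for alt in AMINO_ACIDS:
            if alt == wt_aa:
                continue
            if rng.random() < cfg.neutral_fraction:
                effects[(site, alt)] = float(rng.normal(0.0, cfg.neutral_sd))
            else:
                effects[(site, alt)] = float(-rng.exponential(cfg.deleterious_scale))

    panel = [m for m in reachable_moves(cds) if m[0] not in chromophore]
    if cfg.panel_size is not None and cfg.panel_size < len(panel):
        idx = rng.choice(len(panel), size=cfg.panel_size, replace=False)
        panel = sorted(panel[i] for i in idx)

    terms: dict[tuple[tuple[int, str], tuple[int, str]], float] = {}
    n_terms = int(round(cfg.epistatic_density * len(panel)))
    attempts = 0
    while len(terms) < n_terms and attempts < 50 * max(1, n_terms):
        attempts += 1
        i, j = rng.choice(len(panel), size=2, replace=False)
        a, b = panel[i], panel[j]
        if a[0] == b[0]:
            continue
        key = tuple(sorted((a, b)))
        if key in terms:
            continue
        sign = -1.0 if rng.random() < cfg.epistatic_negative_bias else 1.0
        terms[key] = float(sign * rng.exponential(cfg.epistatic_scale))

    return GroundTruthLandscape(
        wildtype_protein=protein,
        wildtype_cds=cds,
        chromophore_sites=chromophore,
        additive_effects=effects,
        epistatic_terms=terms,
        transform=cfg.transform,
        cell_noise_sd=cfg.cell_noise_sd,
        move_panel=tuple(panel),
    )
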