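"""Replicate merging, quality filtering and protein-level collapsing.

A nucleotide genotype is measured by several replicates — combinations of
primary barcode, secondary barcode and sorter.  Replicates are merged into a
cell-count-weighted mean fluorescence; genotypes with too few replicates, too
few cells, or inconsistent replicates (high index of dispersion) are removed.
Internal controls give empirical error rates: chromophore mutants must be
dark, synonymous-wildtype genotypes must be bright.  Finally, nucleotide
genotypes coding for the same protein are collapsed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import STOP, parse_mutation_set


@dataclass(frozen=True)
class QcThresholds:
    min_replicates: int = 2
    min_cells: float = 26.0
    max_dispersion: float = 525.0


# per-landscape presets; keys are the study ortholog names
QC_PRESETS = {
    "amacGFP": QcThresholds(2, 26.0, 525.0),
    "cgreGFP": QcThresholds(3, 14.0, 575.0),
    "ppluGFP2": QcThresholds(3, 23.0, 1000.0),
}


def merge_replicates(replicates: pd.DataFrame) -> pd.DataFrame:
    """Merge replicate fluorescence estimates per nucleotide genotype.

    ``replicates`` columns: cds, mutations (protein-level string), mu, cells,
    fit_ok.  Replicates without a usable fit or cells are ignored; a genotype
    with no usable replicate is dropped.  The merged fluorescence is the
    cell-count-weighted mean; the index of dispersion is variance/mean of the
    replicate fluorescences on the linear scale.
    """
    usable = replicates[(replicates["fit_ok"]) & (replicates["cells"] > 0)]
    rows = []
    for cds, grp in usable.groupby("cds", sort=True):
        mu = grp["mu"].to_numpy(dtype=float)
        cells = grp["cells"].to_numpy(dtype=float)
        merged = float(np.average(mu, weights=cells))
        linear = 10.0 ** mu
        if len(mu) > 1:
            dispersion = float(np.var(linear, ddof=1) / np.mean(linear))
            se = float(np.std(mu, ddof=1) / np.sqrt(len(mu)))
        else:
            dispersion = 0.0
            se = 0.0
        rows.append(
            (
                cds,
                grp["mutations"].iloc[0],
                merged,
                len(mu),
                float(cells.sum()),
                dispersion,
                se,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cds",
            "mutations",
            "fluorescence",
            "n_replicates",
            "total_cells",
            "dispersion",
            "se",
        ],
    )


def apply_qc(records: pd.DataFrame, thresholds: QcThresholds) -> pd.DataFrame:
    """Keep records with enough replicates and cells and consistent replicates."""
    keep = (
        (records["n_replicates"] >= thresholds.min_replicates)
        & (records["total_cells"] > thresholds.min_cells)
        & (records["dispersion"] < thresholds.max_dispersion)
    )
    return records[keep].reset_index(drop=True)


@dataclass
class ControlErrorRates:
    false_positive_rate: float | None
    false_negative_rate: float | None
    n_false_positive: int
    n_chromophore: int
    n_false_negative: int
    n_wildtype: int


def control_error_rates(
    records: pd.DataFrame,
    chromophore_sites: frozenset[int],
    dark_threshold: float,
) -> ControlErrorRates:
    """False positive/negative rates from the internal control genotypes.

    False positives: genotypes carrying a chromophore-site substitution that
    were nonetheless assigned a bright fluorescence (≥ ``dark_threshold``).
    False negatives: genotypes coding for the wildtype protein (synonymous
    only) that were assigned a dim or dark fluorescence.
    """
    muts = records["mutations"].map(parse_mutation_set)
    is_chromo = muts.map(
        lambda ms: any(site in chromophore_sites and alt != STOP for site, alt in ms)
    )
    is_wt = muts.map(len) == 0

    chromo_f = records.loc[is_chromo, "fluorescence"]
    wt_f = records.loc[is_wt, "fluorescence"]
    n_fp = int((chromo_f >= dark_threshold).sum())
    n_fn = int((wt_f < dark_threshold).sum())
    return ControlErrorRates(
        false_positive_rate=(n_fp / len(chromo_f)) if len(chromo_f) else None,
        false_negative_rate=(n_fn / len(wt_f)) if len(wt_f) else None,
        n_false_positive=n_fp,
        n_chromophore=int(len(chromo_f)),
        n_false_negative=n_fn,
        n_wildtype=int(len(wt_f)),
    )


def collapse_synonymous(records: pd.DataFrame) -> pd.DataFrame:
    """One record per protein genotype: cell-weighted mean over synonyms."""
    has_se = "se" in records.columns
    rows = []
    for mutations, grp in records.groupby("mutations", sort=True):
        w = grp["total_cells"].to_numpy(dtype=float)
        f = grp["fluorescence"].to_numpy(dtype=float)
        if has_se:
            se_in = grp["se"].to_numpy(dtype=float)
            se = float(np.sqrt(np.sum((w * se_in) ** 2)) / w.sum())
        else:
            se = 0.0
        rows.append(
            (
                mutations,
                len(parse_mutation_set(mutations)),
                float(np.average(f, weights=w)),
                int(grp["n_replicates"].sum()),
                float(w.sum()),
                len(grp),
                se,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mutations",
            "n_mutations",
            "fluorescence",
            "n_replicates",
            "total_cells",
            "n_nt_genotypes",
            "se",
        ],
    )


def wildtype_reference(records: pd.DataFrame) -> tuple[float, float, np.ndarray]:
    """Mean, sd and values of the synonymous-wildtype fluorescence population.

    Computed on nucleotide-level (pre-collapse) records so the population
    spread reflects independent measurements of the same protein.
    """
    wt = records.loc[records["mutations"] == "", "fluorescence"].to_numpy(dtype=float)
    if len(wt) == 0:
        raise ValueError("no wildtype-coding genotypes in dataset")
    sd = float(np.std(wt, ddof=1)) if len(wt) > 1 else 0.0
    return float(np.mean(wt)), sd, wt
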