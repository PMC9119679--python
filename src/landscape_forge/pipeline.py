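"""End-to-end driver: simulate → count → estimate → QC → statistics.

`run_pipeline` wires the stages into one reproducible run directory with a
machine-readable summary (genotype counts, mutation load, control error
rates, LD50s and epistasis fractions).  The heavier modeling and design
stages are exposed as separate helpers so callers can budget them explicitly.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fluor import FluorEstimate, calibrate_machines, fit_gate_distribution
from .landscape import FLAT_CONFIG, SHARP_CONFIG, LandscapeConfig, make_landscape
from .qc import (
    QC_PRESETS,
    QcThresholds,
    apply_qc,
    collapse_synonymous,
    control_error_rates,
    merge_replicates,
    wildtype_reference,
)
from .readproc import (
    count_gate_reads,
    merge_secondary_barcodes,
    normalize_by_count_controls,
)
from .simulate import (
    HISEQ_CONSTANT,
    GateScheme,
    LibrarySpec,
    SortExperiment,
    generate_library,
    simulate_sort,
)
from .stats import (
    EPISTASIS_STRONG,
    EPISTASIS_WEAK,
    additive_fraction_curve,
    epistasis,
    fit_ld50,
    single_effects,
)

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    length: int = 235
    preset: str = "flat"  # flat | sharp
    seed: int = 0
    library: LibrarySpec = field(default_factory=LibrarySpec)
    gates: GateScheme = field(default_factory=GateScheme)
    qc_preset: str = "amacGFP"
    landscape_overrides: dict = field(default_factory=dict)

    def landscape_config(self) -> LandscapeConfig:
        base = {"flat": FLAT_CONFIG, "sharp": SHARP_CONFIG}[self.preset]
        return LandscapeConfig(**{**base, **self.landscape_overrides})

    def thresholds(self) -> QcThresholds:
        return QC_PRESETS[self.qc_preset]


@dataclass
class ProcessedExperiment:
    """Everything downstream statistics need from one sorted library."""

    dataset: pd.DataFrame  # protein-level collapsed records
    nt_records: pd.DataFrame  # nucleotide-level QC-passed records
    wt_mean: float
    wt_sd: float
    wt_population: np.ndarray
    calibration_slope: float
    calibration_intercept: float
    drop_log: dict


def process_experiment(
    exp: SortExperiment,
    barcode_map: dict[str, tuple[str, str]],
    anchors_known: set[str],
    thresholds: QcThresholds,
) -> ProcessedExperiment:
    """Gate counting → normalization → per-replicate fits → calibration → QC.

    ``barcode_map`` maps primary barcode → (cds, protein-mutation string);
    primaries missing from the map (e.g. barcode sequencing errors) are
    dropped and logged.  Sorter B estimates are rescaled onto sorter A via the
    wildtype anchors before replicate merging.
    """
    log: dict = {}
    records = count_gate_reads(exp.reads, HISEQ_CONSTANT, drop_log=log)
    records = merge_secondary_barcodes(records)
    records = normalize_by_count_controls(
        records, exp.control_barcodes, exp.spec.count_control_cells
    )
    controls = set(exp.control_barcodes)
    records = [r for r in records if r.primary not in controls]

    # barcodes outside the assignment map (e.g. read errors in the barcode
    # region) can never be attributed to a genotype: drop before fitting
    known = set(barcode_map) | set(anchors_known)
    log["replicates_unknown_barcode"] = sum(1 for r in records if r.primary not in known)
    records = [r for r in records if r.primary in known]

    estimates: dict[tuple[str, str, str], FluorEstimate] = {}
    for r in records:
        if r.normalized_cells.sum() < 3.0:  # spurious-barcode stubs; cannot pass QC
            continue
        estimates[(r.primary, r.secondary, r.sorter)] = fit_gate_distribution(
            r.normalized_cells, exp.gates
        )

    by_sorter: dict[str, dict] = {"A": {}, "B": {}}
    for (pb, sb, sorter), est in estimates.items():
        by_sorter.setdefault(sorter, {})[(pb, sb)] = est
    anchors = [
        key
        for key in by_sorter.get("A", {})
        if key in by_sorter.get("B", {}) and key[0] in anchors_known
    ]
    slope, intercept = 1.0, 0.0
    if len(anchors) >= 2 and by_sorter.get("B"):
        cal = calibrate_machines(by_sorter["A"], by_sorter["B"], anchors)
        slope, intercept = cal.slope, cal.intercept
        for key, est in by_sorter["B"].items():
            by_sorter["B"][key] = cal.apply(est)

    rows = []
    for sorter, ests in by_sorter.items():
        for (pb, sb), est in ests.items():
            mapped = barcode_map.get(pb)
            if mapped is None:  # calibration-only spike-ins
                continue
            cds, mutations = mapped
            rows.append((cds, mutations, pb, sb, sorter, est.mu, est.n_cells, est.fit_ok))
    replicates = pd.DataFrame(
        rows, columns=["cds", "mutations", "primary", "secondary", "sorter", "mu", "cells", "fit_ok"]
    )
    replicates = replicates[replicates["mu"] >= 0]  # negative fluorescence excluded

    merged = merge_replicates(replicates)
    passed = apply_qc(merged, thresholds)
    wt_mean, wt_sd, wt_pop = wildtype_reference(passed)
    dataset = collapse_synonymous(passed)
    return ProcessedExperiment(
        dataset=dataset,
        nt_records=passed,
        wt_mean=wt_mean,
        wt_sd=wt_sd,
        wt_population=wt_pop,
        calibration_slope=slope,
        calibration_intercept=intercept,
        drop_log=log,
    )


def truth_barcode_map(exp: SortExperiment) -> dict[str, tuple[str, str]]:
    """Primary barcode → (cds, mutations), excluding the brightness spike-ins."""
    return {
        row.primary: (row.cds, row.mutations)
        for row in exp.truth.itertuples()
        if pd.isna(row.reference_level)
    }


def anchor_barcodes(exp: SortExperiment) -> set[str]:
    """Known-genotype barcodes usable as cross-machine calibration anchors."""
    t = exp.truth
    return set(t.loc[t["wildtype_control"] | t["reference_level"].notna(), "primary"])


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full simulated experiment and write stage outputs + summary.

    Genotype assignment uses the simulator's truth table for the barcode →
    genotype map (the consensus caller is exercised by its own entry point);
    everything downstream of the raw gate reads is inferred, not copied.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    landscape = make_landscape(config.length, config.landscape_config(), seed=config.seed)
    (outdir / "landscape.json").write_text(landscape.to_json())

    spec = config.library
    library = generate_library(landscape, spec)
    exp = simulate_sort(library, landscape, spec, config.gates)
    exp.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)

    processed = process_experiment(
        exp, truth_barcode_map(exp), anchor_barcodes(exp), config.thresholds()
    )
    processed.dataset.to_csv(outdir / "dataset.tsv", sep="\t", index=False)
    processed.nt_records.to_csv(outdir / "nt_records.tsv", sep="\t", index=False)

    functional_threshold = config.gates.boundaries[0]
    dark_threshold = 0.5 * (landscape.transform.f_dark + processed.wt_mean)
    errors = control_error_rates(
        processed.nt_records, landscape.chromophore_sites, dark_threshold
    )

    singles = single_effects(processed.dataset, processed.wt_population)
    epi = epistasis(processed.dataset, singles)
    epi.to_csv(outdir / "epistasis.tsv", sep="\t", index=False)
    curve = additive_fraction_curve(epi, functional_threshold)
    curve.to_csv(outdir / "additive_fraction.tsv", sep="\t", index=False)

    summary: dict = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "preset": config.preset,
        "n_protein_genotypes": int(len(processed.dataset)),
        "mean_aa_substitutions": float(
            processed.dataset["n_mutations"].mean()
        ),
        "wildtype_fluorescence_mean": processed.wt_mean,
        "wildtype_fluorescence_sd": processed.wt_sd,
        "calibration_slope": processed.calibration_slope,
        "calibration_intercept": processed.calibration_intercept,
        "false_positive_rate": errors.false_positive_rate,
        "false_negative_rate": errors.false_negative_rate,
        "n_single_mutants": len(singles.effects),
        "fraction_epistasis_not_computable": float(1.0 - epi["computable"].mean()),
    }
    comp = epi[epi["computable"] & (epi["n_mutations"] >= 1)]
    if len(comp):
        summary["fraction_weak_epistasis"] = float(
            (comp["epistasis"].abs() > EPISTASIS_WEAK).mean()
        )
        summary["fraction_strong_epistasis"] = float(
            (comp["epistasis"].abs() > EPISTASIS_STRONG).mean()
        )
    for mode, key in (("loss_of_function", "ld50_loss_of_function"),
                      ("loss_of_wt_level", "ld50_loss_of_wt_level")):
        try:
            fit = fit_ld50(
                processed.dataset,
                mode,
                functional_threshold=functional_threshold,
                wt_mean=processed.wt_mean,
                wt_sd=processed.wt_sd,
            )
            summary[key] = fit.ld50
        except ValueError as exc:
            summary[key] = None
            summary[key + "_error"] = str(exc)

    summary["drop_log"] = processed.drop_log
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
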