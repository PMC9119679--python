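"""Simulated sort-seq experiments.

Emulates the experimental chain of a barcoded deep mutational scan of a
fluorescent protein: error-prone mutagenesis of a wildtype coding sequence,
20-nt primary barcodes per mutant molecule and 10-nt secondary barcodes per
cloning replicate, FACS sorting of cells into 8 green-intensity gates on two
machines with slightly different calibrations, spike-in count-control barcodes
at a fixed number of cells per gate, and short-read sequencing of (a) the
barcode region per sorted gate and (b) the coding region in two overlapping
halves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .genotypes import format_mutation_set, mutations_between
from .landscape import GroundTruthLandscape

_BASES = np.array(list("ACGT"))

#: constant region separating primary and secondary barcode in gate reads
HISEQ_CONSTANT = "CTGCAGGTCA"
#: constant region marking the barcode in coding-region reads
MISEQ_CONSTANT = "GAGGTCTCTA"


@dataclass
class LibrarySpec:
    """Parameters of one simulated sort-seq experiment."""

    n_genotypes: int = 2000
    per_nt_mutation_rate: float = 0.0075
    mean_barcode_replicates: float = 7.0
    cells_per_replicate_mean: float = 35.0
    reads_per_cell: float = 2.0
    missort_rate: float = 0.01
    count_control_cells: int = 5000
    n_count_controls: int = 4
    n_wildtype_controls: int = 30
    #: known-brightness spike-in genotypes (one tuple entry per level), emulating
    #: the wildtype sequences of other orthologs added to every library as
    #: cross-machine calibration anchors
    reference_levels: tuple[float, ...] = (2.6, 3.2, 3.8)
    n_reference_barcodes: int = 8
    barcode_error_rate: float = 0.002  # per-base substitution rate on barcode reads
    seed: int = 0

    def __post_init__(self):
        for name in ("per_nt_mutation_rate", "missort_rate", "barcode_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "n_genotypes",
            "mean_barcode_replicates",
            "cells_per_replicate_mean",
            "reads_per_cell",
            "count_control_cells",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GateScheme:
    """Eight green-intensity gates defined by 7 increasing log10-F thresholds.

    Gate 1 is the darkest gate (open below the first boundary); gate 8 is open
    above the last.  Each sorter applies an affine miscalibration to the
    measured log10 fluorescence before gating: ``measured = scale * F + offset``.
    """

    boundaries: tuple[float, ...] = (2.0, 2.4, 2.8, 3.2, 3.6, 4.0, 4.4)
    sorter_scale: dict[str, float] = field(default_factory=lambda: {"A": 1.0, "B": 1.03})
    sorter_offset: dict[str, float] = field(default_factory=lambda: {"A": 0.0, "B": -0.10})

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=float)
        if len(b) != 7 or np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be 7 strictly increasing thresholds")

    @property
    def sorters(self) -> list[str]:
        return sorted(self.sorter_scale)

    def assign(self, log_f: np.ndarray, sorter: str) -> np.ndarray:
        """Gate index 1..8 for measured fluorescence on the given sorter."""
        measured = self.sorter_scale[sorter] * np.asarray(log_f) + self.sorter_offset[sorter]
        return np.searchsorted(self.boundaries, measured) + 1

    def gate_bounds(self, gate: int) -> tuple[float, float]:
        """(lower, upper) log10-F bounds of a gate; open ends are ±inf."""
        b = self.boundaries
        lo = -np.inf if gate == 1 else b[gate - 2]
        hi = np.inf if gate == 8 else b[gate - 1]
        return lo, hi


@dataclass
class LibraryMember:
    primary_barcode: str
    cds: str
    protein: str
    mutations: frozenset[tuple[int, str]]  # amino-acid substitutions vs wildtype
    is_wildtype_control: bool = False
    reference_level: float | None = None  # fixed true fluorescence for spike-ins


def _random_barcodes(rng: np.random.Generator, n: int, length: int, taken: set[str]) -> list[str]:
    """Draw n distinct barcodes not colliding with ``taken`` (regenerate on collision)."""
    out: list[str] = []
    while len(out) < n:
        bc = "".join(rng.choice(_BASES, size=length))
        if bc in taken:
            continue
        taken.add(bc)
        out.append(bc)
    return out


def expected_aa_substitutions(cds: str, rate: float) -> float:
    """Exact expected number of amino-acid changes per genotype.

    Enumerates, per codon, all 4^3 mutation outcomes of independent per-base
    substitution at the given rate (uniform over the 3 alternative bases) and
    sums the probability that the translated amino acid changes.  Serves both
    as the library generator's calibration target and as an independent check
    of its realized mutation load.
    """
    total = 0.0
    n_codons = len(cds) // 3
    for c in range(n_codons):
        codon = cds[3 * c : 3 * c + 3]
        wt_aa = str(Seq(codon).translate())
        p_changed = 0.0
        for b0 in "ACGT":
            p0 = (1 - rate) if b0 == codon[0] else rate / 3
            for b1 in "ACGT":
                p1 = (1 - rate) if b1 == codon[1] else rate / 3
                for b2 in "ACGT":
                    p2 = (1 - rate) if b2 == codon[2] else rate / 3
                    if str(Seq(b0 + b1 + b2).translate()) != wt_aa:
                        p_changed += p0 * p1 * p2
        total += p_changed
    return total


def rate_for_mean_substitutions(cds: str, target_mean: float) -> float:
    """Per-nucleotide rate whose expected amino-acid load equals ``target_mean``."""
    lo, hi = 0.0, 0.2
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if expected_aa_substitutions(cds, mid) < target_mean:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_library(landscape: GroundTruthLandscape, spec: LibrarySpec) -> list[LibraryMember]:
    """Mutagenize the wildtype coding sequence into a barcoded mutant library.

    Substitutions are i.i.d. per nucleotide over the coding region (the stop
    codon is left intact).  Wildtype positive-control members with known
    barcodes are appended after the mutants.
    """
    rng = np.random.default_rng(spec.seed)
    wt_cds = landscape.wildtype_cds
    coding = np.array(list(wt_cds[:-3]))
    taken: set[str] = set()
    n_ref = len(spec.reference_levels) * spec.n_reference_barcodes
    barcodes = _random_barcodes(
        rng, spec.n_genotypes + spec.n_wildtype_controls + n_ref, 20, taken
    )

    members: list[LibraryMember] = []
    for i in range(spec.n_genotypes):
        seq = coding.copy()
        hits = np.flatnonzero(rng.random(len(seq)) < spec.per_nt_mutation_rate)
        for pos in hits:
            alts = [b for b in "ACGT" if b != seq[pos]]
            seq[pos] = alts[rng.integers(3)]
        cds = "".join(seq) + wt_cds[-3:]
        protein = str(Seq(cds[:-3]).translate())
        members.append(
            LibraryMember(
                primary_barcode=barcodes[i],
                cds=cds,
                protein=protein,
                mutations=mutations_between(landscape.wildtype_protein, protein),
            )
        )
    for j in range(spec.n_wildtype_controls):
        members.append(
            LibraryMember(
                primary_barcode=barcodes[spec.n_genotypes + j],
                cds=wt_cds,
                protein=landscape.wildtype_protein,
                mutations=frozenset(),
                is_wildtype_control=True,
            )
        )
    k = spec.n_genotypes + spec.n_wildtype_controls
    for level in spec.reference_levels:
        for _ in range(spec.n_reference_barcodes):
            members.append(
                LibraryMember(
                    primary_barcode=barcodes[k],
                    cds=wt_cds,
                    protein=landscape.wildtype_protein,
                    mutations=frozenset(),
                    reference_level=level,
                )
            )
            k += 1
    return members


@dataclass
class SortExperiment:
    """Output of a simulated sort: gate reads plus ground truth."""

    reads: pd.DataFrame  # columns: seq (40-mer), sorter, gate, n
    truth: pd.DataFrame  # per primary barcode: mutations, true fluorescence
    replicate_truth: pd.DataFrame  # per (primary, secondary, sorter): true cells
    control_barcodes: list[str]
    gates: GateScheme
    spec: LibrarySpec


def _corrupt_reads(rng, seq: str, n: int, per_base_rate: float):
    """Split n reads of ``seq`` into clean reads and single-substitution variants.

    Returns (n_clean, list of (variant_seq, count)).  Multiple errors per read
    are rare at the modeled rates and are approximated by a single substitution.
    """
    if per_base_rate <= 0 or n == 0:
        return n, []
    p_any = 1.0 - (1.0 - per_base_rate) ** len(seq)
    n_err = rng.binomial(n, p_any)
    if n_err == 0:
        return n, []
    variants: dict[str, int] = {}
    positions = rng.integers(0, len(seq), size=n_err)
    picks = rng.integers(0, 3, size=n_err)
    for pos, k in zip(positions, picks):
        alts = [b for b in "ACGT" if b != seq[pos]]
        var = seq[:pos] + alts[k] + seq[pos + 1 :]
        variants[var] = variants.get(var, 0) + 1
    return n - n_err, list(variants.items())


def simulate_sort(
    library: list[LibraryMember],
    landscape: GroundTruthLandscape,
    spec: LibrarySpec,
    gates: GateScheme | None = None,
) -> SortExperiment:
    """Sort each barcoded replicate's cells into gates and emit barcode reads.

    Each (primary, secondary, sorter) replicate receives a Poisson number of
    cells around ``cells_per_replicate_mean``; each cell's log10 fluorescence
    is Normal(true F, cell_noise_sd), miscalibrated per sorter, gated, and with
    probability ``missort_rate`` recorded in an adjacent gate.  Reads per gate
    are Poisson(cells × reads_per_cell); count-control barcodes contribute
    exactly ``count_control_cells`` cells in every gate of every sorter.
    """
    gates = gates or GateScheme()
    rng = np.random.default_rng(spec.seed + 1)
    taken = {m.primary_barcode for m in library}
    control_primaries = _random_barcodes(rng, spec.n_count_controls, 20, taken)

    rows: list[tuple[str, str, int, int]] = []  # seq, sorter, gate, n
    truth_rows = []
    rep_rows = []
    secondary_taken: set[str] = set()

    def emit(primary: str, secondary: str, sorter: str, gate_counts: np.ndarray):
        seq = primary + HISEQ_CONSTANT + secondary
        for g in range(8):
            reads = rng.poisson(gate_counts[g] * spec.reads_per_cell)
            if reads == 0:
                continue
            clean, variants = _corrupt_reads(rng, seq, reads, spec.barcode_error_rate)
            if clean:
                rows.append((seq, sorter, g + 1, clean))
            for var, cnt in variants:
                rows.append((var, sorter, g + 1, cnt))

    for member in library:
        if member.reference_level is not None:
            f_true = member.reference_level
        else:
            f_true = landscape.fluorescence_of_mutations(member.mutations)
        n_secondary = max(1, rng.poisson(spec.mean_barcode_replicates))
        secondaries = _random_barcodes(rng, n_secondary, 10, secondary_taken)
        total_cells = 0
        for sec in secondaries:
            for sorter in gates.sorters:
                n_cells = rng.poisson(spec.cells_per_replicate_mean)
                if n_cells == 0:
                    continue
                log_f = rng.normal(f_true, landscape.cell_noise_sd, size=n_cells)
                gate = gates.assign(log_f, sorter)
                miss = rng.random(n_cells) < spec.missort_rate
                shift = rng.choice([-1, 1], size=n_cells)
                gate = np.where(miss, np.clip(gate + shift, 1, 8), gate)
                counts = np.bincount(gate, minlength=9)[1:]
                emit(member.primary_barcode, sec, sorter, counts)
                rep_rows.append((member.primary_barcode, sec, sorter, n_cells))
                total_cells += n_cells
        truth_rows.append(
            (
                member.primary_barcode,
                format_mutation_set(landscape.wildtype_protein, member.mutations),
                f_true,
                total_cells,
                member.is_wildtype_control,
                member.reference_level,
                member.cds,
            )
        )

    control_cells = np.full(8, spec.count_control_cells, dtype=float)
    for cb in control_primaries:
        sec = "".join(rng.choice(_BASES, size=10))
        for sorter in gates.sorters:
            emit(cb, sec, sorter, control_cells)

    reads = pd.DataFrame(rows, columns=["seq", "sorter", "gate", "n"])
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "primary",
            "mutations",
            "true_fluorescence",
            "true_cells",
            "wildtype_control",
            "reference_level",
            "cds",
        ],
    )
    replicate_truth = pd.DataFrame(rep_rows, columns=["primary", "secondary", "sorter", "cells"])
    return SortExperiment(
        reads=reads,
        truth=truth,
        replicate_truth=replicate_truth,
        control_barcodes=control_primaries,
        gates=gates,
        spec=spec,
    )


def simulate_coding_reads(
    library: list[LibraryMember],
    per_base_error_rate: float = 0.005,
    reads_per_half: int = 10,
    overlap: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired-half coding-region reads for consensus genotype calling.

    Each barcode yields ``reads_per_half`` reads of the N- and C-terminal
    halves of its coding sequence (split between forward and reverse strands),
    with i.i.d. substitution errors; the halves overlap by ``overlap``
    nucleotides.  Columns: barcode, half (N|C), strand (+|-), motif, seq.
    """
    if not 0.0 <= per_base_error_rate <= 0.05:
        raise ValueError("per_base_error_rate must lie in [0, 0.05]")
    rng = np.random.default_rng(seed)
    rows = []
    for member in library:
        coding = member.cds[:-3]  # stop codon is not part of the consensus target
        cut = len(coding) // 2
        n_half = coding[: cut + overlap // 2]
        c_half = coding[cut - (overlap - overlap // 2) :]
        for half, template in (("N", n_half), ("C", c_half)):
            n_fwd = (reads_per_half + 1) // 2
            for i in range(reads_per_half):
                strand = "+" if i < n_fwd else "-"
                seq = template if strand == "+" else str(Seq(template).reverse_complement())
                seq_arr = np.array(list(seq))
                hits = np.flatnonzero(rng.random(len(seq_arr)) < per_base_error_rate)
                for pos in hits:
                    alts = [b for b in "ACGT" if b != seq_arr[pos]]
                    seq_arr[pos] = alts[rng.integers(3)]
                motif = MISEQ_CONSTANT
                m_hits = np.flatnonzero(rng.random(len(motif)) < per_base_error_rate)
                if len(m_hits):
                    m_arr = np.array(list(motif))
                    for pos in m_hits:
                        alts = [b for b in "ACGT" if b != m_arr[pos]]
                        m_arr[pos] = alts[rng.integers(3)]
                    motif = "".join(m_arr)
                rows.append((member.primary_barcode, half, strand, motif, "".join(seq_arr)))
    return pd.DataFrame(rows, columns=["barcode", "half", "strand", "motif", "seq"])


def generate_protein_library(
    landscape: GroundTruthLandscape,
    n_genotypes: int,
    mean_mutations: float = 4.0,
    measurement_sd: float = 0.03,
    seed: int = 0,
) -> pd.DataFrame:
    """Protein-level genotype–fluorescence table drawn from the landscape's move panel.

    Shortcut generator for the modeling and design stages: genotypes carry a
    Poisson number of substitutions drawn uniformly from the landscape's panel
    (one per site), and fluorescence is the ground truth plus Normal
    measurement noise at the replicate-merged precision.  Includes a
    synonymous-wildtype reference population in the returned frame
    (``mutations == ""``).
    """
    rng = np.random.default_rng(seed)
    panel = list(landscape.move_panel)
    by_site: dict[int, list[tuple[int, str]]] = {}
    for mv in panel:
        by_site.setdefault(mv[0], []).append(mv)
    sites = sorted(by_site)

    seen: set[frozenset] = set()
    rows = []
    n_wt = max(30, n_genotypes // 50)
    for _ in range(n_wt):
        f = landscape.fluorescence_of_mutations(()) + rng.normal(0, measurement_sd)
        rows.append(("", 0, f))
    while len(rows) < n_wt + n_genotypes:
        d = rng.poisson(mean_mutations)
        if d == 0:
            continue
        chosen_sites = rng.choice(len(sites), size=min(d, len(sites)), replace=False)
        muts = frozenset(
            by_site[sites[s]][rng.integers(len(by_site[sites[s]]))] for s in chosen_sites
        )
        if muts in seen:
            continue
        seen.add(muts)
        f = landscape.fluorescence_of_mutations(muts) + rng.normal(0, measurement_sd)
        rows.append((format_mutation_set(landscape.wildtype_protein, muts), len(muts), f))
    df = pd.DataFrame(rows, columns=["mutations", "n_mutations", "fluorescence"])
    df["n_replicates"] = 3
    df["total_cells"] = 100.0
    return df
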