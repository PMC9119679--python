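"""Raw-read processing: consensus genotype calling and gate-count tabulation.

Implements the filtering rules used for barcoded sort-seq libraries:

* coding-region consensus per primary barcode requires ≥ ``min_reads`` reads in
  each gene half and ≥ ``agreement`` per-position agreement; forward/reverse and
  N/C-half consensi must merge without conflict (the half overlap must match
  100%), and calls containing indels relative to the wildtype are rejected;
* gate reads lacking the constant motif between the primary and secondary
  barcode are discarded;
* a secondary barcode with fewer than ``merge_max_reads`` reads lying within
  ``merge_max_dist`` nucleotides of a more abundant secondary of the same
  primary is treated as a sequencing error and merged into it;
* read counts are converted to cell counts via the spiked-in count-control
  barcodes of each gate.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Seq import Seq

from .genotypes import mutations_between

DEFAULT_MIN_READS = 5
DEFAULT_AGREEMENT = 0.8
DEFAULT_MERGE_MAX_DIST = 2
DEFAULT_MERGE_MAX_READS = 6


@dataclass
class ConsensusCall:
    primary_barcode: str
    status: str  # "accepted" or "rejected"
    reason: str = ""
    coding_sequence: str = ""
    nt_mutations: tuple[tuple[int, str, str], ...] = ()
    aa_mutations: tuple[tuple[int, str, str], ...] = ()

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"


@dataclass
class GateCountRecord:
    primary: str
    secondary: str
    sorter: str
    raw_reads: np.ndarray  # length 8
    normalized_cells: np.ndarray | None = None

    def total_reads(self) -> int:
        return int(self.raw_reads.sum())


def _column_consensus(seqs: list[str], agreement: float) -> str | None:
    """Per-position majority consensus; None if any position < agreement."""
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        return None
    arr = np.array([list(s) for s in seqs])
    out = []
    n = len(seqs)
    for j in range(length):
        counts = Counter(arr[:, j])
        base, top = counts.most_common(1)[0]
        if top / n < agreement:
            return None
        out.append(base)
    return "".join(out)


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -5
    al.extend_gap_score = -1
    al.end_gap_score = 0  # end-free global alignment
    return al


def call_genotypes(
    half_reads: pd.DataFrame,
    wildtype_cds: str,
    expected_motif: str,
    min_reads: int = DEFAULT_MIN_READS,
    agreement: float = DEFAULT_AGREEMENT,
    drop_log: dict | None = None,
) -> list[ConsensusCall]:
    """Consensus genotype call per primary barcode from paired half reads.

    ``half_reads`` columns: barcode, half (N|C), strand (+|-), motif, seq.
    Reads whose motif differs from ``expected_motif`` are dropped first.
    The wildtype coding sequence includes the stop codon; mutations are
    reported at nucleotide and amino-acid level with 1-based positions.
    """
    log = drop_log if drop_log is not None else {}
    log.setdefault("reads_no_motif", 0)

    ok = half_reads["motif"] == expected_motif
    log["reads_no_motif"] += int((~ok).sum())
    reads = half_reads[ok]

    wt_coding = wildtype_cds[:-3]
    aligner = _aligner()
    calls: list[ConsensusCall] = []

    for barcode, grp in reads.groupby("barcode", sort=True):
        call = _call_one(barcode, grp, wt_coding, wildtype_cds, aligner, min_reads, agreement)
        calls.append(call)
        key = f"barcodes_{call.reason or 'accepted'}"
        log[key] = log.get(key, 0) + 1
    return calls


def _call_one(barcode, grp, wt_coding, wildtype_cds, aligner, min_reads, agreement):
    halves = {}
    for half in ("N", "C"):
        sub = grp[grp["half"] == half]
        if len(sub) < min_reads:
            return ConsensusCall(barcode, "rejected", "insufficient_reads")
        strand_consensi = []
        for strand in ("+", "-"):
            seqs = list(sub[sub["strand"] == strand]["seq"])
            if strand == "-":
                seqs = [str(Seq(s).reverse_complement()) for s in seqs]
            if not seqs:
                continue
            cons = _column_consensus(seqs, agreement)
            if cons is None:
                return ConsensusCall(barcode, "rejected", "low_agreement")
            strand_consensi.append(cons)
        if len(strand_consensi) == 2 and strand_consensi[0] != strand_consensi[1]:
            return ConsensusCall(barcode, "rejected", "strand_conflict")
        halves[half] = strand_consensi[0]

    n_half, c_half = halves["N"], halves["C"]
    ov = len(n_half) + len(c_half) - len(wt_coding)
    if ov < 1:
        return ConsensusCall(barcode, "rejected", "no_overlap")
    if n_half[-ov:] != c_half[:ov]:
        return ConsensusCall(barcode, "rejected", "overlap_mismatch")
    full = n_half + c_half[ov:]

    if len(full) == len(wt_coding):
        pairs = [(i + 1, r, a) for i, (r, a) in enumerate(zip(wt_coding, full)) if r != a]
    else:
        aln = aligner.align(wt_coding, full)[0]
        ref, alt = str(aln[0]), str(aln[1])
        if "-" in ref or "-" in alt:
            return ConsensusCall(barcode, "rejected", "indel")
        pairs = [(i + 1, r, a) for i, (r, a) in enumerate(zip(ref, alt)) if r != a]

    wt_protein = str(Seq(wt_coding).translate())
    protein = str(Seq(full).translate())
    aa_pairs = tuple(
        (s, wt_protein[s - 1], a) for s, a in sorted(mutations_between(wt_protein, protein))
    )
    return ConsensusCall(
        barcode,
        "accepted",
        coding_sequence=full + wildtype_cds[-3:],
        nt_mutations=tuple(pairs),
        aa_mutations=aa_pairs,
    )


def count_gate_reads(
    reads: pd.DataFrame,
    constant_motif: str,
    drop_log: dict | None = None,
) -> list[GateCountRecord]:
    """Tally gate reads per (primary, secondary, sorter).

    ``reads`` columns: seq (20-nt primary + 10-nt constant + 10-nt secondary),
    sorter, gate (1..8), and optionally n (read multiplicity, default 1).
    Reads lacking the constant motif, or of the wrong length, are dropped and
    counted in the log.
    """
    log = drop_log if drop_log is not None else {}
    df = reads.copy()
    if "n" not in df.columns:
        df["n"] = 1

    right_len = df["seq"].str.len() == 40
    log["reads_malformed"] = int(df.loc[~right_len, "n"].sum())
    df = df[right_len]
    has_motif = df["seq"].str.slice(20, 30) == constant_motif
    log["reads_no_motif"] = int(df.loc[~has_motif, "n"].sum())
    df = df[has_motif]

    df = df.assign(primary=df["seq"].str.slice(0, 20), secondary=df["seq"].str.slice(30, 40))
    counts = (
        df.groupby(["primary", "secondary", "sorter", "gate"], sort=True)["n"].sum().reset_index()
    )
    records: list[GateCountRecord] = []
    for (pb, sb, sorter), grp in counts.groupby(["primary", "secondary", "sorter"], sort=True):
        vec = np.zeros(8, dtype=np.int64)
        vec[grp["gate"].to_numpy() - 1] = grp["n"].to_numpy()
        records.append(GateCountRecord(pb, sb, sorter, vec))
    log["reads_assigned"] = int(sum(r.total_reads() for r in records))
    return records


def _hamming_str(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def merge_secondary_barcodes(
    records: list[GateCountRecord],
    max_reads: int = DEFAULT_MERGE_MAX_READS,
    max_dist: int = DEFAULT_MERGE_MAX_DIST,
) -> list[GateCountRecord]:
    """Absorb likely sequencing-error secondaries into abundant ones.

    Within each (primary, sorter) group, a secondary with fewer than
    ``max_reads`` total reads that differs by at most ``max_dist`` nucleotides
    from a more abundant secondary of the same primary is merged into it
    (read vectors added).  Applied iteratively until stable; candidates are
    processed in ascending read count, ties broken lexicographically.
    """
    out: list[GateCountRecord] = []
    groups: dict[tuple[str, str], dict[str, np.ndarray]] = defaultdict(dict)
    for r in records:
        groups[(r.primary, r.sorter)][r.secondary] = r.raw_reads.copy()

    for (pb, sorter), by_sec in sorted(groups.items()):
        changed = True
        while changed:
            changed = False
            totals = {sb: int(v.sum()) for sb, v in by_sec.items()}
            candidates = sorted(
                (sb for sb, t in totals.items() if t < max_reads),
                key=lambda sb: (totals[sb], sb),
            )
            for sb in candidates:
                partners = [
                    other
                    for other in by_sec
                    if other != sb
                    and totals[other] > totals[sb]
                    and _hamming_str(other, sb) <= max_dist
                ]
                if not partners:
                    continue
                target = max(partners, key=lambda o: (totals[o], o))
                by_sec[target] = by_sec[target] + by_sec[sb]
                del by_sec[sb]
                changed = True
                break
        for sb in sorted(by_sec):
            out.append(GateCountRecord(pb, sb, sorter, by_sec[sb]))
    return out


def normalize_by_count_controls(
    records: list[GateCountRecord],
    control_barcodes: set[str] | list[str],
    cells_per_control: float = 5000.0,
) -> list[GateCountRecord]:
    """Convert per-gate read counts to cell counts via the spike-in controls.

    For each (sorter, gate), ``normalized_cells = raw_reads * cells_per_control
    / mean(control reads in that gate)``.  A gate whose controls received no
    reads leaves the normalization undefined and raises.
    """
    controls = set(control_barcodes)
    means: dict[str, np.ndarray] = {}
    for sorter in sorted({r.sorter for r in records}):
        ctrl = [r.raw_reads for r in records if r.sorter == sorter and r.primary in controls]
        if not ctrl:
            raise ValueError(f"no count-control records for sorter {sorter}")
        mean = np.mean(ctrl, axis=0)
        if np.any(mean == 0):
            bad = int(np.flatnonzero(mean == 0)[0]) + 1
            raise ValueError(
                f"gate {bad} on sorter {sorter} has zero count-control reads; "
                "normalization undefined"
            )
        means[sorter] = mean

    out = []
    for r in records:
        cells = r.raw_reads * cells_per_control / means[r.sorter]
        out.append(GateCountRecord(r.primary, r.secondary, r.sorter, r.raw_reads.copy(), cells))
    return out
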