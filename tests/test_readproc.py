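"""Consensus calling, gate counting, secondary merging, count normalization."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from landscape_forge.readproc import (
    GateCountRecord,
    call_genotypes,
    count_gate_reads,
    merge_secondary_barcodes,
    normalize_by_count_controls,
)
from landscape_forge.simulate import (
    HISEQ_CONSTANT,
    MISEQ_CONSTANT,
    LibrarySpec,
    generate_library,
    simulate_coding_reads,
)


def make_half_reads(barcode, coding, n_fwd=5, n_rev=5, overlap=30):
    cut = len(coding) // 2
    n_half = coding[: cut + overlap // 2]
    c_half = coding[cut - (overlap - overlap // 2) :]
    rows = []
    for half, template in (("N", n_half), ("C", c_half)):
        for _ in range(n_fwd):
            rows.append((barcode, half, "+", MISEQ_CONSTANT, template))
        rc = str(Seq(template).reverse_complement())
        for _ in range(n_rev):
            rows.append((barcode, half, "-", MISEQ_CONSTANT, rc))
    return pd.DataFrame(rows, columns=["barcode", "half", "strand", "motif", "seq"])


class TestCallGenotypes:
    def test_error_free_reads_recover_generator_truth(self, flat_landscape):
        spec = LibrarySpec(n_genotypes=15, seed=3)
        lib = generate_library(flat_landscape, spec)
        reads = simulate_coding_reads(lib, per_base_error_rate=0.0, reads_per_half=10, seed=1)
        calls = call_genotypes(reads, flat_landscape.wildtype_cds, MISEQ_CONSTANT)
        by_bc = {c.primary_barcode: c for c in calls}
        for m in lib:
            call = by_bc[m.primary_barcode]
            assert call.accepted
            assert call.coding_sequence == m.cds
            called = frozenset((s, a) for s, _, a in call.aa_mutations)
            assert called == m.mutations

    def test_noisy_reads_accepted_calls_are_correct(self, flat_landscape):
        """Errors may trigger conservative rejections, never wrong calls."""
        spec = LibrarySpec(n_genotypes=10, seed=4)
        lib = generate_library(flat_landscape, spec)
        truth = {m.primary_barcode: m.cds for m in lib}
        reads = simulate_coding_reads(lib, per_base_error_rate=0.01, reads_per_half=20, seed=2)
        calls = call_genotypes(reads, flat_landscape.wildtype_cds, MISEQ_CONSTANT)
        accepted = [c for c in calls if c.accepted]
        assert accepted
        assert all(c.coding_sequence == truth[c.primary_barcode] for c in accepted)

    def test_deep_noisy_reads_recover_most_barcodes(self, flat_landscape):
        spec = LibrarySpec(n_genotypes=10, n_wildtype_controls=0, reference_levels=(), seed=4)
        lib = generate_library(flat_landscape, spec)
        reads = simulate_coding_reads(lib, per_base_error_rate=0.005, reads_per_half=30, seed=2)
        calls = call_genotypes(reads, flat_landscape.wildtype_cds, MISEQ_CONSTANT)
        by_bc = {c.primary_barcode: c for c in calls}
        recovered = [
            by_bc[m.primary_barcode].accepted
            and by_bc[m.primary_barcode].coding_sequence == m.cds
            for m in lib
        ]
        assert np.mean(recovered) >= 0.9

    def test_too_few_reads_in_one_half_rejected(self, flat_landscape):
        coding = flat_landscape.wildtype_cds[:-3]
        reads = pd.concat(
            [
                make_half_reads("X" * 20, coding, n_fwd=2, n_rev=2).query("half == 'N'"),
                make_half_reads("X" * 20, coding, n_fwd=5, n_rev=5).query("half == 'C'"),
            ]
        )
        (call,) = call_genotypes(reads, flat_landscape.wildtype_cds, MISEQ_CONSTANT)
        assert call.status == "rejected" and call.reason == "insufficient_reads"

    def test_seventy_percent_agreement_rejected(self, flat_landscape):
        # one N-half position split 7/3 between two bases: 70% < 80% rule
        coding = flat_landscape.wildtype_cds[:-3]
        reads = make_half_reads("X" * 20, coding, n_fwd=10, n_rev=0)
        n_rows = reads.index[(reads["half"] == "N")].tolist()
        for i in n_rows[:3]:
            s = reads.loc[i, "seq"]
            alt = "A" if s[4] != "A" else "G"
            reads.loc[i, "seq"] = s[:4] + alt + s[5:]
        (call,) = call_genotypes(reads, flat_landscape.wildtype_cds, MISEQ_CONSTANT)
        assert call.status == "rejected" and call.reason == "low_agreement"

    def test_overlap_mismatch_rejected(self, flat_landscape):
        # mutate the overlap region in all C-half reads only
        coding = flat_landscape.wildtype_cds[:-3]
        reads = make_half_reads("X" * 20, coding, n_fwd=5, n_rev=0)
        c_rows = reads.index[reads["half"] == "C"].tolist()
        for i in c_rows:
            s = reads.loc[i, "seq"]
            alt = "A" if s[2] != "A" else "G"
            reads.loc[i, "seq"] = s[:2] + alt + s[3:]
        (call,) = call_genotypes(reads, flat_landscape.wildtype_cds, MISEQ_CONSTANT)
        assert call.status == "rejected" and call.reason == "overlap_mismatch"

    def test_forward_reverse_conflict_rejected(self, flat_landscape):
        # consistent within each strand, conflicting between strands
        coding = flat_landscape.wildtype_cds[:-3]
        reads = make_half_reads("X" * 20, coding, n_fwd=5, n_rev=5)
        rows = reads.index[(reads["half"] == "N") & (reads["strand"] == "+")]
        for i in rows:
            s = reads.loc[i, "seq"]
            alt = "A" if s[10] != "A" else "G"
            reads.loc[i, "seq"] = s[:10] + alt + s[11:]
        (call,) = call_genotypes(reads, flat_landscape.wildtype_cds, MISEQ_CONSTANT)
        assert call.status == "rejected" and call.reason == "strand_conflict"

    def test_motifless_reads_dropped_and_logged(self, flat_landscape):
        coding = flat_landscape.wildtype_cds[:-3]
        reads = make_half_reads("X" * 20, coding)
        reads.loc[reads.index[:4], "motif"] = "TTTTTTTTTT"
        log = {}
        call_genotypes(reads, flat_landscape.wildtype_cds, MISEQ_CONSTANT, drop_log=log)
        assert log["reads_no_motif"] == 4


def rec(pb, sb, sorter, vec):
    return GateCountRecord(pb, sb, sorter, np.array(vec, dtype=np.int64))


class TestCountGateReads:
    def _reads(self, rows):
        return pd.DataFrame(rows, columns=["seq", "sorter", "gate", "n"])

    def test_motifless_reads_excluded(self):
        pb, sb = "A" * 20, "C" * 10
        rows = [
            (pb + HISEQ_CONSTANT + sb, "A", 3, 5),
            (pb + "T" * 10 + sb, "A", 3, 7),
        ]
        log = {}
        records = count_gate_reads(self._reads(rows), HISEQ_CONSTANT, drop_log=log)
        assert len(records) == 1 and records[0].total_reads() == 5
        assert log["reads_no_motif"] == 7

    def test_gate_tally_positions(self):
        pb, sb = "A" * 20, "C" * 10
        rows = [
            (pb + HISEQ_CONSTANT + sb, "A", 3, 1),
            (pb + HISEQ_CONSTANT + sb, "A", 5, 1),
        ]
        (record,) = count_gate_reads(self._reads(rows), HISEQ_CONSTANT)
        expected = np.zeros(8, dtype=int)
        expected[[2, 4]] = 1
        assert np.array_equal(record.raw_reads, expected)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        pbs = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(5)]
        rows = [
            (pb + HISEQ_CONSTANT + "G" * 10, s, g, int(n))
            for pb in pbs
            for s, g, n in [("A", 1, 3), ("B", 4, 2), ("A", 8, 1)]
        ]
        a = count_gate_reads(self._reads(rows), HISEQ_CONSTANT)
        b = count_gate_reads(self._reads(rows[::-1]), HISEQ_CONSTANT)
        assert [(r.primary, r.secondary, r.sorter, tuple(r.raw_reads)) for r in a] == [
            (r.primary, r.secondary, r.sorter, tuple(r.raw_reads)) for r in b
        ]


class TestMergeSecondaries:
    def test_low_count_near_neighbor_merged(self):
        abundant = "AAAAAAAAAA"
        noisy = "AAAAAAAATT"  # distance 2, 5 reads
        records = [
            rec("P" * 20, abundant, "A", [100, 0, 0, 0, 0, 0, 0, 0]),
            rec("P" * 20, noisy, "A", [5, 0, 0, 0, 0, 0, 0, 0]),
        ]
        merged = merge_secondary_barcodes(records)
        assert len(merged) == 1
        assert merged[0].secondary == abundant
        assert merged[0].total_reads() == 105

    def test_six_reads_not_merged(self):
        records = [
            rec("P" * 20, "AAAAAAAAAA", "A", [100, 0, 0, 0, 0, 0, 0, 0]),
            rec("P" * 20, "AAAAAAAAAT", "A", [6, 0, 0, 0, 0, 0, 0, 0]),
        ]
        assert len(merge_secondary_barcodes(records)) == 2

    def test_distance_three_not_merged(self):
        records = [
            rec("P" * 20, "AAAAAAAAAA", "A", [100, 0, 0, 0, 0, 0, 0, 0]),
            rec("P" * 20, "AAAAAAATTT", "A", [5, 0, 0, 0, 0, 0, 0, 0]),
        ]
        assert len(merge_secondary_barcodes(records)) == 2

    def test_chain_absorption_conserves_reads(self):
        pb = "P" * 20
        records = [
            rec(pb, "AAAAAAAAAA", "A", [50, 50, 0, 0, 0, 0, 0, 0]),
            rec(pb, "AAAAAAAAAT", "A", [3, 0, 0, 0, 0, 0, 0, 0]),
            rec(pb, "AAAAAAAATC", "A", [0, 2, 0, 0, 0, 0, 0, 0]),
        ]
        merged = merge_secondary_barcodes(records)
        assert len(merged) == 1
        assert merged[0].total_reads() == 105
        assert np.array_equal(merged[0].raw_reads[:2], [53, 52])

    def test_primaries_and_totals_preserved(self, flat_landscape):
        rng = np.random.default_rng(1)
        records = []
        for i in range(4):
            pb = "".join(rng.choice(list("ACGT"), 20))
            for j in range(3):
                sb = "".join(rng.choice(list("ACGT"), 10))
                records.append(rec(pb, sb, "A", rng.integers(0, 30, size=8)))
        merged = merge_secondary_barcodes(records)
        assert {r.primary for r in merged} == {r.primary for r in records}
        before = {}
        for r in records:
            before[r.primary] = before.get(r.primary, 0) + r.total_reads()
        after = {}
        for r in merged:
            after[r.primary] = after.get(r.primary, 0) + r.total_reads()
        assert before == after


class TestNormalization:
    def test_direct_ratio(self):
        ctrl = rec("C" * 20, "A" * 10, "A", [50] * 8)
        sample = rec("S" * 20, "T" * 10, "A", [0, 10, 0, 0, 0, 0, 0, 0])
        out = normalize_by_count_controls([ctrl, sample], {"C" * 20}, cells_per_control=5000)
        sample_out = [r for r in out if r.primary == "S" * 20][0]
        assert sample_out.normalized_cells[1] == pytest.approx(1000.0)

    def test_uniform_controls_are_global_scale(self):
        ctrl = rec("C" * 20, "A" * 10, "A", [25] * 8)
        sample = rec("S" * 20, "T" * 10, "A", [1, 2, 3, 4, 5, 6, 7, 8])
        out = normalize_by_count_controls([ctrl, sample], {"C" * 20}, 5000)
        sample_out = [r for r in out if r.primary == "S" * 20][0]
        assert np.allclose(sample_out.normalized_cells, sample_out.raw_reads * 200.0)

    def test_zero_control_gate_raises(self):
        ctrl = rec("C" * 20, "A" * 10, "A", [50] * 7 + [0])
        sample = rec("S" * 20, "T" * 10, "A", [1] * 8)
        with pytest.raises(ValueError, match="gate 8"):
            normalize_by_count_controls([ctrl, sample], {"C" * 20}, 5000)

    def test_recovered_cells_close_to_truth(self, flat_landscape):
        from landscape_forge.simulate import simulate_sort

        spec = LibrarySpec(
            n_genotypes=40,
            mean_barcode_replicates=3,
            cells_per_replicate_mean=150,
            barcode_error_rate=0.0,
            seed=5,
        )
        lib = generate_library(flat_landscape, spec)
        exp = simulate_sort(lib, flat_landscape, spec)
        records = count_gate_reads(exp.reads, HISEQ_CONSTANT)
        records = normalize_by_count_controls(
            records, exp.control_barcodes, spec.count_control_cells
        )
        est = {}
        for r in records:
            key = (r.primary, r.secondary, r.sorter)
            est[key] = r.normalized_cells.sum()
        truth = exp.replicate_truth
        rel_errs = []
        for row in truth.itertuples():
            if row.cells >= 100:
                e = est.get((row.primary, row.secondary, row.sorter), 0.0)
                rel_errs.append(abs(e - row.cells) / row.cells)
        assert rel_errs and np.median(rel_errs) < 0.1
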