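"""k-mer spectrum, genome-size estimation, repeat masking/GP and PAV calls."""

import numpy as np
import pytest

from wgdkit import simgenome as sg
from wgdkit._codon import revcomp
from wgdkit.wgsquant import (
    KmerHistogram,
    call_presence,
    cds_breadth,
    cds_breadth_from_sam,
    estimate_genome_size,
    genome_proportion,
    kmer_histogram,
    map_reads_to_cds,
    mask_reads,
    repeat_amount,
)


class TestKmerHistogram:
    def test_occurrence_count(self):
        hist = kmer_histogram(["ACGTACGT"], k=5)
        # L - k + 1 = 4 k-mer occurrences
        assert hist.total_kmers == 4

    def test_canonicalisation_doubles_counts(self):
        read = "ACGGTAGCATCGGATC"
        h1 = kmer_histogram([read], k=7)
        h2 = kmer_histogram([read, revcomp(read)], k=7)
        assert h2.total_kmers == 2 * h1.total_kmers
        assert set(h2.counts) == {2 * c for c in h1.counts}

    def test_k_longer_than_read_rejected(self):
        with pytest.raises(ValueError):
            kmer_histogram(["A" * 23], k=25)

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            kmer_histogram(["ACGTACGTACGT"], k=4)


class TestGenomeSize:
    def test_point_mass_formula(self):
        hist = KmerHistogram(23, {50: 100_000})
        est = estimate_genome_size(hist)
        assert est.peak_depth == 50
        assert est.size_bp == pytest.approx(100_000, rel=0.001)

    def test_error_tail_excluded(self):
        counts = {1: 10**6, 2: 1000, 30: 50_000, 31: 48_000, 29: 47_000}
        est = estimate_genome_size(KmerHistogram(23, counts))
        assert est.excluded_error_depth >= 1
        assert est.peak_depth in (29, 30, 31)

    def test_simulated_recovery_within_5pct(self):
        genome = sg.simulate_ancestral_genome(1, 60, 300, 500, seed=9)
        reads = sg.simulate_reads(genome, coverage=30, read_len=100, seed=10)
        est = estimate_genome_size(kmer_histogram(reads, k=23))
        assert est.size_bp == pytest.approx(genome.total_length, rel=0.05)

    def test_coverage_invariance(self):
        genome = sg.simulate_ancestral_genome(1, 40, 300, 500, seed=11)
        e1 = estimate_genome_size(
            kmer_histogram(sg.simulate_reads(genome, 25, 100, seed=12), k=23)
        )
        e2 = estimate_genome_size(
            kmer_histogram(sg.simulate_reads(genome, 50, 100, seed=13), k=23)
        )
        assert e1.size_bp == pytest.approx(e2.size_bp, rel=0.05)


class TestGPFormulas:
    def test_gp_exact(self):
        assert genome_proportion(25, 100) == 25.0
        assert genome_proportion(0, 10**6) == 0.0
        assert genome_proportion(10**6, 10**6) == 100.0

    def test_gp_preconditions(self):
        with pytest.raises(ValueError):
            genome_proportion(1, 0)
        with pytest.raises(ValueError):
            genome_proportion(2, 1)

    def test_repeat_amount(self):
        assert repeat_amount(30.0, 3.6e9) == pytest.approx(1.08e9)
        assert repeat_amount(0.0, 1e9) == 0.0
        assert repeat_amount(20.0, 2e9) == 2 * repeat_amount(20.0, 1e9)


class TestMaskReads:
    def test_reads_from_consensus_fully_masked(self, rng):
        cons = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        reads = [cons[i : i + 100] for i in range(0, 1900, 50)]
        masked, total = mask_reads(reads, {"FAM": cons}, match_k=17)
        assert masked["FAM"] / total > 0.99

    def test_repeat_free_reads_unmasked(self, rng):
        cons = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
        other = "".join("ACGT"[i] for i in rng.integers(0, 4, 5000))
        reads = [other[i : i + 100] for i in range(0, 4900, 100)]
        masked, _ = mask_reads(reads, {"FAM": cons}, match_k=17)
        assert masked["FAM"] == 0

    def test_longer_run_wins_overlap(self, rng):
        shared = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        tail = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        fam_long = shared + tail  # read matches over 260 bp
        fam_short = shared  # matches only the first 60 bp
        read = shared + tail
        masked, _ = mask_reads(read and [read], {"L": fam_long, "S": fam_short}, match_k=17)
        assert masked["L"] == len(read)
        assert masked["S"] == 0

    def test_simulated_gp_recovery(self, rng):
        genome = sg.simulate_ancestral_genome(1, 60, 300, 500, seed=21)
        cons = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        with_reps, truth = sg.insert_repeats(genome, {"FAM": (cons, 0.2)}, seed=22)
        reads = sg.simulate_reads(with_reps, coverage=10, read_len=100, seed=23)
        masked, total = mask_reads(reads, {"FAM": cons}, match_k=17)
        gp = genome_proportion(masked["FAM"], total)
        assert gp == pytest.approx(truth.repeat_gp["FAM"] * 100, abs=2.0)

    def test_gp_additivity_bound(self, rng):
        genome = sg.simulate_ancestral_genome(1, 30, 300, 500, seed=24)
        fams = {
            "FA": "".join("ACGT"[i] for i in rng.integers(0, 4, 800)),
            "FB": "".join("ACGT"[i] for i in rng.integers(0, 4, 800)),
        }
        with_reps, _ = sg.insert_repeats(
            genome, {f: (c, 0.15) for f, c in fams.items()}, seed=25
        )
        reads = sg.simulate_reads(with_reps, 5, 100, seed=26)
        masked, total = mask_reads(reads, fams, match_k=17)
        assert sum(genome_proportion(m, total) for m in masked.values()) <= 100.0


class TestBreadthAndPresence:
    def test_interval_union_semantics(self):
        cds = {"g": "A" * 300}
        calls = cds_breadth({"g": [(50, 150), (100, 200)]}, cds)
        assert calls[0].covered_bp == 150
        assert calls[0].breadth == pytest.approx(0.5)

    def test_no_reads_zero_breadth(self):
        calls = cds_breadth({}, {"g": "A" * 100})
        assert calls[0].breadth == 0.0

    def test_presence_boundary_rule(self):
        calls = cds_breadth({"g": [(0, 50)]}, {"g": "A" * 100})
        present = call_presence(calls, threshold=0.5)
        assert present[0].call == "present"  # breadth 0.5 >= 0.5
        absent = call_presence(calls, threshold=0.51)
        assert absent[0].call == "absent"

    def test_builtin_mapper_places_exact_reads(self, rng):
        genome = sg.simulate_ancestral_genome(1, 20, 300, 400, seed=31)
        cds = {g.gene_id: g.cds for g in genome.genes}
        reads = sg.simulate_reads(genome, 8, 100, seed=32)
        hits = map_reads_to_cds(reads, cds)
        calls = call_presence(cds_breadth(hits, cds), threshold=0.5)
        assert all(c.call == "present" for c in calls)

    def test_sam_route_matches_builtin(self, tmp_path):
        cds = {"gene1": "ACGTACGTAA" * 30}
        sam = tmp_path / "aln.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:gene1\tLN:300\n"
            "r1\t0\tgene1\t1\t60\t100M\t*\t0\t0\t" + "A" * 100 + "\t*\n"
            "r2\t0\tgene1\t151\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t*\n"
            "r3\t4\t*\t0\t0\t*\t*\t0\t0\t" + "A" * 50 + "\t*\n"
        )
        calls = cds_breadth_from_sam(str(sam), cds)
        assert calls[0].covered_bp == 150
        assert calls[0].breadth == pytest.approx(0.5)


class TestPavRecovery:
    def test_diploid_vs_tetraploid_accuracy(self):
        """Genes deleted from one library are called absent there and present
        in the other, >=98% accuracy at 10x and breadth threshold 0.5."""
        genome = sg.simulate_ancestral_genome(1, 80, 300, 400, seed=41)
        rng = np.random.default_rng(42)
        victims = set(
            np.random.default_rng(42).choice(
                [g.gene_id for g in genome.genes], size=25, replace=False
            )
        )
        reduced = sg.delete_genes(genome, victims)
        cds = {g.gene_id: g.cds for g in genome.genes}
        correct = total = 0
        for lib_genome, absent in ((genome, set()), (reduced, victims)):
            reads = sg.simulate_reads(lib_genome, 10, 100, seed=43)
            calls = call_presence(
                cds_breadth(map_reads_to_cds(reads, cds), cds), threshold=0.5
            )
            for c in calls:
                expected = "absent" if c.gene_id in absent else "present"
                correct += c.call == expected
                total += 1
        assert correct / total >= 0.98
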