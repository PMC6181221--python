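"""Simulator contracts: construction, determinism, conservation, divergence."""

import numpy as np
import pytest

from wgdkit import simgenome as sg
from wgdkit._codon import revcomp
from wgdkit.pipeline import ks_for_pairs


def _genome_bytes(genome):
    fa = "".join(f">{sid}\n{seq}\n" for sid, seq in genome.scaffolds)
    rows = [
        (g.scaffold_id, g.gene_id, g.start, g.end, g.strand, g.cds)
        for g in genome.genes
    ]
    return fa, tuple(rows)


class TestAncestralGenome:
    def test_construction_contract(self):
        g = sg.simulate_ancestral_genome(2, 50, 300, 500, seed=1)
        assert len(g.genes) == 100
        assert len(g.scaffolds) == 2
        g.validate()  # coordinates, non-overlap, stop-free CDS, frame

    @pytest.mark.parametrize("bad", [(0, 10), (2, 0), (-1, 5)])
    def test_nonpositive_counts_rejected(self, bad):
        with pytest.raises(ValueError):
            sg.simulate_ancestral_genome(bad[0], bad[1], 300, 500, seed=1)

    def test_seed_determinism(self):
        a = sg.simulate_ancestral_genome(2, 20, 300, 500, seed=7)
        b = sg.simulate_ancestral_genome(2, 20, 300, 500, seed=7)
        assert _genome_bytes(a) == _genome_bytes(b)
        c = sg.simulate_ancestral_genome(2, 20, 300, 500, seed=8)
        assert _genome_bytes(a) != _genome_bytes(c)


class TestWgd:
    def test_zero_divergence_full_retention(self, ancestor):
        t, truth = sg.apply_wgd(ancestor, target_ks=0.0, retention=1.0, seed=1)
        assert len(t.genes) == 2 * len(ancestor.genes)
        cds = {g.gene_id: g.cds for g in t.genes}
        for a, b, _ in truth.duplicate_pairs:
            assert cds[a] == cds[b]

    def test_zero_retention(self, ancestor):
        t, truth = sg.apply_wgd(ancestor, target_ks=0.1, retention=0.0, seed=1)
        assert len(t.genes) == len(ancestor.genes)
        assert truth.duplicate_pairs == []

    def test_saturation_refused(self, ancestor):
        with pytest.raises(ValueError, match="saturation"):
            sg.apply_wgd(ancestor, target_ks=3.5, seed=1)

    def test_genome_remains_valid(self, tetraploid_with_truth):
        t, _ = tetraploid_with_truth
        t.validate()

    @pytest.mark.parametrize("target", [0.02, 0.05, 0.2, 0.5])
    def test_ks_round_trip(self, target):
        """NG86 on truth pairs recovers the requested divergence (3 SE)."""
        g = sg.simulate_ancestral_genome(1, 210, 300, 60, seed=31)
        t, truth = sg.apply_wgd(g, target_ks=target, ka_ks_ratio=0.0, retention=1.0, seed=32)
        results, _cov = ks_for_pairs(t, [(a, b) for a, b, _ in truth.duplicate_pairs])
        ks = np.array([r.Ks for r in results if r.status == "ok"])
        assert len(ks) >= 200
        se = ks.std(ddof=1) / np.sqrt(len(ks))
        assert abs(ks.mean() - target) < 3 * se + 1e-9

    def test_mean_ks_within_15pct_at_005(self):
        g = sg.simulate_ancestral_genome(1, 210, 300, 60, seed=41)
        t, truth = sg.apply_wgd(g, target_ks=0.05, ka_ks_ratio=0.3, retention=1.0, seed=42)
        results, _ = ks_for_pairs(t, [(a, b) for a, b, _ in truth.duplicate_pairs])
        ks = np.array([r.Ks for r in results if r.status == "ok"])
        assert abs(ks.mean() - 0.05) / 0.05 < 0.15

    def test_ka_centres_on_zero_when_ratio_zero(self):
        g = sg.simulate_ancestral_genome(1, 200, 300, 60, seed=51)
        t, truth = sg.apply_wgd(g, target_ks=0.1, ka_ks_ratio=0.0, retention=1.0, seed=52)
        results, _ = ks_for_pairs(t, [(a, b) for a, b, _ in truth.duplicate_pairs])
        ka = np.array([r.Ka for r in results if r.status == "ok"])
        # pathway averaging across double-hit codons can yield a whisper of
        # apparent Ka even without nonsynonymous events; it must be tiny
        assert 0.0 <= ka.mean() < 0.002
        assert np.median(ka) == 0.0


class TestFragmentation:
    def test_zero_breaks_identity(self, ancestor):
        f, truth = sg.fragment_into_scaffolds(ancestor, 0, seed=1)
        assert [s for s, _ in f.scaffolds] == [s for s, _ in ancestor.scaffolds]
        assert truth.adjacency == []

    def test_break_counts_and_conservation(self, ancestor):
        f, truth = sg.fragment_into_scaffolds(ancestor, 3, min_fragment=100, seed=2)
        assert len(f.scaffolds) == len(ancestor.scaffolds) * 4
        assert len(truth.adjacency) == len(ancestor.scaffolds) * 3
        assert f.total_length == ancestor.total_length
        f.validate()  # no gene split or damaged

    def test_cds_conserved(self, ancestor):
        f, _ = sg.fragment_into_scaffolds(ancestor, 5, seed=3)
        before = {g.gene_id: g.cds for g in ancestor.genes}
        after = {g.gene_id: g.cds for g in f.genes}
        assert before == after

    def test_too_many_breaks_names_chromosome(self, ancestor):
        with pytest.raises(ValueError, match="chr1"):
            sg.fragment_into_scaffolds(ancestor, 1000, seed=4)


class TestRepeats:
    def _consensus(self, rng, n=800):
        return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])

    def test_target_gp_realised(self, ancestor, rng):
        cons = self._consensus(rng)
        out, truth = sg.insert_repeats(ancestor, {"FAM": (cons, 0.10)}, seed=5)
        assert truth.repeat_gp["FAM"] == pytest.approx(0.10, abs=0.005)
        out.validate()

    def test_zero_gp_identity(self, ancestor):
        out, truth = sg.insert_repeats(ancestor, {"FAM": ("A" * 100, 0.0)}, seed=6)
        assert out.scaffolds == ancestor.scaffolds
        assert truth.repeat_gp == {}

    def test_two_families_additive(self, ancestor, rng):
        fams = {
            "FA": (self._consensus(rng), 0.2),
            "FB": (self._consensus(rng), 0.1),
        }
        _, truth = sg.insert_repeats(ancestor, fams, seed=7)
        assert sum(truth.repeat_gp.values()) == pytest.approx(0.3, abs=0.01)

    def test_cds_conserved(self, ancestor, rng):
        out, _ = sg.insert_repeats(ancestor, {"F": (self._consensus(rng), 0.15)}, seed=8)
        assert {g.gene_id: g.cds for g in out.genes} == {
            g.gene_id: g.cds for g in ancestor.genes
        }

    def test_infeasible_packing_rejected(self, ancestor, rng):
        with pytest.raises(ValueError):
            sg.insert_repeats(ancestor, {"F": (self._consensus(rng), 0.95)}, seed=9)


class TestReads:
    def test_read_count_arithmetic(self, ancestor):
        reads = sg.simulate_reads(ancestor, coverage=2.0, read_len=100, seed=1)
        assert len(reads) == round(2.0 * ancestor.total_length / 100)

    def test_error_free_reads_are_substrings(self, ancestor):
        reads = sg.simulate_reads(ancestor, coverage=0.2, read_len=80, error_rate=0.0, seed=2)
        seqs = [s for _, s in ancestor.scaffolds]
        for _rid, r in reads[:50]:
            assert any(r in s or revcomp(r) in s for s in seqs)

    def test_seed_determinism(self, ancestor):
        a = sg.simulate_reads(ancestor, 0.5, 100, 0.01, seed=3)
        b = sg.simulate_reads(ancestor, 0.5, 100, 0.01, seed=3)
        assert a == b

    def test_read_len_exceeding_scaffold_names_it(self):
        g = sg.simulate_ancestral_genome(1, 2, 300, 100, seed=5)
        with pytest.raises(ValueError, match="chr1"):
            sg.simulate_reads(g, 1.0, read_len=10**6, seed=1)

    def test_revcomp_genome_symmetry(self, ancestor):
        """Reads from the reverse-complemented genome are reverse complements
        of substrings of the forward genome."""
        rc = sg.AnnotatedGenome(
            [(sid, revcomp(seq)) for sid, seq in ancestor.scaffolds], [], "rc"
        )
        reads = sg.simulate_reads(rc, 0.1, 80, 0.0, seed=4)
        fwd = [s for _, s in ancestor.scaffolds]
        for _rid, r in reads[:30]:
            assert any(r in s or revcomp(r) in s for s in fwd)


class TestDeleteGenes:
    def test_deletion_removes_models_and_sequence(self, ancestor):
        victims = {g.gene_id for g in ancestor.genes[:5]}
        out = sg.delete_genes(ancestor, victims)
        assert {g.gene_id for g in out.genes} == {
            g.gene_id for g in ancestor.genes
        } - victims
        assert out.total_length < ancestor.total_length
        out.validate()
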