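import numpy as np
import pytest
from scipy import stats

from isbreach import (
    ImplantSpec,
    call_tsd,
    evaluate_detection,
    find_exact_copies,
    generate_locus,
    implant_elements,
)
from isbreach._seq import gc_fraction, matches_iupac, revcomp
from isbreach.synthetic_data import TruthRecord


class TestGenerateLocus:
    def test_eight_gene_operon_layout(self):
        seq, genes = generate_locus(8, (300, 3000), (50, 400), seed=1)
        assert len(genes) == 8
        for a, b in zip(genes, genes[1:]):
            assert a.end < b.start  # non-overlapping, ordered
        assert all(g.end <= len(seq) for g in genes)

    def test_seed_determinism(self):
        a = generate_locus(5, (300, 1000), (50, 200), seed=42)
        b = generate_locus(5, (300, 1000), (50, 200), seed=42)
        assert a[0] == b[0]
        assert [(g.start, g.end, g.strand) for g in a[1]] == [
            (g.start, g.end, g.strand) for g in b[1]
        ]

    def test_gc_within_binomial_bound(self):
        seq, _ = generate_locus(3, (30_000, 35_000), (100, 200), gc=0.5, seed=2)
        assert len(seq) >= 90_000
        assert abs(gc_fraction(seq) - 0.5) < 0.01

    def test_bad_ranges_rejected(self):
        with pytest.raises(ValueError):
            generate_locus(3, (0, 100), (50, 100))


class TestImplantElements:
    def test_length_conservation_single(self, catalog):
        seq, genes = generate_locus(4, (300, 1000), (50, 200), seed=3)
        spec = ImplantSpec("IS1x", 1, {9: 1.0}, seed=4)
        mutated, truth = implant_elements(seq, genes, catalog, spec)
        assert len(mutated) == len(seq) + 768 + 9
        t = truth[0]
        assert mutated[t.insertion_point : t.insertion_point + t.k] == t.tsd_sequence
        assert mutated[t.element_start + 768 : t.element_start + 768 + t.k] == t.tsd_sequence

    def test_truth_records_in_final_coordinates(self, catalog, is10_like):
        seq, genes = generate_locus(6, (500, 1500), (100, 300), seed=5)
        spec = ImplantSpec("IS10x", 8, {9: 1.0}, seed=6)
        mutated, truth = implant_elements(seq, genes, catalog, spec)
        assert len(mutated) == len(seq) + 8 * (1329 + 9)
        for t in truth:
            elem = mutated[t.element_start : t.element_start + 1329]
            expected = is10_like.sequence if t.strand == "+" else revcomp(is10_like.sequence)
            assert elem == expected
            # both TSD copies in place
            assert mutated[t.insertion_point : t.insertion_point + t.k] == t.tsd_sequence
            end = t.element_start + 1329
            assert mutated[end : end + t.k] == t.tsd_sequence

    def test_k_mixture_within_binomial_interval(self, catalog):
        """500 implants at P(9)=0.78 / P(8)=0.22, seed 11."""
        seq, genes = generate_locus(10, (2000, 4000), (200, 600), seed=10)
        spec = ImplantSpec("IS1x", 500, {9: 0.78, 8: 0.22}, seed=11)
        _, truth = implant_elements(seq, genes, catalog, spec)
        p9 = sum(t.k == 9 for t in truth) / len(truth)
        half_width = 1.96 * np.sqrt(0.78 * 0.22 / 500)
        assert abs(p9 - 0.78) <= half_width

    def test_site_motif_respected(self, catalog):
        seq, genes = generate_locus(4, (500, 1500), (100, 300), seed=12)
        spec = ImplantSpec("IS1x", 20, {4: 1.0}, site_motif="YTAR", seed=13)
        _, truth = implant_elements(seq, genes, catalog, spec)
        assert all(matches_iupac(t.tsd_sequence, "YTAR") for t in truth)

    def test_impossible_motif_errors(self, catalog):
        seq, genes = generate_locus(2, (300, 500), (50, 100), seed=14)
        # sequence generated over ACGT only; a pattern needing 8 consecutive
        # G's in a 1 kb locus will essentially never be found
        spec = ImplantSpec("IS1x", 1, {8: 1.0}, site_motif="GGGGGGGG", seed=15)
        with pytest.raises(ValueError, match="looser motif"):
            implant_elements(seq, genes, catalog, spec)

    def test_motif_length_mismatch_rejected(self, catalog):
        seq, genes = generate_locus(2, (300, 500), (50, 100), seed=16)
        spec = ImplantSpec("IS1x", 1, {9: 1.0}, site_motif="YTAR", seed=17)
        with pytest.raises(ValueError, match="disagree"):
            implant_elements(seq, genes, catalog, spec)

    def test_seed_determinism(self, catalog):
        seq, genes = generate_locus(4, (500, 1500), (100, 300), seed=18)
        spec = ImplantSpec("IS1x", 5, {9: 0.5, 8: 0.5}, seed=19)
        a = implant_elements(seq, genes, catalog, spec)
        b = implant_elements(seq, genes, catalog, spec)
        assert a[0] == b[0]
        assert a[1] == b[1]

    def test_disrupted_gene_recorded(self, catalog):
        seq, genes = generate_locus(3, (5000, 8000), (50, 100), seed=20)
        spec = ImplantSpec("IS1x", 10, {9: 1.0}, seed=21)
        mutated, truth = implant_elements(seq, genes, catalog, spec)
        # most implants land in genes here (genes dominate the locus)
        hit_genes = [t for t in truth if t.disrupted_gene]
        assert hit_genes
        gene_names = {g.gene_name for g in genes}
        assert all(t.disrupted_gene in gene_names for t in hit_genes)

    def test_invalid_spec(self):
        with pytest.raises(ValueError, match="sums"):
            ImplantSpec("IS1x", 1, {9: 0.5, 8: 0.4})


class TestEvaluateDetection:
    def _pipeline(self, catalog, seed):
        seq, genes = generate_locus(6, (1000, 3000), (100, 400), seed=seed)
        spec = ImplantSpec("IS10x", 10, {9: 0.7, 8: 0.3}, seed=seed + 1000)
        mutated, truth = implant_elements(seq, genes, catalog, spec)
        hits = find_exact_copies(catalog, {"locus": mutated})
        calls = [call_tsd(mutated, h, canonical_set={9}) for h in hits]
        return truth, calls

    def test_perfect_recovery(self, catalog):
        truth, calls = self._pipeline(catalog, seed=30)
        metrics = evaluate_detection(truth, calls, {"IS1x": 768, "IS10x": 1329})
        assert metrics.recall == 1.0
        assert metrics.precision == 1.0

    def test_spurious_call_lowers_precision(self, catalog):
        from isbreach.locus_scanner import ISHit
        from isbreach.tsd_caller import TSDCall

        truth, calls = self._pipeline(catalog, seed=31)
        fake_hit = ISHit("IS10x", "locus", 50, 50 + 1329, "+", 10**6)
        calls.append(TSDCall(hit=fake_hit, k=0, tsd_sequence="", status="none"))
        n = len(truth)
        metrics = evaluate_detection(truth, calls, {"IS1x": 768, "IS10x": 1329})
        assert metrics.precision == pytest.approx(n / (n + 1))
        assert metrics.recall == 1.0

    def test_calls_equal_truth_trivial(self):
        truth = [TruthRecord("e", "s", 100, 9, "ACGTACGTA", "+")]
        from isbreach.locus_scanner import ISHit
        from isbreach.tsd_caller import TSDCall

        hit = ISHit("e", "s", 109, 109 + 500, "+", 10_000)
        calls = [TSDCall(hit=hit, k=9, tsd_sequence="ACGTACGTA",
                         upstream_interval=(100, 109), downstream_interval=(609, 618),
                         status="canonical")]
        metrics = evaluate_detection(truth, calls, {"e": 500})
        assert (metrics.recall, metrics.precision, metrics.exact_k_rate) == (1.0, 1.0, 1.0)


class TestFullPipelineRecovery:
    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_recall_one_for_k_at_least_7(self, catalog, seed):
        """scan -> call_tsd -> evaluate: recall 1.0, exact-k >= 0.99 per spec."""
        seq, genes = generate_locus(8, (1000, 2500), (100, 400), seed=seed)
        spec = ImplantSpec("IS1x", 40, {9: 0.5, 8: 0.3, 7: 0.2}, seed=seed * 7)
        mutated, truth = implant_elements(seq, genes, catalog, spec)
        hits = find_exact_copies(catalog, {"locus": mutated})
        calls = [call_tsd(mutated, h, canonical_set={8, 9}) for h in hits]
        metrics = evaluate_detection(truth, calls, {"IS1x": 768, "IS10x": 1329})
        assert metrics.recall == 1.0
        assert metrics.exact_k_rate >= 0.99 or metrics.exact_k_rate == 1.0
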