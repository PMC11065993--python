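"""Protein family clustering, prevalence arithmetic and the antitoxin screen."""

import numpy as np
import pytest

from adgscan.adg_caller import PipelineConfig
from adgscan.genome_io import Genome, GeneRecord
from adgscan.protein_families import (
    ProteinFamily,
    ProteinRecord,
    cluster_families,
    motif_prevalence,
    pairwise_align,
    screen_host_homologs,
)
from adgscan.synthetic_fixtures import (
    _mutate_protein,
    _random_protein,
    simulate_protein_families,
)

BLOSUM62_GAP_OPEN = 12  # first gapped residue
BLOSUM62_GAP_EXTEND = 1


def sw_oracle(a, b):
    """Quadratic Smith-Waterman DP with affine gaps; independent of the
    production aligner. Returns the optimal local score."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    n, m = len(a), len(b)
    NEG = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in b (deletion)
    F = np.full((n + 1, m + 1), NEG)  # gap in a (insertion)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - BLOSUM62_GAP_OPEN, E[i - 1][j] - BLOSUM62_GAP_EXTEND)
            F[i][j] = max(H[i][j - 1] - BLOSUM62_GAP_OPEN, F[i][j - 1] - BLOSUM62_GAP_EXTEND)
            s = mat[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestPairwiseAlign:
    def test_identical_sequences(self):
        a = "M" + _random_protein(99, np.random.default_rng(0))
        st = pairwise_align(a, a)
        assert st.pid == 100.0 and st.coverage == 100.0
        assert st.evalue_proxy < 1e-30

    def test_prefix_coverage_of_shorter(self):
        a = "M" + _random_protein(99, np.random.default_rng(1))
        st = pairwise_align(a, a[:50])
        assert st.pid == 100.0
        assert st.coverage == 100.0

    def test_score_matches_dp_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(3):
            a = _random_protein(60, rng)
            b = _random_protein(60, rng)
            st = pairwise_align(a, b)
            assert st.score == pytest.approx(sw_oracle(a, b))

    def test_related_pair_matches_dp_oracle(self):
        rng = np.random.default_rng(3)
        a = _random_protein(80, rng)
        b = _mutate_protein(a, 0.2, rng)
        st = pairwise_align(a, b)
        assert st.score == pytest.approx(sw_oracle(a, b))
        assert st.pid > 60.0

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        a = _random_protein(70, rng)
        b = _mutate_protein(a, 0.3, rng)
        ab, ba = pairwise_align(a, b), pairwise_align(b, a)
        assert ab.score == ba.score
        assert ab.pid == pytest.approx(ba.pid)
        assert ab.coverage == pytest.approx(ba.coverage)

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            pairwise_align("", "MKL")


class TestClusterFamilies:
    def _records(self, seqs):
        return [
            ProteinRecord(genome_id="t", gene_id=f"p{i}", seq=s)
            for i, s in enumerate(seqs)
        ]

    def test_unrelated_proteins_all_singletons(self):
        rng = np.random.default_rng(5)
        fams = cluster_families(self._records(
            [_random_protein(80, rng) for _ in range(4)]
        ))
        assert all(f.singleton for f in fams)

    def test_single_linkage_transitivity(self):
        rng = np.random.default_rng(6)
        a = _random_protein(60, rng)
        c = _random_protein(60, rng)
        b = a[:30] + c[:30]  # similar to both a and c; a~c unrelated
        assert pairwise_align(a, c).evalue_proxy > 1e-3
        assert pairwise_align(a, b).evalue_proxy <= 1e-3
        assert pairwise_align(b, c).evalue_proxy <= 1e-3
        fams = cluster_families(self._records([a, b, c]))
        assert len(fams) == 1 and fams[0].n_members == 3

    def test_two_seeded_clusters_recovered(self):
        records, truth = simulate_protein_families(7, 2, [5, 5], 0.3)
        fams = cluster_families(records)
        assert len(fams) == 2
        for f in fams:
            labels = {truth[m.key] for m in f.members}
            assert len(labels) == 1

    def test_partition_invariant(self):
        records, _ = simulate_protein_families(8, 3, [4, 3, 2], 0.25)
        fams = cluster_families(records)
        seen = [m.key for f in fams for m in f.members]
        assert sorted(seen) == sorted(r.key for r in records)
        assert len(seen) == len(set(seen))

    def test_input_order_invariance(self):
        records, _ = simulate_protein_families(9, 2, [3, 3], 0.3)
        fams1 = cluster_families(records)
        fams2 = cluster_families(records[::-1])
        key1 = [(f.family_id, sorted(m.key for m in f.members)) for f in fams1]
        key2 = [(f.family_id, sorted(m.key for m in f.members)) for f in fams2]
        assert key1 == key2

    def test_naming_prefix_by_provenance(self):
        rng = np.random.default_rng(10)
        recs = [
            ProteinRecord("v1", "a", _random_protein(60, rng), provenance="single"),
            ProteinRecord("m1", "b", _random_protein(60, rng), provenance="mag"),
            ProteinRecord("s1", "c", _random_protein(60, rng), provenance="ssv_operon"),
        ]
        fams = cluster_families(recs)
        prefixes = {f.family_id.split(".")[0] for f in fams}
        assert prefixes == {"ADG", "mADG", "ADGSSV"}


class TestMotifPrevalence:
    @pytest.mark.parametrize(
        "n,with_motif,expected",
        [(4, 3, 0.75), (5, 5, 1.0), (8, 1, 0.125)],
    )
    def test_prevalence_fractions(self, n, with_motif, expected):
        members = [
            ProteinRecord("g", f"p{i}", "M" + "A" * 50) for i in range(n)
        ]
        fam = ProteinFamily(family_id="ADG.01", members=members)
        flags = {m.key: i < with_motif for i, m in enumerate(members)}
        rec = motif_prevalence(fam, flags)
        assert rec.prevalence == pytest.approx(expected)
        assert rec.n_homologs == n

    def test_missing_flag_errors(self):
        fam = ProteinFamily(
            family_id="ADG.01",
            members=[ProteinRecord("g", "p0", "M" + "A" * 20)],
        )
        with pytest.raises(KeyError):
            motif_prevalence(fam, {})


class TestHostHomologScreen:
    def _host(self, genes, length=20000):
        g = Genome(id="host1", sequence="A" * length, genes=genes)
        return g

    def test_small_viral_protein_with_convergent_partner(self):
        rng = np.random.default_rng(11)
        anti = "M" + _random_protein(139, rng)  # 140 aa
        toxin = "M" + _random_protein(109, rng)  # 110 aa
        genes = [
            GeneRecord("h_anti", 1000, 1000 + 140 * 3 + 3, "+"),
            GeneRecord("h_tox", 1500, 1500 + 110 * 3 + 3, "-"),
        ]
        host = self._host(genes)
        host_prot = [
            ProteinRecord("host1", "h_anti", anti),
            ProteinRecord("host1", "h_tox", toxin),
        ]
        viral = [ProteinRecord("v1", "vp1", anti)]
        out = screen_host_homologs(viral, host_prot, [host], PipelineConfig())
        assert len(out) == 1
        c = out[0]
        assert c.host_gene_id == "h_anti"
        assert c.toxin_partner == "h_tox"
        assert c.convergent_pair

    def test_large_viral_protein_excluded(self):
        rng = np.random.default_rng(12)
        big = "M" + _random_protein(199, rng)  # 200 aa
        genes = [GeneRecord("h1", 1000, 1000 + 200 * 3 + 3, "+")]
        host = self._host(genes)
        out = screen_host_homologs(
            [ProteinRecord("v1", "vp1", big)],
            [ProteinRecord("host1", "h1", big)],
            [host],
            PipelineConfig(),
        )
        assert out == []

    def test_integrated_virus_neighborhood_excluded(self):
        rng = np.random.default_rng(13)
        shared = ["M" + _random_protein(99, rng) for _ in range(7)]
        genes = [
            GeneRecord(f"h{i}", 1000 + i * 400, 1300 + i * 400, "+")
            for i in range(7)
        ]
        host = self._host(genes)
        host_prot = [
            ProteinRecord("host1", f"h{i}", shared[i]) for i in range(7)
        ]
        viral = [ProteinRecord("v1", f"vp{i}", shared[i]) for i in range(7)]
        out = screen_host_homologs(viral, host_prot, [host], PipelineConfig())
        # every hit sits in a neighbourhood with >= 5 viral-hit genes
        assert out == []
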