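import numpy as np
import pytest

from anifrac.genome_io import CdsSet, GenomeRecord
from anifrac.relatedness import (
    directional_ani,
    merge_modes,
    pair_relatedness,
    pair_relatedness_cds,
    pair_relatedness_protein,
    results_to_frame,
)
from anifrac.scoring import ACCURATE, ScoringScheme
from anifrac.simulate import SimulationParams, simulate_pair

from oracles import k80_identity, random_dna

UNIT = ScoringScheme.preset("UNIT")


@pytest.fixture(scope="module")
def sim_pair_mid():
    """One simulated pair at moderate distance and partial coverage."""
    rng = np.random.default_rng(11)
    return simulate_pair(SimulationParams(d=0.2, c=0.6), rng)


class TestDirectionalAni:
    def test_self_comparison_exact(self, rng, warm_kernels):
        g = GenomeRecord("g", random_dna(2500, rng))
        ani, aln = directional_ani(g, g, ACCURATE, UNIT)
        assert ani == 1.0
        assert aln == g.length

    def test_unrelated_genomes_no_hits(self, rng):
        a = GenomeRecord("a", random_dna(10_000, rng))
        b = GenomeRecord("b", random_dna(10_000, rng))
        ani, aln = directional_ani(a, b, ACCURATE, UNIT)
        assert (ani, aln) == (0.0, 0)

    def test_tracks_hky_identity(self, rng):
        pair = simulate_pair(SimulationParams(d=0.1, c=1.0), rng)
        ani, aln = directional_ani(pair.genome_a, pair.genome_b, ACCURATE, UNIT)
        assert ani == pytest.approx(k80_identity(0.1, 2.0), abs=0.01)
        assert aln > 0.9 * pair.genome_a.length


class TestPairRelatedness:
    def test_identical_genomes(self, rng):
        g = GenomeRecord("g", random_dna(3000, rng))
        h = GenomeRecord("h", g.seq)
        r = pair_relatedness(g, h, ACCURATE, UNIT)
        assert r.ani == 1.0
        assert r.af_mean == 1.0
        assert r.wgani == 1.0
        assert not r.filtered

    def test_symmetry_under_swap(self, sim_pair_mid):
        a, b = sim_pair_mid.genome_a, sim_pair_mid.genome_b
        r1 = pair_relatedness(a, b, ACCURATE, UNIT)
        r2 = pair_relatedness(b, a, ACCURATE, UNIT)
        assert r1.ani == r2.ani
        assert r1.aln_len == r2.aln_len
        assert r1.af_a == r2.af_b and r1.af_b == r2.af_a
        assert (r1.af_mean, r1.af_min, r1.af_max) == (r2.af_mean, r2.af_min, r2.af_max)

    def test_af_ordering_invariant(self, sim_pair_mid):
        r = pair_relatedness(sim_pair_mid.genome_a, sim_pair_mid.genome_b, ACCURATE, UNIT)
        assert r.af_min <= r.af_mean <= r.af_max
        assert r.af_min == pytest.approx(
            r.aln_len / max(sim_pair_mid.genome_a.length, sim_pair_mid.genome_b.length)
        )
        assert r.af_max == pytest.approx(
            r.aln_len / min(sim_pair_mid.genome_a.length, sim_pair_mid.genome_b.length)
        )

    def test_estimates_track_truth(self, sim_pair_mid):
        r = pair_relatedness(sim_pair_mid.genome_a, sim_pair_mid.genome_b, ACCURATE, UNIT)
        truth_af = (sim_pair_mid.true_af_a + sim_pair_mid.true_af_b) / 2
        assert r.ani == pytest.approx(sim_pair_mid.true_ani, abs=0.02)
        assert r.af_mean == pytest.approx(truth_af, abs=0.05)


def _boundary_pair(shared_len, rng, tail=3000):
    """Two genomes sharing an exact leading segment; junctions mismatch."""
    shared = random_dna(shared_len, rng)
    tail_a = list(random_dna(tail, rng))
    tail_b = list(random_dna(tail, rng))
    swap = {"A": "C", "C": "G", "G": "T", "T": "A"}
    for i in range(8):  # force mismatches right after the shared segment
        if tail_a[i] == tail_b[i]:
            tail_b[i] = swap[tail_b[i]]
    return (
        GenomeRecord("A", shared + "".join(tail_a)),
        GenomeRecord("B", shared + "".join(tail_b)),
    )


class TestMinimumAlignmentFilter:
    def test_499_bp_alignment_zeroes_af(self, rng):
        a, b = _boundary_pair(499, rng)
        r = pair_relatedness(a, b, ACCURATE, UNIT)
        assert r.filtered
        assert r.af_a == r.af_b == r.af_mean == 0.0
        assert 0 < r.aln_len < 500

    def test_500_bp_alignment_retained(self, rng):
        a, b = _boundary_pair(500, rng)
        r = pair_relatedness(a, b, ACCURATE, UNIT)
        assert not r.filtered
        assert r.aln_len == 500
        assert r.af_a > 0 and r.af_b > 0

    def test_filtered_pair_keeps_its_ani(self, rng):
        a, b = _boundary_pair(499, rng)
        r = pair_relatedness(a, b, ACCURATE, UNIT)
        assert r.ani > 0.9  # identity of the shared segment is preserved


class TestCdsMode:
    def test_identical_cds_sets(self, rng):
        genes = [(f"g{i}", random_dna(600, rng)) for i in range(4)]
        a = CdsSet("A", genes)
        b = CdsSet("B", [(f"h{i}", s) for i, (_, s) in enumerate(genes)])
        r = pair_relatedness_cds(a, b, ACCURATE, UNIT)
        assert r.ani == 1.0
        assert r.af_mean == 1.0

    def test_shared_gene_fraction(self, rng):
        shared = random_dna(900, rng)
        a = CdsSet("A", [("s", shared), ("ua", random_dna(900, rng))])
        b = CdsSet("B", [("sb", shared), ("ub", random_dna(900, rng))])
        r = pair_relatedness_cds(a, b, ACCURATE, UNIT)
        assert r.af_mean == pytest.approx(0.5, abs=0.02)
        assert r.ani == 1.0

    def test_bbh_recovers_planted_orthologs(self):
        rng = np.random.default_rng(3)
        pair = simulate_pair(SimulationParams(d=0.15, c=0.6, n_genes=30), rng)
        r = pair_relatedness_cds(pair.cds_a, pair.cds_b, ACCURATE, UNIT)
        truth_af = (pair.true_af_a + pair.true_af_b) / 2
        # with CDS-length denominators the ortholog fraction is the truth AF
        assert r.af_mean == pytest.approx(truth_af, abs=0.05)
        assert r.ani == pytest.approx(pair.true_ani, abs=0.02)


class TestProteinMode:
    def test_identical_proteomes(self, rng):
        genes = [(f"g{i}", random_dna(600, rng)) for i in range(3)]
        a = CdsSet("A", genes).translated()
        b = CdsSet("B", [(f"h{i}", s) for i, (_, s) in enumerate(genes)]).translated()
        r = pair_relatedness_protein(a, b)
        assert r.ani == pytest.approx(1.0)
        assert r.af_mean == pytest.approx(1.0, abs=0.01)

    def test_empty_proteome_excluded(self, rng):
        a = CdsSet("A", [("g", random_dna(300, rng))]).translated()
        b = CdsSet("B", [])
        assert pair_relatedness_protein(a, b) is None

    def test_synonymous_divergence_aai_exceeds_ani(self):
        """Third-position-only substitutions in fourfold-degenerate codons
        leave every protein intact: AAI stays 1 while nucleotide identity
        drops, so protein mode reads through silent divergence."""
        rng = np.random.default_rng(8)
        # codon families whose third position is fully degenerate
        fourfold = ["GG", "GC", "GT", "CG", "AC", "TC", "CC", "CT"]
        bases = "ACGT"

        def make_pair(n_codons):
            cod_a, cod_b = [], []
            for _ in range(n_codons):
                fam = fourfold[rng.integers(len(fourfold))]
                third = bases[rng.integers(4)]
                cod_a.append(fam + third)
                if rng.uniform() < 0.3:  # silent substitution
                    third = bases[rng.integers(4)]
                cod_b.append(fam + third)
            return "".join(cod_a), "".join(cod_b)

        genes = [make_pair(150) for _ in range(5)]
        a = CdsSet("A", [(f"g{i}", ga) for i, (ga, _) in enumerate(genes)])
        b = CdsSet("B", [(f"h{i}", gb) for i, (_, gb) in enumerate(genes)])
        r_nt = pair_relatedness_cds(a, b, ACCURATE, UNIT)
        r_aa = pair_relatedness_protein(a, b)
        assert r_aa.ani == pytest.approx(1.0)
        assert r_nt.ani < 1.0
        assert r_aa.ani > r_nt.ani


class TestMergeModes:
    def _res(self, id_a, id_b, mode, ani=0.9):
        from anifrac.relatedness import RelatednessResult

        return RelatednessResult(
            id_a=id_a, id_b=id_b, mode=mode, ani=ani, aln_len=1000,
            af_a=0.5, af_b=0.5, af_mean=0.5, af_min=0.5, af_max=0.5,
            wgani=ani * 0.5,
        )

    def test_missing_mode_zero_filled(self):
        out = merge_modes(
            {
                "fragment": [self._res("a", "b", "fragment")],
                "protein": [
                    self._res("a", "b", "protein"),
                    self._res("a", "c", "protein", ani=0.4),
                ],
            }
        )
        row_ac = out[(out.id_a == "a") & (out.id_b == "c")].iloc[0]
        assert row_ac.ani_fragment == 0.0
        assert row_ac.ani_protein == 0.4
        row_ab = out[(out.id_a == "a") & (out.id_b == "b")].iloc[0]
        assert row_ab.ani_fragment == 0.9 and row_ab.ani_protein == 0.9

    def test_pair_absent_everywhere_not_in_output(self):
        out = merge_modes({"fragment": [self._res("a", "b", "fragment")]})
        assert len(out) == 1

    def test_results_frame_columns(self):
        df = results_to_frame([self._res("a", "b", "fragment")])
        assert {"id_a", "id_b", "ani", "af_mean", "wgani"} <= set(df.columns)
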