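"""Pseudo reads, spanning-forest phasing, haplotagging and switch error."""

import itertools

import numpy as np
import pytest

from emcap.conversion import AlignedConvertedRead, AlleleSupport, ConversionSpace
from emcap.phasing import (
    AlleleMatrix,
    HaplotagMode,
    Haplotype,
    HetVariant,
    PhasedBlock,
    SNVClass,
    VariantKind,
    build_allele_matrix,
    classify_by_snv,
    haplotag_accuracy,
    haplotag_reads,
    make_pseudo_reads,
    phase_blocks,
    switch_error_rate,
    truth_blocks_from_phase,
)

CT = ConversionSpace.CT


def _read(seq, start=0, read_id="r1", space=CT, primary=True):
    n = len(seq)
    return AlignedConvertedRead(
        read_id=read_id,
        chrom="sim1",
        read_offsets=np.arange(n),
        ref_positions=np.arange(start, start + n),
        read_bases=seq,
        is_primary=primary,
        space=space,
    )


def _variants(*pos_ref_alt, kind=VariantKind.HET_SNP):
    return [HetVariant("sim1", p, r, a, kind) for p, r, a in pos_ref_alt]


class TestBuildAlleleMatrix:
    def test_conversion_aware_cell(self):
        # CT-space read observing A at a C>A site supports ALT
        variants = _variants((2, "C", "A"))
        m = build_allele_matrix([_read("TTATT")], variants)
        assert m.cells["r1"][0] is AlleleSupport.ALT

    def test_supplementary_alignment_excluded(self):
        variants = _variants((2, "C", "A"))
        m = build_allele_matrix([_read("TTATT", primary=False)], variants)
        assert "r1" not in m.cells

    def test_read_without_variants_has_no_cells(self):
        variants = _variants((100, "C", "A"))
        m = build_allele_matrix([_read("TTATT")], variants)
        assert "r1" not in m.cells

    def test_out_of_bounds_variant_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            build_allele_matrix([], _variants((999, "C", "A")), reference_length=100)


class TestPseudoReads:
    def test_restored_bases_and_n_masking(self):
        variants = _variants((1, "A", "G"), (3, "C", "A"), (5, "C", "T"))
        # read: G at 1 (ALT), T at 3 (REF: converted C), T at 5 (AMBIGUOUS)
        read = _read("TGTTTTT")
        m = build_allele_matrix([read], variants)
        pseudo = make_pseudo_reads(m, [read])
        assert len(pseudo) == 1
        info = pseudo[0].informative_positions()
        assert info == {1: "G", 3: "C"}
        assert set(pseudo[0].bases) <= set("ACGTN")
        assert pseudo[0].bases.count("N") == len(pseudo[0].bases) - 2

    def test_all_ambiguous_read_emits_nothing(self):
        variants = _variants((2, "C", "T"))
        read = _read("TTTTT")
        m = build_allele_matrix([read], variants)
        assert make_pseudo_reads(m, [read]) == []

    def test_sam_round_trip(self, tmp_path):
        from emcap.io import read_pseudo_sam, write_pseudo_sam

        variants = _variants((1, "A", "G"), (3, "C", "A"))
        read = _read("TGTTT", read_id="rp")
        m = build_allele_matrix([read], variants)
        pseudo = make_pseudo_reads(m, [read])
        path = tmp_path / "pseudo.sam"
        write_pseudo_sam(pseudo, path, "sim1", 1000)
        back = read_pseudo_sam(path)
        assert back[0].read_id == "rp"
        assert back[0].informative_positions() == pseudo[0].informative_positions()


def _matrix_from_cells(variants, cells):
    """cells: {read_id: {variant_index: bit}} with 0=REF, 1=ALT."""
    m = AlleleMatrix(variants)
    for read_id, entries in cells.items():
        for vi, bit in entries.items():
            m.set(read_id, vi, AlleleSupport.ALT if bit else AlleleSupport.REF)
    return m


def mec_optimal_phasings(matrix):
    """Brute-force minimum-error-correction phasing oracle.

    Enumerates all 2^(v-1) assignments (first variant fixed to break the
    global flip) and returns the set of assignments reaching minimal MEC.
    """
    v = len(matrix.variants)
    reads = [matrix.informative(r) for r in matrix.cells]
    best_cost = None
    best = []
    for bits_rest in itertools.product((0, 1), repeat=v - 1):
        bits = (0,) + bits_rest
        cost = 0
        for info in reads:
            mis_h1 = sum(1 for vi, b in info.items() if b != bits[vi])
            mis_h2 = sum(1 for vi, b in info.items() if b != 1 - bits[vi])
            cost += min(mis_h1, mis_h2)
        if best_cost is None or cost < best_cost:
            best_cost, best = cost, [bits]
        elif cost == best_cost:
            best.append(bits)
    return best_cost, best


class TestPhaseBlocks:
    def test_chain_matches_truth_up_to_flip(self, rng):
        variants = _variants(*[(100 * i, "A", "G") for i in range(4)])
        truth_bits = [0, 1, 1, 0]
        cells = {}
        k = 0
        for i in range(3):  # 20 error-free reads spanning each adjacent pair
            for _ in range(20):
                hap = int(rng.integers(2))
                cells[f"r{k}"] = {
                    i: truth_bits[i] ^ hap,
                    i + 1: truth_bits[i + 1] ^ hap,
                }
                k += 1
        blocks = phase_blocks(_matrix_from_cells(variants, cells))
        assert len(blocks) == 1
        bits = [blocks[0].hap1_allele[i] for i in range(4)]
        flipped = [1 - b for b in bits]
        assert bits == truth_bits or flipped == truth_bits

    def test_disconnected_clusters_yield_two_blocks(self):
        variants = _variants(*[(100 * i, "A", "G") for i in range(4)])
        cells = {
            "a1": {0: 0, 1: 0},
            "a2": {0: 0, 1: 0},
            "b1": {2: 1, 3: 0},
            "b2": {2: 1, 3: 0},
        }
        blocks = phase_blocks(_matrix_from_cells(variants, cells))
        assert sorted(b.variant_indices for b in blocks) == [[0, 1], [2, 3]]

    def test_cis_trans_tie_drops_edge(self):
        variants = _variants((0, "A", "G"), (100, "A", "G"))
        cells = {"r1": {0: 0, 1: 0}, "r2": {0: 0, 1: 1}}
        assert phase_blocks(_matrix_from_cells(variants, cells)) == []

    def test_matches_mec_oracle_on_small_instances(self, rng):
        """Spanning-forest result equals exhaustive MEC phasing on small
        well-covered instances (up to one planted read error)."""
        for trial in range(25):
            v = int(rng.integers(3, 8))
            variants = _variants(*[(50 * i, "A", "G") for i in range(v)])
            truth = rng.integers(0, 2, size=v)
            cells = {}
            for r in range(int(rng.integers(8, 20))):
                start = int(rng.integers(0, v - 1))
                span = int(rng.integers(2, v - start + 1))
                hap = int(rng.integers(2))
                cells[f"r{r}"] = {
                    i: int(truth[i]) ^ hap for i in range(start, start + span)
                }
            if trial % 2:  # flip one observation in one read
                rid = rng.choice(list(cells))
                vi = rng.choice(list(cells[rid]))
                cells[rid][vi] ^= 1
            matrix = _matrix_from_cells(variants, cells)
            blocks = phase_blocks(matrix)
            if len(blocks) != 1 or len(blocks[0].variant_indices) != v:
                continue  # under-covered instance; MEC comparison undefined
            cost, optima = mec_optimal_phasings(matrix)
            bits = tuple(blocks[0].hap1_allele[i] for i in range(v))
            canonical = bits if bits[0] == 0 else tuple(1 - b for b in bits)
            assert canonical in optima


class TestHaplotag:
    VARIANTS = _variants(*[(100 * i, "A", "G") for i in range(4)])
    BLOCK = [PhasedBlock(0, [0, 1, 2], {0: 0, 1: 1, 2: 0})]

    def test_full_match_tags_h1(self):
        m = _matrix_from_cells(self.VARIANTS, {"r1": {0: 0, 1: 1, 2: 0}})
        res = haplotag_reads(m, self.BLOCK)
        assert res.assignments["r1"] is Haplotype.H1
        assert res.n_informative["r1"] == 3

    def test_tie_is_untagged(self):
        m = _matrix_from_cells(self.VARIANTS, {"r1": {0: 0, 1: 0}})
        res = haplotag_reads(m, self.BLOCK)
        assert res.assignments["r1"] is Haplotype.UNTAGGED

    def test_phased_only_ignores_singletons(self):
        m = _matrix_from_cells(self.VARIANTS, {"r1": {3: 1}})
        res = haplotag_reads(m, self.BLOCK, HaplotagMode.PHASED_ONLY)
        assert res.assignments["r1"] is Haplotype.UNTAGGED
        assert res.site_groups == {}

    def test_unphased_mode_groups_reads_per_site(self):
        m = _matrix_from_cells(
            self.VARIANTS, {"r1": {3: 1}, "r2": {3: 0}, "r3": {0: 0, 1: 1}}
        )
        res = haplotag_reads(m, self.BLOCK, HaplotagMode.WITH_UNPHASED_SNPS)
        assert res.site_groups == {3: {"r1": 1, "r2": 0}}

    def test_noiseless_simulation_tags_every_covered_read(self, noiseless_sim):
        sim = noiseless_sim
        m = build_allele_matrix((r.read for r in sim.reads), sim.variants.hets)
        blocks = phase_blocks(m)
        res = haplotag_reads(m, blocks)
        truth = {r.read.read_id: r.truth.haplotype for r in sim.reads}
        assert haplotag_accuracy(res, truth) == 1.0


class TestClassifyBySnv:
    SNVS = _variants((10, "A", "G"), (50, "A", "G"), kind=VariantKind.SOMATIC_SNV)

    def test_any_alt_is_plus(self):
        m = _matrix_from_cells(self.SNVS, {"r1": {0: 1, 1: 0}})
        assert classify_by_snv(m)["r1"] is SNVClass.SNV_PLUS

    def test_all_ref_is_minus(self):
        m = _matrix_from_cells(self.SNVS, {"r1": {0: 0}})
        assert classify_by_snv(m)["r1"] is SNVClass.SNV_MINUS

    def test_ambiguous_only_is_unassigned(self):
        m = AlleleMatrix(self.SNVS)
        m.set("r1", 0, AlleleSupport.AMBIGUOUS)
        assert classify_by_snv(m)["r1"] is SNVClass.UNASSIGNED

    def test_per_locus_mode(self):
        m = _matrix_from_cells(self.SNVS, {"r1": {0: 1, 1: 0}})
        per_locus = classify_by_snv(m, per_locus=True)
        assert per_locus[0]["r1"] is SNVClass.SNV_PLUS
        assert per_locus[1]["r1"] is SNVClass.SNV_MINUS


class TestSwitchError:
    VARIANTS = _variants(*[(1000 * i, "A", "G") for i in range(4)])

    def _blocks(self, bits):
        return [PhasedBlock(0, list(range(4)), dict(enumerate(bits)))]

    def test_identical_phasings(self):
        m = switch_error_rate(
            self._blocks([0, 1, 0, 1]), self._blocks([0, 1, 0, 1]), self.VARIANTS
        )
        assert m.switch_error_rate == 0.0
        assert m.n_comparable_pairs == 3
        assert m.block_n50_length == 3001

    def test_flipped_suffix_is_one_switch(self):
        m = switch_error_rate(
            self._blocks([0, 1, 1, 0]), self._blocks([0, 1, 0, 1]), self.VARIANTS
        )
        assert m.switch_error_rate == pytest.approx(1 / 3)

    def test_global_flip_invariance(self):
        test = self._blocks([0, 1, 1, 0])
        truth = self._blocks([1, 0, 0, 1])
        assert switch_error_rate(test, truth, self.VARIANTS).switch_error_rate == 0.0

    def test_no_comparable_pairs_reported_missing(self):
        m = switch_error_rate([], self._blocks([0, 1, 0, 1]), self.VARIANTS)
        assert m.switch_error_rate is None and m.n_comparable_pairs == 0

    def test_noiseless_end_to_end_switch_error_zero(self, noiseless_sim):
        sim = noiseless_sim
        m = build_allele_matrix((r.read for r in sim.reads), sim.variants.hets)
        blocks = phase_blocks(m)
        truth = truth_blocks_from_phase(sim.variants.hets, sim.variants.phase)
        metrics = switch_error_rate(blocks, truth, sim.variants.hets)
        assert metrics.switch_error_rate == 0.0
        assert metrics.n_comparable_pairs > 50
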