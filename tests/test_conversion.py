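"""Conversion-model unit and property tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emcap.conversion import (
    AlignedConvertedRead,
    AlleleSupport,
    ConversionSpace,
    MethylState,
    allele_support,
    call_cpg_methylation,
    classify_read_space,
    complement,
    convert_base,
    cpg_call_for_read,
    encode_seq,
    observation_set,
    restore_base,
)

CT, GA = ConversionSpace.CT, ConversionSpace.GA
BASES = "ACGT"


def brute_force_support(space, ref, alt, observed):
    """Independent oracle: enumerate convert_base over alleles x states."""
    if observed == "N":
        return AlleleSupport.OTHER
    from_ref = {convert_base(ref, space, m) for m in (False, True)}
    from_alt = {convert_base(alt, space, m) for m in (False, True)}
    if observed in from_ref and observed in from_alt:
        return AlleleSupport.AMBIGUOUS
    if observed in from_ref:
        return AlleleSupport.REF
    if observed in from_alt:
        return AlleleSupport.ALT
    return AlleleSupport.OTHER


@pytest.mark.parametrize(
    "base,space,methylated,expected",
    [
        ("C", CT, False, "T"),  # unmethylated C deaminated, reads as T
        ("C", CT, True, "C"),
        ("A", CT, False, "A"),
        ("G", GA, False, "A"),  # strand-symmetric rule on the bottom strand
        ("G", GA, True, "G"),
        ("C", GA, False, "C"),
    ],
)
def test_convert_base(base, space, methylated, expected):
    assert convert_base(base, space, methylated) == expected


def test_convert_base_rejects_unknown_space():
    with pytest.raises(ValueError):
        convert_base("C", ConversionSpace.UNKNOWN, False)


@pytest.mark.parametrize(
    "allele,space,expected",
    [
        ("C", CT, {"C", "T"}),
        ("T", CT, {"T"}),
        ("G", GA, {"G", "A"}),
        ("G", CT, {"G"}),
    ],
)
def test_observation_set(allele, space, expected):
    assert observation_set(allele, space) == expected


def test_observation_set_is_closure_of_convert_base():
    for space in (CT, GA):
        for allele in BASES:
            closure = {convert_base(allele, space, m) for m in (False, True)}
            assert observation_set(allele, space) == closure


@pytest.mark.parametrize(
    "space,ref,alt,obs,expected",
    [
        (CT, "C", "T", "T", AlleleSupport.AMBIGUOUS),
        (CT, "C", "A", "T", AlleleSupport.REF),
        (CT, "A", "G", "G", AlleleSupport.ALT),
        (CT, "A", "G", "N", AlleleSupport.OTHER),
        (GA, "G", "A", "A", AlleleSupport.AMBIGUOUS),
    ],
)
def test_allele_support_examples(space, ref, alt, obs, expected):
    assert allele_support(space, ref, alt, obs) == expected


def test_allele_support_matches_brute_force_everywhere():
    """Full oracle equivalence over every space x allele pair x observation."""
    for space in (CT, GA):
        for ref, alt in itertools.permutations(BASES, 2):
            for obs in BASES + "N":
                assert allele_support(space, ref, alt, obs) == brute_force_support(
                    space, ref, alt, obs
                ), (space, ref, alt, obs)


def test_allele_support_strand_symmetry():
    for ref, alt in itertools.permutations(BASES, 2):
        for obs in BASES:
            assert allele_support(GA, ref, alt, obs) == allele_support(
                CT, complement(ref), complement(alt), complement(obs)
            )


@pytest.mark.parametrize(
    "space,ref,alt,obs,expected",
    [
        (CT, "C", "A", "T", "C"),  # converted unmethylated ref C restored
        (CT, "C", "T", "T", "N"),  # inherently ambiguous pattern
        (GA, "G", "A", "G", "G"),
    ],
)
def test_restore_base(space, ref, alt, obs, expected):
    assert restore_base(space, ref, alt, obs) == expected


@settings(derandomize=True, max_examples=200)
@given(
    space=st.sampled_from([CT, GA]),
    pair=st.sampled_from(list(itertools.permutations(BASES, 2))),
    methylated=st.booleans(),
    which=st.booleans(),
)
def test_restore_round_trip(space, pair, methylated, which):
    """Unambiguous observations always restore the emitting allele."""
    ref, alt = pair
    allele = ref if which else alt
    obs = convert_base(allele, space, methylated)
    if allele_support(space, ref, alt, obs) in (AlleleSupport.REF, AlleleSupport.ALT):
        assert restore_base(space, ref, alt, obs) == allele


def _read(ref_seq, read_seq, start=0, space=ConversionSpace.UNKNOWN, read_id="r1"):
    n = len(read_seq)
    return AlignedConvertedRead(
        read_id=read_id,
        chrom="sim1",
        read_offsets=np.arange(n),
        ref_positions=np.arange(start, start + n),
        read_bases=read_seq,
        space=space,
    )


class TestClassifyReadSpace:
    def test_fully_converted_ct_read(self, rng):
        ref = "".join(rng.choice(list("ACGT"), size=200))
        read = "".join("T" if b == "C" else b for b in ref)
        assert classify_read_space(_read(ref, read), ref) is CT

    def test_no_c_or_g_in_span(self):
        ref = "ATATATATATATATATATAT"
        assert (
            classify_read_space(_read(ref, ref), ref) is ConversionSpace.UNKNOWN
        )

    def test_mixed_signal_below_ratio(self):
        # 8 C->T and 7 G->A mismatches: ratio 0.53 < 0.8 -> UNKNOWN
        ref = "C" * 8 + "G" * 7 + "A" * 20
        read = "T" * 8 + "A" * 7 + "A" * 20
        assert (
            classify_read_space(_read(ref, read), ref) is ConversionSpace.UNKNOWN
        )

    def test_variant_positions_excluded(self, rng):
        ref = "".join(rng.choice(list("ACGT"), size=200))
        read = "".join("T" if b == "C" else b for b in ref)
        variant_positions = [i for i, b in enumerate(ref) if b == "C"]
        assert (
            classify_read_space(_read(ref, read), ref, variant_positions)
            is ConversionSpace.UNKNOWN
        )


class TestCallCpgMethylation:
    REF = "AACGTACGTTACGAA"  # CpGs at 2, 6, 11

    def test_all_methylated_ct_reads(self):
        reads = [
            _read(self.REF, self.REF, space=CT, read_id=f"r{i}") for i in range(10)
        ]
        table = call_cpg_methylation(reads, [2, 6, 11], self.REF)
        assert (table["n_meth"] == 10).all()
        assert (table["n_unmeth"] == 0).all()
        assert (table["rate"] == 1.0).all()

    def test_destranding_mixes_both_spaces(self):
        # 3 methylated CT votes (C over the C) + 2 unmethylated GA votes
        # (A over the paired G) -> rate 3/5
        ct = self.REF
        ga = self.REF[:3] + "A" + self.REF[4:]  # A over G at pos 3
        reads = [_read(ct, ct, space=CT, read_id=f"c{i}") for i in range(3)]
        reads += [_read(ga, ga, space=GA, read_id=f"g{i}") for i in range(2)]
        table = call_cpg_methylation(reads, [2], self.REF)
        assert table.loc[0, "n_meth"] == 3
        assert table.loc[0, "n_unmeth"] == 2
        assert table.loc[0, "rate"] == pytest.approx(0.6)

    def test_unexpected_base_is_uninformative(self):
        read_seq = self.REF[:2] + "G" + self.REF[3:]  # G over the C in CT space
        table = call_cpg_methylation(
            [_read(self.REF, read_seq, space=CT)], [2], self.REF
        )
        assert table.loc[0, "n_meth"] == 0
        assert table.loc[0, "n_unmeth"] == 0

    def test_non_cpg_position_rejected(self):
        with pytest.raises(ValueError, match="4"):
            call_cpg_methylation([], [4], self.REF)

    def test_variant_overlap_drops_cpg(self):
        table = call_cpg_methylation(
            [_read(self.REF, self.REF, space=CT)],
            [2, 6],
            self.REF,
            exclude_variants={7},  # G of the CpG at 6
        )
        assert list(table["pos"]) == [2]

    def test_per_read_vote(self):
        read = _read(self.REF, self.REF, space=GA)
        assert cpg_call_for_read(read, 2) is MethylState.METHYLATED
        unk = _read(self.REF, self.REF)
        assert cpg_call_for_read(unk, 2) is MethylState.UNINFORMATIVE


def test_under_conversion_bias_matches_model(rng):
    """With efficiency e < 1 the estimated rate converges to
    truth + (1 - truth) * (1 - e)."""
    from emcap.simulate import SimConfig, PlantConfig, simulate_experiment

    e = 0.9
    cfg = SimConfig(
        seed=55,
        genome_length=120_000,
        n_targets=4,
        coverage=40,
        conversion_efficiency=e,
        over_conversion_rate=0.0,
        substitution_rate=0.0,
        insertion_rate=0.0,
        deletion_rate=0.0,
        duplicate_rate=0.0,
        n_somatic_snvs=0,
        snv_vaf=0.0,
        asm=PlantConfig(0),
    )
    sim = simulate_experiment(cfg)
    counts = call_cpg_methylation(
        (r.read for r in sim.reads),
        sim.reference.cpg_positions,
        sim.reference.codes,
        exclude_variants={v.pos for v in sim.variants.hets},
    )
    tm, tu = sim.tally.counts()
    pos_index = {p: i for i, p in enumerate(sim.reference.cpg_positions)}
    idx = np.array([pos_index[p] for p in counts["pos"]])
    cov_est = counts["n_meth"] + counts["n_unmeth"]
    cov_truth = tm[idx] + tu[idx]
    keep = (cov_truth >= 20) & (cov_est > 0)
    truth_rate = tm[idx][keep] / cov_truth[keep]
    expected = truth_rate + (1 - truth_rate) * (1 - e)
    est = (counts["n_meth"] / cov_est).to_numpy()[keep]
    assert abs(np.mean(est - expected)) < 0.02
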