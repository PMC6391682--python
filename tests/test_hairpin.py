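"""Arm density, reporter-antisense selection, and phasing registers."""

from __future__ import annotations

import numpy as np
import pytest

from _factories import aln, lib
from sirnaq import (
    HairpinSpec,
    SimConfig,
    align_library,
    arm_density,
    hairpin_length_abundance,
    phasing_profile,
    select_reporter_targeting,
    simulate_inserts,
    simulate_reference,
)
from sirnaq.hairpin import scaled_start

# hairpin laid out at plasmid positions [500, 1359): 400-nt arms, 59-nt loop
SPEC = HairpinSpec(
    plasmid_contig="plasmid_IR",
    hairpin_start=500, hairpin_end=1359,
    arm5=(500, 900), loop=(900, 959), arm3=(959, 1359),
    reporter_antisense_strand="-",
)


def hp_aln(scaled, length=22, strand="+", n_hits=1, read_id="r"):
    """Alignment whose biological 5' end sits at the given scaled start."""
    p5 = SPEC.hairpin_start + scaled - 1
    start = p5 if strand == "+" else p5 - length + 1
    return aln(contig="plasmid_IR", start=start, length=length, strand=strand,
               n_hits=n_hits, read_id=read_id)


def test_spec_invariants():
    with pytest.raises(ValueError):  # loop before arm5
        HairpinSpec("p", 0, 100, arm5=(40, 60), loop=(0, 10), arm3=(60, 80))
    with pytest.raises(ValueError):  # unequal arms
        HairpinSpec("p", 0, 100, arm5=(0, 30), loop=(30, 40), arm3=(40, 90))
    HairpinSpec("p", 0, 100, arm5=(0, 30), loop=(30, 40), arm3=(40, 90),
                arm_length_tolerance=20)


def test_spec_yaml_roundtrip(tmp_path):
    path = tmp_path / "hp.yaml"
    SPEC.to_yaml(path)
    assert HairpinSpec.from_yaml(path) == SPEC


@pytest.mark.parametrize(
    "starts, expected_registers",
    [
        ([1, 23, 45], {1: 1.0}),                 # all congruent to 1 mod 22
        (list(range(1, 23)), {r: 1 / 22 for r in range(1, 23)}),
        ([1, 1, 2], {1: 2 / 3, 2: 1 / 3}),
    ],
)
def test_phasing_registers(starts, expected_registers):
    alignments = [hp_aln(s, read_id=f"r{i}") for i, s in enumerate(starts)]
    prof = phasing_profile(lib(alignments), SPEC)
    for register in range(1, 23):
        assert prof.register(register) == pytest.approx(
            expected_registers.get(register, 0.0))
    assert prof.proportions.sum() == pytest.approx(1.0)
    assert prof.n_reads == pytest.approx(len(starts))


def test_phasing_minus_strand_uses_biological_five_prime():
    """A minus-strand read enters through its own 5' end (alignment end)."""
    minus = hp_aln(45, strand="-")
    assert scaled_start(minus, SPEC) == 45
    prof = phasing_profile(lib([minus]), SPEC)
    assert prof.register(1) == 1.0


def test_phasing_fractional_weights_and_period():
    alignments = [hp_aln(1, n_hits=2, read_id="mm"),
                  hp_aln(23, strand="-", n_hits=2, read_id="mm"),
                  hp_aln(2, read_id="u")]
    prof = phasing_profile(lib(alignments), SPEC)
    assert prof.register(1) == pytest.approx(0.5)
    assert prof.register(2) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        phasing_profile(lib(alignments), SPEC, period=1)


def test_phasing_empty_flagged():
    prof = phasing_profile(lib([]), SPEC)
    assert prof.n_reads == 0 and not prof.defined
    assert np.isnan(prof.proportions).all()


def test_phasing_sums_to_one_random():
    rng = np.random.default_rng(8)
    alignments = [hp_aln(int(rng.integers(1, 800)), length=int(rng.integers(21, 24)),
                         strand=("+", "-")[rng.integers(2)], read_id=f"r{i}")
                  for i in range(500)]
    for period in (10, 22, 25):
        prof = phasing_profile(lib(alignments), SPEC, period=period)
        assert prof.proportions.sum() == pytest.approx(1.0)


def test_arm_density_block():
    """10 unique 22-mers at arm5 start: 10 CPM over positions 0..21."""
    alignments = [hp_aln(1, read_id=f"r{i}") for i in range(10)]
    up, down = arm_density(lib(alignments, denominator=10**6), SPEC)
    assert up.cpm[:22] == pytest.approx(np.full(22, 10.0))
    assert up.cpm[22:].sum() == 0
    assert down.cpm.sum() == 0
    assert down.sign == -1 and (down.signed_cpm <= 0).all()


def test_arm_density_assignment_by_five_prime_end():
    """Arm membership follows the read's 5' end; loop 5' ends are excluded."""
    in5 = hp_aln(395)            # + strand, 5' end in arm5, covers into the loop
    in_loop = hp_aln(410)        # + strand 5' end inside the loop: dropped
    in3 = hp_aln(470, strand="-")  # 5' end in arm3
    up, down = arm_density(lib([in5, in_loop, in3], denominator=10**6), SPEC)
    assert up.cpm[394:416].sum() == pytest.approx(22.0)  # 22 positions x 1 CPM
    assert down.cpm.sum() == pytest.approx(22.0)
    # per-arm totals equal fractional read counts (x read length x CPM scale)
    assert up.cpm.sum() / 22 == pytest.approx(1.0)


def test_arm_density_five_prime_mode():
    up, _ = arm_density(lib([hp_aln(1), hp_aln(1, read_id="r2")],
                            denominator=10**6), SPEC, mode="five_prime")
    assert up.cpm[0] == pytest.approx(2.0) and up.cpm[1:].sum() == 0


def test_arm_density_contig_check():
    library = lib([aln(contig="chr1", start=100)])
    with pytest.raises(ValueError, match="plasmid"):
        arm_density(library, SPEC)


def test_select_reporter_targeting():
    plus = [hp_aln(i + 1, read_id=f"p{i}") for i in range(6)]
    minus = [hp_aln(i + 40, strand="-", read_id=f"m{i}") for i in range(4)]
    selected = select_reporter_targeting(lib(plus + minus), SPEC)
    assert {a.read_id for a in selected} == {f"m{i}" for i in range(4)}
    assert select_reporter_targeting(lib([]), SPEC) == []


def test_select_reporter_targeting_matches_simulated_split():
    config = SimConfig(seed=21, n_contigs=1, contig_length=10_000, n_mirna_loci=3,
                       n_repeat_families=1, library_size=1000, frac_mirna=0.0,
                       frac_hairpin=1.0, frac_repeat=0.0, frac_random=0.0,
                       strand_bias=0.6)
    reference = simulate_reference(config)
    inserts, truth = simulate_inserts(config, reference, 1)
    library = align_library(inserts, reference.reference, sample_id="s")
    selected = select_reporter_targeting(library, reference.hairpin)
    # palindromic stem reads map once per strand; reads of either true
    # strand appear among the minus-strand placements exactly once
    n_true_minus = int((truth["strand"] == "-").sum())
    assert 0 < n_true_minus < 1000
    assert len({a.read_id for a in selected}) >= n_true_minus


def test_hairpin_length_abundance():
    alignments = [hp_aln(1, length=22, read_id="a"),
                  hp_aln(30, length=21, read_id="b"),
                  # palindromic multimapper: two placements at weight 1/2
                  hp_aln(5, length=22, n_hits=2, read_id="mm"),
                  hp_aln(100, length=22, strand="-", n_hits=2, read_id="mm")]
    out = hairpin_length_abundance(lib(alignments, denominator=10**6), SPEC)
    assert out[22] == pytest.approx(2.0)
    assert out[21] == pytest.approx(1.0)
    assert out[19] == 0.0 and out[24] == 0.0
    empty = hairpin_length_abundance(lib([], denominator=10**6), SPEC)
    assert set(empty.values()) == {0.0}


def test_terminal_mode_lengths_concentrate_21_23(small_config, small_reference):
    inserts, _ = simulate_inserts(small_config, small_reference, 1)
    library = align_library(inserts, small_reference.reference, sample_id="s")
    out = hairpin_length_abundance(library, small_reference.hairpin)
    total = sum(out.values())
    assert total > 0
    assert (out[21] + out[22] + out[23]) / total > 0.95
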