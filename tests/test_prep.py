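import numpy as np
import pytest

from cyclerelax.alignment import CodonAlignment
from cyclerelax.prep import (
    PrepConfig,
    consensus_sequence,
    coverage_filter,
    divergence_zscore_filter,
    homogenize_ambiguities,
    prepare_alignment,
    select_isoform,
    trim_codon_gappy,
)


def make(rows, prefix="t"):
    return CodonAlignment(tuple(f"{prefix}{i}" for i in range(len(rows))), tuple(rows))


def test_config_validation():
    with pytest.raises(ValueError):
        PrepConfig(min_group_fraction=0.0)
    with pytest.raises(ValueError):
        PrepConfig(z_interval=(2.5, -2.5))
    with pytest.raises(ValueError):
        PrepConfig(divergence_denominator="weird")


def test_select_isoform_most_species_then_length_then_id():
    assert select_isoform({"a": 2, "b": 5}) == "b"
    assert select_isoform({"a": 3, "b": 3}, {"a": 10, "b": 30}) == "b"
    assert select_isoform({"a": 3, "b": 3}, {"a": 10, "b": 10}) == "a"
    with pytest.raises(ValueError):
        select_isoform({})


def test_coverage_filter_half_rule_rounds_up():
    # groups of 5 -> need ceil(2.5) = 3 present
    traits = {f"m{i}": "monoecious" for i in range(5)}
    traits |= {f"h{i}": "heteroecious" for i in range(5)}
    full = CodonAlignment(tuple(traits), tuple(["ATG"] * 10))
    ok3 = full.subset(["m0", "m1", "m2", "h0", "h1", "h2"])
    bad2 = full.subset(["m0", "m1", "h0", "h1", "h2"])
    kept = coverage_filter({"good": ok3, "bad": bad2}, traits)
    assert set(kept) == {"good"}


def test_coverage_filter_unknown_taxon():
    aln = CodonAlignment(("x",), ("ATG",))
    with pytest.raises(KeyError, match="x"):
        coverage_filter({"o": aln}, {"m": "monoecious"}, group_sizes={"monoecious": 1})


def test_trim_codon_gappy_boundary():
    # n=10 sequences; codon column 0: two gapped rows -> removed;
    # codon column 1: one gapped row -> kept
    rows = ["---AAA" if i < 2 else "ATGAAA" for i in range(10)]
    rows[5] = "ATGA-A"
    trimmed = trim_codon_gappy(make(rows))
    assert trimmed.n_codons == 1
    assert trimmed.rows[0] == "AAA" and trimmed.rows[5] == "A-A"


def test_homogenize():
    out = homogenize_ambiguities(make(["ARGYWS"]))
    assert out.rows == ("ANGNNN",)


def test_consensus_majority_and_ties():
    assert consensus_sequence(make(["ATG", "ATG", "CCG"])) == "ATG"
    # tie A vs C at column 0 breaks alphabetically
    assert consensus_sequence(make(["ATG", "CTG"]))[0] == "A"
    # all-gap column becomes N
    assert consensus_sequence(make(["-TG", "-TG", "-TG"])) == "NTG"
    with pytest.raises(ValueError):
        consensus_sequence(CodonAlignment((), ()))


def test_zscore_filter_closed_forms():
    # n=11, one divergent row: its z is (n-1)/sqrt(n) = 10/sqrt(11) > 2.5
    aln = make(["ATGAAA"] * 10 + ["ATGCCC"])
    kept, report = divergence_zscore_filter(aln)
    assert report.removed == ("t10",)
    assert report.zscores.max() == pytest.approx(10 / np.sqrt(11))
    assert kept.n_taxa == 10
    # n=6: max achievable z is 5/sqrt(6) < 2.5, removal is impossible
    aln6 = make(["ATGAAA"] * 5 + ["ATGCCC"])
    kept6, report6 = divergence_zscore_filter(aln6)
    assert report6.removed == ()
    assert report6.zscores.max() == pytest.approx(5 / np.sqrt(6))
    assert kept6.n_taxa == 6


def test_zscore_filter_degenerate_cases():
    # identical rows: sd = 0, nothing removed
    same = make(["ATGAAA"] * 5)
    kept, report = divergence_zscore_filter(same)
    assert report.removed == () and report.sd == 0.0
    # fewer than 3 rows: skipped with a note
    two = make(["ATGAAA", "ATGCCC"])
    kept2, report2 = divergence_zscore_filter(two)
    assert report2.skipped and kept2 == two


def test_zscore_comparable_denominator_ignores_missing():
    # row with Ns: divergence counted over its unambiguous sites only
    rows = ["ATGAAA"] * 4 + ["NNNAAA"]
    _, report = divergence_zscore_filter(make(rows))
    assert report.divergence[4] == 0.0


def test_prepare_alignment_order_and_bookkeeping():
    rows = ["---ATGAAA" if i < 2 else "ATGATGAAA" for i in range(10)]
    rows[9] = "ATGATGCCC"
    rows[3] = "ATGRTGAAA"  # ambiguity -> N
    result = prepare_alignment(make(rows + ["ATGATGAAA"]))
    assert result.n_codons_in == 3
    assert result.n_codons_after_trim == 2  # gappy first codon dropped
    assert "N" in result.alignment.row("t3") or "t3" not in result.alignment.taxa
    assert result.removed_sequences == ("t9",)  # 10/sqrt(11) outlier
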