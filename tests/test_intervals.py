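"""Cosegregation interval mapping and narrowing."""

import numpy as np
import pandas as pd
import pytest

from causalmap import (
    CandidateInterval,
    GeneModel,
    genes_in_interval,
    interval_length_mbp,
    map_cosegregating_interval,
    narrow_interval,
    select_informative_markers,
)
from causalmap.intervals import AmbiguousNarrowingError, CoordinateError
from causalmap.simulate import GenotypeTable


def make_table(marker_pos, rows, phenotypes=None, chrom="chr4", chrom_len=70_000_000):
    """Hand-built genotype table; rows map individual -> list of calls."""
    panel = pd.DataFrame(
        {"chrom": [chrom] * len(marker_pos), "pos": marker_pos},
        index=[f"M{i}" for i in range(len(marker_pos))],
    )
    calls = pd.DataFrame.from_dict(rows, orient="index", columns=panel.index)
    phen = pd.Series(phenotypes or {i: "mutant" for i in rows}, name="phenotype")
    return GenotypeTable(
        calls=calls, phenotype=phen, panel=panel, chrom_lengths={chrom: chrom_len}
    )


def test_flanks_are_first_noncosegregating_markers():
    """Recombinants just outside two markers bound the interval there."""
    pos = [int(1e6 * m) for m in (1, 2, 3, 4, 5, 6, 7)]
    rows = {
        "i1": ["BB", "AB", "AA", "AA", "AA", "AA", "AA"],  # crossover left of M2
        "i2": ["AA", "AA", "AA", "AA", "AA", "AB", "BB"],  # crossover right of M4
    }
    res = map_cosegregating_interval(make_table(pos, rows))
    iv = res.interval
    assert (iv.left_marker, iv.right_marker) == ("M1", "M5")
    assert (iv.left, iv.right) == (2_000_000, 6_000_000)
    assert res.run_markers == ["M2", "M3", "M4"]


def test_single_uninformative_individual_returns_whole_chromosome():
    pos = [1_000_000, 2_000_000]
    rows = {"i1": ["AA", "AA"]}
    res = map_cosegregating_interval(make_table(pos, rows, chrom_len=5_000_000))
    assert (res.interval.left, res.interval.right) == (1, 5_000_000)
    assert res.interval.left_marker is None and res.interval.right_marker is None


def test_interval_never_grows_when_individuals_are_added():
    rng = np.random.default_rng(0)
    pos = [int(1e6 * m) for m in range(1, 21)]
    # recombinant patterns: single crossover somewhere, AA around marker 10
    def individual(cross_left, cross_right):
        return [
            "AA" if cross_left < p < cross_right else ("AB" if rng.random() < 0.5 else "BB")
            for p in pos
        ]

    rows = {}
    prev_len = None
    for k in range(1, 8):
        rows[f"i{k}"] = individual(
            int(rng.integers(0, 9_500_000)), int(rng.integers(11_500_000, 21_000_000))
        )
        res = map_cosegregating_interval(make_table(pos, rows))
        length = res.interval.length_bp
        if prev_len is not None:
            assert length <= prev_len
        prev_len = length


def test_heterozygous_mutant_call_breaks_cosegregation():
    pos = [1_000_000, 2_000_000, 3_000_000]
    rows = {"i1": ["AA", "AA", "AA"], "i2": ["AA", "AB", "AA"]}
    res = map_cosegregating_interval(make_table(pos, rows))
    assert res.noncoseg["M1"] == 1
    # the single-individual break is bridged, not allowed to split the run
    assert res.interval.left_marker is None and res.interval.right_marker is None


def test_double_crossover_individual_does_not_split_the_region():
    pos = [int(1e6 * m) for m in range(1, 12)]
    rows = {
        "i1": ["BB"] + ["AA"] * 9 + ["BB"],
        "i2": ["AA"] * 4 + ["AB", "AB"] + ["AA"] * 5,  # double crossover in 5-6 Mbp
        "i3": ["AB"] + ["AA"] * 9 + ["AB"],
    }
    res = map_cosegregating_interval(make_table(pos, rows))
    assert (res.interval.left, res.interval.right) == (1_000_000, 11_000_000)


def test_missing_calls_are_uninformative():
    pos = [1_000_000, 2_000_000, 3_000_000, 4_000_000]
    rows = {
        "i1": ["BB", np.nan, "AA", "BB"],
        "i2": ["BB", "AA", np.nan, "BB"],
    }
    res = map_cosegregating_interval(make_table(pos, rows))
    assert res.run_markers == ["M1", "M2"]


def test_only_mutant_rows_are_used():
    pos = [1_000_000, 2_000_000, 3_000_000]
    rows = {"m": ["BB", "AA", "BB"], "w": ["AA", "BB", "AA"]}
    res = map_cosegregating_interval(
        make_table(pos, rows, phenotypes={"m": "mutant", "w": "wt"})
    )
    assert res.run_markers == ["M1"]
    assert res.n_mutants_used == 1


def test_no_cosegregating_marker_returns_no_interval():
    pos = [1_000_000, 2_000_000]
    rows = {"i1": ["BB", "AA"], "i2": ["AA", "BB"]}
    res = map_cosegregating_interval(make_table(pos, rows))
    assert res.interval is None and not res.found


# ---------------------------------------------------------------------------
# narrowing
# ---------------------------------------------------------------------------


def narrowing_fixture():
    """Interval flanked at the printed positions, plus one recombinant."""
    pos = [57_939_715, 58_500_000, 59_200_000, 60_553_996]
    rows = {
        "i1": ["AA", "AA", "AA", "AB"],   # crossover on the right
        "i2": ["AB", "AA", "AA", "AA"],   # crossover on the left
        "i3": ["BB", "AA", "AA", "AA"],
    }
    table = make_table(pos, rows)
    interval = map_cosegregating_interval(table).interval
    return table, interval


def test_narrowing_replaces_the_failing_side():
    table, interval = narrowing_fixture()
    assert (interval.left, interval.right) == (57_939_715, 60_553_996)
    narrowed = narrow_interval(
        table,
        interval,
        "tomInf4732",
        59_966_064,
        {"i1": "AB", "i2": "AA", "i3": "AA"},
    )
    assert narrowed.right == 59_966_064
    assert narrowed.right_marker == "tomInf4732"
    assert narrowed.left == interval.left


def test_cosegregating_extra_marker_leaves_interval_unchanged():
    table, interval = narrowing_fixture()
    same = narrow_interval(
        table, interval, "x", 59_000_000, {"i1": "AA", "i2": "AA", "i3": "AA"}
    )
    assert same == interval


def test_opposite_side_narrowings_commute():
    table, interval = narrowing_fixture()
    right = ("r", 59_966_064, {"i1": "AB", "i2": "AA", "i3": "AA"})
    left = ("l", 58_200_000, {"i1": "AA", "i2": "AB", "i3": "AA"})
    a = narrow_interval(table, narrow_interval(table, interval, *right), *left)
    b = narrow_interval(table, narrow_interval(table, interval, *left), *right)
    assert a == b
    assert (a.left, a.right) == (58_200_000, 59_966_064)


def test_marker_outside_interval_rejected():
    table, interval = narrowing_fixture()
    with pytest.raises(CoordinateError):
        narrow_interval(table, interval, "x", 57_000_000, {"i1": "AA"})


def test_conflicting_recombinants_raise():
    table, interval = narrowing_fixture()
    with pytest.raises(AmbiguousNarrowingError):
        narrow_interval(
            table, interval, "x", 59_000_000, {"i1": "AB", "i2": "AB", "i3": "AA"}
        )


# ---------------------------------------------------------------------------
# lengths and gene overlap
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "left, right, expected",
    [
        (57_939_715, 60_553_996, 2.6),
        (57_939_715, 59_966_064, 2.0),
        (1_000_000, 1_000_100, 0.0),
    ],
)
def test_interval_length_mbp(left, right, expected):
    iv = CandidateInterval(chrom="chr4", left=left, right=right)
    assert interval_length_mbp(iv) == expected


def _gene(gid, start, end, chrom="chr4"):
    return GeneModel(gid, chrom, "+", ((start, end),), ((start, start + 2),))


def test_genes_in_interval_matches_enumeration():
    rng = np.random.default_rng(6)
    iv = CandidateInterval(chrom="chr4", left=5_000_000, right=6_000_000)
    genes = []
    for i in range(12):
        s = int(rng.integers(4_000_000, 7_000_000))
        genes.append(_gene(f"g{i}", s, s + 8_000))
    got = {g.gene_id for g in genes_in_interval(iv, genes)}
    expected = {g.gene_id for g in genes if g.end >= iv.left and g.start <= iv.right}
    assert got == expected


def test_gene_abutting_flank_is_included():
    iv = CandidateInterval(chrom="chr4", left=5_000_000, right=6_000_000)
    abutting = _gene("edge", 4_990_000, 5_000_000)
    outside = _gene("out", 4_990_000, 4_999_999)
    assert genes_in_interval(iv, [abutting, outside]) == [abutting]
    assert genes_in_interval(iv, []) == []


def test_parents_identical_everywhere_give_empty_panel():
    panel = pd.DataFrame({"chrom": ["c"] * 3, "pos": [1, 2, 3]}, index=["a", "b", "c"])
    calls = pd.Series(["AA", "AA", "AA"], index=panel.index)
    with pytest.warns(UserWarning):
        out = select_informative_markers(calls, calls, panel)
    assert len(out) == 0
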