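import numpy as np
import pytest

from archscan.alignment import MatchAlignment, strip_insert_columns
from archscan.architecture import (
    ArchitectureTemplate,
    Region,
    SegmentationError,
    SegmentationParams,
    TemplateError,
    length_distribution,
    region_lengths,
    segment_regions,
)
from archscan.conservation import conservation_profile


def template_for(n_db, n_var, n_a, n_l, n_b):
    s = 1
    spans = {}
    for name, w in (
        ("dna_binding", n_db), ("variable", n_var), ("alpha", n_a),
        ("linker", n_l), ("beta", n_b),
    ):
        spans[name] = (s, s + w - 1)
        s += w
    return ArchitectureTemplate.from_spans(spans)


def test_template_must_tile_in_order():
    with pytest.raises(TemplateError):
        ArchitectureTemplate(
            regions=(
                Region("dna_binding", 1, 10),
                Region("variable", 12, 20),  # gap at column 11
                Region("alpha", 21, 30),
                Region("linker", 31, 35),
                Region("beta", 36, 40),
            )
        )
    t = template_for(10, 10, 10, 5, 5)
    assert t.n_columns == 40
    assert t.region_of_column(25) == "alpha"


def test_template_allows_empty_variable_region():
    t = ArchitectureTemplate(
        regions=(
            Region("dna_binding", 1, 30),
            Region("variable", 31, 30),  # empty
            Region("alpha", 31, 60),
            Region("linker", 61, 70),
            Region("beta", 71, 100),
        )
    )
    assert t.region("variable").empty
    assert t.region("variable").n_columns == 0


def test_segmentation_recovers_planted_blocks(tight_family):
    spec, _, truth = tight_family
    cp = conservation_profile(truth.true_alignment)
    t = segment_regions(cp)
    assert t.provenance == "inferred"
    true_spans = {r.name: (r.start, r.end) for r in truth.template.regions}
    got = {r.name: (r.start, r.end) for r in t.regions}
    for name in ("variable", "alpha", "linker", "beta"):
        assert abs(got[name][0] - true_spans[name][0]) <= 2, name


def test_flat_profile_raises_segmentation_error():
    rng = np.random.default_rng(1)
    rows = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 80)) for _ in range(30)]
    a = MatchAlignment([f"r{i}" for i in range(30)], rows, [True] * 80)
    with pytest.raises(SegmentationError):
        segment_regions(conservation_profile(a))


def test_short_profile_rejected():
    a = MatchAlignment(["a", "b"], ["ACD", "ACD"], [True] * 3)
    with pytest.raises(SegmentationError):
        segment_regions(conservation_profile(a))


def test_segmentation_invariant_to_all_gap_rows(tight_family):
    """Appending all-gap rows rescales the penalized track uniformly and must
    not move any boundary."""
    _, _, truth = tight_family
    a = strip_insert_columns(truth.true_alignment)
    t1 = segment_regions(conservation_profile(a))
    padded = MatchAlignment(
        a.ids + ["gap1", "gap2"],
        a.rows + ["-" * a.n_match_columns] * 2,
        [True] * a.n_match_columns,
    )
    t2 = segment_regions(conservation_profile(padded))
    assert t1.to_frame().drop(columns="provenance").equals(
        t2.to_frame().drop(columns="provenance")
    )


def test_region_lengths_insert_free_counts_occupancies():
    t = template_for(2, 2, 2, 2, 2)
    a = MatchAlignment(["r0", "r1"], ["ACDEFGHIKL", "AC--FGHIKL"], [True] * 10)
    rec = region_lengths(a, t)
    r0 = rec[rec.sequence_id == "r0"].set_index("region")["length"]
    r1 = rec[rec.sequence_id == "r1"].set_index("region")["length"]
    assert r0.to_dict() == {
        "dna_binding": 2, "variable": 2, "alpha": 2, "linker": 2, "beta": 2
    }
    assert r1["variable"] == 0  # fully deleted region is absent
    assert r1.sum() == 8


def test_region_lengths_match_generator_truth_exactly(small_family):
    _, seqs, truth = small_family
    rec = region_lengths(strip_insert_columns(truth.true_alignment), truth.template)
    piv = rec.pivot(index="sequence_id", columns="region", values="length")
    for i, arch in enumerate(truth.true_architecture):
        sid = f"seq{i + 1:04d}"
        for name, (s, e) in arch.items():
            assert piv.loc[sid, name] == e - s + 1, (sid, name)


def test_region_lengths_sum_to_sequence_length(small_family):
    _, seqs, truth = small_family
    rec = region_lengths(strip_insert_columns(truth.true_alignment), truth.template)
    totals = rec.groupby("sequence_id")["length"].sum()
    for i, s in enumerate(seqs):
        assert totals[f"seq{i + 1:04d}"] == len(s.residues)


def test_region_lengths_rejects_mismatched_template(small_family):
    _, _, truth = small_family
    bad = template_for(2, 2, 2, 2, 2)
    with pytest.raises(TemplateError):
        region_lengths(truth.true_alignment, bad)


def _records(lengths, region="variable"):
    import pandas as pd

    return pd.DataFrame(
        {"sequence_id": [f"s{i}" for i in range(len(lengths))],
         "region": region, "length": lengths}
    )


def test_length_distribution_degenerate_and_quartile_cases():
    dist, mass = length_distribution(_records([50] * 8), "variable",
                                     range_of_interest=(40, 60))
    assert mass.fraction == 1.0 and mass.percent == 100
    dist, mass = length_distribution(_records([10, 20, 30, 40]), "variable",
                                     bin_width=10, range_of_interest=(15, 25))
    assert mass.fraction == 0.25 and mass.percent == 25
    assert dist.counts.sum() == 4
    assert dist.percentages.sum() == pytest.approx(100.0)


def test_range_mass_monotone_in_widening():
    rng = np.random.default_rng(0)
    lengths = rng.integers(0, 120, 300)
    rec = _records(list(lengths))
    prev = -1.0
    for lo, hi in [(45, 55), (40, 60), (30, 70), (0, 120)]:
        _, mass = length_distribution(rec, "variable", range_of_interest=(lo, hi))
        assert mass.fraction >= prev
        prev = mass.fraction


def test_length_distribution_requires_records():
    with pytest.raises(TemplateError):
        length_distribution(_records([1, 2]), "linker")


def test_range_mass_reports_raw_fraction_and_rounded_percent():
    _, mass = length_distribution(_records([50] * 63 + [5] * 37), "variable",
                                  range_of_interest=(40, 60))
    assert mass.fraction == pytest.approx(0.63)
    assert mass.percent == 63
    assert mass.n == 100
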