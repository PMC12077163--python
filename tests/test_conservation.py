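import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import jensenshannon

from archscan._alphabet import AMINO_ACIDS
from archscan.alignment import MatchAlignment, strip_insert_columns
from archscan.conservation import (
    ConservationParams,
    DistributionError,
    call_conserved,
    column_distribution,
    conservation_profile,
    gap_penalize,
    information_content,
    jsd_score,
    logo_matrix,
    residue_identity,
    window_smooth,
)

LOG2_20 = math.log2(20)
UNIFORM = np.full(20, 0.05)


def _jsd_reference(p, q, lam=0.5):
    """Independent double-loop KL evaluation (oracle)."""
    m = [lam * pi + (1 - lam) * qi for pi, qi in zip(p, q)]
    kl_pm = sum(pi * math.log2(pi / mi) for pi, mi in zip(p, m) if pi > 0)
    kl_qm = sum(qi * math.log2(qi / mi) for qi, mi in zip(q, m) if qi > 0)
    return lam * kl_pm + (1 - lam) * kl_qm


def _random_distributions(rng, k=20):
    p = rng.dirichlet(np.ones(k) * rng.uniform(0.2, 3.0))
    q = rng.dirichlet(np.ones(k) * rng.uniform(0.2, 3.0))
    return p, q


def test_jsd_identical_distributions_scores_zero():
    assert jsd_score(UNIFORM, UNIFORM) == pytest.approx(0.0, abs=1e-12)


def test_jsd_point_mass_vs_uniform_closed_form():
    """JSD(delta_G, uniform20) = 0.85499... (frozen from direct summation)."""
    p = np.zeros(20)
    p[AMINO_ACIDS.index("G")] = 1.0
    expected = _jsd_reference(p, UNIFORM)
    assert expected == pytest.approx(0.8549974, abs=1e-6)
    assert jsd_score(p, UNIFORM) == pytest.approx(expected, abs=1e-12)


def test_jsd_matches_independent_oracle_on_1000_pairs():
    rng = np.random.default_rng(123)
    for _ in range(1000):
        p, q = _random_distributions(rng)
        assert jsd_score(p, q) == pytest.approx(_jsd_reference(p, q), abs=1e-12)


def test_jsd_matches_scipy_jensenshannon():
    """Cross-check against scipy's JS distance (sqrt of the divergence)."""
    rng = np.random.default_rng(7)
    for _ in range(50):
        p, q = _random_distributions(rng)
        assert jsd_score(p, q) == pytest.approx(
            jensenshannon(p, q, base=2) ** 2, abs=1e-10
        )


def test_jsd_symmetric_at_half():
    rng = np.random.default_rng(42)
    for _ in range(25):
        p, q = _random_distributions(rng)
        assert jsd_score(p, q) == pytest.approx(jsd_score(q, p), abs=1e-12)


def test_jsd_rejects_unnormalized_input():
    with pytest.raises(DistributionError):
        jsd_score(np.full(20, 0.06), UNIFORM)


@pytest.mark.parametrize(
    "score,gap,expected",
    [(0.8, 0.0, 0.8), (0.8, 1.0, 0.0), (0.855, 0.25, 0.64125)],
)
def test_gap_penalize(score, gap, expected):
    assert gap_penalize(score, gap) == pytest.approx(expected, abs=1e-12)


def test_window_smooth_identity_and_interior_fixed_point():
    s = np.array([0.1, 0.9, 0.4, 0.7])
    assert np.allclose(window_smooth(s, 3, 0.0), s)
    # constant input is a fixed point wherever the flank is complete
    out = window_smooth(np.full(11, 0.3), 3, 0.5)
    assert np.allclose(out[3:-3], 0.3)
    assert np.all(out[:3] <= 0.3) and np.all(out[-3:] <= 0.3)


def test_window_smooth_hand_computed_case():
    assert np.allclose(window_smooth([0, 1, 0], w=1, lam_w=0.5), [0.25, 0.5, 0.25])


def test_window_smooth_preserves_unit_range():
    rng = np.random.default_rng(3)
    s = rng.uniform(0, 1, 60)
    out = window_smooth(s, 3, 0.5)
    assert np.all(out >= 0) and np.all(out <= 1)


@pytest.mark.parametrize(
    "p,expected",
    [
        (np.eye(20)[4], LOG2_20),
        (UNIFORM, 0.0),
        (0.5 * np.eye(20)[0] + 0.5 * np.eye(20)[1], LOG2_20 - 1.0),
    ],
)
def test_information_content_closed_forms(p, expected):
    assert information_content(p, 100) == pytest.approx(expected, abs=1e-12)


def test_information_content_small_sample_correction():
    p = np.eye(20)[0]
    corr = 19 / (2 * math.log(2) * 50)
    assert information_content(p, 50, correct_small_sample=True) == pytest.approx(
        LOG2_20 - corr, abs=1e-12
    )


def test_column_distribution_counts_gaps_and_x():
    p, gap, n = column_distribution("GGA-")
    assert p[AMINO_ACIDS.index("G")] == pytest.approx(2 / 3)
    assert p[AMINO_ACIDS.index("A")] == pytest.approx(1 / 3)
    assert gap == pytest.approx(0.25)
    assert n == 3
    p2, gap2, _ = column_distribution("GGAX")
    assert gap2 == pytest.approx(0.25)
    assert np.allclose(p, p2)


def test_column_distribution_all_gap_flagged():
    p, gap, n = column_distribution("--..")
    assert p is None and gap == 1.0 and n == 0


def test_column_distribution_weighted():
    p, gap, _ = column_distribution("GGA-", weights=[2, 1, 1, 0])
    assert p[AMINO_ACIDS.index("G")] == pytest.approx(0.75)
    assert gap == 0.0


def test_bits_and_jsd_rank_concordantly_on_peak_mixtures():
    """Both scores strictly increase with the point-mass weight alpha."""
    alphas = np.linspace(0.05, 0.95, 10)
    jsds, bits = [], []
    for a in alphas:
        p = a * np.eye(20)[7] + (1 - a) * UNIFORM
        jsds.append(jsd_score(p, UNIFORM))
        bits.append(information_content(p, 1000))
    assert all(b > a for a, b in zip(jsds, jsds[1:]))
    assert all(b >= a for a, b in zip(bits, bits[1:]))
    assert bits[-1] > bits[0]


def test_profile_invariants_on_sampled_family(small_family):
    _, _, truth = small_family
    cp = conservation_profile(truth.true_alignment)
    assert np.all(cp.jsd_raw >= 0) and np.all(cp.jsd_raw <= 1)
    assert np.all(cp.jsd_penalized <= cp.jsd_raw + 1e-12)
    assert np.all(cp.bits >= 0) and np.all(cp.bits <= LOG2_20)
    for j in range(cp.n_columns):
        if not cp.undefined[j]:
            assert cp.freqs[j].sum() == pytest.approx(1.0, abs=1e-9)


def test_call_conserved_empty_on_uniform_columns():
    rng = np.random.default_rng(0)
    rows = ["".join(rng.choice(list(AMINO_ACIDS), 60)) for _ in range(40)]
    a = MatchAlignment([f"r{i}" for i in range(40)], rows, [True] * 60)
    assert call_conserved(conservation_profile(a)) == []


def test_call_conserved_includes_planted_invariant_sites(small_family):
    spec, _, truth = small_family
    cp = conservation_profile(truth.true_alignment)
    called = set(call_conserved(cp))
    planted = {s.column for s in spec.invariant_sites if s.identity >= 0.95}
    assert planted <= called


def test_logo_matrix_heights_sum_to_bits(small_family):
    _, _, truth = small_family
    cp = conservation_profile(truth.true_alignment)
    lm = logo_matrix(cp)
    assert np.allclose(lm.sum(axis=1).to_numpy(), cp.bits, atol=1e-9)


def test_logo_matrix_degenerate_columns():
    a = MatchAlignment(
        [f"r{i}" for i in range(20)],
        ["G" + AMINO_ACIDS[i] for i in range(20)],
        [True, True],
    )
    lm = logo_matrix(conservation_profile(a))
    assert lm.loc[1, "G"] == pytest.approx(LOG2_20, abs=1e-9)  # invariant column
    assert np.allclose(lm.loc[2].to_numpy(), 0.0, atol=1e-9)   # uniform column


def test_residue_identity_toy_and_all_gap():
    rows = ["G"] * 49 + ["A"]
    a = MatchAlignment([f"r{i}" for i in range(50)], rows, [True])
    assert residue_identity(a, 1, "G") == pytest.approx(98.0)
    gap = MatchAlignment(["r0", "r1"], ["-", "-"], [True])
    assert residue_identity(gap, 1, "G") == 0.0
    with pytest.raises(DistributionError):
        residue_identity(a, 1, "B")


def test_all_gap_column_scores_zero():
    a = MatchAlignment(["r0", "r1"], ["G-A", "G-C"], [True] * 3)
    cp = conservation_profile(a)
    assert cp.undefined[1]
    assert cp.jsd_raw[1] == 0.0 and cp.bits[1] == 0.0
    assert cp.consensus[1] == (None, 0.0)


@settings(max_examples=60, derandomize=True)
@given(
    st.lists(st.floats(0, 1), min_size=3, max_size=40),
    st.integers(0, 4),
    st.floats(0, 1),
)
def test_window_smooth_stays_in_range_property(scores, w, lam_w):
    out = window_smooth(scores, w, lam_w)
    assert len(out) == len(scores)
    assert np.all(out >= -1e-12) and np.all(out <= 1 + 1e-12)
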