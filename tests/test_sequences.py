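"""Sequence-grammar metrics: compositions, kappa/omega, aromatic clustering,
rolling profiles and patterning z-scores."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest

from idrmap.sequences import (
    EIGHT_CLASS,
    SIX_CLASS,
    ProteinSequence,
    ResidueGrouping,
    aromatic_clustering,
    composition_fractions,
    disorder_promoting_fraction,
    fcr_ncpr,
    ideal_positions,
    kappa,
    omega_pro,
    patterning_zscores,
    rolling_profile,
)
from idrmap.simulate import gen_sequence

# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def blob_delta_oracle(mask_plus, mask_minus, g):
    """Direct enumeration of the blob-variance statistic."""
    n = len(mask_plus)

    def sigma(fp, fm):
        return 0.0 if fp + fm == 0 else (fp - fm) ** 2 / (fp + fm)

    s_all = sigma(sum(mask_plus) / n, sum(mask_minus) / n)
    devs = []
    for i in range(n - g + 1):
        fp = sum(mask_plus[i:i + g]) / g
        fm = sum(mask_minus[i:i + g]) / g
        devs.append((sigma(fp, fm) - s_all) ** 2)
    return float(np.mean(devs))


def pair_inverse_distance_oracle(positions):
    vals = [1.0 / abs(i - j) for i, j in itertools.combinations(positions, 2)]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# compositions
# ---------------------------------------------------------------------------


def test_composition_direct_counts():
    seq = ProteinSequence("t", "FYAA")
    grouping = ResidueGrouping("aro", (("aromatic", frozenset("FYW")),))
    frac = composition_fractions(seq, grouping)
    assert frac["aromatic"] == 0.5
    assert frac["other"] == 0.5


def test_composition_matches_letter_count_oracle():
    seq = gen_sequence(length=200, seed=7)
    counts = Counter(seq.residues)
    for grouping in (SIX_CLASS, EIGHT_CLASS):
        frac = composition_fractions(seq, grouping)
        for label, members in grouping.classes:
            expected = sum(counts[r] for r in members) / len(seq)
            assert frac[label] == pytest.approx(expected, abs=1e-12)


def test_full_coverage_fractions_sum_to_one():
    seq = gen_sequence(length=150, seed=3)
    frac = composition_fractions(seq, EIGHT_CLASS)
    assert sum(frac.values()) == pytest.approx(1.0, abs=1e-9)


def test_fcr_ncpr_symmetry_and_bound():
    fcr, ncpr = fcr_ncpr(ProteinSequence("t", "EKEK"))
    assert fcr == 1.0 and ncpr == 0.0
    for seed in range(5):
        seq = gen_sequence(length=120, seed=seed)
        fcr, ncpr = fcr_ncpr(seq)
        assert abs(ncpr) <= fcr <= 1.0


def test_disorder_promoting_fraction_extremes():
    assert disorder_promoting_fraction(ProteinSequence("t", "PPPP")) == 1.0
    assert disorder_promoting_fraction(ProteinSequence("t", "WWWW")) == 0.0
    seq = gen_sequence(length=150, seed=11)
    expected = sum(1 for r in seq.residues if r in "TAGRDHQKSEP") / len(seq)
    assert disorder_promoting_fraction(seq) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# kappa / omega
# ---------------------------------------------------------------------------


def test_kappa_fully_segregated_is_one():
    assert kappa(ProteinSequence("t", "EEEEEKKKKK")) == pytest.approx(1.0)


def test_kappa_alternating_is_small():
    assert kappa(ProteinSequence("t", "EKEKEKEKEK")) < 0.1


def test_kappa_undefined_without_both_charges():
    assert math.isnan(kappa(ProteinSequence("t", "AAAAAA")))
    assert math.isnan(kappa(ProteinSequence("t", "KKKKKK")))


def test_kappa_matches_blob_oracle():
    from idrmap.sequences import _delta_ternary

    seqs = ["EKEKEKEKEK", "EEKKAAEEKK", "KAEKAEKAEAKE"]
    for s in seqs:
        plus = np.array([1.0 if c == "K" else 0.0 for c in s])
        minus = np.array([1.0 if c == "E" else 0.0 for c in s])
        for g in (5, 6):
            assert _delta_ternary(plus, minus, g) == pytest.approx(
                blob_delta_oracle(plus.tolist(), minus.tolist(), g))


def test_kappa_reversal_invariant():
    for seed in range(5):
        seq = gen_sequence(length=80, seed=seed)
        rev = ProteinSequence(seq.id, seq.residues[::-1])
        k1, k2 = kappa(seq), kappa(rev)
        if math.isnan(k1):
            assert math.isnan(k2)
        else:
            assert k1 == pytest.approx(k2, abs=1e-12)
        o1, o2 = omega_pro(seq), omega_pro(rev)
        assert o1 == pytest.approx(o2, abs=1e-12)


def test_omega_fully_segregated_and_alternating():
    assert omega_pro(ProteinSequence("t", "PPPPPAAAAA")) == pytest.approx(1.0)
    assert omega_pro(ProteinSequence("t", "PAPAPAPAPA")) < 0.1


def test_omega_undefined_without_class_members():
    # no proline and no charge: the {charged + Pro} class is empty
    assert math.isnan(omega_pro(ProteinSequence("t", "AAAGGGSSS")))


# ---------------------------------------------------------------------------
# aromatic clustering
# ---------------------------------------------------------------------------


def test_aromatic_norm_zero_at_ideal_positions():
    length, k = 60, 5
    pos = set(ideal_positions(length, k).tolist())
    seq = "".join("F" if (i + 1) in pos else "A" for i in range(length))
    res = aromatic_clustering(ProteinSequence("t", seq))
    assert res.norm == pytest.approx(0.0, abs=1e-12)


def test_aromatic_norm_one_when_clustered():
    seq = "A" * 20 + "FFFFF" + "A" * 20
    res = aromatic_clustering(ProteinSequence("t", seq))
    assert res.norm == pytest.approx(1.0, abs=1e-12)


def test_aromatic_raw_matches_pair_sum_oracle():
    seq = ProteinSequence("t", "FAAFAAAF")
    res = aromatic_clustering(seq)
    assert res.raw == pytest.approx(pair_inverse_distance_oracle([1, 4, 8]))
    assert res.ideal == pytest.approx(pair_inverse_distance_oracle([1, 4, 7]))
    assert res.clustered == pytest.approx(
        pair_inverse_distance_oracle([1, 2, 3]))
    assert res.norm == pytest.approx(
        (res.raw - res.ideal) / (res.clustered - res.ideal))


def test_aromatic_undefined_cases():
    assert math.isnan(aromatic_clustering(ProteinSequence("t", "FAAA")).norm)
    # length == aromatic count: ideal == clustered
    assert math.isnan(aromatic_clustering(ProteinSequence("t", "FFFF")).norm)


def test_aromatic_norm_invariances():
    base = "A" * 10 + "F" + "A" * 5 + "Y" + "A" * 3 + "W" + "A" * 10
    res = aromatic_clustering(ProteinSequence("t", base))
    rev = aromatic_clustering(ProteinSequence("t", base[::-1]))
    swapped = aromatic_clustering(
        ProteinSequence("t", base.replace("Y", "F").replace("W", "F")))
    assert res.norm == pytest.approx(rev.norm, abs=1e-12)
    assert res.norm == pytest.approx(swapped.norm, abs=1e-12)


def test_aromatic_his_config():
    seq = ProteinSequence("t", "HAAAAAAAAH")
    assert math.isnan(aromatic_clustering(seq).norm)
    assert math.isfinite(aromatic_clustering(seq, include_his=True).raw)


# ---------------------------------------------------------------------------
# rolling profiles
# ---------------------------------------------------------------------------


def test_rolling_constant_property():
    seq = ProteinSequence("t", "V" * 100)
    prof = rolling_profile(seq, "hydropathy", window=30)
    assert np.allclose(prof.values, 4.2)
    assert len(prof.values) == 71
    lys = ProteinSequence("t", "K" * 40)
    assert np.allclose(rolling_profile(lys, "charge", 30).values, 1.0)


def test_rolling_matches_prefix_sum_oracle():
    seq = gen_sequence(length=40, seed=5)
    prof = rolling_profile(seq, "hydropathy", window=30)
    from idrmap.sequences import KYTE_DOOLITTLE

    vals = [KYTE_DOOLITTLE[r] for r in seq.residues]
    for i, v in enumerate(prof.values):
        assert v == pytest.approx(np.mean(vals[i:i + 30]), abs=1e-12)


def test_rolling_centers_in_construct_coordinates():
    seq = ProteinSequence("t", "A" * 40, numbering_offset=330)
    prof = rolling_profile(seq, "charge", window=5)
    assert prof.centers[0] == 332.0
    assert prof.centers[-1] == 367.0


def test_rolling_window_too_large():
    with pytest.raises(ValueError):
        rolling_profile(ProteinSequence("t", "AAAA"), "charge", window=5)


# ---------------------------------------------------------------------------
# patterning z-scores
# ---------------------------------------------------------------------------

ALL_CLASS_SEQ = "ACDEFGHIKLMNPQRSTVWY" * 4


def test_zscore_matrix_enumerates_36_features():
    zm = patterning_zscores(ProteinSequence("t", ALL_CLASS_SEQ),
                            n_shuffles=200, seed=0)
    assert zm.n_features == 36
    assert zm.z.shape == (8, 8)
    # 6 self-pair features on the diagonal, 30 distinct cross pairs
    assert len(zm.labels) == 8
    assert np.allclose(zm.z, zm.z.T, equal_nan=True)


def test_zscore_deterministic_under_seed():
    seq = ProteinSequence("t", ALL_CLASS_SEQ)
    z1 = patterning_zscores(seq, n_shuffles=200, seed=42)
    z2 = patterning_zscores(seq, n_shuffles=200, seed=42)
    assert np.array_equal(z1.z, z2.z, equal_nan=True)


def test_zscore_homopolymer_all_undefined():
    zm = patterning_zscores(ProteinSequence("t", "A" * 60),
                            n_shuffles=100, seed=0)
    assert np.isnan(zm.z).all()


def test_zscore_absent_class_undefined():
    # no aromatics: every feature touching the aromatic class is NaN
    seq = ProteinSequence("t", ("ACDEGHIKLMNPQRSTV" * 5))
    zm = patterning_zscores(seq, n_shuffles=150, seed=0)
    aro = zm.labels.index("aromatic")
    assert np.isnan(zm.z[aro, :]).all()
    assert np.isnan(zm.z[:, aro]).all()


def test_zscore_random_sequences_are_unremarkable():
    """A random sequence scored against its own null: |z| < 4 for all
    defined features with high probability."""
    ok = 0
    total = 0
    for seed in range(10):
        seq = gen_sequence(length=120, seed=seed)
        zm = patterning_zscores(seq, n_shuffles=1000, seed=seed + 100)
        defined = np.isfinite(zm.z)
        total += 1
        ok += bool(np.all(np.abs(zm.z[defined]) < 4))
    assert ok >= 9
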