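"""Entropy core: marginalization, identities, sI, registry — vs independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from codoninfo.genetic_code import CODONS, CodonPart
from codoninfo.info_measures import (
    MAIN_MEASURES,
    Distribution,
    compute_measure_vector,
    conditional_entropy,
    entropy,
    joint,
    joint_entropy,
    marginalize,
    measure_matrix,
    mutual_information,
    non_redundant_pairs,
    pair_label,
    registry_preset,
    standardized_mi,
)

import _oracles as orc

# frozen constants, computed beforehand with the brute-force oracle
H_AA_UNIFORM = 4.218139062230
H_T_GIVEN_AA_UNIFORM = 1.563110937770
H_F_GIVEN_AA_UNIFORM = 0.258270703328
SI_AA_S_UNIFORM = 0.935432324168
SI_AA_T_UNIFORM = 0.218444531115


def rcf_strategy():
    # positive weights normalized to a valid RCF
    return st.lists(
        st.floats(min_value=1e-6, max_value=1.0), min_size=64, max_size=64
    ).map(lambda w: np.array(w) / np.sum(w))


# ---------------------------------------------------------------------------
# marginalization and joints

def test_marginalize_uniform_bases(uniform_rcf, code):
    d = marginalize(uniform_rcf, CodonPart.F, code)
    np.testing.assert_allclose(d.p, 0.25)


def test_marginalize_uniform_aa_family_sizes(uniform_rcf, code):
    d = marginalize(uniform_rcf, CodonPart.AA, code)
    p = dict(zip(d.labels, d.p))
    assert p["Leu"] == pytest.approx(6 / 64)
    assert p["Trp"] == pytest.approx(1 / 64)
    assert p["Stop"] == pytest.approx(3 / 64)
    assert sum(p.values()) == pytest.approx(1.0, abs=1e-12)


def test_marginal_is_sum_over_preimage(random_rcf, code):
    r = random_rcf()
    d = marginalize(r, CodonPart.F, code)
    pg = d.p[list(d.labels).index("G")]
    assert pg == pytest.approx(
        sum(p for c, p in zip(CODONS, r) if c[0] == "G"), abs=1e-15
    )


def test_unnormalized_input_rejected(code):
    with pytest.raises(ValueError, match="sums to"):
        marginalize(np.full(64, 1.0), CodonPart.F, code)


def test_joint_uniform_f_t_independent(uniform_rcf, code):
    j = joint(uniform_rcf, CodonPart.F, CodonPart.T, code)
    np.testing.assert_allclose(j.p, 1 / 16)


def test_joint_aa_codon_is_diagonal_in_translation(random_rcf, code):
    r = random_rcf()
    j = joint(r, CodonPart.AA, CodonPart.CODON, code)
    for yi, c in enumerate(j.labels_y):
        for xi, a in enumerate(j.labels_x):
            expect = r[CODONS.index(c)] if code.table[c] == a else 0.0
            assert j.p[xi, yi] == pytest.approx(expect, abs=1e-15)


def test_joint_uniform_trp_g_cell(uniform_rcf, code):
    j = joint(uniform_rcf, CodonPart.AA, CodonPart.T, code)
    cell = j.p[j.labels_x.index("Trp"), j.labels_y.index("G")]
    assert cell == pytest.approx(1 / 64)  # only TGG codes Trp


def test_joint_marginals_consistent(random_rcf, code):
    r = random_rcf()
    j = joint(r, CodonPart.AA, CodonPart.ST, code)
    np.testing.assert_allclose(
        j.marginal_x().p, marginalize(r, CodonPart.AA, code).p, atol=1e-12
    )
    np.testing.assert_allclose(
        j.marginal_y().p, marginalize(r, CodonPart.ST, code).p, atol=1e-12
    )


def test_identical_parts_rejected(uniform_rcf, code):
    with pytest.raises(ValueError, match="distinct"):
        joint(uniform_rcf, CodonPart.F, CodonPart.F, code)


# ---------------------------------------------------------------------------
# entropy

@pytest.mark.parametrize(
    "p,h",
    [
        ([0.25, 0.25, 0.25, 0.25], 2.0),
        ([1.0, 0.0, 0.0, 0.0], 0.0),
        ([0.5, 0.25, 0.25], 1.5),
    ],
)
def test_entropy_closed_forms(p, h):
    assert entropy(np.array(p)) == pytest.approx(h, abs=1e-12)


def test_entropy_uniform_aa_matches_family_size_oracle(uniform_rcf, code):
    h = entropy(marginalize(uniform_rcf, CodonPart.AA, code))
    assert h == pytest.approx(H_AA_UNIFORM, abs=1e-9)


def test_entropy_agrees_with_scipy(random_rcf):
    for _ in range(10):
        p = random_rcf()
        assert entropy(p) == pytest.approx(
            float(sps.entropy(p, base=2)), abs=1e-12
        )


def test_negative_probability_rejected():
    with pytest.raises(ValueError):
        entropy(np.array([0.5, 0.6, -0.1]))


# ---------------------------------------------------------------------------
# joint / conditional / mutual information identities

def test_aa_determined_by_codon(random_rcf, code):
    r = random_rcf()
    j = joint(r, CodonPart.AA, CodonPart.CODON, code)
    assert conditional_entropy(j) == pytest.approx(0.0, abs=1e-9)
    assert mutual_information(j) == pytest.approx(
        entropy(marginalize(r, CodonPart.AA, code)), abs=1e-9
    )


def test_conditional_entropy_decomposition(random_rcf, code):
    # H(T|aa) computed two ways: via joint minus marginal, and as the
    # mixture sum_a p(a) * H(third base within family a)
    r = random_rcf()
    j = joint(r, CodonPart.T, CodonPart.AA, code)
    direct = conditional_entropy(j)
    mix = 0.0
    for a in code.signals:
        pa = sum(p for c, p in zip(CODONS, r) if code.table[c] == a)
        if pa <= 0:
            continue
        within: dict = {}
        for c, p in zip(CODONS, r):
            if code.table[c] == a:
                within[c[2]] = within.get(c[2], 0.0) + p / pa
        mix += pa * orc.entropy_bits(within.values())
    assert direct == pytest.approx(mix, abs=1e-9)


def test_uniform_conditional_entropies_match_frozen_oracle(uniform_rcf, code):
    jt = joint(uniform_rcf, CodonPart.T, CodonPart.AA, code)
    jf = joint(uniform_rcf, CodonPart.F, CodonPart.AA, code)
    assert conditional_entropy(jt) == pytest.approx(H_T_GIVEN_AA_UNIFORM, abs=1e-9)
    assert conditional_entropy(jf) == pytest.approx(H_F_GIVEN_AA_UNIFORM, abs=1e-9)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(rcf_strategy())
def test_information_identities_on_random_rcfs(r):
    code = None
    jxy = joint(r, CodonPart.S, CodonPart.FT, code)
    jyx = joint(r, CodonPart.FT, CodonPart.S, code)
    hx = entropy(jxy.marginal_x())
    hy = entropy(jxy.marginal_y())
    hxy = joint_entropy(jxy)
    # symmetry of joint entropy and MI
    assert hxy == pytest.approx(joint_entropy(jyx), abs=1e-9)
    assert mutual_information(jxy) == pytest.approx(mutual_information(jyx), abs=1e-9)
    # H(X|Y) = H(X,Y) - H(Y); mutual consistency
    assert conditional_entropy(jxy) == pytest.approx(hxy - hy, abs=1e-12)
    assert hx + hy - hxy == pytest.approx(
        hx - conditional_entropy(jxy), abs=1e-9
    )
    # conditioning reduces entropy
    assert conditional_entropy(jxy) <= hx + 1e-9


@settings(max_examples=30, deadline=None, derandomize=True)
@given(rcf_strategy())
def test_entropy_bounds_and_chain_rule(r):
    mv = compute_measure_vector(r)
    for part, name in [
        (CodonPart.CODON, "H(codon)"), (CodonPart.AA, "H(aa)"),
        (CodonPart.FS, "H(FS)"), (CodonPart.F, "H(F)"), (CodonPart.T, "H(T)"),
    ]:
        assert -1e-12 <= mv[name] <= part.max_entropy + 1e-9
    # chain rule: H(codon) = H(FS) + H(T|FS) = H(F) + H(S|F) + H(T|FS)
    assert mv["H(codon)"] == pytest.approx(mv["H(FS)"] + mv["H(T|FS)"], abs=1e-9)
    assert mv["H(codon)"] == pytest.approx(
        mv["H(F)"] + mv["H(S|F)"] + mv["H(T|FS)"], abs=1e-9
    )


def test_max_entropy_attained_only_at_uniform(random_rcf):
    r = random_rcf()
    assert entropy(marginalize(r, CodonPart.CODON)) < 6.0
    u = np.full(64, 1 / 64)
    assert entropy(marginalize(u, CodonPart.CODON)) == pytest.approx(6.0, abs=1e-12)


# ---------------------------------------------------------------------------
# standardized MI

def test_si_zero_at_independence(uniform_rcf):
    assert standardized_mi(uniform_rcf, CodonPart.F, CodonPart.T) == pytest.approx(
        0.0, abs=1e-12
    )


def test_si_one_under_full_dependence():
    # uniform over the 16 codons whose third base equals the second:
    # T is a deterministic function of S with H(T) = H(S) = 2 bits
    r = np.array([1 / 16 if c[1] == c[2] else 0.0 for c in CODONS])
    assert standardized_mi(r, CodonPart.S, CodonPart.T) == pytest.approx(1.0, abs=1e-12)


def test_si_uniform_frozen_values(uniform_rcf):
    assert standardized_mi(uniform_rcf, CodonPart.AA, CodonPart.S) == pytest.approx(
        SI_AA_S_UNIFORM, abs=1e-9
    )
    assert standardized_mi(uniform_rcf, CodonPart.AA, CodonPart.T) == pytest.approx(
        SI_AA_T_UNIFORM, abs=1e-9
    )


def test_si_redundant_pair_rejected(uniform_rcf):
    with pytest.raises(ValueError, match="redundant"):
        standardized_mi(uniform_rcf, CodonPart.F, CodonPart.FS)


def test_si_point_mass_is_zero():
    r = np.zeros(64)
    r[0] = 1.0
    assert standardized_mi(r, CodonPart.F, CodonPart.T) == 0.0


def test_si_normalizer_options(random_rcf):
    r = random_rcf()
    vals = {
        n: standardized_mi(r, CodonPart.AA, CodonPart.ST, normalizer=n)
        for n in ("min", "sqrt", "max", "joint")
    }
    assert vals["min"] >= vals["sqrt"] >= vals["max"] >= vals["joint"]
    for v in vals.values():
        assert 0.0 <= v <= 1.0
    with pytest.raises(ValueError):
        standardized_mi(r, CodonPart.AA, CodonPart.ST, normalizer="bogus")


def test_non_redundant_pairs_roster():
    pairs = non_redundant_pairs()
    assert len(pairs) == 15
    labels = {pair_label(x, y) for x, y in pairs}
    assert "aa.T" in labels
    assert "ST.F" in labels and "FS.T" in labels and "FT.S" in labels
    assert labels >= {"aa.F", "aa.S", "aa.FS", "aa.FT", "aa.ST",
                      "FS.FT", "FS.ST", "FT.ST", "F.S", "F.T", "S.T"}
    # containment pairs are excluded
    for bad in ("FS.F", "FS.S", "FT.F", "FT.T", "ST.S", "ST.T"):
        assert bad not in labels


# ---------------------------------------------------------------------------
# registry and measure vectors

def test_registry_presets_sizes():
    assert len(registry_preset("main8")) == 8
    assert registry_preset("main8").names == list(MAIN_MEASURES)
    assert len(registry_preset("extended54")) == 54
    assert len(registry_preset("sI15")) == 15
    with pytest.raises(ValueError):
        registry_preset("bogus")


def test_uniform_measure_vector_attains_maxima(uniform_rcf):
    mv = compute_measure_vector(uniform_rcf, registry_preset("main8"))
    assert mv["H(codon)"] == pytest.approx(6.0, abs=1e-12)
    for name in ("H(F)", "H(S)", "H(T)"):
        assert mv[name] == pytest.approx(2.0, abs=1e-12)
    for name in ("H(FS)", "H(FT)", "H(ST)"):
        assert mv[name] == pytest.approx(4.0, abs=1e-12)
    assert mv["H(aa)"] == pytest.approx(H_AA_UNIFORM, abs=1e-9)


def test_measure_vector_contract(random_rcf):
    reg = registry_preset("extended54")
    mv = compute_measure_vector(random_rcf(), reg)
    assert len(mv.values) == len(reg)
    assert all(np.isfinite(v) for v in mv.values.values())


def test_every_measure_matches_naive_oracle_on_random_rcfs(random_rcf):
    # the spec of correctness: a plain-python loop over all 64 codons
    reg = registry_preset("extended54")
    si = registry_preset("sI15")
    for _ in range(100):
        r = random_rcf()
        mv = compute_measure_vector(r, reg)
        for name, value in mv.values.items():
            assert value == pytest.approx(orc.measure(r, name), abs=1e-12), name
        sv = compute_measure_vector(r, si)
        for name, value in sv.values.items():
            assert value == pytest.approx(orc.measure(r, name), abs=1e-12), name


def test_measure_matrix_scale_invariance(toy_dataset):
    # counts and RCFs give identical measure vectors
    import copy

    m1 = measure_matrix(toy_dataset)
    scaled = copy.deepcopy(toy_dataset)
    for rec in scaled:
        rec.freqs = rec.freqs / rec.freqs.sum()
    m2 = measure_matrix(scaled)
    np.testing.assert_array_equal(m1.to_numpy(), m2.to_numpy())


def test_distribution_validation():
    with pytest.raises(ValueError):
        Distribution(CodonPart.F, ("T", "C", "A", "G"), np.array([0.5, 0.5, 0.5, -0.5]))
    with pytest.raises(ValueError):
        Distribution(CodonPart.F, ("T", "C", "A", "G"), np.array([0.3, 0.3, 0.3, 0.3]))
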