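import numpy as np
import pytest

from epiblup.coding import additive_W, dominance_W, epistasis_W
from epiblup.grm import (
    MODEL_I_TYPES,
    MODEL_II_TYPES,
    agerm,
    agerm_numerator,
    assemble,
    egerm,
    egerm_numerator,
    grm_direct,
    intra_inter,
    read_grm,
    read_grm_tsv,
    write_grm,
    write_grm_tsv,
)
from epiblup.simgen import SimConfig, simulate_genotypes

from conftest import make_random_geno

ALL_TYPES = ("AA", "AD", "DD", "AAA", "AAD", "ADD", "DDD")


# ordered distinct tuples per unordered column of the explicit model matrix
_ORBITS = {"AA": 2, "DD": 2, "AD": 1, "AAA": 6, "DDD": 6, "AAD": 2, "ADD": 2}


def _brute_tuple_numerator(W_a, W_d, effect_type, which):
    """Brute-force numerator over ordered locus tuples: 'all', 'distinct', or
    'repeated' (at least one repeated index)."""
    import itertools

    mats = [{"A": W_a, "D": W_d}[ch] for ch in effect_type]
    n, m = W_a.shape
    out = np.zeros((n, n))
    for tup in itertools.product(range(m), repeat=len(mats)):
        distinct = len(set(tup)) == len(tup)
        if which == "distinct" and not distinct:
            continue
        if which == "repeated" and distinct:
            continue
        col = np.ones(n)
        for M, i in zip(mats, tup):
            col = col * M[:, i]
        out += np.outer(col, col)
    return out


def test_grm_direct_fixture(tiny_geno):
    S = grm_direct(additive_W(tiny_geno)).S
    np.testing.assert_allclose(S, [[1.5, 0, -1.5], [0, 0, 0], [-1.5, 0, 1.5]], atol=1e-14)


def test_agerm_arithmetic_fixture():
    N_A = np.array([[2.0, 0, -2], [0, 0, 0], [-2, 0, 2]])
    num = agerm_numerator(N_A, None, "AA")
    np.testing.assert_allclose(num, [[4, 0, 4], [0, 0, 0], [4, 0, 4]])
    g = agerm(N_A, None, "AA")
    assert g.k == pytest.approx(8 / 3)
    np.testing.assert_allclose(g.S, num * 3 / 8)
    np.testing.assert_allclose(
        agerm_numerator(N_A, None, "AAA"), [[8, 0, -8], [0, 0, 0], [-8, 0, 8]]
    )


def test_agerm_normalize_first_invariance(random_geno_factory):
    """Hadamard of normalized additive matrices, renormalized, equals the
    numerator-first construction (proportionality)."""
    geno = random_geno_factory(8, 10, seed=3)
    mm = additive_W(geno)
    N_A = mm.W @ mm.W.T
    direct = agerm(N_A, None, "AA").S
    S_A = grm_direct(mm).S
    had = S_A * S_A
    renorm = had / (np.trace(had) / had.shape[0])
    np.testing.assert_allclose(direct, renorm, atol=1e-12)


@pytest.mark.parametrize("effect_type", ALL_TYPES)
@pytest.mark.parametrize("seed", range(5))
def test_egerm_equals_explicit_model_matrix(effect_type, seed):
    """Closed-form distinct-locus numerators equal the brute-force pair/triple
    model-matrix cross-products."""
    rng = np.random.default_rng(seed)
    n, m = int(rng.integers(6, 9)), int(rng.integers(6, 9))
    geno = make_random_geno(n, m, seed=seed + 50, n_chrom=2)
    A, D = additive_W(geno), dominance_W(geno)
    Wx = epistasis_W(A, D, effect_type)
    explicit = Wx.W @ Wx.W.T
    closed = egerm_numerator(A.W, D.W, effect_type)
    scale = max(np.abs(explicit).max(), 1e-30)
    assert np.abs(explicit - closed).max() / scale < 1e-10


@pytest.mark.parametrize("effect_type", ALL_TYPES)
def test_agerm_structure_vs_brute_force(effect_type):
    """The Hadamard numerator is the sum over ALL ordered locus tuples; its
    excess over the distinct-locus numerator is exactly the brute-force
    repeated-index (intra-locus) contribution, with nonnegative diagonal."""
    geno = make_random_geno(7, 7, seed=99, n_chrom=2)
    A, D = additive_W(geno), dominance_W(geno)
    N_A, N_D = A.W @ A.W.T, D.W @ D.W.T
    had = agerm_numerator(N_A, N_D, effect_type)
    scale = np.abs(had).max()
    np.testing.assert_allclose(
        had, _brute_tuple_numerator(A.W, D.W, effect_type, "all"),
        rtol=1e-10, atol=1e-10 * scale)
    distinct_ordered = _ORBITS[effect_type] * egerm_numerator(A.W, D.W, effect_type)
    np.testing.assert_allclose(
        distinct_ordered, _brute_tuple_numerator(A.W, D.W, effect_type, "distinct"),
        rtol=1e-10, atol=1e-10 * scale)
    repeated = had - distinct_ordered
    np.testing.assert_allclose(
        repeated, _brute_tuple_numerator(A.W, D.W, effect_type, "repeated"),
        rtol=1e-10, atol=1e-10 * scale)
    assert np.diag(repeated).min() > -1e-10 * scale


def test_agerm_minus_egerm_diagonal_nonnegative():
    geno = make_random_geno(8, 8, seed=123, n_chrom=2)
    A, D = additive_W(geno), dominance_W(geno)
    N_A, N_D = A.W @ A.W.T, D.W @ D.W.T
    for t in ALL_TYPES:
        diff = agerm_numerator(N_A, N_D, t) - egerm_numerator(A.W, D.W, t)
        assert np.diag(diff).min() > -1e-10


def test_single_snp_has_no_pairs():
    geno = make_random_geno(6, 1, seed=5, n_chrom=1)
    A = additive_W(geno)
    assert np.allclose(egerm_numerator(A.W, None, "AA"), 0.0)


@pytest.mark.parametrize("method", ["agerm", "egerm"])
@pytest.mark.parametrize("effect_type", ["AA", "AD", "DD"])
def test_partition_identity(method, effect_type):
    """intra numerator + inter numerator = whole-genome numerator exactly."""
    geno = make_random_geno(8, 8, seed=11, n_chrom=2)
    A, D = additive_W(geno), dominance_W(geno)
    gi, ge = intra_inter(A.W, D.W, geno.chromosomes, effect_type, method=method)
    if method == "agerm":
        whole = agerm_numerator(A.W @ A.W.T, D.W @ D.W.T, effect_type)
    else:
        whole = egerm_numerator(A.W, D.W, effect_type)
    scale = np.abs(whole).max()
    np.testing.assert_allclose(gi.numerator + ge.numerator, whole,
                               rtol=0, atol=1e-14 * scale)


def test_egerm_intra_matches_restricted_oracle():
    geno = make_random_geno(7, 8, seed=13, n_chrom=2)
    A, D = additive_W(geno), dominance_W(geno)
    for t in ("AA", "AD", "DD"):
        gi, ge = intra_inter(A.W, D.W, geno.chromosomes, t, method="egerm")
        for scope, g in (("intra", gi), ("inter", ge)):
            Wx = epistasis_W(A, D, t, scope, geno.chromosomes)
            explicit = Wx.W @ Wx.W.T
            scale = max(np.abs(explicit).max(), 1e-30)
            assert np.abs(explicit - g.S * g.k).max() / scale < 1e-10, (t, scope)


def test_single_chromosome_inter_errors():
    geno = make_random_geno(6, 6, seed=17, n_chrom=1)
    A = additive_W(geno)
    with pytest.raises(ValueError, match="inter-chromosome part is empty"):
        intra_inter(A.W, None, geno.chromosomes, "AA")


def test_agerm_egerm_discrepancy_shrinks_with_snp_count():
    """Normalized AA matrices from the two constructions converge as m grows."""
    def discrepancy(m):
        cfg = SimConfig(n=60, chromosomes=(m // 2, m - m // 2), fractions={}, seed=7)
        geno, _ = simulate_genotypes(cfg)
        A = additive_W(geno)
        Sa = agerm(A.W @ A.W.T, None, "AA").S
        Se = egerm(A.W, None, "AA").S
        return np.linalg.norm(Sa - Se) / np.linalg.norm(Se)

    assert discrepancy(500) < discrepancy(10)


@pytest.mark.parametrize("seed", range(3))
def test_grm_structural_invariants(seed):
    """Symmetry, unit mean diagonal, and PSD-up-to-roundoff for every constructor."""
    geno = make_random_geno(8, 8, seed=seed + 200, n_chrom=2)
    grms = list(assemble(["A", "D", "AA", "AD", "DD", "AAA", "DDD"], geno, method="egerm"))
    grms += list(assemble(["AA", "AD", "DD"], geno, method="agerm"))
    grms += list(intra_inter(additive_W(geno).W, dominance_W(geno).W,
                             geno.chromosomes, "AA", "egerm"))
    for g in grms:
        assert np.abs(g.S - g.S.T).max() < 1e-12
        assert np.mean(np.diag(g.S)) == pytest.approx(1.0, abs=1e-12)
        assert np.linalg.eigvalsh(g.S).min() > -1e-8


def test_assemble_model_orders(sim_dataset):
    _, geno, hap, _, _ = sim_dataset
    gs1 = assemble("Model-I", geno, hap, method="agerm")
    assert gs1.effect_types == MODEL_I_TYPES and len(gs1) == 10
    gs2 = assemble("Model-II", geno, hap, method="agerm")
    assert gs2.effect_types == MODEL_II_TYPES and len(gs2) == 13
    assert gs2.effect_types[3:9] == [
        "AA_intra", "AD_intra", "DD_intra", "AA_inter", "AD_inter", "DD_inter"]
    sub = assemble(["A", "AA"], geno, method="agerm")
    assert sub.effect_types == ["A", "AA"]


def test_assemble_model_ii_needs_two_chromosomes():
    geno = make_random_geno(6, 6, seed=31, n_chrom=1)
    with pytest.raises(ValueError, match="2 chromosomes"):
        assemble(["AA_intra", "AA_inter"], geno)


def test_grm_io_roundtrip(tmp_path, tiny_geno):
    g = grm_direct(additive_W(tiny_geno), ids=list(tiny_geno.individual_ids))
    write_grm(g, tmp_path / "A")
    back = read_grm(tmp_path / "A")
    np.testing.assert_array_equal(back.S, g.S)
    assert back.ids == g.ids and back.effect_type == "A" and back.k == g.k
    write_grm_tsv(g, tmp_path / "A.tsv")
    back2 = read_grm_tsv(tmp_path / "A.tsv", "A", "direct")
    np.testing.assert_allclose(back2.S, g.S, atol=1e-14)
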