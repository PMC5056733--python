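"""Kernel evaluation and the exact additive split of single kernel evaluations.

The closed forms are checked against the brute-force enumeration oracle
(subset products for RBF, multinomial tuples for polynomial), which is the
independent definition of the split.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kernogram import KernelSpec, expand_terms, expansion_oracle, kernel_eval


@pytest.mark.parametrize(
    "spec,x,z,expected",
    [
        (KernelSpec("rbf", gamma=2.0), (0.3, -1, 5), (0.3, -1, 5), 1.0),
        (KernelSpec("linear"), (1, 2, 3), (4, 5, 6), 32.0),
        (KernelSpec("polynomial", scale_a=1, offset_c=1, degree_delta=2), (1, 2), (1, 1), 16.0),
    ],
)
def test_kernel_eval_known_values(spec, x, z, expected):
    assert kernel_eval(spec, x, z) == pytest.approx(expected, abs=1e-12)


def test_kernel_eval_symmetric_and_rbf_bounded(rng):
    for _ in range(20):
        x, z = rng.normal(size=(2, 4))
        for spec in (
            KernelSpec("linear"),
            KernelSpec("polynomial", degree_delta=3),
            KernelSpec("rbf", gamma=0.7),
        ):
            assert kernel_eval(spec, x, z) == pytest.approx(kernel_eval(spec, z, x))
        k = kernel_eval(KernelSpec("rbf", gamma=0.7), x, z)
        assert 0 < k <= 1


def test_kernel_eval_errors():
    spec = KernelSpec("rbf", gamma=1.0)
    with pytest.raises(ValueError):
        kernel_eval(spec, [1, 2], [1, 2, 3])
    with pytest.raises(ValueError):
        kernel_eval(spec, [np.nan, 0], [0, 0])


def test_kernel_spec_validation_and_roundtrip():
    with pytest.raises(ValueError):
        KernelSpec("rbf", gamma=0.0)
    with pytest.raises(ValueError):
        KernelSpec("polynomial", degree_delta=0)
    with pytest.raises(ValueError):
        KernelSpec("sigmoid")
    spec = KernelSpec("polynomial", gamma=0.5, scale_a=2.0, offset_c=0.0, degree_delta=4)
    assert KernelSpec.from_json(spec.to_json()) == spec


def test_rbf_expansion_three_ones():
    """d=3 all-ones displacement: every subset product is a power of u = e^-1 - 1."""
    spec = KernelSpec("rbf", gamma=1.0)
    ts = expand_terms(spec, np.zeros(3), np.ones(3))
    u = np.expm1(-1.0)
    assert ts.const == 1.0
    np.testing.assert_allclose(ts.main, u, atol=1e-12)
    np.testing.assert_allclose(ts.pairs, u * u, atol=1e-12)
    assert ts.rest == pytest.approx(u**3, abs=1e-12)
    assert ts.total == pytest.approx(np.exp(-3.0), abs=1e-12)


def test_poly_expansion_small_case():
    """(u1 + u2 + 1)^2 with u = (1, 2): const 1, mains (3, 8), pair 4, exact."""
    spec = KernelSpec("polynomial", scale_a=1, offset_c=1, degree_delta=2)
    ts = expand_terms(spec, (1, 2), (1, 1))
    assert ts.const == 1.0
    np.testing.assert_allclose(ts.main, [3.0, 8.0])
    np.testing.assert_allclose(ts.pairs, [4.0])
    assert ts.rest == 0.0
    assert ts.total == pytest.approx(16.0)


def test_poly_oracle_triple_product_term():
    """δ=3, c=0, all-ones: the rest is exactly the 3! * u1 u2 u3 monomial."""
    spec = KernelSpec("polynomial", scale_a=1.0, offset_c=0.0, degree_delta=3)
    ts = expansion_oracle(spec, np.ones(3), np.ones(3))
    assert ts.rest == pytest.approx(6.0)
    assert ts.total == pytest.approx(kernel_eval(spec, np.ones(3), np.ones(3)))


def test_linear_expansion_is_pure_main(rng):
    x_i, x = rng.normal(size=(2, 5))
    ts = expand_terms(KernelSpec("linear"), x_i, x)
    np.testing.assert_allclose(ts.main, x_i * x)
    assert ts.const == 0.0 and ts.rest == 0.0
    assert np.all(ts.pairs == 0)


def test_oracle_d1_has_no_interactions(rng):
    spec = KernelSpec("rbf", gamma=0.3)
    x_i, x = rng.normal(size=(2, 1))
    ts = expansion_oracle(spec, x_i, x)
    assert ts.pairs.size == 0 and ts.rest == 0.0
    assert ts.main[0] == pytest.approx(kernel_eval(spec, x_i, x) - 1.0)


@pytest.mark.parametrize("d", range(1, 7))
@pytest.mark.parametrize(
    "spec",
    [KernelSpec("linear")]
    + [KernelSpec("polynomial", scale_a=0.7, offset_c=c, degree_delta=delta)
       for delta in (1, 2, 3, 4) for c in (0.0, 1.0)]
    + [KernelSpec("rbf", gamma=g) for g in (2.0**-7, 0.25, 1.0, 4.0)],
    ids=str,
)
def test_closed_form_matches_oracle(spec, d, rng):
    """Term-wise agreement between closed forms and brute-force enumeration."""
    for _ in range(5):
        x_i, x = rng.normal(size=(2, d))
        got = expand_terms(spec, x_i, x)
        want = expansion_oracle(spec, x_i, x)
        np.testing.assert_allclose(got.const, want.const, atol=1e-10)
        np.testing.assert_allclose(got.main, want.main, atol=1e-10, rtol=1e-8)
        np.testing.assert_allclose(got.pairs, want.pairs, atol=1e-10, rtol=1e-8)
        assert got.rest == pytest.approx(want.rest, abs=max(1e-10, 1e-10 * abs(want.rest)))


def test_rbf_truncated_taylor_oracle_converges():
    """The truncated-series oracle approaches the exact subset split."""
    spec = KernelSpec("rbf", gamma=0.5)
    x_i = np.array([0.2, -0.4, 0.9])
    x = np.array([-0.3, 0.5, 0.1])
    exact = expansion_oracle(spec, x_i, x)
    errs = []
    for order in (2, 6, 14):
        trunc = expansion_oracle(spec, x_i, x, max_order=order)
        errs.append(
            abs(trunc.const - exact.const)
            + np.abs(trunc.main - exact.main).sum()
            + np.abs(trunc.pairs - exact.pairs).sum()
        )
    assert errs[0] > errs[1] > errs[2]
    assert errs[2] < 1e-10


def test_oracle_dimension_guard():
    with pytest.raises(ValueError):
        expansion_oracle(KernelSpec("rbf", gamma=1.0), np.zeros(13), np.ones(13))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    data=st.data(),
    d=st.integers(min_value=1, max_value=6),
    family=st.sampled_from(["linear", "polynomial", "rbf"]),
)
def test_conservation_and_bounds(data, d, family):
    """const + Σ main + Σ pairs + rest always reconstructs the kernel value;
    RBF terms respect their analytic ranges; the split is symmetric in (x, z)."""
    elems = st.floats(min_value=-5, max_value=5, allow_nan=False)
    x_i = np.array(data.draw(st.lists(elems, min_size=d, max_size=d)))
    x = np.array(data.draw(st.lists(elems, min_size=d, max_size=d)))
    if family == "polynomial":
        spec = KernelSpec(
            "polynomial",
            scale_a=data.draw(st.sampled_from([0.5, 1.0])),
            offset_c=data.draw(st.sampled_from([0.0, 1.0])),
            degree_delta=data.draw(st.integers(1, 4)),
        )
    elif family == "rbf":
        spec = KernelSpec("rbf", gamma=data.draw(st.sampled_from([2.0**-7, 1.0, 4.0])))
    else:
        spec = KernelSpec("linear")
    K = kernel_eval(spec, x_i, x)
    ts = expand_terms(spec, x_i, x)
    assert ts.total == pytest.approx(K, abs=1e-10 * max(1.0, abs(K)))
    # symmetry of the split
    ts_swap = expand_terms(spec, x, x_i)
    np.testing.assert_allclose(ts.main, ts_swap.main, atol=1e-9, rtol=1e-9)
    np.testing.assert_allclose(ts.pairs, ts_swap.pairs, atol=1e-9, rtol=1e-9)
    if family == "rbf":
        # analytic ranges are (-1, 0] and [0, 1); float rounding can land on -1/1
        assert np.all(ts.main >= -1) and np.all(ts.main <= 0)
        assert np.all(ts.pairs >= 0) and np.all(ts.pairs <= 1)
    # exactness triggers
    if family == "linear" or d <= 2 or (family == "polynomial" and spec.degree_delta <= 2):
        assert abs(ts.rest) <= 1e-12


def test_rbf_extreme_gamma_distance_stable():
    """expm1 evaluation keeps u_p accurate when gamma * distance is huge."""
    spec = KernelSpec("rbf", gamma=1e6)
    ts = expand_terms(spec, np.zeros(3), np.array([10.0, 10.0, 10.0]))
    np.testing.assert_allclose(ts.main, -1.0, rtol=0, atol=1e-15)
    assert ts.total == pytest.approx(kernel_eval(spec, np.zeros(3), 10 * np.ones(3)), abs=1e-12)
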