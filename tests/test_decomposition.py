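"""Aggregation of kernel-level terms into per-observation model contributions."""

import numpy as np
import pytest

from kernogram import (
    Dataset,
    KernelSpec,
    approximate_latent,
    decompose_model,
    expand_terms,
    fit_svm,
    from_additive_model,
    main_effect_values,
    pair_effect_values,
    shift_contributions,
)
from kernogram.decomposition import apply_shift
from kernogram.svm import PlattCalibration


def _toy(n=80, d=3, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    y = np.where(X[:, 0] - X[:, 1] > 0, 1, -1)
    return Dataset(X, y, [f"x{i+1}" for i in range(d)])


@pytest.mark.parametrize(
    "spec",
    [
        KernelSpec("linear"),
        KernelSpec("polynomial", degree_delta=2),
        KernelSpec("polynomial", degree_delta=4),
        KernelSpec("rbf", gamma=0.5),
    ],
    ids=str,
)
def test_rowwise_conservation(spec):
    data = _toy()
    model = fit_svm(data, spec, 1.0)
    dec = decompose_model(model, data.features)
    recon = dec.intercept_bpp + dec.main_contribs.sum(1) + dec.pair_contribs.sum(1) + dec.rest
    np.testing.assert_allclose(
        recon, dec.latent_full, atol=1e-9 * max(1.0, np.abs(dec.latent_full).max())
    )
    np.testing.assert_allclose(dec.latent_full, model.decision_function(data.features))


def test_linear_kernel_main_effects_closed_form():
    data = _toy()
    model = fit_svm(data, KernelSpec("linear"), 1.0, standardize=False)
    dec = decompose_model(model, data.features)
    w = model.dual_coef_signed_ @ model.support_vectors_
    np.testing.assert_allclose(dec.main_contribs, data.features * w, atol=1e-10)
    assert np.all(dec.pair_contribs == 0) and np.all(dec.rest == 0)


@pytest.mark.parametrize(
    "spec",
    [KernelSpec("linear"), KernelSpec("polynomial", degree_delta=1),
     KernelSpec("polynomial", degree_delta=2)],
    ids=str,
)
def test_exactness_triggers_delta_le_2(spec):
    data = _toy(d=4)
    model = fit_svm(data, spec, 5.0)
    dec = decompose_model(model, data.features)
    assert np.abs(dec.rest).max() <= 1e-12


def test_exactness_trigger_d_le_2():
    data = _toy(d=2)
    model = fit_svm(data, KernelSpec("rbf", gamma=2.0), 10.0)
    dec = decompose_model(model, data.features)
    assert np.abs(dec.rest).max() <= 1e-12


def test_agreement_with_kernel_level_expansion():
    """For few support vectors, observation terms are the coefficient-weighted
    sum of single-kernel expansions."""
    rng = np.random.default_rng(5)
    for spec in (KernelSpec("rbf", gamma=0.8), KernelSpec("polynomial", degree_delta=3)):
        model = fit_svm(_toy(n=8, seed=2), spec, 1.0, standardize=False)
        assert len(model.dual_coef_signed_) <= 8
        X = rng.normal(size=(4, 3))
        dec = decompose_model(model, X)
        for j, x in enumerate(X):
            terms = [expand_terms(spec, sv, x) for sv in model.support_vectors_]
            coef = model.dual_coef_signed_
            main = sum(c * t.main for c, t in zip(coef, terms))
            pairs = sum(c * t.pairs for c, t in zip(coef, terms))
            np.testing.assert_allclose(dec.main_contribs[j], main, atol=1e-10)
            np.testing.assert_allclose(dec.pair_contribs[j], pairs, atol=1e-10)


def test_aggregation_linearity():
    """Doubling the dual coefficients doubles every contribution and the rest."""
    data = _toy()
    model = fit_svm(data, KernelSpec("rbf", gamma=0.5), 1.0)
    dec = decompose_model(model, data.features)
    model.dual_coef_signed_ = 2.0 * model.dual_coef_signed_
    dec2 = decompose_model(model, data.features)
    np.testing.assert_allclose(dec2.main_contribs, 2 * dec.main_contribs, atol=1e-10)
    np.testing.assert_allclose(dec2.pair_contribs, 2 * dec.pair_contribs, atol=1e-10)
    np.testing.assert_allclose(dec2.rest, 2 * dec.rest, atol=1e-9)


def test_single_sv_matches_expand_terms():
    from kernogram.svm import ExplainableSVC

    model = ExplainableSVC(kernel="rbf", gamma=1.0, standardize=False, calibrate=False)
    model.classes_ = np.array([-1, 1])
    sv = np.array([[0.5, -0.2, 1.0]])
    model.support_vectors_ = sv
    model.dual_coef_signed_ = np.array([1.7])
    model.intercept_ = 0.3
    model.kernel_spec_ = KernelSpec("rbf", gamma=1.0)
    model.scale_center_ = np.zeros(3)
    model.scale_spread_ = np.ones(3)
    model.n_features_in_ = 3
    x = np.array([[1.0, 0.0, -0.5]])
    dec = decompose_model(model, x)
    ts = expand_terms(model.kernel_spec_, sv[0], x[0])
    np.testing.assert_allclose(dec.main_contribs[0], 1.7 * ts.main, atol=1e-12)
    np.testing.assert_allclose(dec.pair_contribs[0], 1.7 * ts.pairs, atol=1e-12)
    assert dec.intercept_bpp == pytest.approx(0.3 + 1.7 * ts.const)
    assert dec.rest[0] == pytest.approx(1.7 * ts.rest, abs=1e-10)


def test_approximate_latent_identities():
    data = _toy()
    model = fit_svm(data, KernelSpec("rbf", gamma=1.0), 1.0)
    dec = decompose_model(model, data.features)
    approx = approximate_latent(dec)
    np.testing.assert_allclose(approx + dec.rest, dec.latent_full, atol=1e-12)
    np.testing.assert_allclose(
        approx, dec.intercept_bpp + dec.main_contribs.sum(1) + dec.pair_contribs.sum(1),
        atol=1e-9,
    )


def test_from_additive_model():
    X = np.array([[1.0, 2.0], [0.0, -1.0], [3.0, 0.5]])
    dec = from_additive_model([0.0, 0.0], 1.0, X)
    assert np.all(dec.contributions() == 0)
    np.testing.assert_allclose(dec.latent_full, 1.0)
    dec = from_additive_model([2.0], 0.0, np.array([[1.0], [2.0]]))
    assert dec.main_contribs[1, 0] == 2 * dec.main_contribs[0, 0]


def test_additive_adapter_matches_linear_svm():
    data = _toy()
    model = fit_svm(data, KernelSpec("linear"), 1.0, standardize=False)
    w = model.dual_coef_signed_ @ model.support_vectors_
    dec_svm = decompose_model(model, data.features)
    dec_add = from_additive_model(w, model.intercept_, data.features)
    np.testing.assert_allclose(dec_add.main_contribs, dec_svm.main_contribs, atol=1e-10)
    np.testing.assert_allclose(dec_add.latent_full, dec_svm.latent_full, atol=1e-10)


@pytest.mark.parametrize("mode,check", [
    ("zero", lambda pts: np.allclose(pts, pts)),
    ("mean", lambda pts: np.allclose(pts.mean(0), 0, atol=1e-10)),
    ("median", lambda pts: np.allclose(np.median(pts, axis=0), 0, atol=1e-10)),
    ("minimum", lambda pts: np.allclose(pts.min(0), 0, atol=1e-10)),
])
def test_shift_modes_center_points(mode, check):
    data = _toy()
    model = fit_svm(data, KernelSpec("rbf", gamma=0.5), 1.0)
    dec = decompose_model(model, data.features)
    shifted = shift_contributions(dec, mode)
    assert check(shifted.points())
    # points + offsets reconstruct contributions exactly
    offs = np.concatenate([shifted.main_offsets, shifted.pair_offsets])
    np.testing.assert_allclose(shifted.points() + offs, dec.contributions(), atol=1e-12)


def test_risks_invariant_across_shift_modes():
    data = _toy()
    model = fit_svm(data, KernelSpec("rbf", gamma=0.5), 1.0)
    dec = decompose_model(model, data.features)
    calib = PlattCalibration(slope_A=-1.2, offset_B=0.1)
    reference = calib.risk(approximate_latent(dec))
    for mode in ("zero", "mean", "median", "minimum"):
        shifted = shift_contributions(dec, mode)
        np.testing.assert_allclose(shifted.risk(calib), reference, atol=1e-12)


def test_frozen_offsets_apply_to_new_data():
    data = _toy(n=60)
    new = _toy(n=20, seed=9)
    model = fit_svm(data, KernelSpec("rbf", gamma=0.5), 1.0)
    train_shift = shift_contributions(decompose_model(model, data.features), "median")
    dec_new = decompose_model(model, new.features)
    shifted_new = apply_shift(dec_new, train_shift)
    np.testing.assert_array_equal(shifted_new.main_offsets, train_shift.main_offsets)
    calib = PlattCalibration(-1.0, 0.0)
    np.testing.assert_allclose(
        shifted_new.risk(calib), calib.risk(approximate_latent(dec_new)), atol=1e-12
    )


def test_effect_profiles_match_decomposition():
    """Grid evaluators reproduce per-observation contributions at the same inputs."""
    data = _toy()
    model = fit_svm(data, KernelSpec("rbf", gamma=0.7), 1.0)
    dec = decompose_model(model, data.features)
    vals = main_effect_values(model, 0, data.features[:, 0])
    np.testing.assert_allclose(vals, dec.main_contribs[:, 0], atol=1e-10)
    surf = pair_effect_values(model, 0, 1, data.features[:5, 0], data.features[:5, 1])
    for j in range(5):
        assert surf[j, j] == pytest.approx(dec.pair_contribs[j, 0], abs=1e-10)


def test_decomposition_csv_export(tmp_path):
    data = _toy(n=10)
    model = fit_svm(data, KernelSpec("rbf", gamma=0.5), 1.0)
    dec = decompose_model(model, data.features)
    path = tmp_path / "dec.csv"
    dec.to_csv(path)
    import pandas as pd

    df = pd.read_csv(path)
    assert list(df.columns) == ["x1", "x2", "x3", "x1*x2", "x1*x3", "x2*x3", "rest", "latent"]
    np.testing.assert_allclose(df["latent"], dec.latent_full)
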