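"""Constrained training: estimator behaviour, aggregation, serialization."""

import json

import numpy as np
import pytest
from sklearn.base import clone

import redinfo as ri
from redinfo.estimator import (
    ConstantPredictionWarning,
    DecoderFamilySpec,
    MLPSoftmaxDecoder,
    TrainConfig,
    usable_information_bits,
)

from conftest import FAST, independent_dataset, one_hot_dataset


def fit_estimator(ds, eval_ds=None, **kw):
    kw = {"beta_final": 15.0, "seeds": [5], **FAST, **kw}
    est = ri.RedundancyEstimator(**kw)
    if eval_ds is None:
        est.set_params(random_state=0)
        est.fit(ds, ds.labels)
    else:
        est.fit(ds, ds.labels, X_eval=eval_ds, y_eval=eval_ds.labels)
    return est


# --------------------------------------------------------------- behaviour

def test_shared_clean_signal_recovers_full_entropy():
    train = one_hot_dataset(2000, 2, seed=1)
    test = one_hot_dataset(2000, 2, seed=2)
    est = fit_estimator(train, test)
    assert est.redundancy_bits_ == pytest.approx(1.0, abs=0.05)
    assert est.final_distances_[0] < 0.05


def test_independent_labels_give_no_redundancy():
    train = independent_dataset(2000, 2, 3, seed=1)
    test = independent_dataset(2000, 2, 3, seed=2)
    est = fit_estimator(train, test)
    assert abs(est.redundancy_bits_) < 0.1


def test_usable_information_of_identity_four_classes():
    train = one_hot_dataset(2000, 4, seed=3, duplicate=1)
    test = one_hot_dataset(2000, 4, seed=4, duplicate=1)
    family = DecoderFamilySpec()
    config = TrainConfig(epochs=40, batch_size=128, seeds=(0,))
    iu = usable_information_bits(train, test, family, config, source_index=0, seed=0)
    assert iu == pytest.approx(2.0, abs=0.1)


def test_usable_information_of_noise_is_zero():
    train = independent_dataset(1500, 2, 3, seed=5, n_sources=1)
    test = independent_dataset(1500, 2, 3, seed=6, n_sources=1)
    family = DecoderFamilySpec()
    config = TrainConfig(epochs=30, batch_size=128, seeds=(0,))
    iu = usable_information_bits(train, test, family, config, source_index=0, seed=0)
    assert abs(iu) < 0.1


def test_three_identical_sources_match_single_copy():
    train = one_hot_dataset(2000, 2, seed=7, duplicate=3)
    test = one_hot_dataset(2000, 2, seed=8, duplicate=3)
    est = fit_estimator(train, test)
    assert est.n_sources_ == 3
    assert est.redundancy_bits_ == pytest.approx(1.0, abs=0.1)


def test_noise_third_source_removes_redundancy(canonical_pmfs):
    pmf = canonical_pmfs["RDNXOR"]
    rng = np.random.default_rng(9)
    train = ri.sample_dataset(pmf, 3000, seed=10)
    test = ri.sample_dataset(pmf, 3000, seed=11)

    def with_noise(ds, rng):
        return ri.LabeledDataset(
            ds.sources + [rng.standard_normal((ds.n_samples, 2))],
            ds.labels,
            ds.n_classes,
        )

    est = fit_estimator(
        with_noise(train, rng), with_noise(test, rng), epochs=60, beta_final=50.0
    )
    assert abs(est.redundancy_bits_) < 0.15


# ------------------------------------------------------------- error paths

def test_single_source_fit_is_rejected():
    ds = independent_dataset(100, 2, 2, seed=0, n_sources=1)
    with pytest.raises(ValueError, match="usable_information"):
        ri.RedundancyEstimator(seeds=[0]).fit(ds, ds.labels)


def test_cross_entropy_dimension_mismatch():
    ds = independent_dataset(200, 2, 3, seed=0)
    dec = MLPSoftmaxDecoder(**FAST, random_state=0).fit(
        np.random.default_rng(0).standard_normal((200, 5)), ds.labels
    )
    with pytest.raises(ValueError, match="features"):
        ri.cross_entropy_bits(dec, ds, 0)


def test_empty_seed_list_is_rejected():
    ds = independent_dataset(100, 2, 2, seed=0)
    with pytest.raises(ValueError, match="seeds"):
        ri.RedundancyEstimator(seeds=[]).fit(ds, ds.labels)


def test_mismatched_rows_are_rejected():
    with pytest.raises(ValueError, match="rows"):
        ri.LabeledDataset(
            [np.zeros((5, 1)), np.zeros((4, 1))], np.zeros(5, int), 2
        )


def test_constant_input_triggers_collapse_warning():
    n = 400
    y = np.random.default_rng(0).integers(0, 2, n)
    ds = ri.LabeledDataset([np.zeros((n, 1)), np.zeros((n, 1))], y, 2)
    with pytest.warns(ConstantPredictionWarning):
        fit_estimator(ds, ds, epochs=5)


# --------------------------------------------------------- aggregation / API

def test_multi_seed_aggregation_and_result():
    train = one_hot_dataset(1000, 2, seed=1)
    test = one_hot_dataset(1000, 2, seed=2)
    est = fit_estimator(train, test, seeds=[1, 2, 3], epochs=10)
    assert len(est.per_run_bits_) == 3
    assert est.redundancy_bits_ == pytest.approx(np.mean(est.per_run_bits_))
    assert est.sd_bits_ == pytest.approx(np.std(est.per_run_bits_, ddof=1))
    result = est.result()
    assert result.seeds == [1, 2, 3]
    assert result.sd_bits == est.sd_bits_
    assert len(result.per_seed_cross_entropies) == 3


def test_single_seed_has_no_sd():
    train = one_hot_dataset(800, 2, seed=1)
    est = fit_estimator(train, train, epochs=5)
    assert est.sd_bits_ is None
    assert est.result().sd_bits is None


def test_fit_is_deterministic_given_seeds():
    train = one_hot_dataset(800, 2, seed=1)
    test = one_hot_dataset(800, 2, seed=2)
    a = fit_estimator(train, test, seeds=[3, 4], epochs=8)
    b = fit_estimator(train, test, seeds=[3, 4], epochs=8)
    assert a.per_run_bits_ == b.per_run_bits_
    assert a.final_distances_ == b.final_distances_


def test_sklearn_protocol():
    est = ri.RedundancyEstimator(beta_final=7.0, n_runs=2)
    params = est.get_params()
    assert params["beta_final"] == 7.0
    cloned = clone(est)
    assert cloned.get_params() == params
    cloned.set_params(epochs=3)
    assert cloned.epochs == 3


def test_estimate_json_serialization(tmp_path):
    train = one_hot_dataset(600, 2, seed=1)
    est = fit_estimator(train, train, seeds=[1, 2], epochs=5)
    path = tmp_path / "estimate.json"
    est.result().to_json(path)
    payload = json.loads(path.read_text())
    assert payload["units"] == "bits"
    assert len(payload["per_seed_bits"]) == 2
    assert payload["beta_final"] == 15.0


def test_decoder_checkpoint_roundtrip(tmp_path):
    train = one_hot_dataset(500, 3, seed=2, duplicate=1)
    dec = MLPSoftmaxDecoder(epochs=10, batch_size=128, random_state=1).fit(
        train.sources[0], train.labels
    )
    dec.save(tmp_path / "decoder")
    back = MLPSoftmaxDecoder.load(tmp_path / "decoder")
    X = train.sources[0][:50]
    np.testing.assert_allclose(back.predict_proba(X), dec.predict_proba(X))


def test_functional_wrappers_match_contract(canonical_pmfs):
    pmf = canonical_pmfs["AND"]
    train = ri.sample_dataset(pmf, 1500, seed=1)
    test = ri.sample_dataset(pmf, 1500, seed=2)
    families = [DecoderFamilySpec(), DecoderFamilySpec()]
    config = TrainConfig(epochs=20, batch_size=128, seeds=(1, 2))
    result = ri.estimate_redundancy(train, test, families, config)
    assert len(result.per_seed_bits) == 2
    assert result.n_sources == 2
    single = ri.train_rine(train, test, families, config, seed=1)
    assert np.isfinite(single.redundancy_bits)
    assert len(single.cross_entropies_bits) == 2


def test_convolutional_family_not_implemented():
    with pytest.raises(NotImplementedError):
        DecoderFamilySpec(kind="convolutional")
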