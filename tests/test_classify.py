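import joblib
import numpy as np
import pytest

from rcseg.classify import (
    MEMBER_ACRONYMS,
    CaseScenarioModel,
    combine_predictions,
    load_model,
    save_model,
    segment_regions,
    threshold_fe,
    train_ensemble,
)
from rcseg.colorspace import RegionPartition
from rcseg.errors import ModelError, TrainingError, ValidationError


@pytest.fixture(scope="module")
def blobs():
    """Linearly separable two-blob data with a wide margin."""
    rng = np.random.default_rng(7)
    x0 = rng.normal(0.0, 0.3, size=(40, 4))
    x1 = rng.normal(4.0, 0.3, size=(40, 4))
    x = np.vstack([x0, x1])
    y = np.array([0] * 40 + [1] * 40)
    return x, y


@pytest.fixture(scope="module")
def ensemble(blobs):
    return train_ensemble(*blobs, seed=0)


class TestThresholdRule:
    def test_fe_half_is_plant(self):
        assert threshold_fe(np.array([0.5]))[0] == 1

    def test_fe_below_half_is_background(self):
        assert threshold_fe(np.array([0.49]))[0] == 0

    def test_fe_clipped_to_unit_interval(self):
        assert np.array_equal(threshold_fe(np.array([-3.0, 7.0])), [0, 1])


class TestTraining:
    def test_all_members_separate_training_blobs(self, ensemble, blobs):
        x, y = blobs
        for acronym in MEMBER_ACRONYMS:
            assert np.array_equal(ensemble.predict_single(acronym, x), y), acronym

    def test_single_class_rejected(self):
        x = np.random.default_rng(0).random((20, 3))
        with pytest.raises(TrainingError):
            train_ensemble(x, np.ones(20))

    def test_minimal_viable_table(self, rng):
        x = rng.random((8, 3))
        y = np.array([0, 1] * 4)
        model = train_ensemble(x, y)
        assert set(model.members) == set(MEMBER_ACRONYMS)

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(TrainingError):
            train_ensemble(rng.random((4, 3)), np.array([0, 1, 0, 1]))

    def test_permuting_rows_permutes_predictions(self, ensemble, blobs):
        x, _ = blobs
        perm = np.random.default_rng(3).permutation(x.shape[0])
        direct = ensemble.predict(x, combine="median")
        assert np.array_equal(direct[perm], ensemble.predict(x[perm], "median"))

    def test_constant_feature_warns_but_trains(self, rng, caplog):
        x = rng.random((30, 3))
        x[:, 1] = 0.5
        y = (x[:, 0] > 0.5).astype(int)
        model = train_ensemble(x, y)
        assert model.feature_range[1] == 1.0  # guarded divisor


class TestCombination:
    def test_unanimous_plant(self):
        votes = np.ones((8, 5), dtype=int)
        out = combine_predictions(votes)
        assert np.all(out["median"] == 1) and np.all(out["fusion"] == 1)

    def test_single_vote_fuses_but_no_median(self):
        votes = np.zeros((8, 3), dtype=int)
        votes[2] = 1
        out = combine_predictions(votes)
        assert np.all(out["fusion"] == 1) and np.all(out["median"] == 0)

    def test_four_four_tie_resolves_to_plant(self):
        votes = np.zeros((8, 1), dtype=int)
        votes[:4] = 1
        assert combine_predictions(votes)["median"][0] == 1

    def test_wrong_member_count_rejected(self):
        with pytest.raises(ValidationError):
            combine_predictions(np.zeros((7, 3), dtype=int))

    def test_fusion_is_union_median_is_subset(self, ensemble, rng):
        x = rng.random((50, 4)) * 5
        votes = ensemble.predict_members(x)
        out = combine_predictions(votes)
        assert np.array_equal(out["fusion"], votes.max(axis=0))
        assert np.all(out["median"] <= out["fusion"])


class TestSegmentRegions:
    def _partition(self, ackmr):
        labels = np.repeat(np.arange(len(ackmr)), 4).reshape(2, -1)
        full = np.full((4, labels.shape[1]), -1)
        full[1:3] = labels
        return RegionPartition(labels=full, ackmr=np.asarray(ackmr),
                               n_reg=len(ackmr))

    def test_all_plant_regions_fill_support(self, ensemble):
        part = self._partition(np.full((3, 4), 4.0))  # deep in class-1 blob
        mask = segment_regions(part, ensemble)
        assert np.array_equal(mask.pixels, part.labels >= 0)

    def test_all_background_regions_empty_mask(self, ensemble):
        part = self._partition(np.zeros((3, 4)))
        assert segment_regions(part, ensemble).count() == 0


class TestPersistence:
    def test_save_load_roundtrip_predictions(self, ensemble, blobs, tmp_path):
        x, _ = blobs
        model = CaseScenarioModel(ensemble=ensemble,
                                  meta={"species": "synthetic-rosette",
                                        "stages": ["I"], "n_reg": 10})
        save_model(model, tmp_path / "m")
        loaded = load_model(tmp_path / "m")
        for acronym in MEMBER_ACRONYMS:
            assert np.array_equal(
                loaded.ensemble.predict_single(acronym, x),
                ensemble.predict_single(acronym, x),
            )
        assert loaded.meta["species"] == "synthetic-rosette"

    def test_load_missing_path_fails(self, tmp_path):
        with pytest.raises(ModelError):
            load_model(tmp_path / "nope")

    def test_missing_member_detected_by_name(self, ensemble, tmp_path):
        model = CaseScenarioModel(ensemble=ensemble, meta={"stages": ["I"]})
        save_model(model, tmp_path / "m")
        members = joblib.load(tmp_path / "m" / "members.joblib")
        del members["gpr"]
        joblib.dump(members, tmp_path / "m" / "members.joblib")
        with pytest.raises(ModelError, match="gpr"):
            load_model(tmp_path / "m")

    def test_meta_json_bytes_deterministic(self, ensemble, tmp_path):
        model = CaseScenarioModel(ensemble=ensemble, meta={"stages": ["I"]})
        save_model(model, tmp_path / "a")
        save_model(model, tmp_path / "b")
        assert (tmp_path / "a" / "meta.json").read_bytes() == \
               (tmp_path / "b" / "meta.json").read_bytes()
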