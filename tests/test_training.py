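"""Training orchestration: schedule, determinism, mode equivalence,
ensembles and evaluation plumbing."""
import numpy as np
import pandas as pd
import pytest

from implyseg import (
    BlobNet,
    ClassCatalog,
    ClassWeights,
    ConfigurationError,
    DiceTable,
    EnsemblePredictor,
    SceneSpec,
    TrainConfig,
    compare_runs,
    evaluate_ensemble_members,
    evaluate_run,
    imply_from_multiclass,
    make_dataset,
    nearest_mean_color_accuracy,
    train_mode,
    train_model,
)
from implyseg.labels import ValidationError
from implyseg.synthetic import generate_scene_pool

TINY_SPEC = SceneSpec(
    height=16,
    width=16,
    catalog=ClassCatalog(("red", "green")),
    class_colors={"red": (0.9, 0.1, 0.1), "green": (0.1, 0.9, 0.1)},
    confusable_pairs=(),
    blob_count_range=(1, 2),
    blob_size_range=(0.2, 0.4),
    seed=42,
)


def tiny_dataset(counts=(8, 3, 3)):
    return make_dataset(TINY_SPEC, counts=counts, pool_size=120, center_class="red")


def multiclass_pairs(dataset, include_background=True):
    return [
        (
            f.image,
            imply_from_multiclass(f.annotation, dataset.catalog, include_background),
        )
        for f in dataset.frames(kind="multiclass", split="train")
    ]


class TestTrainConfig:
    def test_learning_rate_schedule_decays_by_gamma_every_step(self):
        config = TrainConfig()
        # during the 21st epoch (0-based epoch 20) two decays have happened
        assert config.lr_at_epoch(20) == pytest.approx(3e-4 * 0.9**2)
        assert config.lr_at_epoch(0) == pytest.approx(3e-4)
        assert config.lr_at_epoch(9) == pytest.approx(3e-4)

    def test_invalid_mode_rejected(self):
        with pytest.raises(ConfigurationError):
            TrainConfig(mode="bogus")


class TestTrainModel:
    def test_single_epoch_produces_single_record_entry(self):
        ds = tiny_dataset()
        pairs = multiclass_pairs(ds)[:2]
        config = TrainConfig(mode="fs", epochs=1, batch_size=2, seed=0)
        model = BlobNet(3, width=4, seed=0)
        weights = ClassWeights({"red": 1.0, "green": 1.0, "background": 1.0})
        record = train_model(
            model, pairs, [], config, weights, ds.catalog, background_channel=True
        )
        assert len(record.epochs) == 1

    def test_empty_trainset_rejected(self):
        ds = tiny_dataset()
        config = TrainConfig(epochs=1)
        with pytest.raises(ValidationError):
            train_model(
                BlobNet(2), [], [], config, ClassWeights({"red": 1, "green": 1}),
                ds.catalog,
            )

    def test_non_finite_loss_aborts_with_diagnostic(self):
        ds = tiny_dataset()
        pairs = multiclass_pairs(ds)[:2]

        class NaNModel:
            n_out = 3
            params = {"w": np.zeros(1)}

            def forward(self, x, train=False):
                return np.full((x.shape[0], 3, x.shape[2], x.shape[3]), np.nan)

            def backward(self, dz):  # pragma: no cover
                return {"w": np.zeros(1)}

            def get_params(self):
                return {"w": np.zeros(1)}

            def set_params(self, p):
                pass

        config = TrainConfig(mode="fs", epochs=1, batch_size=2)
        with pytest.raises(RuntimeError, match="non-finite"):
            train_model(
                NaNModel(), pairs, [], config,
                ClassWeights({"red": 1, "green": 1, "background": 1}),
                ds.catalog, background_channel=True,
            )

    def test_seed_reproducibility_of_run_records(self):
        ds = tiny_dataset()
        pairs = multiclass_pairs(ds)
        val = ds.eval_samples("multiclass", "val")
        records = []
        for _ in range(2):
            config = TrainConfig(mode="fs", epochs=2, batch_size=4, seed=3)
            model = BlobNet(3, width=4, seed=3)
            weights = ClassWeights({"red": 1.0, "green": 1.0, "background": 1.0})
            records.append(
                train_model(model, pairs, val, config, weights, ds.catalog, True)
            )
        assert records[0].epochs == records[1].epochs
        assert records[0].best_epoch == records[1].best_epoch

    def test_il_and_fs_share_per_step_losses_on_fully_annotated_data(self):
        """With identical targets, weights, seeds and initial parameters, the
        implicit-labelling path and the fully supervised path are the same
        optimisation problem and must produce identical per-epoch losses."""
        ds = tiny_dataset()
        pairs = multiclass_pairs(ds)
        weights = ClassWeights({"red": 2.0, "green": 0.5, "background": 1.0})
        losses = []
        for label in ("il-style", "fs-style"):
            config = TrainConfig(mode="fs", epochs=2, batch_size=4, seed=9)
            model = BlobNet(3, width=4, seed=9)
            rec = train_model(model, pairs, [], config, weights, ds.catalog, True)
            losses.append([e["train_loss"] for e in rec.epochs])
        assert losses[0] == losses[1]

    def test_learns_separable_two_class_problem(self):
        """On colour-separable scenes (confirmed by the nearest-mean-colour
        oracle) the bundled CNN reaches a small training loss quickly."""
        pool = generate_scene_pool(TINY_SPEC, 20)
        assert nearest_mean_color_accuracy(pool, TINY_SPEC.catalog) > 0.9
        ds = tiny_dataset(counts=(12, 2, 2))
        pairs = multiclass_pairs(ds, include_background=False)
        config = TrainConfig(
            mode="il", epochs=30, learning_rate=1e-2, batch_size=4, seed=0
        )
        model = BlobNet(2, width=8, seed=0)
        weights = ClassWeights({"red": 1.0, "green": 1.0})
        record = train_model(model, pairs, [], config, weights, ds.catalog, False)
        assert record.epochs[-1]["train_loss"] < 0.1


@pytest.fixture(scope="module")
def dataset():
    return tiny_dataset(counts=(6, 2, 2))


class TestTrainMode:
    def test_ensemble_has_one_member_per_class_in_catalog_order(self, dataset):
        config = TrainConfig(mode="en", epochs=1, batch_size=4, seed=0)
        run = train_mode(dataset, config)
        assert isinstance(run.predictor, EnsemblePredictor)
        assert len(run.predictor.members) == dataset.catalog.n_foreground
        assert all(m.n_out == 1 for m in run.predictor.members)
        assert set(run.records) == set(dataset.catalog.foreground_names)

    def test_ensemble_stacking_matches_member_outputs(self, dataset, rng):
        config = TrainConfig(mode="en", epochs=1, batch_size=4, seed=0)
        run = train_mode(dataset, config)
        image = rng.uniform(size=(16, 16, 3)).astype(np.float32)
        stacked = run.predictor.probs(image)
        x = image.transpose(2, 0, 1)[None]
        for i, member in enumerate(run.predictor.members):
            expected = 1.0 / (1.0 + np.exp(-member.forward(x)[0, 0]))
            np.testing.assert_allclose(stacked[i], expected, atol=1e-6)

    def test_fs_mode_has_background_channel(self, dataset):
        config = TrainConfig(mode="fs", epochs=1, batch_size=4, seed=0)
        run = train_mode(dataset, config)
        assert run.predictor.background_channel
        assert run.predictor.model.n_out == dataset.catalog.n_foreground + 1

    def test_member_evaluation_reports_one_entry_per_test_frame(self, dataset):
        config = TrainConfig(mode="en", epochs=1, batch_size=4, seed=0)
        run = train_mode(dataset, config)
        table = evaluate_ensemble_members(run.predictor.members, dataset)
        n_test = sum(
            len(s.split("test")) for s in dataset.binary_subsets().values()
        )
        assert len(table) == n_test


class _OracleModel:
    """Emits +/-9 logits straight from a ground-truth label map lookup."""

    def __init__(self, lookup, n_out):
        self.lookup = lookup
        self.n_out = n_out
        self.params = {}

    def forward(self, x, train=False):
        out = []
        for img in x:
            lm = self.lookup[img.tobytes()]
            out.append(
                np.stack([np.where(lm == c, 9.0, -9.0) for c in range(self.n_out)])
            )
        return np.stack(out)


class TestEvaluateRun:
    def test_oracle_model_scores_perfect_dice(self):
        ds = tiny_dataset(counts=(4, 2, 2))
        samples = ds.eval_samples("multiclass", "test")
        lookup = {}
        for f in ds.subsets["multiclass"].split("test"):
            key = f.image.transpose(2, 0, 1).astype(np.float32).tobytes()
            lookup[key] = f.annotation.label_map
        from implyseg.training import SingleModelPredictor

        predictor = SingleModelPredictor(
            _OracleModel(lookup, 3), background_channel=True
        )
        table, confusion = evaluate_run(predictor, samples, ds.catalog)
        assert table.overall_mean() == 1.0
        cm = confusion.counts.to_numpy()
        assert np.trace(cm) == cm.sum()

    def test_constant_background_model_misses_present_classes(self):
        ds = tiny_dataset(counts=(4, 2, 2))
        samples = ds.eval_samples("red", "test")

        class Background:
            n_out = 2
            params = {}

            def forward(self, x, train=False):
                return np.full((x.shape[0], 2, x.shape[2], x.shape[3]), -9.0)

        from implyseg.training import SingleModelPredictor

        predictor = SingleModelPredictor(Background(), background_channel=False)
        table, _ = evaluate_run(predictor, samples, ds.catalog)
        assert table.per_class_mean()["red"] < 1.0


class TestCompareRuns:
    def test_identical_tables_are_fully_degenerate(self):
        frame = pd.DataFrame(
            {
                "image_id": ["a", "b", "a", "b"],
                "class": ["A", "A", "B", "B"],
                "dice": [0.5, 0.6, 0.7, 0.8],
            }
        )
        report = compare_runs(DiceTable(frame), DiceTable(frame.copy()))
        assert report.pooled.degenerate
        assert all(r.degenerate for r in report.per_class.values())

    def test_uniform_improvement_flags_only_that_class(self):
        base = pd.DataFrame(
            {
                "image_id": list("abcdefgh") * 2,
                "class": ["A"] * 8 + ["B"] * 8,
                "dice": [0.5] * 8 + [0.6] * 8,
            }
        )
        better = base.copy()
        better.loc[better["class"] == "A", "dice"] += 0.2
        report = compare_runs(DiceTable(better), DiceTable(base))
        assert report.per_class["A"].significant_05
        assert report.per_class["B"].degenerate

    def test_key_mismatch_rejected(self):
        a = pd.DataFrame(
            {"image_id": ["a"], "class": ["A"], "dice": [1.0]}
        )
        b = pd.DataFrame(
            {"image_id": ["b"], "class": ["A"], "dice": [1.0]}
        )
        with pytest.raises(ValidationError):
            compare_runs(DiceTable(a), DiceTable(b))
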