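"""CV engine: accuracy metric, fold making, grid search, combo evaluation,
grid enumeration, dimensionality sweep and reference extension."""

import numpy as np
import pytest

import ramantax as rt
from ramantax import benchmark as bm
from ramantax.classify import ClassifierSpec, fit_classifier, predict
from ramantax.dimred import DRSpec

from conftest import fast_plan, make_tiny_config


class TestAccuracy:
    def test_all_correct(self):
        assert bm.accuracy(["a", "b"], ["a", "b"]) == 1.0

    def test_three_of_four(self):
        assert bm.accuracy(["a", "a", "b", "b"], ["a", "a", "b", "c"]) == 0.75

    def test_disjoint_label_sets(self):
        assert bm.accuracy(["x", "y"], ["a", "b"]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(bm.BenchmarkError):
            bm.accuracy(["a"], ["a", "b"])

    def test_empty(self):
        with pytest.raises(bm.BenchmarkError):
            bm.accuracy([], [])


class TestMakeFolds:
    def test_even_partition(self):
        folds = bm.make_folds(np.repeat(["a", "b"], 50),
                              bm.CVPlan(n_folds=10))[0]
        assert all(te.size == 10 for _, te in folds)
        covered = np.sort(np.concatenate([te for _, te in folds]))
        assert np.array_equal(covered, np.arange(100))

    def test_uneven_sizes_differ_by_at_most_one(self):
        folds = bm.make_folds(np.repeat(["a", "b"], [9, 8]),
                              bm.CVPlan(n_folds=10, stratify_by=None))
        sizes = sorted(te.size for _, te in folds[0])
        assert max(sizes) - min(sizes) <= 1

    def test_stratified_balance_brute_force(self):
        y = np.repeat(["a", "b"], 50)
        folds = bm.make_folds(y, bm.CVPlan(n_folds=10))[0]
        for _, te in folds:
            counts = {c: int(np.sum(y[te] == c)) for c in "ab"}
            assert counts == {"a": 5, "b": 5}

    def test_deterministic(self):
        y = np.repeat(["a", "b", "c"], 20)
        f1 = bm.make_folds(y, bm.CVPlan(n_folds=5, seed=3))
        f2 = bm.make_folds(y, bm.CVPlan(n_folds=5, seed=3))
        for (tr1, te1), (tr2, te2) in zip(f1[0], f2[0]):
            assert np.array_equal(te1, te2)

    def test_small_stratum_warns_and_degrades(self):
        y = np.array(["a"] * 30 + ["b"] * 3)
        with pytest.warns(UserWarning, match="stratum"):
            folds = bm.make_folds(y, bm.CVPlan(n_folds=10))[0]
        assert len(folds) == 10

    def test_repeats_are_independent(self):
        y = np.repeat(["a", "b"], 30)
        reps = bm.make_folds(y, bm.CVPlan(n_folds=5, n_repeats=2))
        assert not all(np.array_equal(a[1], b[1])
                       for a, b in zip(reps[0], reps[1]))


class TestNestedGridSearch:
    def test_single_candidate_returned(self):
        spec = ClassifierSpec("SVM_LIN_CV", tunable_grid={"C": (2.5,)})
        X = np.random.default_rng(0).normal(size=(20, 2))
        y = np.repeat(["a", "b"], 10)
        assert bm.nested_grid_search(spec, X, y, fast_plan()) == {"C": 2.5}

    def test_tie_keeps_first_declared_candidate(self):
        # both candidates separate the toy perfectly -> exact tie -> first wins
        spec = ClassifierSpec("SVM_LIN_CV", tunable_grid={"C": (1.0, 10.0)})
        X, y = _separable(seed=2)
        chosen = bm.nested_grid_search(spec, X, y, fast_plan())
        assert chosen == {"C": 1.0}

    def test_underfitting_candidate_rejected(self):
        # imbalanced classes: a vanishing C collapses to the majority class
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 0.2, (40, 2)), rng.normal(2, 0.2, (8, 2))])
        y = np.repeat(["a", "b"], [40, 8])
        spec = ClassifierSpec("SVM_LIN_CV", tunable_grid={"C": (1e-8, 100.0)})
        chosen = bm.nested_grid_search(spec, X, y, fast_plan())
        assert chosen == {"C": 100.0}

    def test_gridless_classifier_returns_empty(self):
        X, y = _separable()
        assert bm.nested_grid_search(ClassifierSpec("LR"), X, y,
                                     fast_plan()) == {}


def _duplicate_rows(ds):
    idx = np.repeat(np.arange(ds.n_cells), 2)
    labels = ds.labels.iloc[idx].reset_index(drop=True)
    labels["cell_id"] = [f"d{i}" for i in range(len(labels))]
    return rt.SpectraDataset(grid=ds.grid, intensities=ds.intensities[idx],
                             labels=labels)


def _separable(n=30, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 0.2, (n, 2)), rng.normal(2, 0.2, (n, 2))])
    return X, np.repeat(["a", "b"], n)


class TestEvaluateCombo:
    def test_memorizer_on_duplicated_rows_is_perfect(self, tiny_ds):
        dup = _duplicate_rows(tiny_ds)
        combo = bm.ModelCombo(
            DRSpec("NONE"),
            ClassifierSpec("KNN", fixed_params={"n_neighbors": 1}))
        # split each duplicate pair across the folds so every test row has
        # its exact twin in training
        evens = np.arange(0, dup.n_cells, 2)
        odds = np.arange(1, dup.n_cells, 2)
        res = bm.evaluate_combo(combo, dup, bm.t_only(), fast_plan(),
                                folds=[(evens, odds), (odds, evens)])
        assert res.mean == 1.0

    def test_none_plus_lr_equals_manual_cv(self, tiny_ds):
        """Identity DR adds nothing: fold accuracies match a hand-rolled
        classifier CV on the same folds."""
        plan = fast_plan(seed=5)
        y = tiny_ds.labels["strain"].to_numpy()
        folds = bm.make_folds(y, plan)[0]
        combo = bm.ModelCombo(DRSpec("NONE"), ClassifierSpec("LR"))
        res = bm.evaluate_combo(combo, tiny_ds, bm.t_only(), plan, folds=folds)
        manual = []
        for tr, te in folds:
            fc = fit_classifier(ClassifierSpec("LR"),
                                tiny_ds.intensities[tr], y[tr])
            manual.append(bm.accuracy(predict(fc, tiny_ds.intensities[te]),
                                      y[te]))
        assert np.array_equal(res.fold_accuracies, np.array(manual))

    def test_stage_filter_task(self, tiny_ds):
        combo = bm.ModelCombo(DRSpec("NONE"), ClassifierSpec("GNB"))
        res = bm.evaluate_combo(combo, tiny_ds, bm.t_given_stage("S1"),
                                fast_plan())
        n_s1 = int((tiny_ds.labels["stage"] == "S1").sum())
        assert sum(f.test_index.size for f in res.folds) == n_s1

    def test_mean_sd_consistent_with_folds(self, tiny_ds):
        combo = bm.ModelCombo(DRSpec("PCA", out_dim=5), ClassifierSpec("GNB"))
        res = bm.evaluate_combo(combo, tiny_ds, bm.t_only(), fast_plan())
        assert res.mean == pytest.approx(res.fold_accuracies.mean())
        assert res.sd == pytest.approx(res.fold_accuracies.std())
        assert np.all((0 <= res.fold_accuracies)
                      & (res.fold_accuracies <= 1))


class TestEnumerateGrid:
    def test_default_is_six_by_nine(self):
        combos = bm.enumerate_grid()
        assert len(combos) == 54
        assert len({c.name for c in combos}) == 54
        assert not any(c.clf.method == "NN" for c in combos)

    def test_nn_flag_adds_tenth_classifier(self):
        assert len(bm.enumerate_grid(include_nn=True)) == 60

    def test_restricted_grid(self):
        combos = bm.enumerate_grid(dr_methods=("NONE", "LDA"),
                                   clf_methods=("LR", "GNB", "KNN"))
        assert len(combos) == 6

    def test_run_grid_on_restricted_combos(self, tiny_ds):
        table = bm.run_grid(tiny_ds, [bm.t_only()], fast_plan(),
                            dr_methods=("NONE", "PCA"),
                            clf_methods=("GNB", "LR"), out_dim=5)
        df = table.to_dataframe()
        assert len(table.results) == 4
        assert set(df["combo"]) == {"NONE+GNB", "NONE+LR", "PCA+GNB", "PCA+LR"}
        assert len(df) == 4 * 2  # combos x folds
        assert not table.failures


class TestDimSweep:
    def test_singleton_selected(self, tiny_ds):
        combo = bm.ModelCombo(DRSpec("PCA", out_dim=4), ClassifierSpec("GNB"))
        sweep = bm.dim_sweep(tiny_ds, combo, [4], fast_plan())
        assert sweep.selected_dim == 4

    def test_lda_sweep_caps_at_classes_minus_one(self, tiny_ds):
        combo = bm.ModelCombo(DRSpec("LDA", out_dim=3), ClassifierSpec("GNB"))
        with pytest.warns(UserWarning, match="infeasible"):
            sweep = bm.dim_sweep(tiny_ds, combo, [2, 3, 4, 8], fast_plan(),
                                 task=bm.g_step())
        assert set(sweep.per_dim) == {2, 3}

    def test_tie_goes_to_smaller_dim(self, tiny_ds):
        combo = bm.ModelCombo(
            DRSpec("NONE"),
            ClassifierSpec("KNN", fixed_params={"n_neighbors": 1}))
        dup = _duplicate_rows(tiny_ds)
        sweep = bm.dim_sweep(dup, combo, [7, 3], fast_plan())
        assert sweep.selected_dim == 3  # both perfect -> smaller wins


def test_dim_sweep_accuracy_rises_from_one_dimension_to_plateau():
    """Averaged over seeds, chance-adjacent accuracy at 1 dimension rises
    (non-strictly) toward a plateau as PCA keeps more components."""
    dims = (1, 6, 15)
    acc = {d: [] for d in dims}
    for seed in range(3):
        cfg = make_tiny_config(seed=40 + seed, spectra_per_strain_per_stage=15)
        ds = rt.generate_dataset(rt.make_taxonomy(cfg), cfg)
        combo = bm.ModelCombo(DRSpec("PCA", out_dim=1), ClassifierSpec("GNB"))
        sweep = bm.dim_sweep(ds, combo, dims, fast_plan(seed=seed))
        for d in dims:
            acc[d].append(sweep.per_dim[d].mean)
    means = [np.mean(acc[d]) for d in dims]
    assert means[0] <= means[1] + 0.02
    assert means[1] <= means[2] + 0.02
    assert means[2] > means[0]


class TestExtendReference:
    def _base_and_extra(self):
        base_cfg = make_tiny_config(seed=21)
        extra_cfg = rt.SyntheticConfig(
            n_strains=2, genus_partition=(1, 1), phylum_partition=(1, 1),
            spectra_per_strain_per_stage=8, grid=base_cfg.grid, seed=22)
        base = rt.generate_dataset(rt.make_taxonomy(base_cfg), base_cfg)
        extra = rt.generate_dataset(rt.make_taxonomy(extra_cfg), extra_cfg)
        # keep the two libraries' identifiers disjoint
        extra.labels["strain"] = "x" + extra.labels["strain"]
        extra.labels["genus"] = "x" + extra.labels["genus"]
        extra.labels["cell_id"] = "x" + extra.labels["cell_id"]
        return base, extra

    def test_merged_genus_count_and_quota(self):
        base, extra = self._base_and_extra()
        merged = bm.extend_reference(base, extra, quota=20, seed=0)
        sizes = merged.labels.groupby("genus").size()
        assert len(sizes) == 3 + 2
        assert (sizes == 20).all()

    def test_quota_equals_available_is_permutation(self):
        base, _ = self._base_and_extra()
        one_genus = base.subset((base.labels["genus"] == "genus00").to_numpy())
        n = one_genus.n_cells
        # base has 2 strains in genus00 -> 80 spectra; quota = all of them
        merged = bm.extend_reference(
            one_genus, one_genus.subset([0]).with_intensities(
                one_genus.intensities[:1]), quota=n, seed=1)
        # the lone extra row duplicates a cell_id -> disambiguated; sizes right
        assert (merged.labels.groupby("genus").size() == n).all()

    def test_deterministic(self):
        base, extra = self._base_and_extra()
        m1 = bm.extend_reference(base, extra, quota=15, seed=9)
        m2 = bm.extend_reference(base, extra, quota=15, seed=9)
        assert m1.equals(m2)

    def test_insufficient_class_warns_and_resamples(self):
        base, extra = self._base_and_extra()
        with pytest.warns(UserWarning, match="replacement"):
            merged = bm.extend_reference(base, extra, quota=50, seed=2)
        assert (merged.labels.groupby("genus").size() == 50).all()

    def test_grid_mismatch_rejected(self):
        base, extra = self._base_and_extra()
        import ramantax.preprocess as pp
        shrunk = pp.resample(extra, rt.WavenumberGrid(
            extra.grid.values[10:-10]))
        with pytest.raises(bm.BenchmarkError, match="grid"):
            bm.extend_reference(base, shrunk, quota=5)
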