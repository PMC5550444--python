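"""Vote-fraction forest: training, scoring, tiers, CV, importances."""

import numpy as np
import pandas as pd
import pytest
from sklearn.tree import DecisionTreeClassifier

from trapscore.features import FEATURE_NAMES
from trapscore.model import (
    GERPLESS_THRESHOLDS,
    TrapClassifier,
    classify,
    cross_validate,
    feature_importance,
    load_model,
    save_model,
    train,
    train_gerpless,
    vote_fraction,
)


def _separable(n=120, seed=0, n_features=5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_features))
    y = (X[:, 0] > 0).astype(int)
    X[:, 0] += y * 3.0  # feature 0 fully determines the label, with margin
    return X, y


class TestFit:
    def test_separable_set_low_oob_and_top_importance(self):
        X, y = _separable(seed=1)
        clf = TrapClassifier(random_state=0).fit(X, y)
        assert clf.oob_error_ <= 0.02
        assert int(np.argmax(clf.feature_importances_)) == 0

    def test_permuted_labels_oob_near_class_prior(self):
        X, y = _separable(n=100, seed=2)
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            yp = rng.permutation(y)
            clf = TrapClassifier(n_estimators=300, random_state=seed).fit(X, yp)
            accs.append(1.0 - clf.oob_error_)
        prior = max(np.mean(y), 1 - np.mean(y))
        assert abs(np.mean(accs) - prior) <= 0.05

    def test_same_seed_identical_scores(self):
        X, y = _separable(seed=3)
        probe = X[:25]
        a = TrapClassifier(random_state=11).fit(X, y).vote_fractions(probe)
        b = TrapClassifier(random_state=11).fit(X, y).vote_fractions(probe)
        assert np.array_equal(a, b)

    def test_single_class_and_nan_rejected(self):
        X, _ = _separable()
        with pytest.raises(ValueError, match="both classes"):
            TrapClassifier().fit(X, np.zeros(len(X)))
        Xn = X.copy()
        Xn[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            TrapClassifier().fit(Xn, (X[:, 1] > 0).astype(int))

    def test_feature_name_mismatch_rejected(self):
        X, y = _separable(n_features=3)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        clf = TrapClassifier(n_estimators=50, random_state=0).fit(df, y)
        with pytest.raises(ValueError, match="registry"):
            clf.vote_fractions(df.rename(columns={"c": "z"}))


class TestVoteSemantics:
    def test_vote_accounting_is_exact(self, trained_model, annotated_bundle):
        """TraP times the tree count is an integer equal to the number of
        trees voting pathogenic."""
        _, _, merged = annotated_bundle
        X = merged[list(FEATURE_NAMES)].head(40)
        values = trained_model.vote_fractions(X)
        n = trained_model.n_estimators
        recounted = np.zeros(len(X))
        for tree in trained_model.forest_.estimators_:
            pred = trained_model.classes_[
                tree.predict(X.to_numpy(float)).astype(int)
            ]
            recounted += pred == 1
        assert np.array_equal(values * n, recounted)
        assert np.all(np.abs(values * n - np.round(values * n)) < 1e-9)

    def test_hand_built_ensembles_give_exact_fractions(self):
        """An ensemble with a fixed number of pathogenic-voting trees yields
        exactly that fraction: 450/1000 -> 0.45, 1000 -> 1.0, 0 -> 0.0."""
        Xp = [[0.0], [1.0]]
        for n_path, expected in ((450, 0.45), (1000, 1.0), (0, 0.0)):
            trees = [
                DecisionTreeClassifier().fit(Xp, [1, 1])
                for _ in range(n_path)
            ] + [
                DecisionTreeClassifier().fit(Xp, [0, 0])
                for _ in range(1000 - n_path)
            ]
            (frac,) = vote_fraction(trees, np.array([[0.5]]))
            assert frac == expected


class TestTiers:
    @pytest.mark.parametrize(
        "value,tier",
        [
            (0.0, "benign"),
            (0.458, "benign"),
            (0.459, "possibly_damaging"),
            (0.9299, "possibly_damaging"),
            (0.93, "probably_damaging"),
            (1.0, "probably_damaging"),
        ],
    )
    def test_default_thresholds(self, value, tier):
        assert classify(value) == tier

    def test_tiers_partition_unit_interval(self):
        for v in np.linspace(0, 1, 1001):
            assert classify(float(v)) in (
                "benign", "possibly_damaging", "probably_damaging"
            )

    def test_out_of_range_and_bad_thresholds(self):
        with pytest.raises(ValueError):
            classify(1.5)
        with pytest.raises(ValueError):
            classify(0.5, thresholds=(0.9, 0.4))

    def test_gerpless_thresholds(self):
        assert classify(0.7, GERPLESS_THRESHOLDS) == "possibly_damaging"
        assert classify(0.96, GERPLESS_THRESHOLDS) == "probably_damaging"
        assert classify(0.65, GERPLESS_THRESHOLDS) == "benign"


class TestCrossValidation:
    def test_separable_auc_high(self):
        X, y = _separable(n=150, seed=4)
        _, mean = cross_validate(X, y, folds=10, repeats=1, seed=0,
                                 n_estimators=200)
        assert mean >= 0.95

    def test_permuted_labels_auc_near_half(self):
        X, y = _separable(n=150, seed=5)
        yp = np.random.default_rng(0).permutation(y)
        _, mean = cross_validate(X, yp, folds=10, repeats=3, seed=0,
                                 n_estimators=150)
        assert abs(mean - 0.5) <= 0.1

    def test_first_repeat_reproduces_across_repeat_counts(self):
        X, y = _separable(n=100, seed=6)
        aucs1, _ = cross_validate(X, y, folds=5, repeats=1, seed=3,
                                  n_estimators=100)
        aucs3, _ = cross_validate(X, y, folds=5, repeats=3, seed=3,
                                  n_estimators=100)
        assert aucs1[0] == aucs3[0]


class TestImportanceAndGerpless:
    def test_importance_ordering_with_noise_and_duplicates(self):
        rng = np.random.default_rng(9)
        n = 300
        signal = rng.normal(size=n)
        y = (signal > 0).astype(int)
        X = np.column_stack([signal + y, signal + y, rng.normal(size=n)])
        df = pd.DataFrame(X, columns=["sig_a", "sig_b", "noise"])
        clf = TrapClassifier(n_estimators=300, random_state=0).fit(df, y)
        ranked = feature_importance(clf)
        assert list(ranked["feature"])[-1] == "noise"
        imp = dict(zip(ranked["feature"], ranked["importance"]))
        assert imp["sig_a"] / imp["sig_b"] < 2
        assert imp["sig_b"] / imp["sig_a"] < 2

    def test_gerpless_registry_and_conservation_only_contrast(self):
        rng = np.random.default_rng(10)
        n = 200
        y = rng.integers(0, 2, size=n)
        data = {name: rng.normal(size=n) for name in FEATURE_NAMES}
        data["gerp_rs"] = y * 3.0 + rng.normal(size=n)  # only signal
        df = pd.DataFrame(data)[list(FEATURE_NAMES)]
        full = train(df, y, seed=0)
        gerpless = train_gerpless(df, y, seed=0)
        assert gerpless.n_features_in_ == 19
        assert "gerp_rs" not in gerpless.feature_names_in_
        assert gerpless.thresholds == GERPLESS_THRESHOLDS
        probe = df.head(50)
        s_full = full.vote_fractions(probe)
        s_less = gerpless.vote_fractions(probe[list(gerpless.feature_names_in_)])
        assert np.all((0 <= s_less) & (s_less <= 1))
        # with conservation the only signal, the full model separates OOB
        # far better than the conservation-free one
        assert full.oob_error_ < gerpless.oob_error_

    def test_monotone_damage_response(self):
        """Median TraP does not decrease across increasing engineered
        donor-delta magnitude levels (5 levels x 50 variants).

        Levels whose members all sit deep inside the pathogenic training
        range saturate near 1.0, so equal medians are compared with a
        20-vote slack (0.02 of the vote fraction)."""
        from trapscore.features import TrapAnnotator
        from trapscore.synthetic import (
            SimConfig, generate_genome, generate_variants,
        )

        mix = {"donor_disrupt": 0.5, "acceptor_disrupt": 0.0,
               "cryptic_create": 0.0, "esr_hit": 0.0, "neutral": 0.5}
        cfg = SimConfig(n_genes=80, n_variants=500, class_mix=mix)
        syn = generate_genome(cfg, seed=21)
        variants, truth, _ = generate_variants(cfg, syn, seed=21)
        ann = TrapAnnotator(motif_sets=syn.motif_sets)
        ann.fit(syn.transcripts, syn.genome)
        table = ann.annotate(variants)
        merged = table.merge(truth, on=["contig", "pos", "ref", "alt"])
        X = merged[list(FEATURE_NAMES)]
        y = merged["pathogenic"].to_numpy(int)
        clf = TrapClassifier(random_state=21).fit(X, y)
        dd = merged[merged["class"] == "donor_disrupt"].copy()
        assert len(dd) == 250
        dd["level"] = pd.qcut(dd["magnitude"], 5, labels=False,
                              duplicates="drop")
        dd["trap"] = clf.vote_fractions(dd[list(FEATURE_NAMES)])
        medians = dd.groupby("level")["trap"].median()
        assert len(medians) >= 4
        assert (medians.diff().dropna() >= -0.02).all(), medians


class TestPersistence:
    def test_round_trip_and_registry_hash(self, tmp_path):
        X, y = _separable(n=80, seed=12, n_features=4)
        df = pd.DataFrame(X, columns=["a", "b", "c", "d"])
        clf = TrapClassifier(n_estimators=100, random_state=5).fit(df, y)
        path = tmp_path / "model.joblib"
        save_model(clf, path)
        loaded = load_model(path)
        assert np.array_equal(loaded.vote_fractions(df), clf.vote_fractions(df))
        assert list(loaded.feature_names_in_) == ["a", "b", "c", "d"]
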