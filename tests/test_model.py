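"""One-hot encoding, data splits, training filters, and the numpy networks."""

import numpy as np
import pandas as pd
import pytest

from landscape_forge import model as M
from landscape_forge.genotypes import parse_mutation_set
from landscape_forge.landscape import ADDITIVE_CONFIG, LandscapeConfig, make_landscape
from landscape_forge.simulate import generate_protein_library


def frame(rows):
    return pd.DataFrame(rows, columns=["mutations", "fluorescence"])


WT = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL"


class TestEncode:
    def test_wildtype_row_activates_wildtype_states(self):
        ds = M.encode(frame([("", 4.2), ("A1C", 4.0)]), WT)
        wt_row = ds.X[0]
        active = {ds.columns[i] for i in np.flatnonzero(wt_row)}
        assert active == {(s + 1, WT[s]) for s in range(len(WT))}

    def test_observed_states_only(self):
        ds = M.encode(frame([("", 4.2), ("A1C", 4.0), ("A1G", 4.0)]), WT)
        pos1_states = sorted(st for site, st in ds.columns if site == 1)
        assert pos1_states == ["A", "C", "G"]

    def test_one_active_state_per_position(self):
        ds = M.encode(frame([("", 4.2), ("A1C:D3Y", 3.0)]), WT)
        for row in ds.X:
            for site in range(1, len(WT) + 1):
                cols = [i for i, (s, _) in enumerate(ds.columns) if s == site]
                assert row[cols].sum() == 1.0

    def test_decode_round_trip(self):
        rows = [("", 4.2), ("A1C:D3Y", 3.0), ("K9*", 1.8)]
        ds = M.encode(frame(rows), WT)
        assert [M.decode(ds, i) for i in range(3)] == [m for m, _ in rows]

    def test_unknown_state_raises(self):
        with pytest.raises(ValueError):
            M.encode(frame([("A1B", 4.0)]), WT)


class TestSplit:
    def test_sizes_at_ten(self):
        labels = M.split(10, (0.6, 0.2, 0.2), seed=1)
        counts = pd.Series(labels).value_counts()
        assert counts["train"] == 6 and counts["val"] == 2 and counts["test"] == 2

    def test_deterministic_and_exhaustive(self):
        a = M.split(101, seed=3)
        b = M.split(101, seed=3)
        assert (a == b).all()
        assert set(a) == {"train", "val", "test"}

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            M.split(10, (0.5, 0.2, 0.2))


class TestFilterForTraining:
    def test_identity_when_all_mutations_common(self):
        sets = [frozenset({(1, "C")}) for _ in range(12)]
        keep, _ = M.filter_for_training(sets, [])
        assert keep.all()

    def test_cascading_removal_reaches_fixed_point(self):
        # mutation b appears in 10 genotypes, one of which carries rare mutation a;
        # removing that genotype drops b to 9 → everything with b must go too.
        a, b = (1, "C"), (2, "Y")
        sets = [frozenset({a, b})] + [frozenset({b}) for _ in range(9)]
        sets += [frozenset({(3, "G")}) for _ in range(10)]

        # independent brute-force oracle
        def oracle(sets):
            keep = set(range(len(sets)))
            while True:
                counts = {}
                for i in keep:
                    for m in sets[i]:
                        counts[m] = counts.get(m, 0) + 1
                bad = {m for m, c in counts.items() if c < 10}
                drop = {i for i in keep if sets[i] & bad}
                if not drop:
                    return keep
                keep -= drop

        keep, _ = M.filter_for_training(sets, [])
        assert set(np.flatnonzero(keep)) == oracle(sets)
        assert not any(b in sets[i] for i in np.flatnonzero(keep))

    def test_validation_pruned_against_training_alphabet(self):
        train = [frozenset({(1, "C")}) for _ in range(10)]
        val = [frozenset({(1, "C")}), frozenset({(2, "Y")})]
        _, keep_val = M.filter_for_training(train, val)
        assert list(keep_val) == [True, False]

    def test_empty_training_set_raises(self):
        sets = [frozenset({(1, "C")})] * 3
        with pytest.raises(ValueError):
            M.filter_for_training(sets, [])


@pytest.fixture(scope="module")
def additive_data():
    land = make_landscape(40, LandscapeConfig(**ADDITIVE_CONFIG), seed=21)
    df = generate_protein_library(land, 1500, mean_mutations=3.0, measurement_sd=0.0, seed=2)
    ds = M.encode(df, land.wildtype_protein)
    labels = M.split(len(df), seed=0)
    return land, df, ds, labels


class TestLinearModel:
    def test_recovers_additive_effects_above_threshold(self, additive_data):
        land, df, ds, labels = additive_data
        # pre-threshold region: fluorescence strictly above the dark floor
        above = df["fluorescence"].to_numpy() > land.transform.f_dark + 1e-9
        tr = ds.subset((labels == "train") & above)
        va = ds.subset((labels == "val") & above)
        net = M.Network(ds.X.shape[1], M.linear_architecture(), seed=0)
        M.train(
            net, tr.X, tr.y, va.X, va.y,
            max_epochs=400, patience=400, learning_rate=0.01, seed=0,
        )
        assert M.r2(va.y, net.predict(va.X)) >= 0.99

        col = ds.col_index
        wt = land.wildtype_protein
        checked = 0
        for (site, alt), eff in land.additive_effects.items():
            if (site, alt) not in col or abs(eff) > 1.0:
                continue
            w = net.W[0][:, 0] * net.y_scale
            delta = w[col[(site, alt)]] - w[col[(site, wt[site - 1])]]
            assert delta == pytest.approx(eff, abs=0.05)
            checked += 1
        assert checked >= 10

    def test_early_stopping_contract(self, additive_data):
        _, df, ds, labels = additive_data
        tr, va = ds.subset(labels == "train"), ds.subset(labels == "val")
        net = M.Network(ds.X.shape[1], M.linear_architecture(), seed=0)
        hist = M.train(net, tr.X, tr.y, va.X, va.y, max_epochs=60, patience=3, seed=0)
        vl = hist["val_loss"]
        best_epoch = int(np.argmin(vl))
        assert len(vl) <= best_epoch + 3 + 1


class TestSigmoidImprovesThresholdedData:
    def test_sigmoid_output_beats_linear_on_sigmoid_landscape(self):
        land = make_landscape(40, LandscapeConfig(), seed=31)  # sigmoid transform
        df = generate_protein_library(land, 1500, mean_mutations=4.0, measurement_sd=0.02, seed=3)
        ds = M.encode(df, land.wildtype_protein)
        labels = M.split(len(df), seed=1)
        tr, va = ds.subset(labels == "train"), ds.subset(labels == "val")
        gains = []
        for seed in range(3):
            lin = M.Network(ds.X.shape[1], M.linear_architecture(), seed=seed)
            M.train(lin, tr.X, tr.y, va.X, va.y, max_epochs=30, seed=seed)
            sig = M.sigmoid_model_from_linear(lin)
            M.train(sig, tr.X, tr.y, va.X, va.y, max_epochs=30, seed=seed)
            gains.append(
                M.r2(va.y, sig.predict(va.X)) - M.r2(va.y, lin.predict(va.X))
            )
        assert np.median(gains) > 0


@pytest.fixture(scope="module")
def trained_two_layer():
    land = make_landscape(35, LandscapeConfig(), seed=41)
    df = generate_protein_library(land, 600, measurement_sd=0.02, seed=4)
    ds = M.encode(df, land.wildtype_protein)
    labels = M.split(len(df), seed=2)
    tr, va = ds.subset(labels == "train"), ds.subset(labels == "val")
    net = M.Network(ds.X.shape[1], M.two_layer_architecture(20, 10, dropout=0.1), seed=1)
    M.train(net, tr.X, tr.y, va.X, va.y, max_epochs=10, seed=1)
    return net, va


class TestMcDropout:

    def test_zero_dropout_gives_zero_sd(self, additive_data):
        _, df, ds, labels = additive_data
        net = M.Network(ds.X.shape[1], M.two_layer_architecture(5, 5, dropout=0.0), seed=0)
        med, sd = M.predict_mc(net, ds.X[:50], n_samples=10, seed=0)
        assert np.allclose(sd, 0.0, atol=1e-12)
        assert np.allclose(med, net.predict(ds.X[:50]))

    def test_reproducible_given_seed(self, trained_two_layer):
        net, va = trained_two_layer
        a, _ = M.predict_mc(net, va.X[:40], n_samples=20, seed=5)
        b, _ = M.predict_mc(net, va.X[:40], n_samples=20, seed=5)
        assert np.array_equal(a, b)

    def test_sd_grows_with_dropout_rate(self, trained_two_layer):
        net, va = trained_two_layer
        _, sd_low = M.predict_mc(net, va.X[:60], n_samples=40, seed=6)
        net.dropout_rate = 0.3
        _, sd_high = M.predict_mc(net, va.X[:60], n_samples=40, seed=6)
        net.dropout_rate = 0.1
        assert sd_high.mean() > sd_low.mean()

    def test_twenty_sample_median_is_stable(self, trained_two_layer):
        net, va = trained_two_layer
        med20, _ = M.predict_mc(net, va.X[:80], n_samples=20, seed=7)
        med1k, _ = M.predict_mc(net, va.X[:80], n_samples=1000, seed=8)
        assert np.mean(np.abs(med20 - med1k) <= 0.05) >= 0.9


class TestR2:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert M.r2(y, y) == 1.0

    def test_constant_mean_prediction_is_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert M.r2(y, np.full(3, y.mean())) == pytest.approx(0.0)

    def test_offset_closed_form(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        c = 0.5
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert M.r2(y, y + c) == pytest.approx(1 - c**2 * len(y) / ss_tot)

    def test_zero_variance_labels_raise(self):
        with pytest.raises(ValueError):
            M.r2(np.ones(5), np.ones(5))


class TestGridSearch:
    def test_single_architecture_grid(self, additive_data):
        _, df, ds, labels = additive_data
        tr, va = ds.subset(labels == "train"), ds.subset(labels == "val")
        arch, net, hist = M.grid_search(
            tr.X, tr.y, va.X, va.y, width_grid=(4,), n_architectures=1,
            search_epochs=2, final_epochs=3, seed=0,
        )
        assert arch.layers[0][0] == 4 and arch.layers[1][0] == 4

    def test_search_is_reproducible(self, additive_data):
        _, df, ds, labels = additive_data
        tr, va = ds.subset(labels == "train"), ds.subset(labels == "val")
        kw = dict(width_grid=(2, 4), n_architectures=2, search_epochs=2, final_epochs=2, seed=9)
        arch_a, _, hist_a = M.grid_search(tr.X, tr.y, va.X, va.y, **kw)
        arch_b, _, hist_b = M.grid_search(tr.X, tr.y, va.X, va.y, **kw)
        assert arch_a.layers == arch_b.layers
        assert hist_a["search_results"] == hist_b["search_results"]


class TestPosterior:
    def test_deterministic_at_inference_and_sane_fit(self, additive_data):
        _, df, ds, labels = additive_data
        net, hist = M.train_posterior(ds.X, ds.y, max_epochs=40, seed=0)
        a = net.predict(ds.X[:30])
        b = net.predict(ds.X[:30])
        assert np.array_equal(a, b)
        assert M.r2(ds.y, net.predict(ds.X)) > 0.5


class TestPersistence:
    def test_json_round_trip_preserves_predictions(self, additive_data):
        _, df, ds, labels = additive_data
        tr, va = ds.subset(labels == "train"), ds.subset(labels == "val")
        net = M.Network(ds.X.shape[1], M.two_layer_architecture(4, 3), seed=2)
        M.train(net, tr.X, tr.y, va.X, va.y, max_epochs=3, seed=2)
        restored = M.Network.from_json(net.to_json())
        assert np.allclose(restored.predict(va.X[:20]), net.predict(va.X[:20]))


class TestTransformCurve:
    def test_learned_transform_is_monotone_on_sigmoid_data(self):
        land = make_landscape(35, LandscapeConfig(), seed=51)
        df = generate_protein_library(land, 1200, measurement_sd=0.02, seed=6)
        ds = M.encode(df, land.wildtype_protein)
        labels = M.split(len(df), seed=3)
        tr, va = ds.subset(labels == "train"), ds.subset(labels == "val")
        net = M.Network(ds.X.shape[1], M.transform_architecture(), seed=3)
        M.train(net, tr.X, tr.y, va.X, va.y, max_epochs=30, seed=3)
        potentials = net._forward(va.X)[1][1][:, 0]
        grid = np.linspace(potentials.min(), potentials.max(), 50)
        curve = M.transform_curve(net, grid)
        diffs = np.diff(curve)
        # monotone up to small numerical wiggle, in one consistent direction
        assert (diffs >= -1e-3).all() or (diffs <= 1e-3).all()
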