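"""Training loops: freeze contracts, determinism, loss decrease, prediction."""

import numpy as np
import pytest

from spotdecon.containers import CountMatrix, LayerTag
from spotdecon.losses import kld_source_loss
from spotdecon.networks import AdversarialNet
from spotdecon.trainer import (
    TrainingConfig,
    adversarial_train,
    predict_fractions,
    pretrain_source,
    train_nn_wo_da,
)


def _cfg(**kw):
    base = dict(iterations=20, batch_size=32, pretrain_epochs=3, seed=0)
    base.update(kw)
    return TrainingConfig(**base)


@pytest.fixture(scope="module")
def scaled_batch(small_batch):
    return small_batch.scaled01()


@pytest.fixture(scope="module")
def n_panel(small_batch):
    return len(small_batch.gene_ids)


def _new_net(scaled_batch, seed=0):
    return AdversarialNet(
        n_genes=len(scaled_batch.gene_ids),
        n_types=scaled_batch.Y.shape[1],
        seed=seed,
    )


class TestPretrain:
    def test_loss_decreases_on_held_out(self, scaled_batch):
        net = _new_net(scaled_batch)
        held_X, held_Y = scaled_batch.X[:100], scaled_batch.Y[:100]
        before = kld_source_loss(held_Y, net.predict_proportions(held_X))
        pretrain_source(net, scaled_batch, _cfg(pretrain_epochs=8))
        after = kld_source_loss(held_Y, net.predict_proportions(held_X))
        assert after < before

    def test_discriminator_untouched(self, scaled_batch):
        net = _new_net(scaled_batch)
        d_before = net.D.hash()
        pretrain_source(net, scaled_batch, _cfg())
        assert net.D.hash() == d_before

    def test_zero_epochs_is_noop(self, scaled_batch):
        net = _new_net(scaled_batch)
        hashes = net.hashes()
        pretrain_source(net, scaled_batch, _cfg(pretrain_epochs=0))
        assert net.hashes() == hashes

    def test_deterministic_given_seed(self, scaled_batch):
        runs = []
        for _ in range(2):
            net = _new_net(scaled_batch)
            pretrain_source(net, scaled_batch, _cfg())
            runs.append(net.hashes())
        assert runs[0] == runs[1]

    def test_unscaled_input_rejected(self, small_batch):
        net = _new_net(small_batch)
        with pytest.raises(ValueError, match="scaled"):
            pretrain_source(net, small_batch, _cfg())


class TestAdversarialTrain:
    def test_freeze_contracts_every_iteration(self, scaled_batch, small_panel_data):
        _, _, spots_scaled, _ = small_panel_data
        net = _new_net(scaled_batch)
        cfg = _cfg(iterations=50, check_freeze=True)
        pretrain_source(net, scaled_batch, cfg)
        adversarial_train(net, scaled_batch, spots_scaled, cfg)
        assert len(net.history_["L_adv2"]) == 50

    def test_loss_trajectories_recorded(self, scaled_batch, small_panel_data):
        _, _, spots_scaled, _ = small_panel_data
        net = _new_net(scaled_batch)
        adversarial_train(net, scaled_batch, spots_scaled, _cfg(iterations=5))
        for key in ("L_s", "L_adv1", "L_adv2"):
            assert len(net.history_[key]) == 5
            assert np.all(np.isfinite(net.history_[key]))

    def test_gene_panel_mismatch_rejected(self, scaled_batch, small_panel_data):
        _, _, spots_scaled, _ = small_panel_data
        wrong = CountMatrix(
            spots_scaled.values[:-1],
            spots_scaled.gene_ids[:-1],
            spots_scaled.sample_ids,
            layer_tag=LayerTag.SCALED01,
        )
        net = _new_net(scaled_batch)
        with pytest.raises(ValueError, match="panel"):
            adversarial_train(net, scaled_batch, wrong, _cfg())

    def test_deterministic_given_seed(self, scaled_batch, small_panel_data):
        _, _, spots_scaled, _ = small_panel_data
        runs = []
        for _ in range(2):
            net = _new_net(scaled_batch)
            cfg = _cfg(iterations=10)
            pretrain_source(net, scaled_batch, cfg)
            adversarial_train(net, scaled_batch, spots_scaled, cfg)
            runs.append(net.hashes())
        assert runs[0] == runs[1]


@pytest.fixture(scope="module")
def fitted(scaled_batch, small_panel_data):
    net = _new_net(scaled_batch)
    pretrain_source(net, scaled_batch, _cfg(pretrain_epochs=8))
    return net


class TestPredictFractions:
    def test_rows_are_probability_vectors(self, fitted, small_panel_data, scaled_batch):
        _, _, spots_scaled, _ = small_panel_data
        fm = predict_fractions(fitted, spots_scaled, scaled_batch.cell_type_order)
        np.testing.assert_allclose(fm.fractions.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicated_spot_identical_rows(self, fitted, small_panel_data, scaled_batch):
        _, _, spots_scaled, _ = small_panel_data
        dup = CountMatrix(
            np.repeat(spots_scaled.values[:, :1], 2, axis=1),
            spots_scaled.gene_ids,
            ["a", "b"],
            layer_tag=LayerTag.SCALED01,
        )
        fm = predict_fractions(fitted, dup, scaled_batch.cell_type_order)
        np.testing.assert_array_equal(fm.fractions[0], fm.fractions[1])

    def test_single_cell_pseudospot_recovers_its_type(
        self, fitted, small_panel_data
    ):
        """One-hot mixtures from a separated reference: top prediction matches."""
        sc, annot, _, _ = small_panel_data
        from spotdecon.pseudospot import generate_pseudospots

        batch = generate_pseudospots(sc, annot, k=1, n=40, seed=21).scaled01()
        probs = fitted.predict_proportions(batch.X)
        predicted = np.argmax(probs, axis=1)
        true = np.argmax(batch.Y, axis=1)
        assert (predicted == true).mean() >= 0.9

    def test_panel_size_mismatch_rejected(self, fitted, scaled_batch):
        bad = CountMatrix(
            np.zeros((3, 2)), ["x", "y", "z"], ["s1", "s2"],
            layer_tag=LayerTag.SCALED01,
        )
        with pytest.raises(ValueError, match="genes"):
            predict_fractions(fitted, bad, scaled_batch.cell_type_order)


class TestBaselineNN:
    def test_discriminator_stays_at_initialization(self, scaled_batch):
        model = train_nn_wo_da(scaled_batch, _cfg())
        fresh = AdversarialNet(
            n_genes=len(scaled_batch.gene_ids), n_types=scaled_batch.Y.shape[1], seed=0
        )
        assert model.D.hash() == fresh.D.hash()
        assert model.f.hash() != fresh.f.hash()

    def test_same_seed_identical_model(self, scaled_batch):
        a = train_nn_wo_da(scaled_batch, _cfg())
        b = train_nn_wo_da(scaled_batch, _cfg())
        assert a.hashes() == b.hashes()


def test_config_validation():
    with pytest.raises(ValueError):
        TrainingConfig(iterations=0)
    with pytest.raises(ValueError):
        TrainingConfig(lr_main=0)
    with pytest.raises(ValueError):
        TrainingConfig(alpha=-1)
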