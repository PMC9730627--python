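import numpy as np
import pytest

from abte._mlp import bce_loss
from abte.amfp import AMFPConfig, train_amfp
from abte.biotext import BioTextConfig, train_biotext
from abte.data import interaction_counts, temporal_split, InteractionDataset
from abte.embeddings import resolve_drugs
from abte.evaluation import auroc
from abte.hybrid import (
    ABTEModel,
    StackerConfig,
    train_stacking,
    abte_predict,
    tune_M,
    train_abte,
    _routing_mask,
)


class TestTrainStacking:
    def test_recovers_an_informative_component(self):
        """Labels fully explained by the amfp input: stacked loss stays close."""
        rng = np.random.default_rng(0)
        am = rng.random(600)
        labels = (am > 0.5).astype(float)
        text = rng.random(600)  # noise
        stk = train_stacking(text, am, labels,
                             StackerConfig(epochs=400), seed=1)
        stacked = stk.predict(text, am)
        assert bce_loss(stacked, labels) <= bce_loss(am, labels) + 1e-3

    def test_constant_inputs_learn_base_rate(self):
        rng = np.random.default_rng(1)
        labels = (rng.random(500) < 0.3).astype(float)
        const = np.full(500, 0.4)
        stk = train_stacking(const, const, labels,
                             StackerConfig(epochs=400), seed=0)
        base = labels.mean()
        np.testing.assert_allclose(stk.predict(const, const), base, atol=0.02)

    def test_learns_conjunction_of_components(self):
        rng = np.random.default_rng(2)
        text, am = rng.random(800), rng.random(800)
        labels = ((text > 0.5) & (am > 0.5)).astype(float)
        stk = train_stacking(text, am, labels,
                             StackerConfig(hidden_widths=(8,), epochs=500),
                             seed=3)
        assert auroc(stk.predict(text, am), labels) > 0.95

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            train_stacking([0.1, 0.2], [0.3], [1, 0])


@pytest.fixture(scope="module")
def assembled(small_study):
    ds = small_study.dataset
    dvm = resolve_drugs(ds.catalog, small_study.embeddings)
    model, info = train_abte(
        ds, dvm,
        amfp_hp=AMFPConfig(n_factors=8, epochs=10),
        text_hp=BioTextConfig(hidden_widths=(16,), epochs=10),
        stacker_hp=StackerConfig(epochs=100),
        seed=11,
    )
    batch = temporal_split(InteractionDataset(ds.catalog, ds.R_train),
                           InteractionDataset(ds.catalog, ds.R_test))
    return ds, dvm, model, info, batch


class TestSwitching:
    def test_cold_pair_returns_text_score_exactly(self, assembled):
        ds, dvm, model, _, batch = assembled
        text, am = model.component_scores(dvm, batch.pairs)
        out = abte_predict(model, dvm, batch.pairs)
        cold = ~_routing_mask(model.counts, batch.pairs, model.M)
        if cold.any():
            np.testing.assert_array_equal(out[cold], text[cold])

    def test_warm_pair_uses_stacker(self, assembled):
        ds, dvm, model, _, batch = assembled
        text, am = model.component_scores(dvm, batch.pairs)
        stacked = model.stacker.predict(text, am)
        out = abte_predict(model, dvm, batch.pairs)
        warm = _routing_mask(model.counts, batch.pairs, model.M)
        np.testing.assert_array_equal(out[warm], stacked[warm])

    def test_threshold_is_inclusive(self):
        """Both drugs at exactly M interactions route to stacking."""
        counts = np.array([3, 3, 0])
        mask = _routing_mask(counts, np.array([[0, 1], [0, 2]]), M=3)
        np.testing.assert_array_equal(mask, [True, False])

    def test_m_zero_routes_everything_to_stacking(self, assembled):
        ds, dvm, model, _, batch = assembled
        clone = ABTEModel(biotext=model.biotext, amfp=model.amfp,
                          stacker=model.stacker, M=0, counts=model.counts)
        text, am = model.component_scores(dvm, batch.pairs)
        stacked = model.stacker.predict(text, am)
        np.testing.assert_array_equal(abte_predict(clone, dvm, batch.pairs),
                                      stacked)

    def test_branches_partition_all_pairs(self, assembled):
        ds, dvm, model, _, batch = assembled
        warm = _routing_mask(model.counts, batch.pairs, model.M)
        assert warm.sum() + (~warm).sum() == len(batch)

    def test_self_pair_rejected(self, assembled):
        ds, dvm, model, _, _ = assembled
        with pytest.raises(ValueError):
            abte_predict(model, dvm, np.array([[2, 2]]))

    def test_negative_threshold_rejected(self, assembled):
        ds, dvm, model, _, _ = assembled
        with pytest.raises(ValueError):
            ABTEModel(biotext=model.biotext, amfp=model.amfp,
                      stacker=model.stacker, M=-1, counts=model.counts)


class TestTuneM:
    def test_single_candidate_returned(self, assembled):
        ds, dvm, model, info, _ = assembled
        val = info["validation"]
        counts = interaction_counts(info["sub_train"])
        m, table = tune_M(model.biotext, model.amfp, model.stacker, dvm, val,
                          counts, candidate_range=[3])
        assert m == 3 and set(table) == {3}

    def test_ties_resolve_to_smallest(self, assembled):
        """Candidates beyond the max count all route identically -> tie."""
        ds, dvm, model, info, _ = assembled
        val = info["validation"]
        counts = interaction_counts(info["sub_train"])
        big = int(counts.max()) + 1
        m, table = tune_M(model.biotext, model.amfp, model.stacker, dvm, val,
                          counts, candidate_range=[big, big + 5, big + 9])
        assert m == big
        assert len(set(table.values())) == 1

    def test_empty_range_rejected(self, assembled):
        ds, dvm, model, info, _ = assembled
        with pytest.raises(ValueError):
            tune_M(model.biotext, model.amfp, model.stacker, dvm,
                   info["validation"], model.counts, candidate_range=[])


class TestPipeline:
    def test_restriction_identity(self, assembled):
        """ABTE restricted to each branch equals that branch's model exactly."""
        ds, dvm, model, _, batch = assembled
        text, am = model.component_scores(dvm, batch.pairs)
        stacked = model.stacker.predict(text, am)
        out = abte_predict(model, dvm, batch.pairs)
        warm = _routing_mask(model.counts, batch.pairs, model.M)
        np.testing.assert_array_equal(out[warm], stacked[warm])
        np.testing.assert_array_equal(out[~warm], text[~warm])

    def test_end_to_end_reproducible(self, small_study):
        ds = small_study.dataset
        dvm = resolve_drugs(ds.catalog, small_study.embeddings)
        kw = dict(amfp_hp=AMFPConfig(n_factors=4, epochs=3),
                  text_hp=BioTextConfig(hidden_widths=(8,), epochs=3),
                  stacker_hp=StackerConfig(epochs=30), seed=21)
        m1, _ = train_abte(ds, dvm, **kw)
        m2, _ = train_abte(ds, dvm, **kw)
        batch = temporal_split(InteractionDataset(ds.catalog, ds.R_train),
                               InteractionDataset(ds.catalog, ds.R_test))
        np.testing.assert_array_equal(abte_predict(m1, dvm, batch.pairs),
                                      abte_predict(m2, dvm, batch.pairs))
        assert m1.M == m2.M
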