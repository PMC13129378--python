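"""Objectives, training loop, QC filter, patient-level splitting."""

import numpy as np
import pytest

from mr4dctreg import (DEFAULT_WEIGHTS, Grid, LabelMap, OrganInfo, PairSampler,
                       TrainConfig, Volume, k_fold,
                       multimodal_objective, patient_split,
                       qc_filter, temporal_objective)
from mr4dctreg.grids import BinaryMask
from mr4dctreg.losses import LossWeights
from mr4dctreg.network import NetworkConfig, build_network
from mr4dctreg.propagation import fit_grid
from mr4dctreg.training import (SubjectData, _pair_loss, prepare_subject,
                                train)


@pytest.fixture(scope="module")
def wgrid():
    return Grid((16, 16, 16), (2.0, 2.0, 2.0))


@pytest.fixture(scope="module")
def tiny_net(wgrid):
    return build_network(NetworkConfig(wgrid, levels=2, base_channels=4,
                                       seed=0))


def _toy_labelmap(grid, supervised=True):
    data = np.zeros(grid.shape, np.int32)
    data[4:10, 4:10, 4:10] = 1
    return LabelMap(grid, data, {1: OrganInfo("liver", supervised, True)})


class TestDefaultWeights:
    def test_final_training_weights(self):
        # weights of the retained configurations per model kind
        assert DEFAULT_WEIGHTS["temporal"] == LossWeights(0.3, 0.7)
        assert DEFAULT_WEIGHTS["multimodal"] == LossWeights(0.5, 0.5)
        assert DEFAULT_WEIGHTS["direct"] == LossWeights(0.5, 0.5)


class TestObjectives:
    def test_degenerate_temporal_pair_near_minimum(self, wgrid, tiny_net, rng):
        img = Volume(wgrid, rng.random(wgrid.shape))
        lab = _toy_labelmap(wgrid)
        loss, terms = temporal_objective(img, img, lab, lab, tiny_net)
        assert loss <= 0.05

    def test_aligned_multimodal_pair_near_minimum(self, wgrid, tiny_net, rng):
        ct = Volume(wgrid, rng.random(wgrid.shape))
        mr = Volume(wgrid, np.clip(0.9 - 0.8 * ct.data, 0, 1), modality="MR")
        lab = _toy_labelmap(wgrid)
        omega = BinaryMask(wgrid, np.ones(wgrid.shape, bool))
        loss, terms = multimodal_objective(ct, mr, lab, lab, omega, tiny_net)
        assert terms["dice_loss"] <= 0.05
        assert terms["regularization"] <= 1e-4

    def test_empty_omega_rejected(self, wgrid, tiny_net, rng):
        ct = Volume(wgrid, rng.random(wgrid.shape))
        lab = _toy_labelmap(wgrid)
        omega = BinaryMask(wgrid, np.zeros(wgrid.shape, bool))
        with pytest.raises(ValueError, match="empty"):
            multimodal_objective(ct, ct, lab, lab, omega, tiny_net)

    def test_gradient_flows_through_all_terms(self, wgrid, rng):
        """Each loss term responds to a parameter perturbation (no dead
        terms in the objective)."""
        net = build_network(NetworkConfig(wgrid, levels=2, base_channels=4,
                                          seed=3))
        fixed = rng.random(wgrid.shape)
        moving = np.roll(fixed, 2, axis=2)
        probs_f = np.zeros((1,) + wgrid.shape)
        probs_f[0, 4:10, 4:10, 4:10] = 1
        probs_m = np.roll(probs_f, 2, axis=3)
        cfg = TrainConfig("temporal", wgrid, levels=2, base_channels=4)
        w = LossWeights(1.0, 1.0)
        loss, _ = _pair_loss("temporal", fixed, moving, probs_f, probs_m,
                             None, net, w, cfg)
        loss.backward()
        gnorms = [np.abs(p.grad).max() if p.grad is not None else 0.0
                  for p in net.params()]
        assert max(gnorms) > 0.0
        # head weights must receive gradient (the field actually matters)
        assert np.abs(net.head.w.grad).max() > 0.0


class TestTrainLoop:
    @pytest.fixture(scope="class")
    def toy_sampler(self):
        wg = Grid((16, 16, 16), (2, 2, 2))
        r = np.random.default_rng(4)
        base = r.random(wg.shape)
        probs50 = np.zeros((1,) + wg.shape)
        probs50[0, 4:10, 4:10, 4:10] = 1
        ct = {50: base}
        probs = {50: probs50}
        for p in (0, 16, 33, 66, 83):
            shift = int(round(2 * (np.cos(2 * np.pi * (p / 100 if p != 16 else 1/6)) + 1) / 2))
            ct[p] = np.roll(base, -shift, axis=2)
            probs[p] = np.roll(probs50, -shift, axis=3)
        subj = SubjectData("toy", ct, probs, supervised_ids=(1,))
        return PairSampler([subj], "ct50-to-phase", seed=0)

    def test_seeded_training_deterministic(self, toy_sampler):
        wg = Grid((16, 16, 16), (2, 2, 2))
        cfg = TrainConfig("temporal", wg, iterations=5, levels=2,
                          base_channels=4, seed=1, val_every=5)
        n1, _ = train("temporal", toy_sampler, cfg)
        n2, _ = train("temporal", toy_sampler, cfg)
        assert all(np.array_equal(a.data, b.data)
                   for a, b in zip(n1.params(), n2.params()))

    def test_retained_checkpoint_not_worse_than_start(self, toy_sampler):
        wg = Grid((16, 16, 16), (2, 2, 2))
        cfg = TrainConfig("temporal", wg, iterations=30, levels=2,
                          base_channels=4, seed=1, val_every=10)
        _, log = train("temporal", toy_sampler, cfg)
        vals = log[log["val_loss"].notna()]["val_loss"].to_numpy()
        assert log.attrs["best_val_loss"] <= vals[0] + 1e-12

    def test_training_improves_on_one_pair(self, toy_sampler):
        wg = Grid((16, 16, 16), (2, 2, 2))
        cfg = TrainConfig("temporal", wg, iterations=60, levels=2,
                          base_channels=8, seed=0, val_every=60)
        _, log = train("temporal", toy_sampler, cfg)
        first = log["total"].dropna().iloc[:5].mean()
        last = log["total"].dropna().iloc[-5:].mean()
        assert last < first

    def test_wrong_pairing_rejected(self, toy_sampler):
        wg = Grid((16, 16, 16), (2, 2, 2))
        cfg = TrainConfig("multimodal", wg, iterations=2)
        with pytest.raises(ValueError, match="pairing"):
            train("multimodal", toy_sampler, cfg)

    def test_empty_sampler_rejected(self):
        with pytest.raises(ValueError):
            PairSampler([], "ct50-to-phase")


class TestPrepareSubject:
    def test_working_resolution_and_channels(self, phantom_study):
        rec = phantom_study.record
        wg = fit_grid(rec.native_grid, (16, 16, 8))
        subj = prepare_subject(rec, wg, seed=0)
        assert subj.ct[50].shape == (16, 16, 8)
        assert subj.mr_probs.shape[0] == len(subj.supervised_ids)
        assert subj.omega.any()
        assert 0.0 <= subj.ct[0].min() and subj.ct[0].max() <= 1.0


class TestQCFilter:
    def _mask(self, fill):
        g = Grid((12, 12, 12))
        d = np.zeros(g.shape, np.int32)
        d[fill] = 1
        return LabelMap(g, d, {1: OrganInfo("liver")})

    def test_counted_example(self):
        ref = self._mask((slice(2, 10), slice(2, 10), slice(2, 10)))
        good = self._mask((slice(2, 10), slice(2, 10), slice(2, 9)))
        mid = self._mask((slice(2, 10), slice(2, 10), slice(5, 10)))
        bad = self._mask((slice(0, 3), slice(0, 3), slice(0, 3)))
        kept, report = qc_filter([good, mid, bad], [ref, ref, ref],
                                 threshold=0.5)
        assert len(kept) == 2 and len(report) == 1
        assert report[0]["index"] == 2

    def test_threshold_zero_keeps_all(self):
        ref = self._mask((slice(2, 10),) * 3)
        bad = self._mask((slice(0, 2),) * 3)
        kept, _ = qc_filter([bad], [ref], threshold=0.0)
        assert len(kept) == 1

    def test_identical_kept_at_any_threshold(self):
        ref = self._mask((slice(2, 10),) * 3)
        kept, _ = qc_filter([ref], [ref], threshold=1.0)
        assert len(kept) == 1

    def test_unpaired_lists_rejected(self):
        ref = self._mask((slice(2, 10),) * 3)
        with pytest.raises(ValueError):
            qc_filter([ref, ref], [ref])


class TestSplitting:
    def test_clinical_cohort_sizes(self):
        ids = [f"p{i}" for i in range(170)]
        tr, va, te = patient_split(ids, (122 / 170, 32 / 170, 16 / 170),
                                   seed=0)
        assert (len(tr), len(va), len(te)) == (122, 32, 16)

    def test_partition_exact_and_disjoint(self):
        ids = list(range(37))
        tr, va, te = patient_split(ids, (0.6, 0.2, 0.2), seed=3)
        assert sorted(tr + va + te) == ids
        assert not (set(tr) & set(va) or set(tr) & set(te)
                    or set(va) & set(te))

    def test_seeded_reproducibility(self):
        ids = list(range(50))
        assert patient_split(ids, (0.5, 0.25, 0.25), seed=9) == \
            patient_split(ids, (0.5, 0.25, 0.25), seed=9)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            patient_split(list(range(10)), (0.5, 0.2, 0.2))

    def test_k_fold_partition(self):
        ids = list(range(23))
        folds = k_fold(ids, 5, seed=1)
        assert len(folds) == 5
        flat = [i for f in folds for i in f]
        assert sorted(flat) == ids

    def test_k_fold_too_few_subjects(self):
        with pytest.raises(ValueError):
            k_fold([1, 2], 3)


class TestConfigIO:
    def test_train_config_yaml_roundtrip(self, tmp_path):
        cfg = TrainConfig("multimodal", Grid((16, 16, 16), (2, 2, 2)),
                          iterations=50, seed=3, base_channels=4)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        assert TrainConfig.from_yaml(tmp_path / "cfg.yaml") == cfg

    def test_split_manifest(self, tmp_path):
        import json
        from mr4dctreg.training import save_split
        save_split(["a", "b"], ["c"], ["d"], tmp_path / "split.json")
        d = json.loads((tmp_path / "split.json").read_text())
        assert d == {"train": ["a", "b"], "val": ["c"], "test": ["d"]}
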