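import dataclasses

import numpy as np
import pytest

from snpfunnel.features import BLOCK_ROWS, BlockFeatureMap
from snpfunnel import model as M


def make_map(block_id, chrom, matrix, label="positive", confidence=0.9):
    matrix = np.asarray(matrix, dtype=np.int8)
    rows = matrix.shape[0]
    full = np.zeros((BLOCK_ROWS, matrix.shape[1]), dtype=np.int8)
    full[:rows] = matrix
    mask = np.zeros(BLOCK_ROWS, dtype=np.int8)
    mask[:rows] = 1
    return BlockFeatureMap(
        block_id=block_id,
        trait="t",
        chrom=str(chrom),
        matrix=full,
        row_mask=mask,
        snp_ids=[f"{block_id}_r{i}" for i in range(rows)],
        positions=np.arange(1, rows + 1, dtype=np.int64) * 100,
        pvalues=np.full(rows, 1e-5),
        label=label,
        label_confidence=confidence,
    )


def separable_maps(rng, chroms, per_chrom=6, F=12, rows=8):
    """Feature column 0 is a causal indicator present only in positives."""
    maps = []
    for c in chroms:
        for i in range(per_chrom):
            base = (rng.random((rows, F)) < 0.1).astype(np.int8)
            base[:, 0] = 0
            pos = base.copy()
            pos[rng.integers(0, rows), 0] = 1
            maps.append(make_map(f"b{c}_{i}", c, pos))
            maps.append(make_map(f"b{c}_{i}c", c, base, label="control", confidence=0.05))
    return maps


# ------------------------------------------------------------- splitting


def test_split_partitions_by_chromosome():
    maps = [make_map(f"b{c}", c, [[1]]) for c in (1, 2, 3)]
    split = M.split_by_chromosome(maps, {"2"}, {"3"})
    assert split.train_chroms == {"1"}
    assert [m.chrom for m in split.train] == ["1"]
    assert [m.chrom for m in split.val] == ["2"]
    assert [m.chrom for m in split.test] == ["3"]


def test_split_rejects_overlapping_holdouts():
    maps = [make_map("b1", 1, [[1]])]
    with pytest.raises(ValueError, match="both val and test"):
        M.split_by_chromosome(maps, {"1"}, {"1"})


def test_split_rejects_empty_training_set():
    maps = [make_map("b1", 1, [[1]]), make_map("b2", 2, [[1]])]
    with pytest.raises(ValueError, match="empty training"):
        M.split_by_chromosome(maps, {"1"}, {"2"})


def test_split_every_block_in_exactly_one_partition():
    rng = np.random.default_rng(19)
    maps = separable_maps(rng, chroms=[1, 2, 3, 4, 5], per_chrom=10)[:100]
    split = M.split_by_chromosome(maps, {"2"}, {"4", "5"})
    ids = lambda part: {m.block_id for m in part}
    assert ids(split.train) | ids(split.val) | ids(split.test) == {m.block_id for m in maps}
    assert not (ids(split.train) & ids(split.val))
    assert not (ids(split.train) & ids(split.test))
    assert not (ids(split.val) & ids(split.test))
    # control maps follow their source positive's chromosome
    for part in (split.train, split.val, split.test):
        chroms = {m.chrom for m in part}
        for m in part:
            assert m.chrom in chroms


# ------------------------------------------------------------- pretraining


def test_pretrain_zero_epochs_returns_seeded_init():
    rng = np.random.default_rng(0)
    maps = separable_maps(rng, chroms=[1], per_chrom=3)
    cfg = M.ModelConfig(seed=11, pretrain_epochs=0)
    pre = M.pretrain_autoencoder(maps, cfg)
    init = M._init_params(cfg, maps[0].n_features)
    for k in ("W1", "b1", "W2", "b2"):
        assert np.array_equal(pre.encoder_params[k], init[k])


def test_pretrain_reduces_reconstruction_loss():
    rng = np.random.default_rng(1)
    maps = separable_maps(rng, chroms=[1, 2], per_chrom=5)
    pre = M.pretrain_autoencoder(maps, M.ModelConfig(seed=2, pretrain_epochs=25))
    assert pre.final_loss <= pre.initial_loss
    assert len(pre.loss_history) == 26


def test_pretrain_compresses_rank_one_maps():
    """Maps whose rows are all identical are maximally compressible: the
    autoencoder should cut reconstruction error by >90%."""
    rng = np.random.default_rng(23)
    maps = []
    for i in range(16):
        row = (rng.random(12) < 0.5).astype(np.int8)
        maps.append(make_map(f"b{i}", 1, np.tile(row, (10, 1))))
    cfg = M.ModelConfig(seed=23, pretrain_epochs=150, ensemble_size=1)
    pre = M.pretrain_autoencoder(maps, cfg)
    assert pre.final_loss < 0.1 * pre.initial_loss


# ------------------------------------------------------------- loss algebra


def test_soft_cross_entropy_reduces_to_hard_labels_at_endpoints():
    p = np.array([0.2, 0.7, 0.99])
    assert M.soft_cross_entropy(p, np.ones(3)) == pytest.approx(float(np.mean(-np.log(p))))
    assert M.soft_cross_entropy(p, np.zeros(3)) == pytest.approx(float(np.mean(-np.log(1 - p))))
    # soft target: exact linear combination
    q = np.array([0.9, 0.9, 0.9])
    want = np.mean(-(q * np.log(p) + (1 - q) * np.log(1 - p)))
    assert M.soft_cross_entropy(p, q) == pytest.approx(float(want))


def test_config_validation():
    with pytest.raises(ValueError):
        M.ModelConfig(positive_label_confidence=0.4)
    with pytest.raises(ValueError):
        M.ModelConfig(control_label_confidence=0.6)
    with pytest.raises(ValueError):
        M.ModelConfig(kernel_rows=2)
    with pytest.raises(ValueError):
        M.ModelConfig(aggregation="median")
    with pytest.raises(ValueError):
        M.ModelConfig(ensemble_keep=0)


# ------------------------------------------------------------- training


def test_training_on_separable_data_reaches_perfect_training_auc():
    """One feature column flags causal rows in positives only; a threshold on
    that column alone separates blocks, so the trained model must too."""
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(29)
    maps = separable_maps(rng, chroms=[1, 2, 3, 4, 5])
    split = M.split_by_chromosome(maps, {"4"}, {"5"})
    cfg = M.ModelConfig(seed=29, pretrain_epochs=0, train_epochs=50)
    model = M.train(split, cfg)
    y = [1 if m.label == "positive" else 0 for m in split.train]
    auc = roc_auc_score(y, model.block_scores(split.train))
    assert auc == pytest.approx(1.0, abs=0.02)


def test_training_requires_both_classes():
    rng = np.random.default_rng(3)
    maps = [m for m in separable_maps(rng, chroms=[1, 2]) if m.label == "positive"]
    split = M.split_by_chromosome(maps, set(), {"2"})
    with pytest.raises(ValueError, match="both classes"):
        M.train(split, M.ModelConfig(seed=3))


def test_kernel_spanning_neighbor_rows_trains_too():
    rng = np.random.default_rng(6)
    maps = separable_maps(rng, chroms=[1, 2], per_chrom=4)
    split = M.split_by_chromosome(maps, set(), {"2"})
    cfg = M.ModelConfig(seed=6, kernel_rows=3, pretrain_epochs=5, train_epochs=15, ensemble_size=1)
    model = M.train(split, cfg, encoder_params=M.pretrain_autoencoder(split.train, cfg).member_encoders)
    hist = model.history[0]["train_loss"]
    assert hist[-1] < hist[0]


@pytest.mark.parametrize("agg", ["max", "softmax", "mean", "noisy-or"])
def test_aggregation_modes_agree_with_direct_formulas(agg):
    rng = np.random.default_rng(12)
    p = rng.uniform(0.01, 0.99, size=(4, BLOCK_ROWS))
    mask = np.zeros((4, BLOCK_ROWS), dtype=bool)
    for i, k in enumerate((1, 5, 17, 31)):
        mask[i, :k] = True
    s = M._aggregate(p, mask, agg, beta=8.0)
    for i in range(4):
        rows = p[i, mask[i]]
        if agg == "max":
            want = rows.max()
        elif agg == "mean":
            want = rows.mean()
        elif agg == "noisy-or":
            want = 1 - np.prod(1 - rows)
        else:
            w = np.exp(8.0 * (rows - rows.max()))
            want = float((w / w.sum() * rows).sum())
        assert s[i] == pytest.approx(float(want), rel=1e-9)


def test_gradients_match_finite_differences():
    """Manual backprop against numerical gradients on a small random case."""
    rng = np.random.default_rng(77)
    cfg = M.ModelConfig(seed=77, conv_channels=(3, 3), dense_units=3, kernel_rows=3,
                        aggregation="softmax", monotone=False)
    F = 5
    params = M._init_params(cfg, F)
    for k in ("Wdec", "bdec"):
        params.pop(k)
    for k in params:  # move biases off the ReLU kinks (all-zero rows land exactly there)
        params[k] = params[k] + 0.05 * rng.normal(size=params[k].shape)
    X = (rng.random((3, BLOCK_ROWS, F)) < 0.3).astype(float)
    mask = np.zeros((3, BLOCK_ROWS), dtype=bool)
    mask[:, :7] = True
    q = np.array([0.9, 0.05, 0.9])
    _, grads = M._classifier_grads(params, X, mask, q, cfg)

    def loss_at(pp):
        p, _ = M._row_scores(pp, X)
        return M.soft_cross_entropy(M._aggregate(p, mask, cfg.aggregation, cfg.softmax_beta), q)

    eps = 1e-6
    for key in ("Wo", "bd", "W2", "W1"):
        flat = params[key].reshape(-1) if params[key].ndim else params[key].reshape(1)
        gflat = grads[key].reshape(-1) if grads[key].ndim else grads[key].reshape(1)
        for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
            orig = flat[idx]
            flat[idx] = orig + eps
            up = loss_at(params)
            flat[idx] = orig - eps
            down = loss_at(params)
            flat[idx] = orig
            num = (up - down) / (2 * eps)
            assert gflat[idx] == pytest.approx(num, rel=1e-4, abs=1e-7)


def test_monotone_constraint_keeps_weights_nonnegative_and_scores_monotone():
    rng = np.random.default_rng(15)
    maps = separable_maps(rng, chroms=[1, 2], per_chrom=4)
    split = M.split_by_chromosome(maps, set(), {"2"})
    cfg = M.ModelConfig(seed=15, pretrain_epochs=0, train_epochs=20, ensemble_size=2)
    model = M.train(split, cfg)
    for params in model.members:
        for k in M._MONOTONE_KEYS:
            assert (params[k] >= 0).all()
    # adding a feature to a row can only raise its score
    base = make_map("bx", 9, (rng.random((6, 12)) < 0.2).astype(np.int8))
    richer = dataclasses.replace(base, matrix=base.matrix.copy())
    richer.matrix[2, 7] = 1
    if base.matrix[2, 7] == 1:
        base.matrix[2, 7] = 0
    s0 = model.row_score_matrix([base])[0, 2]
    s1 = model.row_score_matrix([richer])[0, 2]
    assert s1 >= s0 - 1e-12


# ------------------------------------------------------------- prediction


def _trained_small(rng_seed=41):
    rng = np.random.default_rng(rng_seed)
    maps = separable_maps(rng, chroms=[1, 2, 3])
    split = M.split_by_chromosome(maps, set(), {"3"})
    cfg = M.ModelConfig(seed=rng_seed, pretrain_epochs=0, train_epochs=25, ensemble_size=2)
    return M.train(split, cfg), split


def test_scores_in_unit_interval_and_deterministic():
    model, split = _trained_small()
    s1 = M.predict_scores(model, split.test)
    s2 = M.predict_scores(model, split.test)
    assert all(0.0 <= s.score <= 1.0 for s in s1)
    assert [(s.snp_id, s.score) for s in s1] == [(s.snp_id, s.score) for s in s2]
    # one score per masked-in row
    assert len(s1) == sum(m.n_valid for m in split.test)


def test_predict_rejects_feature_count_mismatch():
    model, _ = _trained_small()
    other = make_map("bz", 1, np.zeros((3, 5), dtype=np.int8))
    with pytest.raises(ValueError, match="mismatch"):
        M.predict_scores(model, [other])


def test_planted_signal_scores_rank_causal_rows_higher(default_dataset):
    """On the synthetic benchmark, mean prediction score of truth-causal SNPs
    exceeds the mean score of null SNPs."""
    from snpfunnel import blocks as B, features as F, gwas
    from snpfunnel._rng import child_rng

    ds = default_dataset
    filt = gwas.filter_by_pvalue(ds.stats["trait1"])
    blks = B.build_blocks(filt)
    pos = [F.build_block_map(b, ds.tracks) for b in blks]
    rng = child_rng(37, "ctrl-trait1")
    maps = pos + [F.make_control_block(m, rng) for m in pos]
    split = M.split_by_chromosome(maps, {"4"}, {"5", "6"})
    cfg = M.ModelConfig(seed=37)
    pre = M.pretrain_autoencoder(split.train, cfg)
    model = M.train(split, cfg, encoder_params=pre.member_encoders)
    scores = M.predict_scores(model, pos)
    causal = [s.score for s in scores if ds.truth.is_causal(s.snp_id)]
    null = [s.score for s in scores if not ds.truth.is_causal(s.snp_id)]
    assert np.mean(causal) > np.mean(null)


# ------------------------------------------------------------- selection


def test_candidate_threshold_is_strict():
    scores = [
        M.SnpScore("a", "b1", "t", 0.5),
        M.SnpScore("b", "b1", "t", 0.5000001),
        M.SnpScore("c", "b1", "t", 0.4),
    ]
    cands = M.select_candidates(scores)
    assert [s.snp_id for s in cands] == ["b"]
    assert all(s.is_initial_candidate for s in cands)


def test_all_below_threshold_gives_empty_candidates():
    assert M.select_candidates([M.SnpScore("a", "b", "t", 0.4)] * 3) == []


def test_candidate_count_matches_linear_scan():
    rng = np.random.default_rng(200)
    scores = [M.SnpScore(f"s{i}", "b", "t", float(v)) for i, v in enumerate(rng.random(200))]
    got = len(M.select_candidates(scores, 0.5))
    assert got == sum(1 for s in scores if s.score > 0.5)


def test_block_top_hand_enumerated_table():
    mk = lambda i, b, sc: M.SnpScore(f"s{i}", b, "t", sc, pos=i, pvalue=1e-5)
    scores = [mk(1, "b1", 0.9), mk(2, "b1", 0.7), mk(3, "b2", 0.6), mk(4, "b3", 0.4), mk(5, "b3", 0.3)]
    tops = M.select_block_top(M.select_candidates(scores, 0.5))
    assert {(t.block_id, t.snp_id) for t in tops} == {("b1", "s1"), ("b2", "s3")}
    assert all(t.is_block_top and t.is_initial_candidate for t in tops)


def test_block_top_tie_broken_by_lower_pvalue():
    a = M.SnpScore("a", "b1", "t", 0.8, pos=10, pvalue=1e-6, is_initial_candidate=True)
    b = M.SnpScore("b", "b1", "t", 0.8, pos=5, pvalue=1e-5, is_initial_candidate=True)
    [top] = M.select_block_top([a, b])
    assert top.snp_id == "a"


# ------------------------------------------------------------- evaluation


def test_auc_matches_pair_count_oracle_on_model_scores():
    model, split = _trained_small()
    report = M.evaluate_auc(model, split.test)
    scores = model.block_scores(split.test)
    labels = [1 if m.label == "positive" else 0 for m in split.test]
    num, den = 0.0, 0
    for si, li in zip(scores, labels):
        for sj, lj in zip(scores, labels):
            if li == 1 and lj == 0:
                den += 1
                num += 1.0 if si > sj else (0.5 if si == sj else 0.0)
    assert report.auc == pytest.approx(num / den, abs=1e-12)
    assert report.n_test_blocks == len(split.test)


def test_auc_all_tied_scores_is_half():
    model, _ = _trained_small()
    m = make_map("same", 1, np.zeros((4, 12), dtype=np.int8))
    mc = dataclasses.replace(m, block_id="same_c", label="control", label_confidence=0.05)
    report = M.evaluate_auc(model, [m, mc, dataclasses.replace(m, block_id="p2"),
                                    dataclasses.replace(mc, block_id="c2")])
    assert report.auc == pytest.approx(0.5)


def test_auc_single_class_or_empty_rejected():
    model, split = _trained_small()
    positives = [m for m in split.test if m.label == "positive"]
    with pytest.raises(ValueError, match="single class"):
        M.evaluate_auc(model, positives)
    with pytest.raises(ValueError, match="empty"):
        M.evaluate_auc(model, [])
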