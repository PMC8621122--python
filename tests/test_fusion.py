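"""Label fusion: majority vote, global and local NCC weighting."""

import numpy as np
import pytest

from dynajoint import (CandidateStack, FusionConfig, LabelMap, Volume,
                       fuse_labels, lncc_weight_maps, rank_atlases_global)


# -- brute-force oracle ----------------------------------------------------

def brute_force_fuse(label_arrays, image_arrays, target, method, k, r):
    """Per-voxel reimplementation with explicit loops.

    Ranking/weighting reuses the package's score maps (they are checked
    separately against their own limits); the per-voxel atlas selection
    and vote counting — the part fusion can get wrong — is redone by hand.
    """
    from collections import Counter

    stack = _stack(label_arrays, image_arrays)
    config = FusionConfig(method, k=k, r=r)
    shape = target.shape
    alphabet = sorted(set(np.unique(np.stack(label_arrays))) | {0})
    if method == "GNCC":
        order = rank_atlases_global(stack, target, config.air_threshold)[:r]
    if method == "LNCC":
        weights = np.stack([w.voxels for w in
                            lncc_weight_maps(stack, target, config)])
    out = np.zeros(shape, dtype=np.int32)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for l in range(shape[2]):
                if method == "MV":
                    votes = [arr[i, j, l] for arr in label_arrays]
                elif method == "GNCC":
                    votes = [label_arrays[a][i, j, l] for a in order]
                else:
                    w = weights[:, i, j, l]
                    chosen = sorted(range(len(label_arrays)),
                                    key=lambda a: (-w[a], a))[:r]
                    votes = [label_arrays[a][i, j, l] for a in chosen]
                counts = Counter(votes)
                best = max(counts.values())
                out[i, j, l] = min(v for v, c in counts.items() if c == best)
    return out


def _stack(label_arrays, image_arrays):
    return CandidateStack(
        labels=[LabelMap(labels=a.astype(np.int32)) for a in label_arrays],
        images=[Volume(voxels=a.astype(float)) for a in image_arrays],
        atlas_ids=[f"a{i}" for i in range(len(label_arrays))],
    )


def _random_case(rng, size, n_atlas, n_labels=3):
    shape = (size, size, size)
    target = Volume(voxels=rng.normal(200, 80, shape))
    labels = [rng.integers(0, n_labels, shape) for _ in range(n_atlas)]
    images = [target.voxels + rng.normal(0, s, shape)
              for s in rng.uniform(5, 60, n_atlas)]
    return target, labels, images


@pytest.mark.parametrize("method", ["MV", "GNCC", "LNCC"])
def test_fusion_matches_per_voxel_oracle(method):
    rng = np.random.default_rng(11)
    for trial in range(6):
        size = int(rng.integers(5, 11))
        n_atlas = int(rng.integers(3, 6))
        r = int(rng.integers(1, n_atlas + 1))
        target, labels, images = _random_case(rng, size, n_atlas)
        got = fuse_labels(_stack(labels, images), target,
                          FusionConfig(method, k=2, r=r))
        want = brute_force_fuse(labels, images, target, method, k=2, r=r)
        np.testing.assert_array_equal(got.labels, want)


def test_all_candidates_identical_returns_them():
    rng = np.random.default_rng(0)
    base = rng.integers(0, 3, (6, 6, 6))
    target = Volume(voxels=rng.normal(size=(6, 6, 6)))
    for method in ("MV", "GNCC", "LNCC"):
        out = fuse_labels(_stack([base] * 3, [target.voxels] * 3), target,
                          FusionConfig(method, k=2, r=2))
        np.testing.assert_array_equal(out.labels, base)


def test_majority_vote_counts_and_tie_break():
    # votes {1,1,2} -> 1; votes {1,2} (with a 0) -> tie between 0? no:
    # {0,1,2} all singletons -> smallest label 0 wins
    a = np.full((1, 1, 2), 0, dtype=np.int64)
    b = np.full((1, 1, 2), 0, dtype=np.int64)
    c = np.full((1, 1, 2), 0, dtype=np.int64)
    a[0, 0, 0], b[0, 0, 0], c[0, 0, 0] = 1, 1, 2
    a[0, 0, 1], b[0, 0, 1], c[0, 0, 1] = 1, 2, 0
    target = Volume(voxels=np.zeros((1, 1, 2)))
    out = fuse_labels(_stack([a, b, c], [a, b, c]), target, FusionConfig("MV"))
    assert out.labels[0, 0, 0] == 1          # majority
    assert out.labels[0, 0, 1] == 0          # three-way tie -> smallest label


def test_mv_permutation_invariant():
    rng = np.random.default_rng(5)
    target, labels, images = _random_case(rng, 7, 4)
    out1 = fuse_labels(_stack(labels, images), target, FusionConfig("MV"))
    perm = [2, 0, 3, 1]
    out2 = fuse_labels(_stack([labels[i] for i in perm],
                              [images[i] for i in perm]), target,
                       FusionConfig("MV"))
    np.testing.assert_array_equal(out1.labels, out2.labels)


def test_lncc_with_all_atlases_equals_mv():
    rng = np.random.default_rng(9)
    target, labels, images = _random_case(rng, 8, 4)
    mv = fuse_labels(_stack(labels, images), target, FusionConfig("MV"))
    lncc = fuse_labels(_stack(labels, images), target,
                       FusionConfig("LNCC", k=3, r=4))
    np.testing.assert_array_equal(mv.labels, lncc.labels)


def test_r_larger_than_stack_rejected():
    rng = np.random.default_rng(1)
    target, labels, images = _random_case(rng, 5, 3)
    with pytest.raises(ValueError, match="exceeds"):
        fuse_labels(_stack(labels, images), target, FusionConfig("LNCC", r=4))


def test_fused_labels_subset_of_candidate_labels():
    rng = np.random.default_rng(13)
    target, labels, images = _random_case(rng, 9, 5, n_labels=4)
    for method in ("MV", "GNCC", "LNCC"):
        out = fuse_labels(_stack(labels, images), target,
                          FusionConfig(method, k=2, r=3))
        assert set(np.unique(out.labels)) <= set(np.unique(np.stack(labels)))


# -- ranking ---------------------------------------------------------------

def test_exact_copy_ranks_first_with_full_correlation(small_atlas):
    target = small_atlas.image
    rng = np.random.default_rng(2)
    noisy = target.voxels + rng.normal(0, 50, target.shape)
    stack = _stack([np.zeros(target.shape, dtype=int)] * 2,
                   [noisy, target.voxels])
    order = rank_atlases_global(stack, target)
    assert order[0] == 1


def test_ranking_orders_by_noise_level(small_atlas):
    target = small_atlas.image
    rng = np.random.default_rng(3)
    sigmas = [80.0, 5.0, 20.0]
    images = [target.voxels + rng.normal(0, s, target.shape) for s in sigmas]
    stack = _stack([np.zeros(target.shape, dtype=int)] * 3, images)
    assert rank_atlases_global(stack, target) == [1, 2, 0]


def test_ranking_tie_broken_by_stack_order(small_atlas):
    target = small_atlas.image
    stack = _stack([np.zeros(target.shape, dtype=int)] * 2,
                   [target.voxels, target.voxels])
    assert rank_atlases_global(stack, target) == [0, 1]


# -- local weights ---------------------------------------------------------

def test_weight_map_near_one_for_identical_atlas(small_atlas):
    target = small_atlas.image
    stack = _stack([np.zeros(target.shape, dtype=int)], [target.voxels])
    w = lncc_weight_maps(stack, target, FusionConfig("LNCC", k=3))[0]
    interior = w.voxels[4:-4, 4:-4, 4:-4]
    assert np.nanmin(interior) > 0.99


def test_weight_map_separates_good_and_corrupt_halves(small_atlas):
    target = small_atlas.image
    rng = np.random.default_rng(7)
    half = target.shape[0] // 2
    corrupt = target.voxels.copy()
    corrupt[half:] = rng.normal(200, 150, corrupt[half:].shape)
    stack = _stack([np.zeros(target.shape, dtype=int)], [corrupt])
    w = lncc_weight_maps(stack, target, FusionConfig("LNCC", k=2))[0]
    assert w.voxels[:half].mean() > w.voxels[half:].mean() + 0.3


def test_huge_kernel_approaches_global_ncc(small_atlas):
    target = small_atlas.image
    rng = np.random.default_rng(8)
    atlas_img = target.voxels + rng.normal(0, 30, target.shape)
    stack = _stack([np.zeros(target.shape, dtype=int)], [atlas_img])
    w = lncc_weight_maps(stack, target,
                         FusionConfig("LNCC", k=64))[0]
    # global NCC over the whole volume
    t = target.voxels.ravel() - target.voxels.mean()
    a = atlas_img.ravel() - atlas_img.mean()
    gncc = t @ a / np.sqrt((t ** 2).sum() * (a ** 2).sum())
    assert abs(w.voxels.mean() - gncc) < 0.05
    assert w.voxels.std() < 0.05


# -- candidate building and LOOCV driver -----------------------------------

def test_failing_atlas_dropped_with_warning(small_atlas, caplog, monkeypatch):
    import dynajoint.fusion as fusion_mod
    from dynajoint import (RegistrationConfig, RegistrationError,
                           build_candidates, desk_stages)
    from dynajoint.phantom import Atlas

    bad_image = small_atlas.image.with_voxels(small_atlas.image.voxels.copy())
    atlases = [Atlas(image=bad_image if i == 1 else small_atlas.image,
                     labels=small_atlas.labels,
                     landmarks=small_atlas.landmarks, id=f"copy-{i}")
               for i in range(3)]
    real = fusion_mod.register_pairwise

    def flaky(target, moving, config):
        if moving is bad_image:
            raise RegistrationError("synthetic failure for the middle atlas")
        return real(target, moving, config)

    monkeypatch.setattr(fusion_mod, "register_pairwise", flaky)
    cfg = RegistrationConfig(stages=desk_stages("MSD"), rng_seed=1)
    with caplog.at_level("WARNING"):
        stack = build_candidates(small_atlas.image, atlases, cfg)
    assert len(stack) == 2
    assert stack.atlas_ids == ["copy-0", "copy-2"]
    assert any("dropped" in r.message for r in caplog.records)


def test_loocv_identical_atlases_near_perfect_dice(small_atlas):
    from dynajoint import RegistrationConfig, desk_stages, loocv_segmentation
    from dynajoint.phantom import Atlas

    atlases = [Atlas(image=small_atlas.image, labels=small_atlas.labels,
                     landmarks=small_atlas.landmarks, id=f"copy-{i}")
               for i in range(3)]
    cfg = RegistrationConfig(stages=desk_stages("MSD"), rng_seed=2)
    table = loocv_segmentation(atlases, cfg, FusionConfig("MV"))
    assert len(table) == 3 * 2          # 3 folds x 2 bones
    # registering an image to an exact copy of itself leaves at most a
    # sub-voxel boundary wiggle
    assert table.dice.min() > 0.98


def test_loocv_requires_three_atlases(small_atlas):
    from dynajoint import loocv_segmentation
    from dynajoint.phantom import Atlas

    pair = [Atlas(image=small_atlas.image, labels=small_atlas.labels,
                  landmarks=small_atlas.landmarks, id=f"c{i}")
            for i in range(2)]
    with pytest.raises(ValueError):
        loocv_segmentation(pair)
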