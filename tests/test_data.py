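"""Readers, augmentation doubling, split protocols, phantom generator."""

import json

import h5py
import numpy as np
import pytest
from PIL import Image

from ansa_edge.data import (AugmentationSpec, SplitSpec, TRANSFORM_NAMES,
                            UnsupportedMatFormatError, augment_double,
                            read_cheng_mat, read_image_folder, split)
from ansa_edge.synthetic import generate_synthetic_dataset


# ---------------------------------------------------------------------------
# folder reader
# ---------------------------------------------------------------------------

@pytest.fixture
def class_folder(tmp_path, rng):
    for cls in ("glioma", "meningioma"):
        d = tmp_path / cls
        d.mkdir()
        for i in range(3):
            arr = (rng.random((512, 512)) * 255).astype(np.uint8)
            Image.fromarray(arr).save(d / f"im{i}.png")
    return tmp_path


def test_read_image_folder_labels_and_resize(class_folder):
    images = read_image_folder(class_folder, input_size=256)
    assert len(images) == 6
    assert {im.label for im in images} == {0, 1}
    assert all(im.pixels.shape == (256, 256) for im in images)
    assert all(0.0 <= im.pixels.min() and im.pixels.max() <= 1.0 for im in images)
    # lexicographic: glioma < meningioma
    assert images[0].label_name == "glioma"


def test_read_image_folder_deterministic(class_folder):
    a = read_image_folder(class_folder, input_size=64)
    b = read_image_folder(class_folder, input_size=64)
    assert [im.source_id for im in a] == [im.source_id for im in b]
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x.pixels, y.pixels)


def test_read_image_folder_warns_on_empty_class(tmp_path):
    (tmp_path / "empty_class").mkdir()
    (tmp_path / "full").mkdir()
    Image.fromarray(np.zeros((8, 8), dtype=np.uint8)).save(tmp_path / "full" / "a.png")
    with pytest.warns(UserWarning, match="empty"):
        read_image_folder(tmp_path, input_size=8)


# ---------------------------------------------------------------------------
# HDF5 .mat reader
# ---------------------------------------------------------------------------

def write_mat(path, label=2, size=512, with_mask=True, pid="P001"):
    with h5py.File(path, "w") as f:
        cj = f.create_group("cjdata")
        rng = np.random.default_rng(int(label))
        cj.create_dataset("image", data=(rng.random((size, size)) * 3000).astype(np.int16))
        cj.create_dataset("label", data=np.array([[float(label)]]))
        cj.create_dataset("PID", data=np.array([[ord(c)] for c in pid], dtype=np.uint16))
        cj.create_dataset("tumorBorder", data=np.zeros((1, 10)))
        if with_mask:
            cj.create_dataset("tumorMask", data=rng.random((size, size)) > 0.9)


def test_read_cheng_mat_roundtrip(tmp_path):
    write_mat(tmp_path / "1.mat", label=2)
    images = read_cheng_mat(tmp_path, input_size=256)
    assert len(images) == 1
    im = images[0]
    assert im.label == 1 and im.label_name == "glioma"
    assert im.pixels.shape == (256, 256)
    assert im.source_id == "P001"


def test_read_cheng_mat_missing_mask_tolerated(tmp_path):
    write_mat(tmp_path / "1.mat", label=3, with_mask=False)
    images = read_cheng_mat(tmp_path, input_size=64)
    assert images[0].label_name == "pituitary"
    assert images[0].blob_mask is None


def test_read_cheng_mat_stable_order_and_errors(tmp_path):
    for i, lab in enumerate((1, 2, 3)):
        write_mat(tmp_path / f"{i}.mat", label=lab, size=64)
    images = read_cheng_mat(tmp_path, input_size=64)
    assert [im.label for im in images] == [0, 1, 2]
    # missing field
    bad = tmp_path / "bad"
    bad.mkdir()
    with h5py.File(bad / "x.mat", "w") as f:
        f.create_group("cjdata").create_dataset("image", data=np.ones((4, 4)))
    with pytest.raises(ValueError, match="label"):
        read_cheng_mat(bad, input_size=64)
    # legacy non-HDF5 container
    legacy = tmp_path / "legacy"
    legacy.mkdir()
    (legacy / "old.mat").write_bytes(b"MATLAB 5.0 MAT-file" + b"\x00" * 64)
    with pytest.raises(UnsupportedMatFormatError):
        read_cheng_mat(legacy, input_size=64)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def test_augment_doubles_and_preserves_labels():
    images = generate_synthetic_dataset(5, 3, 32, seed=1)
    out = augment_double(images, AugmentationSpec(seed=3))
    assert len(out) == 2 * len(images)
    assert [im.label for im in out[:15]] == [im.label for im in out[15:]]
    assert all("+aug:" in im.source_id for im in out[15:])
    with pytest.raises(ValueError):
        augment_double([])


def test_augment_single_image():
    images = generate_synthetic_dataset(1, 3, 32, seed=1)[:1]
    out = augment_double(images, AugmentationSpec(seed=0))
    assert len(out) == 2 and out[1].label == out[0].label


def test_augment_transform_frequencies_uniform():
    images = generate_synthetic_dataset(2400, 3, 8, seed=2)  # 7200 tiny images
    out = augment_double(images, AugmentationSpec(seed=9))
    names = [im.source_id.rsplit("+aug:", 1)[1] for im in out[len(images):]]
    counts = {t: names.count(t) for t in TRANSFORM_NAMES}
    for t, c in counts.items():
        assert abs(c / len(images) - 1 / 7) < 0.02, (t, c)


def test_augment_deterministic_given_seed():
    images = generate_synthetic_dataset(4, 3, 32, seed=1)
    a = augment_double(images, AugmentationSpec(seed=5))
    b = augment_double(images, AugmentationSpec(seed=5))
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x.pixels, y.pixels)


def test_augment_keeps_pixels_in_unit_range():
    images = generate_synthetic_dataset(10, 3, 32, seed=4)
    out = augment_double(images, AugmentationSpec(seed=1))
    for im in out:
        assert im.pixels.min() >= 0.0 and im.pixels.max() <= 1.0


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def test_holdout_sizes_for_published_dataset_count():
    n = 3064
    images = generate_synthetic_dataset(n // 4 + 1, 4, 8, seed=0)[:n]
    part = split(images, SplitSpec(mode="holdout_70_10_20", seed=1))
    assert (len(part.train), len(part.val), len(part.test)) == (2144, 306, 614)


def test_holdout_disjoint_and_exhaustive():
    images = generate_synthetic_dataset(20, 3, 8, seed=1)
    part = split(images, SplitSpec(seed=2))
    ids = [im.source_id for im in images]
    got = [im.source_id for part_list in part for im in part_list]
    assert sorted(got) == sorted(ids)
    assert len(set(got)) == len(got)


def test_holdout_seed_reproducible():
    images = generate_synthetic_dataset(10, 3, 8, seed=1)
    a = split(images, SplitSpec(seed=7))
    b = split(images, SplitSpec(seed=7))
    assert [im.source_id for im in a.train] == [im.source_id for im in b.train]


def test_stratified_holdout_class_proportions():
    images = generate_synthetic_dataset(40, 3, 8, seed=3)
    part = split(images, SplitSpec(seed=1, stratified=True))
    for subset, frac in zip(part, (0.7, 0.1, 0.2)):
        for lab in (0, 1, 2):
            n_lab = sum(1 for im in subset if im.label == lab)
            assert abs(n_lab - frac * 40) <= 1


def test_kfold_covers_each_sample_once():
    images = generate_synthetic_dataset(20, 3, 8, seed=1)  # n=60
    part = split(images, SplitSpec(mode="kfold_5", seed=4))
    sizes = [len(f) for f in part.folds]
    assert max(sizes) - min(sizes) <= 1 and sum(sizes) == 60
    tested = [im.source_id for f in part.folds for im in f]
    assert sorted(tested) == sorted(im.source_id for im in images)
    pooled = sum(len(test) for _, test in part.iterate())
    assert pooled == 60


def test_split_rejects_tiny_inputs():
    images = generate_synthetic_dataset(1, 3, 8, seed=0)
    with pytest.raises(ValueError):
        split(images[:4], SplitSpec(mode="kfold_5"))
    with pytest.raises(ValueError):
        split(images[:3], SplitSpec(mode="holdout_70_10_20"))
    with pytest.raises(ValueError):
        SplitSpec(mode="bootstrap")


# ---------------------------------------------------------------------------
# phantom generator
# ---------------------------------------------------------------------------

def test_generator_counts_labels_and_masks():
    images = generate_synthetic_dataset(10, 3, 64, seed=1)
    assert len(images) == 30
    assert {im.label for im in images} == {0, 1, 2}
    assert all(im.blob_mask is not None and im.blob_mask.any()
               for im in images)


def test_generator_fourth_class_has_no_blob():
    images = generate_synthetic_dataset(3, 4, 32, seed=1)
    no_tumor = [im for im in images if im.label == 3]
    assert len(no_tumor) == 3
    assert all(im.blob_mask is None for im in no_tumor)


def test_generator_deterministic():
    a = generate_synthetic_dataset(5, 3, 32, seed=9)
    b = generate_synthetic_dataset(5, 3, 32, seed=9)
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x.pixels, y.pixels)
    c = generate_synthetic_dataset(5, 3, 32, seed=10)
    assert any(not np.array_equal(x.pixels, y.pixels) for x, y in zip(a, c))


def test_generator_blob_contrast():
    """Mean intensity inside the blob exceeds the background mean by >= 0.2
    on every tumor image."""
    for im in generate_synthetic_dataset(20, 3, 64, seed=2):
        inside = im.pixels[im.blob_mask].mean()
        outside = im.pixels[~im.blob_mask].mean()
        assert inside - outside >= 0.2, im.source_id


def test_save_synthetic_writes_pngs(tmp_path):
    from ansa_edge.synthetic import save_synthetic_dataset

    images = generate_synthetic_dataset(2, 4, 16, seed=0)
    save_synthetic_dataset(images, tmp_path)
    manifest = json.loads((tmp_path / "labels.json").read_text())
    assert len(manifest) == 8
    assert sum("mask" in e for e in manifest) == 6
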