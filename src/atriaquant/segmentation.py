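"""Training-data preparation, curriculum training, and volume inference.

The segmenter consumes axial 2D slices of min-max-normalized bright-blood
volumes with 4-class label slices.  Training follows a two-phase curriculum:
slices containing at least 50 pixels of *each* foreground label (blood pool,
veins, valve) form a balanced subset that is trained first, before the full
slice set is introduced — this prevents the abundant empty slices from
driving the net toward under-segmentation.  Subjects (not slices) are split
70/10/20 into train/validation/test.

Inference runs slicewise, binarizes each foreground channel at probability
0.5 (a probability of exactly 0.5 counts as foreground), re-stacks the
slices into 3D and keeps only the largest connected foreground component.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage

from .io import LabelMap, Volume, minmax_normalize, resample_slicewise
from .unet import Adam, NetConfig, UNet

#: a slice enters the balanced subset only with >= this many pixels of every
#: foreground label
BALANCED_MIN_PIXELS = 50

_STRUCT_26 = ndimage.generate_binary_structure(3, 3)


@dataclasses.dataclass
class TrainingCorpus:
    """2D slices with one-hot labels, split by subject."""

    images: np.ndarray        # (n_slices, H, W) float32 in [0, 1]
    labels: np.ndarray        # (n_slices, H, W) int labels
    subject: np.ndarray       # (n_slices,) subject index per slice
    split: np.ndarray         # (n_slices,) 0 train / 1 validation / 2 test
    balanced: np.ndarray      # (n_slices,) slice qualifies for phase-1 training

    def subset(self, split_code: int):
        m = self.split == split_code
        return self.images[m], self.labels[m], self.balanced[m]


def _partition_subjects(n: int, fractions, rng: np.random.Generator) -> np.ndarray:
    """Assign each of ``n`` subjects to a split cell; exact counts by rounding."""
    fractions = np.asarray(fractions, dtype=float)
    if not np.isclose(fractions.sum(), 1.0):
        raise ValueError("split fractions must sum to 1")
    n_cells = int(np.count_nonzero(fractions))
    if n < n_cells:
        raise ValueError(f"{n} subjects cannot fill {n_cells} split cells")
    counts = np.floor(fractions * n).astype(int)
    # distribute the remainder to the cells with the largest fractional parts
    rem = n - counts.sum()
    order = np.argsort(-(fractions * n - counts))
    for i in range(rem):
        counts[order[i % len(order)]] += 1
    # every nonzero-fraction cell gets at least one subject
    for c in np.nonzero(fractions)[0]:
        while counts[c] == 0:
            donor = int(np.argmax(counts))
            counts[donor] -= 1
            counts[c] += 1
    assignment = np.repeat(np.arange(len(fractions)), counts)
    return assignment[rng.permutation(n)]


def make_corpus(
    volumes,
    split=(0.7, 0.1, 0.2),
    cfg: NetConfig | None = None,
    seed: int = 0,
    min_pixels: int = BALANCED_MIN_PIXELS,
    slice_step: int = 1,
) -> TrainingCorpus:
    """Build a training corpus from (Volume, LabelMap) pairs.

    The split is per subject, never per slice.  Slices are resampled to the
    network's in-plane matrix, intensities min-max normalized per volume,
    and the balanced (phase-1) subset computed with the >=``min_pixels``
    per-foreground-label rule.  ``slice_step`` subsamples slices along the
    through-plane axis.
    """
    cfg = cfg or NetConfig()
    rng = np.random.default_rng(seed)
    assign = _partition_subjects(len(volumes), split, rng)

    images, labels, subject, split_code = [], [], [], []
    for subj, (vol, lab) in enumerate(volumes):
        target_spacing = (
            vol.spacing[0] * vol.shape[0] / cfg.input_size,
            vol.spacing[1] * vol.shape[1] / cfg.input_size,
        )
        v = resample_slicewise(minmax_normalize(vol), target_spacing, (cfg.input_size, cfg.input_size))
        l = resample_slicewise(lab, target_spacing, (cfg.input_size, cfg.input_size))
        for k in range(0, vol.shape[2], slice_step):
            images.append(v.data[:, :, k].astype(np.float32))
            labels.append(l.data[:, :, k].astype(np.int8))
            subject.append(subj)
            split_code.append(assign[subj])
    images = np.stack(images)
    labels = np.stack(labels)
    balanced = np.array(
        [all(int((sl == c).sum()) >= min_pixels for c in (1, 2, 3)) for sl in labels]
    )
    return TrainingCorpus(
        images=images,
        labels=labels,
        subject=np.asarray(subject),
        split=np.asarray(split_code),
        balanced=balanced,
    )


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment(image: np.ndarray, labels: np.ndarray, seed) -> tuple:
    """Random spatial + intensity augmentation of one slice.

    The identical spatial transform — rotation up to +-15 degrees, shifts up
    to +-10 px, horizontal flip — is applied to the image (linear
    interpolation) and the labels (nearest neighbour); the image additionally
    gets a +-10% intensity scaling.  Label codes are never changed, only
    moved.  ``seed`` may be an int or a Generator.
    """
    if image.shape != labels.shape:
        raise ValueError("image and labels must share shape")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    angle = rng.uniform(-15.0, 15.0)
    shift = rng.uniform(-10.0, 10.0, size=2)
    flip = rng.random() < 0.5
    scale = rng.uniform(0.9, 1.1)

    img = ndimage.rotate(image, angle, reshape=False, order=1, mode="constant", cval=0.0)
    lab = ndimage.rotate(labels.astype(np.int16), angle, reshape=False, order=0, mode="constant", cval=0)
    img = ndimage.shift(img, shift, order=1, mode="constant", cval=0.0)
    lab = ndimage.shift(lab, shift, order=0, mode="constant", cval=0)
    if flip:
        img = img[:, ::-1]
        lab = lab[:, ::-1]
    return (img * scale).astype(image.dtype), lab.astype(labels.dtype)


def rotate90(image: np.ndarray, labels: np.ndarray):
    """Exact 90-degree rotation of a slice pair: pixel (i, j) -> (j, N-1-i)."""
    return np.rot90(image, k=-1).copy(), np.rot90(labels, k=-1).copy()


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _one_hot(labels: np.ndarray, n_classes: int, dtype) -> np.ndarray:
    return np.eye(n_classes, dtype=dtype)[labels].transpose(0, 3, 1, 2)


def _run_epoch(net, opt, images, labels, rng, batch_size, augment_frac=0.0):
    order = rng.permutation(len(images))
    losses = []
    for start in range(0, len(order), batch_size):
        idx = order[start : start + batch_size]
        xb = images[idx].copy()
        lb = labels[idx].copy()
        if augment_frac > 0:
            for j in range(len(idx)):
                if rng.random() < augment_frac:
                    xb[j], lb[j] = augment(xb[j], lb[j], rng)
        probs = net.forward(xb[:, None])
        onehot = _one_hot(lb.astype(int), net.cfg.n_classes, net.dtype)
        losses.append(net.loss(probs, onehot))
        net.backward(onehot)
        opt.step()
    return float(np.mean(losses))


def train(
    corpus: TrainingCorpus,
    cfg: NetConfig,
    augment_frac: float = 0.5,
    curriculum: bool = True,
    verbose: bool = False,
) -> UNet:
    """Train the multilabel net with the two-phase balanced curriculum.

    Phase 1 runs ``cfg.epochs_phase1`` epochs on the balanced subset of the
    training split (slices with >=50 pixels of every foreground label);
    phase 2 runs ``cfg.epochs_phase2`` epochs on all training slices.  With
    ``curriculum=False`` all epochs run on the full training set (used for
    the curriculum-effect comparison).  Deterministic given ``cfg.seed``.
    """
    images, labels, balanced = corpus.subset(0)
    if len(images) == 0:
        raise ValueError("empty training corpus")
    net = UNet(cfg)
    opt = Adam(net, cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    history = []
    n1, n2 = cfg.epochs_phase1, cfg.epochs_phase2
    if curriculum:
        if balanced.any():
            for _ in range(n1):
                history.append(
                    _run_epoch(net, opt, images[balanced], labels[balanced], rng, cfg.batch_size, augment_frac)
                )
                if verbose:
                    print(f"phase1 epoch {len(history)}: loss {history[-1]:.4f}")
        else:
            warnings.warn("balanced subset is empty; skipping curriculum phase 1")
        epochs_rest = n2
    else:
        epochs_rest = n1 + n2
    for _ in range(epochs_rest):
        history.append(_run_epoch(net, opt, images, labels, rng, cfg.batch_size, augment_frac))
        if verbose:
            print(f"phase2 epoch {len(history)}: loss {history[-1]:.4f}")
    net.history_ = history
    return net


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def predict_slices(net: UNet, images: np.ndarray, batch_size: int = 8) -> np.ndarray:
    """Per-pixel class probabilities for a stack of normalized slices."""
    out = []
    for start in range(0, len(images), batch_size):
        out.append(net.forward(images[start : start + batch_size, None], train=False))
    return np.concatenate(out)


def probabilities_to_labels(probs: np.ndarray) -> np.ndarray:
    """Binarize each foreground channel at 0.5 (>= 0.5 counts as foreground).

    With softmax outputs at most one foreground channel can reach 0.5; if one
    does, the pixel takes that label, else background.
    """
    fg = probs[:, 1:]  # (N, 3, H, W)
    best = fg.argmax(axis=1)
    hit = np.take_along_axis(fg, best[:, None], axis=1)[:, 0] >= 0.5
    return np.where(hit, best + 1, 0).astype(np.int16)


def predict_volume(net: UNet, v: Volume, batch_size: int = 8) -> LabelMap:
    """Slicewise inference on a volume: resample, normalize, predict, re-stack.

    The output label map lives on the input grid (labels are resampled back
    with nearest neighbour).
    """
    cfg = net.cfg
    target_spacing = (
        v.spacing[0] * v.shape[0] / cfg.input_size,
        v.spacing[1] * v.shape[1] / cfg.input_size,
    )
    vn = resample_slicewise(minmax_normalize(v), target_spacing, (cfg.input_size, cfg.input_size))
    slices = vn.data.transpose(2, 0, 1).astype(np.float32)
    labels2d = probabilities_to_labels(predict_slices(net, slices, batch_size))
    net_lm = LabelMap(
        labels2d.transpose(1, 2, 0),
        np.array([target_spacing[0], target_spacing[1], v.spacing[2]]),
        v.origin.copy(),
        v.direction.copy(),
    )
    # back onto the input grid
    back = resample_slicewise(net_lm, (v.spacing[0], v.spacing[1]), (v.shape[0], v.shape[1]))
    return LabelMap(back.data, v.spacing.copy(), v.origin.copy(), v.direction.copy())


def keep_largest_component(lm: LabelMap) -> LabelMap:
    """Keep only the largest connected component of the foreground union.

    Components are 26-connected over the union of all foreground labels;
    labels inside the surviving component are preserved.  Ties are broken
    deterministically in favour of the component containing the lowest flat
    voxel index.  An empty input passes through unchanged.
    """
    fg = lm.data > 0
    comp, n = ndimage.label(fg, structure=_STRUCT_26)
    if n <= 1:
        return lm.copy_with(lm.data.copy())
    sizes = ndimage.sum_labels(fg, comp, index=np.arange(1, n + 1))
    best = np.nonzero(sizes == sizes.max())[0] + 1
    if len(best) > 1:  # tie: lowest flat voxel index wins
        flat = comp.ravel()
        first = {int(c): np.argmax(flat == c) for c in best}
        winner = min(best, key=lambda c: first[int(c)])
    else:
        winner = best[0]
    out = lm.data.copy()
    out[comp != winner] = 0
    return lm.copy_with(out)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    s = a.sum() + b.sum()
    return 1.0 if s == 0 else 2.0 * float((a & b).sum()) / float(s)


def repeated_subsampling_cv(volumes, cfg: NetConfig, n_repeats: int = 3, split=(0.7, 0.1, 0.2), seed: int = 0):
    """Repeated random sub-sampling cross-validation harness.

    Each repetition resplits the subjects with an independent seed, trains,
    and reports test-set blood-pool Dice.  Returns a list of per-repetition
    dicts.
    """
    results = []
    for rep in range(n_repeats):
        rep_seed = seed + 1000 * rep
        corpus = make_corpus(volumes, split, cfg, seed=rep_seed)
        rep_cfg = dataclasses.replace(cfg, seed=rep_seed)
        net = train(corpus, rep_cfg)
        test_imgs, test_labs, _ = corpus.subset(2)
        pred = probabilities_to_labels(predict_slices(net, test_imgs))
        results.append(
            {
                "seed": rep_seed,
                "dice_blood_pool": dice(pred == 1, test_labs == 1),
                "dice_veins": dice(pred == 2, test_labs == 2),
                "dice_mv": dice(pred == 3, test_labs == 3),
            }
        )
    return results
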