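"""Synthetic lesion-texture benchmark and a directory-per-class image reader.

Each synthetic class is defined by a "genotype": a background hue shared by a
few classes (so color alone is not enough), a lesion color, and lesion count
and radius ranges. Class identity therefore depends on local texture
statistics, which keeps attention maps class-informative. Pixel values are
quantized to 8-bit levels at generation time so a PNG round-trip through
``write_folder``/``load_folder`` is bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import ConfigurationError, DatasetError

_BACKGROUNDS = [
    (0.30, 0.55, 0.25),
    (0.36, 0.62, 0.30),
    (0.27, 0.48, 0.34),
    (0.41, 0.57, 0.22),
]
_LESION_COLORS = [
    (0.55, 0.38, 0.12),   # brown blight
    (0.78, 0.72, 0.18),   # yellow rust
    (0.48, 0.16, 0.12),   # dark rot
    (0.82, 0.82, 0.74),   # pale mildew
    (0.16, 0.16, 0.14),   # black spot
]
_COUNT_RANGES = [(2, 4), (6, 10), (12, 18)]
_RADIUS_RANGES = [(2, 3), (3, 5), (1, 2)]


@dataclass(frozen=True)
class ClassGenotype:
    background: tuple[float, float, float]
    lesion_color: tuple[float, float, float]
    lesion_count: tuple[int, int]
    lesion_radius: tuple[int, int]


def default_genotypes(n_classes: int) -> list[ClassGenotype]:
    """Deterministic, pairwise-distinct genotypes for ``n_classes`` classes.

    Backgrounds vary in blocks of four while lesion traits cycle quickly, so
    classes within one incremental stage share a background (discrimination
    needs lesion texture) while later stages introduce new backgrounds
    (frozen early-stage features transfer poorly — the benchmark punishes
    pure stability as well as pure plasticity).
    """
    genos = []
    for c in range(n_classes):
        genos.append(ClassGenotype(
            background=_BACKGROUNDS[(c // 4) % len(_BACKGROUNDS)],
            lesion_color=_LESION_COLORS[c % len(_LESION_COLORS)],
            lesion_count=_COUNT_RANGES[c % len(_COUNT_RANGES)],
            lesion_radius=_RADIUS_RANGES[(c // 2) % len(_RADIUS_RANGES)],
        ))
    if len(set(genos)) != n_classes:
        raise ConfigurationError(
            f"cannot derive {n_classes} distinct class genotypes")
    return genos


@dataclass
class SyntheticSpec:
    n_classes: int = 13
    image_size: int = 32
    train_per_class: int = 40
    test_per_class: int = 20
    seed: int = 0
    noise_std: float = 0.05
    genotypes: list[ClassGenotype] | None = None

    def validate(self) -> None:
        bad = []
        if self.n_classes < 1:
            bad.append("n_classes")
        if self.image_size < 8:
            bad.append("image_size")
        if self.train_per_class < 1:
            bad.append("train_per_class")
        if self.test_per_class < 1:
            bad.append("test_per_class")
        if self.noise_std < 0:
            bad.append("noise_std")
        if self.genotypes is not None and len(self.genotypes) != self.n_classes:
            bad.append("genotypes")
        if bad:
            raise ConfigurationError(
                f"invalid SyntheticSpec field(s): {', '.join(bad)}")

    def resolved_genotypes(self) -> list[ClassGenotype]:
        return self.genotypes if self.genotypes is not None \
            else default_genotypes(self.n_classes)


@dataclass
class DatasetSplit:
    train_images: np.ndarray  # (n, C, H, W) in [0, 1]
    train_labels: np.ndarray
    test_images: np.ndarray
    test_labels: np.ndarray
    class_names: list[str]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset_train(self, labels) -> tuple[np.ndarray, np.ndarray]:
        mask = np.isin(self.train_labels, list(labels))
        return self.train_images[mask], self.train_labels[mask]

    def subset_test(self, labels) -> tuple[np.ndarray, np.ndarray]:
        mask = np.isin(self.test_labels, list(labels))
        return self.test_images[mask], self.test_labels[mask]


def _render_image(rng: np.random.Generator, geno: ClassGenotype,
                  size: int, noise_std: float) -> np.ndarray:
    img = np.empty((3, size, size))
    tint = rng.normal(0.0, 0.03, size=3)
    for ch in range(3):
        img[ch] = geno.background[ch] + tint[ch]
    # mild vertical illumination gradient, shared across classes
    img += np.linspace(-0.03, 0.03, size)[None, :, None]

    count = int(rng.integers(geno.lesion_count[0], geno.lesion_count[1] + 1))
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(count):
        cy, cx = rng.integers(0, size, size=2)
        r = int(rng.integers(geno.lesion_radius[0], geno.lesion_radius[1] + 1))
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        alpha = 0.85
        for ch in range(3):
            img[ch][mask] = (1 - alpha) * img[ch][mask] \
                + alpha * geno.lesion_color[ch]

    if noise_std > 0:
        img += rng.normal(0.0, noise_std, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    # quantize to 8-bit levels so PNG round-trips are exact
    return np.round(img * 255.0) / 255.0


def generate(spec: SyntheticSpec) -> DatasetSplit:
    """Render the full benchmark; bit-identical for a given seed."""
    spec.validate()
    genos = spec.resolved_genotypes()
    size = spec.image_size
    train_x, train_y, test_x, test_y = [], [], [], []
    for c, geno in enumerate(genos):
        rng = np.random.default_rng([spec.seed, c])
        for _ in range(spec.train_per_class):
            train_x.append(_render_image(rng, geno, size, spec.noise_std))
            train_y.append(c)
        for _ in range(spec.test_per_class):
            test_x.append(_render_image(rng, geno, size, spec.noise_std))
            test_y.append(c)
    names = [f"class_{c:02d}" for c in range(spec.n_classes)]
    return DatasetSplit(
        train_images=np.stack(train_x), train_labels=np.array(train_y),
        test_images=np.stack(test_x), test_labels=np.array(test_y),
        class_names=names)


# ---------------------------------------------------------------------------
# directory-per-class I/O
# ---------------------------------------------------------------------------

def write_folder(split: DatasetSplit, path) -> None:
    """Emit a train/ test/ directory-per-class PNG tree plus a manifest CSV."""
    path = Path(path)
    rows = ["filename,class,split"]
    for part, images, labels in (("train", split.train_images,
                                  split.train_labels),
                                 ("test", split.test_images,
                                  split.test_labels)):
        counters: dict[int, int] = {}
        for img, lab in zip(images, labels):
            lab = int(lab)
            cname = split.class_names[lab]
            idx = counters.get(lab, 0)
            counters[lab] = idx + 1
            d = path / part / cname
            d.mkdir(parents=True, exist_ok=True)
            fname = f"{cname}_{idx:04d}.png"
            arr = np.round(img * 255.0).astype(np.uint8).transpose(1, 2, 0)
            Image.fromarray(arr).save(d / fname)
            rows.append(f"{part}/{cname}/{fname},{cname},{part}")
    (path / "manifest.csv").write_text("\n".join(rows) + "\n")


def _read_class_dir(d: Path, image_size: int) -> list[np.ndarray]:
    imgs = []
    for f in sorted(d.iterdir()):
        if not f.is_file():
            continue
        try:
            with Image.open(f) as im:
                im = im.convert("RGB")
                if im.size != (image_size, image_size):
                    im = im.resize((image_size, image_size), Image.BILINEAR)
                imgs.append(np.asarray(im, dtype=np.float64)
                            .transpose(2, 0, 1) / 255.0)
        except Exception:  # undecodable file: skip, fail later if class empties
            import warnings
            warnings.warn(f"skipping undecodable image {f}")
    return imgs


def load_folder(path, image_size: int = 32, split_fraction: float = 0.8,
                seed: int = 0) -> DatasetSplit:
    """Read a directory-per-class tree.

    If ``path`` holds explicit ``train/`` and ``test/`` subtrees they are
    used as-is; otherwise each class directory is split with a seeded
    shuffle at ``split_fraction``. Non-square sources are resized to a
    square target without preserving aspect ratio. Class names map to label
    indices in lexicographic order.
    """
    path = Path(path)
    if not path.is_dir():
        raise DatasetError(f"dataset path {path} is not a directory")

    if (path / "train").is_dir() and (path / "test").is_dir():
        def read_part(part):
            classes = sorted(d.name for d in (path / part).iterdir()
                             if d.is_dir())
            return classes, {c: _read_class_dir((path / part) / c, image_size)
                             for c in classes}
        train_classes, train_map = read_part("train")
        test_classes, test_map = read_part("test")
        if train_classes != test_classes:
            raise DatasetError("train/ and test/ class directories differ")
        names = train_classes
        tr_x, tr_y, te_x, te_y = [], [], [], []
        for i, c in enumerate(names):
            if not train_map[c]:
                raise DatasetError(f"class directory {c!r} holds no images")
            tr_x += train_map[c]
            tr_y += [i] * len(train_map[c])
            te_x += test_map[c]
            te_y += [i] * len(test_map[c])
    else:
        names = sorted(d.name for d in path.iterdir() if d.is_dir())
        if not names:
            raise DatasetError(f"no class directories under {path}")
        rng = np.random.default_rng(seed)
        tr_x, tr_y, te_x, te_y = [], [], [], []
        for i, c in enumerate(names):
            imgs = _read_class_dir(path / c, image_size)
            if not imgs:
                raise DatasetError(f"class directory {c!r} holds no images")
            order = rng.permutation(len(imgs))
            n_train = int(round(split_fraction * len(imgs)))
            for j in order[:n_train]:
                tr_x.append(imgs[j]); tr_y.append(i)
            for j in order[n_train:]:
                te_x.append(imgs[j]); te_y.append(i)
    if not tr_x or not te_x:
        raise DatasetError("split produced an empty train or test set; "
                           "adjust split_fraction or add images")
    return DatasetSplit(
        train_images=np.stack(tr_x), train_labels=np.array(tr_y),
        test_images=np.stack(te_x), test_labels=np.array(te_y),
        class_names=list(names))
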