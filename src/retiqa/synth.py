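"""Synthetic fundus images with programmable quality defects.

Real fundus photographs are a bright, roughly circular retina on a dark
frame, with an optic disc and a vessel tree radiating from it.  The
generator emulates that geometry and degrades it along the three
human-visual-system quality dimensions used for annotation:

- **I/C** — uneven illumination or color: a brightness ramp or hotspot;
- **Blur** — loss of clarity: Gaussian blur of the whole image;
- **LC**  — low contrast: shrinking intensity spread around the mean.

Labels (1 = good) follow directly from the defect parameters, so the
ground truth is exact by construction: ic=0 iff an illumination defect of
strength >= 0.3 is present, blur=0 iff blur_sigma >= 2 px, lc=0 iff
contrast_keep <= 0.5, overall=0 iff any item is 0.  Realism is not the
goal; separability and a controlled ground truth are.

The module also ships a transcription of the MSHF per-dataset annotation
counts and the pooling used to summarize them.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

ITEMS = ("ic", "blur", "lc", "overall")
UWF_DATASETS = ("DR_UWF",)

__all__ = ["ITEMS", "DefectSpec", "QualityLabels", "make_fundus",
           "make_dataset", "summarize_table", "load_reference_counts",
           "pool_counts", "write_table", "read_table"]


@dataclass(frozen=True)
class DefectSpec:
    """Quality defects to inject; defaults describe a clean image.

    illum: "none", "gradient" (linear brightness ramp) or "hotspot"
    (localized over-exposure), with `illum_strength` in [0,1].
    blur_sigma: Gaussian blur std in pixels (>= 0).
    contrast_keep: fraction of intensity spread kept, in (0, 1].
    noise_var: additive Gaussian noise variance (>= 0).
    """

    illum: str = "none"
    illum_strength: float = 0.0
    blur_sigma: float = 0.0
    contrast_keep: float = 1.0
    noise_var: float = 0.0

    def __post_init__(self):
        if self.illum not in ("none", "gradient", "hotspot"):
            raise ValueError(f"unknown illumination defect {self.illum!r}")
        if not 0.0 <= self.illum_strength <= 1.0:
            raise ValueError("illum_strength must be in [0,1]")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if not 0.0 < self.contrast_keep <= 1.0:
            raise ValueError("contrast_keep must be in (0,1]")
        if self.noise_var < 0:
            raise ValueError("noise_var must be >= 0")

    def labels(self) -> "QualityLabels":
        """Ground-truth labels as a pure function of the defect parameters."""
        ic = 0 if (self.illum != "none" and self.illum_strength >= 0.3) else 1
        blur = 0 if self.blur_sigma >= 2.0 else 1
        lc = 0 if self.contrast_keep <= 0.5 else 1
        overall = ic & blur & lc
        return QualityLabels(ic=ic, blur=blur, lc=lc, overall=overall)


@dataclass(frozen=True)
class QualityLabels:
    """The four binary quality items; 1 = good."""

    ic: int
    blur: int
    lc: int
    overall: int

    def as_dict(self) -> dict:
        return {"ic": self.ic, "blur": self.blur, "lc": self.lc,
                "overall": self.overall}


def _paint_disk(img, cy, cx, radius, color, soft=2.0):
    yy, xx = np.ogrid[:img.shape[0], :img.shape[1]]
    d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    alpha = np.clip((radius - d) / soft, 0.0, 1.0)[..., None]
    img[...] = img * (1 - alpha) + alpha * np.asarray(color, dtype=np.float32)


def _draw_vessels(img, rng, cy, cx, side, color):
    """Seeded biased random walks from the optic disc."""
    n_vessels = 6
    for _ in range(n_vessels):
        angle = rng.uniform(0, 2 * np.pi)
        y, x = float(cy), float(cx)
        width = rng.uniform(1.5, 3.0)
        for step in range(int(0.45 * side)):
            angle += rng.normal(0, 0.15)
            y += 1.6 * np.sin(angle)
            x += 1.6 * np.cos(angle)
            if not (0 <= y < side and 0 <= x < side):
                break
            w = max(width * (1 - step / (0.5 * side)), 0.7)
            yi, xi = int(y), int(x)
            r = int(np.ceil(w))
            y0, y1 = max(yi - r, 0), min(yi + r + 1, side)
            x0, x1 = max(xi - r, 0), min(xi + r + 1, side)
            sub = img[y0:y1, x0:x1]
            yy = np.arange(y0, y1)[:, None]
            xx = np.arange(x0, x1)[None, :]
            a = np.clip((w - np.sqrt((yy - y) ** 2 + (xx - x) ** 2)) / 1.0,
                        0, 1)[..., None]
            sub[...] = sub * (1 - 0.8 * a) + 0.8 * a * np.asarray(color, np.float32)


def make_fundus(seed: int, side: int = 512,
                defects: DefectSpec = DefectSpec()) -> tuple:
    """Generate one synthetic fundus image and its quality labels.

    Deterministic under `seed`; the labels depend only on `defects`, never
    on the sampled texture or noise.
    """
    if side % 32:
        raise ValueError(f"side must be divisible by 32, got {side}")
    rng = np.random.default_rng(seed)
    img = np.full((side, side, 3), 0.01, dtype=np.float32)
    cy = cx = side / 2
    retina_r = 0.47 * side

    base = np.array([rng.uniform(0.70, 0.82), rng.uniform(0.38, 0.48),
                     rng.uniform(0.10, 0.16)], dtype=np.float32)
    yy, xx = np.ogrid[:side, :side]
    d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    inside = d <= retina_r
    vignette = (1.0 - 0.25 * (d / retina_r) ** 2)[..., None]
    img[inside] = (base * vignette[inside]).astype(np.float32)

    # mottled background texture inside the retina
    texture = ndimage.gaussian_filter(rng.normal(0, 1, (side, side)), side / 40)
    texture = 0.05 * texture / (np.abs(texture).max() + 1e-9)
    img[inside] += texture[inside, None]

    disc_cx = cx + rng.choice([-1, 1]) * 0.22 * side
    disc_cy = cy + rng.uniform(-0.05, 0.05) * side
    _draw_vessels(img, rng, disc_cy, disc_cx, side, (0.40, 0.10, 0.07))
    _paint_disk(img, disc_cy, disc_cx, 0.065 * side, (0.95, 0.84, 0.55),
                soft=0.015 * side)
    img = np.clip(img, 0.0, 1.0)

    # --- defects (order: illumination -> blur -> contrast -> noise) -----
    if defects.illum == "gradient" and defects.illum_strength > 0:
        theta = rng.uniform(0, 2 * np.pi)
        ramp = ((yy - cy) * np.sin(theta) + (xx - cx) * np.cos(theta)) / side
        gain = 1.0 + defects.illum_strength * 1.6 * ramp  # +-0.8*s across
        img = img * gain[..., None]
    elif defects.illum == "hotspot" and defects.illum_strength > 0:
        hy = cy + rng.uniform(-0.25, 0.25) * side
        hx = cx + rng.uniform(-0.25, 0.25) * side
        blob = np.exp(-((yy - hy) ** 2 + (xx - hx) ** 2) / (2 * (0.12 * side) ** 2))
        img = img + defects.illum_strength * blob[..., None]
    if defects.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, (defects.blur_sigma, defects.blur_sigma, 0))
    if defects.contrast_keep < 1.0:
        mu = img[inside].mean()
        img = mu + defects.contrast_keep * (img - mu)
        img[~inside] *= defects.contrast_keep  # keep the frame dark-ish
    if defects.noise_var > 0:
        img = img + rng.normal(0, np.sqrt(defects.noise_var), img.shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32), defects.labels()


def _sample_defects(rng: np.random.Generator, good: dict) -> DefectSpec:
    """Draw defect parameters given per-item good/poor assignments."""
    if good["ic"]:
        illum, strength = "none", 0.0
    else:
        illum = rng.choice(["gradient", "hotspot"])
        strength = rng.uniform(0.45, 0.9)
    sigma = 0.0 if good["blur"] else rng.uniform(2.5, 5.0)
    keep = rng.uniform(0.85, 1.0) if good["lc"] else rng.uniform(0.25, 0.45)
    return DefectSpec(illum=illum, illum_strength=float(strength),
                      blur_sigma=float(sigma), contrast_keep=float(keep))


def make_dataset(n: int, prevalence=None, seed: int = 0,
                 out_dir: str | Path | None = None, side: int = 512,
                 dataset_name: str = "SYNTH") -> tuple:
    """Generate `n` labelled images; returns (annotation table, image list).

    `prevalence` maps item -> probability of a *good* label (default 0.6
    each, drawn independently per item).  With `out_dir`, images are
    written as PNG and the table as annotations.csv with columns
    image_path, dataset, ic, blur, lc, overall (1 = good).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    prev = {item: 0.6 for item in ("ic", "blur", "lc")}
    if prevalence:
        unknown = set(prevalence) - set(prev)
        if unknown:
            raise ValueError(f"unknown items in prevalence: {sorted(unknown)}")
        prev.update(prevalence)
    if not all(0.0 <= p <= 1.0 for p in prev.values()):
        raise ValueError("prevalences must be in [0,1]")
    root = np.random.SeedSequence(seed)
    rows, images = [], []
    for i, child in enumerate(root.spawn(n)):
        rng = np.random.default_rng(child)
        good = {item: int(rng.random() < prev[item]) for item in prev}
        spec = _sample_defects(rng, good)
        img, labels = make_fundus(int(child.generate_state(1)[0] % 2 ** 31),
                                  side=side, defects=spec)
        name = f"{dataset_name.lower()}_{i:05d}.png"
        rows.append({"image_path": name, "dataset": dataset_name,
                     **labels.as_dict()})
        images.append(img)
    table = pd.DataFrame(rows, columns=["image_path", "dataset", *ITEMS])
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        from PIL import Image
        for row, img in zip(rows, images):
            arr = (np.clip(img, 0, 1) * 255).round().astype(np.uint8)
            Image.fromarray(arr).save(out_dir / row["image_path"])
        table.to_csv(out_dir / "annotations.csv", index=False)
    return table, images


def make_blur_benchmark(n: int = 200, side: int = 128, seed: int = 0,
                        sigma: float = 4.0) -> tuple:
    """Balanced sharp-vs-blurred image set for scaled-down learning runs.

    Alternates clean images with images blurred at `sigma` px (default 4,
    an unambiguous defect).  Returns (images (N,3,side,side) float32,
    blur labels (N,), 1 = sharp).
    """
    root = np.random.SeedSequence(seed)
    imgs, labels = [], []
    for i, child in enumerate(root.spawn(n)):
        spec = DefectSpec(blur_sigma=0.0 if i % 2 else sigma)
        img, lab = make_fundus(int(child.generate_state(1)[0] % 2 ** 31),
                               side=side, defects=spec)
        imgs.append(img.transpose(2, 0, 1))
        labels.append(lab.blur)
    return np.stack(imgs), np.asarray(labels, dtype=np.int64)


# --- annotation-table summaries -----------------------------------------

def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = {"dataset", *ITEMS} - set(table.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    for item in ITEMS:
        if not table[item].isin([0, 1]).all():
            raise ValueError(f"column {item!r} must be binary 0/1")
    return table


def summarize_table(table: pd.DataFrame, subset=None) -> pd.DataFrame:
    """Per-item good/poor counts and fractions, per dataset and pooled.

    `subset` restricts to the named datasets (and defines the pool);
    unknown names raise.  Output rows: one per (dataset, item) plus a
    POOLED row per item, with columns n_poor, n_good, frac_good, frac_poor.
    """
    if len(table) == 0:
        raise ValueError("annotation table is empty")
    present = list(dict.fromkeys(table["dataset"]))
    if subset is not None:
        subset = list(subset)
        if not subset:
            raise ValueError("subset filter is empty")
        unknown = set(subset) - set(present)
        if unknown:
            raise ValueError(f"unknown dataset names: {sorted(unknown)}")
        table = table[table["dataset"].isin(subset)]
        present = subset
    out = []
    for scope, sub in ([(d, table[table["dataset"] == d]) for d in present]
                       + [("POOLED", table)]):
        for item in ITEMS:
            n1 = int((sub[item] == 1).sum())
            n0 = int((sub[item] == 0).sum())
            out.append({"dataset": scope, "item": item, "n_poor": n0,
                        "n_good": n1, "frac_good": n1 / (n0 + n1),
                        "frac_poor": n0 / (n0 + n1)})
    return pd.DataFrame(out)


def load_reference_counts() -> pd.DataFrame:
    """Packaged transcription of the MSHF per-dataset annotation counts.

    One row per source dataset, columns ``<item>_0``/``<item>_1`` giving
    poor/good counts for each of the four items (1 = good).
    """
    ref = importlib.resources.files("retiqa") / "data" / "mshf_annotation_counts.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def pool_counts(counts: pd.DataFrame, datasets=None) -> pd.DataFrame:
    """Pool per-dataset annotation counts and derive good/poor fractions.

    Returns one row per item with n_poor, n_good, frac_good, frac_poor.
    """
    if datasets is not None:
        datasets = list(datasets)
        if not datasets:
            raise ValueError("dataset filter is empty")
        unknown = set(datasets) - set(counts["dataset"])
        if unknown:
            raise ValueError(f"unknown dataset names: {sorted(unknown)}")
        counts = counts[counts["dataset"].isin(datasets)]
    rows = []
    for item in ITEMS:
        n0 = int(counts[f"{item}_0"].sum())
        n1 = int(counts[f"{item}_1"].sum())
        rows.append({"item": item, "n_poor": n0, "n_good": n1,
                     "frac_good": n1 / (n0 + n1), "frac_poor": n0 / (n0 + n1)})
    return pd.DataFrame(rows)
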