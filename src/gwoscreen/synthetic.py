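"""Seeded synthetic fundus-like image generator with ground-truth masks.

Real glaucoma screening data consists of retinal fundus photographs: a
reddish textured background, a bright roughly-elliptical optic disc with a
brighter inner cup, and dark vessels crossing the disc.  The class label is
tied to the cup-to-disc ratio (CDR): an enlarged cup relative to the disc
is the clinical glaucoma cue.  This module emulates those images — plus the
acquisition aberrations reported on screening datasets (blur, brightness
jitter, sensor noise, size/color variation of disc and cup) — so that the
segmenter, the classifier and the full pipeline can be trained and verified
at desk scale without any external download.

Masks are rendered analytically *before* degradations are applied, so the
ground truth is exact; the label is glaucoma iff the drawn CDR falls in the
glaucoma range, and the two CDR ranges are disjoint by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "FundusParams",
    "SyntheticSample",
    "generate_dataset",
    "split_dataset",
    "save_dataset",
    "load_dataset",
]


@dataclass
class FundusParams:
    """Generator conditions.

    image_side        : square image side in pixels (128 for segmentation,
                        64 for classification crops)
    disc_radius_range : disc radius as a fraction of the side
    cdr_normal / cdr_glaucoma : cup-to-disc diameter ratio ranges; must be
                        disjoint with glaucoma entirely above normal
    vessel_count      : (lo, hi) number of vessel strokes
    noise_sigma       : additive Gaussian noise std on [0,1] intensities
    blur_sigma_range  : Gaussian blur sigma drawn per image
    brightness_jitter : multiplicative brightness factor range
    seed              : master seed
    """

    image_side: int = 128
    disc_radius_range: tuple[float, float] = (0.15, 0.25)
    cdr_normal: tuple[float, float] = (0.2, 0.4)
    cdr_glaucoma: tuple[float, float] = (0.6, 0.85)
    vessel_count: tuple[int, int] = (3, 6)
    noise_sigma: float = 0.02
    blur_sigma_range: tuple[float, float] = (0.3, 1.2)
    brightness_jitter: tuple[float, float] = (0.85, 1.15)
    seed: int = 0

    def __post_init__(self):
        for rng_ in (self.cdr_normal, self.cdr_glaucoma):
            if not (0.0 < rng_[0] < rng_[1] < 1.0):
                raise ValueError(f"CDR range {rng_} must be within (0, 1)")
        if self.cdr_glaucoma[0] <= self.cdr_normal[1]:
            raise ValueError("cdr_glaucoma must lie entirely above cdr_normal")


@dataclass
class SyntheticSample:
    image: np.ndarray        # (H, W, 3) float in [0, 1]
    disc_mask: np.ndarray    # (H, W) bool
    cup_mask: np.ndarray     # (H, W) bool
    label: str               # "glaucoma" | "normal"
    cdr: float               # drawn cup-to-disc diameter ratio
    provenance: dict = field(default_factory=dict)


def _ellipse_mask(side: int, cy: float, cx: float, ry: float, rx: float,
                  angle: float) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side]
    ca, sa = np.cos(angle), np.sin(angle)
    u = (yy - cy) * ca + (xx - cx) * sa
    v = -(yy - cy) * sa + (xx - cx) * ca
    return (u / ry) ** 2 + (v / rx) ** 2 <= 1.0


def _vessel_stroke(img: np.ndarray, rng: np.random.Generator,
                   cy: float, cx: float, side: int) -> None:
    """Draw one dark quadratic Bezier stroke passing near (cy, cx)."""
    edge_pts = []
    for _ in range(2):
        edge = rng.integers(4)
        t = rng.uniform(0, side - 1)
        pt = {0: (0.0, t), 1: (side - 1.0, t), 2: (t, 0.0), 3: (t, side - 1.0)}[edge]
        edge_pts.append(pt)
    ctrl = (cy + rng.normal(0, side * 0.08), cx + rng.normal(0, side * 0.08))
    ts = np.linspace(0, 1, 4 * side)
    p0, p2 = np.array(edge_pts[0]), np.array(edge_pts[1])
    p1 = np.array(ctrl)
    pts = ((1 - ts)[:, None] ** 2 * p0 + 2 * (ts * (1 - ts))[:, None] * p1
           + ts[:, None] ** 2 * p2)
    width = rng.uniform(0.8, 1.6)
    depth = rng.uniform(0.15, 0.3)
    canvas = np.zeros(img.shape[:2])
    ij = np.round(pts).astype(int)
    ok = (ij[:, 0] >= 0) & (ij[:, 0] < side) & (ij[:, 1] >= 0) & (ij[:, 1] < side)
    canvas[ij[ok, 0], ij[ok, 1]] = 1.0
    canvas = ndimage.gaussian_filter(canvas, sigma=width)
    canvas = canvas / (canvas.max() + 1e-9)
    for ch, f in enumerate((depth, depth * 1.2, depth * 0.8)):
        img[:, :, ch] -= f * canvas


def _render_sample(rng: np.random.Generator, params: FundusParams,
                   label: str) -> SyntheticSample:
    side = params.image_side
    lo, hi = (params.cdr_glaucoma if label == "glaucoma" else params.cdr_normal)
    cdr = float(rng.uniform(lo, hi))
    r_disc = rng.uniform(*params.disc_radius_range) * side
    # keep the disc fully inside with a margin
    margin = r_disc * 1.15 + 2
    for _ in range(50):
        cy = rng.uniform(margin, side - margin)
        cx = rng.uniform(margin, side - margin)
        if margin <= cy <= side - margin and margin <= cx <= side - margin:
            break
    else:
        raise RuntimeError("could not place disc inside image bounds")
    ecc = rng.uniform(0.9, 1.1)
    angle = rng.uniform(0, np.pi)
    ry, rx = r_disc * ecc, r_disc / ecc
    disc_mask = _ellipse_mask(side, cy, cx, ry, rx, angle)
    cup_mask = _ellipse_mask(side, cy, cx, ry * cdr, rx * cdr, angle)

    # background: reddish base + smooth mottle
    base = np.array([0.55, 0.22, 0.12]) * rng.uniform(0.9, 1.1)
    img = np.ones((side, side, 3)) * base[None, None, :]
    mottle = ndimage.gaussian_filter(rng.normal(0, 1.0, (side, side)), sigma=6)
    mottle = mottle / (np.abs(mottle).max() + 1e-9)
    img += 0.05 * mottle[:, :, None]

    # disc: bright yellowish; cup: brighter still (color variation per draw)
    disc_color = np.array([0.95, 0.80, 0.45]) * rng.uniform(0.9, 1.05)
    cup_color = np.array([1.0, 0.95, 0.70]) * rng.uniform(0.95, 1.05)
    edge = ndimage.gaussian_filter(disc_mask.astype(float), sigma=1.0)
    img = img * (1 - edge[:, :, None]) + edge[:, :, None] * disc_color[None, None, :]
    cup_soft = ndimage.gaussian_filter(cup_mask.astype(float), sigma=0.8)
    img = img * (1 - cup_soft[:, :, None]) + cup_soft[:, :, None] * cup_color[None, None, :]

    n_vessels = int(rng.integers(params.vessel_count[0], params.vessel_count[1] + 1))
    for _ in range(n_vessels):
        _vessel_stroke(img, rng, cy, cx, side)

    # acquisition aberrations (masks already rendered, unaffected)
    blur = rng.uniform(*params.blur_sigma_range)
    img = ndimage.gaussian_filter(img, sigma=(blur, blur, 0))
    img *= rng.uniform(*params.brightness_jitter)
    img += rng.normal(0, params.noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0)

    return SyntheticSample(
        image=img.astype(np.float32), disc_mask=disc_mask, cup_mask=cup_mask,
        label=label, cdr=cdr,
        provenance={"cy": cy, "cx": cx, "r_disc": r_disc, "ecc": ecc,
                    "angle": angle, "blur": blur, "n_vessels": n_vessels})


def generate_dataset(params: FundusParams, n_per_class: int
                     ) -> tuple[list[SyntheticSample], pd.DataFrame]:
    """Generate n_per_class samples of each class, fully seeded.

    Returns the samples and a manifest DataFrame with columns
    sample_id, label, cdr (image/mask path columns are filled by
    :func:`save_dataset`).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(params.seed)
    samples: list[SyntheticSample] = []
    rows = []
    idx = 0
    for label in ("normal", "glaucoma"):
        for _ in range(n_per_class):
            s = _render_sample(rng, params, label)
            samples.append(s)
            rows.append({"sample_id": f"s{idx:04d}", "label": label,
                         "cdr": s.cdr})
            idx += 1
    return samples, pd.DataFrame(rows)


def measured_cdr(sample: SyntheticSample) -> float:
    """CDR re-measured from the rasterized masks via equivalent diameters."""
    a_d, a_c = sample.disc_mask.sum(), sample.cup_mask.sum()
    if a_d == 0:
        return 0.0
    return float(np.sqrt(a_c / a_d))


def split_dataset(manifest: pd.DataFrame, train_fraction: float,
                  stratify: bool = True, seed: int = 0
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split with round(n*fraction) per stratum."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if stratify:
        groups = [g for _, g in manifest.groupby("label", sort=True)]
        for g in groups:
            if len(g) < 2:
                raise ValueError(
                    f"class {g['label'].iloc[0]!r} has fewer than 2 members; "
                    "cannot stratify")
    else:
        groups = [manifest]
    train_parts, test_parts = [], []
    for g in groups:
        n_train = int(round(len(g) * train_fraction))
        n_train = min(max(n_train, 1), len(g) - 1)
        perm = rng.permutation(len(g))
        train_parts.append(g.iloc[perm[:n_train]])
        test_parts.append(g.iloc[perm[n_train:]])
    train = pd.concat(train_parts).sort_index()
    test = pd.concat(test_parts).sort_index()
    return train.reset_index(drop=True), test.reset_index(drop=True)


def save_dataset(samples: list[SyntheticSample], manifest: pd.DataFrame,
                 out_dir) -> pd.DataFrame:
    """Write PNGs (image RGB, masks {0,255}) and the manifest CSV.

    Path columns are stored relative to ``out_dir`` so the dataset
    directory is relocatable and re-runs in different directories produce
    byte-identical manifests.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    img_paths, disc_paths, cup_paths = [], [], []
    for s, sid in zip(samples, manifest["sample_id"]):
        rel_i = f"images/{sid}.png"
        rel_d = f"masks/{sid}_disc.png"
        rel_c = f"masks/{sid}_cup.png"
        iio.imwrite(out / rel_i, (s.image * 255).astype(np.uint8))
        iio.imwrite(out / rel_d, (s.disc_mask * 255).astype(np.uint8))
        iio.imwrite(out / rel_c, (s.cup_mask * 255).astype(np.uint8))
        img_paths.append(rel_i); disc_paths.append(rel_d); cup_paths.append(rel_c)
    manifest["image_path"] = img_paths
    manifest["disc_mask_path"] = disc_paths
    manifest["cup_mask_path"] = cup_paths
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_dataset(manifest: pd.DataFrame, base_dir=".") -> list[SyntheticSample]:
    """Read samples back from a manifest written by :func:`save_dataset`.

    ``base_dir`` is the dataset directory the manifest's relative paths are
    resolved against.
    """
    base = Path(base_dir)
    samples = []
    for _, row in manifest.iterrows():
        img = iio.imread(base / row["image_path"]).astype(np.float32) / 255.0
        disc = iio.imread(base / row["disc_mask_path"]) > 127
        cup = iio.imread(base / row["cup_mask_path"]) > 127
        samples.append(SyntheticSample(image=img, disc_mask=disc, cup_mask=cup,
                                       label=row["label"], cdr=float(row["cdr"])))
    return samples
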