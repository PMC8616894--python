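"""Spin-echo knee phantom simulator.

Real knee MR images encode tissue contrast implicitly: intensity is a smooth
function of the sequence parameters TE and TR, and fat saturation suppresses
the fat signal.  This module supplies that ground truth explicitly.  A
:class:`TissueMap` holds per-pixel proton density (PD), T1 and T2 for a
random arrangement of elliptical "anatomy" drawn from six tissue classes,
and :func:`render_image` produces a grayscale image under any acquisition
label using the classical spin-echo signal equation

    S = PD * (1 - exp(-TR / T1)) * exp(-TE / T2)

which reproduces the qualitative contrast behaviour the method relies on:
intensity is non-increasing in TE, non-decreasing in TR, and fat saturation
multiplicatively suppresses fat-class pixels.  The simulator makes no claim
to k-space realism (no coils, no chemical shift, no flip-angle dependence);
it is the analytic oracle against which conditioning is verified.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .conditioning import AcquisitionLabel

__all__ = [
    "TISSUE_CLASSES",
    "TISSUE_PARAMS",
    "TissueMap",
    "LabelSampler",
    "Sample",
    "SyntheticDataset",
    "generate_tissue_map",
    "spin_echo_signal",
    "render_image",
    "make_synthetic_dataset",
]

TISSUE_CLASSES = ("background", "fat", "muscle", "fluid", "bone", "cartilage")

# (PD range, T1 range [ms], T2 range [ms]) — standard 1.5 T literature values.
TISSUE_PARAMS: dict[str, tuple[tuple[float, float], tuple[float, float], tuple[float, float]]] = {
    "fat": ((0.8, 1.0), (240.0, 300.0), (60.0, 80.0)),
    "muscle": ((0.6, 0.8), (800.0, 1100.0), (35.0, 50.0)),
    "fluid": ((0.9, 1.0), (2500.0, 3500.0), (200.0, 400.0)),
    "bone": ((0.05, 0.15), (200.0, 400.0), (1.0, 10.0)),
    "cartilage": ((0.7, 0.9), (900.0, 1200.0), (30.0, 45.0)),
}

#: Relative amplitude of the smooth within-structure parameter variation.
SPATIAL_VARIATION = 0.05

#: Multiplicative suppression applied to fat-class pixels when FS is on.
FS_SUPPRESSION = 0.05


@dataclass
class TissueMap:
    """Per-pixel tissue parameters for one phantom slice."""

    height: int
    width: int
    class_map: np.ndarray  # uint8, indices into TISSUE_CLASSES
    pd_map: np.ndarray
    t1_map: np.ndarray
    t2_map: np.ndarray
    seed: int

    def class_mask(self, name: str) -> np.ndarray:
        return self.class_map == TISSUE_CLASSES.index(name)


def _smooth_field(rng: np.random.Generator, height: int, width: int) -> np.ndarray:
    """A smooth random field in [-1, 1] (low-res noise, bilinearly upsampled)."""
    from skimage.transform import resize

    coarse = rng.uniform(-1.0, 1.0, size=(max(height // 16, 2), max(width // 16, 2)))
    fine = resize(coarse, (height, width), order=1, mode="edge",
                  anti_aliasing=False)
    return fine.astype(np.float64)


def generate_tissue_map(seed: int, height: int, width: int,
                        n_structures: int) -> TissueMap:
    """Random phantom anatomy: ``n_structures`` overlapping ellipses.

    Later ellipses overwrite earlier ones; each is assigned one tissue class
    and per-structure base PD/T1/T2 drawn uniformly from the class ranges,
    with a smooth spatial variation of at most +/-5 % inside the structure.
    Classes are cycled through a shuffled order and ellipses are drawn
    largest-first, so with ``n_structures >= 5`` every tissue class is
    present in the final map (the smallest ellipse of each class is drawn
    last and survives intact).  Deterministic in (seed, height, width,
    n_structures).
    """
    if height < 32 or width < 32:
        raise ValueError("phantom dimensions must be at least 32 pixels")
    if n_structures < 1:
        raise ValueError("n_structures must be >= 1")
    rng = np.random.default_rng(seed)
    class_map = np.zeros((height, width), dtype=np.uint8)
    pd_map = np.zeros((height, width))
    t1_map = np.zeros((height, width))
    t2_map = np.zeros((height, width))
    yy, xx = np.mgrid[0:height, 0:width]

    # knee-like composition: the first structure is always a large fat
    # region (emulating subcutaneous/marrow fat, the dominant bright tissue
    # a fat-saturation pulse visibly removes); fluid appears only as small
    # pockets, as joint fluid does.  Remaining classes cycle in a shuffled
    # order so every class is present once n_structures >= 5.
    inner_cycle = ["muscle", "fluid", "bone", "cartilage"]
    rng.shuffle(inner_cycle)
    inner_cycle.append("fat")
    ellipses = [{
        "cls": "fat",
        "cy": rng.uniform(0.4, 0.6) * height,
        "cx": rng.uniform(0.4, 0.6) * width,
        "ay": rng.uniform(0.38, 0.48) * height,
        "ax": rng.uniform(0.38, 0.48) * width,
        "theta": rng.uniform(0.0, np.pi),
    }]
    for k in range(n_structures - 1):
        cls = inner_cycle[k % len(inner_cycle)]
        hi = 0.14 if cls == "fluid" else 0.30
        ellipses.append({
            "cls": cls,
            "cy": rng.uniform(0.25, 0.75) * height,
            "cx": rng.uniform(0.25, 0.75) * width,
            "ay": rng.uniform(0.05, hi) * height,
            "ax": rng.uniform(0.05, hi) * width,
            "theta": rng.uniform(0.0, np.pi),
        })
    ellipses[1:] = sorted(ellipses[1:], key=lambda e: e["ay"] * e["ax"],
                          reverse=True)

    for e in ellipses:
        cls_name = e["cls"]
        cy, cx, ay, ax = e["cy"], e["cx"], e["ay"], e["ax"]
        ct, st = np.cos(e["theta"]), np.sin(e["theta"])
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        inside = (u / ax) ** 2 + (v / ay) ** 2 <= 1.0

        (pd_lo, pd_hi), (t1_lo, t1_hi), (t2_lo, t2_hi) = TISSUE_PARAMS[cls_name]
        base_pd = rng.uniform(pd_lo, pd_hi)
        base_t1 = rng.uniform(t1_lo, t1_hi)
        base_t2 = rng.uniform(t2_lo, t2_hi)
        variation = 1.0 + SPATIAL_VARIATION * _smooth_field(rng, height, width)

        class_map[inside] = TISSUE_CLASSES.index(cls_name)
        pd_map[inside] = base_pd * variation[inside]
        t1_map[inside] = base_t1 * variation[inside]
        t2_map[inside] = base_t2 * variation[inside]

    background = class_map == 0
    pd_map[background] = 0.0
    t1_map[background] = 0.0
    t2_map[background] = 0.0
    return TissueMap(height=height, width=width, class_map=class_map,
                     pd_map=pd_map, t1_map=t1_map, t2_map=t2_map, seed=seed)


def spin_echo_signal(pd, t1_ms, t2_ms, te_ms, tr_ms):
    """Classical spin-echo signal S = PD (1 - e^(-TR/T1)) e^(-TE/T2).

    Vectorized over all arguments; S = 0 wherever PD = 0 (background), with
    T1/T2 ignored there.  Negative inputs raise.
    """
    pd = np.asarray(pd, dtype=np.float64)
    t1 = np.asarray(t1_ms, dtype=np.float64)
    t2 = np.asarray(t2_ms, dtype=np.float64)
    if np.any(pd < 0) or np.any(t1 < 0) or np.any(t2 < 0):
        raise ValueError("pd, t1 and t2 must be non-negative")
    if np.any(np.asarray(te_ms) <= 0) or np.any(np.asarray(tr_ms) <= 0):
        raise ValueError("te and tr must be positive")
    tissue = pd > 0
    t1b = np.broadcast_to(t1, tissue.shape)
    t2b = np.broadcast_to(t2, tissue.shape)
    if np.any(t1b[tissue] <= 0) or np.any(t2b[tissue] <= 0):
        raise ValueError("t1 and t2 must be positive where pd > 0")
    safe_t1 = np.where(t1b > 0, t1b, 1.0)
    safe_t2 = np.where(t2b > 0, t2b, 1.0)
    signal = np.where(
        tissue,
        pd * (1.0 - np.exp(-np.asarray(tr_ms, dtype=np.float64) / safe_t1))
        * np.exp(-np.asarray(te_ms, dtype=np.float64) / safe_t2),
        0.0)
    return float(signal) if signal.ndim == 0 else signal


def render_image(tissue_map: TissueMap, label: AcquisitionLabel,
                 noise_sd: float = 0.01, seed: int = 0,
                 fs_suppression: float = FS_SUPPRESSION) -> np.ndarray:
    """Render a phantom under one acquisition label; output in [-1, 1].

    The per-pixel spin-echo signal is computed, fat-class pixels are
    multiplied by ``fs_suppression`` when the label requests fat saturation,
    zero-mean Gaussian noise with standard deviation ``noise_sd`` (in signal
    units; signals are O(1)) is added, and the result is clipped to
    [0, max signal] and linearly rescaled to [-1, 1].  The scale is the
    map's maximum *achievable* signal (its peak proton density), fixed
    across labels so that renders of the same map under different TE/TR are
    directly comparable and per-pixel intensity stays monotone in TE and TR.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    signal = spin_echo_signal(tissue_map.pd_map, tissue_map.t1_map,
                              tissue_map.t2_map, label.te_ms, label.tr_ms)
    if label.fs:
        signal = np.where(tissue_map.class_mask("fat"),
                          signal * fs_suppression, signal)
    max_signal = float(tissue_map.pd_map.max())
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    if max_signal <= 0:
        return np.full(signal.shape, -1.0)
    clipped = np.clip(signal, 0.0, max_signal)
    return 2.0 * clipped / max_signal - 1.0


# --------------------------------------------------------------------------
# dataset generation
# --------------------------------------------------------------------------

@dataclass
class LabelSampler:
    """Sampler emulating the clustered TE/TR distribution of clinical knee data.

    Two dense clusters — non-FS (TE 25-35 ms, TR 2000-3500 ms) and FS
    (TE 30-45 ms, TR 2500-4500 ms) — plus a small uniform background mass
    over the full admissible box (TE <= 50 ms, TR <= 5000 ms).
    """

    nonfs_te: tuple[float, float] = (25.0, 35.0)
    nonfs_tr: tuple[float, float] = (2000.0, 3500.0)
    fs_te: tuple[float, float] = (30.0, 45.0)
    fs_tr: tuple[float, float] = (2500.0, 4500.0)
    background_mass: float = 0.1
    te_box: tuple[float, float] = (5.0, 50.0)
    tr_box: tuple[float, float] = (300.0, 5000.0)
    fs_probability: float = 0.5

    def sample(self, rng: np.random.Generator, fs: int | None = None) -> AcquisitionLabel:
        if fs is None:
            fs = int(rng.random() < self.fs_probability)
        if rng.random() < self.background_mass:
            te = rng.uniform(*self.te_box)
            tr = rng.uniform(*self.tr_box)
        elif fs:
            te = rng.uniform(*self.fs_te)
            tr = rng.uniform(*self.fs_tr)
        else:
            te = rng.uniform(*self.nonfs_te)
            tr = rng.uniform(*self.nonfs_tr)
        return AcquisitionLabel(te_ms=float(te), tr_ms=float(tr), fs=int(fs))


@dataclass
class Sample:
    """One rendered image with its acquisition metadata."""

    subject_id: int
    slice_index: int
    image: np.ndarray
    label: AcquisitionLabel
    pair_id: str | None = None
    role: str = "unpaired"  # "source" | "target" | "unpaired"


@dataclass
class SyntheticDataset:
    """A list of phantom renders; paired samples share a TissueMap."""

    samples: list[Sample]
    seed: int
    label_sampler: LabelSampler = field(default_factory=LabelSampler)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.samples[0].image.shape

    def paired_share(self) -> float:
        return sum(s.pair_id is not None for s in self.samples) / len(self.samples)

    def pairs(self) -> list[tuple[Sample, Sample]]:
        """(source, target) tuples for every generated pair, in order."""
        by_id: dict[str, dict[str, Sample]] = {}
        for s in self.samples:
            if s.pair_id is not None:
                by_id.setdefault(s.pair_id, {})[s.role] = s
        return [(d["source"], d["target"]) for d in by_id.values()
                if "source" in d and "target" in d]

    def unpaired(self, fs: int | None = None) -> list[Sample]:
        out = [s for s in self.samples if s.pair_id is None]
        if fs is not None:
            out = [s for s in out if s.label.fs == fs]
        return out

    def manifest(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.samples):
            rows.append({
                "subject_id": s.subject_id, "slice_index": s.slice_index,
                "te_ms": s.label.te_ms, "tr_ms": s.label.tr_ms,
                "fs": s.label.fs, "pair_id": s.pair_id or "",
                "role": s.role, "file": f"img_{i:06d}.npy",
            })
        return pd.DataFrame(rows)

    def save(self, out_dir: str | Path, image_format: str = "npy") -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = self.manifest()
        if image_format == "png16":
            manifest["file"] = [f.replace(".npy", ".png") for f in manifest["file"]]
        for fname, s in zip(manifest["file"], self.samples):
            if image_format == "npy":
                np.save(out_dir / fname, s.image.astype(np.float32))
            elif image_format == "png16":
                import imageio.v3 as iio

                arr = np.round((s.image + 1.0) / 2.0 * 65535).astype(np.uint16)
                iio.imwrite(out_dir / fname, arr)
            else:
                raise ValueError(f"unknown image format {image_format!r}")
        manifest.to_csv(out_dir / "manifest.csv", index=False)

    @classmethod
    def load(cls, in_dir: str | Path) -> "SyntheticDataset":
        in_dir = Path(in_dir)
        manifest = pd.read_csv(in_dir / "manifest.csv", keep_default_na=False)
        samples = []
        for _, row in manifest.iterrows():
            fname = str(row["file"])
            if fname.endswith(".npy"):
                image = np.load(in_dir / fname).astype(np.float64)
            else:
                import imageio.v3 as iio

                image = iio.imread(in_dir / fname).astype(np.float64) / 65535 * 2 - 1
            samples.append(Sample(
                subject_id=int(row["subject_id"]), slice_index=int(row["slice_index"]),
                image=image,
                label=AcquisitionLabel(float(row["te_ms"]), float(row["tr_ms"]),
                                       int(row["fs"])),
                pair_id=str(row["pair_id"]) or None, role=str(row["role"])))
        return cls(samples=samples, seed=-1)


def _subseed(seed: int, *parts) -> int:
    """Named deterministic substream seed (stays below 2**31)."""
    tag = ":".join(str(p) for p in parts)
    return (int(seed) * 2654435761 + zlib.crc32(tag.encode())) % (2 ** 31 - 1)


def make_synthetic_dataset(seed: int, n_subjects: int, slices_per_subject: int,
                           pair_fraction: float,
                           label_sampler: LabelSampler | None = None,
                           height: int = 64, width: int = 64,
                           n_structures: int = 6, noise_sd: float = 0.01,
                           paired_target_fs_probability: float = 0.8) -> SyntheticDataset:
    """Generate a synthetic dataset of phantom renders.

    A "subject" is one TissueMap; each of its ``slices_per_subject`` slots is
    either a *pair* (the same map rendered under a non-FS source label and a
    different target label, sharing a ``pair_id``) or a single unpaired
    render.  The number of paired slots is chosen so that the share of
    samples belonging to pairs equals ``pair_fraction`` (the clinical
    reference ratio is roughly 0.43 paired).
    """
    if not 0.0 <= pair_fraction <= 1.0:
        raise ValueError("pair_fraction must lie in [0, 1]")
    sampler = label_sampler or LabelSampler()
    rng = np.random.default_rng(_subseed(seed, "dataset"))
    n_slots = n_subjects * slices_per_subject
    n_paired = int(round(n_slots * pair_fraction / (2.0 - pair_fraction)))
    paired_slots = set(rng.choice(n_slots, size=n_paired, replace=False).tolist())

    samples: list[Sample] = []
    slot = 0
    for subj in range(n_subjects):
        tmap = generate_tissue_map(_subseed(seed, "map", subj), height, width,
                                   n_structures)
        for sl in range(slices_per_subject):
            render_seed = _subseed(seed, "render", subj, sl)
            if slot in paired_slots:
                src_label = sampler.sample(rng, fs=0)
                tgt_fs = int(rng.random() < paired_target_fs_probability)
                tgt_label = sampler.sample(rng, fs=tgt_fs)
                pair_id = f"s{subj:05d}_{sl:02d}"
                samples.append(Sample(subj, sl,
                                      render_image(tmap, src_label, noise_sd,
                                                   render_seed),
                                      src_label, pair_id, "source"))
                samples.append(Sample(subj, sl,
                                      render_image(tmap, tgt_label, noise_sd,
                                                   render_seed + 1),
                                      tgt_label, pair_id, "target"))
            else:
                label = sampler.sample(rng)
                samples.append(Sample(subj, sl,
                                      render_image(tmap, label, noise_sd,
                                                   render_seed),
                                      label, None, "unpaired"))
            slot += 1
    return SyntheticDataset(samples=samples, seed=seed, label_sampler=sampler)
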