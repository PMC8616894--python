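"""Header-driven data curation: filtering, slice selection, pairing,
preprocessing and augmentation.

The curation rules operate on lightweight :class:`SeriesRecord` metadata
objects so they apply identically to real DICOM series (when pydicom is
available) and to the synthetic manifest.  The rules are:

* **Filtering** — keep records with TR <= 5000 ms and TE <= 50 ms (inclusive
  bounds), matching field strength (1.5 T) and manufacturer; both of the
  latter accept a ``"*"`` wildcard.
* **Slice selection** — keep the central ``k`` (default 14) slices of each
  series, centered on ``floor(n/2)``.
* **Pairing** — images form a pair when they agree on patient ID, study UID,
  image orientation (tolerance 1e-3 per component), slice location
  (tolerance 0.5 mm) and slice thickness; a pair is an ordered
  (non-FS source, target) combination from different series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .conditioning import AcquisitionLabel

__all__ = [
    "SeriesRecord",
    "ImagePair",
    "filter_records",
    "select_central_slices",
    "pair_images",
    "preprocess",
    "augment",
    "read_dicom_records",
    "pairs_from_synthetic",
]

ORIENTATION_TOL = 1e-3
SLICE_LOCATION_TOL_MM = 0.5


@dataclass(frozen=True)
class SeriesRecord:
    """Metadata of one 2-D image extracted from its series header."""

    patient_id: str
    study_uid: str
    series_uid: str
    image_orientation: tuple[float, ...]
    slice_location: float
    slice_thickness: float
    te_ms: float
    tr_ms: float
    fs: int
    field_strength: float
    manufacturer: str
    n_slices: int
    slice_index: int
    image_ref: str = ""

    def __post_init__(self):
        if not 0 <= self.slice_index < self.n_slices:
            raise ValueError("slice_index must lie in [0, n_slices)")

    def label(self) -> AcquisitionLabel:
        return AcquisitionLabel(te_ms=self.te_ms, tr_ms=self.tr_ms, fs=self.fs)


@dataclass
class ImagePair:
    """A (source, target) image pair for translation and evaluation.

    ``source_image``/``target_image`` may be arrays or deferred references;
    the source is always non-fat-saturated.
    """

    source_image: object
    source_label: AcquisitionLabel
    target_image: object
    target_label: AcquisitionLabel
    pair_key: str = ""
    source_record: SeriesRecord | None = field(default=None, repr=False)
    target_record: SeriesRecord | None = field(default=None, repr=False)


def filter_records(records: Sequence[SeriesRecord], tr_max: float = 5000.0,
                   te_max: float = 50.0, field_strength: float | str = 1.5,
                   manufacturer: str = "Siemens") -> list[SeriesRecord]:
    """Apply the header filters; bounds are inclusive, order is preserved."""
    if tr_max <= 0 or te_max <= 0:
        raise ValueError("tr_max and te_max must be positive")
    out = []
    for r in records:
        if r.tr_ms > tr_max or r.te_ms > te_max:
            continue
        if field_strength != "*" and not np.isclose(r.field_strength,
                                                    float(field_strength)):
            continue
        if manufacturer != "*" and manufacturer.lower() not in r.manufacturer.lower():
            continue
        out.append(r)
    return out


def select_central_slices(records_of_one_series: Sequence[SeriesRecord],
                          k: int = 14) -> list[SeriesRecord]:
    """The ``k`` slices centered on floor(n/2); all slices when n <= k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    records = list(records_of_one_series)
    if not records:
        return []
    series = {r.series_uid for r in records}
    if len(series) > 1:
        raise ValueError(f"records span multiple series: {sorted(series)}")
    n = records[0].n_slices
    records = sorted(records, key=lambda r: r.slice_index)
    if n <= k:
        return records
    center = n // 2
    lo, hi = center - k // 2, center + (k + 1) // 2
    return [r for r in records if lo <= r.slice_index < hi]


def _cluster_1d(values: np.ndarray, tol: float) -> np.ndarray:
    """Greedy clustering of sorted scalar values within ``tol`` of the cluster seed."""
    order = np.argsort(values, kind="stable")
    labels = np.empty(len(values), dtype=int)
    cluster, seed_val = -1, None
    for idx in order:
        v = values[idx]
        if seed_val is None or v - seed_val > tol:
            cluster += 1
            seed_val = v
        labels[idx] = cluster
    return labels


def pair_images(records: Sequence[SeriesRecord],
                slice_location_tol: float = SLICE_LOCATION_TOL_MM) -> list[ImagePair]:
    """Pair records agreeing on the five header attributes.

    Within each matching group, one pair is emitted per ordered
    (non-FS source, target) combination with differing series UID.  Records
    without a partner simply yield no pair (they remain available as
    unpaired training data).  Output order is deterministic and independent
    of input order.
    """
    records = sorted(records, key=lambda r: (r.patient_id, r.study_uid,
                                             r.slice_thickness, r.slice_location,
                                             r.series_uid, r.slice_index))
    groups: dict[tuple, list[SeriesRecord]] = {}
    for key, bucket in _group_exact(records).items():
        ori = np.array([r.image_orientation for r in bucket])
        ori_labels = _cluster_vectors(ori, ORIENTATION_TOL)
        locs = np.array([r.slice_location for r in bucket])
        loc_labels = _cluster_1d(locs, slice_location_tol)
        for r, ol, ll in zip(bucket, ori_labels, loc_labels):
            groups.setdefault(key + (int(ol), int(ll)), []).append(r)

    pairs: list[ImagePair] = []
    for key in sorted(groups):
        members = groups[key]
        sources = [r for r in members if r.fs == 0]
        for s in sources:
            for t in members:
                if t.series_uid == s.series_uid:
                    continue
                pair_key = (f"{s.patient_id}|{s.study_uid}|{s.slice_location:.2f}"
                            f"|{s.series_uid}>{t.series_uid}|{s.slice_index}")
                pairs.append(ImagePair(
                    source_image=s.image_ref, source_label=s.label(),
                    target_image=t.image_ref, target_label=t.label(),
                    pair_key=pair_key, source_record=s, target_record=t))
    return pairs


def _group_exact(records: Sequence[SeriesRecord]) -> dict[tuple, list[SeriesRecord]]:
    out: dict[tuple, list[SeriesRecord]] = {}
    for r in records:
        out.setdefault((r.patient_id, r.study_uid, float(r.slice_thickness)), []).append(r)
    return out


def _cluster_vectors(vectors: np.ndarray, tol: float) -> np.ndarray:
    """Greedy clustering of orientation vectors by max-norm distance."""
    labels = np.full(len(vectors), -1, dtype=int)
    seeds: list[np.ndarray] = []
    for i, v in enumerate(vectors):
        for j, s in enumerate(seeds):
            if np.max(np.abs(v - s)) <= tol:
                labels[i] = j
                break
        else:
            seeds.append(v)
            labels[i] = len(seeds) - 1
    return labels


def preprocess(image: np.ndarray, out_size: int) -> np.ndarray:
    """Rescale intensities to [-1, 1] and resize to ``out_size`` square.

    The intensity map is affine (min -> -1, max -> +1); constant images map
    to -1 everywhere.  Resizing is bilinear under the half-pixel-center
    convention.
    """
    from skimage.transform import resize

    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or min(image.shape) < 1:
        raise ValueError("preprocess expects a non-empty 2-D image")
    lo, hi = float(image.min()), float(image.max())
    if hi > lo:
        image = 2.0 * (image - lo) / (hi - lo) - 1.0
    else:
        image = np.full_like(image, -1.0)
    if image.shape != (out_size, out_size):
        image = resize(image, (out_size, out_size), order=1, mode="edge",
                       anti_aliasing=False)
        image = np.clip(image, -1.0, 1.0)
    return image


def _shift_zoom(image: np.ndarray, shift: tuple[float, float],
                zoom: float) -> np.ndarray:
    """Zoom about the image center then translate, reflection-padded."""
    from scipy import ndimage

    h, w = image.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    # output coordinate y maps to input coordinate A (y - center - shift) + center
    matrix = np.eye(2) / zoom
    offset = center - matrix @ (center + np.asarray(shift, dtype=np.float64))
    return ndimage.affine_transform(image, matrix, offset=offset, order=1,
                                    mode="reflect")


def augment(image: np.ndarray, seed: int, max_shift: float = 0.1,
            zoom_range: tuple[float, float] = (0.9, 1.1)) -> np.ndarray:
    """Random shift (up to ``max_shift`` of the image side) and zoom.

    Deterministic in ``seed``; reflection padding; identity when
    ``max_shift == 0`` and ``zoom_range == (1, 1)``.
    """
    if not 0.0 <= max_shift < 0.5:
        raise ValueError("max_shift must lie in [0, 0.5)")
    if not (0.5 < zoom_range[0] <= zoom_range[1] < 2.0):
        raise ValueError("zoom_range must be an interval within (0.5, 2)")
    image = np.asarray(image, dtype=np.float64)
    rng = np.random.default_rng(seed)
    shift = rng.uniform(-max_shift, max_shift, size=2) * np.array(image.shape)
    zoom = rng.uniform(zoom_range[0], zoom_range[1])
    if max_shift == 0.0 and zoom_range == (1.0, 1.0):
        return image.copy()
    return _shift_zoom(image, (float(shift[0]), float(shift[1])), float(zoom))


def pairs_from_synthetic(dataset) -> list[ImagePair]:
    """ImagePairs (with in-memory arrays) from a synthetic dataset's pairs."""
    out = []
    for src, tgt in dataset.pairs():
        out.append(ImagePair(source_image=src.image, source_label=src.label,
                             target_image=tgt.image, target_label=tgt.label,
                             pair_key=src.pair_id))
    return out


# --------------------------------------------------------------------------
# real-data mode (optional; requires pydicom)
# --------------------------------------------------------------------------

_FS_SEQUENCE_HINTS = ("fs", "fat sat", "fatsat", "spair", "stir")


def read_dicom_records(paths: Sequence[str]) -> list[SeriesRecord]:
    """Extract :class:`SeriesRecord` metadata from DICOM files.

    The fat-saturation flag is a heuristic over (0018,0022) scan options and
    the sequence/series description, since no single DICOM tag encodes it;
    the decision is logged per file via :mod:`warnings`.  Requires pydicom.
    """
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "real-data mode requires pydicom, which is not installed; "
            "synthetic manifests do not need it") from exc

    records = []
    for path in paths:
        ds = pydicom.dcmread(path, stop_before_pixels=True)
        text = " ".join(str(ds.get(k, "")) for k in
                        ("ScanOptions", "SequenceName", "SeriesDescription")).lower()
        fs = int(any(h in text for h in _FS_SEQUENCE_HINTS))
        warnings.warn(f"{path}: fat-saturation heuristic -> {fs} (from {text!r})")
        records.append(SeriesRecord(
            patient_id=str(ds.PatientID), study_uid=str(ds.StudyInstanceUID),
            series_uid=str(ds.SeriesInstanceUID),
            image_orientation=tuple(float(v) for v in ds.ImageOrientationPatient),
            slice_location=float(ds.SliceLocation),
            slice_thickness=float(ds.SliceThickness),
            te_ms=float(ds.EchoTime), tr_ms=float(ds.RepetitionTime), fs=fs,
            field_strength=float(ds.MagneticFieldStrength),
            manufacturer=str(ds.Manufacturer),
            n_slices=int(getattr(ds, "ImagesInAcquisition", 0) or 0) or 1,
            slice_index=int(ds.InstanceNumber) - 1, image_ref=str(path)))
    return records
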