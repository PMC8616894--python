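"""Reconstruction-quality metrics (NMSE, PSNR, SSIM) and evaluation harnesses.

Conventions, chosen once and recorded in every report header:

* Metrics are computed on images in the model's [-1, 1] intensity range.
* PSNR's MAX is the *joint* value range of the two images (max - min over
  both), so a typical preprocessed pair has MAX = 2.  Most libraries use a
  fixed per-dataset range instead; the joint-range convention is the one
  this package standardizes on.
* SSIM defaults to the conventional 11x11 Gaussian-windowed mean
  (sigma = 1.5, c1 = (0.01 L)^2, c2 = (0.03 L)^2); ``windowed=False``
  computes the single global-statistics value instead.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from scipy import stats

from .conditioning import AcquisitionLabel, unscale_labels
from .curation import ImagePair

__all__ = [
    "nmse",
    "psnr",
    "ssim",
    "gaussian_window",
    "EvaluationReport",
    "evaluate_reconstruction",
    "evaluate_conditioning",
    "compare_models",
]

SSIM_WINDOW_SIZE = 11
SSIM_SIGMA = 1.5
SSIM_K1 = 0.01
SSIM_K2 = 0.03


def nmse(x: np.ndarray, x_prime: np.ndarray) -> float:
    """Normalized mean squared error ||x - x'||^2 / ||x||^2 (not symmetric)."""
    x = np.asarray(x, dtype=np.float64)
    x_prime = np.asarray(x_prime, dtype=np.float64)
    if x.shape != x_prime.shape:
        raise ValueError("shapes must match")
    denom = float(np.sum(x * x))
    if denom == 0.0:
        raise ZeroDivisionError("NMSE undefined: ground-truth image is identically zero")
    return float(np.sum((x - x_prime) ** 2) / denom)


def psnr(x: np.ndarray, x_prime: np.ndarray) -> float:
    """Peak SNR in dB with MAX = joint value range of the two images."""
    x = np.asarray(x, dtype=np.float64)
    x_prime = np.asarray(x_prime, dtype=np.float64)
    if x.shape != x_prime.shape:
        raise ValueError("shapes must match")
    mse = float(np.mean((x - x_prime) ** 2))
    if mse == 0.0:
        warnings.warn("identical images: PSNR is infinite and will be "
                      "excluded from aggregates")
        return float("inf")
    max_range = float(max(x.max(), x_prime.max()) - min(x.min(), x_prime.min()))
    return float(10.0 * np.log10(max_range ** 2 / mse))


def gaussian_window(size: int = SSIM_WINDOW_SIZE,
                    sigma: float = SSIM_SIGMA) -> np.ndarray:
    """Normalized 2-D Gaussian window used for local SSIM statistics."""
    half = (size - 1) / 2.0
    coords = np.arange(size) - half
    g = np.exp(-(coords ** 2) / (2.0 * sigma ** 2))
    w = np.outer(g, g)
    return w / w.sum()


def _ssim_constants(x, x_prime, data_range):
    if data_range is None:
        data_range = float(max(x.max(), x_prime.max()) -
                           min(x.min(), x_prime.min()))
        if data_range == 0.0:
            data_range = 1.0
    c1 = (SSIM_K1 * data_range) ** 2
    c2 = (SSIM_K2 * data_range) ** 2
    return c1, c2


def ssim(x: np.ndarray, x_prime: np.ndarray, windowed: bool = True,
         data_range: float | None = None) -> float:
    """Structural similarity index.

    ``windowed=True`` (default): mean of the 11x11-Gaussian-windowed local
    SSIM map (valid region only).  ``windowed=False``: the single value from
    global image statistics.  ``data_range`` defaults to the joint value
    range of the pair.
    """
    x = np.asarray(x, dtype=np.float64)
    x_prime = np.asarray(x_prime, dtype=np.float64)
    if x.shape != x_prime.shape:
        raise ValueError("shapes must match")
    c1, c2 = _ssim_constants(x, x_prime, data_range)
    if not windowed:
        mu_x, mu_y = x.mean(), x_prime.mean()
        sigma_x2 = np.mean((x - mu_x) ** 2)
        sigma_y2 = np.mean((x_prime - mu_y) ** 2)
        sigma_xy = np.mean((x - mu_x) * (x_prime - mu_y))
        return float((2 * mu_x * mu_y + c1) * (2 * sigma_xy + c2)
                     / ((mu_x ** 2 + mu_y ** 2 + c1) * (sigma_x2 + sigma_y2 + c2)))
    ssim_map, _ = _local_ssim(x, x_prime, c1, c2)
    return float(ssim_map.mean())


def _local_ssim(x: np.ndarray, y: np.ndarray, c1: float, c2: float,
                window: np.ndarray | None = None):
    """Gaussian-weighted local SSIM and contrast-structure maps (valid mode)."""
    w = gaussian_window() if window is None else window
    if min(x.shape) < w.shape[0]:
        raise ValueError(f"image side must be >= window size {w.shape[0]}")

    def filt(a):
        return fftconvolve(a, w, mode="valid")

    mu_x, mu_y = filt(x), filt(y)
    sigma_x2 = filt(x * x) - mu_x ** 2
    sigma_y2 = filt(y * y) - mu_y ** 2
    sigma_xy = filt(x * y) - mu_x * mu_y
    cs_map = (2 * sigma_xy + c2) / (sigma_x2 + sigma_y2 + c2)
    lum_map = (2 * mu_x * mu_y + c1) / (mu_x ** 2 + mu_y ** 2 + c1)
    return lum_map * cs_map, cs_map


# --------------------------------------------------------------------------
# evaluation harnesses
# --------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-pair metric table plus aggregates; convention recorded in header."""

    per_pair: pd.DataFrame
    convention: str = "intensities in [-1,1]; PSNR/SSIM range = joint pair range"
    conditioning: dict = field(default_factory=dict)

    def aggregates(self) -> dict[str, dict[str, float]]:
        out = {}
        for col in self.per_pair.columns:
            if col in ("pair_key",):
                continue
            vals = self.per_pair[col].to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            out[col] = {"mean": float(finite.mean()) if len(finite) else float("nan"),
                        "sd": float(finite.std(ddof=1)) if len(finite) > 1 else 0.0,
                        "n": int(len(finite))}
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {"convention": self.convention,
                   "aggregates": self.aggregates(),
                   "conditioning": self.conditioning}
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_csv(self, path: str | Path) -> None:
        self.per_pair.to_csv(path, index=False)


Translator = Callable[[np.ndarray, AcquisitionLabel, AcquisitionLabel], np.ndarray]


def evaluate_reconstruction(pairs: Sequence[ImagePair],
                            translator: Translator) -> EvaluationReport:
    """Translate each source to its target's label and score against truth."""
    if not pairs:
        raise ValueError("pairs must be nonempty")
    rows = []
    for p in pairs:
        pred = translator(np.asarray(p.source_image, dtype=np.float64),
                          p.source_label, p.target_label)
        truth = np.asarray(p.target_image, dtype=np.float64)
        rows.append({"pair_key": p.pair_key,
                     "nmse": nmse(truth, pred),
                     "psnr": psnr(truth, pred),
                     "ssim": ssim(truth, pred)})
    return EvaluationReport(per_pair=pd.DataFrame(rows))


def evaluate_conditioning(pairs: Sequence[ImagePair], translator: Translator,
                          ac) -> EvaluationReport:
    """Score how faithfully translations carry the requested acquisition label.

    Each source is translated to the paired target's label, the auxiliary
    classifier predicts (te_scaled, tr_scaled, fs_logit) from the synthetic
    image, and the absolute TE/TR errors (in ms) and FS correctness against
    the requested label are aggregated.
    """
    if not pairs:
        raise ValueError("pairs must be nonempty")
    if getattr(ac, "trained", True) is False:
        raise RuntimeError("auxiliary classifier is not trained")
    rows = []
    for p in pairs:
        pred_img = translator(np.asarray(p.source_image, dtype=np.float64),
                              p.source_label, p.target_label)
        te_s, tr_s, fs_logit = _ac_predict(ac, pred_img)
        te_pred, tr_pred, _ = unscale_labels(np.array([te_s, tr_s, 0.0]))
        rows.append({"pair_key": p.pair_key,
                     "te_abs_err_ms": abs(float(te_pred) - p.target_label.te_ms),
                     "tr_abs_err_ms": abs(float(tr_pred) - p.target_label.tr_ms),
                     "fs_correct": float((fs_logit > 0) == bool(p.target_label.fs))})
    df = pd.DataFrame(rows)
    conditioning = {
        "te_mae_ms": float(df["te_abs_err_ms"].mean()),
        "te_mae_sd_ms": float(df["te_abs_err_ms"].std(ddof=1)) if len(df) > 1 else 0.0,
        "tr_mae_ms": float(df["tr_abs_err_ms"].mean()),
        "tr_mae_sd_ms": float(df["tr_abs_err_ms"].std(ddof=1)) if len(df) > 1 else 0.0,
        "fs_accuracy_pct": float(100.0 * df["fs_correct"].mean()),
    }
    return EvaluationReport(per_pair=df, conditioning=conditioning)


def _ac_predict(ac, image: np.ndarray) -> tuple[float, float, float]:
    pred = ac.predict(image) if hasattr(ac, "predict") else ac(image)
    te_s, tr_s, fs_logit = (float(v) for v in np.asarray(pred).reshape(3))
    return te_s, tr_s, fs_logit


def compare_models(values_a: Sequence[float], values_b: Sequence[float]):
    """Two-sample t test between per-pair metric values of two models."""
    return stats.ttest_ind(np.asarray(values_a, dtype=float),
                           np.asarray(values_b, dtype=float))
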