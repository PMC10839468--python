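"""Full-reference image quality metrics and cohort reporting.

Four complementary metrics quantify how close a synthesized image is to its
ground truth:

* **MAE** — mean absolute pixel error, raw intensity fidelity.
* **PSNR** — ``10 log10(peak^2 / MSE)`` in dB, fidelity on a log scale.
* **MS-SSIM** — multi-scale structural similarity (Wang et al.): per-scale
  contrast/structure terms plus top-scale luminance, combined with the
  standard exponent weights; robust to viewing-condition differences that
  pixel metrics ignore.
* **NQM** — noise quality measure (Damera-Venkata et al. degradation-model
  metric): both images are passed through a model of early human vision
  (cosine-log frequency-band decomposition, band-limited contrast, contrast
  threshold with supra-threshold masking) and the SNR is computed between the
  two *modeled* images, weighting distortion by its visibility.

Cohort reporting aggregates per-image records into mean +/- SD rows, the
percentage enhancement over a named baseline (e.g. the low-resolution input),
and paired Wilcoxon signed-rank p-values between methods.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate
from scipy.stats import wilcoxon

from .image import ImageGrid

__all__ = [
    "MetricReport",
    "mae",
    "psnr",
    "mssim",
    "nqm",
    "enhancement",
    "paired_compare",
    "evaluate_pairs",
]

#: sentinel cap reported for zero-distortion PSNR / NQM
INF_DB = float("inf")

MSSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


def _pixels(img) -> np.ndarray:
    return img.pixels if isinstance(img, ImageGrid) else np.asarray(img, dtype=np.float64)


def _check_pair(ref, test) -> tuple[np.ndarray, np.ndarray]:
    r, t = _pixels(ref), _pixels(test)
    if r.shape != t.shape:
        raise ValueError(f"shape mismatch: ref {r.shape} vs test {t.shape}")
    return r, t


def mae(ref, test) -> float:
    """Mean absolute per-pixel difference."""
    r, t = _check_pair(ref, test)
    return float(np.mean(np.abs(r - t)))


def psnr(ref, test, peak: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` for identical images."""
    r, t = _check_pair(ref, test)
    if peak <= 0:
        raise ValueError(f"peak must be positive, got {peak}")
    mse = float(np.mean((r - t) ** 2))
    if mse == 0.0:
        return INF_DB
    return 10.0 * math.log10(peak**2 / mse)


# ---------------------------------------------------------------------------
# MS-SSIM
# ---------------------------------------------------------------------------


def _gaussian_window(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def _ssim_terms(r: np.ndarray, t: np.ndarray, data_range: float) -> tuple[float, float]:
    """Mean luminance*cs (full SSIM) and mean contrast/structure term."""
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    win = _gaussian_window()
    mu_r = correlate(r, win, mode="reflect")
    mu_t = correlate(t, win, mode="reflect")
    s_rr = correlate(r * r, win, mode="reflect") - mu_r**2
    s_tt = correlate(t * t, win, mode="reflect") - mu_t**2
    s_rt = correlate(r * t, win, mode="reflect") - mu_r * mu_t
    cs_map = (2.0 * s_rt + c2) / (s_rr + s_tt + c2)
    lum_map = (2.0 * mu_r * mu_t + c1) / (mu_r**2 + mu_t**2 + c1)
    pad = 5  # exclude the window-radius border, where padding biases the stats
    sl = (slice(pad, -pad), slice(pad, -pad)) if min(r.shape) > 2 * pad else (slice(None),)
    return float(np.mean((lum_map * cs_map)[sl])), float(np.mean(cs_map[sl]))


def _downsample2(x: np.ndarray) -> np.ndarray:
    h, w = (x.shape[0] // 2) * 2, (x.shape[1] // 2) * 2
    x = x[:h, :w]
    return x.reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))


def mssim(ref, test, data_range: float = 255.0, levels: int = 5) -> float:
    """Multi-scale structural similarity with the standard exponent weights.

    Each scale contributes its mean contrast/structure term; the coarsest
    scale additionally contributes luminance.  Anti-correlated structure
    (negative contrast/structure means) is clamped at zero before the
    geometric combination, so the result lies in ``[0, 1]``.
    """
    r, t = _check_pair(ref, test)
    if levels < 1 or levels > len(MSSIM_WEIGHTS):
        raise ValueError(f"levels must be in [1, {len(MSSIM_WEIGHTS)}]")
    min_side = min(r.shape)
    needed = 2 ** (levels - 1) * 11
    if min_side < needed:
        raise ValueError(
            f"image min side {min_side} < {needed} required for {levels} "
            f"scales; reduce 'levels'"
        )
    weights = np.asarray(MSSIM_WEIGHTS[:levels])
    weights = weights / weights.sum() if levels < len(MSSIM_WEIGHTS) else weights
    vals = []
    for lv in range(levels):
        ssim_full, cs = _ssim_terms(r, t, data_range)
        vals.append(ssim_full if lv == levels - 1 else cs)
        if lv < levels - 1:
            r, t = _downsample2(r), _downsample2(t)
    vals = np.maximum(np.asarray(vals), 0.0)
    return float(np.prod(vals**weights))


# ---------------------------------------------------------------------------
# NQM
# ---------------------------------------------------------------------------


def _cosine_log_filters(shape: tuple[int, int], n_bands: int) -> list[np.ndarray]:
    """DC low-pass plus octave-spaced cosine-log band-pass filters.

    Band ``k`` (1-based) is centered at ``2^k`` cycles/image with support
    ``[2^(k-1), 2^(k+1)]``; together with the low-pass they partition unity
    over the retained spectrum.
    """
    h, w = shape
    fy = np.fft.fftfreq(h)[:, None] * h
    fx = np.fft.fftfreq(w)[None, :] * w
    r = np.sqrt(fy**2 + fx**2)
    with np.errstate(divide="ignore"):
        lr = np.log2(np.where(r > 0, r, 1e-12))
    filters = []
    low = np.zeros(shape)
    low[r <= 1.0] = 1.0
    band0 = (r > 1.0) & (r <= 2.0)
    low[band0] = 0.5 * (1.0 + np.cos(np.pi * lr[band0]))
    filters.append(low)
    for k in range(1, n_bands + 1):
        g = np.zeros(shape)
        sup = (r > 2.0 ** (k - 1)) & (r <= 2.0 ** (k + 1))
        g[sup] = 0.5 * (1.0 + np.cos(np.pi * (lr[sup] - k)))
        filters.append(g)
    return filters


def _ctf(f_cpd: float) -> float:
    """Contrast threshold at spatial frequency ``f`` (cycles/degree).

    Reciprocal of the Barten-style contrast sensitivity function used by the
    degradation-model metric.
    """
    f = max(f_cpd, 1e-3)
    sens = 2.6 * (0.0192 + 0.114 * f) * math.exp(-((0.114 * f) ** 1.1))
    return 1.0 / max(sens * 200.0, 1e-12)


def nqm(ref, test, viewing_angle: float = 4.0) -> float:
    """Noise quality measure in dB (higher is better, ``inf`` if identical).

    Both images are decomposed into octave frequency bands (cosine-log
    filters), converted to band-limited contrast, and thresholded by the
    contrast sensitivity of the eye at each band's frequency — with the
    threshold for the test image elevated where the reference already holds
    supra-threshold contrast (masking).  Bands invisible under this model are
    discarded, the images are resynthesized, and the score is the SNR between
    the two modeled images.  ``viewing_angle`` is the angle (degrees) the
    image subtends, converting cycles/image to cycles/degree.
    """
    r, t = _check_pair(ref, test)
    if np.array_equal(r, t):
        return INF_DB
    n_bands = max(1, int(math.floor(math.log2(min(r.shape) / 2.0))) - 1)
    filters = _cosine_log_filters(r.shape, n_bands)
    fr, ft = np.fft.fft2(r), np.fft.fft2(t)
    bands_r = [np.real(np.fft.ifft2(fr * g)) for g in filters]
    bands_t = [np.real(np.fft.ifft2(ft * g)) for g in filters]

    eps = 1e-6 * max(float(np.abs(r).max()), 1.0)
    acc_r = np.abs(bands_r[0]) + eps  # running low-pass for contrast normalization
    acc_t = np.abs(bands_t[0]) + eps
    restored_r = bands_r[0].copy()
    restored_t = bands_t[0].copy()
    for k in range(1, len(filters)):
        c_r = bands_r[k] / acc_r
        c_t = bands_t[k] / acc_t
        f_cpd = (2.0**k) / viewing_angle
        thr = _ctf(f_cpd)
        vis_r = np.abs(c_r) > thr
        # supra-threshold reference contrast elevates the detection threshold
        masking = np.maximum(np.abs(c_r) / thr, 1.0) ** 0.3
        vis_t = np.abs(c_t) > thr * masking
        restored_r += bands_r[k] * vis_r
        restored_t += bands_t[k] * vis_t
        acc_r = acc_r + np.abs(bands_r[k])
        acc_t = acc_t + np.abs(bands_t[k])

    err = float(np.sum((restored_r - restored_t) ** 2))
    sig = float(np.sum(restored_r**2))
    if err == 0.0:
        return INF_DB
    return 10.0 * math.log10(sig / err)


# ---------------------------------------------------------------------------
# cohort statistics
# ---------------------------------------------------------------------------


def enhancement(baseline: float, method: float, direction: str = "higher-better") -> float:
    """Percent improvement of ``method`` over ``baseline``.

    ``higher-better`` metrics (PSNR, NQM, MS-SSIM) improve upward;
    ``lower-better`` metrics (MAE) improve downward.
    """
    if baseline == 0:
        raise ValueError("enhancement undefined for zero baseline")
    if direction == "higher-better":
        return 100.0 * (method - baseline) / baseline
    if direction == "lower-better":
        return 100.0 * (baseline - method) / baseline
    raise ValueError(f"unknown direction {direction!r}")


def paired_compare(values_a, values_b) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Exact for n <= 25 (scipy's exact mode), normal approximation beyond.
    All-zero differences give p = 1 (no evidence of any difference).
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired sequences must have equal length")
    if a.size < 5:
        raise ValueError(f"need at least 5 pairs, got {a.size}")
    d = a - b
    if np.all(d == 0):
        return 1.0
    mode = "exact" if a.size <= 25 and not np.any(d == 0) else "approx"
    return float(wilcoxon(a, b, zero_method="wilcox", mode=mode).pvalue)


METRIC_DIRECTIONS = {
    "mae": "lower-better",
    "psnr": "higher-better",
    "nqm": "higher-better",
    "mssim": "higher-better",
}


@dataclass
class MetricReport:
    """Per-image metric records plus recomputable aggregate rows.

    ``records`` maps method name -> list of per-image dicts
    (``image_id`` plus one entry per metric).  Aggregates are always derived
    from the stored records, never cached separately.
    """

    records: dict = field(default_factory=dict)
    baseline: "str | None" = None

    def add(self, method: str, image_id: str, values: dict) -> None:
        self.records.setdefault(method, []).append({"image_id": image_id, **values})

    def metric_values(self, method: str, metric: str) -> np.ndarray:
        return np.asarray([rec[metric] for rec in self.records[method]])

    def aggregate(self, method: str, metric: str) -> tuple[float, float]:
        """Mean and SD over images (ddof=0)."""
        v = self.metric_values(method, metric)
        finite = v[np.isfinite(v)]
        return float(np.mean(finite)), float(np.std(finite))

    def enhancement_from(self, method: str, metric: str, mode: str = "per-image") -> float:
        """Percent enhancement of ``method`` over the named baseline.

        ``per-image`` averages each image's own percentage; ``of-means``
        compares the cohort means.  The two disagree slightly whenever the
        baseline varies across images, so both are exposed.
        """
        if self.baseline is None:
            raise ValueError("no baseline method named in this report")
        direction = METRIC_DIRECTIONS[metric]
        base = self.metric_values(self.baseline, metric)
        meth = self.metric_values(method, metric)
        if mode == "per-image":
            vals = [
                enhancement(b, m, direction)
                for b, m in zip(base, meth)
                if np.isfinite(b) and np.isfinite(m) and b != 0
            ]
            return float(np.mean(vals))
        if mode == "of-means":
            return enhancement(float(np.mean(base)), float(np.mean(meth)), direction)
        raise ValueError(f"unknown mode {mode!r}")

    def p_value(self, method_a: str, method_b: str, metric: str) -> float:
        return paired_compare(
            self.metric_values(method_a, metric), self.metric_values(method_b, metric)
        )

    def write_csv(self, path) -> None:
        """Long-format CSV: method, image_id, metric, value; aggregate rows
        (mean, sd, enhancement vs baseline) appended per method/metric."""
        metrics = [k for k in self.records[next(iter(self.records))][0] if k != "image_id"]
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["method", "image_id", "metric", "value"])
            for method, recs in self.records.items():
                for rec in recs:
                    for m in metrics:
                        w.writerow([method, rec["image_id"], m, repr(rec[m])])
            for method in self.records:
                for m in metrics:
                    mean, sd = self.aggregate(method, m)
                    w.writerow([method, "__aggregate__", f"{m}_mean", repr(mean)])
                    w.writerow([method, "__aggregate__", f"{m}_sd", repr(sd)])
                    if self.baseline is not None and method != self.baseline:
                        w.writerow(
                            [
                                method,
                                "__aggregate__",
                                f"{m}_enhancement_pct",
                                repr(self.enhancement_from(method, m)),
                            ]
                        )


def evaluate_pairs(
    ref_images: dict,
    method_images: dict,
    *,
    metrics=("mae", "psnr", "nqm", "mssim"),
    baseline: "str | None" = None,
    peak: float = 255.0,
    mssim_levels: int = 5,
) -> MetricReport:
    """Score several methods' outputs against shared references.

    ``ref_images`` maps image_id -> ground-truth ``ImageGrid``;
    ``method_images`` maps method name -> {image_id -> ``ImageGrid``}.
    """
    fns = {
        "mae": lambda r, t: mae(r, t),
        "psnr": lambda r, t: psnr(r, t, peak=peak),
        "nqm": lambda r, t: nqm(r, t),
        "mssim": lambda r, t: mssim(r, t, data_range=peak, levels=mssim_levels),
    }
    report = MetricReport(baseline=baseline)
    for method, imgs in method_images.items():
        for image_id, ref in ref_images.items():
            if image_id not in imgs:
                raise KeyError(f"method {method!r} missing image {image_id!r}")
            vals = {m: fns[m](ref, imgs[image_id]) for m in metrics}
            report.add(method, image_id, vals)
    return report
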