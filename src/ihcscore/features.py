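"""Per-image scalar features summarizing DAB expression.

Four features are computed per image, all increasing (in general) with the
DAB load, which is what makes norm-ordered clustering meaningful:

* ``f1`` — mean DAB intensity from the cohort-average decomposition,
  normalized by the cohort maximum (so ``f1 in [0, 1]``, max attained).
* ``f2`` — ratio of the robust maxima (99th percentile) of the DAB and H
  intensity matrices, each normalized at the image where the DAB robust
  maximum peaks.  Using H in the denominator cancels section-thickness and
  exposure effects.
* ``f3`` — like f1 but with the 2-norm (root of the average intensity
  power), normalized by the cohort maximum.
* ``f4`` — root-mean DAB intensity power from each image's *own* basis
  estimate (not the cohort average); unnormalized, in OD units.

Intensity matrices are the rank-one products ``w_s h_s`` of a stain column
and its concentration row, so their entry-wise norms factor into products
of vector norms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .separation import StainBasis

#: Percentile used as the outlier-resistant "robust maximum".
ROBUST_PERCENTILE = 99.0

#: Floor for the H robust maximum in f2's denominator (guards synthetic
#: H-free edge cases; real two-stain tissue always has R1 > 0).
EPS_R = 1e-9


class FeatureError(ValueError):
    """Raised when a cohort has no measurable DAB signal anywhere."""


def robust_max(w_col: np.ndarray, h_row: np.ndarray, percentile: float = ROBUST_PERCENTILE) -> float:
    """Percentile of the entries of the rank-one intensity matrix w h."""
    w_col = np.asarray(w_col, dtype=float).reshape(-1, 1)
    h_row = np.asarray(h_row, dtype=float).reshape(1, -1)
    return float(np.percentile(w_col * h_row, percentile))


def feature_f1(w_bar: StainBasis, h_bars: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Normalized mean DAB intensity per image.

    ``M1(m) = ||w_dab||_1 ||h_dab||_1 / (3 N_m)`` (entry-wise 1-norms of the
    rank-one DAB intensity matrix), then ``f1 = M1 / max M1``.
    """
    w1 = np.abs(w_bar.dab).sum()
    m1 = np.array([w1 * np.abs(h[1]).sum() / (3 * h.shape[1]) for h in h_bars])
    top = m1.max()
    if top <= 0:
        raise FeatureError("no DAB signal anywhere in the cohort; unscorable")
    return m1 / top, m1


def feature_f2(
    w_bar: StainBasis, h_bars: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Robust-maximum ratio of DAB to H intensity, cross-normalized.

    With ``m* = argmax_m R2(m)``:
    ``f2(m) = [R2(m)/R2(m*)] / [R1(m)/R1(m*)]``.
    Returns (f2, R1, R2).
    """
    r1 = np.array([robust_max(w_bar.hematoxylin, h[0]) for h in h_bars])
    r2 = np.array([robust_max(w_bar.dab, h[1]) for h in h_bars])
    m_star = int(np.argmax(r2))
    if r2[m_star] <= 0:
        raise FeatureError("no DAB signal anywhere in the cohort; unscorable")
    if r1[m_star] <= 0:
        raise FeatureError("reference image has no hematoxylin signal")
    f2 = (r2 / r2[m_star]) / (np.maximum(r1, EPS_R) / r1[m_star])
    return f2, r1, r2


def feature_f3(w_bar: StainBasis, h_bars: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Normalized root-power DAB intensity per image.

    ``M3(m) = ||w_dab||_2 ||h_dab||_2 / (3 N_m)`` (the Frobenius norm of the
    rank-one intensity matrix factors into the product of 2-norms), then
    ``f3 = M3 / max M3``.
    """
    w2 = np.linalg.norm(w_bar.dab)
    m3 = np.array([w2 * np.linalg.norm(h[1]) / (3 * h.shape[1]) for h in h_bars])
    top = m3.max()
    if top <= 0:
        raise FeatureError("no DAB signal anywhere in the cohort; unscorable")
    return m3 / top, m3


def feature_f4(bases: list[StainBasis], concs: list[np.ndarray]) -> np.ndarray:
    """Root-mean DAB intensity power from each image's own separation.

    ``f4(m) = ||w_dab^m||_2 ||h_dab^m||_2 / sqrt(3 N_m)`` — the square root
    of the average power of the DAB intensity matrix, in OD units.  Unlike
    f1-f3 this uses the per-image basis, so it carries absolute-intensity
    information the cohort normalizations cancel.
    """
    out = np.empty(len(bases))
    for m, (b, h) in enumerate(zip(bases, concs)):
        out[m] = (
            np.linalg.norm(b.dab) * np.linalg.norm(h[1]) / np.sqrt(3 * h.shape[1])
        )
    return out


def compute_features(
    w_bar: StainBasis,
    h_bars: list[np.ndarray],
    per_image_bases: list[StainBasis],
    per_image_concs: list[np.ndarray],
    image_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Assemble the per-image feature table.

    ``per_image_bases``/``per_image_concs`` supply f4; for an image whose own
    basis estimation was degenerate, pass the cohort-average surrogate
    (w_bar, h_bar) in its slot.  Returns a DataFrame with columns
    image_id, f1..f4, M1, M3, R1, R2, N.
    """
    n_img = len(h_bars)
    if not (len(per_image_bases) == len(per_image_concs) == n_img):
        raise ValueError("per-image inputs must match the cohort length")
    f1, m1 = feature_f1(w_bar, h_bars)
    f2, r1, r2 = feature_f2(w_bar, h_bars)
    f3, m3 = feature_f3(w_bar, h_bars)
    f4 = feature_f4(per_image_bases, per_image_concs)
    if image_ids is None:
        image_ids = [f"image_{m:04d}" for m in range(n_img)]
    return pd.DataFrame(
        {
            "image_id": image_ids,
            "f1": f1,
            "f2": f2,
            "f3": f3,
            "f4": f4,
            "M1": m1,
            "M3": m3,
            "R1": r1,
            "R2": r2,
            "N": [h.shape[1] for h in h_bars],
        }
    )
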