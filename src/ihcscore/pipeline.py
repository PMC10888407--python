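"""End-to-end cohort pipeline: separation -> features -> scores.

The cohort is processed in two sweeps.  First each image gets its own
stain-basis estimate (images whose OD cloud is effectively rank-1 are
flagged degenerate and skipped); the per-image bases are averaged into the
cohort color matrix, with which every image — degenerate ones included —
is re-deconvolved.  Features f1-f3 come from the cohort-average
decomposition, f4 from the per-image one, and the p-norm k-means scorer
turns the feature table into "1+".."5+" scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import separation as sep
from .features import compute_features
from .imaging import (
    DEFAULT_EPS_FLOOR,
    DEFAULT_TAU_BG,
    ODMatrix,
    RGBImage,
    background_mask,
    rgb_to_od,
)
from .scoring import ScoreResult, ScoringConfig, score_features

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Constants of the separation stage, collected in one place."""

    tau_bg: float = DEFAULT_TAU_BG
    use_background_mask: bool = True
    n_bins: int = sep.DEFAULT_N_BINS
    butter_order: int = sep.DEFAULT_BUTTER_ORDER
    butter_cutoff: float = sep.DEFAULT_BUTTER_CUTOFF
    dominance: float = sep.DEFAULT_DOMINANCE
    eps_floor: float = DEFAULT_EPS_FLOOR
    eps_rank: float = sep.DEFAULT_EPS_RANK
    refine: bool = True

    def __post_init__(self) -> None:
        if self.n_bins < 10:
            raise ValueError("n_bins must be >= 10")
        for name in ("tau_bg", "butter_cutoff", "dominance", "eps_floor", "eps_rank"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ImageSeparation:
    """Per-image separation outcome and diagnostics."""

    image_id: str
    basis: sep.StainBasis | None
    conc: np.ndarray | None
    eigvals: np.ndarray
    angles: tuple[float, float] | None
    degenerate: bool
    clipped_fraction: float

    def diagnostics(self) -> dict:
        """JSON-ready sidecar payload."""
        return {
            "image_id": self.image_id,
            "degenerate": self.degenerate,
            "angles_rad": list(self.angles) if self.angles else None,
            "stain_basis": self.basis.matrix.tolist() if self.basis else None,
            "eigvals": self.eigvals.tolist(),
            "clipped_fraction": self.clipped_fraction,
        }


@dataclass
class CohortSeparation:
    """Separation results for a whole cohort."""

    per_image: list[ImageSeparation]
    w_bar: sep.StainBasis
    h_bars: list[np.ndarray]
    ods: list[ODMatrix] = field(repr=False, default=None)


@dataclass
class CohortScoring:
    """Scores plus everything needed to audit them."""

    result: ScoreResult
    features: pd.DataFrame
    separation: CohortSeparation

    def table(self) -> pd.DataFrame:
        """Per-image output table: image_id, score, cluster, norm, f1..f4."""
        df = self.features[["image_id", "f1", "f2", "f3", "f4"]].copy()
        df.insert(1, "score", self.result.scores)
        df.insert(2, "label", self.result.labels)
        df.insert(3, "norm", self.result.norms)
        return df


def separate_image(
    od: ODMatrix, config: PipelineConfig | None = None
) -> tuple[sep.StainBasis, np.ndarray]:
    """Single-image convenience wrapper: estimated (basis, concentrations)."""
    config = config or PipelineConfig()
    mask = background_mask(od, config.tau_bg) if config.use_background_mask else None
    basis, conc, _, _ = sep.estimate_image_basis(
        od,
        mask=mask,
        n_bins=config.n_bins,
        butter_order=config.butter_order,
        butter_cutoff=config.butter_cutoff,
        dominance=config.dominance,
        eps_rank=config.eps_rank,
        refine=config.refine,
    )
    return basis, conc


def separate_cohort(
    images: list[RGBImage],
    config: PipelineConfig | None = None,
    image_ids: list[str] | None = None,
) -> CohortSeparation:
    """Two-sweep cohort separation.

    Sweep 1 estimates a stain basis per image; degenerate (single-stain or
    blank) images and bases with substantial negative leakage are excluded
    from the average.  Sweep 2 re-deconvolves every image with the average
    basis, which recovers usable concentrations even for the excluded
    images.
    """
    config = config or PipelineConfig()
    if not images:
        raise sep.SeparationError("empty cohort")
    if image_ids is None:
        image_ids = [f"image_{m:04d}" for m in range(len(images))]
    ods = [rgb_to_od(im, eps_floor=config.eps_floor) for im in images]

    per_image: list[ImageSeparation] = []
    for image_id, od in zip(image_ids, ods):
        mask = background_mask(od, config.tau_bg) if config.use_background_mask else None
        eigvals = np.zeros(3)
        try:
            basis, conc, plane, _ = sep.estimate_image_basis(
                od,
                mask=mask,
                n_bins=config.n_bins,
                butter_order=config.butter_order,
                butter_cutoff=config.butter_cutoff,
                dominance=config.dominance,
                eps_rank=config.eps_rank,
                refine=config.refine,
            )
            eigvals = plane.eigvals
            angles = (
                float(np.arctan2(basis.matrix[1, 0], basis.matrix[0, 0])),
                float(np.arctan2(basis.matrix[1, 1], basis.matrix[0, 1])),
            )
            raw = np.linalg.solve(
                basis.matrix.T @ basis.matrix, basis.matrix.T @ od.values
            )
            clipped = float((raw < 0).mean())
            per_image.append(
                ImageSeparation(image_id, basis, conc, eigvals, angles, False, clipped)
            )
        except sep.DegenerateImageError as exc:
            logger.info("%s flagged degenerate: %s", image_id, exc)
            per_image.append(
                ImageSeparation(image_id, None, None, eigvals, None, True, 0.0)
            )

    usable = [r.basis for r in per_image if r.basis is not None and not r.basis.suspect]
    if not usable:
        usable = [r.basis for r in per_image if r.basis is not None]
    if not usable:
        raise sep.SeparationError("every image in the cohort is degenerate")
    w_bar = sep.average_basis(usable)
    h_bars = sep.cohort_deconvolve(ods, w_bar)
    return CohortSeparation(per_image, w_bar, h_bars, ods=ods)


def score_cohort(
    images: list[RGBImage],
    scoring_config: ScoringConfig | None = None,
    pipeline_config: PipelineConfig | None = None,
    image_ids: list[str] | None = None,
) -> CohortScoring:
    """Full pipeline: images in, ordered semi-quantitative scores out.

    Deterministic given inputs and configuration.  Needs at least
    ``n_clusters`` images (default 5).  Images whose own separation was
    degenerate are still scored, with f4 computed from the cohort-average
    surrogate (and a log message flagging them).
    """
    scoring_config = scoring_config or ScoringConfig()
    if len(images) < scoring_config.n_clusters:
        raise sep.SeparationError(
            f"need at least {scoring_config.n_clusters} images, got {len(images)}"
        )
    cohort = separate_cohort(images, pipeline_config, image_ids)
    bases, concs = [], []
    for r, h_bar in zip(cohort.per_image, cohort.h_bars):
        if r.basis is not None:
            bases.append(r.basis)
            concs.append(r.conc)
        else:
            logger.info("%s: f4 falls back to the cohort-average surrogate", r.image_id)
            bases.append(cohort.w_bar)
            concs.append(h_bar)
    feats = compute_features(
        cohort.w_bar,
        cohort.h_bars,
        bases,
        concs,
        image_ids=[r.image_id for r in cohort.per_image],
    )
    result = score_features(
        feats[["f1", "f2", "f3", "f4"]].to_numpy(), scoring_config
    )
    return CohortScoring(result, feats, cohort)
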