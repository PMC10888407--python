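"""Per-image and cohort stain-vector estimation plus color deconvolution.

The OD point cloud of a two-stain image lies (up to noise) in the cone
spanned by the two stain color vectors.  The estimation pipeline is:

1. uncentered PCA of the 3xN OD matrix — the top-two eigenvectors span the
   stain plane;
2. projection onto that plane with *unit-power* scaling (each principal
   component is divided by the square root of its eigenvalue), which widens
   the angular gap between the stain directions;
3. a density profile of the projected points over angle (1000 bins of the
   mean column norm, smoothed with a zero-phase 8th-order Butterworth filter
   at digital cutoff 0.035) whose two main peaks — one per half of the
   occupied angular range — give the planar stain directions;
4. lifting the planar basis back to 3-D, deconvolving concentrations by
   least squares with negatives clipped, and one refinement pass using
   pixels where one stain dominates the other 10-fold.

A cohort-average basis (the entry-wise mean of per-image estimates) is then
used to re-deconvolve every image, which stabilizes images where one stain
is nearly absent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .imaging import ODMatrix

#: Classical H and DAB OD unit vectors (Ruifrok & Johnston), used only to
#: decide which estimated column is hematoxylin and which is DAB.
HEMATOXYLIN_REF = np.array([0.650, 0.704, 0.286])
DAB_REF = np.array([0.269, 0.568, 0.778])

DEFAULT_N_BINS = 1000
DEFAULT_BUTTER_ORDER = 8
DEFAULT_BUTTER_CUTOFF = 0.035
DEFAULT_DOMINANCE = 10.0
#: L2/L1 below this flags a rank-1 (effectively single-stain) OD cloud.
DEFAULT_EPS_RANK = 1e-4


class SeparationError(ValueError):
    """Raised for degenerate inputs the separation stage cannot handle."""


class DegenerateImageError(SeparationError):
    """The OD cloud is effectively rank-1: a single-stain or blank image."""


@dataclass
class PrincipalPlane:
    """Uncentered-PCA decomposition of an OD matrix.

    ``eigvecs`` columns are the eigenvectors of R = X X^T / N (descending
    eigenvalues); ``projections`` holds the 2xN unit-power principal
    components once :func:`project_unit_power` has run.
    """

    eigvecs: np.ndarray
    eigvals: np.ndarray
    projections: np.ndarray | None = None

    @property
    def lift_matrix(self) -> np.ndarray:
        """3x2 matrix [q1*sqrt(L1), q2*sqrt(L2)] mapping plane -> OD space."""
        return self.eigvecs[:, :2] * np.sqrt(self.eigvals[:2])


@dataclass
class AngularProfile:
    """Binned mean column norm of the planar projections versus angle."""

    bin_centers: np.ndarray
    raw_mean_norm: np.ndarray
    smoothed: np.ndarray | None = None


@dataclass
class PlanarBasis:
    """Two planar unit vectors (cos phi, sin phi) at the estimated angles."""

    angles: tuple[float, float]
    matrix: np.ndarray


@dataclass
class StainBasis:
    """3x2 non-negative stain color matrix; column 0 = H, column 1 = DAB."""

    matrix: np.ndarray
    suspect: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 2):
            raise SeparationError(f"stain basis must be 3x2, got {self.matrix.shape}")
        if self.matrix.min() < 0:
            raise SeparationError("stain basis entries must be non-negative")
        if np.linalg.matrix_rank(self.matrix, tol=1e-12) < 2:
            raise SeparationError("stain basis columns are collinear")

    @property
    def hematoxylin(self) -> np.ndarray:
        return self.matrix[:, 0]

    @property
    def dab(self) -> np.ndarray:
        return self.matrix[:, 1]


def uncentered_pca(od: ODMatrix) -> PrincipalPlane:
    """Eigen-decomposition of the second-moment matrix R = X X^T / N.

    No mean subtraction: the OD cone geometry (all data in the first octant)
    is what makes the stain directions identifiable.  Eigenvalues come out
    descending; each eigenvector is sign-flipped so its entry sum is >= 0,
    pinning the angular frame reproducibly.
    """
    x = od.values
    if x.shape[1] < 3:
        raise SeparationError("need at least 3 pixels for PCA")
    if not x.any():
        raise DegenerateImageError("all-zero OD matrix (blank image)")
    r = x @ x.T / x.shape[1]
    eigvals, eigvecs = np.linalg.eigh(r)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    flip = np.where(eigvecs.sum(axis=0) < 0, -1.0, 1.0)
    return PrincipalPlane(eigvecs * flip, eigvals)


def project_unit_power(
    od: ODMatrix, plane: PrincipalPlane, eps_rank: float = DEFAULT_EPS_RANK
) -> np.ndarray:
    """Project OD columns onto the stain plane with unit-power scaling.

    Row i of the result is ``q_i^T X / sqrt(L_i)``, so each row has mean
    square 1.  Equalizing the component powers spreads the scattering angle
    between the two stain directions, which sharpens the density peaks.

    Raises
    ------
    DegenerateImageError
        If L2 <= eps_rank * L1 (rank-1 cloud: single-stain image); such
        images are excluded from per-image basis estimation and handled
        with the cohort-average basis instead.
    """
    l1, l2 = plane.eigvals[0], plane.eigvals[1]
    if l1 <= 0 or l2 <= eps_rank * l1:
        raise DegenerateImageError(
            f"rank-deficient OD cloud (L2/L1 = {l2 / l1 if l1 > 0 else 0:.2e})"
        )
    z = (plane.eigvecs[:, :2].T @ od.values) / np.sqrt(plane.eigvals[:2, None])
    plane.projections = z
    return z


def angular_profile(
    projections: np.ndarray,
    mask: np.ndarray | None = None,
    n_bins: int = DEFAULT_N_BINS,
) -> AngularProfile:
    """Bin the mean column norm of the projections by planar angle.

    ``theta(n) = atan2(z2, z1)`` and ``r(n) = ||z(:, n)||``.  The occupied
    angle range [min theta, max theta] is split into ``n_bins`` equal bins;
    each bin holds the mean r of its members (0 if empty).  ``mask``
    selects the foreground pixels that enter the profile.
    """
    z = np.asarray(projections, dtype=float)
    if mask is not None:
        z = z[:, np.asarray(mask, dtype=bool)]
    if z.shape[1] == 0:
        raise SeparationError("no foreground pixels for the angular profile")
    theta = np.arctan2(z[1], z[0])
    r = np.hypot(z[0], z[1])
    tmin, tmax = float(theta.min()), float(theta.max())
    if tmax <= tmin:
        raise SeparationError("all foreground points share one angle (degenerate)")
    width = (tmax - tmin) / n_bins
    idx = np.minimum(((theta - tmin) / width).astype(int), n_bins - 1)
    sums = np.bincount(idx, weights=r, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    mean_norm = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    centers = tmin + (np.arange(n_bins) + 0.5) * width
    return AngularProfile(centers, mean_norm)


def smooth_profile(
    profile: AngularProfile,
    order: int = DEFAULT_BUTTER_ORDER,
    cutoff: float = DEFAULT_BUTTER_CUTOFF,
) -> np.ndarray:
    """Zero-phase Butterworth smoothing of the raw angular profile.

    Forward-backward (``sosfiltfilt``) application keeps the filter
    zero-phase so peak positions are not shifted; SOS sections keep the
    8th-order design stable at the low digital cutoff (0.035 x Nyquist).
    The smoothed vector is also stored on ``profile``.
    """
    sos = signal.butter(order, cutoff, output="sos")
    y = np.asarray(profile.raw_mean_norm, dtype=float)
    # sosfiltfilt needs the signal to exceed its edge-padding length
    padlen = 3 * (2 * sos.shape[0] + 1)
    if y.size <= padlen:
        raise SeparationError(
            f"profile too short for the smoothing filter ({y.size} <= {padlen} bins)"
        )
    smoothed = signal.sosfiltfilt(sos, y)
    profile.smoothed = smoothed
    return smoothed


def find_basis_angles(profile: AngularProfile) -> PlanarBasis:
    """Pick the two stain angles from the smoothed angular profile.

    The global maximum of the smoothed profile gives the first angle.  The
    second is the largest *local* maximum restricted to the half of the
    occupied angle range that does not contain the first — spurious
    secondary bumps next to the dominant stain cannot shadow the true
    second stain this way, because the true basis vectors sit near the
    extrema of the range.  Requiring a local maximum keeps the monotone
    tail of the dominant peak, sliced off at the midpoint, from
    masquerading as the second stain.
    """
    if profile.smoothed is None:
        smooth_profile(profile)
    v = profile.smoothed
    centers = profile.bin_centers
    k1 = int(np.argmax(v))
    mid = 0.5 * (centers[0] + centers[-1])
    first_in_lower = centers[k1] < mid
    other = centers >= mid if first_in_lower else centers < mid
    if not np.any(profile.raw_mean_norm[other] > 0):
        raise DegenerateImageError(
            "no density in the opposite angular half (single-stain image)"
        )
    # local maxima of the full smoothed profile (range ends included)
    local = np.ones(v.size, dtype=bool)
    local[1:] &= v[1:] > v[:-1]
    local[:-1] &= v[:-1] >= v[1:]
    cand = np.where(other & local)[0]
    if cand.size == 0:
        cand = np.where(other)[0]
    k2 = cand[int(np.argmax(v[cand]))]
    phi1, phi2 = float(centers[k1]), float(centers[k2])
    mat = np.array([[np.cos(phi1), np.cos(phi2)], [np.sin(phi1), np.sin(phi2)]])
    return PlanarBasis((phi1, phi2), mat)


def _assign_stain_columns(w: np.ndarray) -> np.ndarray:
    """Order the columns of a 3x2 basis as (hematoxylin, DAB).

    Assignment maximizes the summed cosine similarity to the classical H
    and DAB reference directions; an exact tie is broken by the blue-channel
    OD (the larger blue absorbance is DAB).
    """
    norms = np.linalg.norm(w, axis=0)
    norms[norms == 0] = 1.0
    u = w / norms
    keep = u[:, 0] @ HEMATOXYLIN_REF + u[:, 1] @ DAB_REF
    swap = u[:, 1] @ HEMATOXYLIN_REF + u[:, 0] @ DAB_REF
    if np.isclose(keep, swap):
        return w if w[2, 1] >= w[2, 0] else w[:, ::-1]
    return w if keep >= swap else w[:, ::-1]


def lift_basis(
    planar: PlanarBasis, plane: PrincipalPlane, assign_stains: bool = True
) -> StainBasis:
    """Lift a planar basis to OD space: ``W = [q1 sqrt(L1), q2 sqrt(L2)] B``.

    Small negative entries (numerical leakage out of the cone) are clipped
    to zero; a column with a substantial negative entry marks the basis as
    ``suspect`` so the cohort average can skip it.
    """
    w = plane.lift_matrix @ planar.matrix
    col_norms = np.linalg.norm(w, axis=0)
    suspect = bool((w < -0.05 * col_norms).any())
    if suspect:
        warnings.warn(
            "lifted stain basis has a large negative entry; excluded from averaging",
            stacklevel=2,
        )
    w = np.clip(w, 0.0, None)
    if assign_stains:
        w = _assign_stain_columns(w)
    return StainBasis(w, suspect=suspect)


def color_deconvolve(od: ODMatrix | np.ndarray, basis: StainBasis) -> np.ndarray:
    """Estimate stain concentrations H by least squares, clipped at zero.

    ``H = (W^T W)^-1 W^T X`` (the left pseudoinverse of the full-rank 3x2
    basis), negatives set to 0.  Columns left with exactly one strictly
    positive entry are then recalculated by single-vector least squares
    against the corresponding basis column, ``h = max(0, w.x / ||w||^2)``,
    so a pixel attributed to a single stain gets that stain's best fit
    rather than an artifact of the clipped joint fit.
    """
    x = od.values if isinstance(od, ODMatrix) else np.asarray(od, dtype=float)
    w = basis.matrix
    gram = w.T @ w
    if np.linalg.matrix_rank(gram, tol=1e-12) < 2:
        raise SeparationError("rank-deficient stain basis")
    h_ls = np.linalg.solve(gram, w.T @ x)
    h = np.clip(h_ls, 0.0, None)
    single = (h > 0).sum(axis=0) == 1
    if single.any():
        which = np.argmax(h[:, single] > 0, axis=0)
        for s in (0, 1):
            cols = np.where(single)[0][which == s]
            if cols.size:
                ws = w[:, s]
                h[s, cols] = np.clip(ws @ x[:, cols] / (ws @ ws), 0.0, None)
    return h


def refine_basis(
    od: ODMatrix,
    plane: PrincipalPlane,
    basis: StainBasis,
    conc: np.ndarray,
    dominance: float = DEFAULT_DOMINANCE,
) -> tuple[StainBasis, np.ndarray]:
    """One refinement pass using stain-dominant pixels.

    For each stain, pixels whose concentration is at least ``dominance``
    times the other stain's (and positive) are collected; the mean of their
    unit-power planar projections, renormalized, replaces that stain's
    planar direction.  The refined basis is lifted back to OD space and the
    concentrations are re-deconvolved.  A stain with no dominant pixels
    keeps its previous direction.
    """
    if plane.projections is None:
        project_unit_power(od, plane)
    z = plane.projections
    lift = plane.lift_matrix
    w_new = np.empty((3, 2))
    suspect = False
    for s in (0, 1):
        other = 1 - s
        dom = (conc[s] >= dominance * conc[other]) & (conc[s] > 0)
        if dom.any():
            b = z[:, dom].mean(axis=1)
            nb = np.linalg.norm(b)
            if nb == 0:
                raise SeparationError("degenerate refined direction")
            col = lift @ (b / nb)
            if (col < -0.05 * np.linalg.norm(col)).any():
                suspect = True
            w_new[:, s] = np.clip(col, 0.0, None)
        else:
            warnings.warn(f"no dominant pixels for stain column {s}; kept", stacklevel=2)
            w_new[:, s] = basis.matrix[:, s]
    if suspect:
        warnings.warn(
            "refined stain basis has a large negative entry; excluded from averaging",
            stacklevel=2,
        )
    # column identity is already fixed by the concentration rows
    refined = StainBasis(w_new, suspect=suspect or basis.suspect)
    return refined, color_deconvolve(od, refined)


def estimate_image_basis(
    od: ODMatrix,
    mask: np.ndarray | None = None,
    n_bins: int = DEFAULT_N_BINS,
    butter_order: int = DEFAULT_BUTTER_ORDER,
    butter_cutoff: float = DEFAULT_BUTTER_CUTOFF,
    dominance: float = DEFAULT_DOMINANCE,
    eps_rank: float = DEFAULT_EPS_RANK,
    refine: bool = True,
) -> tuple[StainBasis, np.ndarray, PrincipalPlane, AngularProfile]:
    """Full per-image estimation: PCA, angular peaks, lift, deconvolve, refine.

    ``mask`` flags background pixels to exclude from the angular profile
    (they still enter PCA and deconvolution).  Raises
    :class:`DegenerateImageError` for single-stain/blank images.
    """
    plane = uncentered_pca(od)
    z = project_unit_power(od, plane, eps_rank=eps_rank)
    fg = None if mask is None else ~np.asarray(mask, dtype=bool)
    profile = angular_profile(z, mask=fg, n_bins=n_bins)
    smooth_profile(profile, order=butter_order, cutoff=butter_cutoff)
    planar = find_basis_angles(profile)
    basis = lift_basis(planar, plane)
    conc = color_deconvolve(od, basis)
    if refine:
        basis, conc = refine_basis(od, plane, basis, conc, dominance=dominance)
    return basis, conc, plane, profile


def average_basis(bases: list[StainBasis]) -> StainBasis:
    """Entry-wise mean of per-image stain bases (degenerate images excluded
    upstream); the cohort-level color matrix W-bar."""
    if not bases:
        raise SeparationError("no per-image bases to average")
    return StainBasis(np.mean([b.matrix for b in bases], axis=0))


def cohort_deconvolve(ods: list[ODMatrix], w_bar: StainBasis) -> list[np.ndarray]:
    """Re-deconvolve every image of the cohort with the shared average basis."""
    return [color_deconvolve(od, w_bar) for od in ods]
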