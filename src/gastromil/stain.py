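"""Macenko stain estimation and normalization for H&E patches.

The construction follows the canonical singular-vector recipe: convert
RGB to optical density (Beer-Lambert), drop near-transparent pixels
(OD < 0.15 in any channel), project the OD point cloud onto the plane of
its two leading eigenvectors, and take the 1st/99th percentile of the
angular distribution as the hematoxylin and eosin directions.  Per-stain
concentration scale is the 99th percentile of the least-squares
concentrations, which is matched between source and target during
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateStainError, InvalidInputError

# transmitted intensity scale; +1 keeps log finite for I = 255
_IO = 256.0


def rgb_to_od(patch: np.ndarray) -> np.ndarray:
    """Optical density per channel, shape preserved."""
    return -np.log((patch.astype(np.float64) + 1.0) / _IO)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`, clipped to valid 8-bit values."""
    return np.clip(_IO * np.exp(-od) - 1.0, 0, 255).astype(np.uint8)


@dataclass
class StainBasis:
    """Unit-norm H and E optical-density vectors plus concentration scales.

    ``matrix`` is 3x2 with column 0 = hematoxylin, column 1 = eosin;
    ``max_concentrations`` holds the per-stain 99th-percentile scalars.
    """

    matrix: np.ndarray
    max_concentrations: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.max_concentrations = np.asarray(self.max_concentrations, dtype=np.float64)
        if self.matrix.shape != (3, 2):
            raise InvalidInputError("stain basis must be a 3x2 matrix")
        if (self.matrix < -1e-9).any():
            raise InvalidInputError("stain OD vectors must be nonnegative")
        norms = np.linalg.norm(self.matrix, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise InvalidInputError("stain OD vectors must have unit norm")


def _angular_extreme_vectors(plane: np.ndarray, proj: np.ndarray, percentile: float) -> np.ndarray:
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, [percentile, 100.0 - percentile])
    v_lo = plane @ np.array([np.cos(lo), np.sin(lo)])
    v_hi = plane @ np.array([np.cos(hi), np.sin(hi)])
    return np.stack([v_lo, v_hi], axis=1)


def fit_stain_basis(
    patch: np.ndarray,
    od_threshold: float = 0.15,
    angular_percentile: float = 1.0,
    concentration_percentile: float = 99.0,
    source_id: str = "",
) -> StainBasis:
    """Estimate an H&E :class:`StainBasis` from one RGB patch.

    Raises :class:`DegenerateStainError` when the patch carries no
    optical-density signal (e.g. all-white glass).
    """
    if patch.ndim != 3 or patch.shape[2] != 3:
        raise InvalidInputError("patch must be (H, W, 3) RGB")
    od = rgb_to_od(patch).reshape(-1, 3)
    # drop near-transparent pixels: total OD below threshold.  (A per-channel
    # cut would also discard pure-eosin pixels, whose red OD is ~0.07.)
    od_hat = od[np.linalg.norm(od, axis=1) >= od_threshold]
    if len(od_hat) < 16:
        raise DegenerateStainError("too few stained pixels to estimate a basis")
    cov = np.cov(od_hat.T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] < 1e-12:
        raise DegenerateStainError("optical-density cloud is degenerate")
    plane = evecs[:, [-1, -2]]  # two leading eigenvectors, columns
    # orient the plane so projections land in a consistent half-space
    for j in range(2):
        if plane[:, j].sum() < 0:
            plane[:, j] = -plane[:, j]
    proj = od_hat @ plane
    vecs = _angular_extreme_vectors(plane, proj, angular_percentile)
    # flip any vector pointing into the negative orthant, then clip noise
    for j in range(2):
        if vecs[:, j].sum() < 0:
            vecs[:, j] = -vecs[:, j]
    vecs = np.clip(vecs, 0.0, None)
    norms = np.linalg.norm(vecs, axis=0)
    if (norms < 1e-9).any():
        raise DegenerateStainError("estimated stain vector collapsed to zero")
    vecs = vecs / norms
    # hematoxylin (blue-purple) absorbs red more strongly than eosin
    if vecs[0, 0] < vecs[0, 1]:
        vecs = vecs[:, ::-1]
    conc = np.linalg.lstsq(vecs, od.T, rcond=None)[0]
    max_c = np.percentile(np.maximum(conc, 0.0), concentration_percentile, axis=1)
    max_c = np.maximum(max_c, 1e-9)
    return StainBasis(vecs, max_c, source_id=source_id)


def stain_concentrations(patch: np.ndarray, basis: StainBasis) -> np.ndarray:
    """Least-squares H/E concentration maps, shape (H, W, 2), clipped at 0."""
    od = rgb_to_od(patch).reshape(-1, 3)
    conc = np.linalg.lstsq(basis.matrix, od.T, rcond=None)[0]
    return np.maximum(conc.T, 0.0).reshape(patch.shape[0], patch.shape[1], 2)


def macenko_normalize(patch: np.ndarray, source: StainBasis, target: StainBasis) -> np.ndarray:
    """Re-express *patch* in the target stain basis with matched scales.

    Concentrations are estimated under the source basis, rescaled per
    stain by ``target.max / source.max``, and reconstructed through the
    target OD vectors.  Output is clipped to valid 8-bit RGB.
    """
    if patch.ndim != 3 or patch.shape[2] != 3:
        raise InvalidInputError("patch must be (H, W, 3) RGB")
    conc = stain_concentrations(patch, source).reshape(-1, 2)
    conc = conc * (target.max_concentrations / source.max_concentrations)
    od = conc @ target.matrix.T
    return od_to_rgb(od).reshape(patch.shape)


# canonical H&E OD directions, used by the synthetic toy-slide painter
REFERENCE_HE_OD = np.array(
    [[0.65, 0.07], [0.70, 0.99], [0.29, 0.11]], dtype=np.float64
)
REFERENCE_HE_OD /= np.linalg.norm(REFERENCE_HE_OD, axis=0)
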