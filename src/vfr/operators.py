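"""Simulated manual segmentation: operator-dependent mask perturbations.

A human operator contouring a vertebra slice by slice produces masks that
differ from the true solid through (i) a global over/under-segmentation bias,
(ii) smooth, spatially correlated boundary displacement, (iii) per-slice
contour jitter from the slice-wise workflow, and (iv) all-or-nothing
inclusion of ambiguous features such as osteophytes.

All four mechanisms act additively in the signed-distance field of the true
mask: the perturbed mask is ``{x : d(x) <= T(x)}`` where ``d`` is the signed
distance (negative inside) and ``T`` collects the perturbation terms in mm.
This guarantees topologically sane masks whose deviation from truth scales
directly with each amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import SegmentationMask
from .phantoms import VertebraPhantom

__all__ = [
    "OperatorProfile",
    "INTRA_PRESET",
    "INTER_PRESET",
    "simulate_operator_mask",
]


@dataclass(frozen=True)
class OperatorProfile:
    """Amplitudes (mm) of the operator variability mechanisms."""

    offset_sd: float = 0.0          # SD of the global erode/dilate bias
    jitter_amp: float = 0.0         # SD of correlated surface displacement
    jitter_corr_mm: float = 5.0     # correlation length of that displacement
    slice_amp: float = 0.0          # SD of per-slice contour offset
    inclusion_prob: float = 0.0     # P(include the ambiguous feature)

    def __post_init__(self):
        if min(self.offset_sd, self.jitter_amp, self.slice_amp) < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.jitter_corr_mm <= 0:
            raise ValueError("correlation length must be positive")
        if not 0.0 <= self.inclusion_prob <= 1.0:
            raise ValueError("inclusion probability must be in [0, 1]")


#: Repeat segmentations by one operator: small bias drift, tight contours.
INTRA_PRESET = OperatorProfile(offset_sd=0.10, jitter_amp=0.15,
                               jitter_corr_mm=6.0, slice_amp=0.10,
                               inclusion_prob=0.0)

#: Different operators: larger bias and boundary-interpretation spread, and
#: occasional disagreement on an ambiguous bony feature.
INTER_PRESET = OperatorProfile(offset_sd=0.25, jitter_amp=0.35,
                               jitter_corr_mm=8.0, slice_amp=0.20,
                               inclusion_prob=0.25)


def _signed_distance_mm(mask: np.ndarray, spacing) -> np.ndarray:
    """Signed Euclidean distance to the mask surface, negative inside, mm.

    Voxel-centre distance transforms are quantised at one voxel; shifting
    by half a voxel towards the boundary puts the zero level on the actual
    surface, so sub-voxel perturbation amplitudes can flip boundary voxels
    at the correct rate.
    """
    sampling = tuple(spacing)
    outside = ndimage.distance_transform_edt(~mask, sampling=sampling)
    inside = ndimage.distance_transform_edt(mask, sampling=sampling)
    d = outside - inside
    half = 0.5 * float(np.mean(spacing))
    return d - np.sign(d) * half


def _correlated_field(shape, spacing, corr_mm, rng) -> np.ndarray:
    """Unit-variance Gaussian random field with the given correlation length."""
    white = rng.standard_normal(shape)
    sigma_vox = corr_mm / spacing
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    sd = smooth.std()
    if sd < 1e-12:     # pathological: return flat field
        return np.zeros(shape)
    return smooth / sd


def _osteophyte_bump(phantom: VertebraPhantom) -> np.ndarray:
    """Half-ellipsoid bump on the anterior equator of the body surface."""
    g = phantom.geometry
    sp = phantom.grid.spacing
    ax = [(np.arange(n) + 0.5) * sp for n in phantom.grid.shape]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)
    # anterior surface point at mid-height, in world coordinates
    s_mid = float(g.scale_at(0.5))
    center = phantom.body_to_world(np.array([[0.0, g.b * s_mid, 0.0]]))[0]
    radii = np.array([0.35 * g.a, 3.0, 0.30 * g.height])
    d = (pts - center) / radii
    return (d ** 2).sum(axis=-1) <= 1.0


def simulate_operator_mask(phantom: VertebraPhantom,
                           profile: OperatorProfile,
                           seed=None) -> SegmentationMask:
    """Draw one operator segmentation of the phantom.

    With all amplitudes zero and inclusion probability zero the output
    equals the true mask exactly.  Reproducible given ``seed`` (int or
    :class:`numpy.random.SeedSequence`).

    Raises
    ------
    RuntimeError
        If the perturbation erases the mask entirely.
    """
    rng = np.random.default_rng(seed)
    true = phantom.mask.data
    sp = phantom.grid.spacing

    # draw in fixed order so seeds are comparable across profiles
    g_off = rng.normal(0.0, 1.0) * profile.offset_sd
    jitter_seed_field = None
    if profile.jitter_amp > 0:
        jitter_seed_field = _correlated_field(true.shape, sp,
                                              profile.jitter_corr_mm, rng)
    slice_draws = rng.normal(0.0, 1.0, size=true.shape[2])
    include_draw = rng.uniform()

    if (profile.offset_sd == 0 and profile.jitter_amp == 0
            and profile.slice_amp == 0 and profile.inclusion_prob == 0):
        return SegmentationMask(true.copy(), phantom.mask.spacing,
                                scope=phantom.mask.scope,
                                meta={"profile": profile})

    d = _signed_distance_mm(true, phantom.mask.spacing)
    thresh = np.full(true.shape, g_off)
    if jitter_seed_field is not None:
        thresh = thresh + profile.jitter_amp * jitter_seed_field
    if profile.slice_amp > 0:
        thresh = thresh + (profile.slice_amp
                           * slice_draws)[None, None, :]

    out = d <= thresh
    if profile.inclusion_prob > 0 and include_draw < profile.inclusion_prob:
        out = out | _osteophyte_bump(phantom)

    # keep the largest connected component so the mask is a single solid
    labels, n = ndimage.label(out)
    if n == 0:
        raise RuntimeError("perturbation erased the segmentation entirely")
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n + 1))
        out = labels == (1 + int(np.argmax(sizes)))

    return SegmentationMask(out, phantom.mask.spacing,
                            scope=phantom.mask.scope,
                            meta={"profile": profile})
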