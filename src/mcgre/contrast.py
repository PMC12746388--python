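"""Background-phase estimation, pass combination and contrast extraction.

The two acquisition passes differ only in the sign of the RF phase
increment, so their ideal images are x and conj(x) while the nuisance
background phase e^{i phi(r)} (field/transmit inhomogeneity) multiplies
both identically.  The voxelwise product of the two pass images is
e^{2 i phi} |x|^2, whose half angle recovers phi on the principal branch
(-pi/2, pi/2].  Averaging the phase-corrected positive pass with the
conjugated phase-corrected negative pass then restores the multi-contrast
image x, up to a per-voxel sign tied to the half-angle branch — an
ambiguity the extraction step is insensitive to, because extraction takes
the absolute value of the real projection:

    x_psi = | Re( x * e^{i psi} ) |

Extraction is pi-periodic in psi, so psi in [0, 180) deg enumerates every
encodable soft-tissue contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import PhaseMap


@dataclass(frozen=True)
class MultiContrastImage:
    """Background-phase-corrected complex image for one echo."""

    x: np.ndarray
    echo: str = "cte"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.x)):
            raise ValueError("image contains non-finite values")


@dataclass(frozen=True)
class ExtractedContrast:
    """Real non-negative contrast extracted at phase modulation psi (deg)."""

    psi: float
    image: np.ndarray


def estimate_background_phase(
    x_plus: np.ndarray,
    x_minus: np.ndarray,
    floor_fraction: float = 1e-6,
    smooth_sigma: float = 0.0,
) -> PhaseMap:
    """Half-angle of the voxelwise product of the two pass images.

    ``angle(x_plus * x_minus) / 2`` lies on the principal branch
    (-pi/2, pi/2].  Voxels whose product magnitude falls below
    ``floor_fraction * max`` are masked (set to zero phase, excluded from
    the trust mask).  ``smooth_sigma`` optionally smooths the complex
    product before the half angle to stabilize noisy voxels (off by
    default).
    """
    if x_plus.shape != x_minus.shape:
        raise ValueError("pass images must share a grid")
    prod = x_plus * x_minus
    if smooth_sigma > 0:
        prod = ndimage.gaussian_filter(prod.real, smooth_sigma) + 1j * ndimage.gaussian_filter(
            prod.imag, smooth_sigma
        )
    mag = np.abs(prod)
    floor = floor_fraction * float(mag.max()) if mag.max() > 0 else 0.0
    mask = mag > floor
    phi = np.where(mask, 0.5 * np.angle(prod), 0.0)
    return PhaseMap(phi=phi, mask=mask)


def combine_passes(
    x_plus: np.ndarray,
    x_minus: np.ndarray,
    phase: PhaseMap,
    echo: str = "cte",
) -> MultiContrastImage:
    """Average of the phase-corrected passes:
    x = (x_plus e^{-i phi} + conj(x_minus e^{-i phi})) / 2.

    With exact inputs this equals the true multi-contrast image up to a
    per-voxel sign from the half-angle branch; independent noise on the two
    passes averages down by a factor of two in variance.
    """
    corr = np.exp(-1j * phase.phi)
    x = 0.5 * (x_plus * corr + np.conj(x_minus * corr))
    return MultiContrastImage(x=x, echo=echo)


def extract_contrast(x: MultiContrastImage | np.ndarray, psi_deg: float) -> ExtractedContrast:
    """x_psi = |Re(x e^{i psi})| with psi reduced mod 180 degrees."""
    if not np.isfinite(psi_deg):
        raise ValueError("psi must be finite")
    arr = x.x if isinstance(x, MultiContrastImage) else np.asarray(x)
    psi = float(np.mod(psi_deg, 180.0))
    image = np.abs(np.real(arr * np.exp(1j * np.radians(psi))))
    return ExtractedContrast(psi=psi, image=image)


def extract_contrast_sweep(
    x: MultiContrastImage | np.ndarray, psis_deg: np.ndarray
) -> list[ExtractedContrast]:
    return [extract_contrast(x, float(p)) for p in np.asarray(psis_deg, dtype=float)]
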