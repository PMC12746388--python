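"""Seeded digital head phantoms, coil maps and background phase for fixtures.

The default phantom is a concentric head-like object: an outer subcutaneous
fat ring, a cortical-bone shell (T2 0.3-0.4 ms at ~20% proton density — the
collagen-bound bone-water pool), a gray-matter ribbon, a white-matter
interior with CSF pockets, and air outside.  It is not anatomically
realistic; its purpose is to exercise every tissue regime the signal model
distinguishes (short T2, long T2 at several T1s, zero proton density) on a
geometry where class masks are known exactly.

Everything here is a pure function of (shape, parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .sequence_sim import SequenceParams, TissueParams, simulate_steady_state_epg

#: Relaxation times (ms) and relative proton densities of the phantom's
#: tissue classes, representative of brain at 3 T.  Air carries pd = 0.
DEFAULT_TISSUES: dict[str, TissueParams] = {
    "air": TissueParams(t1=1000.0, t2=1.0, pd=0.0, label="air"),
    "bone": TissueParams(t1=300.0, t2=0.35, pd=0.2, label="bone"),
    "wm": TissueParams(t1=800.0, t2=70.0, pd=0.7, label="wm"),
    "gm": TissueParams(t1=1300.0, t2=90.0, pd=0.8, label="gm"),
    "csf": TissueParams(t1=4000.0, t2=2000.0, pd=1.0, label="csf"),
    "fat": TissueParams(t1=380.0, t2=110.0, pd=0.9, label="fat"),
}

CLASS_IDS = {name: i for i, name in enumerate(DEFAULT_TISSUES)}


@dataclass(frozen=True)
class TissueMap:
    """Voxel lattice of tissue-class ids with per-class parameters."""

    class_id: np.ndarray  # integer array, 2D or 3D
    classes: dict[str, TissueParams]
    spacing_mm: float = 1.0

    @property
    def shape(self) -> tuple[int, ...]:
        return self.class_id.shape

    def mask(self, label: str) -> np.ndarray:
        return self.class_id == CLASS_IDS[label]

    def property_map(self, attr: str) -> np.ndarray:
        """Broadcast a per-class scalar (t1/t2/pd) to the voxel grid."""
        lut = np.zeros(max(CLASS_IDS.values()) + 1)
        for name, tp in self.classes.items():
            lut[CLASS_IDS[name]] = getattr(tp, attr)
        return lut[self.class_id]


@dataclass(frozen=True)
class PhaseMap:
    """Real background phase phi(r) in radians; nuisance field e^{i phi}."""

    phi: np.ndarray
    mask: np.ndarray | None = None  # voxels where the estimate is trusted

    @property
    def field(self) -> np.ndarray:
        return np.exp(1j * self.phi)


@dataclass(frozen=True)
class CoilMaps:
    """Per-coil complex sensitivities, shape (n_coils, *grid)."""

    maps: np.ndarray

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.maps.shape[1:]

    def rss(self) -> np.ndarray:
        return np.sqrt(np.sum(np.abs(self.maps) ** 2, axis=0))


@dataclass(frozen=True)
class NoiseSpec:
    """i.i.d. complex Gaussian noise per k-space sample and coil."""

    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def _radius_grid(shape: tuple[int, ...]) -> np.ndarray:
    """Normalized radius from FOV center: 1.0 at the nearest edge midpoint."""
    axes = [(np.arange(n) - n // 2) / (n / 2) for n in shape]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(sum(m**2 for m in mesh))


def make_phantom(
    shape: tuple[int, ...],
    seed: int = 0,
    classes: dict[str, TissueParams] | None = None,
) -> TissueMap:
    """Concentric head-like phantom, deterministic given seed.

    Layers (normalized radius, mild seeded ellipticity): air > 0.92 > fat >
    0.82 > bone > 0.64 > gray-matter ribbon > 0.50 > white matter, with
    seeded CSF pockets in the interior.  The bone shell is several voxels
    wide even at the default 64^2 test scale, so that class-mean metrics
    are not dominated by partial-volume edges.
    """
    shape = tuple(int(n) for n in shape)
    if len(shape) not in (2, 3) or min(shape) < 32:
        raise ValueError("shape must be 2D/3D with every side >= 32")
    classes = dict(classes or DEFAULT_TISSUES)
    rng = np.random.default_rng(seed)

    # mild anisotropic scaling makes the object elliptical but keeps layers
    scale = 1.0 + 0.08 * rng.uniform(-1, 1, size=len(shape))
    axes = [(np.arange(n) - n // 2) / (n / 2) * s for n, s in zip(shape, scale)]
    mesh = np.meshgrid(*axes, indexing="ij")
    r = np.sqrt(sum(m**2 for m in mesh))

    cid = np.full(shape, CLASS_IDS["air"], dtype=np.int16)
    cid[r <= 0.92] = CLASS_IDS["fat"]
    cid[r <= 0.82] = CLASS_IDS["bone"]
    cid[r <= 0.64] = CLASS_IDS["gm"]
    cid[r <= 0.50] = CLASS_IDS["wm"]

    # CSF pockets: ventricle-like ellipses near the center
    n_pockets = 2 if len(shape) == 2 else 3
    for _ in range(n_pockets):
        center = rng.uniform(-0.20, 0.20, size=len(shape))
        radii = rng.uniform(0.10, 0.16, size=len(shape))
        d = sum(((m - c) / rad) ** 2 for m, c, rad in zip(mesh, center, radii))
        cid[(d <= 1.0) & (r <= 0.50)] = CLASS_IDS["csf"]

    return TissueMap(class_id=cid, classes=classes)


def make_background_phase(
    shape: tuple[int, ...], amplitude: float, seed: int = 0
) -> PhaseMap:
    """Smooth background phase: low-order polynomial plus filtered noise.

    The field emulates static-field and transmit inhomogeneity; it is scaled
    so that max|phi| equals ``amplitude`` (radians).  The same map is used
    for both passes — the model's key assumption.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    shape = tuple(int(n) for n in shape)
    if amplitude == 0:
        return PhaseMap(phi=np.zeros(shape))
    rng = np.random.default_rng(seed)
    axes = [(np.arange(n) - n // 2) / (n / 2) for n in shape]
    mesh = np.meshgrid(*axes, indexing="ij")

    phi = np.zeros(shape)
    for m in mesh:
        phi += rng.normal() * m + rng.normal() * m**2
    for i, mi in enumerate(mesh):
        for mj in mesh[i + 1 :]:
            phi += rng.normal() * mi * mj

    rough = rng.normal(size=shape)
    smooth = ndimage.gaussian_filter(rough, sigma=max(shape) / 8)
    if np.max(np.abs(smooth)) > 0:
        phi += 0.5 * smooth / np.max(np.abs(smooth))

    phi *= amplitude / np.max(np.abs(phi))
    return PhaseMap(phi=phi)


def make_coil_maps(
    shape: tuple[int, ...],
    n_coils: int,
    seed: int = 0,
    uniform: bool = False,
) -> CoilMaps:
    """Smooth synthetic receive sensitivities (Gaussian lobes around the FOV).

    Stand-in for measured/calibrated coil maps: each coil is a broad Gaussian
    centered outside the object on a ring, with a smooth linear phase.
    ``uniform=True`` returns all-ones maps (single-channel identity).
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    shape = tuple(int(n) for n in shape)
    if uniform:
        return CoilMaps(maps=np.ones((n_coils, *shape), dtype=complex))
    rng = np.random.default_rng(seed)
    axes = [(np.arange(n) - n // 2) / (n / 2) for n in shape]
    mesh = np.meshgrid(*axes, indexing="ij")

    maps = np.empty((n_coils, *shape), dtype=complex)
    width = 1.1
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils + rng.uniform(0, 0.2)
        center = np.zeros(len(shape))
        center[0] = 1.2 * np.cos(ang)
        center[-1] = 1.2 * np.sin(ang)
        d2 = sum((m - cc) ** 2 for m, cc in zip(mesh, center))
        mag = np.exp(-d2 / (2 * width**2))
        lin = sum(rng.uniform(-0.5, 0.5) * m for m in mesh)
        maps[c] = mag * np.exp(1j * (lin + rng.uniform(0, 2 * np.pi)))
    return CoilMaps(maps=maps)


def tissue_signal_table(
    tmap: TissueMap, seq: SequenceParams, n_states: int | None = None
) -> dict[str, tuple[complex, complex]]:
    """Steady-state (UTE, CTE) signal per tissue class for a pulse train."""
    kwargs = {} if n_states is None else {"n_states": n_states}
    table: dict[str, tuple[complex, complex]] = {}
    for name, tp in tmap.classes.items():
        if tp.pd == 0:
            table[name] = (0j, 0j)
        else:
            s = simulate_steady_state_epg(seq, tp, **kwargs)
            table[name] = (s.s_ute, s.s_cte)
    return table


def synthesize_ideal_images(
    tmap: TissueMap,
    seq: SequenceParams,
    phase: PhaseMap | None = None,
) -> dict[tuple[str, str], np.ndarray]:
    """Ideal voxelwise images x_{k,l} for the four (echo, pass) datasets.

    Per-class steady-state signals at +theta are broadcast to the grid; the
    positive pass is e^{i phi} x_k, the negative pass e^{i phi} conj(x_k)
    (flipping theta conjugates the signal).  Keys are (echo, pass) with
    echo in {"ute", "cte"} and pass in {"+", "-"}.
    """
    if seq.theta <= 0:
        raise ValueError("the positive pass requires theta > 0")
    table = tissue_signal_table(tmap, seq)
    lut_ute = np.zeros(max(CLASS_IDS.values()) + 1, dtype=complex)
    lut_cte = np.zeros_like(lut_ute)
    for name in tmap.classes:
        lut_ute[CLASS_IDS[name]], lut_cte[CLASS_IDS[name]] = table[name]
    x_ute = lut_ute[tmap.class_id]
    x_cte = lut_cte[tmap.class_id]

    field = np.ones(tmap.shape, dtype=complex) if phase is None else phase.field
    return {
        ("ute", "+"): field * x_ute,
        ("ute", "-"): field * np.conj(x_ute),
        ("cte", "+"): field * x_cte,
        ("cte", "-"): field * np.conj(x_cte),
    }


def ideal_multi_contrast(
    tmap: TissueMap, seq: SequenceParams
) -> dict[str, np.ndarray]:
    """Ground-truth multi-contrast images x_k (no background phase)."""
    images = synthesize_ideal_images(tmap, seq, phase=None)
    return {"ute": images[("ute", "+")], "cte": images[("cte", "+")]}
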