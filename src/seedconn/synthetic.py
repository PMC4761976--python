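"""Synthetic 4D BOLD cohorts with known ROI correlation structure.

The generator places disjoint ellipsoidal ROIs inside a brain-shaped
ellipsoid on the acquisition grid, draws band-limited latent signals with
a prescribed ROI-by-ROI correlation matrix, and embeds them in voxel noise
(AR(1) plus linear drift) at a 100:1 brain/background intensity contrast.
Two bundled strain profiles emulate the qualitative group difference under
study: an "SHR-like" network that couples the retrosplenial seed to the
caudate putamen and a cortico-striato-thalamo-cortical set, and a
"WKY-like" network that couples the seed to the hippocampus instead.

Every output is a pure function of (acquisition spec, profile, seeds).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .core import AcquisitionSpec, Image4D, ROIAtlas
from .preprocess import bandpass

__all__ = [
    "StrainProfile",
    "GroundTruth",
    "couplings_from_loadings",
    "make_toy_atlas",
    "build_target_matrix",
    "repair_psd",
    "simulate_subject",
    "simulate_cohort",
    "shr_like_profile",
    "wky_like_profile",
    "get_profile",
]

#: Required region names; the first entries cover the regions referenced by
#: the bundled strain profiles, the remainder pad out a 25-ROI atlas.
CORE_ROI_NAMES = [
    "RSC",
    "CaudatePutamen",
    "Hippocampus",
    "CingulateCortex",
    "MotorCortex",
    "Thalamus",
    "OrbitalCortex",
    "SomatosensoryCortex",
]

#: In-plane radius multipliers for anatomically large structures.
_ROI_SIZE_FACTORS = {"CaudatePutamen": 1.6, "Hippocampus": 1.4}

BRAIN_BASELINE = 100.0  # mean in-brain intensity; background is ~0 (100:1)
BACKGROUND_NOISE_SD = 1.0


@dataclass(frozen=True)
class StrainProfile:
    """Generative profile for one cohort.

    couplings : (roi_a, roi_b, target_r) triples injected into the latent
        correlation matrix.
    signal_band : Hz band of the latent signals; kept inside the analysis
        pass band so filtering does not destroy the injected structure.
    ar_coeff : AR(1) coefficient of the voxel noise.
    noise_sd : stationary standard deviation of the voxel noise.
    drift_amp : peak amplitude of the per-voxel linear drift.
    snr_scale : amplitude of the unit-variance latent signal in voxel units.
    """

    name: str
    couplings: tuple[tuple[str, str, float], ...] = ()
    signal_band: tuple[float, float] = (0.01, 0.05)
    ar_coeff: float = 0.3
    noise_sd: float = 4.0
    drift_amp: float = 10.0
    snr_scale: float = 6.0

    def __post_init__(self) -> None:
        for a, b, r in self.couplings:
            if not abs(r) < 1:
                raise ValueError(f"coupling ({a}, {b}): need |r| < 1, got {r}")
        low, high = self.signal_band
        if not (0 < low < high):
            raise ValueError(f"invalid signal band {self.signal_band}")
        if not (0 <= self.ar_coeff < 1):
            raise ValueError("ar_coeff must be in [0, 1)")
        if self.noise_sd < 0 or self.drift_amp < 0 or self.snr_scale < 0:
            raise ValueError("noise_sd, drift_amp and snr_scale must be >= 0")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "couplings": [list(c) for c in self.couplings],
            "signal_band": list(self.signal_band),
            "ar_coeff": self.ar_coeff,
            "noise_sd": self.noise_sd,
            "drift_amp": self.drift_amp,
            "snr_scale": self.snr_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StrainProfile":
        return cls(
            name=d["name"],
            couplings=tuple((a, b, float(r)) for a, b, r in d.get("couplings", [])),
            signal_band=tuple(d.get("signal_band", (0.01, 0.05))),
            ar_coeff=float(d.get("ar_coeff", 0.3)),
            noise_sd=float(d.get("noise_sd", 4.0)),
            drift_amp=float(d.get("drift_amp", 10.0)),
            snr_scale=float(d.get("snr_scale", 6.0)),
        )


def couplings_from_loadings(loadings: dict[str, float]) -> tuple[tuple[str, str, float], ...]:
    """Pairwise couplings of a one-factor network.

    Region X with loading l_x correlates with region Y at l_x * l_y; the
    resulting target matrix is positive semidefinite by construction
    (rank-one plus diagonal), so no repair distorts the intended values.
    """
    names = list(loadings)
    for n, l in loadings.items():
        if not 0 < l < 1:
            raise ValueError(f"loading for {n} must be in (0, 1), got {l}")
    out = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            out.append((a, b, round(loadings[a] * loadings[b], 6)))
    return tuple(out)


# One-factor loadings chosen once to encode the qualitative strain contrast:
# the SHR-like network couples the RSC seed to the caudate putamen and
# cingulate/orbital/somatosensory cortices plus thalamus (CSTC-flavoured),
# the WKY-like network couples it to the hippocampus and a weaker cortical
# set. The SHR-like seed network is both larger and stronger.
_SHR_LOADINGS = {
    "RSC": 0.90,
    "CaudatePutamen": 0.82,
    "CingulateCortex": 0.80,
    "OrbitalCortex": 0.74,
    "SomatosensoryCortex": 0.70,
    "Thalamus": 0.60,
}
_WKY_LOADINGS = {
    "RSC": 0.80,
    "Hippocampus": 0.70,
    "CingulateCortex": 0.60,
    "OrbitalCortex": 0.56,
    "MotorCortex": 0.50,
}


def shr_like_profile(**overrides) -> StrainProfile:
    """Default SHR-like cohort profile (seed coupled to caudate putamen)."""
    p = StrainProfile(name="SHR-like", couplings=couplings_from_loadings(_SHR_LOADINGS))
    return replace(p, **overrides) if overrides else p


def wky_like_profile(**overrides) -> StrainProfile:
    """Default WKY-like cohort profile (seed coupled to hippocampus)."""
    p = StrainProfile(name="WKY-like", couplings=couplings_from_loadings(_WKY_LOADINGS))
    return replace(p, **overrides) if overrides else p


def get_profile(name: str) -> StrainProfile:
    key = name.lower()
    if key in ("shr", "shr-like"):
        return shr_like_profile()
    if key in ("wky", "wky-like"):
        return wky_like_profile()
    raise KeyError(f"unknown profile {name!r}; expected 'shr' or 'wky'")


@dataclass
class GroundTruth:
    """Everything needed to regenerate a cohort and score recovery."""

    atlas: ROIAtlas
    target_matrix: np.ndarray
    profile: StrainProfile
    acquisition: AcquisitionSpec
    repair_distance: float = 0.0
    per_subject_seeds: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        C = np.asarray(self.target_matrix, dtype=np.float64)
        if C.shape != (self.atlas.n_rois, self.atlas.n_rois):
            raise ValueError("target matrix size does not match atlas")
        if not np.allclose(C, C.T, atol=1e-12):
            raise ValueError("target matrix must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-9):
            raise ValueError("target matrix must have unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-8:
            raise ValueError("target matrix must be positive semidefinite")
        self.target_matrix = C

    def save(self, path: str | Path) -> None:
        payload = {
            "roi_names": self.atlas.names,
            "target_matrix": self.target_matrix.tolist(),
            "repair_distance": self.repair_distance,
            "per_subject_seeds": list(self.per_subject_seeds),
            "profile": self.profile.to_dict(),
            "acquisition": {
                "nx": self.acquisition.nx,
                "ny": self.acquisition.ny,
                "nz": self.acquisition.nz,
                "n_volumes": self.acquisition.n_volumes,
                "tr": self.acquisition.tr,
                "voxel_dims": list(self.acquisition.voxel_dims),
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return d2 <= 1.0


def _roi_names(n_rois: int) -> list[str]:
    names = CORE_ROI_NAMES[:n_rois]
    names += [f"ROI{i:02d}" for i in range(len(names) + 1, n_rois + 1)]
    return names


def make_toy_atlas(
    spec: AcquisitionSpec | None = None,
    n_rois: int = 25,
    roi_radius: float | None = None,
) -> ROIAtlas:
    """Place ``n_rois`` disjoint ellipsoidal ROIs inside a brain ellipsoid.

    Geometry is deterministic given the grid. The named core regions come
    first (seed "RSC" nearest the brain center); large structures
    (caudate putamen, hippocampus) get proportionally larger ROIs. Raises
    a sizing error naming the first region that cannot be placed.
    """
    spec = spec or AcquisitionSpec()
    if n_rois < 2:
        raise ValueError("need n_rois >= 2")
    nx, ny, nz = spec.nx, spec.ny, spec.nz
    center = ((nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0)
    brain_semi = (0.44 * nx, 0.44 * ny, max(0.46 * nz, 1.0))
    brain = _ellipsoid_mask((nx, ny, nz), center, brain_semi)

    rp = roi_radius if roi_radius is not None else max(1.6, min(nx, ny) / 20.0)
    rz = 1.2 if nz >= 5 else 0.9
    names = _roi_names(n_rois)

    # Candidate centers: lattice points per z-level, nearest-to-center first.
    spacing = max(3, int(round(2 * rp + 2)))
    if nz >= 9:
        z_levels = [center[2] - 0.3 * nz, center[2], center[2] + 0.3 * nz]
    elif nz >= 7:
        z_levels = [center[2] - 0.25 * nz, center[2] + 0.25 * nz]
    else:
        z_levels = [center[2]]
    xs = np.arange(spacing // 2, nx, spacing)
    ys = np.arange(spacing // 2, ny, spacing)
    candidates = sorted(
        ((float(x), float(y), float(z)) for z in z_levels for x in xs for y in ys),
        key=lambda c: (
            round((c[0] - center[0]) ** 2 + (c[1] - center[1]) ** 2, 6),
            abs(c[2] - center[2]),
            c,
        ),
    )

    labels = np.zeros((nx, ny, nz), dtype=np.int32)
    used = np.zeros(len(candidates), dtype=bool)
    for label, name in enumerate(names, start=1):
        r_in = rp * _ROI_SIZE_FACTORS.get(name, 1.0)
        placed = False
        for ci, c in enumerate(candidates):
            if used[ci]:
                continue
            roi = _ellipsoid_mask((nx, ny, nz), c, (r_in, r_in, rz))
            if roi.sum() < 8:
                continue
            if np.any(roi & ~brain) or np.any(roi & (labels > 0)):
                continue
            labels[roi] = label
            used[ci] = True
            placed = True
            break
        if not placed:
            raise ValueError(
                f"grid {nx}x{ny}x{nz} too small to place ROI {name!r} "
                f"(radius {r_in:.1f} vox); enlarge the grid or reduce n_rois"
            )
    return ROIAtlas(
        labels=labels, names=names, brain_mask=brain, voxel_dims=spec.voxel_dims
    )


def repair_psd(C: np.ndarray) -> tuple[np.ndarray, float]:
    """Nearest-PSD repair: clip negative eigenvalues, rescale to unit diagonal.

    Returns the repaired correlation matrix and the max absolute entry
    change (0 when the input is already PSD). Idempotent.
    """
    C = np.asarray(C, dtype=np.float64)
    w, V = np.linalg.eigh(C)
    if w.min() >= -1e-12:
        return C.copy(), 0.0
    w_clipped = np.clip(w, 0.0, None)
    R = (V * w_clipped) @ V.T
    d = np.sqrt(np.clip(np.diag(R), 1e-12, None))
    R = R / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    R = (R + R.T) / 2.0
    return R, float(np.abs(R - C).max())


def build_target_matrix(
    atlas: ROIAtlas,
    profile: StrainProfile,
    acquisition: AcquisitionSpec | None = None,
) -> GroundTruth:
    """Assemble the K x K latent correlation matrix from a profile.

    Entries are 1 on the diagonal, the profile's target_r at coupled pairs
    and 0 elsewhere; a non-PSD assembly is repaired by eigenvalue clipping
    with the repair distance recorded on the returned ground truth.
    ``acquisition`` carries the scan length and TR; when omitted, the grid
    is taken from the atlas with the default 300-volume, TR = 1 s scan.
    """
    K = atlas.n_rois
    C = np.eye(K)
    for a, b, r in profile.couplings:
        ia, ib = atlas.label_of(a) - 1, atlas.label_of(b) - 1
        if ia == ib:
            raise ValueError(f"coupling references the same ROI twice: {a}")
        C[ia, ib] = C[ib, ia] = r
    C, dist = repair_psd(C)
    spec = acquisition or AcquisitionSpec(
        nx=atlas.spatial_shape[0],
        ny=atlas.spatial_shape[1],
        nz=atlas.spatial_shape[2],
        voxel_dims=atlas.voxel_dims,
    )
    if spec.spatial_shape != atlas.spatial_shape:
        raise ValueError("acquisition grid does not match the atlas grid")
    return GroundTruth(
        atlas=atlas,
        target_matrix=C,
        profile=profile,
        acquisition=spec,
        repair_distance=dist,
    )


def _latent_signals(truth: GroundTruth, rng: np.random.Generator) -> np.ndarray:
    """K unit-variance band-limited series with the target correlation."""
    K = truth.atlas.n_rois
    T = truth.acquisition.n_volumes
    tr = truth.acquisition.tr
    white = rng.standard_normal((K, T))
    band_limited = bandpass(white, truth.profile.signal_band, tr)
    sd = band_limited.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    band_limited /= sd
    w, V = np.linalg.eigh(truth.target_matrix)
    sqrt_C = (V * np.sqrt(np.clip(w, 0.0, None))) @ V.T
    return sqrt_C @ band_limited


def simulate_subject(truth: GroundTruth, subject_seed: int) -> Image4D:
    """One subject's 4D image; bit-reproducible from ``subject_seed``.

    Brain voxels carry a baseline intensity, their ROI's latent signal
    scaled by ``snr_scale`` (unlabeled brain voxels carry none), AR(1)
    noise and a per-voxel linear drift; background voxels are near-zero
    white noise.
    """
    rng = np.random.default_rng(int(subject_seed))
    spec = truth.acquisition
    prof = truth.profile
    T = spec.n_volumes
    latents = _latent_signals(truth, rng)

    brain = truth.atlas.brain()
    labels = truth.atlas.labels
    n_brain = int(brain.sum())
    brain_labels = labels[brain]  # 0 for unlabeled brain voxels

    series = np.full((n_brain, T), BRAIN_BASELINE)
    labeled = brain_labels > 0
    series[labeled] += prof.snr_scale * latents[brain_labels[labeled] - 1]

    # AR(1) noise at stationary sd = noise_sd (float32 draws: speed, and the
    # downstream statistics are computed in float64 anyway)
    innov_sd = prof.noise_sd * np.sqrt(1.0 - prof.ar_coeff**2)
    innov = rng.standard_normal((n_brain, T), dtype=np.float32) * innov_sd
    series += lfilter([1.0], [1.0, -prof.ar_coeff], innov, axis=1)

    # linear drift, per-voxel slope uniform in [-drift_amp, drift_amp] at peak
    slopes = rng.uniform(-prof.drift_amp, prof.drift_amp, size=n_brain)
    ramp = np.linspace(-0.5, 0.5, T)
    series += slopes[:, None] * ramp[None, :]

    data = np.zeros((*spec.spatial_shape, T), dtype=np.float32)
    data[~brain] = (
        rng.standard_normal((int((~brain).sum()), T), dtype=np.float32)
        * BACKGROUND_NOISE_SD
    )
    data[brain] = series
    return Image4D(data=data, voxel_dims=spec.voxel_dims, tr=spec.tr)


def subject_seed(master_seed: int, index: int) -> int:
    """Stable per-subject seed derived from (master_seed, index)."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def simulate_cohort(
    truth: GroundTruth, n_subjects: int = 9, master_seed: int = 0
) -> tuple[list[Image4D], GroundTruth]:
    """Simulate a cohort; per-subject seeds derive from ``master_seed``."""
    if n_subjects < 2:
        raise ValueError("group statistics need n_subjects >= 2")
    seeds = tuple(subject_seed(master_seed, i) for i in range(n_subjects))
    truth = replace(truth, per_subject_seeds=seeds)
    images = [simulate_subject(truth, s) for s in seeds]
    return images, truth


def iter_cohort(truth: GroundTruth, n_subjects: int, master_seed: int):
    """Yield (seed, image) pairs one at a time (memory-friendly variant)."""
    if n_subjects < 2:
        raise ValueError("group statistics need n_subjects >= 2")
    for i in range(n_subjects):
        s = subject_seed(master_seed, i)
        yield s, simulate_subject(truth, s)
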