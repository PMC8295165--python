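"""Synthetic intravascular-ultrasound vessel phantoms.

Catheter-based coronary ultrasound frames show, from the inside out: the
imaging catheter itself as a bright central disc, the dark blood-filled
lumen, the brighter vessel-wall ring (intima + media) and the surrounding
adventitia.  The texture is dominated by multiplicative speckle, and parts
of the frame are obscured by angular shadow wedges (guidewire artifacts,
calcifications).

This module emulates those features with a deformed-ellipse geometry
described in polar coordinates, which guarantees the mask invariants: the
lumen is a simply connected region strictly inside a closed vessel-wall
ring, and the three classes partition the frame.  Frames are grouped into
synthetic "patients" that share morphology statistics, enabling grouped
(patient-wise) cross-validation exactly as with real multi-patient data.

Not modeled: physically accurate wave propagation, plaque/calcification
echogenicity, transducer-specific texture.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "GeneratorProfile", "PatientParams", "PhantomSample",
    "sample_patient", "render_phantom", "augment",
    "generate_dataset", "generate_arrays", "build_manifest", "load_dataset",
]


@dataclass(frozen=True)
class GeneratorProfile:
    """Population-level ranges from which per-patient morphology is drawn.

    Lengths are fractions of the frame side so the same profile works at
    any resolution; intensities are display levels in [0, 1] with the dark
    lumen below the wall.
    """

    frame_size: int = 256
    lumen_radius_frac: tuple[float, float] = (0.10, 0.22)
    wall_thickness_frac: tuple[float, float] = (0.05, 0.11)
    eccentricity: tuple[float, float] = (0.0, 0.25)
    center_jitter_frac: float = 0.04
    lumen_level: tuple[float, float] = (0.06, 0.14)
    wall_level: tuple[float, float] = (0.45, 0.65)
    adventitia_level: tuple[float, float] = (0.25, 0.38)
    shadow_count: tuple[int, int] = (0, 3)
    speckle_shape: tuple[float, float] = (3.0, 8.0)
    catheter_radius_frac: tuple[float, float] = (0.03, 0.05)
    edge_smoothing: float = 1.0

    def __post_init__(self):
        lo_l, hi_l = self.lumen_radius_frac
        lo_w, hi_w = self.wall_thickness_frac
        # worst case must keep the outer wall inside the frame
        worst = hi_l * (1 + self.eccentricity[1]) + hi_w + self.center_jitter_frac
        if worst >= 0.48:
            raise ValueError(
                "infeasible profile: lumen + wall + jitter do not fit the frame")
        if self.lumen_level[1] >= self.wall_level[0]:
            raise ValueError("lumen must be darker than the vessel wall")


@dataclass
class PatientParams:
    """Morphology of one synthetic patient (pixel units)."""

    frame_size: int
    lumen_radius_range: tuple[float, float]
    wall_thickness_range: tuple[float, float]
    eccentricity: float
    center_jitter: float
    intensity_levels: tuple[float, float, float]   # (lumen, wall, adventitia)
    shadow_count_range: tuple[int, int]
    speckle_shape: float | None                    # None disables speckle
    catheter_radius: float
    edge_smoothing: float = 1.0

    def __post_init__(self):
        half = self.frame_size / 2
        worst = (self.lumen_radius_range[1] * (1 + self.eccentricity)
                 + self.wall_thickness_range[1] + self.center_jitter)
        if worst >= half:
            raise ValueError("lumen + wall + jitter exceed the frame half-size")
        lum, wall, _ = self.intensity_levels
        if not lum < wall:
            raise ValueError("lumen must be darker than the wall")


@dataclass
class PhantomSample:
    """One rendered frame: image in [0, 1], 3-class mask, provenance."""

    image: np.ndarray
    mask: np.ndarray
    patient_id: str
    seed: int


def _rng_for(*entropy) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy))


def sample_patient(seed: int, profile: GeneratorProfile | None = None,
                   patient_index: int = 0) -> PatientParams:
    """Deterministic draw of one patient's morphology from a profile."""
    profile = profile or GeneratorProfile()
    rng = _rng_for(seed, patient_index, 0xC0FFEE)
    s = profile.frame_size

    def span(frac_range, width=0.25):
        center = rng.uniform(*frac_range)
        lo_f, hi_f = frac_range
        half = width * (hi_f - lo_f) / 2
        return (max(lo_f, center - half) * s, min(hi_f, center + half) * s)

    return PatientParams(
        frame_size=s,
        lumen_radius_range=span(profile.lumen_radius_frac),
        wall_thickness_range=span(profile.wall_thickness_frac),
        eccentricity=rng.uniform(*profile.eccentricity),
        center_jitter=profile.center_jitter_frac * s,
        intensity_levels=(rng.uniform(*profile.lumen_level),
                          rng.uniform(*profile.wall_level),
                          rng.uniform(*profile.adventitia_level)),
        shadow_count_range=profile.shadow_count,
        speckle_shape=rng.uniform(*profile.speckle_shape),
        catheter_radius=rng.uniform(*profile.catheter_radius_frac) * s,
        edge_smoothing=profile.edge_smoothing,
    )


def _radial_profiles(p: PatientParams, rng: np.random.Generator):
    """Lumen radius and wall thickness as smooth 2*pi-periodic functions."""
    r0 = rng.uniform(*p.lumen_radius_range)
    t0 = rng.uniform(*p.wall_thickness_range)
    phase = rng.uniform(0, 2 * np.pi, size=3)
    ecc = p.eccentricity
    wobble = rng.uniform(0.0, 0.10)
    thick_mod = rng.uniform(0.0, 0.25)

    def lumen_radius(theta):
        return r0 * (1 + ecc * np.cos(2 * (theta - phase[0]))
                     + wobble * np.cos(3 * (theta - phase[1])))

    def wall_thickness(theta):
        return t0 * (1 + thick_mod * np.cos(theta - phase[2]))

    return lumen_radius, wall_thickness


def render_phantom(params: PatientParams, seed: int,
                   patient_id: str = "p00") -> PhantomSample:
    """Render one frame: geometry, intensity levels, catheter, speckle,
    shadows.  The mask comes from the noise-free geometry."""
    s = params.frame_size
    rng = _rng_for(seed, 0xF00D)
    center = (s / 2 + rng.uniform(-params.center_jitter, params.center_jitter),
              s / 2 + rng.uniform(-params.center_jitter, params.center_jitter))
    lumen_radius, wall_thickness = _radial_profiles(params, rng)

    rows, cols = np.mgrid[0:s, 0:s].astype(np.float64)
    dr, dc = rows - center[0], cols - center[1]
    rho = np.hypot(dr, dc)
    theta = np.arctan2(dc, dr)

    rl = lumen_radius(theta)
    rw = rl + wall_thickness(theta)
    mask = np.zeros((s, s), dtype=np.int64)
    mask[rho < rw] = 1
    mask[rho < rl] = 2

    lum, wall, adv = params.intensity_levels
    image = np.full((s, s), adv)
    image[mask == 1] = wall
    image[mask == 2] = lum
    if params.edge_smoothing > 0:
        image = ndimage.gaussian_filter(image, params.edge_smoothing)

    # bright catheter disc with ring-down halo at the frame center
    cath = rho < params.catheter_radius
    image[cath] = 0.75
    halo = (rho >= params.catheter_radius) & (rho < 1.6 * params.catheter_radius)
    image[halo] = np.maximum(image[halo], 0.45)

    if params.speckle_shape is not None and np.isfinite(params.speckle_shape):
        k = params.speckle_shape
        speckle = rng.gamma(shape=k, scale=1.0 / k, size=(s, s))
        speckle = ndimage.gaussian_filter(speckle, 0.7)
        image = image * speckle

    n_shadows = int(rng.integers(params.shadow_count_range[0],
                                 params.shadow_count_range[1] + 1))
    for _ in range(n_shadows):
        ang = rng.uniform(-np.pi, np.pi)
        width = rng.uniform(0.15, 0.6)
        atten = rng.uniform(0.25, 0.6)
        delta = np.angle(np.exp(1j * (theta - ang)))
        inside = np.abs(delta) < width / 2
        # raised-cosine edges so the wedge fades in smoothly
        fade = 0.5 * (1 + np.cos(np.pi * np.clip(np.abs(delta) / (width / 2), 0, 1)))
        factor = 1.0 - (1.0 - atten) * fade
        wedge = np.where(inside | (fade > 0), factor, 1.0)
        wedge[rho < 1.6 * params.catheter_radius] = 1.0
        image = image * wedge

    return PhantomSample(np.clip(image, 0.0, 1.0), mask, patient_id, seed)


def augment(sample: PhantomSample, seed: int) -> PhantomSample:
    """Random rotation about the frame center plus random flips.

    The image is interpolated bilinearly, the mask with nearest neighbours
    so labels stay integral; both receive identical transforms.
    """
    rng = _rng_for(seed, 0xA06)
    angle = rng.uniform(0.0, 360.0)
    flip_h = bool(rng.integers(0, 2))
    flip_v = bool(rng.integers(0, 2))
    image, mask = sample.image, sample.mask
    if angle != 0.0:
        image = ndimage.rotate(image, angle, reshape=False, order=1,
                               mode="nearest")
        mask = ndimage.rotate(mask, angle, reshape=False, order=0,
                              mode="nearest")
    if flip_h:
        image, mask = image[:, ::-1], mask[:, ::-1]
    if flip_v:
        image, mask = image[::-1, :], mask[::-1, :]
    return PhantomSample(np.ascontiguousarray(np.clip(image, 0, 1)),
                         np.ascontiguousarray(mask), sample.patient_id, seed)


def generate_arrays(n_patients: int, per_patient: int, size: int,
                    seed: int,
                    profile: GeneratorProfile | None = None) -> list[PhantomSample]:
    """In-memory dataset: ``n_patients`` synthetic patients with
    ``per_patient`` frames each, fully reproducible from ``seed``."""
    if n_patients < 1 or per_patient < 1:
        raise ValueError("n_patients and per_patient must be >= 1")
    profile = profile or GeneratorProfile()
    if profile.frame_size != size:
        profile = GeneratorProfile(**{**asdict(profile), "frame_size": size})
    samples = []
    for pi in range(n_patients):
        params = sample_patient(seed, profile, patient_index=pi)
        pid = f"patient{pi:02d}"
        for fi in range(per_patient):
            frame_seed = int(np.random.SeedSequence((seed, pi, fi)).generate_state(1)[0]
                             % (2 ** 31))
            samples.append(render_phantom(params, frame_seed, patient_id=pid))
    return samples


def build_manifest(samples_or_counts, per_patient: int | None = None) -> pd.DataFrame:
    """Manifest rows (sample index, patient_id) for grouped fold assembly.

    Accepts either a list of :class:`PhantomSample` or
    ``(n_patients, per_patient)`` counts for a paths-only manifest.
    """
    if isinstance(samples_or_counts, int):
        n_patients = samples_or_counts
        if per_patient is None:
            raise ValueError("per_patient required with integer input")
        rows = [{"index": pi * per_patient + fi,
                 "image": f"patient{pi:02d}/frame{fi:03d}.png",
                 "mask": f"patient{pi:02d}/frame{fi:03d}_mask.png",
                 "patient_id": f"patient{pi:02d}", "frame": fi}
                for pi in range(n_patients) for fi in range(per_patient)]
    else:
        rows = [{"index": i, "image": "", "mask": "",
                 "patient_id": s.patient_id, "frame": i}
                for i, s in enumerate(samples_or_counts)]
    return pd.DataFrame(rows)


def generate_dataset(n_patients: int, per_patient: int, size: int, seed: int,
                     out_dir,
                     profile: GeneratorProfile | None = None) -> pd.DataFrame:
    """Write a phantom dataset to disk as 8-bit grayscale PNGs plus a CSV
    manifest; masks store raw label values 0/1/2.  Byte-reproducible from
    ``seed``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples = generate_arrays(n_patients, per_patient, size, seed, profile)
    rows = []
    for i, s in enumerate(samples):
        fi = i % per_patient
        pdir = out / s.patient_id
        pdir.mkdir(exist_ok=True)
        img_path = pdir / f"frame{fi:03d}.png"
        mask_path = pdir / f"frame{fi:03d}_mask.png"
        iio.imwrite(img_path, (s.image * 255).round().astype(np.uint8))
        iio.imwrite(mask_path, s.mask.astype(np.uint8))
        rows.append({"index": i, "image": str(img_path.relative_to(out)),
                     "mask": str(mask_path.relative_to(out)),
                     "patient_id": s.patient_id, "frame": fi})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_dataset(manifest: pd.DataFrame, root) -> list[PhantomSample]:
    """Read images/masks referenced by a manifest back into samples."""
    root = Path(root)
    samples = []
    for _, row in manifest.iterrows():
        image = iio.imread(root / row["image"]).astype(np.float64) / 255.0
        mask = iio.imread(root / row["mask"]).astype(np.int64)
        samples.append(PhantomSample(image, mask, row["patient_id"], -1))
    return samples
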