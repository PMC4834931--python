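"""Synthetic multi-contrast brain phantoms with analytically known volumes.

The phantom emulates a same-day scan-rescan study design: one subject imaged
twice, either on the same "scanner" (identical pose, fresh noise) or on two
scanners differing in voxel grid and tissue contrast (a 1.5T-like and a
3T-like preset), with zero or a prescribed true atrophy.

Geometry is a nest of ellipsoids — skull-bounded CSF shell, cortical GM
ribbon, WM core, CSF-filled ventricles, spherical WM lesions — so every
tissue volume has a closed form and the true percentage volume change
between two phantoms is exact by construction.  Atrophy is modelled by
rescaling the continuous geometry, never by warping rendered images, so the
ground truth is independent of any interpolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .grid import RigidTransform, VolumeGrid

# label codes
BG, CSF, GM, WM, VENT, LES = 0, 1, 2, 3, 4, 5
CLASS_NAMES = {BG: "background", CSF: "csf", GM: "gm", WM: "wm",
               VENT: "ventricle", LES: "lesion"}

#: Acquisition voxel sizes (mm) of the two scanner presets.
PRESET_SPACING = {
    "T15": {"t1": (0.87, 1.25, 1.2), "flair": (1.36, 1.77, 1.5)},
    "T30": {"t1": (0.88, 1.19, 1.0), "flair": (1.31, 1.34, 1.3)},
}

#: Per-class mean intensities per preset and contrast.  Values are plausible
#: arbitrary-unit levels chosen once so that (i) each contrast preserves the
#: canonical T1 ordering CSF < GM < WM and the FLAIR ordering CSF < WM < GM
#: < lesion, (ii) the 3T-like preset has a larger GM/WM contrast and darker
#: CSF than the 1.5T-like one, reproducing the inter-scanner contrast
#: confound, and (iii) lesions are hypointense on T1 and hyperintense on
#: FLAIR.
PRESET_CONTRAST = {
    "T15": {
        "t1": {BG: 0.0, CSF: 12.0, GM: 58.0, WM: 82.0, VENT: 12.0, LES: 38.0},
        "flair": {BG: 0.0, CSF: 10.0, GM: 68.0, WM: 58.0, VENT: 10.0, LES: 100.0},
    },
    "T30": {
        "t1": {BG: 0.0, CSF: 7.0, GM: 50.0, WM: 88.0, VENT: 7.0, LES: 33.0},
        "flair": {BG: 0.0, CSF: 6.0, GM: 75.0, WM: 61.0, VENT: 6.0, LES: 112.0},
    },
}


class PhantomConfigError(ValueError):
    """Raised when a phantom spec violates geometric containment."""


def _ellipsoid_volume(radii) -> float:
    r = np.asarray(radii, dtype=float)
    return float(4.0 / 3.0 * np.pi * np.prod(r))


def _sphere_points(n: int = 128) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere surface points (Fibonacci)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


@dataclass
class PhantomSpec:
    """Full description of one synthetic subject/session.

    All geometry is expressed in world mm, phantom centered at the origin
    (an optional rigid ``pose`` repositions it).  ``brain_radii_mm`` are the
    outer parenchyma semi-axes; the CSF shell extends out to
    ``skull_radii_mm``; the GM ribbon is the outer ``gm_thickness_mm`` of the
    parenchyma; ventricles are CSF-filled ellipsoids inside the WM core and
    lesions are spheres carved from WM.
    """

    grid_shape: tuple = (64, 48, 48)
    voxel_spacing_mm: tuple = (2.61, 3.75, 3.6)
    flair_grid_shape: tuple | None = None
    flair_spacing_mm: tuple | None = None
    brain_radii_mm: tuple = (63.0, 80.0, 47.0)
    skull_radii_mm: tuple | None = None  # default: brain_radii + 4 mm
    gm_thickness_mm: float = 10.0
    ventricles: tuple = (((-11.0, -8.0, 2.0), (8.0, 20.0, 8.0)),
                         ((11.0, -8.0, 2.0), (8.0, 20.0, 8.0)))
    lesion_seeds: tuple = ()  # ((center_mm, radius_mm), ...)
    atrophy_pct: float = 0.0
    gm_atrophy_pct: float = 0.0
    contrast_preset: str = "T15"
    bias_amplitude: float = 0.0
    noise_sigma: float = 0.0
    rng_seed: int = 0
    #: seed of the multiplicative shading field; defaults to rng_seed.
    #: Same-scanner same-pose rescans share the coil profile, so intra-
    #: scanner session pairs share bias_seed while redrawing noise.
    bias_seed: int | None = None
    pose: RigidTransform = field(default_factory=RigidTransform)
    supersampling: int = 3

    def __post_init__(self):
        if self.skull_radii_mm is None:
            self.skull_radii_mm = tuple(r + 4.0 for r in self.brain_radii_mm)
        if self.flair_spacing_mm is None:
            self.flair_spacing_mm = self.voxel_spacing_mm
        if self.flair_grid_shape is None:
            self.flair_grid_shape = self.grid_shape
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.contrast_preset not in PRESET_CONTRAST:
            raise PhantomConfigError(
                f"unknown contrast preset {self.contrast_preset!r}; "
                f"valid presets: {sorted(PRESET_CONTRAST)}"
            )
        br = np.asarray(self.brain_radii_mm, dtype=float)
        sk = np.asarray(self.skull_radii_mm, dtype=float)
        if np.any(br <= 0) or np.any(sk <= 0):
            raise PhantomConfigError("brain/skull radii must be strictly positive")
        if self.gm_thickness_mm < 0 or self.gm_thickness_mm >= br.min():
            raise PhantomConfigError(
                "gm_thickness_mm must be in [0, min(brain_radii))"
            )
        if np.any(sk < br):
            raise PhantomConfigError("skull radii must enclose the parenchyma")
        if not -5.0 <= self.atrophy_pct <= 5.0:
            raise PhantomConfigError("atrophy_pct must lie in [-5, 5]")
        if self.noise_sigma < 0:
            raise PhantomConfigError("noise_sigma must be >= 0")
        inner = br - self.gm_thickness_mm
        sphere = _sphere_points()
        for name, center, radii in self._cavities():
            pts = np.asarray(center) + sphere * np.asarray(radii)
            if np.any(np.sum((pts / inner) ** 2, axis=1) >= 1.0):
                raise PhantomConfigError(
                    f"{name} is not strictly inside the WM core"
                )
        # lesions must not touch ventricles or each other
        for name, center, radii in self._cavities():
            if not name.startswith("lesion"):
                continue
            pts = np.asarray(center) + sphere * np.asarray(radii)
            for vc, vr in self.ventricles:
                rel = (pts - np.asarray(vc)) / np.asarray(vr)
                if np.any(np.sum(rel**2, axis=1) <= 1.0):
                    raise PhantomConfigError(f"{name} overlaps a ventricle")
        for i, (c1, r1) in enumerate(self.lesion_seeds):
            for c2, r2 in list(self.lesion_seeds)[i + 1:]:
                if np.linalg.norm(np.subtract(c1, c2)) <= r1 + r2:
                    raise PhantomConfigError("lesions overlap each other")

    def _cavities(self):
        for i, (c, r) in enumerate(self.ventricles):
            yield f"ventricle[{i}]", c, r
        for i, (c, r) in enumerate(self.lesion_seeds):
            yield f"lesion[{i}]", c, (r, r, r)

    # -- analytic volumes (ml) -------------------------------------------
    @property
    def inner_radii_mm(self) -> np.ndarray:
        return np.asarray(self.brain_radii_mm, dtype=float) - self.gm_thickness_mm

    @property
    def ventricle_ml(self) -> float:
        return sum(_ellipsoid_volume(r) for _, r in self.ventricles) / 1000.0

    @property
    def lesion_ml(self) -> float:
        return sum(_ellipsoid_volume((r, r, r)) for _, r in self.lesion_seeds) / 1000.0

    @property
    def gm_ml(self) -> float:
        return (_ellipsoid_volume(self.brain_radii_mm)
                - _ellipsoid_volume(self.inner_radii_mm)) / 1000.0

    @property
    def wm_ml(self) -> float:
        return (_ellipsoid_volume(self.inner_radii_mm) / 1000.0
                - self.ventricle_ml - self.lesion_ml)

    @property
    def pv_ml(self) -> float:
        """Parenchymal volume = GM + WM + lesion (lesions are parenchyma)."""
        return (_ellipsoid_volume(self.brain_radii_mm) / 1000.0
                - self.ventricle_ml)

    def grid_geometry(self, channel: str = "t1") -> VolumeGrid:
        """Empty VolumeGrid centered on the phantom."""
        if channel == "t1":
            shape, spacing = self.grid_shape, self.voxel_spacing_mm
        elif channel == "flair":
            shape, spacing = self.flair_grid_shape, self.flair_spacing_mm
        else:
            raise ValueError("channel must be 't1' or 'flair'")
        shape = tuple(int(n) for n in shape)
        spacing = np.asarray(spacing, dtype=float)
        origin = -spacing * (np.asarray(shape) - 1) / 2.0
        return VolumeGrid(np.zeros(shape), spacing, origin)

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in (
            "grid_shape", "voxel_spacing_mm", "flair_grid_shape",
            "flair_spacing_mm", "brain_radii_mm", "skull_radii_mm",
            "gm_thickness_mm", "ventricles", "lesion_seeds", "atrophy_pct",
            "gm_atrophy_pct", "contrast_preset", "bias_amplitude",
            "noise_sigma", "rng_seed", "bias_seed", "supersampling")}
        d["pose"] = self.pose.to_dict()

        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(type(o))

        return json.dumps(d, indent=2, default=default)

    @staticmethod
    def from_json(s: str) -> "PhantomSpec":
        d = json.loads(s)
        pose = RigidTransform.from_dict(d.pop("pose"))

        def tup(x):
            return tuple(tup(v) for v in x) if isinstance(x, list) else x

        return PhantomSpec(pose=pose, **{k: tup(v) for k, v in d.items()})


@dataclass
class GroundTruth:
    """Rasterized label map plus the analytic volumes it approximates."""

    label_map: VolumeGrid  # categorical, codes BG..LES
    fractions: dict  # class code -> VolumeGrid of partial-volume fractions
    pv_ml: float
    gm_ml: float
    wm_ml: float
    lesion_ml: float
    true_pbvc_pv: float | None = None
    true_pbvc_gm: float | None = None

    def voxel_ml(self, cls: int) -> float:
        """Supersampled voxel-count volume of one class, in ml."""
        return float(self.fractions[cls].data.sum()) * self.label_map.voxel_volume_ml

    @property
    def brain_mask(self) -> VolumeGrid:
        """Parenchyma + all CSF (everything inside the skull boundary)."""
        return self.label_map.with_data(self.label_map.data != BG)

    @property
    def parenchyma_mask(self) -> VolumeGrid:
        lab = self.label_map.data
        return self.label_map.with_data(
            (lab == GM) | (lab == WM) | (lab == LES)
        )


# ---------------------------------------------------------------------------
# Rasterization


def _classify_points(spec: PhantomSpec, pts: np.ndarray) -> np.ndarray:
    """Class code of each world-mm point (phantom coordinates)."""
    lab = np.zeros(pts.shape[0], dtype=np.uint8)
    sk = np.asarray(spec.skull_radii_mm, dtype=float)
    br = np.asarray(spec.brain_radii_mm, dtype=float)
    inner = spec.inner_radii_mm
    in_skull = np.sum((pts / sk) ** 2, axis=1) < 1.0
    lab[in_skull] = CSF
    in_par = np.sum((pts / br) ** 2, axis=1) < 1.0
    lab[in_par] = GM
    if spec.gm_thickness_mm > 0:
        in_wm = np.sum((pts / inner) ** 2, axis=1) < 1.0
    else:
        in_wm = in_par
    lab[in_wm] = WM
    for c, r in spec.ventricles:
        rel = (pts - np.asarray(c, dtype=float)) / np.asarray(r, dtype=float)
        lab[in_wm & (np.sum(rel**2, axis=1) < 1.0)] = VENT
    for c, r in spec.lesion_seeds:
        d2 = np.sum((pts - np.asarray(c, dtype=float)) ** 2, axis=1)
        lab[in_wm & (d2 < r * r)] = LES
    return lab


def build_label_map(spec: PhantomSpec, channel: str = "t1") -> GroundTruth:
    """Rasterize the phantom geometry with supersampled partial volumes.

    Each voxel is sampled on a ``supersampling``:sup:`3` subgrid; the
    resulting per-class fractions capture partial-volume effects at class
    boundaries, and the hard label map takes the majority class.
    """
    spec.validate()
    geo = spec.grid_geometry(channel)
    S = int(spec.supersampling)
    shape = geo.shape
    counts = {c: np.zeros(shape, dtype=np.float32) for c in CLASS_NAMES}
    idx = np.stack(
        np.meshgrid(*(np.arange(n, dtype=np.float32) for n in shape),
                    indexing="ij"), axis=-1)
    offsets = (np.arange(S) + 0.5) / S - 0.5
    inv_pose = spec.pose.inverse()
    identity_pose = np.allclose(spec.pose.homogeneous(), np.eye(4))
    for ox in offsets:
        for oy in offsets:
            for oz in offsets:
                sub = idx + np.array([ox, oy, oz], dtype=np.float32)
                pts = geo.voxel_to_world(sub.reshape(-1, 3))
                if not identity_pose:
                    pts = inv_pose.apply(pts)
                lab = _classify_points(spec, pts).reshape(shape)
                for c in counts:
                    counts[c] += lab == c
    total = float(S**3)
    fractions = {c: geo.with_data(counts[c] / total) for c in counts}
    stacked = np.stack([counts[c] for c in sorted(counts)], axis=0)
    hard = np.argmax(stacked, axis=0).astype(np.uint8)
    return GroundTruth(
        label_map=geo.with_data(hard),
        fractions=fractions,
        pv_ml=spec.pv_ml,
        gm_ml=spec.gm_ml,
        wm_ml=spec.wm_ml,
        lesion_ml=spec.lesion_ml,
    )


# ---------------------------------------------------------------------------
# Atrophy


def true_pbvc(spec_a: PhantomSpec, spec_b: PhantomSpec) -> tuple:
    """Exact (PV, GM) percentage volume change from a to b."""
    pv = 100.0 * (spec_b.pv_ml - spec_a.pv_ml) / spec_a.pv_ml
    gm = (100.0 * (spec_b.gm_ml - spec_a.gm_ml) / spec_a.gm_ml
          if spec_a.gm_ml > 0 else 0.0)
    return pv, gm


def apply_atrophy(spec: PhantomSpec, atrophy_pct: float,
                  gm_atrophy_pct: float = None) -> PhantomSpec:
    """Return a new spec whose PV changed by exactly ``atrophy_pct``.

    The parenchyma semi-axes are scaled uniformly; the skull boundary,
    ventricles and lesions stay fixed, so lost parenchyma is replaced by
    CSF.  The GM ribbon thickness is re-solved so the GM volume changes by
    exactly ``gm_atrophy_pct`` (defaults to ``atrophy_pct``).
    """
    if abs(atrophy_pct) > 5.0:
        raise PhantomConfigError("atrophy_pct must lie in [-5, 5]")
    if gm_atrophy_pct is None:
        gm_atrophy_pct = atrophy_pct
    br = np.asarray(spec.brain_radii_mm, dtype=float)
    v_outer = _ellipsoid_volume(br)
    v_vent = spec.ventricle_ml * 1000.0
    pv = v_outer - v_vent
    # scale c so that c^3 * V_outer - V_vent = (1 + a/100) * PV
    c = (((1.0 + atrophy_pct / 100.0) * pv + v_vent) / v_outer) ** (1.0 / 3.0)
    new_br = br * c
    gm_target = spec.gm_ml * 1000.0 * (1.0 + gm_atrophy_pct / 100.0)

    def gm_vol(t):
        return _ellipsoid_volume(new_br) - _ellipsoid_volume(new_br - t)

    if spec.gm_thickness_mm == 0 and gm_atrophy_pct == 0:
        new_t = 0.0
    else:
        hi = float(new_br.min()) * (1 - 1e-9)
        if not gm_vol(1e-12) <= gm_target <= gm_vol(hi):
            raise PhantomConfigError(
                "requested GM change leaves no valid ribbon thickness"
            )
        new_t = brentq(lambda t: gm_vol(t) - gm_target, 1e-12, hi, xtol=1e-12)
    return replace(
        spec,
        brain_radii_mm=tuple(new_br),
        gm_thickness_mm=float(new_t),
        atrophy_pct=float(spec.atrophy_pct + atrophy_pct),
        gm_atrophy_pct=float(spec.gm_atrophy_pct + gm_atrophy_pct),
    )


# ---------------------------------------------------------------------------
# Contrast rendering


def _bias_field(geo: VolumeGrid, amplitude: float, rng) -> np.ndarray:
    """Smooth multiplicative field: product of per-axis quadratics."""
    coeffs = rng.uniform(-1.0, 1.0, size=(3, 2))
    if amplitude == 0:
        return np.ones(geo.shape)
    field_ = np.ones(geo.shape)
    for ax in range(3):
        n = geo.shape[ax]
        xi = np.linspace(-1.0, 1.0, n)
        poly = 1.0 + amplitude * (coeffs[ax, 0] * xi + coeffs[ax, 1] * xi**2) / 2.0
        sh = [1, 1, 1]
        sh[ax] = n
        field_ = field_ * poly.reshape(sh)
    return field_ / field_.mean()


def render_contrast(truth: GroundTruth, spec: PhantomSpec,
                    channel: str = "t1", rng=None) -> VolumeGrid:
    """Render one contrast channel from partial-volume class fractions.

    Intensity is the fraction-weighted mix of the preset's class means,
    multiplied by a low-order bias field and corrupted by additive Gaussian
    noise of sd ``noise_sigma`` x WM mean; values are clipped non-negative.
    """
    if spec.contrast_preset not in PRESET_CONTRAST:
        raise PhantomConfigError(
            f"unknown contrast preset {spec.contrast_preset!r}; "
            f"valid presets: {sorted(PRESET_CONTRAST)}"
        )
    table = PRESET_CONTRAST[spec.contrast_preset][channel]
    geo = truth.label_map
    img = np.zeros(geo.shape, dtype=float)
    for c, mu in table.items():
        if mu != 0.0:
            img += truth.fractions[c].data * mu
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    bias_seed = (spec.bias_seed if spec.bias_seed is not None
                 else spec.rng_seed)
    img *= _bias_field(geo, spec.bias_amplitude,
                       np.random.default_rng(bias_seed))
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma * table[WM], size=geo.shape)
    return geo.with_data(np.clip(img, 0.0, None))


def render_session(spec: PhantomSpec):
    """Rasterize and render one session: (t1, flair, truth_on_t1_grid).

    T1 and FLAIR are rendered on their own acquisition grids (per preset)
    but share the phantom pose; noise is drawn from a single seeded stream
    so identical (spec, seed) yields bit-identical volumes.
    """
    rng = np.random.default_rng(spec.rng_seed)
    truth_t1 = build_label_map(spec, "t1")
    t1 = render_contrast(truth_t1, spec, "t1", rng)
    truth_fl = build_label_map(spec, "flair")
    flair = render_contrast(truth_fl, spec, "flair", rng)
    return t1, flair, truth_t1


# ---------------------------------------------------------------------------
# Session pairs


@dataclass
class SessionPair:
    """Two rendered sessions of one subject plus everything held back.

    ``pose_b`` is the rigid repositioning applied to the phantom before
    rasterizing session b (identity when ``reposition`` was false); it is
    recorded so registration accuracy can be scored against it.
    """

    t1_a: VolumeGrid
    flair_a: VolumeGrid
    truth_a: GroundTruth
    t1_b: VolumeGrid
    flair_b: VolumeGrid
    truth_b: GroundTruth
    pose_b: RigidTransform
    true_pbvc_pv: float
    true_pbvc_gm: float


def simulate_session_pair(spec_a: PhantomSpec, spec_b: PhantomSpec,
                          reposition: bool = False,
                          pose_seed: int | None = None) -> SessionPair:
    """Simulate a scan-rescan pair.

    With ``reposition`` false the second session reuses the first session's
    pose (the intra-scanner design, where the subject is not removed from
    the scanner); with ``reposition`` true a small seeded rigid transform
    (<= 5 deg, <= 5 mm per axis) is applied before rasterization and
    recorded in the output (the inter-scanner design).
    """
    if reposition:
        pose = reposition_pose(
            pose_seed if pose_seed is not None else spec_b.rng_seed + 777)
        spec_b = replace(spec_b, pose=spec_a.pose.compose(pose))
    else:
        pose = RigidTransform()
        spec_b = replace(spec_b, pose=spec_a.pose)
    t1_a, flair_a, truth_a = render_session(spec_a)
    t1_b, flair_b, truth_b = render_session(spec_b)
    pv, gm = true_pbvc(spec_a, spec_b)
    truth_a.true_pbvc_pv = truth_b.true_pbvc_pv = pv
    truth_a.true_pbvc_gm = truth_b.true_pbvc_gm = gm
    return SessionPair(t1_a, flair_a, truth_a, t1_b, flair_b, truth_b,
                       pose, pv, gm)


# ---------------------------------------------------------------------------
# Study-scale presets


def preset_spec(preset: str = "T15", scale: float = 3.0,
                rng_seed: int = 0, **overrides) -> PhantomSpec:
    """Default MS-like spec on a scanner preset's grid.

    ``scale`` multiplies the acquisition voxel size (the analysis grids used
    throughout the package are coarsened versions of the acquisition
    geometries; 1.0 reproduces them exactly).  Grid shapes are chosen to
    cover the default head with margin.
    """
    if preset not in PRESET_SPACING:
        raise PhantomConfigError(
            f"unknown contrast preset {preset!r}; valid presets: "
            f"{sorted(PRESET_SPACING)}")
    fov = np.array([152.0, 184.0, 120.0])  # default head + margin
    out = {}
    for ch in ("t1", "flair"):
        spacing = np.asarray(PRESET_SPACING[preset][ch]) * scale
        shape = tuple(int(np.ceil(f / s)) for f, s in zip(fov, spacing))
        out[ch] = (shape, tuple(spacing))
    lesions = (((22.0, 18.0, 10.0), 8.0),
               ((-29.0, -26.0, 12.0), 9.0),
               ((5.0, -38.0, -8.0), 10.0))
    kw = dict(
        grid_shape=out["t1"][0], voxel_spacing_mm=out["t1"][1],
        flair_grid_shape=out["flair"][0], flair_spacing_mm=out["flair"][1],
        contrast_preset=preset, lesion_seeds=lesions, rng_seed=rng_seed,
    )
    kw.update(overrides)
    return PhantomSpec(**kw)


def to_preset_grid(spec: PhantomSpec, preset: str,
                   scale: float = 3.0) -> PhantomSpec:
    """Same subject geometry re-gridded onto another scanner preset."""
    ref = preset_spec(preset, scale)
    return replace(
        spec,
        grid_shape=ref.grid_shape, voxel_spacing_mm=ref.voxel_spacing_mm,
        flair_grid_shape=ref.flair_grid_shape,
        flair_spacing_mm=ref.flair_spacing_mm,
        contrast_preset=preset)


def reposition_pose(seed: int) -> RigidTransform:
    """Small seeded rigid repositioning (<= 5 deg, <= 5 mm per axis)."""
    rng = np.random.default_rng(seed)
    return RigidTransform(
        rotation=rng.uniform(-np.deg2rad(5), np.deg2rad(5), 3),
        translation_mm=rng.uniform(-5.0, 5.0, 3))


def cohort_specs(n: int, seed: int = 0, preset: str = "T15",
                 scale: float = 3.0, lesions: bool = True,
                 noise_sigma: float = 0.05,
                 bias_amplitude: float = 0.1) -> list:
    """n subject geometries with seeded anatomical variability.

    Brain semi-axes jitter by +-4%, ventricles by +-15%, lesion radii by
    +-20%; each subject gets its own rng_seed stream.
    """
    rng = np.random.default_rng(seed)
    base = preset_spec(preset, scale)
    specs = []
    for i in range(n):
        br = np.asarray(base.brain_radii_mm) * rng.uniform(0.96, 1.04, 3)
        vent = tuple(
            (c, tuple(np.asarray(r) * rng.uniform(0.85, 1.15)))
            for c, r in base.ventricles)
        if lesions:
            les = tuple((c, float(r * rng.uniform(0.8, 1.15)))
                        for c, r in base.lesion_seeds)
        else:
            les = ()
        specs.append(replace(
            base,
            brain_radii_mm=tuple(br),
            skull_radii_mm=tuple(br + 4.0),
            ventricles=vent,
            lesion_seeds=les,
            noise_sigma=noise_sigma,
            bias_amplitude=bias_amplitude,
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return specs
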