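"""Synthetic phantom, beam and MR-scanner models.

Generates every input the analysis pipeline needs: material labels for a
breast-shaped gel phantom with a water-filled inner dome and a metal
injection-port disk, an analytic two-tangential-beam planned dose, the
"delivered" dose perturbed by near-wall polymerization inhibition and by
the port's beam shadow, noisy multi-echo magnitude volumes, calibration
vials, and a uniform reference scan for inhomogeneity correction.

Geometry is a hemiellipsoid shell standing on the plane z = 0 (the
phantom base); the beam axis is x and the MRI slice axis is y.  The
metal port is a disk attached from the water side to the inner-dome
surface, offset to +y so that a mirror-matched port-free slice exists
at -y.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (
    GEL,
    METAL,
    OUTSIDE,
    WALL,
    WATER,
    DoseVolume,
    EchoSeriesVolume,
    Grid,
    LabelVolume,
)

log = logging.getLogger(__name__)

__all__ = [
    "PhantomSpec",
    "BeamModel",
    "PerturbationModel",
    "ScannerModel",
    "CalibrationTruth",
    "VialEchoSet",
    "make_phantom_labels",
    "planned_dose",
    "delivered_dose",
    "simulate_echoes",
    "simulate_calibration_vials",
    "simulate_reference",
    "make_bias_field",
    "port_shadow_weight",
    "wall_deficit_field",
    "noise_sigma_for_uncertainty",
    "predicted_r2_sigma",
    "DEFAULT_NOISE_SIGMA",
]

# Relative proton-signal amplitude of each material at TE -> 0.  Glass and
# metal give essentially no MR signal; the water cavity is slightly darker
# than gel because of the long TR saturation difference.
S0_FACTORS = {GEL: 1.0, WATER: 0.9, WALL: 0.02, METAL: 0.0, OUTSIDE: 0.0}


def _as_tuple3(v) -> tuple[float, float, float]:
    t = tuple(float(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected a 3-vector, got {v!r}")
    return t


@dataclass
class PhantomSpec:
    """Geometry of the breast-shaped gel phantom.

    ``outer_shell`` and ``inner_dome`` are the semi-axes (mm) of the
    hemiellipsoid surfaces bounding the gel from outside and inside; the
    glass wall of ``wall_thickness_mm`` lies just beyond each surface
    (outward for the shell, inward for the dome) plus a base slab under
    z = 0.  Defaults reproduce a 0.282 L gel fill at the acquisition
    resolution of 144 x 144 in-plane pixels over a 140 mm field of view
    with 2 mm slices.
    """

    grid_shape: tuple[int, int, int] = (144, 72, 68)
    spacing_mm: tuple[float, float, float] = (140.0 / 144.0, 2.0, 140.0 / 144.0)
    outer_shell: tuple[float, float, float] = (66.0, 66.0, 55.0)
    inner_dome: tuple[float, float, float] = (48.0, 48.0, 45.0)
    wall_thickness_mm: float = 2.5
    port_center_mm: tuple[float, float, float] = (0.0, 24.0, 34.16)
    port_diameter_mm: float = 17.9
    port_thickness_mm: float = 3.9
    gel_volume_target_L: float = 0.282
    z_min_mm: float = -6.0

    def __post_init__(self):
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.spacing_mm = _as_tuple3(self.spacing_mm)
        self.outer_shell = _as_tuple3(self.outer_shell)
        self.inner_dome = _as_tuple3(self.inner_dome)
        self.port_center_mm = _as_tuple3(self.port_center_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        if any(o <= i for o, i in zip(self.outer_shell, self.inner_dome)):
            raise ValueError("outer shell must enclose the inner dome")
        if self.wall_thickness_mm < 0 or self.port_diameter_mm < 0 or self.port_thickness_mm < 0:
            raise ValueError("thicknesses and diameters must be non-negative")
        if self.port_diameter_mm > 0:
            # The port must sit on/inside the inner-dome surface region.
            px, py, pz = self.port_center_mm
            a, b, c = self.inner_dome
            f = (px / a) ** 2 + (py / b) ** 2 + (pz / c) ** 2
            if f > 1.0 + 1e-9 or pz < 0:
                raise ValueError(
                    "port centre must lie within the inner-dome surface region, "
                    f"got {self.port_center_mm} (ellipsoid value {f:.3f})"
                )

    @property
    def grid(self) -> Grid:
        nx, ny, nz = self.grid_shape
        sx, sy, sz = self.spacing_mm
        origin = (-(nx - 1) / 2.0 * sx, -(ny - 1) / 2.0 * sy, self.z_min_mm)
        return Grid(self.grid_shape, self.spacing_mm, origin)

    def shell_volume_L(self) -> float:
        """Closed-form hemiellipsoid-shell gel volume (L)."""
        a, b, c = self.outer_shell
        ai, bi, ci = self.inner_dome
        return (2.0 * math.pi / 3.0) * (a * b * c - ai * bi * ci) / 1e6

    def inner_dome_surface_z(self, x_mm: float, y_mm: float) -> float:
        """Height of the gel-side inner-dome surface above (x, y)."""
        a, b, c = self.inner_dome
        s = 1.0 - (x_mm / a) ** 2 - (y_mm / b) ** 2
        if s < 0:
            raise ValueError(f"({x_mm}, {y_mm}) lies outside the inner-dome footprint")
        return c * math.sqrt(s)


@dataclass
class BeamModel:
    """Analytic surrogate for two opposed 6 MV tangential wedged beams.

    Per-beam dose is prescription/2 x buildup x exp(-mu_eff * depth) x a
    linear wedge gradient along z x the rectangular field aperture;
    the summed dose is renormalized to ``prescription_Gy`` at the
    isocenter.  ``buildup_mm = 0`` disables the entrance buildup and
    reduces the depth dose to a pure exponential.
    """

    gantry_angles_deg: tuple[float, ...] = (90.0, 270.0)
    field_size_cm: tuple[float, float] = (19.0, 20.0)
    wedge_angle_deg: float = 15.0
    prescription_Gy: float = 3.0
    mu_eff_per_cm: float = 0.046
    buildup_mm: float = 4.0
    wedge_scale_mm: float = 100.0
    isocenter_mm: tuple[float, float, float] = (0.0, 0.0, 38.0)

    def __post_init__(self):
        self.gantry_angles_deg = tuple(float(a) for a in self.gantry_angles_deg)
        self.isocenter_mm = _as_tuple3(self.isocenter_mm)
        if self.prescription_Gy <= 0:
            raise ValueError("prescription must be positive")
        if len(self.gantry_angles_deg) == 2:
            d = abs(self.gantry_angles_deg[0] - self.gantry_angles_deg[1]) % 360.0
            if not math.isclose(d, 180.0, abs_tol=1e-6):
                raise ValueError("the two beams must be opposed (angles differing by 180 deg)")
        elif len(self.gantry_angles_deg) != 1:
            raise ValueError("provide one beam or two opposed beams")
        for ang in self.gantry_angles_deg:
            if not math.isclose(math.cos(math.radians(ang)), 0.0, abs_tol=1e-9):
                raise ValueError("only lateral beams (gantry 90/270) are supported")


@dataclass
class PerturbationModel:
    """Deviations of the delivered dose from the plan, on gel voxels.

    Near-wall oxygen inhibition suppresses polymerization by
    ``wall_deficit_frac`` within ``wall_plateau_mm`` of any glass wall,
    decaying exponentially with length ``wall_range_mm`` beyond it.
    Inside the port's beam shadow the total deficit deepens to
    ``shadow_deficit_frac``; the shadow edge is blurred by a Gaussian of
    ``shadow_softening_mm``.
    """

    wall_deficit_frac: float = 0.045
    wall_range_mm: float = 1.0
    wall_plateau_mm: float = 4.0
    shadow_deficit_frac: float = 0.098
    shadow_softening_mm: float = 0.5

    def __post_init__(self):
        if not (0.0 <= self.wall_deficit_frac < 1.0 and 0.0 <= self.shadow_deficit_frac < 1.0):
            raise ValueError("deficit fractions must lie in [0, 1)")
        if self.shadow_deficit_frac < self.wall_deficit_frac:
            raise ValueError("shadow deficit must be at least the wall deficit")
        if self.wall_range_mm <= 0 or self.wall_plateau_mm < 0 or self.shadow_softening_mm < 0:
            raise ValueError("lengths must be non-negative (range strictly positive)")


@dataclass
class CalibrationTruth:
    """Ground-truth linear R2(D) response of the gel batch."""

    slope: float = 3.0  # s^-1 per Gy
    intercept: float = 3.0  # s^-1 at 0 Gy
    vial_doses_Gy: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5)

    def __post_init__(self):
        self.vial_doses_Gy = tuple(float(d) for d in self.vial_doses_Gy)
        if self.slope <= 0:
            raise ValueError("R2 must increase with dose (slope > 0)")
        if any(d < 0 for d in self.vial_doses_Gy):
            raise ValueError("vial doses must be non-negative")

    def r2_of_dose(self, dose_Gy):
        return self.intercept + self.slope * np.asarray(dose_Gy, dtype=float)


# Frozen so the default scanner reproduces a 3.0% mean calibration dose
# uncertainty under the default CalibrationTruth; recomputable with
# noise_sigma_for_uncertainty().
DEFAULT_NOISE_SIGMA = 8.004405764907489


@dataclass
class ScannerModel:
    """Multi-spin-echo acquisition model with Rician magnitude noise."""

    echo_times_ms: tuple[float, ...] = tuple(35.0 * i for i in range(1, 9))
    s0: float = 1000.0
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    bias_amplitude: float = 0.03
    bias_mode: str = "s0"  # "s0" | "r2_mult" | "none"
    n_bias_blobs: int = 4
    water_r2_s: float = 0.4
    seed: int = 0

    def __post_init__(self):
        self.echo_times_ms = tuple(float(t) for t in self.echo_times_ms)
        te = np.asarray(self.echo_times_ms)
        if te.size < 3 or te[0] <= 0 or np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be >= 3, positive, strictly increasing")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.bias_mode not in ("s0", "r2_mult", "none"):
            raise ValueError(f"unknown bias_mode {self.bias_mode!r}")

    def rng(self, rng: np.random.Generator | None = None) -> np.random.Generator:
        return rng if rng is not None else np.random.default_rng(self.seed)


@dataclass
class VialEchoSet:
    """Echo data for a set of calibration vials (one small patch each)."""

    doses_Gy: np.ndarray
    data: list  # per-vial 4D arrays (nx, ny, nz, n_echo)
    masks: list  # per-vial boolean vial masks
    echo_times_ms: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.doses_Gy = np.asarray(self.doses_Gy, dtype=float)
        self.echo_times_ms = np.asarray(self.echo_times_ms, dtype=float)
        if len(self.data) != self.doses_Gy.size or len(self.masks) != self.doses_Gy.size:
            raise ValueError("one data block and mask per vial dose required")

    @property
    def n_vials(self) -> int:
        return int(self.doses_Gy.size)

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = []
        for vid, (dose, block, mask) in enumerate(zip(self.doses_Gy, self.data, self.masks)):
            sig = block[mask]  # (n_voxels, n_echo)
            for vox in range(sig.shape[0]):
                for te, s in zip(self.echo_times_ms, sig[vox]):
                    rows.append((vid, dose, vox, te, s))
        pd.DataFrame(
            rows, columns=["vial_id", "dose_Gy", "voxel_index", "TE_ms", "signal"]
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "VialEchoSet":
        import pandas as pd

        df = pd.read_csv(path)
        doses, data, masks = [], [], []
        te = np.sort(df["TE_ms"].unique())
        for vid, grp in df.groupby("vial_id"):
            doses.append(grp["dose_Gy"].iloc[0])
            piv = grp.pivot_table(index="voxel_index", columns="TE_ms", values="signal")
            block = piv.to_numpy()[:, None, None, :]  # degenerate (n, 1, 1, ne) geometry
            data.append(block)
            masks.append(np.ones(block.shape[:3], dtype=bool))
        return cls(np.asarray(doses), data, masks, te)


# ---------------------------------------------------------------------------
# Geometry

def make_phantom_labels(spec: PhantomSpec) -> LabelVolume:
    """Voxelize the phantom: partition the grid into the five materials."""
    grid = spec.grid
    X, Y, Z = grid.meshgrid_mm()
    t = spec.wall_thickness_mm

    def ellips(semi, margin=0.0):
        a, b, c = (s + margin for s in semi)
        return (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2

    above = Z >= 0
    in_glass_outer = (ellips(spec.outer_shell, t) <= 1.0) & above
    in_gel_outer = (ellips(spec.outer_shell) <= 1.0) & above
    in_dome = (ellips(spec.inner_dome) <= 1.0) & above
    in_water = (ellips(spec.inner_dome, -t) <= 1.0) & above

    labels = np.full(grid.shape, OUTSIDE, dtype=np.uint8)
    labels[in_glass_outer] = WALL
    labels[in_gel_outer] = GEL
    labels[in_dome] = WALL
    labels[in_water] = WATER
    # Base slab sealing the shell at z = 0.
    a, b, _ = spec.outer_shell
    base = (Z >= -t) & (Z < 0) & ((X / (a + t)) ** 2 + (Y / (b + t)) ** 2 <= 1.0)
    labels[np.broadcast_to(base, grid.shape)] = WALL

    if spec.port_diameter_mm > 0 and spec.port_thickness_mm > 0:
        px, py, pz = spec.port_center_mm
        r = spec.port_diameter_mm / 2.0
        ht = spec.port_thickness_mm / 2.0
        lo = np.array([px - r, py - r, pz - ht])
        hi = np.array([px + r, py + r, pz + ht])
        gmin = np.asarray(grid.origin_mm)
        gmax = gmin + (np.asarray(grid.shape) - 1) * np.asarray(grid.spacing_mm)
        for ax, name in enumerate("xyz"):
            if lo[ax] < gmin[ax] or hi[ax] > gmax[ax]:
                raise ValueError(
                    f"port extends outside the grid along {name}: "
                    f"[{lo[ax]:.1f}, {hi[ax]:.1f}] mm vs grid [{gmin[ax]:.1f}, {gmax[ax]:.1f}] mm"
                )
        disk = ((X - px) ** 2 + (Y - py) ** 2 <= r**2) & (np.abs(Z - pz) <= ht)
        # Attach from the water side: clip to the inner-dome region.
        labels[disk & in_dome] = METAL

    return LabelVolume(labels, grid)


# ---------------------------------------------------------------------------
# Dose

def _beam_enters_from_positive_x(gantry_deg: float) -> bool:
    # Gantry 90 deg: source on the +x side, beam travels towards -x.
    return math.sin(math.radians(gantry_deg)) > 0


def planned_dose(
    spec: PhantomSpec, beams: BeamModel, labels: LabelVolume | None = None
) -> DoseVolume:
    """Analytic planned (TPS-surrogate) dose on the phantom grid.

    Depth dose along each lateral beam is buildup x exponential
    attenuation through phantom material, modulated by a linear wedge
    gradient along z and the rectangular field aperture, summed over
    beams and renormalized to the prescription at the isocenter.
    """
    if labels is None:
        labels = make_phantom_labels(spec)
    grid = spec.grid
    if not grid.contains_point(beams.isocenter_mm):
        raise ValueError(f"isocenter {beams.isocenter_mm} lies outside the grid")

    material = labels.labels != OUTSIDE
    sx = grid.spacing_mm[0]
    X, Y, Z = grid.meshgrid_mm()
    ix, iy, iz = beams.isocenter_mm

    half_y = beams.field_size_cm[0] * 10.0 / 2.0
    half_z = beams.field_size_cm[1] * 10.0 / 2.0
    aperture = (np.abs(Y - iy) <= half_y) & (np.abs(Z - iz) <= half_z)
    if half_y <= 0 or half_z <= 0:
        raise ValueError("field aperture must have positive extent")

    wedge = 1.0 + math.tan(math.radians(beams.wedge_angle_deg)) * (iz - Z) / beams.wedge_scale_mm
    wedge = np.broadcast_to(wedge, grid.shape)
    if np.any(wedge[material] <= 0):
        raise ValueError("wedge gradient produces non-positive dose inside the phantom")

    mu_mm = beams.mu_eff_per_cm / 10.0
    total = np.zeros(grid.shape)
    per_beam = beams.prescription_Gy / len(beams.gantry_angles_deg)
    for ang in beams.gantry_angles_deg:
        if _beam_enters_from_positive_x(ang):
            depth = (np.cumsum(material[::-1], axis=0)[::-1] - 0.5 * material) * sx
        else:
            depth = (np.cumsum(material, axis=0) - 0.5 * material) * sx
        depth = np.maximum(depth, 0.0)
        pdd = np.exp(-mu_mm * depth)
        if beams.buildup_mm > 0:
            pdd *= 1.0 - np.exp(-depth / beams.buildup_mm)
        total += per_beam * pdd * wedge * aperture * material

    iso_val = _trilinear_at_point(total, grid, beams.isocenter_mm)
    if not np.isfinite(iso_val) or iso_val <= 0:
        raise ValueError("isocenter receives no dose (outside phantom or aperture)")
    total *= beams.prescription_Gy / iso_val
    return DoseVolume(total, grid, kind="planned", mask=material)


def _trilinear_at_point(data: np.ndarray, grid: Grid, point_mm) -> float:
    idx = grid.world_to_index(point_mm)[0]
    return float(ndimage.map_coordinates(data, idx[:, None], order=1, mode="nearest")[0])


def wall_deficit_field(
    labels: LabelVolume, perturb: PerturbationModel
) -> np.ndarray:
    """Fractional near-wall polymerization deficit on the full grid."""
    wallish = (labels.labels == WALL) | (labels.labels == OUTSIDE)
    dist = ndimage.distance_transform_edt(~wallish, sampling=labels.grid.spacing_mm)
    decay = np.exp(-np.maximum(dist - perturb.wall_plateau_mm, 0.0) / perturb.wall_range_mm)
    return perturb.wall_deficit_frac * decay


def port_shadow_weight(labels: LabelVolume, perturb: PerturbationModel) -> np.ndarray:
    """Edge-softened indicator of the port's beam shadow (both tangents).

    A voxel is shadowed when its ray along the beam axis (x) intersects
    the metal disk; with two opposed beams this is the full x-column of
    every (y, z) blocked by the port.  The 2D (y, z) indicator is
    blurred by ``shadow_softening_mm`` and broadcast along x.
    """
    metal = labels.labels == METAL
    if not metal.any():
        return np.zeros(labels.grid.shape)
    proj = metal.any(axis=0).astype(float)
    _, sy, sz = labels.grid.spacing_mm
    soft = perturb.shadow_softening_mm
    if soft > 0:
        proj = ndimage.gaussian_filter(proj, sigma=(soft / sy, soft / sz))
    return np.broadcast_to(proj[None, :, :], labels.grid.shape).copy()


def delivered_dose(
    planned: DoseVolume,
    labels: LabelVolume,
    beams: BeamModel,
    perturb: PerturbationModel,
) -> DoseVolume:
    """Ground-truth delivered dose: the plan minus wall and shadow deficits.

    On gel voxels ``delivered = planned * (1 - wall) * (1 - extra)``
    where ``extra = (shadow - wall_frac) / (1 - wall_frac)`` inside the
    softened shadow, so that the total deficit deep in the shadow (where
    the wall term is at its full value) equals ``shadow_deficit_frac``.
    """
    if not planned.grid.same_as(labels.grid):
        raise ValueError("planned dose and labels must share the same grid")
    gel = labels.labels == GEL
    wall = wall_deficit_field(labels, perturb)

    wf, sf = perturb.wall_deficit_frac, perturb.shadow_deficit_frac
    extra_frac = (sf - wf) / (1.0 - wf)
    shadow = port_shadow_weight(labels, perturb)

    dose = planned.dose.copy()
    dose[gel] *= (1.0 - wall[gel]) * (1.0 - extra_frac * shadow[gel])
    return DoseVolume(dose, planned.grid, kind="measured", mask=planned.mask)


# ---------------------------------------------------------------------------
# MR signal simulation

def make_bias_field(
    grid: Grid,
    scanner: ScannerModel,
    rng: np.random.Generator | None = None,
    norm_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Smooth multiplicative scanner bias field (sum of Gaussian blobs).

    Normalized to unit mean over ``norm_mask`` (whole grid when absent)
    and guaranteed positive everywhere.
    """
    rng = scanner.rng(rng)
    if scanner.bias_amplitude == 0 or scanner.n_bias_blobs == 0:
        return np.ones(grid.shape)
    X, Y, Z = grid.meshgrid_mm()
    lo = np.asarray(grid.origin_mm)
    hi = lo + (np.asarray(grid.shape) - 1) * np.asarray(grid.spacing_mm)
    fld = np.ones(grid.shape)
    for _ in range(scanner.n_bias_blobs):
        ctr = rng.uniform(lo, hi)
        width = rng.uniform(30.0, 80.0)
        amp = rng.uniform(-1.0, 1.0) * scanner.bias_amplitude
        r2 = (X - ctr[0]) ** 2 + (Y - ctr[1]) ** 2 + (Z - ctr[2]) ** 2
        fld = fld + amp * np.exp(-r2 / (2.0 * width**2))
    if norm_mask is not None and norm_mask.any():
        fld /= fld[norm_mask].mean()
    else:
        fld /= fld.mean()
    if np.any(fld <= 0):
        raise ValueError("bias field must be positive everywhere")
    return fld


def _rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return signal
    n1 = rng.normal(0.0, sigma, size=signal.shape)
    n2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


def _echo_decay(
    r2_map: np.ndarray, s0_map: np.ndarray, echo_times_ms: np.ndarray
) -> np.ndarray:
    te_s = np.asarray(echo_times_ms, dtype=float) / 1000.0
    return s0_map[..., None] * np.exp(-r2_map[..., None] * te_s)


def simulate_echoes(
    dose: DoseVolume,
    labels: LabelVolume,
    truth: CalibrationTruth,
    scanner: ScannerModel,
    rng: np.random.Generator | None = None,
    bias: np.ndarray | None = None,
) -> EchoSeriesVolume:
    """Multi-echo magnitude volume of the (irradiated) phantom.

    Gel voxels decay at R2 = intercept + slope * dose; the water cavity
    at a slow fixed rate; glass, metal and air give (near-)zero signal.
    Rician noise is applied per echo; the bias field multiplies S0
    (``bias_mode='s0'``) or R2 (``'r2_mult'``).
    """
    if not dose.grid.same_as(labels.grid):
        raise ValueError("dose and labels must share the same grid")
    rng = scanner.rng(rng)
    lab = labels.labels

    r2 = np.zeros(labels.grid.shape)
    gel = lab == GEL
    r2[gel] = truth.r2_of_dose(dose.dose[gel])
    r2[lab == WATER] = scanner.water_r2_s

    s0 = np.zeros(labels.grid.shape)
    for code, f in S0_FACTORS.items():
        s0[lab == code] = f * scanner.s0

    if bias is None:
        bias = make_bias_field(labels.grid, scanner, rng, norm_mask=lab != OUTSIDE)
    if scanner.bias_mode == "s0":
        s0 = s0 * bias
    elif scanner.bias_mode == "r2_mult":
        r2 = r2 * bias

    signal = _echo_decay(r2, s0, np.asarray(scanner.echo_times_ms))
    data = _rician(signal, scanner.noise_sigma, rng)
    return EchoSeriesVolume(data, np.asarray(scanner.echo_times_ms), labels.grid)


def simulate_reference(
    spec: PhantomSpec,
    scanner: ScannerModel,
    uniform_R2: float = 9.0,
    rng: np.random.Generator | None = None,
    bias: np.ndarray | None = None,
) -> EchoSeriesVolume:
    """Scan of the reference vessel: unirradiated gel of uniform true R2.

    The reference is spatially uniform so that, after fitting, any
    spatial structure in its R2 map isolates the scanner bias field.
    """
    if uniform_R2 <= 0:
        raise ValueError("uniform_R2 must be positive")
    rng = scanner.rng(rng)
    grid = spec.grid
    X, Y, Z = grid.meshgrid_mm()
    a, b, c = spec.outer_shell
    t = spec.wall_thickness_mm
    inside = ((X / (a + t)) ** 2 + (Y / (b + t)) ** 2 + (Z / (c + t)) ** 2 <= 1.0) & (Z >= 0)
    inside = np.broadcast_to(inside, grid.shape)

    r2 = np.where(inside, uniform_R2, 0.0)
    s0 = np.where(inside, scanner.s0, 0.0)
    if bias is None:
        bias = make_bias_field(grid, scanner, rng, norm_mask=inside)
    if scanner.bias_mode == "s0":
        s0 = s0 * bias
    elif scanner.bias_mode == "r2_mult":
        r2 = r2 * bias

    signal = _echo_decay(r2, s0, np.asarray(scanner.echo_times_ms))
    data = _rician(signal, scanner.noise_sigma, rng)
    return EchoSeriesVolume(data, np.asarray(scanner.echo_times_ms), grid)


def simulate_calibration_vials(
    truth: CalibrationTruth,
    scanner: ScannerModel,
    voxels_per_vial: int = 2000,
    rng: np.random.Generator | None = None,
) -> VialEchoSet:
    """Echo data for one cylindrical vial per calibration dose.

    Vials are 12 mm diameter cylinders sampled at 1 mm isotropic
    resolution; the cylinder length is chosen to reach approximately
    ``voxels_per_vial`` voxels (vial ROIs are drawn from the central
    section of the physical 75 mm tubes).
    """
    if len(truth.vial_doses_Gy) == 0:
        raise ValueError("vial dose list must not be empty")
    if voxels_per_vial < 1:
        raise ValueError("voxels_per_vial must be >= 1")
    rng = scanner.rng(rng)

    n_xy = 16
    radius = 6.0
    ax = np.arange(n_xy) - (n_xy - 1) / 2.0
    circ = ax[:, None] ** 2 + ax[None, :] ** 2 <= radius**2
    per_slice = int(circ.sum())
    n_z = max(1, int(math.ceil(voxels_per_vial / per_slice)))
    mask = np.broadcast_to(circ[:, :, None], (n_xy, n_xy, n_z)).copy()

    te = np.asarray(scanner.echo_times_ms)
    data, masks = [], []
    for dose in truth.vial_doses_Gy:
        r2 = np.where(mask, truth.r2_of_dose(dose), 0.0)
        s0 = np.where(mask, scanner.s0, 0.0)
        signal = _echo_decay(r2, s0, te)
        data.append(_rician(signal, scanner.noise_sigma, rng))
        masks.append(mask.copy())
    return VialEchoSet(np.asarray(truth.vial_doses_Gy), data, masks, te)


# ---------------------------------------------------------------------------
# Noise-level calibration

def _wls_sensitivity(r2: float, te_s: np.ndarray) -> float:
    """sqrt(sum w (t - tbar_w)^2) of the log-linear fit, per unit S0."""
    w = np.exp(-2.0 * r2 * te_s)
    tbar = np.sum(w * te_s) / np.sum(w)
    return float(np.sqrt(np.sum(w * (te_s - tbar) ** 2)))


def predicted_r2_sigma(
    truth: CalibrationTruth, scanner: ScannerModel, dose_Gy: float
) -> float:
    """Closed-form single-voxel R2 fit standard deviation at a given dose.

    Delta-method variance of the signal-weighted log-linear slope:
    sigma_R2 = sigma / (S0 * sqrt(sum_i w_i (t_i - tbar_w)^2)) with
    w_i = exp(-2 R2 t_i).
    """
    te_s = np.asarray(scanner.echo_times_ms) / 1000.0
    r2 = float(truth.r2_of_dose(dose_Gy))
    return scanner.noise_sigma / (scanner.s0 * _wls_sensitivity(r2, te_s))


def noise_sigma_for_uncertainty(
    truth: CalibrationTruth, scanner: ScannerModel, target_pct: float = 3.0
) -> float:
    """Channel noise sigma giving a target mean calibration dose uncertainty.

    The mean over vials of 100 * sigma_D / D (sigma_D = sigma_R2 / slope)
    is linear in the channel sigma, so the inversion is exact.
    """
    te_s = np.asarray(scanner.echo_times_ms) / 1000.0
    doses = np.asarray(truth.vial_doses_Gy)
    doses = doses[doses > 0]
    if doses.size == 0:
        raise ValueError("need at least one positive vial dose")
    rel_per_sigma = np.mean(
        [
            1.0
            / (scanner.s0 * _wls_sensitivity(float(truth.r2_of_dose(d)), te_s))
            / (truth.slope * d)
            * 100.0
            for d in doses
        ]
    )
    return float(target_pct / rel_per_sigma)
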