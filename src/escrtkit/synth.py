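"""Synthetic scenes with complete ground truth for every pipeline stage.

Three generators emulate the data the analysis operates on:

* :func:`make_edge_scene` — a vesicle membrane edge in projection: a smooth
  diffuse band of density along a curved path, decorated with protein
  "spikes" (short anisotropic Gaussian ridges normal to the path) at a fixed
  arc-length repeat, plus additive white Gaussian noise.  This is the motif
  the membrane-subtraction algorithm is built for: the membrane signal is
  smooth along the edge while the protein signal is periodic.
* :func:`make_tube_scene` — a membrane tube wrapped by a tilted filament
  array seen in projection: two parallel boundary lines separated by the
  tube's outer diameter, with interior striations at an orientation angle
  to the tube axis and a fixed perpendicular spacing.
* :func:`make_tirf_trace` — a sigmoidal fluorescence-vs-time recruitment
  trace from the nucleation-growth simulator, with a monomer-binding
  baseline offset and white Gaussian noise.

Every generator returns its full ground truth (additive decomposition and
planted parameters), so downstream estimators can be tested for parameter
recovery without any external data.  All generators are deterministic for a
fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .edges import EdgePath, build_path
from .io_formats import Micrograph, make_coord_table
from .kinetics import KineticTrace, SimParams, simulate_coverage

__all__ = [
    "SceneSpec",
    "TubeSpec",
    "GroundTruth",
    "make_edge_scene",
    "make_tube_scene",
    "make_tirf_trace",
    "STANDARD_CONTROL_POINTS",
]

_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))  # sigma -> full width at half max

#: control points (A) of the gently curved standard membrane edge
STANDARD_CONTROL_POINTS = (
    (180.0, 1150.0),
    (900.0, 1420.0),
    (1800.0, 1500.0),
    (2680.0, 1220.0),
)


@dataclass
class SceneSpec:
    """Parameters of a synthetic membrane-edge scene.

    Defaults are the "standard scene": 1024x1024 raster at 2.8 A/px, a gently
    curved edge, a 30-A spike repeat and SNR 1 (noise sigma equal to the
    spike amplitude), seed 1.
    """

    shape: tuple[int, int] = (1024, 1024)
    pixel_size_A: float = 2.8
    control_points: tuple = STANDARD_CONTROL_POINTS
    membrane_amplitude: float = 2.0
    membrane_halfwidth_A: float = 60.0
    membrane_blur_A: float = 20.0
    spike_repeat_A: float = 30.0
    spike_length_A: float = 50.0
    spike_width_A: float = 8.0
    spike_amplitude: float = 1.0
    spike_offset_A: float = 60.0   # normal offset of spike centres from the path
    noise_sigma: float = 1.0
    seed: int = 1

    def __post_init__(self) -> None:
        if not self.spike_repeat_A > 2 * self.pixel_size_A:
            raise ValueError("spike repeat must exceed 2 pixels (sampling limit)")
        if min(self.membrane_amplitude, self.spike_amplitude, self.noise_sigma) < 0:
            raise ValueError("amplitudes and noise sigma must be >= 0")
        if not self.membrane_halfwidth_A > 0:
            raise ValueError("membrane band half-width must be positive")


@dataclass
class TubeSpec:
    """Parameters of a synthetic protein-decorated membrane tube (projection).

    Units follow the measurement conventions: tube geometry in nm,
    raster pixel size in A.  The planted outer diameter ``d_out_nm`` is the
    distance between the *outer half-maximum edges* of the two boundary
    lines, matching the outer-edge measurement convention.
    """

    shape: tuple[int, int] = (512, 512)
    pixel_size_A: float = 2.8
    d_out_nm: float = 31.06
    phi_deg: float = 30.0          # filament orientation vs. tube long axis
    s_if_nm: float = 3.13          # interfilament spacing, perpendicular to filaments
    line_width_nm: float = 2.0     # FWHM of the boundary lines
    boundary_amplitude: float = 1.0
    striation_amplitude: float = 0.4
    noise_sigma: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.phi_deg <= 90):
            raise ValueError("orientation angle must lie in [0, 90] degrees")
        if not self.s_if_nm * 10.0 > self.pixel_size_A:
            raise ValueError("interfilament spacing must exceed the pixel size")
        if not self.d_out_nm > 0:
            raise ValueError("outer diameter must be positive")
        interior = self.d_out_nm - 2 * self.line_width_nm
        if self.s_if_nm >= interior:
            raise ValueError("interfilament spacing must be smaller than the tube interior")


@dataclass
class GroundTruth:
    """Per-scene decomposition and planted parameters.

    The emitted micrograph equals ``protein + membrane + noise`` exactly
    (same float32 arithmetic).
    """

    protein: np.ndarray
    membrane: np.ndarray
    noise: np.ndarray
    path: EdgePath | None
    coords: object                     # true CoordinateTable (DataFrame)
    params: dict
    seed: int

    def reconstruct(self) -> np.ndarray:
        return self.protein + self.membrane + self.noise

    def params_json(self) -> str:
        """Planted parameters as a JSON sidecar string."""
        return json.dumps(self.params, indent=2, sort_keys=True)


def _path_distance_map(shape, path: EdgePath, pixel_size_A: float) -> np.ndarray:
    """Distance (A) of every pixel centre to the (densely rasterized) path."""
    rows, cols = shape
    ds = pixel_size_A / 2.0
    n = max(int(path.length_A / ds), 2)
    pts, _ = path.evaluate(np.linspace(0.0, path.length_A, n))
    mask = np.ones(shape, dtype=bool)
    r = np.clip(np.round(pts[:, 1] / pixel_size_A).astype(int), 0, rows - 1)
    c = np.clip(np.round(pts[:, 0] / pixel_size_A).astype(int), 0, cols - 1)
    mask[r, c] = False
    return distance_transform_edt(mask, sampling=pixel_size_A)


def make_edge_scene(spec: SceneSpec) -> tuple[Micrograph, GroundTruth]:
    """Render a membrane-edge scene and its ground truth."""
    rows, cols = spec.shape
    px = spec.pixel_size_A
    path = build_path(np.asarray(spec.control_points, dtype=float), kind="cubic")
    if path.length_A < 2 * spec.spike_repeat_A:
        raise ValueError("edge path shorter than two repeats: no lattice to study")

    # membrane: Gaussian band around the path, then blurred (diffuse, aperiodic)
    if spec.membrane_amplitude > 0:
        dist = _path_distance_map(spec.shape, path, px)
        membrane = spec.membrane_amplitude * np.exp(
            -dist ** 2 / (2.0 * spec.membrane_halfwidth_A ** 2))
        if spec.membrane_blur_A > 0:
            membrane = gaussian_filter(membrane, spec.membrane_blur_A / px)
    else:
        membrane = np.zeros(spec.shape)

    # protein: anisotropic Gaussian ridges normal to the path at s = k * d
    n_spikes = int(math.floor(path.length_A / spec.spike_repeat_A + 1e-9)) + 1
    s_centers = spec.spike_repeat_A * np.arange(n_spikes)
    pts, tans = path.evaluate(s_centers)
    normals = np.stack([-tans[:, 1], tans[:, 0]], axis=1)
    centers = pts + spec.spike_offset_A * normals
    psi = np.degrees(np.arctan2(tans[:, 1], tans[:, 0]))
    psi = np.where(psi <= -180.0, psi + 360.0, psi)

    protein = np.zeros(spec.shape)
    if spec.spike_amplitude > 0:
        sig_u = spec.spike_width_A / _FWHM    # along the tangent
        sig_v = spec.spike_length_A / _FWHM   # along the normal
        reach = 3.5 * max(sig_u, sig_v)
        half = int(math.ceil(reach / px))
        for (cx, cy), (tx, ty) in zip(centers, tans):
            r0 = int(round(cy / px))
            c0 = int(round(cx / px))
            rs = slice(max(r0 - half, 0), min(r0 + half + 1, rows))
            cs = slice(max(c0 - half, 0), min(c0 + half + 1, cols))
            yy, xx = np.mgrid[rs, cs]
            dx = xx * px - cx
            dy = yy * px - cy
            u = dx * tx + dy * ty
            v = -dx * ty + dy * tx
            protein[rs, cs] += spec.spike_amplitude * np.exp(
                -(u ** 2 / (2 * sig_u ** 2) + v ** 2 / (2 * sig_v ** 2)))

    rng = np.random.default_rng(spec.seed)
    noise = (rng.standard_normal(spec.shape) * spec.noise_sigma
             if spec.noise_sigma > 0 else np.zeros(spec.shape))

    protein32 = protein.astype(np.float32)
    membrane32 = membrane.astype(np.float32)
    noise32 = noise.astype(np.float32)
    pixels = protein32 + membrane32 + noise32
    mic = Micrograph(pixels=pixels, pixel_size_A=px, name=f"edge_scene_seed{spec.seed}")
    coords = make_coord_table(centers[:, 0], centers[:, 1], edge_id=0,
                              s_A=s_centers, psi_deg=psi, micrograph_name=mic.name)
    params = {
        "kind": "edge_scene",
        "d_A": spec.spike_repeat_A,
        "spike_offset_A": spec.spike_offset_A,
        "spike_length_A": spec.spike_length_A,
        "spike_width_A": spec.spike_width_A,
        "membrane_halfwidth_A": spec.membrane_halfwidth_A,
        "noise_sigma": spec.noise_sigma,
        "pixel_size_A": px,
    }
    truth = GroundTruth(protein32, membrane32, noise32, path, coords, params, spec.seed)
    return mic, truth


def make_tube_scene(spec: TubeSpec) -> tuple[Micrograph, GroundTruth]:
    """Render a projected filament-wrapped tube and its ground truth."""
    rows, cols = spec.shape
    px_nm = spec.pixel_size_A / 10.0
    y = (np.arange(rows) - (rows - 1) / 2.0) * px_nm   # nm from tube axis
    x = (np.arange(cols) - (cols - 1) / 2.0) * px_nm
    xx, yy = np.meshgrid(x, y)

    # boundary lines: Gaussian ridges whose OUTER half-max edges sit at +/- D/2
    sig_l = spec.line_width_nm / _FWHM
    hwhm = spec.line_width_nm / 2.0
    c = spec.d_out_nm / 2.0 - hwhm                      # line centres
    boundaries = spec.boundary_amplitude * (
        np.exp(-(yy - c) ** 2 / (2 * sig_l ** 2)) +
        np.exp(-(yy + c) ** 2 / (2 * sig_l ** 2)))

    # interior striations at angle phi to the axis, spaced s_if perpendicular
    phi = math.radians(spec.phi_deg)
    q = xx * math.sin(phi) + yy * math.cos(phi)
    interior = np.abs(yy) < (c - spec.line_width_nm)
    striations = np.where(
        interior,
        spec.striation_amplitude * 0.5 * (1.0 + np.cos(2 * math.pi * q / spec.s_if_nm)),
        0.0)

    rng = np.random.default_rng(spec.seed)
    noise = (rng.standard_normal(spec.shape) * spec.noise_sigma
             if spec.noise_sigma > 0 else np.zeros(spec.shape))

    protein32 = (boundaries + striations).astype(np.float32)
    membrane32 = np.zeros(spec.shape, dtype=np.float32)
    noise32 = noise.astype(np.float32)
    pixels = protein32 + membrane32 + noise32
    mic = Micrograph(pixels=pixels, pixel_size_A=spec.pixel_size_A,
                     name=f"tube_scene_seed{spec.seed}")
    axis_path = build_path([[x[0] * 10, (rows - 1) / 2.0 * spec.pixel_size_A],
                            [x[-1] * 10, (rows - 1) / 2.0 * spec.pixel_size_A]],
                           kind="polyline")
    params = {
        "kind": "tube_scene",
        "d_out_nm": spec.d_out_nm,
        "phi_deg": spec.phi_deg,
        "s_if_nm": spec.s_if_nm,
        "line_width_nm": spec.line_width_nm,
        "pixel_size_A": spec.pixel_size_A,
        "membrane_axis_vec": [1.0, 0.0],
        # striations are lines of constant q; their direction vector:
        "filament_axis_vec": [math.cos(phi), -math.sin(phi)],
        "noise_sigma": spec.noise_sigma,
    }
    truth = GroundTruth(protein32, membrane32, noise32, axis_path,
                        make_coord_table([], []), params, spec.seed)
    return mic, truth


def make_tirf_trace(params: SimParams, noise_sigma: float, seed: int,
                    baseline: float = 0.1, amplitude: float = 1.0) -> KineticTrace:
    """Simulated TIRF recruitment trace: baseline + amplitude * coverage + noise.

    The baseline models uniform monomer binding before nucleation; the
    long-time plateau is ``baseline + amplitude`` for any concentration that
    reaches full coverage.  Deterministic per (params.seed, seed).
    """
    if noise_sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    trace = simulate_coverage(params)
    rng = np.random.default_rng(seed)
    noisy = baseline + amplitude * trace.intensities
    if noise_sigma > 0:
        noisy = noisy + rng.standard_normal(len(noisy)) * noise_sigma
    return KineticTrace(trace.times, noisy, params.concentration_uM, 0)
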