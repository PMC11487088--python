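"""Seeded synthetic-data generators.

The study's raw imaging data are not publicly deposited, so every analysis
stage in this package is exercised on generated data that reproduces the
*structure* of the experiments: a half-ellipse optic tectum with a
periventricular cell band (PVZ) and an inner neuropil, fields of tracked
nuclei that either jitter in place (uninjured) or move directedly toward a
convergence point with damped-oscillator kinetics (injured), movies of
Gaussian "nuclei" for intensity readouts, shrinking per-plane wound
outlines, and retracting ablation-mask series.

Every generator is a pure function of its arguments and seed: the same seed
yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon

from .io import ImageStack, MaskSeries, OutlineStack, Track, TrackSet, ValidationError
from .kinetics import oscillator_displacement

__all__ = [
    "TectumGeometry",
    "SynthSpec",
    "make_geometry",
    "gen_tracks",
    "render_movie",
    "gen_wound_series",
    "gen_ablation_masks",
]

MOTION_MODELS = ("jitter", "directed_oscillator", "ballistic", "random_walk")


@dataclass
class TectumGeometry:
    """Analytic stand-in for the optic tectum's 2D anatomy.

    The tectum is a half-ellipse; the PVZ is a concentric band of the
    half-annulus between two scale factors; the neuropil is the inner
    scaled half-ellipse; the rostrocaudal curve runs along the middle of
    the PVZ band. All coordinates in micrometres, image convention.
    """

    tectum_outline: np.ndarray
    pvz_band: np.ndarray
    neuropil_region: np.ndarray
    rostrocaudal_curve: np.ndarray
    injury_center: tuple[float, float]
    injury_radius: float
    origin: tuple[float, float]
    rostral_axis: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        ax = np.asarray(self.rostral_axis, float)
        n = np.linalg.norm(ax)
        if n == 0:
            raise ValidationError("rostral_axis must be non-zero")
        self.rostral_axis = tuple(ax / n)
        tect = Polygon(self.tectum_outline).buffer(1e-6)
        if not tect.covers(Polygon(self.pvz_band)):
            raise ValidationError("pvz_band must lie inside the tectum outline")
        if not tect.covers(Polygon(self.neuropil_region)):
            raise ValidationError("neuropil_region must lie inside the tectum outline")
        inj = Point(self.injury_center)
        if not (Polygon(self.pvz_band).buffer(1e-6).covers(inj)
                or Polygon(self.neuropil_region).buffer(1e-6).covers(inj)):
            raise ValidationError("injury_center must lie in the PVZ or neuropil")

    @property
    def tectum_polygon(self) -> Polygon:
        return Polygon(self.tectum_outline)


def _half_ellipse(center: np.ndarray, a: float, b: float, scale: float,
                  n: int = 64) -> np.ndarray:
    """Vertices of an upward (image: −y) half-ellipse arc, rostral to caudal."""
    theta = np.linspace(np.pi, 0.0, n)
    return np.column_stack(
        [center[0] + scale * a * np.cos(theta), center[1] - scale * b * np.sin(theta)]
    )


def make_geometry(
    semi_axis_rc: float = 90.0,
    semi_axis_dv: float = 70.0,
    pvz_inner: float = 0.55,
    pvz_outer: float = 0.95,
    neuropil_scale: float = 0.5,
    injury_radius: float = 10.0,
    injury_angle_deg: float = 60.0,
    seed: int = 0,
) -> TectumGeometry:
    """Build the default analytic tectum geometry.

    ``semi_axis_rc``/``semi_axis_dv`` are the rostrocaudal and
    dorsoventral half-ellipse semi-axes (micrometres). The injury site is
    placed at mid-PVZ depth at ``injury_angle_deg`` from the rostral axis.
    The construction is deterministic; ``seed`` is accepted for interface
    uniformity with the other generators.
    """
    if semi_axis_rc <= 0 or semi_axis_dv <= 0 or injury_radius <= 0:
        raise ValidationError("geometry sizes must be positive")
    if not (0 < pvz_inner < pvz_outer <= 1) or not (0 < neuropil_scale < pvz_inner):
        raise ValidationError("need 0 < neuropil < pvz_inner < pvz_outer <= 1")
    if injury_radius >= min(semi_axis_rc, semi_axis_dv):
        raise ValidationError("injury_radius must be smaller than the tectum")
    center = np.array([semi_axis_rc + 10.0, semi_axis_dv + 10.0])
    outer = _half_ellipse(center, semi_axis_rc, semi_axis_dv, 1.0)
    tectum_outline = outer  # the closing base edge is implicit
    pvz = np.vstack(
        [
            _half_ellipse(center, semi_axis_rc, semi_axis_dv, pvz_outer),
            _half_ellipse(center, semi_axis_rc, semi_axis_dv, pvz_inner)[::-1],
        ]
    )
    neuropil = _half_ellipse(center, semi_axis_rc, semi_axis_dv, neuropil_scale)
    mid = (pvz_inner + pvz_outer) / 2
    rc_curve = _half_ellipse(center, semi_axis_rc, semi_axis_dv, mid, n=96)
    ang = np.deg2rad(injury_angle_deg)
    injury_center = (
        float(center[0] + mid * semi_axis_rc * np.cos(ang)),
        float(center[1] - mid * semi_axis_dv * np.sin(ang)),
    )
    centroid = Polygon(tectum_outline).centroid
    return TectumGeometry(
        tectum_outline=tectum_outline,
        pvz_band=pvz,
        neuropil_region=neuropil,
        rostrocaudal_curve=rc_curve,
        injury_center=injury_center,
        injury_radius=float(injury_radius),
        origin=(float(centroid.x), float(centroid.y)),
    )


@dataclass
class SynthSpec:
    """Recipe for a synthetic track set.

    ``noise_sigma`` plays two roles depending on the motion model: for the
    ``jitter`` (uninjured) model it is the per-step random displacement
    scale, because uninjured nuclei show only minimal, undirected movement;
    for ``directed_oscillator`` it is additive per-localisation measurement
    noise on top of the deterministic motion. ``random_walk`` uses the
    separate ``step_sigma``; ``ballistic`` moves each track at
    ``ballistic_speed`` in a random fixed direction.

    Oscillator kinetics of the injured model: each start point moves toward
    ``convergence_point`` by the fraction
    ``closure_fraction * g(t)/g(duration)`` of its initial distance, where
    ``g(t) = 1 - exp(-nu t/2) cos(omega t - phi)``.
    """

    seed: int = 0
    n_tracks: int = 20
    duration: float = 1080.0  # minutes (18 h of imaging)
    frame_interval: float = 15.0  # minutes between frames
    motion_model: str = "jitter"
    convergence_point: tuple[float, float] | None = None  # default: mid-neuropil
    noise_sigma: float = 0.3  # micrometres
    step_sigma: float = 1.0  # micrometres/step, random_walk only
    ballistic_speed: float = 0.5  # micrometres/minute
    nu: float = 0.002  # 1/min, oscillator damping
    omega: float | None = None  # rad/min; default pi/duration (one half-period)
    phi: float = 0.0
    closure_fraction: float = 0.8
    geometry: TectumGeometry = field(default_factory=make_geometry)

    def __post_init__(self) -> None:
        if self.motion_model not in MOTION_MODELS:
            raise ValidationError(f"unknown motion model {self.motion_model!r}")
        if self.noise_sigma < 0 or self.step_sigma < 0:
            raise ValidationError("noise/step sigma must be >= 0")
        if self.n_tracks < 1 or self.duration <= 0 or self.frame_interval <= 0:
            raise ValidationError("n_tracks, duration, frame_interval must be positive")


def _sample_in_polygon(poly: Polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    minx, miny, maxx, maxy = poly.bounds
    pts = np.empty((n, 2))
    got = 0
    while got < n:
        cand = rng.uniform([minx, miny], [maxx, maxy], size=(4 * (n - got), 2))
        keep = [p for p in cand if poly.contains(Point(p))]
        for p in keep[: n - got]:
            pts[got] = p
            got += 1
    return pts


def gen_tracks(spec: SynthSpec) -> TrackSet:
    """Generate a seeded TrackSet according to ``spec`` (see class docs)."""
    rng = np.random.default_rng(spec.seed)
    geom = spec.geometry
    n_frames = int(round(spec.duration / spec.frame_interval)) + 1
    t = np.arange(n_frames) * spec.frame_interval
    band = Polygon(geom.pvz_band)
    starts = _sample_in_polygon(band, spec.n_tracks, rng)

    if spec.convergence_point is None:
        npil = Polygon(geom.neuropil_region).centroid
        conv = np.array([npil.x, npil.y])
    else:
        conv = np.asarray(spec.convergence_point, float)

    tracks = []
    for i in range(spec.n_tracks):
        start = starts[i]
        if spec.motion_model == "jitter":
            steps = rng.normal(0.0, spec.noise_sigma, size=(n_frames - 1, 2))
            pos = start + np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        elif spec.motion_model == "random_walk":
            steps = rng.normal(0.0, spec.step_sigma, size=(n_frames - 1, 2))
            pos = start + np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        elif spec.motion_model == "ballistic":
            ang = rng.uniform(0, 2 * np.pi)
            v = spec.ballistic_speed * np.array([np.cos(ang), np.sin(ang)])
            pos = start + np.outer(t, v)
        else:  # directed_oscillator
            omega = spec.omega if spec.omega is not None else np.pi / spec.duration
            k = omega**2 + spec.nu**2 / 4
            g = 1.0 - oscillator_displacement(t, 1.0, spec.nu, k, spec.phi)
            g_end = 1.0 - oscillator_displacement(
                spec.duration, 1.0, spec.nu, k, spec.phi
            )
            frac = spec.closure_fraction * g / g_end
            pos = start + frac[:, None] * (conv - start)
            pos = pos + rng.normal(0.0, spec.noise_sigma, size=pos.shape)
        tracks.append(
            Track(track_id=f"track{i:04d}", t=t, xy=pos, cell_type="neuron",
                  animal_id="synthetic")
        )
    return TrackSet(tracks, frame_interval=spec.frame_interval)


def render_movie(
    ts: TrackSet,
    shape: tuple[int, int] = (128, 128),
    pixel_size: float = 1.6,
    blob_sigma: float = 2.5,
) -> ImageStack:
    """Render tracks as a movie of unit-mass Gaussian blobs.

    Each track contributes an isotropic Gaussian of standard deviation
    ``blob_sigma`` (micrometres) and unit integrated intensity at its
    position in every frame, so total image intensity counts cells and ROI
    intensities have an exact ground truth.
    """
    if blob_sigma <= 0:
        raise ValidationError("blob_sigma must be positive")
    n_frames = ts.tracks[0].n_samples
    for tr in ts.tracks:
        if tr.n_samples != n_frames:
            raise ValidationError("all tracks must share one time base")
    sig_px = blob_sigma / pixel_size
    half = int(np.ceil(5 * sig_px))
    data = np.zeros((n_frames, *shape))
    for tr in ts.tracks:
        for f in range(n_frames):
            cx, cy = tr.xy[f, 0] / pixel_size, tr.xy[f, 1] / pixel_size
            x0, x1 = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
            y0, y1 = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
            x0c, x1c = max(x0, 0), min(x1, shape[1])
            y0c, y1c = max(y0, 0), min(y1, shape[0])
            if x0c >= x1c or y0c >= y1c:
                continue
            xs = np.arange(x0c, x1c)
            ys = np.arange(y0c, y1c)
            gx = np.exp(-((xs - cx) ** 2) / (2 * sig_px**2))
            gy = np.exp(-((ys - cy) ** 2) / (2 * sig_px**2))
            data[f, y0c:y1c, x0c:x1c] += np.outer(gy, gx) / (2 * np.pi * sig_px**2)
    return ImageStack(
        data=data,
        pixel_size=pixel_size,
        frame_interval=ts.frame_interval,
    )


def gen_wound_series(
    kind: str = "closing",
    v_start: float = 2000.0,
    v_end: float = 500.0,
    n_planes: int = 7,
    z_step: float = 2.0,
    seed: int = 0,
    center: tuple[float, float] = (50.0, 50.0),
) -> tuple[OutlineStack, OutlineStack]:
    """Per-plane injury outlines at two time points with requested volumes.

    Outlines are concentric circles with a spherical-cap radius profile
    across planes; polygon vertex coordinates are rescaled so the
    summed-shoelace-area volume matches the request to floating precision.
    ``v_end = 0`` yields an end stack with zero outlines (vanished injury).
    """
    if kind not in ("closing", "enlarging"):
        raise ValidationError(f"unknown wound kind {kind!r}")
    if n_planes < 1:
        raise ValidationError("need n_planes >= 1")
    if v_start <= 0 or v_end < 0:
        raise ValidationError("need v_start > 0 and v_end >= 0")

    def build(volume: float) -> OutlineStack:
        if volume == 0:
            return OutlineStack(outlines=[], z_step=z_step)
        zc = (n_planes - 1) / 2
        zr = n_planes / 2 + 0.5
        profile = np.sqrt(np.maximum(1 - ((np.arange(n_planes) - zc) / zr) ** 2, 0.05))
        theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        polys = []
        areas = []
        for z in range(n_planes):
            r = profile[z]
            verts = np.column_stack(
                [center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)]
            )
            polys.append(verts)
            areas.append(Polygon(verts).area)
        total = sum(areas) * z_step
        scale = np.sqrt(volume / total)
        ctr = np.asarray(center)
        outlines = [
            (z, ctr + scale * (polys[z] - ctr)) for z in range(n_planes)
        ]
        return OutlineStack(outlines=outlines, z_step=z_step)

    return build(v_start), build(v_end)


def gen_ablation_masks(
    mode: str = "recoil",
    n_frames: int = 10,
    dt: float = 15.0,
    seed: int = 0,
    shape: tuple[int, int] = (96, 96),
    pixel_size: float = 0.3,
) -> MaskSeries:
    """Binary mask series mimicking a laser-ablation recording.

    ``recoil``: a disc shrinks sharply over the first interval and then is
    nearly static, the signature of elastic tissue recoil after a cut.
    ``static``: constant disc. ``drift``: disc translating slowly.
    """
    if mode not in ("recoil", "static", "drift"):
        raise ValidationError(f"unknown ablation mode {mode!r}")
    if n_frames < 2:
        raise ValidationError("need n_frames >= 2")
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy0, cx0 = shape[0] / 2, shape[1] / 2
    masks = np.zeros((n_frames, *shape), dtype=bool)
    for f in range(n_frames):
        if mode == "recoil":
            r = 30.0 if f == 0 else 18.0 - 0.15 * (f - 1)
            cy, cx = cy0, cx0
        elif mode == "static":
            r, cy, cx = 25.0, cy0, cx0
        else:  # drift
            r, cy, cx = 25.0, cy0, cx0 + 1.0 * f
        masks[f] = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    times = np.arange(n_frames) * dt
    return MaskSeries(masks=masks, times=times, pixel_size=pixel_size)
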