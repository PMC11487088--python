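"""Trajectory statistics for tracked cell nuclei.

Implements the quantitative readouts used to demonstrate directed tissue
movement after a tectal stab injury: time-averaged mean-squared
displacement (MSD) with a power-law (superdiffusion) exponent, track
straightness, projection of trajectories onto the curved rostrocaudal axis
(anisotropy analysis), displacement-field convergence with polar
normalisation to the tectum outline, and the discrete Fréchet distance
between microglial and neuronal trajectories with a randomised null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, Point

from .io import Track, TrackSet, ValidationError
from .synthetic import TectumGeometry

__all__ = [
    "MSDResult",
    "TrackSummary",
    "LinearisedTrack",
    "ConvergenceResult",
    "FrechetResult",
    "msd",
    "fit_msd_powerlaw",
    "track_summary",
    "linearise",
    "displacement_field",
    "convergence",
    "normalise_polar",
    "discrete_frechet",
    "frechet_null",
]


@dataclass
class MSDResult:
    """Ensemble MSD curve, optionally annotated with a power-law fit.

    ``msd(tau) ~ 4 * D_eff * tau**alpha``; ``alpha`` near 1 is diffusive,
    near 2 ballistic; the injured tectum shows an early superdiffusive
    phase (``alpha > 1.5``).
    """

    lags: np.ndarray  # minutes
    msd: np.ndarray  # micrometres^2
    n_tracks: int
    alpha: float | None = None
    D_eff: float | None = None
    r2: float | None = None
    fit_range: tuple[float, float] | None = None


@dataclass
class TrackSummary:
    straightness: float  # net displacement / path length, in [0, 1]
    net_displacement: float  # micrometres
    path_length: float  # micrometres
    z_displacement: float | None = None  # signed, 3D tracks only


@dataclass
class LinearisedTrack:
    """A track expressed relative to the curved rostrocaudal axis."""

    s0: float  # arc-length of the projected start point (micrometres)
    lateral0: float  # signed normal offset of the start point
    d_tangential: float  # net displacement along the local tangent
    d_normal: float  # net displacement along the local normal (+90 deg CCW)


@dataclass
class ConvergenceResult:
    intersections: np.ndarray  # (n, 2) kept forward-ray intersection points
    centroid: tuple[float, float] | None
    polar_centroid: tuple[float, float] | None  # (r_norm, theta_deg)
    defined: bool


@dataclass
class FrechetResult:
    distance: float
    null_distances: np.ndarray
    empirical_p: float


# ---------------------------------------------------------------------------
# MSD
# ---------------------------------------------------------------------------


def msd(ts: TrackSet, max_lag_fraction: float = 0.5) -> MSDResult:
    """Time-averaged 2D MSD per track, then unweighted mean across tracks.

    Per track, every overlapping pair of samples at a given lag contributes
    (the time-average convention of standard cell-migration MSD tools);
    lags run up to ``max_lag_fraction`` of each track's length. Requires a
    uniform frame interval shared by all tracks.
    """
    usable = [tr for tr in ts.tracks if tr.n_samples >= 3]
    if not usable:
        raise ValidationError("need at least one track with >= 3 samples")
    dts = []
    for tr in usable:
        d = np.diff(tr.t)
        if not np.allclose(d, d[0], rtol=1e-9, atol=1e-9):
            raise ValidationError(f"track {tr.track_id!r}: non-uniform sampling")
        dts.append(d[0])
    if not np.allclose(dts, dts[0], rtol=1e-9):
        raise ValidationError("tracks do not share one frame interval")
    dt = dts[0]
    max_lag = max(int(np.floor(max_lag_fraction * max(tr.n_samples - 1 for tr in usable))), 1)

    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=int)
    for tr in usable:
        pos = tr.xy2d
        n = len(pos)
        top = min(max_lag, int(np.floor(max_lag_fraction * (n - 1))) or 1)
        for lag in range(1, top + 1):
            disp = pos[lag:] - pos[:-lag]
            sums[lag - 1] += np.mean(np.sum(disp**2, axis=1))
            counts[lag - 1] += 1
    valid = counts > 0
    lags = (np.arange(1, max_lag + 1) * dt)[valid]
    curve = sums[valid] / counts[valid]
    return MSDResult(lags=lags, msd=curve, n_tracks=len(usable))


def fit_msd_powerlaw(
    result: MSDResult, fit_range: tuple[float, float] | None = None
) -> tuple[float, float, float]:
    """Fit ``msd = 4 * D_eff * lag**alpha`` by OLS on the log-log curve.

    Returns ``(alpha, D_eff, r2)`` and annotates ``result`` in place.
    Refuses windows containing non-positive MSD values (log undefined),
    which also covers the all-stationary case.
    """
    lags, curve = result.lags, result.msd
    if fit_range is not None:
        sel = (lags >= fit_range[0]) & (lags <= fit_range[1])
        lags, curve = lags[sel], curve[sel]
    if len(lags) < 3:
        raise ValidationError("need >= 3 lags in the fit range")
    if np.any(curve <= 0):
        raise ValidationError("non-positive MSD in fit range: exponent fit refused")
    X = np.log(lags)
    Y = np.log(curve)
    alpha, intercept = np.polyfit(X, Y, 1)
    pred = alpha * X + intercept
    ss_tot = np.sum((Y - Y.mean()) ** 2)
    r2 = 1.0 - np.sum((Y - pred) ** 2) / ss_tot if ss_tot > 0 else 1.0
    D_eff = float(np.exp(intercept) / 4.0)
    result.alpha, result.D_eff, result.r2 = float(alpha), D_eff, float(r2)
    result.fit_range = (float(lags[0]), float(lags[-1]))
    return float(alpha), D_eff, float(r2)


# ---------------------------------------------------------------------------
# per-track summaries
# ---------------------------------------------------------------------------


def track_summary(tr: Track) -> TrackSummary:
    """Straightness, net displacement, path length (and z-displacement in 3D)."""
    if tr.n_samples < 2:
        raise ValidationError(f"track {tr.track_id!r}: need >= 2 samples")
    steps = np.diff(tr.xy, axis=0)
    path = float(np.sum(np.linalg.norm(steps, axis=1)))
    net = float(np.linalg.norm(tr.xy[-1] - tr.xy[0]))
    straightness = net / path if path > 0 else 0.0
    z_disp = float(tr.xy[-1, 2] - tr.xy[0, 2]) if tr.is_3d else None
    return TrackSummary(
        straightness=straightness,
        net_displacement=net,
        path_length=path,
        z_displacement=z_disp,
    )


# ---------------------------------------------------------------------------
# rostrocaudal linearisation
# ---------------------------------------------------------------------------


def _project_to_polyline(p: np.ndarray, curve: np.ndarray):
    """Nearest point on a polyline: (arc_length, foot, tangent unit vector)."""
    best = (np.inf, 0.0, None, None)
    s_acc = 0.0
    for a, b in zip(curve[:-1], curve[1:]):
        seg = b - a
        seg_len = np.linalg.norm(seg)
        if seg_len == 0:
            continue
        u = seg / seg_len
        tproj = np.clip(np.dot(p - a, u), 0.0, seg_len)
        foot = a + tproj * u
        d = np.linalg.norm(p - foot)
        if d < best[0]:
            best = (d, s_acc + tproj, foot, u)
        s_acc += seg_len
    if best[2] is None:
        raise ValidationError("zero-length curve")
    return best[1], best[2], best[3]


def linearise(tr: Track, curve: np.ndarray) -> LinearisedTrack:
    """Express a track's net displacement in the frame of a reference curve.

    The start point is projected perpendicularly onto the polyline; the net
    planar displacement is decomposed onto the tangent and the normal
    (+90 degrees counter-clockwise from the tangent) at the projection.
    """
    curve = np.asarray(curve, float)
    if curve.ndim != 2 or len(curve) < 2:
        raise ValidationError("curve must be a polyline with >= 2 vertices")
    if tr.n_samples < 2:
        raise ValidationError("need >= 2 samples")
    start, end = tr.xy2d[0], tr.xy2d[-1]
    s0, foot, tangent = _project_to_polyline(start, curve)
    normal = np.array([-tangent[1], tangent[0]])  # +90 deg CCW
    disp = end - start
    return LinearisedTrack(
        s0=float(s0),
        lateral0=float(np.dot(start - foot, normal)),
        d_tangential=float(np.dot(disp, tangent)),
        d_normal=float(np.dot(disp, normal)),
    )


# ---------------------------------------------------------------------------
# displacement field and convergence
# ---------------------------------------------------------------------------


@dataclass
class DisplacementVector:
    anchor: np.ndarray  # start point (x, y)
    vector: np.ndarray  # end - start
    is_zero: bool


def displacement_field(ts: TrackSet) -> list[DisplacementVector]:
    """One net displacement vector per track, anchored at the start point."""
    out = []
    for tr in ts.tracks:
        if tr.n_samples < 2:
            raise ValidationError(f"track {tr.track_id!r}: need >= 2 samples")
        vec = tr.xy2d[-1] - tr.xy2d[0]
        out.append(
            DisplacementVector(
                anchor=tr.xy2d[0].copy(),
                vector=vec,
                is_zero=bool(np.allclose(vec, 0.0)),
            )
        )
    return out


def convergence(
    field: list[DisplacementVector],
    geometry: TectumGeometry,
    min_angle_deg: float = 10.0,
) -> ConvergenceResult:
    """Estimate the point tissue displacement converges toward.

    For every pair of displacement vectors the forward rays are
    intersected; intersections are kept when they lie forward along both
    rays, inside the tectum outline, and the pair's angular separation is
    at least ``min_angle_deg`` (near-parallel pairs produce unstable,
    distant intersections). The centroid of kept points is reported in
    Cartesian and normalised polar coordinates.
    """
    vecs = [f for f in field if not f.is_zero]
    if len(vecs) < 2:
        raise ValidationError("need >= 2 non-zero displacement vectors")
    tect = geometry.tectum_polygon
    min_cos = np.cos(np.deg2rad(min_angle_deg))
    pts = []
    for i in range(len(vecs)):
        for j in range(i + 1, len(vecs)):
            p, r = vecs[i].anchor, vecs[i].vector
            q, s = vecs[j].anchor, vecs[j].vector
            ru = r / np.linalg.norm(r)
            su = s / np.linalg.norm(s)
            if np.dot(ru, su) > min_cos:
                continue  # angular separation below threshold
            denom = ru[0] * su[1] - ru[1] * su[0]
            if abs(denom) < 1e-12:
                continue  # parallel
            d = q - p
            ti = (d[0] * su[1] - d[1] * su[0]) / denom
            tj = (d[0] * ru[1] - d[1] * ru[0]) / denom
            if ti <= 0 or tj <= 0:
                continue  # behind one of the rays
            x = p + ti * ru
            if tect.contains(Point(x)):
                pts.append(x)
    if not pts:
        return ConvergenceResult(
            intersections=np.empty((0, 2)), centroid=None,
            polar_centroid=None, defined=False,
        )
    pts = np.asarray(pts)
    centroid = pts.mean(axis=0)
    polar = normalise_polar(centroid, geometry)
    return ConvergenceResult(
        intersections=pts,
        centroid=(float(centroid[0]), float(centroid[1])),
        polar_centroid=polar,
        defined=True,
    )


def normalise_polar(
    p: np.ndarray | tuple[float, float], geometry: TectumGeometry
) -> tuple[float, float]:
    """Normalised polar coordinates of a point in the tectum frame.

    ``theta`` is the signed angle (degrees) of ``p - origin`` from the
    rostral axis; ``r_norm`` is the distance from the origin divided by the
    distance from the origin to the tectum outline along the same
    direction, so points on the outline have ``r_norm = 1`` whatever the
    tectum's size — the normalisation that makes animals comparable.
    """
    p = np.asarray(p, float)
    origin = np.asarray(geometry.origin, float)
    tect = geometry.tectum_polygon
    if not tect.buffer(1e-9).covers(Point(origin)):
        raise ValidationError("geometry origin lies outside the tectum outline")
    d = p - origin
    dist = np.linalg.norm(d)
    if dist == 0:
        return 0.0, 0.0
    u = d / dist
    ax = np.asarray(geometry.rostral_axis, float)
    theta = np.degrees(np.arctan2(ax[0] * u[1] - ax[1] * u[0], np.dot(ax, u)))
    span = 10.0 * max(tect.bounds[2] - tect.bounds[0], tect.bounds[3] - tect.bounds[1])
    ray = LineString([origin, origin + span * u])
    hit = ray.intersection(tect.exterior)
    if hit.is_empty:
        raise ValidationError("direction ray does not meet the tectum outline")
    if hit.geom_type == "Point":
        candidates = [hit]
    else:
        candidates = list(getattr(hit, "geoms", [hit]))
    dists = [np.linalg.norm(np.array([g.x, g.y]) - origin) for g in candidates
             if g.geom_type == "Point"]
    dists = [dd for dd in dists if dd > 1e-9]
    if not dists:
        raise ValidationError("degenerate outline intersection")
    r_out = min(dists)
    return float(dist / r_out), float(theta)


# ---------------------------------------------------------------------------
# discrete Frechet distance
# ---------------------------------------------------------------------------


def discrete_frechet(P: np.ndarray, Q: np.ndarray) -> float:
    """Discrete Fréchet distance between two point sequences.

    Dynamic programme over the coupling lattice: the minimum, over monotone
    couplings of the two sequences, of the maximum pointwise Euclidean
    distance. Symmetric, non-negative, zero iff the sequences are
    identical, and at least the larger of the two endpoint-pair distances.
    """
    P = np.atleast_2d(np.asarray(P, float))
    Q = np.atleast_2d(np.asarray(Q, float))
    if len(P) == 0 or len(Q) == 0:
        raise ValidationError("sequences must be non-empty")
    d = np.linalg.norm(P[:, None, :] - Q[None, :, :], axis=-1)
    n, m = d.shape
    ca = np.empty((n, m))
    ca[0, 0] = d[0, 0]
    for j in range(1, m):
        ca[0, j] = max(ca[0, j - 1], d[0, j])
    for i in range(1, n):
        ca[i, 0] = max(ca[i - 1, 0], d[i, 0])
        for j in range(1, m):
            ca[i, j] = max(
                min(ca[i - 1, j], ca[i - 1, j - 1], ca[i, j - 1]), d[i, j]
            )
    return float(ca[-1, -1])


def frechet_null(
    microglia_track: Track,
    neuron_track: Track,
    n_perm: int = 999,
    seed: int = 0,
) -> FrechetResult:
    """Observed Fréchet distance against a direction-randomised null.

    The null resamples the neuron track: same start point, step magnitudes
    drawn with replacement from the observed steps, directions uniform.
    This preserves the movement scale while destroying the directional
    correlation that microglial traction would induce. The empirical
    p-value uses the add-one correction
    ``(1 + #{null <= observed}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if microglia_track.n_samples < 2 or neuron_track.n_samples < 2:
        raise ValidationError("both tracks need >= 2 samples")
    rng = np.random.default_rng(seed)
    P = microglia_track.xy2d
    Q = neuron_track.xy2d
    obs = discrete_frechet(P, Q)
    steps = np.diff(Q, axis=0)
    mags = np.linalg.norm(steps, axis=1)
    n_steps = len(mags)
    null = np.empty(n_perm)
    for b in range(n_perm):
        m = rng.choice(mags, size=n_steps, replace=True)
        ang = rng.uniform(0, 2 * np.pi, size=n_steps)
        rand_steps = m[:, None] * np.column_stack([np.cos(ang), np.sin(ang)])
        rand_track = Q[0] + np.vstack([[0.0, 0.0], np.cumsum(rand_steps, axis=0)])
        null[b] = discrete_frechet(P, rand_track)
    p = (1 + int(np.sum(null <= obs))) / (n_perm + 1)
    return FrechetResult(distance=obs, null_distances=null, empirical_p=float(p))
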