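"""Wound-closure and microglial-accumulation kinetics.

The closure of a stab wound in the larval optic tectum behaves like a
viscoelastic relaxation: neurons embedded in a spring-like astrocytic
meshwork and a viscous medium move according to the underdamped harmonic
oscillator

    x'' + nu * x' + k * x = 0        (mass absorbed, m == 1)

whose solution is

    x(t) = a * exp(-nu*t/2) * cos(omega*t - phi),   omega = sqrt(k - nu**2/4).

Fluorescence-intensity readouts of the wound region are fitted with this
form (plus a free baseline) over a single half-period, because the observed
closure displacement is monotone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .io import ImageStack, ValidationError

__all__ = [
    "KineticCurve",
    "OscillatorFit",
    "FitError",
    "oscillator_displacement",
    "fit_oscillator",
    "closure_curve",
    "accumulation_curve",
    "normalise_curve",
    "closure_time",
]


class FitError(RuntimeError):
    """Nonlinear fit failed to converge from any start."""


@dataclass
class KineticCurve:
    """Scalar readout over time (ROI intensity, agent density...)."""

    t: np.ndarray  # minutes
    value: np.ndarray
    normalised: bool = False
    t0_hpi: float = 0.0  # display metadata

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.t.shape != self.value.shape or self.t.ndim != 1:
            raise ValidationError("t and value must be 1D arrays of equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValidationError("curve times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class OscillatorFit:
    """Fitted underdamped-oscillator parameters (m == 1 convention).

    ``a`` and ``offset`` are in curve units; ``nu`` is the damping rate
    (1/min); ``k`` the stiffness rate (1/min^2); ``phi`` the phase (rad);
    ``omega = sqrt(k - nu^2/4)`` and ``half_period = pi/omega`` follow.
    """

    a: float
    nu: float
    k: float
    phi: float
    offset: float
    r2: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.k <= self.nu**2 / 4:
            raise ValidationError("fit is not underdamped (k <= nu^2/4)")

    @property
    def omega(self) -> float:
        return float(np.sqrt(self.k - self.nu**2 / 4))

    @property
    def half_period(self) -> float:
        return float(np.pi / self.omega)

    def predict(self, t: np.ndarray) -> np.ndarray:
        """Model curve at times ``t`` (minutes from the window start)."""
        return self.offset + oscillator_displacement(
            np.asarray(t, float), self.a, self.nu, self.k, self.phi
        )


def oscillator_displacement(
    t: np.ndarray | float, a: float, nu: float, k: float, phi: float
) -> np.ndarray | float:
    """Underdamped displacement a*exp(-nu t/2)*cos(sqrt(k - nu^2/4) t - phi).

    Requires ``k > nu^2/4`` (underdamped) and ``t >= 0``.
    """
    if k <= nu**2 / 4:
        raise ValidationError("overdamped parameters: need k > nu^2/4")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValidationError("t must be >= 0")
    omega = np.sqrt(k - nu**2 / 4)
    out = a * np.exp(-nu * t / 2) * np.cos(omega * t - phi)
    return out if out.ndim else float(out)


def _canonicalise(a: float, phi: float) -> tuple[float, float]:
    # (a, phi) and (-a, phi + pi) describe the same curve; report the
    # representative with phi in (-pi/2, pi/2].
    phi = (phi + np.pi) % (2 * np.pi) - np.pi
    if phi > np.pi / 2:
        phi -= np.pi
        a = -a
    elif phi <= -np.pi / 2:
        phi += np.pi
        a = -a
    return a, phi


def fit_oscillator(
    curve: KineticCurve,
    window: tuple[float, float] | None = None,
    n_phase_starts: int = 12,
) -> OscillatorFit:
    """Least-squares fit of the oscillator model to a kinetic curve.

    The model is ``v(t) ~ offset + a exp(-nu (t - t0)/2) cos(omega (t - t0)
    - phi)`` with ``t0`` the first time in the window. The cosine phase
    creates local minima, so the optimiser is multi-started over a grid of
    ``n_phase_starts`` phases and the best converged fit (by cost) is
    returned. A warning attribute is not raised here; callers can compare
    the fitted window length with ``half_period``.
    """
    t, v = curve.t, curve.value
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        t, v = t[sel], v[sel]
    if len(t) < 6:
        raise ValidationError("need >= 6 points in the fit window")
    if np.ptp(v) == 0:
        raise FitError("constant curve: oscillator fit is undefined")
    t0 = t[0]
    tt = t - t0
    span = tt[-1] if tt[-1] > 0 else 1.0
    amp0 = np.ptp(v) / 2

    def residuals(p: np.ndarray) -> np.ndarray:
        a, log_nu, log_omega, phi, offset = p
        nu, omega = np.exp(log_nu), np.exp(log_omega)
        return offset + a * np.exp(-nu * tt / 2) * np.cos(omega * tt - phi) - v

    # parametrise by (nu, omega) through logs: positivity and the
    # underdamped condition k = omega^2 + nu^2/4 > nu^2/4 hold by construction
    best = None
    omega0 = np.pi / span  # half period spanning the window
    for phi0 in np.linspace(-np.pi, np.pi, n_phase_starts, endpoint=False):
        for a0 in (amp0, -amp0):
            p0 = np.array([a0, np.log(1.0 / span), np.log(omega0), phi0, np.mean(v)])
            try:
                sol = least_squares(residuals, p0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
            except Exception:  # numerical failure from a bad start
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise FitError("oscillator fit failed to converge from any start")
    a, log_nu, log_omega, phi, offset = best.x
    nu, omega = float(np.exp(log_nu)), float(np.exp(log_omega))
    a, phi = _canonicalise(float(a), float(phi))
    k = omega**2 + nu**2 / 4
    ss_res = 2 * best.cost
    ss_tot = float(np.sum((v - np.mean(v)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return OscillatorFit(
        a=a, nu=nu, k=float(k), phi=float(phi), offset=float(offset),
        r2=float(r2), window=(float(t[0]), float(t[-1])),
    )


# ---------------------------------------------------------------------------
# intensity curves from image stacks
# ---------------------------------------------------------------------------


def _roi_mask(shape: tuple[int, int], roi: np.ndarray, pixel_size: float) -> np.ndarray:
    from skimage.draw import polygon2mask

    verts_px = np.asarray(roi, float) / pixel_size
    if len(verts_px) < 3:
        raise ValidationError("ROI polygon needs >= 3 vertices")
    # polygon2mask takes (row, col) = (y, x)
    mask = polygon2mask(shape, verts_px[:, ::-1])
    if not mask.any():
        raise ValidationError("ROI is empty or lies outside the image")
    return mask


def _roi_curve(stack: ImageStack, roi: np.ndarray, plane: int | None) -> KineticCurve:
    data = stack.data
    if data.ndim == 4:
        if plane is None:
            plane = data.shape[1] // 2  # median optical plane
        if not 0 <= plane < data.shape[1]:
            raise ValidationError(f"plane {plane} out of range")
        data = data[:, plane]
    mask = _roi_mask(data.shape[1:], roi, stack.pixel_size)
    values = data[:, mask].mean(axis=1)
    return KineticCurve(
        t=stack.times, value=values, normalised=False, t0_hpi=stack.t0_hpi
    )


def closure_curve(
    stack: ImageStack,
    wound_roi: np.ndarray,
    plane: int | None = None,
    t_ref: float | None = None,
) -> KineticCurve:
    """Wound-closure kinetic: mean intensity inside the initial wound ROI.

    The ROI delimits the wound footprint in the periventricular zone; as
    labelled cells move in, intensity rises. The curve is normalised to 0 at
    the first frame and 1 at ``t_ref`` (default: the last frame).
    """
    raw = _roi_curve(stack, wound_roi, plane)
    return normalise_curve(raw, t_ref=t_ref)


def accumulation_curve(
    stack: ImageStack,
    neuropil_roi: np.ndarray,
    plane: int | None = None,
    t_ref: float | None = None,
) -> KineticCurve:
    """Microglial accumulation kinetic: mean intensity in the neuropil ROI."""
    raw = _roi_curve(stack, neuropil_roi, plane)
    return normalise_curve(raw, t_ref=t_ref)


def normalise_curve(curve: KineticCurve, t_ref: float | None = None) -> KineticCurve:
    """Normalise a curve to 0 at its first sample and 1 at ``t_ref``.

    ``v'(t) = (v(t) - v(t_first)) / (v(t_ref) - v(t_first))``; values are
    not clamped, so overshoot past the reference remains visible.
    """
    t, v = curve.t, curve.value
    if t_ref is None:
        i_ref = len(t) - 1
    else:
        i_ref = int(np.argmin(np.abs(t - t_ref)))
    denom = v[i_ref] - v[0]
    if denom == 0:
        raise ValidationError("zero range: cannot normalise this curve")
    return KineticCurve(
        t=t.copy(), value=(v - v[0]) / denom, normalised=True, t0_hpi=curve.t0_hpi
    )


def closure_time(curve: KineticCurve, threshold: float = 0.95) -> float | None:
    """First time a normalised closure curve reaches ``threshold``.

    Linear interpolation between frames; returns None when the curve never
    reaches the threshold (closure undefined).
    """
    if not curve.normalised:
        raise ValidationError("closure_time expects a normalised curve")
    t, v = curve.t, curve.value
    above = np.nonzero(v >= threshold)[0]
    if len(above) == 0:
        return None
    i = above[0]
    if i == 0:
        return float(t[0])
    frac = (threshold - v[i - 1]) / (v[i] - v[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))
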