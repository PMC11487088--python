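"""Wound-closure kinetics and the damped-oscillator model.

Renders a synthetic movie of cells converging on a wound, measures the
normalised intensity curve in the wound ROI, and fits the underdamped
oscillator displacement model x(t) = a*exp(-nu*t/2)*cos(omega*t - phi)
(unit mass, omega = sqrt(k - nu^2/4)).
"""

import numpy as np

import tectal as T


def main() -> None:
    # A clean oscillator curve with known parameters, recovered by the fitter
    a, nu, k = -0.5, 0.01, 0.001
    t = np.linspace(0, 1000, 120)
    value = 0.5 + T.oscillator_displacement(t, a=a, nu=nu, k=k, phi=0.0)
    rng = np.random.default_rng(0)
    noisy = value + rng.normal(0, 0.005, len(t))

    fit = T.fit_oscillator(T.KineticCurve(t=t, value=noisy))
    print("== Oscillator fit on a noisy synthetic curve ==")
    print(f"true    a={a:.3f}  nu={nu:.4f}  k={k:.5f}")
    print(f"fitted  a={fit.a:.3f}  nu={fit.nu:.4f}  k={fit.k:.5f}  r2={fit.r2:.4f}")
    print(f"half-period = {fit.half_period:.0f} min")

    # The same pipeline from a rendered movie: tracks -> movie -> ROI curve
    geometry = T.make_geometry()
    ts = T.gen_tracks(T.SynthSpec(
        motion_model="directed_oscillator", n_tracks=30, seed=4,
        geometry=geometry,
    ))
    movie = T.render_movie(ts, shape=(128, 128), pixel_size=1.6)
    cx, cy = geometry.injury_center
    roi = np.array(
        [[cx - 12, cy - 12], [cx + 12, cy - 12],
         [cx + 12, cy + 12], [cx - 12, cy + 12]]
    )
    curve = T.closure_curve(movie, roi)
    t50 = T.closure_time(curve, threshold=0.5)
    print("\n== ROI intensity curve from the rendered movie ==")
    print(f"frames={len(curve.t)}, normalised range "
          f"[{curve.value.min():.2f}, {curve.value.max():.2f}]")
    if t50 is not None:
        print(f"time to half-closure = {t50:.0f} min")


if __name__ == "__main__":
    main()
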