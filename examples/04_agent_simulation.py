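"""Agent-based wound-closure model: microglial traction closes the wound.

Runs the overdamped agent model (neurons, microglia, immobile skin wall)
at desk scale for a short demonstration, then shows how the repair
analogue depends on microglia count. Full-length runs (24 simulated
hours) and the 5-count sweep take ~10 minutes on one CPU; pass --full to
run them.
"""

import sys

import tectal as T


def main(full: bool = False) -> None:
    duration = 1440.0 if full else 240.0
    print(f"== Single runs ({duration / 60:.0f} simulated hours) ==")
    for n_mg in (0, 40):
        res = T.run(T.default_sim_config(n_microglia=n_mg, seed=0,
                                         duration=duration))
        print(f"n_microglia={n_mg:3d}  repair analogue = {res.repair.ri:+.3f}")

    if full:
        print("\n== Microglia-count sweep (3 replicates each) ==")
        tab = T.sweep_microglia(
            T.default_sim_config(seed=0), [0, 4, 8, 16, 32],
            replicates=3, seed=0,
        )
        print(tab.to_string(index=False))
        r2 = T.isotonic_r2(tab["n_microglia"].values, tab["mean_ri"].values)
        print(f"isotonic (monotone) fit R^2 = {r2:.3f}")
    else:
        print("\n(pass --full for 24-hour runs and the count sweep)")


if __name__ == "__main__":
    main(full="--full" in sys.argv[1:])
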