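"""Wound morphometry: volumes, repair index, mask turnover, recoil.

Reconstructs injury volumes from z-stack outlines (shoelace area x z-step),
computes the repair index RI = 1 - V_late/V_early, recomputes the
microglia-deficient cohort percentage from per-animal outline stacks, and
quantifies the post-ablation recoil signature from mask series.
"""

import numpy as np

import tectal as T


def main() -> None:
    print("== Repair index from outline stacks ==")
    start, end = T.gen_wound_series(v_start=2000.0, v_end=500.0, seed=0)
    v0, v1 = T.injury_volume(start), T.injury_volume(end)
    ri = T.repair_index(v0, v1)
    print(f"V_early = {v0:.0f} um^3, V_late = {v1:.0f} um^3")
    print(f"RI = {ri.ri:.2f}  closed = {ri.closed}")

    print("\n== Mutant cohort: fraction with enlarged injury ==")
    n_animals, n_enlarging = 17, 10
    enlarged = 0
    for i in range(n_animals):
        kind = "enlarging" if i < n_enlarging else "closing"
        v_end = 1300.0 if i < n_enlarging else 400.0
        s, e = T.gen_wound_series(kind=kind, v_start=1000.0, v_end=v_end,
                                  seed=100 + i)
        enlarged += T.repair_index(T.injury_volume(s), T.injury_volume(e)).ri < 0
    pct = 100.0 * enlarged / n_animals
    print(f"{enlarged} of {n_animals} animals enlarged -> {pct:.0f}%")

    print("\n== Laser-ablation recoil signature ==")
    ms = T.gen_ablation_masks("recoil", n_frames=10, dt=15.0, seed=0)
    res = T.area_change(ms)
    ratio = res.total_remodelled[0] / np.max(res.total_remodelled[1:])
    print(f"remodelled area, first interval = {res.total_remodelled[0]:.1f} um^2")
    print(f"max later interval              = {np.max(res.total_remodelled[1:]):.1f} um^2")
    print(f"first/later ratio               = {ratio:.0f}x")


if __name__ == "__main__":
    main()
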