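import numpy as np
import pytest

from tectal import SynthSpec, Track, TrackSet, gen_tracks, make_geometry


@pytest.fixture(scope="session")
def geometry():
    return make_geometry()


@pytest.fixture
def ballistic_track():
    """Constant-velocity track: v = (1, 0.5) um/min over 20 frames."""
    t = np.arange(21, dtype=float)
    v = np.array([1.0, 0.5])
    return Track(track_id="ball", t=t, xy=np.outer(t, v) + [10.0, 20.0])


@pytest.fixture
def stationary_track():
    t = np.arange(10, dtype=float)
    return Track(track_id="still", t=t, xy=np.tile([5.0, 5.0], (10, 1)))


@pytest.fixture(scope="session")
def injured_trackset(geometry):
    return gen_tracks(
        SynthSpec(seed=11, motion_model="directed_oscillator", n_tracks=20,
                  geometry=geometry)
    )


def random_walk_set(n_tracks: int, n_steps: int, step_sigma: float, seed: int,
                    dt: float = 1.0) -> TrackSet:
    """Seeded 2D random walks with per-axis step sd ``step_sigma``."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_steps + 1, dtype=float) * dt
    tracks = []
    for i in range(n_tracks):
        steps = rng.normal(0, step_sigma, size=(n_steps, 2))
        pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        tracks.append(Track(track_id=f"rw{i}", t=t, xy=pos))
    return TrackSet(tracks, frame_interval=dt)


def frechet_brute_force(P, Q):
    """Independent oracle: minimum over all monotone couplings of the max
    pairwise distance, by explicit path enumeration over the lattice."""
    P, Q = np.asarray(P, float), np.asarray(Q, float)
    d = np.linalg.norm(P[:, None, :] - Q[None, :, :], axis=-1)
    n, m = d.shape
    best = [np.inf]

    def walk(i, j, cur):
        cur = max(cur, d[i, j])
        if cur >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cur
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            ii, jj = i + di, j + dj
            if ii < n and jj < m:
                walk(ii, jj, cur)

    walk(0, 0, 0.0)
    return best[0]


def still_params(**overrides):
    """Simulator parameters with all locomotion off so only pair forces act."""
    from tectal import MechanicsParams

    p = MechanicsParams()
    p.migration_speed = {"neuron": 0.0, "microglia": 0.0, "skin": 0.0}
    for k, v in overrides.items():
        setattr(p, k, v)
    return p


def make_sim_state(pos, kind, params, seed=0):
    """Hand-built simulator state for force/step tests."""
    from tectal.sim import SimState

    pos = np.asarray(pos, float)
    kind = np.asarray(kind, int)
    radius = params.arrays()["radius"][kind]
    n = len(pos)
    return SimState(
        pos=pos.copy(),
        kind=kind,
        radius=radius,
        motility_dir=np.tile([1.0, 0.0], (n, 1)),
        motility_timer=np.full(n, 1e9),
        rng=np.random.default_rng(seed),
    )
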