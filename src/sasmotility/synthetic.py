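"""Seeded generators of 3D cell tracks and cell masks.

The track generator is a two-state (motile/arrested) persistent random walk:
per frame the cell switches state via a Markov chain, draws a speed from a
state-specific truncated normal, and turns with von Mises–Fisher persistence
about its previous direction, optionally mixed with a sign-symmetric bias
along an anatomical axis (long-range movement in *both* directions along the
rostro-caudal axis, not advection toward one end).  Dedicated modes cover the
limiting behaviors: ``ballistic`` straight runs, isotropic ``brownian``
walks, vessel-hugging ``vessel_following`` cells confined to a shell around
the nearest vessel surface, and ``swarming`` cells harmonically pulled back
toward their starting point.

All randomness flows from a single cohort seed through per-track
``numpy.random.SeedSequence`` substreams (``SeedSequence(seed).spawn``), so
cohorts are bit-reproducible and any individual track can be regenerated in
isolation from (seed, track index).

The mask generator builds spherical cells with radial Gaussian protrusion
bumps on a voxel grid, for curvature-based morphometry with ground truth
known by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace
from typing import Sequence

import numpy as np

from .classify import nearest_surface_pullback, vessel_distances
from .track_model import ImagingConfig, TimePoint, Track, VesselGeometry

MODES = ("two_state", "ballistic", "brownian", "vessel_following", "swarming")


@dataclass(frozen=True)
class SyntheticParams:
    """Full parameterization of the track generator.

    Speeds are μm/min; probabilities are per frame.  ``kappa`` is the
    von Mises–Fisher concentration of each new step direction about the
    previous one (0 = isotropic, larger = straighter).  ``drift_bias``
    ∈ [0, 1] mixes the persistent direction with a per-track random sign
    along ``drift_axis``; 1 with large ``kappa`` degenerates to ballistic
    motion along the axis.  ``shell_um`` is the confinement distance from
    the vessel surface in ``vessel_following`` mode and ``swarm_strength``
    the per-frame fractional pull toward the starting point in ``swarming``
    mode.
    """

    v_motile_mean: float = 6.0
    v_motile_sd: float = 2.0
    v_arrest_mean: float = 0.0
    v_arrest_sd: float = 0.0
    p_stop: float = 0.1
    p_go: float = 0.3
    kappa: float = 0.0
    drift_axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    drift_bias: float = 0.0
    mode: str = "two_state"
    n_tracks: int = 100
    n_points: int = 49
    frame_interval: float = 37.5   # s
    seed: int = 0
    shell_um: float = 5.0
    swarm_strength: float = 0.2
    cell_type: str = "synthetic"
    group: str = "CTRL"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; one of {MODES}")
        for p in (self.p_stop, self.p_go, self.drift_bias):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for v in (self.v_motile_mean, self.v_motile_sd,
                  self.v_arrest_mean, self.v_arrest_sd):
            if v < 0:
                raise ValueError("speeds and their SDs must be >= 0")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        ax = np.asarray(self.drift_axis, dtype=float)
        n = np.linalg.norm(ax)
        if not n > 0:
            raise ValueError("drift_axis must be non-zero")
        object.__setattr__(self, "drift_axis", tuple(ax / n))

    @property
    def arrested_fraction(self) -> float:
        """Stationary arrested probability of the state Markov chain,
        p_stop / (p_stop + p_go); 0 if the chain never switches."""
        s = self.p_stop + self.p_go
        return self.p_stop / s if s > 0 else 0.0


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int) -> np.ndarray:
    """Normal(mean, sd) truncated at 0 by rejection (exact, not clipped)."""
    if sd == 0.0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    bad = out < 0
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < 0
    return out


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    """Uniform direction on the unit sphere."""
    w = rng.uniform(-1.0, 1.0)
    phi = rng.uniform(0.0, 2.0 * math.pi)
    s = math.sqrt(max(0.0, 1.0 - w * w))
    return np.array([s * math.cos(phi), s * math.sin(phi), w])


def _vmf_step(rng: np.random.Generator, mu: np.ndarray,
              kappa: float) -> np.ndarray:
    """One von Mises–Fisher draw on S² about mean direction ``mu``.

    Uses the closed-form inverse CDF of the cosine for the 3D case:
    w = 1 + log(u + (1−u)e^{−2κ}) / κ.  κ=0 is exactly isotropic; κ=inf
    returns ``mu``.
    """
    if kappa == 0.0:
        return _random_unit(rng)
    if math.isinf(kappa):
        return mu.copy()
    u = rng.uniform()
    w = 1.0 + math.log(u + (1.0 - u) * math.exp(-2.0 * kappa)) / kappa
    w = min(1.0, max(-1.0, w))
    # orthonormal frame about mu
    helper = np.array([1.0, 0.0, 0.0]) if abs(mu[0]) < 0.9 \
        else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(mu, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(mu, e1)
    phi = rng.uniform(0.0, 2.0 * math.pi)
    s = math.sqrt(max(0.0, 1.0 - w * w))
    return w * mu + s * (math.cos(phi) * e1 + math.sin(phi) * e2)


def _generate_track(rng: np.random.Generator, params: SyntheticParams,
                    field: ImagingConfig,
                    vessels: VesselGeometry | None,
                    track_id: str, field_id: str) -> Track:
    p = params
    n_steps = p.n_points - 1
    dims = np.asarray(field.volume_dims)
    pos = rng.uniform(0.0, 1.0, 3) * dims
    axis = np.asarray(p.drift_axis)
    drift_sign = 1.0 if rng.uniform() < 0.5 else -1.0

    if p.mode == "vessel_following":
        if vessels is None or vessels.is_empty:
            raise ValueError("vessel_following mode requires vessel geometry")
        pos = nearest_surface_pullback(pos[None, :], vessels, p.shell_um)[0]

    start = pos.copy()
    dt_min = p.frame_interval / 60.0

    if p.mode == "ballistic":
        direction = _random_unit(rng)
        step = direction * p.v_motile_mean * dt_min
        positions = pos + np.arange(p.n_points)[:, None] * step
        states = np.ones(n_steps, dtype=bool)
    elif (p.mode == "brownian" and p.kappa == 0.0 and p.drift_bias == 0.0
          and p.p_stop == 0.0):
        # isotropic non-switching walk: all steps drawn at once
        speeds = _truncated_normal(rng, p.v_motile_mean, p.v_motile_sd,
                                   n_steps)
        w = rng.uniform(-1.0, 1.0, n_steps)
        phi = rng.uniform(0.0, 2.0 * math.pi, n_steps)
        s = np.sqrt(np.maximum(0.0, 1.0 - w * w))
        dirs = np.column_stack([s * np.cos(phi), s * np.sin(phi), w])
        steps = dirs * (speeds * dt_min)[:, None]
        positions = pos + np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        states = np.ones(n_steps, dtype=bool)
    else:
        # state sequence: True = motile; initial state from the stationary law
        motile = rng.uniform() >= p.arrested_fraction
        switch_u = rng.uniform(size=n_steps)
        states = np.empty(n_steps, dtype=bool)
        for i in range(n_steps):
            states[i] = motile
            if motile:
                motile = switch_u[i] >= p.p_stop
            else:
                motile = switch_u[i] < p.p_go
        speeds = np.where(
            states,
            _truncated_normal(rng, p.v_motile_mean, p.v_motile_sd, n_steps),
            _truncated_normal(rng, p.v_arrest_mean, p.v_arrest_sd, n_steps),
        )
        positions = np.empty((p.n_points, 3))
        positions[0] = pos
        direction = _random_unit(rng)
        for i in range(n_steps):
            direction = _vmf_step(rng, direction, p.kappa)
            if p.drift_bias > 0.0:
                mixed = ((1.0 - p.drift_bias) * direction
                         + p.drift_bias * drift_sign * axis)
                norm = np.linalg.norm(mixed)
                if norm > 1e-12:
                    direction = mixed / norm
            nxt = positions[i] + direction * speeds[i] * dt_min
            if p.mode == "swarming":
                nxt = nxt + p.swarm_strength * (start - nxt)
            elif p.mode == "vessel_following":
                nxt = nearest_surface_pullback(nxt[None, :], vessels,
                                               p.shell_um)[0]
            positions[i + 1] = nxt

    times = np.arange(p.n_points) * p.frame_interval
    pts = [TimePoint(t=float(t), x=float(x), y=float(y), z=float(z))
           for t, (x, y, z) in zip(times, positions)]
    tr = Track(track_id=track_id, cell_type=p.cell_type, field_id=field_id,
               group=p.group, points=pts)
    tr.state_sequence = states  # ground-truth motile flags, for validation
    return tr


def generate_cohort(
    params: SyntheticParams,
    field: ImagingConfig = ImagingConfig(),
    vessels: VesselGeometry | None = None,
    field_id: str = "F1",
) -> list[Track]:
    """Generate ``params.n_tracks`` tracks, deterministically given the seed.

    Initial positions are uniform in the field volume; positions are not
    confined to the field afterwards (cells may wander out, as real cells
    leave the imaging volume).
    """
    if params.mode == "vessel_following" and (vessels is None
                                              or vessels.is_empty):
        raise ValueError("vessel_following mode requires non-empty vessels")
    children = np.random.SeedSequence(params.seed).spawn(params.n_tracks)
    return [
        _generate_track(np.random.Generator(np.random.PCG64(children[i])),
                        params, field, vessels,
                        track_id=f"T{i:04d}", field_id=field_id)
        for i in range(params.n_tracks)
    ]


def generate_fields(
    params: SyntheticParams,
    n_fields: int,
    field: ImagingConfig = ImagingConfig(),
    vessels: VesselGeometry | None = None,
) -> list[Track]:
    """Split a cohort across ``n_fields`` imaging fields (round-robin),
    using per-field seeds derived from the cohort seed."""
    tracks: list[Track] = []
    per = params.n_tracks // n_fields
    for k in range(n_fields):
        sub = replace(params, n_tracks=per,
                      seed=int(np.random.SeedSequence(
                          [params.seed, k]).generate_state(1)[0] % (2**31)))
        for tr in generate_cohort(sub, field, vessels, field_id=f"F{k + 1}"):
            tr.track_id = f"F{k + 1}_{tr.track_id}"
            tracks.append(tr)
    return tracks


# ---------------------------------------------------------------------------
# cell masks
# ---------------------------------------------------------------------------

def generate_cell_mask(
    radius: float,
    n_protrusions: int,
    protrusion_height: float,
    voxel: float,
    seed: int = 0,
    bump_width: float = 0.35,
    cell_id: str = "C1",
):
    """Binary voxel mask of a sphere with ``n_protrusions`` radial Gaussian
    bumps, for morphometry with known ground truth.

    The local surface radius is r(θ) = radius + Σ_k h·exp(−θ_k²/(2σ²)) with
    θ_k the angle to bump direction k and σ = ``bump_width`` (radians).
    Bump directions are rejection-sampled with pairwise angular separation
    ≥ 4σ (twice the 2σ bump width); if that cannot be met a generation error
    is raised.  Deterministic given the seed.
    """
    from .morphology import CellMask  # local import: morphology is downstream

    if radius <= 2 * voxel:
        raise ValueError("radius must exceed 2 voxels for a resolvable mask")
    rng = np.random.default_rng(seed)
    min_sep = 4.0 * bump_width
    dirs: list[np.ndarray] = []
    attempts = 0
    while len(dirs) < n_protrusions:
        cand = _random_unit(rng)
        if all(math.acos(min(1.0, max(-1.0, float(cand @ d)))) >= min_sep
               for d in dirs):
            dirs.append(cand)
        attempts += 1
        if attempts > 10_000:
            raise ValueError(
                f"cannot place {n_protrusions} protrusions at >= "
                f"{min_sep:.2f} rad separation")

    extent = radius + protrusion_height + 2 * voxel
    n = int(math.ceil(2 * extent / voxel))
    coords = (np.arange(n) + 0.5) * voxel - extent
    X, Y, Z = np.meshgrid(coords, coords, coords, indexing="ij")
    r = np.sqrt(X**2 + Y**2 + Z**2)
    local_radius = np.full_like(r, radius)
    if n_protrusions and protrusion_height > 0:
        with np.errstate(invalid="ignore", divide="ignore"):
            inv_r = np.where(r > 1e-9, 1.0 / r, 0.0)
        for d in dirs:
            cosang = (X * d[0] + Y * d[1] + Z * d[2]) * inv_r
            ang = np.arccos(np.clip(cosang, -1.0, 1.0))
            local_radius = local_radius + protrusion_height * np.exp(
                -(ang**2) / (2.0 * bump_width**2))
    occ = r <= local_radius
    return CellMask(occupancy=occ, voxel_size=(voxel, voxel, voxel),
                    cell_id=cell_id)
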