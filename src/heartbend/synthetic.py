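"""Seeded generator of synthetic heart-tube track datasets.

Emulates the acquisition regime of the looping time-lapses (~28–38 hpf,
one full stack every ≈13 min) on a simplified two-chamber geometry: three
coaxial cylindrical segments joined on a common axis — ventricle, AV canal
(the hinge) and atrium — with cells as points on the lateral surfaces
(the myocardium is an epithelial shell, so no wall thickness is modeled).

Imposed kinematics, applied in a fixed order per frame:

1. chamber *spin* about the instantaneous segment axis (ω_ventricle,
   ω_atrium in degrees/hour, constant or piecewise-constant),
2. planar *bending*: the atrium segment swings about a hinge axis through
   the AV-canal centroid, perpendicular to both chamber axes (the
   ventricle is held fixed in space, one hinge degree of freedom),
3. whole-heart *drift* (linear translation, µm/hour),
4. isotropic Gaussian positional *noise*,
5. per-cell track *truncation* (dropout).

Cells are placed in antipodal pairs on each cylinder surface, so with the
(even) default per-region counts every region centroid lies exactly on
its segment axis. The imposed spin and bend are then recovered exactly by
the unfolding pipeline in the noise-free case, which is what makes the
generator usable as ground truth for parameter-recovery and
confound-rejection tests. Odd counts leave an O(radius/n) centroid
offset, noted in the docs.

All randomness flows from a single integer seed through named, spawned
child streams (placement, noise, dropout), so a seed fixes the entire
output byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .track_io import (
    ATRIUM,
    AVCANAL,
    DEFAULT_FRAME_PERIOD_HOURS,
    VENTRICLE,
    TrackSet,
    write_tracks,
)

__all__ = ["SyntheticHeartParams", "GroundTruth", "generate", "make_fixture_suite"]

#: ω specification: a constant (deg/h) or a piecewise-constant profile given
#: as a sorted sequence of (start_hour, omega) breakpoints, first start at 0.
OmegaSpec = "float | list[tuple[float, float]]"


@dataclass(frozen=True)
class SyntheticHeartParams:
    """Geometry, kinematics and acquisition parameters of a synthetic heart.

    Defaults emulate a wild-type-scale movie: 46 frames at 13 min ≈ 9.75 h,
    60/20/60 cells in ventricle/AV canal/atrium, chamber radius 25 µm,
    AV-canal radius 12 µm, segment lengths 60/20/60 µm, positional noise
    σ = 1 µm. Spins default to zero; scenario constructors set them.
    """

    n_ventricle: int = 60
    n_avcanal: int = 20
    n_atrium: int = 60
    radius_chamber_um: float = 25.0
    radius_avcanal_um: float = 12.0
    length_ventricle_um: float = 60.0
    length_avcanal_um: float = 20.0
    length_atrium_um: float = 60.0
    n_frames: int = 46
    frame_period_hours: float = DEFAULT_FRAME_PERIOD_HOURS
    omega_ventricle: object = 0.0   # OmegaSpec, deg/h
    omega_atrium: object = 0.0      # OmegaSpec, deg/h
    bend_rate_deg_per_h: float = 0.0
    drift_um_per_h: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sigma_um: float = 0.0
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_ventricle", "n_avcanal", "n_atrium", "n_frames"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "radius_chamber_um", "radius_avcanal_um", "length_ventricle_um",
            "length_avcanal_um", "length_atrium_um", "noise_sigma_um",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.frame_period_hours <= 0:
            raise ValueError("frame_period_hours must be positive")
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must be a probability")
        for radius, length, label in (
            (self.radius_chamber_um, self.length_ventricle_um, "ventricle"),
            (self.radius_avcanal_um, self.length_avcanal_um, "avcanal"),
            (self.radius_chamber_um, self.length_atrium_um, "atrium"),
        ):
            if length > 0 and radius > 10 * length:
                raise ValueError(
                    f"impossible geometry: {label} radius {radius} um exceeds "
                    f"10x segment length {length} um"
                )

    @property
    def span_hours(self) -> float:
        """Total imaged time span (n_frames − 1 intervals)."""
        return (self.n_frames - 1) * self.frame_period_hours

    def to_dict(self) -> dict:
        d = asdict(self)
        d["drift_um_per_h"] = list(self.drift_um_per_h)
        for key in ("omega_ventricle", "omega_atrium"):
            if not np.isscalar(d[key]):
                d[key] = [list(p) for p in d[key]]
        return d


def _spin_angle(omega, t_hours: np.ndarray) -> np.ndarray:
    """Cumulative spin angle (degrees) at each time for an ω specification."""
    t = np.asarray(t_hours, dtype=float)
    if np.isscalar(omega):
        return float(omega) * t
    pieces = sorted((float(s), float(w)) for s, w in omega)
    if not pieces or pieces[0][0] != 0.0:
        raise ValueError("piecewise omega must start at hour 0")
    out = np.zeros_like(t)
    for k, (start, w) in enumerate(pieces):
        end = pieces[k + 1][0] if k + 1 < len(pieces) else np.inf
        out += w * np.clip(t - start, 0.0, end - start)
    return out


@dataclass
class GroundTruth:
    """The imposed kinematics of a generated heart, frame by frame.

    Spin angles follow the measurement convention of the analysis: each
    chamber's angle is about the unit axis pointing from the AV canal
    toward that chamber, positive counterclockwise seen from the axis tip.
    """

    t_hours: np.ndarray
    spin_ventricle_deg: np.ndarray
    spin_atrium_deg: np.ndarray
    hinge_angle_deg: np.ndarray
    drift_um: np.ndarray                 # (n_frames, 3)
    params: SyntheticHeartParams

    @property
    def theta_ventricle_end_deg(self) -> float:
        return float(self.spin_ventricle_deg[-1])

    @property
    def theta_atrium_end_deg(self) -> float:
        return float(self.spin_atrium_deg[-1])

    @property
    def twist_end_deg(self) -> float:
        """Imposed final twisting angle Θ_atrium − Θ_ventricle."""
        return self.theta_atrium_end_deg - self.theta_ventricle_end_deg

    def to_dict(self) -> dict:
        return {
            "t_hours": self.t_hours.tolist(),
            "spin_ventricle_deg": self.spin_ventricle_deg.tolist(),
            "spin_atrium_deg": self.spin_atrium_deg.tolist(),
            "hinge_angle_deg": self.hinge_angle_deg.tolist(),
            "drift_um": self.drift_um.tolist(),
            "params": self.params.to_dict(),
        }

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")


def _paired_surface_points(
    rng: np.random.Generator, n: int, radius: float, x_lo: float, x_hi: float
) -> np.ndarray:
    """n points on the lateral surface of a cylinder along x, in antipodal pairs.

    Pairs share an axial position and sit at angles φ and φ+π, so for even
    n the centroid lies exactly on the cylinder axis.
    """
    n_pairs, odd = divmod(n, 2)
    x = rng.uniform(x_lo, x_hi, size=n_pairs + odd)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n_pairs + odd)
    pts = np.empty((n, 3))
    base = np.column_stack([x, radius * np.cos(phi), radius * np.sin(phi)])
    pts[: n_pairs + odd] = base
    if n_pairs:
        anti = base[:n_pairs].copy()
        anti[:, 1:] *= -1.0
        pts[n_pairs + odd:] = anti
    return pts


def generate(params: SyntheticHeartParams) -> tuple[TrackSet, GroundTruth]:
    """Generate one synthetic heart movie and its ground truth.

    Rest geometry (frame 0, before drift/noise): the AV-canal cylinder is
    centered on the origin along +x, the ventricle extends in +x, the
    atrium in −x. The AV→ventricle axis is +x and the AV→atrium axis −x.
    """
    p = params
    ss = np.random.SeedSequence(p.seed)
    rng_place, rng_noise, rng_drop = (np.random.default_rng(s) for s in ss.spawn(3))

    half_av = p.length_avcanal_um / 2.0
    rest = {
        VENTRICLE: _paired_surface_points(
            rng_place, p.n_ventricle, p.radius_chamber_um,
            half_av, half_av + p.length_ventricle_um),
        AVCANAL: _paired_surface_points(
            rng_place, p.n_avcanal, p.radius_avcanal_um, -half_av, half_av),
        ATRIUM: _paired_surface_points(
            rng_place, p.n_atrium, p.radius_chamber_um,
            -half_av - p.length_atrium_um, -half_av),
    }
    av_centroid0 = rest[AVCANAL].mean(axis=0)

    t_hours = np.arange(p.n_frames) * p.frame_period_hours
    spin_v = _spin_angle(p.omega_ventricle, t_hours)
    spin_a = _spin_angle(p.omega_atrium, t_hours)
    hinge = p.bend_rate_deg_per_h * t_hours
    drift = np.outer(t_hours, np.asarray(p.drift_um_per_h, dtype=float))

    x_hat = np.array([1.0, 0.0, 0.0])
    z_hat = np.array([0.0, 0.0, 1.0])

    rows = []
    track_ids = {
        VENTRICLE: [f"ven{i:03d}" for i in range(p.n_ventricle)],
        AVCANAL: [f"avc{i:03d}" for i in range(p.n_avcanal)],
        ATRIUM: [f"atr{i:03d}" for i in range(p.n_atrium)],
    }
    # per-cell truncation frame (inclusive-exclusive upper bound)
    cutoff = {}
    for region in (VENTRICLE, AVCANAL, ATRIUM):
        for tid in track_ids[region]:
            if p.dropout > 0 and rng_drop.uniform() < p.dropout:
                cutoff[tid] = int(rng_drop.integers(1, p.n_frames))
            else:
                cutoff[tid] = p.n_frames

    for k in range(p.n_frames):
        # spin about the rest segment axes (x line); bending afterwards
        # carries the spun atrium with it, i.e. spin acts about the
        # instantaneous (bent) axis
        rot_v = Rotation.from_rotvec(np.deg2rad(spin_v[k]) * x_hat)
        rot_a = Rotation.from_rotvec(np.deg2rad(spin_a[k]) * (-x_hat))
        bend = Rotation.from_rotvec(np.deg2rad(hinge[k]) * z_hat)
        frame_pos = {
            VENTRICLE: rot_v.apply(rest[VENTRICLE]),
            AVCANAL: rest[AVCANAL],
            # hinge axis passes through the AV-canal centroid
            ATRIUM: bend.apply(rot_a.apply(rest[ATRIUM]) - av_centroid0)
            + av_centroid0,
        }
        for region in (VENTRICLE, AVCANAL, ATRIUM):
            pos = frame_pos[region] + drift[k]
            if p.noise_sigma_um > 0:
                pos = pos + rng_noise.normal(0.0, p.noise_sigma_um, size=pos.shape)
            for tid, (x, y, z) in zip(track_ids[region], pos):
                if k < cutoff[tid]:
                    rows.append((tid, k, t_hours[k], x, y, z, region))

    records = pd.DataFrame(
        rows,
        columns=["track_id", "t_index", "t_hours", "x_um", "y_um", "z_um", "region"],
    )
    ts = TrackSet(
        records=records,
        frame_period_hours=p.frame_period_hours,
        provenance=f"synthetic heart (seed={p.seed})",
    )
    gt = GroundTruth(
        t_hours=t_hours,
        spin_ventricle_deg=spin_v,
        spin_atrium_deg=spin_a,
        hinge_angle_deg=hinge,
        drift_um=drift,
        params=p,
    )
    return ts, gt


# ---------------------------------------------------------------------------
# named scenarios
# ---------------------------------------------------------------------------

def wt_like_params(seed: int = 0, **overrides) -> SyntheticHeartParams:
    """Wild-type-like heart: opposite chamber spins (ω_V = −8, ω_A = +6 °/h)."""
    kw = dict(omega_ventricle=-8.0, omega_atrium=6.0, noise_sigma_um=1.0, seed=seed)
    kw.update(overrides)
    return SyntheticHeartParams(**kw)


def oug_like_params(seed: int = 0, **overrides) -> SyntheticHeartParams:
    """Looping-mutant-like heart: no imposed spin, noise only."""
    kw = dict(omega_ventricle=0.0, omega_atrium=0.0, noise_sigma_um=1.0, seed=seed)
    kw.update(overrides)
    return SyntheticHeartParams(**kw)


def bending_only_params(
    seed: int = 0, total_bend_deg: float = 30.0, **overrides
) -> SyntheticHeartParams:
    """Pure planar buckling: the hinge swings (default 30° over the movie),
    no spin, no noise — the confound the unfolding step must reject."""
    base = SyntheticHeartParams(seed=seed)
    kw = dict(
        bend_rate_deg_per_h=total_bend_deg / base.span_hours,
        noise_sigma_um=0.0,
        seed=seed,
    )
    kw.update(overrides)
    return SyntheticHeartParams(**kw)


def drift_only_params(seed: int = 0, **overrides) -> SyntheticHeartParams:
    """Whole-heart translation drift only (2, −1, 0.5 µm/h), no spin, no noise."""
    kw = dict(drift_um_per_h=(2.0, -1.0, 0.5), noise_sigma_um=0.0, seed=seed)
    kw.update(overrides)
    return SyntheticHeartParams(**kw)


def noise_sweep_params(seed: int = 0, **overrides) -> SyntheticHeartParams:
    """Null heart at doubled positional noise (σ = 2 µm)."""
    kw = dict(noise_sigma_um=2.0, seed=seed)
    kw.update(overrides)
    return SyntheticHeartParams(**kw)


SCENARIOS = {
    "wt_like": wt_like_params,
    "oug_like": oug_like_params,
    "bending_only": bending_only_params,
    "drift_only": drift_only_params,
    "noise_sweep": noise_sweep_params,
}


def make_fixture_suite(out_dir, seed: int = 0) -> list[str]:
    """Write the named scenario fixtures: one track CSV + one ground-truth
    JSON sidecar per scenario. Returns the file names written."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    written = []
    for name, make in SCENARIOS.items():
        ts, gt = generate(make(seed=seed))
        csv_path = os.path.join(out_dir, f"{name}.csv")
        gt_path = os.path.join(out_dir, f"{name}.groundtruth.json")
        write_tracks(ts, csv_path)
        gt.write(gt_path)
        written += [f"{name}.csv", f"{name}.groundtruth.json"]
    return written
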