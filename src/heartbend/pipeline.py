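"""Hinge-rooted computational unfolding and chamber-rotation statistics.

The core procedure that turns raw 3D+t cardiomyocyte tracks into chamber
rotation and heart-tube twisting measurements:

1. **Rooting** — at every timepoint, translate all cells so the centroid of
   the atrioventricular (AV) canal sits at the origin. This removes residual
   whole-heart drift.
2. **Unfolding** — per timepoint, rigidly rotate the entire ventricle (and,
   separately, the entire atrium) about the origin by the minimal rotation
   that brings the current chamber axis onto its first-frame direction. The
   AV canal acts as a hinge: its cells are translated but never rotated.
   After unfolding, planar bending of the tube is removed and only rotation
   of cells *about* the chamber axes remains.
3. **Rotation statistics** — for each cell present at two consecutive
   observed timepoints, the signed angle α subtended about the (shared,
   first-frame) chamber axis; per-interval chamber mean ᾱ; angular velocity
   ω = ᾱ/Δt; cumulative rotation Θ(t) = Σ ᾱ with Θ(t₀) = 0.
4. **Twisting** — T(t) = Θ_atrium(t) − Θ_ventricle(t), plus mean twisting
   velocity in tumbling 1.5 h windows.

A pure planar bend (hinge-angle change without axial spin) is exactly
undone by step 2 and therefore contributes no rotation — the property that
distinguishes chamber twisting from planar buckling of the tube.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .geometry import (
    AxisFrame,
    RigidRotation,
    EPS_PROJ_UM,
    centroid,
    chamber_axis,
    minimal_rotation,
    signed_angles_about_axis,
)
from .track_io import ATRIUM, AVCANAL, REGIONS, VENTRICLE, TrackSet, filter_min_length

logger = logging.getLogger("heartbend.pipeline")

__all__ = [
    "PipelineConfig",
    "AxisError",
    "AlignmentError",
    "UnfoldedTrackSet",
    "RotationSeries",
    "TwistSeries",
    "compute_axes",
    "root_and_unfold",
    "chamber_rotation",
    "windowed_angular_velocity",
    "twisting",
    "run_pipeline",
    "write_outputs",
]


class AxisError(ValueError):
    """A frame lacks the cells needed to define an axis."""


class AlignmentError(ValueError):
    """Two series share no common time grid."""


@dataclass
class PipelineConfig:
    """Tunable parameters of the analysis, all serializable.

    ``gap_policy``: how a cell observed at frames i and j > i+1 contributes.
    ``"scale"`` (default) spreads its angle over the spanned grid intervals
    in proportion to each interval's Δt (so Θ accumulates the full angle and
    ω stays per-hour consistent); ``"drop"`` ignores gapped pairs.

    ``view_from_outflow``: report angles with the outflow tract of the
    heart as the viewpoint (the biological convention: positive =
    anticlockwise seen from the outflow). The outflow lies beyond the
    ventricle, so looking from it along the ventricle axis toward the
    hinge coincides with the mathematical convention for the ventricle
    but reverses it for the atrium; the flag therefore flips the sign of
    every series measured about the atrium axis.
    """

    min_points: int = 15
    window_hours: float = 1.5
    eps_proj_um: float = EPS_PROJ_UM
    gap_policy: str = "scale"
    view_from_outflow: bool = False

    def __post_init__(self) -> None:
        if self.gap_policy not in ("scale", "drop"):
            raise ValueError("gap_policy must be 'scale' or 'drop'")
        if self.window_hours <= 0:
            raise ValueError("window_hours must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class UnfoldedTrackSet:
    """Tracks in the rooted, unfolded frame plus the transforms applied.

    ``transforms`` maps ``(t_index, chamber)`` to the applied
    ``(translation, RigidRotation)``; the translation (−AV centroid) is
    shared by all chambers of a frame, the rotation is identity for the
    AV canal. ``reference_axes`` is the first-frame :class:`AxisFrame`
    that every unfolded frame's axes coincide with.
    """

    records: pd.DataFrame
    transforms: dict[tuple[int, str], tuple[np.ndarray, RigidRotation]]
    reference_axes: AxisFrame
    frame_period_hours: float

    def positions(self, mask=None) -> np.ndarray:
        df = self.records if mask is None else self.records[mask]
        return df[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)


@dataclass
class RotationSeries:
    """Per-chamber rotation statistics on the inter-frame interval grid.

    Arrays are aligned per retained interval (intervals where no cell
    contributed are dropped with a warning): midpoint times, interval
    durations, chamber-mean angle ᾱ (degrees), angular velocity ω = ᾱ/Δt
    (degrees/hour), cumulative rotation Θ (degrees, Θ(t₀)=0 so
    ``cum_angle_deg[k] = Σ_{j≤k} mean_alpha_deg[j]``), and the number of
    contributing cells.
    """

    chamber: str
    axis_chamber: str  # chamber whose first-frame axis angles are measured about
    t0_hours: float
    t_mid_hours: np.ndarray
    dt_hours: np.ndarray
    mean_alpha_deg: np.ndarray
    omega_deg_per_h: np.ndarray
    cum_angle_deg: np.ndarray
    n_cells: np.ndarray

    @property
    def theta_end_deg(self) -> float:
        """Total cumulative rotation over the series, degrees."""
        return float(self.cum_angle_deg[-1]) if len(self.cum_angle_deg) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chamber": self.chamber,
                "t_hours": self.t_mid_hours,
                "mean_alpha_deg": self.mean_alpha_deg,
                "omega_deg_per_h": self.omega_deg_per_h,
                "cum_angle_deg": self.cum_angle_deg,
                "n_cells": self.n_cells,
            }
        )

    def flipped(self) -> "RotationSeries":
        """The same series under the opposite sign convention."""
        return RotationSeries(
            chamber=self.chamber,
            axis_chamber=self.axis_chamber,
            t0_hours=self.t0_hours,
            t_mid_hours=self.t_mid_hours,
            dt_hours=self.dt_hours,
            mean_alpha_deg=-self.mean_alpha_deg,
            omega_deg_per_h=-self.omega_deg_per_h,
            cum_angle_deg=-self.cum_angle_deg,
            n_cells=self.n_cells,
        )


@dataclass
class TwistSeries:
    """Twisting angle T(t) = Θ_atrium − Θ_ventricle and windowed twist velocity."""

    t_hours: np.ndarray          # common interval midpoints, T(t0)=0 prepended
    twist_angle_deg: np.ndarray
    windows: pd.DataFrame        # per-window mean of (ω_atrium − ω_ventricle)

    @property
    def twist_end_deg(self) -> float:
        return float(self.twist_angle_deg[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_hours": self.t_hours, "twist_angle_deg": self.twist_angle_deg}
        )


# ---------------------------------------------------------------------------
# step 1-2: axes, rooting, unfolding
# ---------------------------------------------------------------------------

def compute_axes(ts: TrackSet) -> list[AxisFrame]:
    """Per-frame AV centroid and AV→ventricle / AV→atrium unit axes.

    Every frame must contain at least one cell of each of the three
    regions; otherwise an :class:`AxisError` names the frame and region.
    """
    frames = []
    for t_idx, grp in ts.records.groupby("t_index", sort=True):
        by_region = {r: g[["x_um", "y_um", "z_um"]].to_numpy(float)
                     for r, g in grp.groupby("region")}
        for region in REGIONS:
            if region not in by_region:
                raise AxisError(f"frame {t_idx}: no cells in region {region!r}")
        av = centroid(by_region[AVCANAL])
        try:
            v_axis = chamber_axis(av, by_region[VENTRICLE])
            a_axis = chamber_axis(av, by_region[ATRIUM])
        except ValueError as exc:
            raise AxisError(f"frame {t_idx}: {exc}") from exc
        frames.append(
            AxisFrame(t_index=int(t_idx), av_centroid=av,
                      ventricle_axis=v_axis, atrium_axis=a_axis)
        )
    return frames


def root_and_unfold(ts: TrackSet) -> UnfoldedTrackSet:
    """Root the AV centroid at the origin and unfold both chambers.

    Per frame t: all positions are translated by −AV_centroid(t); then
    ventricle cells are rotated by the minimal rotation taking the frame's
    ventricle axis onto the first frame's, atrium cells likewise about the
    atrium axis, and AV-canal cells are left unrotated (they are the hinge).
    """
    axes = compute_axes(ts)
    ref = axes[0]
    ref_shifted = AxisFrame(
        t_index=ref.t_index,
        av_centroid=np.zeros(3),
        ventricle_axis=ref.ventricle_axis,
        atrium_axis=ref.atrium_axis,
    )
    df = ts.records.copy()
    pos = df[["x_um", "y_um", "z_um"]].to_numpy(float)
    out = np.empty_like(pos)
    region = df["region"].to_numpy()
    t_index = df["t_index"].to_numpy()
    transforms: dict[tuple[int, str], tuple[np.ndarray, RigidRotation]] = {}
    identity = RigidRotation(axis=np.array([0.0, 0.0, 1.0]), angle_deg=0.0)
    for frame in axes:
        translation = -frame.av_centroid
        rot = {
            VENTRICLE: minimal_rotation(frame.ventricle_axis, ref.ventricle_axis),
            ATRIUM: minimal_rotation(frame.atrium_axis, ref.atrium_axis),
            AVCANAL: identity,
        }
        in_frame = t_index == frame.t_index
        for chamber in REGIONS:
            transforms[(frame.t_index, chamber)] = (translation, rot[chamber])
            sel = in_frame & (region == chamber)
            if sel.any():
                out[sel] = (pos[sel] + translation) @ rot[chamber].matrix.T
    df[["x_um", "y_um", "z_um"]] = out
    return UnfoldedTrackSet(
        records=df,
        transforms=transforms,
        reference_axes=ref_shifted,
        frame_period_hours=ts.frame_period_hours,
    )


# ---------------------------------------------------------------------------
# step 3: per-interval rotation statistics
# ---------------------------------------------------------------------------

def _frame_grid(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Sorted unique (t_index, t_hours) of the observed frames."""
    grid = records.groupby("t_index", sort=True)["t_hours"].first()
    return grid.index.to_numpy(), grid.to_numpy(float)


def chamber_rotation(
    uts: UnfoldedTrackSet,
    chamber: str,
    reference_axis: np.ndarray | None = None,
    eps_proj: float = EPS_PROJ_UM,
    gap_policy: str = "scale",
    axis_chamber: str | None = None,
) -> RotationSeries:
    """Rotation statistics of one chamber about a first-frame chamber axis.

    For the ventricle/atrium the axis defaults to the chamber's own
    first-frame axis (after unfolding every frame's axis coincides with
    it). For the AV canal no own axis exists and ``reference_axis`` must
    be supplied explicitly (conventionally computed once about each
    chamber axis and reported separately).

    Cells with perpendicular offset below ``eps_proj`` µm at either end of
    an interval are skipped for that interval. Intervals to which no cell
    contributes are dropped from the series with a warning and excluded
    from the Θ accumulation.
    """
    if chamber not in REGIONS:
        raise ValueError(f"unknown chamber {chamber!r}")
    if reference_axis is None:
        if chamber == VENTRICLE:
            reference_axis = uts.reference_axes.ventricle_axis
            axis_chamber = axis_chamber or VENTRICLE
        elif chamber == ATRIUM:
            reference_axis = uts.reference_axes.atrium_axis
            axis_chamber = axis_chamber or ATRIUM
        else:
            raise ValueError(
                "AV-canal rotation needs an explicit reference_axis "
                "(it is the hinge and has no axis of its own)"
            )
    axis = np.asarray(reference_axis, dtype=float)
    axis_chamber = axis_chamber or chamber

    recs = uts.records[uts.records["region"] == chamber]
    t_grid, t_hours = _frame_grid(uts.records)
    if len(t_grid) < 2:
        raise ValueError("need at least two frames for rotation statistics")
    grid_pos = {int(t): k for k, t in enumerate(t_grid)}
    dt = np.diff(t_hours)                      # per grid interval
    t_mid = 0.5 * (t_hours[:-1] + t_hours[1:])
    n_int = len(dt)

    recs = recs.sort_values(["track_id", "t_index"], kind="mergesort")
    pos = recs[["x_um", "y_um", "z_um"]].to_numpy(float)
    k_obs = recs["t_index"].map(grid_pos).to_numpy()
    same_track = recs["track_id"].to_numpy()[1:] == recs["track_id"].to_numpy()[:-1]
    alphas = signed_angles_about_axis(pos[:-1], pos[1:], axis, eps_proj=eps_proj)
    i_grid, j_grid = k_obs[:-1], k_obs[1:]

    alpha_sum = np.zeros(n_int)
    cell_count = np.zeros(n_int, dtype=int)
    n_skipped = 0
    for p in np.nonzero(same_track)[0]:
        a = alphas[p]
        if np.isnan(a):
            n_skipped += 1
            continue
        i, j = int(i_grid[p]), int(j_grid[p])
        if j == i + 1:
            alpha_sum[i] += a
            cell_count[i] += 1
        elif gap_policy == "scale":
            span = t_hours[j] - t_hours[i]
            for m in range(i, j):
                alpha_sum[m] += a * (dt[m] / span)
                cell_count[m] += 1
        # gap_policy == "drop": ignore the gapped pair
    if n_skipped:
        logger.info(
            "%s: skipped %d cell/frame pairs with undefined angle "
            "(perpendicular offset <= %.3g um)", chamber, n_skipped, eps_proj
        )

    keep = cell_count >= 1
    n_empty = int((~keep).sum())
    if n_empty:
        logger.warning(
            "%s: %d interval(s) had no contributing cells; "
            "excluded from cumulative rotation", chamber, n_empty
        )
    mean_alpha = alpha_sum[keep] / cell_count[keep]
    return RotationSeries(
        chamber=chamber,
        axis_chamber=axis_chamber,
        t0_hours=float(t_hours[0]),
        t_mid_hours=t_mid[keep],
        dt_hours=dt[keep],
        mean_alpha_deg=mean_alpha,
        omega_deg_per_h=mean_alpha / dt[keep],
        cum_angle_deg=np.cumsum(mean_alpha),
        n_cells=cell_count[keep],
    )


# ---------------------------------------------------------------------------
# step 4: windows and twisting
# ---------------------------------------------------------------------------

def _window_means(
    t_mid: np.ndarray, values: np.ndarray, t0: float, window_hours: float
) -> pd.DataFrame:
    """Mean of ``values`` over tumbling windows anchored at ``t0``.

    A window's value is the mean over intervals whose midpoint lies in
    [start, end); empty windows carry NaN. The trailing window is flagged
    ``partial`` when the series ends before the window does.
    """
    if len(t_mid) == 0:
        raise ValueError("empty series")
    t_end = t_mid[-1]
    n_win = int(np.ceil((t_end - t0) / window_hours + 1e-12))
    n_win = max(n_win, 1)
    rows = []
    for k in range(n_win):
        lo = t0 + k * window_hours
        hi = lo + window_hours
        sel = (t_mid >= lo) & (t_mid < hi)
        rows.append(
            {
                "window_start_hours": lo,
                "window_end_hours": hi,
                "value": float(np.mean(values[sel])) if sel.any() else np.nan,
                "n_intervals": int(sel.sum()),
                "partial": bool(hi > t_end + 1e-12),
            }
        )
    return pd.DataFrame(rows)


def windowed_angular_velocity(
    rs: RotationSeries, window_hours: float = 1.5
) -> pd.DataFrame:
    """Mean angular velocity per tumbling window (default 1.5 h), anchored at t₀."""
    if window_hours <= 0:
        raise ValueError("window_hours must be positive")
    out = _window_means(rs.t_mid_hours, rs.omega_deg_per_h, rs.t0_hours, window_hours)
    return out.rename(columns={"value": "omega_mean_deg_per_h"})


def twisting(
    rs_ventricle: RotationSeries,
    rs_atrium: RotationSeries,
    window_hours: float = 1.5,
) -> TwistSeries:
    """Twisting angle T(t) = Θ_atrium(t) − Θ_ventricle(t) and windowed velocity.

    The two series are aligned on the intersection of their interval
    midpoints; disjoint grids raise :class:`AlignmentError`. T(t₀) = 0 by
    construction (prepended at the shared start time).
    """
    common, ia, iv = np.intersect1d(
        np.round(rs_atrium.t_mid_hours, 9),
        np.round(rs_ventricle.t_mid_hours, 9),
        return_indices=True,
    )
    if len(common) == 0:
        raise AlignmentError("ventricle and atrium series share no timepoints")
    theta_a = np.cumsum(rs_atrium.mean_alpha_deg[ia])
    theta_v = np.cumsum(rs_ventricle.mean_alpha_deg[iv])
    twist = theta_a - theta_v
    t0 = min(rs_atrium.t0_hours, rs_ventricle.t0_hours)
    d_omega = rs_atrium.omega_deg_per_h[ia] - rs_ventricle.omega_deg_per_h[iv]
    windows = _window_means(common, d_omega, t0, window_hours).rename(
        columns={"value": "twist_velocity_deg_per_h"}
    )
    return TwistSeries(
        t_hours=np.concatenate(([t0], common)),
        twist_angle_deg=np.concatenate(([0.0], twist)),
        windows=windows,
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_pipeline(ts: TrackSet, config: PipelineConfig | None = None) -> dict:
    """Filter, unfold and measure: the full track-to-twist analysis.

    Returns a dict with keys ``ventricle``, ``atrium`` (RotationSeries),
    ``avcanal_about_ventricle_axis``, ``avcanal_about_atrium_axis``
    (the hinge measured about either chamber axis, reported separately),
    ``twist`` (TwistSeries), ``windows`` (per-chamber window tables),
    ``report`` (filter/skip counts) and ``unfolded``.
    """
    config = config or PipelineConfig()
    n_before = ts.n_tracks
    ts = filter_min_length(ts, min_points=config.min_points)
    n_after = ts.n_tracks
    uts = root_and_unfold(ts)

    kw = dict(eps_proj=config.eps_proj_um, gap_policy=config.gap_policy)
    series = {
        VENTRICLE: chamber_rotation(uts, VENTRICLE, **kw),
        ATRIUM: chamber_rotation(uts, ATRIUM, **kw),
        "avcanal_about_ventricle_axis": chamber_rotation(
            uts, AVCANAL, reference_axis=uts.reference_axes.ventricle_axis,
            axis_chamber=VENTRICLE, **kw,
        ),
        "avcanal_about_atrium_axis": chamber_rotation(
            uts, AVCANAL, reference_axis=uts.reference_axes.atrium_axis,
            axis_chamber=ATRIUM, **kw,
        ),
    }
    if config.view_from_outflow:
        # outflow viewpoint reverses every series measured about the atrium axis
        for key, rs in series.items():
            if rs.axis_chamber == ATRIUM:
                series[key] = rs.flipped()
    twist = twisting(series[VENTRICLE], series[ATRIUM], config.window_hours)
    windows = {
        key: windowed_angular_velocity(rs, config.window_hours)
        for key, rs in series.items()
    }
    report = {
        "tracks_before_filter": n_before,
        "tracks_after_filter": n_after,
        "tracks_dropped": n_before - n_after,
        "min_points": config.min_points,
        "config": config.to_dict(),
    }
    return {**series, "twist": twist, "windows": windows,
            "report": report, "unfolded": uts}


def write_outputs(results: dict, out_dir) -> list[str]:
    """Write tidy CSV outputs and a plain-text run log; returns file names.

    Everything is assembled in memory first, so a failure in any series
    leaves no partial output on disk.
    """
    import os

    payload: dict[str, pd.DataFrame] = {}
    for key in (VENTRICLE, ATRIUM,
                "avcanal_about_ventricle_axis", "avcanal_about_atrium_axis"):
        payload[f"rotation_{key}.csv"] = results[key].to_frame()
        payload[f"windows_{key}.csv"] = results["windows"][key]
    payload["twist.csv"] = results["twist"].to_frame()
    payload["twist_windows.csv"] = results["twist"].windows

    os.makedirs(out_dir, exist_ok=True)
    written = []
    for name, df in payload.items():
        df.to_csv(os.path.join(out_dir, name), index=False, lineterminator="\n")
        written.append(name)
    rep = results["report"]
    log_lines = [
        f"tracks before filter: {rep['tracks_before_filter']}",
        f"tracks after filter (min_points={rep['min_points']}): "
        f"{rep['tracks_after_filter']}",
        f"tracks dropped: {rep['tracks_dropped']}",
        f"config: {rep['config']}",
    ]
    with open(os.path.join(out_dir, "run_log.txt"), "w", encoding="utf-8") as fh:
        fh.write("\n".join(log_lines) + "\n")
    written.append("run_log.txt")
    return written
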