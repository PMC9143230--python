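"""Hydration-shell dynamics: occupancy, residence times, MSD and the
Einstein-relation diffusion coefficient.

A water is "in the shell" at a frame when the minimum-image distance from
its oxygen to the nearest membrane atom is at most the cutoff (default
0.5 nm).  Residence events are maximal in-shell runs, optionally bridging
gaps up to ``gap_tolerance`` frames; event duration is run length (frames,
bridged gaps included) times the frame spacing.  Events touching either
trajectory boundary are flagged censored — their true duration is only
bounded below — and are excluded from the headline mean by default.

MSD(tau) averages squared displacements of unwrapped coordinates over all
molecules and sliding time origins (FFT-accelerated); restricting origins
to in-shell molecules (membership at the origin, tracked regardless of
later exit) gives the hydration-layer MSD.  The Einstein relation in 3D,
D = slope/6 of the linear MSD regime, converts to the customary 1e-5
cm^2/s scale; the uncertainty is the standard deviation of D over
contiguous trajectory blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import Trajectory, TrajectoryError, minimum_image, parse_frame_range
from .select import AtomSelection
from .units import NM2_PER_PS_TO_1E5_CM2_PER_S


class DynamicsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# occupancy


@dataclass
class OccupancyMatrix:
    """Boolean in-shell membership, waters x frames."""

    matrix: np.ndarray  # (n_waters, n_frames) bool
    water_atom_ids: np.ndarray
    times: np.ndarray  # ps, aligned with columns
    cutoff: float
    reference: str = "nearest membrane atom"

    @property
    def n_waters(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]

    @property
    def dt(self) -> float:
        if self.n_frames < 2:
            raise DynamicsError("dt undefined for a single-frame occupancy")
        return float(self.times[1] - self.times[0])


def shell_occupancy(
    traj: Trajectory,
    waters: AtomSelection,
    membrane: AtomSelection,
    cutoff: float = 0.5,
    frame_range=None,
) -> OccupancyMatrix:
    """Occupancy by distance to the nearest membrane atom (periodic)."""
    if cutoff <= 0:
        raise DynamicsError("cutoff must be > 0")
    if waters.empty or membrane.empty:
        raise DynamicsError("shell_occupancy requires non-empty selections")
    frames = traj.frame_slice(parse_frame_range(frame_range, traj.n_frames))
    occ = np.empty((len(waters.atom_ids), len(frames)), dtype=bool)
    for k, f in enumerate(frames):
        box = traj.boxes[f]
        tree = cKDTree(traj.coords[f, membrane.atom_ids], boxsize=box)
        d, _ = tree.query(traj.coords[f, waters.atom_ids], k=1)
        occ[:, k] = d <= cutoff
    return OccupancyMatrix(
        matrix=occ,
        water_atom_ids=waters.atom_ids.copy(),
        times=traj.times[frames].copy(),
        cutoff=cutoff,
    )


# ---------------------------------------------------------------------------
# residence times


@dataclass
class ResidenceEvent:
    water: int  # row index into the occupancy matrix
    start_frame: int
    n_frames: int
    duration: float  # ps
    censored: bool


@dataclass
class ResidenceResult:
    events: list[ResidenceEvent]
    mean_residence: float  # ps, over uncensored events (see censored_only)
    censored_count: int
    censored_only: bool  # True when no event is uncensored and the mean
    # falls back to the (lower-bound) censored durations
    gap_tolerance: int
    dt: float

    @property
    def durations(self) -> np.ndarray:
        return np.array([e.duration for e in self.events])

    @property
    def uncensored_durations(self) -> np.ndarray:
        return np.array([e.duration for e in self.events if not e.censored])

    def mean_over(self, censoring: str = "exclude") -> float:
        """Mean duration: 'exclude' drops censored events, 'all' keeps them."""
        d = self.durations if censoring == "all" else self.uncensored_durations
        return float(d.mean()) if len(d) else float("nan")


def _runs(row: np.ndarray, gap_tolerance: int) -> list[tuple[int, int]]:
    """Maximal (start, end) inclusive index runs of True, bridging gaps of
    at most ``gap_tolerance`` False frames."""
    idx = np.nonzero(row)[0]
    if len(idx) == 0:
        return []
    runs: list[tuple[int, int]] = []
    start = prev = int(idx[0])
    for i in idx[1:]:
        if i - prev - 1 <= gap_tolerance:
            prev = int(i)
        else:
            runs.append((start, prev))
            start = prev = int(i)
    runs.append((start, prev))
    return runs


def residence_times(occupancy: OccupancyMatrix, gap_tolerance: int = 0) -> ResidenceResult:
    """Residence events and their mean duration.

    Duration = (end - start + 1) * dt with bridged gap frames counted.
    Events whose run touches frame 0 or the final frame are censored; the
    headline mean excludes them unless nothing else remains, in which case
    it falls back to the censored durations and says so.
    """
    if gap_tolerance < 0:
        raise DynamicsError("gap_tolerance must be >= 0")
    dt = occupancy.dt
    last = occupancy.n_frames - 1
    events: list[ResidenceEvent] = []
    for w in range(occupancy.n_waters):
        for start, end in _runs(occupancy.matrix[w], gap_tolerance):
            events.append(
                ResidenceEvent(
                    water=w,
                    start_frame=start,
                    n_frames=end - start + 1,
                    duration=(end - start + 1) * dt,
                    censored=(start == 0 or end == last),
                )
            )
    uncensored = [e.duration for e in events if not e.censored]
    censored_count = sum(e.censored for e in events)
    if uncensored:
        mean = float(np.mean(uncensored))
        censored_only = False
    elif events:
        mean = float(np.mean([e.duration for e in events]))
        censored_only = True
    else:
        mean = float("nan")
        censored_only = False
    return ResidenceResult(
        events=events,
        mean_residence=mean,
        censored_count=censored_count,
        censored_only=censored_only,
        gap_tolerance=gap_tolerance,
        dt=dt,
    )


def residence_distribution(result: ResidenceResult, bin_width: float = 2.0) -> pd.DataFrame:
    """Normalised histogram (probability density) of event durations.

    Uses uncensored events; falls back to all events when every event is
    censored.  An empty event list yields an empty frame (with a warning).
    """
    if bin_width <= 0:
        raise DynamicsError("bin_width must be > 0")
    d = result.uncensored_durations
    if len(d) == 0:
        d = result.durations
    if len(d) == 0:
        import warnings

        warnings.warn("no residence events; empty distribution", stacklevel=2)
        return pd.DataFrame({"duration_ps": [], "density": []})
    hi = np.ceil(d.max() / bin_width) * bin_width
    edges = np.arange(0.0, hi + bin_width, bin_width)
    dens, _ = np.histogram(d, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"duration_ps": centers, "density": dens})


# ---------------------------------------------------------------------------
# MSD and diffusion


def unwrap(traj: Trajectory, atom_ids: np.ndarray) -> np.ndarray:
    """Unwrap selected atoms by cumulative minimum-image increments.

    A per-frame displacement at (or numerically indistinguishable from)
    half the box on any axis means the frame spacing is too coarse to
    unwrap unambiguously; that is a hard error naming the frame.
    """
    idx = np.asarray(atom_ids, dtype=np.int64)
    wrapped = traj.coords[:, idx, :]
    box = traj.boxes[:, None, :]
    raw = np.diff(wrapped, axis=0)
    steps = minimum_image(raw, box[1:])
    too_big = np.abs(steps) >= 0.5 * box[1:] * (1 - 1e-9)
    if np.any(too_big):
        f = int(np.nonzero(too_big.any(axis=(1, 2)))[0][0]) + 1
        raise TrajectoryError(
            f"displacement into frame {f} reaches half the box; "
            "frame spacing too coarse to unwrap"
        )
    out = np.empty_like(wrapped)
    out[0] = wrapped[0]
    np.cumsum(steps, axis=0, out=out[1:])
    out[1:] += wrapped[0]
    return out


def _msd_fft(pos: np.ndarray, weights: np.ndarray | None = None):
    """Weighted-origin MSD for positions (T, N, 3).

    weights (T, N) selects/weights time origins (1 everywhere = the plain
    all-origins estimator).  Returns (numerator, counts) per lag, summed
    over particles, so callers can combine blocks before dividing.
    """
    T, N, _ = pos.shape
    w = np.ones((T, N)) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (T, N):
        raise DynamicsError("weights must have shape (n_frames, n_particles)")
    nfft = 1 << int(np.ceil(np.log2(2 * T)))
    D = np.einsum("tnd,tnd->tn", pos, pos)  # |r(t)|^2
    wD = w * D
    # A(tau) = sum_{t<=T-1-tau} w(t) D(t); counts(tau) likewise for w
    A = np.cumsum(wD, axis=0)[np.arange(T - 1, -1, -1), :]
    counts = np.cumsum(w, axis=0)[np.arange(T - 1, -1, -1), :]
    # B(tau) = sum_t w(t) D(t+tau) via cross-correlation
    fw = np.fft.rfft(w, n=nfft, axis=0)
    fD = np.fft.rfft(D, n=nfft, axis=0)
    B = np.fft.irfft(np.conj(fw) * fD, n=nfft, axis=0)[:T]
    # C(tau) = sum_t w(t) r(t).r(t+tau), per dimension
    C = np.zeros((T, N))
    for d in range(3):
        fa = np.fft.rfft(w * pos[:, :, d], n=nfft, axis=0)
        fb = np.fft.rfft(pos[:, :, d], n=nfft, axis=0)
        C += np.fft.irfft(np.conj(fa) * fb, n=nfft, axis=0)[:T]
    num = A + B - 2.0 * C
    return num.sum(axis=1), counts.sum(axis=1)


@dataclass
class MsdResult:
    lags: np.ndarray  # ps, starting at 0
    msd: np.ndarray  # nm^2
    dt: float
    n_particles: int
    block_curves: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_ps": self.lags, "msd_nm2": self.msd})


def msd(
    traj: Trajectory,
    selection: AtomSelection,
    max_lag: float | None = None,
    origin_stride: int = 1,
    occupancy: OccupancyMatrix | None = None,
    n_blocks: int = 5,
) -> MsdResult:
    """MSD over molecules and sliding origins, FFT-accelerated.

    ``occupancy`` (rows aligned with the selection) restricts time origins
    to frames where the molecule is in the hydration shell; displacements
    are still tracked after it leaves.  ``origin_stride`` keeps every
    k-th origin.  ``n_blocks`` contiguous time blocks are analysed
    alongside the full curve for the block-uncertainty estimate.
    """
    if selection.empty:
        raise DynamicsError("msd requires a non-empty selection")
    if traj.n_frames < 3:
        raise DynamicsError("msd requires at least 3 frames")
    pos = unwrap(traj, selection.atom_ids)
    T = pos.shape[0]
    dt = traj.dt
    weights = None
    if occupancy is not None or origin_stride > 1:
        weights = np.ones((T, pos.shape[1]))
        if occupancy is not None:
            if occupancy.matrix.shape != (pos.shape[1], T):
                raise DynamicsError("occupancy shape does not match selection/frames")
            weights *= occupancy.matrix.T
        if origin_stride > 1:
            mask = np.zeros(T)
            mask[::origin_stride] = 1.0
            weights *= mask[:, None]
    num, cnt = _msd_fft(pos, weights)
    n_lags = T if max_lag is None else min(T, int(round(max_lag / dt)) + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        curve = np.where(cnt[:n_lags] > 0, num[:n_lags] / np.maximum(cnt[:n_lags], 1e-300), np.nan)
    curve[0] = 0.0

    blocks: list[tuple[np.ndarray, np.ndarray]] = []
    if n_blocks >= 2 and T // n_blocks >= 3:
        size = T // n_blocks
        for b in range(n_blocks):
            sl = slice(b * size, (b + 1) * size)
            wb = None if weights is None else weights[sl]
            nb, cb = _msd_fft(pos[sl], wb)
            with np.errstate(invalid="ignore", divide="ignore"):
                mb = np.where(cb > 0, nb / np.maximum(cb, 1e-300), np.nan)
            mb[0] = 0.0
            blocks.append((np.arange(size) * dt, mb))
    return MsdResult(
        lags=np.arange(n_lags) * dt,
        msd=curve,
        dt=dt,
        n_particles=pos.shape[1],
        block_curves=blocks,
        params={
            "selection": selection.expression,
            "origin_stride": origin_stride,
            "hydration_layer": occupancy is not None,
            "n_blocks": n_blocks,
        },
    )


def _fit_slope(lags: np.ndarray, values: np.ndarray, lo: float, hi: float):
    mask = (lags >= lo) & (lags <= hi) & np.isfinite(values)
    if mask.sum() < 3:
        return None
    x = lags[mask]
    y = values[mask]
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), r2


@dataclass
class DiffusionResult:
    D: float  # 1e-5 cm^2/s
    uncertainty: float  # same units; SD over trajectory blocks
    fit_window: tuple[float, float]  # ps
    r_squared: float
    block_Ds: np.ndarray

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "D_1e-5_cm2_s": [self.D],
                "uncertainty": [self.uncertainty],
                "fit_lo_ps": [self.fit_window[0]],
                "fit_hi_ps": [self.fit_window[1]],
                "r_squared": [self.r_squared],
            }
        )


def diffusion_coefficient(
    result: MsdResult, fit_window: tuple[float, float] = (0.1, 0.5)
) -> DiffusionResult:
    """Einstein-relation D from the MSD slope over a lag-fraction window.

    ``fit_window`` is a fraction of the maximum lag (default 10-50%,
    avoiding the short-time regime and the noisy tail).  D = slope/6,
    reported in 1e-5 cm^2/s.  The uncertainty is the SD of D refit on
    each trajectory block; blocks whose lag range cannot cover at least
    3 fit points are skipped.
    """
    f_lo, f_hi = fit_window
    if not (0 <= f_lo < f_hi <= 1):
        raise DynamicsError("fit_window fractions must satisfy 0 <= lo < hi <= 1")
    max_lag = result.lags[-1]
    lo, hi = f_lo * max_lag, f_hi * max_lag
    fit = _fit_slope(result.lags, result.msd, lo, hi)
    if fit is None:
        raise DynamicsError("fewer than 3 MSD points in the fit window")
    slope, r2 = fit
    d_value = slope / 6.0 * NM2_PER_PS_TO_1E5_CM2_PER_S
    block_ds = []
    for blags, bmsd in result.block_curves:
        bmax = blags[-1]
        bfit = _fit_slope(blags, bmsd, f_lo * bmax, f_hi * bmax)
        if bfit is not None:
            block_ds.append(bfit[0] / 6.0 * NM2_PER_PS_TO_1E5_CM2_PER_S)
    block_ds_arr = np.array(block_ds)
    unc = float(np.std(block_ds_arr, ddof=1)) if len(block_ds_arr) >= 3 else float("nan")
    return DiffusionResult(
        D=float(max(d_value, 0.0)),
        uncertainty=unc,
        fit_window=(lo, hi),
        r_squared=r2,
        block_Ds=block_ds_arr,
    )
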