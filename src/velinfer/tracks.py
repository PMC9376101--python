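"""Track-level data model: filtering, drift correction, masking,
population classification, multi-lag displacement extraction and lifetime
summaries.

Tracks are time-ordered subpixel localizations of fluorescent puncta,
in nm, indexed by acquisition frame.  Cells are partitioned into four
mutually exclusive subcellular populations by combining a stress-fiber
mask (brightest 2% of an actin time projection) and an adhesion mask
(Otsu threshold of a background-subtracted adhesion-marker image) within
the cell mask (mean threshold of the marker image): stress fiber only,
adhesion only, both, or neither (cortical).  A track belongs to the
population of its first localization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage import filters, morphology, restoration

__all__ = [
    "POPULATIONS",
    "Track",
    "RegionMasks",
    "MultiLagDisplacements",
    "LifetimeFit",
    "read_tracks",
    "write_tracks",
    "filter_spot_fits",
    "subtract_drift",
    "top_percent_mask",
    "build_masks",
    "classify_tracks",
    "compute_displacements",
    "fit_lifetimes",
]

POPULATIONS = ("stress_fiber", "adhesion", "sf_and_adhesion", "cortical")


@dataclass(frozen=True)
class Track:
    """One punctum's time-ordered localizations and metadata."""

    track_id: int
    frames: np.ndarray  # strictly increasing integer frame indices
    x: np.ndarray  # nm
    y: np.ndarray  # nm
    sigma_fit: np.ndarray | None = None  # fitted spot width, nm
    center_shift_px: np.ndarray | None = None
    population: str = "unclassified"
    frame_interval: float = 2.0  # s

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.size and np.any(np.diff(frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("coordinates must be finite")

    @property
    def lifetime(self) -> float:
        """Track duration (last - first frame) * frame_interval, in s."""
        return float((self.frames[-1] - self.frames[0]) * self.frame_interval)

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class RegionMasks:
    """Boolean region rasters on the image grid.

    ``cytosol`` is derived: inside the cell but in neither the adhesion
    nor the stress-fiber mask.
    """

    cell: np.ndarray
    adhesion: np.ndarray
    stress_fiber: np.ndarray
    pixel_size: float = 64.0  # nm
    cytosol: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not (self.cell.shape == self.adhesion.shape == self.stress_fiber.shape):
            raise ValueError("masks must share shape")
        object.__setattr__(
            self, "cytosol", self.cell & ~self.adhesion & ~self.stress_fiber
        )


@dataclass
class MultiLagDisplacements:
    """Measured distances grouped by (population, observation timescale)."""

    displacements: dict[tuple[str, float], np.ndarray]
    frame_interval: float = 2.0

    def taus(self) -> list[float]:
        return sorted({tau for _, tau in self.displacements})

    def populations(self) -> list[str]:
        return sorted({pop for pop, _ in self.displacements})

    def get(self, population: str, tau: float) -> np.ndarray:
        return self.displacements.get((population, float(tau)), np.empty(0))

    def by_tau(self, population: str) -> dict[float, np.ndarray]:
        return {
            tau: d for (pop, tau), d in self.displacements.items() if pop == population
        }

    def pooled(self) -> dict[float, np.ndarray]:
        """All populations pooled, keyed by timescale."""
        out: dict[float, np.ndarray] = {}
        for (_, tau), d in self.displacements.items():
            out.setdefault(tau, []).append(d)
        return {tau: np.concatenate(v) for tau, v in out.items()}


def read_tracks(path, frame_interval: float = 2.0) -> list[Track]:
    """Read tracks from CSV (track_id, frame, x_nm, y_nm[, sigma_fit_nm, center_shift_px])."""
    df = pd.read_csv(path)
    required = {"track_id", "frame", "x_nm", "y_nm"}
    if not required <= set(df.columns):
        raise ValueError(f"track CSV must contain columns {sorted(required)}")
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        tracks.append(
            Track(
                track_id=int(tid),
                frames=g["frame"].to_numpy(dtype=int),
                x=g["x_nm"].to_numpy(dtype=float),
                y=g["y_nm"].to_numpy(dtype=float),
                sigma_fit=g["sigma_fit_nm"].to_numpy(dtype=float)
                if "sigma_fit_nm" in g
                else None,
                center_shift_px=g["center_shift_px"].to_numpy(dtype=float)
                if "center_shift_px" in g
                else None,
                population=str(g["population"].iloc[0]) if "population" in g else "unclassified",
                frame_interval=frame_interval,
            )
        )
    return tracks


def write_tracks(tracks: list[Track], path) -> None:
    rows = []
    for t in tracks:
        for i in range(len(t)):
            row = {
                "track_id": t.track_id,
                "frame": int(t.frames[i]),
                "x_nm": t.x[i],
                "y_nm": t.y[i],
                "population": t.population,
            }
            if t.sigma_fit is not None:
                row["sigma_fit_nm"] = t.sigma_fit[i]
            if t.center_shift_px is not None:
                row["center_shift_px"] = t.center_shift_px[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def filter_spot_fits(
    center_shift_px,
    sigma_fit_nm,
    wavelength_nm: float = 675.0,
    na: float = 1.49,
    max_shift_px: float = 2.0,
    sigma_factor: float = 1.5,
) -> np.ndarray:
    """Accept/reject localizations by subpixel-fit quality.

    A localization is accepted iff its fitted center moved at most
    ``max_shift_px`` pixels from the detected center and its fitted spot
    width lies within a factor of ``sigma_factor`` of the diffraction
    scale ``sigma0 = 0.25 * wavelength / NA``.
    """
    if wavelength_nm <= 0 or na <= 0:
        raise ValueError("wavelength and NA must be positive")
    shift = np.asarray(center_shift_px, dtype=float)
    sig = np.asarray(sigma_fit_nm, dtype=float)
    sigma0 = 0.25 * wavelength_nm / na
    return (shift <= max_shift_px) & (sig >= sigma0 / sigma_factor) & (sig <= sigma0 * sigma_factor)


def subtract_drift(tracks: list[Track], drift: pd.DataFrame) -> list[Track]:
    """Subtract per-frame stage drift (columns frame, dx_nm, dy_nm) from positions."""
    drift = drift.set_index("frame") if "frame" in drift.columns else drift
    out = []
    for t in tracks:
        missing = set(t.frames.tolist()) - set(drift.index.tolist())
        if missing:
            raise ValueError(f"drift table missing frames {sorted(missing)[:5]}")
        dx = drift.loc[t.frames, "dx_nm"].to_numpy(dtype=float)
        dy = drift.loc[t.frames, "dy_nm"].to_numpy(dtype=float)
        out.append(replace(t, x=t.x - dx, y=t.y - dy))
    return out


def top_percent_mask(image: np.ndarray, percent: float = 2.0) -> np.ndarray:
    """Mask of the brightest ``percent`` % of pixels."""
    image = np.asarray(image, dtype=float)
    thr = np.quantile(image, 1.0 - percent / 100.0)
    return image >= thr


def build_masks(
    adhesion_marker_image: np.ndarray,
    actin_projection_image: np.ndarray,
    pixel_size: float = 64.0,
    background_radius: float = 50.0,
    sf_percent: float = 2.0,
    smooth: bool = True,
) -> RegionMasks:
    """Derive cell/adhesion/stress-fiber masks from the two channel images.

    Cell: mean threshold of the adhesion-marker image (cytoplasmic signal
    outlines the cell), closed/opened to fill small holes and smooth the
    boundary.  Adhesion: Otsu threshold of the marker image after
    rolling-ball background subtraction (removes the diffuse cytoplasmic
    signal).  Stress fiber: brightest ``sf_percent`` % of the actin
    time-projection.  Cytosol follows by exclusion.
    """
    marker = np.asarray(adhesion_marker_image, dtype=float)
    actin = np.asarray(actin_projection_image, dtype=float)
    if marker.shape != actin.shape:
        raise ValueError("images must share shape")
    if np.ptp(marker) == 0 or np.ptp(actin) == 0:
        raise ValueError("constant image gives a degenerate threshold")

    cell = marker >= marker.mean()
    if smooth:
        footprint = morphology.disk(2)
        cell = morphology.binary_closing(cell, footprint)
        cell = morphology.binary_opening(cell, footprint)
        cell = morphology.remove_small_holes(cell, area_threshold=64)

    background = restoration.rolling_ball(marker, radius=background_radius)
    flattened = marker - background
    adhesion = (flattened > filters.threshold_otsu(flattened)) & cell

    stress_fiber = top_percent_mask(actin, sf_percent)
    return RegionMasks(cell=cell, adhesion=adhesion, stress_fiber=stress_fiber,
                       pixel_size=pixel_size)


def classify_tracks(tracks: list[Track], masks: RegionMasks) -> list[Track]:
    """Assign each track the population of its first localization's pixel.

    Pixel (0, 0) is centered at (0, 0) nm; lookup is by nearest pixel.
    First points outside the image or outside the cell mask are labeled
    ``unclassified``.  Relabeling is idempotent.
    """
    nrow, ncol = masks.cell.shape
    out = []
    for t in tracks:
        col = int(round(t.x[0] / masks.pixel_size))
        row = int(round(t.y[0] / masks.pixel_size))
        if not (0 <= row < nrow and 0 <= col < ncol) or not masks.cell[row, col]:
            label = "unclassified"
        else:
            sf = bool(masks.stress_fiber[row, col])
            ad = bool(masks.adhesion[row, col])
            if sf and ad:
                label = "sf_and_adhesion"
            elif sf:
                label = "stress_fiber"
            elif ad:
                label = "adhesion"
            else:
                label = "cortical"
        out.append(replace(t, population=label))
    return out


def compute_displacements(
    tracks: list[Track],
    max_lag_frames: int = 20,
    frame_interval: float | None = None,
    pairing: str = "all",
) -> MultiLagDisplacements:
    """Euclidean distances between localizations 1..max_lag frames apart.

    For each track and lag m, pairs of localizations whose frame indices
    differ by exactly m contribute one distance each, grouped by the
    track's population and the timescale tau = m * frame_interval.
    ``pairing='all'`` pools every such pair (overlapping pairs are
    statistically dependent); ``'nonoverlapping'`` keeps only disjoint
    pairs.
    """
    if pairing not in ("all", "nonoverlapping"):
        raise ValueError("pairing must be 'all' or 'nonoverlapping'")
    groups: dict[tuple[str, float], list[np.ndarray]] = {}
    dt = frame_interval
    for t in tracks:
        dt_t = t.frame_interval if frame_interval is None else frame_interval
        dt = dt_t
        index = {int(f): i for i, f in enumerate(t.frames)}
        for m in range(1, max_lag_frames + 1):
            tau = m * dt_t
            pairs = []
            used = -1
            for f, i in index.items():
                j = index.get(f + m)
                if j is None:
                    continue
                if pairing == "nonoverlapping" and f < used:
                    continue
                pairs.append((i, j))
                if pairing == "nonoverlapping":
                    used = f + m
            if not pairs:
                continue
            ii, jj = np.array(pairs).T
            d = np.hypot(t.x[jj] - t.x[ii], t.y[jj] - t.y[ii])
            groups.setdefault((t.population, float(tau)), []).append(d)
    merged = {k: np.concatenate(v) for k, v in groups.items()}
    return MultiLagDisplacements(displacements=merged, frame_interval=dt or 2.0)


@dataclass(frozen=True)
class LifetimeFit:
    mean: float  # s
    ci_95: tuple[float, float]
    n: int
    n_events: int  # uncensored
    flagged: bool = False
    note: str = ""


def fit_lifetimes(
    tracks_or_lifetimes,
    max_observation: float = 120.0,
    min_detectable: float | None = None,
    censored=None,
) -> LifetimeFit:
    """Censored-exponential MLE of the mean speckle lifetime.

    Lifetimes are modeled as exponential, right-censored at the
    observation window and left-truncated at the minimum detectable
    lifetime (memorylessness makes the truncation a simple shift).  A
    track is treated as censored when it persists to the end of the
    window.  Returns the mean lifetime with a normal-approximation CI on
    ``mean = sum(t_i - t_min) / n_events``.
    """
    if hasattr(tracks_or_lifetimes[0], "lifetime"):
        tracks = tracks_or_lifetimes
        lifetimes = np.array([t.lifetime for t in tracks])
        ends = np.array(
            [t.frames[-1] * t.frame_interval for t in tracks]
        )
        cens = ends >= max_observation - 1e-9 if censored is None else np.asarray(censored, bool)
    else:
        lifetimes = np.asarray(tracks_or_lifetimes, dtype=float)
        cens = (
            np.zeros(lifetimes.size, dtype=bool)
            if censored is None
            else np.asarray(censored, dtype=bool)
        )
    n = lifetimes.size
    if n < 50:
        warnings.warn(f"only {n} tracks; lifetime estimate will be unstable")
    t0 = float(lifetimes.min()) if min_detectable is None else float(min_detectable)
    n_events = int(np.sum(~cens))
    if n_events == 0:
        return LifetimeFit(np.nan, (np.nan, np.nan), n, 0, flagged=True,
                           note="all lifetimes censored")
    if np.ptp(lifetimes) == 0:
        return LifetimeFit(float(lifetimes[0]), (np.nan, np.nan), n, n_events,
                           flagged=True, note="degenerate: all lifetimes equal")
    mean = float(np.sum(lifetimes - t0) / n_events)
    se = mean / np.sqrt(n_events)
    z = 1.959963984540054
    return LifetimeFit(mean, (mean - z * se, mean + z * se), n, n_events)
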