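"""Otolith-based back-calculation of daily fish length and relative growth.

Daily standard length at increment *a* is back-calculated from cumulative
otolith radii with the biological-intercept proportionality model

    L_a = L_c + (O_a - O_c) * (L_c - L0) / (O_c - O0)

anchored at a species-level biological intercept (L0, O0).  Relative
growth is the daily proportional length increment (mm/mm/day) over the
final window (default 21 days) before capture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BackCalcParams",
    "OtolithTrack",
    "GrowthTrack",
    "PACIFIC_COD_INTERCEPT",
    "back_calculate_lengths",
    "relative_growth",
    "growth_track",
    "qc_replicate_reads",
    "tracks_from_table",
]


@dataclass(frozen=True)
class BackCalcParams:
    """Biological intercept: length (mm) and otolith radius (um) at the
    point where fish and otolith growth become proportional."""

    L0: float
    O0: float

    def __post_init__(self) -> None:
        if self.L0 <= 0 or self.O0 <= 0:
            raise ValueError("biological intercept must be positive")


#: Published biological intercept for Pacific cod (L0 mm, O0 um).
PACIFIC_COD_INTERCEPT = BackCalcParams(L0=3.9, O0=8.3)


@dataclass
class OtolithTrack:
    """Per-fish ordered cumulative increment radii plus capture anchors."""

    fish_id: str
    radii_um: np.ndarray
    radius_at_capture_um: float
    length_at_capture_mm: float

    def __post_init__(self) -> None:
        self.radii_um = np.asarray(self.radii_um, float)
        if np.any(np.diff(self.radii_um) <= 0):
            raise ValueError(f"fish {self.fish_id}: radii not strictly increasing")
        if np.any(self.radii_um > self.radius_at_capture_um + 1e-9):
            raise ValueError(
                f"fish {self.fish_id}: increment radius exceeds radius at capture"
            )


@dataclass
class GrowthTrack:
    fish_id: str
    lengths_mm: np.ndarray
    rel_growth: np.ndarray
    window: int
    truncated: bool = False
    increment_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.increment_index is None:
            n = len(self.rel_growth)
            # window indexing: 1..window with `window` = day before capture
            self.increment_index = np.arange(self.window - n + 1, self.window + 1)


def back_calculate_lengths(
    track: OtolithTrack, params: BackCalcParams = PACIFIC_COD_INTERCEPT
) -> np.ndarray:
    """Daily standard lengths (mm) for each increment radius of ``track``."""
    Oc, Lc = track.radius_at_capture_um, track.length_at_capture_mm
    if Oc <= params.O0:
        raise ValueError(
            f"fish {track.fish_id}: radius at capture {Oc} <= O0 {params.O0}"
        )
    if Lc <= params.L0:
        raise ValueError(
            f"fish {track.fish_id}: length at capture {Lc} <= L0 {params.L0}"
        )
    return Lc + (track.radii_um - Oc) * (Lc - params.L0) / (Oc - params.O0)


def relative_growth(lengths: np.ndarray, window: int = 21) -> np.ndarray:
    """Backward-difference daily relative growth g_t = (L_t - L_{t-1}) / L_{t-1}
    over the final ``window`` days; shorter inputs yield a truncated result."""
    lengths = np.asarray(lengths, float)
    if lengths.size < 2:
        raise ValueError("need at least two lengths to compute growth")
    g = np.diff(lengths) / lengths[:-1]
    return g[-window:]


def growth_track(
    track: OtolithTrack,
    params: BackCalcParams = PACIFIC_COD_INTERCEPT,
    window: int = 21,
) -> GrowthTrack:
    """Back-calculate lengths and derive the relative-growth window."""
    lengths = back_calculate_lengths(track, params)
    g = relative_growth(lengths, window)
    return GrowthTrack(
        fish_id=track.fish_id,
        lengths_mm=lengths[-(len(g) + 1) :],
        rel_growth=g,
        window=window,
        truncated=len(g) < window,
    )


def qc_replicate_reads(reads: pd.DataFrame, tolerance: float = 0.10) -> pd.DataFrame:
    """Flag fish whose replicate increment counts disagree.

    ``reads`` has columns fish_id, count (one row per independent read).
    Discrepancy is the relative range (max-min)/mean; fish above
    ``tolerance`` are flagged for revisit, single reads as unverifiable.
    No fish are discarded.
    """
    if not {"fish_id", "count"}.issubset(reads.columns):
        raise ValueError("reads table needs fish_id and count columns")
    rows = []
    for fid, grp in reads.groupby("fish_id", sort=True):
        c = grp["count"].to_numpy(float)
        if len(c) < 2:
            rows.append((fid, len(c), np.nan, True, "unverifiable"))
            continue
        disc = (c.max() - c.min()) / c.mean()
        rows.append((fid, len(c), disc, disc > tolerance, "revisit" if disc > tolerance else "pass"))
    return pd.DataFrame(
        rows, columns=["fish_id", "n_reads", "discrepancy", "flagged", "status"]
    )


def tracks_from_table(otoliths: pd.DataFrame, fish: pd.DataFrame) -> list[OtolithTrack]:
    """Assemble per-fish tracks from the otolith and fish tables."""
    lengths = fish.set_index("fish_id")["sl_mm"]
    tracks = []
    for fid, grp in otoliths.groupby("fish_id", sort=True):
        grp = grp.sort_values("increment_index")
        tracks.append(
            OtolithTrack(
                fish_id=str(fid),
                radii_um=grp["radius_um"].to_numpy(float),
                radius_at_capture_um=float(grp["radius_at_capture_um"].iloc[0]),
                length_at_capture_mm=float(lengths.loc[fid]),
            )
        )
    return tracks
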