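"""Super-enhancer prediction from H3K27ac peaks (ROSE-style).

The procedure: (1) stitch peaks within ``stitch_distance`` of each other into
candidate regions, (2) score each region by total ChIP signal minus total
input signal (CPM*bp, floored at 0), (3) rank regions by that net signal and
place the super-enhancer cutoff at the elbow of the ranked signal curve,
found geometrically: with the ranked values s_1 <= ... <= s_n and the global
slope m = (s_n - s_1)/(n - 1), the tangent point i* is the index whose
slope-m line leaves the most points strictly above it (ties -> largest i*,
the conservative choice).  Regions with net signal strictly greater than
s_{i*} are super-enhancers.

Total signal (density x width) rather than per-bp density is used for
ranking: wide stitched regions accumulating signal are exactly what
super-enhancers are, and a density rank would penalise them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .intervals import GeneRecord, GenomicInterval, SignalTrack


@dataclass
class SECallParameters:
    """Tunables of the super-enhancer caller.

    stitch_distance : bp
        Maximum gap between consecutive peaks merged into one region
        (default 12500, the published ROSE default).
    tss_exclusion_window : bp
        When > 0, peaks lying entirely within this distance of an annotated
        TSS are removed before stitching (ROSE's promoter exclusion);
        0 disables it (default).
    """

    stitch_distance: int = 12_500
    tss_exclusion_window: int = 0

    def __post_init__(self) -> None:
        if self.stitch_distance < 0 or self.tss_exclusion_window < 0:
            raise ValueError("distances must be >= 0")


@dataclass
class StitchedRegion:
    """A merged cluster of peaks; super-enhancer candidate."""

    interval: GenomicInterval
    constituent_peaks: list[GenomicInterval] = field(default_factory=list)
    chip_signal: float = 0.0
    input_signal: float = 0.0
    net_signal: float = 0.0
    rank: int = 0
    is_super: bool = False

    @property
    def center(self) -> int:
        """Floor midpoint of the stitched interval (the "SE center")."""
        return self.interval.center

    @property
    def region_id(self) -> str:
        iv = self.interval
        return f"{iv.chrom}:{iv.start}-{iv.end}"


def stitch_peaks(
    peaks: list[GenomicInterval], params: SECallParameters | None = None
) -> list[StitchedRegion]:
    """Merge peaks transitively whenever consecutive gaps are <= stitch_distance.

    Output regions are disjoint, sorted by (chrom, start), each spanning
    exactly min-start to max-end of its constituents; the gap between
    consecutive output regions on a chromosome exceeds the stitch distance.
    """
    params = params or SECallParameters()
    d = params.stitch_distance
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    regions: list[StitchedRegion] = []
    for chrom in sorted(by_chrom):
        chrom_peaks = sorted(by_chrom[chrom], key=lambda p: (p.start, p.end))
        cluster: list[GenomicInterval] = []
        cluster_end = -1
        for p in chrom_peaks:
            if cluster and p.start - cluster_end > d:
                regions.append(_make_region(chrom, cluster))
                cluster = []
                cluster_end = -1
            cluster.append(p)
            cluster_end = max(cluster_end, p.end)
        if cluster:
            regions.append(_make_region(chrom, cluster))
    return regions


def _make_region(chrom: str, cluster: list[GenomicInterval]) -> StitchedRegion:
    start = min(p.start for p in cluster)
    end = max(p.end for p in cluster)
    return StitchedRegion(GenomicInterval(chrom, start, end), list(cluster))


def exclude_tss_proximal(
    peaks: list[GenomicInterval], genes: list[GeneRecord], window: int
) -> list[GenomicInterval]:
    """Drop peaks fully contained in [TSS - window, TSS + window] of any gene."""
    if window <= 0:
        return list(peaks)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(
            (g.tss - window, g.tss + window + 1)
        )
    kept = []
    for p in peaks:
        spans = by_chrom.get(p.chrom, ())
        if any(s <= p.start and p.end <= e for s, e in spans):
            continue
        kept.append(p)
    return kept


def rank_regions(
    regions: list[StitchedRegion], chip: SignalTrack, input_track: SignalTrack
) -> list[StitchedRegion]:
    """Score regions by input-subtracted ChIP signal and rank them.

    net_signal = max(chip - input, 0): input can exceed ChIP in noise, and
    negative signal would break the cutoff geometry.  Regions are returned
    sorted by descending net signal (ties by (chrom, start) ascending) with
    ``rank`` 1..n.
    """
    scored = []
    for r in regions:
        chip_s = chip.region_signal(r.interval)
        input_s = input_track.region_signal(r.interval)
        scored.append(
            replace(
                r,
                chip_signal=chip_s,
                input_signal=input_s,
                net_signal=max(chip_s - input_s, 0.0),
            )
        )
    scored.sort(key=lambda r: (-r.net_signal, r.interval.chrom, r.interval.start))
    return [replace(r, rank=i + 1) for i, r in enumerate(scored)]


def call_cutoff(net_signals) -> float:
    """Super-enhancer threshold from an ascending-sorted signal vector.

    Geometry: global slope m = (s_n - s_1)/(n - 1); for each index i the
    line of slope m through (i, s_i) is considered and the points strictly
    above it are counted; the tangent index i* maximises that count, ties
    resolved to the largest i (most conservative threshold, which degenerates
    to "no super-enhancers" on linear or flat curves).  Returns s_{i*};
    regions with net signal strictly greater are super-enhancers.
    """
    s = np.asarray(net_signals, dtype=np.float64)
    n = s.size
    if n < 2:
        raise ValueError("insufficient regions: cutoff needs >= 2 signal values")
    if np.any(np.diff(s) < 0):
        raise ValueError("net_signals must be sorted ascending")
    m = (s[-1] - s[0]) / (n - 1)
    idx = np.arange(n, dtype=np.float64)
    # line through (i, s_i): value at j is s_i + m*(j - i)
    lines = s[:, None] + m * (idx[None, :] - idx[:, None])
    above_counts = (s[None, :] > lines).sum(axis=1)
    best = int(np.flatnonzero(above_counts == above_counts.max())[-1])
    return float(s[best])


def call_super_enhancers(
    peaks: list[GenomicInterval],
    chip: SignalTrack,
    input_track: SignalTrack,
    params: SECallParameters | None = None,
    genes: list[GeneRecord] | None = None,
) -> list[StitchedRegion]:
    """Full caller: stitch -> rank -> cutoff; returns regions sorted by rank.

    With fewer than two stitched regions no cutoff exists and nothing is
    flagged super (an empty peak list yields an empty result).
    """
    params = params or SECallParameters()
    if params.tss_exclusion_window > 0 and genes:
        peaks = exclude_tss_proximal(peaks, genes, params.tss_exclusion_window)
    regions = stitch_peaks(peaks, params)
    ranked = rank_regions(regions, chip, input_track)
    if len(ranked) >= 2:
        threshold = call_cutoff(sorted(r.net_signal for r in ranked))
        ranked = [replace(r, is_super=r.net_signal > threshold) for r in ranked]
    return ranked


SE_TABLE_COLUMNS = [
    "chrom",
    "start",
    "end",
    "n_constituents",
    "chip_signal",
    "input_signal",
    "net_signal",
    "rank",
    "is_super",
    "center",
]


def se_table(regions: list[StitchedRegion]) -> pd.DataFrame:
    """Ranked region table (one row per stitched region, rank order)."""
    rows = [
        {
            "chrom": r.interval.chrom,
            "start": r.interval.start,
            "end": r.interval.end,
            "n_constituents": len(r.constituent_peaks),
            "chip_signal": r.chip_signal,
            "input_signal": r.input_signal,
            "net_signal": r.net_signal,
            "rank": r.rank,
            "is_super": r.is_super,
            "center": r.center,
        }
        for r in sorted(regions, key=lambda r: r.rank)
    ]
    return pd.DataFrame(rows, columns=SE_TABLE_COLUMNS)


def regions_from_table(df: pd.DataFrame) -> list[StitchedRegion]:
    """Rebuild regions from a table written by :func:`se_table`.

    Constituent peak lists are not stored in the table and come back empty.
    """
    out = []
    for row in df.itertuples():
        out.append(
            StitchedRegion(
                GenomicInterval(row.chrom, int(row.start), int(row.end)),
                [],
                float(row.chip_signal),
                float(row.input_signal),
                float(row.net_signal),
                int(row.rank),
                bool(row.is_super),
            )
        )
    return out
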