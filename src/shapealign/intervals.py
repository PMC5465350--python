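"""Genomic interval handling: site containers, unique-site selection and null intervals.

Coordinates are 0-based, half-open throughout.  A width-``w`` window centred
on a peak maximum ``p`` is ``[p - w//2, p - w//2 + w)``; for odd ``w`` the
peak sits at the exact centre, for even ``w`` it sits just left of centre.
Strand is ignored everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Number of random null intervals drawn when none is requested explicitly.
DEFAULT_NULL_COUNT = 1500

#: Width (bp) of the per-site shape window; odd so the peak maximum is centred.
DEFAULT_SHAPE_WINDOW = 201

CLASS_LABELS = ("fast", "slow", "free_mnase", "random")


@dataclass(frozen=True)
class Site:
    """A binding site anchored on its peak-maximum coordinate."""

    chrom: str
    peak_max: int
    class_label: str
    site_id: str

    def __post_init__(self) -> None:
        if self.peak_max < 0:
            raise ValueError(f"site {self.site_id}: negative peak_max {self.peak_max}")

    def window(self, width: int) -> tuple[int, int]:
        start = self.peak_max - width // 2
        return start, start + width


@dataclass(frozen=True)
class GenomeIndex:
    """Chromosome names and lengths (stands in for an assembly's .fai)."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(set(self.chrom_names)):
            raise ValueError("duplicate chromosome names")
        if any(length <= 0 for length in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths))


def _validate_width(width: int) -> None:
    if int(width) != width or width <= 0:
        raise ValueError(f"window width must be a positive integer, got {width!r}")


def _check_unique_ids(sites: Sequence[Site]) -> None:
    ids = [s.site_id for s in sites]
    if len(ids) != len(set(ids)):
        raise ValueError("site_id values must be unique within a dataset")


def find_unique_sites(sites: Sequence[Site], width: int) -> list[Site]:
    """Return sites whose ``width``-bp windows overlap no other site's window.

    All classes are pooled: a site is discarded if its window shares even a
    single base with any other site's window, regardless of class.  Larger
    widths are more stringent, so the selected set shrinks (or stays equal)
    as ``width`` grows.  The result is sorted by (chrom, peak_max, site_id)
    and does not depend on the input order.
    """
    _validate_width(width)
    _check_unique_ids(sites)
    ordered = sorted(sites, key=lambda s: (s.chrom, s.peak_max, s.site_id))
    keep = [True] * len(ordered)
    for i in range(len(ordered) - 1):
        a, b = ordered[i], ordered[i + 1]
        if a.chrom != b.chrom:
            continue
        # Equal widths: only neighbours in sorted order can overlap.
        if b.window(width)[0] < a.window(width)[1]:
            keep[i] = False
            keep[i + 1] = False
    return [s for s, k in zip(ordered, keep) if k]


def select_alignable_sites(
    sites: Sequence[Site],
    genome: GenomeIndex,
    shape_window: int = DEFAULT_SHAPE_WINDOW,
) -> list[Site]:
    """Keep sites whose shape windows are pairwise disjoint and fully on-chromosome.

    Sites whose ``shape_window``-bp window runs off a chromosome end are
    dropped with a logged warning rather than clipped, so every retained
    site yields a complete shape matrix downstream.
    """
    _validate_width(shape_window)
    _check_unique_ids(sites)
    lengths = genome.lengths
    in_bounds = []
    for site in sorted(sites, key=lambda s: (s.chrom, s.peak_max, s.site_id)):
        if site.chrom not in lengths:
            raise ValueError(f"site {site.site_id}: unknown chromosome {site.chrom}")
        start, end = site.window(shape_window)
        if start < 0 or end > lengths[site.chrom]:
            logger.warning(
                "dropping site %s: %d-bp shape window [%d, %d) exits chromosome %s",
                site.site_id, shape_window, start, end, site.chrom,
            )
            continue
        in_bounds.append(site)
    keep = [True] * len(in_bounds)
    for i in range(len(in_bounds) - 1):
        a, b = in_bounds[i], in_bounds[i + 1]
        if a.chrom == b.chrom and b.window(shape_window)[0] < a.window(shape_window)[1]:
            keep[i] = False
            keep[i + 1] = False
    return [s for s, k in zip(in_bounds, keep) if k]


def _merge_intervals(intervals: Iterable[tuple[str, int, int]]) -> dict[str, np.ndarray]:
    """Merge possibly-overlapping (chrom, start, end) triples per chromosome."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(chrom, []).append((int(start), int(end)))
    merged: dict[str, np.ndarray] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out: list[list[int]] = []
        for start, end in ivs:
            if out and start <= out[-1][1]:
                out[-1][1] = max(out[-1][1], end)
            else:
                out.append([start, end])
        merged[chrom] = np.asarray(out, dtype=np.int64).reshape(-1, 2)
    return merged


def generate_null_intervals(
    genome: GenomeIndex,
    exclude: Iterable[tuple[str, int, int]],
    n: int = DEFAULT_NULL_COUNT,
    width: int = DEFAULT_SHAPE_WINDOW,
    seed: int | np.random.Generator = 0,
    max_attempt_factor: int = 1000,
) -> list[tuple[str, int, int]]:
    """Draw ``n`` random ``width``-bp intervals that avoid every excluded window.

    Placement is uniform over all valid start positions via rejection
    sampling; after ``max_attempt_factor * n`` draws without success the
    function raises rather than returning fewer intervals than requested.
    Null intervals may overlap one another (only exclusions are avoided).
    """
    _validate_width(width)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    merged = _merge_intervals(exclude)

    chroms = [c for c, length in genome.lengths.items() if length >= width]
    if not chroms:
        raise ValueError(f"no chromosome can hold a {width}-bp interval")
    n_starts = np.array([genome.lengths[c] - width + 1 for c in chroms], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(n_starts)])
    total = int(offsets[-1])

    accepted: list[tuple[str, int, int]] = []
    attempts = 0
    budget = max_attempt_factor * n
    batch = max(4 * n, 64)
    while len(accepted) < n:
        if attempts >= budget:
            raise RuntimeError(
                f"could not place {n} null intervals after {attempts} attempts; "
                "the permitted space is too small"
            )
        draws = rng.integers(0, total, size=min(batch, budget - attempts))
        attempts += len(draws)
        for flat in draws:
            ci = int(np.searchsorted(offsets, flat, side="right")) - 1
            chrom = chroms[ci]
            start = int(flat - offsets[ci])
            end = start + width
            ivs = merged.get(chrom)
            if ivs is not None and len(ivs):
                j = int(np.searchsorted(ivs[:, 0], end, side="left"))
                # overlap iff some exclusion with ex_start < end has ex_end > start
                if j > 0 and int(ivs[:j, 1].max()) > start:
                    continue
            accepted.append((chrom, start, end))
            if len(accepted) == n:
                break
    return accepted


def null_interval_sites(intervals: Sequence[tuple[str, int, int]], prefix: str = "random") -> list[Site]:
    """Wrap null intervals as random-class Sites anchored at interval midpoints."""
    return [
        Site(chrom=c, peak_max=(s + e) // 2, class_label="random", site_id=f"{prefix}_{i:05d}")
        for i, (c, s, e) in enumerate(intervals)
    ]


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_chrom_sizes(path) -> GenomeIndex:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return GenomeIndex(tuple(df["chrom"].astype(str)), tuple(int(x) for x in df["length"]))


def read_bed_sites(path, class_label: str) -> list[Site]:
    """Read sites from a BED6-like file.

    The peak maximum is the interval midpoint unless a 7th column gives an
    explicit summit offset relative to the interval start.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected at least 3 BED columns")
    sites = []
    for i, row in enumerate(df.itertuples(index=False)):
        chrom, start, end = str(row[0]), int(row[1]), int(row[2])
        name = str(row[3]) if df.shape[1] > 3 else f"{class_label}_{i:05d}"
        peak = start + int(row[6]) if df.shape[1] > 6 else (start + end) // 2
        sites.append(Site(chrom=chrom, peak_max=peak, class_label=class_label, site_id=name))
    _check_unique_ids(sites)
    return sites


def write_bed_sites(sites: Sequence[Site], path, width: int = DEFAULT_SHAPE_WINDOW) -> None:
    """Write sites as sorted BED6+1 (7th column: summit offset from start)."""
    _validate_width(width)
    rows = []
    for site in sorted(sites, key=lambda s: (s.chrom, s.peak_max, s.site_id)):
        start, end = site.window(width)
        rows.append((site.chrom, start, end, site.site_id, 0, ".", site.peak_max - start))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
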