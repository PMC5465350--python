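"""Shape profiles: information gain against shuffled backgrounds, and scoring.

A shape profile is the set of regions in a class's average shape features
whose aligned-site value distributions diverge most from a shuffled
background — regions of largest information gain.  Aligned sites are then
scored against the profile by correlation distance (1 - Pearson r between
the site's values over the profile regions and the stored profile values),
so 0 means a perfect shape match and 2 a perfectly anticorrelated one.

Gain construction: per feature, values are discretized into equal-width
bins spanning the pooled signal+background range; the gain at a (feature,
position) is the Kullback-Leibler divergence, in bits, of the observed
aligned-site distribution from the background distribution at that
position.  Empty bins are regularized with a pseudo-count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import AlignmentConfig
from .shapes import FEATURES, N_FEATURES, compute_shape_from_sequence

logger = logging.getLogger(__name__)

__all__ = ["ProfileRegion", "ShapeProfile", "shuffled_background", "information_gain",
           "define_profile", "score_site", "score_class"]

DEFAULT_N_SHUFFLES = 100
DEFAULT_N_BINS = 10
DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_TOP_FRACTION = 0.10
DEFAULT_MERGE_GAP = 3
DEFAULT_MIN_RUN = 5


@dataclass(frozen=True)
class ProfileRegion:
    feature: str
    start: int  # interval-relative, inclusive
    end: int    # exclusive
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.values):
            raise ValueError("region span does not match stored values")


@dataclass
class ShapeProfile:
    """Selected high-gain regions of a class-average shape, with their values."""

    regions: list[ProfileRegion]
    info_gain: np.ndarray  # (4, align_window)
    threshold: float
    background_spec: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.info_gain < -1e-9).any():
            raise ValueError("information gain must be non-negative")

    @property
    def n_positions(self) -> int:
        return sum(r.end - r.start for r in self.regions)

    @staticmethod
    def standardize(matrix: np.ndarray) -> np.ndarray:
        """Per-feature z-score over the full interval (puts A and degrees on one scale)."""
        matrix = np.asarray(matrix, dtype=float)
        mean = matrix.mean(axis=1, keepdims=True)
        sd = matrix.std(axis=1, keepdims=True)
        return np.divide(matrix - mean, sd, out=np.zeros_like(matrix), where=sd > 0)

    def concatenated_values(self) -> np.ndarray:
        return np.concatenate([r.values for r in self.regions])

    def extract(self, aligned_site: np.ndarray) -> np.ndarray:
        """A site's aligned (4, W) values concatenated over the profile regions."""
        chunks = []
        for r in self.regions:
            chunks.append(aligned_site[FEATURES.index(r.feature), r.start:r.end])
        return np.concatenate(chunks)

    def table(self) -> pd.DataFrame:
        rows = []
        for r in self.regions:
            f = FEATURES.index(r.feature)
            for k, p in enumerate(range(r.start, r.end)):
                rows.append((r.feature, r.start, r.end, p, r.values[k], self.info_gain[f, p]))
        return pd.DataFrame(rows, columns=["feature", "start", "end", "position",
                                           "value", "gain"])

    @classmethod
    def from_table(cls, df: pd.DataFrame, info_gain: np.ndarray | None = None,
                   threshold: float = float("nan")) -> "ShapeProfile":
        regions = []
        gain = info_gain if info_gain is not None else np.zeros((N_FEATURES, 90))
        for (feature, start, end), sub in df.groupby(["feature", "start", "end"], sort=True):
            sub = sub.sort_values("position")
            regions.append(ProfileRegion(str(feature), int(start), int(end),
                                         sub["value"].to_numpy()))
            if info_gain is None:
                gain[FEATURES.index(str(feature)), sub["position"].to_numpy()] = \
                    sub["gain"].to_numpy()
        return cls(regions=regions, info_gain=gain, threshold=threshold)


def _mononucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    rng.shuffle(arr)
    return arr.tobytes().decode("ascii")


def shuffled_background(
    aligned_matrix: np.ndarray | None = None,
    *,
    sequences: list[str] | None = None,
    shifts: list[int] | None = None,
    table=None,
    config: AlignmentConfig | None = None,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
) -> np.ndarray:
    """Per-position background shape distributions from shuffled sites.

    Two modes:

    * sequence mode (``sequences`` + ``table``): each site's underlying
      window sequence is mononucleotide-shuffled per shuffle round, shape
      features are recomputed, and the site's aligned interval (its shift
      applied, window fixed) is extracted;
    * value-permutation mode (``aligned_matrix`` only): each site's aligned
      values are permuted across interval positions, per feature — an
      approximation for track-only inputs where no sequence is available.

    Returns an array of shape (n_shuffles * n_sites, 4, align_window).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    config = config or AlignmentConfig()
    if sequences is not None:
        if table is None:
            raise ValueError("sequence shuffling requires a pentamer table")
        shifts = shifts if shifts is not None else [0] * len(sequences)
        if len(shifts) != len(sequences):
            raise ValueError("one shift per sequence is required")
        out = []
        for _ in range(n_shuffles):
            for seq, shift in zip(sequences, shifts):
                shuffled = _mononucleotide_shuffle(seq, rng)
                matrix, _ = compute_shape_from_sequence(shuffled, table)
                c = len(seq) // 2
                lo = c + int(shift) - config.half
                if lo < 0 or lo + config.align_window > matrix.shape[1]:
                    raise ValueError("aligned interval exits the shuffled window")
                out.append(matrix[:, lo:lo + config.align_window])
        return np.stack(out)
    if aligned_matrix is None:
        raise ValueError(
            "provide sequences (with a table) for sequence shuffling, or an "
            "aligned matrix for the value-permutation approximation"
        )
    aligned_matrix = np.asarray(aligned_matrix, dtype=float)
    n, _, width = aligned_matrix.shape
    out = np.empty((n_shuffles * n, N_FEATURES, width))
    for r in range(n_shuffles):
        for i in range(n):
            for f in range(N_FEATURES):
                out[r * n + i, f] = rng.permutation(aligned_matrix[i, f])
    return out


def information_gain(
    observed: np.ndarray,
    background: np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray:
    """KL divergence (bits) of observed from background value distributions.

    ``observed`` is the aligned per-site matrix (n_sites, 4, W) and
    ``background`` a matching (m, 4, W) stack of background draws.  Binning
    is per feature, with ``n_bins`` equal-width bins spanning the pooled
    observed+background range.  Returns a non-negative (4, W) gain array.
    """
    observed = np.asarray(observed, dtype=float)
    background = np.asarray(background, dtype=float)
    if observed.ndim != 3 or background.ndim != 3 or observed.shape[1:] != background.shape[1:]:
        raise ValueError("observed and background must be (n, 4, W) with matching (4, W)")
    _, n_feat, width = observed.shape
    gain = np.zeros((n_feat, width))
    for f in range(n_feat):
        lo = min(observed[:, f].min(), background[:, f].min())
        hi = max(observed[:, f].max(), background[:, f].max())
        if hi <= lo:
            continue  # constant feature: identical distributions, gain 0
        edges = np.linspace(lo, hi, n_bins + 1)
        for p in range(width):
            p_obs, _ = np.histogram(observed[:, f, p], bins=edges)
            p_bg, _ = np.histogram(background[:, f, p], bins=edges)
            po = (p_obs + pseudocount).astype(float)
            pb = (p_bg + pseudocount).astype(float)
            po /= po.sum()
            pb /= pb.sum()
            nz = po > 0
            gain[f, p] = float(np.sum(po[nz] * np.log2(po[nz] / pb[nz])))
    return np.maximum(gain, 0.0)


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def define_profile(
    class_average: np.ndarray,
    gain: np.ndarray,
    threshold: float | None = None,
    top_fraction: float = DEFAULT_TOP_FRACTION,
    merge_gap: int = DEFAULT_MERGE_GAP,
    min_run: int = DEFAULT_MIN_RUN,
    background_spec: dict | None = None,
) -> ShapeProfile:
    """Select maximal high-gain regions of the class average as the profile.

    Positions with gain strictly above the threshold (default: the
    ``1 - top_fraction`` quantile of all pooled gain values) form candidate
    runs per feature; runs separated by fewer than ``merge_gap`` positions
    are merged, and runs shorter than ``min_run`` are dropped.  Stored
    region values come from the per-feature z-standardized class average,
    so that scoring compares shape patterns rather than absolute units.
    """
    class_average = np.asarray(class_average, dtype=float)
    gain = np.asarray(gain, dtype=float)
    if class_average.shape != gain.shape:
        raise ValueError("class_average and gain shapes differ")
    if threshold is None:
        threshold = float(np.quantile(gain, 1.0 - top_fraction))
    std_average = ShapeProfile.standardize(class_average)
    regions = []
    for f, feature in enumerate(FEATURES[:gain.shape[0]]):
        runs = _runs_above(gain[f] > threshold)
        merged: list[list[int]] = []
        for start, end in runs:
            if merged and start - merged[-1][1] < merge_gap:
                merged[-1][1] = end
            else:
                merged.append([start, end])
        for start, end in merged:
            if end - start >= min_run:
                regions.append(ProfileRegion(feature, start, end,
                                             std_average[f, start:end].copy()))
    if not regions:
        raise ValueError(
            "no profile region passes the information-gain threshold "
            f"({threshold:.4g}); lower the threshold or top_fraction"
        )
    return ShapeProfile(regions=regions, info_gain=gain, threshold=float(threshold),
                        background_spec=background_spec or {})


def score_site(aligned_site: np.ndarray, profile: ShapeProfile) -> float:
    """Correlation distance of one aligned site to the profile, in [0, 2].

    The site's aligned matrix is z-standardized per feature over the full
    interval (as the stored profile values are), then its values over the
    profile regions are correlated with the profile's.  A zero-variance
    site vector over the regions is uninformative and scores 1 (logged).
    """
    site_vals = profile.extract(ShapeProfile.standardize(aligned_site))
    prof_vals = profile.concatenated_values()
    if site_vals.std() == 0 or prof_vals.std() == 0:
        logger.warning("zero-variance vector over profile regions; score set to 1")
        return 1.0
    r = float(np.corrcoef(site_vals, prof_vals)[0, 1])
    return 1.0 - r


def score_class(aligned_matrix: np.ndarray, profile: ShapeProfile) -> np.ndarray:
    """Correlation-distance scores for every site of an aligned class matrix."""
    return np.array([score_site(aligned_matrix[i], profile)
                     for i in range(len(aligned_matrix))])
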