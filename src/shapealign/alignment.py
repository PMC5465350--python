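"""Motif-independent alignment of shape windows by cosine-similarity shift search.

Each site is summarized by a comparison vector: the alignment interval
(default 90 bp) centred on the peak maximum, with the central positions
(default 5 bp) excluded because free MNase cleaves preferentially at A/T and
contaminates shape values right at the peak, each feature z-standardized,
and the four features concatenated.  The best shift of one site against
another maximizes cosine similarity over an exhaustive scan (default
±25 bp).  A class is anchored on its internal centroid — the member with
the smallest sum of squared cosine distances to all other members — and
every site is shifted to the centroid's frame before averaging.

Sign convention: a positive shift moves a site's sampling window rightward
(toward larger coordinates) to match the reference.

The centre-exclusion mask travels with each site's own (unshifted) peak
maximum, since the cleavage bias is a property of the cleavage site, not of
the frame it is being aligned into.

Because the centroid's own offset from the underlying shape signature is
arbitrary, the recovered shift distribution is recentred to zero mean
(integer rounding) by default, restoring the peak-maximum frame that makes
class averages comparable across classes without shifting them against one
another.  Set ``recentre=False`` for the raw centroid frame, in which the
centroid's shift is exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .shapes import FEATURES, N_FEATURES, ShapeWindow

__all__ = ["AlignmentConfig", "AlignmentResult", "site_vector", "pair_similarity",
           "best_shift", "find_centroid", "align_class"]

DEFAULT_MAX_SHIFT = 25
DEFAULT_ALIGN_WINDOW = 90
DEFAULT_CENTER_EXCLUSION = 5


@dataclass(frozen=True)
class AlignmentConfig:
    """Parameters of the shift search; identical for every site class."""

    max_shift: int = DEFAULT_MAX_SHIFT
    align_window: int = DEFAULT_ALIGN_WINDOW
    center_exclusion: int = DEFAULT_CENTER_EXCLUSION
    standardize: bool = True
    recentre: bool = True
    centroid_objective: str = "distance"  # or "similarity" (literal minimum-similarity reading)

    def __post_init__(self) -> None:
        if self.max_shift < 0:
            raise ValueError("max_shift must be non-negative")
        if self.align_window < 2:
            raise ValueError("align_window too small")
        if self.center_exclusion % 2 == 0 or self.center_exclusion < 1:
            raise ValueError("center_exclusion must be odd and positive")
        if self.centroid_objective not in ("distance", "similarity"):
            raise ValueError("centroid_objective must be 'distance' or 'similarity'")
        if self.max_shift + self.center_exclusion // 2 >= self.align_window // 2:
            raise ValueError("center exclusion would exit the alignment interval at max shift")

    @property
    def half(self) -> int:
        return self.align_window // 2

    @property
    def vector_length(self) -> int:
        return N_FEATURES * (self.align_window - self.center_exclusion)

    def validate_window(self, window_width: int) -> None:
        if self.align_window + 2 * self.max_shift > window_width:
            raise ValueError(
                f"align_window {self.align_window} + 2*max_shift {self.max_shift} "
                f"exceeds the {window_width}-bp shape window"
            )

    def shift_order(self) -> list[int]:
        """Shift scan order encoding the tie-break: smallest |shift|, negative first."""
        order = [0]
        for k in range(1, self.max_shift + 1):
            order.extend([-k, k])
        return order


def _interval_columns(window: ShapeWindow, config: AlignmentConfig, shift: int) -> np.ndarray:
    c = window.center_index
    lo = c + shift - config.half
    hi = lo + config.align_window
    if lo < 0 or hi > window.width:
        raise ValueError(
            f"site {window.site_id}: alignment interval at shift {shift} exits the shape window"
        )
    return window.features[:, lo:hi]


def _exclusion_interval_indices(config: AlignmentConfig, shift: int) -> np.ndarray:
    """Interval-relative indices of the site's own excluded centre positions."""
    e = config.center_exclusion // 2
    center = config.half - shift  # unshifted peak within the shifted interval
    return np.arange(center - e, center + e + 1)


def site_vector(window: ShapeWindow, config: AlignmentConfig, shift: int = 0) -> np.ndarray:
    """Flat comparison vector for a site at a given shift.

    Extracts the alignment interval centred at ``center_index + shift``,
    drops the centre-exclusion positions anchored on the site's unshifted
    peak maximum, z-standardizes each feature over the retained positions
    (a zero-variance feature becomes all zeros), and concatenates the four
    features.  Length is ``4 * (align_window - center_exclusion)`` — 340 at
    the defaults.
    """
    if abs(shift) > config.max_shift:
        raise ValueError(f"|shift| {abs(shift)} exceeds max_shift {config.max_shift}")
    config.validate_window(window.width)
    interval = _interval_columns(window, config, shift)
    keep = np.ones(config.align_window, dtype=bool)
    keep[_exclusion_interval_indices(config, shift)] = False
    values = interval[:, keep]
    if config.standardize:
        mean = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, keepdims=True)
        values = np.divide(values - mean, sd, out=np.zeros_like(values), where=sd > 0)
    return values.reshape(-1)


def _union_keep_mask(config: AlignmentConfig, shift: int) -> np.ndarray:
    """Interval positions retained in a pair comparison at a given shift.

    The centre-exclusion travels with each site's own peak, so a pair
    comparison drops the union of both sites' excluded positions: the
    (unshifted) reference's centre and the shifted site's centre.
    """
    keep = np.ones(config.align_window, dtype=bool)
    e = config.center_exclusion // 2
    center = config.half
    keep[max(center - e, 0):center + e + 1] = False
    own = _exclusion_interval_indices(config, shift)
    keep[own[(own >= 0) & (own < config.align_window)]] = False
    return keep


def _masked_z(interval: np.ndarray, keep: np.ndarray, standardize: bool) -> np.ndarray:
    values = interval[:, keep]
    if standardize:
        mean = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, keepdims=True)
        values = np.divide(values - mean, sd, out=np.zeros_like(values), where=sd > 0)
    return values.reshape(-1)


def pair_similarity(a: ShapeWindow, b: ShapeWindow, shift: int,
                    config: AlignmentConfig | None = None) -> float:
    """Cosine similarity of ``b`` shifted by ``shift`` against unshifted ``a``.

    Both vectors cover the same retained interval positions — everything in
    the alignment interval except the union of the two sites' own
    centre-exclusion windows — z-standardized per feature.  A zero-variance
    vector makes the similarity 0.
    """
    config = config or AlignmentConfig()
    config.validate_window(a.width)
    config.validate_window(b.width)
    keep = _union_keep_mask(config, shift)
    u = _masked_z(_interval_columns(a, config, 0), keep, config.standardize)
    v = _masked_z(_interval_columns(b, config, shift), keep, config.standardize)
    nu, nv = float(np.linalg.norm(u)), float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        return 0.0  # zero-variance comparison vector: similarity defined as 0
    return float(np.dot(u, v) / (nu * nv))


def best_shift(a: ShapeWindow, b: ShapeWindow, config: AlignmentConfig | None = None
               ) -> tuple[int, float]:
    """Exhaustive shift scan of ``b`` against unshifted ``a``.

    Returns ``(shift, similarity)`` for the shift in ``[-max_shift,
    +max_shift]`` maximizing :func:`pair_similarity`; ties go to the
    smallest |shift|, then negative before positive.
    """
    config = config or AlignmentConfig()
    best_s, best_sim = 0, -np.inf
    for s in config.shift_order():
        sim = pair_similarity(a, b, s, config)
        if sim > best_sim:
            best_s, best_sim = s, sim
    return best_s, best_sim


def _normalized_rows(matrix: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(matrix, axis=1, keepdims=True)
    return np.divide(matrix, norms, out=np.zeros_like(matrix), where=norms > 0)


def _pairwise_best(windows: list[ShapeWindow], config: AlignmentConfig
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Best shift and similarity of every window against every reference.

    Returns ``(shifts, sims)`` with entry ``[i, j]`` the best shift (and its
    similarity) of window ``j`` scanned against unshifted window ``i`` —
    the vectorized equivalent of :func:`best_shift` for all ordered pairs,
    with identical tie-breaking.
    """
    n = len(windows)
    intervals0 = np.stack([_interval_columns(w, config, 0) for w in windows])
    best_sim = np.full((n, n), -np.inf)
    best_s = np.zeros((n, n), dtype=int)
    for s in config.shift_order():
        keep = _union_keep_mask(config, s)
        refs = np.stack([_masked_z(iv, keep, config.standardize) for iv in intervals0])
        shifted = np.stack([
            _masked_z(_interval_columns(w, config, s), keep, config.standardize)
            for w in windows])
        sims = _normalized_rows(refs) @ _normalized_rows(shifted).T  # [i, j]
        better = sims > best_sim
        best_sim[better] = sims[better]
        best_s[better] = s
    return best_s, best_sim


def _centroid_from_matrix(windows, sims: np.ndarray, config: AlignmentConfig) -> str:
    n = len(windows)
    off = ~np.eye(n, dtype=bool)
    if config.centroid_objective == "distance":
        scores = np.where(off, (1.0 - sims) ** 2, 0.0).sum(axis=1)
    else:
        scores = np.where(off, sims ** 2, 0.0).sum(axis=1)
    ids = [w.site_id for w in windows]
    return min(zip(scores.tolist(), ids))[1]


def find_centroid(windows: list[ShapeWindow], config: AlignmentConfig | None = None) -> str:
    """Identify the class centroid: the most central member under shift-optimized cosine.

    For each candidate reference, the best similarity of every other member
    against it is found; the centroid minimizes the sum of squared cosine
    distances ``(1 - similarity)^2``.  (``centroid_objective='similarity'``
    instead minimizes the sum of squared similarities — the literal
    minimum-similarity reading; see the methods notes.)  Ties break
    lexicographically by site_id.
    """
    config = config or AlignmentConfig()
    if not windows:
        raise ValueError("cannot find the centroid of an empty class")
    if len(windows) == 1:
        return windows[0].site_id
    _, sims = _pairwise_best(windows, config)
    return _centroid_from_matrix(windows, sims, config)


@dataclass
class AlignmentResult:
    """Per-class alignment: shifts, aligned matrix, average features with s.e.m."""

    centroid_id: str
    site_ids: list[str]
    shifts: dict[str, int]
    similarities: dict[str, float]
    aligned_matrix: np.ndarray    # (n_sites, 4, align_window), raw feature units
    exclusion_mask: np.ndarray    # (n_sites, align_window) True at each site's masked centre
    class_average: np.ndarray     # (4, align_window)
    class_sem: np.ndarray         # (4, align_window)
    config: AlignmentConfig = field(default_factory=AlignmentConfig)
    anchor_offset: int = 0        # subtracted from all shifts by recentring

    def shifts_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "site_id": self.site_ids,
            "shift": [self.shifts[s] for s in self.site_ids],
            "similarity": [self.similarities[s] for s in self.site_ids],
        })

    def average_table(self) -> pd.DataFrame:
        rows = []
        for f, feat in enumerate(FEATURES):
            for p in range(self.class_average.shape[1]):
                rows.append((feat, p, self.class_average[f, p], self.class_sem[f, p]))
        return pd.DataFrame(rows, columns=["feature", "position", "mean", "sem"])


def align_class(windows: list[ShapeWindow], config: AlignmentConfig | None = None
                ) -> AlignmentResult:
    """Align a class of shape windows to its internal centroid.

    Every site is shifted by its best shift against the centroid; the
    aligned matrix covers the alignment interval in raw feature units with
    the centre-exclusion positions retained but flagged.  The class average
    is the per-position mean and ``class_sem`` its standard error.
    """
    config = config or AlignmentConfig()
    if not windows:
        raise ValueError("cannot align an empty class")
    for w in windows:
        config.validate_window(w.width)
    if len(windows) == 1:
        centroid_id = windows[0].site_id
        shifts_arr = np.zeros(1, dtype=int)
        sims_arr = np.ones(1)
    else:
        all_shifts, all_sims = _pairwise_best(windows, config)
        centroid_id = _centroid_from_matrix(windows, all_sims, config)
        ci = [w.site_id for w in windows].index(centroid_id)
        shifts_arr = all_shifts[ci].copy()
        sims_arr = all_sims[ci].copy()
        shifts_arr[ci], sims_arr[ci] = 0, 1.0

    offset = int(np.round(shifts_arr.mean())) if config.recentre else 0
    shifts_arr = shifts_arr - offset

    n = len(windows)
    aligned = np.empty((n, N_FEATURES, config.align_window))
    mask = np.zeros((n, config.align_window), dtype=bool)
    for i, (w, s) in enumerate(zip(windows, shifts_arr)):
        c = w.center_index
        lo = c + int(s) - config.half
        if lo < 0 or lo + config.align_window > w.width:
            raise ValueError(
                f"site {w.site_id}: recentred shift {int(s)} exits the shape window"
            )
        aligned[i] = w.features[:, lo:lo + config.align_window]
        excl = _exclusion_interval_indices(config, int(s))
        mask[i, excl[(excl >= 0) & (excl < config.align_window)]] = True

    average = aligned.mean(axis=0)
    if n > 1:
        sem = aligned.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        sem = np.zeros_like(average)
    return AlignmentResult(
        centroid_id=centroid_id,
        site_ids=[w.site_id for w in windows],
        shifts={w.site_id: int(s) for w, s in zip(windows, shifts_arr)},
        similarities={w.site_id: float(v) for w, v in zip(windows, sims_arr)},
        aligned_matrix=aligned,
        exclusion_mask=mask,
        class_average=average,
        class_sem=sem,
        config=config,
        anchor_offset=offset,
    )
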