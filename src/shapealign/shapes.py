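"""DNA shape feature matrices: pentamer lookup model, tracks and site windows.

Four structural features are carried everywhere, in this fixed order and in
these units:

* ``MGW``  — minor groove width, angstrom (strictly positive)
* ``ProT`` — propeller twist, degrees
* ``HelT`` — helix twist, degrees
* ``Roll`` — roll, degrees

Features are predicted per base from the pentamer centred on that base.
HelT and Roll are base-pair-step quantities in the underlying structural
model; the tables consumed here carry one value per pentamer per feature,
understood as the mean of the two steps flanking the central base (the
averaging convention), so that every feature yields one value per position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FEATURES = ("MGW", "ProT", "HelT", "Roll")
FEATURE_UNITS = {"MGW": "angstrom", "ProT": "degrees", "HelT": "degrees", "Roll": "degrees"}
N_FEATURES = len(FEATURES)

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as 0..3 (ACGT); any other symbol becomes -1."""
    table = np.full(128, -1, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        table[ord(base)] = code
        table[ord(base.lower())] = code
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return table[arr]


def reverse_complement(seq: str) -> str:
    comp = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")
    return seq.translate(comp)[::-1]


def _pentamer_codes(codes: np.ndarray) -> np.ndarray:
    """Base-4 integer code of each pentamer (centre at i+2); -1 where any N."""
    L = len(codes)
    if L < 5:
        raise ValueError("sequence shorter than a pentamer")
    windows = np.lib.stride_tricks.sliding_window_view(codes, 5)
    bad = (windows < 0).any(axis=1)
    vals = (windows * (4 ** np.arange(4, -1, -1))).sum(axis=1)
    vals[bad] = -1
    return vals


def _revcomp_code(code: int) -> int:
    digits = [(code >> (2 * k)) & 3 for k in range(5)]  # last base first
    rc = 0
    for d in digits:  # reversing order and complementing (x -> 3-x)
        rc = rc * 4 + (3 - d)
    # digits above are from 3' end, so iterating them reversed the pentamer
    return rc


_REVCOMP_CODES = np.array([_revcomp_code(c) for c in range(1024)], dtype=np.int64)


def pentamer_string(code: int) -> str:
    out = []
    for k in range(4, -1, -1):
        out.append(_BASES[(code >> (2 * k)) & 3])
    return "".join(out)


@dataclass
class PentamerShapeTable:
    """Lookup from each of the 1,024 DNA 5-mers to one value per feature.

    ``values`` has shape (1024, 4) with columns ordered as :data:`FEATURES`.
    Tables are reverse-complement symmetric: a pentamer and its reverse
    complement map to the same value for every feature (step features are
    pre-averaged over their two flanking steps, which makes them symmetric
    as well).
    """

    values: np.ndarray
    feature_names: tuple[str, ...] = FEATURES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (1024, N_FEATURES):
            raise ValueError(f"table must be (1024, {N_FEATURES}), got {self.values.shape}")
        if tuple(self.feature_names) != FEATURES:
            raise ValueError(f"feature names must be {FEATURES}, got {self.feature_names}")
        if np.isnan(self.values).any():
            raise ValueError("table incomplete: NaN entries remain after symmetrization")
        if (self.values[:, 0] <= 0).any():
            raise ValueError("MGW values must be strictly positive")

    def is_symmetric(self) -> bool:
        return bool(np.allclose(self.values, self.values[_REVCOMP_CODES]))

    def lookup(self, pentamer: str) -> np.ndarray:
        codes = encode_sequence(pentamer)
        if len(codes) != 5 or (codes < 0).any():
            raise ValueError(f"invalid pentamer {pentamer!r}")
        code = int((codes * (4 ** np.arange(4, -1, -1))).sum())
        return self.values[code].copy()

    @classmethod
    def from_file(cls, path) -> "PentamerShapeTable":
        """Read a tabular (pentamer, feature, value) file and symmetrize.

        Missing reverse complements are filled in from their partner; when
        both orientations are present their values are averaged.
        """
        df = pd.read_csv(path, sep="\t")
        required = {"pentamer", "feature", "value"}
        if not required.issubset(df.columns):
            raise ValueError(f"{path}: expected columns {sorted(required)}")
        unknown = set(df["feature"]) - set(FEATURES)
        if unknown:
            raise ValueError(f"{path}: unknown features {sorted(unknown)}; expected {FEATURES}")
        values = np.full((1024, N_FEATURES), np.nan)
        counts = np.zeros((1024, N_FEATURES))
        fidx = {f: i for i, f in enumerate(FEATURES)}
        for pent, feat, val in df[["pentamer", "feature", "value"]].itertuples(index=False):
            codes = encode_sequence(str(pent))
            if len(codes) != 5 or (codes < 0).any():
                raise ValueError(f"{path}: invalid pentamer {pent!r}")
            code = int((codes * (4 ** np.arange(4, -1, -1))).sum())
            j = fidx[feat]
            for c in (code, int(_REVCOMP_CODES[code])):
                if np.isnan(values[c, j]):
                    values[c, j] = 0.0
                values[c, j] += float(val)
                counts[c, j] += 1
        with np.errstate(invalid="ignore"):
            values = np.where(counts > 0, values / np.maximum(counts, 1), np.nan)
        return cls(values=values)

    def to_file(self, path) -> None:
        rows = []
        for code in range(1024):
            pent = pentamer_string(code)
            for j, feat in enumerate(FEATURES):
                rows.append((pent, feat, self.values[code, j]))
        pd.DataFrame(rows, columns=["pentamer", "feature", "value"]).to_csv(
            path, sep="\t", index=False
        )


def toy_pentamer_table() -> PentamerShapeTable:
    """A small deterministic, reverse-complement-symmetric pentamer table.

    Synthetic and non-biological: values are a linear function of A/T
    content plus a fixed pseudo-random perturbation per canonical pentamer,
    kept within physically plausible ranges.  It exists so the package runs
    end to end with no external data; supply a real table file for any
    biological use.
    """
    rng = np.random.default_rng(20170605)
    jitter = rng.random((1024, N_FEATURES)) - 0.5
    codes = np.arange(1024)
    canonical = np.minimum(codes, _REVCOMP_CODES)
    jitter = jitter[canonical]
    digits = np.stack([(codes >> (2 * k)) & 3 for k in range(5)], axis=1)
    at = ((digits == 0) | (digits == 3)).sum(axis=1).astype(float)
    values = np.empty((1024, N_FEATURES))
    values[:, 0] = 5.8 - 0.35 * at + 0.40 * jitter[:, 0]   # MGW (A)
    values[:, 1] = -6.5 - 1.30 * at + 1.00 * jitter[:, 1]  # ProT (deg)
    values[:, 2] = 34.0 + 0.25 * at + 0.80 * jitter[:, 2]  # HelT (deg)
    values[:, 3] = 1.5 - 0.50 * at + 1.20 * jitter[:, 3]   # Roll (deg)
    return PentamerShapeTable(values=values)


def compute_shape_from_sequence(
    seq: str,
    table: PentamerShapeTable,
    impute: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position shape features for a sequence via sliding-pentamer lookup.

    Returns ``(matrix, defined)`` where ``matrix`` is (4, L) and ``defined``
    marks positions whose pentamer was fully determined (interior positions
    at least 2 bp from each end and from any N).  Undefined positions are
    imputed by copying the nearest defined value (leftward on ties) when
    ``impute`` is true, else left as NaN.
    """
    if len(seq) < 5:
        raise ValueError(f"sequence of length {len(seq)} is shorter than a pentamer")
    codes = encode_sequence(seq)
    pent = _pentamer_codes(codes)
    L = len(seq)
    matrix = np.full((N_FEATURES, L), np.nan)
    defined = np.zeros(L, dtype=bool)
    centers = np.arange(2, L - 2)
    ok = pent >= 0
    matrix[:, centers[ok]] = table.values[pent[ok]].T
    defined[centers[ok]] = True
    if impute and not defined.all():
        if not defined.any():
            raise ValueError("no defined positions to impute from (sequence all N?)")
        idx = np.flatnonzero(defined)
        pos = np.arange(L)
        left = np.searchsorted(idx, pos, side="right") - 1
        right = np.clip(left + 1, 0, len(idx) - 1)
        left = np.clip(left, 0, len(idx) - 1)
        dl = np.abs(pos - idx[left])
        dr = np.abs(idx[right] - pos)
        nearest = np.where(dl <= dr, idx[left], idx[right])
        fill = ~defined
        matrix[:, fill] = matrix[:, nearest[fill]]
    return matrix, defined


@dataclass
class ShapeWindow:
    """Per-site shape feature matrix centred on the peak maximum."""

    site_id: str
    features: np.ndarray  # (4, W)
    center_index: int
    feature_names: tuple[str, ...] = FEATURES
    imputed_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2 or self.features.shape[0] != N_FEATURES:
            raise ValueError(f"features must be (4, W), got {self.features.shape}")
        if np.isnan(self.features).any():
            raise ValueError(f"site {self.site_id}: undefined values inside shape window")
        if not (0 <= self.center_index < self.features.shape[1]):
            raise ValueError(f"site {self.site_id}: center_index outside window")

    @property
    def width(self) -> int:
        return self.features.shape[1]


class ShapeTrack:
    """Genome-wide per-base shape feature values, one contiguous block per chromosome.

    ``data`` maps chromosome name to ``(start, values)`` with ``values`` of
    shape (4, L) covering positions ``[start, start + L)``.
    """

    def __init__(self, data: dict[str, tuple[int, np.ndarray]] | None = None):
        self.data: dict[str, tuple[int, np.ndarray]] = {}
        for chrom, (start, values) in (data or {}).items():
            self.add(chrom, start, values)

    def add(self, chrom: str, start: int, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != N_FEATURES:
            raise ValueError(f"{chrom}: track block must be (4, L)")
        self.data[chrom] = (int(start), values)

    def get_window(self, chrom: str, start: int, end: int) -> np.ndarray:
        if chrom not in self.data:
            raise KeyError(f"no shape track for chromosome {chrom}")
        block_start, values = self.data[chrom]
        lo, hi = start - block_start, end - block_start
        if lo < 0 or hi > values.shape[1]:
            raise ValueError(
                f"window [{start}, {end}) outside track coverage on {chrom} "
                f"[{block_start}, {block_start + values.shape[1]})"
            )
        return values[:, lo:hi].copy()

    @classmethod
    def from_genome(cls, sequences: dict[str, str], table: PentamerShapeTable) -> "ShapeTrack":
        track = cls()
        for chrom, seq in sequences.items():
            matrix, _ = compute_shape_from_sequence(seq, table)
            track.add(chrom, 0, matrix)
        return track

    def write(self, path) -> None:
        frames = []
        for chrom in sorted(self.data):
            start, values = self.data[chrom]
            df = pd.DataFrame(values.T, columns=list(FEATURES))
            df.insert(0, "pos", np.arange(start, start + values.shape[1]))
            df.insert(0, "chrom", chrom)
            frames.append(df)
        out = pd.concat(frames) if frames else pd.DataFrame(
            columns=["chrom", "pos", *FEATURES]
        )
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def read(cls, path) -> "ShapeTrack":
        df = pd.read_csv(path, sep="\t")
        expected = ["chrom", "pos", *FEATURES]
        if list(df.columns) != expected:
            raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
        track = cls()
        for chrom, sub in df.groupby("chrom", sort=True):
            pos = sub["pos"].to_numpy()
            if len(pos) and not (np.diff(pos) == 1).all():
                raise ValueError(f"{path}: non-contiguous positions on {chrom}")
            track.add(str(chrom), int(pos[0]) if len(pos) else 0,
                      sub[list(FEATURES)].to_numpy().T)
        return track


def extract_shape_window(site, source, window: int = 201,
                         table: PentamerShapeTable | None = None) -> ShapeWindow:
    """Extract the ``window``-bp shape matrix centred on a site's peak maximum.

    ``source`` is either a :class:`ShapeTrack` or a mapping/fetchable of
    chromosome sequences (with ``table`` supplied for the pentamer lookup).
    The window must be odd so the peak maximum sits at the exact centre;
    windows exiting the chromosome raise rather than clip.
    """
    if window % 2 == 0 or window < 5:
        raise ValueError(f"shape window must be odd and >= 5, got {window}")
    half = window // 2
    start, end = site.peak_max - half, site.peak_max + half + 1
    if isinstance(source, ShapeTrack):
        features = source.get_window(site.chrom, start, end)
        imputed = 0.0
    else:
        if table is None:
            raise ValueError("a pentamer table is required to compute shape from sequence")
        chrom_len = len(source[site.chrom])
        if start < 0 or end > chrom_len:
            raise ValueError(
                f"site {site.site_id}: {window}-bp window [{start}, {end}) exits {site.chrom}"
            )
        # fetch up to 2 bp of flanking context so interior positions keep
        # their true pentamers instead of being imputed
        pad_lo = min(2, start)
        pad_hi = min(2, chrom_len - end)
        seq = str(source[site.chrom][start - pad_lo:end + pad_hi])
        matrix, defined = compute_shape_from_sequence(seq, table)
        features = matrix[:, pad_lo:pad_lo + window]
        imputed = float((~defined[pad_lo:pad_lo + window]).mean())
    return ShapeWindow(site_id=site.site_id, features=features, center_index=half,
                       imputed_fraction=imputed)


def open_genome(path):
    """Open an indexed FASTA for sequence-path window extraction.

    The returned object maps chromosome name to a sliceable record, as
    :func:`extract_shape_window` expects; an .fai index is created beside
    the file if missing.
    """
    from pyfaidx import Fasta
    return Fasta(str(path), sequence_always_upper=True)


def filter_imputed_windows(windows, max_imputed_fraction: float = 0.10):
    """Drop windows with more than the allowed fraction of imputed positions."""
    kept = [w for w in windows if w.imputed_fraction <= max_imputed_fraction]
    dropped = len(windows) - len(kept)
    if dropped:
        logger.warning("dropped %d windows with > %.0f%% imputed positions",
                       dropped, 100 * max_imputed_fraction)
    return kept
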