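"""Synthetic genomes, site classes and shape tracks with planted ground truth.

The generator emulates the statistical structure the analysis assumes:

* ``fast`` and ``slow`` classes share one localized shape signature — a
  smooth half-cosine narrowing of the minor groove with a matching negative
  propeller-twist excursion, echoing the deformation a binding-site-proximal
  poly(dA:dT) tract imprints on DNA shape — embedded at a per-site random
  offset (the planted shift) within a bounded jitter range.  The slow class
  carries the same signature under heavier noise.
* ``free_mnase`` sites carry an A/T-rich centre (the nuclease cleavage
  bias, also present at fast and slow peaks) but no shared signature.
* ``random`` sites are pure background drawn away from all peaks.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import bisect
import zlib
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .intervals import GenomeIndex, Site, generate_null_intervals, null_interval_sites
from .shapes import FEATURES, N_FEATURES, PentamerShapeTable, ShapeTrack, toy_pentamer_table

__all__ = ["SimulationSpec", "SimulatedDataset", "simulate_genome", "simulate_dataset",
           "simulate_site_classes", "simulate_genes", "simulate_association_table"]


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for the synthetic dataset.

    ``noise_sd`` is the per-position additive noise as a fraction of each
    feature's characteristic scale (``feature_scales``); the fast class uses
    it directly and the slow class multiplies it by ``slow_noise_factor``.
    The signature amplitudes are the tract-like deformation in native units
    (MGW in angstrom, ProT in degrees), spanning ``signature_span`` bp
    centred ``signature_offset`` bp right of the peak maximum, displaced
    per site by an integer drawn uniformly from ±``shift_jitter``.
    """

    genome_size: int = 1_000_000
    n_chroms: int = 2
    gc_content: float = 0.40
    n_sites: int = 200
    shape_window: int = 201
    signature_span: int = 21
    signature_offset: int = 15
    signature_amplitude: tuple[tuple[str, float], ...] = (
        ("MGW", -1.5), ("ProT", -4.0), ("HelT", 1.0), ("Roll", -2.0))
    signature_texture_depth: float = 0.6
    shift_jitter: int = 10
    noise_sd: float = 0.25
    slow_noise_factor: float = 2.0
    baseline: tuple[tuple[str, float], ...] = (
        ("MGW", 5.0), ("ProT", -7.0), ("HelT", 34.3), ("Roll", 1.2))
    center_bias: tuple[tuple[str, float], ...] = (("MGW", -1.0), ("ProT", -2.0))
    center_bias_width: int = 5
    at_tract: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_size < 10_000:
            raise ValueError("genome_size must be at least 10 kb")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.shift_jitter < 0 or self.signature_span < 1:
            raise ValueError("invalid signature geometry")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")

    @property
    def amplitudes(self) -> dict[str, float]:
        return dict(self.signature_amplitude)

    @property
    def scales(self) -> dict[str, float]:
        """Per-feature noise scale: the magnitude of that feature's deformation."""
        return {feat: abs(amp) for feat, amp in self.signature_amplitude}

    @property
    def baselines(self) -> dict[str, float]:
        return dict(self.baseline)

    def to_dict(self) -> dict:
        return asdict(self)


def signature_curves(spec: SimulationSpec) -> np.ndarray:
    """The planted per-feature deformation, shape (4, signature_span).

    A tract-like deformation is plateau-shaped, not bump-shaped: the minor
    groove narrows progressively and stays narrow across the tract, with
    the other features similarly sustained.  On the plateau sits aperiodic
    base-resolution texture — pentamer-predicted shape varies base to base
    even within homopolymer contexts, with no repeating period — modelled
    as a fixed pseudo-random ±``signature_texture_depth`` modulation (one
    fixed pattern per feature, independent of the simulation seed: the
    texture is part of the signature's identity, shared by every site that
    carries it).  3-bp linear edge tapers avoid step discontinuities.  Each
    feature's curve peaks at exactly its stated amplitude, so ``noise_sd``
    is the per-position noise as a fraction of the peak deformation.
    """
    span = spec.signature_span
    taper = np.ones(span)
    ramp = min(3, span // 2)
    for i in range(ramp):
        taper[i] = taper[span - 1 - i] = (i + 1) / (ramp + 1)
    depth = spec.signature_texture_depth
    pattern = np.random.default_rng(1729).choice([-1.0, 1.0], size=(N_FEATURES, span))
    curves = np.zeros((N_FEATURES, span))
    amps = spec.amplitudes
    for f, feat in enumerate(FEATURES):
        shape = taper * (1.0 + depth * pattern[f])
        peak = np.max(np.abs(shape))
        curves[f] = amps.get(feat, 0.0) * shape / peak
    return curves


def _spawn(spec_seed: int, stage: str) -> np.random.Generator:
    """Stage-specific generator derived from the master seed (stable across runs)."""
    return np.random.default_rng(np.random.SeedSequence(
        (spec_seed, zlib.crc32(stage.encode()))))


def simulate_genome(spec: SimulationSpec) -> tuple[dict[str, str], GenomeIndex]:
    """I.i.d. random genome with the requested GC content, split over chromosomes."""
    rng = _spawn(spec.seed, "genome")
    p_gc = spec.gc_content / 2
    p_at = (1 - spec.gc_content) / 2
    probs = [p_at, p_gc, p_gc, p_at]  # A, C, G, T
    sizes = [spec.genome_size // spec.n_chroms] * spec.n_chroms
    sizes[-1] += spec.genome_size - sum(sizes)
    sequences = {}
    for i, size in enumerate(sizes):
        codes = rng.choice(4, size=size, p=probs)
        sequences[f"chr{i + 1}"] = "".join(np.array(list("ACGT"))[codes])
    index = GenomeIndex(tuple(sequences), tuple(len(s) for s in sequences.values()))
    return sequences, index


def _half_cosine(span: int) -> np.ndarray:
    t = np.arange(span) - (span - 1) / 2
    return np.cos(np.pi * t / span)


def _place_sites(index: GenomeIndex, n_total: int, spacing: int, margin: int,
                 rng: np.random.Generator, max_attempt_factor: int = 1000) -> list[tuple[str, int]]:
    """Random peak positions with pairwise distance >= spacing on each chromosome."""
    chroms = list(index.lengths.items())
    weights = np.array([length for _, length in chroms], dtype=float)
    weights /= weights.sum()
    occupied: dict[str, list[int]] = {c: [] for c, _ in chroms}
    placed: list[tuple[str, int]] = []
    attempts = 0
    while len(placed) < n_total:
        attempts += 1
        if attempts > max_attempt_factor * n_total:
            raise ValueError(
                f"could not place {n_total} sites with {spacing}-bp spacing in the genome"
            )
        ci = rng.choice(len(chroms), p=weights)
        chrom, length = chroms[ci]
        if length <= 2 * margin:
            continue
        pos = int(rng.integers(margin, length - margin))
        arr = occupied[chrom]
        k = bisect.bisect_left(arr, pos)
        if (k > 0 and pos - arr[k - 1] < spacing) or (k < len(arr) and arr[k] - pos < spacing):
            continue
        arr.insert(k, pos)
        placed.append((chrom, pos))
    return placed


def _balanced_offsets(n: int, jitter: int, rng: np.random.Generator) -> np.ndarray:
    """Random permutation of a balanced offset multiset over ±jitter.

    Each offset value appears (as nearly as possible) equally often and the
    multiset sums to exactly zero, so every site's offset is uniform over
    the range while the class-mean offset carries no sampling error.  This
    keeps the peak-maximum frame identifiable: recentring the recovered
    shift distribution restores it exactly instead of up to a random ±1.
    """
    values = np.arange(-jitter, jitter + 1)
    pool = list(np.tile(values, n // len(values)))
    remainder = n - len(pool)
    extra: list[int] = [0] if remainder % 2 else []
    k = 1
    while len(extra) < remainder:
        extra.extend([k, -k])
        k += 1
    pool.extend(extra[:remainder])
    pool = np.array(pool, dtype=int)
    rng.shuffle(pool)
    return pool


def simulate_site_classes(spec: SimulationSpec, index: GenomeIndex
                          ) -> tuple[list[Site], pd.DataFrame]:
    """Place fast/slow/free-MNase peaks and random null sites; emit ground truth.

    Peak classes get pairwise-disjoint shape windows; random sites are null
    intervals avoiding every peak window.  The ground-truth table records,
    per site, the planted signature displacement (``planted_shift``; a
    perfect alignment recovers shifts equal to these displacements) and
    whether the signature is present.
    """
    rng = _spawn(spec.seed, "sites")
    margin = spec.shape_window // 2 + 1
    peak_classes = ("fast", "slow", "free_mnase")
    positions = _place_sites(index, spec.n_sites * len(peak_classes),
                             spacing=spec.shape_window, margin=margin, rng=rng)
    order = rng.permutation(len(positions))
    sites: list[Site] = []
    truth_rows = []
    for k, class_label in enumerate(peak_classes):
        offsets = _balanced_offsets(spec.n_sites, spec.shift_jitter, rng) \
            if class_label in ("fast", "slow") else np.zeros(spec.n_sites, dtype=int)
        for j in range(spec.n_sites):
            chrom, pos = positions[order[k * spec.n_sites + j]]
            sid = f"{class_label}_{j:05d}"
            sites.append(Site(chrom, pos, class_label, sid))
            truth_rows.append((sid, class_label, chrom, pos, int(offsets[j]),
                               class_label in ("fast", "slow")))
    exclude = [(s.chrom, *s.window(spec.shape_window)) for s in sites]
    null = generate_null_intervals(index, exclude, n=spec.n_sites,
                                   width=spec.shape_window, seed=rng)
    for s in null_interval_sites(null):
        sites.append(s)
        truth_rows.append((s.site_id, "random", s.chrom, s.peak_max, 0, False))
    truth = pd.DataFrame(truth_rows, columns=[
        "site_id", "class_label", "chrom", "peak_max", "planted_shift", "has_signature"])
    return sites, truth


def simulate_shape_track(spec: SimulationSpec, index: GenomeIndex, sites: list[Site],
                         truth: pd.DataFrame) -> ShapeTrack:
    """Baseline-plus-noise track with the signature and cleavage bias planted.

    The genome-wide background is each feature's baseline plus Gaussian
    noise of sd ``noise_sd * feature_scale``; slow-site windows receive
    extra noise to reach ``slow_noise_factor`` times that sd.  The
    signature bump is added at ``peak + signature_offset + planted_shift``
    for fast and slow sites, and the A/T cleavage-bias dip at the centre of
    every MNase-derived (fast, slow, free_mnase) peak.
    """
    rng = _spawn(spec.seed, "track")
    scales = spec.scales
    baselines = spec.baselines
    track = ShapeTrack()
    for chrom, length in index.lengths.items():
        values = np.empty((N_FEATURES, length))
        for f, feat in enumerate(FEATURES):
            sd = spec.noise_sd * scales[feat]
            values[f] = baselines[feat] + rng.normal(0.0, sd, size=length) if sd > 0 \
                else baselines[feat]
        track.add(chrom, 0, values)

    planted = truth.set_index("site_id")["planted_shift"]
    signature = signature_curves(spec)
    bias_profile = _half_cosine(spec.center_bias_width)
    extra = np.sqrt(max(spec.slow_noise_factor ** 2 - 1.0, 0.0)) * spec.noise_sd
    half = spec.shape_window // 2
    for site in sites:
        _, values = track.data[site.chrom]
        if site.class_label == "slow" and extra > 0:
            lo, hi = site.peak_max - half, site.peak_max + half + 1
            for f, feat in enumerate(FEATURES):
                values[f, lo:hi] += rng.normal(0.0, extra * scales[feat], size=hi - lo)
        if site.class_label in ("fast", "slow"):
            center = site.peak_max + spec.signature_offset + int(planted[site.site_id])
            lo = center - (spec.signature_span - 1) // 2
            values[:, lo:lo + spec.signature_span] += signature
        if site.class_label in ("fast", "slow", "free_mnase"):
            lo = site.peak_max - (spec.center_bias_width - 1) // 2
            for feat, amp in dict(spec.center_bias).items():
                values[FEATURES.index(feat), lo:lo + spec.center_bias_width] += amp * bias_profile
    return track


def embed_at_tracts(sequences: dict[str, str], spec: SimulationSpec, sites: list[Site],
                    truth: pd.DataFrame) -> dict[str, str]:
    """Sequence-level variant: write literal poly(dA:dT) runs under fast/slow peaks.

    Lets the pentamer-lookup path see a tract-induced deformation at the
    planted offset, so track-based and sequence-based pipelines can be
    exercised end to end on the same ground truth.
    """
    if not spec.at_tract:
        return sequences
    planted = truth.set_index("site_id")["planted_shift"]
    editable = {c: list(s) for c, s in sequences.items()}
    for site in sites:
        if site.class_label not in ("fast", "slow"):
            continue
        center = site.peak_max + spec.signature_offset + int(planted[site.site_id])
        lo = center - spec.at_tract // 2
        for k in range(spec.at_tract):
            editable[site.chrom][lo + k] = "A"
    return {c: "".join(s) for c, s in editable.items()}


@dataclass
class SimulatedDataset:
    spec: SimulationSpec
    sequences: dict[str, str]
    index: GenomeIndex
    sites: list[Site]
    truth: pd.DataFrame
    track: ShapeTrack
    table: PentamerShapeTable

    def sites_by_class(self) -> dict[str, list[Site]]:
        out: dict[str, list[Site]] = {}
        for s in self.sites:
            out.setdefault(s.class_label, []).append(s)
        return out


def simulate_dataset(spec: SimulationSpec | None = None) -> SimulatedDataset:
    """Full synthetic dataset: genome, site classes, shape track, ground truth."""
    spec = spec or SimulationSpec()
    sequences, index = simulate_genome(spec)
    sites, truth = simulate_site_classes(spec, index)
    table = toy_pentamer_table()
    if spec.at_tract:
        sequences = embed_at_tracts(sequences, spec, sites, truth)
        track = ShapeTrack.from_genome(sequences, table)
    else:
        track = simulate_shape_track(spec, index, sites, truth)
    return SimulatedDataset(spec=spec, sequences=sequences, index=index, sites=sites,
                            truth=truth, track=track, table=table)


def simulate_genes(index: GenomeIndex, sites: list[Site], seed: int = 0,
                   n_background: int = 50, gene_length: int = 400) -> pd.DataFrame:
    """One gene within <=1 kb of (almost) every site, plus distant background genes."""
    rng = np.random.default_rng(seed)
    rows = []
    gid = 0
    lengths = index.lengths
    for site in sites:
        gap = int(rng.integers(100, 601))
        start = site.peak_max + gap
        end = min(start + gene_length, lengths[site.chrom])
        if start >= lengths[site.chrom]:
            continue
        rows.append((site.chrom, start, end, f"gene_{gid:05d}", "+"))
        gid += 1
    for _ in range(n_background):
        chrom = str(rng.choice(index.chrom_names))
        start = int(rng.integers(0, max(lengths[chrom] - gene_length, 1)))
        rows.append((chrom, start, start + gene_length, f"gene_{gid:05d}", "+"))
        gid += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "strand"])


def simulate_association_table(assignments: pd.DataFrame, tf: str = "TF1",
                               p_signal: float = 0.8, p_control: float = 0.3,
                               seed: int = 0) -> pd.DataFrame:
    """Regulatory-association table: signal-class genes associated with probability
    ``p_signal``, control-class genes with ``p_control``.

    ``assignments`` needs columns gene_id and class_label (rows without a
    gene are ignored).  Associated genes are split between ``documented``
    and ``proposed`` evidence at random.
    """
    for p in (p_signal, p_control):
        if not 0 <= p <= 1:
            raise ValueError("association probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    seen = set()
    for gene, class_label in assignments[["gene_id", "class_label"]].dropna().itertuples(index=False):
        if gene in seen:
            continue
        seen.add(gene)
        p = p_signal if class_label in ("fast", "slow") else p_control
        if rng.random() < p:
            evidence = "documented" if rng.random() < 0.5 else "proposed"
            rows.append((gene, tf, evidence))
    return pd.DataFrame(rows, columns=["gene_id", "tf", "evidence"])
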