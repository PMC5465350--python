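"""End-to-end driver: select -> shapes -> align -> profile -> score -> stats.

Runs the whole analysis at a ladder of disjointness widths (100-500 bp,
larger widths more stringent).  One configuration object is shared by every
site class at every width — no class ever receives special parameters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import AlignmentConfig, align_class
from .intervals import (
    DEFAULT_NULL_COUNT,
    DEFAULT_SHAPE_WINDOW,
    GenomeIndex,
    Site,
    find_unique_sites,
    generate_null_intervals,
    null_interval_sites,
    select_alignable_sites,
)
from .profile import (
    DEFAULT_MERGE_GAP,
    DEFAULT_MIN_RUN,
    DEFAULT_N_BINS,
    DEFAULT_N_SHUFFLES,
    DEFAULT_PSEUDOCOUNT,
    DEFAULT_TOP_FRACTION,
    define_profile,
    information_gain,
    score_class,
    shuffled_background,
)
from .shapes import ShapeTrack, extract_shape_window
from .stats import association_enrichment, assign_genes, compare_class_averages, \
    compare_score_distributions

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

PEAK_CLASSES = ("fast", "slow", "free_mnase")
REFERENCE_CLASS = "fast"


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name and the offending width."""

    def __init__(self, stage: str, width: int | None, cause: Exception):
        super().__init__(f"pipeline stage '{stage}'"
                         + (f" at width {width}" if width is not None else "")
                         + f" failed: {cause}")
        self.stage, self.width, self.cause = stage, width, cause


@dataclass(frozen=True)
class PipelineConfig:
    """Shared configuration for every class at every width."""

    widths: tuple[int, ...] = (100, 200, 300, 400, 500)
    shape_window: int = DEFAULT_SHAPE_WINDOW
    n_null_intervals: int = DEFAULT_NULL_COUNT
    alignment: AlignmentConfig = field(default_factory=AlignmentConfig)
    n_shuffles: int = DEFAULT_N_SHUFFLES
    n_bins: int = DEFAULT_N_BINS
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    top_fraction: float = DEFAULT_TOP_FRACTION
    merge_gap: int = DEFAULT_MERGE_GAP
    min_run: int = DEFAULT_MIN_RUN
    max_imputed_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.widths:
            raise ValueError("at least one width is required")
        if list(self.widths) != sorted(self.widths):
            raise ValueError("widths must be ascending")
        for w in self.widths:
            if not 100 <= w <= 500:
                raise ValueError(f"width {w} outside the supported range [100, 500]")
        if self.shape_window % 2 == 0:
            raise ValueError("shape_window must be odd")
        self.alignment.validate_window(self.shape_window)


def _stage_seed(master: int, stage: str, width: int = 0) -> int:
    import zlib
    return int(np.random.SeedSequence(
        (master, zlib.crc32(stage.encode()), width)).generate_state(1)[0] % (2 ** 31))


def _extract_windows(sites, source, table, config):
    windows = []
    for site in sites:
        w = extract_shape_window(site, source, window=config.shape_window, table=table)
        if w.imputed_fraction <= config.max_imputed_fraction:
            windows.append(w)
    return windows


def run_pipeline(
    sites_by_class: dict[str, list[Site]],
    shape_source,
    genome_index: GenomeIndex,
    config: PipelineConfig | None = None,
    table=None,
    genes: pd.DataFrame | None = None,
    association: pd.DataFrame | None = None,
    tf: str | None = None,
    out_dir=None,
) -> dict:
    """Run the full analysis over every configured width; return the summary.

    ``sites_by_class`` holds the peak classes (fast / slow / free_mnase);
    the random class is drawn internally as null intervals avoiding every
    peak window (at the most stringent width) unless a ``random`` entry is
    supplied.  ``shape_source`` is a ShapeTrack, or genome sequences with
    ``table`` for the pentamer path.  Optional ``genes`` + ``association``
    + ``tf`` switch on the regulatory-association analysis.  When
    ``out_dir`` is given, per-width tables and the JSON summary are written
    beneath it.
    """
    config = config or PipelineConfig()
    peak_sites = [s for c in PEAK_CLASSES for s in sites_by_class.get(c, [])]
    if not sites_by_class.get(REFERENCE_CLASS):
        raise PipelineError("input", None, ValueError("a fast site class is required"))

    if "random" in sites_by_class:
        random_sites = list(sites_by_class["random"])
    else:
        try:
            exclude = [(s.chrom, *s.window(max(config.widths))) for s in peak_sites]
            random_sites = null_interval_sites(generate_null_intervals(
                genome_index, exclude, n=config.n_null_intervals,
                width=config.shape_window,
                seed=_stage_seed(config.seed, "null_intervals")))
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise PipelineError("null_intervals", None, exc) from exc

    align_cache: dict[tuple, object] = {}
    summary: dict = {"config": {"widths": list(config.widths),
                                "shape_window": config.shape_window,
                                "n_null_intervals": config.n_null_intervals,
                                "max_shift": config.alignment.max_shift,
                                "align_window": config.alignment.align_window,
                                "center_exclusion": config.alignment.center_exclusion,
                                "seed": config.seed},
                     "widths": {}}
    out_path = None
    if out_dir is not None:
        from pathlib import Path
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)

    for width in config.widths:
        record: dict = {"classes": {}, "comparisons": {}}
        try:
            unique = find_unique_sites(peak_sites, width)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("unique_sites", width, exc) from exc
        try:
            alignable = select_alignable_sites(unique + random_sites, genome_index,
                                               config.shape_window)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("alignable_sites", width, exc) from exc

        by_class: dict[str, list[Site]] = {}
        for s in alignable:
            by_class.setdefault(s.class_label, []).append(s)
        for class_label in (*PEAK_CLASSES, "random"):
            n_unique = sum(1 for s in unique if s.class_label == class_label) \
                if class_label != "random" else len(random_sites)
            record["classes"][class_label] = {
                "n_unique": n_unique,
                "n_alignable": len(by_class.get(class_label, [])),
            }

        results = {}
        scores = {}
        try:
            for class_label, class_sites in by_class.items():
                key = (class_label, tuple(s.site_id for s in class_sites))
                if key in align_cache:  # same alignable set as an earlier width
                    results[class_label] = align_cache[key]
                else:
                    windows = _extract_windows(class_sites, shape_source, table, config)
                    if len(windows) < 2:
                        logger.warning("width %d: class %s has %d alignable windows; "
                                       "skipped", width, class_label, len(windows))
                        continue
                    results[class_label] = align_cache[key] = \
                        align_class(windows, config.alignment)
                record["classes"][class_label]["n_aligned"] = len(results[class_label].site_ids)
                record["classes"][class_label]["centroid"] = results[class_label].centroid_id
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("alignment", width, exc) from exc

        if REFERENCE_CLASS not in results:
            raise PipelineError("alignment", width,
                                ValueError("reference class could not be aligned"))

        try:
            fast = results[REFERENCE_CLASS]
            background = shuffled_background(
                fast.aligned_matrix, config=config.alignment,
                n_shuffles=config.n_shuffles,
                seed=_stage_seed(config.seed, "background", width))
            gain = information_gain(fast.aligned_matrix, background,
                                    n_bins=config.n_bins, pseudocount=config.pseudocount)
            profile = define_profile(fast.class_average, gain,
                                     top_fraction=config.top_fraction,
                                     merge_gap=config.merge_gap, min_run=config.min_run,
                                     background_spec={"n_shuffles": config.n_shuffles,
                                                      "mode": "value_permutation"})
            record["profile"] = {
                "threshold": profile.threshold,
                "regions": [{"feature": r.feature, "start": r.start, "end": r.end}
                            for r in profile.regions],
            }
            for class_label, res in results.items():
                scores[class_label] = score_class(res.aligned_matrix, profile)
                record["classes"][class_label]["median_score"] = float(
                    np.median(scores[class_label]))
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("profile", width, exc) from exc

        try:
            for class_label, res in results.items():
                if class_label == REFERENCE_CLASS:
                    continue
                cmp_avg = compare_class_averages(
                    fast.class_average, res.class_average,
                    REFERENCE_CLASS, class_label, config.alignment)
                per_feat = compare_class_averages(
                    fast.class_average, res.class_average,
                    REFERENCE_CLASS, class_label, config.alignment, per_feature=True)
                cmp_scores = compare_score_distributions(
                    scores[REFERENCE_CLASS], scores[class_label],
                    REFERENCE_CLASS, class_label)
                record["comparisons"][class_label] = {
                    "pearson_r": cmp_avg.statistic, "pearson_p": cmp_avg.pvalue,
                    "per_feature_r": {c.statistic_name.split("[")[1][:-1]: c.statistic
                                      for c in per_feat},
                    "mannwhitney_U": cmp_scores.statistic,
                    "mannwhitney_p": cmp_scores.pvalue,
                }
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("statistics", width, exc) from exc

        if genes is not None and association is not None and tf is not None:
            try:
                aligned_sites = [s for c in results for s in by_class[c]]
                assignments = assign_genes(aligned_sites, genes)
                enrich = association_enrichment(assignments, association, tf)
                record["association"] = enrich.to_dict(orient="records")
            except Exception as exc:  # noqa: BLE001
                raise PipelineError("association", width, exc) from exc

        summary["widths"][str(width)] = record

        if out_path is not None:
            wdir = out_path / f"width_{width}"
            wdir.mkdir(exist_ok=True)
            for class_label, res in results.items():
                res.shifts_table().to_csv(wdir / f"shifts_{class_label}.tsv",
                                          sep="\t", index=False)
                res.average_table().to_csv(wdir / f"average_{class_label}.tsv",
                                           sep="\t", index=False)
                pd.DataFrame({"site_id": res.site_ids, "class_label": class_label,
                              "score": scores[class_label]}).to_csv(
                    wdir / f"scores_{class_label}.tsv", sep="\t", index=False)
            profile.table().to_csv(wdir / "profile.tsv", sep="\t", index=False)

    if out_path is not None:
        (out_path / "summary.json").write_text(
            json.dumps(summary, sort_keys=True, indent=2, default=_jsonify) + "\n")
    return summary


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
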