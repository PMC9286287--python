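"""End-to-end orchestration: simulate/read → filter → detect → compare → classify → summarize.

All times are ZT hours (0 = lights-on, 12 = lights-off), phases reported
in [0, 24); bins half-open; thresholds strict.  Every stage writes a TSV
and the run ends with a JSON manifest echoing the full effective
configuration, the seed, per-stage gene counts and a content hash per
output file, so a rerun with the same config and seed reproduces every
output byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import classify_all, default_rule_table
from .compare import compare_table
from .detect import PeriodGrid, TimeSeries, bh_adjust, fisher_combine, jtk_scan, lomb_scargle_test
from .circular import PhaseSample, mean_direction_ci95, mean_vector, phase_histogram, rayleigh_test
from .io import ExpressionTable, low_count_filter, read_expression, write_expression
from .simulate import (
    DEFAULT_FRACTIONS,
    SimulationDesign,
    generate_truth,
    simulate_dataset,
    truth_frame,
)

__all__ = [
    "SimulateConfig",
    "DetectConfig",
    "CompareConfig",
    "ClassifyConfig",
    "SummarizeConfig",
    "PipelineConfig",
    "detect_group",
    "compare_groups",
    "join_stats",
    "summarize_phases",
    "run_pipeline",
]

log = logging.getLogger("rhythmdiff")

_FLOAT_FMT = "%.10g"


@dataclass
class SimulateConfig:
    n_genes: int = 2000
    fractions: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FRACTIONS))
    phases: dict[str, tuple[float, float]] | None = None
    noise: str = "lognormal_cv"
    noise_cv: float = 0.10
    rel_amplitude: float = 0.5
    groups: tuple[str, ...] = ("WT", "KO")
    animals_per_pool: int = 3


@dataclass
class DetectConfig:
    minper: float = 20.0
    maxper: float = 28.0
    interval_h: float = 3.0
    concat: int = 2
    adjust: str = "bonferroni_all"
    lomb_scargle: bool = False


@dataclass
class CompareConfig:
    group_a: str | None = None  # reference; defaults to first group
    group_b: str | None = None  # test; defaults to second group
    period_h: float = 24.0
    include_mesor: bool = False
    concat: int = 1  # harmonic comparison runs on the single-cycle series


@dataclass
class ClassifyConfig:
    orientation: str = "difference_consistent"
    adjp1: float = 0.05
    adjp2: float = 0.1
    metap: float = 0.01
    phase_h: float = 6.0
    rhythm_column: str = "adj_p"  # or 'q_bh'


@dataclass
class SummarizeConfig:
    bin_h: float = 3.0


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "rhythmdiff_out"
    input: str | None = None  # expression TSV; when absent, simulate
    input_kind: str = "abundance"
    counts_input: str | None = None  # optional raw-count TSV for filtering
    min_total_count: float = 100.0
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    compare: CompareConfig = field(default_factory=CompareConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    summarize: SummarizeConfig = field(default_factory=SummarizeConfig)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        kw = dict(d)
        for name, sub in (
            ("simulate", SimulateConfig),
            ("detect", DetectConfig),
            ("compare", CompareConfig),
            ("classify", ClassifyConfig),
            ("summarize", SummarizeConfig),
        ):
            if name in kw and isinstance(kw[name], Mapping):
                kw[name] = sub(**kw[name])
        cfg = cls(**kw)
        cfg.simulate.groups = tuple(cfg.simulate.groups)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict[str, Any]:
        # JSON round-trip normalises tuples to lists so YAML/JSON echoes compare equal
        return json.loads(json.dumps(dataclasses.asdict(self)))

    def validate(self) -> None:
        c = self.classify
        for thr in (c.adjp1, c.adjp2, c.metap):
            if not (0 < thr < 1):
                raise ValueError("classification p thresholds must lie in (0, 1)")
        if not (0 < c.phase_h <= 12):
            raise ValueError("phase threshold must lie in (0, 12] hours")
        if self.detect.concat < 1 or self.compare.concat < 1:
            raise ValueError("concat must be >= 1")


def _concat_block(zts: np.ndarray, values: np.ndarray, n_cycles: int, cycle_h: float = 24.0):
    if n_cycles == 1:
        return zts, values
    times = np.concatenate([zts + k * cycle_h for k in range(n_cycles)])
    return times, np.tile(values, (1, n_cycles))


def detect_group(
    table: ExpressionTable, group: str, cfg: DetectConfig | None = None
) -> pd.DataFrame:
    """Rank-based rhythm statistics for every gene of one group.

    Emits gene_id, group, p, adj_p, q_bh (BH across genes), period_h,
    lag_h, tau, amplitude_est — plus ls_p and meta_p columns when the
    Lomb–Scargle second detector is enabled.
    """
    cfg = cfg or DetectConfig()
    grid = PeriodGrid(cfg.interval_h, cfg.minper, cfg.maxper)
    zts, block = table.group_block(group)
    values = block.to_numpy()
    times, values_c = _concat_block(zts, values, cfg.concat)
    res = jtk_scan(values_c, times, grid, gene_ids=list(block.index), adjust=cfg.adjust)
    res.insert(1, "group", group)
    res["q_bh"] = bh_adjust(res["p"])
    if cfg.lomb_scargle:
        ls = [
            lomb_scargle_test(TimeSeries(times, row), grid)
            for row in values_c
        ]
        res["ls_p"] = ls
        res["meta_p_detect"] = [
            fisher_combine([pj, pl]) for pj, pl in zip(res["p"], res["ls_p"])
        ]
    n_const = int(res["constant"].sum())
    if n_const:
        log.warning("%d constant series in group %s (p set to 1, phase undefined)", n_const, group)
    return res


def compare_groups(
    table: ExpressionTable, group_a: str, group_b: str, cfg: CompareConfig | None = None
) -> pd.DataFrame:
    """Harmonic-regression comparison of every gene between two groups."""
    cfg = cfg or CompareConfig()
    zts_a, block_a = table.group_block(group_a)
    zts_b, block_b = table.group_block(group_b)
    if list(block_a.index) != list(block_b.index):
        raise ValueError("groups carry different gene sets")
    t_a, va = _concat_block(zts_a, block_a.to_numpy(), cfg.concat)
    t_b, vb = _concat_block(zts_b, block_b.to_numpy(), cfg.concat)
    if not np.array_equal(t_a, t_b):
        raise ValueError("groups must share sampling times")
    return compare_table(
        va, vb, t_a, list(block_a.index), period_h=cfg.period_h, include_mesor=cfg.include_mesor
    )


def join_stats(
    detect_g1: pd.DataFrame,
    detect_g2: pd.DataFrame,
    comparison: pd.DataFrame,
    rhythm_column: str = "adj_p",
) -> pd.DataFrame:
    """Join per-group rhythm stats and the comparison into classifier input.

    Group 1 is the test condition, group 2 the reference.  Phases come
    from the rank-test peak lag of each group and are undefined (NaN)
    for constant series.
    """
    if rhythm_column not in ("adj_p", "q_bh"):
        raise ValueError("rhythm_column must be 'adj_p' or 'q_bh'")
    g1 = detect_g1.set_index("gene_id")
    g2 = detect_g2.set_index("gene_id")
    cmp_ = comparison.set_index("gene_id")
    joined = pd.DataFrame(
        {
            "adjp_g1": g1[rhythm_column],
            "adjp_g2": g2[rhythm_column],
            "meta_p": cmp_["meta_p"],
            "phase_g1_h": g1["lag_h"],
            "phase_g2_h": g2["lag_h"],
        }
    )
    if joined.isna().any(axis=None):
        bad = joined[["adjp_g1", "adjp_g2", "meta_p"]].isna().any(axis=1)
        if bad.any():
            raise ValueError(f"gene sets of the stages disagree (e.g. {joined.index[bad][0]!r})")
    return joined.reset_index()


def summarize_phases(
    classified: pd.DataFrame, phase_column: str = "phase_g1_h", bin_h: float = 3.0
) -> pd.DataFrame:
    """Per-category circular summaries of peak phases.

    One row per category present: n, circular mean (ZT h), resultant R,
    Rayleigh p, 95% CI bounds, and 24/bin_h histogram counts.
    """
    rows = []
    n_bins = int(round(24.0 / bin_h))
    for cat, sub in classified.groupby("category", sort=True):
        phases = sub[phase_column].dropna().to_numpy()
        row: dict[str, Any] = {"category": cat, "n": int(phases.size)}
        if phases.size:
            sample = PhaseSample(phases)
            mean_h, r = mean_vector(sample)
            row.update(mean_phase_h=mean_h, R=r)
            row["rayleigh_p"] = rayleigh_test(sample) if phases.size >= 2 else np.nan
            try:
                lo, hi = mean_direction_ci95(sample)
            except ValueError:
                lo = hi = np.nan
            row.update(ci95_lower_h=lo, ci95_upper_h=hi)
            hist = phase_histogram(sample, bin_h)
        else:
            row.update(mean_phase_h=np.nan, R=np.nan, rayleigh_p=np.nan,
                       ci95_lower_h=np.nan, ci95_upper_h=np.nan)
            hist = np.zeros(n_bins, dtype=int)
        for k in range(n_bins):
            row[f"bin_{int(k * bin_h):02d}"] = int(hist[k])
        rows.append(row)
    return pd.DataFrame(rows)


def _write_tsv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full analysis; returns the result bundle.

    Bundle keys: table, truth (when simulated), detect (per group),
    comparison, classified, counts, summary_g1/summary_g2, manifest,
    outdir.  Any stage failure aborts with the stage named.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    stage_counts: dict[str, int] = {}
    bundle: dict[str, Any] = {"outdir": outdir}

    def _stage(name):
        log.info("stage: %s", name)
        return name

    stage = _stage("input")
    try:
        truth_df = None
        if config.input is not None:
            table = read_expression(config.input, kind=config.input_kind)
        else:
            sim = config.simulate
            design = SimulationDesign(
                groups=tuple(sim.groups),
                animals_per_pool=sim.animals_per_pool,
                seed=config.seed,
            )
            truth = generate_truth(
                sim.n_genes,
                sim.fractions,
                sim.phases,
                seed=config.seed,
                groups=design.groups,
                rel_amplitude=sim.rel_amplitude,
                noise_cv=sim.noise_cv,
            )
            ds = simulate_dataset(design, truth, noise_model=sim.noise, seed=config.seed)
            table = ExpressionTable.from_matrix(ds.expression, kind="abundance")
            truth_df = truth_frame(truth, design.groups)
            files["truth"] = _write_tsv(truth_df, outdir / "truth.tsv")
        files["expression"] = write_expression(table, outdir / "expression.tsv")
        stage_counts["input_genes"] = table.matrix.shape[0]
        bundle["table"], bundle["truth"] = table, truth_df

        if config.counts_input is not None:
            stage = _stage("filter")
            counts = read_expression(config.counts_input, kind="counts")
            kept, n_removed = low_count_filter(counts, config.min_total_count)
            table = ExpressionTable(
                matrix=table.matrix.loc[table.matrix.index.intersection(kept.matrix.index)],
                samples=table.samples,
                kind=table.kind,
            )
            stage_counts["filtered_out"] = n_removed
            stage_counts["post_filter_genes"] = table.matrix.shape[0]
            bundle["table"] = table

        stage = _stage("detect")
        groups = list(table.groups)
        ga = config.compare.group_a or groups[0]
        gb = config.compare.group_b or groups[1]
        det = {}
        for g in (ga, gb):
            det[g] = detect_group(table, g, config.detect)
            files[f"rhythm_{g}"] = _write_tsv(det[g], outdir / f"rhythm_{g}.tsv")
        bundle["detect"] = det

        stage = _stage("compare")
        comparison = compare_groups(table, ga, gb, config.compare)
        files["comparison"] = _write_tsv(comparison, outdir / f"compare_{gb}_vs_{ga}.tsv")
        bundle["comparison"] = comparison

        stage = _stage("classify")
        # group 1 of the decision table is the test condition (e.g. KO)
        joined = join_stats(det[gb], det[ga], comparison, config.classify.rhythm_column)
        rules = default_rule_table(
            config.classify.orientation,
            config.classify.adjp1,
            config.classify.adjp2,
            config.classify.metap,
            config.classify.phase_h,
        )
        classified, counts_s = classify_all(joined, rules)
        files["classified"] = _write_tsv(classified, outdir / "classified.tsv")
        counts_df = counts_s.rename_axis("category").reset_index()
        files["category_counts"] = _write_tsv(counts_df, outdir / "category_counts.tsv")
        stage_counts.update({f"category_{k}": int(v) for k, v in counts_s.items()})
        bundle["classified"], bundle["counts"] = classified, counts_s

        stage = _stage("summarize")
        for label, col in (("g1", "phase_g1_h"), ("g2", "phase_g2_h")):
            summ = summarize_phases(classified, col, config.summarize.bin_h)
            files[f"summary_{label}"] = _write_tsv(summ, outdir / f"summary_{label}.tsv")
            bundle[f"summary_{label}"] = summ
    except Exception as exc:  # noqa: BLE001 - annotate failing stage and re-raise
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "software": {"name": "rhythmdiff", "version": __version__},
        "seed": config.seed,
        "groups": {"reference_g2": ga, "test_g1": gb},
        "config": config.to_dict(),
        "stage_counts": stage_counts,
        "files": {k: {"path": p.name, "sha256": _sha256(p)} for k, p in sorted(files.items())},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    bundle["manifest"] = manifest
    return bundle
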