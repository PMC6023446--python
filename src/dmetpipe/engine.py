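"""Pipeline orchestration: one command runs all three analyses.

The stage graph is fixed: load/parse -> preprocess -> two independent
branches run concurrently — the survival screens (OS and/or PFS), and the
statistical branch (Fisher screening + HWE) followed by rule mining.  The
survival branch needs no user-supplied thresholds beyond the endpoint list,
so it proceeds in the background of the statistical branch.  Every output
is bit-identical for the same configuration regardless of worker count:
work is distributed over a bounded thread pool and collected in submission
order, and each stage's result ordering is fully specified.
"""

from __future__ import annotations

import logging
import os
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Any, Callable

from . import io_dmet, preprocess, rulemining, stats, survival
from .io_dmet import GenotypeTable, PhenotypeAssignment, SurvivalAnnotation

log = logging.getLogger("dmetpipe")


@dataclass
class PipelineConfig:
    genotype_path: str | None = None
    class_path: str | None = None
    survival_path: str | None = None
    out_dir: str | None = None
    sep: str = ","
    transpose: bool = False
    max_nocall_fraction: float = 0.1
    drop_monomorphic: bool = True
    corrector: str = "bonferroni"
    alpha: float = 0.05
    fisher_filter: float = 0.05
    min_support: float = 0.2
    min_confidence: float = 0.8
    endpoints: tuple[str, ...] = ("OS", "PFS")
    worker_count: int = 0  # 0 = auto-detect
    seed: int = 0
    collect_curves: bool = False

    def __post_init__(self) -> None:
        if self.worker_count < 0:
            raise ValueError("worker_count must be >= 0")
        if self.corrector not in stats.CORRECTORS:
            raise ValueError(f"corrector must be one of {stats.CORRECTORS}")
        for name in ("alpha", "fisher_filter", "min_support", "min_confidence"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        bad = [e for e in self.endpoints if e not in survival.ENDPOINTS]
        if bad:
            raise ValueError(f"unknown endpoints {bad}; choose from {survival.ENDPOINTS}")

    def echo(self) -> dict:
        return {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }


@dataclass
class PipelineResults:
    config_echo: dict = field(default_factory=dict)
    preprocess_report: preprocess.PreprocessReport | None = None
    distribution: preprocess.DistributionMatrix | None = None
    fisher: Any = None
    hwe: Any = None
    rules: dict | None = None
    survival: dict | None = None
    km_curves: dict | None = None
    stage_status: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)


class WorkItemError(RuntimeError):
    """A worker failed; carries the identity of the offending item."""

    def __init__(self, label, cause: BaseException):
        super().__init__(f"work item {label!r} failed: {cause}")
        self.label = label
        self.cause = cause


def parallel_map(
    fn: Callable,
    items,
    worker_count: int = 0,
    labels=None,
) -> list:
    """Apply ``fn`` over independent items, results in input order.

    The pool is bounded by ``min(worker_count, cpu_count)``; 0 auto-detects.
    1 worker gives plain sequential semantics.  A worker exception is
    re-raised as :class:`WorkItemError` naming the offending item.
    """
    items = list(items)
    if labels is None:
        labels = items
    else:
        labels = list(labels)
    n_workers = worker_count if worker_count > 0 else (os.cpu_count() or 1)
    n_workers = max(1, min(n_workers, os.cpu_count() or 1, len(items) or 1))
    if n_workers == 1:
        out = []
        for label, it in zip(labels, items):
            try:
                out.append(fn(it))
            except Exception as exc:
                raise WorkItemError(label, exc) from exc
        return out
    with ThreadPoolExecutor(max_workers=n_workers) as pool:
        futures = [pool.submit(fn, it) for it in items]
        out = []
        for label, fut in zip(labels, futures):
            try:
                out.append(fut.result())
            except Exception as exc:
                raise WorkItemError(label, exc) from exc
        return out


def run_pipeline_data(
    table: GenotypeTable,
    assignment: PhenotypeAssignment,
    surv: SurvivalAnnotation | None,
    config: PipelineConfig,
) -> PipelineResults:
    """Run every stage on in-memory inputs; see `run_pipeline` for file paths."""
    res = PipelineResults(config_echo=config.echo())

    def _stage(name: str, fn: Callable[[], Any]):
        t0 = time.perf_counter()
        try:
            value = fn()
        except Exception as exc:
            res.stage_status[name] = f"failed: {exc}"
            log.error("stage %s failed: %s", name, exc)
            return None
        res.stage_status[name] = "completed"
        res.stage_seconds[name] = round(time.perf_counter() - t0, 6)
        log.info("stage %s completed in %.2fs", name, res.stage_seconds[name])
        return value

    def _preprocess():
        filtered, report = preprocess.filter_uninformative(
            table, config.max_nocall_fraction, config.drop_monomorphic
        )
        res.preprocess_report = report
        if filtered.probe_ids:
            res.distribution = preprocess.genotype_distribution(filtered)
        return filtered

    filtered = _stage("preprocess", _preprocess)
    if filtered is None:
        return res

    def _stat_branch():
        res.fisher = _stage(
            "fisher_screen",
            lambda: stats.screen_probes(
                filtered, assignment, config.corrector, config.alpha
            ),
        )
        res.hwe = _stage("hwe", lambda: stats.hwe_screen(filtered))
        res.rules = _stage(
            "rule_mining",
            lambda: rulemining.mine_class_rules(
                filtered,
                assignment,
                config.fisher_filter,
                config.min_support,
                config.min_confidence,
            ),
        )

    def _survival_branch():
        if surv is None:
            for ep in config.endpoints:
                res.stage_status[f"survival_{ep}"] = "skipped: no survival annotation"
            return
        res.survival = {}
        res.km_curves = {}

        def _one(ep):
            return survival.survival_screen(
                filtered, surv, ep, collect_curves=config.collect_curves
            )

        for ep, value in zip(
            config.endpoints,
            parallel_map(
                lambda ep: _stage(f"survival_{ep}", lambda: _one(ep)),
                config.endpoints,
                config.worker_count,
            ),
        ):
            if value is not None:
                frame, curves = value
                res.survival[ep] = frame
                res.km_curves.update(curves)

    # the survival branch runs in the background of the statistical branch
    if config.worker_count == 1:
        _survival_branch()
        _stat_branch()
    else:
        with ThreadPoolExecutor(max_workers=2) as pool:
            fut_surv = pool.submit(_survival_branch)
            fut_stat = pool.submit(_stat_branch)
            for fut in (fut_surv, fut_stat):
                fut.result()
    return res


def run_pipeline(config: PipelineConfig) -> dict:
    """File-based entry point: read inputs, run all stages, write the bundle.

    Returns the run manifest (also written to ``out_dir/run_manifest.json``).
    """
    if config.genotype_path is None or config.class_path is None:
        raise ValueError("genotype_path and class_path are required")
    table = io_dmet.read_genotype_table(
        config.genotype_path, sep=config.sep, transpose=config.transpose
    )
    assignment = io_dmet.read_class_file(config.class_path, table.sample_ids)
    surv = None
    if config.survival_path:
        surv = io_dmet.read_survival_file(config.survival_path, table.sample_ids)
    results = run_pipeline_data(table, assignment, surv, config)
    if config.out_dir is None:
        raise ValueError("out_dir is required for a file-based run")
    return io_dmet.write_results_bundle(results, config.out_dir)
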