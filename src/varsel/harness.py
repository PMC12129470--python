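"""Orchestration of the full simulation study.

For every sample size and replicate, one dataset is generated and fed to
*every* method (paired comparison), so between-method differences are not
confounded by Monte-Carlo noise.  Per-replicate selections are archived as
JSON lines; summaries are pure functions of the archive.

Seed schedule: the dataset for (N, replicate) derives from
(master_seed, N, replicate); each method's internal RNG (CV folds etc.)
derives from (master_seed, N, replicate, method), so methods share data but
not RNG state.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .design import SimulationDesign, default_design, generate_dataset
from .metrics import TruthSpec, metric_table
from .result import SelectionResult
from .selectors import METHOD_TAGS, get_selector

__all__ = ["StudyConfig", "run_study", "summarize", "load_archive"]

DEFAULT_SAMPLE_SIZES = (225, 375, 500, 750, 1000)


@dataclass(frozen=True)
class StudyConfig:
    design: SimulationDesign = field(default_factory=lambda: default_design(225))
    methods: tuple[str, ...] = METHOD_TAGS
    sample_sizes: tuple[int, ...] = DEFAULT_SAMPLE_SIZES
    n_sims: int = 1000
    master_seed: int = 0
    output_dir: str = "results"
    workers: int = 1

    def __post_init__(self):
        unknown = [m for m in self.methods if m not in METHOD_TAGS]
        if unknown:
            raise ValueError(f"unknown method tags {unknown}")
        bad = [n for n in self.sample_sizes if n <= self.design.M]
        if bad:
            raise ValueError(f"sample sizes {bad} do not exceed M={self.design.M}")


def _derived_seed(*keys: int) -> int:
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2 ** 31))


def _dataset_for(config: StudyConfig, n: int, replicate: int):
    design = config.design.replace(N=n, seed=_derived_seed(config.master_seed, n))
    return generate_dataset(design, replicate)


def _dataset_hash(X: np.ndarray, Y: np.ndarray) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(Y).tobytes())
    return h.hexdigest()[:12]


def _run_cell(config: StudyConfig, n: int, replicate: int, methods: Sequence[str]):
    data = _dataset_for(config, n, replicate)
    dhash = _dataset_hash(data.X, data.Y)
    records = []
    for tag in methods:
        seed = _derived_seed(config.master_seed, n, replicate,
                             sum(tag.encode()))
        rec = {"method": tag, "N": n, "replicate": replicate, "dataset_hash": dhash}
        try:
            res = get_selector(tag)(data.X, data.Y, seed=seed)
            rec.update(res.as_dict())
        except Exception as exc:  # a method failure never aborts the study
            rec["error"] = f"{type(exc).__name__}: {exc}"
        records.append(rec)
    return records


def run_study(config: StudyConfig, progress: bool = False) -> Path:
    """Run (or resume) the study; returns the path of the JSONL archive."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    archive = outdir / "archive.jsonl"
    done: set[tuple[str, int, int]] = set()
    if archive.exists():
        for rec in load_archive(archive):
            done.add((rec["method"], rec["N"], rec["replicate"]))

    cells = []
    for n in config.sample_sizes:
        for replicate in range(1, config.n_sims + 1):
            todo = [m for m in config.methods if (m, n, replicate) not in done]
            if todo:
                cells.append((n, replicate, todo))

    if config.workers > 1:
        batches = Parallel(n_jobs=config.workers)(
            delayed(_run_cell)(config, n, r, todo) for n, r, todo in cells
        )
    else:
        batches = []
        for i, (n, r, todo) in enumerate(cells):
            batches.append(_run_cell(config, n, r, todo))
            if progress and (i + 1) % 25 == 0:
                import sys
                print(f"[harness] {i + 1}/{len(cells)} cells done", file=sys.stderr)

    with archive.open("a") as fh:
        for batch in batches:
            for rec in batch:
                fh.write(json.dumps(rec) + "\n")
    return archive


def load_archive(path) -> list[dict]:
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(json.loads(line))
    return records


def _records_to_results(records: Sequence[dict]) -> list[SelectionResult]:
    out = []
    for rec in records:
        out.append(SelectionResult(
            selected=tuple(rec["selected"]),
            coef=np.asarray(rec["coef"], float),
            intercept=rec["intercept"],
            method_tag=rec["method"],
        ))
    return out


def summarize(archive, truth: TruthSpec, output_dir=None) -> dict[str, pd.DataFrame]:
    """Aggregate an archive into the study's summary tables.

    Returns (and optionally writes as CSV) tables of average model size,
    error rates, per-predictor inclusion frequency and bias/RMSE, each
    indexed by method and sample size.
    """
    records = load_archive(archive) if not isinstance(archive, list) else archive
    records = [r for r in records if "error" not in r]
    if not records:
        raise ValueError("empty archive")
    tables = []
    keys = sorted({(r["method"], r["N"]) for r in records})
    for method, n in keys:
        cell = [r for r in records if r["method"] == method and r["N"] == n]
        results = _records_to_results(cell)
        tables.append(metric_table(results, truth, method, n))

    tidy = pd.concat([t.to_frame() for t in tables], ignore_index=True)
    scalar = tidy[tidy.predictor == ""].pivot_table(
        index="method", columns=["metric", "N"], values="value"
    )
    avg_tbl = tidy[tidy.metric == "avg_selected"].pivot_table(
        index="method", columns="N", values="value"
    )
    avg_tbl = avg_tbl.sort_values(by=avg_tbl.columns[0])
    err_tbl = tidy[tidy.metric.isin(["fpr", "fnr"])].pivot_table(
        index="method", columns=["metric", "N"], values="value"
    )
    vif_tbl = tidy[tidy.metric == "vif_pct"].pivot_table(
        index=["method", "predictor"], columns="N", values="value"
    )
    inf_tbl = tidy[tidy.metric.isin(["abs_bias", "rmse"])].pivot_table(
        index=["method", "predictor"], columns=["metric", "N"], values="value"
    )
    out = {
        "tidy": tidy, "avg_selected": avg_tbl, "error_rates": err_tbl,
        "vif": vif_tbl, "bias_rmse": inf_tbl, "scalar": scalar,
    }
    if output_dir is not None:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in out.items():
            df.to_csv(outdir / f"{name}.csv")
    return out
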