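"""End-to-end pipeline: screen → (load or synthesize cohort) → reduce → GRA.

A run is fully described by a :class:`PipelineConfig`; every output in the
run directory is regenerable bit-identically from the manifest the run
writes (config echo + seed + package versions).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError
from .factor_reduction import FactorSolution, reduce_block
from .grey_relational import run_gra_table
from .io import read_cohort, write_cohort, write_report
from .screening import ScreeningPanel, screen_items
from .synthetic_cohort import CohortMatrix, MomentSpec, generate_exact, generate_sampled

__all__ = ["PipelineConfig", "run_pipeline", "factor_solution_table"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    output_dir: str
    criterion: str
    cohort_csv: str | None = None  # either a cohort file ...
    moment_spec: dict | None = None  # ... or a spec for synthetic mode
    synthetic_mode: str = "exact"  # "exact" or "sampled"
    n: int | None = None
    seed: int | None = None
    panel_csv: str | None = None
    blocks: dict[str, list[str]] = field(default_factory=dict)
    reduce: bool = False
    # thresholds (defaults mirror the published constants)
    mean_threshold: float = 3.5
    sd_max: float = 1.0
    consensus_rule: str = "sd_max"
    kmo_min: float = 0.5
    bartlett_alpha: float = 0.05
    eigen_cut: float = 1.0
    loading_threshold: float = 0.4
    strong_cut: float = 0.9
    weak_cut: float = 0.8
    p: float = 0.5
    direction_alignment: bool = False

    def validate(self) -> None:
        if self.cohort_csv is None and self.moment_spec is None:
            raise ConfigError("either cohort_csv or moment_spec must be given")
        if self.moment_spec is not None:
            if self.n is None or self.seed is None:
                raise ConfigError("synthetic mode requires both n and seed")
            if self.synthetic_mode not in {"exact", "sampled"}:
                raise ConfigError(f"unknown synthetic_mode {self.synthetic_mode!r}")
        for name, val, lo, hi in [
            ("kmo_min", self.kmo_min, 0.0, 1.0),
            ("bartlett_alpha", self.bartlett_alpha, 0.0, 1.0),
            ("p", self.p, 0.0, 1.0),
            ("strong_cut", self.strong_cut, 0.0, 1.0),
            ("weak_cut", self.weak_cut, 0.0, 1.0),
        ]:
            if not lo <= val <= hi:
                raise ConfigError(f"{name}={val} outside [{lo}, {hi}]")

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def factor_solution_table(solution: FactorSolution) -> pd.DataFrame:
    """Serialize a block's factor solution in the published table layout.

    Columns: Code, Contribution, Representative indicators, Other
    indicators, followed by a diagnostics row (KMO, cumulative
    contribution, Bartlett p).
    """
    rows = []
    for j in sorted(solution.assigned):
        rep = solution.representatives.get(j)
        others = [n for n in solution.assigned[j] if n != rep]
        rows.append(
            {
                "Code": j + 1,
                "Contribution": round(float(solution.contributions[j]), 3),
                "Representative indicators": rep if rep is not None else "(none)",
                "Other indicators": "; ".join(others),
            }
        )
    rows.append(
        {
            "Code": "diagnostics",
            "Contribution": f"Cumulative = {solution.cumulative_contribution:.2f}%",
            "Representative indicators": f"KMO = {solution.kmo:.3f}",
            "Other indicators": f"Bartlett p = {solution.bartlett_p:.3g}"
            + ("" if solution.diagnostics_ok else f" [{solution.diagnostic_message}]"),
        }
    )
    return pd.DataFrame(rows)


def _obtain_cohort(config: PipelineConfig) -> CohortMatrix:
    if config.cohort_csv is not None:
        return read_cohort(config.cohort_csv, config.criterion)
    spec = MomentSpec.from_dict(config.moment_spec)
    gen = generate_exact if config.synthetic_mode == "exact" else generate_sampled
    return gen(spec, n=config.n, seed=config.seed)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all configured stages; return the run directory.

    Stage order: expert screening (if a panel is given) → cohort load or
    synthesis → per-block factor reduction (if requested) → grey relational
    analysis on the representative indicators (or all indicators when
    reduction is off).  Any stage failure aborts with the stage named.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}

    if config.panel_csv is not None:
        panel = ScreeningPanel.from_csv(
            config.panel_csv,
            mean_threshold=config.mean_threshold,
            consensus_rule=config.consensus_rule,
            sd_max=config.sd_max,
        )
        tables["screening_report"] = screen_items(panel)

    cohort = _obtain_cohort(config)
    if config.moment_spec is not None:
        write_cohort(cohort, out / "cohort.csv")
    unknown = [
        c for cols in config.blocks.values() for c in cols
        if c not in cohort.frame.columns
    ]
    if unknown:
        raise ConfigError(f"block columns not in cohort: {sorted(set(unknown))}")

    gra_columns = cohort.indicator_names
    if config.reduce and config.blocks:
        representatives: list[str] = []
        for block_name, columns in config.blocks.items():
            solution = reduce_block(
                cohort, block_name, columns,
                kmo_min=config.kmo_min,
                bartlett_alpha=config.bartlett_alpha,
                eigen_cut=config.eigen_cut,
                loading_threshold=config.loading_threshold,
            )
            tables[f"factors_{block_name}"] = factor_solution_table(solution)
            representatives.extend(solution.representative_names())
        if not representatives:
            raise ConfigError("factor reduction produced no representative indicators")
        gra_columns = representatives
        cohort = CohortMatrix(
            frame=cohort.frame[[config.criterion, *gra_columns]],
            criterion=config.criterion,
        )

    tables["gra_report"] = run_gra_table(
        cohort,
        p=config.p,
        strong_cut=config.strong_cut,
        weak_cut=config.weak_cut,
        direction_alignment=config.direction_alignment,
    )
    write_report(tables, out)

    manifest = {
        "prejump_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": config.to_dict(),
        "outputs": sorted(f"{name}.csv" for name in tables),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    logger.info("pipeline run complete: %s", out)
    return out
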