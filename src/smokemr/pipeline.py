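"""Bi-directional analysis orchestration: config, logging, reports, manifest.

A run takes two summary-statistic files (a smoking phenotype and a
psychiatric outcome), and for each requested direction performs instrument
selection -> harmonisation -> the five MR estimators -> sensitivity
diagnostics, writing results tables, drop logs and a manifest from which
every reported number is regenerable (config hash, seeds, versions).
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .mr_estimators import Diagnostics, MRConfig, run_mr
from .summary_stats import harmonise_datasets, read_summary_stats, select_instruments

logger = logging.getLogger("smokemr")


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce a bi-directional MR run."""

    exposure_path: str = ""
    outcome_path: str = ""
    exposure_type: str = "continuous"  # trait scale of the smoking phenotype
    outcome_type: str = "binary"
    exposure_n: float = float("nan")
    outcome_n: float = float("nan")
    direction: str = "both"  # forward | reverse | both
    p_threshold: float = 5e-8
    maf_limit: float = 0.3
    r2_min: float = 0.8
    clump_distance_kb: float = 10_000.0
    clump_r2: float = 0.001
    i2_simex_trigger: float = 0.9
    random_effects: bool = True
    n_boot: int = 1000
    seed: int = 0
    exclude_snps: tuple = ()
    proxy_path: Optional[str] = None
    ld_path: Optional[str] = None
    exposure_columns: dict = field(default_factory=dict)
    outcome_columns: dict = field(default_factory=dict)
    steiger: bool = True

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "reverse", "both"):
            raise ValueError(f"direction must be forward/reverse/both, got {self.direction!r}")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold outside (0, 1)")
        if not 0 < self.maf_limit <= 0.5:
            raise ValueError("maf_limit outside (0, 0.5]")
        if not 0 < self.r2_min <= 1:
            raise ValueError("r2_min outside (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "exclude_snps" in raw:
            raw["exclude_snps"] = tuple(raw["exclude_snps"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _diag_frame(diag: Diagnostics) -> pd.DataFrame:
    return pd.DataFrame([vars(diag)])


def _run_one_direction(
    exp_records,
    out_records,
    cfg: AnalysisConfig,
    outcome_type: str,
    exposure_n: float,
    outcome_n: float,
    ld_info,
    proxy_table,
):
    instruments = select_instruments(
        exp_records,
        p_threshold=cfg.p_threshold,
        ld_info=ld_info,
        distance_kb=cfg.clump_distance_kb,
        r2_threshold=cfg.clump_r2,
    )
    dataset = harmonise_datasets(
        instruments.records,
        out_records,
        maf_limit=cfg.maf_limit,
        proxy_table=proxy_table,
        r2_min=cfg.r2_min,
    )
    mr_cfg = MRConfig(
        outcome_type=outcome_type,
        random_effects=cfg.random_effects,
        i2_simex_trigger=cfg.i2_simex_trigger,
        n_boot=cfg.n_boot,
        seed=cfg.seed,
        steiger=cfg.steiger,
        exposure_n=exposure_n,
        outcome_n=outcome_n,
        exclude_snps=tuple(cfg.exclude_snps),
    )
    results, diag = run_mr(dataset, mr_cfg)
    return instruments, dataset, results, diag


def run_pipeline(cfg: AnalysisConfig, out_dir) -> dict:
    """Execute the configured analysis and write the report bundle.

    Writes, per direction, ``results_<direction>.tsv``,
    ``diagnostics_<direction>.tsv`` and ``drops_<direction>.tsv``, plus
    ``manifest.json`` recording the config, its hash, seeds and versions.
    A failing direction is recorded in the manifest; the other direction's
    results are preserved. Returns the manifest dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "smokemr": _package_version(),
        },
        "directions": {},
    }

    exp_records, exp_rejects = read_summary_stats(cfg.exposure_path, cfg.exposure_columns or None)
    out_records, out_rejects = read_summary_stats(cfg.outcome_path, cfg.outcome_columns or None)
    manifest["read_rejects"] = {"exposure": exp_rejects, "outcome": out_rejects}

    ld_info = pd.read_csv(cfg.ld_path, sep="\t") if cfg.ld_path else None
    proxy_table = pd.read_csv(cfg.proxy_path, sep="\t") if cfg.proxy_path else None

    directions = []
    if cfg.direction in ("forward", "both"):
        directions.append(("forward", exp_records, out_records, cfg.outcome_type,
                           cfg.exposure_n, cfg.outcome_n))
    if cfg.direction in ("reverse", "both"):
        directions.append(("reverse", out_records, exp_records, cfg.exposure_type,
                           cfg.outcome_n, cfg.exposure_n))

    for name, e_rec, o_rec, o_type, e_n, o_n in directions:
        entry: dict = {}
        try:
            instruments, dataset, results, diag = _run_one_direction(
                e_rec, o_rec, cfg, o_type, e_n, o_n, ld_info, proxy_table
            )
            results_path = out_dir / f"results_{name}.tsv"
            results.to_csv(results_path, sep="\t", index=False, float_format="%.6g")
            _diag_frame(diag).to_csv(out_dir / f"diagnostics_{name}.tsv", sep="\t", index=False)
            dataset.drop_log().to_csv(out_dir / f"drops_{name}.tsv", sep="\t", index=False)
            dataset.to_frame().to_csv(out_dir / f"harmonised_{name}.tsv", sep="\t", index=False)
            entry.update(
                status="ok",
                n_instruments=len(instruments),
                n_harmonised=len(dataset),
                n_dropped=len(dataset.dropped),
                results=str(results_path),
                provenance=instruments.provenance,
            )
            entry["table"] = _render_table(results, o_type)
        except Exception as exc:  # noqa: BLE001 — stage failures land in the manifest
            logger.error("direction %s failed: %s", name, exc)
            entry.update(status="failed", error=str(exc))
        manifest["directions"][name] = entry

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _render_table(results: pd.DataFrame, outcome_type: str) -> str:
    """Plain-text result table, ORs to 3 significant figures for binary
    outcomes (beta and 95% CI otherwise)."""
    lines = []
    if outcome_type == "binary" and "or" in results.columns:
        lines.append(f"{'method':<16}{'nsnp':>6}{'OR':>9}{'95% CI':>19}{'p':>11}")
        for _, r in results.iterrows():
            if np.isnan(r["beta"]):
                lines.append(f"{r['method']:<16}{r['n_snp']:>6}  {r['note']}")
                continue
            ci = f"({r['or_ci_low']:.3g}, {r['or_ci_high']:.3g})"
            lines.append(
                f"{r['method']:<16}{r['n_snp']:>6}{r['or']:>9.3g}{ci:>19}{r['pval']:>11.3g}"
            )
    else:
        lines.append(f"{'method':<16}{'nsnp':>6}{'beta':>10}{'95% CI':>21}{'p':>11}")
        for _, r in results.iterrows():
            if np.isnan(r["beta"]):
                lines.append(f"{r['method']:<16}{r['n_snp']:>6}  {r['note']}")
                continue
            ci = f"({r['ci_low']:.3g}, {r['ci_high']:.3g})"
            lines.append(
                f"{r['method']:<16}{r['n_snp']:>6}{r['beta']:>10.3g}{ci:>21}{r['pval']:>11.3g}"
            )
    return "\n".join(lines)


def _package_version() -> str:
    from . import __version__

    return __version__
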