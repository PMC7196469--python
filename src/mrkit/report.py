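"""End-to-end analysis orchestration and report serialization.

``run_analysis`` wires the full pipeline — read/harmonize/filter →
estimators → heterogeneity → leave-one-out → instrument strength — and
writes a machine-readable bundle (JSON + TSVs + plots + run log) to an
output directory. Every number in the report is the library-level return
serialized at full precision; nothing is recomputed at reporting time, so
identical config and seed produce byte-identical TSV/JSON outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .estimators import (
    DEFAULT_BOOT_SEED,
    DEFAULT_N_BOOT,
    MrEstimate,
    estimate_all,
    wald_ratios,
)
from .plots import forest_plot, leave_one_out_plot, scatter_plot
from .sensitivity import cochran_q, instrument_strength, leave_one_out
from .summary_io import (
    DEFAULT_PALINDROMIC_EAF_WINDOW,
    ConfigurationError,
    InstrumentSet,
    filter_instruments,
    harmonize,
    load_waist_chd_instruments,
    read_summary_table,
)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Settings for one pipeline run; exactly one input source must be set."""

    exposure_path: str | None = None
    outcome_path: str | None = None
    use_fixture: bool = False
    p_threshold: float = 5e-8
    ivw_model: str = "multiplicative_random"
    n_boot: int = DEFAULT_N_BOOT
    seed: int = DEFAULT_BOOT_SEED
    palindromic_eaf_window: float = DEFAULT_PALINDROMIC_EAF_WINDOW
    output_dir: str = "mr_results"
    plot_formats: tuple[str, ...] = ("png",)
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"

    def __post_init__(self) -> None:
        paths = self.exposure_path is not None and self.outcome_path is not None
        if paths == self.use_fixture:
            raise ConfigurationError(
                "provide exposure_path and outcome_path, or use_fixture, but not both"
            )
        bad = set(self.plot_formats) - {"png", "svg", "pdf"}
        if bad:
            raise ConfigurationError(f"unsupported plot formats: {sorted(bad)}")


@dataclass
class ReportBundle:
    """In-memory results of a pipeline run plus the paths written."""

    instruments: InstrumentSet
    estimates: list[MrEstimate]
    heterogeneity: object
    loo: object
    strength: object
    files: dict[str, Path] = field(default_factory=dict)


def _load_instruments(cfg: AnalysisConfig) -> InstrumentSet:
    if cfg.use_fixture:
        return load_waist_chd_instruments()
    exposure = read_summary_table(cfg.exposure_path)
    outcome = read_summary_table(cfg.outcome_path)
    return harmonize(
        exposure,
        outcome,
        palindromic_eaf_window=cfg.palindromic_eaf_window,
        exposure_name=cfg.exposure_name,
        outcome_name=cfg.outcome_name,
    )


def run_analysis(cfg: AnalysisConfig) -> ReportBundle:
    """Execute the full two-sample MR pipeline and write the report bundle."""
    instruments = filter_instruments(_load_instruments(cfg), cfg.p_threshold)
    estimates = estimate_all(
        instruments, ivw_model=cfg.ivw_model, n_boot=cfg.n_boot, seed=cfg.seed
    )
    het = cochran_q(instruments)
    loo = leave_one_out(instruments, model=cfg.ivw_model)
    strength = instrument_strength(instruments)
    ratios = wald_ratios(instruments)

    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    egger_est = next((e for e in estimates if e.method == "egger"), None)
    pleiotropy_flag = (
        "no directional pleiotropy detected (Egger intercept p >= 0.05)"
        if egger_est is not None and egger_est.intercept_p >= 0.05
        else "directional pleiotropy suspected (Egger intercept p < 0.05)"
        if egger_est is not None
        else "not assessed"
    )

    report = {
        "exposure": instruments.exposure_name,
        "outcome": instruments.outcome_name,
        "n_snp": len(instruments),
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
        "estimates": {e.method: e.to_dict() for e in estimates},
        "heterogeneity": {"q": het.q, "df": het.df, "pval": het.pval},
        "pleiotropy_assessment": pleiotropy_flag,
        "instrument_strength": {
            "min_f": strength.min_f,
            "mean_f": strength.mean_f,
            "r2_total": strength.r2_total,
        },
        "provenance": {k: str(v) for k, v in instruments.provenance.items()},
        "version": __version__,
    }
    files["results.json"] = outdir / "results.json"
    files["results.json"].write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

    import pandas as pd

    est_frame = pd.DataFrame([e.to_dict() for e in estimates])
    files["results.tsv"] = outdir / "results.tsv"
    est_frame.to_csv(files["results.tsv"], sep="\t", index=False)

    per_snp = instruments.to_frame()
    per_snp["theta"] = [r.theta for r in ratios]
    per_snp["se_theta"] = [r.se_theta for r in ratios]
    per_snp["pval_theta"] = [r.pval for r in ratios]
    per_snp["f_stat"] = [strength.per_snp_f[r.rsid] for r in ratios]
    per_snp["q_contribution"] = [het.contributions[r.rsid] for r in ratios]
    files["per_snp.tsv"] = outdir / "per_snp.tsv"
    per_snp.to_csv(files["per_snp.tsv"], sep="\t", index=False)

    het_frame = pd.DataFrame([{"q": het.q, "df": het.df, "pval": het.pval}])
    files["heterogeneity.tsv"] = outdir / "heterogeneity.tsv"
    het_frame.to_csv(files["heterogeneity.tsv"], sep="\t", index=False)

    files["loo.tsv"] = outdir / "loo.tsv"
    loo.to_frame().to_csv(files["loo.tsv"], sep="\t", index=False)

    for fmt in cfg.plot_formats:
        files[f"forest.{fmt}"] = outdir / f"forest.{fmt}"
        forest_plot(ratios, estimates, files[f"forest.{fmt}"])
        files[f"scatter.{fmt}"] = outdir / f"scatter.{fmt}"
        scatter_plot(instruments, estimates, files[f"scatter.{fmt}"])
        files[f"loo_plot.{fmt}"] = outdir / f"loo_plot.{fmt}"
        leave_one_out_plot(loo, files[f"loo_plot.{fmt}"])

    files["run.log"] = outdir / "run.log"
    files["run.log"].write_text(
        "\n".join(
            [
                f"mrkit {__version__} (python {platform.python_version()})",
                f"config: {json.dumps(report['config'], sort_keys=True)}",
                f"instruments: {len(instruments)}",
                f"pleiotropy: {pleiotropy_flag}",
            ]
        )
        + "\n"
    )
    return ReportBundle(
        instruments=instruments,
        estimates=estimates,
        heterogeneity=het,
        loo=loo,
        strength=strength,
        files=files,
    )
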