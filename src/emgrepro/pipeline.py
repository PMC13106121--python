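"""End-to-end orchestration: simulate -> preprocess -> analyze -> report.

A run is a pure function of its :class:`RunConfig` (seed included): two runs
with the same config produce byte-identical tables. Every stage writes
delimited text files under the output directory and the run manifest records
their SHA-256 checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import matplotlib
import pandas as pd

from . import __version__
from .cohort import CohortSpec, load_cohort, make_default_spec, spec_to_dict, write_cohort
from .errors import ParameterError, SchemaError
from .preprocessing import FilterSettings, preprocess_cohort
from .reproducibility import ReproducibilityAnalysis

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (display convention; 0.845 -> 0.85)."""
    scale = 10.0**decimals
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


@dataclass
class RunConfig:
    """Everything that defines one reproducible run.

    ``cohort`` is either a :class:`CohortSpec` (synthetic run) or a path to a
    manifest CSV of externally supplied trials — simulation is optional, the
    downstream stages are identical either way.
    """

    cohort: CohortSpec | str | Path = field(default_factory=make_default_spec)
    filters: FilterSettings = field(default_factory=FilterSettings)
    max_lag: int = 25
    method: str = "norm_coeff"
    aggregate: str = "subjects"
    out_dir: str | Path = "emgrepro_run"
    seed: int | None = None
    report_rounding: int = 2

    def resolved_cohort(self) -> CohortSpec | Path:
        if isinstance(self.cohort, CohortSpec):
            spec = self.cohort
            if self.seed is not None:
                spec = dataclasses.replace(spec, seed=self.seed)
            return spec
        path = Path(self.cohort)
        if not path.exists():
            raise ParameterError(f"manifest path {path} does not exist")
        return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format=_FLOAT_FMT, lineterminator="\n")


def run_all(config: RunConfig) -> dict:
    """Execute all stages in order; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    cohort = config.resolved_cohort()
    if isinstance(cohort, CohortSpec):
        logger.info("simulate: %d subjects x %d reps", cohort.n_subjects, cohort.n_reps)
        write_cohort(cohort, out)
        manifest_path = out / "manifest.csv"
        written += [manifest_path, out / "cohort_spec.yaml"]
        written += sorted((out / "trials").glob("*.csv"))
        seed_used = cohort.seed
    else:
        manifest_path = cohort
        seed_used = config.seed

    trials = load_cohort(manifest_path)
    logger.info("preprocess: %d trials", len(trials))
    profiles, normalization = preprocess_cohort(trials, config.filters)
    _write_csv(profiles, out / "profiles.csv")
    _write_csv(normalization, out / "normalization.csv")
    written += [out / "profiles.csv", out / "normalization.csv"]

    n_subjects = profiles["subject_id"].nunique()
    if n_subjects < 2:
        raise SchemaError(
            f"inter-subject analysis needs at least 2 subjects, got {n_subjects}"
        )
    logger.info("analyze: %d profiles", len(profiles) // 100)
    analysis = ReproducibilityAnalysis(
        max_lag=config.max_lag, method=config.method, aggregate=config.aggregate
    ).fit(profiles)
    table = analysis.table_
    _write_csv(table[["intra_mean", "intra_sd"]], out / "intra_table.csv", index=True)
    _write_csv(table[["inter_mean", "inter_sd"]], out / "inter_table.csv", index=True)
    _write_csv(table, out / "composite_table.csv", index=True)
    _write_csv(analysis.group_profiles_, out / "group_profiles.csv")
    written += [
        out / "intra_table.csv",
        out / "inter_table.csv",
        out / "composite_table.csv",
        out / "group_profiles.csv",
    ]
    for muscle, res in analysis.inter_.items():
        p = out / f"pairwise_{muscle}.csv"
        _write_csv(res.pairwise, p, index=True)
        written.append(p)

    report(out, rounding=config.report_rounding)
    written += [out / "report.txt"]
    written += sorted((out / "figures").glob("*.png"))

    run_manifest = {
        "version": __version__,
        "seed": seed_used,
        "config": _config_snapshot(config),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "checksums": {str(p.relative_to(out)): _sha256(p) for p in written},
    }
    (out / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2, sort_keys=True))
    return run_manifest


def _config_snapshot(config: RunConfig) -> dict:
    snap = {
        "max_lag": config.max_lag,
        "method": config.method,
        "aggregate": config.aggregate,
        "report_rounding": config.report_rounding,
        "filters": dataclasses.asdict(config.filters),
    }
    if isinstance(config.cohort, CohortSpec):
        snap["cohort"] = spec_to_dict(config.cohort)
    else:
        snap["cohort"] = str(config.cohort)
    if config.seed is not None:
        snap["seed"] = config.seed
    return snap


def _fmt(x: float, nd: int) -> str:
    return f"{round_half_away(x, nd):.{nd}f}"


def report(out_dir: str | Path, rounding: int = 2, figures: bool = True) -> str:
    """Render the stored analysis tables as a text report plus mean±SD figures.

    Numbers are the stored full-precision values rounded half-away-from-zero;
    nothing is recomputed, so regenerating the report is byte-stable.
    """
    out = Path(out_dir)
    comp_path = out / "composite_table.csv"
    group_path = out / "group_profiles.csv"
    if not comp_path.exists() or not group_path.exists():
        raise SchemaError(f"analysis outputs missing under {out}")
    table = pd.read_csv(comp_path).set_index("muscle")
    group = pd.read_csv(group_path)

    lines = ["Muscle activation repeatability / reproducibility summary", ""]
    lines.append("Intra-subject repeatability (mean ± SD across subjects):")
    for m, row in table.iterrows():
        lines.append(f"  {m:>4s}  {_fmt(row.intra_mean, rounding)} ± {_fmt(row.intra_sd, rounding)}")
    lines.append("")
    lines.append("Inter-subject reproducibility (mean ± SD across subject pairs):")
    for m, row in table.iterrows():
        lines.append(f"  {m:>4s}  {_fmt(row.inter_mean, rounding)} ± {_fmt(row.inter_sd, rounding)}")
    lines.append("")
    lines.append("Composite reproducibility ranking:")
    for m, row in table.sort_values("rank").iterrows():
        bar = "#" * int(round(row.composite * 40))
        lines.append(f"  {int(row['rank']):2d}. {m:>4s}  {_fmt(row.composite, rounding)}  {bar}")
    text = "\n".join(lines) + "\n"
    (out / "report.txt").write_text(text)

    if figures:
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig_dir = out / "figures"
        fig_dir.mkdir(exist_ok=True)
        for muscle, grp in group.groupby("muscle", sort=False):
            fig, ax = plt.subplots(figsize=(4, 3))
            x = grp["point_index"].to_numpy()
            mean, sd = grp["mean"].to_numpy(), grp["sd"].to_numpy()
            ax.plot(x, mean, color="tab:blue")
            ax.fill_between(x, mean - sd, mean + sd, alpha=0.3, color="tab:blue")
            ax.set_xlabel("% movement cycle")
            ax.set_ylabel("normalized activation")
            ax.set_title(muscle)
            fig.tight_layout()
            fig.savefig(fig_dir / f"{muscle}.png", dpi=110)
            plt.close(fig)

        fig, ax = plt.subplots(figsize=(5, 3))
        ranked = table.sort_values("rank")
        ax.bar(ranked.index, ranked["composite"], color="tab:gray")
        ax.set_ylabel("composite score")
        ax.set_ylim(0, 1)
        fig.tight_layout()
        fig.savefig(fig_dir / "ranking.png", dpi=110)
        plt.close(fig)
    return text
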