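"""End-to-end orchestration: read, select, harmonize, pool, sensitivity.

A single :class:`RunConfig` (usually loaded from YAML) names one exposure
file and any number of outcome files; :func:`run` produces one pooled
estimate per outcome, optional re-estimates under named exclusion sets and
leave-one-out, and an instrument-strength block when allele frequencies and
the exposure phenotype SD are available. Outcomes fail independently: an
error in one outcome is recorded and the rest still complete.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .exceptions import ConfigurationError, TsmrError
from .mr_core import (
    InstrumentStrength,
    PooledEstimate,
    f_statistic,
    instrument_r2,
    to_odds_ratio,
)
from .sensitivity import SensitivityReport, exclude_and_rerun, leave_one_out
from .summary_io import (
    HarmonizedPair,
    InstrumentSet,
    harmonize,
    read_association_table,
    retained,
    select_instruments,
    write_results,
)
from .mr_core import pool_with_model_selection

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OutcomeSpec:
    path: str
    column_map: str | Mapping[str, str] = "fixture"
    scale: str = "continuous"  # continuous | log_odds

    def __post_init__(self) -> None:
        if self.scale not in ("continuous", "log_odds"):
            raise ConfigurationError(f"outcome scale must be continuous or log_odds, got {self.scale!r}")


@dataclass(frozen=True)
class RunConfig:
    """Everything one analysis run needs, resolvable from a YAML file."""

    exposure_path: str
    outcomes: Mapping[str, OutcomeSpec]
    exposure_column_map: str | Mapping[str, str] = "fixture"
    exposure_name: str = "exposure"
    unit_label: str = "mg/L"
    exposure_sd: float | None = None
    n_exposure: float | None = None
    p_threshold: float = 5.0e-8
    het_alpha: float = 0.05
    palindromic_policy: str = "infer_by_eaf"
    eaf_ambiguity_band: float = 0.08
    exclusions: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    leave_one_out: bool = False
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.outcomes:
            raise ConfigurationError("config must name at least one outcome")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh)
        except OSError as exc:
            raise ConfigurationError(f"cannot read config {path}: {exc}") from exc
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"malformed YAML in {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config {path} must be a mapping")
        try:
            exposure = raw["exposure"]
            outcomes_raw = raw["outcomes"]
        except KeyError as exc:
            raise ConfigurationError(f"config missing required section {exc}") from None
        outcomes = {
            name: OutcomeSpec(
                path=spec["path"],
                column_map=spec.get("column_map", "fixture"),
                scale=spec.get("scale", "continuous"),
            )
            for name, spec in outcomes_raw.items()
        }
        exclusions = {
            label: tuple(rsids) for label, rsids in (raw.get("exclusions") or {}).items()
        }
        return cls(
            exposure_path=exposure["path"],
            exposure_column_map=exposure.get("column_map", "fixture"),
            exposure_name=exposure.get("name", "exposure"),
            unit_label=exposure.get("unit", "mg/L"),
            exposure_sd=exposure.get("sd"),
            n_exposure=exposure.get("n"),
            outcomes=outcomes,
            p_threshold=float(raw.get("p_threshold", 5.0e-8)),
            het_alpha=float(raw.get("het_alpha", 0.05)),
            palindromic_policy=raw.get("palindromic_policy", "infer_by_eaf"),
            eaf_ambiguity_band=float(raw.get("eaf_ambiguity_band", 0.08)),
            exclusions=exclusions,
            leave_one_out=bool(raw.get("leave_one_out", False)),
            output_dir=raw.get("output_dir"),
        )


@dataclass
class RunReport:
    instruments: InstrumentSet
    main: dict[str, PooledEstimate]
    sensitivity: dict[str, dict[str, PooledEstimate]]
    loo: dict[str, SensitivityReport]
    strength: InstrumentStrength | None
    harmonization: dict[str, list[dict]]
    errors: dict[str, str]


def _instrument_strength(config: RunConfig, instruments: InstrumentSet) -> InstrumentStrength | None:
    if config.exposure_sd is None:
        return None
    if any(snp.eaf is None for snp in instruments):
        return None
    n = config.n_exposure
    if n is None:
        ns = [snp.n for snp in instruments if snp.n is not None]
        n = min(ns) if ns else None
    if n is None:
        return None
    r2 = instrument_r2(instruments, phenotype_variance=config.exposure_sd**2)
    return f_statistic(r2, n=n, k=len(instruments))


def run(config: RunConfig) -> RunReport:
    """Execute the full analysis described by ``config``.

    Deterministic given its input files; writes result tables under
    ``config.output_dir`` when set.
    """
    exposure_table = read_association_table(
        config.exposure_path, config.exposure_column_map, trait_units="continuous"
    )
    instruments = select_instruments(
        exposure_table,
        p_threshold=config.p_threshold,
        exposure_name=config.exposure_name,
        unit_label=config.unit_label,
    )
    strength = _instrument_strength(config, instruments)

    main: dict[str, PooledEstimate] = {}
    sens: dict[str, dict[str, PooledEstimate]] = {label: {} for label in config.exclusions}
    loo: dict[str, SensitivityReport] = {}
    harmonization: dict[str, list[dict]] = {}
    errors: dict[str, str] = {}
    pairs_by_outcome: dict[str, list[HarmonizedPair]] = {}

    for name, spec in sorted(config.outcomes.items()):
        try:
            outcome_table = read_association_table(spec.path, spec.column_map, spec.scale)
            pairs = harmonize(
                instruments,
                outcome_table,
                palindromic_policy=config.palindromic_policy,
                eaf_ambiguity_band=config.eaf_ambiguity_band,
            )
            harmonization[name] = [
                {"rsid": p.rsid, "resolution": p.resolution, "flip_applied": p.flip_applied,
                 "palindromic": p.palindromic}
                for p in pairs
            ]
            main[name] = pool_with_model_selection(
                pairs, het_alpha=config.het_alpha, outcome_name=name, scale=spec.scale
            )
            pairs_by_outcome[name] = pairs
        except TsmrError as exc:
            logger.error("outcome %s failed at estimation: %s", name, exc)
            errors[name] = f"{type(exc).__name__}: {exc}"
            continue
        for label, rsids in config.exclusions.items():
            try:
                sens[label][name] = exclude_and_rerun(
                    pairs, rsids, het_alpha=config.het_alpha, outcome_name=name, scale=spec.scale
                )
            except TsmrError as exc:
                errors[f"{name}/{label}"] = f"{type(exc).__name__}: {exc}"
        if config.leave_one_out:
            try:
                loo[name] = leave_one_out(
                    pairs, het_alpha=config.het_alpha, outcome_name=name, scale=spec.scale
                )
            except TsmrError as exc:
                errors[f"{name}/leave_one_out"] = f"{type(exc).__name__}: {exc}"

    report = RunReport(
        instruments=instruments,
        main=main,
        sensitivity=sens,
        loo=loo,
        strength=strength,
        harmonization=harmonization,
        errors=errors,
    )
    if config.output_dir:
        _write_report(report, Path(config.output_dir))
    return report


def _write_report(report: RunReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_results(
        [report.main[name] for name in sorted(report.main)], outdir / "main_results.tsv"
    )
    for label in sorted(report.sensitivity):
        table = report.sensitivity[label]
        if table:
            write_results(
                [table[name] for name in sorted(table)], outdir / f"sensitivity_{label}.tsv"
            )
    for name in sorted(report.loo):
        rep = report.loo[name]
        rows = [rep.baseline] + [rep.variants[k] for k in sorted(rep.variants)]
        write_results(rows, outdir / f"leave_one_out_{name}.tsv")
    if report.strength is not None:
        with open(outdir / "instrument_strength.tsv", "w") as fh:
            s = report.strength
            fh.write("r2\tn\tk\tf\n")
            fh.write(f"{s.r2:.10g}\t{s.n:.10g}\t{s.k}\t{s.f:.10g}\n")
    with open(outdir / "harmonization.json", "w") as fh:
        json.dump(report.harmonization, fh, indent=2, sort_keys=True)
    with open(outdir / "report.txt", "w") as fh:
        fh.write(render_report(report))


# ---------------------------------------------------------------------------
# Presentation

def _fmt_p(p: float | None) -> str:
    if p is None:
        return "-"
    return "<0.001" if p < 0.001 else f"{p:.2g}"


def _fmt_estimate(est: PooledEstimate) -> tuple[str, str, str]:
    """(point, CI, label) on the paper's display scale: OR for log-odds."""
    if est.scale == "log_odds":
        orr = to_odds_ratio(est)
        return (f"{orr.or_point:.3f}", f"{orr.or_ci_low:.3f} to {orr.or_ci_high:.3f}", "OR")
    return (f"{est.beta:.3f}", f"{est.ci_low:.3f} to {est.ci_high:.3f}", "beta")


def render_report(report: RunReport) -> str:
    """Human-readable tables: main results, exclusion sets, leave-one-out.

    Rounding happens only here; the machine-readable tables keep full
    precision.
    """
    lines: list[str] = []
    header = ["outcome", "k", "type", "estimate", "95% CI", "p", "model", "I2", "het p"]
    lines.append("== Main IVW results (per 1 {}) ==".format(report.instruments.unit_label or "unit"))
    lines.append("\t".join(header))
    for name in sorted(report.main):
        est = report.main[name]
        point, ci, label = _fmt_estimate(est)
        het = est.het
        i2 = "-" if het is None else f"{100 * het.i2:.0f}%"
        hp = "-" if het is None else _fmt_p(het.p_het)
        lines.append(
            "\t".join(
                [name, str(est.k), label, point, ci, _fmt_p(est.pvalue), est.model, i2, hp]
            )
        )
    if report.strength is not None:
        s = report.strength
        lines.append("")
        lines.append(
            f"Instrument strength: R2 = {100 * s.r2:.2f}% , F = {s.f:.1f} "
            f"(n = {s.n:.0f}, k = {s.k})"
        )
    for label in sorted(report.sensitivity):
        table = report.sensitivity[label]
        if not table:
            continue
        lines.append("")
        lines.append(f"== Sensitivity: exclusion set '{label}' ==")
        lines.append("\t".join(header))
        for name in sorted(table):
            est = table[name]
            point, ci, lab = _fmt_estimate(est)
            het = est.het
            i2 = "-" if het is None else f"{100 * het.i2:.0f}%"
            hp = "-" if het is None else _fmt_p(het.p_het)
            lines.append(
                "\t".join(
                    [name, str(est.k), lab, point, ci, _fmt_p(est.pvalue), est.model, i2, hp]
                )
            )
    for name in sorted(report.loo):
        rep = report.loo[name]
        lines.append("")
        lines.append(
            f"== Leave-one-out: {name} (max |shift| = {rep.max_abs_shift:.4f}) =="
        )
        for key in sorted(rep.variants):
            est = rep.variants[key]
            point, ci, _ = _fmt_estimate(est)
            lines.append(f"{key}\t{point}\t{ci}")
    if report.errors:
        lines.append("")
        lines.append("== Errors ==")
        for key in sorted(report.errors):
            lines.append(f"{key}\t{report.errors[key]}")
    return "\n".join(lines) + "\n"
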