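"""Synthetic two-sample GWAS summary statistics.

Generates exposure and outcome association tables with the statistical
structure two-sample MR assumes: a handful of independent biallelic
instruments (no LD — the emulated study's three variants sit on different
chromosomes), per-allele exposure effects measured with first-stage sampling
noise, and outcome effects generated under a chosen true causal effect
``theta`` with optional horizontal pleiotropy on named variants.

Sampling model, for SNP k with effect-allele frequency p_k:

* exposure:  beta^E_k ~ Normal(E_k, sigma_Ek²),
  sigma_Ek = exposure_sd / sqrt(2 p_k (1-p_k) n_exposure)
* outcome:   beta^D_k ~ Normal(theta·E_k + alpha_k, sigma_Dk²),
  sigma_Dk = 1 / sqrt(2 p_k (1-p_k) n_eff)

where alpha_k is the direct (pleiotropic) outcome effect and n_eff is the
outcome sample size for a SD-standardized continuous trait, or
n_cases·n_controls/(n_cases+n_controls) for a binary trait analysed on the
log-odds scale. Reported standard errors are the analytic sigmas; p-values
follow from the two-sided normal test. A single seeded generator is shared
per run: all exposure betas are drawn first (in SNP order), then all
outcome betas.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError
from .mr_core import PooledEstimate, pool_with_model_selection
from .summary_io import COLUMN_PRESETS, SnpAssociation, harmonize

#: The emulated 3-SNP alpha-tocopherol instrument:
#: (rsid, chromosome, effect allele, other allele, EAF, beta in mg/L per allele)
DEFAULT_SNPS: tuple[tuple[str, str, str, str, float, float], ...] = (
    ("rs11057830", "12", "A", "G", 0.15, 0.03),
    ("rs2108622", "19", "T", "C", 0.21, 0.03),
    ("rs964184", "11", "G", "C", 0.15, 0.04),
)

#: Phenotype SD of the exposure (mg/L). Chosen so the implied first-stage
#: standard errors (~0.005) reproduce the published instrument p-values at
#: n = 7781; see docs/methods.md.
DEFAULT_EXPOSURE_SD = 0.24


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of a synthetic two-sample MR study."""

    seed: int = 0
    true_effect: float = 0.0
    snps: Sequence[tuple[str, str, str, str, float, float]] = DEFAULT_SNPS
    n_exposure: int = 7781
    outcome_kind: str = "binary"  # binary | continuous
    n_cases: int = 60801
    n_controls: int = 123504
    n_outcome: int | None = None
    pleiotropy: Mapping[str, float] = field(default_factory=dict)
    exposure_sd: float = DEFAULT_EXPOSURE_SD

    def __post_init__(self) -> None:
        if self.outcome_kind not in ("binary", "continuous"):
            raise ConfigurationError(
                f"outcome_kind must be binary or continuous, got {self.outcome_kind!r}"
            )
        if self.n_exposure <= 0:
            raise ConfigurationError(f"n_exposure must be positive, got {self.n_exposure}")
        if self.exposure_sd <= 0:
            raise ConfigurationError(f"exposure_sd must be positive, got {self.exposure_sd}")
        if self.outcome_kind == "binary":
            if self.n_cases <= 0 or self.n_controls <= 0:
                raise ConfigurationError("n_cases and n_controls must be positive")
        elif not self.n_outcome or self.n_outcome <= 0:
            raise ConfigurationError("continuous outcomes need a positive n_outcome")
        for snp in self.snps:
            rsid, _, ea, oa, eaf, _beta = snp
            if not 0.0 < eaf < 1.0:
                raise ConfigurationError(f"{rsid}: eaf must be in (0, 1), got {eaf}")
            if ea == oa:
                raise ConfigurationError(f"{rsid}: identical alleles")
        known = {s[0] for s in self.snps}
        unknown = set(self.pleiotropy) - known
        if unknown:
            raise ConfigurationError(f"pleiotropy names unknown rsids: {sorted(unknown)}")

    @property
    def n_eff_outcome(self) -> float:
        """Effective outcome sample size governing log-odds/SD sampling variance."""
        if self.outcome_kind == "binary":
            return self.n_cases * self.n_controls / (self.n_cases + self.n_controls)
        return float(self.n_outcome)

    @property
    def outcome_scale(self) -> str:
        return "log_odds" if self.outcome_kind == "binary" else "continuous"


def _two_sided_p(beta: float, se: float) -> float:
    p = float(2.0 * stats.norm.sf(abs(beta) / se))
    return max(p, 5e-324)  # keep inside (0, 1]


def simulate_study(
    config: SimulationConfig,
) -> tuple[list[SnpAssociation], list[SnpAssociation]]:
    """Draw one synthetic exposure table and one outcome table.

    Identical seeds give identical tables. Exposure rows carry the drawn
    first-stage betas; outcome rows carry betas drawn around
    ``true_effect * E_k + pleiotropy[rsid]``.
    """
    rng = np.random.default_rng(config.seed)
    eafs = np.array([s[4] for s in config.snps])
    e_true = np.array([s[5] for s in config.snps])
    het_var = 2.0 * eafs * (1.0 - eafs)

    sigma_e = config.exposure_sd / np.sqrt(het_var * config.n_exposure)
    sigma_d = 1.0 / np.sqrt(het_var * config.n_eff_outcome)
    alphas = np.array([config.pleiotropy.get(s[0], 0.0) for s in config.snps])
    d_true = config.true_effect * e_true + alphas

    beta_e = rng.normal(e_true, sigma_e)
    beta_d = rng.normal(d_true, sigma_d)

    n_out = (
        config.n_cases + config.n_controls
        if config.outcome_kind == "binary"
        else config.n_outcome
    )
    exposure, outcome = [], []
    for i, (rsid, chrom, ea, oa, eaf, _) in enumerate(config.snps):
        exposure.append(
            SnpAssociation(
                rsid=rsid,
                chromosome=chrom,
                effect_allele=ea,
                other_allele=oa,
                beta=float(beta_e[i]),
                se=float(sigma_e[i]),
                eaf=eaf,
                pvalue=_two_sided_p(beta_e[i], sigma_e[i]),
                n=config.n_exposure,
            )
        )
        outcome.append(
            SnpAssociation(
                rsid=rsid,
                chromosome=chrom,
                effect_allele=ea,
                other_allele=oa,
                beta=float(beta_d[i]),
                se=float(sigma_d[i]),
                eaf=eaf,
                pvalue=_two_sided_p(beta_d[i], sigma_d[i]),
                n=n_out,
            )
        )
    return exposure, outcome


def simulate_pooled(
    config: SimulationConfig,
    het_alpha: float = 0.05,
    outcome_name: str = "synthetic outcome",
) -> PooledEstimate:
    """Simulate one study and run it through harmonization and pooling.

    Convenience for Monte-Carlo studies of the estimator; instrument
    selection is bypassed (the SNPs in the config are the instruments).
    """
    exposure, outcome = simulate_study(config)
    pairs = harmonize(exposure, outcome)
    return pool_with_model_selection(
        pairs, het_alpha=het_alpha, outcome_name=outcome_name, scale=config.outcome_scale
    )


def replicate_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-replicate seeds derived from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    return [int(s) for s in state]


_FIXTURE_COLS = COLUMN_PRESETS["fixture"]


def _write_table(records: Iterable[SnpAssociation], path: Path) -> None:
    fields = list(_FIXTURE_COLS)  # canonical == header for the fixture preset
    with open(path, "w") as fh:
        fh.write("\t".join(fields) + "\n")
        for rec in records:
            row = []
            for f in fields:
                v = getattr(rec, f)
                # .17g round-trips IEEE doubles exactly, so the file-based
                # pipeline matches the in-memory pipeline bit for bit
                row.append("NA" if v is None else (format(v, ".17g") if isinstance(v, float) else str(v)))
            fh.write("\t".join(row) + "\n")


def write_fixture(config: SimulationConfig, directory: str | Path) -> dict[str, Path]:
    """Write one simulated study as exposure/outcome tables plus a truth file.

    The tables parse with ``read_association_table(..., column_map="fixture")``
    and round-trip the in-memory values; ``truth.json`` records the causal
    effect and pleiotropy used, for test harnesses.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    exposure, outcome = simulate_study(config)
    paths = {
        "exposure": directory / "exposure.tsv",
        "outcome": directory / "outcome.tsv",
        "truth": directory / "truth.json",
    }
    _write_table(exposure, paths["exposure"])
    _write_table(outcome, paths["outcome"])
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "seed": config.seed,
                "true_effect": config.true_effect,
                "pleiotropy": dict(config.pleiotropy),
                "outcome_kind": config.outcome_kind,
                "outcome_scale": config.outcome_scale,
                "n_exposure": config.n_exposure,
                "n_eff_outcome": config.n_eff_outcome,
                "exposure_sd": config.exposure_sd,
            },
            fh,
            indent=2,
        )
    return paths
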