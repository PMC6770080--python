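"""Reading, validating and harmonizing GWAS summary-statistic tables.

Two-sample MR consumes two tables of per-variant association summaries: one
for the exposure (here, serum alpha-tocopherol in mg/L per effect allele) and
one per outcome (log-odds for case/control traits, SD units for continuous
traits). Consortia publish these as whitespace- or tab-delimited text with
idiosyncratic headers, so parsing is driven by an explicit column map.

Harmonization aligns each exposure/outcome pair to a common effect allele.
Non-palindromic variants are aligned by allele letters (with strand
complementing when the two studies reported opposite strands). Palindromic
variants (A/T or G/C) are letter-ambiguous across strands; they are either
dropped or aligned by comparing effect-allele frequencies to 0.5 on both
sides, with an ambiguity band around 0.5 inside which no call is made.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import (
    ConfigurationError,
    EmptyInstrumentError,
    InputError,
)

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Canonical field names understood by :func:`read_association_table`.
CANONICAL_FIELDS = (
    "rsid",
    "chromosome",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "eaf",
    "pvalue",
    "n",
)
_REQUIRED_FIELDS = ("rsid", "effect_allele", "other_allele", "beta", "se")

#: Built-in column-map presets. "instrument_table" matches the layout of the
#: published 3-SNP vitamin E instrument table; "consortium" matches the
#: common consortium download layout; "fixture" matches tables written by
#: :func:`tsmr.synthetic_data.write_fixture`.
COLUMN_PRESETS: dict[str, dict[str, str]] = {
    "instrument_table": {
        "rsid": "SNP",
        "chromosome": "Chr",
        "effect_allele": "EA",
        "other_allele": "OA",
        "beta": "Beta",
        "se": "SE",
        "pvalue": "P",
        "eaf": "EAF",
    },
    "consortium": {
        "rsid": "markername",
        "effect_allele": "effect_allele",
        "other_allele": "noneffect_allele",
        "beta": "beta",
        "se": "se_dgc",
        "pvalue": "p_dgc",
        "eaf": "effect_allele_freq",
    },
    "fixture": {
        "rsid": "rsid",
        "chromosome": "chromosome",
        "effect_allele": "effect_allele",
        "other_allele": "other_allele",
        "beta": "beta",
        "se": "se",
        "eaf": "eaf",
        "pvalue": "pvalue",
        "n": "n",
    },
}


def resolve_column_map(column_map: str | Mapping[str, str]) -> dict[str, str]:
    """Return a concrete column map from a preset name or an explicit mapping."""
    if isinstance(column_map, str):
        try:
            return dict(COLUMN_PRESETS[column_map])
        except KeyError:
            raise ConfigurationError(
                f"unknown column-map preset {column_map!r}; "
                f"available: {sorted(COLUMN_PRESETS)}"
            ) from None
    return dict(column_map)


@dataclass(frozen=True)
class SnpAssociation:
    """One variant's summary association with a single trait.

    ``beta`` is the per-effect-allele change in the trait: mg/L for the
    exposure, log-odds or SD units for outcomes. ``eaf`` is the frequency of
    the effect allele (the allele ``beta`` refers to).
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    chromosome: str = ""
    eaf: float | None = None
    pvalue: float | None = None
    n: float | None = None

    def __post_init__(self) -> None:
        for name in ("effect_allele", "other_allele"):
            allele = getattr(self, name)
            if allele not in VALID_ALLELES:
                raise ValueError(f"{self.rsid}: {name} {allele!r} is not one of A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: effect and other allele are identical")
        if not (math.isfinite(self.beta) and math.isfinite(self.se)):
            raise ValueError(f"{self.rsid}: beta/se must be finite")
        if self.se <= 0:
            raise ValueError(f"{self.rsid}: se must be > 0, got {self.se}")
        if self.eaf is not None and not 0.0 <= self.eaf <= 1.0:
            raise ValueError(f"{self.rsid}: eaf {self.eaf} outside [0, 1]")
        if self.pvalue is not None and not 0.0 < self.pvalue <= 1.0:
            raise ValueError(f"{self.rsid}: pvalue {self.pvalue} outside (0, 1]")

    @property
    def palindromic(self) -> bool:
        """True for A/T or G/C variants (strand-ambiguous allele pairs)."""
        return _COMPLEMENT[self.effect_allele] == self.other_allele

    def flipped(self) -> "SnpAssociation":
        """The same association expressed for the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )

    def complemented(self) -> "SnpAssociation":
        """The same association expressed on the opposite strand."""
        return replace(
            self,
            effect_allele=_COMPLEMENT[self.effect_allele],
            other_allele=_COMPLEMENT[self.other_allele],
        )


@dataclass(frozen=True)
class AssociationTable(Sequence):
    """Parsed association records plus read provenance."""

    records: tuple[SnpAssociation, ...]
    path: str
    n_read: int
    n_kept: int
    trait_units: str = "continuous"

    @property
    def n_skipped(self) -> int:
        return self.n_read - self.n_kept

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, idx):
        return self.records[idx]


@dataclass(frozen=True)
class InstrumentSet:
    """Exposure instruments surviving the significance threshold, rsid-sorted."""

    exposure_name: str
    unit_label: str
    instruments: tuple[SnpAssociation, ...]
    p_threshold: float

    def __post_init__(self) -> None:
        rsids = [snp.rsid for snp in self.instruments]
        if len(set(rsids)) != len(rsids):
            raise ValueError("duplicate rsids in instrument set")
        if list(rsids) != sorted(rsids):
            object.__setattr__(
                self,
                "instruments",
                tuple(sorted(self.instruments, key=lambda s: s.rsid)),
            )

    def __iter__(self):
        return iter(self.instruments)

    def __len__(self) -> int:
        return len(self.instruments)


@dataclass(frozen=True)
class HarmonizedPair:
    """An exposure/outcome association pair aligned to the same effect allele.

    ``resolution`` records how alignment was achieved: ``direct`` (alleles
    already matched, possibly after strand complementing), ``flipped``
    (outcome re-expressed for the other allele), ``eaf_inferred``
    (palindromic variant aligned by allele frequency), or ``dropped``.
    """

    rsid: str
    exposure: SnpAssociation
    outcome: SnpAssociation | None
    flip_applied: bool
    palindromic: bool
    resolution: str  # direct | flipped | eaf_inferred | dropped

    def __post_init__(self) -> None:
        if self.resolution != "dropped":
            assert self.outcome is not None
            if (
                self.exposure.effect_allele != self.outcome.effect_allele
                or self.exposure.other_allele != self.outcome.other_allele
            ):
                raise ValueError(f"{self.rsid}: pair not allele-aligned")


def retained(pairs: Iterable[HarmonizedPair]) -> list[HarmonizedPair]:
    """Pairs that survived harmonization (resolution != dropped)."""
    return [p for p in pairs if p.resolution != "dropped"]


def _parse_row(row: Mapping[str, object]) -> SnpAssociation:
    def get(field_name, cast=float, required=False):
        if field_name not in row:
            return None
        value = row[field_name]
        if value is None or (isinstance(value, float) and math.isnan(value)):
            if required:
                raise ValueError(f"missing {field_name}")
            return None
        return cast(value)

    rsid = str(row["rsid"]).strip()
    if not rsid or rsid.lower() == "nan":
        raise ValueError("missing rsid")
    n = get("n")
    return SnpAssociation(
        rsid=rsid,
        chromosome=str(row.get("chromosome", "") or ""),
        effect_allele=str(row["effect_allele"]).strip().upper(),
        other_allele=str(row["other_allele"]).strip().upper(),
        beta=get("beta", required=True),
        se=get("se", required=True),
        eaf=get("eaf"),
        pvalue=get("pvalue"),
        n=n,
    )


def read_association_table(
    path: str | Path,
    column_map: str | Mapping[str, str],
    trait_units: str = "continuous",
) -> AssociationTable:
    """Read a whitespace/tab-delimited summary-statistics file.

    Parameters
    ----------
    path
        Text file with a header row.
    column_map
        Mapping from canonical field names (``rsid``, ``effect_allele``,
        ``other_allele``, ``beta``, ``se``, optionally ``chromosome``,
        ``eaf``, ``pvalue``, ``n``) to the file's column headers, or the
        name of a built-in preset.
    trait_units
        ``continuous`` or ``log_odds``; recorded as provenance.

    Rows failing validation (non-positive SE, bad alleles, unparseable
    numbers) are skipped and counted, never fatal.
    """
    cmap = resolve_column_map(column_map)
    missing_required = [f for f in _REQUIRED_FIELDS if f not in cmap]
    if missing_required:
        raise ConfigurationError(
            f"column map must cover {missing_required} (got {sorted(cmap)})"
        )
    if trait_units not in ("continuous", "log_odds"):
        raise ConfigurationError(f"trait_units must be continuous or log_odds, got {trait_units!r}")

    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep=r"\s+", dtype=str)
    except pd.errors.EmptyDataError:
        raise InputError(f"empty input file: {path}") from None
    if df.empty and df.columns.empty:
        raise InputError(f"empty input file: {path}")

    for canonical, header in cmap.items():
        if header not in df.columns:
            raise ConfigurationError(
                f"mapped column {header!r} (for field {canonical!r}) not found in {path}; "
                f"file has columns {list(df.columns)}"
            )

    renamed = df.rename(columns={v: k for k, v in cmap.items()})
    records: list[SnpAssociation] = []
    n_read = len(renamed)
    for _, row in renamed.iterrows():
        try:
            records.append(_parse_row(row))
        except (ValueError, TypeError) as exc:
            logger.warning("skipping row in %s: %s", path, exc)
    table = AssociationTable(
        records=tuple(records),
        path=str(path),
        n_read=n_read,
        n_kept=len(records),
        trait_units=trait_units,
    )
    logger.info(
        "read %s: %d rows, %d kept, %d skipped", path, table.n_read, table.n_kept, table.n_skipped
    )
    return table


def select_instruments(
    associations: Iterable[SnpAssociation],
    p_threshold: float = 5.0e-8,
    exposure_name: str = "exposure",
    unit_label: str = "",
) -> InstrumentSet:
    """Retain associations with p strictly below the significance threshold.

    The genome-wide default is 5e-8. Records without a p-value cannot pass.
    Raises :class:`EmptyInstrumentError` if nothing survives.
    """
    if not 0.0 < p_threshold < 1.0:
        raise ConfigurationError(f"p_threshold must be in (0, 1), got {p_threshold}")
    kept = [a for a in associations if a.pvalue is not None and a.pvalue < p_threshold]
    if not kept:
        raise EmptyInstrumentError(
            f"no association passes p < {p_threshold:g}; MR cannot proceed"
        )
    kept.sort(key=lambda a: a.rsid)
    return InstrumentSet(
        exposure_name=exposure_name,
        unit_label=unit_label,
        instruments=tuple(kept),
        p_threshold=p_threshold,
    )


def _harmonize_one(
    exp: SnpAssociation,
    out: SnpAssociation,
    palindromic_policy: str,
    eaf_ambiguity_band: float,
) -> HarmonizedPair:
    e_alleles = (exp.effect_allele, exp.other_allele)
    pal = exp.palindromic

    def dropped() -> HarmonizedPair:
        return HarmonizedPair(exp.rsid, exp, None, False, pal, "dropped")

    if pal:
        # Letters cannot distinguish strands; allele set must still match.
        if {out.effect_allele, out.other_allele} != set(e_alleles):
            return dropped()
        if palindromic_policy == "drop":
            return dropped()
        if exp.eaf is None or out.eaf is None:
            return dropped()
        if abs(exp.eaf - 0.5) <= eaf_ambiguity_band or abs(out.eaf - 0.5) <= eaf_ambiguity_band:
            return dropped()
        # Candidate 1: take the letters at face value; candidate 2: assume
        # opposite strands (which toggles the flip). Exactly one yields an
        # aligned EAF on the exposure's side of 0.5.
        flip_by_letters = out.effect_allele != exp.effect_allele
        aligned = out.flipped() if flip_by_letters else out
        if (aligned.eaf - 0.5) * (exp.eaf - 0.5) > 0:
            flip = flip_by_letters
        else:
            flip = not flip_by_letters
            aligned = out.flipped() if flip else out
        aligned = replace(
            aligned, effect_allele=exp.effect_allele, other_allele=exp.other_allele
        )
        return HarmonizedPair(exp.rsid, exp, aligned, flip, True, "eaf_inferred")

    candidates = (out, out.complemented())
    for cand in candidates:
        if (cand.effect_allele, cand.other_allele) == e_alleles:
            return HarmonizedPair(exp.rsid, exp, cand, False, False, "direct")
    for cand in candidates:
        flipped = cand.flipped()
        if (flipped.effect_allele, flipped.other_allele) == e_alleles:
            return HarmonizedPair(exp.rsid, exp, flipped, True, False, "flipped")
    return dropped()


def harmonize(
    exposure: InstrumentSet | Iterable[SnpAssociation],
    outcome: Iterable[SnpAssociation],
    palindromic_policy: str = "infer_by_eaf",
    eaf_ambiguity_band: float = 0.08,
) -> list[HarmonizedPair]:
    """Align outcome associations to the exposure's effect alleles.

    Returns one :class:`HarmonizedPair` per instrument, in rsid order;
    instruments absent from the outcome table, allele-mismatched records,
    and unresolvable palindromic variants come back with
    ``resolution="dropped"``. Use :func:`retained` to keep only usable pairs.
    """
    if palindromic_policy not in ("drop", "infer_by_eaf"):
        raise ConfigurationError(
            f"palindromic_policy must be 'drop' or 'infer_by_eaf', got {palindromic_policy!r}"
        )
    instruments = list(exposure)
    by_rsid: dict[str, SnpAssociation] = {}
    for snp in outcome:
        by_rsid.setdefault(snp.rsid, snp)

    pairs: list[HarmonizedPair] = []
    counts = {"direct": 0, "flipped": 0, "eaf_inferred": 0, "dropped": 0, "absent": 0}
    for exp in sorted(instruments, key=lambda s: s.rsid):
        out = by_rsid.get(exp.rsid)
        if out is None:
            pairs.append(HarmonizedPair(exp.rsid, exp, None, False, exp.palindromic, "dropped"))
            counts["absent"] += 1
            continue
        pair = _harmonize_one(exp, out, palindromic_policy, eaf_ambiguity_band)
        counts[pair.resolution] += 1
        pairs.append(pair)
    logger.info(
        "harmonized %d instruments: %d direct, %d flipped, %d eaf-inferred, "
        "%d dropped (%d absent from outcome)",
        len(pairs),
        counts["direct"],
        counts["flipped"],
        counts["eaf_inferred"],
        counts["dropped"] + counts["absent"],
        counts["absent"],
    )
    return pairs


# ---------------------------------------------------------------------------
# Results tables

RESULT_COLUMNS = [
    "outcome",
    "k",
    "model",
    "scale",
    "beta",
    "se",
    "ci_low",
    "ci_high",
    "pvalue",
    "het_q",
    "het_df",
    "het_p",
    "i2",
    "tau2",
    "excluded",
]


def _fmt(value: object) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        if math.isnan(value):
            return "NA"
        return format(value, ".10g")
    return str(value)


def write_results(results: Iterable, path: str | Path) -> None:
    """Write pooled estimates as a tab-delimited table.

    Columns mirror the paper-style main results table (outcome, k, model,
    estimate, 95% CI, p, I², heterogeneity p) at full numeric precision;
    values round-trip through :func:`read_results` to 10 significant digits.
    """
    path = Path(path)
    rows = []
    for est in results:
        het = est.het
        rows.append(
            {
                "outcome": est.outcome_name,
                "k": est.k,
                "model": est.model,
                "scale": est.scale,
                "beta": est.beta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pvalue": est.pvalue,
                "het_q": None if het is None else het.q,
                "het_df": None if het is None else het.df,
                "het_p": None if het is None else het.p_het,
                "i2": None if het is None else het.i2,
                "tau2": None if het is None else het.tau2,
                "excluded": ",".join(est.excluded_rsids) or "-",
            }
        )
    try:
        with open(path, "w") as fh:
            fh.write("\t".join(RESULT_COLUMNS) + "\n")
            for row in rows:
                fh.write("\t".join(_fmt(row[c]) for c in RESULT_COLUMNS) + "\n")
    except OSError as exc:
        raise InputError(f"cannot write results to {path}: {exc}") from exc


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a table written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return df
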