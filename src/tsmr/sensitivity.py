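"""Instrument-exclusion sensitivity analysis.

A variant with horizontal pleiotropy (a direct path to the outcome not
mediated by the exposure) violates the instrumental-variable exclusion
restriction and biases the pooled estimate. The classical check is to drop
the suspect variant and re-estimate; ``leave_one_out`` generalizes this to
every instrument in turn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from .exceptions import EmptyInstrumentError, InsufficientInstrumentsError
from .mr_core import PooledEstimate, pool_with_model_selection
from .summary_io import HarmonizedPair, retained

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SensitivityReport:
    """Baseline pool plus re-estimates under named exclusion sets."""

    baseline: PooledEstimate
    variants: Mapping[str, PooledEstimate]
    max_abs_shift: float


def exclude_and_rerun(
    pairs: Iterable[HarmonizedPair],
    excluded_rsids: Iterable[str],
    het_alpha: float = 0.05,
    outcome_name: str = "",
    scale: str = "continuous",
) -> PooledEstimate:
    """Re-pool after removing the named instruments.

    Excluding the empty set reproduces the baseline exactly. Unknown rsids
    warn rather than fail, so exclusion configs survive instrument-set edits.
    """
    pairs = retained(pairs)
    excluded = set(excluded_rsids)
    present = {p.rsid for p in pairs}
    for rsid in sorted(excluded - present):
        logger.warning("excluded rsid %s not among the instruments; ignored", rsid)
    kept = [p for p in pairs if p.rsid not in excluded]
    if not kept:
        raise EmptyInstrumentError("exclusion removed every instrument")
    return pool_with_model_selection(
        kept,
        het_alpha=het_alpha,
        outcome_name=outcome_name,
        scale=scale,
        excluded=tuple(sorted(excluded & present)),
    )


def leave_one_out(
    pairs: Iterable[HarmonizedPair],
    het_alpha: float = 0.05,
    outcome_name: str = "",
    scale: str = "continuous",
) -> SensitivityReport:
    """Re-estimate excluding each instrument in turn.

    Each variant is labelled ``without:<rsid>``; ``max_abs_shift`` is the
    largest absolute difference between a variant estimate and the baseline,
    a quick screen for a single influential (possibly pleiotropic) SNP.
    """
    pairs = retained(pairs)
    if len(pairs) < 2:
        raise InsufficientInstrumentsError(
            f"leave-one-out needs k >= 2 instruments, got {len(pairs)}"
        )
    baseline = pool_with_model_selection(
        pairs, het_alpha=het_alpha, outcome_name=outcome_name, scale=scale
    )
    variants = {
        f"without:{p.rsid}": exclude_and_rerun(
            pairs, {p.rsid}, het_alpha=het_alpha, outcome_name=outcome_name, scale=scale
        )
        for p in pairs
    }
    max_abs_shift = max(abs(v.beta - baseline.beta) for v in variants.values())
    return SensitivityReport(baseline=baseline, variants=variants, max_abs_shift=max_abs_shift)
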