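"""Successive rare-variant filtering for autosomal-dominant families.

The strategy removes, in order: poor-quality calls; variants common (MAF
above a threshold, default 1%) in ANY public frequency resource; variants
seen in a geographically matched control cohort (presence subtraction by
default, with frequency- and carrier-count relaxations for reduced
penetrance); variants not carried by enough affected family members
(allowing up to ``p`` phenocopies — affected individuals whose disease is
sporadic); and optionally variants carried by too many family members of
unknown affection status.  Every step is a per-variant predicate, so the
surviving set is the intersection of the individual filters and is
invariant to application order; only the step-count waterfall depends on
the order, which is fixed for reporting.

Thresholds are "maximal allowed" counts: a variant is retained when its
count is <= the threshold and removed when it exceeds it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .variants import (
    FrequencyResource,
    GenotypeMatrix,
    VariantKey,
    quality_filter,
)

__all__ = [
    "FilterConfig",
    "RelaxationMatrix",
    "PipelineResult",
    "public_maf_filter",
    "local_control_filter",
    "segregation_filter",
    "unknown_status_filter",
    "relaxation_matrix",
    "run_pipeline",
]


@dataclass
class FilterConfig:
    """Thresholds for the successive filters.

    ``public_maf_threshold`` — frequency above which a variant in any
    public resource is discarded (default 0.01).  ``maf_folded`` switches
    the comparison from plain alt-AF to min(af, 1-af).  ``local_mode`` and
    ``local_threshold`` set the control-cohort subtraction: ``presence``
    removes anything seen in the cohort, ``maf_threshold`` removes above a
    frequency, ``max_carriers`` removes variants carried by more than
    ``local_threshold`` control individuals (the penetrance relaxation).
    ``max_phenocopies`` allows that many affected members to lack the
    variant; ``max_unknown_carriers``, when set, caps carriers among
    unknown-status members.
    """

    public_maf_threshold: float = 0.01
    maf_folded: bool = False
    local_mode: str = "presence"
    local_threshold: float = 0.0
    max_phenocopies: int = 0
    max_control_carriers: int = 0
    max_unknown_carriers: int | None = None
    missing_affected_as_noncarrier: bool = True
    min_qual: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.public_maf_threshold <= 1.0:
            raise ValueError("public_maf_threshold must be in [0,1]")
        if self.max_phenocopies < 0 or self.max_control_carriers < 0:
            raise ValueError("count thresholds must be non-negative")


def public_maf_filter(
    variants: Sequence[VariantKey],
    resources: Iterable[FrequencyResource],
    threshold: float = 0.01,
    folded: bool = False,
) -> list[VariantKey]:
    """Remove variants whose frequency exceeds ``threshold`` in ANY resource.

    Absence from a resource never removes a variant — public catalogues are
    incomplete for local populations, which is the point of the local
    control step.
    """
    resources = list(resources)
    out = []
    for v in variants:
        common = False
        for res in resources:
            af = res.af(v)
            if af is None:
                continue
            maf = min(af, 1.0 - af) if folded else af
            if maf > threshold:
                common = True
                break
        if not common:
            out.append(v)
    return out


def local_control_filter(
    variants: Sequence[VariantKey],
    control: FrequencyResource | GenotypeMatrix,
    mode: str | None = None,
    threshold: float | None = None,
) -> list[VariantKey]:
    """Subtract control-cohort variation.

    ``presence``: remove any variant with at least one control alternate
    allele.  ``maf_threshold``: remove when control frequency exceeds the
    threshold.  ``max_carriers``: remove when more than ``threshold``
    control individuals carry the variant — the relaxation for a causal
    variant of incomplete penetrance slipping into the cohort.
    """
    if isinstance(control, GenotypeMatrix):
        control = FrequencyResource.from_genotype_matrix(control, name="control")
    mode = mode or control.mode
    threshold = control.threshold if threshold is None else threshold

    if mode == "presence":
        return [v for v in variants if v not in control]
    if mode == "maf_threshold":
        return [
            v for v in variants if (control.af(v) or 0.0) <= threshold
        ]
    if mode == "max_carriers":
        out = []
        for v in variants:
            if v not in control:
                out.append(v)
                continue
            carriers = control.carriers(v)
            if carriers is None:
                raise ValueError(
                    "max_carriers mode requires control genotypes or allele counts"
                )
            if carriers <= threshold:
                out.append(v)
        return out
    raise ValueError(f"unknown local filter mode {mode!r}")


def segregation_filter(
    matrix: GenotypeMatrix,
    affected: Sequence[str],
    max_phenocopies: int = 0,
    missing_as_noncarrier: bool = True,
) -> list[VariantKey]:
    """Retain variants carried by all affected members, up to ``max_phenocopies``.

    A variant survives iff the number of affected NON-carriers is <= the
    allowance; a missing genotype in an affected member counts as a
    non-carrier by default (conservative: it consumes a phenocopy).
    """
    if not 0 <= max_phenocopies <= len(list(affected)):
        raise ValueError("max_phenocopies must be between 0 and |affected|")
    non = matrix.noncarrier_counts(affected, missing_as_noncarrier)
    keep = non <= max_phenocopies
    return [v for v, k in zip(matrix.variants, keep) if k]


def unknown_status_filter(
    matrix: GenotypeMatrix,
    unknown_ids: Sequence[str],
    max_unknown_carriers: int,
) -> list[VariantKey]:
    """Retain variants carried by at most ``max_unknown_carriers`` of the
    unknown-affection members (e.g. relatives younger than disease onset)."""
    carriers = matrix.carrier_counts(unknown_ids)
    keep = carriers <= max_unknown_carriers
    return [v for v, k in zip(matrix.variants, keep) if k]


# ---------------------------------------------------------------------------
# Relaxation matrix
# ---------------------------------------------------------------------------


@dataclass
class RelaxationMatrix:
    """Cumulative candidate counts by allowed phenocopies (rows) and allowed
    control-cohort carriers (columns); rows and columns are monotone
    non-decreasing because each cell's constraint set nests the previous."""

    counts: pd.DataFrame  # index: max phenocopies p, columns: max control carriers c

    def __getitem__(self, pc: tuple[int, int]) -> int:
        p, c = pc
        return int(self.counts.loc[p, c])

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "max_phenocopies"
        out.columns.name = "max_control_carriers"
        out.to_csv(path, sep="\t")


def relaxation_matrix(
    matrix: GenotypeMatrix,
    affected: Sequence[str],
    control: GenotypeMatrix,
    p_max: int,
    c_max: int,
    missing_as_noncarrier: bool = True,
) -> RelaxationMatrix:
    """Joint relaxation grid: counts[p][c] = variants with <= p affected
    non-carriers AND <= c control carriers.

    Inputs are expected to be pre-filtered for quality and public-resource
    frequency; control carriers are counted as individuals.
    """
    non_aff = matrix.noncarrier_counts(affected, missing_as_noncarrier)
    ctrl = np.zeros(matrix.n_variants, dtype=int)
    ctrl_counts = {
        v: int(n)
        for v, n in zip(control.variants, control.carrier_counts())
    }
    for i, v in enumerate(matrix.variants):
        ctrl[i] = ctrl_counts.get(v, 0)
    grid = np.zeros((p_max + 1, c_max + 1), dtype=int)
    for p in range(p_max + 1):
        for c in range(c_max + 1):
            grid[p, c] = int(((non_aff <= p) & (ctrl <= c)).sum())
    return RelaxationMatrix(
        pd.DataFrame(grid, index=range(p_max + 1), columns=range(c_max + 1))
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    candidates: list[VariantKey]
    steps: list[tuple[str, int]]  # (step name, surviving count) waterfall
    table: pd.DataFrame

    @property
    def step_counts(self) -> dict[str, int]:
        return dict(self.steps)


def run_pipeline(
    config: FilterConfig,
    matrix: GenotypeMatrix,
    resources: Sequence[FrequencyResource],
    control: FrequencyResource | GenotypeMatrix | None,
    affected: Sequence[str],
    unknown_ids: Sequence[str] | None = None,
) -> PipelineResult:
    """Apply quality → public MAF → local control → segregation → unknown-status.

    Emits the per-step surviving-count waterfall alongside the candidate
    table.  Because every step is an independent per-variant predicate, the
    final set is order-invariant.
    """
    steps: list[tuple[str, int]] = [("input", matrix.n_variants)]

    work = quality_filter(matrix, min_qual=config.min_qual)
    steps.append(("quality", work.n_variants))

    surviving = public_maf_filter(
        work.variants, resources, config.public_maf_threshold, config.maf_folded
    )
    work = work.subset_variants(surviving)
    steps.append(("public_maf", work.n_variants))

    if control is not None:
        mode = config.local_mode
        threshold = (
            config.max_control_carriers
            if mode == "max_carriers"
            else config.local_threshold
        )
        surviving = local_control_filter(work.variants, control, mode, threshold)
        work = work.subset_variants(surviving)
        steps.append(("local_control", work.n_variants))

    surviving = segregation_filter(
        work,
        affected,
        config.max_phenocopies,
        config.missing_affected_as_noncarrier,
    )
    work = work.subset_variants(surviving)
    steps.append(("segregation", work.n_variants))

    if unknown_ids is not None and config.max_unknown_carriers is not None:
        surviving = unknown_status_filter(
            work, unknown_ids, config.max_unknown_carriers
        )
        work = work.subset_variants(surviving)
        steps.append(("unknown_status", work.n_variants))

    carriers_aff = work.carrier_counts(affected)
    table = pd.DataFrame(
        {
            "chrom": [v.chrom for v in work.variants],
            "pos": [v.pos for v in work.variants],
            "ref": [v.ref for v in work.variants],
            "alt": [v.alt for v in work.variants],
            "affected_carriers": carriers_aff,
        }
    )
    return PipelineResult(candidates=list(work.variants), steps=steps, table=table)
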