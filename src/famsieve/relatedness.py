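"""Shared-candidate counts versus expected relatedness.

Progressively adding family members to a filtering analysis shrinks the
set of variants they all carry.  For rare founder-transmitted variants the
shared count is expected to track the shared genome fraction: every
halving of the expected shared fraction should halve the count (a 50%
reduction per halving).  Variants that are common in the local population
are carried by many members through multiple founders, so their counts
decay far more slowly and flatten the curve — unless a geographically
matched control cohort subtracts them first.  The reduction-per-halving
statistic summarizes a curve into a single percentage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree, shared_fraction
from .variants import GenotypeMatrix, VariantKey

__all__ = [
    "CurvePoint",
    "SharingCurve",
    "ReductionResult",
    "shared_count_curve",
    "reduction_per_halving",
]


@dataclass(frozen=True)
class CurvePoint:
    shared_fraction: float
    members: tuple[str, ...]
    shared_count: int


@dataclass
class SharingCurve:
    """Shared-variant counts over nested member sets, largest fraction first."""

    points: list[CurvePoint]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "shared_fraction": [p.shared_fraction for p in self.points],
                "n_members": [len(p.members) for p in self.points],
                "shared_count": [p.shared_count for p in self.points],
            }
        )


def shared_count_curve(
    matrix: GenotypeMatrix,
    ordered_members: Sequence[str],
    ped: Pedigree,
    founder: str,
    min_members: int = 1,
    seed: int = 0,
) -> SharingCurve:
    """Count variants carried by every member of each prefix of ``ordered_members``.

    ``matrix`` should already be filtered (quality / frequency / control
    subtraction); the x-coordinate is the expected shared fraction of the
    prefix relative to the first member, via the closed form with
    gene-dropping fallback for inbred pedigrees.  Duplicate ids in a prefix
    do not change the count (intersection is idempotent).
    """
    reference = ordered_members[0]
    carrier = matrix.dosage > 0
    cols = matrix.sample_columns(ordered_members)
    points = []
    shared = np.ones(matrix.n_variants, dtype=bool)
    for k, col in enumerate(cols, start=1):
        shared &= carrier[:, col]
        if k < min_members:
            continue
        prefix = tuple(ordered_members[:k])
        frac = shared_fraction(ped, set(prefix), founder, reference, seed=seed)
        points.append(
            CurvePoint(
                shared_fraction=frac,
                members=prefix,
                shared_count=int(shared.sum()),
            )
        )
    return SharingCurve(points=points)


@dataclass(frozen=True)
class ReductionResult:
    """Average percent decrease in shared count per halving of shared fraction."""

    percent: float
    halvings: float
    n_points_used: int
    truncated: bool  # True when trailing zero-count points were dropped


def reduction_per_halving(
    curve: SharingCurve, method: str = "geometric"
) -> ReductionResult:
    """Average percent reduction of the shared count per halving of the
    expected shared fraction.

    ``geometric`` (default): with h = log2(f_first / f_last) halvings, the
    per-halving survival ratio is (N_last / N_first)**(1/h) and the result
    is 100 * (1 - ratio).  ``arithmetic``: mean of per-segment per-halving
    reductions.  Counts of 1000 → 500 → 250 over two halvings give 50%;
    1000 → 800 → 640 give 20%.  Trailing zero-count points are dropped
    (flagged ``truncated``) since a zero terminal count has no geometric
    rate.
    """
    pts = list(curve.points)
    truncated = False
    while len(pts) >= 2 and pts[-1].shared_count == 0:
        pts.pop()
        truncated = True
    if len(pts) < 2:
        raise ValueError("need at least 2 points with nonzero counts")
    if pts[0].shared_count <= 0:
        raise ValueError("first point has zero count")

    if method == "geometric":
        h = math.log2(pts[0].shared_fraction / pts[-1].shared_fraction)
        if h <= 0:
            raise ValueError("shared fraction must decrease along the curve")
        ratio = (pts[-1].shared_count / pts[0].shared_count) ** (1.0 / h)
        percent = 100.0 * (1.0 - ratio)
    elif method == "arithmetic":
        reductions = []
        for a, b in zip(pts, pts[1:]):
            h = math.log2(a.shared_fraction / b.shared_fraction)
            if h <= 0:
                continue
            reductions.append(1.0 - (b.shared_count / a.shared_count) ** (1.0 / h))
        if not reductions:
            raise ValueError("no decreasing-fraction segments in curve")
        percent = 100.0 * float(np.mean(reductions))
        h = math.log2(pts[0].shared_fraction / pts[-1].shared_fraction)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ReductionResult(
        percent=percent,
        halvings=h,
        n_points_used=len(pts),
        truncated=truncated,
    )
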