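"""Design-of-experiments selection of a control cohort.

A matched control population should span the phenotypic diversity of its
region without hand-picking.  Per stratum (municipality × gender), numeric
phenotype/health/lifestyle variables are standardized and projected onto
their first two principal components; samples are then chosen to sit at
the points of a two-level full-factorial design with a center point in
that score space (5 points), or a reinforced design that adds a sub-
factorial around each corner plus four extra center replicates (25
points).  A quota allocator spreads half the total cohort evenly over all
strata and dedicates the other half to designated high-population strata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignPoint",
    "pc_scores",
    "design_points",
    "select_samples",
    "allocate_quota",
    "filter_eligible",
]


@dataclass(frozen=True)
class DesignPoint:
    """A target location in (PC1, PC2) score space."""

    x: float
    y: float
    role: str  # corner | center | sub_corner | sub_center


class StratumError(ValueError):
    """Stratum too small or too degenerate for a PC model."""


def standardize(
    table: pd.DataFrame, variables: Sequence[str] | None = None
) -> pd.DataFrame:
    """Impute missing values to the column mean, then scale to zero mean and
    unit variance.  Constant (zero-variance) columns are dropped."""
    df = table[list(variables)] if variables is not None else table.copy()
    df = df.astype(float)
    df = df.fillna(df.mean())
    sd = df.std(ddof=0)
    keep = sd > 0
    df = df.loc[:, keep]
    return (df - df.mean()) / sd[keep]


def pc_scores(
    table: pd.DataFrame,
    variables: Sequence[str] | None = None,
    stratum: str = "",
) -> pd.DataFrame:
    """Top-2 principal-component scores of a stratum's phenotype table.

    Standardizes per stratum (missing values imputed to the stratum mean),
    projects onto the two leading components of the variable covariance,
    and fixes signs so the largest-magnitude loading of each component is
    positive.  Deterministic.  Raises :class:`StratumError` for strata
    with < 3 samples or < 2 non-degenerate (non-constant) variables; fully
    collinear variables are fine (PC2 then carries no variance).
    """
    from sklearn.decomposition import PCA

    label = f" in stratum {stratum!r}" if stratum else ""
    if len(table) < 3:
        raise StratumError(f"need >= 3 samples{label}, got {len(table)}")
    z = standardize(table, variables)
    if z.shape[1] < 2:
        raise StratumError(f"need >= 2 non-degenerate variables{label}")
    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(z.to_numpy())
    for k in range(2):
        loadings = pca.components_[k]
        if loadings[np.argmax(np.abs(loadings))] < 0:
            scores[:, k] = -scores[:, k]
    return pd.DataFrame(scores, index=table.index, columns=["PC1", "PC2"])


def design_points(kind: str = "baseline", level: float = 1.5) -> list[DesignPoint]:
    """Factorial design targets in score space.

    ``baseline``: 2-level full factorial plus a center point — 5 points.
    ``reinforced``: the baseline, another full factorial of half-level
    offsets around each corner (16 sub-corners) and four extra center
    replicates — 25 points.  ``level`` is in score units (SD-scaled
    scores; default 1.5).
    """
    if level <= 0:
        raise ValueError("level must be positive")
    corners = [
        DesignPoint(sx * level, sy * level, "corner")
        for sx in (-1, 1)
        for sy in (-1, 1)
    ]
    base = corners + [DesignPoint(0.0, 0.0, "center")]
    if kind == "baseline":
        return base
    if kind == "reinforced":
        half = level / 2.0
        subs = [
            DesignPoint(c.x + sx * half, c.y + sy * half, "sub_corner")
            for c in corners
            for sx in (-1, 1)
            for sy in (-1, 1)
        ]
        extra_centers = [DesignPoint(0.0, 0.0, "sub_center") for _ in range(4)]
        return base + subs + extra_centers
    raise ValueError(f"unknown design kind {kind!r}")


def select_samples(
    scores: pd.DataFrame,
    points: Sequence[DesignPoint],
) -> pd.DataFrame:
    """Greedy nearest-sample assignment of design points.

    In point order, each design point claims the closest (Euclidean in
    score space) sample not yet selected; ties break on sample id.  If the
    stratum has fewer samples than points the selection is partial (with a
    warning).  Returns a report with sample, point index/role and
    distance.
    """
    import warnings

    ids = list(scores.index)
    xy = scores[["PC1", "PC2"]].to_numpy(dtype=float)
    available = dict(zip(ids, range(len(ids))))
    rows = []
    for pi, pt in enumerate(points):
        if not available:
            warnings.warn(
                f"stratum exhausted after {pi} of {len(points)} design points",
                stacklevel=2,
            )
            break
        dists = {
            sid: float(np.hypot(xy[j, 0] - pt.x, xy[j, 1] - pt.y))
            for sid, j in available.items()
        }
        best = min(dists, key=lambda sid: (dists[sid], str(sid)))
        rows.append(
            {
                "sample": best,
                "point_index": pi,
                "role": pt.role,
                "point_x": pt.x,
                "point_y": pt.y,
                "distance": dists[best],
            }
        )
        del available[best]
    return pd.DataFrame(rows)


def allocate_quota(
    total: int,
    strata: Sequence[str],
    reinforced_strata: Sequence[str],
    per_stratum_base: int,
    weights: Mapping[str, float] | None = None,
    genders: Sequence[str] = ("female", "male"),
) -> pd.DataFrame:
    """Split a sequencing budget over (stratum, gender) cells.

    The baseline allocation gives every stratum ``per_stratum_base``
    samples per gender; the remainder of ``total`` is distributed over the
    ``reinforced_strata`` proportionally to ``weights`` (equal by default),
    split equally between genders.  Quotas sum exactly to ``total`` and
    genders are balanced within every stratum.
    """
    if total % 2 != 0:
        raise ValueError("total must be even for an equal gender split")
    n_cells = len(strata) * len(genders)
    baseline_total = n_cells * per_stratum_base
    if baseline_total > total:
        raise ValueError(
            f"baseline alone needs {baseline_total} > total {total}"
        )
    remainder = total - baseline_total
    quota = {(s, g): per_stratum_base for s in strata for g in genders}
    if remainder:
        if not reinforced_strata:
            raise ValueError("remaining budget but no reinforced strata")
        unknown = set(reinforced_strata) - set(strata)
        if unknown:
            raise ValueError(f"reinforced strata not in strata: {sorted(unknown)}")
        if weights is None:
            weights = {s: 1.0 for s in reinforced_strata}
        w = np.array([weights[s] for s in reinforced_strata], dtype=float)
        if (w <= 0).any():
            raise ValueError("weights must be positive")
        per_gender_rem = remainder // len(genders)
        if per_gender_rem * len(genders) != remainder:
            raise ValueError("remainder does not split evenly across genders")
        # largest-remainder apportionment per gender
        shares = w / w.sum() * per_gender_rem
        extra = np.floor(shares).astype(int)
        frac_order = np.argsort(-(shares - extra))
        for k in range(per_gender_rem - int(extra.sum())):
            extra[frac_order[k]] += 1
        for s, e in zip(reinforced_strata, extra):
            for g in genders:
                quota[(s, g)] += int(e)
    df = pd.DataFrame(
        [
            {"stratum": s, "gender": g, "quota": quota[(s, g)]}
            for s in strata
            for g in genders
        ]
    )
    assert int(df["quota"].sum()) == total
    return df


def filter_eligible(
    table: pd.DataFrame,
    criteria: Mapping[str, tuple[str, object]],
) -> pd.DataFrame:
    """Declarative row filter, e.g. ``{"age": (">=", 80), "cancer": ("==", 0)}``."""
    ops = {
        "==": lambda col, v: col == v,
        "!=": lambda col, v: col != v,
        ">=": lambda col, v: col >= v,
        "<=": lambda col, v: col <= v,
        ">": lambda col, v: col > v,
        "<": lambda col, v: col < v,
    }
    mask = pd.Series(True, index=table.index)
    for column, (op, value) in criteria.items():
        if op not in ops:
            raise ValueError(f"unknown operator {op!r}")
        mask &= ops[op](table[column], value)
    return table[mask]
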