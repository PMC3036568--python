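"""Population-level connectivity statistics.

Two workhorses: per-cell contact censuses with coefficient-of-variation
(CV) summaries — if contact types are sampled proportionally in each cell,
per-cell *ratios* of counts vary much less than the raw counts — and a
one-sided binomial tail test for nonrandom placement of a contact type
across cell classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .model import AnnotationModel, contact_census

__all__ = [
    "CensusSummary",
    "PlacementTest",
    "census_table",
    "census_summary",
    "summary_from_printed",
    "proportional_sampling_check",
    "binomial_placement_test",
]


@dataclass(frozen=True)
class CensusSummary:
    """Mean / SD / CV of per-cell contact counts and of count ratios.

    ``counts`` maps contact type -> (mean, sd, cv, n); ``ratios`` maps
    "a/b" -> (mean, sd, cv, n).  SDs use the n-1 denominator.
    """

    counts: Mapping[str, tuple[float, float, float, int]]
    ratios: Mapping[str, tuple[float, float, float, int]]

    def mean_count_cv(self) -> float:
        return float(np.mean([v[2] for v in self.counts.values()]))

    def mean_ratio_cv(self) -> float:
        return float(np.mean([v[2] for v in self.ratios.values()]))


@dataclass(frozen=True)
class PlacementTest:
    """Binomial placement test record."""

    n: int
    class_sizes: Mapping[str, int]
    focal_class: str
    observed: int
    p0: float
    tail_probability: float


def census_table(model: AnnotationModel, cell_ids: Sequence[int]) -> pd.DataFrame:
    """Per-cell contact censuses as a cells x contact-type table."""
    rows = {cid: contact_census(model, cid) for cid in cell_ids}
    return pd.DataFrame.from_dict(rows, orient="index")


def _msc(x: np.ndarray) -> tuple[float, float, float, int]:
    x = np.asarray(x, dtype=float)
    m = float(x.mean())
    sd = float(x.std(ddof=1)) if len(x) > 1 else 0.0
    cv = sd / m if m > 0 else np.nan
    return m, sd, cv, len(x)


def census_summary(
    counts: pd.DataFrame,
    ratio_pairs: Sequence[tuple[str, str]] = (
        ("postsynaptic", "presynaptic"),
        ("postsynaptic", "gap_junction"),
    ),
) -> CensusSummary:
    """Summarize per-cell contact counts and per-cell count ratios.

    ``counts`` is a cells x contact-type table (see :func:`census_table`).
    Types absent in every cell are omitted.  Ratios are computed per cell
    and summarized only over cells where the denominator is positive.
    """
    if len(counts) < 2:
        raise ValueError("need at least 2 cells")
    ctype_stats = {}
    for col in counts.columns:
        if counts[col].sum() > 0:
            ctype_stats[col] = _msc(counts[col].to_numpy())
    ratio_stats = {}
    for num, den in ratio_pairs:
        if num not in counts.columns or den not in counts.columns:
            continue
        ok = counts[den] > 0
        if ok.sum() >= 2:
            r = (counts.loc[ok, num] / counts.loc[ok, den]).to_numpy()
            ratio_stats[f"{num}/{den}"] = _msc(r)
    return CensusSummary(ctype_stats, ratio_stats)


def summary_from_printed(
    counts: Mapping[str, tuple[float, float]],
    ratios: Mapping[str, tuple[float, float]],
    n: int,
) -> CensusSummary:
    """Build a :class:`CensusSummary` from published mean +/- SD figures."""
    return CensusSummary(
        {k: (m, s, s / m, n) for k, (m, s) in counts.items()},
        {k: (m, s, s / m, n) for k, (m, s) in ratios.items()},
    )


def proportional_sampling_check(
    summary: CensusSummary, threshold: float = 2.0
) -> tuple[float, str]:
    """Ratio of mean raw-count CV to mean ratio CV, with a verdict.

    When every cell's counts are a per-cell scale times fixed proportions,
    count ratios are constant across cells and the quotient diverges; a
    quotient at or above ``threshold`` (default 2, "twofold smaller CV")
    supports proportional sampling of the contact types.
    """
    if not summary.ratios:
        raise ValueError("need at least one defined ratio")
    raw_cv = summary.mean_count_cv()
    ratio_cv = summary.mean_ratio_cv()
    if ratio_cv == 0:
        import warnings

        warnings.warn("zero ratio CV; quotient reported as infinite")
        return float("inf"), "proportional"
    q = raw_cv / ratio_cv
    return q, ("proportional" if q >= threshold else "not proportional")


def binomial_placement_test(
    n: int,
    class_sizes: Mapping[str, int],
    focal_class: str,
    observed: int,
) -> PlacementTest:
    """One-sided binomial test for concentration of contacts in one class.

    Under the null, each of the ``n`` contacts lands in the focal class
    independently with probability ``p0`` equal to the focal class's share
    of cells.  The tail probability is P(X >= observed) for
    X ~ Binomial(n, p0); small values reject random placement in favour of
    concentration in the focal class.
    """
    if focal_class not in class_sizes:
        raise KeyError(focal_class)
    total = sum(class_sizes.values())
    p0 = class_sizes[focal_class] / total
    if not (0 < p0 < 1):
        raise ValueError("null probability must lie strictly in (0, 1)")
    if not (0 <= observed <= n):
        raise ValueError("observed must lie in [0, n]")
    tail = float(binom.sf(observed - 1, n, p0))
    return PlacementTest(n, dict(class_sizes), focal_class, observed, p0, tail)
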