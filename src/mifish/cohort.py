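"""Cohort-level aggregation and association analysis.

Joins per-sample summaries with clinical metadata and reproduces the
cohort-level report: summary statistics per column, per-gene aberration
frequencies over clone annotations, median dichotomization with Fisher's
exact association, and the polyploidization rate.

The package ships transcriptions of the two published case tables
(``table1``: the 11 NASH-HCC resections with clone annotations, ploidy and
instability index; ``table2``: the 11 NAFLD/NASH biopsies with NAS,
tetraploid:octoploid ratio, polyploid fraction and mean ploidy) as
fixtures for regression tests and the worked examples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .panel import ProbePanel, default_panel

_STATISTICS = ("mean", "median", "min", "max", "sd")


class CohortError(ValueError):
    """Raised for invalid cohort-level inputs."""


def _data_path(name: str):
    return resources.files("mifish.data").joinpath(name)


def load_table1() -> pd.DataFrame:
    """The NASH-HCC case table (one row per resection specimen)."""
    with resources.as_file(_data_path("table1.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def load_table2() -> pd.DataFrame:
    """The NAFLD/NASH biopsy ploidy table (one row per biopsy)."""
    with resources.as_file(_data_path("table2.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal-style rounding (0.5 always rounds away from zero)."""
    factor = 10.0**ndigits
    value = math.floor(abs(x) * factor + 0.5) / factor
    value = math.copysign(value, x)
    return value if ndigits > 0 else int(value)


def aggregate(cohort: pd.DataFrame, field: str, statistic: str) -> float:
    """A standard summary statistic of one numeric cohort column.

    ``statistic`` is one of mean/median/min/max/sd (sd uses n-1).
    """
    if statistic not in _STATISTICS:
        raise CohortError(f"statistic must be one of {_STATISTICS}, got {statistic!r}")
    if field not in cohort.columns:
        raise CohortError(f"unknown cohort field {field!r}")
    if len(cohort) == 0:
        raise CohortError("empty cohort")
    col = pd.to_numeric(cohort[field])
    if statistic == "sd":
        return float(col.std(ddof=1))
    return float(getattr(col, statistic)())


# ---------------------------------------------------------------------------
# clone-annotation frequencies
# ---------------------------------------------------------------------------

_DIRECTION_TOKEN = {"gain": "+", "loss": "-"}


def _parse_clone_annotation(text) -> set[tuple[str, str]]:
    """Parse 'MYC+,TP53-' style clone annotations into (gene, token) pairs."""
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return set()
    out = set()
    for tok in str(text).replace(";", ",").split(","):
        tok = tok.strip()
        if not tok:
            continue
        if tok[-1] not in "+-":
            raise CohortError(
                f"clone annotation token {tok!r} must end in '+' (gain) or '-' (loss)"
            )
        out.add((tok[:-1], tok[-1]))
    return out


def gene_frequency(
    cohort: pd.DataFrame,
    gene: str,
    direction: str,
    panel: ProbePanel | None = None,
    clone_columns: tuple[str, ...] = ("major_clone", "minor_clone"),
) -> tuple[int, int, int]:
    """Number and percentage of samples with a clonal aberration of a gene.

    Returns ``(k, n, pct)``: ``k`` samples carry at least one clonal pattern
    with the given gene gained/lost, ``pct = round(100*k/n)`` (half-up).
    """
    if direction not in _DIRECTION_TOKEN:
        raise CohortError("direction must be 'gain' or 'loss'")
    panel = panel or default_panel()
    if gene not in panel.gene_names:
        raise CohortError(f"unknown gene {gene!r}; panel genes: {panel.gene_names}")
    token = _DIRECTION_TOKEN[direction]
    n = len(cohort)
    if n == 0:
        raise CohortError("empty cohort")
    k = 0
    for _, row in cohort.iterrows():
        found = set()
        for col in clone_columns:
            if col in cohort.columns:
                found |= _parse_clone_annotation(row[col])
        if (gene, token) in found:
            k += 1
    return k, n, int(round_half_up(100.0 * k / n))


# ---------------------------------------------------------------------------
# dichotomization and association
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationResult:
    cut: float
    table: tuple[tuple[int, int], tuple[int, int]]  # rows: high/low, cols: pos/neg
    odds_ratio: float | None
    p_value: float | None
    degenerate: bool


def dichotomize_and_associate(
    cohort: pd.DataFrame,
    value_field: str,
    group_field: str,
    positive: object = True,
) -> AssociationResult:
    """Median split of a numeric column, tested against a binary trait.

    Samples strictly above the median form the *high* group (the at-median
    sample stays in the low group).  Association is Fisher's exact test,
    two-sided, on the high/low x positive/negative 2x2 table.  A table with
    an empty margin is flagged degenerate and carries no p-value.
    """
    if len(cohort) < 4:
        raise CohortError("dichotomization needs at least 4 samples")
    values = pd.to_numeric(cohort[value_field])
    cut = float(values.median())
    high = values > cut
    pos = cohort[group_field] == positive
    a = int((high & pos).sum())
    b = int((high & ~pos).sum())
    c = int((~high & pos).sum())
    d = int((~high & ~pos).sum())
    table = ((a, b), (c, d))
    degenerate = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)
    if degenerate:
        return AssociationResult(cut, table, None, None, True)
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return AssociationResult(cut, table, float(odds), float(p), False)


def polyploidization_rate(
    cohort: pd.DataFrame | None = None,
    flags=None,
    column: str = "polyploid_clones",
) -> tuple[int, int, int]:
    """Fraction of samples with polyploid tumor clones.

    Accepts either a cohort table with a yes/no ``polyploid_clones`` column
    or an explicit iterable of booleans (e.g. "tree has a doubling edge"
    flags from the phylogeny stage).  Returns ``(k, n, pct)``.
    """
    if flags is None:
        if cohort is None or column not in cohort.columns:
            raise CohortError(f"need a cohort with a {column!r} column or flags")
        flags = [
            str(v).strip().lower() in ("yes", "true", "1") for v in cohort[column]
        ]
    flags = [bool(f) for f in flags]
    n = len(flags)
    if n == 0:
        raise CohortError("empty cohort")
    k = sum(flags)
    return k, n, int(round_half_up(100.0 * k / n))


def spearman_correlation(
    cohort: pd.DataFrame, field_x: str, field_y: str
) -> tuple[float, float]:
    """Spearman rank correlation (r, p) between two numeric columns."""
    x = pd.to_numeric(cohort[field_x])
    y = pd.to_numeric(cohort[field_y])
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)
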