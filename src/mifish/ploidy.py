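"""Per-sample ploidy, signal-pattern and clonality statistics.

Definitions
-----------
signal pattern
    The full string of per-probe copy numbers observed in one nucleus;
    two nuclei share a pattern iff their complete count vectors (including
    the centromere controls) are identical.
ploidy reference
    Per-nucleus baseline: the round-half-up mean of the two centromere
    control counts (minimum 1).  Gene probes are coded gained/lost/neutral
    by strict comparison against it.
ploidy class
    The 2n/4n/8n grouping: nearest of {2, 4, 8} to the centromere mean,
    ties resolved toward the lower class.
instability index
    Number of distinct signal patterns per 100 analyzed nuclei.
clonal pattern
    A pattern carried by strictly more than 2% of the analyzed nuclei.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .panel import ProbePanel

logger = logging.getLogger(__name__)

GAIN, NEUTRAL, LOSS = 1, 0, -1
CODE_LABELS = {GAIN: "gain", NEUTRAL: "neutral", LOSS: "loss"}

#: strict clonality threshold: a pattern is clonal iff fraction > this value.
CLONAL_FRACTION = 0.02

#: low vs high diversification cut on the number of clonal patterns.
DIVERSIFICATION_CUT = 6

MODE_HCC = "hcc"
MODE_NAFLD = "nafld"


class PloidyError(ValueError):
    """Raised for un-assignable nuclei or invalid per-sample inputs."""


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# per-nucleus operations
# ---------------------------------------------------------------------------

def assign_ploidy(counts, panel: ProbePanel) -> tuple[int, int]:
    """Ploidy reference and 2n/4n/8n class of one nucleus.

    ``counts`` is the full panel-ordered count vector.  The reference is the
    round-half-up mean of the two centromere counts (minimum 1); the class is
    the nearest of {2, 4, 8} to that mean with ties toward the lower class.
    Raises :class:`PloidyError` if both centromere counts are zero.
    """
    counts = np.asarray(counts)
    cen = counts[list(panel.centromere_indices)]
    if int(cen.sum()) == 0:
        raise PloidyError("both centromere counts are 0: ploidy un-assignable")
    mean = float(cen.sum()) / 2.0
    ref = max(1, _round_half_up(mean))
    if mean <= 3.0:  # tie at 3 resolves down to 2n
        cls = 2
    elif mean <= 6.0:  # tie at 6 resolves down to 4n
        cls = 4
    else:
        cls = 8
    return ref, cls


def code_gain_loss(counts, ploidy_ref: int, panel: ProbePanel) -> np.ndarray:
    """Gain/loss/neutral coding of the gene probes against the ploidy.

    Strict comparison: count above the reference is a gain, below a loss,
    equal is neutral.  Centromere controls are excluded from the coding.
    Returns an int8 vector over the panel's gene probes (+1/0/-1).
    """
    if ploidy_ref < 1:
        raise PloidyError(f"ploidy_ref must be >= 1, got {ploidy_ref}")
    counts = np.asarray(counts)
    genes = counts[list(panel.gene_indices)]
    return np.sign(genes - ploidy_ref).astype(np.int8)


@dataclass(frozen=True)
class SignalPattern:
    """A nucleus copy-number string with derived ploidy and coding."""

    counts: tuple[int, ...]
    ploidy_ref: int
    ploidy_class: int
    coding: tuple[int, ...]  # over gene probes, values in {-1, 0, +1}

    @classmethod
    def from_counts(cls, counts, panel: ProbePanel) -> "SignalPattern":
        counts = tuple(int(c) for c in counts)
        ref, pcls = assign_ploidy(counts, panel)
        coding = tuple(int(c) for c in code_gain_loss(counts, ref, panel))
        return cls(counts=counts, ploidy_ref=ref, ploidy_class=pcls, coding=coding)

    @property
    def is_balanced(self) -> bool:
        """True iff every gene count equals the ploidy reference."""
        return all(c == 0 for c in self.coding)

    def coding_labels(self, panel: ProbePanel) -> dict[str, str]:
        return {
            name: CODE_LABELS[code]
            for name, code in zip(panel.gene_names, self.coding)
        }


@dataclass(frozen=True)
class ClonePattern:
    """A signal pattern with its cell count and clonality flag."""

    pattern: SignalPattern
    n_cells: int
    fraction: float
    clonal: bool


# ---------------------------------------------------------------------------
# table-level annotation
# ---------------------------------------------------------------------------

def annotate_cells(
    cells: pd.DataFrame, panel: ProbePanel
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach per-nucleus ploidy columns to a QC-passed cell frame.

    Returns ``(annotated, exclusion_log)``: nuclei whose centromere counts
    are both zero cannot be assigned a ploidy and are excluded (logged with
    reason ``ploidy_unassignable``).  The annotated frame gains columns
    ``ploidy_ref``, ``ploidy_class`` and ``centromere_mean``.
    """
    mat = _io.counts_matrix(cells, panel)
    cen = mat[:, list(panel.centromere_indices)]
    cen_sum = cen.sum(axis=1)
    assignable = cen_sum > 0
    log = pd.DataFrame(
        {
            "cell_id": cells.loc[~assignable, "cell_id"].astype(str).to_numpy(),
            "reason": "ploidy_unassignable",
        }
    )
    out = cells.loc[assignable].copy()
    mean = cen_sum[assignable] / 2.0
    out["centromere_mean"] = mean
    out["ploidy_ref"] = np.maximum(1, np.floor(mean + 0.5).astype(np.int64))
    out["ploidy_class"] = np.where(mean <= 3.0, 2, np.where(mean <= 6.0, 4, 8))
    return out, log


def enumerate_patterns(
    cells: pd.DataFrame, panel: ProbePanel
) -> dict[tuple[int, ...], int]:
    """Map each observed full count vector to its nucleus count.

    Keys are panel-ordered count tuples; values sum to the number of
    analyzed nuclei.
    """
    mat = _io.counts_matrix(cells, panel)
    patterns: dict[tuple[int, ...], int] = {}
    for row in map(tuple, mat.tolist()):
        patterns[row] = patterns.get(row, 0) + 1
    return patterns


def call_clones(
    pattern_counts: dict[tuple[int, ...], int],
    n_analyzed: int,
    panel: ProbePanel,
) -> list[ClonePattern]:
    """Clonality calls for every observed pattern.

    A pattern is clonal iff its fraction of the analyzed nuclei strictly
    exceeds 2%.  The result is sorted by descending fraction (ties broken by
    the count vector, lexicographically), so the first clonal entry is the
    major clone.
    """
    if n_analyzed <= 0:
        raise PloidyError("n_analyzed must be positive")
    out = []
    for counts_vec, n in sorted(pattern_counts.items(), key=lambda kv: (-kv[1], kv[0])):
        frac = n / n_analyzed
        out.append(
            ClonePattern(
                pattern=SignalPattern.from_counts(counts_vec, panel),
                n_cells=n,
                fraction=frac,
                clonal=frac > CLONAL_FRACTION,
            )
        )
    return out


def instability_index(n_patterns: int, n_analyzed: int) -> float:
    """Distinct signal patterns per 100 analyzed nuclei (unrounded)."""
    if n_analyzed <= 0:
        raise PloidyError("n_analyzed must be positive")
    return 100.0 * n_patterns / n_analyzed


def aberrant_filter(
    cells: pd.DataFrame, panel: ProbePanel, mode: str = MODE_HCC
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split annotated nuclei into aberrant and presumed-normal subsets.

    A nucleus is *normal* iff every gene count equals its ploidy reference
    and its ploidy class is an expected class for non-lesional liver:
    {2, 4} in ``hcc`` mode (balanced diploid/tetraploid cells are taken as
    normal liver or stromal cells), {2, 4, 8} in ``nafld`` mode (the ploidy
    screen counts balanced polyploid hepatocytes as polyploid normals).
    Returns ``(aberrant, normal)``.
    """
    if mode not in (MODE_HCC, MODE_NAFLD):
        raise PloidyError(f"mode must be '{MODE_HCC}' or '{MODE_NAFLD}', got {mode!r}")
    if "ploidy_ref" not in cells.columns:
        raise PloidyError("cells must be annotated first (annotate_cells)")
    mat = _io.counts_matrix(cells, panel)
    genes = mat[:, list(panel.gene_indices)]
    ref = cells["ploidy_ref"].to_numpy()
    balanced = (genes == ref[:, None]).all(axis=1)
    normal_classes = (2, 4) if mode == MODE_HCC else (2, 4, 8)
    normal = balanced & cells["ploidy_class"].isin(normal_classes).to_numpy()
    return cells.loc[~normal].copy(), cells.loc[normal].copy()


@dataclass(frozen=True)
class PolyploidyMetrics:
    polyploid_fraction: float  # percent of nuclei in class 4n or 8n
    tetra_octo_ratio: float  # (#4n)/(#8n); inf if no octoploids
    mean_ploidy: float  # mean over nuclei of the centromere-count mean

    @property
    def mean_ploidy_2dp(self) -> float:
        return round(self.mean_ploidy, 2)


def polyploidy_metrics(cells: pd.DataFrame, panel: ProbePanel) -> PolyploidyMetrics:
    """Polyploid fraction, tetraploid:octoploid ratio and mean ploidy."""
    if len(cells) == 0:
        raise PloidyError("polyploidy metrics need at least one nucleus")
    if "ploidy_class" not in cells.columns:
        raise PloidyError("cells must be annotated first (annotate_cells)")
    cls = cells["ploidy_class"].to_numpy()
    n = len(cls)
    n4 = int((cls == 4).sum())
    n8 = int((cls == 8).sum())
    fraction = 100.0 * (n4 + n8) / n
    if n8 > 0:
        ratio = n4 / n8
    elif n4 > 0:
        ratio = math.inf
    else:
        ratio = math.nan
    mean = float(cells["centromere_mean"].mean())
    return PolyploidyMetrics(
        polyploid_fraction=fraction, tetra_octo_ratio=ratio, mean_ploidy=mean
    )


def diversification_class(n_clonal_patterns: int) -> str:
    """'low' for at most 6 clonal patterns, else 'high' (multiclonality)."""
    if n_clonal_patterns < 0:
        raise PloidyError("n_clonal_patterns must be >= 0")
    return "low" if n_clonal_patterns <= DIVERSIFICATION_CUT else "high"


@dataclass(frozen=True)
class NASBins:
    """NAFLD activity score counts per category 1-2, 3-4 and >=5.

    Scores of 0 fall outside the categories and are reported separately
    rather than silently merged into the lowest bin.
    """

    bin_1_2: int
    bin_3_4: int
    bin_ge5: int
    zeros: int = 0

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.bin_1_2, self.bin_3_4, self.bin_ge5)


def nas_binning(nas_values) -> NASBins:
    """Bin NAFLD activity scores into the 1-2 / 3-4 / >=5 categories."""
    values = [int(v) for v in nas_values]
    for v in values:
        if not 0 <= v <= 8:
            raise PloidyError(f"NAS value {v} outside the 0-8 scale")
    zeros = sum(v == 0 for v in values)
    if zeros:
        logger.warning("%d NAS value(s) of 0 fall below category 1-2", zeros)
    return NASBins(
        bin_1_2=sum(1 <= v <= 2 for v in values),
        bin_3_4=sum(3 <= v <= 4 for v in values),
        bin_ge5=sum(v >= 5 for v in values),
        zeros=zeros,
    )


# ---------------------------------------------------------------------------
# per-sample summary
# ---------------------------------------------------------------------------

@dataclass
class SampleSummary:
    """Per-sample statistics: the machine-readable analogue of a case row."""

    sample_id: str
    n_analyzed: int
    average_ploidy: float
    instability_index: float
    n_patterns: int
    n_clonal_patterns: int
    clonal_patterns: list[ClonePattern] = field(default_factory=list)
    polyploid_fraction: float = 0.0
    tetra_octo_ratio: float = math.nan
    diversification: str = "low"
    gene_calls: dict[str, str] = field(default_factory=dict)
    mode: str = MODE_HCC

    @property
    def instability_index_1dp(self) -> float:
        return round(self.instability_index, 1)

    def to_dict(self) -> dict:
        ratio = self.tetra_octo_ratio
        return {
            "sample_id": self.sample_id,
            "n_analyzed": self.n_analyzed,
            "average_ploidy": round(self.average_ploidy, 2),
            "instability_index": self.instability_index_1dp,
            "n_patterns": self.n_patterns,
            "n_clonal_patterns": self.n_clonal_patterns,
            "polyploid_fraction": round(self.polyploid_fraction, 2),
            "tetra_octo_ratio": (
                None if math.isnan(ratio) else ("inf" if math.isinf(ratio) else round(ratio, 2))
            ),
            "diversification": self.diversification,
            "gene_calls": dict(self.gene_calls),
            "mode": self.mode,
            "clonal_patterns": [
                {
                    "counts": list(cp.pattern.counts),
                    "n_cells": cp.n_cells,
                    "fraction": round(cp.fraction, 4),
                    "ploidy_ref": cp.pattern.ploidy_ref,
                    "ploidy_class": cp.pattern.ploidy_class,
                }
                for cp in self.clonal_patterns
                if cp.clonal
            ],
        }


def _gene_calls(
    clones: list[ClonePattern], panel: ProbePanel
) -> dict[str, str]:
    # Clone-level per-gene direction: the call of the most frequent clonal
    # pattern in which the gene is non-neutral; 'none' if no clonal pattern
    # carries an aberration of the gene.
    calls: dict[str, str] = {g: "none" for g in panel.gene_names}
    for cp in clones:  # already sorted by descending fraction
        if not cp.clonal:
            continue
        for gene, code in zip(panel.gene_names, cp.pattern.coding):
            if code != 0 and calls[gene] == "none":
                calls[gene] = CODE_LABELS[code]
    return calls


def summarize_sample(
    cells: pd.DataFrame,
    panel: ProbePanel,
    mode: str = MODE_HCC,
    sample_id: str | None = None,
) -> SampleSummary:
    """Full per-sample analysis of a QC-passed cell frame.

    Pattern enumeration, the instability index and the clonality denominator
    use *all* ploidy-assignable nuclei; the aberrant/normal split (per
    ``mode``) restricts only the clone-level gene calls, mirroring the
    tumor-cell reporting convention.
    """
    kept, _ = _io.apply_qc(cells)
    annotated, _ = annotate_cells(kept, panel)
    n = len(annotated)
    if n == 0:
        raise PloidyError("no analyzable nuclei after QC and ploidy assignment")
    if sample_id is None:
        sample_id = str(annotated["sample_id"].iloc[0])

    patterns = enumerate_patterns(annotated, panel)
    clones = call_clones(patterns, n, panel)
    n_clonal = sum(cp.clonal for cp in clones)
    metrics = polyploidy_metrics(annotated, panel)

    aberrant, _ = aberrant_filter(annotated, panel, mode=mode)
    aberrant_keys = set(
        map(tuple, _io.counts_matrix(aberrant, panel).tolist())
    )
    reportable = [cp for cp in clones if cp.pattern.counts in aberrant_keys]

    return SampleSummary(
        sample_id=sample_id,
        n_analyzed=n,
        average_ploidy=metrics.mean_ploidy,
        instability_index=instability_index(len(patterns), n),
        n_patterns=len(patterns),
        n_clonal_patterns=n_clonal,
        clonal_patterns=clones,
        polyploid_fraction=metrics.polyploid_fraction,
        tetra_octo_ratio=metrics.tetra_octo_ratio,
        diversification=diversification_class(n_clonal),
        gene_calls=_gene_calls(reportable, panel),
        mode=mode,
    )


def export_color_chart(
    cells: pd.DataFrame, panel: ProbePanel, path: str | Path | None = None
) -> pd.DataFrame:
    """Cells x genes gain/loss/neutral matrix, grouped by ploidy class and
    pattern frequency (the tabular form of the color displays)."""
    annotated, _ = annotate_cells(cells, panel)
    patterns = enumerate_patterns(annotated, panel)
    mat = _io.counts_matrix(annotated, panel)
    rows = []
    for i in range(len(annotated)):
        counts_vec = tuple(int(x) for x in mat[i])
        sp = SignalPattern.from_counts(counts_vec, panel)
        row = {
            "cell_id": str(annotated["cell_id"].iloc[i]),
            "ploidy_class": sp.ploidy_class,
            "pattern_n_cells": patterns[counts_vec],
        }
        row.update(sp.coding_labels(panel))
        rows.append(row)
    chart = pd.DataFrame(rows).sort_values(
        ["ploidy_class", "pattern_n_cells", "cell_id"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    chart = chart.reset_index(drop=True)
    if path is not None:
        chart.to_csv(path, sep="\t", index=False)
    return chart
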