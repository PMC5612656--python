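"""Cross-contrast analyses over differential-expression tables.

Chemotype subtraction (removing genes also regulated by an inactive analogue
of the compound, with direction-concordance flags), disease-reversal gene
sets, marker-based flagging of contaminated samples, and summary reporting
of DE tables with the fold-change binning and percentage conventions used
for volcano-plot tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .de import cpm
from .io import CountMatrix


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (the convention of printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage rounded half-away-from-zero to ``ndigits`` decimals."""
    if denominator == 0:
        return 0.0
    return round_half_away(100.0 * numerator / denominator, ndigits)


def fold_change_from_log2(log2fc: float) -> float:
    """Linear fold change implied by a log2 fold change (magnitude only)."""
    return float(2.0 ** abs(log2fc))


def count_from_percentages(percentages, n_detectable: int) -> int:
    """Integer count implied by printed percentages of a detectable total."""
    return int(round_half_away(sum(percentages) / 100.0 * n_detectable, 0))


def _common_universe(a: pd.DataFrame, b: pd.DataFrame) -> pd.Index:
    universe = a.index.intersection(b.index)
    if len(universe) == 0:
        raise ValueError("DE tables share no features: disjoint universes")
    return universe


def subtract_chemotype(
    de_active: pd.DataFrame, de_inactive: pd.DataFrame
) -> tuple[pd.Index, pd.DataFrame]:
    """Separate compound-specific DE genes from chemotype-driven ones.

    ``shared`` holds features DE under both the active compound and its
    inactive analogue, with a concordance flag (same sign of log2fc);
    ``specific`` is the active DE set minus the shared set.  Feature
    universes are intersected first.
    """
    universe = _common_universe(de_active, de_inactive)
    a = de_active.loc[universe]
    b = de_inactive.loc[universe]
    de_a = a.index[a["is_de"]]
    de_b = b.index[b["is_de"]]
    shared_ids = de_a.intersection(de_b)
    shared = pd.DataFrame(
        {
            "log2fc_active": a.loc[shared_ids, "log2fc"],
            "log2fc_inactive": b.loc[shared_ids, "log2fc"],
            "concordant": np.sign(a.loc[shared_ids, "log2fc"])
            == np.sign(b.loc[shared_ids, "log2fc"]),
        }
    )
    specific = de_a.difference(shared_ids)
    return specific, shared


def reversal_set(de_disease: pd.DataFrame, de_treatment: pd.DataFrame) -> pd.Index:
    """Features significantly changed in opposite directions by disease and by
    treatment; a zero log2 fold change never qualifies."""
    universe = _common_universe(de_disease, de_treatment)
    a = de_disease.loc[universe]
    b = de_treatment.loc[universe]
    both = a.index[a["is_de"]].intersection(b.index[b["is_de"]])
    sa = np.sign(a.loc[both, "log2fc"])
    sb = np.sign(b.loc[both, "log2fc"])
    opposite = (sa == -sb) & (sa != 0)
    return both[opposite]


def flag_contaminated_samples(
    matrix: CountMatrix, marker_ids, k_mad: float = 3.0
) -> tuple[list[str], pd.Series]:
    """Flag samples with outlying marker-gene expression.

    The score per sample is the mean log2(CPM+1) over the marker features;
    a sample is flagged iff its score exceeds median + k_mad * MAD (MAD
    scaled by 1.4826).  Flagged samples are reported, never dropped: the
    exclusion decision stays with the analyst.
    """
    if matrix.counts.shape[1] < 4:
        raise ValueError("need at least 4 samples to flag outliers")
    marker_ids = [m for m in marker_ids]
    present = [m for m in marker_ids if m in matrix.counts.index]
    if not present:
        raise ValueError("no marker feature found in the matrix")
    logcpm = np.log2(cpm(matrix).loc[present] + 1.0)
    scores = logcpm.mean(axis=0)
    med = scores.median()
    mad = 1.4826 * (scores - med).abs().median()
    flagged = scores.index[scores > med + k_mad * mad].tolist()
    return flagged, scores.rename("marker_score")


@dataclass
class SummaryReport:
    """Counts and printed-style percentages summarising one DE table.

    Fold-change bins use linear 2-fold and 4-fold boundaries: |log2FC| < 1,
    1 <= |log2FC| <= 2, and > 2.  Percentages are computed from the stated
    integer numerators/denominators and rounded half-away-from-zero to one
    decimal.
    """

    n_detectable: int
    n_de: int
    n_up: int
    n_down: int
    pct_de: float
    pct_up_of_de: float
    n_fc_lt_2fold: int
    n_fc_2_to_4fold: int
    n_fc_gt_4fold: int
    pct_fc_lt_2fold: float
    pct_fc_2_to_4fold: float
    pct_fc_gt_4fold: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SummaryReport":
        return cls(**json.loads(text))


def summarize_de(de_table: pd.DataFrame, n_detectable: int) -> SummaryReport:
    """Summary of a called DE table against the number of detectable features."""
    de = de_table[de_table["is_de"].astype(bool)]
    n_de = len(de)
    if n_detectable < n_de:
        raise ValueError("n_detectable must be >= the number of DE features")
    n_up = int((de["log2fc"] > 0).sum())
    n_down = int((de["log2fc"] < 0).sum())
    abs_fc = de["log2fc"].abs()
    n_lt = int((abs_fc < 1).sum())
    n_gt = int((abs_fc > 2).sum())
    n_mid = n_de - n_lt - n_gt
    return SummaryReport(
        n_detectable=n_detectable,
        n_de=n_de,
        n_up=n_up,
        n_down=n_down,
        pct_de=percentage(n_de, n_detectable),
        pct_up_of_de=percentage(n_up, n_de),
        n_fc_lt_2fold=n_lt,
        n_fc_2_to_4fold=n_mid,
        n_fc_gt_4fold=n_gt,
        pct_fc_lt_2fold=percentage(n_lt, n_de),
        pct_fc_2_to_4fold=percentage(n_mid, n_de),
        pct_fc_gt_4fold=percentage(n_gt, n_de),
    )
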