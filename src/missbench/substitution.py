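"""20x20 ordered-pair mean-score matrices and their analytics.

Each cell (ref, alt) holds the unweighted arithmetic mean of the scores of
all matching substitution records, together with the record count; cells
without records are undefined.  The matrix can be restricted to
SNV-reachable pairs.  On top of it sit three analyses: directional
asymmetries (pairs whose forward and reverse means differ by at least a
delta), label flips (forward pathogenic, reverse benign, by the three-class
bands), and the correlation of pair means with BLOSUM62.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from scipy import stats

from .genetic_code import AA20, is_snv_reachable
from .io import ScoreRecord, ScoreClass
from .metrics import DEFAULT_SCHEME, ThresholdScheme, classify_score

BLOSUM62 = substitution_matrices.load("BLOSUM62")

RESTRICTIONS = ("all", "snv_only")


def blosum62_score(a: str, b: str) -> float:
    """BLOSUM62 log-odds score of the unordered pair (a, b)."""
    return float(BLOSUM62[a][b])


@dataclass
class SubstitutionScoreMatrix:
    """Ordered-pair mean scores (NaN = undefined) with per-cell counts."""

    means: pd.DataFrame  # 20x20 float, rows=ref, cols=alt
    counts: pd.DataFrame  # 20x20 int
    restriction: str = "all"

    def mean(self, ref: str, alt: str) -> float | None:
        value = self.means.at[ref, alt]
        return None if pd.isna(value) else float(value)

    def count(self, ref: str, alt: str) -> int:
        return int(self.counts.at[ref, alt])

    def defined_cells(self) -> list[tuple[str, str, float, int]]:
        cells = []
        for ref in AA20:
            for alt in AA20:
                if ref == alt:
                    continue
                m = self.mean(ref, alt)
                if m is not None:
                    cells.append((ref, alt, m, self.count(ref, alt)))
        return cells

    def to_tsv(self, path: str | Path) -> None:
        """Write the 20x20 mean matrix (row=ref, col=alt, empty=undefined)."""
        out = self.means.copy()
        out.index.name = "ref"
        out.to_csv(path, sep="\t", float_format="%.6g", na_rep="")


def mean_substitution_matrix(
    records: Iterable[ScoreRecord], restriction: str = "all"
) -> SubstitutionScoreMatrix:
    """Average scores per ordered (ref, alt) pair.

    With ``snv_only``, records whose substitution is not reachable by a
    single nucleotide change are excluded before averaging.
    """
    if restriction not in RESTRICTIONS:
        raise ValueError(f"unknown restriction {restriction!r}")
    sums = pd.DataFrame(0.0, index=list(AA20), columns=list(AA20))
    counts = pd.DataFrame(0, index=list(AA20), columns=list(AA20))
    for rec in records:
        if restriction == "snv_only" and not is_snv_reachable(
            rec.ref_aa, rec.alt_aa
        ):
            continue
        sums.at[rec.ref_aa, rec.alt_aa] += rec.score
        counts.at[rec.ref_aa, rec.alt_aa] += 1
    with np.errstate(invalid="ignore"):
        means = sums / counts.replace(0, np.nan)
    return SubstitutionScoreMatrix(means=means, counts=counts, restriction=restriction)


@dataclass(frozen=True)
class AsymmetricPair:
    """An unordered pair whose two directional means differ.

    ``ref``/``alt`` give the higher-mean direction, so the report is stable
    under the arbitrary orientation of the input.
    """

    ref: str
    alt: str
    forward_mean: float
    reverse_mean: float

    @property
    def delta(self) -> float:
        return self.forward_mean - self.reverse_mean


def asymmetric_pairs(
    matrix: SubstitutionScoreMatrix, min_delta: float = 0.2
) -> list[AsymmetricPair]:
    """Unordered pairs with |mean(a->b) - mean(b->a)| >= min_delta (inclusive),
    both directions defined, sorted by delta descending."""
    out = []
    for i, a in enumerate(AA20):
        for b in AA20[i + 1 :]:
            m_ab, m_ba = matrix.mean(a, b), matrix.mean(b, a)
            if m_ab is None or m_ba is None:
                continue
            if abs(m_ab - m_ba) >= min_delta:
                if m_ab >= m_ba:
                    out.append(AsymmetricPair(a, b, m_ab, m_ba))
                else:
                    out.append(AsymmetricPair(b, a, m_ba, m_ab))
    out.sort(key=lambda p: (-p.delta, p.ref, p.alt))
    return out


@dataclass(frozen=True)
class FlipPair:
    """A pair classified pathogenic in one direction and benign in the other.

    ``ref``/``alt`` is the pathogenic direction.
    """

    ref: str
    alt: str
    forward_mean: float
    reverse_mean: float


def label_flip_pairs(
    matrix: SubstitutionScoreMatrix,
    scheme: ThresholdScheme = DEFAULT_SCHEME,
) -> list[FlipPair]:
    """Pairs whose mean-score classes flip between directions.

    An ambiguous class on either side is not a flip.
    """
    out = []
    for i, a in enumerate(AA20):
        for b in AA20[i + 1 :]:
            m_ab, m_ba = matrix.mean(a, b), matrix.mean(b, a)
            if m_ab is None or m_ba is None:
                continue
            c_ab = classify_score(m_ab, scheme)
            c_ba = classify_score(m_ba, scheme)
            if (
                c_ab is ScoreClass.LIKELY_PATHOGENIC
                and c_ba is ScoreClass.LIKELY_BENIGN
            ):
                out.append(FlipPair(a, b, m_ab, m_ba))
            elif (
                c_ba is ScoreClass.LIKELY_PATHOGENIC
                and c_ab is ScoreClass.LIKELY_BENIGN
            ):
                out.append(FlipPair(b, a, m_ba, m_ab))
    out.sort(key=lambda p: (p.ref, p.alt))
    return out


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    slope: float
    intercept: float
    n_points: int


def blosum_correlation(matrix: SubstitutionScoreMatrix) -> CorrelationResult:
    """Pearson correlation and OLS line of per-ordered-pair mean scores
    against the BLOSUM62 score of the (unordered) pair.

    Both directions of each pair enter as separate points sharing one
    BLOSUM62 value; identity pairs are excluded.  The p-value is the
    standard two-sided t test on r.
    """
    cells = matrix.defined_cells()
    if len(cells) < 3:
        raise ValueError(
            f"need at least 3 defined cells for a correlation, got {len(cells)}"
        )
    x = np.array([blosum62_score(ref, alt) for ref, alt, _, _ in cells])
    y = np.array([mean for _, _, mean, _ in cells])
    fit = stats.linregress(x, y)
    return CorrelationResult(
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_points=len(cells),
    )


def write_pair_report(
    asym: list[AsymmetricPair],
    flips: list[FlipPair],
    path: str | Path,
) -> None:
    """Asymmetry and flip lists as one TSV (flip column marks flipped pairs)."""
    flipped = {(f.ref, f.alt) for f in flips} | {(f.alt, f.ref) for f in flips}
    lines = ["ref\talt\tforward_mean\treverse_mean\tdelta\tlabel_flip"]
    for p in asym:
        mark = "yes" if (p.ref, p.alt) in flipped else "no"
        lines.append(
            f"{p.ref}\t{p.alt}\t{p.forward_mean:.6g}\t{p.reverse_mean:.6g}\t"
            f"{p.delta:.6g}\t{mark}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
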