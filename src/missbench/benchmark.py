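"""Joining scores with clinical labels and producing benchmark report rows.

The pipeline applies restrictions in a fixed order — protein-set membership,
then region subset (inside or outside a region type, residue-level), then
confidence filter (drop residues with pLDDT below a cutoff) — joins the
surviving scores with clinical variants on (accession, position, ref, alt),
and reduces the joined subset to one report row of confusion metrics, aucROC
and length-normalized mutation frequencies.

Accounting is explicit: unmatched clinical variants, reference-residue
mismatches, unannotated accessions and residues without confidence data are
counted, never silently discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import genetic_code
from .io import (
    ClinicalLabel,
    ClinicalVariant,
    ProteinMeta,
    ProteinSet,
    RegionAnnotation,
    ResidueConfidence,
    ScoreClass,
    ScoreRecord,
    confidence_lookup,
)
from .metrics import (
    AmbiguousPolicy,
    DEFAULT_SCHEME,
    MetricsReport,
    ThresholdScheme,
    auc_roc,
    build_confusion,
    classify_score,
    compute_metrics,
)


@dataclass(frozen=True)
class JoinedVariant:
    """A scored substitution carrying its clinical label."""

    protein_acc: str
    position: int
    ref_aa: str
    alt_aa: str
    score: float
    class_label: ScoreClass | None
    label: ClinicalLabel
    stars: int


@dataclass
class JoinReport:
    n_joined: int = 0
    n_unmatched_clinical: int = 0
    n_ref_mismatch: int = 0


def join_scores_labels(
    scores: Iterable[ScoreRecord],
    clinical: Iterable[ClinicalVariant],
) -> tuple[list[JoinedVariant], JoinReport]:
    """Inner join on (accession, position, ref, alt).

    Clinical variants with no score are counted as unmatched; matches on
    (accession, position, alt) whose reference residue disagrees between the
    two sides are rejected and counted separately.
    """
    by_key: dict[tuple[str, int, str], ScoreRecord] = {
        (s.protein_acc, s.position, s.alt_aa): s for s in scores
    }
    joined: list[JoinedVariant] = []
    report = JoinReport()
    for var in clinical:
        rec = by_key.get((var.protein_acc, var.position, var.alt_aa))
        if rec is None:
            report.n_unmatched_clinical += 1
            continue
        if rec.ref_aa != var.ref_aa:
            report.n_ref_mismatch += 1
            continue
        joined.append(
            JoinedVariant(
                protein_acc=var.protein_acc,
                position=var.position,
                ref_aa=var.ref_aa,
                alt_aa=var.alt_aa,
                score=rec.score,
                class_label=rec.class_label,
                label=var.label,
                stars=var.stars,
            )
        )
    report.n_joined = len(joined)
    return joined, report


@dataclass
class SubsetReport:
    n_kept: int = 0
    n_dropped: int = 0
    n_dropped_unannotated: int = 0


def _region_positions(
    regions: Iterable[RegionAnnotation], region_type: str | None
) -> dict[str, set[int]]:
    by_acc: dict[str, set[int]] = {}
    for r in regions:
        if region_type is not None and r.region_type != region_type:
            continue
        by_acc.setdefault(r.protein_acc, set()).update(r.positions())
    return by_acc


def subset_residues(
    items: Sequence,
    regions: Iterable[RegionAnnotation],
    mode: str = "inside",
    region_type: str | None = None,
):
    """Keep items whose residue lies inside (or outside) regions of a type.

    Region boundaries are inclusive.  Accessions without any region
    annotation of the requested type are dropped under *both* modes (they
    belong to neither the inside nor the complement subset) and counted.
    """
    if mode not in ("inside", "outside"):
        raise ValueError(f"mode must be 'inside' or 'outside', got {mode!r}")
    by_acc = _region_positions(regions, region_type)
    kept = []
    report = SubsetReport()
    for item in items:
        positions = by_acc.get(item.protein_acc)
        if positions is None:
            report.n_dropped_unannotated += 1
            continue
        inside = item.position in positions
        if inside == (mode == "inside"):
            kept.append(item)
        else:
            report.n_dropped += 1
    report.n_kept = len(kept)
    return kept, report


@dataclass
class ConfidenceFilterReport:
    n_kept: int = 0
    n_below_cutoff: int = 0
    n_missing: int = 0


def filter_by_confidence(
    items: Sequence,
    confidence: Iterable[ResidueConfidence] | Mapping[tuple[str, int], float],
    cutoff: float = 50.0,
):
    """Keep items whose residue has pLDDT >= cutoff (strictly-below excluded).

    Residues lacking confidence data are dropped and counted.
    """
    lookup = (
        dict(confidence)
        if isinstance(confidence, Mapping)
        else confidence_lookup(confidence)
    )
    kept = []
    report = ConfidenceFilterReport()
    for item in items:
        plddt = lookup.get((item.protein_acc, item.position))
        if plddt is None:
            report.n_missing += 1
        elif plddt < cutoff:
            report.n_below_cutoff += 1
        else:
            kept.append(item)
    report.n_kept = len(kept)
    return kept, report


@dataclass(frozen=True)
class Frequencies:
    """Counts per residue of protein length, clinical (CV) and predicted (AM)."""

    f_cv_benign: float
    f_cv_pathogenic: float
    f_am_benign: float
    f_am_pathogenic: float


def mutation_frequencies(
    clinical: Iterable[ClinicalVariant],
    scores: Iterable[ScoreRecord],
    metas: Iterable[ProteinMeta],
    scheme: ThresholdScheme = DEFAULT_SCHEME,
    snv_restrict: bool = False,
) -> Frequencies:
    """Length-normalized mutation counts.

    Each frequency is a count divided by the summed length of the proteins in
    `metas`.  Predicted (AM) counts use the three-way class: ambiguous
    predictions contribute to neither side.  With `snv_restrict`, predicted
    counts include only SNV-reachable substitutions (clinical variants come
    from SNV data by construction and are never restricted).
    """
    metas = list(metas)
    lengths = {m.protein_acc: m.length for m in metas}
    total_len = sum(lengths.values())

    def _check(acc: str) -> None:
        if acc not in lengths:
            raise ValueError(f"no protein length available for accession {acc!r}")

    cv_benign = cv_pathogenic = 0
    for var in clinical:
        _check(var.protein_acc)
        if var.label is ClinicalLabel.BENIGN:
            cv_benign += 1
        else:
            cv_pathogenic += 1

    am_benign = am_pathogenic = 0
    for rec in scores:
        _check(rec.protein_acc)
        if snv_restrict and not genetic_code.is_snv_reachable(
            rec.ref_aa, rec.alt_aa
        ):
            continue
        cls = classify_score(rec.score, scheme)
        if cls is ScoreClass.LIKELY_BENIGN:
            am_benign += 1
        elif cls is ScoreClass.LIKELY_PATHOGENIC:
            am_pathogenic += 1

    if total_len == 0:
        return Frequencies(0.0, 0.0, 0.0, 0.0)
    return Frequencies(
        cv_benign / total_len,
        cv_pathogenic / total_len,
        am_benign / total_len,
        am_pathogenic / total_len,
    )


def benchmark_protein_set(
    protein_set: ProteinSet,
    scores: Sequence[ScoreRecord],
    clinical: Sequence[ClinicalVariant],
    metas: Sequence[ProteinMeta],
    regions: Sequence[RegionAnnotation] | None = None,
    region_type: str | None = None,
    region_mode: str = "inside",
    confidence: Sequence[ResidueConfidence] | None = None,
    plddt_min: float = 50.0,
    scheme: ThresholdScheme = DEFAULT_SCHEME,
    policy: AmbiguousPolicy = AmbiguousPolicy.AS_ERROR,
    snv_restrict: bool = False,
) -> MetricsReport:
    """Produce one benchmark report row for a protein set.

    Restrictions are applied in the fixed order set -> region -> confidence,
    then scores and clinical labels are joined.  Empty joined subsets yield a
    degenerate-flagged report rather than an exception.  The frequency
    denominator is the summed length of set proteins contributing at least
    one joined variant (the same accessions ``n_protein`` counts).
    """
    members = set(protein_set.accessions)
    set_scores = [s for s in scores if s.protein_acc in members]
    set_clinical = [c for c in clinical if c.protein_acc in members]

    if regions is not None:
        set_scores, _ = subset_residues(set_scores, regions, region_mode, region_type)
        set_clinical, _ = subset_residues(
            set_clinical, regions, region_mode, region_type
        )
    if confidence is not None:
        lookup = confidence_lookup(confidence)
        set_scores, _ = filter_by_confidence(set_scores, lookup, plddt_min)
        set_clinical, _ = filter_by_confidence(set_clinical, lookup, plddt_min)

    joined, _ = join_scores_labels(set_scores, set_clinical)
    contributing = sorted({j.protein_acc for j in joined})

    degenerate: set[str] = set()
    pairs = [(j.label, classify_score(j.score, scheme)) for j in joined]
    ct = build_confusion(pairs, policy)
    values = compute_metrics(ct)
    degenerate |= values.degenerate

    labels = {j.label for j in joined}
    if len(labels) == 2:
        auc = auc_roc([j.score for j in joined], [j.label for j in joined])
    else:
        auc = 0.0
        degenerate.add("auc_roc")

    contributing_set = set(contributing)
    freq_metas = [m for m in metas if m.protein_acc in contributing_set]
    freqs = mutation_frequencies(
        [c for c in set_clinical if c.protein_acc in contributing_set],
        [s for s in set_scores if s.protein_acc in contributing_set],
        freq_metas,
        scheme=scheme,
        snv_restrict=snv_restrict,
    )

    return MetricsReport(
        set_name=protein_set.name,
        n_proteins=len(contributing),
        n_mutations=len(joined),
        n_evaluated=ct.n_evaluated,
        ppv=values.ppv,
        tpr=values.tpr,
        f1=values.f1,
        auc_roc=auc,
        mcc=values.mcc,
        f_cv_benign=freqs.f_cv_benign,
        f_cv_pathogenic=freqs.f_cv_pathogenic,
        f_am_benign=freqs.f_am_benign,
        f_am_pathogenic=freqs.f_am_pathogenic,
        degenerate=frozenset(degenerate),
    )


def write_report_tsv(reports: Iterable[MetricsReport], path: str | Path) -> None:
    """Write benchmark rows as TSV in the fixed report column order."""
    lines = ["\t".join(MetricsReport.COLUMNS)]
    for report in reports:
        lines.append("\t".join(report.to_row()))
    Path(path).write_text("\n".join(lines) + "\n")
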