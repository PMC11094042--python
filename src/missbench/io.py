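"""Domain types and tabular readers/writers.

Conventions used throughout the package:

* residue positions are 1-based, matching protein-variant notation (F508C);
* amino acids are upper-case one-letter codes over the 20 standard residues;
* pathogenicity scores live in [0, 1], higher = more likely pathogenic;
* clinical labels are binary (benign / pathogenic) with a ClinVar-style
  review-star count attached.

Score tables are accepted in three tab-separated dialects: the package's own
``canonical`` 6-column layout, and the two public per-variant layouts
(``hg38`` with genomic columns which are carried but never interpreted, and
``aa_substitutions``).  Clinical tables are accepted in a canonical layout or
a ClinVar-export-like layout (protein change + significance + review status).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
from Bio import SeqIO

from .genetic_code import AA_SET

log = logging.getLogger("missbench")


class ScoreClass(str, Enum):
    """Three-way predicted class attached to a score."""

    LIKELY_BENIGN = "likely_benign"
    AMBIGUOUS = "ambiguous"
    LIKELY_PATHOGENIC = "likely_pathogenic"


class ClinicalLabel(str, Enum):
    """Binary clinical interpretation of a variant."""

    BENIGN = "benign"
    PATHOGENIC = "pathogenic"


_VARIANT_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


def parse_protein_variant(token: str) -> tuple[str, int, str]:
    """Decompose a substitution token like ``F508C`` into (ref, position, alt).

    Raises ``ValueError`` naming the token on malformed input, non-standard
    letters, position 0, or identity substitutions.
    """
    m = _VARIANT_RE.match(token.strip())
    if m is None:
        raise ValueError(f"malformed protein variant token {token!r}")
    ref, pos, alt = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    if ref not in AA_SET or alt not in AA_SET:
        raise ValueError(f"non-standard amino acid in variant token {token!r}")
    if pos < 1:
        raise ValueError(f"position must be >= 1 in variant token {token!r}")
    if ref == alt:
        raise ValueError(f"identity substitution in variant token {token!r}")
    return ref, pos, alt


def format_protein_variant(ref_aa: str, position: int, alt_aa: str) -> str:
    return f"{ref_aa}{position}{alt_aa}"


@dataclass(frozen=True)
class ScoreRecord:
    """One predicted substitution with its pathogenicity score."""

    protein_acc: str
    position: int
    ref_aa: str
    alt_aa: str
    score: float
    class_label: ScoreClass | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_aa not in AA_SET:
            raise ValueError(f"invalid ref_aa {self.ref_aa!r}")
        if self.alt_aa not in AA_SET:
            raise ValueError(f"invalid alt_aa {self.alt_aa!r}")
        if self.ref_aa == self.alt_aa:
            raise ValueError(
                f"identity substitution {self.ref_aa}{self.position}{self.alt_aa}"
            )
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.protein_acc, self.position, self.ref_aa, self.alt_aa)


@dataclass(frozen=True)
class ClinicalVariant:
    """One clinically labeled substitution with a review-star count."""

    protein_acc: str
    position: int
    ref_aa: str
    alt_aa: str
    label: ClinicalLabel
    stars: int = 0

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_aa not in AA_SET or self.alt_aa not in AA_SET:
            raise ValueError(f"invalid amino acid in {self!r}")
        if self.ref_aa == self.alt_aa:
            raise ValueError(f"identity substitution in {self!r}")
        if self.stars < 0:
            raise ValueError("stars must be >= 0")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.protein_acc, self.position, self.ref_aa, self.alt_aa)


@dataclass(frozen=True)
class ProteinMeta:
    """Protein length (frequency denominator) and optional sequence."""

    protein_acc: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"length must be > 0 for {self.protein_acc}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != declared length "
                f"{self.length} for {self.protein_acc}"
            )


def parse_selection(text: str) -> list[int]:
    """Parse a residue selection like ``"34-58"`` or ``"12,15,19"`` or
    ``"461-472,1346-1362"`` into a sorted, de-duplicated 1-based position list."""
    positions: set[int] = set()
    for part in str(text).split(","):
        part = part.strip()
        if not part:
            continue
        if "-" in part:
            lo_s, hi_s = part.split("-", 1)
            lo, hi = int(lo_s), int(hi_s)
            if lo < 1 or lo > hi:
                raise ValueError(f"invalid range {part!r} in selection {text!r}")
            positions.update(range(lo, hi + 1))
        else:
            p = int(part)
            if p < 1:
                raise ValueError(f"invalid position {part!r} in selection {text!r}")
            positions.add(p)
    if not positions:
        raise ValueError(f"empty selection {text!r}")
    return sorted(positions)


@dataclass(frozen=True)
class RegionAnnotation:
    """A residue region of a protein (range or explicit list) with a type label."""

    protein_acc: str
    selection: str
    region_type: str

    def positions(self) -> list[int]:
        return parse_selection(self.selection)


@dataclass(frozen=True)
class ResidueConfidence:
    """Per-residue model confidence (pLDDT, 0-100)."""

    protein_acc: str
    position: int
    plddt: float

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if not 0.0 <= self.plddt <= 100.0:
            raise ValueError(
                f"pLDDT {self.plddt} outside [0, 100] at "
                f"{self.protein_acc} position {self.position}"
            )


@dataclass(frozen=True)
class ProteinSet:
    """A named list of unique protein accessions."""

    name: str
    accessions: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.accessions)) != len(self.accessions):
            dupes = sorted(
                {a for a in self.accessions if self.accessions.count(a) > 1}
            )
            raise ValueError(f"duplicate accessions in set {self.name!r}: {dupes}")

    def __contains__(self, acc: str) -> bool:
        return acc in set(self.accessions)


# ---------------------------------------------------------------------------
# score tables


_CLASS_ALIASES: dict[str, ScoreClass | None] = {
    "likely_benign": ScoreClass.LIKELY_BENIGN,
    "benign": ScoreClass.LIKELY_BENIGN,
    "ambiguous": ScoreClass.AMBIGUOUS,
    "likely_pathogenic": ScoreClass.LIKELY_PATHOGENIC,
    "pathogenic": ScoreClass.LIKELY_PATHOGENIC,
    "": None,
    ".": None,
    "na": None,
}

SCORE_DIALECTS = ("canonical", "hg38", "aa_substitutions")


def _read_table_lines(path: str | Path, header_hint: set[str]):
    """Split a TSV into (header, rows, line numbers), tolerating '#' comments.

    A comment line doubles as the header when its fields contain the
    dialect's required columns (the public per-variant tables start their
    header with ``#CHROM``).
    """
    header: list[str] | None = None
    rows: list[list[str]] = []
    linenos: list[int] = []
    for lineno, line in enumerate(
        Path(path).read_text().splitlines(), start=1
    ):
        if not line.strip():
            continue
        if line.startswith("#"):
            fields = line.lstrip("#").split("\t")
            if header is None and header_hint & {f.strip() for f in fields}:
                header = [f.strip() for f in fields]
            continue
        if header is None:
            header = [f.strip() for f in line.split("\t")]
            continue
        rows.append(line.split("\t"))
        linenos.append(lineno)
    if header is None:
        raise ValueError(f"no header line found in {path}")
    return header, rows, linenos


def _column_index(header: Sequence[str], name: str, path) -> int:
    lowered = [h.lower() for h in header]
    if name.lower() not in lowered:
        raise ValueError(f"missing required column {name!r} in {path}")
    return lowered.index(name.lower())


def read_score_table(
    path: str | Path, dialect: str = "canonical"
) -> list[ScoreRecord]:
    """Read a per-substitution score table in one of the supported dialects.

    ``hg38`` rows carry genomic columns; they are accepted and ignored.
    Scores outside [0, 1] and unknown class strings fail with the offending
    line number.
    """
    if dialect not in SCORE_DIALECTS:
        raise ValueError(f"unknown score-table dialect {dialect!r}")
    if dialect == "canonical":
        hint = {"protein_acc"}
    else:
        hint = {"uniprot_id", "am_pathogenicity"}
    header, rows, linenos = _read_table_lines(path, hint)

    records: list[ScoreRecord] = []
    if dialect == "canonical":
        i_acc = _column_index(header, "protein_acc", path)
        i_pos = _column_index(header, "position", path)
        i_ref = _column_index(header, "ref_aa", path)
        i_alt = _column_index(header, "alt_aa", path)
        i_score = _column_index(header, "score", path)
        i_cls = (
            [h.lower() for h in header].index("class")
            if "class" in [h.lower() for h in header]
            else None
        )
    else:
        i_acc = _column_index(header, "uniprot_id", path)
        i_var = _column_index(header, "protein_variant", path)
        i_score = _column_index(header, "am_pathogenicity", path)
        i_cls = (
            [h.lower() for h in header].index("am_class")
            if "am_class" in [h.lower() for h in header]
            else None
        )

    for row, lineno in zip(rows, linenos):
        try:
            if dialect == "canonical":
                acc = row[i_acc].strip()
                pos = int(row[i_pos])
                ref, alt = row[i_ref].strip().upper(), row[i_alt].strip().upper()
            else:
                acc = row[i_acc].strip()
                ref, pos, alt = parse_protein_variant(row[i_var])
            score = float(row[i_score])
            cls: ScoreClass | None = None
            if i_cls is not None and i_cls < len(row):
                raw = row[i_cls].strip().lower()
                if raw not in _CLASS_ALIASES:
                    raise ValueError(f"unknown class string {row[i_cls]!r}")
                cls = _CLASS_ALIASES[raw]
            records.append(
                ScoreRecord(
                    protein_acc=acc,
                    position=pos,
                    ref_aa=ref,
                    alt_aa=alt,
                    score=score,
                    class_label=cls,
                )
            )
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path} line {lineno}: {exc}") from exc
    return records


def write_score_table(records: Iterable[ScoreRecord], path: str | Path) -> None:
    """Write records in the canonical 6-column TSV (lossless round trip)."""
    lines = ["protein_acc\tposition\tref_aa\talt_aa\tscore\tclass"]
    for r in records:
        cls = r.class_label.value if r.class_label is not None else ""
        lines.append(
            f"{r.protein_acc}\t{r.position}\t{r.ref_aa}\t{r.alt_aa}\t{r.score!r}\t{cls}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# clinical tables

#: Review-status text -> star count, standard ClinVar convention.
REVIEW_STATUS_STARS: dict[str, int] = {
    "practice guideline": 4,
    "reviewed by expert panel": 3,
    "criteria provided, multiple submitters, no conflicts": 2,
    "criteria provided, multiple submitters": 2,
    "criteria provided, single submitter": 1,
    "criteria provided, conflicting interpretations": 1,
    "criteria provided, conflicting classifications": 1,
    "no assertion criteria provided": 0,
    "no assertion provided": 0,
    "no classification provided": 0,
    "no classification for the single variant": 0,
    "no classifications from unflagged records": 0,
}

#: Significance text -> binary label; "likely" calls are merged into the
#: plain labels by default.  Anything absent is dropped and counted.
DEFAULT_LABEL_MAP: dict[str, ClinicalLabel] = {
    "benign": ClinicalLabel.BENIGN,
    "likely benign": ClinicalLabel.BENIGN,
    "benign/likely benign": ClinicalLabel.BENIGN,
    "pathogenic": ClinicalLabel.PATHOGENIC,
    "likely pathogenic": ClinicalLabel.PATHOGENIC,
    "pathogenic/likely pathogenic": ClinicalLabel.PATHOGENIC,
}


@dataclass
class ClinicalReadReport:
    """Accounting of a clinical-table read; nothing is dropped silently."""

    n_rows: int = 0
    n_candidates: int = 0
    kept: int = 0
    dropped_by_label: dict[str, int] = field(default_factory=dict)
    dropped_by_stars: int = 0
    dropped_unparsable: int = 0
    n_deduplicated: int = 0

    @property
    def n_dropped_by_label(self) -> int:
        return sum(self.dropped_by_label.values())


def _stars_from_review_status(
    text: str, star_map: Mapping[str, int]
) -> int | None:
    key = text.split("(")[0].strip().lower()
    if key in star_map:
        return star_map[key]
    for known, stars in star_map.items():
        if key.startswith(known):
            return stars
    return None


def read_clinical_table(
    path: str | Path,
    min_stars: int = 1,
    label_map: Mapping[str, ClinicalLabel] | None = None,
    star_map: Mapping[str, int] | None = None,
) -> tuple[list[ClinicalVariant], ClinicalReadReport]:
    """Read clinically labeled variants, keeping rows with >= `min_stars` stars.

    Accepts the canonical layout (protein_acc, position, ref_aa, alt_aa,
    label, stars) or an export-like layout (accession, protein change,
    clinical significance, review status).  Unmappable significance strings
    are dropped and counted; duplicate (acc, pos, ref, alt) keys are
    deduplicated keeping the highest star count.
    """
    label_map = dict(DEFAULT_LABEL_MAP if label_map is None else label_map)
    star_map = dict(REVIEW_STATUS_STARS if star_map is None else star_map)
    header, rows, linenos = _read_table_lines(path, {"protein_acc"})
    lowered = [h.lower() for h in header]
    report = ClinicalReadReport(n_rows=len(rows))

    canonical = {"protein_acc", "position", "ref_aa", "alt_aa", "label", "stars"} <= set(
        lowered
    )
    candidates: list[ClinicalVariant | None] = []
    raw_labels: list[str] = []

    if canonical:
        idx = {name: lowered.index(name) for name in
               ("protein_acc", "position", "ref_aa", "alt_aa", "label", "stars")}
        for row, lineno in zip(rows, linenos):
            report.n_candidates += 1
            raw = row[idx["label"]].strip().lower()
            if raw not in label_map:
                report.dropped_by_label[raw] = report.dropped_by_label.get(raw, 0) + 1
                continue
            try:
                var = ClinicalVariant(
                    protein_acc=row[idx["protein_acc"]].strip(),
                    position=int(row[idx["position"]]),
                    ref_aa=row[idx["ref_aa"]].strip().upper(),
                    alt_aa=row[idx["alt_aa"]].strip().upper(),
                    label=label_map[raw],
                    stars=int(row[idx["stars"]]),
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path} line {lineno}: {exc}") from exc
            candidates.append(var)
    else:
        acc_col = next(
            (c for c in ("protein_acc", "uniprot", "uniprot_acc", "uniprot_id",
                         "accession") if c in lowered),
            None,
        )
        change_col = next(
            (i for i, h in enumerate(lowered) if h.startswith("protein change")), None
        )
        sig_col = next(
            (i for i, h in enumerate(lowered)
             if h.startswith("clinical significance")
             or h.startswith("germline classification")),
            None,
        )
        rev_col = next(
            (i for i, h in enumerate(lowered) if h.startswith("review status")), None
        )
        missing = [
            name
            for name, col in (
                ("protein_acc", acc_col),
                ("protein change", change_col),
                ("clinical significance", sig_col),
                ("review status", rev_col),
            )
            if col is None
        ]
        if missing:
            raise ValueError(f"{path}: unmappable mandatory column(s) {missing}")
        i_acc = lowered.index(acc_col)

        for row, lineno in zip(rows, linenos):
            acc = row[i_acc].strip()
            stars = _stars_from_review_status(row[rev_col], star_map)
            if stars is None:
                log.warning(
                    "%s line %d: unknown review status %r mapped to 0 stars",
                    path, lineno, row[rev_col],
                )
                stars = 0
            raw = row[sig_col].split("(")[0].strip().lower()
            tokens = [t.strip() for t in row[change_col].split(",") if t.strip()]
            if not tokens:
                report.n_candidates += 1
                report.dropped_unparsable += 1
                continue
            for token in tokens:
                report.n_candidates += 1
                try:
                    ref, pos, alt = parse_protein_variant(token)
                except ValueError:
                    report.dropped_unparsable += 1
                    continue
                if raw not in label_map:
                    report.dropped_by_label[raw] = (
                        report.dropped_by_label.get(raw, 0) + 1
                    )
                    continue
                candidates.append(
                    ClinicalVariant(acc, pos, ref, alt, label_map[raw], stars)
                )

    # star filter then dedup keeping the highest-star record
    passing = []
    for var in candidates:
        if var.stars < min_stars:
            report.dropped_by_stars += 1
        else:
            passing.append(var)
    best: dict[tuple, ClinicalVariant] = {}
    for var in passing:
        prev = best.get(var.key)
        if prev is None:
            best[var.key] = var
        else:
            report.n_deduplicated += 1
            if var.stars > prev.stars:
                best[var.key] = var
    kept = list(best.values())
    report.kept = len(kept)
    if report.n_deduplicated:
        log.info("deduplicated %d clinical rows in %s", report.n_deduplicated, path)
    return kept, report


def write_clinical_table(
    variants: Iterable[ClinicalVariant], path: str | Path
) -> None:
    lines = ["protein_acc\tposition\tref_aa\talt_aa\tlabel\tstars"]
    for v in variants:
        lines.append(
            f"{v.protein_acc}\t{v.position}\t{v.ref_aa}\t{v.alt_aa}\t"
            f"{v.label.value}\t{v.stars}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# confidence, regions, sets, lengths


def _looks_like_pdb(path: Path) -> bool:
    if path.suffix.lower() in {".pdb", ".ent"}:
        return True
    try:
        head = path.read_text()[:4000]
    except UnicodeDecodeError:
        return True
    return any(
        line.startswith(("ATOM  ", "HETATM", "HEADER", "CRYST1", "MODEL"))
        for line in head.splitlines()
    )


def read_confidence(
    source: str | Path, protein_acc: str | None = None
) -> list[ResidueConfidence]:
    """Read per-residue confidence from a 3-column TSV or a PDB whose
    B-factor column stores pLDDT (one value per residue, taken at the CA atom).

    Residues without a CA atom are skipped with a log message.
    """
    path = Path(source)
    if not _looks_like_pdb(path):
        header, rows, linenos = _read_table_lines(path, {"protein_acc"})
        i_acc = _column_index(header, "protein_acc", path)
        i_pos = _column_index(header, "position", path)
        i_pl = _column_index(header, "plddt", path)
        out = []
        for row, lineno in zip(rows, linenos):
            try:
                out.append(
                    ResidueConfidence(
                        row[i_acc].strip(), int(row[i_pos]), float(row[i_pl])
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path} line {lineno}: {exc}") from exc
        return out

    if protein_acc is None:
        m = re.match(r"AF-(\w+)-F\d+", path.stem)
        protein_acc = m.group(1) if m else path.stem
    structure = gemmi.read_pdb(str(path))
    out = []
    for chain in structure[0]:
        for residue in chain:
            ca = residue.find_atom("CA", "*")
            if ca is None:
                log.warning(
                    "%s: residue %s %d has no CA atom, skipped",
                    path, residue.name, residue.seqid.num,
                )
                continue
            out.append(
                ResidueConfidence(protein_acc, residue.seqid.num, float(ca.b_iso))
            )
    return out


def write_confidence_table(
    entries: Iterable[ResidueConfidence], path: str | Path
) -> None:
    lines = ["protein_acc\tposition\tplddt"]
    for e in entries:
        lines.append(f"{e.protein_acc}\t{e.position}\t{e.plddt!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def confidence_lookup(
    entries: Iterable[ResidueConfidence],
) -> dict[tuple[str, int], float]:
    return {(e.protein_acc, e.position): e.plddt for e in entries}


def read_region_table(path: str | Path) -> list[RegionAnnotation]:
    """Read region annotations (protein_acc, selection, region_type)."""
    header, rows, linenos = _read_table_lines(path, {"protein_acc"})
    i_acc = _column_index(header, "protein_acc", path)
    i_sel = _column_index(header, "selection", path)
    i_type = _column_index(header, "region_type", path)
    out = []
    for row, lineno in zip(rows, linenos):
        try:
            region = RegionAnnotation(
                row[i_acc].strip(), row[i_sel].strip(), row[i_type].strip()
            )
            region.positions()  # validate eagerly
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path} line {lineno}: {exc}") from exc
        out.append(region)
    return out


def write_region_table(
    regions: Iterable[RegionAnnotation], path: str | Path
) -> None:
    lines = ["protein_acc\tselection\tregion_type"]
    for r in regions:
        lines.append(f"{r.protein_acc}\t{r.selection}\t{r.region_type}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_protein_lengths(path: str | Path) -> list[ProteinMeta]:
    """Read protein lengths from a TSV (protein_acc, length[, sequence]) or,
    when the file starts with '>', from FASTA (lengths derived from sequences)."""
    p = Path(path)
    first = p.read_text()[:1]
    if first == ">":
        return [
            ProteinMeta(rec.id, len(rec.seq), str(rec.seq))
            for rec in SeqIO.parse(str(p), "fasta")
        ]
    header, rows, linenos = _read_table_lines(p, {"protein_acc"})
    i_acc = _column_index(header, "protein_acc", p)
    i_len = _column_index(header, "length", p)
    lowered = [h.lower() for h in header]
    i_seq = lowered.index("sequence") if "sequence" in lowered else None
    out = []
    for row, lineno in zip(rows, linenos):
        try:
            seq = row[i_seq].strip() or None if i_seq is not None and i_seq < len(row) else None
            out.append(ProteinMeta(row[i_acc].strip(), int(row[i_len]), seq))
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{p} line {lineno}: {exc}") from exc
    return out


def write_protein_lengths(metas: Iterable[ProteinMeta], path: str | Path) -> None:
    lines = ["protein_acc\tlength\tsequence"]
    for m in metas:
        lines.append(f"{m.protein_acc}\t{m.length}\t{m.sequence or ''}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_protein_set(path: str | Path, name: str | None = None) -> ProteinSet:
    """Read a protein set: one accession per line, '#' comments allowed."""
    p = Path(path)
    accs = []
    for line in p.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            accs.append(line)
    return ProteinSet(name or p.stem, tuple(accs))
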