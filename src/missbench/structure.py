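"""Per-residue mean-score profiles and their injection into PDB files.

A residue profile averages substitution scores per position in two modes:
``snv`` (only substitutions reachable by a single nucleotide change) and
``all`` (every recorded substitution).  The profile is written into the
fixed-width occupancy (columns 55-60) and B-factor (columns 61-66) fields of
ATOM/HETATM records so structure viewers can color by score; every other
byte of the file is preserved exactly.

Two column layouts are supported: ``snv_both`` puts the SNV mean into both
fields, ``qb`` (the default) puts the SNV mean into the B-factor field and
the all-substitution mean into the occupancy field.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .genetic_code import is_snv_reachable
from .io import ScoreRecord, parse_selection

log = logging.getLogger("missbench")

MODES = ("snv", "all")
LAYOUTS = ("snv_both", "qb")


@dataclass
class ResidueScoreProfile:
    """Per-position mean scores, per mode, for one protein."""

    protein_acc: str
    mean_snv: dict[int, float] = field(default_factory=dict)
    count_snv: dict[int, int] = field(default_factory=dict)
    mean_all: dict[int, float] = field(default_factory=dict)
    count_all: dict[int, int] = field(default_factory=dict)

    def mean(self, position: int, mode: str) -> float | None:
        if mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}")
        table = self.mean_snv if mode == "snv" else self.mean_all
        return table.get(position)

    def count(self, position: int, mode: str) -> int:
        table = self.count_snv if mode == "snv" else self.count_all
        return table.get(position, 0)


def residue_mean_scores(
    records: Sequence[ScoreRecord], mode: str = "all"
) -> ResidueScoreProfile:
    """Arithmetic per-position mean of record scores in one mode.

    All records must share one accession.  Positions with no kept record are
    left undefined (absent from the profile).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    accs = {r.protein_acc for r in records}
    if len(accs) > 1:
        raise ValueError(f"records span multiple accessions: {sorted(accs)}")
    profile = ResidueScoreProfile(protein_acc=next(iter(accs)) if accs else "")
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for rec in records:
        if mode == "snv" and not is_snv_reachable(rec.ref_aa, rec.alt_aa):
            continue
        sums[rec.position] = sums.get(rec.position, 0.0) + rec.score
        counts[rec.position] = counts.get(rec.position, 0) + 1
    means = {pos: sums[pos] / counts[pos] for pos in sums}
    if mode == "snv":
        profile.mean_snv, profile.count_snv = means, counts
    else:
        profile.mean_all, profile.count_all = means, counts
    return profile


def residue_profile(records: Sequence[ScoreRecord]) -> ResidueScoreProfile:
    """Convenience: both modes in one profile (needed for the qb layout)."""
    snv = residue_mean_scores(records, "snv")
    full = residue_mean_scores(records, "all")
    full.mean_snv, full.count_snv = snv.mean_snv, snv.count_snv
    return full


def annotate_structure(
    pdb_text: str, profile: ResidueScoreProfile, layout: str = "qb"
) -> str:
    """Rewrite occupancy and B-factor fields of every ATOM/HETATM line.

    Values are formatted %6.2f into columns 55-60 (occupancy) and 61-66
    (B-factor); residues absent from the profile get 0.00 in both fields and
    are counted in a log message.  All other bytes are unchanged, so the
    operation is idempotent and coordinates round-trip exactly.  Only
    single-model, single-chain files are accepted.
    """
    if layout not in LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}")
    lines = pdb_text.split("\n")
    chains: set[str] = set()
    n_models = 0
    missing: set[int] = set()
    out = []
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("MODEL"):
            n_models += 1
            if n_models > 1:
                raise ValueError("multi-model PDB not supported")
        if not line.startswith(("ATOM  ", "HETATM")):
            out.append(line)
            continue
        if len(line) < 66:
            raise ValueError(f"malformed ATOM record at line {lineno}: too short")
        chains.add(line[21])
        if len(chains) > 1:
            raise ValueError(
                f"multi-chain PDB not supported (second chain at line {lineno})"
            )
        try:
            resseq = int(line[22:26])
        except ValueError as exc:
            raise ValueError(
                f"malformed residue number at line {lineno}: {line[22:26]!r}"
            ) from exc
        mean_snv = profile.mean(resseq, "snv")
        mean_all = profile.mean(resseq, "all")
        if layout == "snv_both":
            occ, bfac = mean_snv, mean_snv
        else:
            occ, bfac = mean_all, mean_snv
        if occ is None or bfac is None:
            missing.add(resseq)
        occ = 0.0 if occ is None else occ
        bfac = 0.0 if bfac is None else bfac
        out.append(f"{line[:54]}{occ:6.2f}{bfac:6.2f}{line[66:]}")
    if missing:
        log.info(
            "annotate_structure: %d residue(s) without profile mean written as 0.00",
            len(missing),
        )
    return "\n".join(out)


def region_mean_score(
    profile: ResidueScoreProfile,
    selection: str | Iterable[int],
    mode: str = "snv",
) -> float:
    """Unweighted mean of per-residue means over the selected positions.

    Positions without a defined mean are ignored; an entirely undefined
    selection is an error.
    """
    positions = (
        parse_selection(selection) if isinstance(selection, str) else sorted(selection)
    )
    values = [m for p in positions if (m := profile.mean(p, mode)) is not None]
    if not values:
        raise ValueError(
            f"no defined {mode} means in selection for {profile.protein_acc}"
        )
    return sum(values) / len(values)
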