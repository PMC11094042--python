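"""Synthetic cohorts with known statistical structure.

The generator emulates the five inputs of the benchmark pipeline — protein
sequences with lengths, substitution score tables, star-rated clinical
labels, transmembrane-like region segments, per-residue confidence profiles
with low-confidence stretches, and toy CA-trace structures — so every stage
is testable without any external download.

The statistical model: a fraction phi of residues is functionally critical;
substitutions at critical residues draw scores from a "pathogenic"
distribution and the rest from a "benign" one (Beta mixtures by default,
bounded like real scores; truncated Gaussians as an alternative because they
admit a closed-form AUC oracle).  Clinical labels equal the ground truth
with probability kappa and are flipped otherwise.  Score coverage per
residue is exactly the set of substitutions reachable by one nucleotide
change from a sampled codon of the reference residue (or all 19 in ``all``
mode).  All randomness flows from one explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm, truncnorm

from .genetic_code import AA20, CODONS_OF, reachable_from_codon
from .io import (
    ClinicalLabel,
    ClinicalVariant,
    ProteinMeta,
    ProteinSet,
    RegionAnnotation,
    ResidueConfidence,
    ScoreRecord,
    write_clinical_table,
    write_confidence_table,
    write_protein_lengths,
    write_region_table,
    write_score_table,
)

AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the synthetic cohort; defaults give a realistic mid-size run.

    ``critical_fraction`` defaults to 0.3, matching the observed share of
    possible missense substitutions that are pathogenic in real predictions.
    """

    n_proteins: int = 24
    length_min: int = 150
    length_max: int = 400
    critical_fraction: float = 0.3
    score_model: str = "beta"  # "beta" | "gaussian"
    benign_alpha: float = 2.0
    benign_beta: float = 8.0
    pathogenic_alpha: float = 8.0
    pathogenic_beta: float = 2.0
    benign_mu: float = 0.2
    pathogenic_mu: float = 0.8
    benign_sigma: float = 0.15
    pathogenic_sigma: float = 0.15
    clinical_rate: float = 0.25
    concordance: float = 0.9  # kappa: P(clinical label == ground truth)
    star_probs: tuple[float, ...] = (0.05, 0.55, 0.25, 0.10, 0.05)
    tm_protein_fraction: float = 0.5
    tm_segment_len_min: int = 19
    tm_segment_len_max: int = 23
    disorder_fraction: float = 0.15
    disorder_len_min: int = 10
    disorder_len_max: int = 40
    coverage: str = "snv"  # "snv" | "all"

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if not 1 <= self.length_min <= self.length_max:
            raise ValueError("require 1 <= length_min <= length_max")
        for name in ("critical_fraction", "clinical_rate", "tm_protein_fraction",
                     "disorder_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.5 <= self.concordance <= 1.0:
            raise ValueError(
                f"concordance must be in [0.5, 1], got {self.concordance}"
            )
        if self.score_model not in ("beta", "gaussian"):
            raise ValueError(f"unknown score_model {self.score_model!r}")
        if self.coverage not in ("snv", "all"):
            raise ValueError(f"unknown coverage {self.coverage!r}")
        if self.score_model == "beta":
            for name in ("benign_alpha", "benign_beta", "pathogenic_alpha",
                         "pathogenic_beta"):
                if getattr(self, name) <= 0:
                    raise ValueError(f"{name} must be > 0")
        else:
            if self.benign_sigma <= 0 or self.pathogenic_sigma <= 0:
                raise ValueError("sigmas must be > 0")
        if len(self.star_probs) != 5 or abs(sum(self.star_probs) - 1.0) > 1e-9:
            raise ValueError("star_probs must be 5 probabilities summing to 1")
        if not 1 <= self.disorder_len_min <= self.disorder_len_max:
            raise ValueError("invalid disorder stretch lengths")
        if not 1 <= self.tm_segment_len_min <= self.tm_segment_len_max:
            raise ValueError("invalid TM segment lengths")


@dataclass
class CohortBundle:
    """Everything one benchmark run consumes, plus the generating truth."""

    seed: int
    config: CohortConfig
    metas: list[ProteinMeta]
    scores: list[ScoreRecord]
    clinical: list[ClinicalVariant]
    regions: list[RegionAnnotation]
    confidence: list[ResidueConfidence]
    structures: dict[str, str]
    critical: dict[str, frozenset[int]]
    protein_set: ProteinSet = field(init=False)

    def __post_init__(self) -> None:
        self.protein_set = ProteinSet(
            "cohort", tuple(m.protein_acc for m in self.metas)
        )

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the canonical TSVs, the set file and the structures."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "scores": outdir / "scores.tsv",
            "clinical": outdir / "clinical.tsv",
            "regions": outdir / "regions.tsv",
            "confidence": outdir / "plddt.tsv",
            "lengths": outdir / "lengths.tsv",
            "set": outdir / "cohort_set.txt",
            "truth": outdir / "critical_residues.tsv",
        }
        write_score_table(self.scores, paths["scores"])
        write_clinical_table(self.clinical, paths["clinical"])
        write_region_table(self.regions, paths["regions"])
        write_confidence_table(self.confidence, paths["confidence"])
        write_protein_lengths(self.metas, paths["lengths"])
        paths["set"].write_text(
            "\n".join(self.protein_set.accessions) + "\n"
        )
        truth = [
            RegionAnnotation(acc, ",".join(map(str, sorted(pos))), "critical_truth")
            for acc, pos in sorted(self.critical.items())
            if pos
        ]
        write_region_table(truth, paths["truth"])
        structdir = outdir / "structures"
        structdir.mkdir(exist_ok=True)
        for acc, text in self.structures.items():
            p = structdir / f"{acc}.pdb"
            p.write_text(text)
            paths[f"structure:{acc}"] = p
        return paths


def expected_auc_gaussian(
    mu_b: float, mu_p: float, sigma_b: float, sigma_p: float
) -> float:
    """Closed-form ROC AUC of two Gaussian score populations:
    Phi((mu_p - mu_b) / sqrt(sigma_b^2 + sigma_p^2))."""
    if sigma_b <= 0 or sigma_p <= 0:
        raise ValueError("sigmas must be > 0")
    return float(norm.cdf((mu_p - mu_b) / np.hypot(sigma_b, sigma_p)))


def _draw_scores(
    rng: np.random.Generator, config: CohortConfig, pathogenic: bool, n: int
) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    if config.score_model == "beta":
        a = config.pathogenic_alpha if pathogenic else config.benign_alpha
        b = config.pathogenic_beta if pathogenic else config.benign_beta
        return rng.beta(a, b, size=n)
    mu = config.pathogenic_mu if pathogenic else config.benign_mu
    sigma = config.pathogenic_sigma if pathogenic else config.benign_sigma
    lo, hi = (0.0 - mu) / sigma, (1.0 - mu) / sigma
    return truncnorm.rvs(lo, hi, loc=mu, scale=sigma, size=n, random_state=rng)


def generate_structure(
    sequence: str, seed: int, plddt: "list[float] | np.ndarray | None" = None
) -> str:
    """A toy single-chain CA-trace PDB: one ATOM per residue on a jittered
    ideal helix, occupancy 1.00, B-factor holding the per-residue pLDDT."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    rng = np.random.default_rng(seed)
    n = len(sequence)
    if plddt is None:
        plddt = rng.uniform(60.0, 95.0, size=n)
    plddt = np.asarray(plddt, dtype=float)
    if plddt.shape != (n,):
        raise ValueError("plddt length must match sequence length")
    theta = np.deg2rad(100.0) * np.arange(n)
    x = 2.3 * np.cos(theta) + rng.normal(0, 0.05, n)
    y = 2.3 * np.sin(theta) + rng.normal(0, 0.05, n)
    z = 1.5 * np.arange(n) + rng.normal(0, 0.05, n)
    lines = []
    for i, aa in enumerate(sequence):
        lines.append(
            f"ATOM  {i + 1:5d}  CA  {AA3[aa]:<3s} A{i + 1:4d}    "
            f"{x[i]:8.3f}{y[i]:8.3f}{z[i]:8.3f}{1.0:6.2f}{plddt[i]:6.2f}"
            f"          {'C':>2s}"
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def _tm_segments(
    rng: np.random.Generator, config: CohortConfig, length: int
) -> list[tuple[int, int]]:
    segments = []
    pos = int(rng.integers(8, 40))
    while True:
        seg_len = int(
            rng.integers(config.tm_segment_len_min, config.tm_segment_len_max + 1)
        )
        if pos + seg_len - 1 > length:
            break
        segments.append((pos, pos + seg_len - 1))
        pos += seg_len + int(rng.integers(40, 90))
    return segments


def _disorder_mask(
    rng: np.random.Generator, config: CohortConfig, length: int
) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    f = config.disorder_fraction
    if f == 0:
        return mask
    mean_len = (config.disorder_len_min + config.disorder_len_max) / 2.0
    # per-step start probability giving an expected disordered fraction f
    p_start = f / (mean_len * (1 - f) + f)
    i = 0
    while i < length:
        if rng.random() < p_start:
            stretch = int(
                rng.integers(config.disorder_len_min, config.disorder_len_max + 1)
            )
            mask[i : i + stretch] = True
            i += stretch
        else:
            i += 1
    return mask


def generate_cohort(config: CohortConfig, seed: int) -> CohortBundle:
    """Deterministically generate a full synthetic cohort from one seed."""
    config.validate()
    rng = np.random.default_rng(seed)

    metas: list[ProteinMeta] = []
    scores: list[ScoreRecord] = []
    clinical: list[ClinicalVariant] = []
    regions: list[RegionAnnotation] = []
    confidence: list[ResidueConfidence] = []
    structures: dict[str, str] = {}
    critical: dict[str, frozenset[int]] = {}

    for p in range(config.n_proteins):
        acc = f"SYN{p:04d}"
        length = int(rng.integers(config.length_min, config.length_max + 1))
        sequence = "".join(rng.choice(list(AA20), size=length))
        metas.append(ProteinMeta(acc, length, sequence))

        crit_mask = rng.random(length) < config.critical_fraction
        critical[acc] = frozenset(np.flatnonzero(crit_mask) + 1)

        # substitution coverage: SNV-reachable alts of one sampled codon per
        # residue, or all 19 alternatives
        alts_per_residue: list[list[str]] = []
        for aa in sequence:
            if config.coverage == "snv":
                codon = rng.choice(CODONS_OF[aa])
                alts_per_residue.append(sorted(reachable_from_codon(codon)))
            else:
                alts_per_residue.append(sorted(set(AA20) - {aa}))

        n_path = sum(
            len(alts) for alts, c in zip(alts_per_residue, crit_mask) if c
        )
        n_ben = sum(
            len(alts) for alts, c in zip(alts_per_residue, crit_mask) if not c
        )
        path_scores = iter(_draw_scores(rng, config, True, n_path))
        ben_scores = iter(_draw_scores(rng, config, False, n_ben))
        for i, (aa, alts) in enumerate(zip(sequence, alts_per_residue)):
            pool = path_scores if crit_mask[i] else ben_scores
            for alt in alts:
                scores.append(
                    ScoreRecord(acc, i + 1, aa, alt, float(next(pool)))
                )

        # clinical sampling: one labeled substitution per selected residue
        sampled = rng.random(length) < config.clinical_rate
        flips = rng.random(length) >= config.concordance
        star_draws = rng.choice(5, size=length, p=config.star_probs)
        for i in np.flatnonzero(sampled):
            alts = alts_per_residue[i]
            if not alts:
                continue
            alt = alts[int(rng.integers(len(alts)))]
            truth_pathogenic = bool(crit_mask[i])
            observed = truth_pathogenic != bool(flips[i])
            clinical.append(
                ClinicalVariant(
                    acc,
                    int(i) + 1,
                    sequence[i],
                    alt,
                    ClinicalLabel.PATHOGENIC if observed else ClinicalLabel.BENIGN,
                    int(star_draws[i]),
                )
            )

        if rng.random() < config.tm_protein_fraction:
            for start, end in _tm_segments(rng, config, length):
                regions.append(RegionAnnotation(acc, f"{start}-{end}", "TM"))

        disordered = _disorder_mask(rng, config, length)
        plddt = np.where(
            disordered,
            rng.uniform(20.0, 49.0, size=length),
            rng.uniform(60.0, 95.0, size=length),
        )
        confidence.extend(
            ResidueConfidence(acc, i + 1, float(plddt[i])) for i in range(length)
        )
        structures[acc] = generate_structure(
            sequence, seed=int(rng.integers(2**31)), plddt=plddt
        )

    return CohortBundle(
        seed=seed,
        config=config,
        metas=metas,
        scores=scores,
        clinical=clinical,
        regions=regions,
        confidence=confidence,
        structures=structures,
        critical=critical,
    )
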