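"""Promoter cis-element scanning and overrepresentation statistics.

Promoters are upstream DNA slices (2 kb by default) written 5'→3' with
position 1 farthest upstream and the last position abutting the start codon.
Motifs are IUPAC patterns; scanning is exact (N in the sequence never
matches), overlapping matches are all reported, and orientation policy
decides whether the reverse complement is scanned too.  Perfect palindromes
are scanned on one strand only — the other strand carries the identical
sites.  Overrepresentation is an exact upper-tail binomial test of the
occurrence count against a per-position expected match probability.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

PALINDROME_PERFECT = "perfect"
PALINDROME_ODD = "odd-center"
PALINDROME_NONE = "none"


def reverse_complement(pattern: str) -> str:
    return pattern.upper().translate(_COMPLEMENT)[::-1]


def is_palindrome(pattern: str) -> str:
    """Classify a DNA pattern: ``perfect`` (equals its reverse complement,
    even length), ``odd-center`` (odd length, all positions except the exact
    center match the reverse complement), else ``none``."""
    p = pattern.upper()
    if any(b not in "ACGT" for b in p):
        raise ValueError(f"palindrome check requires an A/C/G/T pattern: {pattern!r}")
    rc = reverse_complement(p)
    if len(p) % 2 == 0:
        return PALINDROME_PERFECT if p == rc else PALINDROME_NONE
    center = len(p) // 2
    mismatches = [i for i in range(len(p)) if p[i] != rc[i]]
    if mismatches in ([], [center]):
        return PALINDROME_ODD
    return PALINDROME_NONE


@dataclass(frozen=True)
class Motif:
    """An IUPAC DNA pattern with an orientation policy.

    ``single``: forward strand only; ``both-separate``: forward and reverse
    complement scanned and reported as distinct records; ``both-combined``:
    hits of both orientations pooled into one record.
    """

    pattern: str
    name: str = ""
    orientation_policy: str = "single"

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")
        bad = [b for b in self.pattern.upper() if b not in IUPAC]
        if bad:
            raise ValueError(f"invalid IUPAC letters {bad} in motif {self.pattern!r}")
        if self.orientation_policy not in ("single", "both-separate", "both-combined"):
            raise ValueError(f"unknown orientation policy {self.orientation_policy!r}")
        if not self.name:
            object.__setattr__(self, "name", self.pattern.upper())
        object.__setattr__(self, "pattern", self.pattern.upper())

    @property
    def palindrome_class(self) -> str:
        if any(b not in "ACGT" for b in self.pattern):
            return PALINDROME_NONE
        return is_palindrome(self.pattern)


@dataclass(frozen=True)
class MotifHit:
    """One match: gene, 1-based inclusive start on the + strand coordinates,
    and the strand the motif pattern matched on."""

    gene_id: str
    start: int
    strand: str


def load_motifs(path: str | Path | None = None) -> list[Motif]:
    """Load the motif set from YAML (package defaults when no path)."""
    if path is None:
        text = resources.files("symsieve.data").joinpath("motifs.yaml").read_text()
    else:
        text = Path(path).read_text()
    data = yaml.safe_load(text)
    return [
        Motif(pattern=m["pattern"], name=m.get("name", ""),
              orientation_policy=m.get("orientation", "single"))
        for m in data["motifs"]
    ]


def read_promoters(path: str | Path) -> dict[str, str]:
    """Read a promoter FASTA into gene_id → uppercase sequence; promoters
    shorter than the nominal 2 kb are allowed (logged)."""
    promoters: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"{path}: {rec.id}: non-DNA letters {sorted(bad)}")
        promoters[rec.id] = seq
    short = [g for g, s in promoters.items() if len(s) < 2000]
    if short:
        logger.info("%d promoters shorter than 2 kb (scanned at true length)", len(short))
    return promoters


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _pattern_regex(pattern: str) -> re.Pattern:
    # lookahead so overlapping matches are all reported; N in the sequence
    # never matches because the classes list only A/C/G/T
    body = "".join(f"[{IUPAC[b]}]" if len(IUPAC[b]) > 1 else IUPAC[b] for b in pattern)
    return re.compile(f"(?=({body}))")


def _scan_one_strand(sequence: str, pattern: str) -> list[int]:
    rx = _pattern_regex(pattern)
    return [m.start() + 1 for m in rx.finditer(sequence)]


def scan_motif(
    promoters: Mapping[str, str], motif: Motif
) -> tuple[list[MotifHit], dict[str, int]]:
    """Scan all promoters; returns (hits, per-gene counts).

    The orientation policy controls reverse-complement scanning; a perfect
    palindrome is scanned on the + strand only regardless of policy (both
    strands carry identical sites).  Reverse-orientation hits are reported at
    the + strand coordinate of their leftmost base, strand '−'.
    """
    scan_reverse = (
        motif.orientation_policy in ("both-separate", "both-combined")
        and motif.palindrome_class != PALINDROME_PERFECT
    )
    rc = reverse_complement(motif.pattern)
    hits: list[MotifHit] = []
    counts: dict[str, int] = {}
    for gene, seq in promoters.items():
        n = 0
        for start in _scan_one_strand(seq, motif.pattern):
            hits.append(MotifHit(gene, start, "+"))
            n += 1
        if scan_reverse:
            for start in _scan_one_strand(seq, rc):
                hits.append(MotifHit(gene, start, "-"))
                n += 1
        counts[gene] = n
    return hits, counts


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def binomial_overrepresentation(
    observed: int, trials: int, p_expected: float
) -> float:
    """Exact upper-tail binomial p: P[Bin(trials, p_expected) ≥ observed]."""
    if not 0 < p_expected < 1:
        raise ValueError(f"p_expected must be in (0, 1), got {p_expected}")
    if not 0 <= observed <= trials:
        raise ValueError("need 0 <= observed <= trials")
    if observed == 0:
        return 1.0
    return float(binom.sf(observed - 1, trials, p_expected))


def base_composition(promoters: Mapping[str, str]) -> dict[str, float]:
    """Empirical A/C/G/T frequencies over all promoters (N excluded)."""
    counts = {b: 0 for b in "ACGT"}
    for seq in promoters.values():
        for b in "ACGT":
            counts[b] += seq.count(b)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("promoter set contains no unambiguous bases")
    return {b: c / total for b, c in counts.items()}


def expected_match_probability(
    motif: Motif, composition: Mapping[str, float] | None = None
) -> float:
    """Per-position match probability of the motif under a base composition
    (uniform by default).  Doubled for the both-combined policy on
    non-palindromic motifs (either orientation matches)."""
    if composition is None:
        composition = {b: 0.25 for b in "ACGT"}
    if abs(sum(composition.values()) - 1.0) > 1e-9:
        raise ValueError("base frequencies must sum to 1")
    p = 1.0
    for b in motif.pattern:
        p *= sum(composition[x] for x in IUPAC[b])
    if (
        motif.orientation_policy == "both-combined"
        and motif.palindrome_class != PALINDROME_PERFECT
    ):
        p *= 2.0
    return p


def fold_overrepresentation(sample_pct: float, background_pct: float) -> float:
    """Ratio of relative frequencies (% of promoters carrying ≥1 site)."""
    if background_pct == 0:
        return float("nan")
    return sample_pct / background_pct


def _presence_pct(counts: Mapping[str, int]) -> float:
    if not counts:
        return 0.0
    return 100.0 * sum(1 for n in counts.values() if n > 0) / len(counts)


def _scan_trials(promoters: Mapping[str, str], k: int) -> int:
    return sum(max(len(s) - k + 1, 0) for s in promoters.values())


def enrichment_table(
    samples: Mapping[str, Mapping[str, str]],
    motifs: Sequence[Motif],
    background: str,
    composition: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Motif × promoter-sample overrepresentation report.

    ``samples`` maps sample name → promoter set; ``background`` names the
    sample used for the fold denominator (typically "all").  The expected
    per-position probability defaults to the background sample's empirical
    base composition.  For both-separate motifs, each orientation is a
    distinct record (suffix ``_rc`` for the reverse complement).
    """
    if background not in samples:
        raise KeyError(f"background sample {background!r} not among samples")
    if composition is None:
        composition = base_composition(samples[background])

    # expand orientation policies into concrete scan records
    scan_records: list[tuple[str, Motif]] = []
    for m in motifs:
        if (
            m.orientation_policy == "both-separate"
            and m.palindrome_class != PALINDROME_PERFECT
        ):
            fwd = Motif(m.pattern, m.name, "single")
            rev = Motif(reverse_complement(m.pattern), m.name + "_rc", "single")
            scan_records += [(m.name, fwd), (m.name + "_rc", rev)]
        else:
            scan_records.append((m.name, m))

    bg_presence: dict[str, float] = {}
    rows = []
    for record_name, motif in scan_records:
        p_exp = expected_match_probability(motif, composition)
        per_sample = {}
        for sample_name, promoters in samples.items():
            hits, counts = scan_motif(promoters, motif)
            trials = _scan_trials(promoters, len(motif.pattern))
            per_sample[sample_name] = (len(hits), trials, _presence_pct(counts))
        bg_presence[record_name] = per_sample[background][2]
        for sample_name, (observed, trials, presence) in per_sample.items():
            rows.append(
                {
                    "motif": record_name,
                    "pattern": motif.pattern,
                    "sample": sample_name,
                    "n_promoters": len(samples[sample_name]),
                    "observed": observed,
                    "trials": trials,
                    "p_expected": p_exp,
                    "p_binomial": binomial_overrepresentation(observed, trials, p_exp)
                    if trials
                    else 1.0,
                    "rel_freq_pct": presence,
                    "fold_vs_background": fold_overrepresentation(
                        presence, bg_presence[record_name]
                    ),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Exhaustive palindromic k-mer discovery
# ---------------------------------------------------------------------------

def palindromic_kmer_enrichment(
    foreground: Mapping[str, str],
    background: Mapping[str, str],
    k_range: tuple[int, int] = (6, 14),
    max_candidates: int | None = None,
) -> pd.DataFrame:
    """Enumerate palindromic k-mers present in the foreground and rank them
    by binomial overrepresentation against the background occurrence rate.

    A desk-scale, exhaustive alternative to EM-based motif discovery: every
    foreground k-mer classified ``perfect`` or ``odd-center`` palindromic is
    scored by the exact upper tail of Bin(foreground trials, background
    per-position rate).  A Benjamini-Hochberg column is included; ranking is
    by ascending p (descending −log p).
    """
    lo, hi = k_range
    if not 4 <= lo <= hi <= 16:
        raise ValueError("k_range must lie within 4..16")
    if not foreground:
        raise ValueError("empty foreground promoter set")
    rows = []
    for k in range(lo, hi + 1):
        fg_counts: dict[str, int] = {}
        for seq in foreground.values():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                fg_counts[kmer] = fg_counts.get(kmer, 0) + 1
        palindromic = {
            kmer: c
            for kmer, c in fg_counts.items()
            if is_palindrome(kmer) != PALINDROME_NONE
        }
        if not palindromic:
            continue
        fg_trials = _scan_trials(foreground, k)
        bg_trials = _scan_trials(background, k)
        bg_counts: dict[str, int] = {kmer: 0 for kmer in palindromic}
        for seq in background.values():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if kmer in bg_counts:
                    bg_counts[kmer] += 1
        for kmer, observed in sorted(palindromic.items()):
            # continuity floor keeps the expected rate in (0,1) when a k-mer
            # is absent from the background
            p_bg = max(bg_counts[kmer], 0.5) / max(bg_trials, 1)
            rows.append(
                {
                    "kmer": kmer,
                    "k": k,
                    "palindrome": is_palindrome(kmer),
                    "fg_count": observed,
                    "fg_trials": fg_trials,
                    "bg_count": bg_counts[kmer],
                    "bg_trials": bg_trials,
                    "p_expected": p_bg,
                    "p_binomial": binomial_overrepresentation(
                        observed, fg_trials, p_bg
                    ),
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=[
                "kmer", "k", "palindrome", "fg_count", "fg_trials",
                "bg_count", "bg_trials", "p_expected", "p_binomial", "q_bh",
            ]
        )
    df["q_bh"] = multipletests(df["p_binomial"], method="fdr_bh")[1]
    df = df.sort_values(
        ["p_binomial", "kmer"], kind="mergesort"
    ).reset_index(drop=True)
    if max_candidates is not None:
        df = df.head(max_candidates)
    return df


# ---------------------------------------------------------------------------
# Positional distribution
# ---------------------------------------------------------------------------

def positional_distribution(
    hits: Iterable[MotifHit],
    promoter_length: int,
    motif_length: int,
    bin_width: int = 500,
) -> tuple[pd.DataFrame, float]:
    """Bin hits by distance from the start codon and test proximal bias.

    Distance-to-ATG of a hit is ``promoter_length − start − motif_length + 2``
    (the gap between the motif's downstream edge and the start codon, 1-based).
    The proximal-bias statistic is an exact binomial test of the count in the
    first (1..bin_width) bin against the uniform per-hit probability of
    landing there.
    """
    hits = list(hits)
    max_dist = promoter_length - motif_length + 1
    edges = list(range(0, max_dist, bin_width)) + [max_dist]
    labels = [f"{lo + 1}-{hi}" for lo, hi in zip(edges[:-1], edges[1:])]
    counts = [0] * (len(edges) - 1)
    for h in hits:
        dist = promoter_length - h.start - motif_length + 2
        if not 1 <= dist <= max_dist:
            continue
        idx = min((dist - 1) // bin_width, len(counts) - 1)
        counts[idx] += 1
    table = pd.DataFrame({"distance_to_start": labels, "count": counts})
    total = sum(counts)
    if total == 0:
        return table, 1.0
    p_uniform = min(bin_width, max_dist) / max_dist
    p = binomial_overrepresentation(counts[0], total, p_uniform)
    return table, p
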