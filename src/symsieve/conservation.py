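"""Conservation-ratio scoring of candidate clusters from homology-search
E-values.

For each candidate cluster a consensus query (majority-rule over the aligned
trait-positive members) is searched against all proteomes; per species the
best (minimum) E-value is kept, per group (A: trait-positive dicots, B:
trait-positive monocots, C: trait-negative) the per-species best hits are
averaged.  Group divergence is gated by a two-sided Wilcoxon rank-sum test on
the per-species best-hit E-values, and the *conservation ratio*

    ratio_CX = log10(Ē_C) − log10(Ē_X)

measures how much farther the trait-negative homologues sit from the
consensus than group X.  Large positive ratios indicate trait-associated
conservation; housekeeping-like clusters sit near zero or below.  Clusters
with no hit at all in group C form the ``NaN_in_C`` class — maximal trait
specificity.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

from .species import SpeciesGroups

logger = logging.getLogger(__name__)

#: E-values are floored here before taking logs (BLAST reports 0 below its
#: numeric range); records whose raw group average is exactly 0 are flagged.
E_FLOOR = 1e-180

#: Pooled sample size up to which the Wilcoxon null is enumerated exactly.
EXACT_LIMIT = 12

CLASS_NAN = "NaN_in_C"
CLASS_RATIO = "ratio>threshold"
CLASS_SIG = "significant"
CLASS_NONSIG = "nonsignificant"


# ---------------------------------------------------------------------------
# Consensus from a multiple alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignedCluster:
    """Aligned members of one cluster: label → gapped sequence ('-' = gap)."""

    cluster_id: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError(f"alignment {self.cluster_id} is empty")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"alignment {self.cluster_id}: unequal row lengths")


def _default_species_of(label: str) -> str:
    return label.split("_", 1)[0]


def consensus_from_alignment(
    aln: AlignedCluster,
    restrict_to: Iterable[str] | None = None,
    species_of: Callable[[str], str] = _default_species_of,
) -> str:
    """Majority-rule consensus: per column the most frequent non-gap residue,
    ties broken alphabetically; columns where gaps hold a strict majority are
    dropped.  ``restrict_to`` limits the rows to the given species codes."""
    rows = aln.rows
    if restrict_to is not None:
        allowed = set(restrict_to)
        rows = {k: v for k, v in rows.items() if species_of(k) in allowed}
        if not rows:
            raise ValueError(
                f"alignment {aln.cluster_id}: no rows left after species restriction"
            )
    seqs = list(rows.values())
    n = len(seqs)
    out = []
    for col in zip(*seqs):
        gaps = sum(1 for c in col if c == "-")
        if 2 * gaps > n:
            continue
        residues = Counter(c for c in col if c != "-")
        if not residues:
            continue
        best = min(residues.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        out.append(best)
    return "".join(out)


# ---------------------------------------------------------------------------
# Hit tables (BLAST tabular, 12 columns, E-value in column 11)
# ---------------------------------------------------------------------------

HIT_COLUMNS = ["query", "subject", "species", "evalue"]


def ingest_hit_table(
    path: str | Path,
    species_resolver: Callable[[str], str] | None = None,
    groups: SpeciesGroups | None = None,
    species: str | None = None,
) -> pd.DataFrame:
    """Parse a 12-column BLAST-tabular file into (query, subject, species,
    evalue) rows.  Subject species comes from ``species`` (per-file tag), a
    resolver callable, or prefix resolution against ``groups``."""
    if species_resolver is None and groups is not None:
        species_resolver = lambda label: groups.resolve_label(label)[0].code  # noqa: E731
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            query, subject = fields[0], fields[1]
            try:
                evalue = float(fields[10])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric E-value {fields[10]!r}"
                ) from exc
            if evalue < 0:
                raise ValueError(f"{path}:{lineno}: negative E-value")
            if species is not None:
                sp = species
            elif species_resolver is not None:
                sp = species_resolver(subject)
            else:
                raise ValueError("no way to resolve subject species")
            rows.append((query, subject, sp, evalue))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def best_hit_reduce(hits: pd.DataFrame) -> pd.DataFrame:
    """Per (query, species): the minimum E-value among that species' hits."""
    if hits.empty:
        return pd.DataFrame(columns=["query", "species", "evalue"])
    return (
        hits.groupby(["query", "species"], sort=True)["evalue"]
        .min()
        .reset_index()
    )


def group_average(
    per_species: Mapping[str, float], group_codes: Iterable[str]
) -> float:
    """Arithmetic mean of per-species best-hit E-values over group members
    with hits; species without a hit are excluded.  NaN when the whole group
    is absent."""
    values = [per_species[c] for c in group_codes if c in per_species]
    if not values:
        return float("nan")
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum (Mann-Whitney) with exact small-sample enumeration
# ---------------------------------------------------------------------------

def wilcoxon_group_test(
    values_x: Sequence[float], values_y: Sequence[float]
) -> float:
    """Two-sided Wilcoxon rank-sum p-value on two samples of E-values.

    Rank-based, so any strictly monotone transform of the inputs gives the
    identical p.  Ties get mid-ranks.  For pooled n ≤ 12 the null
    distribution of the rank sum is enumerated exactly over all
    C(n, n₁) group assignments; above that a tie-corrected normal
    approximation with continuity correction is used.
    """
    x = [float(v) for v in values_x]
    y = [float(v) for v in values_y]
    if not x or not y:
        return float("nan")
    n1, n2 = len(x), len(y)
    n = n1 + n2
    ranks = rankdata(x + y)
    mu = n1 * (n + 1) / 2.0
    r_obs = float(np.sum(ranks[:n1]))
    if n <= EXACT_LIMIT:
        dev = abs(r_obs - mu)
        total = 0
        extreme = 0
        for combo in itertools.combinations(range(n), n1):
            total += 1
            r = sum(ranks[i] for i in combo)
            if abs(r - mu) >= dev - 1e-9:
                extreme += 1
        return extreme / total
    # normal approximation on U with tie correction
    u_obs = r_obs - n1 * (n1 + 1) / 2.0
    mu_u = n1 * n2 / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        return 1.0
    z = (abs(u_obs - mu_u) - 0.5) / math.sqrt(var_u)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * norm.sf(z)))


# ---------------------------------------------------------------------------
# Conservation ratio and per-cluster records
# ---------------------------------------------------------------------------

def conservation_ratio(
    e_c: float, e_x: float, floor: float = E_FLOOR
) -> float:
    """log10(Ē_C) − log10(Ē_X) with both averages floored at ``floor``.

    Positive ⇒ trait-negative homologues are farther from the consensus than
    group X; antisymmetric in its arguments.
    """
    if math.isnan(e_c) or math.isnan(e_x):
        return float("nan")
    return math.log10(max(e_c, floor)) - math.log10(max(e_x, floor))


RECORD_COLUMNS = [
    "cluster_id", "E_A", "E_B", "E_C", "p_CA", "p_CB", "q_CA",
    "ratio_CA", "ratio_CB", "class", "flag_CA", "flag_CB", "flag_both",
    "zero_E", "n_A", "n_B", "n_C",
]


def build_conservation_records(
    best_hits: pd.DataFrame,
    groups: SpeciesGroups,
    alpha: float = 0.05,
    ratio_threshold: float = 100.0,
    floor: float = E_FLOOR,
) -> pd.DataFrame:
    """Score every query in a best-hit table; one row per cluster.

    Classes: ``NaN_in_C`` (no trait-negative hit at all), ``ratio>threshold``
    (ratio_CA above the threshold), ``significant`` (p_CA < alpha) or
    ``nonsignificant``.  Queries with no group-A hit cannot be scored and are
    dropped with a warning.  ``q_CA`` is a Benjamini-Hochberg adjusted column
    provided for reference; the significance gate itself is uncorrected.
    """
    codes_a, codes_b, codes_c = groups.codes("A"), groups.codes("B"), groups.codes("C")
    rows = []
    for query, sub in best_hits.groupby("query", sort=True):
        per_species = dict(zip(sub["species"], sub["evalue"]))
        vals_a = [per_species[c] for c in sorted(codes_a) if c in per_species]
        vals_b = [per_species[c] for c in sorted(codes_b) if c in per_species]
        vals_c = [per_species[c] for c in sorted(codes_c) if c in per_species]
        e_a = group_average(per_species, codes_a)
        e_b = group_average(per_species, codes_b)
        e_c = group_average(per_species, codes_c)
        if math.isnan(e_a):
            logger.warning("query %s has no group-A hits; dropped", query)
            continue
        p_ca = wilcoxon_group_test(vals_c, vals_a) if vals_c else float("nan")
        p_cb = (
            wilcoxon_group_test(vals_c, vals_b)
            if vals_c and vals_b
            else float("nan")
        )
        ratio_ca = conservation_ratio(e_c, e_a, floor)
        ratio_cb = conservation_ratio(e_c, e_b, floor)
        zero_e = any(v == 0.0 for v in (e_a, e_b, e_c) if not math.isnan(v))
        if math.isnan(e_c):
            cls = CLASS_NAN
        elif ratio_ca > ratio_threshold:
            cls = CLASS_RATIO
        elif not math.isnan(p_ca) and p_ca < alpha:
            cls = CLASS_SIG
        else:
            cls = CLASS_NONSIG
        rows.append(
            {
                "cluster_id": query,
                "E_A": e_a,
                "E_B": e_b,
                "E_C": e_c,
                "p_CA": p_ca,
                "p_CB": p_cb,
                "ratio_CA": ratio_ca,
                "ratio_CB": ratio_cb,
                "class": cls,
                "flag_CA": (not math.isnan(ratio_ca)) and ratio_ca > ratio_threshold,
                "flag_CB": (not math.isnan(ratio_cb)) and ratio_cb > ratio_threshold,
                "zero_E": zero_e,
                "n_A": len(vals_a),
                "n_B": len(vals_b),
                "n_C": len(vals_c),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    df["flag_both"] = df["flag_CA"] & df["flag_CB"]
    pvals = df["p_CA"].to_numpy()
    q = np.full(len(df), np.nan)
    ok = ~np.isnan(pvals)
    if ok.any():
        q[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    df["q_CA"] = q
    return df[RECORD_COLUMNS]


# ---------------------------------------------------------------------------
# Housekeeping reference band and candidate ranking
# ---------------------------------------------------------------------------

@dataclass
class ReferenceBand:
    """Conservation-ratio distribution over selected housekeeping clusters."""

    cluster_ids: list[str]
    ratios: np.ndarray = field(repr=False)

    @property
    def summary(self) -> dict[str, float]:
        r = self.ratios
        return {
            "n": int(len(r)),
            "min": float(np.min(r)),
            "q25": float(np.quantile(r, 0.25)),
            "median": float(np.median(r)),
            "q75": float(np.quantile(r, 0.75)),
            "max": float(np.max(r)),
        }


def select_reference_band(records: pd.DataFrame, n: int = 150) -> ReferenceBand:
    """Select housekeeping reference clusters with intermediate E-values.

    Excluded: records with any raw group-average E of exactly 0 (pre-floor)
    and records with an undefined monocot (Ē_B) or trait-negative (Ē_C)
    average.  The remainder is ranked by Ē_A and the ``n`` records straddling
    the median are kept; with fewer than ``n`` eligible, all are kept with a
    warning.
    """
    eligible = records[
        (~records["zero_E"])
        & records["E_B"].notna()
        & records["E_C"].notna()
    ].copy()
    if eligible.empty:
        raise ValueError("no eligible reference records")
    eligible = eligible.sort_values("E_A", kind="mergesort").reset_index(drop=True)
    m = len(eligible)
    if m <= n:
        if m < n:
            logger.warning("only %d eligible reference records (< %d); using all", m, n)
        window = eligible
    else:
        start = (m - n) // 2
        window = eligible.iloc[start : start + n]
    return ReferenceBand(
        cluster_ids=list(window["cluster_id"]),
        ratios=window["ratio_CA"].to_numpy(dtype=float),
    )


def rank_candidates(
    records: pd.DataFrame,
    reference: ReferenceBand | None = None,
    ratio_threshold: float = 100.0,
) -> pd.DataFrame:
    """Order candidates by trait-association: NaN_in_C class first (maximal
    specificity), then descending ratio_CA.  Reference-band quantiles are
    attached as ``df.attrs['reference']`` for context."""
    if records.empty:
        out = records.copy()
        out.attrs["reference"] = reference.summary if reference else None
        return out
    df = records.copy()
    is_nan_class = (df["class"] == CLASS_NAN).astype(int)
    sort_ratio = df["ratio_CA"].fillna(-np.inf)
    df = (
        df.assign(_nan=is_nan_class, _r=sort_ratio)
        .sort_values(["_nan", "_r"], ascending=[False, False], kind="mergesort")
        .drop(columns=["_nan", "_r"])
        .reset_index(drop=True)
    )
    df["rank"] = np.arange(1, len(df) + 1)
    if reference is not None:
        band_max = reference.summary["max"]
        df["above_reference_max"] = df["ratio_CA"].fillna(np.inf) > band_max
        df.attrs["reference"] = reference.summary
    else:
        df.attrs["reference"] = None
    return df
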