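"""Expression-atlas filtering: probeset curation, fold-induction criteria,
Venn partitioning, scale-score standardization and co-expression clustering.

The expression matrix is probesets × treatments of nonnegative hybridization
intensities (atlas dialect: TSV whose first column is the probeset id and
whose header row holds the treatment names).  Induction criteria are named
test/control treatment contrasts; a gene counts as induced for a criterion
when any of its curated probesets reaches the fold threshold (3-fold by
default, inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

#: Control values are floored at this intensity before ratio division.
CONTROL_FLOOR = 0.01

#: Probeset-id suffixes flagging non-unique / cross-hybridizing probes.
UNRELIABLE_SUFFIXES = ("_x_at", "_s_at")

#: Minimum "genome identity" of a probeset with its target gene; strictly
#: lower values are discarded (exactly 70 is retained).
IDENTITY_CUTOFF = 70.0


@dataclass(frozen=True)
class CriterionDef:
    """A named induction contrast: mean(test columns) / mean(control columns)."""

    name: str
    test_columns: tuple[str, ...]
    control_columns: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.test_columns or not self.control_columns:
            raise ValueError(f"criterion {self.name}: empty column list")


def load_criteria(path: str | Path | None = None) -> list[CriterionDef]:
    """Load criterion definitions from YAML (package defaults when no path)."""
    if path is None:
        text = resources.files("symsieve.data").joinpath("criteria.yaml").read_text()
    else:
        text = Path(path).read_text()
    data = yaml.safe_load(text)
    return [
        CriterionDef(
            name=c["name"],
            test_columns=tuple(c["test"]),
            control_columns=tuple(c["control"]),
        )
        for c in data["criteria"]
    ]


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a probesets × treatments TSV (first column = probeset id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative expression values")
    return df


def read_probeset_meta(path: str | Path) -> pd.DataFrame:
    """Read probeset metadata (probeset_id, gene_id, identity_pct)."""
    meta = pd.read_csv(path, sep="\t")
    required = {"probeset_id", "gene_id", "identity_pct"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return meta.set_index("probeset_id")


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

def curate_probesets(
    matrix: pd.DataFrame, meta: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Drop unreliable probesets; returns (matrix, meta, removal log).

    Removed: ids ending in ``_x_at``/``_s_at`` (non-unique probes) and
    probesets whose genome identity with the target is strictly below 70%.
    """
    missing = [p for p in matrix.index if p not in meta.index]
    if missing:
        raise KeyError(f"probesets without metadata: {missing[:10]}")
    removals = []
    keep = []
    for probeset in matrix.index:
        if probeset.endswith(UNRELIABLE_SUFFIXES):
            removals.append({"probeset_id": probeset, "reason": "suffix"})
        elif float(meta.loc[probeset, "identity_pct"]) < IDENTITY_CUTOFF:
            removals.append({"probeset_id": probeset, "reason": "identity<70"})
        else:
            keep.append(probeset)
    log = pd.DataFrame(removals, columns=["probeset_id", "reason"])
    if len(log):
        logger.info("curation removed %d probesets", len(log))
    return matrix.loc[keep], meta.loc[keep], log


# ---------------------------------------------------------------------------
# Induction ratios and gene-level flags
# ---------------------------------------------------------------------------

def induction_ratio(
    matrix: pd.DataFrame, criterion: CriterionDef, floor: float = CONTROL_FLOOR
) -> pd.Series:
    """Per-probeset fold induction: mean(test) / max(mean(control), floor).

    Replicate test columns (e.g. two inoculum treatments) are averaged before
    the ratio is taken.
    """
    for col in criterion.test_columns + criterion.control_columns:
        if col not in matrix.columns:
            raise KeyError(f"criterion {criterion.name}: missing treatment {col!r}")
    test = matrix[list(criterion.test_columns)].mean(axis=1)
    control = matrix[list(criterion.control_columns)].mean(axis=1).clip(lower=floor)
    ratio = test / control
    ratio.name = criterion.name
    return ratio


def compute_ratios(
    matrix: pd.DataFrame,
    criteria: Sequence[CriterionDef],
    floor: float = CONTROL_FLOOR,
) -> pd.DataFrame:
    """Probesets × criteria table of induction ratios."""
    return pd.concat([induction_ratio(matrix, c, floor) for c in criteria], axis=1)


def gene_level_flags(
    ratios: pd.DataFrame, meta: pd.DataFrame, threshold: float = 3.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate probeset ratios to genes; returns (gene_ratios, gene_flags).

    A gene passes a criterion iff ANY of its probesets reaches the threshold
    (inclusive ≥), so the gene-level ratio is the per-criterion maximum over
    probesets.  Genes with no curated probeset are absent from the table.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    genes = meta.loc[ratios.index, "gene_id"]
    gene_ratios = ratios.groupby(genes).max()
    gene_ratios.index.name = "gene_id"
    return gene_ratios, gene_ratios >= threshold


def venn_partition(
    flags: pd.DataFrame, criteria: Sequence[str] | None = None
) -> dict[frozenset[str], list[str]]:
    """Partition genes by their exact pass pattern over the chosen criteria.

    Regions are disjoint and cover exactly the genes passing ≥1 selected
    criterion; a gene passing none appears in no region.
    """
    if criteria is None:
        criteria = list(flags.columns)
    if not criteria:
        raise ValueError("at least one criterion must be selected")
    sub = flags[list(criteria)]
    regions: dict[frozenset[str], list[str]] = {}
    for gene, row in sub.iterrows():
        passed = frozenset(c for c in criteria if bool(row[c]))
        if passed:
            regions.setdefault(passed, []).append(gene)
    return regions


def venn_table(
    flags: pd.DataFrame,
    criteria: Sequence[str] | None = None,
    extra_flag: str | None = "P-repressed",
) -> pd.DataFrame:
    """Flat table of Venn regions; an orthogonal criterion (phosphate
    repression by default) is reported as a per-region count, mirroring the
    way such genes are marked on the diagram rather than given a region."""
    regions = venn_partition(flags, criteria)
    rows = []
    for key in sorted(regions, key=lambda k: (len(k), sorted(k))):
        genes = sorted(regions[key])
        row = {
            "region": "&".join(sorted(key)),
            "n_genes": len(genes),
            "genes": ",".join(genes),
        }
        if extra_flag is not None and extra_flag in flags.columns:
            row[f"n_{extra_flag}"] = int(flags.loc[genes, extra_flag].sum())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Scale-score standardization (per-treatment z-score of ln intensities)
# ---------------------------------------------------------------------------

def standardize(matrix: pd.DataFrame, floor: float = CONTROL_FLOOR) -> pd.DataFrame:
    """Scale-score standardization: Y = (X − μ) / ρ with X = ln(x).

    μ and ρ are the per-treatment mean and *population* standard deviation of
    the ln intensities over all probesets.  Values are floored at ``floor``
    before the log.  A constant column (ρ = 0) is an error.
    """
    X = np.log(matrix.clip(lower=floor))
    mu = X.mean(axis=0)
    rho = X.std(axis=0, ddof=0)
    zero = rho[rho == 0]
    if len(zero):
        raise ValueError(
            f"zero standard deviation in treatment(s): {list(zero.index)}"
        )
    return (X - mu) / rho


def coexpression_cluster(
    std: pd.DataFrame, cut: float = 0.3
) -> tuple[np.ndarray, pd.Index, pd.Series]:
    """Average-linkage hierarchical clustering on Pearson-correlation distance.

    Distance between rows i, j is 1 − Pearson(r_i, r_j) across treatments.
    Rows with zero variance are excluded with a warning (correlation is
    undefined there).  Returns (linkage matrix, row labels used, flat group
    assignment at the given distance cut).
    """
    variances = std.var(axis=1, ddof=0)
    dropped = variances[variances == 0].index
    if len(dropped):
        logger.warning(
            "excluding %d zero-variance rows from clustering: %s",
            len(dropped),
            list(dropped[:5]),
        )
    data = std.drop(index=dropped)
    if len(data) < 2:
        raise ValueError("need at least 2 variable rows to cluster")
    dist = pdist(data.values, metric="correlation")
    Z = linkage(dist, method="average")
    groups = pd.Series(
        fcluster(Z, t=cut, criterion="distance"), index=data.index, name="group"
    )
    return Z, data.index, groups
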