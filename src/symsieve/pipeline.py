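"""End-to-end orchestration: clusters → subtraction filters → expression
filter → conservation scoring → promoter enrichment, from a single config.

Stage outputs are pure functions of (inputs, config): each stage writes plain
TSV/JSON artifacts into the output directory, later stages read the earlier
artifacts, and a run manifest records thresholds and input checksums.  A
failed stage aborts the run with the stage name and leaves a ``failed``
marker next to any partial outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import conservation as cons
from . import expression as expr
from . import motifs as mot
from . import orthology
from .species import SpeciesGroups

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated inputs and thresholds for one pipeline run."""

    clusters: Path
    groups: Path
    expression: Path
    probeset_meta: Path
    promoters: Path
    hits: list[Path]
    reference_hits: list[Path] = field(default_factory=list)
    criteria: Path | None = None
    motifs: Path | None = None
    outdir: Path = Path("symsieve_out")
    tasks: list[int] = field(default_factory=lambda: [3, 4, 5, 6])
    induction_threshold: float = 3.0
    venn_criteria: list[str] = field(
        default_factory=lambda: ["LCM", "AM", "dmi3", "MF_6h"]
    )
    foreground_criteria: list[str] = field(default_factory=lambda: ["LCM", "AM"])
    cluster_cut: float = 0.3
    alpha: float = 0.05
    ratio_threshold: float = 100.0
    e_floor: float = cons.E_FLOOR
    reference_n: int = 150

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key, val in out.items():
            if isinstance(val, Path):
                out[key] = str(val)
            elif isinstance(val, list) and val and isinstance(val[0], Path):
                out[key] = [str(v) for v in val]
        return out


def validate_config(path: str | Path) -> tuple[RunConfig | None, list[str]]:
    """Parse and validate a run-config YAML; errors are collected, not
    first-failure."""
    errors: list[str] = []
    try:
        data = yaml.safe_load(Path(path).read_text())
    except Exception as exc:
        return None, [f"cannot parse {path}: {exc}"]
    base = Path(path).parent

    def resolve(key: str, required: bool = True) -> Path | None:
        raw = data.get(key)
        if raw is None:
            if required:
                errors.append(f"missing required path {key!r}")
            return None
        p = Path(raw)
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            errors.append(f"{key}: file not found: {p}")
        return p

    def resolve_list(key: str, required: bool = True) -> list[Path]:
        raw = data.get(key) or []
        if isinstance(raw, str):
            raw = [raw]
        if not raw and required:
            errors.append(f"missing required path list {key!r}")
        out = []
        for item in raw:
            p = Path(item)
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                errors.append(f"{key}: file not found: {p}")
            out.append(p)
        return out

    clusters = resolve("clusters")
    groups_path = resolve("groups")
    expression_path = resolve("expression")
    meta_path = resolve("probeset_meta")
    promoters_path = resolve("promoters")
    hits = resolve_list("hits")
    reference_hits = resolve_list("reference_hits", required=False)
    criteria_path = resolve("criteria", required=False) if "criteria" in data else None
    motifs_path = resolve("motifs", required=False) if "motifs" in data else None

    groups = None
    if groups_path is not None and groups_path.exists():
        try:
            groups = SpeciesGroups.from_yaml(groups_path)
        except Exception as exc:
            errors.append(f"groups: {exc}")

    criteria = None
    try:
        criteria = expr.load_criteria(criteria_path)
    except Exception as exc:
        errors.append(f"criteria: {exc}")

    if (
        criteria is not None
        and expression_path is not None
        and expression_path.exists()
    ):
        header = pd.read_csv(expression_path, sep="\t", nrows=0)
        cols = set(header.columns)
        for crit in criteria:
            for col in crit.test_columns + crit.control_columns:
                if col not in cols:
                    errors.append(
                        f"criterion {crit.name}: treatment column {col!r} "
                        "not in expression matrix"
                    )

    for key in ("induction_threshold", "alpha", "ratio_threshold", "cluster_cut"):
        if key in data and not (isinstance(data[key], (int, float)) and data[key] > 0):
            errors.append(f"{key} must be a positive number")

    if errors:
        return None, errors
    config = RunConfig(
        clusters=clusters,
        groups=groups_path,
        expression=expression_path,
        probeset_meta=meta_path,
        promoters=promoters_path,
        hits=hits,
        reference_hits=reference_hits,
        criteria=criteria_path,
        motifs=motifs_path,
        outdir=Path(data.get("outdir", "symsieve_out")),
        tasks=list(data.get("tasks", [3, 4, 5, 6])),
        induction_threshold=float(data.get("induction_threshold", 3.0)),
        venn_criteria=list(data.get("venn_criteria", ["LCM", "AM", "dmi3", "MF_6h"])),
        foreground_criteria=list(data.get("foreground_criteria", ["LCM", "AM"])),
        cluster_cut=float(data.get("cluster_cut", 0.3)),
        alpha=float(data.get("alpha", 0.05)),
        ratio_threshold=float(data.get("ratio_threshold", 100.0)),
        reference_n=int(data.get("reference_n", 150)),
    )
    return config, []


def config_for_bundle(bundle_dir: str | Path, outdir: str | Path) -> RunConfig:
    """RunConfig wired to a synthetic fixture bundle's file layout."""
    bundle = Path(bundle_dir)
    return RunConfig(
        clusters=bundle / "clusters.nwk",
        groups=bundle / "groups.yaml",
        expression=bundle / "expression.tsv",
        probeset_meta=bundle / "probeset_meta.tsv",
        promoters=bundle / "promoters.fasta",
        hits=[bundle / "hits" / "task3.tsv"],
        reference_hits=[bundle / "hits" / "task9.tsv"],
        outdir=Path(outdir),
    )


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.6g"


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def _stage_clusters(config: RunConfig, groups: SpeciesGroups, out: Path) -> dict:
    clusters = orthology.parse_cluster_trees(config.clusters, groups)
    counts = {"total": len(clusters)}
    for x in sorted(config.tasks):
        taskx = orthology.task_filter(clusters, groups, x)
        _cluster_tsv(taskx, out / f"task{x}.tsv")
        rep = orthology.representation_table(taskx, groups)
        rep["total_clusters"] = rep.attrs["total"]
        _write(rep, out / f"task{x}_representation.tsv")
        counts[f"task{x}"] = len(taskx)
    task9 = orthology.task9_filter(clusters, groups)
    _cluster_tsv(task9, out / "task9.tsv")
    counts["task9"] = len(task9)
    return counts


def _cluster_tsv(cs: orthology.ClusterSet, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    orthology.write_cluster_table(cs, path)
    return path


def _stage_expression(config: RunConfig, out: Path) -> dict:
    matrix = expr.read_expression_matrix(config.expression)
    meta = expr.read_probeset_meta(config.probeset_meta)
    criteria = expr.load_criteria(config.criteria)
    matrix, meta, removal_log = expr.curate_probesets(matrix, meta)
    _write(removal_log, out / "curation_log.tsv")
    ratios = expr.compute_ratios(matrix, criteria)
    gene_ratios, flags = expr.gene_level_flags(
        ratios, meta, config.induction_threshold
    )
    _write(gene_ratios, out / "induction_ratios.tsv", index=True)
    _write(flags.astype(int), out / "induction_flags.tsv", index=True)
    venn = expr.venn_table(flags, config.venn_criteria)
    _write(venn, out / "venn.tsv")
    std = expr.standardize(matrix)
    _, _, groups_series = expr.coexpression_cluster(std, cut=config.cluster_cut)
    gene_groups = groups_series.groupby(
        meta.loc[groups_series.index, "gene_id"]
    ).first()
    _write(
        gene_groups.rename("coexpression_group").reset_index(),
        out / "coexpression_groups.tsv",
    )
    induced_any = flags[
        [c for c in config.foreground_criteria if c in flags.columns]
    ].any(axis=1)
    return {
        "probesets_curated": len(matrix),
        "probesets_removed": len(removal_log),
        "genes": len(flags),
        "induced_foreground": int(induced_any.sum()),
    }


def _stage_conservation(config: RunConfig, groups: SpeciesGroups, out: Path) -> dict:
    def load(paths: list[Path]) -> pd.DataFrame:
        tables = [cons.ingest_hit_table(p, groups=groups) for p in paths]
        return (
            pd.concat(tables, ignore_index=True)
            if tables
            else pd.DataFrame(columns=cons.HIT_COLUMNS)
        )

    best = cons.best_hit_reduce(load(config.hits))
    records = cons.build_conservation_records(
        best, groups, alpha=config.alpha,
        ratio_threshold=config.ratio_threshold, floor=config.e_floor,
    )
    _write(records, out / "records.tsv")

    reference = None
    ref_summary = {}
    if config.reference_hits:
        ref_best = cons.best_hit_reduce(load(config.reference_hits))
        ref_records = cons.build_conservation_records(
            ref_best, groups, alpha=config.alpha,
            ratio_threshold=config.ratio_threshold, floor=config.e_floor,
        )
        _write(ref_records, out / "reference_records.tsv")
        reference = cons.select_reference_band(ref_records, n=config.reference_n)
        ref_summary = reference.summary
        (out / "reference_band.json").write_text(
            json.dumps(
                {"summary": ref_summary, "cluster_ids": reference.cluster_ids},
                indent=1, sort_keys=True,
            )
            + "\n"
        )
    candidates = cons.rank_candidates(
        records, reference, ratio_threshold=config.ratio_threshold
    )
    _write(candidates, out / "candidates.tsv")
    return {
        "candidates": len(candidates),
        "nan_class": int((records["class"] == cons.CLASS_NAN).sum())
        if len(records)
        else 0,
        "significant": int(
            (records["p_CA"] < config.alpha).sum()
        ) if len(records) else 0,
        "reference_band": ref_summary,
    }


def _stage_motifs(config: RunConfig, out: Path) -> dict:
    promoters = mot.read_promoters(config.promoters)
    flags = pd.read_csv(
        config.outdir / "expression" / "induction_flags.tsv",
        sep="\t", index_col=0,
    ).astype(bool)
    fg_cols = [c for c in config.foreground_criteria if c in flags.columns]
    fg_genes = set(flags.index[flags[fg_cols].any(axis=1)])
    foreground = {g: s for g, s in promoters.items() if g in fg_genes}
    if not foreground:
        logger.warning("no induced promoters found; motif stage reports background only")
    samples = {"all": promoters}
    if foreground:
        samples["induced"] = foreground
    motif_set = mot.load_motifs(config.motifs)
    table = mot.enrichment_table(samples, motif_set, background="all")
    _write(table, out / "enrichment.tsv")

    positional_counts = {}
    for motif in motif_set:
        if motif.palindrome_class != mot.PALINDROME_PERFECT:
            continue
        hits, _ = mot.scan_motif(foreground or promoters, motif)
        lengths = {len(s) for s in promoters.values()}
        table_pos, p_prox = mot.positional_distribution(
            hits, max(lengths), len(motif.pattern)
        )
        table_pos["motif"] = motif.name
        _write(table_pos, out / f"positional_{motif.name}.tsv")
        positional_counts[motif.name] = p_prox
    return {
        "n_promoters": len(promoters),
        "n_foreground": len(foreground),
        "proximal_bias_p": positional_counts,
    }


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, resume: bool = False) -> dict:
    """Execute all stages; returns the run manifest (also written to
    ``outdir/manifest.json``).  With ``resume=True`` a stage whose outputs
    already exist is skipped."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "failed"
    if failed_marker.exists():
        failed_marker.unlink()
    groups = SpeciesGroups.from_yaml(config.groups)

    stage_outputs = {
        "clusters": [outdir / "clusters" / "task9.tsv"],
        "expression": [outdir / "expression" / "induction_flags.tsv"],
        "conservation": [outdir / "conservation" / "candidates.tsv"],
        "motifs": [outdir / "motifs" / "enrichment.tsv"],
    }
    counts: dict = {}

    def run_stage(name: str, fn, *args):
        if resume and all(p.exists() for p in stage_outputs[name]):
            logger.info("stage %s: cached outputs found, skipping", name)
            counts[name] = {"resumed": True}
            return
        try:
            counts[name] = fn(*args)
        except Exception as exc:
            failed_marker.write_text(f"{name}: {exc}\n")
            raise StageError(name, str(exc)) from exc

    run_stage("clusters", _stage_clusters, config, groups, outdir / "clusters")
    run_stage("expression", _stage_expression, config, outdir / "expression")
    run_stage(
        "conservation", _stage_conservation, config, groups, outdir / "conservation"
    )
    run_stage("motifs", _stage_motifs, config, outdir / "motifs")

    inputs = [config.clusters, config.groups, config.expression,
              config.probeset_meta, config.promoters, *config.hits,
              *config.reference_hits]
    manifest = {
        "symsieve_version": __version__,
        "config": config.to_dict(),
        "input_checksums": {str(p): _checksum(Path(p)) for p in inputs},
        "stage_counts": counts,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return manifest
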