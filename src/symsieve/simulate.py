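"""Seeded synthetic fixture bundles with planted ground truth.

The generator emulates every input the pipeline consumes — proteome FASTAs,
one-tree-per-line orthology clusters, BLAST-tabular hit files, an
expression-atlas TSV with probeset metadata, and a promoter FASTA — with a
known class structure:

``ubiquitous``
    families present in every clustered species (the housekeeping reference);
    best-hit log10 E-values drawn from the same Normal in all three groups.
``trait_specific``
    families restricted to trait-positive species, with *no* hit rows at all
    in the trait-negative group (the maximal-specificity NaN class).
``trait_biased``
    families restricted to trait-positive species at the cluster level but
    with weak trait-negative hits, so the conservation ratio is large and
    positive.
``negative_only``
    families found only in trait-negative species; never queried.

A single integer seed governs all draws; per-stage substreams are derived
deterministically so stages can be regenerated independently, and identical
configs produce byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import expression as expr_mod
from . import orthology
from .motifs import reverse_complement
from .species import DEFAULT_GROUPS, SpeciesGroups

logger = logging.getLogger(__name__)

AA = "ACDEFGHIKLMNPQRSTVWY"

FAMILY_CLASSES = ("ubiquitous", "trait_specific", "trait_biased", "negative_only")

#: Elements planted into promoters of induced genes (name → pattern).
PLANTED_ELEMENTS = {
    "Myc1": "GGGGTTCGAACCCC",
    "Myc2": "TGAGCTTAGCTCA",
    "GCC-palindrome": "GCCGGC",
    "CTTC-extended": "GACTTGTTC",
}


def _default_evalue_model() -> dict:
    # per-class per-group Normal(mu, sigma) on log10 of the best-hit E-value
    return {
        "ubiquitous": {"A": (-110.0, 5.0), "B": (-110.0, 5.0), "C": (-110.0, 5.0)},
        "trait_specific": {"A": (-120.0, 5.0), "B": (-120.0, 5.0), "C": None},
        "trait_biased": {"A": (-130.0, 5.0), "B": (-130.0, 5.0), "C": (-10.0, 2.0)},
    }


def _default_criterion_probs() -> dict:
    return {
        "LCM": 0.7,
        "AM": 0.5,
        "dmi3": 0.1,
        "MF_6h": 0.05,
        "MF_24h": 0.0,
        "P-repressed": 0.15,
    }


@dataclass
class SimConfig:
    """Study conditions for one synthetic bundle (all draws from ``seed``)."""

    seed: int = 0
    groups: SpeciesGroups = field(default_factory=lambda: DEFAULT_GROUPS)
    # family class counts
    n_ubiquitous: int = 80
    n_trait_specific: int = 40
    n_trait_biased: int = 40
    n_negative_only: int = 40
    # cluster membership
    dropout_rate: float = 0.1
    dropout_exact: int | None = None  # drop exactly k positive species instead
    min_positive_present: int = 3
    paralog_rate: float = 0.1
    core_length: int = 120
    mutation_rate: float = 0.1
    # homology-search model
    evalue_model: dict = field(default_factory=_default_evalue_model)
    hit_dropout: float = 0.0
    decoy_rate: float = 0.3
    # expression model
    n_treatments: int = 254
    baseline_log_mean: float = 4.0
    baseline_log_sigma: float = 1.0
    noise_sigma: float = 0.2
    planted_fold: float = 4.0
    induced_fraction: float = 0.3
    criterion_probs: dict = field(default_factory=_default_criterion_probs)
    extra_probeset_rate: float = 0.3
    bad_probeset_rate: float = 0.1
    # promoter model
    promoter_length: int = 2000
    base_composition: dict = field(
        default_factory=lambda: {"A": 0.3, "C": 0.2, "G": 0.2, "T": 0.3}
    )
    plant_rate: float = 0.3
    proximal_window: int = 500
    n_background_genes: int = 300

    def __post_init__(self) -> None:
        for name in ("n_ubiquitous", "n_trait_specific", "n_trait_biased",
                     "n_negative_only"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.plant_rate <= 1:
            raise ValueError("plant_rate must be in [0, 1]")
        if abs(sum(self.base_composition.values()) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")

    def rng(self, stage: int) -> np.random.Generator:
        """Deterministic per-stage substream."""
        return np.random.default_rng([self.seed, stage])

    def class_counts(self) -> dict[str, int]:
        return {
            "ubiquitous": self.n_ubiquitous,
            "trait_specific": self.n_trait_specific,
            "trait_biased": self.n_trait_biased,
            "negative_only": self.n_negative_only,
        }


# ---------------------------------------------------------------------------
# Families: proteomes + cluster trees
# ---------------------------------------------------------------------------

def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = AA[rng.integers(len(AA))]
    return "".join(out)


def simulate_families(config: SimConfig) -> dict:
    """Generate the family truth: classes, members, and member sequences.

    Returns a dict family_id → {class, members: {code: [protein ids]},
    sequences: {label: aa}}; iteration order is family order.
    """
    groups = config.groups
    clustered = [t.code for t in groups.clustered_species]
    pos_clustered = [t.code for t in groups.positive_clustered]
    neg = [c for c in clustered if c in groups.codes("C")]
    for label, codes in (("trait-positive clustered", pos_clustered),
                         ("trait-negative clustered", neg)):
        if not codes:
            raise ValueError(f"no {label} species in the configuration")

    rng = config.rng(1)
    families: dict[str, dict] = {}
    idx = 0
    for cls in FAMILY_CLASSES:
        for _ in range(config.class_counts()[cls]):
            idx += 1
            fam = f"FAM{idx:04d}"
            if cls == "ubiquitous":
                member_codes = list(clustered)
            elif cls == "negative_only":
                member_codes = list(neg)
            else:  # trait_specific / trait_biased
                if config.dropout_exact is not None:
                    k = min(config.dropout_exact, len(pos_clustered) - 1)
                    dropped = set(
                        rng.choice(pos_clustered, size=k, replace=False)
                    )
                    member_codes = [c for c in pos_clustered if c not in dropped]
                else:
                    member_codes = [
                        c for c in pos_clustered if rng.random() >= config.dropout_rate
                    ]
                    for c in pos_clustered:  # re-fill to the floor, fixed order
                        if len(member_codes) >= config.min_positive_present:
                            break
                        if c not in member_codes:
                            member_codes.append(c)
                    member_codes.sort(key=pos_clustered.index)
            members = {c: [fam] for c in member_codes}
            if member_codes and rng.random() < config.paralog_rate:
                host = member_codes[rng.integers(len(member_codes))]
                members[host].append(f"{fam}.2")
            core = _random_peptide(rng, config.core_length)
            sequences = {}
            for code in member_codes:
                for pid in members[code]:
                    sequences[f"{code}_{pid}"] = _mutate(
                        rng, core, config.mutation_rate
                    )
            families[fam] = {
                "class": cls,
                "members": members,
                "sequences": sequences,
            }
    return families


def families_to_newick(families: Mapping[str, dict]) -> str:
    """One left-nested tree per family, in family order."""
    lines = []
    for fam, info in families.items():
        labels = [
            f"{code}_{pid}"
            for code, pids in info["members"].items()
            for pid in pids
        ]
        tree = labels[0]
        for label in labels[1:]:
            tree = f"({tree},{label})"
        lines.append(tree + ";")
    return "\n".join(lines) + "\n"


def write_proteomes(
    families: Mapping[str, dict], groups: SpeciesGroups, outdir: Path
) -> dict[str, Path]:
    """One wrapped FASTA per clustered species."""
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for tag in groups.clustered_species:
        records = []
        for fam, info in families.items():
            for pid in info["members"].get(tag.code, []):
                records.append(
                    orthology.ProteinRecord(
                        tag, pid, info["sequences"][f"{tag.code}_{pid}"]
                    )
                )
        path = outdir / f"{tag.code}.fasta"
        orthology.write_proteome_fasta(records, path)
        paths[tag.code] = path
    return paths


def _filtered_clusters(
    families: Mapping[str, dict], groups: SpeciesGroups, min_positive: int
) -> tuple[orthology.ClusterSet, orthology.ClusterSet]:
    """Run the same deterministic parse→filter the pipeline will run, so hit
    tables can be keyed by the cluster ids homology queries would carry."""
    newick = families_to_newick(families)
    clusters = orthology.parse_cluster_trees(newick, groups)
    return (
        orthology.task_filter(clusters, groups, min_positive),
        orthology.task9_filter(clusters, groups),
    )


def _family_of_cluster(cluster: orthology.Orthocluster) -> str:
    # all member protein ids share the family stem (paralogs add ".n")
    return cluster.members[0][1].split(".")[0]


# ---------------------------------------------------------------------------
# Hit tables
# ---------------------------------------------------------------------------

def simulate_hit_tables(
    config: SimConfig, families: Mapping[str, dict]
) -> dict[str, list[str]]:
    """BLAST-tabular rows for the Task3 candidate queries and the Task9
    reference queries; returns {"task3": lines, "task9": lines}.

    Per query and species, the best-hit E-value is 10**Normal(mu, sigma) from
    the class/group model; trait-specific queries get no trait-negative rows
    at all; decoy secondary hits with worse E exercise best-hit reduction.
    """
    groups = config.groups
    rng = config.rng(2)
    task3, task9 = _filtered_clusters(
        families, groups, config.min_positive_present
    )
    group_members = {
        "A": [t.code for t in groups.group_a],
        "B": [t.code for t in groups.group_b],
        "C": [t.code for t in groups.group_c],
    }

    def rows_for(clusters: orthology.ClusterSet) -> list[str]:
        lines = []
        for cl in clusters:
            fam = _family_of_cluster(cl)
            cls = families[fam]["class"]
            model = config.evalue_model[cls]
            for grp in ("A", "B", "C"):
                params = model.get(grp)
                if params is None:
                    continue
                mu, sigma = params
                codes = group_members[grp]
                kept = [
                    c
                    for c in codes
                    if grp == "C" or rng.random() >= config.hit_dropout
                ]
                if grp == "A" and not kept:
                    kept = codes[:1]
                for code in kept:
                    log10e = rng.normal(mu, sigma)
                    e = 10.0 ** max(log10e, -300.0)
                    lines.append(_blast_line(cl.cluster_id, code, fam, e, config))
                    if rng.random() < config.decoy_rate:
                        e2 = e * 10.0 ** rng.uniform(1.0, 5.0)
                        lines.append(
                            _blast_line(cl.cluster_id, code, fam + "_d", e2, config)
                        )
        return lines

    return {"task3": rows_for(task3), "task9": rows_for(task9)}


def _blast_line(
    query: str, code: str, pid: str, evalue: float, config: SimConfig
) -> str:
    L = config.core_length
    bits = max(30.0, -2.0 * np.log10(max(evalue, 1e-300)))
    return "\t".join(
        [
            query, f"{code}_{pid}", "55.0", str(L), "0", "0",
            "1", str(L), "1", str(L), f"{evalue:.3e}", f"{bits:.1f}",
        ]
    )


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

def _treatment_columns(config: SimConfig) -> list[str]:
    required: list[str] = []
    for crit in expr_mod.load_criteria():
        for col in crit.test_columns + crit.control_columns:
            if col not in required:
                required.append(col)
    fillers = [
        f"Condition {i:03d}" for i in range(1, config.n_treatments + 1)
    ]
    columns = required + fillers[: max(config.n_treatments - len(required), 0)]
    return columns


def assign_expression_truth(
    config: SimConfig, families: Mapping[str, dict]
) -> dict[str, dict]:
    """Assign a trait-positive-model gene and induced criteria per family
    (trait classes only); returns family_id → {gene_id, induced_criteria}."""
    rng = config.rng(3)
    mtr_code = config.groups.clustered_species[0].code
    truth: dict[str, dict] = {}
    for fam, info in families.items():
        if mtr_code not in info["members"]:
            continue
        gene = fam.replace("FAM", "GENE")
        induced: list[str] = []
        if info["class"] in ("trait_specific", "trait_biased"):
            if rng.random() < config.induced_fraction:
                for name, p in config.criterion_probs.items():
                    if rng.random() < p:
                        induced.append(name)
                if not ({"LCM", "AM"} & set(induced)):
                    induced.append("LCM")
                if "AM" in induced and "P-repressed" in induced:
                    # criterion 6's control is criterion 2's test-control;
                    # planting both would cancel the AM ratio
                    induced.remove("P-repressed")
        truth[fam] = {"gene_id": gene, "induced_criteria": induced}
    return truth


def simulate_expression(
    config: SimConfig, families: Mapping[str, dict]
) -> tuple["np.ndarray", list[str], list[str], list[dict], dict[str, dict]]:
    """Build the probesets × treatments matrix plus probeset metadata.

    Returns (values, probeset_ids, treatment_names, meta rows, expression
    truth).  Induced criteria multiply their test columns by the planted
    fold; every cell carries multiplicative lognormal noise; a configurable
    fraction of probesets is made unreliable (suffix or low identity) to
    exercise curation.
    """
    expr_truth = assign_expression_truth(config, families)
    rng = config.rng(4)
    columns = _treatment_columns(config)
    criteria = {c.name: c for c in expr_mod.load_criteria()}

    probeset_ids: list[str] = []
    meta_rows: list[dict] = []
    row_gene: list[str] = []
    row_induced: list[list[str]] = []
    counter = 0
    for fam in expr_truth:
        gene = expr_truth[fam]["gene_id"]
        induced = expr_truth[fam]["induced_criteria"]
        n_probes = 1 + (1 if rng.random() < config.extra_probeset_rate else 0)
        for _ in range(n_probes):
            counter += 1
            bad = rng.random() < config.bad_probeset_rate
            suffix_bad = bad and rng.random() < 0.5
            if suffix_bad:
                kind = "_x_at" if rng.random() < 0.5 else "_s_at"
                pid = f"mtr.{counter}{kind}"
                identity = float(np.round(rng.uniform(90, 100), 1))
            else:
                pid = f"mtr.{counter}_at"
                identity = float(
                    np.round(rng.uniform(40, 69) if bad else rng.uniform(90, 100), 1)
                )
            probeset_ids.append(pid)
            meta_rows.append(
                {"probeset_id": pid, "gene_id": gene, "identity_pct": identity,
                 "planted_bad": bool(bad)}
            )
            row_gene.append(gene)
            row_induced.append(induced)

    n_rows, n_cols = len(probeset_ids), len(columns)
    baseline = np.exp(
        rng.normal(config.baseline_log_mean, config.baseline_log_sigma, n_rows)
    )
    noise = (
        np.exp(rng.normal(0.0, config.noise_sigma, (n_rows, n_cols)))
        if config.noise_sigma > 0
        else np.ones((n_rows, n_cols))
    )
    values = baseline[:, None] * noise
    col_index = {c: i for i, c in enumerate(columns)}
    for i, induced in enumerate(row_induced):
        for name in induced:
            for col in criteria[name].test_columns:
                values[i, col_index[col]] *= config.planted_fold
    return values, probeset_ids, columns, meta_rows, expr_truth


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------

def simulate_promoters(
    config: SimConfig, expr_truth: Mapping[str, dict]
) -> tuple[dict[str, str], dict[str, list[dict]]]:
    """Random promoters with elements planted into the induced subset.

    Returns (gene → sequence, gene → planted-site records).  The GCC
    palindrome is planted within the proximal window next to the start codon;
    the extended CTTC element is planted in either orientation.
    """
    L = config.promoter_length
    for name, pattern in PLANTED_ELEMENTS.items():
        if len(pattern) > L:
            raise ValueError(f"motif {name} longer than the promoter")
    rng = config.rng(5)
    bases = np.array(list("ACGT"))
    probs = np.array([config.base_composition[b] for b in "ACGT"])

    genes = [t["gene_id"] for t in expr_truth.values()]
    genes += [f"BG{i:04d}" for i in range(1, config.n_background_genes + 1)]
    induced_fg = {
        t["gene_id"]
        for t in expr_truth.values()
        if {"LCM", "AM"} & set(t["induced_criteria"])
    }

    promoters: dict[str, str] = {}
    planted: dict[str, list[dict]] = {}
    for gene in genes:
        seq = rng.choice(bases, size=L, p=probs)
        sites = []
        if gene in induced_fg:
            for name, pattern in PLANTED_ELEMENTS.items():
                if rng.random() >= config.plant_rate:
                    continue
                k = len(pattern)
                insert = pattern
                strand = "+"
                if name == "CTTC-extended" and rng.random() < 0.5:
                    insert = reverse_complement(pattern)
                    strand = "-"
                if name == "GCC-palindrome":
                    lo = max(L - k - (config.proximal_window - 2), 1)
                    start = int(rng.integers(lo, L - k + 2))
                else:
                    start = int(rng.integers(1, L - k + 2))
                seq[start - 1 : start - 1 + k] = list(insert)
                sites.append({"motif": name, "start": start, "strand": strand})
        promoters[gene] = "".join(seq)
        if sites:
            planted[gene] = sites
    return promoters, planted


# ---------------------------------------------------------------------------
# Bundle emission
# ---------------------------------------------------------------------------

def emit_fixture_bundle(
    config: SimConfig, outdir: str | Path, force: bool = False
) -> Path:
    """Write every pipeline input plus a truth manifest into ``outdir``.

    Identical configs produce byte-identical bundles.  Refuses to write into
    an existing non-empty directory unless ``force``.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty (use force)")
    outdir.mkdir(parents=True, exist_ok=True)

    groups = config.groups
    groups.to_yaml(outdir / "groups.yaml")

    families = simulate_families(config)
    write_proteomes(families, groups, outdir / "proteomes")
    (outdir / "clusters.nwk").write_text(families_to_newick(families))

    hits = simulate_hit_tables(config, families)
    (outdir / "hits").mkdir(exist_ok=True)
    for name, lines in hits.items():
        (outdir / "hits" / f"{name}.tsv").write_text(
            "\n".join(lines) + ("\n" if lines else "")
        )

    values, probesets, columns, meta_rows, expr_truth = simulate_expression(
        config, families
    )
    with open(outdir / "expression.tsv", "w") as fh:
        fh.write("Probeset\t" + "\t".join(columns) + "\n")
        for pid, row in zip(probesets, values):
            fh.write(pid + "\t" + "\t".join(f"{v:.4f}" for v in row) + "\n")
    with open(outdir / "probeset_meta.tsv", "w") as fh:
        fh.write("probeset_id\tgene_id\tidentity_pct\n")
        for m in meta_rows:
            fh.write(f"{m['probeset_id']}\t{m['gene_id']}\t{m['identity_pct']}\n")

    promoters, planted = simulate_promoters(config, expr_truth)
    with open(outdir / "promoters.fasta", "w") as fh:
        for gene, seq in promoters.items():
            fh.write(f">{gene}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")

    manifest = {
        "config": _config_dict(config),
        "families": {
            fam: {
                "class": info["class"],
                "members": info["members"],
                "gene_id": expr_truth.get(fam, {}).get("gene_id"),
                "induced_criteria": expr_truth.get(fam, {}).get(
                    "induced_criteria", []
                ),
            }
            for fam, info in families.items()
        },
        "planted_bad_probesets": sorted(
            m["probeset_id"] for m in meta_rows if m["planted_bad"]
        ),
        "foreground_genes": sorted(
            t["gene_id"]
            for t in expr_truth.values()
            if {"LCM", "AM"} & set(t["induced_criteria"])
        ),
        "planted_motifs": planted,
    }
    (outdir / "truth.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    logger.info("fixture bundle written to %s", outdir)
    return outdir


def _config_dict(config: SimConfig) -> dict:
    out = dataclasses.asdict(config)
    out["groups"] = config.groups.to_dict()
    return out


def cluster_class_map(manifest: Mapping) -> dict[str, str]:
    """Map pipeline cluster ids (TASK3_n / TASK9_n) to planted family classes.

    Re-derives the filter outcomes directly from the truth manifest's member
    lists (a brute-force membership scan independent of the orthology module),
    relying only on the deterministic file order of the families.
    """
    groups = SpeciesGroups.from_dict(manifest["config"]["groups"])
    min_positive = int(manifest["config"]["min_positive_present"])
    positive = {t.code for t in groups.positive_clustered}
    negative = groups.codes("C")
    clustered = groups.codes("clustered")
    out: dict[str, str] = {}
    j3 = j9 = 0
    for fam in sorted(manifest["families"]):
        info = manifest["families"][fam]
        codes = set(info["members"])
        if not (codes & negative) and len(codes & positive) >= min_positive:
            j3 += 1
            out[f"TASK{min_positive}_{j3}"] = info["class"]
        if clustered <= codes:
            j9 += 1
            out[f"TASK9_{j9}"] = info["class"]
    return out


def load_truth(bundle_dir: str | Path) -> dict:
    """Load and sanity-check a bundle's truth manifest."""
    bundle_dir = Path(bundle_dir)
    manifest = json.loads((bundle_dir / "truth.json").read_text())
    for fname in ("clusters.nwk", "expression.tsv", "probeset_meta.tsv",
                  "promoters.fasta", "groups.yaml"):
        if not (bundle_dir / fname).exists():
            raise FileNotFoundError(f"bundle is missing {fname}")
    return manifest
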