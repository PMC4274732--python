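"""Proteome and orthocluster handling: parsing and presence/absence subtraction.

An *orthocluster* is one group of orthologous/paralogous proteins, produced by
guide-tree-based hierarchical orthology inference and serialized as one Newick
tree per line whose leaves are species-prefixed protein ids (``Mtr_D3J162``).
The subtraction filters retain clusters that are represented in at least X of
the trait-positive clustered species but contain no member of any
trait-negative species (TaskX), or in every clustered species (Task9, the
housekeeping reference set).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .species import SpeciesGroups, SpeciesTag

logger = logging.getLogger(__name__)

#: IUPAC amino-acid letters plus ambiguity/stop characters tolerated on input.
AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWYBZJUOX*")


class FastaParseError(ValueError):
    pass


class NewickParseError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence tagged with its species."""

    species: SpeciesTag
    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.protein_id}")
        bad = set(self.sequence.upper()) - AA_LETTERS
        if bad:
            raise ValueError(
                f"non-amino-acid letters {sorted(bad)} in {self.protein_id}"
            )


@dataclass
class Orthocluster:
    """One protein cluster: id plus (species, protein_id) members."""

    cluster_id: str
    members: list[tuple[SpeciesTag, str]]
    source_tree: str | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"cluster {self.cluster_id} has no members")
        seen = set()
        for sp, pid in self.members:
            key = (sp.code, pid)
            if key in seen:
                raise ValueError(
                    f"duplicate member {sp.code}_{pid} in cluster {self.cluster_id}"
                )
            seen.add(key)

    @property
    def species_codes(self) -> set[str]:
        return {sp.code for sp, _ in self.members}

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ClusterSet:
    """An ordered collection of orthoclusters with a provenance label."""

    clusters: list[Orthocluster]
    provenance: str = "all"

    def __post_init__(self) -> None:
        ids = [c.cluster_id for c in self.clusters]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate cluster ids: {dupes}")

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self) -> Iterator[Orthocluster]:
        return iter(self.clusters)

    def by_id(self) -> dict[str, Orthocluster]:
        return {c.cluster_id: c for c in self.clusters}


# ---------------------------------------------------------------------------
# FASTA proteomes
# ---------------------------------------------------------------------------

def read_proteomes(
    paths: Mapping[SpeciesTag | str, str | Path],
) -> list[ProteinRecord]:
    """Read one FASTA file per species into tagged protein records.

    Raises on a duplicate protein id within a species; an empty file yields
    an empty set for that species with a logged warning.
    """
    records: list[ProteinRecord] = []
    for species, path in paths.items():
        tag = species if isinstance(species, SpeciesTag) else SpeciesTag(species)
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"proteome for {tag.code}: {path}")
        seen: set[str] = set()
        count = 0
        for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
            if not rec.id or len(rec.seq) == 0:
                raise FastaParseError(
                    f"{path}: record {i} is malformed (empty id or sequence)"
                )
            if rec.id in seen:
                raise FastaParseError(
                    f"{path}: duplicate protein id {rec.id!r} in species {tag.code}"
                )
            seen.add(rec.id)
            try:
                records.append(ProteinRecord(tag, rec.id, str(rec.seq).upper()))
            except ValueError as exc:
                raise FastaParseError(f"{path}: record {i} ({rec.id}): {exc}") from exc
            count += 1
        if count == 0:
            logger.warning("proteome %s (%s) contains no sequences", tag.code, path)
        logger.info("read %d proteins for %s", count, tag.code)
    return records


def patch_proteome(
    proteome: Iterable[ProteinRecord],
    extras: Sequence[ProteinRecord],
    known_species: Iterable[SpeciesTag | str] | None = None,
) -> list[ProteinRecord]:
    """Add missing sequences to a proteome (e.g. proteins absent from a
    database release), replacing any record that shares (species, id)."""
    if known_species is not None:
        known = {s.code if isinstance(s, SpeciesTag) else s for s in known_species}
        for rec in extras:
            if rec.species.code not in known:
                raise ValueError(
                    f"patch record {rec.protein_id} has unknown species "
                    f"tag {rec.species.code!r}"
                )
    out = list(proteome)
    index = {(r.species.code, r.protein_id): i for i, r in enumerate(out)}
    for rec in extras:
        key = (rec.species.code, rec.protein_id)
        if key in index:
            logger.info(
                "patch replaces existing record %s_%s", rec.species.code, rec.protein_id
            )
            out[index[key]] = rec
        else:
            index[key] = len(out)
            out.append(rec)
    return out


def write_proteome_fasta(
    records: Iterable[ProteinRecord], path: str | Path, prefix_species: bool = False
) -> None:
    """Write records as FASTA wrapped at 60 columns."""
    seqs = []
    for r in records:
        name = f"{r.species.code}_{r.protein_id}" if prefix_species else r.protein_id
        seqs.append(SeqRecord(Seq(r.sequence), id=name, description=""))
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


# ---------------------------------------------------------------------------
# Newick cluster trees
# ---------------------------------------------------------------------------

def parse_cluster_trees(
    source: str | Path,
    groups: SpeciesGroups,
    provenance: str = "all",
    id_prefix: str = "CL",
) -> ClusterSet:
    """Parse a one-tree-per-line Newick file into a ClusterSet.

    Each tree becomes one cluster whose members are its leaves; inner labels
    and branch lengths are ignored.  A bare ``label;`` line (no parentheses)
    becomes a single-member cluster.  Ids are ``<prefix>_<ordinal>`` in file
    order and stable under re-runs.
    """
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)
    clusters: list[Orthocluster] = []
    ordinal = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        ordinal += 1
        labels = _leaf_labels(line, lineno)
        members = []
        for label in labels:
            tag, pid = groups.resolve_label(label)
            members.append((tag, pid))
        clusters.append(
            Orthocluster(f"{id_prefix}_{ordinal}", members, source_tree=line)
        )
    return ClusterSet(clusters, provenance=provenance)


def _leaf_labels(line: str, lineno: int) -> list[str]:
    if line.count("(") != line.count(")"):
        raise NewickParseError(f"line {lineno}: unbalanced parentheses")
    if "(" not in line:
        label = line.rstrip(";").strip()
        if not label:
            raise NewickParseError(f"line {lineno}: empty tree")
        return [label]
    try:
        tree = dendropy.Tree.get(
            data=line if line.endswith(";") else line + ";",
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"line {lineno}: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if not labels:
        raise NewickParseError(f"line {lineno}: tree has no labelled leaves")
    return labels


# ---------------------------------------------------------------------------
# Presence/absence subtraction filters
# ---------------------------------------------------------------------------

def task_filter(
    clusters: ClusterSet, groups: SpeciesGroups, min_positive: int
) -> ClusterSet:
    """Retain clusters with ≥``min_positive`` distinct trait-positive clustered
    species and zero trait-negative members (the TaskX subtraction).

    Species presence counts *distinct species*; paralogs within a cluster do
    not inflate the count.
    """
    positive = {t.code for t in groups.positive_clustered}
    negative = groups.codes("C")
    if not 1 <= min_positive <= len(positive):
        raise ValueError(
            f"min_positive must be in [1, {len(positive)}], got {min_positive}"
        )
    kept: list[Orthocluster] = []
    for cl in clusters:
        codes = cl.species_codes
        if codes & negative:
            continue
        if len(codes & positive) >= min_positive:
            kept.append(cl)
    provenance = f"Task{min_positive}"
    relabelled = [
        Orthocluster(f"TASK{min_positive}_{j}", cl.members, cl.source_tree)
        for j, cl in enumerate(kept, start=1)
    ]
    logger.info("%s retains %d of %d clusters", provenance, len(kept), len(clusters))
    return ClusterSet(relabelled, provenance=provenance)


def task9_filter(clusters: ClusterSet, groups: SpeciesGroups) -> ClusterSet:
    """Retain clusters with ≥1 member from *every* clustered species
    (the ubiquitously conserved, housekeeping reference set)."""
    required = groups.codes("clustered")
    kept = [cl for cl in clusters if required <= cl.species_codes]
    relabelled = [
        Orthocluster(f"TASK9_{j}", cl.members, cl.source_tree)
        for j, cl in enumerate(kept, start=1)
    ]
    logger.info("Task9 retains %d of %d clusters", len(kept), len(clusters))
    return ClusterSet(relabelled, provenance="Task9")


def representation_table(
    clusters: ClusterSet,
    groups: SpeciesGroups,
    species: Sequence[SpeciesTag] | None = None,
) -> pd.DataFrame:
    """Per-species cluster counts and percentages (columns: species, count,
    percent); ``df.attrs['total']`` holds the total cluster count."""
    if species is None:
        species = groups.clustered_species
    total = len(clusters)
    rows = []
    for tag in species:
        count = sum(1 for cl in clusters if tag.code in cl.species_codes)
        percent = round(100 * count / total) if total else 0
        rows.append({"species": tag.code, "count": count, "percent": percent})
    df = pd.DataFrame(rows, columns=["species", "count", "percent"])
    df.attrs["total"] = total
    return df


def write_cluster_table(clusters: ClusterSet, path: str | Path) -> None:
    """TSV with one row per cluster: id, size, species list, member labels."""
    rows = []
    for cl in clusters:
        rows.append(
            {
                "cluster_id": cl.cluster_id,
                "n_members": len(cl),
                "species": ",".join(sorted(cl.species_codes)),
                "members": ",".join(f"{sp.code}_{pid}" for sp, pid in cl.members),
            }
        )
    pd.DataFrame(
        rows, columns=["cluster_id", "n_members", "species", "members"]
    ).to_csv(path, sep="\t", index=False)
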