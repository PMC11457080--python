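"""Readers/writers for the pipeline's tabular formats plus GFF3 annotation filters.

All tables are UTF-8, tab-delimited text; lines starting with ``#`` are
ignored. The homology table uses one line per group::

    group_id <TAB> species#gene[,species#gene...]

Term maps are GMT-like::

    term_id <TAB> term name <TAB> gene <TAB> gene ...

GFF3 handling is limited to the gene -> mRNA -> exon/CDS hierarchy and the
ID/Parent attributes; the filters reproduce the standard annotation
preparation steps (keep the longest isoform per gene, drop genes whose CDS
encodes fewer than a minimum number of amino acids, remove a kill list of
gene IDs). Coordinates are GFF3 1-based inclusive throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from gffutils.feature import feature_from_line

__all__ = [
    "FormatError",
    "CountMatrix",
    "HomologyTable",
    "Term",
    "TermMap",
    "read_count_matrix",
    "write_count_matrix",
    "read_sample_table",
    "write_sample_table",
    "validate_sample_table",
    "read_homology_table",
    "write_homology_table",
    "read_term_map",
    "write_term_map",
    "gff_keep_longest_isoform",
    "gff_filter_min_orf",
    "gff_remove_kill_list",
]

TREATMENTS = ("HL", "LL")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class CountMatrix:
    """Integer read counts for one species, genes x samples, with gene lengths.

    Parameters
    ----------
    species_id:
        Label of the species the matrix belongs to.
    counts:
        DataFrame of non-negative integers, index = gene IDs (unique, order
        preserved), columns = sample IDs (unique).
    gene_lengths:
        Series of positive integers (nt), aligned to ``counts.index``.
    """

    species_id: str
    counts: pd.DataFrame
    gene_lengths: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene ID {dup!r} in count matrix")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise FormatError(f"duplicate sample ID {dup!r} in count matrix")
        self.counts.index.name = "gene_id"
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            raise FormatError("counts must be integers")
        if (values < 0).any():
            raise FormatError("counts must be non-negative")
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any():
            missing = self.gene_lengths.index[self.gene_lengths.isna()][0]
            raise FormatError(f"missing length for gene {missing!r}")
        self.gene_lengths = self.gene_lengths.astype(np.int64)
        if (self.gene_lengths < 1).any():
            raise FormatError("gene lengths must be >= 1")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]


@dataclass
class HomologyTable:
    """Homology groups mapping group IDs to (species, gene) members."""

    groups: Dict[str, List[Tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: Dict[Tuple[str, str], str] = {}
        for gid, members in self.groups.items():
            for sp, gene in members:
                key = (sp, gene)
                if key in seen and seen[key] != gid:
                    raise FormatError(
                        f"gene {sp}#{gene} listed in two groups: "
                        f"{seen[key]!r} and {gid!r}"
                    )
                seen[key] = gid

    @property
    def group_ids(self) -> List[str]:
        return list(self.groups)

    def members(self, group_id: str) -> List[Tuple[str, str]]:
        return self.groups[group_id]

    def species_genes(self, group_id: str, species_id: str) -> List[str]:
        return [g for sp, g in self.groups[group_id] if sp == species_id]

    def species_present(self, group_id: str) -> set:
        return {sp for sp, _ in self.groups[group_id]}

    def copy_number(self, group_id: str, species_id: str) -> int:
        return len(self.species_genes(group_id, species_id))

    def __len__(self) -> int:
        return len(self.groups)


@dataclass(frozen=True)
class Term:
    """A named gene set in the reference-species namespace."""

    term_id: str
    name: str
    genes: frozenset

    def __post_init__(self) -> None:
        if not self.genes:
            raise FormatError(f"term {self.term_id!r} has an empty gene set")


TermMap = Dict[str, Term]


def _data_lines(path) -> Iterable[Tuple[int, str]]:
    """Yield (1-based line number, stripped line), skipping comments/blanks."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

def read_count_matrix(path, lengths_path, species_id: str = "") -> CountMatrix:
    """Read a gene x sample count TSV plus a gene-length TSV.

    The count file has a header row of sample IDs and gene IDs in the first
    column; input gene order is preserved. A missing length for any gene is
    an error, as are non-integer counts and duplicate gene IDs.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, comment="#", index_col=0)
    values = np.empty(raw.shape, dtype=np.int64)
    for j, col in enumerate(raw.columns):
        for i, cell in enumerate(raw[col]):
            try:
                values[i, j] = int(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-integer count {cell!r} at row {i + 2} "
                    f"(gene {raw.index[i]!r}), column {col!r} in {path}"
                ) from None
    counts = pd.DataFrame(values, index=raw.index.astype(str), columns=raw.columns)
    counts.index.name = "gene_id"
    lengths = pd.read_csv(
        lengths_path, sep="\t", comment="#", index_col=0
    ).iloc[:, 0]
    lengths.index = lengths.index.astype(str)
    if not species_id:
        species_id = Path(path).stem
    return CountMatrix(species_id=species_id, counts=counts, gene_lengths=lengths)


def write_count_matrix(cm: CountMatrix, path, lengths_path=None) -> None:
    cm.counts.to_csv(path, sep="\t")
    if lengths_path is not None:
        cm.gene_lengths.rename("length").to_frame().to_csv(lengths_path, sep="\t")


# ---------------------------------------------------------------------------
# sample table
# ---------------------------------------------------------------------------

def validate_sample_table(df: pd.DataFrame, for_de: bool = False) -> pd.DataFrame:
    """Validate sample metadata (sample_id, species_id, treatment, replicate)."""
    required = ["sample_id", "species_id", "treatment", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"sample table missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample ID {dup!r}")
    bad = set(df["treatment"]) - set(TREATMENTS)
    if bad:
        raise FormatError(f"unknown treatments {sorted(bad)}; expected {TREATMENTS}")
    if for_de:
        sizes = df.groupby(["species_id", "treatment"]).size()
        small = sizes[sizes < 2]
        if len(small):
            raise FormatError(
                f"fewer than 2 replicates in cells: {list(small.index)}"
            )
    return df.reset_index(drop=True)


def read_sample_table(path, for_de: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    df["replicate"] = df["replicate"].astype(int)
    return validate_sample_table(df, for_de=for_de)


def write_sample_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# homology table
# ---------------------------------------------------------------------------

def read_homology_table(path) -> HomologyTable:
    """Parse the one-group-per-line homology TSV dialect in a single pass."""
    groups: Dict[str, List[Tuple[str, str]]] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(
                f"line {lineno}: expected 'group_id<TAB>members', got {line!r}"
            )
        gid, member_field = parts
        if gid in groups:
            raise FormatError(f"line {lineno}: duplicate group ID {gid!r}")
        members = []
        for token in member_field.split(","):
            if "#" not in token:
                raise FormatError(
                    f"line {lineno}: member token {token!r} lacks 'species#gene'"
                )
            sp, gene = token.split("#", 1)
            members.append((sp, gene))
        groups[gid] = members
    return HomologyTable(groups=groups)


def write_homology_table(table: HomologyTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gid, members in table.groups.items():
            tokens = ",".join(f"{sp}#{g}" for sp, g in members)
            fh.write(f"{gid}\t{tokens}\n")


# ---------------------------------------------------------------------------
# term maps (GMT-like)
# ---------------------------------------------------------------------------

def read_term_map(path) -> TermMap:
    terms: TermMap = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(
                f"line {lineno}: expected 'term_id<TAB>name<TAB>gene...'"
            )
        tid, name, genes = parts[0], parts[1], parts[2:]
        if tid in terms:
            raise FormatError(f"line {lineno}: duplicate term ID {tid!r}")
        terms[tid] = Term(term_id=tid, name=name, genes=frozenset(genes))
    return terms


def write_term_map(terms: TermMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in terms.values():
            genes = "\t".join(sorted(term.genes))
            fh.write(f"{term.term_id}\t{term.name}\t{genes}\n")


# ---------------------------------------------------------------------------
# GFF3 filters
# ---------------------------------------------------------------------------

def _parse_gff(gff_in):
    """Parse GFF3 lines, returning (lines, features) in file order.

    ``features[i]`` is None for comment/blank lines; otherwise a gffutils
    Feature for line ``lines[i]``.
    """
    lines: List[str] = []
    feats = []
    with open(gff_in, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            lines.append(line)
            if not line or line.startswith("#"):
                feats.append(None)
            else:
                feats.append(feature_from_line(line))
    return lines, feats


def _hierarchy(feats):
    """Index genes, mRNAs and children; validate mRNA parentage."""
    gene_ids = {}
    mrnas = {}  # mRNA id -> (gene id, summed CDS length, order index)
    for idx, f in enumerate(feats):
        if f is None:
            continue
        if f.featuretype == "gene":
            fid = f.attributes.get("ID", [None])[0]
            gene_ids[fid] = idx
    for idx, f in enumerate(feats):
        if f is None or f.featuretype != "mRNA":
            continue
        fid = f.attributes.get("ID", [None])[0]
        parents = f.attributes.get("Parent", [])
        parent = next((p for p in parents if p in gene_ids), None)
        if parent is None:
            raise FormatError(f"mRNA {fid!r} has no parent gene")
        mrnas[fid] = {"gene": parent, "cds": 0, "order": idx}
    for f in feats:
        if f is None or f.featuretype != "CDS":
            continue
        for p in f.attributes.get("Parent", []):
            if p in mrnas:
                mrnas[p]["cds"] += f.end - f.start + 1
    return gene_ids, mrnas


def _write_filtered(lines, feats, keep_genes, keep_mrnas, gff_out) -> None:
    """Echo input lines whose feature survives the filter (order preserved)."""
    with open(gff_out, "w", encoding="utf-8") as fh:
        for line, f in zip(lines, feats):
            if f is None:
                fh.write(line + "\n")
                continue
            if f.featuretype == "gene":
                if f.attributes.get("ID", [None])[0] in keep_genes:
                    fh.write(line + "\n")
            elif f.featuretype == "mRNA":
                if f.attributes.get("ID", [None])[0] in keep_mrnas:
                    fh.write(line + "\n")
            else:
                parents = f.attributes.get("Parent", [])
                if any(p in keep_mrnas or p in keep_genes for p in parents):
                    fh.write(line + "\n")


def gff_keep_longest_isoform(gff_in, gff_out) -> Dict[str, int]:
    """Retain exactly one mRNA per gene: maximal summed CDS length.

    Ties are broken by file order (first-encountered isoform kept). Child
    features of dropped isoforms are removed. Returns a summary of feature
    counts before/after.
    """
    lines, feats = _parse_gff(gff_in)
    gene_ids, mrnas = _hierarchy(feats)
    best: Dict[str, Tuple[int, int, str]] = {}
    for mid, info in mrnas.items():
        cur = best.get(info["gene"])
        # strictly longer CDS wins; equal keeps earlier file order
        cand = (-info["cds"], info["order"], mid)
        if cur is None or cand < cur:
            best[info["gene"]] = cand
    keep_mrnas = {mid for _, _, mid in best.values()}
    _write_filtered(lines, feats, set(gene_ids), keep_mrnas, gff_out)
    return {
        "genes_in": len(gene_ids),
        "genes_out": len(gene_ids),
        "mrnas_in": len(mrnas),
        "mrnas_out": len(keep_mrnas),
    }


def gff_filter_min_orf(
    gff_in, gff_out, min_aa: int = 30, stop_included: bool = False
) -> Dict[str, int]:
    """Drop genes whose retained CDS encodes fewer than ``min_aa`` amino acids.

    Protein length = (summed CDS length - 3)/3 when the annotation includes
    the stop codon (``stop_included=True``), else summed CDS/3. Genes at
    exactly ``min_aa`` survive. A CDS length not divisible by 3 triggers a
    warning and the gene is retained.
    """
    lines, feats = _parse_gff(gff_in)
    gene_ids, mrnas = _hierarchy(feats)
    gene_cds: Dict[str, int] = {g: 0 for g in gene_ids}
    for info in mrnas.values():
        gene_cds[info["gene"]] += info["cds"]
    keep_genes = set()
    for gene, cds in gene_cds.items():
        if cds % 3 != 0:
            warnings.warn(
                f"gene {gene!r}: CDS length {cds} not divisible by 3; retained"
            )
            keep_genes.add(gene)
            continue
        aa = (cds - 3) // 3 if stop_included else cds // 3
        if cds == 0 or aa >= min_aa:
            keep_genes.add(gene)
    keep_mrnas = {m for m, info in mrnas.items() if info["gene"] in keep_genes}
    _write_filtered(lines, feats, keep_genes, keep_mrnas, gff_out)
    return {
        "genes_in": len(gene_ids),
        "genes_out": len(keep_genes),
        "genes_removed": len(gene_ids) - len(keep_genes),
    }


def gff_remove_kill_list(
    gff_in, ids: Sequence[str], gff_out
) -> Dict[str, object]:
    """Remove listed gene IDs and their descendants; unknown IDs warn only."""
    lines, feats = _parse_gff(gff_in)
    gene_ids, mrnas = _hierarchy(feats)
    kill = set(ids)
    unknown = sorted(kill - set(gene_ids))
    if unknown:
        warnings.warn(f"kill list IDs not in annotation: {unknown}")
    keep_genes = set(gene_ids) - kill
    keep_mrnas = {m for m, info in mrnas.items() if info["gene"] in keep_genes}
    _write_filtered(lines, feats, keep_genes, keep_mrnas, gff_out)
    return {
        "genes_in": len(gene_ids),
        "genes_out": len(keep_genes),
        "unknown_ids": unknown,
    }
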