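"""Readers and writers for the tabular formats the pipeline touches.

Everything here is deliberately strict: malformed lines fail with the line
number, duplicate identifiers fail by name, and every reader validates the
invariants of the record type it builds.  The only formats involved are
FASTA (used solely for coding-sequence lengths), the 12-column tabular
homology-hit dialect, and plain TSV for the KO hierarchy, read counts and
all result tables.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import typing
from dataclasses import dataclass, field
from pathlib import Path

from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

#: Top-level KEGG categories covered by the protein-count and expression
#: analyses; everything else (e.g. organismal systems, human diseases) is
#: dropped when the analyzed-only filter is on.
ANALYZED_CATEGORIES = (
    "Metabolism",
    "Genetic Information Processing",
    "Environmental Information Processing",
    "Cellular Processes",
)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GeneRecord:
    """A coding sequence known only by its id, library and length."""

    gene_id: str
    library: str
    length_bp: int

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"gene {self.gene_id!r}: length_bp must be >= 1")


@dataclass(frozen=True)
class HitRecord:
    """One row of the 12-column tabular homology-hit dialect.

    Coordinates are 1-based inclusive as in the dialect; they are carried
    for provenance but never used in any computation.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: evalue < 0")
        if not math.isfinite(self.bitscore):
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: bitscore not finite")
        if not 0 <= self.pct_identity <= 100:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: pct_identity outside [0,100]")
        if min(self.qstart, self.sstart) < 1:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: 1-based coordinates must be >= 1")


@dataclass
class TaxonMap:
    """Subject-id -> taxon label resolution plus the two label sets that
    drive origin assignment (cryptophyte = putative kleptokaryon donor;
    ciliate = putative host)."""

    subject_to_taxon: dict[str, str]
    cryptophyte_labels: frozenset[str]
    ciliate_labels: frozenset[str]

    def __post_init__(self) -> None:
        self.cryptophyte_labels = frozenset(self.cryptophyte_labels)
        self.ciliate_labels = frozenset(self.ciliate_labels)
        overlap = self.cryptophyte_labels & self.ciliate_labels
        if overlap:
            raise ValueError(f"labels cannot be both cryptophyte and ciliate: {sorted(overlap)}")

    def taxon_of(self, subject_id: str) -> str:
        try:
            return self.subject_to_taxon[subject_id]
        except KeyError:
            raise KeyError(f"subject {subject_id!r} has no taxon label") from None


@dataclass
class KoHierarchy:
    """gene -> KO -> pathway -> subcategory -> category rollup maps.

    Each pathway has exactly one subcategory parent and each subcategory
    exactly one category parent; genes may carry several KOs and KOs may
    sit in several pathways.
    """

    gene_to_kos: dict[str, frozenset[str]]
    ko_to_pathways: dict[str, frozenset[str]]
    pathway_to_subcategory: dict[str, str]
    subcategory_to_category: dict[str, str]

    def kos_of(self, gene_id: str) -> frozenset[str]:
        return self.gene_to_kos.get(gene_id, frozenset())

    def units_of_gene(self, gene_id: str, level: str) -> frozenset[str]:
        """All units at `level` reachable through any KO of the gene."""
        units: set[str] = set()
        for ko in self.kos_of(gene_id):
            for pw in self.ko_to_pathways.get(ko, frozenset()):
                if level == "pathway":
                    units.add(pw)
                elif level == "subcategory":
                    units.add(self.pathway_to_subcategory[pw])
                elif level == "category":
                    units.add(self.subcategory_to_category[self.pathway_to_subcategory[pw]])
                else:
                    raise ValueError(f"unknown level {level!r}")
        return frozenset(units)

    def units(self, level: str) -> list[str]:
        if level == "pathway":
            return sorted(self.pathway_to_subcategory)
        if level == "subcategory":
            return sorted(self.subcategory_to_category)
        if level == "category":
            return sorted(set(self.subcategory_to_category.values()))
        raise ValueError(f"unknown level {level!r}")

    def restrict_to_analyzed(self, categories: tuple[str, ...] = ANALYZED_CATEGORIES) -> "KoHierarchy":
        """Drop every subcategory/pathway outside the analyzed top categories."""
        keep_sub = {s for s, c in self.subcategory_to_category.items() if c in categories}
        keep_pw = {p for p, s in self.pathway_to_subcategory.items() if s in keep_sub}
        ko_to_pw = {
            ko: frozenset(p for p in pws if p in keep_pw)
            for ko, pws in self.ko_to_pathways.items()
        }
        ko_to_pw = {ko: pws for ko, pws in ko_to_pw.items() if pws}
        return KoHierarchy(
            gene_to_kos=self.gene_to_kos,
            ko_to_pathways=ko_to_pw,
            pathway_to_subcategory={p: s for p, s in self.pathway_to_subcategory.items() if p in keep_pw},
            subcategory_to_category={s: c for s, c in self.subcategory_to_category.items() if s in keep_sub},
        )


@dataclass
class CountTable:
    """(library, gene_id) -> read count, joined with gene lengths.

    Counts are assumed to be produced upstream from properly paired reads
    at mapping quality >= 30; this container only enforces that they are
    non-negative integers and that every counted gene has a length.
    """

    counts: dict[tuple[str, str], int]
    lengths: dict[tuple[str, str], int]

    def __post_init__(self) -> None:
        for key, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for {key}")
            if key not in self.lengths:
                raise ValueError(f"counted gene {key} has no length")

    def count(self, library: str, gene_id: str) -> int:
        return self.counts.get((library, gene_id), 0)

    def length(self, library: str, gene_id: str) -> int:
        return self.lengths[(library, gene_id)]

    def genes(self, library: str) -> list[str]:
        return sorted(g for (lib, g) in self.lengths if lib == library)

    def library_total(self, library: str) -> int:
        return sum(c for (lib, _), c in self.counts.items() if lib == library)

    def libraries(self) -> list[str]:
        return sorted({lib for (lib, _) in self.lengths})

    def relabel(self, mapping: dict[str, str], genes: dict[str, set[str]] | None = None) -> "CountTable":
        """Rename libraries (optionally restricting each to a gene subset).

        Used after origin partitioning to carve the KN sub-library out of
        the chimeric host library.
        """

        def keep(lib: str, g: str) -> bool:
            return genes is None or lib not in genes or g in genes[lib]

        return CountTable(
            counts={(mapping.get(lib, lib), g): c for (lib, g), c in self.counts.items() if keep(lib, g)},
            lengths={(mapping.get(lib, lib), g): n for (lib, g), n in self.lengths.items() if keep(lib, g)},
        )


# ---------------------------------------------------------------------------
# readers


def read_fasta(path: str | Path, library: str) -> list[GeneRecord]:
    """Stream a FASTA of coding sequences into GeneRecords (lengths only).

    The gene id is the header token before the first whitespace.  Duplicate
    ids and empty sequences are hard errors; an empty file yields an empty
    list with a logged warning.
    """
    records: list[GeneRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            gene_id = header.split()[0] if header.split() else ""
            if not gene_id:
                raise FormatError(f"{path}: FASTA record with empty header")
            if gene_id in seen:
                raise FormatError(f"{path}: duplicate FASTA id {gene_id!r}")
            seen.add(gene_id)
            seq = seq.replace(" ", "")
            if not seq:
                raise FormatError(f"{path}: empty sequence for {gene_id!r}")
            records.append(GeneRecord(gene_id=gene_id, library=library, length_bp=len(seq)))
    if not records:
        logger.warning("FASTA file %s contained no records", path)
    return records


_HIT_TYPES = (str, str, float, int, int, int, int, int, int, int, float, float)


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Parse a 12-column tab-separated homology hit table (no header)."""
    hits: list[HitRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise FormatError(f"{path}:{lineno}: expected 12 columns, got {len(cols)}")
            try:
                values = [t(c) for t, c in zip(_HIT_TYPES, cols)]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparseable field ({exc})") from None
            try:
                hits.append(HitRecord(*values))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return hits


def write_hit_table(hits: typing.Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as out:
        for h in hits:
            # shortest round-trip float repr: write-then-read is the identity
            out.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pct_identity!r}\t{h.aln_len}\t"
                f"{h.mismatches}\t{h.gap_opens}\t{h.qstart}\t{h.qend}\t{h.sstart}\t{h.send}\t"
                f"{h.evalue!r}\t{h.bitscore!r}\n"
            )


def read_taxon_map(path: str | Path) -> TaxonMap:
    """TSV columns: subject_id, taxon_label, group.

    `group` is one of cryptophyte / ciliate / other and feeds the label sets.
    """
    subject_to_taxon: dict[str, str] = {}
    crypt: set[str] = set()
    cil: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(cols)}")
            subject, taxon, group = cols
            subject_to_taxon[subject] = taxon
            if group == "cryptophyte":
                crypt.add(taxon)
            elif group == "ciliate":
                cil.add(taxon)
            elif group != "other":
                raise FormatError(f"{path}:{lineno}: unknown group {group!r}")
    return TaxonMap(subject_to_taxon, frozenset(crypt), frozenset(cil))


def write_taxon_map(taxa: TaxonMap, path: str | Path) -> None:
    with open(path, "w") as out:
        for subject, taxon in sorted(taxa.subject_to_taxon.items()):
            group = (
                "cryptophyte"
                if taxon in taxa.cryptophyte_labels
                else "ciliate" if taxon in taxa.ciliate_labels else "other"
            )
            out.write(f"{subject}\t{taxon}\t{group}\n")


def read_ko_hierarchy(gene_ko_path: str | Path, hierarchy_path: str | Path) -> KoHierarchy:
    """Build the KO rollup from a gene->KO TSV and a KO/pathway/subcategory/
    category TSV.

    Genes absent from the gene->KO table stay unannotated (they are kept in
    library totals but excluded from category analyses).  A pathway listed
    under two subcategories, or a subcategory under two categories, is a
    hard error.
    """
    gene_to_kos: dict[str, set[str]] = {}
    with open(gene_ko_path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise FormatError(f"{gene_ko_path}:{lineno}: expected 2 columns, got {len(cols)}")
            gene, ko = cols
            gene_to_kos.setdefault(gene, set()).add(ko)

    ko_to_pathways: dict[str, set[str]] = {}
    pathway_to_subcategory: dict[str, str] = {}
    subcategory_to_category: dict[str, str] = {}
    with open(hierarchy_path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise FormatError(f"{hierarchy_path}:{lineno}: expected 4 columns, got {len(cols)}")
            ko, pathway, subcategory, category = cols
            ko_to_pathways.setdefault(ko, set()).add(pathway)
            if pathway in pathway_to_subcategory and pathway_to_subcategory[pathway] != subcategory:
                raise FormatError(
                    f"{hierarchy_path}:{lineno}: pathway {pathway!r} listed under both "
                    f"{pathway_to_subcategory[pathway]!r} and {subcategory!r}"
                )
            pathway_to_subcategory[pathway] = subcategory
            if subcategory in subcategory_to_category and subcategory_to_category[subcategory] != category:
                raise FormatError(
                    f"{hierarchy_path}:{lineno}: subcategory {subcategory!r} listed under two categories"
                )
            subcategory_to_category[subcategory] = category

    return KoHierarchy(
        gene_to_kos={g: frozenset(k) for g, k in gene_to_kos.items()},
        ko_to_pathways={k: frozenset(p) for k, p in ko_to_pathways.items()},
        pathway_to_subcategory=pathway_to_subcategory,
        subcategory_to_category=subcategory_to_category,
    )


def write_ko_hierarchy(hier: KoHierarchy, gene_ko_path: str | Path, hierarchy_path: str | Path) -> None:
    with open(gene_ko_path, "w") as out:
        for gene in sorted(hier.gene_to_kos):
            for ko in sorted(hier.gene_to_kos[gene]):
                out.write(f"{gene}\t{ko}\n")
    with open(hierarchy_path, "w") as out:
        for ko in sorted(hier.ko_to_pathways):
            for pw in sorted(hier.ko_to_pathways[ko]):
                sub = hier.pathway_to_subcategory[pw]
                cat = hier.subcategory_to_category[sub]
                out.write(f"{ko}\t{pw}\t{sub}\t{cat}\n")


def read_count_table(path: str | Path, genes: typing.Iterable[GeneRecord]) -> CountTable:
    """TSV columns (library, gene_id, count), joined with gene lengths.

    Genes present in `genes` but absent from the file get count 0; a counted
    gene without a length, or a negative/non-integer count, is a hard error.
    """
    lengths = {(g.library, g.gene_id): g.length_bp for g in genes}
    counts = {key: 0 for key in lengths}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(cols)}")
            library, gene_id, count_s = cols
            try:
                count = int(count_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer count {count_s!r}") from None
            if count < 0:
                raise FormatError(f"{path}:{lineno}: negative count for {gene_id!r}")
            if (library, gene_id) not in lengths:
                raise FormatError(f"{path}:{lineno}: gene {gene_id!r} in library {library!r} has no length")
            counts[(library, gene_id)] = count
    return CountTable(counts=counts, lengths=lengths)


def write_count_table(table: CountTable, path: str | Path) -> None:
    with open(path, "w") as out:
        for (library, gene_id) in sorted(table.lengths):
            out.write(f"{library}\t{gene_id}\t{table.count(library, gene_id)}\n")


# ---------------------------------------------------------------------------
# generic result-row TSV round-trip

_FLOAT_FMT = "%.6g"  # 6 significant digits for all float columns


def _render(value: object) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return _FLOAT_FMT % value
    return str(value)


def write_results_tsv(rows: typing.Sequence[object], path: str | Path, row_type: type | None = None) -> None:
    """Write a homogeneous list of result-row dataclasses as TSV.

    Column order follows the dataclass field order; floats use 6 significant
    digits so that a round-trip through `read_results_tsv` reproduces values
    at that precision.  An empty list needs `row_type` for the header.
    """
    if rows:
        row_type = type(rows[0])
        if any(type(r) is not row_type for r in rows):
            raise TypeError("mixed row types in write_results_tsv")
    if row_type is None:
        raise TypeError("row_type required for an empty row list")
    if not dataclasses.is_dataclass(row_type):
        raise TypeError(f"{row_type} is not a dataclass row type")
    names = [f.name for f in dataclasses.fields(row_type)]
    with open(path, "w") as out:
        out.write("\t".join(names) + "\n")
        for row in rows:
            out.write("\t".join(_render(getattr(row, n)) for n in names) + "\n")


def read_results_tsv(path: str | Path, row_type: type) -> list[object]:
    """Inverse of `write_results_tsv` for a known dataclass row type."""
    hints = typing.get_type_hints(row_type)
    fields = dataclasses.fields(row_type)

    def parse(raw: str, ann: object) -> object:
        origin = typing.get_origin(ann)
        if raw == "NA":
            return None
        if origin is typing.Union or str(origin) == "types.UnionType":
            args = [a for a in typing.get_args(ann) if a is not type(None)]
            ann = args[0]
        if ann is bool:
            return raw == "true"
        if ann is int:
            return int(raw)
        if ann is float:
            return float(raw)
        return raw

    rows: list[object] = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        expected = [f.name for f in fields]
        if header != expected:
            raise FormatError(f"{path}: header {header} does not match {row_type.__name__} fields")
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != len(fields):
                raise FormatError(f"{path}: row with {len(cols)} columns, expected {len(fields)}")
            kwargs = {f.name: parse(c, hints[f.name]) for f, c in zip(fields, cols)}
            rows.append(row_type(**kwargs))
    return rows
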