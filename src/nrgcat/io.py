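"""Readers and writers: FASTA/FASTQ, source manifest, and the on-disk catalog.

The catalog directory mirrors the numbered-file family of distributed gene
catalogs: one FASTA of representative sequences plus tab-separated tables per
annotation scheme.  All tables are UTF-8, tab-separated, header row required,
no quoting.
"""

from __future__ import annotations

import gzip
import json
import os
from typing import Iterable, Iterator, Optional, TextIO

from .errors import ConfigError, ParseError
from .model import (
    Catalog,
    GeneRecord,
    Lifestyle,
    NRGEntry,
    PhageAnnotation,
    Rank,
    SourceType,
    TaxonomyLabel,
    VALID_SEQ_RE,
)

CATALOG_FASTA = "0.catalog.fna"
CATALOG_TAXONOMY = "1.catalog.taxonomy.txt"
CATALOG_CLUSTERS = "2.catalog.clusters.txt"
CATALOG_CAZY = "8.catalog.CAZy.txt"
CATALOG_PHAGE = "10.catalog.phage.txt"
CATALOG_ANNOT_PREFIX = "annot."
CATALOG_PROVENANCE = "catalog.provenance.json"


def _open_text(path, mode: str = "rt") -> TextIO:
    """Open ``path`` as text, transparently handling ``.gz``."""
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode, encoding="utf-8")


def _normalize(seq: str, name: str, line_no: int) -> str:
    seq = seq.upper().replace("U", "T")
    if not VALID_SEQ_RE.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ParseError(
            f"record {name!r} (ending line {line_no}): invalid characters {bad}"
        )
    return seq


def read_fasta(path) -> Iterator[tuple]:
    """Yield ``(id, sequence)`` in file order.

    Sequences are upper-cased with U mapped to T; characters outside
    {A,C,G,T,N} raise :class:`ParseError` naming the offending record and
    line number, as do empty sequences and data before the first header.
    """
    name = None
    chunks: list = []
    start_line = 0
    with _open_text(path) as fh:
        line_no = 0
        for line in fh:
            line_no += 1
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    if not chunks:
                        raise ParseError(
                            f"record {name!r} at line {start_line}: empty sequence"
                        )
                    yield name, _normalize("".join(chunks), name, line_no - 1)
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise ParseError(f"line {line_no}: empty FASTA header")
                chunks = []
                start_line = line_no
            else:
                if name is None:
                    raise ParseError(f"line {line_no}: sequence data before header")
                chunks.append(line)
        if name is not None:
            if not chunks:
                raise ParseError(f"record {name!r} at line {start_line}: empty sequence")
            yield name, _normalize("".join(chunks), name, line_no)


def write_fasta(records: Iterable[tuple], path, width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path) -> Iterator[tuple]:
    """Yield ``(id, sequence, quality)`` from a FASTQ file (gzip ok)."""
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise ParseError(f"bad FASTQ header line: {header[:40]!r}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not plus.startswith("+") or len(qual) != len(seq):
                raise ParseError(f"truncated FASTQ record {header[1:]!r}")
            yield header[1:].split()[0], seq.upper(), qual


def write_fastq(records: Iterable[tuple], path) -> None:
    """Write ``(id, sequence, quality)`` triples as FASTQ."""
    with _open_text(path, "wt") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# source manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["fasta_path", "source_type", "source_id", "sample_id",
                    "species", "genus"]


def read_source_manifest(path) -> list:
    """Read the 6-column source manifest.

    Returns a list of ``(fasta_path, source_type, source_id, sample_id,
    taxon-or-None)`` tuples.  A row with a species but no genus is a config
    error (SPECIES labels require their genus); unknown source_type tokens
    are config errors.
    """
    rows = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in MANIFEST_COLUMNS if c not in header]
        if missing:
            raise ConfigError(f"manifest missing columns: {missing}")
        idx = {c: header.index(c) for c in MANIFEST_COLUMNS}
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < len(header):
                parts += [""] * (len(header) - len(parts))
            get = lambda c: parts[idx[c]].strip()
            st_token = get("source_type")
            try:
                st = SourceType(st_token)
            except ValueError:
                raise ConfigError(
                    f"manifest line {line_no}: unknown source_type {st_token!r}"
                ) from None
            species, genus = get("species"), get("genus")
            if species and not genus:
                raise ConfigError(
                    f"manifest line {line_no}: species given without genus"
                )
            taxon: Optional[TaxonomyLabel]
            if species:
                taxon = TaxonomyLabel.species(species, genus)
            elif genus:
                taxon = TaxonomyLabel.genus(genus)
            else:
                taxon = None
            rows.append((get("fasta_path"), st, get("source_id"),
                         get("sample_id"), taxon))
    return rows


def load_gene_records(manifest_path, base_dir=None) -> list:
    """Read every source FASTA named in the manifest into GeneRecords."""
    base = base_dir if base_dir is not None else os.path.dirname(
        os.path.abspath(manifest_path))
    genes: list = []
    seen: set = set()
    for fasta_path, st, source_id, sample_id, taxon in read_source_manifest(
            manifest_path):
        full = fasta_path if os.path.isabs(fasta_path) else os.path.join(
            base, fasta_path)
        for gid, seq in read_fasta(full):
            if gid in seen:
                raise ConfigError(f"duplicate gene_id {gid!r} across sources")
            seen.add(gid)
            genes.append(GeneRecord(gid, seq, st, source_id, sample_id, taxon))
    return genes


# ---------------------------------------------------------------------------
# catalog directory
# ---------------------------------------------------------------------------


def _write_tsv(path, header: list, rows: Iterable[list]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def _read_tsv(path) -> tuple:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        rows = [line.rstrip("\n").split("\t") for line in fh if line.rstrip("\n")]
    return header, rows


def write_catalog(catalog: Catalog, out_dir) -> None:
    """Serialize a catalog; ``read_catalog`` round-trips it bit-exactly."""
    os.makedirs(out_dir, exist_ok=True)
    ids = sorted(catalog.entries)
    write_fasta(((nid, catalog.entries[nid].sequence) for nid in ids),
                os.path.join(out_dir, CATALOG_FASTA))

    tax_rows = []
    for nid in ids:
        t = catalog.entries[nid].taxon
        tax_rows.append([nid, t.rank.value, t.name, t.genus_of_species])
    _write_tsv(os.path.join(out_dir, CATALOG_TAXONOMY),
               ["nrg_id", "rank", "name", "genus"], tax_rows)

    _write_tsv(
        os.path.join(out_dir, CATALOG_CLUSTERS),
        ["gene_id", "nrg_id", "is_representative"],
        ([gid, nid, int(gid == nid)]
         for gid, nid in sorted(catalog.cluster_map.items())),
    )

    schemes = sorted({s for e in catalog.entries.values() for s in e.annotations})
    for scheme in schemes:
        rows = []
        for nid in ids:
            for label in sorted(catalog.entries[nid].annotations.get(scheme, ())):
                rows.append([nid, label])
        name = CATALOG_CAZY if scheme == "CAZy" else (
            CATALOG_ANNOT_PREFIX + scheme + ".txt")
        _write_tsv(os.path.join(out_dir, name), ["nrg_id", scheme], rows)

    phage_rows = []
    for nid in ids:
        p = catalog.entries[nid].phage
        if p is not None:
            phage_rows.append([nid, p.lifestyle.value, p.family, p.host_genus])
    if phage_rows:
        _write_tsv(os.path.join(out_dir, CATALOG_PHAGE),
                   ["nrg_id", "lifestyle", "family", "host_genus"], phage_rows)

    with open(os.path.join(out_dir, CATALOG_PROVENANCE), "w",
              encoding="utf-8") as fh:
        json.dump({"provenance": catalog.provenance, "schemes": schemes},
                  fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_catalog(cat_dir) -> Catalog:
    """Load a catalog directory written by :func:`write_catalog`."""
    seqs = dict(read_fasta(os.path.join(cat_dir, CATALOG_FASTA)))

    taxa: dict = {}
    _, rows = _read_tsv(os.path.join(cat_dir, CATALOG_TAXONOMY))
    for nid, rank, name, genus in rows:
        taxa[nid] = TaxonomyLabel(Rank(rank), name, genus)

    cluster_map: dict = {}
    _, rows = _read_tsv(os.path.join(cat_dir, CATALOG_CLUSTERS))
    for gid, nid, _rep in rows:
        cluster_map[gid] = nid

    with open(os.path.join(cat_dir, CATALOG_PROVENANCE), encoding="utf-8") as fh:
        meta = json.load(fh)

    annotations: dict = {nid: {} for nid in seqs}
    for scheme in meta.get("schemes", []):
        name = CATALOG_CAZY if scheme == "CAZy" else (
            CATALOG_ANNOT_PREFIX + scheme + ".txt")
        path = os.path.join(cat_dir, name)
        if not os.path.exists(path):
            continue
        _, rows = _read_tsv(path)
        for nid, label in rows:
            annotations[nid].setdefault(scheme, set()).add(label)

    phage: dict = {}
    phage_path = os.path.join(cat_dir, CATALOG_PHAGE)
    if os.path.exists(phage_path):
        _, rows = _read_tsv(phage_path)
        for nid, lifestyle, family, host in rows:
            phage[nid] = PhageAnnotation(Lifestyle(lifestyle), family, host)

    entries = {
        nid: NRGEntry(nid, seq, taxa.get(nid, TaxonomyLabel.unassigned()),
                      annotations.get(nid, {}), phage.get(nid))
        for nid, seq in seqs.items()
    }
    cat = Catalog(entries, cluster_map, meta.get("provenance", {}))
    cat.validate()
    return cat


def read_phage_table(path):
    """Read a (nrg_id, lifestyle, family, host_genus) TSV into a dict."""
    header, rows = _read_tsv(path)
    from .errors import SchemaError

    required = ["nrg_id", "lifestyle"]
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"phage table missing columns: {missing}")
    idx = {c: header.index(c) for c in header}
    out = {}
    for parts in rows:
        nid = parts[idx["nrg_id"]]
        out[nid] = PhageAnnotation(
            Lifestyle(parts[idx["lifestyle"]].upper()),
            parts[idx["family"]] if "family" in idx else "",
            parts[idx["host_genus"]] if "host_genus" in idx else "",
        )
    return out
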