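"""Catalog-based profiling: read mapping, quantification, and sub-profiles.

The internal mapper is seed-and-verify: exact-match seeds (default length
20) locate candidate gene diagonals, each candidate is verified by a full
end-to-end comparison of the read against the gene (no clipping), and reads
below the identity floor are dropped.  Up to ``max_alignments`` best-scoring
alignments are reported per read; quantification splits each read's unit
weight equally among its best-score alignments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional

import numpy as np
import pandas as pd
import pysam

from .build import revcomp
from .errors import ConfigError, IntegrityError, SchemaError
from .model import Catalog, PhageAnnotation, Lifestyle, Rank, TaxonomyLabel

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _ENC[_b] = _i
_ENC[ord("a")] = 0
_ENC[ord("c")] = 1
_ENC[ord("g")] = 2
_ENC[ord("t")] = 3


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class MapOptions:
    seed_length: int = 20
    max_alignments: int = 10  # -k
    min_identity: float = 0.90
    n_seeds: int = 5  # <=0 means seed every offset (exhaustive sensitivity)
    both_strands: bool = True


@dataclass
class Alignment:
    nrg_id: str
    pos: int  # 0-based start on the gene
    strand: str  # '+' or '-'
    matches: int


@dataclass
class ReadHit:
    read_id: str
    read_length: int
    alignments: List[Alignment]


class CatalogIndex:
    """Exact seed index over catalog gene sequences."""

    def __init__(self, sequences: Dict[str, str], seed_length: int = 20):
        self.seed_length = seed_length
        self.ids = sorted(sequences)
        self.seqs = [sequences[i] for i in self.ids]
        self.arrays = [_encode(s) for s in self.seqs]
        self.lengths = {i: len(sequences[i]) for i in self.ids}
        index: dict = {}
        for gi, seq in enumerate(self.seqs):
            for p in range(len(seq) - seed_length + 1):
                index.setdefault(seq[p : p + seed_length], []).append((gi, p))
        self._index = index

    @classmethod
    def from_catalog(cls, catalog: Catalog, seed_length: int = 20) -> "CatalogIndex":
        return cls({nid: e.sequence for nid, e in catalog.entries.items()},
                   seed_length)


def map_reads(
    reads: Iterable, index: CatalogIndex, opts: Optional[MapOptions] = None
) -> Iterator[ReadHit]:
    """Map ``(read_id, sequence)`` pairs against the index.

    Yields a :class:`ReadHit` per mapped read; unmapped reads are dropped.
    Alignments are end-to-end (a candidate placement must fit entirely
    within the gene), filtered at ``min_identity``, sorted by descending
    match count (ties by nrg_id, position, strand), and truncated to
    ``max_alignments``.
    """
    opts = opts or MapOptions()
    sl = index.seed_length
    if sl != opts.seed_length:
        raise ConfigError("index seed length differs from mapping options")
    lookup = index._index
    arrays = index.arrays
    ids = index.ids
    short_warned = False
    for rid, seq in reads:
        lr = len(seq)
        if lr < sl:
            if not short_warned:
                warnings.warn(f"read {rid!r} shorter than seed length; unmapped")
                short_warned = True
            continue
        if opts.n_seeds <= 0:
            offsets = range(0, lr - sl + 1)
        else:
            offsets = sorted(
                {int(round(x)) for x in np.linspace(0, lr - sl, opts.n_seeds)}
            )
        strands = ("+", "-") if opts.both_strands else ("+",)
        alignments: List[Alignment] = []
        seen: set = set()
        for strand in strands:
            oriented = seq if strand == "+" else revcomp(seq)
            enc = _encode(oriented)
            for off in offsets:
                hits = lookup.get(oriented[off : off + sl])
                if not hits:
                    continue
                for gi, p in hits:
                    start = p - off
                    key = (gi, start, strand)
                    if key in seen:
                        continue
                    seen.add(key)
                    garr = arrays[gi]
                    if start < 0 or start + lr > garr.size:
                        continue
                    matches = int(
                        np.count_nonzero(garr[start : start + lr] == enc)
                    )
                    if matches / lr >= opts.min_identity:
                        alignments.append(Alignment(ids[gi], start, strand, matches))
        if alignments:
            alignments.sort(key=lambda a: (-a.matches, a.nrg_id, a.pos, a.strand))
            yield ReadHit(rid, lr, alignments[: opts.max_alignments])


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------


@dataclass
class GeneProfile:
    """Per-sample mapped reads/bases/depth per NRG (zero-read genes omitted)."""

    sample_id: str
    reads: dict = field(default_factory=dict)  # nrg_id -> fractional read count
    bases: dict = field(default_factory=dict)  # nrg_id -> aligned bases
    depth: dict = field(default_factory=dict)  # nrg_id -> bases / gene length
    n_reads_mapped: float = 0.0

    @property
    def total_depth(self) -> float:
        return float(sum(self.depth.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (nid, self.reads[nid], self.bases[nid], self.depth[nid])
            for nid in sorted(self.reads)
        ]
        return pd.DataFrame(rows, columns=["nrg_id", "reads", "bases", "depth"])


def quantify(hits: Iterable, lengths: Dict[str, int], sample_id: str = "") -> GeneProfile:
    """Aggregate read hits into a gene profile.

    Each read contributes weight 1, split equally among its best-score
    alignments; bases are aligned length times weight; depth is bases over
    gene length.
    """
    profile = GeneProfile(sample_id=sample_id)
    for hit in hits:
        if not hit.alignments:
            continue
        best = max(a.matches for a in hit.alignments)
        winners = [a for a in hit.alignments if a.matches == best]
        w = 1.0 / len(winners)
        for a in winners:
            if a.nrg_id not in lengths:
                raise IntegrityError(f"alignment references unknown NRG {a.nrg_id!r}")
            profile.reads[a.nrg_id] = profile.reads.get(a.nrg_id, 0.0) + w
            profile.bases[a.nrg_id] = (
                profile.bases.get(a.nrg_id, 0.0) + hit.read_length * w
            )
        profile.n_reads_mapped += 1.0
    profile.depth = {
        nid: profile.bases[nid] / lengths[nid] for nid in profile.bases
    }
    return profile


@dataclass
class CompositionProfile:
    sample_id: str
    shares: dict = field(default_factory=dict)  # TaxonomyLabel -> fraction
    total_depth: float = 0.0
    empty: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (t.rank.value, t.name, t.genus_of_species, s)
            for t, s in sorted(
                self.shares.items(), key=lambda kv: (-kv[1], kv[0].rank.value, kv[0].name)
            )
        ]
        return pd.DataFrame(rows, columns=["rank", "name", "genus", "share"])


def compose(profile: GeneProfile, taxonomy: Dict[str, TaxonomyLabel]) -> CompositionProfile:
    """Taxon relative abundances as gene-length-corrected coverage shares."""
    unassigned = TaxonomyLabel.unassigned()
    totals: dict = {}
    total = 0.0
    for nid, depth in profile.depth.items():
        label = taxonomy.get(nid, unassigned)
        if label is None:
            label = unassigned
        totals[label] = totals.get(label, 0.0) + depth
        total += depth
    if total <= 0:
        return CompositionProfile(profile.sample_id, {}, 0.0, empty=True)
    shares = {t: d / total for t, d in totals.items()}
    return CompositionProfile(profile.sample_id, shares, total)


@dataclass
class ExpressionProfile:
    sample_id: str
    tpm: dict = field(default_factory=dict)  # nrg_id -> transcripts per million
    empty: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.tpm.items()), columns=["nrg_id", "tpm"]
        )


def tpm(profile: GeneProfile, lengths: Dict[str, int]) -> ExpressionProfile:
    """Transcripts per million: reads per kilobase, rescaled to sum 1e6."""
    rates = {}
    for nid, reads in profile.reads.items():
        if nid not in lengths:
            raise IntegrityError(f"profile references unknown NRG {nid!r}")
        rates[nid] = reads / (lengths[nid] / 1000.0)
    total = sum(rates.values())
    if total <= 0:
        return ExpressionProfile(profile.sample_id, {}, empty=True)
    return ExpressionProfile(
        profile.sample_id, {nid: r / total * 1e6 for nid, r in rates.items()}
    )


# ---------------------------------------------------------------------------
# species-level projection of a profile against its catalog
# ---------------------------------------------------------------------------


def species_depths(profile: GeneProfile, catalog: Catalog) -> dict:
    """Per-species summed depth, resolving genus-level NRGs.

    Species-labeled NRGs contribute their depth to that species.  Genus- and
    MultiGenera-labeled NRGs cannot be attributed from the label alone, so
    their depth is split equally among the distinct member species of the
    underlying cluster (recorded at build time in the ``source_species``
    annotation).  NRGs without any species information are dropped.
    """
    out: dict = {}
    for nid, depth in profile.depth.items():
        entry = catalog.entries.get(nid)
        if entry is None:
            raise IntegrityError(f"profile references unknown NRG {nid!r}")
        if entry.taxon.rank is Rank.SPECIES:
            out[entry.taxon.name] = out.get(entry.taxon.name, 0.0) + depth
        else:
            members = sorted(entry.annotations.get("source_species", ()))
            if members:
                w = depth / len(members)
                for sp in members:
                    out[sp] = out.get(sp, 0.0) + w
    return out


def species_shares(profile: GeneProfile, catalog: Catalog) -> dict:
    depths = species_depths(profile, catalog)
    total = sum(depths.values())
    if total <= 0:
        return {}
    return {sp: d / total for sp, d in depths.items()}


# ---------------------------------------------------------------------------
# sub-profiles
# ---------------------------------------------------------------------------


@dataclass
class MycobiomeResult:
    total_share: float
    within: dict  # fungal species -> share of the fungal fraction
    detected: bool


def mycobiome(
    comp: CompositionProfile, fungal_species: Iterable, threshold: float = 1e-4
) -> MycobiomeResult:
    """Total fungal share, within-fungi composition, and detection call.

    Detection requires total fungal share strictly above ``threshold``.
    """
    fungal = set(fungal_species)
    if not fungal:
        raise ConfigError("fungal species list is empty")
    totals = {
        t.name: s
        for t, s in comp.shares.items()
        if t.rank is Rank.SPECIES and t.name in fungal
    }
    total = sum(totals.values())
    within = {sp: v / total for sp, v in totals.items()} if total > 0 else {}
    return MycobiomeResult(total, within, total > threshold)


@dataclass
class PhageomeResult:
    phage_share: float
    ratio: float  # virulent depth / temperate depth (nan when undefined)
    ratio_defined: bool
    per_host: dict
    per_family: dict


def phageome(profile: GeneProfile, phage: Dict[str, PhageAnnotation]) -> PhageomeResult:
    """Phage share of total depth and the virulent:temperate depth ratio."""
    total = profile.total_depth
    virulent = temperate = phage_depth = 0.0
    per_host: dict = {}
    per_family: dict = {}
    for nid, depth in profile.depth.items():
        ann = phage.get(nid)
        if ann is None:
            continue
        phage_depth += depth
        if ann.lifestyle is Lifestyle.VIRULENT:
            virulent += depth
        else:
            temperate += depth
        if ann.host_genus:
            per_host[ann.host_genus] = per_host.get(ann.host_genus, 0.0) + depth
        if ann.family:
            per_family[ann.family] = per_family.get(ann.family, 0.0) + depth
    share = phage_depth / total if total > 0 else 0.0
    if temperate > 0:
        return PhageomeResult(share, virulent / temperate, True, per_host, per_family)
    return PhageomeResult(share, float("nan"), False, per_host, per_family)


PHAGE_FILTER_COLUMNS = ["viral_gene_count", "is_prophage", "host_gene_count",
                        "completeness"]

_TRUE_TOKENS = {"1", "y", "yes", "true", "t"}
_FALSE_TOKENS = {"0", "n", "no", "false", "f"}


def _as_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    token = str(value).strip().lower()
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    raise SchemaError(f"cannot interpret prophage flag {value!r}")


def phage_contig_filter(table: pd.DataFrame, score_min: float = 1400.0) -> tuple:
    """Apply the 4-criterion phage contig acceptance filter.

    Accepts a contig iff viral_gene_count > 1, not a prophage,
    host_gene_count < 10, and completeness > 90 (all strict).  Returns
    ``(accepted contig ids, host_genus map)``; a host genus is recorded only
    when the (optional) ``host_score`` column is >= ``score_min``.
    """
    missing = [c for c in PHAGE_FILTER_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"phage filter table missing columns: {missing}")
    id_col = "contig_id" if "contig_id" in table.columns else None
    accepted: list = []
    hosts: dict = {}
    for idx, row in table.iterrows():
        cid = row[id_col] if id_col else idx
        ok = (
            float(row["viral_gene_count"]) > 1
            and not _as_bool(row["is_prophage"])
            and float(row["host_gene_count"]) < 10
            and float(row["completeness"]) > 90
        )
        if not ok:
            continue
        accepted.append(cid)
        if "host_score" in table.columns and "host_genus" in table.columns:
            score = row["host_score"]
            if pd.notna(score) and float(score) >= score_min:
                hosts[cid] = row["host_genus"]
    return accepted, hosts


@dataclass
class SpeciesTranscriptome:
    species: str
    emitted: bool
    n_reads: float
    table: Optional[pd.DataFrame] = None  # nrg_id, tpm_whole, tpm_species


def species_transcriptome(
    profile: GeneProfile,
    expression: ExpressionProfile,
    taxonomy: Dict[str, TaxonomyLabel],
    species: str,
    min_reads: float = 100_000,
) -> SpeciesTranscriptome:
    """Extract one species' per-gene TPM from a metatranscriptome profile.

    Refuses (``emitted=False`` with the observed read count) when the number
    of reads mapping to the species' genes does not exceed ``min_reads``.
    The emitted table carries both whole-sample TPM and a variant
    renormalized to sum 1e6 over the species' genes alone.
    """
    known = {
        t.name for t in taxonomy.values() if t is not None and t.rank is Rank.SPECIES
    }
    if species not in known:
        raise ConfigError(f"species {species!r} not present in catalog taxonomy")
    gene_ids = {
        nid
        for nid, t in taxonomy.items()
        if t is not None and t.rank is Rank.SPECIES and t.name == species
    }
    n_reads = sum(profile.reads.get(nid, 0.0) for nid in gene_ids)
    if n_reads <= min_reads:
        return SpeciesTranscriptome(species, False, n_reads)
    rows = [
        (nid, expression.tpm[nid]) for nid in sorted(gene_ids) if nid in expression.tpm
    ]
    df = pd.DataFrame(rows, columns=["nrg_id", "tpm_whole"])
    total = df["tpm_whole"].sum()
    df["tpm_species"] = df["tpm_whole"] / total * 1e6 if total > 0 else 0.0
    return SpeciesTranscriptome(species, True, n_reads, df)


def _taxon_key(label: Optional[TaxonomyLabel]) -> str:
    if label is None or label.rank is Rank.UNASSIGNED:
        return "Unassigned"
    if label.rank is Rank.MULTIGENERA:
        return "MultiGenera"
    if label.rank is Rank.GENUS:
        return f"g__{label.name}"
    return label.name


def cazy_matrix(
    expressions: Dict[str, ExpressionProfile],
    cazy: Dict[str, Iterable],
    taxonomy: Dict[str, TaxonomyLabel],
) -> tuple:
    """Samples x CAZy-family TPM matrix plus taxon contribution breakdown.

    A gene carrying several families contributes its full TPM to each
    (families are analyzed marginally).  Returns ``(matrix, contributions)``
    where ``contributions`` is a long DataFrame (sample, family, taxon,
    contribution) with contributions summing to 1 within each nonzero
    (sample, family) cell.
    """
    fam_sets = {nid: frozenset(v) for nid, v in cazy.items()}
    families = sorted({f for v in fam_sets.values() for f in v})
    samples = sorted(expressions)
    matrix = pd.DataFrame(0.0, index=samples, columns=families)
    contrib_rows: list = []
    for sid in samples:
        expr = expressions[sid]
        per_fam_taxon: dict = {}
        for nid, value in expr.tpm.items():
            for fam in fam_sets.get(nid, ()):
                matrix.loc[sid, fam] += value
                key = (fam, _taxon_key(taxonomy.get(nid)))
                per_fam_taxon[key] = per_fam_taxon.get(key, 0.0) + value
        for (fam, taxon), value in sorted(per_fam_taxon.items()):
            total = matrix.loc[sid, fam]
            if total > 0:
                contrib_rows.append((sid, fam, taxon, value / total))
    contributions = pd.DataFrame(
        contrib_rows, columns=["sample", "family", "taxon", "contribution"]
    )
    return matrix, contributions


# ---------------------------------------------------------------------------
# SAM interchange
# ---------------------------------------------------------------------------


def write_sam(hits: Iterable, lengths: Dict[str, int], path) -> None:
    """Write mapped reads as SAM (one line per reported alignment)."""
    ids = sorted(lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": nid, "LN": int(lengths[nid])} for nid in ids],
    }
    tid = {nid: i for i, nid in enumerate(ids)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for hit in hits:
            for i, aln in enumerate(hit.alignments):
                seg = pysam.AlignedSegment(out.header)
                seg.query_name = hit.read_id
                seg.flag = (16 if aln.strand == "-" else 0) | (256 if i > 0 else 0)
                seg.reference_id = tid[aln.nrg_id]
                seg.reference_start = aln.pos
                seg.mapping_quality = 255
                seg.cigartuples = [(0, hit.read_length)]
                seg.set_tag("AS", int(aln.matches))
                seg.set_tag("NM", int(hit.read_length - aln.matches))
                out.write(seg)


def read_sam_hits(path) -> Iterator[ReadHit]:
    """Parse a SAM file into ReadHits (alignments grouped by read name).

    The score is taken from the AS tag, falling back to aligned length minus
    the NM tag, falling back to aligned length.
    """
    current_id: Optional[str] = None
    current: List[Alignment] = []
    current_len = 0
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            qlen = seg.infer_query_length() or seg.query_length
            if seg.has_tag("AS"):
                score = int(seg.get_tag("AS"))
            elif seg.has_tag("NM"):
                score = qlen - int(seg.get_tag("NM"))
            else:
                score = qlen
            aln = Alignment(
                seg.reference_name,
                seg.reference_start,
                "-" if seg.is_reverse else "+",
                score,
            )
            if seg.query_name != current_id:
                if current_id is not None and current:
                    yield ReadHit(current_id, current_len, current)
                current_id = seg.query_name
                current = []
                current_len = qlen
            current.append(aln)
    if current_id is not None and current:
        yield ReadHit(current_id, current_len, current)
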