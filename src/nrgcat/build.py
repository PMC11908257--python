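"""Catalog construction: greedy identity clustering and the filter cascade.

Clustering is CD-HIT style: genes sorted by length (descending, then id),
first-fit greedy against existing representatives, with an admissible shared
k-mer count prefilter before alignment.  Identity is computed against the
shorter sequence of a pair (the -c/-aS convention).

The filter cascade runs in fixed order on the representatives:
host screen -> N filter -> exact-containment dedup -> anomaly filter.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from Bio import Align

from .errors import ParameterError
from .model import (
    BuildParams,
    Catalog,
    GeneCluster,
    NRGEntry,
    Rank,
    StrandMode,
    TaxonomyLabel,
)
from .taxonomy import propagate_taxonomy

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentResult:
    identity: float  # matching columns / |shorter|
    shorter_coverage: float  # aligned span of shorter / |shorter|
    aligned: bool


def _overlap_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 2
    a.mismatch_score = -3
    a.open_gap_score = -5
    a.extend_gap_score = -2
    # free end gaps on both sequences: overlap alignment
    a.open_end_gap_score = 0.0
    a.extend_end_gap_score = 0.0
    return a


def _local_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 2
    a.mismatch_score = -3
    a.open_gap_score = -5
    a.extend_gap_score = -2
    return a


_OVERLAP = _overlap_aligner()
_LOCAL = _local_aligner()


def _align_once(shorter: str, longer: str) -> AlignmentResult:
    if shorter == longer:
        return AlignmentResult(1.0, 1.0, True)
    aln = _OVERLAP.align(longer, shorter)[0]  # target=longer, query=shorter
    blocks = aln.aligned
    if len(blocks[1]) == 0:
        return AlignmentResult(0.0, 0.0, False)
    q_start = int(blocks[1][0][0])
    q_end = int(blocks[1][-1][1])
    identities = int(aln.counts().identities)
    n = len(shorter)
    return AlignmentResult(identities / n, (q_end - q_start) / n, True)


def align_pair(a: str, b: str, params: BuildParams) -> AlignmentResult:
    """Semi-global alignment of the shorter of ``a``/``b`` against the longer.

    End gaps on either sequence are free; identity is matching columns over
    the shorter length, coverage is the aligned span of the shorter over its
    length.  With ``strand_mode=BOTH`` the reverse complement is also tried
    and the higher-identity result returned.
    """
    if not a or not b:
        raise ParameterError("align_pair requires non-empty sequences")
    shorter, longer = (a, b) if len(a) <= len(b) else (b, a)
    result = _align_once(shorter, longer)
    if params.strand_mode is StrandMode.BOTH:
        rc = _align_once(revcomp(shorter), longer)
        if rc.identity > result.identity:
            result = rc
    return result


def kmer_counts(seq: str, w: int) -> Counter:
    return Counter(seq[i : i + w] for i in range(len(seq) - w + 1))


def shared_kmer_count(qc: Counter, cc: Counter) -> int:
    if len(cc) < len(qc):
        qc, cc = cc, qc
    return sum(min(n, cc[k]) for k, n in qc.items() if k in cc)


def kmer_prefilter(
    query: str,
    candidate: str,
    params: BuildParams,
    query_counts: Optional[Counter] = None,
    candidate_counts: Optional[Counter] = None,
) -> bool:
    """Admissible may-match test on shared word counts.

    Returns False only when the shared ``word_size``-mer count is provably
    below what any substitution-divergence pair at the identity threshold
    could retain: each of the allowed mismatches destroys at most
    ``word_size`` words of the query.
    """
    lq = len(query)
    if lq > len(candidate):
        raise ParameterError("prefilter requires |query| <= |candidate|")
    w = params.word_size
    if lq < w:
        return True
    max_mismatches = math.floor((1.0 - params.identity_threshold) * lq)
    need = (lq - w + 1) - w * max_mismatches
    if need <= 0:
        return True
    qc = query_counts if query_counts is not None else kmer_counts(query, w)
    cc = candidate_counts if candidate_counts is not None else kmer_counts(candidate, w)
    return shared_kmer_count(qc, cc) >= need


def cluster_genes(genes: Iterable, params: BuildParams) -> list:
    """Greedy incremental clustering of GeneRecords.

    Genes are processed longest-first (ties by gene_id); each gene joins the
    first existing representative it matches at identity >=
    ``identity_threshold`` and shorter-coverage >= ``overlap_threshold``,
    otherwise it founds a new cluster.  Returns GeneClusters whose
    representative is a longest member (ties by smallest gene_id).
    """
    genes = list(genes)
    if not genes:
        raise ParameterError("cluster_genes requires at least one gene")
    order = sorted(genes, key=lambda g: (-g.length, g.gene_id))
    rep_ids: list = []
    rep_seqs: list = []
    rep_counts: list = []
    members: dict = {}
    both = params.strand_mode is StrandMode.BOTH
    for gene in order:
        qc = kmer_counts(gene.sequence, params.word_size)
        qc_rc = kmer_counts(revcomp(gene.sequence), params.word_size) if both else None
        placed = False
        for i in range(len(rep_ids)):
            ok = kmer_prefilter(
                gene.sequence, rep_seqs[i], params, qc, rep_counts[i]
            )
            if not ok and both:
                ok = kmer_prefilter(
                    revcomp(gene.sequence), rep_seqs[i], params, qc_rc, rep_counts[i]
                )
            if not ok:
                continue
            res = align_pair(gene.sequence, rep_seqs[i], params)
            if (
                res.identity >= params.identity_threshold
                and res.shorter_coverage >= params.overlap_threshold
            ):
                members[rep_ids[i]].append(gene.gene_id)
                placed = True
                break
        if not placed:
            rep_ids.append(gene.gene_id)
            rep_seqs.append(gene.sequence)
            rep_counts.append(qc)
            members[gene.gene_id] = [gene.gene_id]
    return [
        GeneCluster(rep, rep, frozenset(members[rep])) for rep in rep_ids
    ]


# ---------------------------------------------------------------------------
# filter cascade
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Removal:
    nrg_id: str
    stage: str
    statistic: str


def screen_against_host(
    seqs: dict, host_sequences: Iterable, params: BuildParams
) -> tuple:
    """Remove NRGs with a local host hit at identity >= ``host_identity``
    covering >= ``host_coverage`` of the NRG; both strands are searched.

    ``seqs`` maps id -> sequence; returns ``(kept ids, removals)``.
    """
    hosts = list(host_sequences)
    kept, removed = [], []
    if not hosts:
        return list(seqs), removed
    for nid in sorted(seqs):
        seq = seqs[nid]
        hit = None
        for host in hosts:
            for query in (seq, revcomp(seq)):
                aln = _LOCAL.align(host, query)
                if len(aln) == 0 or aln.score <= 0:
                    continue
                best = aln[0]
                blocks = best.aligned
                if len(blocks[1]) == 0:
                    continue
                cols = sum(int(e - s) for s, e in blocks[1])
                identities = int(best.counts().identities)
                identity = identities / cols if cols else 0.0
                span = int(blocks[1][-1][1]) - int(blocks[1][0][0])
                coverage = span / len(seq)
                if identity >= params.host_identity and coverage >= params.host_coverage:
                    hit = f"identity={identity:.4f};coverage={coverage:.4f}"
                    break
            if hit:
                break
        if hit:
            removed.append(Removal(nid, "host", hit))
        else:
            kept.append(nid)
    return kept, removed


def drop_n_genes(seqs: dict) -> tuple:
    """Remove exactly the sequences containing at least one N."""
    kept, removed = [], []
    for nid in sorted(seqs):
        if "N" in seqs[nid]:
            removed.append(Removal(nid, "n_filter", "contains_N"))
        else:
            kept.append(nid)
    return kept, removed


def containment_dedup(seqs: dict, params: BuildParams) -> tuple:
    """Remove the shorter of every pair sharing an exact substring of at
    least ``containment_min`` bp (length tie: the lexicographically larger
    id is removed).  Removal is decided against the original set: a removed
    gene still witnesses the removal of others.

    A shared substring of length >= k exists iff the pair shares some
    k-length window, so w-mer anchoring at k = ``containment_min`` is exact.
    """
    k = params.containment_min
    anchors: dict = {}
    for nid in sorted(seqs):
        seq = seqs[nid]
        if len(seq) < k:
            continue
        for i in range(len(seq) - k + 1):
            anchors.setdefault(seq[i : i + k], set()).add(nid)
    removed: dict = {}
    for ids in anchors.values():
        if len(ids) < 2:
            continue
        group = sorted(ids)
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                a, b = group[i], group[j]
                la, lb = len(seqs[a]), len(seqs[b])
                if la > lb:
                    loser, winner = b, a
                elif lb > la:
                    loser, winner = a, b
                else:  # equal length: lexicographically larger id removed
                    loser, winner = max(a, b), min(a, b)
                removed.setdefault(loser, winner)
    kept = [nid for nid in sorted(seqs) if nid not in removed]
    removals = [
        Removal(nid, "containment", f"contained_in={removed[nid]}")
        for nid in sorted(removed)
    ]
    return kept, removals


def tetramer_frequencies(seq: str) -> np.ndarray:
    """256-dim tetranucleotide frequency vector (windows containing N skipped)."""
    idx = {b: i for i, b in enumerate("ACGT")}
    counts = np.zeros(256, dtype=float)
    code = [idx.get(c, -1) for c in seq]
    for i in range(len(seq) - 3):
        c0, c1, c2, c3 = code[i : i + 4]
        if c0 < 0 or c1 < 0 or c2 < 0 or c3 < 0:
            continue
        counts[((c0 * 4 + c1) * 4 + c2) * 4 + c3] += 1
    total = counts.sum()
    return counts / total if total else counts


def _robust_z(values: np.ndarray) -> np.ndarray:
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad == 0:
        z = np.zeros_like(values, dtype=float)
        z[values != med] = np.inf
        return z
    return (values - med) / (1.4826 * mad)


def anomaly_filter(
    seqs: dict,
    taxa: dict,
    depth_table=None,
    params: Optional[BuildParams] = None,
    warn=None,
) -> tuple:
    """Flag genes whose tetramer content, abundance, or prevalence are
    outliers within their species.

    Per species with at least ``params.min_species_genes`` members: three
    per-gene statistics (cosine distance of tetramer frequencies to the
    species centroid; log10 median depth over samples containing the
    species; prevalence among those samples) are each converted to a robust
    z-score (median/MAD) and genes with any |z| > ``params.anomaly_z`` are
    removed.  Genes without a species-level taxon are skipped.  Without a
    depth table only the tetramer statistic is used (a warning is issued).

    Returns ``(kept ids, removals, scores)`` where ``scores`` maps
    nrg_id -> {statistic: z}.
    """
    params = params or BuildParams()
    if depth_table is None and warn is not None:
        warn("anomaly filter: no per-sample depth table; tetramer-only mode")
    by_species: dict = {}
    for nid in sorted(seqs):
        t = taxa.get(nid)
        if t is not None and t.rank is Rank.SPECIES:
            by_species.setdefault(t.name, []).append(nid)

    scores: dict = {}
    flagged: set = set()
    for species, ids in sorted(by_species.items()):
        if len(ids) < params.min_species_genes:
            continue
        mat = np.vstack([tetramer_frequencies(seqs[nid]) for nid in ids])
        centroid = mat.mean(axis=0)
        cnorm = np.linalg.norm(centroid)
        norms = np.linalg.norm(mat, axis=1)
        cos = 1.0 - (mat @ centroid) / np.where(norms * cnorm == 0, 1, norms * cnorm)
        stats = {"tetramer": _robust_z(cos)}

        if depth_table is not None:
            cols = [c for c in depth_table.columns]
            sub = depth_table.reindex(index=ids).fillna(0.0)
            present = [c for c in cols if sub[c].sum() > 0]
            if present:
                d = sub[present].to_numpy(dtype=float)
                med_depth = np.median(d, axis=1)
                stats["abundance"] = _robust_z(np.log10(med_depth + 1e-9))
                stats["prevalence"] = _robust_z((d > 0).mean(axis=1))
        for i, nid in enumerate(ids):
            zrow = {name: float(z[i]) for name, z in stats.items()}
            scores[nid] = zrow
            if any(abs(z) > params.anomaly_z for z in zrow.values()):
                flagged.add(nid)

    kept = [nid for nid in sorted(seqs) if nid not in flagged]
    removals = [
        Removal(
            nid,
            "anomaly",
            ";".join(f"{k}={v:.3f}" for k, v in sorted(scores[nid].items())),
        )
        for nid in sorted(flagged)
    ]
    return kept, removals, scores


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


@dataclass
class BuildReport:
    """Per-stage bookkeeping of a catalog build."""

    n_input_genes: int = 0
    n_clusters: int = 0
    removals: dict = field(default_factory=dict)  # stage -> count
    rule_counts: dict = field(default_factory=dict)  # taxonomy rule -> clusters
    n_final: int = 0
    removal_log: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input_genes": self.n_input_genes,
            "n_clusters": self.n_clusters,
            "removals": dict(self.removals),
            "taxonomy_rule_counts": {str(k): v for k, v in self.rule_counts.items()},
            "n_final": self.n_final,
        }


def build_catalog(
    genes: list,
    params: Optional[BuildParams] = None,
    host_sequences: Optional[Iterable] = None,
    depth_table=None,
    warn=None,
) -> tuple:
    """Cluster, filter, and annotate: the full catalog build.

    Returns ``(catalog, report)``.  ``host_sequences`` is an iterable of
    host DNA strings (empty/None disables the host screen); ``depth_table``
    is an optional per-sample depth DataFrame for the anomaly filter.
    """
    params = params or BuildParams()
    report = BuildReport(n_input_genes=len(genes))

    clusters = cluster_genes(genes, params)
    report.n_clusters = len(clusters)
    gene_taxa = {g.gene_id: g.taxon for g in genes}
    labels, rule_counts = propagate_taxonomy(clusters, gene_taxa)
    report.rule_counts = rule_counts

    seq_by_gene = {g.gene_id: g.sequence for g in genes}
    seqs = {c.representative_id: seq_by_gene[c.representative_id] for c in clusters}
    cluster_by_rep = {c.representative_id: c for c in clusters}

    kept, removals = screen_against_host(seqs, host_sequences or [], params)
    report.removals["host"] = len(removals)
    report.removal_log.extend(removals)
    seqs = {nid: seqs[nid] for nid in kept}

    kept, removals = drop_n_genes(seqs)
    report.removals["n_filter"] = len(removals)
    report.removal_log.extend(removals)
    seqs = {nid: seqs[nid] for nid in kept}

    kept, removals = containment_dedup(seqs, params)
    report.removals["containment"] = len(removals)
    report.removal_log.extend(removals)
    seqs = {nid: seqs[nid] for nid in kept}

    kept, removals, _scores = anomaly_filter(seqs, labels, depth_table, params, warn)
    report.removals["anomaly"] = len(removals)
    report.removal_log.extend(removals)
    seqs = {nid: seqs[nid] for nid in kept}

    entries: dict = {}
    cluster_map: dict = {}
    for nid, seq in seqs.items():
        cluster = cluster_by_rep[nid]
        member_species = frozenset(
            gene_taxa[gid].name
            for gid in cluster.member_ids
            if gene_taxa[gid] is not None and gene_taxa[gid].rank is Rank.SPECIES
        )
        annotations = {"source_species": member_species} if member_species else {}
        entries[nid] = NRGEntry(nid, seq, labels[nid], annotations)
        for gid in cluster.member_ids:
            cluster_map[gid] = nid
    report.n_final = len(entries)

    catalog = Catalog(
        entries,
        cluster_map,
        provenance={"build_params": params.to_dict(), "n_input_genes": len(genes)},
    )
    catalog.validate()
    return catalog, report
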