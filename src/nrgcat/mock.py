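"""Seeded synthetic data: species genomes, mock communities, and reads.

Genomes descend from uniform-random roots by per-site substitution at a
stated rate, so sister species with controlled divergence are available for
clustering and taxonomy tests.  Genes tile each genome in fixed-length
windows, which makes cluster ground truth exact.  Reads are single-end,
substitution-only, constant quality; species are sampled with probability
proportional to (proportion x genome length) so that the expected per-base
depth share of each species equals its stated proportion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ParameterError
from .model import GeneRecord, SourceType, TaxonomyLabel

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_GENE_LENGTH = 900
DEFAULT_SPACER = 100


@dataclass
class SpeciesSpec:
    """Blueprint for one synthetic species genome."""

    species: str
    genus: str
    genome_length: int
    n_genes: int
    divergence_from_parent: float = 0.0
    parent: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence_from_parent <= 0.3):
            raise ParameterError(
                f"{self.species}: divergence must be in [0, 0.3], got "
                f"{self.divergence_from_parent}"
            )


@dataclass
class Genome:
    species: str
    genus: str
    sequence: str
    gene_coords: list  # list of (start, end) half-open intervals

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class MockTruth:
    """Ground truth of one synthetic community."""

    proportions: dict  # species -> fraction (per-base depth share)
    genomes: dict  # species -> Genome
    seed: int
    read_provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"proportions sum to {total}, expected 1")
        for sp in self.proportions:
            if sp not in self.genomes:
                raise ParameterError(f"community member {sp!r} has no genome")


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _str_to_codes(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.zeros(raw.size, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        codes[raw == b] = i
    return codes


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site independently at ``rate``, always to a new base."""
    out = codes.copy()
    if rate <= 0:
        return out
    hits = np.nonzero(rng.random(codes.size) < rate)[0]
    # shift by 1..3 mod 4 guarantees a different base
    out[hits] = (out[hits] + rng.integers(1, 4, size=hits.size)) % 4
    return out


def make_genomes(
    specs: list,
    seed: int,
    gene_length: int = DEFAULT_GENE_LENGTH,
    spacer: int = DEFAULT_SPACER,
) -> dict:
    """Generate genomes for ``specs`` (parents must precede children).

    Returns species -> :class:`Genome`.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    genomes: dict = {}
    codes_by_species: dict = {}
    for spec in specs:
        needed = spec.n_genes * (gene_length + spacer)
        if needed > spec.genome_length + spacer:
            raise ParameterError(
                f"{spec.species}: {spec.n_genes} genes of {gene_length} bp with "
                f"{spacer} bp spacers do not fit in {spec.genome_length} bp"
            )
        if spec.parent is None:
            codes = rng.integers(0, 4, size=spec.genome_length, dtype=np.uint8)
        else:
            if spec.parent not in codes_by_species:
                raise ParameterError(
                    f"{spec.species}: parent {spec.parent!r} not defined earlier"
                )
            parent = codes_by_species[spec.parent]
            if parent.size != spec.genome_length:
                raise ParameterError(
                    f"{spec.species}: genome_length must match parent's"
                )
            codes = _mutate(parent, spec.divergence_from_parent, rng)
        coords = [
            (i * (gene_length + spacer), i * (gene_length + spacer) + gene_length)
            for i in range(spec.n_genes)
        ]
        codes_by_species[spec.species] = codes
        genomes[spec.species] = Genome(
            spec.species, spec.genus, _codes_to_str(codes), coords
        )
    return genomes


def cds_from_genomes(genomes: dict) -> list:
    """Emit every gene window as a forward-strand :class:`GeneRecord`."""
    records = []
    for species in sorted(genomes):
        g = genomes[species]
        for i, (start, end) in enumerate(g.gene_coords):
            if start < 0 or end > g.length:
                raise ParameterError(
                    f"{species}: gene window ({start},{end}) out of bounds"
                )
            records.append(
                GeneRecord(
                    # no whitespace: ids must survive FASTA headers intact
                    gene_id=f"{species.replace(' ', '_')}|g{i:04d}",
                    sequence=g.sequence[start:end],
                    source_type=SourceType.ISOLATE,
                    source_id=species,
                    sample_id="",
                    taxon=TaxonomyLabel.species(species, g.genus),
                )
            )
    return records


@dataclass
class SimReads:
    """In-memory result of a read simulation."""

    ids: list
    sequences: list
    provenance: list  # source species per read
    read_length: int
    quality_char: str = "I"

    def fastq_records(self):
        qual = self.quality_char * self.read_length
        for rid, seq in zip(self.ids, self.sequences):
            yield rid, seq, qual

    def __len__(self) -> int:
        return len(self.ids)


def simulate_reads(
    truth: MockTruth,
    n_reads: int,
    read_length: int = 150,
    error_rate: float = 0.0,
    seed: int = 0,
    id_prefix: str = "r",
) -> SimReads:
    """Simulate single-end substitution-error reads from a community.

    Read starts are uniform on each genome; a read's species is drawn with
    probability proportional to proportion x genome_length (depth share =
    proportion); substitutions are i.i.d. at ``error_rate``.  Deterministic
    given ``seed``.
    """
    if n_reads <= 0:
        raise ParameterError("n_reads must be positive")
    members = sorted(truth.proportions)
    for sp in members:
        if truth.genomes[sp].length < read_length:
            raise ParameterError(
                f"{sp}: genome shorter than read length {read_length}"
            )
    rng = np.random.default_rng(seed)
    weights = np.array(
        [truth.proportions[sp] * truth.genomes[sp].length for sp in members]
    )
    weights = weights / weights.sum()
    counts = rng.multinomial(n_reads, weights)

    ids: list = []
    sequences: list = []
    provenance: list = []
    read_no = 0
    for sp, count in zip(members, counts):
        if count == 0:
            continue
        codes = _str_to_codes(truth.genomes[sp].sequence)
        starts = rng.integers(0, codes.size - read_length + 1, size=count)
        window = starts[:, None] + np.arange(read_length)[None, :]
        reads = codes[window]
        if error_rate > 0:
            mask = rng.random(reads.shape) < error_rate
            shift = rng.integers(1, 4, size=reads.shape, dtype=np.uint8)
            reads = np.where(mask, (reads + shift) % 4, reads).astype(np.uint8)
        chars = _BASES[reads]
        for row in chars:
            ids.append(f"{id_prefix}{read_no:07d}")
            sequences.append(row.tobytes().decode("ascii"))
            provenance.append(sp)
            read_no += 1
    truth.read_provenance = list(provenance)
    return SimReads(ids, sequences, provenance, read_length)


def write_truth_tsv(truth: MockTruth, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("species\tproportion\n")
        for sp in sorted(truth.proportions):
            fh.write(f"{sp}\t{truth.proportions[sp]:.10g}\n")


def write_provenance_tsv(reads: SimReads, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("read_id\tspecies\n")
        for rid, sp in zip(reads.ids, reads.provenance):
            fh.write(f"{rid}\t{sp}\n")
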