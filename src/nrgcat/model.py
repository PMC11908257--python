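"""Domain types for the gene catalog and its build parameters."""

from __future__ import annotations

import re
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Optional

from .errors import ConfigError, IntegrityError, ParameterError

VALID_SEQ_RE = re.compile(r"^[ACGTN]+$")

#: Annotation schemes a catalog may carry.  ``source_species`` records the
#: distinct member species of the underlying cluster and is populated by the
#: builder itself; the rest mirror externally supplied annotation tables.
REGISTERED_SCHEMES = {
    "CAZy",
    "eggNOG",
    "COG",
    "PFAM",
    "GO",
    "EC",
    "KEGG",
    "AMR",
    "product",
    "source_species",
}


class SourceType(Enum):
    MAG = "MAG"
    UNBINNED = "UNBINNED"
    ISOLATE = "ISOLATE"


class Rank(Enum):
    SPECIES = "SPECIES"
    GENUS = "GENUS"
    MULTIGENERA = "MULTIGENERA"
    UNASSIGNED = "UNASSIGNED"


class Lifestyle(Enum):
    TEMPERATE = "TEMPERATE"
    VIRULENT = "VIRULENT"


@dataclass(frozen=True)
class TaxonomyLabel:
    """Taxonomic assignment at one of four terminal ranks.

    ``name`` is empty exactly for MULTIGENERA/UNASSIGNED labels and
    ``genus_of_species`` is present exactly for SPECIES labels.
    """

    rank: Rank
    name: str = ""
    genus_of_species: str = ""

    def __post_init__(self) -> None:
        if self.rank is Rank.SPECIES:
            if not self.name or not self.genus_of_species:
                raise ConfigError(
                    "SPECIES label requires both name and genus_of_species"
                )
        elif self.rank is Rank.GENUS:
            if not self.name or self.genus_of_species:
                raise ConfigError("GENUS label requires name and no genus_of_species")
        else:
            if self.name or self.genus_of_species:
                raise ConfigError(f"{self.rank.value} label must have empty name")

    @classmethod
    def species(cls, name: str, genus: str) -> "TaxonomyLabel":
        return cls(Rank.SPECIES, name, genus)

    @classmethod
    def genus(cls, name: str) -> "TaxonomyLabel":
        return cls(Rank.GENUS, name)

    @classmethod
    def multigenera(cls) -> "TaxonomyLabel":
        return cls(Rank.MULTIGENERA)

    @classmethod
    def unassigned(cls) -> "TaxonomyLabel":
        return cls(Rank.UNASSIGNED)


UNASSIGNED = TaxonomyLabel.unassigned()
MULTIGENERA = TaxonomyLabel.multigenera()


@dataclass
class GeneRecord:
    """One coding sequence with provenance and (optional) source taxonomy."""

    gene_id: str
    sequence: str
    source_type: SourceType
    source_id: str
    sample_id: str = ""
    taxon: Optional[TaxonomyLabel] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ConfigError(f"gene {self.gene_id!r}: empty sequence")
        if not VALID_SEQ_RE.match(self.sequence):
            raise ConfigError(
                f"gene {self.gene_id!r}: sequence contains characters outside ACGTN"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneCluster:
    """A redundancy cluster; the representative is a longest member."""

    cluster_id: str
    representative_id: str
    member_ids: frozenset

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise IntegrityError(
                f"cluster {self.cluster_id}: representative not among members"
            )

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class PhageAnnotation:
    lifestyle: Lifestyle
    family: str = ""
    host_genus: str = ""


@dataclass
class NRGEntry:
    """A non-redundant gene: cluster representative plus joined annotations."""

    nrg_id: str
    sequence: str
    taxon: TaxonomyLabel = UNASSIGNED
    annotations: dict = field(default_factory=dict)  # scheme -> frozenset of labels
    phage: Optional[PhageAnnotation] = None

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        for scheme in self.annotations:
            if scheme not in REGISTERED_SCHEMES:
                raise ConfigError(f"unregistered annotation scheme {scheme!r}")
        self.annotations = {k: frozenset(v) for k, v in self.annotations.items()}


@dataclass
class Catalog:
    """The filtered NRG set, the gene->NRG map, and build provenance."""

    entries: dict  # nrg_id -> NRGEntry
    cluster_map: dict  # gene_id -> nrg_id (total over surviving input genes)
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        for gene_id, nrg_id in self.cluster_map.items():
            if nrg_id not in self.entries:
                raise IntegrityError(
                    f"cluster_map maps {gene_id!r} to missing NRG {nrg_id!r}"
                )

    def taxonomy(self) -> dict:
        return {nid: e.taxon for nid, e in self.entries.items()}

    def lengths(self) -> dict:
        return {nid: e.length for nid, e in self.entries.items()}

    def __eq__(self, other) -> bool:
        if not isinstance(other, Catalog):
            return NotImplemented
        return (
            self.entries == other.entries
            and self.cluster_map == other.cluster_map
            and self.provenance == other.provenance
        )


class StrandMode(Enum):
    FORWARD = "FORWARD"
    BOTH = "BOTH"


@dataclass
class BuildParams:
    """Parameters of the clustering and filter cascade."""

    identity_threshold: float = 0.95
    overlap_threshold: float = 0.90
    word_size: int = 8
    host_identity: float = 0.75
    host_coverage: float = 0.50
    containment_min: int = 100
    anomaly_z: float = 5.0
    strand_mode: StrandMode = StrandMode.FORWARD
    min_species_genes: int = 20  # support guard for the anomaly filter

    def __post_init__(self) -> None:
        for name in ("identity_threshold", "overlap_threshold", "host_identity",
                     "host_coverage"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ParameterError(f"{name} must be in (0, 1], got {v}")
        if self.containment_min < 1:
            raise ParameterError("containment_min must be >= 1")
        if self.word_size < 4:
            raise ParameterError("word_size must be >= 4")
        if isinstance(self.strand_mode, str):
            self.strand_mode = StrandMode(self.strand_mode)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["strand_mode"] = self.strand_mode.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BuildParams":
        return cls(**d)
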