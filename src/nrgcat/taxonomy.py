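"""Cluster taxonomy propagation: the five-rule decision tree.

Rules, applied in order to each cluster's member taxonomy tally:

1. uniform species-level taxonomy        -> that species
2. a strict-majority (>50%) species      -> that species
3. a strict-majority (>50%) genus        -> that genus
4. taxed members but no genus majority   -> MULTIGENERA
5. no member carries taxonomy            -> UNASSIGNED

Majority denominators count members carrying taxonomy at any rank; untaxed
members abstain.  A genus-only member votes its genus but no species.
Exactly 50% is not a majority.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .errors import IntegrityError, ParameterError
from .model import Rank, TaxonomyLabel


@dataclass
class MemberTaxonomyTally:
    """Vote counts over one cluster's members."""

    n_members: int
    species_counts: Counter = field(default_factory=Counter)
    genus_counts: Counter = field(default_factory=Counter)
    n_untaxed: int = 0
    species_genus: dict = field(default_factory=dict)  # species -> its genus

    @classmethod
    def from_members(cls, taxa) -> "MemberTaxonomyTally":
        """Build a tally from an iterable of TaxonomyLabel-or-None."""
        t = cls(n_members=0)
        for label in taxa:
            t.n_members += 1
            if label is None or label.rank in (Rank.UNASSIGNED, Rank.MULTIGENERA):
                t.n_untaxed += 1
            elif label.rank is Rank.SPECIES:
                t.species_counts[label.name] += 1
                t.genus_counts[label.genus_of_species] += 1
                t.species_genus[label.name] = label.genus_of_species
            elif label.rank is Rank.GENUS:
                t.genus_counts[label.name] += 1
        return t

    @property
    def n_taxed(self) -> int:
        return self.n_members - self.n_untaxed


def assign_cluster_taxonomy(tally: MemberTaxonomyTally) -> tuple:
    """Apply the decision tree; returns ``(label, rule_number)``."""
    if tally.n_members < 1:
        raise ParameterError("tally must cover at least one member")
    n_taxed = tally.n_taxed
    if n_taxed == 0:
        return TaxonomyLabel.unassigned(), 5

    # rule 1: uniform species-level taxonomy across all taxed members
    if len(tally.species_counts) == 1:
        (species, count), = tally.species_counts.items()
        if count == n_taxed:
            return (
                TaxonomyLabel.species(species, tally.species_genus[species]),
                1,
            )

    # rule 2: strict species majority
    if tally.species_counts:
        species, count = max(
            tally.species_counts.items(), key=lambda kv: (kv[1], kv[0])
        )
        if count * 2 > n_taxed:
            return (
                TaxonomyLabel.species(species, tally.species_genus[species]),
                2,
            )

    # rule 3: strict genus majority
    if tally.genus_counts:
        genus, count = max(
            tally.genus_counts.items(), key=lambda kv: (kv[1], kv[0])
        )
        if count * 2 > n_taxed:
            return TaxonomyLabel.genus(genus), 3

    # rule 4: taxed but unresolved at genus level
    return TaxonomyLabel.multigenera(), 4


def propagate_taxonomy(clusters, gene_taxa: dict) -> tuple:
    """Assign a label to every cluster's representative.

    ``gene_taxa`` maps gene_id -> TaxonomyLabel-or-None and must cover every
    member of every cluster.  Returns ``(labels, rule_counts)`` where
    ``labels`` maps nrg_id (= representative gene id) to its label and
    ``rule_counts`` maps rule number 1..5 to the number of clusters resolved
    by that rule.
    """
    labels: dict = {}
    rule_counts = Counter({r: 0 for r in range(1, 6)})
    for cluster in clusters:
        taxa = []
        for gid in cluster.member_ids:
            if gid not in gene_taxa:
                raise IntegrityError(
                    f"cluster {cluster.cluster_id}: member {gid!r} has no "
                    "GeneRecord taxonomy entry"
                )
            taxa.append(gene_taxa[gid])
        label, rule = assign_cluster_taxonomy(MemberTaxonomyTally.from_members(taxa))
        labels[cluster.representative_id] = label
        rule_counts[rule] += 1
    return labels, dict(rule_counts)
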