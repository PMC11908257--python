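"""End-to-end mock-community validation.

Generates a panel of synthetic species (including sister pairs at 2% and 6%
divergence), builds a catalog from their CDS, simulates substitution-error
shotgun reads for a set of communities with known proportions, profiles each
read set against the catalog, and regresses observed on expected species
relative abundance.

Observed species abundances are read off the catalog at species resolution:
depth on genus-level (shared-cluster) NRGs is split equally among the
cluster's member species, since the label alone cannot separate them — the
same resolution limit that makes closely related species merge at the
catalog's identity threshold.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .build import BuildParams, build_catalog
from .mock import MockTruth, SpeciesSpec, cds_from_genomes, make_genomes, simulate_reads
from .profiler import CatalogIndex, MapOptions, map_reads, quantify, species_shares

#: Default synthetic panel: 10 species in 6 genera, with one sister pair at
#: 2% divergence (Alphavaga mira/placida — expected to merge and resolve only
#: to genus) and one at 6% (Betavaga celer/lentus — mostly species-resolved).
DEFAULT_GENOME_LENGTH = 30_000
DEFAULT_N_GENES = 29


def default_species_panel(
    genome_length: int = DEFAULT_GENOME_LENGTH, n_genes: int = DEFAULT_N_GENES
) -> list:
    mk = lambda sp, genus, div=0.0, parent=None: SpeciesSpec(
        sp, genus, genome_length, n_genes, div, parent
    )
    return [
        mk("Alphavaga mira", "Alphavaga"),
        mk("Alphavaga placida", "Alphavaga", 0.02, "Alphavaga mira"),
        mk("Alphavaga remota", "Alphavaga", 0.25, "Alphavaga mira"),
        mk("Betavaga celer", "Betavaga"),
        mk("Betavaga lentus", "Betavaga", 0.06, "Betavaga celer"),
        mk("Gammavaga soror", "Gammavaga"),
        mk("Gammavaga dispar", "Gammavaga", 0.25, "Gammavaga soror"),
        mk("Deltavaga una", "Deltavaga"),
        mk("Epsilonvaga sola", "Epsilonvaga"),
        mk("Zetavaga tarda", "Zetavaga"),
    ]


def default_communities() -> list:
    """Ten designed communities of known proportions (each sums to 1).

    The panel mixes single-species-dominated profiles with even mixtures and
    graded combinations of the sister pairs at varying proportions.
    """
    s = [spec.species for spec in default_species_panel()]
    a1, a2, a3 = s[0], s[1], s[2]
    b1, b2 = s[3], s[4]
    c1, c2, d1, e1, z1 = s[5], s[6], s[7], s[8], s[9]
    def comm(named):
        rest = [sp for sp in s if sp not in named]
        remaining = 1.0 - sum(named.values())
        out = dict(named)
        out.update({sp: remaining / len(rest) for sp in rest})
        return out

    return [
        {sp: 0.1 for sp in s},
        comm({a3: 0.72}),
        comm({c2: 0.72}),
        comm({e1: 0.72}),
        comm({z1: 0.65, c1: 0.15}),
        comm({a1: 0.20, a2: 0.20, b1: 0.20, b2: 0.20}),
        comm({a1: 0.15, a2: 0.10, b1: 0.25, b2: 0.05}),
        comm({c1: 0.70}),
        {a1: 0.16, a2: 0.14, b1: 0.13, b2: 0.11, a3: 0.10,
         c1: 0.09, c2: 0.08, d1: 0.07, e1: 0.04, z1: 0.08},
        {a1: 0.02, a2: 0.03, b1: 0.02, b2: 0.03, d1: 0.45, c1: 0.45,
         a3: 0.0, c2: 0.0, e1: 0.0, z1: 0.0},
    ]


@dataclass
class ValidationReport:
    r_squared: float
    slope: float
    intercept: float
    p_value: float
    n_pairs: int
    n_communities: int
    n_species: int
    n_reads_per_sample: int
    error_rate: float
    seed: int
    max_abs_error: float
    pairs: list = field(default_factory=list)  # (community, species, expected, observed)

    def to_dict(self) -> dict:
        return {
            "r_squared": self.r_squared,
            "slope": self.slope,
            "intercept": self.intercept,
            "p_value": self.p_value,
            "n_pairs": self.n_pairs,
            "n_communities": self.n_communities,
            "n_species": self.n_species,
            "n_reads_per_sample": self.n_reads_per_sample,
            "error_rate": self.error_rate,
            "seed": self.seed,
            "max_abs_error": self.max_abs_error,
        }


def run_validation(
    seed: int = 343,
    n_reads: int = 200_000,
    read_length: int = 150,
    error_rate: float = 0.002,
    communities: Optional[list] = None,
    species_panel: Optional[list] = None,
    params: Optional[BuildParams] = None,
    out_dir: Optional[str] = None,
) -> ValidationReport:
    """Run the full mock validation loop and return the regression report."""
    specs = species_panel or default_species_panel()
    communities = communities or default_communities()
    params = params or BuildParams()

    genomes = make_genomes(specs, seed=seed)
    genes = cds_from_genomes(genomes)
    catalog, _report = build_catalog(genes, params)
    index = CatalogIndex.from_catalog(catalog)
    opts = MapOptions()

    pairs = []
    for ci, proportions in enumerate(communities):
        members = {sp: p for sp, p in proportions.items() if p > 0}
        truth = MockTruth(members, genomes, seed=seed + ci)
        reads = simulate_reads(
            truth,
            n_reads,
            read_length=read_length,
            error_rate=error_rate,
            seed=seed * 1000 + ci,
            id_prefix=f"c{ci}_",
        )
        hits = map_reads(zip(reads.ids, reads.sequences), index, opts)
        profile = quantify(hits, catalog.lengths(), sample_id=f"community{ci}")
        observed = species_shares(profile, catalog)
        for sp in sorted(proportions):
            pairs.append(
                (f"community{ci}", sp, proportions[sp], observed.get(sp, 0.0))
            )

    expected = np.array([p[2] for p in pairs])
    obs = np.array([p[3] for p in pairs])
    fit = stats.linregress(expected, obs)
    report = ValidationReport(
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        n_pairs=len(pairs),
        n_communities=len(communities),
        n_species=len(specs),
        n_reads_per_sample=n_reads,
        error_rate=error_rate,
        seed=seed,
        max_abs_error=float(np.max(np.abs(obs - expected))),
        pairs=pairs,
    )
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "validation_report.json"), "w",
                  encoding="utf-8") as fh:
            json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")
        with open(os.path.join(out_dir, "validation_pairs.tsv"), "w",
                  encoding="utf-8") as fh:
            fh.write("community\tspecies\texpected\tobserved\n")
            for community, sp, e, o in pairs:
                fh.write(f"{community}\t{sp}\t{e:.8g}\t{o:.8g}\n")
    return report
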