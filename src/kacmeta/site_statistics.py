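"""Normalized acetylation metrics and per-protein site-count statistics.

Acetylome sizes are not comparable across species: a larger proteome yields
more raw Kac sites.  The normalization used here divides by the denominators
of each species' predicted proteome —

    pct_kac_sites    = 100 * n_kac_sites    / n_lysines_total
    pct_kac_proteins = 100 * n_kac_proteins / n_proteins

Site-count distributions bin each Kac protein by its number of distinct
acetylated positions into the five disjoint classes {1}, {2}, {3-5},
{6-10}, {>10}.  "Highly acetylated" proteins (>= 5 sites) are additionally
split into exactly-5 / 6-10 / >10 classes for domain summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .acetylome_io import AcetylomeDataset, ProteomeIndex

__all__ = [
    "BIN_LABELS",
    "HIGH_CLASS_LABELS",
    "KacSummary",
    "SiteDistribution",
    "HighAcetylSelection",
    "DomainSummary",
    "assign_bin",
    "summarize",
    "site_count_distribution",
    "aggregate_distributions",
    "select_high_acetyl",
    "summarize_domains",
    "protein_kac_percent",
]

BIN_LABELS = ("1", "2", "3-5", "6-10", ">10")
HIGH_CLASS_LABELS = ("exactly_5", "6-10", ">10")


def assign_bin(n_sites: int) -> str:
    """Disjoint site-count class for a protein with ``n_sites`` distinct Kac sites."""
    if n_sites < 1:
        raise ValueError("a Kac protein has at least one site")
    if n_sites == 1:
        return "1"
    if n_sites == 2:
        return "2"
    if n_sites <= 5:
        return "3-5"
    if n_sites <= 10:
        return "6-10"
    return ">10"


@dataclass(frozen=True)
class KacSummary:
    """Proteome-normalized acetylome size metrics (percent scale, 0-100)."""

    acetylome_id: str
    n_kac_sites: int
    n_kac_proteins: int
    pct_kac_sites: float
    pct_kac_proteins: float


@dataclass(frozen=True)
class SiteDistribution:
    """Counts and percentages of Kac proteins per site-count class."""

    counts: tuple[int, ...]
    labels: tuple[str, ...] = BIN_LABELS

    @property
    def n_kac_proteins(self) -> int:
        return sum(self.counts)

    @property
    def percents(self) -> tuple[float, ...]:
        total = self.n_kac_proteins
        if total == 0:
            raise ValueError("empty distribution has no percentages")
        return tuple(100.0 * c / total for c in self.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin": self.labels, "n_proteins": self.counts,
             "percent": self.percents}
        )


@dataclass(frozen=True)
class HighAcetylSelection:
    """Proteins of one acetylome in one high-acetylation class."""

    acetylome_id: str
    species_id: str
    class_label: str
    protein_ids: frozenset[str]


@dataclass(frozen=True)
class DomainSummary:
    """Protein/species tallies for one protein domain within a class."""

    domain_id: str
    n_proteins: int
    n_species: int


def summarize(dataset: AcetylomeDataset, proteome: ProteomeIndex) -> KacSummary:
    """Proteome-normalized Kac site and Kac protein percentages."""
    if proteome.n_proteins == 0:
        raise ValueError("proteome has no proteins")
    if proteome.n_lysines_total == 0:
        raise ValueError("proteome has no lysines; percentages undefined")
    n_sites = dataset.n_sites
    n_prot = len(dataset.kac_proteins)
    return KacSummary(
        acetylome_id=dataset.acetylome_id,
        n_kac_sites=n_sites,
        n_kac_proteins=n_prot,
        pct_kac_sites=100.0 * n_sites / proteome.n_lysines_total,
        pct_kac_proteins=100.0 * n_prot / proteome.n_proteins,
    )


def site_count_distribution(dataset: AcetylomeDataset) -> SiteDistribution:
    """Bin each Kac protein by its number of distinct acetylated positions."""
    counts = dict.fromkeys(BIN_LABELS, 0)
    for positions in dataset.sites_by_protein().values():
        counts[assign_bin(len(positions))] += 1
    return SiteDistribution(tuple(counts[b] for b in BIN_LABELS))


def aggregate_distributions(
    distributions: Sequence[SiteDistribution],
) -> SiteDistribution:
    """Pool distributions by summing counts.

    Pooled percentages are recomputed from the pooled counts (count-weighted),
    never averaged over per-acetylome percentages.
    """
    if not distributions:
        raise ValueError("nothing to aggregate")
    labels = distributions[0].labels
    if any(d.labels != labels for d in distributions):
        raise ValueError("distributions use different bin labels")
    pooled = tuple(sum(d.counts[i] for d in distributions)
                   for i in range(len(labels)))
    return SiteDistribution(pooled, labels)


def select_high_acetyl(dataset: AcetylomeDataset) -> list[HighAcetylSelection]:
    """Split proteins with >= 5 distinct Kac sites into disjoint classes.

    Classes are ``exactly_5``, ``6-10`` and ``>10``; their union is exactly
    the set of proteins with at least five sites.
    """
    members: dict[str, set[str]] = {c: set() for c in HIGH_CLASS_LABELS}
    for pid, positions in dataset.sites_by_protein().items():
        n = len(positions)
        if n == 5:
            members["exactly_5"].add(pid)
        elif 6 <= n <= 10:
            members["6-10"].add(pid)
        elif n > 10:
            members[">10"].add(pid)
    return [
        HighAcetylSelection(dataset.acetylome_id, dataset.species_id,
                            label, frozenset(members[label]))
        for label in HIGH_CLASS_LABELS
    ]


def summarize_domains(
    selections: Iterable[HighAcetylSelection],
    domain_map: Mapping[str, Sequence[str]],
) -> dict[str, list[DomainSummary]]:
    """Per class label, tally proteins and distinct species per domain.

    ``domain_map`` maps protein_id to its domain identifiers (an input table;
    domain assignment itself is out of scope here).  Proteins absent from the
    map are tallied under the pseudo-domain ``"unannotated"``.  Summaries are
    sorted by descending protein count, then domain id.
    """
    per_class: dict[str, dict[str, tuple[set[tuple[str, str]], set[str]]]] = {}
    for sel in selections:
        tallies = per_class.setdefault(sel.class_label, {})
        for pid in sel.protein_ids:
            domains = list(domain_map.get(pid, [])) or ["unannotated"]
            for dom in domains:
                proteins, species = tallies.setdefault(dom, (set(), set()))
                proteins.add((sel.species_id, pid))
                species.add(sel.species_id)
    out: dict[str, list[DomainSummary]] = {}
    for label, tallies in per_class.items():
        rows = [DomainSummary(dom, len(prot), len(spec))
                for dom, (prot, spec) in tallies.items()]
        rows.sort(key=lambda r: (-r.n_proteins, r.domain_id))
        out[label] = rows
    return out


def protein_kac_percent(
    protein_id: str,
    dataset: AcetylomeDataset,
    proteome: ProteomeIndex,
) -> float:
    """Percent of a protein's lysines found acetylated (0-100)."""
    if protein_id not in proteome.proteins:
        raise KeyError(f"protein {protein_id!r} not in proteome")
    n_lys = proteome.per_protein_lysines[protein_id]
    if n_lys == 0:
        raise ValueError(f"protein {protein_id!r} has no lysines")
    n_kac = len(dataset.sites_by_protein().get(protein_id, ()))
    return 100.0 * n_kac / n_lys
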