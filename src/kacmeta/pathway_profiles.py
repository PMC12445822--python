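"""Per-enzyme acetylation matrices for glycolysis and the TCA cycle.

Given a curated catalog mapping canonical enzyme labels (HK, PGI, PFK, ALD,
GAPDH, TIM, PGK, PGM, ENO, PK for glycolysis; CS, ACO, IDH, ODH, SCS, SDH,
FH, MDH for the TCA cycle) to per-species protein identifiers, the matrix
records, per (enzyme, species) cell, whether the enzyme is acetylated (a
single Kac site suffices), the number of distinct Kac sites, and the
acetylation level as a percentage of the enzyme's lysines.

Species lacking a catalog entry for an enzyme are marked *not assessed*,
which is distinct from *not acetylated* (an ortholog present but without any
detected Kac site).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import pandas as pd

from .acetylome_io import AcetylomeDataset, ProteomeIndex

__all__ = [
    "GLYCOLYSIS_ENZYMES",
    "TCA_ENZYMES",
    "EnzymeCatalog",
    "MatrixCell",
    "AcetylationMatrix",
    "build_matrix",
    "rank_enzyme_levels",
]

GLYCOLYSIS_ENZYMES = ("HK", "PGI", "PFK", "ALD", "GAPDH",
                      "TIM", "PGK", "PGM", "ENO", "PK")
TCA_ENZYMES = ("CS", "ACO", "IDH", "ODH", "SCS", "SDH", "FH", "MDH")


@dataclass(frozen=True)
class EnzymeCatalog:
    """enzyme label -> species -> protein ids (curated ortholog table)."""

    entries: dict[str, dict[str, tuple[str, ...]]]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EnzymeCatalog":
        """Load a 3-column TSV: enzyme, species, protein_id."""
        table = pd.read_csv(path, sep="\t", dtype=str)
        entries: dict[str, dict[str, list[str]]] = {}
        for _, row in table.iterrows():
            entries.setdefault(row["enzyme"], {}) \
                .setdefault(row["species"], []).append(row["protein_id"])
        return cls({
            enz: {sp: tuple(pids) for sp, pids in per_sp.items()}
            for enz, per_sp in entries.items()
        })

    @property
    def enzymes(self) -> tuple[str, ...]:
        return tuple(self.entries)

    def species(self) -> set[str]:
        out: set[str] = set()
        for per_sp in self.entries.values():
            out |= set(per_sp)
        return out


@dataclass(frozen=True)
class MatrixCell:
    """One (enzyme, species) cell of the acetylation matrix."""

    enzyme: str
    species_id: str
    group_label: str
    assessed: bool
    n_kac_sites: int = 0
    n_lysines: int = 0
    kac_percent: float = float("nan")

    @property
    def acetylated(self) -> bool:
        return self.assessed and self.n_kac_sites >= 1


@dataclass(frozen=True)
class AcetylationMatrix:
    """Enzymes x species acetylation presence/level matrix."""

    cells: dict[tuple[str, str], MatrixCell]
    enzymes: tuple[str, ...]
    species: tuple[str, ...]

    def cell(self, enzyme: str, species_id: str) -> MatrixCell:
        return self.cells[(enzyme, species_id)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (enz, sp), cell in self.cells.items():
            rows.append({
                "enzyme": enz, "species": sp, "group": cell.group_label,
                "assessed": cell.assessed, "acetylated": cell.acetylated,
                "n_kac_sites": cell.n_kac_sites,
                "n_lysines": cell.n_lysines,
                "kac_percent": cell.kac_percent,
            })
        return pd.DataFrame(rows)


def build_matrix(
    catalog: EnzymeCatalog,
    datasets: Mapping[str, AcetylomeDataset],
    proteomes: Mapping[str, ProteomeIndex],
) -> AcetylationMatrix:
    """Build the per-enzyme, per-species acetylation matrix.

    ``datasets`` and ``proteomes`` are keyed by species id (one merged
    dataset per species).  Isoforms/paralogs listed for the same enzyme are
    pooled: the site count is the union over entries, the percentage is
    total distinct Kac lysines over total lysines of all entries.
    """
    species = tuple(sorted(datasets))
    cells: dict[tuple[str, str], MatrixCell] = {}
    for enzyme in catalog.enzymes:
        per_species = catalog.entries[enzyme]
        for sp in species:
            ds = datasets[sp]
            pids = per_species.get(sp, ())
            if not pids:
                cells[(enzyme, sp)] = MatrixCell(
                    enzyme, sp, ds.group_label, assessed=False)
                continue
            proteome = proteomes[sp]
            missing = [p for p in pids if p not in proteome.proteins]
            if missing:
                raise KeyError(
                    f"catalog proteins not in {sp} proteome: {missing}")
            by_protein = ds.sites_by_protein()
            n_sites = sum(len(by_protein.get(p, ())) for p in pids)
            n_lys = sum(proteome.per_protein_lysines[p] for p in pids)
            pct = 100.0 * n_sites / n_lys if n_lys else float("nan")
            cells[(enzyme, sp)] = MatrixCell(
                enzyme, sp, ds.group_label, assessed=True,
                n_kac_sites=n_sites, n_lysines=n_lys, kac_percent=pct)
    return AcetylationMatrix(cells, catalog.enzymes, species)


def rank_enzyme_levels(
    matrix: AcetylationMatrix,
    by: Literal["species", "group"] = "species",
) -> dict[str, list[tuple[str, float]]]:
    """Per enzyme, rank species (or groups) by acetylation percentage.

    Only assessed cells participate.  Group level pools sites and lysines
    over the group's species before computing the percentage.  Ties are
    broken lexicographically.
    """
    out: dict[str, list[tuple[str, float]]] = {}
    for enzyme in matrix.enzymes:
        if by == "species":
            entries = [
                (sp, matrix.cell(enzyme, sp).kac_percent)
                for sp in matrix.species if matrix.cell(enzyme, sp).assessed
            ]
        else:
            pooled: dict[str, list[int]] = {}
            for sp in matrix.species:
                cell = matrix.cell(enzyme, sp)
                if not cell.assessed:
                    continue
                acc = pooled.setdefault(cell.group_label, [0, 0])
                acc[0] += cell.n_kac_sites
                acc[1] += cell.n_lysines
            entries = [
                (grp, 100.0 * s / l if l else float("nan"))
                for grp, (s, l) in pooled.items()
            ]
        entries.sort(key=lambda kv: (-kv[1], kv[0]))
        out[enzyme] = entries
    return out
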