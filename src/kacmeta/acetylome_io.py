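"""Reading, validation, and indexing of proteomes and acetylome site tables.

An *acetylome* is the set of lysine-acetylated (Kac) proteins of an organism,
recorded as (protein, 1-based lysine position) pairs.  This module loads
proteome FASTA files into a :class:`ProteomeIndex` (the normalization
denominator: total proteins and total lysines), and parses published-style
acetylome tables into :class:`AcetylomeDataset` objects, validating each
reported site against the proteome sequence.

Positions are 1-based throughout, matching the "K147" notation customary for
post-translational modification sites.
"""

from __future__ import annotations

import hashlib
import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, NamedTuple, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

__all__ = [
    "GROUP_LABELS",
    "ProteomeIndex",
    "AcetylationSite",
    "AcetylomeDataset",
    "DialectConfig",
    "ValidationReport",
    "read_proteome_fasta",
    "read_acetylome_table",
    "merge_datasets",
]

#: Taxonomic group labels used to organise species in the compilation.
GROUP_LABELS = (
    "archaea",
    "bacteria",
    "fungi",
    "protozoa",
    "worms",
    "plants",
    "insects",
    "fish",
    "mammals",
)

# 20 standard residues plus ambiguity/unknown codes.  Ambiguity codes are
# accepted in sequences but never counted as lysine.
_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
_ALLOWED_AA = _STANDARD_AA | set("XBZU")


class AcetylationSite(NamedTuple):
    """One acetylated lysine: protein, 1-based position, observed residue."""

    protein_id: str
    position: int
    residue_observed: str
    source_acetylome_id: str


@dataclass(frozen=True)
class ProteomeIndex:
    """Indexed proteome: sequences plus per-protein and total lysine counts."""

    species_id: str
    proteins: dict[str, str]
    per_protein_lysines: dict[str, int]
    source_checksum: str | None = None

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_lysines_total(self) -> int:
        return sum(self.per_protein_lysines.values())

    def residue_at(self, protein_id: str, position: int) -> str | None:
        """Residue (uppercase) at a 1-based position, or None if out of range."""
        seq = self.proteins.get(protein_id)
        if seq is None or not (1 <= position <= len(seq)):
            return None
        return seq[position - 1].upper()


@dataclass
class ValidationReport:
    """Bookkeeping of site validation against a proteome.

    ``n_valid + n_mismatch + n_unmapped`` equals the number of input rows
    after deduplication.
    """

    n_input_rows: int = 0
    n_after_dedup: int = 0
    n_valid: int = 0
    n_mismatch: int = 0
    n_unmapped: int = 0
    mismatches: list[AcetylationSite] = field(default_factory=list)
    unmapped: list[AcetylationSite] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [("valid", self.n_valid), ("mismatch", self.n_mismatch),
                ("unmapped", self.n_unmapped)]
        return pd.DataFrame(rows, columns=["status", "n_sites"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class AcetylomeDataset:
    """A validated set of Kac sites from one acetylome (or a species union)."""

    acetylome_id: str
    species_id: str
    group_label: str
    sites: list[AcetylationSite]
    report: ValidationReport | None = None

    def __post_init__(self) -> None:
        if self.group_label not in GROUP_LABELS:
            raise ValueError(
                f"unknown group_label {self.group_label!r}; "
                f"expected one of {GROUP_LABELS}"
            )
        # collapse duplicate (protein, position) pairs
        seen: dict[tuple[str, int], AcetylationSite] = {}
        for s in self.sites:
            seen.setdefault((s.protein_id, s.position), s)
        self.sites = list(seen.values())

    @property
    def kac_proteins(self) -> set[str]:
        return {s.protein_id for s in self.sites}

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sites_by_protein(self) -> dict[str, set[int]]:
        out: dict[str, set[int]] = {}
        for s in self.sites:
            out.setdefault(s.protein_id, set()).add(s.position)
        return out

    def site_pairs(self) -> set[tuple[str, int]]:
        return {(s.protein_id, s.position) for s in self.sites}

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "acetylome_id": self.acetylome_id,
            "species_id": self.species_id,
            "group_label": self.group_label,
            "sites": [list(s) for s in sorted(self.sites)],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AcetylomeDataset":
        text = Path(source).read_text() if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and Path(source).exists()
        ) else str(source)
        payload = json.loads(text)
        sites = [AcetylationSite(p, int(pos), res, src)
                 for p, pos, res, src in payload["sites"]]
        return cls(payload["acetylome_id"], payload["species_id"],
                   payload["group_label"], sites)


@dataclass
class DialectConfig:
    """Column mapping for a published acetylome table.

    Either ``position_col`` (integer positions) or ``site_string_col``
    (strings like ``"K123"``, parsed with ``site_string_regex``) must be set.
    ``positions_are_one_based=False`` shifts incoming coordinates by +1.
    """

    protein_col: str
    position_col: str | None = None
    site_string_col: str | None = None
    site_string_regex: str = r"K(\d+)"
    positions_are_one_based: bool = True
    sep: str = "\t"
    id_regex: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DialectConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def extract_id(self, raw: str) -> str:
        raw = str(raw).strip()
        if self.id_regex:
            m = re.search(self.id_regex, raw)
            if m:
                return m.group(1) if m.groups() else m.group(0)
        return raw


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def read_proteome_fasta(
    path: str | Path,
    species_id: str,
    id_regex: str | None = None,
) -> ProteomeIndex:
    """Read a proteome FASTA into a :class:`ProteomeIndex`.

    The protein identifier is the first whitespace-delimited header token;
    ``id_regex`` (first capture group) overrides this, e.g.
    ``r"sp\\|([^|]+)\\|"`` for UniProt-style headers.  Lysines are counted
    case-insensitively; ambiguity codes (X/B/Z/U) are accepted but never
    counted as K.

    Raises ``ValueError`` on an empty file, a duplicate identifier, or a
    residue outside the accepted alphabet.
    """
    path = Path(path)
    proteins: dict[str, str] = {}
    lysines: dict[str, int] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        pid = record.id
        if id_regex:
            m = re.search(id_regex, record.description)
            if m:
                pid = m.group(1) if m.groups() else m.group(0)
        if pid in proteins:
            raise ValueError(f"duplicate protein id {pid!r} in {path}")
        seq = str(record.seq).upper()
        bad = set(seq) - _ALLOWED_AA
        if bad:
            raise ValueError(
                f"protein {pid!r} contains characters outside the amino-acid "
                f"alphabet: {sorted(bad)}"
            )
        proteins[pid] = seq
        lysines[pid] = seq.count("K")
    if not proteins:
        raise ValueError(f"no FASTA records found in {path}")
    return ProteomeIndex(species_id, proteins, lysines,
                         source_checksum=_checksum(path))


def read_acetylome_table(
    path: str | Path,
    dialect: DialectConfig,
    proteome: ProteomeIndex,
    mode: Literal["strict", "lenient"] = "lenient",
    acetylome_id: str | None = None,
    group_label: str = "bacteria",
) -> AcetylomeDataset:
    """Parse a delimited acetylome site table and validate it.

    In ``strict`` mode any site whose protein is missing from the proteome,
    or whose reported position is not a lysine, is a hard error listing the
    offending rows.  In ``lenient`` mode such sites are retained but flagged
    in the attached :class:`ValidationReport` — published tables were built
    against proteome releases that may differ from the one at hand.
    """
    path = Path(path)
    table = pd.read_csv(path, sep=dialect.sep, dtype=str)
    acetylome_id = acetylome_id or path.stem

    raw_sites: list[AcetylationSite] = []
    for _, row in table.iterrows():
        pid = dialect.extract_id(row[dialect.protein_col])
        if dialect.position_col is not None:
            pos = int(row[dialect.position_col])
        elif dialect.site_string_col is not None:
            m = re.search(dialect.site_string_regex,
                          str(row[dialect.site_string_col]))
            if not m:
                raise ValueError(
                    f"cannot parse site string {row[dialect.site_string_col]!r} "
                    f"with regex {dialect.site_string_regex!r}"
                )
            pos = int(m.group(1))
        else:
            raise ValueError("dialect must name position_col or site_string_col")
        if not dialect.positions_are_one_based:
            pos += 1
        if pos < 1:
            raise ValueError(f"position {pos} < 1 for protein {pid!r}")
        residue = proteome.residue_at(pid, pos)
        raw_sites.append(AcetylationSite(pid, pos, residue or "?", acetylome_id))

    report = ValidationReport(n_input_rows=len(raw_sites))
    dedup: dict[tuple[str, int], AcetylationSite] = {}
    for s in raw_sites:
        dedup.setdefault((s.protein_id, s.position), s)
    report.n_after_dedup = len(dedup)

    for s in dedup.values():
        if s.protein_id not in proteome.proteins:
            report.n_unmapped += 1
            report.unmapped.append(s)
        elif s.residue_observed != "K":
            report.n_mismatch += 1
            report.mismatches.append(s)
        else:
            report.n_valid += 1

    if mode == "strict":
        if report.unmapped:
            ids = sorted({s.protein_id for s in report.unmapped})
            raise ValueError(f"proteins not in proteome: {ids}")
        if report.mismatches:
            rows = [f"{s.protein_id}:{s.position}={s.residue_observed}"
                    for s in report.mismatches]
            raise ValueError(f"non-lysine residues at reported sites: {rows}")

    return AcetylomeDataset(acetylome_id, proteome.species_id, group_label,
                            list(dedup.values()), report=report)


def merge_datasets(
    datasets: Sequence[AcetylomeDataset],
    level: Literal["per_acetylome", "per_species_union"] = "per_species_union",
) -> list[AcetylomeDataset]:
    """Merge acetylomes.

    ``per_acetylome`` is the identity; ``per_species_union`` takes, for each
    species, the set union of (protein, position) pairs over its acetylomes.
    Conflicting group labels within a species are an error.
    """
    if level == "per_acetylome":
        return list(datasets)
    by_species: dict[str, list[AcetylomeDataset]] = {}
    for ds in datasets:
        by_species.setdefault(ds.species_id, []).append(ds)
    merged = []
    for species, group in by_species.items():
        labels = {ds.group_label for ds in group}
        if len(labels) > 1:
            raise ValueError(
                f"conflicting group labels for species {species!r}: {sorted(labels)}"
            )
        union: dict[tuple[str, int], AcetylationSite] = {}
        for ds in group:
            for s in ds.sites:
                union.setdefault((s.protein_id, s.position), s)
        merged.append(AcetylomeDataset(
            acetylome_id=f"{species}__union",
            species_id=species,
            group_label=labels.pop(),
            sites=list(union.values()),
        ))
    return merged
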