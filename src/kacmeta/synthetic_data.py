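"""Synthetic inputs with planted ground truth for every pipeline stage.

The published compilation behind this pipeline — dozens of curated acetylome
supplementary tables plus the matching proteome releases — cannot be bundled
or downloaded at test time.  Everything the pipeline consumes is therefore
generated here with a ledger of planted truth: proteomes with controllable
lysine frequency, acetylomes whose per-protein site-count distribution is
planted (exactly, under deterministic quota assignment), annotation tables
with one term enriched at a stated odds ratio, ortholog families with a key
lysine conserved or substituted per plan, and toy multi-model structures for
volume and distance measurements.

Every generator is a pure function of its spec and seed: the same inputs
yield byte-identical files.

The module also builds named ortholog-family fixtures (``hsp70_family``,
``aldolase_family``, ``soda_family``).  These are *synthetic stand-ins*, not
database sequences: they are constructed so that the coordinate
relationships of the real families hold (e.g. the reference aldolase K147
projecting to K185/K147/K162/K147/K157 across targets, or an Hsp70 K77
replaced by arginine in the bacterial and plant orthologs), which is what
the conservation machinery is tested against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np

from .acetylome_io import AcetylationSite, AcetylomeDataset, ProteomeIndex
from .structure_region import RegionDefinition, StructureFrame

__all__ = [
    "SyntheticSpec",
    "TruthLedger",
    "TargetPlan",
    "OrthologFamilyFixture",
    "SodaRecord",
    "largest_remainder",
    "generate_proteome",
    "generate_acetylome",
    "generate_annotations",
    "generate_ortholog_family",
    "generate_structure_fixture",
    "write_proteome_fasta",
    "write_acetylome_tsv",
    "write_annotations_tsv",
    "write_multimodel_pdb",
    "hsp70_family",
    "aldolase_family",
    "soda_family",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_NO_K = _AA20.replace("K", "")

#: Site-count bins used for planting, matching the analysis bins.
_BIN_RANGES = ((1, 1), (2, 2), (3, 5), (6, 10), (11, 15))


class TruthLedger(dict):
    """Planted ground truth describing exactly what a generator emitted."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    Defaults mirror the compiled acetylomes: a lysine frequency of 0.07
    (typical proteome composition), roughly 15% of proteins acetylated (the
    observed 10-15% range), and site-count-bin proportions
    (0.50, 0.20, 0.20, 0.07, 0.03) echoing the pooled empirical distribution
    in which about half of Kac proteins carry a single site.
    """

    seed: int = 0
    n_proteins: int = 1000
    length_range: tuple[int, int] = (250, 650)
    lysine_frequency: float = 0.07
    kac_protein_fraction: float = 0.15
    bin_proportions: tuple[float, ...] = (0.50, 0.20, 0.20, 0.07, 0.03)
    assignment_mode: Literal["deterministic_quota", "multinomial"] = \
        "deterministic_quota"
    # enrichment plant
    n_background_genes: int = 1000
    n_terms: int = 50
    term_size: int = 30
    study_size: int = 100
    odds_ratio: float = 8.0

    def __post_init__(self) -> None:
        if abs(sum(self.bin_proportions) - 1.0) > 1e-9:
            raise ValueError("bin proportions must sum to 1")
        if not (0.0 <= self.lysine_frequency < 1.0):
            raise ValueError("lysine frequency must lie in [0, 1)")
        if not (0.0 <= self.kac_protein_fraction <= 1.0):
            raise ValueError("kac_protein_fraction must lie in [0, 1]")


def largest_remainder(proportions: Sequence[float], total: int) -> list[int]:
    """Allocate ``total`` integer counts so realized shares match exactly.

    Floor shares are assigned first; the remainder goes to the bins with the
    largest fractional parts (ties broken by bin order).
    """
    if total < 0:
        raise ValueError("total must be non-negative")
    shares = [p * total for p in proportions]
    counts = [math.floor(s) for s in shares]
    remainder = total - sum(counts)
    order = sorted(range(len(shares)),
                   key=lambda i: (-(shares[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def _max_planted_sites(spec: SyntheticSpec) -> int:
    needed = 0
    for prop, (lo, hi) in zip(spec.bin_proportions, _BIN_RANGES):
        if prop > 0:
            needed = max(needed, hi)
    return needed if spec.kac_protein_fraction > 0 else 0


def generate_proteome(spec: SyntheticSpec) -> tuple[ProteomeIndex, TruthLedger]:
    """Random proteome with the spec's lysine frequency.

    Each protein is guaranteed at least as many lysines as the largest
    plantable site count, so any quota drawn later is feasible.  A zero
    lysine frequency combined with a non-empty acetylation plant is
    infeasible and rejected.
    """
    min_k = _max_planted_sites(spec)
    if spec.lysine_frequency == 0.0 and min_k > 0:
        raise ValueError(
            "lysine frequency 0 cannot support planted acetylation sites")
    rng = np.random.default_rng([spec.seed, 0])
    letters = np.array(list(_AA20))
    probs = np.full(20, (1.0 - spec.lysine_frequency) / 19.0)
    probs[_AA20.index("K")] = spec.lysine_frequency
    proteins: dict[str, str] = {}
    lysines: dict[str, int] = {}
    n_topped_up = 0
    lo, hi = spec.length_range
    for idx in range(spec.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(letters, size=length, p=probs)
        n_k = int(np.count_nonzero(seq == "K"))
        if n_k < min_k:
            # top up: convert random non-K positions until feasible
            non_k = np.flatnonzero(seq != "K")
            picks = rng.choice(non_k, size=min_k - n_k, replace=False)
            seq[picks] = "K"
            n_k = min_k
            n_topped_up += 1
        pid = f"P{idx:05d}"
        proteins[pid] = "".join(seq)
        lysines[pid] = n_k
    proteome = ProteomeIndex(f"syn{spec.seed}", proteins, lysines)
    ledger = TruthLedger(
        n_proteins=spec.n_proteins,
        n_lysines_total=proteome.n_lysines_total,
        n_residues_total=sum(len(s) for s in proteins.values()),
        n_topped_up=n_topped_up,
        lysine_frequency=spec.lysine_frequency,
    )
    return proteome, ledger


def generate_acetylome(
    proteome: ProteomeIndex,
    spec: SyntheticSpec,
    acetylome_id: str = "syn_acetylome",
    group_label: str = "bacteria",
) -> tuple[AcetylomeDataset, TruthLedger]:
    """Plant Kac sites with the spec's site-count-bin proportions.

    ``deterministic_quota`` mode allocates proteins to bins by largest
    remainder, so the realized bin proportions equal the plant exactly;
    ``multinomial`` mode samples bin membership.  Within a bin, the site
    count is drawn uniformly from the bin's range and positions are drawn
    without replacement from the protein's lysines.
    """
    rng = np.random.default_rng([spec.seed, 1])
    n_kac = round(spec.kac_protein_fraction * proteome.n_proteins)
    if n_kac > proteome.n_proteins:
        raise ValueError("more Kac proteins requested than proteins exist")
    ids = sorted(proteome.proteins)
    chosen = rng.choice(np.array(ids), size=n_kac, replace=False)
    if spec.assignment_mode == "deterministic_quota":
        bin_counts = largest_remainder(spec.bin_proportions, n_kac)
    elif spec.assignment_mode == "multinomial":
        bin_counts = rng.multinomial(n_kac, spec.bin_proportions).tolist()
    else:
        raise ValueError(f"unknown assignment mode {spec.assignment_mode!r}")

    sites: list[AcetylationSite] = []
    per_protein: dict[str, int] = {}
    cursor = 0
    for count, (lo, hi) in zip(bin_counts, _BIN_RANGES):
        for pid in chosen[cursor:cursor + count]:
            pid = str(pid)
            n_sites = lo if lo == hi else int(rng.integers(lo, hi + 1))
            seq = proteome.proteins[pid]
            k_positions = [i + 1 for i, aa in enumerate(seq) if aa == "K"]
            if len(k_positions) < n_sites:
                raise ValueError(
                    f"protein {pid} has {len(k_positions)} lysines; "
                    f"cannot plant {n_sites} sites")
            picks = rng.choice(k_positions, size=n_sites, replace=False)
            per_protein[pid] = n_sites
            for pos in sorted(int(p) for p in picks):
                sites.append(AcetylationSite(pid, pos, "K", acetylome_id))
        cursor += count

    dataset = AcetylomeDataset(acetylome_id, proteome.species_id,
                               group_label, sites)
    ledger = TruthLedger(
        bin_counts=list(bin_counts),
        bin_proportions=list(spec.bin_proportions),
        per_protein_sites=per_protein,
        n_kac_proteins=n_kac,
        n_sites=len(sites),
    )
    return dataset, ledger


def _solve_study_term_prob(spec: SyntheticSpec) -> tuple[float, float]:
    """Per-gene term probabilities (study, background) for the planted term.

    Chosen so the study/background odds ratio equals the plant and the
    expected term size matches ``term_size``.
    """
    s = spec.study_size
    m = spec.n_background_genes - s
    t = spec.term_size
    r = spec.odds_ratio
    if r == 1.0:
        q = t / spec.n_background_genes
        return q, q
    # (r-1) m q^2 + (s r + m - t (r-1)) q - t = 0, positive root
    a = (r - 1.0) * m
    b = s * r + m - t * (r - 1.0)
    c = -float(t)
    q = (-b + math.sqrt(b * b - 4 * a * c)) / (2 * a)
    p = r * q / (1.0 + (r - 1.0) * q)
    return p, q


def generate_annotations(
    spec: SyntheticSpec,
) -> tuple[dict[str, set[str]], set[str], TruthLedger]:
    """Annotation table with one term enriched in a planted study set.

    Term ``T0000`` is assigned per gene with probabilities solving the
    planted odds ratio at the expected term size; with ``odds_ratio == 1``
    no enrichment is planted (pure null).  All other terms receive exactly
    ``term_size`` genes drawn independently of study membership.  Odds
    ratios below 1 (depletion) are rejected.
    """
    if spec.odds_ratio < 1.0:
        raise ValueError("odds_ratio < 1 plants depletion, not enrichment")
    rng = np.random.default_rng([spec.seed, 2])
    genes = [f"g{i:04d}" for i in range(spec.n_background_genes)]
    study = set(rng.choice(np.array(genes), size=spec.study_size,
                           replace=False).tolist())
    annotations: dict[str, set[str]] = {g: set() for g in genes}
    p_study, q_bg = _solve_study_term_prob(spec)
    for g in genes:
        prob = p_study if g in study else q_bg
        if rng.random() < prob:
            annotations[g].add("T0000")
    for t in range(1, spec.n_terms):
        term = f"T{t:04d}"
        members = rng.choice(np.array(genes), size=spec.term_size,
                             replace=False)
        for g in members:
            annotations[str(g)].add(term)
    term_sizes = {f"T{t:04d}": sum(1 for s in annotations.values()
                                   if f"T{t:04d}" in s)
                  for t in range(spec.n_terms)}
    ledger = TruthLedger(
        planted_term="T0000" if spec.odds_ratio > 1.0 else None,
        odds_ratio=spec.odds_ratio,
        p_study=p_study,
        q_background=q_bg,
        study=sorted(study),
        term_sizes=term_sizes,
    )
    return annotations, study, ledger


# ---------------------------------------------------------------------------
# ortholog families


@dataclass(frozen=True)
class TargetPlan:
    """How one synthetic ortholog diverges from the reference."""

    mutation_rate: float = 0.10
    n_prefix: int = 0
    key_class: Literal["conserved_K", "conservative_R", "other"] = "conserved_K"


@dataclass(frozen=True)
class OrthologFamilyFixture:
    reference_id: str
    reference: str
    key_position: int
    targets: dict[str, str]
    ledger: TruthLedger


def generate_ortholog_family(
    reference: str,
    key_position: int,
    plans: Mapping[str, TargetPlan],
    seed: int = 0,
    conserved_positions: set[int] | None = None,
    conserved_radius: int = 12,
) -> tuple[dict[str, str], TruthLedger]:
    """Mutate a reference sequence into a family with a planted key column.

    Positions within ``conserved_radius`` of the key (plus any explicitly
    ``conserved_positions``, 1-based) are never mutated, so alignment can
    recover the key column; the key residue itself is then forced to K, R,
    or T according to each plan's class.  N-terminal extensions of
    ``n_prefix`` random residues shift the key coordinate by that amount.
    """
    reference = reference.upper()
    if not (1 <= key_position <= len(reference)):
        raise IndexError("key position outside reference")
    frozen = set(conserved_positions or ())
    frozen |= set(range(key_position - conserved_radius,
                        key_position + conserved_radius + 1))
    rng = np.random.default_rng(seed)
    targets: dict[str, str] = {}
    expected: dict[str, dict[str, object]] = {}
    key_residue = {"conserved_K": "K", "conservative_R": "R", "other": "T"}
    for name in sorted(plans):
        plan = plans[name]
        seq = list(reference)
        for i in range(len(seq)):
            if (i + 1) in frozen:
                continue
            if rng.random() < plan.mutation_rate:
                choices = [aa for aa in _AA20 if aa != seq[i]]
                seq[i] = choices[int(rng.integers(len(choices)))]
        seq[key_position - 1] = key_residue[plan.key_class]
        prefix = "".join(
            _AA_NO_K[int(rng.integers(len(_AA_NO_K)))]
            for _ in range(plan.n_prefix))
        targets[name] = prefix + "".join(seq)
        expected[name] = {
            "position": key_position + plan.n_prefix,
            "class": plan.key_class,
        }
    ledger = TruthLedger(key_position=key_position, targets=expected)
    return targets, ledger


def _random_protein(rng: np.random.Generator, length: int,
                    lysine_frequency: float = 0.07) -> str:
    letters = np.array(list(_AA20))
    probs = np.full(20, (1.0 - lysine_frequency) / 19.0)
    probs[_AA20.index("K")] = lysine_frequency
    return "".join(rng.choice(letters, size=length, p=probs))


def hsp70_family(seed: int = 7) -> OrthologFamilyFixture:
    """Synthetic Hsp70-like ortholog family around the regulatory K77.

    The reference carries the KRLIGERKFGDP regulatory motif at positions
    70-81 so that its second lysine is K77.  Targets emulate the published
    substitution pattern: most orthologs keep K77, while the bacterial and
    plant ones (Ec, At, Os) carry the charge-preserving arginine.  The
    fish target (Dr) diverges least, retaining well over 80% identity.
    All sequences are synthetic constructs, not database entries.
    """
    rng = np.random.default_rng([seed, 70])
    reference = list(_random_protein(rng, 240))
    motif = "KRLIGERKFGDP"
    reference[69:81] = list(motif)
    reference = "".join(reference)
    assert reference[76] == "K"
    plans = {
        "Dr": TargetPlan(0.08),
        "Sc": TargetPlan(0.15),
        "Af": TargetPlan(0.15),
        "Dm": TargetPlan(0.15),
        "Sj": TargetPlan(0.18),
        "Tb": TargetPlan(0.20),
        "Ec": TargetPlan(0.25, key_class="conservative_R"),
        "At": TargetPlan(0.22, key_class="conservative_R"),
        "Os": TargetPlan(0.22, key_class="conservative_R"),
    }
    targets, ledger = generate_ortholog_family(
        reference, key_position=77, plans=plans, seed=seed + 1,
        conserved_radius=12)
    return OrthologFamilyFixture("Hs", reference, 77, targets, ledger)


def aldolase_family(seed: int = 11) -> OrthologFamilyFixture:
    """Synthetic aldolase-like family around the catalytic K147 (and K230).

    Constructed so that projecting the reference K147 lands on K185 (At,
    38-residue N-terminal extension), K147 (Dr, Dm), K162 (Ts, +15) and
    K157 (Tc, +10) — the coordinate pattern of the real catalytic lysine
    across those orthologs.  Synthetic stand-in sequences.
    """
    rng = np.random.default_rng([seed, 147])
    reference = list(_random_protein(rng, 340))
    reference[146] = "K"  # catalytic K147
    reference[229] = "K"  # substrate-binding K230
    reference = "".join(reference)
    conserved = set(range(218, 243))  # keep the K230 block recognisable
    plans = {
        "Dr": TargetPlan(0.08, n_prefix=0),
        "Dm": TargetPlan(0.10, n_prefix=0),
        "Ts": TargetPlan(0.12, n_prefix=15),
        "Tc": TargetPlan(0.15, n_prefix=10),
        "At": TargetPlan(0.15, n_prefix=38),
    }
    targets, ledger = generate_ortholog_family(
        reference, key_position=147, plans=plans, seed=seed + 1,
        conserved_positions=conserved, conserved_radius=12)
    return OrthologFamilyFixture("Hs", reference, 147, targets, ledger)


@dataclass(frozen=True)
class SodaRecord:
    """One synthetic superoxide-dismutase: sequence, funnel region, Kac sites."""

    species_id: str
    sequence: str
    region: RegionDefinition
    kac_positions: frozenset[int]
    fk: int  # planted funnel lysines
    fkac: int  # planted acetylated funnel lysines
    total_k: int
    total_kac: int


# planted per-species funnel/total lysine layout: (funnel K, funnel Kac,
# other K, other Kac) positions.  Human carries the most funnel Kac sites,
# followed by Tb and Dm; totals rank Hs > Ec > Dm > Af.
_SODA_PLAN: dict[str, tuple[list[int], list[int], list[int], list[int]]] = {
    "Hs": ([31, 33, 36, 38, 131, 134, 137, 140], [31, 36, 131, 134, 137],
           [10, 60, 70, 90, 110, 170, 180, 190], [60, 90, 110, 170]),
    "Ec": ([31, 34, 37, 132, 135, 138], [31, 132],
           [12, 55, 75, 95, 115, 165, 185, 195], [55, 75, 95, 115, 165]),
    "Dm": ([32, 35, 38, 133, 136, 139], [32, 133, 136],
           [14, 58, 78, 98, 118, 168], [58, 78, 98]),
    "Af": ([30, 34, 38, 134, 138], [30, 134],
           [16, 56, 76, 96, 116, 176], [56, 76, 96]),
    "Tb": ([31, 35, 39, 135, 139, 143], [31, 35, 135, 139], [20, 80, 160], []),
    "At": ([33, 37, 136, 140], [33], [22, 82, 162], [82, 162]),
    "Ts": ([34, 38, 137, 141], [34], [24, 84, 164], [84]),
    "Dr": ([30, 36, 142], [30], [26, 86, 166], [86]),
}


def soda_family(seed: int = 13) -> dict[str, SodaRecord]:
    """Synthetic superoxide-dismutase family with planted funnel lysines.

    Each record carries a 200-residue synthetic sequence whose lysines sit
    at planted positions inside and outside the funnel region (residues
    30-45 and 130-150), with acetylated subsets arranged so that the human
    enzyme has the most funnel Kac sites.  Synthetic stand-ins for the real
    enzyme set.
    """
    region = RegionDefinition("funnel", ((30, 45), (130, 150)))
    records: dict[str, SodaRecord] = {}
    for i, (species, plan) in enumerate(sorted(_SODA_PLAN.items())):
        funnel_k, funnel_kac, other_k, other_kac = plan
        rng = np.random.default_rng([seed, i])
        seq = list("".join(
            _AA_NO_K[int(rng.integers(len(_AA_NO_K)))] for _ in range(200)))
        for pos in funnel_k + other_k:
            seq[pos - 1] = "K"
        kac = frozenset(funnel_kac + other_kac)
        records[species] = SodaRecord(
            species_id=species,
            sequence="".join(seq),
            region=region,
            kac_positions=kac,
            fk=len(funnel_k),
            fkac=len(funnel_kac),
            total_k=len(funnel_k) + len(other_k),
            total_kac=len(kac),
        )
    return records


# ---------------------------------------------------------------------------
# structures


def generate_structure_fixture(
    n_atoms: int = 3,
    n_models: int = 1,
    seed: int = 0,
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
    spread: float = 5.0,
    oscillation: float = 0.0,
) -> tuple[list[StructureFrame], TruthLedger]:
    """Toy structure frames: random atoms, optional radial breathing.

    Atoms are placed uniformly in a cube of half-width ``spread`` around
    ``center``; in model ``m`` their displacement from the centre is scaled
    by ``1 + oscillation * sin(2*pi*m / n_models)``.  Elements cycle through
    C/N/O/S; each atom is its own residue so distance measurements can
    address atoms individually.
    """
    rng = np.random.default_rng(seed)
    base = rng.uniform(-spread, spread, size=(n_atoms, 3))
    elements = [("C", "N", "O", "S")[i % 4] for i in range(n_atoms)]
    center_arr = np.asarray(center, dtype=float)
    frames: list[StructureFrame] = []
    coords_per_model = []
    for m in range(n_models):
        scale = 1.0 + oscillation * math.sin(2.0 * math.pi * m / n_models)
        coords = center_arr + base * scale
        coords_per_model.append(coords.tolist())
        frames.append(StructureFrame(
            residue_numbers=np.arange(1, n_atoms + 1),
            residue_names=["ALA"] * n_atoms,
            atom_names=["CA"] * n_atoms,
            elements=list(elements),
            coords=coords.copy().reshape(-1, 3),
            frame_index=m,
            chain_ids=["A"] * n_atoms,
        ))
    ledger = TruthLedger(coords=coords_per_model, elements=elements,
                         center=list(center), oscillation=oscillation)
    return frames, ledger


# ---------------------------------------------------------------------------
# writers — emit exactly the formats the pipeline reads


def write_proteome_fasta(proteome: ProteomeIndex, path: str | Path,
                         width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid in sorted(proteome.proteins):
            fh.write(f">{pid}\n")
            seq = proteome.proteins[pid]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_acetylome_tsv(dataset: AcetylomeDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein\tposition\n")
        for site in sorted(dataset.sites):
            fh.write(f"{site.protein_id}\t{site.position}\n")


def write_annotations_tsv(annotations: Mapping[str, set[str]],
                          path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tterm\n")
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                fh.write(f"{gene}\t{term}\n")


def write_multimodel_pdb(frames: Sequence[StructureFrame],
                         path: str | Path) -> None:
    """Write frames as a multi-model PDB (fixed-column ATOM records)."""
    with open(path, "w") as fh:
        for frame in frames:
            fh.write(f"MODEL     {frame.frame_index + 1:4d}\n")
            for i in range(frame.n_atoms):
                x, y, z = frame.coords[i]
                chain = frame.chain_ids[i] if frame.chain_ids else "A"
                name = frame.atom_names[i]
                padded = f" {name:<3s}" if len(name) < 4 else name
                fh.write(
                    f"ATOM  {i + 1:5d} {padded}"
                    f" {frame.residue_names[i]:<3s} {chain}"
                    f"{int(frame.residue_numbers[i]):4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {frame.elements[i]:>2s}\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")
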