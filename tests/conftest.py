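import textwrap

import pytest

from kacmeta.acetylome_io import (
    AcetylationSite,
    AcetylomeDataset,
    ProteomeIndex,
)


def make_proteome(seqs: dict[str, str], species_id: str = "spX") -> ProteomeIndex:
    return ProteomeIndex(
        species_id=species_id,
        proteins={k: v.upper() for k, v in seqs.items()},
        per_protein_lysines={k: v.upper().count("K") for k, v in seqs.items()},
    )


def make_dataset(
    pairs: list[tuple[str, int]],
    acetylome_id: str = "acA",
    species_id: str = "spX",
    group_label: str = "bacteria",
) -> AcetylomeDataset:
    sites = [AcetylationSite(p, pos, "K", acetylome_id) for p, pos in pairs]
    return AcetylomeDataset(acetylome_id, species_id, group_label, sites)


@pytest.fixture
def toy_obo(tmp_path):
    """Three-term is_a chain plus a diamond (two parents)."""
    text = textwrap.dedent("""\
        format-version: 1.2
        ontology: toy

        [Term]
        id: GO:0000001
        name: leaf
        namespace: biological_process
        is_a: GO:0000002 ! mid

        [Term]
        id: GO:0000002
        name: mid
        namespace: biological_process
        is_a: GO:0000003 ! root

        [Term]
        id: GO:0000003
        name: root
        namespace: biological_process

        [Term]
        id: GO:0000004
        name: twoparents
        namespace: biological_process
        is_a: GO:0000002 ! mid
        is_a: GO:0000003 ! root
        """)
    path = tmp_path / "toy.obo"
    path.write_text(text)
    return path


@pytest.fixture
def toy_kegg(tmp_path):
    text = textwrap.dedent("""\
        +D	KO
        #<h2>Toy hierarchy</h2>
        A09100 Metabolism
        B  09101 Carbohydrate metabolism
        C    00010 Glycolysis / Gluconeogenesis [PATH:ko00010]
        D      K00844  HK; hexokinase [EC:2.7.1.1]
        D      K01810  GPI; glucose-6-phosphate isomerase [EC:5.3.1.9]
        C    00020 Citrate cycle (TCA cycle) [PATH:ko00020]
        D      K01647  CS; citrate synthase [EC:2.3.3.1]
        D      K00844  HK; hexokinase [EC:2.7.1.1]
        B  09102 Energy metabolism
        C    00190 Oxidative phosphorylation [PATH:ko00190]
        D      K02108  ATPF0A; F-type H+-transporting ATPase subunit a
        """)
    path = tmp_path / "toy.keg"
    path.write_text(text)
    return path
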