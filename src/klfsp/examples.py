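"""Worked-example fixtures: small synthetic gene-family scenarios.

These encode, as minimal explicit trees, duplication/loss scenarios of the
kind reported for spiralian SP6-9 genes: two nested duplications with a
clitellate loss inside sedentarian annelids, a loss-plus-duplication on the
hypsogastropod branch, retroduplicated intronless paralogs in tandem on
cephalopod genomes, and per-lineage duplications across a spiralian
cladogram with a single-copy root.  All trees here are *synthetic
reconstructions from verbal descriptions of such histories*, not published
tree files; they exist so the inference machinery has small inputs with
known answers, and they double as documentation.
"""

from __future__ import annotations

from .reconcile import (
    OverrideDirective,
    SpeciesTreeIndex,
    gene_tree_from_string,
    species_tree_from_string,
)
from .synteny import GeneModel

__all__ = [
    "sedentaria_species_tree",
    "sedentaria_gene_tree",
    "gastropod_species_tree",
    "gastropod_gene_tree",
    "cephalopod_species_tree",
    "cephalopod_gene_tree",
    "cephalopod_gene_models",
    "spiralia_species_tree",
    "spiralia_gene_tree",
    "spiralia_copy_numbers",
    "mollusc_species_tree",
    "mollusc_copy_numbers",
    "hypsogastropoda_override",
]

# --- Sedentaria (annelids): Orbiniidae and Sabellidae branch off with a
# single copy; two duplications follow on the branch to the remaining
# sedentarians (Serpulidae, Clitellata, Capitellidae, Echiura); Clitellata
# then loses one copy and re-duplicates another, leaving it with paralogs
# in only two of the three clades.

SEDENTARIA_SPECIES_NEWICK = "(Orb,(Sab,(Serp,(Clit,(Cap,Ech)))));"

SEDENTARIA_GENE_NEWICK = (
    "(Orb|Orb_g,(Sab|Sab_g,"
    "((Serp|Serp_x,((Clit|Clit1,Clit|Clit2),(Cap|Cap_x,Ech|Ech_x))),"
    "((Serp|Serp1,(Cap|Cap1,Ech|Ech1)),"
    "(Serp|Serp2,(Clit|Clit3,(Cap|Cap2,Ech|Ech2)))))));"
)


def sedentaria_species_tree() -> SpeciesTreeIndex:
    return species_tree_from_string(SEDENTARIA_SPECIES_NEWICK)


def sedentaria_gene_tree():
    return gene_tree_from_string(SEDENTARIA_GENE_NEWICK)


# --- Hypsogastropoda: two gastropod paralog clades; hypsogastropod genes
# both fall inside clade 1 (a within-lineage duplication) and are absent
# from clade 2 (a loss on the hypsogastropod branch).

GASTROPOD_SPECIES_NEWICK = "(G1,(G2,Hyp));"

GASTROPOD_GENE_NEWICK = (
    "((G1|G1_1,(G2|G2_1,(Hyp|Hyp_a,Hyp|Hyp_b))),(G1|G1_2,G2|G2_2));"
)


def gastropod_species_tree() -> SpeciesTreeIndex:
    return species_tree_from_string(GASTROPOD_SPECIES_NEWICK)


def gastropod_gene_tree():
    return gene_tree_from_string(GASTROPOD_GENE_NEWICK)


# --- Cephalopods: three paralogs a, b, c in three species (octopus Obi,
# bobtail squid Esc, squid Dpe); c is the outgroup to (a, b); b and c are
# intronless in every species while a keeps its introns, so both stem
# duplications are retroduplications.  The three paralogs sit in tandem
# (b, c, a; same strand) within 1.5 Mb on each genome.

CEPHALOPOD_SPECIES_NEWICK = "(Obi,(Esc,Dpe))Cephalopoda;"

CEPHALOPOD_GENE_NEWICK = (
    "((Obi|Obi_c,(Esc|Esc_c,Dpe|Dpe_c)),"
    "((Obi|Obi_a,(Esc|Esc_a,Dpe|Dpe_a)),(Obi|Obi_b,(Esc|Esc_b,Dpe|Dpe_b))));"
)


def cephalopod_species_tree() -> SpeciesTreeIndex:
    return species_tree_from_string(CEPHALOPOD_SPECIES_NEWICK)


def cephalopod_gene_tree():
    return gene_tree_from_string(CEPHALOPOD_GENE_NEWICK)


def cephalopod_gene_models() -> list:
    """Tandem b, c, a paralogs per species: b and c single-exon, a with
    introns, 0.6 Mb apart on one scaffold, same strand."""
    models = []
    for sp in ("Obi", "Esc", "Dpe"):
        scf = f"{sp}_scf1"
        layout = [("b", True), ("c", True), ("a", False)]
        for i, (fam, intronless) in enumerate(layout):
            start = i * 600_000
            if intronless:
                exons = ((start, start + 900),)
            else:
                exons = tuple(
                    (start + k * 500, start + k * 500 + 300) for k in range(3)
                )
            models.append(
                GeneModel(
                    gene_id=f"{sp}_{fam}",
                    species=sp,
                    scaffold=scf,
                    start=start,
                    end=exons[-1][1],
                    strand="+",
                    exons=exons,
                    family=fam,
                )
            )
    return models


# --- Spiralia-wide cladogram (current consensus hypothesis, binary):
# Rotifera branch first, then Gastrotricha+Platyhelminthes, then the
# lophotrochozoan clades.  Independent duplications occurred in Rotifera,
# Platyhelminthes, Annelida, Mollusca and on the Phoronida+Bryozoa stem;
# the lineage-monophyletic gene tree below encodes exactly those, so the
# reconciled root carries a single copy.

SPIRALIA_SPECIES_NEWICK = (
    "(Rotifera,((Gastrotricha,Platyhelminthes),((Annelida,Mollusca),"
    "(Nemertea,(Brachiopoda,(Phoronida,Bryozoa))))))Spiralia;"
)

SPIRALIA_GENE_NEWICK = (
    "((Rotifera|rot1,Rotifera|rot2),((Gastrotricha|gas1,"
    "(Platyhelminthes|pla1,Platyhelminthes|pla2)),"
    "(((Annelida|ann1,Annelida|ann2),(Mollusca|mol1,Mollusca|mol2)),"
    "(Nemertea|nem1,(Brachiopoda|bra1,"
    "((Phoronida|pho1,Bryozoa|bry1),(Phoronida|pho2,Bryozoa|bry2)))))));"
)


def spiralia_species_tree() -> SpeciesTreeIndex:
    return species_tree_from_string(SPIRALIA_SPECIES_NEWICK)


def spiralia_gene_tree():
    return gene_tree_from_string(SPIRALIA_GENE_NEWICK)


def spiralia_copy_numbers() -> dict:
    """Observed per-lineage paralog counts for the spiralian cladogram."""
    return {
        "Rotifera": 2,
        "Gastrotricha": 1,
        "Platyhelminthes": 2,
        "Annelida": 2,
        "Mollusca": 2,
        "Nemertea": 1,
        "Brachiopoda": 1,
        "Phoronida": 2,
        "Bryozoa": 2,
    }


# --- Molluscs: duplication at the base of Conchifera and again in
# Cephalopoda; Protobranchia lost one copy; hypsogastropods lost one
# paralog and re-duplicated the other, which count parsimony alone cannot
# see (their observed count stays 2) — hence the override directive.

MOLLUSC_SPECIES_NEWICK = (
    "(Aculifera,(Cephalopoda,((Protobranchia,Bivalvia),"
    "(Patellogastropoda,Hypsogastropoda)Gastropoda))Conchifera)Mollusca;"
)


def mollusc_species_tree() -> SpeciesTreeIndex:
    return species_tree_from_string(MOLLUSC_SPECIES_NEWICK)


def mollusc_copy_numbers() -> dict:
    return {
        "Aculifera": 1,
        "Cephalopoda": 3,
        "Protobranchia": 1,
        "Bivalvia": 2,
        "Patellogastropoda": 2,
        "Hypsogastropoda": 2,
    }


def hypsogastropoda_override() -> OverrideDirective:
    """Gene-tree evidence: one paralog lost and the survivor re-duplicated
    on the hypsogastropod branch, despite an unchanged observed count."""
    return OverrideDirective(
        clade="Hypsogastropoda",
        replacement={"Hypsogastropoda": (1, 1)},
        justification=(
            "both hypsogastropod paralogs fall within a single gastropod "
            "clade: loss of one paralog, duplication of the other"
        ),
    )
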