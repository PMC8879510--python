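"""Shared fixtures: the published worked examples (guide table, founder
genotype matrix, wild-type/mutant allele pairs) used across the suite."""

import pytest

from multiguide import CohortTable, GuideTarget

#: The five published 23-nt targets (gene -> target-strand sequence).
PUBLISHED_TARGETS = {
    "gabbr1a": "GGATGTCCCTTGAGAACGGGAGG",
    "gabbr2": "GGCACGGCCTGGACAACAACTGG",
    "necap1": "GGAAGTTGGACGCTCCTGACTGG",
    "tmem183a": "GGTGTAGATTCGGGGAGAGGAGG",
    "zgc103499": "GGATCGGAAACCCACCAAGCAGG",
}

#: Published wild-type/mutant pairs with a clean printable alignment:
#: (gene, wt, allele, label, mutation_class, frameshift).
PUBLISHED_ALLELE_PAIRS = [
    ("gabbr1a", "GGATGTCCCTTGAGAACGGGAGGGTGTCGCTG",
     "GGATGTCCCTTGAGGGTGTCGCTG", "-8", "deletion", True),
    ("tmem183a", "CCTCCTCTCCCCGAATCTACACCCACT",
     "CCTCCCCGAATCTACACCCACT", "-5", "deletion", True),
    ("necap1", "TCCAGTCAGGAGCGTCCAACTTCCAGTCCG",
     "TCCGTCCAACTTCCAGTCCG", "-10", "deletion", True),
    ("necap1", "TCCAGTCAGGAGCGTCCAACTTCCAGTCCG",
     "TCCAGGAGCGTCCAACTTCCAGTCCG", "-4", "deletion", True),
    ("zgc103499", "CCTGCTTGGTGGGTTTCCGATCCAGG",
     "CCTGCTATGGTGGGTTTCCGATCCAGG", "+1", "insertion", True),
]

#: The published founder genotype matrix: gene -> {fish: label or None}.
#: Complex components follow the matrix's own rendering ("+1 (-2, +3)" for
#: gabbr2, "+2 (-2, +4)" for gabbr1a).
FOUNDER_MATRIX_LABELS = {
    "gabbr1a": {"KO1": "+2 (-2, +4)", "KO2": None, "KO3": "+2 (-2, +4)",
                "KO4": None, "KO5": None, "KO6": "-8"},
    "gabbr2": {"KO1": None, "KO2": None, "KO3": "+1 (-2, +3)",
               "KO4": None, "KO5": None, "KO6": None},
    "necap1": {"KO1": None, "KO2": "-4", "KO3": None,
               "KO4": "-10", "KO5": None, "KO6": None},
    "tmem183a": {"KO1": "-5", "KO2": None, "KO3": None,
                 "KO4": None, "KO5": "-5", "KO6": None},
    "zgc103499": {"KO1": None, "KO2": "-33", "KO3": None,
                  "KO4": None, "KO5": None, "KO6": "+1"},
}

FISH_IDS = ("KO1", "KO2", "KO3", "KO4", "KO5", "KO6")


@pytest.fixture(scope="session")
def published_targets() -> dict[str, GuideTarget]:
    return {
        gene: GuideTarget(gene=gene, seq=seq, strand="+", start=0, end=23)
        for gene, seq in PUBLISHED_TARGETS.items()
    }


@pytest.fixture(scope="session")
def founder_cohort() -> CohortTable:
    return CohortTable.from_labels(FOUNDER_MATRIX_LABELS, fish_ids=FISH_IDS)
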