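"""Constant-gene (isotype) labels, locus order and reporting groups.

Human IGH constant genes in genomic (locus) order. Class-switch
recombination is deletional, so a cell can only move rightward along
this order; IGHM and IGHD are co-expressed by alternative splicing and
share rank 0.
"""

ISOTYPES = [
    "IGHM", "IGHD", "IGHG3", "IGHG1", "IGHA1",
    "IGHG2", "IGHG4", "IGHE", "IGHA2",
]

#: CSR rank; transitions are only allowed to strictly greater rank
#: (IGHM <-> IGHD excepted: both rank 0, no transition between them).
LOCUS_RANK = {
    "IGHM": 0, "IGHD": 0, "IGHG3": 1, "IGHG1": 2, "IGHA1": 3,
    "IGHG2": 4, "IGHG4": 5, "IGHE": 6, "IGHA2": 7,
}

UNSWITCHED = frozenset({"IGHM", "IGHD"})

#: reporting granularity with IgM and IgD separate (Fig-2-style grouping)
CLASS7 = {
    "IGHM": "IgM", "IGHD": "IgD",
    "IGHG1": "IgG1/2", "IGHG2": "IgG1/2",
    "IGHG3": "IgG3", "IGHG4": "IgG4",
    "IGHA1": "IgA1/2", "IGHA2": "IgA1/2",
    "IGHE": "IgE",
}
CLASS7_LABELS = ["IgM", "IgD", "IgG1/2", "IgG3", "IgG4", "IgA1/2", "IgE"]

#: grouping used for overlap/frequency reporting: IgM and IgD merged
#: (IgM reads arise from IgD transcripts by alternative splicing)
CLASS6 = {
    "IGHM": "IgD/M", "IGHD": "IgD/M",
    "IGHG1": "IgG1/2", "IGHG2": "IgG1/2",
    "IGHG3": "IgG3", "IGHG4": "IgG4",
    "IGHA1": "IgA1/2", "IGHA2": "IgA1/2",
    "IGHE": "IgE",
}
CLASS6_LABELS = ["IgD/M", "IgG1/2", "IgG3", "IgG4", "IgA1/2", "IgE"]
CLASS6_SWITCHED = ["IgG1/2", "IgG3", "IgG4", "IgA1/2", "IgE"]


def is_switched(isotype: str) -> bool:
    return isotype not in UNSWITCHED
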