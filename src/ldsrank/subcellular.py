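"""Bayes-derived subcellular compartment scores.

A reference set of proteins with known essentiality labels and
subcellular compartment annotations is used to score each compartment
C_i with the posterior probability that a protein found there is
essential:

    P(C_i)   = P(E) P(C_i|E) + P(NE) P(C_i|NE)        (total probability)
    P(E|C_i) = P(E) P(C_i|E) / P(C_i)                 (Bayes)

where P(E) and P(NE) are the essential / non-essential fractions of the
reference set and P(C_i|E) is the fraction of essential proteins
annotated to C_i.  A protein annotated to several compartments counts
once toward each of them, so the per-compartment probabilities need not
sum to one across compartments.  Algebraically the posterior reduces to
the count ratio  n_ess_in_Ci / (n_ess_in_Ci + n_noness_in_Ci); the
Bayes route is kept because the intermediate probabilities are part of
the score table contract and the identity is exercised by the tests.

A protein's subcellular compartment score (SCS) is the mean of the
scores of its annotated compartments, and 0 when it has none.

The reference (score-training) protein set is supplied explicitly and
is independent of the PPI network being ranked: in the yeast setting it
is a curated list of essential and non-essential proteins, not the
node set of any particular interaction dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Union

import pandas as pd

log = logging.getLogger(__name__)

#: The 11 subcellular compartments of the default vocabulary.
COMPARTMENTS: tuple[str, ...] = (
    "Cytoskeleton",
    "Cytosol",
    "Endoplasmic Reticulum",
    "Endosome",
    "Extracellular space",
    "Golgi apparatus",
    "Mitochondrion",
    "Nucleus",
    "Peroxisome",
    "Plasma membrane",
    "Vacuole",
)

Lines = Union[IO[str], Iterable[str]]


@dataclass
class AnnotationTable:
    """Protein -> set-of-compartments map with a fixed vocabulary.

    Compartment sets may be empty (unannotated protein).  Compartment
    names are validated against ``vocabulary`` on insertion.
    """

    vocabulary: tuple[str, ...] = COMPARTMENTS
    entries: dict[str, frozenset[str]] = field(default_factory=dict)

    def add(self, protein: str, compartments: Iterable[str]) -> None:
        comps = frozenset(compartments)
        unknown = comps - set(self.vocabulary)
        if unknown:
            raise ValueError(
                f"unknown compartment(s) {sorted(unknown)} for protein {protein!r}"
            )
        self.entries[protein] = self.entries.get(protein, frozenset()) | comps

    def compartments_of(self, protein: str) -> frozenset[str]:
        return self.entries.get(protein, frozenset())

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, protein: str) -> bool:
        return protein in self.entries


def read_annotations(
    stream: Lines,
    vocabulary: tuple[str, ...] = COMPARTMENTS,
    delimiter: str = "\t",
) -> AnnotationTable:
    """Parse a protein-annotation TSV.

    Each line carries a protein ID followed by compartment names, either
    one per extra field or semicolon-joined in the second field.  A line
    with no compartment field records an unannotated protein.  Repeated
    protein lines union their compartments.  Unknown compartment names
    are a hard error carrying the 1-based line number.
    """
    table = AnnotationTable(vocabulary=vocabulary)
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split(delimiter)
        protein = fields[0].strip()
        if not protein:
            raise ValueError(f"line {lineno}: empty protein ID")
        names: list[str] = []
        for fld in fields[1:]:
            names.extend(part.strip() for part in fld.split(";") if part.strip())
        try:
            table.add(protein, names)
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
    return table


@dataclass(frozen=True)
class CompartmentScoreTable:
    """Per-compartment essentiality posteriors plus their count inputs."""

    n_essential: int
    n_nonessential: int
    n_essential_in: Mapping[str, int]
    n_nonessential_in: Mapping[str, int]
    p_comp_given_essential: Mapping[str, float]
    p_comp_given_nonessential: Mapping[str, float]
    p_comp: Mapping[str, float]
    scores: Mapping[str, float]  # P(E|C_i)

    @property
    def p_essential(self) -> float:
        return self.n_essential / (self.n_essential + self.n_nonessential)

    @property
    def p_nonessential(self) -> float:
        return self.n_nonessential / (self.n_essential + self.n_nonessential)

    def to_frame(self) -> pd.DataFrame:
        comps = list(self.scores)
        return pd.DataFrame(
            {
                "compartment": comps,
                "n_essential_in": [self.n_essential_in[c] for c in comps],
                "n_nonessential_in": [self.n_nonessential_in[c] for c in comps],
                "p_comp_given_essential": [self.p_comp_given_essential[c] for c in comps],
                "p_comp_given_nonessential": [
                    self.p_comp_given_nonessential[c] for c in comps
                ],
                "p_comp": [self.p_comp[c] for c in comps],
                "score": [self.scores[c] for c in comps],
            }
        )


def compartment_scores(
    ann: AnnotationTable,
    essential: set[str],
    nonessential: set[str],
) -> CompartmentScoreTable:
    """Score every compartment with the Bayes posterior P(E|C_i).

    ``essential`` and ``nonessential`` together form the reference
    protein universe; they must be disjoint and nonempty.  Proteins in
    the universe missing from ``ann`` simply contribute no compartment
    counts.  A compartment annotated on nobody in the universe has
    P(C_i) = 0; its score is defined as 0.0 and a warning is logged.
    """
    overlap = essential & nonessential
    if overlap:
        raise ValueError(
            f"essential and nonessential sets overlap on {len(overlap)} proteins, "
            f"e.g. {sorted(overlap)[:3]}"
        )
    if not essential or not nonessential:
        raise ValueError("essential and nonessential sets must both be nonempty")

    n_e, n_ne = len(essential), len(nonessential)
    p_e = n_e / (n_e + n_ne)
    p_ne = n_ne / (n_e + n_ne)

    n_in_e: dict[str, int] = {}
    n_in_ne: dict[str, int] = {}
    p_c_e: dict[str, float] = {}
    p_c_ne: dict[str, float] = {}
    p_c: dict[str, float] = {}
    scores: dict[str, float] = {}
    for comp in ann.vocabulary:
        k_e = sum(1 for p in essential if comp in ann.compartments_of(p))
        k_ne = sum(1 for p in nonessential if comp in ann.compartments_of(p))
        n_in_e[comp] = k_e
        n_in_ne[comp] = k_ne
        p_c_e[comp] = k_e / n_e
        p_c_ne[comp] = k_ne / n_ne
        p_c[comp] = p_e * p_c_e[comp] + p_ne * p_c_ne[comp]
        if p_c[comp] == 0.0:
            log.warning("compartment %r annotated on no reference protein; score 0.0", comp)
            scores[comp] = 0.0
        else:
            scores[comp] = p_e * p_c_e[comp] / p_c[comp]
    return CompartmentScoreTable(
        n_essential=n_e,
        n_nonessential=n_ne,
        n_essential_in=n_in_e,
        n_nonessential_in=n_in_ne,
        p_comp_given_essential=p_c_e,
        p_comp_given_nonessential=p_c_ne,
        p_comp=p_c,
        scores=scores,
    )


def protein_scs(
    ann: AnnotationTable,
    table: CompartmentScoreTable,
    proteins: Iterable[str] | None = None,
) -> dict[str, float]:
    """Subcellular compartment score per protein.

    The SCS of a protein is the arithmetic mean of its compartments'
    P(E|C_i) scores, and 0.0 when it has no annotation.  ``proteins``
    selects which IDs to score (default: every annotated protein).
    """
    ids = list(proteins) if proteins is not None else list(ann.entries)
    out: dict[str, float] = {}
    for p in ids:
        comps = ann.compartments_of(p)
        if not comps:
            out[p] = 0.0
        else:
            out[p] = sum(table.scores[c] for c in comps) / len(comps)
    return out
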