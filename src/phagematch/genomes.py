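"""Turning raw genomes into the protein sets the model consumes.

Gene calling and RBP detection are adapter interfaces: in production runs
they wrap external tools (a dedicated phage gene caller; an HMM +
language-model RBP classifier), which are deliberately outside this
package.  Both come with deterministic built-in fallbacks — a six-frame
longest-ORF caller and a keyword annotation matcher — so the whole pipeline
runs hermetically.

Receptor-binding proteins are length-filtered to the 200–1500 amino-acid
window in which tail fibers/spikes are expected; candidates at exactly 200
or 1500 residues are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .data_io import NT_ALPHABET, BacteriumRecord, PhageRecord

logger = logging.getLogger(__name__)

RBP_MIN_LENGTH = 200
RBP_MAX_LENGTH = 1500

# annotation keywords the naive fallback detector flags as RBP candidates
RBP_KEYWORDS = (
    "tail fiber",
    "tail fibre",
    "tailspike",
    "tail spike",
    "receptor binding",
    "receptor-binding",
    "rbp",
    "depolymerase",
)

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class GeneCall:
    """A called gene: 0-based half-open coordinates on the forward strand,
    explicit strand, and the translated protein (stop removed)."""

    contig_id: str
    start: int
    end: int
    strand: str
    protein: str


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def call_genes(
    genome: str,
    *,
    min_aa: int = 30,
    contig_id: str = "contig",
    caller: Callable[[str], list[GeneCall]] | None = None,
) -> list[GeneCall]:
    """Call genes on a nucleotide sequence.

    With ``caller`` given, delegates to that adapter (external tool wrapper).
    The built-in caller returns maximal open reading frames — ATG through
    the first in-frame stop, both strands, translation table 11 — whose
    protein is at least ``min_aa`` residues.  Calls are sorted by start
    coordinate.
    """
    if not genome:
        raise ValueError("genome is empty")
    genome = genome.upper()
    bad = set(genome) - NT_ALPHABET
    if bad:
        raise ValueError(f"non-nucleotide characters in genome: {sorted(bad)}")
    if caller is not None:
        return sorted(caller(genome), key=lambda c: (c.start, c.end, c.strand))

    calls: list[GeneCall] = []
    length = len(genome)
    for strand, seq in (("+", genome), ("-", _revcomp(genome))):
        for frame in range(3):
            orf_start = None  # earliest ATG since the last stop, this frame
            for pos in range(frame, length - 2, 3):
                codon = seq[pos : pos + 3]
                if codon in _STOPS:
                    if orf_start is not None:
                        s, e = orf_start, pos + 3
                        protein = str(
                            Seq(seq[s : e - 3]).translate(table=11)
                        )
                        if len(protein) >= min_aa:
                            if strand == "+":
                                coords = (s, e)
                            else:
                                coords = (length - e, length - s)
                            calls.append(
                                GeneCall(contig_id, coords[0], coords[1],
                                         strand, protein)
                            )
                    orf_start = None
                elif codon == "ATG" and orf_start is None:
                    orf_start = pos
    return sorted(calls, key=lambda c: (c.start, c.end, c.strand))


def detect_rbps(
    proteins: Sequence[tuple[str, str]],
    *,
    detector: Callable[[Sequence[tuple[str, str]]], list[tuple[str, float]]] | None = None,
    annotations: Mapping[str, str] | None = None,
) -> list[tuple[str, float]]:
    """Flag receptor-binding-protein candidates among phage proteins.

    ``proteins`` is a list of (protein_id, amino-acid sequence).  With
    ``detector`` given, that adapter decides (returning (id, score) with
    scores in [0,1]); otherwise the naive fallback flags proteins whose
    annotation (``annotations[protein_id]``, falling back to the id itself)
    contains an RBP keyword, with score 1.0.  Deterministic for a fixed
    detector; an empty result is allowed.
    """
    if detector is not None:
        result = list(detector(proteins))
        for pid, score in result:
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"detector score for {pid!r} outside [0,1]")
        return result
    hits = []
    for pid, _seq in proteins:
        text = (annotations or {}).get(pid, pid).lower()
        if any(kw in text for kw in RBP_KEYWORDS):
            hits.append((pid, 1.0))
    return hits


def filter_rbps_by_length(
    candidates: Sequence[tuple[str, str]],
    min_len: int = RBP_MIN_LENGTH,
    max_len: int = RBP_MAX_LENGTH,
) -> list[tuple[str, str]]:
    """Keep candidates whose length is within [min_len, max_len], inclusive.

    Order-preserving and idempotent.
    """
    return [(pid, seq) for pid, seq in candidates if min_len <= len(seq) <= max_len]


def drop_phages_without_rbps(
    phages: Sequence[PhageRecord],
) -> tuple[list[PhageRecord], list[str]]:
    """Split off phages left with zero RBPs after detection + filtering.

    Such phages carry no receptor information and are excluded from
    training with a logged warning, never silently kept.
    """
    kept = [p for p in phages if p.rbps]
    dropped = [p.phage_id for p in phages if not p.rbps]
    if dropped:
        logger.warning(
            "dropping %d phage(s) with no RBPs after filtering: %s",
            len(dropped), dropped,
        )
    return kept, dropped


def complete_klocus(
    record: BacteriumRecord,
    reference_db: Mapping[str, Mapping[str, str]],
) -> BacteriumRecord:
    """Fill in missing K-locus genes from the best-matching KL-type reference.

    ``reference_db`` maps KL-type -> {gene_name: protein sequence}.  Each
    gene the typing tool reported missing is replaced by the reference
    protein of the record's KL-type, and recorded in ``substituted``.
    A record with no missing genes is returned unchanged.
    """
    if not record.missing_genes:
        return record
    if record.kl_type not in reference_db:
        raise KeyError(
            f"KL-type {record.kl_type!r} absent from reference database; "
            f"cannot complete missing genes {list(record.missing_genes)}"
        )
    reference = reference_db[record.kl_type]
    added = []
    for gene in record.missing_genes:
        if gene not in reference:
            raise KeyError(
                f"gene {gene!r} absent from reference locus {record.kl_type!r}"
            )
        added.append((gene, reference[gene]))
    return replace(
        record,
        klocus_proteins=record.klocus_proteins + tuple(added),
        missing_genes=(),
        substituted=record.substituted + tuple(g for g, _ in added),
    )
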