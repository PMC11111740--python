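"""Reading and writing the external formats the pipeline consumes.

Covers protein/nucleotide FASTA, the tested-interaction CSV, Kaptive-style
K-locus typing output, embedding matrices with id sidecars, and dataset
summary statistics.

A central convention lives here: the interaction table lists *tested*
(phage, bacterium) pairs only.  Pairs absent from the table are untested and
are never imputed as negatives — training and evaluation see exactly the
rows of the table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NT_ALPHABET = frozenset("ACGTN")


class FastaParseError(ValueError):
    """Raised when a FASTA file is syntactically malformed."""


@dataclass(frozen=True)
class PhageRecord:
    """A phage genome with its detected receptor-binding proteins (RBPs).

    ``host_range_kl`` is the set of KL-types the phage is known to infect;
    it is only needed by the informed-microbiologist baseline ranker.
    """

    phage_id: str
    genome: str = ""
    rbps: tuple[tuple[str, str], ...] = ()
    host_range_kl: frozenset[str] | None = None


@dataclass(frozen=True)
class BacteriumRecord:
    """A bacterium's capsule locus: nucleotide sequence, KL-type label and
    translated K-locus proteins.

    ``missing_genes`` lists locus genes the typing tool reported as absent;
    such records need reference completion before prediction.
    ``substituted`` records proteins that were filled in from the reference
    locus of the best-matching KL-type.
    """

    bacterium_id: str
    klocus_nt: str = ""
    kl_type: str = "unknown"
    klocus_proteins: tuple[tuple[str, str], ...] = ()
    missing_genes: tuple[str, ...] = ()
    substituted: tuple[str, ...] = ()


class InteractionTable:
    """Sparse table of tested (phage_id, bacterium_id, label) triples.

    Labels are binary: 1 = visible spot at a 1:10 phage dilution (an
    RBP-receptor interaction, not necessarily productive replication);
    0 = tested and not confirmed.  Any confirmation at higher dilution is
    metadata only and never changes the label.
    """

    REQUIRED_COLUMNS = ("phage_id", "bacterium_id", "label")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"interaction table missing columns: {missing}")
        frame = frame.copy()
        labels = frame["label"]
        if not labels.isin([0, 1]).all():
            bad = sorted(set(labels) - {0, 1})
            raise ValueError(f"labels must be 0 or 1; found {bad}")
        frame["label"] = labels.astype(int)
        dup = frame.duplicated(subset=["phage_id", "bacterium_id"])
        if dup.any():
            pairs = frame.loc[dup, ["phage_id", "bacterium_id"]].values.tolist()
            raise ValueError(f"duplicate tested pairs: {pairs[:5]}")
        self._frame = frame.reset_index(drop=True)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    def __len__(self) -> int:
        return len(self._frame)

    @property
    def n_positives(self) -> int:
        return int(self._frame["label"].sum())

    def validate_against(
        self, phage_ids: Iterable[str], bacterium_ids: Iterable[str]
    ) -> None:
        """Check every row's ids resolve against the two collections."""
        phage_ids, bacterium_ids = set(phage_ids), set(bacterium_ids)
        bad_p = set(self._frame["phage_id"]) - phage_ids
        bad_b = set(self._frame["bacterium_id"]) - bacterium_ids
        if bad_p or bad_b:
            raise ValueError(
                f"unresolvable ids: phages {sorted(bad_p)[:5]}, "
                f"bacteria {sorted(bad_b)[:5]}"
            )

    def to_csv(self, path: str | Path) -> None:
        self._frame.to_csv(path, index=False)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into a list of (id, uppercased sequence).

    The id is the first whitespace-delimited token of the header; record
    order is preserved.  Sequence data appearing before the first header is
    a parse error reported with its line number.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                break
            raise FastaParseError(
                f"{path}: sequence data before first header at line {lineno}"
            )
    return [
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_fasta_with_descriptions(path: str | Path) -> list[tuple[str, str, str]]:
    """Like :func:`read_fasta` but keeps the full header description."""
    read_fasta(path)  # syntax check (reparses; files here are small)
    return [
        (rec.id, rec.description, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 60) -> None:
    """Write (id, sequence) pairs (or (id, description, sequence) triples)."""
    with open(path, "w") as fh:
        for rec in records:
            if len(rec) == 3:
                rid, desc, seq = rec
                header = f"{rid} {desc}" if desc and desc != rid else rid
            else:
                rid, seq = rec
                header = rid
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_interaction_table(path: str | Path) -> InteractionTable:
    """Read the tested-pairs CSV (header: phage_id,bacterium_id,label)."""
    frame = pd.read_csv(path, dtype={"phage_id": str, "bacterium_id": str})
    return InteractionTable(frame)


def positive_rate(table: InteractionTable) -> float:
    """Percentage of tested pairs that are confirmed interactions.

    Reported to two decimals, e.g. 333 positives out of 10,006 spot tests
    gives 3.33.
    """
    if len(table) == 0:
        raise ValueError("positive rate is undefined for an empty table")
    return round(100.0 * table.n_positives / len(table), 2)


def read_klocus_output(
    table_path: str | Path,
    loci_fasta: str | Path,
    proteins_fasta: str | Path,
    dialect: str = "tsv",
) -> list[BacteriumRecord]:
    """Assemble BacteriumRecords from Kaptive-style K-locus typing output.

    ``table_path`` is the typing result table (TSV with columns
    ``assembly``, ``best_match_locus``, ``missing_genes``; or a JSON list of
    objects with those keys).  ``loci_fasta`` holds one nucleotide K-locus
    per assembly (record id = assembly id); ``proteins_fasta`` holds the
    translated locus proteins with ids ``<assembly>|<gene>``.

    Records whose typing reports missing genes are flagged for reference
    completion (see :func:`phagematch.genomes.complete_klocus`).  An
    assembly with an empty protein list is unusable and raises.
    """
    if dialect == "tsv":
        table = pd.read_csv(table_path, sep="\t", dtype=str).fillna("")
    elif dialect == "json":
        with open(table_path) as fh:
            table = pd.DataFrame(json.load(fh)).fillna("")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    required = {"assembly", "best_match_locus", "missing_genes"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ValueError(f"K-locus table missing columns: {sorted(missing_cols)}")

    loci = dict(read_fasta(loci_fasta))
    proteins: dict[str, list[tuple[str, str]]] = {}
    for pid, seq in read_fasta(proteins_fasta):
        assembly, _, gene = pid.partition("|")
        proteins.setdefault(assembly, []).append((gene or pid, seq))

    records = []
    for row in table.itertuples(index=False):
        assembly = row.assembly
        prots = proteins.get(assembly, [])
        if not prots:
            raise ValueError(
                f"assembly {assembly!r} has no K-locus proteins; "
                "record is unusable for prediction"
            )
        missing = tuple(g for g in str(row.missing_genes).split(";") if g)
        records.append(
            BacteriumRecord(
                bacterium_id=assembly,
                klocus_nt=loci.get(assembly, ""),
                kl_type=row.best_match_locus or "unknown",
                klocus_proteins=tuple(prots),
                missing_genes=missing,
            )
        )
    return records


def _embedding_paths(path: str | Path) -> tuple[Path, Path]:
    matrix_path = Path(path if str(path).endswith(".npy") else f"{path}.npy")
    return matrix_path, Path(f"{matrix_path}.ids.json")


def save_embeddings(path: str | Path, ids: Sequence[str], matrix: np.ndarray) -> None:
    """Store one embedding matrix (.npy) with a JSON id-index sidecar."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2 or matrix.shape[0] != len(ids):
        raise ValueError("matrix must be 2-d with one row per id")
    matrix_path, sidecar = _embedding_paths(path)
    np.save(matrix_path, matrix)
    with open(sidecar, "w") as fh:
        json.dump(list(ids), fh)


def load_embeddings(path: str | Path) -> tuple[list[str], np.ndarray]:
    matrix_path, sidecar = _embedding_paths(path)
    matrix = np.load(matrix_path)
    with open(sidecar) as fh:
        ids = json.load(fh)
    return ids, matrix


def dataset_summary(
    phages: Sequence[PhageRecord],
    bacteria: Sequence[BacteriumRecord],
    table: InteractionTable | None = None,
) -> dict:
    """Headline statistics of a dataset (counts, RBP/protein ranges, rate)."""
    rbp_counts = [len(p.rbps) for p in phages]
    prot_counts = [len(b.klocus_proteins) for b in bacteria]
    summary = {
        "n_phages": len(phages),
        "n_bacteria": len(bacteria),
        "n_kl_types": len({b.kl_type for b in bacteria}),
        "rbps_per_phage": (min(rbp_counts), max(rbp_counts)) if rbp_counts else (0, 0),
        "proteins_per_klocus": (
            (min(prot_counts), max(prot_counts)) if prot_counts else (0, 0)
        ),
    }
    if table is not None and len(table) > 0:
        summary["n_tested"] = len(table)
        summary["n_positive"] = table.n_positives
        summary["positive_rate_pct"] = positive_rate(table)
    return summary
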