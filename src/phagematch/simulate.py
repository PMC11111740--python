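"""Hermetic synthetic datasets with the statistical structure of a
strain-level Klebsiella phage-host interaction study.

The generator plants a receptor-compatibility rule that any
sequence-sensitive embedder can pick up: every KL-type carries a distinct
amino-acid motif, written into all of that type's K-locus proteins (and, in
reverse-translated form, into the type's ancestral locus nucleotide
sequence); every phage carries the motifs of the KL-types it infects in at
least one RBP.  A (phage, bacterium) pair interacts exactly when the
bacterium's KL-type is in the phage's host range, optionally XOR-ed with
label noise.  Only a configured fraction of pairs carry a recorded spot
test, mirroring a partially tested interaction matrix.

Default configuration = the study-scale conditions: 105 phages with 1-8
RBPs, 200 bacteria with 10-25 K-locus proteins, ~3.33% positive rate,
half of all pairs tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import json
import numpy as np
import pandas as pd

from .data_io import (
    BacteriumRecord,
    InteractionTable,
    PhageRecord,
    write_fasta,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
NT4 = "ACGT"

# one codon per amino acid, used to reverse-translate synthetic proteins
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition knobs of the generator (defaults = study scale)."""

    n_phages: int = 105
    n_bacteria: int = 200
    n_kl_types: int = 36
    rbps_per_phage: tuple[int, int] = (1, 8)
    proteins_per_klocus: tuple[int, int] = (10, 25)
    target_positive_rate: float = 0.0333
    broad_host_fraction: float = 0.1
    broad_range_sizes: tuple[int, ...] = (2, 3, 4)
    label_noise: float = 0.0
    tested_fraction: float = 0.5
    klocus_nt_len: int = 1000
    within_type_divergence: float = 0.03
    rbp_len: tuple[int, int] = (200, 400)
    klocus_protein_len: tuple[int, int] = (80, 200)
    motif_len: int = 40
    motif_copies: int = 2
    decoys_per_phage: tuple[int, int] = (0, 2)
    seed: int = 0

    def expected_positive_rate(self) -> float:
        """Positive rate implied by the compatibility structure, assuming
        bacteria are spread uniformly over KL-types."""
        b = self.broad_host_fraction
        mean_range = (1 - b) + b * float(np.mean(self.broad_range_sizes))
        return mean_range / self.n_kl_types

    def validate(self) -> None:
        for lo, hi in (self.rbps_per_phage, self.proteins_per_klocus,
                       self.rbp_len, self.klocus_protein_len,
                       self.decoys_per_phage):
            if not (0 <= lo <= hi):
                raise ValueError(f"invalid range ({lo}, {hi})")
        for rate in (self.target_positive_rate, self.broad_host_fraction,
                     self.label_noise, self.tested_fraction,
                     self.within_type_divergence):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")
        if max(self.broad_range_sizes) > self.n_kl_types:
            raise ValueError("broad host range exceeds number of KL-types")
        expected = self.expected_positive_rate()
        if self.target_positive_rate > 0 and (
            abs(expected - self.target_positive_rate) / self.target_positive_rate
            > 0.5
        ):
            raise ValueError(
                f"target positive rate {self.target_positive_rate:.4f} is "
                f"infeasible: the compatibility structure (host ranges over "
                f"{self.n_kl_types} KL-types) yields an expected rate of "
                f"{expected:.4f}; adjust n_kl_types or broad_host_fraction"
            )


def demo_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Desk-scale preset for tests and fast end-to-end runs.

    Same planted structure as the study-scale default, scaled to 30 phages,
    48 bacteria and 9 KL-types (expected positive rate 1.2/9 ≈ 13.3%) so
    full LOGOCV with per-fold retraining completes in seconds-to-minutes on
    one CPU.
    """
    params = dict(
        n_phages=30,
        n_bacteria=48,
        n_kl_types=9,
        rbps_per_phage=(1, 4),
        proteins_per_klocus=(6, 12),
        target_positive_rate=1.2 / 9,
        klocus_nt_len=600,
        rbp_len=(200, 300),
        klocus_protein_len=(80, 150),
        seed=seed,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


def tiny_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Minimal preset for smoke tests: 10 phages, 14 bacteria, 4 KL-types."""
    params = dict(
        n_phages=10,
        n_bacteria=14,
        n_kl_types=4,
        rbps_per_phage=(1, 3),
        proteins_per_klocus=(4, 6),
        target_positive_rate=1.2 / 4,
        tested_fraction=0.8,
        klocus_nt_len=300,
        rbp_len=(200, 260),
        klocus_protein_len=(60, 100),
        seed=seed,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


def _random_aa(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(NT4), size=length))


def _insert(rng: np.random.Generator, seq: str, motif: str, copies: int) -> str:
    for _ in range(copies):
        pos = int(rng.integers(0, len(seq) + 1))
        seq = seq[:pos] + motif + seq[pos:]
    return seq


def reverse_translate(protein: str) -> str:
    return "".join(_CODON[aa] for aa in protein)


def mutate_klocus(sequence: str, divergence: float, seed: int) -> str:
    """Point-mutate ~``divergence`` x length positions (substitutions only),
    so expected pairwise identity to the input is about 100x(1-divergence)."""
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    chars = np.array(list(sequence))
    mask = rng.random(len(chars)) < divergence
    for i in np.flatnonzero(mask):
        options = [b for b in NT4 if b != chars[i]]
        chars[i] = options[int(rng.integers(0, len(options)))]
    return "".join(chars)


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[list[PhageRecord], list[BacteriumRecord], InteractionTable, dict]:
    """Generate (phages, bacteria, interaction table, ground truth).

    Fully reproducible from ``config.seed``.  ``truth`` holds the planted
    host ranges, KL-type assignments, motifs, per-protein annotations and
    the full noiseless compatibility labels.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    kl_names = [f"KL{i + 1}" for i in range(config.n_kl_types)]
    motifs: dict[str, str] = {}
    while len(motifs) < config.n_kl_types:
        m = _random_aa(rng, config.motif_len)
        if m not in motifs.values():
            motifs[kl_names[len(motifs)]] = m
    ancestors = {}
    for kl in kl_names:
        anc = _random_nt(rng, config.klocus_nt_len)
        tag = reverse_translate(motifs[kl])
        pos = int(rng.integers(0, len(anc) + 1))
        ancestors[kl] = anc[:pos] + tag + anc[pos:]

    # bacteria: KL-type, mutated family locus, motif-carrying proteins
    bacteria: list[BacteriumRecord] = []
    kl_of: dict[str, str] = {}
    width_b = len(str(config.n_bacteria))
    for i in range(config.n_bacteria):
        bid = f"B{i + 1:0{width_b}d}"
        kl = kl_names[int(rng.integers(0, config.n_kl_types))]
        kl_of[bid] = kl
        locus = mutate_klocus(
            ancestors[kl], config.within_type_divergence,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        lo, hi = config.proteins_per_klocus
        n_prot = int(rng.integers(lo, hi + 1))
        proteins = []
        for j in range(n_prot):
            plen = int(rng.integers(*config.klocus_protein_len))
            prot = _insert(rng, _random_aa(rng, plen), motifs[kl], 1)
            proteins.append((f"{bid}|gene{j + 1}", prot))
        bacteria.append(
            BacteriumRecord(bid, locus, kl, tuple(proteins))
        )

    # phages: host range over KL-types, motif-carrying RBPs, decoys
    phages: list[PhageRecord] = []
    host_ranges: dict[str, tuple[str, ...]] = {}
    annotations: dict[str, str] = {}
    decoys_of: dict[str, list[tuple[str, str]]] = {}
    width_p = len(str(config.n_phages))
    for i in range(config.n_phages):
        pid = f"P{i + 1:0{width_p}d}"
        if rng.random() < config.broad_host_fraction:
            size = int(rng.choice(config.broad_range_sizes))
        else:
            size = 1
        hrange = tuple(sorted(rng.choice(kl_names, size=size, replace=False)))
        host_ranges[pid] = hrange
        lo, hi = config.rbps_per_phage
        n_rbp = max(int(rng.integers(lo, hi + 1)), 1)
        rbps = []
        for j in range(n_rbp):
            rlen = int(rng.integers(*config.rbp_len))
            rbps.append([f"{pid}_rbp{j + 1}", _random_aa(rng, rlen)])
        # every RBP carries the binding domain of one compatible KL-type,
        # cycling through the host range so each type lands in >= 1 RBP
        # (narrow phages thus carry their domain in every RBP, as redundant
        # fiber variants targeting the same capsule)
        for t in range(max(n_rbp, len(hrange))):
            kl = hrange[t % len(hrange)]
            rbps[t % n_rbp][1] = _insert(rng, rbps[t % n_rbp][1], motifs[kl],
                                         config.motif_copies)
        for rbp_id, _ in rbps:
            annotations[rbp_id] = "tail fiber protein"
        dlo, dhi = config.decoys_per_phage
        decoys = []
        for j in range(int(rng.integers(dlo, dhi + 1))):
            decoy_id = f"{pid}_orf{j + 1}"
            decoys.append((decoy_id, _random_aa(rng, int(rng.integers(50, 150)))))
            annotations[decoy_id] = "hypothetical protein"
        decoys_of[pid] = decoys
        genes = [tuple(r) for r in rbps] + decoys
        genome_parts = []
        for _, prot in genes:
            genome_parts.append(_random_nt(rng, int(rng.integers(10, 30))))
            genome_parts.append("ATG" + reverse_translate(prot) + "TAA")
        phages.append(
            PhageRecord(
                pid,
                genome="".join(genome_parts),
                rbps=tuple(tuple(r) for r in rbps),
                host_range_kl=frozenset(hrange),
            )
        )

    # labels: compatibility XOR noise, over the tested subset of pairs
    compat = {
        (p.phage_id, b.bacterium_id): int(kl_of[b.bacterium_id] in host_ranges[p.phage_id])
        for p in phages
        for b in bacteria
    }
    all_pairs = list(compat)
    n_tested = int(round(config.tested_fraction * len(all_pairs)))
    if n_tested == 0:
        raise ValueError("tested_fraction leaves no tested pairs")
    tested_idx = rng.choice(len(all_pairs), size=n_tested, replace=False)
    rows = []
    for idx in sorted(tested_idx):
        pid, bid = all_pairs[idx]
        label = compat[(pid, bid)]
        if config.label_noise > 0 and rng.random() < config.label_noise:
            label = 1 - label
        rows.append((pid, bid, label))
    table = InteractionTable(
        pd.DataFrame(rows, columns=["phage_id", "bacterium_id", "label"])
    )

    truth = {
        "host_ranges": {pid: list(r) for pid, r in host_ranges.items()},
        "kl_types": dict(kl_of),
        "motifs": motifs,
        "annotations": annotations,
        "decoys": {pid: [list(d) for d in ds] for pid, ds in decoys_of.items()},
        "compatibility": {f"{p}\t{b}": v for (p, b), v in compat.items()},
        "config": asdict(config),
    }
    return phages, bacteria, table, truth


def generate_separable_preset(
    d: int, n: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Two Gaussian clouds made linearly separable by construction.

    The first coordinate is the class signal, fixed at +2 for the positive
    class and -2 for the negative class; the remaining coordinates are
    standard Gaussian noise.  The hyperplane x[0] = 0 separates with margin
    2, and because the signal coordinate is constant within each class, any
    learner that thresholds it classifies held-out points perfectly too.
    """
    if d < 2 or n < 20:
        raise ValueError("need d >= 2 and n >= 20")
    rng = np.random.default_rng(seed)
    y = np.zeros(n, dtype=int)
    y[n // 2 :] = 1
    X = rng.normal(size=(n, d))
    X[:, 0] = np.where(y == 1, 2.0, -2.0)
    return X, y


def write_dataset(
    outdir: str | Path,
    phages: Sequence[PhageRecord],
    bacteria: Sequence[BacteriumRecord],
    table: InteractionTable,
    truth: dict | None = None,
) -> dict[str, Path]:
    """Write a generated dataset in the exact formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotations = (truth or {}).get("annotations", {})
    paths = {
        "phage_genomes": outdir / "phage_genomes.fna",
        "phage_proteins": outdir / "phage_proteins.faa",
        "klocus_nt": outdir / "klocus_nt.fna",
        "klocus_proteins": outdir / "klocus_proteins.faa",
        "klocus_table": outdir / "klocus_table.tsv",
        "interactions": outdir / "interactions.csv",
    }
    write_fasta([(p.phage_id, p.genome) for p in phages], paths["phage_genomes"])
    decoys = (truth or {}).get("decoys", {})
    protein_records = []
    for p in phages:
        for pid, seq in p.rbps:
            protein_records.append((pid, annotations.get(pid, ""), seq))
        for pid, seq in decoys.get(p.phage_id, []):
            protein_records.append((pid, annotations.get(pid, ""), seq))
    write_fasta(protein_records, paths["phage_proteins"])
    write_fasta([(b.bacterium_id, b.klocus_nt) for b in bacteria],
                paths["klocus_nt"])
    write_fasta(
        [(pid, seq) for b in bacteria for pid, seq in b.klocus_proteins],
        paths["klocus_proteins"],
    )
    pd.DataFrame(
        {
            "assembly": [b.bacterium_id for b in bacteria],
            "best_match_locus": [b.kl_type for b in bacteria],
            "missing_genes": [";".join(b.missing_genes) for b in bacteria],
        }
    ).to_csv(paths["klocus_table"], sep="\t", index=False)
    table.to_csv(paths["interactions"])
    if truth is not None:
        paths["truth"] = outdir / "truth.json"
        with open(paths["truth"], "w") as fh:
            json.dump(truth, fh, indent=0, sort_keys=True)
    return paths
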