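"""End-to-end orchestration: simulate -> process -> embed -> train ->
evaluate -> rank, with versioned artifacts and a hash manifest.

Each stage reads only the artifacts of earlier stages and writes its own
under the run directory; re-running with an identical configuration is
idempotent (the manifest hashes do not change).  Protein ids follow the
convention ``<entity_id>_<suffix>`` (phage side) and ``<entity_id>|<gene>``
(bacterium side), which is how proteins are attributed to entities.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data_io, genomes
from .data_io import (
    BacteriumRecord,
    PhageRecord,
    read_fasta_with_descriptions,
    read_interaction_table,
    read_klocus_output,
    write_fasta,
)
from .evaluate import (
    group_by_identity,
    hit_ratio_at_k,
    identity_matrix,
    mean_hit_ratio_curve,
    roc_auc,
    run_logocv,
)
from .features import KmerHashEmbedder, build_pair_matrix, represent_entities
from .model import PhageHostClassifier
from .ranking import rank_phages, write_topk_report
from .simulate import (
    SyntheticConfig,
    demo_config,
    generate_dataset,
    tiny_config,
    write_dataset,
)

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (75.0, 80.0, 85.0, 90.0, 95.0, 100.0)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    outdir: str = "run"
    seed: int = 0
    preset: str = "demo"  # "demo" | "study" | "none" (external data)
    data_dir: str | None = None  # input dir when preset == "none"
    embedder_dim: int = 64
    embedder_k: int = 3
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    k_top: int = 5
    tune: bool = False
    params: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self):
        bad = [t for t in self.thresholds if not 75.0 <= t <= 100.0]
        if bad:
            raise ValueError(f"thresholds outside [75, 100]: {bad}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "thresholds" in data:
            data["thresholds"] = tuple(float(t) for t in data["thresholds"])
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _phage_of(protein_id: str) -> str:
    return protein_id.rsplit("_", 1)[0]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig, outdir: Path) -> dict[str, Path]:
    presets = {"demo": demo_config, "tiny": tiny_config,
               "study": lambda seed: SyntheticConfig(seed=seed)}
    if config.preset not in presets:
        raise ValueError(f"unknown preset {config.preset!r}")
    syn = presets[config.preset](seed=config.seed)
    phages, bacteria, table, truth = generate_dataset(syn)
    return write_dataset(outdir / "data", phages, bacteria, table, truth)


def stage_process(
    config: RunConfig, data_dir: Path, outdir: Path
) -> tuple[list[PhageRecord], list[BacteriumRecord], data_io.InteractionTable]:
    """Detect + length-filter RBPs and assemble bacterium records."""
    proteins = read_fasta_with_descriptions(data_dir / "phage_proteins.faa")
    annotations = {pid: desc for pid, desc, _ in proteins}
    seqs = [(pid, seq) for pid, _, seq in proteins]
    flagged = dict(genomes.detect_rbps(seqs, annotations=annotations))
    candidates = [(pid, seq) for pid, seq in seqs if pid in flagged]
    kept = genomes.filter_rbps_by_length(candidates)

    by_phage: dict[str, list[tuple[str, str]]] = {}
    for pid, seq in kept:
        by_phage.setdefault(_phage_of(pid), []).append((pid, seq))
    genome_file = data_dir / "phage_genomes.fna"
    genomes_by_id = (
        dict(data_io.read_fasta(genome_file)) if genome_file.exists() else {}
    )
    phages = [
        PhageRecord(pid, genomes_by_id.get(pid, ""), tuple(rbps))
        for pid, rbps in sorted(by_phage.items())
    ]
    phages, dropped = genomes.drop_phages_without_rbps(phages)

    bacteria = read_klocus_output(
        data_dir / "klocus_table.tsv",
        data_dir / "klocus_nt.fna",
        data_dir / "klocus_proteins.faa",
    )
    table = read_interaction_table(data_dir / "interactions.csv")
    if dropped:
        table = data_io.InteractionTable(
            table.frame[~table.frame["phage_id"].isin(dropped)]
        )
    table.validate_against(
        [p.phage_id for p in phages], [b.bacterium_id for b in bacteria]
    )

    processed = outdir / "processed"
    processed.mkdir(parents=True, exist_ok=True)
    write_fasta(
        [(pid, seq) for p in phages for pid, seq in p.rbps],
        processed / "rbps_filtered.faa",
    )
    table.to_csv(processed / "interactions.csv")
    with open(processed / "summary.json", "w") as fh:
        json.dump(data_io.dataset_summary(phages, bacteria, table), fh,
                  indent=2, sort_keys=True)
    return phages, bacteria, table


def stage_embed(
    config: RunConfig,
    phages: list[PhageRecord],
    bacteria: list[BacteriumRecord],
    outdir: Path,
):
    embedder = KmerHashEmbedder(dim=config.embedder_dim, k=config.embedder_k)
    phage_reps = represent_entities(
        ((p.phage_id, "phage", p.rbps) for p in phages), embedder
    )
    bact_reps = represent_entities(
        ((b.bacterium_id, "bacterium", b.klocus_proteins) for b in bacteria),
        embedder,
    )
    emb_dir = outdir / "embeddings"
    emb_dir.mkdir(parents=True, exist_ok=True)
    for name, reps in (("phages", phage_reps), ("bacteria", bact_reps)):
        ids = sorted(reps)
        data_io.save_embeddings(
            emb_dir / name, ids, np.vstack([reps[i].vector for i in ids])
        )
    return phage_reps, bact_reps


def stage_train(config, table, phage_reps, bact_reps, outdir: Path):
    X = build_pair_matrix(table.frame, phage_reps, bact_reps)
    y = table.frame["label"].to_numpy()
    clf = PhageHostClassifier(
        **config.params, tune=config.tune, random_state=config.seed
    )
    clf.fit(X, y)
    model_dir = outdir / "model"
    model_dir.mkdir(parents=True, exist_ok=True)
    clf.save(model_dir / "model.joblib")
    with open(model_dir / "metadata.json", "w") as fh:
        json.dump(clf.metadata_, fh, indent=2, sort_keys=True)
    return clf, X, y


def stage_evaluate(config, X, table, bacteria, outdir: Path) -> dict:
    loci = [b.klocus_nt for b in bacteria]
    ids = [b.bacterium_id for b in bacteria]
    M = identity_matrix(loci)
    eval_dir = outdir / "evaluation"
    eval_dir.mkdir(parents=True, exist_ok=True)
    summaries = {}
    for threshold in config.thresholds:
        groups = group_by_identity(M, threshold, ids)
        folds = run_logocv(
            X, table.frame, groups, params=config.params, seed=config.seed,
            tune_per_fold=config.tune,
        )
        pooled = pd.concat([f.pairs for f in folds], ignore_index=True)
        tag = f"t{int(threshold)}"
        pooled.to_csv(eval_dir / f"scores_{tag}.csv", index=False,
                      float_format="%.6f")
        curve = mean_hit_ratio_curve(folds)
        pd.DataFrame(
            {"k": curve.k, "mean_hit_ratio": curve.mean_hit_ratio}
        ).to_csv(eval_dir / f"hit_ratio_{tag}.csv", index=False,
                 float_format="%.6f")
        n_phages = pooled["phage_id"].nunique()
        summary = {
            "threshold": threshold,
            "n_groups": len(set(groups.mapping.values())),
            "auc": round(roc_auc(folds), 4),
            "hit_ratio": {
                str(k): round(hit_ratio_at_k(folds, k), 4)
                for k in (1, 5, 10)
                if k <= n_phages
            },
        }
        with open(eval_dir / f"summary_{tag}.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        summaries[tag] = summary
        logger.info("threshold %s: AUC %.3f", threshold, summary["auc"])
    return summaries


def stage_rank(config, clf, phage_reps, bact_reps, outdir: Path) -> Path:
    panel = [phage_reps[pid] for pid in sorted(phage_reps)]
    rankings = [
        rank_phages(clf, bact_reps[bid], panel) for bid in sorted(bact_reps)
    ]
    rank_dir = outdir / "ranking"
    rank_dir.mkdir(parents=True, exist_ok=True)
    report = rank_dir / f"top{config.k_top}_report.csv"
    write_topk_report(rankings, k=config.k_top, path=report)
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and write a manifest of artifact hashes."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        if config.preset == "none":
            if not config.data_dir:
                raise ValueError("preset 'none' requires data_dir")
            data_dir = Path(config.data_dir)
        else:
            data_dir = stage_simulate(config, outdir)["interactions"].parent
        stage = "process"
        phages, bacteria, table = stage_process(config, data_dir, outdir)
        stage = "embed"
        phage_reps, bact_reps = stage_embed(config, phages, bacteria, outdir)
        stage = "train"
        clf, X, y = stage_train(config, table, phage_reps, bact_reps, outdir)
        stage = "evaluate"
        summaries = stage_evaluate(config, X, table, bacteria, outdir)
        stage = "rank"
        stage_rank(config, clf, phage_reps, bact_reps, outdir)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "config": {**asdict(config), "thresholds": list(config.thresholds)},
        "artifacts": {
            str(p.relative_to(outdir)): _sha256(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {"summaries": summaries, "manifest": manifest}
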