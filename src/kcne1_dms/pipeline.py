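"""End-to-end orchestration of the simulate -> subassemble -> score ->
classify -> calibrate stages, with a reproducibility manifest.

Each stage reads and writes the plain-text formats declared by the
module it wraps; the manifest records every artifact with its SHA-256
hash, the parameters, and the seed, so any number in a report can be
traced to inputs + parameters + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd

from . import classify, io, score_fitness, score_sortseq
from .sim_assay import SimConfig, simulate_depletion, simulate_library, simulate_sortseq
from .variants import ReferenceModel


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class Manifest:
    def __init__(self, out_dir: Path, params: dict):
        self.out_dir = out_dir
        self.entries: list[dict] = []
        self.params = params

    def add(self, path: Path, stage: str) -> None:
        self.entries.append(
            {"stage": stage, "path": str(path.relative_to(self.out_dir)),
             "sha256": _sha256(path)}
        )

    def write(self) -> Path:
        path = self.out_dir / "manifest.json"
        path.write_text(
            json.dumps({"params": self.params, "artifacts": self.entries}, indent=2)
        )
        return path


def simulate_stage(cfg: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Run the generator and write barcode map, truth, and count matrices."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    barcode_map, truth = simulate_library(cfg)
    sort_counts = simulate_sortseq(barcode_map, truth, cfg)
    depl_counts = simulate_depletion(barcode_map, truth, cfg)
    paths = {
        "reference": out_dir / "reference.fasta",
        "barcode_map": out_dir / "barcode_map.tsv",
        "truth": out_dir / "truth.tsv",
        "sortseq_counts": out_dir / "sortseq_counts.tsv",
        "depletion_counts": out_dir / "depletion_counts.tsv",
    }
    io.write_reference_fasta(ReferenceModel.from_cds(truth.attrs["cds"]), paths["reference"])
    io.write_barcode_map(barcode_map, paths["barcode_map"])
    truth.to_csv(paths["truth"], sep="\t")
    io.write_count_matrix(sort_counts, paths["sortseq_counts"])
    io.write_count_matrix(depl_counts, paths["depletion_counts"])
    return paths


def score_stage(
    counts: pd.DataFrame,
    barcode_map: pd.DataFrame,
    truth: pd.DataFrame,
    assay: str,
    n_boot: int = 1000,
    seed: int = 0,
    protein_length: int | None = None,
) -> pd.DataFrame:
    """Score one assay (``trafficking`` or ``functional``) and classify.

    Returns the score table with normalized estimates, CIs, and the
    six-way category column.
    """
    protein_length = protein_length or int(truth["position"].max())
    if assay == "trafficking":
        bc_scores = score_sortseq.barcode_scores(counts)
    elif assay == "functional":
        bc_scores = score_fitness.barcode_slopes(counts)
    else:
        raise ValueError(f"unknown assay {assay!r}")
    variant_scores = score_sortseq.aggregate_variant_scores(bc_scores, barcode_map)
    early = classify.early_nonsense_names(truth, assay, protein_length)
    table = score_sortseq.score_table(
        variant_scores,
        truth["vclass"],
        early,
        n_boot=n_boot,
        seed=seed,
        bc_scores=bc_scores,
        barcode_map=barcode_map,
    )
    syn_scores = table.loc[
        truth["vclass"].reindex(table.index) == "synonymous", "score"
    ].to_numpy()
    non_scores = table.loc[table.index.intersection(early), "score"].to_numpy()
    cutoffs = classify.compute_cutoffs(syn_scores, non_scores)
    table["category"] = classify.classify_table(table, cutoffs)
    table.attrs["cutoffs"] = dataclasses.asdict(cutoffs)
    for col in ("position", "ref_aa", "alt_aa", "vclass"):
        table[col] = truth[col].reindex(table.index)
    return table


def run(cfg: SimConfig, out_dir: str | Path, n_boot: int = 1000) -> Path:
    """Full synthetic run; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(
        out_dir,
        {"seed": cfg.seed, "n_boot": n_boot, "config": dataclasses.asdict(cfg)},
    )
    paths = simulate_stage(cfg, out_dir)
    for path in paths.values():
        manifest.add(path, "simulate")

    barcode_map = io.read_barcode_map(paths["barcode_map"])
    truth = pd.read_csv(paths["truth"], sep="\t").set_index("name")
    for assay, counts_key in (
        ("trafficking", "sortseq_counts"),
        ("functional", "depletion_counts"),
    ):
        counts = io.read_count_matrix(paths[counts_key])
        table = score_stage(
            counts, barcode_map, truth, assay,
            n_boot=n_boot, seed=cfg.seed, protein_length=cfg.protein_length,
        )
        score_path = out_dir / f"{assay}_scores.csv"
        io.write_score_csv(table, score_path)
        manifest.add(score_path, f"score-{assay}")

    traffic = io.read_score_csv(out_dir / "trafficking_scores.csv")
    functional = io.read_score_csv(out_dir / "functional_scores.csv")
    xtab = classify.crosstab_categories(traffic["category"], functional["category"])
    xtab_path = out_dir / "category_crosstab.tsv"
    xtab.to_csv(xtab_path, sep="\t")
    manifest.add(xtab_path, "classify")
    return manifest.write()
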