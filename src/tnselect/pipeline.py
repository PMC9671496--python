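"""End-to-end workflow: configuration, simulate -> enrich -> score.

All randomness flows from a single master seed; artifacts for a fixed
config + seed are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as tio
from .enrichment import TnSeqScreenModel, TnSeqScreenResults
from .simulate import SelectionModel, simulate_experiment

__all__ = ["RunConfig", "run_pipeline", "score_against_truth", "ScreenScore"]

log = logging.getLogger("tnselect")


@dataclass
class RunConfig:
    """Flat run configuration: paths, enrichment thresholds, simulation
    parameters, and the master seed.

    Precedence when assembled by the CLI: command-line flags > config file >
    defaults.  Every field is echoed into the run-metadata output.
    """

    # paths (all optional; simulation fills the gaps)
    counts: str = ""
    gff: str = ""
    fasta: str = ""
    sample_sheet: str = ""
    out_dir: str = "tnselect_out"
    # enrichment thresholds
    fc_threshold: float = 2.0
    strong_threshold: float = 5.0
    min_unique: int = 1
    pseudocount: float = 1.0
    small_gene_len: int = 400
    # simulation
    simulate: bool = False
    sim: SelectionModel = field(default_factory=SelectionModel)
    seed: int = 0
    verbosity: str = "INFO"

    def validate(self) -> list[str]:
        problems = []
        for name in ("fc_threshold", "strong_threshold", "pseudocount"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be > 0")
        if self.min_unique < 0:
            problems.append("min_unique must be >= 0")
        if not self.simulate:
            for name in ("counts", "gff", "sample_sheet"):
                path = getattr(self, name)
                if not path:
                    problems.append(f"{name} path is required unless simulate=true")
                elif not Path(path).exists():
                    problems.append(f"{name} path {path!r} does not exist")
        return problems

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        raw.update({k: v for k, v in overrides.items() if v is not None})
        sim = SelectionModel(**sim_raw)
        cfg = cls(sim=sim, **raw)
        cfg.sim.seed = cfg.seed
        return cfg

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def run_pipeline(config: RunConfig) -> TnSeqScreenResults:
    """Run the full analysis described by ``config``.

    Either simulates an experiment (simulate=true) or loads counts, GFF,
    and sample sheet from the configured paths; fits the screen model;
    writes the per-gene, hits, and review TSVs plus run metadata to
    ``out_dir``.  Raises on any schema problem before computing anything.
    """
    problems = config.validate()
    if problems:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    truth = None
    if config.simulate:
        config.sim.seed = config.seed
        log.info("simulating experiment (seed=%d, %d genes, library %d)",
                 config.seed, config.sim.n_genes, config.sim.library_size)
        exp = simulate_experiment(config.sim, out_dir=out / "simulated")
        annotation, tables, sheet = exp.annotation, exp.tables, exp.sample_sheet
        truth = exp.truth
    else:
        log.info("loading annotation %s", config.gff)
        annotation = tio.read_annotation(config.gff)
        sheet = tio.read_sample_sheet(config.sample_sheet)
        meta = {
            r["sample_id"]: dict(
                condition=r["condition"],
                phage_label=r["phage_label"],
                replicate=int(r["replicate"]),
                paired_control_id=r["paired_control_id"],
            )
            for _, r in sheet.iterrows()
        }
        tables = tio.read_counts_tsv(config.counts, sample_meta=meta)
    log.info("loaded %d samples, %d genes", len(tables), len(annotation))

    model = TnSeqScreenModel.from_tables(
        tables, sheet, annotation, pseudocount=config.pseudocount
    )
    results = model.fit(
        fc_threshold=config.fc_threshold,
        strong_threshold=config.strong_threshold,
        min_unique=config.min_unique,
        small_gene_len=config.small_gene_len,
    )
    log.info(
        "fit complete: %d hits, %d review flags, replicate r=%.3f",
        len(results.hits), len(results.review_flags), results.replicate_correlation,
    )
    results.to_tsv(out)
    with open(out / "run_metadata.txt", "a") as fh:
        fh.write(f"seed\t{config.seed}\n")

    if truth is not None:
        score = score_against_truth(results.hits, truth)
        pd.DataFrame([score.as_dict()]).to_csv(out / "score.tsv", sep="\t", index=False)
        log.info("score vs truth: sensitivity=%.3f FP=%d precision=%.3f",
                 score.sensitivity, score.false_positives, score.precision)
    return results


@dataclass
class ScreenScore:
    sensitivity: float
    false_positives: int
    precision: float
    n_planted: int
    n_called: int

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def score_against_truth(hits: pd.DataFrame, truth: pd.DataFrame) -> ScreenScore:
    """Score called hits against the simulator's planted truth.

    Sensitivity = called planted genes / planted genes (resistance plus
    costly-resistance classes); false positives = called genes that were
    not planted.
    """
    if "planted_hit" not in truth.columns:
        raise ValueError("truth table lacks a planted_hit column")
    called = set(hits["gene_id"])
    universe = set(truth["gene_id"])
    if called and not (called & universe):
        raise ValueError("hit and truth tables share no gene ids")
    planted = set(truth.loc[truth["planted_hit"], "gene_id"])
    tp = len(called & planted)
    fp = len(called - planted)
    sensitivity = tp / len(planted) if planted else float("nan")
    precision = tp / len(called) if called else float("nan")
    return ScreenScore(
        sensitivity=sensitivity,
        false_positives=fp,
        precision=precision,
        n_planted=len(planted),
        n_called=len(called),
    )
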