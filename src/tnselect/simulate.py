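"""Synthetic transposon library under phage selection.

Emulates the statistical structure of a high-density Tn mutant library on a
small bacterial genome passed through a phage challenge: essential-gene
insertion voids, fitness-cost depletion during library growth, enrichment
of phage-surviving mutants, a survivor plating bottleneck, and
overdispersed (Dirichlet-multinomial) sequencing counts.

The generative model, per mutant:

1. insertion site ~ Uniform over non-essential gene bodies + intergenic space
2. abundance   ~ Gamma(shape, 1) * w(gene)      (library growth; w=0 kills)
3. challenge:   survives ~ Bernoulli(s(gene))   for resistance classes,
                Bernoulli(epsilon)              otherwise (phenotypic escape)
4. plating:     survivors subsampled without replacement to plate capacity
5. sequencing:  site counts ~ DirichletMultinomial(read_depth, dispersion)

All randomness flows from one master seed through numpy SeedSequence
children spawned in a fixed order (genome, library, then per-replicate
selection/plating/sequencing), so each stage is independently reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GeneRecord, GenomeAnnotation, InsertionCountTable

__all__ = [
    "GeneSimAttrs",
    "SelectionModel",
    "MutantLibrary",
    "SimulatedExperiment",
    "apportion_classes",
    "generate_genome",
    "build_library",
    "apply_phage_selection",
    "sequence_library",
    "simulate_experiment",
]

GENE_CLASSES = ("neutral", "essential", "resistance", "costly_resistance", "costly_neutral")
#: Classes whose mutants are planted to survive phage challenge.
RESISTANT_CLASSES = frozenset({"resistance", "costly_resistance"})


@dataclass(frozen=True)
class GeneSimAttrs:
    """Per-gene simulation parameters."""

    gene_class: str
    relative_fitness: float  # w in [0, 1]; 0 for essential genes
    survival_prob: float  # s in [0, 1]; chance a mutant survives phage

    def __post_init__(self):
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {self.gene_class!r}")
        if not 0 <= self.relative_fitness <= 1:
            raise ValueError("relative_fitness must be in [0, 1]")
        if not 0 <= self.survival_prob <= 1:
            raise ValueError("survival_prob must be in [0, 1]")
        if self.gene_class == "essential" and self.relative_fitness != 0:
            raise ValueError("essential genes must have relative_fitness 0")


@dataclass
class SelectionModel:
    """Global parameters of the simulated screen.

    Defaults describe a scaled-down two-replicate phage challenge: a
    2,000-gene genome carrying 10 resistance and 5 costly-resistance genes,
    a library of 1e5 mutants challenged at high multiplicity so that
    phage-sensitive mutants survive only at the escape baseline epsilon,
    survivors plated in full while the untreated control is plated through
    a 100x larger bottleneck, and the challenged arm sequenced at 1/100 of
    the control read depth (libraries pooled 1:100).
    """

    n_genes: int = 2000
    class_fractions: dict = field(
        default_factory=lambda: {
            "neutral": 0.9425,
            "essential": 0.05,
            "resistance": 0.005,
            "costly_resistance": 0.0025,
        }
    )
    mean_gene_len: int = 900
    intergenic_len: int = 100
    small_gene_len: int = 400  # genes below this exercise the small-gene review flag
    resistance_survival: float = 0.9  # s for resistance-class genes
    costly_fitness: float = 0.1  # w for costly classes
    escape_baseline: float = 1e-3  # epsilon: survival of phage-sensitive mutants
    library_size: int = 100_000
    survivor_plate_capacity: int = 20_000
    control_plate_capacity: int = 2_000_000  # 100x the challenged capacity
    read_depth: int = 1_000_000  # control-arm sequencing depth
    challenged_depth_fraction: float = 0.01  # 1:100 pooling of challenged libraries
    dispersion: float = 10.0  # per-site Dirichlet concentration; inf = multinomial
    abundance_shape: float = 1.0
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self):
        for p in (self.resistance_survival, self.costly_fitness, self.escape_baseline):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {total}")


@dataclass
class MutantLibrary:
    """Latent pooled library: one row per mutant."""

    positions: np.ndarray  # insertion site, 1-based
    gene_ids: np.ndarray  # gene_id or "" for intergenic
    abundances: np.ndarray  # relative cell abundance, >= 0
    contig_id: str = ""

    def __len__(self) -> int:
        return len(self.positions)

    def site_abundances(self) -> dict[int, float]:
        out: dict[int, float] = {}
        for pos, ab in zip(self.positions.tolist(), self.abundances.tolist()):
            out[pos] = out.get(pos, 0.0) + ab
        return out

    def subset(self, mask: np.ndarray) -> "MutantLibrary":
        return MutantLibrary(
            self.positions[mask], self.gene_ids[mask], self.abundances[mask], self.contig_id
        )


def apportion_classes(n_genes: int, class_fractions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of genes to classes.

    Deterministic: quotas floor-rounded, leftover seats go to the largest
    fractional remainders, ties broken by class-name order.
    """
    items = sorted(class_fractions.items())
    quotas = [(name, n_genes * frac) for name, frac in items]
    counts = {name: int(np.floor(q)) for name, q in quotas}
    leftover = n_genes - sum(counts.values())
    remainders = sorted(quotas, key=lambda nq: (-(nq[1] - np.floor(nq[1])), nq[0]))
    for name, _ in remainders[:leftover]:
        counts[name] += 1
    return counts


def generate_genome(
    n_genes: int,
    mean_gene_len: int = 900,
    intergenic_len: int = 100,
    class_fractions: dict[str, float] | None = None,
    seed: int | np.random.SeedSequence = 0,
    *,
    small_gene_len: int = 400,
    resistance_survival: float = 0.9,
    costly_fitness: float = 0.1,
    escape_baseline: float = 1e-3,
    min_gene_len: int = 150,
    contig_id: str = "simchrom",
    with_sequence: bool = False,
) -> tuple[GenomeAnnotation, str | None]:
    """Generate a deterministic annotated genome with planted gene classes.

    Genes are non-overlapping, separated by fixed intergenic gaps, with
    Gamma-distributed lengths.  Two genes are designated "small" (shorter
    than ``small_gene_len``) to exercise the small-gene review path; they
    are resistance-class when at least two resistance genes exist.
    Returns the annotation and, when requested, a random nucleotide
    sequence of the contig.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    fractions = class_fractions or {"neutral": 1.0}
    counts = apportion_classes(n_genes, fractions)
    rng = np.random.default_rng(seed)

    lengths = np.maximum(
        rng.gamma(shape=4.0, scale=mean_gene_len / 4.0, size=n_genes).astype(int),
        min_gene_len,
    )

    classes = np.array(
        [cls for cls, k in sorted(counts.items()) for _ in range(k)], dtype=object
    )
    rng.shuffle(classes)

    # designate two small genes, preferring resistance genes
    if small_gene_len > min_gene_len:
        resistant_idx = np.flatnonzero(classes == "resistance")
        small_idx = resistant_idx[:2] if len(resistant_idx) >= 2 else np.arange(min(2, n_genes))
        lengths[small_idx] = rng.integers(min_gene_len, small_gene_len, size=len(small_idx))

    def attrs_for(cls: str) -> GeneSimAttrs:
        w = {"essential": 0.0, "costly_resistance": costly_fitness, "costly_neutral": costly_fitness}.get(cls, 1.0)
        s = resistance_survival if cls in RESISTANT_CLASSES else escape_baseline
        return GeneSimAttrs(cls, w, s)

    genes = []
    cursor = intergenic_len + 1
    width = len(str(n_genes))
    for i in range(n_genes):
        start = cursor
        end = start + int(lengths[i]) - 1
        genes.append(
            GeneRecord(
                gene_id=f"g{i + 1:0{width}d}",
                start=start,
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
                sim_attrs=attrs_for(classes[i]),
            )
        )
        cursor = end + intergenic_len + 1
    contig_length = cursor  # trailing intergenic gap included
    annotation = GenomeAnnotation(contig_id=contig_id, contig_length=contig_length, genes=genes)

    sequence = None
    if with_sequence:
        sequence = "".join(rng.choice(list("ACGT"), size=contig_length))
    return annotation, sequence


def _allowed_segments(annotation: GenomeAnnotation) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(starts, lengths, gene_ids) of insertable segments: non-essential
    gene bodies and intergenic stretches ("" id)."""
    starts, lengths, ids = [], [], []
    cursor = 1
    for g in annotation:
        if g.start > cursor:  # intergenic stretch before this gene
            starts.append(cursor)
            lengths.append(g.start - cursor)
            ids.append("")
        attrs: GeneSimAttrs | None = g.sim_attrs
        if attrs is None or attrs.gene_class != "essential":
            starts.append(g.start)
            lengths.append(g.length)
            ids.append(g.gene_id)
        cursor = max(cursor, g.end + 1)
    if cursor <= annotation.contig_length:
        starts.append(cursor)
        lengths.append(annotation.contig_length - cursor + 1)
        ids.append("")
    return np.array(starts, dtype=np.int64), np.array(lengths, dtype=np.int64), ids


def build_library(
    annotation: GenomeAnnotation,
    model: SelectionModel,
    seed: int | np.random.SeedSequence | None = None,
) -> MutantLibrary:
    """Draw the latent mutant library.

    Sites are uniform over non-essential gene bodies and intergenic space
    (essential genes are insertion voids); abundances are Gamma draws scaled
    by the gene's relative fitness, so costly genes are depleted during
    library outgrowth.
    """
    for g in annotation:
        if g.sim_attrs is None:
            raise ValueError(f"gene {g.gene_id} lacks simulation attributes")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    starts, seg_lens, seg_ids = _allowed_segments(annotation)
    cum = np.cumsum(seg_lens)
    total = cum[-1]

    offsets = rng.integers(0, total, size=model.library_size)
    seg_idx = np.searchsorted(cum, offsets, side="right")
    positions = starts[seg_idx] + (offsets - (cum[seg_idx] - seg_lens[seg_idx]))

    gene_ids = np.array([seg_ids[i] for i in seg_idx], dtype=object)
    w = np.ones(model.library_size)
    fitness = {g.gene_id: g.sim_attrs.relative_fitness for g in annotation}
    for i, gid in enumerate(gene_ids):
        if gid:
            w[i] = fitness[gid]
    abundances = rng.gamma(shape=model.abundance_shape, scale=1.0, size=model.library_size) * w
    return MutantLibrary(positions, gene_ids, abundances, annotation.contig_id)


def _weighted_subsample(
    library: MutantLibrary, capacity: int, rng: np.random.Generator
) -> MutantLibrary:
    """Plating bottleneck: keep at most ``capacity`` mutants, chosen without
    replacement with probability proportional to abundance (Gumbel top-k)."""
    n = len(library)
    if n <= capacity:
        return library
    with np.errstate(divide="ignore"):
        keys = np.log(library.abundances) + rng.gumbel(size=n)
    keep = np.argsort(keys)[-capacity:]
    mask = np.zeros(n, dtype=bool)
    mask[keep] = True
    return library.subset(mask)


def apply_phage_selection(
    library: MutantLibrary,
    annotation: GenomeAnnotation,
    model: SelectionModel,
    seed: int | np.random.SeedSequence | None = None,
    *,
    challenged: bool = True,
) -> MutantLibrary:
    """Phage challenge and survivor plating.

    Each mutant survives independently with probability s(gene) when its
    gene is a resistance class, otherwise with the escape baseline epsilon
    (lysogeny / phenotypic escape); intergenic mutants are phage-sensitive.
    Survivors are then plated through the challenged-arm bottleneck.  The
    control arm skips killing but passes through its own (100x larger)
    plating bottleneck, mirroring the dilution asymmetry of the protocol.
    """
    if len(library) == 0:
        raise ValueError("library is empty")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    if challenged:
        surv_prob = {
            g.gene_id: (
                g.sim_attrs.survival_prob
                if g.sim_attrs.gene_class in RESISTANT_CLASSES
                else model.escape_baseline
            )
            for g in annotation
        }
        p = np.array(
            [surv_prob.get(gid, model.escape_baseline) for gid in library.gene_ids]
        )
        survives = rng.random(len(library)) < p
        survivors = library.subset(survives)
        if len(survivors) == 0:
            warnings.warn("no mutants survived the phage challenge", stacklevel=2)
            return survivors
        capacity = model.survivor_plate_capacity
    else:
        survivors = library
        capacity = model.control_plate_capacity
    return _weighted_subsample(survivors, capacity, rng)


def sequence_library(
    library: MutantLibrary,
    read_depth: int,
    dispersion: float = np.inf,
    seed: int | np.random.SeedSequence | None = None,
    *,
    sample_id: str = "sample",
    condition: str = "control",
    **meta,
) -> InsertionCountTable:
    """Sequence the library: overdispersed counts over insertion sites.

    Site proportions are perturbed by a Dirichlet draw with per-site
    concentration ``dispersion * q_i * n_sites`` and counts are multinomial
    at ``read_depth``, i.e. Dirichlet-multinomial noise; dispersion=inf
    gives plain multinomial.  The returned table's total_reads equals
    ``read_depth`` exactly.
    """
    if read_depth < 0:
        raise ValueError("read_depth must be >= 0")
    rng = np.random.default_rng(seed)
    site_ab = library.site_abundances()
    sites = np.array(sorted(site_ab), dtype=np.int64)
    counts_dict: dict[int, int] = {}
    if read_depth > 0 and len(sites) > 0:
        ab = np.array([site_ab[p] for p in sites])
        if ab.sum() <= 0:
            q = np.full(len(sites), 1.0 / len(sites))
        else:
            q = ab / ab.sum()
        if np.isfinite(dispersion):
            alpha = dispersion * len(sites) * q
            draw = rng.gamma(np.maximum(alpha, 1e-300))
            p = draw / draw.sum() if draw.sum() > 0 else q
        else:
            p = q
        counts = rng.multinomial(read_depth, p)
        counts_dict = {
            int(pos): int(c) for pos, c in zip(sites, counts) if c > 0
        }
    return InsertionCountTable(
        sample_id=sample_id,
        condition=condition,
        counts=counts_dict,
        contig_id=library.contig_id,
        **meta,
    )


@dataclass
class SimulatedExperiment:
    """Output bundle of :func:`simulate_experiment`."""

    annotation: GenomeAnnotation
    sequence: str | None
    tables: list[InsertionCountTable]  # phage + control per replicate
    sample_sheet: pd.DataFrame
    truth: pd.DataFrame  # gene_id, gene_class, relative_fitness, survival_prob, planted_hit

    @property
    def challenged(self) -> list[InsertionCountTable]:
        return [t for t in self.tables if t.condition == "phage"]

    @property
    def controls(self) -> list[InsertionCountTable]:
        return [t for t in self.tables if t.condition == "control"]


def simulate_experiment(
    model: SelectionModel,
    *,
    phage_label: str = "phi",
    with_sequence: bool = False,
    out_dir=None,
) -> SimulatedExperiment:
    """Run the full generative model: genome -> library -> two independent
    phage challenges with paired untreated controls -> sequencing.

    One shared library (frozen aliquots) feeds every replicate; selection,
    plating, and sequencing draw independent child seeds per replicate.
    Returns tables, the sample sheet pairing each challenge to its control,
    and a truth table of planted resistance genes for scoring.
    """
    master = np.random.SeedSequence(model.seed)
    # fixed spawn order: genome, library, then 4 children per replicate
    children = master.spawn(2 + 4 * model.n_replicates)
    annotation, sequence = generate_genome(
        model.n_genes,
        model.mean_gene_len,
        model.intergenic_len,
        model.class_fractions,
        children[0],
        small_gene_len=model.small_gene_len,
        resistance_survival=model.resistance_survival,
        costly_fitness=model.costly_fitness,
        escape_baseline=model.escape_baseline,
        with_sequence=with_sequence,
    )
    library = build_library(annotation, model, children[1])

    tables: list[InsertionCountTable] = []
    sheet_rows = []
    challenged_depth = int(round(model.read_depth * model.challenged_depth_fraction))
    for r in range(1, model.n_replicates + 1):
        base = 2 + 4 * (r - 1)
        ctrl_id = f"control_{r}"
        phage_id = f"{phage_label}_{r}"
        survivors = apply_phage_selection(
            library, annotation, model, children[base], challenged=True
        )
        control_pool = apply_phage_selection(
            library, annotation, model, children[base + 1], challenged=False
        )
        tables.append(
            sequence_library(
                survivors,
                challenged_depth,
                model.dispersion,
                children[base + 2],
                sample_id=phage_id,
                condition="phage",
                phage_label=phage_label,
                replicate=r,
                paired_control_id=ctrl_id,
            )
        )
        tables.append(
            sequence_library(
                control_pool,
                model.read_depth,
                model.dispersion,
                children[base + 3],
                sample_id=ctrl_id,
                condition="control",
                replicate=r,
            )
        )
        sheet_rows.append(
            dict(sample_id=phage_id, condition="phage", phage_label=phage_label,
                 replicate=r, paired_control_id=ctrl_id)
        )
        sheet_rows.append(
            dict(sample_id=ctrl_id, condition="control", phage_label="",
                 replicate=r, paired_control_id="")
        )

    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in annotation],
            "gene_class": [g.sim_attrs.gene_class for g in annotation],
            "relative_fitness": [g.sim_attrs.relative_fitness for g in annotation],
            "survival_prob": [g.sim_attrs.survival_prob for g in annotation],
        }
    )
    truth["planted_hit"] = truth["gene_class"].isin(RESISTANT_CLASSES)
    sheet = pd.DataFrame(sheet_rows)

    result = SimulatedExperiment(annotation, sequence, tables, sheet, truth)
    if out_dir is not None:
        _write_experiment(result, out_dir)
    return result


def _write_experiment(exp: SimulatedExperiment, out_dir) -> None:
    from pathlib import Path

    from . import io as tio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tio.write_annotation(exp.annotation, out / "genome.gff3")
    if exp.sequence is not None:
        tio.write_fasta({exp.annotation.contig_id: exp.sequence}, out / "genome.fasta")
    tio.write_counts_tsv(exp.tables, out / "counts.tsv")
    tio.write_sample_sheet(exp.sample_sheet, out / "samples.tsv")
    exp.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
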