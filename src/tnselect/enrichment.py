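"""Per-gene enrichment inference for a phage-challenge Tn-Seq screen.

The analysis mirrors the selection-screen readout: challenged read counts
are normalized to the total of the paired untreated control, each gene gets
a log2 fold change of normalized challenged over control reads plus a
Mann-Whitney U test over per-site counts, and a gene is called a hit when
its fold change exceeds the threshold AND it carries more than the minimum
number of unique insertions in every replicate.  Short genes that fail only
the unique-insertion filter are flagged for manual review rather than
auto-called.  Depleted genes (negative fold change) are reported but never
called: depletion after a killing selection is not interpretable as a
requirement for infection.

The object layer follows the model/results idiom: build a
:class:`TnSeqScreenModel` from paired count tables and an annotation, call
:meth:`~TnSeqScreenModel.fit`, and read estimates off the returned
:class:`TnSeqScreenResults`.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import (
    GenomeAnnotation,
    InsertionCountTable,
    assign_sites_to_genes,
    union_site_values,
)

__all__ = [
    "normalize_counts",
    "gene_log2_fold_change",
    "mann_whitney_gene",
    "MannWhitneyResult",
    "call_hits",
    "replicate_reproducibility",
    "adjust_pvalues",
    "TnSeqScreenModel",
    "TnSeqScreenResults",
]

#: Group sizes at or below which the U test is computed by exact enumeration.
EXACT_ENUMERATION_LIMIT = 8


def normalize_counts(
    challenged: InsertionCountTable, control: InsertionCountTable
) -> InsertionCountTable:
    """Scale challenged counts so their total matches the paired control.

    Every challenged site count is multiplied by
    ``control.total_reads / challenged.total_reads``; control counts are
    untouched.  After scaling the challenged total equals the control total
    up to floating rounding.
    """
    chal_total = challenged.total_reads
    if chal_total == 0:
        raise ZeroDivisionError(
            f"challenged sample {challenged.sample_id!r} has zero total reads; "
            "normalization scale is undefined"
        )
    scale = control.total_reads / chal_total
    return challenged.scaled(scale)


def gene_log2_fold_change(
    challenged_norm_total: float, control_total: float, pseudocount: float = 1.0
) -> float:
    """log2 fold change of normalized challenged over control gene totals.

    A shared pseudocount keeps the ratio finite for zero-count genes (many
    genes have no surviving mutants after a killing selection).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if challenged_norm_total < 0 or control_total < 0:
        raise ValueError("totals must be >= 0")
    return float(
        np.log2((challenged_norm_total + pseudocount) / (control_total + pseudocount))
    )


class MannWhitneyResult(NamedTuple):
    U: float  # statistic for the challenged group
    p: float  # two-sided
    degenerate: bool  # no separable evidence (e.g. all values tied / empty)


def _u_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    """U for group x: wins over y count 1, ties count 1/2."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def _exact_mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided exact p by enumerating every relabeling of the pooled values.

    Handles ties exactly: the null distribution of U is taken over all
    C(n+m, n) assignments of the observed (possibly tied) values to groups.
    """
    pooled = list(x) + list(y)
    n, m = len(x), len(y)
    u_obs = _u_statistic(x, y)
    mu = n * m / 2.0
    dev = abs(u_obs - mu)
    total = 0
    extreme = 0
    idx = range(n + m)
    for chosen in combinations(idx, n):
        chosen_set = set(chosen)
        xs = [pooled[i] for i in chosen]
        ys = [pooled[i] for i in idx if i not in chosen_set]
        total += 1
        if abs(_u_statistic(xs, ys) - mu) >= dev - 1e-12:
            extreme += 1
    return u_obs, extreme / total


def mann_whitney_gene(
    challenged: Sequence[float], control: Sequence[float]
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test of challenged vs control per-site counts.

    The comparison unit is the per-site count vector within one gene over
    the union of sites observed in either sample (absent sites contribute
    zero).  Both group sizes <= 8: exact enumeration over all relabelings
    of the observed values (ties exact).  Larger: tie-corrected normal
    approximation with continuity correction.  All values tied (including
    the all-zero case) carries no evidence: p = 1 and the result is flagged
    degenerate.
    """
    x = np.asarray(challenged, dtype=float)
    y = np.asarray(control, dtype=float)
    if x.size == 0 or y.size == 0:
        return MannWhitneyResult(U=0.0, p=1.0, degenerate=True)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return MannWhitneyResult(U=_u_statistic(x, y), p=1.0, degenerate=True)
    if x.size <= EXACT_ENUMERATION_LIMIT and y.size <= EXACT_ENUMERATION_LIMIT:
        u, p = _exact_mann_whitney(x.tolist(), y.tolist())
        return MannWhitneyResult(U=u, p=p, degenerate=False)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(U=float(res.statistic), p=float(res.pvalue), degenerate=False)


def adjust_pvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (supplementary output;
    hit calling never gates on them)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


def replicate_reproducibility(
    log2fc_a: Sequence[float], log2fc_b: Sequence[float]
) -> float:
    """Pearson correlation of per-gene log2 fold changes between replicates.

    Computed over all genes with finite values in both replicates (not hits
    only)."""
    a = np.asarray(log2fc_a, dtype=float)
    b = np.asarray(log2fc_b, dtype=float)
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    if a.size < 3:
        raise ValueError("need >= 3 genes with finite fold changes in both replicates")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in a replicate; correlation undefined")
    return float(stats.pearsonr(a, b).statistic)


def call_hits(
    records: pd.DataFrame,
    fc_threshold: float = 2.0,
    strong_threshold: float = 5.0,
    min_unique: int = 1,
    *,
    require_all_replicates: bool = True,
    small_gene_len: int = 400,
    replicate_labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Apply the two-replicate hit criteria to a per-gene record table.

    A gene is a ``hit`` when, in EVERY replicate, log2 fold change strictly
    exceeds ``fc_threshold`` AND the challenged unique-insertion count
    strictly exceeds ``min_unique``.  ``strong_hit`` additionally requires
    the fold change above ``strong_threshold`` everywhere.  Genes shorter
    than ``small_gene_len`` that clear the fold-change bar in every
    replicate but fail only the unique-insertion filter get
    ``small_gene_flag`` for manual review; they are never auto-promoted.
    ``depleted`` marks negative mean fold change, reported but never a hit.

    ``records`` needs columns ``log2fc_<r>`` and ``unique_challenged_<r>``
    for each replicate label ``<r>``, plus ``length``.  NaN in a replicate
    column is treated as that replicate missing for the gene.
    """
    labels = replicate_labels or _infer_labels(records)
    if not labels:
        raise ValueError("no replicate columns (log2fc_*) found")
    out = records.copy()
    fc = out[[f"log2fc_{r}" for r in labels]].to_numpy(dtype=float)
    uniq = out[[f"unique_challenged_{r}" for r in labels]].to_numpy(dtype=float)
    missing = np.isnan(fc)
    if require_all_replicates and missing.any():
        bad = out.loc[missing.any(axis=1), "gene_id"].tolist()
        raise ValueError(
            f"replicate values missing for genes {bad[:5]} (set "
            "require_all_replicates=False to evaluate available replicates)"
        )
    with np.errstate(invalid="ignore"):
        fc_pass = np.where(missing, True, fc > fc_threshold).all(axis=1) & ~missing.all(axis=1)
        strong_pass = np.where(missing, True, fc > strong_threshold).all(axis=1)
        uniq_pass = np.where(missing, True, uniq > min_unique).all(axis=1)
    out["hit"] = fc_pass & uniq_pass
    out["strong_hit"] = out["hit"] & strong_pass
    out["small_gene_flag"] = (
        (out["length"].to_numpy() < small_gene_len) & fc_pass & ~uniq_pass
    )
    out["depleted"] = np.nanmean(fc, axis=1) < 0
    return out


def _infer_labels(records: pd.DataFrame) -> list[str]:
    return sorted(
        c.removeprefix("log2fc_")
        for c in records.columns
        if c.startswith("log2fc_") and c != "log2fc_mean"
    )


# ---------------------------------------------------------------------------
# Model / results layer


@dataclass
class TnSeqScreenModel:
    """A phage-selection Tn-Seq screen: paired challenged/control count
    tables over an annotated genome.

    Parameters
    ----------
    pairs
        One ``(challenged, control)`` table pair per replicate, in replicate
        order; replicates are labelled A, B, ... in outputs.
    annotation
        Gene annotation providing the per-gene aggregation frame.
    pseudocount
        Added to both gene totals in the fold change (default 1).
    edge_trim
        Fraction of each gene's length excluded at both termini before site
        assignment (default 0: every position in the annotated span counts).
    """

    pairs: list[tuple[InsertionCountTable, InsertionCountTable]]
    annotation: GenomeAnnotation
    pseudocount: float = 1.0
    edge_trim: float = 0.0

    def __post_init__(self):
        if not self.pairs:
            raise ValueError("need at least one (challenged, control) pair")
        for chal, ctrl in self.pairs:
            if chal.condition != "phage" or ctrl.condition != "control":
                raise ValueError(
                    f"pair ({chal.sample_id}, {ctrl.sample_id}) must be "
                    "(phage, control)"
                )
            if len(ctrl.counts) == 0:
                raise ValueError(f"control table {ctrl.sample_id!r} is empty")

    @classmethod
    def from_tables(
        cls,
        tables: Sequence[InsertionCountTable],
        sample_sheet: pd.DataFrame,
        annotation: GenomeAnnotation,
        *,
        phage_label: str | None = None,
        **kwargs,
    ) -> "TnSeqScreenModel":
        """Pair tables via the sample sheet's paired_control_id column."""
        by_id = {t.sample_id: t for t in tables}
        pairs = []
        phage_rows = sample_sheet[sample_sheet["condition"] == "phage"]
        if phage_label is not None:
            phage_rows = phage_rows[phage_rows["phage_label"] == phage_label]
        for _, row in phage_rows.sort_values("replicate").iterrows():
            chal = by_id[row["sample_id"]]
            ctrl = by_id[row["paired_control_id"]]
            pairs.append((chal, ctrl))
        return cls(pairs=pairs, annotation=annotation, **kwargs)

    @classmethod
    def from_experiment(cls, experiment, **kwargs) -> "TnSeqScreenModel":
        """Build directly from a :class:`~tnselect.simulate.SimulatedExperiment`."""
        return cls.from_tables(
            experiment.tables, experiment.sample_sheet, experiment.annotation, **kwargs
        )

    @property
    def replicate_labels(self) -> list[str]:
        return list(string.ascii_uppercase[: len(self.pairs)])

    def fit(
        self,
        fc_threshold: float = 2.0,
        strong_threshold: float = 5.0,
        min_unique: int = 1,
        *,
        small_gene_len: int = 400,
        require_all_replicates: bool = True,
    ) -> "TnSeqScreenResults":
        """Run the per-gene analysis and call hits.

        Per replicate: normalize challenged counts to the paired control
        total, aggregate both samples per gene, compute log2 fold change
        (with the model's pseudocount) and the per-site Mann-Whitney U
        test.  Then apply the two-replicate hit criteria and compute the
        replicate reproducibility of fold changes.
        """
        labels = self.replicate_labels
        rows: dict[str, dict] = {
            g.gene_id: {"gene_id": g.gene_id, "name": g.name, "start": g.start,
                        "end": g.end, "length": g.length}
            for g in self.annotation
        }
        for label, (chal, ctrl) in zip(labels, self.pairs):
            chal_norm = normalize_counts(chal, ctrl)
            scale = chal_norm.total_reads / chal.total_reads
            prof_chal = assign_sites_to_genes(chal, self.annotation, edge_trim=self.edge_trim)
            prof_ctrl = assign_sites_to_genes(ctrl, self.annotation, edge_trim=self.edge_trim)
            for g in self.annotation:
                pc = prof_chal[g.gene_id]
                pk = prof_ctrl[g.gene_id]
                chal_raw_total = pc.gene_total
                chal_norm_total = chal_raw_total * scale
                ctrl_total = pk.gene_total
                norm_sites = {p: c * scale for p, c in pc.sites}
                vx, vy = union_site_values(norm_sites, pk.site_counts())
                mw = mann_whitney_gene(vx, vy)
                row = rows[g.gene_id]
                row[f"control_total_{label}"] = ctrl_total
                row[f"challenged_total_{label}"] = chal_raw_total
                row[f"challenged_norm_{label}"] = chal_norm_total
                row[f"unique_challenged_{label}"] = pc.unique_insertions
                row[f"unique_control_{label}"] = pk.unique_insertions
                row[f"log2fc_{label}"] = gene_log2_fold_change(
                    chal_norm_total, ctrl_total, self.pseudocount
                )
                row[f"U_{label}"] = mw.U
                row[f"p_{label}"] = mw.p
                row[f"degenerate_{label}"] = mw.degenerate

        table = pd.DataFrame([rows[g.gene_id] for g in self.annotation])
        fc_cols = [f"log2fc_{r}" for r in labels]
        table["log2fc_mean"] = table[fc_cols].mean(axis=1)
        # conservative per-gene combined p: worst replicate, then BH across genes
        table["p_max"] = table[[f"p_{r}" for r in labels]].max(axis=1)
        table["q"] = adjust_pvalues(table["p_max"].to_numpy())

        table = call_hits(
            table,
            fc_threshold=fc_threshold,
            strong_threshold=strong_threshold,
            min_unique=min_unique,
            require_all_replicates=require_all_replicates,
            small_gene_len=small_gene_len,
            replicate_labels=labels,
        )
        corr = count_corr = np.nan
        if len(labels) >= 2 and len(table) >= 3:
            try:
                corr = replicate_reproducibility(
                    table[f"log2fc_{labels[0]}"], table[f"log2fc_{labels[1]}"]
                )
            except ValueError:
                corr = np.nan
            # reproducibility of the insertion read profiles themselves
            a = table[f"challenged_norm_{labels[0]}"].to_numpy(dtype=float)
            b = table[f"challenged_norm_{labels[1]}"].to_numpy(dtype=float)
            if np.std(a) > 0 and np.std(b) > 0:
                count_corr = float(stats.pearsonr(a, b).statistic)
        params = dict(
            fc_threshold=fc_threshold,
            strong_threshold=strong_threshold,
            min_unique=min_unique,
            pseudocount=self.pseudocount,
            small_gene_len=small_gene_len,
            edge_trim=self.edge_trim,
            replicates=len(labels),
        )
        return TnSeqScreenResults(
            model=self,
            gene_table=table,
            replicate_correlation=corr,
            count_correlation=count_corr,
            params=params,
        )


@dataclass
class TnSeqScreenResults:
    """Fitted screen results: per-gene estimates and hit calls.

    ``replicate_correlation`` is the Pearson r of per-gene log2 fold changes
    between the first two replicates; ``count_correlation`` is the Pearson r
    of the normalized challenged gene read totals themselves (the
    reproducibility of the insertion profiles).
    """

    model: TnSeqScreenModel
    gene_table: pd.DataFrame
    replicate_correlation: float
    count_correlation: float = float("nan")
    params: dict = field(default_factory=dict)

    @property
    def hits(self) -> pd.DataFrame:
        return self.gene_table[self.gene_table["hit"]].reset_index(drop=True)

    @property
    def strong_hits(self) -> pd.DataFrame:
        return self.gene_table[self.gene_table["strong_hit"]].reset_index(drop=True)

    @property
    def review_flags(self) -> pd.DataFrame:
        """Short genes failing only the unique-insertion filter: review, not hits."""
        return self.gene_table[self.gene_table["small_gene_flag"]].reset_index(drop=True)

    def summary(self) -> str:
        t = self.gene_table
        lines = [
            "Tn-Seq phage-selection screen".center(60),
            "=" * 60,
            f"genes analysed:            {len(t)}",
            f"replicates:                {self.params.get('replicates')}",
            f"fc threshold (log2):       > {self.params.get('fc_threshold')}",
            f"strong threshold (log2):   > {self.params.get('strong_threshold')}",
            f"min unique insertions:     > {self.params.get('min_unique')}",
            f"pseudocount:               {self.params.get('pseudocount')}",
            f"hits:                      {int(t['hit'].sum())}",
            f"strong hits:               {int(t['strong_hit'].sum())}",
            f"small-gene review flags:   {int(t['small_gene_flag'].sum())}",
            f"depleted genes (not hits): {int(t['depleted'].sum())}",
            f"replicate log2fc Pearson r: {self.replicate_correlation:.3f}",
            f"replicate profile Pearson r: {self.count_correlation:.3f}",
            "=" * 60,
        ]
        if t["hit"].any():
            cols = ["gene_id", "log2fc_mean", "q", "hit", "strong_hit"]
            top = t[t["hit"]].nlargest(10, "log2fc_mean")[cols]
            lines.append("top hits by mean log2 fold change:")
            lines.append(top.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
        return "\n".join(lines)

    def to_tsv(self, out_dir) -> None:
        """Write per-gene, hits, and review tables plus run metadata."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.gene_table.to_csv(out / "per_gene.tsv", sep="\t", index=False)
        self.hits.to_csv(out / "hits.tsv", sep="\t", index=False)
        self.review_flags.to_csv(out / "review_flags.tsv", sep="\t", index=False)
        with open(out / "run_metadata.txt", "w") as fh:
            for k, v in self.params.items():
                fh.write(f"{k}\t{v}\n")
            fh.write(f"replicate_log2fc_pearson_r\t{self.replicate_correlation}\n")
            fh.write(f"replicate_profile_pearson_r\t{self.count_correlation}\n")
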