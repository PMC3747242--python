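"""Expression fold-change screening and three-way integration.

Differential expression between the two conditions uses a two-sample
Student t-test on log2 intensities (equal-variance by default, the
era-standard for microarray data; a Welch option is exposed) together
with a linear-scale fold-change cutoff: a gene passes when
fold_change > fc_cutoff AND p < p_cutoff, fold change being the ratio of
the larger condition mean to the smaller. The final integrated call
requires concordant direction across the binding-site score, the Pol2
score and the expression screen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import DimorphismCall


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    mean_m: float
    mean_f: float
    fold_change: float  # >= 1, larger mean over smaller
    direction: str  # "M" | "F"
    t_statistic: float
    p_value: float
    passes: bool


@dataclass(frozen=True)
class IntegratedCall:
    gene_id: str
    rxr_pass: bool
    pol2_pass: bool
    rna_pass: bool
    final: str  # "male" | "female" | "none"


def _condition_columns(columns: Sequence[str], cond: str) -> list[str]:
    return [c for c in columns if c.split("_")[0] == cond]


def collapse_probes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate gene ids to the probe with maximal mean intensity."""
    if matrix.index.is_unique:
        return matrix
    means = matrix.mean(axis=1).to_numpy()
    order = np.argsort(-means, kind="stable")
    seen: set = set()
    rows = []
    for i in order:
        gid = matrix.index[i]
        if gid not in seen:
            seen.add(gid)
            rows.append(i)
    return matrix.iloc[sorted(rows)]


def differential_expression(
    matrix: pd.DataFrame,
    cond_m: str = "M",
    cond_f: str = "F",
    fc_cutoff: float = 1.5,
    p_cutoff: float = 0.1,
    equal_var: bool = True,
    log_input: bool = False,
) -> list[ExpressionRecord]:
    """Screen a genes x samples intensity matrix for differential genes.

    Columns are named ``<condition>_<replicate>`` (e.g. M_1, M_2, F_1,
    F_2). Values are linear-scale intensities unless ``log_input`` is
    set, in which case they are taken as log2 already. The t-test runs
    on log2 values; the fold change on linear means. A gene with zero
    variance in both groups and equal means gets p = 1; zero variance
    with unequal means gets p = 0.
    """
    cols_m = _condition_columns(matrix.columns, cond_m)
    cols_f = _condition_columns(matrix.columns, cond_f)
    if len(cols_m) < 2 or len(cols_f) < 2:
        raise ValueError("need >= 2 replicates per condition")
    matrix = collapse_probes(matrix)
    if log_input:
        log_m = matrix[cols_m].to_numpy(float)
        log_f = matrix[cols_f].to_numpy(float)
        lin_m = np.exp2(log_m)
        lin_f = np.exp2(log_f)
    else:
        lin_m = matrix[cols_m].to_numpy(float)
        lin_f = matrix[cols_f].to_numpy(float)
        if np.any(lin_m <= 0) or np.any(lin_f <= 0):
            raise ValueError("expression intensities must be positive")
        log_m = np.log2(lin_m)
        log_f = np.log2(lin_f)

    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(log_m, log_f, axis=1, equal_var=equal_var)
    mean_m = lin_m.mean(axis=1)
    mean_f = lin_f.mean(axis=1)
    # degenerate rows: no variance anywhere
    novar = (log_m.std(axis=1) == 0) & (log_f.std(axis=1) == 0)
    eq = np.isclose(mean_m, mean_f)
    t = np.where(novar & eq, 0.0, t)
    p = np.where(novar & eq, 1.0, p)
    p = np.where(novar & ~eq, 0.0, p)
    t = np.where(np.isnan(t), 0.0, t)
    p = np.where(np.isnan(p), 1.0, p)

    records = []
    for gid, mm, mf, ti, pi in zip(matrix.index, mean_m, mean_f, t, p):
        hi, lo = (mm, mf) if mm >= mf else (mf, mm)
        fc = hi / lo
        records.append(
            ExpressionRecord(
                gene_id=str(gid),
                mean_m=float(mm),
                mean_f=float(mf),
                fold_change=float(fc),
                direction="M" if mm >= mf else "F",
                t_statistic=float(ti),
                p_value=float(pi),
                passes=bool(fc > fc_cutoff and pi < p_cutoff),
            )
        )
    return records


def read_expression(path) -> pd.DataFrame:
    """Read a TSV expression matrix: first column gene_id, remaining
    columns <condition>_<replicate>."""
    return pd.read_csv(path, sep="\t", index_col=0)


def integrate_three_way(
    dimorphism_calls: Sequence[DimorphismCall],
    expression_records: Sequence[ExpressionRecord],
) -> list[IntegratedCall]:
    """Final calls requiring all three lines of evidence in the same
    direction: a strong same-direction binding-site score, a strong
    same-direction Pol2 score (both folded into the dominance call), and
    a passing expression screen with matching direction."""
    rna: Mapping[str, ExpressionRecord] = {r.gene_id: r for r in expression_records}
    out = []
    for call in dimorphism_calls:
        rec = rna.get(call.gene_id)
        rxr_pass = call.call != "none"
        pol2_pass = call.call != "none"
        rna_pass = rec.passes if rec is not None else False
        final = "none"
        if rec is not None and rec.passes and call.call != "none":
            if call.call == "male_dominant" and rec.direction == "M":
                final = "male"
            elif call.call == "female_dominant" and rec.direction == "F":
                final = "female"
        out.append(
            IntegratedCall(call.gene_id, rxr_pass, pol2_pass, rna_pass, final)
        )
    return out


def score_expression_correlation(
    gene_scores: Mapping[str, float],
    expression_records: Sequence[ExpressionRecord],
) -> tuple[pd.DataFrame, float, float]:
    """Pair per-gene dimorphism scores with signed expression log2 fold
    changes (positive = condition M higher) and report Pearson and
    Spearman correlations over the shared genes.

    ``gene_scores`` maps gene_id to a signed score — either the Pol2
    score or the best-magnitude binding-site score (see
    :func:`best_peak_score_per_gene`). With fewer than 3 shared genes the
    correlations are returned as NaN.
    """
    rows = []
    for rec in expression_records:
        if rec.gene_id in gene_scores:
            signed_lfc = float(np.log2(rec.mean_m / rec.mean_f))
            rows.append((rec.gene_id, gene_scores[rec.gene_id], signed_lfc))
    table = pd.DataFrame(rows, columns=["gene_id", "score", "log2_fold_change"])
    if len(table) < 3:
        return table, float("nan"), float("nan")
    pearson = float(stats.pearsonr(table["score"], table["log2_fold_change"])[0])
    spearman = float(stats.spearmanr(table["score"], table["log2_fold_change"])[0])
    return table, pearson, spearman


def best_peak_score_per_gene(
    scored_peaks, peak_to_gene: Mapping[str, set[str]]
) -> dict[str, float]:
    """Reduce peak scores to one signed score per gene: the score of
    largest magnitude among the gene's assigned peaks."""
    best: dict[str, float] = {}
    for sp in scored_peaks:
        for gid in peak_to_gene.get(sp.name, ()):
            if gid not in best or abs(sp.score) > abs(best[gid]):
                best[gid] = sp.score
    return best
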