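"""Factorial-expression validation of cis-regulation.

A 2x2 genotype x treatment ANOVA with within-genotype post-hoc t tests
(and a plain two-group t for one-factor designs), plus a negative-control
gene check: a cis-regulatory effect is called "specific" when the target
gene responds to the treatment and the control gene does not.

Post-hoc orientation: t is computed on (treated - untreated), so
attenuation under treatment gives a negative t.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core import DataError, FactorialExpressionSet, FormatError
from .stats import TestResult, anova_2x2, two_sample_t

__all__ = [
    "factorial_analysis",
    "two_group_analysis",
    "control_gene_check",
    "ValidationEntry",
    "read_series_matrix",
]


@dataclass
class ValidationEntry:
    gene: str
    anova: dict[str, TestResult] | None = None
    posthoc: dict[str, TestResult] = field(default_factory=dict)
    two_group: TestResult | None = None
    notes: list[str] = field(default_factory=list)


def _design_levels(es: FactorialExpressionSet, column: str) -> list:
    levels = list(pd.unique(es.factors.loc[list(es.values.columns), column]))
    return levels


def factorial_analysis(es: FactorialExpressionSet, gene: str,
                       treated_level=None) -> ValidationEntry:
    """2x2 genotype x treatment ANOVA plus within-genotype post-hoc t tests.

    ``treated_level`` names the treatment level taken as "treated" in the
    (treated - untreated) post-hoc orientation; defaults to the second
    level encountered in the factor table.
    """
    if "treatment" not in es.factors.columns:
        raise DataError("factorial_analysis requires a 'treatment' factor")
    y = es.gene_values(gene)
    samples = list(es.values.columns)
    geno = es.factors.loc[samples, "genotype"].to_numpy()
    treat = es.factors.loc[samples, "treatment"].to_numpy()
    res = anova_2x2(y.to_numpy(), geno, treat)
    entry = ValidationEntry(gene=gene, anova={
        "genotype": res["factor_a"],
        "treatment": res["factor_b"],
        "interaction": res["interaction"],
    })
    t_levels = list(pd.unique(treat))
    treated = treated_level if treated_level is not None else t_levels[1]
    untreated = next(l for l in t_levels if l != treated)
    for g in pd.unique(geno):
        a = y.to_numpy()[(geno == g) & (treat == treated)]
        b = y.to_numpy()[(geno == g) & (treat == untreated)]
        entry.posthoc[str(g)] = two_sample_t(a, b)
    return entry


def two_group_analysis(es: FactorialExpressionSet, gene: str) -> ValidationEntry:
    """Pooled-variance t test between the two genotype groups."""
    y = es.gene_values(gene)
    samples = list(es.values.columns)
    geno = es.factors.loc[samples, "genotype"].to_numpy()
    levels = list(pd.unique(geno))
    if len(levels) != 2:
        raise DataError("two_group_analysis requires exactly two groups")
    a = y.to_numpy()[geno == levels[0]]
    b = y.to_numpy()[geno == levels[1]]
    entry = ValidationEntry(gene=gene, two_group=two_sample_t(a, b))
    entry.notes.append(f"orientation: {levels[0]} vs {levels[1]}")
    return entry


def control_gene_check(es: FactorialExpressionSet, target_gene: str,
                       control_gene: str, alpha: float = 0.05
                       ) -> tuple[ValidationEntry, ValidationEntry, bool]:
    """Run the factorial analysis on target and negative-control genes.

    Returns (target entry, control entry, specific); ``specific`` is True
    when the target's treatment main effect is significant at ``alpha``
    and the control's is not.
    """
    if control_gene not in es.values.index:
        raise DataError(f"control gene {control_gene!r} not in matrix")
    target = factorial_analysis(es, target_gene)
    control = factorial_analysis(es, control_gene)
    t_p = target.anova["treatment"].p_value
    c_p = control.anova["treatment"].p_value
    specific = (t_p is not None and t_p < alpha
                and (c_p is None or c_p >= alpha))
    return target, control, specific


def read_series_matrix(path, probe_map: dict[str, str] | None = None
                       ) -> pd.DataFrame:
    """Parse a GEO series-matrix text file into a probes x samples table.

    Only the expression block between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` is read. ``probe_map`` (probe id -> gene
    symbol) optionally collapses probes to genes, keeping the
    highest-mean-expression probe per symbol. The file must already be on
    disk; this reader never downloads.
    """
    rows = []
    header = None
    in_table = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                break
            if not in_table:
                continue
            parts = [p.strip('"') for p in line.split("\t")]
            if header is None:
                header = parts
                continue
            rows.append(parts)
    if header is None:
        raise FormatError(f"{path}: no series-matrix table found")
    df = pd.DataFrame(rows, columns=header).set_index(header[0])
    df = df.apply(pd.to_numeric, errors="coerce")
    if probe_map:
        df = df.loc[[p for p in df.index if p in probe_map]]
        gene = pd.Series([probe_map[p] for p in df.index], index=df.index)
        best = df.mean(axis=1).groupby(gene).idxmax()
        df = df.loc[best.values]
        df.index = best.index
    return df
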