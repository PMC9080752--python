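"""Length-normalised proportional opsin expression from read counts.

Per-gene read counts are normalised to coding-sequence length,
R_norm = R / L, so genes of different length are comparable.  The rod
proportion is the normalised rod-opsin count over the total normalised
opsin expression; within single cones and double cones, per-gene
proportions are fractions of the class's normalised total.  Genes with
zero counts are retained with proportion 0 — rare opsins expressed at
trace levels must not silently disappear from profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

GENE_CLASSES = ("rod", "single_cone", "double_cone")

COLUMNS = ("individual_id", "gene_id", "gene_class", "reads", "cds_length_bp")


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    if (df["cds_length_bp"] <= 0).any():
        raise ValueError("cds_length_bp must be positive")
    if (df["reads"] < 0).any():
        raise ValueError("reads must be nonnegative")
    bad = set(df["gene_class"]) - set(GENE_CLASSES)
    if bad:
        raise ValueError(f"unknown gene classes: {sorted(bad)}")
    return df


def normalise(df: pd.DataFrame) -> pd.Series:
    """Length-normalised counts R/L, indexed like the input rows."""
    _validate(df)
    return df["reads"] / df["cds_length_bp"]


def rod_proportion(df: pd.DataFrame) -> float:
    """Rod-opsin share of total normalised opsin expression (one individual)."""
    _validate(df)
    if (df["gene_class"] == "rod").sum() != 1:
        raise ValueError("expected exactly one rod gene per individual")
    norm = normalise(df)
    total = norm.sum()
    if total == 0:
        raise ValueError("total normalised opsin expression is zero")
    return float(norm[df["gene_class"] == "rod"].iloc[0] / total)


def class_proportions(df: pd.DataFrame, gene_class: str) -> dict[str, float]:
    """Per-gene fractions of a cone class's normalised expression total."""
    _validate(df)
    sub = df[df["gene_class"] == gene_class]
    if sub.empty:
        raise ValueError(f"no genes of class {gene_class!r}")
    norm = normalise(sub)
    total = norm.sum()
    if total == 0:
        raise ValueError(f"zero normalised expression for class {gene_class!r}")
    return {g: float(v / total) for g, v in zip(sub["gene_id"], norm)}


@dataclass
class ExpressionProfile:
    """One individual's proportional opsin expression."""

    individual_id: str
    p_rod: float
    single_cone: dict[str, float]
    double_cone: dict[str, float]

    def as_series(self) -> pd.Series:
        data = {"RH1(rod)": self.p_rod}
        data.update({g: p for g, p in self.single_cone.items()})
        data.update({g: p for g, p in self.double_cone.items()})
        return pd.Series(data, name=self.individual_id)


def profile(df: pd.DataFrame) -> ExpressionProfile:
    """Compute the full expression profile for one individual's rows."""
    _validate(df)
    ids = df["individual_id"].unique()
    if len(ids) != 1:
        raise ValueError("profile() expects rows for exactly one individual")
    return ExpressionProfile(
        individual_id=str(ids[0]),
        p_rod=rod_proportion(df),
        single_cone=class_proportions(df, "single_cone"),
        double_cone=class_proportions(df, "double_cone"),
    )


def profiles_from_table(df: pd.DataFrame) -> list[ExpressionProfile]:
    _validate(df)
    return [profile(g) for _, g in df.groupby("individual_id", sort=True)]


def group_summary(
    profiles: Sequence[ExpressionProfile],
    grouping: Mapping[str, str],
) -> pd.DataFrame:
    """Per-gene mean ± s.e.m. of proportions (in %) per group label.

    s.e.m. = sd / sqrt(n) with the sample (n−1) standard deviation.  A
    group of one individual has undefined s.e.m.; it is reported as 0
    with ``sem_undefined`` set.
    """
    rows = []
    labelled: dict[str, list[ExpressionProfile]] = {}
    for p in profiles:
        try:
            labelled.setdefault(grouping[p.individual_id], []).append(p)
        except KeyError:
            raise ValueError(f"no group label for individual {p.individual_id!r}")
    for label, group in sorted(labelled.items()):
        table = pd.DataFrame([p.as_series() for p in group]) * 100.0
        n = len(group)
        for gene in table.columns:
            vals = table[gene].to_numpy(dtype=float)
            sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            rows.append({
                "group": label,
                "gene": gene,
                "n": n,
                "mean_pct": float(np.mean(vals)),
                "sem_pct": sem,
                "sem_undefined": n == 1,
            })
    return pd.DataFrame(rows)


def read_counts_tsv(path) -> pd.DataFrame:
    """Read a counts table (individual, gene, class, reads, cds length)."""
    df = pd.read_csv(path, sep="\t")
    return _validate(df)
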