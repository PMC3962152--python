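"""Two-group differential expression and cross-dataset meta-classification.

Each dataset is a genes x samples matrix of log-scale, median-centered
expression values with a normal/disease group label per sample. Per gene we
compute the two-sample Student's t statistic (pooled variance by default,
Welch behind a flag), a two-sided p-value, and the signed fold change
(difference of group means on the log scale; negative means underexpressed
in disease). Genes are then split by fold-change sign into an
underexpressed and an overexpressed class and ranked within each class by
ascending p-value; the rank is reported as a "top X%" percentile, the
convention of cancer-microarray compendia.

The meta-filter combines two such datasets: a gene must be present in both,
its fold-change signs must agree (otherwise "discordant"), and its
cumulative rank percentile — by default the mean of the two per-dataset
percentiles — must reach the top ``threshold_pct`` percent of its direction
class.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ExpressionDataset",
    "read_expression",
    "differential_stats",
    "rank_percentiles",
    "meta_combine",
    "classify_hub_expression",
    "HubExpressionReport",
    "DifferentialExpression",
    "DifferentialResults",
    "ExpressionMeta",
    "MetaResults",
]

GROUPS = ("normal", "disease")


@dataclass(frozen=True)
class ExpressionDataset:
    """Log-scale expression matrix with a two-group sample annotation."""

    matrix: pd.DataFrame  # genes x samples
    groups: pd.Series  # sample -> "normal" | "disease"
    name: str = "dataset"

    def __post_init__(self) -> None:
        if self.matrix.index.duplicated().any():
            dupes = self.matrix.index[self.matrix.index.duplicated()][:5].tolist()
            raise ValueError(f"duplicate gene symbols: {dupes}")
        missing = set(self.matrix.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)[:5]}")
        bad = set(self.groups.unique()) - set(GROUPS)
        if bad:
            raise ValueError(f"group labels must be in {GROUPS}, got {sorted(bad)}")
        for g in GROUPS:
            if (self.groups.loc[list(self.matrix.columns)] == g).sum() < 2:
                raise ValueError(f"need >=2 samples in group {g!r}")

    def samples_in(self, group: str) -> list[str]:
        labels = self.groups.loc[list(self.matrix.columns)]
        return [s for s in self.matrix.columns if labels[s] == group]


def read_expression(
    matrix_path: str | Path, groups_path: str | Path, name: str | None = None
) -> ExpressionDataset:
    """Read a TSV expression matrix (first column = gene) and a sample→label TSV."""
    matrix_path = Path(matrix_path)
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    groups_df = pd.read_csv(groups_path, sep="\t", header=None, names=["sample", "label"])
    groups = pd.Series(groups_df["label"].values, index=groups_df["sample"].astype(str))
    mat.columns = mat.columns.astype(str)
    return ExpressionDataset(matrix=mat, groups=groups, name=name or matrix_path.stem)


def differential_stats(ds: ExpressionDataset, *, welch: bool = False) -> pd.DataFrame:
    """Per-gene two-sample t statistics for disease vs normal.

    Returns a DataFrame indexed by gene with columns ``t_statistic``,
    ``p_value``, ``fold_change`` (disease − normal log-mean), ``direction``
    ("under"/"over"/"none"), and ``degenerate`` flagging zero-variance genes
    whose p-value is pinned at the smallest positive float.
    """
    normal = ds.matrix[ds.samples_in("normal")].to_numpy(dtype=float)
    disease = ds.matrix[ds.samples_in("disease")].to_numpy(dtype=float)
    n1, n2 = normal.shape[1], disease.shape[1]
    m1, m2 = normal.mean(axis=1), disease.mean(axis=1)
    v1 = normal.var(axis=1, ddof=1)
    v2 = disease.var(axis=1, ddof=1)
    fc = m2 - m1

    with np.errstate(divide="ignore", invalid="ignore"):
        if welch:
            se2 = v1 / n1 + v2 / n2
            t = fc / np.sqrt(se2)
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        else:
            pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            t = fc / np.sqrt(pooled * (1 / n1 + 1 / n2))
            df = np.full_like(t, float(n1 + n2 - 2))
        p = 2.0 * sps.t.sf(np.abs(t), df)

    zero_var = (v1 + v2) == 0
    degenerate = zero_var & (fc != 0)
    # equal values throughout: no evidence of difference
    t[zero_var & (fc == 0)] = 0.0
    p[zero_var & (fc == 0)] = 1.0
    # separated but noiseless: maximally significant, flagged
    t[degenerate] = np.sign(fc[degenerate]) * np.inf
    p[degenerate] = np.nextafter(0.0, 1.0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) with zero within-group variance but "
            "unequal means; p-value pinned at the smallest positive float"
        )

    direction = np.where(fc < 0, "under", np.where(fc > 0, "over", "none"))
    out = pd.DataFrame(
        {
            "t_statistic": t,
            "p_value": p,
            "fold_change": fc,
            "direction": direction,
            "degenerate": degenerate,
        },
        index=ds.matrix.index.copy(),
    )
    out.index.name = "gene"
    return rank_percentiles(out)


def rank_percentiles(stats: pd.DataFrame) -> pd.DataFrame:
    """Fill ``rank`` and ``rank_percentile`` within each direction class.

    Within the under- and over-expressed classes separately, genes are ranked
    by ascending p-value (ties broken by symbol) and the rank is converted to
    a percentile ceil(100·rank/n_class) in (0, 100]. Genes with zero fold
    change belong to neither class and get no rank.
    """
    out = stats.copy()
    out["rank"] = pd.array([pd.NA] * len(out), dtype="Int64")
    out["rank_percentile"] = np.nan
    for cls in ("under", "over"):
        members = out.index[out["direction"] == cls]
        if len(members) == 0:
            continue
        ordered = sorted(members, key=lambda g: (out.at[g, "p_value"], g))
        n_class = len(ordered)
        for r, gene in enumerate(ordered, start=1):
            out.at[gene, "rank"] = r
            out.at[gene, "rank_percentile"] = math.ceil(100 * r / n_class)
    return out


def meta_combine(
    a: pd.DataFrame,
    b: pd.DataFrame,
    threshold_pct: float = 36.0,
    *,
    rule: str = "mean",
    names: tuple[str, str] = ("a", "b"),
) -> pd.DataFrame:
    """Cross-dataset meta-classification of per-gene differential statistics.

    ``a`` and ``b`` are per-dataset stat frames (indexed by gene, with
    ``fold_change`` and ``rank_percentile`` columns; ranked rows only are
    usable). Per gene over the union of both indices:

    - ``absent``      — missing (or unranked) in either dataset;
    - ``discordant``  — fold-change signs disagree;
    - ``under``/``over`` — shared sign; ``cumulative_percentile`` combines the
      two per-dataset percentiles by ``rule`` (mean, the default; sum; max)
      and ``passes_filter`` requires it ≤ ``threshold_pct``.

    Output is sorted by cumulative percentile (absent genes last).
    """
    if rule not in ("mean", "sum", "max"):
        raise ValueError(f"unknown cumulative rule {rule!r}")
    if a.empty or b.empty:
        raise ValueError("both stat frames must be non-empty")
    genes = sorted(set(a.index) | set(b.index))
    rows = []
    for g in genes:
        in_a = g in a.index and np.isfinite(a.at[g, "rank_percentile"])
        in_b = g in b.index and np.isfinite(b.at[g, "rank_percentile"])
        row: dict = {"gene": g, "present_a": in_a, "present_b": in_b}
        for label, frame, ok in ((names[0], a, in_a), (names[1], b, in_b)):
            row[f"fold_change_{label}"] = frame.at[g, "fold_change"] if ok else np.nan
            row[f"rank_percentile_{label}"] = (
                frame.at[g, "rank_percentile"] if ok else np.nan
            )
            if ok and "p_value" in frame.columns:
                row[f"p_value_{label}"] = frame.at[g, "p_value"]
        if not (in_a and in_b):
            row.update(direction="absent", cumulative_percentile=np.nan, passes_filter=False)
        else:
            fa = row[f"fold_change_{names[0]}"]
            fb = row[f"fold_change_{names[1]}"]
            pa = row[f"rank_percentile_{names[0]}"]
            pb = row[f"rank_percentile_{names[1]}"]
            cum = {"mean": (pa + pb) / 2, "sum": pa + pb, "max": max(pa, pb)}[rule]
            if np.sign(fa) != np.sign(fb) or fa == 0 or fb == 0:
                row.update(direction="discordant", cumulative_percentile=cum, passes_filter=False)
            else:
                row.update(
                    direction="under" if fa < 0 else "over",
                    cumulative_percentile=cum,
                    passes_filter=bool(cum <= threshold_pct),
                )
        rows.append(row)
    df = pd.DataFrame(rows).set_index("gene")
    return df.sort_values(
        ["cumulative_percentile", "gene"], na_position="last", kind="mergesort"
    )


@dataclass(frozen=True)
class HubExpressionReport:
    """Hub genes partitioned by meta-expression direction."""

    under: pd.DataFrame
    over: pd.DataFrame
    discordant: pd.DataFrame
    absent: pd.DataFrame

    @property
    def n_under(self) -> int:
        return len(self.under)

    @property
    def n_over(self) -> int:
        return len(self.over)

    def summary(self) -> str:
        lines = [
            "Hub expression report",
            "=====================",
            f"underexpressed  {self.n_under}: " + ", ".join(self.under.index),
            f"overexpressed   {self.n_over}: " + ", ".join(self.over.index),
            f"discordant      {len(self.discordant)}: " + ", ".join(self.discordant.index),
            f"absent          {len(self.absent)}: " + ", ".join(self.absent.index),
        ]
        return "\n".join(lines)


def classify_hub_expression(
    hubs: Iterable[str], records: pd.DataFrame
) -> HubExpressionReport:
    """Restrict meta records to hub genes and partition by direction."""
    hubs = set(hubs)
    sub = records.loc[[g for g in records.index if g in hubs]]
    return HubExpressionReport(
        under=sub[sub["direction"] == "under"],
        over=sub[sub["direction"] == "over"],
        discordant=sub[sub["direction"] == "discordant"],
        absent=sub[sub["direction"] == "absent"],
    )


class DifferentialExpression:
    """Two-group differential-expression model for one dataset."""

    def __init__(self, dataset: ExpressionDataset, *, welch: bool = False):
        self.dataset = dataset
        self.welch = welch

    def fit(self) -> "DifferentialResults":
        return DifferentialResults(self, differential_stats(self.dataset, welch=self.welch))


class DifferentialResults:
    def __init__(self, model: DifferentialExpression, stats: pd.DataFrame):
        self.model = model
        self.stats = stats

    def summary(self) -> str:
        s = self.stats
        lines = [
            f"Differential expression: {self.model.dataset.name}",
            "=" * (25 + len(self.model.dataset.name)),
            f"genes            {len(s)}",
            f"underexpressed   {(s['direction'] == 'under').sum()}",
            f"overexpressed    {(s['direction'] == 'over').sum()}",
            f"p < 0.05         {(s['p_value'] < 0.05).sum()}",
        ]
        return "\n".join(lines)


class ExpressionMeta:
    """Two-dataset meta-filter over per-gene differential statistics.

    Construct either from two already-computed stat frames or, via
    :meth:`from_datasets`, from two raw :class:`ExpressionDataset` objects.
    """

    def __init__(
        self,
        stats_a: pd.DataFrame,
        stats_b: pd.DataFrame,
        *,
        threshold_pct: float = 36.0,
        rule: str = "mean",
        names: tuple[str, str] = ("a", "b"),
    ):
        self.stats_a = stats_a
        self.stats_b = stats_b
        self.threshold_pct = threshold_pct
        self.rule = rule
        self.names = names

    @classmethod
    def from_datasets(
        cls,
        a: ExpressionDataset,
        b: ExpressionDataset,
        *,
        threshold_pct: float = 36.0,
        rule: str = "mean",
        welch: bool = False,
    ) -> "ExpressionMeta":
        return cls(
            differential_stats(a, welch=welch),
            differential_stats(b, welch=welch),
            threshold_pct=threshold_pct,
            rule=rule,
            names=(a.name, b.name),
        )

    def fit(self) -> "MetaResults":
        records = meta_combine(
            self.stats_a,
            self.stats_b,
            self.threshold_pct,
            rule=self.rule,
            names=self.names,
        )
        return MetaResults(self, records)


class MetaResults:
    """Combined records; ``classify_hubs`` produces the final hub report."""

    def __init__(self, model: ExpressionMeta, records: pd.DataFrame):
        self.model = model
        self.records = records

    def classify_hubs(self, hubs: Iterable[str]) -> HubExpressionReport:
        return classify_hub_expression(hubs, self.records)

    def summary(self) -> str:
        r = self.records
        counts = r["direction"].value_counts()
        lines = [
            "Expression meta-analysis",
            "========================",
            f"datasets          {self.model.names[0]}, {self.model.names[1]}",
            f"genes (union)     {len(r)}",
            f"underexpressed    {counts.get('under', 0)}",
            f"overexpressed     {counts.get('over', 0)}",
            f"discordant        {counts.get('discordant', 0)}",
            f"absent in one     {counts.get('absent', 0)}",
            f"pass top-{self.model.threshold_pct:g}% filter  {int(r['passes_filter'].sum())}",
        ]
        return "\n".join(lines)
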