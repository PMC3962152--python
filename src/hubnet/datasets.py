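"""Bundled reference tables for the T-ALL hub-gene analysis.

Two small fixtures ship with the package: the 42-symbol common-hub list
(proteins in the top 50 by both degree and betweenness of a high-confidence
NOTCH1 interactome) and the 27-gene summary of their differential expression
in two independent T-ALL microarray studies (per-dataset rank percentile,
p-value and signed fold change).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_hub_genes", "load_expression_summary", "expression_summary_stats"]


def _fixture_path(name: str):
    return resources.files("hubnet").joinpath("fixtures", name)


def load_hub_genes() -> list[str]:
    """The 42 common hub gene symbols."""
    with _fixture_path("table2_hubs.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df["protein"].tolist()


def load_expression_summary() -> pd.DataFrame:
    """Per-gene two-study differential summary (27 hub genes).

    Columns: ``percentile_a``, ``p_a``, ``fc_a`` for the first study and the
    ``_b`` triple for the second; percentiles are the published "top X%"
    integers, fold changes signed (negative = underexpressed in disease).
    """
    with _fixture_path("table3_expression.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="gene")


def expression_summary_stats() -> tuple[pd.DataFrame, pd.DataFrame]:
    """The bundled summary reshaped into per-dataset stat frames.

    Each frame is indexed by gene with columns ``p_value``, ``fold_change``
    and ``rank_percentile``, directly consumable by
    :func:`hubnet.expression.meta_combine`.
    """
    df = load_expression_summary()
    a = pd.DataFrame(
        {
            "p_value": df["p_a"],
            "fold_change": df["fc_a"],
            "rank_percentile": df["percentile_a"].astype(float),
        }
    )
    b = pd.DataFrame(
        {
            "p_value": df["p_b"],
            "fold_change": df["fc_b"],
            "rank_percentile": df["percentile_b"].astype(float),
        }
    )
    return a, b
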