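"""Gene-level consensus statistics over a contingency matrix.

Answers "how many genes are up-regulated in exactly / at least k studies",
lists the genes at any consensus level, and reports the per-study calls for
curated marker panels (contractile genes, transcription factors, ion
channels, ...).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contingency import ContingencyMatrix


@dataclass
class ConsensusProfile:
    """Counts of genes by number of supporting studies.

    ``at_least[k]`` and ``exactly[k]`` are dicts keyed k = 1..D; the
    at-least counts are non-increasing in k and at_least[1] equals the
    universe size.
    """

    at_least: dict
    exactly: dict
    gene_to_count: dict

    def to_frame(self) -> pd.DataFrame:
        ks = sorted(self.at_least)
        return pd.DataFrame({
            "k": ks,
            "at_least": [self.at_least[k] for k in ks],
            "exactly": [self.exactly[k] for k in ks],
        })


def consensus_profile(M: ContingencyMatrix) -> ConsensusProfile:
    """Tally genes by the number of studies calling them up-regulated."""
    counts = M.row_sums()
    d = M.n_studies
    exactly = {k: int((counts == k).sum()) for k in range(1, d + 1)}
    at_least = {k: int((counts >= k).sum()) for k in range(1, d + 1)}
    gene_to_count = {g: int(c) for g, c in zip(M.gene_ids, counts)}
    return ConsensusProfile(at_least=at_least, exactly=exactly,
                            gene_to_count=gene_to_count)


def genes_in_at_least(M: ContingencyMatrix, k: int) -> list:
    """Lexicographically ordered genes up-regulated in >= k studies."""
    if not 1 <= k <= M.n_studies:
        raise ValueError(f"k must be in 1..{M.n_studies} (got {k})")
    counts = M.row_sums()
    return sorted(g for g, c in zip(M.gene_ids, counts) if c >= k)


def marker_panel_report(M: ContingencyMatrix, panels: dict) -> pd.DataFrame:
    """Per-gene per-study calls for named marker panels.

    Panel genes absent from the combined universe are flagged and count 0.

    Parameters
    ----------
    panels : dict of str -> iterable of str
        Panel name -> gene identifiers.

    Returns
    -------
    DataFrame with columns panel, gene, one 0/1 column per study,
    n_studies, in_universe.
    """
    if not panels:
        raise ValueError("panels must be non-empty")
    index = {g: i for i, g in enumerate(M.gene_ids)}
    rows = []
    for panel, genes in panels.items():
        for gene in genes:
            gene = str(gene).strip().upper()
            row = {"panel": panel, "gene": gene}
            if gene in index:
                calls = M.entries[index[gene]]
                row.update({s: int(v) for s, v in zip(M.study_ids, calls)})
                row["n_studies"] = int(calls.sum())
                row["in_universe"] = True
            else:
                row.update({s: 0 for s in M.study_ids})
                row["n_studies"] = 0
                row["in_universe"] = False
            rows.append(row)
    return pd.DataFrame(rows)


def go_category_breakdown(genes, collection) -> pd.DataFrame:
    """Term-frequency report of a gene list over a gene-set collection.

    For each set: how many of the given genes belong to it and the fraction
    of the list covered.  A descriptive summary, not a significance test.
    """
    genes = {str(g).strip().upper() for g in genes}
    rows = []
    for gs in collection:
        hit = len(genes & {g.upper() for g in gs.genes})
        if hit:
            rows.append({"set_id": gs.set_id, "name": gs.name,
                         "n_hits": hit,
                         "fraction_of_list": hit / max(len(genes), 1)})
    df = pd.DataFrame(rows, columns=["set_id", "name", "n_hits",
                                     "fraction_of_list"])
    return df.sort_values(["n_hits", "set_id"],
                          ascending=[False, True]).reset_index(drop=True)
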