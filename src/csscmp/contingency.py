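"""Binary gene x study contingency matrices built from up-regulated gene lists.

Each study contributes one column: entry (i, j) is 1 when gene i appears on
study j's list of genes up-regulated in the case condition, 0 otherwise.  The
gene universe is the union of all study lists, so every row has at least one
call.  A gene absent from one study's list scores 0 there even if the gene was
never measured on that study's platform -- a documented limitation of working
from significant-gene lists alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """Invalid inputs or options detected before any computation."""


@dataclass(frozen=True)
class StudyGeneList:
    """One study's harmonized list of up-regulated genes.

    Parameters
    ----------
    study_id : str
        Short unique label for the study (e.g. ``"S1"``).
    genes : frozenset of str
        Harmonized gene identifiers, deduplicated.
    source_note : str
        Free-text provenance: platform, threshold, original list size.
    """

    study_id: str
    genes: frozenset
    source_note: str = ""

    def __post_init__(self):
        if not self.genes:
            raise ConfigurationError(
                f"study {self.study_id!r} has an empty gene list"
            )

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ContingencyMatrix:
    """N x D binary matrix of up-regulation calls.

    Rows are genes (the combined universe, lexicographically ordered), columns
    are studies (input order).  ``entries`` is an int8 array of 0/1.
    """

    gene_ids: list
    study_ids: list
    entries: np.ndarray

    def __post_init__(self):
        self.entries = np.asarray(self.entries, dtype=np.int8)
        if self.entries.shape != (len(self.gene_ids), len(self.study_ids)):
            raise ValueError("entries shape does not match gene/study labels")
        if not np.isin(self.entries, (0, 1)).all():
            raise ValueError("contingency entries must be 0 or 1")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        self._row_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_studies(self) -> int:
        return len(self.study_ids)

    def column_sums(self) -> np.ndarray:
        return self.entries.sum(axis=0)

    def row_sums(self) -> np.ndarray:
        return self.entries.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, index=pd.Index(self.gene_ids, name="gene"),
            columns=self.study_ids,
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "ContingencyMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), list(df.columns),
                   df.to_numpy(dtype=np.int8))


@dataclass
class GeneSetSubmatrix:
    """Rows of a parent contingency matrix restricted to one gene set.

    ``n_genes`` may be 0 when the set does not intersect the universe; such a
    submatrix is flagged unscorable rather than raising.
    """

    set_id: str
    gene_ids: list
    entries: np.ndarray

    def __post_init__(self):
        self.entries = np.asarray(self.entries, dtype=np.int8)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_studies(self) -> int:
        return self.entries.shape[1] if self.entries.ndim == 2 else 0

    @property
    def scorable(self) -> bool:
        return self.n_genes > 0


def harmonize_ids(
    raw_lists: Mapping[str, Iterable[str]],
    alias_map: Mapping[str, str] | None = None,
    source_notes: Mapping[str, str] | None = None,
) -> list:
    """Normalize raw gene identifiers into :class:`StudyGeneList` objects.

    Identifiers are whitespace-stripped and upper-cased, an optional alias map
    (e.g. ANF -> NPPA) is applied, then duplicates are collapsed.  The alias
    map is keyed on the normalized (upper-cased) form.

    Raises
    ------
    ConfigurationError
        If the alias map assigns conflicting targets to one source.
    """
    alias = {}
    if alias_map:
        for src, dst in alias_map.items():
            key = str(src).strip().upper()
            val = str(dst).strip().upper()
            if key in alias and alias[key] != val:
                raise ConfigurationError(
                    f"alias map conflict: {key} -> {alias[key]} and {val}"
                )
            alias[key] = val
    out = []
    for study_id, raw in raw_lists.items():
        raw = list(raw)
        normalized = [str(g).strip().upper() for g in raw if str(g).strip()]
        remapped = [alias.get(g, g) for g in normalized]
        n_remapped = sum(a != b for a, b in zip(normalized, remapped))
        genes = frozenset(remapped)
        n_collapsed = len(remapped) - len(genes)
        logger.info(
            "study %s: %d raw ids -> %d genes (%d remapped, %d collapsed)",
            study_id, len(raw), len(genes), n_remapped, n_collapsed,
        )
        note = (source_notes or {}).get(study_id, "")
        out.append(StudyGeneList(study_id=study_id, genes=genes,
                                 source_note=note))
    return out


def build_contingency(lists: Sequence[StudyGeneList]) -> ContingencyMatrix:
    """Assemble the overall contingency matrix from >= 2 harmonized lists.

    The gene universe is the union of all lists; rows are ordered
    lexicographically and columns follow input order, so output is
    deterministic.
    """
    if len(lists) < 2:
        raise ConfigurationError("need at least 2 studies to build a "
                                 f"contingency matrix (got {len(lists)})")
    study_ids = [sl.study_id for sl in lists]
    if len(set(study_ids)) != len(study_ids):
        raise ConfigurationError(f"duplicate study ids: {study_ids}")
    for sl in lists:
        if not sl.genes:
            raise ConfigurationError(f"study {sl.study_id!r} has no genes")
    universe = sorted(set().union(*(sl.genes for sl in lists)))
    entries = np.zeros((len(universe), len(lists)), dtype=np.int8)
    index = {g: i for i, g in enumerate(universe)}
    for j, sl in enumerate(lists):
        rows = [index[g] for g in sl.genes]
        entries[rows, j] = 1
    return ContingencyMatrix(universe, study_ids, entries)


def extract_submatrix(M: ContingencyMatrix, genes: Iterable[str],
                      set_id: str = "") -> GeneSetSubmatrix:
    """Rows of ``M`` for the given gene set, in parent (lexicographic) order.

    Genes absent from the universe are dropped; an empty intersection yields
    an unscorable submatrix, not an exception.
    """
    members = set(genes)
    keep = [i for i, g in enumerate(M.gene_ids) if g in members]
    return GeneSetSubmatrix(
        set_id=set_id,
        gene_ids=[M.gene_ids[i] for i in keep],
        entries=M.entries[keep, :] if keep
        else np.empty((0, M.n_studies), dtype=np.int8),
    )


def derive_uplist_from_matrix(
    expr: pd.DataFrame,
    case_samples: Sequence[str],
    control_samples: Sequence[str],
    fc_threshold: float = 2.0,
    study_id: str = "derived",
    log2_input: bool = False,
) -> StudyGeneList:
    """Threshold an expression table into an up-regulated gene list.

    A gene is included when mean(case) / mean(control) >= ``fc_threshold``;
    only up-regulation is considered.  Genes whose control mean is 0 cannot be
    assigned a ratio and are excluded with a warning count.

    Parameters
    ----------
    expr : DataFrame
        Genes x samples, non-negative linear-scale values (set
        ``log2_input=True`` for log2 data, which is exponentiated first).
    """
    if not case_samples or not control_samples:
        raise ConfigurationError("need >=1 sample per group")
    table = expr[list(case_samples) + list(control_samples)]
    if log2_input:
        table = np.power(2.0, table)
    if (table.to_numpy() < 0).any():
        raise ConfigurationError("expression values must be non-negative")
    case_mean = table[list(case_samples)].mean(axis=1)
    ctrl_mean = table[list(control_samples)].mean(axis=1)
    zero_ctrl = ctrl_mean == 0
    if zero_ctrl.any():
        logger.warning("%d genes excluded: control mean is 0",
                       int(zero_ctrl.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = case_mean / ctrl_mean
    up = fc.index[(~zero_ctrl) & np.isfinite(fc) & (fc >= fc_threshold)]
    note = (f"derived: FC>={fc_threshold}, {len(case_samples)} case vs "
            f"{len(control_samples)} control samples")
    return StudyGeneList(study_id=study_id,
                         genes=frozenset(str(g).strip().upper() for g in up),
                         source_note=note)


def read_gene_list(path) -> list:
    """Read one identifier per line; '#' comments and blanks ignored.

    Also accepts a two-column TSV dialect ``gene<TAB>fold_change`` (the fold
    change is ignored here; the list is assumed pre-thresholded).
    """
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        token = line.split("\t")[0].strip()
        if token and token.lower() not in {"gene", "gene_symbol"}:
            genes.append(token)
    return genes
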